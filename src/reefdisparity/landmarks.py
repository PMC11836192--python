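"""Landmark morphometrics: TPS I/O, Generalized Procrustes Analysis, trait
ratios, and the morphospace (PCA scores + convex-hull morphological richness).

The unit of data is a :class:`LandmarkConfiguration` — one individual's k
two-dimensional landmarks plus taxonomy/location metadata. Datasets are plain
lists of configurations; helpers stack them into ``(n, k, 2)`` arrays and a
metadata :class:`pandas.DataFrame`.

Shape superimposition is a partial (reflection-free) Procrustes fit: every
configuration is translated to zero centroid, scaled to unit centroid size and
rotated to the iteratively re-estimated consensus. Linear trait measures are
Euclidean distances between landmark pairs, combined into dimensionless
ratios; because ratios of distances are invariant to translation, rotation and
scaling, they are extracted from the raw (pre-alignment) coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "LandmarkConfiguration",
    "TraitDefinition",
    "Morphospace",
    "TPSFormatError",
    "DEFAULT_LANDMARK_SCHEME",
    "DEFAULT_TRAITS",
    "read_tps",
    "write_tps",
    "configs_to_array",
    "configs_metadata",
    "GeneralizedProcrustes",
    "gpa_align",
    "extract_traits",
    "morphospace_pca",
    "mric",
]


class TPSFormatError(ValueError):
    """A TPS file violates the LM=/coordinate-line convention."""


@dataclass
class LandmarkConfiguration:
    """One individual's 2-D landmark configuration with metadata."""

    individual_id: str
    coords: np.ndarray  # (k, 2)
    species: str = ""
    genus: str = ""
    family: str = ""
    location: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"{self.individual_id}: coords must be (k, 2), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValueError(f"{self.individual_id}: need at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.individual_id}: non-finite coordinate")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def centroid_size(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum()))


@dataclass(frozen=True)
class TraitDefinition:
    """A morphological ratio: distance(numerator pair) / distance(denominator pair)."""

    name: str
    numerator: tuple[int, int]
    denominator: tuple[int, int]

    def landmarks_used(self) -> frozenset[int]:
        return frozenset(self.numerator) | frozenset(self.denominator)

    def validate(self, k: int) -> None:
        for i in (*self.numerator, *self.denominator):
            if not 0 <= i < k:
                raise ValueError(f"trait {self.name}: landmark index {i} out of range for k={k}")


# ---------------------------------------------------------------------------
# Default 14-landmark convention and trait registry.
#
# The landmark indices below are a repository convention for a left-facing
# fish body; users with their own digitization scheme override the registry.
DEFAULT_LANDMARK_SCHEME: dict[int, str] = {
    0: "snout tip",
    1: "posterior tip of the jaw",
    2: "anterior margin of the eye",
    3: "posterior margin of the eye",
    4: "dorsal-fin origin",
    5: "dorsal-fin end",
    6: "caudal peduncle, dorsal",
    7: "caudal peduncle, ventral",
    8: "caudal-fin base midpoint",
    9: "anal-fin end",
    10: "anal-fin origin",
    11: "pelvic-fin origin",
    12: "posterior margin of the opercle",
    13: "ventral margin of the head",
}

# Linear measures on that scheme (pairs of landmark indices):
#   SL standard length (0,8); BD body depth (4,11); PH peduncle height (6,7);
#   PL peduncle length (5,8); AL anal-fin length (10,9); DL dorsal-fin length
#   (4,5); HL head length (0,12); JL jaw length (0,1); ED eye diameter (2,3);
#   preA pre-anal length (0,10); preD pre-dorsal length (0,4);
#   preE pre-eye length (0,2).
DEFAULT_TRAITS: tuple[TraitDefinition, ...] = (
    TraitDefinition("body_elongation", (0, 8), (4, 11)),          # SL / BD
    TraitDefinition("caudal_peduncle_elongation", (5, 8), (6, 7)),  # PL / PH
    TraitDefinition("caudal_peduncle_body_height", (6, 7), (4, 11)),  # PH / BD
    TraitDefinition("std_anal_fin_length", (10, 9), (0, 8)),      # AL / SL
    TraitDefinition("std_dorsal_fin_length", (4, 5), (0, 8)),     # DL / SL
    TraitDefinition("jaw_head_length", (0, 1), (0, 12)),          # JL / HL
    TraitDefinition("eye_head_size", (2, 3), (0, 12)),            # ED / HL
    TraitDefinition("std_preanal_length", (0, 10), (0, 8)),       # preA / SL
    TraitDefinition("std_predorsal_length", (0, 4), (0, 8)),      # preD / SL
    TraitDefinition("eye_head_position", (0, 2), (0, 12)),        # preE / HL
)


# ---------------------------------------------------------------------------
# TPS I/O


def read_tps(
    path: str | Path,
    metadata: str | Path | pd.DataFrame | None = None,
) -> list[LandmarkConfiguration]:
    """Read a TPS landmark file into a list of configurations.

    Records begin with ``LM=k`` followed by k ``x y`` lines and optional
    ``IMAGE=``, ``ID=`` and ``SCALE=`` lines. Coordinates are multiplied by
    SCALE when present. ``metadata`` is an optional sidecar table (CSV path or
    DataFrame) with columns ``individual_id, species, genus, family, location``
    merged by individual id.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[dict] = []
    current: dict | None = None
    expect_coords = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM="):
            if current is not None and expect_coords > 0:
                raise TPSFormatError(
                    f"record {len(records) + 1}: expected {expect_coords} more "
                    f"coordinate line(s) before line {lineno}"
                )
            if current is not None:
                records.append(current)
            try:
                k = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise TPSFormatError(f"line {lineno}: malformed LM= line {line!r}") from exc
            current = {"k": k, "coords": [], "id": None, "scale": None, "image": None}
            expect_coords = k
        elif current is None:
            raise TPSFormatError(f"line {lineno}: content before first LM= record")
        elif expect_coords > 0:
            parts = line.split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (IndexError, ValueError) as exc:
                raise TPSFormatError(
                    f"line {lineno}: non-numeric coordinate line {line!r}"
                ) from exc
            current["coords"].append((x, y))
            expect_coords -= 1
        elif upper.startswith("ID="):
            current["id"] = line.split("=", 1)[1].strip()
        elif upper.startswith("SCALE="):
            current["scale"] = float(line.split("=", 1)[1])
        elif upper.startswith("IMAGE="):
            current["image"] = line.split("=", 1)[1].strip()
        else:
            raise TPSFormatError(f"line {lineno}: unexpected content {line!r}")
    if current is not None:
        if expect_coords > 0:
            raise TPSFormatError(
                f"record {len(records) + 1}: truncated record "
                f"({expect_coords} coordinate line(s) missing)"
            )
        records.append(current)
    if not records:
        raise TPSFormatError(f"{path}: no LM= records found")

    ks = {r["k"] for r in records}
    if len(ks) > 1:
        bad = next(i for i, r in enumerate(records) if r["k"] != records[0]["k"])
        raise TPSFormatError(
            f"record {bad + 1}: LM={records[bad]['k']} differs from LM={records[0]['k']}"
        )

    meta_df: pd.DataFrame | None = None
    if metadata is not None:
        meta_df = metadata if isinstance(metadata, pd.DataFrame) else pd.read_csv(metadata)
        meta_df = meta_df.set_index(meta_df["individual_id"].astype(str))

    configs = []
    for i, rec in enumerate(records):
        coords = np.asarray(rec["coords"], dtype=float)
        if rec["scale"] is not None:
            coords = coords * rec["scale"]
        ind_id = rec["id"] if rec["id"] is not None else (rec["image"] or f"record_{i + 1}")
        kwargs: dict = {}
        if meta_df is not None and ind_id in meta_df.index:
            row = meta_df.loc[ind_id]
            kwargs = {
                key: str(row[key])
                for key in ("species", "genus", "family", "location")
                if key in meta_df.columns
            }
        configs.append(
            LandmarkConfiguration(
                individual_id=str(ind_id), coords=coords, scale=rec["scale"], **kwargs
            )
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file (LM=, coordinate lines, ID=)."""
    out = []
    for cfg in configs:
        out.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.coords:
            out.append(f"{x:.10g} {y:.10g}")
        out.append(f"ID={cfg.individual_id}")
    Path(path).write_text("\n".join(out) + "\n")


def configs_to_array(configs: Sequence[LandmarkConfiguration]) -> np.ndarray:
    """Stack configurations into an (n, k, 2) array, enforcing a common k."""
    ks = {c.n_landmarks for c in configs}
    if len(ks) != 1:
        raise ValueError(f"configurations disagree on landmark count: {sorted(ks)}")
    return np.stack([c.coords for c in configs])


def configs_metadata(configs: Sequence[LandmarkConfiguration]) -> pd.DataFrame:
    """Metadata table (one row per configuration), indexed by individual id."""
    df = pd.DataFrame(
        {
            "individual_id": [c.individual_id for c in configs],
            "species": [c.species for c in configs],
            "genus": [c.genus for c in configs],
            "family": [c.family for c in configs],
            "location": [c.location for c in configs],
        }
    )
    return df.set_index("individual_id", drop=False)


# ---------------------------------------------------------------------------
# Generalized Procrustes Analysis


def _center_and_size(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each (k,2) configuration; return centered coords and centroid sizes."""
    centered = coords - coords.mean(axis=-2, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(-2, -1)))
    return centered, sizes


def _optimal_rotation_angles(shapes: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotation angle (per shape) best aligning each centered shape to reference.

    2-D closed form: theta = atan2(sum(x × y), sum(x · y)); a pure rotation,
    never a reflection.
    """
    dots = np.einsum("nki,ki->n", shapes, reference)
    crosses = (shapes[..., 0] * reference[..., 1]
               - shapes[..., 1] * reference[..., 0]).sum(axis=1)
    return np.arctan2(crosses, dots)


def _rotate(shapes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    c, s = np.cos(angles), np.sin(angles)
    rot = np.empty((len(angles), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    return np.einsum("nkj,nij->nki", shapes, rot)


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Generalized Procrustes superimposition of 2-D landmark configurations.

    ``fit`` estimates the consensus (mean) shape by iterative superimposition:
    each configuration is translated to zero centroid, scaled to unit centroid
    size and rotated (no reflection) onto the current consensus; the consensus
    is re-estimated and re-normalized until its Frobenius change falls below
    ``tol``. ``transform`` superimposes configurations onto the fitted
    consensus.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the Frobenius norm of the consensus change.
    max_iter : int
        Iteration cap.

    Attributes
    ----------
    mean_shape_ : ndarray of shape (k, 2)
        Consensus configuration (zero centroid, unit centroid size).
    n_iter_ : int
        Iterations actually run.
    objective_path_ : ndarray
        Summed squared distance of aligned shapes to the consensus after each
        iteration (non-increasing).
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def _validate(self, X, ids: Sequence[str] | None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 2:
            raise ValueError(f"expected (n, k, 2) landmark array, got {X.shape}")
        if X.shape[0] < 1:
            raise ValueError("need at least one configuration")
        centered, sizes = _center_and_size(X)
        zero = np.flatnonzero(sizes <= 0)
        if zero.size:
            name = ids[zero[0]] if ids is not None else f"index {zero[0]}"
            raise ValueError(f"degenerate configuration (centroid size 0): {name}")
        return centered / sizes[:, None, None]

    def fit(self, X, y=None, *, ids: Sequence[str] | None = None):
        """Estimate the consensus shape from (n, k, 2) coordinates."""
        shapes = self._validate(X, ids)
        if shapes.shape[0] < 2:
            self.mean_shape_ = shapes[0]
            self.n_iter_ = 0
            self.objective_path_ = np.array([0.0])
            self._fitted_aligned = shapes.copy()
            return self
        consensus = shapes[0]
        objective = []
        for it in range(1, self.max_iter + 1):
            aligned = _rotate(shapes, _optimal_rotation_angles(shapes, consensus))
            new_consensus = aligned.mean(axis=0)
            size = np.sqrt((new_consensus**2).sum())
            if size <= 0:
                raise ValueError("degenerate consensus (all shapes cancel)")
            new_consensus = new_consensus / size
            objective.append(float(((aligned - new_consensus) ** 2).sum()))
            delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
            consensus = new_consensus
            if delta < self.tol:
                break
        # final pass against the converged consensus
        aligned = _rotate(shapes, _optimal_rotation_angles(shapes, consensus))
        self.mean_shape_ = consensus
        self.n_iter_ = it
        self.objective_path_ = np.asarray(objective)
        self._fitted_aligned = aligned
        return self

    def transform(self, X, *, ids: Sequence[str] | None = None) -> np.ndarray:
        """Superimpose (n, k, 2) configurations onto the fitted consensus."""
        if not hasattr(self, "mean_shape_"):
            raise ValueError("GeneralizedProcrustes instance is not fitted yet")
        shapes = self._validate(X, ids)
        return _rotate(shapes, _optimal_rotation_angles(shapes, self.mean_shape_))

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        self.fit(X, **kwargs)
        return self._fitted_aligned


def gpa_align(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[LandmarkConfiguration], np.ndarray]:
    """Align a dataset by GPA; return (aligned configurations, consensus shape)."""
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    X = configs_to_array(configs)
    ids = [c.individual_id for c in configs]
    gpa = GeneralizedProcrustes(tol=tol, max_iter=max_iter)
    aligned = gpa.fit_transform(X, ids=ids)
    out = [replace(c, coords=a, scale=None) for c, a in zip(configs, aligned)]
    return out, gpa.mean_shape_


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations (after centering,
    unit-size scaling and optimal rotation of b onto a)."""
    ca, sa = _center_and_size(np.asarray(a, dtype=float))
    cb, sb = _center_and_size(np.asarray(b, dtype=float))
    ca, cb = ca / sa, cb / sb
    rb = _rotate(cb[None], _optimal_rotation_angles(cb[None], ca))[0]
    return float(np.sqrt(((ca - rb) ** 2).sum()))


# ---------------------------------------------------------------------------
# Trait ratios


def extract_traits(
    configs: Sequence[LandmarkConfiguration],
    trait_definitions: Iterable[TraitDefinition] = DEFAULT_TRAITS,
    *,
    min_denominator: float = 1e-12,
) -> pd.DataFrame:
    """Compute the trait-ratio table from raw landmark coordinates.

    One row per configuration (carrying its metadata), one column per trait:
    ratio = d(numerator pair) / d(denominator pair) of Euclidean landmark
    distances. Ratios are similarity-invariant, so raw (pre-GPA) coordinates
    are used.
    """
    defs = list(trait_definitions)
    X = configs_to_array(configs)
    k = X.shape[1]
    for t in defs:
        t.validate(k)
    table = configs_metadata(configs)
    for t in defs:
        num = np.linalg.norm(X[:, t.numerator[0]] - X[:, t.numerator[1]], axis=1)
        den = np.linalg.norm(X[:, t.denominator[0]] - X[:, t.denominator[1]], axis=1)
        bad = np.flatnonzero(den <= min_denominator)
        if bad.size:
            raise ValueError(
                f"trait {t.name}: zero denominator distance for individual "
                f"{configs[bad[0]].individual_id}"
            )
        table[t.name] = num / den
    return table


# ---------------------------------------------------------------------------
# Morphospace


@dataclass
class Morphospace:
    """PCA morphospace of aligned shapes.

    ``scores`` holds per-configuration coordinates on the principal axes,
    ``explained_variance`` the fraction of total shape variance per axis, and
    ``mric`` convex-hull areas (first two axes by default) per group plus
    ``overall``.
    """

    scores: pd.DataFrame
    explained_variance: np.ndarray
    components: np.ndarray
    mric: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def morphospace_pca(
    aligned: np.ndarray | Sequence[LandmarkConfiguration],
    n_axes: int | None = None,
    index: Sequence[str] | None = None,
) -> Morphospace:
    """PCA of flattened aligned shapes ((n, 2k) vectors), axes ordered by
    decreasing variance; ``n_axes`` above the available rank is clamped with a
    warning."""
    if not isinstance(aligned, np.ndarray):
        if index is None:
            index = [c.individual_id for c in aligned]
        aligned = configs_to_array(aligned)
    flat = aligned.reshape(aligned.shape[0], -1)
    rank = min(flat.shape[0] - 1, flat.shape[1])
    if n_axes is None:
        n_axes = rank
    elif n_axes > rank:
        warnings.warn(
            f"n_axes={n_axes} exceeds available rank {rank}; clamping", stacklevel=2
        )
        n_axes = rank
    pca = PCA(n_components=n_axes)
    scores = pca.fit_transform(flat)
    idx = index if index is not None else pd.RangeIndex(len(flat))
    return Morphospace(
        scores=pd.DataFrame(
            scores, index=idx, columns=[f"PC{i + 1}" for i in range(n_axes)]
        ),
        explained_variance=pca.explained_variance_ratio_,
        components=pca.components_,
    )


def mric(
    scores: pd.DataFrame | np.ndarray,
    groups: Sequence[str] | None = None,
    n_axes: int = 2,
) -> pd.Series:
    """Morphological richness: convex-hull area on the first ``n_axes`` score
    axes, per group and overall. Groups with < 3 points or collinear points get
    0 with a warning."""
    pts = np.asarray(scores)[:, :n_axes]

    def hull_area(p: np.ndarray, label: str) -> float:
        if p.shape[0] < 3:
            warnings.warn(f"MRic({label}): fewer than 3 points; recording 0", stacklevel=3)
            return 0.0
        try:
            return float(ConvexHull(p).volume)  # 2-D "volume" is the area
        except QhullError:
            warnings.warn(f"MRic({label}): degenerate (collinear) points; recording 0",
                          stacklevel=3)
            return 0.0

    out = {"overall": hull_area(pts, "overall")}
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            out[str(g)] = hull_area(pts[groups == g], str(g))
    return pd.Series(out, name="mric")
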