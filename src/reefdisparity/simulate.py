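"""Synthetic multi-species study generator with known ground truth.

Emulates the statistical structure of a multi-location reef-fish study:

* a pure-birth ultrametric phylogeny whose clade structure defines genera and
  families;
* species mean shapes = a fish-like 14-landmark template plus Brownian
  deviation along the tree, location effects as per-(species, location)
  displacements of designated landmarks with species magnitude δ_s, isotropic
  individual noise σ, and a random similarity transform per individual (so
  superimposition is actually exercised);
* island-model SNP genotypes per species: ancestral frequency p0 per locus,
  population frequencies p_k ~ Beta(p0(1-F)/F, (1-p0)(1-F)/F) with target
  differentiation F, genotypes Binomial(2, p_k);
* dispersal traits (adult body size, pelagic larval duration) correlated
  positively with a species' expected total diversity and negatively with its
  differentiation F;
* optional diversity→disparity coupling κ: δ_s = δ0·(1 + κ·z(J_index,s)),
  clipped at zero, where J_index is the species' expected total diversity
  computed from the drawn population allele frequencies. Ground truth (δ_s,
  F_s, J_index, which traits a location effect touches) is stored with every
  dataset.

Defaults reproduce the study design scale: 17 species in 10 families, 4
locations, 20 individuals per species per location, 500 loci per species.
Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from ._seeds import as_rng, child_rng
from .landmarks import (
    DEFAULT_TRAITS,
    LandmarkConfiguration,
    TraitDefinition,
    write_tps,
)
from .popgen import GenotypeMatrix, write_vcf

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "FISH_TEMPLATE",
    "simulate_tree",
    "taxonomy_from_tree",
    "simulate_genotypes",
    "expected_hill_index",
    "simulate_landmarks",
    "simulate_study",
]

# A fish-like left-facing body outline for the default 14-landmark scheme
# (see landmarks.DEFAULT_LANDMARK_SCHEME). Only the geometry matters for the
# statistics; coordinates are dimensionless, body length ~ 1.
FISH_TEMPLATE: np.ndarray = np.array(
    [
        [0.00, 0.50],  # 0 snout tip
        [0.10, 0.42],  # 1 posterior jaw
        [0.12, 0.60],  # 2 eye anterior
        [0.22, 0.60],  # 3 eye posterior
        [0.45, 0.78],  # 4 dorsal-fin origin
        [0.80, 0.72],  # 5 dorsal-fin end
        [0.88, 0.58],  # 6 peduncle dorsal
        [0.88, 0.42],  # 7 peduncle ventral
        [0.95, 0.50],  # 8 caudal-fin base midpoint
        [0.80, 0.30],  # 9 anal-fin end
        [0.60, 0.25],  # 10 anal-fin origin
        [0.38, 0.26],  # 11 pelvic-fin origin
        [0.28, 0.50],  # 12 opercle posterior
        [0.15, 0.32],  # 13 ventral head
    ]
)

# Landmarks a location effect displaces by default: fins, peduncle, caudal
# base. Head landmarks (0-3, 12, 13) stay put, so head-based ratios act as
# negative controls.
DEFAULT_DISPLACED_LANDMARKS: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    The defaults are the emulated study conditions: 17 species / 10 families /
    4 locations / 20 individuals per species-location / 500 SNP loci, with a
    location-effect magnitude δ0 and landmark noise σ chosen so per-location
    mean shifts are a few percent of a trait value (of the order that separates
    the clearly detectable from the undetectable at n = 20 per location).
    """

    n_species: int = 17
    family_sizes: tuple[int, ...] = (3, 3, 2, 2, 2, 1, 1, 1, 1, 1)
    n_locations: int = 4
    individuals_per_location: int = 20
    n_landmarks: int = 14
    location_effect: float = 0.08        # δ0, landmark displacement scale
    landmark_noise: float = 0.02         # σ, per-individual isotropic noise
    bm_scale: float = 0.05               # Brownian shape deviation per unit depth
    displaced_landmarks: tuple[int, ...] = DEFAULT_DISPLACED_LANDMARKS
    coupling: float = 0.0                # κ, diversity→disparity coupling
    n_loci: int = 500
    n_per_pop: int = 20                  # genotyped individuals per population
    fst_range: tuple[float, float] = (0.02, 0.30)
    diversity_range: tuple[float, float] = (0.3, 1.0)  # per-species p0 spread scale
    missing_rate: float = 0.0
    dispersal_coupling: float = 0.7      # strength of dispersal ~ diversity link
    # interspecific (species-level) dataset emulating a one-adult-per-species
    # reference collection
    inter_species_per_genus: int = 3
    inter_genera_per_family: int = 3
    inter_genus_effect: float = 0.06     # genus displacement scale γ0
    inter_congruence: float = 0.8        # links family γ to its members' mean δ
    master_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.family_sizes) != self.n_species:
            raise ValueError("family_sizes must sum to n_species")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must be in [0, 1]")
        if self.location_effect < 0 or self.landmark_noise < 0:
            raise ValueError("effect scales must be non-negative")
        if max(self.displaced_landmarks, default=0) >= self.n_landmarks:
            raise ValueError("displaced landmark index out of range")


@dataclass
class GroundTruth:
    """What was injected: per species δ, F, expected diversity; per trait,
    whether a location effect touches any of its landmarks."""

    species: pd.DataFrame          # index species; delta, fst, j_index, diversity_scale
    affected_traits: dict[str, bool]

    def to_json(self) -> str:
        return json.dumps(
            {
                "species": self.species.reset_index().to_dict(orient="list"),
                "affected_traits": self.affected_traits,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        df = pd.DataFrame(obj["species"]).set_index("species")
        return cls(species=df, affected_traits=dict(obj["affected_traits"]))


# ---------------------------------------------------------------------------
# Tree


def simulate_tree(n_species: int, seed: int | None = None) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_species`` tips, rescaled to
    depth 1; tips are labeled sp01, sp02, ... in ladderized leaf order."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    from dendropy.simulate import treesim

    py_rng = random.Random(0 if seed is None else int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=py_rng,
    )
    # The simulator stops exactly at the n-th speciation, leaving the youngest
    # pair with zero terminal branches; extend all tips by the Exp(n·λ) waiting
    # time to the next (unobserved) event so every terminal branch is positive.
    extra = py_rng.expovariate(n_species * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    tree.ladderize()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:02d}"
    return tree


def taxonomy_from_tree(tree: dendropy.Tree, family_sizes: Sequence[int]) -> pd.DataFrame:
    """Assign genera and families to tips by contiguous blocks of the
    ladderized leaf order, so closely related species share genera/families.

    Within a family of m species, genera are blocks of at most 2 species,
    giving every multi-species family at least 2 genera.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if sum(family_sizes) != len(leaves):
        raise ValueError("family sizes must sum to the number of tips")
    rows = []
    pos = 0
    for f_idx, size in enumerate(family_sizes):
        members = leaves[pos:pos + size]
        pos += size
        g_idx = 0
        for start in range(0, size, 2):
            g_idx += 1
            for sp in members[start:start + 2]:
                rows.append(
                    {"species": sp, "genus": f"gen{f_idx + 1:02d}_{g_idx}",
                     "family": f"fam{f_idx + 1:02d}"}
                )
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(
    n_pops: int,
    n_per_pop: int,
    n_loci: int,
    fst: float,
    seed: int | np.random.Generator | None = None,
    diversity_scale: float = 1.0,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Island-model genotypes with target differentiation ``fst``.

    Ancestral frequencies follow a symmetric Beta(a, a) site-frequency
    spectrum (clipped to [0.05, 0.95]) whose concentration a rises with
    ``diversity_scale``: U-shaped spectra (frequencies near the edges) give
    low expected heterozygosity, spectra concentrated near 0.5 give high.
    Population frequencies p_k are Beta-distributed around p0 with
    Var(p_k) = fst·p0·(1-p0) (p_k = p0 when fst = 0); genotypes are
    Binomial(2, p_k) per diploid individual. Returns the genotype matrix and
    the (n_pops, n_loci) population allele frequencies (the ground truth).
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must be in [0, 1)")
    rng = as_rng(seed)
    a = 10.0 ** (2.0 * float(np.clip(diversity_scale, 0.0, 1.0)) - 1.0)
    p0 = np.clip(rng.beta(a, a, size=n_loci), 0.05, 0.95)
    if fst == 0:
        p_k = np.repeat(p0[None, :], n_pops, axis=0)
    else:
        a = p0 * (1 - fst) / fst
        b = (1 - p0) * (1 - fst) / fst
        p_k = rng.beta(a, b, size=(n_pops, n_loci))
    geno = rng.binomial(2, p_k[:, None, :], size=(n_pops, n_per_pop, n_loci))
    geno = geno.reshape(n_pops * n_per_pop, n_loci).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    populations = np.repeat([f"loc{i + 1}" for i in range(n_pops)], n_per_pop)
    samples = [f"{populations[i]}_ind{i % n_per_pop + 1:03d}" for i in range(len(populations))]
    gm = GenotypeMatrix(
        genotypes=geno,
        populations=populations.astype(object),
        samples=samples,
        locus_ids=[f"locus{j + 1:04d}" for j in range(n_loci)],
    )
    return gm, p_k


def expected_hill_index(pop_freqs: np.ndarray) -> float:
    """Expected total diversity J = 1/(1-H_T) at infinite sample size, from the
    drawn population allele frequencies (unweighted pbar over populations)."""
    pbar = pop_freqs.mean(axis=0)
    h_t = float(np.mean(2 * pbar * (1 - pbar)))
    return 1.0 / (1.0 - h_t)


# ---------------------------------------------------------------------------
# Landmarks


def _brownian_deviations(
    tree: dendropy.Tree, n_dims: int, scale: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Brownian deviations along the tree: each node inherits its parent's
    value plus N(0, scale²·edge_length) per dimension."""
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        parent = values.get(id(node.parent_node), np.zeros(n_dims))
        edge = node.edge.length or 0.0
        values[id(node)] = parent + rng.normal(0.0, scale * np.sqrt(edge), size=n_dims)
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def _random_similarity(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0, 2 * np.pi)
    s = rng.uniform(0.7, 1.4)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    t = rng.uniform(-1, 1, size=2)
    return s * coords @ R.T + t


def _affected_traits(
    trait_definitions: Sequence[TraitDefinition], displaced: Sequence[int]
) -> dict[str, bool]:
    displaced_set = set(displaced)
    return {
        t.name: bool(t.landmarks_used() & displaced_set) for t in trait_definitions
    }


def simulate_landmarks(
    config: SimulationConfig,
    tree: dendropy.Tree,
    taxonomy: pd.DataFrame,
    delta_per_species: pd.Series,
    seed: int | np.random.Generator | None = None,
    apply_similarity: bool = True,
    species_means: dict[str, np.ndarray] | None = None,
) -> list[LandmarkConfiguration]:
    """Individual landmark configurations for every (species, location).

    Species mean = template + Brownian deviation along the tree (or the
    ``species_means`` passed in); location effect = a fixed displacement of
    the designated landmarks drawn per (species, location) with magnitude
    δ_s; individual noise is isotropic Gaussian σ on all landmarks; finally a
    random similarity transform is applied per individual.
    """
    k = config.n_landmarks
    if k != FISH_TEMPLATE.shape[0]:
        raise ValueError("the built-in template defines 14 landmarks")
    rng = as_rng(seed)
    if species_means is None:
        devs = _brownian_deviations(tree, 2 * k, config.bm_scale, rng)
        species_means = {sp: FISH_TEMPLATE + devs[sp].reshape(k, 2) for sp in taxonomy.index}
    displaced = np.asarray(config.displaced_landmarks, dtype=int)
    configs = []
    for sp in taxonomy.index:
        mean_shape = species_means[sp]
        delta = float(delta_per_species[sp])
        meta = taxonomy.loc[sp]
        for loc_i in range(config.n_locations):
            loc = f"loc{loc_i + 1}"
            shift = np.zeros((k, 2))
            if delta > 0 and displaced.size:
                shift[displaced] = rng.normal(0.0, delta, size=(displaced.size, 2))
            loc_mean = mean_shape + shift
            for ind_i in range(config.individuals_per_location):
                coords = loc_mean + rng.normal(0.0, config.landmark_noise, size=(k, 2))
                if apply_similarity:
                    coords = _random_similarity(coords, rng)
                configs.append(
                    LandmarkConfiguration(
                        individual_id=f"{sp}_{loc}_i{ind_i + 1:03d}",
                        coords=coords,
                        species=sp,
                        genus=str(meta["genus"]),
                        family=str(meta["family"]),
                        location=loc,
                    )
                )
    return configs


def _simulate_inter_landmarks(
    config: SimulationConfig,
    taxonomy: pd.DataFrame,
    species_means: dict[str, np.ndarray],
    delta_per_species: pd.Series,
    rng: np.random.Generator,
) -> list[LandmarkConfiguration]:
    """Species-level interspecific dataset (one adult per species).

    Per family: base shape = mean of its member species' mean shapes; each
    genus displaces the designated landmarks with magnitude
    γ_f = γ0·(1 + ρ·z(mean member δ)), so families whose members carry strong
    location effects also spread their genera (tunable congruence ρ); species
    scatter within genus with a smaller displacement.
    """
    k = config.n_landmarks
    displaced = np.asarray(config.displaced_landmarks, dtype=int)
    fam_delta = delta_per_species.groupby(taxonomy["family"]).mean()
    z = (fam_delta - fam_delta.mean()) / (fam_delta.std(ddof=0) or 1.0)
    gamma = config.inter_genus_effect * np.clip(1.0 + config.inter_congruence * z, 0.05, None)
    configs = []
    for f_idx, family in enumerate(fam_delta.index):
        members = taxonomy.index[taxonomy["family"] == family]
        base = np.mean([species_means[sp] for sp in members], axis=0)
        g = float(gamma[family])
        for g_idx in range(config.inter_genera_per_family):
            genus_shift = np.zeros((k, 2))
            genus_shift[displaced] = rng.normal(0.0, g, size=(displaced.size, 2))
            for s_idx in range(config.inter_species_per_genus):
                sp_shift = np.zeros((k, 2))
                sp_shift[displaced] = rng.normal(0.0, 0.4 * g, size=(displaced.size, 2))
                coords = base + genus_shift + sp_shift + rng.normal(
                    0.0, config.landmark_noise, size=(k, 2)
                )
                coords = _random_similarity(coords, rng)
                configs.append(
                    LandmarkConfiguration(
                        individual_id=f"ref_{family}_g{g_idx + 1}_s{s_idx + 1}",
                        coords=coords,
                        species=f"ref_{family}_g{g_idx + 1}_s{s_idx + 1}",
                        genus=f"ref_{family}_g{g_idx + 1}",
                        family=family,
                        location="reference",
                    )
                )
    return configs


# ---------------------------------------------------------------------------
# Whole study


@dataclass
class SimulatedStudy:
    """A self-contained synthetic study bundle (in memory)."""

    config: SimulationConfig
    tree: dendropy.Tree
    taxonomy: pd.DataFrame
    landmarks: list[LandmarkConfiguration]
    inter_landmarks: list[LandmarkConfiguration]
    genotypes: dict[str, GenotypeMatrix]
    dispersal_traits: pd.DataFrame  # index species; body_size_cm, pld_days
    ground_truth: GroundTruth

    @property
    def species(self) -> list[str]:
        return list(self.taxonomy.index)


def simulate_study(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> SimulatedStudy:
    """Generate a full study bundle: landmarks + metadata, per-species
    genotypes, phylogeny, dispersal traits and ground truth.

    When ``out_dir`` is given, writes TPS/CSV/VCF/newick/JSON files the
    pipeline can consume; an existing non-empty directory raises unless
    ``overwrite`` is set.
    """
    config = config or SimulationConfig()
    master = config.master_seed
    tree = simulate_tree(config.n_species, seed=child_rng(master, "tree").integers(2**31))
    taxonomy = taxonomy_from_tree(tree, config.family_sizes)
    species = list(taxonomy.index)

    # genotypes and expected diversity per species
    fst_rng = child_rng(master, "fst")
    fst = pd.Series(
        fst_rng.uniform(*config.fst_range, size=len(species)), index=species
    )
    div_scale = pd.Series(
        fst_rng.uniform(*config.diversity_range, size=len(species)), index=species
    )
    genotypes: dict[str, GenotypeMatrix] = {}
    j_index = {}
    for sp in species:
        gm, freqs = simulate_genotypes(
            n_pops=config.n_locations,
            n_per_pop=config.n_per_pop,
            n_loci=config.n_loci,
            fst=float(fst[sp]),
            seed=child_rng(master, "genotypes", sp),
            diversity_scale=float(div_scale[sp]),
            missing_rate=config.missing_rate,
        )
        genotypes[sp] = gm
        j_index[sp] = expected_hill_index(freqs)
    j_index = pd.Series(j_index)

    # diversity → disparity coupling
    z = (j_index - j_index.mean()) / (j_index.std(ddof=0) or 1.0)
    delta = config.location_effect * np.clip(1.0 + config.coupling * z, 0.0, None)
    delta.name = "delta"

    species_means = {
        sp: FISH_TEMPLATE + dev.reshape(config.n_landmarks, 2)
        for sp, dev in _brownian_deviations(
            tree, 2 * config.n_landmarks, config.bm_scale, child_rng(master, "bm")
        ).items()
    }
    landmarks = simulate_landmarks(
        config, tree, taxonomy, delta,
        seed=child_rng(master, "landmarks"), species_means=species_means,
    )
    inter = _simulate_inter_landmarks(
        config, taxonomy, species_means, delta, child_rng(master, "inter")
    )

    # dispersal traits: latent dispersal ability rises with diversity, falls
    # with differentiation
    d_rng = child_rng(master, "dispersal")
    zf = (fst - fst.mean()) / (fst.std(ddof=0) or 1.0)
    latent = (
        config.dispersal_coupling * z
        - 0.5 * zf
        + np.sqrt(max(1e-9, 1 - config.dispersal_coupling**2))
        * d_rng.standard_normal(len(species))
    )
    body_size = 25.0 * np.exp(0.45 * (latent + 0.3 * d_rng.standard_normal(len(species))))
    pld = 32.0 + 10.0 * (latent + 0.3 * d_rng.standard_normal(len(species)))
    pld = np.clip(pld, 5.0, None)
    dispersal = pd.DataFrame(
        {"body_size_cm": body_size, "pld_days": pld}, index=pd.Index(species, name="species")
    )

    truth = GroundTruth(
        species=pd.DataFrame(
            {
                "delta": delta,
                "fst": fst,
                "diversity_scale": div_scale,
                "j_index": j_index,
            },
            index=pd.Index(species, name="species"),
        ),
        affected_traits=_affected_traits(DEFAULT_TRAITS, config.displaced_landmarks),
    )
    study = SimulatedStudy(
        config=config,
        tree=tree,
        taxonomy=taxonomy,
        landmarks=landmarks,
        inter_landmarks=inter,
        genotypes=genotypes,
        dispersal_traits=dispersal,
        ground_truth=truth,
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir), overwrite=overwrite)
    return study


def _write_study(study: SimulatedStudy, out_dir: Path, overwrite: bool) -> None:
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "genotypes").mkdir(exist_ok=True)

    write_tps(study.landmarks, out_dir / "landmarks.tps")
    meta = pd.DataFrame(
        {
            "individual_id": [c.individual_id for c in study.landmarks],
            "species": [c.species for c in study.landmarks],
            "genus": [c.genus for c in study.landmarks],
            "family": [c.family for c in study.landmarks],
            "location": [c.location for c in study.landmarks],
        }
    )
    meta.to_csv(out_dir / "metadata.csv", index=False)
    write_tps(study.inter_landmarks, out_dir / "inter_landmarks.tps")
    imeta = pd.DataFrame(
        {
            "individual_id": [c.individual_id for c in study.inter_landmarks],
            "species": [c.species for c in study.inter_landmarks],
            "genus": [c.genus for c in study.inter_landmarks],
            "family": [c.family for c in study.inter_landmarks],
            "location": [c.location for c in study.inter_landmarks],
        }
    )
    imeta.to_csv(out_dir / "inter_metadata.csv", index=False)

    popmap_rows = []
    for sp, gm in study.genotypes.items():
        write_vcf(gm, out_dir / "genotypes" / f"{sp}.vcf")
        for s, p in zip(gm.samples, gm.populations):
            popmap_rows.append({"species": sp, "sample_id": s, "population": p})
    pd.DataFrame(popmap_rows).to_csv(out_dir / "popmap.csv", index=False)

    study.tree.write(path=str(out_dir / "tree.nwk"), schema="newick",
                     suppress_rooting=True)
    study.dispersal_traits.to_csv(out_dir / "dispersal_traits.csv")
    (out_dir / "ground_truth.json").write_text(study.ground_truth.to_json())
    cfg = dataclasses.asdict(study.config)
    (out_dir / "manifest.txt").write_text(
        "synthetic study bundle\n"
        + "\n".join(f"{k} = {v}" for k, v in cfg.items())
        + "\n"
    )
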