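"""Cross-scale and cross-data comparative statistics.

Implements the statistics that link the disparity and diversity tables:

* RV coefficient and co-inertia analysis (two-table ordination maximizing
  squared covariance between projections) with a row-permutation test;
* Brownian-motion covariance from a time-calibrated newick tree and
  phylogenetic generalized least squares (PGLS; identity covariance recovers
  OLS exactly);
* PERMANOVA with sequential sums of squares on Euclidean distances (pseudo-F
  per term, row-permutation p-values);
* the dispersal PCA axis from adult body size and pelagic larval duration;
* a piecewise standardized path model (each structural equation fit by OLS on
  z-scored variables).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.decomposition import PCA

from ._seeds import as_rng

__all__ = [
    "rv_coefficient",
    "CoInertia",
    "CoInertiaResult",
    "coinertia",
    "build_paired_tables",
    "bm_covariance",
    "PGLS",
    "ModelFit",
    "pgls_fit",
    "ols_fit",
    "permanova",
    "dispersal_axis",
    "DispersalAxis",
    "path_model",
]


# ---------------------------------------------------------------------------
# RV coefficient & co-inertia


def _center(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=0, keepdims=True)


def rv_coefficient(X, Y) -> float:
    """RV matrix correlation between two column-centered tables with matched
    rows: trace((XᵀY)(YᵀX)) / sqrt(trace((XᵀX)²)·trace((YᵀY)²)), in [0, 1]."""
    Xc, Yc = _center(X), _center(Y)
    if Xc.shape[0] != Yc.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    sxy = Xc.T @ Yc
    sxx = Xc.T @ Xc
    syy = Yc.T @ Yc
    denom = np.sqrt(np.trace(sxx @ sxx) * np.trace(syy @ syy))
    if denom == 0:
        raise ValueError("RV undefined: a table has no variance")
    return float(np.trace(sxy @ sxy.T) / denom)


@dataclass
class CoInertiaResult:
    rv: float
    axis_covariances: np.ndarray  # singular values of the cross-covariance
    perm_p: float
    n_perm: int
    seed: int | None


class CoInertia(BaseEstimator):
    """Co-inertia analysis of two matched tables with an RV permutation test.

    ``fit(X, Y)`` column-centers both tables (uniform row weights), takes the
    SVD of the cross-covariance XᵀY to get the co-inertia axes, and tests the
    observed RV by permuting the rows of Y ``n_perm`` times
    (p = (1 + #{RV_perm >= RV_obs}) / (1 + n_perm)).

    Attributes
    ----------
    rv_ : float
        Observed RV coefficient.
    singular_values_ : ndarray
        Axis covariances (singular values of the centered cross-product).
    x_weights_, y_weights_ : ndarray
        Loadings of X and Y columns on the co-inertia axes.
    perm_p_ : float
        Permutation p-value of RV.
    """

    def __init__(self, n_perm: int = 99, random_state: int | None = None):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, Y):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        Xc, Yc = _center(X), _center(Y)
        self.rv_ = rv_coefficient(Xc, Yc)
        U, s, Vt = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        self.singular_values_ = s
        self.x_weights_ = U
        self.y_weights_ = Vt.T
        rng = as_rng(self.random_state)
        n = Xc.shape[0]
        count = 0
        for _ in range(self.n_perm):
            count += rv_coefficient(Xc, Yc[rng.permutation(n)]) >= self.rv_
        self.perm_p_ = float((1 + count) / (1 + self.n_perm))
        return self

    def result(self) -> CoInertiaResult:
        return CoInertiaResult(
            rv=self.rv_, axis_covariances=self.singular_values_,
            perm_p=self.perm_p_, n_perm=self.n_perm, seed=self.random_state,
        )


def coinertia(X, Y, n_perm: int = 99, seed: int | None = None) -> CoInertiaResult:
    return CoInertia(n_perm=n_perm, random_state=seed).fit(X, Y).result()


def _pcoa_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Principal-coordinate scores from Euclidean distances, keeping all
    positive-eigenvalue axes (exact for Euclidean input)."""
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa

    import warnings as _warnings

    dm = DistanceMatrix(squareform(pdist(table.to_numpy())), ids=[str(i) for i in table.index])
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        ord_ = pcoa(dm, method="eigh")
    eig = ord_.eigvals.to_numpy()
    keep = eig > max(eig.max(), 1.0) * 1e-10
    scores = ord_.samples.to_numpy()[:, keep]
    return pd.DataFrame(scores, index=table.index,
                        columns=[f"PCo{i + 1}" for i in range(keep.sum())])


def build_paired_tables(
    intra: pd.DataFrame,
    inter: pd.DataFrame,
    species_to_family: Mapping[str, str] | pd.Series,
    mode: str = "raw",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair the species-level intraspecific mtD table with the family-level
    interspecific mtD table.

    ``intra``: species × traits; ``inter``: family × traits. Each species' Y
    row is its family's interspecific row (replicated across the family's
    member species, which aligns the two tables row-by-row). Species whose
    family lacks interspecific values are dropped with a warning. ``mode
    "pcoa"`` replaces each table by its principal-coordinate scores from
    Euclidean distances (all positive-eigenvalue axes); with Euclidean
    distances this is an orthogonal change of basis and leaves RV unchanged.
    """
    import warnings as _warnings

    fam = pd.Series(species_to_family)
    keep = [sp for sp in intra.index if fam.get(sp) in set(inter.index)]
    dropped = sorted(set(intra.index) - set(keep))
    if dropped:
        _warnings.warn(f"species without family-level interspecific values dropped: {dropped}",
                       stacklevel=2)
    if not keep:
        raise ValueError("no species left after pairing")
    X = intra.loc[keep]
    Y = inter.loc[[fam[sp] for sp in keep]].set_axis(keep, axis=0)
    if mode == "pcoa":
        X, Y = _pcoa_scores(X), _pcoa_scores(Y)
    elif mode != "raw":
        raise ValueError(f"unknown mode {mode!r}")
    return X, Y


# ---------------------------------------------------------------------------
# Phylogenetics: Brownian covariance and PGLS


def bm_covariance(tree: dendropy.Tree | str | Path, tips: Sequence[str]) -> pd.DataFrame:
    """Brownian-motion covariance from a rooted tree with branch lengths.

    C[i, j] is the root-to-MRCA shared path length of tips i and j; C[i, i]
    the root-to-tip length. The tree is pruned to ``tips`` first (so the root
    of the pruned subtree defines zero shared history). Missing tips raise.
    """
    if not isinstance(tree, dendropy.Tree):
        text = Path(tree).read_text() if Path(str(tree)).exists() else str(tree)
        tree = dendropy.Tree.get(data=text, schema="newick")
    tree = tree.clone(depth=1)
    labels = {t.label for t in tree.taxon_namespace}
    missing = [t for t in tips if t not in labels]
    if missing:
        raise ValueError(f"tips absent from tree: {missing}")
    tree.retain_taxa_with_labels(list(tips))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(tips)}
    root_dist = {}
    for leaf in tree.leaf_node_iter():
        root_dist[leaf.taxon.label] = leaf.distance_from_root()
    n = len(tips)
    C = np.zeros((n, n))
    for i, a in enumerate(tips):
        C[i, i] = root_dist[a]
        for j in range(i + 1, n):
            b = tips[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            C[i, j] = C[j, i] = 0.5 * (root_dist[a] + root_dist[b] - d)
    return pd.DataFrame(C, index=list(tips), columns=list(tips))


@dataclass
class ModelFit:
    """Coefficient table and fit summary of an OLS/PGLS regression."""

    coefficients: pd.DataFrame  # index term; columns estimate, se, t, p
    r_squared: float
    sigma2: float
    df_resid: int
    method: str  # "OLS" | "PGLS"
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def p(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


class PGLS(RegressorMixin, BaseEstimator):
    """Phylogenetic generalized least squares under Brownian motion.

    Generalized least squares with error covariance proportional to the
    Brownian phylogenetic covariance C: b = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y, fit through a
    square-root (Cholesky) transform of C. With ``covariance=None`` (identity)
    the fit is exactly OLS, and the coefficients are invariant to rescaling C
    by any positive constant.

    ``pagel_lambda`` relaxes the strict Brownian assumption by shrinking the
    off-diagonal covariance: V(λ) = λ·C + (1-λ)·diag(C). λ = 1 is strict BM;
    λ = 0 keeps only tip variances (OLS-like inference on an ultrametric
    tree). ``"ml"`` profiles the Gaussian likelihood over a λ grid
    (0..1, step 0.01); this protects the test from the anti-conservative
    behaviour of strict BM when residuals carry no phylogenetic signal.

    Parameters
    ----------
    covariance : ndarray/DataFrame of shape (n, n), optional
        Positive-definite covariance aligned with the rows of X/y; None means
        identity (OLS).
    pagel_lambda : None | float | "ml"
        Branch-length transform; None means λ = 1 (strict BM). Ignored when
        ``covariance`` is None.
    fit_intercept : bool

    Attributes
    ----------
    coef_, intercept_ : fitted coefficients.
    lambda_ : the λ actually used (None for OLS).
    result_ : the underlying statsmodels GLS results object.
    """

    def __init__(self, covariance=None, pagel_lambda=None, fit_intercept: bool = True):
        self.covariance = covariance
        self.pagel_lambda = pagel_lambda
        self.fit_intercept = fit_intercept

    @staticmethod
    def _lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
        return lam * C + (1.0 - lam) * np.diag(np.diag(C))

    @staticmethod
    def _profile_loglik(y, design, V) -> float:
        n = len(y)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(design.T @ Vi @ design, design.T @ Vi @ y)
        r = y - design @ b
        s2 = float(r @ Vi @ r) / n
        sign, logdet = np.linalg.slogdet(V)
        return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        names = [f"x{i + 1}" for i in range(X.shape[1])]
        design = sm.add_constant(X, has_constant="add") if self.fit_intercept else X
        dnames = (["intercept"] + names) if self.fit_intercept else names
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("collinear predictors: design matrix is rank deficient")
        self.lambda_ = None
        if self.covariance is None:
            sigma = None
        else:
            sigma = np.asarray(self.covariance, dtype=float)
            if sigma.shape != (n, n):
                raise ValueError(f"covariance shape {sigma.shape} != ({n}, {n})")
            try:
                np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError as exc:
                raise ValueError("covariance matrix is not positive definite") from exc
            if self.pagel_lambda == "ml":
                grid = np.linspace(0.0, 1.0, 101)
                logliks = [
                    self._profile_loglik(y, design, self._lambda_transform(sigma, g))
                    for g in grid
                ]
                self.lambda_ = float(grid[int(np.argmax(logliks))])
                sigma = self._lambda_transform(sigma, self.lambda_)
            elif self.pagel_lambda is not None:
                lam = float(self.pagel_lambda)
                if not 0.0 <= lam <= 1.0:
                    raise ValueError("pagel_lambda must be in [0, 1]")
                self.lambda_ = lam
                sigma = self._lambda_transform(sigma, lam)
            else:
                self.lambda_ = 1.0
        model = sm.GLS(y, design, sigma=sigma)
        res = model.fit()
        self.result_ = res
        params = np.asarray(res.params, dtype=float)
        if self.fit_intercept:
            self.intercept_ = params[0]
            self.coef_ = params[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = params
        self._dnames = dnames
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def summary_frame(self) -> pd.DataFrame:
        res = self.result_
        return pd.DataFrame(
            {
                "estimate": np.asarray(res.params, dtype=float),
                "se": np.asarray(res.bse, dtype=float),
                "t": np.asarray(res.tvalues, dtype=float),
                "p": np.asarray(res.pvalues, dtype=float),
            },
            index=self._dnames,
        )


def pgls_fit(y, predictors, covariance=None, names: Sequence[str] | None = None,
             pagel_lambda=None) -> ModelFit:
    """Fit y ~ intercept + predictors by PGLS (or OLS when covariance=None).

    ``pagel_lambda=None`` is strict Brownian motion (λ = 1); pass ``"ml"`` for
    the maximum-likelihood λ grid search.
    """
    est = PGLS(covariance=covariance, pagel_lambda=pagel_lambda).fit(predictors, y)
    res = est.result_
    table = est.summary_frame()
    if names is not None:
        table.index = ["intercept"] + list(names)
    return ModelFit(
        coefficients=table,
        r_squared=float(res.rsquared),
        sigma2=float(res.scale),
        df_resid=int(res.df_resid),
        method="OLS" if covariance is None else "PGLS",
        n_obs=int(res.nobs),
    )


def ols_fit(y, predictors, names: Sequence[str] | None = None) -> ModelFit:
    """Ordinary least squares: PGLS with identity covariance."""
    return pgls_fit(y, predictors, covariance=None, names=names)


# ---------------------------------------------------------------------------
# PERMANOVA with sequential sums of squares


def _term_columns(col: pd.Series) -> np.ndarray:
    """Design columns for one model term (numeric as-is; categorical dummy)."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(col, drop_first=True)
    return dummies.to_numpy(dtype=float)


def _hat(Xd: np.ndarray) -> np.ndarray:
    return Xd @ np.linalg.pinv(Xd)


def permanova(
    response: pd.DataFrame | np.ndarray,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """PERMANOVA on Euclidean distances with sequential (Type I) sums of squares.

    The Gower-centered inner-product matrix G = -½·J D² J (J the centering
    projector) decomposes the total SS; term j contributes
    SS_j = tr(H_{1..j} G) - tr(H_{1..j-1} G), with H the hat matrix of the
    design including terms 1..j (plus intercept). Pseudo-F per term uses the
    full-model residual mean square; p-values come from free permutation of
    the response rows. Returns a table with rows = terms, Residual, Total and
    columns df, ss, r2, pseudo_f, p_value.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if len(predictors) != n:
        raise ValueError("response and predictors row counts differ")

    terms = list(predictors.columns)
    blocks = [_term_columns(predictors[t]) for t in terms]
    df_terms = []
    intercept = np.ones((n, 1))
    design = intercept
    for b in blocks:
        prev_rank = np.linalg.matrix_rank(design)
        design = np.hstack([design, b])
        df_terms.append(np.linalg.matrix_rank(design) - prev_rank)
    df_model = sum(df_terms)
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ValueError("more model degrees of freedom than units")

    # Hat matrices of the nested designs (intercept, +term1, +term1+term2, ...)
    hats = []
    cum = intercept
    hats.append(_hat(cum))
    for b in blocks:
        cum = np.hstack([cum, b])
        hats.append(_hat(cum))
    h_full = hats[-1]
    eye = np.eye(n)

    def gower(Ymat: np.ndarray) -> np.ndarray:
        D2 = squareform(pdist(Ymat)) ** 2
        J = eye - np.ones((n, n)) / n
        return -0.5 * J @ D2 @ J

    def seq_stats(G: np.ndarray):
        tr = [float(np.trace(h @ G)) for h in hats]
        ss_terms = np.diff(tr)
        ss_resid = float(np.trace((eye - h_full) @ G))
        ms_resid = ss_resid / df_resid
        F = np.array([
            (ss / df) / ms_resid if df > 0 else np.nan
            for ss, df in zip(ss_terms, df_terms)
        ])
        return ss_terms, ss_resid, F

    G_obs = gower(Y)
    ss_terms, ss_resid, F_obs = seq_stats(G_obs)
    ss_total = float(np.trace(G_obs))

    rng = as_rng(seed)
    count = np.ones(len(terms))  # add-one estimator
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, F_perm = seq_stats(gower(Y[perm]))
        count += F_perm >= F_obs
    pvals = count / (1 + n_perm)

    rows = []
    for t, df, ss, F, p in zip(terms, df_terms, ss_terms, F_obs, pvals):
        rows.append({"term": t, "df": df, "ss": ss, "r2": ss / ss_total,
                     "pseudo_f": F, "p_value": p})
    rows.append({"term": "Residual", "df": df_resid, "ss": ss_resid,
                 "r2": ss_resid / ss_total, "pseudo_f": np.nan, "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "ss": ss_total, "r2": 1.0,
                 "pseudo_f": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Dispersal axis


@dataclass
class DispersalAxis:
    """First PCA axis of z-scored dispersal traits, oriented so the
    correlation with the first trait (body size) is positive."""

    scores: pd.Series
    loadings: pd.Series
    explained_variance: np.ndarray
    trait_correlations: pd.Series


def dispersal_axis(traits: pd.DataFrame) -> DispersalAxis:
    """Rank units along a dispersal gradient: z-score the trait columns
    (body size first, then PLD), run PCA, return oriented axis-1 scores."""
    X = traits.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 units")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = traits.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance trait(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA()
    scores = pca.fit_transform(Z)
    axis1 = scores[:, 0]
    r0 = np.corrcoef(axis1, Z[:, 0])[0, 1]
    if r0 < 0:
        axis1 = -axis1
        pca.components_[0] = -pca.components_[0]
    corr = pd.Series(
        {c: float(np.corrcoef(axis1, Z[:, i])[0, 1]) for i, c in enumerate(traits.columns)}
    )
    return DispersalAxis(
        scores=pd.Series(axis1, index=traits.index, name="dispersal_axis"),
        loadings=pd.Series(pca.components_[0], index=traits.columns),
        explained_variance=pca.explained_variance_ratio_,
        trait_correlations=corr,
    )


# ---------------------------------------------------------------------------
# Piecewise path model


_EQ_RE = re.compile(r"^\s*([\w.]+)\s*~\s*(.+)$")


def _parse_equation(eq: str) -> tuple[str, list[str]]:
    m = _EQ_RE.match(eq)
    if not m:
        raise ValueError(f"malformed equation {eq!r} (expected 'y ~ x1 + x2')")
    response = m.group(1)
    predictors = [p.strip() for p in m.group(2).split("+")]
    if any(not p for p in predictors):
        raise ValueError(f"malformed predictor list in {eq!r}")
    return response, predictors


def path_model(data: pd.DataFrame, equations: Sequence[str]) -> pd.DataFrame:
    """Piecewise path analysis: z-score all variables, fit each structural
    equation by OLS, report standardized coefficients with df and p per path.

    With a single predictor the standardized coefficient equals the Pearson
    correlation. Cyclic equation sets raise.
    """
    parsed = [_parse_equation(eq) for eq in equations]
    # cycle check on the directed graph predictor -> response
    edges = {(p, r) for r, preds in parsed for p in preds}
    nodes = {v for e in edges for v in e}
    adj = {v: [b for a, b in edges if a == v] for v in nodes}
    state: dict[str, int] = {}

    def visit(v: str) -> None:
        state[v] = 1
        for w in adj.get(v, []):
            if state.get(w) == 1:
                raise ValueError("cyclic equation set")
            if state.get(w, 0) == 0:
                visit(w)
        state[v] = 2

    for v in nodes:
        if state.get(v, 0) == 0:
            visit(v)

    used = sorted({v for r, preds in parsed for v in [r, *preds]})
    missing = [v for v in used if v not in data.columns]
    if missing:
        raise ValueError(f"variables absent from data: {missing}")
    Z = (data[used] - data[used].mean()) / data[used].std(ddof=1)

    rows = []
    for response, predictors in parsed:
        fit = ols_fit(Z[response].to_numpy(), Z[predictors].to_numpy(), names=predictors)
        for p_name in predictors:
            rows.append(
                {
                    "response": response,
                    "predictor": p_name,
                    "std_estimate": fit.coef(p_name),
                    "se": float(fit.coefficients.loc[p_name, "se"]),
                    "t": float(fit.coefficients.loc[p_name, "t"]),
                    "df": fit.df_resid,
                    "p_value": fit.p(p_name),
                    "r_squared": fit.r_squared,
                }
            )
    return pd.DataFrame(rows)
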