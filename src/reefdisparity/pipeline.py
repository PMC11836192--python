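"""End-to-end orchestration: from landmark/genotype/tree inputs to tidy
result tables.

The full analysis runs these stages:

1. trait extraction (ratios from raw landmarks) and GPA + morphospace
   (PCA scores, MRic hull areas);
2. intraspecific disparity (mtD across locations per species × trait, with
   permutation SES) and interspecific disparity (mtD across genera per family
   × trait);
3. Hill-number genetic diversity per species (down-sampled to a common number
   of individuals per population and SNPs);
4. comparative statistics: co-inertia/RV between the intra- and interspecific
   mtD tables, per-trait OLS + PGLS of intra on inter disparity, PERMANOVA of
   the intra-mtD matrix on (J_T, J_ST), the dispersal PCA axis, and a
   standardized path model (dispersal → J_T → disparity, dispersal → J_ST).

Everything is deterministic given the master seed; child seeds are derived
per (stage, unit). ``analyze_study`` runs in memory on a loaded or simulated
bundle; ``load_study`` reads a bundle directory; ``run_study`` adds manifest
and CSV output for the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from ._seeds import child_seed
from .comparative import (
    CoInertiaResult,
    DispersalAxis,
    bm_covariance,
    build_paired_tables,
    coinertia,
    dispersal_axis,
    ols_fit,
    path_model,
    permanova,
    pgls_fit,
)
from .disparity import disparity_table, disparity_to_frame
from .landmarks import (
    DEFAULT_TRAITS,
    Morphospace,
    extract_traits,
    gpa_align,
    morphospace_pca,
    mric,
    read_tps,
)
from .popgen import GenotypeMatrix, downsample_diversity, read_genotypes_vcf
from .simulate import SimulatedStudy

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "StudyResults", "analyze_study", "load_study", "run_study"]


@dataclass
class AnalysisParams:
    """Analysis knobs with the study's canonical values as defaults:
    999 permutations for disparity nulls and PERMANOVA, 99 for co-inertia,
    at most 10 individuals per population and 99 SNP down-sampling
    replicates."""

    n_perm_disparity: int = 999
    n_perm_permanova: int = 999
    n_perm_coinertia: int = 99
    max_ind_per_pop: int = 10
    snp_downsample_reps: int = 99
    coinertia_mode: str = "pcoa"
    n_morphospace_axes: int = 2
    # λ for the PGLS fits: "ml" guards against anti-conservative inference
    # when residuals carry no phylogenetic signal; set None for strict BM.
    pagel_lambda: str | float | None = "ml"
    master_seed: int = 0


@dataclass
class StudyResults:
    """All stage outputs of one full analysis run."""

    trait_table: pd.DataFrame
    morphospace: Morphospace
    mric_by_species: pd.Series
    intra_disparity: pd.DataFrame
    inter_disparity: pd.DataFrame
    intra_mtd: pd.DataFrame          # species × traits (observed mtD)
    inter_mtd: pd.DataFrame          # family × traits (observed mtD)
    hill: pd.DataFrame               # species × (J_T, J_S, J_ST, ...)
    coinertia: CoInertiaResult | None
    trait_models: pd.DataFrame       # per-trait OLS + PGLS of intra ~ inter
    diversity_models: pd.DataFrame   # per-trait OLS + PGLS of intra mtD ~ J_T
    permanova_table: pd.DataFrame
    dispersal: DispersalAxis | None
    dispersal_models: pd.DataFrame
    paths: pd.DataFrame
    warnings_log: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trait_table.to_csv(out / "trait_table.csv", index=False)
        self.morphospace.scores.to_csv(out / "morphospace_scores.csv")
        self.mric_by_species.rename("mric").to_csv(out / "mric.csv")
        self.intra_disparity.to_csv(out / "disparity_intraspecific.csv", index=False)
        self.inter_disparity.to_csv(out / "disparity_interspecific.csv", index=False)
        self.hill.to_csv(out / "hill_diversity.csv")
        if self.coinertia is not None:
            pd.Series(
                {
                    "rv": self.coinertia.rv,
                    "perm_p": self.coinertia.perm_p,
                    "n_perm": self.coinertia.n_perm,
                    "seed": self.coinertia.seed,
                }
            ).to_csv(out / "coinertia.csv", header=False)
        self.trait_models.to_csv(out / "trait_models.csv", index=False)
        self.diversity_models.to_csv(out / "diversity_models.csv", index=False)
        self.permanova_table.to_csv(out / "permanova.csv")
        if self.dispersal is not None:
            self.dispersal.scores.rename("dispersal_axis").to_csv(out / "dispersal_axis.csv")
        self.dispersal_models.to_csv(out / "dispersal_models.csv", index=False)
        self.paths.to_csv(out / "path_model.csv", index=False)


def _wide_mtd(disp: pd.DataFrame) -> pd.DataFrame:
    sub = disp[disp["computable"]]
    return sub.pivot(index="unit", columns="trait", values="observed_mtd")


def analyze_study(study: SimulatedStudy, params: AnalysisParams | None = None) -> StudyResults:
    """Run the full analysis on a study bundle (simulated or loaded)."""
    params = params or AnalysisParams()
    seed = params.master_seed
    warn_log: list[str] = []
    trait_names = [t.name for t in DEFAULT_TRAITS]

    # --- morphometrics -----------------------------------------------------
    traits = extract_traits(study.landmarks)
    aligned, _consensus = gpa_align(study.landmarks)
    space = morphospace_pca(aligned, n_axes=max(params.n_morphospace_axes, 2))
    richness = mric(
        space.scores, groups=[c.species for c in aligned], n_axes=params.n_morphospace_axes
    )
    space.mric = richness

    # --- disparity ---------------------------------------------------------
    intra_results = disparity_table(
        traits, trait_names, level="intraspecific",
        n_perm=params.n_perm_disparity, master_seed=seed,
    )
    intra_df = disparity_to_frame(intra_results)
    inter_traits = extract_traits(study.inter_landmarks)
    inter_results = disparity_table(
        inter_traits, trait_names, level="interspecific",
        n_perm=params.n_perm_disparity, master_seed=seed,
    )
    inter_df = disparity_to_frame(inter_results)
    intra_mtd = _wide_mtd(intra_df)
    inter_mtd = _wide_mtd(inter_df)

    # --- genetic diversity -------------------------------------------------
    common_snps = min(gm.n_loci for gm in study.genotypes.values())
    hill_rows = {}
    for sp, gm in study.genotypes.items():
        ds = downsample_diversity(
            gm,
            max_ind_per_pop=params.max_ind_per_pop,
            n_snps=common_snps,
            n_reps=params.snp_downsample_reps,
            seed=child_seed(seed, "hill", sp),
        )
        hill_rows[sp] = ds.summary
    hill = pd.DataFrame(hill_rows).T
    hill.index.name = "species"
    hill["n_snps"] = common_snps
    hill["n_reps"] = params.snp_downsample_reps

    # --- congruence: co-inertia + per-trait OLS/PGLS -----------------------
    species_to_family = study.taxonomy["family"]
    coin = None
    trait_model_rows = []
    common = [sp for sp in intra_mtd.index if species_to_family.get(sp) in inter_mtd.index]
    if len(common) >= 3 and not inter_mtd.empty:
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            X, Y = build_paired_tables(
                intra_mtd, inter_mtd, species_to_family, mode=params.coinertia_mode
            )
        warn_log += [str(c.message) for c in caught]
        coin = coinertia(
            X.to_numpy(), Y.to_numpy(),
            n_perm=params.n_perm_coinertia, seed=child_seed(seed, "coinertia"),
        )
        # per-trait intra ~ inter models on the raw mtD pairing
        Xr, Yr = build_paired_tables(intra_mtd, inter_mtd, species_to_family, mode="raw")
        C = bm_covariance(study.tree, list(Xr.index)).to_numpy()
        for trait in trait_names:
            if trait not in Xr.columns or trait not in Yr.columns:
                continue
            y, x = Xr[trait].to_numpy(), Yr[trait].to_numpy()
            if np.std(x) == 0:
                continue
            for method, covar in (("OLS", None), ("PGLS", C)):
                fit = pgls_fit(
                    y, x, covariance=covar, names=["inter_mtd"],
                    pagel_lambda=params.pagel_lambda if covar is not None else None,
                )
                trait_model_rows.append(
                    {
                        "trait": trait,
                        "method": method,
                        "coeff": fit.coef("inter_mtd"),
                        "se": float(fit.coefficients.loc["inter_mtd", "se"]),
                        "p_value": fit.p("inter_mtd"),
                        "r_squared": fit.r_squared,
                        "n": fit.n_obs,
                    }
                )
    else:
        warn_log.append("co-inertia skipped: fewer than 3 species with family-level values")
    trait_models = pd.DataFrame(trait_model_rows)

    # --- per-trait OLS/PGLS of intra-mtD on total genetic diversity --------
    units = [sp for sp in intra_mtd.index if sp in hill.index]
    diversity_model_rows = []
    C_units = bm_covariance(study.tree, units).to_numpy()
    jt = hill.loc[units, "J_T"].to_numpy()
    for trait, y_col in list(intra_mtd.loc[units].items()) + [
        ("mean_mtd", intra_mtd.loc[units].mean(axis=1))
    ]:
        y = np.asarray(y_col, dtype=float)
        if not np.all(np.isfinite(y)):
            continue
        for method, covar in (("OLS", None), ("PGLS", C_units)):
            fit = pgls_fit(
                y, jt, covariance=covar, names=["J_T"],
                pagel_lambda=params.pagel_lambda if covar is not None else None,
            )
            diversity_model_rows.append(
                {
                    "trait": trait,
                    "method": method,
                    "coeff": fit.coef("J_T"),
                    "p_value": fit.p("J_T"),
                    "r_squared": fit.r_squared,
                    "n": fit.n_obs,
                }
            )
    diversity_models = pd.DataFrame(diversity_model_rows)

    # --- PERMANOVA of intra-mtD on genetic diversity -----------------------
    response = intra_mtd.loc[units].dropna(axis=1)
    predictors = pd.DataFrame(
        {"J_T": hill.loc[units, "J_T"], "J_ST": hill.loc[units, "J_ST"]}, index=units
    )
    perm_table = permanova(
        response, predictors,
        n_perm=params.n_perm_permanova, seed=child_seed(seed, "permanova"),
    )

    # --- dispersal axis, OLS links, path model -----------------------------
    disp_axis = None
    disp_model_rows = []
    paths = pd.DataFrame()
    if study.dispersal_traits is not None and len(study.dispersal_traits) >= 3:
        disp_axis = dispersal_axis(study.dispersal_traits.loc[units])
        for gvar in ("J_T", "J_ST"):
            fit = ols_fit(
                hill.loc[units, gvar].to_numpy(),
                disp_axis.scores.loc[units].to_numpy(),
                names=["dispersal_axis"],
            )
            disp_model_rows.append(
                {
                    "response": gvar,
                    "coeff": fit.coef("dispersal_axis"),
                    "p_value": fit.p("dispersal_axis"),
                    "r_squared": fit.r_squared,
                    "n": fit.n_obs,
                }
            )
        # species-level summary of intraspecific disparity: first PCoA axis of
        # the intra-mtD matrix (oriented so it rises with mean disparity)
        from .comparative import _pcoa_scores

        pco = _pcoa_scores(response)
        axis1 = pco.iloc[:, 0]
        if np.corrcoef(axis1, response.mean(axis=1))[0, 1] < 0:
            axis1 = -axis1
        sem_data = pd.DataFrame(
            {
                "dispersal": disp_axis.scores.loc[units],
                "j_t": hill.loc[units, "J_T"],
                "j_st": hill.loc[units, "J_ST"],
                "pcoa_intra": axis1,
            }
        )
        paths = path_model(
            sem_data,
            ["j_t ~ dispersal", "pcoa_intra ~ j_t", "j_st ~ dispersal"],
        )
    dispersal_models = pd.DataFrame(disp_model_rows)

    return StudyResults(
        trait_table=traits,
        morphospace=space,
        mric_by_species=richness,
        intra_disparity=intra_df,
        inter_disparity=inter_df,
        intra_mtd=intra_mtd,
        inter_mtd=inter_mtd,
        hill=hill,
        coinertia=coin,
        trait_models=trait_models,
        diversity_models=diversity_models,
        permanova_table=perm_table,
        dispersal=disp_axis,
        dispersal_models=dispersal_models,
        paths=paths,
        warnings_log=warn_log,
    )


# ---------------------------------------------------------------------------
# File-driven entry points


def load_study(bundle_dir: str | Path) -> SimulatedStudy:
    """Load a study bundle directory (the format ``simulate_study`` writes)."""
    d = Path(bundle_dir)
    for required in ("landmarks.tps", "metadata.csv", "tree.nwk"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing input file: {d / required}")
    landmarks = read_tps(d / "landmarks.tps", metadata=d / "metadata.csv")
    inter = (
        read_tps(d / "inter_landmarks.tps", metadata=d / "inter_metadata.csv")
        if (d / "inter_landmarks.tps").exists()
        else []
    )
    meta = pd.read_csv(d / "metadata.csv")
    taxonomy = (
        meta[["species", "genus", "family"]].drop_duplicates().set_index("species")
    )
    tree = dendropy.Tree.get(path=str(d / "tree.nwk"), schema="newick")
    genotypes: dict[str, GenotypeMatrix] = {}
    popmap_path = d / "popmap.csv"
    if popmap_path.exists():
        popmap = pd.read_csv(popmap_path)
        for sp, sub in popmap.groupby("species"):
            vcf = d / "genotypes" / f"{sp}.vcf"
            if not vcf.exists():
                raise FileNotFoundError(f"missing VCF for species {sp}: {vcf}")
            genotypes[str(sp)] = read_genotypes_vcf(
                vcf, dict(zip(sub["sample_id"].astype(str), sub["population"].astype(str)))
            )
    dispersal = (
        pd.read_csv(d / "dispersal_traits.csv", index_col="species")
        if (d / "dispersal_traits.csv").exists()
        else None
    )
    truth = None
    if (d / "ground_truth.json").exists():
        from .simulate import GroundTruth

        truth = GroundTruth.from_json((d / "ground_truth.json").read_text())
    from .simulate import SimulationConfig

    return SimulatedStudy(
        config=SimulationConfig(),
        tree=tree,
        taxonomy=taxonomy,
        landmarks=landmarks,
        inter_landmarks=inter,
        genotypes=genotypes,
        dispersal_traits=dispersal,
        ground_truth=truth,
    )


def _config_hash(params: AnalysisParams, bundle_dir: str) -> str:
    payload = repr(dataclasses.asdict(params)) + "|" + str(bundle_dir)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(
    bundle_dir: str | Path,
    out_dir: str | Path,
    params: AnalysisParams | None = None,
) -> StudyResults:
    """Load a bundle, run the full analysis, and write result CSVs plus a run
    manifest (written before any result file)."""
    params = params or AnalysisParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "run_manifest.txt"
    lines = [
        f"reefdisparity {__version__}",
        f"config_hash = {_config_hash(params, str(bundle_dir))}",
        f"bundle = {bundle_dir}",
        f"master_seed = {params.master_seed}",
    ]
    lines += [f"{k} = {v}" for k, v in dataclasses.asdict(params).items()]
    manifest.write_text("\n".join(lines) + "\n")
    try:
        study = load_study(bundle_dir)
        lines.append(f"n_landmark_configs = {len(study.landmarks)}")
        lines.append(f"n_species = {len(study.taxonomy)}")
        results = analyze_study(study, params)
        results.write(out)
        lines += [f"warning: {w}" for w in results.warnings_log]
        lines.append("status = ok")
    except Exception as exc:
        lines.append(f"status = failed: {exc!r}")
        manifest.write_text("\n".join(lines) + "\n")
        raise
    manifest.write_text("\n".join(lines) + "\n")
    return results
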