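"""Hill-number partitioning of SNP genetic diversity with Nei small-sample
corrections.

Genotypes are biallelic diploid SNPs coded as alternate-allele counts
{0, 1, 2} with -1 for missing, one row per individual, one column per locus,
plus a population label per individual.

Per locus, with ``np`` populations genotyped, ``n_k`` genotyped diploids in
population k and ``ñ`` the harmonic mean of the ``n_k`` (Nei & Chesser 1983
estimators, the ones behind hierfstat's ``basic.stats``):

    Ho       = mean_k (observed heterozygote fraction in k)
    Hs~      = mean_k (1 - sum_a p_{k,a}^2)
    Hs       = ñ/(ñ-1) * (Hs~ - Ho/(2ñ))
    Ht~      = 1 - sum_a pbar_a^2,  pbar_a = unweighted mean_k p_{k,a}
    Ht       = Ht~ + Hs/(ñ·np) - Ho/(2·ñ·np)

Populations are weighted equally throughout (no sample-size weighting).
Multi-locus H_S and H_T are plain means of Hs and Ht over retained loci; the
Hill-number ("effective number of alleles") partition is

    J_S = 1/(1-H_S),  H_ST = (H_T-H_S)/(1-H_S),  J_ST = 1/(1-H_ST),
    J_T = 1/(1-H_T) = J_S × J_ST   (exact algebraic identity).

Per-locus corrected values may leave [0, 1] on tiny samples; they are kept raw
and only the multi-locus means enter the partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._seeds import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "HillDiversity",
    "DownsampleResult",
    "read_genotypes_vcf",
    "read_genotypes_csv",
    "write_genotypes_csv",
    "write_vcf",
    "nei_locus_stats",
    "hill_partition",
    "downsample_diversity",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals × loci diploid genotypes (0/1/2 alt-allele counts, -1
    missing) with a population label per individual."""

    genotypes: np.ndarray  # (n_individuals, n_loci), int8
    populations: np.ndarray  # (n_individuals,) of str
    samples: list[str]
    locus_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotypes must be coded 0/1/2 or -1 (missing)")
        n, L = self.genotypes.shape
        if len(self.populations) != n or len(self.samples) != n:
            raise ValueError("populations/samples length must match genotype rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length must match genotype columns")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            genotypes=self.genotypes[np.ix_(ind, loc)],
            populations=self.populations[ind],
            samples=[self.samples[i] for i in ind],
            locus_ids=[self.locus_ids[j] for j in loc],
        )


def _load_pop_map(pop_map) -> Mapping[str, str]:
    if isinstance(pop_map, Mapping):
        return {str(k): str(v) for k, v in pop_map.items()}
    if isinstance(pop_map, pd.DataFrame):
        df = pop_map
    else:
        df = pd.read_csv(pop_map)
    return dict(zip(df["sample_id"].astype(str), df["population"].astype(str)))


def read_genotypes_vcf(path: str | Path, pop_map) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF (GT field only).

    Multiallelic or non-SNP records are skipped (count logged). ``pop_map``
    maps every sample to a population (dict, DataFrame or CSV path with
    columns ``sample_id, population``); samples missing from it are an error.
    """
    from cyvcf2 import VCF

    pops = _load_pop_map(pop_map)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pops]
    if missing_samples:
        raise ValueError(f"samples absent from pop_map: {missing_samples}")
    columns, locus_ids, skipped = [], [], 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            skipped += 1
            continue
        gt = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        columns.append(gt)
        locus_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    vcf.close()
    if skipped:
        logger.info("read_genotypes_vcf: skipped %d non-biallelic-SNP record(s)", skipped)
    if not columns:
        raise ValueError(f"{path}: no biallelic SNP records")
    geno = np.stack(columns, axis=1)
    return GenotypeMatrix(
        genotypes=geno,
        populations=np.array([pops[s] for s in samples], dtype=object),
        samples=samples,
        locus_ids=locus_ids,
    )


def read_genotypes_csv(path: str | Path, pop_map) -> GenotypeMatrix:
    """Genotype-matrix fallback: CSV with a ``sample_id`` column and one 0/1/2/NA
    column per locus."""
    df = pd.read_csv(path)
    pops = _load_pop_map(pop_map)
    samples = df["sample_id"].astype(str).tolist()
    missing_samples = [s for s in samples if s not in pops]
    if missing_samples:
        raise ValueError(f"samples absent from pop_map: {missing_samples}")
    loci = [c for c in df.columns if c != "sample_id"]
    geno = df[loci].to_numpy(dtype=float)
    out = np.full(geno.shape, MISSING, dtype=np.int8)
    ok = np.isfinite(geno)
    out[ok] = geno[ok].astype(np.int8)
    return GenotypeMatrix(
        genotypes=out,
        populations=np.array([pops[s] for s in samples], dtype=object),
        samples=samples,
        locus_ids=loci,
    )


def write_genotypes_csv(geno: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        geno.genotypes.astype(float), index=geno.samples, columns=geno.locus_ids
    )
    df[geno.genotypes == MISSING] = np.nan
    df.insert(0, "sample_id", geno.samples)
    df.to_csv(path, index=False)


def write_vcf(geno: GenotypeMatrix, path: str | Path, chrom: str = "1") -> None:
    """Write a minimal valid VCF 4.2 (GT only); loci are placed at consecutive
    positions on one contig with alleles A/T."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples),
    ]
    for j, locus in enumerate(geno.locus_ids):
        gts = "\t".join(gt_strings[int(g)] for g in geno.genotypes[:, j])
        lines.append(f"{chrom}\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Nei-corrected per-locus statistics


def nei_locus_stats(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus Ho, Hs~, Hs, Ht~, Ht with Nei small-sample corrections.

    Loci genotyped in fewer than 2 populations, or with harmonic-mean sample
    size ñ <= 1 (correction undefined), are dropped (count logged). Returns a
    DataFrame indexed by locus id with columns ``ho, hs_tilde, hs, ht_tilde,
    ht, n_harmonic, n_pops``.
    """
    g = geno.genotypes
    pops = pd.unique(geno.populations)
    K, L = len(pops), geno.n_loci
    n_k = np.zeros((K, L))
    p_k = np.full((K, L), np.nan)
    het_k = np.full((K, L), np.nan)
    for i, pop in enumerate(pops):
        rows = g[geno.populations == pop]
        ok = rows != MISSING
        n = ok.sum(axis=0)
        n_k[i] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            alt = np.where(ok, rows, 0).sum(axis=0)
            p_k[i] = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
            het_k[i] = np.where(n > 0, np.where(ok, rows == 1, False).sum(axis=0)
                                / np.maximum(n, 1), np.nan)

    genotyped = n_k >= 1
    np_l = genotyped.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_harm = np_l / np.where(genotyped, 1.0 / np.maximum(n_k, 1e-300), 0.0).sum(axis=0)
    keep = (np_l >= 2) & (n_harm > 1)
    dropped = int(L - keep.sum())
    if dropped:
        logger.info("nei_locus_stats: dropped %d locus/loci (<2 pops genotyped or ñ<=1)",
                    dropped)
    if keep.sum() == 0:
        raise ValueError("no locus retained (need >=2 genotyped populations and ñ>1)")

    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # loci about to be dropped may have empty population slices
        _warnings.simplefilter("ignore", RuntimeWarning)
        ho = np.nanmean(het_k, axis=0)
        hs_tilde = np.nanmean(2 * p_k * (1 - p_k), axis=0)
        pbar = np.nanmean(p_k, axis=0)
        ht_tilde = 2 * pbar * (1 - pbar)
        hs = n_harm / (n_harm - 1) * (hs_tilde - ho / (2 * n_harm))
        ht = ht_tilde + hs / (n_harm * np_l) - ho / (2 * n_harm * np_l)

    idx = np.flatnonzero(keep)
    return pd.DataFrame(
        {
            "ho": ho[idx],
            "hs_tilde": hs_tilde[idx],
            "hs": hs[idx],
            "ht_tilde": ht_tilde[idx],
            "ht": ht[idx],
            "n_harmonic": n_harm[idx],
            "n_pops": np_l[idx],
        },
        index=pd.Index([geno.locus_ids[j] for j in idx], name="locus"),
    )


@dataclass
class HillDiversity:
    """Multiplicative Hill-number partition of genetic diversity.

    H's are heterozygosity-scale diversities in [0, 1); J's their effective-
    number equivalents, with J_T = J_S × J_ST exact by construction.
    """

    h_s: float
    h_t: float
    h_st: float
    j_s: float
    j_st: float
    j_t: float
    n_loci: int
    n_individuals: int
    seed: int | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "H_S": self.h_s, "H_T": self.h_t, "H_ST": self.h_st,
                "J_S": self.j_s, "J_ST": self.j_st, "J_T": self.j_t,
                "n_loci": self.n_loci, "n_individuals": self.n_individuals,
            }
        )


def hill_partition(locus_stats: pd.DataFrame, n_individuals: int = 0,
                   seed: int | None = None) -> HillDiversity:
    """Multi-locus Hill partition from per-locus Nei statistics.

    H_S and H_T are means of the corrected per-locus Hs and Ht; H_ST, J_S,
    J_ST, J_T follow algebraically, and J_T = J_S × J_ST is asserted.
    """
    if len(locus_stats) < 1:
        raise ValueError("need at least one retained locus")
    h_s = float(locus_stats["hs"].mean())
    h_t = float(locus_stats["ht"].mean())
    if not (0 <= h_s < 1) or not (0 <= h_t < 1):
        raise ValueError(f"multi-locus H_S={h_s}, H_T={h_t} outside [0, 1): corrupt input")
    h_st = (h_t - h_s) / (1 - h_s)
    j_s = 1.0 / (1.0 - h_s)
    j_st = 1.0 / (1.0 - h_st)
    j_t = 1.0 / (1.0 - h_t)
    assert abs(j_t - j_s * j_st) <= 1e-12 * max(1.0, j_t), "multiplicative identity violated"
    return HillDiversity(
        h_s=h_s, h_t=h_t, h_st=h_st, j_s=j_s, j_st=j_st, j_t=j_t,
        n_loci=len(locus_stats), n_individuals=n_individuals, seed=seed,
    )


@dataclass
class DownsampleResult:
    """Replicate table and replicate means of the down-sampled Hill partition.

    ``summary`` holds the means of the per-replicate J's and H's (the headline
    values); the multiplicative identity holds within each replicate, not for
    the means of ratios.
    """

    replicates: pd.DataFrame
    summary: pd.Series = field(init=False)
    n_reps: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.summary = self.replicates[["H_S", "H_T", "H_ST", "J_S", "J_ST", "J_T"]].mean()
        self.n_reps = len(self.replicates)


def downsample_diversity(
    geno: GenotypeMatrix,
    max_ind_per_pop: int = 10,
    n_snps: int | None = None,
    n_reps: int = 99,
    seed: int | np.random.Generator | None = None,
) -> DownsampleResult:
    """Sample-size-standardized Hill partition.

    Each replicate samples (without replacement) at most ``max_ind_per_pop``
    individuals per population and ``n_snps`` loci, then recomputes the
    partition. Populations smaller than the cap keep all their individuals.
    """
    if n_snps is None:
        n_snps = geno.n_loci
    if n_snps > geno.n_loci:
        raise ValueError(f"n_snps={n_snps} exceeds available loci ({geno.n_loci})")
    rng = as_rng(seed)
    pops = pd.unique(geno.populations)
    pop_indices = {p: np.flatnonzero(geno.populations == p) for p in pops}
    rows = []
    for rep in range(n_reps):
        ind = np.concatenate(
            [
                idx if len(idx) <= max_ind_per_pop
                else rng.choice(idx, size=max_ind_per_pop, replace=False)
                for p, idx in pop_indices.items()
            ]
        )
        loci = (np.arange(geno.n_loci) if n_snps == geno.n_loci
                else rng.choice(geno.n_loci, size=n_snps, replace=False))
        sub = geno.subset(individuals=np.sort(ind), loci=np.sort(loci))
        hd = hill_partition(nei_locus_stats(sub), n_individuals=sub.n_individuals)
        rows.append(hd.as_series().rename(rep))
    replicates = pd.DataFrame(rows)
    replicates.index.name = "replicate"
    return DownsampleResult(
        replicates=replicates,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
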