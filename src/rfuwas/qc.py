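"""Genotype and repertoire quality control.

Implements the variant filters (MAF, Hardy-Weinberg, call rate, imputation
quality), the individual filters (heterozygosity outliers, KING kinship
pruning, minimum unique-CDR3 floor), RFU prevalence filtering, and HLA
haplotype-probability binarization.  Two threshold profiles are provided:
the discovery-cohort profile (MAF > 0.05, pHWE > 1e-6) and the biobank
profile (imputation quality > 0.8, call rate > 0.95, MAF > 0.001,
pHWE > 1e-10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import AbundanceMatrix, Repertoire

#: named variant-filter profiles: (maf_min, phwe_min, call_rate_min, impute_quality_min)
VARIANT_FILTER_PROFILES = {
    "training": dict(maf_min=0.05, phwe_min=1e-6, call_rate_min=0.0, impute_quality_min=0.0),
    "rfuwas": dict(maf_min=0.001, phwe_min=1e-10, call_rate_min=0.95, impute_quality_min=0.8),
}

KINSHIP_SECOND_DEGREE = 0.0884  # KING cut between 2nd- and 3rd-degree relatives


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with per-variant metadata.

    ``dosages`` holds additive allele counts in {0, 1, 2} (real-valued for
    imputed data); ``variants`` is indexed by variant id with columns
    ``chrom``, ``pos`` (1-based), ``locus`` (TRB / HLA / other) and
    optionally ``ref``, ``alt``, ``maf``, ``phwe``, ``call_rate``,
    ``impute_quality``.
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self):
        if not self.dosages.columns.equals(self.variants.index):
            raise ValueError("variant metadata index must match dosage columns")

    @property
    def individual_ids(self) -> list:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list:
        return list(self.dosages.columns)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def computed_maf(self) -> pd.Series:
        """Minor allele frequency from the dosage matrix (folded to <= 0.5)."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def computed_phwe(self) -> pd.Series:
        """HWE chi-square p-value per variant from hard-called dosages."""
        out = {}
        for v in self.dosages.columns:
            d = np.round(self.dosages[v].to_numpy()).astype(int)
            out[v] = hwe_test((int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())))
        return pd.Series(out)

    def subset(self, individuals=None, variants=None) -> "GenotypeMatrix":
        d = self.dosages
        m = self.variants
        if individuals is not None:
            d = d.loc[individuals]
        if variants is not None:
            d = d[variants]
            m = m.loc[variants]
        return GenotypeMatrix(d.copy(), m.copy())


@dataclass
class QCReport:
    """Itemized removal record: each removal carries one primary reason."""

    removed_individuals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["individual_id", "reason"])
    )
    removed_variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )
    thresholds: dict = field(default_factory=dict)


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """Hardy-Weinberg goodness-of-fit p-value (1-df chi-square).

    ``genotype_counts`` are the (hom-ref, het, hom-alt) counts.  Returns 1.0
    when any expected count is zero (monomorphic variants carry no HWE
    information).
    """
    n_aa, n_ab, n_bb = genotype_counts
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype observations")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    if np.any(expected == 0):
        return 1.0
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def filter_variants(
    g: GenotypeMatrix,
    maf_min: float | None = None,
    phwe_min: float | None = None,
    call_rate_min: float | None = None,
    impute_quality_min: float | None = None,
    profile: str = "training",
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants failing MAF / pHWE / call-rate / imputation-quality cuts.

    Explicit thresholds override the named ``profile`` (default the
    discovery profile: MAF > 0.05, pHWE > 1e-6).  Metadata columns are used
    when present; MAF and pHWE are computed from dosages otherwise.  The
    filters are an intersection, so application order is irrelevant; the
    report records one primary reason per removed variant (first failing
    criterion in maf, phwe, call_rate, imputation order).
    """
    prof = dict(VARIANT_FILTER_PROFILES[profile])
    for key, val in (
        ("maf_min", maf_min),
        ("phwe_min", phwe_min),
        ("call_rate_min", call_rate_min),
        ("impute_quality_min", impute_quality_min),
    ):
        if val is not None:
            prof[key] = val

    maf = g.variants["maf"] if "maf" in g.variants else g.computed_maf()
    phwe = g.variants["phwe"] if "phwe" in g.variants else g.computed_phwe()
    call_rate = (
        g.variants["call_rate"]
        if "call_rate" in g.variants
        else pd.Series(1.0, index=g.variants.index)
    )
    quality = (
        g.variants["impute_quality"]
        if "impute_quality" in g.variants
        else pd.Series(1.0, index=g.variants.index)
    )

    removed = []
    for v in g.variant_ids:
        if not maf[v] > prof["maf_min"]:
            removed.append((v, "maf"))
        elif not phwe[v] > prof["phwe_min"]:
            removed.append((v, "phwe"))
        elif not call_rate[v] > prof["call_rate_min"]:
            removed.append((v, "call_rate"))
        elif not quality[v] > prof["impute_quality_min"]:
            removed.append((v, "imputation_quality"))
    removed_ids = {v for v, _ in removed}
    kept = [v for v in g.variant_ids if v not in removed_ids]
    if not kept:
        raise ValueError("all variants removed by QC filters")
    report = QCReport(
        removed_variants=pd.DataFrame(removed, columns=["variant_id", "reason"]),
        thresholds=prof,
    )
    return g.subset(variants=kept), report


def kinship_king(g: GenotypeMatrix, pair: tuple) -> float:
    """KING-robust pairwise kinship coefficient.

    phi-hat = (N_het,het - 2 N_opposite_hom) / (N_het(i) + N_het(j)), over
    variants with hard-called dosages in both individuals.  Requires >= 50
    overlapping variants; a zero denominator (no heterozygous sites) yields
    NaN with a warning.
    """
    i, j = pair
    di = np.round(g.dosages.loc[i].to_numpy()).astype(int)
    dj = np.round(g.dosages.loc[j].to_numpy()).astype(int)
    ok = ~(np.isnan(g.dosages.loc[i].to_numpy()) | np.isnan(g.dosages.loc[j].to_numpy()))
    di, dj = di[ok], dj[ok]
    if di.size < 50:
        raise ValueError("fewer than 50 overlapping variants for kinship estimation")
    n_het_het = int(((di == 1) & (dj == 1)).sum())
    n_opp_hom = int((((di == 0) & (dj == 2)) | ((di == 2) & (dj == 0))).sum())
    n_het_i = int((di == 1).sum())
    n_het_j = int((dj == 1).sum())
    denom = n_het_i + n_het_j
    if denom == 0:
        warnings.warn("kinship undefined: no heterozygous sites in either individual")
        return float("nan")
    return (n_het_het - 2 * n_opp_hom) / denom


def heterozygosity_rate(g: GenotypeMatrix) -> pd.Series:
    """Fraction of heterozygous calls per individual (post-filter panel)."""
    d = np.round(g.dosages.to_numpy()).astype(int)
    return pd.Series((d == 1).mean(axis=1), index=g.dosages.index)


def filter_individuals(
    g: GenotypeMatrix,
    repertoires: list[Repertoire] | None = None,
    het_sd: float = 3.0,
    kinship_max: float = KINSHIP_SECOND_DEGREE,
    min_unique_cdr3: int = 2500,
) -> QCReport:
    """Individual-level QC: heterozygosity outliers, relatives, small repertoires.

    Removes individuals whose heterozygosity rate deviates by more than
    ``het_sd`` standard deviations from the cohort mean, one member of each
    pair with KING kinship above ``kinship_max`` (greedy: the individual in
    the most flagged pairs goes first, ties broken by id order), and
    individuals with strictly fewer than ``min_unique_cdr3`` unique CDR3s.
    Each removal is attributed to the first rule that fired.
    """
    removed: list[tuple[str, str]] = []
    taken: set = set()

    het = heterozygosity_rate(g)
    mu, sd = het.mean(), het.std(ddof=1)
    if sd > 0:
        for ind in g.individual_ids:
            if abs(het[ind] - mu) > het_sd * sd:
                removed.append((ind, "heterozygosity"))
                taken.add(ind)

    survivors = [ind for ind in g.individual_ids if ind not in taken]
    flagged: list[tuple] = []
    for a_pos in range(len(survivors)):
        for b_pos in range(a_pos + 1, len(survivors)):
            phi = kinship_king(g, (survivors[a_pos], survivors[b_pos]))
            if np.isfinite(phi) and phi > kinship_max:
                flagged.append((survivors[a_pos], survivors[b_pos]))
    while flagged:
        degree: dict = {}
        for a, b in flagged:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        drop = sorted(degree, key=lambda ind: (-degree[ind], str(ind)))[0]
        removed.append((drop, "kinship"))
        taken.add(drop)
        flagged = [p for p in flagged if drop not in p]

    if repertoires is not None:
        sizes = {r.individual_id: r.n_unique for r in repertoires}
        for ind in g.individual_ids:
            if ind not in taken and sizes.get(ind, 0) < min_unique_cdr3:
                removed.append((ind, "repertoire_size"))
                taken.add(ind)

    return QCReport(
        removed_individuals=pd.DataFrame(removed, columns=["individual_id", "reason"]),
        thresholds=dict(het_sd=het_sd, kinship_max=kinship_max, min_unique_cdr3=min_unique_cdr3),
    )


def filter_rfus(a: AbundanceMatrix, min_nonzero_fraction: float = 0.2) -> AbundanceMatrix:
    """Keep RFUs with abundance above zero in at least ``min_nonzero_fraction``
    of individuals (inclusive boundary)."""
    if a.stage != "raw":
        raise ValueError("RFU prevalence filtering applies to the raw stage")
    frac = (a.data > 0).mean(axis=0)
    kept = frac[frac >= min_nonzero_fraction].index
    if len(kept) == 0:
        raise ValueError("no RFU passes the prevalence filter")
    return AbundanceMatrix(a.data[kept].copy(), stage="raw")


def binarize_haplotypes(
    probabilities: pd.DataFrame,
    threshold: float = 0.7,
    freq_min: float = 0.05,
) -> pd.DataFrame:
    """Binarize imputed haplotype probabilities and drop rare haplotypes.

    An entry becomes 1 iff its probability is strictly greater than
    ``threshold``; haplotype columns with carrier frequency <= ``freq_min``
    after binarization are dropped.
    """
    p = probabilities.to_numpy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("haplotype probabilities must lie in [0, 1]")
    binary = (probabilities > threshold).astype(int)
    freq = binary.mean(axis=0)
    return binary.loc[:, freq[freq > freq_min].index].copy()
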