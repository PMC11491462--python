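"""Mass univariate association between genetic predictors and RFU abundances.

Each (predictor, RFU) pair is tested with a simple linear regression of the
residualized trait on the allele dosage (or binarized haplotype); p-values
come from the t distribution with n-2 degrees of freedom.  Family-wise
control uses Bonferroni thresholds; significant variants can be tested for
enrichment in genomic annotation tracks with a one-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import GenotypeMatrix
from .quantify import AbundanceMatrix

#: output columns of an association scan; one row per (predictor, trait) test
ASSOCIATION_COLUMNS = ["predictor_id", "rfu_id", "beta", "se", "statistic", "p", "n", "flag"]


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (half-open [start, end), 1-based)."""

    label: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self):
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            raise ValueError("annotation intervals must satisfy start < end")

    @classmethod
    def from_bed(cls, path, label: str | None = None) -> "AnnotationTrack":
        """Read a BED file (0-based half-open) into 1-based half-open intervals."""
        bed = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
        )
        bed["start"] = bed["start"] + 1
        bed["end"] = bed["end"] + 1
        return cls(label=label or str(path), intervals=bed)

    def contains(self, chrom, pos) -> np.ndarray:
        """Membership of 1-based positions in the track (vectorized)."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        hit = np.zeros(pos.shape, dtype=bool)
        for c, sub in self.intervals.groupby("chrom"):
            on_c = chrom == c
            if not on_c.any():
                continue
            p = pos[on_c]
            inside = np.zeros(p.shape, dtype=bool)
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                inside |= (p >= s) & (p < e)
            hit[on_c] = inside
        return hit


def association_scan(predictors, traits: AbundanceMatrix) -> pd.DataFrame:
    """Simple-regression scan of every trait on every predictor.

    ``predictors`` is a :class:`GenotypeMatrix` or an individuals x
    predictors DataFrame (e.g. binarized haplotypes); ``traits`` must be a
    residual-stage abundance matrix aligned on individuals.  Zero-variance
    predictors yield flagged NA records rather than being dropped.
    """
    X = predictors.dosages if isinstance(predictors, GenotypeMatrix) else predictors
    if not X.index.equals(traits.data.index):
        X = X.loc[traits.data.index]
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 individuals, got {n}")

    Xc = X.to_numpy(dtype=float)
    Yc = traits.data.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    Yc = Yc - Yc.mean(axis=0)
    sxx = (Xc * Xc).sum(axis=0)          # (m,)
    syy = (Yc * Yc).sum(axis=0)          # (k,)
    sxy = Xc.T @ Yc                      # (m, k)

    ok = sxx > 0
    beta = np.full_like(sxy, np.nan)
    beta[ok] = sxy[ok] / sxx[ok, None]
    rss = syy[None, :] - beta * sxy
    sigma2 = np.clip(rss, 0.0, None) / (n - 2)
    se = np.full_like(sxy, np.nan)
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    m, k = sxy.shape
    pred_ids = np.repeat(np.asarray(X.columns, dtype=object), k)
    trait_ids = np.tile(np.asarray(traits.data.columns, dtype=object), m)
    flag = np.where(np.repeat(~ok, k), "zero_variance_predictor", "")
    return pd.DataFrame({
        "predictor_id": pred_ids,
        "rfu_id": trait_ids,
        "beta": beta.ravel(),
        "se": se.ravel(),
        "statistic": tstat.ravel(),
        "p": pval.ravel(),
        "n": n,
        "flag": flag,
    })


def bonferroni_threshold(
    alpha_per_test: float,
    n_traits: int,
    n_predictor_groups: int = 1,
) -> float:
    """Bonferroni significance bar: alpha / (n_traits * n_predictor_groups).

    The full-precision value is returned; report it at 2 significant
    figures for display (the convention of printed thresholds).
    """
    if n_traits < 1 or n_predictor_groups < 1:
        raise ValueError("counts must be positive")
    return alpha_per_test / (n_traits * n_predictor_groups)


def annotation_enrichment(
    hit_variants: set,
    background_variants: set,
    track: AnnotationTrack,
    positions: pd.DataFrame,
) -> tuple[float, float]:
    """Enrichment of hit variants in a genomic annotation track.

    Builds the 2x2 table (hit / non-hit x in-track / out-of-track) over
    ``background_variants`` (hits must be a subset) using half-open
    interval overlap of ``positions`` (indexed by variant id, columns
    chrom / pos), and returns (odds ratio, one-sided greater Fisher p).
    The odds ratio uses the Haldane 0.5 continuity correction only when a
    cell is zero; the p-value is the exact hypergeometric tail.
    """
    if not background_variants:
        raise ValueError("background variant set is empty")
    if not hit_variants <= background_variants:
        raise ValueError("hit variants must be a subset of the background")
    bg = sorted(background_variants, key=str)
    sub = positions.loc[bg]
    in_track = pd.Series(
        track.contains(sub["chrom"].to_numpy(), sub["pos"].to_numpy()), index=bg
    )
    is_hit = pd.Series([v in hit_variants for v in bg], index=bg)
    a = int((is_hit & in_track).sum())
    b = int((is_hit & ~in_track).sum())
    c = int((~is_hit & in_track).sum())
    d = int((~is_hit & ~in_track).sum())
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def effect_replication(
    train: pd.DataFrame,
    test: pd.DataFrame,
    keys: list[tuple] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of effect sizes across two cohorts.

    Records are matched on (predictor_id, rfu_id); ``keys`` optionally
    restricts to a stated pair list.  Returns (r, two-sided p).
    """
    merged = train.merge(test, on=["predictor_id", "rfu_id"], suffixes=("_train", "_test"))
    if keys is not None:
        wanted = set(keys)
        merged = merged[
            [tuple(t) in wanted for t in merged[["predictor_id", "rfu_id"]].itertuples(index=False)]
        ]
    merged = merged.dropna(subset=["beta_train", "beta_test"])
    if len(merged) < 3:
        raise ValueError("need at least 3 shared (predictor, trait) pairs")
    r, p = stats.pearsonr(merged["beta_train"], merged["beta_test"])
    return float(r), float(p)
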