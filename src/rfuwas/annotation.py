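"""RFU annotation: T-cell compartments, antigen specificity, DE contrast.

RFUs are labelled by the T-cell compartment in which they are enriched
(CD4/CD8 from paired sorted repertoires, replicated across two datasets;
TN/CM/Treg/Tscm by a Bonferroni-corrected Friedman test with the
highest-median subset as the label) and by antigen specificity (any
database CDR3 of known specificity mapping into the RFU donates its
antigen labels).  Antigen-specific RFUs can then be prioritized by the
strength of their disease associations, and a rank-based differential-
expression contrast compares samples with and without protective RFUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import AbundanceMatrix, RFUAssigner, RFUCentroids

SUBSETS = ("TN", "CM", "Treg", "Tscm")


@dataclass
class CellTypeAnnotation:
    rfu_id: str
    label: str  # CD4 / CD8 / TN / CM / Treg / Tscm / unannotated
    p: float = float("nan")
    medians: dict = field(default_factory=dict)
    flag: str = ""


@dataclass
class AntigenTCRTable:
    """CDR3 sequences of known antigen specificity (cdr3_aa, antigen, source)."""

    table: pd.DataFrame

    def __post_init__(self):
        required = {"cdr3_aa", "antigen"}
        if len(self.table) and not required <= set(self.table.columns):
            raise ValueError(f"antigen table needs columns {sorted(required)}")


def annotate_cd4_cd8(
    dataset1: tuple[AbundanceMatrix, AbundanceMatrix],
    dataset2: tuple[AbundanceMatrix, AbundanceMatrix],
    alpha: float = 0.05,
) -> list[CellTypeAnnotation]:
    """Label RFUs CD4 or CD8 from two paired sorted-repertoire datasets.

    Within each dataset, per-individual CD4 and CD8 abundances of an RFU
    are compared with a one-sided paired Wilcoxon signed-rank test; the
    direction is fixed by the dataset-1 median difference and must
    replicate (same direction, p < alpha) in dataset 2, otherwise the RFU
    stays unannotated.  Fewer than 6 pairs leaves the test degenerate.
    """
    out = []
    cd4_1, cd8_1 = dataset1
    cd4_2, cd8_2 = dataset2
    for rfu in cd4_1.rfu_ids:
        d1 = cd4_1.data[rfu].to_numpy(float) - cd8_1.data[rfu].to_numpy(float)
        d2 = cd4_2.data[rfu].to_numpy(float) - cd8_2.data[rfu].to_numpy(float)
        medians = {
            "cd4_d1": float(np.median(cd4_1.data[rfu])),
            "cd8_d1": float(np.median(cd8_1.data[rfu])),
            "cd4_d2": float(np.median(cd4_2.data[rfu])),
            "cd8_d2": float(np.median(cd8_2.data[rfu])),
        }
        if min(d1.size, d2.size) < 6:
            warnings.warn(f"{rfu}: fewer than 6 pairs, test degenerate")
            out.append(CellTypeAnnotation(rfu, "unannotated", medians=medians, flag="too_few_pairs"))
            continue
        direction = np.median(d1)
        if direction == 0 or np.all(d1 == 0) or np.all(d2 == 0):
            out.append(CellTypeAnnotation(rfu, "unannotated", medians=medians))
            continue
        alt = "greater" if direction > 0 else "less"
        p1 = stats.wilcoxon(d1, alternative=alt).pvalue
        p2 = stats.wilcoxon(d2, alternative=alt).pvalue
        if p1 < alpha and p2 < alpha:
            label = "CD4" if direction > 0 else "CD8"
            out.append(CellTypeAnnotation(rfu, label, p=float(max(p1, p2)), medians=medians))
        else:
            out.append(CellTypeAnnotation(rfu, "unannotated", p=float(max(p1, p2)), medians=medians))
    return out


def annotate_subsets(
    subset_abundances: dict[str, AbundanceMatrix],
    n_rfus_tested: int,
    alpha: float = 0.05,
) -> list[CellTypeAnnotation]:
    """Label RFUs by phenotypic subset via a Bonferroni-corrected Friedman test.

    ``subset_abundances`` maps subset name (e.g. TN/CM/Treg/Tscm) to an
    abundance matrix over the same individuals.  An RFU is annotated only
    when the Friedman p across subsets beats ``alpha / n_rfus_tested``; the
    label is the subset with the highest median abundance (ties leave the
    RFU unannotated with a flag).
    """
    if len(subset_abundances) < 3:
        raise ValueError("Friedman test needs at least 3 subsets")
    names = list(subset_abundances)
    first = subset_abundances[names[0]]
    threshold = alpha / n_rfus_tested
    out = []
    for rfu in first.rfu_ids:
        cols = [subset_abundances[s].data[rfu].to_numpy(float) for s in names]
        if all(np.array_equal(cols[0], c) for c in cols[1:]):
            out.append(CellTypeAnnotation(rfu, "unannotated", p=1.0))
            continue
        p = float(stats.friedmanchisquare(*cols).pvalue)
        medians = {s: float(np.median(c)) for s, c in zip(names, cols)}
        if p >= threshold:
            out.append(CellTypeAnnotation(rfu, "unannotated", p=p, medians=medians))
            continue
        best = max(medians.values())
        winners = [s for s, m in medians.items() if m == best]
        if len(winners) > 1:
            out.append(CellTypeAnnotation(rfu, "unannotated", p=p, medians=medians, flag="median_tie"))
        else:
            out.append(CellTypeAnnotation(rfu, winners[0], p=p, medians=medians))
    return out


def map_antigen_specificity(
    db: AntigenTCRTable,
    centroids: RFUCentroids,
    encoder=None,
) -> dict[str, set]:
    """Map database CDR3s to RFUs; an RFU inherits every antigen that lands in it."""
    mapping: dict[str, set] = {}
    if len(db.table) == 0:
        return mapping
    assigner = RFUAssigner(encoder=encoder).fit(centroids)
    seqs = db.table["cdr3_aa"].tolist()
    idx = assigner.assign_indices(seqs)
    for i, antigen in zip(idx, db.table["antigen"]):
        rfu = centroids.rfu_ids[i]
        mapping.setdefault(rfu, set())
        if isinstance(antigen, (list, set, tuple)):
            mapping[rfu].update(antigen)
        else:
            mapping[rfu].add(antigen)
    return mapping


def prioritize_antigen_rfus(
    associations: pd.DataFrame,
    specific_rfus: set,
    top_n_grid: tuple[int, ...] = (10, 20, 50),
    expected_fraction: float | None = None,
) -> tuple[float, pd.DataFrame]:
    """Test whether disease-associated pathogenic gdRFUs are antigen-specific.

    ``associations`` are records for one disease with ``rfu_id``, ``beta``
    and ``statistic`` (z) columns; pathogenic records (beta > 0) are used.
    Returns (i) the one-sided rank-test p that specific RFUs carry higher
    association z than non-specific ones, and (ii) per-N Fisher exact
    p-values for over-representation of specific RFUs among the top N
    associations ranked by p.  The background specific fraction defaults to
    the fraction among all pathogenic RFUs considered; an explicit
    ``expected_fraction`` replaces the background count.
    """
    path = associations[associations["beta"] > 0].copy()
    if not specific_rfus:
        warnings.warn("no antigen-specific RFU supplied; tests undefined")
        return float("nan"), pd.DataFrame(columns=["top_n", "n_specific", "odds_ratio", "p"])
    is_spec = path["rfu_id"].isin(specific_rfus)
    z_spec = path.loc[is_spec, "statistic"].to_numpy(float)
    z_other = path.loc[~is_spec, "statistic"].to_numpy(float)
    if z_spec.size and z_other.size:
        wilcox_p = float(stats.mannwhitneyu(z_spec, z_other, alternative="greater").pvalue)
    else:
        wilcox_p = float("nan")

    M = len(path)
    S = int(is_spec.sum()) if expected_fraction is None else int(round(expected_fraction * M))
    ranked = path.sort_values("p", kind="stable")
    rows = []
    for N in top_n_grid:
        N = min(N, M)
        top = ranked.head(N)
        k = int(top["rfu_id"].isin(specific_rfus).sum())
        table = [[k, N - k], [S - k, (M - N) - (S - k)]]
        if min(min(r) for r in table) < 0:
            rows.append((N, k, np.nan, np.nan))
            continue
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append((N, k, float(odds), float(p)))
    return wilcox_p, pd.DataFrame(rows, columns=["top_n", "n_specific", "odds_ratio", "p"])


def cd4cd8_mhc_correlation(
    cd4cd8_ratio: pd.Series,
    effect_ratio: pd.Series,
) -> tuple[float, float, int]:
    """Spearman correlation between CD4/CD8 abundance ratio and the
    MHC-II/MHC-I effect-size ratio per RFU.

    Undefined ratios (NaN/inf from zero denominators) are excluded;
    returns (rho, two-sided p, number excluded).  At least 10 RFUs with
    both quantities defined are required.
    """
    joined = pd.concat({"cc": cd4cd8_ratio, "ee": effect_ratio}, axis=1)
    finite = joined.replace([np.inf, -np.inf], np.nan).dropna()
    n_excluded = len(joined) - len(finite)
    if len(finite) < 10:
        raise ValueError("fewer than 10 RFUs with both ratios defined")
    rho, p = stats.spearmanr(finite["cc"], finite["ee"])
    return float(rho), float(p), n_excluded


def differential_expression_contrast(
    expression: pd.DataFrame,
    group: pd.Series,
    top_var_genes: int = 2000,
    fc_cut: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank-based DE contrast between samples with and without protective RFUs.

    ``expression`` is genes x samples; ``group`` is a boolean per sample
    (True = has protective RFU).  Restricted to the ``top_var_genes``
    highest-variance genes, per-gene fold change is the ratio of group
    medians (zero reference median flagged), the p-value an unpaired
    two-sided rank-sum test, adjusted by Bonferroni over tested genes.
    ``significant`` requires fold change strictly > ``fc_cut`` or
    < 1/``fc_cut`` and adjusted p < ``alpha``.
    """
    group = group.astype(bool)
    g1 = expression.loc[:, group.index[group]]
    g0 = expression.loc[:, group.index[~group]]
    if g1.shape[1] < 5 or g0.shape[1] < 5:
        raise ValueError("both groups need at least 5 samples")
    variances = expression.var(axis=1)
    genes = variances.sort_values(ascending=False).head(top_var_genes).index
    rows = []
    m = len(genes)
    for gene in genes:
        a = g1.loc[gene].to_numpy(float)
        b = g0.loc[gene].to_numpy(float)
        med1, med0 = np.median(a), np.median(b)
        flag = ""
        if med0 == 0:
            fc = np.inf if med1 > 0 else np.nan
            flag = "zero_reference_median"
        else:
            fc = med1 / med0
        if np.array_equal(np.sort(a), np.sort(b)) and np.all(a == a[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_adj = min(1.0, p * m)
        sig = bool(
            np.isfinite(fc)
            and (fc > fc_cut or fc < 1.0 / fc_cut)
            and p_adj < alpha
        ) or bool(fc == np.inf and p_adj < alpha)
        rows.append((gene, fc, p, p_adj, sig, flag))
    return pd.DataFrame(
        rows, columns=["gene", "fold_change", "p", "p_adj", "significant", "flag"]
    )
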