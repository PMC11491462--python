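"""Phenome-wide association of gdRFU abundances with disease and survival.

Binary (phecode-style) traits are residualized on covariates once and then
regressed on each gdRFU with a linear model — a valid test whose effect is
on the linear-probability rather than odds-ratio scale.  Cancer survival
uses Cox proportional-hazards models (Efron ties) per (cancer, gdRFU) with
covariates, restricted to cancers with enough events, and
Benjamini-Hochberg FDR across all tests.  Positive effects on disease are
called pathogenic, negative protective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import FactorResidualizer
from .qtl import bonferroni_threshold
from .quantify import AbundanceMatrix

MIN_EVENTS_DEFAULT = 130  # minimum event count for a cancer to be tested
MIN_CASES_DEFAULT = 20    # binary traits with fewer cases are skipped


@dataclass
class PhenotypeTable:
    """Binary case/control traits, survival endpoints and covariates.

    ``binary`` is individuals x traits in {0, 1}; ``survival`` maps a
    cancer label to a per-patient frame with columns ``time`` (follow-up,
    > 0), ``event`` (1 = death) and optionally ``diagnosis_age``;
    ``covariates`` holds numeric columns (sex, age, PCs) for the same
    individuals.
    """

    binary: pd.DataFrame = field(default_factory=pd.DataFrame)
    survival: dict = field(default_factory=dict)
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.binary):
            vals = self.binary.to_numpy()
            if not np.isin(vals[~pd.isna(vals)], [0, 1]).all():
                raise ValueError("binary traits must be coded 0/1")
        for label, frame in self.survival.items():
            if (frame["time"] <= 0).any():
                raise ValueError(f"non-positive follow-up time in {label!r}")


def _mass_simple_regression(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Per-column simple regressions of every Y column on every X column."""
    n = X.shape[0]
    Xc = X.to_numpy(dtype=float)
    Yc = Y.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    Yc = Yc - Yc.mean(axis=0)
    sxx = (Xc * Xc).sum(axis=0)
    syy = (Yc * Yc).sum(axis=0)
    sxy = Xc.T @ Yc
    ok = sxx > 0
    beta = np.full_like(sxy, np.nan)
    beta[ok] = sxy[ok] / sxx[ok, None]
    sigma2 = np.clip(syy[None, :] - beta * sxy, 0.0, None) / (n - 2)
    se = np.full_like(sxy, np.nan)
    se[ok] = np.sqrt(sigma2[ok] / sxx[ok, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    m, k = sxy.shape
    return pd.DataFrame({
        "rfu_id": np.repeat(np.asarray(X.columns, dtype=object), k),
        "trait_id": np.tile(np.asarray(Y.columns, dtype=object), m),
        "beta": beta.ravel(),
        "se": se.ravel(),
        "statistic": tstat.ravel(),
        "p": pval.ravel(),
        "n": n,
    })


def phenome_scan(
    gdrfu: pd.DataFrame,
    phenotypes: PhenotypeTable,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_cases: int = MIN_CASES_DEFAULT,
) -> pd.DataFrame:
    """Scan every binary trait against every gdRFU abundance.

    Covariates are regressed out of the phenotypes once; the
    covariate-corrected traits are then tested against each gdRFU with a
    simple linear regression.  Traits with fewer than ``min_cases`` cases
    are skipped with a warning.  The returned frame carries a
    ``significant`` column at the Bonferroni bar
    ``alpha / (n_traits * n_rfus)`` (also stored in ``attrs``), with
    positive beta = pathogenic and negative = protective.
    """
    cov = covariates if covariates is not None else phenotypes.covariates
    traits = phenotypes.binary
    n_cases = traits.sum(axis=0)
    keep = n_cases[n_cases >= min_cases].index
    skipped = [t for t in traits.columns if t not in set(keep)]
    if skipped:
        warnings.warn(f"skipping {len(skipped)} trait(s) with fewer than {min_cases} cases")
    traits = traits[keep]
    if traits.shape[1] == 0:
        raise ValueError("no binary trait has enough cases")

    resid = FactorResidualizer(n_factors=0).fit(traits.to_numpy(float), cov).transform(
        traits.to_numpy(float)
    )
    resid = pd.DataFrame(resid, index=traits.index, columns=traits.columns)
    out = _mass_simple_regression(gdrfu.loc[traits.index], resid)
    threshold = bonferroni_threshold(alpha, traits.shape[1] * gdrfu.shape[1])
    out["significant"] = out["p"] < threshold
    out.attrs["bonferroni_threshold"] = threshold
    return out


def category_enrichment(
    significant_traits,
    trait_categories: dict,
) -> tuple[float, float]:
    """Chi-square test for uneven allocation of hits across disease categories.

    ``significant_traits`` lists the trait label of each significant
    association (with multiplicity); expected counts allocate the total
    proportionally to category size in ``trait_categories``.  Falls back to
    a Fisher test of the largest category versus the rest when an expected
    cell drops below 1.  Returns (statistic, p).
    """
    cats = sorted(set(trait_categories.values()))
    if len(cats) < 2:
        raise ValueError("need at least 2 trait categories")
    sizes = pd.Series({c: sum(v == c for v in trait_categories.values()) for c in cats}, dtype=float)
    observed = pd.Series(0.0, index=cats)
    for t in significant_traits:
        observed[trait_categories[t]] += 1
    total = observed.sum()
    if total == 0:
        raise ValueError("no significant associations to test")
    expected = total * sizes / sizes.sum()
    if (expected < 1).any():
        warnings.warn("expected count < 1; falling back to Fisher exact on top category vs rest")
        top = observed.idxmax()
        table = [
            [int(observed[top]), int(total - observed[top])],
            [int(sizes[top]), int(sizes.sum() - sizes[top])],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        return float(odds), float(p)
    chi2, p = stats.chisquare(observed.to_numpy(), expected.to_numpy())
    return float(chi2), float(p)


def celltype_association_fraction(
    associations: pd.DataFrame,
    rfu_celltypes: dict,
    restrict_pathogenic: bool = False,
) -> pd.DataFrame:
    """Per-(disease, cell type) fraction of associated annotated RFUs.

    For each disease and cell type, the fraction of that cell type's
    annotated RFUs that are significantly associated (positive beta only
    when ``restrict_pathogenic``), with a one-sided Fisher exact test
    against the rate among all other annotated RFUs.  Empty cell types
    yield NA rows.
    """
    annotated = {r: c for r, c in rfu_celltypes.items() if c and c != "unannotated"}
    celltypes = sorted(set(annotated.values()))
    sig = associations[associations["significant"]]
    if restrict_pathogenic:
        sig = sig[sig["beta"] > 0]
    rows = []
    for disease, dsub in sig.groupby("trait_id"):
        assoc_rfus = set(dsub["rfu_id"])
        for ct in celltypes:
            members = [r for r, c in annotated.items() if c == ct]
            others = [r for r in annotated if annotated[r] != ct]
            if not members:
                rows.append((disease, ct, 0, 0, np.nan, np.nan, np.nan))
                continue
            k = sum(r in assoc_rfus for r in members)
            k_o = sum(r in assoc_rfus for r in others)
            table = [[k, len(members) - k], [k_o, len(others) - k_o]]
            odds, p = stats.fisher_exact(table, alternative="greater")
            rows.append((disease, ct, len(members), k, k / len(members), float(odds), float(p)))
    return pd.DataFrame(
        rows,
        columns=["trait_id", "celltype", "n_rfus", "n_associated", "fraction", "odds_ratio", "p"],
    )


def cox_scan(
    gdrfu: pd.DataFrame,
    phenotypes: PhenotypeTable,
    covariates: pd.DataFrame | None = None,
    min_events: int = MIN_EVENTS_DEFAULT,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Cox proportional-hazards scan of gdRFUs against cancer survival.

    For each cancer with at least ``min_events`` events, each gdRFU
    (standardized within the cancer cohort, so log HR is per SD) is fit in
    a Cox model with Efron tie handling alongside the covariates.
    Non-convergent fits are flagged, never silently dropped.  q-values are
    Benjamini-Hochberg across all tests; ``significant`` is q < fdr_alpha.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cov = covariates if covariates is not None else phenotypes.covariates
    rows = []
    for cancer, surv in phenotypes.survival.items():
        n_events = int(surv["event"].sum())
        if n_events < min_events:
            continue
        ids = surv.index
        if len(ids) < 3:
            raise ValueError(f"degenerate survival table for {cancer!r}")
        base = surv[["time", "event"]].copy()
        cov_cols = []
        if cov is not None and len(cov.columns):
            for c in cov.columns:
                base[c] = cov.loc[ids, c].to_numpy()
                cov_cols.append(c)
        if "diagnosis_age" in surv.columns and "diagnosis_age" not in base.columns:
            base["diagnosis_age"] = surv["diagnosis_age"]
            cov_cols.append("diagnosis_age")
        for rfu in gdrfu.columns:
            x = gdrfu.loc[ids, rfu].to_numpy(dtype=float)
            sd = x.std(ddof=0)
            frame = base.copy()
            frame["gdrfu"] = (x - x.mean()) / sd if sd > 0 else 0.0
            flag = ""
            log_hr = se = p = np.nan
            if sd == 0:
                flag = "zero_variance_gdrfu"
            else:
                cph = CoxPHFitter()
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cph.fit(frame, duration_col="time", event_col="event")
                    log_hr = float(cph.params_["gdrfu"])
                    se = float(cph.standard_errors_["gdrfu"])
                    p = float(cph.summary.loc["gdrfu", "p"])
                except (ConvergenceError, ValueError) as exc:
                    flag = f"non_convergence: {exc}"
            rows.append((cancer, rfu, log_hr, se, p, n_events, flag))
    out = pd.DataFrame(
        rows, columns=["trait_id", "rfu_id", "log_hr", "se", "p", "n_events", "flag"]
    )
    if len(out) == 0:
        return out.assign(q=[], significant=[])
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["q"] < fdr_alpha
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
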