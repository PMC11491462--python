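"""Genetic prediction of RFU abundances (gdRFU models).

For each RFU, a lasso or elastic-net model is trained on genotype dosages
from locus-based variant sets (1-Mb window, gene locus "o", significant
span "s" for each of TRB, HLA and TRB+HLA).  Model quality is the
cross-validated squared Pearson correlation between out-of-fold predictions
and the observed residualized abundance (cv R^2); an RFU is called
predictable when cv R^2 exceeds 0.01.  Single-component REML heritability
from the variant-set GRM provides the accuracy ceiling.

Coordinate descent for the penalized fits is scikit-learn's; the lambda
grid, fold logic, out-of-fold selection rule and prediction contract
(missing variants contribute zero post-standardization) live here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

from .qc import GenotypeMatrix

GENOME_WIDE_ALPHA = 5e-8  # per-test bar defining "significant span" variant sets
PREDICTABLE_CV_R2 = 0.01  # strict lower bound for calling an RFU predictable


# ---------------------------------------------------------------------------
# variant sets
# ---------------------------------------------------------------------------

def build_variant_sets(
    g: GenotypeMatrix,
    scan: pd.DataFrame | None = None,
    loci: tuple[str, ...] = ("TRB", "HLA"),
    window: int = 1_000_000,
    alpha: float = GENOME_WIDE_ALPHA,
) -> dict[str, list]:
    """Label variant subsets for model training.

    For each locus (and the union of all loci) three rules apply:
    ``window1mb`` — variants on the locus chromosome within ``window`` bp of
    the span of locus-labelled variants; ``o`` — variants carrying the locus
    label; ``s`` — variants between the first and last locus-window variant
    with any scan p < ``alpha`` (empty, with NaN span, when there is no
    hit).  Returns a mapping like ``{"TRB_window1mb": [...], ...,
    "TRB+HLA_s": [...]}``.
    """
    meta = g.variants
    for locus in loci:
        if not (meta["locus"] == locus).any():
            raise ValueError(f"locus {locus!r} absent from variant metadata")

    sig_pred: set = set()
    if scan is not None and len(scan):
        sig = scan[(scan["p"] < alpha) & (scan["flag"] == "")]
        sig_pred = set(sig["predictor_id"])

    sets: dict[str, list] = {}
    per_locus: dict[str, dict[str, list]] = {}
    for locus in loci:
        own = meta.index[meta["locus"] == locus]
        chrom = meta.loc[own[0], "chrom"]
        lo = meta.loc[own, "pos"].min() - window
        hi = meta.loc[own, "pos"].max() + window
        on_chrom = meta[meta["chrom"] == chrom]
        window_ids = list(on_chrom.index[(on_chrom["pos"] >= lo) & (on_chrom["pos"] <= hi)])
        hits = [v for v in window_ids if v in sig_pred]
        if hits:
            s_lo = meta.loc[hits, "pos"].min()
            s_hi = meta.loc[hits, "pos"].max()
            span_ids = list(
                on_chrom.index[(on_chrom["pos"] >= s_lo) & (on_chrom["pos"] <= s_hi)]
            )
        else:
            span_ids = []
        per_locus[locus] = {"window1mb": window_ids, "o": list(own), "s": span_ids}
        for rule, ids in per_locus[locus].items():
            sets[f"{locus}_{rule}"] = ids

    combo = "+".join(loci)
    for rule in ("window1mb", "o", "s"):
        union: list = []
        seen = set()
        for locus in loci:
            for v in per_locus[locus][rule]:
                if v not in seen:
                    union.append(v)
                    seen.add(v)
        sets[f"{combo}_{rule}"] = union
    return sets


# ---------------------------------------------------------------------------
# penalized models
# ---------------------------------------------------------------------------

@dataclass
class PredictionModel:
    """Serialized per-RFU genotype->abundance model (nonzero weights only).

    Weights act on dosages standardized by the frozen training ``means`` /
    ``sds``, so cohort shifts never silently rescale predictions.
    """

    rfu_id: str
    variant_ids: list
    weights: np.ndarray
    intercept: float
    means: np.ndarray
    sds: np.ndarray
    family: str = "lasso"
    mixing_alpha: float = 1.0
    lambda_: float = 0.0
    variant_set: str = ""
    cv_r2: float = float("nan")
    predictable: bool | None = None
    alleles: dict = field(default_factory=dict)  # variant_id -> (ref, alt)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))


class PenalizedRFUModel(BaseEstimator, RegressorMixin):
    """Cross-validated lasso / elastic-net regression of abundance on dosage.

    Parameters
    ----------
    family : {"lasso", "elastic_net"}
        Penalty family; the elastic net uses ``mixing_alpha`` as l1 ratio.
    mixing_alpha : float, default 0.5
        Elastic-net mixing parameter (ignored for lasso, which is l1=1).
    n_lambda, lambda_min_ratio : grid of 100 log-spaced penalties from
        lambda_max (smallest all-zero penalty) down to
        ``lambda_max * lambda_min_ratio``.
    folds : int, default 10
        Cross-validation folds; fold assignment depends only on (seed, n).
    seed : int, default 0

    The selected penalty maximizes the mean across folds of the squared
    Pearson correlation between out-of-fold predictions and the held-out
    trait; the reported ``cv_r2_`` is the squared correlation of the pooled
    out-of-fold predictions at that penalty.  Final weights are refit on
    all data.
    """

    def __init__(
        self,
        family: str = "lasso",
        mixing_alpha: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-3,
        folds: int = 10,
        seed: int = 0,
        rfu_id: str = "",
        variant_set: str = "",
    ):
        self.family = family
        self.mixing_alpha = mixing_alpha
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.folds = folds
        self.seed = seed
        self.rfu_id = rfu_id
        self.variant_set = variant_set

    def _l1_ratio(self) -> float:
        if self.family == "lasso":
            return 1.0
        if self.family == "elastic_net":
            return float(self.mixing_alpha)
        raise ValueError(f"unknown penalty family {self.family!r}")

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        if n < 50:
            raise ValueError(f"need at least 50 individuals to train, got {n}")
        if np.all(y == y[0]):
            raise ValueError("constant trait: nothing to fit")

        means = X.to_numpy(dtype=float).mean(axis=0)
        sds = X.to_numpy(dtype=float).std(axis=0, ddof=0)
        safe_sds = np.where(sds > 0, sds, 1.0)
        Z = (X.to_numpy(dtype=float) - means) / safe_sds

        l1 = self._l1_ratio()
        yc = y - y.mean()
        lambda_max = np.max(np.abs(Z.T @ yc)) / (n * l1)
        if lambda_max <= 0:
            raise ValueError("all predictors are orthogonal to the trait")
        grid = np.geomspace(lambda_max, lambda_max * self.lambda_min_ratio, self.n_lambda)

        kf = KFold(n_splits=self.folds, shuffle=True, random_state=self.seed % (2**32))
        oof = np.full((n, self.n_lambda), np.nan)
        fold_r2 = np.zeros((self.folds, self.n_lambda))
        import warnings as _warnings
        for f, (tr, te) in enumerate(kf.split(Z)):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = enet_path(Z[tr], y[tr], l1_ratio=l1, alphas=grid, max_iter=3000)
            icept = y[tr].mean() - Z[tr].mean(axis=0) @ coefs
            preds = Z[te] @ coefs + icept  # (n_te, n_lambda)
            oof[te] = preds
            yt = y[te]
            for a in range(self.n_lambda):
                p = preds[:, a]
                if np.std(p) > 0 and np.std(yt) > 0:
                    fold_r2[f, a] = np.corrcoef(p, yt)[0, 1] ** 2
        mean_r2 = fold_r2.mean(axis=0)
        best = int(np.argmax(mean_r2))

        pooled = oof[:, best]
        if np.std(pooled) > 0:
            self.cv_r2_ = float(np.corrcoef(pooled, y)[0, 1] ** 2)
        else:
            self.cv_r2_ = 0.0

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs_full, _ = enet_path(Z, y, l1_ratio=l1, alphas=grid, max_iter=3000)
        w = coefs_full[:, best]
        w = np.where(sds > 0, w, 0.0)
        self.lambda_path_ = grid
        self.nonzero_path_ = np.count_nonzero(coefs_full, axis=0)
        self.lambda_ = float(grid[best])
        self.intercept_ = float(y.mean() - Z.mean(axis=0) @ w)
        nz = np.flatnonzero(w)
        self.model_ = PredictionModel(
            rfu_id=self.rfu_id,
            variant_ids=[X.columns[i] for i in nz],
            weights=w[nz].copy(),
            intercept=self.intercept_,
            means=means[nz].copy(),
            sds=safe_sds[nz].copy(),
            family=self.family,
            mixing_alpha=l1,
            lambda_=self.lambda_,
            variant_set=self.variant_set,
            cv_r2=self.cv_r2_,
        )
        return self

    def predict(self, X) -> np.ndarray:
        pred, _ = predict_gdrfu(self.model_, X)
        return pred


def fit_penalized_model(
    X: pd.DataFrame,
    y,
    family: str = "lasso",
    mixing_alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    rfu_id: str = "",
    variant_set: str = "",
) -> PredictionModel:
    """Train one per-RFU model and return its serializable form."""
    est = PenalizedRFUModel(
        family=family, mixing_alpha=mixing_alpha, folds=folds, seed=seed,
        rfu_id=rfu_id, variant_set=variant_set,
    ).fit(X, y)
    return est.model_


def select_best_model(candidates: list[PredictionModel]) -> PredictionModel:
    """Pick the best candidate across variant sets and penalty families.

    Highest cv R^2 wins; ties prefer fewer nonzero weights, then the
    lexicographically first variant-set label.  The winner's
    ``predictable`` flag is set from the strict cv R^2 > 0.01 rule.
    """
    if not candidates:
        raise ValueError("no candidate models")
    best = sorted(
        candidates,
        key=lambda m: (-(m.cv_r2 if np.isfinite(m.cv_r2) else -np.inf), m.n_nonzero, str(m.variant_set)),
    )[0]
    best.predictable = bool(best.cv_r2 > PREDICTABLE_CV_R2)
    return best


def predict_gdrfu(model: PredictionModel, g) -> tuple[np.ndarray, np.ndarray]:
    """Impute gdRFU abundance into a genotype cohort.

    ``g`` is a :class:`GenotypeMatrix` or dosage DataFrame.  Model variants
    absent from the cohort contribute zero after standardization
    (equivalent to mean imputation); the second return value is the
    per-individual absolute weight mass lost to missing variants.  A model
    with nonzero weights and no overlapping variant is an error.
    """
    X = g.dosages if isinstance(g, GenotypeMatrix) else g
    n = X.shape[0]
    pred = np.full(n, model.intercept, dtype=float)
    missing_mass = np.zeros(n)
    present = [v in X.columns for v in model.variant_ids]
    if model.variant_ids and not any(present):
        raise ValueError("no model variant present in the genotype matrix")
    for ok, vid, w, mu, sd in zip(
        present, model.variant_ids, model.weights, model.means, model.sds
    ):
        if ok:
            z = (X[vid].to_numpy(dtype=float) - mu) / sd
            pred += w * z
        else:
            missing_mass += abs(w)
    return pred, missing_mass


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    rfu_id: str
    h2: float
    se: float
    variant_set: str = ""


def compute_grm(X, variant_set: str = "") -> np.ndarray:
    """Genetic relationship matrix A = Z Z' / m from standardized dosages.

    Monomorphic variants carry no information and are dropped; an input
    with only monomorphic variants is an error.
    """
    D = (X.dosages if isinstance(X, GenotypeMatrix) else X).to_numpy(dtype=float)
    if D.shape[1] < 2:
        raise ValueError("need at least 2 variants for a GRM")
    sds = D.std(axis=0, ddof=0)
    poly = sds > 0
    if not poly.any():
        raise ValueError("all variants are monomorphic")
    Z = (D[:, poly] - D[:, poly].mean(axis=0)) / sds[poly]
    m = Z.shape[1]
    return Z @ Z.T / m


def estimate_heritability(
    grm: np.ndarray,
    y,
    rfu_id: str = "",
    variant_set: str = "",
) -> HeritabilityEstimate:
    """Single-component REML heritability with a [0, 1] constraint.

    Model: y ~ N(mu, sigma_g^2 A + sigma_e^2 I).  The GRM is
    eigendecomposed once and the restricted likelihood profiled over
    h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) on [0, 1]; estimates are
    clamped at the boundary rather than allowed negative.  The standard
    error comes from the numerical curvature of the restricted
    log-likelihood at the optimum.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    A = np.asarray(grm, dtype=float)
    if A.shape != (n, n):
        raise ValueError("GRM shape does not match trait length")
    if np.max(np.abs(A - A.T)) > 1e-8:
        raise ValueError("GRM must be symmetric")
    d, U = np.linalg.eigh(A)
    if d.min() < -1e-6:
        raise ValueError(f"GRM is not positive semidefinite (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg2_reml(h2: float) -> float:
        w = h2 * d + (1.0 - h2)
        xvx = np.sum(xt * xt / w)
        xvy = np.sum(xt * yt / w)
        yvy = np.sum(yt * yt / w)
        ypy = max(yvy - xvy * xvy / xvx, 1e-300)
        sigma2 = ypy / (n - 1)
        return (n - 1) * np.log(sigma2) + np.sum(np.log(w)) + np.log(xvx)

    eps = 1e-6
    res = optimize.minimize_scalar(neg2_reml, bounds=(0.0, 1.0 - eps), method="bounded")
    h2 = float(np.clip(res.x, 0.0, 1.0))
    # near-boundary solutions snap to the constraint
    if h2 < 1e-4 and neg2_reml(0.0) <= res.fun + 1e-9:
        h2 = 0.0
    step = 1e-4
    lo, hi = max(h2 - step, 0.0), min(h2 + step, 1.0 - eps)
    curv = (neg2_reml(hi) - 2.0 * neg2_reml((lo + hi) / 2) + neg2_reml(lo)) / ((hi - lo) / 2) ** 2
    se = float(np.sqrt(2.0 / curv)) if curv > 0 else float("nan")
    return HeritabilityEstimate(rfu_id=rfu_id, h2=h2, se=se, variant_set=variant_set)


# ---------------------------------------------------------------------------
# weight serialization
# ---------------------------------------------------------------------------

def export_weights(models: list[PredictionModel], path) -> None:
    """Write models as a weight TSV plus a JSON metadata sidecar.

    The TSV has one row per nonzero weight (rfu_id, variant_id, ref, alt,
    weight, mean, sd); the sidecar ``<path>.json`` carries per-model
    intercepts, penalties, cv R^2 and variant-set labels.  Floats are
    written at full precision so import reproduces predictions exactly.
    """
    rows = []
    meta = {}
    for m in models:
        for vid, w, mu, sd in zip(m.variant_ids, m.weights, m.means, m.sds):
            ref, alt = m.alleles.get(vid, (".", "."))
            rows.append((m.rfu_id, vid, ref, alt, repr(float(w)), repr(float(mu)), repr(float(sd))))
        meta[str(m.rfu_id)] = {
            "intercept": float(m.intercept),
            "family": m.family,
            "mixing_alpha": float(m.mixing_alpha),
            "lambda": float(m.lambda_),
            "variant_set": m.variant_set,
            "cv_r2": float(m.cv_r2),
            "predictable": m.predictable,
        }
    with open(path, "w") as fh:
        fh.write("rfu_id\tvariant_id\tref\talt\tweight\tmean\tsd\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def import_weights(path) -> list[PredictionModel]:
    """Read models written by :func:`export_weights` (round-trip exact)."""
    with open(f"{path}.json") as fh:
        meta = json.load(fh)
    per_rfu: dict[str, dict] = {r: {"variant_ids": [], "weights": [], "means": [], "sds": [], "alleles": {}} for r in meta}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["rfu_id", "variant_id", "ref", "alt", "weight", "mean", "sd"]:
            raise ValueError(f"malformed weight file header: {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"malformed weight row at line {lineno}")
            rfu, vid, ref, alt, w, mu, sd = parts
            try:
                rec = per_rfu[rfu]
                rec["variant_ids"].append(vid)
                rec["weights"].append(float(w))
                rec["means"].append(float(mu))
                rec["sds"].append(float(sd))
                rec["alleles"][vid] = (ref, alt)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed weight row at line {lineno}: {exc}") from exc
    models = []
    for rfu, info in meta.items():
        rec = per_rfu[rfu]
        models.append(PredictionModel(
            rfu_id=rfu,
            variant_ids=rec["variant_ids"],
            weights=np.array(rec["weights"], dtype=float),
            intercept=info["intercept"],
            means=np.array(rec["means"], dtype=float),
            sds=np.array(rec["sds"], dtype=float),
            family=info["family"],
            mixing_alpha=info["mixing_alpha"],
            lambda_=info["lambda"],
            variant_set=info["variant_set"],
            cv_r2=info["cv_r2"],
            predictable=info["predictable"],
            alleles=rec["alleles"],
        ))
    return models
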