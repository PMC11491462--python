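"""Reproducible validation benchmarks for the pipeline.

Each function regenerates its inputs from a seed, runs the relevant stage
of the package, and returns summary statistics: printed multiple-testing
bars, type-I calibration of the rfuQTL scan under a fully null cohort,
REML heritability and lasso support recovery under planted architectures,
end-to-end disease and survival recovery, agreement with independent
brute-force oracles, and serialization/generation round trips.

Problem sizes are desk-scale (hundreds of individuals and variants rather
than biobank cohorts); they are chosen so each benchmark exercises the
statistical property it certifies.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import AtchleyEncoder
from .normalize import inverse_normal_columns, normalize_pipeline, quantile_normalize_individuals
from .phenome import cox_scan, phenome_scan
from .prediction import (
    compute_grm,
    estimate_heritability,
    export_weights,
    fit_penalized_model,
    import_weights,
    predict_gdrfu,
)
from .qc import filter_rfus
from .qtl import AnnotationTrack, annotation_enrichment, association_scan, bonferroni_threshold
from .quantify import AbundanceMatrix, RFUAssigner, RFUCentroids
from .simulate import (
    SimulationConfig,
    _clones_for_rfu,
    latent_genetic_values,
    simulate_centroids,
    simulate_covariates,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_repertoires,
    simulate_rfu_effects,
)


def _sub(seed: int, k: int) -> int:
    """Derived seed below 2**31."""
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# printed multiple-testing thresholds
# ---------------------------------------------------------------------------

def printed_bonferroni_bars() -> dict[str, float]:
    """The five cohort-scale Bonferroni bars, at 2 significant figures."""
    bars = {
        "bonferroni_rfuqtl_genomewide": bonferroni_threshold(5e-8, 4953),
        "bonferroni_hla_haplotype": bonferroni_threshold(0.05, 4953, 28),
        "bonferroni_subset_friedman": bonferroni_threshold(0.05, 1351),
        "bonferroni_rfuwas_phenome": bonferroni_threshold(0.05, 1086, 1351),
        "bonferroni_tf_enrichment": bonferroni_threshold(0.05, 324),
    }
    return {k: float(f"{v:.1e}") for k, v in bars.items()}


# ---------------------------------------------------------------------------
# scan calibration under a fully null cohort
# ---------------------------------------------------------------------------

def null_scan_calibration(seed: int = 101, n_individuals: int = 500) -> dict:
    """rfuQTL scan on a zero-effect cohort: empirical type-I error and KS p.

    Runs the full path (repertoire generation, quantification, two-stage
    normalization, hidden-factor residualization, mass regression) with all
    genetic effects removed, giving ~6000 null tests.
    """
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        n_rfus=30,
        n_causal_variants_per_rfu=0,
        n_variants_per_locus={"TRB": 120, "HLA": 80},
        repertoire_size_range=(800, 1200),
        seed=_sub(seed, 1),
    )
    g = simulate_genotypes(cfg)
    eff = simulate_rfu_effects(cfg, g)
    centroids, templates = simulate_centroids(cfg)
    reps = simulate_repertoires(g, eff, centroids, cfg, templates)
    raw = RFUAssigner().fit(centroids).transform(reps)
    cov = simulate_covariates(cfg, raw.individual_ids)
    traits = normalize_pipeline(filter_rfus(raw), cov, n_hidden_factors=2)
    scan = association_scan(g, traits)
    p = scan.loc[scan["flag"] == "", "p"].to_numpy()
    return {
        "type_i_error_at_005": float((p < 0.05).mean()),
        "ks_uniformity_p": float(stats.kstest(p, "uniform").pvalue),
        "n_tests": int(p.size),
    }


# ---------------------------------------------------------------------------
# heritability and prediction recovery
# ---------------------------------------------------------------------------

def _grm_trait(n: int, m: int, h2: float, seed: int):
    """GRM plus a trait with an infinitesimal architecture at the given h2."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float))
    A = compute_grm(X)
    Z = (X - X.mean()) / X.std(ddof=0)
    u = rng.normal(0, math.sqrt(max(h2, 1e-12) / m), size=m)
    y = Z.to_numpy() @ u + rng.normal(0, math.sqrt(1 - h2), size=n)
    return A, y


def heritability_recovery(
    seed: int = 7,
    h2: float = 0.4,
    n: int = 800,
    m: int = 500,
    n_replicates: int = 20,
) -> dict:
    """REML recovery of a simulated h2 plus null-trait behavior."""
    ests = [
        estimate_heritability(*_grm_trait(n, m, h2, _sub(seed, 10 + k))).h2
        for k in range(n_replicates)
    ]
    nulls = [
        estimate_heritability(*_grm_trait(500, 300, 0.0, _sub(seed, 100 + k))).h2
        for k in range(10)
    ]
    return {
        "mean_h2_estimate": float(np.mean(ests)),
        "null_median_h2": float(np.median(nulls)),
        "n_replicates": n_replicates,
    }


def _sparse_trait(n: int, m: int, h2: float, n_causal: int, seed: int):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float),
        columns=[f"v{j}" for j in range(m)],
    )
    causal = rng.choice(m, size=n_causal, replace=False)
    w = rng.normal(0, 1, size=n_causal)
    gv = X.to_numpy()[:, causal] @ w
    gv = (gv - gv.mean()) / gv.std()
    y = math.sqrt(h2) * gv + math.sqrt(1 - h2) * rng.normal(size=n)
    return X, y, {f"v{j}" for j in causal}


def prediction_recovery(
    seed: int = 3,
    n: int = 600,
    m: int = 150,
    h2: float = 0.5,
    n_causal: int = 3,
    n_seeds: int = 10,
) -> dict:
    """Lasso predictability calls and causal-support recovery over seeds."""
    predictable = support = ceiling_ok = 0
    for k in range(n_seeds):
        X, y, causal = _sparse_trait(n, m, h2, n_causal, _sub(seed, 200 + k))
        model = fit_penalized_model(X, y, seed=_sub(seed, 300 + k))
        reml = estimate_heritability(compute_grm(X), y).h2
        predictable += model.cv_r2 > 0.01
        support += len(set(model.variant_ids) & causal) >= 2
        ceiling_ok += model.cv_r2 <= reml + 0.1
    return {
        "predictable_fraction": predictable / n_seeds,
        "support_recovery_fraction": support / n_seeds,
        "cv_r2_below_h2_ceiling_fraction": ceiling_ok / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# end-to-end phenome and survival recovery
# ---------------------------------------------------------------------------

def rfuwas_recovery(
    seed: int = 5,
    n_individuals: int = 20_000,
    n_seeds: int = 10,
    disease_effect: float = 0.3,
    prevalence: float = 0.05,
) -> dict:
    """Top-association recovery of the driving gdRFU and null family-wise control."""
    driver_top = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_individuals=n_individuals, n_rfus=20,
            n_variants_per_locus={"TRB": 60, "HLA": 40},
            disease_effect=disease_effect, baseline_prevalence=prevalence,
            seed=_sub(seed, 400 + k),
        )
        g = simulate_genotypes(cfg)
        gv = latent_genetic_values(g, simulate_rfu_effects(cfg, g))
        pheno = simulate_phenotypes(gv, cfg, driver_rfus=("RFU7",))
        scan = phenome_scan(gv, pheno)
        d = scan[scan["trait_id"] == "disease_RFU7"]
        driver_top += d.loc[d["p"].idxmin(), "rfu_id"] == "RFU7"

    null_zero = 0
    n_null_seeds = 20
    for k in range(n_null_seeds):
        cfg = SimulationConfig(
            n_individuals=n_individuals, n_rfus=50,
            n_variants_per_locus={"TRB": 40, "HLA": 25},
            disease_effect=0.0, baseline_prevalence=prevalence,
            seed=_sub(seed, 600 + k),
        )
        g = simulate_genotypes(cfg)
        gv = latent_genetic_values(g, simulate_rfu_effects(cfg, g))
        pheno = simulate_phenotypes(gv, cfg, driver_rfus=("RFU0",), n_null_traits=26)
        scan = phenome_scan(gv, pheno)
        null_zero += int(scan["significant"].sum()) == 0
    return {
        "driver_top_fraction": driver_top / n_seeds,
        "null_zero_hit_fraction": null_zero / n_null_seeds,
        "n_seeds": n_seeds,
    }


def survival_recovery(
    seed: int = 9,
    hazard_ratio: float = 1.5,
    n_individuals: int = 2000,
    n_seeds: int = 10,
) -> dict:
    """Cox log-HR recovery at HR=1.5 plus null BH-FDR control over 50 seeds."""
    logs = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            n_individuals=n_individuals, hazard_ratio=hazard_ratio,
            censoring_rate=0.2, n_rfus=10,
            n_variants_per_locus={"TRB": 40, "HLA": 25},
            seed=_sub(seed, 700 + k),
        )
        g = simulate_genotypes(cfg)
        gv = latent_genetic_values(g, simulate_rfu_effects(cfg, g))
        pheno = simulate_phenotypes(gv, cfg, driver_rfus=("RFU0",))
        out = cox_scan(gv[["RFU0"]], pheno, covariates=pheno.covariates[["sex"]], min_events=130)
        logs.append(float(out["log_hr"].iloc[0]))

    fracs = []
    for k in range(50):
        rng = np.random.default_rng(_sub(seed, 800 + k))
        cfg = SimulationConfig(
            n_individuals=400, hazard_ratio=1.0, censoring_rate=0.2, n_rfus=5,
            n_variants_per_locus={"TRB": 20, "HLA": 10}, seed=_sub(seed, 900 + k),
        )
        g = simulate_genotypes(cfg)
        gv = latent_genetic_values(g, simulate_rfu_effects(cfg, g))
        pheno = simulate_phenotypes(gv, cfg, driver_rfus=("RFU0",))
        null_gd = pd.DataFrame(
            rng.normal(size=(len(gv), 10)), index=gv.index,
            columns=[f"N{j}" for j in range(10)],
        )
        out = cox_scan(null_gd, pheno, covariates=pheno.covariates[["sex"]], min_events=50)
        fracs.append(float(out["significant"].mean()))
    mean_log_hr = float(np.mean(logs))
    return {
        "mean_log_hr": mean_log_hr,
        "log_hr_relative_error": abs(mean_log_hr - math.log(hazard_ratio)) / math.log(hazard_ratio),
        "null_fdr_discovery_fraction": float(np.mean(fracs)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# oracle agreement
# ---------------------------------------------------------------------------

def assignment_oracle_agreement(seed: int = 13, n_instances: int = 5) -> dict:
    """Fraction of nearest-centroid assignments agreeing with exhaustive search."""
    rng = np.random.default_rng(_sub(seed, 1000))
    encoder = AtchleyEncoder()
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    agree = total = 0
    for _ in range(n_instances):
        seqs = ["".join(rng.choice(aas, size=rng.integers(8, 20))) for _ in range(200)]
        cents = ["".join(rng.choice(aas, size=rng.integers(8, 20))) for _ in range(50)]
        centroids = RFUCentroids(matrix=encoder.encode_many(cents))
        got = RFUAssigner().fit(centroids).assign_indices(seqs)
        for s, j in zip(seqs, got):
            v = encoder.encode(s)
            best = int(np.argmin([np.linalg.norm(v - c) for c in centroids.matrix]))
            agree += int(j == best)
            total += 1
    return {"agreement_fraction": agree / total, "n_assignments": total}


def _hypergeom_tail(k, n_hits, n_in, n_total):
    return sum(
        math.comb(n_in, j) * math.comb(n_total - n_in, n_hits - j) / math.comb(n_total, n_hits)
        for j in range(k, min(n_hits, n_in) + 1)
    )


def fisher_oracle_max_diff(max_margin: int = 30) -> dict:
    """Max |Fisher p - brute-force hypergeometric tail| over small tables."""
    worst = 0.0
    n_tables = 0
    for n_total in (10, 20, max_margin):
        positions = pd.DataFrame(
            {"chrom": "7", "pos": [100 + i for i in range(n_total)]},
            index=[f"v{i}" for i in range(n_total)],
        )
        for n_in in range(1, n_total):
            track = AnnotationTrack(
                "t", pd.DataFrame({"chrom": ["7"], "start": [100], "end": [100 + n_in]})
            )
            for n_hits in range(1, n_total):
                hits = {f"v{i}" for i in range(n_hits)}
                _, p = annotation_enrichment(hits, set(positions.index), track, positions)
                k = min(n_hits, n_in)
                expected = _hypergeom_tail(k, n_hits, n_in, n_total)
                worst = max(worst, abs(p - expected))
                n_tables += 1
    return {"max_abs_p_difference": float(worst), "n_tables": n_tables}


def cox_reference_max_diff(seed: int = 17, n_datasets: int = 5) -> dict:
    """Max |log HR difference| against an independent Cox implementation."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    from .phenome import PhenotypeTable

    worst = 0.0
    for k in range(n_datasets):
        rng = np.random.default_rng(_sub(seed, 1100 + k))
        n = 200
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        t_event = rng.exponential(1.0 / (0.1 * np.exp(0.4 * x - 0.2 * z)))
        cens = rng.exponential(20.0, size=n)
        time = np.minimum(t_event, cens)
        event = t_event <= cens
        ids = [f"I{i}" for i in range(n)]
        table = PhenotypeTable(
            survival={"c": pd.DataFrame({"time": time, "event": event.astype(int)}, index=ids)},
            covariates=pd.DataFrame({"z": z}, index=ids),
        )
        gd = pd.DataFrame({"RFU0": x}, index=ids)
        mine = cox_scan(gd, table, covariates=table.covariates, min_events=10)
        y = np.array(list(zip(event, time)), dtype=[("event", bool), ("time", float)])
        ref = CoxPHSurvivalAnalysis().fit(
            np.column_stack([(x - x.mean()) / x.std(), z]), y
        )
        worst = max(worst, abs(float(mine["log_hr"].iloc[0]) - float(ref.coef_[0])))
    return {"max_abs_log_hr_difference": float(worst), "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

def weight_roundtrip(seed: int = 19, tmpdir=None) -> dict:
    """Export -> import -> predict reproduces predictions bit for bit."""
    import tempfile
    from pathlib import Path

    X, y, _ = _sparse_trait(300, 50, 0.5, 3, _sub(seed, 1200))
    model = fit_penalized_model(X, y, seed=_sub(seed, 1201), rfu_id="RFU0")
    with tempfile.TemporaryDirectory() as d:
        path = Path(tmpdir or d) / "weights.tsv"
        export_weights([model], path)
        loaded = import_weights(path)[0]
    p1, _ = predict_gdrfu(model, X)
    p2, _ = predict_gdrfu(loaded, X)
    return {
        "bit_exact": bool(np.array_equal(p1, p2)),
        "max_abs_difference": float(np.max(np.abs(p1 - p2))),
        "n_individuals": X.shape[0],
    }


def clone_roundtrip_fraction(seed: int = 23, clones_per_rfu: int = 50) -> dict:
    """Generated clones re-assign to the RFU that emitted them."""
    cfg = SimulationConfig(n_rfus=40, seed=_sub(seed, 1300))
    centroids, templates = simulate_centroids(cfg)
    assigner = RFUAssigner().fit(centroids)
    rng = cfg.rng("roundtrip")
    ok = total = 0
    for r in range(centroids.n_rfus):
        seqs = _clones_for_rfu(templates[r], r, clones_per_rfu, rng, assigner)
        idx = assigner.assign_indices(seqs)
        ok += int((idx == r).sum())
        total += len(seqs)
    return {"recovery_fraction": ok / total, "n_clones": total}


def monotone_invariance_max_diff(seed: int = 29) -> dict:
    """Quantile + inverse-normal output under per-individual monotone distortion."""
    rng = np.random.default_rng(_sub(seed, 1400))
    raw = rng.gamma(2.0, size=(20, 40))
    distorted = raw.copy()
    for i in range(raw.shape[0]):
        distorted[i] = np.exp(raw[i] / (1.0 + i)) + i
    za = inverse_normal_columns(
        quantile_normalize_individuals(AbundanceMatrix(pd.DataFrame(raw)))
    )
    zb = inverse_normal_columns(
        quantile_normalize_individuals(AbundanceMatrix(pd.DataFrame(distorted)))
    )
    diff = float(np.max(np.abs(za.data.to_numpy() - zb.data.to_numpy())))
    return {"max_abs_difference": diff, "n_values": int(za.data.size)}
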