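"""Penalized gdRFU models, GRM/REML heritability, weight serialization."""

import numpy as np
import pandas as pd
import pytest

import rfuwas as rw
from rfuwas.prediction import PenalizedRFUModel, PredictionModel


def simulate_sparse_trait(n, m, h2, n_causal, seed):
    """Dosage matrix + trait with a planted sparse architecture at given h2."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)).astype(float),
        columns=[f"v{j}" for j in range(m)],
    )
    causal = rng.choice(m, size=n_causal, replace=False)
    w = rng.normal(0, 1, size=n_causal)
    gvals = X.to_numpy()[:, causal] @ w
    gvals = (gvals - gvals.mean()) / gvals.std()
    y = np.sqrt(h2) * gvals + np.sqrt(1 - h2) * rng.normal(size=n)
    return X, y, [f"v{j}" for j in causal]


class TestVariantSets:
    def test_no_hits_leaves_span_sets_empty(self, genotypes):
        sets = rw.build_variant_sets(genotypes, scan=None)
        assert sets["TRB_s"] == [] and sets["HLA_s"] == [] and sets["TRB+HLA_s"] == []
        assert len(sets) == 9

    def test_span_rule_covers_first_to_last_hit(self, genotypes):
        # plant hits at two TRB variants and check the inclusive span
        vids = [v for v in genotypes.variant_ids if v.startswith("TRB")]
        scan = pd.DataFrame({
            "predictor_id": [vids[3], vids[10]],
            "rfu_id": ["RFU0", "RFU0"],
            "p": [1e-12, 1e-9],
            "flag": ["", ""],
        })
        sets = rw.build_variant_sets(genotypes, scan)
        lo = genotypes.variants.loc[vids[3], "pos"]
        hi = genotypes.variants.loc[vids[10], "pos"]
        expected = [
            v for v in vids
            if lo <= genotypes.variants.loc[v, "pos"] <= hi
        ]
        assert sets["TRB_s"] == expected

    def test_combined_window_set_is_the_union(self, genotypes):
        sets = rw.build_variant_sets(genotypes)
        assert set(sets["TRB+HLA_window1mb"]) == set(sets["TRB_window1mb"]) | set(sets["HLA_window1mb"])

    def test_missing_locus_is_an_error(self, genotypes):
        with pytest.raises(ValueError, match="absent"):
            rw.build_variant_sets(genotypes, loci=("TRB", "IGK"))


class TestPenalizedFit:
    def test_at_lambda_max_all_weights_are_zero(self, rng):
        X = pd.DataFrame(rng.binomial(2, 0.3, size=(100, 20)).astype(float))
        y = rng.normal(size=100)
        est = PenalizedRFUModel(seed=1).fit(X, y)
        # largest grid point yields the all-zero solution along the stored path
        assert est.nonzero_path_[0] == 0

    def test_orthonormal_design_matches_soft_thresholding(self, rng):
        # columns of an orthogonal matrix scaled so Z'Z = n I
        n, m = 64, 8
        raw = rng.normal(size=(n, m))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered, so Z'1 = 0
        Z = Q * np.sqrt(n)
        y = rng.normal(size=n) + Z[:, 0] * 0.8
        lam = 0.05
        from sklearn.linear_model import Lasso
        fitted = Lasso(alpha=lam, fit_intercept=True, tol=1e-12).fit(Z, y)
        ols = Z.T @ (y - y.mean()) / n
        expected = np.sign(ols) * np.clip(np.abs(ols) - lam, 0, None)
        np.testing.assert_allclose(fitted.coef_, expected, atol=1e-6)

    def test_support_recovery_under_planted_signal(self):
        X, y, causal = simulate_sparse_trait(n=600, m=120, h2=0.5, n_causal=3, seed=5)
        model = rw.fit_penalized_model(X, y, seed=5)
        recovered = set(model.variant_ids) & set(causal)
        assert len(recovered) >= 2
        assert model.cv_r2 > 0.01

    def test_nonzero_count_monotone_along_lambda_path(self, rng):
        X = pd.DataFrame(rng.binomial(2, 0.3, size=(120, 30)).astype(float))
        y = X.to_numpy()[:, 0] * 0.5 + rng.normal(size=120)
        est = PenalizedRFUModel(seed=3).fit(X, y)
        diffs = np.diff(est.nonzero_path_.astype(int))
        # sparsity should not decrease as the penalty relaxes (small jitter allowed)
        assert (diffs >= -1).all() and est.nonzero_path_[-1] >= est.nonzero_path_[0]

    def test_same_seed_reproduces_cv_r2_exactly(self):
        X, y, _ = simulate_sparse_trait(n=200, m=40, h2=0.4, n_causal=3, seed=9)
        a = PenalizedRFUModel(seed=42).fit(X, y).cv_r2_
        b = PenalizedRFUModel(seed=42).fit(X, y).cv_r2_
        assert a == b

    def test_constant_trait_rejected(self, rng):
        X = pd.DataFrame(rng.binomial(2, 0.3, size=(60, 5)).astype(float))
        with pytest.raises(ValueError, match="constant trait"):
            PenalizedRFUModel().fit(X, np.ones(60))

    def test_elastic_net_family_runs(self):
        X, y, _ = simulate_sparse_trait(n=150, m=30, h2=0.5, n_causal=3, seed=2)
        model = rw.fit_penalized_model(X, y, family="elastic_net", seed=2)
        assert model.mixing_alpha == 0.5


class TestModelSelection:
    def make(self, cv_r2, nnz=3, label="TRB_o"):
        return PredictionModel(
            rfu_id="r", variant_ids=[f"v{i}" for i in range(nnz)],
            weights=np.ones(nnz), intercept=0.0,
            means=np.zeros(nnz), sds=np.ones(nnz),
            cv_r2=cv_r2, variant_set=label,
        )

    def test_single_candidate_returned(self):
        m = self.make(0.2)
        assert rw.select_best_model([m]) is m

    def test_highest_cv_r2_wins_and_is_predictable(self):
        best = rw.select_best_model([self.make(0.02), self.make(0.05)])
        assert best.cv_r2 == 0.05 and best.predictable is True

    def test_exactly_001_is_not_predictable(self):
        assert rw.select_best_model([self.make(0.01)]).predictable is False

    def test_ties_prefer_sparser_then_lexicographic(self):
        a = self.make(0.1, nnz=5, label="B_set")
        b = self.make(0.1, nnz=2, label="C_set")
        c = self.make(0.1, nnz=2, label="A_set")
        assert rw.select_best_model([a, b, c]) is c


class TestPrediction:
    def fitted_model(self):
        X, y, _ = simulate_sparse_trait(n=300, m=40, h2=0.6, n_causal=4, seed=8)
        return rw.fit_penalized_model(X, y, seed=8), X

    def test_full_overlap_equals_manual_dot_product(self):
        model, X = self.fitted_model()
        pred, missing = rw.predict_gdrfu(model, X)
        Z = (X[model.variant_ids].to_numpy() - model.means) / model.sds
        np.testing.assert_allclose(pred, model.intercept + Z @ model.weights, atol=1e-12)
        assert np.all(missing == 0)

    def test_masked_variants_contribute_zero(self):
        model, X = self.fitted_model()
        keep = model.variant_ids[: len(model.variant_ids) // 2]
        pred_masked, missing = rw.predict_gdrfu(model, X[keep])
        Z = (X[keep].to_numpy() - model.means[: len(keep)]) / model.sds[: len(keep)]
        manual = model.intercept + Z @ model.weights[: len(keep)]
        np.testing.assert_allclose(pred_masked, manual, atol=1e-12)
        assert np.all(missing > 0)

    def test_no_overlapping_variant_is_an_error(self, rng):
        model, _ = self.fitted_model()
        other = pd.DataFrame(rng.binomial(2, 0.3, size=(10, 3)).astype(float),
                             columns=["x1", "x2", "x3"])
        with pytest.raises(ValueError, match="no model variant"):
            rw.predict_gdrfu(model, other)


class TestGRM:
    def test_symmetry_and_psd(self, rng):
        X = pd.DataFrame(rng.binomial(2, 0.3, size=(50, 100)).astype(float))
        A = rw.compute_grm(X)
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert np.linalg.eigvalsh(A).min() >= -1e-8

    def test_duplicated_individual_has_offdiagonal_near_diagonal(self, rng):
        d = rng.binomial(2, 0.3, size=(20, 300)).astype(float)
        d[1] = d[0]
        A = rw.compute_grm(pd.DataFrame(d))
        assert A[0, 1] == pytest.approx(A[0, 0], rel=1e-9)

    def test_unrelateds_have_near_zero_offdiagonal_mean(self, rng):
        n = 200
        X = pd.DataFrame(rng.binomial(2, rng.uniform(0.1, 0.5, 1000), size=(n, 1000)).astype(float))
        A = rw.compute_grm(X)
        off = A[~np.eye(n, dtype=bool)]
        # sample-centering forces the off-diagonal mean to -1/(n-1) exactly
        assert abs(off.mean()) < 0.01

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            rw.compute_grm(pd.DataFrame(np.ones((10, 5))))


class TestHeritability:
    def grm_and_values(self, n, m, h2, seed):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float))
        A = rw.compute_grm(X)
        Z = (X - X.mean()) / X.std(ddof=0)
        u = rng.normal(0, np.sqrt(h2 / m), size=m)
        g = Z.to_numpy() @ u
        e = rng.normal(0, np.sqrt(1 - h2), size=n)
        return A, g + e, g

    def test_pure_genetic_signal_saturates(self):
        A, _, g = self.grm_and_values(300, 200, 1.0, seed=4)
        est = rw.estimate_heritability(A, g)
        assert est.h2 > 0.9

    def test_null_trait_estimates_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.binomial(2, 0.3, size=(500, 300)).astype(float))
            est = rw.estimate_heritability(rw.compute_grm(X), rng.normal(size=500))
            vals.append(est.h2)
        assert np.median(vals) < 0.05

    def test_moderate_h2_recovered(self):
        ests = []
        for seed in range(5):
            A, y, _ = self.grm_and_values(500, 300, 0.4, seed=20 + seed)
            ests.append(rw.estimate_heritability(A, y).h2)
        assert abs(np.mean(ests) - 0.4) < 0.12

    def test_estimates_respect_bounds(self):
        A, y, _ = self.grm_and_values(200, 100, 0.3, seed=1)
        est = rw.estimate_heritability(A, y)
        assert 0.0 <= est.h2 <= 1.0

    def test_asymmetric_matrix_rejected(self, rng):
        A = rng.normal(size=(20, 20))
        with pytest.raises(ValueError, match="symmetric"):
            rw.estimate_heritability(A, rng.normal(size=20))


class TestWeightSerialization:
    def test_round_trip_reproduces_predictions_bit_for_bit(self, tmp_path):
        X, y, _ = simulate_sparse_trait(n=200, m=30, h2=0.5, n_causal=3, seed=6)
        model = rw.fit_penalized_model(X, y, seed=6, rfu_id="RFU7", variant_set="TRB_o")
        path = tmp_path / "weights.tsv"
        rw.export_weights([model], path)
        loaded = rw.import_weights(path)
        assert len(loaded) == 1
        p1, _ = rw.predict_gdrfu(model, X)
        p2, _ = rw.predict_gdrfu(loaded[0], X)
        np.testing.assert_array_equal(p1, p2)
        assert loaded[0].cv_r2 == model.cv_r2

    def test_empty_model_writes_valid_file(self, tmp_path):
        empty = PredictionModel(
            rfu_id="RFU0", variant_ids=[], weights=np.array([]), intercept=0.3,
            means=np.array([]), sds=np.array([]),
        )
        path = tmp_path / "w.tsv"
        rw.export_weights([empty], path)
        loaded = rw.import_weights(path)
        assert loaded[0].n_nonzero == 0 and loaded[0].intercept == 0.3

    def test_hand_written_file_predicts_manual_dot_product(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "rfu_id\tvariant_id\tref\talt\tweight\tmean\tsd\n"
            "RFU1\tva\tA\tG\t0.5\t1.0\t0.5\n"
            "RFU1\tvb\tA\tG\t-0.25\t0.5\t1.0\n"
        )
        (tmp_path / "w.tsv.json").write_text(
            '{"RFU1": {"intercept": 0.1, "family": "lasso", "mixing_alpha": 1.0,'
            ' "lambda": 0.0, "variant_set": "TRB_o", "cv_r2": 0.2, "predictable": true}}'
        )
        model = rw.import_weights(path)[0]
        X = pd.DataFrame({"va": [2.0], "vb": [0.5]})
        pred, _ = rw.predict_gdrfu(model, X)
        manual = 0.1 + 0.5 * (2.0 - 1.0) / 0.5 + (-0.25) * (0.5 - 0.5) / 1.0
        assert pred[0] == pytest.approx(manual)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text(
            "rfu_id\tvariant_id\tref\talt\tweight\tmean\tsd\n"
            "RFU1\tva\tA\tG\t0.5\n"
        )
        (tmp_path / "w.tsv.json").write_text(
            '{"RFU1": {"intercept": 0.0, "family": "lasso", "mixing_alpha": 1.0,'
            ' "lambda": 0.0, "variant_set": "", "cv_r2": 0.0, "predictable": false}}'
        )
        with pytest.raises(ValueError, match="line 2"):
            rw.import_weights(path)


def test_cv_r2_stays_below_heritability_ceiling():
    """Prediction accuracy cannot beat the variance genetics explains."""
    X, y, _ = simulate_sparse_trait(n=500, m=150, h2=0.4, n_causal=3, seed=13)
    model = rw.fit_penalized_model(X, y, seed=13)
    h2 = rw.estimate_heritability(rw.compute_grm(X), y).h2
    assert model.cv_r2 <= h2 + 0.1
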