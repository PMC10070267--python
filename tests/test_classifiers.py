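"""Gene ranking, particle swarm, SVM and elastic-net training contracts."""

import numpy as np
import pandas as pd
import pytest

from tepseq.classifiers import (ClassifierModel, PSOConfig, _fit_en_point, pso_optimize,
                                predict_proba, rank_candidate_genes, train_elastic_net,
                                train_pso_svm)
from tepseq.evaluation import roc_auc
from tepseq.partitioning import PartitionConfig, assign_partitions
from tepseq.synthetic_data import (SimConfig, balanced_design, build_confounded_design,
                                   attach_lib_size, simulate_counts)


def welch_t_oracle(a, b):
    """Loop-based Welch t statistic."""
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    return (ma - mb) / np.sqrt(va / len(a) + vb / len(b))


class TestRankCandidateGenes:
    def _expr(self, rng, n_genes=30, n=20):
        x = rng.normal(0, 1, (n_genes, n))
        labels = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        return pd.DataFrame(x, index=[f"g{i:02d}" for i in range(n_genes)],
                            columns=[f"s{i}" for i in range(n)]), labels

    def test_flat_gene_ranked_last_shifted_first(self, rng):
        expr, labels = self._expr(rng)
        expr.iloc[0] = 1.0  # identical means, zero variance -> statistic 0
        expr.iloc[1, :10] += 4.0  # 4-SD shift in cases
        ranking = rank_candidate_genes(expr, labels)
        assert ranking.iloc[0]["gene_id"] == "g01"
        assert ranking.iloc[-1]["gene_id"] == "g00"

    def test_matches_welch_oracle(self, rng):
        expr, labels = self._expr(rng)
        ranking = rank_candidate_genes(expr, labels)
        stats = {}
        for g in expr.index:
            a = expr.loc[g][labels == "case"].tolist()
            b = expr.loc[g][labels == "control"].tolist()
            stats[g] = abs(welch_t_oracle(a, b))
        oracle_order = sorted(expr.index, key=lambda g: (-stats[g], g))
        assert ranking["gene_id"].tolist() == oracle_order

    def test_single_class_is_error(self, rng):
        expr, _ = self._expr(rng)
        with pytest.raises(ValueError):
            rank_candidate_genes(expr, np.array(["case"] * expr.shape[1]))


class TestPSO:
    def test_constant_objective(self):
        cfg = PSOConfig(n_particles=5, n_iterations=3,
                        bounds={"x": (-1.0, 1.0)}, seed=0)
        _, best, _ = pso_optimize(lambda p: 0.3, cfg)
        assert best == 0.3

    def test_sphere_beats_random_search(self):
        cfg = PSOConfig(n_particles=100, n_iterations=10,
                        bounds={"x": (-5.0, 5.0), "y": (-5.0, 5.0)}, seed=0)
        pos, best, trace = pso_optimize(lambda p: float(p @ p), cfg)
        assert best < 0.01
        # typical random search with the same evaluation budget does worse
        rands = []
        for s in range(5):
            rng = np.random.default_rng(s)
            rands.append(min(float(p @ p) for p in rng.uniform(-5, 5, size=(1100, 2))))
        assert best < np.median(rands)

    def test_trace_monotone_nonincreasing(self, rng):
        cfg = PSOConfig(n_particles=20, n_iterations=8,
                        bounds={"x": (-3.0, 3.0)}, seed=1)
        _, _, trace = pso_optimize(lambda p: float(np.cos(3 * p[0]) + p[0] ** 2), cfg)
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_single_stationary_particle_reduces_to_initial_eval(self):
        cfg = PSOConfig(n_particles=1, n_iterations=4, cognitive=0.0, social=0.0,
                        inertia=0.0, bounds={"x": (2.0, 4.0)}, seed=7)
        pos, best, _ = pso_optimize(lambda p: float(p[0]), cfg)
        x0 = np.random.default_rng(7).uniform(2.0, 4.0, size=(1, 1))[0, 0]
        assert best == pytest.approx(x0)

    def test_nonfinite_objective_penalised(self):
        cfg = PSOConfig(n_particles=4, n_iterations=2, bounds={"x": (0.0, 1.0)}, seed=0)
        _, best, _ = pso_optimize(lambda p: np.nan, cfg)
        assert best == 1.0


class TestElasticNet:
    def _toy(self, rng, n=40):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        x = rng.normal(0, 1, (2, n))
        x[0] += 5 * y  # perfectly separating gene
        expr = pd.DataFrame(x, index=["gA", "gB"], columns=[f"s{i}" for i in range(n)])
        return expr, y

    def test_separable_toy_training_auc_one(self, rng):
        expr, y = self._toy(rng)
        model = train_elastic_net(expr, y, n_folds=5, seed=0, n_lambdas=20)
        scores = model.decision_scores(
            ((expr.to_numpy().T - model.scaler_mean) / model.scaler_scale))
        assert roc_auc(y, scores) == 1.0

    def test_infinite_lambda_zeroes_coefficients(self, rng):
        expr, y = self._toy(rng)
        x = ((expr.to_numpy().T - expr.to_numpy().T.mean(0))
             / expr.to_numpy().T.std(0))
        coef, _ = _fit_en_point(x, y.astype(float), alpha=1.0, lam=1e4)
        assert np.all(coef == 0.0)

    def test_lasso_support_matches_sklearn_oracle(self, rng):
        # 10 samples x 20 genes; our FISTA solver vs an independent solver
        from sklearn.linear_model import LogisticRegression
        n, p = 10, 20
        x = rng.normal(0, 1, (n, p))
        y = (x[:, 0] + 0.5 * x[:, 1] + 0.3 * rng.normal(size=n) > 0).astype(float)
        x = (x - x.mean(0)) / x.std(0)
        for lam in (0.02, 0.05, 0.1):
            coef, b0 = _fit_en_point(x, y, alpha=1.0, lam=lam, max_iter=20000, tol=1e-12)
            sk = LogisticRegression(penalty="l1", solver="saga", C=1.0 / (n * lam),
                                    max_iter=50000, tol=1e-10).fit(x, y)
            assert np.abs(coef - sk.coef_[0]).max() < 1e-3
            assert set(np.flatnonzero(np.abs(coef) > 1e-6)) == \
                set(np.flatnonzero(np.abs(sk.coef_[0]) > 1e-6))

    def test_lasso_path_support_nonincreasing_in_lambda(self):
        # staggered effect sizes: predictors enter one by one as lambda drops
        rng = np.random.default_rng(42)
        n = 40
        y = np.array([1.0] * (n // 2) + [0.0] * (n // 2))
        x = rng.normal(0, 1, (n, 6))
        for j, eff in enumerate([2.0, 1.2, 0.7, 0.4, 0.0, 0.0]):
            x[:, j] += eff * y
        x = (x - x.mean(0)) / x.std(0)
        nnz = []
        for lam in np.logspace(-0.5, -3, 12):  # decreasing lambda
            coef, _ = _fit_en_point(x, y, alpha=1.0, lam=lam, max_iter=30000, tol=1e-13)
            nnz.append(int((np.abs(coef) > 1e-7).sum()))
        assert all(b >= a for a, b in zip(nnz, nnz[1:]))
        assert nnz[0] < nnz[-1]

    def test_loocv_and_downsampling_run(self, rng):
        expr, y = self._toy(rng, n=24)
        y_unbal = y.copy()
        y_unbal[:4] = 0  # unbalanced classes
        m1 = train_elastic_net(expr, y_unbal, cv_scheme="loocv", seed=1, n_lambdas=8)
        m2 = train_elastic_net(expr, y_unbal, n_folds=4, balance="downsample",
                               seed=1, n_lambdas=8)
        for m in (m1, m2):
            assert np.isfinite(m.params["coef"]).all()


@pytest.fixture(scope="module")
def trained_svm():
    """A small separable cohort with a trained reduced-swarm PSO-SVM."""
    table = balanced_design(n_hospitals=3, cases_per_hospital=20, controls_per_hospital=20)
    meta = build_confounded_design(table, seed=20)
    cfg = SimConfig(n_genes=150, hospital_effect_sd=0.0, case_effect_sd=0.8, seed=20)
    counts = simulate_counts(meta, cfg, seed=21)
    meta = attach_lib_size(meta, counts)
    meta = assign_partitions(meta, PartitionConfig(seed=22))
    pso = PSOConfig(n_particles=10, n_iterations=3, seed=23)
    model = train_pso_svm(counts, meta, pso, ruv_k=5)
    return counts, meta, model


class TestTrainPsoSvm:
    def test_separable_fixture_high_internal_auc(self, trained_svm):
        counts, meta, model = trained_svm
        midx = meta.set_index("sample_id")
        val = midx.index[midx["partition"] == "internal_validation"]
        scores = predict_proba(model, counts[list(val)])
        auc = roc_auc(midx.loc[val, "group"].to_numpy(), scores.to_numpy())
        assert auc >= 0.95

    def test_gene_count_within_search_bounds(self, trained_svm):
        _, _, model = trained_svm
        lo, hi = PSOConfig().bounds["n_genes"]
        assert lo <= len(model.gene_ids) <= hi

    def test_training_scores_reproduce_exactly(self, trained_svm):
        counts, meta, model = trained_svm
        train_ids = model.training_meta["partitions"]["training"]
        s1 = predict_proba(model, counts[train_ids])
        s2 = predict_proba(model, counts[train_ids])
        assert (s1 == s2).all()

    def test_probabilities_bounded(self, trained_svm, rng):
        counts, _, model = trained_svm
        noise = pd.DataFrame(rng.integers(0, 200, counts.shape),
                             index=counts.index, columns=[f"x{i}" for i in
                                                          range(counts.shape[1])])
        scores = predict_proba(model, noise)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_gene_mismatch_is_error(self, trained_svm):
        counts, _, model = trained_svm
        with pytest.raises(ValueError, match="missing"):
            predict_proba(model, counts.iloc[5:])

    def test_serialization_roundtrip_predicts_identically(self, trained_svm, tmp_path):
        counts, meta, model = trained_svm
        path = tmp_path / "model.json"
        model.save(path)
        clone = ClassifierModel.load(path)
        s1 = predict_proba(model, counts.iloc[:, :10])
        s2 = predict_proba(clone, counts.iloc[:, :10])
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_label_permutation_yields_chance_auc(self):
        """Permuting labels destroys the signal: median internal AUC ~ 0.5."""
        table = balanced_design(n_hospitals=2, cases_per_hospital=18, controls_per_hospital=18)
        aucs = []
        for s in range(10):
            meta = build_confounded_design(table, seed=30 + s)
            cfg = SimConfig(n_genes=150, hospital_effect_sd=0.0, case_effect_sd=0.8,
                            seed=30 + s)
            counts = simulate_counts(meta, cfg, seed=40 + s)
            rng = np.random.default_rng(50 + s)
            meta["group"] = rng.permutation(meta["group"].to_numpy())
            meta["stage"] = np.where(meta["group"] == "case", "II", "")
            meta = attach_lib_size(meta, counts)
            meta = assign_partitions(meta, PartitionConfig(seed=60 + s))
            model = train_pso_svm(counts, meta,
                                  PSOConfig(n_particles=8, n_iterations=2, seed=70 + s),
                                  ruv_k=4)
            midx = meta.set_index("sample_id")
            val = midx.index[midx["partition"] == "internal_validation"]
            scores = predict_proba(model, counts[list(val)])
            aucs.append(roc_auc(midx.loc[val, "group"].to_numpy(), scores.to_numpy()))
        assert 0.35 <= float(np.median(aucs)) <= 0.65


class TestParity:
    def test_both_classifiers_solve_separable_data(self, trained_svm):
        counts, meta, svm_model = trained_svm
        from tepseq.normalization import compute_tmm_factors, cpm_log2
        midx = meta.set_index("sample_id")
        fit_ids = midx.index[midx["partition"].isin(["training", "evaluation"])].tolist()
        ctx = compute_tmm_factors(counts[fit_ids], training_ids=fit_ids)
        expr = cpm_log2(counts[fit_ids], ctx)
        en = train_elastic_net(expr, midx.loc[fit_ids, "group"].to_numpy(),
                               n_folds=5, seed=0, l1_ratios=[0.5], n_lambdas=10)
        en.norm_ctx = ctx
        val = midx.index[midx["partition"] == "internal_validation"]
        for model in (svm_model, en):
            scores = predict_proba(model, counts[list(val)])
            auc = roc_auc(midx.loc[val, "group"].to_numpy(), scores.to_numpy())
            assert auc >= 0.95
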