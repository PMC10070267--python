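"""Variance partitioning, NB-GLM DE, ComBat, ORA and contamination scoring."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import scipy.special

from tepseq.batch_analysis import (DesignSpec, build_design_matrix, combat_correct,
                                   contamination_scores, nb_glm_de, ora_test,
                                   variance_partition)
from tepseq.normalization import compute_tmm_factors, cpm_log2
from tepseq.synthetic_data import (SimConfig, balanced_design, build_confounded_design,
                                   module_gene_ids, simulate_counts, DesignTable)


def _meta(n, rng, n_hosp=2):
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": ["case"] * (n // 2) + ["control"] * (n - n // 2),
        "hospital": [f"H{i % n_hosp}" for i in range(n)],
        "age": rng.uniform(30, 70, n),
    })


class TestVariancePartition:
    def test_pure_noise_gene_mostly_residual(self, rng):
        n = 200
        meta = _meta(n, rng, n_hosp=4)
        expr = pd.DataFrame(rng.normal(0, 1, (5, n)), columns=meta["sample_id"],
                            index=[f"g{i}" for i in range(5)])
        vp = variance_partition(expr, meta)
        assert (vp["fraction_residual"] >= 0.9).all()

    def test_fractions_sum_to_one(self, rng):
        n = 120
        meta = _meta(n, rng, n_hosp=3)
        expr = pd.DataFrame(rng.normal(0, 1, (8, n)), columns=meta["sample_id"],
                            index=[f"g{i}" for i in range(8)])
        expr.iloc[0] += 2.0 * (meta["hospital"] == "H0").to_numpy()
        vp = variance_partition(expr, meta)
        frac_cols = [c for c in vp.columns if c.startswith("fraction_")]
        assert np.allclose(vp[frac_cols].sum(axis=1), 1.0, atol=1e-6)

    def test_hospital_effect_attributed_to_hospital(self, rng):
        n = 160
        meta = _meta(n, rng, n_hosp=4)
        y = rng.normal(0, 1, n) + 2.0 * (meta["hospital"] == "H1").to_numpy()
        expr = pd.DataFrame([y], columns=meta["sample_id"], index=["g0"])
        vp = variance_partition(expr, meta)
        assert vp.loc["g0", "fraction_hospital"] > 0.3
        assert vp.loc["g0", "fraction_cancer"] < 0.1

    def test_requires_two_levels_per_random_term(self, rng):
        meta = _meta(20, rng, n_hosp=1)
        expr = pd.DataFrame(rng.normal(0, 1, (2, 20)), columns=meta["sample_id"])
        with pytest.raises(ValueError):
            variance_partition(expr, meta)


class TestNbGlmDe:
    def test_spiked_genes_detected_with_correct_sign(self, rng):
        n = 80
        meta = _meta(n, rng)
        G = 300
        mu = rng.uniform(30, 400, G)
        lfc = np.zeros(G)
        lfc[:20] = 2.0
        is_case = (meta["group"] == "case").to_numpy()
        m = mu[:, None] * 2.0 ** (np.where(is_case[None, :], 0.5, -0.5) * lfc[:, None])
        lam = rng.gamma(5.0, m / 5.0)
        counts = pd.DataFrame(rng.poisson(lam), columns=meta["sample_id"],
                              index=[f"g{i}" for i in range(G)])
        res = nb_glm_de(counts, meta, DesignSpec(fixed=("age", "group", "hospital")),
                        contrast="group")
        assert (res["fdr"].iloc[:20] < 0.05).sum() >= 18
        assert (np.sign(res["log2fc"].iloc[:20]) == 1).all()
        assert (res["fdr"].iloc[20:] < 0.05).mean() < 0.05

    def test_null_pvalues_uniform(self, rng):
        n = 50
        meta = _meta(n, rng)
        G = 500
        mu = rng.uniform(30, 400, G)
        lam = rng.gamma(5.0, np.tile(mu[:, None], (1, n)) / 5.0)
        counts = pd.DataFrame(rng.poisson(lam), columns=meta["sample_id"],
                              index=[f"g{i}" for i in range(G)])
        res = nb_glm_de(counts, meta, DesignSpec(fixed=("age", "group")), contrast="group")
        assert scipy.stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_fdr_monotone_in_pvalue(self, rng):
        n = 40
        meta = _meta(n, rng)
        counts = pd.DataFrame(rng.poisson(100, (50, n)), columns=meta["sample_id"],
                              index=[f"g{i}" for i in range(50)])
        res = nb_glm_de(counts, meta, DesignSpec(fixed=("age", "group")), contrast="group")
        ordered = res.sort_values("pvalue")
        assert ordered["fdr"].is_monotonic_increasing or \
            np.all(np.diff(ordered["fdr"].to_numpy()) >= -1e-12)

    def test_non_full_rank_design_rejected(self, rng):
        meta = _meta(20, rng)
        meta["hospital"] = np.where(meta["group"] == "case", "H0", "H1")  # aliased
        counts = pd.DataFrame(rng.poisson(50, (5, 20)), columns=meta["sample_id"])
        with pytest.raises(ValueError):
            build_design_matrix(meta, ("group", "hospital"))


class TestCombat:
    def test_single_batch_identity_with_warning(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (30, 10)))
        with pytest.warns(UserWarning, match="single batch"):
            out = combat_correct(expr, ["b1"] * 10)
        pd.testing.assert_frame_equal(out, expr)

    def test_constant_shift_removed(self, rng):
        n_per, delta = 50, 3.0
        expr = pd.DataFrame(rng.normal(5, 1, (200, 2 * n_per)),
                            columns=[f"s{i}" for i in range(2 * n_per)])
        expr.iloc[:, n_per:] += delta
        batch = ["a"] * n_per + ["b"] * n_per
        out = combat_correct(expr, batch)
        resid = (out.iloc[:, n_per:].mean(axis=1) - out.iloc[:, :n_per].mean(axis=1))
        assert resid.abs().mean() < 0.05 * delta
        assert out.shape == expr.shape

    def test_batch_f_statistic_reduced_tenfold(self, rng):
        n_per = 40
        expr = pd.DataFrame(rng.normal(0, 1, (150, 3 * n_per)),
                            columns=[f"s{i}" for i in range(3 * n_per)])
        batch = np.repeat(["a", "b", "c"], n_per)
        shifts = {"a": 0.0, "b": 1.5, "c": -1.0}
        for lev, sh in shifts.items():
            expr.loc[:, batch == lev] += sh
        out = combat_correct(expr, batch)

        def mean_f(df):
            groups = [df.loc[:, batch == lev].to_numpy() for lev in "abc"]
            fs = [scipy.stats.f_oneway(*[g[i] for g in groups]).statistic
                  for i in range(df.shape[0])]
            return float(np.mean(fs))

        assert mean_f(expr) >= 10 * mean_f(out)

    def test_two_samples_per_batch_required(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (10, 3)))
        with pytest.raises(ValueError):
            combat_correct(expr, ["a", "a", "b"])


class TestOra:
    def test_total_overlap_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        gene_set = universe[:5]
        p, overlap = ora_test(gene_set, gene_set, universe)
        assert overlap == 5
        assert p == pytest.approx(1.0 / scipy.special.comb(20, 5), rel=1e-12)

    def test_set_equals_universe(self):
        universe = [f"g{i}" for i in range(15)]
        p, _ = ora_test(universe[:4], universe, universe)
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_tail(self, rng):
        for _ in range(10):
            m, k, n = 30, int(rng.integers(3, 12)), int(rng.integers(3, 12))
            universe = [f"g{i}" for i in range(m)]
            gene_set = list(rng.choice(universe, size=k, replace=False))
            selected = list(rng.choice(universe, size=n, replace=False))
            p, overlap = ora_test(selected, gene_set, universe)
            # brute-force tail: sum of hypergeometric point masses >= overlap
            tail = sum(scipy.special.comb(k, j) * scipy.special.comb(m - k, n - j)
                       for j in range(overlap, min(k, n) + 1)) / scipy.special.comb(m, n)
            assert p == pytest.approx(tail, rel=1e-9)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            ora_test(["a"], ["a"], [])


class TestContamination:
    def test_spiked_sample_has_highest_score(self, rng):
        expr = pd.DataFrame(rng.normal(2, 0.3, (20, 8)),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(8)])
        expr.loc[["g0", "g1"], "s3"] += 10.0
        scores = contamination_scores(expr, {"haemoglobin": ["g0", "g1"]})
        assert scores["haemoglobin"].idxmax() == "s3"

    def test_zero_expression_zero_score(self):
        expr = pd.DataFrame(np.zeros((5, 3)), index=[f"g{i}" for i in range(5)],
                            columns=list("abc"))
        scores = contamination_scores(expr, {"m": ["g0", "g2"]})
        assert (scores["m"] == 0).all()

    def test_score_strictly_monotone_in_marker_counts(self):
        expr = pd.DataFrame([[1.0, 1.0], [2.0, 2.0]], index=["g0", "g1"],
                            columns=["a", "b"])
        s1 = contamination_scores(expr, {"m": ["g0", "g1"]})
        expr2 = expr.copy()
        expr2.loc["g0", "b"] += 0.5
        s2 = contamination_scores(expr2, {"m": ["g0", "g1"]})
        assert s2.loc["b", "m"] > s1.loc["b", "m"]
        assert s2.loc["a", "m"] == s1.loc["a", "m"]

    def test_missing_markers_is_error(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (4, 2)), index=list("wxyz"))
        with pytest.raises(ValueError):
            contamination_scores(expr, {"m": ["nope"]})


class TestModuleEnrichment:
    def test_platelet_module_enriched_in_hospital_not_case_contrast(self):
        """On the confounded simulation the hospital contrast is enriched for
        the platelet-activation module while the case contrast is not."""
        rng = np.random.default_rng(0)
        table = DesignTable(rows=(("NKI", 40, 20), ("VUMC", 10, 50), ("MGH", 30, 5)))
        meta = build_confounded_design(table, seed=1)
        cfg = SimConfig(n_genes=400, seed=1, hospital_effect_sd=0.6, case_effect_sd=0.12)
        counts = simulate_counts(meta, cfg, seed=2)
        mods = module_gene_ids(cfg, counts)
        ctx = compute_tmm_factors(counts)
        # hospital contrast within controls (stratified, as in the study design)
        ctl = meta[meta["group"] == "control"]
        ctl = ctl[ctl["hospital"].isin(["NKI", "VUMC"])]
        res_h = nb_glm_de(counts[ctl["sample_id"]], ctl,
                          DesignSpec(fixed=("age", "hospital")), contrast="hospital",
                          tmm_factors=ctx.tmm_factor)
        top_h = res_h.nsmallest(60, "pvalue").index.tolist()
        p_h, _ = ora_test(top_h, mods["platelet_activation"], list(counts.index))
        assert p_h < 0.01
        # case contrast within one hospital: weak signal, no platelet enrichment
        nki = meta[meta["hospital"] == "NKI"]
        res_c = nb_glm_de(counts[nki["sample_id"]], nki,
                          DesignSpec(fixed=("age", "group")), contrast="group",
                          tmm_factors=ctx.tmm_factor)
        top_c = res_c.nsmallest(60, "pvalue").index.tolist()
        p_c, _ = ora_test(top_c, mods["platelet_activation"], list(counts.index))
        assert p_c > 0.05
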