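"""Tests for genotype QC, association models and multiple-testing correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genometab import ValidationError
from genometab.genassoc import (
    GenotypeMatrix,
    assoc_linear,
    assoc_logistic,
    associate_panel,
    encode_model,
    holm_bonferroni,
    hwe_test,
    posthoc_power,
    qc_filter,
)
from genometab.simulate import EffectSpec, SnpSpec, gen_covariates, gen_genotypes, gen_uae


class TestHwe:
    def test_exact_proportions(self):
        chi2, p = hwe_test(250, 500, 250)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # allele freq 0.45 -> expected 20.25 / 49.5 / 30.25
        chi2, p = hwe_test(30, 30, 40)
        assert chi2 == pytest.approx(15.52, abs=0.01)
        assert p < 1e-3

    def test_monomorphic(self):
        chi2, p = hwe_test(100, 0, 0)
        assert chi2 == 0.0 and p == 1.0

    def test_empty_error(self):
        with pytest.raises(ValidationError):
            hwe_test(0, 0, 0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=50, deadline=None)
    def test_label_swap_invariance(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_test(a, b, c)[0] == pytest.approx(hwe_test(c, b, a)[0], rel=1e-9, abs=1e-9)


class TestQcFilter:
    def _matrix(self, cols):
        return GenotypeMatrix(pd.DataFrame(cols))

    def test_low_call_rate_excluded(self):
        n = 200
        rng = np.random.default_rng(0)
        good = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.49, 0.42, 0.09])
        bad = good.copy()
        bad[: int(0.15 * n)] = np.nan  # 85% call rate
        geno = self._matrix({"good": good, "bad": bad})
        filtered, qc = qc_filter(geno)
        assert "bad" not in filtered.snp_ids
        assert "call_rate" in qc.loc["bad", "fail_reasons"]
        assert qc.loc["good", "passed"]

    def test_hwe_calibration(self):
        # a SNP simulated at HWE should pass in >= (1 - alpha) of seeds
        passes = 0
        n_seeds = 100
        for seed in range(n_seeds):
            geno = gen_genotypes(1200, [SnpSpec("s", maf=0.3)], seed=seed)
            _, qc = qc_filter(geno, hwe_alpha=0.001)
            passes += bool(qc.loc["s", "passed"])
        assert passes >= (1 - 0.001) * n_seeds - 2

    def test_empty_matrix(self):
        geno = GenotypeMatrix(pd.DataFrame(index=["a", "b"]))
        filtered, qc = qc_filter(geno)
        assert filtered.snp_ids == [] and len(qc) == 0


class TestEncodeModel:
    @pytest.mark.parametrize(
        "model,expected",
        [("ADD", [0, 1, 2]), ("DOM", [0, 1, 1]), ("REC", [0, 0, 1])],
    )
    def test_codings(self, model, expected):
        np.testing.assert_array_equal(encode_model(np.array([0.0, 1.0, 2.0]), model), expected)

    def test_missing_propagates(self):
        out = encode_model(np.array([np.nan, 1.0, np.nan]), "DOM")
        assert np.isnan(out[0]) and out[1] == 1.0 and np.isnan(out[2])

    def test_all_missing(self):
        assert np.isnan(encode_model(np.array([np.nan] * 3), "REC")).all()

    def test_unknown_model(self):
        with pytest.raises(ValidationError):
            encode_model(np.array([0.0]), "XYZ")

    @given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=1, max_size=50))
    @settings(max_examples=30, deadline=None)
    def test_add_equals_dom_plus_rec(self, calls):
        calls = np.array(calls)
        np.testing.assert_array_equal(
            encode_model(calls, "ADD"),
            encode_model(calls, "DOM") + encode_model(calls, "REC"),
        )


class TestAssocLinear:
    def test_beta_matches_normal_equations_oracle(self, rng):
        n = 300
        g = rng.choice([0.0, 1.0, 2.0], size=n)
        cov = rng.normal(size=(n, 3))
        y = 0.25 * g + cov @ [0.1, -0.2, 0.05] + rng.normal(scale=0.5, size=n)
        res = assoc_linear(y, g, cov)
        X = np.column_stack([np.ones(n), g, cov])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert res.beta == pytest.approx(beta_oracle, abs=1e-8)

    def test_type_one_error_calibrated(self):
        hits = 0
        n_seeds = 1000
        rng = np.random.default_rng(0)
        for _ in range(n_seeds):
            g = rng.choice([0.0, 1.0, 2.0], size=120, p=[0.49, 0.42, 0.09])
            y = rng.normal(size=120)
            if len(np.unique(g)) < 2:
                continue
            hits += assoc_linear(y, g, None).p < 0.05
        assert abs(hits / n_seeds - 0.05) < 0.02

    def test_beta_recovery_mean(self):
        snp = SnpSpec("s", maf=0.3, beta=0.18)
        betas = []
        for seed in range(100):
            pheno = gen_covariates(1200, seed=seed)
            geno = gen_genotypes(1200, [snp], seed=seed + 1)
            out = gen_uae(pheno, geno, [snp], EffectSpec(), seed=seed + 2)
            res = assoc_linear(
                out["log_uae"].to_numpy(),
                geno.calls["s"].to_numpy(),
                out[["age", "sex", "bmi", "sbp", "glucose"]].to_numpy(),
            )
            betas.append(res.beta)
        assert abs(np.mean(betas) - 0.18) < 0.02

    def test_constant_genotype_error(self, rng):
        y = rng.normal(size=50)
        with pytest.raises(ValidationError):
            assoc_linear(y, np.ones(50), None)

    def test_complete_case_count(self, rng):
        y = rng.normal(size=60)
        g = rng.choice([0.0, 1.0, 2.0], size=60)
        g[:5] = np.nan
        res = assoc_linear(y, g, None)
        assert res.n_used == 55

    def test_too_few_cases(self):
        with pytest.raises(ValidationError):
            assoc_linear(np.ones(5), np.array([0, 1, 2, 0, 1.0]), None)


class TestAssocLogistic:
    def test_type_one_error_calibrated(self):
        hits = 0
        n_done = 0
        rng = np.random.default_rng(1)
        for _ in range(400):
            g = rng.choice([0.0, 1.0, 2.0], size=400, p=[0.49, 0.42, 0.09])
            y = (rng.random(400) < 0.2).astype(float)
            res = assoc_logistic(y, g, None)
            if res.converged and not res.separation:
                hits += res.p < 0.05
                n_done += 1
        assert n_done > 350
        assert abs(hits / n_done - 0.05) < 0.03

    def test_separation_flagged_no_crash(self):
        g = np.array([0.0] * 20 + [2.0] * 20)
        y = np.array([0.0] * 20 + [1.0] * 20)
        res = assoc_logistic(y, g, None)
        assert res.separation

    def test_or_recovery_coverage(self):
        # simulated OR=2 per allele, ~7% prevalence: CI coverage >= 90%
        rng = np.random.default_rng(7)
        covered = 0
        n_seeds = 60
        true_beta = np.log(2.0)
        for _ in range(n_seeds):
            g = rng.choice([0.0, 1.0, 2.0], size=1200, p=[0.49, 0.42, 0.09])
            logit = -3.3 + true_beta * g
            y = (rng.random(1200) < 1 / (1 + np.exp(-logit))).astype(float)
            res = assoc_logistic(y, g, None)
            if abs(res.beta - true_beta) <= 1.96 * res.se:
                covered += 1
        assert covered >= 0.90 * n_seeds


class TestHolm:
    def test_single_pvalue(self):
        adj, rej = holm_bonferroni(np.array([0.04]), alpha=0.05)
        assert rej[0] and adj[0] == pytest.approx(0.04)

    def test_hand_stepdown(self):
        # 0.01 < 0.05/3 rejects; 0.03 > 0.05/2 stops the procedure
        adj, rej = holm_bonferroni(np.array([0.01, 0.04, 0.03]), alpha=0.05)
        np.testing.assert_array_equal(rej, [True, False, False])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])

    def test_adjusted_monotone_in_sorted_order(self, rng):
        p = rng.random(20)
        adj, _ = holm_bonferroni(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_dominance_over_bonferroni(self, pvals):
        p = np.array(pvals)
        m = len(p)
        adj, rej = holm_bonferroni(p, alpha=0.05)
        bonf_rej = p <= 0.05 / m
        bonf_adj = np.minimum(1.0, m * p)
        assert np.all(rej[bonf_rej])  # Holm rejects whatever Bonferroni rejects
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= bonf_adj + 1e-12)

    def test_bad_pvalues(self):
        with pytest.raises(ValidationError):
            holm_bonferroni(np.array([0.5, 1.2]))


class TestPower:
    def test_null_equals_alpha(self):
        assert posthoc_power(0.0, 1.0, alpha=0.05) == pytest.approx(0.05, abs=1e-9)
        assert posthoc_power(0.0, 0.3, alpha=0.10) == pytest.approx(0.10, abs=1e-9)

    def test_boundary_half(self):
        from scipy.stats import norm

        z = norm.ppf(0.975)
        assert posthoc_power(z, 1.0, alpha=0.05) == pytest.approx(0.5, abs=0.001)

    def test_reference_row_value(self):
        # formula evaluation; the published table prints 96.23 for this row,
        # the normal approximation gives ~95.5 (method difference documented)
        assert posthoc_power(0.1755, 0.04799, alpha=0.05) == pytest.approx(0.955, abs=0.003)

    def test_bad_se(self):
        with pytest.raises(ValidationError):
            posthoc_power(0.1, 0.0)


class TestPanel:
    def test_panel_table_structure(self, mid_cohort):
        pheno, geno = mid_cohort["pheno"], mid_cohort["geno"]
        covars = pheno[["age", "sex", "bmi", "sbp", "glucose"]].to_numpy()
        table = associate_panel(
            pheno["log_uae"].to_numpy(), pheno["malb"].to_numpy(), geno, covars
        )
        assert {"snp_id", "model", "beta", "se", "p", "power", "best_model", "p_holm"}.issubset(
            table.columns
        )
        # one best model flagged per SNP
        assert (table.groupby("snp_id")["best_model"].sum() == 1).all()
        best = table[table["best_model"]]
        assert (best["p_holm"] >= best["p"] - 1e-12).all()
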