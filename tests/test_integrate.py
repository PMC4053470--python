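"""Tests for stratified metabolomic differences and discordance selection."""

import numpy as np
import pandas as pd
import pytest

from genometab import ValidationError, simulate
from genometab.chemometrics import CvPlan
from genometab.genassoc import GenotypeMatrix
from genometab.integrate import (
    DiscordanceCriteria,
    characterize_subgroup,
    cohort_differences,
    contingency_chi2,
    normalized_difference_ratio,
    ratio_matrix,
    select_discordant,
    significance_category,
    significance_pattern,
    stratified_differences,
    stratum_plsda,
    summary_ttest,
)


def masked_cohort(n=500, seed=0, mask_genotype=2.0, masked=True):
    """Cohort where genotype==2 subjects optionally lose the malb contrast.

    Returns (levels, malb flags, GenotypeMatrix with one SNP 's').
    """
    rng = np.random.default_rng(seed)
    peaks = simulate.default_peak_specs()
    malb = rng.random(n) < 0.15
    calls = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.45, 0.42, 0.13])
    pheno = pd.DataFrame({"malb": malb.astype(int)})
    if masked:
        # inside the masked stratum every subject draws from the normo law
        eff_malb = malb & ~(calls == mask_genotype)
    else:
        eff_malb = malb
    levels = simulate.gen_metabolite_levels(
        pd.DataFrame({"malb": eff_malb.astype(int)}), peaks, seed=seed + 1
    )
    geno = GenotypeMatrix(pd.DataFrame({"s": calls}, index=levels.index))
    return levels, malb, geno


class TestCohortDifferences:
    def test_identical_groups(self, rng):
        X = pd.DataFrame(np.tile(rng.normal(size=(1, 4)), (20, 1)), columns=list("abcd"))
        res = cohort_differences(X, np.repeat([True, False], 10))
        np.testing.assert_allclose(res["diff"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_label_swap_antisymmetry(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        flags = rng.random(40) < 0.4
        r1 = cohort_differences(X, flags)
        r2 = cohort_differences(X, ~flags)
        np.testing.assert_allclose(r1["diff"], -r2["diff"], atol=1e-12)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)

    def test_power_at_reference_sizes(self, peaks):
        hits = 0
        for seed in range(100):
            pheno = pd.DataFrame({"malb": [0] * 1150 + [1] * 81})
            levels = simulate.gen_metabolite_levels(pheno, peaks, seed=seed)
            res = cohort_differences(levels, pheno["malb"].astype(bool))
            hits += res.loc["cholesterol", "p"] < 0.001
        assert hits >= 80


class TestStratified:
    def test_weighted_identity(self):
        levels, malb, geno = masked_cohort(n=400, seed=2, masked=False)
        cohort = cohort_differences(levels, malb)
        strat = stratified_differences(levels, malb, geno, "s")
        for met in levels.columns:
            sub = strat[strat["metabolite"] == met]
            m_malb = (sub["mean_malb"] * sub["n_malb"]).sum() / sub["n_malb"].sum()
            m_normo = (sub["mean_normo"] * sub["n_normo"]).sum() / sub["n_normo"].sum()
            assert m_malb - m_normo == pytest.approx(cohort.loc[met, "diff"], abs=1e-9)

    def test_null_genotype_ratio_near_one(self):
        ratios = []
        for seed in range(10):
            levels, malb, geno = masked_cohort(n=800, seed=seed, masked=False)
            cohort = cohort_differences(levels, malb)
            strat = stratified_differences(levels, malb, geno, "s")
            prof = normalized_difference_ratio(strat, cohort)
            big = cohort["diff"].abs() > 0.02  # skip near-zero cohort diffs
            ratios.append(prof[prof["metabolite"].isin(cohort.index[big])]["ratio"].mean())
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_zero_malb_stratum_flagged(self):
        rng = np.random.default_rng(0)
        levels = pd.DataFrame(rng.normal(10, 1, size=(30, 2)), columns=["a", "b"])
        malb = np.zeros(30, dtype=bool)
        malb[:5] = True
        calls = np.zeros(30)
        calls[:5] = 1.0  # genotype 0 stratum has no malb subjects
        geno = GenotypeMatrix(pd.DataFrame({"s": calls}, index=levels.index))
        strat = stratified_differences(levels, malb, geno, "s")
        g0 = strat[strat["genotype"] == "AA"]
        assert g0["low_confidence"].all()
        assert g0["mean_malb"].isna().all()

    def test_malb_percent(self):
        levels, malb, geno = masked_cohort(n=300, seed=5, masked=False)
        strat = stratified_differences(levels, malb, geno, "s")
        labels = geno.genotype_labels("s")
        for genotype, grp in strat.groupby("genotype"):
            expected = 100.0 * malb[(labels == genotype).to_numpy()].mean()
            assert grp["malb_percent"].iloc[0] == pytest.approx(expected)


class TestSignificance:
    @pytest.mark.parametrize(
        "p,cat", [(0.05, 0), (0.01, 0), (0.009, 1), (0.0005, 2), (1e-6, 3), (1.0, 0)]
    )
    def test_boundaries(self, p, cat):
        assert significance_category(p) == cat

    def test_monotone_step_function(self):
        ps = np.logspace(-8, 0, 200)
        cats = [significance_category(p) for p in ps]
        assert all(a >= b for a, b in zip(cats[:-1], cats[1:]))

    def test_pattern_matrix_cohort_first(self):
        levels, malb, geno = masked_cohort(n=300, seed=1, masked=False)
        cohort = cohort_differences(levels, malb)
        strat = stratified_differences(levels, malb, geno, "s")
        pattern = significance_pattern(strat, cohort)
        assert pattern.columns[0] == "cohort"
        assert pattern.shape[0] == levels.shape[1]


class TestRatios:
    def _fake_strat(self, diff, cohort_diff):
        strat = pd.DataFrame(
            {
                "snp_id": ["s"],
                "genotype": ["AA"],
                "metabolite": ["m"],
                "mean_malb": [diff],
                "mean_normo": [0.0],
                "diff": [diff],
                "p": [0.5],
                "n_malb": [5],
                "n_normo": [20],
                "malb_percent": [20.0],
                "low_confidence": [False],
            }
        )
        cohort = pd.DataFrame({"diff": [cohort_diff], "p": [0.01]}, index=["m"])
        return strat, cohort

    @pytest.mark.parametrize("diff,cdiff,expected", [(0.3, 0.3, 1.0), (0.0, 0.3, 0.0), (-0.3, 0.3, -1.0)])
    def test_ratio_values(self, diff, cdiff, expected):
        strat, cohort = self._fake_strat(diff, cdiff)
        prof = normalized_difference_ratio(strat, cohort)
        assert prof["ratio"].iloc[0] == pytest.approx(expected)

    def test_degenerate_cohort_diff_flagged(self):
        strat, cohort = self._fake_strat(0.3, 0.0)
        prof = normalized_difference_ratio(strat, cohort)
        assert prof["cohort_diff_degenerate"].iloc[0]
        assert np.isnan(prof["ratio"].iloc[0])

    def test_scale_invariance(self):
        levels, malb, geno = masked_cohort(n=300, seed=9, masked=False)
        scaled = levels * 3.7
        c1 = cohort_differences(levels, malb)
        c2 = cohort_differences(scaled, malb)
        r1 = ratio_matrix(normalized_difference_ratio(stratified_differences(levels, malb, geno, "s"), c1))
        r2 = ratio_matrix(normalized_difference_ratio(stratified_differences(scaled, malb, geno, "s"), c2))
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), rtol=1e-9)


class TestStratumPlsda:
    def test_no_signal_low_q2(self):
        levels, malb, geno = masked_cohort(n=600, seed=3, masked=True)
        in_stratum = (geno.calls["s"] == 2.0).to_numpy()
        res = stratum_plsda(levels, malb, in_stratum, plan=CvPlan(n_repeats=2, seed=0))
        assert res.q2 < 0.35

    def test_signal_stratum_comparable_to_cohort(self):
        levels, malb, geno = masked_cohort(n=900, seed=4, masked=False)
        from genometab.chemometrics import cross_validate

        plan = CvPlan(n_repeats=2, seed=0)
        cohort_q2 = cross_validate(levels.to_numpy(), malb.astype(float), plan, 2).q2
        in_stratum = (geno.calls["s"] == 0.0).to_numpy()
        res = stratum_plsda(levels, malb, in_stratum, plan=plan)
        assert abs(res.q2 - cohort_q2) < 0.2

    def test_tiny_stratum_error(self):
        levels, malb, geno = masked_cohort(n=100, seed=0)
        in_stratum = np.zeros(100, dtype=bool)
        in_stratum[:5] = True
        with pytest.raises(ValidationError):
            stratum_plsda(levels, malb, in_stratum)


class TestDiscordance:
    def _run(self, masked, seed):
        levels, malb, geno = masked_cohort(n=1000, seed=seed, masked=masked)
        cohort = cohort_differences(levels, malb)
        strat = stratified_differences(levels, malb, geno, "s")
        report = select_discordant(
            strat, cohort, criteria=DiscordanceCriteria(require_q2_below_cohort=False)
        )
        return report.set_index("genotype")

    def test_planted_masked_genotype_selected(self):
        hits = 0
        for seed in range(30):
            report = self._run(masked=True, seed=seed)
            hits += bool(report.loc["BB", "selected"])
        assert hits >= 27  # sensitivity >= 0.9

    def test_null_genotype_rarely_selected(self):
        false_hits = 0
        for seed in range(30):
            report = self._run(masked=False, seed=seed)
            false_hits += bool(report.loc["BB", "selected"])
        assert false_hits <= 3  # specificity >= 0.9

    def test_empty_selection_valid(self):
        report = self._run(masked=False, seed=123)
        assert "selected" in report.columns  # report exists even with no hits

    def test_criteria_echoed(self):
        levels, malb, geno = masked_cohort(n=400, seed=0, masked=False)
        cohort = cohort_differences(levels, malb)
        strat = stratified_differences(levels, malb, geno, "s")
        crit = DiscordanceCriteria(min_nonsig_fraction=0.66)
        report = select_discordant(strat, cohort, criteria=crit)
        assert report.attrs["criteria"]["min_nonsig_fraction"] == 0.66


class TestClinicalComparisons:
    def test_diabetes_table_from_printed_counts(self):
        chi2, p, odds = contingency_chi2(np.array([[77, 1073], [22, 59]]))
        assert chi2 == pytest.approx(42.9, abs=0.5)
        assert p < 0.0001
        assert odds < 1  # diabetics enriched in the second row

    def test_identical_proportions(self):
        chi2, p, _ = contingency_chi2(np.array([[20, 80], [40, 160]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_cell_haldane(self):
        chi2, p, odds = contingency_chi2(np.array([[10, 0], [5, 5]]))
        assert np.isfinite(odds) and odds > 1

    def test_bad_table(self):
        with pytest.raises(ValidationError):
            contingency_chi2(np.array([[1, 2, 3], [4, 5, 6]]))

    def test_welch_from_summaries(self):
        t, df, p = summary_ttest(74, 6, 17, 67, 18, 81, variant="welch")
        assert round(p, 3) == 0.006

    def test_student_from_summaries(self):
        t, df, p = summary_ttest(50, 18, 7, 67, 18, 81, variant="student")
        assert df == 86
        assert round(p, 2) == 0.02

    def test_equal_means(self):
        t, _, p = summary_ttest(5, 1, 10, 5, 1, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_vs_scipy_oracle(self, rng):
        a = rng.normal(10, 2, 30)
        b = rng.normal(11, 3, 40)
        from scipy.stats import ttest_ind

        ref = ttest_ind(a, b, equal_var=False)
        t, _, p = summary_ttest(
            a.mean(), a.std(ddof=1), 30, b.mean(), b.std(ddof=1), 40, variant="welch"
        )
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestCharacterizeSubgroup:
    def test_whole_cohort_identity(self, mid_cohort):
        pheno = mid_cohort["pheno"]
        table = characterize_subgroup(pheno, np.ones(len(pheno), dtype=bool))
        age_row = table[table["variable"] == "age"].iloc[0]
        malb = pheno["malb"].astype(bool)
        assert f"{pheno.loc[malb, 'age'].mean():.1f}" in age_row["malb_summary"]

    def test_age_shift_detected(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 400
            pheno = pd.DataFrame(
                {
                    "age": rng.normal(55, 10, n),
                    "malb": (rng.random(n) < 0.25).astype(int),
                }
            )
            in_stratum = rng.random(n) < 0.3
            # plant a large age shift in the stratum's malb subjects
            shift_idx = in_stratum & (pheno["malb"] == 1)
            pheno.loc[shift_idx, "age"] += 12.0
            table = characterize_subgroup(
                pheno, in_stratum, variables=[("age", "continuous")]
            )
            p = table[table["variable"] == "age"]["p"].iloc[0]
            hits += p < 0.05
        assert hits >= 24  # >= 80%

    def test_empty_stratum(self, mid_cohort):
        pheno = mid_cohort["pheno"]
        with pytest.warns(UserWarning):
            table = characterize_subgroup(pheno, np.zeros(len(pheno), dtype=bool))
        assert table.empty
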