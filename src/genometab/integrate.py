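"""Genotype-stratified metabolomic differences and discordant-genotype selection.

For one SNP at a time, subjects are stratified by genotype and each
metabolite is compared between microalbuminuric and normoalbuminuric
subjects within the stratum. Three derived objects mirror the published
presentation: a significance-category matrix (four p-value bands), a
normalized difference-ratio profile (stratum difference divided by the
cohort difference, so 1 means "same change as the whole population", 0
means "no change" and negative values mean a reversed change), and a
per-genotype discordance report used to nominate genotypes in which the
metabolomic contrast with UAE status disappears.

The cohort difference used in the ratio is recomputed on the subjects
genotyped for the SNP in question, which makes the per-group
subject-count-weighted average of stratum means reproduce the cohort means
exactly; a full-cohort variant is available via ``cohort_diffs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import CvPlan, cross_validate
from .errors import ValidationError
from .genassoc import GenotypeMatrix

#: upper p-value boundaries of categories 1..3; p above the first entry is category 0
SIGNIFICANCE_BOUNDS = (0.01, 0.001, 0.00001)

TESTS = ("welch", "student", "mannwhitney")


def _two_group_test(a: np.ndarray, b: np.ndarray, test: str) -> float:
    """Two-sided p-value comparing groups a (malb) and b (normo)."""
    if test not in TESTS:
        raise ValidationError(f"test must be one of {TESTS}")
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "student":
        return float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def cohort_differences(
    metab: pd.DataFrame, malb: np.ndarray | pd.Series, test: str = "welch"
) -> pd.DataFrame:
    """Per-metabolite group means, difference (malb - normo) and p-value."""
    flags = np.asarray(malb, dtype=bool)
    if len(flags) != len(metab):
        raise ValidationError("malb flags must match the metabolite table rows")
    rows = []
    for name in metab.columns:
        col = metab[name].to_numpy(dtype=float)
        a, b = col[flags], col[~flags]
        mean_malb = float(np.mean(a)) if len(a) else float("nan")
        mean_normo = float(np.mean(b)) if len(b) else float("nan")
        rows.append(
            {
                "metabolite": name,
                "mean_malb": mean_malb,
                "mean_normo": mean_normo,
                "diff": mean_malb - mean_normo,
                "p": _two_group_test(a, b, test),
                "n_malb": int(len(a)),
                "n_normo": int(len(b)),
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")


@dataclass
class StratumComparison:
    snp_id: str
    genotype: str
    metabolite: str
    mean_malb: float
    mean_normo: float
    diff: float
    p: float
    n_malb: int
    n_normo: int
    malb_percent: float
    low_confidence: bool = False


def stratified_differences(
    metab: pd.DataFrame,
    malb: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    snp_id: str,
    test: str = "welch",
    min_malb: int = 3,
) -> pd.DataFrame:
    """Per-(genotype, metabolite) group comparison for one SNP.

    Strata with fewer than `min_malb` microalbuminurics (or no subjects in
    one group) are flagged low-confidence, never dropped.
    """
    flags = np.asarray(malb, dtype=bool)
    labels = geno.genotype_labels(snp_id)
    rows = []
    for genotype in labels.dropna().unique():
        in_stratum = (labels == genotype).to_numpy()
        sub = metab.loc[in_stratum]
        sub_flags = flags[in_stratum]
        n_malb = int(sub_flags.sum())
        n_normo = int((~sub_flags).sum())
        pct = 100.0 * n_malb / (n_malb + n_normo) if (n_malb + n_normo) else float("nan")
        low_conf = n_malb < min_malb or n_normo < min_malb
        for name in metab.columns:
            col = sub[name].to_numpy(dtype=float)
            a, b = col[sub_flags], col[~sub_flags]
            mean_malb = float(np.mean(a)) if len(a) else float("nan")
            mean_normo = float(np.mean(b)) if len(b) else float("nan")
            rows.append(
                {
                    "snp_id": snp_id,
                    "genotype": genotype,
                    "metabolite": name,
                    "mean_malb": mean_malb,
                    "mean_normo": mean_normo,
                    "diff": mean_malb - mean_normo,
                    "p": _two_group_test(a, b, test),
                    "n_malb": n_malb,
                    "n_normo": n_normo,
                    "malb_percent": pct,
                    "low_confidence": low_conf,
                }
            )
    return pd.DataFrame(rows)


def significance_category(p: float) -> int:
    """Map a p-value to its band: 0 (p>0.01), 1 (p<0.01), 2 (p<0.001), 3 (p<1e-5)."""
    if np.isnan(p):
        return -1  # not computable (empty stratum side)
    category = 0
    for level, bound in enumerate(SIGNIFICANCE_BOUNDS, start=1):
        if p < bound:
            category = level
    return category


def significance_pattern(
    stratified: pd.DataFrame, cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Metabolite x genotype matrix of significance categories.

    When cohort results are given, a 'cohort' column is placed first,
    mirroring the whole-population column of the published pattern figure.
    """
    pivot = stratified.pivot_table(
        index="metabolite", columns="genotype", values="p", aggfunc="first", sort=False
    )
    out = pivot.map(significance_category).astype(int)
    if cohort is not None:
        cohort_cat = cohort["p"].map(significance_category).astype(int)
        out.insert(0, "cohort", cohort_cat.reindex(out.index))
    return out


def normalized_difference_ratio(
    stratified: pd.DataFrame,
    cohort: pd.DataFrame,
    diff_floor: float = 1e-12,
) -> pd.DataFrame:
    """Stratum difference divided by the cohort difference, per genotype.

    Ratio 1 = the stratum shows the population's UAE-associated change;
    0 = no change; negative = reversed change. Metabolites whose cohort
    difference is smaller in magnitude than `diff_floor` are flagged and
    get a NaN ratio.
    """
    out = stratified.copy()
    cohort_diff = cohort["diff"]
    out["cohort_diff"] = out["metabolite"].map(cohort_diff)
    out["cohort_diff_degenerate"] = out["cohort_diff"].abs() < diff_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = np.where(
            out["cohort_diff_degenerate"], np.nan, out["diff"] / out["cohort_diff"]
        )
    return out


def ratio_matrix(profile: pd.DataFrame) -> pd.DataFrame:
    """Metabolite x genotype matrix of normalized difference ratios."""
    return profile.pivot_table(
        index="metabolite", columns="genotype", values="ratio", aggfunc="first", sort=False
    )


def stratum_plsda(
    metab: pd.DataFrame,
    malb: np.ndarray | pd.Series,
    in_stratum: np.ndarray,
    plan: CvPlan | None = None,
    k: int = 2,
):
    """Cross-validated PLS-DA restricted to one genotype stratum."""
    plan = plan or CvPlan()
    flags = np.asarray(malb, dtype=float)
    in_stratum = np.asarray(in_stratum, dtype=bool)
    n = int(in_stratum.sum())
    if n < plan.n_folds:
        raise ValidationError(
            f"stratum holds {n} subjects; cannot run {plan.n_folds}-fold cross-validation"
        )
    X = metab.loc[in_stratum].to_numpy(dtype=float)
    y = flags[in_stratum]
    if len(np.unique(y)) < 2:
        raise ValidationError("stratum contains a single UAE class; PLS-DA undefined")
    k = min(k, np.linalg.matrix_rank(X - X.mean(axis=0)))
    return cross_validate(X, y, plan, k)


@dataclass
class DiscordanceCriteria:
    """Thresholds operationalizing 'minimal or no significant differences'."""

    cohort_significance_p: float = 0.00001  # a metabolite counts as globally significant below this
    stratum_nonsig_p: float = 0.01  # stratum comparison counts as non-significant at/above this
    min_nonsig_fraction: float = 0.8
    require_q2_below_cohort: bool = True


@dataclass
class GenotypeReport:
    snp_id: str
    genotype: str
    nonsig_fraction: float
    median_abs_ratio: float
    q2: float | None
    n_malb: int
    n_normo: int
    selected: bool = False
    low_confidence: bool = False


def select_discordant(
    stratified: pd.DataFrame,
    cohort: pd.DataFrame,
    stratum_q2: dict[str, float] | None = None,
    cohort_q2: float | None = None,
    criteria: DiscordanceCriteria | None = None,
) -> pd.DataFrame:
    """Nominate genotypes whose strata lose the cohort's metabolomic contrast.

    A genotype is selected when the fraction of globally-significant
    metabolites that are non-significant within the stratum exceeds the
    threshold and (optionally) the stratum's cross-validated Q2 falls below
    the cohort's. Thresholds are echoed in the output attrs.
    """
    criteria = criteria or DiscordanceCriteria()
    profile = normalized_difference_ratio(stratified, cohort)
    global_sig = cohort.index[cohort["p"] < criteria.cohort_significance_p]
    reports = []
    for genotype, grp in profile.groupby("genotype", sort=False):
        sig_rows = grp[grp["metabolite"].isin(global_sig)]
        if len(sig_rows):
            nonsig = (sig_rows["p"].isna() | (sig_rows["p"] >= criteria.stratum_nonsig_p)).mean()
        else:
            nonsig = float("nan")
        q2 = float("nan") if stratum_q2 is None else stratum_q2.get(genotype)
        q2 = float("nan") if q2 is None else float(q2)
        selected = bool(len(sig_rows)) and nonsig > criteria.min_nonsig_fraction
        if criteria.require_q2_below_cohort and cohort_q2 is not None:
            selected = selected and np.isfinite(q2) and q2 < cohort_q2
        reports.append(
            GenotypeReport(
                snp_id=grp["snp_id"].iloc[0],
                genotype=genotype,
                nonsig_fraction=float(nonsig),
                median_abs_ratio=(
                    float(grp["ratio"].abs().median()) if grp["ratio"].notna().any() else float("nan")
                ),
                q2=q2,
                n_malb=int(grp["n_malb"].iloc[0]),
                n_normo=int(grp["n_normo"].iloc[0]),
                selected=selected,
                low_confidence=bool(grp["low_confidence"].iloc[0]),
            )
        )
    out = pd.DataFrame([r.__dict__ for r in reports])
    out.attrs["criteria"] = criteria.__dict__ | {"cohort_q2": cohort_q2}
    return out


# ---------------------------------------------------------------------------
# clinical subgroup comparisons


def contingency_chi2(table: np.ndarray) -> tuple[float, float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    Returns (chi2, p, odds_ratio); the odds ratio uses the Haldane 0.5
    correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("contingency_chi2 expects a 2x2 table")
    if np.any(t < 0):
        raise ValidationError("counts must be non-negative")
    n = t.sum()
    if n == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("table has an empty margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    chi2 = float(np.sum((t - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    h = t + 0.5 if np.any(t == 0) else t
    odds = float((h[0, 0] * h[1, 1]) / (h[0, 1] * h[1, 0]))
    return chi2, p, odds


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int, variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test from summary statistics.

    Returns (t, df, p). 'welch' uses the Welch-Satterthwaite df; 'student'
    pools the variances with n1 + n2 - 2 df.
    """
    if variant not in ("welch", "student"):
        raise ValidationError("variant must be 'welch' or 'student'")
    if n1 < 2 or n2 < 2:
        raise ValidationError("both groups need n >= 2")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "student")
    )
    if variant == "student":
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


#: clinical variables summarized per subgroup: (column, kind)
_CLINICAL_VARS = [
    ("age", "continuous"),
    ("bmi", "continuous"),
    ("sbp", "continuous"),
    ("dbp", "continuous"),
    ("glucose", "continuous"),
    ("diabetes", "categorical"),
    ("hypertension", "categorical"),
]


def characterize_subgroup(
    pheno: pd.DataFrame,
    in_stratum: np.ndarray,
    malb: np.ndarray | pd.Series | None = None,
    variables: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Clinical comparison of malb vs normo subjects within a stratum.

    Continuous variables get mean +/- SD and a Welch t-test; binary ones
    get counts (%) and a Pearson chi-square. A final row compares the
    stratum's microalbuminurics' age against ALL microalbuminurics (note
    the groups overlap; the comparison is reported as published).
    """
    in_stratum = np.asarray(in_stratum, dtype=bool)
    flags = np.asarray(pheno["malb"] if malb is None else malb, dtype=bool)
    variables = variables or [(v, k) for v, k in _CLINICAL_VARS if v in pheno.columns]
    if not in_stratum.any():
        warnings.warn("empty stratum; returning empty table", stacklevel=2)
        return pd.DataFrame(
            columns=["variable", "malb_summary", "normo_summary", "statistic", "p"]
        )
    sub = pheno.loc[in_stratum]
    sub_flags = flags[in_stratum]
    rows = []
    for var, kind in variables:
        a = sub.loc[sub_flags, var].to_numpy(dtype=float)
        b = sub.loc[~sub_flags, var].to_numpy(dtype=float)
        if kind == "continuous":
            p = _two_group_test(a, b, "welch") if len(a) >= 2 and len(b) >= 2 else float("nan")
            rows.append(
                {
                    "variable": var,
                    "malb_summary": f"{np.mean(a):.1f}±{np.std(a, ddof=1):.1f}" if len(a) > 1 else "n/a",
                    "normo_summary": f"{np.mean(b):.1f}±{np.std(b, ddof=1):.1f}" if len(b) > 1 else "n/a",
                    "statistic": float("nan"),
                    "p": p,
                }
            )
        else:
            table = np.array(
                [
                    [np.sum(a == 1), np.sum(a == 0)],
                    [np.sum(b == 1), np.sum(b == 0)],
                ]
            )
            try:
                chi2, p, _ = contingency_chi2(table)
            except ValidationError:
                chi2, p = float("nan"), float("nan")
            pct_a = 100 * np.mean(a) if len(a) else float("nan")
            pct_b = 100 * np.mean(b) if len(b) else float("nan")
            rows.append(
                {
                    "variable": var,
                    "malb_summary": f"{int(np.sum(a == 1))} ({pct_a:.1f}%)",
                    "normo_summary": f"{int(np.sum(b == 1))} ({pct_b:.1f}%)",
                    "statistic": chi2,
                    "p": p,
                }
            )
    # stratum microalbuminurics vs all microalbuminurics (overlapping groups)
    all_malb_age = pheno.loc[flags, "age"].to_numpy(dtype=float)
    stratum_malb_age = sub.loc[sub_flags, "age"].to_numpy(dtype=float)
    if len(stratum_malb_age) >= 2 and len(all_malb_age) >= 2:
        _, _, p_age = summary_ttest(
            float(np.mean(stratum_malb_age)),
            float(np.std(stratum_malb_age, ddof=1)),
            len(stratum_malb_age),
            float(np.mean(all_malb_age)),
            float(np.std(all_malb_age, ddof=1)),
            len(all_malb_age),
            variant="welch",
        )
        rows.append(
            {
                "variable": "age_vs_all_malb",
                "malb_summary": f"{np.mean(stratum_malb_age):.1f}±{np.std(stratum_malb_age, ddof=1):.1f}",
                "normo_summary": f"{np.mean(all_malb_age):.1f}±{np.std(all_malb_age, ddof=1):.1f}",
                "statistic": float("nan"),
                "p": p_age,
            }
        )
    return pd.DataFrame(rows)
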