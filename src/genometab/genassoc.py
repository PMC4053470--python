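"""Genotype QC and genetic-model association with urinary albumin excretion.

Genotypes are coded as minor-allele counts {0, 1, 2}; missing calls are NaN.
Association fits are ordinary least squares on log10 UAE (linear) or
maximum-likelihood logistic fits on the microalbuminuria flag, both adjusted
for a caller-supplied covariate matrix. Multiple testing is handled by the
Holm-Bonferroni step-down procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AlignmentError, ValidationError

MODELS = ("ADD", "DOM", "REC")

#: model name -> mapping applied to minor-allele counts
_MODEL_CODING = {
    "ADD": {0: 0.0, 1: 1.0, 2: 2.0},
    "DOM": {0: 0.0, 1: 1.0, 2: 1.0},
    "REC": {0: 0.0, 1: 0.0, 2: 1.0},
}


class GenotypeMatrix:
    """Subjects x SNPs minor-allele-count matrix with per-SNP allele labels.

    Parameters
    ----------
    calls
        DataFrame of floats in {0, 1, 2, NaN}; index = subject ids,
        columns = SNP ids.
    alleles
        Mapping snp_id -> (major_allele, minor_allele). SNPs absent from the
        mapping get the placeholder alleles ('A', 'B').
    """

    def __init__(self, calls: pd.DataFrame, alleles: dict[str, tuple[str, str]] | None = None):
        calls = calls.astype(float)
        bad = calls.stack(future_stack=True).dropna()
        if not bad.isin([0.0, 1.0, 2.0]).all():
            raise ValidationError("genotype codes must be 0, 1, 2 or missing")
        self.calls = calls
        self.alleles = dict(alleles or {})
        for snp in calls.columns:
            self.alleles.setdefault(snp, ("A", "B"))

    @property
    def sample_ids(self) -> list:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list:
        return list(self.calls.columns)

    def genotype_labels(self, snp_id: str) -> pd.Series:
        """Human-readable genotype per subject, e.g. 'CC', 'CT', 'TT'."""
        major, minor = self.alleles[snp_id]
        label = {0.0: major + major, 1.0: major + minor, 2.0: minor + minor}
        return self.calls[snp_id].map(lambda c: label.get(c, None))

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n_major_hom, n_het, n_minor_hom) among non-missing calls."""
        col = self.calls[snp_id].dropna()
        return (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.calls.shape[0]} subjects x {self.calls.shape[1]} SNPs)"


@dataclass
class SnpQc:
    snp_id: str
    call_rate: float
    maf: float
    hwe_chi2: float
    hwe_p: float
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)


@dataclass
class AssocResult:
    """One genotype term from an adjusted regression fit."""

    snp_id: str
    model: str
    beta: float
    se: float
    p: float
    power: float
    n_used: int
    converged: bool = True
    separation: bool = False


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions, 1 df.

    Expected genotype counts are computed from the observed allele
    frequency. Monomorphic samples return (0, 1): the expected counts
    equal the observed ones exactly.
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValidationError("hwe_test requires at least one genotype")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def snp_qc(geno: GenotypeMatrix, min_call_rate: float = 0.90, hwe_alpha: float = 0.001) -> pd.DataFrame:
    """Per-SNP QC table: call rate, MAF, HWE chi2/p, pass flag and reasons."""
    rows = []
    n_subjects = geno.calls.shape[0]
    for snp in geno.snp_ids:
        col = geno.calls[snp]
        n_called = int(col.notna().sum())
        call_rate = n_called / n_subjects if n_subjects else 0.0
        n0, n1, n2 = geno.genotype_counts(snp)
        if n_called:
            maf = (n1 + 2 * n2) / (2 * n_called)
            chi2, hwe_p = hwe_test(n0, n1, n2)
        else:
            maf, chi2, hwe_p = float("nan"), float("nan"), float("nan")
        reasons = []
        if call_rate <= min_call_rate:
            reasons.append(f"call_rate {call_rate:.3f} <= {min_call_rate}")
        if n_called and hwe_p < hwe_alpha:
            reasons.append(f"hwe_p {hwe_p:.2e} < {hwe_alpha}")
        rows.append(
            {
                "snp_id": snp,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_chi2": chi2,
                "hwe_p": hwe_p,
                "passed": not reasons,
                "fail_reasons": "; ".join(reasons),
            }
        )
    columns = ["snp_id", "call_rate", "maf", "hwe_chi2", "hwe_p", "passed", "fail_reasons"]
    return pd.DataFrame(rows, columns=columns).set_index("snp_id")


def qc_filter(
    geno: GenotypeMatrix, min_call_rate: float = 0.90, hwe_alpha: float = 0.001
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs failing call-rate or HWE thresholds; report every SNP."""
    qc = snp_qc(geno, min_call_rate=min_call_rate, hwe_alpha=hwe_alpha)
    keep = [s for s in geno.snp_ids if qc.loc[s, "passed"]]
    filtered = GenotypeMatrix(geno.calls[keep], {s: geno.alleles[s] for s in keep})
    return filtered, qc


def encode_model(calls: np.ndarray | pd.Series, model: str) -> np.ndarray:
    """Recode minor-allele counts under a genetic model.

    ADD keeps {0,1,2}; DOM collapses to carrier {0,1,1}; REC to
    minor-homozygote {0,0,1}. Missing values propagate as NaN.
    """
    if model not in _MODEL_CODING:
        raise ValidationError(f"unknown genetic model {model!r}; expected one of {MODELS}")
    arr = np.asarray(calls, dtype=float)
    coding = _MODEL_CODING[model]
    out = np.full_like(arr, np.nan)
    for raw, coded in coding.items():
        out[arr == raw] = coded
    return out


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a) if a.ndim == 1 else np.isfinite(a).all(axis=1)
    return mask


def _design(geno_coded: np.ndarray, covariates: np.ndarray | None, mask: np.ndarray) -> np.ndarray:
    cols = [np.ones(mask.sum()), np.asarray(geno_coded, dtype=float)[mask]]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov[mask])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via near-zero diagonal of R in QR
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = np.where(diag < 1e-8 * diag.max())[0].tolist()
        names = ["intercept", "genotype"] + [f"covariate_{i}" for i in range(X.shape[1] - 2)]
        raise ValidationError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(names[i] for i in bad)
        )
    return X


def assoc_linear(
    log_uae: np.ndarray,
    geno_coded: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "",
    model: str = "ADD",
    alpha: float = 0.05,
) -> AssocResult:
    """OLS of log10 UAE on a coded genotype plus covariates (complete case).

    Reports the genotype term's beta, SE, two-sided t-test p-value, the
    normal-approximation post-hoc power at `alpha`, and the number of
    subjects actually used.
    """
    y = np.asarray(log_uae, dtype=float)
    g = np.asarray(geno_coded, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if len(y) != len(g) or (cov is not None and len(cov) != len(y)):
        raise AlignmentError("log_uae, genotype and covariates must share subjects")
    mask = _complete_cases(y, g) if cov is None else _complete_cases(y, g, cov)
    if mask.sum() < 10:
        raise ValidationError(f"only {int(mask.sum())} complete cases; need >= 10")
    X = _design(g, cov, mask)
    fit = sm.OLS(y[mask], X).fit()
    beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    return AssocResult(
        snp_id=snp_id,
        model=model,
        beta=float(beta),
        se=float(se),
        p=float(p),
        power=posthoc_power(beta, se, alpha),
        n_used=int(mask.sum()),
    )


def assoc_logistic(
    malb: np.ndarray,
    geno_coded: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "",
    model: str = "ADD",
    alpha: float = 0.05,
) -> AssocResult:
    """Logistic regression of the microalbuminuria flag on a coded genotype.

    beta is the log-odds per coded unit with a Wald p-value. Separation or
    non-convergence is flagged on the result rather than raised.
    """
    y = np.asarray(malb, dtype=float)
    g = np.asarray(geno_coded, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if len(y) != len(g) or (cov is not None and len(cov) != len(y)):
        raise AlignmentError("malb, genotype and covariates must share subjects")
    mask = _complete_cases(y, g) if cov is None else _complete_cases(y, g, cov)
    if mask.sum() < 10:
        raise ValidationError(f"only {int(mask.sum())} complete cases; need >= 10")
    if len(np.unique(y[mask])) < 2:
        raise ValidationError("outcome is constant; logistic fit undefined")
    X = _design(g, cov, mask)
    converged, separation = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y[mask], X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
            if not np.isfinite(se) or abs(beta) > 15:
                separation = True
        except Exception:
            converged = False
            separation = True
            beta, se, p = float("nan"), float("nan"), float("nan")
    power = posthoc_power(beta, se, alpha) if np.isfinite(se) and se > 0 else float("nan")
    return AssocResult(
        snp_id=snp_id,
        model=model,
        beta=float(beta),
        se=float(se),
        p=float(p),
        power=power,
        n_used=int(mask.sum()),
        converged=converged,
        separation=separation,
    )


def holm_bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down multiple-testing correction.

    Sorted p-values p_(i) are compared with alpha/(m-i+1); rejection stops
    at the first failure. Adjusted p-values are the running maximum of
    min(1, (m-i+1) * p_(i)), which makes them monotone in the sort order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("pvals must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    running_max = 0.0
    still_rejecting = True
    for rank, idx in enumerate(order):
        factor = m - rank
        running_max = max(running_max, min(1.0, factor * p[idx]))
        adjusted[idx] = running_max
        if still_rejecting and p[idx] <= alpha / factor:
            reject[idx] = True
        else:
            still_rejecting = False
    return adjusted, reject


def posthoc_power(beta: float, se: float, alpha: float = 0.05) -> float:
    """Normal-approximation post-hoc power of a two-sided Wald test.

    Phi(|beta|/se - z) + Phi(-|beta|/se - z) with z the two-sided critical
    value; equals alpha when beta = 0.
    """
    if se <= 0 or not np.isfinite(se):
        raise ValidationError("se must be positive and finite")
    z = stats.norm.ppf(1 - alpha / 2)
    ratio = abs(beta) / se
    return float(stats.norm.cdf(ratio - z) + stats.norm.cdf(-ratio - z))


def associate_panel(
    log_uae: np.ndarray,
    malb: np.ndarray,
    geno: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    models: tuple[str, ...] = MODELS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every SNP under every requested genetic model.

    Returns a tidy table with one row per (SNP, model); `best_model` flags
    the minimum-p model within each SNP, and `p_holm` is the Holm-adjusted
    linear-model p-value computed across the flagged rows.
    """
    rows = []
    for snp in geno.snp_ids:
        calls = geno.calls[snp].to_numpy()
        for model in models:
            coded = encode_model(calls, model)
            finite = coded[np.isfinite(coded)]
            if len(np.unique(finite)) < 2:
                continue  # model collapses to a constant for this SNP
            lin = assoc_linear(log_uae, coded, covariates, snp_id=snp, model=model, alpha=alpha)
            logi = assoc_logistic(malb, coded, covariates, snp_id=snp, model=model, alpha=alpha)
            rows.append(
                {
                    "snp_id": snp,
                    "model": model,
                    "beta": lin.beta,
                    "se": lin.se,
                    "p": lin.p,
                    "power": lin.power,
                    "n_used": lin.n_used,
                    "beta_logistic": logi.beta,
                    "p_logistic": logi.p,
                    "separation": logi.separation,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["best_model"] = False
    for snp, grp in table.groupby("snp_id"):
        table.loc[grp["p"].idxmin(), "best_model"] = True
    best = table[table["best_model"]]
    adjusted, reject = holm_bonferroni(best["p"].to_numpy(), alpha=alpha)
    table.loc[best.index, "p_holm"] = adjusted
    table.loc[best.index, "holm_reject"] = reject
    return table
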