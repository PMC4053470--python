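"""Synthetic-cohort generators.

Every generator is a pure function of its parameter objects and an integer
seed. Covariates are drawn independently from truncated normals (only
marginal summaries are published for the reference cohort); genotypes
follow Hardy-Weinberg proportions unless an inbreeding-style deviation is
requested; log10 ACR is generated by the same linear model the association
stage fits, with the intercept calibrated by bisection to hit a target
microalbuminuria prevalence.

Spectra are forward-modelled from Lorentzian lineshapes. Peak amplitudes
are obtained by solving a small linear system so that, analytically, each
metabolite window's integrated area equals the subject's level and the
total aliphatic area equals a fixed constant; broad filler peaks placed in
the gaps between windows absorb the remaining area. This makes the
levels -> spectra -> quantification round trip exact up to discretization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ..errors import AlignmentError, ValidationError
from ..genassoc import GenotypeMatrix, encode_model
from .specs import CovariateSpec, EffectSpec, PeakSpec, SnpSpec

SPECTRUM_GRID = (0.40, 4.80, 0.0005)  # lo, hi, spacing (ppm)
ALIPHATIC_WINDOW = (0.50, 4.70)


def _trunc_normal(rng, n, mean, sd, lower=-np.inf, upper=np.inf):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def gen_covariates(n: int, spec: CovariateSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a partial phenotype table: ids, demographics and vitals.

    Age is truncated at `spec.min_age`; physiological floors keep the other
    covariates positive. Diabetes and hypertension flags follow standard
    clinical cut-offs on the drawn values.
    """
    if n < 2:
        raise ValidationError(f"need n >= 2 subjects, got {n}")
    spec = spec or CovariateSpec()
    rng = np.random.default_rng(seed)
    pheno = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(1, n + 1)],
            "age": _trunc_normal(rng, n, spec.age_mean, spec.age_sd, lower=spec.min_age),
            "sex": (rng.random(n) < spec.sex_fraction_male).astype(int),
            "bmi": _trunc_normal(rng, n, spec.bmi_mean, spec.bmi_sd, lower=12.0),
            "sbp": _trunc_normal(rng, n, spec.sbp_mean, spec.sbp_sd, lower=70.0),
            "dbp": _trunc_normal(rng, n, spec.dbp_mean, spec.dbp_sd, lower=40.0),
            "glucose": _trunc_normal(rng, n, spec.glucose_mean, spec.glucose_sd, lower=40.0),
            "creatinine": _trunc_normal(rng, n, spec.creatinine_mean, spec.creatinine_sd, lower=0.3),
        }
    ).set_index("subject_id")
    pheno["diabetes"] = (pheno["glucose"] >= 126.0).astype(int)
    pheno["hypertension"] = ((pheno["sbp"] >= 140.0) | (pheno["dbp"] >= 90.0)).astype(int)
    return pheno


def gen_genotypes(
    n: int,
    snps: list[SnpSpec],
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypeMatrix:
    """Draw genotypes in (possibly perturbed) Hardy-Weinberg proportions.

    With ``hwe_deviation`` F the genotype probabilities become
    (p^2 + Fpq, 2pq(1-F), q^2 + Fpq), the standard inbreeding
    parameterization; F = 0 recovers exact HWE in expectation.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValidationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    calls = {}
    alleles = {}
    for snp in snps:
        q = snp.maf
        p = 1.0 - q
        F = snp.hwe_deviation
        probs = np.array([p * p + F * p * q, 2 * p * q * (1 - F), q * q + F * p * q])
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()
        col = rng.choice(np.array([0.0, 1.0, 2.0]), size=n, p=probs)
        if missing_rate > 0:
            col[rng.random(n) < missing_rate] = np.nan
        calls[snp.snp_id] = col
        alleles[snp.snp_id] = (snp.major_allele, snp.minor_allele)
    return GenotypeMatrix(pd.DataFrame(calls, index=ids), alleles)


def _calibrate_intercept(eta: np.ndarray, threshold_log: float, target: float) -> float:
    """Bisection on the intercept until prevalence brackets the target."""
    lo, hi = threshold_log - eta.max() - 1.0, threshold_log - eta.min() + 1.0

    def prevalence(c):
        return float(np.mean(eta + c >= threshold_log))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return hi


def gen_uae(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix | None,
    snps: list[SnpSpec] | None,
    eff: EffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete a phenotype table with ACR, log10 UAE and the malb flag.

    log10(ACR) = intercept + covariate effects + per-SNP coded-genotype
    effects + Gaussian noise. Missing genotype calls contribute their SNP's
    mean coded value so no subject is dropped at generation time.
    """
    eff = eff or EffectSpec()
    rng = np.random.default_rng(seed)
    n = len(pheno)
    eta = np.zeros(n)
    for name, beta in eff.covariate_betas.items():
        if name not in pheno.columns:
            raise ValidationError(f"covariate {name!r} not in phenotype table")
        eta += beta * pheno[name].to_numpy(dtype=float)
    if geno is not None:
        if snps is None:
            raise ValidationError("snps specs required when genotypes are supplied")
        if len(geno.calls) != n or not geno.calls.index.equals(pheno.index):
            raise AlignmentError("genotype and phenotype tables must index the same subjects")
        for snp in snps:
            coded = encode_model(geno.calls[snp.snp_id].to_numpy(), snp.model)
            fill = np.nanmean(coded) if np.isnan(coded).any() else 0.0
            coded = np.where(np.isnan(coded), fill, coded)
            eta += snp.beta * coded
    eta = eta + rng.normal(0.0, eff.noise_sd, size=n)
    intercept = _calibrate_intercept(eta, np.log10(eff.malb_threshold), eff.target_prevalence)
    out = pheno.copy()
    out["log_uae"] = eta + intercept
    out["acr"] = 10.0 ** out["log_uae"]
    out["malb"] = (out["acr"] >= eff.malb_threshold).astype(int)
    return out


def gen_metabolite_levels(
    pheno: pd.DataFrame,
    peaks: list[PeakSpec],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject metabolite levels from group-conditional truncated normals.

    Each subject's level for a metabolite is drawn from the normo- or
    microalbuminuric Gaussian of its PeakSpec (selected by the malb flag),
    truncated at zero. Output columns follow the peak-spec order.
    """
    if "malb" not in pheno.columns:
        raise ValidationError("phenotype table must carry a 'malb' flag; run gen_uae first")
    rng = np.random.default_rng(seed)
    malb = pheno["malb"].to_numpy(dtype=bool)
    n = len(pheno)
    data = {}
    for pk in peaks:
        mean = np.where(malb, pk.amplitude_mean_malb, pk.amplitude_mean_normo)
        sd = np.where(malb, pk.amplitude_sd_malb, pk.amplitude_sd_normo)
        vals = np.empty(n)
        zero_sd = sd == 0
        vals[zero_sd] = mean[zero_sd]
        if (~zero_sd).any():
            a = (0.0 - mean[~zero_sd]) / sd[~zero_sd]
            vals[~zero_sd] = truncnorm.rvs(
                a, np.inf, loc=mean[~zero_sd], scale=sd[~zero_sd], random_state=rng
            )
        data[pk.metabolite] = vals
    return pd.DataFrame(data, index=pheno.index)


# ---------------------------------------------------------------------------
# spectrum forward model


def _components(pk: PeakSpec) -> list[tuple[float, float, float]]:
    """(center, hwhm, weight) Lorentzian components for one metabolite."""
    if pk.doublet_split_ppm > 0:
        half = 0.5 * pk.doublet_split_ppm
        return [
            (pk.center_ppm - half, pk.linewidth_ppm, 0.5),
            (pk.center_ppm + half, pk.linewidth_ppm, 0.5),
        ]
    return [(pk.center_ppm, pk.linewidth_ppm, 1.0)]


def _mass_in(components, lo: float, hi: float) -> float:
    """Analytic unit-Lorentzian mass within [lo, hi]."""
    total = 0.0
    for c, g, w in components:
        total += w / np.pi * (np.arctan((hi - c) / g) - np.arctan((lo - c) / g))
    return total


def _filler_components(windows: list[tuple[float, float]]) -> list[tuple[float, float, float]]:
    """Broad Lorentzians in the gaps between metabolite windows.

    Weights are proportional to gap width so the unassigned spectral area
    is spread smoothly across the whole aliphatic range.
    """
    lo, hi = ALIPHATIC_WINDOW
    edges = sorted(windows)
    gaps = []
    cursor = lo
    for wlo, whi in edges:
        if wlo - cursor >= 0.02:
            gaps.append((cursor, wlo))
        cursor = max(cursor, whi)
    if hi - cursor >= 0.02:
        gaps.append((cursor, hi))
    total_width = sum(b - a for a, b in gaps)
    comps = []
    for a, b in gaps:
        width = b - a
        gamma = min(max(width / 20.0, 0.002), 0.05)
        comps.append((0.5 * (a + b), gamma, width / total_width))
    return comps


class SpectrumForwardModel:
    """Precomputed linear map from metabolite levels to peak amplitudes.

    Solves ``M a = [levels, total]`` where row i of M holds each
    component's analytic mass fraction inside metabolite window i and the
    last row holds masses over the whole aliphatic window. The final
    unknown scales the filler peaks.
    """

    def __init__(self, peaks: list[PeakSpec], total_area: float = 100.0):
        self.peaks = peaks
        self.total_area = total_area
        self.windows = [(pk.ppm_lo, pk.ppm_hi) for pk in peaks]
        self.peak_components = [_components(pk) for pk in peaks]
        self.fillers = _filler_components(self.windows)
        k = len(peaks)
        M = np.zeros((k + 1, k + 1))
        for i, (wlo, whi) in enumerate(self.windows):
            for j, comps in enumerate(self.peak_components):
                M[i, j] = _mass_in(comps, wlo, whi)
            M[i, k] = _mass_in(self.fillers, wlo, whi)
        alo, ahi = ALIPHATIC_WINDOW
        for j, comps in enumerate(self.peak_components):
            M[k, j] = _mass_in(comps, alo, ahi)
        M[k, k] = _mass_in(self.fillers, alo, ahi)
        self._matrix = M
        self._lu = np.linalg.inv(M)  # small fixed-size system; inverse is fine

    def amplitudes(self, levels: np.ndarray) -> np.ndarray:
        """Component amplitudes reproducing `levels` (percent) exactly.

        When a drawn level is smaller than the unavoidable leak of
        neighbouring peaks into its window, the exact solve would need a
        negative amplitude; a non-negative least-squares fallback then
        yields the closest physically realizable spectrum.
        """
        rhs = np.concatenate([np.asarray(levels, dtype=float), [self.total_area]])
        amps = self._lu @ rhs
        if np.any(amps < -1e-9):
            from scipy.optimize import nnls

            warnings.warn(
                "exact amplitude solve went negative (level below neighbour leak); "
                "falling back to non-negative least squares",
                stacklevel=2,
            )
            amps, _ = nnls(self._matrix, rhs)
        return np.clip(amps, 0.0, None)


def _lorentzian_sum(x: np.ndarray, components, amplitude: float) -> np.ndarray:
    y = np.zeros_like(x)
    for c, g, w in components:
        y += amplitude * w * (g / np.pi) / ((x - c) ** 2 + g**2)
    return y


def gen_spectra(
    levels: pd.DataFrame,
    peaks: list[PeakSpec],
    noise_sd: float = 0.0,
    seed: int = 0,
    grid: tuple[float, float, float] = SPECTRUM_GRID,
    baseline_amplitude: float = 0.0,
    total_area: float = 100.0,
) -> list:
    """Forward-model one spectrum per row of `levels`.

    Optional additive Gaussian noise (intensity units) and a smooth
    low-order cosine baseline. Levels are interpreted as percent of the
    target total aliphatic area.
    """
    from ..spectra import Spectrum  # local import to avoid cycle at package load

    glo, ghi, h = grid
    names = [pk.metabolite for pk in peaks]
    missing = [m for m in names if m not in levels.columns]
    if missing:
        raise ValidationError(f"levels table lacks metabolites: {missing}")
    for pk in peaks:
        if not glo <= pk.center_ppm <= ghi:
            raise ValidationError(
                f"{pk.metabolite}: peak center {pk.center_ppm} outside grid [{glo}, {ghi}]"
            )
    model = SpectrumForwardModel(peaks, total_area=total_area)
    rng = np.random.default_rng(seed)
    x = glo + h * np.arange(int(round((ghi - glo) / h)) + 1)
    spectra = []
    for sample_id, row in levels[names].iterrows():
        amps = model.amplitudes(row.to_numpy())
        y = np.zeros_like(x)
        for comps, a in zip(model.peak_components, amps[:-1]):
            y += _lorentzian_sum(x, comps, a)
        y += _lorentzian_sum(x, model.fillers, amps[-1])
        if baseline_amplitude > 0:
            y += baseline_amplitude * (1.0 + np.cos(2 * np.pi * (x - glo) / (ghi - glo)))
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=len(x))
        spectra.append(Spectrum(x.copy(), y, sample_id=str(sample_id)))
    return spectra


# ---------------------------------------------------------------------------
# clinical formulas


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index, weight (kg) / height (m) squared."""
    if height_m <= 0:
        raise ValidationError("height must be > 0")
    return weight_kg / height_m**2


def egfr_mdrd(creatinine_mg_dl: float, age_years: float, female: bool) -> float:
    """Abbreviated MDRD estimated GFR (ml/min/1.73 m^2)."""
    if creatinine_mg_dl <= 0 or age_years <= 0:
        raise ValidationError("creatinine and age must be > 0")
    value = 186.0 * creatinine_mg_dl**-1.154 * age_years**-0.203
    if female:
        value *= 0.742
    return value


def gen_cohort(
    n: int,
    seed: int = 0,
    covariate_spec: CovariateSpec | None = None,
    snps: list[SnpSpec] | None = None,
    effect_spec: EffectSpec | None = None,
    peaks: list[PeakSpec] | None = None,
    missing_rate: float = 0.0,
    spectra_noise_sd: float = 0.0,
    make_spectra: bool = False,
) -> dict:
    """Convenience wrapper: full cohort from one master seed.

    Stage seeds are spawned from the master seed so each stage stays
    individually reproducible. Returns a dict with keys 'pheno', 'geno',
    'levels' and (optionally) 'spectra'.
    """
    from .specs import default_peak_specs, default_snp_specs

    snps = default_snp_specs() if snps is None else snps
    peaks = default_peak_specs() if peaks is None else peaks
    ss = np.random.SeedSequence(seed)
    s_cov, s_gen, s_uae, s_lvl, s_spec = [int(c.generate_state(1)[0]) for c in ss.spawn(5)]
    pheno = gen_covariates(n, covariate_spec, seed=s_cov)
    geno = gen_genotypes(n, snps, seed=s_gen, missing_rate=missing_rate)
    pheno = gen_uae(pheno, geno, snps, effect_spec, seed=s_uae)
    levels = gen_metabolite_levels(pheno, peaks, seed=s_lvl)
    out = {"pheno": pheno, "geno": geno, "levels": levels}
    if make_spectra:
        out["spectra"] = gen_spectra(levels, peaks, noise_sd=spectra_noise_sd, seed=s_spec)
    return out
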