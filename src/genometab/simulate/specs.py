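"""Parameter objects for the synthetic-cohort generators.

Defaults are calibrated to the reference cohort's published summary
statistics (covariate marginals, SNP effect sizes on log10 ACR, metabolite
group means/SDs). Minor-allele frequencies in the packaged SNP panel are
artifact defaults: the source tables report effects, not frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from ..errors import ValidationError
from ..genassoc import MODELS
from ..spectra import load_metabolite_reference, _load_packaged_tsv

MALB_THRESHOLD = 30.0  # ACR (ug/mg) at or above which microalbuminuria is flagged
DEFAULT_PREVALENCE = 0.07


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distributions for the simulated clinical covariates."""

    age_mean: float = 53.0
    age_sd: float = 19.0
    sex_fraction_male: float = 0.506
    bmi_mean: float = 26.0
    bmi_sd: float = 6.0
    sbp_mean: float = 129.0
    sbp_sd: float = 21.0
    dbp_mean: float = 79.0
    dbp_sd: float = 12.0
    glucose_mean: float = 92.0
    glucose_sd: float = 20.0
    creatinine_mean: float = 0.95
    creatinine_sd: float = 0.20
    min_age: float = 18.0

    def __post_init__(self):
        for f in fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) <= 0:
                raise ValidationError(f"{f.name} must be > 0")
        if not 0.0 <= self.sex_fraction_male <= 1.0:
            raise ValidationError("sex_fraction_male must lie in [0, 1]")


@dataclass(frozen=True)
class SnpSpec:
    """One SNP's simulation parameters: frequency, model and effect size."""

    snp_id: str
    maf: float
    model: str = "ADD"
    beta: float = 0.0
    hwe_deviation: float = 0.0
    chrom: str = ""
    gene: str = ""
    major_allele: str = "A"
    minor_allele: str = "B"

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValidationError(f"{self.snp_id}: maf must lie in (0, 0.5], got {self.maf}")
        if self.model not in MODELS:
            raise ValidationError(f"{self.snp_id}: model must be one of {MODELS}")
        if not -1.0 <= self.hwe_deviation <= 1.0:
            raise ValidationError(f"{self.snp_id}: hwe_deviation must lie in [-1, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Generative model for log10 ACR and the microalbuminuria flag."""

    covariate_betas: dict = field(
        default_factory=lambda: {
            "age": 0.006,
            "sex": 0.05,
            "bmi": 0.008,
            "sbp": 0.004,
            "glucose": 0.002,
        }
    )
    noise_sd: float = 0.45
    malb_threshold: float = MALB_THRESHOLD
    target_prevalence: float = DEFAULT_PREVALENCE

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.malb_threshold <= 0:
            raise ValidationError("malb_threshold must be > 0")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValidationError("target_prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class PeakSpec:
    """Forward-model parameters for one metabolite's spectral contribution."""

    metabolite: str
    ppm_lo: float
    ppm_hi: float
    center_ppm: float
    linewidth_ppm: float
    amplitude_mean_normo: float
    amplitude_sd_normo: float
    amplitude_mean_malb: float
    amplitude_sd_malb: float
    doublet_split_ppm: float = 0.0

    def __post_init__(self):
        if not self.ppm_lo <= self.center_ppm <= self.ppm_hi:
            raise ValidationError(
                f"{self.metabolite}: center {self.center_ppm} outside window "
                f"[{self.ppm_lo}, {self.ppm_hi}]"
            )
        if self.linewidth_ppm <= 0:
            raise ValidationError(f"{self.metabolite}: linewidth must be > 0")
        for attr in ("amplitude_mean_normo", "amplitude_mean_malb"):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{self.metabolite}: {attr} must be > 0")
        for attr in ("amplitude_sd_normo", "amplitude_sd_malb"):
            if getattr(self, attr) < 0:
                raise ValidationError(f"{self.metabolite}: {attr} must be >= 0")


# peak placement tweaks: the alanine doublet sits at 1.478 ppm, and the
# hydroxyisovalerate window overlaps the pyruvate one, so its peak is
# centered in the non-shared part of its window.
_CENTER_OVERRIDES = {"alanine": 1.478, "hydroxyisovalerate": 2.395}
_DOUBLET_SPLITS = {"alanine": 0.012}


def default_peak_specs() -> list[PeakSpec]:
    """One PeakSpec per packaged metabolite window, reference-calibrated."""
    ref = load_metabolite_reference()
    specs = []
    for row in ref.itertuples():
        lo, hi = float(row.ppm_lo), float(row.ppm_hi)
        center = _CENTER_OVERRIDES.get(row.name, 0.5 * (lo + hi))
        width = hi - lo
        specs.append(
            PeakSpec(
                metabolite=row.name,
                ppm_lo=lo,
                ppm_hi=hi,
                center_ppm=center,
                linewidth_ppm=max(0.0015, width / 30.0),
                amplitude_mean_normo=float(row.normo_mean),
                amplitude_sd_normo=float(row.normo_sd),
                amplitude_mean_malb=float(row.malb_mean),
                amplitude_sd_malb=float(row.malb_sd),
                doublet_split_ppm=_DOUBLET_SPLITS.get(row.name, 0.0),
            )
        )
    return specs


def default_snp_specs() -> list[SnpSpec]:
    """The packaged 14-SNP panel with published models and effect sizes."""
    panel = _load_packaged_tsv("snp_panel.tsv")
    return [
        SnpSpec(
            snp_id=row.snp_id,
            maf=float(row.maf),
            model=row.model,
            beta=float(row.beta),
            chrom=str(row.chrom),
            gene=row.gene,
            major_allele=row.major_allele,
            minor_allele=row.minor_allele,
        )
        for row in panel.itertuples()
    ]
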