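"""Run configuration: every pipeline threshold with its default, YAML round trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    """All knobs of the end-to-end pipeline in one serializable object."""

    # stage toggles
    run_simulate: bool = True
    run_spectra: bool = True
    run_chemometrics: bool = True
    run_genassoc: bool = True
    run_integrate: bool = True

    # simulate
    n_subjects: int = 400
    seed: int = 0
    target_prevalence: float = 0.07
    genotype_missing_rate: float = 0.0
    spectra_noise_sd: float = 0.0

    # spectra
    bin_width: float = 0.01
    window_lo: float = 0.50
    window_hi: float = 4.70

    # chemometrics
    cv_folds: int = 10
    cv_repeats: int = 10
    max_components: int = 5

    # genassoc
    min_call_rate: float = 0.90
    hwe_alpha: float = 0.001
    assoc_alpha: float = 0.05
    covariates: list = field(default_factory=lambda: ["age", "sex", "bmi", "sbp", "glucose"])

    # integrate
    significance_bounds: list = field(default_factory=lambda: [0.01, 0.001, 0.00001])
    min_malb_per_stratum: int = 3
    discordance_nonsig_fraction: float = 0.8

    # paths (None = in-memory only)
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if not 0 < self.target_prevalence < 1:
            raise ValidationError("target_prevalence must lie in (0, 1)")
        if not self.window_lo < self.window_hi:
            raise ValidationError("window_lo must be < window_hi")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        return cls() if path is None else cls.from_yaml(path)
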