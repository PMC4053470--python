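"""1H-NMR spectrum preprocessing and metabolite quantification.

The processing chain is: reference the chemical-shift axis to the alanine
doublet (1.478 ppm), integrate into 0.01 ppm buckets over the 0.50-4.70 ppm
aliphatic window, normalize to total aliphatic area, and either reduce to
the packaged 51 analysis regions or quantify the 26 named metabolite
windows. Quantified levels are expressed as percent of total aliphatic
area, the same scale the reference group means use.

Conventions fixed here (the underlying protocol states neither): buckets
are half-open ``[lo, lo + width)`` anchored at 0.50 ppm, a bucket belongs
to a region when its midpoint falls in ``[ppm_lo, ppm_hi)``, and per-bucket
areas come from trapezoidal integration on the native grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .errors import CoverageError, NormalizationError, ReferencingError, ValidationError

DEFAULT_WINDOW = (0.50, 4.70)
DEFAULT_BIN_WIDTH = 0.01
ALANINE_PPM = 1.478
ALANINE_SEARCH_WINDOW = (1.43, 1.53)
LEVEL_SCALE = 100.0  # levels reported as percent of total aliphatic area


@dataclass
class Spectrum:
    """One sample's chemical-shift axis and signal."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValidationError("ppm and intensity must be 1-d arrays of equal length")
        if len(self.ppm) < 2:
            raise ValidationError("spectrum needs at least two points")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        if np.all(d < 0):  # store ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()


@dataclass
class BinnedSpectrum:
    bin_edges: np.ndarray
    bin_areas: np.ndarray
    sample_id: str = ""
    normalized: bool = False

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_area(self) -> float:
        return float(self.bin_areas.sum())


@dataclass(frozen=True)
class RegionDefinition:
    name: str
    ppm_lo: float
    ppm_hi: float
    role: str = "analysis_region"

    def __post_init__(self):
        if not self.ppm_lo < self.ppm_hi:
            raise ValidationError(f"region {self.name}: ppm_lo must be < ppm_hi")
        if self.role not in ("analysis_region", "metabolite_region"):
            raise ValidationError(f"region {self.name}: unknown role {self.role!r}")


def _load_packaged_tsv(filename: str) -> pd.DataFrame:
    with resources.files("genometab.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_analysis_regions() -> list[RegionDefinition]:
    """The packaged 51 contiguous, non-overlapping analysis regions.

    They tile 0.50-4.70 ppm and contain each metabolite window as an exact
    union of tiles.
    """
    df = _load_packaged_tsv("analysis_regions.tsv")
    return [RegionDefinition(r.name, float(r.ppm_lo), float(r.ppm_hi), "analysis_region") for r in df.itertuples()]


def load_metabolite_regions() -> list[RegionDefinition]:
    """The packaged 26 named metabolite quantification windows (may overlap)."""
    df = _load_packaged_tsv("metabolite_windows.tsv")
    return [RegionDefinition(r.name, float(r.ppm_lo), float(r.ppm_hi), "metabolite_region") for r in df.itertuples()]


def load_metabolite_reference() -> pd.DataFrame:
    """Windows plus reference group means/SDs for the 26 metabolites."""
    return _load_packaged_tsv("metabolite_windows.tsv")


def read_regions_tsv(path) -> list[RegionDefinition]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "ppm_lo", "ppm_hi", "role"}
    if not required.issubset(df.columns):
        raise ValidationError(f"region TSV must have columns {sorted(required)}")
    return [RegionDefinition(r.name, float(r.ppm_lo), float(r.ppm_hi), r.role) for r in df.itertuples()]


def reference_spectrum(
    spec: Spectrum,
    target_ppm: float = ALANINE_PPM,
    search_window: tuple[float, float] = ALANINE_SEARCH_WINDOW,
) -> tuple[Spectrum, float]:
    """Shift the ppm axis so the alanine doublet midpoint sits at `target_ppm`.

    The doublet is located as the two tallest local maxima inside the search
    window; with a single maximum its position is used directly. Returns the
    shifted spectrum and the applied shift (new ppm = old ppm + shift).
    """
    lo, hi = search_window
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    if mask.sum() < 3:
        raise ReferencingError(f"spectrum has <3 points in the search window [{lo}, {hi}]")
    y = spec.intensity[mask]
    x = spec.ppm[mask]
    span = float(y.max() - y.min())
    if span <= 0:
        raise ReferencingError("flat signal in the reference search window; no doublet found")
    idx, props = find_peaks(y, prominence=0.05 * span)
    if len(idx) == 0:
        raise ReferencingError(
            f"no local maximum with sufficient prominence in [{lo}, {hi}] "
            f"(signal span {span:.3g})"
        )
    if len(idx) >= 2:
        top2 = idx[np.argsort(props["prominences"])[-2:]]
        midpoint = float(x[top2].mean())
    else:
        midpoint = float(x[idx[0]])
    shift = target_ppm - midpoint
    return Spectrum(spec.ppm + shift, spec.intensity.copy(), spec.sample_id), shift


def _cumulative_area(spec: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    cum = np.concatenate([[0.0], cumulative_trapezoid(spec.intensity, spec.ppm)])
    return spec.ppm, cum


def bin_spectrum(
    spec: Spectrum,
    width: float = DEFAULT_BIN_WIDTH,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> BinnedSpectrum:
    """Integrate the spectrum into fixed-width buckets over the window."""
    lo, hi = window
    if width <= 0:
        raise ValidationError("bin width must be positive")
    if spec.ppm[0] > lo + 1e-12 or spec.ppm[-1] < hi - 1e-12:
        raise CoverageError(
            f"spectrum [{spec.ppm[0]:.3f}, {spec.ppm[-1]:.3f}] does not cover the window [{lo}, {hi}]"
        )
    n_bins = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n_bins + 1)
    x, cum = _cumulative_area(spec)
    cum_at_edges = np.interp(edges, x, cum)
    areas = np.diff(cum_at_edges)
    return BinnedSpectrum(edges, areas, sample_id=spec.sample_id)


def normalize_total_area(b: BinnedSpectrum) -> BinnedSpectrum:
    """Divide every bucket by the total area over the analysis window."""
    total = b.total_area
    if total <= 0:
        raise NormalizationError(f"total spectral area {total:.3g} is not positive")
    return BinnedSpectrum(b.bin_edges.copy(), b.bin_areas / total, b.sample_id, normalized=True)


def reduce_regions(b: BinnedSpectrum, regions: list[RegionDefinition]) -> pd.Series:
    """Sum bucket areas into named regions (bucket midpoint in [lo, hi)).

    Analysis regions must not overlap; metabolite regions may, in which case
    shared buckets count toward every region containing them.
    """
    analysis = [r for r in regions if r.role == "analysis_region"]
    spans = sorted((r.ppm_lo, r.ppm_hi) for r in analysis)
    for (alo, ahi), (blo, _bhi) in zip(spans[:-1], spans[1:]):
        if blo < ahi - 1e-12:
            raise ValidationError("analysis regions overlap; regions must partition the window")
    mid = b.bin_midpoints
    values = {}
    for r in regions:
        inside = (mid >= r.ppm_lo) & (mid < r.ppm_hi)
        values[r.name] = float(b.bin_areas[inside].sum())
    return pd.Series(values)


def quantify_metabolites(
    spectra: list[Spectrum],
    regions: list[RegionDefinition] | None = None,
    width: float = DEFAULT_BIN_WIDTH,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Relative metabolite levels for a collection of spectra.

    Each spectrum is binned, total-area normalized, and the metabolite
    windows integrated; output is subjects x metabolites in the packaged
    column order, as percent of total aliphatic area.
    """
    if regions is None:
        regions = load_metabolite_regions()
    names = [r.name for r in regions]
    rows, ids = [], []
    for spec in spectra:
        b = normalize_total_area(bin_spectrum(spec, width=width, window=window))
        mid = b.bin_midpoints
        rows.append(
            [LEVEL_SCALE * float(b.bin_areas[(mid >= r.ppm_lo) & (mid < r.ppm_hi)].sum()) for r in regions]
        )
        ids.append(spec.sample_id)
    return pd.DataFrame(rows, index=ids, columns=names)


def mean_center(m: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center a matrix; returns (centered, column_means)."""
    X = np.asarray(m, dtype=float)
    if X.ndim != 2:
        raise ValidationError("mean_center expects a 2-d matrix")
    center = X.mean(axis=0)
    return X - center, center
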