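"""Per-region band statistics and dataset-level spectral summaries.

For each spectral region (UV, Vis, nIR) the analysis reports the strongest
excitation — the one with the largest oscillator strength among those with
f above a significance threshold (default f > 0.01, strict) — and a band
broadness statistic

    σ_R = |Δλ_R| · n_R

where |Δλ_R| is the wavelength span (max − min) of the region's excitations
and n_R their count; σ_R = 0 whenever the region holds at most one excitation.
A ``ratio`` mode (span divided by count) is available behind a flag for users
who prefer a per-excitation spacing, but the product form is the definition
used throughout.

Dataset-level summaries are an averaged stick spectrum smoothed with a
Lorentzian kernel, and a Gaussian kernel density over (Δλ, Δf) scatter points
min–max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .errors import InputError
from .records_io import (
    Excitation,
    ExcitationList,
    Phase,
    SpectralRegion,
    TMCRecord,
    classify_region,
)

#: Oscillator strengths must strictly exceed this for an excitation to count
#: as significant when reporting per-region maxima.
DEFAULT_F_THRESHOLD = 0.01

BROADNESS_MODES = ("product", "ratio")


@dataclass(frozen=True)
class RegionSummary:
    """Strongest excitation and band broadness of one spectral region.

    ``lambda_max_nm``/``f_max`` are None when no excitation in the region
    passes the intensity threshold.  ``n_region`` counts all excitations in
    the region regardless of intensity, matching the broadness definition.
    """

    region: SpectralRegion
    lambda_max_nm: float | None
    f_max: float | None
    sigma_nm: float
    n_region: int

    def __post_init__(self) -> None:
        if (self.lambda_max_nm is None) != (self.f_max is None):
            raise InputError("lambda_max and f_max must be jointly present or absent")
        if self.sigma_nm < 0:
            raise InputError("band broadness must be non-negative")
        if self.lambda_max_nm is not None and classify_region(self.lambda_max_nm) is not self.region:
            raise InputError(
                f"lambda_max {self.lambda_max_nm} nm does not lie in region {self.region.value}"
            )

    @property
    def has_maximum(self) -> bool:
        return self.lambda_max_nm is not None


def band_broadness(
    excitations: ExcitationList,
    region: SpectralRegion,
    *,
    mode: str = "product",
) -> float:
    """Band broadness of one region: wavelength span times excitation count.

    Returns 0 for regions with at most one excitation (the span is then
    undefined or zero).  ``mode='ratio'`` divides the span by the count
    instead of multiplying.
    """
    if mode not in BROADNESS_MODES:
        raise InputError(f"unknown broadness mode {mode!r}; expected one of {BROADNESS_MODES}")
    wavelengths = [e.wavelength_nm for e in excitations.in_region(region)]
    n = len(wavelengths)
    if n <= 1:
        return 0.0
    span = max(wavelengths) - min(wavelengths)
    return span * n if mode == "product" else span / n


def region_maxima(
    excitations: ExcitationList,
    f_threshold: float = DEFAULT_F_THRESHOLD,
    *,
    broadness_mode: str = "product",
) -> dict[SpectralRegion, RegionSummary]:
    """Strongest significant excitation and broadness for each region.

    Among the region's excitations with f strictly above ``f_threshold`` the
    entry with the largest oscillator strength is reported; ties go to the
    smaller state index.  Regions with no significant excitation get an
    absent maximum but still carry σ and the excitation count.
    """
    out: dict[SpectralRegion, RegionSummary] = {}
    for region in SpectralRegion:
        members = excitations.in_region(region)
        significant = [e for e in members if e.oscillator_strength > f_threshold]
        best: Excitation | None = None
        for e in significant:
            if best is None or e.oscillator_strength > best.oscillator_strength:
                best = e
        sigma = band_broadness(excitations, region, mode=broadness_mode)
        out[region] = RegionSummary(
            region=region,
            lambda_max_nm=None if best is None else best.wavelength_nm,
            f_max=None if best is None else best.oscillator_strength,
            sigma_nm=sigma,
            n_region=len(members),
        )
    return out


@dataclass(frozen=True)
class AveragedSpectrum:
    """Dataset-averaged absorption curve on a wavelength grid."""

    grid_nm: np.ndarray
    intensity: np.ndarray
    kernel_hwhm_nm: float
    f_threshold: float
    phase: Phase

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_nm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "grid_nm", grid)
        object.__setattr__(self, "intensity", inten)
        if grid.ndim != 1 or inten.shape != grid.shape:
            raise InputError("grid and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(grid) <= 0):
            raise InputError("wavelength grid must be strictly increasing")
        if np.any(inten < 0):
            raise InputError("intensity must be non-negative")
        if self.kernel_hwhm_nm <= 0:
            raise InputError("kernel half-width must be positive")

    @property
    def peak_nm(self) -> float:
        """Grid wavelength of the global intensity maximum."""
        return float(self.grid_nm[int(np.argmax(self.intensity))])


def averaged_spectrum(
    records: Sequence[TMCRecord],
    phase: Phase,
    f_threshold: float = 0.0,
    grid_nm: np.ndarray | None = None,
    hwhm_nm: float = 10.0,
) -> AveragedSpectrum:
    """Average the dataset's stick spectra after Lorentzian smoothing.

    Each retained excitation (f strictly above ``f_threshold``) contributes a
    Lorentzian centered at its wavelength with peak amplitude equal to its
    oscillator strength and half-width-at-half-maximum ``hwhm_nm``; the summed
    contributions are divided by the number of records (mean, not sum).

    The default grid spans 100–1000 nm in 1 nm steps.
    """
    if len(records) == 0:
        raise InputError("averaged_spectrum requires at least one record")
    phase = Phase(phase)
    if grid_nm is None:
        grid_nm = np.arange(100.0, 1000.0 + 1.0, 1.0)
    grid = np.asarray(grid_nm, dtype=float)
    gamma2 = float(hwhm_nm) ** 2
    total = np.zeros_like(grid)
    for rec in records:
        for e in rec.excitations(phase):
            if e.oscillator_strength > f_threshold:
                total += e.oscillator_strength * gamma2 / ((grid - e.wavelength_nm) ** 2 + gamma2)
    return AveragedSpectrum(
        grid_nm=grid,
        intensity=total / len(records),
        kernel_hwhm_nm=float(hwhm_nm),
        f_threshold=float(f_threshold),
        phase=phase,
    )


def density2d(
    points: Iterable[tuple[float, float]],
    bandwidth: float | str | None = None,
) -> np.ndarray:
    """Gaussian kernel density at each (Δλ, Δf) point, min–max normalized.

    Axes are standardized (zero mean, unit variance) before the KDE so the
    default Scott bandwidth treats the nm-scale and unit-scale axes evenly.
    The returned densities are rescaled to [0, 1] with the min mapped to 0
    and the max to 1.  If one axis is degenerate (zero spread) the density is
    computed on the other axis alone; fully coincident points are an error.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InputError("density2d requires at least two (x, y) points")
    std = pts.std(axis=0, ddof=0)
    varying = std > 0
    if not varying.any():
        raise InputError("all points identical: density is undefined (zero variance)")
    z = (pts[:, varying] - pts[:, varying].mean(axis=0)) / std[varying]
    kde = gaussian_kde(z.T, bw_method=bandwidth)
    dens = kde(z.T)
    lo, hi = dens.min(), dens.max()
    if hi == lo:  # e.g. two points: perfectly symmetric density
        return np.ones_like(dens)
    return (dens - lo) / (hi - lo)
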