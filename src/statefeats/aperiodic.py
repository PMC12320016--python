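"""Peak-exclusion aperiodic (1/f) estimation.

Short (1 s) segments make the separation of periodic and aperiodic spectral
components unstable, so the procedure here works in two stages:

1. Oscillatory peaks are detected once per spatial unit, on the spectrum
   *averaged over all repetitions*, by iterative Gaussian extraction in
   log-power space (an in-package re-implementation of the usual spectral
   parameterization scheme; fixed aperiodic mode, no knee).
2. The frequency ranges covered by those peaks — center +/- one bandwidth —
   are erased from every single repetition's spectrum, and the aperiodic
   slope and offset are obtained per repetition by ordinary least squares of
   log10(power) on log10(frequency) over the retained 1-100 Hz bins.

The exclusion half-width multiplier (1 x bandwidth each side) is exposed in
the config; bandwidth is defined as 2 sigma of the fitted Gaussian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .spectral import PowerSpectrum

__all__ = [
    "SpectralPeak",
    "PeakDetectConfig",
    "AperiodicFit",
    "detect_spectral_peaks",
    "build_aperiodic_mask",
    "fit_aperiodic",
]


@dataclass(frozen=True)
class SpectralPeak:
    center_freq: float  # Hz
    bandwidth: float  # Hz, 2 sigma of the fitted Gaussian
    height: float  # log10-power units above the aperiodic line

    def __post_init__(self) -> None:
        if self.center_freq <= 0 or self.bandwidth <= 0:
            raise ValueError("center_freq and bandwidth must be > 0")


@dataclass(frozen=True)
class PeakDetectConfig:
    fit_range: tuple[float, float] = (1.0, 100.0)
    max_n_peaks: int = 6
    min_peak_height: float = 0.1  # log10-power units
    peak_width_limits: tuple[float, float] = (1.0, 12.0)  # Hz, as 2-sigma bandwidth
    exclusion_multiplier: float = 1.0  # half-width = multiplier * bandwidth
    aperiodic_mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.fit_range[0] <= 0 or self.fit_range[0] >= self.fit_range[1]:
            raise ValueError("fit_range must be positive and ordered")
        if self.peak_width_limits[0] <= 0 or (
            self.peak_width_limits[0] >= self.peak_width_limits[1]
        ):
            raise ValueError("peak_width_limits must be positive and ordered")
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the fixed (no-knee) aperiodic mode is supported")


@dataclass(frozen=True)
class AperiodicFit:
    slope: float  # d log10(power) / d log10(f); <= 0 for 1/f-like spectra
    offset: float  # log10-power at log10(f) = 0
    n_bins_used: int


def _loglog_line(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    slope, offset = np.polyfit(log_f, log_p, 1)
    return float(slope), float(offset)


def _robust_line(log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
    """Aperiodic seed line that under-weights oscillatory peaks.

    Plain OLS first; then refit using only the bins whose residual lies at
    or below the median residual (peaks sit well above the line, so the
    lower half tracks the aperiodic floor).
    """
    slope, offset = _loglog_line(log_f, log_p)
    resid = log_p - (offset + slope * log_f)
    keep = resid <= np.median(resid)
    if keep.sum() >= 3:
        slope, offset = _loglog_line(log_f[keep], log_p[keep])
    return slope, offset


def _gauss(x: np.ndarray, height: float, center: float, sigma: float) -> np.ndarray:
    return height * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def detect_spectral_peaks(
    avg_spec: PowerSpectrum, cfg: PeakDetectConfig = PeakDetectConfig()
) -> list[SpectralPeak]:
    """Iterative Gaussian peak extraction on an average log-power spectrum."""
    lo, hi = cfg.fit_range
    if lo < avg_spec.freqs[0] - 1e-9 or hi > avg_spec.freqs[-1] + 1e-9:
        raise ValueError(
            f"fit_range {cfg.fit_range} outside spectrum support "
            f"[{avg_spec.freqs[0]}, {avg_spec.freqs[-1]}]"
        )
    spec = avg_spec.restrict(lo, hi)
    pos = spec.power > 0
    freqs = spec.freqs[pos]
    log_p = np.log10(spec.power[pos])
    log_f = np.log10(freqs)
    if freqs.size < 3:
        return []

    slope, offset = _robust_line(log_f, log_p)
    resid = log_p - (offset + slope * log_f)

    sig_lo = cfg.peak_width_limits[0] / 2.0
    sig_hi = cfg.peak_width_limits[1] / 2.0
    peaks: list[SpectralPeak] = []
    for _ in range(cfg.max_n_peaks):
        i_max = int(np.argmax(resid))
        height0 = float(resid[i_max])
        if height0 < cfg.min_peak_height:
            break
        center0 = float(freqs[i_max])
        # local half-height width as the sigma guess
        above = resid >= height0 / 2.0
        j = i_max
        while j > 0 and above[j - 1]:
            j -= 1
        k = i_max
        while k < len(resid) - 1 and above[k + 1]:
            k += 1
        sigma0 = np.clip((freqs[k] - freqs[j]) / 2.355 or 1.0, sig_lo, sig_hi)
        try:
            popt, _ = curve_fit(
                _gauss,
                freqs,
                resid,
                p0=[height0, center0, sigma0],
                bounds=(
                    [0.0, max(center0 - 2 * sigma0, freqs[0]), sig_lo],
                    [2 * height0 + 1e-12, min(center0 + 2 * sigma0, freqs[-1]), sig_hi],
                ),
                maxfev=2000,
            )
            height, center, sigma = map(float, popt)
        except RuntimeError:
            height, center, sigma = height0, center0, float(sigma0)
        resid = resid - _gauss(freqs, height, center, sigma)
        if height >= cfg.min_peak_height:
            peaks.append(SpectralPeak(center, 2.0 * sigma, height))
    return peaks


def build_aperiodic_mask(
    freqs: np.ndarray,
    peaks: list[SpectralPeak],
    exclusion_multiplier: float = 1.0,
) -> np.ndarray:
    """True for bins retained in the log-log fit; peak ranges excluded.

    Each peak removes [center - m*bw, center + m*bw] inclusive; overlapping
    exclusions simply union.
    """
    freqs = np.asarray(freqs, dtype=float)
    mask = np.ones(freqs.shape, dtype=bool)
    for p in peaks:
        half = exclusion_multiplier * p.bandwidth
        mask &= ~((freqs >= p.center_freq - half) & (freqs <= p.center_freq + half))
    return mask


def fit_aperiodic(spec: PowerSpectrum, mask: np.ndarray | None = None) -> AperiodicFit:
    """OLS of log10(power) on log10(freq) over retained bins.

    ``spec`` is typically a single 1 s repetition's spectrum restricted to
    the fit range; ``mask`` comes from :func:`build_aperiodic_mask` on the
    same frequency axis. Zero-power bins are dropped with a warning before
    taking logs; fewer than 3 usable bins yields a NaN fit (never raises).
    """
    freqs = spec.freqs
    power = spec.power
    if mask is None:
        mask = np.ones(freqs.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != freqs.shape:
        raise ValueError("mask shape must match the spectrum's frequency axis")

    usable = mask & (freqs > 0)
    n_zero = int(np.sum(usable & (power <= 0)))
    if n_zero:
        warnings.warn(
            f"dropping {n_zero} zero-power bins before the log-log fit",
            RuntimeWarning,
            stacklevel=2,
        )
        usable &= power > 0
    n = int(usable.sum())
    if n < 3:
        return AperiodicFit(np.nan, np.nan, n)
    slope, offset = _loglog_line(np.log10(freqs[usable]), np.log10(power[usable]))
    return AperiodicFit(slope, offset, n)
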