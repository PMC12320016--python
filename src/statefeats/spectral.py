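"""Power spectra, band-power ("FreqBands") and full-spectrum ("fullFFT")
feature sets, and zero-phase band-pass filtering.

The per-epoch spectrum is a single-taper periodogram (Hann by default) with
``scaling="spectrum"`` normalization: for an untapered signal the sum of the
one-sided power values over *all* bins equals the signal's mean square, so the
sum over non-DC bins equals the population variance (Parseval). Epochs are
never averaged before spectral feature extraction — each 1 s epoch is one
observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "PowerSpectrum",
    "DEFAULT_BANDS",
    "power_spectrum",
    "band_power_features",
    "fullfft_features",
    "bandpass_filter",
]


@dataclass(frozen=True)
class BandDefinition:
    """A closed frequency interval [f_lo, f_hi] in Hz.

    Integer-Hz bins at both edges are included when averaging power, so
    adjacent bands in the default bank share their boundary bin.
    """

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi}]"
            )

    def validate_against_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: f_hi={self.f_hi} Hz reaches the "
                f"Nyquist frequency {fs / 2} Hz"
            )


#: Canonical M/EEG band bank. The 45–55 Hz gap (line-noise region) is
#: intentional; bands need not tile the axis.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("low_gamma", 30.0, 45.0),
    BandDefinition("high_gamma", 55.0, 100.0),
)


@dataclass
class PowerSpectrum:
    """One epoch's one-sided power spectrum."""

    freqs: np.ndarray
    power: np.ndarray
    taper: str = "hann"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def restrict(self, f_lo: float, f_hi: float) -> "PowerSpectrum":
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return PowerSpectrum(self.freqs[m], self.power[m], self.taper)


def power_spectrum(epoch: np.ndarray, fs: float, taper: str = "hann") -> PowerSpectrum:
    """Single-taper periodogram of a whole epoch.

    Parameters
    ----------
    epoch : 1-d signal vector; its length must give >= 1 Hz resolution
        (``len(epoch) >= fs`` for 1 s epochs is the typical case; the hard
        floor is 8 samples).
    taper : ``"hann"`` (default) or ``"none"``; the untapered variant exists
        so the Parseval identity holds exactly.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1 or epoch.size < 8:
        raise ValueError("epoch must be a 1-d vector of at least 8 samples")
    if taper not in ("hann", "none"):
        raise ValueError(f"unknown taper {taper!r}")
    window = "hann" if taper == "hann" else "boxcar"
    freqs, pxx = sps.periodogram(epoch, fs=fs, window=window, scaling="spectrum")
    return PowerSpectrum(freqs, pxx, taper)


def average_spectrum(epochs: np.ndarray, fs: float, taper: str = "hann") -> PowerSpectrum:
    """Mean spectrum across repetitions (rows) of one spatial unit."""
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    specs = [power_spectrum(e, fs, taper) for e in epochs]
    power = np.mean([s.power for s in specs], axis=0)
    return PowerSpectrum(specs[0].freqs, power, taper)


def band_power_features(
    spec: PowerSpectrum, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> np.ndarray:
    """Arithmetic mean of power over the bins of each band, in bank order."""
    out = np.empty(len(bands))
    for i, band in enumerate(bands):
        if band.f_lo < spec.freqs[0] or band.f_hi > spec.freqs[-1]:
            raise ValueError(
                f"band {band.name!r} [{band.f_lo}, {band.f_hi}] outside the "
                f"spectrum support [{spec.freqs[0]}, {spec.freqs[-1]}]"
            )
        m = (spec.freqs >= band.f_lo) & (spec.freqs <= band.f_hi)
        if not m.any():
            raise ValueError(f"band {band.name!r} contains no frequency bins")
        out[i] = spec.power[m].mean()
    return out


FREQBANDS_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)
FULLFFT_NAMES: tuple[str, ...] = tuple(f"power_{f}Hz" for f in range(1, 101))


def fullfft_features(spec: PowerSpectrum) -> np.ndarray:
    """Power at integer frequencies 1..100 Hz (requires 1 Hz resolution)."""
    if spec.resolution > 1.0 + 1e-9:
        raise ValueError(
            f"spectrum resolution {spec.resolution} Hz is coarser than 1 Hz"
        )
    targets = np.arange(1, 101, dtype=float)
    if spec.freqs[-1] < 100.0:
        raise ValueError("spectrum must cover 1-100 Hz")
    idx = np.searchsorted(spec.freqs, targets)
    if not np.allclose(spec.freqs[idx], targets):
        raise ValueError("spectrum bins are not aligned to integer frequencies")
    return spec.power[idx]


def bandpass_filter(epoch: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase (forward-reverse) 4th-order Butterworth band-pass."""
    band.validate_against_fs(fs)
    epoch = np.asarray(epoch, dtype=float)
    sos = sps.butter(4, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, epoch)
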