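"""The "TimeFeats" set: 41 per-epoch time-series descriptors.

Composition (41 = 22 + 2 + 5 + 2 + 1 + 1 + 1 + 7):

* the 22 canonical catch22 descriptors (:mod:`statefeats.catch22`);
* aperiodic slope and offset from the peak-exclusion log-log fit
  (:mod:`statefeats.aperiodic`);
* distribution statistics: mean, median, standard deviation (N-1
  denominator), skewness, kurtosis (non-excess, i.e. a Gaussian scores 3);
* Hjorth mobility and complexity;
* Hurst exponent (rescaled-range estimate over dyadic windows);
* zero crossings of the mean-removed signal;
* mean curve length (mean absolute first difference, no sampling-rate
  scaling);
* seven entropy/complexity measures: sample entropy, approximate entropy,
  permutation entropy, weighted permutation entropy, spectral entropy,
  Lempel-Ziv complexity, Higuchi fractal dimension.

Degenerate inputs (e.g. constant epochs) yield NaN for the features whose
definition breaks down (tolerance-based entropies, Hjorth, Hurst, slope),
never exceptions; NaNs are imputed downstream by the classification stage.

All features are deterministic functions of their input. The entropy
hyperparameters (m = 2, r = 0.2 sd, order 3, delay 1, k_max = 10) are the
field's standard defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from . import aperiodic as ap
from .catch22 import CATCH22_NAMES, _is_constant, catch22_features
from .spectral import BandDefinition, PowerSpectrum, bandpass_filter, power_spectrum

__all__ = [
    "TIMEFEATS_NAMES",
    "FeatureVector",
    "mean_curve_length",
    "hjorth_params",
    "zero_crossings",
    "distribution_stats",
    "hurst_exponent",
    "entropy_features",
    "compute_timefeats",
    "compute_timefeats_banded",
]

ENTROPY_NAMES: tuple[str, ...] = (
    "sample_entropy",
    "approximate_entropy",
    "permutation_entropy",
    "weighted_permutation_entropy",
    "spectral_entropy",
    "lempel_ziv_complexity",
    "higuchi_fd",
)

#: Canonical registry, fixed order. Length is exactly 41.
TIMEFEATS_NAMES: tuple[str, ...] = (
    CATCH22_NAMES
    + ("aperiodic_slope", "aperiodic_offset")
    + ("mean", "median", "std", "skewness", "kurtosis")
    + ("hjorth_mobility", "hjorth_complexity")
    + ("hurst_exponent",)
    + ("zero_crossings",)
    + ("mean_curve_length",)
    + ENTROPY_NAMES
)
assert len(TIMEFEATS_NAMES) == 41


@dataclass
class FeatureVector:
    """One epoch x one spatial unit's named feature values."""

    values: dict[str, float]
    epoch_id: int | None = None
    spatial_unit: str | None = None
    band: str = "broadband"

    def __post_init__(self) -> None:
        if tuple(self.values) != TIMEFEATS_NAMES:
            missing = set(TIMEFEATS_NAMES) - set(self.values)
            extra = set(self.values) - set(TIMEFEATS_NAMES)
            raise ValueError(
                f"feature vector must carry exactly the registry entries; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in TIMEFEATS_NAMES])


# ------------------------------------------------------------ simple features


def mean_curve_length(x: np.ndarray) -> float:
    """Mean absolute first difference (raw differences, no fs scaling)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("mean_curve_length needs at least 2 samples")
    if not np.isfinite(x).all():
        raise ValueError("mean_curve_length requires finite values")
    return float(np.mean(np.abs(np.diff(x))))


def hjorth_params(x: np.ndarray) -> tuple[float, float]:
    """(mobility, complexity) = (sqrt(var(dx)/var(x)), mobility(dx)/mobility(x)).

    Zero-variance input returns (nan, nan) for downstream imputation.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("hjorth_params needs at least 3 samples")
    v0 = np.var(x)
    if _is_constant(x):
        return (np.nan, np.nan)
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1, v2 = np.var(d1), np.var(d2)
    mobility = np.sqrt(v1 / v0)
    if v1 == 0:
        return (float(mobility), np.nan)
    complexity = np.sqrt(v2 / v1) / mobility
    return (float(mobility), float(complexity))


def zero_crossings(x: np.ndarray) -> int:
    """Sign changes of the mean-removed signal; exact zeros count positive."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("zero_crossings needs at least 2 samples")
    s = np.where(x - x.mean() >= 0, 1, -1)
    return int(np.sum(s[1:] != s[:-1]))


def distribution_stats(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, median, sd[N-1], skewness, kurtosis[non-excess])."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("distribution_stats needs at least 4 samples")
    sd = float(np.std(x, ddof=1))
    if _is_constant(x):
        return (float(x.mean()), float(np.median(x)), sd, np.nan, np.nan)
    return (
        float(x.mean()),
        float(np.median(x)),
        sd,
        float(spstats.skew(x, bias=True)),
        float(spstats.kurtosis(x, fisher=False, bias=True)),
    )


def hurst_exponent(x: np.ndarray) -> float:
    """Rescaled-range (R/S) Hurst estimate over dyadic windows 8..N/2."""
    x = np.asarray(x, dtype=float)
    if x.size < 64 or _is_constant(x):
        return np.nan
    n = x.size
    sizes = []
    w = 8
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    log_w, log_rs = [], []
    for w in sizes:
        k = n // w
        segs = x[: k * w].reshape(k, w)
        dev = segs - segs.mean(axis=1, keepdims=True)
        cum = np.cumsum(dev, axis=1)
        r = cum.max(axis=1) - cum.min(axis=1)
        s = segs.std(axis=1)
        ok = s > 0
        if not ok.any():
            continue
        rs = float(np.mean(r[ok] / s[ok]))
        if rs > 0:
            log_w.append(np.log(w))
            log_rs.append(np.log(rs))
    if len(log_w) < 2:
        return np.nan
    slope, _ = np.polyfit(log_w, log_rs, 1)
    return float(slope)


# --------------------------------------------------------- entropy features


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def _phi_counts(x: np.ndarray, m: int, r: float, exclude_self: bool) -> np.ndarray:
    """Per-template counts of Chebyshev-distance matches within r."""
    emb = _embed(x, m)
    d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    match = d <= r
    if exclude_self:
        np.fill_diagonal(match, False)
    return match.sum(axis=1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if _is_constant(x) or x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * sd
    # both template lengths truncated to N - m vectors (standard convention)
    n_templ = x.size - m
    b = _phi_counts(x, m, r, exclude_self=True)[:n_templ].sum()
    a = _phi_counts(x, m + 1, r, exclude_self=True).sum()
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if _is_constant(x) or x.size < m + 2:
        return np.nan
    if r is None:
        r = 0.2 * sd

    def phi(mm: int) -> float:
        c = _phi_counts(x, mm, r, exclude_self=False)
        return float(np.mean(np.log(c / len(c))))

    return float(phi(m) - phi(m + 1))


def _embed_delay(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    n = x.size - (order - 1) * delay
    idx = np.arange(order) * delay
    return x[np.arange(n)[:, None] + idx[None, :]]


def permutation_entropy(
    x: np.ndarray, order: int = 3, delay: int = 1, weighted: bool = False
) -> float:
    """Normalized (to [0, 1]) Shannon entropy of ordinal patterns.

    ``weighted=True`` weights each pattern occurrence by the variance of its
    embedding vector (weighted permutation entropy).
    """
    import math

    x = np.asarray(x, dtype=float)
    if x.size < (order - 1) * delay + 2:
        return np.nan
    emb = _embed_delay(x, order, delay)
    # ordinal pattern code: rank vector encoded in base `order`
    ranks = np.argsort(np.argsort(emb, axis=1, kind="stable"), axis=1, kind="stable")
    codes = ranks @ (order ** np.arange(order))
    n_codes = order**order
    if weighted:
        weights = emb.var(axis=1)
        mass = np.bincount(codes, weights=weights, minlength=n_codes)
        if mass.sum() == 0:
            return np.nan
    else:
        mass = np.bincount(codes, minlength=n_codes).astype(float)
    p = mass / mass.sum()
    p = p[p > 0]
    h = float(-np.sum(p * np.log(p)))
    return h / np.log(math.factorial(order))


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Shannon entropy of the normalized non-DC periodogram / log(#bins)."""
    x = np.asarray(x, dtype=float)
    if _is_constant(x):
        return np.nan
    spec = power_spectrum(x, fs, taper="none")
    p = spec.power[1:]
    tot = p.sum()
    if tot <= 0:
        return np.nan
    p = p / tot
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(len(spec.power) - 1))


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """LZ76 phrase count of the median-binarized signal, normalized by N/log2(N)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return np.nan
    b = (x > np.median(x)).astype(np.uint8)
    n = b.size
    return float(_lz76(b) / (n / np.log2(n)))


def _lz76(b: np.ndarray) -> int:
    s = b.tolist()
    n = len(s)
    i, k, l = 0, 1, 1
    c = 1
    k_max = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < k_max * 2 or _is_constant(x):
        return np.nan
    lk = []
    ks = np.arange(1, k_max + 1)
    for k in ks:
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.sum(np.abs(np.diff(x[idx])))
            norm = (n - 1) / (idx.size - 1) / k / k
            lm.append(dist * norm)
        lk.append(np.mean(lm))
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


def entropy_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """The seven entropy/complexity measures, by name."""
    x = np.asarray(x, dtype=float)
    if x.size < 32:
        raise ValueError("entropy_features needs at least 32 samples")
    return {
        "sample_entropy": sample_entropy(x),
        "approximate_entropy": approximate_entropy(x),
        "permutation_entropy": permutation_entropy(x),
        "weighted_permutation_entropy": permutation_entropy(x, weighted=True),
        "spectral_entropy": spectral_entropy(x, fs),
        "lempel_ziv_complexity": lempel_ziv_complexity(x),
        "higuchi_fd": higuchi_fd(x),
    }


# --------------------------------------------------------------- assembly


def compute_timefeats(
    epoch: np.ndarray,
    fs: float,
    avg_peaks: list[ap.SpectralPeak] | None = None,
    fit_range: tuple[float, float] = (1.0, 100.0),
    epoch_id: int | None = None,
    spatial_unit: str | None = None,
    band_label: str = "broadband",
) -> FeatureVector:
    """All 41 TimeFeats for one epoch of one spatial unit.

    ``avg_peaks`` is the peak list detected once per spatial unit on the
    spectrum averaged over all that unit's repetitions; the aperiodic
    slope/offset of this epoch are fitted with those peak ranges masked.
    """
    epoch = np.asarray(epoch, dtype=float)
    values: dict[str, float] = {}

    c22 = catch22_features(epoch)
    values.update(dict(zip(CATCH22_NAMES, c22)))

    spec = power_spectrum(epoch, fs).restrict(*fit_range)
    mask = ap.build_aperiodic_mask(spec.freqs, avg_peaks or [])
    fit = ap.fit_aperiodic(spec, mask)
    values["aperiodic_slope"] = fit.slope
    values["aperiodic_offset"] = fit.offset

    mean, median, sd, skew, kurt = distribution_stats(epoch)
    values.update(mean=mean, median=median, std=sd, skewness=skew, kurtosis=kurt)

    mob, comp = hjorth_params(epoch)
    values["hjorth_mobility"] = mob
    values["hjorth_complexity"] = comp
    values["hurst_exponent"] = hurst_exponent(epoch)
    values["zero_crossings"] = float(zero_crossings(epoch))
    values["mean_curve_length"] = mean_curve_length(epoch)
    values.update(entropy_features(epoch, fs))

    ordered = {k: float(values[k]) for k in TIMEFEATS_NAMES}
    return FeatureVector(ordered, epoch_id, spatial_unit, band_label)


def compute_timefeats_banded(
    epoch: np.ndarray,
    fs: float,
    band: BandDefinition,
    avg_peaks: list[ap.SpectralPeak] | None = None,
    **kw,
) -> FeatureVector:
    """TimeFeats on the band-passed epoch; aperiodic fit restricted to the band."""
    band.validate_against_fs(fs)
    filtered = bandpass_filter(epoch, fs, band)
    return compute_timefeats(
        filtered,
        fs,
        avg_peaks=avg_peaks,
        fit_range=(band.f_lo, band.f_hi),
        band_label=band.name,
        **kw,
    )
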