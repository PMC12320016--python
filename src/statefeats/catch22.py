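"""The 22 canonical catch22 time-series descriptors.

Implemented in-package from the published definitions of the set (the 22
features distilled from the hctsa library to cover most of its variance).
Every feature operates on the z-scored signal, as is the set's convention;
a zero-variance input yields a NaN vector. Where a published definition
leaves a micro-convention open (histogram bin rules, spline knot placement)
the choice made here is recorded in the docs.

Feature order is fixed and matches :data:`CATCH22_NAMES`.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import LSQUnivariateSpline

CATCH22_NAMES: tuple[str, ...] = (
    "DN_HistogramMode_5",
    "DN_HistogramMode_10",
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "CO_HistogramAMI_even_2_5",
    "CO_trev_1_num",
    "MD_hrv_classic_pnn40",
    "SB_BinaryStats_mean_longstretch1",
    "SB_TransitionMatrix_3ac_sumdiagcov",
    "PD_PeriodicityWang_th0_01",
    "CO_Embed2_Dist_tau_d_expfit_meandiff",
    "IN_AutoMutualInfoStats_40_gaussian_fmmi",
    "FC_LocalSimple_mean1_tauresrat",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "SP_Summaries_welch_rect_area_5_1",
    "SB_BinaryStats_diff_longstretch0",
    "SB_MotifThree_quantile_hh",
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1",
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1",
    "SP_Summaries_welch_rect_centroid",
    "FC_LocalSimple_mean3_stderr",
)

__all__ = ["CATCH22_NAMES", "catch22_features"]


# ---------------------------------------------------------------- helpers


def _is_constant(x: np.ndarray) -> bool:
    # float rounding leaves constants like full(n, 3.7) with std ~1e-16
    return x.std() <= 1e-12 * (1.0 + abs(float(x.mean())))


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation (FFT-based), acf[0] = 1."""
    n = len(x)
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    ps = np.abs(np.fft.rfft(xc, nfft)) ** 2
    ac = np.fft.irfft(ps)[:n]
    if ac[0] <= 0:
        return np.full(n, np.nan)
    return ac / ac[0]


def _first_zero_ac(ac: np.ndarray) -> int:
    """Lag of the first non-positive autocorrelation value."""
    below = np.flatnonzero(ac[1:] <= 0)
    return int(below[0] + 1) if below.size else len(ac)


def _longest_stretch(b: np.ndarray) -> int:
    """Longest run of True values."""
    best = cur = 0
    for v in b:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------- features


def _histogram_mode(z: np.ndarray, n_bins: int) -> float:
    counts, edges = np.histogram(z, bins=n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    return float(centers[int(np.argmax(counts))])


def _f1ecac(ac: np.ndarray) -> float:
    """First 1/e crossing of the ACF, linearly interpolated."""
    thresh = 1.0 / np.e
    for i in range(1, len(ac)):
        if ac[i] < thresh:
            return float(i - 1 + (ac[i - 1] - thresh) / (ac[i - 1] - ac[i]))
    return float(len(ac))


def _first_min_ac(ac: np.ndarray) -> float:
    for i in range(1, len(ac) - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            return float(i)
    return float(len(ac))


def _histogram_ami_even(z: np.ndarray, tau: int = 2, n_bins: int = 5) -> float:
    """Auto mutual information, even-width bins (0.1-padded range), lag 2."""
    x, y = z[:-tau], z[tau:]
    edges = np.linspace(z.min() - 0.1, z.max() + 0.1, n_bins + 1)
    joint, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    pij = joint / joint.sum()
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pij * np.log(pij / (pi * pj))
    return float(np.nansum(terms))


def _trev(z: np.ndarray) -> float:
    d = np.diff(z)
    return float(np.mean(d**3))


def _pnn40(z: np.ndarray) -> float:
    d = np.abs(np.diff(z))
    return float(np.mean(d > 0.04))


def _transition_matrix_3ac_sumdiagcov(z: np.ndarray, ac: np.ndarray) -> float:
    tau = _first_zero_ac(ac)
    y = z[::tau]
    if len(y) < 4:
        return np.nan
    # 3 equiprobable symbols via terciles of the downsampled series
    q = np.quantile(y, [1 / 3, 2 / 3])
    sym = np.digitize(y, q)
    t = np.zeros((3, 3))
    for a, b in zip(sym[:-1], sym[1:]):
        t[a, b] += 1
    t /= max(len(sym) - 1, 1)
    cov = np.cov(t, rowvar=False)
    return float(np.trace(cov))


def _periodicity_wang(z: np.ndarray, th: float = 0.01) -> float:
    """First trough-then-peak ACF period after cubic-spline detrending."""
    n = len(z)
    t = np.arange(n, dtype=float)
    # piecewise-cubic detrend; two interior knots give three pieces
    knots = [n / 3.0, 2 * n / 3.0]
    try:
        spline = LSQUnivariateSpline(t, z, knots, k=3)
        y = z - spline(t)
    except Exception:
        y = z - np.polyval(np.polyfit(t, z, 3), t)
    ac = _autocorr(y)
    max_tau = n // 3
    trough = -1
    for i in range(1, max_tau - 1):
        if ac[i] < ac[i - 1] and ac[i] < ac[i + 1]:
            trough = i
        elif trough >= 0 and ac[i] > ac[i - 1] and ac[i] > ac[i + 1]:
            if ac[i] > 0 and ac[i] - ac[trough] >= th:
                return float(i)
    return 0.0


def _embed2_dist_expfit_meandiff(z: np.ndarray, ac: np.ndarray) -> float:
    """Mean |histogram - exponential fit| of successive 2-d embedding jumps."""
    tau = min(_first_zero_ac(ac), max(len(z) // 10, 1))
    x1, x2 = z[: len(z) - tau], z[tau:]
    d = np.sqrt(np.diff(x1) ** 2 + np.diff(x2) ** 2)
    d = d[np.isfinite(d)]
    if d.size < 10 or d.mean() == 0:
        return np.nan
    lam = 1.0 / d.mean()
    counts, edges = np.histogram(d, bins="auto", density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    expf = lam * np.exp(-lam * centers)
    return float(np.mean(np.abs(counts - expf)))


def _ami_gaussian_fmmi(z: np.ndarray, max_lag: int = 40) -> float:
    """First minimum of the Gaussian-estimator auto mutual information."""
    n = len(z)
    max_lag = min(max_lag, n // 2)
    ami = np.empty(max_lag)
    for tau in range(1, max_lag + 1):
        r = np.corrcoef(z[:-tau], z[tau:])[0, 1]
        r = np.clip(r, -0.999999, 0.999999)
        ami[tau - 1] = -0.5 * np.log(1 - r**2)
    for i in range(1, max_lag - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            return float(i + 1)
    return float(max_lag)


def _local_simple_mean_resid(z: np.ndarray, train_len: int) -> np.ndarray:
    """Residuals of forecasting each point by the mean of the previous k."""
    kernel = np.ones(train_len) / train_len
    pred = np.convolve(z, kernel, mode="valid")[:-1]
    return z[train_len:] - pred


def _tauresrat(z: np.ndarray, ac: np.ndarray) -> float:
    res = _local_simple_mean_resid(z, 1)
    return _first_zero_ac(_autocorr(res)) / _first_zero_ac(ac)


def _mean3_stderr(z: np.ndarray) -> float:
    res = _local_simple_mean_resid(z, 3)
    return float(np.std(res, ddof=1))


def _outlier_include_mdrmd(z: np.ndarray, sign: int, inc: float = 0.01) -> float:
    """Median relative position of threshold exceedances, median over thresholds."""
    y = sign * z
    n = len(y)
    hi = y.max()
    if hi < inc:
        return 0.0
    thresholds = np.arange(0.0, hi + inc, inc)
    med_rel = []
    counts = []
    for th in thresholds:
        r = np.flatnonzero(y >= th)
        counts.append(r.size)
        if r.size == 0:
            med_rel.append(np.nan)
        else:
            med_rel.append(np.median(r) / (n / 2.0) - 1.0)
    med_rel = np.asarray(med_rel)
    counts = np.asarray(counts)
    keep = counts > 0.02 * n  # curve truncated once <2% of samples remain
    if not keep.any():
        return 0.0
    last = np.flatnonzero(keep).max()
    return float(np.median(med_rel[: last + 1]))


def _welch_rect(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-segment rectangular-window PSD over angular frequency [0, pi]."""
    f, pxx = sps.periodogram(z, fs=1.0, window="boxcar", scaling="density")
    w = 2 * np.pi * f
    s = pxx / (2 * np.pi)  # per radian
    return w, s


def _sp_area_5_1(w: np.ndarray, s: np.ndarray) -> float:
    n5 = int(np.floor(len(s) / 5.0))
    dw = w[1] - w[0]
    return float(np.sum(s[:n5]) * dw)


def _sp_centroid(w: np.ndarray, s: np.ndarray) -> float:
    cs = np.cumsum(s)
    half = cs[-1] / 2.0
    i = int(np.searchsorted(cs, half))
    return float(w[min(i, len(w) - 1)])


def _fluct_anal(z: np.ndarray, how: str, n_tau: int = 50) -> float:
    """Two-regime log-log fluctuation analysis; proportion in first regime.

    ``how`` = "rsrange" (linear fit then range of residual per window) or
    "dfa" (linear detrend then rms per window, 50%-overlapping windows).
    """
    y = np.cumsum(z)
    n = len(y)
    taus = np.unique(
        np.round(np.exp(np.linspace(np.log(5), np.log(n / 2), n_tau))).astype(int)
    )
    taus = taus[taus >= 5]
    fs_ = []
    kept = []
    for tau in taus:
        starts = (
            range(0, n - tau + 1, max(tau // 2, 1)) if how == "dfa" else range(0, n - tau + 1, tau)
        )
        t = np.arange(tau, dtype=float)
        vals = []
        for s0 in starts:
            seg = y[s0 : s0 + tau]
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            if how == "rsrange":
                vals.append(resid.max() - resid.min())
            else:
                vals.append(np.sqrt(np.mean(resid**2)))
        v = float(np.mean(vals))
        if v > 0:
            fs_.append(v)
            kept.append(tau)
    if len(kept) < 12:
        return np.nan
    lt = np.log(np.asarray(kept, dtype=float))
    lf = np.log(np.asarray(fs_))
    # choose the split minimizing the summed squared error of two lines
    best_sse, best_k = np.inf, None
    for k in range(6, len(lt) - 5):
        sse = 0.0
        for sl in (slice(0, k), slice(k, len(lt))):
            c = np.polyfit(lt[sl], lf[sl], 1)
            sse += float(np.sum((lf[sl] - np.polyval(c, lt[sl])) ** 2))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return float(best_k / len(lt))


def _motif_three_quantile_hh(z: np.ndarray) -> float:
    """Shannon entropy (nats) of successive pairs of 3 equiprobable symbols."""
    q = np.quantile(z, [1 / 3, 2 / 3])
    sym = np.digitize(z, q)
    pairs = sym[:-1] * 3 + sym[1:]
    counts = np.bincount(pairs, minlength=9).astype(float)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def catch22_features(x: np.ndarray) -> np.ndarray:
    """All 22 descriptors, in :data:`CATCH22_NAMES` order.

    Zero-variance or too-short (< 32 samples) input returns a NaN vector of
    length 22 (never raises).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input must be a 1-d signal vector")
    if x.size < 32 or not np.isfinite(x).all() or _is_constant(x):
        return np.full(22, np.nan)
    z = _zscore(x)
    ac = _autocorr(z)
    w, s = _welch_rect(z)

    return np.array(
        [
            _histogram_mode(z, 5),
            _histogram_mode(z, 10),
            _f1ecac(ac),
            _first_min_ac(ac),
            _histogram_ami_even(z),
            _trev(z),
            _pnn40(z),
            float(_longest_stretch(z > z.mean())),
            _transition_matrix_3ac_sumdiagcov(z, ac),
            _periodicity_wang(z),
            _embed2_dist_expfit_meandiff(z, ac),
            _ami_gaussian_fmmi(z),
            _tauresrat(z, ac),
            _outlier_include_mdrmd(z, +1),
            _outlier_include_mdrmd(z, -1),
            _sp_area_5_1(w, s),
            float(_longest_stretch(np.diff(z) < 0)),
            _motif_three_quantile_hh(z),
            _fluct_anal(z, "rsrange"),
            _fluct_anal(z, "dfa"),
            _sp_centroid(w, s),
            _mean3_stderr(z),
        ]
    )
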