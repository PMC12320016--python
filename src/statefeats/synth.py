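"""Synthetic multi-subject, four-state epoched M/EEG-like signals.

The generative model is additive: a 1/f^chi power-law background with a
state-dependent exponent, state-dependent narrow-band oscillations (possibly
bursting), a slow baseline drift realized as a per-epoch constant offset
drawn from a random walk across the epoch sequence, and i.i.d. Gaussian
sensor noise. These are exactly the signal properties the downstream feature
sets measure: band power, 1/f slope and offset, variance, baseline shifts.

Default state presets encode the canonical resting/task contrasts: alpha
power is stronger with eyes closed (EC) than eyes open (EO), and broadband
gamma is stronger under visual stimulation (VS) than in the pre-stimulus
baseline (BSL), with VS also showing a flattened aperiodic slope (a
correlate of increased cortical excitation).

All randomness is funneled through ``numpy.random.SeedSequence`` streams
derived from a single master seed; an identical configuration reproduces a
bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

STATES: tuple[str, ...] = ("EC", "EO", "BSL", "VS")

__all__ = [
    "STATES",
    "Oscillation",
    "StateParams",
    "CohortConfig",
    "EpochedRecording",
    "default_presets",
    "make_powerlaw_noise",
    "synthesize_state_epoch",
    "generate_cohort",
]


@dataclass(frozen=True)
class Oscillation:
    """A narrow-band sinusoidal component.

    ``burst_fraction`` is the fraction of the epoch during which the
    oscillation is "on": 1.0 means sustained, values below 1 gate the
    sinusoid with a rectangular envelope of that duty cycle placed uniformly
    at random, 0 removes the component entirely.
    """

    center_freq: float
    amplitude: float
    burst_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.burst_fraction <= 1.0):
            raise ValueError("burst_fraction must lie in [0, 1]")
        if self.center_freq <= 0 or self.amplitude < 0:
            raise ValueError("center_freq must be > 0 and amplitude >= 0")


@dataclass(frozen=True)
class StateParams:
    state_label: str
    aperiodic_exponent: float
    aperiodic_scale: float = 1.0
    oscillations: tuple[Oscillation, ...] = ()
    drift_amplitude: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.state_label not in STATES:
            raise ValueError(f"unknown state label {self.state_label!r}")
        if not np.isfinite(self.aperiodic_exponent) or self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be finite and >= 0")
        if self.aperiodic_scale <= 0:
            raise ValueError("aperiodic_scale must be > 0")
        if self.drift_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("drift_amplitude and noise_sd must be >= 0")

    def validate_against_fs(self, fs: float) -> None:
        for osc in self.oscillations:
            if osc.center_freq >= fs / 2:
                raise ValueError(
                    f"oscillation at {osc.center_freq} Hz is not strictly "
                    f"below the Nyquist frequency {fs / 2} Hz"
                )


def default_presets() -> dict[str, StateParams]:
    """Per-state generative presets.

    Calibrated to reproduce the qualitative orderings of the real
    conditions (alpha EC > EO, gamma VS > BSL, flatter slope under
    stimulation), not any real-data effect magnitude.
    """
    return {
        "EC": StateParams(
            "EC",
            aperiodic_exponent=1.5,
            aperiodic_scale=5.0,
            oscillations=(Oscillation(10.0, 1.2, 0.8),),
            drift_amplitude=0.6,
            noise_sd=0.2,
        ),
        "EO": StateParams(
            "EO",
            aperiodic_exponent=1.3,
            aperiodic_scale=5.0,
            oscillations=(Oscillation(10.0, 0.45, 0.8),),
            drift_amplitude=0.25,
            noise_sd=0.2,
        ),
        "BSL": StateParams(
            "BSL",
            aperiodic_exponent=1.4,
            aperiodic_scale=5.0,
            oscillations=(Oscillation(10.0, 0.8, 0.8), Oscillation(60.0, 0.1, 0.7)),
            drift_amplitude=0.35,
            noise_sd=0.2,
        ),
        "VS": StateParams(
            "VS",
            aperiodic_exponent=1.15,
            aperiodic_scale=5.0,
            oscillations=(Oscillation(10.0, 0.55, 0.8), Oscillation(60.0, 0.45, 0.9)),
            drift_amplitude=0.35,
            noise_sd=0.2,
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 5
    n_epochs_per_state: int = 10
    epoch_len_s: float = 1.0
    fs: float = 256.0
    n_spatial_units: int = 4
    subject_sd: float = 0.15
    master_seed: int = 0

    def __post_init__(self) -> None:
        n = self.epoch_len_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_len_s * fs must be an integer sample count")
        if self.n_subjects < 1 or self.n_epochs_per_state < 1 or self.n_spatial_units < 1:
            raise ValueError("counts must be >= 1")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len_s * self.fs))


@dataclass
class EpochedRecording:
    """One subject's labeled 1 s epochs over spatial units."""

    subject_id: str
    epochs: np.ndarray  # [n_epochs, n_spatial_units, n_samples]
    state_labels: np.ndarray  # [n_epochs] of str
    fs: float
    unit_names: list[str]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.state_labels = np.asarray(self.state_labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be [n_epochs, n_units, n_samples]")
        if len(self.state_labels) != self.epochs.shape[0]:
            raise ValueError("state_labels length must equal n_epochs")
        unknown = set(map(str, self.state_labels)) - set(STATES)
        if unknown:
            raise ValueError(f"unknown state labels: {sorted(unknown)}")
        if len(self.unit_names) != self.epochs.shape[1]:
            raise ValueError("unit_names length must equal n_spatial_units")
        if np.isnan(self.epochs).any():
            raise ValueError("epochs contain NaN at construction time")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def make_powerlaw_noise(exponent: float, n_samples: int, fs: float, seed) -> np.ndarray:
    """Zero-mean noise with expected power spectrum P(f) ~ f**(-exponent).

    White Gaussian noise is transformed to the frequency domain, its
    spectral amplitudes are shaped by f**(-exponent/2) (DC is zeroed), and
    the result is transformed back. Deterministic given ``seed``.
    """
    if not np.isfinite(exponent) or exponent < 0:
        raise ValueError("exponent must be finite and >= 0")
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    rng = _rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[0] = 0.0
    spec[1:] = spec[1:] * freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_samples)
    return x - x.mean()


def synthesize_state_epoch(
    params: StateParams,
    fs: float,
    n_samples: int,
    seed,
    drift_value: float | None = None,
) -> np.ndarray:
    """One epoch: power-law background + oscillations + drift offset + noise.

    ``drift_value`` lets a caller (e.g. :func:`generate_cohort`) supply the
    slow-drift offset from a random walk over the epoch sequence; when None
    a single Gaussian draw of sd ``drift_amplitude`` is used.
    """
    params.validate_against_fs(fs)
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) else seed
    bg_seed, osc_seed, drift_seed, noise_seed = ss.spawn(4)
    rng_osc = _rng(osc_seed)

    t = np.arange(n_samples) / fs
    x = params.aperiodic_scale * make_powerlaw_noise(
        params.aperiodic_exponent, n_samples, fs, bg_seed
    )

    for osc in params.oscillations:
        if osc.amplitude == 0 or osc.burst_fraction == 0:
            # draws kept so the stream layout is independent of amplitudes
            rng_osc.uniform(0, 2 * np.pi)
            rng_osc.uniform()
            continue
        phase = rng_osc.uniform(0, 2 * np.pi)
        onset_frac = rng_osc.uniform()
        tone = osc.amplitude * np.sin(2 * np.pi * osc.center_freq * t + phase)
        if osc.burst_fraction < 1.0:
            burst_len = int(round(osc.burst_fraction * n_samples))
            onset = int(round(onset_frac * (n_samples - burst_len)))
            env = np.zeros(n_samples)
            env[onset : onset + burst_len] = 1.0
            tone = tone * env
        x = x + tone

    if drift_value is None:
        drift_value = params.drift_amplitude * _rng(drift_seed).standard_normal()
    x = x + drift_value

    if params.noise_sd > 0:
        x = x + params.noise_sd * _rng(noise_seed).standard_normal(n_samples)
    return x


def _jitter_params(params: StateParams, sd: float, rng: np.random.Generator) -> StateParams:
    """Multiplicative log-normal jitter of all positive magnitudes."""
    if sd == 0:
        # keep the stream layout identical regardless of sd
        rng.standard_normal(4 + 2 * len(params.oscillations))
        return params
    g = lambda: float(np.exp(sd * rng.standard_normal()))
    oscs = tuple(
        replace(o, center_freq=o.center_freq * float(np.exp(0.2 * sd * rng.standard_normal())),
                amplitude=o.amplitude * g())
        for o in params.oscillations
    )
    return replace(
        params,
        aperiodic_exponent=params.aperiodic_exponent * g(),
        aperiodic_scale=params.aperiodic_scale * g(),
        drift_amplitude=params.drift_amplitude * g(),
        noise_sd=params.noise_sd * g(),
        oscillations=oscs,
    )


def generate_cohort(
    config: CohortConfig, presets: dict[str, StateParams] | None = None
) -> list[EpochedRecording]:
    """One EpochedRecording per subject.

    Per-subject parameters are the presets jittered multiplicatively by
    ``subject_sd`` using a subject-specific stream. Epochs for each state are
    laid out in contiguous temporal order (epoch index = time order), so the
    contiguous-fold logic downstream is meaningful, and the drift offset
    follows a random walk across that order.
    """
    if presets is None:
        presets = default_presets()
    missing = set(STATES) - set(presets)
    if missing:
        raise ValueError(f"missing state presets: {sorted(missing)}")

    master = np.random.SeedSequence(config.master_seed)
    subject_streams = master.spawn(config.n_subjects)
    recordings = []
    n = config.n_samples

    for si, sub_ss in enumerate(subject_streams):
        jitter_ss, epochs_ss = sub_ss.spawn(2)
        rng_j = _rng(jitter_ss)
        sub_params = {s: _jitter_params(presets[s], config.subject_sd, rng_j) for s in STATES}

        n_ep = len(STATES) * config.n_epochs_per_state
        epochs = np.empty((n_ep, config.n_spatial_units, n))
        labels = np.empty(n_ep, dtype=object)
        unit_streams = epochs_ss.spawn(config.n_spatial_units)

        for ui, unit_ss in enumerate(unit_streams):
            ep_i = 0
            state_streams = unit_ss.spawn(len(STATES))
            for state, state_ss in zip(STATES, state_streams):
                p = sub_params[state]
                drift_ss, *epoch_ss = state_ss.spawn(config.n_epochs_per_state + 1)
                # slow random walk across the contiguous epoch block
                steps = _rng(drift_ss).standard_normal(config.n_epochs_per_state)
                walk = np.cumsum(steps) / np.sqrt(max(config.n_epochs_per_state, 1))
                drifts = p.drift_amplitude * walk
                for k, e_ss in enumerate(epoch_ss):
                    epochs[ep_i, ui] = synthesize_state_epoch(
                        p, config.fs, n, e_ss, drift_value=float(drifts[k])
                    )
                    labels[ep_i] = state
                    ep_i += 1

        recordings.append(
            EpochedRecording(
                subject_id=f"sub-{si + 1:02d}",
                epochs=epochs,
                state_labels=np.array([str(l) for l in labels]),
                fs=config.fs,
                unit_names=[f"unit-{u + 1:02d}" for u in range(config.n_spatial_units)],
            )
        )
    return recordings
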