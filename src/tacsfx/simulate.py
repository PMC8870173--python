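"""Synthetic data generators for the tACS after-effect analysis pipeline.

Three generators mirror the three data streams the analysis consumes:

* :func:`generate_eeg` — multichannel resting EEG (1/f background, narrow-band
  alpha/beta oscillations, blink transients) sampled at 1 kHz on the
  five-electrode motor hotspot layout (HS, LA, MA, LP, MP).
* :func:`generate_mep_series` — trial series of peak-to-peak motor evoked
  potential (MEP) amplitudes drawn from the local linear trend state-space
  model (random-walk level and slope plus observation noise), with optional
  multiplicative outlier contamination.
* :func:`generate_field_table` — per-subject, per-montage ROI-averaged
  electric-field values (mV/m) with group-level means and dispersions shaped
  like the seven-montage simulation table, coupled within subject through a
  Gaussian copula (the same head anatomy underlies every montage).

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EegSimConfig",
    "MepSimConfig",
    "FieldSimConfig",
    "EegRecording",
    "MepSeries",
    "generate_eeg",
    "generate_mep_series",
    "generate_field_table",
    "DEFAULT_MONTAGE_MEANS",
    "DEFAULT_MONTAGE_RSDS",
    "default_field_config",
]

#: Standard five-electrode layout around the FDI hotspot: the hotspot itself
#: plus lateral/medial anterior and lateral/medial posterior sites 2.5 cm away.
DEFAULT_CHANNELS = ("HS", "LA", "MA", "LP", "MP")

#: Relative blink amplitude per channel: ocular artifacts project most
#: strongly onto anterior sites.
_BLINK_GAIN = {"LA": 1.0, "MA": 1.0, "HS": 0.6, "LP": 0.3, "MP": 0.3}

#: Group-level ROI means (mV/m) of the normal field component for the seven
#: 10-20-system montages evaluated in the planning simulation.
DEFAULT_MONTAGE_MEANS: dict[str, float] = {
    "C1-Pz": 79.0,
    "FC1-Pz": 107.0,
    "FC3-Pz": 74.0,
    "C3-Pz": 58.0,
    "Cz-CP1": 120.0,
    "C1-CPz": 65.0,
    "C3-CPz": 59.0,
}

#: Corresponding relative standard deviations across subjects (percent).
DEFAULT_MONTAGE_RSDS: dict[str, float] = {
    "C1-Pz": 141.0,
    "FC1-Pz": 40.0,
    "FC3-Pz": 77.0,
    "C3-Pz": 56.0,
    "Cz-CP1": 38.0,
    "C1-CPz": 168.0,
    "C3-CPz": 58.0,
}


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EegSimConfig:
    """Parameters of the synthetic EEG generator.

    Parameters
    ----------
    duration_s : float
        Recording length in seconds (baseline blocks are 180 s).
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Electrode labels; defaults to the five-channel hotspot layout.
    background_exponent : float
        Spectral slope of the 1/f background (power ∝ 1/f**exponent).
    background_rms_uv : float
        RMS amplitude of the background noise per channel, μV.
    band_components : sequence of (freq_hz, amplitude_uv, phase_rad)
        Sinusoidal oscillatory components added to every channel.
    blink_rate_per_min : float
        Mean Poisson rate of blink artifacts.
    blink_amplitude_uv : float
        Peak amplitude of a blink transient on anterior channels.
    shared_fraction : float
        Fraction (0..1) of background variance that is common to all
        channels; the rest is channel-independent.
    seed : int
        RNG seed; identical config + seed gives identical output.
    """

    duration_s: float = 180.0
    fs: float = 1000.0
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    background_exponent: float = 1.0
    background_rms_uv: float = 10.0
    band_components: Sequence[tuple[float, float, float]] = (
        (10.0, 5.0, 0.0),
        (20.0, 3.0, 0.0),
    )
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 150.0
    shared_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if len(self.channel_labels) < 1:
            raise ConfigurationError("need at least one channel")
        for f, _, _ in self.band_components:
            if self.fs <= 2 * f:
                raise ConfigurationError(
                    f"fs={self.fs} violates Nyquist for component at {f} Hz"
                )
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if self.blink_rate_per_min < 0 or self.blink_amplitude_uv < 0:
            raise ConfigurationError("blink parameters must be nonnegative")


@dataclass(frozen=True)
class MepSimConfig:
    """Parameters of the MEP trial-series generator (local linear trend).

    The observation at trial t is ``y_t = mu_t + eps_t`` with
    ``mu_{t+1} = mu_t + nu_t + xi_t`` and ``nu_{t+1} = nu_t + zeta_t``.
    Variances are in μV² (level/obs) and (μV/trial)² (slope).
    """

    n_trials: int = 20
    initial_level: float = 500.0
    initial_slope: float = 0.0
    var_obs: float = 2500.0
    var_level: float = 25.0
    var_slope: float = 0.25
    outlier_prob: float = 0.0
    outlier_scale: float = 3.0
    condition: str = "unconditioned"
    phase: str = "pre"
    session: str = "sham"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ConfigurationError("n_trials must be >= 2")
        if min(self.var_obs, self.var_level, self.var_slope) < 0:
            raise ConfigurationError("variances must be nonnegative")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ConfigurationError("outlier_prob must lie in [0, 1]")


@dataclass(frozen=True)
class FieldSimConfig:
    """Parameters of the subject × montage electric-field table generator.

    ``montage_means`` / ``montage_sds`` give the target group mean and SD
    (mV/m) of the ROI-averaged normal field component per montage.
    ``within_subject_corr`` is the Gaussian-copula correlation between
    montages within one subject: the same head anatomy produces every
    montage's field, so values co-vary strongly across montages.
    """

    n_subjects: int = 18
    montage_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MONTAGE_MEANS)
    )
    montage_sds: Mapping[str, float] = field(
        default_factory=lambda: {
            m: DEFAULT_MONTAGE_MEANS[m] * DEFAULT_MONTAGE_RSDS[m] / 100.0
            for m in DEFAULT_MONTAGE_MEANS
        }
    )
    within_subject_corr: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if set(self.montage_means) != set(self.montage_sds):
            raise ConfigurationError("montage label sets of means and sds differ")
        if any(s < 0 for s in self.montage_sds.values()):
            raise ConfigurationError("montage sds must be nonnegative")
        if any(m <= 0 for m in self.montage_means.values()):
            raise ConfigurationError("montage means must be positive")
        if not 0.0 <= self.within_subject_corr <= 1.0:
            raise ConfigurationError("within_subject_corr must lie in [0, 1]")


def default_field_config(seed: int = 0, n_subjects: int = 18) -> FieldSimConfig:
    """Field config with the seven-montage group means/RSDs of the planning study."""
    return FieldSimConfig(n_subjects=n_subjects, seed=seed)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class EegRecording:
    """A multichannel EEG recording: ``data`` is channels × samples, μV."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV dialect: one column per channel."""
        return pd.DataFrame(self.data.T, columns=list(self.channel_labels))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, fs: float) -> "EegRecording":
        return cls(
            data=frame.to_numpy(dtype=float).T,
            fs=float(fs),
            channel_labels=tuple(map(str, frame.columns)),
        )


@dataclass
class MepSeries:
    """Ordered MEP trial amplitudes with condition/phase/session labels.

    ``level`` and ``slope`` hold the true latent states when the series was
    simulated (None for real data); they make state-recovery tests possible.
    """

    trial: np.ndarray  # 1-based trial index
    amplitude: np.ndarray  # peak-to-peak, μV
    condition: str = "unconditioned"
    phase: str = "pre"
    session: str = "sham"
    level: np.ndarray | None = None
    slope: np.ndarray | None = None
    outlier_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trial = np.asarray(self.trial, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.trial.shape != self.amplitude.shape:
            raise ValueError("trial and amplitude must have equal length")
        if np.any(np.diff(self.trial) <= 0):
            raise ValueError("trial indices must be strictly increasing")

    def __len__(self) -> int:
        return self.amplitude.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "amplitude_uv": self.amplitude,
                "condition": self.condition,
                "phase": self.phase,
                "session": self.session,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MepSeries":
        first = frame.iloc[0]
        return cls(
            trial=frame["trial"].to_numpy(),
            amplitude=frame["amplitude_uv"].to_numpy(),
            condition=str(first.get("condition", "unconditioned")),
            phase=str(first.get("phase", "pre")),
            session=str(first.get("session", "sham")),
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float
) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectral density ∝ 1/f**exponent.

    White noise is shaped in the frequency domain; frequencies below 1 Hz are
    held at the 1 Hz gain (DC removed) so the variance stays finite.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs)
    above = freqs >= 1.0
    gain[above] = freqs[above] ** (-exponent / 2.0)
    gain[~above] = 1.0
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def generate_eeg(config: EegSimConfig) -> EegRecording:
    """Simulate a multichannel EEG recording.

    Each channel is the sum of a 1/f-shaped Gaussian background (a mixture of
    a source shared across channels and channel-specific noise), the
    configured sinusoidal band components, and blink transients (400 ms
    half-sine pulses at Poisson times, anterior-weighted).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    if n < 1:
        raise ConfigurationError("recording would contain no samples")
    n_ch = len(config.channel_labels)
    t = np.arange(n) / config.fs

    data = np.zeros((n_ch, n))
    if config.background_rms_uv > 0:
        shared = _one_over_f_noise(rng, n, config.fs, config.background_exponent)
        w_shared = np.sqrt(config.shared_fraction)
        w_indep = np.sqrt(1.0 - config.shared_fraction)
        for c in range(n_ch):
            indep = _one_over_f_noise(rng, n, config.fs, config.background_exponent)
            data[c] = config.background_rms_uv * (w_shared * shared + w_indep * indep)

    for freq, amp, phase in config.band_components:
        if amp:
            data += amp * np.sin(2 * np.pi * freq * t + phase)[None, :]

    if config.blink_rate_per_min > 0 and config.blink_amplitude_uv > 0:
        n_blinks = rng.poisson(config.blink_rate_per_min * config.duration_s / 60.0)
        blink_len = int(round(0.4 * config.fs))  # 400 ms half-sine
        pulse = np.sin(np.pi * np.arange(blink_len) / blink_len)
        starts = rng.integers(0, max(n - blink_len, 1), size=n_blinks)
        gains = np.array(
            [_BLINK_GAIN.get(lbl, 0.5) for lbl in config.channel_labels]
        )
        for s in starts:
            stop = min(s + blink_len, n)
            data[:, s:stop] += (
                config.blink_amplitude_uv * gains[:, None] * pulse[: stop - s][None, :]
            )

    return EegRecording(
        data=data, fs=config.fs, channel_labels=tuple(config.channel_labels)
    )


def generate_mep_series(config: MepSimConfig) -> MepSeries:
    """Simulate an MEP amplitude series from the local linear trend model.

    Level and slope evolve as Gaussian random walks; each observation adds
    independent Gaussian noise. With probability ``outlier_prob`` a trial's
    observed amplitude is multiplied by ``outlier_scale`` (the latent states
    are untouched), emulating the occasional aberrant evoked response.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    level = np.empty(n)
    slope = np.empty(n)
    level[0] = config.initial_level
    slope[0] = config.initial_slope
    sd_level = np.sqrt(config.var_level)
    sd_slope = np.sqrt(config.var_slope)
    for tt in range(n - 1):
        level[tt + 1] = level[tt] + slope[tt] + sd_level * rng.standard_normal()
        slope[tt + 1] = slope[tt] + sd_slope * rng.standard_normal()
    y = level + np.sqrt(config.var_obs) * rng.standard_normal(n)
    outliers = rng.random(n) < config.outlier_prob
    y = np.where(outliers, y * config.outlier_scale, y)
    return MepSeries(
        trial=np.arange(1, n + 1),
        amplitude=y,
        condition=config.condition,
        phase=config.phase,
        session=config.session,
        level=level,
        slope=slope,
        outlier_mask=outliers,
    )


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Shape/scale of a gamma distribution with the given mean and SD."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def generate_field_table(config: FieldSimConfig) -> pd.DataFrame:
    """Simulate a subject × montage ROI-averaged electric-field table.

    Margins are gamma distributions moment-matched to each montage's target
    (mean, sd) — strictly nonnegative and able to represent relative standard
    deviations above 100%, which the most variable montages show. Montages
    are coupled within subject by a Gaussian copula with correlation
    ``within_subject_corr``: one subject's anatomy scales all montages.

    Returns a long-format DataFrame with columns
    ``subject, montage, efield_mvpm``.
    """
    rng = np.random.default_rng(config.seed)
    montages = list(config.montage_means)
    n_s, n_m = config.n_subjects, len(montages)
    rho = config.within_subject_corr
    common = rng.standard_normal(n_s)
    specific = rng.standard_normal((n_s, n_m))
    z = np.sqrt(rho) * common[:, None] + np.sqrt(1.0 - rho) * specific
    u = sps.norm.cdf(z)

    values = np.empty((n_s, n_m))
    for j, m in enumerate(montages):
        mu, sd = config.montage_means[m], config.montage_sds[m]
        if sd == 0:
            values[:, j] = mu
        else:
            shape, scale = _gamma_params(mu, sd)
            values[:, j] = sps.gamma.ppf(u[:, j], a=shape, scale=scale)

    records = [
        {"subject": f"S{i + 1:02d}", "montage": m, "efield_mvpm": values[i, j]}
        for i in range(n_s)
        for j, m in enumerate(montages)
    ]
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# file I/O for the CSV dialects
# ---------------------------------------------------------------------------


def write_eeg_csv(recording: EegRecording, path, sidecar: dict | None = None) -> None:
    """Write the wide EEG CSV plus a JSON sidecar holding fs and metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    recording.to_frame().to_csv(path, index=False)
    meta = {"fs": recording.fs, "channel_labels": list(recording.channel_labels)}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_eeg_csv(path) -> EegRecording:
    """Read the wide EEG CSV dialect; fs comes from the JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    frame = pd.read_csv(path)
    rec = EegRecording.from_frame(frame, fs=meta["fs"])
    return rec


def read_eeg_edf(path) -> EegRecording:
    """Read an EDF recording into an :class:`EegRecording` (signals in μV).

    Requires :mod:`mne`; EDF stores physical units per channel, which mne
    converts to volts — rescaled to μV here.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF files requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EegRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def config_to_dict(config) -> dict:
    """Round-trippable plain-dict form of any simulation config."""
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
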