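"""EEG band-power quantification: epoching, artifact rejection, windowed
power spectra, log-power aggregation, and baseline-normalized change (ERS/ERD).

The processing chain follows the standard resting-EEG protocol for
stimulation after-effect studies: the recording is split into non-overlapping
1 s epochs; epochs containing large-amplitude artifacts are discarded; a Hann
window and FFT give per-epoch power at 1 Hz resolution from 0 to 40 Hz; power
is log-transformed and averaged over retained epochs and electrodes; band
power is the mean log power over the alpha (10 ± 1 Hz) or beta (20 ± 1 Hz)
bins; and the post-stimulation value A is expressed relative to the baseline
mean R as NP = (A − R) / R. Positive NP is event-related synchronization
(ERS), negative is desynchronization (ERD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann

from .simulate import EegRecording

__all__ = [
    "EpochedEEG",
    "LogPowerSpectrum",
    "BandPower",
    "NormalizedChange",
    "split_epochs",
    "reject_artifacts",
    "epoch_power",
    "aggregate_log_power",
    "band_power",
    "normalize_change",
    "recording_log_spectrum",
    "BAND_BINS",
]

#: Frequency bins (Hz) per band: center ± 1 Hz, matching the two
#: stimulation frequencies.
BAND_BINS = {"alpha": (9, 10, 11), "beta": (19, 20, 21)}

MAX_FREQ_HZ = 40
LOG_FLOOR = 1e-12  # power floor (μV²) applied before the log transform


class InputError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass
class EpochedEEG:
    """Non-overlapping fixed-length epochs: epochs × channels × samples."""

    epochs: np.ndarray
    fs: float
    epoch_len_s: float
    channel_labels: tuple[str, ...]
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise InputError("epochs must be a 3-d array")
        if self.epochs.shape[2] != int(round(self.fs * self.epoch_len_s)):
            raise InputError("samples per epoch must equal fs × epoch_len_s")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.epochs.shape[0], dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())


@dataclass
class LogPowerSpectrum:
    """Log power at integer-Hz bins 0..40, averaged over epochs and channels."""

    freqs: np.ndarray
    logpower: np.ndarray
    n_epochs_used: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs)
        self.logpower = np.asarray(self.logpower, dtype=float)
        if self.freqs.size != MAX_FREQ_HZ + 1 or self.logpower.size != MAX_FREQ_HZ + 1:
            raise InputError("spectrum must have 41 bins at 0..40 Hz")
        if not np.allclose(np.diff(self.freqs), 1.0):
            raise InputError("bin spacing must be exactly 1 Hz")


@dataclass
class BandPower:
    band_label: str
    center: float
    halfwidth: float
    value: float


@dataclass
class NormalizedChange:
    """NP = (A − R)/R: relative change of a post-stimulation quantity A from
    its baseline mean R."""

    np_value: float
    a_value: float
    r_value: float


def split_epochs(
    recording: EegRecording | np.ndarray,
    fs: float | None = None,
    epoch_len_s: float = 1.0,
) -> EpochedEEG:
    """Split a recording into non-overlapping fixed-length epochs.

    Trailing samples that do not fill a complete epoch are discarded.
    A 3-min recording at 1 kHz thus yields exactly 180 one-second epochs.
    """
    if isinstance(recording, EegRecording):
        data, fs_, labels = recording.data, recording.fs, recording.channel_labels
    else:
        if fs is None:
            raise InputError("fs is required for a bare array")
        data = np.atleast_2d(np.asarray(recording, dtype=float))
        fs_, labels = float(fs), tuple(f"ch{i}" for i in range(data.shape[0]))
    n_per = int(round(fs_ * epoch_len_s))
    n_epochs = data.shape[1] // n_per
    if n_epochs < 1:
        raise InputError(
            f"recording of {data.shape[1]} samples is shorter than one "
            f"{epoch_len_s} s epoch at fs={fs_}"
        )
    trimmed = data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(data.shape[0], n_epochs, n_per).transpose(1, 0, 2)
    return EpochedEEG(
        epochs=epochs, fs=fs_, epoch_len_s=epoch_len_s, channel_labels=labels
    )


def reject_artifacts(epoched: EpochedEEG, amp_threshold: float = 100.0) -> EpochedEEG:
    """Flag epochs whose absolute amplitude exceeds the threshold on any channel.

    Deterministic surrogate for visual artifact screening: blinks and muscle
    bursts are large-amplitude events, so an epoch is rejected iff
    max |x| > ``amp_threshold`` (μV) on at least one channel. Returns a new
    ``EpochedEEG`` with an updated ``kept_mask``; raises if nothing survives.
    """
    if amp_threshold <= 0:
        raise InputError("amp_threshold must be positive")
    peak = np.abs(epoched.epochs).max(axis=(1, 2))
    kept = epoched.kept_mask & (peak <= amp_threshold)
    if not kept.any():
        raise PipelineError(
            f"all {epoched.n_epochs} epochs exceed the {amp_threshold} μV "
            "artifact threshold"
        )
    return EpochedEEG(
        epochs=epoched.epochs,
        fs=epoched.fs,
        epoch_len_s=epoched.epoch_len_s,
        channel_labels=epoched.channel_labels,
        kept_mask=kept,
    )


def epoch_power(epoch: np.ndarray, fs: float) -> np.ndarray:
    """Hann-windowed power at integer-Hz bins 0..40 for one 1 s epoch.

    The epoch must contain exactly ``fs`` samples so the DFT bin spacing is
    1 Hz. Power is the squared modulus of the one-sided DFT of the windowed
    signal (no amplitude-correction factor: every epoch uses the same window,
    so powers are comparable and baseline normalization cancels the factor).
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise InputError("epoch_power expects a single-channel 1-d epoch")
    n = x.size
    if n != int(round(fs)):
        raise InputError(
            f"epoch of {n} samples does not give 1 Hz resolution at fs={fs}"
        )
    w = hann(n, sym=False)
    spec = np.fft.rfft(x * w)
    power = np.abs(spec[: MAX_FREQ_HZ + 1]) ** 2
    if power.size < MAX_FREQ_HZ + 1:
        raise InputError("fs too low to resolve 40 Hz")
    return power


def aggregate_log_power(
    epoched: EpochedEEG, log_floor: float = LOG_FLOOR
) -> LogPowerSpectrum:
    """Log-transform per-epoch/channel power and average over both.

    Natural log with a floor of ``log_floor`` μV² (zero-power bins occur for
    noise-free synthetic inputs). Averaging over retained epochs and over
    electrodes commutes, so the order is immaterial.
    """
    kept = np.flatnonzero(epoched.kept_mask)
    if kept.size == 0:
        raise PipelineError("no retained epochs to aggregate")
    powers = np.empty((kept.size, len(epoched.channel_labels), MAX_FREQ_HZ + 1))
    for i, e in enumerate(kept):
        for c in range(len(epoched.channel_labels)):
            powers[i, c] = epoch_power(epoched.epochs[e, c], epoched.fs)
    logp = np.log(np.maximum(powers, log_floor))
    return LogPowerSpectrum(
        freqs=np.arange(MAX_FREQ_HZ + 1),
        logpower=logp.mean(axis=(0, 1)),
        n_epochs_used=kept.size,
    )


def band_power(spectrum: LogPowerSpectrum, band_label: str) -> BandPower:
    """Mean log power over the band's three 1 Hz bins (center ± 1)."""
    try:
        bins = BAND_BINS[band_label]
    except KeyError:
        raise InputError(
            f"unknown band {band_label!r}; expected one of {sorted(BAND_BINS)}"
        ) from None
    value = float(np.mean([spectrum.logpower[b] for b in bins]))
    return BandPower(
        band_label=band_label, center=float(bins[1]), halfwidth=1.0, value=value
    )


def normalize_change(
    a_value: float, r_value: float, tolerance: float = 1e-6
) -> NormalizedChange:
    """Baseline-relative change NP = (A − R)/R.

    Raises when |R| ≤ tolerance — a baseline this close to zero makes the
    relative change meaningless.
    """
    if abs(r_value) <= tolerance:
        raise PipelineError(
            f"baseline {r_value!r} is within tolerance {tolerance} of zero"
        )
    return NormalizedChange(
        np_value=(a_value - r_value) / r_value,
        a_value=float(a_value),
        r_value=float(r_value),
    )


def recording_log_spectrum(
    recording: EegRecording,
    amp_threshold: float = 100.0,
    epoch_len_s: float = 1.0,
) -> LogPowerSpectrum:
    """Convenience chain: epoch → artifact-reject → aggregate log power."""
    epoched = split_epochs(recording, epoch_len_s=epoch_len_s)
    epoched = reject_artifacts(epoched, amp_threshold=amp_threshold)
    return aggregate_log_power(epoched)
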