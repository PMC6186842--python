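"""EEG band power and mu-suppression scoring.

The mu rhythm is an 8-13 Hz sensorimotor oscillation that desynchronises
(drops in power) during movement, motor imagery, or action observation.
The mu suppression score quantifies this drop relative to a rest
baseline:

    MSS = -(P_task - P_rest) / P_rest * 100

so a task-to-rest power ratio of 0.8 scores exactly 20.  A closed-loop
trainer triggers assistance when the score strictly exceeds a threshold
(20 by default), computed from the ipsilesional sensorimotor electrode
(C3 for left-hemisphere lesions, C4 for right).

Band power is a single Hann-tapered FFT periodogram over the whole
segment; a spectral bin contributes when its centre frequency falls in
the closed band interval.  Preprocessing is a zero-phase 4th-order
Butterworth band-pass (2-60 Hz) plus band-stop (48-52 Hz) for line
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "MONTAGE_16",
    "EpochedEEG",
    "MuSuppression",
    "preprocess",
    "band_power",
    "mu_suppression_score",
    "trigger_decision",
    "online_channel",
    "trial_mu_suppression",
]

#: The 16-electrode sensorimotor montage (international 10-20 extension).
MONTAGE_16 = (
    "C1", "C2", "C3", "C4", "C5", "C6", "Cz",
    "FC1", "FC2", "FC3", "FC4", "FCz",
    "CP1", "CP2", "CP3", "CP4",
)

MU_BAND = (8.0, 13.0)
DEFAULT_BANDPASS = (2.0, 60.0)
DEFAULT_NOTCH = (48.0, 52.0)


@dataclass
class EpochedEEG:
    """Paired task/rest segments per trial with channel labels.

    ``trials`` holds (task_segment, rest_segment) pairs, each a
    channels x samples array; the two segments of a trial have equal
    duration.  ``session_ids`` optionally tags each trial with its
    training-session index (used by the discriminant-rate pipeline).
    """

    channel_labels: tuple[str, ...]
    sampling_rate: float
    trials: list[tuple[np.ndarray, np.ndarray]]
    lesion_side: str  # "L" or "R"
    session_ids: list[int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n_ch = len(self.channel_labels)
        for i, (task, rest) in enumerate(self.trials):
            if task.shape[0] != n_ch or rest.shape[0] != n_ch:
                raise ValueError(f"trial {i}: channel count mismatch with labels")
            if task.shape[1] != rest.shape[1]:
                raise ValueError(f"trial {i}: task and rest segments differ in duration")
        if self.session_ids is not None and len(self.session_ids) != len(self.trials):
            raise ValueError("session_ids must align with trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in montage {self.channel_labels}"
            ) from None


@dataclass
class MuSuppression:
    """Mu power during task and rest, and the resulting suppression score."""

    p_task: float
    p_rest: float
    score: float = field(init=False)

    def __post_init__(self) -> None:
        if self.p_rest <= 0:
            raise ValueError("rest-period power must be positive")
        if self.p_task < 0:
            raise ValueError("task-period power must be non-negative")
        self.score = -(self.p_task - self.p_rest) / self.p_rest * 100.0


def preprocess(raw: np.ndarray, sampling_rate: float,
               bandpass: tuple[float, float] = DEFAULT_BANDPASS,
               notch: tuple[float, float] | None = DEFAULT_NOTCH) -> np.ndarray:
    """Zero-phase band-pass + band-stop filtering of a channels x samples array.

    4th-order Butterworth designs applied forward-backward (filtfilt).
    Raises if the segment is shorter than the filter warm-up (filtfilt's
    default padding length).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.isfinite(raw).all():
        raise ValueError("input contains non-finite samples")
    if sampling_rate < 128:
        raise ValueError("sampling rate must be at least 128 Hz")
    nyq = sampling_rate / 2.0
    if bandpass[1] >= nyq:
        raise ValueError(f"band-pass edge {bandpass[1]} Hz at or above Nyquist {nyq} Hz")

    sos_bp = signal.butter(4, bandpass, btype="bandpass", fs=sampling_rate, output="sos")
    out = _sosfiltfilt_checked(sos_bp, raw)
    if notch is not None:
        sos_bs = signal.butter(4, notch, btype="bandstop", fs=sampling_rate, output="sos")
        out = _sosfiltfilt_checked(sos_bs, out)
    return out


def _sosfiltfilt_checked(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"segment of {x.shape[-1]} samples shorter than filter warm-up ({padlen})"
        )
    return signal.sosfiltfilt(sos, x, axis=-1)


def band_power(segment: np.ndarray, band: tuple[float, float],
               sampling_rate: float, channels=None) -> float:
    """Mean spectral power in a frequency band, averaged over channels.

    A single Hann-tapered FFT is taken over the whole segment (no
    Welch averaging); the power spectrum is averaged across the bins
    whose centre frequency lies in the closed interval ``band``, then
    across the selected channels.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    f_lo, f_hi = band
    if not 0 < f_lo < f_hi:
        raise ValueError(f"invalid band {band}")
    nyq = sampling_rate / 2.0
    if f_hi > nyq:
        raise ValueError(f"band edge {f_hi} Hz beyond Nyquist {nyq} Hz")
    n = segment.shape[1]
    if n < sampling_rate / (f_hi - f_lo):
        raise ValueError("segment too short to resolve the requested band")

    if channels is not None:
        idx = np.asarray(channels, dtype=int)
        if idx.size == 0:
            raise ValueError("empty channel selection")
        segment = segment[idx]
    if segment.shape[0] == 0:
        raise ValueError("empty channel selection")

    window = signal.get_window("hann", n)
    spectrum = np.fft.rfft(segment * window, axis=1)
    # one-sided power spectrum normalised by the window energy
    power = (np.abs(spectrum) ** 2) / np.sum(window**2)
    power[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    if not in_band.any():
        raise ValueError(f"no FFT bins fall inside band {band}")
    return float(power[:, in_band].mean())


def mu_suppression_score(p_task: float, p_rest: float) -> MuSuppression:
    """Score = -(P_task - P_rest)/P_rest * 100; positive when power drops."""
    return MuSuppression(p_task=float(p_task), p_rest=float(p_rest))


def trigger_decision(mss, threshold: float = 20.0, mode: str = "eeg_guided",
                     success_rate: float = 0.8, rng=None) -> bool:
    """Decide whether the robot hand fires on this trial.

    ``eeg_guided`` fires iff the suppression score strictly exceeds the
    threshold; ``random`` (the sham arm) fires with probability
    ``success_rate`` regardless of the score and requires a seeded
    ``rng``.
    """
    score = mss.score if isinstance(mss, MuSuppression) else float(mss)
    if mode == "eeg_guided":
        return bool(score > threshold)
    if mode == "random":
        if rng is None:
            raise ValueError("random mode requires a seeded rng")
        rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        return bool(rng.random() < success_rate)
    raise ValueError(f"mode must be 'eeg_guided' or 'random', got {mode!r}")


def online_channel(lesion_side: str) -> str:
    """Ipsilesional sensorimotor electrode: C3 for left lesions, C4 for right."""
    side = str(lesion_side).upper()
    if side == "L":
        return "C3"
    if side == "R":
        return "C4"
    raise ValueError(f"lesion side must be 'L' or 'R', got {lesion_side!r}")


def trial_mu_suppression(epochs: EpochedEEG, band: tuple[float, float] = MU_BAND,
                         channel: str | None = None,
                         rest_baseline: str = "per_trial",
                         preprocessed: bool = False) -> list[MuSuppression]:
    """Per-trial mu suppression through the full online pipeline.

    Filters each segment, takes mu-band power on the ipsilesional online
    electrode (or an explicit ``channel``), and scores task against the
    rest baseline.  ``rest_baseline`` is ``"per_trial"`` (the rest
    segment of the same trial) or ``"running"`` (mean rest power over
    all trials so far, inclusive).
    """
    if rest_baseline not in ("per_trial", "running"):
        raise ValueError("rest_baseline must be 'per_trial' or 'running'")
    label = channel or online_channel(epochs.lesion_side)
    idx = [epochs.channel_index(label)]
    scores: list[MuSuppression] = []
    rest_history: list[float] = []
    for task, rest in epochs.trials:
        if not preprocessed:
            task = preprocess(task, epochs.sampling_rate)
            rest = preprocess(rest, epochs.sampling_rate)
        p_task = band_power(task, band, epochs.sampling_rate, channels=idx)
        p_rest = band_power(rest, band, epochs.sampling_rate, channels=idx)
        rest_history.append(p_rest)
        baseline = p_rest if rest_baseline == "per_trial" else float(np.mean(rest_history))
        scores.append(mu_suppression_score(p_task, baseline))
    return scores
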