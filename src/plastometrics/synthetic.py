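"""Synthetic EEG, BOLD and clinical-table generators.

Each generator is a pure function of a spec dataclass plus a seed, so
every analysis stage is testable end to end without any recorded data.

* EEG: a mu-band (~10 Hz) oscillator on every channel over 1/f
  background noise; on the designated "affected" channels the oscillator
  amplitude drops by sqrt(erd_ratio) during task segments, so the
  task/rest mu *power* ratio equals ``erd_ratio`` and the expected mu
  suppression score is analytic: (1 - erd_ratio) * 100.
* BOLD: a hidden Markov chain over K covariance states with geometric
  dwell times; "flexible" regions change their factor loadings between
  states (graded per region), stable regions keep one loading vector,
  giving controllable ground-truth temporal variability.
* Clinical: baseline scores ~ Normal, per-group change distributions at
  the two follow-ups, optional missingness at the 6-month endpoint,
  clipped to the 0-66 FMA-UE range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical import ClinicalTable, FMA_UE_MAX
from .spectral import EpochedEEG, MONTAGE_16

__all__ = [
    "EEGGenSpec",
    "BOLDGenSpec",
    "ClinicalGenSpec",
    "generate_eeg",
    "generate_bold",
    "generate_clinical",
]


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

#: Ipsilesional 7-channel set for a right-hemisphere lesion.
_RIGHT_SET = ("C2", "C4", "C6", "FC2", "FC4", "CP2", "CP4")


@dataclass
class EEGGenSpec:
    """Parameters of the task/rest EEG simulator.

    ``erd_ratio`` is the task-to-rest mu *power* ratio on the affected
    channels (1.0 = no desynchronisation); ``snr`` is the rest mu
    amplitude over the broadband noise standard deviation.
    """

    n_trials: int = 20
    rate_hz: float = 256.0
    task_s: float = 6.0
    rest_s: float = 6.0
    mu_freq_hz: float = 10.0
    rest_mu_amp: float = 1.0
    erd_ratio: float = 0.8
    affected_channels: tuple[str, ...] = _RIGHT_SET
    noise_exponent: float = 1.0
    snr: float = 10.0
    lesion_side: str = "R"
    n_sessions: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.erd_ratio <= 1:
            raise ValueError("erd_ratio must lie in (0, 1]")
        unknown = set(self.affected_channels) - set(MONTAGE_16)
        if unknown:
            raise ValueError(f"affected channels outside montage: {sorted(unknown)}")
        if self.n_trials < 1 or self.snr <= 0 or self.rest_mu_amp <= 0:
            raise ValueError("n_trials, snr and rest_mu_amp must be positive")


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, int],
                      rate_hz: float, exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    n = shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spectrum = (rng.standard_normal((shape[0], len(freqs)))
                + 1j * rng.standard_normal((shape[0], len(freqs)))) * scale
    noise = np.fft.irfft(spectrum, n=n, axis=1)
    sd = noise.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def generate_eeg(spec: EEGGenSpec) -> EpochedEEG:
    """Simulate paired task/rest trials with mu-band desynchronisation."""
    rng = np.random.default_rng(spec.seed)
    n_ch = len(MONTAGE_16)
    n_task = int(round(spec.task_s * spec.rate_hz))
    n_rest = int(round(spec.rest_s * spec.rate_hz))
    affected = np.array([c in spec.affected_channels for c in MONTAGE_16])
    task_amp = np.where(affected, spec.rest_mu_amp * np.sqrt(spec.erd_ratio),
                        spec.rest_mu_amp)
    noise_sd = spec.rest_mu_amp / spec.snr

    trials = []
    session_ids = []
    trials_per_session = max(1, spec.n_trials // spec.n_sessions)
    for trial in range(spec.n_trials):
        segs = []
        for amp, n_samp in ((task_amp, n_task), (np.full(n_ch, spec.rest_mu_amp), n_rest)):
            t = np.arange(n_samp) / spec.rate_hz
            phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
            osc = amp[:, None] * np.sin(2 * np.pi * spec.mu_freq_hz * t + phase)
            noise = noise_sd * _one_over_f_noise(
                rng, (n_ch, n_samp), spec.rate_hz, spec.noise_exponent
            )
            segs.append(osc + noise)
        trials.append((segs[0], segs[1]))
        session_ids.append(min(trial // trials_per_session, spec.n_sessions - 1))
    return EpochedEEG(
        channel_labels=MONTAGE_16,
        sampling_rate=spec.rate_hz,
        trials=trials,
        lesion_side=spec.lesion_side,
        session_ids=session_ids if spec.n_sessions > 1 else None,
    )


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------


@dataclass
class BOLDGenSpec:
    """Parameters of the covariance-state-switching BOLD simulator.

    ``n_states`` latent states with geometric dwell times (mean
    ``mean_dwell_tp`` time points).  Region correlations come from a
    low-rank factor model; the first ``n_flexible`` regions redraw their
    loadings per state with a graded mixing weight (so flexibility is
    heterogeneous across the flexible set), the rest keep a single
    loading vector across states.
    """

    n_regions: int = 84
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    n_states: int = 2
    mean_dwell_tp: float = 15.0
    n_flexible: int = 16
    n_factors: int = 3
    loading_scale: float = 1.2
    min_flex_weight: float = 0.6
    noise_sd: float = 0.4
    lesion_side: str = "R"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("need at least one state")
        if not 0 < self.n_flexible < self.n_regions:
            raise ValueError("n_flexible must lie strictly between 0 and n_regions")
        if self.mean_dwell_tp < 1 or self.noise_sd < 0:
            raise ValueError("invalid dwell time or noise level")

    @property
    def flexible_regions(self) -> np.ndarray:
        return np.arange(self.n_flexible)

    @property
    def stable_regions(self) -> np.ndarray:
        return np.arange(self.n_flexible, self.n_regions)


def _state_sequence(rng: np.random.Generator, T: int, K: int,
                    mean_dwell: float) -> np.ndarray:
    """Hidden state per time point; dwell ~ geometric, uniform jumps."""
    seq = np.empty(T, dtype=int)
    state = int(rng.integers(K))
    t = 0
    p_switch = 1.0 / mean_dwell
    while t < T:
        dwell = int(rng.geometric(p_switch))
        seq[t:t + dwell] = state
        t += dwell
        if K > 1:
            others = [s for s in range(K) if s != state]
            state = int(rng.choice(others))
    return seq


def generate_bold(spec: BOLDGenSpec) -> tuple:
    """Simulate state-switching BOLD series.

    Returns ``(RegionTimeSeries, flexible_region_indices, state_seq)``.
    Region labels are paired ``R001_L / R001_R`` style so the midline
    flip applies; flexible regions are spread over both hemispheres.
    """
    from .variability import RegionTimeSeries

    rng = np.random.default_rng(spec.seed)
    R, T, K, q = spec.n_regions, spec.n_timepoints, spec.n_states, spec.n_factors

    base = rng.standard_normal((R, q)) * spec.loading_scale
    loadings = np.stack([base.copy() for _ in range(K)])
    # graded flexibility: weight from min_flex_weight up to 1 across the set
    weights = np.linspace(spec.min_flex_weight, 1.0, spec.n_flexible)
    for s in range(1, K):
        alt = rng.standard_normal((spec.n_flexible, q)) * spec.loading_scale
        g = weights[:, None]
        loadings[s, :spec.n_flexible] = (1 - g) * base[:spec.n_flexible] + g * alt

    states = _state_sequence(rng, T, K, spec.mean_dwell_tp)
    factors = rng.standard_normal((T, q))
    noise = rng.standard_normal((R, T)) * spec.noise_sd
    data = np.empty((R, T))
    for t in range(T):
        data[:, t] = loadings[states[t]] @ factors[t] + noise[:, t]

    half = (R + 1) // 2
    labels = []
    for i in range(R):
        pair, hemi = (i, "L") if i < half else (i - half, "R")
        labels.append(f"R{pair:03d}_{hemi}")
    # an odd region count would leave one label unpaired; R is even by default
    ts = RegionTimeSeries(
        region_labels=tuple(labels),
        data=data,
        tr_seconds=spec.tr_seconds,
        subject_id="sim",
        session="pre",
        lesion_side=spec.lesion_side,
    )
    return ts, spec.flexible_regions, states


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------


@dataclass
class ClinicalGenSpec:
    """Parameters of the randomised two-arm clinical-score simulator.

    Change distributions are Normal per group and endpoint; the study
    conditions this emulates are 13 guided / 11 sham subjects with a
    24 +/- 8 baseline and a 6-month endpoint missing for two guided
    subjects.
    """

    n_guided: int = 13
    n_sham: int = 11
    baseline_mean: float = 24.0
    baseline_sd: float = 8.0
    guided_change_post: tuple[float, float] = (4.0, 4.0)  # (mean, sd)
    guided_change_6mo: tuple[float, float] = (4.0, 4.0)
    sham_change_post: tuple[float, float] = (1.0, 4.0)
    sham_change_6mo: tuple[float, float] = (1.0, 4.0)
    n_missing_6mo: dict = field(default_factory=lambda: {"guided": 2, "sham": 0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_guided < 1 or self.n_sham < 1:
            raise ValueError("both arms need at least one subject")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")


def generate_clinical(spec: ClinicalGenSpec) -> ClinicalTable:
    """Draw a randomised two-arm table with three time points."""
    rng = np.random.default_rng(spec.seed)

    def clip(scores: np.ndarray) -> np.ndarray:
        return np.clip(np.round(scores), 0, FMA_UE_MAX)

    rows = []
    sid = 1
    for group, n, chg_post, chg_6mo in (
        ("guided", spec.n_guided, spec.guided_change_post, spec.guided_change_6mo),
        ("sham", spec.n_sham, spec.sham_change_post, spec.sham_change_6mo),
    ):
        pre = clip(rng.normal(spec.baseline_mean, spec.baseline_sd, size=n))
        post = clip(pre + rng.normal(chg_post[0], chg_post[1], size=n))
        m6 = clip(pre + rng.normal(chg_6mo[0], chg_6mo[1], size=n))
        n_miss = int(spec.n_missing_6mo.get(group, 0))
        missing_idx = rng.choice(n, size=n_miss, replace=False) if n_miss else []
        for i in range(n):
            rows.append({
                "subject_id": f"S{sid}",
                "group": group,
                "lesion_side": rng.choice(["L", "R"]),
                "fma_pre": pre[i],
                "fma_post": post[i],
                "fma_6mo": np.nan if i in missing_idx else m6[i],
            })
            sid += 1
    return ClinicalTable(pd.DataFrame(rows))
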