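"""Temporal variability of dynamic functional connectivity.

A region-by-time BOLD matrix is partitioned into non-overlapping
windows; within each window an adjacency matrix of pairwise Pearson
correlations is formed.  Region k's connectivity profile in window i is
its adjacency row with the self-entry removed, and its temporal
variability is

    V_k = 1 - mean_{i < j} corr(profile_i(k), profile_j(k))

so V_k in [0, 2]: 0 when the region's network affiliation is frozen in
time, larger when it reconfigures.  To blunt the arbitrary choice of
window length, V is averaged across lengths 10, 12, ..., 30 time points
(20-60 s at TR = 2 s); a consistency diagnostic reports the correlation
of the per-region V vectors between lengths.

Group analyses flip left-lesion subjects' region values across the
midline so all lesions sit in the right hemisphere, aggregate regions
into six functional subnetworks, and contrast pre- vs post-intervention
V per region with a paired t-test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .clinical import paired_t

__all__ = [
    "DEFAULT_WINDOW_LENGTHS",
    "SUBNETWORKS",
    "RegionTimeSeries",
    "WindowedConnectivity",
    "VariabilityProfile",
    "TemporalVariability",
    "partition_windows",
    "regional_variability",
    "multiscale_variability",
    "windowlength_consistency",
    "flip_to_lesion_right",
    "subnetwork_aggregate",
    "prepost_region_contrast",
    "load_default_subnetworks",
]

DEFAULT_WINDOW_LENGTHS = tuple(range(10, 31, 2))
SUBNETWORKS = ("SMA", "ATT", "AUD", "VIS", "DMN", "SUB")


@dataclass
class RegionTimeSeries:
    """Region-mean BOLD series for one subject and session."""

    region_labels: tuple[str, ...]
    data: np.ndarray  # regions x time
    tr_seconds: float = 2.0
    subject_id: str = ""
    session: str = ""
    lesion_side: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a regions x time matrix")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.data.shape[0]} rows"
            )
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("missing time points are not allowed")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowedConnectivity:
    """Sequence of per-window region x region Pearson adjacency matrices."""

    window_length_tp: int
    windows: list[np.ndarray] = field(repr=False)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class VariabilityProfile:
    """Per-region temporal variability with optional subnetwork rollup."""

    region_labels: tuple[str, ...]
    values: np.ndarray
    window_lengths_used: tuple[int, ...]
    subnetwork_means: dict[str, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.region_labels), name="V")


def _window_correlation(block: np.ndarray) -> np.ndarray:
    """Pearson adjacency for one window; degenerate regions yield 0 rows."""
    sd = block.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.corrcoef(block)
    w = np.atleast_2d(w)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant region(s) in a window; "
            "their correlations set to 0",
            stacklevel=3,
        )
        w[degenerate, :] = 0.0
        w[:, degenerate] = 0.0
    np.fill_diagonal(w, 1.0)
    return np.clip(w, -1.0, 1.0)


def partition_windows(ts, window_length: int) -> WindowedConnectivity:
    """Cut the series into non-overlapping windows and correlate within each.

    Windows start at t = 0; a trailing remainder shorter than the window
    is discarded.  ``ts`` may be a RegionTimeSeries or a plain
    regions x time array.
    """
    data = ts.data if isinstance(ts, RegionTimeSeries) else np.asarray(ts, dtype=float)
    L = int(window_length)
    if L < 3:
        raise ValueError(f"window length must be >= 3 time points, got {L}")
    n_windows = data.shape[1] // L
    if n_windows < 2:
        raise ValueError(
            f"{data.shape[1]} time points give only {n_windows} window(s) of "
            f"length {L}; need at least 2"
        )
    windows = [
        _window_correlation(data[:, i * L:(i + 1) * L]) for i in range(n_windows)
    ]
    return WindowedConnectivity(window_length_tp=L, windows=windows)


def _profile_stack(wc: WindowedConnectivity) -> np.ndarray:
    """(regions, windows, regions-1): row k of each W with the self-entry cut."""
    W = np.stack(wc.windows)  # (n_windows, R, R)
    R = W.shape[1]
    mask = ~np.eye(R, dtype=bool)
    return np.stack([W[:, k, :][:, mask[k]] for k in range(R)])


def _pairwise_profile_corr_mean(profiles: np.ndarray) -> float:
    """Mean Pearson correlation over unordered window pairs for one region.

    ``profiles`` is (n_windows, p).  A zero-variance profile contributes
    0 to each of its pairs.
    """
    n_w = profiles.shape[0]
    sd = profiles.std(axis=1)
    degenerate = sd == 0
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(centered, axis=1)
    denom[degenerate] = 1.0
    unit = centered / denom[:, None]
    corr = unit @ unit.T
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    iu = np.triu_indices(n_w, k=1)
    if degenerate.any():
        warnings.warn(
            "zero-variance connectivity profile; pair correlations set to 0",
            stacklevel=3,
        )
    return float(np.clip(corr[iu], -1.0, 1.0).mean())


def regional_variability(wc: WindowedConnectivity, region: int | None = None):
    """V_k = 1 - mean pairwise profile correlation across windows.

    With ``region`` given returns that region's scalar V; otherwise the
    full per-region vector.
    """
    if wc.n_windows < 2:
        raise ValueError("need at least 2 windows")
    profiles = _profile_stack(wc)
    if region is not None:
        return 1.0 - _pairwise_profile_corr_mean(profiles[region])
    return np.array([1.0 - _pairwise_profile_corr_mean(p) for p in profiles])


def multiscale_variability(ts: RegionTimeSeries,
                           window_lengths=DEFAULT_WINDOW_LENGTHS,
                           subnetworks: dict[str, str] | None = None) -> VariabilityProfile:
    """Average V_k over a set of window lengths (equal weights)."""
    lengths = tuple(int(L) for L in window_lengths)
    if not lengths:
        raise ValueError("at least one window length required")
    bad = [L for L in lengths if L < 3 or ts.n_timepoints // L < 2]
    if bad:
        raise ValueError(
            f"window lengths {bad} unusable for {ts.n_timepoints} time points"
        )
    per_length = np.vstack([
        regional_variability(partition_windows(ts, L)) for L in lengths
    ])
    profile = VariabilityProfile(
        region_labels=ts.region_labels,
        values=per_length.mean(axis=0),
        window_lengths_used=lengths,
    )
    if subnetworks is not None:
        profile.subnetwork_means = subnetwork_aggregate(profile, subnetworks)
    return profile


def windowlength_consistency(ts: RegionTimeSeries,
                             window_lengths=DEFAULT_WINDOW_LENGTHS) -> pd.DataFrame:
    """Correlation of the per-region V vectors between window lengths."""
    lengths = tuple(int(L) for L in window_lengths)
    if len(lengths) < 2:
        raise ValueError("need at least 2 window lengths")
    vs = [regional_variability(partition_windows(ts, L)) for L in lengths]
    frame = pd.DataFrame(np.column_stack(vs), columns=list(range(len(lengths))))
    corr = frame.corr(method="pearson")
    corr.index = corr.columns = list(lengths)
    return corr


class TemporalVariability(BaseEstimator, TransformerMixin):
    """Transformer mapping BOLD series to per-region temporal variability.

    ``transform`` accepts one regions x time matrix (returning a
    (n_regions,) vector) or a stack of subjects (n_subjects, regions,
    time) returning (n_subjects, n_regions).  Stateless: ``fit`` only
    validates parameters, so the estimator drops into sklearn pipelines
    ahead of any group-level model.
    """

    def __init__(self, window_lengths=DEFAULT_WINDOW_LENGTHS):
        self.window_lengths = window_lengths

    def fit(self, X, y=None):
        lengths = tuple(int(L) for L in self.window_lengths)
        if not lengths or any(L < 3 for L in lengths):
            raise ValueError("window lengths must be >= 3 time points")
        self.window_lengths_ = lengths
        return self

    def transform(self, X):
        if not hasattr(self, "window_lengths_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        stack = X[None] if single else X
        out = np.vstack([
            np.vstack([
                regional_variability(partition_windows(subject, L))
                for L in self.window_lengths_
            ]).mean(axis=0)
            for subject in stack
        ])
        return out[0] if single else out


def _hemisphere_pairs(labels) -> dict[str, str]:
    """Map each lateralised label to its mirror (suffix or prefix L/R)."""
    pairs: dict[str, str] = {}
    labelset = set(labels)
    for label in labels:
        if label.endswith("_L"):
            mirror = label[:-2] + "_R"
        elif label.endswith("_R"):
            mirror = label[:-2] + "_L"
        elif label.startswith("L_"):
            mirror = "R_" + label[2:]
        elif label.startswith("R_"):
            mirror = "L_" + label[2:]
        else:
            raise ValueError(f"region label {label!r} carries no L/R marker")
        if mirror not in labelset:
            raise ValueError(f"region {label!r} has no contralateral partner {mirror!r}")
        pairs[label] = mirror
    return pairs


def flip_to_lesion_right(obj, lesion_side: str | None = None):
    """Mirror left-lesion subjects across the midline (L/R label swap).

    Works on a RegionTimeSeries or a VariabilityProfile; right-lesion
    input is returned unchanged.  Involutive on left-lesion input.
    """
    side = lesion_side or getattr(obj, "lesion_side", "")
    if str(side).upper() == "R":
        return obj
    if str(side).upper() != "L":
        raise ValueError(f"lesion side must be 'L' or 'R', got {side!r}")
    labels = obj.region_labels
    pairs = _hemisphere_pairs(labels)
    order = [labels.index(pairs[label]) for label in labels]
    if isinstance(obj, RegionTimeSeries):
        return RegionTimeSeries(
            region_labels=labels,
            data=obj.data[order],
            tr_seconds=obj.tr_seconds,
            subject_id=obj.subject_id,
            session=obj.session,
            lesion_side=obj.lesion_side,
        )
    if isinstance(obj, VariabilityProfile):
        return VariabilityProfile(
            region_labels=labels,
            values=obj.values[order],
            window_lengths_used=obj.window_lengths_used,
            subnetwork_means=dict(obj.subnetwork_means),
        )
    raise TypeError(f"cannot flip object of type {type(obj).__name__}")


def subnetwork_aggregate(profile: VariabilityProfile,
                         mapping: dict[str, str]) -> dict[str, float]:
    """Unweighted mean V per subnetwork; every region must be mapped."""
    unmapped = [r for r in profile.region_labels if r not in mapping]
    if unmapped:
        raise ValueError(f"regions missing from the subnetwork map: {unmapped}")
    series = profile.as_series()
    nets = pd.Series({r: mapping[r] for r in profile.region_labels})
    return series.groupby(nets).mean().to_dict()


def prepost_region_contrast(pre: np.ndarray, post: np.ndarray,
                            region_labels, alpha: float = 0.01,
                            correction: str | None = None) -> pd.DataFrame:
    """Per-region paired t-test of post vs pre variability.

    ``pre`` and ``post`` are (n_subjects, n_regions) with matched rows.
    Returns a DataFrame (t, p, significant) indexed by region.  By
    default p-values are uncorrected at ``alpha``; ``correction="bh"``
    applies Benjamini-Hochberg.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError(
            f"pre {pre.shape} and post {post.shape} must hold the same "
            "subjects and regions"
        )
    if pre.shape[1] != len(region_labels):
        raise ValueError("region_labels length mismatch")
    results = [paired_t(pre[:, k], post[:, k]) for k in range(pre.shape[1])]
    t_vals = np.array([r.statistic for r in results])
    p_vals = np.array([r.p_two_tailed for r in results])
    if correction is None:
        significant = p_vals < alpha
    elif correction == "bh":
        from statsmodels.stats.multitest import multipletests
        significant = multipletests(p_vals, alpha=alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return pd.DataFrame(
        {"t": t_vals, "p": p_vals, "significant": significant},
        index=list(region_labels),
    )


def load_default_subnetworks() -> dict[str, str]:
    """Bundled 84-region six-subnetwork map (AAL-style labels).

    A synthetic stand-in assembled from the AAL atlas naming convention
    and the usual functional groupings; it is NOT the study's own
    region list, which was never published in machine-readable form.
    """
    path = resources.files("plastometrics.data").joinpath("subnetworks.json")
    with path.open() as fh:
        return json.load(fh)
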