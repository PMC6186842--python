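"""Discriminant rate: band-power LDA separating motor imagery from rest.

The discriminant rate (DR) indexes how separable a subject's motor
imagery and resting EEG states are under a fixed linear classifier.
Four band powers — alpha (8-13 Hz), low-beta (12.5-16 Hz), beta
(16.5-20 Hz), high-beta (20.5-28 Hz) — are averaged over a hemispheric
electrode set (ipsilesional or contralesional, 7 electrodes each,
midline excluded), giving one 4-feature vector per trial per state.
A two-class linear discriminant is trained on two sessions chosen at
random from a four-session stage (first four sessions = early stage,
last four = late) and scored on the other two; the DR is the held-out
accuracy.

The linear discriminant is implemented here from class means and the
pooled within-class covariance (with a small ridge when near-singular)
as a scikit-learn estimator, so it composes with pipelines and model
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import spectral
from .spectral import EpochedEEG, MONTAGE_16

__all__ = [
    "BANDS",
    "hemispheric_channels",
    "extract_features",
    "LinearDiscriminant",
    "session_split",
    "discriminant_rate",
    "DiscriminantRate",
    "dr_pipeline",
]

#: The four spectral features fed to the classifier, in order.
BANDS = {
    "alpha": (8.0, 13.0),
    "low_beta": (12.5, 16.0),
    "beta": (16.5, 20.0),
    "high_beta": (20.5, 28.0),
}

STATE_IMAGERY = "imagery"
STATE_REST = "rest"


@dataclass
class DiscriminantRate:
    """Held-out classification accuracy for one hemisphere and stage."""

    value: float
    hemisphere: str
    stage: str
    n_test: int
    per_split: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "hemisphere": self.hemisphere,
            "stage": self.stage,
            "n_test": self.n_test,
            "per_split": list(self.per_split),
        }


def hemispheric_channels(channel_labels, lesion_side: str) -> tuple[list[str], list[str]]:
    """Split a 10-20 montage into (ipsilesional, contralesional) sets.

    Odd-numbered electrode labels lie over the left hemisphere, even
    over the right; midline electrodes (Cz, FCz) belong to neither set.
    """
    side = str(lesion_side).upper()
    if side not in ("L", "R"):
        raise ValueError(f"lesion side must be 'L' or 'R', got {lesion_side!r}")
    unknown = set(channel_labels) - set(MONTAGE_16)
    if unknown:
        raise ValueError(f"labels outside the 16-channel montage: {sorted(unknown)}")
    left, right = [], []
    for label in channel_labels:
        digits = "".join(ch for ch in label if ch.isdigit())
        if not digits:
            continue  # midline (Cz, FCz)
        (left if int(digits) % 2 == 1 else right).append(label)
    ipsi, contra = (left, right) if side == "L" else (right, left)
    return ipsi, contra


def extract_features(epochs: EpochedEEG, channels: list[str],
                     preprocessed: bool = False,
                     average_per_session: bool = False):
    """Band-power feature vectors for every trial and state.

    Returns ``(X, y, sessions)``: X is (2 x n_trials, 4) with columns in
    ``BANDS`` order, y holds state labels, sessions the trial's session
    id (0 if untagged).  With ``average_per_session`` the trial vectors
    of each (session, state) cell are averaged into a single vector.
    """
    idx = [epochs.channel_index(c) for c in channels]
    if not idx:
        raise ValueError("empty channel selection")
    sessions_in = epochs.session_ids or [0] * epochs.n_trials
    rows, labels, sess = [], [], []
    for trial_i, (task, rest) in enumerate(epochs.trials):
        if task.size == 0 or rest.size == 0:
            warnings.warn(f"trial {trial_i}: missing segment, skipped", stacklevel=2)
            continue
        if not preprocessed:
            task = spectral.preprocess(task, epochs.sampling_rate)
            rest = spectral.preprocess(rest, epochs.sampling_rate)
        for segment, state in ((task, STATE_IMAGERY), (rest, STATE_REST)):
            vec = [
                spectral.band_power(segment, band, epochs.sampling_rate, channels=idx)
                for band in BANDS.values()
            ]
            rows.append(vec)
            labels.append(state)
            sess.append(sessions_in[trial_i])
    X = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    sessions = np.asarray(sess)
    if average_per_session:
        keys = sorted({(s, st) for s, st in zip(sessions, labels)})
        X = np.vstack([
            X[(sessions == s) & (y == st)].mean(axis=0) for s, st in keys
        ])
        y = np.asarray([st for _, st in keys])
        sessions = np.asarray([s for s, _ in keys])
    return X, y, sessions


class LinearDiscriminant(BaseEstimator, ClassifierMixin):
    """Two-class linear discriminant from pooled within-class covariance.

    Fits class means mu_0, mu_1 and the pooled covariance Sigma; the
    decision rule is sign(w.x + b) with w = Sigma^-1 (mu_1 - mu_0) and b
    placing the boundary midway between the projected means, shifted by
    the log-prior ratio.  A ridge of ``ridge * trace(Sigma)/d`` is added
    only when the covariance condition number exceeds ``cond_threshold``.

    Parameters
    ----------
    priors : "equal", "empirical", or array of two probabilities
        Class priors; balanced task/rest designs warrant "equal".
    ridge : float
        Relative ridge magnitude used when regularisation triggers.
    cond_threshold : float
        Condition-number cutoff above which the ridge is applied.
    """

    def __init__(self, priors="equal", ridge: float = 1e-6,
                 cond_threshold: float = 1e8):
        self.priors = priors
        self.ridge = ridge
        self.cond_threshold = cond_threshold

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required, got {list(self.classes_)}"
            )
        n, d = X.shape
        means = np.vstack([X[y_idx == k].mean(axis=0) for k in (0, 1)])
        counts = np.bincount(y_idx, minlength=2)
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples")

        centered = X - means[y_idx]
        cov = centered.T @ centered / (n - 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > self.cond_threshold:
            scale = np.trace(cov) / d
            cov = cov + self.ridge * (scale if scale > 0 else 1.0) * np.eye(d)

        if isinstance(self.priors, str):
            if self.priors == "equal":
                priors = np.array([0.5, 0.5])
            elif self.priors == "empirical":
                priors = counts / n
            else:
                raise ValueError(f"unknown priors {self.priors!r}")
        else:
            priors = np.asarray(self.priors, dtype=float)
            priors = priors / priors.sum()

        w = np.linalg.solve(cov, means[1] - means[0])
        b = -0.5 * w @ (means[0] + means[1]) + np.log(priors[1] / priors[0])

        self.means_ = means
        self.covariance_ = cov
        self.priors_ = priors
        self.coef_ = w
        self.intercept_ = float(b)
        self.n_features_in_ = d
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def session_split(sessions, stage: str, rng) -> tuple[list, list]:
    """Pick 2 training + 2 testing sessions from a four-session stage.

    ``stage`` selects the first four ("early") or last four ("late")
    sessions of the ordered list; a seeded uniform draw assigns two of
    them to training and the remaining two to testing.
    """
    sessions = list(sessions)
    if len(sessions) < 8:
        raise ValueError(f"need at least 8 sessions, got {len(sessions)}")
    if stage == "early":
        pool = sessions[:4]
    elif stage == "late":
        pool = sessions[-4:]
    else:
        raise ValueError(f"stage must be 'early' or 'late', got {stage!r}")
    if len(pool) < 4:
        raise ValueError(f"stage {stage!r} has fewer than 4 sessions")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    train_idx = sorted(rng.choice(4, size=2, replace=False))
    train = [pool[i] for i in train_idx]
    test = [s for s in pool if s not in train]
    return train, test


def discriminant_rate(model: LinearDiscriminant, X_test, y_test,
                      hemisphere: str = "", stage: str = "") -> DiscriminantRate:
    """Proportion of held-out feature vectors classified correctly."""
    X_test = np.asarray(X_test, dtype=float)
    if len(X_test) == 0:
        raise ValueError("empty test set")
    accuracy = float(np.mean(model.predict(X_test) == np.asarray(y_test)))
    return DiscriminantRate(
        value=accuracy, hemisphere=hemisphere, stage=stage, n_test=len(X_test)
    )


def dr_pipeline(epochs: EpochedEEG, hemisphere: str, stage: str,
                n_splits: int = 10, seed: int | None = 0,
                preprocessed: bool = False,
                average_per_session: bool = False) -> DiscriminantRate:
    """Full DR protocol: features -> session split -> LDA -> held-out accuracy.

    Averages the DR over ``n_splits`` seeded 2+2 session splits
    (``n_splits=1`` reproduces a single-split protocol).  Trials must be
    tagged with session ids covering at least 8 sessions.
    """
    if epochs.session_ids is None:
        raise ValueError("epochs must carry session_ids for the DR protocol")
    ipsi, contra = hemispheric_channels(epochs.channel_labels, epochs.lesion_side)
    if hemisphere in ("ipsi", "ipsilesional"):
        channels, hemi_name = ipsi, "ipsilesional"
    elif hemisphere in ("contra", "contralesional"):
        channels, hemi_name = contra, "contralesional"
    else:
        raise ValueError(f"hemisphere must be 'ipsi' or 'contra', got {hemisphere!r}")

    X, y, sessions = extract_features(
        epochs, channels, preprocessed=preprocessed,
        average_per_session=average_per_session,
    )
    ordered_sessions = sorted(set(epochs.session_ids))
    rng = np.random.default_rng(seed)
    rates = []
    n_test_total = 0
    for _ in range(n_splits):
        train_s, test_s = session_split(ordered_sessions, stage, rng)
        train_mask = np.isin(sessions, train_s)
        test_mask = np.isin(sessions, test_s)
        model = LinearDiscriminant().fit(X[train_mask], y[train_mask])
        res = discriminant_rate(model, X[test_mask], y[test_mask])
        rates.append(res.value)
        n_test_total = int(test_mask.sum())
    return DiscriminantRate(
        value=float(np.mean(rates)),
        hemisphere=hemi_name,
        stage=stage,
        n_test=n_test_total,
        per_split=tuple(rates),
    )


def all_session_splits(stage_sessions) -> list[tuple[list, list]]:
    """Enumerate all C(4,2)=6 train/test splits of a four-session stage."""
    pool = list(stage_sessions)
    if len(pool) != 4:
        raise ValueError("a stage holds exactly 4 sessions")
    out = []
    for train in combinations(pool, 2):
        test = [s for s in pool if s not in train]
        out.append((list(train), test))
    return out
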