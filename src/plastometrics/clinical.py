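"""Rank-based clinical statistics and responder analysis.

Nonparametric tests for a three-time-point clinical outcome (here the
Fugl-Meyer Assessment for the upper extremity, FMA-UE, a 0-66 motor
impairment score): a tie-corrected Friedman omnibus test across time
points within a group, Wilcoxon signed-rank post-hoc contrasts, a
tie-corrected Mann-Whitney U for the baseline between-group comparison,
the Scheirer-Ray-Hare two-way ANOVA on ranks, a paired t-test, and a
responder analysis against a minimal clinically important difference
(MCID).

All rank statistics use mid-ranks for ties and the classical tie
corrections (the conventions of SPSS), with large-sample chi-square or
normal p-values.  The Wilcoxon Z follows the zero-exclusion convention:
zero differences are dropped before ranking, S is the sum of the ranks
of the negative differences, and no continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalTable",
    "TestResult",
    "ResponderSummary",
    "DegenerateDataError",
    "friedman_tie_corrected",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "scheirer_ray_hare",
    "paired_t",
    "mcid_responders",
    "clinical_report",
]

GROUPS = ("guided", "sham")
TIME_COLUMNS = ("fma_pre", "fma_post", "fma_6mo")
CONTRASTS = {
    "pre_post": ("fma_pre", "fma_post"),
    "pre_6mo": ("fma_pre", "fma_6mo"),
    "post_6mo": ("fma_post", "fma_6mo"),
}
FMA_UE_MAX = 66


class DegenerateDataError(ValueError):
    """Raised when the data admit no information for the requested test."""


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``df`` is None for tests using a normal reference distribution.
    """

    statistic: float
    df: int | None
    p_two_tailed: float
    n_used: int
    tie_correction_applied: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_two_tailed}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": float(self.statistic),
            "df": self.df,
            "p_two_tailed": float(self.p_two_tailed),
            "n_used": int(self.n_used),
            "tie_correction_applied": bool(self.tie_correction_applied),
        }


@dataclass
class ResponderSummary:
    """Count of subjects whose score change meets the MCID threshold."""

    contrast: str
    n_eligible: int
    n_exceeding: int

    def __post_init__(self) -> None:
        if self.n_exceeding > self.n_eligible:
            raise ValueError("n_exceeding cannot exceed n_eligible")

    @property
    def proportion(self) -> float:
        return self.n_exceeding / self.n_eligible

    @property
    def percent(self) -> float:
        """Proportion as a percentage, rounded half away from zero to 1 d.p."""
        return _round_half_away(100.0 * self.proportion, 1)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "n_eligible": self.n_eligible,
            "n_exceeding": self.n_exceeding,
            "proportion": self.proportion,
            "percent": self.percent,
        }


def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of most clinical reports)."""
    factor = 10.0**ndigits
    return np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor


@dataclass
class ClinicalTable:
    """Per-subject group membership and FMA-UE scores at three time points.

    Wraps a DataFrame with columns ``subject_id``, ``group`` (guided/sham),
    ``lesion_side`` (L/R/unknown) and the three score columns; extra
    metadata columns are carried along untouched.  Missing scores are NaN.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["subject_id", "group", "lesion_side", *TIME_COLUMNS]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if self.data["subject_id"].duplicated().any():
            dupes = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject_id: {sorted(set(dupes))}")
        bad_group = set(self.data["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")
        for col in TIME_COLUMNS:
            vals = self.data[col].dropna()
            out = vals[(vals < 0) | (vals > FMA_UE_MAX)]
            if len(out):
                rows = self.data.loc[out.index, "subject_id"].tolist()
                raise ValueError(
                    f"score out of range 0-{FMA_UE_MAX} in column {col}, subjects {rows}"
                )

    def __len__(self) -> int:
        return len(self.data)

    def group(self, name: str) -> pd.DataFrame:
        if name not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {name!r}")
        return self.data[self.data["group"] == name]

    def scores(self, group: str, columns=TIME_COLUMNS, complete_only: bool = False) -> pd.DataFrame:
        sub = self.group(group)[list(columns)]
        return sub.dropna() if complete_only else sub

    def long(self) -> pd.DataFrame:
        """Long form (subject_id, group, time, score) with missing rows dropped."""
        melted = self.data.melt(
            id_vars=["subject_id", "group"],
            value_vars=list(TIME_COLUMNS),
            var_name="time",
            value_name="score",
        )
        melted["time"] = melted["time"].str.removeprefix("fma_")
        return melted.dropna(subset=["score"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def friedman_tie_corrected(scores) -> TestResult:
    """Friedman test across k related samples, with the tie-correction divisor.

    ``scores`` is an n-subjects x k-conditions matrix with no missing
    entries (drop incomplete rows first).  Scores are mid-ranked within
    each row; the uncorrected statistic

        chi2 = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)

    is divided by C = 1 - sum(t^3 - t) / (n (k^3 - k)) taken over the
    within-row tie groups, and referred to chi-square with k-1 df.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D n x k matrix")
    n, k = scores.shape
    if k < 2 or n < 2:
        raise ValueError(f"need n >= 2 subjects and k >= 2 conditions, got {n} x {k}")
    if np.isnan(scores).any():
        raise ValueError(
            "missing entries present; apply complete-case filtering before calling"
        )

    ranks = np.apply_along_axis(stats.rankdata, 1, scores)
    col_sums = ranks.sum(axis=0)
    chi2_uncorrected = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)

    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    correction = 1.0 - tie_term / (n * (k**3 - k))
    if correction <= 0.0:
        raise DegenerateDataError(
            "every row is fully tied; the Friedman statistic is undefined"
        )

    statistic = chi2_uncorrected / correction
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(
        statistic=float(statistic),
        df=df,
        p_two_tailed=p,
        n_used=n,
        tie_correction_applied=tie_term > 0,
        name="friedman",
    )


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Wilcoxon signed-rank Z for paired samples, SPSS conventions.

    Differences d = y - x; zero differences are excluded; |d| is
    mid-ranked; S is the sum of the ranks of the *negative* differences,
    so Z is negative when scores increase.  The normal approximation uses
    the tie-corrected variance and no continuity correction.  Pairs with
    a missing value are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = y[keep] - x[keep]
    n_pairs = int(keep.sum())
    d = d[d != 0.0]
    m = len(d)
    if m == 0:
        raise DegenerateDataError("all paired differences are zero")

    ranks = stats.rankdata(np.abs(d))
    s_neg = float(ranks[d < 0].sum())
    mu = m * (m + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance after tie correction")
    z = (s_neg - mu) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(
        statistic=float(z),
        df=None,
        p_two_tailed=p,
        n_used=n_pairs,
        tie_correction_applied=tie_term > 0,
        name="wilcoxon_signed_rank",
    )


def wilcoxon_exact_p(x, y) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^m sign patterns.

    Zero differences excluded, mid-ranks on |d|.  Intended as an
    independent reference for small m (cost 2^m); two-sided p is the
    null probability of an |S - mu| at least as large as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y - x
    d = d[d != 0.0]
    m = len(d)
    if m == 0:
        raise DegenerateDataError("all paired differences are zero")
    if m > 20:
        raise ValueError("exact enumeration limited to m <= 20")
    ranks = stats.rankdata(np.abs(d))
    s_obs = float(ranks[d < 0].sum())
    mu = m * (m + 1) / 4.0
    # S under the null: each rank independently assigned to the negative set
    signs = np.array(np.meshgrid(*[[0.0, 1.0]] * m)).reshape(m, -1)
    s_null = ranks @ signs
    return float(np.mean(np.abs(s_null - mu) >= abs(s_obs - mu) - 1e-12))


def mann_whitney_u(a, b) -> TestResult:
    """Mann-Whitney U with tie-corrected normal approximation, two-tailed.

    U is reported for sample ``a``; the variance uses the pooled tie
    correction n1 n2 / 12 * [(N+1) - sum(t^3 - t) / (N (N-1))].  No
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        raise DegenerateDataError("all pooled observations identical")
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(
        statistic=float(u1),
        df=None,
        p_two_tailed=p,
        n_used=n,
        tie_correction_applied=tie_term > 0,
        name="mann_whitney_u",
    )


def scheirer_ray_hare(table: pd.DataFrame, score: str = "score",
                      factor_a: str = "group", factor_b: str = "time") -> dict[str, TestResult]:
    """Scheirer-Ray-Hare two-way nonparametric ANOVA on ranks.

    All observations are pooled and mid-ranked; two-way sums of squares
    are computed on the ranks (cells may be unbalanced); each effect's
    H = SS_effect / MS_total is referred to chi-square with the effect's
    df.  Returns TestResults keyed by the factor names and
    ``"interaction"``.
    """
    for col in (score, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    data = table[[score, factor_a, factor_b]].dropna().copy()
    levels_a = data[factor_a].unique()
    levels_b = data[factor_b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")

    data["_rank"] = stats.rankdata(data[score].to_numpy(dtype=float))
    n = len(data)
    grand = data["_rank"].sum()
    cf = grand**2 / n  # correction factor

    def ss_of(groupby_cols) -> float:
        g = data.groupby(groupby_cols, observed=True)["_rank"]
        return float((g.sum() ** 2 / g.count()).sum() - cf)

    ss_a = ss_of([factor_a])
    ss_b = ss_of([factor_b])
    ss_cells = ss_of([factor_a, factor_b])
    ss_ab = ss_cells - ss_a - ss_b
    ss_total = float((data["_rank"] ** 2).sum() - cf)
    ms_total = ss_total / (n - 1)

    df_a = len(levels_a) - 1
    df_b = len(levels_b) - 1
    df_ab = df_a * df_b

    def result(ss: float, df: int, label: str) -> TestResult:
        h = ss / ms_total if ms_total > 0 else 0.0
        h = max(h, 0.0)
        return TestResult(
            statistic=float(h),
            df=df,
            p_two_tailed=float(stats.chi2.sf(h, df)) if ms_total > 0 else 1.0,
            n_used=n,
            tie_correction_applied=True,  # rank variance implicitly tie-adjusted
            name=f"scheirer_ray_hare_{label}",
        )

    return {
        factor_a: result(ss_a, df_a, factor_a),
        factor_b: result(ss_b, df_b, factor_b),
        "interaction": result(ss_ab, df_ab, "interaction"),
    }


def paired_t(x, y) -> TestResult:
    """Two-tailed paired t-test on complete pairs, t = mean(d)/(sd(d)/sqrt(n))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = (y - x)[keep]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical pairs: no evidence either way
            return TestResult(statistic=0.0, df=n - 1, p_two_tailed=1.0,
                              n_used=n, name="paired_t")
        raise DegenerateDataError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return TestResult(
        statistic=float(t), df=n - 1, p_two_tailed=p, n_used=n, name="paired_t"
    )


# ---------------------------------------------------------------------------
# responder analysis
# ---------------------------------------------------------------------------


def mcid_responders(table: ClinicalTable, contrast: str,
                    threshold: float = 4.0) -> dict[str, ResponderSummary]:
    """Per-group proportion of subjects whose score change meets the MCID.

    A subject responds when (later - earlier) >= threshold.  Subjects
    missing the later endpoint are excluded from the eligible count.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(CONTRASTS)}, got {contrast!r}")
    earlier, later = CONTRASTS[contrast]
    out: dict[str, ResponderSummary] = {}
    for group in GROUPS:
        sub = table.group(group)
        if len(sub) == 0:
            raise ValueError(f"group {group!r} is empty")
        eligible = sub.dropna(subset=[earlier, later])
        change = eligible[later] - eligible[earlier]
        out[group] = ResponderSummary(
            contrast=contrast,
            n_eligible=len(eligible),
            n_exceeding=int((change >= threshold).sum()),
        )
    return out


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------


def clinical_report(table: ClinicalTable, mcid: float = 4.0) -> dict:
    """Run the full clinical analysis battery on a three-time-point table.

    Per group: tie-corrected Friedman over the complete-case rows, then
    Wilcoxon signed-rank post-hoc contrasts on pairwise-available data.
    Between groups: Mann-Whitney U at baseline, Scheirer-Ray-Hare on the
    long table, and MCID responder proportions.  Returns a plain dict
    ready for JSON serialisation.
    """
    report: dict = {"groups": {}, "between": {}, "responders": {}}
    for group in GROUPS:
        complete = table.scores(group, complete_only=True).to_numpy()
        entry: dict = {"friedman": friedman_tie_corrected(complete).to_dict()}
        for cname, (earlier, later) in CONTRASTS.items():
            sub = table.group(group)
            res = wilcoxon_signed_rank(sub[earlier].to_numpy(), sub[later].to_numpy())
            entry[f"wilcoxon_{cname}"] = res.to_dict()
        report["groups"][group] = entry

    baseline = [table.group(g)["fma_pre"].to_numpy() for g in GROUPS]
    report["between"]["mann_whitney_baseline"] = mann_whitney_u(*baseline).to_dict()
    srh = scheirer_ray_hare(table.long())
    report["between"]["scheirer_ray_hare"] = {k: v.to_dict() for k, v in srh.items()}

    for cname in ("pre_post", "pre_6mo"):
        resp = mcid_responders(table, cname, threshold=mcid)
        report["responders"][cname] = {g: r.to_dict() for g, r in resp.items()}
    return report


def format_report(report: dict) -> str:
    """Human-readable text rendering of ``clinical_report`` output."""
    lines = []
    for group, entry in report["groups"].items():
        fr = entry["friedman"]
        lines.append(
            f"{group}: Friedman chi2({fr['df']}) = {fr['statistic']:.3f}, "
            f"p = {fr['p_two_tailed']:.3f} (n = {fr['n_used']})"
        )
        for key, res in entry.items():
            if key.startswith("wilcoxon_"):
                lines.append(
                    f"  {key.removeprefix('wilcoxon_')}: Z = {res['statistic']:.3f}, "
                    f"p = {res['p_two_tailed']:.3f} (n = {res['n_used']})"
                )
    mw = report["between"]["mann_whitney_baseline"]
    lines.append(
        f"baseline between-group: U = {mw['statistic']:.1f}, p = {mw['p_two_tailed']:.3f}"
    )
    for eff, res in report["between"]["scheirer_ray_hare"].items():
        lines.append(
            f"SRH {eff}: H = {res['statistic']:.3f}, p = {res['p_two_tailed']:.3f}"
        )
    for cname, groups in report["responders"].items():
        parts = ", ".join(
            f"{g}: {r['n_exceeding']}/{r['n_eligible']} = {r['percent']}%"
            for g, r in groups.items()
        )
        lines.append(f"MCID responders {cname}: {parts}")
    return "\n".join(lines)
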