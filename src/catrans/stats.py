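"""Group-comparison statistics for event counts and behavioral readouts.

Implements the normality-gated two-group testing rule (Shapiro-Wilk, then
t / Welch t / Mann-Whitney U), Kruskal-Wallis for >= 3 groups, effect sizes
(pooled-SD Cohen's d, rank-biserial r, partial eta squared), the mixed
two-way ANOVA on per-window event counts (group as between-subjects factor,
5-min window as within-subjects factor, cell as the repeated unit), the
per-window percent-change summary, and the cumulative-dose arithmetic of a
titrated seizure-susceptibility test.

Raw p-values are reported throughout; no multiple-testing correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import EventCountTable
from .errors import InsufficientSampleError, InvalidDesignError, InvalidParameterError

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# two-group tests

@dataclass
class TwoGroupResult:
    test_name: str              # "t" | "welch" | "mannwhitney"
    statistic: float
    p_value: float
    delta_mean: float           # mean(x) - mean(y)
    sem_of_delta: float
    effect_size: float
    effect_size_kind: str       # "cohen_d" | "rank_biserial"


def _check_samples(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientSampleError("each sample needs n >= 3")
    return x, y


def variance_ratio_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test of equal variances (larger variance in the numerator)."""
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 >= v2:
        F, dfn, dfd = v1 / v2, x.size - 1, y.size - 1
    else:
        F, dfn, dfd = v2 / v1, y.size - 1, x.size - 1
    p = 2.0 * sps.f.sf(F, dfn, dfd)
    return F, min(p, 1.0)


def choose_two_group_test(x, y, alpha: float = DEFAULT_ALPHA) -> str:
    """Select t, Welch t, or Mann-Whitney U by normality and variance gates.

    Both samples normal (Shapiro-Wilk at ``alpha``) and variances compatible
    -> Student t; both normal but variances significantly different -> Welch;
    any non-normal sample -> Mann-Whitney U.
    """
    x, y = _check_samples(x, y)
    normal = all(sps.shapiro(s).pvalue > alpha for s in (x, y))
    if not normal:
        return "mannwhitney"
    _, p_var = variance_ratio_test(x, y)
    return "welch" if p_var < alpha else "t"


def cohens_d(x, y) -> float:
    """Pooled-SD standardized mean difference, mean(x) - mean(y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    pooled = np.sqrt(((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1))
                     / (n1 + n2 - 2))
    if pooled == 0:
        return 0.0
    return (x.mean() - y.mean()) / pooled


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Mann-Whitney effect size 2U/(n1 n2) - 1, in [-1, 1]."""
    return 2.0 * U / (n1 * n2) - 1.0


def two_group_compare(x, y, alpha: float = DEFAULT_ALPHA,
                      test_name: str | None = None) -> TwoGroupResult:
    """Run the gate-selected two-group test with its matched effect size."""
    x, y = _check_samples(x, y)
    if test_name is None:
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn("degenerate data: all values tied", stacklevel=2)
            return TwoGroupResult("mannwhitney", np.nan, 1.0, 0.0, 0.0, 0.0, "rank_biserial")
        test_name = choose_two_group_test(x, y, alpha)
    delta = float(x.mean() - y.mean())
    sem = float(np.sqrt(np.var(x, ddof=1) / x.size + np.var(y, ddof=1) / y.size))
    if test_name == "mannwhitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        eff = rank_biserial(float(res.statistic), x.size, y.size)
        return TwoGroupResult("mannwhitney", float(res.statistic), float(res.pvalue),
                              delta, sem, eff, "rank_biserial")
    res = sps.ttest_ind(x, y, equal_var=(test_name == "t"))
    return TwoGroupResult(test_name, float(res.statistic), float(res.pvalue),
                          delta, sem, cohens_d(x, y), "cohen_d")


# ---------------------------------------------------------------------------
# >= 3 groups

@dataclass
class KruskalResult:
    H: float
    p_value: float
    df_between: int             # k - 1
    df_within: int              # N - k (one-way-ANOVA-style echo of the design)
    eta_sq: float               # (H - k + 1)/(N - k)
    welch_F: float
    welch_df: tuple[float, float]
    welch_p: float


def kruskal_wallis(samples: list[np.ndarray]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with an eta-squared effect size.

    Also reports a Welch one-way ANOVA F on the same samples, since a rank
    test is sometimes summarized with an F-style statistic; the two address
    the same design but are distinct statistics.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 3:
        raise InvalidDesignError("need >= 3 groups; use two_group_compare for 2")
    if any(s.size < 3 for s in samples):
        raise InsufficientSampleError("each group needs n >= 3")
    k = len(samples)
    N = sum(s.size for s in samples)
    H, p = sps.kruskal(*samples)
    eta = (H - k + 1) / (N - k)
    import pingouin as pg
    long = pd.DataFrame({
        "value": np.concatenate(samples),
        "group": np.repeat([str(i) for i in range(k)], [s.size for s in samples]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant groups degenerate the Welch fit
        w = pg.welch_anova(data=long, dv="value", between="group").iloc[0]
    return KruskalResult(H=float(H), p_value=float(p), df_between=k - 1, df_within=N - k,
                         eta_sq=float(eta), welch_F=float(w["F"]),
                         welch_df=(float(w["ddof1"]), float(w["ddof2"])),
                         welch_p=float(w["p_unc"]))


# ---------------------------------------------------------------------------
# mixed two-way ANOVA on event counts

@dataclass
class AnovaResult:
    F_group: float
    df: tuple[int, int]                 # between-subjects (df1, df2) = (g-1, N-g)
    p_value: float                      # group effect
    F_time: float
    p_time: float
    F_interaction: float
    p_interaction: float
    partial_eta_sq_group: float
    partial_eta_sq_time: float
    partial_eta_sq_interaction: float


def mixed_anova(counts: EventCountTable) -> AnovaResult:
    """Mixed two-way ANOVA: group between subjects, window within subjects.

    Cells are the repeated unit; the design must be complete (every cell has
    a count in every window, which EventCountTable guarantees).  Partial eta
    squared is SS_effect/(SS_effect + SS_error-for-that-effect).  Within
    df are uncorrected for sphericity.
    """
    long = counts.to_long()
    groups = pd.unique(long["group"])
    if len(groups) < 2:
        raise InvalidDesignError("need >= 2 groups")
    if counts.n_windows < 2:
        raise InvalidDesignError("need >= 2 windows")
    import pingouin as pg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=long, dv="count", within="window",
                             between="group", subject="cell", effsize="np2")
    aov = aov.set_index("Source")
    g = aov.loc["group"]
    t = aov.loc["window"]
    i = aov.loc["Interaction"]
    return AnovaResult(
        F_group=float(g["F"]), df=(int(g["DF1"]), int(g["DF2"])), p_value=float(g["p_unc"]),
        F_time=float(t["F"]), p_time=float(t["p_unc"]),
        F_interaction=float(i["F"]), p_interaction=float(i["p_unc"]),
        partial_eta_sq_group=float(g["np2"]),
        partial_eta_sq_time=float(t["np2"]),
        partial_eta_sq_interaction=float(i["np2"]),
    )


def percent_change(counts: EventCountTable, reference_group) -> pd.Series:
    """Per-window percent change of mean counts vs the reference group.

    100 * (mean_test - mean_ref)/mean_ref for each window; requires exactly
    two groups and a positive reference mean in every window.
    """
    groups = list(pd.unique(np.asarray(counts.groups)))
    if reference_group not in groups:
        raise InvalidDesignError(f"reference group {reference_group!r} not in table")
    if len(groups) != 2:
        raise InvalidDesignError("percent_change needs exactly two groups")
    test_group = next(g for g in groups if g != reference_group)
    gmask = np.asarray(counts.groups) == reference_group
    mean_ref = counts.counts[gmask].mean(axis=0)
    mean_test = counts.counts[~gmask].mean(axis=0)
    if np.any(mean_ref == 0):
        bad = [counts.window_labels[j] for j in np.flatnonzero(mean_ref == 0)]
        raise InvalidParameterError(f"zero reference mean in window(s) {bad}: percentage undefined")
    pc = 100.0 * (mean_test - mean_ref) / mean_ref
    return pd.Series(pc, index=counts.window_labels, name=f"{test_group} vs {reference_group} (%)")


# ---------------------------------------------------------------------------
# cumulative-dose arithmetic of the titrated seizure-susceptibility test

@dataclass(frozen=True)
class DoseSchedule:
    """Initial convulsant dose plus timed booster doses (mg/kg, minutes)."""

    initial_dose: float
    booster_doses: tuple[tuple[float, float], ...]  # (dose mg/kg, offset min)

    def __post_init__(self) -> None:
        if self.initial_dose <= 0 or any(d <= 0 for d, _ in self.booster_doses):
            raise InvalidParameterError("doses must be positive")
        offsets = [t for _, t in self.booster_doses]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise InvalidParameterError("booster offsets must be strictly increasing")

    @property
    def doses(self) -> tuple[float, ...]:
        return (self.initial_dose,) + tuple(d for d, _ in self.booster_doses)


def ptz_sst_schedule(initial_dose: float = 40.0, n_boosters: int = 20) -> DoseSchedule:
    """Standard titration: two 5-mg/kg boosters 10 min apart, then 10 mg/kg
    every 5 min.  ``initial_dose`` 40 mg/kg for the standard arm, 30 mg/kg
    for the reduced-start arm."""
    boosters = [(5.0, 10.0), (5.0, 20.0)]
    t = 25.0
    while len(boosters) < n_boosters:
        boosters.append((10.0, t))
        t += 5.0
    return DoseSchedule(initial_dose=initial_dose, booster_doses=tuple(boosters))


def cumulative_dose(schedule: DoseSchedule, grade5_at_injection: int) -> float:
    """Total dose received through the injection that evoked a Grade V seizure.

    ``grade5_at_injection`` is 1-based: 1 means the initial dose alone.
    """
    doses = schedule.doses
    if not (1 <= grade5_at_injection <= len(doses)):
        raise InvalidParameterError(
            f"injection index {grade5_at_injection} outside schedule of {len(doses)}")
    return float(sum(doses[:grade5_at_injection]))
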