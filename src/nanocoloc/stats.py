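"""Condition-level aggregation of per-FOV Pearson coefficients.

The analysis unit is the FOV.  Per-condition Pearson values are summarized
(mean, SEM, median, normality diagnostic), the two control classes are
pooled into a single background group when they are statistically
indistinguishable, condition means are normalized to that background, and
all condition pairs are compared with a global one-way ANOVA followed by
pairwise Welch t-tests under a multiple-testing adjustment (Bonferroni by
default).  SEM (not SD) is the reported dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError


@dataclass
class ConditionSummary:
    """Location/dispersion summary of one condition's Pearson values."""

    condition: str
    n_fovs: int
    mean_r: float
    sem_r: float
    median_r: float
    normality_p: float  # NaN when the test is not applicable


@dataclass
class NormalizedSummary:
    """Condition mean expressed as a multiple of the control background."""

    condition: str
    normalized_mean: float
    normalized_sem: float


@dataclass
class PairResult:
    condition_a: str
    condition_b: str
    p_value: float  # adjusted
    raw_p: float
    fold_ratio: float  # mean_a / mean_b


@dataclass
class ComparisonTable:
    """All pairwise comparisons plus the global ANOVA p-value.

    The table is symmetric under pair swap with the fold ratio inverted;
    ``get(a, b)`` resolves either orientation.
    """

    pairs: list[PairResult]
    anova_p: float
    adjustment: str
    alpha: float = 0.05

    def get(self, a: str, b: str) -> PairResult:
        for p in self.pairs:
            if (p.condition_a, p.condition_b) == (a, b):
                return p
            if (p.condition_a, p.condition_b) == (b, a):
                fold = 1.0 / p.fold_ratio if p.fold_ratio else float("nan")
                return PairResult(a, b, p.p_value, p.raw_p, fold)
        raise KeyError(f"no comparison between {a!r} and {b!r}")

    def to_matrix(self) -> pd.DataFrame:
        """Square matrix of adjusted p-values (diagonal NaN)."""
        names: list[str] = []
        for p in self.pairs:
            for c in (p.condition_a, p.condition_b):
                if c not in names:
                    names.append(c)
        m = pd.DataFrame(np.nan, index=names, columns=names)
        for p in self.pairs:
            m.loc[p.condition_a, p.condition_b] = p.p_value
            m.loc[p.condition_b, p.condition_a] = p.p_value
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "condition_a": p.condition_a,
                    "condition_b": p.condition_b,
                    "p_adjusted": p.p_value,
                    "p_raw": p.raw_p,
                    "fold_ratio": p.fold_ratio,
                }
                for p in self.pairs
            ]
        )


@dataclass
class ControlPooling:
    """Outcome of testing whether the two control classes may be pooled."""

    pooled: np.ndarray | None
    p_value: float
    combined: bool
    neg: np.ndarray
    pos: np.ndarray

    @property
    def values(self) -> np.ndarray:
        if self.pooled is None:
            raise UndefinedStatisticError(
                "controls differ significantly "
                f"(Welch p = {self.p_value:.4g}); no pooled background available"
            )
        return self.pooled


def _check_values(values: Sequence[float], what: str, n_min: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{what}: expected a 1-D list of values")
    if len(arr) < n_min:
        raise InsufficientDataError(f"{what}: need at least {n_min} values, got {len(arr)}")
    return arr


def summarize_condition(values: Sequence[float], condition: str) -> ConditionSummary:
    """Mean, SEM (= sd/sqrt(n)), median and a D'Agostino-Pearson omnibus
    normality p-value.  Degenerate inputs (all equal, or n < 8 where the
    omnibus test is unreliable) report the normality diagnostic as NaN."""
    arr = _check_values(values, f"condition {condition!r}")
    n = len(arr)
    sd = float(np.std(arr, ddof=1))
    if np.ptp(arr) > 0 and n >= 8:
        normality_p = float(sps.normaltest(arr).pvalue)
    else:
        normality_p = float("nan")
    return ConditionSummary(
        condition=condition,
        n_fovs=n,
        mean_r=float(np.mean(arr)),
        sem_r=sd / np.sqrt(n),
        median_r=float(np.median(arr)),
        normality_p=normality_p,
    )


def combine_controls(
    neg: Sequence[float], pos: Sequence[float], alpha: float = 0.05
) -> ControlPooling:
    """Pool the two control classes when a Welch test cannot tell them apart.

    Identical lists pool trivially (p = 1); otherwise a Welch two-sample
    t-test decides: p >= alpha pools, p < alpha refuses and both groups are
    reported separately alongside the p-value.
    """
    a = _check_values(neg, "negative control")
    b = _check_values(pos, "positive control")
    if len(a) == len(b) and np.array_equal(a, b):
        p = 1.0
    else:
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    combined = bool(p >= alpha)
    return ControlPooling(
        pooled=np.concatenate([a, b]) if combined else None,
        p_value=p,
        combined=combined,
        neg=a,
        pos=b,
    )


def normalize_to_background(
    summary: ConditionSummary, control: ConditionSummary
) -> NormalizedSummary:
    """Express a condition mean as a multiple of the control background mean.

    The SEM of the ratio uses first-order propagation for a ratio of
    independent means: sem = |m_a/m_b| * sqrt((sem_a/m_a)^2 + (sem_b/m_b)^2).
    The control normalizes to exactly 1 by construction.
    """
    if control.mean_r <= 0:
        raise UndefinedStatisticError(
            f"control background mean must be positive, got {control.mean_r}"
        )
    ratio = summary.mean_r / control.mean_r
    if summary.mean_r == 0:
        sem = summary.sem_r / control.mean_r
    else:
        sem = abs(ratio) * np.sqrt(
            (summary.sem_r / summary.mean_r) ** 2 + (control.sem_r / control.mean_r) ** 2
        )
    return NormalizedSummary(summary.condition, float(ratio), float(sem))


def fold_difference(a: ConditionSummary, b: ConditionSummary) -> float:
    """Ratio of condition means a/b (the "X times more" quantity)."""
    if b.mean_r <= 0:
        raise UndefinedStatisticError(
            f"fold difference undefined: denominator mean is {b.mean_r}"
        )
    return a.mean_r / b.mean_r


def pairwise_comparisons(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
) -> ComparisonTable:
    """Global one-way ANOVA plus all pairwise Welch tests with adjustment.

    Returns every condition pair (including controls), shaped like a
    significance matrix between cell lines and treatments.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 groups to compare")
    arrays: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        arrays[name] = _check_values(vals, f"group {name!r}")

    samples = list(arrays.values())
    if all(np.array_equal(samples[0], s) for s in samples[1:]):
        anova_p = 1.0  # identical groups: no variation between means
    else:
        anova_p = float(sps.f_oneway(*samples).pvalue)

    names = list(arrays)
    raw_ps: list[float] = []
    pair_keys: list[tuple[str, str]] = []
    for a, b in combinations(names, 2):
        if np.array_equal(arrays[a], arrays[b]):
            p = 1.0
        else:
            p = float(sps.ttest_ind(arrays[a], arrays[b], equal_var=False).pvalue)
        raw_ps.append(p)
        pair_keys.append((a, b))

    adj = multipletests(raw_ps, alpha=alpha, method=adjustment)[1]
    pairs = []
    for (a, b), p_raw, p_adj in zip(pair_keys, raw_ps, adj):
        mean_b = float(np.mean(arrays[b]))
        fold = float(np.mean(arrays[a])) / mean_b if mean_b != 0 else float("nan")
        pairs.append(PairResult(a, b, float(p_adj), float(p_raw), fold))
    return ComparisonTable(pairs=pairs, anova_p=anova_p, adjustment=adjustment, alpha=alpha)
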