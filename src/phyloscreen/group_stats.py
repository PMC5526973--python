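"""Two-group statistics for small-sample screening contrasts.

The kernel used by every screening stage: two-sample t-tests (Student or
Welch), Benjamini-Hochberg FDR, a standardized effect-size correlation
``r`` that accommodates inhomogeneous variances and unequal group sizes,
post-hoc power via the noncentral t distribution, per-condition fold
changes with a minimum-fold summary, and the Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "MWUResult",
    "TTestResult",
    "ZeroVarianceError",
    "t_test",
    "bh_fdr",
    "effect_size_r",
    "posthoc_power",
    "min_fold_change",
    "mwu_test",
    "compare_groups",
]


class ZeroVarianceError(ValueError):
    """Both samples have zero variance but unequal means: effect undefined."""


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class MWUResult:
    U: float
    p_two_sided: float
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    exact: bool


@dataclass
class GroupComparison:
    """Full statistical record for one focal-vs-pooled-comparison contrast."""

    gene: str
    N: int
    M: int
    mean_focal: float
    mean_other: float
    sd_focal: float
    sd_other: float
    t_stat: float
    df: float
    p_two_sided: float
    d_av: float
    r_effect: float
    power: float
    fold_by_condition: dict[str, float]
    min_fold_change: float
    direction: str
    fdr: float = math.nan
    degenerate: bool = False
    excluded_conditions: tuple[str, ...] = field(default_factory=tuple)


def _as_array(x: Sequence[float], name: str, min_n: int = 2) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1 or a.size < min_n:
        raise ValueError(f"{name} must be a 1-d sample with >= {min_n} values")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def t_test(x: Sequence[float], y: Sequence[float],
           variant: str = "welch") -> TTestResult:
    """Two-tailed two-sample t-test.

    ``student`` pools variances (df = n+m-2); ``welch`` uses the
    Welch-Satterthwaite df. Degenerate zero-variance inputs are resolved
    explicitly rather than propagating NaN: identical constant samples
    give t=0, p=1; constant samples with unequal means give p=0 and the
    result is flagged.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        df = float(xa.size + ya.size - 2)
        if xa.mean() == ya.mean():
            return TTestResult(0.0, df, 1.0, degenerate=True)
        sign = math.copysign(1.0, xa.mean() - ya.mean())
        return TTestResult(sign * math.inf, df, 0.0, degenerate=True)
    res = stats.ttest_ind(xa, ya, equal_var=(variant == "student"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def effect_size_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Standardized difference d_av and effect-size correlation r.

    d_av standardizes the mean difference by the variance-averaged SD,
    sqrt((var_x + var_y)/2), which keeps the measure meaningful under
    inhomogeneous variances. r maps d_av to [0, 1) accounting for
    unequal group sizes through the proportion term 1/(p*q) with
    p = n/(n+m), q = m/(n+m):

        r = |d_av| / sqrt(d_av**2 + 1/(p*q))
    """
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    sd = math.sqrt((xa.var(ddof=1) + ya.var(ddof=1)) / 2.0)
    diff = ya.mean() - xa.mean()
    if sd == 0.0:
        if diff == 0.0:
            return 0.0, 0.0
        raise ZeroVarianceError(
            "both samples have zero variance with unequal means; r undefined")
    d_av = diff / sd
    n, m = xa.size, ya.size
    p = n / (n + m)
    q = m / (n + m)
    r = abs(d_av) / math.sqrt(d_av * d_av + 1.0 / (p * q))
    return float(d_av), float(r)


def posthoc_power(d_av: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Post-hoc power of the two-tailed two-sample t-test.

    Noncentrality ncp = |d_av| * sqrt(n1*n2/(n1+n2)), df = n1+n2-2,
    rejection at |t| > t_{1-alpha/2, df} under the noncentral t.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    ncp = abs(d_av) * math.sqrt(n1 * n2 / (n1 + n2))
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = (1.0 - stats.nct.cdf(t_crit, df, ncp)
             + stats.nct.cdf(-t_crit, df, ncp))
    return float(min(max(power, 0.0), 1.0))


def min_fold_change(
    mean_focal: float,
    means_by_condition: Mapping[str, float],
) -> tuple[dict[str, float], float, str, tuple[str, ...]]:
    """Per-condition fold changes and the least extreme one.

    fold_c = mean_focal / mean_c. The minimum fold change is the fold
    with minimal |log2|, i.e. the comparison-condition mean closest to
    the focal mean in log space. Direction is ``up`` if every fold > 1,
    ``down`` if every fold < 1, otherwise ``mixed`` (a fold of exactly 1
    counts as mixed). Conditions with nonpositive means are excluded and
    returned separately.
    """
    if mean_focal <= 0:
        raise ValueError("focal mean must be positive")
    if not means_by_condition:
        raise ValueError("at least one comparison condition required")
    excluded = tuple(c for c, m in means_by_condition.items() if m <= 0)
    folds = {c: mean_focal / m for c, m in means_by_condition.items() if m > 0}
    if not folds:
        raise ValueError("all comparison means are nonpositive")
    min_cond = min(folds, key=lambda c: (abs(math.log2(folds[c])), c))
    if all(f > 1.0 for f in folds.values()):
        direction = "up"
    elif all(f < 1.0 for f in folds.values()):
        direction = "down"
    else:
        direction = "mixed"
    return folds, folds[min_cond], direction, excluded


def mwu_test(a: Sequence[float], b: Sequence[float]) -> MWUResult:
    """Two-tailed Mann-Whitney U test.

    Exact null distribution when n_a*n_b <= 400 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    aa = _as_array(a, "a", min_n=1)
    ba = _as_array(b, "b", min_n=1)
    has_ties = np.unique(np.concatenate([aa, ba])).size < aa.size + ba.size
    exact = (aa.size * ba.size <= 400) and not has_ties
    res = stats.mannwhitneyu(
        aa, ba, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return MWUResult(
        U=float(res.statistic),
        p_two_sided=float(res.pvalue),
        median_a=float(np.median(aa)),
        median_b=float(np.median(ba)),
        mean_a=float(aa.mean()),
        mean_b=float(ba.mean()),
        exact=exact,
    )


def compare_groups(
    gene: str,
    focal: Sequence[float],
    by_condition: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    variant: str = "welch",
) -> GroupComparison:
    """Assemble the full statistical record for one contrast.

    ``focal`` is tested against the pooled values of all comparison
    conditions; fold changes are computed condition-wise. FDR is left
    NaN here and attached later across the test family.
    """
    xa = _as_array(focal, "focal")
    pooled = np.concatenate([np.asarray(v, dtype=float)
                             for v in by_condition.values()])
    pooled = _as_array(pooled, "pooled comparisons")
    tt = t_test(xa, pooled, variant=variant)
    try:
        d_av, r = effect_size_r(xa, pooled)
        power = posthoc_power(d_av, xa.size, pooled.size, alpha)
    except ZeroVarianceError:
        d_av, r, power = math.nan, math.nan, math.nan
    cond_means = {c: float(np.mean(v)) for c, v in by_condition.items()}
    folds, min_fold, direction, excluded = min_fold_change(
        float(xa.mean()), cond_means)
    return GroupComparison(
        gene=gene,
        N=int(xa.size),
        M=int(pooled.size),
        mean_focal=float(xa.mean()),
        mean_other=float(pooled.mean()),
        sd_focal=float(xa.std(ddof=1)),
        sd_other=float(pooled.std(ddof=1)),
        t_stat=tt.t,
        df=tt.df,
        p_two_sided=tt.p,
        d_av=d_av,
        r_effect=r,
        power=power,
        fold_by_condition=folds,
        min_fold_change=min_fold,
        direction=direction,
        degenerate=tt.degenerate or math.isnan(r),
        excluded_conditions=excluded,
    )
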