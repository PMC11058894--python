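"""Method-agreement statistics for paired E/A measurements.

Implements the comparison machinery used to benchmark velocity-based
methods against a reference: ordinary least-squares regression
(y = beta1 * x + beta0, with R^2 the squared Pearson correlation),
Bland-Altman analysis with mean +/- 2 SD limits of agreement and per-pair
percentage differences, paired Student t-tests, Fisher r-to-z comparison
of correlation coefficients, and the conventional R^2 association
categories (weak <= 0.25 < moderate <= 0.5 < strong <= 0.8 < very strong).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

__all__ = [
    "ols_regression",
    "bland_altman",
    "normal_upper_tail",
    "fisher_rz_compare",
    "steiger_rz_compare",
    "paired_t_test",
    "categorize_association",
    "MethodPairResult",
    "CorrelationComparison",
    "AgreementReport",
    "run_comparison",
]

logger = logging.getLogger(__name__)


def _pair(x, y, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return x, y


def ols_regression(x, y) -> tuple[float, float, float]:
    """Least-squares line y = beta1*x + beta0; returns (beta1, beta0, R^2)."""
    x, y = _pair(x, y, 3)
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(d1, d2) -> tuple[float, float, float, float]:
    """Bland-Altman agreement of two paired measurement series.

    Returns ``(mean_diff, loa_low, loa_high, mean_pct_diff)`` where the
    limits of agreement are mean +/- 2 sample SD (n-1 denominator) of the
    differences d1 - d2, and the percentage difference of each pair is
    100 * (d1_i - d2_i) / ((d1_i + d2_i) / 2), reported as its mean.
    """
    d1, d2 = _pair(d1, d2, 2)
    diff = d1 - d2
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pair_means = (d1 + d2) / 2.0
    zero = np.flatnonzero(pair_means == 0)
    if len(zero):
        raise ValueError(
            f"pair mean is zero at index {int(zero[0])}; percentage difference undefined"
        )
    pct = 100.0 * diff / pair_means
    return mean_diff, mean_diff - 2 * sd, mean_diff + 2 * sd, float(pct.mean())


def normal_upper_tail(z: float) -> float:
    """P(Z > z) for standard normal Z, via the complementary error function."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(0.5 * special.erfc(z / math.sqrt(2.0)))


@dataclass
class CorrelationComparison:
    """Fisher r-to-z comparison of two correlation coefficients."""

    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p_one_sided: float

    def __post_init__(self) -> None:
        if not (abs(self.r1) < 1 and abs(self.r2) < 1):
            raise ValueError("correlations must satisfy |r| < 1")
        if min(self.n1, self.n2) <= 3:
            raise ValueError("sample sizes must exceed 3")
        if not 0 < self.p_one_sided < 1:
            raise ValueError("p must lie in (0, 1)")


def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two correlations via the Fisher r-to-z transformation.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with the
    one-sided upper-tail normal probability (independent-samples formula).
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must satisfy |r| < 1")
    if min(n1, n2) <= 3:
        raise ValueError("sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return CorrelationComparison(r1, r2, n1, n2, z, normal_upper_tail(z))


def steiger_rz_compare(
    r1: float, r2: float, r12: float, n: int
) -> CorrelationComparison:
    """Steiger's Z for dependent correlations sharing one variable.

    ``r1`` and ``r2`` correlate two methods with a common reference on the
    same ``n`` subjects; ``r12`` is the correlation between the methods.
    """
    for r in (r1, r2, r12):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n <= 3:
        raise ValueError("sample size must exceed 3")
    rbar2 = ((r1 + r2) / 2.0) ** 2
    cov = r12 * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r12**2)
    denom = (1 - rbar2) ** 2
    z = (math.atanh(r1) - math.atanh(r2)) * math.sqrt(
        (n - 3) / (2 * (1 - cov / denom))
    )
    return CorrelationComparison(r1, r2, n, n, z, normal_upper_tail(z))


def paired_t_test(d1, d2) -> tuple[float, float]:
    """Paired Student t-test on d1 - d2; returns (t, two-sided p)."""
    d1, d2 = _pair(d1, d2, 2)
    if np.std(d1 - d2, ddof=1) == 0:
        raise ValueError("differences have zero variance; t undefined")
    res = sps.ttest_rel(d1, d2)
    return float(res.statistic), float(res.pvalue)


#: Upper edges (inclusive) of the R^2 association bins.
ASSOCIATION_BINS = (
    (0.25, "weak"),
    (0.5, "moderate"),
    (0.8, "strong"),
    (1.0, "very strong"),
)


def categorize_association(r_squared: float) -> str:
    """Conventional association category from the determination coefficient."""
    if not 0 <= r_squared <= 1:
        raise ValueError("R^2 must lie in [0, 1]")
    for upper, name in ASSOCIATION_BINS:
        if r_squared <= upper:
            return name
    raise AssertionError("unreachable")


@dataclass
class MethodPairResult:
    """Agreement summary of one (method, reference) pair for one metric."""

    method: str
    reference: str
    metric: str
    n: int
    r_squared: float
    beta1: float
    beta0: float
    mean_diff: float
    loa_low: float
    loa_high: float
    mean_pct_diff: float
    t_stat: float
    t_p: float
    category: str


@dataclass
class AgreementReport:
    """All pairwise agreement results, one row per (pair, metric)."""

    results: list[MethodPairResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.results])

    def to_dict(self) -> list[dict]:
        return [asdict(r) for r in self.results]


METRICS = ("ea", "peak_e", "peak_a")


def run_comparison(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    metrics: Sequence[str] = METRICS,
) -> AgreementReport:
    """Run the full agreement analysis on a tidy measurement table.

    ``table`` must have columns ``subject_id, metric, method, value``;
    ``pairs`` lists (method, reference) comparisons, e.g.
    ``[("lvvel", "echo"), ("mvvel", "lvvel")]``.  Rows with a missing value
    in either column of a pair are dropped pairwise (with a logged count).
    """
    required = {"subject_id", "metric", "method", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    known_methods = set(table["method"].unique())
    results = []
    for method, reference in pairs:
        for name in (method, reference):
            if name not in known_methods:
                raise ValueError(f"unknown method column '{name}'")
        for metric in metrics:
            sub = table[table["metric"] == metric]
            wide = sub.pivot_table(
                index="subject_id", columns="method", values="value", aggfunc="first"
            )
            if method not in wide.columns or reference not in wide.columns:
                raise ValueError(f"metric '{metric}' missing for pair {method}/{reference}")
            paired = wide[[method, reference]].dropna()
            dropped = len(wide) - len(paired)
            if dropped:
                logger.info(
                    "run_comparison: dropped %d incomplete subject(s) for %s vs %s (%s)",
                    dropped,
                    method,
                    reference,
                    metric,
                )
            if len(paired) < 4:
                raise ValueError(
                    f"fewer than 4 complete rows for {method} vs {reference} ({metric})"
                )
            y = paired[method].to_numpy()
            x = paired[reference].to_numpy()
            beta1, beta0, r2 = ols_regression(x, y)
            mean_diff, lo, hi, pct = bland_altman(y, x)
            try:
                t_stat, t_p = paired_t_test(y, x)
            except ValueError:
                # zero-variance differences (e.g. identical methods): the
                # paired t is undefined; agreement is already exact
                t_stat, t_p = float("nan"), float("nan")
                logger.info(
                    "run_comparison: zero-variance differences for %s vs %s (%s); "
                    "paired t undefined",
                    method,
                    reference,
                    metric,
                )
            results.append(
                MethodPairResult(
                    method=method,
                    reference=reference,
                    metric=metric,
                    n=len(paired),
                    r_squared=r2,
                    beta1=beta1,
                    beta0=beta0,
                    mean_diff=mean_diff,
                    loa_low=lo,
                    loa_high=hi,
                    mean_pct_diff=pct,
                    t_stat=t_stat,
                    t_p=t_p,
                    category=categorize_association(r2),
                )
            )
    return AgreementReport(results=results)
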