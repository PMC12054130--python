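"""Cohort statistics: Spearman rank correlation with an exact small-sample
permutation test, the paired t comparison against the clinical prism
measurement, and the cohort summary.

For small samples without ties the two-sided Spearman p-value is computed
from the exact permutation null distribution of the rank statistic rather
than the large-sample t approximation.  The exact distribution is obtained
by dynamic programming over rank assignments (distribution of
``T = Σ i·R_i`` over all ``n!`` permutations, to which ``S = Σ d_i²`` and
``r_s`` are affinely related), which is feasible up to n = 13 — the cohort
size this package targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sp_stats

from .errors import DegenerateTestError, ParameterError, UndefinedCorrelationError
from .units import deg_to_pd

__all__ = [
    "CorrelationResult",
    "CohortSummary",
    "spearman_rank",
    "paired_t_test",
    "summarize_cohort",
]

#: Sample size up to which the exact test runs automatically (no ties).
EXACT_AUTO_N = 9
#: Hard cap for the exact permutation distribution (opt-in above EXACT_AUTO_N).
EXACT_MAX_N = 13


@dataclass
class CorrelationResult:
    """Spearman rank correlation with its two-sided p-value."""

    rs: float
    p_value: float
    n: int
    method: str  # "exact_permutation" | "t_approximation"
    s_statistic: float  # sum of squared rank differences


@lru_cache(maxsize=8)
def _rank_product_counts(n: int) -> np.ndarray:
    """Counts of ``T = Σ i·R_i`` over all permutations R of 1..n.

    Subset dynamic programming: positions are filled in order and
    ``dp[mask]`` holds the distribution of the partial sum using exactly
    the ranks in ``mask``.  Returns an int64 array ``c`` with ``c[t]`` the
    number of permutations achieving ``T = t`` (sums to n!).
    """
    t_max = n * (n + 1) * (2 * n + 1) // 6
    dp = np.zeros((1 << n, t_max + 1), dtype=np.int64)
    dp[0, 0] = 1
    for mask in range(1 << n):
        row = dp[mask]
        if not row.any():
            continue
        pos = bin(mask).count("1") + 1  # next position to fill (1-based)
        if pos > n:
            continue
        for rank in range(1, n + 1):
            bit = 1 << (rank - 1)
            if mask & bit:
                continue
            shift = pos * rank
            dp[mask | bit, shift:] += row[: t_max + 1 - shift]
    return dp[(1 << n) - 1]


def exact_spearman_p(n: int, s_statistic: float) -> float:
    """Exact two-sided p-value for Spearman's S (no ties), by full
    enumeration of the permutation null via dynamic programming."""
    if n > EXACT_MAX_N:
        raise ParameterError(f"exact permutation distribution limited to n <= {EXACT_MAX_N}")
    counts = _rank_product_counts(n)
    t_vals = np.arange(counts.size)
    # T = Σi² − S/2; the null distribution of T is symmetric about its mean.
    t_obs = n * (n + 1) * (2 * n + 1) / 6.0 - s_statistic / 2.0
    center2 = n * (n + 1) ** 2 / 2.0  # 2 × mean of T
    dev = np.abs(2 * t_vals - center2)
    dev_obs = abs(2 * t_obs - center2)
    p = counts[dev >= dev_obs - 1e-9].sum() / math.factorial(n)
    return float(min(p, 1.0))


def spearman_rank(x, y, method: str = "auto") -> CorrelationResult:
    """Spearman rank correlation with exact or approximate two-sided p.

    ``method``:

    * ``"auto"`` — exact permutation test when ``n <= 9`` and there are no
      ties, otherwise the t approximation
      ``t = r_s √((n−2)/(1−r_s²))`` on ``n − 2`` df;
    * ``"exact_s"`` — exact permutation test for ``n <= 13`` (no ties);
    * ``"t"`` — force the t approximation.

    Raises :class:`UndefinedCorrelationError` for a constant input vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ParameterError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")

    rx = sp_stats.rankdata(x)
    ry = sp_stats.rankdata(y)
    s_stat = float(np.sum((rx - ry) ** 2))
    ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if ties:
        rs = float(np.corrcoef(rx, ry)[0, 1])
    else:
        rs = 1.0 - 6.0 * s_stat / (n**3 - n)

    exact_ok = not ties and (
        (method == "auto" and n <= EXACT_AUTO_N)
        or (method == "exact_s" and n <= EXACT_MAX_N)
    )
    if method == "exact_s" and (ties or n > EXACT_MAX_N):
        raise ParameterError(
            "exact_s requires no ties and n <= 13; use method='auto' or 't'"
        )
    if exact_ok:
        p = exact_spearman_p(n, s_stat)
        used = "exact_permutation"
    else:
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * math.sqrt((n - 2) / (1.0 - rs**2))
            p = 2.0 * sp_stats.t.sf(abs(t), n - 2)
        used = "t_approximation"
    return CorrelationResult(rs=rs, p_value=float(p), n=n, method=used, s_statistic=s_stat)


def paired_t_test(x, y) -> tuple[float, float, float]:
    """Two-sided paired t-test on ``x − y``; returns ``(t, p, mean_diff)``.

    Raises :class:`DegenerateTestError` when the differences have zero
    variance (including ``x == y``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ParameterError("need >= 2 pairs of equal length")
    d = x - y
    if np.ptp(d) == 0:
        raise DegenerateTestError("differences have zero variance; paired t undefined")
    res = sp_stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), float(np.mean(d))


def _mean_sd(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(np.mean(v)), float(np.std(v, ddof=1))


@dataclass
class CohortSummary:
    """Group-level summary over the phoric subgroup plus the paired
    device-vs-APCT comparison over all subjects."""

    n_by_diagnosis: dict
    mean_sd_angle_deg: tuple[float, float]
    mean_sd_angle_pd: tuple[float, float]
    mean_sd_peak_speed: tuple[float, float]
    mean_sd_stab_time_s: tuple[float, float]
    mean_sd_overshoot_deg: tuple[float, float]
    category_counts: dict
    corr_angle_speed: CorrelationResult
    corr_angle_stabtime: CorrelationResult
    corr_depth_speed: CorrelationResult
    apct_vs_device: dict  # t, p, mean_diff_pd (APCT − device)

    def to_dict(self) -> dict:
        def corr(c: CorrelationResult) -> dict:
            return {
                "rs": c.rs,
                "p_value": c.p_value,
                "n": c.n,
                "method": c.method,
                "s_statistic": c.s_statistic,
            }

        return {
            "n_by_diagnosis": self.n_by_diagnosis,
            "angle_deg": {"mean": self.mean_sd_angle_deg[0], "sd": self.mean_sd_angle_deg[1]},
            "angle_pd": {"mean": self.mean_sd_angle_pd[0], "sd": self.mean_sd_angle_pd[1]},
            "peak_speed_deg_s": {
                "mean": self.mean_sd_peak_speed[0],
                "sd": self.mean_sd_peak_speed[1],
            },
            "stabilization_time_s": {
                "mean": self.mean_sd_stab_time_s[0],
                "sd": self.mean_sd_stab_time_s[1],
            },
            "overshoot_depth_deg": {
                "mean": self.mean_sd_overshoot_deg[0],
                "sd": self.mean_sd_overshoot_deg[1],
            },
            "category_counts": self.category_counts,
            "corr_angle_speed": corr(self.corr_angle_speed),
            "corr_angle_stabtime": corr(self.corr_angle_stabtime),
            "corr_depth_speed": corr(self.corr_depth_speed),
            "apct_vs_device": self.apct_vs_device,
        }


def summarize_cohort(records) -> CohortSummary:
    """Summarize a cohort of records with computed metrics.

    Group means ± SD, the overshoot category counts and the three Spearman
    correlations (angle↔speed, angle↔stabilization time, depth↔speed) are
    computed over the phoric (exophoria) subgroup; manifest cases enter
    only the paired device-vs-APCT comparison, which converts each
    subject's device angle to prism diopters and tests APCT − device.

    The exact permutation p-value is used for the correlations whenever the
    subgroup is small enough (n ≤ 13, no ties).
    """
    missing = [r.subject_id for r in records if r.metrics is None]
    if missing:
        raise ParameterError(f"records without computed metrics: {missing}")

    n_by_dx: dict[str, int] = {}
    for r in records:
        n_by_dx[r.diagnosis] = n_by_dx.get(r.diagnosis, 0) + 1

    phoric = [r for r in records if r.diagnosis == "exophoria"]
    if len(phoric) < 3:
        raise ParameterError("need >= 3 exophoria records for cohort correlations")

    angle = np.array([r.metrics.angle_deg for r in phoric])
    angle_pd = np.array([r.metrics.angle_pd for r in phoric])
    speed = np.array([r.metrics.peak_speed_deg_s for r in phoric])
    stab = np.array([r.metrics.stabilization_time_s for r in phoric])
    depth = np.array([r.metrics.overshoot_depth_deg for r in phoric])

    counts = {"gt1": 0, "mid": 0, "lt0p5": 0}
    for r in phoric:
        counts[r.metrics.overshoot_category] += 1

    def corr(u, v) -> CorrelationResult:
        method = "exact_s" if len(u) <= EXACT_MAX_N else "auto"
        try:
            return spearman_rank(u, v, method=method)
        except ParameterError:  # ties at n in (9, 13]: fall back to t
            return spearman_rank(u, v, method="t")

    apct_all = np.array([r.apct_pd for r in records])
    device_all = np.array([deg_to_pd(r.metrics.angle_deg) for r in records])
    t_stat, p_val, mean_diff = paired_t_test(apct_all, device_all)

    return CohortSummary(
        n_by_diagnosis=n_by_dx,
        mean_sd_angle_deg=_mean_sd(angle),
        mean_sd_angle_pd=_mean_sd(angle_pd),
        mean_sd_peak_speed=_mean_sd(speed),
        mean_sd_stab_time_s=_mean_sd(stab),
        mean_sd_overshoot_deg=_mean_sd(depth),
        category_counts=counts,
        corr_angle_speed=corr(angle, speed),
        corr_angle_stabtime=corr(angle, stab),
        corr_depth_speed=corr(depth, speed),
        apct_vs_device={"t": t_stat, "p": p_val, "mean_diff_pd": mean_diff},
    )
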