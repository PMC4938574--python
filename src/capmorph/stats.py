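"""Group-comparison statistics: one-way ANOVA, Tukey HSD, two-sample t.

The F and t statistics and the Tukey studentized-range machinery are
implemented from first principles (sums of squares, the studentized-range
CDF by numerical integration); only the elementary normal / F / t
distribution functions come from scipy.  The test suite validates the
ANOVA p against an exact permutation oracle and the studentized-range CDF
against an independent high-accuracy implementation.

The experimental unit is the animal: callers are expected to pass one value
per animal (e.g. the mean over that animal's capillaries), not per-capillary
values.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps
from scipy.optimize import brentq


@dataclass(frozen=True)
class GroupSample:
    label: str
    values: tuple[float, ...]

    def __init__(self, label: str, values: Sequence[float]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    statistic: float
    adjusted_p: float


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    method: str = ""
    pairwise: Optional[list[PairwiseResult]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


class DegenerateDataError(ValueError):
    """All variability is zero; the test statistic is undefined."""


def _check_groups(groups: Sequence[GroupSample], min_groups: int = 2) -> None:
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(groups)}")
    for g in groups:
        if g.n < 2:
            raise ValueError(
                f"group {g.label!r} has {g.n} values; variance-based tests need >= 2"
            )


def _sums_of_squares(groups: Sequence[GroupSample]) -> tuple[float, float, int, int]:
    """(SS_between, SS_within, df_between, df_within)."""
    k = len(groups)
    all_values = np.concatenate([np.asarray(g.values) for g in groups])
    grand_mean = all_values.mean()
    ss_between = sum(g.n * (g.mean - grand_mean) ** 2 for g in groups)
    ss_within = sum(
        float(((np.asarray(g.values) - g.mean) ** 2).sum()) for g in groups
    )
    return float(ss_between), float(ss_within), k - 1, len(all_values) - k


def one_way_anova(groups: Sequence[GroupSample]) -> TestResult:
    """F = MS_between / MS_within with the upper-tail F p-value."""
    _check_groups(groups)
    ss_b, ss_w, df_b, df_w = _sums_of_squares(groups)
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        if ms_b == 0.0:
            raise DegenerateDataError(
                "zero between- and within-group variance: F is undefined"
            )
        return TestResult(
            statistic=math.inf, df=(df_b, df_w), p_value=0.0, method="one-way ANOVA"
        )
    f_stat = ms_b / ms_w
    p = float(_sps.f.sf(f_stat, df_b, df_w))
    return TestResult(statistic=f_stat, df=(df_b, df_w), p_value=p, method="one-way ANOVA")


# ---------------------------------------------------------------------------
# studentized range distribution (numerical integration)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gauss_legendre(n: int, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.legendre.leggauss(n)
    half = 0.5 * (b - a)
    return a + half * (nodes + 1.0), half * weights


def _range_cdf_normal(w: np.ndarray, k: int) -> np.ndarray:
    """P(range of k i.i.d. standard normals < w), vectorised over w."""
    w = np.atleast_1d(np.asarray(w, dtype=float))
    z, wz = _gauss_legendre(240, -9.0, 9.0)
    # matrix of Phi(z_i) - Phi(z_i - w_j)
    span = _sps.norm.cdf(z)[:, None] - _sps.norm.cdf(z[:, None] - w[None, :])
    span = np.clip(span, 0.0, None)
    integrand = _sps.norm.pdf(z)[:, None] * span ** (k - 1)
    out = k * (wz[:, None] * integrand).sum(axis=0)
    return np.clip(out, 0.0, 1.0)


@lru_cache(maxsize=65536)
def studentized_range_cdf(q: float, k: int, df: float) -> float:
    """CDF of the studentized range Q(k, df), by double numerical integration.

    Integrates the normal-range probability against the density of the
    scaled chi variable s/σ with ``df`` degrees of freedom, on tensorised
    Gauss–Legendre grids (accurate to well below 1e-6).
    """
    if q <= 0.0:
        return 0.0
    if k < 2:
        raise ValueError("studentized range needs k >= 2 groups")
    if math.isinf(df):
        return float(_range_cdf_normal(np.array([q]), k)[0])
    # density of u = s/sigma: f(u) ∝ u^{df-1} exp(-df u^2 / 2)
    log_const = (
        0.5 * df * math.log(df) - math.lgamma(0.5 * df) - (0.5 * df - 1.0) * math.log(2.0)
    )
    u_hi = 1.0 + 14.0 / math.sqrt(df)
    u, wu = _gauss_legendre(240, 1e-12, u_hi)
    log_f = log_const + (df - 1.0) * np.log(u) - 0.5 * df * u * u
    f_u = np.exp(log_f)
    inner = _range_cdf_normal(q * u, k)
    return float(min((wu * f_u * inner).sum(), 1.0))


def studentized_range_sf(q: float, k: int, df: float) -> float:
    return max(0.0, 1.0 - studentized_range_cdf(q, k, df))


def studentized_range_quantile(p: float, k: int, df: float) -> float:
    """Inverse CDF, accurate to the integration tolerance (~1e-6)."""
    if not 0.0 < p < 1.0:
        raise ValueError("quantile level must be in (0, 1)")
    lo, hi = 1e-6, 2.0
    while studentized_range_cdf(hi, k, df) < p:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("quantile bracket failed")
    return float(brentq(lambda q: studentized_range_cdf(q, k, df) - p, lo, hi, xtol=1e-8))


def tukey_hsd(groups: Sequence[GroupSample]) -> TestResult:
    """All-pairs Tukey(-Kramer) comparison following a one-way ANOVA.

    The returned :class:`TestResult` carries the ANOVA F and p; every pair
    appears in ``pairwise`` with its studentized-range statistic and
    adjusted p.
    """
    anova = one_way_anova(groups)
    k = len(groups)
    _, ss_w, _, df_w = _sums_of_squares(groups)
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        raise DegenerateDataError("zero within-group variance: Tukey q is undefined")
    pairwise: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = b.mean - a.mean
            se = math.sqrt(0.5 * ms_w * (1.0 / a.n + 1.0 / b.n))
            q = abs(diff) / se
            p_adj = studentized_range_sf(q, k, df_w)
            pairwise.append(
                PairwiseResult(
                    group_a=a.label,
                    group_b=b.label,
                    mean_diff=diff,
                    statistic=q,
                    adjusted_p=p_adj,
                )
            )
    return TestResult(
        statistic=anova.statistic,
        df=anova.df,
        p_value=anova.p_value,
        method="one-way ANOVA + Tukey HSD",
        pairwise=pairwise,
    )


def two_sample_t(
    a: GroupSample, b: GroupSample, welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test; pooled variance by default, Welch optional."""
    _check_groups([a, b])
    xa = np.asarray(a.values)
    xb = np.asarray(b.values)
    va = float(np.var(xa, ddof=1))
    vb = float(np.var(xb, ddof=1))
    diff = float(xa.mean() - xb.mean())
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            warnings.warn(
                "zero variance in both groups with equal means; p = 1 by convention",
                RuntimeWarning,
                stacklevel=2,
            )
            return TestResult(0.0, (a.n + b.n - 2,), 1.0, method="two-sample t (pooled)")
        return TestResult(
            math.copysign(math.inf, diff),
            (a.n + b.n - 2,),
            0.0,
            method="two-sample t (pooled)",
        )
    if welch:
        se2a, se2b = va / a.n, vb / b.n
        se = math.sqrt(se2a + se2b)
        df = (se2a + se2b) ** 2 / (
            se2a**2 / (a.n - 1) + se2b**2 / (b.n - 1)
        )
        method = "two-sample t (Welch)"
    else:
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = a.n + b.n - 2
        method = "two-sample t (pooled)"
    t = diff / se
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=(df,), p_value=min(p, 1.0), method=method)


def paired_t(differences: Sequence[float]) -> TestResult:
    """One-sample t on paired differences (used for modality comparisons)."""
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("paired t needs at least 2 differences")
    sd = float(np.std(d, ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(0.0, (len(d) - 1,), 1.0, method="paired t")
        return TestResult(math.copysign(math.inf, mean), (len(d) - 1,), 0.0, method="paired t")
    t = mean / (sd / math.sqrt(len(d)))
    p = float(2.0 * _sps.t.sf(abs(t), len(d) - 1))
    return TestResult(statistic=t, df=(len(d) - 1,), p_value=min(p, 1.0), method="paired t")
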