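"""Group-comparison statistics: Levene homogeneity test, one-way ANOVA
(raw-data and summary-statistics modes), Student-Newman-Keuls post hoc,
and Pearson correlation.

The summary-statistics ANOVA mode reconstructs the full decomposition
from per-group (mean, SEM, n) alone, which lets published tables be
re-analyzed without raw data: SD = SEM*sqrt(n), SS_within =
sum((n_i - 1) * sd_i^2), SS_between = sum(n_i * (m_i - grand_mean)^2).
Raw and summary modes agree exactly when summaries come from the raw
values.

The SNK procedure sorts the k group means and compares each pair with
the studentized range statistic q = |m_i - m_j| / sqrt(MS_within / n),
referred to the upper-alpha quantile of the studentized range for the
number of means spanned (the "stretch" r) and the ANOVA error df.  The
defining stepwise rule is enforced: a pair inside a non-significant
range is never declared significant.  The studentized-range quantile is
computed from first principles by root-finding on a quadrature-
evaluated CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import lgamma

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.stats import f as f_dist
from scipy.stats import norm, t as t_dist

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PairComparison",
    "PosthocResult",
    "levene_test",
    "oneway_anova",
    "studentized_range_cdf",
    "studentized_range_quantile",
    "snk_posthoc",
    "pearson_correlation",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean +/- SEM with sample size; SD = SEM*sqrt(n)."""

    label: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        n = len(values)
        return cls(
            label=label,
            mean=float(np.mean(values)),
            sem=float(np.std(values, ddof=1) / np.sqrt(n)),
            n=n,
        )


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ms_between: float
    ms_within: float


@dataclass(frozen=True)
class PairComparison:
    group_a: str
    group_b: str
    diff: float
    q: float
    stretch: int
    q_crit: float
    significant: bool


@dataclass(frozen=True)
class PosthocResult:
    comparisons: list[PairComparison]
    alpha: float
    df_error: int
    unequal_n: bool = False

    def is_significant(self, a: str, b: str) -> bool:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {a, b}:
                return c.significant
        raise KeyError(f"no comparison between {a!r} and {b!r}")

    def significant_pairs(self) -> set[frozenset]:
        return {
            frozenset((c.group_a, c.group_b))
            for c in self.comparisons
            if c.significant
        }


def levene_test(groups: list) -> tuple[float, float]:
    """Classic (mean-centered) Levene test for homogeneity of variance.

    W = [(N-k)/(k-1)] * sum(n_i*(zbar_i - zbar)^2) / sum((z_ij - zbar_i)^2)
    with z_ij = |x_ij - xbar_i|, referred to F(k-1, N-k).  Degenerate
    all-equal-spread inputs return (0, 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    big_n = int(ns.sum())
    z = [np.abs(g - g.mean()) for g in groups]
    zbar_i = np.array([zi.mean() for zi in z])
    zbar = float(np.concatenate(z).mean())
    num = float(np.sum(ns * (zbar_i - zbar) ** 2))
    den = float(sum(np.sum((zi - m) ** 2) for zi, m in zip(z, zbar_i)))
    if den <= 0:
        # all groups internally constant-spread: W is 0/0 (no evidence,
        # return 0) unless the spreads differ, where W diverges
        return (0.0, 1.0) if num <= 0 else (float("inf"), 0.0)
    w = (big_n - k) / (k - 1) * num / den
    return w, float(f_dist.sf(w, k - 1, big_n - k))


def oneway_anova(
    groups: list | None = None,
    summaries: list[GroupSummary] | None = None,
) -> AnovaResult:
    """One-way fixed-effects ANOVA, from raw values or from summaries.

    Exactly one of ``groups`` (list of value arrays) or ``summaries``
    (list of :class:`GroupSummary`) must be given; the raw mode reduces
    to the summary mode via the algebraic identity, so the two agree
    exactly when summaries are computed from the raw data.
    """
    if (groups is None) == (summaries is None):
        raise ValueError("pass exactly one of groups or summaries")
    if groups is not None:
        summaries = [GroupSummary.from_values(str(i), g) for i, g in enumerate(groups)]
    k = len(summaries)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    big_n = ns.sum()
    df_b = k - 1
    df_w = int(big_n - k)
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = float(np.sum(ns * means) / big_n)
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(np.sum((ns - 1) * sds**2))
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0:
        f = np.inf if ms_b > 0 else 0.0
    else:
        f = ms_b / ms_w
    return AnovaResult(
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p=float(f_dist.sf(f, df_b, df_w)),
        ms_between=ms_b,
        ms_within=ms_w,
    )


# ---------------------------------------------------------------------------
# Studentized range distribution, from first principles.
#
# For r independent standard normals, P(range <= w) =
#     r * Int phi(z) * [Phi(z) - Phi(z - w)]^(r-1) dz.
# The studentized range Q = range / S, with S = sqrt(chi2_df / df)
# independent of the range, has
#     P(Q <= q) = Int_0^inf f_S(s) * P(range <= q*s) ds.
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)
_Z_LO, _Z_HI = -8.5, 8.5
_Z = 0.5 * (_Z_HI - _Z_LO) * _GL_NODES + 0.5 * (_Z_HI + _Z_LO)
_ZW = 0.5 * (_Z_HI - _Z_LO) * _GL_WEIGHTS
_PHI_Z = norm.pdf(_Z)
_CDF_Z = norm.cdf(_Z)


def _range_cdf(w: float, r: int) -> float:
    """P(range of r iid standard normals <= w), Gauss-Legendre."""
    if w <= 0:
        return 0.0
    val = r * np.sum(_ZW * _PHI_Z * (_CDF_Z - norm.cdf(_Z - w)) ** (r - 1))
    return float(min(max(val, 0.0), 1.0))


def _chi_scale_logpdf(s: np.ndarray, df: float) -> np.ndarray:
    """log density of S = sqrt(chi2_df / df)."""
    return (
        0.5 * df * np.log(df)
        + (df - 1.0) * np.log(s)
        - 0.5 * df * s**2
        + np.log(2.0)
        - 0.5 * df * np.log(2.0)
        - lgamma(df / 2.0)
    )


def studentized_range_cdf(q: float, r: int, df: float) -> float:
    """CDF of the studentized range of r means with df error df.

    ``df=inf`` gives the plain range distribution.  Quadrature accuracy
    is well below the 1e-3 contract of the quantile function.
    """
    if q <= 0:
        return 0.0
    if r < 2 or df < 1:
        raise ValueError("need r >= 2 and df >= 1")
    if np.isinf(df):
        return _range_cdf(q, r)

    def integrand(s: float) -> float:
        return float(np.exp(_chi_scale_logpdf(np.array(s), df))) * _range_cdf(q * s, r)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(min(max(val, 0.0), 1.0))


@lru_cache(maxsize=4096)
def studentized_range_quantile(p: float, r: int, df: float) -> float:
    """Upper-``p`` quantile of the studentized range (the critical value
    q such that P(Q > q) = p), accurate to about 1e-4.

    Computed by Brent root-finding on the quadrature CDF; raises on
    non-convergence with the bracketing diagnostics.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    target = 1.0 - p
    lo, hi = 1e-6, 20.0
    while studentized_range_cdf(hi, r, df) < target:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError(
                f"studentized range quantile failed to bracket: "
                f"p={p}, r={r}, df={df}, cdf({hi / 2})="
                f"{studentized_range_cdf(hi / 2, r, df)}"
            )
    return float(
        brentq(lambda q: studentized_range_cdf(q, r, df) - target, lo, hi, xtol=1e-6)
    )


def snk_posthoc(
    summaries: list[GroupSummary],
    ms_within: float | None = None,
    df_error: int | None = None,
    alpha: float = 0.05,
) -> PosthocResult:
    """Student-Newman-Keuls stepwise multiple comparisons.

    Means are ordered; each pair spanning r ordered means is tested with
    q = |m_i - m_j| / sqrt(MS_within / n) against the upper-alpha
    studentized-range quantile for (r, df_error).  Pairs enclosed by any
    non-significant wider range are declared non-significant without
    regard to their own q (the stepwise containment rule).  With unequal
    group sizes the harmonic mean n is used and a warning issued.
    ``ms_within``/``df_error`` default to the one-way ANOVA on the same
    summaries.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    if ms_within is None or df_error is None:
        an = oneway_anova(summaries=summaries)
        ms_within = an.ms_within if ms_within is None else ms_within
        df_error = an.df_within if df_error is None else df_error

    ns = [s.n for s in summaries]
    unequal = len(set(ns)) > 1
    if unequal:
        warnings.warn(
            "unequal group sizes: SNK uses the harmonic mean n", stacklevel=2
        )
        n_eff = len(ns) / np.sum(1.0 / np.asarray(ns, dtype=float))
    else:
        n_eff = ns[0]
    se = np.sqrt(ms_within / n_eff) if ms_within > 0 else 0.0

    order = sorted(range(len(summaries)), key=lambda i: summaries[i].mean)
    means = [summaries[i].mean for i in order]
    labels = [summaries[i].label for i in order]
    k = len(means)

    sig: dict[tuple[int, int], bool] = {}
    comps: list[PairComparison] = []
    for stretch in range(k, 1, -1):
        for i in range(0, k - stretch + 1):
            j = i + stretch - 1
            diff = means[j] - means[i]
            q = diff / se if se > 0 else (np.inf if diff > 0 else 0.0)
            q_crit = studentized_range_quantile(alpha, stretch, float(df_error))
            blocked = any(
                not sig[(a, b)]
                for (a, b) in sig
                if a <= i and b >= j and (a, b) != (i, j)
            )
            significant = (not blocked) and q > q_crit
            sig[(i, j)] = significant
            comps.append(
                PairComparison(
                    group_a=labels[i],
                    group_b=labels[j],
                    diff=float(diff),
                    q=float(q),
                    stretch=stretch,
                    q_crit=float(q_crit),
                    significant=significant,
                )
            )
    return PosthocResult(
        comparisons=comps, alpha=alpha, df_error=int(df_error), unequal_n=unequal
    )


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Pearson r with its t statistic (n-2 df) and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return r, float(t), p
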