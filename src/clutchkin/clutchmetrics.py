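"""Clutch-quality metrics and morphometric computations.

Emergence success summarises a nest inventory as the fraction of eggs that
produced hatchlings which left the nest unaided.  Female body size is
summarised as the surface area of a half ellipsoid fitted to the carapace:
the two straight measurements give the length and width semi-axes, and the
depth semi-axis is recovered from the curved length, treated as half the
perimeter of the length-depth ellipse.  A thin statistics layer wraps the
standard two-sample comparisons (t, variance-ratio F, chi-square) and
ordinary least-squares regression used when comparing clutch groups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "NestInventory",
    "MorphometricRecord",
    "emergence_success",
    "half_ellipsoid_sa",
    "solve_depth_semiaxis",
    "group_comparisons",
    "chi_square",
    "linear_fit",
]

#: exponent of the Thomsen-type ellipsoid surface-area approximation
_THOMSEN_P = 1.6


@dataclass(frozen=True)
class NestInventory:
    """Post-emergence nest inventory counts.

    Attributes
    ----------
    hatched : int
        Number of hatched eggs (``H``).
    total : int
        Total number of eggs in the clutch (``T``).
    live_in_nest : int
        Live hatchlings found in the nest at inventory (``L``).
    dead_in_nest : int
        Dead hatchlings found in the nest at inventory (``D``).
    """

    hatched: int
    total: int
    live_in_nest: int
    dead_in_nest: int

    def __post_init__(self) -> None:
        H, T, L, D = self.hatched, self.total, self.live_in_nest, self.dead_in_nest
        if min(H, T, L, D) < 0:
            raise ValueError("inventory counts must be non-negative")
        if H > T:
            raise ValueError(f"hatched ({H}) exceeds total eggs ({T})")
        if L + D > H:
            raise ValueError(f"in-nest hatchlings ({L}+{D}) exceed hatched ({H})")


def emergence_success(inv: NestInventory) -> float:
    """Fraction of eggs yielding hatchlings that left the nest unaided.

    ``E = (H - (L + D)) / T``.  Returns NaN (with a warning) for an empty
    clutch, where the proportion is undefined.
    """
    if inv.total == 0:
        warnings.warn("emergence success undefined for an empty clutch (T=0)")
        return math.nan
    return (inv.hatched - (inv.live_in_nest + inv.dead_in_nest)) / inv.total


def _ramanujan_perimeter(a: float, c: float) -> float:
    """Ramanujan's first approximation to the perimeter of an ellipse."""
    return math.pi * (3.0 * (a + c) - math.sqrt((3.0 * a + c) * (a + 3.0 * c)))


def solve_depth_semiaxis(scl: float, ccl: float, tol: float = 1e-9) -> float:
    """Recover the depth semi-axis ``c`` from the curved carapace length.

    The curved length is modelled as half the perimeter of the ellipse with
    semi-axes ``a = SCL/2`` and ``c``; the perimeter uses Ramanujan's
    approximation and is inverted numerically.
    """
    if scl <= 0 or ccl <= 0:
        raise ValueError("carapace measurements must be positive")
    a = scl / 2.0
    # as c -> 0 the half-perimeter tends to 2a, so CCL must exceed the
    # straight length for a positive depth to exist
    if ccl <= 2.0 * a:
        raise ValueError(
            f"no positive depth semi-axis: CCL ({ccl}) must exceed SCL ({scl})"
        )
    hi = 2.0 * ccl  # half-perimeter ~ (pi/2) c for c >> a, so this brackets
    root = optimize.brentq(
        lambda c: 0.5 * _ramanujan_perimeter(a, c) - ccl, 1e-12, hi, xtol=tol
    )
    return root


def half_ellipsoid_sa(scl: float, scw: float, ccl: float) -> float:
    """Half-ellipsoid carapace surface area in cm^2.

    Semi-axes are ``a = SCL/2``, ``b = SCW/2`` and ``c`` solved from CCL by
    :func:`solve_depth_semiaxis`.  The full ellipsoid area uses the
    Thomsen-type approximation with exponent 1.6 and is divided by two
    because only the dorsal surface is measured.
    """
    if scw <= 0:
        raise ValueError("carapace measurements must be positive")
    a = scl / 2.0
    b = scw / 2.0
    c = solve_depth_semiaxis(scl, ccl)
    p = _THOMSEN_P
    mean_term = (a**p * b**p + a**p * c**p + b**p * c**p) / 3.0
    return 4.0 * math.pi * mean_term ** (1.0 / p) / 2.0


@dataclass(frozen=True)
class MorphometricRecord:
    """Carapace measurements (cm) with derived half-ellipsoid geometry."""

    individual_id: str
    ccl: float
    ccw: float
    scl: float
    scw: float
    a: float = field(init=False)
    b: float = field(init=False)
    c: float = field(init=False)
    surface_area: float = field(init=False)

    def __post_init__(self) -> None:
        if min(self.ccl, self.ccw, self.scl, self.scw) <= 0:
            raise ValueError("all carapace measurements must be positive")
        object.__setattr__(self, "a", self.scl / 2.0)
        object.__setattr__(self, "b", self.scw / 2.0)
        object.__setattr__(self, "c", solve_depth_semiaxis(self.scl, self.ccl))
        object.__setattr__(
            self, "surface_area", half_ellipsoid_sa(self.scl, self.scw, self.ccl)
        )


@dataclass(frozen=True)
class TwoSampleReport:
    """Pooled t test and variance-ratio F test for two groups."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    var1: float
    var2: float
    t_stat: float
    t_df: int
    t_p_two_tailed: float
    t_p_one_tailed: float
    f_stat: float
    f_df: tuple[int, int]
    f_p_two_tailed: float
    f_p_one_tailed: float
    degenerate_variance: bool


def group_comparisons(group1, group2) -> TwoSampleReport:
    """Two-sample comparison: pooled-variance t test and F variance-ratio test.

    One-tailed p-values are reported alongside two-tailed ones because the
    direction convention of historical analyses is not always stated.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    n1, n2 = len(x), len(y)
    v1 = float(np.var(x, ddof=1))
    v2 = float(np.var(y, ddof=1))
    degenerate = v1 == 0.0 and v2 == 0.0
    if degenerate:
        warnings.warn("both groups have zero variance; t undefined, reported as 0")
        t_stat, p2 = 0.0, 1.0
    else:
        t_stat, p2 = stats.ttest_ind(x, y, equal_var=True)
        t_stat, p2 = float(t_stat), float(p2)
    df = n1 + n2 - 2
    p1 = p2 / 2.0 if not degenerate else 0.5
    if v2 == 0.0:
        f_stat = math.inf if v1 > 0 else 1.0
        fp_upper = 0.0 if v1 > 0 else 1.0
    else:
        f_stat = v1 / v2
        fp_upper = float(stats.f.sf(f_stat, n1 - 1, n2 - 1))
    fp_one = min(fp_upper, 1.0 - fp_upper) if math.isfinite(f_stat) else 0.0
    fp_two = min(1.0, 2.0 * fp_one)
    return TwoSampleReport(
        n1=n1,
        n2=n2,
        mean1=float(np.mean(x)),
        mean2=float(np.mean(y)),
        var1=v1,
        var2=v2,
        t_stat=t_stat,
        t_df=df,
        t_p_two_tailed=p2,
        t_p_one_tailed=p1,
        f_stat=f_stat,
        f_df=(n1 - 1, n2 - 1),
        f_p_two_tailed=fp_two,
        f_p_one_tailed=fp_one,
        degenerate_variance=degenerate,
    )


def chi_square(table) -> tuple[float, int, float]:
    """Chi-square test of independence on a contingency table.

    Returns ``(statistic, df, p)``; no continuity correction, matching the
    conventional test on r x c count tables.
    """
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass(frozen=True)
class LinearFitReport:
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int


def linear_fit(x, y) -> LinearFitReport:
    """Ordinary least squares of y on x with the standard overall F test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("linear fit needs at least three points")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = r2 / ((1.0 - r2) / (n - 2))
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return LinearFitReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_stat=f_stat,
        p_value=p,
        n=n,
    )
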