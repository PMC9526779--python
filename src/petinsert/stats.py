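"""Agreement statistics implemented from their defining formulas.

Rank tests (Mann-Whitney U, Spearman), the D'Agostino-Pearson K^2 normality
test and Bland-Altman limits of agreement are written out from the standard
formulas (average ranks for ties, moment transforms, normal / chi-square /
t approximations) rather than delegated, so their small-sample behavior can
be validated against exact enumeration oracles in the test suite. Only
special functions (erf, incomplete beta) come from libraries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import special

__all__ = [
    "rankdata_average",
    "mann_whitney_u",
    "spearman_rho",
    "dagostino_pearson",
    "bland_altman",
    "BlandAltmanResult",
]

EXACT_MW_MAX_N = 16  # total sample size at or below which U is enumerated


def rankdata_average(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their rank range."""
    x = np.asarray(x, dtype=np.float64)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=np.float64)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def _u_statistic(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U counted for the first sample. Ties get average
    ranks. For total n <= 16 the null distribution of U is enumerated
    exactly over all assignments of the pooled values; above that, the
    normal approximation with tie correction and a 0.5 continuity
    correction is used.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata_average(pooled)
    u = _u_statistic(ranks[:n1], n1)
    n = n1 + n2

    if n <= EXACT_MW_MAX_N:
        # Exact two-sided p: P(|U - n1 n2 / 2| >= |u - n1 n2 / 2|) over all
        # C(n, n1) assignments of the pooled (possibly tied) values.
        center = n1 * n2 / 2.0
        dev = abs(u - center) - 1e-12  # tolerate float ranks
        hits = total = 0
        for idx in combinations(range(n), n1):
            u_perm = float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0)
            total += 1
            if abs(u_perm - center) >= dev:
                hits += 1
        return u, hits / total

    mean_u = n1 * n2 / 2.0
    ties = np.unique(pooled, return_counts=True)[1]
    tie_term = ((ties**3 - ties).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u == 0:
        return u, 1.0
    num = abs(u - mean_u) - 0.5  # continuity correction
    z = max(num, 0.0) / math.sqrt(var_u)
    return u, min(1.0, 2.0 * _norm_sf(z))


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; two-sided p from the
    t approximation with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = rankdata_average(x)
    ry = rankdata_average(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0 or sy == 0:
        raise ValueError("rho undefined for a constant sample")
    if np.array_equal(rx, ry):  # perfectly concordant: exact +1
        return 1.0, 0.0
    if np.array_equal(rx + ry, np.full(n, n + 1.0)):  # discordant: exact -1
        return -1.0, 0.0
    rho = float(dx @ dy) / (sx * sy)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    df = n - 2
    # two-sided p from the t CDF via the regularized incomplete beta
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return rho, min(1.0, p)


def _sample_central_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(x.mean())
    d = x - mean
    m2 = float((d**2).mean())
    m3 = float((d**3).mean())
    m4 = float((d**4).mean())
    return mean, m2, m3, m4


def dagostino_pearson(x, min_n: int = 20) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test.

    K^2 = Z1(skewness)^2 + Z2(kurtosis)^2 with the standard transformed
    moments; p from chi-square with 2 df (sf(k2) = exp(-k2/2)). For
    n < ``min_n`` the approximation is unreliable: K^2 is still returned
    but p is NaN, with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 8:
        raise ValueError("need n >= 8 for the moment transforms")
    _, m2, m3, m4 = _sample_central_moments(x)
    if m2 == 0:
        raise ValueError("normality test undefined for a constant sample")

    # Skewness transform (D'Agostino 1970)
    g1 = m3 / m2**1.5
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (
        3.0 * (n * n + 27 * n - 70) * (n + 1) * (n + 3)
        / ((n - 2) * (n + 5) * (n + 7) * (n + 9))
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(math.log(math.sqrt(w2)))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    ya = y / alpha
    z1 = delta * math.log(ya + math.sqrt(ya * ya + 1.0))

    # Kurtosis transform (Anscombe & Glynn 1983)
    g2 = m4 / (m2 * m2)
    e_g2 = 3.0 * (n - 1) / (n + 1)
    var_g2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (g2 - e_g2) / math.sqrt(var_g2)
    sqrt_b1 = (
        6.0 * (n * n - 5 * n + 2) / ((n + 7) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_b1 * (2.0 / sqrt_b1 + math.sqrt(1.0 + 4.0 / sqrt_b1**2))
    inner = (1.0 - 2.0 / a) / (1.0 + xk * math.sqrt(2.0 / (a - 4.0)))
    z2 = (
        (1.0 - 2.0 / (9.0 * a)) - math.copysign(abs(inner) ** (1.0 / 3.0), inner)
    ) / math.sqrt(2.0 / (9.0 * a))

    k2 = z1 * z1 + z2 * z2
    if n < min_n:
        warnings.warn(
            f"D'Agostino-Pearson p-value is unreliable for n={n} < {min_n}; "
            "returning NaN",
            stacklevel=2,
        )
        return k2, float("nan")
    return k2, math.exp(-k2 / 2.0)


@dataclass
class BlandAltmanResult:
    """Bland-Altman agreement summary in percent.

    ``mean_pct`` is the mean paired difference d-bar; ``halfwidth_pct`` is
    1.96 x SD(d) (SD with n-1 denominator), so the limits of agreement are
    mean_pct +/- halfwidth_pct. ``differences_pct`` keeps the per-pair
    values for plotting; ``convention`` records the denominator used.
    """

    mean_pct: float
    halfwidth_pct: float
    differences_pct: np.ndarray
    convention: str


def bland_altman(
    reference, test, convention: str = "percent_of_reference"
) -> BlandAltmanResult:
    """Bland-Altman differences between paired measurements, in percent.

    convention "percent_of_reference": d_i = (test - ref)/ref * 100
    (reference values must be > 0); "percent_of_mean": d_i =
    (test - ref)/((test + ref)/2) * 100.
    """
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError("paired samples must have equal length")
    if len(ref) < 2:
        raise ValueError("need at least 2 pairs")
    if convention == "percent_of_reference":
        if np.any(ref == 0):
            raise ValueError("zero reference value with percent convention")
        d = (tst - ref) / ref * 100.0
    elif convention == "percent_of_mean":
        mean = (tst + ref) / 2.0
        if np.any(mean == 0):
            raise ValueError("zero pairwise mean with percent convention")
        d = (tst - ref) / mean * 100.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return BlandAltmanResult(
        mean_pct=float(d.mean()),
        halfwidth_pct=float(1.96 * d.std(ddof=1)),
        differences_pct=d,
        convention=convention,
    )
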