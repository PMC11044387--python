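"""Reliability and correlation statistics plus printed-table summaries.

Inter-observer reliability uses the two-way, average-measures, absolute-
agreement intraclass correlation ICC(A,k), computed from the two-way ANOVA
mean squares:

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

with MSR the between-rows (targets), MSC the between-columns (raters) and
MSE the residual mean square, n the number of targets. Spearman rank
correlations use exact permutation p-values at small n so results are fully
reproducible. Test-retest variability between the two sessions is summarized
per individual by the intra-individual SD and coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import permutations

import numpy as np
from scipy import stats as sps

from cervikin.segments import ZeroVarianceError


def icc_absolute_average(matrix) -> float:
    """ICC(A,k): two-way, absolute-agreement, average-measures reliability.

    Parameters
    ----------
    matrix : (n, k) array-like or DataFrame
        Rows are targets (segments/recordings), columns raters; complete,
        n >= 2 and k >= 2.

    Raises
    ------
    ZeroVarianceError
        If the ratings have no variance at all (the coefficient is undefined).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ratings matrix must be at least 2 x 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("ratings matrix must be complete (no missing cells)")
    n, k = m.shape
    gm = m.mean()
    sst = ((m - gm) ** 2).sum()
    if sst < 1e-15:
        raise ZeroVarianceError("ratings have zero total variance; ICC undefined")
    ssr = k * ((m.mean(axis=1) - gm) ** 2).sum()
    ssc = n * ((m.mean(axis=0) - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (msc - mse) / n))


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  #: 'exact' | 'monte-carlo' | 'asymptotic'


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_exact(x, y, seed: int = 0, n_mc: int = 99_999,
                   exact_max_n: int = 8, mc_max_n: int = 30) -> SpearmanResult:
    """Spearman rank correlation with a permutation p-value.

    Average ranks are used for ties. The two-sided p-value comes from full
    enumeration of all n! pairings for n <= 8, from a seeded Monte-Carlo
    permutation sample (>= 99,999 draws, add-one corrected) for 8 < n <= 30,
    and from the asymptotic approximation beyond that.

    Raises
    ------
    ZeroVarianceError
        If either vector is constant (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("constant vector: Spearman rho undefined")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)
    eps = 1e-12

    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(_rank_rho(rx, ry[list(perm)])) >= abs(rho) - eps:
                count += 1
        return SpearmanResult(rho=rho, p=count / total, n=n, method="exact")
    if n <= mc_max_n:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_mc):
            if abs(_rank_rho(rx, rng.permutation(ry))) >= abs(rho) - eps:
                count += 1
        return SpearmanResult(rho=rho, p=(1 + count) / (1 + n_mc), n=n, method="monte-carlo")
    res = sps.spearmanr(x, y)
    return SpearmanResult(rho=rho, p=float(res.pvalue), n=n, method="asymptotic")


def cv_and_intraindividual_sd(t1, t2):
    """Per-individual test-retest SD and coefficient of variation.

    For each paired (T1, T2) measurement the intra-individual SD is the
    sample SD of the two values, ``|t1 - t2| / sqrt(2)``, and the CV is
    SD / mean.

    Returns
    -------
    (sd, cv) : two float arrays

    Raises
    ------
    ZeroVarianceError
        If any pair has zero mean (CV undefined), naming the pair.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != t2.shape or t1.ndim != 1:
        raise ValueError("t1 and t2 must be paired 1-D vectors")
    sd = np.abs(t1 - t2) / math.sqrt(2.0)
    mean = (t1 + t2) / 2.0
    zero = np.nonzero(mean == 0)[0]
    if len(zero):
        raise ZeroVarianceError(f"zero mean for pair(s) {zero.tolist()}: CV undefined")
    return sd, sd / mean


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero, matching the printed-table convention."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass
class SummaryRow:
    """One 'Average [min;max]' summary cell of a cohort table."""

    mean: float
    min: float
    max: float
    n: int
    decimals: int = 1

    def __post_init__(self):
        slack = 0.5 * 10.0 ** (-self.decimals) + 1e-12  # the mean is rounded
        if not self.min - slack <= self.mean <= self.max + slack:
            raise ValueError("summary violates min <= mean <= max")

    @property
    def text(self) -> str:
        fmt = f"{{:.{self.decimals}f}}"
        if self.decimals == 0:
            return f"{self.mean:g} [{self.min:g};{self.max:g}]"
        return f"{fmt.format(self.mean)} [{fmt.format(self.min)};{fmt.format(self.max)}]"


def summarize(values, decimals: int = 1) -> SummaryRow:
    """Column summary as printed in the cohort tables: rounded mean, min, max.

    The mean is rounded half-away-from-zero to ``decimals``; min and max are
    reported unrounded (table brackets reproduce the column extremes).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty column")
    return SummaryRow(
        mean=round_half_away(float(v.mean()), decimals),
        min=float(v.min()),
        max=float(v.max()),
        n=int(v.size),
        decimals=decimals,
    )
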