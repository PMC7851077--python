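"""Agreement statistics: OLS R², Bland–Altman, RMSCV, t-tests, percent difference.

Conventions: Bland–Altman differences are ``y − x`` where ``y`` is the
condition of interest and ``x`` the reference, so a positive bias means the
condition reads higher than the reference.  t-tests are two-tailed; the
unpaired test is Welch's (unequal variances).  Degenerate zero-variance
inputs with identical means report p = 1 by convention; zero variance with a
nonzero mean difference reports t = ±inf, p = 0 with a ``degenerate`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementReport",
    "TTestResult",
    "linear_fit_r2",
    "bland_altman",
    "rmscv",
    "t_tests",
    "percent_difference",
]


@dataclass
class AgreementReport:
    slope: float
    intercept: float
    r_squared: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    paired: bool
    degenerate: bool = False


def linear_fit_r2(x, y) -> tuple[float, float, float]:
    """OLS slope, intercept and R² (= squared Pearson correlation)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def bland_altman(x, y):
    """Bland–Altman agreement of ``y`` (condition) against ``x`` (reference).

    Returns ``(bias, loa_low, loa_high, means, diffs)`` with limits of
    agreement at bias ± 1.96 · sd(differences) (sample sd, n−1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = y - x
    means = (x + y) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, means, diffs


def rmscv(repeated_measurements) -> float:
    """Root-mean-square coefficient of variation across subjects, in percent.

    ``repeated_measurements`` is an iterable of per-subject repeat arrays
    (each with at least 2 repeats and a positive mean); per-subject
    CV = sd/mean with sample sd (n−1), RMSCV = 100·sqrt(mean(CV²)).
    """
    cvs = []
    for rep in repeated_measurements:
        rep = np.asarray(rep, dtype=np.float64)
        if rep.size < 2:
            raise ValueError("each subject needs at least 2 repeats")
        m = rep.mean()
        if m <= 0:
            raise ValueError("subject mean must be positive for a CV")
        cvs.append(rep.std(ddof=1) / m)
    if not cvs:
        raise ValueError("no subjects given")
    return float(100.0 * np.sqrt(np.mean(np.square(cvs))))


def t_tests(a, b, paired: bool) -> TTestResult:
    """Two-tailed t-test: paired on difference scores, unpaired Welch."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if paired and a.shape != b.shape:
        raise ValueError("paired test needs equal-length samples")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    summary = dict(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        paired=paired,
    )
    if paired:
        d = a - b
        if d.std(ddof=1) == 0:
            if d.mean() == 0:
                return TTestResult(t=0.0, p=1.0, **summary)
            return TTestResult(
                t=float(np.sign(d.mean()) * np.inf), p=0.0, degenerate=True, **summary
            )
        res = sps.ttest_rel(a, b)
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return TTestResult(t=0.0, p=1.0, **summary)
            return TTestResult(
                t=float(np.sign(a.mean() - b.mean()) * np.inf),
                p=0.0,
                degenerate=True,
                **summary,
            )
        res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), **summary)


def percent_difference(with_val: float, without_val: float) -> float:
    """100·(with − without)/without; the reference must be positive.

    Not antisymmetric: +5% one way is −4.76% the other; callers must keep
    the reference fixed.
    """
    if without_val <= 0:
        raise ValueError("reference value must be positive")
    return float(100.0 * (with_val - without_val) / without_val)
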