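"""The study's statistical battery, implemented with exact small-sample behavior.

Four procedures: the Wilcoxon matched-pairs signed-rank test (two-tailed,
exact by full enumeration of the sign-pattern null for small n), the Fisher
exact test on a 2x2 table (two-sided by the probability-mass method), the
chi-square goodness-of-fit test against uniform selection, and the paired
t test.  Conventions are stated explicitly because they differ across
software:

* Wilcoxon zero differences are discarded (Wilcoxon's original treatment
  and the GraphPad Prism default), not handled by Pratt's method.
* The exact two-sided Wilcoxon p is 2 * min(lower tail, upper tail), capped
  at 1.
* The Fisher two-sided p sums hypergeometric probabilities of all tables
  with the observed margins whose probability does not exceed the observed
  table's (within relative tolerance 1e-7).

scipy supplies only distribution tail functions; the test statistics and
exact null enumerations are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import DegenerateSampleError, ValidationError

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "fisher_exact_2x2",
    "chi_square_gof",
    "paired_t",
    "format_p",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of one named statistical test.

    ``exact`` is True only when the null distribution was fully enumerated
    rather than approximated.
    """

    method: str
    statistic: float
    p_value: float
    n: int
    two_sided: bool = True
    exact: bool = False
    details: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def _signed_rank_null_cdf(double_ranks: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ under the signed-rank null, by dynamic programming.

    ``double_ranks`` are the rank values doubled so midranks become integers.
    Returns the probability mass over 2*W+ = 0 .. sum(double_ranks); this is
    equivalent to enumerating all 2^n sign patterns.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(x, y=None, method: str = "auto") -> TestResult:
    """Two-tailed Wilcoxon matched-pairs signed-rank test.

    Pass paired samples ``x, y`` (differences are x - y) or a single vector
    of differences.  Zero differences are discarded; ties in |d| get
    midranks.  With ``method='auto'`` the p-value is exact (full enumeration
    of the 2^n equiprobable sign patterns) for n <= 25 retained pairs;
    beyond that a normal approximation with tie and continuity corrections
    is used.  ``method='exact'`` or ``'approx'`` forces one path.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValidationError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")

    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    exact = method == "exact" or (method == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if exact:
        double_ranks = np.round(2 * ranks).astype(int)
        pmf = _signed_rank_null_cdf(double_ranks)
        w2 = int(round(2 * w_plus))
        lower = pmf[: w2 + 1].sum()
        upper = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult("wilcoxon_signed_rank", w_plus, float(p), n, exact=True)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise DegenerateSampleError("zero variance in signed-rank statistic")
    # continuity correction pulls the statistic half a step toward the mean
    delta = w_plus - mean
    cc = 0.5 * np.sign(delta)
    z = (delta - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * _sps.norm.sf(abs(z)))
    return TestResult(
        "wilcoxon_signed_rank", w_plus, float(p), n, exact=False, details={"z": float(z)}
    )


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    The p-value sums hypergeometric probabilities, over all tables with the
    observed margins, of outcomes no more probable than the observed one.
    The statistic reported is the sample odds ratio (a*d)/(b*c).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(t < 0) or not np.all(t == np.floor(t)):
        raise ValidationError("table entries must be nonnegative integers")
    a, b, c, d = (int(v) for v in t.ravel())
    n = a + b + c + d
    if n == 0:
        raise DegenerateSampleError("empty contingency table")
    row1 = a + b
    col1 = a + c
    rv = _sps.hypergeom(n, row1, col1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = 1.0 if p > 1 - 1e-9 else p  # snap float-summation residue
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return TestResult("fisher_exact", float(odds), p, n, exact=True)


def chi_square_gof(counts) -> TestResult:
    """Chi-square goodness-of-fit test against uniform selection frequencies.

    Used for the annotator-selection survey questions: under the null every
    one of the k annotators is chosen equally often.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValidationError("need at least 2 categories")
    if np.any(counts < 0):
        raise ValidationError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValidationError("total count is zero")
    k = counts.size
    expected = total / k
    stat = float(((counts - expected) ** 2 / expected).sum())
    p = float(_sps.chi2.sf(stat, k - 1))
    return TestResult(
        "chi_square_gof", stat, p, int(total), exact=False, details={"df": k - 1}
    )


def paired_t(x, y=None) -> TestResult:
    """Two-tailed paired t test on samples ``x, y`` (or a difference vector)."""
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValidationError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    n = d.size
    if n < 2:
        raise ValidationError("paired t test needs at least 2 pairs")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("paired differences have zero variance")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(min(1.0, 2.0 * _sps.t.sf(abs(t), n - 1)))
    return TestResult(
        "paired_t", t, p, n, exact=False, details={"df": n - 1}
    )


def format_p(p: float) -> str:
    """Report a p-value the way clinical journals print them.

    Below 0.001 the value is reported as the bound "<.001"; otherwise three
    significant figures with no leading zero (e.g. ".01", ".47").
    """
    if p < 0.001:
        return "<.001"
    s = f"{p:.3g}"
    if s.startswith("0."):
        s = s[1:]
    elif s.startswith("1"):
        return ">.99" if p < 1 else "1.0"
    return s
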