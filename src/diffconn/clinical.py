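"""Clinical statistics: exact Mann-Whitney with ties, paired t, summaries.

The group comparisons in a nine-patient trial need *exact* small-sample
tests.  The Mann-Whitney U here is computed from midranks and its
two-sided p by complete enumeration of all C(n1+n2, n1) assignments of the
observed (possibly tied) values to the two groups, counting assignments
whose U deviates from the null mean n1*n2/2 at least as much as observed:

    p = #{ |U* - n1*n2/2| >= |U - n1*n2/2| } / C(n1+n2, n1).

Under heavy ties this deviation definition differs from doubling the
one-sided tail (e.g. six zeros vs three positive doses gives 1/84 = 0.012,
where 2x one-sided would give 0.024) and is the definition reproduced here.

GADA titers are natural-log transformed before testing (rank tests are
unaffected; paired t and summaries on the log scale are).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ClinicalTable

log = logging.getLogger(__name__)

__all__ = [
    "ExactTestResult",
    "mann_whitney_exact",
    "paired_t",
    "summarize_group",
    "log_gada",
    "auc_trapezoid",
    "group_compare",
    "insulin_independence_rate",
]

_MAX_EXACT = 25


@dataclass(frozen=True)
class ExactTestResult:
    """Exact two-sided Mann-Whitney result."""

    U: float
    n1: int
    n2: int
    p: float
    ties: bool

    @property
    def method(self) -> str:
        note = "midranks, ties present" if self.ties else "no ties"
        return f"exact two-sided Mann-Whitney by enumeration ({note})"


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def mann_whitney_exact(x, y) -> ExactTestResult:
    """Exact two-sided Mann-Whitney U test, tie-aware.

    Enumerates every assignment of the observed value multiset to groups of
    sizes (n1, n2); feasible for n1 + n2 <= 25.  Larger samples should use
    an asymptotic test instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    N = n1 + n2
    if N > _MAX_EXACT:
        raise ValueError(
            f"n1 + n2 = {N} > {_MAX_EXACT}: exact enumeration infeasible, "
            "use an asymptotic Mann-Whitney instead"
        )
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    ties = len(np.unique(combined)) < N
    R1 = float(ranks[:n1].sum())
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    dev = abs(U - mu)

    # enumerate assignments of the smaller group's indices; U for group 1 is
    # determined by the complement's rank sum
    small = min(n1, n2)
    total = math.comb(N, small)
    rank_total = ranks.sum()
    count = 0
    for idx in itertools.combinations(range(N), small):
        r_small = ranks[list(idx)].sum()
        if small == n1:
            R1_star = r_small
        else:
            R1_star = rank_total - r_small
        U_star = R1_star - n1 * (n1 + 1) / 2.0
        if abs(U_star - mu) >= dev - 1e-9:
            count += 1
    return ExactTestResult(U=U, n1=n1, n2=n2, p=count / total, ties=ties)


def paired_t(pre, post) -> tuple[float, int, float]:
    """Ordinary paired t-test on (post - pre); returns (t, df, p).

    Pairs with a missing member are dropped (logged).  Identical columns
    give t = 0, p = 1; zero-variance differences with a non-zero mean are
    an error (the statistic is undefined).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be the same length")
    keep = np.isfinite(pre) & np.isfinite(post)
    if keep.sum() < len(pre):
        log.info("dropping %d incomplete pair(s)", int(len(pre) - keep.sum()))
    d = post[keep] - pre[keep]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    dbar = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if dbar == 0:
            return 0.0, df, 1.0
        raise ValueError("zero variance of differences with non-zero mean")
    t = dbar / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def summarize_group(
    table: ClinicalTable, variable: str, group: str | None = None
) -> tuple[float, float, int]:
    """(mean, sample SD, n) for one variable, missing values excluded.

    With a single observation the SD is undefined and reported as NaN.
    """
    v = table.values(variable, group=group)
    n = len(v)
    if n == 0:
        raise ValueError(f"no observations for {variable!r} in group {group!r}")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
    return mean, sd, n


def log_gada(values) -> np.ndarray:
    """Natural log of GADA titers (must be strictly positive)."""
    v = np.asarray(values, dtype=float)
    if (v[np.isfinite(v)] <= 0).any():
        raise ValueError("GADA values must be > 0")
    return np.log(v)


def auc_trapezoid(times, values) -> float:
    """Trapezoidal area under a stimulation curve (e.g. C-peptide vs minutes)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points")
    if not (np.diff(t) > 0).all():
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def group_compare(
    table: ClinicalTable,
    variable: str,
    groups: tuple[str, str] = ("IF", "ID"),
) -> ExactTestResult:
    """Exact Mann-Whitney comparison of one clinical variable between groups.

    GADA is log-transformed first (a no-op for the rank test, kept for a
    uniform contract with the summary statistics).
    """
    x = table.values(variable, group=groups[0])
    y = table.values(variable, group=groups[1])
    if variable == "gada":
        x, y = log_gada(x), log_gada(y)
    return mann_whitney_exact(x, y)


def insulin_independence_rate(
    table: ClinicalTable, variable: str = "insulin_12mo"
) -> tuple[int, int, float]:
    """(count, total, percent) of patients with a zero insulin dose."""
    v = table.values(variable)
    count = int((v == 0).sum())
    return count, len(v), 100.0 * count / len(v)
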