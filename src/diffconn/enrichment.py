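"""Gene-set over-representation analysis (Fisher's exact + chi-square).

For each set the 2x2 table of (in DE list) x (in set) over a background
universe is scored with the one-sided Fisher exact test (hypergeometric
upper tail; a two-sided variant is available) and the chi-square test with
continuity correction.  Benjamini-Hochberg FDR is applied across sets and
results are ranked by Fisher p.  The recommended universe is the genes
actually measured on the array, not all annotated genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = ["enrich"]


def enrich(
    de_genes: list[str],
    collection: GeneSetCollection,
    universe: list[str] | None = None,
    alternative: str = "greater",
    top: int | None = None,
) -> pd.DataFrame:
    """Rank gene sets by over-representation of ``de_genes``.

    Returns one row per set with ``k`` (DE genes in the set), ``K`` (set
    size within the universe), ``n`` (DE list size within the universe),
    ``N`` (universe size), ``ratio`` = (k/n)/(K/N), ``p_fisher``,
    ``p_chi2`` and BH ``q`` (on the Fisher p).  ``top`` truncates the
    ranked table (the conventional report shows the top 20).
    """
    if universe is None:
        universe = collection.universe
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    de = set(de_genes)
    outside = de - uni
    if outside:
        log.warning("%d DE gene(s) outside the universe dropped", len(outside))
        de &= uni
    N, n = len(uni), len(de)
    rows = []
    for name, members in collection.sets.items():
        in_set = set(members) & uni
        K = len(in_set)
        if K == 0:
            continue
        k = len(de & in_set)
        if n == 0:
            p_fisher, ratio = 1.0, np.nan
        else:
            if alternative == "greater":
                p_fisher = float(stats.hypergeom.sf(k - 1, N, K, n))
            elif alternative == "two-sided":
                table = [[k, n - k], [K - k, N - K - (n - k)]]
                p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])
            else:
                raise ValueError(f"unknown alternative {alternative!r}")
            ratio = (k / n) / (K / N)
        p_chi2 = _chi2_p(k, K, n, N)
        rows.append((name, k, K, n, N, ratio, p_fisher, p_chi2))
    out = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "ratio", "p_fisher", "p_chi2"]
    ).set_index("set")
    out["q"] = multipletests(out["p_fisher"], method="fdr_bh")[1] if len(out) else []
    out = out.sort_values(["p_fisher", "k"], ascending=[True, False], kind="mergesort")
    if top is not None:
        out = out.head(top)
    return out


def _chi2_p(k: int, K: int, n: int, N: int) -> float:
    table = np.array([[k, n - k], [K - k, N - K - (n - k)]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan
    try:
        return float(stats.chi2_contingency(table, correction=True)[1])
    except ValueError:
        return np.nan
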