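"""Hypergeometric over-representation analysis against GMT gene sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named annotation sets over a gene universe.

    Members outside the universe are dropped at construction; empty set
    names are rejected. The universe is typically all genes of the RNA
    class under test.
    """

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty gene universe")
        if any(not name for name in self.sets):
            raise ValueError("gene set with empty name")
        self.sets = {n: s & self.universe for n, s in self.sets.items()}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def ora(
    query: set[str], collection: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation set.

    For a universe of N genes, a set of K, and a query of n, the p-value is
    the hypergeometric upper tail P(X >= k) of the observed overlap k.
    Rows are sorted by (p, set name); ``enriched`` flags raw p < alpha, and
    a Benjamini-Hochberg column is reported alongside.
    """
    dropped = query - collection.universe
    if dropped:
        log.info("dropping %d query ids outside the universe", len(dropped))
    query = query & collection.universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")

    N, n = len(collection.universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append({"set": name, "overlap": k, "set_size": K, "query_size": n,
                     "universe_size": N, "pvalue": p})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "query_size",
                                      "universe_size", "pvalue"])
    if len(out):
        out["padj"] = multipletests(out["pvalue"].to_numpy(), method="fdr_bh")[1]
        out["enriched"] = out["pvalue"] < alpha
        out = out.sort_values(["pvalue", "set"], kind="mergesort").reset_index(drop=True)
    else:
        out["padj"] = np.nan
        out["enriched"] = np.array([], dtype=bool)
    return out
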