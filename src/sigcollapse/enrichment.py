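"""Direction-stratified over-representation analysis and the informative-set rule.

Up- and down-regulated DEGs are tested separately against a gene-set
collection with the upper-tail hypergeometric test, Benjamini-Hochberg
corrected within each direction.  A significant set is *informative* when it
covers more than a fixed fraction of the same-direction DEGs, or when it
contains at least one DEG that passed the multiple-comparisons correction;
when both a parent set and one of its children are informative the parent is
dropped in favor of the more specific child.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io_formats import GeneSetCollection

ENRICHMENT_COLUMNS = ["direction", "set_name", "K", "k", "genes",
                      "p_hyper", "fdr", "coverage"]


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the set size within the universe, ``n``
    the number of DEGs drawn, ``k`` the observed overlap.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (K <= N and n <= N):
        raise ValueError(f"require K <= N and n <= N; got K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overrepresentation(degs: pd.DataFrame, sets: GeneSetCollection,
                       universe: Sequence[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of DEGs in each gene set.

    Run separately for up- and down-regulated DEGs; sets are intersected
    with the universe before testing, BH correction is applied across all
    tested sets within a direction, and sets with zero overlap are dropped
    from the output.

    Parameters
    ----------
    degs : pandas.DataFrame
        DEG table indexed by gene with a ``direction`` column.
    universe : sequence of str
        The testable gene population (typically all genes on the platform
        after transcript collapse); must contain every DEG.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    stray = sorted(set(degs.index) - uni)
    if stray:
        raise ValueError(f"DEGs absent from universe: {stray[:10]}")
    restricted = sets.intersect_universe(uni)
    N = len(universe)

    frames = []
    for direction in ("up", "down"):
        deg_genes = set(degs.index[degs["direction"] == direction])
        n = len(deg_genes)
        if n == 0:
            continue
        rows = []
        for name in restricted:
            members = set(restricted.members(name))
            K = len(members)
            overlap = sorted(members & deg_genes)
            k = len(overlap)
            rows.append({"direction": direction, "set_name": name, "K": K, "k": k,
                         "genes": tuple(overlap),
                         "p_hyper": hypergeometric_p(k, K, n, N),
                         "coverage": k / n})
        if not rows:
            continue
        frame = pd.DataFrame(rows)
        frame["fdr"] = benjamini_hochberg(frame["p_hyper"].to_numpy())
        frames.append(frame[frame["k"] > 0])
    if not frames:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[ENRICHMENT_COLUMNS]


def select_informative_sets(table: pd.DataFrame,
                            fdr_passing: Iterable[str] = (),
                            parent: Mapping[str, str] | None = None,
                            fdr_alpha: float = 0.05,
                            coverage_min: float = 0.10) -> list[str]:
    """Apply the informativeness rule to an enrichment table.

    Among sets with ``fdr < fdr_alpha``, keep those that cover strictly more
    than ``coverage_min`` of the same-direction DEGs *or* contain at least one
    FDR-passing DEG.  If a kept set's parent (per ``parent``) is also kept,
    the parent is dropped in favor of its children.  Returns set names in
    table order.
    """
    fdr_pass = set(fdr_passing)
    kept: list[str] = []
    for _, row in table.iterrows():
        if row["fdr"] >= fdr_alpha:
            continue
        if row["coverage"] > coverage_min or (set(row["genes"]) & fdr_pass):
            if row["set_name"] not in kept:
                kept.append(row["set_name"])
    if parent:
        parents_of_kept = {parent[name] for name in kept if name in parent}
        kept = [name for name in kept if name not in parents_of_kept]
    return kept


def write_enrichment_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["genes"] = out["genes"].map(lambda gs: ",".join(gs))
    out.to_csv(path, sep="\t", index=False)


def read_enrichment_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["genes"] = table["genes"].map(lambda s: tuple(str(s).split(",")))
    return table[ENRICHMENT_COLUMNS]
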