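"""Set-overlap statistics and a generic over-representation engine.

Szymkiewicz-Simpson overlap coefficients, exclusive Venn region counts,
two-sided Fisher's exact tests on a shared universe, and hypergeometric
over-representation against user-supplied gene-set collections (GMT), with
Benjamini-Hochberg adjustment across the collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io_formats import GeneSetCollection


@dataclass
class OverlapStat:
    name_a: str
    name_b: str
    size_a: int
    size_b: int
    intersection: int
    coefficient: float       # |A ∩ B| / min(|A|, |B|)
    odds_ratio: float = None
    fisher_p: float = None
    universe_size: int = None


def overlap_coefficient(a, b) -> float:
    """Szymkiewicz-Simpson coefficient |A ∩ B| / min(|A|, |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def fisher_overlap(a, b, universe):
    """Two-sided Fisher's exact test of the 2x2 membership table.

    Rows: in A / not in A; columns: in B / not in B, over ``universe``.
    Returns ``(odds_ratio, p)``.
    """
    a, b, universe = set(a), set(b), set(universe)
    stray = (a - universe) | (b - universe)
    if stray:
        raise ValueError(f"sets exceed the universe: {sorted(stray)[:5]}")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return float(odds), float(p)


def overlap_stat(a, b, universe=None, name_a="A", name_b="B") -> OverlapStat:
    a, b = set(a), set(b)
    stat = OverlapStat(
        name_a=name_a, name_b=name_b, size_a=len(a), size_b=len(b),
        intersection=len(a & b), coefficient=overlap_coefficient(a, b),
    )
    if universe is not None:
        stat.odds_ratio, stat.fisher_p = fisher_overlap(a, b, universe)
        stat.universe_size = len(set(universe))
    return stat


def venn_counts(*sets) -> dict:
    """Counts of every exclusive region of a 2- or 3-set Venn diagram.

    Keys are tuples of member indicators, e.g. ``(1, 0, 1)`` is the region
    in sets 1 and 3 but not 2.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts takes 2 or 3 sets")
    sets = [set(s) for s in sets]
    everything = set().union(*sets)
    out = {}
    k = len(sets)
    for mask in range(1, 2 ** k):
        member = tuple((mask >> i) & 1 for i in range(k))
        region = everything.copy()
        for i, bit in enumerate(member):
            region = region & sets[i] if bit else region - sets[i]
        out[member] = len(region)
    return out


def enrich(query, collection: GeneSetCollection, universe,
           collapse_jaccard: float = None) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with the universe first; the one-sided upper-tail
    p-value P(X >= overlap) is BH-adjusted across the collection.  With
    ``collapse_jaccard`` set, any set whose Jaccard similarity with a more
    significant retained set exceeds the threshold is dropped (redundant
    categories report only their strongest representative).
    """
    query, universe = set(query), set(universe)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be contained in the universe")
    n_universe, n_query = len(universe), len(query)
    rows = []
    members = {}
    for name in sorted(collection.sets):
        s = set(collection.sets[name]) & universe
        if not s:
            continue
        members[name] = s
        k = len(query & s)
        # P(X >= k), X ~ Hypergeom(N, |set|, |query|)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(s), n_query))
        rows.append({
            "set": name, "set_size": len(s), "overlap": k,
            "expected": len(s) * n_query / n_universe, "pvalue": p,
        })
    if not rows:
        return pd.DataFrame(
            columns=["set", "set_size", "overlap", "expected", "pvalue", "qvalue"]
        ).set_index("set")
    table = pd.DataFrame(rows).set_index("set")
    table["qvalue"] = bh_adjust(table["pvalue"].values)
    table = table.sort_values(["pvalue", "set"], kind="mergesort")
    if collapse_jaccard is not None:
        kept = []
        for name in table.index:
            s = members[name]
            redundant = any(
                len(s & members[other]) / len(s | members[other]) > collapse_jaccard
                for other in kept
            )
            if not redundant:
                kept.append(name)
        table = table.loc[kept]
    return table


def pairwise_overlap_matrix(named_sets: dict) -> pd.DataFrame:
    """Symmetric Szymkiewicz-Simpson matrix over a dict of named sets."""
    names = list(named_sets)
    out = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        c = overlap_coefficient(named_sets[a], named_sets[b])
        out.at[a, b] = out.at[b, a] = c
    return out
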