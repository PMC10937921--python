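"""Gene-set over-representation analysis (hypergeometric test).

Generic set-based ORA: for each named gene set, the upper-tail
hypergeometric probability of observing at least the attained overlap
between a module's genes and the set, within a declared gene universe,
followed by Benjamini-Hochberg FDR adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .clinical import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional explicit universe."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        empty = [name for name, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        restricted = {name: s & universe for name, s in self.sets.items()}
        return GeneSetCollection(
            sets={k: v for k, v in restricted.items() if v}, universe=set(universe)
        )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, then member genes per line)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def hypergeometric_ora(
    module_genes, collection: GeneSetCollection, universe=None
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each set in the module.

    For a universe of size N containing K set members, and a module of n
    genes with k overlapping the set, p = P(X >= k) with X hypergeometric.
    Sets with zero overlap are reported with p = 1. The universe defaults to
    the collection's declared universe; the module must lie inside it.
    """
    module = set(module_genes)
    if universe is None:
        universe = collection.universe
    if not universe:
        raise ValueError("an explicit nonempty gene universe is required")
    universe = set(universe)
    outside = module - universe
    if outside:
        raise ValueError(f"module genes outside the universe: {sorted(outside)[:5]}")
    N = len(universe)
    n = len(module)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        k = len(module & members)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values("p")
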