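"""Directional over-representation analysis against GMT gene-set
collections.

For each gene set and each direction (up- or down-regulated along
pseudotime) the overlap between the direction's significant-gene list and
the set is scored with a one-sided hypergeometric upper-tail p-value,
conditioned on the analysis universe (all genes that survived expression
filtering and carry a valid identifier). Sets are intersected with the
universe before testing. No multiplicity adjustment is applied across sets
by default, matching the convention of the classical GO over-representation
tools; a BH column is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .nbql import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "directional_ora",
    "top_sets",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional category tag per set (e.g. the GO
    ontology BP/CC/MF, or a pathway database name)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # unique members within a set, order preserved
        self.sets = {
            name: list(dict.fromkeys(members)) for name, members in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path, category: "str | dict | None" = None) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, members...).

    ``category`` may be a single tag for every set or a name->tag map.
    Duplicate members within a set are collapsed.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    categories: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: GMT lines need name, description and >=1 member"
                )
            name, desc, *members = parts
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
            if isinstance(category, dict):
                categories[name] = category.get(name, "")
            elif category is not None:
                categories[name] = category
    return GeneSetCollection(sets, descriptions, categories)


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def directional_ora(
    up,
    down,
    universe,
    sets: GeneSetCollection,
    adjust: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of up/down lists in each set.

    ``up`` and ``down`` must be disjoint subsets of ``universe``. For a set
    with K members in the universe of size M, a direction list of size n
    and overlap k, the p-value is P(X >= k) under Hypergeom(M, K, n).
    Returns one row per set: N (set size in universe), Up, Down, P.Up,
    P.Down (plus FDR columns when ``adjust``).
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    up = set(up)
    down = set(down)
    if not up <= uni:
        raise ValueError("up list contains genes outside the universe")
    if not down <= uni:
        raise ValueError("down list contains genes outside the universe")
    if up & down:
        raise ValueError("up and down lists overlap")
    M = len(uni)
    n_up, n_down = len(up), len(down)
    rows = []
    for name, members in sets:
        inset = uni.intersection(members)
        K = len(inset)
        k_up = len(inset & up)
        k_down = len(inset & down)
        p_up = float(hypergeom.sf(k_up - 1, M, K, n_up)) if K else 1.0
        p_down = float(hypergeom.sf(k_down - 1, M, K, n_down)) if K else 1.0
        rows.append(
            {
                "set": name,
                "term": sets.descriptions.get(name, ""),
                "category": sets.categories.get(name, ""),
                "N": K,
                "Up": k_up,
                "Down": k_down,
                "P.Up": min(p_up, 1.0),
                "P.Down": min(p_down, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    if adjust and len(out):
        out["FDR.Up"] = bh_adjust(out["P.Up"].to_numpy())
        out["FDR.Down"] = bh_adjust(out["P.Down"].to_numpy())
    return out


def top_sets(
    rows: pd.DataFrame,
    direction: str = "Down",
    n: int = 10,
    category: "str | None" = None,
) -> pd.DataFrame:
    """Sets sorted by the chosen direction's p-value (optionally within a
    category), truncated to n rows."""
    if direction not in ("Up", "Down"):
        raise ValueError("direction must be 'Up' or 'Down'")
    df = rows
    if category is not None:
        df = df[df["category"] == category]
    col = f"P.{direction}"
    df = df.sort_values([col, "N"], ascending=[True, False], kind="stable")
    return df.head(n)
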