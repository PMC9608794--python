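"""Over-representation analysis against user-supplied gene-set collections.

A generic replacement for database-backed GO/KEGG enrichment: gene sets are
read from GMT files, and for each set the overlap between the query gene
list and the set (both restricted to a universe) is scored with the same
hypergeometric upper tail used by the ceRNA pair test —
``p = P(X >= k)`` for a draw of the query size ``q`` from a universe of
size ``U`` containing ``K`` set members.  Benjamini-Hochberg adjustment is
applied across all tested sets by default.

The universe defaults to the union of all loaded set members; passing the
measured-gene list instead is statistically preferable and supported.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cerna import hypergeom_tail
from .preprocess import bh_adjust

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: map set id -> (description, frozenset of gene ids)."""

    sets: dict
    source: str = ""

    def __len__(self):
        return len(self.sets)

    def members(self, set_id: str):
        return self.sets[set_id][1]

    def all_genes(self) -> frozenset:
        if not self.sets:
            return frozenset()
        return frozenset().union(*(m for _, m in self.sets.values()))


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (set id, description, members...; tab-separated).

    Duplicate member ids within a line are deduplicated.  A line with fewer
    than three fields, or an empty file, is an error.
    """
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields "
                    f"(id, description, members...), got {len(fields)}")
            set_id, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {set_id!r} has no members")
            sets[set_id] = (desc, members)
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(collection.sets):
            desc, members = collection.sets[set_id]
            fh.write("\t".join([set_id, desc, *sorted(members)]) + "\n")


def ora(query, sets: GeneSetCollection, universe=None,
        p_max: float = 0.05, adjust: bool = True) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Parameters
    ----------
    query
        Gene ids of interest; ids outside the universe are dropped with a
        warning (an empty query after restriction is an error).
    sets
        The collection to test; each set is restricted to the universe and
        skipped if the restriction is empty.
    universe
        Background gene ids; defaults to the union of all set members.
    p_max
        Threshold stored in the ``significant`` column (strict), applied to
        ``fdr`` when ``adjust`` else to raw ``p``.

    Returns
    -------
    DataFrame sorted by (p, set id) with columns set, description, k, K, q,
    U, p, fdr, overlap, significant.  Sets with no overlap report p = 1.
    """
    universe = frozenset(universe) if universe is not None else sets.all_genes()
    if not universe:
        raise ValueError("empty universe")
    query_set = frozenset(query)
    dropped = query_set - universe
    if dropped:
        log.warning("dropped %d query genes outside the universe", len(dropped))
    query_set &= universe
    if not query_set:
        raise ValueError("no query gene lies in the universe")
    q, U = len(query_set), len(universe)
    rows = []
    for set_id in sorted(sets.sets):
        desc, members = sets.sets[set_id]
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        overlap = query_set & members
        k = len(overlap)
        p = hypergeom_tail(k, U, q, K)
        rows.append({
            "set": set_id, "description": desc, "k": k, "K": K, "q": q,
            "U": U, "p": p, "overlap": ",".join(sorted(overlap)),
        })
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    crit = df["fdr"] if adjust else df["p"]
    df["significant"] = crit < p_max
    df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return df[["set", "description", "k", "K", "q", "U", "p", "fdr",
               "overlap", "significant"]]


def write_ora(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
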