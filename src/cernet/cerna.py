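"""Shared-miRNA hypergeometric pair test and ceRNA network assembly.

For a candidate lncRNA-mRNA pair the statistic is the upper tail of the
hypergeometric distribution: given a miRNA universe of size ``m``, an mRNA
targeted by ``t`` of them and a lncRNA interacting with ``n`` of them, the
probability that a random size-``n`` draw contains at least the observed
``r`` of the mRNA's miRNAs,

    P(X >= r) = sum_{i=r}^{min(n,t)} C(t,i) C(m-t, n-i) / C(m,n).

Pairs passing ``p < p_max`` with strictly more than ``min_shared`` shared
miRNAs become edges of a bipartite lncRNA-mRNA network, on which hub
lncRNAs are subsequently called by centrality ranking.

The tail is evaluated as a log-gamma sum over the upper terms rather than as
one minus the lower sum, which avoids catastrophic cancellation when the
tail is small; equivalence with the literal complement form is exercised in
the test suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .background import InteractionBackground

log = logging.getLogger(__name__)

__all__ = [
    "CeRNAPair", "CeRNANetwork", "hypergeom_tail", "score_pair",
    "build_network", "write_edges", "read_edges", "write_sif",
    "network_summary",
]


def _log_comb(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(r: int, m: int, n: int, t: int) -> float:
    """Upper-tail probability P(X >= r), X ~ Hypergeometric(m, t, n).

    Parameters
    ----------
    r
        Observed count of shared elements (shared miRNAs of the pair).
    m
        Universe (population) size.
    n
        Number of draws (miRNA partners of the lncRNA).
    t
        Number of marked elements (miRNA partners of the mRNA).

    Returns
    -------
    float
        P(X >= r); exactly 1.0 when ``r == 0``.

    Raises
    ------
    ValueError
        If the arguments violate ``0 <= r <= min(n, t)`` or ``n, t <= m``.
    """
    for name, v in (("r", r), ("m", m), ("n", n), ("t", t)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    r, m, n, t = int(r), int(m), int(n), int(t)
    if m == 0:
        raise ValueError("m must be >= 1 (empty miRNA universe)")
    if n > m:
        raise ValueError(f"n={n} exceeds universe size m={m}")
    if t > m:
        raise ValueError(f"t={t} exceeds universe size m={m}")
    if r > min(n, t):
        raise ValueError(f"r={r} exceeds min(n, t)={min(n, t)}")
    if r == 0:
        return 1.0
    i = np.arange(r, min(n, t) + 1)
    logp = _log_comb(t, i) + _log_comb(m - t, n - i) - _log_comb(m, n)
    return float(min(1.0, np.exp(logp).sum()))


@dataclass(frozen=True)
class CeRNAPair:
    """One scored lncRNA-mRNA candidate.

    ``shared`` is the sorted tuple of miRNA ids common to both (clipped)
    target sets; ``r = len(shared)``; ``n``/``t`` are the clipped set sizes
    of the lncRNA/mRNA; ``m`` the universe size; ``p`` the upper-tail
    probability.
    """

    lnc: str
    mrna: str
    r: int
    n: int
    t: int
    m: int
    shared: tuple
    p: float


@dataclass(frozen=True)
class CeRNANetwork:
    """Bipartite lncRNA-mRNA network of retained pairs.

    Nodes are only those incident to at least one retained edge.  Edges are
    stored sorted by (p, lnc, mrna) so serialized outputs are deterministic.
    """

    edges: tuple  # of CeRNAPair
    lnc_nodes: tuple
    mrna_nodes: tuple
    p_max: float
    min_shared: int
    n_scored: int = 0
    skipped_dels: int = 0
    skipped_degs: int = 0

    def to_graph(self):
        """Materialize as an undirected :class:`networkx.Graph`.

        lncRNA nodes carry ``kind='lncRNA'`` / ``bipartite=0``; mRNA nodes
        ``kind='mRNA'`` / ``bipartite=1``.
        """
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.lnc_nodes, kind="lncRNA", bipartite=0)
        g.add_nodes_from(self.mrna_nodes, kind="mRNA", bipartite=1)
        for e in self.edges:
            g.add_edge(e.lnc, e.mrna, r=e.r, p=e.p, shared=e.shared)
        return g


def score_pair(lnc: str, mrna: str, bg: InteractionBackground) -> CeRNAPair:
    """Score one candidate pair against the background.

    Raises
    ------
    KeyError
        If either id is absent from the background (at network level absent
        candidates are skipped and counted instead).
    """
    try:
        lnc_set = bg.lnc_targets[lnc]
    except KeyError:
        raise KeyError(f"lncRNA {lnc!r} not in background") from None
    try:
        mrna_set = bg.mrna_targets[mrna]
    except KeyError:
        raise KeyError(f"mRNA {mrna!r} not in background") from None
    shared = lnc_set & mrna_set
    r, n, t = len(shared), len(lnc_set), len(mrna_set)
    p = hypergeom_tail(r, bg.m, n, t)
    return CeRNAPair(lnc=lnc, mrna=mrna, r=r, n=n, t=t, m=bg.m,
                     shared=tuple(sorted(shared)), p=p)


def build_network(dels, degs, bg: InteractionBackground,
                  p_max: float = 0.01, min_shared: int = 3) -> CeRNANetwork:
    """Score every DEL x DEG candidate and keep the significant sponges.

    An edge is retained iff ``p < p_max`` and ``r > min_shared`` (both
    strict; the defaults keep pairs sharing at least ``min_shared + 1``
    miRNAs).  Candidates absent from the background are skipped and counted.

    Raises
    ------
    ValueError
        If a gene id appears in both input lists (bipartiteness would break)
        or a threshold is invalid.
    """
    if p_max <= 0 and p_max != 0:
        raise ValueError("p_max must be >= 0")
    if min_shared < 0:
        raise ValueError("min_shared must be >= 0")
    dels = list(dict.fromkeys(dels))
    degs = list(dict.fromkeys(degs))
    collision = set(dels) & set(degs)
    if collision:
        raise ValueError(
            "gene ids present in both the lncRNA and mRNA lists "
            f"(bipartite network impossible): {sorted(collision)[:5]}"
        )
    dels_in = [d for d in dels if d in bg.lnc_targets]
    degs_in = [g for g in degs if g in bg.mrna_targets]
    skipped_dels = len(dels) - len(dels_in)
    skipped_degs = len(degs) - len(degs_in)
    if skipped_dels or skipped_degs:
        log.info("background lookup skipped %d/%d DELs and %d/%d DEGs",
                 skipped_dels, len(dels), skipped_degs, len(degs))
    edges = []
    n_scored = 0
    for lnc in dels_in:
        for mrna in degs_in:
            pair = score_pair(lnc, mrna, bg)
            n_scored += 1
            if pair.p < p_max and pair.r > min_shared:
                edges.append(pair)
    if n_scored == 0:
        log.warning("no DEL x DEG candidate had both ids in the background; "
                    "network is empty")
    edges.sort(key=lambda e: (e.p, e.lnc, e.mrna))
    lnc_nodes = tuple(sorted({e.lnc for e in edges}))
    mrna_nodes = tuple(sorted({e.mrna for e in edges}))
    return CeRNANetwork(edges=tuple(edges), lnc_nodes=lnc_nodes,
                        mrna_nodes=mrna_nodes, p_max=p_max,
                        min_shared=min_shared, n_scored=n_scored,
                        skipped_dels=skipped_dels, skipped_degs=skipped_degs)


# ---------------------------------------------------------------------------
# serialization

_EDGE_COLUMNS = ("lnc", "mrna", "r", "n", "t", "m", "p", "shared_mirnas")


def write_edges(net: CeRNANetwork, path) -> None:
    """Write the retained pairs as a TSV with a threshold-bearing header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# p_max={net.p_max!r}\tmin_shared={net.min_shared}\n")
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for e in net.edges:
            fh.write("\t".join([
                e.lnc, e.mrna, str(e.r), str(e.n), str(e.t), str(e.m),
                repr(e.p), ",".join(e.shared),
            ]) + "\n")


def read_edges(path) -> CeRNANetwork:
    """Read a network back from :func:`write_edges` output."""
    p_max, min_shared = 0.01, 3
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                for token in line[1:].split("\t"):
                    key, _, val = token.strip().partition("=")
                    if key == "p_max":
                        p_max = float(val)
                    elif key == "min_shared":
                        min_shared = int(val)
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if fields[: len(_EDGE_COLUMNS) - 1] and fields[0] == "lnc":
                continue  # header
            if len(fields) != len(_EDGE_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"{len(_EDGE_COLUMNS)} columns, got {len(fields)}")
            lnc, mrna, r, n, t, m, p, shared = fields
            shared_t = tuple(shared.split(",")) if shared else ()
            edges.append(CeRNAPair(lnc=lnc, mrna=mrna, r=int(r), n=int(n),
                                   t=int(t), m=int(m), shared=shared_t,
                                   p=float(p)))
    edges.sort(key=lambda e: (e.p, e.lnc, e.mrna))
    return CeRNANetwork(
        edges=tuple(edges),
        lnc_nodes=tuple(sorted({e.lnc for e in edges})),
        mrna_nodes=tuple(sorted({e.mrna for e in edges})),
        p_max=p_max, min_shared=min_shared, n_scored=len(edges),
    )


def write_sif(net: CeRNANetwork, path) -> None:
    """Write edges in simple-interaction format for graph viewers."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(net.edges, key=lambda e: (e.lnc, e.mrna)):
            fh.write(f"{e.lnc}\tceRNA\t{e.mrna}\n")


def network_summary(net: CeRNANetwork) -> dict:
    return {
        "n_edges": len(net.edges),
        "n_lncrna_nodes": len(net.lnc_nodes),
        "n_mrna_nodes": len(net.mrna_nodes),
        "n_scored_pairs": net.n_scored,
        "skipped_dels": net.skipped_dels,
        "skipped_degs": net.skipped_degs,
        "p_max": net.p_max,
        "min_shared": net.min_shared,
    }
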