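"""Tripartite ceRNA subnetworks around hub lncRNAs.

For a hub lncRNA the subnetwork contains its adjacent mRNA neighbours in
the parent network and, for each retained pair, the shared miRNAs stored on
that edge.  The result is tripartite: typed ``sponges`` edges from the hub
to each shared miRNA and ``targets`` edges from each miRNA to the mRNAs it
links the hub with — never a direct lncRNA-mRNA edge.  miRNA nodes are
taken from the stored shared sets (not recomputed from the full background),
so the subnetwork reflects exactly the hypothesis the pair test accepted.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .cerna import CeRNANetwork

SPONGES = "sponges"  # hub lncRNA -> miRNA
TARGETS = "targets"  # miRNA -> mRNA


@dataclass(frozen=True)
class SubNetwork:
    """First-neighbourhood tripartite subnetwork of one hub lncRNA."""

    hub: str
    mrnas: tuple
    mirnas: tuple
    hub_mirna_edges: tuple   # (hub, mirna), sorted
    mirna_mrna_edges: tuple  # (mirna, mrna), sorted

    @property
    def typed_edges(self):
        """Uniform (interaction, source, target) triples, deterministic order."""
        return tuple((SPONGES, a, b) for a, b in self.hub_mirna_edges) + \
               tuple((TARGETS, a, b) for a, b in self.mirna_mrna_edges)


def extract_subnetwork(hub: str, net: CeRNANetwork) -> SubNetwork:
    """Expand the hub's retained pairs into the tripartite subnetwork.

    Raises
    ------
    ValueError
        If ``hub`` is not a lncRNA node of the network.
    """
    if hub not in net.lnc_nodes:
        raise ValueError(f"{hub!r} is not a lncRNA node of the network")
    mrnas = set()
    mirnas = set()
    mm_edges = set()
    for e in net.edges:
        if e.lnc != hub:
            continue
        mrnas.add(e.mrna)
        for mir in e.shared:
            mirnas.add(mir)
            mm_edges.add((mir, e.mrna))
    hm_edges = tuple((hub, mir) for mir in sorted(mirnas))
    return SubNetwork(
        hub=hub,
        mrnas=tuple(sorted(mrnas)),
        mirnas=tuple(sorted(mirnas)),
        hub_mirna_edges=hm_edges,
        mirna_mrna_edges=tuple(sorted(mm_edges)),
    )


def export_subnetwork(sub: SubNetwork, outdir) -> dict:
    """Write SIF, node-attribute TSV and a JSON summary under ``outdir``.

    Output ordering is deterministic (sorted by interaction type, then ids).
    Returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "network.sif", "w", encoding="utf-8") as fh:
        for kind, a, b in sub.typed_edges:
            fh.write(f"{a}\t{kind}\t{b}\n")
    with open(outdir / "nodes.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\ttype\n")
        fh.write(f"{sub.hub}\tlncRNA\n")
        for mir in sub.mirnas:
            fh.write(f"{mir}\tmiRNA\n")
        for g in sub.mrnas:
            fh.write(f"{g}\tmRNA\n")
    summary = {
        "hub": sub.hub,
        "n_mrna": len(sub.mrnas),
        "n_mirna": len(sub.mirnas),
        "n_sponges_edges": len(sub.hub_mirna_edges),
        "n_targets_edges": len(sub.mirna_mrna_edges),
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def read_sif(path) -> tuple:
    """Read typed edges back from a SIF file as (interaction, source, target)."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            a, kind, b = fields
            edges.append((kind, a, b))
    return tuple(edges)
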