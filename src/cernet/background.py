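"""Interaction tables and the sampling frame for the shared-miRNA test.

A competing-endogenous-RNA (ceRNA) pair test asks whether a lncRNA and an
mRNA share more miRNA partners than expected under random targeting.  The
null model draws the lncRNA's miRNA partners uniformly from a fixed miRNA
universe, so before any pair can be scored the two interaction tables
(lncRNA->miRNA, e.g. CLIP-supported associations; mRNA->miRNA, e.g. curated
target pairs) have to be reconciled into a single
:class:`InteractionBackground`: one universe of size ``m``, and per-gene
target sets clipped to that universe so that set sizes never exceed ``m``.

The two source databases typically cover different miRNA universes.  Three
policies are offered: ``mrna_db`` (the universe is every miRNA appearing in
the mRNA-side table), ``union`` and ``intersection``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

log = logging.getLogger(__name__)

UNIVERSE_POLICIES = ("mrna_db", "union", "intersection")


@dataclass(frozen=True)
class InteractionBackground:
    """miRNA universe plus clipped per-gene target sets.

    Attributes
    ----------
    universe
        All miRNA ids admissible under the chosen policy; ``m = len(universe)``.
    lnc_targets, mrna_targets
        Maps gene id -> frozenset of miRNA ids, already clipped to the
        universe.  Entries whose clipped set was empty have been dropped.
    universe_policy
        One of :data:`UNIVERSE_POLICIES`.
    dropped_lnc, dropped_mrna
        Number of entries removed because clipping emptied their target set.
    """

    universe: frozenset
    lnc_targets: dict = field(repr=False)
    mrna_targets: dict = field(repr=False)
    universe_policy: str = "mrna_db"
    dropped_lnc: int = 0
    dropped_mrna: int = 0

    @property
    def m(self) -> int:
        """Universe size (the hypergeometric population size)."""
        return len(self.universe)


def read_interactions(path, kind: str = "interaction") -> dict:
    """Read a two-column interaction TSV into a source -> miRNA-set map.

    The dialect is ``source<TAB>mirna`` with an optional header row, ``#``
    comment lines, and extra columns ignored.  Duplicate rows collapse to a
    single set membership; identifiers are taken verbatim (case-sensitive).

    Parameters
    ----------
    path
        TSV file.  For a lncRNA-miRNA table the source column holds lncRNA
        ids; for a miRNA-mRNA table it holds mRNA ids.
    kind
        Label used in log/error messages only.

    Raises
    ------
    ValueError
        On a row with fewer than two columns (reported with its line number).
    """
    out: dict = {}
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: malformed {kind} row "
                    f"(expected >=2 tab-separated columns, got {len(fields)})"
                )
            source, mirna = fields[0], fields[1]
            if n_rows == 0 and (source, mirna) == ("source", "mirna"):
                n_rows += 1  # header
                continue
            n_rows += 1
            out.setdefault(source, set()).add(mirna)
    if not out:
        log.warning("%s: empty %s table", path, kind)
    return {k: frozenset(v) for k, v in out.items()}


def _clip(targets: Mapping, universe: frozenset):
    clipped, dropped = {}, 0
    for gene, mirnas in targets.items():
        kept = frozenset(mirnas) & universe
        if kept:
            clipped[gene] = kept
        else:
            dropped += 1
    return clipped, dropped


def build_background(lnc_map: Mapping, mrna_map: Mapping,
                     policy: str = "mrna_db") -> InteractionBackground:
    """Reconcile the two interaction maps into a single sampling frame.

    The default policy ``mrna_db`` defines the universe as every miRNA
    appearing in the mRNA-side table, mirroring the convention that ``m`` is
    the total miRNA count of the mRNA-target database.  lncRNA target sets
    are clipped to the universe (required for the hypergeometric test to be
    well defined, since a draw cannot exceed the population); entries whose
    clipped set is empty are dropped and counted.
    """
    if policy not in UNIVERSE_POLICIES:
        raise ValueError(f"unknown universe policy {policy!r}; choose from {UNIVERSE_POLICIES}")
    if not lnc_map or not mrna_map:
        raise ValueError("both interaction maps must be non-empty")
    lnc_mirnas = frozenset().union(*lnc_map.values())
    mrna_mirnas = frozenset().union(*mrna_map.values())
    if policy == "mrna_db":
        universe = mrna_mirnas
    elif policy == "union":
        universe = lnc_mirnas | mrna_mirnas
    else:
        universe = lnc_mirnas & mrna_mirnas
    if not universe:
        raise ValueError(f"universe is empty under policy {policy!r}")
    lnc_targets, dropped_lnc = _clip(lnc_map, universe)
    mrna_targets, dropped_mrna = _clip(mrna_map, universe)
    if dropped_lnc or dropped_mrna:
        log.warning(
            "background clipping dropped %d lncRNA and %d mRNA entries "
            "with no miRNA inside the %s universe", dropped_lnc, dropped_mrna, policy,
        )
    return InteractionBackground(
        universe=universe,
        lnc_targets=lnc_targets,
        mrna_targets=mrna_targets,
        universe_policy=policy,
        dropped_lnc=dropped_lnc,
        dropped_mrna=dropped_mrna,
    )


def background_stats(bg: InteractionBackground) -> dict:
    """Summary counts analogous to a database release note.

    Reports pair counts (sum of clipped set sizes), distinct entity counts on
    each side, the universe size ``m`` and clipping losses.  Invariant to the
    row order of the source tables (everything is set-based).
    """
    lnc_mirnas = frozenset().union(*bg.lnc_targets.values()) if bg.lnc_targets else frozenset()
    mrna_mirnas = frozenset().union(*bg.mrna_targets.values()) if bg.mrna_targets else frozenset()
    return {
        "lnc_mirna_pairs": sum(len(v) for v in bg.lnc_targets.values()),
        "mirna_mrna_pairs": sum(len(v) for v in bg.mrna_targets.values()),
        "n_lncrna": len(bg.lnc_targets),
        "n_mrna": len(bg.mrna_targets),
        "n_mirna_lnc_side": len(lnc_mirnas),
        "n_mirna_mrna_side": len(mrna_mirnas),
        "m": bg.m,
        "universe_policy": bg.universe_policy,
        "dropped_lnc": bg.dropped_lnc,
        "dropped_mrna": bg.dropped_mrna,
    }
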