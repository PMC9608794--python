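"""Synthetic interaction backgrounds and expression matrices with planted truth.

Every downstream stage of the pipeline is testable without external
downloads: this module generates (a) lncRNA->miRNA and mRNA->miRNA target
maps over one shared miRNA universe, with a configurable number of planted
lncRNA-mRNA pairs that are forced to share ``planted_shared`` dedicated
miRNAs on top of sparse uniform base targeting, and (b) a two-group log2
expression matrix in which a planted fraction of genes receives a +/-
``effect_size`` mean shift with i.i.d. Gaussian noise — the simplest model
consistent with quantile-normalized microarray intensities.

Planted pairs can be grouped onto hub lncRNAs
(``partners_per_planted_lnc`` pairs share one lncRNA), which plants both the
ceRNA-pair signal and the topological hub signal in one structure.  The
ground truth (planted pairs, hub lncRNAs, DE genes and directions) is
returned as a :class:`SimTruth` so recovery can be measured exactly.

All randomness flows from ``SimConfig.seed`` through a single
:class:`numpy.random.Generator`; no global state is touched.  Identical
configs produce byte-identical serialized outputs.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .background import InteractionBackground
from .preprocess import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the study conditions at desk scale.

    The interaction side mimics two sparse target databases over one miRNA
    universe (real databases list hundreds of miRNAs and thousands of
    targets; counts here are scaled down to keep the full pipeline fast).
    The expression side mimics a 10-vs-10 granulosa-cell microarray
    comparison on log2 scale.

    Attributes
    ----------
    n_mirna, n_lnc, n_mrna
        Universe and gene-space sizes.
    base_targets_per_lnc, base_targets_per_mrna
        miRNAs drawn uniformly without replacement for every gene.
    n_planted_pairs
        lncRNA-mRNA pairs forced to share miRNAs beyond chance.
    planted_shared
        Dedicated miRNAs common to each planted pair (its guaranteed
        minimum shared count).
    partners_per_planted_lnc
        Planted pairs grouped onto each planted lncRNA; values > 1 plant
        hub lncRNAs (defaults give 24 / 6 = 4 hubs with 6 mRNA partners each).
    n_genes
        Genes in a standalone expression matrix (the study generator uses
        ``n_lnc + n_mrna`` instead so expression and interaction ids match).
    n_per_group
        Samples per group (case and control).
    de_fraction
        Fraction of genes receiving a mean shift.
    effect_size, noise_sd
        log2-scale shift magnitude and i.i.d. Gaussian noise sd.
    """

    n_mirna: int = 600
    n_lnc: int = 80
    n_mrna: int = 300
    base_targets_per_lnc: int = 10
    base_targets_per_mrna: int = 8
    n_planted_pairs: int = 24
    planted_shared: int = 8
    partners_per_planted_lnc: int = 6
    n_genes: int = 380
    n_per_group: int = 10
    de_fraction: float = 0.15
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mirna", "n_lnc", "n_mrna", "base_targets_per_lnc",
                     "base_targets_per_mrna", "n_planted_pairs",
                     "planted_shared", "n_genes", "n_per_group"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.partners_per_planted_lnc < 1:
            raise ValueError("partners_per_planted_lnc must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError(f"de_fraction must lie in [0, 1], got {self.de_fraction}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        reserved = self.n_planted_pairs * self.planted_shared
        if reserved > self.n_mirna:
            raise ValueError(
                f"infeasible config: n_planted_pairs * planted_shared = {reserved} "
                f"dedicated shared miRNAs exceed the universe (n_mirna={self.n_mirna})")
        free = self.n_mirna - reserved
        if self.base_targets_per_lnc > free:
            raise ValueError(
                f"infeasible config: base_targets_per_lnc={self.base_targets_per_lnc} "
                f"exceeds the {free} miRNAs left after reserving "
                f"{reserved} for planted sharing (n_mirna={self.n_mirna})")
        if self.base_targets_per_mrna > free:
            raise ValueError(
                f"infeasible config: base_targets_per_mrna={self.base_targets_per_mrna} "
                f"exceeds the {free} miRNAs left after reserving "
                f"{reserved} for planted sharing (n_mirna={self.n_mirna})")
        if self.n_planted_hubs > self.n_lnc:
            raise ValueError(
                f"infeasible config: {self.n_planted_pairs} planted pairs at "
                f"{self.partners_per_planted_lnc} partners per lncRNA need "
                f"{self.n_planted_hubs} lncRNAs, but n_lnc={self.n_lnc}")
        if self.n_planted_pairs > self.n_mrna:
            raise ValueError(
                f"infeasible config: n_planted_pairs={self.n_planted_pairs} "
                f"exceeds n_mrna={self.n_mrna} (each pair uses a distinct mRNA)")

    @property
    def n_planted_hubs(self) -> int:
        if self.n_planted_pairs == 0:
            return 0
        return math.ceil(self.n_planted_pairs / self.partners_per_planted_lnc)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulation.

    ``planted_pairs`` lists (lncRNA, mRNA) pairs with forced sharing;
    ``planted_shared_mirnas`` maps each pair to its dedicated common miRNAs;
    ``planted_lncs`` are the (hub) lncRNAs carrying planted pairs;
    ``de_genes`` lists (gene id, direction) for the shifted genes.
    """

    planted_pairs: tuple = ()
    planted_lncs: tuple = ()
    planted_shared_mirnas: dict = field(default_factory=dict)
    de_genes: tuple = ()

    @property
    def de_gene_ids(self) -> frozenset:
        return frozenset(g for g, _ in self.de_genes)


def _ids(prefix: str, n: int) -> list:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def mirna_ids(cfg: SimConfig) -> list:
    return _ids("MIR", cfg.n_mirna)


def lnc_ids(cfg: SimConfig) -> list:
    return _ids("LNC", cfg.n_lnc)


def mrna_ids(cfg: SimConfig) -> list:
    return _ids("MRNA", cfg.n_mrna)


def generate_background(cfg: SimConfig, rng=None):
    """Generate the two target maps with planted shared-miRNA structure.

    Every gene draws its base targets uniformly without replacement from the
    non-reserved part of the universe; each planted pair additionally gets a
    dedicated, pairwise-disjoint block of ``planted_shared`` miRNAs added to
    both sides, so its shared count is at least ``planted_shared`` by
    construction while non-planted pairs share only by chance.

    Returns
    -------
    (InteractionBackground, SimTruth)
        The background's universe is the full simulated miRNA id space.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    mirnas = np.array(mirna_ids(cfg))
    lncs = lnc_ids(cfg)
    mrnas = mrna_ids(cfg)

    reserved_n = cfg.n_planted_pairs * cfg.planted_shared
    perm = rng.permutation(cfg.n_mirna)
    reserved = mirnas[perm[:reserved_n]]
    free = np.sort(mirnas[perm[reserved_n:]])

    lnc_targets = {
        l: set(rng.choice(free, size=cfg.base_targets_per_lnc, replace=False))
        for l in lncs
    }
    mrna_targets = {
        g: set(rng.choice(free, size=cfg.base_targets_per_mrna, replace=False))
        for g in mrnas
    }

    planted_pairs = []
    planted_shared_mirnas = {}
    for pair_idx in range(cfg.n_planted_pairs):
        hub = lncs[pair_idx // cfg.partners_per_planted_lnc]
        partner = mrnas[pair_idx]
        chunk = frozenset(reserved[pair_idx * cfg.planted_shared:
                                   (pair_idx + 1) * cfg.planted_shared])
        lnc_targets[hub] |= chunk
        mrna_targets[partner] |= chunk
        planted_pairs.append((hub, partner))
        planted_shared_mirnas[(hub, partner)] = chunk

    bg = InteractionBackground(
        universe=frozenset(mirnas),
        lnc_targets={k: frozenset(v) for k, v in lnc_targets.items()},
        mrna_targets={k: frozenset(v) for k, v in mrna_targets.items()},
        universe_policy="union",
    )
    truth = SimTruth(
        planted_pairs=tuple(planted_pairs),
        planted_lncs=tuple(dict.fromkeys(l for l, _ in planted_pairs)),
        planted_shared_mirnas=planted_shared_mirnas,
    )
    return bg, truth


def generate_expression(cfg: SimConfig, rng=None, gene_ids=None, de_genes=None):
    """Generate a two-group log2 expression matrix with planted DE genes.

    Baseline per-gene means are uniform on [6, 12] log2 units; DE genes get
    ``+effect_size`` (up) or ``-effect_size`` (down) added to the case-group
    mean, directions assigned 50/50 at random unless ``de_genes`` (a list of
    (gene id, direction) pairs) is supplied.  Noise is i.i.d. Gaussian with
    sd ``noise_sd``.

    Returns
    -------
    (ExpressionMatrix, SimTruth)
    """
    cfg.validate()
    if cfg.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (group variance undefined below)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if gene_ids is None:
        gene_ids = _ids("GENE", cfg.n_genes)
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)
    if de_genes is None:
        n_de = round(cfg.de_fraction * n_genes)
        chosen = sorted(rng.choice(np.array(gene_ids), size=n_de, replace=False))
        dirs = rng.choice(np.array(["up", "down"]), size=n_de)
        de_genes = list(zip(chosen, dirs))
    de_genes = [(g, str(d)) for g, d in de_genes]
    unknown = [g for g, _ in de_genes if g not in set(gene_ids)]
    if unknown:
        raise ValueError(f"de_genes outside the gene id space: {unknown[:5]}")

    base = rng.uniform(6.0, 12.0, size=n_genes)
    shift = np.zeros(n_genes)
    pos = {g: i for i, g in enumerate(gene_ids)}
    for g, d in de_genes:
        shift[pos[g]] = cfg.effect_size if d == "up" else -cfg.effect_size

    n = cfg.n_per_group
    samples = [f"case{i:02d}" for i in range(1, n + 1)] + \
              [f"ctrl{i:02d}" for i in range(1, n + 1)]
    means = np.column_stack([
        np.repeat((base + shift)[:, None], n, axis=1),
        np.repeat(base[:, None], n, axis=1),
    ])
    values = means + rng.normal(0.0, cfg.noise_sd, size=means.shape) \
        if cfg.noise_sd > 0 else means
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene"),
                      columns=samples)
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    em = ExpressionMatrix(values=df, groups=groups)
    return em, SimTruth(de_genes=tuple(de_genes))


@dataclass(frozen=True)
class StudyData:
    """A complete synthetic study: interactions + expression + ground truth."""

    config: SimConfig
    background: InteractionBackground
    expression: ExpressionMatrix
    biotypes: dict
    truth: SimTruth


def simulate_study(cfg: SimConfig) -> StudyData:
    """Generate a coherent study: expression genes are the interaction genes.

    All members of planted pairs are forced into the DE set (the remaining
    DE slots up to ``de_fraction`` are filled at random), so the planted
    ceRNA edges survive the differential-expression gate and recovery of the
    full pipeline can be scored against truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    bg, truth_bg = generate_background(cfg, rng)
    genes = lnc_ids(cfg) + mrna_ids(cfg)
    planted_genes = sorted({g for pair in truth_bg.planted_pairs for g in pair})
    n_de = max(round(cfg.de_fraction * len(genes)), len(planted_genes))
    pool = sorted(set(genes) - set(planted_genes))
    extra = sorted(rng.choice(np.array(pool), size=n_de - len(planted_genes),
                              replace=False)) if n_de > len(planted_genes) else []
    de_ids = planted_genes + list(extra)
    dirs = rng.choice(np.array(["up", "down"]), size=len(de_ids))
    de_genes = list(zip(de_ids, dirs))
    expr, truth_expr = generate_expression(cfg, rng, gene_ids=genes,
                                           de_genes=de_genes)
    biotypes = {g: "lncRNA" for g in lnc_ids(cfg)}
    biotypes.update({g: "protein_coding" for g in mrna_ids(cfg)})
    truth = SimTruth(
        planted_pairs=truth_bg.planted_pairs,
        planted_lncs=truth_bg.planted_lncs,
        planted_shared_mirnas=truth_bg.planted_shared_mirnas,
        de_genes=truth_expr.de_genes,
    )
    return StudyData(config=cfg, background=bg, expression=expr,
                     biotypes=biotypes, truth=truth)


# ---------------------------------------------------------------------------
# writers (same TSV dialects the real-data readers consume)

def write_interactions(targets: dict, path) -> None:
    """Write a source -> miRNA-set map as a ``source<TAB>mirna`` TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\tmirna\n")
        for src in sorted(targets):
            for mir in sorted(targets[src]):
                fh.write(f"{src}\t{mir}\n")


def write_expression(em: ExpressionMatrix, path) -> None:
    out = em.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_groups(em: ExpressionMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgroup\n")
        for s in em.values.columns:
            fh.write(f"{s}\t{em.groups[s]}\n")


def write_biotypes(biotypes: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tbiotype\n")
        for g in sorted(biotypes):
            fh.write(f"{g}\t{biotypes[g]}\n")


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "planted_pairs": [list(p) for p in truth.planted_pairs],
        "planted_lncs": list(truth.planted_lncs),
        "planted_shared_mirnas": {
            f"{l}|{g}": sorted(mirs)
            for (l, g), mirs in sorted(truth.planted_shared_mirnas.items())
        },
        "de_genes": [list(p) for p in truth.de_genes],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_study(study: StudyData, outdir) -> dict:
    """Write every study artifact under ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "lnc_mirna": outdir / "lnc_mirna.tsv",
        "mirna_mrna": outdir / "mirna_mrna.tsv",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "biotypes": outdir / "biotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_interactions(study.background.lnc_targets, files["lnc_mirna"])
    write_interactions(study.background.mrna_targets, files["mirna_mrna"])
    write_expression(study.expression, files["expression"])
    write_groups(study.expression, files["groups"])
    write_biotypes(study.biotypes, files["biotypes"])
    write_truth(study.truth, files["truth"])
    return {k: str(v) for k, v in files.items()}
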