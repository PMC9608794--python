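"""Two-group differential expression on a log2 intensity matrix.

The stage mirrors a standard two-colour/one-colour microarray workflow:
quantile-normalize log2 intensities across samples, test each gene with a
two-sided Welch (unequal-variance) t-test, adjust p-values by
Benjamini-Hochberg, and keep genes with ``fdr < fdr_max`` and
``|log2FC| > lfc_min``.  Retained genes are split by biotype into DELs
(differentially expressed lncRNAs) and DEGs (differentially expressed
protein-coding mRNAs), the inputs of the ceRNA pair test.

The matrix is assumed to be on log2 scale already; an explicit
``log2_offset`` can be requested to apply ``log2(x + offset)``, but no
auto-detection is performed.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GROUPS = ("case", "control")
BIOTYPES = ("lncRNA", "protein_coding")


@dataclass
class ExpressionMatrix:
    """A genes x samples log2 expression matrix with a two-group design.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``groups`` maps every sample id to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: dict

    def __post_init__(self):
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene ids: {dups}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in df.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing[:5]}")
        bad = sorted({g for s, g in self.groups.items() if g not in GROUPS})
        if bad:
            raise ValueError(f"group labels must be in {GROUPS}, got {bad}")
        labels = [self.groups[s] for s in df.columns]
        for g in GROUPS:
            if labels.count(g) == 0:
                raise ValueError(f"group {g!r} has no samples")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ValueError(_nonfinite_report(df))

    def samples_of(self, group: str):
        return [s for s in self.values.columns if self.groups[s] == group]


def _nonfinite_report(df: pd.DataFrame) -> str:
    arr = df.to_numpy(dtype=float)
    rows, cols = np.nonzero(~np.isfinite(arr))
    cells = [f"({df.index[i]}, {df.columns[j]})" for i, j in zip(rows[:5], cols[:5])]
    return f"non-finite expression values at {', '.join(cells)}" + (
        " ..." if len(rows) > 5 else "")


def collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene ids to the row with highest mean expression.

    The common convention when several probes map to one gene symbol.
    """
    if not df.index.has_duplicates:
        return df
    means = df.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="mergesort")  # stable: first-highest wins
    keep = ~pd.Index(df.index[order]).duplicated()
    chosen = np.sort(order[keep])
    return df.iloc[chosen]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; each
    column's values are replaced by the reference values at their
    within-column ranks, so after normalization all columns share the same
    multiset of values while within-column rank order is preserved.  Ties
    within a column receive the mean of the reference values at the tied
    positions.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    arr = df.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(_nonfinite_report(df))
    n = arr.shape[0]
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        sorter = np.argsort(col, kind="mergesort")
        sorted_col = col[sorter]
        starts = np.r_[0, np.nonzero(np.diff(sorted_col))[0] + 1]
        lens = np.diff(np.r_[starts, n])
        seg_means = np.add.reduceat(ref, starts) / lens
        out[sorter, j] = np.repeat(seg_means, lens)
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=df.index, columns=df.columns),
        groups=dict(matrix.groups),
    )


def welch_t(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene two-sided Welch t-test, case vs control.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (case mean
    minus control mean) and ``p``.  Degenerate genes with zero variance in
    both groups get ``p = 1`` when the means are equal and ``p = 0``
    otherwise.
    """
    case = matrix.samples_of("case")
    ctrl = matrix.samples_of("control")
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got case={len(case)}, control={len(ctrl)}")
    a = matrix.values[case].to_numpy(dtype=float)
    b = matrix.values[ctrl].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's precision-loss warning; those rows
        # are overwritten by the degenerate rules below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    p = np.where(degenerate, np.where(lfc == 0, 1.0, 0.0), p)
    return pd.DataFrame({"log2fc": lfc, "p": p}, index=matrix.values.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Equivalent to ``min_{j >= i} min(1, p_(j) * m / j)`` placed back at each
    input position.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][:5]
        raise ValueError(f"p-values outside [0, 1]: {bad}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_table(matrix: ExpressionMatrix, biotypes: Mapping | None = None,
             quantile: bool = True, log2_offset: float | None = None) -> pd.DataFrame:
    """Run the full per-gene stage: normalize, test, adjust, annotate.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``p``,
    ``fdr``, ``direction`` (``up`` iff log2fc > 0) and, when ``biotypes`` is
    given, ``biotype``.
    """
    df = collapse_duplicates(matrix.values)
    if log2_offset is not None:
        df = np.log2(df + log2_offset)
    em = ExpressionMatrix(values=df, groups=dict(matrix.groups))
    if quantile:
        em = quantile_normalize(em)
    table = welch_t(em)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    if biotypes is not None:
        table["biotype"] = [biotypes.get(g) for g in table.index]
    return table


@dataclass(frozen=True)
class FilterResult:
    """DE genes split by biotype, with direction counts."""

    dels: tuple
    degs: tuple
    n_up: int
    n_down: int
    dropped_missing: int = 0

    def __iter__(self):  # allows `dels, degs = filter_de(...)`
        return iter((list(self.dels), list(self.degs)))


def filter_de(de: pd.DataFrame, biotypes: Mapping,
              fdr_max: float = 0.05, lfc_min: float = 1.0,
              use_raw_p: bool = False, on_missing: str = "drop") -> FilterResult:
    """Apply the significance filter and split retained genes by biotype.

    A gene is retained iff its (adjusted, or raw if ``use_raw_p``) p-value
    is strictly below ``fdr_max`` and ``|log2fc|`` strictly exceeds
    ``lfc_min``.  Genes absent from the biotype table are dropped with a
    warning by default, or raise when ``on_missing='error'``.
    """
    if fdr_max <= 0 or lfc_min < 0:
        raise ValueError("thresholds must be positive")
    if on_missing not in ("drop", "error"):
        raise ValueError("on_missing must be 'drop' or 'error'")
    pcol = de["p"] if use_raw_p else de["fdr"]
    mask = (pcol < fdr_max) & (de["log2fc"].abs() > lfc_min)
    retained = de.index[mask]
    dels, degs, missing = [], [], []
    n_up = n_down = 0
    for gene in retained:
        bt = biotypes.get(gene)
        if bt is None:
            missing.append(gene)
            continue
        if bt == "lncRNA":
            dels.append(gene)
        elif bt == "protein_coding":
            degs.append(gene)
        else:
            raise ValueError(f"unknown biotype {bt!r} for gene {gene!r}")
        if de.at[gene, "log2fc"] > 0:
            n_up += 1
        else:
            n_down += 1
    if missing:
        if on_missing == "error":
            raise ValueError(f"genes missing from biotype table: {missing[:5]}")
        log.warning("dropped %d retained genes missing from the biotype table",
                    len(missing))
    return FilterResult(dels=tuple(sorted(dels)), degs=tuple(sorted(degs)),
                        n_up=n_up, n_down=n_down, dropped_missing=len(missing))


# ---------------------------------------------------------------------------
# readers / writers (TSV dialects shared with the synthetic writers)

def read_expression(expr_path, groups_path) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids) and a group table."""
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups = read_groups(groups_path)
    return ExpressionMatrix(values=df.astype(float), groups=groups)


def read_groups(path) -> dict:
    g = pd.read_csv(path, sep="\t", dtype=str)
    if list(g.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: expected columns 'sample' and 'group'")
    return dict(zip(g["sample"], g["group"]))


def read_biotypes(path) -> dict:
    b = pd.read_csv(path, sep="\t", dtype=str)
    if list(b.columns[:2]) != ["gene", "biotype"]:
        raise ValueError(f"{path}: expected columns 'gene' and 'biotype'")
    bad = sorted(set(b["biotype"]) - set(BIOTYPES))
    if bad:
        raise ValueError(f"{path}: biotypes must be in {BIOTYPES}, got {bad}")
    return dict(zip(b["gene"], b["biotype"]))


def write_de_table(de: pd.DataFrame, path) -> None:
    out = de.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
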