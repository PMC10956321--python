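"""Differential-expression thresholds, NSV-DEG linking, and chromatin overlay.

Expression statistics arrive as a long table with one row per
(gene, tissue, comparison); genes passing |log2FC| >= 1 and adjusted
P < 0.05 in both breed comparisons of a tissue (with a consistent direction
by default) are that tissue's common DEGs. NSVs within the flank distance of
a common DEG are linked to it, and the linked NSVs are then intersected with
per-tissue chromatin-state segmentations to flag promoter-class (TssA,
TssAFlnk) and enhancer-class (Enh, EnhG) overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genes import GeneModel, genes_by_chrom
from .svcalls import StructuralVariant
from .synteny import interval_gap

DEFAULT_LFC_MIN = 1.0
DEFAULT_PADJ_MAX = 0.05
DEFAULT_FLANK = 5_000
PROMOTER_STATES = ("TssA", "TssAFlnk")
ENHANCER_STATES = ("Enh", "EnhG")
KNOWN_STATES = ("TssA", "TssAFlnk", "Tx", "Enh", "EnhG", "Quies")

EXPRESSION_COLUMNS = ["gene_id", "tissue", "comparison", "log2fc", "padj"]
CHROMATIN_COLUMNS = ["tissue", "chrom", "start", "end", "state"]


def validate_expression_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(EXPRESSION_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"expression table lacks columns: {sorted(missing)}")
    if ((records["padj"] < 0) | (records["padj"] > 1)).any():
        raise ValueError("padj values must lie in [0, 1]")
    return records


def call_degs(records: pd.DataFrame,
              lfc_min: float = DEFAULT_LFC_MIN,
              padj_max: float = DEFAULT_PADJ_MAX) -> dict[tuple[str, str], set[str]]:
    """DEG sets per (tissue, comparison): |log2FC| >= lfc_min and padj < padj_max."""
    if lfc_min <= 0 or padj_max <= 0:
        raise ValueError("thresholds must be positive")
    records = validate_expression_table(records)
    hit = records[(records["log2fc"].abs() >= lfc_min) & (records["padj"] < padj_max)]
    out: dict[tuple[str, str], set[str]] = {
        (t, c): set() for t, c in records[["tissue", "comparison"]].drop_duplicates().itertuples(index=False)
    }
    for (t, c), sub in hit.groupby(["tissue", "comparison"]):
        out[(t, c)] = set(sub["gene_id"])
    return out


def common_degs(records: pd.DataFrame,
                lfc_min: float = DEFAULT_LFC_MIN,
                padj_max: float = DEFAULT_PADJ_MAX,
                require_consistent_sign: bool = True) -> dict[str, set[str]]:
    """Per-tissue intersection of the two breed comparisons' DEG sets.

    With ``require_consistent_sign`` (default), a gene must be regulated in
    the same direction in both comparisons.
    """
    records = validate_expression_table(records)
    deg_sets = call_degs(records, lfc_min, padj_max)
    tissues = sorted({t for t, _ in deg_sets})
    out: dict[str, set[str]] = {}
    for tissue in tissues:
        comps = sorted({c for t, c in deg_sets if t == tissue})
        if len(comps) != 2:
            raise ValueError(f"tissue {tissue!r}: expected 2 comparisons, found {comps}")
        genes = deg_sets[(tissue, comps[0])] & deg_sets[(tissue, comps[1])]
        if require_consistent_sign and genes:
            sub = records[(records["tissue"] == tissue)
                          & (records["gene_id"].isin(genes))]
            signs = sub.pivot_table(index="gene_id", columns="comparison",
                                    values="log2fc", aggfunc="first")
            consistent = signs.apply(lambda r: np.sign(r[comps[0]]) == np.sign(r[comps[1]]),
                                     axis=1)
            genes = set(consistent.index[consistent])
        out[tissue] = genes
    return out


@dataclass
class LinkedTriple:
    sv_id: str
    gene_id: str
    tissue: str


def link_nsv_deg(nsvs: Sequence[StructuralVariant],
                 common: Mapping[str, set[str]],
                 genes: Sequence[GeneModel],
                 flank: int = DEFAULT_FLANK) -> list[LinkedTriple]:
    """(NSV, gene, tissue) triples: gene is a common DEG of the tissue and the
    NSV lies within gene body +/- ``flank``."""
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    gene_map = {g.gene_id: g for g in genes}
    by_chrom = genes_by_chrom(genes)
    out: list[LinkedTriple] = []
    for sv in nsvs:
        lo, hi = sv.interval0()
        near = [g.gene_id for g in by_chrom.get(sv.chrom, [])
                if interval_gap(g.start, g.end, lo, hi) <= flank]
        for tissue in sorted(common):
            for gid in near:
                if gid in common[tissue]:
                    out.append(LinkedTriple(sv.sv_id, gid, tissue))
    return out


def validate_chromatin_table(segments: pd.DataFrame) -> pd.DataFrame:
    missing = set(CHROMATIN_COLUMNS) - set(segments.columns)
    if missing:
        raise ValueError(f"chromatin table lacks columns: {sorted(missing)}")
    if (segments["start"] >= segments["end"]).any():
        raise ValueError("chromatin segments must have start < end")
    unknown = set(segments["state"]) - set(KNOWN_STATES)
    if unknown:
        warnings.warn(f"unknown chromatin state label(s) kept verbatim: {sorted(unknown)}")
    return segments


def regulatory_overlap(triples: Sequence[LinkedTriple],
                       nsvs: Sequence[StructuralVariant],
                       segments: pd.DataFrame,
                       promoter_states: Sequence[str] = PROMOTER_STATES,
                       enhancer_states: Sequence[str] = ENHANCER_STATES,
                       background_states: Sequence[str] = ("Quies",)) -> pd.DataFrame:
    """Chromatin states under each linked NSV in the linked tissue.

    One row per triple with the overlapped state labels (background states
    excluded from the regulatory flags) and promoter/enhancer class flags;
    triples overlapping nothing are retained with an empty state list.
    """
    segments = validate_chromatin_table(segments)
    sv_map = {v.sv_id: v for v in nsvs}
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in segments.itertuples(index=False):
        trees.setdefault((row.tissue, row.chrom), IntervalTree()) \
            .addi(int(row.start), int(row.end), row.state)
    rows = []
    for tr in triples:
        sv = sv_map[tr.sv_id]
        lo, hi = sv.interval0()
        hi = max(hi, lo + 1)
        tree = trees.get((tr.tissue, sv.chrom), IntervalTree())
        states = sorted({iv.data for iv in tree.overlap(lo, hi)})
        reg = [s for s in states if s not in set(background_states)]
        rows.append({
            "sv_id": tr.sv_id, "gene_id": tr.gene_id, "tissue": tr.tissue,
            "states": ",".join(reg),
            "promoter": any(s in set(promoter_states) for s in states),
            "enhancer": any(s in set(enhancer_states) for s in states),
        })
    return pd.DataFrame(rows, columns=["sv_id", "gene_id", "tissue", "states",
                                       "promoter", "enhancer"])
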