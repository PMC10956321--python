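"""Synteny blocks and breakpoint regions from pairwise alignment blocks.

A synteny block is a maximal chain of collinear, consistently oriented
alignment blocks whose reference (target) span reaches a minimum size, the
"resolution". Breakpoint regions are the gaps between adjacent blocks that
belong to different synteny chains; they are the positional signature of a
rearrangement junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .alignment import AlignmentBlock
from .genes import GeneModel

DEFAULT_RESOLUTION = 300_000
DEFAULT_FLANK = 5_000


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Separation in bases between two 0-based half-open intervals (0 if they touch/overlap)."""
    return max(0, b_start - a_end, a_start - b_end)


@dataclass
class SyntenyBlock:
    """A chain of collinear alignment blocks with one orientation."""

    block_id: str
    members: list[AlignmentBlock] = field(default_factory=list, repr=False)
    target_name: str = ""
    target_start: int = 0
    target_end: int = 0
    query_name: str = ""
    query_start: int = 0
    query_end: int = 0
    orientation: str = "+"

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start


@dataclass
class BreakpointRegion:
    """Gap between two adjacent blocks of different synteny chains."""

    assembly_label: str
    chrom: str
    start: int
    end: int
    left_synteny_id: str
    right_synteny_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"breakpoint start {self.start} > end {self.end}")
        if self.left_synteny_id == self.right_synteny_id:
            raise ValueError("breakpoint must separate two different synteny chains")


def resolve_conflicts(blocks: Sequence[AlignmentBlock],
                      overlap_tol: int = 25) -> list[AlignmentBlock]:
    """Greedily drop blocks that overlap an already-accepted block on either genome.

    Blocks are considered in order of descending ``n_matches`` (ties broken by
    target coordinate), so the best-supported placement of any region wins.
    Edge overlaps up to ``overlap_tol`` bases (anchor-boundary effects) are
    tolerated rather than discarding an otherwise consistent block.
    """

    def _overlap_len(tree: IntervalTree, start: int, end: int) -> int:
        return sum(min(end, iv.end) - max(start, iv.begin)
                   for iv in tree.overlap(start, end))

    ranked = sorted(blocks, key=lambda b: (-b.n_matches, b.target_name, b.target_start))
    t_trees: dict[str, IntervalTree] = {}
    q_trees: dict[str, IntervalTree] = {}
    kept = []
    for b in ranked:
        tt = t_trees.setdefault(b.target_name, IntervalTree())
        qt = q_trees.setdefault(b.query_name, IntervalTree())
        if _overlap_len(tt, b.target_start, b.target_end) > overlap_tol \
                or _overlap_len(qt, b.query_start, b.query_end) > overlap_tol:
            continue
        tt.addi(b.target_start, b.target_end)
        qt.addi(b.query_start, b.query_end)
        kept.append(b)
    kept.sort(key=lambda b: (b.target_name, b.target_start))
    return kept


def _chain_compatible(a: SyntenyBlock, b: SyntenyBlock, slack: int) -> bool:
    """Can chain ``b`` (next on target) extend chain ``a`` collinearly?"""
    if a.query_name != b.query_name or a.orientation != b.orientation:
        return False
    if a.target_name != b.target_name or b.target_start < a.target_end - 50:
        return False
    t_gap = b.target_start - a.target_end
    if a.orientation == "+":
        q_gap = b.query_start - a.query_end
    else:
        q_gap = a.query_start - b.query_end
    return q_gap >= -50 and abs(t_gap - q_gap) <= slack


def _merge(a: SyntenyBlock, b: SyntenyBlock) -> SyntenyBlock:
    return SyntenyBlock(
        block_id=a.block_id, members=a.members + b.members,
        target_name=a.target_name,
        target_start=min(a.target_start, b.target_start),
        target_end=max(a.target_end, b.target_end),
        query_name=a.query_name,
        query_start=min(a.query_start, b.query_start),
        query_end=max(a.query_end, b.query_end),
        orientation=a.orientation)


def build_synteny_blocks(blocks: Sequence[AlignmentBlock],
                         resolution: int = DEFAULT_RESOLUTION,
                         merge_slack: int | None = None) -> list[SyntenyBlock]:
    """Chain collinear alignment blocks and keep chains spanning >= ``resolution``.

    Overlapping input blocks are first reduced to a consistent tiling
    (:func:`resolve_conflicts`). Adjacent blocks on the target that keep the
    same query chromosome, orientation and query order are chained; chains
    below the resolution are discarded as noise, and surviving neighbours
    separated only by sub-resolution material are re-joined when still
    collinear (gap discrepancy <= ``merge_slack``, default the resolution).
    """
    if merge_slack is None:
        merge_slack = resolution
    kept = resolve_conflicts(blocks)

    chains: list[SyntenyBlock] = []
    for b in kept:
        seed = SyntenyBlock("", [b], b.target_name, b.target_start, b.target_end,
                            b.query_name, b.query_start, b.query_end, b.strand)
        if chains and _chain_compatible(chains[-1], seed, merge_slack):
            chains[-1] = _merge(chains[-1], seed)
        else:
            chains.append(seed)

    # merge collinear chains separated only by sub-resolution material (which
    # is treated as noise at this resolution and discarded afterwards)
    changed = True
    while changed:
        changed = False
        chains.sort(key=lambda c: (c.target_name, c.target_start))
        for i in range(len(chains)):
            merged_any = False
            for j in range(i + 1, len(chains)):
                if any(chains[m].target_span >= resolution for m in range(i + 1, j)):
                    break
                if _chain_compatible(chains[i], chains[j], merge_slack):
                    chains[i] = _merge(chains[i], chains[j])
                    del chains[j]
                    changed = merged_any = True
                    break
            if merged_any:
                break
    chains = [c for c in chains if c.target_span >= resolution]

    chains.sort(key=lambda c: (c.target_name, c.target_start))
    for i, c in enumerate(chains):
        c.block_id = f"syn_{i:04d}"
    return chains


def find_breakpoint_regions(synteny_blocks: Sequence[SyntenyBlock],
                            assembly_label: str = "",
                            side: str = "target") -> list[BreakpointRegion]:
    """Gaps between adjacent synteny chains on one genome.

    ``side`` selects the coordinate system: ``"target"`` reports regions on
    the reference, ``"query"`` on the assembly being compared. Zero-length
    gaps are kept as point breakpoints. Chromosomes covered by a single
    chain yield nothing.
    """
    if side not in {"target", "query"}:
        raise ValueError(f"side must be 'target' or 'query', got {side!r}")
    get = ((lambda c: (c.target_name, c.target_start, c.target_end)) if side == "target"
           else (lambda c: (c.query_name, c.query_start, c.query_end)))
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c in synteny_blocks:
        name, s, e = get(c)
        by_chrom.setdefault(name, []).append((s, e, c.block_id))
    out: list[BreakpointRegion] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
            if id1 == id2:
                continue
            out.append(BreakpointRegion(assembly_label, chrom, e1, max(e1, s2), id1, id2))
    return out


@dataclass
class BreakpointAnnotation:
    breakpoint: BreakpointRegion
    genes: list[str]
    category: str  # exonic / intronic / intergenic


def annotate_breakpoints(breakpoints: Sequence[BreakpointRegion],
                         genes: Sequence[GeneModel],
                         flank: int = DEFAULT_FLANK) -> list[BreakpointAnnotation]:
    """List genes within ``flank`` of each breakpoint and classify the region.

    A breakpoint is *exonic* if it intersects any exon or UTR, *intronic* if
    it lies inside a gene body without touching exonic sequence, otherwise
    *intergenic*. Gene proximity is measured from the gene body, closed at
    the flank boundary.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for bp in breakpoints:
        s, e = bp.start, max(bp.end, bp.start + 1)  # point breakpoints probe one base
        near, category = [], "intergenic"
        for g in by_chrom.get(bp.chrom, []):
            if interval_gap(g.start, g.end, s, e) > flank:
                continue
            near.append(g.gene_id)
            if interval_gap(g.start, g.end, s, e) == 0 and category != "exonic":
                category = "intronic"
            for fs, fe in list(g.exons):
                if fs < e and fe > s:
                    category = "exonic"
                    break
        out.append(BreakpointAnnotation(bp, sorted(near), category))
    return out


def synteny_to_bed(synteny_blocks: Iterable[SyntenyBlock], path: str,
                   side: str = "target") -> None:
    rows = []
    for c in synteny_blocks:
        if side == "target":
            rows.append((c.target_name, c.target_start, c.target_end, c.block_id))
        else:
            rows.append((c.query_name, c.query_start, c.query_end, c.block_id))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]) \
        .to_csv(path, sep="\t", header=False, index=False)


def breakpoints_to_bed(breakpoints: Iterable[BreakpointRegion], path: str) -> None:
    rows = [(b.chrom, b.start, b.end, f"{b.left_synteny_id}|{b.right_synteny_id}")
            for b in breakpoints]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]) \
        .to_csv(path, sep="\t", header=False, index=False)
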