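"""Variant consequence classification against gene models.

Each (SV, gene) pair within the flank distance receives exactly one detail
term, chosen by precedence: coding sequence > UTR > splice region > intron >
upstream/downstream. Detail terms map onto three categories:

* exonic     - coding_sequence_variant, 5/3_prime_UTR_variant
* intronic   - splice_region_variant, intron_variant
* intergenic - upstream_gene_variant, downstream_gene_variant,
               intergenic_variant

SVs touching no gene within the flank receive a single gene-less
intergenic_variant call. Insertions are evaluated at their anchor point;
deletions, duplications and inversions over their full reference interval.
Distances are measured from the gene body with the flank boundary included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genes import GeneModel, genes_by_chrom
from .svcalls import StructuralVariant
from .synteny import interval_gap

DEFAULT_FLANK = 5_000
SPLICE_REGION_WINDOW = 8

CATEGORY_OF_DETAIL = {
    "coding_sequence_variant": "exonic",
    "5_prime_UTR_variant": "exonic",
    "3_prime_UTR_variant": "exonic",
    "splice_region_variant": "intronic",
    "intron_variant": "intronic",
    "upstream_gene_variant": "intergenic",
    "downstream_gene_variant": "intergenic",
    "intergenic_variant": "intergenic",
}


@dataclass
class ConsequenceCall:
    sv_id: str
    gene_id: str | None
    category: str
    detail: str

    def __post_init__(self) -> None:
        if CATEGORY_OF_DETAIL.get(self.detail) != self.category:
            raise ValueError(f"{self.sv_id}: detail {self.detail!r} does not map to "
                             f"category {self.category!r}")
        if self.gene_id is None and self.detail != "intergenic_variant":
            raise ValueError(f"{self.sv_id}: only intergenic_variant may lack a gene")


def _detail_for_pair(sv_lo: int, sv_hi: int, g: GeneModel, flank: int) -> str | None:
    """Most severe detail term for one SV interval against one gene, or None."""
    if interval_gap(g.start, g.end, sv_lo, sv_hi) > flank:
        return None
    overlaps_body = sv_lo < g.end and sv_hi > g.start
    if overlaps_body:
        if any(sv_lo < e and sv_hi > s for s, e in g.cds):
            return "coding_sequence_variant"
        if any(sv_lo < e and sv_hi > s for s, e in g.utr5):
            return "5_prime_UTR_variant"
        if any(sv_lo < e and sv_hi > s for s, e in g.utr3):
            return "3_prime_UTR_variant"
        for is_, ie in g.introns:
            w = min(SPLICE_REGION_WINDOW, ie - is_)
            if (sv_lo < is_ + w and sv_hi > is_) or (sv_lo < ie and sv_hi > ie - w):
                return "splice_region_variant"
        return "intron_variant"
    # flanking only: upstream/downstream is strand-aware
    before_gene = sv_hi <= g.start
    if g.strand == "+":
        return "upstream_gene_variant" if before_gene else "downstream_gene_variant"
    return "downstream_gene_variant" if before_gene else "upstream_gene_variant"


def classify_consequences(svs: Sequence[StructuralVariant],
                          genes: Sequence[GeneModel],
                          flank: int = DEFAULT_FLANK) -> list[ConsequenceCall]:
    """One consequence call per (SV, nearby gene); gene-less intergenic otherwise."""
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    by_chrom = genes_by_chrom(genes)
    calls: list[ConsequenceCall] = []
    for sv in svs:
        lo, hi = sv.interval0()
        found = False
        for g in by_chrom.get(sv.chrom, []):
            detail = _detail_for_pair(lo, hi, g, flank)
            if detail is not None:
                calls.append(ConsequenceCall(sv.sv_id, g.gene_id,
                                             CATEGORY_OF_DETAIL[detail], detail))
                found = True
        if not found:
            calls.append(ConsequenceCall(sv.sv_id, None, "intergenic", "intergenic_variant"))
    return calls


def flanking_genes(svs: Sequence[StructuralVariant],
                   genes: Sequence[GeneModel],
                   flank: int = DEFAULT_FLANK) -> dict[str, list[str]]:
    """Genes whose body +/- ``flank`` intersects at least one SV.

    Returns gene_id -> sorted list of linking SV ids (each gene once).
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    by_chrom = genes_by_chrom(genes)
    out: dict[str, set[str]] = {}
    for sv in svs:
        lo, hi = sv.interval0()
        for g in by_chrom.get(sv.chrom, []):
            if interval_gap(g.start, g.end, lo, hi) <= flank:
                out.setdefault(g.gene_id, set()).add(sv.sv_id)
    return {gid: sorted(ids) for gid, ids in sorted(out.items())}


def consequence_table(calls: Sequence[ConsequenceCall]) -> pd.DataFrame:
    return pd.DataFrame([{"sv_id": c.sv_id, "gene_id": c.gene_id,
                          "category": c.category, "detail": c.detail} for c in calls])


def category_breakdown(calls: Sequence[ConsequenceCall]) -> pd.DataFrame:
    """Counts and fractions per category, under both normalizations.

    ``fraction_of_calls`` divides by the number of (SV, gene) calls,
    ``fraction_of_svs`` by the number of distinct SVs (an SV near several
    genes counts once per category).
    """
    df = consequence_table(calls)
    if df.empty:
        return pd.DataFrame(columns=["category", "n_calls", "n_svs",
                                     "fraction_of_calls", "fraction_of_svs"])
    by_calls = df.groupby("category").size().rename("n_calls")
    by_svs = (df.drop_duplicates(["sv_id", "category"])
                .groupby("category").size().rename("n_svs"))
    out = pd.concat([by_calls, by_svs], axis=1).fillna(0).astype(int).reset_index()
    out["fraction_of_calls"] = out["n_calls"] / out["n_calls"].sum()
    out["fraction_of_svs"] = out["n_svs"] / df["sv_id"].nunique()
    return out
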