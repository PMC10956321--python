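"""Gene models and GFF3 serialization.

Coordinates are 0-based half-open in memory and converted to 1-based
inclusive GFF3 only at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A single-transcript gene: body, exons, and UTR/CDS partition.

    ``exons`` are sorted, non-overlapping intervals inside ``[start, end)``.
    ``utr5``/``utr3`` are the strand-aware untranslated ends of the first and
    last exon; ``cds`` is the remainder of the exons.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid body {self.start}-{self.end}")
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside body")

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cds(self) -> list[Interval]:
        """Exonic intervals minus UTR segments."""
        utr = sorted(self.utr5 + self.utr3)
        out: list[Interval] = []
        for s, e in self.exons:
            cur = [(s, e)]
            for us, ue in utr:
                nxt = []
                for cs, ce in cur:
                    if ue <= cs or us >= ce:
                        nxt.append((cs, ce))
                        continue
                    if cs < us:
                        nxt.append((cs, us))
                    if ue < ce:
                        nxt.append((ue, ce))
                cur = nxt
            out.extend(cur)
        return [iv for iv in out if iv[0] < iv[1]]

    @property
    def introns(self) -> list[Interval]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 < s2:
                out.append((e1, s2))
        return out


def write_gff3(genes: Iterable[GeneModel], path: str) -> None:
    """Serialize gene models to a GFF3 file (gene/mRNA/exon/CDS/UTR rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            rows = [("gene", g.start, g.end, f"ID={g.gene_id}"),
                    ("mRNA", g.start, g.end, f"ID={g.gene_id}.t1;Parent={g.gene_id}")]
            for s, e in g.exons:
                rows.append(("exon", s, e, f"Parent={g.gene_id}.t1"))
            for s, e in g.cds:
                rows.append(("CDS", s, e, f"Parent={g.gene_id}.t1"))
            for s, e in g.utr5:
                rows.append(("five_prime_UTR", s, e, f"Parent={g.gene_id}.t1"))
            for s, e in g.utr3:
                rows.append(("three_prime_UTR", s, e, f"Parent={g.gene_id}.t1"))
            for ftype, s, e, attrs in rows:
                fh.write("\t".join([g.chrom, "breedsv", ftype, str(s + 1), str(e),
                                    ".", g.strand, ".", attrs]) + "\n")


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        gid = gf.id
        g = GeneModel(gid, gf.seqid, gf.start - 1, gf.end, gf.strand)
        g.exons = sorted((f.start - 1, f.end) for f in db.children(gid, featuretype="exon"))
        g.utr5 = sorted((f.start - 1, f.end)
                        for f in db.children(gid, featuretype="five_prime_UTR"))
        g.utr3 = sorted((f.start - 1, f.end)
                        for f in db.children(gid, featuretype="three_prime_UTR"))
        out.append(g)
    return sorted(out, key=lambda g: (g.chrom, g.start))


def genes_by_chrom(genes: Sequence[GeneModel]) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for v in out.values():
        v.sort(key=lambda g: g.start)
    return out
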