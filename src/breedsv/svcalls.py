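"""Structural variant calling from collinear alignment blocks.

Variants are reported on reference coordinates, 1-based inclusive: a deletion
spanning reference bases ``pos..end`` has ``length = end - pos + 1`` (so the
X:53,609,703-53,609,995 convention gives 293 bp). Insertions are anchored at
the last reference base before the inserted sequence (``end == pos``).
Breakend-like terminal discordances are never emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import AlignmentBlock

SV_TYPES = ("DEL", "INS", "DUP", "INV")
MIN_SV_LENGTH = 50


@dataclass
class StructuralVariant:
    """A typed SV interval/point on reference coordinates (1-based inclusive)."""

    sv_id: str
    sv_type: str
    chrom: str
    pos: int
    end: int
    length: int
    alt_sequence: str | None = None
    source_breed: str | None = None
    provenance: str = "assembly_call"

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"{self.sv_id}: unknown sv_type {self.sv_type!r}")
        if self.pos < 1:
            raise ValueError(f"{self.sv_id}: pos must be >= 1")
        if self.length < 1:
            raise ValueError(f"{self.sv_id}: length must be >= 1")
        if self.sv_type == "INS":
            if self.end != self.pos:
                raise ValueError(f"{self.sv_id}: INS must have end == pos")
            if self.alt_sequence is not None and len(self.alt_sequence) != self.length:
                raise ValueError(f"{self.sv_id}: INS length != len(alt_sequence)")
        else:
            if self.end - self.pos + 1 != self.length:
                raise ValueError(f"{self.sv_id}: length must equal end - pos + 1")

    @classmethod
    def from_interval(cls, sv_id: str, sv_type: str, chrom: str, pos: int, end: int,
                      **kwargs) -> "StructuralVariant":
        """Build a DEL/DUP/INV from its 1-based inclusive span (length derived)."""
        if sv_type == "INS":
            raise ValueError("INS length is not defined by a reference span")
        return cls(sv_id, sv_type, chrom, pos, end, end - pos + 1, **kwargs)

    @property
    def start0(self) -> int:
        """0-based start of the reference interval (INS: anchor base)."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the reference interval (INS: anchor base + 1)."""
        return self.pos if self.sv_type == "INS" else self.end

    def interval0(self, ins_pad: int = 0) -> tuple[int, int]:
        """0-based half-open interval; insertions optionally padded +/- ``ins_pad``."""
        if self.sv_type == "INS":
            return max(0, self.start0 - ins_pad), self.end0 + ins_pad
        return self.start0, self.end0


def _subseq(seqs, name: str, start: int, end: int) -> str:
    """Fetch a subsequence from a dict of strings or a pyfaidx.Fasta."""
    start = max(0, start)
    if end <= start:
        return ""
    chunk = seqs[name][start:end]
    return chunk if isinstance(chunk, str) else str(chunk)


def _identity(a: str, b: str) -> float:
    """Sequence identity 1 - editdist/maxlen (edlib global alignment)."""
    if not a or not b:
        return 0.0
    import edlib

    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _try_tandem_dup(chrom: str, left_end: int, right_start: int, g_q: int,
                    qgap_seq: str | None, reference, min_len: int,
                    identity_min: float) -> StructuralVariant | None:
    """Test whether an inter-block gap is the signature of a tandem duplication.

    A tandem copy of a source segment leaves a symmetric anchor desert: the
    flanking blocks each extend ``c`` bases into the source, so the assembly
    gap should read ``ref[left_end:source_end] + ref[source_start:right_start]``.
    The degenerate case c == 0 (external aligners report a pure insertion at
    the source end) reduces to the inserted sequence matching the reference
    window immediately preceding it.
    """
    if reference is None or qgap_seq is None:
        return None
    g_t = right_start - left_end
    dup_len = g_q - g_t
    if dup_len < min_len:
        return None
    c = (dup_len - g_t) // 2
    candidates = []
    if c > 0 and g_t >= 0:
        src_start, src_end = left_end - c, right_start + c
        if src_start >= 0 and src_end > src_start:
            expected = (_subseq(reference, chrom, left_end, src_end)
                        + _subseq(reference, chrom, src_start, right_start))
            candidates.append((src_start, src_end, expected))
    if g_t < min_len:
        # pure-insertion representation: copy inserted right after its source
        src_start, src_end = left_end - dup_len, left_end
        if src_start >= 0:
            candidates.append((src_start, src_end,
                               _subseq(reference, chrom, src_start, src_end)))
    for src_start, src_end, expected in candidates:
        if expected and _identity(qgap_seq, expected) >= identity_min:
            return StructuralVariant(
                sv_id="", sv_type="DUP", chrom=chrom, pos=src_start + 1,
                end=src_end, length=src_end - src_start)
    return None


def call_svs(blocks: Sequence[AlignmentBlock],
             reference: Mapping[str, str] | None = None,
             assembly: Mapping[str, str] | None = None,
             min_len: int = MIN_SV_LENGTH,
             dup_identity: float = 0.9,
             source_breed: str | None = None) -> list[StructuralVariant]:
    """Call DEL/INS/DUP/INV >= ``min_len`` from one assembly-vs-reference block set.

    Within each run of collinear blocks sorted on the reference, an
    inter-block gap of ``g_t`` target bases and ``g_q`` query bases yields a
    deletion (``g_t`` >= min, ``g_q`` < min), an insertion (``g_q`` >= min,
    ``g_t`` < min), or a paired deletion+insertion replacement (both >= min),
    except where the gap geometry matches a tandem duplication, which is
    emitted as DUP over the source locus. A maximal run of blocks whose
    strand differs from consistently-oriented neighbours on both sides is an
    inversion over its reference interval. Discordant terminal blocks
    (breakend-like signatures) are dropped.
    """
    labels = {b.comparison for b in blocks if b.comparison is not None}
    if len(labels) > 1:
        raise ValueError(f"blocks from mixed comparisons: {sorted(labels)}")
    from .synteny import resolve_conflicts

    blocks = resolve_conflicts(blocks)
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.target_name, []).append(b)

    calls: list[StructuralVariant] = []
    for chrom in sorted(by_chrom):
        chrom_blocks = sorted(by_chrom[chrom], key=lambda b: (b.target_start, b.target_end))
        # maximal runs of consecutive blocks sharing query chromosome and strand
        runs: list[list[AlignmentBlock]] = []
        for b in chrom_blocks:
            if runs and runs[-1][-1].query_name == b.query_name \
                    and runs[-1][-1].strand == b.strand:
                runs[-1].append(b)
            else:
                runs.append([b])

        # inversions: interior runs oriented against the chromosome backbone
        # (the dominant strand by aligned target span)
        span_by_strand = {"+": 0, "-": 0}
        for b in chrom_blocks:
            span_by_strand[b.strand] += b.target_span
        backbone = "+" if span_by_strand["+"] >= span_by_strand["-"] else "-"
        for i in range(1, len(runs) - 1):
            cur = runs[i]
            if cur[0].strand == backbone:
                continue
            if runs[i - 1][-1].query_name != cur[0].query_name \
                    or runs[i + 1][0].query_name != cur[0].query_name:
                continue
            t_lo = cur[0].target_start
            t_hi = cur[-1].target_end
            if t_hi - t_lo >= min_len:
                calls.append(StructuralVariant(
                    sv_id="", sv_type="INV", chrom=chrom, pos=t_lo + 1,
                    end=t_hi, length=t_hi - t_lo, source_breed=source_breed))

        # indel-like gaps between consecutive blocks on the same query chromosome
        for a, b in zip(chrom_blocks, chrom_blocks[1:]):
            if a.query_name != b.query_name:
                continue  # rearrangement junction, not an indel
            g_t = b.target_start - a.target_end
            if a.strand == "+" and b.strand == "+":
                g_q = b.query_start - a.query_end
            elif a.strand == "-" and b.strand == "-":
                g_q = a.query_start - b.query_end
            else:
                g_q = max(a.query_start, b.query_start) - min(a.query_end, b.query_end)
            if g_q < -min_len or g_t < -min_len:
                continue  # inconsistent overlap: junction artefact, drop
            net = g_q - g_t  # junction micro-homology cancels out of the net
            if max(g_t, 0) < min_len and max(g_q, 0) < min_len and abs(net) < min_len:
                continue
            qgap_seq = None
            if assembly is not None and a.strand == "+" and b.strand == "+" and g_q > 0:
                qgap_seq = _subseq(assembly, a.query_name, a.query_end, b.query_start)
            dup = _try_tandem_dup(chrom, a.target_end, b.target_start, max(g_q, 0),
                                  qgap_seq, reference, min_len, dup_identity)
            if dup is not None:
                dup.source_breed = source_breed
                calls.append(dup)
                continue
            if g_t >= min_len and g_q >= min_len:
                # replacement: paired deletion + insertion at one locus
                calls.append(StructuralVariant(
                    sv_id="", sv_type="DEL", chrom=chrom, pos=a.target_end + 1,
                    end=b.target_start, length=g_t, source_breed=source_breed))
                calls.append(StructuralVariant(
                    sv_id="", sv_type="INS", chrom=chrom, pos=a.target_end,
                    end=a.target_end, length=g_q, alt_sequence=qgap_seq,
                    source_breed=source_breed))
            elif -net >= min_len:
                start0 = b.target_start + net
                calls.append(StructuralVariant(
                    sv_id="", sv_type="DEL", chrom=chrom, pos=start0 + 1,
                    end=b.target_start, length=-net, source_breed=source_breed))
            elif net >= min_len:
                anchor = min(a.target_end, b.target_start)
                alt = None
                if assembly is not None and a.strand == "+" and b.strand == "+":
                    alt = _subseq(assembly, a.query_name,
                                  b.query_start - net, b.query_start)
                calls.append(StructuralVariant(
                    sv_id="", sv_type="INS", chrom=chrom, pos=anchor,
                    end=anchor, length=net, alt_sequence=alt,
                    source_breed=source_breed))

    calls.sort(key=lambda v: (v.chrom, v.pos, v.sv_type))
    for i, v in enumerate(calls):
        v.sv_id = f"sv_{i:05d}"
    return calls


# ---------------------------------------------------------------------------
# VCF 4.2 I/O (INFO: SVTYPE, SVLEN, END)

def write_sv_vcf(svs: Iterable[StructuralVariant],
                 reference: Mapping[str, str],
                 path: str,
                 contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write SVs as VCF 4.2 with symbolic ALTs and SVTYPE/SVLEN/END INFO."""
    import pysam

    if contig_lengths is None:
        contig_lengths = {name: len(reference[name]) for name in reference.keys()}
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer",
                    "Length of the variant (negative for deletions)")
    header.info.add("BREED", 1, "String", "Assembly of origin")
    with pysam.VariantFile(path, "w", header=header) as vf:
        for sv in sorted(svs, key=lambda v: (v.chrom, v.pos)):
            if sv.sv_type == "INS":
                # VCF anchors the record at the base before the inserted
                # sequence, which is already the INS pos convention
                start0, stop = sv.pos - 1, sv.pos
            else:
                # VCF POS is the base preceding the affected interval, so
                # END = POS + |SVLEN| equals the 1-based inclusive end
                start0, stop = max(sv.pos - 2, 0), sv.end
            ref_base = _subseq(reference, sv.chrom, start0, start0 + 1) or "N"
            if sv.sv_type == "INS" and sv.alt_sequence is not None:
                alt = ref_base + sv.alt_sequence
            else:
                alt = f"<{sv.sv_type}>"
            rec = vf.new_record(contig=sv.chrom, start=start0, stop=stop,
                                alleles=(ref_base, alt), id=sv.sv_id or None)
            rec.info["SVTYPE"] = sv.sv_type
            rec.info["SVLEN"] = -sv.length if sv.sv_type == "DEL" else sv.length
            if sv.source_breed:
                rec.info["BREED"] = sv.source_breed
            vf.write(rec)


def read_sv_vcf(path: str) -> list[StructuralVariant]:
    """Read SVs from a VCF; BND records are skipped with a warning."""
    import pysam

    out: list[StructuralVariant] = []
    n_bnd = 0
    with pysam.VariantFile(path) as vf:
        has_breed = "BREED" in vf.header.info
        for i, rec in enumerate(vf, start=1):
            try:
                svtype = rec.info.get("SVTYPE")
                if svtype == "BND":
                    n_bnd += 1
                    continue
                if svtype not in SV_TYPES:
                    raise ValueError(f"unsupported SVTYPE {svtype!r}")
                svlen = rec.info.get("SVLEN")
                if isinstance(svlen, tuple):
                    svlen = svlen[0]
                length = abs(int(svlen))
                alt_seq = None
                if svtype == "INS":
                    pos = rec.pos
                    end = rec.pos
                    alt = rec.alts[0] if rec.alts else ""
                    if alt and not alt.startswith("<"):
                        alt_seq = alt[len(rec.ref):]
                        length = len(alt_seq)
                else:
                    # undo the VCF base-before-event anchoring: the affected
                    # interval starts one base after POS and ends at END
                    pos, end = rec.pos + 1, rec.stop
                out.append(StructuralVariant(
                    sv_id=rec.id or f"sv_{i:05d}", sv_type=svtype, chrom=rec.chrom,
                    pos=pos, end=end, length=length, alt_sequence=alt_seq,
                    source_breed=rec.info.get("BREED") if has_breed else None,
                    provenance="file"))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: record {i}: {exc}") from exc
    if n_bnd:
        warnings.warn(f"{path}: skipped {n_bnd} breakend (BND) record(s)")
    return out


def summarize_svs(svs: Sequence[StructuralVariant]) -> pd.DataFrame:
    """Per-type count, median length, and total length (Table-1-style summary)."""
    if not svs:
        return pd.DataFrame(columns=["sv_type", "count", "median_length", "total_length"])
    df = pd.DataFrame({"sv_type": [v.sv_type for v in svs],
                       "length": [v.length for v in svs]})
    out = (df.groupby("sv_type")["length"]
             .agg(count="size", median_length="median", total_length="sum")
             .reset_index())
    order = {t: i for i, t in enumerate(SV_TYPES)}
    return (out.sort_values("sv_type", key=lambda s: s.map(order))
               .reset_index(drop=True))
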