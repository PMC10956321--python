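"""Pairwise whole-genome alignment blocks.

Two sources are supported: PAF files produced by an external aligner, and a
built-in exact-anchor aligner intended for repeat-free (simulated) genomes.
The anchor aligner indexes k-mers that occur exactly once in each genome,
matches them on both strands, and chains diagonal runs of anchors into
alignment blocks. All coordinates are 0-based half-open, PAF-style; minus
strand blocks carry forward-strand query coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentBlock:
    """One strand-aware collinear segment of an assembly-vs-reference alignment."""

    query_name: str
    query_start: int
    query_end: int
    target_name: str
    target_start: int
    target_end: int
    strand: str
    n_matches: int
    block_id: int = -1
    comparison: str | None = None  # label of the assembly-vs-reference pair

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.query_start < self.query_end):
            raise ValueError(f"block {self.block_id}: invalid query interval "
                             f"{self.query_start}-{self.query_end}")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(f"block {self.block_id}: invalid target interval "
                             f"{self.target_start}-{self.target_end}")
        span = min(self.query_end - self.query_start, self.target_end - self.target_start)
        if self.n_matches > span:
            raise ValueError(f"block {self.block_id}: n_matches {self.n_matches} "
                             f"exceeds span {span}")

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


def read_paf(path: str, comparison: str | None = None) -> list[AlignmentBlock]:
    """Read alignment blocks from a PAF file (one block per record)."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {ln}: expected >=12 PAF columns, got {len(f)}")
            try:
                qs, qe = int(f[2]), int(f[3])
                ts, te = int(f[7]), int(f[8])
                nm = int(f[9])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer coordinate field") from exc
            if f[4] not in {"+", "-"}:
                raise ValueError(f"{path}: line {ln}: bad strand {f[4]!r}")
            try:
                blocks.append(AlignmentBlock(f[0], qs, qe, f[5], ts, te, f[4], nm,
                                             block_id=len(blocks), comparison=comparison))
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
    return blocks


def write_paf(blocks: Iterable[AlignmentBlock],
              query_lengths: Mapping[str, int],
              target_lengths: Mapping[str, int],
              path: str) -> None:
    """Write blocks as minimal 12-column PAF records."""
    with open(path, "w") as fh:
        for b in blocks:
            aln_len = max(b.query_span, b.target_span)
            fh.write("\t".join(map(str, [
                b.query_name, query_lengths[b.query_name], b.query_start, b.query_end,
                b.strand, b.target_name, target_lengths[b.target_name],
                b.target_start, b.target_end, b.n_matches, aln_len, 60,
            ])) + "\n")


# ---------------------------------------------------------------------------
# exact-anchor aligner

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i
    _CODE[base + 32] = i


def _encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        arr = arr.copy()
        arr[arr == 255] = 0  # non-ACGT treated as A; simulated genomes have none
    return arr


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (uint64); empty if the sequence is shorter than k."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n - k + 1, dtype=np.uint64)
    for i in range(k):
        out = (out << np.uint64(2)) | codes[i:n - k + 1 + i].astype(np.uint64)
    return out


def _revcomp_codes(kmers: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros_like(kmers)
    tmp = kmers.copy()
    three = np.uint64(3)
    for _ in range(k):
        out = (out << np.uint64(2)) | (three - (tmp & three))
        tmp = tmp >> np.uint64(2)
    return out


def _genome_kmer_table(seqs: Mapping[str, str], k: int):
    """Concatenated k-mer codes with chromosome index and position arrays."""
    names = list(seqs)
    codes, chrom_idx, pos = [], [], []
    for ci, name in enumerate(names):
        c = _kmer_codes(_encode(seqs[name]), k)
        codes.append(c)
        chrom_idx.append(np.full(c.size, ci, dtype=np.int32))
        pos.append(np.arange(c.size, dtype=np.int64))
    if codes:
        codes = np.concatenate(codes)
        chrom_idx = np.concatenate(chrom_idx)
        pos = np.concatenate(pos)
    else:
        codes = np.empty(0, dtype=np.uint64)
        chrom_idx = np.empty(0, dtype=np.int32)
        pos = np.empty(0, dtype=np.int64)
    return names, codes, chrom_idx, pos


def _unique_mask(codes: np.ndarray) -> np.ndarray:
    """Boolean mask of k-mers whose code occurs exactly once (forward strand)."""
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    is_new = np.empty(sorted_codes.size, dtype=bool)
    if sorted_codes.size:
        is_new[0] = True
        is_new[1:] = sorted_codes[1:] != sorted_codes[:-1]
    starts = np.flatnonzero(is_new)
    counts = np.diff(np.append(starts, sorted_codes.size))
    uniq_sorted = np.zeros(sorted_codes.size, dtype=bool)
    uniq_sorted[starts[counts == 1]] = True
    mask = np.empty(codes.size, dtype=bool)
    mask[order] = uniq_sorted
    return mask


def anchor_align(assembly: Mapping[str, str],
                 reference: Mapping[str, str],
                 k: int = 21,
                 max_gap: int = 30,
                 diag_slack: int = 20,
                 min_anchors: int = 10,
                 comparison: str | None = None) -> list[AlignmentBlock]:
    """Align an assembly to a reference by chaining unique k-mer anchors.

    K-mers occurring exactly once in each genome are matched on both strands
    and chained while consecutive anchors stay within ``max_gap`` on both
    sides and within ``diag_slack`` of the chain diagonal, so any indel of at
    least ``diag_slack`` bases splits the chain and becomes visible as an
    inter-block gap. ``max_gap`` must stay below the minimum SV length of
    interest, otherwise a length-neutral event (a small inversion) whose
    anchor desert fits inside ``max_gap`` is silently bridged. Valid for genomes without repeat families; on repetitive
    sequence the unique-k-mer assumption removes anchors rather than
    producing false ones.
    """
    if k < 11:
        raise ValueError(f"k must be >= 11, got {k}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd to exclude palindromic k-mers, got {k}")

    t_names, t_codes, t_chrom, t_pos = _genome_kmer_table(reference, k)
    q_names, q_codes, q_chrom, q_pos = _genome_kmer_table(assembly, k)

    t_uni = _unique_mask(t_codes)
    q_uni = _unique_mask(q_codes)
    if not t_uni.any() or not q_uni.any():
        warnings.warn("no unique k-mers shared between genomes; empty alignment")
        return []

    tu_codes = t_codes[t_uni]
    tu_chrom = t_chrom[t_uni]
    tu_pos = t_pos[t_uni]
    t_order = np.argsort(tu_codes, kind="stable")
    tu_codes, tu_chrom, tu_pos = tu_codes[t_order], tu_chrom[t_order], tu_pos[t_order]

    qu_codes = q_codes[q_uni]
    qu_chrom = q_chrom[q_uni]
    qu_pos = q_pos[q_uni]

    anchors = []  # (strand, q_chrom, q_pos, t_chrom, t_pos)
    for strand, probe in (("+", qu_codes), ("-", _revcomp_codes(qu_codes, k))):
        idx = np.searchsorted(tu_codes, probe)
        idx_c = np.minimum(idx, tu_codes.size - 1)
        hit = tu_codes[idx_c] == probe
        anchors.append((strand, qu_chrom[hit], qu_pos[hit],
                        tu_chrom[idx_c[hit]], tu_pos[idx_c[hit]]))

    blocks: list[AlignmentBlock] = []
    for strand, qc, qp, tc, tp in anchors:
        if qp.size == 0:
            continue
        sgn = 1 if strand == "+" else -1
        order = np.lexsort((tp, tc.astype(np.int64), qc.astype(np.int64)))
        qc, qp, tc, tp = qc[order], qp[order], tc[order], tp[order]
        dt = np.diff(tp)
        dq = np.diff(qp) * sgn  # expected positive along the chain
        same_group = (np.diff(qc) == 0) & (np.diff(tc) == 0)
        ok = same_group & (dt > 0) & (dt <= max_gap) & (dq > 0) & (dq <= max_gap) \
            & (np.abs(dt - dq) <= diag_slack)
        breaks = np.flatnonzero(~ok)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [qp.size - 1]))
        for s, e in zip(starts, ends):
            n_anchor = e - s + 1
            if n_anchor < min_anchors:
                continue
            q_lo, q_hi = (qp[s], qp[e]) if strand == "+" else (qp[e], qp[s])
            t_span = int(tp[e] - tp[s]) + k
            q_span = int(q_hi - q_lo) + k
            blocks.append(AlignmentBlock(
                query_name=q_names[qc[s]], query_start=int(q_lo), query_end=int(q_hi) + k,
                target_name=t_names[tc[s]], target_start=int(tp[s]), target_end=int(tp[e]) + k,
                strand=strand, n_matches=min(n_anchor + k - 1, t_span, q_span),
                comparison=comparison))

    blocks.sort(key=lambda b: (b.target_name, b.target_start, b.query_name, b.query_start))
    for i, b in enumerate(blocks):
        b.block_id = i
    return blocks
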