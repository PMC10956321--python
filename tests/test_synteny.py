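"""Synteny chaining, breakpoint regions, and breakpoint annotation."""

import pytest

from breedsv.alignment import AlignmentBlock
from breedsv.genes import GeneModel
from breedsv.simulate import FOCAL_BREED
from breedsv.synteny import (BreakpointRegion, annotate_breakpoints,
                             build_synteny_blocks, find_breakpoint_regions,
                             interval_gap, resolve_conflicts)


def _block(ts, te, qs=None, qe=None, strand="+", t="chr1", q="chr1", nm=None, bid=0):
    qs = ts if qs is None else qs
    qe = te if qe is None else qe
    nm = min(te - ts, qe - qs) if nm is None else nm
    return AlignmentBlock(q, qs, qe, t, ts, te, strand, nm, block_id=bid)


class TestBuildSyntenyBlocks:
    def test_single_megabase_block_passes_300kb_resolution(self):
        blocks = [_block(0, 1_000_000)]
        syn = build_synteny_blocks(blocks, resolution=300_000)
        assert len(syn) == 1
        assert syn[0].target_span == 1_000_000

    def test_block_below_resolution_discarded(self):
        assert build_synteny_blocks([_block(0, 200_000)], resolution=300_000) == []

    def test_collinear_blocks_merge_into_one_chain(self):
        blocks = [_block(0, 150_000), _block(150_200, 400_000, 150_200, 400_000)]
        syn = build_synteny_blocks(blocks, resolution=300_000)
        assert len(syn) == 1
        assert (syn[0].target_start, syn[0].target_end) == (0, 400_000)

    def test_strand_flip_breaks_chain(self):
        blocks = [_block(0, 400_000),
                  _block(400_000, 800_000, 400_000, 800_000, strand="-"),
                  _block(800_000, 1_200_000, 800_000, 1_200_000)]
        syn = build_synteny_blocks(blocks, resolution=300_000)
        assert [s.orientation for s in syn] == ["+", "-", "+"]

    def test_translocation_partitions_target_span(self, small_dataset, focal_blocks):
        # chromosomes carrying a planted rearrangement split into chains whose
        # target spans partition the chromosome around the moved segment
        ds = small_dataset
        syn = build_synteny_blocks(focal_blocks, resolution=ds.config.synteny_resolution)
        for r in ds.truth.planted_rearrangements:
            chains = sorted([(s.target_start, s.target_end, s.orientation)
                             for s in syn if s.target_name == r.chrom])
            assert len(chains) >= 3
            inv = [c for c in chains if c[2] == "-"]
            assert len(inv) == 1
            assert abs(inv[0][0] - r.start0) <= 30 + 21
            assert abs(inv[0][1] - r.end0) <= 30 + 21

    def test_undisturbed_chromosomes_form_single_chain(self, small_dataset, focal_blocks):
        ds = small_dataset
        syn = build_synteny_blocks(focal_blocks, resolution=ds.config.synteny_resolution)
        disturbed = {r.chrom for r in ds.truth.planted_rearrangements}
        for chrom in ds.reference:
            if chrom not in disturbed:
                assert sum(s.target_name == chrom for s in syn) == 1


class TestResolveConflicts:
    def test_higher_scoring_block_wins(self):
        keep = _block(0, 10_000, nm=9_000)
        lose = _block(5_000, 15_000, 5_000, 15_000, nm=4_000)
        assert resolve_conflicts([lose, keep]) == [keep]

    def test_small_edge_overlap_tolerated(self):
        a = _block(0, 10_000, nm=9_000)
        b = _block(9_990, 20_000, 9_990, 20_000, nm=8_000)  # 10-bp edge overlap
        assert len(resolve_conflicts([a, b])) == 2


class TestBreakpointRegions:
    def test_single_chain_chromosome_has_no_breakpoints(self):
        syn = build_synteny_blocks([_block(0, 1_000_000)], resolution=300_000)
        assert find_breakpoint_regions(syn) == []

    def test_planted_rearrangement_recovered_within_tolerance(self, small_dataset,
                                                              focal_blocks):
        # both junctions of each rearrangement >= resolution are recovered
        ds = small_dataset
        syn = build_synteny_blocks(focal_blocks, resolution=ds.config.synteny_resolution)
        bps = find_breakpoint_regions(syn, assembly_label=FOCAL_BREED)
        tol = 30 + 21  # max_gap + k
        for r in ds.truth.planted_rearrangements:
            for chrom, coord in r.junctions():
                dist = min(max(0, bp.start - coord, coord - bp.end)
                           for bp in bps if bp.chrom == chrom)
                assert dist <= tol
        disturbed = {r.chrom for r in ds.truth.planted_rearrangements}
        assert all(bp.chrom in disturbed for bp in bps)

    def test_zero_length_gap_kept_as_point_breakpoint(self):
        blocks = [_block(0, 400_000),
                  _block(400_000, 800_000, 400_000, 800_000, strand="-")]
        syn = build_synteny_blocks(blocks, resolution=300_000)
        bps = find_breakpoint_regions(syn)
        assert len(bps) == 1
        assert bps[0].start == bps[0].end == 400_000

    def test_query_side_regions(self):
        blocks = [_block(0, 400_000),
                  _block(400_100, 800_000, 400_050, 799_950, strand="-")]
        syn = build_synteny_blocks(blocks, resolution=300_000)
        bps = find_breakpoint_regions(syn, side="query")
        assert len(bps) == 1
        assert (bps[0].start, bps[0].end) == (400_000, 400_050)

    def test_region_lies_between_flanking_chains(self, focal_blocks, small_dataset):
        syn = build_synteny_blocks(focal_blocks,
                                   resolution=small_dataset.config.synteny_resolution)
        spans = {s.block_id: (s.target_name, s.target_start, s.target_end) for s in syn}
        for bp in find_breakpoint_regions(syn):
            lc, ls, le = spans[bp.left_synteny_id]
            rc, rs, re = spans[bp.right_synteny_id]
            assert lc == rc == bp.chrom
            # chains may share <= 25 bp of anchor-edge overlap at a junction
            assert le <= bp.start + 25 and bp.end <= rs + 25
            assert ls < bp.start and bp.end < re

    def test_same_ids_rejected(self):
        with pytest.raises(ValueError, match="different"):
            BreakpointRegion("a", "chr1", 5, 10, "syn_0", "syn_0")


class TestAnnotateBreakpoints:
    def _gene(self, start, end, gid="g1", strand="+"):
        g = GeneModel(gid, "chr1", start, end, strand, exons=[(start, end)])
        g.utr5, g.utr3 = [], []
        return g

    def test_flank_distance_boundary(self):
        # gene body ends at base 10,000 (1-based); breakpoints 4,999 and
        # 5,001 bases away fall on either side of the 5-kb flank
        gene = self._gene(0, 10_000)
        near = BreakpointRegion("a", "chr1", 14_999, 15_100, "s1", "s2")
        far = BreakpointRegion("a", "chr1", 15_001, 15_100, "s1", "s2")
        ann_near = annotate_breakpoints([near], [gene], flank=5_000)[0]
        ann_far = annotate_breakpoints([far], [gene], flank=5_000)[0]
        assert ann_near.genes == ["g1"]
        assert ann_far.genes == []

    def test_intron_only_breakpoint_is_intronic(self):
        g = GeneModel("g1", "chr1", 0, 10_000, "+",
                      exons=[(0, 2_000), (8_000, 10_000)])
        bp = BreakpointRegion("a", "chr1", 4_000, 4_500, "s1", "s2")
        assert annotate_breakpoints([bp], [g])[0].category == "intronic"

    def test_exon_touching_breakpoint_is_exonic(self):
        g = self._gene(1_000, 3_000)
        bp = BreakpointRegion("a", "chr1", 2_900, 5_000, "s1", "s2")
        assert annotate_breakpoints([bp], [g])[0].category == "exonic"

    def test_matches_exhaustive_scan_on_random_breakpoints(self, small_dataset, rng):
        """Brute-force oracle: per-base membership decides class and gene list."""
        ds = small_dataset
        genes = ds.genes
        bps = []
        for i in range(300):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, ds.config.chrom_length - 500))
            e = s + int(rng.integers(0, 400))
            bps.append(BreakpointRegion("a", chrom, s, e, f"l{i}", f"r{i}"))
        flank = 5_000
        got = annotate_breakpoints(bps, genes, flank=flank)
        for bp, ann in zip(bps, got):
            probe = set(range(bp.start, max(bp.end, bp.start + 1)))
            exp_genes, exp_cat = [], "intergenic"
            for g in genes:
                if g.chrom != bp.chrom:
                    continue
                flanked = set(range(max(0, g.start - flank), g.end + flank))
                if probe & flanked:
                    exp_genes.append(g.gene_id)
                body = set(range(g.start, g.end))
                exonic = set()
                for s, e in g.exons:
                    exonic |= set(range(s, e))
                if probe & exonic:
                    exp_cat = "exonic"
                elif probe & body and exp_cat != "exonic":
                    exp_cat = "intronic"
            assert ann.genes == sorted(exp_genes)
            assert ann.category == exp_cat


def test_interval_gap_basic():
    assert interval_gap(0, 10, 10, 20) == 0
    assert interval_gap(0, 10, 15, 20) == 5
    assert interval_gap(15, 20, 0, 10) == 5
    assert interval_gap(0, 10, 5, 8) == 0
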