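"""Generator correctness: determinism, composition, conservation, truth."""

import numpy as np
import pandas as pd
import pytest

from breedsv.alignment import revcomp
from breedsv.simulate import (COMPARATOR_BREED, FOCAL_BREED, REFERENCE_BREED,
                              Rearrangement, SimulationConfig, SimulationTruth,
                              derive_breed_assembly, simulate_expression,
                              simulate_gene_annotation, simulate_genotypes,
                              simulate_chromatin, simulate_reference)
from breedsv.svcalls import StructuralVariant


def _mini_config(**kw):
    base = dict(n_chromosomes=1, chrom_length=50_000, n_shared_svs=0,
                n_private_svs=0, n_rearrangements=0, n_genes=0, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestReference:
    def test_deterministic_given_seed(self):
        cfg = _mini_config()
        assert simulate_reference(cfg) == simulate_reference(cfg)

    def test_gc_content_within_binomial_bounds(self):
        # n = 10^6 i.i.d. bases: observed GC within +/-0.01 of the target
        cfg = _mini_config(chrom_length=1_000_000, gc_content=0.5)
        seq = simulate_reference(cfg)["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51

    def test_zero_chromosomes_is_empty_not_error(self):
        assert simulate_reference(_mini_config(n_chromosomes=0)) == {}

    @pytest.mark.parametrize("field,value", [
        ("gc_content", 0.0), ("gc_content", 1.2), ("chrom_length", 0),
        ("n_genes", -1), ("genotyping_rate", 1.5),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            _mini_config(**{field: value}).validate()

    def test_sv_length_below_minimum_rejected(self):
        cfg = _mini_config()
        cfg.sv_length_range["DEL"] = (10, 100)
        with pytest.raises(ValueError, match="sv_length_range"):
            cfg.validate()


class TestDeriveAssembly:
    def setup_method(self):
        self.ref = simulate_reference(_mini_config())

    def test_empty_plans_give_identity(self):
        asm = derive_breed_assembly(self.ref, "b", [], [])
        assert asm == self.ref

    def test_deletion_shortens_by_exact_length(self):
        # the 293-bp worked-example length, applied to a synthetic chromosome
        sv = StructuralVariant.from_interval("d1", "DEL", "chr1", 10_001, 10_293)
        assert sv.length == 293
        asm = derive_breed_assembly(self.ref, "b", [sv], [])
        assert len(asm["chr1"]) == len(self.ref["chr1"]) - 293

    def test_each_event_type_applied_correctly(self):
        ref = self.ref["chr1"]
        events = [
            StructuralVariant.from_interval("d", "DEL", "chr1", 1_001, 1_100),
            StructuralVariant("i", "INS", "chr1", 5_000, 5_000, 60,
                              alt_sequence="A" * 60),
            StructuralVariant.from_interval("u", "DUP", "chr1", 9_001, 9_080),
            StructuralVariant.from_interval("v", "INV", "chr1", 20_001, 20_200),
        ]
        asm = derive_breed_assembly(self.ref, "b", events, [])["chr1"]
        # independent right-to-left re-application with plain string surgery
        exp = ref
        exp = exp[:20_000] + revcomp(exp[20_000:20_200]) + exp[20_200:]
        exp = exp[:9_080] + exp[9_000:9_080] + exp[9_080:]
        exp = exp[:5_000] + "A" * 60 + exp[5_000:]
        exp = exp[:1_000] + exp[1_100:]
        assert asm == exp

    def test_length_conservation(self):
        events = [
            StructuralVariant.from_interval("d", "DEL", "chr1", 1_001, 1_100),
            StructuralVariant("i", "INS", "chr1", 5_000, 5_000, 60, alt_sequence="C" * 60),
            StructuralVariant.from_interval("u", "DUP", "chr1", 9_001, 9_080),
            StructuralVariant.from_interval("v", "INV", "chr1", 20_001, 20_200),
        ]
        asm = derive_breed_assembly(self.ref, "b", events, [])
        expected = len(self.ref["chr1"]) - 100 + 60 + 80  # INV length-neutral
        assert len(asm["chr1"]) == expected

    def test_overlapping_events_rejected(self):
        events = [StructuralVariant.from_interval("a", "DEL", "chr1", 1_001, 1_100),
                  StructuralVariant.from_interval("b", "INV", "chr1", 1_050, 1_200)]
        with pytest.raises(ValueError, match="overlap"):
            derive_breed_assembly(self.ref, "b", events, [])

    def test_swap_rearrangement_exchanges_segments(self):
        cfg = _mini_config(n_chromosomes=2)
        ref = simulate_reference(cfg)
        r = Rearrangement("swap", "b", "chr1", 10_000, 12_000,
                          chrom2="chr2", start2=20_000, end2=23_000)
        asm = derive_breed_assembly(ref, "b", [], [r])
        assert asm["chr1"][10_000:13_000] == ref["chr2"][20_000:23_000]
        assert asm["chr2"][20_000:22_000] == ref["chr1"][10_000:12_000]


class TestTruthConsistency:
    def test_reapplying_truth_reproduces_assemblies(self, small_dataset):
        """Sequence-level oracle: truth events -> assembly, re-done independently."""
        ds = small_dataset
        for breed in (FOCAL_BREED, COMPARATOR_BREED):
            ops = []  # (chrom, start0, end0, replacement)
            for p in ds.truth.planted_svs:
                sv = p.sv
                if breed not in p.breeds or p.is_rearrangement:
                    continue
                if sv.sv_type == "DEL":
                    ops.append((sv.chrom, sv.pos - 1, sv.end, ""))
                elif sv.sv_type == "INS":
                    ops.append((sv.chrom, sv.pos, sv.pos, sv.alt_sequence))
                elif sv.sv_type == "DUP":
                    seg = ds.reference[sv.chrom][sv.pos - 1:sv.end]
                    ops.append((sv.chrom, sv.end, sv.end, seg))
                elif sv.sv_type == "INV":
                    seg = ds.reference[sv.chrom][sv.pos - 1:sv.end]
                    ops.append((sv.chrom, sv.pos - 1, sv.end, revcomp(seg)))
            for r in ds.truth.planted_rearrangements:
                if r.breed != breed:
                    continue
                seg = ds.reference[r.chrom][r.start0:r.end0]
                ops.append((r.chrom, r.start0, r.end0, revcomp(seg)))
            rebuilt = {}
            for chrom, seq in ds.reference.items():
                for s, e, repl in sorted([o[1:] for o in ops if o[0] == chrom],
                                         reverse=True):
                    seq = seq[:s] + repl + seq[e:]
                rebuilt[chrom] = seq
            assert rebuilt == ds.assemblies[breed]

    def test_private_events_in_exactly_one_breed(self, small_dataset):
        for p in small_dataset.truth.planted_svs:
            if not p.shared:
                assert len(p.breeds) == 1
            else:
                assert set(p.breeds) == {FOCAL_BREED, COMPARATOR_BREED}

    def test_reference_breed_assembly_is_reference(self, small_dataset):
        assert small_dataset.assemblies[REFERENCE_BREED] == small_dataset.reference


class TestGeneAnnotation:
    def test_zero_genes_empty(self):
        ref = simulate_reference(_mini_config())
        assert simulate_gene_annotation(ref, 0, seed=1) == []

    def test_structure_invariants(self):
        ref = simulate_reference(_mini_config(chrom_length=200_000))
        genes = simulate_gene_annotation(ref, 12, seed=3)
        assert len(genes) == 12
        for g in genes:
            assert all(g.start <= s < e <= g.end for s, e in g.exons)
            assert g.exons == sorted(g.exons)
            # UTRs sit at transcript ends, inside the terminal exons
            for s, e in g.utr5 + g.utr3:
                assert any(es <= s < e <= ee for es, ee in (g.exons[0], g.exons[-1]))
            assert g.cds  # some coding sequence remains
        # non-overlapping bodies per chromosome
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_deterministic(self):
        ref = simulate_reference(_mini_config(chrom_length=200_000))
        a = simulate_gene_annotation(ref, 10, seed=5)
        b = simulate_gene_annotation(ref, 10, seed=5)
        assert a == b

    def test_infeasible_gene_count_rejected(self):
        ref = simulate_reference(_mini_config(chrom_length=30_000))
        with pytest.raises(ValueError, match="n_genes"):
            simulate_gene_annotation(ref, 500, seed=1)


def _toy_truth():
    truth = SimulationTruth(seed=0)
    from breedsv.simulate import PlantedSV

    for i in range(40):
        sv = StructuralVariant.from_interval(f"t{i}", "DEL", "chr1",
                                             1 + i * 2_000, 100 + i * 2_000)
        breed = FOCAL_BREED if i % 2 == 0 else COMPARATOR_BREED
        truth.planted_svs.append(PlantedSV(sv, (breed,), shared=False))
    return truth


class TestGenotypes:
    def test_full_rate_has_no_missing(self):
        gm = simulate_genotypes(_toy_truth(), {FOCAL_BREED: 5, REFERENCE_BREED: 3},
                                genotyping_rate=1.0, seed=1)
        assert not gm.dosages.isna().any().any()

    def test_observed_missingness_matches_rate(self):
        # the reported per-sample genotyping rate: 41.73% of NSVs genotyped
        truth = SimulationTruth(seed=0)
        from breedsv.simulate import PlantedSV

        for i in range(2_000):
            sv = StructuralVariant.from_interval(f"t{i}", "DEL", "chr1",
                                                 1 + i * 200, 60 + i * 200)
            truth.planted_svs.append(PlantedSV(sv, (FOCAL_BREED,), shared=False))
        gm = simulate_genotypes(truth, {FOCAL_BREED: 5, REFERENCE_BREED: 5},
                                genotyping_rate=0.4173, seed=2)
        observed = 1.0 - gm.dosages.isna().to_numpy().mean()
        assert abs(observed - 0.4173) < 0.01

    def test_breed_stratified_frequencies(self):
        gm = simulate_genotypes(_toy_truth(), {FOCAL_BREED: 60, COMPARATOR_BREED: 60},
                                genotyping_rate=1.0, seed=3)
        focal = gm.dosages.loc[gm.breeds == FOCAL_BREED]
        other = gm.dosages.loc[gm.breeds == COMPARATOR_BREED]
        focal_private = [p.sv.sv_id for p in _toy_truth().planted_svs
                         if p.breeds == (FOCAL_BREED,)]
        assert focal[focal_private].mean().mean() / 2 > 0.8
        assert other[focal_private].mean().mean() / 2 < 0.1

    def test_deterministic(self):
        a = simulate_genotypes(_toy_truth(), {FOCAL_BREED: 4}, 0.8, seed=9)
        b = simulate_genotypes(_toy_truth(), {FOCAL_BREED: 4}, 0.8, seed=9)
        pd.testing.assert_frame_equal(a.dosages, b.dosages)

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError, match="genotyping_rate"):
            simulate_genotypes(_toy_truth(), {FOCAL_BREED: 2}, 1.5, seed=1)


class TestExpression:
    def test_linked_gene_passes_both_comparisons(self):
        truth = SimulationTruth(seed=0, de_genes=[("g0", "muscle", -1)])
        df = simulate_expression(["g0", "g1"], truth, ["muscle"], seed=4)
        sub = df[(df.gene_id == "g0") & (df.tissue == "muscle")]
        assert len(sub) == 2
        assert (sub.log2fc <= -1.0).all() and (sub.padj < 0.05).all()

    def test_null_pass_rate_matches_analytic_expectation(self):
        # no planted effects: P(pass one comparison) = P(padj<.05) P(|lfc|>=1)
        from scipy.stats import norm

        truth = SimulationTruth(seed=0)
        genes = [f"g{i}" for i in range(30_000)]
        df = simulate_expression(genes, truth, ["liver"], seed=5, null_lfc_sd=0.75)
        p_pass = 0.05 * 2 * norm.sf(1 / 0.75)
        hits = ((df.log2fc.abs() >= 1) & (df.padj < 0.05)).sum()
        lam = p_pass * len(df)
        assert abs(hits - lam) <= 4 * np.sqrt(lam) + 2

    def test_unknown_truth_gene_rejected(self):
        truth = SimulationTruth(seed=0, de_genes=[("nope", "liver", 1)])
        with pytest.raises(ValueError, match="nope"):
            simulate_expression(["g0"], truth, ["liver"], seed=1)

    def test_deterministic(self):
        truth = SimulationTruth(seed=0)
        a = simulate_expression(["g0", "g1"], truth, ["liver"], seed=6)
        b = simulate_expression(["g0", "g1"], truth, ["liver"], seed=6)
        pd.testing.assert_frame_equal(a, b)


class TestChromatin:
    def test_every_tss_covered_by_promoter_class(self, small_dataset):
        ds = small_dataset
        prom = ds.chromatin[ds.chromatin.state.isin(["TssA", "TssAFlnk"])]
        for tissue in ds.config.tissues:
            sub = prom[prom.tissue == tissue]
            for g in ds.genes:
                cover = sub[(sub.chrom == g.chrom) & (sub.start <= g.tss)
                            & (sub.end > g.tss)]
                assert not cover.empty, f"TSS of {g.gene_id} uncovered in {tissue}"

    def test_placements_overlap_named_state_in_named_tissue(self, small_dataset):
        ds = small_dataset
        sv_map = {p.sv.sv_id: p.sv for p in ds.truth.planted_svs}
        assert ds.truth.regulatory_placements
        for sv_id, state, tissue in ds.truth.regulatory_placements:
            sv = sv_map[sv_id]
            lo, hi = sv.interval0()
            hi = max(hi, lo + 1)
            sub = ds.chromatin[(ds.chromatin.tissue == tissue)
                               & (ds.chromatin.chrom == sv.chrom)
                               & (ds.chromatin.state == state)
                               & (ds.chromatin.start < hi)
                               & (ds.chromatin.end > lo)]
            assert not sub.empty, f"{sv_id} misses {state} in {tissue}"

    def test_segments_sorted_and_non_overlapping(self, small_dataset):
        ch = small_dataset.chromatin
        for (_, _), sub in ch.groupby(["tissue", "chrom"]):
            starts = sub.start.to_numpy()
            ends = sub.end.to_numpy()
            assert (starts[1:] >= ends[:-1]).all()
            assert (ends > starts).all()
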