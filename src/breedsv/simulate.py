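"""Synthetic reference genome, derived breed assemblies, and matched omics data.

The generator emulates the study design the package analyses: a reference
breed assembly (here "duroc"), a focal breed ("nanchukmacdon") and a
comparator breed ("landrace") derived from the reference by planting shared
and private structural variants plus large rearrangements, a genotype panel
per breed with missingness, differential-expression statistics with effects
planted on genes near the focal breed's private SVs, and per-tissue
chromatin-state segmentations. Every planted event is recorded in a truth
set keyed by the seed, so callers can be scored exactly.

Sequence is i.i.d. per base (GC-parameterized) with no repeat families, so
unique-k-mer anchor alignment is well posed. Events are applied
right-to-left per chromosome so earlier reference coordinates stay valid,
and are separated by a guard distance so calls cannot collide.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import revcomp
from .genes import GeneModel, genes_by_chrom
from .popstruct import GenotypeMatrix
from .svcalls import SV_TYPES, MIN_SV_LENGTH, StructuralVariant
from .synteny import interval_gap

REFERENCE_BREED = "duroc"
FOCAL_BREED = "nanchukmacdon"
COMPARATOR_BREED = "landrace"
DEFAULT_TISSUES = ("backfat", "liver", "muscle")
DEFAULT_COMPARISONS = ("vs_duroc", "vs_landrace")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Analysis thresholds (min SV length 50 bp, 300-kb synteny resolution,
    5-kb flank, MAF 0.05, missing rate 0.1, |log2FC| 1, padj 0.05, 3 PCs)
    are carried here as defaults so every stage reads the same values.
    """

    n_chromosomes: int = 3
    chrom_length: int = 1_000_000
    gc_content: float = 0.42
    n_shared_svs: int = 30
    n_private_svs: int = 100          # per non-reference breed
    sv_type_mix: dict = field(default_factory=lambda: {
        "DEL": 0.4, "INS": 0.4, "DUP": 0.1, "INV": 0.1})
    sv_length_range: dict = field(default_factory=lambda: {
        "DEL": (50, 500), "INS": (50, 500), "DUP": (60, 400), "INV": (50, 1000)})
    n_rearrangements: int = 2
    rearrangement_length_range: tuple = (300_000, 360_000)
    n_genes: int = 150
    n_samples_per_breed: dict = field(default_factory=lambda: {
        FOCAL_BREED: 10, REFERENCE_BREED: 6, COMPARATOR_BREED: 13})
    genotyping_rate: float = 0.9
    de_fraction_near_private_svs: float = 0.5
    seed: int = 0

    # analysis thresholds, fixed by convention
    min_sv_length: int = MIN_SV_LENGTH
    synteny_resolution: int = 300_000
    flank: int = 5_000
    maf_min: float = 0.05
    missing_max: float = 0.1
    lfc_min: float = 1.0
    padj_max: float = 0.05
    n_pcs: int = 3
    tissues: tuple = DEFAULT_TISSUES

    # generator conventions
    guard_distance: int = 1_000
    private_alt_freq: float = 0.9
    background_alt_freq: float = 0.02
    shared_alt_freq: float = 0.5
    null_lfc_sd: float = 0.75

    def validate(self) -> "SimulationConfig":
        for name in ("n_chromosomes", "n_shared_svs", "n_private_svs",
                     "n_rearrangements", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.chrom_length < 1:
            raise ValueError(f"chrom_length must be >= 1, got {self.chrom_length}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError(f"gc_content must be in (0,1), got {self.gc_content}")
        for name in ("genotyping_rate", "de_fraction_near_private_svs",
                     "private_alt_freq", "background_alt_freq", "shared_alt_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for svt, (lo, hi) in self.sv_length_range.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"sv_length_range[{svt}] invalid: ({lo}, {hi})")
            if lo < self.min_sv_length:
                raise ValueError(f"sv_length_range[{svt}] minimum {lo} is below "
                                 f"min_sv_length {self.min_sv_length}")
        lo, hi = self.rearrangement_length_range
        if self.n_rearrangements > 0 and (lo < 1 or hi < lo):
            raise ValueError(f"rearrangement_length_range invalid: ({lo}, {hi})")
        if self.guard_distance < 0:
            raise ValueError(f"guard_distance must be >= 0, got {self.guard_distance}")
        return self

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def breeds(self) -> list[str]:
        return list(self.n_samples_per_breed)


@dataclass
class Rearrangement:
    """A resolution-scale event: an in-place inversion or a segment swap."""

    kind: str                 # "inversion" or "swap"
    breed: str
    chrom: str
    start0: int
    end0: int
    chrom2: str | None = None
    start2: int | None = None
    end2: int | None = None

    def junctions(self) -> list[tuple[str, int]]:
        out = [(self.chrom, self.start0), (self.chrom, self.end0)]
        if self.kind == "swap":
            out += [(self.chrom2, self.start2), (self.chrom2, self.end2)]
        return out


@dataclass
class PlantedSV:
    """A planted SV plus its breed-of-origin bookkeeping."""

    sv: StructuralVariant
    breeds: tuple
    shared: bool
    is_rearrangement: bool = False


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset."""

    planted_svs: list = field(default_factory=list)
    planted_rearrangements: list = field(default_factory=list)
    de_genes: list = field(default_factory=list)            # (gene_id, tissue, sign)
    regulatory_placements: list = field(default_factory=list)  # (sv_id, state, tissue)
    seed: int = 0

    def svs_for_breed(self, breed: str, include_rearrangements: bool = True) -> list[StructuralVariant]:
        """SVs expected in ``breed``'s assembly, as reference-coordinate truth."""
        return [p.sv for p in self.planted_svs
                if breed in p.breeds and (include_rearrangements or not p.is_rearrangement)]

    def private_svs(self, breed: str,
                    include_rearrangements: bool = True) -> list[StructuralVariant]:
        return [p.sv for p in self.planted_svs
                if p.breeds == (breed,) and not p.shared
                and (include_rearrangements or not p.is_rearrangement)]

    def shared_svs(self) -> list[StructuralVariant]:
        return [p.sv for p in self.planted_svs if p.shared]


def _stage_seeds(seed: int, n: int = 10) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def simulate_reference(config: SimulationConfig) -> dict[str, str]:
    """I.i.d. reference genome over {A,C,G,T}; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(_stage_seeds(config.seed)[0])
    return {name: _random_seq(rng, config.chrom_length, config.gc_content)
            for name in config.chrom_names}


# ---------------------------------------------------------------------------
# event planning

class _Occupancy:
    """Per-chromosome interval bookkeeping with a guard distance."""

    def __init__(self, guard: int):
        self.guard = guard
        self.by_chrom: dict[str, list[tuple[int, int]]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        return all(interval_gap(s, e, start, end) > self.guard
                   for s, e in self.by_chrom.get(chrom, []))

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((start, end))


def _mix_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    keys = [t for t in SV_TYPES if mix.get(t, 0) > 0]
    total = sum(mix[t] for t in keys)
    counts = {t: int(n * mix[t] / total) for t in keys}
    i = 0
    while sum(counts.values()) < n:
        counts[keys[i % len(keys)]] += 1
        i += 1
    return counts


def plan_rearrangements(config: SimulationConfig,
                        rng: np.random.Generator,
                        occupancy: _Occupancy,
                        breed: str = FOCAL_BREED) -> list[Rearrangement]:
    """Place large in-place inversions, one per chromosome, with margins of at
    least the synteny resolution so both flanks can form synteny blocks."""
    margin = config.synteny_resolution
    out: list[Rearrangement] = []
    used_chroms: set[str] = set()
    for _ in range(config.n_rearrangements):
        lo, hi = config.rearrangement_length_range
        placed = False
        for _try in range(200):
            chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
            if chrom in used_chroms:
                continue
            length = int(rng.integers(lo, hi + 1))
            if config.chrom_length - 2 * margin - length < 1:
                continue
            start = int(rng.integers(margin, config.chrom_length - margin - length))
            if occupancy.is_free(chrom, start, start + length):
                occupancy.reserve(chrom, start, start + length)
                used_chroms.add(chrom)
                out.append(Rearrangement("inversion", breed, chrom, start, start + length))
                placed = True
                break
        if not placed:
            raise ValueError("n_rearrangements: cannot place rearrangements with the "
                             "required margins; enlarge chrom_length or reduce counts")
    return out


def plan_structural_variants(config: SimulationConfig,
                             rng: np.random.Generator,
                             occupancy: _Occupancy,
                             genes: Sequence[GeneModel] | None = None) -> list[PlantedSV]:
    """Plant shared SVs (both non-reference breeds) and private SVs per breed.

    About half of the focal breed's private SVs are targeted at gene
    neighbourhoods so that expression effects can be linked to them.
    """
    gmap = genes_by_chrom(genes or [])
    edge_margin = 10_000

    def sample_interval(svt: str, near_genes: bool) -> tuple[str, int, int]:
        lo, hi = config.sv_length_range[svt]
        for _try in range(500):
            length = int(rng.integers(lo, hi + 1))
            if near_genes and gmap:
                chrom = list(gmap)[int(rng.integers(len(gmap)))]
                g = gmap[chrom][int(rng.integers(len(gmap[chrom])))]
                center = int(rng.integers(max(0, g.start - 2000), g.end + 2000))
                start = center - length // 2
            else:
                chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
                start = int(rng.integers(edge_margin, config.chrom_length - edge_margin - length))
            if start < edge_margin or start + length > config.chrom_length - edge_margin:
                continue
            if occupancy.is_free(chrom, start, start + length):
                occupancy.reserve(chrom, start, start + length)
                return chrom, start, start + length
        raise ValueError("n_private_svs/n_shared_svs: cannot place all events with the "
                         "guard distance; enlarge the genome or reduce counts")

    planted: list[PlantedSV] = []
    counter = 0

    def make(svt: str, breeds: tuple, shared: bool, near_genes: bool) -> None:
        nonlocal counter
        chrom, s, e = sample_interval(svt, near_genes)
        length = e - s
        if svt == "INS":
            sv = StructuralVariant(f"truth_{counter:05d}", "INS", chrom, s, s, length,
                                   alt_sequence=_random_seq(rng, length, config.gc_content),
                                   source_breed=breeds[0], provenance="truth")
        else:
            sv = StructuralVariant(f"truth_{counter:05d}", svt, chrom, s + 1, e, length,
                                   source_breed=breeds[0], provenance="truth")
        planted.append(PlantedSV(sv, breeds, shared))
        counter += 1

    shared_breeds = tuple(b for b in config.breeds if b != REFERENCE_BREED)
    for svt, n in _mix_counts(config.n_shared_svs, config.sv_type_mix).items():
        for _ in range(n):
            make(svt, shared_breeds, shared=True, near_genes=False)
    for breed in shared_breeds:
        near_fraction = 0.5 if breed == FOCAL_BREED else 0.0
        for svt, n in _mix_counts(config.n_private_svs, config.sv_type_mix).items():
            for i in range(n):
                make(svt, (breed,), shared=False,
                     near_genes=bool(genes) and rng.random() < near_fraction)
    return planted


# ---------------------------------------------------------------------------
# assembly derivation

def _replacement_ops(svs: Iterable[StructuralVariant],
                     rearrangements: Iterable[Rearrangement],
                     reference: Mapping[str, str]) -> dict[str, list[tuple[int, int, str]]]:
    """Express every event as 'replace ref[start:end) with seq' on its chromosome."""
    ops: dict[str, list[tuple[int, int, str]]] = {}

    def add(chrom: str, start: int, end: int, seq: str) -> None:
        ops.setdefault(chrom, []).append((start, end, seq))

    for sv in svs:
        if sv.sv_type == "DEL":
            add(sv.chrom, sv.start0, sv.end0, "")
        elif sv.sv_type == "INS":
            add(sv.chrom, sv.pos, sv.pos, sv.alt_sequence)
        elif sv.sv_type == "DUP":
            seg = reference[sv.chrom][sv.start0:sv.end0]
            add(sv.chrom, sv.end0, sv.end0, seg)   # tandem copy after the source
        elif sv.sv_type == "INV":
            seg = reference[sv.chrom][sv.start0:sv.end0]
            add(sv.chrom, sv.start0, sv.end0, revcomp(seg))
    for r in rearrangements:
        if r.kind == "inversion":
            seg = reference[r.chrom][r.start0:r.end0]
            add(r.chrom, r.start0, r.end0, revcomp(seg))
        elif r.kind == "swap":
            seg_a = reference[r.chrom][r.start0:r.end0]
            seg_b = reference[r.chrom2][r.start2:r.end2]
            add(r.chrom, r.start0, r.end0, seg_b)
            add(r.chrom2, r.start2, r.end2, seg_a)
        else:
            raise ValueError(f"unknown rearrangement kind {r.kind!r}")
    return ops


def derive_breed_assembly(reference: Mapping[str, str],
                          breed: str,
                          sv_plan: Sequence[StructuralVariant],
                          rearrangement_plan: Sequence[Rearrangement] = (),
                          guard_distance: int = 1_000) -> dict[str, str]:
    """Apply planted events to the reference, right-to-left per chromosome.

    Events must be non-overlapping and separated by at least the guard
    distance on each chromosome; INS anchors count as points.
    """
    occ = _Occupancy(guard_distance - 1 if guard_distance else 0)
    for sv in sv_plan:
        lo, hi = sv.interval0()
        if not occ.is_free(sv.chrom, lo, hi):
            raise ValueError(f"planned events overlap or violate the guard distance "
                             f"near {sv.chrom}:{sv.pos}")
        occ.reserve(sv.chrom, lo, hi)
    for r in rearrangement_plan:
        for chrom, s, e in ([(r.chrom, r.start0, r.end0)]
                            + ([(r.chrom2, r.start2, r.end2)] if r.kind == "swap" else [])):
            if not occ.is_free(chrom, s, e):
                raise ValueError(f"planned rearrangement overlaps another event on {chrom}")
            occ.reserve(chrom, s, e)

    ops = _replacement_ops(sv_plan, rearrangement_plan, reference)
    assembly: dict[str, str] = {}
    for chrom, seq in reference.items():
        for start, end, repl in sorted(ops.get(chrom, []), reverse=True):
            seq = seq[:start] + repl + seq[end:]
        assembly[chrom] = seq
    return assembly


# ---------------------------------------------------------------------------
# annotation, genotypes, expression, chromatin

def simulate_gene_annotation(reference: Mapping[str, str],
                             n_genes: int,
                             seed: int,
                             min_gene_len: int = 2_000,
                             max_gene_len: int = 10_000) -> list[GeneModel]:
    """Non-overlapping single-transcript genes with 1-10 exons and terminal UTRs."""
    rng = np.random.default_rng(seed)
    chroms = list(reference)
    total = sum(len(reference[c]) for c in chroms)
    if n_genes * (max_gene_len + 2_000) > total:
        raise ValueError(f"n_genes={n_genes} infeasible for a {total}-bp genome")
    occ = _Occupancy(guard=1_000)
    genes: list[GeneModel] = []
    for i in range(n_genes):
        for _try in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(min_gene_len, max_gene_len + 1))
            limit = len(reference[chrom]) - length - 1_000
            if limit <= 1_000:
                continue
            start = int(rng.integers(1_000, limit))
            if occ.is_free(chrom, start, start + length):
                occ.reserve(chrom, start, start + length)
                break
        else:
            raise ValueError(f"n_genes={n_genes}: could not place gene {i}")
        strand = "+" if rng.random() < 0.5 else "-"
        max_exons = max(1, min(10, (length - 100) // 200))
        n_exons = int(rng.integers(1, max_exons + 1))
        # partition: n_exons exons of >=100 bp separated by introns of >=100 bp
        slack = length - n_exons * 100 - (n_exons - 1) * 100
        cuts = np.sort(rng.integers(0, slack + 1, size=2 * n_exons - 1)) if slack > 0 \
            else np.zeros(2 * n_exons - 1, dtype=int)
        exons: list[tuple[int, int]] = []
        pos = start
        prev = 0
        for j in range(2 * n_exons - 1):
            seg = 100 + int(cuts[j] - prev)
            prev = cuts[j]
            if j % 2 == 0:
                exons.append((pos, pos + seg))
            pos += seg
        exons[-1] = (exons[-1][0], start + length)
        g = GeneModel(f"gene_{i:04d}", chrom, start, start + length, strand, exons=exons)
        first, last = exons[0], exons[-1]
        left_utr = (first[0], first[0] + min(int(rng.integers(50, 201)), first[1] - first[0] - 10))
        right_utr = (last[1] - min(int(rng.integers(50, 201)), last[1] - last[0] - 10), last[1])
        g.utr5, g.utr3 = ([left_utr], [right_utr]) if strand == "+" else ([right_utr], [left_utr])
        genes.append(g)
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def simulate_genotypes(truth: SimulationTruth,
                       n_samples_per_breed: Mapping[str, int],
                       genotyping_rate: float,
                       seed: int,
                       private_alt_freq: float = 0.9,
                       background_alt_freq: float = 0.02,
                       shared_alt_freq: float = 0.5,
                       reference_breed: str = REFERENCE_BREED) -> GenotypeMatrix:
    """Dosage matrix for all planted SVs (rearrangements excluded).

    Private SVs segregate at ``private_alt_freq`` in the owning breed and
    ``background_alt_freq`` elsewhere; shared SVs at ``shared_alt_freq`` in
    both non-reference breeds. Each call is independently missing with
    probability 1 - ``genotyping_rate``.
    """
    for name, v in (("genotyping_rate", genotyping_rate),
                    ("private_alt_freq", private_alt_freq),
                    ("background_alt_freq", background_alt_freq),
                    ("shared_alt_freq", shared_alt_freq)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    planted = [p for p in truth.planted_svs if not p.is_rearrangement]
    if not planted:
        raise ValueError("truth contains no genotypeable SVs")
    rng = np.random.default_rng(seed)
    samples, breeds = [], []
    for breed, n in n_samples_per_breed.items():
        for i in range(n):
            samples.append(f"{breed}_{i + 1:02d}")
            breeds.append(breed)
    freqs = np.empty((len(samples), len(planted)))
    for j, p in enumerate(planted):
        for i, breed in enumerate(breeds):
            if p.shared:
                f = shared_alt_freq if breed != reference_breed else background_alt_freq
            else:
                f = private_alt_freq if breed in p.breeds else background_alt_freq
            freqs[i, j] = f
    dos = rng.binomial(2, freqs).astype(float)
    if genotyping_rate < 1.0:
        dos[rng.random(dos.shape) > genotyping_rate] = np.nan
    df = pd.DataFrame(dos, index=samples, columns=[p.sv.sv_id for p in planted])
    info = pd.DataFrame({"chrom": [p.sv.chrom for p in planted],
                         "pos": [p.sv.pos for p in planted],
                         "sv_type": [p.sv.sv_type for p in planted]},
                        index=df.columns)
    return GenotypeMatrix(df, pd.Series(breeds, index=samples, name="breed"), info)


def select_de_genes(genes: Sequence[GeneModel],
                    truth: SimulationTruth,
                    tissues: Sequence[str],
                    flank: int,
                    fraction: float,
                    seed: int,
                    focal_breed: str = FOCAL_BREED) -> list[tuple[str, str, int]]:
    """Pick genes near focal private SVs and flag a fraction as DE (into truth).

    A selected gene is differentially expressed in all tissues (30% of
    picks) or in one random tissue, with one direction shared by both breed
    comparisons.
    """
    rng = np.random.default_rng(seed)
    private = truth.private_svs(focal_breed, include_rearrangements=False)
    near: list[str] = []
    for g in genes:
        for sv in private:
            lo, hi = sv.interval0()
            if g.chrom == sv.chrom and interval_gap(g.start, g.end, lo, hi) <= flank:
                near.append(g.gene_id)
                break
    chosen = [gid for gid in near if rng.random() < fraction]
    de: list[tuple[str, str, int]] = []
    for gid in chosen:
        sign = 1 if rng.random() < 0.5 else -1
        if rng.random() < 0.3:
            de.extend((gid, t, sign) for t in tissues)
        else:
            de.append((gid, tissues[int(rng.integers(len(tissues)))], sign))
    truth.de_genes = de
    return de


def simulate_expression(genes: Sequence[GeneModel] | Sequence[str],
                        truth: SimulationTruth,
                        tissues: Sequence[str],
                        seed: int,
                        comparisons: Sequence[str] = DEFAULT_COMPARISONS,
                        null_lfc_sd: float = 0.75) -> pd.DataFrame:
    """Long DE-statistics table per (gene, tissue, comparison).

    Genes flagged DE in the truth get |log2FC| >= 1 with the planted sign
    and padj < 0.05 in both comparisons of their tissue; background genes
    draw log2FC ~ N(0, null_lfc_sd) and padj ~ U(0, 1).
    """
    if not tissues:
        raise ValueError("tissues must be non-empty")
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    known = set(gene_ids)
    linked: dict[tuple[str, str], int] = {}
    for gid, tissue, sign in truth.de_genes:
        if gid not in known:
            raise ValueError(f"truth de_gene {gid!r} not in the gene annotation")
        linked[(gid, tissue)] = sign
    rng = np.random.default_rng(seed)
    n = len(gene_ids) * len(tissues) * len(comparisons)
    rows = {"gene_id": [], "tissue": [], "comparison": []}
    for gid in gene_ids:
        for tissue in tissues:
            for comp in comparisons:
                rows["gene_id"].append(gid)
                rows["tissue"].append(tissue)
                rows["comparison"].append(comp)
    lfc = rng.normal(0.0, null_lfc_sd, size=n)
    padj = rng.uniform(0.0, 1.0, size=n)
    df = pd.DataFrame(rows)
    df["log2fc"] = lfc
    df["padj"] = padj
    if linked:
        key = pd.Series(zip(df["gene_id"], df["tissue"]))
        mask = key.map(lambda k: k in linked).to_numpy()
        n_hit = int(mask.sum())
        signs = key[mask].map(lambda k: linked[k]).to_numpy(dtype=float)
        df.loc[mask, "log2fc"] = signs * (1.0 + rng.exponential(0.8, size=n_hit))
        df.loc[mask, "padj"] = 10.0 ** rng.uniform(-6.0, -2.0, size=n_hit)
    return df


def select_regulatory_placements(genes: Sequence[GeneModel],
                                 truth: SimulationTruth,
                                 tissues: Sequence[str],
                                 flank: int,
                                 seed: int,
                                 max_placements: int = 10,
                                 focal_breed: str = FOCAL_BREED) -> list[tuple[str, str, str]]:
    """Choose (sv_id, state, tissue) placements for focal SVs near DE genes.

    Promoter-class placements (TssAFlnk) cover all tissues; enhancer-class
    placements (EnhG inside a gene body, Enh otherwise) are tissue-specific.
    SVs overlapping a promoter window of any gene are only given
    promoter-class states, so TSS promoter coverage is never displaced.
    """
    rng = np.random.default_rng(seed)
    de_gene_ids = {gid for gid, _, _ in truth.de_genes}
    gmap = {g.gene_id: g for g in genes}
    by_chrom = genes_by_chrom(genes)
    candidates: list[tuple[StructuralVariant, str]] = []
    for sv in truth.private_svs(focal_breed, include_rearrangements=False):
        lo, hi = sv.interval0()
        for g in by_chrom.get(sv.chrom, []):
            if g.gene_id in de_gene_ids and interval_gap(g.start, g.end, lo, hi) <= flank:
                candidates.append((sv, g.gene_id))
                break
    rng.shuffle(candidates)
    placements: list[tuple[str, str, str]] = []
    for sv, gid in candidates[:max_placements]:
        lo, hi = sv.interval0()
        in_promoter_window = any(
            interval_gap(max(0, g.tss - 1000), g.tss + 1000, lo, hi) == 0
            for g in by_chrom.get(sv.chrom, []))
        if in_promoter_window or rng.random() < 0.5:
            placements.extend((sv.sv_id, "TssAFlnk", t) for t in tissues)
        else:
            g = gmap[gid]
            state = "EnhG" if (lo < g.end and hi > g.start) else "Enh"
            tissue = tissues[int(rng.integers(len(tissues)))]
            placements.append((sv.sv_id, state, tissue))
    truth.regulatory_placements = placements
    return placements


def simulate_chromatin(genes: Sequence[GeneModel],
                       truth: SimulationTruth,
                       tissues: Sequence[str],
                       seed: int,
                       chrom_lengths: Mapping[str, int],
                       enhancers_per_tissue: int | None = None) -> pd.DataFrame:
    """Per-tissue chromatin-state segmentation (sorted, non-overlapping).

    Every TSS is covered by a promoter-class segment (TssA core with
    TssAFlnk shoulders); enhancer segments (EnhG in gene bodies, Enh
    elsewhere) are scattered per tissue; planted regulatory placements are
    guaranteed to overlap the named state in the named tissue; everything
    else is Quies.
    """
    if not tissues:
        raise ValueError("tissues must be non-empty")
    rng = np.random.default_rng(seed)
    sv_map = {p.sv.sv_id: p.sv for p in truth.planted_svs}
    if enhancers_per_tissue is None:
        enhancers_per_tissue = max(20, len(genes))
    chroms = list(chrom_lengths)
    rows = []
    for tissue in tissues:
        cand: list[tuple[int, str, int, int, str]] = []  # (priority, chrom, s, e, state)
        for sv_id, state, t in truth.regulatory_placements:
            if t != tissue:
                continue
            sv = sv_map[sv_id]
            lo, hi = sv.interval0()
            hi = max(hi, lo + 1)
            pad = int(rng.integers(50, 300))
            cand.append((0, sv.chrom, max(0, lo - pad),
                         min(chrom_lengths[sv.chrom], hi + pad), state))
        for g in genes:
            tss = g.tss
            L = chrom_lengths[g.chrom]
            cand.append((1, g.chrom, max(0, tss - 200), min(L, tss + 200), "TssA"))
            if tss - 200 > 0:
                cand.append((1, g.chrom, max(0, tss - 1000), tss - 200, "TssAFlnk"))
            if tss + 200 < L:
                cand.append((1, g.chrom, tss + 200, min(L, tss + 1000), "TssAFlnk"))
        gmap = genes_by_chrom(genes)
        for _ in range(enhancers_per_tissue):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(500, 2001))
            if chrom_lengths[chrom] <= length:
                continue
            s = int(rng.integers(0, chrom_lengths[chrom] - length))
            in_gene = any(g.start < s + length and g.end > s for g in gmap.get(chrom, []))
            cand.append((2, chrom, s, s + length, "EnhG" if in_gene else "Enh"))

        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
        for prio, chrom, s, e, state in sorted(cand, key=lambda c: (c[0], c[1], c[2], c[3])):
            pieces = [(s, e)]
            for os_, oe in occupied[chrom]:
                nxt = []
                for ps, pe in pieces:
                    if oe <= ps or os_ >= pe:
                        nxt.append((ps, pe))
                    else:
                        if ps < os_:
                            nxt.append((ps, os_))
                        if oe < pe:
                            nxt.append((oe, pe))
                pieces = nxt
            for ps, pe in pieces:
                if pe > ps:
                    occupied[chrom].append((ps, pe))
                    rows.append((tissue, chrom, ps, pe, state))
        for chrom in chroms:
            prev = 0
            for s, e in sorted(occupied[chrom]):
                if s > prev:
                    rows.append((tissue, chrom, prev, s, "Quies"))
                prev = max(prev, e)
            if prev < chrom_lengths[chrom]:
                rows.append((tissue, chrom, prev, chrom_lengths[chrom], "Quies"))
    df = pd.DataFrame(rows, columns=["tissue", "chrom", "start", "end", "state"])
    return df.sort_values(["tissue", "chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# whole-dataset orchestration

@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, with its truth set."""

    config: SimulationConfig
    reference: dict
    assemblies: dict                 # breed -> {chrom: seq}
    genes: list
    truth: SimulationTruth
    genotypes: GenotypeMatrix
    expression: pd.DataFrame
    chromatin: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: reference, assemblies, truth, and omics tables."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    reference = simulate_reference(config)
    genes = simulate_gene_annotation(reference, config.n_genes, seeds[1])

    rng = np.random.default_rng(seeds[2])
    occupancy = _Occupancy(config.guard_distance)
    rearrangements = plan_rearrangements(config, rng, occupancy)
    planted = plan_structural_variants(config, rng, occupancy, genes)
    truth = SimulationTruth(planted_svs=list(planted),
                            planted_rearrangements=rearrangements,
                            seed=config.seed)
    for i, r in enumerate(rearrangements):
        truth.planted_svs.append(PlantedSV(
            StructuralVariant(f"rearr_{i:03d}", "INV", r.chrom, r.start0 + 1, r.end0,
                              r.end0 - r.start0, source_breed=r.breed, provenance="truth"),
            breeds=(r.breed,), shared=False, is_rearrangement=True))

    assemblies = {}
    for breed in config.breeds:
        if breed == REFERENCE_BREED:
            assemblies[breed] = dict(reference)
            continue
        svs = truth.svs_for_breed(breed, include_rearrangements=False)
        rearr = [r for r in rearrangements if r.breed == breed]
        assemblies[breed] = derive_breed_assembly(reference, breed, svs, rearr,
                                                  config.guard_distance)

    select_de_genes(genes, truth, config.tissues, config.flank,
                    config.de_fraction_near_private_svs, seeds[3])
    select_regulatory_placements(genes, truth, config.tissues, config.flank, seeds[4])
    if any(not p.is_rearrangement for p in truth.planted_svs):
        genotypes = simulate_genotypes(truth, config.n_samples_per_breed,
                                       config.genotyping_rate, seeds[5],
                                       config.private_alt_freq,
                                       config.background_alt_freq,
                                       config.shared_alt_freq)
    else:
        samples, breeds = [], []
        for breed, n in config.n_samples_per_breed.items():
            samples += [f"{breed}_{i + 1:02d}" for i in range(n)]
            breeds += [breed] * n
        genotypes = GenotypeMatrix(
            pd.DataFrame(index=samples, columns=pd.Index([], dtype=object),
                         dtype=float),
            pd.Series(breeds, index=samples, name="breed"))
    expression = simulate_expression(genes, truth, config.tissues, seeds[6],
                                     null_lfc_sd=config.null_lfc_sd)
    chromatin = simulate_chromatin(genes, truth, config.tissues, seeds[7],
                                   {c: len(s) for c, s in reference.items()})
    return SimulatedDataset(config, reference, assemblies, genes, truth,
                            genotypes, expression, chromatin)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def truth_to_dict(truth: SimulationTruth) -> dict:
    return {
        "seed": truth.seed,
        "planted_svs": [{**dataclasses.asdict(p.sv), "breeds": list(p.breeds),
                         "shared": p.shared, "is_rearrangement": p.is_rearrangement}
                        for p in truth.planted_svs],
        "planted_rearrangements": [dataclasses.asdict(r)
                                   for r in truth.planted_rearrangements],
        "de_genes": [list(x) for x in truth.de_genes],
        "regulatory_placements": [list(x) for x in truth.regulatory_placements],
    }


def truth_from_dict(d: dict) -> SimulationTruth:
    truth = SimulationTruth(seed=d["seed"])
    for p in d["planted_svs"]:
        p = dict(p)
        breeds = tuple(p.pop("breeds"))
        shared = p.pop("shared")
        is_rearr = p.pop("is_rearrangement")
        truth.planted_svs.append(PlantedSV(StructuralVariant(**p), breeds, shared, is_rearr))
    truth.planted_rearrangements = [Rearrangement(**r)
                                    for r in d["planted_rearrangements"]]
    truth.de_genes = [tuple(x) for x in d["de_genes"]]
    truth.regulatory_placements = [tuple(x) for x in d["regulatory_placements"]]
    return truth
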