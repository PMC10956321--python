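"""End-to-end orchestration: simulate -> align -> synteny -> call -> subtract
-> annotate -> PCA -> integrate, with truth-based evaluation.

Each stage's outputs can be written to a run directory as standard formats
(VCF/BED/TSV/JSON) together with a run log recording the seed and
parameters; a stage failure aborts with the stage name while earlier
outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import anchor_align
from .breed_specific import (OverlapPolicy, evaluate_specificity,
                             filter_breed_specific, precision_recall)
from .consequences import category_breakdown, classify_consequences, consequence_table, flanking_genes
from .integrate import common_degs, link_nsv_deg, regulatory_overlap
from .popstruct import compute_grm, filter_genotypes, pca_from_grm
from .simulate import (FOCAL_BREED, REFERENCE_BREED, Rearrangement,
                       SimulatedDataset, SimulationConfig, simulate_dataset)
from .svcalls import call_svs, summarize_svs, write_sv_vcf
from .synteny import (breakpoints_to_bed, build_synteny_blocks,
                      find_breakpoint_regions, synteny_to_bed)
from .io import write_fixture_bundle


def evaluate_breakpoints(breakpoints, rearrangements: Sequence[Rearrangement],
                         tol: int) -> dict:
    """Recall of true rearrangement junctions by predicted breakpoint regions.

    A junction (chrom, coordinate) is recovered when some breakpoint region
    on that chromosome lies within ``tol`` bases of it.
    """
    junctions = [j for r in rearrangements for j in r.junctions()]
    n_found = 0
    errors = []
    for chrom, coord in junctions:
        best = None
        for bp in breakpoints:
            if bp.chrom != chrom:
                continue
            d = max(0, bp.start - coord, coord - bp.end)
            best = d if best is None else min(best, d)
        if best is not None and best <= tol:
            n_found += 1
            errors.append(best)
    return {"n_junctions": len(junctions), "n_found": n_found,
            "recall": n_found / len(junctions) if junctions else float("nan"),
            "max_positional_error": max(errors) if errors else None}


@dataclass
class PipelineResult:
    dataset: SimulatedDataset
    blocks: dict = field(default_factory=dict)
    synteny: dict = field(default_factory=dict)
    breakpoints: dict = field(default_factory=dict)
    sv_calls: dict = field(default_factory=dict)
    nsvs: list = field(default_factory=list)
    consequences: list = field(default_factory=list)
    flanking: dict = field(default_factory=dict)
    eigenvalues: np.ndarray | None = None
    pc_coords: pd.DataFrame | None = None
    common_deg: dict = field(default_factory=dict)
    linked: list = field(default_factory=list)
    regulatory: pd.DataFrame | None = None
    evaluation: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: SimulationConfig,
                 outdir: str | None = None,
                 k: int = 21,
                 max_gap: int = 30,
                 evaluate: bool = True,
                 write_bundle: bool = False) -> PipelineResult:
    """Run the full analysis on a freshly simulated dataset.

    Returns all stage products in memory; when ``outdir`` is given, per-stage
    files, a run log, and a summary JSON are written as the stages complete.
    """
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    ds = _stage("simulate")(simulate_dataset)(config)
    res = PipelineResult(dataset=ds)
    focal = FOCAL_BREED
    comparator = [b for b in config.breeds if b not in (REFERENCE_BREED, FOCAL_BREED)][0]
    if outdir and write_bundle:
        write_fixture_bundle(ds, os.path.join(outdir, "simulated"))

    for breed in (focal, comparator):
        res.blocks[breed] = _stage("align")(anchor_align)(
            ds.assemblies[breed], ds.reference, k=k, max_gap=max_gap,
            comparison=f"{breed}_vs_{REFERENCE_BREED}")

    for breed in (focal, comparator):
        syn = _stage("synteny")(build_synteny_blocks)(
            res.blocks[breed], resolution=config.synteny_resolution)
        res.synteny[breed] = syn
        res.breakpoints[breed] = find_breakpoint_regions(syn, assembly_label=breed)
        if outdir:
            synteny_to_bed(syn, os.path.join(outdir, f"synteny_{breed}.bed"))
            breakpoints_to_bed(res.breakpoints[breed],
                               os.path.join(outdir, f"breakpoints_{breed}.bed"))

    for breed in (focal, comparator):
        res.sv_calls[breed] = _stage("callsv")(call_svs)(
            res.blocks[breed], ds.reference, ds.assemblies[breed],
            min_len=config.min_sv_length, source_breed=breed)
        if outdir:
            write_sv_vcf(res.sv_calls[breed], ds.reference,
                         os.path.join(outdir, f"svs_{breed}.vcf"))

    res.nsvs = _stage("specific")(filter_breed_specific)(
        res.sv_calls[focal], res.sv_calls[comparator], OverlapPolicy())
    if outdir:
        write_sv_vcf(res.nsvs, ds.reference, os.path.join(outdir, "nsvs.vcf"))

    res.consequences = _stage("annotate")(classify_consequences)(
        res.nsvs, ds.genes, flank=config.flank)
    res.flanking = flanking_genes(res.nsvs, ds.genes, flank=config.flank)
    if outdir:
        consequence_table(res.consequences).to_csv(
            os.path.join(outdir, "nsv_consequences.tsv"), sep="\t", index=False)

    # genotyped-NSV PCA: subset the genotype panel to the truth variants the
    # called NSVs recover, then filter and decompose
    matched_ids = {t.sv_id for _, t in _matched_pairs(res.nsvs, ds)}
    geno = ds.genotypes.subset_variants(
        [vid for vid in ds.genotypes.dosages.columns if vid in matched_ids]) \
        if matched_ids else ds.genotypes
    filt = _stage("pca")(filter_genotypes)(geno, config.maf_min, config.missing_max)
    grm = compute_grm(filt)
    res.eigenvalues, res.pc_coords = pca_from_grm(grm, n_pcs=config.n_pcs)
    if outdir:
        grm.to_csv(os.path.join(outdir, "grm.tsv"), sep="\t")
        pcs = res.pc_coords.copy()
        pcs.insert(0, "breed", ds.genotypes.breeds)
        pcs.to_csv(os.path.join(outdir, "pca.tsv"), sep="\t")

    res.common_deg = _stage("integrate")(common_degs)(
        ds.expression, config.lfc_min, config.padj_max)
    res.linked = link_nsv_deg(res.nsvs, res.common_deg, ds.genes, flank=config.flank)
    res.regulatory = regulatory_overlap(res.linked, res.nsvs, ds.chromatin)
    if outdir:
        res.regulatory.to_csv(os.path.join(outdir, "nsv_deg_regulatory.tsv"),
                              sep="\t", index=False)

    if evaluate:
        res.evaluation = _evaluate(res, ds, focal, comparator, tol_bp=max_gap + k)
    res.summary = _summarize(res, ds, focal, comparator)
    if outdir:
        with open(os.path.join(outdir, "run_log.json"), "w") as fh:
            json.dump({"version": __version__, "seed": config.seed,
                       "k": k, "max_gap": max_gap,
                       "config": dataclasses.asdict(config)}, fh, indent=1)
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(res.summary, fh, indent=1, default=str)
    return res


def _matched_pairs(nsvs, ds: SimulatedDataset):
    from .breed_specific import match_sv

    truth = ds.truth.svs_for_breed(FOCAL_BREED, include_rearrangements=False)
    pairs = []
    remaining = list(truth)
    for c in nsvs:
        hit = next((t for t in remaining if match_sv(c, t)), None)
        if hit is not None:
            remaining.remove(hit)
            pairs.append((c, hit))
    return pairs


def _evaluate(res: PipelineResult, ds: SimulatedDataset,
              focal: str, comparator: str, tol_bp: int) -> dict:
    from sklearn.metrics import silhouette_score

    ev: dict = {}
    for breed in (focal, comparator):
        ev[f"sv_{breed}"] = {
            k: v for k, v in precision_recall(
                res.sv_calls[breed], ds.truth.svs_for_breed(breed)).items()
            if k not in {"false_positives", "false_negatives", "per_type"}}
    ev["breakpoints"] = evaluate_breakpoints(
        res.breakpoints[focal],
        [r for r in ds.truth.planted_rearrangements if r.breed == focal], tol_bp)
    nsv_ev = evaluate_specificity(res.nsvs, ds.truth.private_svs(focal))
    ev["nsv"] = {k: v for k, v in nsv_ev.items()
                 if k not in {"false_positives", "false_negatives", "per_type"}}

    labels = (ds.genotypes.breeds.loc[res.pc_coords.index] == focal).to_numpy()
    pc1 = res.pc_coords["PC1"].to_numpy().reshape(-1, 1)
    ev["pca_silhouette_pc1"] = float(silhouette_score(pc1, labels))

    truth_pairs = {(gid, t) for gid, t, _ in ds.truth.de_genes}
    found_pairs = {(tr.gene_id, tr.tissue) for tr in res.linked}
    ev["linked_gene_recovery"] = (len(truth_pairs & found_pairs) / len(truth_pairs)
                                  if truth_pairs else float("nan"))
    return ev


def _summarize(res: PipelineResult, ds: SimulatedDataset,
               focal: str, comparator: str) -> dict:
    out = {
        "sv_summary": {breed: summarize_svs(res.sv_calls[breed]).to_dict("records")
                       for breed in (focal, comparator)},
        "nsv_summary": summarize_svs(res.nsvs).to_dict("records"),
        "n_nsvs": len(res.nsvs),
        "n_breakpoints": {b: len(res.breakpoints[b]) for b in res.breakpoints},
        "n_flanking_genes": len(res.flanking),
        "consequence_breakdown": category_breakdown(res.consequences).to_dict("records"),
        "common_degs": {t: sorted(g) for t, g in res.common_deg.items()},
        "n_linked_triples": len(res.linked),
        "n_regulatory_nsvs": int(res.regulatory[
            res.regulatory["promoter"] | res.regulatory["enhancer"]]["sv_id"].nunique())
        if res.regulatory is not None and not res.regulatory.empty else 0,
        "eigenvalues": [float(v) for v in (res.eigenvalues if res.eigenvalues is not None else [])],
        "evaluation": res.evaluation,
    }
    return out
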