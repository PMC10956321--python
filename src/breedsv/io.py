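"""Fixture-bundle serialization: FASTA, GFF3, BED, TSV, VCF, JSON + manifest.

Everything a simulation produces can be written to a directory and read
back losslessly; the manifest records a sha256 per file so any content
change is detectable.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Mapping

import pandas as pd

from .genes import read_gff3, write_gff3
from .popstruct import GenotypeMatrix
from .simulate import (SimulatedDataset, SimulationConfig, config_to_dict,
                       truth_from_dict, truth_to_dict)
from .svcalls import write_sv_vcf

FASTA_WIDTH = 60


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name] if isinstance(seqs[name], str) else str(seqs[name])
            for i in range(0, len(s), FASTA_WIDTH):
                fh.write(s[i:i + FASTA_WIDTH] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA into plain strings (via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(path, rebuild=True)
    try:
        out = {name: str(fa[name][:]) for name in fa.keys()}
    finally:
        fa.close()
    try:
        os.remove(path + ".fai")
    except OSError:
        pass
    return out


def write_chromatin_bed(segments: pd.DataFrame, outdir: str,
                        prefix: str = "chromatin") -> list[str]:
    """One 4-column BED (chrom, start, end, state) per tissue."""
    paths = []
    for tissue, sub in segments.groupby("tissue"):
        path = os.path.join(outdir, f"{prefix}_{tissue}.bed")
        sub[["chrom", "start", "end", "state"]].to_csv(
            path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def read_chromatin_bed(paths: Mapping[str, str]) -> pd.DataFrame:
    """Read {tissue: bed_path} back into the long chromatin table."""
    frames = []
    for tissue, path in paths.items():
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "state"])
        df.insert(0, "tissue", tissue)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["tissue", "chrom", "start"], kind="stable").reset_index(drop=True)


def write_genotypes_tsv(gm: GenotypeMatrix, matrix_path: str, samples_path: str) -> None:
    df = gm.variant_info.copy() if not gm.variant_info.empty \
        else pd.DataFrame(index=gm.dosages.columns)
    df.index.name = "variant_id"
    dosage_t = gm.dosages.T
    dosage_t.index.name = "variant_id"
    df.join(dosage_t).to_csv(matrix_path, sep="\t", na_rep="NA")
    gm.breeds.rename("breed").to_frame().rename_axis("sample").to_csv(
        samples_path, sep="\t")


def read_genotypes_tsv(matrix_path: str, samples_path: str) -> GenotypeMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", index_col="variant_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    info_cols = [c for c in mat.columns if c not in samples.index]
    info = mat[info_cols]
    dosages = mat[list(samples.index)].T.astype(float)
    return GenotypeMatrix(dosages, samples["breed"], info)


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(ds: SimulatedDataset, outdir: str) -> dict[str, str]:
    """Write every simulated object to ``outdir``; returns {relpath: sha256}."""
    os.makedirs(outdir, exist_ok=True)
    produced: list[str] = []

    def emit(name: str) -> str:
        produced.append(name)
        return os.path.join(outdir, name)

    write_fasta(ds.reference, emit("reference.fa"))
    for breed, seqs in ds.assemblies.items():
        write_fasta(seqs, emit(f"assembly_{breed}.fa"))
    write_gff3(ds.genes, emit("genes.gff3"))
    for tissue, sub in ds.chromatin.groupby("tissue"):
        sub[["chrom", "start", "end", "state"]].to_csv(
            emit(f"chromatin_{tissue}.bed"), sep="\t", header=False, index=False)
    ds.expression.to_csv(emit("expression.tsv"), sep="\t", index=False)
    write_genotypes_tsv(ds.genotypes, emit("genotypes.tsv"), emit("samples.tsv"))
    for breed in ds.assemblies:
        svs = ds.truth.svs_for_breed(breed, include_rearrangements=False)
        if svs:
            write_sv_vcf(svs, ds.reference, emit(f"truth_svs_{breed}.vcf"))
    with open(emit("truth.json"), "w") as fh:
        json.dump(truth_to_dict(ds.truth), fh, indent=1)
    with open(emit("config.json"), "w") as fh:
        json.dump(config_to_dict(ds.config), fh, indent=1)

    manifest = {name: sha256_of(os.path.join(outdir, name)) for name in sorted(produced)}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_fixture_bundle(outdir: str) -> SimulatedDataset:
    """Reload a bundle written by :func:`write_fixture_bundle`."""
    from .genes import read_gff3 as _read_gff3
    from .simulate import SimulatedDataset

    with open(os.path.join(outdir, "config.json")) as fh:
        cfg_d = fh.read()
    config = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in json.loads(cfg_d).items()})
    with open(os.path.join(outdir, "truth.json")) as fh:
        truth = truth_from_dict(json.load(fh))
    reference = read_fasta(os.path.join(outdir, "reference.fa"))
    assemblies = {}
    for name in sorted(os.listdir(outdir)):
        if name.startswith("assembly_") and name.endswith(".fa"):
            assemblies[name[len("assembly_"):-3]] = read_fasta(os.path.join(outdir, name))
    genes = _read_gff3(os.path.join(outdir, "genes.gff3"))
    chromatin = read_chromatin_bed({
        name[len("chromatin_"):-4]: os.path.join(outdir, name)
        for name in sorted(os.listdir(outdir))
        if name.startswith("chromatin_") and name.endswith(".bed")})
    expression = pd.read_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
    genotypes = read_genotypes_tsv(os.path.join(outdir, "genotypes.tsv"),
                                   os.path.join(outdir, "samples.tsv"))
    return SimulatedDataset(config, reference, assemblies, genes, truth,
                            genotypes, expression, chromatin)
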