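"""Genotype filtering, genetic relationship matrix, and PCA.

The GRM entry for samples j, k is

    G_jk = (1/M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with x the alt-allele dosage in {0,1,2}, p_i the alt-allele frequency from
non-missing calls, and the sum over the M_jk variants non-missing in both
samples (pairwise-complete handling; a mean-imputation mode is also
provided). Principal components are the top eigenpairs of G, with sample
coordinates scaled by sqrt(eigenvalue).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with missingness and breed labels.

    ``dosages`` is a float DataFrame (rows = samples, columns = variant ids)
    with entries in {0, 1, 2} and NaN for missing calls. ``breeds`` maps
    sample id -> breed label; ``variant_info`` (optional) carries per-variant
    chrom/pos metadata indexed by variant id.
    """

    dosages: pd.DataFrame
    breeds: pd.Series
    variant_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.dosages.shape[0] < 1:
            raise ValueError("GenotypeMatrix requires at least one sample")
        if self.dosages.columns.duplicated().any():
            raise ValueError("variant ids must be unique")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if not self.breeds.index.equals(self.dosages.index):
            self.breeds = self.breeds.reindex(self.dosages.index)
            if self.breeds.isna().any():
                raise ValueError("breed label missing for some samples")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        info = (self.variant_info.loc[list(ids)]
                if not self.variant_info.empty else self.variant_info)
        return GenotypeMatrix(self.dosages[list(ids)], self.breeds, info)

    def restrict_chromosomes(self, include: Sequence[str]) -> "GenotypeMatrix":
        """Keep variants on an include-list of chromosomes (autosome restriction)."""
        if self.variant_info.empty or "chrom" not in self.variant_info:
            raise ValueError("variant_info with a 'chrom' column is required")
        keep = self.variant_info.index[self.variant_info["chrom"].isin(set(include))]
        return self.subset_variants(list(keep))


def allele_frequencies(gm: GenotypeMatrix) -> pd.Series:
    """Alt-allele frequency per variant from non-missing dosages."""
    return gm.dosages.mean(axis=0, skipna=True) / 2.0


def filter_genotypes(gm: GenotypeMatrix,
                     maf_min: float = 0.05,
                     missing_max: float = 0.1) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` and missing fraction <= ``missing_max``.

    Monomorphic variants are always dropped. Raises if nothing survives.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError(f"missing_max must be in [0, 1], got {missing_max}")
    p = allele_frequencies(gm)
    maf = np.minimum(p, 1.0 - p)
    miss = gm.dosages.isna().mean(axis=0)
    keep = gm.dosages.columns[(maf >= maf_min) & (miss <= missing_max)
                              & (p > 0.0) & (p < 1.0)]
    if len(keep) == 0:
        raise ValueError("no variants pass the MAF/missingness filters")
    return gm.subset_variants(list(keep))


def compute_grm(gm: GenotypeMatrix, missing: str = "pairwise") -> pd.DataFrame:
    """Genetic relationship matrix over all polymorphic variants.

    ``missing="pairwise"`` excludes a variant from a sample pair when either
    call is missing and divides by the per-pair count; ``missing="impute"``
    replaces missing dosages with 2p first. Pairs sharing no non-missing
    variant get NaN.
    """
    x = gm.dosages.to_numpy(dtype=float)
    p = np.nanmean(x, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("GRM requires at least one polymorphic variant")
    x = x[:, poly]
    p = p[poly]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (x - 2.0 * p) / denom
    if missing == "impute":
        z = np.where(np.isnan(z), 0.0, z)
        g = z @ z.T / z.shape[1]
    elif missing == "pairwise":
        obs = (~np.isnan(z)).astype(float)
        zf = np.where(np.isnan(z), 0.0, z)
        m = obs @ obs.T
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(m > 0, (zf @ zf.T) / m, np.nan)
    else:
        raise ValueError(f"missing must be 'pairwise' or 'impute', got {missing!r}")
    return pd.DataFrame(g, index=gm.dosages.index, columns=gm.dosages.index)


def pca_from_grm(grm: pd.DataFrame, n_pcs: int = 3) -> tuple[np.ndarray, pd.DataFrame]:
    """Top eigenpairs of a GRM; coordinates are eigenvectors * sqrt(eigenvalue).

    Eigenvalues come in descending order; each PC's sign is fixed so its
    largest-magnitude loading is positive.
    """
    g = grm.to_numpy(dtype=float)
    if np.isnan(g).any():
        raise ValueError("GRM contains undefined entries; impute or drop samples first")
    if not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    n = g.shape[0]
    if not 1 <= n_pcs <= n:
        raise ValueError(f"n_pcs must be in [1, {n}], got {n_pcs}")
    vals, vecs = eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1][:n_pcs]
    vals = vals[order]
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return vals, pd.DataFrame(coords, index=grm.index, columns=cols)
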