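"""Marker quality control and the genomic relationship matrix (GRM).

QC follows the conventional rules for inbred-line SNP panels: drop markers
with more than a missingness threshold (default 50%) of missing calls, a
minor allele frequency below a floor (default 0.03, computed on non-missing
calls), or no polymorphism at all.

The GRM is G = XX'/p where X is the genotype x marker dosage matrix after
marker-mean imputation of missing cells, column-centering and scaling each
column to unit standard deviation (population convention, divisor n).
Under that scaling mean(diag(G)) = 1 exactly when no data are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FitError, ValidationError
from .io_model import MarkerMatrix

__all__ = ["GenomicRelationship", "qc_filter", "standardize", "grm"]

#: divisor convention for the per-column standard deviation ("n" or "n-1")
SD_DDOF = 0


@dataclass
class GenomicRelationship:
    """Genomic relationship matrix with its construction record."""

    genotype_ids: list[str]
    G: np.ndarray = field(repr=False)
    n_markers_used: int
    #: per-marker means and scales of the standardized X (imputation+scaling contract)
    standardization: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.genotype_ids)
        if self.G.shape != (n, n):
            raise ValidationError(f"G shape {self.G.shape} != ({n}, {n})")
        if not np.allclose(self.G, self.G.T):
            raise ValidationError("G must be symmetric")

    def subset(self, ids: list[str]) -> np.ndarray:
        """Square sub-block of G for `ids`, in the given order."""
        idx = self.indices(ids)
        return self.G[np.ix_(idx, idx)]

    def cross(self, rows: list[str], cols: list[str]) -> np.ndarray:
        return self.G[np.ix_(self.indices(rows), self.indices(cols))]

    def indices(self, ids: list[str]) -> list[int]:
        index = {g: i for i, g in enumerate(self.genotype_ids)}
        try:
            return [index[g] for g in ids]
        except KeyError as e:
            raise ValidationError(f"genotype {e.args[0]!r} not in GRM") from None


def qc_filter(markers: MarkerMatrix, max_missing: float = 0.5,
              min_maf: float = 0.03) -> MarkerMatrix:
    """Drop markers exceeding `max_missing` missingness or below `min_maf`
    minor allele frequency (computed on non-missing calls); monomorphic
    markers go regardless.

    Both rules are evaluated per marker on the input, so the operation is
    idempotent and order-independent.
    """
    calls = markers.calls
    observed = ~np.isnan(calls)
    counts = observed.sum(axis=0)
    miss = 1.0 - counts / calls.shape[0]
    safe = np.maximum(counts, 1)
    mean = np.nansum(calls, axis=0) / safe
    f = mean / 2.0
    maf = np.minimum(f, 1.0 - f)
    variance = np.nansum(calls ** 2, axis=0) / safe - mean ** 2
    polymorphic = (counts > 0) & (variance > 0)
    keep = (miss <= max_missing) & (maf >= min_maf) & polymorphic
    if not keep.any():
        raise FitError(
            "all markers removed by QC; review max_missing/min_maf thresholds")
    kept_ids = [m for m, k in zip(markers.marker_ids, keep) if k]
    return MarkerMatrix(list(markers.genotype_ids), kept_ids,
                        calls[:, keep].copy())


def standardize(markers: MarkerMatrix) -> tuple[np.ndarray, dict]:
    """Impute missing cells with the marker mean, then center and scale
    each column (divisor-n standard deviation).

    Returns the standardized matrix X and a record of the per-marker means
    and scales so the transform is reproducible.
    """
    calls = markers.calls.astype(float).copy()
    means = np.nanmean(calls, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(calls))
    calls[nan_rows, nan_cols] = means[nan_cols]
    scales = np.std(calls, axis=0, ddof=SD_DDOF)
    zero = scales <= 0
    if zero.any():
        bad = [m for m, z in zip(markers.marker_ids, zero) if z]
        raise FitError(
            f"zero-variance markers {bad[:5]} — run qc_filter first")
    X = (calls - means) / scales
    record = {"marker_ids": list(markers.marker_ids),
              "means": means, "scales": scales, "sd_ddof": SD_DDOF}
    return X, record


def grm(markers: MarkerMatrix) -> GenomicRelationship:
    """Genomic relationship matrix G = XX'/p on the standardized dosages."""
    if markers.n_genotypes < 2:
        raise FitError("GRM needs at least 2 genotypes")
    X, record = standardize(markers)
    p = markers.n_markers
    G = X @ X.T / p
    G = (G + G.T) / 2.0  # enforce exact symmetry
    return GenomicRelationship(list(markers.genotype_ids), G, p, record)
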