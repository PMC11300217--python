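"""Marker QC filters, dosage imputation, and the VanRaden kinship matrix.

Dosages are scaled allele contents in [0, 2]; in a high polyploid like
sugarcane these arrive in fractional steps (0.2 here). The VanRaden
construction K = WW' / sum_k 2 p_k (1 - p_k), with W the column-centered
dosages and p_k = mean dosage / 2, is applied verbatim to fractional
dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "KinshipMatrix",
    "EmptyMarkerWarning",
    "filter_markers",
    "impute_missing",
    "vanraden_grm",
]


class EmptyMarkerWarning(UserWarning):
    """All markers were removed by filtering."""


@dataclass
class MarkerMatrix:
    """Genotype x marker dosage grid; NaN marks a missing dosage."""

    genotypes: list[str]
    markers: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.genotypes), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.genotypes)} genotypes x {len(self.markers)} markers"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or (
                np.nanmax(self.dosages, initial=0.0) > 2.0
            ):
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freqs(self) -> np.ndarray:
        """Per-marker allele frequency p = mean non-missing dosage / 2."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def missing_fractions(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.genotypes, columns=self.markers)
        df.to_csv(path, sep="\t", na_rep="NA", index_label="genotype")

    @classmethod
    def from_tsv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(float))


@dataclass
class KinshipMatrix:
    """Symmetric genotype x genotype genomic relationship matrix."""

    genotypes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genotypes)
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square over the genotype list")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("kinship must be symmetric")

    def submatrix(self, genotype_ids: list[str]) -> "KinshipMatrix":
        idx = {g: i for i, g in enumerate(self.genotypes)}
        missing = [g for g in genotype_ids if g not in idx]
        if missing:
            raise KeyError(f"genotypes absent from kinship: {missing[:5]}")
        sel = [idx[g] for g in genotype_ids]
        return KinshipMatrix(list(genotype_ids), self.values[np.ix_(sel, sel)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.genotypes, columns=self.genotypes).to_csv(
            path, sep="\t", index_label="genotype"
        )

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float))


def filter_markers(
    markers: MarkerMatrix, maf_min: float = 0.03, max_missing: float = 0.5
) -> MarkerMatrix:
    """Drop markers with MAF below ``maf_min`` or too many missing dosages.

    A marker survives when min(p, 1-p) >= maf_min (so a MAF exactly at the
    threshold is retained) and its missing fraction is <= ``max_missing``.
    Genotype rows are never touched. Removing every marker emits
    :class:`EmptyMarkerWarning` rather than failing silently.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must lie in [0, 1]")
    maf = markers.minor_allele_freqs()
    miss = markers.missing_fractions()
    keep = (maf >= maf_min) & (miss <= max_missing)
    if not keep.any():
        warnings.warn(
            "all markers removed by MAF/missingness filtering", EmptyMarkerWarning
        )
    return MarkerMatrix(
        list(markers.genotypes),
        [m for m, k in zip(markers.markers, keep) if k],
        markers.dosages[:, keep],
    )


def impute_missing(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing dosages with the marker's non-missing mean."""
    dosages = markers.dosages.copy()
    fully_missing = np.isnan(dosages).all(axis=0)
    if fully_missing.any():
        bad = [m for m, f in zip(markers.markers, fully_missing) if f]
        raise ValueError(f"markers with no observed dosages: {bad[:5]}")
    col_means = np.nanmean(dosages, axis=0)
    idx = np.where(np.isnan(dosages))
    dosages[idx] = col_means[idx[1]]
    return MarkerMatrix(list(markers.genotypes), list(markers.markers), dosages)


def vanraden_grm(markers: MarkerMatrix, ridge: float = 1e-6) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from a complete dosage matrix.

    K = WW' / sum_k 2 p_k (1 - p_k) with W = dosages - 2 p (column
    centering) and p_k the observed allele frequency. A small ridge is
    added to the diagonal for numerical invertibility downstream.
    """
    if np.isnan(markers.dosages).any():
        raise ValueError("marker matrix has missing values; impute first")
    p = markers.allele_freqs()
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = markers.dosages - 2.0 * p[None, :]
    K = (W @ W.T) / denom
    K = (K + K.T) / 2.0
    K[np.diag_indices_from(K)] += ridge
    return KinshipMatrix(list(markers.genotypes), K)
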