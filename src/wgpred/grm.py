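"""Marker-based genomic relationship matrices.

Two estimators of realized genetic similarity are provided:

* method "Y" — per-marker standardized cross-products,

  off-diagonal  G_ij = (1/p) sum_l (x_il - 2 p_l)(x_jl - 2 p_l) / (2 p_l (1 - p_l)),
  diagonal      G_ii = 1 + (1/p) sum_l [x_il^2 - (1 + 2 p_l) x_il + 2 p_l^2]
                                        / (2 p_l (1 - p_l));

* method "H" — cross-products of centered genotypes scaled by a single
  constant,

  G = Z Z' / (2 sum_l p_l (1 - p_l)),    Z = X - 2 p.

Both are standardized so the average diagonal equals one, which puts the
additive variance parameters of models using either matrix on the same
scale.  Allele frequencies are estimated from the (post-imputation)
sample itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeMatrix


class MonomorphicMarkerError(ValueError):
    """A marker with p in {0, 1} reached the GRM; it belongs in QC."""


@dataclass
class GenomicRelationship:
    """Symmetric n x n realized-relationship matrix with its provenance."""

    ids: np.ndarray
    matrix: np.ndarray
    method: str
    n_markers_used: int
    mean_diagonal_prestandardization: float

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def submatrix(self, index: np.ndarray) -> np.ndarray:
        return self.matrix[np.ix_(index, index)]

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="individual_id"
        )

    @classmethod
    def from_tsv(cls, path: str, method: str = "unknown") -> "GenomicRelationship":
        df = pd.read_csv(path, sep="\t", index_col="individual_id")
        mat = df.to_numpy(dtype=float)
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise ValueError("relationship matrix on disk is not symmetric")
        return cls(df.index.to_numpy(dtype=object), mat, method,
                   n_markers_used=0, mean_diagonal_prestandardization=float(np.diag(mat).mean()))


def _checked_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    if genotypes.missing_mask.any():
        raise ValueError("GRM construction requires imputed (complete) genotypes")
    p = genotypes.allele_frequency()
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise MonomorphicMarkerError(
            "monomorphic marker in panel; run the MAF filter before building a GRM"
        )
    return p


def standardize_mean_diagonal(G: GenomicRelationship) -> GenomicRelationship:
    """Divide all entries by the mean diagonal so that it becomes one.

    Idempotent; raises on a non-positive mean diagonal (degenerate panel).
    """
    d = float(np.diag(G.matrix).mean())
    if d <= 0:
        raise ValueError("non-positive mean diagonal; degenerate relationship matrix")
    return GenomicRelationship(
        ids=G.ids,
        matrix=G.matrix / d,
        method=G.method,
        n_markers_used=G.n_markers_used,
        mean_diagonal_prestandardization=float(G.mean_diagonal_prestandardization),
    )


def build_grm_Y(genotypes: GenotypeMatrix) -> GenomicRelationship:
    """Per-marker standardized cross-product GRM with its dedicated diagonal
    estimator, then average-diagonal standardization."""
    p = _checked_frequencies(genotypes)
    X = genotypes.counts.astype(float)
    n, m = X.shape
    denom = 2.0 * p * (1.0 - p)
    Z = (X - 2.0 * p) / np.sqrt(denom)
    G = (Z @ Z.T) / m
    # diagonal uses the homozygosity-based estimator rather than the
    # squared self cross-product
    diag = 1.0 + ((X**2 - (1.0 + 2.0 * p) * X + 2.0 * p**2) / denom).mean(axis=1)
    np.fill_diagonal(G, diag)
    raw = GenomicRelationship(
        ids=genotypes.ids,
        matrix=0.5 * (G + G.T),
        method="Y",
        n_markers_used=m,
        mean_diagonal_prestandardization=float(diag.mean()),
    )
    return standardize_mean_diagonal(raw)


def build_grm_H(genotypes: GenotypeMatrix) -> GenomicRelationship:
    """Centered cross-product GRM with a single heterozygosity scaling,
    then average-diagonal standardization."""
    p = _checked_frequencies(genotypes)
    X = genotypes.counts.astype(float)
    Z = X - 2.0 * p
    scale = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / scale
    raw = GenomicRelationship(
        ids=genotypes.ids,
        matrix=0.5 * (G + G.T),
        method="H",
        n_markers_used=X.shape[1],
        mean_diagonal_prestandardization=float(np.diag(G).mean()),
    )
    return standardize_mean_diagonal(raw)


def build_grm(genotypes: GenotypeMatrix, method: str = "Y") -> GenomicRelationship:
    """Dispatch on method {"Y", "H"}."""
    if method == "Y":
        return build_grm_Y(genotypes)
    if method == "H":
        return build_grm_H(genotypes)
    raise ValueError(f"unknown GRM method {method!r}; expected 'Y' or 'H'")
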