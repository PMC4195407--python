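"""Relationship matrices: genomic (whole-genome or regional) and pedigree-based.

The genomic relationship matrix follows VanRaden's first method with
observed allele frequencies,

    G = Z Z' / (2 * sum_j p_j (1 - p_j)),

where Z is the genotype matrix column-centred by twice the allele
frequency.  A regional GRM is the same construction restricted to the
SNPs inside a window, with the denominator taken over the region's own
SNPs so that the regional variance component is scaled per region.

The pedigree numerator relationship matrix (NRM, the A matrix) is built
with the standard recursive tabular method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)

__all__ = ["RelationshipMatrix", "compute_grm", "compute_nrm"]


@dataclass
class RelationshipMatrix:
    """Symmetric covariance-structure matrix over a set of individuals."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # genomic_all | genomic_region | pedigree
    snp_count: int | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = self.ids.size
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix not symmetric")

    @property
    def n(self) -> int:
        return self.ids.size

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        idx = np.array([pos[v] for v in ids], dtype=int)
        return RelationshipMatrix(np.asarray(ids, dtype=object),
                                  self.values[np.ix_(idx, idx)],
                                  self.kind, self.snp_count)


def compute_grm(genotypes: GenotypeMatrix, snp_subset=None,
                kind: str | None = None) -> RelationshipMatrix:
    """VanRaden method-1 GRM from all SNPs or from a subset (regional GRM).

    Missing genotypes are mean-imputed per SNP before centring; monomorphic
    SNPs are dropped with a logged count.  ``snp_subset`` is an array of
    0-based column indices; ``kind`` defaults to ``genomic_all`` for the
    full panel and ``genomic_region`` for a subset.
    """
    if snp_subset is None:
        cols = np.arange(genotypes.n_snps)
        kind = kind or "genomic_all"
    else:
        cols = np.asarray(snp_subset, dtype=int)
        kind = kind or "genomic_region"
    M = genotypes.codes[:, cols].astype(float, copy=True)
    colmean = np.nanmean(M, axis=0)
    nan_mask = np.isnan(M)
    if nan_mask.any():
        M[nan_mask] = np.take(colmean, np.nonzero(nan_mask)[1])
    p = colmean / 2.0
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("compute_grm: dropped %d monomorphic SNPs", n_dropped)
    if not poly.any():
        raise ValueError("no informative markers: all SNPs monomorphic")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(genotypes.individual_ids, G, kind,
                              snp_count=int(poly.sum()))


def compute_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    Founders have diagonal 1 and mutual relationship 0; for individual i
    with parents s and d,

        a(i,i) = 1 + a(s,d)/2,    a(i,j) = (a(j,s) + a(j,d))/2  for j < i.

    The pedigree must be topologically ordered (guaranteed by
    :meth:`Pedigree.from_records`).
    """
    n = len(pedigree)
    pos = {v: i for i, v in enumerate(pedigree.individual_ids)}
    A = np.zeros((n, n))
    for i in range(n):
        s = pedigree.sire[i]
        d = pedigree.dam[i]
        si = pos[s] if s is not None else -1
        di = pos[d] if d is not None else -1
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += A[si, :i]
            if di >= 0:
                row += A[di, :i]
            A[i, :i] = A[:i, i] = 0.5 * row
        inb = 0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + inb
    return RelationshipMatrix(pedigree.individual_ids, A, "pedigree")
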