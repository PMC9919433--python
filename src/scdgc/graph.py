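"""Weighted gene adjacency and the symmetric-normalized propagation matrix.

The adjacency A is built over the *selected* genes from an interaction
edge list (weights are interaction probabilities in [0, 1]); its diagonal
is zero — a gene's self-interaction carries no information.  Every graph
convolution then uses the first-order propagation matrix

    P = D_hat^{-1/2} (A + I) D_hat^{-1/2},

where D_hat is the diagonal degree matrix of A + I.  Adding the identity
before computing degrees guarantees invertibility, so isolated genes are
well-defined (they reduce to a pure self-loop, P[i, i] = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import GeneInteractionTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneGraph:
    """Gene list + symmetric adjacency A (zero diagonal) + propagation P."""

    gene_ids: list[str]
    A: np.ndarray
    P: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def propagation_matrix(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization of the self-looped adjacency (see module doc)."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    if A.size and A.min() < 0:
        raise ValidationError("adjacency weights must be non-negative")
    if np.any(np.diag(A) != 0):
        raise ValidationError("adjacency diagonal must be zero")
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    assert np.all(d > 0), "degrees are positive after adding self-loops"
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


def build_adjacency(
    tbl: GeneInteractionTable,
    gene_ids: list[str],
    min_weight: float = 0.0,
) -> GeneGraph:
    """Assemble A over ``gene_ids`` from an edge list and derive P.

    Edges touching genes outside ``gene_ids`` are skipped (counted in the
    log); self-pairs are ignored so the diagonal stays zero; duplicate
    unordered pairs resolve to their maximum weight.  Genes without any
    interaction remain isolated nodes.
    """
    gene_ids = list(gene_ids)
    pos = {g: i for i, g in enumerate(gene_ids)}
    if len(pos) != len(gene_ids):
        raise ValidationError("gene_ids contain duplicates")
    tbl = tbl.deduplicated()
    M = len(gene_ids)
    A = np.zeros((M, M))
    skipped_outside = skipped_self = 0
    for a, b, w in zip(tbl.gene_a, tbl.gene_b, tbl.weight):
        if w < min_weight:
            continue
        if a not in pos or b not in pos:
            skipped_outside += 1
            continue
        if a == b:
            skipped_self += 1
            continue
        i, j = pos[a], pos[b]
        A[i, j] = A[j, i] = max(A[i, j], float(w))
    if skipped_outside or skipped_self:
        logger.info(
            "build_adjacency: skipped %d edges outside the gene set and %d self-pairs",
            skipped_outside, skipped_self,
        )
    return GeneGraph(gene_ids=gene_ids, A=A, P=propagation_matrix(A))
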