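"""Preprocessing: cell filtering, rare-gene filtering, log scaling, selection.

The pipeline is the standard one for supervised cell-type classification:

1. drop cells whose label marks them unusable (unlabeled / debris / doublet);
2. drop genes whose expression summed over all cells is below a threshold
   (default 5) — rarely expressed genes carry little class information;
3. transform counts to ``log2(1 + x)``;
4. rank genes by variance (or one-way ANOVA F across cell types) and keep
   the top *k* (default 1000).

The selector is *fitted* on one set of cells (normally the training split)
and *applied* to any matrix, which is what prevents information leaking
from validation/test cells into the feature choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import f_classif

from .data import CellAnnotation, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def filter_cells(
    X: ExpressionMatrix, ann: CellAnnotation
) -> tuple[ExpressionMatrix, CellAnnotation, int]:
    """Remove cells carrying invalid labels; returns the removed count."""
    if X.n_cells != ann.n_cells:
        raise ValidationError(
            f"expression has {X.n_cells} cells but annotation has {ann.n_cells}")
    keep = np.flatnonzero(ann.is_valid())
    removed = X.n_cells - keep.size
    if keep.size == 0:
        raise ValidationError("all cells carry invalid labels; empty dataset")
    if removed:
        logger.info("filter_cells: removed %d invalid-labeled cells", removed)
    return X.subset_cells(keep), ann.subset(keep), removed


def filter_genes(
    X: ExpressionMatrix, threshold: int = 5, mode: str = "total"
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove rarely expressed genes from a raw counts matrix.

    mode="total" (default): drop a gene iff its counts summed over all
    cells are < threshold.  mode="max": drop iff its per-cell maximum is
    < threshold (the stricter reading).  Returns the surviving matrix and
    the removed gene ids.
    """
    if X.stage != "raw":
        raise ValidationError(f"filter_genes expects stage 'raw', got {X.stage!r}")
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    if mode not in ("total", "max"):
        raise ValidationError(f"unknown gene-filter mode {mode!r}")
    stat = X.values.sum(axis=0) if mode == "total" else X.values.max(axis=0)
    keep = np.flatnonzero(stat >= threshold)
    removed = [X.gene_ids[i] for i in np.flatnonzero(stat < threshold)]
    if removed:
        logger.info("filter_genes: removed %d genes (%s < %d)", len(removed), mode, threshold)
    return X.subset_genes(keep), removed


def log_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log2(1 + x)``; stage becomes ``lognorm``."""
    if X.stage != "raw":
        raise ValidationError(f"log_normalize expects stage 'raw', got {X.stage!r}")
    if X.values.size and X.values.min() < 0:
        raise ValidationError("negative values cannot be log-normalized")
    return ExpressionMatrix(
        values=np.log2(1.0 + X.values.astype(np.float64)),
        cell_ids=X.cell_ids,
        gene_ids=X.gene_ids,
        stage="lognorm",
    )


@dataclass
class GeneSelector:
    """A fitted top-k gene ranking.

    ``ranked_genes`` is strictly ordered by (score descending, gene id
    ascending); ``fitted_on`` records the cells used for the fit so that
    leakage can be audited downstream.
    """

    method: str
    k: int
    ranked_genes: list[tuple[str, float]]
    fitted_on: frozenset[str]

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, _ in self.ranked_genes[: self.k]]


def fit_selector(
    X: ExpressionMatrix,
    ann: CellAnnotation | None = None,
    k: int = 1000,
    method: str = "variance",
) -> GeneSelector:
    """Rank genes by variance or one-way ANOVA F and keep the top ``k``.

    ``method="variance"`` needs no labels.  ``method="anova_f"`` scores each
    gene by the between-group / within-group mean-square ratio across cell
    types and requires at least two classes with two cells each.  Genes
    with zero variance score 0 under both methods.
    """
    if X.stage != "lognorm":
        raise ValidationError(f"fit_selector expects stage 'lognorm', got {X.stage!r}")
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if method == "variance":
        scores = np.var(X.values, axis=0, ddof=1) if X.n_cells > 1 else np.zeros(X.n_genes)
    elif method == "anova_f":
        if ann is None:
            raise ValidationError("anova_f requires cell-type labels")
        y = np.array(ann.labels)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValidationError("anova_f requires at least two cell types")
        if counts.min() < 2:
            raise ValidationError("anova_f requires >= 2 cells in every cell type")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant genes yield 0/0
            scores, _ = f_classif(X.values, y)
        constant = np.var(X.values, axis=0) == 0
        scores = np.where(constant | ~np.isfinite(scores), 0.0, scores)
        # a non-constant gene with zero within-class variance has an
        # infinite F statistic; rank it first with a large finite stand-in
        scores = np.where(np.isinf(scores), np.finfo(np.float64).max, scores)
    else:
        raise ValidationError(f"unknown selection method {method!r}")
    if k > X.n_genes:
        warnings.warn(
            f"k={k} exceeds the {X.n_genes} available genes; selecting all",
            stacklevel=2,
        )
    order = sorted(range(X.n_genes), key=lambda i: (-scores[i], X.gene_ids[i]))
    return GeneSelector(
        method=method,
        k=min(k, X.n_genes),
        ranked_genes=[(X.gene_ids[i], float(scores[i])) for i in order],
        fitted_on=frozenset(X.cell_ids),
    )


def apply_selector(sel: GeneSelector, X: ExpressionMatrix) -> ExpressionMatrix:
    """Restrict columns to the selector's top-k genes, in ranked order."""
    if X.stage != "lognorm":
        raise ValidationError(f"apply_selector expects stage 'lognorm', got {X.stage!r}")
    wanted = sel.selected_genes
    pos = {g: i for i, g in enumerate(X.gene_ids)}
    missing = [g for g in wanted if g not in pos]
    if missing:
        raise ValidationError(f"selected genes missing from matrix: {missing[:10]}")
    return X.subset_genes([pos[g] for g in wanted], stage="selected")


def preprocess_pipeline(
    X: ExpressionMatrix,
    ann: CellAnnotation,
    gene_filter_threshold: int = 5,
    gene_filter_mode: str = "total",
    top_k: int = 1000,
    select_method: str = "variance",
    selector: GeneSelector | None = None,
) -> tuple[ExpressionMatrix, CellAnnotation, GeneSelector]:
    """Full preprocessing chain; pass ``selector`` to reuse a fitted one."""
    X, ann, _ = filter_cells(X, ann)
    X, _ = filter_genes(X, threshold=gene_filter_threshold, mode=gene_filter_mode)
    X = log_normalize(X)
    if selector is None:
        selector = fit_selector(X, ann, k=top_k, method=select_method)
    X = apply_selector(selector, X)
    return X, ann, selector
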