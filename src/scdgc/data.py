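"""Core containers: expression matrices, cell annotations, interaction tables.

Everything downstream operates on a cells x genes orientation.  The
containers are thin dataclasses over numpy arrays with eager validation so
that malformed inputs fail at construction, not deep inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_INVALID_LABELS = frozenset({"unlabeled", "debris", "doublet"})

STAGES = ("raw", "lognorm", "selected")


class ValidationError(ValueError):
    """Raised when an input container violates its contract."""


def _check_unique(ids, kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {kind} ids: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with a processing-stage tag.

    Parameters
    ----------
    values
        Non-negative matrix, shape ``(n_cells, n_genes)``.  Integer counts
        at stage ``raw``; floats after log transformation.
    cell_ids, gene_ids
        Ordered unique identifiers matching the matrix axes.
    stage
        One of ``raw``, ``lognorm``, ``selected``.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    stage: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {self.values.shape}")
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise ValidationError(
                f"{n} rows but {len(self.cell_ids)} cell ids")
        if m != len(self.gene_ids):
            raise ValidationError(
                f"{m} columns but {len(self.gene_ids)} gene ids")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("expression values must be non-negative")
        if self.stage == "raw" and self.values.size:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("stage 'raw' requires integer counts")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
        )

    def subset_genes(self, idx, stage: str | None = None) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            stage=stage or self.stage,
        )


@dataclass
class CellAnnotation:
    """Per-cell labels aligned with an :class:`ExpressionMatrix`.

    ``vocabulary`` holds the valid cell-type names in a fixed order (this
    order defines class indices everywhere).  Labels in ``invalid_labels``
    (case-insensitive) mark cells to be dropped by the cell filter.
    """

    labels: list[str]
    vocabulary: list[str] | None = None
    invalid_labels: frozenset[str] = field(default_factory=lambda: DEFAULT_INVALID_LABELS)

    def __post_init__(self):
        self.labels = list(self.labels)
        self.invalid_labels = frozenset(s.lower() for s in self.invalid_labels)
        if self.vocabulary is None:
            valid = [l for l in self.labels if l.lower() not in self.invalid_labels]
            self.vocabulary = sorted(set(valid))
        else:
            self.vocabulary = list(self.vocabulary)
        _check_unique(self.vocabulary, "vocabulary")
        vocab = set(self.vocabulary)
        for lab in self.labels:
            if lab not in vocab and lab.lower() not in self.invalid_labels:
                raise ValidationError(
                    f"label {lab!r} is neither in the vocabulary nor invalid")

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def is_valid(self) -> np.ndarray:
        return np.array([l.lower() not in self.invalid_labels for l in self.labels])

    def class_indices(self) -> np.ndarray:
        """Integer class index per cell (valid labels only; -1 for invalid)."""
        lut = {name: i for i, name in enumerate(self.vocabulary)}
        return np.array([lut.get(l, -1) for l in self.labels])

    def subset(self, idx) -> "CellAnnotation":
        return CellAnnotation(
            labels=[self.labels[i] for i in np.asarray(idx)],
            vocabulary=self.vocabulary,
            invalid_labels=self.invalid_labels,
        )


@dataclass
class GeneInteractionTable:
    """Undirected weighted gene-gene interactions (STRING-style edge list).

    Pairs are unordered; duplicate pairs are resolved by keeping the
    maximum weight.  Self-pairs are allowed in the input but carry no
    information (the adjacency diagonal is forced to zero downstream).
    """

    gene_a: list[str]
    gene_b: list[str]
    weight: np.ndarray

    def __post_init__(self):
        self.gene_a = list(self.gene_a)
        self.gene_b = list(self.gene_b)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if not (len(self.gene_a) == len(self.gene_b) == len(self.weight)):
            raise ValidationError("interaction columns have unequal lengths")
        for row, w in enumerate(self.weight):
            if not (0.0 <= w <= 1.0):
                raise ValidationError(
                    f"interaction weight {w} out of [0, 1] at row {row}")

    def __len__(self) -> int:
        return len(self.weight)

    def deduplicated(self) -> "GeneInteractionTable":
        """Resolve unordered duplicate pairs by max weight (stable order)."""
        best: dict[tuple[str, str], float] = {}
        order: list[tuple[str, str]] = []
        for a, b, w in zip(self.gene_a, self.gene_b, self.weight):
            key = (a, b) if a <= b else (b, a)
            if key not in best:
                best[key] = float(w)
                order.append(key)
            else:
                best[key] = max(best[key], float(w))
        return GeneInteractionTable(
            gene_a=[k[0] for k in order],
            gene_b=[k[1] for k in order],
            weight=np.array([best[k] for k in order]),
        )

    def genes(self) -> set[str]:
        return set(self.gene_a) | set(self.gene_b)
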