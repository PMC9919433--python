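"""Readers and writers for the on-disk formats, plus checkpointing.

Conventions: tab-separated text is canonical (comma accepted on read);
dense expression matrices are cells-in-rows with a gene-id header and the
cell id in the first column; sparse matrices use MatrixMarket coordinate
files in the genes-in-rows convention with ``genes.tsv``/``barcodes.tsv``
sidecars (indices are 1-based per the MatrixMarket standard).  Checkpoints
are a directory of ``.npy`` tensors plus a JSON manifest, which makes the
save -> load -> forward round trip bit-identical and the files themselves
reproducible byte-for-byte across runs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .data import CellAnnotation, ExpressionMatrix, GeneInteractionTable, ValidationError
from .model import ModelConfig


def _sniff_sep(path: Path) -> str:
    first = Path(path).open().readline()
    return "\t" if "\t" in first else ","


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path, stage: str = "raw") -> ExpressionMatrix:
    path = Path(path)
    sep = _sniff_sep(path)
    header = path.open().readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):   # pandas would mangle these to g.1
        raise ValidationError(f"{path}: duplicate gene ids in header")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate cell ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric expression values")
    if values.size and values.min() < 0:
        raise ValidationError(f"{path}: negative expression values")
    return ExpressionMatrix(
        values=values,
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
        stage=stage,
    )


def write_expression_tsv(X: ExpressionMatrix, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids).to_csv(
        path, sep="\t", index_label="cell_id")


def read_expression_mtx(mtx_path, stage: str = "raw") -> ExpressionMatrix:
    """MatrixMarket triplets (genes x cells) with genes.tsv/barcodes.tsv."""
    mtx_path = Path(mtx_path)
    genes = [l.split("\t")[0].strip() for l in
             (mtx_path.parent / "genes.tsv").read_text().splitlines() if l.strip()]
    cells = [l.strip() for l in
             (mtx_path.parent / "barcodes.tsv").read_text().splitlines() if l.strip()]
    _validate_mtx_indices(mtx_path, n_rows=len(genes), n_cols=len(cells))
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    if mat.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"{mtx_path}: matrix is {mat.shape} but sidecars give "
            f"{len(genes)} genes x {len(cells)} cells")
    return ExpressionMatrix(
        values=np.asarray(mat).T,  # cells x genes in memory
        cell_ids=cells,
        gene_ids=genes,
        stage=stage,
    )


def _validate_mtx_indices(path: Path, n_rows: int, n_cols: int) -> None:
    """Enforce the standard's 1-based coordinate indexing with line numbers."""
    body = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("%") or not line.strip():
                continue
            if not body:   # the size line
                body = True
                continue
            i, j = (int(tok) for tok in line.split()[:2])
            if not (1 <= i <= n_rows and 1 <= j <= n_cols):
                raise ValidationError(
                    f"{path}:{lineno}: coordinate ({i}, {j}) outside the "
                    f"1-based range 1..{n_rows} x 1..{n_cols}")


def write_expression_mtx(X: ExpressionMatrix, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mtx_path = out_dir / "matrix.mtx"
    scipy.io.mmwrite(mtx_path, scipy.sparse.coo_matrix(X.values.T))
    (out_dir / "genes.tsv").write_text("".join(f"{g}\n" for g in X.gene_ids))
    (out_dir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in X.cell_ids))
    return mtx_path


# ---------------------------------------------------------------------------
# labels and interactions
# ---------------------------------------------------------------------------

def write_labels(cell_ids: list[str], labels: list[str], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("cell_id\tlabel\n")
        for c, l in zip(cell_ids, labels):
            fh.write(f"{c}\t{l}\n")


def read_labels(path) -> tuple[list[str], list[str]]:
    """Two-column (cell_id, label) TSV, optional header; returns both columns."""
    path = Path(path)
    cells, labels = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t" if "\t" in line else ",")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in ("cell_id", "cell", "barcode"):
                continue
            cells.append(parts[0])
            labels.append(parts[1])
    return cells, labels


def align_annotation(
    X: ExpressionMatrix,
    cell_ids: list[str],
    labels: list[str],
    vocabulary: list[str] | None = None,
) -> CellAnnotation:
    """Order labels to match X's cells; missing cells are an error."""
    lut = dict(zip(cell_ids, labels))
    missing = [c for c in X.cell_ids if c not in lut]
    if missing:
        raise ValidationError(f"cells without labels: {missing[:5]}")
    return CellAnnotation(labels=[lut[c] for c in X.cell_ids], vocabulary=vocabulary)


def write_interactions(tbl: GeneInteractionTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in zip(tbl.gene_a, tbl.gene_b, tbl.weight):
            fh.write(f"{a}\t{b}\t{float(w)!r}\n")


def read_interactions(path, score_scale: float = 1.0) -> GeneInteractionTable:
    """Three-column (gene_a, gene_b, weight) TSV; STRING 0-1000 scores can
    be rescaled with ``score_scale=1000``."""
    path = Path(path)
    ga, gb, w = [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t" if "\t" in line else ",")
            if len(parts) != 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1 and parts[2].lower() in ("weight", "score", "combined_score"):
                continue
            try:
                weight = float(parts[2]) / score_scale
            except ValueError as err:
                raise ValidationError(
                    f"{path}:{lineno}: unparseable weight {parts[2]!r}") from err
            if not (0.0 <= weight <= 1.0):
                raise ValidationError(
                    f"{path}:{lineno}: weight {weight} outside [0, 1]")
            ga.append(parts[0])
            gb.append(parts[1])
            w.append(weight)
    return GeneInteractionTable(gene_a=ga, gene_b=gb, weight=np.array(w))


# ---------------------------------------------------------------------------
# reports, history, configs
# ---------------------------------------------------------------------------

def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_history(history: list[dict], path) -> None:
    cols = ["epoch", "lr", "l_fnn", "l_fr", "l_vat", "total", "val_accuracy"]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in history:
            cells = []
            for c in cols:
                v = rec.get(c)
                cells.append("" if v is None else repr(float(v)) if isinstance(v, float) else str(v))
            fh.write("\t".join(cells) + "\n")


def write_config_echo(cfg: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    out_dir,
    params: dict[str, np.ndarray],
    model_cfg: ModelConfig,
    gene_ids: list[str],
    vocabulary: list[str],
) -> None:
    out_dir = Path(out_dir)
    (out_dir / "params").mkdir(parents=True, exist_ok=True)
    manifest = {
        "model_config": dataclasses.asdict(model_cfg),
        "genes": list(gene_ids),
        "classes": list(vocabulary),
        "params": sorted(params),
    }
    write_json(manifest, out_dir / "manifest.json")
    for name, value in params.items():
        np.save(out_dir / "params" / f"{name}.npy", np.asarray(value))


def load_checkpoint(out_dir) -> tuple[dict[str, np.ndarray], ModelConfig, list[str], list[str]]:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    cfg = ModelConfig(**manifest["model_config"])
    params = {
        name: np.load(out_dir / "params" / f"{name}.npy")
        for name in manifest["params"]
    }
    return params, cfg, manifest["genes"], manifest["classes"]
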