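"""Losses, virtual adversarial training, dataset splitting and the SGD loop.

The training objective combines three terms,

    L = L_FNN + lambda1 * L_FR + lambda2 * L_VAT,

with L_FNN the classification cross-entropy, L_FR the mean-squared error
of the decoder reconstruction, and L_VAT the virtual-adversarial
smoothness penalty: the KL divergence between the clean predictive
distribution (held fixed) and the prediction at the input shifted by the
worst-case perturbation inside an epsilon-ball, located by power
iteration.  Batch reductions are means, so the lambda weights do not
depend on the batch size; ``loss_reduction="sum"`` restores plain batch
sums.

Ablation variants are pure configuration states: ``novat`` drops L_VAT,
``nofr`` drops L_FR, and ``nodc`` is the model-config switch that removes
dense connectivity — there are no code forks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .data import CellAnnotation, ExpressionMatrix, ValidationError
from .model import ModelConfig, VatConfig, forward, init_parameters, is_bias

logger = logging.getLogger(__name__)

VARIANTS = ("full", "novat", "nodc", "nofr")

_P_FLOOR = 1e-12


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference setup)."""

    lr: float = 0.01
    l2: float = 5e-4
    batch_size: int = 128
    epochs: int = 100
    eval_every: int = 10
    decay_factor: float = 0.5
    decay_every: int = 30
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    variant: str = "full"
    loss_reduction: str = "mean"

    def __post_init__(self):
        for name in ("lr", "batch_size", "epochs", "eval_every", "decay_every"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.l2 < 0:
            raise ValidationError("l2 must be >= 0")
        if abs(sum(self.split) - 1.0) > 1e-9 or any(s < 0 for s in self.split):
            raise ValidationError("split fractions must be non-negative and sum to 1")
        if self.variant not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}")
        if self.loss_reduction not in ("mean", "sum"):
            raise ValidationError("loss_reduction must be 'mean' or 'sum'")


@dataclass
class LossBundle:
    """Loss components of one batch; ``total`` obeys the weighted-sum identity."""

    l_fnn: float
    l_fr: float
    l_vat: float
    total: float
    r_vat: np.ndarray | None = None


# ---------------------------------------------------------------------------
# losses (plain-array versions used for reporting and in tests)
# ---------------------------------------------------------------------------

def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 2:
        return y.astype(np.float64)
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


def cross_entropy_loss(p: np.ndarray, y_true: np.ndarray,
                       reduction: str = "mean") -> float:
    """Mean (or sum) over the batch of -sum_j y_ij log p_ij, with a 1e-12 floor."""
    p = np.asarray(p, dtype=np.float64)
    y = one_hot(y_true, p.shape[1])
    if y.shape != p.shape:
        raise ValidationError(f"shape mismatch: p {p.shape} vs labels {y.shape}")
    per_cell = -(y * np.log(np.maximum(p, _P_FLOOR))).sum(axis=1)
    return float(per_cell.sum() if reduction == "sum" else per_cell.mean())


def reconstruction_loss(X: np.ndarray, x_hat: np.ndarray,
                        reduction: str = "mean") -> float:
    """Elementwise mean squared error (or per-cell squared-distance sum)."""
    X, x_hat = np.asarray(X, dtype=np.float64), np.asarray(x_hat, dtype=np.float64)
    if X.shape != x_hat.shape:
        raise ValidationError(f"shape mismatch: X {X.shape} vs x_hat {x_hat.shape}")
    sq = (X - x_hat) ** 2
    return float(sq.sum() if reduction == "sum" else sq.mean())


def kl_divergence(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise KL(p || q) with both arguments floored at 1e-12."""
    p = np.maximum(np.asarray(p, dtype=np.float64), _P_FLOOR)
    q = np.maximum(np.asarray(q, dtype=np.float64), _P_FLOOR)
    return (p * (np.log(p) - np.log(q))).sum(axis=1)


def total_loss(l_fnn: float, l_fr: float, l_vat: float,
               lambda1: float = 1.0, lambda2: float = 0.1,
               variant: str = "full") -> float:
    """Weighted combination; ablated variants contribute zero for their term."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValidationError("lambda weights must be >= 0")
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    if variant == "novat":
        l_vat = 0.0
    if variant == "nofr":
        l_fr = 0.0
    return float(l_fnn + lambda1 * l_fr + lambda2 * l_vat)


# ---------------------------------------------------------------------------
# graph-building loss helpers (used inside the SGD step)
# ---------------------------------------------------------------------------

def _ce_graph(logp: Tensor, y_oh: np.ndarray, reduction: str) -> Tensor:
    per_cell = ad.mul(ad.sum_(ad.mul(Tensor(y_oh), logp), axis=1), -1.0)
    return ad.sum_(per_cell) if reduction == "sum" else ad.mean(per_cell)


def _fr_graph(X: np.ndarray, x_hat: Tensor, reduction: str) -> Tensor:
    sq = ad.square(ad.add(x_hat, -X))
    return ad.sum_(sq) if reduction == "sum" else ad.mean(sq)


def _kl_graph(p_clean: np.ndarray, logp_pert: Tensor) -> Tensor:
    """Mean over the batch of KL(p_clean || p_pert); p_clean is constant."""
    p_c = np.maximum(p_clean, _P_FLOOR)
    log_p_c = np.log(p_c)
    per_cell = ad.sum_(ad.mul(Tensor(p_c), ad.add(Tensor(log_p_c), ad.mul(logp_pert, -1.0))), axis=1)
    return ad.mean(per_cell)


def _normalize_rows(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale each row to unit L2 norm; zero rows stay zero."""
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    ok = norms[:, 0] > 0
    out = np.zeros_like(r)
    out[ok] = r[ok] / norms[ok]
    return out, ok


# ---------------------------------------------------------------------------
# virtual adversarial training
# ---------------------------------------------------------------------------

def vat_perturbation(
    X: np.ndarray,
    P: np.ndarray,
    params: dict,
    cfg: ModelConfig,
    vat: VatConfig,
    rng: np.random.Generator,
    p_clean: np.ndarray | None = None,
) -> np.ndarray:
    """Worst-case perturbation direction scaled to norm ``epsilon`` per cell.

    Starts from a unit-normalized Gaussian draw and runs ``ip`` power
    iterations: differentiate KL(p_clean || p(x + xi * r)) with respect to
    r and re-normalize.  Returns epsilon * r; rows where the gradient
    vanishes (locally flat model) come back as zeros.
    """
    X = np.asarray(X, dtype=np.float64)
    if vat.epsilon == 0.0:
        return np.zeros_like(X)
    const_params = {k: np.asarray(v.data if isinstance(v, Tensor) else v)
                    for k, v in params.items()}
    if p_clean is None:
        p_clean = forward(X, P, const_params, cfg).p.data
    r, _ = _normalize_rows(rng.standard_normal(X.shape))
    for _ in range(vat.ip):
        r_t = Tensor(r, requires_grad=True)
        x_pert = ad.add(Tensor(X), ad.mul(r_t, vat.xi))
        out = forward(x_pert, P, const_params, cfg)
        _kl_graph(p_clean, out.logp).backward()
        grad = r_t.grad if r_t.grad is not None else np.zeros_like(r)
        r, ok = _normalize_rows(grad)
        if not ok.all():
            logger.debug("vat_perturbation: %d cells with vanishing KL gradient",
                         int((~ok).sum()))
    return vat.epsilon * r


def vat_loss(
    X: np.ndarray,
    P: np.ndarray,
    params: dict,
    cfg: ModelConfig,
    vat: VatConfig,
    rng: np.random.Generator,
) -> float:
    """Mean KL between clean predictions and predictions at x + lambda*r_vat."""
    return float(_vat_loss_graph(np.asarray(X, float), P, params, cfg, vat, rng)[0].data)


def _vat_loss_graph(X, P, params, cfg, vat, rng) -> tuple[Tensor, np.ndarray]:
    const_params = {k: np.asarray(v.data if isinstance(v, Tensor) else v)
                    for k, v in params.items()}
    p_clean = forward(X, P, const_params, cfg).p.data
    r_vat = vat_perturbation(X, P, const_params, cfg, vat, rng, p_clean=p_clean)
    if not r_vat.any():
        return Tensor(0.0), r_vat
    out = forward(ad.add(Tensor(X), Tensor(vat.lds_lambda * r_vat)), P, params, cfg)
    return _kl_graph(p_clean, out.logp), r_vat


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_indices(
    labels: list[str],
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/val/test indices with largest-remainder rounding.

    Cells of each class are shuffled (seeded) and partitioned so every
    class honors the requested proportions as closely as integers allow.
    Classes with fewer than 3 cells go entirely to the training split
    (with a warning).
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    labels_arr = np.array(labels)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(labels_arr == cls)
        idx = idx[rng.permutation(idx.size)]
        if idx.size < 3:
            warnings.warn(
                f"class {cls!r} has only {idx.size} cells; assigning all to train",
                stacklevel=2,
            )
            parts[0].extend(idx.tolist())
            continue
        raw = np.array(split) * idx.size
        sizes = np.floor(raw).astype(int)
        # largest remainder; ties favor train > val > test (stable argsort)
        for j in np.argsort(-(raw - sizes), kind="stable")[: idx.size - sizes.sum()]:
            sizes[j] += 1
        bounds = np.cumsum(sizes)
        parts[0].extend(idx[: bounds[0]].tolist())
        parts[1].extend(idx[bounds[0]: bounds[1]].tolist())
        parts[2].extend(idx[bounds[1]: bounds[2]].tolist())
    return tuple(np.array(sorted(p), dtype=int) for p in parts)


def split_dataset(
    X: ExpressionMatrix,
    ann: CellAnnotation,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
):
    """Stratified (train, val, test) triples of (ExpressionMatrix, CellAnnotation)."""
    tr, va, te = split_indices(ann.labels, split=split, seed=seed)
    return (
        (X.subset_cells(tr), ann.subset(tr)),
        (X.subset_cells(va), ann.subset(va)),
        (X.subset_cells(te), ann.subset(te)),
    )


# ---------------------------------------------------------------------------
# the SGD loop
# ---------------------------------------------------------------------------

def compute_batch_loss(
    X_batch: np.ndarray,
    y_batch: np.ndarray,
    P: np.ndarray,
    params: dict[str, Tensor],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[Tensor, LossBundle]:
    """Build the loss graph for one batch and return (total tensor, bundle)."""
    out = forward(X_batch, P, params, model_cfg)
    y_oh = one_hot(y_batch, model_cfg.n_classes)
    l_fnn_t = _ce_graph(out.logp, y_oh, cfg.loss_reduction)
    terms = [l_fnn_t]
    l_fr = l_vat = 0.0
    r_vat = None
    if cfg.variant != "nofr" and model_cfg.lambda1 > 0:
        l_fr_t = _fr_graph(X_batch, out.x_hat, cfg.loss_reduction)
        terms.append(ad.mul(l_fr_t, model_cfg.lambda1))
        l_fr = float(l_fr_t.data)
    if cfg.variant != "novat" and model_cfg.lambda2 > 0:
        l_vat_t, r_vat = _vat_loss_graph(
            X_batch, P, params, model_cfg, model_cfg.vat, rng)
        terms.append(ad.mul(l_vat_t, model_cfg.lambda2))
        l_vat = float(l_vat_t.data)
    total_t = terms[0]
    for t in terms[1:]:
        total_t = ad.add(total_t, t)
    bundle = LossBundle(
        l_fnn=float(l_fnn_t.data), l_fr=l_fr, l_vat=l_vat,
        total=float(total_t.data), r_vat=r_vat,
    )
    return total_t, bundle


def train(
    dataset: tuple[ExpressionMatrix, CellAnnotation],
    graph_P: np.ndarray,
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    val_dataset: tuple[ExpressionMatrix, CellAnnotation] | None = None,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Mini-batch SGD with weight decay and step learning-rate decay.

    ``dataset`` is the (already preprocessed, gene-selected) training
    split.  Returns the final parameters and a per-epoch history of loss
    components (validation accuracy appended every ``eval_every`` epochs
    when a validation set is given).  Fully deterministic given the seeds.
    """
    X_all, ann = dataset
    if model_cfg.n_genes != X_all.n_genes:
        raise ValidationError(
            f"model expects {model_cfg.n_genes} genes, data has {X_all.n_genes}")
    y_all = ann.class_indices()
    if (y_all < 0).any():
        raise ValidationError("training data contains invalid-labeled cells")
    if cfg.variant == "nodc" and model_cfg.dense_connectivity:
        raise ValidationError(
            "variant 'nodc' requires ModelConfig(dense_connectivity=False)")
    params_np = init_parameters(model_cfg)
    rng = np.random.default_rng(cfg.seed)
    n = X_all.n_cells
    batch = min(cfg.batch_size, n)
    history: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        lr = cfg.lr * cfg.decay_factor ** ((epoch - 1) // cfg.decay_every)
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, batch):
            idx = order[start: start + batch]
            params_t = {k: Tensor(v, requires_grad=True) for k, v in params_np.items()}
            total_t, bundle = compute_batch_loss(
                X_all.values[idx], y_all[idx], graph_P, params_t,
                model_cfg, cfg, rng)
            if not np.isfinite(bundle.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {bundle}")
            total_t.backward()
            for name, t in params_t.items():
                g = t.grad if t.grad is not None else np.zeros_like(t.data)
                if cfg.l2 > 0 and not is_bias(name):
                    g = g + cfg.l2 * params_np[name]
                params_np[name] = params_np[name] - lr * g
            sums += (bundle.l_fnn, bundle.l_fr, bundle.l_vat, bundle.total)
            n_batches += 1
        rec = {
            "epoch": epoch,
            "lr": lr,
            "l_fnn": sums[0] / n_batches,
            "l_fr": sums[1] / n_batches,
            "l_vat": sums[2] / n_batches,
            "total": sums[3] / n_batches,
        }
        if val_dataset is not None and epoch % cfg.eval_every == 0:
            rec["val_accuracy"] = evaluate_accuracy(
                params_np, model_cfg, graph_P, val_dataset)
        history.append(rec)
        logger.info(
            "epoch %d: l_fnn=%.4f l_fr=%.4f l_vat=%.4f total=%.4f%s",
            epoch, rec["l_fnn"], rec["l_fr"], rec["l_vat"], rec["total"],
            f" val_acc={rec['val_accuracy']:.4f}" if "val_accuracy" in rec else "",
        )
    return params_np, history


def evaluate_accuracy(
    params: dict[str, np.ndarray],
    model_cfg: ModelConfig,
    P: np.ndarray,
    dataset: tuple[ExpressionMatrix, CellAnnotation],
) -> float:
    X, ann = dataset
    p = forward(X.values, P, params, model_cfg).p.data
    return float((p.argmax(axis=1) == ann.class_indices()).mean())
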