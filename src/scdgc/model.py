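"""The hybrid adversarially trainable dense graph convolutional classifier.

Architecture, for a batch X (B x M log-expression rows) and propagation
matrix P (M x M):

* **Channel lift.**  H0[b, m, :] = X[b, m] * w_lift + b_lift — a learned
  1x1 projection from the single expression channel to ``conv_channels``.
* **Densely connected graph convolutions.**  Layer k = 1..K receives an
  attention-weighted sum of *all* previous representations,
  ``Hin = sum_u beta_u H_u`` (softmax weights from a per-layer scorer),
  then applies the first-order spectral convolution
  ``H_k = ReLU(P . Hin . W_k + b_k)``.
* **Attention aggregation.**  A final scorer weights H_0..H_K into
  ``Hout = ReLU(sum_u alpha_u H_u)``.  Each scorer computes a scalar score
  per layer from its mean-pooled channel vector: ``s_u = w2 . ReLU(W1 v_u)``
  with ``v_u = mean over batch and genes of H_u``.
* **Graph head.**  Max-pool over channels (B x M), then a dense layer +
  ReLU to a ``latent_dim`` embedding ``z_graph``.
* **Fully connected branch.**  ``z_fnn = ReLU(W2 ReLU(W1 X))`` with hidden
  width ``fnn_hidden`` and output width ``latent_dim`` — global, receptive-
  field-free features complementing the graph branch.
* **Decoder.**  Two dense layers map the flattened Hout back to an M-wide
  reconstruction ``x_hat`` (auxiliary loss).
* **Classifier.**  ``p = softmax(W [z_graph ; z_fnn] + b)``.

With ``dense_connectivity=False`` (the NoDC ablation) each convolution
reads only its predecessor and the final layer is used directly as Hout —
no attention parameters exist in that configuration.

All parameters are Xavier-uniform initialized from a seeded generator;
biases start at zero.  The forward pass is pure (no dropout/noise), so it
is deterministic given the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, as_tensor
from .data import ValidationError


@dataclass
class VatConfig:
    """Virtual adversarial training knobs.

    epsilon — L2 radius of the adversarial perturbation per cell;
    xi — finite-difference scale used inside the power iteration;
    ip — number of power iterations locating the worst-case direction;
    lds_lambda — multiplier on the perturbation inside the smoothness loss.
    """

    epsilon: float = 1.0
    xi: float = 1e-6
    ip: int = 1
    lds_lambda: float = 1.0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValidationError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.xi <= 0:
            raise ValidationError(f"xi must be > 0, got {self.xi}")
        if self.ip < 1:
            raise ValidationError(f"ip must be >= 1, got {self.ip}")


@dataclass
class ModelConfig:
    """Hyperparameters of the network (defaults follow the reference setup)."""

    n_genes: int
    n_classes: int
    n_conv_layers: int = 4
    conv_channels: int = 5
    fnn_hidden: int = 256
    latent_dim: int = 32
    decoder_hidden: int = 256
    dense_connectivity: bool = True
    lambda1: float = 1.0
    lambda2: float = 0.1
    vat: VatConfig = field(default_factory=VatConfig)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_classes", "n_conv_layers", "conv_channels",
                     "fnn_hidden", "latent_dim", "decoder_hidden"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("loss weights lambda1/lambda2 must be >= 0")
        if isinstance(self.vat, dict):
            self.vat = VatConfig(**self.vat)


@dataclass
class ForwardOutputs:
    """All intermediates of one forward pass (autodiff tensors)."""

    H: list[Tensor]                 # H_0..H_K, each B x M x channels
    block_alphas: dict[int, np.ndarray]  # per-conv-layer attention weights
    alpha: np.ndarray               # final aggregation weights over H_0..H_K
    Hout: Tensor                    # B x M x channels
    z_graph: Tensor                 # B x latent_dim
    z_fnn: Tensor                   # B x latent_dim
    logits: Tensor                  # B x C
    logp: Tensor                    # B x C log class probabilities
    p: Tensor                       # B x C class probabilities
    x_hat: Tensor                   # B x M reconstruction


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _xavier(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    if len(shape) == 1:          # vector scorers: fan_out of 1
        fan_in, fan_out = shape[0], 1
    else:
        fan_in, fan_out = shape[0], shape[1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def parameter_shapes(cfg: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Named tensor shapes in their fixed initialization order."""
    c, M, K = cfg.conv_channels, cfg.n_genes, cfg.n_conv_layers
    shapes: dict[str, tuple[int, ...]] = {"lift_w": (1, c), "lift_b": (c,)}
    for k in range(1, K + 1):
        if cfg.dense_connectivity and k >= 2:
            shapes[f"att{k}_w1"] = (c, c)
            shapes[f"att{k}_w2"] = (c,)
        shapes[f"conv{k}_w"] = (c, c)
        shapes[f"conv{k}_b"] = (c,)
    if cfg.dense_connectivity:
        shapes["agg_w1"] = (c, c)
        shapes["agg_w2"] = (c,)
    shapes.update({
        "pool_w": (M, cfg.latent_dim), "pool_b": (cfg.latent_dim,),
        "fnn1_w": (M, cfg.fnn_hidden), "fnn1_b": (cfg.fnn_hidden,),
        "fnn2_w": (cfg.fnn_hidden, cfg.latent_dim), "fnn2_b": (cfg.latent_dim,),
        "dec1_w": (M * c, cfg.decoder_hidden), "dec1_b": (cfg.decoder_hidden,),
        "dec2_w": (cfg.decoder_hidden, M), "dec2_b": (M,),
        "head_w": (2 * cfg.latent_dim, cfg.n_classes), "head_b": (cfg.n_classes,),
    })
    return shapes


def init_parameters(cfg: ModelConfig) -> dict[str, np.ndarray]:
    """Xavier-uniform weights / zero biases, from a generator seeded by cfg."""
    rng = np.random.default_rng(cfg.seed)
    params: dict[str, np.ndarray] = {}
    for name, shape in parameter_shapes(cfg).items():
        if name.endswith("_b"):
            params[name] = np.zeros(shape)
        else:
            params[name] = _xavier(rng, shape)
    return params


def is_bias(name: str) -> bool:
    return name.endswith("_b")


# ---------------------------------------------------------------------------
# forward-pass building blocks
# ---------------------------------------------------------------------------

def graph_conv(H_in, P: np.ndarray, W, b) -> Tensor:
    """One first-order spectral convolution: ReLU(P . H . W + b)."""
    H_in = as_tensor(H_in)
    if H_in.ndim != 3:
        raise ValidationError(f"H_in must be batch x genes x channels, got {H_in.shape}")
    if P.shape[0] != P.shape[1] or P.shape[0] != H_in.shape[1]:
        raise ValidationError(
            f"propagation matrix {P.shape} does not match gene axis {H_in.shape[1]}")
    W = as_tensor(W)
    if W.shape[0] != H_in.shape[2]:
        raise ValidationError(
            f"W input channels {W.shape[0]} do not match H channels {H_in.shape[2]}")
    return ad.relu(ad.channel_affine(ad.propagate(P, H_in), W, b))


def attention_scores(H: list[Tensor], W1, w2) -> Tensor:
    """Scalar score per layer from its mean-pooled channel vector."""
    if not H:
        raise ValidationError("attention over an empty layer list")
    scores = []
    for H_u in H:
        v = ad.mean(H_u, axis=(0, 1))                     # channel vector
        scores.append(ad.dot(w2, ad.relu(ad.matvec(W1, v))))
    return ad.stack_scalars(scores)


def attention_aggregate(H: list[Tensor], W1, w2) -> tuple[Tensor, Tensor]:
    """Softmax-weighted sum of layer representations: Hout, alpha."""
    alpha = ad.softmax1d(attention_scores(H, W1, w2))
    return ad.relu(weighted_sum(H, alpha)), alpha


def weighted_sum(H: list[Tensor], alpha: Tensor) -> Tensor:
    out = ad.mul(ad.index(alpha, 0), H[0])
    for u in range(1, len(H)):
        out = ad.add(out, ad.mul(ad.index(alpha, u), H[u]))
    return out


def dense_forward(
    X, P: np.ndarray, params: dict, cfg: ModelConfig
) -> tuple[list[Tensor], dict[int, np.ndarray]]:
    """Channel lift + K (densely connected) graph convolutions."""
    X = as_tensor(X)
    B, M = X.shape
    x3 = ad.reshape(X, (B, M, 1))
    H = [ad.channel_affine(x3, params["lift_w"], params["lift_b"])]
    block_alphas: dict[int, np.ndarray] = {}
    for k in range(1, cfg.n_conv_layers + 1):
        if cfg.dense_connectivity and k >= 2:
            beta = ad.softmax1d(
                attention_scores(H, params[f"att{k}_w1"], params[f"att{k}_w2"]))
            block_alphas[k] = beta.data.copy()
            H_in = weighted_sum(H, beta)
        else:
            H_in = H[-1]
        H.append(graph_conv(H_in, P, params[f"conv{k}_w"], params[f"conv{k}_b"]))
    return H, block_alphas


def pool_project(Hout, params: dict) -> Tensor:
    """Max over channels, then dense + ReLU to the latent embedding."""
    pooled = ad.max_axis(as_tensor(Hout), axis=2)          # B x M
    return ad.relu(ad.affine(pooled, params["pool_w"], params["pool_b"]))


def fnn_forward(X, params: dict) -> Tensor:
    """The fully connected branch: affine-ReLU-affine-ReLU."""
    h = ad.relu(ad.affine(as_tensor(X), params["fnn1_w"], params["fnn1_b"]))
    return ad.relu(ad.affine(h, params["fnn2_w"], params["fnn2_b"]))


def decode(Hout, params: dict) -> Tensor:
    """Two-layer decoder mapping the aggregated representation back to M genes."""
    Hout = as_tensor(Hout)
    B = Hout.shape[0]
    flat = ad.reshape(Hout, (B, -1))
    h = ad.relu(ad.affine(flat, params["dec1_w"], params["dec1_b"]))
    return ad.affine(h, params["dec2_w"], params["dec2_b"])


def classify(z_graph, z_fnn, params: dict) -> tuple[Tensor, Tensor, Tensor]:
    """Concatenate branch embeddings, dense layer, softmax: logits, logp, p."""
    logits = ad.affine(ad.concat([as_tensor(z_graph), as_tensor(z_fnn)], axis=1),
                       params["head_w"], params["head_b"])
    logp = ad.log_softmax(logits)
    return logits, logp, ad.exp(logp)


def forward(X, P: np.ndarray, params: dict, cfg: ModelConfig) -> ForwardOutputs:
    """Full forward pass; ``X`` may be a numpy array or a Tensor (for VAT)."""
    X = as_tensor(X)
    tensor_params = {
        name: (value if isinstance(value, Tensor) else Tensor(value))
        for name, value in params.items()
    }
    H, block_alphas = dense_forward(X, P, tensor_params, cfg)
    if cfg.dense_connectivity:
        Hout, alpha_t = attention_aggregate(
            H, tensor_params["agg_w1"], tensor_params["agg_w2"])
        alpha = alpha_t.data.copy()
    else:
        Hout = H[-1]
        alpha = np.eye(len(H))[-1]
    z_graph = pool_project(Hout, tensor_params)
    z_fnn = fnn_forward(X, tensor_params)
    x_hat = decode(Hout, tensor_params)
    logits, logp, p = classify(z_graph, z_fnn, tensor_params)
    return ForwardOutputs(
        H=H, block_alphas=block_alphas, alpha=alpha, Hout=Hout,
        z_graph=z_graph, z_fnn=z_fnn, logits=logits, logp=logp, p=p,
        x_hat=x_hat,
    )


def predict_proba(X: np.ndarray, P: np.ndarray, params: dict, cfg: ModelConfig) -> np.ndarray:
    """Class probabilities as a plain array (no gradient bookkeeping)."""
    return forward(X, P, params, cfg).p.data
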