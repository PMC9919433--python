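"""Independent straight-line reimplementation of the forward pass.

Everything here is written with explicit Python loops and shares no code
with the package; it exists solely as an oracle for equivalence tests.
"""

import math

import numpy as np


def ref_relu(x):
    return x if x > 0 else 0.0


def ref_softmax(v):
    m = max(v)
    e = [math.exp(x - m) for x in v]
    s = sum(e)
    return [x / s for x in e]


def ref_scores(H_list, W1, w2):
    """Per-layer scalar attention scores from mean-pooled channel vectors."""
    scores = []
    for H in H_list:
        B, M, C = H.shape
        v = [0.0] * C
        for b in range(B):
            for m in range(M):
                for c in range(C):
                    v[c] += H[b, m, c]
        v = [x / (B * M) for x in v]
        s = 0.0
        for c in range(C):
            acc = 0.0
            for d in range(C):
                acc += W1[c, d] * v[d]
            s += w2[c] * ref_relu(acc)
        scores.append(s)
    return scores


def ref_conv(H_in, P, W, bias):
    B, M, C_in = H_in.shape
    C_out = W.shape[1]
    out = np.zeros((B, M, C_out))
    for b in range(B):
        for i in range(M):
            for o in range(C_out):
                acc = 0.0
                for c in range(C_in):
                    prop = 0.0
                    for j in range(M):
                        prop += P[i, j] * H_in[b, j, c]
                    acc += prop * W[c, o]
                out[b, i, o] = ref_relu(acc + bias[o])
    return out


def ref_forward(X, P, params, cfg):
    """Full forward pass by loops; returns a dict of intermediates."""
    B, M = X.shape
    C = cfg.conv_channels
    K = cfg.n_conv_layers

    H0 = np.zeros((B, M, C))
    for b in range(B):
        for m in range(M):
            for c in range(C):
                H0[b, m, c] = X[b, m] * params["lift_w"][0, c] + params["lift_b"][c]
    H = [H0]
    block_alphas = {}
    for k in range(1, K + 1):
        if cfg.dense_connectivity and k >= 2:
            beta = ref_softmax(
                ref_scores(H, params[f"att{k}_w1"], params[f"att{k}_w2"]))
            block_alphas[k] = np.array(beta)
            H_in = np.zeros_like(H[0])
            for u, Hu in enumerate(H):
                H_in = H_in + beta[u] * Hu
        else:
            H_in = H[-1]
        H.append(ref_conv(H_in, P, params[f"conv{k}_w"], params[f"conv{k}_b"]))

    if cfg.dense_connectivity:
        alpha = ref_softmax(ref_scores(H, params["agg_w1"], params["agg_w2"]))
        Hout = np.zeros_like(H[0])
        for u, Hu in enumerate(H):
            Hout = Hout + alpha[u] * Hu
        for b in range(B):
            for m in range(M):
                for c in range(C):
                    Hout[b, m, c] = ref_relu(Hout[b, m, c])
        alpha = np.array(alpha)
    else:
        Hout = H[-1]
        alpha = np.zeros(K + 1)
        alpha[-1] = 1.0

    # channel max pool + projection
    pooled = np.zeros((B, M))
    for b in range(B):
        for m in range(M):
            pooled[b, m] = max(Hout[b, m, c] for c in range(C))
    z_graph = np.zeros((B, cfg.latent_dim))
    for b in range(B):
        for o in range(cfg.latent_dim):
            acc = params["pool_b"][o]
            for m in range(M):
                acc += pooled[b, m] * params["pool_w"][m, o]
            z_graph[b, o] = ref_relu(acc)

    # fully connected branch
    h1 = np.zeros((B, cfg.fnn_hidden))
    for b in range(B):
        for o in range(cfg.fnn_hidden):
            acc = params["fnn1_b"][o]
            for m in range(M):
                acc += X[b, m] * params["fnn1_w"][m, o]
            h1[b, o] = ref_relu(acc)
    z_fnn = np.zeros((B, cfg.latent_dim))
    for b in range(B):
        for o in range(cfg.latent_dim):
            acc = params["fnn2_b"][o]
            for m in range(cfg.fnn_hidden):
                acc += h1[b, m] * params["fnn2_w"][m, o]
            z_fnn[b, o] = ref_relu(acc)

    # decoder on the flattened (row-major) Hout
    flat = np.zeros((B, M * C))
    for b in range(B):
        for m in range(M):
            for c in range(C):
                flat[b, m * C + c] = Hout[b, m, c]
    d1 = np.zeros((B, cfg.decoder_hidden))
    for b in range(B):
        for o in range(cfg.decoder_hidden):
            acc = params["dec1_b"][o]
            for m in range(M * C):
                acc += flat[b, m] * params["dec1_w"][m, o]
            d1[b, o] = ref_relu(acc)
    x_hat = np.zeros((B, M))
    for b in range(B):
        for o in range(M):
            acc = params["dec2_b"][o]
            for m in range(cfg.decoder_hidden):
                acc += d1[b, m] * params["dec2_w"][m, o]
            x_hat[b, o] = acc

    # classifier head on [z_graph ; z_fnn]
    logits = np.zeros((B, cfg.n_classes))
    for b in range(B):
        z = list(z_graph[b]) + list(z_fnn[b])
        for o in range(cfg.n_classes):
            acc = params["head_b"][o]
            for m in range(2 * cfg.latent_dim):
                acc += z[m] * params["head_w"][m, o]
            logits[b, o] = acc
    p = np.array([ref_softmax(list(row)) for row in logits])

    return {
        "H": H, "block_alphas": block_alphas, "alpha": alpha, "Hout": Hout,
        "z_graph": z_graph, "z_fnn": z_fnn, "logits": logits, "p": p,
        "x_hat": x_hat,
    }


def ref_anova_f(values, labels):
    """Textbook one-way ANOVA F per gene: between-group MS / within-group MS."""
    groups = sorted(set(labels))
    n, m = values.shape
    F = np.zeros(m)
    for g in range(m):
        col = values[:, g]
        grand = sum(col) / n
        ss_between = 0.0
        ss_within = 0.0
        for cls in groups:
            sub = [col[i] for i in range(n) if labels[i] == cls]
            mu = sum(sub) / len(sub)
            ss_between += len(sub) * (mu - grand) ** 2
            ss_within += sum((x - mu) ** 2 for x in sub)
        df_b = len(groups) - 1
        df_w = n - len(groups)
        if ss_within == 0.0:
            F[g] = 0.0 if ss_between == 0.0 else np.inf
        else:
            F[g] = (ss_between / df_b) / (ss_within / df_w)
    return F


def ref_auc(y_bin, scores):
    """Pair-counting AUC: (concordant + 0.5 * ties) / (pos * neg)."""
    pos = [s for s, y in zip(scores, y_bin) if y]
    neg = [s for s, y in zip(scores, y_bin) if not y]
    num = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                num += 1.0
            elif sp == sn:
                num += 0.5
    return num / (len(pos) * len(neg))
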