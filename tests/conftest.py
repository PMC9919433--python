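import numpy as np
import pytest

import scdgc
from scdgc.training import TrainConfig, evaluate_accuracy, split_dataset, train

# Reference study condition: 600 cells x 120 genes, 4 balanced well-separated
# types (mean_shift 2.5, dropout 0.2), top-100 gene selection, 100-epoch SGD.
STUDY_TOP_K = 100
NOISE_SIGMA = 0.5
STUDY_SEEDS = (1, 2, 3, 4, 5)


def build_study_dataset(seed: int, **spec_overrides):
    spec = scdgc.SyntheticSpec(seed=seed, **spec_overrides)
    X, ann, tbl, truth = scdgc.generate_dataset(spec)
    Xp, annp, sel = scdgc.preprocess_pipeline(X, ann, top_k=STUDY_TOP_K)
    gg = scdgc.build_adjacency(tbl, Xp.gene_ids)
    return Xp, annp, gg, truth


def run_study(seed: int, variant: str = "full") -> dict:
    """Train one model under the reference condition; report test accuracies."""
    Xp, annp, gg, _ = build_study_dataset(seed)
    train_set, val_set, test_set = split_dataset(Xp, annp, seed=seed)
    mcfg = scdgc.ModelConfig(
        n_genes=Xp.n_genes,
        n_classes=len(annp.vocabulary),
        dense_connectivity=variant != "nodc",
        seed=seed,
    )
    tcfg = TrainConfig(seed=seed, variant=variant)
    params, history = train(train_set, gg.P, tcfg, mcfg, val_dataset=val_set)
    X_te, ann_te = test_set
    y = ann_te.class_indices()
    p_clean = scdgc.forward(X_te.values, gg.P, params, mcfg).p.data
    noise = np.random.default_rng(7000 + seed).normal(
        0.0, NOISE_SIGMA, X_te.values.shape)
    p_noisy = scdgc.forward(X_te.values + noise, gg.P, params, mcfg).p.data
    return {
        "seed": seed,
        "variant": variant,
        "params": params,
        "history": history,
        "test_accuracy": float((p_clean.argmax(1) == y).mean()),
        "noisy_test_accuracy": float((p_noisy.argmax(1) == y).mean()),
    }


@pytest.fixture(scope="session")
def study_runs():
    """Full and NoVAT models trained under the reference condition, 5 seeds each."""
    return {
        "full": [run_study(s, "full") for s in STUDY_SEEDS],
        "novat": [run_study(s, "novat") for s in STUDY_SEEDS],
    }


@pytest.fixture
def fixture_dataset():
    return scdgc.worked_fixture()


@pytest.fixture
def tiny_trained():
    """A small, quick end-to-end training run shared by a few tests."""
    spec = scdgc.SyntheticSpec(n_cells=80, n_genes=20, n_types=2, n_modules=2,
                               seed=11)
    X, ann, tbl, _ = scdgc.generate_dataset(spec)
    Xp, annp, _ = scdgc.preprocess_pipeline(X, ann, top_k=20)
    gg = scdgc.build_adjacency(tbl, Xp.gene_ids)
    tr, va, te = split_dataset(Xp, annp, seed=11)
    mcfg = scdgc.ModelConfig(n_genes=Xp.n_genes, n_classes=2, fnn_hidden=16,
                             latent_dim=8, decoder_hidden=16, seed=11)
    tcfg = TrainConfig(seed=11, epochs=5, eval_every=5)
    params, history = train(tr, gg.P, tcfg, mcfg, val_dataset=va)
    return dict(params=params, history=history, mcfg=mcfg, tcfg=tcfg,
                gg=gg, splits=(tr, va, te))
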