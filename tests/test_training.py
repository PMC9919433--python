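"""Losses, VAT, splitting and the SGD loop against closed forms and oracles."""

import numpy as np
import pytest

import scdgc
from scdgc import _autodiff as ad
from scdgc.data import CellAnnotation, ExpressionMatrix, ValidationError
from scdgc.model import ModelConfig, VatConfig, forward, init_parameters
from scdgc.training import (
    TrainConfig,
    compute_batch_loss,
    cross_entropy_loss,
    kl_divergence,
    reconstruction_loss,
    split_indices,
    total_loss,
    train,
    vat_loss,
    vat_perturbation,
)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        p = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(p, np.array([0, 1])) == pytest.approx(0.0)

    def test_uniform_four_class_is_ln4(self):
        p = np.full((3, 4), 0.25)
        assert cross_entropy_loss(p, np.array([0, 1, 2])) == pytest.approx(
            np.log(4), abs=1e-9)

    def test_matches_explicit_summation_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=8)
        y = rng.integers(0, 3, size=8)
        oracle = sum(-np.log(p[i, y[i]]) for i in range(8)) / 8
        assert cross_entropy_loss(p, y) == pytest.approx(oracle, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cross_entropy_loss(np.ones((2, 3)) / 3, np.ones((3, 3)))


class TestReconstruction:
    def test_zero_iff_equal(self):
        X = np.random.default_rng(1).random((3, 4))
        assert reconstruction_loss(X, X) == 0.0
        assert reconstruction_loss(X, X + 0.1) > 0

    def test_single_element_difference_two_gives_four(self):
        assert reconstruction_loss(np.array([[1.0]]), np.array([[3.0]])) == 4.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        X, Xh = rng.random((4, 3)), rng.random((4, 3))
        oracle = sum((X[i, j] - Xh[i, j]) ** 2 for i in range(4) for j in range(3)) / 12
        assert reconstruction_loss(X, Xh) == pytest.approx(oracle, abs=1e-12)


class TestTotalLoss:
    def test_reference_weights_arithmetic(self):
        assert total_loss(0.9, 0.3, 0.5, 1.0, 0.1) == pytest.approx(1.25)

    def test_novat_is_independent_of_lvat(self):
        assert total_loss(1.0, 0.5, 99.0, variant="novat") == total_loss(
            1.0, 0.5, 0.0, variant="novat")

    def test_zero_lambdas_leave_classification_loss(self):
        assert total_loss(0.7, 5.0, 5.0, 0.0, 0.0) == pytest.approx(0.7)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError):
            total_loss(1.0, 1.0, 1.0, -1.0, 0.1)


def toy_model(seed=0, n_genes=2, **kw):
    cfg = ModelConfig(n_genes=n_genes, n_classes=2, n_conv_layers=2,
                      conv_channels=3, fnn_hidden=8, latent_dim=4,
                      decoder_hidden=6, seed=seed, **kw)
    return cfg, init_parameters(cfg), np.eye(n_genes)


class TestVat:
    def test_zero_epsilon_gives_zero_perturbation_and_loss(self):
        cfg, params, P = toy_model()
        X = np.random.default_rng(3).random((4, 2))
        vat = VatConfig(epsilon=0.0)
        rng = np.random.default_rng(0)
        assert not vat_perturbation(X, P, params, cfg, vat, rng).any()
        assert vat_loss(X, P, params, cfg, vat, rng) == 0.0

    def test_input_constant_model_gives_zero_perturbation(self):
        cfg, params, P = toy_model()
        params = {k: np.zeros_like(v) for k, v in params.items()}
        X = np.random.default_rng(4).random((3, 2))
        r = vat_perturbation(X, P, params, cfg, VatConfig(), np.random.default_rng(0))
        assert not r.any()

    def test_perturbation_norm_is_epsilon(self):
        cfg, params, P = toy_model(seed=5)
        X = np.random.default_rng(5).random((6, 2)) * 3
        vat = VatConfig(epsilon=2.5)
        r = vat_perturbation(X, P, params, cfg, vat, np.random.default_rng(1))
        norms = np.linalg.norm(r, axis=1)
        nz = norms > 0
        np.testing.assert_allclose(norms[nz], 2.5, atol=1e-9)

    def test_vat_loss_nonnegative_on_random_instances(self):
        rng = np.random.default_rng(6)
        for i in range(20):
            cfg, params, P = toy_model(seed=100 + i, n_genes=3)
            X = rng.random((3, 3)) * 2
            assert vat_loss(X, P, params, cfg, VatConfig(), rng) >= 0.0

    def test_vat_loss_matches_explicit_kl_oracle(self):
        cfg, params, P = toy_model(seed=7)
        X = np.random.default_rng(7).random((4, 2)) * 2
        vat = VatConfig(epsilon=0.8)
        r = vat_perturbation(X, P, params, cfg, vat, np.random.default_rng(3))
        p0 = forward(X, P, params, cfg).p.data
        p1 = forward(X + vat.lds_lambda * r, P, params, cfg).p.data
        oracle = float(np.mean([
            sum(p0[i, j] * (np.log(p0[i, j]) - np.log(p1[i, j]))
                for j in range(2)) for i in range(4)
        ]))
        got = vat_loss(X, P, params, cfg, vat, np.random.default_rng(3))
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_kl_invariant_under_class_relabeling(self):
        rng = np.random.default_rng(8)
        p = rng.dirichlet(np.ones(4), size=5)
        q = rng.dirichlet(np.ones(4), size=5)
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(
            kl_divergence(p, q), kl_divergence(p[:, perm], q[:, perm]), atol=1e-12)


class TestSplit:
    def test_balanced_two_class_hundred_cells(self):
        labels = ["a"] * 50 + ["b"] * 50
        tr, va, te = split_indices(labels, seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_deterministic_and_partitioning(self):
        labels = ["a"] * 33 + ["b"] * 41 + ["c"] * 26
        s1 = split_indices(labels, seed=5)
        s2 = split_indices(labels, seed=5)
        for x, y in zip(s1, s2):
            np.testing.assert_array_equal(x, y)
        allidx = np.concatenate(s1)
        assert sorted(allidx) == list(range(100))

    def test_per_class_train_fraction_within_one_cell(self):
        labels = ["a"] * 50 + ["b"] * 60 + ["c"] * 40
        tr, _, _ = split_indices(labels, seed=1)
        arr = np.array(labels)
        for cls, n in (("a", 50), ("b", 60), ("c", 40)):
            n_train = (arr[tr] == cls).sum()
            assert abs(n_train - 0.8 * n) <= 1

    def test_tiny_class_goes_to_train_with_warning(self):
        labels = ["a"] * 20 + ["b"] * 2
        with pytest.warns(UserWarning, match="'b'"):
            tr, va, te = split_indices(labels)
        arr = np.array(labels)
        assert (arr[tr] == "b").sum() == 2


def tiny_dataset(seed=11):
    spec = scdgc.SyntheticSpec(n_cells=60, n_genes=12, n_types=2, n_modules=2,
                               seed=seed)
    X, ann, tbl, _ = scdgc.generate_dataset(spec)
    Xp, annp, _ = scdgc.preprocess_pipeline(X, ann, top_k=12)
    gg = scdgc.build_adjacency(tbl, Xp.gene_ids)
    return Xp, annp, gg


def tiny_model_cfg(Xp, annp, seed=11, **kw):
    return ModelConfig(n_genes=Xp.n_genes, n_classes=len(annp.vocabulary),
                       fnn_hidden=8, latent_dim=4, decoder_hidden=8,
                       seed=seed, **kw)


class TestLossBundle:
    @pytest.mark.parametrize("variant", ["full", "novat", "nofr", "nodc"])
    def test_total_identity_holds_per_batch(self, variant):
        Xp, annp, gg = tiny_dataset()
        mcfg = tiny_model_cfg(Xp, annp,
                              dense_connectivity=variant != "nodc")
        tcfg = TrainConfig(seed=1, variant=variant, epochs=1)
        params = {k: ad.Tensor(v, requires_grad=True)
                  for k, v in init_parameters(mcfg).items()}
        _, bundle = compute_batch_loss(
            Xp.values[:16], annp.class_indices()[:16], gg.P, params,
            mcfg, tcfg, np.random.default_rng(0))
        lam1 = mcfg.lambda1 if variant != "nofr" else 0.0
        lam2 = mcfg.lambda2 if variant != "novat" else 0.0
        assert bundle.total == pytest.approx(
            bundle.l_fnn + lam1 * bundle.l_fr + lam2 * bundle.l_vat, abs=1e-9)
        if variant == "novat":
            assert bundle.l_vat == 0.0
        if variant == "nofr":
            assert bundle.l_fr == 0.0


class TestTrain:
    def test_same_seed_reproduces_parameters_and_history(self):
        Xp, annp, gg = tiny_dataset()
        mcfg = tiny_model_cfg(Xp, annp)
        tcfg = TrainConfig(seed=2, epochs=3, batch_size=32)
        p1, h1 = train((Xp, annp), gg.P, tcfg, mcfg)
        p2, h2 = train((Xp, annp), gg.P, tcfg, mcfg)
        assert h1 == h2
        for k in p1:
            np.testing.assert_array_equal(p1[k], p2[k])

    def test_vanishing_learning_rate_freezes_parameters(self):
        Xp, annp, gg = tiny_dataset()
        mcfg = tiny_model_cfg(Xp, annp)
        tcfg = TrainConfig(seed=2, epochs=1, lr=1e-15, l2=0.0)
        init = init_parameters(mcfg)
        params, _ = train((Xp, annp), gg.P, tcfg, mcfg)
        for k in params:
            np.testing.assert_allclose(params[k], init[k], atol=1e-10)

    def test_training_reduces_classification_loss(self):
        Xp, annp, gg = tiny_dataset()
        mcfg = tiny_model_cfg(Xp, annp)
        tcfg = TrainConfig(seed=3, epochs=15, eval_every=5)
        _, history = train((Xp, annp), gg.P, tcfg, mcfg)
        assert history[-1]["l_fnn"] < history[0]["l_fnn"]

    def test_learning_rate_decays_by_half_every_thirty_epochs(self):
        Xp, annp, gg = tiny_dataset()
        mcfg = tiny_model_cfg(Xp, annp)
        tcfg = TrainConfig(seed=4, epochs=31, variant="novat")
        _, history = train((Xp, annp), gg.P, tcfg, mcfg)
        assert history[0]["lr"] == pytest.approx(0.01)
        assert history[29]["lr"] == pytest.approx(0.01)
        assert history[30]["lr"] == pytest.approx(0.005)

    def test_validation_logged_at_eval_interval(self):
        Xp, annp, gg = tiny_dataset()
        mcfg = tiny_model_cfg(Xp, annp)
        tcfg = TrainConfig(seed=5, epochs=10, eval_every=5, variant="novat")
        _, history = train((Xp, annp), gg.P, tcfg, mcfg, val_dataset=(Xp, annp))
        logged = [r["epoch"] for r in history if "val_accuracy" in r]
        assert logged == [5, 10]

    def test_nodc_variant_requires_matching_model_config(self):
        Xp, annp, gg = tiny_dataset()
        mcfg = tiny_model_cfg(Xp, annp)  # dense_connectivity=True
        with pytest.raises(ValidationError, match="nodc"):
            train((Xp, annp), gg.P, TrainConfig(variant="nodc", epochs=1), mcfg)
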