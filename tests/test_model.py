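import warnings

import numpy as np
import pytest
import scipy.sparse as sp

import spatialfuse as sf
from spatialfuse.containers import NeighborGraph

from conftest import make_fusion_inputs


def dense_gcn_oracle(A, X, Ws):
    """Step-by-step dense evaluation of the propagation rule."""
    Z = np.asarray(X, float)
    A = np.asarray(A, float)
    for i, W in enumerate(Ws):
        Z = A @ (Z @ W)
        if i < len(Ws) - 1:
            Z = np.maximum(Z, 0.0)
    return Z


def random_graph(n, k, seed):
    rng = np.random.default_rng(seed)
    coords = sf.SpotCoordinates(rng.uniform(0, 10, (n, 2)), [f"s{i}" for i in range(n)])
    return sf.normalize_adjacency(sf.build_spatial_graph(coords, k))


def one_node_graph():
    """Single spot with a self loop; normalized operator is the 1x1 identity."""
    eye = sp.identity(1, format="csr")
    zero = sp.csr_matrix((1, 1))
    return NeighborGraph(adjacency=zero, knn=zero, k=0, kind="spatial",
                         normalized_form=eye)


class TestEncoderDecoder:
    def test_zeros_propagate_to_zeros(self):
        g = random_graph(8, 2, 0)
        rng = np.random.default_rng(1)
        Ws = [rng.standard_normal(s) for s in [(5, 4), (4, 3), (3, 3)]]
        out = sf.encoder_forward(np.zeros((8, 5)), g, Ws)
        np.testing.assert_array_equal(out, 0.0)

    def test_identity_chain_on_one_node(self):
        g = one_node_graph()
        x = np.array([[0.3, 1.7]])
        Ws = [np.eye(2)] * 3
        np.testing.assert_allclose(sf.encoder_forward(x, g, Ws), x, atol=1e-15)
        np.testing.assert_allclose(sf.decoder_forward(x, g, Ws), x, atol=1e-15)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        g = random_graph(n, 2, seed + 100)
        d_in, h, latent = 5, 4, 3
        Ws = [rng.standard_normal(s) * 0.7 for s in [(d_in, h), (h, latent), (latent, latent)]]
        X = rng.standard_normal((n, d_in))
        ours = sf.encoder_forward(X, g, Ws)
        oracle = dense_gcn_oracle(g.normalized_form.toarray(), X, Ws)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_shape_mismatch_named(self):
        g = random_graph(6, 2, 2)
        Ws = [np.eye(4)]
        with pytest.raises(sf.ValidationError, match="width 3 != weight rows 4"):
            sf.encoder_forward(np.zeros((6, 3)), g, Ws)

    def test_row_count_mismatch(self):
        g = random_graph(6, 2, 3)
        with pytest.raises(sf.ValidationError, match="rows but graph"):
            sf.encoder_forward(np.zeros((5, 3)), g, [np.eye(3)])


class TestAttention:
    def test_identical_inputs_give_uniform_weights(self):
        rng = np.random.default_rng(0)
        R = rng.standard_normal((7, 4))
        res = sf.attention_fuse([R, R], rng.standard_normal((4, 4)),
                                rng.standard_normal((4, 1)))
        np.testing.assert_allclose(res.weights, 0.5, atol=1e-12)
        np.testing.assert_allclose(res.fused, R, atol=1e-12)

    def test_three_identical_inputs(self):
        rng = np.random.default_rng(1)
        R = rng.standard_normal((5, 3))
        res = sf.attention_fuse([R, R, R], rng.standard_normal((3, 3)),
                                rng.standard_normal((3, 1)))
        np.testing.assert_allclose(res.weights, 1.0 / 3, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        R1 = np.array([[1.0, 0.0], [0.5, -1.0]])
        R2 = np.array([[0.0, 2.0], [1.0, 1.0]])
        W = np.array([[0.3, -0.2], [0.1, 0.4]])
        mu = np.array([[0.7], [-0.5]])
        eps = 1e-8
        s1 = np.tanh(R1 @ W) @ mu + eps
        s2 = np.tanh(R2 @ W) @ mu + eps
        S = np.hstack([s1, s2])
        e = np.exp(S - S.max(axis=1, keepdims=True))
        alpha = e / e.sum(axis=1, keepdims=True)
        fused = alpha[:, :1] * R1 + alpha[:, 1:] * R2
        res = sf.attention_fuse([R1, R2], W, mu, epsilon=eps)
        np.testing.assert_allclose(res.weights, alpha, atol=1e-12)
        np.testing.assert_allclose(res.fused, fused, atol=1e-12)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(2)
        inputs = [rng.standard_normal((9, 5)) * 3 for _ in range(4)]
        res = sf.attention_fuse(inputs, rng.standard_normal((5, 5)),
                                rng.standard_normal((5, 1)))
        assert (res.weights >= 0).all()
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("eps", [1e-10, 1e-2])
    def test_epsilon_invariance(self, eps):
        rng = np.random.default_rng(3)
        inputs = [rng.standard_normal((6, 4)) for _ in range(2)]
        W, mu = rng.standard_normal((4, 4)), rng.standard_normal((4, 1))
        ref = sf.attention_fuse(inputs, W, mu, epsilon=1e-8)
        other = sf.attention_fuse(inputs, W, mu, epsilon=eps)
        np.testing.assert_allclose(ref.weights, other.weights, atol=1e-12)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(sf.ValidationError, match="disagree"):
            sf.attention_fuse([np.zeros((3, 2)), np.zeros((4, 2))],
                              np.eye(2), np.zeros((2, 1)))


class TestForwardPass:
    def test_zero_llm_embedding_still_runs(self, small_inputs):
        data = sf.FusionInputs(
            emb_llm=np.zeros_like(small_inputs.emb_llm),
            emb_omics1=small_inputs.emb_omics1,
            emb_omics2=small_inputs.emb_omics2,
            g_spatial=small_inputs.g_spatial,
            g_llm=small_inputs.g_llm,
            g_omics1=small_inputs.g_omics1,
            g_omics2=small_inputs.g_omics2,
        )
        params = sf.init_params(data.emb_llm.shape[1], data.emb_omics1.shape[1],
                                data.emb_omics2.shape[1], hidden_dims=(8,),
                                latent_dim=6, seed=0)
        ls = sf.forward_pass(params, data)
        np.testing.assert_array_equal(ls.R_fs, 0.0)
        np.testing.assert_array_equal(ls.R_fe, 0.0)
        assert np.all(np.isfinite(ls.Emb_final))

    def test_shapes_and_weight_sets(self, small_inputs):
        params = sf.init_params(6, 5, 4, hidden_dims=(8,), latent_dim=6, seed=1)
        ls = sf.forward_pass(params, small_inputs)
        n = small_inputs.n_spots
        for name in ("R_fs", "R_fe", "R_os1", "R_oe1", "R_os2", "R_oe2",
                     "EA_s", "EA_e", "EA_1", "EA_2", "Emb_final"):
            assert getattr(ls, name).shape == (n, 6), name
        assert set(ls.attention_weights) == {"s", "e", "1", "2", "final"}
        for res in ls.attention_weights.values():
            np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-6)

    def test_llm_branch_is_the_only_difference_in_controlled_setup(self):
        """With both omics identical (data, graphs, weights) and a zero LLM
        embedding, the omics-2 branch reproduces its encoder output exactly
        while the omics-1 branch is diluted by the zero LLM latent."""
        base = make_fusion_inputs(n=12, d_f=5, d1=5, d2=5, seed=7)
        g = base.g_spatial
        data = sf.FusionInputs(
            emb_llm=np.zeros((12, 5)),
            emb_omics1=base.emb_omics1,
            emb_omics2=base.emb_omics1,
            g_spatial=g, g_llm=g, g_omics1=g, g_omics2=g,
        )
        params = sf.init_params(5, 5, 5, hidden_dims=(6,), latent_dim=4, seed=2)
        for name in list(params.tensors):
            if name.startswith("enc_o1_"):
                twin = name.replace("enc_o1_", "enc_o2_")
                params.tensors[twin].data = params.tensors[name].data.copy()
        ls = sf.forward_pass(params, data)
        np.testing.assert_allclose(ls.R_os1, ls.R_os2, atol=1e-12)
        # omics-2 view fuses two identical inputs -> identity
        np.testing.assert_allclose(ls.EA_2, ls.R_os2, atol=1e-12)
        # LLM view: fused latent is the omics latent scaled by its attention weight
        w_omics = ls.attention_weights["s"].weights[:, 1:2]
        np.testing.assert_allclose(ls.EA_s, w_omics * ls.R_os1, atol=1e-12)


class TestLosses:
    def _identity_setup(self, d=3):
        g = one_node_graph()
        x = np.array([[0.5, 1.0, 2.0]])
        data = sf.FusionInputs(emb_llm=x, emb_omics1=x, emb_omics2=x,
                               g_spatial=g, g_llm=g, g_omics1=g, g_omics2=g)
        params = sf.init_params(d, d, d, hidden_dims=(d, d), latent_dim=d, seed=0)
        for name, t in params.tensors.items():
            if "_W" in name and name.startswith(("enc", "dec")):
                t.data = np.eye(d)
        return data, params

    def test_perfect_autoencoder_has_zero_reconstruction(self):
        data, params = self._identity_setup()
        report = sf.compute_losses(params, data, sf.LossConfig())
        for term in ("L_rec_1", "L_rec_2", "L_rec_fs", "L_rec_fe",
                     "L_cor_1", "L_cor_2"):
            assert getattr(report, term) == pytest.approx(0.0, abs=1e-18), term
        assert report.total == pytest.approx(0.0, abs=1e-18)

    def test_mse_formula_single_row(self):
        from spatialfuse import autodiff as ad

        out = ad.mse(ad.constant(np.array([[1.0, 0.0]])),
                     ad.constant(np.array([[0.0, 0.0]])))
        assert out.item() == pytest.approx(1.0, abs=1e-15)

    def test_weighted_sum_contract(self, small_inputs):
        params = sf.init_params(6, 5, 4, hidden_dims=(8,), latent_dim=6, seed=3)
        cfg = sf.LossConfig(alpha1=2.0, alpha2=0.0, alpha3=0.0, alpha4=0.0,
                            beta1=0.0, beta2=0.0)
        report = sf.compute_losses(params, small_inputs, cfg)
        assert report.total == pytest.approx(2.0 * report.L_rec_1, abs=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(sf.ValidationError):
            sf.LossConfig(alpha1=0, alpha2=0, alpha3=0, alpha4=0, beta1=0, beta2=0)

    def test_total_equals_weighted_sum_every_epoch(self, small_inputs):
        cfg = sf.LossConfig(alpha1=1.5, alpha2=0.5, alpha3=2.0, alpha4=1.0,
                            beta1=0.7, beta2=0.3, epochs=15, seed=4)
        _, _, history = sf.train(small_inputs, cfg, hidden_dims=(8,), latent_dim=6)
        for rep in history:
            expected = (cfg.alpha1 * rep.L_rec_1 + cfg.alpha2 * rep.L_rec_2
                        + cfg.alpha3 * rep.L_rec_fs + cfg.alpha4 * rep.L_rec_fe
                        + cfg.beta1 * rep.L_cor_1 + cfg.beta2 * rep.L_cor_2)
            assert rep.total == pytest.approx(expected, abs=1e-9)


class TestTraining:
    def test_loss_decreases_on_synthetic_fixture(self, trained_small_model):
        history = trained_small_model.loss_history_
        assert history[-1].total < history[0].total

    def test_same_seed_same_loss(self, small_inputs):
        cfg = sf.LossConfig(epochs=10, seed=5)
        _, _, h1 = sf.train(small_inputs, cfg, hidden_dims=(8,), latent_dim=6)
        _, _, h2 = sf.train(small_inputs, cfg, hidden_dims=(8,), latent_dim=6)
        assert abs(h1[-1].total - h2[-1].total) < 1e-6

    def test_zero_epochs_returns_init(self, small_inputs):
        params, ls, history = sf.train(
            small_inputs, sf.LossConfig(epochs=0, seed=6), hidden_dims=(8,), latent_dim=6
        )
        assert history == []
        ref = sf.init_params(6, 5, 4, hidden_dims=(8,), latent_dim=6, seed=6)
        for k in ref.tensors:
            np.testing.assert_array_equal(params.tensors[k].data, ref.tensors[k].data)
        assert ls.Emb_final.shape == (small_inputs.n_spots, 6)

    def test_zero_embedding_training_is_healthy(self):
        data = make_fusion_inputs(n=12, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            zero = sf.FusionInputs(
                emb_llm=np.zeros_like(data.emb_llm),
                emb_omics1=data.emb_omics1,
                emb_omics2=data.emb_omics2,
                g_spatial=data.g_spatial,
                g_llm=sf.normalize_adjacency(
                    sf.build_embedding_graph(np.zeros_like(data.emb_llm), 3)
                ),
                g_omics1=data.g_omics1,
                g_omics2=data.g_omics2,
            )
        _, ls, history = sf.train(zero, sf.LossConfig(epochs=20, seed=0),
                                  hidden_dims=(8,), latent_dim=6)
        assert np.all(np.isfinite(ls.Emb_final))
        assert history[-1].total < history[0].total


class TestEstimator:
    def test_get_set_params_round_trip(self):
        est = sf.GraphAttentionAutoencoder(latent_dim=32, epochs=5)
        params = est.get_params()
        assert params["latent_dim"] == 32
        est.set_params(epochs=7)
        assert est.epochs == 7

    def test_checkpoint_round_trip(self, tmp_path, trained_small_model, small_inputs):
        path = tmp_path / "ckpt.npz"
        trained_small_model.save_checkpoint(path)
        fresh = sf.GraphAttentionAutoencoder(hidden_dims=(8,), latent_dim=6)
        fresh.load_checkpoint(path)
        np.testing.assert_allclose(
            fresh.transform(small_inputs), trained_small_model.transform(small_inputs),
            atol=1e-12,
        )

    def test_transform_requires_fit(self, small_inputs):
        est = sf.GraphAttentionAutoencoder()
        with pytest.raises(sf.ValidationError, match="not fitted"):
            est.transform(small_inputs)
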