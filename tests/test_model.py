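"""Layer contracts of the network: extractor, GCN, attention, classifier."""

import numpy as np
import pytest

from seizuregraph import ModelConfig, MultiBranchGCN, attention_flops, describe
from seizuregraph.autodiff import Tensor
from seizuregraph.graphs import normalize_adjacency
from seizuregraph.model import (
    GCNBranch,
    IntrachannelExtractor,
    SeparableAttention,
    load_checkpoint,
    save_checkpoint,
)


class TestIntrachannelExtractor:
    def test_output_shape_halves_per_layer(self, rng):
        ext = IntrachannelExtractor(22, 2, rng)
        out = ext(Tensor(rng.standard_normal((1, 22, 768))))
        assert out.shape == (1, 22, 192)

    def test_k_zero_is_identity(self, rng):
        ext = IntrachannelExtractor(22, 0, rng)
        x = rng.standard_normal((2, 22, 768))
        np.testing.assert_array_equal(ext(Tensor(x)).data, x)

    def test_channel_independence(self, rng):
        """Depthwise: perturbing channel 5 changes only output row 5."""
        ext = IntrachannelExtractor(22, 2, rng)
        x = rng.standard_normal((1, 22, 768))
        base = ext(Tensor(x)).data
        x2 = x.copy()
        x2[0, 5] += rng.standard_normal(768)
        pert = ext(Tensor(x2)).data
        changed = np.abs(pert - base).sum(axis=2)[0] > 0
        assert changed[5] and not changed[np.arange(22) != 5].any()

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(window_samples=770, k_depthwise=2)


class TestGCNLayer:
    def test_zero_graph_reduces_to_dense_relu(self, rng):
        """A = 0 gives propagation I, so the layer is ReLU(H theta)."""
        branch = GCNBranch(4, 3, 1, rng)
        h = rng.standard_normal((2, 5, 4))
        s = Tensor(normalize_adjacency(np.zeros((5, 5))))
        out = branch(Tensor(h), s, use_bn=False)
        expected = np.maximum(h @ branch.thetas[0].data, 0.0)
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_two_node_hand_example(self, rng):
        """A=[[0,1],[1,0]], H=[[1,0],[3,0]], theta=I: rows become [2,0]."""
        branch = GCNBranch(2, 2, 1, rng)
        branch.thetas[0].data = np.eye(2)
        s = Tensor(normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]])))
        h = Tensor(np.array([[[1.0, 0.0], [3.0, 0.0]]]))
        out = branch(h, s, use_bn=False)
        np.testing.assert_allclose(out.data[0], [[2.0, 0.0], [2.0, 0.0]], atol=1e-12)

    def test_constant_vector_preserved_on_regular_graph(self):
        """On a 4-cycle the constant vector is an eigenvector of the
        normalized propagation operator (eigenvalue 1)."""
        a = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], float
        )
        s = normalize_adjacency(a)
        h = np.ones((4, 3)) * [2.0, -1.0, 0.5]
        np.testing.assert_allclose(s @ h, h, atol=1e-12)


class TestMultiBranch:
    def test_full_stack_shape(self, small_segments):
        model = MultiBranchGCN(ModelConfig(gcn_dim=16, seed=0))
        x = small_segments.segments[:4]
        _, outs = model.branch_outputs(x)
        assert len(outs) == 3
        assert all(o.shape == (4, 22, 16) for o in outs)
        probs = model(x)
        assert probs.shape == (4, 2)
        assert ((probs.data > 0) & (probs.data < 1)).all()

    @pytest.mark.parametrize(
        "switches",
        [
            dict(branch_connectivity=False, branch_adaptive=False),
            dict(branch_distance=False, branch_adaptive=False),
            dict(branch_distance=False, branch_connectivity=False),
        ],
    )
    def test_single_branch_ablations(self, small_segments, switches):
        cfg = ModelConfig(gcn_dim=8, classifier_channels=(4, 8), seed=0, **switches)
        model = MultiBranchGCN(cfg)
        x = small_segments.segments[:3]
        _, outs = model.branch_outputs(x)
        assert len(outs) == 1
        assert model(x).shape == (3, 2)

    def test_all_branches_disabled_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(
                branch_distance=False,
                branch_connectivity=False,
                branch_adaptive=False,
            )

    def test_identical_adjacency_and_weights_give_identical_branches(self, rng):
        """Unshared parameters: two branches agree iff their parameters and
        adjacencies agree."""
        b1 = GCNBranch(6, 4, 2, rng)
        b2 = GCNBranch(6, 4, 2, rng)
        for p, q in zip(b1.parameters(), b2.parameters()):
            q.data = p.data.copy()
        s = Tensor(normalize_adjacency(rng.uniform(0, 1, (5, 5))))
        h = Tensor(rng.standard_normal((2, 5, 6)))
        np.testing.assert_array_equal(
            b1(h, s, use_bn=False).data, b2(h, s, use_bn=False).data
        )

    def test_node_permutation_equivariance(self, tiny_config, tiny_layout, rng):
        """Permuting channels (and all graphs/parameters tied to channel
        identity) permutes pre-BN branch outputs identically."""
        cfg = tiny_config
        model = MultiBranchGCN(cfg, layout=tiny_layout)
        perm = rng.permutation(cfg.n_channels)

        from seizuregraph import ElectrodeLayout

        layout_p = ElectrodeLayout(
            [tiny_layout.names[i] for i in perm], tiny_layout.coords[perm]
        )
        model_p = MultiBranchGCN(cfg, layout=layout_p)
        state = model.state_dict()
        for k in list(state):
            if "extractor" in k:
                state[k] = state[k][perm]
            if "adaptive.raw" in k:
                state[k] = state[k][np.ix_(perm, perm)]
        model_p.load_state_dict(state)

        x = rng.standard_normal((3, cfg.n_channels, cfg.window_samples))
        _, outs = model.branch_outputs(x, use_bn=False)
        _, outs_p = model_p.branch_outputs(x[:, perm, :], use_bn=False)
        for o, op in zip(outs, outs_p):
            np.testing.assert_allclose(op.data, o.data[:, perm, :], atol=1e-10)

    def test_forward_finite_across_seeds(self, tiny_config, tiny_layout):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cfg = ModelConfig(**{**tiny_config.to_dict(), "seed": seed})
            model = MultiBranchGCN(cfg, layout=tiny_layout)
            probs = model(rng.standard_normal((2, 6, 64)))
            assert np.isfinite(probs.data).all()


class TestSeparableAttention:
    def test_shape_preserved(self, rng):
        att = SeparableAttention(3, 3, 1, rng)
        z = Tensor(rng.standard_normal((2, 3, 6, 8)))
        assert att(z).shape == (2, 3, 6, 8)

    def test_scores_sum_to_one_per_head(self, rng):
        att = SeparableAttention(3, 3, 2, rng)
        att(Tensor(rng.standard_normal((4, 3, 6, 8))))
        sums = att.last_scores.sum(axis=-1)
        np.testing.assert_allclose(sums, np.ones_like(sums), atol=1e-6)

    def test_zeroed_fusion_isolates_residual(self, rng):
        """With the 3x3 fusion conv zeroed the block must reduce to BN(Z)."""
        att = SeparableAttention(3, 3, 1, rng)
        att.fuse.weight.data[:] = 0.0
        att.fuse.bias.data[:] = 0.0
        z = Tensor(rng.standard_normal((4, 3, 6, 8)))
        out = att(z)
        expected = att.bn_out(z)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_flop_count_linear_in_feature_dim(self):
        base = ModelConfig(gcn_dim=32)
        doubled = ModelConfig(gcn_dim=64)
        ratio = attention_flops(doubled) / attention_flops(base)
        assert abs(ratio - 2.0) < 0.2


class TestClassifierHead:
    def test_probability_tie_resolves_to_interictal(self, tiny_config, tiny_layout):
        model = MultiBranchGCN(tiny_config, layout=tiny_layout)
        model.classifier.fc.weight.data[:] = 0.0
        model.classifier.fc.bias.data[:] = 0.0
        x = np.random.default_rng(0).standard_normal((3, 6, 64))
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs, 0.5)
        assert (model.predict(x) == 0).all()

    def test_sigmoid_closed_form_on_fixed_logits(self, tiny_config, tiny_layout):
        """Bias-only logits (-10, 10) give probabilities (4.5e-5, 0.99995)."""
        model = MultiBranchGCN(tiny_config, layout=tiny_layout)
        model.classifier.fc.weight.data[:] = 0.0
        model.classifier.fc.bias.data = np.array([-10.0, 10.0])
        probs = model.predict_proba(np.zeros((1, 6, 64)) + 0.1)
        np.testing.assert_allclose(
            probs[0], [1 / (1 + np.e**10), 1 / (1 + np.e**-10)], rtol=1e-9
        )
        assert model.predict(np.zeros((1, 6, 64)) + 0.1)[0] == 1

    def test_eval_mode_deterministic(self, tiny_config, tiny_layout, rng):
        model = MultiBranchGCN(tiny_config, layout=tiny_layout)
        x = rng.standard_normal((4, 6, 64))
        np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_dropout_active_only_in_training(self, tiny_config, tiny_layout, rng):
        model = MultiBranchGCN(tiny_config, layout=tiny_layout)
        x = rng.standard_normal((4, 6, 64))
        model.train()
        a = model(x).data
        b = model(x).data
        assert not np.array_equal(a, b)  # dropout masks differ


class TestIntrospection:
    def test_parameter_count_independent_of_batch(self, tiny_config, tiny_layout, rng):
        model = MultiBranchGCN(tiny_config, layout=tiny_layout)
        n0 = model.n_parameters()
        model(rng.standard_normal((1, 6, 64)))
        model(rng.standard_normal((7, 6, 64)))
        assert model.n_parameters() == n0

    def test_describe_totals(self, tiny_config, tiny_layout):
        model = MultiBranchGCN(tiny_config, layout=tiny_layout)
        table = describe(model)
        total = table[table["name"] == "TOTAL"]["n_params"].iloc[0]
        assert total == model.n_parameters()

    def test_checkpoint_roundtrip(self, tiny_config, tiny_layout, rng, tmp_path):
        model = MultiBranchGCN(tiny_config, layout=tiny_layout)
        x = rng.standard_normal((3, 6, 64))
        before = model.predict_proba(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        np.testing.assert_array_equal(clone.predict_proba(x), before)
        assert clone.config.to_dict() == model.config.to_dict()
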