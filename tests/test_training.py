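"""Loss values, balanced resampling, gradient flow, and protocol plumbing."""

import numpy as np
import pytest

from seizuregraph import (
    ModelConfig,
    MultiBranchGCN,
    SyntheticSpec,
    TrainConfig,
    balanced_epoch_subset,
    bce_loss,
    fit,
    generate_recording,
    make_splits,
    protocol_on_segments,
    run_protocol,
)
from seizuregraph.autodiff import Tensor


class TestLoss:
    def _probs(self, p1):
        return Tensor(np.array([[1.0 - p1, p1]]))

    def test_confident_correct_is_zero(self):
        assert bce_loss(self._probs(1.0), [1]).item() == pytest.approx(0.0, abs=2e-7)

    def test_half_probability(self):
        assert bce_loss(self._probs(0.5), [1]).item() == pytest.approx(0.6931, abs=1e-4)

    def test_confident_wrong(self):
        assert bce_loss(self._probs(0.9), [0]).item() == pytest.approx(2.3026, abs=1e-4)

    def test_explicit_l2_penalty_adds_global_norm(self):
        from seizuregraph.nn import Parameter

        params = [Parameter(np.array([3.0])), Parameter(np.array([4.0]))]
        base = bce_loss(self._probs(0.5), [1]).item()
        with_pen = bce_loss(self._probs(0.5), [1], tau=0.1, params=params).item()
        assert with_pen == pytest.approx(base + 0.1 * 5.0)

    def test_two_unit_form_trains_both_units(self):
        probs = Tensor(np.array([[0.5, 0.5]]), requires_grad=True)
        bce_loss(probs, [1], two_unit=True).backward()
        assert (np.abs(probs.grad) > 0).all()


class TestBalancedEpochs:
    def test_counts_balanced(self):
        labels = np.r_[np.zeros(200, int), np.ones(40, int)]
        sub = balanced_epoch_subset(labels, seed=0)
        assert len(sub) == 80
        assert (labels[sub] == 1).sum() == 40
        assert (labels[sub] == 0).sum() == 40

    def test_already_balanced_keeps_all(self):
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        sub = balanced_epoch_subset(labels, seed=0)
        assert sorted(sub) == list(range(80))

    def test_epochs_draw_different_interictal_subsets(self):
        labels = np.r_[np.zeros(500, int), np.ones(40, int)]
        ictal = set(np.flatnonzero(labels == 1))
        drawn = []
        for ep in range(10):
            sub = balanced_epoch_subset(labels, seed=1000 + ep)
            assert ictal <= set(sub)
            drawn.append(frozenset(set(sub) - ictal))
        assert len(set(drawn)) > 1

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_epoch_subset(np.zeros(10, int), seed=0)


def _tiny_training_setup(rng, n=60):
    """Small segment set + tiny model over 6 channels."""
    from seizuregraph import SegmentSet

    labels = (np.arange(n) % 3 == 0).astype(int)
    x = rng.standard_normal((n, 6, 64))
    x[labels == 1] += 1.5  # separable offset
    segs = SegmentSet(x, labels, np.full(n, "P00", object), 64.0, 1.0)
    cfg = ModelConfig(
        n_channels=6, window_samples=64, gcn_dim=8, classifier_channels=(4, 8), seed=0
    )
    return segs, cfg


class TestFit:
    def test_one_epoch_smoke(self, rng, tiny_layout):
        segs, cfg = _tiny_training_setup(rng)
        model = MultiBranchGCN(cfg, layout=tiny_layout)
        splits = make_splits(segs, "patient_specific", seed=0)
        tcfg = TrainConfig(epochs=1, batch_size=16, seed=0)
        res = fit(model, segs, splits[0], tcfg)
        assert len(res.history) == 1
        assert all(np.isfinite(p.data).all() for p in model.parameters())

    def test_epoch_batches_class_balanced(self, rng, tiny_layout):
        segs, cfg = _tiny_training_setup(rng)
        model = MultiBranchGCN(cfg, layout=tiny_layout)
        splits = make_splits(segs, "patient_specific", seed=0)
        res = fit(model, segs, splits[0], TrainConfig(epochs=3, batch_size=8, seed=0))
        for n_inter, n_ictal in res.balance_audit:
            assert n_inter == n_ictal

    def test_reproducible_history(self, rng, tiny_layout):
        segs, cfg = _tiny_training_setup(rng)
        splits = make_splits(segs, "patient_specific", seed=0)
        tcfg = TrainConfig(epochs=2, batch_size=16, seed=5)
        h1 = fit(MultiBranchGCN(cfg, layout=tiny_layout), segs, splits[0], tcfg).history
        h2 = fit(MultiBranchGCN(cfg, layout=tiny_layout), segs, splits[0], tcfg).history
        cols = ["epoch", "train_loss", "val_loss", "val_acc"]  # not wall time
        assert h1[cols].equals(h2[cols])

    def test_adaptive_adjacency_receives_gradient(self, rng, tiny_layout):
        """Autodiff gradient on one raw-adjacency entry matches central
        finite differences to 1e-3 relative."""
        segs, cfg = _tiny_training_setup(rng)
        model = MultiBranchGCN(cfg, layout=tiny_layout)
        x, y = segs.segments[:8], segs.labels[:8]
        model.eval()  # freeze dropout/BN batch statistics out of the path

        def loss_value():
            return bce_loss(model(x), y).item()

        loss = bce_loss(model(x), y)
        loss.backward()
        g = model.adaptive.raw.grad
        assert g is not None and np.abs(g).max() > 0
        i, j = np.unravel_index(np.abs(g).argmax(), g.shape)
        eps = 1e-4
        model.adaptive.raw.data[i, j] += eps
        up = loss_value()
        model.adaptive.raw.data[i, j] -= 2 * eps
        down = loss_value()
        model.adaptive.raw.data[i, j] += eps
        fd = (up - down) / (2 * eps)
        assert abs(fd - g[i, j]) / max(abs(fd), 1e-12) < 1e-3

    def test_disabled_adaptive_branch_has_no_trainable_graph(self, rng, tiny_layout):
        segs, cfg = _tiny_training_setup(rng)
        cfg = ModelConfig(**{**cfg.to_dict(), "branch_adaptive": False})
        model = MultiBranchGCN(cfg, layout=tiny_layout)
        assert model.adaptive is None
        assert not any("adaptive" in n for n, _ in model.named_parameters())

    def test_validation_loss_decreases_on_separable_data(self, rng, tiny_layout):
        segs, cfg = _tiny_training_setup(rng, n=90)
        splits = make_splits(segs, "patient_specific", seed=0)
        tcfg = TrainConfig(epochs=12, batch_size=16, seed=0, early_stop_patience=12)
        model = MultiBranchGCN(cfg, layout=tiny_layout)
        hist = fit(model, segs, splits[0], tcfg).history
        assert hist["val_loss"].iloc[-1] < hist["val_loss"].iloc[0]


class TestProtocols:
    def test_patient_specific_five_rows_plus_mean(self, rng, tiny_layout):
        segs, cfg = _tiny_training_setup(rng, n=80)
        tcfg = TrainConfig(epochs=1, batch_size=16, seed=0)
        table, reports = protocol_on_segments(
            segs, "patient_specific", cfg, tcfg, layout=tiny_layout
        )
        assert len(table) == 6
        assert list(table["case"]) == [f"fold{i}" for i in range(5)] + ["Mean"]
        assert len(reports) == 5

    def test_loso_rows_test_on_single_patient(self, rng):
        """Provenance audit: LOSO fold i is evaluated only on patient i."""
        recs = []
        for i in range(3):
            spec = SyntheticSpec(
                duration_s=60.0,
                seizure_intervals=[(10.0, 25.0)],
                patient_id=f"P{i:02d}",
                seed=100 + i,
            )
            recs.append(generate_recording(spec))
        cfg = ModelConfig(gcn_dim=8, classifier_channels=(4, 8), seed=0)
        tcfg = TrainConfig(epochs=1, batch_size=16, seed=0, mode="patient_independent")
        table, reports = run_protocol(recs, "patient_independent", cfg, tcfg)
        assert list(table["case"]) == ["P00", "P01", "P02", "Mean"]
        # counts per report match each patient's segment total
        for rep in reports:
            assert rep.total > 0

    def test_per_fold_rebalance_caps_training_interictal(self, rng, tiny_layout):
        """The alternative rebalancing stage caps interictal:ictal on each
        fold's training indices after splitting, leaving test folds intact."""
        from unittest.mock import patch

        from seizuregraph import SegmentSet
        from seizuregraph.training import fit as real_fit

        n = 120
        labels = (np.arange(n) % 12 == 0).astype(int)  # 10 ictal, 110 inter
        segs = SegmentSet(
            rng.standard_normal((n, 6, 64)), labels, np.full(n, "P00", object),
            64.0, 1.0,
        )
        cfg = ModelConfig(
            n_channels=6, window_samples=64, gcn_dim=8,
            classifier_channels=(4, 8), seed=0,
        )
        seen = []

        def spy(model, s, split, tcfg, verbose=False):
            y = s.labels[split[0]]
            seen.append((int((y == 0).sum()), int((y == 1).sum())))
            return real_fit(model, s, split, tcfg, verbose)

        with patch("seizuregraph.training.fit", side_effect=spy):
            protocol_on_segments(
                segs, "patient_specific", cfg,
                TrainConfig(epochs=1, batch_size=16, seed=0),
                folds=[0], layout=tiny_layout, train_rebalance_ratio=5.0,
            )
        (n_inter, n_ictal), = seen
        assert n_inter == 5 * n_ictal

    def test_divergence_aborts_with_diagnostic(self, rng, tiny_layout):
        segs, cfg = _tiny_training_setup(rng)
        model = MultiBranchGCN(cfg, layout=tiny_layout)
        model.classifier.fc.bias.data = np.array([np.nan, np.nan])
        splits = make_splits(segs, "patient_specific", seed=0)
        with pytest.raises(RuntimeError, match="diverged"):
            fit(model, segs, splits[0], TrainConfig(epochs=1, batch_size=16, seed=0))
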