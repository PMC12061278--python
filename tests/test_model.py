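"""Bridge model: survival head closed forms, losses, training contracts."""

import numpy as np
import pytest

from bridgemil.model import (BridgeNet, SurvivalOutput, TrainedBridge,
                             bridge_loss, predict, survival_nll, total_loss)
from bridgemil.nn import Tensor
from bridgemil import BridgedSurvivalModel
from tests.conftest import tiny_config


class TestSurvivalOutput:
    def test_zero_logits_closed_form(self):
        out = SurvivalOutput.from_logits(np.zeros(4))
        assert np.allclose(out.hazards, 0.5)
        assert np.allclose(out.survival, [0.5, 0.25, 0.125, 0.0625])
        assert out.risk == pytest.approx(-0.9375)

    def test_low_hazard_limit_best_prognosis(self):
        out = SurvivalOutput.from_logits(np.full(4, -40.0))
        assert out.risk == pytest.approx(-4.0)

    def test_risk_strictly_increases_in_each_logit(self):
        base = np.array([0.3, -0.2, 0.1, 0.5])
        r0 = SurvivalOutput.from_logits(base).risk
        for j in range(4):
            bumped = base.copy()
            bumped[j] += 0.5
            assert SurvivalOutput.from_logits(bumped).risk > r0

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(0)
        out = SurvivalOutput.from_logits(rng.normal(size=6))
        assert (np.diff(out.survival) <= 0).all()

    def test_uniform_shift_preserves_risk_ordering(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=4)
        b = a + rng.normal(size=4) * 0.5
        ra, rb = (SurvivalOutput.from_logits(v).risk for v in (a, b))
        sa, sb = (SurvivalOutput.from_logits(v + 1.0).risk for v in (a, b))
        assert (ra > rb) == (sa > sb) or ra == rb


class TestSurvivalNLL:
    def test_event_closed_form(self):
        # uncensored at bin 1 with all hazards 1/2: -log(1/2) - log(1/2)
        logits = Tensor(np.zeros((1, 4)))
        loss = survival_nll(logits, np.array([1]), np.array([1]))
        assert loss.data == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_censored_closed_form(self):
        logits = Tensor(np.zeros((1, 4)))
        loss = survival_nll(logits, np.array([0]), np.array([0]))
        assert loss.data == pytest.approx(np.log(2), abs=1e-6)

    def test_saturated_hazard_minimizes_single_patient_loss(self):
        # event at bin 2: hazard 1 at bin 2, 0 before, is the MLE
        good = np.array([[-15.0, -15.0, 15.0, 0.0]])
        worse = np.array([[0.0, 0.0, 0.0, 0.0]])
        lg = survival_nll(Tensor(good), np.array([2]), np.array([1]))
        lw = survival_nll(Tensor(worse), np.array([2]), np.array([1]))
        assert lg.data < lw.data

    def test_bin_out_of_range_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            survival_nll(Tensor(np.zeros((1, 4))), np.array([4]),
                         np.array([1]))

    def test_batch_mean(self):
        logits = Tensor(np.zeros((2, 4)))
        loss = survival_nll(logits, np.array([1, 0]), np.array([1, 0]))
        assert loss.data == pytest.approx(1.5 * np.log(2), abs=1e-6)


class TestTotalLoss:
    def test_lambda_zero_is_survival_only(self):
        ls = Tensor(np.array(0.7))
        lb = Tensor(np.array(123.0))
        assert total_loss(ls, lb, 0.0) is ls

    def test_arithmetic(self):
        ls = Tensor(np.array(0.7))
        lb = Tensor(np.array(2.0))   # both residual mean squares equal 1
        assert total_loss(ls, lb, 0.5).data == pytest.approx(1.7)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(Tensor(np.array(1.0)), Tensor(np.array(1.0)), -0.1)


@pytest.fixture(scope="module")
def net():
    cfg = tiny_config()
    return BridgeNet(cfg, 40, np.random.default_rng(0)), cfg


class TestBridge:
    def test_pseudo_omics_dimension(self, net):
        model, cfg = net
        h_w = Tensor(np.random.default_rng(1).normal(size=cfg.encoder.d_wsi))
        out = model.bridge_forward(h_w, None)
        assert out["pseudo_omics"].shape == (cfg.encoder.d_omics,)
        assert "pseudo_slide" not in out

    def test_both_directions_with_omics(self, net):
        model, cfg = net
        rng = np.random.default_rng(2)
        h_w = Tensor(rng.normal(size=cfg.encoder.d_wsi))
        h_o = Tensor(rng.normal(size=cfg.encoder.d_omics))
        out = model.bridge_forward(h_w, h_o)
        assert out["pseudo_slide"].shape == (cfg.encoder.d_wsi,)

    def test_both_absent_rejected(self, net):
        model, _ = net
        with pytest.raises(ValueError):
            model.bridge_forward(None, None)

    def test_recovers_realizable_linear_mapping(self, net):
        # when the omics embedding is an exact linear map of the slide
        # embedding, bridge training drives the residual well below the
        # target variance
        model, cfg = net
        rng = np.random.default_rng(42)
        d_w, d_o = cfg.encoder.d_wsi, cfg.encoder.d_omics
        W = rng.normal(0, 1.0 / np.sqrt(d_w), size=(d_w, d_o))
        H_w = rng.normal(size=(64, d_w))
        H_o = H_w @ W
        from bridgemil.nn import Adam
        opt = Adam(model.bridge_wo.parameters(), lr=1e-2, weight_decay=0.0)
        for _ in range(400):
            opt.zero_grad()
            pred = model.bridge_wo(Tensor(H_w))
            loss = ((pred - Tensor(H_o)) ** 2).mean()
            loss.backward()
            opt.step()
        pred = model.bridge_wo(Tensor(H_w)).data
        assert np.mean((pred - H_o) ** 2) < 0.1 * H_o.var()

    def test_single_directional_drops_reverse_term(self, net):
        model, cfg = net
        rng = np.random.default_rng(3)
        h_w = Tensor(rng.normal(size=cfg.encoder.d_wsi))
        h_o = Tensor(rng.normal(size=cfg.encoder.d_omics))
        full = bridge_loss(model, h_w, h_o, "bridge").data
        single = bridge_loss(model, h_w, h_o, "single_directional").data
        assert single < full
        assert bridge_loss(model, h_w, h_o, "non_bridge").data == 0.0


class TestTraining:
    def test_loss_decreases(self, small_fit):
        for trained in small_fit.fold_models:
            assert trained.train_log[-1] < trained.train_log[0]

    def test_same_seed_identical_weights(self, small_cohort):
        cfg = tiny_config(epochs=1)
        runs = []
        for _ in range(2):
            m = BridgedSurvivalModel.from_synthetic(small_cohort, cfg)
            res = m.fit(seed=9, n_folds=2)
            runs.append(res.fold_models[0].net.state_arrays())
        assert all((a == b).all() for a, b in zip(*runs))

    def test_non_bridge_mode_leaves_bridge_frozen(self, small_cohort):
        cfg = tiny_config(epochs=1)
        cfg.bridge.mode = "non_bridge"
        m = BridgedSurvivalModel.from_synthetic(small_cohort, cfg)
        init = BridgeNet(cfg, m.omics.shape[1],
                       np.random.default_rng(0))
        res = m.fit(seed=0, n_folds=2)
        trained = res.fold_models[0].net
        assert np.allclose(trained.bridge_wo.fc1.weight.data.std(),
                           init.bridge_wo.fc1.weight.data.std(), rtol=0.5)
        # more direct: retrain and diff bridge weights against a fresh
        # clone initialised with the identical per-fold seed
        from bridgemil.api import _fold_seed
        clone = BridgeNet(cfg, m.omics.shape[1],
                        np.random.default_rng(_fold_seed(0, 0, 1)))
        assert (trained.bridge_wo.fc1.weight.data
                == clone.bridge_wo.fc1.weight.data).all()
        assert not (trained.head.fc1.weight.data
                    == clone.head.fc1.weight.data).all()


class TestGatedAttentionBaseline:
    def test_trains_end_to_end(self, small_cohort):
        cfg = tiny_config(epochs=1)
        cfg.encoder.wsi_pooling = "gated_attention"
        m = BridgedSurvivalModel.from_synthetic(small_cohort, cfg,
                                                modality="wsi_only")
        res = m.fit(seed=1, n_folds=2)
        assert len(res.fold_concordances()) == 2
        assert res.fold_models[0].train_log[-1] < \
            res.fold_models[0].train_log[0] * 1.5  # trains without blowup


class TestPseudoEmbeddingFidelity:
    def test_pseudo_and_real_risks_correlate(self, bridge_fit):
        """On a cohort with strong shared signal, WSI-only inference via
        the bridge ranks patients similarly to full multimodal inference."""
        from scipy.stats import spearmanr
        real = bridge_fit.predictions[["patient_id", "risk"]]
        pseudo = bridge_fit.predict_risks(missing_omics=True)
        merged = real.merge(pseudo, on="patient_id",
                            suffixes=("_real", "_pseudo"))
        rho = spearmanr(merged["risk_real"], merged["risk_pseudo"]).statistic
        assert rho > 0.3


class TestPredict:
    def test_missing_omics_never_reads_omics(self, small_fit, small_cohort):
        trained = small_fit.fold_models[0]
        pid = small_fit.folds[0].test_ids[0]
        idx = small_cohort.patient_ids.index(pid)
        from bridgemil.io import PatchBag
        bag = PatchBag(pid, small_cohort.bag_features[idx],
                       small_cohort.bag_coords[idx])
        out = predict(trained, bag, None, missing_omics=True)
        assert np.isfinite(out.risk)

    def test_real_omics_path_requires_values(self, small_fit, small_cohort):
        trained = small_fit.fold_models[0]
        pid = small_fit.folds[0].test_ids[0]
        idx = small_cohort.patient_ids.index(pid)
        from bridgemil.io import PatchBag
        bag = PatchBag(pid, small_cohort.bag_features[idx],
                       small_cohort.bag_coords[idx])
        with pytest.raises(ValueError, match="omics"):
            predict(trained, bag, None, missing_omics=False)

    def test_save_load_bit_identical(self, small_fit, small_cohort,
                                     tmp_path):
        trained = small_fit.fold_models[0]
        trained.save(tmp_path / "ckpt")
        loaded = TrainedBridge.load(tmp_path / "ckpt")
        pid = small_fit.folds[0].test_ids[0]
        idx = small_cohort.patient_ids.index(pid)
        from bridgemil.io import PatchBag
        bag = PatchBag(pid, small_cohort.bag_features[idx],
                       small_cohort.bag_coords[idx])
        om = small_fit.model.standardized_omics(trained, pid)
        a = predict(trained, bag, om)
        b = predict(loaded, bag, om)
        assert (a.logits == b.logits).all()
        assert a.risk == b.risk
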