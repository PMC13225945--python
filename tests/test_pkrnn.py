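"""Recurrent PK models: embedding, forward semantics, loss, training
mechanics, and prospective prediction."""

import math

import numpy as np
import pytest

from vancopk import ehr_model, pk_core, pkrnn
from vancopk.pkrnn import ModelConfig, PKRNNModel

from conftest import frames_of


@pytest.fixture(scope="module")
def cfg2():
    return ModelConfig(head="2cm", seed=0)


@pytest.fixture(scope="module")
def model2(cfg2):
    return PKRNNModel(cfg2)


class TestEmbedStep:
    def test_no_codes_gives_zero_embedding(self, model2):
        out = model2.embed_step((), np.zeros(40))
        assert out.shape == (48,)
        assert np.allclose(out[:8], 0.0)

    def test_single_code_is_its_row(self, model2):
        out = model2.embed_step((17,), np.zeros(40))
        assert np.allclose(out[:8], model2.params["emb"].data[17])

    def test_mean_of_codes(self, model2):
        out = model2.embed_step((3, 9), np.zeros(40))
        expected = model2.params["emb"].data[[3, 9]].mean(axis=0)
        assert np.allclose(out[:8], expected)

    def test_out_of_vocabulary_rejected(self, model2):
        with pytest.raises(ValueError, match="vocabulary"):
            model2.embed_step((911,), np.zeros(40))


class TestForward:
    def test_zero_head_matches_population_curve(self, small_frames, cfg2):
        model = PKRNNModel(cfg2)
        model.zero_head()
        f = frames_of(small_frames, "test")[0]
        recs, _ = pkrnn.predict_prospective(model, f)
        crcl_series = list(zip(f.times.tolist(), f.crcl.tolist()))
        ref = pk_core.build_curve_2c(pk_core.EtaVector(), f.doses,
                                     float(f.times[-1]), crcl_series)
        for r in recs:
            assert r.predicted == pytest.approx(
                max(ref.evaluate(r.t), 0.0), abs=1e-9)

    def test_zero_doses_predicts_zero_everywhere(self, cfg2):
        from datetime import datetime
        from vancopk.ehr_model import ClinicalEvent, EventTimeline
        tl = EventTimeline("P", "E", datetime(2024, 1, 1), [
            ClinicalEvent(0.0, "LAB", code="sodium", value=140.0),
            ClinicalEvent(10.0, "VANC_LEVEL", value=0.0),
            ClinicalEvent(20.0, "VANC_LEVEL", value=0.0)],
            {"age": 50.0, "sex": "male", "race": "w", "height_cm": 170.0,
             "weight_kg": 80.0})
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frames, _ = ehr_model.impute_and_standardize([tl], [tl])
        model = PKRNNModel(cfg2)
        batch = pkrnn.prepare_batch([frames["E"]], cfg2)
        preds, _ = model.forward(batch)
        assert np.allclose(preds.data, 0.0)

    def test_batch_permutation_leaves_predictions_unchanged(self, small_frames, cfg2):
        model = PKRNNModel(cfg2)
        frames = frames_of(small_frames, "train")[:6]
        preds_a, _ = model.forward(pkrnn.prepare_batch(frames, cfg2))
        perm = [3, 0, 5, 1, 4, 2]
        preds_b, _ = model.forward(pkrnn.prepare_batch([frames[i] for i in perm], cfg2))
        for b, a in enumerate(perm):
            n = frames[a].n_steps
            assert np.array_equal(preds_a.data[:n, a], preds_b.data[:n, b])

    def test_causality_under_truncation(self, small_frames, cfg2):
        """Predictions at or before a cut time are exactly invariant to the
        removal of all later events."""
        model = PKRNNModel(cfg2)
        tl = small_frames["train"][0]
        full = small_frames["frames"][tl.encounter_id]
        cut = full.times[full.n_steps // 2]
        truncated = ehr_model.EventTimeline(
            tl.patient_id, "CUT", tl.start_time,
            [e for e in tl.events if e.t <= cut + 1e-9], dict(tl.static))
        # preprocess with the same training split, so the standardizer and
        # imputation values are identical and inputs are bitwise equal
        frames2, _ = ehr_model.impute_and_standardize(
            small_frames["train"] + [truncated], small_frames["train"])
        recs_full, _ = pkrnn.predict_prospective(model, full)
        recs_cut, _ = pkrnn.predict_prospective(model, frames2["CUT"])
        assert len(recs_cut) >= 3
        for rf, rc in zip(recs_full, recs_cut):
            assert rf.t == rc.t
            assert rf.predicted == rc.predicted
            assert rf.eta == rc.eta


class TestLoss:
    def _tiny_batch(self, cfg):
        """Two steps, one observation, hand-checkable numbers."""
        batch = pkrnn.PreparedBatch(
            encounter_ids=["E"], x=np.zeros((2, 1, 40)),
            code_idx=[np.zeros((1, 1), int)] * 2, code_w=[np.zeros((1, 1))] * 2,
            crcl=np.full((2, 1), 100.0), seq_mask=np.ones((2, 1)),
            level=np.array([[0.0], [10.0]]), level_mask=np.array([[0.0], [1.0]]),
            seg_dur=np.zeros((2, 1, 1)), seg_rate=np.zeros((2, 1, 1)),
            times=[np.array([0.0, 1.0])])
        return batch

    def test_perfect_predictions_and_zero_eta_give_zero_loss(self, cfg2):
        import vancopk.autodiff as ad
        batch = self._tiny_batch(cfg2)
        preds = ad.Tensor(np.array([[0.0], [10.0]]))
        etas = ad.Tensor(np.zeros((2, 1, 4)))
        total, mse, pri, smo = pkrnn.loss_components(preds, etas, batch, cfg2)
        assert total.item() == mse.item() == pri.item() == smo.item() == 0.0

    def test_constant_eta_trajectory_has_zero_smoothness(self, cfg2):
        import vancopk.autodiff as ad
        batch = self._tiny_batch(cfg2)
        etas = ad.Tensor(np.tile([[0.3, -0.1, 0.2, 0.1]], (2, 1, 1)))
        preds = ad.Tensor(np.array([[0.0], [10.0]]))
        _, _, _, smo = pkrnn.loss_components(preds, etas, batch, cfg2)
        assert smo.item() == 0.0

    def test_hand_computed_two_step_case(self, cfg2):
        """Independently scripted arithmetic for the documented loss:
        MSE over observations + w1 * mean step quad + w2 * mean pair diff."""
        import vancopk.autodiff as ad
        batch = self._tiny_batch(cfg2)
        eta0, eta1 = [0.2, 0.0, -0.1, 0.0], [0.1, 0.3, -0.1, 0.2]
        preds = ad.Tensor(np.array([[0.0], [8.5]]))
        etas = ad.Tensor(np.array([[eta0], [eta1]]))
        total, mse, pri, smo = pkrnn.loss_components(preds, etas, batch, cfg2)
        var = pk_core.DEFAULT_PRIOR.variances
        exp_mse = (8.5 - 10.0) ** 2 / 1.0
        quad = lambda e: sum(x * x / v for x, v in zip(e, var))
        exp_pri = (quad(eta0) + quad(eta1)) / 2.0
        exp_smo = sum((a - b) ** 2 for a, b in zip(eta0, eta1)) / 1.0
        assert mse.item() == pytest.approx(exp_mse, rel=1e-12)
        assert pri.item() == pytest.approx(exp_pri, rel=1e-12)
        assert smo.item() == pytest.approx(exp_smo, rel=1e-12)
        assert total.item() == pytest.approx(
            exp_mse + cfg2.prior_penalty_weight * exp_pri
            + cfg2.smoothness_penalty_weight * exp_smo, rel=1e-12)

    def test_decomposition_identity_on_real_batch(self, small_frames, cfg2):
        model = PKRNNModel(cfg2)
        batch = pkrnn.prepare_batch(frames_of(small_frames, "train")[:4], cfg2)
        preds, etas = model.forward(batch)
        total, mse, pri, smo = pkrnn.loss_components(preds, etas, batch, cfg2)
        assert total.item() == pytest.approx(
            mse.item() + cfg2.prior_penalty_weight * pri.item()
            + cfg2.smoothness_penalty_weight * smo.item(), abs=1e-9)

    def test_batch_without_observations_rejected(self, cfg2):
        import vancopk.autodiff as ad
        batch = self._tiny_batch(cfg2)
        batch.level_mask[:] = 0.0
        with pytest.raises(ValueError, match="no observed levels"):
            pkrnn.loss_components(ad.Tensor(np.zeros((2, 1))),
                                  ad.Tensor(np.zeros((2, 1, 4))), batch, cfg2)


class TestTraining:
    def test_early_stopping_stops_after_patience_exhausted(self, small_frames,
                                                           monkeypatch):
        """Strictly worsening validation: 1 best epoch + `patience` bad ones."""
        seq = iter(range(1, 100))
        monkeypatch.setattr(pkrnn, "evaluate_mse",
                            lambda model, batches: float(next(seq)))
        cfg = ModelConfig(head="2cm", max_epochs=50, patience=10, seed=0)
        _, hist = pkrnn.train(frames_of(small_frames, "train")[:3],
                              frames_of(small_frames, "val")[:2], cfg)
        assert len(hist) == 11

    def test_same_seed_reproduces_weights_exactly(self, small_frames):
        cfg = ModelConfig(head="2cm", max_epochs=2, patience=10, seed=5)
        tr = frames_of(small_frames, "train")[:4]
        va = frames_of(small_frames, "val")[:2]
        m1, _ = pkrnn.train(tr, va, cfg)
        m2, _ = pkrnn.train(tr, va, cfg)
        d1, d2 = pkrnn.checkpoint_digest(m1), pkrnn.checkpoint_digest(m2)
        assert d1 == d2

    def test_empty_sets_rejected(self, small_frames):
        cfg = ModelConfig()
        with pytest.raises(ValueError):
            pkrnn.train([], frames_of(small_frames, "val"), cfg)


class TestOneCompartmentHead:
    def test_mass_conserved_while_concentration_may_jump(self, small_frames):
        cfg = ModelConfig(head="1cm", seed=3)
        model = PKRNNModel(cfg)
        f = frames_of(small_frames, "train")[0]
        _, curve = pkrnn.predict_prospective(model, f)
        jumps = 0
        for a, b in zip(curve.pieces[:-1], curve.pieces[1:]):
            (mass_end,) = a.end_state()
            assert mass_end == pytest.approx(b.state0[0], rel=1e-12)  # mass carried
            ca, cb = a.evaluate(a.t1), b.evaluate(b.t0)
            if a.params.v != b.params.v and mass_end > 1e-9:
                assert ca != pytest.approx(cb, rel=1e-9)
                jumps += 1
        assert jumps > 0  # volumes do change between steps

    def test_two_compartment_curve_is_continuous(self, small_frames, cfg2):
        model = PKRNNModel(cfg2)
        f = frames_of(small_frames, "train")[0]
        _, curve = pkrnn.predict_prospective(model, f)
        for a, b in zip(curve.pieces[:-1], curve.pieces[1:]):
            assert a.evaluate(a.t1) == pytest.approx(b.evaluate(b.t0), abs=1e-9)


class TestCheckpoint:
    def test_round_trip(self, small_frames, tmp_path, cfg2):
        model = PKRNNModel(cfg2)
        path = tmp_path / "m.json"
        pkrnn.save_checkpoint(model, path)
        loaded = pkrnn.load_checkpoint(path)
        assert pkrnn.checkpoint_digest(loaded) == pkrnn.checkpoint_digest(model)

    def test_registry_mismatch_refused(self, tmp_path, cfg2):
        model = PKRNNModel(cfg2)
        path = tmp_path / "m.json"
        pkrnn.save_checkpoint(model, path)
        other = ehr_model.FeatureRegistry(vocab_size=500)
        with pytest.raises(ValueError, match="registry"):
            pkrnn.load_checkpoint(path, registry=other)
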