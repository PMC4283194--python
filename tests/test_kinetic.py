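"""Compartmental fits, frame weighting and the SRTM."""

import numpy as np
import pytest

from cb1tacs.core import TimeActivityCurve, build_frame_schedule, frame_average
from cb1tacs.kinetic import (SRTM, OneTissueModel, TwoTissueModel,
                             compute_weights, fit_2kbv, fit_srtm,
                             srtm_forward)
from cb1tacs.simulate import TruthEntry, simulate_tac


class TestComputeWeights:
    def test_formula(self, schedule):
        trues = np.full(schedule.n_frames, 1000.0)
        tac = TimeActivityCurve("r", np.ones(schedule.n_frames), schedule,
                                trues_rate=trues)
        w = compute_weights(tac)
        assert w[0] == pytest.approx(30.0 / 1000.0)  # L=30 s, T=1000/s
        assert w[1] == pytest.approx(0.01)

    def test_uniform_fallback_without_trues(self, schedule, caplog):
        tac = TimeActivityCurve("r", np.ones(schedule.n_frames), schedule)
        with caplog.at_level("WARNING", logger="cb1tacs.kinetic"):
            w = compute_weights(tac)
        assert np.all(w == 1.0)
        assert any("uniform" in r.message for r in caplog.records)

    def test_long_late_frames_with_decaying_trues_weigh_more(self, schedule):
        trues = np.geomspace(5000.0, 50.0, schedule.n_frames)
        tac = TimeActivityCurve("r", np.ones(schedule.n_frames), schedule,
                                trues_rate=trues)
        w = compute_weights(tac)
        assert w[-1] > 10 * w[1]


class TestOneTissueModel:
    def test_noise_free_recovery(self, schedule, input_fn):
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        m = OneTissueModel().fit(tac, input_fn)
        assert m.converged_
        assert m.vt_ == pytest.approx(7.5, rel=0.01)
        assert m.K1_ == pytest.approx(0.15, rel=0.01)
        assert m.bv_ == pytest.approx(0.05, abs=0.005)

    def test_vt_equals_rate_ratio_exactly(self, schedule, input_fn):
        truth = TruthEntry(K1=0.12, k2=0.03, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=1.0, seed=5)
        m = OneTissueModel().fit(tac, input_fn)
        assert m.vt_ == m.K1_ / m.k2_  # identity, not approximation

    def test_pure_vascular_signal(self, schedule, input_fn):
        truth = TruthEntry(K1=0.0, k2=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        m = OneTissueModel().fit(tac, input_fn)
        assert m.K1_ == pytest.approx(0.0, abs=1e-4)
        assert m.bv_ == pytest.approx(0.05, abs=0.002)

    def test_scale_invariance(self, schedule, input_fn):
        from dataclasses import replace
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=1.0, seed=3)
        m1 = OneTissueModel().fit(tac, input_fn)
        c = 4.0
        tac2 = TimeActivityCurve(tac.region_id, c * tac.values, schedule,
                                 trues_rate=tac.trues_rate)
        inp2 = replace(input_fn, parent_plasma=c * input_fn.parent_plasma,
                       whole_blood=c * input_fn.whole_blood)
        m2 = OneTissueModel().fit(tac2, inp2)
        assert m2.K1_ == pytest.approx(m1.K1_, rel=1e-4)
        assert m2.k2_ == pytest.approx(m1.k2_, rel=1e-4)
        assert m2.vt_ == pytest.approx(m1.vt_, rel=1e-4)

    def test_median_bias_under_noise_below_5pct(self, schedule, input_fn):
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        rng = np.random.default_rng(17)
        vts = []
        for _ in range(100):
            tac = simulate_tac(truth, input_fn, schedule, noise_scale=1.0,
                               seed=rng)
            vts.append(OneTissueModel().fit(tac, input_fn).vt_)
        assert abs(np.median(vts) / truth.vt - 1) < 0.05

    def test_all_starts_failing_yields_flagged_nan(self, schedule, input_fn,
                                                   monkeypatch):
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        import cb1tacs.kinetic as kin

        def boom(*a, **k):
            raise RuntimeError("synthetic optimiser failure")

        monkeypatch.setattr(kin, "least_squares", boom)
        m = OneTissueModel().fit(tac, input_fn)
        assert not m.converged_
        assert np.isnan(m.vt_)
        assert "all_starts_failed" in m.flags_

    def test_sklearn_params_roundtrip(self):
        m = OneTissueModel(dt=2.0)
        assert m.get_params()["dt"] == 2.0
        m.set_params(bv_max=0.1)
        assert m.bv_max == 0.1


class TestTwoTissueModel:
    def test_noise_free_recovery(self, schedule, input_fn):
        truth = TruthEntry(K1=0.1, k2=0.05, k3=0.03, k4=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        m = TwoTissueModel().fit(tac, input_fn)
        assert m.vt_ == pytest.approx(5.0, rel=0.02)
        assert m.vt_ == (m.K1_ / m.k2_) * (1 + m.k3_ / m.k4_)

    def test_nested_limit_matches_one_tissue(self, schedule, input_fn):
        """On 1TC-generated data the 4kbv V_T collapses to K1/k2."""
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        vt2 = OneTissueModel().fit(tac, input_fn).vt_
        vt4 = TwoTissueModel().fit(tac, input_fn).vt_
        assert vt4 == pytest.approx(vt2, rel=0.02)

    def test_near_singular_k4_flagged(self, schedule, input_fn, monkeypatch):
        truth = TruthEntry(K1=0.1, k2=0.05, k3=0.03, k4=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        m = TwoTissueModel().fit(tac, input_fn)
        m._set_fitted(np.array([0.05, 0.03, 1.5e-4]), 0.1, 0.05,
                      type("R", (), {"cost": 0.0, "success": True})(), 1)
        assert "k4_near_zero" in m.flags_


class TestSRTM:
    def _reference(self, schedule, input_fn, noise=0.0, seed=None):
        truth = TruthEntry(K1=0.12, k2=0.04, bv=0.0)
        return simulate_tac(truth, input_fn, schedule, noise_scale=noise,
                            seed=seed, region_id="pons")

    def test_self_reference_is_null(self, schedule, input_fn):
        ref = self._reference(schedule, input_fn)
        f = fit_srtm(ref, ref)
        assert f.bp_nd == pytest.approx(0.0, abs=1e-6)
        assert f.R1 == pytest.approx(1.0, abs=1e-6)

    def test_forward_model_recovery(self, schedule, input_fn):
        ref = self._reference(schedule, input_fn)
        dt = 1.0
        t = np.arange(0.0, schedule.total_duration
                      - schedule.injection_offset + dt, dt)
        mids = schedule.midpoints_post_injection
        keep = mids > 0
        ref_fine = np.interp(t, np.r_[0.0, mids[keep]],
                             np.r_[0.0, ref.values[keep]])
        R1, k2, bp = 1.0, 0.04, 1.0
        conv = srtm_forward(ref_fine, dt, R1, k2, bp) - R1 * ref_fine
        tgt_vals = R1 * ref.values + frame_average(
            conv, dt, schedule, time_origin="injection")
        tgt = TimeActivityCurve("hippocampus", tgt_vals, schedule,
                                trues_rate=ref.trues_rate)
        m = SRTM().fit(tgt, ref)
        assert m.bp_nd_ == pytest.approx(bp, rel=0.02)
        assert m.R1_ == pytest.approx(R1, rel=0.02)
        assert m.k2_ == pytest.approx(k2, rel=0.02)

    def test_nonpositive_reference_rejected(self, schedule, input_fn):
        ref = self._reference(schedule, input_fn)
        bad = TimeActivityCurve("pons", np.zeros(schedule.n_frames), schedule)
        with pytest.raises(ValueError, match="positive"):
            SRTM().fit(ref, bad)

    def test_mismatched_schedule_rejected(self, schedule, input_fn):
        ref = self._reference(schedule, input_fn)
        other = build_frame_schedule([(4, 60.0)], 0.0)
        tac = TimeActivityCurve("r", np.ones(4), other)
        with pytest.raises(ValueError, match="schedule"):
            SRTM().fit(tac, ref)


def test_functional_wrapper_matches_estimator(schedule, input_fn):
    truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
    tac = simulate_tac(truth, input_fn, schedule, noise_scale=1.0, seed=8)
    assert fit_2kbv(tac, input_fn).vt == OneTissueModel().fit(tac, input_fn).vt_
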