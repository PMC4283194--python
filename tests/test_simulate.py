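"""The synthetic generator: input functions, TACs, phantoms, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from cb1tacs.core import TimeActivityCurve, default_schedule
from cb1tacs.kinetic import OneTissueModel
from cb1tacs.simulate import (REGION_VT_PROFILE, FengInputParams, TruthEntry,
                              block_masks, noise_free_tac, simulate_cohort,
                              simulate_input, simulate_phantom, simulate_tac)


class TestSimulateInput:
    def test_bolus_shape(self, input_fn):
        cp = input_fn.parent_plasma
        peak = int(np.argmax(cp))
        assert 30.0 <= input_fn.time[peak] <= 120.0  # peak in 0.5-2 min
        assert np.all(np.diff(cp[:peak]) >= 0)
        assert np.all(np.diff(cp[peak:]) <= 1e-12)

    def test_seed_jitter_reproducible(self):
        a = simulate_input(seed=5)
        b = simulate_input(seed=5)
        c = simulate_input(seed=6)
        assert np.array_equal(a.parent_plasma, b.parent_plasma)
        assert not np.array_equal(a.parent_plasma, c.parent_plasma)

    def test_negative_tail_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_input(FengInputParams(l3=-0.01))

    def test_zero_amplitude_input_rejected_by_fitter(self, schedule):
        inp = simulate_input(amplitude_scale=0.0)
        truth = TruthEntry(K1=0.1, k2=0.02)
        tac = simulate_tac(truth, inp, schedule, noise_scale=0.0)
        with pytest.raises(ValueError, match="zero"):
            OneTissueModel().fit(tac, inp)

    def test_amplitude_scale_invariance_of_vt(self, schedule):
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        vts = []
        for amp in (1.0, 2.0):
            inp = simulate_input(amplitude_scale=amp)
            tac = simulate_tac(truth, inp, schedule, noise_scale=0.0)
            vts.append(OneTissueModel().fit(tac, inp).vt_)
        assert vts[0] == pytest.approx(vts[1], rel=1e-6)


class TestSimulateTac:
    def test_noise_free_matches_quadrature_oracle(self, schedule, input_fn):
        """Frame values equal the analytic convolution averaged per frame."""
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        cp = lambda s: np.interp(s, input_fn.time, input_fn.parent_plasma)
        cb = lambda s: np.interp(s, input_fn.time, input_fn.whole_blood)
        k2s = truth.k2 / 60.0

        def model(t):  # t seconds post-injection
            conv = quad(lambda s: cp(s) * np.exp(-k2s * (t - s)), 0, t,
                        limit=500)[0]
            return (1 - truth.bv) * truth.K1 / 60.0 * conv + truth.bv * cb(t)

        for i in (3, 12, 25, 32):
            lo = schedule.frame_start[i] - schedule.injection_offset
            hi = schedule.frame_end[i] - schedule.injection_offset
            ref = quad(model, max(lo, 0.0), hi, limit=200)[0] / (hi - lo)
            assert tac.values[i] == pytest.approx(ref, rel=2e-3)

    def test_no_uptake_is_scaled_blood(self, schedule, input_fn):
        from cb1tacs.core import frame_average
        truth = TruthEntry(K1=0.0, k2=0.02, bv=0.05)
        tac = simulate_tac(truth, input_fn, schedule, noise_scale=0.0)
        t = np.arange(0.0, schedule.total_duration
                      - schedule.injection_offset + 1.0)
        blood = frame_average(input_fn.blood_on_grid(t), 1.0, schedule,
                              time_origin="injection")
        assert np.allclose(tac.values, 0.05 * blood)

    def test_noise_is_zero_mean(self, schedule, input_fn):
        truth = TruthEntry(K1=0.15, k2=0.02, bv=0.05)
        clean = simulate_tac(truth, input_fn, schedule, noise_scale=0.0).values
        rng = np.random.default_rng(11)
        reps = np.stack([
            simulate_tac(truth, input_fn, schedule, noise_scale=1.0,
                         seed=rng).values
            for _ in range(1000)])
        sd = reps.std(axis=0) / np.sqrt(len(reps))
        late = slice(10, None)  # frames with non-trivial signal
        z = (reps.mean(axis=0)[late] - clean[late]) / sd[late]
        assert np.all(np.abs(z) < 4.5)

    def test_schedule_beyond_input_support_rejected(self, schedule):
        short = simulate_input(t_max=1000.0)
        with pytest.raises(ValueError, match="support"):
            simulate_tac(TruthEntry(K1=0.1, k2=0.02), short, schedule)


class TestSimulateCohort:
    def test_reproducible_from_seed(self):
        a, ta = simulate_cohort(n_subjects=3, seed=9)
        b, tb = simulate_cohort(n_subjects=3, seed=9)
        pd.testing.assert_frame_equal(ta.frame, tb.frame)
        for sa, sb in zip(a, b):
            for r in sa.tacs:
                assert np.array_equal(sa.tacs[r].values, sb.tacs[r].values)

    def test_zero_within_subject_cv_gives_identical_sessions(self):
        _, truth = simulate_cohort(n_subjects=4, ws_cv=0.0, noise_scale=0.0,
                                   seed=3)
        vt = truth.vt_table()
        test = vt.xs("test", level="session")
        retest = vt.xs("retest", level="session")
        assert np.allclose(test.to_numpy(), retest.to_numpy())

    def test_between_subject_cv_near_requested(self):
        _, truth = simulate_cohort(n_subjects=15, bs_cv=0.35, ws_cv=0.0,
                                   seed=21)
        vt = truth.vt_table()["pallidum"].to_numpy()
        subj_means = vt.reshape(-1, 2).mean(axis=1)
        cv = subj_means.std(ddof=1) / subj_means.mean()
        assert cv == pytest.approx(0.35, rel=0.35)

    def test_profile_ratio_pallidum_over_pons(self):
        assert (REGION_VT_PROFILE["pallidum"] / REGION_VT_PROFILE["pons"]
                == pytest.approx(3.6, abs=0.01))
        _, truth = simulate_cohort(n_subjects=5, seed=2)
        vt = truth.vt_table()
        ratio = np.median(vt["pallidum"] / vt["pons"])
        assert ratio == pytest.approx(3.6, rel=1e-6)  # shared factors cancel

    def test_demographics_within_reference_ranges(self):
        sessions, _ = simulate_cohort(n_subjects=10, seed=4)
        for s in sessions:
            assert 25 <= s.age <= 65
            assert 316 <= s.injected_dose <= 399
            assert 1 <= s.scan_interval <= 309
            assert s.weight > 0

    def test_rejects_degenerate_requests(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=1)
        with pytest.raises(ValueError):
            simulate_cohort(n_subjects=3, bs_cv=-0.1)


class TestSimulatePhantom:
    def test_uniform_regions_and_background(self, schedule, input_fn):
        shape = (8, 8, 4)
        masks = block_masks(shape, ["a", "b"])
        masks = {k: m for k, m in masks.items()}
        # free half the grid: shrink masks to 2 slabs of 2
        for k in masks:
            masks[k][4:, :, :] = False
        truth = {"a": TruthEntry(K1=0.15, k2=0.02, bv=0.05),
                 "b": TruthEntry(K1=0.1, k2=0.05, bv=0.05)}
        vol = simulate_phantom(shape, masks, truth, input_fn, schedule,
                               noise_scale=0.0, seed=0)
        va = vol[masks["a"]]
        assert np.allclose(va, va[0])       # identical TACs within a region
        outside = ~(masks["a"] | masks["b"])
        assert np.all(vol[outside] == 0.0)  # untouched background

    def test_region_mean_matches_roi_tac(self, schedule, input_fn):
        shape = (4, 4, 2)
        masks = block_masks(shape, ["a", "b"])
        truth = {"a": TruthEntry(K1=0.15, k2=0.02, bv=0.05),
                 "b": TruthEntry(K1=0.1, k2=0.05, bv=0.05)}
        vol = simulate_phantom(shape, masks, truth, input_fn, schedule,
                               noise_scale=0.5, seed=12)
        roi = noise_free_tac(truth["a"], input_fn, schedule)
        mean_tac = vol[masks["a"]].mean(axis=0)
        sd = 0.5 * np.sqrt(np.clip(roi, 0, None) / schedule.frame_duration)
        sd_mean = sd / np.sqrt(masks["a"].sum())
        ok = sd_mean > 0
        assert np.all(np.abs(mean_tac[ok] - roi[ok]) < 5 * sd_mean[ok])

    def test_overlapping_masks_rejected(self, schedule, input_fn):
        shape = (4, 4, 2)
        m = np.ones(shape, dtype=bool)
        with pytest.raises(ValueError, match="overlap"):
            simulate_phantom(shape, {"a": m, "b": m},
                             {"a": TruthEntry(K1=0.1, k2=0.02),
                              "b": TruthEntry(K1=0.1, k2=0.02)},
                             input_fn, schedule)
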