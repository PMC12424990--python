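import numpy as np
import pandas as pd
import pytest

import slicepasef as sp
from slicepasef.scheme import FrameKind
from slicepasef.simulate import FrameSpectrum

from conftest import fragments_of

NOISELESS = dict(mz_jitter_ppm=0.0, im_jitter_sd=0.0, intensity_cv=0.0,
                 noise_peaks_per_frame=0)


def make_frame(peaks, subcycle=0, frame=0, repeat=0, rt=10.0, kind=FrameKind.MS2):
    """peaks: list of (mz, intensity, inv_k0, q1_lo, q1_hi)."""
    arr = np.array(peaks, dtype=float).reshape(-1, 5)
    return FrameSpectrum(rt_s=rt, cycle_index=0, subcycle_index=subcycle,
                         frame_index=frame, repeat_index=repeat, kind=kind,
                         mz=arr[:, 0], intensity=arr[:, 1], inv_k0=arr[:, 2],
                         q1_lo=arr[:, 3], q1_hi=arr[:, 4])


def prec(mz, ik0):
    return sp.PrecursorIon(id="p", mz=mz, charge=2, inv_k0=ik0,
                           intensity=1.0, rt_apex_s=10.0, rt_fwhm_s=2.0)


class TestCandidateFrames:
    def test_boundary_containment_qualifies(self):
        fr = make_frame([(620.0, 10.0, 0.90, 400.0, 700.0)])
        assert sp.candidate_frames(prec(500.0, 0.90), [fr]) == [fr]

    def test_im_mismatch_disqualifies(self):
        fr = make_frame([(620.0, 10.0, 0.90, 400.0, 700.0)])
        assert sp.candidate_frames(prec(500.0, 0.70), [fr]) == []

    def test_mz_outside_boundaries_disqualifies(self):
        fr = make_frame([(620.0, 10.0, 0.90, 400.0, 700.0)])
        assert sp.candidate_frames(prec(700.0, 0.90), [fr]) == []

    def test_matches_bruteforce_peak_scan(self, joint_subcloud, one_f,
                                          reference_scheme):
        """Candidate sets equal an exhaustive scan over every peak, for
        random precursors against simulated frames of both schemes."""
        rng = np.random.default_rng(23)
        cfg = sp.MatchConfig()
        sim = sp.SimConfig(seed=2, noise_peaks_per_frame=30, intensity_cv=0.05)
        for scheme in (one_f, reference_scheme):
            stream = [f for f in sp.simulate_acquisition(
                joint_subcloud, scheme, sim, (28.0, 31.0))
                if f.kind is FrameKind.MS2][:16]
            peak_lists = [f.peaks() for f in stream]
            mzs = rng.uniform(380.0, 1020.0, size=500)
            iks = rng.uniform(0.7, 1.25, size=500)
            for mz, ik in zip(mzs, iks):
                p = sp.PrecursorIon(id="q", mz=mz, charge=2, inv_k0=ik,
                                    intensity=1.0, rt_apex_s=1.0, rt_fwhm_s=1.0)
                got = sp.candidate_frames(p, stream, cfg)
                brute = [f for f, pks in zip(stream, peak_lists) if any(
                    (pk.q1_lo <= mz < pk.q1_hi)
                    and abs(pk.inv_k0 - ik) <= cfg.im_tol
                    for pk in pks)]
                assert got == brute


class TestFragmentIntensity:
    frag = sp.FragmentIon(parent_id="p", mz=620.0, rel_intensity=0.5)

    def test_max_across_frames(self):
        f1 = make_frame([(620.0, 100.0, 0.90, 400.0, 700.0)], frame=0)
        f2 = make_frame([(620.0, 250.0, 0.90, 400.0, 700.0)], frame=1)
        got = sp.fragment_intensity_multiframe(self.frag, prec(500.0, 0.90), [f1, f2])
        assert got == 250.0

    def test_no_match_gives_zero(self):
        f1 = make_frame([(900.0, 100.0, 0.90, 400.0, 700.0)])
        assert sp.fragment_intensity_multiframe(self.frag, prec(500.0, 0.90), [f1]) == 0.0

    def test_tie_resolves_to_lower_frame_deterministically(self):
        f1 = make_frame([(620.0, 250.0, 0.90, 400.0, 700.0)], frame=0)
        f2 = make_frame([(620.0, 250.0, 0.90, 400.0, 700.0)], frame=1)
        a = sp.fragment_intensity_multiframe(self.frag, prec(500.0, 0.90), [f1, f2])
        b = sp.fragment_intensity_multiframe(self.frag, prec(500.0, 0.90), [f2, f1])
        assert a == b == 250.0

    def test_ppm_tolerance_boundary(self):
        cfg = sp.MatchConfig(mz_tol_ppm=15.0)
        off = 620.0 * (1 + 20e-6)  # 20 ppm away: outside tolerance
        fr = make_frame([(off, 100.0, 0.90, 400.0, 700.0)])
        assert sp.fragment_intensity_multiframe(self.frag, prec(500.0, 0.90),
                                                [fr], cfg) == 0.0


class TestMergeRepeats:
    def test_identical_peaks_sum(self):
        r0 = make_frame([(620.0, 50.0, 0.90, 400.0, 700.0)], repeat=0)
        r1 = make_frame([(620.0, 50.0, 0.90, 400.0, 700.0)], repeat=1)
        merged = sp.merge_repeats([r0, r1])
        assert merged.n_peaks == 1
        assert merged.intensity[0] == 100.0
        assert merged.mz[0] == 620.0

    def test_single_repeat_identity(self):
        r0 = make_frame([(620.0, 50.0, 0.90, 400.0, 700.0)])
        assert sp.merge_repeats([r0]) is r0

    def test_differing_boundaries_not_merged(self):
        r0 = make_frame([(620.0, 50.0, 0.90, 400.0, 700.0)], repeat=0)
        r1 = make_frame([(620.0, 50.0, 0.90, 500.0, 800.0)], repeat=1)
        merged = sp.merge_repeats([r0, r1])
        assert merged.n_peaks == 2

    def test_weighted_mean_coordinates(self):
        r0 = make_frame([(620.000, 100.0, 0.90, 400.0, 700.0)], repeat=0)
        r1 = make_frame([(620.002, 300.0, 0.92, 400.0, 700.0)], repeat=1)
        merged = sp.merge_repeats([r0, r1], sp.MatchConfig(mz_tol_ppm=15, im_tol=0.05))
        assert merged.n_peaks == 1
        assert merged.mz[0] == pytest.approx((620.0 * 100 + 620.002 * 300) / 400)
        assert merged.inv_k0[0] == pytest.approx((0.90 * 100 + 0.92 * 300) / 400)

    def test_total_intensity_conserved_on_random_repeats(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            reps = []
            for r in range(rng.integers(1, 4)):
                n = int(rng.integers(1, 40))
                peaks = np.column_stack([
                    rng.uniform(300, 1000, n), rng.lognormal(3, 1, n),
                    rng.uniform(0.7, 1.2, n),
                    np.full(n, 400.0), np.full(n, 700.0)])
                reps.append(make_frame(peaks.tolist(), repeat=r))
            merged = sp.merge_repeats(reps)
            total_in = sum(f.intensity.sum() for f in reps)
            assert merged.intensity.sum() == pytest.approx(total_in, rel=1e-12)

    def test_mismatched_position_is_contract_error(self):
        r0 = make_frame([(620.0, 50.0, 0.90, 400.0, 700.0)], frame=0)
        r1 = make_frame([(620.0, 50.0, 0.90, 400.0, 700.0)], frame=1)
        with pytest.raises(ValueError, match="scheme positions"):
            sp.merge_repeats([r0, r1])


class TestXIC:
    def test_points_at_fwhm_1f_with_ms1(self, small_cloud, joint_subcloud):
        """2 s peak sampled by a 0.2 s cycle (MS1 + MS2) -> ~10 points."""
        cfg = sp.DesignConfig(im_range=(0.75, 1.2), mz_range=(400.0, 1000.0),
                              ms1_per_subcycle=1)
        scheme = sp.design_1f(small_cloud, cfg)
        one = joint_subcloud.subset([joint_subcloud.ions["id"].iloc[0]])
        p = one.precursors()[0]
        stream = sp.simulate_acquisition(one, scheme, sp.SimConfig(**NOISELESS),
                                         (p.rt_apex_s - 4, p.rt_apex_s + 4))
        xic = sp.extract_xic(p, fragments_of(one, p), stream)
        assert abs(xic.points_at_fwhm - 10) <= 1

    def test_fewer_points_on_slower_cycle(self, joint_subcloud, one_f,
                                          reference_scheme):
        one = joint_subcloud.subset([joint_subcloud.ions["id"].iloc[0]])
        p = one.precursors()[0]
        window = (p.rt_apex_s - 4, p.rt_apex_s + 4)
        sim = sp.SimConfig(**NOISELESS)
        x1 = sp.extract_xic(p, fragments_of(one, p),
                            sp.simulate_acquisition(one, one_f, sim, window))
        xr = sp.extract_xic(p, fragments_of(one, p),
                            sp.simulate_acquisition(one, reference_scheme, sim, window))
        assert xr.points_at_fwhm < x1.points_at_fwhm

    def test_triangle_area_matches_closed_form(self):
        # symmetric triangle peak: apex 100 at t=5, half-max width 5
        rt = np.arange(11, dtype=float)
        y = 100.0 - 20.0 * np.abs(rt - 5.0)
        y[y < 0] = 0.0
        xic = sp.XIC(rt_s=rt, intensity=y, apex=100.0, area=0.0,
                     total_signal=float(y.sum()), points_at_fwhm=0, all_zero=False)
        from slicepasef.matcher import _xic_stats
        apex, area, pts, _ = _xic_stats(rt, y)
        assert apex == 100.0
        # region above half apex: t in [3, 7], trapezoid of the triangle top
        expected = 2 * (0.5 * (60.0 + 80.0) + 0.5 * (80.0 + 100.0))
        assert area == pytest.approx(expected)
        assert pts == 5

    def test_all_zero_trace_flagged(self):
        fr = make_frame([(620.0, 0.0, 0.90, 400.0, 700.0)])
        p = prec(500.0, 0.90)
        xic = sp.extract_xic(p, [sp.FragmentIon("p", 900.0, 0.5)], [fr])
        assert xic.all_zero
        assert sp.quantify(xic) == 0.0


class TestEndToEndDutyOracle:
    def test_noiseless_ratio_is_8_per_precursor(self, joint_subcloud, one_f,
                                                reference_scheme):
        """Quantified 1F / reference signal equals the duty ratio of 8
        within 1% for every jointly covered precursor."""
        sim = sp.SimConfig(**NOISELESS)
        window = (24.0, 40.0)
        s1 = sp.simulate_acquisition(joint_subcloud, one_f, sim, window)
        sr = sp.simulate_acquisition(joint_subcloud, reference_scheme, sim, window)
        n = 0
        for p in joint_subcloud.precursors():
            frags = fragments_of(joint_subcloud, p)
            q1 = sp.quantify(sp.extract_xic(p, frags, s1))
            qr = sp.quantify(sp.extract_xic(p, frags, sr))
            if qr > 0:
                assert q1 / qr == pytest.approx(8.0, rel=0.01)
                n += 1
        assert n >= 10

    def test_cv_recovery_from_replicates(self, joint_subcloud, one_f):
        """Median measured CV across 5 replicate runs tracks the injected
        run-level intensity CV within +/-20%."""
        c = 0.2
        quants = []
        for rep in range(5):
            sim = sp.SimConfig(seed=200 + rep, intensity_cv=c,
                               noise_peaks_per_frame=0)
            stream = sp.simulate_acquisition(joint_subcloud, one_f, sim,
                                             (26.0, 38.0))
            for p in joint_subcloud.precursors():
                xic = sp.extract_xic(p, fragments_of(joint_subcloud, p), stream)
                quants.append((p.id, f"run{rep}", sp.quantify(xic)))
        df = pd.DataFrame(quants, columns=["precursor_id", "run", "quantity"])
        summary = sp.cv_summary(df)
        assert (summary["n"] == 5).all()
        med = summary["cv"].median()
        assert 0.8 * c <= med <= 1.2 * c

    def test_noiseless_replicates_have_zero_cv(self, joint_subcloud, one_f):
        sim = sp.SimConfig(**NOISELESS, seed=7)
        vals = []
        for _ in range(3):
            stream = sp.simulate_acquisition(joint_subcloud, one_f, sim, (28.0, 33.0))
            p = joint_subcloud.precursors()[0]
            vals.append(sp.quantify(sp.extract_xic(
                p, fragments_of(joint_subcloud, p), stream)))
        assert sp.cv(vals) == 0.0


class TestCV:
    def test_zero_variance(self):
        assert sp.cv([5.0, 5.0, 5.0]) == 0.0

    def test_direct_formula(self):
        # sd([1,2,3], ddof=1) = 1, mean = 2
        assert sp.cv([1.0, 2.0, 3.0]) == pytest.approx(0.5)

    def test_n2_suppressed_by_default_policy(self):
        df = pd.DataFrame({"precursor_id": ["a", "a"], "run": ["r1", "r2"],
                           "quantity": [1.0, 2.0]})
        out = sp.cv_summary(df)
        assert bool(out.loc[0, "suppressed"])
        assert np.isnan(out.loc[0, "cv"])
        assert out.loc[0, "cv_unsuppressed"] == pytest.approx(
            np.std([1.0, 2.0], ddof=1) / 1.5)

    def test_zero_mean_flagged_nan(self):
        assert np.isnan(sp.cv([1.0, -1.0]))
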