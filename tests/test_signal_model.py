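"""SPGR physics: forward signal, VFA T1 mapping, concentration conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcepk.signal_model import (AcquisitionParams, ConcentrationSeries,
                                DynamicSeries, T1Map, VFASeries,
                                concentration_to_signal, fit_t10_vfa,
                                signal_to_concentration, spgr_signal)

from oracles import concentration_to_signal_oracle, spgr_signal_oracle


def make_vfa(t1_grid, acq, s0=1.0, noise=None, rng=None):
    """Simulate a VFA stack from a T1 grid via the forward SPGR model."""
    t1_grid = np.atleast_2d(t1_grid)
    sig = np.stack([spgr_signal(t1_grid, s0, acq, tr=acq.vfa_tr, flip_angle=a)
                    for a in acq.vfa_angles], axis=-1)
    if noise:
        sig = sig + rng.normal(0.0, noise, sig.shape)
    return VFASeries(signals=sig, angles=acq.vfa_angles,
                     mask=np.ones(t1_grid.shape, dtype=bool))


class TestSpgrSignal:
    def test_zero_flip_angle_gives_zero_signal(self, acq):
        assert spgr_signal(2.0, 1.0, acq, flip_angle=1e-12) == pytest.approx(0.0)

    def test_long_t1_limit_vanishes(self, acq):
        assert spgr_signal(1e9, 1.0, acq) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("t1,tr,theta", [(2.0, 0.1, 30.0), (1.2, 0.043, 30.0),
                                             (0.5, 0.1, 5.0), (3.0, 0.043, 90.0)])
    def test_matches_independent_formula_evaluation(self, acq, t1, tr, theta):
        ours = spgr_signal(t1, 1.0, acq, tr=tr, flip_angle=theta)
        assert ours == pytest.approx(spgr_signal_oracle(t1, 1.0, tr, theta),
                                     rel=1e-12)

    def test_nonpositive_t1_rejected(self, acq):
        with pytest.raises(ValueError):
            spgr_signal(-1.0, 1.0, acq)


class TestVfaT1Mapping:
    def test_known_slope_inverts_analytically(self, acq):
        """Constant slope Sp = e^-0.05 at Tr = 0.1 s maps to T10 = 2.0 s."""
        t1 = 2.0
        vfa = make_vfa(np.array([[t1]]), acq)
        out = fit_t10_vfa(vfa, acq)
        assert out.slope[0, 0] == pytest.approx(np.exp(-acq.vfa_tr / t1), rel=1e-10)
        assert -0.1 / np.log(np.exp(-0.05)) == pytest.approx(2.0, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(t1=st.floats(0.1, 5.0))
    def test_noise_free_roundtrip_recovers_t1(self, t1):
        acq = AcquisitionParams()
        vfa = make_vfa(np.array([[t1]]), acq)
        out = fit_t10_vfa(vfa, acq)
        assert out.valid[0, 0]
        assert out.t10[0, 0] == pytest.approx(t1, rel=1e-8)

    def test_all_zero_voxel_flagged_invalid(self, acq):
        sig = np.zeros((1, 1, 4))
        vfa = VFASeries(signals=sig, angles=acq.vfa_angles,
                        mask=np.ones((1, 1), bool))
        out = fit_t10_vfa(vfa, acq)
        assert not out.valid[0, 0]
        assert np.isnan(out.t10[0, 0])

    def test_fewer_than_two_angles_rejected(self, acq):
        with pytest.raises(ValueError):
            VFASeries(signals=np.ones((1, 1, 1)), angles=(10.0,),
                      mask=np.ones((1, 1), bool))

    def test_noisy_median_recovery_within_5pct(self, acq, rng):
        """Monte-Carlo: 1% Gaussian SI noise at T1 = 1.8 s, many repeats."""
        n = 10_000
        t1 = 1.8
        vfa = make_vfa(np.full((n, 1), t1), acq, noise=0.01 *
                       spgr_signal(t1, 1.0, acq, tr=acq.vfa_tr,
                                   flip_angle=acq.vfa_angles[-1]), rng=rng)
        out = fit_t10_vfa(vfa, acq)
        med = np.nanmedian(out.t10[out.valid])
        assert med == pytest.approx(t1, rel=0.05)


def _uniform_t1map(shape, t10, acq):
    t = np.full(shape, float(t10))
    return T1Map(t10=t, slope=np.exp(-acq.vfa_tr / t),
                 mask=np.ones(shape, bool), valid=np.ones(shape, bool))


class TestConcentrationConversion:
    def test_baseline_signal_maps_to_zero_concentration(self, acq):
        t1map = _uniform_t1map((2, 2), 2.0, acq)
        base = spgr_signal(2.0, 100.0, acq)
        sig = np.full((2, 2, 12), base)
        dyn = DynamicSeries(signal=sig, time=np.arange(12) * acq.dt,
                            mask=np.ones((2, 2), bool))
        conc = signal_to_concentration(dyn, t1map, acq)
        assert np.allclose(conc.ct, 0.0, atol=1e-12)

    def test_half_millimolar_roundtrip(self, acq):
        # 1/T1 = 1/2.0 + 3.11 * 0.5 = 2.055 s^-1
        t1map = _uniform_t1map((1, 1), 2.0, acq)
        ct = np.zeros((1, 1, 10))
        ct[..., 5:] = 0.5
        cs = ConcentrationSeries(ct=ct, time=np.arange(10) * acq.dt,
                                 mask=np.ones((1, 1), bool), arrival_index=5)
        dyn = concentration_to_signal(cs, t1map, acq, m0=50.0)
        rec = signal_to_concentration(dyn, t1map, acq)
        assert rec.ct[0, 0, 7] == pytest.approx(0.5, abs=1e-9)
        r1_post = 1.0 / 2.0 + acq.r1 * 0.5
        assert r1_post == pytest.approx(2.055, abs=1e-12)

    def test_forward_matches_independent_formula(self, acq):
        t1map = _uniform_t1map((1, 1), 2.0, acq)
        ct = np.full((1, 1, 10), 1.0)
        cs = ConcentrationSeries(ct=ct, time=np.arange(10) * acq.dt,
                                 mask=np.ones((1, 1), bool))
        dyn = concentration_to_signal(cs, t1map, acq, m0=1.0)
        expected = concentration_to_signal_oracle(1.0, 2.0, acq.r1, acq.tr,
                                                  acq.flip_angle)
        assert dyn.signal[0, 0, 3] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ct_val=st.floats(0.0, 3.0), t10=st.floats(0.5, 4.0))
    def test_conversion_pair_are_mutual_inverses(self, ct_val, t10):
        acq = AcquisitionParams()
        t1map = _uniform_t1map((1, 1), t10, acq)
        ct = np.zeros((1, 1, 10))
        ct[..., acq.baseline_frames:] = ct_val  # pre-contrast baseline first
        cs = ConcentrationSeries(ct=ct, time=np.arange(10) * acq.dt,
                                 mask=np.ones((1, 1), bool))
        dyn = concentration_to_signal(cs, t1map, acq, m0=10.0)
        rec = signal_to_concentration(dyn, t1map, acq)
        assert np.allclose(rec.ct, ct, atol=1e-9)

    def test_concentration_monotone_in_relaxation_rate(self, acq):
        """Ct is strictly increasing in 1/T1 at fixed T10."""
        t10 = 2.0
        r1_grid = np.linspace(1.0 / t10 + 1e-3, 6.0, 40)
        ct = (r1_grid - 1.0 / t10) / acq.r1
        assert np.all(np.diff(ct) > 0)

    def test_relaxivity_linearity(self, acq):
        """Doubling r1 halves the recovered concentration exactly."""
        t1map = _uniform_t1map((1, 1), 2.0, acq)
        ct = np.zeros((1, 1, 10))
        ct[..., acq.baseline_frames:] = 0.8
        cs = ConcentrationSeries(ct=ct, time=np.arange(10) * acq.dt,
                                 mask=np.ones((1, 1), bool))
        dyn = concentration_to_signal(cs, t1map, acq, m0=10.0)
        acq2 = AcquisitionParams(r1=2 * acq.r1)
        rec = signal_to_concentration(dyn, t1map, acq2)
        assert np.allclose(rec.ct[..., acq.baseline_frames:], 0.4, atol=1e-9)

    def test_phantom_concentration_recovered_exactly(self, micro_study, acq):
        """Noise-free phantom: forward-simulated signal inverts to truth Ct."""
        t1map = fit_t10_vfa(micro_study.vfa, acq)
        rec = signal_to_concentration(micro_study.dynamic, t1map, acq)
        m = micro_study.brain_mask
        sel = np.broadcast_to(m[:, :, np.newaxis, :],
                              rec.ct.shape) if rec.ct.ndim == 4 else m
        err = np.abs(rec.ct - micro_study.concentration.ct)[sel]
        assert np.nanmax(err) < 1e-8
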