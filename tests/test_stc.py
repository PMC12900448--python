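import math

import numpy as np
import pytest

from synplast.plasticity.calcium import calcium_events
from synplast.plasticity.stc import (PROTOCOLS, PrpPool, StcParams,
                                     StcSynapse, prp_step, run_stc_synapse,
                                     stc_protocol, stc_step)
from synplast.rng import NoiseStream

P = StcParams()


class TestParameterIdentities:
    def test_baseline_weight_from_rates(self):
        assert 0.5 * P.gamma_p / (P.gamma_p + P.gamma_d) * 10.0 == \
            pytest.approx(P.h0, abs=5e-4)

    def test_thresholds_are_fixed_fractions_of_h0(self):
        # printed to five decimals, so agreement to half an ulp of print
        assert 0.5 * P.h0 == pytest.approx(P.theta_pro, abs=6e-6)
        assert 0.2 * P.h0 == pytest.approx(P.theta_tag, abs=5e-6)

    def test_in_vivo_correction(self):
        q = P.in_vivo()
        assert q.c_pre == pytest.approx(0.6)
        assert q.c_post == pytest.approx(0.2758 * 0.6)


class TestStcStep:
    def test_baseline_is_fixed_point(self):
        syn = StcSynapse(P)
        pool = PrpPool(P)
        for _ in range(1000):
            stc_step(syn, pool, 0.5)
        assert syn.h == pytest.approx(P.h0, abs=1e-12)
        assert syn.z == 0.0

    def test_total_weight_composition(self):
        syn = StcSynapse(P, h=6.0, z=0.25)
        assert syn.weight == pytest.approx(6.0 + P.h0 * 0.25)

    def test_presynaptic_calcium_delayed(self):
        syn = StcSynapse(P)
        pool = PrpPool(P)
        stc_step(syn, pool, 0.5, [("pre", 0.0)])
        assert syn.c == 0.0
        for _ in range(int(P.tc_delay / 0.5)):
            stc_step(syn, pool, 0.5)
        assert syn.c > 0.5  # influx arrived (and started to decay)

    def test_sustained_potentiation_drift_fixed_point(self):
        # c above both thresholds: h -> (0.1 h0 + 10 gamma_p)/(0.1 + gp + gd)
        syn = StcSynapse(P)
        pool = PrpPool(P)
        target = ((0.1 * P.h0 + 10.0 * P.gamma_p)
                  / (0.1 + P.gamma_p + P.gamma_d))
        assert target == pytest.approx(8.402, abs=2e-3)
        for _ in range(40_000):
            syn.c = 10.0  # clamp above theta_p
            stc_step(syn, pool, 0.5)
        assert syn.h == pytest.approx(target, abs=1e-3)

    def test_late_phase_growth_rate_at_full_prp(self):
        # tag on, p = p_max, f_int = 0.1 l/umol: dz/dt = (1-z)/tau_z
        syn = StcSynapse(P, h=P.h0 + 2.0)  # tagged (2.0 > theta_tag)
        pool = PrpPool(P, p=P.p_max)
        dt = 1000.0
        n = int(3600e3 / dt)  # one hour = one late-phase time constant
        for _ in range(n):
            stc_step(syn, pool, dt)
            syn.h = P.h0 + 2.0  # hold the tag
        assert syn.z == pytest.approx(1.0 - math.exp(-1.0), rel=2e-3)

    def test_noise_off_matches_dense_oracle(self):
        from oracles import stc_dense_euler

        pre = 1000.0 * np.arange(10)
        post = pre + 15.0
        t_end = 11_000.0
        dt = 0.01
        res = run_stc_synapse(pre, post, P, None, t_end, dt=dt)
        ev = calcium_events(pre, post, P.c_pre, P.c_post, P.tc_delay)
        h_ref = stc_dense_euler(ev[:, 0].copy(), ev[:, 1].copy(), dt / 100.0,
                                t_end, P.h0, P.tau_c, P.tau_h, P.gamma_p,
                                P.gamma_d, P.theta_p, P.theta_d, P.h_max)
        assert abs(res["h"] - h_ref) / abs(h_ref) < 1e-4

    def test_noisy_state_bounds(self):
        # strong random stimulation, many trials: h in [0, 10],
        # z in [-0.5, 1], p in [0, p_max]
        for trial in range(40):
            stream = NoiseStream((101, trial))
            pre = np.sort(stream.uniforms(200) * 20_000.0)
            post = np.sort(stream.uniforms(50) * 20_000.0)
            noise = NoiseStream((102, trial))
            res = run_stc_synapse(pre, post, P, noise, 25_000.0, dt=0.5)
            assert 0.0 <= res["h"] <= 10.0
            assert -0.5 <= res["z"] <= 1.0
            assert 0.0 <= res["p"] <= P.p_max


class TestPrpPool:
    def test_subthreshold_stays_at_zero(self):
        pool = PrpPool(P)
        prp_step(pool, 0.5 * P.theta_pro, 60e3)
        assert pool.p == 0.0

    def test_subthreshold_decay_with_tau_p(self):
        pool = PrpPool(P, p=4.0)
        prp_step(pool, 0.0, P.tau_p)  # one time constant = 60 min
        assert pool.p == pytest.approx(4.0 / math.e, rel=1e-12)

    def test_suprathreshold_saturates_at_pmax(self):
        pool = PrpPool(P)
        for _ in range(100):
            prp_step(pool, 2 * P.theta_pro, P.tau_p)
        assert pool.p == pytest.approx(P.p_max, rel=1e-9)


class TestProtocols:
    @pytest.fixture(scope="class")
    def outcomes(self):
        return {name: stc_protocol(name, seed=2, n_trials=5)
                for name in PROTOCOLS}

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            stc_protocol("TBS")

    def test_stet_consolidates(self, outcomes):
        r = outcomes["STET"]
        assert r["tag_crossed"].all() and r["pro_crossed"].all()
        assert r["z"].mean() > 0.5

    def test_wtet_early_only(self, outcomes):
        r = outcomes["WTET"]
        assert r["tag_crossed"].all()
        assert not r["pro_crossed"].any()
        assert abs(r["z"].mean()) < 0.05

    def test_slfs_late_depression(self, outcomes):
        r = outcomes["SLFS"]
        assert r["pro_crossed"].all()
        assert r["z"].mean() < -0.1
        assert (r["h_end_protocol"] < P.h0).all()

    def test_wlfs_early_depression_only(self, outcomes):
        r = outcomes["WLFS"]
        assert (r["h_end_protocol"] < P.h0).all()
        assert abs(r["z"].mean()) < 0.05
        assert not r["pro_crossed"].any()

    def test_total_weight_identity_in_trace(self, outcomes):
        r = outcomes["STET"]
        assert r["w"] == pytest.approx(r["h"] + P.h0 * r["z"])
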