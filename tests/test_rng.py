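import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from synplast.rng import (NoiseStream, SdeSystem, CounterOverflowError,
                          draw_uniforms, draw_normal_pair,
                          euler_maruyama_step)


class TestNoiseStream:
    def test_same_key_counter_is_bitwise_identical(self):
        a = NoiseStream((1, 2, 3, 4), counter=7).draw_block()
        b = NoiseStream((1, 2, 3, 4), counter=7).draw_block()
        assert a == b

    @settings(max_examples=50, deadline=None, derandomize=True,
              database=None)
    @given(key=st.tuples(*[st.integers(0, 2**32 - 1)] * 4),
           counter=st.integers(0, 2**40))
    def test_statelessness_property(self, key, counter):
        assert (NoiseStream(key, counter).draw_block()
                == NoiseStream(key, counter).draw_block())

    def test_four_values_per_invocation_cache_refresh_on_depletion(self):
        s = NoiseStream((5,))
        block = draw_uniforms(s)
        assert len(block) == 4
        assert s.counter == 1
        vals = [s.uniform() for _ in range(4)]
        assert s.counter == 1  # served from cache
        s.uniform()
        assert s.counter == 2  # refreshed only on depletion
        assert all(0.0 <= v < 1.0 for v in list(block) + vals)

    def test_scalar_and_bulk_draws_agree(self):
        scalar = [NoiseStream((3, 1)).uniform() for _ in range(1)]
        s = NoiseStream((3, 1))
        seq = [s.uniform() for _ in range(11)]
        bulk = NoiseStream((3, 1)).uniforms(11)
        assert np.allclose(seq, bulk)
        assert scalar[0] == seq[0]

    def test_counter_overflow_is_hard_error(self):
        s = NoiseStream((1,), counter=2**64 - 1)
        with pytest.raises(CounterOverflowError):
            s.draw_block()

    def test_uniformity_chi_square(self):
        u = NoiseStream((11, 0, 0, 0)).uniforms(100_000)
        counts, _ = np.histogram(u, bins=100, range=(0, 1))
        _, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_distinct_keys_uncorrelated(self):
        n = 100_000
        a = NoiseStream((7, 0, 0, 0)).uniforms(n)
        b = NoiseStream((7, 0, 0, 1)).uniforms(n)  # differs in var index
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3.0 / math.sqrt(n)


class TestBoxMuller:
    def test_closed_form_values(self):
        z1, z2 = draw_normal_pair(0.5, 0.25)
        assert z1 == pytest.approx(0.0, abs=1e-12)
        assert z2 == pytest.approx(math.sqrt(-2 * math.log(0.5)), rel=1e-12)
        z1, z2 = draw_normal_pair(math.exp(-0.5), 0.0)
        assert (z1, z2) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_zero_u1_guarded(self):
        z1, z2 = draw_normal_pair(0.0, 0.3)
        assert np.isfinite(z1) and np.isfinite(z2)

    def test_moments(self):
        n = 200_000
        z = NoiseStream((13,)).normals(n)
        assert abs(z.mean()) < 3.0 / math.sqrt(n)
        assert z.var() == pytest.approx(1.0, abs=0.02)

    def test_both_outputs_consumed(self):
        s = NoiseStream((17,))
        z = [s.normal() for _ in range(4)]
        assert np.allclose(z, NoiseStream((17,)).normals(4))


class TestEulerMaruyama:
    def test_zero_drift_zero_diffusion_state_unchanged(self):
        sys = SdeSystem(np.array([2.0]), lambda t, x: 0 * x)
        euler_maruyama_step(sys, 0.0, 0.1)
        assert sys.state[0] == 2.0

    def test_deterministic_limit_is_forward_euler(self):
        sys = SdeSystem(np.array([1.0]), lambda t, x: -x)
        euler_maruyama_step(sys, 0.0, 0.01)
        assert sys.state[0] == pytest.approx(0.99, rel=1e-14)
        # zero diffusion functions match the no-diffusion trajectory
        sys2 = SdeSystem(np.array([1.0]), lambda t, x: -x,
                         diffusions=[lambda t, x: 0.0 * x],
                         streams=[NoiseStream((1,))])
        euler_maruyama_step(sys2, 0.0, 0.01)
        assert sys2.state[0] == sys.state[0]

    def test_mismatched_streams_rejected(self):
        with pytest.raises(ValueError):
            SdeSystem(np.array([0.0]), lambda t, x: x,
                      diffusions=[lambda t, x: x], streams=[])

    def test_nonfinite_drift_named(self):
        sys = SdeSystem(np.array([1.0]), lambda t, x: x / 0.0)
        with pytest.raises(FloatingPointError, match="drift"):
            euler_maruyama_step(sys, 0.0, 0.1)

    def test_increment_scaling(self):
        # empirical std of dW over many steps equals sqrt(dt) within 2%
        dt = 1e-3
        n = 100_000
        z = NoiseStream((23,)).normals(n) * math.sqrt(dt)
        assert z.std() == pytest.approx(math.sqrt(dt), rel=0.02)

    def test_ou_stationary_variance(self):
        # dX = -X dt + sqrt(2) dB has stationary variance 1
        dt = 1e-3
        stream = NoiseStream((29,))
        sys = SdeSystem(np.array([0.0]), lambda t, x: -x,
                        diffusions=[lambda t, x: math.sqrt(2.0)],
                        streams=[stream])
        n = 400_000
        # vectorized recurrence identical to repeated euler_maruyama_step
        z = stream.normals(n)
        x = np.empty(n)
        xi = 0.0
        a = 1.0 - dt
        b = math.sqrt(2.0 * dt)
        from scipy.signal import lfilter
        x = lfilter([b], [1.0, -a], z)
        # spot-check the recurrence against the stepper
        sys.state = np.array([0.0])
        stream2 = NoiseStream((29,))
        sys2 = SdeSystem(np.array([0.0]), lambda t, x_: -x_,
                         diffusions=[lambda t, x_: math.sqrt(2.0)],
                         streams=[stream2])
        for k in range(100):
            euler_maruyama_step(sys2, k * dt, dt)
        assert sys2.state[0] == pytest.approx(x[99], rel=1e-9)
        burn = 20_000
        assert x[burn:].var() == pytest.approx(1.0, rel=0.05)
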