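"""Synaptic kinetics: first-order activation, GABA-B cascade, short-term
depression and the miniature-PSP release process."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcsleep import constants as C
from tcsleep.synapses import (MiniProcess, SynapseParams, SynapseState,
                              depression_step, gabab_step, mini_quantum,
                              mini_rate, open_fraction_step,
                              sample_mini_times, synaptic_current)


class TestSynapticCurrent:
    def test_zero_at_reversal_potential(self):
        p = SynapseParams("AMPA", 0.024)
        s = SynapseState(open_fraction=0.7)
        assert synaptic_current(s, p, v_post=0.0) == pytest.approx(0.0)

    def test_zero_with_closed_channels(self):
        p = SynapseParams("GABAA", 0.05)
        s = SynapseState(open_fraction=0.0)
        assert synaptic_current(s, p, v_post=-55.0) == pytest.approx(0.0)

    def test_direct_evaluation_with_scaling(self):
        p = SynapseParams("AMPA", 0.024)
        s = SynapseState(open_fraction=0.5)
        i = synaptic_current(s, p, v_post=-70.0, l_scale=2.0)
        assert i == pytest.approx(2.0 * 0.024 * 0.5 * (-70.0))

    @given(o=st.floats(0.01, 1.0), v=st.floats(-90, 50),
           l=st.floats(0.1, 3.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_current_is_linear_in_the_modulator_scale(self, o, v, l):
        p = SynapseParams("AMPA", 0.024)
        s = SynapseState(open_fraction=o)
        i1 = synaptic_current(s, p, v, l)
        i2 = synaptic_current(s, p, v, 2.0 * l)
        assert i2 == pytest.approx(2.0 * i1, rel=1e-12, abs=1e-15)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            synaptic_current(SynapseState(), SynapseParams("AMPA", 0.01),
                             -60.0, l_scale=0.0)

    def test_printed_conductance_table(self):
        assert C.G_SYN[("PY", "PY", "AMPA")] == 0.024
        assert C.G_SYN[("PY", "PY", "NMDA")] == 0.001
        assert C.G_SYN[("PY", "TC", "AMPA")] == 0.005
        assert C.G_SYN[("PY", "RE", "AMPA")] == 0.015
        assert C.G_SYN[("PY", "IN", "AMPA")] == 0.012
        assert C.G_SYN[("IN", "PY", "GABAA")] == 0.024
        assert C.G_SYN[("TC", "PY", "AMPA")] == 0.02
        assert C.G_SYN[("TC", "IN", "AMPA")] == 0.02
        assert C.G_SYN[("RE", "RE", "GABAA")] == 0.05
        assert C.G_SYN[("RE", "TC", "GABAA")] == 0.05
        assert C.G_SYN[("RE", "TC", "GABAB")] == 0.02
        assert C.G_SYN[("TC", "RE", "AMPA")] == 0.05
        assert C.G_MINI == {"PY_PY": 0.033, "PY_IN": 0.02, "IN_PY": 0.02}


class TestOpenFraction:
    @given(o=st.floats(0, 1), dt=st.floats(0.001, 1.0),
           pulse=st.booleans())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_stays_in_unit_interval(self, o, dt, pulse):
        o2 = open_fraction_step(o, pulse, dt, C.AMPA_ALPHA, C.AMPA_BETA)
        assert 0.0 <= o2 <= 1.0

    def test_decay_is_exact_exponential(self):
        o = open_fraction_step(0.8, False, 5.0, C.AMPA_ALPHA, C.AMPA_BETA)
        assert o == pytest.approx(0.8 * math.exp(-C.AMPA_BETA * 5.0))

    def test_propofol_scale_lengthens_ipsc_half_decay(self):
        """An isolated GABA-A pulse decays to half its peak later when the
        decay-time scale exceeds 1."""
        def half_decay(scale):
            p = SynapseParams("GABAA", 0.05, decay_scale=scale)
            o, dt = 0.0, 0.02
            for _ in range(int(C.T_DUR / dt)):
                o = open_fraction_step(o, True, dt, p.alpha, p.beta_eff)
            peak, t = o, 0.0
            while o > peak / 2:
                o = open_fraction_step(o, False, dt, p.alpha, p.beta_eff)
                t += dt
            return t
        t1, t25 = half_decay(1.0), half_decay(2.5)
        assert t25 > t1
        assert t25 == pytest.approx(2.5 * t1, rel=0.05)

    def test_decay_scale_below_one_rejected(self):
        with pytest.raises(ValueError):
            SynapseParams("GABAA", 0.05, decay_scale=0.5)


class TestGabaB:
    def test_decays_to_zero_without_input(self):
        s = SynapseState(g_protein_r=0.5, g_protein=2.0)
        for _ in range(400000):
            act = gabab_step(s, False, 0.5)
        assert act == pytest.approx(0.0, abs=1e-8)

    def test_slow_onset_peaks_after_gabaa(self):
        """For an identical presynaptic pulse the GABA-B activation peaks
        much later than the GABA-A open fraction."""
        dt = 0.1
        sb = SynapseState()
        oa, t_peak_a, t_peak_b = 0.0, 0.0, 0.0
        best_a, best_b = -1.0, -1.0
        for i in range(20000):
            t = i * dt
            pulse = t < 1.0
            oa = open_fraction_step(oa, pulse, dt, C.GABAA_ALPHA,
                                    C.GABAA_BETA)
            act = gabab_step(sb, pulse, dt)
            if oa > best_a:
                best_a, t_peak_a = oa, t
            if act > best_b:
                best_b, t_peak_b = act, t
        assert best_b > 0.0
        assert t_peak_b > t_peak_a + 20.0

    def test_sustained_input_saturates_at_closed_form(self):
        # R* = K1 T/(K1 T + K2), G* = K3 R*/K4, s* = G*^4/(G*^4 + Kd)
        s = SynapseState()
        for _ in range(200000):
            act = gabab_step(s, True, 0.1)
        k = C.GABAB
        r_ss = k["k1"] * C.T_MAX / (k["k1"] * C.T_MAX + k["k2"])
        g_ss = k["k3"] * r_ss / k["k4"]
        expected = g_ss ** 4 / (g_ss ** 4 + k["kd"])
        assert act == pytest.approx(expected, rel=1e-3)
        assert 0.0 < act < 1.0


class TestDepression:
    def test_full_recovery_without_spikes(self):
        e = 0.2
        for _ in range(1000):
            e = depression_step(e, False, 10.0)
        assert e == pytest.approx(1.0, abs=1e-4)

    def test_single_spike_drop_is_use_fraction(self):
        e = depression_step(1.0, True, 1e-9, u=0.07)
        assert e == pytest.approx(0.93, rel=1e-6)

    def test_periodic_train_reaches_analytic_fixed_point(self):
        """For spikes every T the map E -> (1-U)(1-(1-E)exp(-T/tau)) has the
        fixed point E* = (1-U)(1-f)/(1-(1-U)f) with f = exp(-T/tau)."""
        u, tau, period = 0.07, 700.0, 100.0   # 10 Hz train
        e = 1.0
        for _ in range(500):
            e = depression_step(e, True, period, u=u, tau=tau)
        f = math.exp(-period / tau)
        expected = (1 - u) * (1 - f) / (1 - (1 - u) * f)
        assert e == pytest.approx(expected, rel=1e-6)


class TestMinis:
    def test_rate_zero_immediately_after_spike(self):
        assert mini_rate(0.0) == pytest.approx(0.0)

    def test_rate_saturates_at_bound(self):
        assert mini_rate(1e6) == pytest.approx(C.MINI_RATE_MAX)

    def test_rate_at_twenty_ms(self):
        # (2/(1+e^-1) - 1)/250
        expected = (2.0 / (1.0 + math.exp(-1.0)) - 1.0) / 250.0
        assert mini_rate(20.0) == pytest.approx(expected)
        assert expected == pytest.approx(1.8485e-3, rel=1e-3)

    def test_rate_monotone_increasing(self):
        d = np.linspace(0, 500, 1001)
        r = mini_rate(d)
        assert np.all(np.diff(r) >= -1e-15)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            mini_rate(-1.0)

    def test_thinning_reproduces_the_hazard(self, rng):
        """Empirical post-spike release rate from many sampled intervals
        matches mini_rate within 3 standard errors per bin."""
        n_rep, horizon = 20000, 120.0
        bins = np.arange(0.0, horizon + 1e-9, 20.0)
        counts = np.zeros(len(bins) - 1)
        for _ in range(n_rep):
            for t in sample_mini_times(0.0, horizon, 0.0, rng):
                counts[min(int(t // 20.0), len(counts) - 1)] += 1
        for k in range(len(counts)):
            lo, hi = bins[k], bins[k + 1]
            lam = np.mean(mini_rate(np.linspace(lo, hi, 50)))
            expect = lam * 20.0 * n_rep
            se = math.sqrt(max(expect, 1.0))
            assert abs(counts[k] - expect) < 3.0 * se, \
                f"bin {k}: {counts[k]} vs {expect} +- {se}"

    def test_mini_process_respects_presynaptic_suppression(self, rng):
        mp = MiniProcess(g_mini=0.033, rng=np.random.default_rng(7))
        mp.on_presynaptic_spike(1000.0)
        # immediately after the spike the hazard is ~0
        released = sum(mp.step(1000.0 + i * 1.0, 1.0) for i in range(5))
        assert released == 0

    def test_quantum_below_pulse_peak(self):
        q = mini_quantum()
        full = mini_quantum(t_dur=1e9)
        assert 0.0 < q < full < 1.0
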