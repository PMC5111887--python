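"""Neuromodulator mapping: stage tables, continuous interpolation, schedules
and the anesthesia / tonic-inhibition modes."""

import numpy as np
import pytest

from tcsleep.neuromodulation import (STAGE_LEVELS, STAGES, NeuromodulatorState,
                                     StageSchedule, apply_modulators,
                                     continuous_scalars, propofol_mode,
                                     stage_scalars, tonic_gaba_variant)


class TestStageTables:
    """The four named stages must reproduce the scaling tables exactly."""

    def test_awake_scalars(self):
        s = stage_scalars("awake")
        assert (s.ach_py, s.ach_re, s.l_ach, s.l_gaba) == (1.0, 1.0, 1.0, 1.0)
        assert s.shift_ha == -8.0

    def test_n2_scalars(self):
        s = stage_scalars("N2")
        assert (s.ach_py, s.ach_tc, s.ach_re) == (1.25, 1.25, 0.8)
        assert (s.l_ach, s.l_gaba, s.shift_ha) == (1.25, 1.15, -3.0)

    def test_n3_scalars(self):
        s = stage_scalars("N3")
        assert (s.ach_py, s.ach_re) == (1.8, 0.5)
        assert (s.l_ach, s.l_gaba, s.shift_ha) == (2.0, 1.3, -2.0)
        assert s.ach_tc == 2.0   # documented fill of the table gap

    def test_rem_scalars(self):
        s = stage_scalars("REM")
        assert (s.ach_py, s.ach_tc, s.ach_re) == (0.85, 0.85, 1.15)
        assert (s.l_ach, s.l_gaba, s.shift_ha) == (0.8, 0.75, 0.0)

    def test_stage_levels(self):
        assert STAGE_LEVELS["awake"] == dict(ach=100.0, ha=100.0, gaba=100.0)
        assert STAGE_LEVELS["N2"] == dict(ach=80.0, ha=40.0, gaba=115.0)
        assert STAGE_LEVELS["N3"] == dict(ach=50.0, ha=30.0, gaba=130.0)
        assert STAGE_LEVELS["REM"] == dict(ach=115.0, ha=10.0, gaba=75.0)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_scalars("N1")


class TestContinuousScalars:
    @pytest.mark.parametrize("stage", STAGES)
    def test_round_trip_through_stage_levels(self, stage):
        lv = STAGE_LEVELS[stage]
        cont = continuous_scalars(lv["ach"], lv["ha"], lv["gaba"])
        ref = stage_scalars(stage)
        for name in ("ach_py", "ach_tc", "ach_re", "l_ach", "l_gaba",
                     "shift_ha"):
            assert getattr(cont, name) == pytest.approx(getattr(ref, name))
        assert cont.stage == stage

    def test_lower_ach_strengthens_leak_and_ampa(self):
        hi = continuous_scalars(100.0, 50.0, 100.0)
        lo = continuous_scalars(60.0, 50.0, 100.0)
        assert lo.ach_py > hi.ach_py and lo.ach_tc > hi.ach_tc
        assert lo.l_ach > hi.l_ach
        assert lo.ach_re < hi.ach_re

    def test_intermediate_levels_lie_between_stages(self):
        mid = continuous_scalars(75.0, 30.0, 130.0)
        n2, n3 = stage_scalars("N2"), stage_scalars("N3")
        for name in ("ach_py", "ach_tc", "ach_re", "l_ach"):
            lo = min(getattr(n2, name), getattr(n3, name))
            hi = max(getattr(n2, name), getattr(n3, name))
            assert lo <= getattr(mid, name) <= hi
        # HA and GABA levels are exactly at the deep-sleep anchors
        assert mid.shift_ha == pytest.approx(n3.shift_ha)
        assert mid.l_gaba == pytest.approx(n3.l_gaba)

    def test_gaba_scalar_tracks_level_linearly(self):
        for lv in (80.0, 100.0, 120.0, 130.0, 180.0):
            assert continuous_scalars(100.0, 100.0, lv).l_gaba == \
                pytest.approx(lv / 100.0)

    def test_out_of_range_levels_rejected_with_bound_name(self):
        with pytest.raises(ValueError, match="gaba"):
            continuous_scalars(100.0, 100.0, 5.0)
        with pytest.raises(ValueError, match="ach"):
            continuous_scalars(200.0, 100.0, 100.0)

    def test_monotone_over_the_sweep_range(self):
        achs = np.linspace(0.0, 120.0, 25)
        vals = [continuous_scalars(max(a, 1e-9) if a > 0 else 0.0001,
                                   60.0, 100.0).ach_py for a in achs]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestApplyModulators:
    def test_awake_state_is_identity(self, reduced_net):
        eff = apply_modulators(reduced_net, stage_scalars("awake"))
        for key, g in eff["g_syn_effective"].items():
            assert g == pytest.approx(reduced_net.synapse_params[key].g_syn)
        assert all(v == 1.0 for v in eff["k_leak_scale"].values())

    def test_n3_scales_leak_and_synapses_per_table(self, reduced_net):
        eff = apply_modulators(reduced_net, stage_scalars("N3"))
        assert eff["k_leak_scale"]["PY"] == 1.8
        assert eff["k_leak_scale"]["RE"] == 0.5
        base = reduced_net.synapse_params
        assert eff["g_syn_effective"][("PY", "PY", "AMPA")] == \
            pytest.approx(2.0 * base[("PY", "PY", "AMPA")].g_syn)
        assert eff["g_syn_effective"][("IN", "PY", "GABAA")] == \
            pytest.approx(1.3 * base[("IN", "PY", "GABAA")].g_syn)
        # NMDA and corticothalamic AMPA are not ACh-scaled
        assert eff["g_syn_effective"][("PY", "PY", "NMDA")] == \
            pytest.approx(base[("PY", "PY", "NMDA")].g_syn)
        assert eff["g_syn_effective"][("PY", "RE", "AMPA")] == \
            pytest.approx(base[("PY", "RE", "AMPA")].g_syn)

    def test_n2_scales_cortical_inhibition(self, reduced_net):
        eff = apply_modulators(reduced_net, stage_scalars("N2"))
        base = reduced_net.synapse_params[("IN", "PY", "GABAA")].g_syn
        assert eff["g_syn_effective"][("IN", "PY", "GABAA")] == \
            pytest.approx(1.15 * base)

    def test_reapplication_is_idempotent(self, reduced_net):
        st = stage_scalars("N3")
        e1 = apply_modulators(reduced_net, st)
        e2 = apply_modulators(reduced_net, st)
        assert e1["g_syn_effective"] == e2["g_syn_effective"]
        # base parameters were never mutated
        assert reduced_net.synapse_params[("PY", "PY", "AMPA")].g_syn == 0.024


class TestPropofol:
    def test_default_reading_multiplies_decay_by_two_and_a_half(self):
        st = propofol_mode(150.0, combined=False)
        assert st.gaba_tau_scale == pytest.approx(2.5)
        # every neuromodulator scalar stays at its awake value
        aw = stage_scalars("awake")
        for name in ("ach_py", "ach_tc", "ach_re", "l_ach", "l_gaba",
                     "shift_ha"):
            assert getattr(st, name) == getattr(aw, name)

    def test_alternative_reading(self):
        assert propofol_mode(150.0, combined=False,
                             interpretation="to").gaba_tau_scale == \
            pytest.approx(1.5)

    def test_combined_mode_reduces_ach_and_ha(self):
        st = propofol_mode(150.0, combined=True)
        assert st.ach == 75.0 and st.ha == 30.0
        aw = stage_scalars("awake")
        assert st.ach_py > aw.ach_py         # lower ACh -> stronger K-leak
        assert st.shift_ha > aw.shift_ha     # lower HA -> weaker Ih

    def test_zero_increase_is_identity(self):
        assert propofol_mode(0.0, combined=False).gaba_tau_scale == 1.0


class TestTonicGaba:
    def test_variant_a_is_flat(self):
        assert all(tonic_gaba_variant("A", s) == 1.0 for s in STAGES)

    def test_variant_b_follows_extracellular_gaba(self):
        assert tonic_gaba_variant("B", "N2") == 1.15
        assert tonic_gaba_variant("B", "N3") == 1.30
        assert tonic_gaba_variant("B", "REM") == 0.75

    def test_variant_c_follows_co_release(self):
        assert tonic_gaba_variant("C", "N2") == 0.85
        assert tonic_gaba_variant("C", "N3") == 0.70
        assert tonic_gaba_variant("C", "REM") == 1.25

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            tonic_gaba_variant("D", "N2")
        with pytest.raises(ValueError):
            tonic_gaba_variant("A", "N1")


class TestStageSchedule:
    def test_durations_and_ramps_validated(self):
        with pytest.raises(ValueError):
            StageSchedule().add("awake", 0.0)
        with pytest.raises(ValueError):
            StageSchedule().add("awake", 1.0, ramp_s=-1.0)

    def test_stepwise_course_without_ramp(self):
        sched = StageSchedule().add("awake", 1.0).add("N3", 1.0)
        course = sched.scalar_time_course(1.0)
        assert course.shape == (2000, 9)
        assert np.all(course[:1000, 0] == 1.0)     # awake ach_py
        assert np.all(course[1000:, 0] == 1.8)     # N3 ach_py, sharp step

    def test_ramp_makes_the_course_continuous(self):
        sched = StageSchedule().add("awake", 1.0).add("N3", 2.0, ramp_s=1.0)
        course = sched.scalar_time_course(1.0)
        seg = course[1000:2000, 0]
        assert np.all(np.diff(seg) >= 0)
        assert np.max(np.abs(np.diff(course[:, 0]))) < 0.002  # no jump
        assert course[2999, 0] == pytest.approx(1.8)

    def test_stage_labels_align_with_segments(self):
        sched = StageSchedule().add("awake", 1.0).add("N2", 1.0)
        labels = sched.stage_labels(1.0)
        assert labels[0] == "awake" and labels[-1] == "N2"
        assert len(labels) == 2000

    def test_gaba_split_defaults_to_shared_scalar(self):
        st = NeuromodulatorState(l_gaba=1.3)
        v = st.scalar_vector()
        assert v[4] == v[5] == 1.3
        st2 = NeuromodulatorState(l_gaba=1.3, l_gaba_cx=1.0)
        v2 = st2.scalar_vector()
        assert v2[4] == 1.0 and v2[5] == 1.3
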