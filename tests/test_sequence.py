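"""Flip-schedule design and the TR-cycle / steady-state engine."""

import math
from dataclasses import replace

import numpy as np
import pytest

from vwisim.bloch import CSF, TissueParams, VESSEL_WALL
from vwisim.epg import epg_echo_train
from vwisim.sequence import (
    SequenceSpec,
    SequenceTiming,
    design_flip_schedule,
    resolve_flip_schedule,
    run_to_steady_state,
    signal_at_te,
)


class TestFlipScheduleDesign:
    def test_constant_mode(self):
        sch = design_flip_schedule(VESSEL_WALL, 10, 4.4, mode="constant")
        assert np.all(sch.flips_deg == 180.0)

    def test_t2var_holds_plateau_for_design_tissue(self):
        """Prescribed-signal inversion: the design tissue's echo amplitudes sit
        on the plateau through the hold window (the k-space center)."""
        sch = design_flip_schedule(VESSEL_WALL, 77, 4.4, hold_through=21)
        res = epg_echo_train(1.0, sch.flips_deg, 4.4, VESSEL_WALL)
        held = res.echoes[:21]
        assert np.all(np.abs(held - sch.plateau) < 0.1 * sch.plateau)
        # echo 21 is the effective-TE echo of the 92-ms-TE protocol
        assert held[20] == pytest.approx(sch.plateau, rel=1e-2)

    def test_flips_stay_in_physical_range(self):
        sch = design_flip_schedule(VESSEL_WALL, 60, 4.4, hold_through=28)
        assert np.all(sch.flips_deg > 0.0) and np.all(sch.flips_deg <= 180.0)

    def test_infeasible_plateau_reports_maximum(self):
        sch = design_flip_schedule(VESSEL_WALL, 77, 4.4, plateau=0.9, hold_through=21)
        assert not sch.feasible
        assert 0.0 < sch.max_feasible_plateau < 0.9

    def test_zero_plateau_rejected(self):
        with pytest.raises(ValueError):
            design_flip_schedule(VESSEL_WALL, 77, 4.4, plateau=0.0)

    def test_explicit_plateau_below_maximum_is_feasible(self):
        sch = design_flip_schedule(VESSEL_WALL, 40, 4.4, plateau=0.1, hold_through=20)
        assert sch.feasible
        res = epg_echo_train(1.0, sch.flips_deg, 4.4, VESSEL_WALL)
        assert np.all(np.abs(res.echoes[:20] - 0.1) < 0.01)


class TestTiming:
    def test_effective_echo_index_rounds(self):
        assert SequenceTiming(2500, 92, 4.4, 77).effective_echo_index == 21
        assert SequenceTiming(6250, 345, 4.4, 195).effective_echo_index == 78
        assert SequenceTiming(2500, 4.4, 4.4, 77).effective_echo_index == 1

    def test_te_outside_train_rejected(self):
        with pytest.raises(ValueError):
            SequenceTiming(2500, 400, 4.4, 77)

    def test_overlong_train_rejected_with_deficit(self):
        spec = SequenceSpec(
            "bad", SequenceTiming(300, 92, 4.4, 77), prep="none"
        )
        with pytest.raises(ValueError, match="exceed TR"):
            _ = spec.t_rec_ms

    def test_signal_at_te_reads_center_echo(self):
        echoes = np.arange(1, 78, dtype=float)
        assert signal_at_te(echoes, SequenceTiming(2500, 92, 4.4, 77)) == 21.0
        assert signal_at_te(echoes, SequenceTiming(2500, 4.4, 4.4, 77)) == 1.0

    def test_signal_at_te_out_of_range(self):
        with pytest.raises(IndexError):
            signal_at_te(np.ones(10), SequenceTiming(2500, 92, 4.4, 77))


class TestCycleStructure:
    @pytest.mark.parametrize(
        "name, n_parts",
        [("t2w-space", 2), ("flair-space", 3), ("t2ir-space", 4)],
    )
    def test_number_of_cycle_parts(self, presets, name, n_parts):
        """T2w: acquisition + recovery; FLAIR adds the inversion-recovery
        part; T2IR adds the preparation part as well."""
        res = run_to_steady_state(presets[name], [CSF], n_reps=2)
        assert res.trace.n_parts() == n_parts

    def test_trace_values_bounded(self, presets):
        res = run_to_steady_state(presets["t2ir-space"], [CSF, VESSEL_WALL], 3)
        df = res.trace.frame
        assert (df["mz"].abs() <= 1.0 + 1e-9).all()
        assert (df["mxy_abs"] <= 1.0 + 1e-9).all()
        assert (df["mxy_abs"] >= 0.0).all()


class TestSteadyState:
    def test_all_presets_converge_by_rep_10(self, steady_table):
        assert (steady_table["delta_mz"] < 1e-3).all()

    def test_rep10_matches_rep50(self, presets):
        a = run_to_steady_state(presets["t2ir-space"], [CSF, VESSEL_WALL], 10,
                                collect_trace="none")
        b = run_to_steady_state(presets["t2ir-space"], [CSF, VESSEL_WALL], 50,
                                collect_trace="none")
        for name in ("csf", "vessel_wall"):
            assert a.signals[name] == pytest.approx(b.signals[name], abs=1e-3)
            assert a.mz_acq_start[name] == pytest.approx(
                b.mz_acq_start[name], abs=1e-3
            )

    def test_t2ir_operates_near_csf_null(self, presets):
        res = run_to_steady_state(presets["t2ir-space"], [CSF], 10,
                                  collect_trace="none")
        assert abs(res.mz_acq_start["csf"]) < 0.08

    def test_t2ir_trace_structure(self, presets):
        """Longitudinal magnetization is negative right after the prep and
        recovers monotonically through TI, crossing zero near acquisition."""
        res = run_to_steady_state(presets["t2ir-space"], [CSF], 10)
        df = res.trace.frame
        ti = df[df["segment"] == "inversion_recovery"].sort_values("time_ms")
        assert ti["mz"].iloc[0] < 0.0
        assert (np.diff(ti["mz"]) >= -1e-12).all()
        assert abs(ti["mz"].iloc[-1]) < 0.1

    def test_fast_recovering_tissue_is_steady_from_first_rep(self, presets):
        quick = TissueParams("quick", t1_ms=50.0, t2_ms=30.0)
        a = run_to_steady_state(presets["t2w-space"], [quick], 1,
                                collect_trace="none")
        b = run_to_steady_state(presets["t2w-space"], [quick], 10,
                                collect_trace="none")
        assert a.signals["quick"] == pytest.approx(b.signals["quick"], abs=1e-6)

    def test_trace_sampling_does_not_change_physics(self, presets):
        a = run_to_steady_state(presets["t2ir-space"], [CSF], 5, n_samples=8)
        b = run_to_steady_state(presets["t2ir-space"], [CSF], 5, n_samples=64)
        assert a.signals["csf"] == pytest.approx(b.signals["csf"], abs=1e-15)
        assert a.mz_acq_start["csf"] == pytest.approx(
            b.mz_acq_start["csf"], abs=1e-15
        )

    def test_t2ir_without_prep_reduces_to_t2w_engine_path(self, presets):
        """Removing the preparation and TI from the T2IR preset must give
        exactly the unprepared-sequence output at the same TE."""
        t2ir = presets["t2ir-space"]
        stripped = replace(
            t2ir,
            prep="none",
            t2ir=None,
            timing=replace(t2ir.timing, ti_ms=None, te_prep_ms=None),
        )
        t2w = replace(
            presets["t2w-space"],
            timing=replace(presets["t2w-space"].timing, te_ms=92.0),
        )
        a = run_to_steady_state(stripped, [CSF, VESSEL_WALL], 10,
                                collect_trace="none")
        b = run_to_steady_state(t2w, [CSF, VESSEL_WALL], 10,
                                collect_trace="none")
        for name in ("csf", "vessel_wall"):
            assert a.signals[name] == pytest.approx(b.signals[name], abs=1e-12)


class TestComparators:
    def test_dante_suppresses_flowing_csf(self, presets):
        res = run_to_steady_state(
            presets["dante-space"], [CSF.with_flow("flowing"), VESSEL_WALL], 10,
            collect_trace="none",
        )
        assert res.signals["csf"] < 0.15
        assert res.signals["vessel_wall"] > res.signals["csf"]

    def test_antidrive_leaves_csf_bright(self, presets, signal):
        """With the long TR the restored CSF recovers to a high value: CSF
        stays insufficiently suppressed compared with the T2IR preset."""
        res = run_to_steady_state(
            presets["t2w-antidrive"], [CSF, VESSEL_WALL], 10, collect_trace="none"
        )
        assert res.signals["csf"] > 3 * signal("t2ir-space", "csf")
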