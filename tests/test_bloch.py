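"""Elementary magnetization physics: rotations, relaxation, spoiling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vwisim.bloch import (
    CSF,
    FieldConditions,
    Magnetization,
    RFPulseSpec,
    TissueParams,
    relax,
    rotate,
    rotate_offres,
    rotation_matrix,
    spoil,
)

finite_floats = st.floats(-1.0, 1.0, allow_nan=False)


class TestRotation:
    @pytest.mark.parametrize(
        "m_in, pulse, expected",
        [
            # convention-defining case: 90° about x takes z to +y
            ((0, 0, 1), RFPulseSpec(90, 0), (0, 1, 0)),
            ((1, 0, 0), RFPulseSpec(180, 90), (-1, 0, 0)),
            ((0, 1, 0), RFPulseSpec(90, 0), (0, 0, -1)),  # tip-down direction
            ((0.3, -0.2, 0.7), RFPulseSpec(360, 123.4), (0.3, -0.2, 0.7)),
        ],
    )
    def test_reference_rotations(self, m_in, pulse, expected):
        out = rotate(Magnetization(*m_in), pulse)
        assert out.as_array() == pytest.approx(np.array(expected), abs=1e-12)

    @given(
        flip=st.floats(0, 360),
        phase=st.floats(-180, 360),
        mx=finite_floats, my=finite_floats, mz=finite_floats,
    )
    @settings(max_examples=100, deadline=None)
    def test_rotations_preserve_norm(self, flip, phase, mx, my, mz):
        m = Magnetization(mx, my, mz)
        out = rotate(m, RFPulseSpec(flip, phase))
        assert out.norm == pytest.approx(m.norm, abs=1e-12)

    @given(flip=st.floats(0, 360), phase=st.floats(0, 360))
    @settings(max_examples=50, deadline=None)
    def test_rotation_matrix_is_orthogonal(self, flip, phase):
        r = rotation_matrix(flip, phase)
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)


class TestRelaxation:
    def test_zero_duration_is_identity(self):
        m = Magnetization(0.3, -0.4, 0.5)
        out = relax(m, 0.0, CSF)
        assert out == m

    def test_longitudinal_recovery_closed_form(self):
        # saturated CSF recovering for 2500 ms with T1 = 4300 ms
        out = relax(Magnetization(0, 0, 0), 2500.0, CSF)
        assert out.mz == pytest.approx(1 - math.exp(-2500 / 4300), abs=1e-12)
        assert out.mz == pytest.approx(0.4409, abs=5e-5)

    def test_transverse_decay_closed_form(self):
        out = relax(Magnetization(1, 0, 0), 200.0, CSF)
        assert out.mx == pytest.approx(math.exp(-200 / 2200), abs=1e-12)
        assert out.mx == pytest.approx(0.9131, abs=5e-5)

    def test_matches_small_step_integration(self):
        """Closed-form relaxation equals explicit Euler integration of the
        Bloch relaxation terms at small step size."""
        tissue = TissueParams("t", 1200.0, 50.0)
        mx, my, mz = 0.6, -0.2, -0.5
        dt, t_total = 1e-3, 40.0
        n = int(round(t_total / dt))
        for _ in range(n):
            mx += -mx / tissue.t2_ms * dt
            my += -my / tissue.t2_ms * dt
            mz += (tissue.m0 - mz) / tissue.t1_ms * dt
        out = relax(Magnetization(0.6, -0.2, -0.5), t_total, tissue)
        assert out.as_array() == pytest.approx([mx, my, mz], abs=1e-4)

    def test_relaxation_contracts_toward_equilibrium(self):
        m = Magnetization(0.5, 0.5, -0.8)
        out = relax(m, 123.0, CSF)
        assert abs(out.mz - 1.0) <= abs(m.mz - 1.0)
        assert out.mxy_abs <= m.mxy_abs

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            relax(Magnetization(), -1.0, CSF)


class TestSpoil:
    def test_zeroes_transverse_only(self):
        assert spoil(Magnetization(0.3, -0.4, 0.5)) == Magnetization(0, 0, 0.5)
        assert spoil(Magnetization(0, 0, 1)) == Magnetization(0, 0, 1)

    def test_idempotent(self):
        m = Magnetization(0.1, 0.9, -0.3)
        assert spoil(spoil(m)) == spoil(m)


class TestFiniteDurationPulse:
    def test_nominal_field_matches_instantaneous(self):
        m = Magnetization(0.2, 0.1, 0.9)
        pulse = RFPulseSpec(137.0, 42.0)
        a = rotate_offres(m, pulse, FieldConditions(), n_steps=100)
        b = rotate(m, pulse)
        assert a.as_array() == pytest.approx(b.as_array(), abs=1e-9)

    def test_b1_scale_scales_flip(self):
        out = rotate_offres(
            Magnetization.equilibrium(), RFPulseSpec(90, 0),
            FieldConditions(b1_scale=0.5),
        )
        assert out.mz == pytest.approx(math.cos(math.radians(45)), abs=1e-9)

    def test_self_convergence_under_offresonance(self):
        m = Magnetization.equilibrium()
        pulse = RFPulseSpec(180, 0, duration_ms=1.0)
        field = FieldConditions(b0_offset_hz=500.0)
        a = rotate_offres(m, pulse, field, n_steps=100)
        b = rotate_offres(m, pulse, field, n_steps=1000)
        assert a.as_array() == pytest.approx(b.as_array(), abs=1e-6)

    def test_norm_preserved(self):
        out = rotate_offres(
            Magnetization(0.1, 0.2, 0.95),
            RFPulseSpec(270, 30),
            FieldConditions(b0_offset_hz=300, b1_scale=1.3),
        )
        assert out.norm == pytest.approx(Magnetization(0.1, 0.2, 0.95).norm, abs=1e-12)


class TestTissueParams:
    def test_presets(self):
        assert (CSF.t1_ms, CSF.t2_ms) == (4300, 2200)

    @pytest.mark.parametrize("t1, t2", [(100, 200), (100, 0), (0, 0), (-5, -1)])
    def test_invalid_relaxation_times_rejected(self, t1, t2):
        with pytest.raises(ValueError):
            TissueParams("bad", t1, t2)

    def test_pulse_duration_scales_with_flip(self):
        assert RFPulseSpec(90, 0).duration == pytest.approx(0.5)
        assert RFPulseSpec(180, 0).duration == pytest.approx(1.0)
        assert RFPulseSpec(270, 0).duration == pytest.approx(1.5)
        assert RFPulseSpec(360, 0).duration == pytest.approx(2.0)
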