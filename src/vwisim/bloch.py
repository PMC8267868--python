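"""Elementary magnetization physics: rotations, relaxation, precession, spoiling.

All magnetization is dimensionless, normalized so that thermal equilibrium is
``(0, 0, 1)`` for ``m0 = 1``.  Times are in milliseconds throughout the
package, off-resonance offsets in Hz.

Rotation convention
-------------------
RF rotations are parametrized by a nominal flip angle and the azimuth of the
rotation axis in the transverse plane (``phase_deg``, measured from +x).  The
handedness is fixed so that a 90° pulse at phase 0 ("x") takes equilibrium
``(0, 0, 1)`` to ``(0, 1, 0)``; equivalently, an infinitesimal rotation about
axis ``n`` moves the magnetization by ``d m = dtheta (m x n)``.  All composite
pulse identities in the package are stated and tested under this single
convention.

Hard pulses are instantaneous by default (relaxation and off-resonance are
ignored during the pulse).  :func:`rotate_offres` provides a finite-duration
mode that subdivides the pulse and interleaves nutation with free precession,
for B0/B1 robustness analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "FlowState",
    "TissueParams",
    "Magnetization",
    "RFPulseSpec",
    "FieldConditions",
    "CSF",
    "VESSEL_WALL",
    "PARENCHYMA",
    "axis_rotation",
    "rotation_matrix",
    "rotate",
    "rotate_offres",
    "precess",
    "relax",
    "relax_transverse",
    "spoil",
]


class FlowState(str, Enum):
    """Macroscopic motion state of a tissue compartment."""

    STATIC = "static"
    FLOWING = "flowing"


@dataclass(frozen=True)
class TissueParams:
    """Relaxation constants and flow state of one tissue compartment.

    Parameters
    ----------
    name
        Compartment label used in traces and reports.
    t1_ms, t2_ms
        Longitudinal and transverse relaxation times in milliseconds.
        ``math.inf`` is accepted (relaxation disabled).
    flow_state
        Whether spins in this compartment move through the voxel; only the
        DANTE preparation distinguishes the two.
    m0
        Equilibrium magnetization scale.
    """

    name: str
    t1_ms: float
    t2_ms: float
    flow_state: FlowState = FlowState.STATIC
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.t2_ms <= self.t1_ms):
            raise ValueError(
                f"require 0 < T2 <= T1, got T1={self.t1_ms}, T2={self.t2_ms}"
            )
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")

    def with_flow(self, flow_state: FlowState | str) -> "TissueParams":
        return replace(self, flow_state=FlowState(flow_state))


#: Cerebrospinal fluid at 3 T.
CSF = TissueParams("csf", t1_ms=4300.0, t2_ms=2200.0)
#: Intracranial vessel wall at 3 T.
VESSEL_WALL = TissueParams("vessel_wall", t1_ms=1200.0, t2_ms=50.0)
#: White-matter-like background compartment (literature placeholder values).
PARENCHYMA = TissueParams("parenchyma", t1_ms=850.0, t2_ms=70.0)


@dataclass(frozen=True)
class Magnetization:
    """Three-component magnetization of one tissue / isochromat."""

    mx: float = 0.0
    my: float = 0.0
    mz: float = 1.0
    m0: float = 1.0

    @classmethod
    def equilibrium(cls, m0: float = 1.0) -> "Magnetization":
        return cls(0.0, 0.0, m0, m0)

    @classmethod
    def longitudinal(cls, mz: float, m0: float = 1.0) -> "Magnetization":
        return cls(0.0, 0.0, mz, m0)

    @classmethod
    def from_array(cls, v: np.ndarray, m0: float = 1.0) -> "Magnetization":
        return cls(float(v[0]), float(v[1]), float(v[2]), m0)

    def as_array(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz], dtype=float)

    @property
    def mxy_abs(self) -> float:
        return math.hypot(self.mx, self.my)

    @property
    def norm(self) -> float:
        return math.sqrt(self.mx**2 + self.my**2 + self.mz**2)


@dataclass(frozen=True)
class RFPulseSpec:
    """A hard RF pulse: nominal flip, transverse-plane axis phase, duration.

    When ``duration_ms`` is omitted it scales in proportion to the flip angle
    at constant amplitude, anchored at 0.5 ms for a 90° pulse (so 90/180/270/
    360° pulses last 0.5/1/1.5/2 ms).
    """

    flip_deg: float
    phase_deg: float = 0.0
    duration_ms: float | None = None

    @property
    def duration(self) -> float:
        if self.duration_ms is not None:
            if self.duration_ms <= 0:
                raise ValueError("pulse duration must be positive")
            return self.duration_ms
        return abs(self.flip_deg) / 90.0 * 0.5


@dataclass(frozen=True)
class FieldConditions:
    """Static-field offset and RF amplitude error at one spatial location."""

    b0_offset_hz: float = 0.0
    b1_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.b1_scale <= 0:
            raise ValueError("b1_scale must be positive")


NOMINAL_FIELD = FieldConditions()


def axis_rotation(m: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate ``m`` about unit vector ``axis`` by ``angle_rad``.

    Uses the package convention ``dm = dtheta (m x n)`` (Rodrigues form
    ``m' = m cos + (m x n) sin + n (n . m)(1 - cos)``).
    """
    c = math.cos(angle_rad)
    s = math.sin(angle_rad)
    n = np.asarray(axis, dtype=float)
    return m * c + np.cross(m, n) * s + n * (np.dot(n, m)) * (1.0 - c)


def rotation_matrix(flip_deg: float, phase_deg: float) -> np.ndarray:
    """3x3 matrix of the instantaneous rotation for a hard pulse."""
    theta = math.radians(flip_deg)
    phi = math.radians(phase_deg)
    n = np.array([math.cos(phi), math.sin(phi), 0.0])
    c, s = math.cos(theta), math.sin(theta)
    # m' = c m + s (m x n) + (1-c) n (n.m)  =>  R = c I - s [n]_x + (1-c) n n^T
    k = np.array([[0.0, -n[2], n[1]], [n[2], 0.0, -n[0]], [-n[1], n[0], 0.0]])
    return c * np.eye(3) - s * k + (1.0 - c) * np.outer(n, n)


def rotate(m: Magnetization, pulse: RFPulseSpec) -> Magnetization:
    """Apply a hard pulse as an instantaneous rotation."""
    out = rotation_matrix(pulse.flip_deg, pulse.phase_deg) @ m.as_array()
    return Magnetization.from_array(out, m.m0)


def rotate_offres(
    m: Magnetization,
    pulse: RFPulseSpec,
    field: FieldConditions = NOMINAL_FIELD,
    n_steps: int = 200,
) -> Magnetization:
    """Finite-duration hard pulse under off-resonance and B1 error.

    The pulse is subdivided into ``n_steps`` intervals; within each, the
    magnetization precesses about the effective field combining nutation
    (scaled by ``b1_scale``) and the off-resonance z component.  Relaxation
    during the pulse is neglected (hard-pulse idealization).  Converges to
    :func:`rotate` as ``b0_offset_hz -> 0`` and ``b1_scale -> 1``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dur = pulse.duration
    if dur == 0.0:
        return rotate(m, pulse)
    phi = math.radians(pulse.phase_deg)
    w1 = field.b1_scale * math.radians(pulse.flip_deg) / dur  # rad/ms
    wz = 2.0 * math.pi * field.b0_offset_hz * 1e-3  # rad/ms
    w = math.hypot(w1, wz)
    v = m.as_array()
    if w == 0.0:
        return m
    axis = np.array([w1 * math.cos(phi), w1 * math.sin(phi), wz]) / w
    dt = dur / n_steps
    ang = w * dt
    for _ in range(n_steps):
        v = axis_rotation(v, axis, ang)
    return Magnetization.from_array(v, m.m0)


def precess(m: Magnetization, t_ms: float, field: FieldConditions) -> Magnetization:
    """Free precession about z for ``t_ms`` at the field's off-resonance."""
    ang = 2.0 * math.pi * field.b0_offset_hz * 1e-3 * t_ms
    v = axis_rotation(m.as_array(), np.array([0.0, 0.0, 1.0]), ang)
    return Magnetization.from_array(v, m.m0)


def relax(m: Magnetization, t_ms: float, tissue: TissueParams) -> Magnetization:
    """Free relaxation for ``t_ms``: T2 decay of mx/my, T1 recovery of mz."""
    if t_ms < 0:
        raise ValueError("relaxation duration must be non-negative")
    e2 = math.exp(-t_ms / tissue.t2_ms) if math.isfinite(tissue.t2_ms) else 1.0
    e1 = math.exp(-t_ms / tissue.t1_ms) if math.isfinite(tissue.t1_ms) else 1.0
    m0 = tissue.m0
    return Magnetization(
        m.mx * e2, m.my * e2, m0 + (m.mz - m0) * e1, m.m0
    )


def relax_transverse(m: Magnetization, t_ms: float, tissue: TissueParams) -> Magnetization:
    """T2 decay of the transverse components only; mz held fixed.

    Used inside magnetization-preparation modules where the longitudinal
    component is (nominally) zero and pinning it preserves the pure-T2
    weighting law of the module.
    """
    if t_ms < 0:
        raise ValueError("relaxation duration must be non-negative")
    e2 = math.exp(-t_ms / tissue.t2_ms) if math.isfinite(tissue.t2_ms) else 1.0
    return Magnetization(m.mx * e2, m.my * e2, m.mz, m.m0)


def spoil(m: Magnetization) -> Magnetization:
    """Ideal spoiler gradient: dephase (zero) all transverse magnetization."""
    return Magnetization(0.0, 0.0, m.mz, m.m0)
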