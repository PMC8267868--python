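"""Magnetization-preparation building blocks.

* T2IR: an MLEV-style T2-preparation whose final composite 90° pulse tips the
  T2-decayed transverse magnetization down to the -z axis, so the module
  weights the longitudinal magnetization by ``-exp(-TEprep/T2)`` before the
  inversion-recovery delay.
* IR: a plain inversion (the FLAIR preparation); the ``TEprep -> 0`` limit of
  T2IR.
* DANTE: a train of low-flip hard pulses interleaved with strong gradients
  that attenuates flowing spins while largely sparing static tissue.
* AntiDrive: a restore pulse at the end of an echo train that tips residual
  transverse magnetization to the negative longitudinal axis.

Every module obeys the spoiler contract: zero transverse magnetization at
exit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bloch import (
    CSF,
    FieldConditions,
    FlowState,
    Magnetization,
    NOMINAL_FIELD,
    RFPulseSpec,
    TissueParams,
    axis_rotation,
    relax_transverse,
    rotate,
    rotate_offres,
    precess,
    spoil,
)

__all__ = [
    "T2IRConfig",
    "DanteConfig",
    "PrepResult",
    "EfficiencyMap",
    "t2ir_module",
    "ir_pulse",
    "dante_module",
    "antidrive_restore",
    "composite_refocus_efficiency",
]


@dataclass(frozen=True)
class T2IRConfig:
    """Configuration of the T2-preparation + inversion (T2IR) module.

    ``phase_scheme`` selects the phase pattern of the composite refocusing
    pulses (90x-180y-90x): ``"mlev4"`` is R,R,R',R' (R' phase-inverted),
    ``"alternating"`` is R,R',R,R', and ``"none"`` repeats R.  The refocusing
    pulses are centered at ``te_prep * (2k - 1) / (2 n_refocus)`` (uniform
    CPMG spacing).
    """

    te_prep_ms: float = 200.0
    n_refocus: int = 4
    phase_scheme: str = "mlev4"
    composite_tipdown: bool = True

    def __post_init__(self) -> None:
        if self.te_prep_ms < 0:
            raise ValueError("te_prep_ms must be non-negative")
        if self.n_refocus < 1:
            raise ValueError("n_refocus must be >= 1")
        if self.phase_scheme not in ("mlev4", "alternating", "none"):
            raise ValueError(f"unknown phase scheme {self.phase_scheme!r}")

    def inverted_cycle(self) -> list[bool]:
        """Per-refocusing-pulse flag: is this composite phase-inverted?"""
        if self.phase_scheme == "mlev4":
            base = [False, False, True, True]
        elif self.phase_scheme == "alternating":
            base = [False, True]
        else:
            base = [False]
        return [base[i % len(base)] for i in range(self.n_refocus)]


@dataclass(frozen=True)
class DanteConfig:
    """DANTE pulse-train parameters."""

    flip_deg: float = 8.0
    n_pulses: int = 150
    interpulse_ms: float = 1.5
    gradient_mT_m: float = 20.0

    def __post_init__(self) -> None:
        if self.flip_deg < 0 or self.n_pulses < 1 or self.interpulse_ms <= 0 or self.gradient_mT_m < 0:
            raise ValueError("all DANTE parameters must be positive")

    @property
    def duration_ms(self) -> float:
        return self.n_pulses * self.interpulse_ms


@dataclass(frozen=True)
class PrepResult:
    """Output state of a preparation module and the time it consumed."""

    magnetization: Magnetization
    duration_ms: float


# -- T2IR ---------------------------------------------------------------------

_COMPOSITE_REFOCUS = ((90.0, 0.0), (180.0, 90.0), (90.0, 0.0))
# tip-down composite "270(-x) 360(x)": net -90 about x at nominal field
_COMPOSITE_TIPDOWN = ((270.0, 180.0), (360.0, 0.0))


def _refocus_pulses(inverted: bool, plain: bool) -> tuple[tuple[float, float], ...]:
    if plain:
        # constant-phase CPMG comparator: no composite, no phase cycling
        return ((180.0, 90.0),)
    pulses = _COMPOSITE_REFOCUS
    if inverted:
        pulses = tuple((f, p + 180.0) for f, p in pulses)
    return pulses


def _apply_pulses(
    m: Magnetization,
    pulses,
    field: FieldConditions | None,
    n_steps: int,
) -> Magnetization:
    for flip, phase in pulses:
        pulse = RFPulseSpec(flip, phase)
        if field is None:
            m = rotate(m, pulse)
        else:
            m = rotate_offres(m, pulse, field, n_steps=n_steps)
    return m


def t2ir_module(
    m_in: Magnetization,
    cfg: T2IRConfig,
    tissue: TissueParams,
    field: FieldConditions | None = None,
    *,
    plain_refocus: bool = False,
    n_steps: int = 50,
) -> PrepResult:
    """Run the T2IR preparation on a (longitudinal) entry state.

    With instantaneous pulses at nominal field (``field=None``) the output is
    exactly ``mz_out = -mz_in * exp(-te_prep/T2)``; transverse residue is
    spoiled at exit.  Passing ``field`` switches to finite-duration pulses
    with free precession at the B0 offset during the inter-pulse delays, used
    by the B0/B1 robustness analysis.  T1 recovery during the module is
    suppressed (the longitudinal component is nominally zero throughout),
    preserving the pure-T2 weighting law.

    ``plain_refocus`` replaces the MLEV composites with plain 180° pulses,
    for efficiency comparisons.
    """
    m = spoil(m_in)
    n = cfg.n_refocus
    te = cfg.te_prep_ms

    if te == 0.0:
        return ir_pulse(m)

    def evolve(m: Magnetization, t: float) -> Magnetization:
        m = relax_transverse(m, t, tissue)
        if field is not None:
            m = precess(m, t, field)
        return m

    # tip-down excitation 90x
    m = _apply_pulses(m, ((90.0, 0.0),), field, n_steps)
    gaps = [te / (2 * n)] + [te / n] * (n - 1) + [te / (2 * n)]
    inverted = cfg.inverted_cycle()
    for k in range(n):
        m = evolve(m, gaps[k])
        m = _apply_pulses(m, _refocus_pulses(inverted[k], plain_refocus), field, n_steps)
    m = evolve(m, gaps[-1])
    if cfg.composite_tipdown:
        m = _apply_pulses(m, _COMPOSITE_TIPDOWN, field, n_steps)
    else:
        m = _apply_pulses(m, ((90.0, 180.0),), field, n_steps)  # plain -90x
    return PrepResult(spoil(m), te)


def ir_pulse(m_in: Magnetization) -> PrepResult:
    """Ideal inversion pulse: ``mz -> -mz``, transverse spoiled."""
    return PrepResult(Magnetization(0.0, 0.0, -m_in.mz, m_in.m0), 0.0)


# -- DANTE --------------------------------------------------------------------


def dante_module(
    m_in: Magnetization,
    cfg: DanteConfig,
    tissue: TissueParams,
    flow_state: FlowState | str | None = None,
    *,
    n_phase: int = 64,
    disable_relaxation: bool = False,
) -> PrepResult:
    """DANTE preparation: a train of ``n_pulses`` hard pulses of
    ``flip_deg`` separated by ``interpulse_ms`` with strong gradients.

    Flowing spins acquire a velocity-randomized phase every interval, modeled
    as ideal per-interval transverse spoiling, so their longitudinal
    magnetization is attenuated by ``cos(flip)^n_pulses`` interleaved with T1
    recovery.  Static spins keep a fixed, position-dependent per-interval
    phase; the module returns the voxel average over a uniform phase grid,
    which substantially preserves mz (spins at exact multiples of 2pi of
    gradient-induced phase form the narrow attenuated DANTE comb).
    """
    fs = FlowState(flow_state) if flow_state is not None else tissue.flow_state
    tau = cfg.interpulse_ms
    alpha = math.radians(cfg.flip_deg)
    if disable_relaxation:
        e1 = 1.0
        e2 = 1.0
        rec = 0.0
    else:
        e1 = math.exp(-tau / tissue.t1_ms) if math.isfinite(tissue.t1_ms) else 1.0
        e2 = math.exp(-tau / tissue.t2_ms) if math.isfinite(tissue.t2_ms) else 1.0
        rec = tissue.m0 * (1.0 - e1)

    if fs is FlowState.FLOWING:
        mz = m_in.mz
        ca = math.cos(alpha)
        for _ in range(cfg.n_pulses):
            mz = mz * ca  # transverse part spoiled by randomized flow phase
            mz = mz * e1 + rec
        return PrepResult(Magnetization(0.0, 0.0, mz, m_in.m0), cfg.duration_ms)

    # static: coherent per-interval phase, voxel-averaged over a uniform grid
    theta = 2.0 * math.pi * (np.arange(n_phase) + 0.5) / n_phase
    ct, st = np.cos(theta), np.sin(theta)
    m = np.tile(m_in.as_array(), (n_phase, 1))
    rot = np.array(
        [[1.0, 0.0, 0.0],
         [0.0, math.cos(alpha), math.sin(alpha)],
         [0.0, -math.sin(alpha), math.cos(alpha)]]
    )  # flip about x under the package convention
    for _ in range(cfg.n_pulses):
        m = m @ rot.T
        mx = m[:, 0] * e2
        my = m[:, 1] * e2
        mz = m[:, 2] * e1 + rec
        m = np.column_stack([mx * ct + my * st, my * ct - mx * st, mz])
    mz_mean = float(np.mean(m[:, 2]))
    return PrepResult(Magnetization(0.0, 0.0, mz_mean, m_in.m0), cfg.duration_ms)


# -- AntiDrive ----------------------------------------------------------------


def antidrive_restore(m_end_of_train: Magnetization) -> Magnetization:
    """Restore pulse at the last echo: tip residual transverse magnetization
    to the -z axis.

    A -90° rotation about the axis orthogonal to the coherent transverse
    component sends ``|mxy|`` to ``-z`` while the existing longitudinal
    component is tipped into the transverse plane and spoiled.
    """
    return Magnetization(0.0, 0.0, -m_end_of_train.mxy_abs, m_end_of_train.m0)


# -- composite-pulse robustness ----------------------------------------------


@dataclass(frozen=True)
class EfficiencyMap:
    """Refocusing efficiency of the T2-prep train over a (b0, b1) grid.

    Efficiency is the signed preserved fraction ``-mz_out / mz_in`` of the
    full module, which equals ``exp(-te_prep/T2)`` for ideal refocusing.
    """

    b0_offsets_hz: np.ndarray
    b1_scales: np.ndarray
    composite: np.ndarray  # shape (len(b1), len(b0))
    plain: np.ndarray
    te_prep_ms: float
    tissue: TissueParams = field(default=CSF)


def composite_refocus_efficiency(
    b0_offsets_hz,
    b1_scales,
    cfg: T2IRConfig | None = None,
    tissue: TissueParams = CSF,
    *,
    n_steps: int = 50,
) -> EfficiencyMap:
    """Map MLEV-composite vs plain-180 refocusing efficiency over field errors.

    Runs the finite-pulse T2IR module for every grid point and reports the
    preserved longitudinal fraction for the composite train and for a train of
    plain 180° pulses with the same timing.
    """
    cfg = cfg or T2IRConfig()
    b0 = np.atleast_1d(np.asarray(b0_offsets_hz, dtype=float))
    b1 = np.atleast_1d(np.asarray(b1_scales, dtype=float))
    comp = np.empty((len(b1), len(b0)))
    plain = np.empty_like(comp)
    m_in = Magnetization.equilibrium()
    for i, s in enumerate(b1):
        for j, f in enumerate(b0):
            fc = FieldConditions(b0_offset_hz=f, b1_scale=s)
            comp[i, j] = -t2ir_module(
                m_in, cfg, tissue, fc, n_steps=n_steps
            ).magnetization.mz
            plain[i, j] = -t2ir_module(
                m_in, cfg, tissue, fc, plain_refocus=True, n_steps=n_steps
            ).magnetization.mz
    return EfficiencyMap(b0, b1, comp, plain, cfg.te_prep_ms, tissue)
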