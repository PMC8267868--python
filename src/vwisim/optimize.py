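"""CSF null-time solvers, prep-parameter grid search, scan-time estimation.

Two null solvers bracket the design problem: :func:`ir_null_ti` is the
closed-form cyclic inversion-recovery null (perfect inversion, no echo-train
saturation), and :func:`t2ir_null_search` finds the TI that nulls the
steady-state CSF longitudinal magnetization at acquisition start by running
the full simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .bloch import CSF, TissueParams, VESSEL_WALL
from .prep import T2IRConfig
from .sequence import SequenceSpec, SequenceTiming, run_to_steady_state

__all__ = [
    "ScanProtocol",
    "NullSearchResult",
    "OptimizationResult",
    "ir_null_ti",
    "t2ir_null_search",
    "optimize_prep",
    "scan_time_estimate",
]


@dataclass(frozen=True)
class ScanProtocol:
    """Sampling geometry of one 3D protocol (defaults: the 0.6 mm isotropic
    whole-brain protocol: 288 x 288 x 224 matrix, 5/8 slice partial Fourier,
    parallel factor 2 with 24 integrated reference lines)."""

    matrix: tuple[int, int, int] = (288, 288, 224)  # read, phase, partition
    fov_mm: tuple[float, float, float] = (170.0, 170.0, 134.4)
    partial_fourier: float = 5.0 / 8.0
    parallel_factor: int = 2
    ref_lines: int = 24
    voxel_mm: float = 0.6

    def __post_init__(self) -> None:
        if not (0.5 <= self.partial_fourier <= 1.0):
            raise ValueError("partial_fourier must be in [0.5, 1]")
        if self.parallel_factor < 1:
            raise ValueError("parallel_factor must be >= 1")


def ir_null_ti(tissue: TissueParams, tr_ms: float | None = None) -> float:
    """Inversion time nulling a tissue under cyclic perfect inversion.

    Solves ``1 - 2 exp(-TI/T1) + exp(-TR/T1) = 0``; for ``TR -> inf`` this
    reduces to ``T1 ln 2``.  Echo-train saturation is deliberately ignored
    (use :func:`t2ir_null_search` for the simulation-consistent null).
    """
    t1 = tissue.t1_ms
    if tr_ms is None or math.isinf(tr_ms):
        return t1 * math.log(2.0)
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    return -t1 * math.log((1.0 + math.exp(-tr_ms / t1)) / 2.0)


@dataclass(frozen=True)
class NullSearchResult:
    ti_ms: float
    residual_mz: float  # signed steady-state CSF mz at acquisition start
    ti_grid: np.ndarray
    mz_grid: np.ndarray


def t2ir_null_search(
    te_prep_ms: float,
    preset: SequenceSpec,
    ti_grid,
    *,
    tissue: TissueParams = CSF,
    n_reps: int = 10,
) -> NullSearchResult:
    """Grid search for the TI nulling steady-state CSF at acquisition start.

    Every candidate TI is evaluated with a full steady-state run of the
    preset (T2IR preparation of the given ``te_prep_ms``).  The grid must
    bracket a sign change of the steady-state mz, otherwise a ``ValueError``
    names the bracket failure.
    """
    ti_grid = np.sort(np.atleast_1d(np.asarray(ti_grid, dtype=float)))
    mz = np.empty(len(ti_grid))
    for i, ti in enumerate(ti_grid):
        spec = _with_prep(preset, te_prep_ms, float(ti))
        res = run_to_steady_state(spec, [tissue], n_reps, collect_trace="none")
        mz[i] = res.mz_acq_start[tissue.name]
    if len(ti_grid) > 1 and not (mz.min() <= 0.0 <= mz.max()):
        raise ValueError(
            "TI grid does not bracket the CSF null: steady-state mz spans "
            f"[{mz.min():.4f}, {mz.max():.4f}] over TI [{ti_grid[0]:.0f}, "
            f"{ti_grid[-1]:.0f}] ms"
        )
    k = int(np.argmin(np.abs(mz)))
    return NullSearchResult(float(ti_grid[k]), float(mz[k]), ti_grid, mz)


def _with_prep(preset: SequenceSpec, te_prep_ms: float, ti_ms: float) -> SequenceSpec:
    timing = replace(preset.timing, te_prep_ms=te_prep_ms, ti_ms=ti_ms)
    if te_prep_ms > 0:
        t2ir = (
            replace(preset.t2ir, te_prep_ms=te_prep_ms)
            if preset.t2ir is not None
            else T2IRConfig(te_prep_ms=te_prep_ms)
        )
        return replace(preset, timing=timing, prep="t2ir", t2ir=t2ir)
    return replace(preset, timing=timing, prep="ir", t2ir=None)


@dataclass(frozen=True)
class OptimizationResult:
    """Grid-search optimum of the preparation parameters.

    ``objective`` is the steady-state vessel-wall-minus-CSF signal at the
    effective TE over the full (TEprep x TI) grid; the reported optimum is
    the feasible grid cell maximizing it, with the CSF signal constrained
    below ``csf_threshold``.
    """

    te_prep_ms: float
    ti_ms: float
    objective: np.ndarray  # shape (len(te_prep_grid), len(ti_grid))
    csf_residual: np.ndarray
    te_prep_grid: np.ndarray
    ti_grid: np.ndarray
    feasible: bool


def optimize_prep(
    preset: SequenceSpec,
    te_prep_grid,
    ti_grid,
    csf_threshold: float = 0.05,
    *,
    vessel_wall: TissueParams = VESSEL_WALL,
    csf: TissueParams = CSF,
    n_reps: int = 10,
) -> OptimizationResult:
    """Maximize wall-CSF signal difference over a (TEprep, TI) grid subject
    to a CSF residual constraint.

    The sweep is deterministic and seedless; the full objective surface is
    returned for plotting.  If no cell satisfies the constraint the
    best-effort unconstrained optimum is returned flagged infeasible.
    """
    tp = np.atleast_1d(np.asarray(te_prep_grid, dtype=float))
    ti = np.atleast_1d(np.asarray(ti_grid, dtype=float))
    if tp.size == 0 or ti.size == 0:
        raise ValueError("grids must be non-empty")
    obj = np.empty((len(tp), len(ti)))
    csf_res = np.empty_like(obj)
    for i, te_prep in enumerate(tp):
        for j, t in enumerate(ti):
            spec = _with_prep(preset, float(te_prep), float(t))
            res = run_to_steady_state(
                spec, [vessel_wall, csf], n_reps, collect_trace="none"
            )
            obj[i, j] = res.signals[vessel_wall.name] - res.signals[csf.name]
            csf_res[i, j] = res.signals[csf.name]
    ok = csf_res < csf_threshold
    feasible = bool(ok.any())
    masked = np.where(ok, obj, -np.inf) if feasible else obj
    i, j = np.unravel_index(int(np.argmax(masked)), obj.shape)
    return OptimizationResult(
        float(tp[i]), float(ti[j]), obj, csf_res, tp, ti, feasible
    )


def scan_time_estimate(
    protocol: ScanProtocol,
    timing: SequenceTiming,
    *,
    include_ref_lines: bool = True,
) -> float:
    """Scan time in seconds: ``TR * ceil(n_lines / ETL)``.

    ``n_lines = phase * partition * partial_fourier / parallel_factor``;
    integrated reference lines add back the central ``ref_lines`` phase
    encodes at full sampling (switchable off — vendor accounting of the
    reference scan is not standardized, hence the documented ~10% envelope
    on absolute scan times).
    """
    _, n_phase, n_part = protocol.matrix
    n_part_sampled = n_part * protocol.partial_fourier
    lines = n_phase * n_part_sampled / protocol.parallel_factor
    if include_ref_lines and protocol.parallel_factor > 1:
        lines += protocol.ref_lines * n_part_sampled * (
            1.0 - 1.0 / protocol.parallel_factor
        )
    shots = math.ceil(lines / timing.etl)
    return shots * timing.tr_ms / 1000.0
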