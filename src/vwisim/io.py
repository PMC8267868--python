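"""CSV / plot writers with deterministic output."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .sequence import SignalTrace

__all__ = ["write_trace_csv", "read_trace_csv", "write_summary_csv", "plot_trace"]

_TRACE_COLUMNS = ["rep", "time_ms", "tissue", "mz", "mxy_abs", "segment"]


def write_trace_csv(trace: SignalTrace | pd.DataFrame, path) -> Path:
    """Write a signal trace; rows sorted by (rep, time, tissue), full float
    precision so a read round-trips losslessly."""
    df = trace.frame if isinstance(trace, SignalTrace) else trace
    df = df.reindex(columns=_TRACE_COLUMNS)
    df = df.sort_values(["rep", "time_ms", "tissue"], kind="mergesort")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path) -> SignalTrace:
    return SignalTrace(pd.read_csv(path, float_precision="round_trip"))


def write_summary_csv(summary: pd.DataFrame, path) -> Path:
    """Deterministic summary table: sorted columns-stable, row-sorted."""
    sort_cols = [c for c in ("sequence", "tissue") if c in summary.columns]
    if sort_cols:
        summary = summary.sort_values(sort_cols, kind="mergesort")
    path = Path(path)
    summary.to_csv(path, index=False)
    return path


def plot_trace(trace: SignalTrace, path, title: str | None = None) -> Path:
    """Signal-evolution figure: mz and |mxy| vs time per tissue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trace.frame
    fig, ax = plt.subplots(figsize=(9, 4))
    for tissue, grp in df.groupby("tissue"):
        grp = grp.sort_values("time_ms")
        ax.plot(grp["time_ms"], grp["mz"], label=f"{tissue} mz")
        ax.plot(grp["time_ms"], grp["mxy_abs"], "--", label=f"{tissue} |mxy|")
    for t in df.groupby("segment")["time_ms"].min().sort_values():
        ax.axvline(t, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("signal (fraction of M0)")
    ax.set_ylim(-1.05, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
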