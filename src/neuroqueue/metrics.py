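"""Node- and edge-level communication metrics from raw simulation output.

Three node metrics summarize information flow: the number of signal
units arriving at a node (**arrivals**), the time-averaged number of
units at the node, server plus queue (**node contents**,
n_i(t) = s_i(t) + q_i(t)), and the fraction of time the server is busy
(**utilization**).  All are computed on the post-transient window.

Time-averages come from the exact event-time integral of the step
trajectory; uniform resampling (zero-order hold or linear interpolation)
is provided for export and plotting parity, not for the averages
themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SimResult

__all__ = [
    "resample_uniform",
    "remove_transient",
    "ensemble_transient_estimate",
    "node_metrics",
    "edge_traffic",
]

METRICS = ("arrivals", "contents", "utilization")


def resample_uniform(
    trajectory: tuple[np.ndarray, np.ndarray],
    dt: float,
    t_end: float | None = None,
    kind: str = "previous",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an event-stamped step function on a uniform grid.

    Parameters
    ----------
    trajectory:
        ``(times, values)`` with ``values[k]`` holding on
        ``[times[k], times[k+1])``.
    dt:
        Grid spacing, starting at ``times[0]``.
    kind:
        ``"previous"`` (zero-order hold, the physically faithful choice
        for a queue-length trajectory) or ``"linear"`` ("table lookup"
        interpolation between event points).
    """
    t, v = np.asarray(trajectory[0], dtype=float), np.asarray(trajectory[1], dtype=float)
    if t.size == 0:
        raise ValueError("empty trajectory")
    if dt <= 0:
        raise ValueError("dt must be positive")
    stop = t[-1] if t_end is None else t_end
    grid = np.arange(t[0], stop + dt * 1e-9, dt)
    if kind == "previous":
        idx = np.searchsorted(t, grid, side="right") - 1
        return grid, v[np.clip(idx, 0, v.size - 1)]
    if kind == "linear":
        return grid, np.interp(grid, t, v)
    raise ValueError(f"unknown interpolation kind {kind!r}")


def remove_transient(result: SimResult, t_transient: float) -> SimResult:
    """Re-window a recorded run to the interval ``(t_transient, T]``.

    All windowed counters (arrivals, busy time, contents integral, edge
    traversals) are recomputed from the event logs; the conservation
    ledger, which describes the full run, is untouched.  Requires a run
    recorded with ``record_events=True``.
    """
    T = result.window[1]
    if not 0 <= t_transient < T:
        raise ValueError(f"transient must lie in [0, T), got {t_transient}")
    if result.trajectory_log is None:
        raise ValueError("remove_transient needs a recorded run (record_events=True)")
    n = len(result.node_labels)
    arrivals = np.zeros(n, dtype=np.int64)
    count_absorbed = result.params.count_deliveries_as_arrivals
    for t, i, _uid, absorbed in result.arrival_log:
        if t >= t_transient and (count_absorbed or not absorbed):
            arrivals[i] += 1
    edge_counts = np.zeros((n, n), dtype=np.int64)
    for t, i, j, _uid in result.traversal_log:
        if t >= t_transient:
            edge_counts[i, j] += 1
    busy = np.zeros(n)
    contents = np.zeros(n)
    for i, entries in result.trajectory_log.items():
        ts = np.array([e[0] for e in entries])
        occ = np.array([e[1] for e in entries], dtype=float)
        srv = np.array([e[2] for e in entries], dtype=float)
        # clip the step function to the window and integrate
        lo = np.clip(ts, t_transient, T)
        seg = np.diff(lo, append=T)
        contents[i] = float(np.sum(occ * np.clip(seg, 0, None)))
        busy[i] = float(np.sum(srv * np.clip(seg, 0, None)))
    return SimResult(
        node_labels=result.node_labels,
        params=result.params,
        window=(t_transient, T),
        arrivals=arrivals,
        busy_time=busy,
        contents_integral=contents,
        edge_counts=edge_counts,
        max_queue=result.max_queue,
        generated=result.generated,
        delivered=result.delivered,
        ejected=result.ejected,
        residual=result.residual,
        total_contents_series=result.total_contents_series,
        trajectory_log=result.trajectory_log,
        arrival_log=result.arrival_log,
        traversal_log=result.traversal_log,
        fates=result.fates,
        hop_paths=result.hop_paths,
    )


def ensemble_transient_estimate(
    times: np.ndarray,
    replicates: np.ndarray,
    rel_tol: float = 0.05,
    tail_fraction: float = 0.5,
) -> float:
    """Estimate the initial transient from replicate total-contents series.

    Averages the replicates point-wise (the ensemble-average method of
    Welch), takes the mean over the trailing ``tail_fraction`` of the
    series as the stationary level, and returns the earliest grid time
    after which the ensemble average stays within ``rel_tol`` of that
    level for good.

    Parameters
    ----------
    times:
        Common sampling grid, shape (n_samples,).
    replicates:
        Series stacked as shape (n_replicates, n_samples).
    """
    times = np.asarray(times, dtype=float)
    replicates = np.atleast_2d(np.asarray(replicates, dtype=float))
    if replicates.shape[0] < 2:
        raise ValueError("need at least two replicate series")
    if replicates.shape[1] != times.size:
        raise ValueError(
            f"replicates on a mismatched grid: {replicates.shape[1]} vs {times.size} samples"
        )
    avg = replicates.mean(axis=0)
    tail_start = int(times.size * (1.0 - tail_fraction))
    level = float(avg[tail_start:].mean())
    band = rel_tol * abs(level) if level != 0 else rel_tol
    outside = np.abs(avg - level) > band
    if not outside.any():
        return float(times[0])
    last_outside = int(np.max(np.flatnonzero(outside)))
    if last_outside + 1 >= times.size:
        raise ValueError("ensemble average never settles inside the tolerance band")
    return float(times[last_outside + 1])


def node_metrics(result: SimResult) -> pd.DataFrame:
    """Per-node arrivals, mean contents and utilization for one run.

    The result's own (post-transient) window is used; utilization is
    busy time over window length and mean contents is the exact
    time-integral of n_i over window length.
    """
    w = result.window_length
    return pd.DataFrame(
        {
            "arrivals": result.arrivals,
            "contents": result.contents_integral / w,
            "utilization": result.busy_time / w,
        },
        index=pd.Index(result.node_labels, name="node"),
    )


def edge_traffic(result: SimResult) -> np.ndarray:
    """N x N post-transient traversal counts (copy of the run's tally)."""
    return result.edge_counts.copy()


def edge_traffic_frame(result: SimResult) -> pd.DataFrame:
    """Sparse long-form (source, target, count) table of traversed edges."""
    src, dst = np.nonzero(result.edge_counts)
    return pd.DataFrame(
        {
            "source": [result.node_labels[i] for i in src],
            "target": [result.node_labels[j] for j in dst],
            "count": result.edge_counts[src, dst],
        }
    )
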