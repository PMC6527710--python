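"""Sensor-space spatiotemporal searchlight and neural RDM computation.

A searchlight at (sensor s, time t) contains the k sensors nearest to s
in the 2-D layout (including s; k = 10 by default) and the time samples
t - r .. t + r truncated at the epoch edges (r = 10 by default: 21
samples, 52.5 ms at 400 Hz).  Within each searchlight the stimulus
patterns (sensor-set x time-window, flattened) are z-scored per stimulus
and compared with the correlation distance 1 - Pearson's r, yielding one
vectorized RDM per (sensor, time).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist

from .containers import NeuralRDMSeries, PseudoTrials, SensorArray

__all__ = ["spatial_neighbors", "temporal_window", "searchlight_rdms", "sensor_adjacency"]


def spatial_neighbors(sensors: SensorArray, k: int) -> np.ndarray:
    """For each sensor, itself plus its k-1 nearest neighbors.

    Euclidean layout distance; ties broken deterministically by sensor
    order.  Returns an ``(n_sensors, k)`` index array whose first column
    is the center sensor.
    """
    n = sensors.n_sensors
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    d = cdist(sensors.positions, sensors.positions)
    order = np.lexsort((np.tile(np.arange(n), (n, 1)), d), axis=1)
    return order[:, :k]


def temporal_window(t: int, r: int, n_times: int) -> np.ndarray:
    """Sample indices t-r .. t+r inclusive, truncated at the epoch edges."""
    if not 0 <= t < n_times:
        raise ValueError("t out of range")
    return np.arange(max(0, t - r), min(n_times - 1, t + r) + 1)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    """z-score along the last axis; zero-variance rows become all-zero."""
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)


def _corr_distance_vec(patterns: np.ndarray, iu: tuple) -> np.ndarray:
    """Vectorized correlation distance of z-scored pattern stacks.

    ``patterns``: (..., n_stimuli, n_features), already z-scored per row.
    Zero-variance (all-zero) rows get distance 1 to everything.
    """
    f = patterns.shape[-1]
    corr = patterns @ np.swapaxes(patterns, -1, -2) / f
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    # all-zero rows: corr 0 with everything -> distance 1 already; but a
    # zero row against itself gives corr 0 on the diagonal, which is not
    # read out (upper triangle only). Pairs of one zero and one valid row
    # land at exactly 1, the documented fallback.
    return dist[..., iu[0], iu[1]]


def searchlight_rdms(
    pseudo: PseudoTrials,
    sensors: SensorArray | None = None,
    k: int = 10,
    r: int = 10,
) -> NeuralRDMSeries:
    """Neural RDM per spatiotemporal searchlight.

    Interior time points are processed in batch with a sliding window;
    edge time points use truncated windows.
    """
    if pseudo.n_stimuli < 3:
        raise ValueError("need at least 3 stimuli for an informative RDM")
    if sensors is None:
        sensors = pseudo.sensors
    n_stim = pseudo.n_stimuli
    n_times = pseudo.n_times
    neighbors = spatial_neighbors(sensors, k)
    iu = np.triu_indices(n_stim, k=1)
    n_pairs = n_stim * (n_stim - 1) // 2
    out = np.empty((sensors.n_sensors, n_times, n_pairs))
    win = 2 * r + 1
    for s in range(sensors.n_sensors):
        sub = pseudo.data[:, neighbors[s], :]  # (stim, k, T)
        if n_times >= win:
            # interior: (T-2r) windows of length 2r+1
            windows = sliding_window_view(sub, win, axis=2)  # (stim, k, T-2r, win)
            windows = windows.transpose(2, 0, 1, 3).reshape(n_times - 2 * r, n_stim, k * win)
            out[s, r : n_times - r] = _corr_distance_vec(_zscore_rows(windows), iu)
        for t in list(range(min(r, n_times))) + list(range(max(n_times - r, r), n_times)):
            idx = temporal_window(t, r, n_times)
            pat = sub[:, :, idx].reshape(n_stim, -1)
            out[s, t] = _corr_distance_vec(_zscore_rows(pat), iu)
    return NeuralRDMSeries(
        rdms=out,
        sensor_ids=sensors.sensor_ids,
        times=pseudo.times,
        stimulus_ids=pseudo.stimulus_ids,
    )


def sensor_adjacency(sensors: SensorArray, n_neighbors: int = 4) -> np.ndarray:
    """Symmetric boolean sensor adjacency from mutualized nearest neighbors.

    Sensor i and j are adjacent if either is among the other's
    ``n_neighbors`` nearest.  Used by the cluster-level statistics.
    """
    idx = spatial_neighbors(sensors, min(n_neighbors + 1, sensors.n_sensors))
    n = sensors.n_sensors
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in idx[i, 1:]:
            adj[i, j] = adj[j, i] = True
    np.fill_diagonal(adj, False)
    return adj
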