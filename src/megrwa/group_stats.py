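"""Group-level inference: permutation rank test with TFCE correction.

Subject-level relative-weight maps are tested against a chance baseline
with a one-sample non-parametric sign-flip test.  Because the relative
weight is a sum of squares (non-negative), testing it against zero would
be degenerate; each subject's map is therefore first centered on a
searchlight-wise null mean obtained by permuting the stimulus labels of
the neural RDMs and recomputing the weights.

The map statistic is the normalized Wilcoxon signed-rank z per point.
Multiple comparisons are corrected at cluster level with threshold-free
cluster enhancement (TFCE): each map value v is replaced by

    TFCE(v) = sum_h e(h)^E * h^H * dh

over thresholds h, where e(h) is the extent of the supra-threshold
cluster containing v in the (sensor-graph x time) adjacency.  Corrected
one-tailed p-values come from the permutation distribution of the map
maximum of the TFCE statistic; when 2^n_subjects does not exceed the
requested permutation count, all sign flips are enumerated and the test
is exact.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import norm, rankdata

from .containers import BinnedSignificance, EpsilonMap, GroupStatMap, ModelRDM, NeuralRDMSeries
from .rwa import _epsilon_batch, _standardize_columns

logger = logging.getLogger(__name__)

__all__ = [
    "tfce",
    "spatiotemporal_edges",
    "subject_null_epsilon",
    "group_rank_test",
    "bin_significance",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _tfce_kernel(values, node_order, edge_u, edge_v, edge_min, E, H, dh, n_steps):
    """Incremental TFCE: sweep thresholds downward, growing a union-find.

    ``node_order``: node indices sorted by value descending.
    ``edge_min``: per-edge min endpoint value; edges sorted descending.
    At each threshold the newly supra nodes/edges are activated and every
    active node accrues e(h)^E * h^H * dh for its current cluster.
    """
    n = values.shape[0]
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    out = np.zeros(n)
    ni = 0
    ei = 0
    for step in range(n_steps, 0, -1):
        h = step * dh
        while ni < n and values[node_order[ni]] >= h:
            v = node_order[ni]
            parent[v] = v
            size[v] = 1
            ni += 1
        while ei < edge_u.shape[0] and edge_min[ei] >= h:
            a = edge_u[ei]
            b = edge_v[ei]
            ei += 1
            ra = a
            while parent[ra] != ra:
                ra = parent[ra]
            rb = b
            while parent[rb] != rb:
                rb = parent[rb]
            if ra != rb:
                if size[ra] < size[rb]:
                    ra, rb = rb, ra
                parent[rb] = ra
                size[ra] += size[rb]
        inc = h**H * dh
        for j in range(ni):
            v = node_order[j]
            root = v
            while parent[root] != root:
                root = parent[root]
            # path compression
            while parent[v] != root:
                nxt = parent[v]
                parent[v] = root
                v = nxt
            out[node_order[j]] += size[root] ** E * inc
    return out


def spatiotemporal_edges(sensor_adjacency: np.ndarray, n_times: int) -> np.ndarray:
    """Undirected edge list of the (sensor-graph x time) lattice.

    Node (s, t) is flattened to s * n_times + t.  Spatially adjacent
    sensors are connected at equal times; consecutive samples are
    connected within each sensor.
    """
    adj = np.asarray(sensor_adjacency, dtype=bool)
    if adj.shape[0] != adj.shape[1] or not (adj == adj.T).all():
        raise ValueError("sensor adjacency must be square and symmetric")
    n_sensors = adj.shape[0]
    su, sv = np.nonzero(np.triu(adj, k=1))
    t = np.arange(n_times)
    spatial_u = (su[:, None] * n_times + t[None, :]).ravel()
    spatial_v = (sv[:, None] * n_times + t[None, :]).ravel()
    s = np.arange(n_sensors)
    temp_u = (s[:, None] * n_times + t[None, : n_times - 1]).ravel()
    temp_v = temp_u + 1
    return np.stack(
        [np.concatenate([spatial_u, temp_u]), np.concatenate([spatial_v, temp_v])], axis=1
    )


def tfce(
    stat_map: np.ndarray,
    sensor_adjacency: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    edges: np.ndarray | None = None,
    h_max: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a sensors x times map.

    Only positive values are enhanced (one-tailed inference).  The step
    is ``dh = h_max / n_steps`` with ``h_max`` the map maximum by default;
    pass ``h_max`` explicitly to share a threshold ladder across maps.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if not np.isfinite(stat_map).all():
        raise ValueError("stat map must be finite")
    n_sensors, n_times = stat_map.shape
    if edges is None:
        edges = spatiotemporal_edges(sensor_adjacency, n_times)
    values = stat_map.ravel()
    top = float(values.max()) if h_max is None else float(h_max)
    if top <= 0:
        return np.zeros_like(stat_map)
    dh = top / n_steps
    node_order = np.argsort(values)[::-1].astype(np.int64)
    emin = np.minimum(values[edges[:, 0]], values[edges[:, 1]])
    eorder = np.argsort(emin)[::-1]
    out = _tfce_kernel(
        values,
        node_order,
        edges[eorder, 0].astype(np.int64),
        edges[eorder, 1].astype(np.int64),
        emin[eorder],
        float(E),
        float(H),
        dh,
        int(n_steps),
    )
    return out.reshape(n_sensors, n_times)


def _pair_permutation_index(n_stimuli: int, perm: np.ndarray) -> np.ndarray:
    """Index into an upper-triangle RDM vector realizing a stimulus relabeling."""
    n = n_stimuli
    pair_id = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    pair_id[iu] = np.arange(len(iu[0]))
    pair_id = pair_id + pair_id.T
    return pair_id[perm[iu[0]], perm[iu[1]]]


def subject_null_epsilon(
    neural: NeuralRDMSeries,
    models: list[ModelRDM],
    n_null: int = 100,
    seed: int | np.random.Generator = 0,
    orthogonalization: str = "johnson",
) -> tuple[np.ndarray, np.ndarray]:
    """Chance distribution of the relative weights per searchlight.

    Each null iteration applies one random stimulus relabeling to the
    neural RDMs (rows/columns permuted consistently) and recomputes the
    weights.  Returns (null_mean, null_sd), each sensors x times x models.
    """
    if n_null < 20:
        raise ValueError("n_null must be >= 20 for a stable chance baseline")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_stim = len(neural.stimulus_ids)
    X = _standardize_columns(np.column_stack([m.vector for m in models]), "model RDMs")
    s, t, n_pairs = neural.rdms.shape
    Y = neural.rdms.reshape(s * t, n_pairs).T.astype(float)
    sd = Y.std(axis=0)
    mean = Y.mean(axis=0)
    Y = (Y - mean) / np.where(sd == 0, 1.0, sd)
    Y[:, sd == 0] = 0.0
    p = len(models)
    acc = np.zeros((s * t, p))
    acc2 = np.zeros((s * t, p))
    for _ in range(n_null):
        perm = rng.permutation(n_stim)
        eps = _epsilon_batch(Y[_pair_permutation_index(n_stim, perm)], X, orthogonalization)
        acc += eps
        acc2 += eps**2
    null_mean = acc / n_null
    null_var = np.clip(acc2 / n_null - null_mean**2, 0.0, None)
    return (
        null_mean.reshape(s, t, p),
        np.sqrt(null_var).reshape(s, t, p),
    )


def _signflip_matrix(n_subjects: int, n_permutations: int, rng: np.random.Generator):
    """Sign-flip designs: exhaustive if 2^n fits the budget, else sampled."""
    if 2**n_subjects <= n_permutations:
        logger.info(
            "2^%d = %d <= %d permutations requested: exhaustive sign-flip enumeration",
            n_subjects,
            2**n_subjects,
            n_permutations,
        )
        bits = np.arange(2**n_subjects)
        flips = 1 - 2 * ((bits[:, None] >> np.arange(n_subjects)[None, :]) & 1)
        return flips.astype(float), True
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, n_subjects))
    flips[0] = 1.0  # the identity flip keeps the test valid
    return flips, False


def group_rank_test(
    subject_maps: list[EpsilonMap] | list[np.ndarray],
    sensor_adjacency: np.ndarray,
    n_permutations: int = 100_000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    E: float = 0.5,
    H: float = 2.0,
    n_steps: int = 100,
    model_names: list[str] | None = None,
    sensor_ids: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> GroupStatMap:
    """One-sample sign-flip rank test with TFCE correction, one-tailed.

    ``subject_maps`` hold chance-centered weights (see
    :func:`subject_null_epsilon`), each sensors x times x models.  The
    per-point statistic is the normalized signed-rank z; the corrected
    p-value of a point is the fraction of sign-flip designs whose maximum
    TFCE statistic reaches that point's observed TFCE value.
    """
    if len(subject_maps) < 2:
        raise ValueError("need at least 2 subjects")
    if isinstance(subject_maps[0], EpsilonMap):
        model_names = model_names or list(subject_maps[0].model_names)
        sensor_ids = subject_maps[0].sensor_ids if sensor_ids is None else sensor_ids
        times = subject_maps[0].times if times is None else times
        data = np.stack([m.epsilon for m in subject_maps])
    else:
        data = np.stack([np.asarray(m) for m in subject_maps])
    n_subj, n_sensors, n_times, n_models = data.shape
    if model_names is None:
        model_names = [f"model{j}" for j in range(n_models)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flips, exhaustive = _signflip_matrix(n_subj, n_permutations, rng)
    n_flips = flips.shape[0]
    edges = spatiotemporal_edges(sensor_adjacency, n_times)

    # Signed ranks are invariant under flips up to the sign vector.
    ranks = rankdata(np.abs(data), axis=0)
    signed = np.sign(data) * ranks
    denom = np.sqrt((ranks**2).sum(axis=0))
    denom = np.where(denom == 0, 1.0, denom)

    z_out = np.empty((n_models, n_sensors, n_times))
    p_out = np.empty((n_models, n_sensors, n_times))
    for j in range(n_models):
        sj = signed[..., j]  # (subj, sensors, times)
        dj = denom[..., j]
        obs_stat = sj.sum(axis=0) / dj
        obs_tfce = tfce(obs_stat, sensor_adjacency, E, H, n_steps, edges=edges)
        max_null = np.empty(n_flips)
        for f in range(n_flips):
            stat = np.tensordot(flips[f], sj, axes=(0, 0)) / dj
            max_null[f] = tfce(stat, sensor_adjacency, E, H, n_steps, edges=edges).max()
        exceed = (max_null[:, None, None] >= obs_tfce[None, :, :]).sum(axis=0)
        if exhaustive:
            p = exceed / n_flips
        else:
            p = exceed / n_flips  # identity flip included -> p >= 1/n_flips
        p = np.clip(p, 1.0 / n_flips, 1.0)
        p_out[j] = p
        # keep z finite at the resolution of the permutation distribution
        z_out[j] = norm.isf(np.clip(p, 0.5 / n_flips, 1.0 - 0.5 / n_flips))
    return GroupStatMap(
        z=z_out,
        p_corrected=p_out,
        model_names=list(model_names),
        sensor_ids=np.asarray(sensor_ids) if sensor_ids is not None else np.arange(n_sensors),
        times=np.asarray(times) if times is not None else np.arange(n_times, dtype=float),
        alpha=alpha,
        n_permutations=n_flips,
        exhaustive=exhaustive,
    )


def bin_significance(stat_map: GroupStatMap, bin_ms: float = 50.0) -> BinnedSignificance:
    """Sensors significant at *every* sample of each time bin.

    Bins are ``bin_ms``-long intervals aligned to multiples of ``bin_ms``
    (in ms); a sensor enters a bin's set for a model only if its corrected
    p is below alpha at every sample falling inside the bin.
    """
    times_ms = np.asarray(stat_map.times, dtype=float) * 1000.0
    sig = stat_map.significant()  # (models, sensors, times)
    start = np.floor(times_ms.min() / bin_ms) * bin_ms
    stop = times_ms.max()
    bins: list[tuple[float, float]] = []
    edges = np.arange(start, stop + bin_ms, bin_ms)
    sensors_per_bin: dict = {}
    sensor_ids = np.asarray(stat_map.sensor_ids)
    for b0 in edges[:-1]:
        b1 = b0 + bin_ms
        in_bin = (times_ms >= b0) & (times_ms < b1)
        if not in_bin.any():
            continue
        bins.append((float(b0), float(b1)))
        for j, name in enumerate(stat_map.model_names):
            keep = sig[j][:, in_bin].all(axis=1)
            sensors_per_bin[(name, len(bins) - 1)] = sensor_ids[keep]
    return BinnedSignificance(
        bins=bins, model_names=list(stat_map.model_names), sensors_per_bin=sensors_per_bin
    )
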