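"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package implementation:
TFCE is computed by an explicit threshold sweep with scipy's connected
components, and relative weights by two literal least-squares regressions.
"""

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from megrwa.group_stats import spatiotemporal_edges


def brute_force_tfce(stat_map, sensor_adjacency, E=0.5, H=2.0, n_steps=100, h_max=None):
    """Threshold sweep: at each height, label supra-threshold clusters and
    add extent**E * h**H * dh to every member."""
    values = np.asarray(stat_map, dtype=float).ravel()
    top = values.max() if h_max is None else h_max
    out = np.zeros_like(values)
    if top <= 0:
        return out.reshape(stat_map.shape)
    n_times = stat_map.shape[1]
    edges = spatiotemporal_edges(sensor_adjacency, n_times)
    n = values.size
    graph = sp.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    ).tocsr()
    dh = top / n_steps
    for step in range(1, n_steps + 1):
        h = step * dh
        mask = values >= h
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        sub = graph[idx][:, idx]
        n_comp, labels = connected_components(sub + sub.T, directed=False)
        sizes = np.bincount(labels, minlength=n_comp)
        out[idx] += sizes[labels] ** E * h**H * dh
    return out.reshape(stat_map.shape)


def rwa_oracle(y, X, n_null=None):
    """Step-by-step relative weights: standardize, orthogonalize via SVD,
    run the two regressions literally with lstsq, then apply the epsilon
    sum.  Returns (epsilon, r_squared_ols)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    Xs = (X - X.mean(0)) / X.std(0)
    ys = (y - y.mean()) / y.std()
    U, D, Vt = np.linalg.svd(Xs, full_matrices=False)
    Z = np.sqrt(n) * (U @ Vt)  # unit-variance orthogonal counterpart
    beta, *_ = np.linalg.lstsq(Z, ys, rcond=None)
    lam_cols = []
    for j in range(Xs.shape[1]):
        c, *_ = np.linalg.lstsq(Z, Xs[:, j], rcond=None)
        lam_cols.append(c)
    lam = np.stack(lam_cols)  # (j, k)
    eps = (lam**2) @ (beta**2)
    b_ols, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ b_ols
    r2 = 1.0 - (resid**2).sum() / (ys**2).sum()
    return eps, r2
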