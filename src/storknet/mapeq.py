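"""Two-level map-equation community detection for weighted directed networks.

Random-walk visit rates come from the teleporting walk (PageRank with uniform
teleportation, probability tau); the map equation scores a partition M by the
expected per-step description length

    L(M) = q H(Q) + sum_m p_m~ H(P_m)

where q is the total module-exit flow, H(Q) the entropy of the exit-flow
distribution, and H(P_m) the entropy of module m's internal visit + exit
codebook. Teleportation steps are recorded in the exit flows, so the
one-module partition has L equal to the entropy of the visit rates. The
optimiser is deterministic greedy search (seeded restart order): single-node
moves to neighbouring modules to convergence, then module merges, repeated
until no improvement; this optimises the same objective as random-walk-based
implementations without simulating walks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FlowDistribution:
    p: np.ndarray  # stationary visit rate per node, sums to 1
    tau: float
    transition: np.ndarray = field(repr=False)  # row-stochastic walk matrix (link part)


@dataclass
class ModulePartition:
    modules: np.ndarray  # module id per node index (canonical: first-seen order)
    codelength_bits: float
    seed: int
    tau: float

    def as_series(self, node_ids) -> pd.Series:
        return pd.Series(self.modules, index=pd.Index(node_ids, name="node_id"), name="module_id")


def _weight_matrix(network) -> np.ndarray:
    if isinstance(network, np.ndarray):
        w = np.asarray(network, dtype=float).copy()
        np.fill_diagonal(w, 0.0)
        return w
    return network.weight_matrix()


def stationary_flow(network, tau: float = 0.15, tol: float = 1e-12, max_iter: int = 100_000) -> FlowDistribution:
    """Visit rates of the weighted walk with uniform teleportation.

    Power iteration on p <- tau/n + (1-tau) p P, where P follows out-weights
    proportionally and dangling nodes teleport uniformly; converged when the
    L1 change drops below ``tol``.
    """
    w = _weight_matrix(network)
    n = w.shape[0]
    if n == 1:
        return FlowDistribution(p=np.ones(1), tau=tau, transition=np.ones((1, 1)))
    s = w.sum(axis=1)
    dangling = s == 0
    P = w / np.where(dangling, 1.0, s)[:, None]
    P[dangling] = 1.0 / n
    p = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = tau / n + (1.0 - tau) * (p @ P)
        if np.abs(new - p).sum() < tol:
            return FlowDistribution(p=new / new.sum(), tau=tau, transition=P)
        p = new
    raise RuntimeError(f"stationary flow did not converge in {max_iter} iterations")


def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out if out.ndim else float(out)


def codelength(modules: np.ndarray, flow: FlowDistribution, network) -> float:
    """Map-equation description length (bits) of a two-level partition."""
    w = _weight_matrix(network)
    n = w.shape[0]
    modules = np.asarray(modules)
    labels = np.unique(modules)
    if len(modules) != n:
        raise ValueError("partition must cover all nodes")
    p = flow.p
    tau = flow.tau
    P = flow.transition
    # node-to-module flow: F[alpha, m] = (1-tau) * p_alpha * sum_{beta in m} P[alpha, beta]
    M = np.zeros((n, len(labels)))
    for k, m in enumerate(labels):
        M[:, k] = modules == m
    if np.any(M.sum(axis=0) == 0):
        raise ValueError("empty module in partition")
    F = (1.0 - tau) * (p[:, None] * (P @ M))
    node_mod = np.argmax(M, axis=1)
    p_mod = np.array([p[modules == m].sum() for m in labels])
    n_mod = M.sum(axis=0)
    # exit flow: teleportation to nodes outside the module + link flow leaving it
    q = tau * p_mod * (n - n_mod) / n
    for k in range(len(labels)):
        inside = node_mod == k
        q[k] += F[inside].sum() - F[inside, k].sum()
    q_tot = q.sum()
    p_tilde = q + p_mod
    L = _plogp(q_tot) - 2.0 * _plogp(q).sum() + _plogp(p_tilde).sum() - _plogp(p).sum()
    return float(L)


def _canonical(modules: np.ndarray) -> np.ndarray:
    """Relabel modules by first appearance (0, 1, ...)."""
    seen: dict[int, int] = {}
    out = np.empty(len(modules), dtype=int)
    for i, m in enumerate(modules):
        out[i] = seen.setdefault(int(m), len(seen))
    return out


def detect_modules(network, seed: int = 0, n_restarts: int = 10, tau: float = 0.15) -> ModulePartition:
    """Minimise the map equation by greedy moves and merges with restarts.

    Deterministic for a given seed. The returned codelength is never worse
    than the one-module partition (which is always evaluated as a candidate).
    """
    w = _weight_matrix(network)
    n = w.shape[0]
    flow = stationary_flow(w, tau=tau)
    rng = np.random.default_rng(seed)
    neighbours = [np.flatnonzero((w[i] > 0) | (w[:, i] > 0)) for i in range(n)]

    def optimise(order: np.ndarray) -> tuple[np.ndarray, float]:
        modules = np.arange(n)
        best_L = codelength(modules, flow, w)
        improved = True
        while improved:
            improved = False
            # single-node moves to a neighbouring module
            for i in order:
                current = modules[i]
                cands = {modules[j] for j in neighbours[i]} - {current}
                # a singleton cannot move to an empty module; others may split off
                if np.sum(modules == current) > 1:
                    cands.add(n + i)  # fresh module id
                for cand in sorted(cands):
                    trial = modules.copy()
                    trial[i] = cand
                    L = codelength(trial, flow, w)
                    if L < best_L - 1e-12:
                        modules, best_L = trial, L
                        improved = True
            # merges of connected module pairs
            merged = True
            while merged:
                merged = False
                labels = np.unique(modules)
                for a_i in range(len(labels)):
                    for b_i in range(a_i + 1, len(labels)):
                        a, b = labels[a_i], labels[b_i]
                        ia, ib = modules == a, modules == b
                        if not (w[ia][:, ib].any() or w[ib][:, ia].any()):
                            continue
                        trial = modules.copy()
                        trial[ib] = a
                        L = codelength(trial, flow, w)
                        if L < best_L - 1e-12:
                            modules, best_L = trial, L
                            improved = merged = True
        return modules, best_L

    best_modules = np.zeros(n, dtype=int)
    best_L = codelength(best_modules, flow, w)  # one-module baseline
    for _ in range(max(1, n_restarts)):
        order = rng.permutation(n)
        modules, L = optimise(order)
        if L < best_L - 1e-12:
            best_modules, best_L = modules, L
    return ModulePartition(modules=_canonical(best_modules), codelength_bits=best_L, seed=seed, tau=tau)


def module_hulls(net, partition: ModulePartition) -> list[dict]:
    """Convex hulls of node centroids per module, as GeoJSON-ready records."""
    import shapely

    recs = []
    lon = net.nodes["lon"].to_numpy()
    lat = net.nodes["lat"].to_numpy()
    for m in np.unique(partition.modules):
        pts = shapely.MultiPoint(
            [(float(x), float(y)) for x, y in zip(lon[partition.modules == m], lat[partition.modules == m])]
        )
        recs.append({"geometry": pts.convex_hull, "module_id": int(m), "n_nodes": int(np.sum(partition.modules == m))})
    return recs
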