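"""Community detection and modularity scoring for fully connected signed graphs.

The partition-quality statistic is the asymmetric signed modularity

    Q* = Q+ - (v- / (v+ + v-)) * Q-

where, separately for the positive-part and negative-part weights,

    Q+- = (1/v+-) * sum_{ij} (w_ij - s_i s_j / v) * delta(c_i, c_j)

with ``v`` the total weight of that sign, ``s_i`` the node strengths, and
the sum running over all node pairs with ``w_ii = 0`` (the diagonal carries
no weight, but its expected-weight term ``-s_i^2 / v`` is kept, which makes
the all-in-one partition score exactly 0 on an all-positive graph).
Positive within-module weight is rewarded at full strength while negative
within-module weight is penalized, down-weighted by the negative fraction of
total weight.  For a graph with no negative weights the negative term
vanishes and Q* reduces to ordinary weighted modularity, which is exactly 0
for the all-in-one partition.

Because Q* is linear in the community indicator, maximizing it is equivalent
to maximizing ``sum_{i != j} B_ij delta(c_i, c_j)`` over the combined
modularity matrix ``B`` returned by :func:`modularity_matrix`; the optimizer
works on ``B`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windows import ConnectivityMatrix

__all__ = [
    "Partition",
    "NodeModuleMetrics",
    "modularity_matrix",
    "qstar",
    "detect_modules",
    "null_model",
    "within_module_degree_z",
    "canonicalize_labels",
]

_EPS = 1e-12


def _as_weights(graph) -> np.ndarray:
    w = graph.weights if isinstance(graph, ConnectivityMatrix) else np.asarray(graph, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("graph weights must be a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("graph weights must be symmetric")
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)  # diagonal never contributes
    return w


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber module labels 1..m in order of first appearance (idempotent)."""
    labels = np.asarray(labels)
    out = np.empty(labels.size, dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        key = lab.item() if hasattr(lab, "item") else lab
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        out[i] = mapping[key]
    return out


@dataclass
class Partition:
    """Per-node module labels (contiguous integers from 1) with their Q* value."""

    labels: np.ndarray
    n_modules: int
    qstar: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("labels must be contiguous integers starting at 1")
        if self.n_modules != uniq.size:
            raise ValueError(f"n_modules {self.n_modules} does not match label count {uniq.size}")


@dataclass
class NodeModuleMetrics:
    """Per-node within-module degree Z-scores under some partition."""

    within_module_z: np.ndarray


def modularity_matrix(graph) -> np.ndarray:
    """Combined signed modularity matrix B.

    ``Q*(labels) = sum_{ij} B_ij delta(c_i, c_j)`` over all pairs; the
    diagonal holds only the (partition-independent) expected-weight terms,
    so it shifts Q* but never changes which partition is optimal.
    """
    w = _as_weights(graph)
    wp = np.clip(w, 0.0, None)
    wn = np.clip(-w, 0.0, None)
    vp = wp.sum()
    vn = wn.sum()
    b = np.zeros_like(w)
    if vp > 0:
        sp = wp.sum(axis=1)
        b += (wp - np.outer(sp, sp) / vp) / vp
    if vn > 0:
        sn = wn.sum(axis=1)
        b -= (vn / (vp + vn)) * (wn - np.outer(sn, sn) / vn) / vn
    return b


def qstar(graph, labels: np.ndarray) -> float:
    """Evaluate Q* for the given module labels; lies in [-1, 1]."""
    w = _as_weights(graph)
    labels = np.asarray(labels)
    if labels.size != w.shape[0]:
        raise ValueError("labels length must match node count")
    b = modularity_matrix(w)
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum())


# ---------------------------------------------------------------------------
# Louvain-style optimizer on the combined modularity matrix
# ---------------------------------------------------------------------------

def _local_move_py(M: np.ndarray, order: np.ndarray, comm: np.ndarray) -> np.ndarray:
    """Greedy single-node moves until no move improves the objective.

    On equal gain the lowest candidate community index wins (canonical
    tie-break).  Written loop-wise so it can be JIT-compiled.
    """
    n = M.shape[0]
    improved = True
    while improved:
        improved = False
        for oi in range(n):
            i = order[oi]
            ci = comm[i]
            k = np.zeros(n)
            for j in range(n):
                if j != i:
                    k[comm[j]] += M[i, j]
            best_c = ci
            best_gain = 0.0
            base = k[ci]
            for c in range(n):
                g = k[c] - base
                if g > best_gain + _EPS:
                    best_gain = g
                    best_c = c
            if best_c != ci:
                comm[i] = best_c
                improved = True
    return comm


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _local_move = njit(cache=False)(_local_move_py)
except Exception:  # pragma: no cover
    _local_move = _local_move_py


def _louvain_run(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One seeded Louvain pass (local moves + agglomeration) on matrix B."""
    node_labels = np.arange(B.shape[0])
    M = B.copy()
    while True:
        n = M.shape[0]
        order = rng.permutation(n)
        comm = _local_move(M, order, np.arange(n))
        uniq, compact = np.unique(comm, return_inverse=True)
        c = uniq.size
        if c == n:
            break
        node_labels = compact[node_labels]
        onehot = np.zeros((n, c))
        onehot[np.arange(n), compact] = 1.0
        M = onehot.T @ M @ onehot
    return node_labels


def detect_modules(graph, n_restarts: int = 10, seed: int | np.random.Generator = 0) -> Partition:
    """Maximize Q* by Louvain-style agglomeration with seeded random restarts.

    Each restart shuffles the node visiting order; the best partition over
    restarts is returned with canonicalized labels.  Identical seed gives an
    identical partition.
    """
    w = _as_weights(graph)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    b = modularity_matrix(w)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    best_q = -np.inf
    best_labels = None
    for _ in range(n_restarts):
        labels = _louvain_run(b, rng)
        same = labels[:, None] == labels[None, :]
        q = float(b[same].sum())
        if q > best_q + _EPS:
            best_q = q
            best_labels = labels
    labels = canonicalize_labels(best_labels)
    return Partition(labels=labels, n_modules=int(labels.max()), qstar=best_q)


# ---------------------------------------------------------------------------
# Weight- and strength-preserving null model
# ---------------------------------------------------------------------------

def _place_sign(
    slots_i: np.ndarray,
    slots_j: np.ndarray,
    values: np.ndarray,
    target_strength: np.ndarray,
    rng: np.random.Generator,
    n_passes: int,
) -> np.ndarray:
    """Assign the weight magnitudes ``values`` to the given edge slots.

    Initial placement ranks slots by jittered expected strength (sum of the
    two endpoints' original strengths of this sign) and matches them with the
    sorted magnitudes; ``n_passes`` vectorized swap-refinement passes then
    reduce the squared error between realized and original node strengths.
    """
    e = values.size
    if e == 0:
        return values
    score = target_strength[slots_i] + target_strength[slots_j]
    jitter = 0.15 * (score.std() + 1e-12)
    noisy = score + jitter * rng.standard_normal(e)
    slot_order = np.argsort(-noisy, kind="stable")
    placed = np.empty(e)
    placed[slot_order] = np.sort(values)[::-1]
    n = target_strength.size

    def _swap_round() -> None:
        t = np.bincount(slots_i, weights=placed, minlength=n) + np.bincount(
            slots_j, weights=placed, minlength=n
        )
        err = t - target_strength
        perm = rng.permutation(e)
        half = e // 2
        a, b = perm[:half], perm[half : 2 * half]
        d = placed[b] - placed[a]
        delta = (
            2.0 * d * (err[slots_i[a]] + err[slots_j[a]] - err[slots_i[b]] - err[slots_j[b]])
            + 4.0 * d**2
        )
        # apply best swaps first, skipping any whose endpoints were already
        # touched this round (interacting swaps would invalidate the deltas)
        used = np.zeros(n, dtype=bool)
        for idx in np.argsort(delta):
            if delta[idx] >= 0.0:
                break
            quad = (slots_i[a[idx]], slots_j[a[idx]], slots_i[b[idx]], slots_j[b[idx]])
            if len(set(quad)) < 4 or used[list(quad)].any():
                continue
            placed[a[idx]], placed[b[idx]] = placed[b[idx]], placed[a[idx]]
            used[list(quad)] = True

    for _ in range(n_passes):
        for _ in range(6):  # a pass proposes several conflict-free swap rounds
            _swap_round()
    return placed


def null_model(graph, seed: int | np.random.Generator = 0, n_passes: int = 10) -> ConnectivityMatrix:
    """Randomized graph preserving the signed weight multisets and, approximately,
    the per-node positive and negative strength sequences.

    On a complete graph the degree distribution is trivially preserved, so
    randomization acts on the weights: which node pairs carry positive versus
    negative weights is drawn at random, the exact positive and negative
    weight multisets are then re-placed by a strength-targeted rank matching,
    and ``n_passes`` refinement passes tighten the match between each node's
    null and original strengths.
    """
    w = _as_weights(graph)
    n = w.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    pos_vals = vals[vals > 0]
    neg_vals = vals[vals <= 0]
    sp = np.clip(w, 0.0, None).sum(axis=1)
    sn = np.clip(-w, 0.0, None).sum(axis=1)
    e = vals.size
    perm = rng.permutation(e)
    pos_slots = perm[: pos_vals.size]
    neg_slots = perm[pos_vals.size :]
    new_vals = np.empty(e)
    new_vals[pos_slots] = _place_sign(iu[pos_slots], ju[pos_slots], pos_vals, sp, rng, n_passes)
    new_vals[neg_slots] = -_place_sign(
        iu[neg_slots], ju[neg_slots], -neg_vals, sn, rng, n_passes
    )
    out = np.zeros((n, n))
    out[iu, ju] = new_vals
    out += out.T
    np.fill_diagonal(out, 1.0)
    idx = graph.window_index if isinstance(graph, ConnectivityMatrix) else 0
    ctr = graph.center_volume if isinstance(graph, ConnectivityMatrix) else 0
    return ConnectivityMatrix(weights=out, window_index=idx, center_volume=ctr)


def within_module_degree_z(graph, labels: np.ndarray, weight_mode: str = "signed") -> NodeModuleMetrics:
    """Within-module degree Z-score of every node under the given labels.

    ``kappa_i`` is the summed (signed, or positive-only) weight from node i
    to the other members of its module; ``z_i`` standardizes ``kappa`` within
    the module using the population (divide-by-n) standard deviation.
    Singleton modules and zero-variance modules get z = 0.
    """
    w = _as_weights(graph)
    if weight_mode == "positive":
        w = np.clip(w, 0.0, None)
    elif weight_mode != "signed":
        raise ValueError(f"weight_mode must be 'signed' or 'positive', got {weight_mode!r}")
    labels = np.asarray(labels)
    if labels.size != w.shape[0]:
        raise ValueError("labels length must match node count")
    z = np.zeros(labels.size)
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if members.size < 2:
            continue
        sub = w[np.ix_(members, members)]
        kappa = sub.sum(axis=1)
        sd = kappa.std()  # population form
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return NodeModuleMetrics(within_module_z=z)
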