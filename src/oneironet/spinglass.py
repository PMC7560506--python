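"""Potts-model (spin-glass) community detection by simulated annealing.

Communities are found by minimizing the weighted Reichardt–Bornholdt
Hamiltonian with a configuration-model null model on node strengths:

    H(sigma) = - sum_{i<j} [ w_ij - gamma * s_i * s_j / (2W) ] * delta(sigma_i, sigma_j)

where ``w_ij`` is the edge weight (phi), ``s_i`` the strength of node
``i`` (sum of incident weights), ``W`` the total edge weight, ``gamma``
the null-model coefficient and ``delta`` the same-community indicator.
Placing two nodes together is rewarded when their edge weight exceeds the
null-model expectation and penalised otherwise; the all-singleton
configuration has energy exactly 0, so the optimal energy is always <= 0.
At ``gamma = 1`` minimizing H is equivalent to maximizing weighted
modularity.

Optimization is Metropolis simulated annealing over spin states
(community labels), run independently on each connected component — the
thresholded dream networks are typically disconnected, and nodes in
different components never profit from sharing a label. The best state
ever visited across restarts is kept, the singleton configuration is
always among the evaluated candidates, and the whole procedure is
deterministic given the seed.

For graphs of at most eight nodes, :func:`brute_force_best_partition`
finds the exact ground state by enumerating every set partition; it
serves as an independent oracle for the annealer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from oneironet._util import round12
from oneironet.cooccurrence import WordNetwork

__all__ = [
    "SpinglassParams",
    "Partition",
    "hamiltonian",
    "spinglass",
    "brute_force_best_partition",
]


@dataclass(frozen=True)
class SpinglassParams:
    """Annealer settings.

    ``spins`` caps the number of communities per component; ``gamma``
    weighs the null model (larger values fragment the graph more);
    ``t_start``/``t_stop``/``cooling`` define the geometric temperature
    schedule; ``restarts`` independent runs guard against local minima.
    """

    spins: int = 25
    gamma: float = 1.0
    t_start: float = 1.0
    t_stop: float = 0.01
    cooling: float = 0.99
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spins < 2:
            raise ValueError("spins must be >= 2")
        if not self.t_start > self.t_stop > 0:
            raise ValueError("need t_start > t_stop > 0")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class Partition:
    """A community assignment with its Hamiltonian energy.

    Cluster ids are contiguous from 1; when the network is disconnected
    each component was optimized independently (``per_component``) and
    ids are globally unique across components.
    """

    assignment: dict[str, int]
    energy: float
    params: SpinglassParams
    per_component: bool = True

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for word in sorted(self.assignment):
            out.setdefault(self.assignment[word], []).append(word)
        return out


def _strengths(network: WordNetwork) -> dict[str, float]:
    s = {w: 0.0 for w in network.nodes}
    for (a, b), (w, _) in network.edges.items():
        s[a] += w
        s[b] += w
    return s


def hamiltonian(network: WordNetwork, assignment: dict[str, int], gamma: float = 1.0) -> float:
    """Evaluate H(sigma) for a full assignment; singleton assignment gives 0.

    The null-model term runs over *all* same-community pairs, not just
    edges, so padding a community with unrelated nodes costs energy.
    """
    missing = set(network.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")
    total_w = network.total_weight
    if not total_w > 0:
        raise ValueError("Hamiltonian undefined: total edge weight is not positive")
    strengths = _strengths(network)
    intra_edge_weight = sum(
        w for (a, b), (w, _) in network.edges.items() if assignment[a] == assignment[b]
    )
    # sum over same-community pairs of s_i s_j = (S_c^2 - sum s_i^2) / 2 per community
    s_sum: dict[int, float] = {}
    s_sq: dict[int, float] = {}
    for word, cluster in assignment.items():
        s = strengths[word]
        s_sum[cluster] = s_sum.get(cluster, 0.0) + s
        s_sq[cluster] = s_sq.get(cluster, 0.0) + s * s
    null_pairs = sum((s_sum[c] ** 2 - s_sq[c]) / 2.0 for c in s_sum)
    return -intra_edge_weight + gamma * null_pairs / (2.0 * total_w)


def _components(network: WordNetwork) -> list[list[str]]:
    parent = {w: w for w in network.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in network.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for w in sorted(network.nodes):
        groups.setdefault(find(w), []).append(w)
    return sorted(groups.values(), key=lambda g: g[0])


def _anneal_component(
    nodes: list[str],
    adj: dict[str, list[tuple[str, float]]],
    strengths: dict[str, float],
    total_w: float,
    params: SpinglassParams,
    rng: np.random.Generator,
) -> tuple[dict[str, int], float]:
    """Metropolis annealing on one connected component; global W null model."""
    n = len(nodes)
    q = min(params.spins, n)
    coeff = params.gamma / (2.0 * total_w)

    def energy_of(state: dict[str, int]) -> float:
        e = 0.0
        for v in nodes:
            cv = state[v]
            for u, w in adj[v]:
                if state[u] == cv and u > v:
                    e -= w
        s_sum: dict[int, float] = {}
        s_sq: dict[int, float] = {}
        for v in nodes:
            s = strengths[v]
            s_sum[state[v]] = s_sum.get(state[v], 0.0) + s
            s_sq[state[v]] = s_sq.get(state[v], 0.0) + s * s
        return e + coeff * sum((s_sum[c] ** 2 - s_sq[c]) / 2.0 for c in s_sum)

    best_state: dict[str, int] | None = None
    best_energy = math.inf
    for _ in range(params.restarts):
        state = {v: int(c) for v, c in zip(nodes, rng.integers(0, q, size=n))}
        cluster_strength: dict[int, float] = {}
        for v in nodes:
            cluster_strength[state[v]] = cluster_strength.get(state[v], 0.0) + strengths[v]
        energy = energy_of(state)
        if energy < best_energy:
            best_energy, best_state = energy, dict(state)
        t = params.t_start
        while t > params.t_stop:
            for _ in range(n):
                v = nodes[int(rng.integers(0, n))]
                old = state[v]
                new = int(rng.integers(0, q))
                if new == old:
                    continue
                sv = strengths[v]
                w_old = w_new = 0.0
                for u, w in adj[v]:
                    cu = state[u]
                    if cu == old:
                        w_old += w
                    elif cu == new:
                        w_new += w
                delta = (w_old - sv * (cluster_strength[old] - sv) * coeff) - (
                    w_new - sv * cluster_strength.get(new, 0.0) * coeff
                )
                if delta <= 0 or rng.random() < math.exp(-delta / t):
                    state[v] = new
                    cluster_strength[old] -= sv
                    cluster_strength[new] = cluster_strength.get(new, 0.0) + sv
                    energy += delta
                    if energy < best_energy - 1e-12:
                        best_energy, best_state = energy, dict(state)
            t *= params.cooling
    assert best_state is not None
    # singleton configuration (energy 0) is always a candidate
    if best_energy > 0.0:
        return {v: i for i, v in enumerate(nodes)}, 0.0
    return best_state, best_energy


def spinglass(network: WordNetwork, params: SpinglassParams | None = None) -> Partition:
    """Best-found community partition of a word network.

    Each connected component is annealed independently; cluster ids are
    relabelled contiguously from 1 across components in deterministic
    order. Identical seeds yield identical partitions. The returned
    energy is recomputed from the stored assignment, so it is always
    reproducible via :func:`hamiltonian`.
    """
    params = params or SpinglassParams()
    if network.n_nodes == 0:
        raise ValueError("cannot cluster an empty network")
    rng = np.random.default_rng(params.seed)
    total_w = network.total_weight
    strengths = _strengths(network)
    adj: dict[str, list[tuple[str, float]]] = {w: [] for w in network.nodes}
    for (a, b), (w, _) in network.edges.items():
        adj[a].append((b, w))
        adj[b].append((a, w))

    assignment: dict[str, int] = {}
    next_id = 1
    for component in _components(network):
        if len(component) == 1 or total_w <= 0:
            for v in component:
                assignment[v] = next_id
                next_id += 1
            continue
        local, _ = _anneal_component(component, adj, strengths, total_w, params, rng)
        relabel: dict[int, int] = {}
        for v in component:  # components are sorted, so relabelling is deterministic
            c = local[v]
            if c not in relabel:
                relabel[c] = next_id
                next_id += 1
            assignment[v] = relabel[c]
    energy = round12(hamiltonian(network, assignment, params.gamma)) if total_w > 0 else 0.0
    return Partition(assignment=assignment, energy=energy, params=params, per_component=True)


def _set_partitions(items: Sequence[str]) -> Iterator[list[list[str]]]:
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield smaller + [[first]]


def brute_force_best_partition(network: WordNetwork, gamma: float = 1.0) -> Partition:
    """Exact ground state by enumerating all set partitions (<= 8 nodes).

    Ties are broken by enumeration order (first minimum wins), which is
    deterministic for a given node set.
    """
    nodes = sorted(network.nodes)
    if len(nodes) > 8:
        raise ValueError(f"brute force limited to 8 nodes, got {len(nodes)}")
    if not network.total_weight > 0:
        raise ValueError("Hamiltonian undefined: total edge weight is not positive")
    best_energy = math.inf
    best_blocks: list[list[str]] | None = None
    for blocks in _set_partitions(nodes):
        assignment = {v: i + 1 for i, block in enumerate(blocks) for v in block}
        energy = hamiltonian(network, assignment, gamma)
        if energy < best_energy - 1e-12:
            best_energy, best_blocks = energy, blocks
    assert best_blocks is not None
    assignment = {}
    next_id = 1
    for i, block in enumerate(best_blocks):
        for v in block:
            assignment[v] = i
    relabel: dict[int, int] = {}
    final: dict[str, int] = {}
    for v in nodes:
        c = assignment[v]
        if c not in relabel:
            relabel[c] = next_id
            next_id += 1
        final[v] = relabel[c]
    params = SpinglassParams(gamma=gamma)
    return Partition(assignment=final, energy=round12(best_energy), params=params,
                     per_component=False)
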