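"""Node-importance indexes for word networks.

Three families of centrality are reported per word:

* **degree / strength** — the count of adjacent edges, and the sum of the
  incident phi weights (how strongly, in total, a word is associated with
  its neighbours);
* **betweenness** — the (fractionally credited) number of shortest paths
  between other word pairs passing through the word, with unweighted
  hop-count paths by default, endpoints excluded, and each unordered pair
  counted once (Brandes accumulation via networkx);
* **closeness** — the reciprocal of the sum of shortest-path distances
  from the word to every other word in its connected component; an
  isolated-in-component convention of 0 covers single-node components.

A weighted-path mode (edge length 1/phi, so strong associations are
short) exists behind a flag, as does the mean-distance closeness variant
(a component-size rescaling); hop counts and the reciprocal-of-sum form
are the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from oneironet._util import round12
from oneironet.cooccurrence import WordNetwork

__all__ = [
    "CentralityRow",
    "degree_and_strength",
    "betweenness",
    "closeness",
    "centrality_table",
    "top_k",
]

METRICS = ("degree", "strength", "betweenness", "closeness")


@dataclass(frozen=True)
class CentralityRow:
    word: str
    degree: int
    strength: float
    betweenness: float
    closeness: float


def _graph(network: WordNetwork, weighted: bool) -> nx.Graph:
    g = network.to_networkx()
    if weighted:
        for _, _, data in g.edges(data=True):
            data["distance"] = 1.0 / data["weight"]
    return g


def degree_and_strength(network: WordNetwork) -> dict[str, tuple[int, float]]:
    """Per-word (edge count, sum of incident phi weights)."""
    out = {w: [0, 0.0] for w in network.nodes}
    for (a, b), (w, _) in network.edges.items():
        out[a][0] += 1
        out[a][1] += w
        out[b][0] += 1
        out[b][1] += w
    return {w: (d, round12(s)) for w, (d, s) in out.items()}


def betweenness(network: WordNetwork, weighted: bool = False) -> dict[str, float]:
    """Raw (unnormalized) betweenness; fractional credit across ties."""
    g = _graph(network, weighted)
    raw = nx.betweenness_centrality(
        g, normalized=False, weight="distance" if weighted else None
    )
    return {w: round12(v) for w, v in raw.items()}


def closeness(
    network: WordNetwork, weighted: bool = False, mean_distance: bool = False
) -> dict[str, float]:
    """Reciprocal of the summed distances to all words in the component.

    With ``mean_distance`` the reciprocal of the *mean* shortest distance
    is returned instead (a factor component-size−1 rescaling). Nodes in
    single-node components get 0.
    """
    g = _graph(network, weighted)
    out: dict[str, float] = {}
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        m = len(component)
        for v in component:
            if m == 1:
                out[v] = 0.0
                continue
            if weighted:
                dist = nx.single_source_dijkstra_path_length(sub, v, weight="distance")
            else:
                dist = nx.single_source_shortest_path_length(sub, v)
            total = sum(dist.values())
            value = (m - 1) / total if mean_distance else 1.0 / total
            out[v] = round12(value)
    return out


def centrality_table(
    network: WordNetwork, weighted: bool = False, mean_distance: bool = False
) -> list[CentralityRow]:
    """All four indexes per word, sorted by word."""
    ds = degree_and_strength(network)
    btw = betweenness(network, weighted=weighted)
    cls = closeness(network, weighted=weighted, mean_distance=mean_distance)
    return [
        CentralityRow(word=w, degree=ds[w][0], strength=ds[w][1],
                      betweenness=btw[w], closeness=cls[w])
        for w in sorted(network.nodes)
    ]


def top_k(table: Sequence[CentralityRow], metric: str, k: int) -> list[str]:
    """Top-``k`` words by a metric, descending, alphabetical tie-break."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table, key=lambda r: (-getattr(r, metric), r.word))
    return [r.word for r in ranked[:k]]
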