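"""Word co-occurrence networks scored with the phi coefficient.

A corpus of dream reports is reduced to a report × word binary incidence
structure (a word counts once per report, however often it recurs within
it). For every word pair the 2×2 co-occurrence table over reports gives
the phi coefficient

    phi = (n11*n00 - n10*n01) / sqrt((n11+n10)(n01+n00)(n11+n01)(n10+n00)),

which equals the Pearson correlation of the two binary presence vectors:
it measures how much more likely the two words are to appear together or
to be jointly absent than to appear alone. The association network keeps
words present in at least ``min_doc_freq`` reports and edges with
phi strictly above ``min_phi`` (defaults 5 and 0.2); words left without
any edge are dropped, since they can contribute to no cluster or
centrality ranking.

Adjacent-pair (bigram) counts from the chronological token lists are kept
as an edge attribute: tokenization splits each dream into ordered word
pairs, but the association statistic itself is computed on report-level
co-appearance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from oneironet._util import round12
from oneironet.corpus_io import DreamReport

__all__ = [
    "UndefinedStatisticError",
    "PairCount",
    "NetworkThresholds",
    "WordNetwork",
    "Incidence",
    "tokenize_bigrams",
    "build_incidence",
    "pair_counts",
    "phi",
    "bigram_pair_counts",
    "build_network",
]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. a zero margin)."""


def tokenize_bigrams(tokens: Sequence[str]) -> list[tuple[str, str]]:
    """Split an ordered token list into its adjacent word pairs.

    Returns ``max(0, len(tokens) - 1)`` pairs in order, without
    deduplication: ``[a, b, c] -> [(a, b), (b, c)]``.
    """
    return list(zip(tokens, tokens[1:]))


@dataclass(frozen=True)
class PairCount:
    """2×2 report-level co-occurrence table for a word pair.

    ``n11``/``n10``/``n01``/``n00`` count reports containing both words /
    only ``word_a`` / only ``word_b`` / neither. ``bigram_count`` is the
    number of times the two words were chronologically adjacent (either
    order) anywhere in the corpus.
    """

    word_a: str
    word_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    bigram_count: int = 0

    def __post_init__(self) -> None:
        if self.word_a >= self.word_b:
            raise ValueError("word_a must be lexicographically before word_b")
        if min(self.n11, self.n10, self.n01, self.n00, self.bigram_count) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_reports(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class NetworkThresholds:
    """Retention filters: document frequency floor and strict phi floor."""

    min_doc_freq: int = 5
    min_phi: float = 0.2

    def __post_init__(self) -> None:
        if self.min_doc_freq < 1:
            raise ValueError("min_doc_freq must be >= 1")
        if not -1.0 <= self.min_phi <= 1.0:
            raise ValueError("min_phi must be in [-1, 1]")


@dataclass
class WordNetwork:
    """Undirected word-association network.

    ``nodes`` maps each retained word to its document frequency; ``edges``
    maps lexicographically ordered pairs to ``(phi, bigram_count)``.
    """

    nodes: dict[str, int]
    edges: dict[tuple[str, str], tuple[float, int]]
    thresholds: NetworkThresholds = field(default_factory=NetworkThresholds)
    stratum: str = "all"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> float:
        return sum(phi_val for phi_val, _ in self.edges.values())

    def neighbors(self, word: str) -> Iterator[tuple[str, float]]:
        for (a, b), (phi_val, _) in self.edges.items():
            if a == word:
                yield b, phi_val
            elif b == word:
                yield a, phi_val

    def validate(self) -> None:
        for (a, b), (phi_val, bigrams) in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a >= b:
                raise ValueError(f"edge {(a, b)!r} not lexicographically ordered")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)!r} has endpoint outside node set")
            if not phi_val > self.thresholds.min_phi and not abs(phi_val) > self.thresholds.min_phi:
                raise ValueError(f"edge {(a, b)!r} below phi threshold")
            if bigrams < 0:
                raise ValueError("negative bigram count")
        for word, doc_freq in self.nodes.items():
            if doc_freq < self.thresholds.min_doc_freq:
                raise ValueError(f"node {word!r} below doc-freq floor")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for word, doc_freq in self.nodes.items():
            g.add_node(word, doc_freq=doc_freq)
        for (a, b), (phi_val, bigrams) in self.edges.items():
            g.add_edge(a, b, weight=phi_val, bigram_count=bigrams)
        return g


@dataclass
class Incidence:
    """Binary report × word presence structure with document frequencies."""

    words: tuple[str, ...]
    matrix: np.ndarray  # shape (n_reports, n_words), dtype bool
    doc_freq: dict[str, int]

    @property
    def n_reports(self) -> int:
        return int(self.matrix.shape[0])

    def column(self, word: str) -> np.ndarray:
        try:
            idx = self.words.index(word)
        except ValueError:
            raise KeyError(f"unknown word {word!r}") from None
        return self.matrix[:, idx]


def build_incidence(reports: Sequence[DreamReport]) -> Incidence:
    """Report-level binary presence; duplicates within a report count once."""
    if not reports:
        raise ValueError("cannot build incidence from zero reports")
    vocab = sorted({t for r in reports for t in r.tokens})
    index = {w: i for i, w in enumerate(vocab)}
    matrix = np.zeros((len(reports), len(vocab)), dtype=bool)
    for i, report in enumerate(reports):
        for token in report.tokens:
            matrix[i, index[token]] = True
    doc_freq = {w: int(matrix[:, i].sum()) for w, i in index.items()}
    return Incidence(words=tuple(vocab), matrix=matrix, doc_freq=doc_freq)


def pair_counts(incidence: Incidence, word_a: str, word_b: str,
                bigram_count: int = 0) -> PairCount:
    """2×2 table for two distinct words over the incidence reports."""
    if word_a == word_b:
        raise ValueError("self-pairs are not defined")
    a, b = sorted((word_a, word_b))
    col_a, col_b = incidence.column(a), incidence.column(b)
    n11 = int((col_a & col_b).sum())
    n10 = int((col_a & ~col_b).sum())
    n01 = int((~col_a & col_b).sum())
    n00 = int((~col_a & ~col_b).sum())
    return PairCount(a, b, n11, n10, n01, n00, bigram_count)


def phi(pc: PairCount) -> float:
    """Phi coefficient of a 2×2 table; equals binary-vector Pearson r.

    Raises :class:`UndefinedStatisticError` when any margin is zero (a
    word present in every report or in none), in which case the pair is
    excluded from networks.
    """
    m_a1 = pc.n11 + pc.n10
    m_a0 = pc.n01 + pc.n00
    m_b1 = pc.n11 + pc.n01
    m_b0 = pc.n10 + pc.n00
    if min(m_a1, m_a0, m_b1, m_b0) == 0:
        raise UndefinedStatisticError(
            f"phi undefined for {pc.word_a}/{pc.word_b}: zero margin"
        )
    num = pc.n11 * pc.n00 - pc.n10 * pc.n01
    den = float(m_a1) * m_a0 * m_b1 * m_b0
    return num / np.sqrt(den)


def bigram_pair_counts(reports: Sequence[DreamReport]) -> Counter:
    """Adjacency counts per unordered word pair (self-adjacency excluded)."""
    counts: Counter = Counter()
    for report in reports:
        for x, y in tokenize_bigrams(report.tokens):
            if x != y:
                counts[tuple(sorted((x, y)))] += 1
    return counts


def build_network(
    reports: Sequence[DreamReport],
    thresholds: NetworkThresholds | None = None,
    stratum: str = "all",
    keep_negative: bool = False,
) -> WordNetwork:
    """Build the thresholded phi network for a set of reports.

    Words below the document-frequency floor are dropped; among retained
    words, edges keep pairs with defined phi strictly above ``min_phi``
    (signed by default; with ``keep_negative`` the threshold applies to
    \\|phi\\| so strong negative associations survive too). Words left
    isolated after edge filtering are removed. Construction is invariant
    to report order and may return an empty network.
    """
    thresholds = thresholds or NetworkThresholds()
    if not reports:
        return WordNetwork(nodes={}, edges={}, thresholds=thresholds, stratum=stratum)
    incidence = build_incidence(reports)
    n_reports = incidence.n_reports
    doc_freq = np.asarray([incidence.doc_freq[w] for w in incidence.words])
    kept = doc_freq >= thresholds.min_doc_freq
    kept_words = [w for w, k in zip(incidence.words, kept) if k]
    if len(kept_words) < 2:
        return WordNetwork(nodes={}, edges={}, thresholds=thresholds, stratum=stratum)

    x = incidence.matrix[:, kept].astype(np.int64)
    r = x.sum(axis=0)
    n11 = x.T @ x
    # margins: (n11+n10)=r_a, (n01+n00)=N-r_a, (n11+n01)=r_b, (n10+n00)=N-r_b;
    # r_a > 0 is guaranteed, so phi is defined iff both words miss >= 1 report
    n10 = r[:, None] - n11
    n01 = r[None, :] - n11
    n00 = n_reports - r[:, None] - r[None, :] + n11
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.sqrt((r[:, None] * (n_reports - r[:, None])).astype(float)
                      * (r[None, :] * (n_reports - r[None, :])).astype(float))
        phi_matrix = (n11 * n00 - n10 * n01) / den
    defined = (r[:, None] < n_reports) & (r[None, :] < n_reports)
    if keep_negative:
        passing = np.abs(phi_matrix) > thresholds.min_phi
    else:
        passing = phi_matrix > thresholds.min_phi
    ii, jj = np.where(np.triu(defined & passing, k=1))

    bigrams = bigram_pair_counts(reports)
    edges: dict[tuple[str, str], tuple[float, int]] = {}
    for i, j in zip(ii.tolist(), jj.tolist()):
        a, b = kept_words[i], kept_words[j]
        edges[(a, b)] = (round12(phi_matrix[i, j]), bigrams.get((a, b), 0))

    connected = {w for pair in edges for w in pair}
    nodes = {w: incidence.doc_freq[w] for w in sorted(connected)}
    return WordNetwork(nodes=nodes, edges=edges, thresholds=thresholds, stratum=stratum)
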