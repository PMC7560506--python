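"""Text I/O for dream-report corpora, surveys, harmonization rules and artifacts.

Every artifact the pipeline consumes or emits is a plain-text file:

* **Reports** — TSV with columns ``report_id``, ``respondent_id``,
  ``stratum``, ``tokens``. The token field is comma-separated; hyphens are
  reserved for compound words (``high-risk-group``), so the field parses
  unambiguously. Stratum labels are ``increased``, ``unchanged_lowered``
  and ``unspecified``.
* **Survey** — CSV with one row per respondent: ordinal stress change
  (1=lowered … 4=high increase), five ordinal sleep-change items coded in
  the worsening direction (1=improved, 2=no change, 3=worsened),
  demographics, and whether a dream was reported.
* **Rules** — YAML (or JSON) mapping file with keys ``synonyms``,
  ``categories``, ``keep``, ``notes``.
* **Networks / partitions / centralities** — TSV tables with ``#``-prefixed
  metadata headers; every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import yaml

from oneironet._util import round12

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids import cycles
    from oneironet.centrality import CentralityRow
    from oneironet.cooccurrence import WordNetwork
    from oneironet.spinglass import Partition

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Stratum",
    "DreamReport",
    "SurveyRecord",
    "HarmonizationRules",
    "read_reports",
    "write_reports",
    "read_survey",
    "write_survey",
    "read_rules",
    "write_rules",
    "read_network",
    "write_network",
    "write_graphml",
    "read_partition",
    "write_partition",
    "read_centrality",
    "write_centrality",
]


class FormatError(ValueError):
    """Raised when an input file violates the declared format."""


class Stratum(str, Enum):
    """Perceived-stress stratum of a dream report.

    Respondents rate how their stress changed under lockdown on a
    four-point ordinal scale; for the dream-content analysis the scale is
    aggregated to two groups (stress increased vs. unchanged/lowered).
    ``UNSPECIFIED`` absorbs reports whose respondent did not answer the
    stress item.
    """

    INCREASED = "increased"
    UNCHANGED_LOWERED = "unchanged_lowered"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class DreamReport:
    """One transcribed dream: an ordered list of harmonizable noun tokens.

    Token order encodes the chronology of the dream narrative and is
    preserved end-to-end; duplicate tokens are meaningful and retained.
    """

    report_id: str
    respondent_id: str
    stratum: Stratum
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) == 0:
            raise ValueError(f"report {self.report_id!r}: token list is empty")
        object.__setattr__(self, "stratum", Stratum(self.stratum))
        object.__setattr__(self, "tokens", tuple(self.tokens))


_SEX_VALUES = ("female", "male", "other_unspecified")

#: Accepted spellings for the ordinal survey answers, mapped onto the
#: canonical integer codes (higher = worse for sleep items).
_STRESS_LABELS = {
    "lowered": 1,
    "unchanged": 2,
    "modest increase": 3,
    "high increase": 4,
}
_SLEEP_LABELS = {"improved": 1, "no change": 2, "worsened": 3}
_BOOL_LABELS = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False,
}


@dataclass(frozen=True)
class SurveyRecord:
    """One survey respondent.

    ``stress_change`` is ordinal 1–4 (1=lowered, 2=unchanged, 3=modest
    increase, 4=high increase). The five sleep-change items are ordinal
    1–3 coded in the worsening direction (1=improved, 2=no change,
    3=worsened), e.g. for sleep duration "worsened" means *shorter* sleep.
    """

    respondent_id: str
    age: int
    sex: str
    stress_change: int
    sleep_duration: int
    sleep_latency: int
    awakenings: int
    sleep_regularity: int
    nightmares: int
    reported_dream: bool

    def __post_init__(self) -> None:
        if self.sex not in _SEX_VALUES:
            raise ValueError(f"invalid sex {self.sex!r}")
        if not 1 <= self.stress_change <= 4:
            raise ValueError(f"stress_change out of range: {self.stress_change}")
        for item, value in self.sleep_items().items():
            if not 1 <= value <= 3:
                raise ValueError(f"{item} out of range: {value}")

    def sleep_items(self) -> dict[str, int]:
        return {
            "sleep_duration": self.sleep_duration,
            "sleep_latency": self.sleep_latency,
            "awakenings": self.awakenings,
            "sleep_regularity": self.sleep_regularity,
            "nightmares": self.nightmares,
        }


@dataclass(frozen=True)
class HarmonizationRules:
    """Synonym and category-grouping rules for token harmonization.

    ``synonym_map`` collapses spelling/synonym variants onto one chosen
    word (shoes→shoe); ``category_map`` groups word types under a category
    token (aunt→relative, paris→city); ``keep`` lists tokens that are
    exempt from category grouping (close kin terms, country names). Rules
    must form an idempotent closure: no rule target may itself be a rule
    source, so applying the rules twice equals applying them once.
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    category_map: dict[str, str] = field(default_factory=dict)
    keep: frozenset[str] = field(default_factory=frozenset)
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "synonym_map", dict(self.synonym_map))
        object.__setattr__(self, "category_map", dict(self.category_map))
        object.__setattr__(self, "keep", frozenset(self.keep))
        self.validate()

    def validate(self) -> None:
        from oneironet.harmonization import harmonize_tokens

        # every image of the composed synonym-then-category map must be a
        # fixed point, so applying the rules twice equals applying them once
        sources = set(self.synonym_map) | set(self.category_map)
        for src in sorted(sources):
            (image,) = harmonize_tokens([src], self)
            if harmonize_tokens([image], self) != [image]:
                raise ValueError(
                    f"rules are not idempotent: {src!r} maps to {image!r}, "
                    f"which is itself remapped"
                )


# ---------------------------------------------------------------------------
# dream reports

REPORT_COLUMNS = ("report_id", "respondent_id", "stratum", "tokens")


def read_reports(path: str | Path) -> list[DreamReport]:
    """Read a report TSV, preserving file order and within-report token order.

    Tokens are lowercased on ingestion. Unknown stratum labels map to
    ``unspecified`` with a logged warning; an empty token field is a
    hard error naming the offending row.
    """
    path = Path(path)
    reports: list[DreamReport] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: file is empty, expected header") from None
        if tuple(header) != REPORT_COLUMNS:
            raise FormatError(
                f"{path}: malformed header {header!r}, expected {list(REPORT_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(REPORT_COLUMNS):
                raise FormatError(f"{path}: row {lineno}: expected 4 fields, got {len(row)}")
            report_id, respondent_id, stratum_label, token_field = (c.strip() for c in row)
            tokens = tuple(t.strip().lower() for t in token_field.split(",") if t.strip())
            if not tokens:
                raise FormatError(f"{path}: row {lineno}: empty token field")
            try:
                stratum = Stratum(stratum_label)
            except ValueError:
                log.warning(
                    "%s: row %d: unknown stratum label %r, using 'unspecified'",
                    path, lineno, stratum_label,
                )
                stratum = Stratum.UNSPECIFIED
            reports.append(DreamReport(report_id, respondent_id, stratum, tokens))
    return reports


def write_reports(reports: Iterable[DreamReport], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for r in reports:
            writer.writerow([r.report_id, r.respondent_id, r.stratum.value, ",".join(r.tokens)])


# ---------------------------------------------------------------------------
# survey

SURVEY_COLUMNS = (
    "respondent_id", "age", "sex", "stress_change",
    "sleep_duration", "sleep_latency", "awakenings", "sleep_regularity",
    "nightmares", "reported_dream",
)


def _coerce_ordinal(value: str, labels: dict[str, int], lo: int, hi: int) -> int:
    value = value.strip().lower()
    if value in labels:
        return labels[value]
    coded = int(value)  # may raise ValueError
    if not lo <= coded <= hi:
        raise ValueError(f"ordinal {coded} outside [{lo}, {hi}]")
    return coded


def read_survey(path: str | Path) -> list[SurveyRecord]:
    """Read a survey CSV, coercing text answers onto the canonical codes.

    Rows with out-of-range or unparseable values are rejected individually
    with a logged warning; a missing mandatory column is a format error.
    """
    path = Path(path)
    records: list[SurveyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(SURVEY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FormatError(f"{path}: missing mandatory columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                sleep = {
                    item: _coerce_ordinal(row[item], _SLEEP_LABELS, 1, 3)
                    for item in ("sleep_duration", "sleep_latency", "awakenings",
                                 "sleep_regularity", "nightmares")
                }
                records.append(SurveyRecord(
                    respondent_id=row["respondent_id"].strip(),
                    age=int(row["age"]),
                    sex=row["sex"].strip().lower(),
                    stress_change=_coerce_ordinal(row["stress_change"], _STRESS_LABELS, 1, 4),
                    reported_dream=_BOOL_LABELS[row["reported_dream"].strip().lower()],
                    **sleep,
                ))
            except (ValueError, KeyError) as exc:
                log.warning("%s: row %d rejected: %s", path, lineno, exc)
    return records


def write_survey(records: Iterable[SurveyRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SURVEY_COLUMNS)
        for r in records:
            writer.writerow([
                r.respondent_id, r.age, r.sex, r.stress_change,
                r.sleep_duration, r.sleep_latency, r.awakenings,
                r.sleep_regularity, r.nightmares, str(r.reported_dream).lower(),
            ])


# ---------------------------------------------------------------------------
# harmonization rules

def read_rules(path: str | Path) -> HarmonizationRules:
    """Read a YAML/JSON rules file (JSON is a YAML subset)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: rules file must be a mapping")
    return HarmonizationRules(
        synonym_map={str(k).lower(): str(v).lower() for k, v in (raw.get("synonyms") or {}).items()},
        category_map={str(k).lower(): str(v).lower() for k, v in (raw.get("categories") or {}).items()},
        keep=frozenset(str(t).lower() for t in (raw.get("keep") or [])),
        notes=str(raw.get("notes") or ""),
    )


def write_rules(rules: HarmonizationRules, path: str | Path) -> None:
    payload = {
        "synonyms": dict(sorted(rules.synonym_map.items())),
        "categories": dict(sorted(rules.category_map.items())),
        "keep": sorted(rules.keep),
        "notes": rules.notes,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# network artifacts

def _write_meta(fh, meta: dict[str, object]) -> None:
    for key, value in meta.items():
        fh.write(f"# {key}={value}\n")


def _read_meta(lines: list[str]) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line.rstrip("\n"))
    return meta, body


def write_network(network: "WordNetwork", prefix: str | Path) -> None:
    """Write ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``.

    Phi weights are printed at fixed 12-decimal precision; network
    construction rounds phi identically, so read(write(x)) == x.
    """
    prefix = Path(prefix)
    meta = {
        "stratum": network.stratum,
        "min_doc_freq": network.thresholds.min_doc_freq,
        "min_phi": repr(network.thresholds.min_phi),
    }
    with open(f"{prefix}.nodes.tsv", "w", encoding="utf-8") as fh:
        _write_meta(fh, meta)
        fh.write("word\tdoc_freq\n")
        for word in sorted(network.nodes):
            fh.write(f"{word}\t{network.nodes[word]}\n")
    with open(f"{prefix}.edges.tsv", "w", encoding="utf-8") as fh:
        _write_meta(fh, meta)
        fh.write("word_a\tword_b\tphi\tbigram_count\n")
        for a, b in sorted(network.edges):
            phi_val, bigrams = network.edges[(a, b)]
            fh.write(f"{a}\t{b}\t{phi_val:.12f}\t{bigrams}\n")


def read_network(prefix: str | Path) -> "WordNetwork":
    from oneironet.cooccurrence import NetworkThresholds, WordNetwork

    prefix = Path(prefix)
    with open(f"{prefix}.nodes.tsv", encoding="utf-8") as fh:
        meta, body = _read_meta(fh.readlines())
    if not body or body[0].split("\t") != ["word", "doc_freq"]:
        raise FormatError(f"{prefix}.nodes.tsv: malformed header")
    nodes = {}
    for line in body[1:]:
        word, doc_freq = line.split("\t")
        nodes[word] = int(doc_freq)
    with open(f"{prefix}.edges.tsv", encoding="utf-8") as fh:
        _, body = _read_meta(fh.readlines())
    if not body or body[0].split("\t") != ["word_a", "word_b", "phi", "bigram_count"]:
        raise FormatError(f"{prefix}.edges.tsv: malformed header")
    edges = {}
    for line in body[1:]:
        a, b, phi_val, bigrams = line.split("\t")
        edges[(a, b)] = (round12(float(phi_val)), int(bigrams))
    thresholds = NetworkThresholds(
        min_doc_freq=int(meta.get("min_doc_freq", 5)),
        min_phi=float(meta.get("min_phi", 0.2)),
    )
    return WordNetwork(nodes=nodes, edges=edges, thresholds=thresholds,
                       stratum=meta.get("stratum", "all"))


def write_graphml(network: "WordNetwork", path: str | Path) -> None:
    """Export the network to GraphML (for Gephi/Cytoscape-style viewers)."""
    import networkx as nx

    nx.write_graphml(network.to_networkx(), str(path))


# ---------------------------------------------------------------------------
# partitions

def write_partition(partition: "Partition", path: str | Path) -> None:
    p = partition.params
    meta = {
        "energy": f"{partition.energy:.12f}",
        "gamma": repr(p.gamma),
        "spins": p.spins,
        "t_start": repr(p.t_start),
        "t_stop": repr(p.t_stop),
        "cooling": repr(p.cooling),
        "restarts": p.restarts,
        "seed": p.seed,
        "per_component": str(partition.per_component).lower(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta)
        fh.write("word\tcluster\n")
        for word in sorted(partition.assignment):
            fh.write(f"{word}\t{partition.assignment[word]}\n")


def read_partition(path: str | Path) -> "Partition":
    from oneironet.spinglass import Partition, SpinglassParams

    with open(path, encoding="utf-8") as fh:
        meta, body = _read_meta(fh.readlines())
    if not body or body[0].split("\t") != ["word", "cluster"]:
        raise FormatError(f"{path}: malformed header")
    assignment = {}
    for line in body[1:]:
        word, cluster = line.split("\t")
        assignment[word] = int(cluster)
    params = SpinglassParams(
        spins=int(meta.get("spins", 25)),
        gamma=float(meta.get("gamma", 1.0)),
        t_start=float(meta.get("t_start", 1.0)),
        t_stop=float(meta.get("t_stop", 0.01)),
        cooling=float(meta.get("cooling", 0.99)),
        restarts=int(meta.get("restarts", 10)),
        seed=int(meta.get("seed", 0)),
    )
    return Partition(
        assignment=assignment,
        energy=round12(float(meta.get("energy", 0.0))),
        params=params,
        per_component=meta.get("per_component", "true") == "true",
    )


# ---------------------------------------------------------------------------
# centrality tables

CENTRALITY_COLUMNS = ("word", "degree", "strength", "betweenness", "closeness")


def write_centrality(rows: Sequence["CentralityRow"], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CENTRALITY_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.word}\t{r.degree}\t{r.strength:.12f}"
                f"\t{r.betweenness:.12f}\t{r.closeness:.12f}\n"
            )


def read_centrality(path: str | Path) -> list["CentralityRow"]:
    from oneironet.centrality import CentralityRow

    with open(path, encoding="utf-8") as fh:
        _, body = _read_meta(fh.readlines())
    if not body or tuple(body[0].split("\t")) != CENTRALITY_COLUMNS:
        raise FormatError(f"{path}: malformed header")
    rows = []
    for line in body[1:]:
        word, degree, strength, betw, close = line.split("\t")
        rows.append(CentralityRow(
            word=word, degree=int(degree), strength=round12(float(strength)),
            betweenness=round12(float(betw)), closeness=round12(float(close)),
        ))
    return rows
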