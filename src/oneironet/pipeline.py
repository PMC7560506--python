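"""End-to-end orchestration: harmonize → network → cluster → centrality → stats.

``run_pipeline`` reads a report corpus (and optionally harmonization
rules and a survey table), then for each stress stratum — the pooled
corpus, the stress-increased group and the unchanged/lowered group —
rebuilds the incidence within that stratum's reports only, constructs
the thresholded phi network, partitions it with the spin-glass annealer
and writes the centrality table. Word-frequency tables per stratum and,
when a survey is supplied, the Spearman/chi-square summary complete the
bundle. A JSON manifest records parameters, seeds, input checksums and
per-stage counts; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from oneironet._version import __version__
from oneironet._util import sha256_file
from oneironet.centrality import centrality_table
from oneironet.cooccurrence import NetworkThresholds, build_network
from oneironet.corpus_io import (
    DreamReport,
    Stratum,
    read_reports,
    read_rules,
    read_survey,
    write_centrality,
    write_network,
    write_partition,
    write_reports,
)
from oneironet.group_stats import (
    dream_reporting_by_stress,
    sleep_stress_associations,
    word_frequencies,
)
from oneironet.harmonization import harmonize_reports
from oneironet.spinglass import Partition, SpinglassParams, spinglass

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STRATA = ("all", Stratum.INCREASED.value, Stratum.UNCHANGED_LOWERED.value)


@dataclass(frozen=True)
class PipelineConfig:
    reports_path: str
    output_dir: str
    rules_path: str | None = None
    survey_path: str | None = None
    thresholds: NetworkThresholds = field(default_factory=NetworkThresholds)
    spinglass: SpinglassParams = field(default_factory=SpinglassParams)
    weighted_paths: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        inputs = raw.get("inputs", {})
        seed = int(raw.get("seed", 0))
        sg = dict(raw.get("spinglass", {}))
        sg.setdefault("seed", seed)
        return cls(
            reports_path=inputs["reports"],
            rules_path=inputs.get("rules"),
            survey_path=inputs.get("survey"),
            output_dir=raw["output_dir"],
            thresholds=NetworkThresholds(**raw.get("thresholds", {})),
            spinglass=SpinglassParams(**sg),
            weighted_paths=bool(raw.get("weighted_paths", False)),
            seed=seed,
        )


def _subset(reports: Sequence[DreamReport], stratum: str) -> list[DreamReport]:
    if stratum == "all":
        return list(reports)
    return [r for r in reports if r.stratum.value == stratum]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "spinglass": dataclasses.asdict(config.spinglass),
        "weighted_paths": config.weighted_paths,
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    reports = read_reports(config.reports_path)
    manifest["inputs"]["reports"] = {
        "path": str(config.reports_path), "sha256": sha256_file(config.reports_path)}
    log.info("stage=read_reports reports=%d", len(reports))
    if config.rules_path:
        rules = read_rules(config.rules_path)
        manifest["inputs"]["rules"] = {
            "path": str(config.rules_path), "sha256": sha256_file(config.rules_path)}
        reports = harmonize_reports(reports, rules)
        log.info("stage=harmonize reports=%d rules=%d",
                 len(reports),
                 len(rules.synonym_map) + len(rules.category_map))
    harmonized_path = out / "harmonized_reports.tsv"
    write_reports(reports, harmonized_path)
    manifest["stages"]["harmonize"] = {"reports": len(reports)}

    for i, stratum in enumerate(STRATA):
        subset = _subset(reports, stratum)
        network = build_network(subset, thresholds=config.thresholds, stratum=stratum)
        prefix = out / f"network_{stratum}"
        write_network(network, prefix)
        log.info("stage=network stratum=%s reports=%d words=%d edges=%d",
                 stratum, len(subset), network.n_nodes, network.n_edges)
        partition_path = out / f"partition_{stratum}.tsv"
        if network.n_nodes > 0:
            params = dataclasses.replace(config.spinglass,
                                         seed=config.spinglass.seed + i)
            partition = spinglass(network, params)
        else:
            partition = Partition(assignment={}, energy=0.0, params=config.spinglass)
        write_partition(partition, partition_path)
        centrality_path = out / f"centrality_{stratum}.tsv"
        write_centrality(
            centrality_table(network, weighted=config.weighted_paths), centrality_path)
        log.info("stage=cluster stratum=%s clusters=%d energy=%.6f",
                 stratum, partition.n_clusters, partition.energy)
        freq_path = out / f"word_frequencies_{stratum}.tsv"
        with open(freq_path, "w", encoding="utf-8") as fh:
            fh.write("word\tcount\n")
            for word, count in word_frequencies(reports, stratum):
                fh.write(f"{word}\t{count}\n")
        manifest["stages"][f"stratum_{stratum}"] = {
            "reports": len(subset),
            "words_retained": network.n_nodes,
            "edges": network.n_edges,
            "clusters": partition.n_clusters,
            "energy": partition.energy,
        }

    stats_summary: dict = {}
    if config.survey_path:
        survey = read_survey(config.survey_path)
        manifest["inputs"]["survey"] = {
            "path": str(config.survey_path), "sha256": sha256_file(config.survey_path)}
        chi = dream_reporting_by_stress(survey)
        stats_summary = {
            "n_respondents": len(survey),
            "sleep_stress_spearman": {
                a.item: {"rho": a.rho, "n": a.n}
                for a in sleep_stress_associations(survey)
            },
            "dream_reporting_chi_square": {
                "statistic": chi.statistic, "df": chi.df, "p_value": chi.p_value},
        }
        log.info("stage=stats respondents=%d", len(survey))
    stats_path = out / "stats_summary.json"
    with open(stats_path, "w", encoding="utf-8") as fh:
        json.dump(stats_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    for artifact in sorted(out.iterdir()):
        if artifact.name != "manifest.json":
            manifest["outputs"][artifact.name] = sha256_file(artifact)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
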