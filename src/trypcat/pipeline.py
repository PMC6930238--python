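"""End-to-end orchestration: load -> predict -> score -> transporters ->
differential abundance -> pathway links -> report files."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import metadata as _im
from pathlib import Path

from . import abundance as ab
from .catalog import Catalog, default_catalog, load_catalog
from .errors import PipelineStageError
from .evidence import Thresholds
from .genome_io import load_genome_collection
from .predict import build_call_matrix, gut_level_counts, phylum_proportions
from .scoring import score_matrix
from .transporters import (
    profile_transporters,
    profiles_to_frame,
    transporter_summary,
    venn_to_frame,
)


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    catalog_path: str | None = None
    abundance: str | None = None
    groups: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    p_max: float = 0.01
    gut_only: bool = True
    widen_transporter_screen: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")


def _config_hash(config: RunConfig) -> str:
    doc = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the mapping of report name -> path.

    Stage errors propagate as :class:`PipelineStageError` carrying the stage
    name; no partial output for the failing stage is left behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    reports: dict[str, Path] = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            for path in reports.values():
                path.unlink(missing_ok=True)
            raise PipelineStageError(name, exc) from exc

    catalog: Catalog = stage("catalog", lambda: (
        load_catalog(config.catalog_path) if config.catalog_path
        else default_catalog()))
    collection = stage("load", lambda: load_genome_collection(config.manifest))
    matrix = stage("predict", lambda: build_call_matrix(collection, catalog, t))

    def write_calls():
        path = out / "call_matrix.tsv"
        matrix.write_tsv(path)
        return path
    reports["call_matrix"] = stage("predict", write_calls)

    def write_phyla():
        path = out / "phylum_proportions.tsv"
        phylum_proportions(matrix, collection).to_csv(path, sep="\t",
                                                      float_format="%.4f")
        return path
    reports["phylum_proportions"] = stage("summaries", write_phyla)

    def write_gut():
        path = out / "gut_counts.tsv"
        gut_level_counts(matrix, collection).to_csv(path, sep="\t")
        return path
    reports["gut_counts"] = stage("summaries", write_gut)

    scores = stage("score", lambda: score_matrix(matrix, collection,
                                                 gut_only=config.gut_only))

    def write_scores():
        path = out / "score_matrix.tsv"
        scores.write_tsv(path)
        return path
    reports["score_matrix"] = stage("score", write_scores)

    def run_transporters():
        profiles = [
            profile_transporters(
                genome, catalog, t,
                indole_call=matrix.call(genome.genome_id, "indole"),
                restrict_to_indole=not config.widen_transporter_screen)
            for genome in collection]
        summary = transporter_summary(profiles, collection)
        ppath = out / "transporter_profiles.tsv"
        profiles_to_frame(profiles).to_csv(ppath, sep="\t")
        spath = out / "transporter_summary.tsv"
        venn = venn_to_frame(summary)
        with open(spath, "w") as fh:
            fh.write(f"# profiled\t{summary.n_profiled}\n")
            fh.write(f"# with_any_transporter\t{summary.n_with_any}\n")
            fh.write(f"# proportion_with_any\t{summary.proportion_with_any:.4f}\n")
            venn.to_csv(fh, sep="\t", index=False)
        gpath = out / "transporter_genus_proportions.tsv"
        summary.per_genus.to_csv(gpath, sep="\t", float_format="%.4f")
        return ppath, spath, gpath
    ppath, spath, gpath = stage("transporters", run_transporters)
    reports["transporter_profiles"] = ppath
    reports["transporter_summary"] = spath
    reports["transporter_genus_proportions"] = gpath

    differentials = []
    if config.abundance and config.groups:
        def run_diff():
            table = ab.read_abundance_table(config.abundance, config.groups)
            table = ab.relative_abundance(table)
            return ab.differential_genera(table, p_max=config.p_max)
        differentials = stage("differential", run_diff)

        def write_diff():
            path = out / "differential_genera.tsv"
            ab.differentials_to_frame(differentials).to_csv(path, sep="\t",
                                                            index=False,
                                                            float_format="%.6g")
            return path
        reports["differential_genera"] = stage("differential", write_diff)

        def write_links():
            links = ab.pathway_links(differentials, scores)
            path = out / "sankey.json"
            ab.write_sankey(links, path)
            return path
        reports["sankey"] = stage("link", write_links)

    def write_log():
        try:
            version = _im.version("trypcat")
        except _im.PackageNotFoundError:
            version = "unknown"
        path = out / "run_log.json"
        doc = {
            "package_version": version,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "thresholds": asdict(t),
            "score_metadata": dict(scores.metadata),
            "n_genomes": len(collection),
            "n_differential_genera": len(differentials),
            "reports": {k: str(v) for k, v in sorted(reports.items())},
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True, default=str)
                        + "\n")
        return path
    reports["run_log"] = stage("report", write_log)
    return reports
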