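"""Strain-level TRYP-6 pathway calls and their phylum/gut summaries.

Each genome is evaluated against every catalog rule: domain leaves through
Pfam-domain presence, homolog leaves through thresholded BLAST evidence, and
cluster-bearing rules (IPA) additionally through gene-neighborhood detection.
Calls are monotone in evidence — adding hits can only turn a call on — and
every positive call carries an auditable evidence trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .catalog import Catalog, EnzymeSpec, METABOLITES, eval_logic, logic_leaves
from .errors import TrypcatError
from .evidence import (
    ClusterCall,
    Thresholds,
    filter_homology_hits,
    find_gene_cluster,
    has_domain,
)
from .genome_io import GenomeCollection, GenomeRecord


@dataclass(frozen=True)
class LeafEvidence:
    leaf: str
    satisfied: bool
    supporting: tuple = ()


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    metabolite: str
    present: bool
    evidence: tuple[LeafEvidence, ...] = ()
    clusters: tuple[ClusterCall, ...] = ()


@dataclass
class PathwayCallMatrix:
    """Strain x metabolite boolean calls with the per-call evidence retained."""

    calls: pd.DataFrame  # index genome_id (sorted), columns METABOLITES, bool
    evidence: Mapping[tuple[str, str], PathwayCall] = field(default_factory=dict)

    def call(self, genome_id: str, metabolite: str) -> PathwayCall:
        return self.evidence[(genome_id, metabolite)]

    def write_tsv(self, path) -> None:
        out = self.calls.astype(int)
        out.index.name = "genome_id"
        out.to_csv(path, sep="\t")


def _leaf_evidence(genome: GenomeRecord, spec: EnzymeSpec,
                   t: Thresholds) -> LeafEvidence:
    if spec.evidence_kind == "domain":
        supporting = []
        for acc in spec.pfam_accessions:
            ok, hits = has_domain(genome, acc, t)
            supporting.extend(hits)
        return LeafEvidence(spec.name, bool(supporting), tuple(supporting))
    if spec.evidence_kind == "homolog":
        hits = [h for h in genome.homology_hits if h.query_tag in spec.query_tags]
        passing = filter_homology_hits(hits, t)
        return LeafEvidence(spec.name, bool(passing), tuple(passing))
    raise TrypcatError(f"enzyme {spec.name!r}: unknown evidence kind "
                       f"{spec.evidence_kind!r}")


def supporting_proteins(evidence: LeafEvidence) -> set[str]:
    """Protein ids carrying the evidence behind a satisfied leaf."""
    proteins = set()
    for hit in evidence.supporting:
        proteins.add(getattr(hit, "protein_id", None)
                     or getattr(hit, "subject_protein_id"))
    return proteins


def predict_strain(genome: GenomeRecord, catalog: Catalog,
                   t: Thresholds | None = None) -> list[PathwayCall]:
    """Evaluate all six pathway rules on one genome (deterministic, order-
    independent in the input hit lists)."""
    t = t or Thresholds()
    calls = []
    for metabolite in METABOLITES:
        rule = catalog.rule_for(metabolite)
        leaves = {}
        for name in dict.fromkeys(logic_leaves(rule.logic)):
            leaves[name] = _leaf_evidence(genome, catalog.enzyme_specs[name], t)
        satisfied = {name: ev.satisfied for name, ev in leaves.items()}
        present = eval_logic(rule.logic, satisfied)
        clusters: tuple[ClusterCall, ...] = ()
        if rule.cluster is not None:
            for role in rule.cluster.member_roles:
                if role not in leaves:
                    leaves[role] = _leaf_evidence(
                        genome, catalog.enzyme_specs[role], t)
            role_proteins = {role: supporting_proteins(leaves[role])
                             for role in rule.cluster.member_roles}
            clusters = tuple(find_gene_cluster(genome, role_proteins,
                                               rule.cluster, t))
            present = present and bool(clusters)
        calls.append(PathwayCall(genome.genome_id, metabolite, present,
                                 tuple(leaves.values()), clusters))
    return calls


def build_call_matrix(collection: GenomeCollection, catalog: Catalog,
                      t: Thresholds | None = None) -> PathwayCallMatrix:
    """One row per genome (sorted by genome_id), one column per metabolite."""
    t = t or Thresholds()
    rows = {}
    evidence = {}
    for genome in sorted(collection, key=lambda g: g.genome_id):
        calls = predict_strain(genome, catalog, t)
        rows[genome.genome_id] = {c.metabolite: c.present for c in calls}
        for c in calls:
            evidence[(genome.genome_id, c.metabolite)] = c
    frame = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(METABOLITES)).fillna(False).astype(bool)
    frame = frame.sort_index()
    return PathwayCallMatrix(frame, evidence)


def phylum_proportions(matrix: PathwayCallMatrix,
                       collection: GenomeCollection) -> pd.DataFrame:
    """Per-phylum proportion of strains carrying each pathway (heat-map-ready)."""
    phyla = pd.Series({g.genome_id: g.phylum for g in collection})
    calls = matrix.calls.join(phyla.rename("phylum"))
    props = calls.groupby("phylum")[list(METABOLITES)].mean().sort_index()
    props.index.name = "phylum"
    return props


def gut_level_counts(matrix: PathwayCallMatrix,
                     collection: GenomeCollection) -> pd.DataFrame:
    """Among gut-associated genomes: distinct phyla, genera and strain counts
    positive for each pathway."""
    meta = pd.DataFrame({g.genome_id: {"phylum": g.phylum, "genus": g.genus,
                                       "gut": g.is_gut_associated}
                         for g in collection}).T
    rows = {}
    for metabolite in METABOLITES:
        pos = matrix.calls.index[matrix.calls[metabolite]]
        gut_pos = [gid for gid in pos if meta.loc[gid, "gut"]]
        rows[metabolite] = {
            "n_phyla": meta.loc[gut_pos, "phylum"].nunique(),
            "n_genera": meta.loc[gut_pos, "genus"].nunique(),
            "n_strains": len(gut_pos),
        }
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(list(METABOLITES))
    out.index.name = "metabolite"
    return out
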