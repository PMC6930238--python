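"""Synthetic inputs with known ground truth.

Two generators cover everything the pipeline consumes:

- :func:`make_collection` — a genome collection under a prevalence design.
  Each strain draws pathway presence per (genus, gut-status) prevalence; for
  every planted pathway the generator emits the *minimal sufficient* evidence
  satisfying the default catalog rule (one diagnostic item per evidence leaf,
  e.g. a single PF03301 domain hit for kynurenine, a contiguous five-gene Fld
  block for IPA, one strong tryptophanase homolog for indole), plus decoy
  domain/homolog hits that satisfy no rule.  Planted values sit far from the
  thresholds (identity 95, coverage 100, e-values 1e-30 and below) so that
  rule-logic tests stay separate from threshold-boundary tests.  The truth
  record carries the intended call matrix, transporter plan and per-pathway
  evidence items, so deleting any single planted item must flip its call.

- :func:`make_abundance_study` — a case/control genus abundance study.  Per
  sample, genus compositions follow a log-normal model around per-genus
  baselines; case compositions of effect genera are multiplied by their fold
  change before renormalization; counts are the composition scaled to a
  sampled sequencing depth and rounded.

Same seed, same bytes: all output files are written deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, METABOLITES, default_catalog
from .genome_io import (
    DomainHit,
    GeneRecord,
    GenomeCollection,
    GenomeRecord,
    HomologyHit,
    write_domain_hits,
    write_gene_table,
    write_homology_hits,
    write_query_lengths,
)

#: Query-protein lengths (aa) for the default catalog's homolog tags.
QUERY_LENGTHS = {
    "tnaA_ECOLI": 471,
    "iaaM_PSESY": 557,
    "ipdC_ENTCL": 552,
    "tdc_CLOSG": 470,
    "tdc_RUMGN": 468,
    "aroP_ECOLI": 457,
    "aroP_CORGL": 462,
    "mtr_ECOLI": 414,
}

#: Decoy Pfam accessions guaranteed to match no catalog rule.
DECOY_ACCESSIONS = ("PF77777", "PF88888", "PF55555")

_N_GENES = 40
# fixed gene slots per pathway on the single synthetic contig; the IPA block
# is contiguous (ranks 22..26) and the TnaB slot is adjacent to tnaA (12/13)
_SLOTS = {
    "kynurenine": (2,),
    "quinolinate": (5, 7, 9),
    "indole": (12,),
    "IAA": (16,),
    "tryptamine": (18,),
    "IPA": (22, 23, 24, 25, 26),
}
_TNAB_SLOT = 13


def _default_genera():
    # (genus, phylum, n_strains, n_gut_strains): 40 strains over the five
    # gut-associated phyla the genome census highlights
    return (
        ("Clostridium", "Firmicutes", 10, 6),
        ("Burkholderia", "Proteobacteria", 8, 3),
        ("Bacteroides", "Bacteroidetes", 8, 5),
        ("Bifidobacterium", "Actinobacteria", 6, 4),
        ("Fusobacterium", "Fusobacteria", 8, 4),
    )


def _default_prevalence():
    # (gut prevalence, non-gut prevalence) per (genus, metabolite); sparse —
    # unlisted pairs default to (0, 0).  Patterned after the census: indole
    # widespread and strongest in Fusobacterium, kynurenine/quinolinate in
    # Proteobacteria, IPA rare and Clostridium-bound.
    return {
        ("Clostridium", "indole"): (0.6, 0.4),
        ("Clostridium", "IPA"): (0.5, 0.2),
        ("Clostridium", "tryptamine"): (0.5, 0.25),
        ("Clostridium", "quinolinate"): (0.3, 0.1),
        ("Burkholderia", "kynurenine"): (0.9, 0.6),
        ("Burkholderia", "quinolinate"): (0.6, 0.4),
        ("Burkholderia", "indole"): (0.4, 0.25),
        ("Burkholderia", "IAA"): (0.5, 0.4),
        ("Burkholderia", "tryptamine"): (0.3, 0.2),
        ("Bacteroides", "indole"): (0.7, 0.5),
        ("Bacteroides", "kynurenine"): (0.3, 0.2),
        ("Bacteroides", "quinolinate"): (0.3, 0.2),
        ("Bifidobacterium", "IAA"): (0.5, 0.3),
        ("Bifidobacterium", "tryptamine"): (0.3, 0.1),
        ("Fusobacterium", "indole"): (0.75, 0.5),
        ("Fusobacterium", "IAA"): (0.3, 0.2),
    }


@dataclass(frozen=True)
class CollectionDesign:
    genera: tuple = field(default_factory=_default_genera)
    planted_prevalence: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=_default_prevalence)
    transporter_probs: Mapping[str, float] = field(
        default_factory=lambda: {"TnaB": 0.5, "Mtr": 0.4, "AroP": 0.2})
    decoy_domain_rate: float = 0.2
    decoy_homolog_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for genus, phylum, n, n_gut in self.genera:
            if n_gut > n or n < 1:
                raise ValueError(f"genus {genus!r}: invalid strain counts "
                                 f"n={n} n_gut={n_gut}")
        for key, (pg, ph) in self.planted_prevalence.items():
            if not (0 <= pg <= 1 and 0 <= ph <= 1):
                raise ValueError(f"prevalence for {key} outside [0, 1]")
        if not 0 <= self.decoy_domain_rate <= 1:
            raise ValueError("decoy_domain_rate outside [0, 1]")


@dataclass
class CollectionTruth:
    call_matrix: pd.DataFrame                      # genome x metabolite, bool
    transporters: Mapping[str, frozenset]          # genome -> planted importers
    evidence: Mapping[str, Mapping[str, list]]     # genome -> metabolite -> items
    design: CollectionDesign

    def to_json(self) -> str:
        doc = {
            "seed": self.design.seed,
            "call_matrix": {gid: {m: bool(v) for m, v in row.items()}
                            for gid, row in
                            self.call_matrix.to_dict(orient="index").items()},
            "transporters": {gid: sorted(s)
                             for gid, s in sorted(self.transporters.items())},
            "evidence": self.evidence,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def _plant_domain(genome: GenomeRecord, slot: int, accession: str,
                  name: str) -> dict:
    protein = genome.genes[slot].protein_id
    genome.domain_hits.append(DomainHit(protein, accession, name, 1e-30, 250.0))
    return {"kind": "domain", "protein_id": protein, "accession": accession}


def _plant_homolog(genome: GenomeRecord, slot: int, tag: str) -> dict:
    protein = genome.genes[slot].protein_id
    length = QUERY_LENGTHS[tag]
    genome.homology_hits.append(HomologyHit(tag, protein, 95.0, length,
                                            1e-50, 2.0 * length, length))
    return {"kind": "homolog", "protein_id": protein, "query_tag": tag}


def _build_genome(genome_id: str, genus: str, phylum: str, gut: bool,
                  planted: Mapping[str, bool], transporters: frozenset,
                  catalog: Catalog, rng: np.random.Generator,
                  decoy_domain_rate: float, decoy_homolog_rate: float,
                  ) -> tuple[GenomeRecord, dict[str, list]]:
    strands = rng.choice(["+", "-"], size=_N_GENES)
    # tnaA and the TnaB slot must be operonic (same strand) when planted
    strands[_TNAB_SLOT] = strands[_SLOTS["indole"][0]]
    genes = []
    for k in range(_N_GENES):
        start = 100 + 1000 * k
        genes.append(GeneRecord(
            gene_id=f"{genome_id}_g{k:03d}", protein_id=f"{genome_id}_p{k:03d}",
            contig="c1", start=start, end=start + 800, strand=str(strands[k]),
            rank_on_contig=k, product="hypothetical_protein"))
    genome = GenomeRecord(genome_id, phylum, genus, f"{genus} sp.",
                          f"{genus}_{genome_id}", gut, genes, [], [])

    evidence: dict[str, list] = {}
    for metabolite in METABOLITES:
        if not planted.get(metabolite):
            continue
        items = []
        rule = catalog.rule_for(metabolite)
        slots = _SLOTS[metabolite]
        if metabolite == "kynurenine":
            items.append(_plant_domain(genome, slots[0], "PF03301",
                                       "Trp_dioxygenase"))
        elif metabolite == "quinolinate":
            for slot, (role, acc, name) in zip(slots, (
                    ("HAD", "PF06052", "3-HAO"),
                    ("KMO", "PF01494", "FAD_binding_3"),
                    ("KYN", "PF00266", "Aminotran_5"))):
                items.append(_plant_domain(genome, slot, acc, name))
        elif metabolite == "indole":
            items.append(_plant_homolog(genome, slots[0], "tnaA_ECOLI"))
        elif metabolite == "IAA":
            # alternate routes: plant exactly one (minimal sufficiency)
            tag = ("iaaM_PSESY", "ipdC_ENTCL")[int(rng.integers(2))]
            items.append(_plant_homolog(genome, slots[0], tag))
        elif metabolite == "tryptamine":
            tag = ("tdc_CLOSG", "tdc_RUMGN")[int(rng.integers(2))]
            items.append(_plant_homolog(genome, slots[0], tag))
        elif metabolite == "IPA":
            for slot, role in zip(slots, rule.cluster.member_roles):
                spec = catalog.enzyme_specs[role]
                items.append(_plant_domain(genome, slot,
                                           spec.pfam_accessions[0], role))
        evidence[metabolite] = items

    if planted.get("indole"):
        if "TnaB" in transporters:
            spec = catalog.transporter("TnaB")
            _plant_domain(genome, _TNAB_SLOT, spec.pfam_accessions[0],
                          "TnaB_perm")
        if "AroP" in transporters:
            _plant_homolog(genome, 30, "aroP_ECOLI")
        if "Mtr" in transporters:
            _plant_homolog(genome, 32, "mtr_ECOLI")

    used = {s for slots in _SLOTS.values() for s in slots} | {_TNAB_SLOT, 30, 32}
    for k in range(_N_GENES):
        if k in used:
            continue
        if rng.random() < decoy_domain_rate:
            acc = DECOY_ACCESSIONS[int(rng.integers(len(DECOY_ACCESSIONS)))]
            genome.domain_hits.append(DomainHit(
                genes[k].protein_id, acc, "decoy_domain",
                float(10.0 ** rng.uniform(-30, -6)), 50.0))
        if rng.random() < decoy_homolog_rate:
            # sub-threshold hit on a real query tag: must never pass
            tag = sorted(QUERY_LENGTHS)[int(rng.integers(len(QUERY_LENGTHS)))]
            length = QUERY_LENGTHS[tag]
            genome.homology_hits.append(HomologyHit(
                tag, genes[k].protein_id, 55.0, int(length * 0.7), 1e-10,
                100.0, length))
    return genome, evidence


def build_collection(design: CollectionDesign | None = None,
                     catalog: Catalog | None = None,
                     ) -> tuple[GenomeCollection, CollectionTruth]:
    """Draw a collection in memory; see :func:`make_collection` to write it."""
    design = design or CollectionDesign()
    design.validate()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(design.seed)
    genomes, truth_rows, transporters, evidence = [], {}, {}, {}
    for genus, phylum, n, n_gut in design.genera:
        for idx in range(n):
            gut = idx < n_gut
            genome_id = f"{genus[:4].upper()}{idx:03d}"
            planted = {}
            for metabolite in METABOLITES:
                pg, ph = design.planted_prevalence.get((genus, metabolite),
                                                       (0.0, 0.0))
                planted[metabolite] = bool(rng.random() < (pg if gut else ph))
            trans = frozenset(
                name for name, prob in sorted(design.transporter_probs.items())
                if planted["indole"] and rng.random() < prob)
            genome, items = _build_genome(
                genome_id, genus, phylum, gut, planted, trans, catalog, rng,
                design.decoy_domain_rate, design.decoy_homolog_rate)
            genomes.append(genome)
            truth_rows[genome_id] = dict(planted)
            transporters[genome_id] = trans
            evidence[genome_id] = items
    matrix = (pd.DataFrame.from_dict(truth_rows, orient="index")
              .reindex(columns=list(METABOLITES)).sort_index())
    truth = CollectionTruth(matrix, transporters, evidence, design)
    return GenomeCollection(genomes, source="trypcat.simulate"), truth


def make_collection(design: CollectionDesign | None = None, out_dir=None,
                    catalog: Catalog | None = None,
                    ) -> tuple[Path, CollectionTruth]:
    """Write a synthetic collection (manifest, per-genome tables, query
    lengths, truth record) and return (manifest path, truth)."""
    design = design or CollectionDesign()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "genomes").mkdir(exist_ok=True)
    collection, truth = build_collection(design, catalog)
    rows = []
    for genome in collection:
        stem = f"genomes/{genome.genome_id}"
        write_gene_table(genome.genes, out_dir / f"{stem}.genes.tsv")
        write_domain_hits(genome.domain_hits, out_dir / f"{stem}.domtbl")
        write_homology_hits(genome.homology_hits, out_dir / f"{stem}.blast.tsv")
        rows.append((genome.genome_id, genome.phylum, genome.genus,
                     genome.species, genome.strain,
                     int(genome.is_gut_associated), f"{stem}.genes.tsv",
                     f"{stem}.domtbl", f"{stem}.blast.tsv"))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("genome_id\tphylum\tgenus\tspecies\tstrain\t"
                 "is_gut_associated\tgene_table\tdomain_table\thomology_table\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    write_query_lengths(QUERY_LENGTHS, out_dir / "query_lengths.tsv")
    (out_dir / "truth.json").write_text(truth.to_json() + "\n")
    return manifest, truth


def delete_evidence_item(genome: GenomeRecord, item: Mapping) -> GenomeRecord:
    """A copy of the genome with one planted evidence item removed (for
    minimal-sufficiency mutation tests)."""
    if item["kind"] == "domain":
        hits = [h for h in genome.domain_hits
                if not (h.protein_id == item["protein_id"]
                        and h.accession == item["accession"])]
        return dc_replace(genome, domain_hits=hits)
    if item["kind"] == "homolog":
        hits = [h for h in genome.homology_hits
                if not (h.subject_protein_id == item["protein_id"]
                        and h.query_tag == item["query_tag"])]
        return dc_replace(genome, homology_hits=hits)
    raise ValueError(f"unknown evidence kind {item['kind']!r}")


# ---------------------------------------------------------------------------
# Case/control abundance studies


def _default_study_genera():
    collection_genera = [g for g, *_ in _default_genera()]
    fillers = [f"Genus{chr(ord('A') + i)}" for i in range(15)]
    return tuple(collection_genera + fillers)


@dataclass(frozen=True)
class StudyDesign:
    n_case: int = 15
    n_control: int = 15
    genera: tuple[str, ...] = field(default_factory=_default_study_genera)
    baseline_log_sd: float = 1.0    # spread of per-genus baseline means
    sample_log_sd: float = 0.4      # within-group log-normal noise
    effect_genera: Mapping[str, float] = field(
        default_factory=lambda: {"Burkholderia": 4.0, "Clostridium": 4.0})
    depth_range: tuple[int, int] = (20000, 50000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both cohorts need at least one sample")
        if any(f <= 0 for f in self.effect_genera.values()):
            raise ValueError("fold changes must be positive")
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ValueError("invalid depth range")
        unknown = set(self.effect_genera) - set(self.genera)
        if unknown:
            raise ValueError(f"effect genera not in the genus list: "
                             f"{sorted(unknown)}")


@dataclass
class StudyTruth:
    effect_genera: Mapping[str, float]
    groups: pd.Series
    design: StudyDesign


def simulate_abundance(design: StudyDesign | None = None,
                       ) -> tuple["pd.DataFrame", pd.Series, StudyTruth]:
    """Draw the sample x genus count table and group labels in memory."""
    design = design or StudyDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)
    genera = list(design.genera)
    baselines = rng.normal(0.0, design.baseline_log_sd, len(genera))
    sample_ids, labels, rows = [], [], []
    for group, n in (("case", design.n_case), ("control", design.n_control)):
        for i in range(n):
            sid = f"{group}{i:03d}"
            comp = np.exp(baselines
                          + rng.normal(0.0, design.sample_log_sd, len(genera)))
            if group == "case":
                for genus, fold in design.effect_genera.items():
                    comp[genera.index(genus)] *= fold
            comp /= comp.sum()
            depth = int(rng.integers(design.depth_range[0],
                                     design.depth_range[1] + 1))
            rows.append(np.round(comp * depth))
            sample_ids.append(sid)
            labels.append(group)
    counts = pd.DataFrame(rows, index=sample_ids, columns=genera, dtype=float)
    groups = pd.Series(labels, index=sample_ids)
    truth = StudyTruth(dict(design.effect_genera), groups, design)
    return counts, groups, truth


def make_abundance_study(design: StudyDesign | None = None, out_dir=None,
                         ) -> tuple[Path, Path, StudyTruth]:
    """Write the long-format abundance TSV, the groups TSV and the truth
    record; returns (abundance path, groups path, truth)."""
    design = design or StudyDesign()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts, groups, truth = simulate_abundance(design)
    abundance_path = out_dir / "abundance.tsv"
    with open(abundance_path, "w") as fh:
        fh.write("sample_id\tgenus\tcount\n")
        for sid in counts.index:
            for genus in counts.columns:
                fh.write(f"{sid}\t{genus}\t{counts.loc[sid, genus]:.0f}\n")
    groups_path = out_dir / "groups.tsv"
    with open(groups_path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid in groups.index:
            fh.write(f"{sid}\t{groups[sid]}\n")
    (out_dir / "study_truth.json").write_text(json.dumps(
        {"seed": design.seed,
         "effect_genera": dict(sorted(truth.effect_genera.items()))},
        indent=1, sort_keys=True) + "\n")
    return abundance_path, groups_path, truth
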