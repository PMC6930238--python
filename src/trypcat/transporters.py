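"""Tryptophan-importer screen (TnaB / AroP / Mtr) over indole-producing genomes.

TnaB is tryptophan-specific and its gene sits in the tryptophanase (tnaA)
operon, so it is called by finding a TnaB-domain gene proximal — same strand —
to a gene with passing tryptophanase homology.  AroP and Mtr are generic
aromatic-amino-acid permeases called by thresholded homology alone.  The
screen is scoped to indole-positive genomes by default, since importer
profiling is only informative where tryptophan is actually catabolized to
indole; ``restrict_to_indole=False`` widens it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .catalog import Catalog, TRANSPORTERS
from .evidence import Thresholds, filter_homology_hits, has_domain, proximal_pair
from .genome_io import GenomeCollection, GenomeRecord
from .predict import PathwayCall


@dataclass(frozen=True)
class TransporterProfile:
    genome_id: str
    applicable: bool
    transporters_present: frozenset[str] = frozenset()
    evidence: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "transporters_present",
                           frozenset(self.transporters_present))
        object.__setattr__(self, "evidence", dict(self.evidence))


@dataclass
class TransporterSummary:
    n_profiled: int
    n_with_any: int
    proportion_with_any: float
    venn: Mapping[frozenset, int]          # 7 nonempty subsets of the trio
    per_genus: pd.DataFrame                # genus x transporter proportions


def _tnab_present(genome: GenomeRecord, catalog: Catalog,
                  t: Thresholds) -> tuple[bool, tuple]:
    spec = catalog.transporter("TnaB")
    anchor = catalog.enzyme_specs[spec.anchor_enzyme]
    anchor_hits = filter_homology_hits(
        [h for h in genome.homology_hits if h.query_tag in anchor.query_tags], t)
    anchor_proteins = {h.subject_protein_id for h in anchor_hits}
    domain_hits = []
    for acc in spec.pfam_accessions:
        domain_hits.extend(has_domain(genome, acc, t)[1])
    for dh in domain_hits:
        for anchor_protein in anchor_proteins:
            if proximal_pair(genome, dh.protein_id, anchor_protein,
                             t.proximity_max_gap, same_strand=True):
                return True, (dh, anchor_protein)
    return False, ()


def profile_transporters(genome: GenomeRecord, catalog: Catalog,
                         t: Thresholds | None = None,
                         indole_call: PathwayCall | None = None,
                         restrict_to_indole: bool = True) -> TransporterProfile:
    """Screen one genome; returns a not-applicable profile for genomes outside
    the scope (indole-negative when the screen is restricted)."""
    t = t or Thresholds()
    if restrict_to_indole and (indole_call is None or not indole_call.present):
        return TransporterProfile(genome.genome_id, applicable=False)
    present = set()
    evidence = {}
    ok, ev = _tnab_present(genome, catalog, t)
    if ok:
        present.add("TnaB")
        evidence["TnaB"] = ev
    for name in ("AroP", "Mtr"):
        spec = catalog.transporter(name)
        passing = filter_homology_hits(
            [h for h in genome.homology_hits if h.query_tag in spec.query_tags], t)
        if passing:
            present.add(name)
            evidence[name] = tuple(passing)
    return TransporterProfile(genome.genome_id, True, frozenset(present), evidence)


def transporter_summary(profiles: Iterable[TransporterProfile],
                        collection: GenomeCollection) -> TransporterSummary:
    """Counts/proportions with vs without importers, the 7 Venn cells of
    {TnaB, Mtr, AroP}, and per-genus usage proportions among profiled strains."""
    applicable = [p for p in profiles if p.applicable]
    n_with = sum(1 for p in applicable if p.transporters_present)
    venn = {}
    for p in applicable:
        if p.transporters_present:
            venn[p.transporters_present] = venn.get(p.transporters_present, 0) + 1

    genus_of = {g.genome_id: g.genus for g in collection}
    rows: dict[str, dict[str, float]] = {}
    totals: dict[str, int] = {}
    for p in applicable:
        genus = genus_of[p.genome_id]
        totals[genus] = totals.get(genus, 0) + 1
        row = rows.setdefault(genus, {name: 0 for name in TRANSPORTERS})
        for name in p.transporters_present:
            row[name] += 1
    per_genus = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(TRANSPORTERS)).fillna(0.0).astype(float)
    for genus in per_genus.index:
        per_genus.loc[genus] /= totals[genus]
    per_genus = per_genus.sort_index()
    per_genus.index.name = "genus"

    n = len(applicable)
    return TransporterSummary(
        n_profiled=n,
        n_with_any=n_with,
        proportion_with_any=(n_with / n) if n else 0.0,
        venn=venn,
        per_genus=per_genus,
    )


def profiles_to_frame(profiles: Iterable[TransporterProfile]) -> pd.DataFrame:
    rows = {}
    for p in sorted(profiles, key=lambda p: p.genome_id):
        rows[p.genome_id] = {
            "applicable": int(p.applicable),
            **{name: int(name in p.transporters_present) for name in TRANSPORTERS},
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genome_id"
    return out


def venn_to_frame(summary: TransporterSummary) -> pd.DataFrame:
    """The 7 nonempty subsets of {TnaB, AroP, Mtr} with their strain counts."""
    cells = []
    names = list(TRANSPORTERS)
    for mask in range(1, 8):
        subset = frozenset(n for k, n in enumerate(names) if mask >> k & 1)
        cells.append({"subset": "+".join(sorted(subset)),
                      "count": summary.venn.get(subset, 0)})
    return pd.DataFrame(cells).sort_values("subset").reset_index(drop=True)
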