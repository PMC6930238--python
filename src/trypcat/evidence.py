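"""The three evidence primitives behind every pathway call.

1. homology-threshold filtering (identity >= 70%, coverage >= 90%,
   e-value <= 1e-5 by default, all boundaries inclusive);
2. Pfam domain presence (versionless accession match, e-value gate);
3. genomic proximity — gene-cluster windows and gene pairs measured in
   intervening-gene counts along a contig (rank units), not base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .catalog import ClusterRequirement, is_pfam_accession
from .errors import UnknownProteinError
from .genome_io import DomainHit, GeneRecord, GenomeRecord, HomologyHit


@dataclass(frozen=True)
class Thresholds:
    """Evidence cutoffs; defaults follow the standard homology-screen setting
    of 70% identity, 90% query coverage and 1e-5 e-value."""

    identity_min: float = 70.0
    coverage_min: float = 90.0
    evalue_max: float = 1e-5
    domain_evalue_max: float = 1e-5
    proximity_max_gap: int = 3

    def __post_init__(self):
        if not (0.0 <= self.identity_min <= 100.0):
            raise ValueError("identity_min must be in [0, 100]")
        if not (0.0 <= self.coverage_min <= 100.0):
            raise ValueError("coverage_min must be in [0, 100]")
        if self.evalue_max <= 0 or self.domain_evalue_max <= 0:
            raise ValueError("e-value cutoffs must be positive")
        if self.proximity_max_gap < 0:
            raise ValueError("proximity_max_gap must be >= 0")


@dataclass(frozen=True)
class ClusterCall:
    """One minimal gene window jointly covering all required roles."""

    contig: str
    member_gene_ids: tuple[str, ...]
    role_assignment: Mapping[str, str]
    span_genes: int

    def __post_init__(self):
        object.__setattr__(self, "member_gene_ids", tuple(self.member_gene_ids))
        object.__setattr__(self, "role_assignment", dict(self.role_assignment))


def filter_homology_hits(hits: Iterable[HomologyHit],
                         t: Thresholds) -> list[HomologyHit]:
    """Keep hits passing identity/coverage/e-value thresholds (inclusive).

    Coverage is 100 * min(alignment_length, query_length) / query_length.
    Pure filter: order preserved, output is a subset of the input.
    """
    return [h for h in hits
            if h.percent_identity >= t.identity_min
            and h.coverage >= t.coverage_min
            and h.evalue <= t.evalue_max]


def has_domain(genome: GenomeRecord, accession: str,
               t: Thresholds) -> tuple[bool, list[DomainHit]]:
    """Does the genome carry the Pfam domain (versionless comparison)?"""
    if not is_pfam_accession(accession):
        raise ValueError(f"malformed Pfam accession {accession!r}")
    supporting = [h for h in genome.domain_hits
                  if h.matches(accession) and h.evalue <= t.domain_evalue_max]
    return bool(supporting), supporting


@dataclass(frozen=True)
class _Candidate:
    gene: GeneRecord
    roles: frozenset[str]


def _candidates_by_contig(genome: GenomeRecord,
                          role_proteins: Mapping[str, Iterable[str]],
                          ) -> dict[str, list[_Candidate]]:
    protein_roles: dict[str, set[str]] = {}
    for role, proteins in role_proteins.items():
        for p in proteins:
            protein_roles.setdefault(p, set()).add(role)
    by_contig: dict[str, list[_Candidate]] = {}
    for gene in genome.genes:
        roles = protein_roles.get(gene.protein_id)
        if roles:
            by_contig.setdefault(gene.contig, []).append(
                _Candidate(gene, frozenset(roles)))
    for cands in by_contig.values():
        cands.sort(key=lambda c: c.gene.rank_on_contig)
    return by_contig


def _window_valid(cands: list[_Candidate], i: int, j: int,
                  req: ClusterRequirement) -> bool:
    members = cands[i:j + 1]
    if req.same_strand and len({c.gene.strand for c in members}) > 1:
        return False
    for a, b in zip(members, members[1:]):
        if b.gene.rank_on_contig - a.gene.rank_on_contig - 1 > req.max_gap_genes:
            return False
    covered = frozenset().union(*(c.roles for c in members))
    return all(role in covered for role in req.member_roles)


def _call_from_window(contig: str, cands: list[_Candidate], i: int, j: int,
                      req: ClusterRequirement) -> ClusterCall:
    members = cands[i:j + 1]
    assignment = {}
    for role in req.member_roles:
        for c in members:
            if role in c.roles:
                assignment[role] = c.gene.gene_id
                break
    span = members[-1].gene.rank_on_contig - members[0].gene.rank_on_contig + 1
    return ClusterCall(contig, tuple(c.gene.gene_id for c in members),
                       assignment, span)


def find_gene_cluster(genome: GenomeRecord,
                      role_proteins: Mapping[str, Iterable[str]],
                      req: ClusterRequirement,
                      t: Thresholds | None = None) -> list[ClusterCall]:
    """Every minimal single-contig gene window covering all required roles.

    A window is a run of candidate genes (genes encoding any role protein),
    valid when every role is represented, consecutive candidates are separated
    by at most ``req.max_gap_genes`` intervening genes, and — when
    ``req.same_strand`` — all candidates in the window share a strand.
    Minimal means no proper sub-window is itself valid.  Returns [] whenever
    some role has no candidate gene.
    """
    missing = [r for r in req.member_roles if not set(role_proteins.get(r, ()))]
    if missing:
        return []
    calls: list[ClusterCall] = []
    for contig, cands in sorted(_candidates_by_contig(genome, role_proteins).items()):
        # split into maximal runs respecting the gap (and strand) constraint,
        # then slide a minimal covering window within each run
        runs: list[list[int]] = [[0]] if cands else []
        for k in range(1, len(cands)):
            gap = cands[k].gene.rank_on_contig - cands[k - 1].gene.rank_on_contig - 1
            same = (not req.same_strand
                    or cands[k].gene.strand == cands[k - 1].gene.strand)
            if gap <= req.max_gap_genes and same:
                runs[-1].append(k)
            else:
                runs.append([k])
        for run in runs:
            pairs: list[tuple[int, int]] = []
            for pos, i in enumerate(run):
                j_min = next((j for j in run[pos:]
                              if _window_valid(cands, i, j, req)), None)
                if j_min is not None:
                    pairs.append((i, j_min))
            # j_min is nondecreasing in the start index, so a window is
            # minimal exactly when it is the latest start sharing its right
            # end (shrinking it from either side breaks role coverage)
            for idx, (i, j) in enumerate(pairs):
                if idx + 1 == len(pairs) or pairs[idx + 1][1] != j:
                    calls.append(_call_from_window(contig, cands, i, j, req))
    return calls


def proximal_pair(genome: GenomeRecord, protein_a: str, protein_b: str,
                  max_gap: int, same_strand: bool) -> bool:
    """True iff the two proteins' genes share a contig, are separated by at
    most ``max_gap`` intervening genes, and (optionally) share a strand."""
    ga = genome.gene_by_protein(protein_a)
    gb = genome.gene_by_protein(protein_b)
    if ga.contig != gb.contig:
        return False
    if abs(ga.rank_on_contig - gb.rank_on_contig) - 1 > max_gap:
        return False
    if same_strand and ga.strand != gb.strand:
        return False
    return True
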