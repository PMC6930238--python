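import numpy as np
import pytest
from hypothesis import given, strategies as st

from trypcat.catalog import ClusterRequirement
from trypcat.errors import UnknownProteinError
from trypcat.evidence import (
    Thresholds,
    filter_homology_hits,
    find_gene_cluster,
    has_domain,
    proximal_pair,
)
from trypcat.genome_io import DomainHit, GeneRecord, GenomeRecord, HomologyHit

from _oracles import clusters_bruteforce, filter_hits_bruteforce, \
    proximal_bruteforce
from conftest import build_toy_genome


def random_hits(rng, n=200):
    return [HomologyHit(
        query_tag="q", subject_protein_id=f"p{k}",
        percent_identity=float(rng.uniform(40, 100)),
        alignment_length=int(rng.integers(100, 600)),
        evalue=float(10.0 ** rng.uniform(-60, 0)),
        bitscore=float(rng.uniform(30, 900)),
        query_length=500) for k in range(n)]


class TestHomologyFilter:
    def test_exact_boundary_hit_retained(self, thresholds):
        hit = HomologyHit("q", "p", 70.0, 450, 1e-5, 100.0, 500)
        assert hit.coverage == 90.0
        assert filter_homology_hits([hit], thresholds) == [hit]

    @pytest.mark.parametrize("identity,length,evalue", [
        (69.9, 450, 1e-10),    # identity just below
        (70.0, 449, 1e-10),    # coverage just below (89.8%)
        (70.0, 450, 1.1e-5),   # e-value just above
    ])
    def test_epsilon_violations_removed(self, thresholds, identity, length,
                                        evalue):
        hit = HomologyHit("q", "p", identity, length, evalue, 100.0, 500)
        assert filter_homology_hits([hit], thresholds) == []

    def test_matches_bruteforce_on_random_table(self, thresholds, rng):
        hits = random_hits(rng, 200)
        assert filter_homology_hits(hits, thresholds) == \
            filter_hits_bruteforce(hits, 70.0, 90.0, 1e-5)

    def test_pure_filter_subset_and_idempotent(self, thresholds, rng):
        hits = random_hits(rng, 100)
        kept = filter_homology_hits(hits, thresholds)
        assert set(id(h) for h in kept) <= set(id(h) for h in hits)
        assert filter_homology_hits(kept, thresholds) == kept

    @given(identity=st.floats(0, 100), coverage=st.floats(0, 100))
    def test_loosening_thresholds_is_monotone(self, identity, coverage):
        hits = random_hits(np.random.default_rng(5), 50)
        strict = Thresholds(identity_min=identity, coverage_min=coverage)
        loose = Thresholds(identity_min=max(0.0, identity - 10),
                           coverage_min=max(0.0, coverage - 10),
                           evalue_max=1e-4)
        assert set(map(id, filter_homology_hits(hits, strict))) <= \
            set(map(id, filter_homology_hits(hits, loose)))


class TestDomainPresence:
    def make_genome(self, hits):
        g = build_toy_genome(3)
        g.domain_hits = hits
        return g

    def test_strong_hit_found(self, thresholds):
        hit = DomainHit("p000", "PF03301", "Trp_dioxygenase", 1e-30, 250.0)
        present, support = has_domain(self.make_genome([hit]), "PF03301",
                                      thresholds)
        assert present and support == [hit]

    def test_versionless_match(self, thresholds):
        hit = DomainHit("p000", "PF03301.13", "Trp_dioxygenase", 1e-30, 250.0)
        present, _ = has_domain(self.make_genome([hit]), "PF03301", thresholds)
        assert present

    def test_no_hits_or_weak_evalue_absent(self, thresholds):
        assert has_domain(self.make_genome([]), "PF03301", thresholds) == \
            (False, [])
        weak = DomainHit("p000", "PF03301", "Trp_dioxygenase", 1e-3, 20.0)
        assert has_domain(self.make_genome([weak]), "PF03301",
                          thresholds) == (False, [])

    def test_malformed_accession_rejected(self, thresholds):
        with pytest.raises(ValueError, match="malformed"):
            has_domain(self.make_genome([]), "TDO_DOMAIN", thresholds)


def place_roles(genome, placements):
    """placements: mapping role -> list of gene ranks."""
    return {role: {genome.genes[r].protein_id for r in ranks}
            for role, ranks in placements.items()}


class TestGeneCluster:
    def test_adjacent_triplet_found(self):
        genome = build_toy_genome(10)
        roles = place_roles(genome, {"A": [4], "B": [5], "C": [6]})
        req = ClusterRequirement(("A", "B", "C"), max_gap_genes=3)
        call, = find_gene_cluster(genome, roles, req)
        assert call.member_gene_ids == ("g004", "g005", "g006")
        assert call.role_assignment == {"A": "g004", "B": "g005", "C": "g006"}

    def test_roles_on_different_contigs_yield_nothing(self):
        genes = [GeneRecord("a", "pa", "c1", 100, 200, "+", 0),
                 GeneRecord("b", "pb", "c2", 100, 200, "+", 0)]
        genome = GenomeRecord("G", genes=genes)
        req = ClusterRequirement(("A", "B"), max_gap_genes=3)
        assert find_gene_cluster(genome, {"A": {"pa"}, "B": {"pb"}}, req) == []

    def test_gap_beyond_limit_breaks_cluster(self):
        genome = build_toy_genome(20)
        roles = place_roles(genome, {"A": [2], "B": [10]})
        req = ClusterRequirement(("A", "B"), max_gap_genes=3)
        assert find_gene_cluster(genome, roles, req) == []
        wide = ClusterRequirement(("A", "B"), max_gap_genes=7)
        assert len(find_gene_cluster(genome, roles, wide)) == 1

    def test_empty_role_returns_empty(self):
        genome = build_toy_genome(10)
        roles = place_roles(genome, {"A": [4], "B": []})
        req = ClusterRequirement(("A", "B"), max_gap_genes=3)
        assert find_gene_cluster(genome, roles, req) == []

    def test_same_strand_requirement(self):
        strands = ["+"] * 10
        strands[5] = "-"
        genome = build_toy_genome(10, strands=strands)
        roles = place_roles(genome, {"A": [4], "B": [5]})
        req = ClusterRequirement(("A", "B"), max_gap_genes=3, same_strand=True)
        assert find_gene_cluster(genome, roles, req) == []
        relaxed = ClusterRequirement(("A", "B"), max_gap_genes=3,
                                     same_strand=False)
        assert len(find_gene_cluster(genome, roles, relaxed)) == 1

    @pytest.mark.parametrize("same_strand", [False, True])
    def test_matches_exhaustive_enumeration(self, rng, same_strand):
        for trial in range(50):
            strands = [str(s) for s in rng.choice(["+", "-"], 30)]
            genome = build_toy_genome(30, strands=strands)
            placements = {
                role: list(map(int, rng.choice(30, size=int(rng.integers(0, 4)),
                                               replace=False)))
                for role in ("A", "B", "C")}
            roles = place_roles(genome, placements)
            req = ClusterRequirement(("A", "B", "C"),
                                     max_gap_genes=int(rng.integers(0, 5)),
                                     same_strand=same_strand)
            got = {(c.contig, c.member_gene_ids)
                   for c in find_gene_cluster(genome, roles, req)}
            assert got == clusters_bruteforce(genome, roles, req)

    def test_invariant_to_coordinate_translation(self):
        genome_a = build_toy_genome(12)
        genes_b = [GeneRecord(g.gene_id, g.protein_id, g.contig,
                              g.start + 50_000, g.end + 50_000, g.strand,
                              g.rank_on_contig) for g in genome_a.genes]
        genome_b = GenomeRecord("G2", genes=genes_b)
        roles_a = place_roles(genome_a, {"A": [3], "B": [4], "C": [7]})
        req = ClusterRequirement(("A", "B", "C"), max_gap_genes=3)
        sig = lambda calls: [(c.member_gene_ids, c.span_genes) for c in calls]
        assert sig(find_gene_cluster(genome_a, roles_a, req)) == \
            sig(find_gene_cluster(genome_b, roles_a, req))


class TestProximalPair:
    def test_adjacent_same_strand(self):
        genome = build_toy_genome(5)
        assert proximal_pair(genome, "p001", "p002", 0, True)

    def test_far_apart_rejected(self):
        genome = build_toy_genome(15)
        assert not proximal_pair(genome, "p001", "p012", 3, False)

    def test_unknown_protein_raises(self):
        genome = build_toy_genome(3)
        with pytest.raises(UnknownProteinError):
            proximal_pair(genome, "p000", "pXXX", 3, False)

    @pytest.mark.parametrize("same_strand", [False, True])
    def test_all_pairs_match_bruteforce_and_symmetry(self, rng, same_strand):
        strands = [str(s) for s in rng.choice(["+", "-"], 15)]
        genome = build_toy_genome(15, strands=strands)
        max_gap = 3
        for a in genome.genes:
            for b in genome.genes:
                if a is b:
                    continue
                got = proximal_pair(genome, a.protein_id, b.protein_id,
                                    max_gap, same_strand)
                assert got == proximal_bruteforce(a, b, max_gap, same_strand)
                assert got == proximal_pair(genome, b.protein_id, a.protein_id,
                                            max_gap, same_strand)
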