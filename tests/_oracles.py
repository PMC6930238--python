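"""Brute-force reference implementations used only to cross-check the package.

Each oracle re-derives its answer by exhaustive enumeration from first
principles, sharing no code with the implementation under test.
"""

from itertools import combinations


def filter_hits_bruteforce(hits, identity_min, coverage_min, evalue_max):
    """Per-hit predicate evaluation, written as a plain loop."""
    kept = []
    for h in hits:
        coverage = 100.0 * min(h.alignment_length, h.query_length) / h.query_length
        if (h.percent_identity >= identity_min and coverage >= coverage_min
                and h.evalue <= evalue_max):
            kept.append(h)
    return kept


def clusters_bruteforce(genome, role_proteins, req):
    """All minimal valid candidate windows by checking every (i, j) pair.

    Returns a set of (contig, member gene id tuple) signatures.
    """
    protein_roles = {}
    for role, proteins in role_proteins.items():
        for p in proteins:
            protein_roles.setdefault(p, set()).add(role)
    if any(not set(role_proteins.get(r, ())) for r in req.member_roles):
        return set()

    by_contig = {}
    for gene in genome.genes:
        if gene.protein_id in protein_roles:
            by_contig.setdefault(gene.contig, []).append(gene)
    valid = []
    for contig, genes in by_contig.items():
        genes = sorted(genes, key=lambda g: g.rank_on_contig)
        for i in range(len(genes)):
            for j in range(i, len(genes)):
                members = genes[i:j + 1]
                if req.same_strand and len({g.strand for g in members}) > 1:
                    continue
                if any(b.rank_on_contig - a.rank_on_contig - 1 > req.max_gap_genes
                       for a, b in zip(members, members[1:])):
                    continue
                covered = set()
                for g in members:
                    covered |= protein_roles[g.protein_id]
                if all(r in covered for r in req.member_roles):
                    valid.append((contig, tuple(g.gene_id for g in members)))
    minimal = set()
    for contig, ids in valid:
        if not any(c == contig and set(other) < set(ids)
                   for c, other in valid):
            minimal.add((contig, ids))
    return minimal


def proximal_bruteforce(gene_a, gene_b, max_gap, same_strand):
    if gene_a.contig != gene_b.contig:
        return False
    lo, hi = sorted([gene_a.rank_on_contig, gene_b.rank_on_contig])
    intervening = hi - lo - 1
    if intervening > max_gap:
        return False
    if same_strand and gene_a.strand != gene_b.strand:
        return False
    return True


def ranksum_exact_bruteforce(n_x, n_total, w):
    """Exact two-sided p by enumerating every size-n_x subset of ranks
    1..n_total (tie-free case)."""
    ranks = range(1, n_total + 1)
    sums = [sum(c) for c in combinations(ranks, n_x)]
    total = len(sums)
    p_le = sum(s <= w for s in sums) / total
    p_ge = sum(s >= w for s in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
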