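# Methods

This note documents the models, defaults and design choices behind
`trypcat`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Pathway rulebook

Each of the six metabolite pathways is a rule: an AND/OR tree whose leaves
are enzyme specifications, optionally tightened by a gene-cluster
requirement.

- **kynurenine** — presence of the tryptophan 2,3-dioxygenase (TDO) domain
  Trp_dioxygenase (PF03301). TDO catalyzes the committed, rate-limiting
  oxidation of L-tryptophan and its domain is diagnostic on its own, so the
  default rule does not additionally demand kynurenine formamidase (kynB)
  evidence; the two genes are not consistently clustered across kynurenine
  producers, and a stricter two-gene variant can be configured via the
  catalog config if desired.
- **quinolinate** — AND of three domains: 3-HAO (PF06052, on
  3-hydroxyanthranilate-3,4-dioxygenase), FAD_binding_3 (PF01494, kynurenine
  3-monooxygenase) and Aminotran_5 (PF00266, kynureninase). The rule does
  *not* also require the TDO domain: quinolinate-route genes occur in
  genomes lacking the kynurenine-producing precursor genes, consistent with
  cross-feeding of kynurenine between community members, and the call
  reports what the genome itself encodes.
- **indole** — tryptophanase homolog by BLAST. The enzyme's catalytic
  domain (Beta_elim_lyase) is shared by many unrelated lyases, so
  whole-protein homology is used instead of domain presence.
- **IAA** — OR of two alternate routes: tryptophan 2-monooxygenase
  (EC 1.13.12.3) or indolepyruvate decarboxylase (EC 4.1.1.74). Either
  homolog alone suffices, since the routes operate independently in
  different organisms.
- **IPA** — AND of the five Fld roles (phenyllactate dehydratase subunits
  FldA/FldB/FldC, the activator FldI and the AMP-binding protein FldL),
  plus a cluster requirement: at least one gene per role inside a single
  contiguous gene neighborhood.
- **tryptamine** — tryptophan decarboxylase homolog (EC 4.1.1.28), pooled
  over two characterized query proteins; a passing hit to either counts.
  The enzyme is a generic aromatic amino acid decarboxylase, hence homology
  to characterized tryptophan decarboxylases rather than domain presence.

Transporters: TnaB is called by proximity — a TnaB-domain gene on the same
strand within the proximity window of a tryptophanase-homolog gene —
because tnaB is encoded in the tryptophanase (tnaA) operon; AroP and Mtr
are called by thresholded homology alone.

**Placeholder accessions.** The Pfam families for the five Fld roles and the
TnaB permease domain are shipped as documented placeholders
(PF99901–PF99906): syntactically valid accessions that collide with no real
family. They make the rule engine fully exercisable and are meant to be
overridden with curated accessions through `load_catalog` (YAML config;
`trypcat catalog dump` prints an editable template). Homolog query tags
(`tnaA_ECOLI`, `iaaM_PSESY`, `ipdC_ENTCL`, `tdc_CLOSG`, `tdc_RUMGN`,
`aroP_ECOLI`, `aroP_CORGL`, `mtr_ECOLI`) are likewise package-chosen
identifiers for the curated query set; any BLAST run against queries under
these names plugs in directly.

## Evidence thresholds and proximity

| parameter | default | meaning |
|---|---|---|
| identity_min | 70 % | minimum BLAST percent identity |
| coverage_min | 90 % | minimum query coverage |
| evalue_max | 1e-5 | maximum homology e-value |
| domain_evalue_max | 1e-5 | maximum domain i-e-value |
| proximity_max_gap | 3 genes | max intervening genes in clusters/pairs |

All comparisons are inclusive (≥, ≥, ≤), the standard reading of a
"threshold" in BLAST filtering. Query coverage is computed as
100·min(alignment_length, query_length)/query_length because tabular BLAST
output does not carry coverage; the clip at 100 guards against gapped local
alignments longer than the query. Domain presence needs one hit under the
e-value gate; no bitscore gathering thresholds are applied since the calls
are presence/absence.

Gene proximity is measured in *intervening genes* (differences of the gene's
rank along its contig), not base pairs: this is robust to intergenic-length
variation and matches the operon heuristic. The cluster default of at most
3 intervening genes between consecutive members, same contig, strand-free,
is the package's own choice of a "close proximity" window; the tnaA–tnaB
pair additionally requires equal strands because the pair is operonic.
Cluster detection returns every *minimal* valid window (no valid proper
sub-window), found per contig by splitting candidates at gap/strand breaks
and sliding a minimal covering window; ties in gene start coordinates are
broken by end then gene id so that ranks, and therefore all proximity
results, are deterministic.

## SCORBPEO

For genus *j* and metabolite *i*: `SCORBPEO_ij = P · α · β`, raw range
0–50, reported on a 0–10 scale via the linear rescale `score = raw / 5`.

- **P** — exact proportion of the genus's strains with a positive call.
- **α (confidence)** — the score definition asks for a percentile-derived
  rank 1–10 growing with how well the genus is represented in the
  collection. The package maps the inclusive percentile of the genus's
  strain count, p = 100·#{genera with count ≤ own}/#genera, through a
  decile ceiling `α = max(1, ⌈p/10⌉)`. This gives the best-represented
  genus α = 10 (and a single-genus collection α = 10); with strain counts
  1..10 over ten genera the ranks enumerate 1..10.
- **β (gut-weightage)** — must span 1–5 and grow with enrichment of the
  pathway among gut-associated strains relative to the genus's other
  strains. With gut prevalence g and non-gut prevalence h, the gut share
  s = g/(g+h) (0 when both vanish) is mapped affinely: `β = 1 + 4s`. The
  share form is bounded, symmetric (equal prevalence gives the midpoint
  β = 3), and handles genera with no non-gut strains (β = 5 whenever the
  pathway occurs only in gut strains).

The exact percentile→rank and enrichment→β functions are underdetermined by
the score's published description; both mappings are pluggable
(`score_matrix(..., alpha_fn=..., beta_fn=...)`) and the chosen mapping
names are recorded in the score metadata and the run log. Published
per-genus score values from the original genome census are not a validation
target here: they depend on a 2019 snapshot of the NCBI/HMP genome
databases that cannot be reconstituted from a desk-scale package.

## Differential abundance

Counts are normalized to per-sample relative abundances (no rarefaction;
none is assumed by the rank-based test). Each genus is tested case vs
control with a two-sided Wilcoxon rank-sum test and screened at raw
p ≤ 0.01 with **no multiple-testing correction** — the screen is
deliberately a raw-p filter, and this is recorded in the run log. Direction
is assigned from group medians of relative abundance (ties fall back to
means, then to an explicit "ambiguous" flag).

The statistic W is the pooled mid-rank sum of the first sample. For pooled
size ≤ 20 with no ties the two-sided p is exact,
p = min(1, 2·min(P(W' ≤ w), P(W' ≥ w))), with the null distribution
obtained by a subset-sum counting recurrence (cached per sample-size pair);
otherwise the normal approximation is used with tie-corrected variance and
a 0.5 continuity correction, degenerating to p = 1 when the tie-corrected
variance vanishes. The test suite cross-checks the exact branch against
full C(16,8) enumeration and both branches against
`scipy.stats.mannwhitneyu`.

Compositionality caveat: relative abundances are closed, so a strong shift
in one genus necessarily moves others in the opposite direction; the
rank-sum screen inherits this, as any relative-abundance analysis does.

## Synthetic data

`make_collection` emulates a genome census: 5 genera across the five
gut-associated phyla (Actinobacteria, Firmicutes, Bacteroidetes,
Proteobacteria, Fusobacteria), 40 strains by default, each with a 40-gene
single-contig genome. Pathway presence is drawn per strain from
(genus, gut-status)-specific prevalences patterned after the census
structure (indole widespread and strongest in *Fusobacterium*,
kynurenine/quinolinate concentrated in Proteobacteria, IPA rare and
*Clostridium*-bound). For each planted pathway the generator emits the
*minimal sufficient* evidence for the default rule — one item per required
leaf, placed at fixed gene slots, with values far from the thresholds
(identity 95, coverage 100, e-values ≤ 1e-30) — so that deleting any single
planted item provably flips the call; threshold-boundary behavior is tested
with dedicated fixtures at exactly (70, 90, 1e-5) instead. Decoy domain
hits (non-catalog accessions) and sub-threshold homolog hits are sprinkled
over non-slot genes and must never trigger a rule. Transporters are planted
only in indole-positive strains, TnaB as a domain gene adjacent (same
strand) to the planted tryptophanase gene.

`make_abundance_study` draws genus compositions log-normally: per-genus
baseline log-means ~ N(0, 1), within-group noise σ = 0.4 on the natural-log
scale, case-group compositions of effect genera multiplied by their fold
change (default 4 in 2 of 20 genera) before renormalization, then scaled to
a uniformly drawn depth (20 000–50 000) and rounded. The noise default was
chosen so that the planted-effect design is reliably detectable by the
rank-sum screen at n = 15 vs 15 while the groups still overlap
substantially. Same seed, same bytes: all files are written
deterministically.

**What passing these tests does and does not show.** The generator produces
exchangeable within-group samples with modest, homoscedastic log-normal
noise and no phylogenetic correlation between genomes, no annotation error,
and evidence either clearly present or clearly absent. Passing therefore
demonstrates that the rule logic, thresholds, proximity detection, scoring
arithmetic and testing machinery are correct — not that the pipeline's
sensitivity/specificity on real genomes or 16S profiles matches these
numbers. Real 16S genus abundances are typically more dispersed
(overdispersion, zero inflation) and real annotations noisier; power and
calibration on real data will be correspondingly lower than in the planted
designs.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive everywhere in memory; rank order is the
  unique (start, end, gene_id) sort per contig.
- `filter_homology_hits` is a pure, order-preserving, idempotent filter,
  monotone under threshold loosening.
- Genera spanning two phyla are rejected at manifest load: genus-level
  aggregation requires a single taxonomy path.
- An all-zero sample fails normalization explicitly rather than silently
  producing NaNs.
- Empty differential input, empty Sankey link lists, and collections with a
  single genus are all valid inputs with defined outputs.
- The problem sizes used by the test suite and the acceptance script
  (40-strain collections, 30-gene contigs, 100-genus null studies, 100-seed
  repetitions) are the package's chosen desk-scale study conditions; all
  statistical assertions are stated with tolerances derived from binomial
  noise at those sizes.

## Known limitations

- The shipped Fld/TnaB accessions are placeholders (above); real screens
  must override them with curated families.
- Pathway calls are boolean with an evidence trail, not probabilistic; no
  partial credit for near-threshold evidence.
- No cross-genome pathway complementation: a genome is called on its own
  gene content only, although the quinolinate rule's independence from the
  kynurenine rule leaves room for cross-feeding interpretations.
- The transporter screen covers the three characterized importers only;
  genomes using uncharacterized non-specific transporters will appear
  importer-free.
- The microbiome stage consumes genus-level tables; OTU/ASV-level analysis,
  covariate adjustment and 16S read processing are out of scope.
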