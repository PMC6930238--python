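# trypcat

Genome mining of bacterial tryptophan catabolism for the gut–brain axis.

Gut bacteria catabolize dietary tryptophan into a set of neuro-active
metabolites — kynurenine, quinolinate, indole, indole acetic acid (IAA),
indole propionic acid (IPA), and tryptamine — that are implicated in
signaling along the gut–brain axis. `trypcat` is a pipeline for asking, from
annotated bacterial genomes and case/control microbiome profiles, *which*
bacteria can make these compounds and whether the taxa that can are shifted
in disease:

1. **Pathway prediction.** A declarative rulebook encodes one rule per
   metabolite as an AND/OR tree over enzyme-evidence leaves. Evidence is
   either a diagnostic Pfam domain (e.g. the tryptophan 2,3-dioxygenase
   domain PF03301 suffices for the kynurenine route; quinolinate needs the
   3-HAO, FAD_binding_3 and Aminotran_5 domains jointly) or a thresholded
   protein homolog (BLAST tabular input filtered at identity ≥ 70%, query
   coverage ≥ 90%, e-value ≤ 1e-5; used for tryptophanase, the two IAA
   routes, and tryptophan decarboxylase). The IPA rule additionally requires
   the five Fld roles (FldA/B/C, FldI, FldL) to form a gene cluster — every
   member within a bounded number of intervening genes on one contig.
2. **Transporter profiling.** Indole-producing genomes are screened for the
   tryptophan importers TnaB (a TnaB-domain gene operonic — same strand,
   proximal — with a tryptophanase homolog), AroP and Mtr (homology).
3. **Genus-level scoring.** Strain calls aggregate to a genus × metabolite
   score

   SCORBPEO_ij = P · α · β

   where *P* ∈ [0, 1] is the proportion of the genus's strains carrying the
   pathway, α ∈ {1..10} is a confidence rank from the percentile of the
   genus's strain count in the collection, and β ∈ [1, 5] weights enrichment
   of the pathway among the genus's gut-associated strains. The raw product
   spans 0–50 and is rescaled linearly to 0–10.
4. **Microbiome linking.** Genus abundance tables (case vs control) are
   normalized to relative abundances, tested per genus with a two-sided
   Wilcoxon rank-sum test, screened at raw p ≤ 0.01, and every differential
   genus is linked to its positively scored pathways as a weighted Sankey
   edge list.

A synthetic-data module generates genome collections with planted evidence
and case/control studies with planted fold changes, each with a ground-truth
record, so every stage is testable end to end without external data.

## Worked example

Generate a seeded synthetic bundle (40 strains in 5 genera across the five
gut-associated phyla, plus a 15 vs 15 case/control study with 4-fold shifts
planted in *Burkholderia* and *Clostridium*) and run the full pipeline:

```sh
trypcat simulate --out demo --seed 7
trypcat run --manifest demo/genomes/manifest.tsv \
            --abundance demo/study/abundance.tsv \
            --groups demo/study/groups.tsv \
            --out demo/out --seed 7
```

`demo/out/score_matrix.tsv` holds the genus × metabolite scores (0–10):

```
genus	kynurenine	quinolinate	indole	IAA	IPA	tryptamine
Bacteroides	0.0000	3.0000	2.1429	0.0000	0.0000	0.0000
Bifidobacterium	0.0000	0.0000	0.0000	0.6000	0.0000	0.3333
Burkholderia	3.4667	4.2000	1.6909	2.1765	0.0000	2.0000
```

e.g. *Burkholderia*'s kynurenine cell 3.47 = P (0.5) · α (8, from its
strain-count percentile) · β (4.33, gut-leaning enrichment) / 5 — a genus
whose strains frequently carry the TDO domain, with the pathway somewhat
enriched in its gut strains. `transporter_summary.tsv` reports that 15 of the
21 indole-producing strains (71.4%) carry at least one tryptophan importer,
with the Venn breakdown over {TnaB, Mtr, AroP}. `differential_genera.tsv`
recovers the two planted genera as the top case-enriched hits:

```
genus	W	p_value	direction	median_case	median_control
Clostridium	345	3.39182e-06	case_enriched	0.150004	0.0509482
Burkholderia	342	6.15164e-06	case_enriched	0.171038	0.0667886
```

and `sankey.json` links them to every pathway they score positively for,
edge widths carrying the SCORBPEO values.

Each stage is also available separately (`trypcat predict / score /
transporters / diff / link`), and `trypcat catalog dump` exports the
rulebook as a YAML config that can be edited (e.g. alternative Fld Pfam
accessions, a wider cluster gap) and passed back via `--catalog`.

## Layout

- `src/trypcat/catalog.py` — the TRYP-6 rulebook and transporter specs
- `src/trypcat/genome_io.py` — gene tables (GFF3/TSV), domain and BLAST hit
  tables, collection manifests
- `src/trypcat/evidence.py` — homology filtering, domain presence,
  gene-cluster and proximity detection
- `src/trypcat/predict.py` — strain-level calls and phylum/gut summaries
- `src/trypcat/transporters.py` — importer profiles and Venn summaries
- `src/trypcat/scoring.py` — SCORBPEO genus scoring
- `src/trypcat/abundance.py` — normalization, rank-sum testing, Sankey export
- `src/trypcat/simulate.py` — synthetic genomes and abundance studies
- `src/trypcat/pipeline.py`, `src/trypcat/cli.py` — orchestration and CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
design choices.
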