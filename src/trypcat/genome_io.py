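"""Data model and readers/writers for genomes, annotations and hit tables.

All in-memory coordinates are 1-based inclusive (GFF3 convention); any
half-open dialect must be converted at the boundary.  Genes are ranked along
each contig in (start, end, gene_id) order; proximity logic downstream works
exclusively in these rank units.

Input dialects
--------------
- gene tables: GFF3 (CDS features with ``ID`` and ``protein_id`` attributes)
  or TSV with header ``gene_id  protein_id  contig  start  end  strand  product``;
- domain hits: HMMER domtblout-style whitespace table ('#' comments); columns
  consumed: 1 target name (protein), 2 accession (Pfam), 4 query name (domain),
  13 independent e-value, 14 score;
- homology hits: BLAST tabular outfmt 6 (12 tab-separated columns), with query
  lengths supplied separately since outfmt 6 does not carry them;
- collection manifest: TSV with header ``genome_id  phylum  genus  species
  strain  is_gut_associated  gene_table  domain_table  homology_table``
  (paths relative to the manifest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

import pandas as pd

from .catalog import strip_pfam_version
from .errors import (
    FormatError,
    IntegrityError,
    ManifestError,
    UnknownProteinError,
    UnknownQueryTagError,
)

GENE_TSV_COLUMNS = ("gene_id", "protein_id", "contig", "start", "end",
                    "strand", "product")
MANIFEST_COLUMNS = ("genome_id", "phylum", "genus", "species", "strain",
                    "is_gut_associated", "gene_table", "domain_table",
                    "homology_table")
BLAST6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    protein_id: str
    contig: str
    start: int
    end: int
    strand: str
    rank_on_contig: int = -1
    product: str = ""


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    accession: str
    domain_name: str
    evalue: float
    bitscore: float

    def matches(self, accession: str) -> bool:
        return strip_pfam_version(self.accession) == strip_pfam_version(accession)


@dataclass(frozen=True)
class HomologyHit:
    query_tag: str
    subject_protein_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_length: int

    @property
    def coverage(self) -> float:
        """Query coverage in percent, clipped at 100 (local alignments with
        gaps may exceed the query length)."""
        return 100.0 * min(self.alignment_length, self.query_length) / self.query_length


@dataclass
class GenomeRecord:
    genome_id: str
    phylum: str = ""
    genus: str = ""
    species: str = ""
    strain: str = ""
    is_gut_associated: bool = False
    genes: list[GeneRecord] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)
    homology_hits: list[HomologyHit] = field(default_factory=list)

    def gene_by_protein(self, protein_id: str) -> GeneRecord:
        for g in self.genes:
            if g.protein_id == protein_id:
                return g
        raise UnknownProteinError(
            f"genome {self.genome_id!r}: no gene encodes protein {protein_id!r}")

    def protein_ids(self) -> set[str]:
        return {g.protein_id for g in self.genes}


@dataclass
class GenomeCollection:
    genomes: list[GenomeRecord]
    source: str = ""
    date: str = ""

    def __post_init__(self):
        ids = [g.genome_id for g in self.genomes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ManifestError(f"duplicate genome_id(s): {sorted(dupes)}")

    def __iter__(self):
        return iter(self.genomes)

    def __len__(self):
        return len(self.genomes)

    def by_id(self, genome_id: str) -> GenomeRecord:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)


def _rank_genes(records: Iterable[GeneRecord]) -> list[GeneRecord]:
    """Sort by (contig, start, end, gene_id) and assign per-contig ranks."""
    ordered = sorted(records, key=lambda g: (g.contig, g.start, g.end, g.gene_id))
    ranked = []
    counters: dict[str, int] = {}
    for g in ordered:
        rank = counters.get(g.contig, 0)
        counters[g.contig] = rank + 1
        ranked.append(GeneRecord(g.gene_id, g.protein_id, g.contig, g.start,
                                 g.end, g.strand, rank, g.product))
    return ranked


def _check_gene(gene_id: str, start: int, end: int, strand: str, path) -> None:
    if start < 1 or start > end:
        raise FormatError(f"{path}: gene {gene_id!r} has invalid coordinates "
                          f"start={start} end={end} (need 1 <= start <= end)")
    if strand not in ("+", "-"):
        raise FormatError(f"{path}: gene {gene_id!r} has invalid strand {strand!r}")


def _read_gene_tsv(path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: gene {row.gene_id!r} has non-integer "
                              "coordinates")
        _check_gene(row.gene_id, start, end, row.strand, path)
        records.append(GeneRecord(row.gene_id, row.protein_id, row.contig,
                                  start, end, row.strand,
                                  product="" if pd.isna(row.product) else row.product))
    return records


def _read_gene_gff3(path) -> list[GeneRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated "
                                  f"GFF3 columns, found {len(parts)}")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            attributes = {}
            for item in attrs.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attributes[key.strip()] = unquote(value)
            gene_id = attributes.get("ID")
            protein_id = attributes.get("protein_id")
            if not gene_id or not protein_id:
                raise FormatError(f"{path}:{lineno}: CDS feature lacks ID or "
                                  "protein_id attribute")
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            _check_gene(gene_id, s, e, strand, path)
            records.append(GeneRecord(gene_id, protein_id, contig, s, e, strand,
                                      product=attributes.get("product", "")))
    return records


def read_gene_table(path, format: str | None = None) -> list[GeneRecord]:
    """Read a gene annotation table (GFF3 CDS features or documented TSV).

    Records come back sorted by (contig, start) with ``rank_on_contig``
    assigned; coordinates stay 1-based inclusive.
    """
    if format is None:
        format = "gff3" if str(path).endswith((".gff", ".gff3")) else "tsv"
    if format == "gff3":
        records = _read_gene_gff3(path)
    elif format == "tsv":
        records = _read_gene_tsv(path)
    else:
        raise ValueError(f"unknown gene table format {format!r}")
    return _rank_genes(records)


def write_gene_table(genes: Iterable[GeneRecord], path, format: str = "tsv") -> None:
    genes = list(genes)
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("\t".join(GENE_TSV_COLUMNS) + "\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.protein_id}\t{g.contig}\t{g.start}\t"
                         f"{g.end}\t{g.strand}\t{g.product}\n")
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={quote(g.gene_id)};protein_id={quote(g.protein_id)}"
                if g.product:
                    attrs += f";product={quote(g.product)}"
                fh.write(f"{g.contig}\ttrypcat\tCDS\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t0\t{attrs}\n")
        else:
            raise ValueError(f"unknown gene table format {format!r}")


def read_domain_hits(path) -> list[DomainHit]:
    """Read a domtblout-style whitespace-delimited domain hit table."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 14:
                raise FormatError(f"{path}:{lineno}: expected >=14 whitespace-"
                                  f"delimited columns, found {len(parts)}")
            try:
                evalue = float(parts[12])
                score = float(parts[13])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric field "
                                  f"({exc})")
            if evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative e-value")
            hits.append(DomainHit(parts[0], parts[1], parts[3], evalue, score))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    """Write hits in the domtblout-style dialect :func:`read_domain_hits` reads."""
    with open(path, "w") as fh:
        fh.write("# target_name accession tlen query_name q_accession qlen "
                 "seq_evalue seq_score seq_bias n of c_evalue i_evalue "
                 "dom_score dom_bias\n#\n")
        for h in hits:
            fh.write(f"{h.protein_id} {h.accession} 300 {h.domain_name} - 300 "
                     f"{h.evalue:.3g} {h.bitscore:.1f} 0.1 1 1 {h.evalue:.3g} "
                     f"{h.evalue:.3g} {h.bitscore:.1f} 0.1\n")


def read_homology_hits(path, query_lengths: Mapping[str, int]) -> list[HomologyHit]:
    """Read BLAST outfmt-6 rows and attach query lengths from the mapping."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 tab-separated "
                                  f"columns (outfmt 6), found {len(parts)}")
            qseqid, sseqid = parts[0], parts[1]
            if qseqid not in query_lengths:
                raise UnknownQueryTagError(
                    f"{path}:{lineno}: query tag {qseqid!r} absent from the "
                    "query-length table")
            try:
                pident = float(parts[2])
                length = int(parts[3])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric field "
                                  f"({exc})")
            if not 0.0 <= pident <= 100.0:
                raise FormatError(f"{path}:{lineno}: percent identity {pident} "
                                  "outside [0, 100]")
            hits.append(HomologyHit(qseqid, sseqid, pident, length, evalue,
                                    bitscore, int(query_lengths[qseqid])))
    return hits


def write_homology_hits(hits: Iterable[HomologyHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qend = h.alignment_length
            fh.write(f"{h.query_tag}\t{h.subject_protein_id}\t{h.percent_identity:.1f}\t"
                     f"{h.alignment_length}\t0\t0\t1\t{qend}\t1\t{qend}\t"
                     f"{h.evalue:.3g}\t{h.bitscore:.1f}\n")


def read_query_lengths(path) -> dict[str, int]:
    """Read a TSV with header ``query_tag  length``."""
    df = pd.read_csv(path, sep="\t", dtype={"query_tag": str, "length": int})
    missing = [c for c in ("query_tag", "length") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    if (df["length"] < 1).any():
        bad = df.loc[df["length"] < 1, "query_tag"].tolist()
        raise FormatError(f"{path}: non-positive query length for {bad}")
    return dict(zip(df["query_tag"], df["length"]))


def write_query_lengths(query_lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_tag\tlength\n")
        for tag in sorted(query_lengths):
            fh.write(f"{tag}\t{query_lengths[tag]}\n")


def load_genome_collection(manifest_path,
                           query_lengths: Mapping[str, int] | None = None,
                           ) -> GenomeCollection:
    """Load a full genome collection from its manifest.

    If ``query_lengths`` is not given, a ``query_lengths.tsv`` file next to
    the manifest is used.  Every hit table is cross-reference-validated
    against its gene table; genera spanning several phyla are rejected since
    genus-level aggregation needs a single taxonomy path.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{manifest_path}: missing mandatory column(s) {missing}")
    if df["genome_id"].duplicated().any():
        dupes = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ManifestError(f"{manifest_path}: duplicate genome_id(s) {dupes}")

    if query_lengths is None:
        ql_path = base / "query_lengths.tsv"
        query_lengths = read_query_lengths(ql_path) if ql_path.exists() else {}

    genus_phylum: dict[str, str] = {}
    genomes = []
    for row in df.itertuples(index=False):
        prev = genus_phylum.setdefault(row.genus, row.phylum)
        if prev != row.phylum:
            raise ManifestError(
                f"{manifest_path}: genus {row.genus!r} assigned to both "
                f"phyla {prev!r} and {row.phylum!r}")
        genes = read_gene_table(base / row.gene_table)
        domain_hits = read_domain_hits(base / row.domain_table)
        homology_hits = read_homology_hits(base / row.homology_table, query_lengths)
        genome = GenomeRecord(
            genome_id=row.genome_id, phylum=row.phylum, genus=row.genus,
            species=row.species, strain=row.strain,
            is_gut_associated=str(row.is_gut_associated).strip() in ("1", "true", "True"),
            genes=genes, domain_hits=domain_hits, homology_hits=homology_hits)
        known = genome.protein_ids()
        for h in domain_hits:
            if h.protein_id not in known:
                raise IntegrityError(f"genome {row.genome_id!r}: domain hit "
                                     f"references unknown protein {h.protein_id!r}")
        for h in homology_hits:
            if h.subject_protein_id not in known:
                raise IntegrityError(f"genome {row.genome_id!r}: homology hit "
                                     f"references unknown protein "
                                     f"{h.subject_protein_id!r}")
        genomes.append(genome)
    return GenomeCollection(genomes, source=str(manifest_path))
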