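"""Genus-level pathway-potential scoring (SCORBPEO).

For metabolite *i* and genus *j* the score is the product

    SCORBPEO_ij = P * alpha * beta

with

- ``P`` in [0, 1]: proportion of the genus's strains predicted to carry the
  pathway;
- ``alpha`` in {1..10}: confidence rank from the percentile of the genus's
  strain count among all genera (better-sampled genera score higher);
- ``beta`` in [1, 5]: gut-weightage, growing with the enrichment of the
  pathway among the genus's gut-associated strains relative to its other
  strains.

The raw product lies in [0, 50] and is rescaled linearly to a 0-10 scale
(``score = raw / 5``).  The percentile-to-rank and enrichment-to-beta mappings
are package choices (the score definition fixes only their ranges and
monotonicity); both are pluggable and recorded in output metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .catalog import METABOLITES
from .genome_io import GenomeCollection
from .predict import PathwayCallMatrix


@dataclass(frozen=True)
class GenusSummary:
    genus: str
    phylum: str
    n_strains: int
    n_gut_strains: int
    n_with_pathway: Mapping[str, int]
    n_gut_with_pathway: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "n_with_pathway", dict(self.n_with_pathway))
        object.__setattr__(self, "n_gut_with_pathway", dict(self.n_gut_with_pathway))


@dataclass(frozen=True)
class GenusScore:
    genus: str
    metabolite: str
    P: float
    alpha: int
    beta: float
    raw: float
    score: float


def summarize_genus(matrix: PathwayCallMatrix,
                    collection: GenomeCollection) -> list[GenusSummary]:
    """Exact per-genus tallies of strains and pathway-positive strains."""
    by_genus: dict[str, list] = {}
    for genome in collection:
        by_genus.setdefault(genome.genus, []).append(genome)
    summaries = []
    for genus in sorted(by_genus):
        genomes = by_genus[genus]
        ids = [g.genome_id for g in genomes]
        gut_ids = [g.genome_id for g in genomes if g.is_gut_associated]
        calls = matrix.calls.loc[ids]
        gut_calls = matrix.calls.loc[gut_ids]
        summaries.append(GenusSummary(
            genus=genus,
            phylum=genomes[0].phylum,
            n_strains=len(ids),
            n_gut_strains=len(gut_ids),
            n_with_pathway={m: int(calls[m].sum()) for m in METABOLITES},
            n_gut_with_pathway={m: int(gut_calls[m].sum()) for m in METABOLITES},
        ))
    return summaries


def confidence_alpha(genus_summary: GenusSummary,
                     all_summaries: Iterable[GenusSummary]) -> int:
    """Decile rank (1..10) of the genus's strain count.

    percentile = 100 * (# genera with n_strains <= own) / (# genera),
    mapped with an inclusive decile ceiling, so the best-represented genus
    always ranks 10 and a single-genus collection ranks 10.
    """
    counts = [s.n_strains for s in all_summaries]
    if not counts:
        raise ValueError("all_summaries must be nonempty")
    percentile = 100.0 * sum(c <= genus_summary.n_strains for c in counts) / len(counts)
    return max(1, math.ceil(percentile / 10.0))


def gut_weightage_beta(genus_summary: GenusSummary, metabolite: str) -> float:
    """Gut-enrichment factor in [1, 5].

    With g = gut prevalence and h = non-gut prevalence of the pathway within
    the genus, the gut share s = g / (g + h) (0 when both are 0) is mapped
    affinely to beta = 1 + 4 s: beta = 5 when the pathway occurs only in gut
    strains, 3 when equally prevalent, 1 when absent from gut strains.
    """
    n_gut = genus_summary.n_gut_strains
    n_other = genus_summary.n_strains - n_gut
    k_gut = genus_summary.n_gut_with_pathway[metabolite]
    k_other = genus_summary.n_with_pathway[metabolite] - k_gut
    g = k_gut / n_gut if n_gut else 0.0
    h = k_other / n_other if n_other else 0.0
    s = g / (g + h) if g + h > 0 else 0.0
    return 1.0 + 4.0 * s


def scorbpeo(P: float, alpha: int, beta: float) -> tuple[float, float]:
    """The score product and its 0-10 rescaling: (raw, raw / 5)."""
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P={P} outside [0, 1]")
    if alpha not in range(1, 11):
        raise ValueError(f"alpha={alpha} outside 1..10")
    if not 1.0 <= beta <= 5.0:
        raise ValueError(f"beta={beta} outside [1, 5]")
    raw = P * alpha * beta
    return raw, raw / 5.0


@dataclass
class ScoreMatrix:
    scores: pd.DataFrame     # genus x metabolite, rescaled 0-10
    raw: pd.DataFrame        # genus x metabolite, 0-50
    cells: Mapping[tuple[str, str], GenusScore] = field(default_factory=dict)
    metadata: Mapping[str, object] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "genus"
        out.to_csv(path, sep="\t", float_format="%.4f")


AlphaFn = Callable[[GenusSummary, list[GenusSummary]], int]
BetaFn = Callable[[GenusSummary, str], float]


def score_matrix(matrix: PathwayCallMatrix, collection: GenomeCollection,
                 gut_only: bool = False,
                 alpha_fn: AlphaFn = confidence_alpha,
                 beta_fn: BetaFn = gut_weightage_beta) -> ScoreMatrix:
    """Compose the tallies and the three factors into the genus x metabolite
    score matrix; ``gut_only`` keeps genera with at least one gut strain."""
    summaries = summarize_genus(matrix, collection)
    kept = [s for s in summaries if s.n_gut_strains > 0] if gut_only else summaries
    cells = {}
    score_rows, raw_rows = {}, {}
    for s in kept:
        alpha = alpha_fn(s, summaries)
        score_rows[s.genus], raw_rows[s.genus] = {}, {}
        for m in METABOLITES:
            P = s.n_with_pathway[m] / s.n_strains
            beta = beta_fn(s, m)
            raw, rescaled = scorbpeo(P, alpha, beta)
            cells[(s.genus, m)] = GenusScore(s.genus, m, P, alpha, beta,
                                             raw, rescaled)
            score_rows[s.genus][m] = rescaled
            raw_rows[s.genus][m] = raw
    scores = pd.DataFrame.from_dict(score_rows, orient="index").reindex(
        columns=list(METABOLITES)).sort_index()
    raw = pd.DataFrame.from_dict(raw_rows, orient="index").reindex(
        columns=list(METABOLITES)).sort_index()
    metadata = {
        "alpha_mapping": getattr(alpha_fn, "__name__", str(alpha_fn)),
        "beta_mapping": getattr(beta_fn, "__name__", str(beta_fn)),
        "rescaling": "linear raw/5 (0-50 -> 0-10)",
        "gut_only": gut_only,
        "n_genera": len(kept),
    }
    return ScoreMatrix(scores, raw, cells, metadata)
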