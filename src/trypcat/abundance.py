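"""Case/control microbiome stage: normalization, rank-sum testing, linking.

Genus counts are normalized to per-sample relative abundances, each genus is
tested case vs control with a two-sided Wilcoxon rank-sum test, genera passing
the raw p <= 0.01 screen (no multiple-testing adjustment) are labelled by
direction, and every (differential genus, positively scored metabolite) pair
becomes a weighted edge for Sankey rendering.

The rank-sum statistic W is the sum of pooled mid-ranks of the first sample.
The two-sided p-value is exact (by counting rank-subset sums) when the pooled
size is at most 20 and tie-free, and otherwise uses the normal approximation
with tie-corrected variance and a continuity correction — the behavior of the
classical wilcox.test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import FormatError, ManifestError, NormalizationError
from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")


@dataclass
class AbundanceTable:
    counts: pd.DataFrame   # index sample_id, columns genus, non-negative
    groups: pd.Series      # index sample_id, values in GROUPS
    normalized: bool = False

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise FormatError("abundance table contains negative entries")
        missing = set(self.counts.index) - set(self.groups.index)
        if missing:
            raise ManifestError(f"samples without group label: {sorted(missing)}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ManifestError(f"unknown group label(s): {sorted(bad)}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.index if self.groups[s] == group]


@dataclass(frozen=True)
class DifferentialResult:
    genus: str
    statistic: float
    p_value: float
    direction: str            # "case_enriched" | "control_enriched" | "ambiguous"
    median_case: float
    median_control: float


@dataclass(frozen=True)
class DifferentialLink:
    genus: str
    metabolite: str
    group: str
    scorbpeo_weight: float
    p_value: float


def read_abundance_table(path, groups_path) -> AbundanceTable:
    """Read a long TSV (sample_id, genus, count) plus a groups TSV
    (sample_id, group); absent (sample, genus) pairs become zero cells."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genus": str})
    missing = [c for c in ("sample_id", "genus", "count") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0]
        raise FormatError(f"{path}: negative count for sample "
                          f"{bad.iloc[0]['sample_id']!r} genus "
                          f"{bad.iloc[0]['genus']!r}")
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    gmissing = [c for c in ("sample_id", "group") if c not in gdf.columns]
    if gmissing:
        raise FormatError(f"{groups_path}: missing mandatory column(s) {gmissing}")
    groups = pd.Series(gdf["group"].values, index=gdf["sample_id"])
    counts = (df.pivot_table(index="sample_id", columns="genus", values="count",
                             aggfunc="sum", fill_value=0.0)
              .sort_index().sort_index(axis=1))
    counts = counts.astype(float)
    counts.columns.name = None
    return AbundanceTable(counts, groups, normalized=False)


def relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample's row by its total; every row then sums to one."""
    if table.normalized:
        raise ValueError("table is already normalized")
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise NormalizationError(f"sample(s) with all-zero counts: {list(zero)}")
    return AbundanceTable(table.counts.div(totals, axis=0), table.groups,
                          normalized=True)


@lru_cache(maxsize=64)
def _exact_rank_sum_counts(n_x: int, n_total: int) -> tuple[np.ndarray, int]:
    """Number of rank subsets of size n_x from ranks 1..n_total attaining each
    sum; returns (counts indexed by sum, offset = minimal sum)."""
    w_min = n_x * (n_x + 1) // 2
    w_max = n_x * (2 * n_total - n_x + 1) // 2
    width = w_max - w_min + 1
    # counts[k][w] = subsets of size k with rank-sum w (shifted by k-minimum)
    counts = np.zeros((n_x + 1, w_max + 1), dtype=float)
    counts[0][0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(r, n_x), 0, -1):
            counts[k, r:] += counts[k - 1, :-r or None]
    return counts[n_x, w_min:w_max + 1].copy(), w_min


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (W, p) with W the mid-rank sum of x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    n_x, n = x.size, pooled.size
    ranks = rankdata(pooled)
    w = float(ranks[:n_x].sum())
    has_ties = np.unique(pooled).size < n

    if n <= 20 and not has_ties:
        counts, offset = _exact_rank_sum_counts(n_x, n)
        total = counts.sum()
        wi = int(round(w)) - offset
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        return w, min(1.0, 2.0 * min(p_le, p_ge))

    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    n_y = n - n_x
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    d = abs(w - mu) - 0.5           # continuity correction
    z = max(0.0, d) / np.sqrt(var)
    return w, min(1.0, 2.0 * float(norm.sf(z)))


def _direction(case: np.ndarray, control: np.ndarray) -> str:
    mc, mh = float(np.median(case)), float(np.median(control))
    if mc > mh:
        return "case_enriched"
    if mc < mh:
        return "control_enriched"
    meanc, meanh = float(np.mean(case)), float(np.mean(control))
    if meanc > meanh:
        return "case_enriched"
    if meanc < meanh:
        return "control_enriched"
    return "ambiguous"


def differential_genera(table: AbundanceTable,
                        p_max: float = 0.01) -> list[DifferentialResult]:
    """Rank-sum test per genus on relative abundances; keep raw p <= p_max."""
    if not table.normalized:
        raise ValueError("differential testing expects relative abundances; "
                         "call relative_abundance first")
    case_ids = table.samples_in("case")
    control_ids = table.samples_in("control")
    if not case_ids or not control_ids:
        raise ValueError("both case and control groups must be nonempty")
    results = []
    for genus in table.counts.columns:
        case = table.counts.loc[case_ids, genus].to_numpy()
        control = table.counts.loc[control_ids, genus].to_numpy()
        w, p = wilcoxon_rank_sum(case, control)
        if p <= p_max:
            results.append(DifferentialResult(
                genus=genus, statistic=w, p_value=p,
                direction=_direction(case, control),
                median_case=float(np.median(case)),
                median_control=float(np.median(control))))
    return results


def pathway_links(differentials: Iterable[DifferentialResult],
                  scores: ScoreMatrix | pd.DataFrame) -> list[DifferentialLink]:
    """One edge per (differential genus, metabolite with positive score)."""
    frame = scores.scores if isinstance(scores, ScoreMatrix) else scores
    links = []
    for res in differentials:
        if res.genus not in frame.index:
            logger.info("differential genus %r absent from the score matrix; "
                        "no edges emitted", res.genus)
            continue
        group = {"case_enriched": "case",
                 "control_enriched": "control"}.get(res.direction, "ambiguous")
        for metabolite in frame.columns:
            weight = float(frame.loc[res.genus, metabolite])
            if weight > 0:
                links.append(DifferentialLink(res.genus, metabolite, group,
                                              weight, res.p_value))
    return sorted(links, key=lambda l: (l.group, l.genus, l.metabolite))


def differentials_to_frame(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    rows = [{"genus": r.genus, "W": r.statistic, "p_value": r.p_value,
             "direction": r.direction, "median_case": r.median_case,
             "median_control": r.median_control}
            for r in sorted(results, key=lambda r: (r.p_value, r.genus))]
    return pd.DataFrame(rows, columns=["genus", "W", "p_value", "direction",
                                       "median_case", "median_control"])


def write_sankey(links: Iterable[DifferentialLink], path) -> None:
    """Write a nodes/links JSON edge list consumable by Sankey renderers
    (e.g. plotly's sankey trace).  Deterministic (group, genus, metabolite)
    order; genus nodes are tagged with their enrichment group."""
    links = sorted(links, key=lambda l: (l.group, l.genus, l.metabolite))
    nodes: list[dict] = []
    index: dict[tuple[str, str], int] = {}

    def node(kind: str, label: str, group: str = "") -> int:
        key = (kind, label if kind == "metabolite" else f"{label}|{group}")
        if key not in index:
            index[key] = len(nodes)
            entry = {"id": index[key], "kind": kind, "label": label}
            if kind == "genus":
                entry["group"] = group
            nodes.append(entry)
        return index[key]

    edges = []
    for l in links:
        edges.append({
            "source": node("genus", l.genus, l.group),
            "target": node("metabolite", l.metabolite),
            "value": l.scorbpeo_weight,
            "p_value": l.p_value,
            "group": l.group,
        })
    doc = {"nodes": nodes, "links": edges}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_sankey(path) -> list[DifferentialLink]:
    """Parse a document written by :func:`write_sankey` back into links."""
    doc = json.loads(Path(path).read_text())
    nodes = {n["id"]: n for n in doc["nodes"]}
    return [DifferentialLink(
        genus=nodes[e["source"]]["label"],
        metabolite=nodes[e["target"]]["label"],
        group=e["group"], scorbpeo_weight=e["value"], p_value=e["p_value"])
        for e in doc["links"]]
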