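"""Cohort-level SCNA statistics.

Region-by-group frequency tables, exact contingency tests (2x2 Fisher and
its Freeman-Halton r x c generalisation, both by minimum-likelihood
enumeration), germline-CNV blacklist filtering, and arm-level SCNA-type
clustering (Ward linkage on Manhattan distances over one-hot types).

Coordinates are 1-based inclusive throughout; overlap means >= 1 shared
base pair unless configured otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom, kendalltau, wilcoxon

from .segmentation import Segment

_REL_TOL = 1.0 + 1e-7  # relative slack for 'as or more extreme' comparisons

# which segment classes satisfy a queried SCNA type
TYPE_MATCH: dict[str, frozenset] = {
    "gain": frozenset({"gain", "amplification"}),
    "amplification": frozenset({"amplification"}),
    "loss": frozenset({"loss"}),
    "cnLOH": frozenset({"cnLOH"}),
    "gain_or_cnloh": frozenset({"gain", "amplification", "cnLOH"}),
    "loss_or_cnloh": frozenset({"loss", "cnLOH"}),
}


@dataclass(frozen=True)
class FisherResult:
    table: tuple
    p_two_sided: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 < self.p_two_sided <= 1.0 + 1e-12:
            raise ValueError("p-value outside (0, 1]")


def fisher_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test for the table [[a, b], [c, d]].

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's (minimum-likelihood rule, the convention of the major
    statistics packages).  A table with an empty margin has p = 1."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return FisherResult(((a, b), (c, d)), 1.0, "hypergeom-enumeration")
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = float(hypergeom.pmf(a, n, c1, r1))
    p = float(pmf[pmf <= p_obs * _REL_TOL].sum())
    return FisherResult(((a, b), (c, d)), min(p, 1.0), "hypergeom-enumeration")


def _log_comb(n, k):
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _table_logprob(row1, col_totals, r1, n):
    lp = -_log_comb(n, r1)
    for aj, cj in zip(row1, col_totals):
        lp += _log_comb(cj, aj)
    return lp


def fisher_rxc(table, max_margin: int = 60, method: str = "exact",
               n_mc: int = 100_000, seed: int = 0) -> FisherResult:
    """Freeman-Halton exact test for a 2 x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of those as or less likely than the observed table.
    Tables with any margin above ``max_margin`` are refused under
    ``method='exact'``; pass ``method='montecarlo'`` to estimate the
    p-value by sampling tables from the margin-conditional distribution.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("fisher_rxc expects a 2 x c table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    col_totals = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    if n == 0 or r1 in (0, n) or (col_totals > 0).sum() < 2:
        return FisherResult(tuple(map(tuple, t)), 1.0, "freeman-halton")
    lp_obs = _table_logprob(t[0], col_totals, r1, n)

    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_mc):
            row1, remaining, left = [], n, r1
            for cj in col_totals[:-1]:
                x = rng.hypergeometric(cj, remaining - cj, left) if left else 0
                row1.append(x)
                remaining -= cj
                left -= x
            row1.append(left)
            if _table_logprob(row1, col_totals, r1, n) <= lp_obs + math.log(_REL_TOL):
                hits += 1
        p = (hits + 1) / (n_mc + 1)
        return FisherResult(tuple(map(tuple, t)), p, "freeman-halton-mc")

    # enumeration ranges over the free cells of row 1, so the column
    # margins (not the row margins) set the cost
    if col_totals.max() > max_margin:
        raise ValueError(
            "table margins too large for complete enumeration; "
            "call fisher_rxc(..., method='montecarlo')")
    p = 0.0
    ranges = [range(0, int(cj) + 1) for cj in col_totals[:-1]]
    for head in itertools.product(*ranges):
        last = r1 - sum(head)
        if not 0 <= last <= col_totals[-1]:
            continue
        row1 = list(head) + [last]
        lp = _table_logprob(row1, col_totals, r1, n)
        if lp <= lp_obs + math.log(_REL_TOL):
            p += math.exp(lp)
    return FisherResult(tuple(map(tuple, t)), min(p, 1.0), "freeman-halton")


# ---------------------------------------------------------------------------
# frequency tables


@dataclass(frozen=True)
class RegionQuery:
    """A genomic region queried for one SCNA type (1-based inclusive)."""

    name: str
    chrom: str
    start: int
    end: int
    scna_type: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.name}: end < start")
        if self.scna_type not in TYPE_MATCH:
            raise ValueError(f"unknown SCNA type {self.scna_type!r}")


@dataclass
class CohortTable:
    region: RegionQuery
    counts: dict  # group -> (affected, total)

    def two_group_table(self, g1: str, g2: str) -> tuple[int, int, int, int]:
        a1, n1 = self.counts[g1]
        a2, n2 = self.counts[g2]
        return a1, n1 - a1, a2, n2 - a2

    def all_group_table(self, order) -> np.ndarray:
        aff = [self.counts[g][0] for g in order]
        una = [self.counts[g][1] - self.counts[g][0] for g in order]
        return np.array([aff, una])


def _overlaps(seg: Segment, region: RegionQuery) -> bool:
    return seg.chrom == region.chrom and seg.start <= region.end and region.start <= seg.end


def build_frequency_table(
    calls_by_sample: dict[str, list[Segment]],
    groups: dict[str, str],
    regions: list[RegionQuery],
) -> list[CohortTable]:
    """Per region and SCNA type, count affected samples per group.

    A sample is affected when any of its segments of a matching class
    overlaps the region by at least one base pair; samples with no calls
    still count in the group totals."""
    missing = set(calls_by_sample) - set(groups)
    if missing:
        raise ValueError(f"samples without a group label: {sorted(missing)[:5]}")
    group_names = sorted(set(groups[s] for s in calls_by_sample))
    tables = []
    for region in regions:
        match = TYPE_MATCH[region.scna_type]
        counts = {g: [0, 0] for g in group_names}
        for sample, segs in calls_by_sample.items():
            g = groups[sample]
            counts[g][1] += 1
            if any(s.scna_class in match and _overlaps(s, region) for s in segs):
                counts[g][0] += 1
        tables.append(CohortTable(region, {g: tuple(v) for g, v in counts.items()}))
    return tables


def cohort_table_tests(table: CohortTable, group_order) -> dict[str, float]:
    """Pairwise 2x2 Fisher p-values for consecutive groups plus the
    Freeman-Halton p across all groups."""
    out = {}
    for g1, g2 in zip(group_order, group_order[1:]):
        out[f"{g1}_vs_{g2}"] = fisher_2x2(*table.two_group_table(g1, g2)).p_two_sided
    out["across_all"] = fisher_rxc(table.all_group_table(group_order)).p_two_sided
    return out


# ---------------------------------------------------------------------------
# blacklist filtering


def filter_cnv_regions(
    regions: list[RegionQuery],
    blacklist: list[tuple[str, int, int]],
) -> tuple[list[RegionQuery], list[tuple[RegionQuery, tuple[str, int, int]]]]:
    """Drop regions overlapping (>= 1 bp) any germline-CNV blacklist
    interval.  Blacklist intervals are 1-based inclusive (BED input is
    converted by the reader).  Returns (kept, removal log)."""
    kept, removed = [], []
    for region in regions:
        hit = next((iv for iv in blacklist
                    if iv[0] == region.chrom
                    and region.start <= iv[2] and iv[1] <= region.end), None)
        if hit is None:
            kept.append(region)
        else:
            removed.append((region, hit))
    return kept, removed


# ---------------------------------------------------------------------------
# arm-level matrix and clustering

ARM_TYPE_PRIORITY = ("amplification", "loss", "gain", "cnLOH")


def arm_level_matrix(
    calls_by_sample: dict[str, list[Segment]],
    arm_defs: pd.DataFrame,
    min_probes: int = 100,
    priority: tuple[str, ...] = ARM_TYPE_PRIORITY,
) -> pd.DataFrame:
    """Sample x arm categorical matrix of SCNA types.

    Only segments with >= ``min_probes`` probes contribute; when several
    SCNA types touch one arm the first in ``priority`` wins (the order is
    a package convention -- the analysis it mirrors does not state one)."""
    if arm_defs is None or arm_defs.empty:
        raise ValueError("arm definition table is required")
    arms = list(arm_defs.itertuples(index=False))
    data = {}
    for sample, segs in calls_by_sample.items():
        row = {}
        for arm in arms:
            types = {
                s.scna_class for s in segs
                if s.n_probes >= min_probes and s.scna_class not in (None, "neutral")
                and s.chrom == arm.chrom and s.start <= arm.end and arm.start <= s.end
            }
            row[arm.arm] = next((t for t in priority if t in types), "none")
        data[sample] = row
    return pd.DataFrame.from_dict(data, orient="index").sort_index()


def hierarchical_cluster(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Ward linkage on Manhattan distances over the one-hot-encoded
    arm-type matrix; returns (linkage, leaf order by sample id)."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    onehot = pd.get_dummies(matrix).astype(float)
    dist = pdist(onehot.to_numpy(), metric="cityblock")
    linkage = hierarchy.linkage(dist, method="ward")
    order = [matrix.index[i] for i in hierarchy.leaves_list(linkage)]
    return linkage, order


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage as a Newick tree (branch lengths from
    merge heights)."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# trend / paired tests (the source analyses name no test for these)


def rank_trend_test(values, group_ordinals) -> tuple[float, float]:
    """Rank-based trend across ordered groups: Kendall tau-b between the
    group ordinal and the value.  Returns (tau, two-sided p)."""
    res = kendalltau(group_ordinals, values)
    return float(res.statistic), float(res.pvalue)


def paired_burden_test(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired per-sample burdens (e.g. SCNA
    counts in invasive vs paired in-situ components)."""
    res = wilcoxon(np.asarray(y, dtype=float), np.asarray(x, dtype=float),
                   alternative=alternative)
    return float(res.statistic), float(res.pvalue)
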