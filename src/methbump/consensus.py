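"""Cross-cohort consensus of significant DMRs and nearest-gene annotation.

A consensus region is a locus where every cohort contributes a significant
region of the same direction (hyper- or hypomethylated) and the common
intersection of the contributed intervals is at least ``min_overlap`` bp wide
(default 2 bp, 1-based inclusive widths).  Consensus is direction-stratified:
a hyper region in one cohort never matches a hypo region in another.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

from intervaltree import IntervalTree

from .io import (
    CandidateRegion,
    CohortRegionRecord,
    ConsensusRegion,
    GeneModel,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusConfig",
    "select_significant",
    "consensus_overlap",
    "count_overlaps",
    "annotate_nearest_gene",
]


@dataclass
class ConsensusConfig:
    min_overlap: int = 2
    alpha: float = 0.05
    require_all: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def select_significant(
    regions: list[CandidateRegion], alpha: float = 0.05
) -> dict[str, list[CandidateRegion]]:
    """Regions with P strictly below alpha, partitioned by direction."""
    out: dict[str, list[CandidateRegion]] = {"hyper": [], "hypo": []}
    for r in regions:
        if not r.scored:
            raise ValidationError(f"region {r.chrom}:{r.start}-{r.end} is unscored")
        if r.p_value < alpha:
            out[r.direction].append(r)
    return out


def _tree_by_chrom(regions: list[CandidateRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        # interval tree is half-open; store [start, end+1) for inclusive ends
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r)
    return trees


def consensus_overlap(
    cohort_regions: dict[str, list[CandidateRegion]],
    config: ConsensusConfig | None = None,
) -> list[ConsensusRegion]:
    """Direction-stratified intersection of significant regions across cohorts.

    A consensus exists where one region per cohort shares a common
    intersection of width >= ``min_overlap``.  If a cohort contributes more
    than one region overlapping the same locus, the larger-area one is used
    and a warning logged.  The result is invariant to cohort ordering.
    """
    from itertools import product

    config = config or ConsensusConfig()
    if len(cohort_regions) < 2:
        raise ValidationError("consensus requires at least two cohorts")
    labels = sorted(cohort_regions)
    out: list[ConsensusRegion] = []
    for direction in ("hyper", "hypo"):
        per_cohort = {
            lab: [r for r in cohort_regions[lab] if r.direction == direction]
            for lab in labels
        }
        anchor = labels[0]
        trees = {lab: _tree_by_chrom(per_cohort[lab]) for lab in labels[1:]}
        for base in sorted(per_cohort[anchor], key=lambda r: (r.chrom, r.start)):
            # candidates per other cohort: regions whose overlap with the anchor
            # alone could still satisfy min_overlap
            cand_lists = []
            for lab in labels[1:]:
                tree = trees[lab].get(base.chrom)
                hits = [
                    iv.data for iv in (tree.overlap(base.start, base.end + 1) if tree else [])
                    if min(base.end, iv.data.end) - max(base.start, iv.data.start) + 1
                    >= config.min_overlap
                ]
                cand_lists.append(hits)
            if not all(cand_lists):
                continue
            # evaluate every combination; keep those whose common intersection
            # is wide enough, then prefer the largest total area
            best = None
            n_valid = 0
            for combo in product(*cand_lists):
                lo = max([base.start] + [r.start for r in combo])
                hi = min([base.end] + [r.end for r in combo])
                if hi - lo + 1 < config.min_overlap:
                    continue
                n_valid += 1
                key = (sum(r.area for r in combo), -lo)
                if best is None or key > best[0]:
                    best = (key, combo, lo, hi)
            if best is None:
                continue
            if n_valid > 1:
                logger.warning(
                    "multiple region combinations overlap consensus locus %s:%d-%d; "
                    "using the largest-area one", base.chrom, best[2], best[3],
                )
            _, combo, lo, hi = best
            chosen = dict(zip(labels[1:], combo))
            chosen[anchor] = base
            out.append(ConsensusRegion(
                chrom=base.chrom,
                intersect_start=lo,
                intersect_end=hi,
                direction=direction,
                cohort_records=[
                    CohortRegionRecord(
                        lab, chosen[lab].chrom, chosen[lab].start,
                        chosen[lab].end, chosen[lab].avg_delta_m,
                    )
                    for lab in labels
                ],
            ))
    out.sort(key=lambda c: (c.chrom, c.intersect_start))
    return out


def count_overlaps(
    cohort_regions: dict[str, list[CandidateRegion]],
    config: ConsensusConfig | None = None,
) -> dict:
    """Per-pair and all-cohort overlap counts, stratified by direction."""
    config = config or ConsensusConfig()
    labels = sorted(cohort_regions)
    summary: dict = {"pairs": {}, "all": {}}
    for a, b in combinations(labels, 2):
        pair = consensus_overlap({a: cohort_regions[a], b: cohort_regions[b]}, config)
        summary["pairs"][(a, b)] = {
            d: sum(1 for c in pair if c.direction == d) for d in ("hyper", "hypo")
        }
    full = consensus_overlap(cohort_regions, config)
    summary["all"] = {
        d: sum(1 for c in full if c.direction == d) for d in ("hyper", "hypo")
    }
    summary["all"]["total"] = len(full)
    return summary


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Unstranded distance in bp between 1-based inclusive intervals.

    0 when overlapping; otherwise the coordinate difference between the
    nearest ends (adjacent intervals are 1 bp apart), matching the usual
    nearest-feature convention.
    """
    if a_end >= b_start and b_end >= a_start:
        return 0
    if a_end < b_start:
        return b_start - a_end
    return a_start - b_end


def annotate_nearest_gene(
    regions: list[ConsensusRegion], genes: list[GeneModel]
) -> list[ConsensusRegion]:
    """Annotate each consensus region with its nearest gene and gap distance.

    Distance is 0 when region and gene overlap; ties are broken by smaller
    gene start, then name.  Regions on chromosomes with no gene get
    nearest_gene='none' and NaN distance.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.name))
    for r in regions:
        cands = by_chrom.get(r.chrom, [])
        if not cands:
            r.nearest_gene = "none"
            r.gene_distance = math.nan
            continue
        best = min(
            cands,
            key=lambda g: (
                _gap(r.intersect_start, r.intersect_end, g.start, g.end),
                g.start,
                g.name,
            ),
        )
        r.nearest_gene = best.name
        r.gene_distance = float(
            _gap(r.intersect_start, r.intersect_end, best.start, best.end)
        )
    return regions
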