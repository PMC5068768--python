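"""End-to-end orchestration: filter each cohort, bump-hunt, then consensus.

These helpers tie the per-module operations together the way the study
workflow runs them; the CLI is a thin wrapper over this module.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

from .bumphunt import BumpHunterConfig, BumpHunterResult, run_bumphunter
from .consensus import (
    ConsensusConfig,
    annotate_nearest_gene,
    consensus_overlap,
    count_overlaps,
    select_significant,
)
from .filters import FilterConfig, FilterReport, run_filter_stack
from .io import (
    ConsensusRegion,
    DetectionPMatrix,
    GeneModel,
    MethylMatrix,
    ProbeManifest,
    SampleSheet,
)
from .simulate import StudySim

logger = logging.getLogger(__name__)

__all__ = ["CohortResult", "StudyResult", "run_cohort", "run_study", "build_run_manifest"]

VERSION = "0.1.0"


@dataclass
class CohortResult:
    label: str
    bumphunt: BumpHunterResult
    filter_report: FilterReport


@dataclass
class StudyResult:
    cohorts: list[CohortResult]
    consensus: list[ConsensusRegion]
    overlap_counts: dict

    def cohort(self, label: str) -> CohortResult:
        return next(c for c in self.cohorts if c.label == label)


def run_cohort(
    label: str,
    betas: MethylMatrix,
    detp: DetectionPMatrix | None,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    filter_config: FilterConfig,
    bump_config: BumpHunterConfig,
) -> CohortResult:
    """Filter stack then bump hunting for one cohort."""
    filtered, fmanifest, report = run_filter_stack(betas, detp, manifest, filter_config)
    result = run_bumphunter(filtered, None, fmanifest, sheet, bump_config)
    return CohortResult(label, result, report)


def run_study(
    study: StudySim,
    filter_config: FilterConfig | None = None,
    bump_config: BumpHunterConfig | None = None,
    consensus_config: ConsensusConfig | None = None,
    genes: list[GeneModel] | None = None,
    celltype_mask: bool = True,
) -> StudyResult:
    """Run the whole multi-cohort workflow on a simulated (or loaded) study.

    ``celltype_mask`` controls whether the cell-type-marker probe list is
    excluded (the default) or retained (the cell-composition sensitivity
    mode).
    """
    bump_config = bump_config or BumpHunterConfig()
    consensus_config = consensus_config or ConsensusConfig(alpha=bump_config.alpha)
    if filter_config is None:
        lists = {"celltype": study.celltype_probes} if celltype_mask else {}
        filter_config = FilterConfig(exclusion_lists=lists)

    cohort_results = []
    per_cohort_sig: dict[str, list] = {}
    for cohort in study.cohorts:
        res = run_cohort(
            cohort.label, cohort.betas, cohort.detp, study.manifest,
            cohort.sheet, filter_config, bump_config,
        )
        cohort_results.append(res)
        sig = select_significant(res.bumphunt.regions, consensus_config.alpha)
        per_cohort_sig[cohort.label] = sig["hyper"] + sig["hypo"]
        logger.info("%s: %s", cohort.label, res.bumphunt.summary())

    consensus = consensus_overlap(per_cohort_sig, consensus_config)
    counts = count_overlaps(per_cohort_sig, consensus_config)
    if genes:
        consensus = annotate_nearest_gene(consensus, genes)
    return StudyResult(cohort_results, consensus, counts)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def build_run_manifest(
    seed: int,
    config: dict,
    input_paths: list[str | Path] | None = None,
    counts: dict | None = None,
    cutoffs: dict | None = None,
) -> dict:
    """Provenance record: config snapshot, input digests, seed and stage counts."""
    return {
        "tool_version": VERSION,
        "seed": seed,
        "config": config,
        "inputs": {str(p): _digest(Path(p)) for p in (input_paths or [])},
        "counts": counts or {},
        "cutoffs": cutoffs or {},
    }


def write_run_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
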