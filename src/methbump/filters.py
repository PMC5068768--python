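"""Probe-exclusion stages applied before DMR detection.

Four stages, applied in a fixed order: (1) detection-P — drop any probe whose
signal is indistinguishable from background (P > threshold) in at least one
sample; (2) SNP probes — drop probes with an annotated SNP at the single-base
extension (offset 0) or the CpG dinucleotide itself (offsets 1-2); (3) sex
chromosomes — drop chrX/chrY probes; (4) named exclusion lists, e.g. probes
that are cell-type-specific methylation marks in brain and would otherwise
confound a case-control comparison with different neuronal proportions.

The final probe set is order-insensitive (removals are set unions); the
per-stage counts in :class:`FilterReport` use sequential semantics, i.e. each
stage is counted on the set surviving the previous stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import (
    DetectionPMatrix,
    MethylMatrix,
    ProbeManifest,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_detection",
    "filter_snp_probes",
    "filter_sex_chromosomes",
    "mask_probe_list",
    "run_filter_stack",
]


@dataclass
class FilterConfig:
    """Parameters of the probe-exclusion stack."""

    detection_p_threshold: float = 0.05
    snp_offset_window: frozenset[int] = frozenset({0, 1, 2})
    drop_sex_chromosomes: bool = True
    #: name -> list of probe ids (e.g. {"celltype": [...]})
    exclusion_lists: dict[str, list[str]] = field(default_factory=dict)
    #: disables the detection-P stage when no detection matrix is supplied
    apply_detection: bool = True
    apply_snp: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.detection_p_threshold < 1:
            raise ValueError("detection_p_threshold must be in (0, 1)")
        self.snp_offset_window = frozenset(self.snp_offset_window)


@dataclass
class FilterReport:
    """Ordered per-stage removal counts and the final probe tally."""

    n_input: int
    stages: list[tuple[str, int]] = field(default_factory=list)
    n_output: int = 0

    def add(self, name: str, n_removed: int) -> None:
        self.stages.append((name, n_removed))

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.stages)

    def check(self) -> None:
        if self.n_input - self.total_removed != self.n_output:
            raise AssertionError(
                f"filter accounting broken: {self.n_input} - {self.total_removed} "
                f"!= {self.n_output}"
            )

    def to_lines(self) -> list[str]:
        lines = [f"input probes: {self.n_input}"]
        lines += [f"removed ({name}): {n}" for name, n in self.stages]
        lines.append(f"remaining probes: {self.n_output}")
        return lines


def filter_detection(
    matrix: MethylMatrix, detp: DetectionPMatrix, threshold: float = 0.05
) -> tuple[MethylMatrix, list[str]]:
    """Drop probes with detection P strictly above ``threshold`` in any sample."""
    if not matrix.probe_ids.equals(detp.probe_ids):
        raise ValidationError("methylation and detection-P matrices are misaligned")
    fail = (detp.values.to_numpy() > threshold).any(axis=1)
    removed = matrix.probe_ids[fail].tolist()
    kept = matrix.probe_ids[~fail]
    return matrix.subset(kept), removed


def filter_snp_probes(
    manifest: ProbeManifest, window: frozenset[int] = frozenset({0, 1, 2})
) -> tuple[ProbeManifest, list[str]]:
    """Drop probes whose annotated SNP offsets intersect ``window``."""
    window = frozenset(window)
    hit = manifest.df["snp_offsets"].map(lambda s: bool(s & window))
    removed = manifest.df.index[hit].tolist()
    return ProbeManifest(manifest.df.loc[~hit].copy()), removed


def filter_sex_chromosomes(manifest: ProbeManifest) -> tuple[ProbeManifest, list[str]]:
    """Drop all probes on chrX/chrY (labels 'X'/'Y' are normalised on read)."""
    sexual = manifest.df["chrom"].isin(["chrX", "chrY"])
    removed = manifest.df.index[sexual].tolist()
    return ProbeManifest(manifest.df.loc[~sexual].copy()), removed


def mask_probe_list(
    matrix: MethylMatrix, list_name: str, probe_ids: list[str]
) -> tuple[MethylMatrix, list[str]]:
    """Remove the named probe list from the matrix; unknown ids are ignored."""
    wanted = set(probe_ids)
    present = [p for p in matrix.probe_ids if p in wanted]
    unknown = len(wanted) - len(present)
    if unknown:
        logger.warning(
            "exclusion list %r: %d ids not present in matrix (ignored)",
            list_name, unknown,
        )
    kept = matrix.probe_ids[~matrix.probe_ids.isin(present)]
    return matrix.subset(kept), present


def run_filter_stack(
    matrix: MethylMatrix,
    detp: DetectionPMatrix | None,
    manifest: ProbeManifest,
    config: FilterConfig,
) -> tuple[MethylMatrix, ProbeManifest, FilterReport]:
    """Apply all configured exclusion stages and return aligned survivors.

    Stage order: detection-P, SNP offsets, sex chromosomes, then each named
    exclusion list.  Raises if no probes survive.
    """
    if not matrix.probe_ids.equals(manifest.probe_ids):
        raise ValidationError("methylation matrix and manifest are misaligned")
    report = FilterReport(n_input=len(matrix.probe_ids))

    if config.apply_detection and detp is not None:
        matrix, removed = filter_detection(matrix, detp, config.detection_p_threshold)
        manifest = manifest.subset(matrix.probe_ids)
        report.add("detection_p", len(removed))

    if config.apply_snp:
        manifest, removed = filter_snp_probes(manifest, config.snp_offset_window)
        matrix = matrix.subset(manifest.probe_ids)
        report.add("snp_offsets", len(removed))

    if config.drop_sex_chromosomes:
        manifest, removed = filter_sex_chromosomes(manifest)
        matrix = matrix.subset(manifest.probe_ids)
        report.add("sex_chromosomes", len(removed))

    for name, ids in config.exclusion_lists.items():
        matrix, removed = mask_probe_list(matrix, name, ids)
        manifest = manifest.subset(matrix.probe_ids)
        report.add(name, len(removed))

    report.n_output = len(matrix.probe_ids)
    report.check()
    if report.n_output == 0:
        raise ValidationError("no probes remain after filtering")
    for line in report.to_lines():
        logger.info(line)
    return matrix, manifest, report
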