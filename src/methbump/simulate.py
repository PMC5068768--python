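"""Synthetic multi-cohort 450K-like studies with known planted ground truth.

The generator emulates the statistical structure the analysis assumes: probes
laid out in tight clusters (within-cluster gaps far below ``maxgap``, clusters
separated by much more), per-probe baseline methylation drawn from a bimodal
unmethylated/intermediate/methylated mixture on the M scale, planted
case-control DMRs of fixed M-value effect size shared across cohorts (plus
cohort-private ones), global sex/age/PMI covariate effects, and probe-level
Gaussian noise.  A fraction of probes is planted to fail each exclusion stage
(detection P, SNP offsets, sex chromosomes, cell-type list); planted DMR
probes are kept clear of those so the ground truth survives filtering.

Betas are produced by the inverse logit of the simulated M-values, matching
the transform the pipeline applies on the way back in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import (
    DetectionPMatrix,
    MethylMatrix,
    ProbeManifest,
    SampleSheet,
    m_to_beta,
)

__all__ = [
    "SimConfig",
    "PlantedDMR",
    "SimTruth",
    "CohortSim",
    "StudySim",
    "simulate_manifest",
    "simulate_cohort",
    "simulate_study",
]

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the three-cohort post-mortem prefrontal-cortex design:
    case/control sizes 24/24, 20/23 and 18/15, with 5 shared hypermethylated
    and 2 shared hypomethylated DMRs planted at dM = 0.7.
    """

    n_cohorts: int = 3
    cohort_sizes: tuple[tuple[int, int], ...] = ((24, 24), (20, 23), (18, 15))
    n_clusters: int = 250
    probes_per_cluster: tuple[int, int] = (5, 11)       # uniform inclusive
    within_gap: tuple[int, int] = (20, 400)             # bp, uniform
    between_gap: int = 5000                             # bp between clusters
    baseline_levels: tuple[float, ...] = (-3.0, 0.0, 3.0)
    baseline_weights: tuple[float, ...] = (0.45, 0.10, 0.45)
    noise_sd: float = 0.5                               # M units
    n_shared_hyper: int = 5
    n_shared_hypo: int = 2
    n_private_per_cohort: int = 2
    effect_size: float = 0.7                            # |dM| of planted DMRs
    dmr_probes: tuple[int, int] = (4, 10)               # uniform inclusive
    sex_shift: float = 0.2                              # M shift for males
    age_slope: float = 0.01                             # M units per year
    pmi_slope: float = 0.005                            # M units per hour
    frac_detection_fail: float = 0.01
    frac_snp: float = 0.02
    frac_sex_chrom: float = 0.02
    frac_celltype: float = 0.01
    cohort_shift: float = 0.0                           # global batch offset

    def __post_init__(self) -> None:
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ValueError("cohort_sizes must list one (cases, controls) per cohort")
        for nc, nk in self.cohort_sizes:
            if nc < 2 or nk < 2:
                raise ValueError("need >=2 cases and >=2 controls per cohort")
        if abs(sum(self.baseline_weights) - 1.0) > 1e-9:
            raise ValueError("baseline_weights must sum to 1")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass(frozen=True)
class PlantedDMR:
    """One planted differentially methylated region."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    direction: str          # hyper / hypo
    delta_m: float          # signed effect
    cluster_id: int
    shared: bool            # shared across cohorts vs cohort-private


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic study."""

    shared_dmrs: list[PlantedDMR]
    private_dmrs: dict[str, list[PlantedDMR]]
    detection_fail_probes: list[str]
    snp_probes: list[str]
    sexchrom_probes: list[str]
    celltype_probes: list[str]
    covariates: dict[str, float]

    def shared_by_direction(self, direction: str) -> list[PlantedDMR]:
        return [d for d in self.shared_dmrs if d.direction == direction]

    def to_dict(self) -> dict:
        return {
            "shared_dmrs": [asdict(d) for d in self.shared_dmrs],
            "private_dmrs": {
                k: [asdict(d) for d in v] for k, v in self.private_dmrs.items()
            },
            "detection_fail_probes": self.detection_fail_probes,
            "snp_probes": self.snp_probes,
            "sexchrom_probes": self.sexchrom_probes,
            "celltype_probes": self.celltype_probes,
            "covariates": self.covariates,
        }


@dataclass
class CohortSim:
    label: str
    betas: MethylMatrix
    detp: DetectionPMatrix
    sheet: SampleSheet


@dataclass
class StudySim:
    manifest: ProbeManifest
    truth: SimTruth
    cohorts: list[CohortSim]

    @property
    def celltype_probes(self) -> list[str]:
        return self.truth.celltype_probes


# ---------------------------------------------------------------------------
# manifest + truth
# ---------------------------------------------------------------------------

def simulate_manifest(
    config: SimConfig, seed: int
) -> tuple[ProbeManifest, SimTruth]:
    """Generate a sorted probe manifest plus the planted ground truth.

    Cluster geometry guarantees that ``cluster_probes`` at the default maxgap
    recovers exactly the generated clusters: within-cluster gaps are drawn
    from ``within_gap`` (max 400 bp by default) and clusters are separated by
    ``between_gap`` (5 kb), which also keeps them apart at maxgap 1000.
    """
    rng = np.random.default_rng(seed)
    lo_p, hi_p = config.probes_per_cluster
    sizes = rng.integers(lo_p, hi_p + 1, size=config.n_clusters)

    # chromosome per cluster: sex chromosomes at the configured probe fraction
    chroms = []
    for i in range(config.n_clusters):
        if rng.random() < config.frac_sex_chrom:
            chroms.append("chrX" if rng.random() < 0.5 else "chrY")
        else:
            chroms.append(_AUTOSOMES[i % len(_AUTOSOMES)])

    rows = []
    next_pos: dict[str, int] = {}
    cluster_probe_ids: list[list[str]] = []
    probe_counter = 0
    for cid in range(config.n_clusters):
        chrom = chroms[cid]
        pos = next_pos.get(chrom, 10_000) + config.between_gap
        ids_here = []
        for _ in range(sizes[cid]):
            pid = f"cg{probe_counter:07d}"
            probe_counter += 1
            rows.append((pid, chrom, pos))
            ids_here.append(pid)
            pos += int(rng.integers(config.within_gap[0], config.within_gap[1] + 1))
        next_pos[chrom] = pos
        cluster_probe_ids.append(ids_here)

    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"]).set_index("probe_id")
    df["snp_offsets"] = [frozenset()] * len(df)

    # ---- plant DMRs in distinct autosomal clusters --------------------------
    eligible = [
        cid for cid in range(config.n_clusters)
        if chroms[cid] in _AUTOSOMES and sizes[cid] >= config.dmr_probes[0]
    ]
    n_private = config.n_private_per_cohort * config.n_cohorts
    n_needed = config.n_shared_hyper + config.n_shared_hypo + n_private
    if len(eligible) < n_needed:
        raise ValueError(
            f"only {len(eligible)} eligible clusters for {n_needed} planted DMRs"
        )
    chosen = rng.choice(eligible, size=n_needed, replace=False)

    def plant(cid: int, direction: str) -> PlantedDMR:
        ids = cluster_probe_ids[cid]
        span = int(rng.integers(config.dmr_probes[0],
                                min(config.dmr_probes[1], len(ids)) + 1))
        offset = int(rng.integers(0, len(ids) - span + 1))
        run = ids[offset:offset + span]
        positions = df.loc[run, "pos"]
        sign = 1.0 if direction == "hyper" else -1.0
        return PlantedDMR(
            chrom=chroms[cid], start=int(positions.min()), end=int(positions.max()),
            probe_ids=tuple(run), direction=direction,
            delta_m=sign * config.effect_size, cluster_id=cid, shared=True,
        )

    shared = []
    k = 0
    for _ in range(config.n_shared_hyper):
        shared.append(plant(int(chosen[k]), "hyper")); k += 1
    for _ in range(config.n_shared_hypo):
        shared.append(plant(int(chosen[k]), "hypo")); k += 1
    private: dict[str, list[PlantedDMR]] = {}
    for c in range(config.n_cohorts):
        label = f"cohort{c + 1}"
        mine = []
        for _ in range(config.n_private_per_cohort):
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            d = plant(int(chosen[k]), direction); k += 1
            mine.append(PlantedDMR(**{**asdict(d), "shared": False,
                                      "probe_ids": d.probe_ids}))
        private[label] = mine

    planted_ids = {p for d in shared for p in d.probe_ids}
    for lst in private.values():
        planted_ids |= {p for d in lst for p in d.probe_ids}

    # ---- filter-failure planting (never on planted DMR probes) -------------
    free = np.array([pid for pid in df.index if pid not in planted_ids])
    rng.shuffle(free)
    n_free = len(free)
    n_snp = int(round(config.frac_snp * n_free))
    n_fail = int(round(config.frac_detection_fail * n_free))
    n_cell = int(round(config.frac_celltype * n_free))
    snp_probes = free[:n_snp].tolist()
    fail_probes = free[n_snp:n_snp + n_fail].tolist()
    cell_probes = free[n_snp + n_fail:n_snp + n_fail + n_cell].tolist()
    for pid in snp_probes:
        df.at[pid, "snp_offsets"] = frozenset({int(rng.integers(0, 3))})
    sexchrom_probes = df.index[df["chrom"].isin(["chrX", "chrY"])].tolist()

    manifest = ProbeManifest(df).sort()
    truth = SimTruth(
        shared_dmrs=shared,
        private_dmrs=private,
        detection_fail_probes=fail_probes,
        snp_probes=snp_probes,
        sexchrom_probes=sexchrom_probes,
        celltype_probes=cell_probes,
        covariates={
            "sex_shift": config.sex_shift,
            "age_slope": config.age_slope,
            "pmi_slope": config.pmi_slope,
        },
    )
    return manifest, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    manifest: ProbeManifest,
    n_case: int,
    n_control: int,
    truth: SimTruth,
    config: SimConfig,
    seed: int,
    label: str = "cohort1",
) -> CohortSim:
    """Simulate one cohort's beta matrix, detection-P matrix and sample sheet.

    M-values are baseline + planted group effect + covariate effects + noise;
    betas are their inverse logit.  Group effects appear only inside the
    planted intervals (shared DMRs plus this cohort's private ones).
    """
    rng = np.random.default_rng(seed)
    probes = manifest.probe_ids
    n = n_case + n_control

    sample_ids = [f"{label}_s{i:02d}" for i in range(n)]
    group = np.array(["case"] * n_case + ["control"] * n_control)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    age = rng.uniform(30, 90, n)
    pmi = rng.uniform(5, 40, n)
    sheet = SampleSheet(pd.DataFrame(
        {"group": group, "sex": sex, "age": age, "pmi": pmi},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    baseline = rng.choice(
        config.baseline_levels, size=len(probes), p=config.baseline_weights
    )
    effect = pd.Series(0.0, index=probes)
    planted = list(truth.shared_dmrs) + list(truth.private_dmrs.get(label, []))
    for d in planted:
        effect.loc[list(d.probe_ids)] = d.delta_m

    is_case = (group == "case").astype(float)
    is_male = (sex == "M").astype(float)
    M = (
        baseline[:, None]
        + np.outer(effect.to_numpy(), is_case)
        + config.sex_shift * is_male[None, :]
        + config.age_slope * (age - 60.0)[None, :]
        + config.pmi_slope * (pmi - 22.5)[None, :]
        + config.cohort_shift
    )
    if config.noise_sd > 0:
        M = M + rng.normal(0.0, config.noise_sd, M.shape)

    betas = MethylMatrix(
        pd.DataFrame(m_to_beta(M), index=probes, columns=sample_ids), "beta"
    )

    detp_vals = rng.uniform(0.0, 0.01, (len(probes), n))
    fail = probes.isin(truth.detection_fail_probes)
    detp_vals[fail] = rng.uniform(
        np.nextafter(0.05, 1.0), 1.0, (int(fail.sum()), n)
    )
    detp = DetectionPMatrix(pd.DataFrame(detp_vals, index=probes, columns=sample_ids))
    return CohortSim(label, betas, detp, sheet)


def simulate_study(config: SimConfig | None = None, seed: int = 0) -> StudySim:
    """Simulate the full multi-cohort study: one shared manifest, one truth,
    and per-cohort matrices.  Deterministic under the seed."""
    config = config or SimConfig()
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(config.n_cohorts + 1) % (2**31)
    manifest, truth = simulate_manifest(config, int(child[0]))
    cohorts = []
    for c, (n_case, n_control) in enumerate(config.cohort_sizes):
        label = f"cohort{c + 1}"
        cohorts.append(simulate_cohort(
            manifest, n_case, n_control, truth, config,
            seed=int(child[c + 1]), label=label,
        ))
    return StudySim(manifest, truth, cohorts)
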