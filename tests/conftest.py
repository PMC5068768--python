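import numpy as np
import pandas as pd
import pytest

from methbump import (
    DetectionPMatrix,
    MethylMatrix,
    ProbeManifest,
    SampleSheet,
    SimConfig,
    simulate_study,
)


def make_manifest(positions, chrom="chr1", snp_offsets=None, prefix="cg"):
    """Build a small sorted manifest from a list of positions."""
    if isinstance(chrom, str):
        chrom = [chrom] * len(positions)
    offsets = snp_offsets or [frozenset()] * len(positions)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "snp_offsets": [frozenset(o) for o in offsets],
    }, index=pd.Index([f"{prefix}{i:04d}" for i in range(len(positions))],
                      name="probe_id"))
    return ProbeManifest(df)


def make_sheet(n_case, n_control, sex=None, age=None, pmi=None, prefix="s"):
    n = n_case + n_control
    rng = np.random.default_rng(n)  # deterministic, and not collinear covariates
    df = pd.DataFrame({
        "group": ["case"] * n_case + ["control"] * n_control,
        "sex": sex if sex is not None else ["M", "F"] * (n // 2) + ["M"] * (n % 2),
        "age": age if age is not None else rng.uniform(30, 90, n).round(1),
        "pmi": pmi if pmi is not None else rng.uniform(5, 40, n).round(1),
    }, index=pd.Index([f"{prefix}{i:02d}" for i in range(n)], name="sample_id"))
    return SampleSheet(df)


def make_m_matrix(values, sample_ids=None, prefix="cg"):
    values = np.asarray(values, float)
    cols = sample_ids or [f"s{i:02d}" for i in range(values.shape[1])]
    df = pd.DataFrame(values,
                      index=pd.Index([f"{prefix}{i:04d}" for i in range(values.shape[0])],
                                     name="probe_id"),
                      columns=cols)
    return MethylMatrix(df, "M")


def consensus_hits(truth, consensus_regions):
    """(n planted shared DMRs recovered, n unexplained consensus regions)."""
    planted = {(d.direction, d.chrom, d.start, d.end) for d in truth.shared_dmrs}
    hits, extra = set(), 0
    for c in consensus_regions:
        match = [p for p in planted
                 if p[0] == c.direction and p[1] == c.chrom
                 and not (c.intersect_end < p[2] or c.intersect_start > p[3])]
        if match:
            hits.add(match[0])
        else:
            extra += 1
    return len(hits), extra


@pytest.fixture(scope="session")
def small_study():
    """A compact 2-cohort study for fast end-to-end tests."""
    cfg = SimConfig(
        n_cohorts=2, cohort_sizes=((10, 10), (8, 9)), n_clusters=60,
        n_shared_hyper=2, n_shared_hypo=1, n_private_per_cohort=1,
    )
    return simulate_study(cfg, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """One default-condition 3-cohort study (2000-probe scale)."""
    return simulate_study(seed=11)
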