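"""Bump-hunting core: clusters, effects, smoothing, bootstrap null, regions.

The procedure, per cohort:

1. Probes are grouped into clusters so that neighbouring probes in a cluster
   are at most ``maxgap`` bp apart (default 500 bp).
2. For each probe, the case-control difference in mean M-value (dM) is
   estimated by OLS, adjusting for sex, age and post-mortem interval where
   available.
3. The per-probe estimates are smoothed within clusters with running medians.
4. An empirical null is built from ``n_boot`` bootstrap samples: residuals
   from the no-group (null) model are resampled over samples with
   replacement, added back to the null fit, and the full model re-fit and
   smoothed.  The cutoff is the ``cutoff_quantile`` of the pooled absolute
   smoothed null statistics.
5. Candidate regions are maximal within-cluster runs of probes whose smoothed
   dM exceeds +cutoff (hyper) or falls below -cutoff (hypo).
6. Each region is scored by its area (sum of |smoothed dM|): the region
   P-value is the fraction of null regions (pooled over bootstraps) with at
   least that area, the FWER is the fraction of bootstraps whose maximum null
   region area reaches it, and FDR is the Benjamini-Hochberg adjustment of
   the region P-values.

Everything downstream of the seed is deterministic; the bootstrap statistic
is computed through the linear-estimator identity (the OLS group coefficient
is linear in the response), which is exactly equivalent to re-fitting the
full design on each resampled matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .filters import filter_detection
from .io import (
    CandidateRegion,
    DetectionPMatrix,
    MethylMatrix,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BumpHunterConfig",
    "Design",
    "EffectProfile",
    "NullDistribution",
    "BumpHunterResult",
    "cluster_probes",
    "build_design",
    "fit_probe_effects",
    "smooth_effects",
    "running_median",
    "bootstrap_null",
    "pick_cutoff",
    "find_candidate_regions",
    "score_regions",
    "run_bumphunter",
]


@dataclass
class BumpHunterConfig:
    """Tunables of the region-calling procedure.

    maxgap
        Maximum within-cluster gap between neighbouring probes, bp.
    cutoff_quantile
        Quantile of the pooled absolute smoothed null statistics used as the
        region-calling cutoff (0.95 default; 0.975 in sensitivity mode).
    n_boot
        Number of bootstrap samples for the empirical null.
    smooth_k
        Odd running-median window size (probes).
    """

    maxgap: int = 500
    cutoff_quantile: float = 0.95
    n_boot: int = 1000
    smooth_k: int = 5
    min_probes_per_region: int = 1
    seed: int = 0
    alpha: float = 0.05
    fwer_alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.maxgap < 1:
            raise ValueError("maxgap must be >= 1")
        if not 0 < self.cutoff_quantile < 1:
            raise ValueError("cutoff_quantile must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.smooth_k < 1 or self.smooth_k % 2 == 0:
            raise ValueError("smooth_k must be odd and >= 1")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_probes(manifest: ProbeManifest, maxgap: int) -> np.ndarray:
    """Greedy left-to-right cluster assignment over a sorted manifest.

    A new cluster starts whenever the chromosome changes or the gap to the
    previous probe exceeds ``maxgap``.  Returns an int array of cluster ids
    aligned to the manifest rows.
    """
    if not manifest.is_sorted():
        raise ValidationError("manifest must be sorted by (chrom, pos) before clustering")
    chrom = manifest.df["chrom"].to_numpy()
    pos = manifest.df["pos"].to_numpy()
    if len(pos) == 0:
        return np.zeros(0, dtype=int)
    new = np.ones(len(pos), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    close = (pos[1:] - pos[:-1]) <= maxgap
    new[1:] = ~(same_chrom & close)
    return np.cumsum(new) - 1


# ---------------------------------------------------------------------------
# design and per-probe effects
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """An OLS design: n x p matrix, column names, and the group column index."""

    matrix: np.ndarray
    columns: list[str]
    sample_ids: pd.Index
    dropped: list[str] = field(default_factory=list)

    @property
    def group_index(self) -> int:
        return self.columns.index("group")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_design(sheet: SampleSheet) -> Design:
    """Build the covariate-adjusted design from a sample sheet.

    Columns: intercept, group (case=1), sex (M=1), centred age, centred PMI.
    A covariate with any missing value, or one that is constant, is dropped
    with a warning — adjustment uses covariates "when available".  Collinear
    designs (e.g. group perfectly confounded with sex) raise an error naming
    the dependency.
    """
    df = sheet.df
    if sheet.n_cases < 2 or sheet.n_controls < 2:
        raise ValidationError(
            f"need >=2 cases and >=2 controls, got {sheet.n_cases}/{sheet.n_controls}"
        )
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(df)),
        "group": (df["group"] == "case").to_numpy(float),
    }
    dropped: list[str] = []

    def covariate(name: str, values: np.ndarray) -> None:
        if np.isnan(values).any():
            dropped.append(name)
            logger.warning("covariate %r has missing values; dropped from design", name)
            return
        if np.ptp(values) == 0:
            dropped.append(name)
            logger.warning("covariate %r is constant; dropped from design", name)
            return
        cols[name] = values

    sex_raw = df["sex"]
    sex = np.where(sex_raw.isna(), np.nan, (sex_raw == "M").astype(float))
    covariate("sex", sex.astype(float))
    age = df["age"].to_numpy(float)
    covariate("age", age - np.nanmean(age) if not np.isnan(age).any() else age)
    pmi = df["pmi"].to_numpy(float)
    covariate("pmi", pmi - np.nanmean(pmi) if not np.isnan(pmi).any() else pmi)

    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pin down which columns are linearly dependent on the rest
        dependent = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                dependent.append(names[j])
        raise ValidationError(
            f"collinear design: column(s) {dependent} are linear combinations of the others"
        )
    return Design(X, names, df.index, dropped)


@dataclass
class EffectProfile:
    """Per-probe raw and smoothed case-control M-value differences."""

    probe_ids: pd.Index
    raw: np.ndarray
    smoothed: np.ndarray | None = None
    design_columns: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.raw)


def fit_probe_effects(matrix: MethylMatrix, design: Design) -> EffectProfile:
    """Per-probe OLS on M-values; dM is the group-indicator coefficient."""
    if matrix.scale != "M":
        raise ValidationError("fit_probe_effects expects an M-scale matrix")
    if not matrix.sample_ids.equals(design.sample_ids):
        raise ValidationError("matrix samples and design rows are misaligned")
    X = design.matrix
    if X.shape[0] < X.shape[1]:
        raise ValidationError(
            f"{X.shape[0]} samples cannot identify {X.shape[1]} design columns"
        )
    Y = matrix.values.to_numpy()  # probes x samples
    pinv = np.linalg.pinv(X)  # p x n
    coefs = Y @ pinv.T  # probes x p
    raw = coefs[:, design.group_index]
    return EffectProfile(matrix.probe_ids, raw, None, list(design.columns))


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def running_median(rows: np.ndarray, k: int) -> np.ndarray:
    """Row-wise running median with windows truncated at the ends.

    ``rows`` is (B, m); at index i the window is the intersection of
    [i-(k-1)/2, i+(k-1)/2] with [0, m).  Rows shorter than ``k`` are
    returned unchanged (the caller's below-window rule).
    """
    B, m = rows.shape
    if m < k or k == 1:
        return rows.copy()
    half = (k - 1) // 2
    padded = np.full((B, m + 2 * half), np.nan)
    padded[:, half:half + m] = rows
    windows = np.lib.stride_tricks.sliding_window_view(padded, k, axis=1)
    return np.nanmedian(windows, axis=2)


def _cluster_segments(clusters: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs, half-open, of each cluster run."""
    if len(clusters) == 0:
        return []
    breaks = np.flatnonzero(np.diff(clusters)) + 1
    starts = np.r_[0, breaks]
    stops = np.r_[breaks, len(clusters)]
    return list(zip(starts.tolist(), stops.tolist()))


def smooth_effects(
    profile: EffectProfile, clusters: np.ndarray, k: int
) -> EffectProfile:
    """Running-median smoothing of raw effects within each cluster."""
    if k % 2 == 0:
        raise ValueError("smoothing window k must be odd")
    if len(clusters) != len(profile):
        raise ValidationError("cluster assignment and profile lengths differ")
    raw = profile.raw
    smoothed = raw.copy()
    for start, stop in _cluster_segments(clusters):
        if stop - start >= k:
            smoothed[start:stop] = running_median(raw[None, start:stop], k)[0]
    return EffectProfile(profile.probe_ids, raw, smoothed, profile.design_columns)


def _smooth_rows(rows: np.ndarray, clusters: np.ndarray, k: int) -> np.ndarray:
    """Smooth many profiles at once (rows: B x P), cluster-wise."""
    out = rows.copy()
    for start, stop in _cluster_segments(clusters):
        if stop - start >= k:
            out[:, start:stop] = running_median(rows[:, start:stop], k)
    return out


# ---------------------------------------------------------------------------
# bootstrap empirical null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Smoothed null statistics from the residual bootstrap.

    ``smoothed`` holds one smoothed null dM profile per bootstrap (B x P);
    the pooled absolute values drive cutoff selection.  After a cutoff is
    chosen, :meth:`scan_regions` fills the per-bootstrap null region areas
    and their per-bootstrap maxima (0 when a bootstrap yields no region).
    """

    smoothed: np.ndarray
    B: int
    seed: int
    null_areas: list[np.ndarray] | None = None
    boot_max: np.ndarray | None = None

    @property
    def pooled_abs(self) -> np.ndarray:
        return np.abs(self.smoothed).ravel()

    @property
    def pooled_areas(self) -> np.ndarray:
        if self.null_areas is None:
            raise ValidationError("scan_regions has not been run on this null")
        nonempty = [a for a in self.null_areas if len(a)]
        return np.concatenate(nonempty) if nonempty else np.zeros(0)

    def scan_regions(
        self, cutoff: float, clusters: np.ndarray, min_probes: int = 1
    ) -> None:
        areas: list[np.ndarray] = []
        maxima = np.zeros(self.B)
        for b in range(self.B):
            runs = _find_runs(self.smoothed[b], clusters, cutoff, min_probes)
            a = np.array(
                [np.abs(self.smoothed[b, s:e + 1]).sum() for s, e, _ in runs]
            )
            areas.append(a)
            maxima[b] = a.max() if len(a) else 0.0
        self.null_areas = areas
        self.boot_max = maxima


def bootstrap_null(
    matrix: MethylMatrix,
    design: Design,
    clusters: np.ndarray,
    config: BumpHunterConfig,
) -> NullDistribution:
    """Residual bootstrap of the smoothed dM statistic under the null.

    The null model is the design without the group column.  For each
    bootstrap, sample indices are drawn with replacement, the null residual
    columns are permuted accordingly and added back to the null fit, and the
    full-design group coefficient is recomputed and smoothed.  Because the
    OLS coefficient is linear in the response, the recomputation reduces to
    a single matrix product per bootstrap batch.
    """
    if config.n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    Y = matrix.values.to_numpy()
    X = design.matrix
    g = design.group_index
    X0 = np.delete(X, g, axis=1)
    beta0 = np.linalg.pinv(X0) @ Y.T  # (p-1) x probes
    F = (X0 @ beta0).T  # probes x n, null fitted values
    # OLS residuals underestimate the noise variance by (n - p0)/n; rescale so
    # the resampled residuals match the error scale (standard bootstrap fix)
    n_samp, p0 = X0.shape
    R = (Y - F) * math.sqrt(n_samp / (n_samp - p0))
    w = np.linalg.pinv(X)[g]  # n-vector extracting the group coefficient
    f0 = F @ w  # fixed contribution of the null fit

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    idx = rng.integers(0, n, size=(config.n_boot, n))
    # W[:, b] aggregates w over the resampled indices of bootstrap b
    W = np.zeros((n, config.n_boot))
    for b in range(config.n_boot):
        W[:, b] = np.bincount(idx[b], weights=w, minlength=n)
    D = f0[:, None] + R @ W  # probes x B
    smoothed = _smooth_rows(D.T, clusters, config.smooth_k)
    return NullDistribution(smoothed=smoothed, B=config.n_boot, seed=config.seed)


def pick_cutoff(null: NullDistribution, q: float) -> float:
    """Linear-interpolation empirical quantile of the pooled |smoothed| null."""
    pool = null.pooled_abs
    if pool.size == 0:
        raise ValidationError("null distribution pool is empty")
    return float(np.quantile(pool, q))


# ---------------------------------------------------------------------------
# region calling and scoring
# ---------------------------------------------------------------------------

def _find_runs(
    values: np.ndarray, clusters: np.ndarray, cutoff: float, min_probes: int = 1
) -> list[tuple[int, int, int]]:
    """Maximal within-cluster runs with values strictly beyond +/-cutoff.

    Returns (start_index, end_index, sign) triples, end inclusive.
    """
    sign = np.zeros(len(values), dtype=np.int8)
    sign[values > cutoff] = 1
    sign[values < -cutoff] = -1
    if len(values) == 0:
        return []
    change = np.empty(len(values), dtype=bool)
    change[0] = True
    change[1:] = (sign[1:] != sign[:-1]) | (clusters[1:] != clusters[:-1])
    starts = np.flatnonzero(change)
    ends = np.r_[starts[1:] - 1, len(values) - 1]
    return [
        (int(s), int(e), int(sign[s]))
        for s, e in zip(starts, ends)
        if sign[s] != 0 and e - s + 1 >= min_probes
    ]


def find_candidate_regions(
    profile: EffectProfile,
    clusters: np.ndarray,
    manifest: ProbeManifest,
    cutoff: float,
    min_probes: int = 1,
) -> list[CandidateRegion]:
    """Call candidate DMRs from the smoothed profile at the given cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if profile.smoothed is None:
        raise ValidationError("profile has not been smoothed")
    sm = profile.smoothed
    pos = manifest.df["pos"].to_numpy()
    chrom = manifest.df["chrom"].to_numpy()
    ids = manifest.df.index.to_numpy()
    regions = []
    for s, e, sign in _find_runs(sm, clusters, cutoff, min_probes):
        seg = sm[s:e + 1]
        regions.append(CandidateRegion(
            chrom=str(chrom[s]),
            start=int(pos[s]),
            end=int(pos[e]),
            probe_ids=[str(p) for p in ids[s:e + 1]],
            cluster_id=int(clusters[s]),
            n_probes=e - s + 1,
            avg_delta_m=float(seg.mean()),
            area=float(np.abs(seg).sum()),
            direction="hyper" if sign > 0 else "hypo",
        ))
    return regions


def score_regions(
    regions: list[CandidateRegion], null: NullDistribution, B: int | None = None
) -> list[CandidateRegion]:
    """Fill P (pooled-null proportion), FWER (bootstrap maxima) and BH FDR."""
    if null.null_areas is None or null.boot_max is None:
        raise ValidationError("null distribution has not been scanned for regions")
    B = B or null.B
    pool = null.pooled_areas
    maxima = null.boot_max
    if not regions:
        return regions
    areas = np.array([r.area for r in regions])
    if pool.size:
        pvals = (pool[None, :] >= areas[:, None]).sum(axis=1) / pool.size
    else:
        pvals = np.zeros(len(areas))
    fwers = (maxima[None, :] >= areas[:, None]).sum(axis=1) / B
    fdrs = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    for r, p, fw, fd in zip(regions, pvals, fwers, fdrs):
        r.p_value = float(p)
        r.fwer = float(fw)
        r.fdr = float(fd)
    return regions


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class BumpHunterResult:
    """All intermediates of one cohort's bump-hunting run."""

    regions: list[CandidateRegion]
    null: NullDistribution
    profile: EffectProfile
    cutoff: float
    clusters: np.ndarray
    manifest: ProbeManifest
    design: Design
    config: BumpHunterConfig

    @property
    def significant(self) -> list[CandidateRegion]:
        return [r for r in self.regions if r.p_value < self.config.alpha]

    def summary(self) -> str:
        return (
            f"{len(self.regions)} candidate DMR (cut-off M-value "
            f"{self.cutoff:.3f}); {len(self.significant)} with P<{self.config.alpha}"
        )


def run_bumphunter(
    matrix: MethylMatrix,
    detp: DetectionPMatrix | None,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    config: BumpHunterConfig,
    detection_p_threshold: float = 0.05,
) -> BumpHunterResult:
    """Full single-cohort pipeline from a (beta or M) matrix to scored regions.

    Inputs are aligned internally: the manifest is sorted by (chrom, pos) and
    the matrix reindexed to it, so probe row order of the inputs does not
    affect the result.  If a detection-P matrix is supplied, failing probes
    are removed first.
    """
    if set(matrix.probe_ids) != set(manifest.probe_ids):
        raise ValidationError("matrix and manifest cover different probe sets")
    if set(matrix.sample_ids) != set(sheet.sample_ids):
        raise ValidationError("matrix samples and sample sheet disagree")

    if detp is not None:
        matrix, _ = filter_detection(matrix, detp, detection_p_threshold)
        manifest = manifest.subset(matrix.probe_ids)

    manifest = manifest.sort()
    matrix = matrix.subset(manifest.probe_ids)
    sheet = SampleSheet(sheet.df.loc[matrix.sample_ids].copy())

    m_matrix = matrix.to_m()
    design = build_design(sheet)
    clusters = cluster_probes(manifest, config.maxgap)
    profile = fit_probe_effects(m_matrix, design)
    profile = smooth_effects(profile, clusters, config.smooth_k)
    null = bootstrap_null(m_matrix, design, clusters, config)
    cutoff = pick_cutoff(null, config.cutoff_quantile)
    null.scan_regions(cutoff, clusters, config.min_probes_per_region)
    regions = find_candidate_regions(
        profile, clusters, manifest, cutoff, config.min_probes_per_region
    )
    regions = score_regions(regions, null)
    result = BumpHunterResult(
        regions, null, profile, cutoff, clusters, manifest, design, config
    )
    logger.info(result.summary())
    return result
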