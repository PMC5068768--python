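"""Domain types and readers/writers for the tabular formats the pipeline touches.

Coordinates are 1-based inclusive throughout (UCSC/array-manifest convention);
BED export converts to 0-based half-open.  Methylation is carried either as
beta values (methylated fraction, in [0, 1]) or M-values (log2 odds of
methylation); ``beta_to_m``/``m_to_beta`` convert between the two scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeManifest",
    "SampleSheet",
    "MethylMatrix",
    "DetectionPMatrix",
    "CandidateRegion",
    "ConsensusRegion",
    "CohortRegionRecord",
    "GeneModel",
    "ValidationError",
    "beta_to_m",
    "m_to_beta",
    "read_methyl_matrix",
    "write_methyl_matrix",
    "read_detection_p",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_models",
    "write_regions",
    "read_candidate_regions",
    "DEFAULT_EPSILON",
]

#: Beta values are clamped to [epsilon, 1 - epsilon] before the logit so that
#: probes reported as exactly 0 or 1 map to finite M-values.
DEFAULT_EPSILON = 1e-3


class ValidationError(ValueError):
    """Raised when an input file or matrix violates a format invariant."""


# ---------------------------------------------------------------------------
# scale transforms
# ---------------------------------------------------------------------------

def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """log2 odds (M-value) of a methylation fraction.

    Computes ``log2(b / (1 - b))`` with ``b`` clamped to
    ``[epsilon, 1 - epsilon]``.  Works elementwise on scalars, arrays and
    DataFrames.  Betas outside [0, 1] are rejected.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    arr = np.asarray(beta, dtype=float) if not isinstance(beta, pd.DataFrame) else beta
    vals = arr.to_numpy() if isinstance(arr, pd.DataFrame) else arr
    if np.any(np.isnan(vals)) or np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("beta values must lie in [0, 1] with no missing values")
    clamped = np.clip(vals, epsilon, 1.0 - epsilon)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(arr, pd.DataFrame):
        return pd.DataFrame(m, index=arr.index, columns=arr.columns)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (without the clamp): ``2^m / (1 + 2^m)``."""
    arr = np.asarray(m, dtype=float) if not isinstance(m, pd.DataFrame) else m
    vals = arr.to_numpy() if isinstance(arr, pd.DataFrame) else arr
    # expit(x * ln 2) is numerically stable for large |m|
    from scipy.special import expit

    b = expit(vals * math.log(2.0))
    if isinstance(arr, pd.DataFrame):
        return pd.DataFrame(b, index=arr.index, columns=arr.columns)
    if np.isscalar(m):
        return float(b)
    return b


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

def _norm_chrom(c: str) -> str:
    c = str(c)
    return c if c.startswith("chr") else f"chr{c}"


@dataclass
class ProbeManifest:
    """Genomic placement and SNP annotation of array probes.

    ``df`` is indexed by probe id with columns ``chrom`` (normalised to a
    ``chr`` prefix), ``pos`` (1-based position of the CpG site) and
    ``snp_offsets`` (a frozenset of annotated SNP offsets relative to the
    assay: 0 = single-base extension, 1-2 = the CpG dinucleotide).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        required = {"chrom", "pos", "snp_offsets"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"manifest missing columns: {sorted(missing)}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids in manifest: {dups[:5]}")
        if (df["pos"] < 1).any():
            bad = df.index[df["pos"] < 1][0]
            raise ValidationError(f"probe {bad} has position < 1")
        df["chrom"] = df["chrom"].map(_norm_chrom)
        if df.duplicated(subset=["chrom", "pos"]).any():
            bad = df[df.duplicated(subset=["chrom", "pos"])].index[0]
            raise ValidationError(f"duplicate (chrom, pos) pair at probe {bad}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def __len__(self) -> int:
        return len(self.df)

    def sort(self) -> "ProbeManifest":
        """Return a copy sorted by (chrom, pos); chroms sort lexicographically."""
        return ProbeManifest(self.df.sort_values(["chrom", "pos"], kind="stable").copy())

    def is_sorted(self) -> bool:
        df = self.df
        key = list(zip(df["chrom"], df["pos"]))
        return key == sorted(key)

    def subset(self, probe_ids: Iterable[str]) -> "ProbeManifest":
        ids = pd.Index(probe_ids)
        unknown = ids.difference(self.df.index)
        if len(unknown):
            raise ValidationError(f"unknown probe ids: {list(unknown[:5])}")
        return ProbeManifest(self.df.loc[ids].copy())


@dataclass
class SampleSheet:
    """Per-sample phenotype table: group (case/control), sex, age, PMI.

    ``df`` is indexed by sample id.  ``sex`` is 'F'/'M' or NaN; ``age`` is
    years; ``pmi`` is the post-mortem interval in hours.  Missing covariates
    are permitted and handled at design-building time.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if "group" not in df.columns:
            raise ValidationError("sample sheet needs a 'group' column")
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in sample sheet")
        bad = set(df["group"].unique()) - {"case", "control"}
        if bad:
            raise ValidationError(f"group values must be case/control, got {sorted(bad)}")
        for col in ("sex", "age", "pmi"):
            if col not in df.columns:
                df[col] = np.nan

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def n_cases(self) -> int:
        return int((self.df["group"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.df["group"] == "control").sum())


@dataclass
class MethylMatrix:
    """Probes x samples methylation matrix on a declared scale ('beta' or 'M')."""

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValidationError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        v = self.values.to_numpy()
        if not np.issubdtype(v.dtype, np.number):
            raise ValidationError("methylation matrix contains non-numeric cells")
        if np.isnan(v).any():
            r, c = np.argwhere(np.isnan(v))[0]
            raise ValidationError(
                f"missing value at probe {self.values.index[r]}, sample {self.values.columns[c]}"
            )
        if self.scale == "beta":
            if (v < 0).any() or (v > 1).any():
                r, c = np.argwhere((v < 0) | (v > 1))[0]
                raise ValidationError(
                    f"beta outside [0,1] at probe {self.values.index[r]}, "
                    f"sample {self.values.columns[c]} (value {v[r, c]})"
                )
        else:
            if not np.isfinite(v).all():
                r, c = np.argwhere(~np.isfinite(v))[0]
                raise ValidationError(
                    f"non-finite M-value at probe {self.values.index[r]}, "
                    f"sample {self.values.columns[c]}"
                )
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe ids in methylation matrix")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def to_m(self, epsilon: float = DEFAULT_EPSILON) -> "MethylMatrix":
        if self.scale == "M":
            return self
        return MethylMatrix(beta_to_m(self.values, epsilon), "M")

    def subset(self, probe_ids: Iterable[str]) -> "MethylMatrix":
        return MethylMatrix(self.values.loc[pd.Index(probe_ids)].copy(), self.scale)


@dataclass
class DetectionPMatrix:
    """Per-probe, per-sample detection P-values, aligned like a MethylMatrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.isnan(v).any() or (v < 0).any() or (v > 1).any():
            raise ValidationError("detection P-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index


@dataclass
class CandidateRegion:
    """A called DMR: a maximal run of probes whose smoothed effect exceeds the cutoff."""

    chrom: str
    start: int
    end: int
    probe_ids: list[str]
    cluster_id: int
    n_probes: int
    avg_delta_m: float
    area: float
    direction: str  # 'hyper' or 'hypo'
    p_value: float = math.nan
    fdr: float = math.nan
    fwer: float = math.nan

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region start {self.start} > end {self.end}")
        if self.direction not in ("hyper", "hypo"):
            raise ValidationError(f"direction must be hyper/hypo, got {self.direction!r}")

    @property
    def scored(self) -> bool:
        return not math.isnan(self.p_value)


@dataclass
class CohortRegionRecord:
    """One cohort's contribution to a consensus region."""

    cohort: str
    chrom: str
    start: int
    end: int
    avg_delta_m: float


@dataclass
class ConsensusRegion:
    """A region significant with consistent direction in every cohort."""

    chrom: str
    intersect_start: int
    intersect_end: int
    direction: str
    cohort_records: list[CohortRegionRecord]
    nearest_gene: str = ""
    gene_distance: float = math.nan

    @property
    def width(self) -> int:
        return self.intersect_end - self.intersect_start + 1


@dataclass(frozen=True)
class GeneModel:
    """A gene interval used for nearest-feature annotation."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.name}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.name}: strand must be + or -")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype={0: str})


def read_methyl_matrix(path, scale: str) -> MethylMatrix:
    """Read a probes x samples TSV/CSV (probe ids first column, sample header)."""
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return MethylMatrix(df, scale)


def write_methyl_matrix(matrix: MethylMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    matrix.values.to_csv(path, sep=sep, index_label="probe_id", float_format="%.10g")


def read_detection_p(path) -> DetectionPMatrix:
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index.name = "probe_id"
    return DetectionPMatrix(df.astype(float))


def write_detection_p(detp: DetectionPMatrix, path) -> None:
    detp.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")


def _parse_offsets(s) -> frozenset[int]:
    if s is None or (isinstance(s, float) and math.isnan(s)) or str(s).strip() in ("", "."):
        return frozenset()
    # pandas may have coerced the column to float ("0.0"); accept both
    return frozenset(int(float(tok)) for tok in str(s).split(",") if tok.strip() != "")


def read_probe_manifest(path) -> ProbeManifest:
    """Read a probe manifest TSV: probe_id, chrom, pos, snp_offsets (comma-joined)."""
    df = _read_table(path)
    need = {"probe_id", "chrom", "pos"}
    if not need <= set(df.columns):
        raise ValidationError(f"manifest must have columns {sorted(need)}")
    df = df.set_index("probe_id")
    df["pos"] = df["pos"].astype(int)
    if "snp_offsets" not in df.columns:
        df["snp_offsets"] = ""
    df["snp_offsets"] = df["snp_offsets"].map(_parse_offsets)
    return ProbeManifest(df[["chrom", "pos", "snp_offsets"]])


def write_probe_manifest(manifest: ProbeManifest, path) -> None:
    out = manifest.df.copy()
    out["snp_offsets"] = out["snp_offsets"].map(
        lambda s: ",".join(str(o) for o in sorted(s))
    )
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path) -> SampleSheet:
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValidationError("sample sheet must have a sample_id column")
    df = df.set_index("sample_id")
    for col in ("age", "pmi"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from TSV (name, chrom, start, end, strand) or BED."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        genes = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "browser", "#")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start0, end0 = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{start0}-{end0}"
                strand = f[5] if len(f) > 5 else "+"
                genes.append(GeneModel(name, _norm_chrom(chrom), start0 + 1, end0, strand))
        return genes
    df = _read_table(path)
    need = {"name", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValidationError(f"gene table must have columns {sorted(need)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    return [
        GeneModel(str(r["name"]), _norm_chrom(r["chrom"]), int(r["start"]),
                  int(r["end"]), str(r["strand"]))
        for _, r in df.iterrows()
    ]


_CANDIDATE_COLS = [
    "chrom", "start", "end", "n_probes", "avg_delta_m", "area",
    "direction", "p_value", "fdr", "fwer", "cluster_id", "probe_ids",
]


def _regions_sorted(regions: Sequence) -> bool:
    key = [(r.chrom, getattr(r, "start", getattr(r, "intersect_start", 0))) for r in regions]
    return key == sorted(key)


def write_regions(regions: Sequence, path, format: str = "tsv") -> None:
    """Write candidate or consensus regions as TSV (1-based inclusive) or BED.

    BED output is 0-based half-open: a 1-based inclusive region [start, end]
    becomes the BED interval [start-1, end).
    """
    if format not in ("tsv", "bed"):
        raise ValueError(f"format must be tsv or bed, got {format!r}")
    if not _regions_sorted(regions):
        raise ValidationError("regions must be sorted by (chrom, start) before writing")
    path = Path(path)
    if format == "bed":
        with open(path, "w") as fh:
            for r in regions:
                start = getattr(r, "start", None) or getattr(r, "intersect_start")
                end = getattr(r, "end", None) or getattr(r, "intersect_end")
                name = getattr(r, "direction", ".")
                fh.write(f"{r.chrom}\t{start - 1}\t{end}\t{name}\n")
        return
    if regions and isinstance(regions[0], ConsensusRegion):
        rows = []
        for r in regions:
            row = {
                "chrom": r.chrom,
                "intersect_start": r.intersect_start,
                "intersect_end": r.intersect_end,
                "direction": r.direction,
                "nearest_gene": r.nearest_gene,
                "gene_distance": r.gene_distance,
            }
            for rec in r.cohort_records:
                row[f"avg_delta_m_{rec.cohort}"] = rec.avg_delta_m
                row[f"region_{rec.cohort}"] = f"{rec.chrom}:{rec.start}-{rec.end}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
        return
    rows = []
    for r in regions:
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "n_probes": r.n_probes, "avg_delta_m": r.avg_delta_m, "area": r.area,
            "direction": r.direction, "p_value": r.p_value, "fdr": r.fdr,
            "fwer": r.fwer, "cluster_id": r.cluster_id,
            "probe_ids": ",".join(r.probe_ids),
        })
    pd.DataFrame(rows, columns=_CANDIDATE_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_candidate_regions(path) -> list[CandidateRegion]:
    """Read back a candidate-region TSV written by :func:`write_regions`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(CandidateRegion(
            chrom=str(r["chrom"]), start=int(r["start"]), end=int(r["end"]),
            probe_ids=str(r["probe_ids"]).split(",") if pd.notna(r["probe_ids"]) else [],
            cluster_id=int(r["cluster_id"]), n_probes=int(r["n_probes"]),
            avg_delta_m=float(r["avg_delta_m"]), area=float(r["area"]),
            direction=str(r["direction"]), p_value=float(r["p_value"]),
            fdr=float(r["fdr"]), fwer=float(r["fwer"]),
        ))
    return out
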