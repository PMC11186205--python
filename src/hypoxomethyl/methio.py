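"""File formats and sequencing-level QC for the methylation pipeline.

All coordinates are 0-based half-open internally; conversion to the 1-based
Bismark cytosine-report convention happens only at the I/O boundary. CpG
sites are single plus-strand C positions (optional strand merging of the
symmetric CpG is handled upstream of this module).
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TISSUE_CLASSES = ("TP", "TN", "Benign")

#: column layout of ``MethylomeSample.sites``
SITE_COLUMNS = ["chrom", "pos", "cov", "meth"]

_CPG_CONTEXTS = {"CpG", "CG"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


def chrom_sort_key(chrom: str):
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


# ---------------------------------------------------------------------------
# Genomic intervals


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "name": [iv.name if iv.name is not None else "." for iv in intervals],
        }
    )


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    names = df["name"] if "name" in df.columns else ["."] * len(df)
    return [
        GenomicInterval(str(c), int(s), int(e), None if n in (".", None) else str(n))
        for c, s, e, n in zip(df["chrom"], df["start"], df["end"], names)
    ]


# ---------------------------------------------------------------------------
# Methylome samples


@dataclass
class MethylomeSample:
    """Per-CpG methylation track for one laser-microdissected sample.

    ``sites`` has columns (chrom, pos, cov, meth); pos is 0-based, rows are
    sorted by (chrom, pos) and unique, and meth <= cov at every site.
    """

    sample_id: str
    sites: pd.DataFrame
    tissue_class: str = "TP"
    patient_id: str | None = None

    def __post_init__(self):
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(
                f"tissue_class {self.tissue_class!r} not in {TISSUE_CLASSES}"
            )
        self.sites = validate_sites(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def proportions(self) -> np.ndarray:
        """Raw methylation proportions; 0 where coverage is 0."""
        cov = self.sites["cov"].to_numpy(float)
        meth = self.sites["meth"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(cov > 0, meth / np.maximum(cov, 1), 0.0)
        return p

    def with_sites(self, sites: pd.DataFrame) -> "MethylomeSample":
        return MethylomeSample(
            sample_id=self.sample_id,
            sites=sites,
            tissue_class=self.tissue_class,
            patient_id=self.patient_id,
        )


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, SITE_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "cov", "meth"):
        df[col] = df[col].astype(np.int64)
    if (df["pos"] < 0).any():
        raise ValidationError("negative position")
    if (df["cov"] < 0).any() or (df["meth"] < 0).any():
        raise ValidationError("negative count")
    bad = df.index[df["meth"] > df["cov"]]
    if len(bad):
        raise ValidationError(
            f"meth_count > coverage at row {int(bad[0])} "
            f"({df.loc[bad[0], 'chrom']}:{int(df.loc[bad[0], 'pos'])})"
        )
    key = df["chrom"].map(chrom_sort_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df["pos"].iloc[i]))
    df = df.iloc[order].reset_index(drop=True)
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"duplicate site {df.loc[i, 'chrom']}:{int(df.loc[i, 'pos'])}"
        )
    return df


# ---------------------------------------------------------------------------
# Bismark-style cytosine report


def read_cytosine_report(
    path,
    sample_id: str | None = None,
    tissue_class: str = "TP",
    patient_id: str | None = None,
) -> MethylomeSample:
    """Read a Bismark-style cytosine report.

    Expected tab-separated columns: chrom, 1-based position, strand,
    count-methylated, count-unmethylated, context[, trinucleotide]. Only CpG
    context rows are retained.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = re.sub(r"\.(cov|txt|tsv|CpG_report)(\.gz)?$", "", path.name)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty cytosine report; returning empty sample")
        raw = pd.DataFrame(columns=range(6))
    if len(raw.columns) < 6:
        if len(raw) == 0:
            sites = pd.DataFrame(columns=SITE_COLUMNS)
            return MethylomeSample(sample_id, sites, tissue_class, patient_id)
        raise ParseError(f"{path}: expected >=6 tab-separated columns")
    raw = raw.rename(
        columns={0: "chrom", 1: "pos", 2: "strand", 3: "meth", 4: "unmeth", 5: "context"}
    )
    for col, kind in (("pos", "position"), ("meth", "count"), ("unmeth", "count")):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: malformed {kind} at line {line}")
        raw[col] = converted.astype(np.int64)
    if (raw["pos"] < 1).any():
        line = int(np.flatnonzero((raw["pos"] < 1).to_numpy())[0]) + 1
        raise ParseError(f"{path}: non-positive 1-based position at line {line}")
    if (raw["meth"] < 0).any() or (raw["unmeth"] < 0).any():
        raise ParseError(f"{path}: negative count")
    keep = raw["context"].isin(_CPG_CONTEXTS)
    raw = raw.loc[keep]
    sites = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "pos": raw["pos"] - 1,  # to 0-based
            "cov": raw["meth"] + raw["unmeth"],
            "meth": raw["meth"],
        }
    ).reset_index(drop=True)
    if len(sites) == 0:
        warnings.warn(f"{path}: no CpG-context rows; returning empty sample")
    return MethylomeSample(sample_id, sites, tissue_class, patient_id)


def write_cytosine_report(sample: MethylomeSample, path) -> None:
    df = sample.sites
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,  # to 1-based
            "strand": "+",
            "meth": df["meth"],
            "unmeth": df["cov"] - df["meth"],
            "context": "CpG",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bedGraph (methylation percentage 0-100, common WGBS convention)


def write_bedgraph(sample: MethylomeSample, path) -> None:
    df = sample.sites
    cov = df["cov"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * df["meth"].to_numpy(float) / np.maximum(cov, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "pct": np.round(pct, 6),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(
    path,
    coverage: pd.DataFrame | None = None,
    sample_id: str | None = None,
    tissue_class: str = "TP",
    patient_id: str | None = None,
) -> pd.DataFrame:
    """Read a methylation bedGraph into a (chrom, pos, pct) frame."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty bedGraph")
        return pd.DataFrame(columns=["chrom", "pos", "pct"])
    if len(df.columns) < 4:
        raise ParseError(f"{path}: bedGraph needs 4 columns")
    df = df.rename(columns={0: "chrom", 1: "pos", 2: "end", 3: "pct"})
    return df[["chrom", "pos", "pct"]]


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: Sequence[GenomicInterval], path, extra: pd.DataFrame | None = None) -> None:
    """Write BED3(+name[+extra columns]), 0-based half-open, sorted.

    ``extra`` optionally supplies additional columns aligned with ``intervals``
    (pre-sorting order); it is reordered together with the intervals.
    """
    df = intervals_to_frame(list(intervals))
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    try:
        keys = [chrom_sort_key(c) for c in df["chrom"]]
    except Exception:
        warnings.warn("unsortable chromosome names; falling back to lexicographic")
        keys = list(df["chrom"])
    order = sorted(range(len(df)), key=lambda i: (keys[i], int(df["start"].iloc[i]), int(df["end"].iloc[i])))
    df = df.iloc[order]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> list[GenomicInterval]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if len(df.columns) < 3:
        raise ParseError(f"{path}: BED needs >=3 columns")
    cols = {0: "chrom", 1: "start", 2: "end"}
    if len(df.columns) > 3:
        cols[3] = "name"
    df = df.rename(columns=cols)
    if "name" not in df.columns:
        df["name"] = "."
    return frame_to_intervals(df)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return {str(c): int(l) for c, l in zip(df["chrom"], df["length"])}


def write_chrom_sizes(genome: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(genome, key=chrom_sort_key):
            fh.write(f"{c}\t{genome[c]}\n")


# ---------------------------------------------------------------------------
# Matrices and clinical tables


def write_matrix_tsv(values: pd.DataFrame, path) -> None:
    """Samples x features matrix; index = sample ids, header = feature ids."""
    values.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Bisulfite conversion QC


@dataclass(frozen=True)
class ConversionQc:
    """Bisulfite conversion efficiency from the spiked-in lambda genome.

    The unmethylated lambda phage genome is spiked into each library; every
    lambda cytosine should read as thymine after full conversion, so the
    conversion rate is the fraction of thymine base calls at lambda cytosine
    reference positions.
    """

    lambda_c_positions: int
    lambda_t_observed: int

    @property
    def conversion_rate(self) -> float:
        return self.lambda_t_observed / self.lambda_c_positions


def conversion_rate(lambda_c_positions: int, lambda_t_observed: int) -> ConversionQc:
    if lambda_c_positions <= 0:
        raise ValidationError("lambda_c_positions must be positive")
    if not 0 <= lambda_t_observed <= lambda_c_positions:
        raise ValidationError("lambda_t_observed out of [0, lambda_c_positions]")
    return ConversionQc(lambda_c_positions, lambda_t_observed)
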