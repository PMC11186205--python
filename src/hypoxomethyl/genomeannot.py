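"""Genomic annotation of region sets and permutation enrichment testing.

Feature classes (CpG island geography, gene-model parts) are plain interval
lists; the enrichment statistic is the number of query regions overlapping a
class by >= 1 bp, and its null distribution comes from relocating every query
region uniformly at random on its own chromosome, preserving length.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .methio import GenomicInterval, chrom_sort_key, read_bed, read_chrom_sizes

CPG_GEOGRAPHY_FLANK = 2_000  # shore = +/-2 kb of an island, shelf = next +/-2 kb


# ---------------------------------------------------------------------------
# Interval algebra on (starts, ends) arrays, per chromosome


def _by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    out: dict[str, list] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in out.items()}


def _merge(arr: np.ndarray) -> np.ndarray:
    """Merge sorted (start, end) rows into disjoint intervals."""
    if len(arr) == 0:
        return arr
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    out = []
    for c in sorted(_by_chrom(intervals), key=chrom_sort_key):
        for s, e in _merge(_by_chrom(intervals)[c]):
            out.append(GenomicInterval(c, int(s), int(e)))
    return out


def _subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a \\ b for merged disjoint arrays on one chromosome."""
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _flank(arr: np.ndarray, lo_ext: int, hi_ext: int, chrom_len: int) -> np.ndarray:
    ext = np.stack(
        [np.maximum(arr[:, 0] - lo_ext, 0), np.minimum(arr[:, 1] + hi_ext, chrom_len)],
        axis=1,
    )
    return _merge(ext[np.argsort(ext[:, 0])])


# ---------------------------------------------------------------------------
# Annotation set


@dataclass
class AnnotationSet:
    """Named feature classes plus chromosome lengths."""

    classes: dict[str, list[GenomicInterval]]
    genome: dict[str, int]

    def __post_init__(self):
        for name, ivs in self.classes.items():
            for iv in ivs:
                if iv.chrom in self.genome and iv.end > self.genome[iv.chrom]:
                    raise ValueError(f"{name}: {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome")

    def merged(self) -> dict[str, dict[str, np.ndarray]]:
        """class -> chrom -> merged (n, 2) array."""
        return {
            name: {c: _merge(arr) for c, arr in _by_chrom(ivs).items()}
            for name, ivs in self.classes.items()
        }

    @classmethod
    def from_bed_dir(cls, directory, genome: dict[str, int]) -> "AnnotationSet":
        directory = Path(directory)
        classes = {p.stem: read_bed(p) for p in sorted(directory.glob("*.bed"))}
        return cls(classes, genome)

    @classmethod
    def from_files(cls, bed_paths: dict[str, str], chrom_sizes_path) -> "AnnotationSet":
        genome = read_chrom_sizes(chrom_sizes_path)
        return cls({k: read_bed(v) for k, v in bed_paths.items()}, genome)


def cpg_geography(
    islands: Sequence[GenomicInterval],
    genome: dict[str, int],
    flank: int = CPG_GEOGRAPHY_FLANK,
) -> dict[str, list[GenomicInterval]]:
    """Standard CpG-island geography derived from the island track.

    shore = +/-``flank`` bp around islands (islands excluded); shelf = the
    next +/-``flank`` bp; open sea = everything else.
    """
    by = {c: _merge(a) for c, a in _by_chrom(islands).items()}
    out = {"cgi": [], "shore": [], "shelf": [], "open_sea": []}
    for chrom, L in genome.items():
        isl = by.get(chrom, np.empty((0, 2), dtype=np.int64))
        shore_zone = _flank(isl, flank, flank, L) if len(isl) else isl
        shelf_zone = _flank(isl, 2 * flank, 2 * flank, L) if len(isl) else isl
        shore = _subtract(shore_zone, isl)
        shelf = _subtract(shelf_zone, shore_zone)
        whole = np.array([[0, L]], dtype=np.int64)
        open_sea = _subtract(whole, shelf_zone)
        for key, arr in (("cgi", isl), ("shore", shore), ("shelf", shelf), ("open_sea", open_sea)):
            out[key].extend(GenomicInterval(chrom, int(s), int(e)) for s, e in arr)
    return out


# ---------------------------------------------------------------------------
# Overlap counting


def _hits(qs: np.ndarray, qe: np.ndarray, merged: np.ndarray) -> np.ndarray:
    """Boolean: does each half-open query [qs, qe) overlap any merged interval."""
    if len(merged) == 0:
        return np.zeros(qs.shape, dtype=bool)
    starts, ends = merged[:, 0], merged[:, 1]
    idx = np.searchsorted(starts, qe, side="left")
    has_left = idx > 0
    prev_end = ends[np.maximum(idx - 1, 0)]
    return has_left & (prev_end > qs)


def annotate_regions(
    query: Sequence[GenomicInterval], ann: AnnotationSet
) -> dict[str, int]:
    """Count query regions overlapping each class by >= 1 bp.

    A region may count toward several classes; chromosomes absent from the
    genome map are an error.
    """
    if len(query) == 0:
        raise ValueError("query is empty")
    for iv in query:
        if iv.chrom not in ann.genome:
            raise ValueError(f"chromosome {iv.chrom!r} absent from genome map")
    qby = _by_chrom(query)
    merged = ann.merged()
    counts = {}
    for name in ann.classes:
        total = 0
        for chrom, arr in qby.items():
            m = merged[name].get(chrom, np.empty((0, 2), dtype=np.int64))
            total += int(_hits(arr[:, 0], arr[:, 1], m).sum())
        counts[name] = total
    return counts


# ---------------------------------------------------------------------------
# Permutation enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    class_name: str
    observed_overlap: int
    perm_mean: float
    perm_sd: float
    z: float
    p_empirical: float
    direction: str  # enriched | depleted
    n_iterations: int


def permutation_enrichment(
    query: Sequence[GenomicInterval],
    ann: AnnotationSet,
    n_iter: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Permutation test of region-count overlap against each class.

    Every iteration relocates each query region uniformly at random on its
    own chromosome (length preserved); the empirical tail probability uses
    the add-one rule p = (1 + #{perm >= obs}) / (n_iter + 1) for enrichment,
    mirrored for depletion, with the reported tail chosen by the sign of z.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    obs = annotate_regions(query, ann)
    rng = np.random.default_rng(seed)
    qby = _by_chrom(query)
    merged = ann.merged()

    # random starts per chromosome, all iterations at once
    perm_pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, arr in qby.items():
        lens = arr[:, 1] - arr[:, 0]
        L = ann.genome[chrom]
        if (lens > L).any():
            raise ValueError(f"query region longer than chromosome {chrom}")
        starts = rng.integers(0, L - lens + 1, size=(n_iter, len(lens)))
        perm_pos[chrom] = (starts, starts + lens)

    results = []
    for name in ann.classes:
        perm_counts = np.zeros(n_iter, dtype=np.int64)
        for chrom, (ps, pe) in perm_pos.items():
            m = merged[name].get(chrom, np.empty((0, 2), dtype=np.int64))
            perm_counts += _hits(ps, pe, m).sum(axis=1)
        o = obs[name]
        mean = float(perm_counts.mean())
        sd = float(perm_counts.std(ddof=1)) if n_iter > 1 else 0.0
        z = (o - mean) / sd if sd > 0 else 0.0
        p_enr = (1 + int((perm_counts >= o).sum())) / (n_iter + 1)
        p_dep = (1 + int((perm_counts <= o).sum())) / (n_iter + 1)
        if o >= mean:
            direction, p = "enriched", p_enr
        else:
            direction, p = "depleted", p_dep
        results.append(
            EnrichmentResult(name, o, mean, sd, float(z), float(p), direction, n_iter)
        )
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
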