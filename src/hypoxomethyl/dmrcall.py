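"""Differential methylation region calling between two groups of methylomes.

The comparison has no biological replicates per group member, so evidence is
borrowed along the genome: pooled group counts are smoothed over a fixed
window and each CpG is tested with a two-proportion Wald statistic whose
effective sample size is the coverage pooled over that window. Region calling
then follows the stringent rule set of the upstream caller: per-site
significance (p <= p_threshold and |diff| >= delta), maximal same-sign runs
whose significant fraction stays above pct_sig, merging of nearby runs, and
hard filters on length, CpG count, significant fraction and mean difference.

Semantics of region construction (deterministic, order-independent; one
genomic scan per sign implements both run construction and run merging):

1. Significant sites of one sign are *anchors*; any site whose difference has
   the opposite sign — significant or not — is a *barrier* for that sign.
2. Anchors chain into a run while (a) no barrier lies between consecutive
   anchors, (b) consecutive anchors are separated by <= dis_merge_bp, and
   (c) the running significant fraction (anchors over all grid sites spanned
   so far) stays >= pct_sig; extension wins ties, so runs are as long as the
   rules allow.
3. A run spans [first anchor, last anchor] and must satisfy
   length >= minlen_bp, n_cpg >= min_cg, n_sig/n_cpg >= pct_sig and
   |mean diff| >= delta with matching sign.

On small grids this is identical to an independent literal re-evaluation of
the rules (the reference oracle used in the test suite).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methio import GenomicInterval, MethylomeSample, ValidationError

logger = logging.getLogger(__name__)

_PROP_EPS = 1e-6  # clamp for Wald variance at smoothed proportions of 0/1


@dataclass(frozen=True)
class DmrCallParams:
    """Site filter, smoothing and region thresholds.

    Defaults reproduce the stringent published setting: sites kept when read
    count exceeds 5 in at least one sample, 500 bp smoothing span, and region
    rules delta=0.2, p.threshold=1e-16, minlen=200, minCG=5, dis.merge=50,
    pct.sig=0.5.
    """

    min_site_count: int = 5  # strict ">"
    smoothing_span_bp: int = 500
    delta: float = 0.2
    p_threshold: float = 1e-16
    minlen_bp: int = 200
    min_cg: int = 5
    dis_merge_bp: int = 50
    pct_sig: float = 0.5

    def __post_init__(self):
        if min(self.min_site_count, self.smoothing_span_bp, self.minlen_bp,
               self.min_cg, self.dis_merge_bp) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 <= self.delta < 1:
            raise ValueError("delta must be in [0, 1)")
        if not 0 < self.pct_sig <= 1:
            raise ValueError("pct_sig must be in (0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass(frozen=True)
class Dmr:
    """A called differentially methylated region."""

    interval: GenomicInterval
    n_cpg: int
    mean_diff: float
    direction: str  # hyper | hypo, relative to group1
    n_sig: int


#: column layout of the per-site test table (one row per CpG)
SITE_TEST_COLUMNS = ["chrom", "pos", "mu1", "mu2", "diff", "se", "stat", "p"]


# ---------------------------------------------------------------------------
# Site filter


def filter_sites(
    samples: Sequence[MethylomeSample], params: DmrCallParams
) -> list[MethylomeSample]:
    """Keep sites whose coverage exceeds ``min_site_count`` in >=1 sample.

    All output samples share one common site grid (the union of input sites,
    with absent sites given zero counts, restricted to the kept sites).
    """
    if len(samples) < 2:
        raise ValueError("need >=2 samples")
    frames = []
    for s in samples:
        f = s.sites.set_index(["chrom", "pos"])[["cov", "meth"]]
        f.columns = pd.MultiIndex.from_product([[s.sample_id], ["cov", "meth"]])
        frames.append(f)
    wide = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    cov = wide.xs("cov", axis=1, level=1)
    keep = (cov > params.min_site_count).any(axis=1)
    wide = wide.loc[keep]
    if len(wide) == 0:
        warnings.warn("site filter removed every site")
    wide = wide.sort_index()
    out = []
    for s in samples:
        sites = wide[s.sample_id].reset_index()
        sites = sites[["chrom", "pos", "cov", "meth"]]
        out.append(s.with_sites(sites))
    logger.info("filter_sites: kept %d of %d union sites", len(wide), len(cov))
    return out


def _common_grid(samples: Sequence[MethylomeSample]) -> pd.DataFrame:
    grid = samples[0].sites[["chrom", "pos"]]
    for s in samples[1:]:
        if len(s.sites) != len(grid) or not (
            s.sites["pos"].to_numpy() == grid["pos"].to_numpy()
        ).all() or not (s.sites["chrom"].to_numpy() == grid["chrom"].to_numpy()).all():
            raise ValidationError("samples are not on a common site grid; run filter_sites first")
    return grid


# ---------------------------------------------------------------------------
# Smoothing


def _window_sums(pos: np.ndarray, values: np.ndarray, half_span: int):
    """Sum of ``values`` over sites within +/- half_span bp of each site."""
    csum = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    lo = np.searchsorted(pos, pos - half_span, side="left")
    hi = np.searchsorted(pos, pos + half_span, side="right")
    return csum[hi] - csum[lo]


def _smooth_track(pos, cov, meth, span_bp):
    """Coverage-weighted smoothed proportion and window-pooled coverage."""
    half = span_bp // 2
    wc = _window_sums(pos, cov.astype(float), half)
    wm = _window_sums(pos, meth.astype(float), half)
    mu = np.full(len(pos), 0.5)
    has_window = wc > 0
    mu[has_window] = wm[has_window] / wc[has_window]
    # fall back to the site's own proportion when the window is empty
    own = cov > 0
    orphan = ~has_window & own
    mu[orphan] = meth[orphan] / cov[orphan]
    dead = ~has_window & ~own
    if dead.any():
        warnings.warn(f"{int(dead.sum())} sites with no coverage in window; smoothed to 0.5")
    return mu, wc


def smooth_proportions(sample: MethylomeSample, span_bp: int) -> np.ndarray:
    """Per-site smoothed methylation proportion for one sample.

    The smoother is a coverage-weighted running mean of meth/coverage over
    all sites within +/- span_bp/2, computed per chromosome.
    """
    out = np.empty(sample.n_sites)
    sites = sample.sites
    for chrom, sub in sites.groupby("chrom", sort=False):
        mu, _ = _smooth_track(
            sub["pos"].to_numpy(),
            sub["cov"].to_numpy(),
            sub["meth"].to_numpy(),
            span_bp,
        )
        out[sub.index.to_numpy()] = mu
    return out


# ---------------------------------------------------------------------------
# Per-site two-group test


def _pool_group(samples: Sequence[MethylomeSample]):
    cov = np.sum([s.sites["cov"].to_numpy() for s in samples], axis=0)
    meth = np.sum([s.sites["meth"].to_numpy() for s in samples], axis=0)
    return cov, meth


def _wald_from_pooled(pos, cov1, meth1, cov2, meth2, chrom, span_bp):
    mu1, n1 = _smooth_track(pos, cov1, meth1, span_bp)
    mu2, n2 = _smooth_track(pos, cov2, meth2, span_bp)
    ok = (n1 > 0) & (n2 > 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.info("site_test: skipped %d sites with empty group window", n_skipped)
    mu1, mu2, n1, n2 = mu1[ok], mu2[ok], n1[ok], n2[ok]
    m1 = np.clip(mu1, _PROP_EPS, 1 - _PROP_EPS)
    m2 = np.clip(mu2, _PROP_EPS, 1 - _PROP_EPS)
    se = np.sqrt(m1 * (1 - m1) / n1 + m2 * (1 - m2) / n2)
    diff = mu1 - mu2
    stat = diff / se
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos[ok],
            "mu1": mu1,
            "mu2": mu2,
            "diff": diff,
            "se": se,
            "stat": stat,
            "p": p,
        }
    )


def site_test(
    group1: Sequence[MethylomeSample],
    group2: Sequence[MethylomeSample],
    params: DmrCallParams,
) -> pd.DataFrame:
    """Smoothed two-proportion Wald test per CpG (no replicates needed).

    Counts are pooled within each group, smoothed over the span window, and
    compared with stat = (mu1 - mu2)/se where
    se^2 = mu1(1-mu1)/n1 + mu2(1-mu2)/n2 and n is the coverage pooled over
    the group's samples and the smoothing window. Two-sided p from the
    standard normal. Returns one row per testable site
    (columns ``SITE_TEST_COLUMNS``).
    """
    grid = _common_grid(list(group1) + list(group2))
    cov1, meth1 = _pool_group(group1)
    cov2, meth2 = _pool_group(group2)
    chunks = []
    for chrom, sub in grid.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        chunks.append(
            _wald_from_pooled(
                sub["pos"].to_numpy(),
                cov1[idx], meth1[idx], cov2[idx], meth2[idx],
                chrom, params.smoothing_span_bp,
            )
        )
    if not chunks:
        return pd.DataFrame(columns=SITE_TEST_COLUMNS)
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# Region calling


def _chain_runs(
    anchors: np.ndarray,
    barrier: np.ndarray,
    pos: np.ndarray,
    params: DmrCallParams,
) -> list[tuple[int, int]]:
    """One genomic scan chaining anchor grid indices into candidate runs.

    ``anchors`` are grid indices of significant same-sign sites; ``barrier``
    flags every grid site whose diff has the opposite sign. A new anchor
    extends the current run unless a barrier lies between, the separation
    exceeds dis_merge_bp, or extension would drop the running significant
    fraction below pct_sig.
    """
    barrier_cum = np.concatenate([[0], np.cumsum(barrier)])
    runs: list[tuple[int, int]] = []
    first = last = int(anchors[0])
    n_anchor = 1
    for g in anchors[1:]:
        g = int(g)
        blocked = barrier_cum[g] - barrier_cum[last + 1] > 0
        too_far = pos[g] - (pos[last] + 1) > params.dis_merge_bp
        dilution = (n_anchor + 1) < params.pct_sig * (g - first + 1)
        if blocked or too_far or dilution:
            runs.append((first, last))
            first, n_anchor = g, 0
        last = g
        n_anchor += 1
    runs.append((first, last))
    return runs


def call_dmrs(site_results: pd.DataFrame, params: DmrCallParams) -> list[Dmr]:
    """Apply the region rule set to a per-site test table."""
    if len(site_results) == 0:
        return []
    dmrs: list[Dmr] = []
    for chrom, sub in site_results.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        diff = sub["diff"].to_numpy(float)
        p = sub["p"].to_numpy(float)
        sig = (p <= params.p_threshold) & (np.abs(diff) >= params.delta) & (diff != 0)
        sign = np.sign(diff)
        for d, name in ((1.0, "hyper"), (-1.0, "hypo")):
            anchors = np.flatnonzero(sig & (sign == d))
            if len(anchors) == 0:
                continue
            barrier = sign == -d
            own = np.zeros(len(pos), dtype=bool)
            own[anchors] = True
            own_cum = np.concatenate([[0], np.cumsum(own)])
            for lo, hi in _chain_runs(anchors, barrier, pos, params):
                n_cpg = hi - lo + 1
                n_sig = int(own_cum[hi + 1] - own_cum[lo])
                length = int(pos[hi]) + 1 - int(pos[lo])
                mean_diff = float(diff[lo : hi + 1].mean())
                if (
                    length >= params.minlen_bp
                    and n_cpg >= params.min_cg
                    and n_sig >= params.pct_sig * n_cpg
                    and abs(mean_diff) >= params.delta
                    and np.sign(mean_diff) == d
                ):
                    dmrs.append(
                        Dmr(
                            interval=GenomicInterval(chrom, int(pos[lo]), int(pos[hi]) + 1),
                            n_cpg=n_cpg,
                            mean_diff=mean_diff,
                            direction=name,
                            n_sig=n_sig,
                        )
                    )
    dmrs.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.direction))
    return dmrs


def dmrs_between(
    group1: Sequence[MethylomeSample],
    group2: Sequence[MethylomeSample],
    params: DmrCallParams | None = None,
) -> list[Dmr]:
    """Full two-group pipeline: site filter, site test, region calling."""
    params = params or DmrCallParams()
    filtered = filter_sites(list(group1) + list(group2), params)
    g1 = filtered[: len(group1)]
    g2 = filtered[len(group1) :]
    results = site_test(g1, g2, params)
    dmrs = call_dmrs(results, params)
    logger.info("dmrs_between: %d DMRs called", len(dmrs))
    return dmrs


# ---------------------------------------------------------------------------
# Paired design (one hypoxic + one normoxic sample per patient)


def paired_dmrs(
    pairs: Sequence[tuple[MethylomeSample, MethylomeSample]],
    params: DmrCallParams | None = None,
) -> list[Dmr]:
    """Consensus DMRs over matched (hypoxic, normoxic) sample pairs.

    Each pair is tested without replicates as in :func:`site_test`; per-site
    signed z statistics are then combined across pairs with equal-weight
    Stouffer's method, the combined diff being the mean of per-pair smoothed
    differences. Region calling runs on the combined track. Sites not
    testable in every pair are dropped.
    """
    if len(pairs) < 1:
        raise ValueError("need >=1 pair")
    params = params or DmrCallParams()
    for a, b in pairs:
        if a.patient_id is not None and b.patient_id is not None and a.patient_id != b.patient_id:
            raise ValidationError(
                f"unmatched pair members: {a.sample_id} / {b.sample_id}"
            )
    flat: list[MethylomeSample] = [s for pair in pairs for s in pair]
    filtered = filter_sites(flat, params)
    tracks = []
    for k in range(len(pairs)):
        res = site_test([filtered[2 * k]], [filtered[2 * k + 1]], params)
        tracks.append(res.set_index(["chrom", "pos"]))
    common = tracks[0].index
    for t in tracks[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        return []
    zs = np.stack([t.loc[common, "stat"].to_numpy(float) for t in tracks])
    diffs = np.stack([t.loc[common, "diff"].to_numpy(float) for t in tracks])
    mu1s = np.stack([t.loc[common, "mu1"].to_numpy(float) for t in tracks])
    mu2s = np.stack([t.loc[common, "mu2"].to_numpy(float) for t in tracks])
    z_comb = zs.sum(axis=0) / np.sqrt(len(pairs))
    p_comb = 2.0 * stats.norm.sf(np.abs(z_comb))
    combined = pd.DataFrame(
        {
            "chrom": common.get_level_values(0),
            "pos": common.get_level_values(1),
            "mu1": mu1s.mean(axis=0),
            "mu2": mu2s.mean(axis=0),
            "diff": diffs.mean(axis=0),
            "se": np.where(z_comb != 0, np.abs(diffs.mean(axis=0) / np.where(z_comb == 0, 1, z_comb)), np.nan),
            "stat": z_comb,
            "p": p_comb,
        }
    ).sort_values(["chrom", "pos"], kind="mergesort", key=None).reset_index(drop=True)
    return call_dmrs(combined, params)


def stouffer(z_scores: Sequence[float]) -> float:
    """Equal-weight Stouffer combination of signed z statistics."""
    z = np.asarray(z_scores, float)
    return float(z.sum() / np.sqrt(len(z)))


# ---------------------------------------------------------------------------
# Output


def dmrs_to_frame(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in dmrs],
            "start": [r.interval.start for r in dmrs],
            "end": [r.interval.end for r in dmrs],
            "direction": [r.direction for r in dmrs],
            "n_cpg": [r.n_cpg for r in dmrs],
            "mean_diff": [round(r.mean_diff, 6) for r in dmrs],
            "n_sig": [r.n_sig for r in dmrs],
        }
    )


def write_dmrs_bed(dmrs: Sequence[Dmr], path) -> None:
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", header=False, index=False)


def read_dmrs_bed(path) -> list[Dmr]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "direction", "n_cpg", "mean_diff", "n_sig"],
    )
    return [
        Dmr(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            int(r.n_cpg), float(r.mean_diff), str(r.direction), int(r.n_sig),
        )
        for r in df.itertuples()
    ]
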