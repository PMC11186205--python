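"""Methylation hypoxia signature: build from WGBS hyper-DMRs refined by an
RNA-hypoxia-dichotomized array cohort, then score any methylation cohort.

The construction mirrors a two-layer filter: (1) hyper-DMRs called between
hypoxic and normoxic tumor regions, (2) retention of only those DMRs whose
overlapping array probes are significantly more methylated in samples with a
high RNA hypoxia score. The per-sample signature score is the unweighted mean
methylation over the retained regions.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dmrcall import Dmr
from .methio import GenomicInterval, MethylomeSample, intervals_to_frame, frame_to_intervals
from .simdata import CohortMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RNA hypoxia score


@dataclass(frozen=True)
class HypoxiaGeneSet:
    """Up-regulated hypoxia signature genes (Ragnum-style gene list)."""

    gene_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.gene_ids) == 0:
            raise ValueError("gene set is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")


@dataclass(frozen=True)
class RnaHypoxiaScore:
    sample_id: str
    score: float
    group: str  # high | low


def rna_hypoxia_score(expr: CohortMatrix, genes: HypoxiaGeneSet) -> list[RnaHypoxiaScore]:
    """Per-sample hypoxia score: count of signature genes expressed above
    their cohort median, then median dichotomization (ties go to 'low')."""
    values = expr.values
    if len(values) < 2:
        raise ValueError("need >=2 samples")
    present = [g for g in genes.gene_ids if g in values.columns]
    missing = [g for g in genes.gene_ids if g not in values.columns]
    if not present:
        raise ValueError(f"no signature gene found in expression matrix; expected any of {list(genes.gene_ids)}")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix, dropped: {missing[:5]}")
    sub = values[present]
    above = sub.gt(sub.median(axis=0), axis=1)
    score = above.sum(axis=1).astype(float)
    med = float(score.median())
    return [
        RnaHypoxiaScore(str(s), float(v), "high" if v > med else "low")
        for s, v in score.items()
    ]


# ---------------------------------------------------------------------------
# Probe differential


def probe_differential(beta: CohortMatrix, groups: Sequence[RnaHypoxiaScore]) -> pd.DataFrame:
    """Rank-sum test per probe between hypoxia-score groups with BH FDR.

    Returns one row per probe: probe_id, chrom, pos, mean_high, mean_low,
    p, q, hyper_in_high. Probes constant across all samples get p = 1.
    """
    labels = {g.sample_id: g.group for g in groups}
    values = beta.values.loc[[s for s in beta.values.index if s in labels]]
    grp = np.array([labels[s] for s in values.index])
    hi = values.loc[grp == "high"]
    lo = values.loc[grp == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >=2 samples per group")
    mean_high = hi.mean(axis=0)
    mean_low = lo.mean(axis=0)
    pvals = np.ones(values.shape[1])
    hi_m = hi.to_numpy()
    lo_m = lo.to_numpy()
    const = values.nunique(axis=0).to_numpy() <= 1
    testable = ~const
    if testable.any():
        res = stats.mannwhitneyu(
            hi_m[:, testable], lo_m[:, testable], alternative="two-sided", axis=0
        )
        pvals[testable] = res.pvalue
    q = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "probe_id": values.columns,
            "mean_high": mean_high.to_numpy(),
            "mean_low": mean_low.to_numpy(),
            "p": pvals,
            "q": q,
            "hyper_in_high": (mean_high > mean_low).to_numpy(),
        }
    )
    if beta.feature_coords is not None:
        coords = beta.feature_coords.set_index("feature")
        out["chrom"] = coords.loc[out["probe_id"], "chrom"].to_numpy()
        out["pos"] = coords.loc[out["probe_id"], "start"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Signature model


@dataclass
class SignatureModel:
    """Ordered hyper-DMR signature regions with probe support provenance."""

    regions: list[GenomicInterval]
    supporting_probes: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [region_key(r) for r in self.regions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate signature regions")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        intervals_to_frame(self.regions).to_csv(
            outdir / "signature_regions.bed", sep="\t", header=False, index=False
        )
        (outdir / "signature_meta.json").write_text(
            json.dumps(
                {"supporting_probes": self.supporting_probes, "provenance": self.provenance},
                indent=2,
            )
        )

    @classmethod
    def load(cls, outdir) -> "SignatureModel":
        outdir = Path(outdir)
        df = pd.read_csv(
            outdir / "signature_regions.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "name"],
        )
        meta = json.loads((outdir / "signature_meta.json").read_text())
        return cls(frame_to_intervals(df), meta["supporting_probes"], meta["provenance"])


def region_key(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def params_hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def build_signature(
    hyper_dmrs: Sequence[Dmr],
    probes: pd.DataFrame,
    q_cut: float = 0.05,
    dmr_source: str = "wgbs",
    cohort_id: str = "array",
) -> SignatureModel:
    """Retain hyper-DMRs overlapping >=1 probe with q < q_cut that is more
    methylated in the hypoxia-high group; probes are genomic points matched
    by the half-open point-in-interval rule."""
    for d in hyper_dmrs:
        if d.direction != "hyper":
            raise ValueError("build_signature expects hyper DMRs only")
    if "chrom" not in probes.columns or "pos" not in probes.columns:
        raise ValueError("probe table needs chrom/pos coordinates")
    retained = probes.loc[(probes["q"] < q_cut) & probes["hyper_in_high"]]
    regions: list[GenomicInterval] = []
    support: dict[str, list[str]] = {}
    seen = set()
    for d in hyper_dmrs:
        iv = d.interval
        key = region_key(iv)
        if key in seen:
            continue
        inside = retained.loc[
            (retained["chrom"].astype(str) == iv.chrom)
            & (retained["pos"] >= iv.start)
            & (retained["pos"] < iv.end)
        ]
        if len(inside):
            seen.add(key)
            regions.append(iv)
            support[key] = list(inside["probe_id"].astype(str))
    if not regions:
        warnings.warn("no hyper-DMR overlaps a retained probe; empty signature")
    model = SignatureModel(
        regions=regions,
        supporting_probes=support,
        provenance={
            "dmr_source": dmr_source,
            "cohort_id": cohort_id,
            "q_cut": q_cut,
            "params_hash": params_hash((q_cut, len(hyper_dmrs), len(probes))),
        },
    )
    logger.info("build_signature: retained %d of %d hyper-DMRs", len(regions), len(hyper_dmrs))
    return model


# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class MethHypoxiaScore:
    sample_id: str
    score: float  # nan when no region measurable
    n_regions_used: int


def _score_array(model: SignatureModel, meth: CohortMatrix) -> pd.DataFrame:
    if meth.feature_coords is None:
        raise ValueError("array cohort needs probe coordinates")
    coords = meth.feature_coords
    region_means = {}
    for iv in model.regions:
        inside = coords.loc[
            (coords["chrom"].astype(str) == iv.chrom)
            & (coords["start"] >= iv.start)
            & (coords["start"] < iv.end),
            "feature",
        ]
        if len(inside):
            region_means[region_key(iv)] = meth.values[list(inside)].mean(axis=1)
    if not region_means:
        raise ValueError("no model region measurable in the cohort")
    rm = pd.DataFrame(region_means)
    return pd.DataFrame(
        {
            "sample_id": rm.index,
            "score": rm.mean(axis=1).to_numpy(),
            "n_regions_used": rm.notna().sum(axis=1).to_numpy(),
        }
    )


def _score_wgbs(model: SignatureModel, samples: Sequence[MethylomeSample]) -> pd.DataFrame:
    rows = []
    any_measurable = False
    for s in samples:
        sites = s.sites
        means = []
        for iv in model.regions:
            sub = sites.loc[
                (sites["chrom"] == iv.chrom)
                & (sites["pos"] >= iv.start)
                & (sites["pos"] < iv.end)
            ]
            cov = sub["cov"].sum()
            if cov > 0:
                means.append(sub["meth"].sum() / cov)  # coverage-weighted mean
        if means:
            any_measurable = True
            rows.append((s.sample_id, float(np.mean(means)), len(means)))
        else:
            logger.info("score_cohort: sample %s has no measurable region", s.sample_id)
            rows.append((s.sample_id, np.nan, 0))
    if not any_measurable:
        raise ValueError("no model region measurable in the cohort")
    return pd.DataFrame(rows, columns=["sample_id", "score", "n_regions_used"])


def score_cohort(model: SignatureModel, meth) -> pd.DataFrame:
    """Per-sample signature score: unweighted mean over regions with data of
    the region's mean methylation (probe mean for arrays, coverage-weighted
    CpG mean for WGBS). Samples with zero measurable regions get score NaN.

    Returns a frame (sample_id, score, n_regions_used).
    """
    if model.n_regions == 0:
        raise ValueError("empty signature model")
    if isinstance(meth, CohortMatrix):
        return _score_array(model, meth)
    return _score_wgbs(model, list(meth))


def scores_to_list(df: pd.DataFrame) -> list[MethHypoxiaScore]:
    return [
        MethHypoxiaScore(str(r.sample_id), float(r.score), int(r.n_regions_used))
        for r in df.itertuples()
    ]
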