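"""Synthetic cohorts with the statistical structure the pipeline assumes.

One generator produces every input the downstream stages consume:

* paired hypoxic (TP) / normoxic (TN) per-CpG bisulfite tracks with planted
  hyper- and hypo-methylated regions, plus optional benign tracks;
* an array cohort whose probe betas are elevated at planted hyper regions in
  latently hypoxic samples;
* a gene-expression matrix whose hypoxia gene set is shifted in the same
  latently hypoxic samples (the coupling that lets an RNA hypoxia score
  recover the latent labels);
* survival times whose hazard increases with any supplied per-sample score.

A single global seed is expanded into independent child streams (placement,
methylomes, array, expression, survival, clinical) so each stage is
reproducible in isolation and the stages stay decoupled.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .methio import GenomicInterval, MethylomeSample

_STREAMS = ("placement", "methylomes", "array", "expression", "survival", "clinical")

DEFAULT_CHROM = "chrS"


class PlacementError(RuntimeError):
    """Raised when non-overlapping planted regions cannot be placed."""


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohorts.

    Defaults emulate the source study's design where it states one: five
    patients with paired hypoxic/normoxic tumor methylomes (the pairs behind
    the hypoxia DMR comparison), ~30x CpG coverage, a ~100-sample array
    cohort with matched expression, and a hypoxia gene set of 32 genes (the
    size of the Ragnum signature). Effect sizes of real hypoxia DMRs are not
    published; the planted methylation difference defaults to 0.4, comfortably
    above the caller's delta = 0.2 region threshold. Planted regions default
    to ~1 kb with 40 CpGs at island-like density (~25 bp spacing): tumor CGI
    hyper-DMRs are typically 0.5-2 kb and CpG-dense, and a region must both
    exceed the caller's smoothing window with margin (smoothing dilutes the
    methylation difference within half a window of each edge) and keep
    consecutive CpGs closer than the caller's merge distance to be
    recoverable at all.
    """

    n_patients: int = 5
    n_benign: int = 0
    chrom: str = DEFAULT_CHROM
    chrom_length_bp: int = 500_000
    n_cpg: int = 10_000
    mean_coverage: float = 30.0
    baseline_beta_dist: tuple[float, float] = (2.0, 2.0)
    n_planted_hyper: int = 10
    n_planted_hypo: int = 10
    planted_delta: float = 0.4
    planted_len_bp: int = 1_000
    planted_n_cpg: int = 40
    region_buffer_bp: int = 2_000
    n_array_samples: int = 100
    n_array_decoys: int = 400
    n_genes: int = 200
    hypoxia_gene_n: int = 32
    hypoxia_effect: float = 3.0
    hazard_log_hr: float = 1.0
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        n_planted = self.n_planted_hyper + self.n_planted_hypo
        if self.n_cpg < self.planted_n_cpg * n_planted:
            raise ValueError("n_cpg too small for the requested planted regions")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if not 0 <= self.planted_delta <= 1:
            raise ValueError("planted_delta must be in [0, 1]")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_cpg > self.chrom_length_bp:
            raise ValueError("more CpGs than base pairs")
        if self.planted_n_cpg < 2:
            raise ValueError("planted_n_cpg must be >= 2")
        if self.planted_len_bp / (self.planted_n_cpg - 1) > 35:
            raise ValueError(
                "planted regions sparser than ~35 bp/CpG are not island-like; "
                "increase planted_n_cpg or reduce planted_len_bp"
            )
        if n_planted * (self.planted_len_bp + self.region_buffer_bp) > self.chrom_length_bp:
            raise ValueError("planted regions plus buffers exceed the chromosome")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for a named stage stream."""
        idx = _STREAMS.index(stream)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return np.random.default_rng(ss)


@dataclass
class SimTruth:
    """Ground truth of one simulated study: what was planted where."""

    planted_regions: list[tuple[GenomicInterval, str, float]]
    per_sample_hypoxia_label: dict[str, str]
    true_signature_regions: list[GenomicInterval]
    true_betas: pd.DataFrame  # sites x samples latent methylation
    array_hypoxia_label: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_regions": [
                [iv.chrom, iv.start, iv.end, direction, delta]
                for iv, direction, delta in self.planted_regions
            ],
            "per_sample_hypoxia_label": self.per_sample_hypoxia_label,
            "true_signature_regions": [
                [iv.chrom, iv.start, iv.end] for iv in self.true_signature_regions
            ],
            "array_hypoxia_label": self.array_hypoxia_label,
            "true_betas": {
                "index": list(map(int, self.true_betas.index)),
                "columns": list(self.true_betas.columns),
                "values": self.true_betas.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        betas = pd.DataFrame(
            payload["true_betas"]["values"],
            index=payload["true_betas"]["index"],
            columns=payload["true_betas"]["columns"],
        )
        return cls(
            planted_regions=[
                (GenomicInterval(c, s, e), d, float(delta))
                for c, s, e, d, delta in payload["planted_regions"]
            ],
            per_sample_hypoxia_label=payload["per_sample_hypoxia_label"],
            true_signature_regions=[
                GenomicInterval(c, s, e) for c, s, e in payload["true_signature_regions"]
            ],
            true_betas=betas,
            array_hypoxia_label=payload.get("array_hypoxia_label", {}),
        )


def _region_baseline(config: SimConfig, direction: str) -> float:
    """Latent baseline inside a planted region, chosen so baseline +/- delta
    stays inside the clamp range [0.01, 0.99]."""
    a, b = config.baseline_beta_dist
    mean = a / (a + b)
    d = config.planted_delta
    if direction == "hyper":
        return float(np.clip(mean, 0.05, 0.94 - d))
    return float(np.clip(mean, 0.06 + d, 0.95))


def _region_positions(start: int, length: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """CpG-island-like dense positions inside one planted region: a jittered
    regular grid, so adjacent CpGs are 10-45 bp apart as in real islands."""
    spacing = length / (k - 1)
    jitter = min(0.25 * spacing, 8.0)
    grid = start + np.arange(k) * spacing + rng.uniform(-jitter, jitter, size=k)
    pos = np.clip(np.round(grid).astype(np.int64), start, start + length - 1)
    return np.unique(pos)


def _place_regions(config: SimConfig, rng: np.random.Generator):
    """Choose non-overlapping planted intervals separated by the buffer."""
    n_regions = config.n_planted_hyper + config.n_planted_hypo
    L, length, buf = config.chrom_length_bp, config.planted_len_bp, config.region_buffer_bp
    starts: list[int] = []
    for _ in range(10_000):
        s = int(rng.integers(0, L - length))
        if all(abs(s - t) >= length + buf for t in starts):
            starts.append(s)
            if len(starts) == n_regions:
                break
    else:
        raise PlacementError("placement attempts exhausted; reduce regions or buffer")
    starts.sort()
    directions = ["hyper"] * config.n_planted_hyper + ["hypo"] * config.n_planted_hypo
    rng.shuffle(directions)
    return starts, directions


def simulate_methylomes(config: SimConfig) -> tuple[list[MethylomeSample], SimTruth]:
    """Paired TP/TN (plus benign) per-CpG tracks with planted DMRs.

    Counts are Binomial(coverage, latent beta) with Poisson coverage
    truncated at >= 1; the latent beta is shared within a hypoxia class and
    shifted by +/- planted_delta inside planted regions for hypoxic samples.
    """
    rng_place = config.rng("placement")
    rng = config.rng("methylomes")

    # planted regions are CpG-dense blocks (island-like); the background grid
    # is uniform over the rest of the chromosome
    starts, directions = _place_regions(config, rng_place)
    region_pos = [
        _region_positions(s, config.planted_len_bp, config.planted_n_cpg, rng_place)
        for s in starts
    ]
    n_background = config.n_cpg - sum(len(r) for r in region_pos)
    allowed = np.ones(config.chrom_length_bp, dtype=bool)
    for s in starts:
        allowed[s : s + config.planted_len_bp] = False
    bg = rng_place.choice(np.flatnonzero(allowed), size=n_background, replace=False)
    positions = np.sort(np.concatenate([bg] + region_pos))

    a, b = config.baseline_beta_dist
    baseline = np.clip(rng_place.beta(a, b, size=len(positions)), 0.01, 0.99)

    normoxic = baseline.copy()
    hypoxic = baseline.copy()
    planted_regions = []
    for rp, direction in zip(region_pos, directions):
        iv = GenomicInterval(config.chrom, int(rp[0]), int(rp[-1]) + 1)
        lo = np.searchsorted(positions, iv.start, side="left")
        hi = np.searchsorted(positions, iv.end, side="left")
        sl = slice(lo, hi)
        delta = config.planted_delta
        base = _region_baseline(config, direction)
        normoxic[sl] = base
        hypoxic[sl] = base + delta if direction == "hyper" else base - delta
        planted_regions.append((iv, direction, delta))
    planted_regions.sort(key=lambda t: t[0].start)
    normoxic = np.clip(normoxic, 0.01, 0.99)
    hypoxic = np.clip(hypoxic, 0.01, 0.99)

    samples: list[MethylomeSample] = []
    labels: dict[str, str] = {}
    latent_cols: dict[str, np.ndarray] = {}

    def make_sample(sample_id, tissue_class, patient_id, latent):
        cov = rng.poisson(config.mean_coverage, size=len(positions))
        cov = np.maximum(cov, 1)
        meth = rng.binomial(cov, latent)
        sites = pd.DataFrame(
            {"chrom": config.chrom, "pos": positions, "cov": cov, "meth": meth}
        )
        samples.append(MethylomeSample(sample_id, sites, tissue_class, patient_id))
        latent_cols[sample_id] = latent

    for p in range(1, config.n_patients + 1):
        pid = f"P{p:03d}"
        make_sample(f"{pid}_TP", "TP", pid, hypoxic)
        labels[f"{pid}_TP"] = "hypoxic"
        make_sample(f"{pid}_TN", "TN", pid, normoxic)
        labels[f"{pid}_TN"] = "normoxic"
    for k in range(1, config.n_benign + 1):
        sid = f"B{k:03d}_Benign"
        make_sample(sid, "Benign", f"B{k:03d}", normoxic)
        labels[sid] = "normoxic"

    true_betas = pd.DataFrame(latent_cols, index=positions)
    truth = SimTruth(
        planted_regions=planted_regions,
        per_sample_hypoxia_label=labels,
        true_signature_regions=[iv for iv, d, _ in planted_regions if d == "hyper"],
        true_betas=true_betas,
    )
    return samples, truth


# ---------------------------------------------------------------------------
# Array + expression cohort (shared latent hypoxia labels)


@dataclass
class CohortMatrix:
    """Samples x features matrix with optional feature coordinates.

    ``values`` is indexed by sample id with feature ids as columns;
    ``feature_coords`` (when present) maps feature id to a genomic point or
    interval (chrom, start, end).
    """

    values: pd.DataFrame
    feature_coords: pd.DataFrame | None = None
    kind: str = "beta"

    def __post_init__(self):
        if self.feature_coords is not None:
            missing = set(self.feature_coords["feature"]) - set(self.values.columns)
            if missing:
                raise ValueError(f"coords for unknown features: {sorted(missing)[:3]}")


def _cohort_labels(config: SimConfig, truth: SimTruth) -> dict[str, str]:
    """Latent hypoxia status of the array/expression cohort (lazily created,
    shared between the two matrices regardless of generation order)."""
    if not truth.array_hypoxia_label:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(100,))
        )
        status = rng.random(config.n_array_samples) < 0.5
        truth.array_hypoxia_label = {
            f"A{i + 1:04d}": ("hypoxic" if h else "normoxic")
            for i, h in enumerate(status)
        }
    return truth.array_hypoxia_label


def simulate_array_cohort(config: SimConfig, truth: SimTruth) -> CohortMatrix:
    """Methylation-array betas: one probe per planted region plus decoys.

    Probes inside planted regions shift by +/- planted_delta in latently
    hypoxic samples (sign following the region direction); decoys are
    exchangeable between groups. Betas are Beta-distributed around their
    latent mean (concentration 60, array-like noise).
    """
    if not truth.planted_regions:
        raise ValueError("truth contains no planted regions")
    rng = config.rng("array")
    labels = _cohort_labels(config, truth)
    sample_ids = list(labels)
    hyp = np.array([labels[s] == "hypoxic" for s in sample_ids])

    probe_ids, coords, mus = [], [], []
    for j, (iv, direction, delta) in enumerate(truth.planted_regions):
        pos = (iv.start + iv.end) // 2
        base = _region_baseline(config, direction)
        shift = delta if direction == "hyper" else -delta
        probe_ids.append(f"probe_region_{j + 1:03d}")
        coords.append((iv.chrom, pos, pos + 1))
        mus.append((base, shift))
    a, b = config.baseline_beta_dist
    planted_ivs = [iv for iv, _, _ in truth.planted_regions]
    j = 0
    while j < config.n_array_decoys:
        pos = int(rng.integers(0, config.chrom_length_bp))
        if any(r.contains_point(config.chrom, pos) for r in planted_ivs):
            continue  # decoys live outside planted regions by construction
        j += 1
        probe_ids.append(f"probe_decoy_{j:04d}")
        coords.append((config.chrom, pos, pos + 1))
        mus.append((float(np.clip(rng.beta(a, b), 0.05, 0.95)), 0.0))

    kappa = 60.0
    mat = np.empty((len(sample_ids), len(probe_ids)))
    for k, (base, shift) in enumerate(mus):
        mu = np.where(hyp, np.clip(base + shift, 0.01, 0.99), base)
        mat[:, k] = rng.beta(mu * kappa, (1 - mu) * kappa)
    values = pd.DataFrame(mat, index=sample_ids, columns=probe_ids)
    feature_coords = pd.DataFrame(
        {
            "feature": probe_ids,
            "chrom": [c for c, s, e in coords],
            "start": [s for c, s, e in coords],
            "end": [e for c, s, e in coords],
        }
    )
    return CohortMatrix(values, feature_coords, kind="beta")


HYPOXIA_GENE_PREFIX = "HYPX"


def hypoxia_gene_ids(config: SimConfig) -> list[str]:
    return [f"{HYPOXIA_GENE_PREFIX}_{i + 1:03d}" for i in range(config.hypoxia_gene_n)]


def simulate_expression(config: SimConfig, truth: SimTruth) -> CohortMatrix:
    """Log-scale expression: hypoxia-set genes shifted by ``hypoxia_effect``
    standard deviations in latently hypoxic samples; all other genes
    exchangeable between groups."""
    if config.hypoxia_gene_n < 1:
        raise ValueError("hypoxia_gene_n must be >= 1")
    rng = config.rng("expression")
    labels = _cohort_labels(config, truth)
    sample_ids = list(labels)
    hyp = np.array([labels[s] == "hypoxic" for s in sample_ids])

    genes = hypoxia_gene_ids(config) + [
        f"GENE_{i + 1:04d}" for i in range(max(config.n_genes - config.hypoxia_gene_n, 0))
    ]
    mu_g = rng.normal(8.0, 2.0, size=len(genes))
    mat = rng.normal(mu_g[None, :], 1.0, size=(len(sample_ids), len(genes)))
    mat[hyp, : config.hypoxia_gene_n] += config.hypoxia_effect
    values = pd.DataFrame(mat, index=sample_ids, columns=genes)
    return CohortMatrix(values, None, kind="expression")


# ---------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class SurvivalOutcome:
    sample_id: str
    time: float  # months
    event: bool
    endpoint: str = "BCR"

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be positive")
        if self.endpoint not in ("PFS", "BCR", "OS"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")


BASELINE_MEDIAN_MONTHS = 40.0


def simulate_survival(
    scores,
    log_hr: float,
    censor_rate: float,
    seed: int,
    sample_ids: Sequence[str] | None = None,
    endpoint: str = "BCR",
) -> list[SurvivalOutcome]:
    """Exponential event times with hazard proportional to
    exp(log_hr * standardized score) and independent exponential censoring
    calibrated so the event fraction is about 1 - censor_rate."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    lam0 = np.log(2) / BASELINE_MEDIAN_MONTHS
    lam = lam0 * np.exp(log_hr * z)
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        lam_c = lam.mean() * censor_rate / (1 - censor_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=len(scores))
        event = t_event <= t_cens
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(len(scores), bool)
        time = t_event
    time = np.maximum(time, 1e-9)
    if sample_ids is None:
        sample_ids = [f"A{i + 1:04d}" for i in range(len(scores))]
    return [
        SurvivalOutcome(str(s), float(t), bool(e), endpoint)
        for s, t, e in zip(sample_ids, time, event)
    ]


# ---------------------------------------------------------------------------
# Annotation track + clinical table (pipeline plumbing)


def simulate_annotation(config: SimConfig, n_islands: int = 60, island_len: int = 800, seed: int | None = None):
    """Synthetic CpG-island and gene-model tracks on the simulated chromosome.

    Returns (islands, promoters, exons, introns) interval lists; geography
    classes (shore/shelf/open sea) are derived downstream from the islands.
    """
    rng = np.random.default_rng(config.seed + 17 if seed is None else seed)
    L = config.chrom_length_bp
    starts = np.sort(rng.choice(L - island_len, size=n_islands, replace=False))
    islands = []
    last_end = -1
    for s in starts:
        s = int(max(s, last_end + 1))
        e = min(s + island_len, L)
        if e - s < 50:
            continue
        islands.append(GenomicInterval(config.chrom, s, e))
        last_end = e
    promoters, exons, introns = [], [], []
    gene_starts = np.sort(rng.choice(L - 6000, size=max(n_islands // 2, 1), replace=False))
    for g in gene_starts:
        g = int(g)
        promoters.append(GenomicInterval(config.chrom, g, min(g + 1000, L)))
        exons.append(GenomicInterval(config.chrom, min(g + 1000, L - 2), min(g + 1500, L - 1)))
        introns.append(GenomicInterval(config.chrom, min(g + 1500, L - 1), min(g + 4000, L)))
    return islands, promoters, exons, introns


def simulate_clinical(
    n: int = 80,
    seed: int = 0,
    intensity_grade_coupling: float = 1.2,
) -> pd.DataFrame:
    """Clinicopathologic table with one planted association.

    PIMO intensity is coupled to grade group (effect ``intensity_grade_coupling``
    on the latent scale); all other features are independent of intensity and
    of one another.
    """
    rng = np.random.default_rng(seed)
    grade_group = rng.integers(1, 6, size=n)
    latent = intensity_grade_coupling * (grade_group - 3) + rng.normal(0, 2, size=n)
    pimo_intensity = np.clip(np.round((latent + 6) / 3), 0, 3).astype(int)
    pattern_levels = np.array(["negative", "diffuse", "focal", "comedo-like"])
    pimo_pattern = pattern_levels[rng.integers(0, 4, size=n)]
    df = pd.DataFrame(
        {
            "patient_id": [f"PT{i + 1:03d}" for i in range(n)],
            "pimo_pattern": pimo_pattern,
            "pimo_intensity": pimo_intensity,
            "grade_group": grade_group,
            "idcca": rng.integers(0, 2, size=n),
            "pt_category": rng.choice(["pT2", "pT3a", "pT3b"], size=n),
            "lvi": rng.integers(0, 2, size=n),
            "margins_n": rng.poisson(0.7, size=n),
            "epe": rng.integers(0, 2, size=n),
            "psa": np.round(rng.lognormal(2.0, 0.4, size=n), 1),
        }
    )
    return df


CLINICAL_TYPES = {
    "pimo_pattern": "categorical",
    "pimo_intensity": "continuous",
    "grade_group": "continuous",
    "idcca": "binary",
    "pt_category": "categorical",
    "lvi": "binary",
    "margins_n": "continuous",
    "epe": "binary",
    "psa": "continuous",
}
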