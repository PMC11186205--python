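# hypoxomethyl

Tumor hypoxia drives treatment resistance and recurrence in localized
prostate cancer, and it leaves a stable mark on the DNA methylome: loss of
oxygen-dependent TET demethylase activity pushes hypoxic tumor regions toward
hypermethylation. `hypoxomethyl` implements the full computational chain that
turns this biology into a biomarker — from per-CpG bisulfite counts of
hypoxic (pimonidazole-positive) and normoxic (pimonidazole-negative)
laser-microdissected tumor regions, through differential methylation region
(DMR) calling and integration with an RNA-hypoxia-dichotomized methylation
array cohort, to a hyper-DMR signature score that stratifies patient survival
— together with the permutation-based genomic annotation enrichment and
mixed-type clinicopathologic association statistics that accompany such a
study. A synthetic-data module generates every input with the statistical
structure the analysis assumes, so the whole chain is testable end to end
without access to controlled patient data.

It is intended for methylation bioinformaticians and biostatisticians who
want a transparent, fully specified reference implementation of this kind of
signature pipeline.

## The statistics at the core

**DMR calling without replicates.** For groups 1 and 2 with pooled,
window-smoothed methylation proportions μ̃₁, μ̃₂ (coverage-weighted mean over
±250 bp) each CpG is tested with the Wald statistic

    z = (μ̃₁ − μ̃₂) / se,   se² = μ̃₁(1−μ̃₁)/n₁ + μ̃₂(1−μ̃₂)/n₂,

where n_g is the coverage pooled over the group's samples and the smoothing
window. Matched pairs are combined per site with Stouffer's method,
z = Σzᵢ/√k. Regions are maximal chains of same-sign significant sites
(p ≤ 10⁻¹⁶, |Δ| ≥ 0.2) with consecutive sites ≤ 50 bp apart, no
opposite-sign site in between and a running significant fraction ≥ 0.5,
filtered to length ≥ 200 bp, ≥ 5 CpGs and |mean Δ| ≥ 0.2.

**Signature.** Samples of an array cohort are median-dichotomized by an RNA
hypoxia score (count of hypoxia-set genes above their cohort median); a
hyper-DMR is retained iff it contains a probe significantly more methylated
in the hypoxia-high group (rank-sum, Benjamini–Hochberg q < 0.05). The
per-sample score is the unweighted mean methylation over retained regions,
and cohorts are split at the median score for Kaplan–Meier / log-rank
analysis; a univariate Cox model (Newton–Raphson, Breslow ties) quantifies
the hazard per unit score.

**Enrichment and clinical associations.** Region sets are tested against
annotation classes (CpG island / shore / shelf / open sea, gene-model parts)
by uniform random relocation with the add-one empirical p; clinical
associations dispatch on declared variable types — Spearman ρ, Cramér's V
with Fisher's exact p (exact r×c enumeration up to n = 200), or the
correlation ratio η with Kruskal–Wallis p.

## Worked example

```python
import numpy as np
from hypoxomethyl import simdata, dmrcall, hypoxsig, survstats
from hypoxomethyl.simdata import SimConfig

# five patients with paired hypoxic/normoxic methylomes, 10 hyper- and
# 10 hypo-methylated 1-kb regions planted at a 0.4 methylation difference
cfg = SimConfig(seed=42)
samples, truth = simdata.simulate_methylomes(cfg)
pairs = [(samples[2 * i], samples[2 * i + 1]) for i in range(cfg.n_patients)]
dmrs = dmrcall.paired_dmrs(pairs)
hyper = [d for d in dmrs if d.direction == "hyper"]
print(f"{len(dmrs)} DMRs called ({len(hyper)} hyper)")

# array + expression cohort sharing latent hypoxia labels
beta = simdata.simulate_array_cohort(cfg, truth)
expr = simdata.simulate_expression(cfg, truth)
genes = hypoxsig.HypoxiaGeneSet(tuple(simdata.hypoxia_gene_ids(cfg)))
rna = hypoxsig.rna_hypoxia_score(expr, genes)
probes = hypoxsig.probe_differential(beta, rna)
model = hypoxsig.build_signature(hyper, probes)
scores = hypoxsig.score_cohort(model, beta)

# survival stratification by the median-split signature score
outcomes = simdata.simulate_survival(
    scores["score"].to_numpy(), log_hr=1.0, censor_rate=0.3, seed=42,
    sample_ids=list(scores["sample_id"]),
)
groups = survstats.dichotomize(scores)
hi = [o for o in outcomes if groups[o.sample_id] == "high"]
lo = [o for o in outcomes if groups[o.sample_id] == "low"]
lr = survstats.log_rank(hi, lo)
cox = survstats.cox_univariate(scores["score"].to_numpy(), outcomes)
```

Output:

```
20 DMRs called (10 hyper)
signature: 10 regions retained from 10 hyper-DMRs
signature scores: mean 0.728, range 0.445-0.935
log-rank: chi2 = 54.14, p = 1.86e-13 (n_high = 50, n_low = 50)
Cox per-SD log HR = 1.28 (HR = 3.60, Wald p = 1.82e-11)
```

All 20 planted regions are recovered as DMRs of the correct direction; every
hyper-DMR is confirmed by the array layer (10 signature regions, none
spurious); and because survival was simulated with hazard increasing in the
score, the median split separates the groups decisively (log-rank
p ≈ 2×10⁻¹³) with a fitted Cox hazard ratio of 3.6 per score SD.

The same pipeline runs from the shell:

```bash
hypoxomethyl run --outdir pipeline_out --seed 42
```

which writes cytosine reports, DMR BEDs, enrichment tables, the signature
model, scores, Kaplan–Meier step coordinates, survival statistics and
clinical association tables, plus a manifest with parameters, seed and output
hashes. Individual stages are exposed as `hypoxomethyl simulate | dmr |
enrich | signature | survival | clinassoc`.

## Layout

| module | role |
| --- | --- |
| `simdata` | synthetic methylomes, array/expression cohorts, survival, clinical tables |
| `methio` | cytosine reports, bedGraph, BED, TSV matrices, conversion-rate QC |
| `dmrcall` | site filter, smoothing, no-replicate Wald test, region calling, paired consensus |
| `genomeannot` | annotation classes, CpG-island geography, permutation enrichment |
| `hypoxsig` | RNA hypoxia score, probe differential, signature build/score |
| `survstats` | median split, Kaplan–Meier, log-rank, univariate Cox |
| `clinassoc` | typed association dispatch, r×c Fisher exact, cohort summaries |
| `cli` | subcommands and the end-to-end `run` pipeline |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
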