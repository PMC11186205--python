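# Methods

`hypoxomethyl` implements the computational chain from per-CpG bisulfite
counts in hypoxic (PIMO-positive) and normoxic (PIMO-negative) prostate-tumor
regions to a DNA-methylation hypoxia signature and its downstream clinical
statistics. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic cohorts do and do not emulate.

## Differential methylation without replicates

Each group comparison (hypoxic vs normoxic tumor; tumor vs benign) starts
from per-CpG counts. Sites are kept when the read count exceeds
`min_site_count = 5` in at least one sample (strict inequality); all samples
are then placed on the common union grid, with zero counts where a sample
lacks the site.

Because each comparison has no biological replicates, evidence is borrowed
along the genome. Counts are pooled within each group and smoothed with a
coverage-weighted running mean over a `smoothing_span_bp = 500` window
(±250 bp around each site, clipped at chromosome ends). Each CpG is tested
with a two-proportion Wald statistic

    stat = (mu1 - mu2) / se,
    se^2 = mu1 (1 - mu1) / n1 + mu2 (1 - mu2) / n2,

where `mu_g` is the smoothed group proportion and `n_g` the coverage pooled
over the group's samples *and the smoothing window*. The window-pooled `n` is
what makes a no-replicate design testable at all: neighbouring CpGs act as
pseudo-replicates, and a 0.4 methylation difference at 30× coverage reaches
|z| ≈ 15–30 instead of the ≈ 3.4 that a single site's coverage would allow —
without it the region caller's p ≤ 1e-16 stringency would be unreachable at
any realistic coverage. Two-sided p-values come from the standard normal;
smoothed proportions are clamped to [1e-6, 1−1e-6] inside the variance only.
Site-level p-values are deliberately not multiplicity-adjusted: the region
threshold `p_threshold = 1e-16` plays that role.

For the paired design (one hypoxic and one normoxic sample per patient), the
per-pair site tests are combined with equal-weight Stouffer's method,
`z = Σ z_i / sqrt(k)`, and the combined difference is the mean of per-pair
smoothed differences. Sites not testable in every pair are dropped. Pairs are
weighted equally because per-pair coverages are comparable by design;
coverage-weighted Stouffer would be a one-line change.

## Region calling

Region construction runs once per chromosome and per sign, in a single
genomic scan (deterministic and order-independent):

* a site is *significant* when `p ≤ p_threshold` and `|diff| ≥ delta`;
  significant sites of the working sign are anchors, and any site whose
  difference has the opposite sign — significant or not — is a barrier;
* consecutive anchors chain into one run while no barrier lies between them,
  their separation is ≤ `dis_merge_bp`, and the running significant fraction
  (anchors over all grid sites spanned so far) stays ≥ `pct_sig`; ties extend
  the run, so runs are as long as the rules allow. The same scan therefore
  also performs run merging: two all-significant runs 40 bp apart become one
  region, runs 60 bp apart stay separate (at the default 50 bp limit);
* a run spans `[first anchor, last anchor]` in 0-based half-open coordinates
  and is reported iff length ≥ `minlen_bp`, CpG count ≥ `min_cg`, significant
  fraction ≥ `pct_sig`, and |mean difference over all its sites| ≥ `delta`
  with the matching sign.

Defaults are the stringent published setting: `delta = 0.2`,
`p_threshold = 1e-16`, `minlen_bp = 200`, `min_cg = 5`, `dis_merge_bp = 50`,
`pct_sig = 0.5`. `delta` is enforced both per significant site and on the
region mean (the stricter reading). The test suite contains an independent,
deliberately naive re-evaluation of these rules (`tests/oracle_dmr.py`) and
checks exact agreement on hundreds of random small grids.

A direct consequence of `dis_merge_bp = 50` is that a detectable region needs
CpGs spaced well under 50 bp — i.e. CpG-island-like density. Regions on a
sparse background grid fragment into sub-threshold pieces no matter how
strong the methylation difference. This is intended stringency, not a defect:
it confines calls to CpG-dense territory, where hypermethylation events
concentrate.

## Synthetic cohorts

The generator (`simdata`) produces every input the pipeline consumes, from a
single seed expanded into independent child streams per stage.

**Methylomes.** One synthetic chromosome (`chrS`, 500 kb) carries 10,000
CpGs: planted regions are CpG-dense blocks (jittered regular grid, ~25 bp
spacing — island-like), the background is uniform (~50 bp spacing). Latent
per-site methylation is Beta(2, 2) clamped to [0.01, 0.99]; inside a planted
region the baseline is set near the Beta mean and shifted by ±`planted_delta`
in hypoxic samples only (clamped so both levels stay in range). Counts are
Binomial(coverage, latent) with Poisson(30) coverage truncated at ≥ 1. Each
patient contributes a hypoxic (TP) and a normoxic (TN) track; benign samples
share the normoxic latent. Default planted geometry is 1 kb / 40 CpGs: a
region must exceed the 500 bp smoothing window with margin, because smoothing
dilutes the observed difference within half a window of each edge (a 0.3
effect in a 500 bp region leaves a significant core shorter than the 200 bp
minimum length), and its CpG spacing must stay under the 50 bp merge
distance.

**Array + expression cohort.** One latent hypoxia label per sample (fair
coin, default n = 100) couples two matrices: probe betas
(Beta-distributed around their latent mean, concentration 60) with one probe
at each planted-region midpoint plus decoys placed outside planted regions;
and log-scale expression (unit-variance Gaussian) where a 32-gene hypoxia set
is shifted by `hypoxia_effect` (default 3 SD) in hypoxic samples. The labels
are created lazily from a dedicated stream, so array and expression are
consistent regardless of generation order.

**Survival.** Event times are exponential with hazard
`λ0 · exp(log_hr · z)` for the standardized score (λ0 fixed at a 40-month
baseline median), censoring is independent exponential calibrated so the
event fraction ≈ 1 − `censor_rate` (default 0.3).

**Clinical table.** A mixed-type table with one planted association (PIMO
intensity coupled to grade group); every other feature is independent.

What the generator does *not* emulate: multi-chromosome genomes, bimodal
genome-wide methylation, sample-to-sample latent heterogeneity within a
class, batch effects, probe cross-hybridization, informative censoring, and
correlated clinical covariates. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own assumptions — not
performance on real cohorts, where inter-patient variation and smaller effect
sizes will reduce sensitivity.

## Signature construction and scoring

The RNA hypoxia score of a sample is the number of hypoxia-set genes
expressed above their cohort median (the construction of published RNA
hypoxia scores of this type); any numeric per-sample score can be injected in
its place. Cohorts are median-dichotomized with ties assigned to the low
group. Probe-level differential methylation between score groups uses the
two-sided rank-sum test with Benjamini–Hochberg correction; probes constant
across samples get p = 1. A hyper-DMR enters the signature iff it contains
(half-open point-in-interval) at least one probe with q < 0.05 that is more
methylated in the hypoxia-high group. The signature score of a sample is the
unweighted mean over signature regions of the region's mean methylation
(probe mean on arrays; coverage-weighted CpG mean on WGBS); regions without
data in a sample are dropped from its average and the denominator is
reported.

## Annotation enrichment

Feature classes are interval lists; CpG-island geography (shore = ±2 kb
flanks, shelf = the next ±2 kb, open sea = remainder) is derived from the
island track when not supplied. The statistic is the number of query regions
overlapping a class by ≥ 1 bp. The null relocates every region uniformly at
random on its own chromosome, preserving length, with no masking track
(none is published for this analysis); the empirical tail probability uses
the add-one rule `p = (1 + #{perm ≥ obs}) / (n_iter + 1)` (mirrored for
depletion), so p is never zero, and the reported tail follows the sign of the
permutation z-score. Discreteness of overlap counts makes the test mildly
conservative; measured type-I error at α = 0.05 sits near 0.03.

## Survival and clinical statistics

Kaplan–Meier curves and the two-group log-rank test are computed with
lifelines. The univariate Cox model is fit by Newton–Raphson on the partial
likelihood with Breslow tie handling (Efron behind a flag), covariate
centered for stability, convergence at |Δβ| < 1e-9 within 50 iterations.
Degenerate fits are flagged rather than silently reported: a constant
covariate yields coef 0 with flag `degenerate`; a monotone likelihood
(complete separation) is flagged `separation`. The score chi-square at β = 0
is also reported — for a binary covariate on tie-free data it equals the
log-rank statistic, which the tests exploit as a cross-check.

Clinical associations dispatch purely on declared variable types
(binary variables are ordered, hence rank-based): Spearman for
non-categorical pairs, Cramér's V with Fisher's exact p for categorical
pairs, and the correlation ratio η with the Kruskal–Wallis p for mixed pairs.
Fisher's exact test beyond 2×2 enumerates all tables with the observed
margins up to a grand total of 200, and switches to seeded Monte Carlo
(100,000 draws, add-one rule) above that. Percentages in cohort summaries use
half-up rounding at the printed precision.

## Problem sizes used in the checks

The statistical suites run at the scale the package's own study conditions
define: 20 seeds for planted-DMR recovery and for the null caller (5 patient
pairs, 10k CpGs, 30× coverage each), 500 replicates for permutation type-I
error (999 iterations each) and for log-rank null uniformity, 20 seeds of
n = 500 for Cox parameter recovery, 5 seeds for the end-to-end signature run
(n = 100 arrays), and 200 random grids for the region-caller/oracle
equivalence.

## Known limitations

* The per-site test is a smoothed Wald approximation, not a shrinkage-based
  dispersion model; it is exact about its own formula and swappable behind
  the site-test contract.
* Whether CpG counts should be strand-merged before testing is left to the
  caller of the I/O layer (symmetric-CpG merging is not applied by default).
* The shifted-null variant of the site test (testing |diff| ≤ delta rather
  than the point null with a hard delta filter) is not implemented; the hard
  filter is the stricter behavior.
* Permutation enrichment has no gap/mask track, so depleted classes near
  chromosome ends are slightly mis-calibrated on real genomes.
* The r×c Monte-Carlo Fisher p has sampling error ~1/sqrt(draws); exact
  enumeration covers every table the clinical analyses produce.
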