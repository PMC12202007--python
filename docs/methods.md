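# Methods

## Model

Each gene is analysed independently. Let `p ∈ (0,1)` be the proportion of
the gene's expression originating from the maternal copy (the maternal
label is arbitrary; the model is exchangeable under swapping labels, which
corresponds to `L(p; X) = L(1−p; N−X)` and is enforced by tests). The
effect size is the odds `θ = p/(1−p)`.

At heterozygous site `i` with depth `N_i`, the alternate-allele count is

    X_i ~ Binom(N_i, p)      if the alt allele is on the maternal copy,
    X_i ~ Binom(N_i, 1−p)    otherwise.

Which copy carries the alt allele is latent. The inputs are a predicted
phasing `ϕ*_i ∈ {0,1}` (0 = alt on haplotype 1) and switching-error rates
`π_i ∈ [0, 0.5]` for each adjacent site pair. A switching error flips every
downstream assignment, so conditional on the reference site the only
relevant latent state at site `i` is the parity (even/odd) of the number of
switching errors between the reference site and `i`: even means `ϕ*_i` is
effectively correct, odd means it is flipped.

### Parity chain

The reference site is the one with the highest coverage (ties: lowest
position), fixed at parity even — anchoring at the best-measured site
promotes identifiability, since relative phasing is all that statistical
phasers provide. From the reference the parity evolves outward in both
directions as a two-state inhomogeneous Markov chain: stay `1−π_i`, flip
`π_i`. The marginal likelihood

    L(p) = Σ_phasings Π(transition probs) Π(binomial emissions)

is computed by a forward recursion in O(n) — equivalent to the explicit sum
over all `2^(n−1)` phasings, which the test suite verifies to 1e−10
relative error by enumeration. Start/stop transitions common to every path
cancel under posterior normalization and are omitted.

Numerics: the recursion runs in linear space with per-site rescaling (each
site's even/odd emissions are divided by their maximum) and per-step
renormalization of the two-state vector, with all scales re-accumulated in
log space. This is ~3× faster than a `logaddexp` recursion and remains
finite at depths of thousands of reads. Exact `π = 0` and `π = 0.5` are
valid inputs (the recursion has no degenerate branch), and reduce to the
perfectly-phased product and the independent-mixture closed form
respectively.

### Posterior over θ

Prior: `ln θ ~ Normal(0, σ²)`, σ = 1.0 by default. The posterior is
evaluated on a uniform grid of K = 1001 points in `ln θ` over
`[−ln 128, ln 128]` (θ from 1/128 to 128, covering the range seen in real
cohorts; population studies report gene-level θ spanning roughly 0.01–97,
and the last decade at the extremes carries no count information at
realistic depths anyway), normalized by the trapezoid rule. Summaries:

* point estimate: posterior **median** of `log2 θ` (robust on skewed
  grids), reported as `log2_theta` / `theta_median`;
* evidence statistic: posterior **mean magnitude** `E[|log2 θ|]`. When a
  gene carries switching errors the posterior can be bimodal with modes of
  opposite sign; the signed posterior mean cancels between modes and loses
  discriminative power, while the folded mean does not. This statistic
  scores genes in the benchmark and drives the null-simulation p-value;
* equal-tailed credible interval from the interpolated CDF (95% default).

Doubling K changes all summaries by < 1e−4; σ ∈ [0.5, 2] changes benchmark
AUCs by < 0.01 (sensitivity measured on the θ = 0.5/0.75 cohorts below).

### Switching-error rates

Three sources for `π_i`, in order of preference:

1. **SELR predictions** per adjacent pair (below);
2. a user-supplied column in the counts table;
3. the fixed default `π = 0.05`, a typical genome-wide switching-error
   rate for statistical phasers against gold-standard phasing.

The **latent-π** variant replaces all of these: one unknown rate shared by
the gene's pairs is marginalized against a Uniform(0, 0.5) prior (Beta and
point-mass priors are options) using 32-point Gauss–Legendre quadrature —
exact here, because the likelihood is a polynomial in π of degree `n−1`.
One shared scalar (rather than per-site latent rates) is used because
per-pair rates are unidentifiable from one gene's counts at realistic
depths. Marginalizing an unknown π can only widen the posterior relative
to knowing the true π; a simulation test asserts the average credible
interval is never sharper.

### Significance

The null-simulation p-value redraws every site's count as
`Binom(N_i, 1/2)` (θ = 1), keeping depths, predicted phases and π fixed,
and compares the observed `E[|log2 θ|]` against B = 1000 null replicates by
default (B is configurable; larger B sharpens the p-value floor
`1/(B+1)`). At θ = 1 the count law is independent of phasing, so
re-corrupting the predicted phases in the replicates would not change the
null distribution; phases are therefore held fixed. The plus-one estimator
`(1 + #{T_null ≥ T_obs})/(B + 1)` never returns 0. Across genes,
Benjamini–Hochberg step-up FDR control is applied (level 0.05 default) and
`ase_call = (fdr < level)`. "Extreme-ASE" selection takes significant genes
whose `|log2 θ|` is at or above the 0.75 empirical quantile (linear
interpolation) of all analysed genes.

## SELR

A logistic regression predicting the probability that a statistical phaser
switch-errs between an adjacent SNP pair. Features (order frozen and stored
with the model): `min_maf`, `delta_maf`, `log10_dist`, `r2`, `d_prime`,
plus all C(5,2) = 10 pairwise products. Fitting is plain maximum likelihood
(statsmodels Logit; deterministic given data; optional L2). Predictions are
clamped to `[1e−6, 0.5]` before use as transition probabilities — a rate
above 0.5 would mean the phaser is anti-correlated with truth.

No pre-trained model is shipped: training requires a sample with known
truth phasing, which is external data. A synthetic pair generator is
provided instead; it draws MAFs uniform on (0.005, 0.5), distances
log-uniform from 10 bp to ~30 kb, D′ skewed high with `r² ≤ D′²` enforced
(a mathematical constraint of the LD definitions), and labels from a
logistic law whose coefficient signs encode the documented trends (error
up with distance, down with MAF and LD) and whose intercept is solved so
the error prevalence is 3.7%, the class balance typical of a statistical
phaser scored against gold-standard phasing. Coefficient magnitudes were
set once so that held-out discrimination lands in the mid-0.8 AUC range
such phasers show in practice. The generator has no interaction effects,
so fitted interaction coefficients should recover zero — asserted within
3 standard errors.

LD statistics follow the standard definitions: `D = p_AB − p_A p_B`,
`r² = D²/(p_A q_A p_B q_B)`, `D′ = |D|/D_max` with the usual sign-dependent
`D_max`; `D = 0` gives `D′ = 0`; monomorphic panel sites are an error.

## Baselines

* **MajorSite** — exact two-sided binomial test of the single deepest
  site's counts against 1/2 (ties: lowest position). Discards the rest of
  the gene.
* **NaiveSum** — sums counts onto haplotypes using the predicted phasing
  at face value, then the same exact test. Optimal when phasing is perfect;
  any switch error sums wrong counts.
* **Pseudo-phasing** — pools the majority allele of every site (ties: alt);
  structurally anti-conservative under the null (measured type-I error at
  nominal 0.05 is ≈ 0.7 at depth 10 with 10 sites) and therefore excluded
  from AUC comparisons by default.

The exact two-sided test uses the "minlike" convention (sum of outcome
probabilities ≤ the observed one), i.e. `scipy.stats.binomtest`. ROC score
is `−log10 p`.

## Simulator

`simulate_gene` draws the true alt-carrying haplotype uniformly per site,
counts from the binomial law above, and corrupts the *relative* predicted
phasing with independent per-adjacent-pair switches. Defaults follow the
benchmark conditions used throughout: 10 heterozygous sites per gene,
fixed per-site depth ∈ {5, 10, 20}, positives at θ = 0.5 or 0.75 versus
nulls at θ = 1, switch rates 0–12%. Positions are uniformly spaced (500 bp)
so SELR featurization can run end-to-end. An odd-switch cohort variant
rejection-samples switch patterns to odd total parity — the regime where
part of the gene is guaranteed mis-phased — with the per-pair rate
calibrated (via the closed-form conditional rate) so the marginal pair
rate still equals the target.

What the generator emulates: binomial allelic sampling, relative-phasing
corruption with the downstream-flip structure of real switching errors,
and cohort class balance. What it does not: composition from real reads
(variable per-site depths, correlated counts across sites from shared
read spans), allelic mapping bias, genotyping error, or overdispersion.
Passing benchmarks therefore demonstrate correctness of the inference
under the stated generative law, not robustness to alignment artefacts —
those belong to the upstream processing pipeline, which is out of scope
here (the count-level genotyping-error filter is a stand-in, documented
as such).

## Benchmark

AUC is the Mann–Whitney rank statistic (ties ½), cross-checked against
scikit-learn in tests. Cohorts are 1000 positives + 1000 negatives; at
that size the binomial sampling error of AUC is within ±0.03, which is the
tolerance used by the acceptance tests for level comparisons. The
inference-side score is `E[|log2 θ|]` rather than the null-simulation
p-value: within a cohort of identical depths and site counts the p-value
is a monotone transform of the same statistic, so the AUC is unchanged
while the cost drops by a factor of B.

Measured at these settings (assumed π = 0.05 everywhere): AUC ≈ 0.998 at
depth 20, θ = 0.5, 5% switch errors; minimum ≈ 0.995 across 0–10% switch
at depth 20; ≈ 0.86 at depth 5; ≈ 0.78 at θ = 0.75, depth 20, 10% switch.
With switch errors present the ordering is phasing-aware caller >
NaiveSum > MajorSite; with none, NaiveSum is on par (|ΔAUC| ≤ 0.01).

## I/O and filters

Counts TSV: `gene_id chrom pos ref alt totalCount altCount phase [pi]`
(π on each row refers to the gap to the next row of the same gene). VCF
extraction keeps phased heterozygous biallelic SNVs only; "0/1" genotypes
are counted and warned about, never silently phased; GT "1|0" → phase 0,
"0|1" → phase 1. Coordinates are 1-based internally; gene maps are BED
(0-based half-open) or `gene_id  chrom:start-end` TSV.

Site thinning removes sites closer than a read length so no read is
counted twice: greedy by descending depth (ties: lower position), which
makes the output deterministic and independent of input order. Genomic
distance is used rather than transcript distance — conservative within an
exon (genomic ≥ transcript distance there); across introns it can
under-thin, which matters only for reads spanning exon junctions between
two kept sites. The genotyping-error filter removes sites with
`X = 0` or `X = N` at depth ≥ 20 (suspected genotype miscalls) and sites
below a minimum depth; both thresholds are configurable and the filter can
be disabled.

## Reproducibility

All randomness flows through `numpy.random.Generator`. Cohort simulation
is deterministic given its config seed. Per-gene null simulations use
substreams keyed by (global seed, CRC32 of gene id), so results are stable
under gene reordering. `scripts/acceptance.py --seed S` derives all cohort
seeds from S.

## Known limitations

* The phasing-error model only represents switch errors between adjacent
  sites; isolated genotype-flip errors at a single site are not modelled
  (the count-quality filter catches the gross cases).
* Genes are analysed independently; no strength is borrowed across genes.
* The likelihood anchor (highest-coverage site) is assumed correctly
  phased relative to itself by construction, but its *counts* still enter
  the likelihood; a pathological anchor (e.g. mapping bias at that one
  site) biases the gene.
* The grid truncates |log2 θ| at 7; genes with essentially mono-allelic
  expression at high depth are reported at the boundary.
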