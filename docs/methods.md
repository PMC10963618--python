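# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator's construction, the defaults and the numerical
choices, in the package's own terms.

## Differential expression

**Model.** Counts for feature *f* in sample *j* are negative binomial with
mean μ and common dispersion φ, Var = μ + φμ². Library sizes are equalized
by scaling each sample's counts to the mean library size and rounding
("pseudo-counts"), which plays the role of total-count offsets.

**Dispersion.** A single common φ is estimated by a ratio-of-sums method of
moments: within each group, E[s² − m̄] = φμ² and E[m̄² − s²/n] = μ², so

    φ̂ = Σ_f Σ_g w_g (s² − m̄) / Σ_f Σ_g w_g (m̄² − s²/n_g),  w_g = n_g − 1,

clipped to [10⁻⁶, 10]. The ratio-of-sums form matters: a per-feature
median underestimates φ at small n because s² is right-skewed, which makes
the test anticonservative (observed type-I ≈ 0.07 instead of 0.05 at
n = 4 + 4; the pooled estimator restores ≈ 0.05).

**Exact test.** For groups A and B with equalized per-group sums
S_A + S_B = s, each group sum is NB with shape r_g = n_g/φ̂. Conditioning
on s removes the unknown mean: P(S_A = a | s) ∝ C(a + r_A − 1, a) ·
C(s − a + r_B − 1, s − a), a negative hypergeometric. The two-sided
p-value is the total probability of splits no more likely than the
observed one (method of small p-values). For large s the support is
truncated to ±12 conditional SDs around the mode (always including the
observed split); the discarded tail mass is ≪ 10⁻¹⁰.

**Calls.** log₂FC = log₂((m̄_B + 0.5)/(m̄_A + 0.5)) — the 0.5 pseudo-count
guards zeros; calls use strict inequalities |log₂FC| > 1 and BH-adjusted
p < 0.05. With one sample per group the test is instead an exact binomial
of the feature's count split against the library-size ratio, with the BH
step-up applied as a q-value estimate and the stricter q < 0.01 gate.
One replicate-path statistic is used for all three biotypes; its
calibration is verified by simulation rather than by reproducing any
particular R package's internals.

**Contrast orientation** is log₂FC = log₂(B/A) for contrast (A, B), with
the default contrast list (CON, MOD), (MOD, TRT).

## Targeting

Seed matching scans the transcript for exact reverse complements of the
miRNA seed (positions 2–7, the "core"); a match to position 8 immediately
5′ of the core and/or an A immediately 3′ of it upgrade the class
(8mer > 7mer-m8 > 7mer-A1 > 6mer). Every core occurrence is reported with
its strongest class; the default acceptance threshold for a target pair is
7mer-A1. G:U wobbles are not counted. Full hybridization-energy scoring is
deliberately out of scope: seed class is the dominant determinant of
targeting, no published score cut-off was available to mirror, and exact
seed semantics make the stage testable against planted truth.

Cis targets pair a lncRNA with any coding gene on the same chromosome
whose boundary gap is ≤ the window (overlap ⇒ distance 0); both printed
windows (10 kb, 100 kb) are supported, default 100 kb, strand ignored.
Trans targets require both features expressed (TPM > 0.1) in more than 5
shared samples and Pearson |r| ≥ 0.9 over all shared samples (the trans
correlation threshold is a package default; only the cis windows, the
>5-sample rule and the −0.85 ceRNA threshold are fixed by convention).

## Anti-correlation filter and triplets

For each targeting-supported pair the Pearson correlation is computed on
the TPM scale over the samples of the contrast's two groups (maximizing n
for the contrast while keeping the edge set contrast-specific); an edge
survives iff r < −0.85, strictly. Triplets are the per-miRNA cross product
of surviving lncRNA and mRNA partners, kept when the lncRNA and mRNA move
in the same differential direction and the miRNA in the opposite one —
the sponge-consistent patterns (lnc↑, mi↓, mRNA↑) and (lnc↓, mi↑, mRNA↓).
A `require_directions=False` escape hatch exists because the direction
constraint is a modelling convention, not a mathematical necessity. No
additional positive lncRNA–mRNA correlation is required. The network is
the tripartite union of triplet edges.

## Centrality and key lncRNAs

Degree is the undirected edge count; betweenness is unnormalized Brandes
accumulation with each unordered pair counted once (the CytoNCA undirected
convention; a `normalized` flag divides by (n−1)(n−2)/2). Key lncRNAs are
ranked by degree, ties broken by betweenness, then lexicographically by id
for determinism; the cut k is user-chosen (default 7). A combination rule
reducing DC and BC to a single published cut-off does not exist, so the
simplest deterministic rule using both criteria was adopted.

## Enrichment

Hypergeometric upper tail p = P(X ≥ k), X ~ HG(N, K, n), per term, BH
across terms, significance at adjusted p < 0.05; terms are consumed as
generic GMT files (no live GO/KEGG queries — database-snapshot term lists
are inherently non-reproducible). The optional length-bias correction fits
a monotone P(DE | length) by isotonic regression over length-decile bins
and replaces each p-value with a Monte-Carlo tail probability under
study-set resampling weighted by the fitted probabilities (Gumbel top-k
sampling without replacement; p = (1 + hits)/(1 + draws); 10,000 draws by
default, seeded). With uniform weights this estimator converges to the
hypergeometric p (within ±0.01 at 10,000 draws), which is the
implementation's internal consistency check. The default is the plain
hypergeometric test.

## Synthetic data generator

The generator emulates the *statistical structure* the analysis assumes,
not the sequencing process:

* **Background**: counts i.i.d. NB(μ_f, φ) across samples, baseline means
  log-normal (median 200, log-sd 1), φ = 0.1 — typical bulk RNA-seq
  magnitudes. All counts are floored at 1 so no feature has zero variance.
* **Perturbation layout**: the middle group (MOD) is perturbed; CON and
  TRT sit at baseline, mirroring a treatment that reverses the disease
  signature. Every planted feature is therefore differential in both
  consecutive contrasts with opposite directions.
* **Planted DE**: 40 features per biotype with the perturbed group's mean
  scaled by 2^±1.5 (alternating up/down) — comfortably beyond the
  |log₂FC| > 1 calling threshold.
* **Sponge triplets** (10 by default): a shared latent factor
  u_s = g_s + ε_s (g = ±1 by group, jitter sd 0.1) drives the miRNA and
  its two targets with opposite linear loadings: the count mean is
  μ·(1 ± a·u)·N, with a = (2^1.5 − 1)/(2^1.5 + 1) so the group fold
  equals the planted log₂FC, N a unit-mean log-normal residual, and
  Poisson sampling on top. The residual CV c is calibrated in closed form
  from r = −S/(S + c²(1+S) + 1/μ), S = a²(Var(g) + σ_ε²), so the
  *count-scale* Pearson correlation hits the configured −0.95. The loading
  is linear rather than log-linear because correlations are evaluated on
  the TPM scale, where log-scale coupling attenuates strongly. Triplet
  baseline means are floored at 300 to keep the Poisson term small.
* **Sequences**: miRNAs are random 22-nt RNAs with pairwise-distinct seed
  cores, additionally constrained so no miRNA's embedded site string
  contains another's core. Each planted (miRNA, transcript) pair gets one
  embedded site (8mer by default) at a random interior position; all
  transcripts are then screened so that no site of class ≥ 7mer-A1 (the
  default prediction threshold) survives anywhere outside the planted
  sites, by point-mutating offending cores until the scan is clean
  (bounded passes). Plain 6mers are left alone — they sit below the
  prediction threshold, and forbidding them everywhere is combinatorially
  wasteful. Screening at the prediction threshold rather than only at the
  embedded class keeps chance 7mers from contaminating precision scoring.
* **Coordinates**: planted cis pairs at boundary gaps 5 kb / 50 kb /
  250 kb (below, inside, beyond the windows) on a dedicated chromosome;
  all other features live on per-biotype chromosomes so the planted pairs
  are the only cis pairs.
* **Terms**: random member sets plus two terms concentrated in planted DE
  mRNAs, recorded as enriched in the truth.

Fixed seed ⇒ bit-identical outputs; all sub-stages draw from seed-derived
independent streams.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: per-gene dispersion heterogeneity and
outliers, batch effects, GC/length-dependent coverage, isoform structure,
imperfect/non-canonical miRNA sites, wobble pairing, and secondary
structure. Recovery metrics on this generator certify the pipeline's
correctness, not field performance on noisy tissue RNA-seq.

## Problem sizes and defaults

The default simulation is 500 features per biotype over 3 × 8 samples
with 10 triplets — large enough that TPM compositionality is negligible
(with ≲ 40 features the planted rows dominate library size and distort
correlations) while a full replicate runs in a few seconds. Recovery
statistics in the acceptance checks average 20 seeded replicates; the
reproduction script uses 5. Degenerate inputs are errors, not silent
fixes: all-zero samples, missing group labels, missing DE calls, zero
variance (dropped per-pair with a warning in the edge filter, fatal in
`pearson_r`).

## Known limitations

* One DE statistic serves all biotypes and both replicate regimes ≥ 2;
  there is no dispersion shrinkage or per-feature empirical Bayes.
* miRanda/TargetScan-style energy and context scoring is replaced by seed
  classes; non-canonical sites are invisible.
* The trans-target correlation threshold and the key-lncRNA count k are
  conventions, not derived quantities.
* The "expressed in > 5 samples" rule uses a fixed TPM floor (0.1).
* Enrichment assumes the supplied background equals the measured universe.
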