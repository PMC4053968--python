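# Methods

This note documents the models, defaults and numerical choices behind
`lncsel`, and what the synthetic cohort does and does not emulate.

## The scientific question

Whether mutations inside intergenic lncRNAs are removed by purifying
selection is a population-scale question: between-species conservation
integrates selection over millions of years, while the site-frequency
spectrum (SFS) of segregating variants reflects selection acting now.
The nearly neutral expectation is that a deleterious mutation with
scaled effect |Nes| ≲ 1 behaves as neutral, so identical per-mutation
fitness effects produce visible constraint in a large-Ne species
(Drosophila, Ne ~ 1.5×10⁶; selection acts down to |s| ~ 7×10⁻⁷) and
effective neutrality in humans (Ne ~ 10³–10⁴; threshold |s| ~ 7×10⁻⁵,
taking the upper printed Ne bound of 15,000). The package's two presets
encode exactly this contrast.

## Selection and sampling model (simulator)

Scaled selection uses the additive convention γ = 4·Ne·s throughout
(negative = deleterious); a single stated convention avoids factor-of-2
drift between the simulator and the estimator.

Segregating sites are drawn from the standard equilibrium
influx-stationary density of the Wright–Fisher diffusion,

    f(q) ∝ (1 − e^{−γ(1−q)}) / ((1 − e^{−γ}) · q(1−q)),   0 < q < 1,

normalized so the neutral limit is 1/q. Sample allele counts at size n
integrate f against the binomial kernel,
P(k) ∝ ∫ f(q)·C(n,k) q^k (1−q)^{n−k} dq, evaluated on a fixed 4096-point
midpoint grid; for neutral classes this reproduces P(k) ∝ 1/k exactly
(analytically, and to ~10⁻⁴ relative on the grid). The number of
segregating sites per class is Poisson with mean θ·L·Σₖ P(k), which
makes π̂ and θ̂_W unbiased for θ under neutrality and automatically
reduces the SNP yield of deleterious classes.

Gamma-DFE classes draw each SNP's |γ| from the DFE *conditioned on the
site segregating* (weights ∝ DFE density × segregating yield), snapped to
a 64-point log grid for count sampling; the snapped value is recorded as
the site's true γ. This is a deliberate approximation: strongly
deleterious draws almost never segregate, and the conditioning keeps the
realized spectrum consistent with the analytic mixture the estimator
assumes.

Outgroup tracks apply, per base, the Jukes–Cantor end-state substitution
probability p = (3/4)(1 − e^{−4dw/3}) with branch divergence d scaled by
the class's relative fixation probability w(γ) = γ/(1 − e^{−γ}) (w = 1
neutral, < 1 deleterious). Drawing a uniformly random different base at
probability p reproduces the JC end-state distribution, so double hits
occur at the realistic rate and parsimony polarization has a small,
divergence-dependent error rate. Outgroups are coordinate-identical to
the reference (gap-free by construction); real MAF/axt ingestion is out
of scope.

Conservation scores are per-base Beta draws with class-specific
parameters (fly defaults: exons of protein-coding genes Beta(8,2),
lncRNA exons Beta(3,3), introns/intergenic Beta(1,6)); they emulate the
*marginal distribution* of a conservation track, not its spatial
autocorrelation.

### What the generator does *not* emulate

No linkage disequilibrium, recombination maps, selective sweeps or true
background-selection structure (an optional per-class θ rescaling stands
in for the two-epoch effect on diversity levels); no alignment gaps; no
spatial autocorrelation in conservation scores; ref allele always equals
the ancestral state. A green end-to-end test therefore establishes that
the estimators recover the *stated* generative world, not that they are
robust to alignment error or linked selection.

### Preset calibration (the stated world)

Fly preset: n = 162 haplotypes, filters "≥10 reads, ≥150 unambiguous
strains", θ = 0.01/site, outgroup divergences 0.06/0.12, lncRNA-exon DFE
gamma(shape 0.5, mean |Nes| 1.1846) — the mean is fixed once so that the
gamma CDF puts 64.18% of mutations below |Nes| = 1, the reported
effectively-neutral fraction. Human preset: n = 348 haplotypes, θ =
1.5×10⁻³, divergences 0.012/0.06, lncRNA classes neutral, near-indel and
quality filters (the quality cutoff default of 30 rejects ~0.1% of true
sites under the simulator's N(60,10) quality model, standing in for the
irreproducible 0.1%-FDR threshold). The human preset simulates a larger
genome (2 × 1.5 Mb) because its per-site diversity is ~7× lower and SFS
inference needs adequate class-wise SNP counts.

## Polarization

Strict maximum parsimony: the ancestral allele is the base carried
identically by both outgroups when that base is one of the two
segregating alleles; everything else (disagreement, third state, N or
gap, missing track) is ambiguous and removed. A "nearest" policy
(nearest outgroup wins unless the farther one carries the opposite
allele; falls back to the farther outgroup when the nearest is unusable)
is provided but off by default — unanimity is the most conservative
reading and its error rate under the JC model is bounded by the
double-hit probability (~(p₁/3)(p₂/3) per site).

## Popgen estimators

Per-site π uses the unbiased 2p̂(1−p̂)·n/(n−1) per segregating site;
θ_W = S/(a₁L); Tajima's D uses the standard constants (a₁, a₂, b₁, b₂,
c₁, c₂, e₁, e₂) and is NA at S = 0 (excluded from class averages).
Class-level tables report per-locus means with standard deviations
rather than pooled estimates (pooling is available); this matches the
"average (SD)" presentation style and weights loci equally. Fixed n per
stratum: sites with missing calls are removed by the n_called filter,
not projected.

## Neutral proxies

Small introns: ≤86 nt pc introns of genes that are direct neighbours
(nearest on either side, ties to smaller distance then the 5′ side) of a
lncRNA within 5 kb, trimmed 6 nt (5′) and 16 nt (3′) in transcript
orientation — the trims remove splice-functional sequence. Ancestral
repeats: intergenic ARs within 10 kb of the lncRNA span (5/20 kb
alternates available). Matched flanks: for each lncRNA with N analyzable
exonic sites, exactly N positions sampled uniformly without replacement
from its flanking intergenic blocks after conserved-element masking,
requiring ≥1,000 usable nt (loci failing this are excluded and logged).
Masking has two modes: window identity (≥90% over a 20-nt sliding
window against the nearer outgroup — the literal rule, appropriate for
deeply diverged comparators) and score-based (conservation ≥ 0.8),
which the pipeline uses because at the synthetic divergences (d ≤ 0.12)
nearly all neutral background exceeds 90% identity per 20-mer and the
identity rule would mask everything. Distances are between closest
interval edges. Masking is idempotent.

## Selection tests

The MK contrast compares polymorphic/divergent counts in lncRNA exons
(or introns) against the locus-matched neutral sites with a Pearson χ²
(1 df), no continuity correction (counts are large in intended use;
correction is switchable); a zero margin is an error, not a 0. DAF
spectra are compared with two-sample KS tests (asymptotic p), reporting
the DAF ≤ 0.01 fractions and the composition-split (G:C→A:T, A:T→G:C)
subsets. The Bonferroni family is all tests emitted by one pipeline run,
and family membership is written to the test table so any other grouping
can be reproduced.

## DFE inference

Expected folded spectra come from a discrete Wright–Fisher grid of
2·N_ref+1 frequency classes (N_ref = 100 by default) with haploid
selection s = γ/(4·N_ref) — the standard small-grid rescaling that
preserves γ. The influx-stationary interior spectrum solves
f = fP + e₁ directly (a linear solve, the exact fixed point of the
generation iteration). The recent size change multiplies the mutation
influx by r and applies the transition matrix for round(t2·r·2·N_ref)
generations on the same grid; this captures the transient young-allele
excess of an expansion as a documented approximation rather than
regridding to the new size. Sample spectra are binomial down-samples
conditioned on segregating; because the grid bias is O(1/N_ref), every
spectrum is computed at N_ref and 2·N_ref and Richardson-extrapolated
(2f₂ − f₁), giving <1% per-bin error against the closed-form density
route even at γ = −50 (the convergence was checked at N_ref ∈ {50, 100,
200}). The gamma DFE is integrated over a fixed 32-point log-spaced |γ|
grid truncated at 2·N_ref, with cell weights from gamma-CDF differences
(first cell absorbs mass below the grid, last the tail), and mixes
*unnormalized* spectra so each coefficient contributes in proportion to
its segregating yield.

Likelihoods are multinomial, conditional on S — this removes the
mutation-rate scaler from the optimization — over folded bins (folding
also immunizes the fit against polarization error). Optimization is
Nelder–Mead on log-scale parameters from fixed multi-starts (8 for
demography, 9 for the DFE), bit-reproducible. Two nested-model parsimony
tie-breaks handle flat likelihood ridges: (1) at t2 → 0 the size ratio r
is unidentifiable, so the equilibrium model is reported unless the
two-epoch fit gains > 2 log-units; (2) with no selection signal the
gamma-DFE boundary (mean → 0) is flat, so the effectively-neutral
solution is reported unless the DFE gains > 2 log-units. Without these,
the reported point estimates are arbitrary ridge points. Bin proportions
over |Nes| ∈ [0,1), [1,10), [10,100), [100,∞) come from the gamma CDF;
bootstrap CIs resample sites with replacement within each locus (B = 200
by default) and refit with cached spectra.

## Conservation profiles

Features are split into 10 strand-oriented portions by integer position
splitting with remainder bases assigned to the earlier windows (the rule
is fixed and tested). The per-decile statistic is the median over
features of per-portion median scores; CIs are percentile bootstraps
over features (the feature, not the base, is the resampling unit).
Control envelopes draw 1,000 interval sets from intergenic sequence
>1 kb from any annotated gene, one interval per target feature with
identical length, and report the 2.5/97.5 percentiles of set medians.
Splice-site information content is IC = 2 − H (log base 2) per alignment
column over ungapped bases; columns with fewer than 3 ungapped bases are
dropped, and gaps are excluded rather than treated as a fifth symbol
(switchable). Controls sample GT/AG occurrences in flanking intergenic
sequence, matched 1:1 in count with the real sites.

## Positional equivalence

Each lncRNA is anchored to its nearest flanking protein-coding gene
(edge distance; ties toward the lncRNA's 5′ side); "same location" means
the same side of the anchor in the anchor's orientation — no distance
criterion is applied, distance is only reported. A pair is positionally
equivalent when both species' lncRNAs anchor to 1-to-1 orthologous genes
with identical side and identical relative orientation; anchored lncRNAs
whose orthologous anchor carries a lncRNA with mismatched side or
orientation form the control set. The relation is symmetric and PE and
control sets are disjoint by construction.

## Orchestration and determinism

One run seed is fanned out to named per-stage substreams (stage-name
CRC mixed with the seed, kept below 2³¹), so toggling stages never
perturbs the others and reruns are byte-identical. Resample counts
default to 10,000 (metagene bootstraps) / 1,000 (control sets,
single-site resamples) / 200 (DFE bootstraps); the `ci` scale divides
these by 10 for fast runs. The splice-site sub-stage runs only where
splice alignments exist (the fly-style cohort); the human-like preset
logs it as skipped.

## Known limitations

- The two-epoch treatment on a fixed grid models the expansion signature
  as a transient; a long second epoch re-equilibrates to the ancestral
  shape, so very old size changes are under-detected.
- The DFE is identified from folded spectra only; shape and mean are
  individually noisy at realistic SNP counts (the bin proportions, which
  are what is reported, are much better determined).
- Sites are treated as independent (no linkage); bootstrap CIs are
  accordingly optimistic relative to data with LD.
- The window-identity masker and the positional-equivalence caller
  assume gap-free coordinate-aligned outgroups, as produced by the
  simulator.
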