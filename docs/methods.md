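# Methods

## Read-origin genotype-pair model

Each site is scored over the full grid of genotype pairs `(k_g, k_t)`,
`k_g ∈ 0..n_g`, `k_t ∈ 0..n_t`, where `n_g`/`n_t` are the locus copy
numbers of normal and tumour cells from the segment file (diploid fallback
for uncovered sites, with a gap counter). Pairs are labelled REF
(`k_g = k_t = 0`), SOMATIC (`k_g = 0, k_t ≥ 1`) or GERMLINE (`k_g ≥ 1`).
No evolutionary constraint links `k_g` and `k_t`: LOH can delete germline
alleles from the tumour genome, so the full grid is kept.

A sample with aberrant cell fraction `α` draws a read from a tumour cell
with probability `π = α·n_t/(α·n_t + (1−α)·n_g)`; cells contribute reads in
proportion to abundance times local copy number. Given the cell of origin
the read reports the alt base with probability `f(1−e) + (1−f)e/3` where
`f` is that cell's mutant-allele fraction — a uniform substitution error
model in which a miscall lands on a specific wrong base with probability
`e/3`. Counts mode treats every non-alt read as reference (count tables do
not record the other two bases); per-read mode converts each read's Phred
quality to `e = 10^(−Q/10)`. When one cell class has zero copies it
contributes no reads (`π` handles this); a fully degenerate locus
(`α·n_t + (1−α)·n_g = 0`) raises an error.

Both samples are scored with the same machinery: the tumour with `α_t`, the
matched normal with its own `α_n` (the TiN level). This is the entire
difference from conventional calling, and setting `α_n = 0` reduces to it
exactly (a property the tests verify on a deterministic grid).

**Priors.** REF takes `1 − p_snp − p_somatic`; `p_snp` (default `1e-4`,
roughly the heterozygous-SNP rate per base) is split equally over germline
pairs and `p_somatic` (default `6e-6`) over somatic pairs, mirroring
conventional defaults in this caller family. A site is classified at
posterior threshold 0.95 (SOMATIC first, then GERMLINE, then REF, else
UNCLASSIFIED). All of these are configurable.

**Numerics.** Likelihoods accumulate in log space; normalization uses
max-subtraction; an impossible read yields `−inf` rather than an exception,
and a site where every pair is impossible falls back to a uniform posterior
flagged UNCLASSIFIED. The suite checks the posterior against a brute-force
per-read product enumeration to `1e-10` per pair.

## TiN estimation

`α_n` is estimated by maximizing the summed log marginal likelihood of
candidate sites over a grid (default step 0.005, ceiling 0.5), with the
genotype pair marginalized out per site under the calling priors. A
one-dimensional bounded grid search was chosen over EM because it is exactly
checkable against a direct-summation oracle and cannot converge to a local
optimum. Ties break toward smaller `α_n` (less assumed contamination); grid
points within 1.92 log-units of the maximum form the ~95% profile interval.
Candidate gates — tumour VAF ≥ 0.10, normal VAF ≤ 0.35, both depths ≥ 10,
at least 50 survivors for a confident estimate — keep only sites that can
move the profile; they are pragmatic defaults, configurable. `α_t` is taken
as given (from configuration or an upstream purity estimate) rather than
estimated jointly; the profile is one-dimensional by design. The production
calling default is a fixed `α_n = 0.10`, the level generally sufficient to
recover contaminated variants in practice; the estimator is for checking
and overriding it per sample.

## GLOD indel rescue

Indel error profiles differ enough from SNVs that the genotype model is not
re-run; instead, indels rejected upstream for matched-normal evidence are
re-examined with a single binomial contrast on the normal counts:

    GLOD = log10 B(a_n; d_n, 0.5·ξ) − log10 B(a_n; d_n, clamp(v_t·α_n/α_t))

with the somatic leakage probability clamped to `[1e-3, 0.5]` and `α_t`
floored at 0.01. `ξ` (default 0.9) absorbs the systematic undercounting of
indel-supporting reads by aligners. A flagged candidate with GLOD below the
threshold (default 0) is rescued; unflagged candidates are never touched.
This two-stage recover-then-filter form, and its constants, are a
reconstruction of common practice; everything is configurable and the score
is verified against an independent log-gamma binomial computation.

## CCF and clone trajectories

Variant CCF uses the standard purity/copy-number correction with
multiplicity by rounding the raw mutation-copy estimate into
`[1, max(n_t, 1)]`; CCFs above 1.5 are clamped and flagged (values slightly
above 1 are ordinary sampling noise and kept). Clone-level CCF is twice the
median VAF of the clone's diploid autosomal SNVs — median for robustness to
a stray member, doubled because a diploid het VAF of 0.5 means every cell —
capped at 1 with a flag; clones without diploid autosomal members fall back
to the mean variant CCF, flagged by provenance. Cluster assignments come
from an external file; clustering itself is out of scope.

The longitudinal coordination check asks whether a clone's members move
together between consecutive timepoints. A pair of timepoints is
*informative* when the median absolute per-member VAF change exceeds twice
the pooled binomial standard error of the median change; an informative
pair passes when at least 80% of members move in the majority direction,
and the clone passes when every informative pair does (score = smallest
agreeing fraction). The informativeness rule is deliberately based on the
median absolute change, not the median signed change: a clone split into
equal rising and falling halves has median signed change zero yet is
exactly the incoherent case the check must fail. Clones with fewer than 3
members or 2 timepoints are UNSCORED, never passed or failed.

Fishplot export repairs nesting violations — children clamped into their
parent, sibling groups rescaled proportionally onto the parent, rootless
clones nested in an implicit root of CCF 1 — so the output satisfies
`child ≤ parent` and `Σ siblings ≤ parent` exactly. Every violation is
repaired; only excesses beyond 0.05 CCF (more than routine sampling noise
at typical depths) are logged as repairs. Cyclic parent relations and
variants assigned to two clones are hard errors.

## Simulator and benchmark

The generator draws alt counts binomially with the per-read alt probability
computed by the *same* formula the caller scores — the simulator and model
are consistent by construction, and a test confirms empirical alt fractions
match expectations within 3 standard errors over ~10⁵ reads. Truth classes
are REF, GERMLINE_HET (`(1,1)` at diploid loci) and SOMATIC (`(0, m)`, `m`
uniform on `1..n_t`); these are the contrasts the benchmark needs. Default
study conditions: tumour purity 0.8, tumour depth 80, normal depth 40, base
error 0.01, TiN grid {0, 0.05, 0.10, 0.20} spanning the contamination range
observed in contaminated haematological cohorts (up to ~18%);
TiN-estimation cohorts use 500 somatic sites at depth 60. Seeding is
per-site: each site's stream is keyed by (seed, TiN level, class, site
index), so any subset regenerates identically regardless of what else is
simulated.

The benchmark reports, per (true TiN, assumed TiN): sensitivity on somatic
sites, specificity on non-somatic sites, and the *rescued fraction* — among
true somatic sites the assumed-TiN-0 baseline missed, the fraction a
TiN-aware configuration recovers. Empty denominators are reported as
missing, never zero. At the default conditions the matched configuration
rescues ≳ 98% of baseline misses at 10–20% true TiN with sensitivity
≥ 0.99, while the germline false-positive rate stays at 0 for assumed TiN
up to 0.2 — numbers the acceptance script recomputes from scratch on every
run.

## Known limitations

* Counts mode collapses the four-base error model to alt/ref; sites whose
  "ref" reads contain a second variant allele should be split upstream.
* The simulator draws independent binomial reads: no mapping artefacts,
  strand bias, overlapping mates or error-rate heterogeneity, so passing
  benchmarks bound statistical, not artefactual, behaviour on real data.
* Timepoints are called independently; joint multi-timepoint likelihoods
  are out of scope (coordination is checked downstream instead).
* `α_t` is an input; a badly wrong purity biases both calling and the TiN
  estimate in the direction of the error.
* GLOD constants (`ξ`, threshold) are reconstructions of common practice,
  not fitted values.
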