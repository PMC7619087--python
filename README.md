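# tinvar — tumour-in-normal aware somatic variant calling

Somatic variant callers classify each site by contrasting a tumour sample
against a matched "normal". In haematological malignancies the matched
normal — purified T cells, buccal swabs, remission blood — routinely carries
a few percent of tumour cells (**tumour-in-normal contamination, TiN**). A
genuine somatic variant then shows alt reads in the normal and is filtered
as germline, silently deleting part of the call set. `tinvar` is for cancer
genomics analysts who face this: it models the contamination instead of
being defeated by it.

## The model

At a locus with `n_g` copies per normal cell and `n_t` copies per tumour
cell, every genotype pair `(k_g, k_t)` — mutant-allele copies per normal
cell and per tumour cell — is scored exhaustively. A sample with aberrant
cell fraction `α` yields a read from a tumour cell with probability

    π = α·n_t / (α·n_t + (1−α)·n_g)

and the probability of observing the alt base on one read is

    P(alt) = π·q(k_t/n_t) + (1−π)·q(k_g/n_g),   q(f) = f(1−e) + (1−f)·e/3

with base-error rate `e` (per-read Phred qualities override `e` when
present). The site likelihood is the product over reads; the key point is
that **both** samples are treated this way: the tumour with its purity
`α_t`, and the normal with its own aberrant cell fraction `α_n` — the TiN
level. Posteriors over genotype pairs combine both likelihoods with
configurable priors; a site is called somatic when the summed posterior
mass of pairs with `k_g = 0, k_t ≥ 1` reaches the threshold (default 0.95).
Setting `α_n = 0` recovers conventional calling exactly.

Around this core the package provides:

* **TiN estimation** — a marginal-likelihood grid search for `α_n` over
  informative candidate sites, with a profile-likelihood interval.
* **GLOD indel rescue** — indels rejected upstream for "present in matched
  normal" (F015-style flags) are re-examined with a germline log-odds
  contrast: binomial likelihood of the normal alt count under a germline
  heterozygote (alt fraction `0.5·ξ`) versus TiN leakage (alt fraction
  `VAF_t·α_n/α_t`). Negative GLOD rescues the call.
* **Clonal utilities** — copy-number-corrected cancer cell fractions
  (`CCF = v·(α_t·n_t + (1−α_t)·n_g)/(α_t·m)` with rounded multiplicity
  `m`), clone CCFs as twice the median VAF of diploid autosomal SNVs,
  a coordinated-VAF check for longitudinal clone assignments, and a nested
  fishplot table exporter.
* **Simulator + benchmark** — synthetic paired pileups with known truth,
  measuring sensitivity, specificity and the fraction of somatic variants a
  naive caller loses that TiN-aware calling recovers.

## Worked example

Simulate a cohort at 10% TiN (tumour purity 0.8, depths 80/40), estimate
the TiN level, and call variants with the estimated value:

```bash
$ tinvar simulate --n-per-class 500 --tin 0.1 --seed 1 \
      --out counts.tsv --truth-out truth.tsv
simulated 1500 sites across TiN levels [0.1]

$ tinvar estimate-tin --table counts.tsv --alpha-t 0.8 --out tin.tsv
alpha_n_hat = 0.100 [0.100, 0.105] (525 sites)

$ tinvar call --table counts.tsv --alpha-t 0.8 --alpha-n estimate --out calls.vcf
estimated TiN alpha_n = 0.100 [0.100, 0.105] from 525 sites
wrote 1500 records (500 somatic) to calls.vcf
```

The estimator recovers the simulated 10% contamination from 525 candidate
sites, and the caller then recovers all 500 simulated somatic sites
(`FILTER=PASS`, with the posterior in `PSOM` and the MAP genotype pair in
`MAPGT`). Calling the same table with `--alpha-n 0` instead classifies the
somatic sites with appreciable normal alt counts as germline — the
misclassification TiN-aware calling exists to prevent. The benchmark
quantifies this directly:

```bash
tinvar benchmark --n-per-class 1000 --seed 1 --out bench.tsv
```

which tabulates, per true/assumed TiN combination, sensitivity, specificity
and the fraction of naive-caller misses that each TiN-aware configuration
rescues.

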