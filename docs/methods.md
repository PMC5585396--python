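# Methods

## The background model and test statistic

The unit of testing is a DNase I hypersensitive site (DHS) with repeat-
masked length `L` (bp) and somatic mutation count `n` pooled over a tumor
cohort. Under neutral evolution `n ~ Poisson(mu * L)`, where `mu` is the
per-nucleotide cohort mutation probability of the DHS's genomic
neighborhood. Selection can only be inferred relative to `mu`, which varies
by more than an order of magnitude across the genome, so `mu` is shared
only within clusters of DHSs with similar mutational covariates and fitted
there by maximum likelihood, `mu_hat = sum(n_i) / sum(L_i)`. The per-DHS
statistic is the exact upper tail `p = P(X >= n | mu_hat * L)`.

Two properties shape everything downstream:

* **Discreteness.** `p` takes values only in `{P(X >= k)}`; its
  distribution has atoms and a large mass at `p = 1`. Uniform-null
  reasoning (e.g. Benjamini–Hochberg, provided only as a diagnostic) is
  inappropriate; calibration must come from a simulated null.
* **Conservativeness.** If a cluster contains selected DHSs, `mu_hat`
  exceeds the true neutral rate, so the p-values of those same DHSs are
  overestimated. The test under-calls rather than over-calls.

## The simulated null and empirical FDR

The expected p distribution is obtained by drawing `R = 100` replicate
cohorts `n_i ~ Poisson(mu_hat_i * L_i)` and recomputing p against the
*original* fitted rates (refitting per replicate is available behind
`refit_null=True` for sensitivity analysis; with hundreds of members per
cluster the difference is negligible). All replicates and all clusters are
pooled. At every distinct observed p value `t`,

    FDR(t) = F_exp(t) / F_obs(t),

both cumulative fractions counting values <= t. The significance threshold
is derived from the largest evaluated `t` with FDR <= q (default q = 0.25).
Because the statistic is atomic, the reported `p*` is placed one float ULP
above that `t`: the strict rule `p < p*` then rejects exactly the set
`{p <= t}` whose FDR the curve certified. With no qualifying threshold the
significant set is empty.

The Poisson assumption itself is checked with a two-sample
Kolmogorov–Smirnov comparison of observed vs pooled simulated p-values
(asymptotic p-value; both samples are large and heavily tied). On neutral
cohorts the KS p-value is large; a driver component in the cohort drives
it to zero because the observed small-p mass exceeds the null's.

## Covariates and clustering

Five covariates per DHS: replication timing and chromatin compartment
(consumed as bedGraph-like tracks, coverage-weighted mean over the DHS
footprint; DHSs with no overlapping tile are imputed at the cohort mean
and flagged), GC content of the unmasked sequence, gene density (fraction
of gene-covered bases within 250 kb of the DHS edges), and the
trinucleotide-context expected mutation count `mu_i = sum_t n_{i,t} M_t /
N_t` over all 64 reference-strand contexts (a 32-context strand-collapsed
mode exists behind a flag). Contexts are counted on unmasked pieces only,
each piece independently, consistent with `L` being masked length; `mu_i`
is therefore additive over pieces and linear in the mutation spectrum.

Covariates are z-normalized with the population SD over the full cohort
(the cohort *is* the population); constant covariates are dropped with a
warning. Clustering is k-means (k-means++ initialization, 10 restarts,
fixed seed) per chromosome, with the cohort-level cluster count
apportioned to chromosomes by DHS share. Final clusters must hold >= 100
DHSs and >= 20 kb of masked length; violating clusters are merged greedily
— smallest first — into the nearest-centroid valid cluster (ties to the
lower cluster id), making the assignment deterministic given the seed.

## Kataegis

Rainfall distances are the mean of a mutation's gaps to its two same-
sample, same-chromosome neighbors (single neighbor at chromosome ends;
undefined for a lone mutation). A kataegis locus is a maximal per-sample
run of >= 6 consecutive mutations in which **every adjacent gap** is below
1,000 bp — a deterministic O(n) rule that guarantees the mean-gap
condition; a windows-by-mean-only mode (`mode="mean"`) is provided since
the informal definition admits both readings. DHSs overlapping any
sample's locus are removed before background fitting, since localized
hypermutation violates the Poisson field assumption.

## Filters 2–4 and the pan-cancer tests

Filter 2 computes, within each DHS's own covariate cluster, Z-scores of
mean read count, mean read quality and improperly-aligned-read fraction
(metrics consumed from a TSV; their computation from alignments is out of
scope) and removes a DHS iff count-Z < −2 OR quality-Z < −2 OR
improper-Z > +2, all strict. Zero-SD clusters leave the Z undefined and
the DHS retained.

Filter 3 links a candidate DHS to genes within 500 kb (edge-to-edge) that
are supported by an interaction whose other anchor overlaps the gene body
or a 2-kb upstream promoter window (the window is configurable; no
standard definition exists). Expression of each linked gene in the tumors
carrying the DHS mutation is compared with a normal panel by a two-sided
rank-sum test — exact when both groups have <= 25 tie-free values, normal
approximation with continuity correction otherwise — at alpha = 0.05,
pooling mutated samples without requiring directional consistency. Genes
overlapping a CNV in any mutated sample are excluded. Count matrices can
be normalized with native median-of-ratios size factors or passed through
pre-normalized. Filter 4 requires >= 1 mutation in each replication
catalog (each pre-filtered with the same catalog rules).

The pan-cancer recurrence tests reuse the Poisson tail with backgrounds
estimated from (a) the DHS's ±50 kb flanks, non-repetitive bases only,
with other candidate DHSs excised from the flanks by default (a
strict-flanks mode keeps them), and (b) 20 same-cluster DHSs sampled with
a fixed seed. Each test is thresholded at empirical FDR 0.05 with a null
simulated from its own fitted lambdas; a recurrence call requires
significance in both.

## Mutation catalogs

Internal coordinates are BED-style 0-based half-open everywhere; catalog
readers accept 1-based input (VCF convention) and shift on read. Only
single-base substitutions are analyzed; multi-base rows are rejected with
a count, not an error. Defaults mirror standard somatic-calling hygiene:
>= 14× tumor and >= 8× normal coverage, allele fraction >= 0.10 (all
inclusive), removal of mutations on repeat elements or known SNP loci.
Mutations on masked bases inside a DHS are not counted for that DHS,
keeping the numerator consistent with `L`.

## Synthetic data

Two generators share one generative law, `n ~ Poisson(m * mu(z) * L)` with
driver multiplier `m >= 1`:

* `simulate_cohort` draws count-level cohorts: each chromosome carries its
  own covariate *archetypes* (latent groups); a DHS's five covariates sit
  near its archetype center (noise SD 0.15) and its neutral rate is the
  archetype rate. Rates are log-normal around a baseline with log-SD 0.5.
  This is exactly the structure the per-chromosome k-means is meant to
  recover, so it isolates the statistical machinery from covariate-
  estimation error.
* `simulate_genome` / `simulate_mutations` / `simulate_expression` emit
  full fixtures — multi-chromosome FASTA with per-chromosome GC targets
  (hence heterogeneous trinucleotide composition), DHS/repeat/gene BED,
  smooth covariate tracks, mutation TSVs with depths and allele fractions,
  negative-binomial expression with fold-shifts on driver target genes,
  linking and decoy interactions, per-sample CNVs — to exercise parsing
  and the full cascade.

Defaults are the study conditions: baseline **3e-3 mutations/bp**
cohort-wide, the scale of a pooled multi-hundred-to-thousand-genome
somatic catalog (for reference, a single 560-genome breast cohort reaches
~1.2e-3/bp); DHS lengths log-normal with ~300 bp median, matching DNase
track length scales; driver DHSs carry multiplier 5 and lengths 1–2.5 kb;
kataegis injections place 8 mutations with gaps uniform on
[1, 2·gap_scale] (mean = gap_scale, bounded so an injected locus cannot be
split by a single outlier gap, which an exponential tail would produce by
artifact). Mutation placement within a DHS is uniform — the model is
count-level — so positional hotspots other than injected kataegis are not
emulated. Everything is deterministic under a fixed seed.

What passing on this synthetic data does **not** show: robustness to
covariates that only partially explain rate variation (real clusters are
leakier than archetypes), to signature-driven context effects, to
subclonal allele fractions, or to mapping artifacts; those require real
cohorts. Kataegis detection is evaluated at realistic *per-sample*
intermutation distances (catalog density 3e-4/bp over 20 samples), since
the caller operates per sample and the cohort-scale density of a small toy
genome would otherwise be unrealistically tight.

## Numerical choices

* Poisson upper tail: regularized lower incomplete gamma
  (`P(X >= n) = gammainc(n, lambda)`) when `n <= lambda`; for `n > lambda`
  a direct ratio-series summation of pmf terms starting at `n`, carried in
  log space — all terms positive, no cancellation, full relative accuracy
  into the deep tail (validated to ~2e-13 against exact rational
  arithmetic for `lambda <= 50`, `n <= 200`). Results below the smallest
  positive double underflow to 0.
* `n = 0` gives `p = 1` identically; a zero-rate cluster with observed
  mutations (impossible under the MLE) reports `p = 0` with a warning.
* FDR curve evaluated at observed p values only (they are the only
  decision points); `F_obs > 0` there by construction.
* Cluster-merge ties broken by lower cluster id; k-means seeded; null
  replicate draws come from one seeded generator, so the entire analysis
  is reproducible bit-for-bit.

## Problem sizes used in validation

Calibration and conservativeness use a neutral cohort of 40,000 DHSs in
40 archetypes (100-replicate null: 4×10^6 simulated p-values); driver
recovery uses 10 cohorts of 20,000 DHSs with 20 injected drivers each;
the KS contrast uses cohorts with a 2% driver fraction, where the
distribution-level distortion is visible (20 drivers in 20,000 shift the
p CDF by ~0.1%, below KS resolution at this sample size — the per-DHS
test, not the cohort-level KS, is the instrument for sparse drivers).
These sizes give Monte-Carlo error comfortably inside the tolerances the
checks assert while keeping the whole suite under a minute of compute.

## Known limitations

* The per-chromosome k-means granularity rule (cohort k apportioned by
  DHS share) reproduces cohort-scale cluster counts but is a heuristic; k
  is configurable per run.
* Interval-analysis flanks assume the ±50 kb neighborhood is neutral
  after masking and candidate excision; broad selected regions would
  contaminate the background.
* The aberrant-expression filter treats samples as exchangeable and uses
  a single pooled comparison per gene; batch structure in real expression
  panels is not modeled.
* BigWig/BigBed, tabix and BAM access are out of scope; all inputs are
  plain-text BED/TSV/FASTA.
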