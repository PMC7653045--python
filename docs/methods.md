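# Methods

This note documents the models and procedures implemented in `hervscreen`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Antigen library construction

Each HERV locus is represented by one to four deposited transcript
sequences. A transcript is translated on the forward strand only, in the
reading frame set by the **first** ATG anywhere in the sequence, up to but
excluding the first in-frame stop codon; if no stop occurs, the trailing
incomplete codon is dropped, and a transcript without any ATG translates to
the empty string. Codons containing characters outside {A, C, G, T}
translate to `X`. These rules are deliberately literal: transcripts are
treated as deposited mRNA-like sequences with a single candidate ORF, and no
attempt is made to scan alternative frames or the reverse strand.

The translated protein is chopped into all overlapping 9-, 10-, and 11-mers
(proteins shorter than 9 residues contribute nothing — the "long enough"
exclusion). Peptides containing `X` are dropped before prediction because
binding-rank predictors are undefined on non-standard residues. Binding is
delegated to a `RankProvider` — any deterministic callable
`(peptide, allele) → percentile rank` — so a NetMHCpan-style predictor, a
precomputed rank table, or the packaged synthetic provider are
interchangeable. A peptide enters the library when its rank is **≤ 2.0**
(inclusive at the boundary, compared at the precision of the rank source),
once per allele it binds: a peptide binding two alleles is two library
entries. Records are deduplicated per (peptide, allele) with source loci
unioned; two transcripts of the same locus count that locus once. A
non-deterministic provider (conflicting ranks for the same query) aborts.

## Barcode enrichment

Each sorted (multimer-positive) sample is sequenced alongside triplicate
baseline aliquots of the full pMHC pool; the baselines define the null
barcode composition.

* **Normalization** uses trimmed-mean-of-M-values (TMM) factors. The
  reference sample is the one whose 75th-percentile count fraction is
  closest to the across-sample mean. Per sample, barcodes with positive
  counts in both the sample and the reference contribute log-ratios
  M = log2(f_s/f_r) and abundances A = ½·log2(f_s·f_r); the top and bottom
  30% by M and 5% by A are trimmed (the method's published defaults, exposed
  as parameters) and the remaining M averaged with inverse asymptotic
  binomial-variance weights. Factors are rescaled to geometric mean 1. The
  test suite checks this against an independently coded step-by-step oracle
  to 1e-10.
* **Fold change**: log2 of the sample's normalized barcode fraction over the
  mean of the three baseline fractions, with a pseudo-fraction of
  0.5 / median effective library size added to both numerator and
  denominator so zero counts stay finite. The pseudo-count is configurable.
* **Test**: one-sided upper-tail p-value P(X ≥ c_obs) under a negative
  binomial with mean μ = (mean baseline fraction) × (sorted sample's
  effective library size) and fixed dispersion φ = 0.1 in the
  variance = μ + φμ² parametrization (size parameter 1/φ). The fixed
  dispersion reflects the screening design: with only three baseline
  replicates per experiment, a per-barcode dispersion estimate would be
  unstable, so a single empirically motivated value is assumed for all
  barcodes. μ = 0 with a nonzero observation is floored at 0.5 reads so a
  barcode absent from the baselines cannot produce p = 0; μ = 0 with a zero
  observation gives p = 1. This is a direct tail test against the estimated
  baseline mean, not a two-group exact test; its error control is validated
  by simulation rather than by bit-compatibility with any count-model
  package.
* **Multiple testing**: Benjamini–Hochberg per sorted sample — each
  experiment is tested individually.
* **Detection**: a barcode is significant iff FDR < 0.1% **and** it carries
  at least 1/1000 of the sample's raw (pre-normalization) barcode reads.
  The raw-read convention for the fraction filter matches its purpose of
  guarding against low-coverage artifacts.

Optional clonal reduction collapses reads to distinct molecule tags per
(barcode, sample); without a tag column it is an identity pass-through.

## Response aggregation and scoring

Detections are aggregated to one row per (individual, class) — a patient's
pre- and post-treatment samples are separate rows sharing the individual ID —
over (peptide, HLA) columns. A cell is **positive** if any of the
individual's samples in that class has a detection, **not-tested** if the
individual lacks the allele (the pMHC never entered their staining pool),
otherwise **negative**. Epitopes recognized anywhere are classified
patient-only / healthy-donor-only / shared, with pre- and post-treatment
rows both counting as "patient".

The per-HERV reactivity score is the number of positive peptide
observations of that locus divided by the number of tested peptide
observations, both summed over patient rows (sample-weighted denominators:
each tested sample contributes its own slots). The detected-epitope
proportion is the number of distinct (peptide, HLA) pairs of the locus ever
positive in a patient row over the number predicted in the library. Peptides
attributable to several loci credit every source locus in both scores,
while the packaged 29-row catalog keeps each multi-locus peptide as a single
entry — attribution is a scoring convention, not a catalog expansion.

## Bayesian cohort models

All models run on an adaptive Gaussian random-walk Metropolis sampler, by
default 3 independent chains × 10,000 iterations with 5,000 warmup
(15,000 post-warmup draws). The proposal scale adapts by Robbins–Monro
toward the classic optimal acceptance rate and the proposal covariance to
the running warmup covariance; for targets that factorize over coordinates
(the proportion model) each coordinate is proposed and accepted
independently, which mixes substantially better. The models are
low-dimensional (≤ 10 free parameters) with smooth unimodal posteriors, so
this sampler is adequate; correctness is checked against conjugate closed
forms and parameter-recovery simulations rather than assumed. Split-R̂ and
bulk ESS are computed per parameter (via arviz); a fit is flagged — never
silently accepted — unless R̂ < 1.01 and ESS exceeds a configurable minimum.
Credible intervals are equal-tailed quantile intervals (50% and 90%),
matching the eye-plot convention of median, 50% and 90% CI.

* **Proportion model**: independent Binomial(n_g, p_g) per group with
  Beta(1,1) priors, sampled on the logit scale. The exact posterior is
  Beta(k+1, n−k+1); the sampler's quantiles are required to match it within
  ±0.01 at the default draw count. Contrast probabilities P(p_a > p_b) come
  from paired draws.
* **HLA-corrected regression**: one observation per (individual, allele)
  with N_i = peptides tested (from the responder-matrix denominators; the
  per-allele panel is the unit of testing) and n_i = peptides recognized;
  p_i = logistic(β₀ + β_HLA[i] + β_class[i]), n_i ~ Binomial(N_i, p_i).
  Sum-to-zero constraints on the HLA and class deflections are exact: K−1
  free coefficients with the last set to minus their sum. Priors are
  weakly-informative normal(0, 2.5) on all coefficients (the prior scale is
  a parameter, and a `prior_sensitivity` helper refits across a scale grid
  and tabulates posterior-median shifts). Per draw, HLA-corrected class
  proportions p_class = logistic(β₀ + β_class) and pairwise contrasts
  log(p_class1/p_class2) are derived, so the reported CIs propagate full
  posterior uncertainty. Log fold changes of proportions use the natural
  log; expression fold changes (below) use log2 — the two conventions are
  kept deliberately distinct.
* **Viral normalization**: per-class ratio of HERV to viral proportion
  draws, paired by draw index; draw indices with a zero viral proportion
  are excluded with a warning and a count. Contrasts of the normalized
  quantity are computed from the same paired draws.
* **Clinical-outcome model**: p(responder) = logistic(β₀ + β_HLA·x_HLA +
  β_HERV·x_HERV + β_VIR·x_VIR + β_HxV·x_HERV·x_VIR) with a hierarchical
  normal(0, τ) prior shared by the three response coefficients and
  half-normal(1) on τ. The hierarchy is sampled non-centered
  (β = τ·u, u ~ N(0,1)) to avoid the funnel geometry. The shared prior
  regularizes against complete separation in small cohorts: separated toy
  data still yields finite posterior medians.

**Exact rank tests.** Unpaired comparisons use the Mann–Whitney–Wilcoxon
rank-sum test, paired comparisons the Wilcoxon signed-rank test (zero
differences dropped), both with midrank tie handling and exact permutation
null distributions: full enumeration when the permutation space is at most a
configurable bound (default 50,000), otherwise a counted-shift convolution
over doubled (integer) midranks — both routes are exact and verified to
agree. Two-sided p-values sum the null probability of deviations from the
exact null mean at least as large as observed, which reduces to tail
doubling in the symmetric no-ties case.

## Synthetic data

The generators emulate the screening study's structure with planted truth;
every generator is byte-deterministic given the seed.

* **Cohort**: 27 healthy donors and 34 patients (paired pre/post samples)
  by default, each individual carrying 1–4 alleles drawn uniformly from the
  four screened HLA class I alleles. True recognition of a peptide is
  Bernoulli per (individual, peptide), restricted to HLA-matched peptides.
  Per-class probabilities default to 0.002 (healthy), 0.010 (pre), 0.012
  (post) per peptide — synthetic choices giving a realistic sparse response
  pattern (most responders recognize a handful of peptides; patients respond
  more often than donors); they are not estimates, since per-peptide
  response probabilities are not published. Patients' pre and post samples
  share one truth by default, with optional post-only gain/loss
  probabilities (default 0) to emulate treatment-driven turnover; the "post"
  class probability is used only for patients generated without a paired
  pre sample.
* **Transcripts**: 30 loci by default, 400–2,500 nt, 85% carrying a planted
  ORF (ATG + 12–60 sense codons + stop) and the rest containing no ATG at
  all, exercising the "long enough" exclusion. Loci own 1–3 transcripts
  sharing the ORF with different flanks, so same-locus deduplication is
  exercised.
* **Rank provider**: a stable hash of (seed, peptide, allele) mapped to a
  percentile rank in (0, 100], piecewise-calibrated so P(rank ≤ 2) equals
  the configured binder rate (default 0.019). Non-standard residues get the
  sentinel rank 100.
* **Barcode counts**: negative binomial in the variance = μ + φμ²
  parametrization, φ = 0.1, baseline depth 100 reads per barcode;
  responders' sorted-sample counts have mean enrichment_fold × depth
  (default 50×). Out-of-panel barcodes (allele not carried) are zero
  throughout.
* **Expression**: log-normal TPM with per-locus base levels ~ 2^N(0.5, 1),
  log2-scale noise sd 0.5, and a +2 log2 disease shift on flagged loci in
  patient columns, plus an optional per-patient heterogeneous post-treatment
  shift (default off).

What the generators do **not** emulate: read-level structure (UMIs,
sequencing error, demultiplexing), FACS gating variability, inter-barcode
composition correlations, batch effects, HLA linkage disequilibrium, or
biologically structured expression covariance. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
noise models, not robustness to every artifact of real screens.

## Expression analysis

All TPM values are floored at 0.05 **before any** log computation,
including inside the healthy-donor mean; the floor is idempotent and
negative inputs are rejected. Fold changes are log2(x) − log2(y). Mode A
compares each pre-treatment patient column to the mean floored healthy TPM
per locus; mode B computes paired post-vs-pre fold changes within patients
and drops unpaired patients with a logged count. Heatmap values are clipped
to ±6 (a projection). The Spearman correlation between per-locus mean
patient expression and detected-epitope proportion uses midranks; its
p-value is the two-tailed t-approximation by default, with an exact
permutation option for ≤ 10 loci (the t-approximation is the default
because realistic locus counts make enumeration infeasible). The
immunogenic-vs-non-immunogenic comparison reports group medians and the
exact two-tailed Mann–Whitney p-value. When mean patient expression is
computed from matrices containing both pre- and post-treatment columns,
each patient's columns are pooled before averaging across patients.

## Numerical choices and verification sizes

* NB parametrization is fixed project-wide as variance = μ + φμ² (size
  1/φ), matching the count-model convention the enrichment test assumes.
* BH adjustment is delegated to statsmodels' step-up implementation.
* Posterior summaries use numpy quantiles on pooled post-warmup draws.
* Replicate-based calibration checks (credible-interval coverage of the two
  regression models) run 50 replicates each at 2 chains × 4,000 iterations
  (2,000 warmup) — enough draws to locate 90% CI endpoints to well within
  the coverage tolerance while keeping the checks fast; single-fit checks
  use the full 3 × 10,000 default.
* The acceptance script's synthetic screen uses the default cohort
  (27 + 34×2 samples, ~30 loci, ~150–200 library entries); the expression
  recovery check uses 49 loci × (14 healthy + 16 paired patients), mirroring
  the RNA-seq cohort sizes of the study design.

## Known limitations

* The enrichment test conditions on the estimated baseline mean rather than
  modelling its uncertainty; with triplicate baselines and φ = 0.1 the
  simulated null detection rate stays well under the nominal bound, but the
  p-values are not exactly calibrated for very low baseline counts.
* Mode-A expression fold changes against the arithmetic mean of log-normal
  healthy values are biased slightly below the true log-scale shift
  (≈ 0.09 log2 units at noise sd 0.5); the recovery check bands account for
  this.
* The random-walk sampler's ESS per draw is modest (roughly 2–10% depending
  on dimension); the defaults compensate with draw count. Models with many
  more parameters would warrant a gradient-based sampler.
* The packaged catalog reproduces the published table verbatim, including
  its multi-locus attribution ambiguity: counting "distinct source loci"
  from multi-locus rows is convention-dependent, so no single locus count is
  asserted as canonical.
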