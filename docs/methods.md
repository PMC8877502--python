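# Methods

This note documents the models, conventions and open design choices behind
ticquant, in the order data flows through the pipeline.

## Quantitation model

Protein abundance within one LC-MS/MS run is the total ion current (TIC):
the sum of MS/MS fragment-ion intensities over every accepted PSM of the
protein. TIC is a relative, within-run measure; the pipeline never
normalises intensities across runs. Instead, both differential procedures
centre their difference populations, which removes any global
(multiplicative on the raw scale, additive on log2) run offset exactly;
both statistics are provably invariant to such offsets and the test suite
asserts it.

Accepted PSMs satisfy log10(e) < −1.5 (strict), at most one missed tryptic
cleavage, and precursor charge +2..+4. The PSM interchange format is a
package convention: UTF-8 TSV, `#` comments, fixed column names
(`ticquant.io_formats.PSM_COLUMNS`). Each PSM is credited to the single
protein id the search assigned it; there is no razor-peptide or
protein-group inference — if the upstream engine emits shared peptides
ambiguously, resolve them before import.

Zero TIC means "not detected". log2 is undefined there (NaN): no −∞, no
imputation. Detection status uses one of two rules: a strain *carries* a
protein if it is detected in **all** of that strain's runs (strict) or in
at least one (lenient). The default is strict for replicated designs and
lenient for single-replicate designs; under strict, a protein seen in one
of two wild-type runs and both mutant runs is classed mutant-only and
excluded from quantitative testing rather than half-trusted. Counts of
detected-in-both proteins are therefore rule-dependent; upstream reports
of such counts are themselves not always internally consistent, and the
package simply reports what its configured rule produces.

## Single-replicate differential rule (z-score)

With one run per strain the only available null model is the difference
population itself. For proteins detected in both runs,
d_i = log2 TIC(mutant) − log2 TIC(wt); the {d_i} are standardised with
their mean and sample SD (n−1 denominator), and |z| > 1.96 (strict) flags
a protein. Mean-centering (not median) is used; at the hundreds of
proteins this procedure sees, the mean/median and n vs n−1 choices are
immaterial, but they are fixed for exactness. Fewer than 3 both-detected
proteins is an error (the SD is meaningless), as is a zero-variance
population. This rule assumes most proteins are unchanged — true effects
inflate the SD and make the call conservative — and carries no
multiple-testing correction by design: it flags the extreme 5% of the
empirical difference distribution.

## Replicated differential rule (Wstat signal-to-noise)

For two replicates per strain, per protein:

* R0 = wt1 − wt2, R1 = mut1 − mut2 (within-strain noise),
* Z0 = mut1 − wt1, Z1 = mut2 − wt2 (between-strain signal,
  replicate-matched pairing; a crossed pairing Z0 = mut1 − wt2,
  Z1 = mut2 − wt1 is available as a sensitivity check, since replicate
  labels are exchangeable).

Each of the four across-protein populations is centred to mean 0. The
noise scale is the sample SD of the pooled centred {R0, R1} (a single
pooled SD rather than per-strain, trading strain-specific variance for a
doubled noise sample size), and

S/N_i = |Z0c_i + Z1c_i| / noise,  mean_diff_i = (Z0c_i + Z1c_i)/2.

Calibration: with i.i.d. Gaussian replicate noise σ, Var(Z0c+Z1c) = 4σ²
while the pooled R SD estimates √2·σ, so S/N ~ √2·|N(0,1)| and
P(S/N ≥ 2.8) = 2(1 − Φ(2.8/√2)) ≈ 0.048 — the 2.8 cut-off is a p < 0.05
rule, which the Monte-Carlo suite verifies to within three binomial
standard errors. A protein is reported when S/N ≥ 2.8 **and**
|mean_diff| ≥ 1 (two-fold); both comparisons are inclusive and the filters
are conjunctive. Whether the original formulation centred each population
separately or pooled first is not decidable from the available
description; this implementation centres each of the four populations
separately, the choice that makes the analytic calibration exact.

Note that S/N and mean_diff are proportional per protein (S/N =
2·|mean_diff|/noise), so the conjunctive rule is equivalent to a single
threshold at max(2.8·noise, 2·fc_cutoff) on |Z0c+Z1c|; both knobs are
still exposed because their units (noise-relative vs fold-change) answer
different scientific questions.

## Set analysis

Compartment annotation is multi-label set intersection: counts come from
independent list comparisons, so a protein present in, say, both the
mitochondrial and ER lists counts in both and is reported in the
multi-label group, with the unassigned remainder listed. Venn
decomposition supports 2–3 named sets and returns the disjoint regions
(7 for three sets); region counts always sum to the union size.

Enrichment is a hypergeometric upper-tail test P(X ≥ k) for a category of
size K in a universe of size N against a query of size n with overlap k,
Benjamini–Hochberg-adjusted across categories. The default universe in the
pipeline is the detected-in-both-strains list. The significance machinery
is an optional addition on top of the raw overlap counts and fractions
(`compare_overlap_fraction` reports both the count and the
query-denominated fraction, taking no position on which denominator a
reader prefers).

## Phenotype assays

All five operations are exact closed-form arithmetic on instrument
exports; chromatogram peak detection and spectral correction are out of
scope (areas and fluorescence values are inputs).

* **Laurdan fluidity**: ratio F440/F490 per temperature; a higher ratio
  means lower fluidity (fluid-phase emission red-shifts toward 490 nm).
  Replicates are ratioed first, then averaged.
* **Acyl chains**: percent of total GC peak area, internal standard
  (C17:1) excluded from the total; absolute amounts relative to the
  standard are available but percentages are the default report.
* **Ergosterol**: peak area over the 5α-cholestanol standard, expressed as
  percent of the reference strain (reference ≡ 100%); invariant to any
  common chromatogram rescaling.
* **Catalase**: U/mg with 1 U = 1 µmol H₂O₂ decomposed per minute.
* **ROS**: DCF fluorescence per mg protein as percent of reference;
  invariant to common fluorometer gain.

Replicate aggregation is mean ± SD with a two-sample t-test; the pooled
Student form is the default, Welch optional.

## Synthetic data

The generator draws per-protein log2 baselines ~ Normal(mu0=10, tau=2),
gives a Bernoulli(pi_de=0.1) subset a ±delta (default 2.0 log2 units)
strain effect with equal sign probability, adds i.i.d. Normal(0,
sigma_rep=0.5) noise per run, converts to TIC, and splits each
protein-sample TIC across 2–8 peptides with symmetric Dirichlet(1)
weights — a lossless split, so rollup reproduces the latent values to
1e−9, which is asserted. Dropout zeroes whole protein-sample cells with
probability 2·rate·Φ(−(b−mu0)/tau) (probit link on the standardised
baseline, average ≈ rate, default 0.05), mimicking detection limits at
low abundance. All emitted PSM fields pass the identification filters.

The defaults describe a deep label-free experiment at the noise level used
throughout the calibration studies; the noise SD 0.5 log2 units matches
the null-simulation condition Normal(10, 0.5). What the generator does
**not** emulate: spectra, retention-time structure, identification error,
correlated peptide ionisation efficiencies, or any real organism's
abundance distribution. Passing recovery tests therefore demonstrate the
statistics' correctness under their own assumptions, not robustness to
real-data pathologies such as batch effects or intensity-dependent
variance.

Null calibration draws matrices directly on the log2 scale (bypassing the
peptide layer, which is exactly invertible anyway) for speed:
100,000-protein Wstat and 10,000-protein z-score calibrations run in
seconds. The S/N statistic is scale-free, so the calibrated fraction is
bit-identical across sigma_rep values under a fixed seed — a property the
suite checks.

## Numerical and interface conventions

* Sample SDs use the n−1 denominator everywhere.
* Cut-offs: |z| > 1.96 strict; S/N ≥ 2.8 and |mean_diff| ≥ 1 inclusive.
* Result TSVs carry `#` provenance headers (tool version, config hash,
  input SHA-256 digests) and full-precision floats; write-then-read is the
  identity and equal-config reruns are byte-identical.
* MGF dialect: BEGIN/END IONS, TITLE, PEPMASS, CHARGE, RTINSECONDS
  (converted to minutes); unknown keys ignored; unterminated blocks are an
  error with a byte offset; blocks without PEPMASS are skipped with a
  warning.
* Accessions are compared as exact case-sensitive strings; no id-mapping
  across genome annotation versions.
* The CLI dispatches the differential procedure by replicate count,
  overridable; a procedure/design mismatch fails before any computation.
  Exit codes: 0 ok, 2 config error, 3 data error.

## Known limitations

* No >2-replicate generalisation of the Wstat rule, no moderated-variance
  (limma-style) estimators, and no p-values beyond the calibrated
  threshold semantics.
* No protein inference, match-between-runs, or iBAQ/LFQ normalisation.
* The z-score rule's error calibration is conditional on "most proteins
  unchanged"; heavy contamination of the difference population biases it
  conservative.
* Gene lists are user-supplied files; no live annotation-service queries.
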