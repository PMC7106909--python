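# Methods

This document defines the quantities `tvburden` computes, the defaults it
ships with, the semantics of the synthetic data generator, and the numerical
choices that matter for reproducing its output.

## 1. Variant normalization and consensus calling

Variants are reduced to a minimal (parsimonious) representation before any
cross-caller comparison: shared trailing bases are trimmed first, then shared
leading bases (advancing the position), always leaving at least one base on
each allele. The identity key is `(chrom, pos, ref, alt)` after
normalization; the caller name never enters identity. Alleles must be
non-empty strings over `ACGTN`.

`consensus_variants` keeps a variant iff its identity key is reported by at
least `min_callers` callers (default **2** of however many are supplied).
`min_callers=1` yields the union, `min_callers = n_callers` the intersection.
The emitted call carries the sorted, comma-joined supporting caller names.
Duplicate reports of the same key within a single caller count as one vote.

## 2. TMB and cross-caller instability

Raw TMB is the consensus variant count. Coverage-adjusted TMB divides it by
the number of megabases covered at depth **≥ 6** (inclusive), computed from a
BED-style depth track (0-based half-open intervals). Zero covered megabases
raises `UndefinedMetricError` rather than returning infinity. Multi-sample
patients aggregate by the median.

Two statistics quantify caller-choice instability, both computed on
**raw per-caller counts** by default (coverage-adjusted values are accepted
equally):

- `caller_variability`: median over all caller pairs of |TMB_i − TMB_j|,
  divided by the median per-caller TMB. Cohort-level value is the median over
  patients.
- `tmb_range_fraction`: (max − min) of per-caller counts, and that range as a
  fraction of the median.

## 3. Neoepitope enumeration

For a single amino-acid substitution at 1-based position *p* in a protein of
length *n*, the candidate neoepitopes are all windows of every length
L ∈ {8, …, 24} whose span contains *p*: start positions
max(1, p − L + 1) … min(p, n − L + 1). For an interior substitution (≥ 24
residues from both termini) this yields exactly Σ L = **272** windows; at a
terminus it degrades to one window per length (17). In-frame indels use the
same logic over the altered span. Frameshifts and retained-intron readthrough
produce a novel C-terminal tail; every window that contains at least one
novel residue counts — both windows straddling the junction and windows fully
inside the tail.

Duplicate window sequences are collapsed with a multiplicity count;
`n_windows` counts windows, `n_distinct` counts distinct peptide sequences.

## 4. Closest normal peptide and the M weight

For each binder peptide, the closest normal peptide is found by exhaustive
ungapped scan of every same-length window of the normal proteome, scored with
BLOSUM62. Ties on the raw score are broken by weighted similarity
score(neo, candidate) / score(candidate, candidate), then lexicographically,
making the result deterministic. The **M** weight is the Hamming mismatch
count between the neoepitope and that closest normal peptide.

## 5. Weighted burdens

A peptide is a **binder** when its predicted affinity is ≤ **500 nM**
(inclusive) for at least one allele of the patient's HLA genotype; binding
records for alleles absent from the genotype are skipped with a warning.
Per-epitope weights:

- **A** — number of patient alleles binding at ≤ 500 nM;
- **M** — mismatches to the closest normal peptide (§4);
- **T** — number of the variant's transcripts exceeding **1 TPM (strictly)**
  at the reference cohort's 75th expression quantile;
- **E** — 1 if any exon of a carrying transcript has ≥ 1 patient RNA read,
  else 0; undefined (error, naming the patient) when the patient has no RNA.

A weighted burden over component set C is Σ_epitopes Π_{c∈C} w_c; the empty
component set degenerates to the raw burden (count of epitopes with A ≥ 1).
Consequently the {A}-weighted burden is ≥ the raw burden, with equality iff
every counted epitope binds exactly one allele.

`tmb_times_hla` multiplies TMB by the count of distinct HLA alleles
(homozygosity lowers it). **TVB** is the exact integer sum
somatic + tumor-specific junctions + tumor-specific retained introns.

## 6. Tumor-specific splice junctions

Junction tables use the STAR `SJ.out.tab` dialect: 1-based first and last
intronic base, strand codes 0/1/2 → `.`/`+`/`−`, motif codes 0–6. A junction
is removed when **any** of four rules applies:

1. non-canonical motif (kept motifs: `GT-AG`, `GC-AG`, `AT-AC`);
2. present in the normal compendium — a single read in a single normal sample
   suffices; an unknown strand (`.`) on either side matches either strand;
3. fully annotated (exact annotated donor–acceptor pair);
4. neither end at an annotated splice site.

What survives is partially novel, canonical, and absent from normals. The
junction burden counts distinct identity keys `(chrom, donor, acceptor)`.
The compendium persists to SQLite for reuse. Annotation derives from exon
structures: donor = exon end + 1, acceptor = next exon start − 1.

## 7. Retained introns

Transcript-level expression filters (all must hold, fractions over samples):

- TPM ≥ 1 in ≥ 25% of samples;
- ≥ 5 unique counts in ≥ 25% of samples;
- mean retention fraction strictly between 0 and 1.

Within each transcript of each patient, an intron is an outlier when its
read count **strictly exceeds** median + 3 × MAD of the transcript's intron
counts **and** is ≥ the transcript-level count. The MAD is **unscaled**
(no 1.4826 factor) by default. Retained introns observed in normal samples
are subtracted by identity key `(transcript, intron_index)`. Surviving RIs
are translated across the exon–intron boundary in the annotated reading frame
until the first stop codon; windows containing ≥ 1 intron-derived residue are
enumerated as in §3. Ambiguous nucleotides abort translation with a warning
and contribute no peptides.

## 8. Outcome evaluation

- **ROC/AUC**: curve via threshold sweep; area by trapezoidal integration,
  which equals the Mann–Whitney statistic P(score_pos > score_neg) +
  0.5 P(tie) exactly; the rank-sum identity is kept as an oracle.
- **Logistic response model**: response ~ log2(burden + 1) (pseudocount 1),
  plus an αCTLA4-vs-αPD1 indicator where both therapies occur (melanoma);
  combination therapy is excluded upstream. Reported: slope, Wald SE/CI,
  p value, and fitted response probabilities at the cohort's 25th/75th burden
  percentiles, marginalized over the observed therapy mix. Perfect separation
  is flagged and the fit falls back to a weak-ridge regularized estimate with
  NaN p value. Minimum n = 10. P values across metrics/cohorts are
  Benjamini–Hochberg adjusted.
- **High/low classification**: "high" iff burden **strictly exceeds** the
  cohort percentile (default **80th**), computed with linear interpolation
  between order statistics (numpy default, type-7). With all values equal,
  nobody is high.
- **Survival**: Cox proportional hazards (lifelines, Efron tie handling) of
  high vs low, with Kaplan–Meier curves and at-risk tables per stratum.
  Strata without any event yield a flagged result with NaN hazard ratio
  instead of a divergent fit. An optional horizon applies administrative
  censoring. Threshold sweeps refit at each percentile of a grid.
- **Concordance**: fraction of patients labeled incongruously high/low by two
  metrics over a percentile grid.

## 9. Synthetic cohort generator

The generator produces a complete multi-omic bundle with recorded ground
truth, designed so each pipeline stage can be validated by exact recovery.

**Determinism.** Every patient/layer draws from
`SeedSequence([seed, crc32(patient_id), stage])`, so per-patient streams are
stable under changes of cohort composition, and the clinical/outcome layer
(stages 1–2) is bit-identical whether or not the heavy emission layers
(variant sets, RNA) are generated. `with_variant_sets=False` /
`with_rna=False` are pure emission switches for large parameter-recovery
runs; they change no distribution.

**DNA layer.** Per patient: a lognormal true variant count (per-cancer-type
(μ, σ)), a coverage track with one well-covered segment (depth 30, Gaussian
size, mean 200 Mbp) and one below-threshold segment (depth 3), and one call
set per caller model. A caller with sensitivity *s* keeps each true variant
with probability *s* and adds Poisson(fp_rate × Mbp) false positives. True
variants occupy positions 1–9×10⁸ and false positives 9×10⁸–10⁹, so planted
truth and noise are disjoint by construction and recovery checks are exact.

**Epitope layer.** HLA genotypes are drawn from fixed class I/II pools.
Binding affinities are lognormal (median 5 kNM) with a configurable fraction
forced into the ≤ 500 nM binder range. Affinity tables are generated for a
capped subsample of protein variants (default 10 per patient, 8–11-mer
windows): full-scale enumeration (every variant × 272 windows × every
allele) is computationally pointless for validating the burden arithmetic.
This cap is a deliberate scaled-down choice, not a model parameter.

**RNA layer** (a configurable patient fraction, default 25%): tumor junction
tables mix annotated background junctions, planted novel junctions (one end
annotated, acceptor ≥ 10⁹, guaranteed absent from the normal compendium), and
decoys exercising every removal rule. Intron counts are Poisson(10) with
planted outliers set to median + 10 × max(MAD, 1) + transcript count, always
avoiding the designated normal-RI set.

**Outcomes.** Therapy: melanoma 20% αPD1 / 80% αCTLA4, all other types αPD1.
Response is Bernoulli with logit = β₀ + β·log2(true count + 1) + αCTLA4
offset (defaults −4.0, 0.3, −0.5). Survival is exponential with baseline
hazard 1/1500 per day, multiplied by a planted hazard ratio (default 0.5) for
patients whose true count strictly exceeds their disease-matched 80th
percentile; times are administratively censored at 2885 days.

The shipped `default_config` mirrors a pan-cancer meta-cohort: 302 melanoma,
34 NSCLC, 10 prostate, 57 RCC, 28 MMR-deficient patients with per-type
lognormal count medians 3600 / 1500 / 635 / 1100 / 5632. Generator defaults
are study conditions: they are fixed up front and never tuned to outcomes.

## 10. Numerical choices

- Percentiles (quartiles, the 80th-percentile cut) use numpy's default linear
  interpolation (type-7).
- The MAD is unscaled unless `scaled=True` is passed (factor 1.4826).
- All thresholds state their boundary semantics: depth ≥ 6, affinity
  ≤ 500 nM, TCGA TPM strictly > 1, RI outlier strictly > median + 3·MAD and
  ≥ transcript count, "high" strictly > the percentile.
- Medians use exact midpoint interpolation for even counts.
- TSV tables carry a `# tvburden-table v1 <name>` header line; reports are
  JSON with a SHA-256 digest of their canonical serialization.

## 11. Limitations

- The synthetic generator validates *software correctness*, not biology: its
  AUCs, hazard ratios, and variability levels follow from planted parameters
  and say nothing about real cohorts.
- Binding affinities are simulated; no MHC-binding predictor is bundled.
  Real use requires externally produced binding tables.
- The variant space is a single abstract contig with disjoint truth/noise
  coordinate ranges; mapping artifacts, clonality, and purity are out of
  scope.
- The closest-normal scan is exhaustive and ungapped; for full-size proteomes
  it is O(proteome × peptide length) per peptide and will be slow in Python
  at scale.
- Logistic fits under perfect separation report a flagged, regularized slope
  with no p value rather than failing — downstream consumers must check
  `separation_flag`.
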