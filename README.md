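# tvburden

Tumor variant burden metrics and their evaluation as immunotherapy biomarkers.

Tumor mutational burden (TMB) — the count of somatic variants in a tumor,
usually normalized to megabases of adequately covered genome — is widely used
to predict which patients respond to immune checkpoint inhibitors (αPD1,
αCTLA4). This package implements the full family of burden metrics around
that idea and the statistical machinery to judge them:

- **Consensus TMB.** Somatic variant callers disagree substantially on the
  same tumor; `tvburden` forms a consensus call set (variants supported by a
  minimum number of callers, default 2), normalizes variants to a minimal
  representation so identity keys are comparable across callers, and reports
  TMB both raw and per megabase covered at depth ≥ 6. Two instability
  statistics quantify how strongly the choice of caller moves the metric.
- **Neoepitope burden.** Every 8–24-mer peptide window covering an altered
  residue is a candidate neoepitope — an interior substitution yields exactly
  272 such windows. Peptides predicted to bind a patient HLA allele at
  ≤ 500 nM are *binders*; burdens are weighted by the number of presenting
  alleles (A), the Hamming distance to the closest normal proteome peptide
  found by exhaustive BLOSUM62 scan (M), reference-cohort expression (T), and
  patient-level expression evidence (E), singly or multiplicatively.
- **Tumor variant burden (TVB).** RNA-seq adds two tumor-specific variant
  classes: splice junctions with canonical motifs seen in tumor but in no
  normal sample (partially but not fully annotated), and retained introns
  passing expression filters plus a median + 3·MAD outlier rule. TVB is the
  exact sum of somatic variants, tumor-specific junctions, and retained
  introns.
- **Outcome evaluation.** ROC/AUC (trapezoidal area, identical to the
  Mann–Whitney pair statistic), logistic regression of response on
  log2(burden + 1) with Benjamini–Hochberg adjustment across metrics, high/low
  classification at the disease-matched 80th percentile, Cox proportional
  hazards and Kaplan–Meier survival, threshold sweeps, and cross-metric
  classification concordance.
- **Synthetic cohorts.** A fully seeded generator plants ground truth at every
  level (true variant sets with caller-specific noise, novel junctions,
  retained-intron outliers, logistic response, proportional-hazards survival)
  so that every pipeline stage can be validated by exact recovery.

## Worked example

Library primitives:

```python
from tvburden.epitopes import enumerate_snv_peptides, closest_normal_peptide
from tvburden.consensus import caller_variability, coverage_adjusted_tmb

protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
res = enumerate_snv_peptides(protein, 60)
print("windows covering residue 60:", res.n_windows)

best, mismatches = closest_normal_peptide("SLAKWKRQT", {"asnB": protein})
print("closest normal peptide:", best, "| mismatches:", mismatches)

rec = coverage_adjusted_tmb(3606, 200.0, patient="P1")
print("coverage-adjusted TMB:", rec.adjusted, "mut/Mbp")
print("instability {100,150,200}:", round(caller_variability({"a":100.,"b":150.,"c":200.}), 4))
```

prints:

```
windows covering residue 60: 272
closest normal peptide: SLAKWKRQT | mismatches: 0
coverage-adjusted TMB: 18.03 mut/Mbp
instability {100,150,200}: 0.3333
```

End-to-end on a synthetic cohort — generate a 60-patient bundle, then run
all pipeline stages (consensus → burdens → evaluation):

```python
import numpy as np
from tvburden.synthetic import CohortConfig, CallerModel, generate_cohort, write_bundle
from tvburden.pipeline import PipelineConfig, run_pipeline

config = CohortConfig(
    n_patients_per_type={"melanoma": 40, "NSCLC": 20},
    tmb_lognormal={"melanoma": (np.log(300.0), 0.9), "NSCLC": (np.log(150.0), 0.7)},
    caller_models=(
        CallerModel("muse", 0.90, 1.0),
        CallerModel("mutect", 0.95, 2.0),
        CallerModel("varscan2", 0.85, 1.5),
    ),
    coverage_mbp=(100.0, 15.0),
    jx_lognormal=(np.log(25.0), 0.3),
    rna_fraction=0.5,
    epitope_variants_cap=3,
    seed=42,
)
write_bundle(generate_cohort(config), "demo")

report = run_pipeline(PipelineConfig(workdir="demo", cohorts=("melanoma", "NSCLC", "all")))
print("AUC (all):", report["auc"]["all"])
print("cohort caller variability:", round(report["cohort_caller_variability"], 4))
```

Actual output (deterministic for `seed=42`):

```
INFO:tvburden.pipeline:consensus stage: 60 patients
INFO:tvburden.pipeline:burden stage: 60 patients x 20 metrics
AUC (all): {'tmb_raw': 0.5660377358490566, 'tmb_per_mbp': 0.5552560646900269,
 'tmb_x_hla': 0.549865229110512, 'nb': 0.2533692722371968,
 'nb_A': 0.25606469002695414, 'nb_M': 0.376010781671159,
 'nb_T': 0.376010781671159, 'tvb': 0.8115942028985507}
cohort caller variability: 0.1968
```

The intermediate tables are plain TSV, e.g. `demo/tmb.tsv`:

```
# tvburden-table v1 consensus_tmb
patient_id	tmb_raw	mbp_covered	tmb_per_mbp	caller_variability	count_range	range_fraction
NSCLC-0000	90	89.162627	1.0093915245453682	0.265	65.0	0.325
NSCLC-0001	97	107.081123	0.9058552738562519	0.42290748898678415	122.0	0.5374449339207048
```

The same stages are available on the command line:

```bash
tvburden simulate --outdir demo --seed 42
tvburden consensus --workdir demo
tvburden burden --workdir demo
tvburden evaluate --workdir demo --cohorts melanoma,NSCLC,all
# or everything at once:
tvburden run --workdir demo --seed 42 --simulate
```

## Reproduction

The acceptance suite lives in `tests/test_acceptance.py` (one test per
criterion; see its module docstring for the list) and runs with the rest of
the tests:

```bash
python -m pytest -q tests/
```

The quantitative acceptance target — the 272-window count for an interior
substitution — is recomputed from scratch, cross-checked against a brute-force
substring oracle, and written as JSON by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints

```
{
 "t1": {
  "value": 272,
  "n": 25
 }
}
```

See `docs/methods.md` for the underlying models, parameter defaults, and the
scope and limitations of the synthetic data generator.
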