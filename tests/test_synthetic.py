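"""Synthetic cohort generator: determinism, planted truth, and validation."""

import numpy as np
import pandas as pd
import pytest
from conftest import small_config

from tvburden.consensus import VariantCall, consensus_variants
from tvburden.synthetic import (
    NOVEL_COORD_BASE,
    SURVIVAL_HORIZON_DAYS,
    CallerModel,
    ConfigError,
    default_config,
    generate_cohort,
    generate_proteome_and_variants,
)


def tiny_config(**overrides):
    kwargs = dict(
        n_patients_per_type={"melanoma": 5, "RCC": 4},
        tmb_lognormal={"melanoma": (np.log(300.0), 0.8), "RCC": (np.log(150.0), 0.6)},
        epitope_variants_cap=2,
    )
    kwargs.update(overrides)
    return small_config(**kwargs)


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        a = generate_cohort(tiny_config(seed=3))
        b = generate_cohort(tiny_config(seed=3))
        pd.testing.assert_frame_equal(a.clinical, b.clinical)
        pd.testing.assert_frame_equal(a.binding, b.binding)
        assert a.truth.true_count == b.truth.true_count
        assert a.truth.true_variants == b.truth.true_variants
        assert a.caller_calls == b.caller_calls

    def test_different_seed_differs(self):
        a = generate_cohort(tiny_config(seed=3, epitope_variants_cap=0))
        b = generate_cohort(tiny_config(seed=4, epitope_variants_cap=0))
        assert a.truth.true_count != b.truth.true_count

    def test_patient_streams_stable_under_cohort_composition(self):
        base = generate_cohort(tiny_config(seed=3), with_variant_sets=False, with_rna=False)
        grown = generate_cohort(
            tiny_config(
                seed=3,
                n_patients_per_type={"melanoma": 5, "RCC": 4, "NSCLC": 3},
                tmb_lognormal={
                    "melanoma": (np.log(300.0), 0.8),
                    "RCC": (np.log(150.0), 0.6),
                    "NSCLC": (np.log(200.0), 0.7),
                },
            ),
            with_variant_sets=False,
            with_rna=False,
        )
        for pid, c in base.truth.true_count.items():
            assert grown.truth.true_count[pid] == c
            assert grown.truth.response_prob[pid] == base.truth.response_prob[pid]

    def test_emission_switches_leave_outcome_layer_unchanged(self):
        full = generate_cohort(tiny_config(seed=5))
        lean = generate_cohort(tiny_config(seed=5), with_variant_sets=False, with_rna=False)
        pd.testing.assert_frame_equal(full.clinical, lean.clinical)
        assert lean.caller_calls == {}
        assert lean.tumor_junctions == {}


class TestPlantedTruthAndNoise:
    def test_caller_calls_split_cleanly_into_truth_and_fp_space(self, bundle):
        for pid, calls in bundle.caller_calls.items():
            truth = bundle.truth.true_variants[pid]
            assert all(v[1] > 900_000_000 for s in calls.values() for v in s - truth)
            assert all(v[1] <= 900_000_000 for v in truth)

    def test_consensus_recovers_truth_with_high_recall_and_no_fps(self, bundle):
        recalls = []
        for pid, calls in bundle.caller_calls.items():
            as_records = {
                caller: {VariantCall(*k, caller=caller) for k in keys}
                for caller, keys in calls.items()
            }
            cons = {v.key for v in consensus_variants(as_records, min_callers=2)}
            truth = bundle.truth.true_variants[pid]
            assert all(k[1] <= 900_000_000 for k in cons), "no consensus false positive"
            assert cons <= truth
            if truth:
                recalls.append(len(cons & truth) / len(truth))
        assert np.mean(recalls) > 0.9

    def test_planted_junction_acceptors_live_in_novel_space(self, bundle):
        for keys in bundle.truth.true_junctions.values():
            assert all(k[2] >= NOVEL_COORD_BASE for k in keys)

    def test_truth_tables_cover_exactly_the_emitted_patients(self, bundle):
        pids = set(bundle.clinical["patient_id"])
        assert set(bundle.truth.true_count) == pids
        assert set(bundle.caller_calls) == pids
        rna_pids = set(bundle.clinical.loc[bundle.clinical["has_rna"], "patient_id"])
        assert set(bundle.tumor_junctions) == rna_pids
        assert set(bundle.truth.true_introns) == rna_pids


class TestClinicalLayer:
    def test_schema_and_outcome_ranges(self, bundle):
        c = bundle.clinical
        assert {
            "patient_id", "cancer_type", "therapy", "response", "has_rna",
            "hla_alleles", "os_time", "os_event",
        } <= set(c.columns)
        assert ((c["os_time"] > 0) & (c["os_time"] <= SURVIVAL_HORIZON_DAYS)).all()
        assert c["os_event"].dtype == bool
        assert (~c.loc[c["os_event"], "os_time"].eq(SURVIVAL_HORIZON_DAYS) |
                c.loc[c["os_event"], "os_time"].lt(SURVIVAL_HORIZON_DAYS + 1)).all()

    def test_therapy_assignment_rule(self, bundle):
        c = bundle.clinical
        assert (c.loc[c["cancer_type"] != "melanoma", "therapy"] == "aPD1").all()
        assert set(c.loc[c["cancer_type"] == "melanoma", "therapy"]) <= {"aPD1", "aCTLA4"}

    def test_high_hazard_class_is_top_quintile_per_type(self, bundle):
        for ctype, grp in bundle.clinical.groupby("cancer_type"):
            counts = np.array([bundle.truth.true_count[p] for p in grp["patient_id"]])
            cut = np.percentile(counts, 80)
            for p, cnt in zip(grp["patient_id"], counts):
                assert bundle.truth.hazard_class[p] == ("high" if cnt > cut else "low")

    def test_binding_table_is_well_formed(self, bundle):
        b = bundle.binding
        assert (b["affinity_nm"] > 0).all()
        assert b["peptide"].str.len().between(8, 11).all()
        hla_ok = [
            allele in bundle.hla[pid]
            for pid, allele in zip(b["patient_id"], b["allele"])
        ]
        assert all(hla_ok)


class TestConfigValidation:
    def test_default_config_is_valid_and_meta_cohort_scaled(self):
        cfg = default_config()
        cfg.validate()
        assert sum(cfg.n_patients_per_type.values()) == 431
        assert len(cfg.caller_models) == 6

    @pytest.mark.parametrize(
        "overrides,needle",
        [
            (dict(n_patients_per_type={}), "n_patients_per_type"),
            (dict(rna_fraction=1.5), "rna_fraction"),
            (dict(coverage_mbp=(0.0, 1.0)), "coverage_mbp"),
            (dict(epitope_variants_cap=-1), "epitope_variants_cap"),
        ],
    )
    def test_errors_name_the_offending_field(self, overrides, needle):
        cfg = tiny_config()
        for k, v in overrides.items():
            setattr(cfg, k, v)
        with pytest.raises(ConfigError, match=needle):
            generate_cohort(cfg)

    def test_caller_model_validation(self):
        with pytest.raises(ConfigError):
            CallerModel("bad", 1.5, 1.0).validate()
        with pytest.raises(ConfigError):
            CallerModel("bad", 0.9, -1.0).validate()


class TestProteome:
    def test_proteome_generation_is_deterministic_and_valid(self):
        p1, v1 = generate_proteome_and_variants(5, range(50, 80), 10, seed=2)
        p2, v2 = generate_proteome_and_variants(5, range(50, 80), 10, seed=2)
        assert p1 == p2 and len(p1) == 5
        for v in v1:
            assert p1[v.protein_id][v.position - 1] == v.ref_aa != v.alt_aa
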