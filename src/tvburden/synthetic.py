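"""Synthetic cohorts with the statistical structure the burden analysis assumes.

The generator emulates a pan-cancer immunotherapy meta-cohort: per-cancer-type
lognormal somatic variant counts, a depth-thresholded genome coverage per
sample, multiple imperfect variant callers (a sensitivity subsample of the
true variant set plus Poisson false positives per Mbp), HLA genotypes drawn
from allele pools, lognormal peptide-MHC affinities with a controllable
binder fraction, tumor splice junctions overlapping a normal compendium with
planted tumor-specific junctions, per-transcript intron read counts with
planted retention outliers, and response/survival outcomes generated from
logistic and proportional-hazards models on the true log2 burden.

All randomness derives from a single root seed; per-patient substreams are
keyed by a hash of the patient id, so regenerating any patient is bit-stable
regardless of cohort composition.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.special import expit

from . import io as tio
from .epitopes import AA_ALPHABET, enumerate_snv_peptides
from .junctions import JunctionRecord, SpliceAnnotation

CHROM = "chr1"
NOVEL_COORD_BASE = 1_000_000_000  # planted junction acceptors live above this
SURVIVAL_HORIZON_DAYS = 2885.0  # administrative censoring horizon
HIGH_TMB_PERCENTILE = 80.0


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class CallerModel:
    """Sensitivity / false-positive behavior of one variant caller."""

    name: str
    sensitivity: float
    fp_rate: float  # false positives per Mbp covered

    def validate(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigError(f"caller_models[{self.name}].sensitivity outside [0, 1]")
        if self.fp_rate < 0:
            raise ConfigError(f"caller_models[{self.name}].fp_rate must be >= 0")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients_per_type: Mapping[str, int]
    tmb_lognormal: Mapping[str, tuple[float, float]]  # type -> (mu, sigma) on counts
    caller_models: tuple[CallerModel, ...]
    coverage_mbp: tuple[float, float] = (200.0, 30.0)  # (mean, sd)
    n_hla_alleles: int = 6  # draws per MHC class
    affinity_model: tuple[float, float, float] = (np.log(5000.0), 1.5, 0.1)
    # (beta0, beta per log2 burden, additive offset for aCTLA4 therapy)
    response_model: tuple[float, float, float] = (-4.0, 0.3, -0.5)
    survival_model: tuple[float, float] = (1.0 / 1500.0, 0.5)  # (baseline hazard/day, HR high TMB)
    rna_fraction: float = 0.25
    jx_lognormal: tuple[float, float] = (np.log(1500.0), 0.3)  # planted junctions/patient
    epitope_variants_cap: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not self.n_patients_per_type:
            raise ConfigError("n_patients_per_type is empty")
        for t, n in self.n_patients_per_type.items():
            if n < 0:
                raise ConfigError(f"n_patients_per_type[{t}] must be >= 0")
            if t not in self.tmb_lognormal:
                raise ConfigError(f"tmb_lognormal missing cancer type {t}")
        for t, (_, sigma) in self.tmb_lognormal.items():
            if sigma <= 0:
                raise ConfigError(f"tmb_lognormal[{t}].sigma must be > 0")
        if not self.caller_models:
            raise ConfigError("caller_models is empty")
        for cm in self.caller_models:
            cm.validate()
        if self.coverage_mbp[0] <= 0 or self.coverage_mbp[1] <= 0:
            raise ConfigError("coverage_mbp mean and sd must be > 0")
        if self.n_hla_alleles < 1:
            raise ConfigError("n_hla_alleles must be >= 1")
        if self.affinity_model[1] <= 0:
            raise ConfigError("affinity_model.sd must be > 0")
        if not 0.0 <= self.affinity_model[2] <= 1.0:
            raise ConfigError("affinity_model.binder_fraction outside [0, 1]")
        if self.survival_model[0] <= 0 or self.survival_model[1] <= 0:
            raise ConfigError("survival_model entries must be > 0")
        if not 0.0 <= self.rna_fraction <= 1.0:
            raise ConfigError("rna_fraction outside [0, 1]")
        if self.epitope_variants_cap < 0:
            raise ConfigError("epitope_variants_cap must be >= 0")


DEFAULT_CALLERS = (
    CallerModel("muse", 0.92, 2.0),
    CallerModel("mutect", 0.95, 3.0),
    CallerModel("pindel", 0.70, 4.0),
    CallerModel("radia", 0.85, 2.5),
    CallerModel("somaticsniper", 0.88, 1.5),
    CallerModel("varscan2", 0.90, 2.0),
)


def default_config(seed: int = 0) -> CohortConfig:
    """Pan-cancer meta-cohort emulating the analysis's study composition.

    Patient counts per cancer type match the assembled meta-cohort (302
    melanoma, 34 NSCLC, 10 prostate, 57 RCC, 28 MMR-deficient); lognormal
    medians approximate the per-type consensus variant-count medians.
    """
    return CohortConfig(
        n_patients_per_type={
            "melanoma": 302,
            "NSCLC": 34,
            "prostate": 10,
            "RCC": 57,
            "MMR": 28,
        },
        tmb_lognormal={
            "melanoma": (np.log(3600.0), 1.0),
            "NSCLC": (np.log(1500.0), 0.8),
            "prostate": (np.log(635.0), 0.6),
            "RCC": (np.log(1100.0), 0.6),
            "MMR": (np.log(5632.0), 0.7),
        },
        caller_models=DEFAULT_CALLERS,
        seed=seed,
    )


@dataclass
class SyntheticTruth:
    """Ground truth recorded before noise is applied."""

    true_count: dict[str, int] = field(default_factory=dict)
    true_variants: dict[str, set] = field(default_factory=dict)
    true_junctions: dict[str, set] = field(default_factory=dict)
    true_introns: dict[str, set] = field(default_factory=dict)
    response_prob: dict[str, float] = field(default_factory=dict)
    hazard_class: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_count": self.true_count,
            "true_variants": {p: sorted(map(list, v)) for p, v in self.true_variants.items()},
            "true_junctions": {p: sorted(map(list, v)) for p, v in self.true_junctions.items()},
            "true_introns": {p: sorted(map(list, v)) for p, v in self.true_introns.items()},
            "response_prob": self.response_prob,
            "hazard_class": self.hazard_class,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class CohortBundle:
    """Everything downstream modules consume, in memory."""

    config: CohortConfig
    clinical: pd.DataFrame
    hla: dict[str, set[str]]
    coverage: dict[str, list[tuple[str, int, int, int]]]
    caller_calls: dict[str, dict[str, set[tuple]]]
    proteome: dict[str, str]
    protein_variants: pd.DataFrame
    binding: pd.DataFrame
    transcripts: dict[str, tuple[str, list[tuple[int, int]]]]
    annotation: SpliceAnnotation
    normal_junction_tables: list[list[JunctionRecord]]
    tumor_junctions: dict[str, list[JunctionRecord]]
    transcript_quant: pd.DataFrame
    intron_counts: pd.DataFrame
    intron_sequences: dict[tuple[str, int], str]
    upstream_cds: dict[str, str]
    normal_ris: set[tuple[str, int]]
    truth: SyntheticTruth


def _patient_rng(seed: int, patient_id: str, stage: int) -> Generator:
    """Deterministic per-patient substream, stable under cohort composition."""
    return default_rng(SeedSequence([seed, zlib.crc32(patient_id.encode()), stage]))


def _random_protein(rng: Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


@dataclass(frozen=True)
class ProteinVariant:
    """A protein-coordinate variant emitted by the generator."""

    variant_id: str
    protein_id: str
    position: int  # 1-based residue index
    ref_aa: str
    alt_aa: str
    vclass: str  # substitution | insertion | deletion


def generate_proteome_and_variants(
    n_proteins: int,
    lengths: range,
    n_variants: int,
    seed: int,
    sub_fraction: float = 0.9,
) -> tuple[dict[str, str], list[ProteinVariant]]:
    """Random proteome plus protein-coordinate variants, deterministic under seed."""
    if min(lengths) < 1:
        raise ValueError("protein lengths must be >= 1")
    rng = default_rng(SeedSequence([seed, 0x5E0]))
    proteome = {
        f"PROT{i:04d}": _random_protein(rng, int(rng.integers(lengths.start, lengths.stop)))
        for i in range(n_proteins)
    }
    positions = [(pid, p) for pid, seq in proteome.items() for p in range(1, len(seq) + 1)]
    if n_variants > len(positions):
        raise ValueError(
            f"n_variants={n_variants} exceeds {len(positions)} available positions"
        )
    chosen = rng.choice(len(positions), size=n_variants, replace=False)
    variants = []
    for k, idx in enumerate(sorted(chosen)):
        pid, pos = positions[idx]
        ref = proteome[pid][pos - 1]
        u = rng.random()
        if u < sub_fraction:
            alt = rng.choice([a for a in AA_ALPHABET if a != ref])
            vclass = "substitution"
        elif u < sub_fraction + (1 - sub_fraction) / 2:
            alt = ref + _random_protein(rng, int(rng.integers(1, 4)))
            vclass = "insertion"
        else:
            alt = "-"
            vclass = "deletion"
        variants.append(ProteinVariant(f"var{k:05d}", pid, pos, ref, str(alt), vclass))
    return proteome, variants


def _gene_model(rng: Generator, n_transcripts: int = 120) -> dict[str, tuple[str, list[tuple[int, int]]]]:
    """Synthetic single-chromosome transcript models with 4-8 exons each."""
    transcripts = {}
    cursor = 10_000
    for i in range(n_transcripts):
        n_exons = int(rng.integers(4, 9))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            elen = int(rng.integers(100, 300))
            exons.append((pos, pos + elen - 1))
            pos += elen + int(rng.integers(200, 2000))  # intron
        transcripts[f"TX{i:04d}"] = (CHROM, exons)
        cursor = pos + 5_000
    return transcripts


def _sample_variant(rng: Generator, pos: int) -> tuple[str, int, str, str]:
    bases = "ACGT"
    ref = bases[int(rng.integers(4))]
    u = rng.random()
    if u < 0.9:  # SNV
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
    elif u < 0.95:  # insertion
        alt = ref + "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
    else:  # deletion
        ref = ref + "".join(rng.choice(list(bases), size=int(rng.integers(1, 4))))
        alt = ref[0]
    return (CHROM, pos, ref, alt)


def _draw_variant_set(rng: Generator, count: int, lo: int = 1, hi: int = 900_000_000) -> set[tuple]:
    positions: set[int] = set()
    while len(positions) < count:
        need = count - len(positions)
        positions.update(int(p) for p in rng.integers(lo, hi, size=need * 2))
    out = set()
    for pos in sorted(positions)[:count]:
        out.add(_sample_variant(rng, pos))
    return out


def generate_cohort(
    config: CohortConfig,
    with_variant_sets: bool = True,
    with_rna: bool = True,
) -> CohortBundle:
    """Generate a full synthetic cohort bundle (see module docstring).

    ``with_variant_sets`` / ``with_rna`` skip emission of the per-caller
    variant sets and the RNA-layer tables when a consumer needs only the
    clinical/outcome layer; the generated quantities and their random streams
    are unchanged for the parts that are emitted.
    """
    config.validate()
    seed = config.seed
    cohort_rng = default_rng(SeedSequence([seed, 0xC0110]))

    # ---- cohort-level structures --------------------------------------
    class1_pool = [f"HLA-A*{i:02d}:01" for i in range(1, 11)] + [
        f"HLA-B*{i:02d}:01" for i in range(1, 11)
    ] + [f"HLA-C*{i:02d}:01" for i in range(1, 11)]
    class2_pool = [f"HLA-DRB1*{i:02d}:01" for i in range(1, 16)] + [
        f"HLA-DQB1*{i:02d}:01" for i in range(1, 16)
    ]
    proteome, _ = generate_proteome_and_variants(
        n_proteins=40, lengths=range(120, 400), n_variants=0, seed=seed
    )
    protein_ids = sorted(proteome)
    transcripts = _gene_model(cohort_rng)
    annotation = SpliceAnnotation.from_transcript_exons(transcripts)
    tids = sorted(transcripts)

    # normal junction compendium tables: all annotated junctions, plus some
    # unannotated junctions seen in normal tissue (single-read evidence counts)
    annotated_pairs = sorted(annotation.pairs)
    novel_normals = []
    donors = sorted(annotation.donor_sites)
    for _ in range(200):
        chrom, donor = donors[int(cohort_rng.integers(len(donors)))]
        acceptor = donor + int(cohort_rng.integers(50, 5000))
        novel_normals.append((chrom, donor, acceptor))
    def _jrec(key, reads):
        return JunctionRecord(
            chrom=key[0], donor_pos=key[1], acceptor_pos=key[2], strand="+",
            motif="GT-AG", reads=reads,
        )
    normal_tables = [
        [_jrec(k, 5) for k in annotated_pairs] + [_jrec(k, 1) for k in novel_normals[:100]],
        [_jrec(k, 3) for k in annotated_pairs[::2]] + [_jrec(k, 1) for k in novel_normals[100:]],
    ]
    normal_keys = set(annotated_pairs) | set(novel_normals)

    # retained-intron layer: designate RI-capable transcripts, random intron
    # sequences and in-frame upstream CDS context per transcript
    ri_tids = tids[: max(1, len(tids) // 3)]
    intron_sequences: dict[tuple[str, int], str] = {}
    upstream_cds: dict[str, str] = {}
    n_introns_of: dict[str, int] = {}
    bases = list("ACGT")
    for tid in ri_tids:
        n_int = len(transcripts[tid][1]) - 1
        n_introns_of[tid] = n_int
        upstream_cds[tid] = "".join(cohort_rng.choice(bases, size=90))
        for j in range(n_int):
            intron_sequences[(tid, j)] = "".join(cohort_rng.choice(bases, size=120))
    normal_ris = {
        (tid, int(cohort_rng.integers(n_introns_of[tid])))
        for tid in ri_tids[::7]
    }

    # ---- per-patient generation ---------------------------------------
    mean_cov, sd_cov = config.coverage_mbp
    log_aff_mu, log_aff_sd, binder_frac = config.affinity_model
    beta0, beta_burden, ctla4_offset = config.response_model

    clinical_rows = []
    hla: dict[str, set[str]] = {}
    coverage: dict[str, list[tuple[str, int, int, int]]] = {}
    caller_calls: dict[str, dict[str, set[tuple]]] = {}
    pv_rows = []
    binding_rows = []
    tumor_junctions: dict[str, list[JunctionRecord]] = {}
    quant_rows = []
    intron_rows = []
    truth = SyntheticTruth()

    patients = [
        (ctype, f"{ctype}-{i:04d}")
        for ctype in sorted(config.n_patients_per_type)
        for i in range(config.n_patients_per_type[ctype])
    ]

    for ctype, pid in patients:
        rng = _patient_rng(seed, pid, stage=0)
        mu, sigma = config.tmb_lognormal[ctype]
        true_count = int(round(rng.lognormal(mu, sigma)))
        truth.true_count[pid] = true_count
        cov = max(1.0, rng.normal(mean_cov, sd_cov))
        cov_bp = int(round(cov * 1e6))
        coverage[pid] = [
            (CHROM, 0, cov_bp, 30),  # well covered
            (CHROM, cov_bp, cov_bp + 500_000, 3),  # below depth threshold
        ]

        # each emission layer draws from its own substream so that skipping a
        # layer (with_variant_sets / with_rna) cannot shift any other draw
        if with_variant_sets:
            rng_var = _patient_rng(seed, pid, stage=3)
            true_set = _draw_variant_set(rng_var, true_count)
            truth.true_variants[pid] = true_set
            true_list = sorted(true_set)
            calls: dict[str, set[tuple]] = {}
            for cm in config.caller_models:
                keep = rng_var.random(len(true_list)) < cm.sensitivity
                called = {v for v, k in zip(true_list, keep) if k}
                n_fp = int(rng_var.poisson(cm.fp_rate * cov))
                called |= _draw_variant_set(rng_var, n_fp, lo=900_000_001, hi=999_999_999)
                calls[cm.name] = called
            caller_calls[pid] = calls

        alleles = {str(a) for a in rng.choice(class1_pool, size=config.n_hla_alleles)} | {
            str(a) for a in rng.choice(class2_pool, size=config.n_hla_alleles)
        }
        hla[pid] = alleles

        # protein-level epitope layer: capped subsample of the true variants
        rng_epi = _patient_rng(seed, pid, stage=4)
        n_prot_vars = min(true_count, config.epitope_variants_cap)
        peptides: set[str] = set()
        for k in range(n_prot_vars):
            prot_id = protein_ids[int(rng_epi.integers(len(protein_ids)))]
            seq = proteome[prot_id]
            pos = int(rng_epi.integers(1, len(seq) + 1))
            ref = seq[pos - 1]
            alt = str(rng_epi.choice([a for a in AA_ALPHABET if a != ref]))
            pv_rows.append((pid, f"{pid}.v{k}", prot_id, pos, ref, alt, "substitution"))
            mutated = seq[: pos - 1] + alt + seq[pos:]
            res = enumerate_snv_peptides(mutated, pos, lengths=range(8, 12), variant_id=f"{pid}.v{k}")
            peptides |= res.peptides
        for pep in sorted(peptides):
            for allele in sorted(alleles):
                if rng_epi.random() < binder_frac:
                    affinity = float(rng_epi.uniform(1.0, 500.0))
                else:
                    affinity = float(np.exp(rng_epi.normal(log_aff_mu, log_aff_sd)))
                binding_rows.append((pid, pep, allele, max(affinity, 0.01)))

        has_rna = bool(rng.random() < config.rna_fraction)

        if has_rna and with_rna:
            rng_rna = _patient_rng(seed, pid, stage=5)
            # tumor junction table: annotated background + planted novel +
            # decoys exercising every removal rule
            jx_mu, jx_sigma = config.jx_lognormal
            n_planted = max(1, int(round(rng_rna.lognormal(jx_mu, jx_sigma))))
            bg_idx = rng_rna.choice(len(annotated_pairs), size=min(100, len(annotated_pairs)), replace=False)
            table = [
                annotation.annotate(_jrec(annotated_pairs[i], int(rng_rna.integers(1, 50))))
                for i in sorted(bg_idx)
            ]
            planted_keys = set()
            used_acceptors = set()
            while len(planted_keys) < n_planted:
                chrom, donor = donors[int(rng_rna.integers(len(donors)))]
                acceptor = NOVEL_COORD_BASE + int(rng_rna.integers(1, 900_000_000))
                if acceptor in used_acceptors:
                    continue
                used_acceptors.add(acceptor)
                key = (chrom, donor, acceptor)
                planted_keys.add(key)
                table.append(
                    JunctionRecord(
                        chrom=chrom, donor_pos=donor, acceptor_pos=acceptor,
                        strand="+", motif="GT-AG", reads=int(rng_rna.integers(1, 20)),
                        left_annotated=True, right_annotated=False,
                    )
                )
            # decoys: non-canonical motif, and neither-end-annotated
            table.append(
                JunctionRecord(
                    chrom=CHROM, donor_pos=NOVEL_COORD_BASE + 1, acceptor_pos=NOVEL_COORD_BASE + 999,
                    strand="+", motif="other", reads=4, left_annotated=True,
                )
            )
            table.append(
                JunctionRecord(
                    chrom=CHROM, donor_pos=NOVEL_COORD_BASE + 5, acceptor_pos=NOVEL_COORD_BASE + 777,
                    strand="+", motif="GT-AG", reads=4,
                )
            )
            tumor_junctions[pid] = table
            truth.true_junctions[pid] = planted_keys

            # retained-intron layer: counts with planted outliers
            planted_ris = set()
            for tid in ri_tids:
                n_int = n_introns_of[tid]
                counts = rng_rna.poisson(10.0, size=n_int).astype(float)
                tx_count = float(rng_rna.poisson(30.0) + 10)
                plant_here = rng_rna.random() < 0.15
                chosen = None
                if plant_here and n_int > 0:
                    candidates = [
                        j for j in range(n_int) if (tid, j) not in normal_ris
                    ]
                    if candidates:
                        chosen = int(rng_rna.choice(candidates))
                        med = float(np.median(counts))
                        madv = float(np.median(np.abs(counts - med)))
                        counts[chosen] = med + 10.0 * max(madv, 1.0) + tx_count
                        planted_ris.add((tid, chosen))
                for j in range(n_int):
                    intron_rows.append((pid, tid, j, float(counts[j]), tx_count))
                quant_rows.append(
                    (
                        tid,
                        pid,
                        float(rng_rna.uniform(2.0, 20.0)),
                        float(rng_rna.poisson(60.0)),
                        float(rng_rna.uniform(0.1, 0.6)),
                    )
                )
            truth.true_introns[pid] = planted_ris

        # outcomes: separate substream so the outcome layer is stable even if
        # upstream emission options change
        rng_out = _patient_rng(seed, pid, stage=1)
        if ctype == "melanoma":
            therapy = "aPD1" if rng_out.random() < 0.2 else "aCTLA4"
        else:
            therapy = "aPD1"
        eta = beta0 + beta_burden * np.log2(true_count + 1.0)
        if therapy == "aCTLA4":
            eta += ctla4_offset
        p_resp = float(expit(eta))
        truth.response_prob[pid] = p_resp
        response = bool(rng_out.random() < p_resp)
        clinical_rows.append(
            {
                "patient_id": pid,
                "cancer_type": ctype,
                "therapy": therapy,
                "response": response,
                "has_rna": has_rna,
                "hla_alleles": ";".join(sorted(alleles)),
            }
        )

    clinical = pd.DataFrame(clinical_rows)

    # survival: hazard class depends on the disease-matched 80th percentile of
    # the true counts, so it is assigned after the full cohort is drawn
    baseline_hazard, hr_high = config.survival_model
    os_time, os_event = [], []
    for ctype_grp, grp in clinical.groupby("cancer_type", sort=False):
        counts = np.array([truth.true_count[p] for p in grp["patient_id"]])
        cut = np.percentile(counts, HIGH_TMB_PERCENTILE)
        for p, c in zip(grp["patient_id"], counts):
            high = c > cut
            truth.hazard_class[p] = "high" if high else "low"
    for row in clinical.itertuples():
        rng_surv = _patient_rng(seed, row.patient_id, stage=2)
        hazard = baseline_hazard * (hr_high if truth.hazard_class[row.patient_id] == "high" else 1.0)
        t = float(rng_surv.exponential(1.0 / hazard))
        os_time.append(max(1.0, min(t, SURVIVAL_HORIZON_DAYS)))
        os_event.append(bool(t <= SURVIVAL_HORIZON_DAYS))
    clinical["os_time"] = os_time
    clinical["os_event"] = os_event

    protein_variants = pd.DataFrame(
        pv_rows,
        columns=["patient_id", "variant_id", "protein_id", "position", "ref_aa", "alt_aa", "vclass"],
    )
    binding = pd.DataFrame(
        binding_rows, columns=["patient_id", "peptide", "allele", "affinity_nm"]
    )
    transcript_quant = pd.DataFrame(
        quant_rows, columns=["transcript_id", "sample", "tpm", "unique_counts", "retention_frac"]
    )
    intron_counts = pd.DataFrame(
        intron_rows,
        columns=["patient_id", "transcript_id", "intron_index", "read_count", "transcript_count"],
    )

    return CohortBundle(
        config=config,
        clinical=clinical,
        hla=hla,
        coverage=coverage,
        caller_calls=caller_calls,
        proteome=proteome,
        protein_variants=protein_variants,
        binding=binding,
        transcripts=transcripts,
        annotation=annotation,
        normal_junction_tables=normal_tables,
        tumor_junctions=tumor_junctions,
        transcript_quant=transcript_quant,
        intron_counts=intron_counts,
        intron_sequences=intron_sequences,
        upstream_cds=upstream_cds,
        normal_ris=normal_ris,
        truth=truth,
    )


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    """Persist the bundle in the standard on-disk formats the CLI stages read."""
    out = Path(outdir)
    for sub in ("vcf", "coverage", "junctions", "normals"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    tio.write_table(bundle.clinical, out / "clinical.tsv", "clinical")
    bundle.truth.to_json(out / "truth.json")
    tio.write_fasta(out / "proteome.fa", bundle.proteome)
    tio.write_table(bundle.protein_variants, out / "protein_variants.tsv", "protein_variants")
    tio.write_table(bundle.binding, out / "binding.tsv", "binding")
    hla_df = pd.DataFrame(
        [(p, a) for p, alleles in sorted(bundle.hla.items()) for a in sorted(alleles)],
        columns=["patient_id", "allele"],
    )
    tio.write_table(hla_df, out / "hla.tsv", "hla_genotypes")
    tio.write_gtf(out / "annotation.gtf", bundle.transcripts)
    for pid, track in bundle.coverage.items():
        tio.write_bed_coverage(out / "coverage" / f"{pid}.bed", track)
    for pid, calls in bundle.caller_calls.items():
        for caller, vs in calls.items():
            tio.write_vcf(out / "vcf" / f"{pid}.{caller}.vcf", sorted(vs))
    for i, table in enumerate(bundle.normal_junction_tables):
        tio.write_sj_tab(out / "normals" / f"normal{i}.SJ.out.tab", table)
    for pid, table in bundle.tumor_junctions.items():
        tio.write_sj_tab(out / "junctions" / f"{pid}.SJ.out.tab", table)
    tio.write_table(bundle.transcript_quant, out / "transcript_quant.tsv", "transcript_quant")
    tio.write_table(bundle.intron_counts, out / "intron_counts.tsv", "intron_counts")
    seq_df = pd.DataFrame(
        [
            (tid, idx, seq, bundle.upstream_cds[tid])
            for (tid, idx), seq in sorted(bundle.intron_sequences.items())
        ],
        columns=["transcript_id", "intron_index", "intron_sequence", "upstream_cds"],
    )
    tio.write_table(seq_df, out / "intron_sequences.tsv", "intron_sequences")
    ri_df = pd.DataFrame(sorted(bundle.normal_ris), columns=["transcript_id", "intron_index"])
    tio.write_table(ri_df, out / "normal_ris.tsv", "normal_retained_introns")
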