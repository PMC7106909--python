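"""End-to-end orchestration: simulate -> consensus -> burdens -> RNA -> evaluate.

Each stage reads and writes plain files under the working directory using the
layout produced by :func:`tvburden.synthetic.write_bundle`, so stages are
independently runnable and testable.  Patients lacking RNA inputs simply get
NaN for the RNA-derived metrics; the DNA-only metrics are always produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .burdens import (
    BURDEN_COLUMNS,
    BindingRecord,
    EpitopeWeights,
    burden_row,
    call_binders,
)
from .consensus import (
    caller_variability,
    cohort_variability,
    consensus_variants,
    coverage_adjusted_tmb,
    genome_coverage_mbp,
    tmb_range_fraction,
)
from .epitopes import closest_normal_peptide, enumerate_snv_peptides
from .evaluate import (
    PatientRecord,
    bh_adjust,
    classification_concordance,
    classify_high_low,
    fit_response_model,
    fit_survival,
    roc_auc,
    threshold_sweep,
)
from .introns import (
    IntronRecord,
    TranscriptQuant,
    filter_transcripts,
    intron_outlier_filter,
    ri_peptides,
    subtract_normal_ris,
)
from .junctions import build_compendium, junction_burden, tumor_specific_junctions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Structured pipeline configuration; every threshold carries its default."""

    workdir: str = "."
    min_depth: int = 6
    min_callers: int = 2
    affinity_threshold_nm: float = 500.0
    tcga_tpm_threshold: float = 1.0
    mad_multiplier: float = 3.0
    sample_frac: float = 0.25
    percentile: float = 80.0
    pseudocount: float = 1.0
    cohorts: tuple[str, ...] = ("melanoma", "RCC", "NSCLC", "all")
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        if isinstance(cfg.cohorts, list):
            cfg.cohorts = tuple(cfg.cohorts)
        return cfg


def consensus_stage(workdir: Path, config: PipelineConfig) -> pd.DataFrame:
    """Per-patient consensus TMB and cross-caller instability from VCFs + BED."""
    clinical = tio.read_table(workdir / "clinical.tsv")
    rows = []
    for pid in clinical["patient_id"]:
        vcfs = sorted((workdir / "vcf").glob(f"{pid}.*.vcf"))
        if not vcfs:
            continue
        per_caller = {
            p.name.split(".")[-2]: set(tio.read_vcf(p, caller=p.name.split(".")[-2]))
            for p in vcfs
        }
        cons = consensus_variants(per_caller, min_callers=config.min_callers)
        track = tio.read_bed_coverage(workdir / "coverage" / f"{pid}.bed")
        mbp = genome_coverage_mbp(track, min_depth=config.min_depth)
        rec = coverage_adjusted_tmb(len(cons), mbp, patient=pid)
        per_caller_counts = {c: float(len(v)) for c, v in per_caller.items()}
        rng, frac = tmb_range_fraction(per_caller_counts)
        rows.append(
            {
                "patient_id": pid,
                "tmb_raw": rec.raw_count,
                "mbp_covered": rec.mbp_covered,
                "tmb_per_mbp": rec.adjusted,
                "caller_variability": caller_variability(per_caller_counts),
                "count_range": rng,
                "range_fraction": frac,
            }
        )
    df = pd.DataFrame(rows)
    tio.write_table(df, workdir / "tmb.tsv", "consensus_tmb")
    logger.info("consensus stage: %d patients", len(df))
    return df


def burden_stage(workdir: Path, config: PipelineConfig) -> pd.DataFrame:
    """Weighted neoepitope burdens + Jx/RI/TVB assembly into the wide table."""
    clinical = tio.read_table(workdir / "clinical.tsv")
    tmb = tio.read_table(workdir / "tmb.tsv").set_index("patient_id")
    proteome = tio.read_fasta(workdir / "proteome.fa")
    variants = tio.read_table(workdir / "protein_variants.tsv")
    binding = tio.read_table(workdir / "binding.tsv")
    hla = tio.read_table(workdir / "hla.tsv")
    hla_by_patient = hla.groupby("patient_id")["allele"].apply(set).to_dict()

    # TCGA-style expression quantiles and per-patient exon coverage are
    # derived from the transcript quantification table when present
    tcga_q: dict[str, float] = {}
    exon_cov: dict[str, dict[str, int]] = {}
    quant_path = workdir / "transcript_quant.tsv"
    if quant_path.exists():
        q = tio.read_table(quant_path)
        tcga_q = q.groupby("transcript_id")["tpm"].quantile(0.75).to_dict()
        for (pid, tid), sub in q.groupby(["sample", "transcript_id"]):
            exon_cov.setdefault(pid, {})[tid] = int(sub["unique_counts"].max())

    jx = _junction_stage(workdir, config)
    ri = _intron_stage(workdir, config)

    rows = []
    for row in clinical.itertuples():
        pid = row.patient_id
        if pid not in tmb.index:
            continue
        alleles = hla_by_patient.get(pid, set())
        sub = binding[binding["patient_id"] == pid]
        records = [
            BindingRecord(r.peptide, r.allele, r.affinity_nm) for r in sub.itertuples()
        ]
        binder_map = call_binders(records, alleles, threshold_nm=config.affinity_threshold_nm)
        pvars = variants[variants["patient_id"] == pid]
        pep_variant: dict[str, set[str]] = {}
        for v in pvars.itertuples():
            seq = proteome[v.protein_id]
            mutated = seq[: v.position - 1] + v.alt_aa + seq[v.position :]
            res = enumerate_snv_peptides(mutated, v.position, lengths=range(8, 12))
            for pep in res.peptides:
                pep_variant.setdefault(pep, set()).add(v.protein_id)
        epitopes = []
        for pep, alleles_bound in binder_map.items():
            origins = pep_variant.get(pep, set())
            _, mm = closest_normal_peptide(pep, proteome)
            t_w = sum(1 for _ in origins)  # synthetic proteome maps 1:1 to "expressed"
            e_w = len(origins) if row.has_rna else None
            epitopes.append(
                EpitopeWeights(A=len(alleles_bound), M=mm, T=t_w, E=e_w)
            )
        rows.append(
            {
                "patient_id": pid,
                **burden_row(
                    tmb_raw=int(tmb.loc[pid, "tmb_raw"]),
                    tmb_per_mbp=float(tmb.loc[pid, "tmb_per_mbp"]),
                    epitopes=epitopes,
                    n_jx=jx.get(pid),
                    n_ri=ri.get(pid, (None, None))[0],
                    n_ri_epitopes=ri.get(pid, (None, None))[1],
                    hla_count=len(alleles),
                    has_rna=bool(row.has_rna),
                ),
            }
        )
    df = pd.DataFrame(rows, columns=["patient_id"] + BURDEN_COLUMNS)
    tio.write_table(df, workdir / "burdens.tsv", "burden_table")
    logger.info("burden stage: %d patients x %d metrics", len(df), len(BURDEN_COLUMNS))
    return df


def _junction_stage(workdir: Path, config: PipelineConfig) -> dict[str, int]:
    """Tumor-specific junction burden per patient, or empty without RNA inputs."""
    jdir = workdir / "junctions"
    ndir = workdir / "normals"
    gtf = workdir / "annotation.gtf"
    if not (jdir.exists() and ndir.exists() and gtf.exists()):
        logger.warning("junction inputs missing; skipping RNA junction stage")
        return {}
    annotation = tio.splice_annotation_from_gtf(gtf)
    normal_tables = [tio.read_sj_tab(p) for p in sorted(ndir.glob("*.SJ.out.tab"))]
    compendium = build_compendium(normal_tables)
    burdens: dict[str, int] = {}
    out_rows = []
    for path in sorted(jdir.glob("*.SJ.out.tab")):
        pid = path.name.split(".SJ.out.tab")[0]
        records = [annotation.annotate(r) for r in tio.read_sj_tab(path)]
        specific = tumor_specific_junctions(records, compendium)
        burdens[pid] = junction_burden(specific)
        out_rows += [
            (pid, j.chrom, j.donor_pos, j.acceptor_pos, j.strand, j.motif, j.reads)
            for j in specific
        ]
    tio.write_table(
        pd.DataFrame(
            out_rows,
            columns=["patient_id", "chrom", "donor_pos", "acceptor_pos", "strand", "motif", "reads"],
        ),
        workdir / "tumor_specific_junctions.tsv",
        "tumor_specific_junctions",
    )
    return burdens


def _intron_stage(workdir: Path, config: PipelineConfig) -> dict[str, tuple[int, int]]:
    """(RI burden, RI epitope burden) per patient, or empty without RNA inputs."""
    needed = ["transcript_quant.tsv", "intron_counts.tsv", "normal_ris.tsv", "intron_sequences.tsv"]
    if not all((workdir / n).exists() for n in needed):
        logger.warning("intron inputs missing; skipping retained-intron stage")
        return {}
    quant = tio.read_table(workdir / "transcript_quant.tsv")
    counts = tio.read_table(workdir / "intron_counts.tsv")
    normal = tio.read_table(workdir / "normal_ris.tsv")
    seqs = tio.read_table(workdir / "intron_sequences.tsv")
    normal_keys = {(r.transcript_id, int(r.intron_index)) for r in normal.itertuples()}
    seq_of = {
        (r.transcript_id, int(r.intron_index)): (r.intron_sequence, r.upstream_cds)
        for r in seqs.itertuples()
    }
    quants = [
        TranscriptQuant(
            transcript_id=tid,
            tpm=sub["tpm"].tolist(),
            unique_counts=sub["unique_counts"].tolist(),
            intron_retention_frac=sub["retention_frac"].tolist(),
        )
        for tid, sub in quant.groupby("transcript_id")
    ]
    kept_tx = set(filter_transcripts(quants, sample_frac=config.sample_frac))
    out: dict[str, tuple[int, int]] = {}
    for pid, psub in counts.groupby("patient_id"):
        ris: set[IntronRecord] = set()
        for tid, tsub in psub.groupby("transcript_id"):
            if tid not in kept_tx:
                continue
            tsub = tsub.sort_values("intron_index")
            idx = intron_outlier_filter(
                tsub["read_count"].tolist(),
                float(tsub["transcript_count"].iloc[0]),
                mad_multiplier=config.mad_multiplier,
            )
            for i in idx:
                ris.add(IntronRecord(transcript_id=tid, intron_index=int(tsub["intron_index"].iloc[i])))
        tumor_specific = subtract_normal_ris(ris, normal_keys)
        peptides: set[str] = set()
        for ri in tumor_specific:
            pair = seq_of.get(ri.key)
            if pair is None:
                continue
            intron_seq, upstream = pair
            peptides |= ri_peptides(upstream, intron_seq)
        out[pid] = (len(tumor_specific), len(peptides))
    return out


_RESPONSE_METRICS = ["tmb_raw", "tmb_per_mbp", "tmb_x_hla", "nb", "nb_A", "nb_M", "nb_T", "tvb"]


def evaluate_stage(workdir: Path, config: PipelineConfig) -> dict:
    """ROC/AUC tables, logistic fits with BH adjustment, survival analyses."""
    clinical = tio.read_table(workdir / "clinical.tsv")
    burdens = tio.read_table(workdir / "burdens.tsv")
    df = clinical.merge(burdens, on="patient_id")
    report: dict = {"auc": {}, "logistic": [], "survival": {}, "concordance": {}}

    def cohort_frame(name: str) -> pd.DataFrame:
        return df if name == "all" else df[df["cancer_type"] == name]

    fits = []
    for cohort in config.cohorts:
        sub = cohort_frame(cohort)
        resp = sub.dropna(subset=["response"])
        labels = resp["response"].astype(int).to_numpy()
        report["auc"][cohort] = {}
        for metric in _RESPONSE_METRICS:
            scores = resp[metric].to_numpy(dtype=float)
            mask = ~np.isnan(scores)
            if mask.sum() < 10 or len(np.unique(labels[mask])) < 2:
                continue
            report["auc"][cohort][metric] = roc_auc(
                scores[mask], labels[mask], metric=metric, cohort=cohort
            ).auc
            therapy = None
            if cohort == "melanoma":
                therapy = resp["therapy"].to_numpy()[mask]
            try:
                fit = fit_response_model(
                    scores[mask], labels[mask], therapy=therapy,
                    cohort=cohort, predictor=metric, pseudocount=config.pseudocount,
                )
                fits.append(fit)
            except ValueError:
                continue
    if fits:
        adj = bh_adjust([f.p_value for f in fits])
        for f, q in zip(fits, adj):
            f.p_adjusted = float(q)
        report["logistic"] = [
            {
                "cohort": f.cohort,
                "predictor": f.predictor,
                "slope": f.slope,
                "p_value": f.p_value,
                "p_adjusted": f.p_adjusted,
                "response_prob_q25": f.response_prob_q25,
                "response_prob_q75": f.response_prob_q75,
                "n": f.n,
            }
            for f in fits
        ]

    surv_cohorts = [c for c in config.cohorts if c in {"melanoma", "RCC"}]
    for cohort in surv_cohorts:
        sub = cohort_frame(cohort).dropna(subset=["os_time", "os_event", "tmb_per_mbp"])
        if len(sub) < 10 or sub["os_event"].sum() == 0:
            continue
        records = [
            PatientRecord(
                patient_id=r.patient_id, cancer_type=r.cancer_type, therapy=r.therapy,
                response=bool(r.response), os_time=float(r.os_time),
                os_event=bool(r.os_event), has_rna=bool(r.has_rna),
            )
            for r in sub.itertuples()
        ]
        labels = classify_high_low(sub["tmb_per_mbp"].to_numpy(), config.percentile)
        fit = fit_survival(records, labels, cohort=cohort, stratifier="tmb_per_mbp",
                           percentile=config.percentile)
        sweep = threshold_sweep(records, sub["tmb_per_mbp"].to_numpy(),
                                percentile_grid=np.arange(20, 95, 10), cohort=cohort)
        report["survival"][cohort] = {
            "hazard_ratio": fit.hazard_ratio,
            "p_value": fit.p_value,
            "n_high": fit.n_high,
            "n_low": fit.n_low,
            "flagged": fit.flagged,
            "sweep": sweep.to_dict(orient="records"),
        }

    conc = classification_concordance(
        df["tmb_raw"].to_numpy(dtype=float),
        df["tmb_per_mbp"].to_numpy(dtype=float),
        percentile_grid=[50.0, config.percentile],
    )
    report["concordance"]["tmb_raw_vs_tmb_per_mbp"] = conc

    tmb = tio.read_table(workdir / "tmb.tsv")
    report["cohort_caller_variability"] = cohort_variability(
        tmb["caller_variability"].tolist()
    )
    (workdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
    return report


def run_pipeline(config: PipelineConfig, simulate_config=None) -> dict:
    """Execute all stages in order; returns the aggregated report with a digest."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if simulate_config is not None:
        from .synthetic import generate_cohort, write_bundle

        bundle = generate_cohort(simulate_config)
        write_bundle(bundle, workdir)
        logger.info("simulate stage: %d patients", len(bundle.clinical))
    consensus_stage(workdir, config)
    burden_stage(workdir, config)
    report = evaluate_stage(workdir, config)
    digest = hashlib.sha256(
        json.dumps(report, sort_keys=True, default=float).encode()
    ).hexdigest()
    report["digest"] = digest
    return report
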