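"""Binder calling and the family of raw, weighted, and combined burden metrics.

A candidate peptide counts toward the raw neoepitope burden when it is
predicted to bind at least one of the patient's MHC alleles with affinity
<= 500 nM (inclusive).  Weighted burdens re-count each epitope by per-epitope
weight components and their multiplicative combinations:

    A  number of patient MHC alleles binding the epitope (<= 500 nM)
    M  amino-acid mismatches to the closest normal proteome peptide
    T  transcripts of origin expressed in the matched TCGA cancer type
       (75th-quantile TPM strictly > 1)
    E  transcripts of origin expressed in the patient's own tumor RNA
       (>= 1 read on any exon)

The combined tumor variant burden (TVB) is the exact sum of somatic variants,
tumor-specific splice junctions, and tumor-specific retained introns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

BINDING_THRESHOLD_NM = 500.0
TCGA_TPM_THRESHOLD = 1.0


@dataclass(frozen=True)
class BindingRecord:
    """Predicted binding affinity of one peptide for one HLA allele."""

    peptide: str
    allele: str
    affinity_nm: float

    def __post_init__(self) -> None:
        if self.affinity_nm <= 0:
            raise ValueError(f"affinity must be > 0 nM, got {self.affinity_nm}")


@dataclass
class EpitopeWeights:
    """Per-epitope weight components; E is None without patient RNA data."""

    A: int = 0
    M: int = 0
    T: int = 0
    E: int | None = None

    def __post_init__(self) -> None:
        for name in ("A", "M", "T"):
            if getattr(self, name) < 0:
                raise ValueError(f"component {name} must be >= 0")
        if self.E is not None and self.E < 0:
            raise ValueError("component E must be >= 0")


def call_binders(
    records: Iterable[BindingRecord],
    patient_alleles: set[str],
    threshold_nm: float = BINDING_THRESHOLD_NM,
) -> dict[str, set[str]]:
    """Map each peptide to the set of patient alleles it binds at <= threshold.

    Records naming alleles outside the patient's genotype are skipped with a
    warning.  Peptides with records but no qualifying allele map to an empty
    set; peptides without any record are absent.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be > 0")
    binders: dict[str, set[str]] = {}
    for rec in records:
        if rec.allele not in patient_alleles:
            logger.warning(
                "skipping binding record for allele %s not in patient genotype", rec.allele
            )
            continue
        alleles = binders.setdefault(rec.peptide, set())
        if rec.affinity_nm <= threshold_nm:
            alleles.add(rec.allele)
    return binders


def raw_neoepitope_burden(binder_map: Mapping[str, set[str]]) -> int:
    """Number of peptides bound by at least one patient allele."""
    return sum(1 for alleles in binder_map.values() if alleles)


def weighted_burden(
    epitopes: Sequence[EpitopeWeights],
    components: Iterable[str] = (),
    patient: str = "",
) -> float:
    """Sum over epitopes of the product of the requested weight components.

    An empty component set falls back to the raw count of epitopes presented
    by at least one allele (A >= 1).  Requesting E for an epitope lacking
    patient RNA data is an error.
    """
    comps = list(components)
    bad = [c for c in comps if c not in "AMTE"]
    if bad:
        raise ValueError(f"unknown components {bad}; expected subset of A,M,T,E")
    if not comps:
        return float(sum(1 for e in epitopes if e.A >= 1))
    total = 0.0
    for e in epitopes:
        term = 1.0
        for c in comps:
            v = getattr(e, c)
            if v is None:
                raise ValueError(
                    f"component E requested but patient {patient!r} has no RNA data"
                )
            term *= v
        total += term
    return total


def tcga_expression_weight(
    transcripts_of_origin: Iterable[str],
    tcga_tpm_quantiles: Mapping[str, float],
) -> int:
    """T: origin transcripts whose TCGA 75th-quantile TPM is strictly > 1."""
    t = 0
    for tx in set(transcripts_of_origin):
        q = tcga_tpm_quantiles.get(tx)
        if q is None:
            logger.debug("transcript %s absent from TCGA quantile table; unexpressed", tx)
            continue
        if q > TCGA_TPM_THRESHOLD:
            t += 1
    return t


def patient_expression_weight(
    transcripts_of_origin: Iterable[str],
    exon_coverage: Mapping[str, int] | None,
) -> int:
    """E: origin transcripts with >= 1 patient RNA-seq read on any exon."""
    if exon_coverage is None:
        raise ValueError("patient has no RNA coverage data; E weight undefined")
    return sum(1 for tx in set(transcripts_of_origin) if exon_coverage.get(tx, 0) >= 1)


def tumor_variant_burden(n_somatic: int, n_jx: int, n_ri: int) -> int:
    """TVB: exact sum of somatic variants, tumor-specific junctions, and RIs."""
    for name, v in (("n_somatic", n_somatic), ("n_jx", n_jx), ("n_ri", n_ri)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return n_somatic + n_jx + n_ri


def tmb_times_hla(tmb: float, n_unique_hla: int) -> float:
    """Multiplicative combination of TMB with the patient's unique HLA count."""
    if n_unique_hla < 0:
        raise ValueError("n_unique_hla must be >= 0")
    return tmb * n_unique_hla


# Column order of the wide per-patient burden table assembled by the pipeline.
BURDEN_COLUMNS = [
    "tmb_raw",
    "tmb_per_mbp",
    "nb",
    "nb_A",
    "nb_M",
    "nb_T",
    "nb_E",
    "nb_AM",
    "nb_AT",
    "nb_AE",
    "nb_MT",
    "nb_ME",
    "nb_AMT",
    "nb_AME",
    "jx_burden",
    "ri_burden",
    "ri_epitope_burden",
    "tvb",
    "hla_count",
    "tmb_x_hla",
]


def burden_row(
    tmb_raw: int,
    tmb_per_mbp: float,
    epitopes: Sequence[EpitopeWeights],
    n_jx: int | None,
    n_ri: int | None,
    n_ri_epitopes: int | None,
    hla_count: int,
    has_rna: bool,
) -> dict[str, float]:
    """Assemble one patient's row of the wide burden table.

    RNA-derived metrics (E-weighted burdens, Jx/RI burdens, TVB) are NaN for
    patients without tumor RNA data; TVB otherwise conserves the exact sum of
    its components.
    """
    row: dict[str, float] = {
        "tmb_raw": float(tmb_raw),
        "tmb_per_mbp": tmb_per_mbp,
        "nb": weighted_burden(epitopes, ()),
        "hla_count": float(hla_count),
        "tmb_x_hla": tmb_times_hla(tmb_raw, hla_count),
    }
    for comps in ("A", "M", "T", "AM", "AT", "MT", "AMT"):
        row["nb_" + comps] = weighted_burden(epitopes, comps)
    for comps in ("E", "AE", "ME", "AME"):
        if has_rna:
            row["nb_" + comps] = weighted_burden(epitopes, comps)
        else:
            row["nb_" + comps] = float("nan")
    if has_rna and n_jx is not None and n_ri is not None:
        row["jx_burden"] = float(n_jx)
        row["ri_burden"] = float(n_ri)
        row["ri_epitope_burden"] = float(n_ri_epitopes or 0)
        row["tvb"] = float(tumor_variant_burden(tmb_raw, n_jx, n_ri))
    else:
        row["jx_burden"] = float("nan")
        row["ri_burden"] = float("nan")
        row["ri_epitope_burden"] = float("nan")
        row["tvb"] = float("nan")
    return row
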