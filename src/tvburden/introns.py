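"""Tumor-specific retained-intron (RI) detection and RI-derived peptides.

Transcript-level expression filters keep transcripts quantified at >= 1 TPM
in >= 25% of samples, with >= 5 unique counts in >= 25% of samples, and with
strictly between 0% and 100% of introns retained.  Within a kept transcript,
an intron is called retained when its read count is an outlier: strictly
greater than the median intron count plus 3 median absolute deviations
(unscaled MAD, no normal-consistency factor) AND at least the read count of
the transcript itself.  Retained introns also seen in normal (melanocyte)
samples are subtracted.  RI peptides are translated across the exon-intron
boundary in the upstream reading frame until the first stop codon, and every
8-24-mer containing at least one intron-encoded residue is enumerated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .epitopes import DEFAULT_LENGTHS

MAD_MULTIPLIER = 3.0
TPM_MIN = 1.0
COUNT_MIN = 5
SAMPLE_FRAC = 0.25


@dataclass
class TranscriptQuant:
    """Per-sample quantification of one transcript."""

    transcript_id: str
    tpm: Sequence[float]
    unique_counts: Sequence[float]
    intron_retention_frac: Sequence[float]

    def __post_init__(self) -> None:
        if min(self.tpm, default=0) < 0:
            raise ValueError("TPM must be >= 0")
        fr = np.asarray(self.intron_retention_frac, dtype=float)
        if fr.size and (fr.min() < 0 or fr.max() > 1):
            raise ValueError("intron retention fraction must lie in [0, 1]")


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a transcript, with per-sample read-count evidence."""

    transcript_id: str
    intron_index: int
    chrom: str = ""
    start: int = 0
    end: int = 0
    read_count: int = 0
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read count must be >= 0")

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript_id, self.intron_index)


def filter_transcripts(
    quants: Sequence[TranscriptQuant],
    tpm_min: float = TPM_MIN,
    count_min: float = COUNT_MIN,
    sample_frac: float = SAMPLE_FRAC,
) -> list[str]:
    """Transcript-level expression filters; returns retained transcript ids."""
    if len(quants) == 0:
        raise ValueError("need at least one transcript quantification")
    kept = []
    for q in quants:
        tpm = np.asarray(q.tpm, dtype=float)
        counts = np.asarray(q.unique_counts, dtype=float)
        frac = np.asarray(q.intron_retention_frac, dtype=float)
        if tpm.size == 0:
            raise ValueError(f"transcript {q.transcript_id} has no samples")
        if (tpm >= tpm_min).mean() < sample_frac:
            continue
        if (counts >= count_min).mean() < sample_frac:
            continue
        mean_frac = frac.mean()
        if not 0.0 < mean_frac < 1.0:
            continue
        kept.append(q.transcript_id)
    return kept


def mad(values: np.ndarray, scaled: bool = False) -> float:
    """Median absolute deviation; unscaled by default (no 1.4826 factor)."""
    values = np.asarray(values, dtype=float)
    m = float(np.median(np.abs(values - np.median(values))))
    return m * 1.4826 if scaled else m


def intron_outlier_filter(
    intron_counts: Sequence[float],
    transcript_count: float,
    mad_multiplier: float = MAD_MULTIPLIER,
    scaled_mad: bool = False,
) -> list[int]:
    """Indices of introns whose read count is an outlier for the transcript.

    Retained iff count > median + mad_multiplier * MAD (strict) and
    count >= transcript_count (inclusive), exactly as the two thresholds are
    phrased.  Order-invariant and scale-equivariant.
    """
    counts = np.asarray(intron_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one intron count")
    med = float(np.median(counts))
    threshold = med + mad_multiplier * mad(counts, scaled=scaled_mad)
    return [
        i
        for i, c in enumerate(counts)
        if c > threshold and c >= transcript_count
    ]


def subtract_normal_ris(
    tumor_ris: Iterable[IntronRecord] | set,
    normal_ris: Iterable[IntronRecord] | set,
) -> set:
    """Remove retained introns also found in normal samples (set difference).

    Accepts IntronRecords (compared on (transcript_id, intron_index)) or raw
    identity keys.
    """

    def keys(items):
        return {it.key if isinstance(it, IntronRecord) else it for it in items}

    tumor_by_key = {
        (it.key if isinstance(it, IntronRecord) else it): it for it in tumor_ris
    }
    normal_keys = keys(normal_ris)
    return {v for k, v in tumor_by_key.items() if k not in normal_keys}


def ri_peptides(
    upstream_coding_sequence: str,
    intron_sequence: str,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    frame_offset: int = 0,
) -> set[str]:
    """Peptides spanning a retained exon-intron boundary.

    Translation starts at ``frame_offset`` within the upstream coding
    sequence and runs across the boundary until the first stop codon (or the
    end of the intron).  Every window of each requested length containing at
    least one intron-encoded residue is returned.  Ambiguous nucleotides
    abort enumeration with a warning.
    """
    upstream = upstream_coding_sequence.upper()
    intron = intron_sequence.upper()
    seq = upstream + intron
    if set(seq) - set("ACGT"):
        warnings.warn(
            "ambiguous nucleotides in RI sequence; skipping peptide enumeration",
            stacklevel=2,
        )
        return set()
    coding = seq[frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    peptide = str(Seq(coding).translate(to_stop=True))
    if not peptide:
        return set()
    # first peptide index whose codon uses >= 1 intronic nucleotide
    boundary = len(upstream) - frame_offset  # nt offset of intron start in frame
    first_novel = boundary // 3
    if first_novel >= len(peptide):  # stop codon reached before the intron
        return set()
    out: set[str] = set()
    for L in lengths:
        for start in range(0, len(peptide) - L + 1):
            if start + L > first_novel:
                out.add(peptide[start : start + L])
    return out
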