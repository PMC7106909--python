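"""Multi-caller consensus variants, coverage-adjusted TMB, and instability statistics.

Somatic variant callers disagree substantially on the same tumor sample;
ensemble ("consensus") calling keeps variants supported by a minimum number
of callers.  Tumor mutational burden (TMB) is reported both as a raw
consensus count and normalized to the megabases of genome covered at a
minimum read depth.  Two instability statistics quantify how strongly the
choice of caller moves the metric for a patient: the median pairwise
TMB difference divided by the median TMB across callers, and the max-minus-min
range of per-caller counts as a fraction of their median.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from statistics import median
from typing import Iterable, Mapping, Sequence


class UndefinedMetricError(ValueError):
    """A ratio metric is requested where its denominator is zero."""


def classify_variant(ref: str, alt: str) -> str:
    """Classify a normalized ref/alt pair as SNV, insertion, or deletion."""
    if len(ref) == len(alt):
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Reduce a variant to its minimal (parsimonious) representation.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing ``pos``), always leaving at least one base on each allele.
    Idempotent; applied before any cross-caller set operation so that the
    identity key (chrom, pos, ref, alt) is comparable across callers.
    """
    if pos < 1:
        raise ValueError(f"pos must be >= 1, got {pos}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}) at {chrom}:{pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


@dataclass(frozen=True)
class VariantCall:
    """A single somatic variant in normalized representation.

    ``caller`` holds the emitting caller name, or a comma-joined list of
    supporting callers for consensus output.  Identity for set operations is
    (chrom, pos, ref, alt) only.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    caller: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or any(b not in "ACGTNacgtn" for b in allele):
                raise ValueError(
                    f"invalid {name} allele {allele!r} at {self.chrom}:{self.pos}"
                )

    @property
    def vclass(self) -> str:
        return classify_variant(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @classmethod
    def normalized(cls, chrom: str, pos: int, ref: str, alt: str, caller: str = "") -> "VariantCall":
        return cls(*normalize_variant(chrom, pos, ref, alt), caller=caller)


@dataclass
class TmbRecord:
    """Consensus variant count for one sample, with coverage normalization."""

    patient: str
    raw_count: int
    mbp_covered: float
    adjusted: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mbp_covered < 0:
            raise ValueError("mbp_covered must be >= 0")
        if self.mbp_covered == 0:
            raise UndefinedMetricError(
                f"TMB undefined for patient {self.patient!r}: 0 Mbp covered"
            )
        self.adjusted = self.raw_count / self.mbp_covered


def consensus_variants(
    per_caller_sets: Mapping[str, Iterable[VariantCall]],
    min_callers: int = 2,
) -> set[VariantCall]:
    """Variants whose identity key is reported by at least ``min_callers`` callers.

    The returned calls carry the sorted, comma-joined supporting caller names
    in their ``caller`` field.  ``min_callers=1`` yields the union;
    ``min_callers == number of callers`` the intersection.
    """
    if not per_caller_sets:
        raise ValueError("per_caller_sets is empty: need at least one caller")
    n = len(per_caller_sets)
    if not 1 <= min_callers <= n:
        raise ValueError(f"min_callers must be in [1, {n}], got {min_callers}")
    support: dict[tuple, list[str]] = {}
    exemplar: dict[tuple, VariantCall] = {}
    for caller, calls in per_caller_sets.items():
        seen: set[tuple] = set()
        for v in calls:
            if v.key in seen:  # duplicate within one caller: single vote
                continue
            seen.add(v.key)
            support.setdefault(v.key, []).append(caller)
            exemplar.setdefault(v.key, v)
    return {
        replace(exemplar[k], caller=",".join(sorted(callers)))
        for k, callers in support.items()
        if len(callers) >= min_callers
    }


def genome_coverage_mbp(
    depth_track: Iterable[tuple[str, int, int, int]],
    min_depth: int = 6,
) -> float:
    """Mbp of genome covered at read depth >= ``min_depth``.

    ``depth_track`` holds (chrom, start, end, depth) intervals in BED
    convention (0-based, half-open).  The inclusive depth threshold defaults
    to 6 reads.
    """
    total_bp = 0
    for chrom, start, end, depth in depth_track:
        if depth < 0:
            raise ValueError(f"negative depth {depth} at {chrom}:{start}-{end}")
        if end < start:
            raise ValueError(f"interval end < start at {chrom}:{start}-{end}")
        if depth >= min_depth:
            total_bp += end - start
    return total_bp / 1e6


def coverage_adjusted_tmb(
    consensus: Iterable[VariantCall] | int,
    mbp: float,
    patient: str = "",
) -> TmbRecord:
    """Coverage-adjusted TMB: consensus variant count per Mbp covered."""
    raw = consensus if isinstance(consensus, int) else len(set(consensus))
    return TmbRecord(patient=patient, raw_count=raw, mbp_covered=mbp)


def aggregate_multisample(per_sample_values: Sequence[float]) -> float:
    """Median burden across a patient's tumor samples (midpoint for even n)."""
    if len(per_sample_values) == 0:
        raise ValueError("need at least one sample value")
    return float(median(per_sample_values))


def caller_variability(per_caller_tmb: Mapping[str, float]) -> float:
    """Per-patient cross-caller instability of TMB.

    Median over all unordered caller pairs of |TMB_i - TMB_j|, divided by the
    median per-caller TMB.  Scale-invariant and invariant to caller labels.
    """
    if len(per_caller_tmb) < 2:
        raise ValueError("need TMB from at least two callers")
    values = list(per_caller_tmb.values())
    med = median(values)
    if med == 0:
        raise UndefinedMetricError("median TMB across callers is 0")
    pair_diffs = [abs(a - b) for a, b in combinations(values, 2)]
    return float(median(pair_diffs) / med)


def cohort_variability(per_patient_variability: Sequence[float]) -> float:
    """Cohort-level instability: median of per-patient variability values."""
    if len(per_patient_variability) == 0:
        raise ValueError("need at least one patient")
    return float(median(per_patient_variability))


def tmb_range_fraction(per_caller_counts: Mapping[str, float]) -> tuple[float, float]:
    """Max-minus-min spread of per-caller counts, and its fraction of the median."""
    if len(per_caller_counts) < 2:
        raise ValueError("need counts from at least two callers")
    values = list(per_caller_counts.values())
    med = median(values)
    if med == 0:
        raise UndefinedMetricError("median count across callers is 0")
    rng = max(values) - min(values)
    return rng, float(rng / med)
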