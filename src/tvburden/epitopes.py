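"""Candidate neoepitope enumeration and closest-normal-peptide search.

A protein-level variant can surface in many MHC-presentable peptides: every
window of 8-24 residues that covers the altered position is a candidate, so a
single interior substitution yields up to sum(8..24) = 272 windows.
Frameshifts and retained introns contribute a novel C-terminal tail, for
which every window containing at least one novel residue is enumerated,
borrowing up to L-1 flanking residues of wild-type context.

The amino-acid-mismatch weight compares each candidate against its closest
same-length peptide in the normal proteome, found by an exhaustive ungapped
BLOSUM62 scan (ties broken by self-normalized similarity, then
lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_LENGTHS = range(8, 25)


@dataclass
class NeoepitopeRecord:
    """One candidate peptide arising from a variant."""

    sequence: str
    source_variant: str = ""
    transcripts_of_origin: frozenset = frozenset()
    closest_normal: str | None = None
    mismatches: int | None = None
    window_multiplicity: int = 1

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set(AA_ALPHABET):
            bad = sorted(set(self.sequence) - set(AA_ALPHABET))
            raise ValueError(f"non-standard amino acids {bad} in {self.sequence!r}")
        if self.mismatches is not None and self.mismatches > len(self.sequence):
            raise ValueError("mismatches cannot exceed peptide length")


@dataclass
class EnumerationResult:
    """Distinct peptides plus the raw (pre-dedup) window count."""

    records: list[NeoepitopeRecord]
    n_windows: int

    @property
    def n_distinct(self) -> int:
        return len(self.records)

    @property
    def peptides(self) -> set[str]:
        return {r.sequence for r in self.records}


def _collapse(windows: list[str], variant_id: str) -> EnumerationResult:
    counts: dict[str, int] = {}
    for w in windows:
        counts[w] = counts.get(w, 0) + 1
    records = [
        NeoepitopeRecord(sequence=s, source_variant=variant_id, window_multiplicity=m)
        for s, m in counts.items()
    ]
    return EnumerationResult(records=records, n_windows=len(windows))


def enumerate_snv_peptides(
    protein: str,
    altered_position: int,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    variant_id: str = "",
) -> EnumerationResult:
    """All 8-24-mer windows of ``protein`` covering ``altered_position`` (1-based).

    ``protein`` is the post-substitution sequence.  Windows are truncated at
    the protein termini; identical peptide strings are collapsed with their
    window multiplicity recorded.
    """
    n = len(protein)
    if not 1 <= altered_position <= n:
        raise ValueError(
            f"altered_position {altered_position} outside protein of length {n}"
        )
    windows: list[str] = []
    for L in lengths:
        lo = max(1, altered_position - L + 1)
        hi = min(altered_position, n - L + 1)
        for start in range(lo, hi + 1):  # 1-based window start
            windows.append(protein[start - 1 : start - 1 + L])
    return _collapse(windows, variant_id)


def enumerate_indel_peptides(
    protein: str,
    first_altered: int,
    last_altered: int,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    variant_id: str = "",
) -> EnumerationResult:
    """Windows overlapping any altered residue of an in-frame indel.

    For an insertion, [first_altered, last_altered] spans the inserted
    residues in the mutant protein; for a deletion both bounds name the
    residue 5' of the removed junction, which every informative window must
    straddle (symmetric with the SNV logic).
    """
    n = len(protein)
    if not 1 <= first_altered <= last_altered <= n:
        raise ValueError("altered interval outside protein bounds")
    windows: list[str] = []
    for L in lengths:
        lo = max(1, first_altered - L + 1)
        hi = min(last_altered, n - L + 1)
        for start in range(lo, hi + 1):
            windows.append(protein[start - 1 : start - 1 + L])
    return _collapse(windows, variant_id)


def enumerate_frameshift_peptides(
    novel_tail: str,
    upstream_context: str,
    lengths: Iterable[int] = DEFAULT_LENGTHS,
    variant_id: str = "",
) -> EnumerationResult:
    """Windows containing >= 1 novel residue of a frameshift tail.

    ``novel_tail`` is the translated post-frameshift sequence up to (not
    including) the first stop; up to L-1 flanking residues are drawn from
    ``upstream_context``.  An empty tail yields an empty result.
    """
    if not novel_tail:
        return EnumerationResult(records=[], n_windows=0)
    full = upstream_context + novel_tail
    novel_start = len(upstream_context)  # 0-based index of first novel residue
    windows: list[str] = []
    for L in lengths:
        for start in range(0, len(full) - L + 1):
            if start + L > novel_start:  # window reaches into the novel region
                windows.append(full[start : start + L])
    return _collapse(windows, variant_id)


@lru_cache(maxsize=1)
def _blosum62() -> np.ndarray:
    """BLOSUM62 as a 20x20 array indexed by AA_ALPHABET positions."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = m[a, b]
    return out


_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.int64, count=len(seq))


def blosum62_score(a: str, b: str) -> float:
    """Ungapped BLOSUM62 alignment score of two equal-length peptides."""
    if len(a) != len(b):
        raise ValueError("peptides must have equal length")
    m = _blosum62()
    return float(m[_encode(a), _encode(b)].sum())


def weighted_similarity(neo: str, candidate: str) -> float:
    """BLOSUM62 score of neo vs candidate, normalized by the candidate self-score."""
    return blosum62_score(neo, candidate) / blosum62_score(candidate, candidate)


def closest_normal_peptide(
    neo: str,
    proteome: Mapping[str, str] | Iterable[str],
) -> tuple[str, int]:
    """Best same-length normal-proteome window for a candidate neoepitope.

    Exhaustive ungapped BLOSUM62 scan over every window of every proteome
    sequence; primary criterion maximal score, ties broken by weighted
    (self-normalized) similarity, remaining ties lexicographically.  Returns
    (closest peptide, Hamming mismatch count).
    """
    seqs = list(proteome.values()) if isinstance(proteome, Mapping) else list(proteome)
    seqs = [s for s in seqs if len(s) >= len(neo)]
    if not seqs:
        raise ValueError("proteome has no sequence at least as long as the peptide")
    m = _blosum62()
    L = len(neo)
    neo_codes = _encode(neo)
    best_score = -np.inf
    candidates: list[str] = []
    for seq in seqs:
        codes = _encode(seq)
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        scores = m[win, neo_codes].sum(axis=1)
        top = scores.max()
        if top < best_score:
            continue
        idx = np.nonzero(scores == top)[0]
        peps = {seq[i : i + L] for i in idx}
        if top > best_score:
            best_score = top
            candidates = sorted(peps)
        else:
            candidates = sorted(set(candidates) | peps)
    if len(candidates) > 1:
        sims = [weighted_similarity(neo, c) for c in candidates]
        top_sim = max(sims)
        candidates = [c for c, s in zip(candidates, sims) if s == top_sim]
    best = min(candidates)  # lexicographic final tie-break
    return best, mismatch_count(neo, best)


def mismatch_count(a: str, b: str) -> int:
    """Hamming distance between two equal-length peptides."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))
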