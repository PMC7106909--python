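"""Retained-intron filters (expression, MAD outlier) and RI peptide enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvburden.introns import (
    IntronRecord,
    TranscriptQuant,
    filter_transcripts,
    intron_outlier_filter,
    mad,
    ri_peptides,
    subtract_normal_ris,
)


def quant(tid="tx", tpm=(2, 2, 2, 2), counts=(10, 10, 10, 10), frac=(0.3, 0.3, 0.3, 0.3)):
    return TranscriptQuant(tid, list(tpm), list(counts), list(frac))


class TestTranscriptFilters:
    def test_tpm_fraction_by_hand(self):
        q = quant(tpm=(1, 1, 0.5, 0.2))  # 2/4 = 50% >= 25%
        assert filter_transcripts([q]) == ["tx"]

    def test_tpm_fraction_below_quarter_removed(self):
        q = quant(tpm=(1, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
                  counts=(10,) * 8, frac=(0.3,) * 8)  # 1/8 < 25%
        assert filter_transcripts([q]) == []

    def test_retention_boundaries_are_strict(self):
        assert filter_transcripts([quant(frac=(0, 0, 0, 0))]) == []
        assert filter_transcripts([quant(frac=(1, 1, 1, 1))]) == []
        assert filter_transcripts([quant(frac=(0.01,) * 4)]) == ["tx"]

    def test_unique_count_criterion(self):
        assert filter_transcripts([quant(counts=(4, 4, 4, 4))]) == []
        assert filter_transcripts([quant(counts=(5, 4, 4, 4))]) == ["tx"]

    def test_empty_quants_rejected(self):
        with pytest.raises(ValueError):
            filter_transcripts([])


class TestMadOutlierFilter:
    def test_hand_fixture_keeps_only_planted_outlier(self):
        # median 10, MAD 0 -> threshold 10; only 100 passes, and 100 >= 20
        assert intron_outlier_filter([10, 10, 10, 10, 100], 20) == [4]

    def test_all_equal_counts_yield_nothing(self):
        assert intron_outlier_filter([7, 7, 7], 1) == []

    def test_two_intron_hand_computation(self):
        # median 27.5, MAD 22.5 -> threshold 95; 50 fails
        assert intron_outlier_filter([5, 50], 60) == []

    def test_transcript_count_criterion_is_inclusive(self):
        counts = [10, 10, 10, 10, 100]
        assert intron_outlier_filter(counts, 100) == [4]
        assert intron_outlier_filter(counts, 101) == []

    def test_order_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.poisson(20, size=8).astype(float)
            counts[3] = counts.max() + 200
            tc = float(rng.integers(1, 100))
            base = {tuple(sorted((counts[i], i) for i in intron_outlier_filter(counts, tc)))}
            perm = rng.permutation(len(counts))
            permuted = counts[perm]
            got = intron_outlier_filter(permuted, tc)
            assert {permuted[i] for i in got} == {counts[i] for i in intron_outlier_filter(counts, tc)}
            c = float(rng.uniform(0.5, 10))
            assert intron_outlier_filter(counts * c, tc * c) == intron_outlier_filter(counts, tc)

    def test_planted_outlier_recovery(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            counts = rng.poisson(15, size=10).astype(float)
            m = float(np.median(counts))
            d = mad(counts)
            if d == 0:
                continue
            tc = float(rng.integers(5, 40))
            counts[0] = max(m + 10 * d, tc) + 1
            kept = intron_outlier_filter(counts, tc)
            assert 0 in kept

    def test_unscaled_mad_by_default(self):
        vals = np.array([1.0, 2.0, 4.0, 9.0])
        assert mad(vals) == 1.5
        assert mad(vals, scaled=True) == pytest.approx(1.5 * 1.4826)


class TestNormalSubtraction:
    def test_set_difference_semantics(self):
        t = {IntronRecord("tx1", 0), IntronRecord("tx1", 1), IntronRecord("tx2", 0)}
        n = {("tx1", 1)}
        out = subtract_normal_ris(t, n)
        assert {r.key for r in out} == {("tx1", 0), ("tx2", 0)}
        assert subtract_normal_ris(t, {r.key for r in t}) == set()
        assert {r.key for r in subtract_normal_ris(t, set())} == {r.key for r in t}


class TestRiPeptides:
    def test_immediate_in_frame_stop_yields_nothing(self):
        upstream = "ATGGCTGCT"  # M A A
        intron = "TAAACGT"  # stop immediately
        assert ri_peptides(upstream, intron) == set()

    def test_ten_novel_residues_window_count(self):
        rng = np.random.default_rng(2)
        codons = [c for c in ("GCT", "TGT", "GAT", "GAA", "TTT", "GGT", "CAT", "ATT",
                              "AAA", "TTG", "ATG", "AAT", "CCT", "CAA", "CGT")]
        upstream = "".join(rng.choice(codons, size=30))  # 30 codons, no stops
        intron = "".join(rng.choice(codons, size=10)) + "TAA"  # 10 novel residues
        out = ri_peptides(upstream, intron, lengths=[8])
        # windows of length 8 over the 40-residue peptide that reach past
        # residue 30: 7 straddling + 3 fully intronic = 10
        assert len(out) == 10

    def test_hand_translation_of_30nt_fixture_and_frame_shift(self):
        upstream = "ATGGCTTGTGATGAATTTGGTCATATTAAA"  # MACDEFGHIK
        intron = "TTGATGAATCCTTAA"  # LMNP then stop
        out = ri_peptides(upstream, intron, lengths=[8])
        assert "GHIKLMNP" in out
        assert "CDEFGHIK" not in out  # no intronic residue
        shifted = ri_peptides(upstream, intron, lengths=[8], frame_offset=1)
        assert shifted != out

    def test_ambiguous_nucleotides_abort_with_warning(self):
        with pytest.warns(UserWarning):
            assert ri_peptides("ATGNCT", "GCTTAA") == set()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_every_window_overlaps_the_novel_region(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        upstream = "".join(rng.choice(bases, size=3 * int(rng.integers(8, 15))))
        intron = "".join(rng.choice(bases, size=int(rng.integers(24, 60))))
        out = ri_peptides(upstream, intron, lengths=range(8, 12))
        from Bio.Seq import Seq

        coding = (upstream + intron)[: len(upstream + intron) - len(upstream + intron) % 3]
        peptide = str(Seq(coding).translate(to_stop=True))
        first_novel = len(upstream) // 3
        oracle = {
            peptide[s : s + L]
            for L in range(8, 12)
            for s in range(len(peptide) - L + 1)
            if s + L > first_novel
        }
        assert out == oracle


def test_planted_intron_recovery_on_synthetic_cohort(bundle):
    """The pipeline filters recover exactly the planted retained introns."""
    from tvburden.introns import filter_transcripts, intron_outlier_filter

    quants = [
        TranscriptQuant(tid, sub["tpm"].tolist(), sub["unique_counts"].tolist(),
                        sub["retention_frac"].tolist())
        for tid, sub in bundle.transcript_quant.groupby("transcript_id")
    ]
    kept = set(filter_transcripts(quants))
    counts = bundle.intron_counts
    assert bundle.truth.true_introns, "cohort must include RNA patients"
    for pid, psub in counts.groupby("patient_id"):
        found = set()
        for tid, tsub in psub.groupby("transcript_id"):
            if tid not in kept:
                continue
            tsub = tsub.sort_values("intron_index")
            for i in intron_outlier_filter(
                tsub["read_count"].tolist(), float(tsub["transcript_count"].iloc[0])
            ):
                found.add((tid, int(tsub["intron_index"].iloc[i])))
        found -= bundle.normal_ris
        assert found == bundle.truth.true_introns[pid]
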