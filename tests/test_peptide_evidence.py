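"""Peptide matching, validation counts, frameshift calls, decoy FDR."""

from __future__ import annotations

import collections

import pytest

from txomeval._dna import six_frame_translate
from txomeval.assembly_qc import Transcript
from txomeval.orf_toolkit import extract_orfs
from txomeval.peptide_evidence import (
    InvalidPeptideError,
    PeptideHit,
    build_decoy_db,
    collapse_il,
    decoy_fdr,
    detect_frameshifts,
    match_peptides,
    summarize_validation,
)


def _orfs(seq: str, tid: str = "a"):
    return extract_orfs(Transcript(tid, seq))


class TestMatchPeptides:
    def test_hand_translated_hit(self):
        hits = match_peptides(["MK"], _orfs("ATGAAATAA"))
        h = next(h for h in hits if h.frame == 1)
        assert (h.aa_start, h.aa_end) == (0, 2)
        assert (h.nt_start, h.nt_end) == (0, 6)

    def test_il_equivalence(self):
        # transcript encodes LK; peptide IK must match under I/L collapse
        seq = "TTGAAA"  # L K in frame +1
        hits = match_peptides(["IK"], _orfs(seq))
        assert any(h.frame == 1 for h in hits)
        assert match_peptides(["IK"], _orfs(seq), il_equivalent=False) == []

    def test_absent_peptide_no_hit(self):
        assert match_peptides(["WWWWW"], _orfs("ATGAAATAA")) == []

    def test_x_never_matches(self):
        seq = "ATGNNNAAA"  # frame +1 = MXK
        assert match_peptides(["MXK"], _orfs(seq)) == []

    def test_invalid_residues_rejected(self):
        with pytest.raises(InvalidPeptideError):
            match_peptides(["MZ"], _orfs("ATGAAATAA"))

    def test_coordinate_round_trip(self, small_dataset):
        """Re-translating nt [start, end) in the hit's frame reproduces the
        peptide under I/L equivalence."""
        by_id = {t.id: t for t in small_dataset["transcripts"]}
        for h in small_dataset["hits"][:300]:
            t = by_id[h.transcript_id]
            trans = six_frame_translate(t.sequence)[h.frame]
            sl = trans[h.aa_start : h.aa_end]
            assert collapse_il(sl) == collapse_il(h.peptide)
            assert h.nt_end - h.nt_start == 3 * len(h.peptide)

    def test_full_recall_on_synthetic_truth(self, small_dataset):
        """With sampling_rate=1 every surviving tryptic peptide is recovered
        on its source transcript."""
        obs = small_dataset["observed"]
        hitset = {
            (h.peptide, h.transcript_id) for h in small_dataset["hits"]
        }
        for row in obs.itertuples():
            assert (row.peptide, row.transcript_id) in hitset


class TestValidationSummary:
    def _hit(self, pep, tid="t1", frame=1, start=0):
        return PeptideHit(pep, tid, frame, start, start + len(pep),
                          3 * start, 3 * (start + len(pep)))

    def test_two_distinct_peptides(self):
        s = summarize_validation([self._hit("AAAK"), self._hit("CCCR", start=10)])
        assert (s.n_transcripts_ge1, s.n_transcripts_ge2) == (1, 1)

    def test_same_peptide_twice_counts_once(self):
        s = summarize_validation([self._hit("AAAK"), self._hit("AAAK", start=20)])
        assert (s.n_transcripts_ge1, s.n_transcripts_ge2) == (1, 0)

    def test_il_variants_count_once(self):
        s = summarize_validation([self._hit("AIAK"), self._hit("ALAK", start=20)])
        assert s.n_peptides == 1

    def test_truth_table_oracle_on_synthetic(self, small_dataset):
        """Every coding transcript with >=2 distinct sampled peptides appears
        in the >=2 tier."""
        obs = small_dataset["observed"]
        per_tid = collections.defaultdict(set)
        for row in obs.itertuples():
            per_tid[row.transcript_id].add(collapse_il(row.peptide))
        expect_ge2 = {t for t, peps in per_tid.items() if len(peps) >= 2}
        summary = summarize_validation(small_dataset["hits"])
        got_ge2 = {t for t, c in summary.per_transcript.items() if c >= 2}
        assert expect_ge2 <= got_ge2  # cross-matches can only add transcripts
        assert summary.n_transcripts_ge2 >= len(expect_ge2)


class TestDetectFrameshifts:
    def _hit(self, frame, nt_start, nt_end, pep="AAAAAAA", tid="t"):
        return PeptideHit(pep, tid, frame, 0, len(pep), nt_start, nt_end)

    def test_constructed_single_shift(self):
        calls, mixed = detect_frameshifts(
            [self._hit(1, 0, 30), self._hit(2, 33, 63)]
        )
        assert mixed == []
        assert len(calls) == 1
        assert calls[0].n_shifts == 1
        assert calls[0].frame_path == (1, 2)

    def test_single_frame_no_call(self):
        calls, _ = detect_frameshifts(
            [self._hit(1, 0, 30), self._hit(1, 60, 90)]
        )
        assert calls == []

    def test_mixed_strand_reported_not_called(self):
        calls, mixed = detect_frameshifts(
            [self._hit(1, 0, 30), self._hit(-2, 60, 90)]
        )
        assert calls == []
        assert mixed == ["t"]

    def test_overlapping_conflict_not_counted(self):
        calls, _ = detect_frameshifts(
            [self._hit(1, 0, 30), self._hit(2, 15, 45)]
        )
        assert calls == []

    def test_synthetic_truth_recovery(self, small_dataset):
        """Called shifts equal implanted indels whenever every inter-indel
        segment carries at least one observed peptide, and never exceed the
        implanted count."""
        table = small_dataset["peptide_table"]
        truth = {
            t.transcript_id: len(t.frameshift_positions)
            for t in small_dataset["truths"]
            if t.frameshift_positions
        }
        seg_obs = collections.defaultdict(set)
        for row in table[table["observed"]].itertuples():
            seg_obs[row.transcript_id].add(row.segment)
        calls, mixed = detect_frameshifts(small_dataset["hits"])
        callmap = {c.transcript_id: c.n_shifts for c in calls}
        assert mixed == []
        n_checked = 0
        for tid, k in truth.items():
            if len(seg_obs[tid]) == k + 1:  # full segment coverage
                assert callmap.get(tid, 0) == k
                n_checked += 1
            else:
                assert callmap.get(tid, 0) <= k  # no false inflation
        assert n_checked > 0
        for tid in callmap:
            assert tid in truth  # no shift called on clean transcripts


class TestDecoyFdr:
    def _hits(self, n, decoy=False):
        return [
            PeptideHit(f"PEP{i}K", "t", 1, 0, 5, 0, 15, decoy) for i in range(n)
        ]

    @pytest.mark.parametrize(
        "n_target,n_decoy,fdr,passed",
        [
            (99, 0, 0.0, True),
            (100, 1, 0.01, False),  # "below 1%" is strict
            (200, 1, 0.005, True),
        ],
    )
    def test_formula_and_boundary(self, n_target, n_decoy, fdr, passed):
        res = decoy_fdr(self._hits(n_target), self._hits(n_decoy, True))
        assert res.fdr == pytest.approx(fdr)
        assert res.passed is passed

    def test_no_matches_at_all(self):
        res = decoy_fdr([], [])
        assert res.fdr == 0.0 and res.passed

    def test_decoys_without_targets_warns(self):
        res = decoy_fdr([], self._hits(3, True))
        assert res.fdr == 1.0
        assert res.warning is not None

    def test_decoy_db_is_per_entry_reversal(self, small_dataset):
        db = small_dataset["search_db"][:20]
        decoys = build_decoy_db(db)
        for orf, dec in zip(db, decoys):
            assert dec.aa_sequence == orf.aa_sequence[::-1]
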