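"""Ground-truth generator: construction rules, digestion, hit tables."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import tryptic_oracle
from txomeval._dna import six_frame_translate
from txomeval.synthetic_data import (
    CONSERVED,
    NO_HIT,
    URODELE_ONLY,
    SyntheticConfig,
    SyntheticConfigError,
    cleave_tryptic,
    digest_and_sample_peptides,
    generate_hit_tables,
    generate_ortholog_tables,
    generate_transcriptome,
    observed_peptides,
)


class TestConfigValidation:
    def test_bad_composition_rejected(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(base_composition=(0.5, 0.5, 0.1, 0.1))

    def test_negative_counts_rejected(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(n_coding=-1)

    def test_orf_too_short_for_indels_rejected(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(
                n_frameshifted=1, orf_length_range=(30, 40),
                indels_range=(2, 2), indel_min_spacing=90,
            )

    def test_empty_ranges_rejected(self):
        with pytest.raises(SyntheticConfigError):
            SyntheticConfig(orf_length_range=(100, 60))


class TestGenerateTranscriptome:
    def test_degenerate_single_noncoding(self):
        cfg = SyntheticConfig(n_coding=0, n_noncoding=1, n_frameshifted=0, seed=1)
        transcripts, truths = generate_transcriptome(cfg)
        assert len(transcripts) == 1
        assert truths[0].is_coding is False

    def test_construction_arithmetic(self):
        cfg = SyntheticConfig(
            n_coding=1, n_noncoding=0, n_frameshifted=0,
            orf_length_range=(100, 100), utr_length_range=(50, 50), seed=3,
        )
        (t,), (tr,) = generate_transcriptome(cfg)
        assert t.length == 50 + 3 * (100 + 1) + 50  # UTR + ORF aa + stop + UTR
        assert tr.orf_nt_interval == (50, 50 + 303)
        assert len(tr.source_protein) == 100
        assert tr.source_protein.startswith("M")

    def test_determinism_byte_identical(self):
        cfg = SyntheticConfig(n_coding=5, n_noncoding=3, n_frameshifted=2, seed=9)
        t1, r1 = generate_transcriptome(cfg)
        t2, r2 = generate_transcriptome(cfg)
        assert [x.sequence for x in t1] == [x.sequence for x in t2]
        assert r1 == r2

    def test_class_counts_exact(self, small_dataset):
        truths = small_dataset["truths"]
        cfg = small_dataset["config"]
        n_fs = sum(1 for t in truths if t.frameshift_positions)
        n_cod = sum(1 for t in truths if t.is_coding and not t.frameshift_positions)
        n_non = sum(1 for t in truths if not t.is_coding)
        assert (n_cod, n_non, n_fs) == (
            cfg.n_coding, cfg.n_noncoding, cfg.n_frameshifted,
        )
        from collections import Counter

        spec_counts = Counter(t.specificity_class for t in truths)
        n = len(truths)
        for cls, frac in zip((CONSERVED, URODELE_ONLY, NO_HIT), cfg.specificity_mix):
            assert abs(spec_counts[cls] - frac * n) < 1

    def test_coding_transcript_encodes_its_protein(self, small_dataset):
        by_id = {t.id: t for t in small_dataset["transcripts"]}
        for tr in small_dataset["truths"]:
            if tr.is_coding and not tr.frameshift_positions:
                t = by_id[tr.transcript_id]
                s, e = tr.orf_nt_interval
                assert six_frame_translate(t.sequence[s:e])[1] == tr.source_protein + "*"

    def test_frameshift_truth_recorded_inside_orf(self, small_dataset):
        for tr in small_dataset["truths"]:
            if tr.frameshift_positions:
                s, e = tr.orf_nt_interval
                assert all(s < p < e for p in tr.frameshift_positions)
                assert set(tr.frameshift_ops) <= {1, -1}
                assert len(tr.frameshift_codons) == len(tr.frameshift_positions)


class TestTrypticDigestion:
    @pytest.mark.parametrize(
        "protein,expected",
        [
            ("MKRAAAK", ["MK", "R", "AAAK"]),
            ("MKPRA", ["MKPR", "A"]),
            ("", []),
            ("KKK", ["K", "K", "K"]),
            ("RPRPK", ["RPRPK"]),
        ],
    )
    def test_hand_cleavages(self, protein, expected):
        assert [p for _, _, p in cleave_tryptic(protein)] == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=80))
    def test_matches_regex_oracle_and_rejoins(self, protein):
        frags = [p for _, _, p in cleave_tryptic(protein)]
        assert frags == tryptic_oracle(protein)
        assert "".join(frags) == protein

    def test_sampling_rate_zero_gives_empty_observed(self, small_dataset):
        cfg = SyntheticConfig(
            n_coding=5, n_noncoding=0, n_frameshifted=0,
            peptide_sampling_rate=0.0, seed=2,
        )
        _, truths = generate_transcriptome(cfg)
        table = digest_and_sample_peptides(truths, cfg)
        assert len(observed_peptides(table)) == 0
        assert len(table) > 0  # the truth side still lists the digest

    def test_every_observed_peptide_is_conserved(self, small_dataset):
        """Observed peptides are exact substrings of a six-frame translation
        of their source transcript (frameshifted ones included)."""
        by_id = {t.id: t for t in small_dataset["transcripts"]}
        obs = observed_peptides(small_dataset["peptide_table"])
        for row in obs.itertuples():
            trans = six_frame_translate(by_id[row.transcript_id].sequence)
            assert any(row.peptide in p for p in trans.values())


class TestHitTables:
    def test_all_no_hit_truth_gives_empty_tables(self):
        cfg = SyntheticConfig(
            n_coding=5, n_noncoding=2, n_frameshifted=0,
            specificity_mix=(0.0, 0.0, 1.0), seed=4,
        )
        _, truths = generate_transcriptome(cfg)
        tables, go_map = generate_hit_tables(truths, cfg)
        assert all(tab.empty for tab in tables.values())
        assert go_map == {}

    def test_conserved_get_strong_protein_hits(self, small_dataset):
        tables, _ = generate_hit_tables(
            small_dataset["truths"], small_dataset["config"]
        )
        conserved = {
            t.transcript_id
            for t in small_dataset["truths"]
            if t.specificity_class == CONSERVED
        }
        nr = tables["nr"]
        assert set(nr["qseqid"]) == conserved
        assert (nr["evalue"] <= 1e-20).all()
        urodele_ids = set(tables["est_urodele"]["qseqid"])
        assert urodele_ids == {
            t.transcript_id
            for t in small_dataset["truths"]
            if t.specificity_class == URODELE_ONLY
        }
        # urodele-only transcripts never leak into other tables
        for db, tab in tables.items():
            if db != "est_urodele" and not tab.empty:
                assert not (set(tab["qseqid"]) & urodele_ids)

    def test_keyword_fraction_one_flags_everything(self):
        from txomeval.annotation_filter import flag_low_quality

        cfg = SyntheticConfig(
            n_coding=10, n_noncoding=0, n_frameshifted=0,
            specificity_mix=(1.0, 0.0, 0.0),
            low_quality_keyword_fraction=1.0, seed=5,
        )
        _, truths = generate_transcriptome(cfg)
        tables, _ = generate_hit_tables(truths, cfg)
        for tab in tables.values():
            if not tab.empty:
                assert flag_low_quality(tab["description"]).all()


class TestOrthologTables:
    def test_planted_pairs_have_known_fractions(self, small_dataset):
        q, s, lengths, truth = generate_ortholog_tables(
            small_dataset["truths"], small_dataset["config"]
        )
        assert len(truth) == sum(
            1 for t in small_dataset["truths"]
            if t.is_coding and t.specificity_class == CONSERVED
        )
        merged = truth.merge(lengths, on="subject_id")
        assert (merged["subject_length"] == merged["length"]).all()
        assert np.allclose(
            truth["align_fraction"],
            truth["align_length"] / truth["subject_length"],
        )
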