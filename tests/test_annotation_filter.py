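"""E-value thresholding, quality flags, best-hit selection, rate curves."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from conftest import random_dna
from txomeval.annotation_filter import (
    annotation_rate_curve,
    filter_hits,
    flag_low_quality,
    load_blast_table,
    select_best_annotation,
)
from txomeval.assembly_qc import Transcript


def _hits(rows):
    return pd.DataFrame(
        rows,
        columns=["query_id", "database", "taxon", "subject_id", "description",
                 "evalue", "bitscore", "align_length"],
    )


class TestFilterHits:
    def test_cutoff_is_inclusive_boundary(self):
        hits = _hits([
            ("q1", "nr", "m", "s1", "fine protein", 1e-16, 80.0, 100),
            ("q2", "nr", "m", "s2", "fine protein", 1e-14, 80.0, 100),
        ])
        kept = filter_hits(hits, 1e-15)
        assert list(kept["query_id"]) == ["q1"]

    def test_keyword_flagging(self):
        hits = _hits([
            ("q1", "nr", "m", "s1", "hypothetical mRNA clone 42", 1e-30, 80.0, 100),
            ("q2", "nr", "m", "s2", "ATP synthase", 1e-30, 80.0, 100),
        ])
        kept = filter_hits(hits)
        assert bool(kept.loc[kept["query_id"] == "q1", "low_quality"].item()) is True
        assert bool(kept.loc[kept["query_id"] == "q2", "low_quality"].item()) is False

    def test_flag_is_case_insensitive_substring(self):
        s = pd.Series(["GENOMIC region", "some cdna", "clean description"])
        assert flag_low_quality(s).tolist() == [True, True, False]

    def test_filtering_monotone_in_cutoff(self, rng):
        rows = [
            (f"q{i}", "nr", "m", f"s{i}", "desc",
             float(10.0 ** rng.uniform(-60, -5)), 50.0, 100)
            for i in range(100)
        ]
        hits = _hits(rows)
        strict = set(filter_hits(hits, 1e-20)["subject_id"])
        loose = set(filter_hits(hits, 1e-10)["subject_id"])
        assert strict <= loose

    def test_malformed_rows_counted_not_fatal(self):
        text = "q1\ts1\t90\t100\t5\t0\t1\t100\t1\t100\t1e-30\t200\tdesc\n" \
               "broken line\n" \
               "q2\ts2\t90\t100\t5\t0\t1\t100\t1\t100\tnot_a_number\t200\tdesc\n"
        df, n_bad = load_blast_table(io.StringIO(text), "nr", "metazoa")
        assert len(df) == 1 and n_bad == 2


class TestSelectBestAnnotation:
    def test_go_bearing_hit_preferred_over_better_evalue(self):
        hits = filter_hits(_hits([
            ("q1", "nr", "mouse", "noGO", "d", 1e-30, 90.0, 100),
            ("q1", "nr", "mouse", "hasGO", "d", 1e-25, 80.0, 100),
        ]))
        _, assignments = select_best_annotation(hits, {"hasGO": ["GO:0001"]})
        assert list(assignments["subject_id"]) == ["hasGO"]

    def test_no_go_hit_leaves_query_unassigned(self):
        hits = filter_hits(_hits([
            ("q1", "nr", "mouse", "s1", "d", 1e-30, 90.0, 100),
        ]))
        topk, assignments = select_best_annotation(hits, {})
        assert len(topk) == 1
        assert assignments.empty

    def test_functional_cutoff_stricter_than_retention(self):
        hits = filter_hits(_hits([
            ("q1", "nr", "mouse", "weakGO", "d", 1e-18, 90.0, 100),
        ]))
        topk, assignments = select_best_annotation(hits, {"weakGO": ["GO:1"]})
        assert len(topk) == 1  # retained at the working cutoff
        assert assignments.empty  # but 1e-18 fails the 1e-20 functional bar

    def test_top_k_by_ascending_evalue(self):
        rows = [
            ("q1", "nr", "mouse", f"s{i}", "d", ev, 50.0, 100)
            for i, ev in enumerate([1e-40, 1e-20, 1e-60, 1e-30, 1e-50])
        ]
        topk, _ = select_best_annotation(filter_hits(_hits(rows)), {}, k=3)
        assert list(topk["subject_id"]) == ["s2", "s4", "s0"]
        assert topk["evalue"].is_monotonic_increasing


class TestRateCurve:
    def _make_step_data(self, rng, step_at=300):
        transcripts, rows = [], []
        for i in range(400):
            L = int(rng.integers(100, 500))
            tid = f"q{i}"
            transcripts.append(Transcript(tid, random_dna(rng, L)))
            if L >= step_at:  # annotation probability steps 0 -> 1 here
                rows.append((tid, "nr", "m", f"s{i}", "d", 1e-30, 50.0, 100))
        return transcripts, _hits(rows)

    def test_step_function_l50(self, rng):
        transcripts, hits = self._make_step_data(rng)
        (curve,) = annotation_rate_curve(transcripts, hits, [1e-15])
        assert curve.l50 == 300

    def test_l50_monotone_in_cutoff(self, rng):
        transcripts = [
            Transcript(f"q{i}", random_dna(rng, int(rng.integers(100, 800))))
            for i in range(300)
        ]
        rows = []
        for i, t in enumerate(transcripts):
            # longer transcripts get stronger e-values on average
            ev = 10.0 ** (-t.length / 40 + rng.uniform(0, 6))
            rows.append((t.id, "nr", "m", f"s{i}", "d", float(ev), 50.0, 100))
        curves = annotation_rate_curve(
            transcripts, _hits(rows), [1e-5, 1e-10, 1e-15]
        )
        l50s = [c.l50 for c in curves]
        assert all(a is not None for a in l50s)
        assert l50s == sorted(l50s)

    def test_per_bin_rate_matches_recount(self, rng):
        transcripts, hits = self._make_step_data(rng, step_at=250)
        (curve,) = annotation_rate_curve(transcripts, hits, [1e-15])
        annotated = set(hits["query_id"])
        for _, row in curve.bins.iterrows():
            b = row["bin_start"]
            in_bin = [t for t in transcripts if b <= t.length < b + 50]
            assert row["n_total"] == len(in_bin)
            assert row["n_annotated"] == sum(
                1 for t in in_bin if t.id in annotated
            )

    def test_all_annotated_l50_is_first_bin(self, rng):
        transcripts = [
            Transcript(f"q{i}", random_dna(rng, 100 + 50 * i)) for i in range(5)
        ]
        rows = [
            (t.id, "nr", "m", "s", "d", 1e-30, 50.0, 100) for t in transcripts
        ]
        (curve,) = annotation_rate_curve(transcripts, _hits(rows), [1e-15])
        assert curve.l50 == 100

    def test_empty_cutoffs_rejected(self, rng):
        with pytest.raises(ValueError):
            annotation_rate_curve(
                [Transcript("a", random_dna(rng, 100))], _hits([]), []
            )

    def test_length_filter_rate_exact_on_synthetic_truth(self, small_dataset):
        """With hits generated exactly for the conserved+urodele classes, the
        >=400 bp annotation rate equals their share among >=400 bp
        transcripts."""
        from txomeval.annotation_filter import hits_from_tables
        from txomeval.synthetic_data import generate_hit_tables

        tables, _ = generate_hit_tables(
            small_dataset["truths"], small_dataset["config"]
        )
        hits = hits_from_tables(tables, {db: db for db in tables})
        transcripts = small_dataset["transcripts"]
        (curve,) = annotation_rate_curve(transcripts, hits, [1e-15])
        with_hits = {
            t.transcript_id
            for t in small_dataset["truths"]
            if t.specificity_class in ("conserved", "urodele_only")
        }
        ge400 = [t for t in transcripts if t.length >= 400]
        expected = sum(1 for t in ge400 if t.id in with_hits) / len(ge400)
        assert curve.rate_ge_length == pytest.approx(expected)
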