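"""End-to-end orchestration: QC -> ORFs -> peptide validation -> annotation
-> orthologues -> specificity, with a reproducible report bundle.

Every stage writes its outputs under the run directory together with a
manifest recording every parameter that affected any output (defaults
included — nothing is hidden).  Reruns with the same configuration are
byte-identical; wall-clock timings go to the run log only, which is excluded
from any determinism comparison.
"""

from __future__ import annotations

import configparser
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import annotation_filter, assembly_qc, io, orf_toolkit, ortholog_fullness
from . import peptide_evidence, specificity_novelty, synthetic_data
from .synthetic_data import DATABASES, URODELE_DBS, SyntheticConfig


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    evalue_cutoff: float = 1e-15
    functional_cutoff: float = 1e-20
    length_filter: int = 400
    min_identity: float = 0.90
    max_overhang: int = 30
    min_orf_aa_exclusive: int = 25  # ORFs must be longer than this
    full_length_fraction: float = 0.75
    fdr_threshold: float = 0.01
    bin_width: int = 50
    curve_cutoffs: tuple[float, ...] = (1e-10, 1e-15, 1e-20)
    null_replicates: int = 3
    null_composition: str = "matched"
    urodele_dbs: tuple[str, ...] = tuple(sorted(URODELE_DBS))
    cluster_min_identity: float = 0.35
    cluster_min_coverage: float = 0.6
    patterns: tuple[str, ...] = ()
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def manifest(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "synthetic"}
        d["curve_cutoffs"] = list(self.curve_cutoffs)
        d["urodele_dbs"] = list(self.urodele_dbs)
        d["patterns"] = list(self.patterns)
        d["synthetic"] = asdict(self.synthetic)
        for key in ("orf_length_range", "utr_length_range", "base_composition",
                    "specificity_mix", "indels_range"):
            d["synthetic"][key] = list(d["synthetic"][key])
        return d


def load_config(path) -> PipelineConfig:
    """Read a key = value config file with one section per stage."""
    cp = configparser.ConfigParser()
    cp.read(str(path))

    def get(section, key, cast, default):
        if cp.has_option(section, key):
            raw = cp.get(section, key)
            if cast is tuple:
                return tuple(float(x) for x in raw.split(","))
            return cast(raw)
        return default

    dflt = PipelineConfig()
    sflt = SyntheticConfig()

    def get_pair(section, key, cast, default):
        if cp.has_option(section, key):
            a, b = cp.get(section, key).split(",")
            return (cast(a), cast(b))
        return default

    synth = SyntheticConfig(
        n_coding=get("synthetic", "n_coding", int, sflt.n_coding),
        n_noncoding=get("synthetic", "n_noncoding", int, sflt.n_noncoding),
        n_frameshifted=get("synthetic", "n_frameshifted", int, sflt.n_frameshifted),
        orf_length_range=get_pair("synthetic", "orf_length_range", int, sflt.orf_length_range),
        utr_length_range=get_pair("synthetic", "utr_length_range", int, sflt.utr_length_range),
        peptide_min_len=get("synthetic", "peptide_min_len", int, sflt.peptide_min_len),
        peptide_max_len=get("synthetic", "peptide_max_len", int, sflt.peptide_max_len),
        peptide_sampling_rate=get("synthetic", "peptide_sampling_rate", float, sflt.peptide_sampling_rate),
        seed=get("synthetic", "seed", int, sflt.seed),
    )
    return PipelineConfig(
        evalue_cutoff=get("annotation", "evalue_cutoff", float, dflt.evalue_cutoff),
        functional_cutoff=get("annotation", "functional_cutoff", float, dflt.functional_cutoff),
        length_filter=get("annotation", "length_filter", int, dflt.length_filter),
        min_identity=get("assembly", "min_identity", float, dflt.min_identity),
        max_overhang=get("assembly", "max_overhang", int, dflt.max_overhang),
        min_orf_aa_exclusive=get("orf", "min_orf_aa_exclusive", int, dflt.min_orf_aa_exclusive),
        full_length_fraction=get("orthologs", "full_length_fraction", float, dflt.full_length_fraction),
        fdr_threshold=get("peptides", "fdr_threshold", float, dflt.fdr_threshold),
        bin_width=get("report", "bin_width", int, dflt.bin_width),
        null_replicates=get("orf", "null_replicates", int, dflt.null_replicates),
        null_composition=get("orf", "null_composition", str, dflt.null_composition),
        seed=get("report", "seed", int, dflt.seed),
        synthetic=synth,
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_synthetic_pipeline(config: PipelineConfig, outdir) -> dict:
    """Generate the synthetic inputs, run every stage, write the bundle.

    Returns the report dictionary (also written to ``report.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    t0 = time.time()

    def note(stage: str, msg: str) -> None:
        log.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    # --- synthetic inputs -------------------------------------------------
    scfg = config.synthetic
    transcripts, truths = synthetic_data.generate_transcriptome(scfg)
    peptide_table = synthetic_data.digest_and_sample_peptides(truths, scfg)
    observed = synthetic_data.observed_peptides(peptide_table)
    tables, go_map = synthetic_data.generate_hit_tables(truths, scfg)
    q_hits, s_hits, s_lengths, orth_truth = synthetic_data.generate_ortholog_tables(
        truths, scfg
    )
    io.write_fasta(out / "transcripts.fasta", transcripts)
    io.write_truth_tsv(out / "truth.tsv", truths)
    io.write_tsv(out / "peptides_observed.tsv", observed)
    io.write_go_map(out / "go_map.tsv", go_map)
    for db, tab in tables.items():
        io.write_blast_table(out / f"hits_{db}.tsv", tab)
    io.write_blast_table(out / "ortholog_query_hits.tsv", q_hits)
    io.write_blast_table(out / "ortholog_subject_hits.tsv", s_hits)
    io.write_tsv(out / "ortholog_subject_lengths.tsv", s_lengths)
    io.write_tsv(out / "ortholog_truth.tsv", orth_truth)
    note("synth", f"{len(transcripts)} transcripts, {len(observed)} observed peptides")

    report = run_pipeline(
        config,
        out,
        transcripts=transcripts,
        observed_peptides=observed["peptide"].tolist(),
        hit_tables=tables,
        go_map=go_map,
        ortholog_query_hits=q_hits,
        ortholog_subject_hits=s_hits,
        subject_lengths=s_lengths,
        log=log,
        note=note,
    )
    return report


def run_pipeline(
    config: PipelineConfig,
    outdir,
    transcripts,
    observed_peptides,
    hit_tables,
    go_map,
    ortholog_query_hits,
    ortholog_subject_hits,
    subject_lengths,
    log: list[str] | None = None,
    note=None,
) -> dict:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if log is None:
        log = []
        t0 = time.time()

        def note(stage, msg):  # noqa: ANN001 - local logger
            log.append(f"[{time.time() - t0:8.2f}s] {stage}: {msg}")

    report: dict = {"parameters": config.manifest(), "stages": {}}

    # --- assembly QC ------------------------------------------------------
    try:
        stats = assembly_qc.assembly_stats(transcripts)
        clusters = assembly_qc.greedy_redundancy_cluster(
            transcripts, config.min_identity, config.max_overhang
        )
        by_id = {t.id: t for t in transcripts}
        representatives = [by_id[c.representative_id] for c in clusters]
        io.write_json(out / "assembly_stats.json", stats.to_dict())
        io.write_clusters_tsv(out / "clusters.tsv", clusters)
        io.write_fasta(out / "representatives.fasta", representatives)
        report["stages"]["assembly_qc"] = {
            **stats.to_dict(),
            "n_clusters": len(clusters),
            "n_representatives": len(representatives),
        }
        note("assembly_qc", f"{stats.n_transcripts} in -> {len(clusters)} clusters")
    except Exception as exc:  # pragma: no cover - fail loud with stage name
        raise StageError("assembly_qc", str(exc)) from exc

    # --- ORFs and search database ----------------------------------------
    try:
        search_db = orf_toolkit.build_search_db(
            representatives, config.min_orf_aa_exclusive
        )
        io.write_orf_fasta(out / "search_db.fasta", search_db)
        report["stages"]["orf_toolkit"] = {"n_search_db_entries": len(search_db)}
        note("orf_toolkit", f"{len(search_db)} ORFs > {config.min_orf_aa_exclusive} aa")
    except Exception as exc:
        raise StageError("orf_toolkit", str(exc)) from exc

    # --- peptide matching, FDR, frameshifts -------------------------------
    try:
        hits = peptide_evidence.match_peptides(observed_peptides, search_db)
        decoy_db = peptide_evidence.build_decoy_db(search_db)
        decoy_hits = peptide_evidence.match_peptides(
            observed_peptides, decoy_db, decoy=True
        )
        fdr = peptide_evidence.decoy_fdr(hits, decoy_hits, config.fdr_threshold)
        validation = peptide_evidence.summarize_validation(hits)
        shifts, mixed = peptide_evidence.detect_frameshifts(hits)
        io.write_tsv(out / "peptide_hits.tsv", peptide_evidence.hits_to_frame(hits))
        io.write_tsv(
            out / "frameshifts.tsv",
            pd.DataFrame(
                [
                    (c.transcript_id, c.n_shifts,
                     ",".join(map(str, c.frame_path)))
                    for c in shifts
                ],
                columns=["transcript_id", "n_shifts", "frame_path"],
            ),
        )
        io.write_json(
            out / "validation.json",
            {**validation.to_dict(), "fdr": fdr.fdr, "fdr_passed": fdr.passed,
             "n_frameshift_transcripts": len(shifts),
             "mixed_strand_transcripts": mixed},
        )
        report["stages"]["peptide_evidence"] = {
            **validation.to_dict(),
            "fdr": fdr.fdr,
            "fdr_passed": fdr.passed,
            "n_frameshift_transcripts": len(shifts),
            "n_mixed_strand": len(mixed),
        }
        note("peptides", f"{validation.n_transcripts_ge1} transcripts verified, "
             f"{len(shifts)} frameshifted, FDR {fdr.fdr:.4f}")
    except Exception as exc:
        raise StageError("peptide_evidence", str(exc)) from exc

    # --- annotation --------------------------------------------------------
    try:
        taxa = {db: DATABASES.get(db, (None, db))[1] for db in hit_tables}
        all_hits = annotation_filter.hits_from_tables(hit_tables, taxa)
        surviving = annotation_filter.filter_hits(all_hits, config.evalue_cutoff)
        topk, assignments = annotation_filter.select_best_annotation(
            surviving, go_map, functional_cutoff=config.functional_cutoff
        )
        curves = annotation_filter.annotation_rate_curve(
            representatives, all_hits, config.curve_cutoffs,
            config.bin_width, config.length_filter,
        )
        io.write_tsv(out / "annotation_decisions.tsv", topk)
        curve_rows = []
        for c in curves:
            for _, row in c.bins.iterrows():
                curve_rows.append(
                    (c.cutoff, int(row["bin_start"]), int(row["n_total"]),
                     int(row["n_annotated"]), round(float(row["rate"]), 6))
                )
        io.write_tsv(out / "annotation_curve.tsv", pd.DataFrame(
            curve_rows,
            columns=["cutoff", "bin_start", "n_total", "n_annotated", "rate"],
        ))
        main_curve = next(
            (c for c in curves if c.cutoff == config.evalue_cutoff), curves[0]
        )
        report["stages"]["annotation_filter"] = {
            "n_hits_in": int(len(all_hits)),
            "n_hits_surviving": int(len(surviving)),
            "n_annotated_transcripts": int(surviving["query_id"].nunique()),
            "n_functional_assignments": int(assignments["query_id"].nunique())
            if not assignments.empty else 0,
            "l50_per_cutoff": {str(c.cutoff): c.l50 for c in curves},
            "annotation_rate_ge_length": main_curve.rate_ge_length,
        }
        note("annotation", f"{len(all_hits)} hits -> {len(surviving)} at "
             f"cutoff {config.evalue_cutoff}")
    except Exception as exc:
        raise StageError("annotation_filter", str(exc)) from exc

    # --- coding potential of non-annotated transcripts ---------------------
    try:
        annotated_now = set(surviving["query_id"])
        unannotated = [
            t for t in representatives
            if t.id not in annotated_now and t.length >= config.length_filter
        ]
        if unannotated:
            excess = orf_toolkit.coding_potential_excess(
                unannotated,
                orf_toolkit.NullModelConfig(
                    config.null_replicates, config.null_composition, config.seed
                ),
                config.bin_width,
            )
            io.write_tsv(out / "coding_potential.tsv", pd.DataFrame(
                [
                    (b.bin_start, b.bin_end, b.n_real, b.null_max_aa,
                     b.n_exceed, round(b.fraction, 6))
                    for b in excess
                ],
                columns=["bin_start", "bin_end", "n_real", "null_max_aa",
                         "n_exceed", "fraction"],
            ))
            n_exceed = sum(b.n_exceed for b in excess)
            n_real = sum(b.n_real for b in excess)
        else:
            n_exceed = n_real = 0
        report["stages"]["coding_potential"] = {
            "n_unannotated_ge_length": n_real,
            "n_exceeding_null_max": n_exceed,
            "fraction_exceeding": n_exceed / n_real if n_real else 0.0,
        }
        note("coding_potential", f"{n_exceed}/{n_real} exceed the null maximum")
    except Exception as exc:
        raise StageError("coding_potential", str(exc)) from exc

    # --- orthologues -------------------------------------------------------
    try:
        pairs = ortholog_fullness.reciprocal_best_pairs(
            ortholog_query_hits, ortholog_subject_hits
        )
        called, orth_summary, orth_errors = ortholog_fullness.call_full_length(
            pairs, subject_lengths, config.full_length_fraction
        )
        io.write_tsv(out / "ortholog_pairs.tsv",
                     ortholog_fullness.pairs_to_frame(called))
        report["stages"]["ortholog_fullness"] = orth_summary
        note("orthologs", f"{orth_summary['n_pairs']} pairs, "
             f"{orth_summary['n_full_length']} full length")
    except Exception as exc:
        raise StageError("ortholog_fullness", str(exc)) from exc

    # --- specificity and novelty ------------------------------------------
    try:
        validation_counts = validation.per_transcript
        calls = specificity_novelty.classify_specificity(
            [t.id for t in representatives],
            surviving,
            config.urodele_dbs,
            validation_counts,
            known_dbs=set(hit_tables),
        )
        calls_df = specificity_novelty.calls_to_frame(calls)
        io.write_tsv(out / "specificity.tsv", calls_df)
        candidates = [c.transcript_id for c in calls if c.candidate]
        cand_proteins = {}
        for tid in candidates:
            orf = orf_toolkit.longest_orf(by_id[tid])
            if orf is not None:
                cand_proteins[tid] = orf.aa_sequence
        families = specificity_novelty.cluster_novel_proteins(
            cand_proteins, config.cluster_min_identity, config.cluster_min_coverage
        )
        io.write_tsv(out / "novel_clusters.tsv", pd.DataFrame(
            [(f"fam{i:04d}", m) for i, fam in enumerate(families) for m in fam],
            columns=["cluster_id", "member_id"],
        ))
        pattern_matches = []
        for pat_text in config.patterns:
            pattern = specificity_novelty.parse_prosite(pat_text)
            for m in specificity_novelty.scan_pattern(pattern, cand_proteins):
                pattern_matches.append((pat_text, m.sequence_id, m.start, m.end))
        io.write_tsv(out / "pattern_matches.tsv", pd.DataFrame(
            pattern_matches, columns=["pattern", "sequence_id", "start", "end"],
        ))
        report["stages"]["specificity_novelty"] = {
            "n_no_hit": sum(1 for c in calls if c.specificity_class == "no_hit"),
            "n_urodele_only": sum(
                1 for c in calls if c.specificity_class == "urodele_only"
            ),
            "n_annotated": sum(
                1 for c in calls if c.specificity_class == "annotated"
            ),
            "n_candidates": len(candidates),
            "n_families_ge2": sum(1 for f in families if len(f) >= 2),
            "n_pattern_matches": len(pattern_matches),
        }
        note("specificity", f"{len(candidates)} candidate novel proteins")
    except Exception as exc:
        raise StageError("specificity_novelty", str(exc)) from exc

    # --- three-way partition (length / annotation / peptide evidence) ------
    try:
        annotated_ids = set(surviving["query_id"])
        verified_ids = {t for t, c in validation_counts.items() if c >= 1}
        crosstab: dict[str, int] = {}
        for t in representatives:
            key = (
                ("L" if t.length >= config.length_filter else "-")
                + ("A" if t.id in annotated_ids else "-")
                + ("P" if t.id in verified_ids else "-")
            )
            crosstab[key] = crosstab.get(key, 0) + 1
        report["crosstab"] = dict(sorted(crosstab.items()))
        report["crosstab_legend"] = (
            "L: length >= length_filter, A: annotated at the working cutoff, "
            "P: peptide verified (>=1 peptide)"
        )
    except Exception as exc:
        raise StageError("report", str(exc)) from exc

    io.write_json(out / "report.json", report)
    (out / "run.log").write_text("\n".join(log) + "\n")
    return report
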