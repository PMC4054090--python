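"""File I/O: FASTA via Biopython, tab-separated tables via pandas.

All tables are plain TSV; BLAST tabular files follow the 12-column dialect
with an optional 13th description column.  Coordinates on disk are 0-based
half-open, matching the in-memory records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly_qc import Cluster, Transcript
from .orf_toolkit import OrfRecord, parse_orf_header
from .synthetic_data import BLAST13_COLUMNS, TruthRecord


def read_fasta(path) -> list[Transcript]:
    return [
        Transcript(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, transcripts: Iterable[Transcript]) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_orf_fasta(path, orfs: Iterable[OrfRecord]) -> None:
    records = [
        SeqRecord(Seq(o.aa_sequence), id=o.header(), description="") for o in orfs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_orf_fasta(path) -> list[OrfRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tid, frame, nt_s, nt_e = parse_orf_header(rec.id)
        off = abs(frame) - 1
        # frame_aa_start is recoverable for forward frames only from the
        # header; reverse frames need the transcript length, so it is
        # recomputed lazily by callers that need it.  Forward suffices here.
        frame_aa_start = (nt_s - off) // 3 if frame > 0 else 0
        out.append(OrfRecord(tid, frame, nt_s, nt_e, str(rec.seq), frame_aa_start))
    return out


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_blast_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=BLAST13_COLUMNS, float_format="%.6g")


def write_clusters_tsv(path, clusters: Sequence[Cluster]) -> None:
    rows = [
        (c.cluster_id, m, m == c.representative_id)
        for c in clusters
        for m in c.member_ids
    ]
    write_tsv(path, pd.DataFrame(
        rows, columns=["cluster_id", "member_id", "is_representative"]
    ))


def write_truth_tsv(path, truths: Iterable[TruthRecord]) -> None:
    rows = []
    for tr in truths:
        interval = (
            f"{tr.orf_nt_interval[0]}-{tr.orf_nt_interval[1]}"
            if tr.orf_nt_interval
            else ""
        )
        rows.append(
            (
                tr.transcript_id,
                tr.is_coding,
                interval,
                ",".join(map(str, tr.frameshift_positions)),
                ",".join(map(str, tr.frameshift_ops)),
                tr.specificity_class,
                tr.source_protein or "",
            )
        )
    write_tsv(path, pd.DataFrame(
        rows,
        columns=["transcript_id", "is_coding", "orf_nt_interval",
                 "frameshift_positions", "frameshift_ops",
                 "specificity_class", "source_protein"],
    ))


def write_json(path, obj: Mapping) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_go_map(path) -> dict[str, list[str]]:
    go_map: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        subject, terms = line.split("\t", 1)
        go_map[subject] = terms.split(";")
    return go_map


def write_go_map(path, go_map: Mapping[str, Sequence[str]]) -> None:
    lines = [f"{sid}\t{';'.join(terms)}" for sid, terms in sorted(go_map.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
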