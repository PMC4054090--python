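"""Homology-hit thresholding, quality flagging, best-hit selection and
annotation-rate-versus-length curves.

Hits arrive as 12-column BLAST tabular rows with a 13th free-text
description column; the originating database and taxon are file-level
metadata attached at load time.  Filtering is inclusive (e-value <= cutoff).
Description lines containing generic submission keywords ('mRNA', 'cDNA',
'clone', 'genomic') are flagged low-quality but kept, so downstream stages
can choose whether to trust them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assembly_qc import Transcript
from .synthetic_data import BLAST13_COLUMNS, LOW_QUALITY_KEYWORDS

DEFAULT_CUTOFF = 1e-15
FUNCTIONAL_CUTOFF = 1e-20
DEFAULT_LENGTH_FILTER = 400

HIT_COLUMNS = ["query_id", "database", "taxon", "subject_id", "description",
               "evalue", "bitscore", "align_length", "low_quality"]


def load_blast_table(
    path_or_buf, database: str, taxon: str
) -> tuple[pd.DataFrame, int]:
    """Read a 12+1-column BLAST tabular file, attaching database/taxon.

    Malformed rows are counted and skipped, not fatal.  Returns
    ``(hits, n_malformed)``.
    """
    if isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text()
    else:
        text = path_or_buf.read()
    rows = []
    n_bad = 0
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            n_bad += 1
            continue
        try:
            rows.append(
                {
                    "query_id": parts[0],
                    "database": database,
                    "taxon": taxon,
                    "subject_id": parts[1],
                    "description": parts[12] if len(parts) > 12 else "",
                    "evalue": float(parts[10]),
                    "bitscore": float(parts[11]),
                    "align_length": int(parts[3]),
                }
            )
        except ValueError:
            n_bad += 1
    df = pd.DataFrame(rows, columns=HIT_COLUMNS[:-1])
    return df, n_bad


def hits_from_tables(
    tables: Mapping[str, pd.DataFrame],
    taxa: Mapping[str, str],
) -> pd.DataFrame:
    """Normalise per-database 13-column tables into the internal hit frame."""
    frames = []
    for db, tab in tables.items():
        if tab.empty:
            continue
        df = pd.DataFrame(
            {
                "query_id": tab["qseqid"],
                "database": db,
                "taxon": taxa.get(db, db),
                "subject_id": tab["sseqid"],
                "description": tab["description"],
                "evalue": tab["evalue"].astype(float),
                "bitscore": tab["bitscore"].astype(float),
                "align_length": tab["length"].astype(int),
            }
        )
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=HIT_COLUMNS[:-1])
    return pd.concat(frames, ignore_index=True)


def flag_low_quality(
    descriptions: pd.Series,
    keywords: Sequence[str] = LOW_QUALITY_KEYWORDS,
    word_boundary: bool = False,
) -> pd.Series:
    """Case-insensitive keyword flag; substring match by default, whole-word
    match when ``word_boundary`` is set."""
    if word_boundary:
        pat = r"\b(?:" + "|".join(re.escape(k) for k in keywords) + r")\b"
    else:
        pat = "|".join(re.escape(k) for k in keywords)
    return descriptions.str.contains(pat, case=False, regex=True)


def filter_hits(
    hits: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    keywords: Sequence[str] = LOW_QUALITY_KEYWORDS,
) -> pd.DataFrame:
    """Retain hits with evalue <= cutoff and attach the low_quality flag."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    kept = hits.loc[hits["evalue"] <= cutoff].copy()
    if kept.empty:
        kept["low_quality"] = pd.Series(dtype=bool)
        return kept.reset_index(drop=True)
    kept["low_quality"] = flag_low_quality(kept["description"], keywords).values
    return kept.reset_index(drop=True)


@dataclass(frozen=True)
class AnnotationDecision:
    query_id: str
    taxon: str
    database: str
    subject_id: str
    evalue: float
    has_go: bool
    go_terms: tuple[str, ...]


def select_best_annotation(
    hits: pd.DataFrame,
    go_map: Mapping[str, Sequence[str]],
    k: int = 3,
    functional_cutoff: float = FUNCTIONAL_CUTOFF,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k retention and GO-based functional assignment.

    Per (query, taxon, database) the top ``k`` hits by ascending e-value
    (ties: descending bitscore, then subject id) are retained.  The
    functional assignment per (query, taxon) is the best-rated hit whose
    subject carries at least one GO term, applying the stricter functional
    e-value cutoff.  Queries with no GO-bearing hit stay annotated but
    functionally unassigned.

    Returns ``(topk, assignments)``.
    """
    if hits.empty:
        return hits.copy(), pd.DataFrame(
            columns=["query_id", "taxon", "database", "subject_id", "evalue",
                     "go_terms"]
        )
    ranked = hits.sort_values(
        ["query_id", "taxon", "database", "evalue", "bitscore", "subject_id"],
        ascending=[True, True, True, True, False, True],
        kind="mergesort",
    )
    topk = ranked.groupby(
        ["query_id", "taxon", "database"], sort=False
    ).head(k).reset_index(drop=True)

    func = ranked.loc[ranked["evalue"] <= functional_cutoff].copy()
    func["go_terms"] = func["subject_id"].map(
        lambda s: tuple(go_map.get(s, ()))
    )
    func = func.loc[func["go_terms"].map(bool)]
    assignments = (
        func.sort_values(
            ["query_id", "taxon", "evalue", "bitscore", "subject_id"],
            ascending=[True, True, True, False, True],
            kind="mergesort",
        )
        .groupby(["query_id", "taxon"], sort=False)
        .head(1)
        .reset_index(drop=True)[
            ["query_id", "taxon", "database", "subject_id", "evalue", "go_terms"]
        ]
    )
    return topk, assignments


@dataclass(frozen=True)
class RateCurve:
    cutoff: float
    bin_width: int
    bins: pd.DataFrame  # bin_start, n_total, n_annotated, rate
    l50: int | None  # smallest bin start with rate >= 0.5, scanning ascending
    rate_ge_length: float  # annotation rate among transcripts >= length_filter
    length_filter: int


def annotation_rate_curve(
    transcripts: Sequence[Transcript],
    hits: pd.DataFrame,
    cutoffs: Sequence[float],
    bin_width: int = 50,
    length_filter: int = DEFAULT_LENGTH_FILTER,
    cumulative: bool = False,
) -> list[RateCurve]:
    """Annotation rate as a function of transcript length, per e-value cutoff.

    A transcript counts annotated at a cutoff when at least one hit survives
    it.  Rates are computed per 50 bp length bin (or cumulatively up to each
    bin when ``cumulative`` is set); L50 is the smallest bin start whose rate
    reaches 0.5, with no requirement that later bins stay above it.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    if not list(cutoffs):
        raise ValueError("cutoff list is empty")
    lengths = pd.Series({t.id: t.length for t in transcripts})
    curves = []
    for cutoff in cutoffs:
        annotated_ids = set(hits.loc[hits["evalue"] <= cutoff, "query_id"])
        ann = lengths.index.isin(annotated_ids)
        bin_start = (lengths.values // bin_width) * bin_width
        df = pd.DataFrame(
            {"bin_start": bin_start, "annotated": ann}
        ).groupby("bin_start").agg(
            n_total=("annotated", "size"), n_annotated=("annotated", "sum")
        ).reset_index()
        if cumulative:
            df["n_total"] = df["n_total"].cumsum()
            df["n_annotated"] = df["n_annotated"].cumsum()
        df["rate"] = df["n_annotated"] / df["n_total"]
        l50 = None
        for _, row in df.iterrows():
            if row["rate"] >= 0.5:
                l50 = int(row["bin_start"])
                break
        sel = lengths >= length_filter
        rate_ge = float(ann[sel.values].mean()) if sel.any() else float("nan")
        curves.append(
            RateCurve(cutoff, bin_width, df, l50, rate_ge, length_filter)
        )
    return curves
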