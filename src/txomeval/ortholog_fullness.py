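"""Orthologue pairing and full-length transcript calling.

Orthologues are assigned by reciprocal best hit: a transcript and a
reference protein are paired when each is the other's best-scoring match
(lowest e-value, bitscore tiebreak).  A pair is called full length when the
alignment covers strictly more than 75% of the orthologue protein; assembled
transcripts are routinely somewhat longer than their orthologues, so
fractions above 1 are legitimate and kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

FULL_LENGTH_FRACTION = 0.75


@dataclass(frozen=True)
class OrthologPair:
    query_id: str
    subject_id: str
    subject_length: int
    align_length: int
    align_fraction: float
    full_length: bool


def _best_hits(hits: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: lowest e-value, then highest bitscore, then
    lexicographic subject id."""
    if hits.empty:
        return {}
    ranked = hits.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ranked.groupby("qseqid", sort=False).head(1)
    return dict(zip(best["qseqid"], best["sseqid"]))


def _alignment_length(row: pd.Series) -> int:
    """Aligned positions from the hit's alignment-length column.

    Gap columns count, so a transcript longer than its orthologue can yield
    an alignment longer than the subject itself (fraction > 1), which the
    full-length rule deliberately permits.
    """
    return int(row["length"])


def reciprocal_best_pairs(
    query_hits: pd.DataFrame,
    subject_hits: pd.DataFrame,
    one_directional: bool = False,
) -> pd.DataFrame:
    """Reciprocal-best-hit pairs from the two directional hit tables.

    ``one_directional`` keeps every query's best hit without requiring
    reciprocity (a looser mapping exposed for comparison).  Returns one row
    per query with columns query_id, subject_id, align_length.
    """
    q_best = _best_hits(query_hits)
    s_best = _best_hits(subject_hits)
    rows = []
    for q, s in sorted(q_best.items()):
        if not one_directional and s_best.get(s) != q:
            continue
        sub = query_hits.loc[
            (query_hits["qseqid"] == q) & (query_hits["sseqid"] == s)
        ]
        ranked = sub.sort_values(["evalue", "bitscore"], ascending=[True, False])
        rows.append((q, s, _alignment_length(ranked.iloc[0])))
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "align_length"])


def call_full_length(
    pairs: pd.DataFrame,
    subject_lengths: Mapping[str, int] | pd.DataFrame,
    full_length_fraction: float = FULL_LENGTH_FRACTION,
) -> tuple[list[OrthologPair], dict, list[dict]]:
    """Flag pairs whose alignment exceeds the full-length fraction of the
    orthologue length (strict inequality: exactly 75% is not full length).

    Rows whose subject length is missing or non-positive are rejected into
    the error list rather than silently dropped.  Returns
    ``(pairs, summary, errors)``.
    """
    if isinstance(subject_lengths, pd.DataFrame):
        subject_lengths = dict(
            zip(subject_lengths["subject_id"], subject_lengths["length"])
        )
    out: list[OrthologPair] = []
    errors: list[dict] = []
    for _, row in pairs.iterrows():
        slen = subject_lengths.get(row["subject_id"])
        if slen is None or slen <= 0:
            errors.append(
                {"query_id": row["query_id"], "subject_id": row["subject_id"],
                 "reason": f"invalid subject length {slen!r}"}
            )
            continue
        frac = row["align_length"] / slen
        out.append(
            OrthologPair(
                row["query_id"], row["subject_id"], int(slen),
                int(row["align_length"]), frac, frac > full_length_fraction,
            )
        )
    n_full = sum(1 for p in out if p.full_length)
    summary = {
        "n_pairs": len(out),
        "n_full_length": n_full,
        "pct_full_length": 100.0 * n_full / len(out) if out else 0.0,
        "n_rejected": len(errors),
    }
    return out, summary, errors


def pairs_to_frame(pairs: list[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.query_id, p.subject_id, p.subject_length, p.align_length,
             round(p.align_fraction, 6), p.full_length)
            for p in pairs
        ],
        columns=["query_id", "subject_id", "subject_length", "align_length",
                 "align_fraction", "full_length"],
    )
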