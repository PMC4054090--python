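"""Peptide-to-transcript matching, coding validation, frameshift detection
and target-decoy FDR control.

Matching is exact substring search of already-identified peptide sequences
against the six-frame ORF search database, under I/L equivalence (leucine
and isoleucine are isobaric and indistinguishable by standard MS/MS).
Spectrum-level scoring is out of scope: the pipeline consumes peptide
strings, not spectra.

A frameshift is called when peptide evidence on one transcript falls into
different reading frames on the same strand in non-overlapping stretches:
an indel introduced during assembly moves the true coding sequence between
frames, and the peptides bracket the event.  Transcripts with peptide
evidence on both strands are anomalies reported separately, never counted
as shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .orf_toolkit import OrfRecord

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class InvalidPeptideError(ValueError):
    pass


@dataclass(frozen=True)
class PeptideHit:
    peptide: str
    transcript_id: str
    frame: int
    aa_start: int  # 0-based half-open on the frame's full translation
    aa_end: int
    nt_start: int  # forward-strand nt coordinates
    nt_end: int
    is_decoy: bool = False


@dataclass(frozen=True)
class FrameshiftCall:
    transcript_id: str
    n_shifts: int
    frame_path: tuple[int, ...]
    supporting_peptides: tuple[tuple[str, ...], ...]  # per segment


@dataclass(frozen=True)
class ValidationSummary:
    n_transcripts_ge1: int
    n_transcripts_ge2: int
    n_peptides: int
    per_transcript: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_transcripts_ge1": self.n_transcripts_ge1,
            "n_transcripts_ge2": self.n_transcripts_ge2,
            "n_peptides": self.n_peptides,
        }


def collapse_il(seq: str) -> str:
    """Map I to L so isobaric residues compare equal."""
    return seq.replace("I", "L")


def _check_peptides(peptides: Iterable[str]) -> list[str]:
    out = []
    for pep in peptides:
        if not pep:
            raise InvalidPeptideError("empty peptide string")
        bad = set(pep) - VALID_AA
        if bad:
            raise InvalidPeptideError(
                f"peptide {pep!r} contains invalid residues {sorted(bad)!r}"
            )
        out.append(pep)
    return out


def build_decoy_db(search_db: Sequence[OrfRecord]) -> list[OrfRecord]:
    """Per-entry sequence reversal of the search database."""
    return [
        OrfRecord(
            orf.transcript_id, orf.frame, orf.nt_start, orf.nt_end,
            orf.aa_sequence[::-1], orf.frame_aa_start,
        )
        for orf in search_db
    ]


def match_peptides(
    peptides: Iterable[str],
    search_db: Sequence[OrfRecord],
    il_equivalent: bool = True,
    decoy: bool = False,
) -> list[PeptideHit]:
    """Every occurrence of every peptide in the search database.

    Peptides containing 'X', and database slices containing 'X', never match
    (an ambiguous codon cannot support an identification).  Coordinates are
    mapped from the ORF's frame back to forward-strand nucleotides.
    """
    peptides = _check_peptides(peptides)
    entries = []
    for orf in search_db:
        key = collapse_il(orf.aa_sequence) if il_equivalent else orf.aa_sequence
        entries.append((orf, key))

    hits: list[PeptideHit] = []
    for pep in dict.fromkeys(peptides):  # unique, order kept
        if "X" in pep:
            continue
        key_pep = collapse_il(pep) if il_equivalent else pep
        for orf, key in entries:
            start = key.find(key_pep)
            while start != -1:
                end = start + len(pep)
                if "X" not in orf.aa_sequence[start:end]:
                    aa_s = orf.frame_aa_start + start
                    aa_e = orf.frame_aa_start + end
                    if orf.frame > 0:
                        nt_s = orf.nt_start + 3 * start
                        nt_e = orf.nt_start + 3 * end
                    else:
                        nt_s = orf.nt_end - 3 * end
                        nt_e = orf.nt_end - 3 * start
                    hits.append(
                        PeptideHit(pep, orf.transcript_id, orf.frame,
                                   aa_s, aa_e, nt_s, nt_e, decoy)
                    )
                start = key.find(key_pep, start + 1)
    return hits


def hits_to_frame(hits: Iterable[PeptideHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.peptide, h.transcript_id, h.frame, h.aa_start, h.aa_end,
             h.nt_start, h.nt_end, h.is_decoy)
            for h in hits
        ],
        columns=["peptide", "transcript_id", "frame", "aa_start", "aa_end",
                 "nt_start", "nt_end", "is_decoy"],
    )


def summarize_validation(hits: Iterable[PeptideHit]) -> ValidationSummary:
    """Distinct non-decoy peptides per transcript, with >=1 / >=2 thresholds.

    Distinctness is by sequence after I/L collapse, so the same isobaric
    peptide matched at two positions counts once.
    """
    per_transcript: dict[str, set[str]] = {}
    all_peps: set[str] = set()
    for h in hits:
        if h.is_decoy:
            continue
        key = collapse_il(h.peptide)
        per_transcript.setdefault(h.transcript_id, set()).add(key)
        all_peps.add(key)
    counts = {tid: len(peps) for tid, peps in per_transcript.items()}
    return ValidationSummary(
        n_transcripts_ge1=sum(1 for c in counts.values() if c >= 1),
        n_transcripts_ge2=sum(1 for c in counts.values() if c >= 2),
        n_peptides=len(all_peps),
        per_transcript=counts,
    )


def detect_frameshifts(
    hits: Iterable[PeptideHit],
) -> tuple[list[FrameshiftCall], list[str]]:
    """Frameshift calls from multi-frame peptide evidence.

    Per transcript, non-decoy hits are ordered by nt_start and runs of
    same-frame hits are collapsed into segments; each adjacent pair of
    segments in different frames on the same strand with non-overlapping
    nt spans counts one shift.  Returns ``(calls, mixed_strand_ids)``:
    transcripts whose evidence spans both strands are reported in the second
    list and never produce calls.
    """
    by_tid: dict[str, list[PeptideHit]] = {}
    for h in hits:
        if not h.is_decoy:
            by_tid.setdefault(h.transcript_id, []).append(h)

    calls: list[FrameshiftCall] = []
    mixed: list[str] = []
    for tid in sorted(by_tid):
        txh = sorted(by_tid[tid], key=lambda h: (h.nt_start, h.nt_end))
        strands = {1 if h.frame > 0 else -1 for h in txh}
        if len(strands) > 1:
            mixed.append(tid)
            continue
        segments: list[list[PeptideHit]] = []
        for h in txh:
            if segments and segments[-1][0].frame == h.frame:
                segments[-1].append(h)
            else:
                segments.append([h])
        n_shifts = 0
        for prev, nxt in zip(segments, segments[1:]):
            prev_end = max(h.nt_end for h in prev)
            if nxt[0].nt_start >= prev_end:  # non-overlapping spans
                n_shifts += 1
        if n_shifts >= 1:
            calls.append(
                FrameshiftCall(
                    tid, n_shifts,
                    tuple(seg[0].frame for seg in segments),
                    tuple(
                        tuple(sorted({h.peptide for h in seg})) for seg in segments
                    ),
                )
            )
    return calls, mixed


@dataclass(frozen=True)
class FdrResult:
    n_target: int
    n_decoy: int
    fdr: float
    passed: bool
    warning: str | None = None


def decoy_fdr(
    hits_target: Iterable[PeptideHit],
    hits_decoy: Iterable[PeptideHit],
    threshold: float = 0.01,
) -> FdrResult:
    """Target-decoy FDR on distinct matched peptides; pass iff FDR is
    strictly below the threshold ("below 1%")."""
    targets = {collapse_il(h.peptide) for h in hits_target}
    decoys = {collapse_il(h.peptide) for h in hits_decoy}
    warning = None
    if not targets:
        if decoys:
            fdr = 1.0
            warning = "decoy matches without any target match"
        else:
            fdr = 0.0
    else:
        fdr = len(decoys) / len(targets)
    return FdrResult(len(targets), len(decoys), fdr, fdr < threshold, warning)
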