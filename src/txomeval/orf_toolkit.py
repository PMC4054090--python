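"""Six-frame translation, ORF extraction, search-database construction and
the coding-potential test against a length-matched random null.

ORFs are stop-to-stop: a maximal stop-free stretch of codons in one reading
frame, with the sequence ends counting as boundaries.  No start codon is
required — the search database built here feeds substring-based peptide
matching, where an ATG anchor would only lose evidence.  'X' (ambiguous
codon) does not terminate an ORF, but peptides overlapping an 'X' can never
match downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._dna import FRAMES, six_frame_translate, validate_dna
from .assembly_qc import Transcript

#: ORFs must be longer than this many residues to enter the search database.
MIN_ORF_AA_EXCLUSIVE = 25


@dataclass(frozen=True)
class OrfRecord:
    """A stop-free translated stretch located on its transcript.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the forward
    strand; ``frame_aa_start`` is the ORF's offset (in residues) within the
    full translation of its frame, which lets peptide hits be mapped back
    without re-translating.
    """

    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    frame_aa_start: int

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    def header(self) -> str:
        sign = "+" if self.frame > 0 else ""
        return f"{self.transcript_id}|{sign}{self.frame}|{self.nt_start}-{self.nt_end}"


def parse_orf_header(header: str) -> tuple[str, int, int, int]:
    """Inverse of :meth:`OrfRecord.header` -> (transcript_id, frame, nt_start, nt_end)."""
    m = re.match(r"^(.*)\|([+-]\d)\|(\d+)-(\d+)$", header)
    if m is None:
        raise ValueError(f"malformed ORF header: {header!r}")
    return m.group(1), int(m.group(2)), int(m.group(3)), int(m.group(4))


def _frame_to_forward(frame: int, L: int, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map a residue interval on a frame's translation to forward-strand nt."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    # residues count from the 5' end of the reverse complement
    return L - (off + 3 * aa_end), L - (off + 3 * aa_start)


def extract_orfs(transcript: Transcript) -> list[OrfRecord]:
    """All maximal stop-free stretches in the six frames.

    Records are ordered by frame (+1,+2,+3,-1,-2,-3), then by position within
    the frame's translation.
    """
    L = transcript.length
    translations = six_frame_translate(transcript.sequence)
    orfs: list[OrfRecord] = []
    for frame in FRAMES:
        prot = translations[frame]
        pos = 0
        for chunk in prot.split("*"):
            if chunk:
                nt_s, nt_e = _frame_to_forward(frame, L, pos, pos + len(chunk))
                orfs.append(
                    OrfRecord(transcript.id, frame, nt_s, nt_e, chunk, pos)
                )
            pos += len(chunk) + 1
    return orfs


def longest_orf(transcript: Transcript) -> OrfRecord | None:
    """Longest ORF; ties broken by frame order +1,+2,+3,-1,-2,-3, then by
    position within the frame (leftmost first)."""
    best: OrfRecord | None = None
    for orf in extract_orfs(transcript):  # already in tie-break order
        if best is None or orf.aa_length > best.aa_length:
            best = orf
    return best


def longest_orf_aa(transcript: Transcript) -> int:
    orf = longest_orf(transcript)
    return orf.aa_length if orf else 0


def build_search_db(
    transcripts: Iterable[Transcript],
    min_aa_exclusive: int = MIN_ORF_AA_EXCLUSIVE,
) -> list[OrfRecord]:
    """ORFs strictly longer than ``min_aa_exclusive`` residues, i.e. the
    peptide-search database (a 25 aa ORF is excluded, 26 aa is included)."""
    db: list[OrfRecord] = []
    for t in transcripts:
        for orf in extract_orfs(t):
            if orf.aa_length > min_aa_exclusive:
                db.append(orf)
    return db


# ---------------------------------------------------------------------------
# coding-potential null model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NullModelConfig:
    n_replicates: int = 1
    composition: str = "matched"  # or "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.composition not in ("matched", "uniform"):
            raise ValueError("composition must be 'matched' or 'uniform'")


@dataclass(frozen=True)
class ExcessBin:
    bin_start: int
    bin_end: int
    n_real: int
    null_max_aa: int
    n_exceed: int
    fraction: float


def _base_frequencies(transcripts: Sequence[Transcript]) -> np.ndarray:
    counts = np.zeros(4, dtype=np.int64)
    lut = {b: i for i, b in enumerate("ACGT")}
    for t in transcripts:
        for ch in t.sequence.upper():
            i = lut.get(ch)
            if i is not None:
                counts[i] += 1
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def random_transcripts(
    lengths: Sequence[int],
    rng: np.random.Generator,
    composition: np.ndarray | None = None,
    prefix: str = "null",
) -> list[Transcript]:
    """Random DNA of the given lengths at the given base composition."""
    p = np.full(4, 0.25) if composition is None else np.asarray(composition, float)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = []
    for i, L in enumerate(lengths):
        seq = bases[rng.choice(4, size=int(L), p=p)].tobytes().decode("ascii")
        out.append(Transcript(f"{prefix}{i:06d}", seq))
    return out


def coding_potential_excess(
    real: Sequence[Transcript],
    null_cfg: NullModelConfig = NullModelConfig(),
    bin_width: int = 50,
) -> list[ExcessBin]:
    """Per length bin, how many real transcripts carry a longer longest-ORF
    than the maximum seen in a random set of the same number and lengths.

    The null set replicates the real length multiset ``n_replicates`` times;
    its base composition is matched to the input pool by default.  A real
    transcript "exceeds" only when its longest ORF is strictly longer than
    the null maximum of its 50 bp length bin.  Bins with no real transcript
    are omitted.
    """
    if not real:
        raise ValueError("real transcript set is empty")
    rng = np.random.default_rng(null_cfg.seed)
    comp = (
        _base_frequencies(real) if null_cfg.composition == "matched" else None
    )
    lengths = [t.length for t in real]
    null_lengths = lengths * null_cfg.n_replicates
    nulls = random_transcripts(null_lengths, rng, comp)

    real_by_bin: dict[int, list[int]] = {}
    for t in real:
        real_by_bin.setdefault((t.length // bin_width) * bin_width, []).append(
            longest_orf_aa(t)
        )
    null_by_bin: dict[int, int] = {}
    for t in nulls:
        b = (t.length // bin_width) * bin_width
        v = longest_orf_aa(t)
        if v > null_by_bin.get(b, -1):
            null_by_bin[b] = v

    report: list[ExcessBin] = []
    for b in sorted(real_by_bin):
        vals = real_by_bin[b]
        null_max = null_by_bin.get(b, 0)
        n_exceed = sum(1 for v in vals if v > null_max)
        report.append(
            ExcessBin(b, b + bin_width, len(vals), null_max, n_exceed,
                      n_exceed / len(vals))
        )
    return report


def global_excess(real: Sequence[Transcript], null_cfg: NullModelConfig = NullModelConfig()) -> float:
    """Variant of the excess statistic pooling all bins: the fraction of real
    transcripts whose longest ORF exceeds the global null maximum."""
    if not real:
        raise ValueError("real transcript set is empty")
    rng = np.random.default_rng(null_cfg.seed)
    comp = _base_frequencies(real) if null_cfg.composition == "matched" else None
    lengths = [t.length for t in real] * null_cfg.n_replicates
    nulls = random_transcripts(lengths, rng, comp)
    null_max = max(longest_orf_aa(t) for t in nulls)
    vals = [longest_orf_aa(t) for t in real]
    return sum(1 for v in vals if v > null_max) / len(vals)
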