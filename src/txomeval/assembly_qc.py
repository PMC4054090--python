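"""Assembly summary statistics and redundancy-reduction clustering.

The clustering step merges pre-assembled contig pools into a non-redundant
transcript set: two sequences are linked when a local alignment (on either
strand) reaches the identity threshold over the aligned region and leaves at
most ``max_overhang`` unaligned nucleotides at each end of the shorter
sequence.  Links are closed transitively (single linkage), mirroring a
cluster-then-assemble merge; the representative of each cluster is its
longest member rather than a base-level consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from ._dna import revcomp, validate_dna


@dataclass(frozen=True)
class Transcript:
    """One assembled DNA sequence."""

    id: str
    sequence: str
    is_coding: bool | None = None  # optional truth label, None if unknown

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has empty sequence")
        validate_dna(self.sequence, context=f"transcript {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts: int
    n50: int
    n_ge_400: int
    n_ge_500: int
    n_ge_1000: int
    total_bases: int

    def to_dict(self) -> dict:
        return {
            "n_transcripts": self.n_transcripts,
            "n50": self.n50,
            "n_ge_400": self.n_ge_400,
            "n_ge_500": self.n_ge_500,
            "n_ge_1000": self.n_ge_1000,
            "total_bases": self.total_bases,
        }


@dataclass
class Cluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str


def compute_n50(transcripts: Iterable[Transcript | int]) -> int:
    """Smallest length L such that transcripts of length >= L hold at least
    half of all assembled bases.

    Accepts transcripts or raw lengths.  The accumulating transcript's own
    length is counted before the half-total comparison, the usual
    assembly-stats convention at exact-half boundaries.
    """
    lengths = sorted(
        (t.length if isinstance(t, Transcript) else int(t) for t in transcripts),
        reverse=True,
    )
    if not lengths:
        raise ValueError("cannot compute N50 of an empty transcript set")
    if min(lengths) <= 0:
        raise ValueError("transcript lengths must be positive")
    total = sum(lengths)
    acc = 0
    for length in lengths:
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def assembly_stats(transcripts: Sequence[Transcript]) -> AssemblyStats:
    lengths = [t.length for t in transcripts]
    return AssemblyStats(
        n_transcripts=len(lengths),
        n50=compute_n50(lengths),
        n_ge_400=sum(1 for x in lengths if x >= 400),
        n_ge_500=sum(1 for x in lengths if x >= 500),
        n_ge_1000=sum(1 for x in lengths if x >= 1000),
        total_bases=sum(lengths),
    )


def length_histogram(
    transcripts: Iterable[Transcript | int], bin_width: int = 50
) -> dict[int, int]:
    """Counts per half-open length bin [k*w, (k+1)*w), keyed by bin start."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hist: dict[int, int] = {}
    for t in transcripts:
        length = t.length if isinstance(t, Transcript) else int(t)
        start = (length // bin_width) * bin_width
        hist[start] = hist.get(start, 0) + 1
    return dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# redundancy clustering
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass(frozen=True)
class PairAlignment:
    """Identity and terminal-overhang summary of the best local alignment."""

    identity: float  # matches / aligned columns (gap columns included)
    overhang_left: int  # unaligned nt at the 5' end of the shorter sequence
    overhang_right: int
    strand: int  # +1 or -1, orientation of seq2 relative to seq1


def _score_alignment(aln, s1: str, s2: str) -> tuple[float, int, int]:
    blocks1, blocks2 = aln.aligned
    if len(blocks1) == 0:
        return 0.0, len(s2), len(s2)
    matches = 0
    columns = 0
    prev1 = prev2 = None
    for (a1, b1), (a2, b2) in zip(blocks1, blocks2):
        if prev1 is not None:
            columns += (a1 - prev1) + (a2 - prev2)  # gap columns
        for c1, c2 in zip(s1[a1:b1], s2[a2:b2]):
            columns += 1
            if c1 == c2 and c1 in _ACGT:  # ambiguity codes never match
                matches += 1
        prev1, prev2 = b1, b2
    start2, end2 = blocks2[0][0], blocks2[-1][1]
    identity = matches / columns if columns else 0.0
    return identity, start2, len(s2) - end2


def strand_alignments(s1: str, s2: str) -> list[PairAlignment]:
    """Best local alignment of s2 against s1 on each strand.

    Overhangs are measured on s2, which callers arrange to be the shorter
    sequence.  Both orientations are returned because a spurious short
    perfect-identity alignment on the wrong strand must not mask a genuine
    near-full-length alignment on the other.
    """
    aligner = _make_aligner()
    out: list[PairAlignment] = []
    for strand, seq2 in ((1, s2), (-1, revcomp(s2))):
        alns = aligner.align(s1, seq2)
        try:
            aln = alns[0]
        except IndexError:  # no positive-scoring alignment
            continue
        identity, left, right = _score_alignment(aln, s1, seq2)
        out.append(PairAlignment(identity, left, right, strand))
    return out


def best_local_alignment(s1: str, s2: str) -> PairAlignment:
    """The higher-identity strand alignment (reporting convenience)."""
    cands = strand_alignments(s1, s2)
    if not cands:
        return PairAlignment(0.0, len(s2), len(s2), 1)
    return max(cands, key=lambda pa: pa.identity)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    n = len(seq)
    out: set[str] = set()
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        out.add(min(fwd, rev))
    return out


def transcripts_linked(
    t1: Transcript,
    t2: Transcript,
    min_identity: float = 0.90,
    max_overhang: int = 30,
) -> bool:
    """Redundancy link test: identity over the aligned region and terminal
    overhangs on the shorter sequence, either strand."""
    if t1.length >= t2.length:
        long_t, short_t = t1, t2
    else:
        long_t, short_t = t2, t1
    return any(
        pa.identity >= min_identity
        and pa.overhang_left <= max_overhang
        and pa.overhang_right <= max_overhang
        for pa in strand_alignments(
            long_t.sequence.upper(), short_t.sequence.upper()
        )
    )


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def greedy_redundancy_cluster(
    transcripts: Sequence[Transcript],
    min_identity: float = 0.90,
    max_overhang: int = 30,
    kmer_size: int = 16,
) -> list[Cluster]:
    """Single-linkage redundancy clusters at >=``min_identity`` identity with
    <=``max_overhang`` nt unmatched overhang per end of the shorter sequence.

    Candidate pairs are prefiltered by a shared canonical k-mer (either
    strand) before alignment.  The output partitions the input; the
    representative is the longest member (ties: lexicographically smallest
    id).  The result is invariant to input order and to reverse-complementing
    members.
    """
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    if max_overhang < 0:
        raise ValueError("max_overhang must be >= 0")
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("transcript ids must be unique")
    by_id = {t.id: t for t in transcripts}

    kmer_index: dict[str, list[str]] = {}
    for t in transcripts:
        k = min(kmer_size, t.length)
        for km in _canonical_kmers(t.sequence.upper(), k):
            kmer_index.setdefault(km, []).append(t.id)
    candidate_pairs: set[tuple[str, str]] = set()
    for members in kmer_index.values():
        if len(members) < 2:
            continue
        uniq = sorted(set(members))
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                candidate_pairs.add((uniq[i], uniq[j]))

    uf = _UnionFind(ids)
    for a, b in sorted(candidate_pairs):
        if uf.find(a) == uf.find(b):
            continue
        if transcripts_linked(by_id[a], by_id[b], min_identity, max_overhang):
            uf.union(a, b)

    groups: dict[str, list[str]] = {}
    for tid in ids:
        groups.setdefault(uf.find(tid), []).append(tid)

    clusters: list[Cluster] = []
    reps = []
    for members in groups.values():
        rep = min(members, key=lambda m: (-by_id[m].length, m))
        reps.append((rep, sorted(members)))
    reps.sort()
    for i, (rep, members) in enumerate(reps):
        clusters.append(Cluster(f"cl{i:06d}", members, rep))
    return clusters
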