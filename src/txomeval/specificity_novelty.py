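"""Species-specificity classification, PROSITE-style motif scanning and
similarity clustering of candidate novel proteins.

A peptide-verified transcript with no surviving homology hit anywhere
(``no_hit``), or with hits exclusively in databases designated urodele-only
(``urodele_only``), is a candidate novel urodele protein.  Candidate protein
sets are screened with PROSITE-dialect patterns and clustered by direct
pairwise similarity (single linkage) to propose putative families.

The pattern dialect is deliberately restricted to the constructs needed
here: fixed residues, residue classes in brackets, and flexible wildcards
``x`` / ``x(n)`` / ``x(m,n)``, joined by ``-`` with optional surrounding
parentheses.  Anything else (anchors, class repetition, negated classes) is
rejected loudly rather than half-supported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

NO_HIT, URODELE_ONLY_CLASS, ANNOTATED = "no_hit", "urodele_only", "annotated"

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SpecificityCall:
    transcript_id: str
    specificity_class: str
    peptide_verified: bool
    candidate: bool


def classify_specificity(
    transcript_ids: Sequence[str],
    surviving_hits: pd.DataFrame,
    urodele_dbs: Iterable[str],
    peptide_counts: Mapping[str, int],
    known_dbs: Iterable[str] | None = None,
) -> list[SpecificityCall]:
    """Partition transcripts into no_hit / urodele_only / annotated and flag
    candidates.

    ``surviving_hits`` must already be filtered at the working e-value
    cutoff and carry a ``database`` column.  A transcript is a candidate
    novel protein when it is peptide verified (>=1 matched peptide) and its
    class is no_hit or urodele_only.  Hits naming a database outside
    ``known_dbs`` (when provided) raise, catching plumbing mistakes early.
    """
    urodele = set(urodele_dbs)
    if known_dbs is not None:
        known = set(known_dbs) | urodele
        unknown = set(surviving_hits["database"]) - known
        if unknown:
            raise ValueError(f"hits reference unknown databases: {sorted(unknown)}")
    dbs_by_tid: dict[str, set[str]] = {}
    if not surviving_hits.empty:
        for tid, db in zip(surviving_hits["query_id"], surviving_hits["database"]):
            dbs_by_tid.setdefault(tid, set()).add(db)
    calls = []
    for tid in transcript_ids:
        dbs = dbs_by_tid.get(tid, set())
        if not dbs:
            cls = NO_HIT
        elif dbs <= urodele:
            cls = URODELE_ONLY_CLASS
        else:
            cls = ANNOTATED
        verified = peptide_counts.get(tid, 0) >= 1
        calls.append(
            SpecificityCall(tid, cls, verified,
                            verified and cls in (NO_HIT, URODELE_ONLY_CLASS))
        )
    return calls


# ---------------------------------------------------------------------------
# PROSITE-dialect patterns
# ---------------------------------------------------------------------------


class PatternSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class PatternElement:
    kind: str  # 'fixed' | 'class' | 'wildcard'
    residues: frozenset[str] | None
    min_count: int
    max_count: int

    def render(self) -> str:
        if self.kind == "fixed":
            return next(iter(self.residues))
        if self.kind == "class":
            return "[" + "".join(sorted(self.residues)) + "]"
        if self.min_count == self.max_count:
            return "x" if self.min_count == 1 else f"x({self.min_count})"
        return f"x({self.min_count},{self.max_count})"


@dataclass(frozen=True)
class PrositePattern:
    elements: tuple[PatternElement, ...]

    @property
    def min_span(self) -> int:
        return sum(e.min_count for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_count for e in self.elements)

    def render(self) -> str:
        return "-".join(e.render() for e in self.elements)

    def to_regex(self) -> str:
        parts = []
        for e in self.elements:
            if e.kind == "fixed":
                parts.append(next(iter(e.residues)))
            elif e.kind == "class":
                parts.append("[" + "".join(sorted(e.residues)) + "]")
            elif e.min_count == e.max_count == 1:
                parts.append(".")
            elif e.min_count == e.max_count:
                parts.append(f".{{{e.min_count}}}")
            else:
                parts.append(f".{{{e.min_count},{e.max_count}}}")
        return "".join(parts)


_WILDCARD_RE = re.compile(r"^x(?:\((\d+)(?:,(\d+))?\))?$")


def parse_prosite(pattern: str) -> PrositePattern:
    """Parse the restricted PROSITE dialect into an element list.

    Errors name the offending element index so malformed patterns are easy
    to locate.
    """
    text = pattern.strip()
    if not text:
        raise PatternSyntaxError("empty pattern")
    if text.startswith("(") and text.endswith(")"):
        inner = text[1:-1]
        if inner.count("(") == inner.count(")"):  # a true wrapping pair
            text = inner
    if text.endswith("."):  # PROSITE terminator
        text = text[:-1]
    tokens = text.split("-")
    elements: list[PatternElement] = []
    for i, tok in enumerate(tokens):
        tok = tok.strip()
        if not tok:
            raise PatternSyntaxError(f"element {i}: empty token")
        m = _WILDCARD_RE.match(tok)
        if m:
            lo = int(m.group(1)) if m.group(1) else 1
            hi = int(m.group(2)) if m.group(2) else lo
            if lo > hi or lo < 0 or hi == 0:
                raise PatternSyntaxError(f"element {i}: bad wildcard range {tok!r}")
            elements.append(PatternElement("wildcard", None, lo, hi))
            continue
        if tok.startswith("[") and tok.endswith("]"):
            body = tok[1:-1]
            if not body:
                raise PatternSyntaxError(f"element {i}: empty residue class")
            bad = set(body) - _VALID_RESIDUES
            if bad:
                raise PatternSyntaxError(
                    f"element {i}: invalid residues {sorted(bad)!r} in class"
                )
            elements.append(PatternElement("class", frozenset(body), 1, 1))
            continue
        if "[" in tok or "]" in tok:
            raise PatternSyntaxError(f"element {i}: unbalanced brackets in {tok!r}")
        if len(tok) == 1 and tok in _VALID_RESIDUES:
            elements.append(PatternElement("fixed", frozenset(tok), 1, 1))
            continue
        raise PatternSyntaxError(f"element {i}: unsupported token {tok!r}")
    return PrositePattern(tuple(elements))


@dataclass(frozen=True)
class PatternMatch:
    sequence_id: str
    start: int
    end: int
    matched: str


def _match_here(seq: str, pos: int, elements: tuple[PatternElement, ...], idx: int) -> int | None:
    """Backtracking matcher; flexible wildcards try their longest count
    first, so the first success is the greedy (leftmost-longest) match — the
    same preference order as a greedy regular expression."""
    if idx == len(elements):
        return pos
    e = elements[idx]
    if e.kind == "wildcard":
        for cnt in range(e.max_count, e.min_count - 1, -1):
            if pos + cnt > len(seq):
                continue
            end = _match_here(seq, pos + cnt, elements, idx + 1)
            if end is not None:
                return end
        return None
    if pos >= len(seq):
        return None
    ch = seq[pos]
    if e.kind == "fixed":
        if ch not in e.residues:
            return None
    elif ch not in e.residues:
        return None
    return _match_here(seq, pos + 1, elements, idx + 1)


def scan_pattern(
    pattern: PrositePattern,
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
) -> list[PatternMatch]:
    """All matches at all start positions (overlaps included); per start the
    greedy leftmost-longest extension is reported."""
    items = proteins.items() if isinstance(proteins, Mapping) else proteins
    matches: list[PatternMatch] = []
    for sid, seq in items:
        for start in range(len(seq) + 1):
            end = _match_here(seq, start, pattern.elements, 0)
            if end is not None:
                matches.append(PatternMatch(sid, start, end, seq[start:end]))
    return matches


# ---------------------------------------------------------------------------
# similarity clustering of novel proteins
# ---------------------------------------------------------------------------


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    from Bio.Align import substitution_matrices

    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _pair_similarity(s1: str, s2: str) -> tuple[float, float]:
    """(identity over aligned columns, coverage of the shorter sequence)."""
    aligner = _protein_aligner()
    try:
        aln = aligner.align(s1, s2)[0]
    except IndexError:
        return 0.0, 0.0
    blocks1, blocks2 = aln.aligned
    if len(blocks1) == 0:
        return 0.0, 0.0
    matches = columns = 0
    prev1 = prev2 = None
    for (a1, b1), (a2, b2) in zip(blocks1, blocks2):
        if prev1 is not None:
            columns += (a1 - prev1) + (a2 - prev2)
        for c1, c2 in zip(s1[a1:b1], s2[a2:b2]):
            columns += 1
            if c1 == c2 and c1 != "X":
                matches += 1
        prev1, prev2 = b1, b2
    shorter = min(len(s1), len(s2))
    span_short = (
        blocks1[-1][1] - blocks1[0][0]
        if len(s1) <= len(s2)
        else blocks2[-1][1] - blocks2[0][0]
    )
    identity = matches / columns if columns else 0.0
    return identity, span_short / shorter if shorter else 0.0


def cluster_novel_proteins(
    proteins: Mapping[str, str],
    min_identity: float = 0.35,
    min_coverage: float = 0.6,
) -> list[list[str]]:
    """Single-linkage clusters from pairwise local alignment.

    Two proteins are linked when identity over the aligned columns reaches
    ``min_identity`` and the alignment covers at least ``min_coverage`` of
    the shorter sequence.  Returns all clusters sorted by size (descending)
    then by first member; clusters of size >= 2 are the putative families.
    """
    ids = sorted(proteins)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if find(a) == find(b):
                continue
            ident, cov = _pair_similarity(proteins[a], proteins[b])
            if ident >= min_identity and cov >= min_coverage:
                ra, rb = find(a), find(b)
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for x in ids:
        groups.setdefault(find(x), []).append(x)
    clusters = [sorted(v) for v in groups.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


def calls_to_frame(calls: list[SpecificityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.transcript_id, c.specificity_class, c.peptide_verified, c.candidate)
            for c in calls
        ],
        columns=["transcript_id", "class", "peptide_verified", "candidate"],
    )
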