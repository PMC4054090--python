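"""Independent reference implementations used only to check txomeval.

These deliberately take the dumbest correct path (per-position scanning,
brute-force enumeration, regex translation, Biopython translation) and never
share code with the package internals they verify.
"""

from __future__ import annotations

import re

from Bio.Data import CodonTable
from Bio.Seq import Seq

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON2AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON2AA[_stop] = "*"


def n50_oracle(lengths) -> int:
    """Largest distinct length L whose >=L transcripts hold half the bases."""
    total = sum(lengths)
    best = None
    for cand in sorted(set(lengths)):
        if 2 * sum(x for x in lengths if x >= cand) >= total:
            best = cand
    return best


def codon_to_aa(codon: str) -> str:
    if codon in _CODON2AA:
        return _CODON2AA[codon]
    return "X"  # any ambiguity-containing codon


def revcomp_oracle(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "R": "Y",
            "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K", "B": "V",
            "V": "B", "D": "H", "H": "D"}
    return "".join(comp[c] for c in reversed(seq))


def translate_oracle(seq: str) -> dict[int, str]:
    """Position-by-position six-frame translation."""
    out = {}
    rc = revcomp_oracle(seq)
    for frame in (1, 2, 3):
        for strand_seq, key in ((seq, frame), (rc, -frame)):
            aas = []
            pos = frame - 1
            while pos + 3 <= len(strand_seq):
                aas.append(codon_to_aa(strand_seq[pos : pos + 3]))
                pos += 3
            out[key] = "".join(aas)
    return out


def longest_orf_oracle(seq: str) -> int:
    """Longest stop-free stretch over all six frames, counted positionally."""
    best = 0
    for prot in translate_oracle(seq).values():
        run = 0
        for aa in prot:
            if aa == "*":
                run = 0
            else:
                run += 1
                best = max(best, run)
    return best


def bio_longest_orf(seq: str) -> int:
    """Fast Monte-Carlo variant built on Biopython translation."""
    best = 0
    for s in (seq, str(Seq(seq).reverse_complement())):
        for off in range(3):
            n = (len(s) - off) // 3 * 3
            if n <= 0:
                continue
            prot = str(Seq(s[off : off + n]).translate())
            best = max(best, max(len(chunk) for chunk in prot.split("*")))
    return best


def tryptic_oracle(protein: str) -> list[str]:
    """Regex-based tryptic digest: cleave after K/R not before P."""
    if not protein:
        return []
    return [p for p in re.split(r"(?<=[KR])(?!P)", protein) if p]


def prosite_regex_oracle(pattern_text: str) -> re.Pattern:
    """Mechanical token-by-token translation of the dialect to a regex."""
    text = pattern_text.strip()
    if text.startswith("(") and text.endswith(")"):
        inner = text[1:-1]
        if inner.count("(") == inner.count(")"):
            text = inner
    parts = []
    for tok in text.split("-"):
        m = re.fullmatch(r"x\((\d+)(?:,(\d+))?\)", tok)
        if m:
            lo = m.group(1)
            hi = m.group(2)
            parts.append(f".{{{lo},{hi}}}" if hi else f".{{{lo}}}")
        elif tok == "x":
            parts.append(".")
        elif tok.startswith("["):
            parts.append(tok)
        else:
            parts.append(re.escape(tok))
    return re.compile("".join(parts))


def regex_scan_oracle(pattern_text: str, seq: str) -> list[tuple[int, int]]:
    """All (start, end) matches at every start, greedy extension per start."""
    rx = prosite_regex_oracle(pattern_text)
    out = []
    for start in range(len(seq) + 1):
        m = rx.match(seq, start)
        if m:
            out.append((start, m.end()))
    return out
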