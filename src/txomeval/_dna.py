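"""Low-level nucleotide/protein helpers shared across the package.

Translation uses the standard genetic code (table 1). Any codon containing
an IUPAC ambiguity code is rendered as 'X'; stop codons are rendered as '*'.
This is deliberately stricter than resolving partially-ambiguous codons
(e.g. GCN) to an amino acid: downstream peptide matching treats 'X' as
matching nothing, so ambiguous positions can never support an identification.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
STOP = "*"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

# base -> digit; 4 marks any ambiguity code so that every codon touching an
# ambiguous base lands on an index whose table entry is 'X'.
_BASE5 = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE5[ord(_b)] = _i
    _BASE5[ord(_b.lower())] = _i

_STD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA125 = np.full(125, ord("X"), dtype=np.uint8)
for _codon, _aa in _STD_TABLE.forward_table.items():
    _a, _b, _c = (_BASE5[ord(ch)] for ch in _codon)
    _AA125[_a * 25 + _b * 5 + _c] = ord(_aa)
for _codon in _STD_TABLE.stop_codons:
    _a, _b, _c = (_BASE5[ord(ch)] for ch in _codon)
    _AA125[_a * 25 + _b * 5 + _c] = ord(STOP)


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the IUPAC DNA alphabet."""


def validate_dna(seq: str, context: str = "sequence") -> None:
    bad = set(seq.upper()) - IUPAC_DNA
    if bad:
        raise InvalidSequenceError(
            f"{context} contains non-IUPAC characters: {sorted(bad)!r}"
        )


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_offset(seq: str, offset: int) -> str:
    """Translate ``seq`` starting at ``offset`` until the last full codon."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[offset:]
    n = (len(arr) // 3) * 3
    if n == 0:
        return ""
    cod = arr[:n].reshape(-1, 3)
    b = _BASE5[cod]
    idx = b[:, 0].astype(np.int32) * 25 + b[:, 1] * 5 + b[:, 2]
    return _AA125[idx].tobytes().decode("ascii")


FRAMES = (1, 2, 3, -1, -2, -3)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six conceptual translations, keyed by frame +1..+3 / -1..-3.

    Negative frames read the reverse complement; frame -k of ``seq`` equals
    frame +k of ``revcomp(seq)``.
    """
    validate_dna(seq)
    up = seq.upper()
    rc = revcomp(up)
    out: dict[int, str] = {}
    for k in (1, 2, 3):
        out[k] = translate_offset(up, k - 1)
        out[-k] = translate_offset(rc, k - 1)
    return out
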