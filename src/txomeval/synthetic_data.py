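"""Ground-truth synthetic data emulating a de novo assembled transcriptome.

The generator produces the inputs every downstream stage consumes, with the
truth needed to score them:

* coding transcripts with a 5'UTR - ATG...stop ORF - 3'UTR layout,
* noncoding transcripts of random sequence at the configured composition,
* frameshifted transcripts: coding transcripts carrying one or more
  single-nucleotide indels inside the ORF (the minimal event that moves
  peptide evidence between reading frames),
* tryptic peptides sampled from the encoded proteins (cleavage after K/R,
  not before P), with peptides spanning a corrupted indel codon removed
  because the assembled transcript no longer encodes them,
* homology hit tables (12-column BLAST tabular plus a description column)
  whose e-value structure separates conserved / urodele-only / no-hit
  transcripts, and
* an orthologue table pair with planted reciprocal-best pairs and known
  alignment fractions.

Everything is deterministic for a fixed seed; independent operations draw
from independent seeded streams so adding peptides never reshuffles hit
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._dna import AA20, translate_offset
from .assembly_qc import Transcript

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
BLAST13_COLUMNS = BLAST_COLUMNS + ["description"]

CONSERVED, URODELE_ONLY, NO_HIT = "conserved", "urodele_only", "no_hit"
SPECIFICITY_CLASSES = (CONSERVED, URODELE_ONLY, NO_HIT)

LOW_QUALITY_KEYWORDS = ("mRNA", "cDNA", "clone", "genomic")

#: database name -> (is_protein_db, taxon); est_urodele is the urodele-only table
DATABASES = {
    "nr": (True, "metazoa"),
    "nt": (False, "metazoa"),
    "est_human": (False, "human"),
    "est_mouse": (False, "mouse"),
    "est_others": (False, "other"),
    "est_urodele": (False, "urodele"),
}
URODELE_DBS = frozenset({"est_urodele"})

_PROTEIN_NAMES = (
    "ATP synthase subunit beta", "collagen alpha-1 chain", "plectin",
    "myosin heavy chain", "elongation factor 1-alpha", "heat shock protein 70",
    "beta-actin", "tubulin alpha chain", "fibronectin", "vimentin",
    "serum albumin", "glyceraldehyde-3-phosphate dehydrogenase",
    "troponin C", "crystallin beta B1", "matrix metalloproteinase-9",
)


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    n_coding: int = 200
    n_noncoding: int = 100
    n_frameshifted: int = 50
    orf_length_range: tuple[int, int] = (60, 400)  # residues incl. initial Met
    utr_length_range: tuple[int, int] = (30, 300)  # nt, each UTR
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    peptide_min_len: int = 7
    peptide_max_len: int = 30
    peptide_sampling_rate: float = 0.5
    specificity_mix: tuple[float, float, float] = (0.7, 0.15, 0.15)
    indels_range: tuple[int, int] = (1, 3)
    indel_min_spacing: int = 90  # nt between indels and from ORF ends
    low_quality_keyword_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_coding", "n_noncoding", "n_frameshifted"):
            if getattr(self, name) < 0:
                raise SyntheticConfigError(f"{name} must be >= 0")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise SyntheticConfigError("base_composition must sum to 1")
        if any(p < 0 or p > 1 for p in self.base_composition):
            raise SyntheticConfigError("base_composition entries must be in [0,1]")
        for name in ("peptide_sampling_rate", "low_quality_keyword_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SyntheticConfigError(f"{name} must be in [0,1]")
        if abs(sum(self.specificity_mix) - 1.0) > 1e-9:
            raise SyntheticConfigError("specificity_mix must sum to 1")
        for rng_name in ("orf_length_range", "utr_length_range", "indels_range"):
            lo, hi = getattr(self, rng_name)
            if lo > hi or lo < 0:
                raise SyntheticConfigError(f"{rng_name} is empty or negative")
        if self.orf_length_range[0] < 2:
            raise SyntheticConfigError("ORFs need at least 2 residues (Met + 1)")
        if not (0 < self.peptide_min_len <= self.peptide_max_len):
            raise SyntheticConfigError("peptide length range is empty")
        if self.n_frameshifted > 0:
            k_max = self.indels_range[1]
            # indels live between the ATG and stop codons with `spacing` nt
            # of clearance, so the ORF must span (k+1) gaps plus those codons
            min_aa = -(-((k_max + 1) * self.indel_min_spacing) // 3) + 1
            if self.orf_length_range[1] < min_aa:
                raise SyntheticConfigError(
                    f"orf_length_range upper bound must be >= {min_aa} aa to "
                    f"place {k_max} indels with spacing {self.indel_min_spacing}"
                )


@dataclass(frozen=True)
class TruthRecord:
    transcript_id: str
    is_coding: bool
    orf_nt_interval: tuple[int, int] | None  # 0-based half-open, final coords
    frameshift_positions: tuple[int, ...]  # nt offsets in the final transcript
    frameshift_ops: tuple[int, ...]  # +1 insertion, -1 deletion, per position
    frameshift_codons: tuple[int, ...]  # corrupted codon index in source protein
    specificity_class: str
    source_protein: str | None

    def __post_init__(self) -> None:
        if self.frameshift_positions and not self.is_coding:
            raise ValueError("frameshifted transcripts must be coding")
        if len(self.frameshift_positions) != len(self.frameshift_ops):
            raise ValueError("frameshift positions/ops length mismatch")


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")


def _random_dna(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    if n == 0:
        return ""
    idx = rng.choice(4, size=n, p=p)
    return "".join(_BASES[i] for i in idx)


def _codon_pools(p: np.ndarray) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Non-stop codons with composition-derived weights, plus stop weights."""
    codons, weights = [], []
    lut = {b: i for i, b in enumerate(_BASES)}
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                cod = a + b + c
                if cod in _STOPS:
                    continue
                codons.append(cod)
                weights.append(p[lut[a]] * p[lut[b]] * p[lut[c]])
    w = np.array(weights)
    stop_w = np.array([p[lut[s[0]]] * p[lut[s[1]]] * p[lut[s[2]]] for s in _STOPS])
    return codons, w / w.sum(), stop_w / stop_w.sum()


def _spaced_positions(
    rng: np.random.Generator, region_len: int, k: int, spacing: int
) -> list[int]:
    """k positions in [0, region_len) with pairwise and boundary gaps >= spacing."""
    slack = region_len - (k + 1) * spacing
    if slack < 0:
        raise SyntheticConfigError("cannot place indels with requested spacing")
    extras = np.sort(rng.integers(0, slack + 1, size=k))
    return [spacing * (i + 1) + int(extras[i]) for i in range(k)]


def generate_transcriptome(
    config: SyntheticConfig,
) -> tuple[list[Transcript], list[TruthRecord]]:
    """Build the synthetic transcript pool and its truth table.

    Coding transcripts carry an ATG-initiated, stop-terminated ORF flanked by
    UTRs; with an ORF of ``n`` residues and UTRs of ``u5``/``u3`` nt the
    transcript is ``u5 + 3*(n+1) + u3`` nt long (stop codon included).
    Frameshifted transcripts additionally carry single-nucleotide indels at
    recorded offsets inside the ORF.
    """
    rng = np.random.default_rng([config.seed, 0])
    p = np.asarray(config.base_composition, dtype=float)
    p = p / p.sum()
    codons, codon_w, stop_w = _codon_pools(p)

    n_total = config.n_coding + config.n_frameshifted + config.n_noncoding
    spec_classes = _assign_specificity(rng, n_total, config.specificity_mix)

    transcripts: list[Transcript] = []
    truths: list[TruthRecord] = []
    olo, ohi = config.orf_length_range
    ulo, uhi = config.utr_length_range

    def _orf_parts(orf_aa: int) -> tuple[str, str, str, str]:
        utr5 = _random_dna(rng, int(rng.integers(ulo, uhi + 1)), p)
        utr3 = _random_dna(rng, int(rng.integers(ulo, uhi + 1)), p)
        body_idx = rng.choice(len(codons), size=orf_aa - 1, p=codon_w)
        orf_nt = "ATG" + "".join(codons[i] for i in body_idx)
        stop = _STOPS[int(rng.choice(3, p=stop_w))]
        return utr5, orf_nt, stop, utr3

    idx = 0
    for _ in range(config.n_coding):
        orf_aa = int(rng.integers(olo, ohi + 1))
        utr5, orf_nt, stop, utr3 = _orf_parts(orf_aa)
        tid = f"t{idx:06d}"
        transcripts.append(Transcript(tid, utr5 + orf_nt + stop + utr3, True))
        truths.append(
            TruthRecord(
                tid, True,
                (len(utr5), len(utr5) + len(orf_nt) + 3),
                (), (), (), spec_classes[idx],
                translate_offset(orf_nt, 0),
            )
        )
        idx += 1

    klo, khi = config.indels_range
    spacing = config.indel_min_spacing
    for _ in range(config.n_frameshifted):
        k = int(rng.integers(klo, khi + 1))
        min_aa = -(-((k + 1) * spacing) // 3) + 1  # ceil, keep stop intact
        orf_aa = int(rng.integers(max(olo, min_aa), max(ohi, min_aa) + 1))
        utr5, orf_nt, stop, utr3 = _orf_parts(orf_aa)
        # indel offsets within the codable region, avoiding the ATG codon
        region = len(orf_nt) - 3
        offsets = _spaced_positions(rng, region, k, spacing)
        offsets = [o + 3 for o in offsets]  # skip ATG
        ops = [1 if rng.random() < 0.5 else -1 for _ in range(k)]
        mutated = orf_nt
        shift = 0
        final_positions: list[int] = []
        codon_breaks: list[int] = []
        for o, op in zip(offsets, ops):
            pos = o + shift  # position in the mutated ORF
            if op == 1:
                ins = _BASES[int(rng.choice(4, p=p))]
                mutated = mutated[:pos] + ins + mutated[pos:]
                shift += 1
            else:
                mutated = mutated[:pos] + mutated[pos + 1 :]
                shift -= 1
            final_positions.append(len(utr5) + pos)
            codon_breaks.append(o // 3)
        tid = f"t{idx:06d}"
        transcripts.append(Transcript(tid, utr5 + mutated + stop + utr3, True))
        truths.append(
            TruthRecord(
                tid, True,
                (len(utr5), len(utr5) + len(mutated) + 3),
                tuple(final_positions), tuple(ops), tuple(codon_breaks),
                spec_classes[idx],
                translate_offset(orf_nt, 0),
            )
        )
        idx += 1

    min_len = 2 * ulo + 3 * (olo + 1)
    max_len = 2 * uhi + 3 * (ohi + 1)
    for _ in range(config.n_noncoding):
        L = int(rng.integers(min_len, max_len + 1))
        tid = f"t{idx:06d}"
        transcripts.append(Transcript(tid, _random_dna(rng, L, p), False))
        truths.append(
            TruthRecord(tid, False, None, (), (), (), spec_classes[idx], None)
        )
        idx += 1

    return transcripts, truths


def _assign_specificity(
    rng: np.random.Generator, n: int, mix: tuple[float, float, float]
) -> list[str]:
    """Largest-remainder apportionment of classes, then a seeded shuffle."""
    raw = [m * n for m in mix]
    counts = [int(x) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([-(x - int(x)) for x in raw])
    for i in range(rem):
        counts[order[i]] += 1
    labels = [c for c, k in zip(SPECIFICITY_CLASSES, counts) for _ in range(k)]
    perm = rng.permutation(n)
    return [labels[i] for i in perm]


# ---------------------------------------------------------------------------
# tryptic digestion
# ---------------------------------------------------------------------------


def cleave_tryptic(protein: str) -> list[tuple[int, int, str]]:
    """Tryptic fragments as (aa_start, aa_end, peptide): cleave after K or R
    except when the next residue is P.  An empty protein yields no peptides.
    """
    peptides: list[tuple[int, int, str]] = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR" and (i + 1 == len(protein) or protein[i + 1] != "P"):
            peptides.append((start, i + 1, protein[start : i + 1]))
            start = i + 1
    if start < len(protein):
        peptides.append((start, len(protein), protein[start:]))
    return peptides


def _segments(protein_len: int, codon_breaks: Sequence[int]) -> list[tuple[int, int]]:
    """Intact residue intervals between corrupted indel codons."""
    segs = []
    prev = 0
    for b in sorted(codon_breaks):
        if b > prev:
            segs.append((prev, b))
        prev = b + 1
    if prev < protein_len:
        segs.append((prev, protein_len))
    return segs


def digest_and_sample_peptides(
    truths: Iterable[TruthRecord], config: SyntheticConfig
) -> pd.DataFrame:
    """In-silico tryptic digest of every source protein, length-filtered and
    thinned to the configured sampling rate.

    Returns one row per surviving (length-filtered, non-indel-spanning)
    peptide with columns ``peptide``, ``transcript_id``, ``segment`` (index of
    the inter-indel segment the peptide lies in; 0 when no indels) and
    ``observed`` (seeded Bernoulli(``peptide_sampling_rate``)).  The table
    handed to the pipeline is the ``observed`` subset; the rest is truth
    bookkeeping.
    """
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for tr in truths:
        if not tr.is_coding or not tr.source_protein:
            continue
        segs = _segments(len(tr.source_protein), tr.frameshift_codons)
        for aa_s, aa_e, pep in cleave_tryptic(tr.source_protein):
            if not (config.peptide_min_len <= len(pep) <= config.peptide_max_len):
                continue
            seg_idx = next(
                (i for i, (s, e) in enumerate(segs) if s <= aa_s and aa_e <= e),
                None,
            )
            if seg_idx is None:  # spans a corrupted codon: not encoded any more
                continue
            rows.append((pep, tr.transcript_id, seg_idx))
    df = pd.DataFrame(rows, columns=["peptide", "transcript_id", "segment"])
    df["observed"] = rng.random(len(df)) < config.peptide_sampling_rate
    return df


def observed_peptides(table: pd.DataFrame) -> pd.DataFrame:
    """The columns handed to the pipeline: observed peptides and a label."""
    sub = table.loc[table["observed"], ["peptide", "transcript_id"]]
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# homology hit tables
# ---------------------------------------------------------------------------


def _evalue(rng: np.random.Generator, log10_lo: float, log10_hi: float) -> float:
    """e-value with log10 uniform on [log10_lo, log10_hi]."""
    return float(10.0 ** rng.uniform(log10_lo, log10_hi))


def _description(rng: np.random.Generator, keyword_fraction: float) -> str:
    name = _PROTEIN_NAMES[int(rng.integers(len(_PROTEIN_NAMES)))]
    if rng.random() < keyword_fraction:
        kw = LOW_QUALITY_KEYWORDS[int(rng.integers(len(LOW_QUALITY_KEYWORDS)))]
        return f"{name}, {kw} sequence"
    return name


def _hit_row(
    rng: np.random.Generator,
    qid: str,
    sid: str,
    qlen: int,
    evalue: float,
    description: str,
) -> list:
    alen = int(rng.integers(max(30, qlen // 4), max(31, qlen + 1)))
    pident = float(np.round(rng.uniform(40, 99.9), 1))
    mism = int(alen * (100 - pident) / 100)
    qstart = int(rng.integers(1, max(2, qlen - alen + 2)))
    bits = float(np.round(max(30.0, -10.0 * np.log10(evalue) + rng.uniform(0, 40)), 1))
    return [qid, sid, pident, alen, mism, 0, qstart, qstart + alen - 1,
            1, alen, evalue, bits, description]


def generate_hit_tables(
    truths: Iterable[TruthRecord], config: SyntheticConfig
) -> tuple[dict[str, pd.DataFrame], dict[str, list[str]]]:
    """Per-database BLAST-tabular hit tables plus a GO map.

    Conserved transcripts always receive at least one protein-database hit
    with e-value <= 1e-20 (and may pick up weaker nucleotide/EST hits);
    urodele-only transcripts receive hits exclusively in the urodele EST
    table at e-values <= 1e-16; no-hit transcripts receive nothing.  A
    configured fraction of description lines carries a low-quality keyword.
    GO terms are attached to most conserved protein-database subjects.
    """
    rng = np.random.default_rng([config.seed, 2])
    tables: dict[str, list[list]] = {db: [] for db in DATABASES}
    go_map: dict[str, list[str]] = {}
    kf = config.low_quality_keyword_fraction
    for tr in truths:
        qlen = 600  # nominal query length for plausible coordinates
        if tr.specificity_class == CONSERVED:
            sid = f"sp|P{rng.integers(10000, 99999)}|{tr.transcript_id.upper()}"
            ev = _evalue(rng, -80.0, -21.0)
            tables["nr"].append(
                _hit_row(rng, tr.transcript_id, sid, qlen, ev, _description(rng, kf))
            )
            if rng.random() < 0.8:
                go_map[sid] = [f"GO:{int(rng.integers(1000000, 9999999)):07d}"]
            n_extra = int(rng.integers(0, 3))
            for _ in range(n_extra):
                db = ("nt", "est_human", "est_mouse", "est_others")[
                    int(rng.integers(4))
                ]
                tables[db].append(
                    _hit_row(
                        rng, tr.transcript_id,
                        f"gb|X{rng.integers(10000, 99999)}",
                        qlen, _evalue(rng, -40.0, -8.0), _description(rng, kf),
                    )
                )
        elif tr.specificity_class == URODELE_ONLY:
            n = int(rng.integers(1, 3))
            for _ in range(n):
                tables["est_urodele"].append(
                    _hit_row(
                        rng, tr.transcript_id,
                        f"est|U{rng.integers(10000, 99999)}",
                        qlen, _evalue(rng, -60.0, -16.0), _description(rng, kf),
                    )
                )
        # NO_HIT: nothing
    out = {
        db: pd.DataFrame(rows, columns=BLAST13_COLUMNS)
        for db, rows in tables.items()
    }
    return out, go_map


# ---------------------------------------------------------------------------
# orthologue tables
# ---------------------------------------------------------------------------


def generate_ortholog_tables(
    truths: Iterable[TruthRecord], config: SyntheticConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Planted reciprocal-best orthologue evidence with known fractions.

    Returns ``(query_hits, subject_hits, subject_lengths, truth)``: the two
    BLAST-tabular tables (transcript->orthologue and orthologue->transcript),
    the orthologue protein lengths, and the planted truth with the alignment
    fraction of each pair.  Conserved coding transcripts receive a mutual
    best hit; half of them also receive a weaker cross hit to a different
    orthologue, which reciprocal-best filtering must discard.
    """
    rng = np.random.default_rng([config.seed, 3])
    conserved = [
        tr for tr in truths
        if tr.is_coding and tr.specificity_class == CONSERVED and tr.source_protein
    ]
    q_rows, s_rows, len_rows, truth_rows = [], [], [], []
    sids = [f"ORTH_{tr.transcript_id}" for tr in conserved]
    for tr, sid in zip(conserved, sids):
        plen = len(tr.source_protein)
        slen = max(30, int(plen * rng.uniform(0.9, 1.2)))
        frac = float(rng.uniform(0.5, 1.05))
        alen = max(1, int(round(frac * slen)))
        ev = _evalue(rng, -120.0, -30.0)
        bits = float(np.round(-10 * np.log10(ev) + 60, 1))
        desc = "orthologue reference protein"
        q_rows.append([tr.transcript_id, sid, 90.0, alen, 2, 0,
                       1, alen, 1, min(alen, slen), ev, bits, desc])
        s_rows.append([sid, tr.transcript_id, 90.0, alen, 2, 0,
                       1, min(alen, slen), 1, alen, ev, bits, desc])
        len_rows.append([sid, slen])
        truth_rows.append([tr.transcript_id, sid, slen, alen,
                           alen / slen, alen / slen > 0.75])
    # weaker cross hits between consecutive pairs (never mutual best)
    for i in range(0, len(conserved) - 1, 2):
        tr, other_sid = conserved[i], sids[i + 1]
        ev = _evalue(rng, -20.0, -10.0)
        q_rows.append([tr.transcript_id, other_sid, 55.0, 50, 20, 1,
                       1, 50, 1, 50, ev, 45.0, "weak cross hit"])
        s_rows.append([other_sid, tr.transcript_id, 55.0, 50, 20, 1,
                       1, 50, 1, 50, ev, 45.0, "weak cross hit"])
    query_hits = pd.DataFrame(q_rows, columns=BLAST13_COLUMNS)
    subject_hits = pd.DataFrame(s_rows, columns=BLAST13_COLUMNS)
    subject_lengths = pd.DataFrame(len_rows, columns=["subject_id", "length"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["query_id", "subject_id", "subject_length", "align_length",
                 "align_fraction", "full_length"],
    )
    return query_hits, subject_hits, subject_lengths, truth
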