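"""Local similarity search with bit-score / E-value statistics.

Optimal Smith-Waterman local alignment is delegated to
:func:`skbio.alignment.pair_align`; this module adds six-frame
translation, Karlin-Altschul normalization (bit score, E-value), a
shared k-mer candidate prefilter, and database search over ordered
target collections.

Gap convention: a gap of length *k* costs ``open + extend * k`` (the
NCBI convention, so the standard published (lambda, K) pairs apply).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Data import CodonTable
from skbio.alignment import pair_align

_LN2 = math.log(2.0)

# standard genetic code; stop -> '*', any codon containing N -> 'X'
_CODON = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
for _stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
    _CODON[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NUCLEOTIDES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_frame(seq: str, offset: int) -> str:
    """Translate one forward frame (offset 0..2) of an A/C/G/T/N string."""
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else _CODON[codon])
    return "".join(out)


def translate_six_frames(seq: str) -> dict[int, str]:
    """All six translations, keyed by frame +1..+3 / -1..-3.

    Frames -1..-3 translate the reverse complement.  Illegal characters
    raise a ``ValueError`` naming the offending position.
    """
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in NUCLEOTIDES:
            raise ValueError(f"illegal nucleotide {ch!r} at position {pos}")
    rc = reverse_complement(seq)
    frames = {}
    for off in range(3):
        frames[off + 1] = translate_frame(seq, off)
        frames[-(off + 1)] = translate_frame(rc, off)
    return frames


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores, affine gap costs and Karlin-Altschul constants."""

    name: str
    mode: str  # 'protein' | 'nucleotide'
    sub_score: object  # matrix name for skbio, or (match, mismatch)
    gap_open: float
    gap_extend: float
    lam: float  # Karlin-Altschul lambda
    k: float  # Karlin-Altschul K

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.k)) / _LN2

    def raw_for_bits(self, bits: float) -> float:
        return (bits * _LN2 + math.log(self.k)) / self.lam

    def e_value(self, raw: float, m: int, n: int) -> float:
        # search space m*n; for a database search n is the total database length
        return self.k * m * n * math.exp(-self.lam * raw)


#: gapped BLOSUM62 with existence 11 / extension 1 (published constants)
PROTEIN_BLOSUM62 = ScoringScheme(
    name="blosum62-11-1", mode="protein", sub_score="BLOSUM62",
    gap_open=11.0, gap_extend=1.0, lam=0.267, k=0.041,
)

#: +1/-2 nucleotide scheme with gap existence 5 / extension 2
NUCLEOTIDE_1_2 = ScoringScheme(
    name="nt+1-2-5-2", mode="nucleotide", sub_score=(1.0, -2.0),
    gap_open=5.0, gap_extend=2.0, lam=1.28, k=0.46,
)


@dataclass
class AlignmentHit:
    """Best scored local alignment of a query against a named target."""

    query_id: str
    target_id: str
    database_name: str
    raw_score: float
    bit_score: float
    e_value: float
    query_span: tuple[int, int]  # 0-based half-open, on the aligned unit
    target_span: tuple[int, int]
    frame: int  # -3..-1, 1..3 translated; 0 nucleotide
    strand: str  # '+' or '-'


def local_align_score(query: str, target: str, scheme: ScoringScheme) -> float:
    """Optimal local alignment score (no traceback)."""
    if not query or not target:
        raise ValueError("empty sequence in local alignment")
    res = pair_align(query, target, mode="local", sub_score=scheme.sub_score,
                     gap_cost=(scheme.gap_open, scheme.gap_extend), max_paths=0)
    return float(res.score)


def local_align(query: str, target: str, scheme: ScoringScheme,
                query_id: str = "query", target_id: str = "target",
                database_name: str = "", db_length: int | None = None,
                frame: int = 0, strand: str = "+") -> AlignmentHit:
    """Optimal local alignment with spans and Karlin-Altschul statistics.

    ``db_length`` overrides the target length in the E-value search
    space (set it to the summed length of a database).
    """
    if not query or not target:
        raise ValueError("empty sequence in local alignment")
    res = pair_align(query, target, mode="local", sub_score=scheme.sub_score,
                     gap_cost=(scheme.gap_open, scheme.gap_extend), max_paths=1)
    raw = float(res.score)
    if res.paths:
        rng = res.paths[0].ranges
        qspan = (int(rng[0][0]), int(rng[0][1]))
        tspan = (int(rng[1][0]), int(rng[1][1]))
    else:  # empty local alignment
        qspan = (0, 0)
        tspan = (0, 0)
    n = db_length if db_length is not None else len(target)
    return AlignmentHit(
        query_id=query_id, target_id=target_id, database_name=database_name,
        raw_score=raw, bit_score=scheme.bit_score(raw),
        e_value=scheme.e_value(raw, len(query), n),
        query_span=qspan, target_span=tspan, frame=frame, strand=strand,
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class KmerPrefilter:
    """Shared exact k-mer candidate filter over a target collection.

    A local alignment strong enough to pass the pipeline thresholds is
    overwhelmingly likely to contain a run of >= k identities (defaults:
    k=5 peptide, k=11 nucleotide libraries, k=13 genome scaffolds), so
    targets sharing no k-mer with the query are skipped before dynamic
    programming.  Pass ``k=None`` to disable filtering (exhaustive
    mode, used by the oracle tests).
    """

    def __init__(self, targets: dict[str, str], k: int | None):
        self.k = k
        self.targets = targets
        self._sets = ({tid: _kmers(s, k) for tid, s in targets.items()}
                      if k else None)

    def candidates(self, query: str) -> list[str]:
        if self.k is None:
            return list(self.targets)
        qk = _kmers(query, self.k)
        return [tid for tid, tk in self._sets.items() if not qk.isdisjoint(tk)]

    def ranked(self, query: str) -> list[str]:
        """Candidates ordered by shared k-mer count (descending), so a
        search that short-circuits on the first passing hit aligns the
        most promising target first."""
        if self.k is None:
            return list(self.targets)
        qk = _kmers(query, self.k)
        scored = [(len(qk & tk), tid) for tid, tk in self._sets.items()
                  if not qk.isdisjoint(tk)]
        scored.sort(key=lambda x: -x[0])
        return [tid for _, tid in scored]


def search_protein_db(query_id: str, transcript: str, db_name: str,
                      db: dict[str, str], scheme: ScoringScheme = PROTEIN_BLOSUM62,
                      prefilter: KmerPrefilter | None = None,
                      kmer: int | None = 5) -> AlignmentHit | None:
    """Best translated (six-frame) hit of a transcript against a peptide DB.

    Returns the hit with maximal bit score (ties: minimal E-value, then
    first target in database order), or ``None`` for an empty database.
    Stops inside a frame translate to '*' and score as mismatches.
    """
    if not db:
        return None
    if prefilter is None:
        prefilter = KmerPrefilter(db, kmer)
    frames = translate_six_frames(transcript)
    db_len = sum(len(s) for s in db.values())
    order = {tid: i for i, tid in enumerate(db)}
    best = None
    best_key = None
    for frame, pep in frames.items():
        if len(pep) < 1:
            continue
        for tid in prefilter.candidates(pep):
            raw = local_align_score(pep, db[tid], scheme)
            key = (-raw, order[tid], abs(frame), frame < 0)
            if best_key is None or key < best_key:
                best_key = key
                best = (frame, tid, pep)
    if best is None:
        return None
    frame, tid, pep = best
    hit = local_align(pep, db[tid], scheme, query_id=query_id, target_id=tid,
                      database_name=db_name, db_length=db_len, frame=frame,
                      strand="+" if frame > 0 else "-")
    return hit


def search_nucleotide_db(query_id: str, query: str, db_name: str,
                         db: dict[str, str],
                         scheme: ScoringScheme = NUCLEOTIDE_1_2,
                         prefilter_fwd: KmerPrefilter | None = None,
                         kmer: int | None = 11) -> AlignmentHit | None:
    """Best nucleotide hit of a query against a sequence collection.

    Both query strands are searched; frame is 0.
    """
    if not db:
        return None
    if prefilter_fwd is None:
        prefilter_fwd = KmerPrefilter(db, kmer)
    db_len = sum(len(s) for s in db.values())
    order = {tid: i for i, tid in enumerate(db)}
    best = None
    best_key = None
    for strand, q in (("+", query.upper()), ("-", reverse_complement(query.upper()))):
        for tid in prefilter_fwd.candidates(q):
            raw = local_align_score(q, db[tid], scheme)
            key = (-raw, order[tid], strand == "-")
            if best_key is None or key < best_key:
                best_key = key
                best = (strand, tid, q)
    if best is None:
        return None
    strand, tid, q = best
    return local_align(q, db[tid], scheme, query_id=query_id, target_id=tid,
                       database_name=db_name, db_length=db_len, frame=0,
                       strand=strand)
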