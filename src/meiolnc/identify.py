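"""Sequential identification cascade and identifier-based collapsing.

Transcripts are queried against an ordered list of peptide databases;
the first database yielding a hit with bit score >= 90 and E-value
< 1e-6 assigns the transcript's identity.  Transcripts failing every
database are cataloged as 'unidentified' and feed the downstream
lncRNA classification.  Identified transcripts sharing the same
(database, identifier) pair are collapsed to a single gene by summing
their per-sample read counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from meiolnc.align import (AlignmentHit, KmerPrefilter, PROTEIN_BLOSUM62,
                           search_protein_db)

BIT_THRESHOLD = 90.0
E_THRESHOLD = 1e-6


@dataclass
class IdentityAssignment:
    transcript_id: str
    status: str  # 'identified' | 'unidentified'
    identifier: str | None
    source_db: str | None
    best_hit: AlignmentHit | None  # best hit seen anywhere (may be sub-threshold)

    def __post_init__(self) -> None:
        ok = self.identifier is not None and self.source_db is not None
        if (self.status == "identified") != ok:
            raise ValueError("identified status requires identifier and source_db")


def hit_is_significant(hit: AlignmentHit | None,
                       bit_threshold: float = BIT_THRESHOLD,
                       e_threshold: float = E_THRESHOLD) -> bool:
    return (hit is not None and hit.bit_score >= bit_threshold
            and hit.e_value < e_threshold)


def identify_transcripts(transcripts: dict[str, str],
                         databases: list[tuple[str, dict[str, str]]],
                         bit_threshold: float = BIT_THRESHOLD,
                         e_threshold: float = E_THRESHOLD,
                         kmer: int | None = 5) -> dict[str, IdentityAssignment]:
    """Run the ordered identification cascade.

    ``databases`` is a precedence-ordered list of ``(name, {id: peptide})``.
    Later databases are only consulted for transcripts the earlier ones
    failed to identify.  The best sub-threshold hit seen across all
    databases is retained (it feeds the CPC-like discriminant).
    """
    if not databases:
        raise ValueError("empty database list")
    prefilters = {name: KmerPrefilter(db, kmer) for name, db in databases}
    out: dict[str, IdentityAssignment] = {}
    for tid, seq in transcripts.items():
        best_any: AlignmentHit | None = None
        assigned = None
        for name, db in databases:
            hit = search_protein_db(tid, seq, name, db,
                                    scheme=PROTEIN_BLOSUM62,
                                    prefilter=prefilters[name])
            if hit is not None and (best_any is None
                                    or hit.bit_score > best_any.bit_score):
                best_any = hit
            if hit_is_significant(hit, bit_threshold, e_threshold):
                assigned = (name, hit)
                break
        if assigned is not None:
            name, hit = assigned
            out[tid] = IdentityAssignment(tid, "identified", hit.target_id,
                                          name, hit)
        else:
            out[tid] = IdentityAssignment(tid, "unidentified", None, None,
                                          best_any)
    return out


def assignments_frame(assignments: dict[str, IdentityAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments.values():
        h = a.best_hit
        rows.append({
            "transcript_id": a.transcript_id, "status": a.status,
            "identifier": a.identifier, "source_db": a.source_db,
            "best_bit": h.bit_score if h else 0.0,
            "best_evalue": h.e_value if h else float("inf"),
            "best_frame": h.frame if h else 0,
        })
    return pd.DataFrame(rows).set_index("transcript_id")


def collapse_by_identifier(assignments: dict[str, IdentityAssignment],
                           counts: pd.DataFrame,
                           lengths: dict[str, int] | None = None,
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """Merge transcripts sharing (source_db, identifier) into single genes.

    Per-sample counts are summed; the representative transcript is the
    longest member.  Unidentified transcripts never merge.  Returns the
    collapsed count matrix (indexed by gene id) and a Series mapping
    each transcript to its gene.
    """
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate transcript id {dup!r} in count matrix")
    if lengths is None:
        lengths = {}
    gene_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for tid in counts.index:
        a = assignments.get(tid)
        if a is not None and a.status == "identified":
            gid = f"{a.source_db}:{a.identifier}"
        else:
            gid = tid  # unidentified transcripts never merge
        gene_of[tid] = gid
        members.setdefault(gid, []).append(tid)
    representatives = {gid: max(ms, key=lambda t: (lengths.get(t, 0), t))
                       for gid, ms in members.items()}
    mapping = pd.Series(gene_of, name="gene_id")
    collapsed = counts.groupby(mapping.reindex(counts.index)).sum()
    collapsed.index.name = "gene_id"
    collapsed.attrs["representatives"] = representatives
    return collapsed, mapping
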