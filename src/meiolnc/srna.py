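"""Small-RNA population processing and best-stratum mapping.

Reads of 20-25 nt are collapsed to unique sequences with
multiplicities, profiled (length redundancy, 5'-nucleotide bias) and
mapped against a mixed reference (genome scaffolds plus transcripts) on
both strands allowing at most one mismatch.  Only the minimal-mismatch
stratum is reported, with all co-best hits kept - the behavior of a
``-v 1 --best --strata -a`` short-read search.  A gene acquires "sRNA
similarity" only when a best-stratum hit lies on the transcript itself;
a read whose best hits are all genomic confers nothing, which avoids
crediting intergenic matches to genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from meiolnc.align import reverse_complement

LENGTH_MIN = 20
LENGTH_MAX = 25
SEED_K = 10  # half-read seed; lossless for <=1 mismatch at read length >= 20


# ---------------------------------------------------------------------------
# Read filtering and profiles

def filter_reads(reads: pd.DataFrame, length_min: int = LENGTH_MIN,
                 length_max: int = LENGTH_MAX) -> pd.DataFrame:
    """Keep reads in the length window, collapsing identical sequences.

    ``reads`` needs columns ``sequence`` and optionally ``multiplicity``
    (default 1) and ``genotype``.  Identical sequences (within genotype
    when present) merge into one record whose multiplicity is the sum.
    """
    df = reads.copy()
    if "multiplicity" not in df:
        df["multiplicity"] = 1
    df["sequence"] = df["sequence"].str.upper()
    df["length"] = df["sequence"].str.len()
    df = df[(df["length"] >= length_min) & (df["length"] <= length_max)]
    keys = ["sequence"] + (["genotype"] if "genotype" in df else [])
    out = (df.groupby(keys, as_index=False)
             .agg(multiplicity=("multiplicity", "sum")))
    out["length"] = out["sequence"].str.len()
    return out


def redundancy_profile(reads: pd.DataFrame) -> pd.DataFrame:
    """Per-length counts of unique (multiplicity 1) vs redundant reads.

    Redundant sequences contribute their full multiplicity, mirroring
    the 'found more than once' framing of read-length histograms.
    """
    df = filter_reads(reads) if "length" not in reads else reads
    rows = []
    for length, grp in df.groupby("length"):
        uniq = grp.loc[grp["multiplicity"] == 1, "multiplicity"].sum()
        red = grp.loc[grp["multiplicity"] > 1, "multiplicity"].sum()
        rows.append({"length": int(length), "unique": int(uniq),
                     "redundant": int(red)})
    return pd.DataFrame(rows).set_index("length").sort_index()


def five_prime_bias(reads: pd.DataFrame, length: int | None = None
                    ) -> pd.Series:
    """Multiplicity-weighted fraction of reads starting with each base."""
    df = reads if "multiplicity" in reads else reads.assign(multiplicity=1)
    if length is not None:
        df = df[df["sequence"].str.len() == length]
    if df.empty:
        raise ValueError("no reads at the requested length")
    first = df["sequence"].str[0]
    weights = df["multiplicity"].astype(float)
    total = weights.sum()
    return pd.Series({b: float(weights[first == b].sum()) / total
                      for b in "ACGT"}, name="five_prime_fraction")


# ---------------------------------------------------------------------------
# Best-stratum mapping

@dataclass(frozen=True)
class SRnaHit:
    target_id: str
    target_kind: str  # 'genome' | 'transcript'
    position: int  # 0-based on the target's '+' sequence
    strand: str
    mismatches: int


class MixedReference:
    """Seed index over genome scaffolds and transcripts for 0/1-mismatch search.

    Indexes every ``SEED_K``-mer of the reference.  For a read of
    length L >= 2k, the first and last k-mers are disjoint, so any
    alignment with <= 1 mismatch leaves at least one of them exact:
    looking both seeds up is lossless for the 1-mismatch stratum.
    """

    def __init__(self, genome: dict[str, str], transcripts: dict[str, str]):
        if not genome and not transcripts:
            raise ValueError("empty mixed reference")
        self.targets: dict[str, tuple[str, str]] = {}
        for tid, seq in genome.items():
            self.targets[tid] = ("genome", seq.upper())
        for tid, seq in transcripts.items():
            if tid in self.targets:
                raise ValueError(f"duplicate reference id {tid!r}")
            self.targets[tid] = ("transcript", seq.upper())
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, (_, seq) in self.targets.items():
            for i in range(len(seq) - SEED_K + 1):
                self._index.setdefault(seq[i:i + SEED_K], []).append((tid, i))

    def _candidates(self, read: str):
        L = len(read)
        seen = set()
        for qoff in (0, L - SEED_K):
            for tid, pos in self._index.get(read[qoff:qoff + SEED_K], ()):
                start = pos - qoff
                if start >= 0 and (tid, start) not in seen:
                    seen.add((tid, start))
                    yield tid, start

    def map_read(self, read: str, max_mismatches: int = 1) -> list[SRnaHit]:
        """All best-stratum hits of one read on both strands."""
        read = read.upper()
        best = max_mismatches + 1
        hits: list[tuple[int, SRnaHit]] = []
        for strand, q in (("+", read), ("-", reverse_complement(read))):
            for tid, start in self._candidates(q):
                kind, seq = self.targets[tid]
                window = seq[start:start + len(q)]
                if len(window) < len(q):
                    continue
                mm = sum(a != b for a, b in zip(q, window))
                if mm <= max_mismatches:
                    hits.append((mm, SRnaHit(tid, kind, start, strand, mm)))
                    best = min(best, mm)
        return sorted((h for mm, h in hits if mm == best),
                      key=lambda h: (h.target_id, h.position, h.strand))


def map_srna(reads: pd.DataFrame, reference: MixedReference,
             max_mismatches: int = 1) -> pd.DataFrame:
    """Map collapsed reads; one output row per best-stratum alignment.

    Output columns: read index (``read``), sequence, multiplicity,
    length, genotype (when present), target_id, target_kind, position,
    strand, mismatches.
    """
    rows = []
    for idx, row in reads.iterrows():
        for hit in reference.map_read(row["sequence"], max_mismatches):
            rec = {"read": idx, "sequence": row["sequence"],
                   "length": len(row["sequence"]),
                   "multiplicity": row.get("multiplicity", 1),
                   "target_id": hit.target_id, "target_kind": hit.target_kind,
                   "position": hit.position, "strand": hit.strand,
                   "mismatches": hit.mismatches}
            if "genotype" in row:
                rec["genotype"] = row["genotype"]
            rows.append(rec)
    cols = ["read", "sequence", "length", "multiplicity", "target_id",
            "target_kind", "position", "strand", "mismatches"]
    return pd.DataFrame(rows, columns=cols + (["genotype"] if rows and
                        "genotype" in rows[0] else []))


# ---------------------------------------------------------------------------
# Association with gene classes

def associate_srna(mapping: pd.DataFrame, gene_classes: pd.Series
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene sRNA support and per-class strand proportions.

    A gene "has sRNA similarity" iff at least one best-stratum read maps
    to its transcript.  Returns:

    * per-gene table: reads-by-length counts (multiplicity-weighted)
      plus an ``srna_similarity`` flag;
    * per (gene class, read length): '+'-strand proportion of mapped
      read multiplicity.
    """
    tx = mapping[mapping["target_kind"] == "transcript"].copy()
    tx["gene_class"] = tx["target_id"].map(gene_classes)

    per_gene = (tx.pivot_table(index="target_id", columns="length",
                               values="multiplicity", aggfunc="sum",
                               fill_value=0)
                if not tx.empty else pd.DataFrame())
    per_gene = per_gene.reindex(gene_classes.index, fill_value=0)
    per_gene["srna_similarity"] = per_gene.sum(axis=1) > 0
    per_gene.index.name = "gene_id"

    if tx.empty:
        strand = pd.DataFrame(columns=["gene_class", "length",
                                       "plus_fraction", "reads"])
    else:
        grp = tx.groupby(["gene_class", "length"])
        strand = grp.apply(
            lambda g: pd.Series({
                "plus_fraction": g.loc[g["strand"] == "+", "multiplicity"].sum()
                / g["multiplicity"].sum(),
                "reads": g["multiplicity"].sum()}),
            include_groups=False).reset_index()
    return per_gene, strand


def mirna_family_assign(reads: pd.DataFrame, families: dict[str, str],
                        max_mismatches: int = 1) -> pd.Series:
    """Assign reads to miRNA families by best <=1-mismatch match.

    Family names are FASTA ids up to the first '-' or '_' suffix (so
    ``miR166-a`` and ``miR166_b`` pool into ``miR166``).  A read
    matching two families equally well is ambiguous and unassigned.
    Returns multiplicity-weighted read counts per family.
    """
    def family_of(name: str) -> str:
        for sep in ("-", "_"):
            if sep in name:
                return name.split(sep)[0]
        return name

    fam_seqs = [(family_of(n), s.upper()) for n, s in families.items()]
    counts: dict[str, int] = {}
    for _, row in reads.iterrows():
        read = row["sequence"].upper()
        best_mm = max_mismatches + 1
        best_fams: set[str] = set()
        for fam, seq in fam_seqs:
            for q in (read, reverse_complement(read)):
                if len(q) > len(seq):
                    continue
                for start in range(len(seq) - len(q) + 1):
                    mm = sum(a != b for a, b in zip(q, seq[start:start + len(q)]))
                    if mm < best_mm:
                        best_mm = mm
                        best_fams = {fam}
                    elif mm == best_mm:
                        best_fams.add(fam)
        if len(best_fams) == 1 and best_mm <= max_mismatches:
            fam = best_fams.pop()
            counts[fam] = counts.get(fam, 0) + int(row.get("multiplicity", 1))
    return pd.Series(counts, dtype=int, name="reads").sort_index()
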