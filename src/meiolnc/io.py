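"""FASTA and TSV input/output helpers.

Sequences are handled as ``{id: sequence}`` ordered dicts throughout the
package; Biopython does the parsing/writing so the files interoperate
with standard tools.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    """Write ``{id: sequence}`` to FASTA, deterministically ordered."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    return df.astype(int)


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
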