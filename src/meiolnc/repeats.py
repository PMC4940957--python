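"""Transposable-element and natural-antisense annotation of lncRNAs.

Nucleotide similarity search against a family-coded TE library and a
NAT reference database, both at the relaxed repeat thresholds (bit
score >= 70, E < 1e-6).  Family codes follow the three-letter repeat
taxonomy (``D*`` = DNA transposon, ``R*`` = retrotransposon); library
headers carry them as ``>elementID#CODE``.
"""

from __future__ import annotations

import pandas as pd

from meiolnc.align import KmerPrefilter, NUCLEOTIDE_1_2, search_nucleotide_db
from meiolnc.identify import E_THRESHOLD

TE_BIT_THRESHOLD = 70.0

#: family code -> human-readable element name
TE_FAMILY_NAMES = {
    "DH": "Helitron", "DT": "Unknown DNA transposon", "DTA": "hAT",
    "DTC": "CACTA", "DTH": "Harbinger", "DTM": "Mutator", "DXX": "MITE",
    "RI": "Unknown non-LTR retrotransposon", "RIL": "LINE",
    "RLC": "Copia", "RLG": "Gypsy", "RLR": "Retrovirus",
    "RLX": "Unknown LTR retrotransposon", "RX": "Unknown retrotransposon",
}


def te_class(family: str | None) -> str | None:
    """DNA-transposon vs retrotransposon, derived from the family code."""
    if family is None or (isinstance(family, float) and pd.isna(family)):
        return None
    if family.startswith("D"):
        return "DNA-transposon"
    if family.startswith("R"):
        return "retrotransposon"
    raise ValueError(f"unrecognized TE family code {family!r}")


def _family_from_header(name: str) -> str:
    if "#" not in name:
        raise ValueError(f"TE library header {name!r} lacks a '#CODE' suffix")
    return name.split("#", 1)[1].split()[0]


def annotate_te(lncrnas: dict[str, str], te_library: dict[str, str],
                bit_threshold: float = TE_BIT_THRESHOLD,
                e_threshold: float = E_THRESHOLD,
                kmer: int | None = 11) -> pd.DataFrame:
    """Best-hit TE annotation per lncRNA at bit >= 70 and E < 1e-6.

    One family per lncRNA - that of the best-scoring library hit (ties
    resolve to the earlier library entry).  Returns a frame indexed by
    lncRNA id with ``te_family`` and ``te_class`` (None when no hit
    passes).
    """
    prefilter = KmerPrefilter(te_library, kmer) if te_library else None
    rows = {}
    for tid, seq in lncrnas.items():
        family = None
        if te_library:
            hit = search_nucleotide_db(tid, seq, "te", te_library,
                                       scheme=NUCLEOTIDE_1_2,
                                       prefilter_fwd=prefilter)
            if (hit is not None and hit.bit_score >= bit_threshold
                    and hit.e_value < e_threshold):
                family = _family_from_header(hit.target_id)
        rows[tid] = {"te_family": family, "te_class": te_class(family)}
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["te_family", "te_class"])
    out.index.name = "lncRNA_id"
    return out


def annotate_nat(lncrnas: dict[str, str], nat_db: dict[str, str],
                 bit_threshold: float = TE_BIT_THRESHOLD,
                 e_threshold: float = E_THRESHOLD,
                 kmer: int | None = 11) -> pd.Series:
    """Trans-NAT flags: similarity to a NAT-database entry on either
    strand at the repeat thresholds."""
    prefilter = KmerPrefilter(nat_db, kmer) if nat_db else None
    flags = {}
    for tid, seq in lncrnas.items():
        flag = False
        if nat_db:
            hit = search_nucleotide_db(tid, seq, "nat", nat_db,
                                       scheme=NUCLEOTIDE_1_2,
                                       prefilter_fwd=prefilter)
            flag = (hit is not None and hit.bit_score >= bit_threshold
                    and hit.e_value < e_threshold)
        flags[tid] = flag
    return pd.Series(flags, name="nat_flag", dtype=bool)


def family_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-family lncRNA counts with the DNA/retrotransposon split.

    Percentages are taken over TE-carrying lncRNAs; the two class
    percentages sum to 100 when any annotation exists.
    """
    ann = annotations.dropna(subset=["te_family"])
    if ann.empty:
        return pd.DataFrame(columns=["te_class", "count", "percent"])
    total = len(ann)
    rows = []
    for family, grp in ann.groupby("te_family"):
        rows.append({"te_family": family, "te_class": te_class(family),
                     "count": len(grp), "percent": 100.0 * len(grp) / total})
    return pd.DataFrame(rows).set_index("te_family").sort_index()


def class_split(annotations: pd.DataFrame) -> pd.Series:
    """Percent of annotated lncRNAs per TE class (DNA vs retro)."""
    ann = annotations.dropna(subset=["te_class"])
    if ann.empty:
        return pd.Series(dtype=float, name="percent")
    return (100.0 * ann["te_class"].value_counts() / len(ann)).rename("percent")
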