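"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (plain dynamic
programming, exhaustive scans, direct table lookups) and deliberately
shares no code with the package modules it checks.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# Affine-gap Smith-Waterman by explicit Gotoh recursion

def sw_score(query: str, target: str, score_fn, gap_open: float,
             gap_extend: float) -> float:
    """Optimal local alignment score; a gap of length k costs
    gap_open + gap_extend * k."""
    n, m = len(query), len(target)
    neg = -1e18
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in query (along target)
    f = np.full((n + 1, m + 1), neg)  # gap in target
    best = 0.0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - first_gap, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - first_gap, f[i - 1][j] - gap_extend)
            diag = h[i - 1][j - 1] + score_fn(query[i - 1], target[j - 1])
            h[i][j] = max(0.0, diag, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def blosum62_score(a: str, b: str) -> float:
    return float(BLOSUM62[a][b])


def match_mismatch(match: float, mismatch: float):
    return lambda a, b: match if a == b else mismatch


# ---------------------------------------------------------------------------
# Exhaustive ORF scan

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def scan_longest_orf(seq: str) -> int:
    """Length (nt, incl. stop) of the longest ATG..stop ORF over both
    strands; exhaustive over every ATG."""
    best = 0
    for s in (seq.upper(), revcomp(seq.upper())):
        for start in range(len(s) - 2):
            if s[start:start + 3] != "ATG":
                continue
            for j in range(start + 3, len(s) - 2, 3):
                if CODON_TABLE.get(s[j:j + 3]) == "*":
                    best = max(best, j + 3 - start)
                    break
    return best


# ---------------------------------------------------------------------------
# Fickett TESTCODE oracle (direct table lookups, published 1982 values)

_POS_PARAM = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_POS_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.63, 0.48, 0.29],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.51, 0.40, 0.28],
}
_POS_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_CONT_PARAM = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.17, 0.0]
_CONT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.24, 0.30, 0.23],
    "G": [0.21, 0.40, 0.47, 0.46, 0.52, 0.58, 0.54, 0.52, 0.30],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.45],
}
_CONT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def fickett_terms(seq: str) -> tuple[float, float]:
    """(position term, content term) of the TESTCODE statistic."""
    seq = seq.upper()
    total = sum(seq.count(b) for b in "ACGT")
    pos_term = 0.0
    cont_term = 0.0
    for base in "ACGT":
        counts = [sum(1 for i in range(k, len(seq), 3) if seq[i] == base)
                  for k in range(3)]
        asym = max(counts) / (min(counts) + 1.0)
        content = sum(counts) / total if total else 0.0
        for t, p in zip(_POS_PARAM, _POS_PROB[base]):
            if asym >= t:
                pos_term += p * _POS_WEIGHT[base]
                break
        for t, p in zip(_CONT_PARAM, _CONT_PROB[base]):
            if content >= t:
                cont_term += p * _CONT_WEIGHT[base]
                break
    return pos_term, cont_term


def fickett_oracle(seq: str) -> float:
    pos, cont = fickett_terms(seq)
    return pos + cont


# ---------------------------------------------------------------------------
# Conditional NB exact test by explicit enumeration of the joint pmf

def nb_exact_oracle(y_a: int, y_b: int, dispersion: float,
                    n_a: int = 1, n_b: int = 1, mu: float = 10.0) -> float:
    """Small-p exact test: enumerate the conditional distribution of the
    first group sum given the total, from the joint NB pmf (any common
    per-replicate mean cancels)."""
    from scipy import stats

    s = y_a + y_b
    if s == 0:
        return 1.0
    if dispersion <= 0:
        pa = stats.poisson.pmf(np.arange(s + 1), n_a * mu)
        pb = stats.poisson.pmf(s - np.arange(s + 1), n_b * mu)
    else:
        r = 1.0 / dispersion
        pr_a = (n_a * r) / (n_a * r + n_a * mu)
        pr_b = (n_b * r) / (n_b * r + n_b * mu)
        pa = stats.nbinom.pmf(np.arange(s + 1), n_a * r, pr_a)
        pb = stats.nbinom.pmf(s - np.arange(s + 1), n_b * r, pr_b)
    joint = pa * pb
    cond = joint / joint.sum()
    obs = cond[y_a]
    return float(min(1.0, cond[cond <= obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# Exhaustive small-RNA scan

def scan_read(read: str, targets: dict[str, tuple[str, str]],
              max_mm: int = 1) -> set[tuple[str, str, int, str, int]]:
    """All best-stratum alignments of a read: every start position on
    every target, both strands, mismatches <= max_mm."""
    hits = []
    best = max_mm + 1
    for strand, q in (("+", read.upper()), ("-", revcomp(read.upper()))):
        for tid, (kind, seq) in targets.items():
            seq = seq.upper()
            for start in range(len(seq) - len(q) + 1):
                mm = sum(a != b for a, b in zip(q, seq[start:start + len(q)]))
                if mm <= max_mm:
                    hits.append((mm, (tid, kind, start, strand, mm)))
                    best = min(best, mm)
    return {h for mm, h in hits if mm == best}


# ---------------------------------------------------------------------------
# Two-proportion z-test closed form

def proportion_z_oracle(x1: int, n1: int, x2: int, n2: int) -> float:
    from scipy import stats

    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return 2.0 * (1.0 - stats.norm.cdf(abs(z)))
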