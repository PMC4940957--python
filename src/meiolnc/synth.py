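"""Synthetic-data generator for every input the pipeline consumes.

Each generator stage draws from an independent deterministic stream
derived from ``(seed, stage name)``, so outputs are byte-reproducible
and adding one stage never perturbs another.  Ground truth (true coding
class, genome membership, DE status, TE family, NAT partner, sRNA read
provenance) is recorded alongside every artifact so that downstream
modules can be scored against it.

Design notes:

* Coding transcripts carry a planted ORF (ATG ... in-frame stop) whose
  codons are drawn from a built-in biased codon-usage table; non-coding
  transcripts are dinucleotide-preserving shuffles of coding ones, so
  mono- and di-nucleotide composition alone cannot separate the
  classes and the ORF/Fickett/hexamer features have to do real work.
* TE insertion and NAT planting rewrite windows of non-coding
  transcripts, so ``generate_all`` applies them before the genome and
  count stages see the sequences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from meiolnc.align import reverse_complement, translate_frame
from meiolnc.config import SynthConfig

_STOPS = ("TAA", "TAG", "TGA")

# three-letter repeat taxonomy codes: D* = DNA transposon, R* = retrotransposon
TE_FAMILIES_RETRO = ("RLG", "RLC", "RLX", "RIL", "RX")
TE_FAMILIES_DNA = ("DTA", "DTC", "DTH", "DTM", "DH")


def load_codon_weights() -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Sense codons, sampling weights and codon->aa map from the data file."""
    ref = importlib.resources.files("meiolnc.data") / "codon_usage.tsv"
    df = pd.read_csv(ref, sep="\t", comment="#")
    codons = df["codon"].tolist()
    aa_of = dict(zip(df["codon"], df["amino_acid"]))
    w = df["weight"].to_numpy(float)
    return codons, w / w.sum(), aa_of


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide counts.

    Builds the multigraph of adjacent-symbol edges and samples a uniform
    Eulerian path with the original first and last symbols fixed.
    """
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    vertices = list(edges)
    last = seq[-1]
    # pick a random final edge out of each non-terminal vertex such that the
    # chosen edges form a tree directed toward the terminal vertex
    for _ in range(1000):
        final = {}
        for v in vertices:
            if v == last:
                continue
            final[v] = edges[v][rng.integers(len(edges[v]))]
        # connectivity check: every non-terminal vertex must reach `last`
        ok = True
        for v in final:
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in final:
                    ok = False
                    break
                seen.add(u)
                u = final[u]
            if not ok:
                break
        if ok:
            break
    else:  # pathological composition; give up on structure, plain shuffle
        chars = list(seq[1:-1])
        rng.shuffle(chars)
        return seq[0] + "".join(chars) + seq[-1]
    # shuffle remaining edges, append the reserved final edge
    pools = {}
    for v in vertices:
        rest = list(edges[v])
        if v in final:
            rest.remove(final[v])
        rng.shuffle(rest)
        if v in final:
            rest.append(final[v])
        pools[v] = rest
    out = [seq[0]]
    idx = {v: 0 for v in vertices}
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[u][idx[u]]
        idx[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def longest_orf_length(seq: str) -> int:
    """Longest ATG..stop ORF (nt, incl. stop) over both strands, brute force."""
    best = 0
    for s in (seq, reverse_complement(seq)):
        for off in range(3):
            pep_start = None
            for i in range(off, len(s) - 2, 3):
                codon = s[i:i + 3]
                if codon in _STOPS:
                    if pep_start is not None:
                        best = max(best, i + 3 - pep_start)
                        pep_start = None
                elif codon == "ATG" and pep_start is None:
                    pep_start = i
    return best


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@dataclass
class SyntheticData:
    """Bundle of all generated artifacts plus merged ground truth."""

    config: SynthConfig
    transcripts: dict[str, str] = field(default_factory=dict)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    peptide_dbs: list[tuple[str, dict[str, str]]] = field(default_factory=list)
    genome: dict[str, str] = field(default_factory=dict)
    placements: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    srna_reads: pd.DataFrame = field(default_factory=pd.DataFrame)
    te_library: dict[str, str] = field(default_factory=dict)
    nat_db: dict[str, str] = field(default_factory=dict)


def gen_transcripts(cfg: SynthConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate coding (planted-ORF) and shuffled non-coding transcripts.

    Returns the transcript dict and a ground-truth frame with columns
    ``true_class``, ``orf_start``, ``orf_end``, ``peptide_id``.  A
    ``paralog_fraction`` of coding transcripts reuse the ORF (and hence
    the peptide identifier) of an earlier one, which plants the sharing
    structure that identifier collapsing must recover.
    """
    cfg.validate()
    rng = cfg.rng("transcripts")
    codons, cw, _ = load_codon_weights()
    codon_arr = np.array(codons)
    transcripts: dict[str, str] = {}
    rows = []

    orfs: list[tuple[str, str]] = []  # (peptide_id, orf_nt) for paralog reuse
    for i in range(cfg.n_coding):
        tid = f"tc{i:05d}"
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        if orfs and rng.random() < cfg.paralog_fraction:
            pep_id, orf = orfs[rng.integers(len(orfs))]
        else:
            max_orf = max(150, min(int(3 * ((length - 60) // 3)), length - 30))
            target = rng.normal(cfg.orf_length_mean, cfg.orf_length_mean / 4)
            n_codons = int(np.clip(target, 150, max_orf)) // 3 - 2
            body = codon_arr[rng.choice(len(codons), n_codons, p=cw)]
            orf = "ATG" + "".join(body) + _STOPS[rng.integers(3)]
            pep_id = f"PEP{len(orfs):05d}"
            orfs.append((pep_id, orf))
        if len(orf) > length - 6:
            length = len(orf) + int(rng.integers(6, 60))
        utr5 = int(rng.integers(0, length - len(orf) + 1))
        seq = _random_nt(rng, utr5) + orf + _random_nt(rng, length - len(orf) - utr5)
        transcripts[tid] = seq
        rows.append({"transcript_id": tid, "true_class": "coding",
                     "orf_start": utr5, "orf_end": utr5 + len(orf),
                     "peptide_id": pep_id})

    coding_ids = list(transcripts)
    for i in range(cfg.n_noncoding):
        tid = f"tn{i:05d}"
        if coding_ids:
            for _ in range(200):
                src = transcripts[coding_ids[rng.integers(len(coding_ids))]]
                seq = dinucleotide_shuffle(src, rng)
                if longest_orf_length(seq) <= cfg.noncoding_orf_cap:
                    break
        else:
            seq = _random_nt(rng, int(rng.integers(cfg.length_range[0],
                                                   cfg.length_range[1] + 1)))
        transcripts[tid] = seq
        rows.append({"transcript_id": tid, "true_class": "noncoding",
                     "orf_start": -1, "orf_end": -1, "peptide_id": None})

    truth = pd.DataFrame(rows).set_index("transcript_id") if rows else \
        pd.DataFrame(columns=["true_class", "orf_start", "orf_end",
                              "peptide_id"])
    return transcripts, truth


def gen_peptide_dbs(transcripts: dict[str, str], truth: pd.DataFrame,
                    cfg: SynthConfig) -> tuple[list[tuple[str, dict[str, str]]],
                                               pd.Series]:
    """Ordered peptide databases built from the planted coding peptides.

    A ``db_coverage`` fraction of distinct peptides is placed in exactly
    one database (earlier databases receive more entries); the rest are
    absent everywhere, emulating species-specific genes.  Returns the
    ordered ``(name, {peptide_id: peptide})`` list and a per-transcript
    Series naming the database holding its peptide (None if uncovered).
    """
    rng = cfg.rng("peptide_dbs")
    dbs: dict[str, dict[str, str]] = {name: {} for name in cfg.db_names}
    placement: dict[str, str | None] = {}
    coding = truth[truth["true_class"] == "coding"] if len(truth) else truth
    seen: dict[str, str | None] = {}
    # decreasing share per database in precedence order
    shares = np.array([2.0 ** -i for i in range(len(cfg.db_names))])
    shares /= shares.sum()
    for tid, row in coding.iterrows():
        pid = row["peptide_id"]
        if pid not in seen:
            if rng.random() < cfg.db_coverage:
                name = cfg.db_names[rng.choice(len(cfg.db_names), p=shares)]
                orf = transcripts[tid][row["orf_start"]:row["orf_end"]]
                dbs[name][pid] = translate_frame(orf, 0).rstrip("*")
                seen[pid] = name
            else:
                seen[pid] = None
        placement[tid] = seen[pid]
    return [(name, dbs[name]) for name in cfg.db_names], pd.Series(
        placement, name="db_name", dtype=object)


def gen_genome(transcripts: dict[str, str], cfg: SynthConfig,
               dropout_eligible: list[str] | None = None
               ) -> tuple[dict[str, str], pd.DataFrame]:
    """Embed transcripts in flanked scaffolds, dropping an exact fraction.

    Exactly ``round(genome_dropout * n)`` transcripts are absent from
    the genome.  ``dropout_eligible`` restricts which transcripts may be
    dropped: transcripts sharing planted content with others (paralogous
    ORFs, TE or antisense windows) remain similar to the genome even
    when their own copy is removed, so a meaningful absence ground truth
    only drops content-unique transcripts.  The placement map records
    0-based half-open insert coordinates and the embedded strand.
    """
    if not transcripts:
        raise ValueError("gen_genome requires a non-empty transcript set")
    rng = cfg.rng("genome")
    ids = list(transcripts)
    n_drop = int(round(cfg.genome_dropout * len(ids)))
    pool = ids if dropout_eligible is None else \
        [t for t in ids if t in set(dropout_eligible)]
    if n_drop > len(pool):
        raise ValueError(f"genome_dropout requires {n_drop} droppable "
                         f"transcripts but only {len(pool)} are eligible")
    pool_idx = [i for i, t in enumerate(ids) if t in set(pool)]
    chosen = rng.choice(len(pool_idx), size=n_drop, replace=False) \
        if n_drop else np.array([], int)
    dropped = {pool_idx[int(i)] for i in chosen}
    genome: dict[str, str] = {}
    rows = []
    scf = 0
    for i, tid in enumerate(ids):
        if i in dropped:
            rows.append({"transcript_id": tid, "scaffold": None, "start": -1,
                         "end": -1, "strand": ".", "in_genome": False})
            continue
        name = f"scf{scf:05d}"
        scf += 1
        strand = "+" if rng.random() < 0.5 else "-"
        insert = transcripts[tid] if strand == "+" else \
            reverse_complement(transcripts[tid])
        left = _random_nt(rng, cfg.flank_length)
        right = _random_nt(rng, cfg.flank_length)
        genome[name] = left + insert + right
        rows.append({"transcript_id": tid, "scaffold": name,
                     "start": len(left), "end": len(left) + len(insert),
                     "strand": strand, "in_genome": True})
    placements = pd.DataFrame(rows).set_index("transcript_id")
    return genome, placements


def gen_counts(transcript_ids: list[str], cfg: SynthConfig
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """NB-distributed count matrix over the genotype/tissue design.

    Counts for gene *g* in sample *j* are NB with mean ``mu_g * s_j``
    and dispersion ``nb_dispersion``.  A ``de_fraction`` of genes has
    its domesticated-genotype mean scaled by ``2**log2_effect`` (F1
    intermediate at half the log effect); a ``meiocyte_exclusive_fraction``
    is silenced in the somatic samples.  Returns (counts, sample
    metadata, per-gene truth with ``true_DE`` and ``meiocyte_exclusive``).
    """
    rng = cfg.rng("counts")
    n = len(transcript_ids)
    genotypes = ["domesticated", "wild", "F1"][:cfg.n_genotypes]
    samples = []
    for g in genotypes:
        for r in range(cfg.n_replicates):
            samples.append({"sample": f"{g}_meio_{r + 1}", "genotype": g,
                            "tissue": "meiocyte", "replicate": r + 1})
    for r in range(cfg.n_somatic_replicates):
        samples.append({"sample": f"domesticated_soma_{r + 1}",
                        "genotype": "domesticated", "tissue": "somatic",
                        "replicate": r + 1})
    meta = pd.DataFrame(samples).set_index("sample")

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    base /= base.sum() if n else 1.0
    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    de_flag = np.zeros(n, bool)
    de_flag[de_idx] = True
    n_excl = int(round(cfg.meiocyte_exclusive_fraction * n))
    excl_idx = rng.choice(n, size=n_excl, replace=False) if n_excl else np.array([], int)
    excl = np.zeros(n, bool)
    excl[excl_idx] = True

    fold = {"domesticated": 2.0 ** cfg.log2_effect,
            "F1": 2.0 ** (cfg.log2_effect / 2.0), "wild": 1.0}
    counts = {}
    for s, row in meta.iterrows():
        depth = cfg.library_size * rng.uniform(0.8, 1.2)
        mu = base * depth
        if row["tissue"] == "meiocyte":
            mu = mu * np.where(de_flag, fold[row["genotype"]], 1.0)
        else:
            mu = mu * np.where(excl, 0.0, 1.0)
        if cfg.nb_dispersion <= 1e-12:
            counts[s] = rng.poisson(mu)
        else:
            r_nb = 1.0 / cfg.nb_dispersion
            counts[s] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    cmat = pd.DataFrame(counts, index=pd.Index(transcript_ids, name="gene_id"))
    gtruth = pd.DataFrame({"true_DE": de_flag, "meiocyte_exclusive": excl},
                          index=cmat.index)
    return cmat, meta, gtruth


def gen_srna_reads(transcripts: dict[str, str], truth: pd.DataFrame,
                   cfg: SynthConfig) -> pd.DataFrame:
    """Small-RNA reads sampled as exact substrings of precursor transcripts.

    Lengths follow ``srna_length_weights``; 24-nt reads start with A at
    exactly the configured rate; reads of <= 21 nt come from the '+'
    strand only (miRNA-like single-stranded precursors) while longer
    reads come from both strands (siRNA-like).  Multiplicities are
    geometric with shorter reads more redundant.  Ground truth (source
    transcript, strand) is carried on each row.
    """
    rng = cfg.rng("srna")
    nc = truth[truth["true_class"] == "noncoding"].index.tolist() if len(truth) else []
    pool = nc if nc else list(transcripts)
    if not pool:
        return pd.DataFrame(columns=["sequence", "length", "multiplicity",
                                     "genotype", "source_transcript", "strand"])
    n_prec = max(1, int(round(cfg.srna_precursor_fraction * len(pool))))
    prec = [pool[i] for i in rng.choice(len(pool), n_prec, replace=False)]
    lengths = np.array(sorted(cfg.srna_length_weights))
    redundancy_p = {20: 0.35, 21: 0.30, 22: 0.6, 23: 0.7, 24: 0.85, 25: 0.8}
    # srna_length_weights describe the share of TOTAL reads per length;
    # sampling events are deflated by the expected multiplicity (1/p of
    # the geometric) so that redundant lengths do not dominate totals
    weights = np.array([cfg.srna_length_weights[k] * redundancy_p[k]
                        for k in lengths], float)
    weights /= weights.sum()
    rows = []
    for i in range(cfg.n_srna_reads):
        L = int(lengths[rng.choice(len(lengths), p=weights)])
        tid = prec[rng.integers(len(prec))]
        src = transcripts[tid]
        if len(src) < L:
            continue
        strand = "+" if (L <= 21 or rng.random() < 0.5) else "-"
        want_a = L == 24 and rng.random() < cfg.fiveprime_A_bias
        seq = None
        for _ in range(200):
            p = int(rng.integers(0, len(src) - L + 1))
            cand = src[p:p + L] if strand == "+" else \
                reverse_complement(src[p:p + L])
            if L != 24 or (cand[0] == "A") == want_a:
                seq = cand
                break
        if seq is None:
            continue
        rows.append({"sequence": seq, "length": L,
                     "multiplicity": int(rng.geometric(redundancy_p[L])),
                     "genotype": "wild" if rng.random() < 0.5 else "domesticated",
                     "source_transcript": tid, "strand": strand})
    df = pd.DataFrame(rows)
    df.index.name = "read_id"
    return df


def _mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    out = list(seq)
    alt = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i in range(len(out)):
        if rng.random() > identity:
            out[i] = alt[out[i]][rng.integers(3)]
    return "".join(out)


def gen_te_nat(transcripts: dict[str, str], truth: pd.DataFrame,
               cfg: SynthConfig) -> tuple[dict[str, str], dict[str, str],
                                          dict[str, str], pd.DataFrame]:
    """Plant TE insertions and NAT windows into non-coding transcripts.

    Returns ``(modified transcripts, TE library, NAT database, truth)``.
    TE library headers carry the repeat-family code (``>id#CODE``);
    insertions copy a ~300 bp window of a library element at the
    configured identity into a transcript (replacing a same-length
    window).  NAT planting writes the reverse complement of an internal
    window of a partner transcript into the lncRNA candidate; the NAT
    database holds the partner sequences.
    """
    rng = cfg.rng("te_nat")
    transcripts = dict(transcripts)
    te_library: dict[str, str] = {}
    fams = list(TE_FAMILIES_RETRO) + list(TE_FAMILIES_DNA)
    for i, fam in enumerate(fams):
        te_library[f"TE{i:03d}#{fam}"] = _random_nt(rng, int(rng.integers(800, 2000)))

    nc = truth[truth["true_class"] == "noncoding"].index.tolist() if len(truth) else []
    te_family = pd.Series(None, index=truth.index, dtype=object, name="te_family")
    nat_partner = pd.Series(None, index=truth.index, dtype=object,
                            name="nat_partner")

    n_te = min(cfg.n_te_insertions, len(nc))
    te_targets = [nc[i] for i in rng.choice(len(nc), n_te, replace=False)] if n_te else []
    retro_names = [n for n in te_library if n.split("#")[1] in TE_FAMILIES_RETRO]
    dna_names = [n for n in te_library if n.split("#")[1] in TE_FAMILIES_DNA]
    # exact class composition: round(te_retro_fraction * n) insertions
    # come from retrotransposons, the rest from DNA transposons
    n_retro = int(round(cfg.te_retro_fraction * n_te))
    for k, tid in enumerate(te_targets):
        pool2 = retro_names if k < n_retro else dna_names
        elem = pool2[rng.integers(len(pool2))]
        esq = te_library[elem]
        win = min(300, len(transcripts[tid]) // 2)
        s = transcripts[tid]
        # planting must not break the non-coding ORF cap: a random-content
        # window can create a long spurious ORF, so redraw until it does not
        for _ in range(200):
            ep = int(rng.integers(0, len(esq) - win + 1))
            frag = _mutate(esq[ep:ep + win], cfg.te_identity, rng)
            tp = int(rng.integers(0, len(s) - win + 1))
            cand = s[:tp] + frag + s[tp + win:]
            if longest_orf_length(cand) <= cfg.noncoding_orf_cap:
                break
        transcripts[tid] = cand
        te_family[tid] = elem.split("#")[1]

    nat_db: dict[str, str] = {}
    remaining = [t for t in nc if t not in te_targets]
    n_nat = min(cfg.n_nat_pairs, len(remaining) // 2)
    nat_targets = [remaining[i] for i in
                   rng.choice(len(remaining), n_nat, replace=False)] if n_nat else []
    # partners are drawn from other non-coding transcripts so that the
    # planted antisense window never carries protein-coding signal
    others = [t for t in remaining if t not in nat_targets] or \
        [t for t in transcripts if t not in nat_targets]
    for tid in nat_targets:
        partner = others[rng.integers(len(others))]
        psq = transcripts[partner]
        win = min(cfg.nat_window, len(psq) // 2, len(transcripts[tid]) // 2)
        s = transcripts[tid]
        for _ in range(200):  # same ORF-cap guard as TE planting
            pp = int(rng.integers(0, len(psq) - win + 1))
            frag = reverse_complement(psq[pp:pp + win])
            tp = int(rng.integers(0, len(s) - win + 1))
            cand = s[:tp] + frag + s[tp + win:]
            if longest_orf_length(cand) <= cfg.noncoding_orf_cap:
                break
        transcripts[tid] = cand
        nat_db[f"NAT_{partner}"] = psq
        nat_partner[tid] = partner

    new_truth = truth.copy()
    new_truth["te_family"] = te_family
    new_truth["nat_partner"] = nat_partner
    return transcripts, te_library, nat_db, new_truth


def generate_all(cfg: SynthConfig) -> SyntheticData:
    """Run every generator stage in dependency order and merge truth."""
    data = SyntheticData(config=cfg)
    data.transcripts, truth = gen_transcripts(cfg)
    data.transcripts, data.te_library, data.nat_db, truth = gen_te_nat(
        data.transcripts, truth, cfg)
    data.peptide_dbs, db_placement = gen_peptide_dbs(data.transcripts, truth, cfg)
    pep_counts = truth["peptide_id"].value_counts()
    paralogs = set(truth.index[truth["peptide_id"].map(pep_counts).fillna(0) > 1])
    nat_involved = set(truth.index[truth["nat_partner"].notna()]) | \
        set(truth["nat_partner"].dropna())
    te_carriers = set(truth.index[truth["te_family"].notna()])
    eligible = [t for t in data.transcripts
                if t not in paralogs | nat_involved | te_carriers]
    data.genome, data.placements = gen_genome(data.transcripts, cfg,
                                              dropout_eligible=eligible)
    data.counts, data.samples, gtruth = gen_counts(list(data.transcripts), cfg)
    data.srna_reads = gen_srna_reads(data.transcripts, truth, cfg)
    truth = truth.join(db_placement).join(
        data.placements[["in_genome"]]).join(gtruth)
    data.truth = truth
    return data
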