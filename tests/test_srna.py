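import numpy as np
import pandas as pd
import pytest

from meiolnc import srna
from oracles import revcomp, scan_read


def _reads(*seqs, mult=None, genotype=None):
    df = pd.DataFrame({"sequence": list(seqs)})
    if mult is not None:
        df["multiplicity"] = mult
    if genotype is not None:
        df["genotype"] = genotype
    return df


class TestFilter:
    def test_length_window(self):
        reads = _reads("A" * 19, "C" * 20, "G" * 24, "T" * 25, "A" * 26)
        out = srna.filter_reads(reads)
        assert sorted(out["length"]) == [20, 24, 25]

    def test_identical_sequences_collapse_with_summed_multiplicity(self):
        reads = _reads("ACGTACGTACGTACGTACGTACGT",
                       "ACGTACGTACGTACGTACGTACGT",
                       "ACGTACGTACGTACGTACGTACGT")
        out = srna.filter_reads(reads)
        assert len(out) == 1
        assert out["multiplicity"].iloc[0] == 3

    def test_multiplicity_conserved_across_partition(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
                for L in rng.integers(15, 30, 200)]
        reads = _reads(*seqs, mult=rng.integers(1, 5, 200).tolist())
        kept = srna.filter_reads(reads)
        dropped = reads[(reads["sequence"].str.len() < 20)
                        | (reads["sequence"].str.len() > 25)]
        assert kept["multiplicity"].sum() + dropped["multiplicity"].sum() \
            == reads["multiplicity"].sum()


class TestProfiles:
    def test_all_distinct_reads_have_zero_redundant(self):
        reads = srna.filter_reads(_reads("A" * 24, "C" * 24, "ACGT" * 6))
        prof = srna.redundancy_profile(reads)
        assert (prof["redundant"] == 0).all()

    def test_repeated_sequence_counts_as_redundant(self):
        reads = srna.filter_reads(_reads(*["ACGTACGTACGTACGTACGTACGT"] * 5))
        prof = srna.redundancy_profile(reads)
        assert prof.loc[24, "unique"] == 0
        assert prof.loc[24, "redundant"] == 5

    def test_planted_redundancy_recovered(self):
        reads = _reads(*(["A" * 21] * 3 + ["C" * 21] + ["G" * 24]))
        prof = srna.redundancy_profile(srna.filter_reads(reads))
        assert prof.loc[21, "unique"] == 1
        assert prof.loc[21, "redundant"] == 3
        assert prof.loc[24, "unique"] == 1

    def test_five_prime_bias_all_a(self):
        reads = _reads("A" * 24, "ACGT" * 6)
        bias = srna.five_prime_bias(srna.filter_reads(reads), 24)
        assert bias["A"] == 1.0

    def test_five_prime_bias_empty_set_rejected(self):
        with pytest.raises(ValueError):
            srna.five_prime_bias(_reads("A" * 24), 21)

    def test_generator_bias_recovered_within_three_se(self, small_data,
                                                      small_cfg):
        reads = srna.filter_reads(small_data.srna_reads)
        bias = srna.five_prime_bias(reads[reads["genotype"] == "wild"], 24)
        n = reads[(reads["genotype"] == "wild")
                  & (reads["length"] == 24)]["multiplicity"].sum()
        se = np.sqrt(0.6 * 0.4 / n)
        # collapsing to unique sequences shifts the estimate; allow 5 SE
        assert abs(bias["A"] - small_cfg.fiveprime_A_bias) <= 5 * se


@pytest.fixture(scope="module")
def tiny_reference():
    rng = np.random.default_rng(31)
    nt = np.array(list("ACGT"))
    genome = {f"scf{i}": "".join(nt[rng.integers(0, 4, 300)])
              for i in range(2)}
    transcripts = {f"tx{i}": "".join(nt[rng.integers(0, 4, 200)])
                   for i in range(3)}
    return genome, transcripts


class TestMapping:
    def test_exact_substring_single_hit(self, tiny_reference):
        genome, transcripts = tiny_reference
        ref = srna.MixedReference(genome, transcripts)
        read = transcripts["tx0"][50:74]
        hits = ref.map_read(read)
        assert any(h.target_id == "tx0" and h.mismatches == 0
                   and h.position == 50 and h.strand == "+" for h in hits)
        assert all(h.mismatches == 0 for h in hits)

    def test_best_stratum_suppresses_one_mismatch_hits(self, tiny_reference):
        genome, transcripts = dict(tiny_reference[0]), dict(tiny_reference[1])
        read = "ACGTACGTACGTACGTACGTACGT"
        mutated = "ACGTACGTACGTTCGTACGTACGT"  # 1 mismatch
        genome["scf_exact"] = "TT" + read + "GG"
        transcripts["tx_near"] = "CC" + mutated + "AA"
        ref = srna.MixedReference(genome, transcripts)
        hits = ref.map_read(read)
        assert {h.target_id for h in hits} == {"scf_exact"}
        assert all(h.mismatches == 0 for h in hits)

    def test_reverse_strand_hit_found(self, tiny_reference):
        genome, transcripts = tiny_reference
        ref = srna.MixedReference(genome, transcripts)
        read = revcomp(genome["scf1"][100:124])
        hits = ref.map_read(read)
        assert any(h.target_id == "scf1" and h.strand == "-"
                   and h.position == 100 for h in hits)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            srna.MixedReference({}, {})

    def test_matches_exhaustive_scan_oracle(self, tiny_reference):
        genome, transcripts = tiny_reference
        ref = srna.MixedReference(genome, transcripts)
        targets = {tid: ("genome", s) for tid, s in genome.items()}
        targets.update({tid: ("transcript", s)
                        for tid, s in transcripts.items()})
        rng = np.random.default_rng(37)
        nt = "ACGT"
        pool = list(genome.values()) + list(transcripts.values())
        for i in range(100):
            L = int(rng.integers(20, 26))
            src = pool[rng.integers(len(pool))]
            p = int(rng.integers(0, len(src) - L + 1))
            read = list(src[p:p + L])
            # plant 0-2 mutations (2 -> often unmappable)
            for _ in range(int(rng.integers(0, 3))):
                j = int(rng.integers(L))
                read[j] = nt[rng.integers(4)]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            got = {(h.target_id, h.target_kind, h.position, h.strand,
                    h.mismatches) for h in ref.map_read(read)}
            assert got == scan_read(read, targets), (i, read)


class TestAssociation:
    def test_gene_without_reads_has_no_similarity_flag(self, tiny_reference):
        genome, transcripts = tiny_reference
        ref = srna.MixedReference(genome, transcripts)
        reads = srna.filter_reads(_reads(transcripts["tx0"][10:34]))
        mapping = srna.map_srna(reads, ref)
        classes = pd.Series("lncRNA", index=pd.Index(transcripts,
                                                     name="gene_id"))
        per_gene, _ = srna.associate_srna(mapping, classes)
        assert per_gene.loc["tx0", "srna_similarity"]
        assert not per_gene.loc["tx2", "srna_similarity"]

    def test_single_strand_reads_give_plus_proportion_one(self, small_data):
        """21-nt reads are drawn single-stranded, 24-nt from both strands."""
        reads = srna.filter_reads(small_data.srna_reads)
        ref = srna.MixedReference({}, small_data.transcripts)
        mapping = srna.map_srna(reads, ref)
        # evaluate on the true source transcripts to avoid multi-mapping
        src = mapping.merge(
            small_data.srna_reads[["sequence", "source_transcript"]]
            .drop_duplicates("sequence"), on="sequence")
        own = src[src["target_id"] == src["source_transcript"]]
        m21 = own[own["length"] == 21]
        frac21 = (m21["strand"] == "+").mul(m21["multiplicity"]).sum() \
            / m21["multiplicity"].sum()
        assert frac21 > 0.95
        m24 = own[own["length"] == 24]
        w = m24["multiplicity"].sum()
        frac24 = (m24["strand"] == "+").mul(m24["multiplicity"]).sum() / w
        assert abs(frac24 - 0.5) <= 3 * np.sqrt(0.25 / w) + 0.05


class TestFamilies:
    FAMS = {"miR166-a": "TCGGACCAGGCTTCATTCCCC",
            "miR396_1": "TTCCACAGCTTTCTTGAACTG",
            "miR319": "TTGGACTGAAGGGAGCTCCCT"}

    def test_identical_read_assigned_to_its_family(self):
        reads = _reads(self.FAMS["miR166-a"], mult=[4])
        out = srna.mirna_family_assign(reads, self.FAMS)
        assert out.to_dict() == {"miR166": 4}

    def test_equal_match_to_two_families_is_unassigned(self):
        fams = {"famA-1": "A" * 21, "famB-1": "A" * 21}
        reads = _reads("A" * 21)
        out = srna.mirna_family_assign(reads, fams)
        assert out.empty

    def test_planted_mixture_recovered_exactly(self):
        rng = np.random.default_rng(41)
        rows, expected = [], {}
        for fam, seq in self.FAMS.items():
            name = fam.split("-")[0].split("_")[0]
            n = int(rng.integers(2, 6))
            rows += [seq] * n
            expected[name] = expected.get(name, 0) + n
        out = srna.mirna_family_assign(_reads(*rows), self.FAMS)
        assert out.to_dict() == expected

    def test_one_mismatch_still_assigned(self):
        seq = self.FAMS["miR319"]
        mutated = "A" + seq[1:]
        out = srna.mirna_family_assign(_reads(mutated), self.FAMS)
        assert out.to_dict() == {"miR319": 1}
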