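import numpy as np
import pandas as pd
import pytest

from meiolnc import quant
from meiolnc.config import SynthConfig
from meiolnc.synth import gen_counts
from oracles import nb_exact_oracle, proportion_z_oracle


class TestTpm:
    def test_equal_counts_and_lengths_split_evenly(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        lengths = pd.Series({"a": 500, "b": 500})
        out = quant.tpm(counts, lengths)
        assert out["s"].tolist() == [5e5, 5e5]

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (30, 4)),
                              index=[f"g{i}" for i in range(30)])
        lengths = pd.Series(rng.integers(200, 2000, 30),
                            index=counts.index)
        out = quant.tpm(counts, lengths)
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_length_normalization_hand_case(self):
        counts = pd.DataFrame({"s": [10, 20]}, index=["a", "b"])
        lengths = pd.Series({"a": 100, "b": 400})
        out = quant.tpm(counts, lengths)["s"]
        assert out["a"] == pytest.approx(666666.6667, abs=0.01)
        assert out["b"] == pytest.approx(333333.3333, abs=0.01)

    def test_missing_length_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["a"])
        with pytest.raises(ValueError):
            quant.tpm(counts, pd.Series({"b": 100}))


class TestDetection:
    def _counts(self):
        counts = pd.DataFrame({"d1": [0, 2, 0], "d2": [0, 2, 1],
                               "w1": [0, 0, 5], "w2": [0, 0, 0]},
                              index=["g0", "g1", "g2"])
        groups = pd.Series({"d1": "dom", "d2": "dom",
                            "w1": "wild", "w2": "wild"})
        return counts, groups

    def test_zero_everywhere_undetected(self):
        counts, groups = self._counts()
        det = quant.detect(counts, groups)
        assert not det.loc["g0"].any()

    def test_single_read_detected_at_default(self):
        counts, groups = self._counts()
        det = quant.detect(counts, groups)
        assert det.loc["g2", "wild"]

    def test_threshold_sums_replicates(self):
        counts, groups = self._counts()
        det = quant.detect(counts, groups, min_count=5)
        assert not det.loc["g1", "dom"]  # 2 + 2 < 5
        assert det.loc["g2", "wild"]  # 5 + 0 >= 5


class TestVenn:
    def test_all_detected_everywhere_is_triple_region(self):
        det = pd.DataFrame(True, index=[f"g{i}" for i in range(7)],
                           columns=["a", "b", "c"])
        venn = quant.venn_partition(det)
        assert venn["a&b&c"] == 7
        assert venn.sum() == 7

    def test_planted_regions_recovered_exactly(self):
        regions = {
            (True, False, False): 3, (False, True, False): 2,
            (False, False, True): 5, (True, True, False): 7,
            (True, False, True): 1, (False, True, True): 4,
            (True, True, True): 11,
        }
        rows, idx = [], []
        n = 0
        for pattern, count in regions.items():
            for _ in range(count):
                rows.append(pattern)
                idx.append(f"g{n}")
                n += 1
        det = pd.DataFrame(rows, index=idx, columns=["a", "b", "c"])
        venn = quant.venn_partition(det)
        assert venn["a"] == 3 and venn["b&c"] == 4 and venn["a&b&c"] == 11
        assert venn.sum() == sum(regions.values())

    def test_requires_three_groups(self):
        det = pd.DataFrame(True, index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            quant.venn_partition(det)


def test_exclusivity_three_way_classification():
    meio = pd.Series({"a": True, "b": True, "c": False, "d": False})
    soma = pd.Series({"a": False, "b": True, "c": True, "d": False})
    out = quant.exclusivity(meio, soma)
    assert out["a"] == "meiocyte-exclusive"
    assert out["b"] == "shared"
    assert out["c"] == "somatic-only"
    assert out["d"] == "undetected"


class TestMissingGenes:
    def test_no_singletons_gives_zero(self):
        counts = pd.DataFrame({"s": [5, 8, 10]})
        est, _ = quant.estimate_missing_genes(counts)
        assert est == 0.0

    def test_chao_formula_hand_case(self):
        counts = pd.DataFrame({"s": [1, 1, 2, 50]})
        est, _ = quant.estimate_missing_genes(counts)
        assert est == 2.0  # f1=2, f2=1 -> 4/2

    def test_deep_sampling_estimates_zero_with_tight_ci(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame({"s1": rng.poisson(200, 500),
                               "s2": rng.poisson(200, 500)})
        est, (lo, hi) = quant.estimate_missing_genes(counts, seed=1)
        assert est == 0.0
        assert hi <= 3.0


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 500, 300)
        counts = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(quant.tmm_factors(counts), 1.0)

    def test_depth_scaling_absorbed_by_library_size(self):
        """Doubling a column's depth leaves its composition factor at ~1
        while doubling the effective library size."""
        rng = np.random.default_rng(3)
        col = rng.integers(1, 500, 2000)
        counts = pd.DataFrame({"a": col, "b": col * 2})
        f = quant.tmm_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(1.0, rel=0.01)
        eff = counts.sum() * f
        assert eff["b"] / eff["a"] == pytest.approx(2.0, rel=0.01)

    def test_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, (500, 4)),
            columns=list("abcd")) + 1
        f = quant.tmm_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


class TestExactTest:
    def test_equal_counts_equal_sizes_give_p_one(self):
        assert quant.nb_exact_test(17, 17, 0.1, 2, 2) == pytest.approx(1.0)

    def test_poisson_limit_equals_binomial_enumeration(self):
        from scipy import stats
        pmf = stats.binom.pmf(np.arange(11), 10, 0.5)
        expected = pmf[pmf <= pmf[0] + 1e-15].sum()
        assert quant.nb_exact_test(0, 10, 0.0, 1, 1) == \
            pytest.approx(expected)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.3, 1.0])
    @pytest.mark.parametrize("na,nb", [(1, 1), (2, 2), (1, 3)])
    def test_matches_conditional_enumeration_all_small_totals(self, phi,
                                                              na, nb):
        for s in range(1, 31):
            for ya in range(s + 1):
                got = quant.nb_exact_test(ya, s - ya, phi, na, nb)
                want = nb_exact_oracle(ya, s - ya, phi, na, nb)
                assert got == pytest.approx(want, abs=1e-9), (phi, na, nb,
                                                              ya, s)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            quant.nb_exact_test(-1, 3, 0.1)

    def test_label_swap_preserves_p_and_negates_log_fold_change(self):
        cfg = SynthConfig(seed=13, de_fraction=0.2, library_size=50_000)
        counts, meta, _ = gen_counts([f"g{i}" for i in range(80)], cfg)
        a = meta.index[(meta["genotype"] == "domesticated")
                       & (meta["tissue"] == "meiocyte")].tolist()
        b = meta.index[meta["genotype"] == "wild"].tolist()
        p_ab, disp = quant.exact_test_matrix(counts, a, b)
        p_ba, _ = quant.exact_test_matrix(counts, b, a, dispersion=disp)
        assert np.allclose(p_ab, p_ba)
        lfc_ab = quant.log2_fold_changes(counts, a, b)
        lfc_ba = quant.log2_fold_changes(counts, b, a)
        assert np.allclose(lfc_ab, -lfc_ba)


def test_common_dispersion_recovers_simulated_value():
    rng = np.random.default_rng(19)
    phi = 0.2
    r = 1.0 / phi
    mu = rng.lognormal(4, 1, 2000)
    y = rng.negative_binomial(r, r / (r + mu[:, None]), (2000, 4))
    counts = pd.DataFrame(y, columns=["a1", "a2", "b1", "b2"])
    est = quant.estimate_common_dispersion(counts, ["a1", "a2"],
                                           ["b1", "b2"])
    assert 0.15 <= est <= 0.25


class TestFdr:
    def test_all_ones_flag_nothing(self):
        out = quant.fdr_control(pd.Series(np.ones(50)))
        assert not out["de_flag"].any()
        assert (out["q_value"] == 1.0).all()

    def test_bh_fallback_hand_computation(self):
        p = pd.Series([1e-4] * 10 + [1.0] * 89)
        out = quant.fdr_control(p, level=0.01)
        # m < 100 -> BH with pi0 = 1: q(10th) = 1e-4 * 99/10 < 0.01
        assert out["de_flag"].sum() == 10
        assert out.loc[0, "q_value"] == pytest.approx(1e-4 * 99 / 10)

    def test_q_monotone_in_ranked_p(self):
        rng = np.random.default_rng(7)
        p = pd.Series(rng.uniform(0, 1, 500) ** 2)
        out = quant.fdr_control(p)
        ranked = out.sort_values("p_value")["q_value"].to_numpy()
        assert (np.diff(ranked) >= -1e-12).all()

    def test_storey_pi0_near_one_on_null(self):
        rng = np.random.default_rng(11)
        p = pd.Series(rng.uniform(0, 1, 5000))
        out = quant.fdr_control(p)
        assert 0.85 <= out.attrs["pi0"] <= 1.0

    def test_invalid_p_values_rejected(self):
        with pytest.raises(ValueError):
            quant.fdr_control(pd.Series([0.5, 1.2]))


class TestDePowerProperty:
    def test_planted_effects_recovered_with_controlled_fdr(self):
        """log2 effect 2 at 10% DE fraction: >= 70% power, FDR <= 5%."""
        cfg = SynthConfig(seed=23, de_fraction=0.1, log2_effect=2.0,
                          library_size=1_000_000, nb_dispersion=0.05)
        genes = [f"g{i}" for i in range(2000)]
        counts, meta, truth = gen_counts(genes, cfg)
        a = meta.index[(meta["genotype"] == "domesticated")
                       & (meta["tissue"] == "meiocyte")].tolist()
        b = meta.index[meta["genotype"] == "wild"].tolist()
        res = quant.differential_expression(counts, a, b, level=0.01)
        flags = res.table["de_flag"]
        true_de = truth["true_DE"]
        power = flags[true_de].mean()
        fdr = (flags & ~true_de).sum() / max(1, flags.sum())
        assert power >= 0.7
        assert fdr <= 0.05


class TestProportionTest:
    def test_identical_proportions_give_p_one(self):
        assert quant.proportion_test(5, 50, 10, 100) == 1.0
        assert quant.proportion_test(50, 100, 50, 100) == 1.0

    def test_matches_closed_form_z(self):
        got = quant.proportion_test(60, 100, 40, 100)
        assert got == pytest.approx(proportion_z_oracle(60, 100, 40, 100),
                                    rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            quant.proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            quant.proportion_test(11, 10, 1, 10)
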