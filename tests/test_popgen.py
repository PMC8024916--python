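"""Allotype classification, frequency/diplotype tables, ERAP2 calling."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eraptype import catalog as catalog_mod
from eraptype.popgen import (
    PhasedPanel,
    call_erap2,
    classify_haplotype,
    cross_tabulate,
    diplotype_table,
    expected_cooccurrence,
    filter_polymorphic_sites,
    allotype_frequencies,
    pair_key,
    random_pairing_simulation,
)

ERAP1_ALLELES = {
    12: "MT", 56: "EK", 127: "PR", 276: "IM", 346: "GD",
    349: "MV", 528: "KR", 575: "DN", 725: "RQ", 730: "QE",
}


class TestSiteFilter:
    def test_signal_peptide_exclusion_leaves_nine_canonical_sites(self):
        freqs = {p: 0.05 for p in ERAP1_ALLELES}
        sites = filter_polymorphic_sites(
            freqs, 0.01, excluded_positions={12}, alleles=ERAP1_ALLELES
        )
        assert sites.positions == (56, 127, 276, 346, 349, 528, 575, 725, 730)

    def test_below_cutoff_site_dropped(self):
        freqs = {56: 0.005, 127: 0.3}
        sites = filter_polymorphic_sites(freqs, 0.01, alleles=ERAP1_ALLELES)
        assert sites.positions == (127,)

    def test_zero_cutoff_no_exclusions_is_identity(self):
        freqs = {p: 0.05 for p in ERAP1_ALLELES}
        sites = filter_polymorphic_sites(freqs, 0.0, alleles=ERAP1_ALLELES)
        assert sites.positions == tuple(freqs)

    def test_empty_result_is_an_error(self):
        with pytest.raises(ValueError, match="no polymorphic sites"):
            filter_polymorphic_sites({56: 0.001}, 0.01, alleles=ERAP1_ALLELES)


class TestClassify:
    @pytest.mark.parametrize(
        "hap,label", [("ERIGMKDRQ", "2"), ("EPIGVRNQE", "10"), ("EPMGMRDRE", "8")]
    )
    def test_known_haplotypes(self, cat, hap, label):
        assert classify_haplotype(hap, cat) == label

    def test_catalog_round_trip_is_identity(self, cat):
        for label in cat.labels:
            assert classify_haplotype(cat.haplotype(label), cat) == label

    def test_non_catalog_haplotype_is_unassigned(self, cat):
        # exhaustive check: differs from every catalog entry
        hap = "EPIGMKDRE"
        assert all(hap != entry for entry in cat.entries)
        assert classify_haplotype(hap, cat) == "unassigned"

    def test_length_mismatch_raises(self, cat):
        with pytest.raises(ValueError, match="length"):
            classify_haplotype("ERIG", cat)

    def test_alien_residue_rejected_with_sites(self, cat, erap1_sites):
        with pytest.raises(ValueError, match="allele set"):
            classify_haplotype("XRIGMKDRQ", cat, sites=erap1_sites)


class TestFrequencies:
    def test_single_homozygous_sample_is_100_percent(self, cat):
        hap = cat.haplotype("2")
        panel = PhasedPanel(["s"], ["EUR"], [hap], [hap])
        table = allotype_frequencies(panel, cat)
        assert table.percent().loc["2", "ALL"] == 100.0

    def test_toy_panel_matches_hand_count(self, cat, toy_panel):
        table = allotype_frequencies(toy_panel, cat)
        # independent brute-force chromosome count
        expected = Counter()
        for pop, hap in toy_panel.chromosomes():
            expected[cat.entries.get(hap, "unassigned")] += 1
        for label, n in expected.items():
            assert table.counts.loc[label, "ALL"] == n
        assert table.chromosomes["ALL"] == 20

    def test_population_columns_sum_to_100(self, cat, toy_panel):
        pct = allotype_frequencies(toy_panel, cat).percent()
        assert np.allclose(pct.sum(axis=0), 100.0, atol=0.3)

    def test_empty_panel_rejected(self, cat):
        with pytest.raises(ValueError):
            allotype_frequencies(PhasedPanel([], [], [], []), cat)


class TestDiplotypes:
    def test_unordered_pairs_share_a_key(self, cat):
        h2, h8 = cat.haplotype("2"), cat.haplotype("8")
        panel = PhasedPanel(["a", "b"], ["EUR"] * 2, [h8, h2], [h2, h8])
        table = diplotype_table(panel, cat)
        assert table.counts == {("2", "8"): 2}

    def test_homozygous_panel_has_only_diagonal_keys(self, cat):
        haps = [cat.haplotype(l) for l in ("1", "5", "5")]
        panel = PhasedPanel(["a", "b", "c"], ["EUR"] * 3, haps, haps)
        table = diplotype_table(panel, cat)
        assert set(table.counts) == {("1", "1"), ("5", "5")}

    def test_toy_panel_matches_brute_force(self, cat, toy_panel):
        table = diplotype_table(toy_panel, cat)
        brute = Counter()
        for h1, h2 in zip(toy_panel.hap1, toy_panel.hap2):
            lab = sorted(
                (cat.entries.get(h1, "unassigned"), cat.entries.get(h2, "unassigned")),
                key=lambda x: (0, int(x)) if x.isdigit() else (1, x),
            )
            brute[tuple(lab)] += 1
        assert table.counts == dict(brute)
        assert sum(table.counts.values()) == toy_panel.n_samples

    @given(st.lists(st.sampled_from(["1", "2", "8", "10"]), min_size=2, max_size=40))
    def test_counts_always_sum_to_sample_count(self, labels):
        cat = catalog_mod.load_catalog()
        if len(labels) % 2:
            labels = labels + ["2"]
        haps = [cat.haplotype(l) for l in labels]
        n = len(haps) // 2
        panel = PhasedPanel(
            [f"s{i}" for i in range(n)], ["ALL"] * n, haps[:n], haps[n:]
        )
        table = diplotype_table(panel, cat)
        assert sum(table.counts.values()) == n
        assert all(k == pair_key(*k) for k in table.counts)


class TestExpectedCooccurrence:
    def test_product_mode_arithmetic(self):
        # 25.6% x 21.8% -> 5.6%
        pct = round(100 * expected_cooccurrence(0.256, 0.218, "product"), 1)
        assert pct == 5.6

    def test_hwe_mode_distinct_is_2pq(self):
        assert expected_cooccurrence(0.256, 0.218, "hwe") == pytest.approx(0.111616)

    def test_hwe_mode_identical_is_p_squared(self):
        assert expected_cooccurrence(0.3, 0.3, "hwe", identical=True) == pytest.approx(0.09)

    def test_zero_frequency_gives_zero(self):
        assert expected_cooccurrence(0.0, 0.5, "product") == 0.0


class TestRandomPairing:
    def test_same_seed_reproduces_table(self):
        freqs = {"2": 0.256, "8": 0.218, "rest": 0.526}
        t1 = random_pairing_simulation(freqs, 500, seed=9)
        t2 = random_pairing_simulation(freqs, 500, seed=9)
        assert t1.counts == t2.counts

    def test_degenerate_frequency_vector(self):
        table = random_pairing_simulation({"2": 1.0}, 50, seed=0)
        assert table.counts == {("2", "2"): 50}

    def test_mean_pair_frequency_matches_hwe_expectation(self):
        freqs = {"a": 0.3, "b": 0.2, "c": 0.5}
        n = 400
        het, hom = [], []
        for seed in range(200):
            table = random_pairing_simulation(freqs, n, seed=seed)
            het.append(table.frequency(("a", "b")))
            hom.append(table.frequency(("a", "a")))
        for observed, expected in [
            (het, 2 * 0.3 * 0.2),
            (hom, 0.3**2),
        ]:
            observed = np.asarray(observed)
            mc_se = observed.std(ddof=1) / np.sqrt(len(observed))
            assert abs(observed.mean() - expected) < 3 * mc_se + 1e-12


class TestErap2:
    def test_haplotype_labelling(self):
        panel = PhasedPanel(["s"], ["ALL"], ["GA"], ["TG"])
        calls = call_erap2(panel)
        assert calls.calls == [("A", "B")]
        assert calls.expression_null == [False]

    def test_all_bb_panel_is_fully_expression_null(self):
        panel = PhasedPanel(["a", "b"], ["ALL"] * 2, ["TG", "TG"], ["TG", "TG"])
        calls = call_erap2(panel)
        assert calls.null_fraction() == 1.0
        assert calls.haplotype_frequencies() == {"B": 1.0}

    def test_unlisted_combination_is_other(self):
        # neither GG nor TA is a catalogued ERAP2 haplotype
        calls = call_erap2(PhasedPanel(["s"], ["ALL"], ["GG"], ["TA"]))
        assert calls.calls == [("other", "other")]

    def test_mixed_panel_matches_hand_count(self):
        hap1 = ["GA", "GA", "TG", "TG", "GA", "TG", "GA", "TG", "GA", "TG"]
        hap2 = ["GA", "TG", "TG", "GA", "GA", "TG", "TG", "TG", "GA", "GA"]
        panel = PhasedPanel(
            [f"s{i}" for i in range(10)], ["ALL"] * 10, hap1, hap2
        )
        calls = call_erap2(panel)
        # hand count: GA appears 5 times in hap1 and 5 in hap2; samples
        # 2, 5 and 7 are TG/TG and therefore expression-null
        assert calls.haplotype_frequencies()["A"] == pytest.approx(10 / 20)
        assert calls.null_fraction() == pytest.approx(3 / 10)


class TestCrossTab:
    def test_single_class_conditional_equals_marginal(self):
        pairs = {"s1": ("2", "8"), "s2": ("2", "2"), "s3": ("8", "8")}
        classes = {s: "A/A" for s in pairs}
        ct = cross_tabulate(pairs, classes)
        assert np.allclose(ct.percent["A/A"], ct.percent["ALL"])

    def test_toy_matches_brute_force(self):
        pairs = {
            "s1": ("8", "8"), "s2": ("8", "8"), "s3": ("2", "2"),
            "s4": ("2", "8"), "s5": ("2", "8"), "s6": ("2", "2"),
        }
        classes = {
            "s1": "A/A", "s2": "A/A", "s3": "B/B",
            "s4": "A/B", "s5": "A/B", "s6": "B/B",
        }
        ct = cross_tabulate(pairs, classes)
        assert ct.percent.loc["8/8", "A/A"] == 100.0
        assert ct.percent.loc["2/2", "B/B"] == 100.0
        assert ct.counts["ALL"].sum() == 6
        assert np.allclose(ct.percent.sum(axis=0), 100.0)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different sample sets"):
            cross_tabulate({"s1": ("2", "8")}, {"s2": "A/A"})
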