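"""Tier counting, Venn partitions, percentages, and cross-compartment hits."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cilicopd.concordance import (
    common_gene_table,
    cross_compartment_hits,
    direction_consistent_membership,
    percent_of_geneset,
    tier_counts,
)
from cilicopd.geneset import merge_sources

from .conftest import de_results_from_sig_sets, sig_sets_with_tier_profile


def geneset_with_flags(plain, ciliopathy):
    return merge_sources(
        [
            ("uniprot_cilia", [(s, "", "") for s in plain]),
            ("uniprot_ciliopathy", [(s, "", "") for s in ciliopathy]),
        ]
    )


class TestTierCounts:
    def test_single_dataset(self):
        summary = tier_counts({"D1": {"A", "B"}})
        assert summary.tier_counts == {1: 2}
        assert summary.venn == {("D1",): 2}

    def test_three_nested_sets(self):
        summary = tier_counts(
            {"S1": {"A", "B", "C"}, "S2": {"B", "C"}, "S3": {"C"}}
        )
        assert summary.tier_counts == {1: 3, 2: 2, 3: 1}
        assert summary.venn == {
            ("S1",): 1,
            ("S1", "S2"): 1,
            ("S1", "S2", "S3"): 1,
        }
        assert summary.membership["B"] == {"S1", "S2"}

    def test_empty_sets_allowed(self):
        summary = tier_counts({"D1": set(), "D2": set()})
        assert summary.tier_counts == {1: 0, 2: 0}
        assert summary.venn == {}

    def test_printed_tier_profile_reconstructed(self):
        """A 4-dataset instance built to the published whole-lung profile
        (279 genes in >=1, 100 in >=2, 14 in >=3) recounts exactly."""
        sig = sig_sets_with_tier_profile(4, {1: 179, 2: 86, 3: 13, 4: 1}, seed=11)
        summary = tier_counts(sig, geneset_size=350)
        counts = summary.tier_counts
        assert (counts[1], counts[2], counts[3]) == (279, 100, 14)
        # brute-force re-count from raw sets
        genes = set().union(*sig.values())
        for k in range(1, 5):
            brute = sum(
                1 for g in genes if sum(g in s for s in sig.values()) >= k
            )
            assert counts[k] == brute

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(25):
            n_ds = int(rng.integers(1, 7))
            n_genes = int(rng.integers(1, 200))
            genes = [f"G{i}" for i in range(n_genes)]
            sig = {
                f"D{d}": {g for g in genes if rng.random() < 0.3}
                for d in range(n_ds)
            }
            summary = tier_counts(sig)
            counts = summary.tier_counts
            venn = summary.venn
            # tiers agree with per-gene membership counting
            for k in range(1, n_ds + 1):
                brute = sum(
                    1 for g in genes if sum(g in s for s in sig.values()) >= k
                )
                assert counts[k] == brute
            # venn regions partition the tier-1 genes
            assert sum(venn.values()) == counts[1]
            assert len(venn) <= 2**n_ds - 1
            for k in range(1, n_ds + 1):
                assert counts[k] == sum(
                    v for region, v in venn.items() if len(region) >= k
                )

    def test_tier_counts_non_increasing(self, rng):
        sig = {f"D{d}": {f"G{i}" for i in rng.integers(0, 50, 20)} for d in range(4)}
        counts = tier_counts(sig).tier_counts
        values = [counts[k] for k in sorted(counts)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_requires_at_least_one_dataset(self):
        with pytest.raises(ValueError):
            tier_counts({})


class TestPercentOfGeneset:
    @pytest.mark.parametrize(
        "count,size,decimals,expected",
        [
            (100, 350, 0, 29),
            (14, 350, 0, 4),
            (279, 350, 0, 80),
            (10, 399, 1, 2.5),
            (100, 399, 0, 25),
            (12, 189, 0, 6),
            (88, 189, 0, 47),
            (0, 350, 0, 0),
        ],
    )
    def test_half_up_rounding(self, count, size, decimals, expected):
        assert percent_of_geneset(count, size, decimals) == expected

    def test_half_up_not_bankers(self):
        assert percent_of_geneset(1, 8, 0) == 13  # 12.5 rounds up

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            percent_of_geneset(1, 0)
        with pytest.raises(ValueError):
            percent_of_geneset(5, 3)


class TestCrossCompartment:
    def summaries(self, lung_sig, saec_sig):
        return (
            tier_counts(lung_sig, compartment="lung"),
            tier_counts(saec_sig, compartment="saec"),
        )

    def test_empty_saec_membership_gives_no_hits(self):
        lung, saec = self.summaries(
            {"L1": {"A"}, "L2": {"A"}}, {"S1": set(), "S2": set()}
        )
        gs = geneset_with_flags(["A"], [])
        assert cross_compartment_hits(lung, saec, gs).hits == set()

    def test_thresholds_applied_per_compartment(self):
        lung, saec = self.summaries(
            {"L1": {"A", "B"}, "L2": {"A"}},
            {"S1": {"A", "B"}, "S2": {"B"}},
        )
        gs = geneset_with_flags(["A"], ["B"])
        res = cross_compartment_hits(lung, saec, gs, lung_min=2, saec_min=1)
        assert res.hits == {"A"}
        assert res.ciliopathy_hits == set()
        assert res.union_deregulated == {"A", "B"}
        assert res.ciliopathy_union == {"B"}

    def test_monotone_in_thresholds(self, rng):
        lung_sig = {f"L{d}": {f"G{i}" for i in rng.integers(0, 60, 25)} for d in range(4)}
        saec_sig = {f"S{d}": {f"G{i}" for i in rng.integers(0, 60, 25)} for d in range(3)}
        lung, saec = self.summaries(lung_sig, saec_sig)
        gs = geneset_with_flags([f"G{i}" for i in range(60)], [])
        prev = cross_compartment_hits(lung, saec, gs, lung_min=1, saec_min=1).hits
        for lung_min in (2, 3, 4):
            cur = cross_compartment_hits(lung, saec, gs, lung_min=lung_min).hits
            assert cur <= prev
            prev = cur

    def test_compartment_labels_checked(self):
        lung, saec = self.summaries({"L1": set()}, {"S1": set()})
        gs = geneset_with_flags(["A"], [])
        with pytest.raises(ValueError):
            cross_compartment_hits(saec, lung, gs)

    def test_ciliopathy_summary_percentages(self):
        lung, saec = self.summaries(
            {"L1": {"A", "B"}, "L2": {"A", "B"}}, {"S1": {"A", "B"}}
        )
        gs = geneset_with_flags(["X"] * 0 + ["P"], ["A", "B"])
        res = cross_compartment_hits(lung, saec, gs)
        summary = res.summary(n_ciliopathy=2)
        assert summary["n_hits"] == 2
        assert summary["pct_ciliopathy_hits"] == 100


class TestCommonGeneTable:
    def test_disjoint_lung_and_saec_lists_concatenate(self):
        """Exactly 14 genes at >=3 of 4 lung datasets plus a disjoint 10 at
        >=2 of 3 SAEC datasets give a 24-row table."""
        lung_sig = sig_sets_with_tier_profile(4, {3: 13, 4: 1}, seed=5, prefix="L")
        saec_sig = sig_sets_with_tier_profile(3, {2: 7, 3: 3}, seed=6, prefix="S")
        lung = tier_counts(lung_sig, compartment="lung")
        saec = tier_counts(saec_sig, compartment="saec")
        de = de_results_from_sig_sets(lung_sig, "lung") + de_results_from_sig_sets(
            saec_sig, "saec"
        )
        table = common_gene_table(lung, saec, de, lung_min=3, saec_min=2)
        assert len(table) == 24
        assert (table.compartment == "lung").sum() == 14
        assert (table.compartment == "saec").sum() == 10

    def test_empty_significance_gives_empty_table(self):
        lung = tier_counts({"L1": set(), "L2": set()}, compartment="lung")
        saec = tier_counts({"S1": set(), "S2": set()}, compartment="saec")
        de = de_results_from_sig_sets(
            {"L1": set(), "L2": set()}, "lung"
        ) + de_results_from_sig_sets({"S1": set(), "S2": set()}, "saec")
        assert len(common_gene_table(lung, saec, de)) == 0

    def test_gene_significant_everywhere_flagged_fully_concordant(self):
        lung_sig = {f"L{d}": {"NEK6"} for d in range(1, 5)}
        lung_sig["L1"].add("PART")
        lung_sig["L2"].add("PART")
        lung_sig["L3"].add("PART")
        saec_sig = {f"S{d}": set() for d in range(1, 4)}
        lung = tier_counts(lung_sig, compartment="lung")
        saec = tier_counts(saec_sig, compartment="saec")
        de = de_results_from_sig_sets(lung_sig, "lung") + de_results_from_sig_sets(
            saec_sig, "saec"
        )
        table = common_gene_table(lung, saec, de, lung_min=3, saec_min=2)
        flags = dict(zip(table.gene, table.fully_concordant))
        assert flags == {"NEK6": True, "PART": False}
        # non-significant cells are blank
        row = table[table.gene == "PART"].iloc[0]
        assert np.isnan(row["L4"])


def test_direction_consistent_variant_drops_minority_sign():
    sig = {"L1": {"A"}, "L2": {"A"}, "L3": {"A"}}
    de = de_results_from_sig_sets(sig, "lung")
    # flip the sign of A in one dataset
    res = de[0].results["A"]
    de[0].results["A"] = type(res)(
        gene="A", log2fc=-0.5, log10_ratio=0.1, t_stat=-3.0, df=50.0, p=0.01,
        q=0.04, significant=True, n_copd=30, n_noncopd=30,
    )
    summary = tier_counts(sig, compartment="lung")
    strict = direction_consistent_membership(summary, de)
    assert len(strict.membership["A"]) == 2
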