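"""Community profiling, Bray-Curtis/UPGMA clustering and environmental tests."""

import numpy as np
import pandas as pd
import pytest

from synrecruit import community
from synrecruit.community import (
    aggregate_by_clade,
    bray_curtis,
    build_count_table,
    compare_clusters_env,
    cut_clusters,
    filter_stations,
    length_normalize,
    relative_abundance,
    upgma,
)
from synrecruit.errors import ConfigurationError, ValidationError
from synrecruit.recruitment import ReadAssignment


def assignments_at(tree, taxon_ids):
    return [
        ReadAssignment(f"r{i}", tree.node(t), 1) for i, t in enumerate(taxon_ids)
    ]


# ---------------------------------------------------------------------------
# Aggregation and normalization
# ---------------------------------------------------------------------------


class TestAggregation:
    def test_strain_and_subclade_roll_up_to_clade(self, tree):
        row = aggregate_by_clade(
            assignments_at(tree, ["CC9311"] * 3 + ["Ib"] * 2), tree, "S1"
        )
        assert row["I"] == 5

    def test_subcluster_and_genus_categories(self, tree):
        row = aggregate_by_clade(
            assignments_at(tree, ["5.1", "Synechococcus", "WH5701", "RCC307"]),
            tree, "S1",
        )
        assert row["5.1"] == 1 and row["Syn"] == 1
        assert row["5.2"] == 1 and row["5.3"] == 1

    def test_matches_brute_force_tally(self, tree, rng):
        taxa = ["CC9311", "ROS8604", "Ia", "I", "II", "5.1",
                "Synechococcus", "WH5701", "RS9915"]
        picks = [taxa[i] for i in rng.integers(0, len(taxa), size=200)]
        row = aggregate_by_clade(assignments_at(tree, picks), tree, "S1")

        def oracle_category(tid):
            ranks = {n.rank: n.id for n in tree.node(tid).path()}
            return ranks.get("clade") or ranks.get("subcluster") or "Syn"

        expected = pd.Series([oracle_category(t) for t in picks]).value_counts()
        for cat in expected.index:
            assert row[cat] == expected[cat]
        assert row.sum() == 200

    def test_length_normalize_arithmetic(self, tree):
        # 250 reads over a 2.5-Mbp mean genome -> 100 reads/Mbp
        table = pd.DataFrame({"5.2": [286.0]}, index=["S1"])
        out = length_normalize(table, tree)  # WH5701 genome = 2.86 Mbp
        assert out.loc["S1", "5.2"] == pytest.approx(100.0)

    def test_normalization_favors_smaller_genomes(self, tree):
        table = pd.DataFrame({"5.2": [100.0], "5.3": [100.0]}, index=["S1"]).T
        out = length_normalize(table.T, tree)
        # 5.3 genome (2.22 Mbp) < 5.2 genome (2.86 Mbp)
        assert out.loc["S1", "5.3"] > out.loc["S1", "5.2"]

    def test_normalize_equals_elementwise_oracle(self, tree, rng):
        cats = ["I", "II", "III", "IV", "5.2"]
        table = pd.DataFrame(
            rng.integers(0, 500, size=(4, len(cats))).astype(float),
            index=[f"S{i}" for i in range(4)], columns=cats,
        )
        out = length_normalize(table, tree)
        for cat in cats:
            strains = tree.strains_under(cat)
            mean_mbp = np.mean([tree.strain(s).genome_length for s in strains]) / 1e6
            assert np.allclose(out[cat], table[cat] / mean_mbp)

    def test_unknown_category_raises(self, tree):
        with pytest.raises((ConfigurationError, KeyError)):
            length_normalize(pd.DataFrame({"XX": [1.0]}, index=["S1"]), tree)


class TestFilterAndProfiles:
    def test_density_floor_is_inclusive(self):
        table = pd.DataFrame(
            {"I": [650.0, 600.0, 599.0]}, index=["a", "b", "c"]
        )
        kept, removed = filter_stations(table, 600.0)
        assert list(kept.index) == ["a", "b"] and removed == ["c"]

    def test_empty_table_passes_through(self):
        table = pd.DataFrame(columns=["I"]).astype(float)
        kept, removed = filter_stations(table)
        assert kept.empty and removed == []

    def test_relative_abundance_rows_sum_to_one_and_scale_invariant(self):
        table = pd.DataFrame({"I": [30.0, 5.0], "II": [70.0, 15.0]},
                             index=["a", "b"])
        prof = relative_abundance(table)
        assert prof.loc["a", "I"] == pytest.approx(0.3)
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(relative_abundance(table * 10).values, prof.values)

    def test_zero_total_station_excluded_with_warning(self):
        table = pd.DataFrame({"I": [10.0, 0.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="zero-total"):
            prof = relative_abundance(table)
        assert list(prof.index) == ["a"]


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


class TestBrayCurtis:
    def test_hand_values(self):
        prof = pd.DataFrame(
            [[0.5, 0.5, 0.0], [1.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]],
            index=list("abcd"),
        )
        d = bray_curtis(prof)
        assert d.loc["a", "b"] == pytest.approx(0.5)
        assert d.loc["a", "c"] == pytest.approx(0.0)   # identical profiles
        assert d.loc["a", "d"] == pytest.approx(1.0)   # disjoint support

    def test_properties_on_random_profiles(self, rng):
        profiles = pd.DataFrame(rng.random(size=(30, 6)))
        d = bray_curtis(profiles).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d.min() >= 0.0 and d.max() <= 1.0 + 1e-12

    def test_all_zero_profile_rejected(self):
        prof = pd.DataFrame([[0.0, 0.0], [1.0, 0.0]], index=["a", "b"])
        with pytest.raises(ValidationError):
            bray_curtis(prof)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def brute_force_upgma_heights(d: np.ndarray) -> list[float]:
    """O(n^3) oracle: clusters as explicit leaf sets; inter-cluster distance
    recomputed each round as the mean over all original leaf pairs."""
    clusters = [frozenset([i]) for i in range(len(d))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def random_distance_matrix(rng, n):
    x = rng.random(size=(n, n))
    d = (x + x.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=[f"S{i}" for i in range(n)],
                        columns=[f"S{i}" for i in range(n)])


class TestUPGMA:
    def test_two_stations_single_merge(self):
        d = pd.DataFrame([[0.0, 0.3], [0.3, 0.0]], index=["a", "b"], columns=["a", "b"])
        dend = upgma(d)
        assert len(dend.merges) == 1 and dend.merges[0][2] == pytest.approx(0.3)

    def test_three_station_hand_example(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        dend = upgma(d)
        assert list(dend.heights) == pytest.approx([0.1, 0.4])
        labels = cut_clusters(dend, height=0.2)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(40):
            d = random_distance_matrix(rng, 8)
            dend = upgma(d)
            oracle = brute_force_upgma_heights(d.to_numpy())
            assert np.allclose(dend.heights, oracle, atol=1e-12)

    def test_heights_non_decreasing_and_cophenetic_consistent(self, rng):
        d = random_distance_matrix(rng, 10)
        dend = upgma(d)
        assert np.all(np.diff(dend.heights) >= -1e-12)
        coph = dend.cophenetic()
        # cophenetic distance of the first merged pair equals its height
        left, right, h0, _ = dend.merges[0]
        assert coph.iloc[left, right] == pytest.approx(h0)

    def test_nan_rejected(self):
        d = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValidationError):
            upgma(d)

    def test_tie_break_is_deterministic(self):
        # equilateral triangle: every pair at distance 0.2; lexicographically
        # smallest pair (A, B) must merge first
        d = pd.DataFrame(0.2, index=list("CBA"), columns=list("CBA"))
        np.fill_diagonal(d.values, 0.0)
        dend = upgma(d)
        i, j, _, _ = dend.merges[0]
        assert {dend.ids[i], dend.ids[j]} == {"A", "B"}

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        d = random_distance_matrix(np.random.default_rng(0), 6)
        dend = upgma(d)
        t = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == set(dend.ids)
        # leaf depths equal the root merge height (ultrametric tree)
        root_h = dend.heights[-1]
        for leaf in t.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_h, abs=1e-9)


class TestCutClusters:
    @pytest.fixture
    def dend(self, rng):
        return upgma(random_distance_matrix(rng, 7))

    def test_k_equals_n_and_k_equals_one(self, dend):
        assert cut_clusters(dend, k=7).nunique() == 7
        assert cut_clusters(dend, k=1).nunique() == 1

    def test_intermediate_k(self, dend):
        assert cut_clusters(dend, k=3).nunique() == 3

    def test_k_out_of_range_rejected(self, dend):
        with pytest.raises(ValidationError):
            cut_clusters(dend, k=8)
        with pytest.raises(ValidationError):
            cut_clusters(dend, k=2, height=0.5)


# ---------------------------------------------------------------------------
# Environmental comparison
# ---------------------------------------------------------------------------


def make_labels_meta(groups: dict):
    labels, temps, idx = {}, {}, 0
    for cl, values in groups.items():
        for v in values:
            sid = f"S{idx}"
            labels[sid] = cl
            temps[sid] = v
            idx += 1
    labels = pd.Series(labels, name="cluster")
    meta = pd.DataFrame({"temperature_C": pd.Series(temps)})
    return labels, meta


class TestCompareClustersEnv:
    def test_disjoint_ranges_get_distinct_letters(self, rng):
        labels, meta = make_labels_meta(
            {1: rng.uniform(10, 12, 10), 2: rng.uniform(25, 27, 10)}
        )
        report = compare_clusters_env(labels, meta, "temperature_C")
        assert report.testable and report.distinct(1, 2)

    def test_same_distribution_usually_shares_a_letter(self):
        shared = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            labels, meta = make_labels_meta(
                {1: r.normal(20, 2, 10), 2: r.normal(20, 2, 10)}
            )
            report = compare_clusters_env(labels, meta, "temperature_C")
            if not report.distinct(1, 2):
                shared += 1
        assert shared >= 90  # type-I error control at alpha = 0.05

    def test_constant_values_share_one_letter(self):
        labels, meta = make_labels_meta({1: [20.0] * 5, 2: [20.0] * 5, 3: [20.0] * 5})
        report = compare_clusters_env(labels, meta, "temperature_C")
        assert report.h_statistic == 0.0
        assert len(set(report.letters.values())) == 1

    def test_missing_variable_not_testable(self):
        labels, meta = make_labels_meta({1: [1.0, 2.0], 2: [3.0, 4.0]})
        report = compare_clusters_env(labels, meta, "salinity_psu")
        assert not report.testable

    def test_missing_values_dropped_per_variable(self, rng):
        labels, meta = make_labels_meta(
            {1: rng.uniform(10, 12, 6), 2: rng.uniform(25, 27, 6)}
        )
        meta.loc["S0", "temperature_C"] = np.nan
        report = compare_clusters_env(labels, meta, "temperature_C")
        assert report.group_stats.loc[1, "n"] == 5

    def test_three_groups_letter_consistency(self, rng):
        # middle group overlapping both extremes: letters must respect the
        # pairwise significance pattern
        labels, meta = make_labels_meta(
            {
                1: rng.uniform(10, 12, 8),
                2: rng.uniform(11.9, 14, 8),
                3: rng.uniform(25, 27, 8),
            }
        )
        report = compare_clusters_env(labels, meta, "temperature_C")
        for _, row in report.pairwise.iterrows():
            a, b = row["cluster_a"], row["cluster_b"]
            if row["p_adj"] < 0.05:
                assert report.distinct(a, b)
            else:
                assert not report.distinct(a, b)
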