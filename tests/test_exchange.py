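import numpy as np
import pytest

from kleptopop import (
    DistanceMatrix,
    KleptopopError,
    alternative_alleles_per_locus,
    carrier_frequency,
    compare_dispersions,
    detect_divergent_alleles,
    dispersion_partition,
    mutation_steps,
    prob_no_carrier,
    rarefied_allele_count,
    weighted_haplome_count,
    weighted_ploidy_level,
)
from kleptopop.exchange import allele_copy_counts

from conftest import diploid, triploid
from oracles import rarefaction_enumeration


class TestMutationSteps:
    @pytest.mark.parametrize(
        "a, b, expected", [(133, 137, 1), (108, 144, 9), (100, 100, 0)]
    )
    def test_step_counts(self, a, b, expected):
        assert mutation_steps(a, b, 4) == expected


class TestDivergentAlleles:
    def test_isolated_allele_flagged_with_gap(self):
        freqs = {"L1": {100: 0.3, 104: 0.3, 108: 0.3, 144: 0.1}}
        div = detect_divergent_alleles(freqs, {"L1": 4}, gap_threshold=8)
        assert div.flagged["L1"] == {144: 9}

    def test_tight_cluster_unflagged(self):
        freqs = {"L1": {100: 0.5, 104: 0.3, 108: 0.2}}
        div = detect_divergent_alleles(freqs, {"L1": 4}, gap_threshold=8)
        assert div.is_empty()

    def test_far_pair_both_flagged(self):
        # a small satellite cluster far from the main one, as for the
        # divergent 241-253 bp alleles above a main cluster ending at 209
        freqs = {
            "AmaD42-L": {197: 0.3, 201: 0.3, 205: 0.2, 209: 0.1, 241: 0.06, 253: 0.04}
        }
        div = detect_divergent_alleles(freqs, {"AmaD42-L": 4}, gap_threshold=8)
        assert set(div.flagged["AmaD42-L"]) == {241, 253}
        assert div.flagged["AmaD42-L"][241] == 8
        assert div.flagged["AmaD42-L"][253] == 11

    def test_equal_clusters_ambiguous(self):
        freqs = {"L1": {100: 0.5, 160: 0.5}}
        with pytest.raises(KleptopopError, match="equal size"):
            detect_divergent_alleles(freqs, {"L1": 4}, gap_threshold=8)


class TestCarrierFrequency:
    def _divergent(self):
        freqs = {"Sp-L": {197: 0.6, 201: 0.3, 241: 0.1}}
        return detect_divergent_alleles(freqs, {"Sp-L": 4}, gap_threshold=8)

    def test_no_carriers_zero(self, make_dataset):
        ds = make_dataset([triploid("u1"), triploid("u2")])
        assert carrier_frequency(ds.individuals, self._divergent(), "Sp-L") == 0.0

    def test_one_copy_among_four_slots(self, make_dataset):
        ds = make_dataset(
            [triploid("u1", l_alleles=(197, 241)), triploid("u2", l_alleles=(197, 201))]
        )
        # two LLJ individuals: 4 L slots, u1 holds one divergent copy
        assert carrier_frequency(
            ds.individuals, self._divergent(), "Sp-L"
        ) == pytest.approx(25.0)

    def test_all_slots_divergent(self, make_dataset):
        ds = make_dataset([diploid("u1", l_allele=241)])
        assert carrier_frequency(
            ds.individuals, self._divergent(), "Sp-L"
        ) == pytest.approx(100.0)

    def test_individual_mode_counts_carriers(self, make_dataset):
        ds = make_dataset(
            [triploid("u1", l_alleles=(197, 241)), triploid("u2")]
        )
        assert carrier_frequency(
            ds.individuals, self._divergent(), "Sp-L", mode="individuals"
        ) == pytest.approx(50.0)

    def test_no_data_is_nan(self, make_dataset):
        ds = make_dataset([("u1", "S1", {"Ja": (104,)})])
        assert np.isnan(carrier_frequency(ds.individuals, self._divergent(), "Sp-L"))


class TestProbNoCarrier:
    def test_realistic_clonal_group_scale(self):
        # 36 carrier-free individuals at a ~29% mean carrier frequency
        assert prob_no_carrier(0.2895, 36) == pytest.approx(4.53e-6, rel=1e-3)

    def test_edge_cases(self):
        assert prob_no_carrier(0.0, 99) == 1.0
        assert prob_no_carrier(0.5, 0) == 1.0

    def test_monotone_in_p_and_n(self):
        ps = np.linspace(0, 0.9, 10)
        vals = [prob_no_carrier(p, 10) for p in ps]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        ns = range(0, 50, 5)
        vals = [prob_no_carrier(0.3, n) for n in ns]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestWeightedCounts:
    def _group(self, make_dataset):
        rows = [triploid(f"u{i}") for i in range(3)] + [diploid("u3")]
        return make_dataset(rows).individuals

    def test_three_triploids_one_diploid(self, make_dataset):
        group = self._group(make_dataset)
        assert weighted_haplome_count(group, "L") == 7
        assert weighted_haplome_count(group, "J") == 4
        assert weighted_ploidy_level(group, "L") == pytest.approx(1.75)
        assert weighted_ploidy_level(group, "J") == pytest.approx(1.0)

    def test_pure_ll_group(self, make_dataset):
        ds = make_dataset(
            [("h1", "S1", {"Sp": (197, 201)}), ("h2", "S1", {"Sp": (205,)})]
        )
        assert weighted_ploidy_level(ds.individuals, "L") == pytest.approx(2.0)
        assert weighted_haplome_count(ds.individuals, "J") == 0

    def test_empty_group(self):
        assert weighted_haplome_count([], "L") == 0
        with pytest.raises(KleptopopError):
            weighted_ploidy_level([], "L")

    def test_uncalled_excluded_with_warning(self, make_dataset):
        ds = make_dataset([triploid("u1"), ("u2", "S1", {"Nd": (96,)})])
        with pytest.warns(UserWarning, match="UNCALLED"):
            assert weighted_haplome_count(ds.individuals, "L") == 2


class TestRarefaction:
    def test_worked_example(self):
        assert rarefied_allele_count({1: 3, 2: 1}, 2) == pytest.approx(1.5)

    def test_full_sample_returns_distinct_count(self):
        counts = {1: 3, 2: 2, 3: 1}
        assert rarefied_allele_count(counts, 6) == pytest.approx(3.0)

    def test_monomorphic_locus(self):
        for n in (1, 3, 5):
            assert rarefied_allele_count({1: 5}, n) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Exact hypergeometric identity against all C(N, n) subsamples."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_alleles = rng.integers(1, 5)
            counts = {a: int(rng.integers(1, 5)) for a in range(n_alleles)}
            total = sum(counts.values())
            if total > 12:
                continue
            n = int(rng.integers(1, total + 1))
            assert rarefied_allele_count(counts, n) == pytest.approx(
                rarefaction_enumeration(counts, n)
            )

    def test_invalid_sizes_rejected(self):
        with pytest.raises(KleptopopError):
            rarefied_allele_count({1: 3}, 0)
        with pytest.raises(KleptopopError):
            rarefied_allele_count({1: 3}, 5)


class TestAlternativeAlleles:
    def test_perfect_clones_have_zero(self, make_dataset):
        group = make_dataset([triploid(f"u{i}") for i in range(4)]).individuals
        assert alternative_alleles_per_locus(group, ["Sp-L"], 7) == 0.0

    def test_haploid_example(self, make_dataset):
        # 4 haploid J copies {A,A,A,B}: rarefied(4) = 2; consensus has 1
        rows = [diploid(f"u{i}", j_allele=137) for i in range(3)]
        rows.append(diploid("u3", j_allele=141))
        group = make_dataset(rows).individuals
        counts = allele_copy_counts(group, "Sp-J")
        assert counts == {137: 3.0, 141: 1.0}
        assert alternative_alleles_per_locus(group, ["Sp-J"], 4) == pytest.approx(1.0)

    def test_exchange_raises_l_but_not_j(self, mixed_run):
        """Simulated exchange lineages show L diversity above the clonal-J
        baseline."""
        dataset, truth = mixed_run
        from kleptopop.bruvo import isolocus_set

        j_set = isolocus_set(dataset, "J")
        l_set = isolocus_set(dataset, "L")
        exchanged = [
            i
            for i in dataset.individuals
            if truth.of(i.id)["group"] == "B"
            and any(e[0] == "exchange" for e in truth.of(i.id)["events"])
        ]
        group_b = [i for i in dataset.individuals if truth.of(i.id)["group"] == "B"]
        assert exchanged, "preset should produce exchange events"
        n_l = weighted_haplome_count(group_b, "L")
        n_j = weighted_haplome_count(group_b, "J")
        alt_l = alternative_alleles_per_locus(group_b, l_set, min(n_l, n_j))
        alt_j = alternative_alleles_per_locus(group_b, j_set, min(n_l, n_j))
        assert alt_l > alt_j

    def test_min_baseline_flag(self, make_dataset):
        rows = [triploid(f"u{i}", l_alleles=(197, 201)) for i in range(3)]
        rows.append(diploid("u3", l_allele=205))
        group = make_dataset(rows).individuals
        cons = alternative_alleles_per_locus(group, ["Sp-L"], 4, baseline="consensus")
        mini = alternative_alleles_per_locus(group, ["Sp-L"], 4, baseline="min")
        assert mini >= cons  # min baseline (1 allele) subtracts less


def two_site_clone_matrix():
    """Four individuals: two identical pairs at two sites, inter-site d=0.4."""
    labels = ["a1", "a2", "b1", "b2"]
    values = np.array(
        [
            [0.0, 0.0, 0.4, 0.4],
            [0.0, 0.0, 0.4, 0.4],
            [0.4, 0.4, 0.0, 0.0],
            [0.4, 0.4, 0.0, 0.0],
        ]
    )
    return DistanceMatrix(labels, values)


class TestDispersionPartition:
    def test_identical_members_all_zero(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        part = dispersion_partition(
            dm, {l: "G" for l in dm.labels}, {l: "S1" for l in dm.labels}
        )
        row = part.table.loc["G"]
        assert row["total"] == pytest.approx(0.0, abs=1e-12)
        assert row["intra"] == pytest.approx(0.0, abs=1e-12)

    def test_two_clone_sites_all_variation_inter(self):
        dm = two_site_clone_matrix()
        part = dispersion_partition(
            dm,
            {l: "G" for l in dm.labels},
            {"a1": "S1", "a2": "S1", "b1": "S2", "b2": "S2"},
        )
        row = part.table.loc["G"]
        assert row["intra"] == pytest.approx(0.0, abs=1e-9)
        assert row["inter_pct"] == pytest.approx(100.0)
        # Euclidean check: two point-clusters 0.4 apart -> all at 0.2 from centroid
        assert row["total"] == pytest.approx(0.2)

    def test_single_site_all_variation_intra(self):
        dm = two_site_clone_matrix()
        part = dispersion_partition(
            dm, {l: "G" for l in dm.labels}, {l: "S1" for l in dm.labels}
        )
        row = part.table.loc["G"]
        assert row["inter"] == pytest.approx(0.0, abs=1e-9)
        assert row["intra_pct"] == pytest.approx(100.0)

    def test_singleton_group_is_nan(self):
        dm = two_site_clone_matrix()
        groups = {"a1": "G1", "a2": "G2", "b1": "G2", "b2": "G2"}
        part = dispersion_partition(dm, groups, {l: "S1" for l in dm.labels})
        assert np.isnan(part.table.loc["G1", "total"])

    def test_percentages_sum_to_100_on_simulation(self, mixed_run):
        dataset, _ = mixed_run
        from kleptopop import Dataset, pairwise_matrix
        from kleptopop.bruvo import isolocus_set

        unisex = [i for i in dataset.individuals if i.biotype != "LL"]
        sub = Dataset(individuals=unisex, loci=dataset.loci, sites=dataset.sites)
        dm = pairwise_matrix(sub, isolocus_set(sub, "LJ"))
        part = dispersion_partition(
            dm, {i.id: i.group for i in unisex}, {i.id: i.site for i in unisex}
        )
        valid = part.table.dropna(subset=["total"])
        np.testing.assert_allclose(
            valid["inter_pct"] + valid["intra_pct"], 100.0, atol=0.1
        )


class TestCompareDispersions:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(1, 0.1, 20)] * 2)
        labels = ["g1"] * 20 + ["g2"] * 20
        res = compare_dispersions(vals, labels)
        assert res["letters"]["g1"] == res["letters"]["g2"]

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.normal(0.1, 0.02, 20), rng.normal(0.5, 0.02, 20)]
        )
        labels = ["lo"] * 20 + ["hi"] * 20
        res = compare_dispersions(vals, labels)
        assert res["p"] < 1e-6
        assert set(res["letters"]["lo"]) != set(res["letters"]["hi"])

    def test_overlapping_middle_group_pattern(self):
        """Three groups where the middle one overlaps both ends: a / ab / b."""
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 0.05, 25)
        vals = np.concatenate([0.10 + noise, 0.125 + noise, 0.15 + noise])
        labels = ["lo"] * 25 + ["mid"] * 25 + ["hi"] * 25
        res = compare_dispersions(vals, labels)
        letters = res["letters"]
        assert len(letters["mid"]) == 2
        assert set(letters["lo"]) | set(letters["hi"]) == set(letters["mid"])
        assert letters["lo"] != letters["hi"]

    def test_zero_variance_reported_undefined(self):
        vals = [0.5] * 10
        labels = ["g1"] * 5 + ["g2"] * 5
        res = compare_dispersions(vals, labels)
        assert np.isnan(res["F"])
        assert res["letters"]["g1"] == res["letters"]["g2"] == "a"

    def test_power_at_twofold_dispersion(self):
        """Groups with 2x dispersion at n=20 are separated in >= 95% of runs.

        Each group is a 20-point cloud in a 10-dimensional ordination space
        (the shape centroid distances actually take after PCoA) with one
        group's dispersion doubled.
        """
        rng = np.random.default_rng(3)
        hits = 0
        n_reps = 100
        for _ in range(n_reps):
            lo_cloud = rng.normal(0, 0.05, size=(20, 10))
            hi_cloud = rng.normal(0, 0.10, size=(20, 10))
            dist = [
                np.linalg.norm(c - c.mean(axis=0), axis=1)
                for c in (lo_cloud, hi_cloud)
            ]
            res = compare_dispersions(
                np.concatenate(dist), ["lo"] * 20 + ["hi"] * 20
            )
            if set(res["letters"]["lo"]) != set(res["letters"]["hi"]):
                hits += 1
        assert hits / n_reps >= 0.95
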