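"""HOR haplotype clades, superHOR periodicity, age and homogeneity tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenchrom import (
    GenomicInterval,
    HorArraySpec,
    IdentityTrack,
    WardCladeClusterer,
    binomial_age_test,
    cdr_homogeneity_permutation,
    clade_divergence_ranking,
    generate_hor_units,
    hamming_distance_matrix,
    neighbor_average_identity,
    superhor_scan,
    ward_clade_assignment,
)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGA", 1), ("ACGT", "ACGT", 0), ("AC-T", "ACGT", 1), ("----", "ACGT", 4)],
    )
    def test_pair_distances(self, a, b, expected):
        D = hamming_distance_matrix([a, b])
        assert D[0, 1] == expected

    def test_identical_set_zero_matrix(self):
        D = hamming_distance_matrix(["ACGT"] * 4)
        assert np.all(D == 0)

    def test_ignore_gap_columns_mode(self):
        D = hamming_distance_matrix(["AC-T", "ACGT"], ignore_gap_columns=True)
        assert D[0, 1] == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="one length"):
            hamming_distance_matrix(["ACG", "ACGT"])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT-", min_size=8, max_size=8), min_size=3, max_size=6
        )
    )
    def test_metric_axioms(self, seqs):
        D = hamming_distance_matrix(seqs)
        n = len(seqs)
        assert np.all(np.diag(D) == 0)
        np.testing.assert_array_equal(D, D.T)
        for i, j, k in itertools.permutations(range(n), 3):
            assert D[i, k] <= D[i, j] + D[j, k]


class TestWardClades:
    def test_planted_partition_recovered(self):
        spec = HorArraySpec(n_units=20, unit_length=100, n_clades=2, variants_per_clade=10)
        units, truth = generate_hor_units(spec, mutation_rate=0.0, seed=0)
        labels = WardCladeClusterer(n_clades=2).fit_predict(units)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_singletons(self):
        labels = WardCladeClusterer(n_clades=4).fit_predict(["AAAA", "AAAT", "TTTT", "TTTA"])
        assert sorted(labels) == [0, 1, 2, 3]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="n_clades"):
            WardCladeClusterer(n_clades=5).fit(["AAAA", "TTTT"])

    def test_identical_units_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            clusterer = WardCladeClusterer(n_clades=2).fit(["AAAA"] * 5)
        assert clusterer.degenerate_

    def test_labels_renumbered_by_first_occurrence(self):
        units = ["TTTT", "TTTA", "AAAA", "AAAC"]
        labels = WardCladeClusterer(n_clades=2).fit_predict(units)
        assert labels[0] == 0  # the first unit anchors clade 0


class TestDivergence:
    def test_identical_clade_is_youngest(self):
        units = ["AAAA", "AAAA", "AATT", "ACTT", "GCTT"]
        labels = np.array([0, 0, 1, 1, 1])
        D = hamming_distance_matrix(units)
        div, youngest, oldest = clade_divergence_ranking(D, labels, 4)
        assert div[0] == 0.0 and youngest == 0 and oldest == 1

    def test_quarter_divergence(self):
        D = hamming_distance_matrix(["AAAA", "AAAT"])
        div, _, _ = clade_divergence_ranking(D, np.array([0, 0]), 4)
        assert div[0] == pytest.approx(0.25)

    def test_three_unit_mean_of_pairs(self):
        # three units of length 10, pairwise distance 2 -> divergence 0.2
        units = ["AAAAAAAAAA", "TTAAAAAAAA", "ATTAAAAAAA"]
        D = hamming_distance_matrix(units)
        div, _, _ = clade_divergence_ranking(D, np.zeros(3, int), 10)
        assert div[0] == pytest.approx(0.2)

    def test_all_singletons_error(self):
        D = hamming_distance_matrix(["AAAA", "TTTT"])
        with pytest.raises(ValueError, match="singleton"):
            clade_divergence_ranking(D, np.array([0, 1]), 4)


def brute_force_superhor(seq, n_range=(2, 9), min_repeats=3, suppress=True):
    """Independent enumeration: maximal periodic regions per n, python loops."""
    hits = []
    L = len(seq)
    for n in range(n_range[0], n_range[1] + 1):
        i = 0
        while i < L - n:
            if seq[i] != seq[i + n]:
                i += 1
                continue
            j = i
            while j + n < L and seq[j] == seq[j + n]:
                j += 1
            repeats = (j - i + n) // n  # region [i, j+n), length j-i+n
            if repeats >= min_repeats:
                pattern = tuple(seq[i : i + n])
                period = next(
                    p
                    for p in range(1, n + 1)
                    if n % p == 0 and all(pattern[q] == pattern[q % p] for q in range(n))
                )
                if not (suppress and period < n):
                    hits.append((i, i + n * repeats, pattern, repeats))
            i = j + 1
    return sorted(hits)


class TestSuperHor:
    def test_three_repeat_dimer(self):
        (hit,) = superhor_scan([1, 2, 1, 2, 1, 2])
        assert (hit.start_unit, hit.end_unit, hit.pattern, hit.repeats) == (0, 6, (1, 2), 3)

    def test_homopolymer_suppressed(self):
        assert superhor_scan([1, 1, 1, 1]) == []

    def test_two_repeats_insufficient(self):
        assert superhor_scan([3, 4, 3, 4]) == []

    def test_subperiod_suppression_switchable(self):
        seq = [1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2]
        ns = {h.n for h in superhor_scan(seq)}
        assert ns == {2}
        ns_raw = {h.n for h in superhor_scan(seq, suppress_subperiods=False)}
        assert 4 in ns_raw

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            seq = rng.integers(0, 3, size=rng.integers(6, 60)).tolist()
            got = [
                (h.start_unit, h.end_unit, h.pattern, h.repeats) for h in superhor_scan(seq)
            ]
            assert sorted(got) == brute_force_superhor(seq)

    def test_hit_geometry_invariant(self):
        rng = np.random.default_rng(6)
        seq = (list(rng.integers(0, 2, 4)) * 5)[:18]
        for h in superhor_scan(seq):
            assert h.end_unit - h.start_unit == h.n * h.repeats


class TestBinomialAgeTest:
    def test_reported_configuration(self):
        assert binomial_age_test(28, 37, 0.64) == pytest.approx(0.092888, abs=1e-6)

    def test_zero_successes_gives_one(self):
        assert binomial_age_test(0, 12, 0.3) == 1.0

    def test_symmetric_half(self):
        # P(X >= 3 | n=5, p=0.5) = (10 + 5 + 1) / 32
        assert binomial_age_test(3, 5, 0.5) == pytest.approx(0.5)

    def test_matches_direct_mass_summation(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(1, 51))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            direct = sum(
                math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
            )
            assert binomial_age_test(k, n, p) == pytest.approx(direct, abs=1e-12)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            binomial_age_test(1, 2, 1.5)


def make_identity_track(values, window=5_000, contig="chrT"):
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * window
    return IdentityTrack(contig, starts, starts + window, values)


class TestNeighborAverage:
    def test_constant_unchanged(self):
        track = make_identity_track([95.0] * 6)
        out = neighbor_average_identity(track)
        np.testing.assert_allclose(out.smoothed_pct, 95.0)

    def test_neighbors_only_hand_values(self):
        track = make_identity_track([0, 0, 1, 0, 0])
        out = neighbor_average_identity(track, k_each_side=1)
        np.testing.assert_allclose(out.smoothed_pct, [0, 0.5, 0, 0.5, 0])

    def test_single_window_copied_through(self):
        out = neighbor_average_identity(make_identity_track([88.0]))
        np.testing.assert_allclose(out.smoothed_pct, [88.0])

    def test_color_floor_modes(self):
        track = make_identity_track(np.linspace(80, 100, 20))
        fixed = neighbor_average_identity(track, color_floor_mode="fixed")
        assert fixed.color_floor_pct == 90.0
        p10 = neighbor_average_identity(track, color_floor_mode="p10")
        assert p10.color_floor_pct == pytest.approx(np.percentile(p10.smoothed_pct, 10))


class TestHomogeneityPermutation:
    def test_uniform_track_p_one(self):
        track = neighbor_average_identity(make_identity_track([95.0] * 10))
        res = cdr_homogeneity_permutation(
            [GenomicInterval("chrT", 1_000, 3_000)],
            track,
            GenomicInterval("chrT", 0, 50_000),
            n_perm=99,
            seed=0,
        )
        assert res["p_value"] == 1.0

    def test_cdr_on_unique_plateau(self):
        values = np.full(200, 91.0)
        values[80:100] = 99.5  # one 100 kb high-identity plateau
        track = neighbor_average_identity(make_identity_track(values))
        # the CDR occupies exactly the smoothed plateau interior, the unique
        # placement maximizing the statistic
        res = cdr_homogeneity_permutation(
            [GenomicInterval("chrT", 410_000, 490_000)],
            track,
            GenomicInterval("chrT", 0, 1_000_000),
            n_perm=999,
            seed=1,
        )
        assert res["p_value"] == pytest.approx(1 / 1000)

    def test_p_bounds(self):
        rng = np.random.default_rng(3)
        track = neighbor_average_identity(make_identity_track(rng.uniform(85, 99, 50)))
        for seed in range(5):
            res = cdr_homogeneity_permutation(
                [GenomicInterval("chrT", 10_000, 20_000)],
                track,
                GenomicInterval("chrT", 0, 250_000),
                n_perm=49,
                seed=seed,
            )
            assert 1 / 50 <= res["p_value"] <= 1.0

    def test_oversize_cdr_rejected(self):
        track = neighbor_average_identity(make_identity_track([95.0] * 4))
        with pytest.raises(ValueError, match="exceed"):
            cdr_homogeneity_permutation(
                [GenomicInterval("chrT", 0, 19_000)],
                track,
                GenomicInterval("chrT", 0, 10_000),
                n_perm=9,
            )
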