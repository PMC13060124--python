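"""Single-molecule density, Gini threshold learning, co-occupancy, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cenchrom import (
    FiberConfig,
    GenomicInterval,
    GiniThresholdClassifier,
    MethylationTrack,
    ReadRecord,
    build_methylation_matrix,
    classify_read,
    cluster_methylation_matrix,
    cooccupancy_analysis,
    learn_density_threshold,
    read_region_density,
    sample_background_windows,
)
from cenchrom.fiber import ThresholdModel


def make_read(read_id, start, end, mod="6mA", positions=(), probs=(), contig="chrT"):
    return ReadRecord(read_id, contig, start, end, calls={mod: (list(positions), list(probs))})


def brute_force_stump(x, y):
    """Independent exhaustive midpoint scan (pure python, from counts)."""
    pairs = sorted(zip(x, y))
    xs = [p[0] for p in pairs]
    distinct = sorted(set(xs))
    best = (None, float("inf"))
    n = len(pairs)
    for a, b in zip(distinct, distinct[1:]):
        thr = (a + b) / 2
        left = [yy for xx, yy in pairs if xx <= thr]
        right = [yy for xx, yy in pairs if xx > thr]
        imp = 0.0
        for side in (left, right):
            if not side:
                continue
            p1 = sum(side) / len(side)
            imp += len(side) / n * (1 - p1 * p1 - (1 - p1) ** 2)
        if imp < best[1] - 1e-15:
            best = (thr, imp)
    return best


class TestRegionDensity:
    def test_quality_filter_arithmetic(self):
        # 10 candidate positions; 3 with high probabilities, cutoff 230 -> 2/10
        positions = list(range(100, 200, 10))
        probs = [250, 240, 100] + [10] * 7
        read = make_read("r", 0, 1000, positions=positions, probs=probs)
        d = read_region_density(read, GenomicInterval("chrT", 0, 1000), "6mA")
        assert d.density == pytest.approx(0.2)

    def test_zero_candidates_excluded_not_zero(self):
        read = make_read("r", 0, 1000, positions=[500], probs=[255])
        region = GenomicInterval("chrT", 600, 900)
        assert read_region_density(read, region, "6mA") is None

    def test_all_saturated_density_one(self):
        read = make_read("r", 0, 100, positions=[10, 20, 30], probs=[255, 255, 255])
        d = read_region_density(read, GenomicInterval("chrT", 0, 100), "6mA")
        assert d.density == 1.0

    def test_unknown_mod_type_errors(self):
        read = make_read("r", 0, 100, positions=[10], probs=[255])
        with pytest.raises(ValueError, match="mod_type"):
            read_region_density(read, GenomicInterval("chrT", 0, 100), "7mG")

    def test_scale_free(self):
        """Replicating every candidate k-fold leaves the density unchanged."""
        region = GenomicInterval("chrT", 0, 1000)
        read1 = make_read("r", 0, 1000, positions=[10, 20, 30, 40], probs=[250, 250, 10, 10])
        positions_k = [10, 11, 12, 20, 21, 22, 30, 31, 32, 40, 41, 42]
        probs_k = [250] * 6 + [10] * 6
        read2 = make_read("r", 0, 1000, positions=positions_k, probs=probs_k)
        assert (
            read_region_density(read1, region, "6mA").density
            == read_region_density(read2, region, "6mA").density
        )


class TestBackgroundWindows:
    def test_interval_arithmetic_and_cap(self):
        array = GenomicInterval("chrT", 0, 200_000)
        subcdr = [GenomicInterval("chrT", 90_000, 110_000)]
        windows = sample_background_windows(array, subcdr, seed=0)
        assert len(windows) == 15
        for w in windows:
            assert w.end <= 80_000 or w.start >= 120_000
            assert len(w) == 5_000

    def test_candidate_count_before_cap(self):
        array = GenomicInterval("chrT", 0, 200_000)
        subcdr = [GenomicInterval("chrT", 90_000, 110_000)]
        config = FiberConfig(max_background_windows_per_homolog=1000)
        windows = sample_background_windows(array, subcdr, config, seed=0)
        assert len(windows) == 32  # 16 left of the buffer zone + 16 right

    def test_no_subcdrs_tiles_whole_array(self):
        array = GenomicInterval("chrT", 0, 60_000)
        windows = sample_background_windows(array, [], seed=0)
        assert [(w.start, w.end) for w in windows] == [
            (i * 5_000, (i + 1) * 5_000) for i in range(12)
        ]

    def test_seeded_subsample_deterministic(self):
        array = GenomicInterval("chrT", 0, 500_000)
        w1 = sample_background_windows(array, [], seed=7)
        w2 = sample_background_windows(array, [], seed=7)
        w3 = sample_background_windows(array, [], seed=8)
        assert [(w.start, w.end) for w in w1] == [(w.start, w.end) for w in w2]
        assert [(w.start, w.end) for w1_, w3_ in [(w1, w3)] for w in w1_] != [
            (w.start, w.end) for w in w3
        ]

    def test_no_eligible_territory_errors(self):
        array = GenomicInterval("chrT", 0, 30_000)
        subcdr = [GenomicInterval("chrT", 0, 30_000)]
        with pytest.raises(ValueError, match="eligible"):
            sample_background_windows(array, subcdr)


class TestGiniThreshold:
    def test_separable_example(self):
        model = learn_density_threshold([0.02, 0.03], [0.001, 0.002])
        assert model.threshold == pytest.approx(0.011)
        assert model.achieved_impurity == pytest.approx(0.0)

    def test_two_points(self):
        model = learn_density_threshold([0.9], [0.1])
        assert model.threshold == pytest.approx(0.5)
        assert model.achieved_impurity == pytest.approx(0.0)

    def test_identical_distributions_maximal_impurity(self):
        model = learn_density_threshold([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert model.achieved_impurity == pytest.approx(0.5, abs=0.06)

    def test_degenerate_identical_values_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            model = learn_density_threshold([0.5, 0.5], [0.5, 0.5])
        assert model.achieved_impurity == pytest.approx(0.5)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = 100
            cdr = rng.beta(2, 30, size=n) + rng.normal(0, 0.001, n)
            bg = rng.beta(1, 100, size=n)
            model = learn_density_threshold(cdr.tolist(), bg.tolist())
            x = np.concatenate([bg, cdr])
            y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
            thr, imp = brute_force_stump(x.tolist(), y.tolist())
            assert model.threshold == pytest.approx(thr)
            assert model.achieved_impurity == pytest.approx(imp)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=2, max_size=30),
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=2, max_size=30),
    )
    def test_gini_invariant_to_class_relabeling(self, a, b):
        if len(set(a) | set(b)) < 2:
            return
        m1 = learn_density_threshold(a, b)
        m2 = learn_density_threshold(b, a)
        assert m1.achieved_impurity == pytest.approx(m2.achieved_impurity)
        assert m1.threshold == pytest.approx(m2.threshold)

    def test_classification_strict_inequality(self):
        model = ThresholdModel("6mA", 0.011, 0.0, 10, 10)
        read = make_read("r", 0, 1000, positions=list(range(0, 1000, 10)), probs=[0] * 100)
        at = read_region_density(
            make_read(
                "r", 0, 1000, positions=list(range(0, 1000, 1)),
                probs=[255] * 11 + [0] * 989,
            ),
            GenomicInterval("chrT", 0, 1000),
            "6mA",
        )
        assert at.density == pytest.approx(0.011)
        assert classify_read(at, model) == "not_enriched"  # ties are conservative
        above = read_region_density(
            make_read(
                "r", 0, 1000, positions=list(range(0, 1000, 1)),
                probs=[255] * 12 + [0] * 988,
            ),
            GenomicInterval("chrT", 0, 1000),
            "6mA",
        )
        assert classify_read(above, model) == "enriched"
        zero = read_region_density(read, GenomicInterval("chrT", 0, 1000), "6mA")
        assert classify_read(zero, model) == "not_enriched"


class TestCooccupancy:
    def _two_domain_setup(self):
        subcdrs = [GenomicInterval("chrT", 1000, 2000), GenomicInterval("chrT", 5000, 6000)]
        cenpa = ThresholdModel("6mA", 0.011, 0.0, 1, 1)
        mcpg = ThresholdModel("5mC", 0.5, 0.0, 1, 1)
        return subcdrs, cenpa, mcpg

    def test_fully_positive_read_counted_in_both(self):
        subcdrs, cenpa, mcpg = self._two_domain_setup()
        pos = list(range(0, 7000, 10))
        read = ReadRecord(
            "r", "chrT", 0, 7000,
            calls={"6mA": (pos, [255] * len(pos)), "5mC": (pos, [0] * len(pos))},
        )
        s = cooccupancy_analysis([read], subcdrs, cenpa, mcpg)
        assert s.n_spanning_2plus == 1
        assert s.frac_cenpa_multi == 1.0
        assert s.frac_mcpg_depleted_all == 1.0

    def test_94_percent_coverage_not_spanning(self):
        subcdrs, cenpa, mcpg = self._two_domain_setup()
        # covers all of domain 1 but only 94% of domain 2
        read = make_read("r", 0, 5940, positions=[10], probs=[255])
        s = cooccupancy_analysis([read], subcdrs, cenpa, mcpg)
        assert s.n_spanning_2plus == 0
        assert s.n_overlapping == 1
        assert s.frac_cenpa_multi is None

    def test_mixed_molecule_population(self):
        subcdrs, cenpa, mcpg = self._two_domain_setup()
        reads = []
        for i in range(10):
            pos = list(range(0, 7000, 10))
            if i < 8:  # CENP-A positive at both domains
                probs6 = [255] * len(pos)
            else:  # positive only at the first
                probs6 = [255 if p < 3000 else 0 for p in pos]
            reads.append(
                ReadRecord(
                    f"r{i}", "chrT", 0, 7000,
                    calls={"6mA": (pos, probs6), "5mC": (pos[:1], [0])},
                )
            )
        s = cooccupancy_analysis(reads, subcdrs, cenpa, mcpg)
        assert s.n_spanning_2plus == 10
        assert s.frac_cenpa_multi == pytest.approx(0.8)


class TestMethylationMatrix:
    def _track(self):
        positions = np.array([100, 200, 300, 400, 500])
        return MethylationTrack("chrT", positions, np.full(5, 60.0))

    def test_full_probability_row(self):
        track = self._track()
        region = GenomicInterval("chrT", 0, 600)
        read = make_read(
            "r", 0, 600, mod="5mC", positions=[100, 200, 300, 400, 500], probs=[255] * 5
        )
        matrix, ids, cols = build_methylation_matrix([read], region, track)
        assert matrix.shape == (1, 5)
        np.testing.assert_allclose(matrix[0], 1.0)

    def test_short_read_excluded(self):
        track = self._track()
        region = GenomicInterval("chrT", 0, 600)
        good = make_read("good", 0, 600, mod="5mC", positions=[100], probs=[255])
        short = make_read("short", 0, 540, mod="5mC", positions=[100], probs=[255])
        matrix, ids, _ = build_methylation_matrix([good, short], region, track)
        assert ids == ["good"]

    def test_column_count_equals_region_cpgs(self):
        track = self._track()
        region = GenomicInterval("chrT", 150, 450)
        read = make_read("r", 0, 600, mod="5mC", positions=[200], probs=[128])
        matrix, _, cols = build_methylation_matrix([read], region, track)
        assert matrix.shape[1] == cols.size == 3
        assert np.isnan(matrix[0, 1]) and matrix[0, 0] == pytest.approx(128 / 255)


class TestClustering:
    def test_two_planted_groups_recovered(self):
        rows = np.vstack([np.zeros((10, 40)), np.ones((10, 40))])
        labels, order = cluster_methylation_matrix(rows)
        assert set(labels) == {0, 1}
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_identical_rows_single_cluster(self):
        rows = np.full((12, 30), 0.8)
        labels, _ = cluster_methylation_matrix(rows)
        assert set(labels) == {0}

    def test_too_few_rows_all_noise(self):
        rows = np.random.default_rng(0).random((4, 30))
        with pytest.warns(UserWarning, match="noise"):
            labels, _ = cluster_methylation_matrix(rows)
        assert np.all(labels == -1)
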