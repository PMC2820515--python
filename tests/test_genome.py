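"""Circular-genome model: arrangements, rearrangements, distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from operonevo import (
    Arrangement,
    ConfigError,
    GenomeConfig,
    apply_inversion,
    apply_translocation,
    draw_breakpoints,
    inversion_viable,
    min_arc_distance,
    proportion_clustered,
    random_arrangement,
)
from operonevo.genome import invert_positions, positions_min_arc

from conftest import brute_force_min_arc


class TestRandomArrangement:
    def test_full_genome_is_forced(self, rng):
        cfg = GenomeConfig(length_kb=10, n_genes=10)
        arr = random_arrangement(cfg, rng)
        assert list(arr.positions) == list(range(1, 11))

    def test_distinct_positions_in_range(self, rng, config):
        for _ in range(100):
            arr = random_arrangement(config, rng)
            assert len(set(arr.positions)) == config.n_genes
            assert arr.positions.min() >= 1
            assert arr.positions.max() <= config.length_kb

    def test_same_seed_reproduces(self, config):
        a = random_arrangement(config, np.random.default_rng(42))
        b = random_arrangement(config, np.random.default_rng(42))
        assert a == b

    def test_too_many_genes_rejected(self):
        with pytest.raises(ConfigError):
            GenomeConfig(length_kb=5, n_genes=6)

    def test_mean_distance_matches_analytic_expectation(self, rng, config):
        # largest of 3 uniform circular gaps has mean (L/3)(1+1/2+1/3),
        # so E[min arc] = 7L/18
        n_rep = 5000
        d = np.array(
            [min_arc_distance(random_arrangement(config, rng)) for _ in range(n_rep)]
        )
        expected = 7 * config.length_kb / 18
        se = d.std() / np.sqrt(n_rep)
        assert abs(d.mean() - expected) < 4 * se


class TestMinArcDistance:
    @pytest.mark.parametrize(
        "L, positions, expected",
        [
            (100, [10, 30], 20),
            (20, [1, 2, 3, 11], 10),
            (18, [1, 7, 13], 12),  # equally spaced: L(n-1)/n
            (100, [42], 0),  # fewer than 2 genes: 0 by convention
        ],
    )
    def test_known_values(self, L, positions, expected):
        assert positions_min_arc(np.array(positions), L) == expected

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(1000):
            L = int(rng.integers(10, 60))
            n = int(rng.integers(2, min(8, L) + 1))
            pos = rng.choice(L, size=n, replace=False) + 1
            assert positions_min_arc(pos, L) == brute_force_min_arc(pos, L)

    def test_rotation_and_reflection_invariance(self, rng):
        L = 360
        for _ in range(200):
            n = int(rng.integers(2, 7))
            pos = rng.choice(L, size=n, replace=False) + 1
            d = positions_min_arc(pos, L)
            shift = int(rng.integers(L))
            rotated = (pos - 1 + shift) % L + 1
            reflected = (L - pos) % L + 1
            assert positions_min_arc(rotated, L) == d
            assert positions_min_arc(reflected, L) == d


class TestBreakpoints:
    def test_half_integers_ordered_in_range(self, rng, config):
        for _ in range(500):
            a, b = draw_breakpoints(config, rng)
            assert a <= b
            assert a % 1 == 0.5 and b % 1 == 0.5
            assert 0 < a < config.length_kb and 0 < b < config.length_kb

    def test_offset_convention(self):
        # integer draws (3, 7) and (7, 3) both give breakpoints (2.5, 6.5)
        class TwoInts:
            def __init__(self, u, v):
                self.vals = [u, v]

            def integers(self, low, high, size):
                return np.array(self.vals)

        cfg = GenomeConfig(length_kb=100, n_genes=3)
        assert draw_breakpoints(cfg, TwoInts(3, 7)) == (2.5, 6.5)
        assert draw_breakpoints(cfg, TwoInts(7, 3)) == (2.5, 6.5)


class TestInversionViability:
    @pytest.mark.parametrize(
        "a, b, viable",
        [
            (5.5, 25.5, True),  # segment misses the terminus
            (40.5, 70.5, False),  # terminus displaced |111-100| = 11 > 10
            (45.5, 60.5, True),  # displacement 6 <= 10
        ],
    )
    def test_terminus_displacement_rule(self, small_config, a, b, viable):
        assert inversion_viable(a, b, small_config) is viable

    def test_tolerance_extremes(self, rng):
        permissive = GenomeConfig(length_kb=100, n_genes=3, tolerance_kb=100)
        strict = GenomeConfig(length_kb=100, n_genes=3, tolerance_kb=0)
        for _ in range(300):
            a, b = draw_breakpoints(permissive, rng)
            assert inversion_viable(a, b, permissive)
            if inversion_viable(a, b, strict):
                # only same-side or perfectly terminus-symmetric segments
                assert b < 50 or a > 50 or a + b == 100

    def test_unordered_breakpoints_rejected(self, small_config):
        with pytest.raises(ValueError):
            inversion_viable(10.5, 2.5, small_config)


class TestApplyInversion:
    def test_reflection_of_interior_genes(self):
        cfg = GenomeConfig(length_kb=100, n_genes=3)
        arr = Arrangement(np.array([10, 20, 90]), cfg)
        out = apply_inversion(arr, 5.5, 25.5)
        assert sorted(out.positions) == [11, 21, 90]  # g -> 31 - g inside

    def test_empty_segment_is_identity(self):
        cfg = GenomeConfig(length_kb=100, n_genes=3)
        arr = Arrangement(np.array([10, 20, 90]), cfg)
        assert apply_inversion(arr, 0.5, 0.5) == arr

    @given(data=st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_involution_preserves_genes(self, data):
        L = data.draw(st.integers(10, 200))
        n = data.draw(st.integers(2, min(8, L)))
        pos = data.draw(
            st.lists(st.integers(1, L), min_size=n, max_size=n, unique=True)
        )
        u = data.draw(st.integers(1, L))
        v = data.draw(st.integers(1, L))
        a, b = min(u, v) - 0.5, max(u, v) - 0.5
        once = invert_positions(np.array(pos), a, b)
        assert len(set(once)) == n  # distinctness preserved
        assert ((once >= 1) & (once <= L)).all()
        twice = invert_positions(once, a, b)
        assert sorted(twice) == sorted(pos)


class TestTranslocation:
    def test_single_free_slot_is_forced(self, rng):
        cfg = GenomeConfig(length_kb=4, n_genes=3)
        for _ in range(50):
            arr = Arrangement(np.array([1, 2, 3]), cfg)
            out = apply_translocation(arr, rng)
            assert len(set(out.positions)) == 3
            assert set(out.positions) < {1, 2, 3, 4}
            assert set(out.positions) != {1, 2, 3}  # gene moved to the free slot

    def test_destination_uniform_over_free_slots(self, rng):
        cfg = GenomeConfig(length_kb=20, n_genes=3)
        start = {1, 2, 3}
        free = sorted(set(range(1, 21)) - start)
        counts = dict.fromkeys(free, 0)
        n_draws = 10_000
        for _ in range(n_draws):
            arr = Arrangement(np.array([1, 2, 3]), cfg)
            out = apply_translocation(arr, rng)
            (dest,) = set(out.positions) - start
            counts[dest] += 1
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-3

    def test_same_seed_reproduces(self, config):
        arr = random_arrangement(config, np.random.default_rng(7))
        a = apply_translocation(arr, np.random.default_rng(11))
        b = apply_translocation(arr, np.random.default_rng(11))
        assert a == b


class TestProportionClustered:
    def test_counts_below_threshold(self):
        cfg = GenomeConfig(length_kb=4900, n_genes=2)
        mk = lambda d: Arrangement(np.array([1, 1 + d]), cfg)
        arrs = [mk(10), mk(200), mk(300)]
        # default threshold = 3 minutes = 147 kb
        assert proportion_clustered(arrs) == pytest.approx(1 / 3)
        assert proportion_clustered(arrs, threshold_kb=301) == 1.0
        assert proportion_clustered(arrs, threshold_kb=5) == 0.0

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            proportion_clustered([])


class TestSerialization:
    def test_tsv_round_trip(self, rng, config):
        arr = random_arrangement(config, rng)
        line = arr.to_tsv()
        assert line == f"4900\t{','.join(map(str, arr.positions))}"
        assert Arrangement.from_tsv(line, config) == arr
        assert Arrangement.from_tsv(line) == arr
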