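import math

import numpy as np
import pytest

from odepkit.kinetics import (
    LOCAL_DESCRIPTOR_NAMES,
    KineticsSeries,
    approximate_entropy,
    distribution_stats,
    local_descriptors,
    mean_cos_phase,
    relative_series,
    spatial_mean_components,
)
from odepkit.piv import DisplacementField


def apen_direct(u, m=2, r_factor=0.2):
    """O(N^2) direct-count approximate entropy, written from the definition."""
    u = list(map(float, u))
    n = len(u)
    sigma = float(np.std(u))
    if sigma == 0.0:
        return 0.0
    r = r_factor * sigma

    def phi(mm):
        nb = n - mm + 1
        blocks = [u[i : i + mm] for i in range(nb)]
        total = 0.0
        for i in range(nb):
            count = 0
            for j in range(nb):
                if j == i:
                    continue
                if max(abs(a - b) for a, b in zip(blocks[i], blocks[j])) < r:
                    count += 1
            if count == 0:
                count = 1  # keep the self-match so the log stays finite
            total += math.log(count / (nb - 1))
        return total / nb

    return phi(m) - phi(m + 1)


def make_field(u, v, valid=None):
    u = np.atleast_2d(np.asarray(u, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if valid is None:
        valid = np.ones_like(u, dtype=bool)
    rows = np.arange(u.shape[0])
    cols = np.arange(u.shape[1])
    return DisplacementField(u=u, v=v, valid=valid, grid_rows=rows, grid_cols=cols, window=10)


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(100, 3.7)) == 0.0

    def test_matches_direct_count_oracle_on_alternating_series(self):
        u = np.tile([0.0, 1.0], 150)  # N = 300
        assert approximate_entropy(u) == pytest.approx(apen_direct(u), abs=1e-12)

    def test_matches_direct_count_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        u = rng.standard_normal(50)
        assert approximate_entropy(u) == pytest.approx(apen_direct(u), abs=1e-12)

    def test_periodic_series_less_entropic_than_noise(self):
        rng = np.random.default_rng(0)
        periodic = np.tile([0.0, 1.0], 150)
        noise = rng.uniform(size=300)
        assert approximate_entropy(periodic) < approximate_entropy(noise)

    def test_nonnegative_on_varied_inputs(self):
        rng = np.random.default_rng(5)
        for u in (
            rng.standard_normal(80),
            np.sin(np.arange(120) * 0.3),
            rng.integers(0, 3, 90).astype(float),
        ):
            assert approximate_entropy(u) >= 0.0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.array([1.0, 2.0, 3.0]), m=2)


class TestDistributionStats:
    def test_constant_series_convention(self):
        s = distribution_stats(np.full(10, 2.0))
        assert s["sd"] == s["mad"] == s["skew"] == s["kurt"] == 0.0
        assert s["max"] == s["min"] == 2.0

    def test_symmetric_two_point_law_has_kurtosis_one(self):
        s = distribution_stats(np.tile([-1.0, 1.0], 20))
        assert s["kurt"] == pytest.approx(1.0)
        assert s["skew"] == pytest.approx(0.0)

    def test_gaussian_sample_kurtosis_near_three(self):
        rng = np.random.default_rng(11)
        s = distribution_stats(rng.standard_normal(100_000))
        assert s["kurt"] == pytest.approx(3.0, abs=0.1)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            distribution_stats(np.array([1.0]))


class TestFieldReduction:
    def test_uniform_field_mean(self):
        f = make_field(np.ones((3, 3)), np.zeros((3, 3)))
        assert spatial_mean_components(f) == (1.0, 0.0)

    def test_half_and_half_mean(self):
        u = np.array([[2.0, 2.0], [0.0, 0.0]])
        f = make_field(u, np.zeros_like(u))
        assert spatial_mean_components(f) == (1.0, 0.0)

    def test_invalid_nodes_excluded_from_mean(self):
        u = np.array([[5.0, 99.0]])
        valid = np.array([[True, False]])
        f = make_field(u, np.zeros_like(u), valid)
        assert spatial_mean_components(f)[0] == 5.0

    def test_no_valid_nodes_gives_nan(self):
        f = make_field([[1.0]], [[1.0]], np.array([[False]]))
        assert np.isnan(spatial_mean_components(f)[0])
        assert np.isnan(mean_cos_phase(f))

    def test_mean_cos_phase_cardinal_directions(self):
        assert mean_cos_phase(make_field([[1.0]], [[0.0]])) == pytest.approx(1.0)
        assert mean_cos_phase(make_field([[0.0]], [[1.0]])) == pytest.approx(0.0)
        f = make_field([[1.0, -1.0]], [[0.0, 0.0]])
        assert mean_cos_phase(f) == pytest.approx(0.0)

    def test_zero_magnitude_nodes_contribute_zero(self):
        f = make_field([[0.0, 1.0]], [[0.0, 0.0]])
        assert mean_cos_phase(f) == pytest.approx(0.5)

    def test_phase_mean_even_under_v_mirror(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal((5, 5))
        v = rng.standard_normal((5, 5))
        assert mean_cos_phase(make_field(u, v)) == pytest.approx(
            mean_cos_phase(make_field(u, -v))
        )

    def test_phase_mean_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            f = make_field(rng.standard_normal((4, 4)), rng.standard_normal((4, 4)))
            assert -1.0 <= mean_cos_phase(f) <= 1.0


class TestRelativeSeries:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
            ([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]),
            ([-2.0, 4.0], [0.0, 6.0]),
        ],
    )
    def test_referenced_to_first_sample(self, raw, expected):
        assert np.allclose(relative_series(np.array(raw)), expected)

    def test_first_element_always_zero(self):
        rng = np.random.default_rng(1)
        assert relative_series(rng.standard_normal(30))[0] == 0.0


class TestLocalDescriptors:
    def _series(self, x, y, th):
        return KineticsSeries(
            x_mu=np.asarray(x, dtype=float),
            y_mu=np.asarray(y, dtype=float),
            theta_mu=np.asarray(th, dtype=float),
            frame_rate=20.0,
            valid=np.ones(len(x), dtype=bool),
        )

    def test_vector_has_21_named_values(self):
        rng = np.random.default_rng(4)
        k = self._series(*rng.standard_normal((3, 60)))
        values, names = local_descriptors(k)
        assert len(values) == len(names) == 21
        assert tuple(names) == LOCAL_DESCRIPTOR_NAMES

    def test_zero_series_gives_zero_vector(self):
        k = self._series(np.zeros(30), np.zeros(30), np.zeros(30))
        values, _ = local_descriptors(k)
        assert np.allclose(values, 0.0)

    def test_tabular_export_round_trips(self, tmp_path):
        rng = np.random.default_rng(12)
        k = self._series(*rng.standard_normal((3, 25)))
        df = k.to_frame()
        assert list(df.columns) == [
            "frame", "x_mu", "y_mu", "theta_mu", "dx", "dy", "dtheta", "valid",
        ]
        df.to_csv(tmp_path / "k.csv", index=False)
        import pandas as pd

        back = pd.read_csv(tmp_path / "k.csv")
        assert np.allclose(back["dtheta"], k.dtheta)

    def test_recomputation_is_bit_identical(self):
        rng = np.random.default_rng(6)
        k = self._series(*rng.standard_normal((3, 50)))
        v1, _ = local_descriptors(k)
        v2, _ = local_descriptors(k)
        assert np.array_equal(v1, v2)

    def test_scaling_dx_scales_dispersion_not_shape(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(80)
        y = rng.standard_normal(80)
        th = rng.uniform(-1, 1, 80)
        v1, names = local_descriptors(self._series(x, y, th))
        v2, _ = local_descriptors(self._series(3.0 * x, y, th))
        d1 = dict(zip(names, v1))
        d2 = dict(zip(names, v2))
        for stat in ("sd_dx", "mad_dx", "max_dx", "min_dx"):
            assert d2[stat] == pytest.approx(3.0 * d1[stat])
        for stat in ("skew_dx", "kurt_dx", "apen_dx"):
            assert d2[stat] == pytest.approx(d1[stat], abs=1e-9)
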