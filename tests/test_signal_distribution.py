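"""Log-normal signal-strength fits, detection fractions, and decile bins."""

import math

import numpy as np
import pytest

from eqtlpower import (
    SignalStrengthDistribution,
    assign_decile,
    decile_edges,
    detection_fraction,
    fit_lognormal,
    power,
)


class TestFitLognormal:
    def test_closed_form_two_point_fit(self):
        # logs are {-2, -4} so mu = -3 and sigma = 1 under MLE denominators
        values = [math.exp(-2.0)] * 5 + [math.exp(-4.0)] * 5
        dist = fit_lognormal(values)
        assert dist.mu == pytest.approx(-3.0, abs=1e-12)
        assert dist.sigma == pytest.approx(1.0, abs=1e-12)
        assert dist.n_signals == 10

    def test_parameter_recovery(self, rng):
        draws = rng.lognormal(-2.3, 0.6, 50_000)
        draws = draws[draws < 1.0]
        dist = fit_lognormal(draws)
        assert dist.mu == pytest.approx(-2.3, abs=0.01)
        assert dist.sigma == pytest.approx(0.6, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_lognormal([0.1] * 5)
        with pytest.raises(ValueError, match="strictly in"):
            fit_lognormal([0.1] * 9 + [0.0])
        with pytest.raises(ValueError, match="strictly in"):
            fit_lognormal([0.1] * 9 + [1.0])

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_lognormal([0.1] * 10)

    def test_json_round_trip(self, tmp_path):
        dist = SignalStrengthDistribution(mu=-2.5, sigma=0.7, n_signals=42,
                                          source_label="test")
        path = tmp_path / "dist.json"
        dist.to_json(path)
        back = SignalStrengthDistribution.from_json(path)
        assert back == dist

    def test_mass_above_one_negligible_for_realistic_fit(self):
        dist = SignalStrengthDistribution(mu=-2.3, sigma=0.6)
        assert dist.mass_above_one() < 1e-3


class TestDetectionFraction:
    def test_point_mass_reduces_to_power(self):
        dist = SignalStrengthDistribution.point_mass(0.10)
        frac = detection_fraction(dist, 2000, alpha=2e-5)
        assert frac == pytest.approx(float(power(0.10, 2000, 2e-5)), abs=1e-12)
        # and it sits at the value a 2,000-sample study should give (~58.7%)
        assert frac == pytest.approx(0.587, abs=0.002)

    def test_monte_carlo_oracle(self, rng):
        dist = SignalStrengthDistribution(mu=-2.3, sigma=0.6)
        n = 2000
        quad = detection_fraction(dist, n, alpha=2e-5)
        draws = dist.sample(200_000, rng)
        pw = np.asarray(power(draws, n, 2e-5))
        mc = float(pw.mean())
        se = float(pw.std(ddof=1) / math.sqrt(pw.size))
        assert abs(quad - mc) < 3 * se

    def test_strictly_increasing_in_n(self):
        dist = SignalStrengthDistribution(mu=-2.3, sigma=0.6)
        fracs = [detection_fraction(dist, n) for n in (100, 500, 1000, 2000, 5000)]
        assert all(0.0 < f < 1.0 for f in fracs)
        assert np.all(np.diff(fracs) > 0)

    def test_large_n_approaches_one(self):
        dist = SignalStrengthDistribution(mu=-2.3, sigma=0.6)
        assert detection_fraction(dist, 2_000_000) > 0.99

    def test_invalid_n(self):
        dist = SignalStrengthDistribution(mu=-2.3, sigma=0.6)
        with pytest.raises(ValueError):
            detection_fraction(dist, 3)


class TestDecileBins:
    def test_uniform_grid_edges(self):
        values = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
        bins = decile_edges(values)
        assert bins.edges[0] == 0.0
        assert bins.edges[-1] == 1.0
        assert bins.edges[1] == pytest.approx(0.10)
        assert bins.edges[9] == pytest.approx(0.90)

    def test_edges_match_brute_force_order_statistics(self, rng):
        values = rng.uniform(0.01, 0.99, 137)
        bins = decile_edges(values)
        s = np.sort(values)
        for k in range(1, 10):
            expected = s[math.ceil(k / 10 * len(s)) - 1]
            assert bins.edges[k] == pytest.approx(expected)

    def test_identical_values_warn_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            decile_edges([0.5] * 20)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            decile_edges([0.1, 0.2])


class TestAssignDecile:
    @pytest.fixture
    def bins(self):
        return decile_edges(np.arange(1, 101) / 100.0)

    def test_interior_edge_goes_to_lower_bin(self, bins):
        # intervals are (a, b]: a value exactly on an edge belongs below
        assert assign_decile(bins.edges[3], bins) == 3

    def test_extremes(self, bins):
        assert assign_decile(1.0, bins) == 10
        assert assign_decile(5e-324, bins) == 1

    def test_zero_below_support(self, bins):
        with pytest.raises(ValueError, match="below the support"):
            assign_decile(0.0, bins)

    def test_partition_is_balanced(self, rng):
        values = rng.uniform(0.001, 0.999, 1000)
        bins = decile_edges(values)
        counts = np.bincount([assign_decile(v, bins) for v in values],
                             minlength=11)[1:]
        assert counts.sum() == 1000
        assert counts.max() - counts.min() <= 1
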