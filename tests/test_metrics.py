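"""Spike-train measures: binning, van Rossum distance, cross-correlation, hits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynsynrl import (
    BinnedTrain,
    ConfigurationError,
    DistanceConfig,
    InputError,
    SpikeTrain,
    bin_train,
    crosscorr_at_lag,
    hit_rate,
    max_crosscorr,
    van_rossum_distance,
    van_rossum_distance_numeric,
)

from conftest import make_train


# ---------------------------------------------------------------------------
# independent quadrature oracle (coded separately from the package evaluator)
# ---------------------------------------------------------------------------
def quadrature_distance(events_a, events_b, tau, dt=None):
    """Trapezoidal evaluation of (1/tau) * int (f - g)^2 on a fine grid."""
    dt = dt if dt is not None else 1e-3 * tau
    t_end = max(list(events_a) + list(events_b) + [0]) + 12 * tau
    grid = np.arange(0.0, t_end, dt)
    f = np.zeros_like(grid)
    g = np.zeros_like(grid)
    for target, events in ((f, events_a), (g, events_b)):
        for tj in events:
            target[grid >= tj] += np.exp(-(grid[grid >= tj] - tj) / tau)
    return float(np.trapezoid((f - g) ** 2, dx=dt) / tau)


class TestBinning:
    def test_standard_epoch_bins_to_forty_steps(self):
        binned = bin_train(make_train([3, 10, 199]), window_ms=5)
        assert len(binned) == 40

    def test_empty_train_bins_to_zeros(self):
        assert not bin_train(make_train([]), 5).bits.any()

    def test_multiple_spikes_in_one_window_give_one_bit(self):
        binned = bin_train(make_train([0, 1, 2], length_ms=20), window_ms=5)
        assert binned.bits.tolist() == [1, 0, 0, 0]

    def test_indivisible_window_rejected(self):
        with pytest.raises(InputError):
            bin_train(make_train([], length_ms=200), window_ms=7)

    def test_unit_window_is_identity_on_digital_sequences(self):
        bits = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        rebinned = bin_train(SpikeTrain.from_binary(bits), window_ms=1)
        assert np.array_equal(rebinned.bits, bits)


class TestVanRossum:
    def test_identical_trains_have_zero_distance(self, poisson_events):
        assert van_rossum_distance(poisson_events, poisson_events) == 0.0

    def test_single_unpaired_spike_contributes_one_half(self):
        d = van_rossum_distance(make_train([50]), make_train([]))
        assert d == pytest.approx(0.5, abs=1e-12)
        # independent quadrature agrees (grid not aligned with the event,
        # so the jump contributes ~dt/2 quadrature error)
        assert quadrature_distance([50], [], tau=15.0) == pytest.approx(0.5, abs=1e-3)

    def test_distant_spikes_contribute_independently(self):
        cfg = DistanceConfig(tau_c=5.0)
        d = van_rossum_distance(make_train([10], 1000), make_train([900], 1000), cfg)
        assert d == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n_events", [1, 3, 7])
    def test_matches_independent_quadrature(self, rng, n_events):
        for _ in range(3):
            a = np.sort(rng.choice(200, size=n_events, replace=False))
            b = np.sort(rng.choice(200, size=n_events, replace=False))
            d = van_rossum_distance(make_train(a), make_train(b))
            # quadrature error grows with the event count (one jump each)
            assert d == pytest.approx(quadrature_distance(a, b, 15.0), rel=2e-3, abs=2e-3)

    def test_package_numeric_evaluator_agrees_with_closed_form(self, rng):
        a = np.sort(rng.choice(200, size=8, replace=False))
        b = np.sort(rng.choice(200, size=5, replace=False))
        exact = van_rossum_distance(make_train(a), make_train(b))
        numeric = van_rossum_distance_numeric(make_train(a), make_train(b))
        assert numeric == pytest.approx(exact, rel=1e-3)

    def test_binned_trains_use_bin_unit_time_base(self):
        # one mismatched bin: same 0.5 whatever the window, since tau scales
        F = BinnedTrain(np.array([1, 0, 0, 0, 0, 0, 0, 0], dtype=np.uint8), 5)
        G = BinnedTrain(np.zeros(8, dtype=np.uint8), 5)
        assert van_rossum_distance(F, G) == pytest.approx(0.5)
        with pytest.raises(InputError):  # mixed time bases are rejected
            van_rossum_distance(F, make_train([3]))

    def test_displacement_moves_distance_monotonically(self):
        target = make_train([100])
        distances = [
            van_rossum_distance(make_train([t]), target) for t in (70, 85, 95, 100)
        ]
        assert all(np.diff(distances) < 0)
        assert distances[-1] == 0.0

    def test_displacement_cost_decreases_with_tau_c(self):
        """A misplaced spike costs more under a sharper filter: a shift by
        dt contributes 1 - exp(-dt/tau_c). (A pure insertion costs exactly
        1/2 under the unit-jump normalization, independent of tau_c.)"""
        a, b = make_train([100]), make_train([110])
        d_sharp = van_rossum_distance(a, b, DistanceConfig(tau_c=5.0))
        d_broad = van_rossum_distance(a, b, DistanceConfig(tau_c=25.0))
        assert d_sharp == pytest.approx(1.0 - np.exp(-2.0), rel=1e-9)
        assert d_broad == pytest.approx(1.0 - np.exp(-0.4), rel=1e-9)
        assert d_sharp > d_broad
        # insertion invariance under this normalization
        base, spoiled = make_train([50, 150]), make_train([50, 100, 150])
        for tau in (5.0, 25.0):
            assert van_rossum_distance(
                base, spoiled, DistanceConfig(tau_c=tau)
            ) == pytest.approx(0.5, abs=1e-6)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 99), max_size=8), min_size=3, max_size=3))
    def test_sqrt_distance_is_a_metric(self, triple):
        """Non-negativity, symmetry, and the triangle inequality for sqrt(D)
        (D itself is a squared-L2 dissimilarity)."""
        a, b, c = (make_train(sorted(s), length_ms=100) for s in triple)
        dab = van_rossum_distance(a, b)
        dba = van_rossum_distance(b, a)
        assert dab >= 0.0
        assert dab == pytest.approx(dba, rel=1e-9, abs=1e-12)
        assert np.sqrt(van_rossum_distance(a, c)) <= (
            np.sqrt(dab) + np.sqrt(van_rossum_distance(b, c)) + 1e-9
        )

    def test_invalid_filter_constant_rejected(self):
        with pytest.raises(ConfigurationError):
            DistanceConfig(tau_c=-1.0)


class TestCrossCorrelation:
    def test_self_correlation_is_unity(self, rng):
        F = BinnedTrain((rng.random(40) < 0.3).astype(np.uint8), 5)
        assert max_crosscorr(F, F) == pytest.approx(1.0)

    def test_shifted_copy_recovered_at_its_lag(self, rng):
        bits = (rng.random(40) < 0.3).astype(np.uint8)
        shifted = np.zeros_like(bits)
        shifted[2:] = bits[:-2]
        F, G = BinnedTrain(bits, 5), BinnedTrain(shifted, 5)
        lags = range(-5, 6)
        cc = {lag: crosscorr_at_lag(F, G, lag) for lag in lags}
        assert max(cc, key=cc.get) == 2
        # smoothing edge effects keep the peak slightly below unity
        assert max_crosscorr(F, G) >= 0.97

    def test_complemented_sequence_anticorrelates_at_zero_lag(self, rng):
        bits = (rng.random(40) < 0.5).astype(np.uint8)
        F, G = BinnedTrain(bits, 5), BinnedTrain(1 - bits, 5)
        assert crosscorr_at_lag(F, G, 0) < 0.0

    def test_zero_variance_input_warns_and_returns_zero(self):
        F = BinnedTrain(np.zeros(40, dtype=np.uint8), 5)
        G = BinnedTrain(np.ones(40, dtype=np.uint8), 5)
        with pytest.warns(UserWarning):
            assert max_crosscorr(F, G) == 0.0

    def test_bounded_in_minus_one_one(self, rng):
        for _ in range(10):
            F = BinnedTrain((rng.random(40) < 0.3).astype(np.uint8), 5)
            G = BinnedTrain((rng.random(40) < 0.3).astype(np.uint8), 5)
            assert -1.0 <= max_crosscorr(F, G) <= 1.0


class TestHitRate:
    def test_identical_sequences_hit_everywhere(self, poisson_events):
        assert hit_rate(poisson_events, poisson_events) == 100.0

    def test_opposite_sequences_never_hit(self):
        a = BinnedTrain(np.ones(40, dtype=np.uint8), 5)
        b = BinnedTrain(np.zeros(40, dtype=np.uint8), 5)
        assert hit_rate(a, b) == 0.0

    def test_counts_agreements_of_ones_and_zeros(self):
        a = BinnedTrain(np.zeros(40, dtype=np.uint8), 5)
        bits = np.zeros(40, dtype=np.uint8)
        bits[:6] = 1  # 6 disagreements -> 34/40 agree
        assert hit_rate(a, BinnedTrain(bits, 5)) == pytest.approx(85.0)

    def test_length_and_base_mismatches_rejected(self):
        with pytest.raises(InputError):
            hit_rate(make_train([], 100), make_train([], 200))
        with pytest.raises(InputError):
            hit_rate(make_train([], 40), BinnedTrain(np.zeros(40, dtype=np.uint8), 5))
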