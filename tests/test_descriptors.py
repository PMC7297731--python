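import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wph.descriptors import (
    EntropyParams,
    betti_energy,
    boltzmann_persistent_entropy,
    boltzmann_probabilities,
    default_grid,
    max_finite_death,
    persistent_betti_number,
    persistent_entropy,
    prdf_from_barcode,
)
from wph.rips import Barcode


def barcode_from_lengths(lengths, n_infinite=0, k=0):
    bars = [(0.0, float(l)) for l in lengths] + [(0.0, math.inf)] * n_infinite
    return Barcode.from_pairs({k: bars}, max_homology_dim=k)


class TestPBN:
    @pytest.mark.parametrize("x,expected", [(1.5, 2), (1.0, 3), (3.0, 1)])
    def test_indicator_counts_closed_intervals(self, x, expected):
        bc = Barcode.from_pairs({0: [(0, 1), (0, 2), (0, math.inf)]})
        curve = persistent_betti_number(bc, 0, np.array([x]))
        assert curve.values[0] == expected

    def test_dim0_at_zero_equals_point_count_and_is_nonincreasing(self):
        bc = barcode_from_lengths([0.5, 1.0, 2.5], n_infinite=1)
        grid = default_grid(4.0)
        curve = persistent_betti_number(bc, 0, grid)
        assert curve.values[0] == 4
        assert np.all(np.diff(curve.values) <= 0)
        assert curve.values[-1] == 1  # only the infinite bar survives

    def test_unordered_grid_rejected(self):
        bc = barcode_from_lengths([1.0])
        with pytest.raises(ValueError):
            persistent_betti_number(bc, 0, np.array([1.0, 0.5]))


class TestMaxFiniteDeath:
    def test_examples(self):
        assert max_finite_death(barcode_from_lengths([2, 2, 4]), 0) == 4.0
        assert max_finite_death(barcode_from_lengths([1.0]), 0) == 1.0

    def test_random_matches_direct_scan(self, rng):
        deaths = rng.uniform(0.1, 9.0, 17)
        bc = barcode_from_lengths(deaths, n_infinite=2)
        assert max_finite_death(bc, 0) == pytest.approx(deaths.max())

    def test_no_finite_bars_rejected(self):
        with pytest.raises(ValueError):
            max_finite_death(barcode_from_lengths([], n_infinite=1), 0)


class TestPersistentEntropy:
    def test_single_bar_is_zero(self):
        assert persistent_entropy(barcode_from_lengths([3.0]), 0) == 0.0

    def test_lengths_one_three(self):
        # p = {1/4, 3/4}: S = -(1/4)ln(1/4) - (3/4)ln(3/4)
        s = persistent_entropy(barcode_from_lengths([1.0, 3.0]), 0)
        assert s == pytest.approx(0.5623, abs=2e-4)

    def test_infinite_bar_included_forces_zero(self):
        bc = barcode_from_lengths([1.0, 2.0, 5.0], n_infinite=1)
        assert persistent_entropy(bc, 0, include_infinite=True) == 0.0
        assert persistent_entropy(bc, 0, include_infinite=False) > 0.0

    def test_empty_barcode_is_zero(self):
        assert persistent_entropy(Barcode(bars={}), 1) == 0.0


class TestBettiEnergy:
    def test_default_parameters(self):
        assert betti_energy(0.0, 2.0) == pytest.approx(4.0)  # alpha*(2/1)^2
        assert betti_energy(1.0, 1.0) == 0.0

    def test_infinite_bar_infinite_energy(self):
        assert betti_energy(0.0, math.inf) == math.inf

    def test_scaling_with_parameters(self):
        p = EntropyParams(alpha=2.0, eta=0.5, kappa=3)
        assert betti_energy(0.0, 1.0, p) == pytest.approx(2.0 * 2.0**3)


class TestBoltzmannProbabilities:
    def test_equal_lengths_uniform(self):
        p = boltzmann_probabilities(barcode_from_lengths([2.0] * 5), 0)
        assert np.allclose(p, 0.2)

    def test_lengths_one_two(self):
        # E/kBT = {1, 4}: p = {e^-1, e^-4} / Z
        p = boltzmann_probabilities(barcode_from_lengths([1.0, 2.0]), 0)
        assert p == pytest.approx([0.9526, 0.0474], abs=2e-4)

    def test_infinite_bars_get_zero(self):
        bc = barcode_from_lengths([1.0, 2.0], n_infinite=2)
        p = boltzmann_probabilities(bc, 0)
        finite_mask = np.isfinite(bc.get(0)[:, 1])
        assert np.all(p[~finite_mask] == 0.0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_longer_bar_lower_probability(self, rng):
        lengths = np.sort(rng.uniform(0.1, 5.0, 10))
        bc = barcode_from_lengths(lengths)
        bars = bc.get(0)
        p = boltzmann_probabilities(bc, 0)
        order = np.argsort(bars[:, 1] - bars[:, 0])
        assert np.all(np.diff(p[order]) <= 0)

    def test_no_finite_bars_rejected(self):
        with pytest.raises(ValueError):
            boltzmann_probabilities(barcode_from_lengths([], n_infinite=1), 0)


class TestBPE:
    def test_equal_bars_give_ln_n(self):
        assert boltzmann_persistent_entropy(
            barcode_from_lengths([1.5] * 4), 0
        ) == pytest.approx(math.log(4), abs=1e-12)

    def test_lengths_one_two(self):
        s = boltzmann_persistent_entropy(barcode_from_lengths([1.0, 2.0]), 0)
        assert s == pytest.approx(0.191, abs=1e-3)

    def test_empty_barcode_is_zero(self):
        assert boltzmann_persistent_entropy(Barcode(bars={}), 1) == 0.0

    def test_only_infinite_bars_is_zero(self):
        assert boltzmann_persistent_entropy(
            barcode_from_lengths([], n_infinite=3), 1
        ) == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.05, 20.0), min_size=1, max_size=15))
    def test_entropies_bounded_by_ln_n(self, lengths):
        bc = barcode_from_lengths(lengths)
        n = len(lengths)
        for s in (
            persistent_entropy(bc, 0),
            boltzmann_persistent_entropy(bc, 0),
        ):
            assert -1e-12 <= s <= math.log(n) + 1e-9

    def test_equality_at_ln_n_iff_equal_lengths(self):
        equal = barcode_from_lengths([2.0, 2.0, 2.0])
        unequal = barcode_from_lengths([2.0, 2.0, 2.5])
        assert persistent_entropy(equal, 0) == pytest.approx(math.log(3))
        assert boltzmann_persistent_entropy(equal, 0) == pytest.approx(math.log(3))
        assert persistent_entropy(unequal, 0) < math.log(3) - 1e-6
        assert boltzmann_persistent_entropy(unequal, 0) < math.log(3) - 1e-6


class TestPRDF:
    def test_direct_evaluation(self):
        bc = barcode_from_lengths([2.0, 2.0, 4.0])
        curve = prdf_from_barcode(bc, bin_width=1.0, rho=0.01)
        # bin centred at 1.5 covers [1,2): empty; deaths 2,2 land in [2,3)
        idx = np.argmin(np.abs(curve.bin_centers - 2.5))
        expected = 2 / (4 * math.pi * 2.5**2 * 1.0 * 0.01)
        assert curve.values[idx] == pytest.approx(expected)
        assert curve.x_t == 4.0 and curve.n0 == 3

    def test_zero_above_largest_death(self):
        bc = barcode_from_lengths([1.0, 2.0])
        curve = prdf_from_barcode(bc, bin_width=0.5, rho=0.02, r_max=10.0)
        assert np.all(curve.values[curve.bin_centers > 2.5] == 0.0)

    def test_value_independent_of_bin_width(self):
        bc = barcode_from_lengths([3.05])
        for dr in (0.1, 0.05):
            curve = prdf_from_barcode(bc, bin_width=dr, rho=0.01, r_max=5.0)
            r = curve.bin_centers[np.argmax(curve.values)]
            assert curve.values.max() * (4 * math.pi * r**2 * dr * 0.01) == pytest.approx(1.0)

    def test_literal_mode_prefactor(self):
        bc = barcode_from_lengths([2.0, 2.0, 4.0])
        curve = prdf_from_barcode(bc, bin_width=1.0, mode="literal")
        idx = np.argmin(np.abs(curve.bin_centers - 2.5))
        expected = 2 * (4.0 / 3) / (4 * math.pi * 2.5**2)
        assert curve.values[idx] == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        bc = barcode_from_lengths([1.0])
        with pytest.raises(ValueError):
            prdf_from_barcode(bc, bin_width=0.0, rho=0.01)
        with pytest.raises(ValueError):
            prdf_from_barcode(bc, bin_width=0.1)  # conventional mode needs rho
        with pytest.raises(ValueError):
            prdf_from_barcode(barcode_from_lengths([], n_infinite=1), rho=0.01)
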