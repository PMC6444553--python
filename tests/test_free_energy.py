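"""Free-energy estimators and aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dualfep.constants import kT
from dualfep.free_energy import (
    BarConvergenceError,
    BornParameters,
    PerturbationResult,
    WindowSamples,
    bar,
    bar_residual,
    born_correction,
    combine_branches,
    combine_replicates,
    cycle_ddg,
    hysteresis,
    leg_free_energy,
    neighbor_delta_u,
    overlap_sampling,
    read_samples_csv,
    sum_windows,
    write_samples_csv,
    zwanzig,
)
from dualfep.synthetic_data import (
    gen_gaussian_work,
    gen_harmonic_pair,
    harmonic_delta_f,
)

KT = kT(298.0)


class TestNeighborDeltaU:
    def test_identical_potentials_give_zero(self):
        w1 = WindowSamples(0.0, np.ones(10), np.ones(10))
        w2 = WindowSamples(0.02, np.ones(10), np.ones(10))
        f, r = neighbor_delta_u(w1, w2)
        assert np.all(f == 0) and np.all(r == 0)

    def test_constant_gap_scaling(self):
        w1 = WindowSamples(0.0, np.zeros(5), np.full(5, 10.0))
        w2 = WindowSamples(0.02, np.zeros(5), np.full(5, 10.0))
        f, r = neighbor_delta_u(w1, w2)
        assert f == pytest.approx(np.full(5, 0.2))
        assert r == pytest.approx(np.full(5, -0.2))

    def test_matches_mixed_potential_oracle(self):
        rng = np.random.default_rng(31)
        ua, ub = rng.normal(size=20), rng.normal(size=20)
        li, lj = 0.3, 0.45
        w_i = WindowSamples(li, ua, ub)
        w_j = WindowSamples(lj, rng.normal(size=20), rng.normal(size=20))
        f, _ = neighbor_delta_u(w_i, w_j)
        expected = ((1 - lj) * ua + lj * ub) - ((1 - li) * ua + li * ub)
        assert f == pytest.approx(expected)

    def test_equal_lambda_rejected(self):
        w = WindowSamples(0.5, np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            neighbor_delta_u(w, w)


class TestZwanzig:
    def test_zero_work(self):
        assert zwanzig(np.zeros(100)) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-5, 5, allow_nan=False))
    def test_constant_shift(self, c):
        assert zwanzig(np.full(50, c)) == pytest.approx(c, abs=1e-9)

    def test_two_point_closed_form(self):
        c = 1.7
        du = np.array([0.0, c] * 50)
        expected = -KT * math.log((1 + math.exp(-c / KT)) / 2)
        assert zwanzig(du) == pytest.approx(expected, rel=1e-12)


class TestOverlapSampling:
    def test_zero(self):
        assert overlap_sampling(np.zeros(10), np.zeros(10)) == pytest.approx(0.0)

    def test_antisymmetric_constants(self):
        c = 2.5
        assert overlap_sampling(np.full(10, c), np.full(10, -c)) == pytest.approx(c)

    def test_agrees_with_bar_at_high_overlap(self):
        f, r = gen_gaussian_work(0.5, 0.5, 20000, seed=41)
        assert overlap_sampling(f, r) == pytest.approx(bar(f, r), abs=0.02)


class TestBar:
    def test_zero_work_equal_counts(self):
        assert bar(np.zeros(10), np.zeros(10)) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_constant_work_is_exact(self):
        f, r = gen_gaussian_work(1.3, 0.0, 50, seed=1)
        assert bar(f, r) == pytest.approx(1.3, abs=1e-7)

    def test_tiny_sample_matches_root_scan_oracle(self):
        rng = np.random.default_rng(43)
        f = rng.normal(1.0, 1.0, size=5)
        r = rng.normal(-1.0, 1.0, size=5)
        got = bar(f, r, tol=1e-10)
        # independent 1-D root scan of the implicit equation
        grid = np.linspace(-5, 5, 20001)
        res = np.array([bar_residual(x, f, r) for x in grid])
        sign_change = np.where(np.diff(np.sign(res)) != 0)[0]
        assert len(sign_change) >= 1
        root = 0.5 * (grid[sign_change[0]] + grid[sign_change[0] + 1])
        assert got == pytest.approx(root, abs=5e-4)

    def test_gaussian_analytic_recovery(self):
        dg_true, sigma, n = 2.0, 1.5, 5000
        f, r = gen_gaussian_work(dg_true, sigma, n, seed=44)
        dg, err = bar(f, r, return_error=True)
        assert abs(dg - dg_true) < 3 * err

    def test_unequal_sample_counts(self):
        f, r = gen_gaussian_work(1.0, 0.8, 4000, seed=45)
        dg, err = bar(f, r[:1000], return_error=True)
        assert abs(dg - 1.0) < 4 * err

    def test_antisymmetry_exact_under_swap(self):
        f, r = gen_gaussian_work(0.7, 1.0, 500, seed=46)
        assert bar(f, r) == -bar(r, f)

    def test_nonconvergence_carries_last_iterate(self):
        f, r = gen_gaussian_work(1.0, 1.0, 100, seed=47)
        with pytest.raises(BarConvergenceError) as exc:
            bar(f, r, tol=0.0, max_iter=5)
        assert np.isfinite(exc.value.last_iterate)

    def test_estimator_consistency_at_high_overlap(self):
        f, r = gen_gaussian_work(0.3, 0.4, 20000, seed=48)
        dg_bar, err = bar(f, r, return_error=True)
        band = 3 * max(err, 0.003)
        assert abs(zwanzig(f) - dg_bar) < band
        assert abs(-zwanzig(r) - dg_bar) < band
        assert abs(overlap_sampling(f, r) - dg_bar) < band


class TestAggregation:
    def test_sum_windows(self):
        assert sum_windows([1.5]) == 1.5
        assert sum_windows([0.5, -0.5, 0.25]) == pytest.approx(0.25)

    def test_reversed_branch_negates(self):
        windows = gen_harmonic_pair(1.0, 2.0, n_windows=11, n=400, seed=50)
        fwd, per = leg_free_energy(windows)
        rev, _ = leg_free_energy(windows[::-1])
        assert rev == pytest.approx(-fwd, abs=1e-9)

    def test_self_perturbation_sums_to_zero(self):
        windows = gen_harmonic_pair(2.0, 2.0, n_windows=11, n=500, seed=51)
        dg, _ = leg_free_energy(windows)
        assert dg == pytest.approx(0.0, abs=1e-9)

    def test_combine_branches_arithmetic(self):
        assert combine_branches(1.0, 1.0) == 0.0
        assert combine_branches(2.0, -3.0) == 5.0

    def test_branch_route_independence_on_harmonic_pair(self):
        k_a, k_b = 1.0, 4.0
        lam_up = np.linspace(0.5, 1.0, 26)
        lam_down = np.linspace(0.5, 0.0, 26)
        up, _ = leg_free_energy(gen_harmonic_pair(k_a, k_b, n=4000, seed=52,
                                                  lambdas=lam_up))
        down, _ = leg_free_energy(gen_harmonic_pair(k_a, k_b, n=4000, seed=53,
                                                    lambdas=lam_down))
        combined = combine_branches(up, down)
        assert combined == pytest.approx(harmonic_delta_f(k_a, k_b), abs=0.02)

    def test_combine_replicates_closed_forms(self):
        mean, sem = combine_replicates([1.0, 1.0, 1.0])
        assert mean == 1.0 and sem == 0.0
        a, b = -4.2, -3.0
        mean, sem = combine_replicates([a, b])
        assert mean == pytest.approx((a + b) / 2)
        assert sem == pytest.approx(abs(a - b) / 2)
        mean, sem = combine_replicates([2.5])
        assert mean == 2.5 and sem is None

    def test_cycle_ddg_quadrature(self):
        # SEM of two replicates {m−d, m+d} is exactly d
        bound = PerturbationResult([-5.3, -4.7], leg="bound")
        water = PerturbationResult([-3.4, -2.6], leg="water")
        assert bound.sem == pytest.approx(0.3)
        ddg, sem = cycle_ddg(bound, water)
        assert ddg == pytest.approx(-2.0)
        assert sem == pytest.approx(0.5)

    def test_cycle_identical_legs_zero(self):
        leg = PerturbationResult([1.0, 1.2, 0.8])
        ddg, _ = cycle_ddg(leg, leg)
        assert ddg == 0.0

    def test_cycle_estimator_mismatch(self):
        a = PerturbationResult([1.0, 1.1], estimator="bar")
        b = PerturbationResult([1.0, 1.1], estimator="os")
        with pytest.raises(ValueError):
            cycle_ddg(a, b)

    @pytest.mark.parametrize("fwd,bwd,expected", [
        (0.20, -0.19, 0.01),   # annihilation vs creation of the same mimic
        (1.0, -1.0, 0.0),
        (8.16, -7.20, 0.96),
    ])
    def test_hysteresis(self, fwd, bwd, expected):
        assert hysteresis(fwd, bwd) == pytest.approx(expected)


class TestBorn:
    def test_zero_charge_and_vacuum_limits(self):
        assert born_correction(BornParameters(0.0, 25.0, 80.0)) == 0.0
        assert born_correction(BornParameters(-1.0, 25.0, 1.0)) == 0.0

    def test_unit_anion_in_water_sphere(self):
        dg = born_correction(BornParameters(-1.0, 25.0, 80.0))
        assert dg == pytest.approx(-332.0 / 50.0 * (79.0 / 80.0), rel=1e-12)
        assert dg == pytest.approx(-6.557, abs=1e-3)

    def test_monotone_in_charge_and_radius(self):
        mags = [abs(born_correction(BornParameters(q, 25.0, 80.0)))
                for q in (0.0, 1.0, 2.0, 3.0)]
        assert mags == sorted(mags)
        radii = [abs(born_correction(BornParameters(-1.0, r, 80.0)))
                 for r in (15.0, 20.0, 25.0, 30.0)]
        assert radii == sorted(radii, reverse=True)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            BornParameters(-1.0, 0.0, 80.0)
        with pytest.raises(ValueError):
            BornParameters(-1.0, 25.0, 0.5)


class TestSamplesCsv:
    def test_roundtrip(self, tmp_path):
        windows = gen_harmonic_pair(1.0, 3.0, n_windows=5, n=50, seed=60)
        p = tmp_path / "samples.csv"
        write_samples_csv(windows, p)
        back = read_samples_csv(p)
        assert [w.lam for w in back] == [w.lam for w in windows]
        for a, b in zip(back, windows):
            assert a.u_a == pytest.approx(b.u_a)
            assert a.u_b == pytest.approx(b.u_b)
            assert a.temperature == b.temperature

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="expected columns"):
            read_samples_csv(p)
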