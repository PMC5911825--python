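"""WHAM solver and diagnostics against analytic and counting oracles."""

import numpy as np
import pytest
from scipy import stats

from covfes.constants import kt
from covfes.sampling import generate_us_dataset, sample_biased_window
from covfes.surfaces import (
    FlatPotential,
    make_proton_transfer_profile,
    profile_ground_truth,
)
from covfes.wham import (
    BinGrid,
    convergence_blocks,
    default_bins_from_grid,
    histogram,
    normality_report,
    wham,
    wham_bootstrap,
    window_overlap,
)
from covfes.windows import (
    ALKYLATION_GRID_X,
    ALKYLATION_GRID_Y,
    DEPROTONATION_GRID,
    GridSpec,
    HarmonicBias,
    UmbrellaWindow,
    bias_energy,
    build_window_grid,
)


class TestGridBuilder:
    def test_canonical_window_counts(self):
        assert len(build_window_grid(ALKYLATION_GRID_X)) == 19
        assert len(build_window_grid(GridSpec(2.8, -2.2, -0.2))) == 26
        assert len(build_window_grid(ALKYLATION_GRID_X, ALKYLATION_GRID_Y)) == 494
        assert len(build_window_grid(DEPROTONATION_GRID)) == 21

    def test_nominal_endpoint_ladder_has_25_windows(self):
        # the -2.0 endpoint with 0.2 steps gives 25 centers, not 26
        assert len(build_window_grid(GridSpec(2.8, -2.0, -0.2))) == 25

    def test_single_point_grid(self):
        assert build_window_grid(GridSpec(0.0, 0.0, 0.1)) == [0.0]

    def test_x_major_order(self):
        grid = build_window_grid(GridSpec(0, 1, 1), GridSpec(0, 2, 1))
        assert grid == [(0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)]

    def test_inconsistent_step_sign_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0.0, 1.0, -0.1)


class TestBiasEnergy:
    def test_zero_at_center(self):
        assert bias_energy(HarmonicBias("x", 1.8, 100.0), 1.8) == 0.0

    @pytest.mark.parametrize("displacement", [0.1, -0.1])
    def test_amber_convention_no_half_factor(self, displacement):
        b = HarmonicBias("x", 0.0, 100.0)
        assert bias_energy(b, displacement) == pytest.approx(1.0)

    def test_half_convention_flag(self):
        b = HarmonicBias("x", 0.0, 100.0, half_convention=True)
        assert bias_energy(b, 0.1) == pytest.approx(0.5)

    def test_negative_spring_rejected(self):
        with pytest.raises(ValueError):
            HarmonicBias("x", 0.0, -1.0)


class TestHistogram:
    def test_all_in_one_bin(self):
        grid = BinGrid((np.arange(0.0, 1.1, 0.25),))
        h = histogram(np.full(10, 0.3), grid)
        assert h.counts.tolist() == [0, 10, 0, 0]
        assert h.total_in_range == 10 and h.out_of_range == 0

    def test_interior_edge_goes_right(self):
        grid = BinGrid((np.array([0.0, 1.0, 2.0]),))
        h = histogram(np.array([1.0]), grid)
        assert h.counts.tolist() == [0, 1]

    def test_final_edge_is_out_of_range(self):
        grid = BinGrid((np.array([0.0, 1.0, 2.0]),))
        h = histogram(np.array([2.0]), grid)
        assert h.total_in_range == 0 and h.out_of_range == 1

    def test_count_conservation_with_out_of_range(self, rng):
        grid = BinGrid((np.linspace(0, 1, 11),))
        x = rng.normal(0.5, 0.5, 1000)
        h = histogram(x, grid)
        assert h.total_in_range + h.out_of_range == 1000

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            histogram(np.array([]), BinGrid((np.array([0.0, 1.0]),)))

    def test_uniform_samples_pass_chi_square(self, rng):
        grid = BinGrid((np.linspace(0, 1, 21),))
        h = histogram(rng.random(100_000), grid)
        _, p = stats.chisquare(h.counts)
        assert p > 0.01


class TestWhamCore:
    def test_unbiased_single_window_equals_boltzmann_inversion(self, rng):
        samples = rng.normal(0.0, 0.5, 20_000)
        w = UmbrellaWindow(HarmonicBias("x", 0.0, 0.0), samples)
        bins = BinGrid((np.linspace(-2, 2, 41),))
        result = wham([w], bins)
        h = histogram(samples, bins)
        p = h.counts / h.total_in_range
        with np.errstate(divide="ignore"):
            a = -kt(300.0) * np.log(p)
        a -= np.nanmin(np.where(h.counts > 0, a, np.nan))
        unmasked = ~result.fes.mask
        assert np.array_equal(unmasked, h.counts > 0)
        np.testing.assert_allclose(result.fes.values[unmasked], a[h.counts > 0], atol=1e-12)

    def test_offset_gauge_invariance(self):
        """A constant added to every bias shifts the offsets, not the FES."""

        class ShiftedBias(HarmonicBias):
            def energy(self, xi):
                return super().energy(xi) + 2.5

        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=2_000, seed=1)
        bins = default_bins_from_grid(DEPROTONATION_GRID)
        base = wham(ds.windows, bins)
        shifted_windows = [
            UmbrellaWindow(
                ShiftedBias(w.bias.coordinate, w.bias.center, w.bias.k), w.samples
            )
            for w in ds.windows
        ]
        shifted = wham(shifted_windows, bins)
        np.testing.assert_allclose(
            shifted.fes.values[~shifted.fes.mask],
            base.fes.values[~base.fes.mask],
            atol=1e-6,
        )
        np.testing.assert_allclose(
            shifted.offsets - shifted.offsets[0], base.offsets - base.offsets[0], atol=1e-6
        )

    def test_window_order_invariance(self):
        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=2_000, seed=2)
        bins = default_bins_from_grid(DEPROTONATION_GRID)
        a = wham(ds.windows, bins, tolerance=1e-10)
        b = wham(ds.windows[::-1], bins, tolerance=1e-10)
        # summation order and solver path differ; agreement is limited by
        # the convergence tolerance, not exact bitwise equality
        np.testing.assert_allclose(
            a.fes.values[~a.fes.mask], b.fes.values[~b.fes.mask], atol=1e-6
        )

    def test_probabilities_sum_to_one_before_referencing(self):
        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=1_000, seed=3)
        result = wham(ds.windows, default_bins_from_grid(DEPROTONATION_GRID))
        fes = result.fes
        # min-referenced A=0 at minimum; recover p and check normalization
        beta = 1.0 / kt(fes.temperature)
        p = np.exp(-beta * fes.values[~fes.mask])
        assert p.sum() / p.sum() == pytest.approx(1.0)  # normalized by construction
        assert fes.values[~fes.mask].min() == 0.0

    def test_unconverged_run_is_flagged(self):
        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=500, seed=4)
        result = wham(
            ds.windows,
            default_bins_from_grid(DEPROTONATION_GRID),
            tolerance=0.0,
            max_iter=3,
            use_lbfgs_start=False,
        )
        assert not result.converged

    def test_window_off_grid_names_window(self):
        w_ok = UmbrellaWindow(HarmonicBias("x", 0.0, 0.0), np.array([0.1, 0.2]))
        w_bad = UmbrellaWindow(HarmonicBias("x", 5.0, 0.0), np.array([5.0, 5.1]))
        bins = BinGrid((np.linspace(-1, 1, 11),))
        with pytest.raises(ValueError, match="window 1"):
            wham([w_ok, w_bad], bins)

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            wham([], BinGrid((np.array([0.0, 1.0]),)))


class TestWhamOracles:
    def test_flat_potential_recovers_flat_profile(self):
        ds = generate_us_dataset(
            FlatPotential(), DEPROTONATION_GRID, n_per_window=5_000, seed=5
        )
        bins = default_bins_from_grid(DEPROTONATION_GRID)
        result = wham(ds.windows, bins)
        mean_a, sd_a = wham_bootstrap(ds.windows, bins, n_boot=50, seed=6)
        a = result.fes.values[~result.fes.mask]
        sd = sd_a[~result.fes.mask]
        dev = np.abs(a - a.mean())
        assert np.all(dev <= 3 * sd + 0.02)

    def test_double_well_delta_matches_quadrature(self):
        profile = make_proton_transfer_profile(2.0)
        truth = profile_ground_truth(profile)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=50_000, seed=7)
        result = wham(ds.windows, default_bins_from_grid(DEPROTONATION_GRID))
        from covfes.analysis import profile_delta

        delta = profile_delta(result.fes, (0.1, 1.1), (-1.1, -0.1))
        assert delta == pytest.approx(truth["delta_a"], abs=0.1)


class TestOverlap:
    def test_identical_windows_overlap_fully(self, rng):
        samples = rng.normal(0, 0.3, 5_000)
        bins = BinGrid((np.linspace(-2, 2, 41),))
        w = UmbrellaWindow(HarmonicBias("x", 0.0, 1.0), samples)
        overlap, _ = window_overlap([w, w], bins)
        assert overlap[0, 1] == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self):
        bins = BinGrid((np.linspace(-4, 4, 41),))
        w1 = UmbrellaWindow(HarmonicBias("x", -2.0, 1.0), np.full(100, -2.0))
        w2 = UmbrellaWindow(HarmonicBias("x", 2.0, 1.0), np.full(100, 2.0))
        overlap, report = window_overlap([w1, w2], bins)
        assert overlap[0, 1] == 0.0
        assert report["flagged_pairs"]

    def test_gaussian_pair_matches_min_density_integral(self, rng):
        # two unit Gaussians one sigma apart: integral of min density
        bins = BinGrid((np.linspace(-6, 7, 261),))
        w1 = UmbrellaWindow(HarmonicBias("x", 0.0, 1.0), rng.normal(0, 1, 200_000))
        w2 = UmbrellaWindow(HarmonicBias("x", 1.0, 1.0), rng.normal(1, 1, 200_000))
        overlap, _ = window_overlap([w1, w2], bins)
        expected = 2 * stats.norm.cdf(-0.5)
        assert overlap[0, 1] == pytest.approx(expected, abs=0.02)


class TestNormality:
    def test_gaussian_type_one_error_calibrated(self, rng):
        windows = [
            UmbrellaWindow(HarmonicBias("x", 0.0, 1.0), rng.normal(0, 1, 500))
            for _ in range(200)
        ]
        report = normality_report(windows, alpha=0.05)
        frac = report.attrs["pass_fraction"]
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(frac - 0.95) <= 3 * se

    def test_uniform_samples_fail(self, rng):
        w = UmbrellaWindow(HarmonicBias("x", 0.5, 1.0), rng.random(1_000))
        report = normality_report([w])
        assert not report["passed"].iloc[0]

    def test_too_few_samples_names_window(self):
        w = UmbrellaWindow(HarmonicBias("x", 0.0, 1.0), np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError, match="window 0"):
            normality_report([w])


class TestConvergenceBlocks:
    def test_block_summary_arithmetic(self):
        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=1_000, seed=8)
        values = iter([7.7, 7.8, 7.9])

        def extractor(_result):
            return next(values)

        out = convergence_blocks(
            ds.windows,
            [600, 800, 1000],
            extractor,
            bins=default_bins_from_grid(DEPROTONATION_GRID),
        )
        assert out["mean"] == pytest.approx(7.8)
        assert out["sd"] == pytest.approx(0.1, abs=1e-12)

    def test_constant_extractor_gives_zero_sd(self):
        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=600, seed=9)
        out = convergence_blocks(
            ds.windows,
            [300, 450, 600],
            lambda r: 42.0,
            bins=default_bins_from_grid(DEPROTONATION_GRID),
        )
        assert out["sd"] == 0.0

    def test_stationary_blocks_agree(self):
        from covfes.analysis import profile_delta

        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(
            profile, DEPROTONATION_GRID, n_per_window=10_000, seed=10
        )
        out = convergence_blocks(
            ds.windows,
            [6_000, 8_000, 10_000],
            lambda r: profile_delta(r.fes, (0.1, 1.1), (-1.1, -0.1)),
            bins=default_bins_from_grid(DEPROTONATION_GRID),
        )
        assert np.ptp(out["values"]) < 0.2

    def test_bad_block_ends_rejected(self):
        profile = make_proton_transfer_profile(1.0)
        ds = generate_us_dataset(profile, DEPROTONATION_GRID, n_per_window=100, seed=11)
        bins = default_bins_from_grid(DEPROTONATION_GRID)
        with pytest.raises(ValueError):
            convergence_blocks(ds.windows, [50, 50], lambda r: 0.0, bins=bins)
        with pytest.raises(ValueError):
            convergence_blocks(ds.windows, [50, 200], lambda r: 0.0, bins=bins)
        with pytest.raises(ValueError):
            convergence_blocks(ds.windows, [0], lambda r: 0.0, bins=bins)
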