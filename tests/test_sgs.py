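"""Spatial genetic structure: kinship, correlogram, slope, Sp, dispersal."""

import numpy as np
import pandas as pd
import pytest

from aflpop import sgs
from aflpop.freqs import compute_freq_table, freq_table_from_counts
from aflpop.io import BandMatrix
from aflpop.sim import simulate_spatial_population
from conftest import random_bands, single_site_table


def _freqs_for(bands, fis=-0.14):
    samples = pd.DataFrame({"sample_id": bands.sample_ids, "site": "S",
                            "habitat": "h", "x": 0.0, "y": 0.0,
                            "elevation": 0.0})
    return compute_freq_table(bands, samples, fis=fis, by=("site",))


class TestDominantKinship:
    def test_all_absent_pair_at_half_frequency(self):
        # both individuals band-absent everywhere, q = 0.5, F = 0:
        # x = 0, F_ij = sum (0 - 0.5)^2 / sum 0.25 = 1
        L = 6
        bands = BandMatrix(["a", "b"], [f"m{j}" for j in range(L)],
                           np.zeros((2, L), dtype=np.int8))
        # fix reference frequencies at p = q = 0.5 via explicit counts
        ft = freq_table_from_counts(["S"], bands.marker_ids,
                                    np.full((1, L), 30), np.full((1, L), 30),
                                    fis=0.0)
        K = sgs.dominant_kinship_matrix(bands, ft, fis=0.0)
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_random_profiles_near_zero(self, rng):
        bands = random_bands(rng, 30, 400)
        ft = _freqs_for(bands)
        K = sgs.dominant_kinship_matrix(bands, ft)
        np.testing.assert_allclose(K.values, K.values.T, equal_nan=True)
        iu, ju, v = K.condensed()
        # independent individuals: mean kinship slightly negative, near zero
        assert abs(np.nanmean(v)) < 0.05

    def test_centering_identity_and_mean_bound(self, rng):
        # per-locus dosage deviations sum to zero by construction, hence the
        # all-pairs mean is -sum Var(x/2) / ((N-1) sum q(1-q)), in (-1/(N-1), 0)
        bands = random_bands(rng, 25, 300)
        ft = _freqs_for(bands)
        decomp = sgs.dominant_kinship(bands, ft)
        colsum = decomp.centered.sum(axis=0)
        # exact centering holds wherever the genotype law needed no
        # truncation, i.e. estimated p below 1 - (-F)/(1-F) at F < 0
        fis = ft.fis
        untruncated = (decomp.weights > 0) & (ft.p[0] <= 1 + fis / (1 - fis))
        np.testing.assert_allclose(colsum[untruncated], 0.0, atol=1e-9)
        iu, ju, v = decomp.matrix().condensed()
        n = bands.n_samples
        assert -1.0 / (n - 1) - 1e-9 < np.nanmean(v) < 0.0


class TestDistanceClasses:
    def test_default_widths(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        bounds = sgs.build_distance_classes(coords)
        assert len(bounds) == 21
        np.testing.assert_allclose(np.diff(bounds), 25.0)

    def test_explicit_bounds(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0]])
        bounds = sgs.build_distance_classes(coords, n_classes=4, dmax=100)
        np.testing.assert_allclose(bounds, [0, 25, 50, 75, 100])

    def test_boundary_pair_left_open_right_closed(self):
        bounds = np.linspace(0, 500, 21)
        idx = sgs.assign_classes(np.array([25.0, 25.01, 600.0]), bounds)
        assert idx[0] == 0          # exactly 25 m -> first class (0, 25]
        assert idx[1] == 1
        assert idx[2] == -1         # beyond dmax excluded

    def test_duplicate_coordinates_jittered_with_warning(self):
        with pytest.warns(UserWarning, match="jitter"):
            _, _, d = sgs.pair_distances(
                np.array([[0, 0], [0, 0], [5, 5]], dtype=float), rng=0)
        assert (d > 0).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            sgs.build_distance_classes(np.zeros((1, 2)))


class TestCorrelogram:
    def test_null_data_inside_envelope(self, rng):
        bands = random_bands(rng, 40, 150)
        samples = single_site_table(bands, rng, extent=400.0)
        ft = compute_freq_table(bands, samples, by=("site",))
        K = sgs.dominant_kinship_matrix(bands, ft)
        coords = samples[["x", "y"]].to_numpy()
        bounds = sgs.build_distance_classes(coords, n_classes=10, dmax=400)
        corr = sgs.autocorrelogram(K, coords, bounds, n_perm=200, seed=1)
        ok = np.isfinite(corr.mean_f) & np.isfinite(corr.envelope_lo)
        inside = ((corr.mean_f >= corr.envelope_lo)
                  & (corr.mean_f <= corr.envelope_hi))[ok]
        # panmictic data: the observed means are draws from the null
        assert inside.mean() >= 0.8

    def test_no_permutations_still_computes_means(self, rng):
        bands = random_bands(rng, 10, 60)
        samples = single_site_table(bands, rng)
        ft = compute_freq_table(bands, samples, by=("site",))
        K = sgs.dominant_kinship_matrix(bands, ft)
        coords = samples[["x", "y"]].to_numpy()
        corr = sgs.autocorrelogram(K, coords,
                                   sgs.build_distance_classes(coords, 5, 300),
                                   n_perm=0)
        assert corr.envelope_lo is None
        assert np.isfinite(corr.mean_f).any()

    def test_clustered_population_first_class_exceeds_envelope(self, rng):
        bands, samples = simulate_spatial_population(
            grid=6, deme_size=25, migration=0.02, n_generations=400,
            n_loci=150, sampled_per_deme=2, deme_spacing=60.0, rng=rng)
        ft = compute_freq_table(bands, samples, by=("site",))
        K = sgs.dominant_kinship_matrix(bands, ft)
        coords = samples[["x", "y"]].to_numpy()
        bounds = sgs.build_distance_classes(coords, n_classes=8, dmax=320)
        corr = sgs.autocorrelogram(K, coords, bounds, n_perm=200, seed=3)
        assert corr.f1 > corr.envelope_hi[0]


class TestSlopeAndSp:
    def test_closed_form_ols(self):
        # three pairs (d, F) = (1, .03), (2, .02), (3, .01) -> slope -0.01
        assert sgs._ols_slope([1, 2, 3], [0.03, 0.02, 0.01]) == pytest.approx(-0.01)

    def test_constant_kinship_zero_slope_zero_se(self, rng):
        # all profiles identical -> F_ij constant across pairs
        row = (rng.random(80) < 0.6).astype(np.int8)
        bands = BandMatrix([f"s{i}" for i in range(6)],
                           [f"m{j}" for j in range(80)],
                           np.tile(row, (6, 1)))
        ft = freq_table_from_counts(["S"], bands.marker_ids,
                                    np.full((1, 80), 20), np.full((1, 80), 20),
                                    fis=0.0)
        decomp = sgs.dominant_kinship(bands, ft, fis=0.0)
        coords = np.column_stack([np.arange(6) * 10.0, np.zeros(6)])
        b, se = sgs.kinship_distance_slope(decomp, coords, scale="linear")
        assert b == pytest.approx(0.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_ibd_population_has_significant_negative_slope(self, rng):
        bands, samples = simulate_spatial_population(
            grid=7, deme_size=25, migration=0.03, n_generations=400,
            n_loci=150, sampled_per_deme=2, rng=rng)
        ft = compute_freq_table(bands, samples, by=("site",))
        decomp = sgs.dominant_kinship(bands, ft)
        b, se = sgs.kinship_distance_slope(
            decomp, samples[["x", "y"]].to_numpy(), scale="log")
        assert b < 0 and abs(b) / se > 2

    def test_sp_worked_examples(self):
        assert round(sgs.sp_statistic(-0.016, 0.037), 3) == 0.017
        assert round(sgs.sp_statistic(-0.012, 0.04), 3) == 0.013
        assert sgs.sp_statistic(0.0, 0.05) == 0.0
        with pytest.raises(ValueError):
            sgs.sp_statistic(-0.01, 1.0)

    def test_sp_scale_invariance_on_log_slope(self, rng):
        # multiplying coordinates by a constant shifts ln(d) -> slope unchanged
        bands, samples = simulate_spatial_population(
            grid=5, deme_size=25, migration=0.05, n_generations=300,
            n_loci=100, sampled_per_deme=2, rng=rng)
        ft = compute_freq_table(bands, samples, by=("site",))
        decomp = sgs.dominant_kinship(bands, ft)
        coords = samples[["x", "y"]].to_numpy()
        b1, _ = sgs.kinship_distance_slope(decomp, coords, scale="log")
        b2, _ = sgs.kinship_distance_slope(decomp, coords * 3.7, scale="log")
        assert b1 == pytest.approx(b2, rel=1e-9)


class TestDispersal:
    def test_first_iterate_from_printed_inputs(self):
        # Nb0 = -(1 - F1)/b with F1 = 0.037, b = -0.016
        assert sgs.neighborhood_size(-0.016, 0.037) == pytest.approx(60.19, abs=0.01)

    def test_sigma_consistency_with_half_density(self):
        # sigma = sqrt(Nb / (4 pi De)), De = D/2: Nb = 65.62, D = 0.005 -> 45.7 m
        assert sgs.sigma_from_nb(65.62, 0.005 / 2) == pytest.approx(45.7, abs=0.05)

    def test_positive_slope_flags_non_convergent(self, rng):
        bands = random_bands(rng, 12, 60)
        samples = single_site_table(bands, rng)
        ft = compute_freq_table(bands, samples, by=("site",))
        decomp = sgs.dominant_kinship(bands, ft)
        est = sgs.dispersal_estimate(decomp, samples[["x", "y"]].to_numpy(),
                                     b=+0.01, f1=0.03, D=0.005)
        assert not est.converged and np.isnan(est.sigma_g)

    def test_iterative_estimate_on_ibd_data(self, rng):
        bands, samples = simulate_spatial_population(
            grid=7, deme_size=25, migration=0.03, n_generations=400,
            n_loci=150, sampled_per_deme=2, rng=rng)
        ft = compute_freq_table(bands, samples, by=("site",))
        decomp = sgs.dominant_kinship(bands, ft)
        coords = samples[["x", "y"]].to_numpy()
        corr = sgs.autocorrelogram(
            decomp.matrix(), coords,
            sgs.build_distance_classes(coords, 10, 400), n_perm=0)
        b, _ = sgs.kinship_distance_slope(decomp, coords, scale="log")
        est = sgs.dispersal_estimate(decomp, coords, b, corr.f1, D=0.01)
        if est.converged:
            assert est.Nb > 0 and est.sigma_g > 0
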