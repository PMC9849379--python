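import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvpac import core
from cvpac.io import window_from_samples
from cvpac.simulate import CouplingComponent, CouplingProfile, generate_coupled_signal

from conftest import random_images, random_simplex


def dist(p):
    p = np.asarray(p, float)
    return core.PhaseAmplitudeDistribution(p, core.FrequencyGrid.default().bin_centers())


class TestFrequencyGrid:
    def test_default_edges(self, grid):
        assert grid.low_edges[0] == 1.0 and grid.low_edges[-1] == 10.0
        assert grid.high_edges[0] == 30.0 and grid.high_edges[-1] == pytest.approx(160.0)
        assert grid.shape == (10, 10)
        # equal steps in log space
        assert np.allclose(np.diff(np.log(grid.low_edges)), np.log(10) / 10)
        assert np.allclose(np.diff(np.log(grid.high_edges)), np.log(160 / 30) / 10)

    def test_centers_inside_intervals(self, grid):
        for edges, centers in (
            (grid.low_edges, grid.low_centers),
            (grid.high_edges, grid.high_centers),
        ):
            assert np.all(centers > edges[:-1]) and np.all(centers < edges[1:])

    def test_monotone_edges_required(self):
        with pytest.raises(ValueError, match="increasing"):
            core.FrequencyGrid([1, 1, 2], [30, 60, 120])

    def test_cell_of(self, grid):
        assert grid.cell_of(2.5, 100.0) == (7, 3)
        with pytest.raises(ValueError):
            grid.cell_of(0.5, 100.0)


class TestPhaseAmplitudeDistribution:
    def test_constant_amplitude_is_uniform(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 20000)
        d = core.phase_amplitude_distribution(phase, np.ones_like(phase))
        np.testing.assert_allclose(d.p, 1 / 18, atol=1e-12)

    def test_single_bin_mass_is_one_hot(self):
        centers = dist(np.ones(18) / 18).bin_centers
        phase = np.full(1000, centers[5])
        amp = np.ones(1000)
        d = core.phase_amplitude_distribution(phase, amp)
        # every other bin is empty -> flagged, means 0
        assert d.p[5] == pytest.approx(1.0)
        assert d.empty_bins.sum() == 17

    def test_cosine_profile_matches_bin_integrals(self):
        """amplitude = 1 + cos(phase) with uniform phase: P(j) equals the
        normalised analytic bin integral of the profile."""
        n = 18
        phase = np.linspace(-np.pi, np.pi, 200000, endpoint=False)
        d = core.phase_amplitude_distribution(phase, 1 + np.cos(phase), n_bins=n)
        edges = -np.pi + np.arange(n + 1) * (2 * np.pi / n)
        integrals = np.diff(edges) + (np.sin(edges[1:]) - np.sin(edges[:-1]))
        np.testing.assert_allclose(d.p, integrals / integrals.sum(), atol=1e-4)

    def test_normalisation_invariant(self, rng):
        for _ in range(20):
            n = rng.integers(100, 5000)
            d = core.phase_amplitude_distribution(
                rng.uniform(-np.pi, np.pi, n), rng.random(n)
            )
            assert d.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_bin_strict_mode(self):
        phase = np.zeros(100)
        with pytest.raises(ValueError, match="empty"):
            core.phase_amplitude_distribution(phase, np.ones(100), empty_bin="error")

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            core.phase_amplitude_distribution(np.zeros(5), np.zeros(6))


class TestModulationIndex:
    def test_uniform_is_zero(self):
        assert core.kl_to_uniform(dist(np.ones(18) / 18)) == 0.0
        assert core.modulation_index(dist(np.ones(18) / 18)) == 0.0

    def test_one_hot_attains_log_n(self):
        p = np.zeros(18)
        p[7] = 1.0
        assert core.kl_to_uniform(dist(p)) == pytest.approx(np.log(18), abs=1e-15)
        assert core.modulation_index(dist(p)) == pytest.approx(1.0, abs=1e-15)

    def test_two_bin_distribution(self):
        p = np.zeros(18)
        p[0] = p[1] = 0.5
        assert core.kl_to_uniform(dist(p)) == pytest.approx(np.log(9.0), abs=1e-12)
        assert core.modulation_index(dist(p)) == pytest.approx(
            np.log(9) / np.log(18), abs=1e-12
        )

    def test_kl_matches_direct_summation_oracle(self, rng):
        """Vectorised KL equals a term-by-term python-loop oracle."""
        for p in random_simplex(rng, 1000):
            direct = sum(pj * np.log(pj * 18) for pj in p if pj > 0)
            assert abs(core.kl_to_uniform(dist(p)) - direct) < 1e-10

    def test_bounds_on_random_simplex(self, rng):
        vals = [core.modulation_index(dist(p)) for p in random_simplex(rng, 500)]
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError, match="normalised"):
            core.kl_to_uniform(dist(np.ones(18)))


class TestCouplingPhase:
    def test_one_hot_at_bin_center(self):
        d0 = dist(np.ones(18) / 18)
        j = int(np.argmin(np.abs(d0.bin_centers)))  # bin nearest 0 rad
        p = np.zeros(18)
        p[j] = 1.0
        assert core.coupling_phase(dist(p)) == d0.bin_centers[j]

    def test_shifted_cosine_peak(self):
        phase = np.linspace(-np.pi, np.pi, 100000, endpoint=False)
        d = core.phase_amplitude_distribution(phase, 1 + np.cos(phase - np.pi / 2))
        assert abs(core.coupling_phase(d) - np.pi / 2) <= np.pi / 9

    def test_uniform_tie_breaks_to_lowest_bin(self):
        d = dist(np.ones(18) / 18)
        assert core.coupling_phase(d) == d.bin_centers[0]

    def test_range(self, rng):
        for p in random_simplex(rng, 50):
            psi = core.coupling_phase(dist(p))
            assert -np.pi <= psi < np.pi


class TestCvpacPixel:
    @pytest.mark.parametrize(
        "strength,phase,expected",
        [
            (1.0, 0.0, 1 + 0j),
            (0.5, np.pi / 2, 0.5j),
            (0.7601, -np.pi / 3, 0.38005 - 0.658266j),
            (0.0, 2.0, 0j),
        ],
    )
    def test_polar_identity(self, strength, phase, expected):
        assert core.cvpac_pixel(strength, phase) == pytest.approx(expected, abs=1e-5)

    def test_out_of_range_strength(self):
        with pytest.raises(ValueError):
            core.cvpac_pixel(1.2, 0.0)
        with pytest.raises(ValueError):
            core.cvpac_pixel(-0.1, 0.0)


class TestComputeCvpac:
    def test_simulated_coupling_peaks_at_the_right_cell(self, coupled_image):
        img, (r, c), psi = coupled_image
        assert np.unravel_index(np.argmax(img.strength), img.strength.shape) == (r, c)
        delta = np.angle(np.exp(1j * (img.phase[r, c] - psi)))
        assert abs(delta) <= np.pi / 9

    def test_white_noise_far_below_coupled_peak(self, rng, grid, coupled_image):
        img, (r, c), _ = coupled_image
        noise = window_from_samples(rng.standard_normal(10000), 1000.0)
        noise_img = core.compute_cvpac(noise, grid)
        assert noise_img.strength.max() < 0.5 * img.strength[r, c]

    def test_scale_invariance(self, grid):
        prof = CouplingProfile(
            components=(CouplingComponent(3.0, 90.0, 0.6, 0.3),), noise_sd=0.2
        )
        w1 = generate_coupled_signal(prof, seed=7)
        w2 = generate_coupled_signal(prof, seed=7)
        w2.samples = 10.0 * w2.samples
        w2.context_before = 10.0 * w2.context_before
        w2.context_after = 10.0 * w2.context_after
        i1, i2 = core.compute_cvpac(w1, grid), core.compute_cvpac(w2, grid)
        np.testing.assert_allclose(i1.pixels, i2.pixels, atol=1e-12)

    def test_phase_equivariance(self, grid):
        """Shifting the simulated coupled phase by delta rotates the
        recovered pixel argument by delta (within bin width)."""
        f_low, f_high = float(grid.low_centers[4]), float(grid.high_centers[7])
        base = np.pi / 4
        delta = 2 * np.pi / 3
        psis = []
        for phase in (base, base + delta):
            prof = CouplingProfile(
                components=(CouplingComponent(f_low, f_high, 0.8, phase),),
                noise_sd=0.2,
            )
            img = core.compute_cvpac(generate_coupled_signal(prof, seed=11), grid)
            psis.append(img.phase[7, 4])
        measured = np.angle(np.exp(1j * (psis[1] - psis[0])))
        assert abs(np.angle(np.exp(1j * (measured - delta)))) <= np.pi / 9

    def test_rate_too_low_rejected(self, grid):
        win = window_from_samples(np.zeros(3000), 300.0)
        with pytest.raises(ValueError, match="rate"):
            core.compute_cvpac(win, grid)

    def test_strength_bounded(self, coupled_image):
        img, _, _ = coupled_image
        assert np.all(img.strength <= 1.0) and np.all(img.strength >= 0.0)


class TestSurrogateTest:
    def test_strong_coupling_retained(self, coupled_window, grid):
        win, (r, c), _ = coupled_window
        st = core.surrogate_test(win, grid, seed=0)
        assert st.pixels[r, c] != 0

    def test_null_retention_near_alpha(self, grid):
        """Loose sanity check on 15 noise windows; the full 200-window
        binomial calibration lives in the acceptance suite."""
        rng = np.random.default_rng(5)
        kept = 0
        for _ in range(15):
            w = window_from_samples(rng.standard_normal(10000), 1000.0)
            kept += (core.surrogate_test(w, grid, seed=rng).pixels != 0).sum()
        assert kept / 1500 < 0.15

    def test_alpha_extremes(self, coupled_window, grid):
        win, _, _ = coupled_window
        st = core.surrogate_test(win, grid, n_shuffles=20, alpha=1.0, seed=0)
        # threshold at the null minimum: retention ~ 1 - 1/(n_shuffles + 1)
        assert (st.pixels != 0).mean() >= 0.9
        with pytest.raises(ValueError, match="alpha"):
            core.surrogate_test(win, grid, alpha=0.0, seed=0)

    def test_few_shuffles_rejected(self, coupled_window, grid):
        win, _, _ = coupled_window
        with pytest.raises(ValueError, match="n_shuffles"):
            core.surrogate_test(win, grid, n_shuffles=5, seed=0)

    def test_deterministic_given_seed(self, coupled_window, grid):
        win, _, _ = coupled_window
        a = core.surrogate_test(win, grid, n_shuffles=20, seed=3)
        b = core.surrogate_test(win, grid, n_shuffles=20, seed=3)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestBandMasks:
    def test_low_bands_partition_columns(self, grid):
        total = np.zeros(10, int)
        for name in ("slow_delta", "fast_delta", "theta", "alpha"):
            total += core.band_mask(grid, name).selected.all(axis=0)
        assert np.all(total == 1)

    def test_high_bands_partition_rows(self, grid):
        g = core.band_mask(grid, "gamma").selected.all(axis=1)
        h = core.band_mask(grid, "hfo").selected.all(axis=1)
        assert np.all(g.astype(int) + h.astype(int) == 1)

    def test_slow_delta_columns_are_centers_in_1_2(self, grid):
        cols = core.band_mask(grid, "slow_delta").columns
        np.testing.assert_array_equal(
            cols, np.flatnonzero((grid.low_centers >= 1) & (grid.low_centers < 2))
        )
        assert cols.tolist() == [0, 1, 2]

    def test_unknown_band(self, grid):
        with pytest.raises(ValueError, match="unknown band"):
            core.band_mask(grid, "beta")


class TestAblation:
    def test_empty_mask_is_identity(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        mask = core.BandMask("none", np.zeros(grid.shape, bool))
        out = core.ablate_band(img, mask, seed=0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_moment_matching_under_full_mask(self, rng, grid):
        imgs = random_images(rng, 1000, grid)
        mask = core.BandMask("all", np.ones(grid.shape, bool))
        stats = core.ablation_statistics(imgs, mask)
        out = [core.ablate_band(im, mask, seed=rng, stats=stats) for im in imgs]
        vals_in = np.concatenate([im.pixels.ravel() for im in imgs])
        vals_out = np.concatenate([im.pixels.ravel() for im in out])
        # Monte-Carlo tolerance at n = 100,000 pixels
        assert vals_out.real.mean() == pytest.approx(vals_in.real.mean(), abs=0.01)
        assert vals_out.imag.std() == pytest.approx(vals_in.imag.std(), rel=0.05)

    def test_unmasked_pixels_untouched(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        mask = core.band_mask(grid, "alpha")
        out = core.ablate_band(img, mask, seed=1)
        np.testing.assert_array_equal(
            out.pixels[~mask.selected], img.pixels[~mask.selected]
        )
        assert np.all(out.pixels[mask.selected] != img.pixels[mask.selected])

    def test_seeded_reproducibility(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        mask = core.band_mask(grid, "theta")
        a = core.ablate_band(img, mask, seed=9)
        b = core.ablate_band(img, mask, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestRestrictRows:
    def test_gamma_restriction_rows(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        out = core.restrict_rows(img, core.band_mask(grid, "gamma"))
        expect = np.flatnonzero((grid.high_centers >= 30) & (grid.high_centers < 80))
        assert out.pixels.shape[0] == expect.size
        assert np.all(out.grid.high_centers < 80)

    def test_restack_round_trip(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        g = core.restrict_rows(img, core.band_mask(grid, "gamma"))
        h = core.restrict_rows(img, core.band_mask(grid, "hfo"))
        np.testing.assert_array_equal(np.vstack([g.pixels, h.pixels]), img.pixels)

    def test_hfo_bit_exact(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        h = core.restrict_rows(img, core.band_mask(grid, "hfo"))
        rows = core.band_mask(grid, "hfo").rows
        assert np.array_equal(h.pixels, img.pixels[rows])

    def test_column_band_rejected(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        with pytest.raises(ValueError, match="rows"):
            core.restrict_rows(img, core.band_mask(grid, "alpha"))


class TestSerialization:
    def test_npz_round_trip(self, rng, grid, tmp_path):
        imgs = random_images(rng, 5, grid)
        for i, im in enumerate(imgs):
            im.label = "pathological" if i % 2 else "normal"
            im.provenance = {"channel": f"C{i}", "patient": "P1"}
        path = tmp_path / "images.npz"
        core.save_images(path, imgs)
        back = core.load_images(path)
        assert len(back) == 5
        for a, b in zip(imgs, back):
            np.testing.assert_array_equal(a.pixels, b.pixels)
            assert a.label == b.label and a.provenance == b.provenance

    def test_csv_export(self, rng, grid):
        img = random_images(rng, 1, grid)[0]
        df = img.to_frame()
        assert len(df) == 100
        np.testing.assert_allclose(df["strength"], img.strength.ravel())


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_modulation_index_bounds_property(seed):
    """S in [0,1] for arbitrary simplex points; 0 iff uniform."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(18))
    s = core.modulation_index(dist(p))
    assert 0.0 <= s <= 1.0
    if np.allclose(p, 1 / 18):
        assert s == 0.0
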