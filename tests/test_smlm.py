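import numpy as np
import pandas as pd
import pytest

from disc3d import smlm
from disc3d.core import GAUSSIAN_FWHM_FACTOR, PixelImage
from disc3d.phantoms import FiberNetworkPhantom, FiberSegment, SMLMMovieSpec, generate_smlm_movie

from conftest import brute_force_dbscan_noise


def make_table(**cols) -> smlm.LocalizationTable:
    n = max(len(v) for v in cols.values())
    base = {
        "frame": np.zeros(n, dtype=int),
        "x_nm": np.zeros(n),
        "y_nm": np.zeros(n),
        "sigma_nm": np.full(n, 150.0),
        "photons": np.full(n, 1000.0),
        "uncertainty_nm": np.full(n, 5.0),
    }
    base.update({k: np.asarray(v) for k, v in cols.items()})
    return smlm.LocalizationTable(pd.DataFrame(base))


def test_adu_to_photons_on_images(camera):
    img = PixelImage(np.array([[197.0, 97.0], [50.0, 297.0]]), pixel_size_um=0.097)
    out = smlm.adu_to_photons(img, camera)
    np.testing.assert_allclose(out.data, [[46.0, 0.0], [0.0, 92.0]])


class TestDetectAndFit:
    def test_single_emitter_subpixel_recovery_noiseless(self, camera):
        spec = SMLMMovieSpec(
            emitters_nm=[[1551.0, 1203.0]], n_frames=3, on_rate=1.0,
            mean_on_frames=np.inf, background_photons=0.0, seed=1,
        )
        movie, _ = generate_smlm_movie(spec, noise=False)
        table = smlm.detect_and_fit(movie, camera)
        assert len(table) == 3
        assert np.allclose(table.df["x_nm"], 1551.0, atol=0.5)
        assert np.allclose(table.df["y_nm"], 1203.0, atol=0.5)
        assert np.allclose(table.df["photons"], 1000.0, rtol=0.01)

    def test_dark_movie_yields_empty_table(self, camera):
        dark = np.full((4, 24, 24), 97.0)
        assert len(smlm.detect_and_fit(dark, camera)) == 0

    def test_two_distant_emitters_both_recovered(self, camera):
        pos = np.array([[800.0, 800.0], [2800.0, 2300.0]])  # 2 um+ apart
        spec = SMLMMovieSpec(
            emitters_nm=pos, frame_shape=(40, 40), n_frames=20, on_rate=1.0,
            mean_on_frames=np.inf, background_photons=2.0, seed=3,
        )
        movie, _ = generate_smlm_movie(spec, noise=True)
        table = smlm.detect_and_fit(movie, camera)
        sigma_loc = smlm.thompson_precision(150.0, 1000.0, 97.0, 2.0)
        for p in pos:
            d = np.hypot(table.df["x_nm"] - p[0], table.df["y_nm"] - p[1])
            matched = (d < 3 * sigma_loc * np.sqrt(2)).sum()
            assert matched >= 18  # nearly every frame localizes each emitter


class TestFilters:
    @pytest.mark.parametrize(
        "photons,sigma,kept",
        [
            (90.0, 120.0, False),   # fails the > 100 photon rule
            (100.0, 120.0, False),  # boundary is strict
            (500.0, 260.0, False),  # sigma above 250 nm
            (500.0, 50.0, False),   # sigma boundary is strict
            (101.0, 51.0, True),
            (500.0, 249.0, True),
        ],
    )
    def test_photon_sigma_predicate(self, photons, sigma, kept):
        table = make_table(photons=[photons], sigma_nm=[sigma])
        assert (len(smlm.filter_localizations(table)) == 1) is kept

    def test_filter_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        photons = rng.uniform(0, 300, 200)
        sigma = rng.uniform(20, 300, 200)
        table = make_table(photons=photons, sigma_nm=sigma)
        expected = int(np.sum((photons > 100) & (sigma > 50) & (sigma < 250)))
        assert len(smlm.filter_localizations(table)) == expected

    def test_filter_idempotent(self):
        rng = np.random.default_rng(1)
        table = make_table(photons=rng.uniform(0, 300, 100), sigma_nm=rng.uniform(20, 300, 100))
        once = smlm.filter_localizations(table)
        twice = smlm.filter_localizations(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestDBSCAN:
    def test_isolated_point_removed_cluster_kept(self):
        rng = np.random.default_rng(2)
        cluster = rng.uniform(-15, 15, (20, 2))
        pts = np.vstack([cluster, [[1000.0, 1000.0]]])
        table = make_table(x_nm=pts[:, 0], y_nm=pts[:, 1])
        out = smlm.dbscan_filter(table)
        assert len(out) == 20
        assert out.df["x_nm"].max() < 500

    def test_all_sparse_points_removed(self):
        pts = np.arange(10) * 100.0  # mutually > 50 nm apart
        table = make_table(x_nm=pts, y_nm=pts)
        assert len(smlm.dbscan_filter(table)) == 0

    def test_membership_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        xy = np.vstack([
            rng.normal(0, 40, (200, 2)),
            rng.normal(400, 40, (200, 2)),
            rng.uniform(-2000, 2000, (100, 2)),
        ])
        table = make_table(x_nm=xy[:, 0], y_nm=xy[:, 1])
        out = smlm.dbscan_filter(table, epsilon_nm=50.0, min_pts=5)
        member = brute_force_dbscan_noise(xy, 50.0, 5)
        kept = set(map(tuple, out.xy.round(6)))
        expected = set(map(tuple, xy[member].round(6)))
        assert kept == expected

    def test_dbscan_idempotent(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 500, (120, 2))
        table = make_table(x_nm=xy[:, 0], y_nm=xy[:, 1])
        once = smlm.dbscan_filter(table)
        twice = smlm.dbscan_filter(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


def _cross_pattern_table(n=4000, n_frames=5000, drift=(0.0, 0.0), seed=5):
    """Localizations on a fiber cross with optional linear drift (nm over movie)."""
    rng = np.random.default_rng(seed)
    vert = rng.random(n) < 0.5
    x = np.where(vert, 1500 + rng.normal(0, 15, n), rng.uniform(0, 3000, n))
    y = np.where(vert, rng.uniform(0, 3000, n), 800 + rng.normal(0, 15, n))
    frames = rng.integers(0, n_frames, n)
    frac = frames / (n_frames - 1)
    return make_table(
        frame=frames, x_nm=x + drift[0] * frac, y_nm=y + drift[1] * frac
    ), frames


class TestDriftCorrection:
    def test_zero_drift_estimate_small(self):
        table, _ = _cross_pattern_table(drift=(0.0, 0.0))
        _, trace = smlm.drift_correct(table, n_bins=5)
        assert np.abs(trace.bin_dx_nm).max() < 15  # below render bin/2
        assert np.abs(trace.bin_dy_nm).max() < 15

    def test_linear_drift_recovered(self):
        table, frames = _cross_pattern_table(drift=(100.0, -60.0))
        corrected, trace = smlm.drift_correct(table, n_bins=5)
        # bin centres at 10%..90% of the movie; relative drift spans 80%
        assert trace.bin_dx_nm[-1] == pytest.approx(80.0, abs=10.0)
        assert trace.bin_dy_nm[-1] == pytest.approx(-48.0, abs=10.0)
        assert len(corrected) == len(table)  # conservation

    def test_correction_is_a_fixed_point(self):
        table, _ = _cross_pattern_table(drift=(100.0, -60.0))
        corrected, _ = smlm.drift_correct(table, n_bins=5)
        _, residual = smlm.drift_correct(corrected, n_bins=5)
        assert np.abs(residual.bin_dx_nm).max() < 10
        assert np.abs(residual.bin_dy_nm).max() < 10

    def test_first_bin_is_reference(self):
        table, _ = _cross_pattern_table()
        _, trace = smlm.drift_correct(table, n_bins=5)
        assert trace.bin_dx_nm[0] == 0.0 and trace.bin_dy_nm[0] == 0.0


class TestRendering:
    def test_single_record_has_unit_mass(self):
        img = smlm.render(make_table(x_nm=[500.0], y_nm=[500.0]))
        assert img.data.sum() == pytest.approx(1.0, rel=1e-3)

    def test_coincident_records_double_the_peak(self):
        one = smlm.render(make_table(x_nm=[500.0], y_nm=[500.0]), extent_nm=(400, 600, 400, 600))
        two = smlm.render(
            make_table(x_nm=[500.0, 500.0], y_nm=[500.0, 500.0]), extent_nm=(400, 600, 400, 600)
        )
        assert two.data.max() == pytest.approx(2 * one.data.max(), rel=1e-9)

    def test_total_mass_equals_record_count(self):
        rng = np.random.default_rng(6)
        n = 250
        img = smlm.render(make_table(x_nm=rng.uniform(200, 800, n), y_nm=rng.uniform(200, 800, n)))
        assert img.data.sum() == pytest.approx(n, rel=1e-3)


class TestResolutionMetrics:
    def test_precision_closed_form_no_background(self):
        # sigma 150 nm, N = 1000, a = 97 nm, b = 0
        val = smlm.thompson_precision(150.0, 1000.0, 97.0, 0.0)
        assert val == pytest.approx(np.sqrt((150.0**2 + 97.0**2 / 12) / 1000.0), rel=1e-12)
        assert val == pytest.approx(4.83, abs=0.01)

    def test_precision_shot_noise_limit(self):
        # a -> 0 with b = 0 collapses to sigma / sqrt(N)
        val = smlm.thompson_precision(150.0, 1000.0, 1e-6, 0.0)
        assert val == pytest.approx(150.0 / np.sqrt(1000.0), rel=1e-6)

    def test_estimate_precision_median_aggregation(self, camera):
        table = make_table(photons=[400.0, 1000.0, 2500.0])
        per = smlm.thompson_precision(150.0, np.array([400.0, 1000.0, 2500.0]), 97.0, 2.0)
        assert smlm.estimate_precision(table, camera, 2.0) == pytest.approx(np.median(per))

    def test_nyquist_density_formula(self):
        # 400 localizations/um^2 -> 2 / 20 um = 100 nm
        table = make_table(x_nm=np.zeros(400), y_nm=np.zeros(400))
        assert smlm.estimate_nyquist(table, roi_area_um2=1.0) == pytest.approx(100.0)
        # 4x fewer localizations, same area -> 2x coarser
        quarter = make_table(x_nm=np.zeros(100), y_nm=np.zeros(100))
        assert smlm.estimate_nyquist(quarter, 1.0) == pytest.approx(200.0)

    def test_combined_resolution_pythagorean(self):
        est = smlm.combined_resolution(3.0, 4.0)
        assert est.combined_resolution_nm == pytest.approx(5.0, rel=1e-12)
        assert smlm.combined_resolution(10.0, 10.0).combined_resolution_nm == pytest.approx(
            np.sqrt(200.0)
        )
        assert smlm.combined_resolution(7.0, 1e-9).combined_resolution_nm == pytest.approx(7.0)
        with pytest.raises(ValueError):
            smlm.combined_resolution(0.0, 4.0)

    def test_resolution_estimate_enforces_quadrature(self):
        with pytest.raises(ValueError):
            smlm.ResolutionEstimate(3.0, 4.0, combined_resolution_nm=6.0)


def test_end_to_end_fiber_width_matches_quadrature_model(camera):
    """Rendered fiber FWHM = sqrt(FWHM_true^2 + (2.355 sigma_eff)^2) within 10%."""
    from disc3d import fibers as fib

    phantom = FiberNetworkPhantom(
        fibers=[FiberSegment((1.5, 0.0), (1.5, 3.0), sigma_nm=31.85)],
        field_size_um=(3.0, 3.0),
        pixel_size_um=0.01,
        seed=0,
    )
    # sparse activity (~0.4 active emitters/frame) so two molecules rarely
    # blink inside one fit window: overlapping fits average their offsets
    # and would bias the apparent cross-section low
    spec = SMLMMovieSpec.on_fibers(
        phantom, density_per_um=30.0, jitter_nm=31.85, seed=7,
        n_frames=1500, mean_photons=2000.0, on_rate=0.003, mean_on_frames=1.5,
        background_photons=1.0, frame_shape=(31, 31),
    )
    movie, _ = generate_smlm_movie(spec, noise=True)
    result = smlm.reconstruct(movie, camera, roi_area_um2=9.0, drift_correction=False)
    image = result["image"]
    assert image is not None and len(result["localizations"]) > 300

    precision = result["resolution"].localization_precision_nm
    sigma_eff = np.hypot(precision, 10.0)  # rendering kernel adds 10 nm
    # oracle uses the realized emitter spread of this finite sample, whose
    # std fluctuates around the nominal 31.85 nm
    sigma_true = spec.emitters_nm[:, 0].std()
    expected_nm = np.hypot(GAUSSIAN_FWHM_FACTOR * sigma_true, GAUSSIAN_FWHM_FACTOR * sigma_eff)

    # average the rendering along the (vertical) fiber axis, then fit the
    # mean cross-section: individual rows are too sparsely sampled
    x0_nm, _ = image.meta["origin_nm"]
    ny = image.data.shape[0]
    mean_profile = image.data[ny // 5 : 4 * ny // 5].mean(axis=0)
    positions_nm = x0_nm + (np.arange(image.data.shape[1]) + 0.5) * 10.0
    keep = np.abs(positions_nm - 1500.0) < 300.0
    fit = fib.fit_gaussian_profile(positions_nm[keep], mean_profile[keep], r2_threshold=0.8)
    assert fit.accepted
    assert fit.fwhm_um == pytest.approx(expected_nm, rel=0.10)  # both in nm here


def test_resolution_vs_frames_full_movie_matches_single_pass(camera):
    spec = SMLMMovieSpec(
        emitters_nm=np.column_stack(
            [np.linspace(300, 2000, 12), np.linspace(400, 1900, 12)]
        ),
        frame_shape=(24, 24), n_frames=300, on_rate=0.05, mean_on_frames=2.0,
        background_photons=1.0, seed=9,
    )
    movie, _ = generate_smlm_movie(spec, noise=True)
    curve = smlm.resolution_vs_frames(
        movie, camera, [150, 300], roi_area_um2=5.4, drift_correction=False
    )
    single = smlm.reconstruct(movie, camera, roi_area_um2=5.4, drift_correction=False)
    assert curve.iloc[-1]["n_localizations"] == len(single["localizations"])
    assert curve.iloc[-1]["resolution_nm"] == pytest.approx(
        single["resolution"].combined_resolution_nm
    )
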