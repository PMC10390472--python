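import numpy as np
import pytest

from disc3d import pores
from disc3d.core import PixelImage
from disc3d.phantoms import FiberNetworkPhantom, generate_fiber_image


def brute_force_line_gaps(mask: np.ndarray, pixel_size: float) -> list[float]:
    """Independent per-line run scanner: interior off-runs between on pixels."""
    out = []
    lines = [mask[i, :] for i in range(mask.shape[0])] + [mask[:, j] for j in range(mask.shape[1])]
    for line in lines:
        run, seen_on = 0, False
        for v in line:
            if v:
                if seen_on and run > 0:
                    out.append(run * pixel_size)
                seen_on, run = True, 0
            else:
                run += 1
    return out


class TestCountGaps:
    def test_periodic_stripes(self):
        # vertical on-stripes of period 10 px, width 2 px, pixel 0.1 um
        mask = np.zeros((20, 100), dtype=bool)
        for start in range(0, 100, 10):
            mask[:, start : start + 2] = True
        gaps = pores.count_gaps(pores.BinarizedNetwork(mask, 0.1))
        assert np.allclose(gaps, 0.8)
        assert len(gaps) == 20 * 9  # 9 interior gaps per row, none per column

    def test_checkerboard_gaps_are_one_pixel(self):
        mask = np.indices((16, 16)).sum(axis=0) % 2 == 0
        gaps = pores.count_gaps(pores.BinarizedNetwork(mask, 0.25))
        assert np.allclose(gaps, 0.25)

    def test_matches_brute_force_scanner_on_random_masks(self):
        rng = np.random.default_rng(7)
        for density in (0.1, 0.4, 0.8):
            mask = rng.random((40, 60)) < density
            net = pores.BinarizedNetwork(mask, 0.2)
            got = np.sort(pores.count_gaps(net))
            expected = np.sort(brute_force_line_gaps(mask, 0.2))
            np.testing.assert_allclose(got, expected)

    def test_border_truncated_runs_excluded_by_default(self):
        mask = np.zeros((1, 10), dtype=bool)
        mask[0, [3, 7]] = True
        net = pores.BinarizedNetwork(np.vstack([mask, np.ones((1, 10), bool)]), 1.0)
        interior = pores.count_gaps(net)
        with_border = pores.count_gaps(net, include_border=True)
        assert 3.0 in interior and len(with_border) > len(interior)


class TestFitExponential:
    def test_constant_gaps_give_rate_one_over_c(self):
        res = pores.fit_exponential(np.full(200, 2.5))
        assert res.rate_per_um == pytest.approx(0.4)
        assert res.pore_size_um == pytest.approx(2.5)

    def test_seeded_draws_recover_4um_pore_size(self):
        rng = np.random.default_rng(0)
        gaps = rng.exponential(scale=4.0, size=10_000)  # rate 0.25 per um
        res = pores.fit_exponential(gaps)
        assert res.pore_size_um == pytest.approx(4.0, rel=0.02)
        assert res.ks_pvalue > 0.01

    def test_mle_matches_grid_search_of_likelihood(self):
        rng = np.random.default_rng(1)
        gaps = rng.exponential(2.0, 500)
        res = pores.fit_exponential(gaps)
        lams = np.linspace(0.01, 5.0, 20000)
        nll = lams * gaps.sum() - len(gaps) * np.log(lams)
        assert res.rate_per_um == pytest.approx(lams[np.argmin(nll)], abs=3e-4)

    def test_histogram_fit_agrees_with_mle(self):
        rng = np.random.default_rng(2)
        gaps = rng.exponential(3.0, 20_000)
        mle = pores.fit_exponential(gaps, method="mle")
        hist = pores.fit_exponential(gaps, method="histogram")
        assert hist.pore_size_um == pytest.approx(mle.pore_size_um, rel=0.1)

    def test_pore_size_is_exact_reciprocal_of_rate(self):
        res = pores.fit_exponential(np.random.default_rng(3).exponential(1.7, 500))
        assert res.pore_size_um * res.rate_per_um == pytest.approx(1.0, rel=1e-15)

    def test_too_few_gaps_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            pores.fit_exponential(np.ones(50))


class TestPreprocessBinarize:
    def test_constant_image_flattens_to_zero(self):
        img = PixelImage(np.full((120, 120), 40.0), pixel_size_um=0.1)
        out = pores.preprocess(img)
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_smooth_gradient_background_removed(self):
        sparse = FiberNetworkPhantom.grid(
            field_size_um=(120.0, 120.0), pixel_size_um=0.1,
            gap_rate_per_um=0.15, sigma_nm=130.0, seed=4,
        )
        img = generate_fiber_image(sparse, "confocal", noise=False, background=0.0)
        gradient = np.linspace(0, 60, img.data.shape[1])[None, :] * np.ones((img.data.shape[0], 1))
        out = pores.preprocess(img.with_data(img.data + gradient))
        mask = sparse.ideal_mask()
        assert out.data[~mask].mean() < 0.05 * out.data[mask].max()
        # the left-right ramp (0 -> 60) is levelled after preprocessing
        w = out.data.shape[1]
        left = out.data[:, : w // 3][~mask[:, : w // 3]].mean()
        right = out.data[:, 2 * w // 3 :][~mask[:, 2 * w // 3 :]].mean()
        assert abs(right - left) < 0.05 * out.data[mask].max()

    def test_binarize_recovers_fiber_mask(self, gap_phantom):
        img = generate_fiber_image(gap_phantom, "confocal", noise=True)
        net = pores.binarize(pores.preprocess(img))
        truth = gap_phantom.ideal_mask()
        inter = (net.mask & truth).sum()
        union = (net.mask | truth).sum()
        assert inter / union > 0.5  # the blurred mask is wider than the ideal one

    def test_inverted_contrast_with_polarity_flag(self, gap_phantom):
        img = generate_fiber_image(gap_phantom, "confocal", noise=True)
        bright = pores.binarize(img, polarity="bright")
        dark = pores.binarize(img.with_data(img.data.max() - img.data), polarity="dark")
        assert (bright.mask == dark.mask).all()

    def test_blank_noise_image_raises(self):
        rng = np.random.default_rng(4)
        img = PixelImage(rng.poisson(5.0, (60, 60)).astype(float), pixel_size_um=0.1)
        flat = pores.preprocess(img, 2, 20, 25)
        with pytest.raises(ValueError):
            pores.binarize(flat.with_data(np.zeros_like(flat.data)))

    def test_degenerate_bandpass_radii_rejected(self):
        img = PixelImage(np.zeros((50, 50)), pixel_size_um=0.1)
        with pytest.raises(ValueError):
            pores.preprocess(img, bandpass_small_px=10, bandpass_large_px=5)


class TestPipeline:
    def test_same_image_same_config_is_deterministic(self, gap_phantom):
        img = generate_fiber_image(gap_phantom, "confocal", noise=True)
        a = pores.pore_size_pipeline(img)
        b = pores.pore_size_pipeline(img)
        assert a.pore_size_um == b.pore_size_um and a.n_gaps == b.n_gaps

    def test_recovers_phantom_gap_rate(self, gap_phantom):
        img = generate_fiber_image(gap_phantom, "confocal", noise=True)
        res = pores.pore_size_pipeline(img)
        assert res.pore_size_um == pytest.approx(gap_phantom.true_gaps_um.mean(), rel=0.08)

    def test_scale_equivariance_in_pixel_size(self, gap_phantom):
        img = generate_fiber_image(gap_phantom, "confocal", noise=True)
        res1 = pores.pore_size_pipeline(img)
        rescaled = PixelImage(img.data, pixel_size_um=img.pixel_size_um * 2)
        res2 = pores.pore_size_pipeline(rescaled)
        assert res2.pore_size_um == pytest.approx(2 * res1.pore_size_um, rel=1e-12)

    def test_doubling_gap_rate_halves_pore_size(self):
        results, truths = {}, {}
        for rate in (0.25, 0.5):
            ph = FiberNetworkPhantom.grid(
                field_size_um=(150.0, 150.0), pixel_size_um=0.1,
                gap_rate_per_um=rate, sigma_nm=130.0, seed=13,
            )
            img = generate_fiber_image(ph, "confocal", noise=True)
            results[rate] = pores.pore_size_pipeline(img).pore_size_um
            truths[rate] = ph.true_gaps_um.mean()
        # estimates scale like the realized gap samples of the two phantoms
        assert results[0.25] / results[0.5] == pytest.approx(
            truths[0.25] / truths[0.5], rel=0.10
        )

    def test_adding_fibers_never_increases_pore_size(self):
        sparse = FiberNetworkPhantom.grid(
            field_size_um=(120.0, 120.0), pixel_size_um=0.1, gap_rate_per_um=0.25, seed=5
        )
        # nested phantom: same fibers plus an extra denser overlay
        extra = FiberNetworkPhantom.grid(
            field_size_um=(120.0, 120.0), pixel_size_um=0.1, gap_rate_per_um=0.4, seed=6
        )
        dense = FiberNetworkPhantom(
            fibers=sparse.fibers + extra.fibers,
            field_size_um=(120.0, 120.0), pixel_size_um=0.1, seed=5,
        )
        img_sparse = generate_fiber_image(sparse, "confocal", noise=True)
        img_dense = generate_fiber_image(dense, "confocal", noise=True)
        assert (
            pores.pore_size_pipeline(img_dense).pore_size_um
            <= pores.pore_size_pipeline(img_sparse).pore_size_um
        )
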