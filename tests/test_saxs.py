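"""Lamellar SAXS: peaks, indexing, reconstruction, round trips."""

import warnings

import numpy as np
import pytest

from chainstick.saxs import (EDProfile, LamellarIndexing, Peak, SAXSProfile,
                             azimuthal_average, find_peaks,
                             hexagonal_interaxial, index_lamellar,
                             reconstruct_edp, slab_widths,
                             synthesize_lamellar_profile,
                             two_slab_form_factor)


def phase_variants(phases, orders=None):
    """A centrosymmetric structure is defined up to global sign and a
    half-period origin shift (factor (-1)^h per order h); ``orders`` selects
    the harmonics actually present (extinct reflections drop out)."""
    p = np.asarray(phases)
    if orders is None:
        orders = tuple(range(1, len(p) + 1))
    p = np.array([p[h - 1] for h in orders])
    h = np.asarray(orders)
    shift = p * (-1) ** h
    return {tuple(p), tuple(-p), tuple(shift), tuple(-shift)}


class TestFindPeaks:
    def test_single_gaussian(self):
        q = np.linspace(0.05, 0.5, 300)
        I = 5 * np.exp(-0.5 * ((q - 0.185) / 0.006) ** 2) + 0.1
        peaks = find_peaks(SAXSProfile(q, I))
        assert len(peaks) == 1
        assert peaks[0].q == pytest.approx(0.185, abs=np.diff(q)[0] / 2)

    def test_flat_noise_yields_nothing(self, rng):
        q = np.linspace(0.05, 1.0, 400)
        I = 1 + 0.01 * rng.standard_normal(400)
        assert find_peaks(SAXSProfile(q, np.clip(I, 0, None))) == []

    def test_four_order_ladder_located(self, rng):
        prof = synthesize_lamellar_profile(noise=0.02, rng=rng)
        peaks = find_peaks(prof)
        assert len(peaks) == 4
        q_star = 2 * np.pi / 34.0
        for h, p in enumerate(peaks, start=1):
            assert p.q == pytest.approx(h * q_star, rel=0.01)


class TestIndexing:
    def test_fundamental_at_01848(self):
        idx = index_lamellar([Peak(0.1848, 1.0, 0.01, 1.0)])
        assert idx.d == pytest.approx(34.0, abs=0.01)
        assert idx.d * idx.q_star == pytest.approx(2 * np.pi, abs=1e-12)

    def test_low_concentration_ladder(self):
        peaks = [Peak(q, 1.0, 0.01, 1.0)
                 for q in (0.1881, 0.3762, 0.5643, 0.7524)]
        idx = index_lamellar(peaks)
        assert idx.orders == [1, 2, 3, 4]
        assert idx.d == pytest.approx(33.4, abs=0.05)

    def test_unit_spacing(self):
        idx = index_lamellar([Peak(2 * np.pi, 1.0, 0.01, 1.0)])
        assert idx.d == pytest.approx(1.0, abs=1e-9)

    def test_inconsistent_ladder_raises(self):
        peaks = [Peak(q, 1.0, 0.01, 1.0) for q in (0.2, 0.33, 0.61)]
        with pytest.raises(ValueError):
            index_lamellar(peaks)


class TestHexagonal:
    @pytest.mark.parametrize("q, d", [
        (4 * np.pi / np.sqrt(3), 1.0),
        (1.9937, 3.64),   # dilute duplex-diameter peak
        (2.3, 3.15),      # high-concentration duplex-diameter peak
    ])
    def test_interaxial_values(self, q, d):
        assert hexagonal_interaxial(q) == pytest.approx(d, abs=0.005)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            hexagonal_interaxial(0.0)


class TestReconstruction:
    def test_single_order_is_cosine(self):
        idx = LamellarIndexing(2 * np.pi / 34, [1], 34.0, {1: 2.5}, 0.0)
        e = reconstruct_edp(idx, [1])
        imax = np.argmax(e.rho)
        assert abs(e.z[imax]) < 34 / 500
        assert slab_widths(e) == (pytest.approx(17.0, abs=0.1),
                                  pytest.approx(17.0, abs=0.1))

    def test_amplitude_linearity(self):
        """Amplitudes scale as sqrt(h^2 I_h): scaling all intensities by k
        scales the (unnormalized) harmonic content by sqrt(k)."""
        i1 = LamellarIndexing(2 * np.pi / 34, [1, 2], 34.0,
                              {1: 1.0, 2: 0.5}, 0.0)
        i2 = LamellarIndexing(2 * np.pi / 34, [1, 2], 34.0,
                              {1: 4.0, 2: 2.0}, 0.0)
        e1 = reconstruct_edp(i1, [1, -1])
        e2 = reconstruct_edp(i2, [1, -1])
        # normalized profiles are identical; the scale factor shows up in
        # the pre-normalization amplitude sqrt(h^2 I_h)
        np.testing.assert_allclose(e1.rho, e2.rho, atol=1e-12)
        a1 = np.sqrt(1 * i1.intensities[1])
        a2 = np.sqrt(1 * i2.intensities[1])
        assert a2 == pytest.approx(2 * a1)

    def test_two_slab_round_trip_noise_free(self):
        """The headline reconstruction: a 31 nm dsDNA slab and 3 nm gap in
        a 34 nm period are recovered from the synthetic Bragg intensities
        (raw intensities for the real system are unpublished)."""
        prof = synthesize_lamellar_profile(noise=0.0)
        idx = index_lamellar(find_peaks(prof))
        best, ranked = reconstruct_edp(idx)
        wh, wl = slab_widths(best)
        grid = 34.0 / best.rho.size
        assert idx.d == pytest.approx(34.0, abs=0.05)
        assert max(wh, wl) == pytest.approx(31.0, abs=2 * grid)
        assert min(wh, wl) == pytest.approx(3.0, abs=2 * grid)

    def test_randomized_round_trips(self):
        """20 random two-slab draws: d within one q bin, widths within the
        intensity-noise limit, true phases in the top-2 ranked vectors."""
        rng = np.random.default_rng(42)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(20):
                d = rng.uniform(25, 45)
                whigh = rng.uniform(0.55, 0.95) * d
                prof = synthesize_lamellar_profile(
                    d=d, slab_widths_nm=(whigh, d - whigh), n_orders=4,
                    noise=0.01, rng=rng)
                idx = index_lamellar(find_peaks(prof))
                best, ranked = reconstruct_edp(idx)
                wh, wl = slab_widths(best)
                qbin = np.diff(prof.q).mean()
                assert abs(idx.q_star - 2 * np.pi / d) < qbin
                assert min(abs(wh - whigh), abs(wl - whigh)) < 2.5
                truth = phase_variants(prof.meta["true_phases"],
                                       ranked[0].orders)
                top2 = {tuple(int(s) for s in ranked[0].phases),
                        tuple(int(s) for s in ranked[1].phases)}
                assert truth & top2

    def test_offset_leaves_widths_unchanged(self):
        idx = LamellarIndexing(2 * np.pi / 34, [1, 2], 34.0,
                               {1: 1.0, 2: 0.7}, 0.0)
        e = reconstruct_edp(idx, [1, -1])
        w0 = slab_widths(e)
        shifted = EDProfile(e.z, e.rho + 5.0, e.phases, e.d,
                            orders=e.orders)
        assert slab_widths(shifted) == w0


class TestSynthesis:
    def test_peak_intensities_match_form_factor(self):
        """Noise-free synthesis: integrated peak areas equal the two-slab
        Fourier intensities |F_h|^2 / h^2."""
        prof = synthesize_lamellar_profile(noise=0.0)
        peaks = find_peaks(prof)
        h = np.arange(1, 5)
        F = two_slab_form_factor(34.0, 31.0, 1.0, h)
        expect = F**2 / h.astype(float) ** 2
        got = np.array([p.intensity for p in peaks])
        ratio = got / expect
        np.testing.assert_allclose(ratio / ratio[0], 1.0, atol=0.05)

    def test_peak_positions(self):
        prof = synthesize_lamellar_profile(noise=0.0)
        peaks = find_peaks(prof)
        for h, p in enumerate(peaks, start=1):
            assert p.q == pytest.approx(0.1848 * h, rel=0.002)

    def test_zero_contrast_is_featureless(self):
        prof = synthesize_lamellar_profile(densities=(1.0, 1.0), noise=0.0)
        assert find_peaks(prof) == []


class TestAzimuthalAverage:
    def test_isotropic_ring(self):
        yy, xx = np.indices((201, 201))
        r = np.hypot(yy - 100, xx - 100)
        img = np.exp(-0.5 * ((r - 40) / 2.0) ** 2)
        prof = azimuthal_average(img, (100, 100), q_per_pixel=0.01)
        peaks = find_peaks(prof, min_prominence=0.2)
        assert len(peaks) == 1
        assert peaks[0].q == pytest.approx(0.40, abs=0.01)

    def test_uniform_image_is_flat(self):
        img = np.full((101, 101), 3.0)
        prof = azimuthal_average(img, (50, 50), q_per_pixel=0.02)
        inner = prof.I[prof.q < 0.9]  # corners are partially sampled
        np.testing.assert_allclose(inner, 3.0, rtol=1e-9)

    def test_two_rings_preserve_intensity_ratio(self):
        yy, xx = np.indices((301, 301))
        r = np.hypot(yy - 150, xx - 150)
        img = (4.0 * np.exp(-0.5 * ((r - 40) / 2) ** 2)
               + 2.0 * np.exp(-0.5 * ((r - 90) / 2) ** 2))
        prof = azimuthal_average(img, (150, 150), q_per_pixel=0.01)
        p = sorted(find_peaks(prof, min_prominence=0.5), key=lambda x: x.q)
        assert len(p) == 2
        assert p[0].height / p[1].height == pytest.approx(2.0, rel=0.1)

    def test_center_outside_image_raises(self):
        with pytest.raises(ValueError):
            azimuthal_average(np.zeros((10, 10)), (20, 5), 0.01)
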