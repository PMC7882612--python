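"""Opponency mapping, detectability, and discriminability statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from flymosaic.errors import AdaptationError, GridMismatchError, InputError
from flymosaic.spectra import (
    DEFAULT_GRID,
    Spectrum,
    WavelengthGrid,
    equal_energy_illuminant,
    nomogram_receptor_set,
)
from flymosaic.vision import (
    QuantumCatches,
    SpeciesCloud,
    VisionPoint,
    centroid_distance,
    classify_quadrant,
    detectability_verdict,
    mean_catches,
    quantum_catch,
    region_mean_point,
    troje_point,
    welch_t,
)


def gaussian_reflectance(grid, peak_nm, sd_nm, amp=0.8):
    wl = grid.wavelengths
    return Spectrum(grid, amp * np.exp(-0.5 * ((wl - peak_nm) / sd_nm) ** 2))


class TestQuantumCatch:
    def test_zero_stimulus_gives_zero_catches(self, grid, illuminant, receptors):
        r = Spectrum(grid, np.zeros(len(grid)))
        q = quantum_catch(r, illuminant, receptors)
        assert np.all(q.as_array() == 0)

    def test_constant_integrand_equals_span(self, grid):
        # R = I = S = 1 over 300-700 nm: trapezoid of a constant is the span
        ones = np.ones(len(grid))
        r = Spectrum(grid, ones)
        i = Spectrum(grid, ones, kind="illuminant")
        flat = {
            name: Spectrum(grid, ones, kind="sensitivity", label=name)
            for name in ("R7p", "R7y", "R8p", "R8y")
        }
        from flymosaic.spectra import ReceptorSet

        q = quantum_catch(r, i, ReceptorSet(flat))
        assert np.allclose(q.as_array(), 400.0)

    def test_matches_fine_grid_oracle(self, grid, illuminant, receptors):
        # independent brute-force integration at 0.1 nm of the same integrand
        from flymosaic.spectra import WavelengthGrid, d65_illuminant, nomogram_receptor_set

        fine = WavelengthGrid(300, 700, 0.1)
        fine_ill = d65_illuminant(fine)
        fine_rec = nomogram_receptor_set(grid=fine)
        r = gaussian_reflectance(grid, 550.0, 30.0)
        r_fine = gaussian_reflectance(fine, 550.0, 30.0)
        q = quantum_catch(r, illuminant, receptors).as_array()
        q_fine = quantum_catch(r_fine, fine_ill, fine_rec).as_array()
        np.testing.assert_allclose(q, q_fine, rtol=1e-3)

    def test_mismatched_grids_raise(self, grid, illuminant, receptors):
        other = WavelengthGrid(300, 700, 2.0)
        r = Spectrum(other, np.ones(len(other)))
        with pytest.raises(GridMismatchError):
            quantum_catch(r, illuminant, receptors)

    def test_negative_catch_rejected(self):
        with pytest.raises(InputError):
            QuantumCatches(-1.0, 1.0, 1.0, 1.0)


class TestTrojePoint:
    def test_background_is_fixed_point(self):
        bg = QuantumCatches(2.0, 3.0, 4.0, 5.0)
        pt = troje_point(bg, bg)
        assert pt.x == 0.0 and pt.y == 0.0
        assert pt.dist_origin == 0.0 and pt.quadrant == "boundary"

    def test_closed_form_example(self):
        pt = troje_point(QuantumCatches(3, 1, 1, 3), QuantumCatches(1, 1, 1, 1))
        assert pt.x == pytest.approx(0.25)
        assert pt.y == pytest.approx(-0.25)
        assert pt.quadrant == "p+y-"
        assert pt.dist_origin == pytest.approx(0.25 * np.sqrt(2))

    def test_zero_background_catch_raises(self):
        with pytest.raises(AdaptationError):
            troje_point(QuantumCatches(1, 1, 1, 1), QuantumCatches(0, 1, 1, 1))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        qs=st.lists(st.floats(0.0, 100.0), min_size=4, max_size=4),
        bgs=st.lists(st.floats(0.01, 100.0), min_size=4, max_size=4),
    )
    def test_coordinates_bounded(self, qs, bgs):
        pt = troje_point(QuantumCatches(*qs), QuantumCatches(*bgs))
        assert -1 < pt.x < 1 and -1 < pt.y < 1
        assert pt.dist_origin == pytest.approx(np.hypot(pt.x, pt.y))

    def test_illuminant_scale_invariance(self, grid, receptors):
        ill = equal_energy_illuminant(grid)
        scaled = Spectrum(grid, ill.values * 7.3, kind="illuminant")
        r = gaussian_reflectance(grid, 500, 40)
        bg = gaussian_reflectance(grid, 600, 80, amp=0.3)
        pts = []
        for i in (ill, scaled):
            pts.append(
                troje_point(quantum_catch(r, i, receptors), quantum_catch(bg, i, receptors))
            )
        assert pts[0].x == pytest.approx(pts[1].x, abs=1e-12)
        assert pts[0].y == pytest.approx(pts[1].y, abs=1e-12)

    def test_mixing_toward_background_shrinks_distance(self, grid, illuminant, receptors):
        flower = gaussian_reflectance(grid, 620, 40)
        soil = gaussian_reflectance(grid, 550, 120, amp=0.3)
        bg = quantum_catch(soil, illuminant, receptors)
        dists = []
        for w in np.arange(1.0, -0.01, -0.2):
            mix = Spectrum(grid, w * flower.values + (1 - w) * soil.values)
            dists.append(troje_point(quantum_catch(mix, illuminant, receptors), bg).dist_origin)
        assert np.all(np.diff(dists) < 0)
        assert dists[-1] == pytest.approx(0.0, abs=1e-12)


class TestRegionMean:
    def test_single_region_equals_direct_point(self, grid, illuminant, receptors):
        flower = gaussian_reflectance(grid, 620, 40)
        soil = gaussian_reflectance(grid, 550, 120, amp=0.3)
        direct = troje_point(
            quantum_catch(flower, illuminant, receptors),
            quantum_catch(soil, illuminant, receptors),
        )
        via = region_mean_point([flower], soil, illuminant, receptors)
        assert via.x == pytest.approx(direct.x, abs=1e-15)
        assert via.y == pytest.approx(direct.y, abs=1e-15)
        assert via.quadrant == direct.quadrant

    def test_identical_regions_equal_one_region(self, grid, illuminant, receptors):
        flower = gaussian_reflectance(grid, 620, 40)
        soil = gaussian_reflectance(grid, 550, 120, amp=0.3)
        one = region_mean_point([flower], soil, illuminant, receptors)
        five = region_mean_point([flower] * 5, soil, illuminant, receptors)
        assert one.x == pytest.approx(five.x) and one.y == pytest.approx(five.y)

    def test_catches_average_arithmetically(self):
        a = QuantumCatches(1, 1, 1, 1)
        b = QuantumCatches(3, 3, 3, 3)
        assert np.allclose(mean_catches([a, b]).as_array(), 2.0)

    def test_empty_region_list_raises(self, grid, illuminant, receptors):
        soil = gaussian_reflectance(grid, 550, 120, amp=0.3)
        with pytest.raises(InputError):
            region_mean_point([], soil, illuminant, receptors)


class TestQuadrants:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (0.3, -0.1, "p+y-"),
            (0.3, 0.1, "p+y+"),
            (-0.3, 0.1, "p-y+"),
            (-0.3, -0.1, "p-y-"),
            (0.0, 0.2, "boundary"),
            (-1e-15, -0.5, "boundary"),
        ],
    )
    def test_sign_pattern(self, x, y, expected):
        assert classify_quadrant(x, y) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            classify_quadrant(np.nan, 0.1)


class TestCentroidsAndVerdicts:
    def _cloud(self, name, coords):
        pts = [
            VisionPoint(x=x, y=y, quadrant=classify_quadrant(x, y),
                        dist_origin=float(np.hypot(x, y)))
            for x, y in coords
        ]
        return SpeciesCloud(species=name, points=pts)

    def test_three_four_five_triangle(self):
        a = self._cloud("a", [(0, 0)])
        b = self._cloud("b", [(0.3, 0.4)])
        assert centroid_distance(a, b) == pytest.approx(0.5)

    def test_identical_clouds_zero(self, rng):
        coords = rng.normal(size=(10, 2)) * 0.2
        a = self._cloud("a", coords)
        b = self._cloud("b", coords)
        assert centroid_distance(a, b) == 0.0

    def test_matches_brute_force_recomputation(self, rng):
        ca = rng.normal(size=(7, 2)) * 0.3
        cb = rng.normal(size=(5, 2)) * 0.3
        a, b = self._cloud("a", ca), self._cloud("b", cb)
        brute = np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0))
        assert centroid_distance(a, b) == pytest.approx(brute)
        assert centroid_distance(b, a) == pytest.approx(brute)  # symmetry

    def test_triangle_inequality(self, rng):
        clouds = [self._cloud(str(i), rng.normal(size=(4, 2))) for i in range(3)]
        d01 = centroid_distance(clouds[0], clouds[1])
        d12 = centroid_distance(clouds[1], clouds[2])
        d02 = centroid_distance(clouds[0], clouds[2])
        assert d02 <= d01 + d12 + 1e-12

    def test_empty_cloud_rejected(self):
        with pytest.raises(InputError):
            SpeciesCloud(species="x", points=[])

    @pytest.mark.parametrize(
        "dist,quadrant,expected",
        [
            (0.004, "p-y-", "not_detectable"),
            (0.059, "p+y-", "detectable"),   # >= rule at the boundary
            (0.5, "p+y+", "unknown"),        # no threshold in that quadrant
        ],
    )
    def test_detectability_verdicts(self, dist, quadrant, expected):
        pt = VisionPoint(x=0.1, y=0.1, quadrant=quadrant, dist_origin=dist)
        assert detectability_verdict(pt) == expected


class TestWelch:
    def test_identical_samples_null(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0]
        res = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)
        assert res.df == pytest.approx(ref.df)

    def test_swapping_samples_negates_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 6)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_one_sided_halves_p_in_direction(self, rng):
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        two = welch_t(a, b)
        one = welch_t(a, b, one_sided=True)
        if two.t > 0:
            assert one.p == pytest.approx(two.p / 2)

    def test_too_small_sample_rejected(self):
        with pytest.raises(InputError):
            welch_t([1.0], [1.0, 2.0])
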