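import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from capmorph.core_io import (
    AnnotationError,
    CalibratedImage,
    CapillaryAnnotation,
    CaveolaMark,
    JunctionMark,
    Polygon,
)
from capmorph.morphometry import (
    chromatin_density_variation,
    count_marks,
    cytoplasm_area,
    mean_cytoplasm_thickness,
    measure_capillary,
    polygon_area,
    polygon_perimeter,
    polygon_pixel_mask,
)

from conftest import rect, regular_polygon


class TestPolygonArea:
    def test_square_closed_form(self):
        # 10x10 px at 100 nm/px -> (1000 nm)^2 = 1 um^2
        assert polygon_area(rect(0, 0, 10, 10), 100.0) == pytest.approx(1.0)

    def test_orientation_invariance(self):
        sq = rect(0, 0, 10, 10)
        rev = Polygon(sq.vertices[::-1])
        assert polygon_area(sq, 100.0) == polygon_area(rev, 100.0)

    def test_circle_polygon_matches_mask_count(self):
        # oracle: pixel count of the filled mask of the same polygon
        poly = regular_polygon(60.5, 60.5, 50.0, 64)
        area_px2 = polygon_area(poly, 1000.0)  # 1000 nm/px -> um^2 == px^2
        mask_px2 = polygon_pixel_mask(poly, (121, 121)).sum()
        assert area_px2 == pytest.approx(mask_px2, rel=0.01)


class TestPolygonPerimeter:
    def test_square(self):
        assert polygon_perimeter(rect(0, 0, 10, 10), 100.0) == pytest.approx(4.0)

    def test_repeated_vertex_ignored(self):
        v = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], float)
        assert polygon_perimeter(Polygon(v), 100.0) == pytest.approx(4.0)

    def test_circle_closed_form_limit(self):
        poly = regular_polygon(0.0, 0.0, 100.0, 256)
        # perimeter of inscribed 256-gon vs 2*pi*r, within 0.1%
        assert polygon_perimeter(poly, 1000.0) == pytest.approx(
            2 * math.pi * 100.0, rel=1e-3
        )


class TestCytoplasmArea:
    def test_arithmetic(self, square_annotation):
        # total 50, lumen 20, nucleus 10 at 100 nm/px
        assert cytoplasm_area(square_annotation, 100.0) == pytest.approx(20.0)

    def test_zero_cytoplasm_boundary(self):
        square = rect(0, 0, 10, 10)
        ann = CapillaryAnnotation(vessel_outer=square, lumen=square, capillary_id="z")
        assert cytoplasm_area(ann, 100.0) == 0.0

    def test_excess_interior_area_rejected(self):
        # overlapping nuclei are not individually checked, so their sum can
        # exceed the container: the measurement must notice
        ann = CapillaryAnnotation(
            vessel_outer=rect(0, 0, 100, 50),
            lumen=rect(5, 5, 55, 45),
            nuclei=[rect(60, 5, 85, 45)] * 4,
            capillary_id="inconsistent",
        )
        with pytest.raises(AnnotationError, match="inconsistent"):
            cytoplasm_area(ann, 100.0)


class TestThickness:
    def test_concentric_annulus_closed_form(self):
        # R=500 nm, r=300 nm at 10 nm/px: area/midline -> R - r = 200 nm
        outer = regular_polygon(100, 100, 50.0, 256)
        inner = regular_polygon(100, 100, 30.0, 256)
        ann = CapillaryAnnotation(vessel_outer=outer, lumen=inner, capillary_id="ann")
        assert mean_cytoplasm_thickness(ann, 10.0) == pytest.approx(200.0, rel=0.01)

    def test_degenerate_zero_width(self):
        ring = regular_polygon(0, 0, 40.0, 128)
        ann = CapillaryAnnotation(vessel_outer=ring, lumen=ring, capillary_id="z")
        assert mean_cytoplasm_thickness(ann, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_summed_convention_halves_thin_annulus(self):
        outer = regular_polygon(100, 100, 50.0, 256)
        inner = regular_polygon(100, 100, 30.0, 256)
        ann = CapillaryAnnotation(vessel_outer=outer, lumen=inner, capillary_id="ann")
        midline = mean_cytoplasm_thickness(ann, 10.0, "midline")
        summed = mean_cytoplasm_thickness(ann, 10.0, "summed")
        assert summed == pytest.approx(midline / 2, rel=1e-9)

    def test_unknown_convention(self):
        outer = regular_polygon(0, 0, 50.0, 64)
        inner = regular_polygon(0, 0, 30.0, 64)
        ann = CapillaryAnnotation(vessel_outer=outer, lumen=inner, capillary_id="a")
        with pytest.raises(ValueError, match="convention"):
            mean_cytoplasm_thickness(ann, 10.0, "midpoint")

    def test_elliptical_annulus_against_distance_transform(self):
        # oracle: distance-transform wall width of the rasterised wall on a
        # 2048^2 raster (elliptical annulus with 5 small nuclei subtracted);
        # for a strip of width w the mean boundary distance over the strip is
        # w/4, so 4 * mean(EDT) estimates the mean wall width
        from scipy.ndimage import distance_transform_edt

        def ellipse(cx, cy, a, b, n=512):
            t = np.linspace(0, 2 * np.pi, n, endpoint=False)
            return Polygon(np.column_stack([cx + a * np.cos(t), cy + b * np.sin(t)]))

        cx = cy = 1024.0
        outer = ellipse(cx, cy, 900.0, 600.0)
        lumen = ellipse(cx, cy, 740.0, 460.0)
        nuclei = []
        for ang in np.linspace(0.2, 2 * np.pi, 5, endpoint=False):
            # midpoint of the wall along the ray
            rx = 0.5 * (900 + 740) * np.cos(ang)
            ry = 0.5 * (600 + 460) * np.sin(ang)
            nuclei.append(regular_polygon(cx + rx, cy + ry, 15.0, 32))
        ann = CapillaryAnnotation(
            vessel_outer=outer, lumen=lumen, nuclei=nuclei, capillary_id="ell"
        )
        measured_px = mean_cytoplasm_thickness(ann, nm_per_px=1.0)

        shape = (2048, 2048)
        wall = polygon_pixel_mask(outer, shape) & ~polygon_pixel_mask(lumen, shape)
        for nuc in nuclei:
            wall &= ~polygon_pixel_mask(nuc, shape)
        dist = distance_transform_edt(wall)
        oracle_px = 4.0 * float(dist[wall].mean())
        assert measured_px == pytest.approx(oracle_px, rel=0.10)


class TestChromatinDensityVariation:
    def test_constant_region_is_zero(self):
        img = CalibratedImage(np.full((20, 20), 128, np.uint8), 10.0)
        assert chromatin_density_variation(img, rect(2, 2, 18, 18)) == 0.0

    def test_two_pixel_region_hand_computed(self):
        px = np.zeros((3, 4), np.uint8)
        px[1, 1] = 100
        px[1, 2] = 120
        img = CalibratedImage(px, 10.0)
        # centres (1,1) and (2,1) strictly inside the rect
        nucleus = rect(0.5, 0.5, 2.5, 1.5)
        assert chromatin_density_variation(img, nucleus) == pytest.approx(
            math.sqrt(200.0)
        )

    def test_too_few_pixels(self):
        img = CalibratedImage(np.zeros((5, 5), np.uint8), 10.0)
        with pytest.raises(ValueError, match="interior pixels"):
            chromatin_density_variation(img, rect(0.6, 0.6, 1.4, 1.4))

    def test_gaussian_sd_consistency(self):
        # SD estimator consistency at >= 10^4 pixels, sigma on the 8-bit scale
        rng = np.random.default_rng(0)
        sigma = 35.4
        px = np.clip(rng.normal(127.5, sigma, (120, 120)), 0, 255)
        img = CalibratedImage(px.astype(np.uint8), 10.0)
        cdv = chromatin_density_variation(img, rect(1, 1, 119, 119))
        assert cdv == pytest.approx(sigma, rel=0.03)

    def test_shift_invariance_and_intensity_scaling(self):
        rng = np.random.default_rng(1)
        base = rng.integers(40, 80, (50, 50)).astype(np.float64) / 255.0
        nucleus = rect(2, 2, 48, 48)
        cdv0 = chromatin_density_variation(CalibratedImage(base, 10.0), nucleus)
        shifted = chromatin_density_variation(
            CalibratedImage(base + 0.4, 10.0), nucleus
        )
        scaled = chromatin_density_variation(
            CalibratedImage(base * 2.0, 10.0), nucleus
        )
        assert shifted == pytest.approx(cdv0, rel=1e-12)
        assert scaled == pytest.approx(2.0 * cdv0, rel=1e-12)


class TestCountMarks:
    def _ann(self, caveolae=(), junctions=()):
        return CapillaryAnnotation(
            vessel_outer=rect(0, 0, 100, 100),
            lumen=rect(10, 10, 50, 50),
            caveolae=list(caveolae),
            junctions=list(junctions),
            capillary_id="m",
        )

    def test_junction_count(self):
        ann = self._ann(junctions=[JunctionMark(1, 1)] * 3)
        assert count_marks(ann, "junctions") == (3, None)

    def test_no_caveolae_missing_diameter(self):
        assert count_marks(self._ann(), "caveolae") == (0, None)

    def test_caveola_mean_diameter(self):
        ann = self._ann(
            caveolae=[CaveolaMark(1, 1, 90.0), CaveolaMark(2, 2, 110.0)]
        )
        count, diameter = count_marks(ann, "caveolae")
        assert count == 2
        assert diameter == pytest.approx(100.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            count_marks(self._ann(), "vesicles")


class TestMeasureCapillary:
    def test_conservation_and_no_nucleus(self):
        ann = CapillaryAnnotation(
            vessel_outer=rect(0, 0, 100, 50),
            lumen=rect(5, 5, 55, 45),
            capillary_id="nn",
        )
        m = measure_capillary(None, ann, nm_per_px=100.0)
        assert m.nucleus_area_um2 == 0.0
        assert m.cdv is None
        assert m.total_area_um2 == pytest.approx(
            m.lumen_area_um2 + m.nucleus_area_um2 + m.cytoplasm_area_um2
        )

    def test_requires_calibration(self, square_annotation):
        with pytest.raises(ValueError, match="nm_per_px"):
            measure_capillary(None, square_annotation)

    def test_conflicting_calibration(self, square_annotation):
        img = CalibratedImage(np.zeros((60, 110), np.uint8), 100.0)
        with pytest.raises(ValueError, match="conflicting"):
            measure_capillary(img, square_annotation, nm_per_px=50.0)

    def test_scale_equivariance(self, square_annotation):
        m1 = measure_capillary(None, square_annotation, nm_per_px=100.0)
        m2 = measure_capillary(None, square_annotation, nm_per_px=200.0)
        assert m2.total_area_um2 == pytest.approx(4 * m1.total_area_um2)
        assert m2.cytoplasm_perimeter_um == pytest.approx(2 * m1.cytoplasm_perimeter_um)
        assert m2.thickness_nm == pytest.approx(2 * m1.thickness_nm)
        assert m2.n_caveolae == m1.n_caveolae
        assert m2.n_junctions == m1.n_junctions

    def test_per_animal_mean_is_hand_average(self, ir_infarct_preset):
        from capmorph.synthetic import generate_capillary

        rng = np.random.default_rng(5)
        values = []
        for i in range(5):
            _, ann, _ = generate_capillary(
                ir_infarct_preset, rng=rng, render=False, capillary_id=f"c{i}"
            )
            values.append(measure_capillary(None, ann, nm_per_px=12.0).thickness_nm)
        assert np.mean(values) == pytest.approx(sum(values) / 5)


@settings(max_examples=25, deadline=None)
@given(
    radius=hst.floats(min_value=5.0, max_value=80.0),
    n=hst.integers(min_value=3, max_value=64),
    scale=hst.floats(min_value=1.0, max_value=500.0),
)
def test_area_perimeter_scale_equivariance(radius, n, scale):
    poly = regular_polygon(0.0, 0.0, radius, n)
    assert polygon_area(poly, 2 * scale) == pytest.approx(
        4 * polygon_area(poly, scale), rel=1e-9
    )
    assert polygon_perimeter(poly, 2 * scale) == pytest.approx(
        2 * polygon_perimeter(poly, scale), rel=1e-9
    )


@settings(max_examples=20, deadline=None)
@given(shift=hst.integers(min_value=0, max_value=150))
def test_cdv_shift_invariance(shift):
    rng = np.random.default_rng(99)
    base = rng.integers(0, 100, (30, 30)).astype(np.uint8)
    nucleus = rect(1, 1, 29, 29)
    a = chromatin_density_variation(CalibratedImage(base, 10.0), nucleus)
    b = chromatin_density_variation(
        CalibratedImage(base + np.uint8(shift), 10.0), nucleus
    )
    assert b == pytest.approx(a, rel=1e-12, abs=1e-12)
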