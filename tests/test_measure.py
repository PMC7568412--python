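import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vesica.measure import (
    EllipsoidAxes,
    MeasurementError,
    WallDelineation,
    delineate_phantom,
    ellipsoid_volume,
    lumen_mean_diameter,
    mean_wall_thickness,
    measure_phantom,
    wall_area,
)
from vesica.phantom import (
    BModePhantom,
    SpeckleModel,
    geometry_for_volume,
    render,
    truth_masks,
)

NO_SPECKLE = SpeckleModel(enabled=False)
SPACING = 0.02


# ---------------------------------------------------------------- ellipsoid

@pytest.mark.parametrize(
    "axes, expected_ml",
    [
        (EllipsoidAxes(6.2035, 6.2035, 6.2035), 1.000),   # sphere holding 1 mL
        (EllipsoidAxes(5.0, 5.0, 10.0), 4 / 3 * math.pi * 250 / 1000),
    ],
)
def test_ellipsoid_volume_values(axes, expected_ml):
    assert ellipsoid_volume(axes) == pytest.approx(expected_ml, abs=1e-3)


@given(r=st.floats(0.5, 10.0))
def test_ellipsoid_cubic_scaling(r):
    v1 = ellipsoid_volume(EllipsoidAxes(r, r, r))
    v2 = ellipsoid_volume(EllipsoidAxes(2 * r, 2 * r, 2 * r))
    assert v2 == pytest.approx(8 * v1, rel=1e-12)


@given(
    a=st.floats(0.5, 12.0), b=st.floats(0.5, 12.0), c=st.floats(0.5, 12.0)
)
def test_ellipsoid_axis_symmetry(a, b, c):
    vols = {
        ellipsoid_volume(EllipsoidAxes(*perm)) for perm in itertools.permutations((a, b, c))
    }
    assert max(vols) - min(vols) < 1e-12


def test_ellipsoid_caliper_convention():
    """Full-axis (caliper) inputs are halved to semi-axes: the literal
    (4/3)*pi*product-of-full-axes would be 8x the true volume."""
    semi = EllipsoidAxes(5.0, 5.0, 10.0)
    via_caliper = EllipsoidAxes.from_caliper(10.0, 10.0, 20.0)
    assert ellipsoid_volume(via_caliper) == pytest.approx(ellipsoid_volume(semi), rel=1e-12)


def test_ellipsoid_invalid_axes():
    with pytest.raises(ValueError):
        EllipsoidAxes(1.0, -2.0, 3.0)


# ------------------------------------------------------------------- areas

def _band_mask(n_cols=200, n_rows=15, shape=(300, 300), row0=100, col0=50):
    mask = np.zeros(shape, dtype=bool)
    mask[row0 : row0 + n_rows, col0 : col0 + n_cols] = True
    return mask


def test_wall_area_rectangular_band_mask():
    """A 4 mm x 0.30 mm band at 0.02 mm/px is 200x15 px = 1.20 mm^2."""
    delin = WallDelineation("ventral", _band_mask())
    assert wall_area(delin, SPACING) == pytest.approx(1.20, abs=1e-12)
    assert mean_wall_thickness(delin, SPACING) == pytest.approx(0.30, abs=1e-12)


def test_bwa_bwt_identity():
    delin = WallDelineation("ventral", _band_mask(n_rows=23))
    bwa = wall_area(delin, SPACING)
    bwt = mean_wall_thickness(delin, SPACING)
    assert bwt * delin.segment_length_mm == bwa  # L = 4 mm is exact in binary fp


def test_wall_area_polygon_shoelace():
    tri = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 1.0]])
    delin = WallDelineation("ventral", tri, window_x_mm=(0.0, 4.0))
    assert wall_area(delin) == pytest.approx(2.0, rel=1e-12)


def test_wall_area_polygon_clipped_to_window():
    # 8 mm x 0.3 mm rectangle clipped to the central 4 mm -> 1.2 mm^2
    rect = np.array([[0.0, 0.0], [8.0, 0.0], [8.0, 0.3], [0.0, 0.3]])
    delin = WallDelineation("ventral", rect, window_x_mm=(2.0, 6.0))
    assert wall_area(delin) == pytest.approx(1.2, rel=1e-12)
    centered = WallDelineation("ventral", rect)  # window defaults to centroid
    assert wall_area(centered) == pytest.approx(1.2, rel=1e-12)


def test_wall_area_errors():
    empty = WallDelineation("ventral", np.zeros((300, 300), dtype=bool))
    with pytest.raises(MeasurementError):
        wall_area(empty, SPACING)
    with pytest.raises(ValueError):
        wall_area(WallDelineation("ventral", _band_mask()), spacing_mm=None)
    with pytest.raises(ValueError):
        WallDelineation("sideways", _band_mask())


@pytest.mark.parametrize(
    "area, expected",
    [(math.pi, 2.0), (0.0, 0.0), (50.0, 7.9788)],
)
def test_lumen_mean_diameter_values(area, expected):
    assert lumen_mean_diameter(area) == pytest.approx(expected, abs=1e-4)


def test_lumen_mean_diameter_circle_identity():
    for r in (1.0, 3.7, 8.2):
        assert lumen_mean_diameter(math.pi * r**2) == pytest.approx(2 * r, rel=1e-12)
    with pytest.raises(ValueError):
        lumen_mean_diameter(-1.0)


# ------------------------------------------------------------- delineation

def test_noiseless_delineation_equals_truth_masks(clean_phantom):
    delin, lumen = delineate_phantom(clean_phantom, side="ventral", smooth_sigma_px=0)
    truth_lumen, truth_ventral, _ = truth_masks(
        clean_phantom.truth, clean_phantom.image.shape, clean_phantom.spacing_mm
    )
    np.testing.assert_array_equal(lumen, truth_lumen)
    clipped = np.zeros_like(truth_ventral)
    c0 = int(np.nonzero(delin.region.any(axis=0))[0][0])
    c1 = int(np.nonzero(delin.region.any(axis=0))[0][-1]) + 1
    clipped[:, c0:c1] = truth_ventral[:, c0:c1]
    np.testing.assert_array_equal(delin.region, clipped)


def _segment_area_thickness(radius_mm, t_mm, half_window_mm=2.0):
    """Analytic oracle: area between concentric circles of radii R and R+t
    over the 4-mm segment, divided by the segment length.  This is what the
    area-over-segment definition measures at the pole of a curved wall; it
    exceeds the normal thickness slightly when t/R is large."""

    def half_circle_integral(a, x):
        return 0.5 * (x * math.sqrt(a**2 - x**2) + a**2 * math.asin(x / a))

    w = half_window_mm
    area = 2 * (
        half_circle_integral(radius_mm + t_mm, w) - half_circle_integral(radius_mm, w)
    )
    return area / (2 * w)


@pytest.mark.parametrize("t_mm", [0.15, 0.30, 0.60, 0.90])
@pytest.mark.parametrize("volume_ml", [0.2, 1.0, 3.0])
def test_roundtrip_sweep_noiseless(t_mm, volume_ml):
    """Across the thickness/volume envelope, noiseless measurement matches
    the analytic area-based expectation within 1 px, the normal thickness
    within 2 px in the thin-wall regime, and lumen area within 3%."""
    truth = geometry_for_volume(volume_ml, t_mm, t_mm)
    radius = truth.lumen.semi_x_mm
    expected = _segment_area_thickness(radius, t_mm)
    ph = render(truth, speckle=NO_SPECKLE)
    for side in ("ventral", "dorsal"):
        m = measure_phantom(ph, side=side, smooth_sigma_px=0)
        assert abs(m.bwt_mean_mm - expected) <= SPACING
        if t_mm / radius < 0.15:  # thin-wall regime: curvature bias sub-pixel
            assert abs(m.bwt_mean_mm - t_mm) <= 2 * SPACING
        assert m.lumen_area_mm2 == pytest.approx(truth.lumen.area_mm2(), rel=0.03)


def test_roundtrip_with_speckle(law):
    """Automated delineation under default speckle stays within 2 px of the
    sidecar ground truth."""
    rng = np.random.default_rng(99)
    for volume_ml in (1.6, 2.2, 2.9):
        tv = law.ventral_thickness(volume_ml)
        td = law.dorsal_thickness(volume_ml)
        truth = geometry_for_volume(volume_ml, tv, td)
        ph = render(truth, seed=int(rng.integers(2**31)))
        mv = measure_phantom(ph, side="ventral")
        md = measure_phantom(ph, side="dorsal")
        assert abs(mv.bwt_mean_mm - tv) <= 2 * SPACING
        assert abs(md.bwt_mean_mm - td) <= 2 * SPACING


def test_oracle_mode_matches_truth(speckle_phantom):
    m = measure_phantom(speckle_phantom, mode="oracle")
    truth = speckle_phantom.truth
    assert m.bwt_mean_mm == pytest.approx(truth.t_ventral_mm, abs=2 * SPACING)
    assert m.lumen_area_mm2 == pytest.approx(truth.lumen.area_mm2(), rel=0.03)
    assert m.diameter_mm == pytest.approx(
        lumen_mean_diameter(m.lumen_area_mm2), rel=1e-12
    )


def test_no_lumen_raises_named_error():
    flat = BModePhantom(image=np.full((300, 300), 0.35, dtype=np.float32), spacing_mm=SPACING)
    with pytest.raises(MeasurementError, match="no lumen"):
        measure_phantom(flat)


def test_oracle_mode_requires_sidecar():
    flat = BModePhantom(image=np.full((300, 300), 0.1, dtype=np.float32), spacing_mm=SPACING)
    with pytest.raises(MeasurementError, match="sidecar"):
        measure_phantom(flat, mode="oracle")


def test_measurement_result_identities(clean_measurement):
    m = clean_measurement
    assert m.bwt_mean_mm * m.segment_length_mm == pytest.approx(m.bwa_mm2, rel=1e-12)
    assert m.diameter_mm == pytest.approx(
        2 * math.sqrt(m.lumen_area_mm2 / math.pi), rel=1e-12
    )
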