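"""Geometric core: adequacy indices, profiles, sphere/ellipsoid fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvspect.geometry import (
    DegenerateFitError,
    EllipsoidModel,
    GeometryIndices,
    ScalarVolume,
    eccentricity_half,
    extract_radial_profiles,
    fit_ellipsoid_least_squares,
    fit_sphere_least_squares,
    sphericity_ratio,
    truncate2,
)


# --- model-adequacy ratios -------------------------------------------------


@pytest.mark.parametrize(
    "x, expected, printed",
    [
        (2.0, 0.5 * np.sqrt(5.0), 1.11),  # end-systolic population index
        (1.7, 0.5 * np.sqrt(1.7**2 + 1), 0.98),  # end-diastolic
        (np.sqrt(3.0), 1.0, None),  # exact unity; truncation of 1-eps is moot
    ],
)
def test_sphericity_ratio_values(x, expected, printed):
    assert sphericity_ratio(x) == pytest.approx(expected, abs=1e-12)
    if printed is not None:
        assert truncate2(sphericity_ratio(x)) == pytest.approx(printed, abs=1e-12)


def test_sphericity_ratio_rejects_nonpositive():
    with pytest.raises(ValueError):
        sphericity_ratio(0.0)
    with pytest.raises(ValueError):
        sphericity_ratio(-1.0)


@pytest.mark.parametrize("ecc, expected", [(2.0, 1.0), (1.8, 0.9), (1.0, 0.5)])
def test_eccentricity_half_values(ecc, expected):
    assert eccentricity_half(ecc) == pytest.approx(expected, abs=1e-12)


def test_eccentricity_half_rejects_below_one():
    with pytest.raises(ValueError):
        eccentricity_half(0.9)


@given(st.floats(min_value=0.05, max_value=20.0))
@settings(max_examples=100, deadline=None)
def test_sphericity_ratio_exact_identity(x):
    assert sphericity_ratio(x) ** 2 - 0.25 * (x * x + 1.0) == pytest.approx(0.0, abs=1e-12)


def test_geometry_indices_relations():
    g = GeometryIndices(a=40.0, b=80.0, c=50.0, d=30.0)
    assert g.f == pytest.approx(0.5 * np.hypot(40.0, 80.0), abs=1e-12)
    assert g.x == pytest.approx(0.5)
    assert g.eccentricity == pytest.approx(50.0 / 30.0)
    assert g.m == pytest.approx(25.0)
    with pytest.raises(ValueError):
        GeometryIndices(a=-1.0, b=80.0, c=50.0, d=30.0)


# --- radial profiles -------------------------------------------------------


def _constant_volume(value=3.0, n=24, spacing=4.0):
    return ScalarVolume(np.full((n, n, n), value), spacing=(spacing,) * 3)


@pytest.mark.parametrize("n_long, n_lat", [(48, 96), (120, 320), (1, 1)])
def test_profile_counts(n_long, n_lat):
    vol = _constant_volume()
    center = vol.extent_mm() / 2
    ps = extract_radial_profiles(vol, center, n_long, n_lat, max_radius=20.0)
    assert len(ps) == n_long * n_lat
    assert ps.samples.shape[0] == n_long * n_lat


def test_profiles_constant_volume_and_linearity():
    vol = _constant_volume(value=5.0)
    center = vol.extent_mm() / 2
    ps = extract_radial_profiles(vol, center, 6, 12, step=2.0, max_radius=25.0)
    assert np.allclose(ps.samples, 5.0)
    scaled = ScalarVolume(vol.data * 7.0, spacing=vol.spacing)
    ps7 = extract_radial_profiles(scaled, center, 6, 12, step=2.0, max_radius=25.0)
    assert np.allclose(ps7.samples, 7.0 * ps.samples)


def test_profiles_zero_outside_grid_and_origin_check():
    vol = _constant_volume(value=2.0, n=16, spacing=2.0)
    center = vol.extent_mm() / 2
    ps = extract_radial_profiles(vol, center, 4, 4, step=5.0, max_radius=200.0)
    assert np.allclose(ps.samples[:, -1], 0.0)  # far outside the grid
    with pytest.raises(ValueError):
        extract_radial_profiles(vol, (-5.0, 0.0, 0.0), 4, 4)
    with pytest.raises(ValueError):
        extract_radial_profiles(vol, center, 0, 4)


def test_profile_angular_grid_covers_sphere():
    vol = _constant_volume()
    ps = extract_radial_profiles(vol, vol.extent_mm() / 2, 8, 16, max_radius=10.0)
    assert np.allclose(np.linalg.norm(ps.directions, axis=1), 1.0)
    # mean direction of a full regular grid is (numerically) zero
    assert np.linalg.norm(ps.directions.mean(axis=0)) < 1e-12
    p = ps[17]
    assert p.angular_index == (1, 1)
    assert p.samples.shape == ps.samples[17].shape


# --- sphere fitting --------------------------------------------------------


def _sphere_points(center, radius, n, rng, sigma=0.0):
    t = np.arccos(rng.uniform(-1, 1, n))
    p = rng.uniform(0, 2 * np.pi, n)
    d = np.stack([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)], axis=1)
    pts = np.asarray(center) + radius * d
    if sigma:
        pts = pts + rng.normal(0, sigma, pts.shape)
    return pts


def brute_force_sphere(pts):
    """Geometric least-squares oracle: grid search over centers to 0.1 mm.

    For a fixed center the optimal radius of the summed squared geometric
    residual is the mean point distance, so the search is over centers only.
    """
    center = pts.mean(axis=0)
    for step, span in ((1.0, 6.0), (0.5, 2.0), (0.1, 1.0)):
        offs = np.arange(-span, span + step / 2, step)
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        cand = center + np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
        d = np.linalg.norm(pts[None, :, :] - cand[:, None, :], axis=2)
        r = d.mean(axis=1)
        cost = ((d - r[:, None]) ** 2).sum(axis=1)
        k = int(np.argmin(cost))
        center = cand[k]
    d = np.linalg.norm(pts - center, axis=1)
    return center, d.mean()


def test_sphere_fit_exact_axis_points():
    c = np.array([1.0, 2.0, 3.0])
    pts = c + 5.0 * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
    )
    m = fit_sphere_least_squares(pts)
    assert np.allclose(m.center, c, atol=1e-9)
    assert m.radius == pytest.approx(5.0, abs=1e-9)


def test_sphere_fit_matches_brute_force_on_noisy_cloud():
    rng = np.random.default_rng(42)
    pts = _sphere_points((10.0, -5.0, 0.0), 25.0, 200, rng, sigma=1.0)
    m = fit_sphere_least_squares(pts)
    c_oracle, r_oracle = brute_force_sphere(pts)
    assert np.linalg.norm(m.center_arr - c_oracle) < 0.5
    assert abs(m.radius - r_oracle) < 0.5


def test_sphere_fit_translation_equivariance():
    rng = np.random.default_rng(3)
    pts = _sphere_points((0.0, 0.0, 0.0), 12.0, 50, rng, sigma=0.5)
    t = np.array([13.7, -4.2, 8.9])
    m0 = fit_sphere_least_squares(pts)
    m1 = fit_sphere_least_squares(pts + t)
    assert np.allclose(m1.center_arr, m0.center_arr + t, atol=1e-9)
    assert m1.radius == pytest.approx(m0.radius, abs=1e-9)


def test_sphere_fit_exact_radius_on_many_points():
    rng = np.random.default_rng(0)
    pts = _sphere_points((2.0, 2.0, 2.0), 31.5, 40, rng)
    assert fit_sphere_least_squares(pts).radius == pytest.approx(31.5, abs=1e-6)


def test_sphere_fit_degenerate_inputs():
    with pytest.raises(DegenerateFitError):
        fit_sphere_least_squares(np.zeros((3, 3)))
    rng = np.random.default_rng(1)
    coplanar = np.column_stack([rng.normal(size=10), rng.normal(size=10), np.ones(10)])
    with pytest.raises(DegenerateFitError):
        fit_sphere_least_squares(coplanar)


# --- ellipsoid fitting -----------------------------------------------------


def _ellipsoid_points(semi, center, n, rng, sigma=0.0):
    t = np.arccos(rng.uniform(-1, 1, n))
    p = rng.uniform(0, 2 * np.pi, n)
    d = np.stack([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)], axis=1)
    pts = np.asarray(center) + d * np.asarray(semi)
    if sigma:
        pts = pts + rng.normal(0, sigma, pts.shape)
    return pts


def test_ellipsoid_fit_exact():
    rng = np.random.default_rng(5)
    pts = _ellipsoid_points((20.0, 30.0, 45.0), (5.0, -2.0, 1.0), 200, rng)
    m = fit_ellipsoid_least_squares(pts)
    assert np.allclose(m.semi_axes, (20.0, 30.0, 45.0), atol=0.1)
    assert np.allclose(m.center, (5.0, -2.0, 1.0), atol=0.1)


def test_ellipsoid_fit_noisy_recovery():
    rng = np.random.default_rng(12)
    pts = _ellipsoid_points((20.0, 30.0, 45.0), (0.0, 0.0, 0.0), 400, rng, sigma=1.0)
    m = fit_ellipsoid_least_squares(pts)
    assert np.allclose(m.semi_axes, (20.0, 30.0, 45.0), atol=1.0)


def test_ellipsoid_fit_errors():
    rng = np.random.default_rng(2)
    with pytest.raises(DegenerateFitError):
        fit_ellipsoid_least_squares(_ellipsoid_points((20, 30, 45), (0, 0, 0), 8, rng))
    coplanar = np.column_stack(
        [rng.normal(size=30), rng.normal(size=30), np.zeros(30)]
    )
    with pytest.raises(DegenerateFitError):
        fit_ellipsoid_least_squares(coplanar)


def test_ellipsoid_model_radius_along():
    m = EllipsoidModel(center=(0, 0, 0), semi_axes=(10.0, 20.0, 30.0))
    r = m.radius_along(np.eye(3))
    assert np.allclose(r, (10.0, 20.0, 30.0))
    with pytest.raises(ValueError):
        EllipsoidModel(center=(0, 0, 0), semi_axes=(30.0, 20.0, 10.0))


def test_scalar_volume_invariants():
    with pytest.raises(ValueError):
        ScalarVolume(-np.ones((16, 16, 16)))
    with pytest.raises(ValueError):
        ScalarVolume(np.ones((8, 16, 16)))
    with pytest.raises(ValueError):
        ScalarVolume(np.ones((16, 16, 16)), spacing=(0.0, 1.0, 1.0))
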