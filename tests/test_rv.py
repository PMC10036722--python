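"""RV segmentation: initialization, adaptive threshold, delineation, fitting,
surface construction and mask building."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rvspect import phantom as ph
from rvspect.geometry import (
    DegenerateFitError,
    Plane,
    RadialProfile,
    ScalarVolume,
    SphereModel,
    sphere_directions,
)
from rvspect.lv import LVResult, segment_lv
from rvspect.geometry import EllipsoidModel
from rvspect import rv as rvm
from rvspect.stats import dice


def _stub_lv(center=(0.0, 0.0, 0.0), semi=(20.0, 25.0, 40.0), valve_z=20.0):
    """Minimal LVResult for unit tests of RV helpers."""
    n_long, n_lat = 8, 16
    model = EllipsoidModel(center=center, semi_axes=semi)
    fill = np.full((n_long, n_lat), semi[2] + 5.0)
    return LVResult(
        model=model,
        mask_myocardium=np.zeros((16, 16, 16), dtype=bool),
        valve_plane=Plane(
            point=(center[0], center[1], center[2] + valve_z), normal=(0, 0, 1)
        ),
        max_count=1.0,
        intra_patient_threshold=0.5,
        n_long=n_long,
        n_lat=n_lat,
        epi_r=fill,
        endo_r=fill * 0.6,
        mid_r=fill * 0.8,
        valid=np.ones((n_long, n_lat), dtype=bool),
        wall_mm=10.0,
    )


# --- initialization ---------------------------------------------------------


@pytest.mark.parametrize(
    "semi, exp_center, exp_radius",
    [
        ((20.0, 25.0, 40.0), (-20.0, 0.0, -8.0), 30.0),
        ((25.0, 25.0, 45.0), (-25.0, 0.0, -9.0), 37.5),
    ],
)
def test_init_rv_sphere_from_lv(semi, exp_center, exp_radius):
    lv = _stub_lv(semi=semi)
    m = rvm.init_rv_sphere(lv)
    assert np.allclose(m.center, exp_center, atol=1e-12)
    assert m.radius == pytest.approx(exp_radius, abs=1e-12)


def test_init_rv_sphere_user_override():
    lv = _stub_lv()
    m = rvm.init_rv_sphere(lv, center_override=(1.0, 2.0, 3.0), radius_override=17.5)
    assert m.center == (1.0, 2.0, 3.0)
    assert m.radius == 17.5


# --- adaptive threshold ------------------------------------------------------


@pytest.mark.parametrize(
    "c_profile, expected",
    [
        (0.5, 0.40),  # difference term vanishes
        (0.25, 0.8 * 0.25 / 0.9),  # 0.2222...
        (0.4, 0.8 * 0.4 / 0.96),  # 0.3333...
    ],
)
def test_adaptive_threshold_worked_values(c_profile, expected):
    assert rvm.eq5_threshold(c_profile) == pytest.approx(expected, abs=1e-12)


def test_adaptive_threshold_domain_errors():
    with pytest.raises(ValueError):
        rvm.eq5_threshold(0.0)
    with pytest.raises(ValueError):
        rvm.eq5_threshold(1.5)
    with pytest.raises(ValueError):
        rvm.eq5_threshold(0.5, c_max=3.0)  # denominator <= 0


@given(st.floats(min_value=0.2500001, max_value=1.0))
@settings(max_examples=100, deadline=None)
def test_adaptive_threshold_below_profile_maximum(c):
    assert rvm.eq5_threshold(c) < c


# --- profile validity and delineation ----------------------------------------


def _bump_profile(peak_r, height, width=8.0, step=1.0, n=80):
    radii = np.arange(n) * step
    samples = np.clip(height * (1 - np.abs(radii - peak_r) / width), 0, None)
    return RadialProfile(
        origin=(0.0, 0.0, 0.0),
        direction=(1.0, 0.0, 0.0),
        samples=samples,
        step=step,
        angular_index=(0, 0),
    )


def test_validity_conditions():
    sphere = SphereModel(center=(0, 0, 0), radius=40.0)
    ok, c, r_pk = rvm.select_valid_profile(_bump_profile(35.0, 0.4), sphere, 6.4)
    assert ok and c == pytest.approx(0.4) and r_pk == pytest.approx(35.0)
    ok, _, _ = rvm.select_valid_profile(_bump_profile(50.0, 0.4), sphere, 6.4)
    assert not ok  # 10 mm from the surface
    ok, _, _ = rvm.select_valid_profile(_bump_profile(40.0, 0.2), sphere, 6.4)
    assert not ok  # below one quarter of LV max


def test_delineation_of_symmetric_bump():
    sphere = SphereModel(center=(0, 0, 0), radius=40.0)
    prof = _bump_profile(40.0, 0.4, width=10.0, step=1.0)
    d = rvm.delineate_profile(prof, 0.4, sphere, voxel=6.4)
    assert d.valid
    assert d.mid_r == pytest.approx(40.0, abs=1.0)  # within one sampling step
    assert d.endocardial_r < 40.0 < d.epicardial_r
    assert d.mid_r == pytest.approx((d.endocardial_r + d.epicardial_r) / 2.0, abs=1e-12)
    assert not (d.far_off_epi or d.far_off_endo)


def test_far_off_flagging():
    # flat-topped run from 25 to 55 mm -> both crossings far from the surface
    radii = np.arange(80.0)
    samples = np.where((radii >= 25) & (radii <= 55), 0.4, 0.0)
    samples[40] = 0.401  # unique maximum near the sphere surface
    prof = RadialProfile(
        origin=(0.0, 0.0, 0.0),
        direction=(1.0, 0.0, 0.0),
        samples=samples,
        step=1.0,
        angular_index=(0, 0),
    )
    sphere = SphereModel(center=(0, 0, 0), radius=40.0)
    d = rvm.delineate_profile(prof, 0.401, sphere, voxel=6.4)
    assert d.valid
    assert d.epicardial_r > 52.8 and d.far_off_epi
    assert d.far_off_endo  # endocardial crossing below 27.2 mm


def test_delineation_demotes_below_threshold():
    sphere = SphereModel(center=(0, 0, 0), radius=40.0)
    prof = _bump_profile(40.0, 0.3)
    # claimed c_profile far above the actual peak -> run empty -> demoted
    d = rvm.delineate_profile(prof, 0.9, sphere, voxel=6.4, peak_radius=40.0)
    assert not d.valid


# --- iterative model fit ------------------------------------------------------


def test_fit_recovers_truth_sphere(clean_phantom, clean_lv, clean_rv):
    _, truth = clean_phantom
    rv = clean_rv
    assert np.linalg.norm(rv.model.center_arr - truth.rv_model.center_arr) < 2.0
    assert abs(rv.model.radius - truth.rv_model.radius) < 2.0


def test_fit_repeatability_across_noise_seeds():
    radii = []
    for seed in (1, 2):
        vol, _ = ph.generate_phantom(ph.PhantomSpec(seed=seed))
        lv = segment_lv(vol)
        rv = rvm.segment_rv(vol, lv, fallback_to_init=True)
        radii.append(rv.model.radius)
    assert abs(radii[0] - radii[1]) < 1.5


def test_fit_basin_of_attraction(clean_phantom, clean_lv, clean_rv):
    vol, _ = clean_phantom
    lv = clean_lv
    ref = clean_rv.model
    init = rvm.init_rv_sphere(lv)
    displaced = SphereModel(
        center=tuple(init.center_arr + np.array([-6.0, 6.0, 5.0])), radius=init.radius
    )
    sphere, _ = rvm.fit_rv_model(vol, displaced, lv)
    assert np.linalg.norm(sphere.center_arr - ref.center_arr) < 1.0
    assert abs(sphere.radius - ref.radius) < 1.0


def test_not_detectable_on_empty_rv():
    spec = ph.PhantomSpec(
        rv_fraction=0.01, psf_fwhm_mm=0, apply_poisson=False, apply_butterworth=False
    )
    vol, _ = ph.generate_phantom(spec)
    lv = segment_lv(vol)
    with pytest.raises(rvm.RVNotDetectableError):
        rvm.segment_rv(vol, lv, fallback_to_init=False)
    # the fallback accepts the initial model instead
    rv = rvm.segment_rv(vol, lv, fallback_to_init=True)
    assert rv.iterations == 0


# --- dense refinement ---------------------------------------------------------


def test_refinement_profile_count_and_replacements(clean_phantom, clean_lv):
    vol, truth = clean_phantom
    dense, refreshed = rvm.refine_surfaces(vol, truth.rv_model, clean_lv)
    assert len(dense.profiles) == 120 * 320
    assert dense.replaced is not None
    # the free-wall interior is fully measured on a clean phantom
    wrap = np.abs(np.angle(np.exp(1j * (dense.profiles.phis - np.pi))))
    interior = (
        (wrap < np.deg2rad(60))
        & (dense.profiles.thetas > np.pi / 3)
        & (dense.profiles.thetas < 2 * np.pi / 3)
    )
    assert dense.replaced[interior].sum() == 0
    assert abs(refreshed.radius - truth.rv_model.radius) < 2.0


def test_refinement_closes_defect(clean_phantom):
    spec = dataclasses.replace(
        ph.PhantomSpec(psf_fwhm_mm=0, apply_poisson=False, apply_butterworth=False),
        defect=ph.DefectSpec("basal", "severe"),
    )
    vol, truth = ph.generate_phantom(spec)
    lv = segment_lv(vol)
    rv = rvm.segment_rv(vol, lv, fallback_to_init=True)
    assert rv.delineation.replaced.sum() > 0
    # surface evaluates finitely everywhere on its domain (closed surface)
    t = np.linspace(0.1, np.pi - 0.1, 30)
    p = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    T, P = np.meshgrid(t, p)
    r = rv.mid_surface.evaluate(T.ravel(), P.ravel())
    assert np.all(np.isfinite(r)) and np.all(r > 0)
    # and the defect region is still covered by the myocardium mask
    d = dice(rv.mask_myocardium, truth.rv_myocardium)
    assert d >= 0.85


# --- valve plane --------------------------------------------------------------


def test_rv_valve_plane_untilted():
    lv = _stub_lv(center=(50.0, 50.0, 50.0), valve_z=25.0)
    plane = rvm.rv_valve_plane(lv)
    assert np.allclose(plane.normal, (0, 0, 1), atol=1e-9)
    assert plane.point[2] == pytest.approx(75.0, abs=1e-6)


def test_rv_valve_plane_shares_tilt_and_sits_on_epicardium():
    lv = _stub_lv(center=(50.0, 50.0, 50.0), valve_z=25.0)
    tilt = np.deg2rad(10.0)
    lv.valve_plane = Plane(
        point=(50.0, 50.0, 75.0), normal=(0.0, np.sin(tilt), np.cos(tilt))
    )
    plane = rvm.rv_valve_plane(lv)
    assert np.allclose(plane.normal, (0.0, np.sin(tilt), np.cos(tilt)), atol=1e-9)
    q = np.asarray(plane.point)
    r = np.linalg.norm(q - lv.model.center_arr)
    assert abs(r - lv.epi_radius_at(q[None, :])[0]) < 3.2  # on the surface (half voxel)


# --- mid-surface polynomial ---------------------------------------------------


def _synthetic_dense(radius_fn, n_long=24, n_lat=48, sphere_r=35.0):
    dirs, thetas, phis = sphere_directions(n_long, n_lat)

    class _P:
        pass

    prof = _P()
    prof.origin = np.zeros(3)
    prof.directions = dirs
    prof.thetas = thetas
    prof.phis = phis
    prof.n_long = n_long
    prof.n_lat = n_lat
    mid = radius_fn(thetas, phis)
    n = len(thetas)
    return rvm.DelineationSet(
        profiles=prof,
        sphere=SphereModel(center=(0, 0, 0), radius=sphere_r),
        c_profile=np.full(n, 0.4),
        peak_r=mid.copy(),
        valid=np.ones(n, dtype=bool),
        epi_r=mid + 5.0,
        endo_r=mid - 5.0,
        mid_r=mid,
        far_off_epi=np.zeros(n, dtype=bool),
        far_off_endo=np.zeros(n, dtype=bool),
    )


FAR_VALVE = Plane(point=(0.0, 0.0, 500.0), normal=(0.0, 0.0, 1.0))


def test_mid_surface_reproduces_constant_radius():
    dense = _synthetic_dense(lambda t, p: np.full_like(t, 35.0))
    surf = rvm.build_mid_surface(dense, FAR_VALVE)
    t = np.linspace(0.3, np.pi - 0.3, 20)
    p = np.linspace(0.2, 2 * np.pi - 0.2, 40)
    T, P = np.meshgrid(t, p)
    r = surf.evaluate(T.ravel(), P.ravel())
    assert np.allclose(r, 35.0, atol=1e-6)
    assert surf.rms_residual < 1e-6


def test_mid_surface_fits_smooth_variation():
    dense = _synthetic_dense(lambda t, p: 35.0 + 3.0 * np.cos(t))
    surf = rvm.build_mid_surface(dense, FAR_VALVE)
    assert surf.rms_residual < 0.1


def test_mid_surface_underdetermined():
    dense = _synthetic_dense(lambda t, p: np.full_like(t, 35.0), n_long=2, n_lat=5)
    with pytest.raises(DegenerateFitError):
        rvm.build_mid_surface(dense, FAR_VALVE)


# --- masks and cavity volume ---------------------------------------------------


def _cap_surface(center, mid_radius):
    coeffs = np.zeros(len(rvm._POLY_EXPONENTS))
    coeffs[0] = mid_radius
    return rvm.MidSurface(
        center=np.asarray(center, dtype=float),
        coeffs=coeffs,
        phi0=np.pi,
        theta_range=(0.0, np.pi),
        phi_range=(0.0, 2 * np.pi),
        sphere_radius=mid_radius,
        rms_residual=0.0,
    )


def test_half_sphere_cavity_volume():
    sp = 4.0
    vol = ScalarVolume(np.zeros((48, 48, 48)), spacing=(sp,) * 3)
    center = vol.extent_mm() / 2
    wall = 12.8
    surf = _cap_surface(center, 30.0 + wall / 2.0)  # endocardial radius 30 mm
    valve = Plane(point=tuple(center), normal=(0, 0, 1))
    res = rvm.build_masks(surf, valve, vol, lv=None, wall_mm=wall)
    expected = (2.0 / 3.0) * np.pi * 30.0**3 / 1000.0
    assert res.cavity_volume_ml == pytest.approx(expected, rel=0.05)
    assert res.cavity_volume_ml == pytest.approx(
        res.mask_cavity.sum() * vol.voxel_volume_ml, abs=1e-12
    )


def test_cavity_grows_when_valve_moves_basal():
    sp = 4.0
    vol = ScalarVolume(np.zeros((48, 48, 48)), spacing=(sp,) * 3)
    center = vol.extent_mm() / 2
    surf = _cap_surface(center, 36.4)
    v1 = rvm.build_masks(
        surf, Plane(point=tuple(center), normal=(0, 0, 1)), vol, wall_mm=12.8
    )
    basal = center + np.array([0.0, 0.0, 6.4])
    v2 = rvm.build_masks(
        surf, Plane(point=tuple(basal), normal=(0, 0, 1)), vol, wall_mm=12.8
    )
    assert v2.cavity_volume_ml > v1.cavity_volume_ml


def test_zero_wall_gives_empty_myocardium():
    sp = 4.0
    vol = ScalarVolume(np.zeros((48, 48, 48)), spacing=(sp,) * 3)
    center = vol.extent_mm() / 2
    surf = _cap_surface(center, 30.0)
    res = rvm.build_masks(
        surf, Plane(point=tuple(center), normal=(0, 0, 1)), vol, wall_mm=0.0
    )
    assert res.mask_myocardium.sum() == 0


def test_cavity_mask_respects_valve_and_lv(clean_phantom, clean_lv, clean_rv):
    vol, _ = clean_phantom
    rv = clean_rv
    idx = np.argwhere(rv.mask_cavity) * np.array(vol.spacing)
    assert np.all(rv.valve_plane.signed_distance(idx) <= 0)
    assert not np.any(rv.mask_cavity & clean_lv.mask_myocardium)
    assert not np.any(rv.mask_myocardium & clean_lv.mask_myocardium)
    assert not np.any(rv.mask_myocardium & rv.mask_cavity)


# --- end-to-end properties ------------------------------------------------------


def test_count_scale_invariance(noisy_phantom):
    vol, _ = noisy_phantom
    lv1 = segment_lv(vol)
    rv1 = rvm.segment_rv(vol, lv1, fallback_to_init=True)
    vol_k = ScalarVolume(vol.data * 3.7, spacing=vol.spacing)
    lvk = segment_lv(vol_k)
    rvk = rvm.segment_rv(vol_k, lvk, fallback_to_init=True)
    assert np.array_equal(rv1.mask_myocardium, rvk.mask_myocardium)
    assert np.array_equal(rv1.mask_cavity, rvk.mask_cavity)
    assert rv1.cavity_volume_ml == pytest.approx(rvk.cavity_volume_ml, abs=1e-12)


def test_segmentation_is_deterministic(noisy_phantom):
    vol, _ = noisy_phantom
    out = []
    for _ in range(2):
        lv = segment_lv(vol)
        rv = rvm.segment_rv(vol, lv, fallback_to_init=True)
        out.append(rv)
    assert np.array_equal(out[0].mask_myocardium, out[1].mask_myocardium)
    assert out[0].cavity_volume_ml == out[1].cavity_volume_ml
    assert out[0].model == out[1].model
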