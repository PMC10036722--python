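"""Iterative spherical-model right-ventricle segmentation.

The RV wall in non-gated perfusion SPECT is thin (below one voxel) and
faint; only part of it rises above background.  The method therefore fits a
geometric model: a sphere initialized from the LV ellipsoid, refined by
alternating (a) radial count-profile delineation of epicardial/endocardial
crossings around an adaptive per-profile threshold and (b) a least-squares
sphere refit to the mid-myocardial points, until the sphere coefficients
converge.  A dense delineation pass then builds a fifth-degree polynomial
mid-myocardial surface, the valve plane is carried over from the LV, and
myocardium/cavity masks are produced by dilating/enclosing that surface.

All count thresholds are fractions of the maximum LV count, so every output
is invariant to scaling the raw counts; there is no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import (
    DegenerateFitError,
    Plane,
    ProfileSet,
    RadialProfile,
    ScalarVolume,
    SphereModel,
    extract_radial_profiles,
    fit_sphere_least_squares,
    local_maxima_1d,
)
from .lv import LVResult

C_MAX = 0.5  # 50% of the maximum LV count, on the LV-max-normalized scale
VALIDITY_FLOOR = 0.25  # local maxima must exceed one quarter of the LV max


class RVNotDetectableError(RuntimeError):
    """Too few usable mid-myocardial points: prompt re-initialization."""


@dataclass
class ProfileDelineation:
    """Delineation of one radial profile (radii in mm from the sphere center)."""

    profile_ref: tuple[int, int]
    c_profile: float
    valid: bool
    epicardial_r: float = np.nan
    endocardial_r: float = np.nan
    mid_r: float = np.nan
    far_off_epi: bool = False
    far_off_endo: bool = False


def eq5_threshold(c_profile: float, c_max: float = C_MAX) -> float:
    """Adaptive delineation threshold from the accepted profile maximum.

    ``threshold = 0.8 * c_profile / (1 - 0.4 * (c_max - c_profile))`` with all
    counts normalized to the LV maximum.  The threshold is always below
    ``c_profile`` for valid inputs, so the above-threshold run containing the
    chosen maximum is never empty.
    """
    if not (0.0 < c_profile <= 1.0):
        raise ValueError("c_profile must lie in (0, 1] on the LV-normalized scale")
    denom = 1.0 - 0.4 * (c_max - c_profile)
    if denom <= 0:
        raise ValueError("threshold denominator is non-positive")
    return 0.8 * c_profile / denom


def init_rv_sphere(
    lv: LVResult,
    center_override: Optional[Sequence[float]] = None,
    radius_override: Optional[float] = None,
) -> SphereModel:
    """Initial RV sphere from the LV ellipsoid.

    The center is the LV center shifted by the smallest LV radius toward the
    patient's right (-X) and one fifth of the longest radius toward the apex
    (-Z); the radius is 1.5x the smallest LV radius.  Both may be overridden
    by the user in case of model misplacement (the semiautomatic contract).
    """
    r_min, r_max = lv.model.semi_axes[0], lv.model.semi_axes[2]
    center = lv.model.center_arr + np.array([-r_min, 0.0, -0.2 * r_max])
    radius = 1.5 * r_min
    if center_override is not None:
        center = np.asarray(center_override, dtype=float)
    if radius_override is not None:
        radius = float(radius_override)
    return SphereModel(center=tuple(center), radius=radius)


# ---------------------------------------------------------------------------
# Profile validity and delineation
# ---------------------------------------------------------------------------


def select_valid_profile(
    profile: RadialProfile, sphere: SphereModel, voxel: float
) -> tuple[bool, float, float]:
    """Check the two validity conditions on one profile.

    Finds the local maxima; accepts the one nearest the sphere surface whose
    distance to the surface is <= one voxel and whose (LV-normalized) value
    exceeds one quarter.  Returns ``(valid, c_profile, peak_radius_mm)``.
    """
    radii = profile.radii
    cand = local_maxima_1d(profile.samples)
    if len(cand) == 0:
        return False, 0.0, np.nan
    vals = profile.samples[cand]
    dist = np.abs(radii[cand] - sphere.radius)
    ok = (vals > VALIDITY_FLOOR) & (dist <= voxel)
    if not ok.any():
        return False, 0.0, np.nan
    k = cand[ok][int(np.argmin(dist[ok]))]
    return True, float(profile.samples[k]), float(radii[k])


def delineate_profile(
    profile: RadialProfile,
    c_profile: float,
    sphere: SphereModel,
    voxel: float,
    c_max: float = C_MAX,
    peak_radius: float | None = None,
) -> ProfileDelineation:
    """Delineate epicardial/endocardial crossings around the chosen maximum.

    The contiguous above-threshold run containing the accepted maximum is the
    per-profile myocardium; its outer/inner crossings (sub-sample linear
    interpolation) are the epicardial/endocardial points, their midpoint the
    mid-myocardial point.  Points more than two voxels from the sphere
    surface are flagged far-off and do not contribute to refitting.
    """
    if peak_radius is None:
        valid, c_profile, peak_radius = select_valid_profile(profile, sphere, voxel)
        if not valid:
            return ProfileDelineation(profile.angular_index, c_profile, False)
    thr = eq5_threshold(c_profile, c_max)
    s, radii = profile.samples, profile.radii
    pk = int(round(peak_radius / profile.step))
    if s[pk] <= thr:
        return ProfileDelineation(profile.angular_index, c_profile, False)
    endo_r, epi_r = _run_crossings(s, radii, pk, thr)
    mid_r = 0.5 * (endo_r + epi_r)
    return ProfileDelineation(
        profile_ref=profile.angular_index,
        c_profile=c_profile,
        valid=True,
        epicardial_r=epi_r,
        endocardial_r=endo_r,
        mid_r=mid_r,
        far_off_epi=abs(epi_r - sphere.radius) > 2.0 * voxel,
        far_off_endo=abs(endo_r - sphere.radius) > 2.0 * voxel,
    )


def _run_crossings(
    s: np.ndarray, radii: np.ndarray, peak: int, thr: float
) -> tuple[float, float]:
    """Sub-sample inner/outer threshold crossings of the run containing peak."""
    i = peak
    while i > 0 and s[i - 1] > thr:
        i -= 1
    if i == 0:
        lo = radii[0]
    else:
        f = (s[i] - thr) / (s[i] - s[i - 1])
        lo = radii[i] - f * (radii[i] - radii[i - 1])
    j, n = peak, len(s)
    while j < n - 1 and s[j + 1] > thr:
        j += 1
    if j == n - 1:
        hi = radii[n - 1]
    else:
        f = (s[j] - thr) / (s[j] - s[j + 1])
        hi = radii[j] + f * (radii[j + 1] - radii[j])
    return float(lo), float(hi)


@dataclass
class DelineationSet:
    """Vectorized delineation of a whole profile set."""

    profiles: ProfileSet
    sphere: SphereModel
    c_profile: np.ndarray  # (N,)
    peak_r: np.ndarray
    valid: np.ndarray
    epi_r: np.ndarray
    endo_r: np.ndarray
    mid_r: np.ndarray
    far_off_epi: np.ndarray
    far_off_endo: np.ndarray
    replaced: np.ndarray | None = None  # set by the refinement stage

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def usable_mid_points(
        self, valve: Plane | None = None, valve_margin_mm: float = 0.0
    ) -> np.ndarray:
        """Mid points whose parents are valid and not far-off, as (n,3) mm.

        When a valve plane is given, profiles whose epicardial point lies
        within ``valve_margin_mm`` of it (or basal of it) are dropped as
        well: the wall is truncated by the valve, so delineations that close
        to the plane are partial-volume corrupted.
        """
        ok = self.valid & ~self.far_off_epi & ~self.far_off_endo
        pts = self.profiles.origin + self.mid_r[:, None] * self.profiles.directions
        if valve is not None:
            epi_pts = self.profiles.origin + self.epi_r[:, None] * self.profiles.directions
            ok = ok & (valve.signed_distance(epi_pts) <= -valve_margin_mm)
        return pts[ok]

    def __iter__(self):
        for k in range(len(self.profiles)):
            i, j = divmod(k, self.profiles.n_lat)
            yield ProfileDelineation(
                (i, j),
                float(self.c_profile[k]),
                bool(self.valid[k]),
                float(self.epi_r[k]),
                float(self.endo_r[k]),
                float(self.mid_r[k]),
                bool(self.far_off_epi[k]),
                bool(self.far_off_endo[k]),
            )


def _local_max_mask(samples: np.ndarray) -> np.ndarray:
    """Vectorized local-maxima mask per row (plateaus count once via >=/>)."""
    pad = np.full((samples.shape[0], 1), -np.inf)
    prev = np.concatenate([pad, samples[:, :-1]], axis=1)
    nxt = np.concatenate([samples[:, 1:], pad], axis=1)
    m = (samples >= prev) & (samples >= nxt) & ((samples > prev) | (samples > nxt))
    return m & (samples > 0)


def delineate_set(
    profiles: ProfileSet, sphere: SphereModel, voxel: float, c_max: float = C_MAX
) -> DelineationSet:
    """Validity selection + delineation for every profile in the set."""
    N = len(profiles)
    radii = profiles.radii
    s = profiles.samples
    maxmask = _local_max_mask(s)
    dist = np.broadcast_to(np.abs(radii - sphere.radius), s.shape)
    ok = maxmask & (s > VALIDITY_FLOOR) & (dist <= voxel)
    dist_masked = np.where(ok, dist, np.inf)
    peak_idx = np.argmin(dist_masked, axis=1)
    valid = np.isfinite(dist_masked[np.arange(N), peak_idx])
    c_profile = np.where(valid, s[np.arange(N), peak_idx], 0.0)
    peak_r = np.where(valid, radii[peak_idx], np.nan)

    epi = np.full(N, np.nan)
    endo = np.full(N, np.nan)
    for k in np.nonzero(valid)[0]:
        thr = eq5_threshold(c_profile[k], c_max)
        endo[k], epi[k] = _run_crossings(s[k], radii, int(peak_idx[k]), thr)
    mid = 0.5 * (endo + epi)
    fo_epi = valid & (np.abs(epi - sphere.radius) > 2.0 * voxel)
    fo_endo = valid & (np.abs(endo - sphere.radius) > 2.0 * voxel)
    return DelineationSet(
        profiles=profiles,
        sphere=sphere,
        c_profile=c_profile,
        peak_r=peak_r,
        valid=valid,
        epi_r=epi,
        endo_r=endo,
        mid_r=mid,
        far_off_epi=fo_epi,
        far_off_endo=fo_endo,
    )


# ---------------------------------------------------------------------------
# Iterative model fitting
# ---------------------------------------------------------------------------


def normalized_excluded_volume(vol: ScalarVolume, lv: LVResult) -> ScalarVolume:
    """Counts normalized to the LV maximum, with the LV zeroed out.

    The LV is removed by zeroing voxels inside its epicardial surface dilated
    by one voxel, which prevents septal counts from bleeding into RV profiles.
    """
    data = vol.data / lv.max_count
    excl = lv.exclusion_mask(vol, dilate_mm=min(vol.spacing))
    data = np.where(excl, 0.0, data)
    return vol.with_data(data)


def auto_adjust_sphere(
    work: ScalarVolume,
    init: SphereModel,
    radius_multipliers: np.ndarray | None = None,
    n_long: int = 48,
    n_lat: int = 96,
) -> SphereModel:
    """Automated stand-in for the operator's manual model adjustment.

    A dilated RV can put the whole wall more than one voxel away from the
    suggested sphere surface, in which case no profile passes the validity
    conditions and an operator would drag the model.  This scans a range of
    radii about the suggested one and keeps the radius that maximizes the
    number of valid profiles; the suggested radius is kept whenever it is
    within half of the best count.  Deterministic.
    """
    if radius_multipliers is None:
        radius_multipliers = np.round(np.arange(0.7, 2.21, 0.1), 2)
    voxel = min(work.spacing)
    r_cands = radius_multipliers * init.radius
    profiles = extract_radial_profiles(
        work,
        np.clip(init.center_arr, 0, work.extent_mm()),
        n_long,
        n_lat,
        step=0.5 * voxel,
        max_radius=float(r_cands.max()) + 4.0 * voxel,
    )
    m = _local_max_mask(profiles.samples) & (profiles.samples > VALIDITY_FLOOR)
    radii = profiles.radii
    counts = np.array(
        [int((m & (np.abs(radii - r) <= voxel)[None, :]).any(axis=1).sum()) for r in r_cands]
    )
    default = int(np.argmin(np.abs(radius_multipliers - 1.0)))
    if counts.max() == 0:
        return init
    if counts[default] >= 0.5 * counts.max():
        return init
    best = int(np.argmax(counts))
    return SphereModel(center=init.center, radius=float(r_cands[best]))


def fit_rv_model(
    vol: ScalarVolume,
    init: SphereModel,
    lv: LVResult,
    n_long: int = 48,
    n_lat: int = 96,
    max_iter: int = 50,
    tol_mm: float = 0.1,
    _norm_vol: ScalarVolume | None = None,
) -> tuple[SphereModel, int]:
    """Iterate profile delineation and sphere refits until convergence.

    Uses 48x96 radial profiles per iteration; the sphere is refit to the
    non-far-off mid-myocardial points; stops when center and radius both move
    less than ``tol_mm`` (or at ``max_iter``).  Deterministic.
    """
    work = _norm_vol if _norm_vol is not None else normalized_excluded_volume(vol, lv)
    voxel = min(vol.spacing)
    valve = rv_valve_plane(lv)
    sphere = init
    iterations = 0
    best = (-1, None)  # (usable points, sphere): stablest iterate of a limit cycle
    for iterations in range(1, max_iter + 1):
        profiles = extract_radial_profiles(
            work,
            np.clip(sphere.center_arr, 0, work.extent_mm()),
            n_long,
            n_lat,
            step=0.5 * voxel,
            max_radius=sphere.radius + 4.0 * voxel,
        )
        delin = delineate_set(profiles, sphere, voxel)
        pts = delin.usable_mid_points(valve, valve_margin_mm=voxel)
        if len(pts) < 4:
            raise RVNotDetectableError(
                "fewer than 4 usable mid-myocardial points; re-initialize the sphere"
            )
        try:
            new = fit_sphere_least_squares(pts)
        except DegenerateFitError as exc:
            raise RVNotDetectableError(str(exc)) from exc
        # plausibility gate: a fit wandering far from the (operator-accepted)
        # initial model is noise-driven and would be rejected on screen
        if not (0.3 * init.radius <= new.radius <= 2.5 * init.radius) or (
            np.linalg.norm(new.center_arr - init.center_arr) > 6.0 * voxel
        ):
            raise RVNotDetectableError(
                "sphere fit diverged from the initial model; re-initialize"
            )
        if len(pts) >= best[0]:
            best = (len(pts), new)
        dc = np.linalg.norm(new.center_arr - sphere.center_arr)
        dr = abs(new.radius - sphere.radius)
        sphere = new
        if dc < tol_mm and dr < tol_mm:
            return sphere, iterations
    # no strict convergence: the point sets cycle discretely; return the
    # iterate supported by the most delineated points
    return best[1], iterations


def refine_surfaces(
    vol: ScalarVolume,
    final: SphereModel,
    lv: LVResult,
    wall_mm: float = 12.8,
    n_long: int = 120,
    n_lat: int = 320,
    _norm_vol: ScalarVolume | None = None,
) -> tuple[DelineationSet, SphereModel]:
    """Dense 120x320 delineation from the converged model.

    A refreshed sphere is fitted to the dense mid points; epicardial and
    endocardial points of profiles failing the local-maxima criterion (and
    far-off points) are replaced by the corresponding points on that sphere
    (radius +/- half the nominal wall thickness).
    """
    work = _norm_vol if _norm_vol is not None else normalized_excluded_volume(vol, lv)
    voxel = min(vol.spacing)
    profiles = extract_radial_profiles(
        work,
        np.clip(final.center_arr, 0, work.extent_mm()),
        n_long,
        n_lat,
        step=0.5 * voxel,
        max_radius=final.radius + 4.0 * voxel,
    )
    delin = delineate_set(profiles, final, voxel)
    pts = delin.usable_mid_points(rv_valve_plane(lv), valve_margin_mm=voxel)
    if len(pts) >= 4:
        try:
            refreshed = fit_sphere_least_squares(pts)
        except DegenerateFitError:
            refreshed = final
    else:
        refreshed = final
    replaced = ~delin.valid
    delin.epi_r = np.where(
        delin.valid & ~delin.far_off_epi, delin.epi_r, refreshed.radius + wall_mm / 2.0
    )
    delin.endo_r = np.where(
        delin.valid & ~delin.far_off_endo, delin.endo_r, refreshed.radius - wall_mm / 2.0
    )
    delin.mid_r = 0.5 * (delin.epi_r + delin.endo_r)
    delin.replaced = replaced
    delin.sphere = refreshed
    return delin, refreshed


# ---------------------------------------------------------------------------
# Valve plane, mid-surface and masks
# ---------------------------------------------------------------------------


def rv_valve_plane(lv: LVResult) -> Plane:
    """RV valve plane carried over from the LV valve plane.

    It is parallel to the X axis in the horizontal long-axis view (its normal
    has no X component), shares the LV valve plane's tilt in the vertical
    long-axis view, and passes through the line where it meets the LV
    epicardial surface on the septal (-X) side.
    """
    n_lv = np.asarray(lv.valve_plane.normal)
    n_rv = np.array([0.0, n_lv[1], n_lv[2]])
    if np.linalg.norm(n_rv) < 1e-9:
        n_rv = np.array([0.0, 0.0, 1.0])
    n_rv /= np.linalg.norm(n_rv)
    p0 = np.asarray(lv.valve_plane.point)
    # walk within the LV valve plane toward -X until the epicardial surface
    d = np.array([-1.0, 0.0, 0.0]) - (np.array([-1.0, 0.0, 0.0]) @ n_lv) * n_lv
    d /= np.linalg.norm(d)
    t_lo, t_hi = 0.0, 150.0
    for _ in range(60):
        t = 0.5 * (t_lo + t_hi)
        q = p0 + t * d
        rel = q - lv.model.center_arr
        if np.linalg.norm(rel) <= lv.epi_radius_at(q[None, :])[0]:
            t_lo = t
        else:
            t_hi = t
    q = p0 + 0.5 * (t_lo + t_hi) * d
    return Plane(point=tuple(q), normal=tuple(n_rv))


_POLY_EXPONENTS = [(i, j) for i in range(6) for j in range(6 - i)]


@dataclass
class MidSurface:
    """Fifth-degree bivariate polynomial mid-myocardial surface.

    Radius as a function of the sphere's angular coordinates,
    ``r(theta, phi)``, with the azimuth unwrapped about the RV free-wall
    center so the domain is a simple rectangle.  Outside the fitted angular
    domain the refreshed sphere radius applies (the model-replaced septal
    side); the surface is clipped at the valve plane when masks are built.
    """

    center: np.ndarray
    coeffs: np.ndarray
    phi0: float  # free-wall center azimuth
    theta_range: tuple[float, float]
    phi_range: tuple[float, float]  # in unwrapped coordinates about phi0
    sphere_radius: float
    rms_residual: float

    def _design(self, t: np.ndarray, p: np.ndarray) -> np.ndarray:
        t0, t1 = self.theta_range
        p0, p1 = self.phi_range
        tn = (2 * t - (t0 + t1)) / max(t1 - t0, 1e-6)
        pn = (2 * p - (p0 + p1)) / max(p1 - p0, 1e-6)
        return np.stack([tn**i * pn**j for i, j in _POLY_EXPONENTS], axis=-1)

    def unwrap_phi(self, phi: np.ndarray) -> np.ndarray:
        return self.phi0 + np.angle(np.exp(1j * (np.asarray(phi) - self.phi0)))

    def in_domain(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Angular support of the RV free wall: the fitted azimuth span.

        The polar direction is not restricted: where the fit had no data
        (e.g. a perfusion defect or the apical pole) the replaced points on
        the refreshed sphere stand in, and the valve plane delimits the base.
        """
        pu = self.unwrap_phi(phi)
        p0, p1 = self.phi_range
        return np.broadcast_to((pu >= p0) & (pu <= p1), np.broadcast_shapes(
            np.shape(theta), np.shape(pu)
        ))

    def evaluate(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Mid-surface radius (mm).

        The polynomial applies over the fitted angular rectangle; elsewhere
        (model-replaced regions and outside the free wall) the refreshed
        sphere radius applies.
        """
        theta = np.asarray(theta, dtype=float)
        pu = self.unwrap_phi(phi)
        r = np.full(np.broadcast_shapes(theta.shape, pu.shape), self.sphere_radius)
        theta, pu = np.broadcast_arrays(theta, pu)
        t0, t1 = self.theta_range
        p0, p1 = self.phi_range
        fit = (theta >= t0) & (theta <= t1) & (pu >= p0) & (pu <= p1)
        if fit.any():
            r[fit] = self._design(theta[fit], pu[fit]) @ self.coeffs
        return r

    def mesh(self, n_theta: int = 60, n_phi: int = 120, offset: float = 0.0):
        """(vertices, faces) of the surface over its domain, radius + offset."""
        t = np.linspace(*self.theta_range, n_theta)
        p = np.linspace(*self.phi_range, n_phi)
        T, P = np.meshgrid(t, p, indexing="ij")
        r = self._design(T.ravel(), P.ravel()) @ self.coeffs + offset
        verts = self.center + np.stack(
            [
                r * np.sin(T.ravel()) * np.cos(P.ravel()),
                r * np.sin(T.ravel()) * np.sin(P.ravel()),
                r * np.cos(T.ravel()),
            ],
            axis=1,
        )
        idx = np.arange(n_theta * n_phi).reshape(n_theta, n_phi)
        quads = np.stack(
            [idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1
        ).reshape(-1, 4)
        faces = np.concatenate([quads[:, [0, 1, 2]], quads[:, [0, 2, 3]]], axis=0)
        return verts, faces


def build_mid_surface(
    dense: DelineationSet,
    valve: Plane,
    lv: LVResult | None = None,
    damping: float = 1e-8,
    valve_margin_mm: float = 0.0,
) -> MidSurface:
    """Fit the degree-5 polynomial surface to the dense mid points.

    Only measured (non-replaced, non-far-off) mid points apical of the valve
    plane enter the fit, by damped least squares.  Boundary condition: at the
    septal junction (the azimuthal edges of the free-wall domain) the surface
    is tied to the LV epicardial surface with high-weight constraint points.
    """
    sphere = dense.sphere
    prof = dense.profiles
    measured = dense.valid & ~dense.far_off_epi & ~dense.far_off_endo
    if dense.replaced is not None:
        measured &= ~dense.replaced
    epi_pts = prof.origin + dense.epi_r[:, None] * prof.directions
    measured &= valve.signed_distance(epi_pts) <= -valve_margin_mm
    n_pts = int(measured.sum())
    if n_pts < len(_POLY_EXPONENTS):
        raise DegenerateFitError(
            f"mid-surface fit needs >= {len(_POLY_EXPONENTS)} points, got {n_pts}"
        )
    theta = prof.thetas[measured]
    phi = prof.phis[measured]
    r = dense.mid_r[measured]

    # unwrap azimuth about the free-wall center; the azimuthal span of the
    # free wall is measured away from the poles, where azimuth degenerates
    phi0 = float(np.angle(np.mean(np.exp(1j * phi))))
    pu = phi0 + np.angle(np.exp(1j * (phi - phi0)))
    dt = np.pi / prof.n_long
    dp = 2 * np.pi / prof.n_lat
    theta_range = (float(theta.min() - dt), float(theta.max() + dt))
    mid_lat = np.sin(theta) >= 0.3
    pu_span = pu[mid_lat] if mid_lat.any() else pu
    phi_range = (float(pu_span.min() - dp), float(pu_span.max() + dp))

    t_fit = [theta]
    p_fit = [pu]
    r_fit = [r]
    w_fit = [np.ones_like(r)]
    if lv is not None:
        tc, pc, rc = _junction_constraints(sphere, lv, theta_range, phi_range, phi0)
        if len(tc):
            t_fit.append(tc)
            p_fit.append(pc)
            r_fit.append(rc)
            w_fit.append(np.full_like(rc, 100.0))
    t_all = np.concatenate(t_fit)
    p_all = np.concatenate(p_fit)
    r_all = np.concatenate(r_fit)
    w_all = np.concatenate(w_fit)

    surf = MidSurface(
        center=prof.origin.copy(),
        coeffs=np.zeros(len(_POLY_EXPONENTS)),
        phi0=phi0,
        theta_range=theta_range,
        phi_range=phi_range,
        sphere_radius=sphere.radius,
        rms_residual=np.nan,
    )
    A = surf._design(t_all, p_all)
    W = w_all[:, None]
    ATA = (A * W).T @ A
    lam = damping * np.trace(ATA) / len(ATA)
    coeffs = np.linalg.solve(ATA + lam * np.eye(len(ATA)), (A * W).T @ r_all)
    surf.coeffs = coeffs
    resid = surf._design(theta, pu) @ coeffs - r
    surf.rms_residual = float(np.sqrt(np.mean(resid**2)))
    return surf


def _junction_constraints(
    sphere: SphereModel,
    lv: LVResult,
    theta_range: tuple[float, float],
    phi_range: tuple[float, float],
    phi0: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constraint points tying the surface edges to the LV epicardium.

    At each azimuthal edge of the free-wall domain, for a fan of polar
    angles, the target radius is the distance from the sphere center to the
    LV epicardial surface along that direction when the ray meets it at a
    plausible range, else the refreshed sphere radius.
    """
    thetas = np.linspace(theta_range[0], theta_range[1], 12)
    out_t, out_p, out_r = [], [], []
    # a junction radius is plausible only near the sphere surface; rays that
    # miss the LV (or hit it far from the wall) fall back to the sphere
    ts = np.linspace(0.6 * sphere.radius, 1.5 * sphere.radius, 40)
    for p_edge in phi_range:
        d = np.stack(
            [np.sin(thetas) * np.cos(p_edge), np.sin(thetas) * np.sin(p_edge), np.cos(thetas)],
            axis=1,
        )
        r_target = np.full(len(thetas), sphere.radius)
        pts = sphere.center_arr[None, None, :] + d[:, None, :] * ts[None, :, None]
        flat = pts.reshape(-1, 3)
        rel = np.linalg.norm(flat - lv.model.center_arr, axis=1)
        inside = (rel <= lv.epi_radius_at(flat)) & (
            lv.valve_plane.signed_distance(flat) <= 0
        )
        inside = inside.reshape(len(thetas), len(ts))
        for k in range(len(thetas)):
            hit = np.nonzero(inside[k])[0]
            if len(hit):
                r_target[k] = ts[hit[0]]
        out_t.append(thetas)
        out_p.append(np.full(len(thetas), p_edge))
        out_r.append(r_target)
    return np.concatenate(out_t), np.concatenate(out_p), np.concatenate(out_r)


@dataclass
class RVSegmentationResult:
    """Final RV model, surfaces, masks and cavity volume."""

    model: SphereModel
    mid_surface: MidSurface
    valve_plane: Plane
    mask_myocardium: np.ndarray
    mask_cavity: np.ndarray
    cavity_volume_ml: float
    n_valid_profiles: int
    iterations: int
    wall_mm: float
    delineation: DelineationSet | None = None


def build_masks(
    surface: MidSurface,
    valve: Plane,
    vol: ScalarVolume,
    lv: LVResult | None = None,
    wall_mm: float = 12.8,
) -> RVSegmentationResult:
    """Myocardium and cavity masks from the mid surface and valve plane.

    Myocardium: voxels within half the nominal wall of the mid surface
    (inside its angular domain), apical of the valve plane, excluding the LV.
    Cavity: voxels strictly inside the endocardial surface (mid - wall/2;
    the refreshed-sphere radius closes the septal side), apical of the valve
    plane and outside the LV epicardium, which bounds the cavity at the
    septum.  The volume is the voxel count times the voxel volume.
    """
    X, Y, Z = vol.voxel_centers_mm()
    pts = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1).reshape(-1, 3)
    rel = pts - surface.center
    r = np.linalg.norm(rel, axis=1)
    r_safe = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(rel[:, 2] / r_safe, -1, 1))
    phi = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    r_mid = surface.evaluate(theta, phi)
    dom = surface.in_domain(theta, phi)
    apical = valve.signed_distance(pts) <= 0

    myo = dom & apical & (np.abs(r - r_mid) <= wall_mm / 2.0)
    cavity = apical & (r < r_mid - wall_mm / 2.0)
    if lv is not None:
        in_lv_epi = lv.inside_epicardium(pts)
        myo &= ~in_lv_epi
        myo &= ~lv.mask_myocardium.reshape(-1)
        cavity &= ~in_lv_epi
    myo = myo.reshape(vol.shape)
    cavity = cavity.reshape(vol.shape)
    return RVSegmentationResult(
        model=SphereModel(center=tuple(surface.center), radius=surface.sphere_radius),
        mid_surface=surface,
        valve_plane=valve,
        mask_myocardium=myo,
        mask_cavity=cavity,
        cavity_volume_ml=float(cavity.sum()) * vol.voxel_volume_ml,
        n_valid_profiles=0,
        iterations=0,
        wall_mm=wall_mm,
    )


def segment_rv(
    vol: ScalarVolume,
    lv: LVResult,
    center_override: Optional[Sequence[float]] = None,
    radius_override: Optional[float] = None,
    wall_mm: float = 12.8,
    fallback_to_init: bool = False,
    auto_adjust: bool = True,
) -> RVSegmentationResult:
    """Full RV segmentation given a segmented LV.

    With ``fallback_to_init`` the initial sphere stands in for the fitted
    model when too few profiles are usable (very faint RV), mimicking an
    operator accepting the suggested model; otherwise
    :class:`RVNotDetectableError` propagates.
    """
    work = normalized_excluded_volume(vol, lv)
    init = init_rv_sphere(lv, center_override, radius_override)
    if auto_adjust and radius_override is None:
        init = auto_adjust_sphere(work, init)
    valve = rv_valve_plane(lv)
    dense = None
    try:
        sphere, iterations = fit_rv_model(vol, init, lv, _norm_vol=work)
        dense, refreshed = refine_surfaces(vol, sphere, lv, wall_mm=wall_mm, _norm_vol=work)
        try:
            surface = build_mid_surface(
                dense, valve, lv, valve_margin_mm=min(vol.spacing)
            )
        except DegenerateFitError:
            surface = _sphere_cap_surface(refreshed)
    except RVNotDetectableError:
        if not fallback_to_init:
            raise
        # operator-accepted model: the segmentation is the initial sphere
        # itself, which keeps repeated acquisitions of a sub-threshold RV
        # consistent with each other
        sphere, iterations = init, 0
        surface = _sphere_cap_surface(init)
    result = build_masks(surface, valve, vol, lv, wall_mm=wall_mm)
    result.n_valid_profiles = dense.n_valid if dense is not None else 0
    result.iterations = iterations
    result.delineation = dense
    return result


def _sphere_cap_surface(sphere: SphereModel) -> MidSurface:
    """Spherical fallback surface over the free-wall wedge (operator accept)."""
    coeffs = np.zeros(len(_POLY_EXPONENTS))
    coeffs[0] = sphere.radius
    return MidSurface(
        center=sphere.center_arr.copy(),
        coeffs=coeffs,
        phi0=np.pi,
        theta_range=(0.0, np.pi),
        phi_range=(np.pi - np.deg2rad(75), np.pi + np.deg2rad(75)),
        sphere_radius=sphere.radius,
        rms_residual=np.nan,
    )
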