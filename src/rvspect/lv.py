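"""Left-ventricle segmentation by thresholding and iterative ellipsoid fitting.

The LV is segmented first because it anchors everything downstream: the RV
sphere is initialized from the LV ellipsoid, every count threshold in the RV
stage is expressed as a fraction of the maximum LV count, and the RV valve
plane is derived from the LV valve plane.

Pipeline: optional prior-angle reorientation -> 50%-threshold cluster
selection in the upper-right search region (the bounding box can be
overridden by the user: the semiautomatic contract) -> intra-patient
threshold from 10x10 averaged radial profiles -> iterative ellipsoid fit to
per-profile myocardial points -> long-axis realignment -> valve-plane
placement from the mid-myocardial count distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import (
    DegenerateFitError,
    EllipsoidModel,
    Plane,
    ProfileSet,
    ScalarVolume,
    extract_radial_profiles,
    fit_ellipsoid_least_squares,
    local_maxima_1d,
    rotation_between,
)


class NoLVCandidateError(RuntimeError):
    """No cluster in the expected LV size window: ask for a manual box."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel-index box, lo inclusive / hi exclusive."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(h <= l for l, h in zip(self.lo, self.hi)):
            raise ValueError("bounding box must be non-empty")

    def center_mm(self, spacing: tuple[float, float, float]) -> np.ndarray:
        return (np.array(self.lo) + np.array(self.hi) - 1) / 2.0 * np.array(spacing)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    def expanded(self, pad: int, shape: tuple[int, int, int]) -> "BoundingBox":
        lo = tuple(max(0, l - pad) for l in self.lo)
        hi = tuple(min(n, h + pad) for h, n in zip(self.hi, shape))
        return BoundingBox(lo, hi)


@dataclass
class LVResult:
    """Final LV model, surfaces, valve plane and the global count normalizer."""

    model: EllipsoidModel
    mask_myocardium: np.ndarray
    valve_plane: Plane
    max_count: float
    intra_patient_threshold: float
    # dense per-profile delineation on the (theta, phi) grid
    n_long: int
    n_lat: int
    epi_r: np.ndarray  # (n_long, n_lat) mm from model center
    endo_r: np.ndarray
    mid_r: np.ndarray
    valid: np.ndarray
    wall_mm: float  # median delineated wall thickness
    iterations: int = 0
    residual_history: list = None  # summed squared point-to-model residual per iteration

    def _angle_bins(self, points_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rel = np.atleast_2d(points_mm) - self.model.center_arr
        r = np.linalg.norm(rel, axis=1)
        r_safe = np.where(r == 0, 1.0, r)
        theta = np.arccos(np.clip(rel[:, 2] / r_safe, -1, 1))
        phi = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        i = np.clip((theta / np.pi * self.n_long).astype(int), 0, self.n_long - 1)
        j = np.clip((phi / (2 * np.pi) * self.n_lat).astype(int), 0, self.n_lat - 1)
        return r, i, j

    def epi_radius_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Delineated epicardial radius along the direction of each point."""
        _, i, j = self._angle_bins(points_mm)
        return self.epi_r[i, j]

    def inside_epicardium(self, points_mm: np.ndarray, dilate_mm: float = 0.0) -> np.ndarray:
        r, i, j = self._angle_bins(points_mm)
        return r <= self.epi_r[i, j] + dilate_mm

    def exclusion_mask(self, vol: ScalarVolume, dilate_mm: float) -> np.ndarray:
        """Voxels inside the epicardial surface dilated by ``dilate_mm``."""
        X, Y, Z = vol.voxel_centers_mm()
        pts = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1).reshape(-1, 3)
        return self.inside_epicardium(pts, dilate_mm).reshape(vol.shape)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def prereorient(vol: ScalarVolume, prior_angle_deg: float) -> ScalarVolume:
    """Rotate about the Y axis by a predefined prior angle (trilinear).

    Approximates the short-axis view before any model exists; 0 degrees is
    the identity (synthetic data is generated already short-axis).
    """
    if prior_angle_deg == 0:
        return vol
    return _rotate_volume(vol, _rot_y(np.deg2rad(prior_angle_deg)))


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rotate_volume(
    vol: ScalarVolume, R: np.ndarray, center_mm: np.ndarray | None = None
) -> ScalarVolume:
    """Resample the volume rotated by R (mm space) about ``center_mm``."""
    sp = np.array(vol.spacing)
    if center_mm is None:
        center_mm = vol.extent_mm() / 2.0
    c_vox = center_mm / sp
    # output voxel o maps to input voxel S^-1 R^T S (o - c) + c
    M = np.diag(1.0 / sp) @ R.T @ np.diag(sp)
    offset = c_vox - M @ c_vox
    data = ndimage.affine_transform(vol.data, M, offset=offset, order=1, cval=0.0)
    return vol.with_data(np.clip(data, 0.0, None))


DEFAULT_REGION = (0.5, 0.5)  # x >= fx * extent, y <= fy * extent
SIZE_WINDOW_ML = (15.0, 400.0)


def initial_cluster(
    vol: ScalarVolume,
    region: tuple[float, float] = DEFAULT_REGION,
    size_window_ml: tuple[float, float] = SIZE_WINDOW_ML,
) -> tuple[np.ndarray, BoundingBox]:
    """Select the initial LV cluster and its bounding box.

    Binarizes at 50% of the maximum count inside the upper-right search
    region of the transversal slices (``x >= fx*extent`` and
    ``y <= fy*extent`` in array coordinates; orientation dialects vary, so
    the region is configurable), labels 26-connected components, and keeps
    the component whose centroid lies in the region, scored by LV-like size
    and centrality.  The returned box is a suggestion the caller may replace.
    """
    data = vol.data
    if data.max() <= data.min():
        raise NoLVCandidateError("volume is constant; no LV candidate")
    nx, ny, nz = vol.shape
    fx, fy = region
    region_mask = np.zeros(vol.shape, dtype=bool)
    x_lo = int(np.ceil(fx * (nx - 1)))
    y_hi = int(np.floor(fy * (ny - 1)))
    region_mask[x_lo:, : y_hi + 1, :] = True
    region_max = data[region_mask].max()
    if region_max <= 0:
        raise NoLVCandidateError("no counts in the LV search region")
    binary = (data >= 0.5 * region_max) & region_mask
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3)))
    if n == 0:
        raise NoLVCandidateError("no cluster above threshold")
    vox_ml = vol.voxel_volume_ml
    region_center = np.array(
        [(x_lo + nx - 1) / 2.0, y_hi / 2.0, (nz - 1) / 2.0]
    ) * np.array(vol.spacing)
    half_diag = np.linalg.norm(vol.extent_mm()) / 2.0
    best, best_score = None, -np.inf
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(binary, labels, index=np.arange(1, n + 1))
    for lab, size, cen in zip(range(1, n + 1), sizes, centroids):
        volume_ml = size * vox_ml
        if not (size_window_ml[0] <= volume_ml <= size_window_ml[1]):
            continue
        cen_vox = np.array(cen)
        if cen_vox[0] < x_lo or cen_vox[1] > y_hi:
            continue  # centroid outside the search region (e.g. hepatic blob)
        cen_mm = cen_vox * np.array(vol.spacing)
        centrality = 1.0 - np.linalg.norm(cen_mm - region_center) / half_diag
        score = 0.7 * centrality + 0.3 * min(volume_ml / 150.0, 1.0)
        if score > best_score:
            best, best_score = lab, score
    if best is None:
        raise NoLVCandidateError(
            "no cluster in the expected LV size window; supply a bounding box"
        )
    mask = labels == best
    idx = np.argwhere(mask)
    box = BoundingBox(tuple(idx.min(axis=0)), tuple(idx.max(axis=0) + 1))
    return mask, box


def intra_patient_threshold(vol: ScalarVolume, box: BoundingBox) -> float:
    """Maximum of the average of 10x10 radial count profiles from the box center."""
    for l, h, n in zip(box.lo, box.hi, vol.shape):
        if l < 0 or h > n:
            raise ValueError("bounding box lies outside the volume")
    center = box.center_mm(vol.spacing)
    if not vol.contains_point(center):
        raise ValueError("box center lies outside the volume")
    half_diag = float(
        np.linalg.norm((np.array(box.hi) - np.array(box.lo)) * np.array(vol.spacing)) / 2.0
    )
    profiles = extract_radial_profiles(
        vol, center, 10, 10, max_radius=max(half_diag, min(vol.spacing))
    )
    return float(profiles.samples.mean(axis=0).max())


def _best_profile_point(
    samples: np.ndarray,
    radii: np.ndarray,
    model_r: float,
    voxel: float,
    floor: float,
) -> float | None:
    """Radius of the myocardial point on one profile, or None.

    The global profile maximum wins when it lies within 2 voxels of the
    current model surface; otherwise the nearest local maximum within 3
    voxels is used.  Candidates below ``floor`` counts are ignored.
    """
    if samples.max() < floor:
        return None
    g = int(np.argmax(samples))
    if abs(radii[g] - model_r) <= 2.0 * voxel:
        return float(radii[g])
    cand = local_maxima_1d(samples)
    cand = cand[samples[cand] >= floor]
    if len(cand) == 0:
        return None
    dist = np.abs(radii[cand] - model_r)
    k = int(np.argmin(dist))
    if dist[k] > 3.0 * voxel:
        return None
    return float(radii[cand[k]])


def _delineate_lv_profiles(
    profiles: ProfileSet, model: EllipsoidModel, voxel: float, floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-profile epicardial/endocardial radii at 50% of the profile peak."""
    n = len(profiles)
    radii = profiles.radii
    model_r = model.radius_along(profiles.directions)
    epi = np.full(n, np.nan)
    endo = np.full(n, np.nan)
    mid = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for k in range(n):
        s = profiles.samples[k]
        r_pk = _best_profile_point(s, radii, model_r[k], voxel, floor)
        if r_pk is None:
            continue
        pk = int(round(r_pk / profiles.step))
        level = 0.5 * s[pk]
        lo, hi = _crossings_around(s, radii, pk, level)
        if lo is None:
            continue
        endo[k], epi[k] = lo, hi
        mid[k] = 0.5 * (lo + hi)
        valid[k] = True
    return epi, endo, mid, valid


def _crossings_around(
    samples: np.ndarray, radii: np.ndarray, peak: int, level: float
) -> tuple[float | None, float | None]:
    """Sub-sample inner/outer crossings of ``level`` around ``peak``."""
    if samples[peak] <= level:
        return None, None
    i = peak
    while i > 0 and samples[i - 1] > level:
        i -= 1
    if i == 0:
        lo = radii[0]
    else:
        f = (samples[i] - level) / (samples[i] - samples[i - 1])
        lo = radii[i] - f * (radii[i] - radii[i - 1])
    j = peak
    n = len(samples)
    while j < n - 1 and samples[j + 1] > level:
        j += 1
    if j == n - 1:
        hi = radii[n - 1]
    else:
        f = (samples[j] - level) / (samples[j] - samples[j + 1])
        hi = radii[j] + f * (radii[j + 1] - radii[j])
    return float(lo), float(hi)


def segment_lv(
    vol: ScalarVolume,
    box: BoundingBox | None = None,
    prior_angle_deg: float = 0.0,
    region: tuple[float, float] = DEFAULT_REGION,
    n_long: int = 32,
    n_lat: int = 64,
    max_iter: int = 50,
    tol_mm: float = 0.1,
) -> LVResult:
    """Segment the LV and return model, mask, valve plane and normalizer.

    The iterative loop alternates radial-profile point selection (the profile
    maximum nearest the current ellipsoid surface) and an algebraic ellipsoid
    refit until the center moves < ``tol_mm`` and every semi-axis changes
    < ``tol_mm``.  All count thresholds are relative, so the result is
    invariant to scaling the volume by any positive constant.
    """
    vol = prereorient(vol, prior_angle_deg)
    if box is None:
        _, box = initial_cluster(vol, region=region)
    thr = intra_patient_threshold(vol, box)
    voxel = min(vol.spacing)
    step = 0.5 * voxel

    # final LV cluster: intra-patient threshold inside the (padded) box
    work = np.zeros(vol.shape, dtype=bool)
    sl = box.expanded(2, vol.shape).slices()
    work[sl] = vol.data[sl] >= thr
    labels, n = ndimage.label(work, structure=np.ones((3, 3, 3)))
    if n == 0:
        raise NoLVCandidateError("no voxels above the intra-patient threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    cluster = labels == (1 + int(np.argmax(sizes)))
    pts = np.argwhere(cluster) * np.array(vol.spacing)
    model = fit_ellipsoid_least_squares(pts)

    floor = 0.5 * thr
    iterations = 0
    residual_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        max_radius = 1.6 * model.semi_axes[2] + 4 * voxel
        profiles = extract_radial_profiles(
            vol, model.center_arr, 24, 48, step=step, max_radius=max_radius
        )
        model_r = model.radius_along(profiles.directions)
        chosen = []
        for k in range(len(profiles)):
            r_pk = _best_profile_point(
                profiles.samples[k], profiles.radii, model_r[k], voxel, floor
            )
            if r_pk is not None:
                chosen.append(profiles.origin + r_pk * profiles.directions[k])
        if len(chosen) < 9:
            raise DegenerateFitError("too few myocardial points for the LV fit")
        new_model = fit_ellipsoid_least_squares(np.array(chosen))
        pts_arr = np.array(chosen)
        rel = pts_arr - new_model.center_arr
        dist = np.linalg.norm(rel, axis=1)
        dirs = rel / np.where(dist[:, None] == 0, 1.0, dist[:, None])
        residual_history.append(float(np.sum((dist - new_model.radius_along(dirs)) ** 2)))
        dc = np.linalg.norm(new_model.center_arr - model.center_arr)
        ds = np.max(np.abs(np.array(new_model.semi_axes) - np.array(model.semi_axes)))
        model = new_model
        if dc < tol_mm and ds < tol_mm:
            break
    else:
        warnings.warn("LV ellipsoid fit did not converge; using the last model")

    # realign the long axis with Z (apex toward -Z)
    u = model.long_axis
    b = model.semi_axes[2]
    probe = np.array([model.center_arr + b * u, model.center_arr - b * u])
    c_plus, c_minus = vol.sample(probe)
    u_apex = u if c_plus >= c_minus else -u
    R = rotation_between(u_apex, np.array([0.0, 0.0, -1.0]))
    angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
    if angle > 1.0:
        vol = _rotate_volume(vol, R, center_mm=model.center_arr)
        model = EllipsoidModel(
            center=model.center,
            semi_axes=model.semi_axes,
            orientation=R @ model.orientation,
        )
        u_apex = np.array([0.0, 0.0, -1.0])
    u_base = -u_apex

    # dense delineation of epi/endo/mid surfaces on the (theta, phi) grid
    max_radius = 1.6 * model.semi_axes[2] + 4 * voxel
    dense = extract_radial_profiles(
        vol, model.center_arr, n_long, n_lat, step=step, max_radius=max_radius
    )
    epi, endo, mid, valid = _delineate_lv_profiles(dense, model, voxel, floor)
    wall = float(np.nanmedian(epi - endo)) if valid.any() else 2 * voxel
    model_r = model.radius_along(dense.directions)
    offset = float(np.nanmedian(mid - model_r)) if valid.any() else 0.0
    fill = model_r + offset
    epi = np.where(valid, epi, fill + wall / 2.0).reshape(n_long, n_lat)
    endo = np.where(valid, endo, np.clip(fill - wall / 2.0, 0, None)).reshape(n_long, n_lat)
    mid = np.where(valid, mid, fill).reshape(n_long, n_lat)
    valid = valid.reshape(n_long, n_lat)

    valve, max_count = _valve_plane_and_max(vol, model, u_base)

    result = LVResult(
        model=model,
        mask_myocardium=np.zeros(vol.shape, dtype=bool),
        valve_plane=valve,
        max_count=max_count,
        intra_patient_threshold=thr,
        n_long=n_long,
        n_lat=n_lat,
        epi_r=epi,
        endo_r=endo,
        mid_r=mid,
        valid=valid,
        wall_mm=wall,
        iterations=iterations,
        residual_history=residual_history,
    )
    result.mask_myocardium = _myocardium_mask(vol, result)
    result.max_count = float(
        vol.data[result.mask_myocardium].max()
        if result.mask_myocardium.any()
        else max_count
    )
    return result


def _valve_plane_and_max(
    vol: ScalarVolume, model: EllipsoidModel, u_base: np.ndarray
) -> tuple[Plane, float]:
    """Valve plane from the mid-myocardial count distribution.

    Circumferential mean counts are sampled on the mid-surface ellipse of
    each plane along the long axis; the plateau is the median over the middle
    third, and the valve sits at the first basal plane falling below 50% of
    the plateau (sub-plane interpolation).
    """
    a1, a2, b = model.semi_axes[0], model.semi_axes[1], model.semi_axes[2]
    e1 = model.orientation[:, 0]
    e2 = model.orientation[:, 1]
    zeta = np.arange(-0.95, 1.151, 0.02)
    psi = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    ring = np.sqrt(np.clip(1 - zeta**2, 0, None))
    pts = (
        model.center_arr[None, None, :]
        + (zeta[:, None] * b)[..., None] * u_base[None, None, :]
        + ring[:, None, None]
        * (
            np.outer(np.cos(psi), a1 * e1)[None, :, :]
            + np.outer(np.sin(psi), a2 * e2)[None, :, :]
        )
    )
    means = vol.sample(pts.reshape(-1, 3)).reshape(len(zeta), len(psi)).mean(axis=1)
    mid_third = (zeta >= -1.0 / 3.0) & (zeta <= 1.0 / 3.0)
    plateau = float(np.median(means[mid_third]))
    max_count = float(means.max()) if plateau <= 0 else plateau
    level = 0.5 * plateau
    z_star = zeta[-1]
    basal = np.where(zeta >= 0)[0]
    for i in basal:
        if means[i] < level:
            if i == 0:
                z_star = zeta[i]
            else:
                f = (means[i - 1] - level) / (means[i - 1] - means[i])
                z_star = zeta[i - 1] + f * (zeta[i] - zeta[i - 1])
            break
    point = model.center_arr + z_star * b * u_base
    return Plane(point=tuple(point), normal=tuple(u_base)), max_count


def _myocardium_mask(vol: ScalarVolume, lv: LVResult) -> np.ndarray:
    """Voxels between the delineated endo and epi surfaces, apical of the valve."""
    X, Y, Z = vol.voxel_centers_mm()
    pts = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1).reshape(-1, 3)
    r, i, j = lv._angle_bins(pts)
    inside = (r >= lv.endo_r[i, j]) & (r <= lv.epi_r[i, j])
    apical = lv.valve_plane.signed_distance(pts) <= 0
    return (inside & apical).reshape(vol.shape)
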