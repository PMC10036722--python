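"""Geometric primitives for model-based cardiac SPECT segmentation.

This module holds the coordinate conventions, the geometric models that are
iteratively fitted to the ventricles (sphere for the RV, ellipsoid for the
LV), radial count-profile extraction, closed-form least-squares model
fitting, and the adequacy indices that justify a spherical RV model.

Coordinate conventions
----------------------
Volumes are indexed ``data[ix, iy, iz]`` with voxel centers at integer
indices (0-based).  Physical positions are ``index * spacing`` in mm.
Semantically, after short-axis reorientation:

* X: septal -> lateral, increasing toward the left ventricle (the right
  ventricle lies on the -X side of the LV),
* Y: anterior -> inferior,
* Z: the LV long axis, base on the +Z side, apex toward -Z.

All model mathematics is carried out in mm; masks live in voxel space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage


class DegenerateFitError(ValueError):
    """Raised when a model fit is under-determined or degenerate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ScalarVolume:
    """A 3D non-negative count grid with physical voxel spacing.

    Parameters
    ----------
    data:
        3D array of counts (non-negative).
    spacing:
        Per-axis voxel size in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (6.4, 6.4, 6.4)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if any(n < 16 for n in self.data.shape):
            raise ValueError("grid dimensions must be >= 16 per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on every axis")
        if np.any(self.data < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def extent_mm(self) -> np.ndarray:
        """Physical coordinate of the last voxel center per axis."""
        return (np.array(self.shape) - 1) * np.array(self.spacing)

    def contains_point(self, point_mm: Sequence[float]) -> bool:
        p = np.asarray(point_mm, dtype=float)
        return bool(np.all(p >= 0) and np.all(p <= self.extent_mm()))

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at physical points (zero outside the grid).

        ``points_mm`` has shape (N, 3); returns shape (N,).
        """
        pts = np.asarray(points_mm, dtype=float)
        coords = (pts / np.array(self.spacing)).T
        return ndimage.map_coordinates(self.data, coords, order=1, mode="constant", cval=0.0)

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (sparse) of voxel-center physical coordinates."""
        axes = [np.arange(n) * s for n, s in zip(self.shape, self.spacing)]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def with_data(self, data: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(data=data, spacing=self.spacing)


@dataclass(frozen=True)
class SphereModel:
    """Spherical RV model: center (the sphere point P) and radius, in mm."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "radius", float(self.radius))
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def signed_surface_distance(self, points_mm: np.ndarray) -> np.ndarray:
        """Radial distance to the sphere surface (positive outside)."""
        d = np.linalg.norm(np.atleast_2d(points_mm) - self.center_arr, axis=1)
        return d - self.radius


@dataclass(frozen=True)
class EllipsoidModel:
    """Ellipsoidal LV model: center, sorted semi-axes and rotation (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]  # ascending
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        axes = tuple(float(a) for a in self.semi_axes)
        if any(a <= 0 for a in axes):
            raise ValueError("semi-axes must be positive")
        if list(axes) != sorted(axes):
            raise ValueError("semi-axes must be sorted ascending")
        object.__setattr__(self, "semi_axes", axes)
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("orientation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("orientation must have determinant +1")
        object.__setattr__(self, "orientation", R)

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def long_axis(self) -> np.ndarray:
        """Unit vector along the longest semi-axis."""
        return self.orientation[:, 2]

    def _quadric_matrix(self, inflate: float = 0.0) -> np.ndarray:
        s = np.array(self.semi_axes) + inflate
        return self.orientation @ np.diag(1.0 / s**2) @ self.orientation.T

    def radius_along(self, directions: np.ndarray, inflate: float = 0.0) -> np.ndarray:
        """Distance from center to the surface along unit directions."""
        d = np.atleast_2d(directions)
        M = self._quadric_matrix(inflate)
        q = np.einsum("ni,ij,nj->n", d, M, d)
        return 1.0 / np.sqrt(q)

    def contains(self, points_mm: np.ndarray, inflate: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the (optionally inflated) surface."""
        p = np.atleast_2d(points_mm) - self.center_arr
        M = self._quadric_matrix(inflate)
        return np.einsum("ni,ij,nj->n", p, M, p) <= 1.0


@dataclass(frozen=True)
class Plane:
    """A plane (point + unit normal) in mm.  For valve planes the normal
    points toward the base; the apical side has negative signed distance."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(n)
        if nrm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", tuple(n / nrm))
        object.__setattr__(self, "point", tuple(float(c) for c in self.point))

    def signed_distance(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_mm) - np.asarray(self.point)
        return p @ np.asarray(self.normal)


@dataclass(frozen=True)
class RadialProfile:
    """A single radial count profile originating from a model center."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    samples: np.ndarray
    step: float
    angular_index: tuple[int, int]  # (longitudinal i, latitudinal j)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def radii(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.step


class ProfileSet:
    """Profiles on a regular (polar, azimuth) grid around an origin.

    Stored as arrays for speed; indexing yields :class:`RadialProfile`
    views.  Longitudinal index i maps to the polar angle band center
    ``theta_i = pi * (i + 0.5) / n_long`` and latitudinal index j to the
    azimuth ``phi_j = 2*pi*j / n_lat``.
    """

    def __init__(
        self,
        origin: np.ndarray,
        directions: np.ndarray,
        samples: np.ndarray,
        step: float,
        n_long: int,
        n_lat: int,
        thetas: np.ndarray,
        phis: np.ndarray,
    ) -> None:
        self.origin = np.asarray(origin, dtype=float)
        self.directions = directions
        self.samples = samples
        self.step = float(step)
        self.n_long = int(n_long)
        self.n_lat = int(n_lat)
        self.thetas = thetas  # per-profile polar angle
        self.phis = phis  # per-profile azimuth

    @property
    def radii(self) -> np.ndarray:
        return np.arange(self.samples.shape[1]) * self.step

    def __len__(self) -> int:
        return self.samples.shape[0]

    def __getitem__(self, k: int) -> RadialProfile:
        i, j = divmod(k, self.n_lat)
        return RadialProfile(
            origin=tuple(self.origin),
            direction=tuple(self.directions[k]),
            samples=self.samples[k],
            step=self.step,
            angular_index=(i, j),
        )

    def __iter__(self) -> Iterator[RadialProfile]:
        for k in range(len(self)):
            yield self[k]


@dataclass(frozen=True)
class GeometryIndices:
    """Model-adequacy indices for the spherical RV assumption.

    ``a``/``b`` are the LV short/long axes, ``f`` the distance from the
    sphere center to the apex, ``x = a/b`` the sphericity index; ``c``/``d``
    are the longest/shortest mid-RV short-axis diameters, ``m`` the
    center-to-free-wall distance, and ``eccentricity = c/d``.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def f(self) -> float:
        return 0.5 * np.hypot(self.a, self.b)

    @property
    def x(self) -> float:
        return self.a / self.b

    @property
    def m(self) -> float:
        # the center-to-free-wall distance is close to half the longest
        # mid-RV diameter when the center sits on the septum
        return 0.5 * self.c

    @property
    def eccentricity(self) -> float:
        return self.c / self.d

    @property
    def f_over_b(self) -> float:
        return sphericity_ratio(self.x)

    @property
    def m_over_d(self) -> float:
        return eccentricity_half(self.eccentricity)


# ---------------------------------------------------------------------------
# Model-adequacy ratios
# ---------------------------------------------------------------------------


def sphericity_ratio(x: float) -> float:
    """f/b ratio of a ventricle with sphericity index ``x = a/b``.

    A value near 1 means the distance from the septal sphere center to the
    apex matches the LV long axis, i.e. a sphere is an acceptable RV model.
    """
    if x <= 0:
        raise ValueError("sphericity index must be positive")
    return 0.5 * np.sqrt(x * x + 1.0)


def eccentricity_half(eccentricity: float) -> float:
    """m/d ratio given the mid-RV eccentricity index ``c/d`` (>= 1)."""
    if eccentricity < 1:
        raise ValueError("eccentricity index must be >= 1 (c is the longest diameter)")
    return eccentricity / 2.0


def truncate2(value: float) -> float:
    """Truncate (not round) to two decimal places, as conventionally printed."""
    return np.trunc(value * 100.0) / 100.0


# ---------------------------------------------------------------------------
# Radial profile extraction
# ---------------------------------------------------------------------------


def sphere_directions(n_long: int, n_lat: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit directions on a regular (polar, azimuth) grid covering the sphere.

    Returns (directions (N,3), thetas (N,), phis (N,)), ordered with the
    latitudinal (azimuth) index fastest.
    """
    theta = np.pi * (np.arange(n_long) + 0.5) / n_long
    phi = 2.0 * np.pi * np.arange(n_lat) / n_lat
    T, P = np.meshgrid(theta, phi, indexing="ij")
    t, p = T.ravel(), P.ravel()
    d = np.stack([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)], axis=1)
    return d, t, p


def extract_radial_profiles(
    vol: ScalarVolume,
    origin_mm: Sequence[float],
    n_long: int,
    n_lat: int,
    step: float | None = None,
    max_radius: float = 100.0,
) -> ProfileSet:
    """Extract ``n_long x n_lat`` radial count profiles from ``origin_mm``.

    Samples are taken by trilinear interpolation at multiples of ``step``
    (default: half the voxel size) out to ``max_radius``; points outside the
    grid read as zero.
    """
    if n_long < 1 or n_lat < 1:
        raise ValueError("profile counts must be >= 1")
    origin = np.asarray(origin_mm, dtype=float)
    if not vol.contains_point(origin):
        raise ValueError("profile origin lies outside the volume")
    if step is None:
        step = 0.5 * min(vol.spacing)
    if step <= 0:
        raise ValueError("step must be positive")
    directions, thetas, phis = sphere_directions(n_long, n_lat)
    radii = np.arange(0.0, max_radius + 0.5 * step, step)
    pts = origin[None, None, :] + directions[:, None, :] * radii[None, :, None]
    samples = vol.sample(pts.reshape(-1, 3)).reshape(len(directions), len(radii))
    return ProfileSet(origin, directions, samples, step, n_long, n_lat, thetas, phis)


def local_maxima_1d(samples: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a 1D array.

    Plateaus report their first index; endpoints qualify when the signal
    falls away from them.
    """
    s = np.asarray(samples, dtype=float)
    n = len(s)
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.array([0], dtype=int)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left_ok = i == 0 or s[i - 1] < s[i]
        right_ok = j == n - 1 or s[j + 1] < s[i]
        if left_ok and right_ok and s[i] > 0:
            out.append(i)
        i = j + 1
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# Least-squares model fitting
# ---------------------------------------------------------------------------


def fit_sphere_least_squares(points: np.ndarray) -> SphereModel:
    """Algebraic least-squares sphere through >= 4 non-coplanar points.

    Solves the linear system for ``x^2+y^2+z^2 + Dx + Ey + Fz + G = 0``;
    closed-form and deterministic.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 4 or pts.shape[1] != 3:
        raise DegenerateFitError("sphere fit needs at least 4 points in 3D")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise DegenerateFitError("points are coplanar or otherwise degenerate")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateFitError("fitted sphere has non-positive radius")
    return SphereModel(center=tuple(center), radius=float(np.sqrt(r2)))


def fit_ellipsoid_least_squares(points: np.ndarray) -> EllipsoidModel:
    """Algebraic least-squares ellipsoid through >= 9 points.

    Fits the 9-parameter quadric ``x'Ax + b'x = 1`` and decomposes it into
    center, sorted semi-axes and a proper rotation.  Raises
    :class:`DegenerateFitError` if the points are under-determined or the
    best-fit quadric is not an ellipsoid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 9 or pts.shape[1] != 3:
        raise DegenerateFitError("ellipsoid fit needs at least 9 points in 3D")
    # shift and scale for conditioning
    mu = pts.mean(axis=0)
    scale = max(np.ptp(pts, axis=0).max() / 2.0, 1e-9)
    q = (pts - mu) / scale
    x, y, z = q.T
    D = np.column_stack([x * x, y * y, z * z, x * y, x * z, y * z, x, y, z])
    sol, _, rank, sv = np.linalg.lstsq(D, np.ones(len(q)), rcond=None)
    if rank < 9 or sv[-1] < 1e-12 * sv[0]:
        raise DegenerateFitError("points are in a degenerate configuration")
    A = np.array(
        [
            [sol[0], sol[3] / 2, sol[4] / 2],
            [sol[3] / 2, sol[1], sol[5] / 2],
            [sol[4] / 2, sol[5] / 2, sol[2]],
        ]
    )
    bvec = sol[6:9]
    try:
        center_q = np.linalg.solve(A, -bvec / 2.0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular A
        raise DegenerateFitError("quadric has no finite center") from exc
    k = 1.0 + center_q @ A @ center_q
    evals, evecs = np.linalg.eigh(A)
    if np.any(evals <= 0) or k <= 0:
        raise DegenerateFitError("best-fit quadric is not an ellipsoid")
    semi = np.sqrt(k / evals) * scale  # eigh returns ascending evals -> semi desc
    order = np.argsort(semi)
    semi = semi[order]
    R = evecs[:, order]
    if np.linalg.det(R) < 0:
        R = R.copy()
        R[:, 0] = -R[:, 0]
    center = center_q * scale + mu
    return EllipsoidModel(center=tuple(center), semi_axes=tuple(semi), orientation=R)


def rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u onto unit vector v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(u @ v)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + 2.0 * K @ K
    w = np.cross(u, v)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + K + K @ K / (1.0 + c)
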