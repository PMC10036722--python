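"""Analytic cardiac phantoms emulating reconstructed non-gated MPI SPECT.

The generator builds a truncated ellipsoidal LV myocardial shell, a faint
partial spherical RV shell wrapping the septum, an optional RV perfusion
defect and an optional intense hepatic blob, then degrades the intensity map
the way a reconstructed perfusion study looks: Gaussian blur at the system
resolution, a Poisson count draw, and a 3D Butterworth low-pass.  Ground
truth (masks, cavity volume) is computed from the pre-degradation geometry,
analogous to the chamber volumes a digital anthropomorphic phantom reports.

All stochasticity of the package lives here, keyed by explicit seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import EllipsoidModel, Plane, ScalarVolume, SphereModel

DEFECT_MULTIPLIERS = {"mild": 0.6, "moderate": 0.3, "severe": 0.0}


@dataclass(frozen=True)
class DefectSpec:
    """An RV wall perfusion defect: basal or apical, three severities."""

    location: str = "basal"  # 'basal' | 'apical'
    severity: str = "moderate"  # 'mild' | 'moderate' | 'severe'

    def __post_init__(self) -> None:
        if self.location not in ("basal", "apical"):
            raise ValueError("defect location must be 'basal' or 'apical'")
        if self.severity not in DEFECT_MULTIPLIERS:
            raise ValueError("defect severity must be mild/moderate/severe")

    @property
    def multiplier(self) -> float:
        return DEFECT_MULTIPLIERS[self.severity]


@dataclass(frozen=True)
class LiverSpec:
    """A bright hepatic blob adjacent to the inferior wall."""

    offset_mm: tuple[float, float, float] = (20.0, 70.0, -20.0)  # from LV center
    radius_mm: float = 30.0
    intensity: float = 1.5


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic perfusion phantom.

    Intensities are relative to the LV myocardium (1.0).  The Poisson scale
    is the expected count of the hottest LV voxel after blurring, matching
    the count statistics of a summed non-gated acquisition.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 6.4
    lv_center_mm: tuple[float, float, float] = (256.0, 153.6, 204.8)
    lv_semi_axes: tuple[float, float, float] = (25.0, 25.0, 45.0)  # (x, y, long-z)
    lv_wall_mm: float = 10.0
    lv_basal_fraction: float = 0.3  # valve plane at center_z + fraction * long axis
    rv_offset_mm: Optional[tuple[float, float, float]] = None  # default (-a, 0, -b/5)
    rv_mid_radius_mm: float = 35.0
    rv_wall_mm: float = 12.8
    rv_fraction: float = 0.4  # RV/LV intensity fraction
    rv_extent_deg: float = 150.0  # azimuthal free-wall wrap
    defect: Optional[DefectSpec] = None
    liver: Optional[LiverSpec] = None
    psf_fwhm_mm: float = 9.0
    poisson_scale: float = 100.0  # expected LV-max counts
    apply_poisson: bool = True
    butterworth_order: int = 5
    butterworth_cutoff: float = 0.5  # cycles/voxel
    apply_butterworth: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.rv_fraction <= 1.0):
            raise ValueError("RV/LV intensity fraction must be in (0, 1]")
        if self.rv_mid_radius_mm <= 0 or self.rv_wall_mm <= 0 or self.lv_wall_mm <= 0:
            raise ValueError("radii and wall thicknesses must be positive")

    @property
    def rv_center_mm(self) -> np.ndarray:
        c = np.asarray(self.lv_center_mm, dtype=float)
        if self.rv_offset_mm is not None:
            return c + np.asarray(self.rv_offset_mm, dtype=float)
        a = min(self.lv_semi_axes[0], self.lv_semi_axes[1])
        b = self.lv_semi_axes[2]
        return c + np.array([-a, 0.0, -0.2 * b])

    @property
    def valve_z_mm(self) -> float:
        return self.lv_center_mm[2] + self.lv_basal_fraction * self.lv_semi_axes[2]

    @property
    def lv_model(self) -> EllipsoidModel:
        s = tuple(sorted(self.lv_semi_axes))
        # orientation: long axis along Z for the default (x, y, z) ordering
        order = np.argsort(self.lv_semi_axes)
        R = np.eye(3)[:, order]
        if np.linalg.det(R) < 0:
            R[:, 0] = -R[:, 0]
        return EllipsoidModel(center=tuple(self.lv_center_mm), semi_axes=s, orientation=R)

    @property
    def rv_model(self) -> SphereModel:
        return SphereModel(center=tuple(self.rv_center_mm), radius=self.rv_mid_radius_mm)

    @property
    def valve_plane(self) -> Plane:
        return Plane(
            point=(self.lv_center_mm[0], self.lv_center_mm[1], self.valve_z_mm),
            normal=(0.0, 0.0, 1.0),
        )


@dataclass
class PhantomTruth:
    """Ground truth of a phantom, computed from the pre-degradation geometry."""

    lv_myocardium: np.ndarray
    rv_myocardium: np.ndarray
    rv_cavity: np.ndarray
    cavity_volume_ml: float  # analytic (fine sub-grid) cavity volume
    cavity_volume_voxel_ml: float  # voxelized-mask volume
    lv_model: EllipsoidModel
    rv_model: SphereModel
    valve_plane: Plane
    spec: PhantomSpec


def _grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = [np.arange(n) * spec.voxel_mm for n in spec.grid_shape]
    return np.meshgrid(*ax, indexing="ij", sparse=True)


def _ellipsoid_shell(X, Y, Z, center, semi, wall, z_max):
    def q(inflate):
        s = np.asarray(semi) + inflate
        return (
            ((X - center[0]) / s[0]) ** 2
            + ((Y - center[1]) / s[1]) ** 2
            + ((Z - center[2]) / s[2]) ** 2
        )

    shell = (q(wall / 2.0) <= 1.0) & (q(-wall / 2.0) >= 1.0)
    return shell & (Z <= z_max)


def _rv_geometry(X, Y, Z, spec: PhantomSpec):
    c = spec.rv_center_mm
    dx, dy, dz = X - c[0], Y - c[1], Z - c[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    phi = np.arctan2(dy, dx)  # free wall centered at phi = pi (-X direction)
    wrap = np.abs(np.angle(np.exp(1j * (phi - np.pi))))
    half = np.deg2rad(spec.rv_extent_deg) / 2.0
    shell = (
        (np.abs(r - spec.rv_mid_radius_mm) <= spec.rv_wall_mm / 2.0)
        & (wrap <= half)
        & (Z <= spec.valve_z_mm)
    )
    return shell, r


def _defect_zone(Z, spec: PhantomSpec) -> np.ndarray:
    """Basal/apical third of the RV shell's axial extent."""
    cz = spec.rv_center_mm[2]
    lo = cz - (spec.rv_mid_radius_mm + spec.rv_wall_mm / 2.0)
    hi = min(spec.valve_z_mm, cz + spec.rv_mid_radius_mm + spec.rv_wall_mm / 2.0)
    third = (hi - lo) / 3.0
    if spec.defect is not None and spec.defect.location == "basal":
        return Z >= hi - third
    return Z <= lo + third


def _intensity_and_truth(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    X, Y, Z = _grid_mm(spec)
    lv_shell = _ellipsoid_shell(
        X, Y, Z, spec.lv_center_mm, spec.lv_semi_axes, spec.lv_wall_mm, spec.valve_z_mm
    )
    rv_shell, r = _rv_geometry(X, Y, Z, spec)
    # the septum bounds the RV: carve the RV shell at the LV epicardial
    # surface where the two abut; gross overlap signals a misconfigured model
    lv_epi_in = _ellipsoid_interior(X, Y, Z, spec)
    raw = int(rv_shell.sum())
    rv_shell = rv_shell & ~lv_epi_in
    if raw and (raw - int(rv_shell.sum())) > 0.25 * raw:
        raise ValueError("LV and RV shells overlap; adjust the RV offset or radius")

    img = np.zeros(spec.grid_shape, dtype=float)
    img[lv_shell] = 1.0
    rv_img = np.where(rv_shell, spec.rv_fraction, 0.0)
    if spec.defect is not None:
        zone = _defect_zone(Z, spec) & rv_shell
        rv_img = np.where(zone, rv_img * spec.defect.multiplier, rv_img)
    img = np.maximum(img, rv_img)
    if spec.liver is not None:
        lc = np.asarray(spec.lv_center_mm) + np.asarray(spec.liver.offset_mm)
        liver = (X - lc[0]) ** 2 + (Y - lc[1]) ** 2 + (Z - lc[2]) ** 2 <= spec.liver.radius_mm**2
        img = np.maximum(img, np.where(liver, spec.liver.intensity, 0.0))

    # RV cavity: inside the endocardial sphere, apical side of the valve
    # plane, outside the LV epicardial surface (the septum bounds the cavity)
    cavity = (r < spec.rv_mid_radius_mm - spec.rv_wall_mm / 2.0) & (Z <= spec.valve_z_mm)
    cavity &= ~lv_epi_in

    vox_ml = spec.voxel_mm**3 / 1000.0
    truth = PhantomTruth(
        lv_myocardium=lv_shell,
        rv_myocardium=rv_shell,
        rv_cavity=cavity,
        cavity_volume_ml=analytic_cavity_volume(spec),
        cavity_volume_voxel_ml=float(cavity.sum()) * vox_ml,
        lv_model=spec.lv_model,
        rv_model=spec.rv_model,
        valve_plane=spec.valve_plane,
        spec=spec,
    )
    return img, truth


def _ellipsoid_interior(X, Y, Z, spec: PhantomSpec):
    s = np.asarray(spec.lv_semi_axes) + spec.lv_wall_mm / 2.0
    c = spec.lv_center_mm
    return ((X - c[0]) / s[0]) ** 2 + ((Y - c[1]) / s[1]) ** 2 + ((Z - c[2]) / s[2]) ** 2 <= 1.0


def analytic_cavity_volume(spec: PhantomSpec, subgrid_mm: float = 1.6) -> float:
    """Cavity volume in ml from fine sub-grid integration of the geometry.

    This is the continuous-geometry truth (independent of the acquisition
    voxel grid), analogous to the chamber volumes a digital phantom reports.
    """
    c = spec.rv_center_mm
    r_endo = spec.rv_mid_radius_mm - spec.rv_wall_mm / 2.0
    h = subgrid_mm
    ax = [np.arange(ci - r_endo - h, ci + r_endo + h, h) for ci in c]
    X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
    inside = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 < r_endo**2
    inside &= Z <= spec.valve_z_mm
    inside &= ~_ellipsoid_interior(X, Y, Z, spec)
    return float(inside.sum()) * h**3 / 1000.0


def butterworth_lowpass(data: np.ndarray, order: int, cutoff: float) -> np.ndarray:
    """3D zero-phase Butterworth low-pass, cutoff in cycles/voxel."""
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n) for n in data.shape], indexing="ij", sparse=True
    )
    f2 = sum(f**2 for f in freqs)
    H = 1.0 / np.sqrt(1.0 + (f2 / cutoff**2) ** order)
    out = np.fft.ifftn(np.fft.fftn(data) * H).real
    return np.clip(out, 0.0, None)


def generate_phantom(spec: PhantomSpec) -> tuple[ScalarVolume, PhantomTruth]:
    """Build one phantom volume and its ground truth.

    Degradation chain: Gaussian blur at the PSF FWHM, Poisson counts scaled
    so the hottest LV voxel has expectation ``poisson_scale``, then the
    Butterworth post-filter.  With ``apply_poisson`` and the blur/filter
    disabled the volume is the noiseless intensity map (scaled to counts),
    whose support equals the truth masks exactly.
    """
    img, truth = _intensity_and_truth(spec)
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / spec.voxel_mm
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="constant")
    lv_max = img[truth.lv_myocardium].max()
    if lv_max <= 0:
        raise ValueError("LV shell carries no counts")
    lam = img * (spec.poisson_scale / lv_max)
    if spec.apply_poisson:
        if spec.seed is None:
            raise ValueError("a seed is required when Poisson noise is enabled")
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = lam
    if spec.apply_butterworth:
        counts = butterworth_lowpass(
            counts, spec.butterworth_order, spec.butterworth_cutoff
        )
    vol = ScalarVolume(data=counts, spacing=(spec.voxel_mm,) * 3)
    return vol, truth


def generate_repeat_pair(
    spec: PhantomSpec, seed1: int, seed2: int
) -> tuple[ScalarVolume, ScalarVolume, PhantomTruth]:
    """Two acquisitions of the same geometry with independent noise draws."""
    if spec.apply_poisson and seed1 == seed2:
        raise ValueError("repeat pair needs two distinct seeds")
    v1, truth = generate_phantom(dataclasses.replace(spec, seed=seed1))
    v2, _ = generate_phantom(dataclasses.replace(spec, seed=seed2))
    return v1, v2, truth


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges of the phantom cohort."""

    cavity_volume_ml: tuple[float, float] = (40.0, 220.0)
    rv_fraction: tuple[float, float] = (0.2, 0.6)
    lv_short_axis_mm: tuple[float, float] = (22.0, 28.0)
    lv_long_axis_mm: tuple[float, float] = (40.0, 50.0)
    defect_probability: float = 1.0 / 3.0


def _solve_radius_for_volume(spec: PhantomSpec, target_ml: float) -> float:
    """Bisection on the (monotone) analytic cavity volume over the mid radius."""
    lo, hi = 12.0, 75.0
    f = lambda r: analytic_cavity_volume(dataclasses.replace(spec, rv_mid_radius_mm=r))
    if f(lo) > target_ml or f(hi) < target_ml:
        raise ValueError("target cavity volume outside the attainable range")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if f(mid) < target_ml:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_spec(rng: np.random.Generator, ranges: CohortRanges, seed: int) -> PhantomSpec:
    """Draw one cohort phantom spec with a calibrated cavity volume."""
    target = rng.uniform(*ranges.cavity_volume_ml)
    q = rng.uniform(*ranges.rv_fraction)
    a = rng.uniform(*ranges.lv_short_axis_mm)
    b = rng.uniform(*ranges.lv_long_axis_mm)
    defect = None
    if rng.uniform() < ranges.defect_probability:
        defect = DefectSpec(
            location=rng.choice(["basal", "apical"]),
            severity=rng.choice(["mild", "moderate", "severe"]),
        )
    base = PhantomSpec(
        lv_semi_axes=(a, a, b),
        rv_fraction=q,
        defect=defect,
        seed=int(seed),
    )
    r = _solve_radius_for_volume(base, target)
    return dataclasses.replace(base, rv_mid_radius_mm=r)


def generate_cohort(
    n: int,
    ranges: CohortRanges | None = None,
    master_seed: int = 0,
) -> list[tuple[ScalarVolume, PhantomTruth]]:
    """Generate ``n`` phantoms with cohort-sampled geometry and noise.

    Per-phantom seeds are derived deterministically from ``master_seed``, so
    the same master seed reproduces the identical cohort.
    """
    return [generate_phantom(s) for s in sample_cohort_specs(n, ranges, master_seed)]


def sample_cohort_specs(
    n: int, ranges: CohortRanges | None = None, master_seed: int = 0
) -> list[PhantomSpec]:
    """Cohort specs only (no volume generation), same seeding as the cohort."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(master_seed)
    specs = []
    for _ in range(n):
        seed = int(rng.integers(0, 2**30))
        specs.append(sample_spec(rng, ranges or CohortRanges(), seed))
    return specs
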