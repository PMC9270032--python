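"""Synthetic phantoms and point-cloud cohorts.

Two generators back the test harness end to end:

* :func:`generate_phantom` renders nucleus-like blobs (isotropic Gaussian
  profile, FWHM equal to the nominal nucleus diameter) into a 3D volume on
  anisotropic voxels, returning the ground-truth centre coordinates.
* :func:`generate_cohort` produces two classes of point clouds ("female" /
  "male") that are approximately matched in count and first-order
  pairwise-distance statistics but differ in the number of planted loops —
  a multiscale topological signal for degree-1 persistence to detect.

The loop surrogate is a stand-in for whatever geometric feature drives sex
differences in real nuclei point clouds, not a claim about biology: loops
are the feature class that degree-1 persistent homology is built to see.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (ConfigurationError, ParameterError, PlacementError,
                   PointCloud, Sex, VolumeImage)

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort"]

_MAX_ATTEMPTS_PER_NUCLEUS = 1000


@dataclass
class PhantomSpec:
    """Specification of a nuclei image phantom.

    Defaults emulate the acquisition geometry of the study: ~4.5 um nuclei
    on 0.317 um lateral / 1 um axial voxels.
    """

    n_nuclei: int = 50
    nucleus_diameter_um: float = 4.5
    min_separation_um: float = 6.75
    volume_shape_vox: tuple[int, int, int] = (64, 256, 256)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (0.317, 0.317, 1.0)  # (sx, sy, sz)
    peak_intensity: float = 1000.0
    background: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ParameterError("n_nuclei must be >= 0")
        if self.nucleus_diameter_um <= 0 or self.min_separation_um < 0:
            raise ParameterError("nucleus diameter/separation must be positive")
        if any(s < 1 for s in self.volume_shape_vox):
            raise ParameterError("volume shape must be >= 1 per axis")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be strictly positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def _place_centres(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample centres (um, xyz) with a minimum pairwise separation."""
    nz, ny, nx = spec.volume_shape_vox
    sx, sy, sz = spec.spacing
    margin = spec.nucleus_diameter_um / 2.0
    hi = np.array([nx * sx, ny * sy, nz * sz]) - margin
    lo = np.full(3, margin)
    if np.any(hi <= lo):
        raise PlacementError("volume too small for the nucleus diameter")
    centres: list[np.ndarray] = []
    min_sep2 = spec.min_separation_um**2
    for _ in range(spec.n_nuclei):
        for _attempt in range(_MAX_ATTEMPTS_PER_NUCLEUS):
            cand = rng.uniform(lo, hi)
            if all(((cand - c) ** 2).sum() >= min_sep2 for c in centres):
                centres.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place nucleus {len(centres) + 1} of "
                f"{spec.n_nuclei} after {_MAX_ATTEMPTS_PER_NUCLEUS} attempts")
    return np.asarray(centres).reshape(-1, 3)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, PointCloud]:
    """Render a nuclei phantom and its ground-truth centre cloud.

    Nuclei are isotropic Gaussians with sigma = diameter / (2 sqrt(2 ln 2)),
    so the full width at half maximum equals the nominal diameter.
    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    centres = _place_centres(spec, rng)
    nz, ny, nx = spec.volume_shape_vox
    sx, sy, sz = spec.spacing
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    sigma_um = spec.nucleus_diameter_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # Render each blob only inside its +-4 sigma bounding box.
    half_um = 4.0 * sigma_um
    spacing_xyz = np.array([sx, sy, sz])
    for cx, cy, cz in centres:
        lo_v = np.maximum(
            np.floor((np.array([cx, cy, cz]) - half_um) / spacing_xyz), 0
        ).astype(int)
        hi_v = np.minimum(
            np.ceil((np.array([cx, cy, cz]) + half_um) / spacing_xyz) + 1,
            [nx, ny, nz],
        ).astype(int)
        xs = (np.arange(lo_v[0], hi_v[0]) * sx) - cx
        ys = (np.arange(lo_v[1], hi_v[1]) * sy) - cy
        zs = (np.arange(lo_v[2], hi_v[2]) * sz) - cz
        d2 = (zs[:, None, None] ** 2 + ys[None, :, None] ** 2
              + xs[None, None, :] ** 2)
        vol[lo_v[2]:hi_v[2], lo_v[1]:hi_v[1], lo_v[0]:hi_v[0]] += (
            spec.peak_intensity * np.exp(-d2 / (2.0 * sigma_um**2)))
    vol += spec.background
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, vol.shape)
    truth = PointCloud(animal_id=f"phantom-{spec.seed}", line="phantom",
                       sex=Sex.UNKNOWN, points=centres)
    return VolumeImage(intensities=vol, spacing=spec.spacing), truth


@dataclass
class CohortSpec:
    """Specification of a two-class synthetic point-cloud cohort.

    Defaults emulate the study's data shape: ~10,000 nuclei per animal in a
    CNS-sized ellipsoid envelope (semiaxes 200 x 80 x 50 um, mean spacing
    ~7 um), with classes differing only in the number of planted loops
    (5 vs 25, radius 15 um).
    """

    n_per_class: int = 8
    points_per_cloud: int = 10000
    envelope_semiaxes_um: tuple[float, float, float] = (200.0, 80.0, 50.0)
    n_loops_class0: int = 5
    n_loops_class1: int = 25
    loop_radius_um: float = 15.0
    loop_points: int = 40
    loop_jitter_um: float = 1.0
    animal_scale_jitter_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.points_per_cloud < 1:
            raise ParameterError("cohort sizes must be positive")
        if min(self.envelope_semiaxes_um) <= 0:
            raise ParameterError("envelope semiaxes must be positive")
        if self.loop_radius_um <= 0 or self.loop_points < 3:
            raise ParameterError("loops need a positive radius and >= 3 points")
        if self.loop_jitter_um < 0 or min(self.n_loops_class0,
                                          self.n_loops_class1) < 0:
            raise ParameterError("loop jitter and counts must be >= 0")
        if self.animal_scale_jitter_sd < 0:
            raise ParameterError("animal_scale_jitter_sd must be >= 0")
        needed = self.loop_points * max(self.n_loops_class0, self.n_loops_class1)
        if self.points_per_cloud < needed:
            raise ConfigurationError(
                f"points_per_cloud={self.points_per_cloud} cannot hold "
                f"{needed} loop points")


def _uniform_in_ellipsoid(n: int, semiaxes: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(size=n) ** (1.0 / 3.0)
    return v * r[:, None] * semiaxes


def _random_orthonormal_pair(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    w = rng.normal(size=3)
    w -= (w @ u) * u
    w /= np.linalg.norm(w)
    return u, w


def _one_cloud(spec: CohortSpec, n_loops: int,
               rng: np.random.Generator) -> np.ndarray:
    semiaxes = np.asarray(spec.envelope_semiaxes_um, dtype=float)
    n_loop_pts = n_loops * spec.loop_points
    pts = [_uniform_in_ellipsoid(spec.points_per_cloud - n_loop_pts,
                                 semiaxes, rng)]
    # Loop centres are drawn from a slightly shrunken envelope chosen so
    # that the per-axis positional variance of structured points (centre
    # variance + ring offset R^2/3 + jitter^2) equals the background's
    # (a^2/5): second-moment matching keeps the classes' first-order
    # distance statistics aligned regardless of loop count.
    extra_var = spec.loop_radius_um**2 / 3.0 + spec.loop_jitter_um**2
    shrink = np.sqrt(np.maximum(1.0 - 5.0 * extra_var / semiaxes**2, 0.0))
    centres = _uniform_in_ellipsoid(n_loops, semiaxes * shrink, rng)
    theta = 2.0 * np.pi * np.arange(spec.loop_points) / spec.loop_points
    for c in centres:
        u, w = _random_orthonormal_pair(rng)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ring = (c + spec.loop_radius_um
                * (np.cos(theta + phase)[:, None] * u
                   + np.sin(theta + phase)[:, None] * w))
        if spec.loop_jitter_um > 0:
            ring = ring + rng.normal(0.0, spec.loop_jitter_um, ring.shape)
        pts.append(ring)
    cloud = np.vstack(pts)
    # Per-animal overall size factor (lognormal): real animals differ in
    # organ size, which dominates between-animal variation of first-order
    # distance statistics and is shared by both classes.
    if spec.animal_scale_jitter_sd > 0:
        cloud = cloud * np.exp(rng.normal(0.0, spec.animal_scale_jitter_sd))
    return cloud


def generate_cohort(spec: CohortSpec) -> list[PointCloud]:
    """Generate ``2 * n_per_class`` clouds; class 0 = female, class 1 = male.

    Every cloud has exactly ``points_per_cloud`` points: uniform points in
    the ellipsoid envelope plus jittered circles at random positions and
    orientations.  The classes differ only in loop count.  Deterministic
    for a fixed ``spec.seed``.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_class)
    clouds = []
    for k, (sex, n_loops) in enumerate([(Sex.FEMALE, spec.n_loops_class0),
                                        (Sex.MALE, spec.n_loops_class1)]):
        for i in range(spec.n_per_class):
            rng = np.random.default_rng(seeds[k * spec.n_per_class + i])
            pts = _one_cloud(spec, n_loops, rng)
            clouds.append(PointCloud(
                animal_id=f"{sex.value[0].upper()}{i:02d}",
                line="sim", sex=sex, points=pts))
    return clouds
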