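"""Shared domain types for the whole-CNS census pipeline.

Coordinates are world coordinates in micrometres, ``(x, y, z)`` order.
Volumes are indexed ``(z, y, x)`` internally, with the per-axis voxel
spacing carried alongside as ``(sx, sy, sz)`` in micrometres.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CensusError",
    "FormatError",
    "ParameterError",
    "ConfigurationError",
    "InsufficientDataError",
    "DegenerateInputError",
    "PlacementError",
    "Sex",
    "PointCloud",
    "VolumeImage",
    "SegmentationConfig",
    "PersistenceDiagram",
    "KernelGram",
    "ExperimentConfig",
    "SplitExperimentResult",
    "CensusLineSummary",
]


class CensusError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CensusError):
    """A file did not match the expected on-disk format."""


class ParameterError(CensusError, ValueError):
    """A numeric parameter is outside its valid range."""


class ConfigurationError(CensusError):
    """A configuration is internally inconsistent or incomplete."""


class InsufficientDataError(CensusError):
    """Not enough data points for the requested computation."""


class DegenerateInputError(CensusError):
    """Input is geometrically degenerate (e.g. all points collinear)."""


class PlacementError(CensusError):
    """Synthetic object placement failed within the retry budget."""


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: str) -> "Sex":
        v = str(value).strip().lower()
        if v in ("female", "f"):
            return cls.FEMALE
        if v in ("male", "m"):
            return cls.MALE
        return cls.UNKNOWN


@dataclass
class PointCloud:
    """One animal's nuclei centroids (micrometres) plus metadata.

    ``points`` is an ``(n, 3)`` float array in ``(x, y, z)`` order.
    """

    animal_id: str
    line: str
    sex: Sex
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ParameterError("points must be an (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("point coordinates must be finite")
        self.points = pts
        self.sex = Sex.parse(self.sex) if not isinstance(self.sex, Sex) else self.sex

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    def __len__(self) -> int:
        return self.n_points


@dataclass
class VolumeImage:
    """3D intensity grid, indexed ``(z, y, x)``; spacing ``(sx, sy, sz)`` um."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ParameterError("intensities must be a non-empty 3D array")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ParameterError("spacing must be three strictly positive values")
        self.intensities = arr
        self.spacing = sp

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        sx, sy, sz = self.spacing
        return (sz, sy, sx)

    @property
    def voxel_volume_um3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class SegmentationConfig:
    """Parameters of the blob-based nucleus quantitation stage.

    Defaults follow the study protocol: 4.5 um nominal nucleus diameter and
    a 15 um^3 minimum object volume.  ``detection_threshold`` is expressed
    in multiples of the robust background SD (MAD) of the detector response.
    """

    blob_diameter_um: float = 4.5
    min_volume_um3: float = 15.0
    denoise_iterations: int = 5
    denoise_timestep: float = 0.125
    detection_threshold: float = 4.0

    def __post_init__(self) -> None:
        if self.blob_diameter_um <= 0:
            raise ParameterError("blob_diameter_um must be > 0")
        if self.min_volume_um3 < 0:
            raise ParameterError("min_volume_um3 must be >= 0")
        if self.denoise_iterations < 0:
            raise ParameterError("denoise_iterations must be >= 0")


@dataclass
class PersistenceDiagram:
    """Finite (birth, death) pairs of one homology degree.

    Values are in squared-radius units (um^2), the alpha-filtration scale.
    """

    degree: int
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("diagram points must be an (n, 2) array")
        if pts.size and (np.any(pts[:, 0] < 0) or np.any(pts[:, 1] < pts[:, 0])):
            raise ParameterError("diagram requires 0 <= birth <= death")
        if pts.size and not np.all(np.isfinite(pts)):
            raise ParameterError("diagram points must be finite")
        self.points = pts

    @property
    def persistence(self) -> np.ndarray:
        return self.points[:, 1] - self.points[:, 0]

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass
class KernelGram:
    """Symmetric similarity matrix over items with per-item animal ids."""

    matrix: np.ndarray
    item_ids: list[str]
    group_ids: list[str]
    kernel_kind: str = "persistence_heat"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.item_ids)
        if m.shape != (n, n) or len(self.group_ids) != n:
            raise ParameterError("gram dimensions must match item count")
        scale = np.abs(m).max() if m.size else 0.0
        if m.size and not np.allclose(m, m.T, rtol=1e-9, atol=1e-9 * max(scale, 1.0)):
            raise ParameterError("gram matrix must be symmetric")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.item_ids)


@dataclass
class ExperimentConfig:
    """Knobs of the sex-classification experiment.

    Defaults are the study's settings: subsample to 8000 points 100 times,
    5000 leakage-avoiding splits, 6 training animals per class, SVM c=10,
    heat-kernel bandwidth sigma=1/100, baseline RBF bandwidth 1e5.
    """

    subsample_size: int = 8000
    subsample_repeats: int = 100
    n_splits: int = 5000
    train_animals_per_class: int = 6
    svm_regularizer_c: float = 10.0
    heat_bandwidth_sigma: float = 0.01
    feature_rbf_bandwidth: float = 1e5
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subsample_size", "subsample_repeats", "n_splits",
                     "train_animals_per_class"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in ("svm_regularizer_c", "heat_bandwidth_sigma",
                     "feature_rbf_bandwidth"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")


@dataclass
class SplitExperimentResult:
    """Per-split true/control correlations plus the overlap summary.

    ``overlap_fraction`` is the fraction of splits in which the
    randomized-label control correlation exceeds the true-label one — the
    experiment's significance summary.
    """

    per_split: np.ndarray  # (n_splits, 2): columns rho_true, rho_control
    overlap_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.per_split, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ParameterError("per_split must be (n, 2)")
        if arr.size and (arr.min() < -1 - 1e-9 or arr.max() > 1 + 1e-9):
            raise ParameterError("correlations must lie in [-1, 1]")
        self.per_split = arr
        if arr.shape[0]:
            self.overlap_fraction = float(np.mean(arr[:, 1] > arr[:, 0]))
        else:
            self.overlap_fraction = float("nan")

    @property
    def rho_true(self) -> np.ndarray:
        return self.per_split[:, 0]

    @property
    def rho_control(self) -> np.ndarray:
        return self.per_split[:, 1]


@dataclass
class CensusLineSummary:
    """Per-line count summary in the Results convention: mean (+-CV%, n)."""

    line: str
    sex: Sex
    mean_count: float
    cv_percent: float
    n_animals: int

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise ParameterError("mean_count must be >= 0")
        if self.n_animals < 1:
            raise ParameterError("n_animals must be >= 1")
        if self.cv_percent < 0:
            raise ParameterError("cv_percent must be >= 0")
        self.sex = Sex.parse(self.sex) if not isinstance(self.sex, Sex) else self.sex


def as_point_array(points: Sequence) -> np.ndarray:
    """Coerce a sequence of (x, y, z) positions to a float (n, 3) array."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ParameterError("expected an (n, 3) coordinate array")
    return pts
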