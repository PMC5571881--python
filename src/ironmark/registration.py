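"""Rigid alignment of the post-contrast visit to the pre-contrast visit.

USPIO enhancement is read off a voxelwise *difference* of T2* maps, so the
two visits must sit on the same grid.  A generic intensity-based rigid
registration (6 degrees of freedom, multi-resolution, centre-of-mass
initialisation) estimates the inter-visit motion; the recovered transform
is then applied to the post-visit T2* map before the percent-change
computation.

Coordinate convention: volumes are (x, y, z) arrays, voxel indices are
0-based, and world coordinates are index * spacing (axis-aligned, origin at
the first voxel).  Transforms map points of the *fixed* image's world frame
into the *moving* image's frame (the resampling convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

from .relaxometry import T2StarMap

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "RegistrationError",
    "register_rigid",
    "apply_transform",
    "apply_transform_map",
]


class RegistrationError(RuntimeError):
    """Raised when the optimiser cannot produce a finite-metric alignment."""


@dataclass
class RigidTransform:
    """Euler rigid transform: x -> R(x - c) + c + t, all in physical mm.

    rotation    : Euler angles (about x, y, z axes) in radians
    translation : mm per axis
    center      : rotation centre in mm
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(v) for v in self.center])
        t.SetRotation(*[float(v) for v in self.rotation])
        t.SetTranslation([float(v) for v in self.translation])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        return cls(
            rotation=(t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()),
            translation=tuple(t.GetTranslation()),
            center=tuple(t.GetCenter()),
        )

    def inverse(self) -> "RigidTransform":
        inv = sitk.Euler3DTransform()
        fwd = self.to_sitk()
        rt = np.asarray(fwd.GetMatrix()).reshape(3, 3).T  # R^-1 = R^T
        inv.SetCenter(fwd.GetCenter())
        inv.SetMatrix(rt.ravel().tolist())
        inv.SetTranslation((-rt @ np.asarray(self.translation)).tolist())
        return RigidTransform.from_sitk(inv)

    def transform_point(self, point) -> np.ndarray:
        return np.asarray(self.to_sitk().TransformPoint([float(v) for v in point]))

    def to_dict(self) -> dict:
        return {
            "rotation_rad": list(self.rotation),
            "translation_mm": list(self.translation),
            "center_mm": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation=tuple(d["rotation_rad"]),
            translation=tuple(d["translation_mm"]),
            center=tuple(d["center_mm"]),
        )


@dataclass
class RegistrationConfig:
    metric: str = "mean-squared-difference"  # or "normalized-correlation"
    pyramid_levels: int = 2
    max_iterations: int = 200
    parameter_tolerance: float = 1e-5
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.metric not in ("mean-squared-difference", "normalized-correlation"):
            raise ValueError(f"unknown metric {self.metric!r}")


_INTERPOLATORS = {"nearest": sitk.sitkNearestNeighbor, "linear": sitk.sitkLinear}


def _to_sitk(arr: np.ndarray, spacing) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))).astype(np.float64))
    img.SetSpacing([float(s) for s in spacing])
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def _setup_method(config: RegistrationConfig) -> sitk.ImageRegistrationMethod:
    reg = sitk.ImageRegistrationMethod()
    if config.metric == "mean-squared-difference":
        reg.SetMetricAsMeanSquares()
    else:
        reg.SetMetricAsCorrelation()
    reg.SetInterpolator(_INTERPOLATORS[config.interpolation])
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=config.parameter_tolerance,
        numberOfIterations=config.max_iterations,
        relaxationFactor=0.5,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2 ** (config.pyramid_levels - 1 - i) for i in range(config.pyramid_levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(s - 1, 0) for s in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    return reg


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    config: RegistrationConfig | None = None,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Multi-resolution gradient-descent over the 6 rigid parameters,
    initialised at centre-of-mass (moments) alignment.  Deterministic: the
    metric is evaluated on the full voxel grid, never on a random sample.

    Single-slice volumes (one axis of length 1) are registered in-plane
    with 3 degrees of freedom.
    """
    config = config or RegistrationConfig()
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.ndim != 3 or moving.ndim != 3:
        raise ValueError("expected 3D volumes")
    if fixed.shape[2] == 1 and moving.shape[2] == 1:
        return _register_rigid_2d(fixed, moving, spacing, config)

    f_img, m_img = _to_sitk(fixed, spacing), _to_sitk(moving, spacing)
    initial = sitk.CenteredTransformInitializer(
        f_img,
        m_img,
        sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )
    reg = _setup_method(config)
    reg.SetInitialTransform(sitk.Euler3DTransform(initial), inPlace=True)
    try:
        result = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # empty overlap etc.
        raise RegistrationError(f"registration failed: {exc}") from exc
    if not np.isfinite(reg.GetMetricValue()):
        raise RegistrationError("non-finite metric at optimum (empty overlap?)")
    return RigidTransform.from_sitk(sitk.Euler3DTransform(result))


def _register_rigid_2d(fixed, moving, spacing, config) -> RigidTransform:
    f2 = sitk.GetImageFromArray(np.ascontiguousarray(fixed[:, :, 0].T).astype(np.float64))
    m2 = sitk.GetImageFromArray(np.ascontiguousarray(moving[:, :, 0].T).astype(np.float64))
    for im in (f2, m2):
        im.SetSpacing([float(spacing[0]), float(spacing[1])])
    initial = sitk.CenteredTransformInitializer(
        f2, m2, sitk.Euler2DTransform(), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    reg = _setup_method(config)
    reg.SetInitialTransform(sitk.Euler2DTransform(initial), inPlace=True)
    try:
        result = sitk.Euler2DTransform(reg.Execute(f2, m2))
    except RuntimeError as exc:
        raise RegistrationError(f"registration failed: {exc}") from exc
    cx, cy = result.GetCenter()
    tx, ty = result.GetTranslation()
    return RigidTransform(
        rotation=(0.0, 0.0, result.GetAngle()),
        translation=(tx, ty, 0.0),
        center=(cx, cy, 0.0),
    )


def registration_cost(
    fixed: np.ndarray,
    moving: np.ndarray,
    transform: RigidTransform,
    spacing=(1.0, 1.0, 1.0),
    config: RegistrationConfig | None = None,
) -> float:
    """Evaluate the configured similarity metric at a given transform."""
    config = config or RegistrationConfig()
    f_img, m_img = _to_sitk(fixed, spacing), _to_sitk(moving, spacing)
    reg = _setup_method(config)
    reg.SetInitialTransform(transform.to_sitk(), inPlace=False)
    return float(reg.MetricEvaluate(f_img, m_img))


def apply_transform(
    image: np.ndarray,
    transform: RigidTransform,
    interpolation: str = "linear",
    spacing=(1.0, 1.0, 1.0),
    default_value: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` through ``transform`` onto its own grid.

    Out-of-field voxels receive ``default_value``.  Masks must use
    ``interpolation='nearest'``.
    """
    if interpolation not in _INTERPOLATORS:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; expected one of "
            f"{sorted(_INTERPOLATORS)}"
        )
    arr = np.asarray(image, dtype=float)
    img = _to_sitk(arr, spacing)
    out = sitk.Resample(
        img,
        img,
        transform.to_sitk(),
        _INTERPOLATORS[interpolation],
        float(default_value),
        sitk.sitkFloat64,
    )
    return _from_sitk(out)


def apply_transform_map(
    t2map: T2StarMap,
    transform: RigidTransform,
    interpolation: str = "linear",
) -> T2StarMap:
    """Resample a T2* map; voxels touching invalid or out-of-field source
    voxels under linear interpolation are marked invalid."""
    sp = t2map.voxel_spacing
    validity = apply_transform(
        t2map.valid.astype(float), transform, interpolation, sp, default_value=0.0
    )
    valid = validity > 0.999
    filled = np.where(t2map.valid, t2map.t2star, 0.0)
    s0_filled = np.where(t2map.valid, t2map.s0, 0.0)
    r2_filled = np.where(t2map.valid, t2map.r_squared, 0.0)
    t2 = apply_transform(filled, transform, interpolation, sp)
    s0 = apply_transform(s0_filled, transform, interpolation, sp)
    r2 = apply_transform(r2_filled, transform, interpolation, sp)
    return replace(
        t2map,
        t2star=np.where(valid, t2, np.nan),
        s0=np.where(valid, s0, np.nan),
        r_squared=np.where(valid, r2, 0.0),
        valid=valid,
    )
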