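"""Voxelwise T2* estimation from multi-echo gradient-echo magnitude volumes.

The gradient-echo signal in a voxel with amplitude S0 and effective
transverse relaxation time T2* decays mono-exponentially with echo time TE:

    S(TE) = S0 * exp(-TE / T2*)

Taking logs turns the fit into a weighted linear regression of ln S on TE.
Plain OLS on the log signal over-weights the late, noisy echoes (the
log transform inflates the variance of small signals), so weights
proportional to the squared signal are used, which restores approximately
homoscedastic errors for additive noise of constant variance.

Voxels are screened after the fit: non-positive decay rates, T2* above a
physiological cap, or a poor weighted R^2 mark the voxel invalid rather
than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiEchoVolume",
    "T2StarMap",
    "RelaxometryConfig",
    "fit_monoexponential",
    "fit_t2star_map",
]

#: value stored in invalid voxels of a T2* map
INVALID_T2STAR = np.nan


@dataclass
class RelaxometryConfig:
    """Quality gates for the voxelwise fit.

    t2star_cap : longest credible T2* (ms); longer fits are marked invalid.
    r2_min     : minimum weighted R^2 of the log-domain fit.
    """

    t2star_cap: float = 200.0
    r2_min: float = 0.5


@dataclass
class MultiEchoVolume:
    """4D magnitude image (x, y, z, echo) with its echo times in ms."""

    intensities: np.ndarray
    echo_times: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.intensities.ndim != 4:
            raise ValueError(
                f"expected a 4D (x, y, z, echo) array, got {self.intensities.ndim}D"
            )
        if self.intensities.shape[3] != self.echo_times.size:
            raise ValueError(
                f"echo axis length {self.intensities.shape[3]} does not match "
                f"{self.echo_times.size} echo times"
            )
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.echo_times.size < 2:
            raise ValueError("at least 2 echoes are required")
        if self.echo_times.size == 2:
            warnings.warn(
                "only 2 echoes: T2* fit is exact-through-two-points, "
                "no quality assessment possible",
                stacklevel=2,
            )
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.echo_times.size


@dataclass
class T2StarMap:
    """Voxelwise T2* (ms) with amplitude, fit quality and validity mask."""

    t2star: np.ndarray
    s0: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    config: RelaxometryConfig = field(default_factory=RelaxometryConfig)


def _weighted_linefit(te: np.ndarray, logs: np.ndarray, w: np.ndarray):
    """Weighted least squares of logs on te; returns (intercept, slope, r2).

    Vectorised over leading axes: te/logs/w have shape (..., n_echoes),
    with zero weights excluding echoes from the fit.
    """
    sw = w.sum(axis=-1)
    sw = np.where(sw > 0, sw, np.nan)
    mx = (w * te).sum(axis=-1) / sw
    my = (w * logs).sum(axis=-1) / sw
    dx = te - mx[..., None]
    dy = logs - my[..., None]
    sxx = (w * dx * dx).sum(axis=-1)
    sxy = (w * dx * dy).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = my - slope * mx
    resid = dy - slope[..., None] * dx
    ss_res = (w * resid * resid).sum(axis=-1)
    ss_tot = (w * dy * dy).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    # a perfect (or horizontal-data) fit has ss_tot ~ ss_res ~ 0
    r2 = np.where(ss_tot <= np.finfo(float).eps * np.maximum(sw, 1.0), 1.0, r2)
    r2 = np.clip(r2, 0.0, 1.0)
    return intercept, slope, r2


def _usable_mask(signals: np.ndarray) -> np.ndarray:
    """Echoes usable for the log fit: positive, and before the first
    non-positive echo (everything after a signal void is distrusted)."""
    return np.cumprod(signals > 0, axis=-1).astype(bool)


def fit_monoexponential(
    signals,
    echo_times,
    config: RelaxometryConfig | None = None,
) -> tuple[float, float, float]:
    """Fit S(TE) = S0 exp(-TE/T2*) to one voxel's echo train.

    Returns ``(s0, t2star, r_squared)``; a failed fit (fewer than 2 usable
    echoes, or a non-decaying signal) returns ``(nan, nan, 0.0)``.
    """
    config = config or RelaxometryConfig()
    signals = np.asarray(signals, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if signals.shape != te.shape:
        raise ValueError("signals and echo_times must have equal length")

    usable = _usable_mask(signals)
    if usable.sum() < 2:
        return (np.nan, np.nan, 0.0)
    w = np.where(usable, signals**2, 0.0)
    logs = np.where(usable, np.log(np.where(usable, signals, 1.0)), 0.0)
    intercept, slope, r2 = _weighted_linefit(te, logs, w)
    if not np.isfinite(slope) or slope >= 0:
        return (np.nan, np.nan, 0.0)
    return (float(np.exp(intercept)), float(-1.0 / slope), float(r2))


def fit_t2star_map(
    volume: MultiEchoVolume,
    mask: np.ndarray,
    config: RelaxometryConfig | None = None,
) -> T2StarMap:
    """Fit the mono-exponential model in every voxel of ``mask``.

    Voxels that fail the fit, exceed ``t2star_cap`` or fall below
    ``r2_min`` are marked invalid (NaN in the output maps).
    """
    config = config or RelaxometryConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume grid {volume.grid_shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")

    sig = volume.intensities[mask]  # (n_voxels, n_echoes)
    te = volume.echo_times

    usable = _usable_mask(sig)
    enough = usable.sum(axis=1) >= 2
    w = np.where(usable, sig**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, sig, 1.0)), 0.0)
    intercept, slope, r2 = _weighted_linefit(te[None, :], logs, w)

    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = -1.0 / slope
        s0 = np.exp(intercept)
    ok = (
        enough
        & np.isfinite(slope)
        & (slope < 0)
        & (t2 <= config.t2star_cap)
        & (r2 >= config.r2_min)
    )

    shape = volume.grid_shape
    t2star_map = np.full(shape, INVALID_T2STAR)
    s0_map = np.full(shape, np.nan)
    r2_map = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)

    t2star_map[mask] = np.where(ok, t2, np.nan)
    s0_map[mask] = np.where(ok, s0, np.nan)
    r2_map[mask] = np.where(ok, r2, 0.0)
    valid[mask] = ok

    return T2StarMap(
        t2star=t2star_map,
        s0=s0_map,
        r_squared=r2_map,
        valid=valid,
        voxel_spacing=volume.voxel_spacing,
        config=config,
    )
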