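"""USPIO enhancement call from pre/post-contrast T2* maps.

Iron-oxide particles taken up by wall macrophages shorten T2*, so the
percent change is defined as the *reduction*

    100 * (T2*_pre - T2*_post) / T2*_pre

and a patient is called *enhanced* when the wall contains a connected
cluster of at least ``min_cluster_voxels`` voxels each changing by at least
``threshold_percent`` (defaults 10 voxels and 71%).  When too much of the
wall ROI is unusable — failed fits or registration fallout — the call is
*indeterminate* rather than a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .relaxometry import T2StarMap

__all__ = [
    "PercentChangeMap",
    "ClassifierConfig",
    "EnhancementCall",
    "percent_change_map",
    "label_clusters",
    "classify_enhancement",
    "export_overlay",
]


@dataclass
class ClassifierConfig:
    threshold_percent: float = 71.0
    min_cluster_voxels: int = 10
    connectivity: str = "face"  # or "face+edge+corner"
    max_invalid_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_percent):
            raise ValueError("threshold must be finite")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.connectivity not in ("face", "face+edge+corner"):
            raise ValueError(f"unknown connectivity {self.connectivity!r}")


@dataclass
class PercentChangeMap:
    """Per-voxel percent change in T2*, defined where both visits are valid
    and the voxel lies in the wall ROI."""

    percent_change: np.ndarray
    valid: np.ndarray
    wall_mask: np.ndarray
    invalid_fraction: float


@dataclass
class EnhancementCall:
    status: str  # enhanced | nonenhanced | indeterminate
    clusters: list = field(default_factory=list)  # (size_voxels, centroid) desc
    largest_cluster: int = 0
    suprathreshold_voxels: int = 0
    invalid_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "clusters": [
                {"size_voxels": int(s), "centroid": [float(c) for c in cen]}
                for s, cen in self.clusters
            ],
            "largest_cluster": int(self.largest_cluster),
            "suprathreshold_voxels": int(self.suprathreshold_voxels),
            "invalid_fraction": float(self.invalid_fraction),
        }


def percent_change_map(
    t2_pre: T2StarMap,
    t2_post_registered: T2StarMap,
    wall_mask: np.ndarray,
) -> PercentChangeMap:
    """Percent T2* reduction per wall voxel valid in both visits."""
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if t2_pre.t2star.shape != t2_post_registered.t2star.shape:
        raise ValueError("pre and post maps are not on the same grid")
    if wall_mask.shape != t2_pre.t2star.shape:
        raise ValueError("wall mask shape does not match the maps")
    if not wall_mask.any():
        raise ValueError("wall mask is empty")

    valid = wall_mask & t2_pre.valid & t2_post_registered.valid & (t2_pre.t2star > 0)
    invalid_fraction = 1.0 - valid.sum() / wall_mask.sum()
    if not valid.any():
        raise ValueError("no valid voxels in the wall ROI")

    pc = np.full(wall_mask.shape, np.nan)
    pre = t2_pre.t2star[valid]
    post = t2_post_registered.t2star[valid]
    pc[valid] = 100.0 * (pre - post) / pre
    return PercentChangeMap(
        percent_change=pc,
        valid=valid,
        wall_mask=wall_mask,
        invalid_fraction=float(invalid_fraction),
    )


def label_clusters(mask: np.ndarray, connectivity: str = "face"):
    """Connected components of a boolean volume.

    Returns ``(labels, sizes)`` with sizes in voxels sorted descending and
    labels relabelled so label 1 is the largest cluster.  ``face``
    connectivity is the 6-neighbourhood; ``face+edge+corner`` the
    26-neighbourhood.
    """
    mask = np.asarray(mask, dtype=bool)
    conn = 1 if connectivity == "face" else mask.ndim
    labels = measure.label(mask, connectivity=conn)
    if labels.max() == 0:
        return labels, []
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(-sizes, kind="stable")
    remap = np.zeros(labels.max() + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, sizes.size + 1)
    return remap[labels], sizes[order].tolist()


#: absolute slack on the percent scale so a voxel computed at exactly the
#: threshold (e.g. pre 30 ms, post 8.7 ms -> 71%) is not lost to rounding
THRESHOLD_EPS = 1e-9


def _suprathreshold(pcmap: PercentChangeMap, config: ClassifierConfig) -> np.ndarray:
    pc = np.nan_to_num(pcmap.percent_change, nan=-np.inf)
    return pcmap.valid & (pc >= config.threshold_percent - THRESHOLD_EPS)


def classify_enhancement(
    pcmap: PercentChangeMap,
    config: ClassifierConfig | None = None,
) -> EnhancementCall:
    """Apply the threshold/cluster rule to a percent-change map."""
    config = config or ClassifierConfig()
    if pcmap.invalid_fraction > config.max_invalid_fraction:
        return EnhancementCall(
            status="indeterminate", invalid_fraction=pcmap.invalid_fraction
        )

    supra = _suprathreshold(pcmap, config)
    labels, sizes = label_clusters(supra, config.connectivity)
    clusters = []
    for lab, size in enumerate(sizes, start=1):
        centroid = tuple(np.mean(np.nonzero(labels == lab), axis=1))
        clusters.append((int(size), centroid))
    largest = sizes[0] if sizes else 0
    status = "enhanced" if largest >= config.min_cluster_voxels else "nonenhanced"
    return EnhancementCall(
        status=status,
        clusters=clusters,
        largest_cluster=int(largest),
        suprathreshold_voxels=int(supra.sum()),
        invalid_fraction=pcmap.invalid_fraction,
    )


def export_overlay(
    pcmap: PercentChangeMap,
    background: np.ndarray,
    out_path,
    config: ClassifierConfig | None = None,
    max_slices: int = 12,
) -> Path:
    """Write a PNG slice montage: suprathreshold voxels in red over the
    anatomical background (axial slices through the wall ROI)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or ClassifierConfig()
    background = np.asarray(background, dtype=float)
    if background.shape != pcmap.percent_change.shape:
        raise ValueError("background grid does not match the percent-change map")

    supra = _suprathreshold(pcmap, config)
    z_roi = np.nonzero(pcmap.wall_mask.any(axis=(0, 1)))[0]
    if z_roi.size == 0:
        z_roi = np.arange(background.shape[2])
    step = max(1, int(np.ceil(z_roi.size / max_slices)))
    z_sel = z_roi[::step]

    ncol = min(4, len(z_sel))
    nrow = int(np.ceil(len(z_sel) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, z in zip(axes.ravel(), z_sel):
        ax.imshow(background[:, :, z].T, cmap="gray", origin="lower")
        overlay = np.ma.masked_where(~supra[:, :, z].T, supra[:, :, z].T.astype(float))
        ax.imshow(overlay, cmap="autumn", origin="lower", vmin=0, vmax=1, alpha=0.9)
        ax.set_title(f"z={z}", fontsize=8)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return out_path
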