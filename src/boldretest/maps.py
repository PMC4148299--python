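"""Statistic-map thresholding, cluster labeling and ROI management.

Activation masks are formed by thresholding a t-map at the upper-tail t
quantile for a voxelwise p (cluster-forming threshold, one-sided), labeling
connected components, and dropping components smaller than a minimum extent.
Face (6-neighbor) connectivity is the default; 18-neighbor is available.
Family-wise cluster correction via random-field theory is deliberately not
implemented: the extent threshold is either user-set or calibrated by a
sign-flip permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "RoiMask",
    "ClusterResult",
    "threshold_clusters",
    "overlap_mask",
    "permutation_cluster_extent",
]


@dataclass
class RoiMask:
    """A named boolean ROI with provenance."""

    mask: np.ndarray
    name: str
    provenance: str = "anatomical"  # anatomical | task-derived | overlap
    source_threshold: tuple | None = None  # (voxel_p, min_extent) if task-derived
    connectivity: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.provenance not in ("anatomical", "task-derived", "overlap"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ClusterResult:
    """Labeled supra-threshold clusters of one statistic map."""

    labels: np.ndarray
    mask: RoiMask
    table: pd.DataFrame  # label, size, peak stat, peak coordinate (0-based)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6 or 18")


def threshold_clusters(
    t_map: np.ndarray,
    df: int,
    voxel_p: float = 0.001,
    min_extent: int = 1,
    connectivity: int = 6,
    name: str = "task",
) -> ClusterResult:
    """Threshold a 3D t-map and keep connected clusters of sufficient extent."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    if min_extent <= 0:
        raise ValueError("min_extent must be positive")
    if not 0.0 < voxel_p < 1.0:
        raise ValueError("voxel_p must lie in (0, 1)")
    t_map = np.asarray(t_map, dtype=float)
    if t_map.ndim != 3:
        raise ValueError("expected a 3D t-map")
    threshold = stats.t.isf(voxel_p, df)
    supra = t_map > threshold
    labels, n_clusters = ndimage.label(supra, structure=_structure(connectivity))
    rows = []
    keep = np.zeros_like(supra)
    out_labels = np.zeros_like(labels)
    next_label = 0
    for lab in range(1, n_clusters + 1):
        members = labels == lab
        size = int(members.sum())
        if size < min_extent:
            continue
        next_label += 1
        keep |= members
        out_labels[members] = next_label
        masked = np.where(members, t_map, -np.inf)
        peak_flat = int(np.argmax(masked))
        peak = np.unravel_index(peak_flat, t_map.shape)
        rows.append((next_label, size, float(t_map[peak]), peak))
    table = pd.DataFrame(rows, columns=["label", "size", "peak_t", "peak_voxel"])
    roi = RoiMask(
        mask=keep,
        name=name,
        provenance="task-derived",
        source_threshold=(voxel_p, min_extent),
        connectivity=connectivity,
    )
    return ClusterResult(labels=out_labels, mask=roi, table=table)


def overlap_mask(masks, name: str = "overlap") -> RoiMask:
    """Voxelwise intersection of activation masks across pipelines."""
    if isinstance(masks, dict):
        items = list(masks.items())
    else:
        items = [(getattr(m, "name", f"mask_{i}"), m) for i, m in enumerate(masks)]
    if len(items) == 0:
        raise ValueError("no masks to intersect")
    arrays = []
    for _, m in items:
        arr = m.mask if isinstance(m, RoiMask) else np.asarray(m, dtype=bool)
        arrays.append(arr)
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("masks have mismatched geometry")
    inter = np.logical_and.reduce(arrays)
    if not inter.any():
        counts = {label: int(a.sum()) for (label, _), a in zip(items, arrays)}
        raise ValueError(f"empty overlap; per-pipeline voxel counts: {counts}")
    return RoiMask(mask=inter, name=name, provenance="overlap")


def permutation_cluster_extent(
    contrast_maps: np.ndarray,
    voxel_p: float = 0.001,
    n_perm: int = 500,
    connectivity: int = 6,
    seed: int = 0,
    quantile: float = 0.95,
) -> int:
    """Sign-flip permutation calibration of the minimum cluster extent.

    ``contrast_maps`` is (n_subjects, x, y, z). Each permutation flips subject
    signs, recomputes the one-sample t-map, and records the largest
    supra-threshold cluster; the returned extent is the requested quantile of
    that null distribution (at least 1).
    """
    maps4d = np.asarray(contrast_maps, dtype=float)
    if maps4d.ndim != 4:
        raise ValueError("expected (n_subjects, x, y, z) contrast maps")
    n = maps4d.shape[0]
    rng = np.random.default_rng(seed)
    threshold = stats.t.isf(voxel_p, n - 1)
    struct = _structure(connectivity)
    max_sizes = np.zeros(n_perm)
    flat = maps4d.reshape(n, -1)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        flipped = flat * signs[:, None]
        mean = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
        supra = (t > threshold).reshape(maps4d.shape[1:])
        labels, n_clusters = ndimage.label(supra, structure=struct)
        if n_clusters:
            sizes = ndimage.sum_labels(supra, labels, index=range(1, n_clusters + 1))
            max_sizes[b] = sizes.max()
    return max(1, int(np.quantile(max_sizes, quantile)))
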