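"""Modified CompCor (mCompCor) physiological-noise regressor.

Physiological noise is concentrated in white matter, CSF and voxels with high
temporal standard deviation. The mCompCor regressor is deliberately a single
nuisance series: the mean time course over the union of the top-SD voxels
(top 2% of the brain by temporal SD) and a WM/CSF mask, demeaned. No PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "McompcorSelection",
    "temporal_sd_map",
    "select_pooled_voxels",
    "mcompcor_regressor",
]


@dataclass
class McompcorSelection:
    """Voxel sets feeding the mCompCor regressor (flat voxel indices)."""

    high_sd_voxels: np.ndarray
    tissue_voxels: np.ndarray
    pooled_voxels: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        pooled = np.union1d(self.high_sd_voxels, self.tissue_voxels)
        if not np.array_equal(np.sort(self.pooled_voxels), pooled):
            raise ValueError("pooled_voxels must be the union of the two sets")

    def to_mask(self, shape) -> np.ndarray:
        """Pooled selection as a boolean 3D mask (e.g. for NIfTI export)."""
        mask = np.zeros(int(np.prod(shape)), dtype=bool)
        mask[self.pooled_voxels] = True
        return mask.reshape(shape)


def temporal_sd_map(data4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-voxel temporal sample SD (ddof=1) inside a mask.

    Returns a 3D map with NaN outside the mask.
    """
    data4d = np.asarray(data4d)
    mask = np.asarray(mask, dtype=bool)
    if data4d.shape[-1] < 2:
        raise ValueError("need at least two volumes to compute a temporal SD")
    if mask.shape != data4d.shape[:-1]:
        raise ValueError("mask shape does not match the volume grid")
    if not mask.any():
        raise ValueError("empty mask")
    sd = np.full(mask.shape, np.nan)
    sd[mask] = data4d[mask].std(axis=-1, ddof=1)
    return sd


def select_pooled_voxels(
    sd_map: np.ndarray,
    brain_mask: np.ndarray,
    wm_csf_mask: np.ndarray,
    fraction: float = 0.02,
) -> McompcorSelection:
    """Select the top-``fraction`` brain voxels by temporal SD, pooled with WM/CSF.

    Ties are broken by flat voxel order (stable sort on the negated SD), so the
    selection is reproducible. A brain mask too small to honour the fraction
    still yields at least one high-SD voxel.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    wm_csf_mask = np.asarray(wm_csf_mask, dtype=bool)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if wm_csf_mask.shape != brain_mask.shape or sd_map.shape != brain_mask.shape:
        raise ValueError("mask/SD-map geometries disagree")
    brain_idx = np.flatnonzero(brain_mask.ravel())
    if brain_idx.size == 0:
        raise ValueError("empty brain mask")
    n_high = max(1, int(np.ceil(fraction * brain_idx.size)))
    sd_flat = sd_map.ravel()[brain_idx]
    order = np.argsort(-sd_flat, kind="stable")
    high = np.sort(brain_idx[order[:n_high]])
    tissue = np.flatnonzero(wm_csf_mask.ravel())
    pooled = np.union1d(high, tissue)
    return McompcorSelection(
        high_sd_voxels=high,
        tissue_voxels=tissue,
        pooled_voxels=pooled,
        fraction=fraction,
    )


def mcompcor_regressor(data4d: np.ndarray, selection: McompcorSelection) -> np.ndarray:
    """Mean time series over the pooled voxel set, demeaned."""
    pooled = np.asarray(selection.pooled_voxels)
    if pooled.size == 0:
        raise ValueError("pooled voxel set is empty")
    data4d = np.asarray(data4d)
    flat = data4d.reshape(-1, data4d.shape[-1])
    series = flat[pooled].mean(axis=0)
    return series - series.mean()
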