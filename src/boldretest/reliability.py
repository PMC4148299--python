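"""Voxelwise test-retest reliability via the consistency ICC, ICC(3,1).

ICC(3,1) comes from a two-way ANOVA with subjects as random effects and
sessions as fixed effects (one observation per cell):

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)

where BMS is the between-subjects mean square and EMS the residual mean
square. It measures consistency (rank-order stability) rather than absolute
agreement: adding a constant to one session leaves it unchanged. The primary
regional summary is the median of the voxelwise ICCs (mvICC). Qualitative
labels follow the conventional cut points Poor (<0.40), Fair (0.40-0.60),
Good (0.60-0.75) and Excellent (>=0.75).

Negative ICC estimates are retained (medians and rank comparisons use them);
categorization maps them to Poor. Voxels with an undefined ICC (zero
denominator) are excluded from medians with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnovaTable",
    "IccMap",
    "two_way_anova",
    "icc31",
    "icc_from_matrix",
    "icc_variants",
    "icc_map",
    "mvicc",
    "mvicc_bootstrap_se",
    "cicchetti_category",
]

logger = logging.getLogger(__name__)

@dataclass
class AnovaTable:
    """Mean squares of the two-way, one-observation-per-cell ANOVA."""

    BMS: float  # between-subjects
    WMS: float  # within-subjects
    EMS: float  # residual (error)
    SMS: float  # between-sessions
    n: int
    k: int

    def __post_init__(self) -> None:
        for name in ("BMS", "WMS", "EMS", "SMS"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"negative mean square {name}")


def two_way_anova(values: np.ndarray) -> AnovaTable:
    """Decompose an (n subjects x k sessions) table into ANOVA mean squares."""
    Y = np.asarray(values, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected an n x k table")
    n, k = Y.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells are not allowed")
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    sess_means = Y.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_sess = n * np.sum((sess_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_sess
    ss_within = ss_total - ss_subj
    return AnovaTable(
        BMS=ss_subj / (n - 1),
        WMS=ss_within / (n * (k - 1)),
        EMS=max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        SMS=ss_sess / (k - 1),
        n=n,
        k=k,
    )


def icc31(table: AnovaTable) -> float:
    """Consistency ICC(3,1) from a two-way ANOVA table; NaN if undefined."""
    denom = table.BMS + (table.k - 1) * table.EMS
    if denom <= 0:
        return float("nan")
    return float((table.BMS - table.EMS) / denom)


def icc_from_matrix(values: np.ndarray) -> float:
    """ICC(3,1) straight from an n x k measurement table."""
    return icc31(two_way_anova(values))


def icc_variants(values: np.ndarray, form: str = "icc31") -> float:
    """ICC(1,1), ICC(2,1) or ICC(3,1) from an n x k table.

    The alternative forms are provided for comparison only; the package's
    reliability statistic is ICC(3,1).
    """
    t = two_way_anova(values)
    if form == "icc31":
        return icc31(t)
    if form == "icc21":
        denom = t.BMS + (t.k - 1) * t.EMS + t.k * (t.SMS - t.EMS) / t.n
        return float((t.BMS - t.EMS) / denom) if denom > 0 else float("nan")
    if form == "icc11":
        denom = t.BMS + (t.k - 1) * t.WMS
        return float((t.BMS - t.WMS) / denom) if denom > 0 else float("nan")
    raise ValueError(f"unknown ICC form {form!r}")


def _icc31_vectorized(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """ICC(3,1) per column for two (n subjects x V voxels) session matrices."""
    n = y1.shape[0]
    grand = (y1 + y2) / 2.0
    subj_mean = grand                      # per-subject mean over k=2 sessions
    gm = (y1.mean(axis=0) + y2.mean(axis=0)) / 2.0
    ss_subj = 2.0 * np.sum((subj_mean - gm) ** 2, axis=0)
    ss_sess = n * ((y1.mean(axis=0) - gm) ** 2 + (y2.mean(axis=0) - gm) ** 2)
    ss_total = np.sum((y1 - gm) ** 2 + (y2 - gm) ** 2, axis=0)
    ss_err = np.clip(ss_total - ss_subj - ss_sess, 0.0, None)
    bms = ss_subj / (n - 1)
    ems = ss_err / (n - 1)
    denom = bms + ems
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (bms - ems) / denom, np.nan)
    return icc


@dataclass
class IccMap:
    """Per-voxel ICC(3,1) over a 3D grid (NaN outside the mask)."""

    icc: np.ndarray
    mask: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        inside = self.icc[self.mask]
        finite = inside[np.isfinite(inside)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("ICC(3,1) with k=2 must lie in [-1, 1]")

    @property
    def category(self) -> np.ndarray:
        out = np.full(self.icc.shape, "undefined", dtype=object)
        defined = self.mask & np.isfinite(self.icc)
        out[defined] = cicchetti_category(self.icc[defined])
        return out

    def plot_histogram(self, roi_mask: np.ndarray | None = None, ax=None):
        """Histogram of in-mask (or in-ROI) voxelwise ICCs with the median marked."""
        import matplotlib.pyplot as plt

        sel = self.mask if roi_mask is None else (self.mask & roi_mask)
        vals = self.icc[sel]
        vals = vals[np.isfinite(vals)]
        if ax is None:
            _, ax = plt.subplots()
        ax.hist(vals, bins=40, color="steelblue")
        ax.axvline(np.median(vals), color="crimson", label=f"mvICC={np.median(vals):.2f}")
        ax.set_xlabel("ICC(3,1)")
        ax.legend()
        return ax


def icc_map(
    contrasts_t1: np.ndarray,
    contrasts_t2: np.ndarray,
    mask: np.ndarray,
    subjects_t1=None,
    subjects_t2=None,
) -> IccMap:
    """Voxelwise ICC(3,1) from two sessions of per-subject contrast maps.

    ``contrasts_t*`` are (n_subjects x V) matrices over the in-mask voxels,
    in the same subject order; if subject identifiers are supplied for both
    sessions they must match exactly (no positional re-inference).
    """
    c1 = np.asarray(contrasts_t1, dtype=float)
    c2 = np.asarray(contrasts_t2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("session contrast matrices must share a shape")
    if subjects_t1 is not None or subjects_t2 is not None:
        if subjects_t1 is None or subjects_t2 is None:
            raise ValueError("subject identifiers must be given for both sessions")
        if list(subjects_t1) != list(subjects_t2):
            raise ValueError(
                "subject identity mismatch between sessions; re-key before mapping"
            )
    mask = np.asarray(mask, dtype=bool)
    if c1.shape[1] != int(mask.sum()):
        raise ValueError("contrast columns must match the in-mask voxel count")
    vol = np.full(mask.shape, np.nan)
    vol[mask] = _icc31_vectorized(c1, c2)
    return IccMap(icc=vol, mask=mask, n_subjects=c1.shape[0])


def mvicc(icc_values, roi_mask: np.ndarray | None = None) -> float:
    """Median voxelwise ICC over an ROI (midpoint convention for even counts).

    Accepts an IccMap plus ROI mask, or a bare array of ICC values. Undefined
    voxels are excluded; an empty ROI is an error.
    """
    if isinstance(icc_values, IccMap):
        if roi_mask is None:
            roi_mask = icc_values.mask
        vals = icc_values.icc[roi_mask & icc_values.mask]
    else:
        vals = np.asarray(icc_values, dtype=float)
        if roi_mask is not None:
            vals = vals[np.asarray(roi_mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    finite = vals[np.isfinite(vals)]
    dropped = vals.size - finite.size
    if dropped:
        logger.info("mvICC: excluded %d voxels with undefined ICC", dropped)
    if finite.size == 0:
        raise ValueError("no defined ICC values in the ROI")
    return float(np.median(finite))


def mvicc_bootstrap_se(
    contrasts_t1: np.ndarray,
    contrasts_t2: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Subject-level bootstrap standard error of the mvICC.

    Resamples subjects with replacement, recomputes the voxelwise ICCs and
    the ROI median each time, and returns the SD of the bootstrap medians.
    (The resampling unit is the subject, matching the two-way ANOVA model.)
    """
    c1 = np.asarray(contrasts_t1, dtype=float)
    c2 = np.asarray(contrasts_t2, dtype=float)
    n = c1.shape[0]
    rng = np.random.default_rng(seed)
    medians = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        icc = _icc31_vectorized(c1[idx], c2[idx])
        medians[b] = np.nanmedian(icc)
    return float(medians.std(ddof=1))


def cicchetti_category(icc):
    """Qualitative reliability label(s) for ICC value(s).

    Poor (<0.40), Fair (0.40-0.60), Good (0.60-0.75), Excellent (>=0.75);
    negative values are Poor.
    """
    arr = np.asarray(icc, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.select(
        [arr < 0.40, arr < 0.60, arr < 0.75, arr >= 0.75],
        ["Poor", "Fair", "Good", "Excellent"],
        default="undefined",
    )
    out = np.where(np.isnan(arr), "undefined", out)
    return out[0] if scalar else out
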