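"""Design-matrix construction for first-level BOLD GLMs.

Provides the canonical double-gamma hemodynamic response function (HRF) and its
temporal/dispersion derivative bases, a discrete-cosine drift basis for high-pass
filtering, convolved task regressors, and assembly of the full time x regressor
design matrix for each modeling pipeline.

Four named pipelines are supported:

``default``
    block regressors convolved with the canonical HRF;
``flexhrf``
    mixed block/event model with temporal and dispersion derivative bases;
``mcompcor``
    block model plus a single physiological-noise nuisance regressor;
``combined``
    both of the above.

All pipelines share six motion covariates, a 128 s high-pass discrete-cosine
drift basis and an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HrfParams",
    "PipelineSpec",
    "DesignMatrix",
    "PIPELINE_NAMES",
    "canonical_hrf",
    "hrf_derivatives",
    "dct_drift_basis",
    "condition_regressor",
    "build_design",
    "contrast_vector",
]

PIPELINE_NAMES = ("default", "flexhrf", "mcompcor", "combined")


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the canonical double-gamma HRF.

    The kernel is ``gammapdf(t; peak_delay, peak_disp) -
    undershoot_ratio * gammapdf(t; undershoot_delay, undershoot_disp)``,
    sampled on a microtime grid of step ``dt`` over ``kernel_length`` seconds
    and scaled so the canonical peak equals 1.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0
    dt: float = 0.125

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_disp", "undershoot_disp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfParams.{name} must be positive")
        if self.dt <= 0:
            raise ValueError("HrfParams.dt must be positive")
        if self.kernel_length <= 0:
            raise ValueError("HrfParams.kernel_length must be positive")


@dataclass(frozen=True)
class PipelineSpec:
    """Which optional model components a first-level pipeline uses."""

    name: str
    use_derivatives: bool = False
    use_mcompcor: bool = False
    event_model: str = "block"  # "block" | "mixed-block-event"

    def __post_init__(self) -> None:
        if self.event_model not in ("block", "mixed-block-event"):
            raise ValueError(f"unknown event_model {self.event_model!r}")
        if self.use_derivatives and self.event_model != "mixed-block-event":
            raise ValueError("derivative bases require the mixed-block-event model")

    @classmethod
    def from_name(cls, name: str) -> "PipelineSpec":
        if name == "default":
            return cls("default")
        if name == "flexhrf":
            return cls("flexhrf", use_derivatives=True, event_model="mixed-block-event")
        if name == "mcompcor":
            return cls("mcompcor", use_mcompcor=True)
        if name == "combined":
            return cls(
                "combined",
                use_derivatives=True,
                use_mcompcor=True,
                event_model="mixed-block-event",
            )
        raise ValueError(f"unknown pipeline {name!r}; expected one of {PIPELINE_NAMES}")


@dataclass
class DesignMatrix:
    """A labeled time x regressor matrix with column-group annotations."""

    frame: pd.DataFrame
    column_groups: dict = field(default_factory=dict)
    tr_seconds: float = 2.0
    highpass_cutoff: float = 128.0

    def __post_init__(self) -> None:
        labels = list(self.frame.columns)
        if len(set(labels)) != len(labels):
            raise ValueError("design column labels must be unique")
        if set(labels) != set(self.column_groups):
            raise ValueError("column_groups must annotate exactly the design columns")
        values = self.frame.to_numpy()
        zero = np.flatnonzero(np.all(values == 0, axis=0))
        if zero.size:
            raise ValueError(f"all-zero design columns: {[labels[i] for i in zero]}")
        n_intercept = sum(1 for c in labels if self.column_groups[c] == "intercept")
        if n_intercept != 1:
            raise ValueError("design must contain exactly one intercept column")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def labels(self) -> list:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return self.frame.shape[0]

    def columns_in_group(self, group: str) -> list:
        return [c for c in self.frame.columns if self.column_groups[c] == group]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _double_gamma(t: np.ndarray, params: HrfParams) -> np.ndarray:
    """Unnormalized double-gamma evaluated at times ``t`` (seconds)."""
    peak = stats.gamma.pdf(
        t, params.peak_delay / params.peak_disp, scale=params.peak_disp
    )
    under = stats.gamma.pdf(
        t, params.undershoot_delay / params.undershoot_disp,
        scale=params.undershoot_disp,
    )
    return peak - params.undershoot_ratio * under


def _time_grid(params: HrfParams) -> np.ndarray:
    return np.arange(0.0, params.kernel_length, params.dt)


def _dense_peak(params: HrfParams) -> float:
    """Peak height of the double gamma on a dense grid (independent of dt)."""
    t = np.arange(0.0, params.kernel_length, min(params.dt, 0.01))
    peak = _double_gamma(t, params).max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return float(peak)


def canonical_hrf(params: HrfParams | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``params.dt``, peak scaled to 1.

    The normalizing peak is evaluated on a dense grid so the kernel's scale
    does not depend on the sampling resolution.
    """
    params = params or HrfParams()
    return _double_gamma(_time_grid(params), params) / _dense_peak(params)


def hrf_derivatives(
    params: HrfParams | None = None,
    delta_t: float = 1.0,
    delta_disp: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal and dispersion derivative bases of the canonical HRF.

    Both are finite differences: the temporal derivative under an onset shift of
    ``delta_t`` seconds, the dispersion derivative under a ``delta_disp``
    perturbation of the peak dispersion. They share the canonical kernel's
    peak normalization so the three bases live on one scale.
    """
    params = params or HrfParams()
    if delta_t <= 0 or delta_disp <= 0:
        raise ValueError("finite-difference steps must be positive")
    t = _time_grid(params)
    h = _double_gamma(t, params)
    scale = _dense_peak(params)
    shifted = _double_gamma(np.clip(t - delta_t, 0.0, None), params)
    shifted[t < delta_t] = 0.0
    temporal = (h - shifted) / delta_t / scale
    wider = _double_gamma(t, replace(params, peak_disp=params.peak_disp + delta_disp))
    dispersion = (h - wider) / delta_disp / scale
    return temporal, dispersion


def dct_drift_basis(n_volumes: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (constant term excluded).

    Returns ``floor(2 * n_volumes * tr / cutoff_s) + 1`` orthonormal cosine
    columns spanning fluctuations slower than the cutoff period; the constant
    is left to the design intercept.
    """
    if n_volumes < 2:
        raise ValueError("need at least two volumes for a drift basis")
    if cutoff_s <= 2 * tr:
        raise ValueError("high-pass cutoff must exceed twice the TR")
    n_col = int(np.floor(2.0 * n_volumes * tr / cutoff_s)) + 1
    t = np.arange(n_volumes)
    basis = np.empty((n_volumes, n_col))
    for k in range(1, n_col + 1):
        basis[:, k - 1] = np.sqrt(2.0 / n_volumes) * np.cos(
            np.pi * k * (2 * t + 1) / (2.0 * n_volumes)
        )
    return basis


def condition_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_volumes: int,
    tr: float,
    kernel: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Convolve an onset/duration boxcar with an HRF kernel on a microtime grid.

    The stimulus function is built at resolution ``dt``, convolved (Riemann
    scaling by ``dt``), and sampled at the middle of each TR.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must have equal length")
    n_bins = int(np.ceil(n_volumes * tr / dt)) + 1
    u = np.zeros(n_bins)
    for onset, dur in zip(onsets, durations):
        lo = int(round(onset / dt))
        hi = int(round((onset + dur) / dt))
        u[lo:hi] += 1.0
    conv = np.convolve(u, kernel)[:n_bins] * dt
    sample = np.floor((np.arange(n_volumes) * tr + tr / 2.0) / dt + 1e-9).astype(int)
    return conv[np.minimum(sample, n_bins - 1)]


def _orthogonalize(col: np.ndarray, against: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(against, col, rcond=None)
    return col - against @ coef


def build_design(
    schedule,
    spec: PipelineSpec,
    motion: np.ndarray,
    n_volumes: int,
    tr: float,
    mcompcor_series: np.ndarray | None = None,
    hrf_params: HrfParams | None = None,
    highpass_cutoff: float = 128.0,
    orthogonalize_derivatives: bool = False,
) -> DesignMatrix:
    """Assemble the full design matrix for one pipeline and one run.

    Task columns are condition regressors (block boxcars, or per-stimulus
    events under the mixed block/event model) convolved with the canonical HRF
    and, when requested, its temporal and dispersion derivatives; followed by
    six motion covariates, the optional mCompCor nuisance column, the
    discrete-cosine drift basis and an intercept.
    """
    frame = schedule.frame if hasattr(schedule, "frame") else schedule
    if len(frame) == 0:
        raise ValueError("empty event schedule")
    if spec.use_mcompcor and mcompcor_series is None:
        raise ValueError(f"pipeline {spec.name!r} requires an mCompCor series")
    if not spec.use_mcompcor and mcompcor_series is not None:
        raise ValueError(f"pipeline {spec.name!r} does not accept an mCompCor series")
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape != (n_volumes, 6):
        raise ValueError(f"motion must have shape ({n_volumes}, 6)")

    hrf_params = hrf_params or HrfParams(dt=tr / 16.0)
    if spec.event_model == "mixed-block-event" and hasattr(schedule, "stimulus_events"):
        events = schedule.stimulus_events()
    else:
        events = frame
    conditions = _ordered_conditions(frame["trial_type"])

    kernels = {"": canonical_hrf(hrf_params)}
    if spec.use_derivatives:
        temporal, dispersion = hrf_derivatives(hrf_params)
        kernels["_tderiv"] = temporal
        kernels["_dderiv"] = dispersion

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    group_of = {"": "task-canonical", "_tderiv": "task-temporal-derivative",
                "_dderiv": "task-dispersion-derivative"}
    for cond in conditions:
        sel = events[events["trial_type"] == cond]
        if len(sel) == 0:
            raise ValueError(f"condition {cond!r} has no events in the schedule")
        canon = None
        for suffix, kernel in kernels.items():
            reg = condition_regressor(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                n_volumes, tr, kernel, hrf_params.dt,
            )
            if suffix == "":
                canon = reg
            elif orthogonalize_derivatives:
                reg = _orthogonalize(reg, canon[:, None])
            columns[f"{cond}{suffix}"] = reg
            groups[f"{cond}{suffix}"] = group_of[suffix]

    for j in range(6):
        columns[f"motion_{j + 1}"] = motion[:, j]
        groups[f"motion_{j + 1}"] = "motion"
    if spec.use_mcompcor:
        series = np.asarray(mcompcor_series, dtype=float)
        if series.shape != (n_volumes,):
            raise ValueError(f"mCompCor series must have length {n_volumes}")
        columns["mcompcor"] = series
        groups["mcompcor"] = "mcompcor"
    drift = dct_drift_basis(n_volumes, tr, highpass_cutoff)
    for k in range(drift.shape[1]):
        columns[f"drift_{k + 1}"] = drift[:, k]
        groups[f"drift_{k + 1}"] = "drift"
    columns["intercept"] = np.ones(n_volumes)
    groups["intercept"] = "intercept"

    return DesignMatrix(
        frame=pd.DataFrame(columns),
        column_groups=groups,
        tr_seconds=tr,
        highpass_cutoff=highpass_cutoff,
    )


def _ordered_conditions(trial_types) -> list:
    """Emotion conditions alphabetically, then control conditions last."""
    unique = sorted(set(trial_types))
    tail = [c for c in ("shapes", "identity") if c in unique]
    head = [c for c in unique if c not in tail]
    return head + tail


def contrast_vector(design: DesignMatrix, contrast_name: str = "emotions_minus_shapes") -> np.ndarray:
    """Contrast weights over the design columns for a named contrast.

    ``emotions_minus_shapes`` places ``1/n_emotions`` on each canonical emotion
    column and -1 on the canonical shapes column; derivative, nuisance, drift
    and intercept columns receive weight 0, so the weights sum to zero.
    """
    if contrast_name != "emotions_minus_shapes":
        raise ValueError(f"unknown contrast {contrast_name!r}")
    canonical = design.columns_in_group("task-canonical")
    if "shapes" not in canonical:
        raise ValueError("design has no canonical 'shapes' column")
    emotions = [c for c in canonical if c not in ("shapes", "identity")]
    if not emotions:
        raise ValueError("design has no emotion task columns")
    weights = pd.Series(0.0, index=design.frame.columns)
    weights[emotions] = 1.0 / len(emotions)
    weights["shapes"] = -1.0
    return weights.to_numpy()
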