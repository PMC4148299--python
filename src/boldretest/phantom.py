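"""Synthetic BOLD phantom with known activation amplitudes and reliability.

Generates cohorts of subjects scanned twice on a pseudorandomized emotional
faces block paradigm: four emotion conditions (three 12 s blocks of twelve
contiguous 1 s stimuli each) and six 6 s shape-control blocks, no two
consecutive blocks sharing a condition. Each run is 378 volumes at TR = 2 s.

Signal model per voxel::

    BOLD(t) = baseline
            + amplitude * [task regressors convolved with the subject-session HRF]
            + physiological confound (full weight in WM/CSF and a designated
              high-variance voxel set, partial weight elsewhere in brain)
            + optional linear drift, motion leakage
            + stationary AR(1) + white noise

Subject-session contrast amplitudes follow a two-way random-effects model
``amp = amplitude_mean * (1 + b_s + w_sj)`` with ``b ~ N(0, sigma2_between)``
and ``w ~ N(0, sigma2_within)``, so the true test-retest reliability
(consistency ICC) is analytically ``sigma2_between / (sigma2_between +
sigma2_within)`` in every active region.

All randomness derives from a single integer seed through named substreams, so
any run is reproducible in isolation: ``SeedSequence(seed, spawn_key=(stream,
subject, session))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .design import HrfParams, canonical_hrf, condition_regressor

__all__ = [
    "EMOTIONS",
    "SHAPES",
    "PhantomGeometry",
    "SimulationConfig",
    "EventSchedule",
    "GroundTruth",
    "BoldRun",
    "Cohort",
    "default_geometry",
    "make_paradigm",
    "simulate_session",
    "simulate_cohort",
]

EMOTIONS = ("anger", "fear", "happy", "sad")
SHAPES = "shapes"
IDENTITY = "identity"

BACKGROUND, GRAY, WHITE, CSF, VISUAL, AMYGDALA = range(6)
_BASELINE = 100.0

# substream tags for SeedSequence spawn keys
_STREAM_PARADIGM, _STREAM_SUBJECT, _STREAM_SESSION, _STREAM_GEOMETRY = range(4)


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel grid, tissue labels and masks of the phantom 'anatomy'.

    ``region_labels`` assigns each voxel one of: background, gray matter,
    white matter, CSF, the 'visual' active region, or the small
    amygdala-analog active region. ``highvar_mask`` marks gray-matter voxels
    that carry full physiological-confound weight (the analog of
    high-temporal-SD voxels in real data).
    """

    shape: tuple
    voxel_size: float
    region_labels: np.ndarray
    brain_mask: np.ndarray
    highvar_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.region_labels.shape != tuple(self.shape):
            raise ValueError("region_labels shape mismatch")
        if self.brain_mask.shape != tuple(self.shape):
            raise ValueError("brain_mask shape mismatch")
        if np.any((self.region_labels > 0) & ~self.brain_mask):
            raise ValueError("labeled tissue outside the brain mask")
        for code, name in ((VISUAL, "visual"), (AMYGDALA, "amygdala")):
            if np.any((self.region_labels == code) & ~self.brain_mask):
                raise ValueError(f"{name} region outside brain mask")
        if np.any(self.highvar_mask & ~self.brain_mask):
            raise ValueError("high-variance voxels outside brain mask")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def mask(self, code: int) -> np.ndarray:
        return self.region_labels == code

    @property
    def wm_csf_mask(self) -> np.ndarray:
        return (self.region_labels == WHITE) | (self.region_labels == CSF)

    @property
    def visual_mask(self) -> np.ndarray:
        return self.region_labels == VISUAL

    @property
    def amygdala_mask(self) -> np.ndarray:
        return self.region_labels == AMYGDALA

    @property
    def active_mask(self) -> np.ndarray:
        return self.visual_mask | self.amygdala_mask


def default_geometry(
    shape: tuple = (20, 20, 12),
    voxel_size: float = 3.0,
    highvar_fraction: float = 0.02,
    seed: int = 0,
) -> PhantomGeometry:
    """Desk-scale phantom anatomy: ellipsoidal brain, WM core, central CSF,
    a posterior 'visual' slab and two small amygdala-analog blobs."""
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rho2 = ((ii - cx) / (nx / 2.0)) ** 2 + ((jj - cy) / (ny / 2.0)) ** 2 + (
        (kk - cz) / (nz / 2.0)
    ) ** 2
    brain = rho2 <= 0.95
    labels = np.where(brain, GRAY, BACKGROUND).astype(np.int16)
    labels[(rho2 <= 0.30) & brain] = WHITE
    # ventricle-analog CSF box at the center
    csf = np.zeros(shape, dtype=bool)
    csf[
        int(cx) - max(1, nx // 10): int(cx) + max(1, nx // 10),
        int(cy) - max(1, ny // 10): int(cy) + max(1, ny // 10),
        int(cz): int(cz) + max(1, nz // 6),
    ] = True
    labels[csf & brain] = CSF
    # posterior visual slab (small j = posterior by convention)
    visual = np.zeros(shape, dtype=bool)
    visual[
        nx // 4: nx - nx // 4,
        max(0, ny // 10): ny // 4,
        nz // 3: nz - nz // 3,
    ] = True
    labels[visual & (labels == GRAY)] = VISUAL
    # two bilateral amygdala-analog blobs
    amyg = np.zeros(shape, dtype=bool)
    for x0 in (max(1, nx // 6), nx - max(1, nx // 6) - 2):
        amyg[x0: x0 + 2, int(cy): int(cy) + 2, nz // 3: nz // 3 + 2] = True
    labels[amyg & (labels == GRAY)] = AMYGDALA

    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM_GEOMETRY,))
    )
    gray_idx = np.flatnonzero(labels.ravel() == GRAY)
    n_high = max(1, int(np.ceil(highvar_fraction * brain.sum())))
    chosen = rng.choice(gray_idx, size=min(n_high, gray_idx.size), replace=False)
    highvar = np.zeros(labels.size, dtype=bool)
    highvar[chosen] = True

    return PhantomGeometry(
        shape=tuple(shape),
        voxel_size=voxel_size,
        region_labels=labels,
        brain_mask=brain,
        highvar_mask=highvar.reshape(shape),
    )


@dataclass
class SimulationConfig:
    """All knobs of the phantom generator; the defaults are the study conditions.

    Variance parameters ``sigma2_between``/``sigma2_within`` are *relative*
    variances of the subject amplitude factor ``1 + b + w``; the true
    consistency ICC of every active region is their ratio
    ``sigma2_between / (sigma2_between + sigma2_within)``.
    """

    n_subjects: int = 48
    n_volumes: int = 378
    tr_seconds: float = 2.0
    amplitude_mean: float = 0.5          # % signal change per unit regressor height
    shape_response_scale: float = 0.2    # shapes response as fraction of amplitude_mean
    amygdala_scale: float = 0.5          # amygdala amplitude relative to visual
    sigma2_between: float = 0.12
    sigma2_within: float = 0.12
    ar1_rho: float = 0.3
    sigma2_noise: float = 1.0
    hrf_latency_sd: float = 1.0          # s, subject-level peak-delay jitter
    hrf_latency_session_sd: float = 0.5  # s, session-level peak-delay jitter
    hrf_dispersion_sd: float = 0.10      # log-scale width jitter, subject level
    hrf_dispersion_session_sd: float = 0.05
    physio_amplitude: float = 2.5        # SD of the shared confound in WM/CSF/high-var
    physio_gm_fraction: float = 0.5      # confound weight elsewhere in brain
    physio_spectrum: tuple = ((0.025, 0.035), (0.20, 0.30))  # Hz bands
    motion_amplitude: float = 0.2
    motion_leak: float = 0.0
    drift_amplitude: float = 0.0
    smoothing_fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "sigma2_between", "sigma2_within", "sigma2_noise",
            "hrf_latency_sd", "hrf_latency_session_sd",
            "hrf_dispersion_sd", "hrf_dispersion_session_sd",
            "physio_amplitude", "motion_amplitude", "smoothing_fwhm_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"SimulationConfig.{name} must be >= 0")
        if abs(self.ar1_rho) >= 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def true_icc(self) -> float:
        total = self.sigma2_between + self.sigma2_within
        if total == 0:
            return 0.0
        return self.sigma2_between / total

    def to_json(self) -> str:
        return json.dumps(
            {k: (list(map(list, v)) if k == "physio_spectrum" else v)
             for k, v in self.__dict__.items()},
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        raw = json.loads(text)
        raw["physio_spectrum"] = tuple(tuple(b) for b in raw["physio_spectrum"])
        return cls(**raw)


@dataclass
class EventSchedule:
    """Block onsets/durations/conditions of one run of the paradigm.

    Each row is a block; ``n_stimuli`` contiguous 1 s stimuli make up the
    block, so ``duration == n_stimuli`` seconds. ``stimulus_events`` expands
    the blocks to per-stimulus rows for mixed block/event modeling.
    """

    frame: pd.DataFrame

    @property
    def conditions(self) -> list:
        return sorted(set(self.frame["trial_type"]))

    @property
    def span(self) -> float:
        last = self.frame["onset"] + self.frame["duration"]
        return float(last.max())

    def stimulus_events(self) -> pd.DataFrame:
        rows = []
        for block in self.frame.itertuples(index=False):
            n = int(block.n_stimuli)
            for i in range(n):
                rows.append((block.onset + i * 1.0, 1.0, block.trial_type))
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EventSchedule":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame=frame)


def make_paradigm(
    seed: int,
    n_volumes: int = 378,
    tr: float = 2.0,
    include_identity_control: bool = False,
) -> EventSchedule:
    """Pseudorandomized block schedule of the emotional faces paradigm.

    Twelve emotion blocks (four conditions x three blocks, twelve 1 s stimuli
    each) and six shape-control blocks (six stimuli each), ordered so that no
    two consecutive blocks share a condition, with uniform gaps filling the
    run. ``include_identity_control`` adds three identity-morph control blocks
    that are modeled but never contrasted.
    """
    blocks = [(cond, 12) for cond in EMOTIONS for _ in range(3)]
    blocks += [(SHAPES, 6) for _ in range(6)]
    if include_identity_control:
        blocks += [(IDENTITY, 6) for _ in range(3)]
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM_PARADIGM,))
    )
    order = _constrained_order(blocks, rng)
    total_time = n_volumes * tr
    block_time = sum(n for _, n in order)
    if block_time >= total_time:
        raise ValueError("paradigm does not fit in the run")
    gap = (total_time - block_time) / (len(order) + 1)
    rows, t = [], gap
    for cond, n in order:
        rows.append((round(t, 3), float(n), cond, n))
        t += n + gap
    frame = pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "n_stimuli"])
    return EventSchedule(frame=frame)


def _constrained_order(blocks: list, rng: np.random.Generator) -> list:
    """Permute until no two consecutive blocks share a condition."""
    blocks = list(blocks)
    for _ in range(10000):
        perm = [blocks[i] for i in rng.permutation(len(blocks))]
        if all(a[0] != b[0] for a, b in zip(perm, perm[1:])):
            return perm
    raise RuntimeError("could not satisfy the block-ordering constraint")


@dataclass
class GroundTruth:
    """What the generator actually drew, for validating downstream estimates."""

    true_icc_by_region: dict
    subject_amplitudes: np.ndarray      # (n_subjects, 2) emotion amplitude per session
    shape_amplitude: float
    confound_series: np.ndarray         # (n_subjects, 2, n_volumes)
    subject_hrf_params: pd.DataFrame    # subject, session, peak_delay, peak_disp

    def __post_init__(self) -> None:
        for region, icc in self.true_icc_by_region.items():
            if not 0.0 <= icc <= 1.0:
                raise ValueError(f"true ICC for {region!r} outside [0, 1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "true_icc_by_region": self.true_icc_by_region,
                "subject_amplitudes": self.subject_amplitudes.tolist(),
                "shape_amplitude": self.shape_amplitude,
                "confound_series": self.confound_series.tolist(),
                "subject_hrf_params": self.subject_hrf_params.to_dict("list"),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            true_icc_by_region=raw["true_icc_by_region"],
            subject_amplitudes=np.asarray(raw["subject_amplitudes"]),
            shape_amplitude=raw["shape_amplitude"],
            confound_series=np.asarray(raw["confound_series"]),
            subject_hrf_params=pd.DataFrame(raw["subject_hrf_params"]),
        )


@dataclass
class BoldRun:
    """One subject-session 4D BOLD series with its nuisance sidecars."""

    data: np.ndarray            # (x, y, z, t)
    tr_seconds: float
    subject_id: int
    session_id: int
    motion: np.ndarray          # (t, 6)
    affine: np.ndarray

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    def timeseries(self, mask: np.ndarray) -> np.ndarray:
        """Extract a (time x voxel) matrix of the series under a 3D mask."""
        return self.data[mask].T


def _subject_draws(config: SimulationConfig, subject: int) -> dict:
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAM_SUBJECT, subject))
    )
    return {
        "b": rng.normal(0.0, np.sqrt(config.sigma2_between)),
        "latency": rng.normal(0.0, config.hrf_latency_sd),
        "log_disp": rng.normal(0.0, config.hrf_dispersion_sd),
    }


def _bandlimited_series(rng: np.random.Generator, n: int, tr: float, bands) -> np.ndarray:
    """Sum of band-limited Gaussian processes, normalized to unit SD."""
    freqs = np.fft.rfftfreq(n, d=tr)
    total = np.zeros(n)
    for lo, hi in bands:
        spectrum = np.fft.rfft(rng.standard_normal(n))
        keep = (freqs >= lo) & (freqs <= hi)
        if not keep.any():
            continue
        spectrum[~keep] = 0.0
        comp = np.fft.irfft(spectrum, n)
        sd = comp.std()
        if sd > 0:
            total += comp / sd
    sd = total.std()
    return total / sd if sd > 0 else total


def _session_state(config: SimulationConfig, subject: int, session: int) -> dict:
    """Session-level draws plus the RNG positioned for the voxel noise field.

    The draw order is fixed (amplitude, HRF jitter, confound, motion, drift)
    so that GroundTruth assembly and data simulation consume identical values.
    """
    sub = _subject_draws(config, subject)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_STREAM_SESSION, subject, session))
    )
    w = rng.normal(0.0, np.sqrt(config.sigma2_within))
    lat_j = rng.normal(0.0, config.hrf_latency_session_sd)
    disp_j = rng.normal(0.0, config.hrf_dispersion_session_sd)
    confound = _bandlimited_series(
        rng, config.n_volumes, config.tr_seconds, config.physio_spectrum
    )
    walk = np.cumsum(rng.normal(0.0, 0.05, size=(config.n_volumes, 6)), axis=0)
    motion = config.motion_amplitude * gaussian_filter1d(walk, sigma=3.0, axis=0)
    drift_slope = rng.normal(0.0, 1.0)

    base_hrf = HrfParams(dt=config.tr_seconds / 16.0)
    peak_delay = float(np.clip(base_hrf.peak_delay + sub["latency"] + lat_j, 2.0, 12.0))
    peak_disp = float(
        np.clip(base_hrf.peak_disp * np.exp(sub["log_disp"] + disp_j), 0.25, 4.0)
    )
    amplitude = config.amplitude_mean * (1.0 + sub["b"] + w)
    return {
        "amplitude": amplitude,
        "hrf": replace(base_hrf, peak_delay=peak_delay, peak_disp=peak_disp),
        "confound": confound,
        "motion": motion,
        "drift_slope": drift_slope,
        "rng": rng,
    }


def _stationary_ar1(
    rng: np.random.Generator, rho: float, sigma2: float, shape: tuple
) -> np.ndarray:
    """Exact stationary AR(1) field along axis 0 with marginal variance sigma2."""
    n_t = shape[0]
    sigma = np.sqrt(sigma2)
    if sigma == 0:
        return np.zeros(shape)
    innov_sd = sigma * np.sqrt(1.0 - rho ** 2)
    x = np.empty(shape)
    x[0] = rng.normal(0.0, sigma, size=shape[1:])
    innov = rng.normal(0.0, innov_sd, size=(n_t - 1,) + shape[1:])
    for t in range(1, n_t):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return x


def simulate_session(
    geometry: PhantomGeometry,
    schedule: EventSchedule,
    config: SimulationConfig,
    subject_id: int,
    session_id: int,
) -> BoldRun:
    """Simulate one subject-session 4D BOLD run.

    Deterministic given ``(config.seed, subject_id, session_id)``.
    """
    T = config.n_volumes
    tr = config.tr_seconds
    if schedule.span > T * tr:
        raise ValueError(
            f"paradigm spans {schedule.span:.1f}s but the run is only {T * tr:.1f}s:"
            " the schedule would be truncated"
        )
    state = _session_state(config, subject_id, session_id)
    labels = geometry.region_labels.ravel()
    brain = geometry.brain_mask.ravel()
    highvar = geometry.highvar_mask.ravel()
    n_vox = labels.size

    data = np.zeros((T, n_vox))
    data[:, brain] = _BASELINE

    # task signal in the active regions
    signal = _task_signal(schedule, config, state, T, tr)
    if signal is not None:
        data[:, labels == VISUAL] += signal[:, None]
        data[:, labels == AMYGDALA] += config.amygdala_scale * signal[:, None]

    # shared physiological confound
    if config.physio_amplitude > 0:
        loading = np.zeros(n_vox)
        loading[brain] = config.physio_gm_fraction
        loading[(labels == WHITE) | (labels == CSF) | highvar] = 1.0
        data += config.physio_amplitude * np.outer(state["confound"], loading)

    if config.drift_amplitude > 0:
        trend = np.linspace(-1.0, 1.0, T) * config.drift_amplitude * state["drift_slope"]
        data[:, brain] += trend[:, None]

    if config.motion_leak > 0:
        grad = _edge_weight(geometry)
        leak_series = state["motion"] - state["motion"].mean(axis=0)
        data += config.motion_leak * np.outer(leak_series.sum(axis=1), grad)

    if config.sigma2_noise > 0:
        noise = _stationary_ar1(
            state["rng"], config.ar1_rho, config.sigma2_noise, (T, int(brain.sum()))
        )
        data[:, brain] += noise

    vol = data.T.reshape(geometry.shape + (T,))
    if config.smoothing_fwhm_mm > 0:
        sigma_vox = config.smoothing_fwhm_mm / (2.354820045 * geometry.voxel_size)
        vol = np.stack(
            [gaussian_filter(vol[..., t], sigma_vox) for t in range(T)], axis=-1
        )
    return BoldRun(
        data=vol,
        tr_seconds=tr,
        subject_id=subject_id,
        session_id=session_id,
        motion=state["motion"],
        affine=geometry.affine,
    )


def _task_signal(schedule, config, state, T, tr) -> np.ndarray | None:
    """Combined emotion + shapes response time course for active voxels."""
    amp = state["amplitude"]
    shape_amp = config.shape_response_scale * config.amplitude_mean
    if amp == 0 and shape_amp == 0:
        return None
    kernel = canonical_hrf(state["hrf"])
    frame = schedule.frame
    signal = np.zeros(T)
    for cond in set(frame["trial_type"]):
        sel = frame[frame["trial_type"] == cond]
        reg = condition_regressor(
            sel["onset"].to_numpy(), sel["duration"].to_numpy(),
            T, tr, kernel, state["hrf"].dt,
        )
        if cond in EMOTIONS:
            signal += amp * reg
        elif cond == SHAPES:
            signal += shape_amp * reg
        # identity-morph control blocks evoke the shapes-level response
        elif cond == IDENTITY:
            signal += shape_amp * reg
    return signal


def _edge_weight(geometry: PhantomGeometry) -> np.ndarray:
    base = np.where(geometry.brain_mask, _BASELINE, 0.0)
    gx, gy, gz = np.gradient(base)
    mag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2).ravel()
    peak = mag.max()
    return mag / peak if peak > 0 else mag


class Cohort:
    """Lazy collection of the 2 x n_subjects runs of one simulated study."""

    def __init__(
        self,
        config: SimulationConfig,
        geometry: PhantomGeometry,
        schedule: EventSchedule,
    ) -> None:
        self.config = config
        self.geometry = geometry
        self.schedule = schedule

    def __len__(self) -> int:
        return 2 * self.config.n_subjects

    @property
    def subjects(self) -> list:
        return list(range(self.config.n_subjects))

    @property
    def sessions(self) -> tuple:
        return (1, 2)

    def get_run(self, subject_id: int, session_id: int) -> BoldRun:
        return simulate_session(
            self.geometry, self.schedule, self.config, subject_id, session_id
        )

    def runs(self):
        for subject in self.subjects:
            for session in self.sessions:
                yield self.get_run(subject, session)

    def write(self, path) -> None:
        """Write the cohort as NIfTI runs + events TSV + motion text files."""
        from . import io as bio

        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        self.schedule.to_tsv(root / "events.tsv")
        (root / "config.json").write_text(self.config.to_json())
        masks = root / "masks"
        masks.mkdir(exist_ok=True)
        bio.save_nifti(
            self.geometry.region_labels.astype(np.int16),
            self.geometry.affine, masks / "labels.nii.gz",
        )
        bio.save_nifti(
            self.geometry.highvar_mask.astype(np.uint8),
            self.geometry.affine, masks / "highvar.nii.gz",
        )
        for run in self.runs():
            sub_dir = root / f"sub-{run.subject_id + 1:02d}" / f"ses-{run.session_id}"
            sub_dir.mkdir(parents=True, exist_ok=True)
            bio.save_nifti(run.data, run.affine, sub_dir / "bold.nii.gz")
            np.savetxt(sub_dir / "motion.txt", run.motion, fmt="%.8f")


def simulate_cohort(
    config: SimulationConfig,
    geometry: PhantomGeometry | None = None,
    schedule: EventSchedule | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Simulate a two-session cohort and return it with its ground truth."""
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    geometry = geometry or default_geometry()
    schedule = schedule or make_paradigm(
        config.seed, config.n_volumes, config.tr_seconds
    )
    n = config.n_subjects
    amplitudes = np.empty((n, 2))
    confounds = np.empty((n, 2, config.n_volumes))
    hrf_rows = []
    for s in range(n):
        for j, session in enumerate((1, 2)):
            state = _session_state(config, s, session)
            amplitudes[s, j] = state["amplitude"]
            confounds[s, j] = state["confound"]
            hrf_rows.append(
                (s, session, state["hrf"].peak_delay, state["hrf"].peak_disp)
            )
    truth = GroundTruth(
        true_icc_by_region={"visual": config.true_icc, "amygdala": config.true_icc},
        subject_amplitudes=amplitudes,
        shape_amplitude=config.shape_response_scale * config.amplitude_mean,
        confound_series=confounds,
        subject_hrf_params=pd.DataFrame(
            hrf_rows, columns=["subject", "session", "peak_delay", "peak_disp"]
        ),
    )
    return Cohort(config, geometry, schedule), truth
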