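"""End-to-end study orchestration.

simulate -> fit all pipelines x two sessions -> activation maps and overlap
ROI -> voxelwise ICC and mvICC summaries -> residual diagnostics and
violation tables -> Friedman/Nemenyi pipeline comparisons.

The run loop simulates each subject-session once and fits every pipeline to
it; diagnostics require the task-derived overlap ROI (known only after all
session-1 fits), so a second deterministic pass re-simulates runs for
residual testing. All stages derive their randomness from the single study
seed, and a manifest records the configuration hash, seed and version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as bio
from .compare import ComparisonSummary, compare_pipelines
from .design import PipelineSpec, build_design, contrast_vector
from .diagnostics import DiagnosticReport, run_diagnostics, summarize_violations
from .glm import fit_voxelwise
from .maps import RoiMask, overlap_mask, threshold_clusters
from .nuisance import mcompcor_regressor, select_pooled_voxels, temporal_sd_map
from .phantom import (
    BoldRun,
    Cohort,
    EventSchedule,
    PhantomGeometry,
    SimulationConfig,
    default_geometry,
    make_paradigm,
    simulate_cohort,
)
from .reliability import IccMap, cicchetti_category, icc_map, mvicc

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResults", "run_study", "load_real_inputs", "DiskCohort"]


@dataclass
class StudyConfig:
    """Configuration of one full simulated study."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    pipeline_names: tuple = ("default", "flexhrf", "mcompcor", "combined")
    alpha: float = 0.05
    voxel_p: float = 0.001
    min_extent: int = 10
    highpass_cutoff: float = 128.0
    geometry_shape: tuple = (20, 20, 12)
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.pipeline_names)) != len(self.pipeline_names):
            raise ValueError("pipeline names must be unique")
        # single root seed: the study seed overrides the simulation seed
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["simulation"]["physio_spectrum"] = [
            list(b) for b in payload["simulation"]["physio_spectrum"]
        ]
        import json

        return json.dumps(payload, sort_keys=True)


@dataclass
class StudyResults:
    """Everything `run_study` computes, plus the provenance manifest."""

    config: StudyConfig
    geometry: PhantomGeometry
    schedule: EventSchedule
    ground_truth: object | None
    contrast_maps: dict      # pipeline -> (n_subjects, 2, n_brain_voxels)
    group_t_session1: dict   # pipeline -> 3D t-map
    activation_masks: dict   # pipeline -> RoiMask
    overlap_roi: RoiMask
    icc_maps: dict           # pipeline -> IccMap
    mvicc_table: pd.DataFrame
    violation_table: pd.DataFrame
    comparisons: dict        # "t" | "icc" -> ComparisonSummary; "violations" -> dict
    manifest: dict
    cluster_tables: dict = field(default_factory=dict)   # pipeline -> DataFrame
    diagnostics_frame: pd.DataFrame | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "reports").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
        bio.write_json(self.manifest, out / "manifest.json")
        self.mvicc_table.to_csv(out / "reports" / "mvicc.csv")
        self.violation_table.to_csv(out / "reports" / "violations.csv")
        if self.diagnostics_frame is not None:
            self.diagnostics_frame.to_csv(
                out / "reports" / "diagnostics.tsv", sep="\t", index=False
            )
        for key, comp in self.comparisons.items():
            if isinstance(comp, ComparisonSummary):
                (out / "reports" / f"comparison_{key}.json").write_text(comp.to_json())
            elif isinstance(comp, dict):
                for sub, c in comp.items():
                    (out / "reports" / f"comparison_{key}_{sub}.json").write_text(
                        c.to_json()
                    )
        affine = self.geometry.affine
        bio.save_nifti(
            self.overlap_roi.mask.astype(np.uint8), affine, out / "masks" / "overlap.nii.gz"
        )
        bio.save_nifti(
            self.geometry.amygdala_mask.astype(np.uint8),
            affine,
            out / "masks" / "amygdala.nii.gz",
        )
        for name, roi in self.activation_masks.items():
            pdir = out / name
            pdir.mkdir(exist_ok=True)
            bio.save_nifti(
                roi.mask.astype(np.uint8), affine, pdir / "activation_ses-1.nii.gz"
            )
            bio.save_nifti(self.group_t_session1[name], affine, pdir / "group_t_ses-1.nii.gz")
            bio.save_nifti(self.icc_maps[name].icc, affine, pdir / "icc.nii.gz")
            if name in self.cluster_tables:
                self.cluster_tables[name].to_csv(
                    pdir / "clusters_ses-1.tsv", sep="\t", index=False
                )


def _mcompcor_for_run(run: BoldRun, geometry: PhantomGeometry) -> np.ndarray:
    sd = temporal_sd_map(run.data, geometry.brain_mask)
    selection = select_pooled_voxels(sd, geometry.brain_mask, geometry.wm_csf_mask)
    return mcompcor_regressor(run.data, selection)


def _fit_run(run, geometry, schedule, spec, highpass, mcompcor=None, prewhiten=True):
    series = mcompcor if spec.use_mcompcor else None
    design = build_design(
        schedule,
        spec,
        run.motion,
        run.n_volumes,
        run.tr_seconds,
        mcompcor_series=series,
        highpass_cutoff=highpass,
    )
    weights = contrast_vector(design)
    return fit_voxelwise(
        design, run, contrast_weights=weights, mask=geometry.brain_mask,
        prewhiten_data=prewhiten,
    )


def _group_t(contrasts: np.ndarray) -> np.ndarray:
    """One-sample t across subjects for each voxel (session-1 group map)."""
    n = contrasts.shape[0]
    mean = contrasts.mean(axis=0)
    sd = contrasts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)


def run_study(
    config: StudyConfig,
    cohort=None,
    resume: bool = False,
    write_outputs: bool = True,
) -> StudyResults:
    """Run the full study and return (and optionally write) all results.

    ``cohort`` may be a pre-built Cohort or DiskCohort (real or previously
    simulated data); by default a phantom cohort is simulated from the config.
    An existing non-empty output directory is refused unless ``resume`` is
    set, in which case outputs are recomputed and overwritten.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None and out.exists() and any(out.iterdir()) and not resume:
        raise FileExistsError(
            f"output directory {out} already contains results; pass resume=True "
            "to overwrite"
        )
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    ground_truth = None
    if cohort is None:
        geometry = default_geometry(shape=config.geometry_shape)
        schedule = make_paradigm(
            config.seed, config.simulation.n_volumes, config.simulation.tr_seconds
        )
        cohort, ground_truth = simulate_cohort(config.simulation, geometry, schedule)
    geometry = cohort.geometry
    schedule = cohort.schedule
    subjects = cohort.subjects
    n_sub = len(subjects)
    if n_sub < 2:
        raise ValueError("the study requires at least two subjects")
    pipelines = [PipelineSpec.from_name(name) for name in config.pipeline_names]
    needs_mc = any(p.use_mcompcor for p in pipelines)
    brain = geometry.brain_mask
    n_brain = int(brain.sum())

    # ------------------------------------------------------------------ fit
    contrast_maps = {p.name: np.empty((n_sub, 2, n_brain)) for p in pipelines}
    df_error: dict[str, int] = {}
    for si, subject in enumerate(subjects):
        for ji, session in enumerate(cohort.sessions):
            run = cohort.get_run(subject, session)
            mc = _mcompcor_for_run(run, geometry) if needs_mc else None
            for spec in pipelines:
                fit = _fit_run(
                    run, geometry, schedule, spec, config.highpass_cutoff, mc
                )
                contrast_maps[spec.name][si, ji] = fit.contrast_value
                df_error[spec.name] = fit.df_error
    timings["fit"] = time.perf_counter() - t0
    logger.info("fit stage done in %.1fs", timings["fit"])

    # ----------------------------------------------------------------- maps
    t1 = time.perf_counter()
    group_t = {}
    activation = {}
    cluster_tables = {}
    for spec in pipelines:
        tvec = _group_t(contrast_maps[spec.name][:, 0, :])
        tvol = np.zeros(geometry.shape)
        tvol[brain] = tvec
        group_t[spec.name] = tvol
        result = threshold_clusters(
            tvol, n_sub - 1, config.voxel_p, config.min_extent, name=spec.name
        )
        activation[spec.name] = result.mask
        cluster_tables[spec.name] = result.table
    overlap = overlap_mask({n: activation[n] for n in config.pipeline_names})
    amygdala = RoiMask(geometry.amygdala_mask, "amygdala", "anatomical")
    rois = {"visual_overlap": overlap.mask, "amygdala": amygdala.mask}
    timings["maps"] = time.perf_counter() - t1

    # ------------------------------------------------------------------ icc
    t2 = time.perf_counter()
    icc_maps_: dict[str, IccMap] = {}
    mv_rows = []
    for spec in pipelines:
        maps_ = contrast_maps[spec.name]
        imap = icc_map(
            maps_[:, 0, :], maps_[:, 1, :], brain,
            subjects_t1=subjects, subjects_t2=subjects,
        )
        icc_maps_[spec.name] = imap
        for roi_name, roi in rois.items():
            value = mvicc(imap, roi)
            mv_rows.append(
                (roi_name, spec.name, value, int(roi.sum()), cicchetti_category(value))
            )
    mvicc_table = pd.DataFrame(
        mv_rows, columns=["roi", "pipeline", "mvicc", "n_voxels", "category"]
    ).set_index(["roi", "pipeline"])
    timings["icc"] = time.perf_counter() - t2

    # ---------------------------------------------------------- diagnostics
    t3 = time.perf_counter()
    brain_flat = brain.ravel()
    union_mask = np.zeros(geometry.shape, dtype=bool)
    for roi in rois.values():
        union_mask |= roi
    union_cols = np.flatnonzero(union_mask.ravel()[brain_flat])
    roi_sel = {
        name: np.isin(union_cols, np.flatnonzero(roi.ravel()[brain_flat]))
        for name, roi in rois.items()
    }
    reports: dict[str, list[DiagnosticReport]] = {name: [] for name in rois}
    overlap_flags: dict[str, list] = {p.name: [] for p in pipelines}
    diag_frames: list = []
    for si, subject in enumerate(subjects):
        per_session_flags = {p.name: [] for p in pipelines}
        for session in cohort.sessions:
            run = cohort.get_run(subject, session)
            mc = _mcompcor_for_run(run, geometry) if needs_mc else None
            for spec in pipelines:
                fit = _fit_run(
                    run, geometry, schedule, spec, config.highpass_cutoff, mc
                )
                report = run_diagnostics(
                    fit,
                    voxel_columns=union_cols,
                    alpha=config.alpha,
                    pipeline_name=spec.name,
                    subject_id=subject,
                    session_id=session,
                )
                diag_frames.append(report.to_frame())
                for roi_name, sel in roi_sel.items():
                    reports[roi_name].append(
                        DiagnosticReport(
                            p_normality=report.p_normality[sel],
                            p_homoscedasticity=report.p_homoscedasticity[sel],
                            p_independence=report.p_independence[sel],
                            alpha=config.alpha,
                            pipeline_name=spec.name,
                            subject_id=subject,
                            session_id=session,
                        )
                    )
                sel = roi_sel["visual_overlap"]
                flags = np.stack(
                    [
                        report.violated_normality[sel],
                        report.violated_homoscedasticity[sel],
                        report.violated_independence[sel],
                    ]
                )
                per_session_flags[spec.name].append(flags)
        for spec in pipelines:
            overlap_flags[spec.name].append(
                np.mean(per_session_flags[spec.name], axis=0)
            )
    tables = []
    for roi_name in rois:
        tab = summarize_violations(reports[roi_name])
        tab.insert(0, "roi", roi_name)
        tables.append(tab.reset_index())
    violation_table = pd.concat(tables, ignore_index=True).set_index(
        ["roi", "pipeline"]
    )
    timings["diagnostics"] = time.perf_counter() - t3

    # -------------------------------------------------------------- compare
    t4 = time.perf_counter()
    comparisons: dict = {}
    if len(pipelines) >= 2:
        overlap_cols_sel = roi_sel["visual_overlap"]
        overlap_cols = union_cols[overlap_cols_sel]
        comparisons["t"] = compare_pipelines(
            {
                name: group_t[name][brain][overlap_cols]
                for name in config.pipeline_names
            },
            stat_kind="t_value",
            alpha=config.alpha,
        )
        comparisons["icc"] = compare_pipelines(
            {
                name: icc_maps_[name].icc[brain][overlap_cols]
                for name in config.pipeline_names
            },
            stat_kind="icc",
            alpha=config.alpha,
        )
        comparisons["violations"] = {}
        order = ("normality", "homoscedasticity", "independence")
        for ai, assumption in enumerate(order):
            comparisons["violations"][assumption] = compare_pipelines(
                {
                    name: np.array(
                        [subj_flags[ai].mean() for subj_flags in overlap_flags[name]]
                    )
                    for name in config.pipeline_names
                },
                stat_kind="violation_proportion",
                block_kind="subject",
                alpha=config.alpha,
            )
    else:
        logger.info("single pipeline configured; comparison stage skipped")
    timings["compare"] = time.perf_counter() - t4

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "n_subjects": n_sub,
        "pipelines": list(config.pipeline_names),
        "df_error": df_error,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    results = StudyResults(
        config=config,
        geometry=geometry,
        schedule=schedule,
        ground_truth=ground_truth,
        contrast_maps=contrast_maps,
        group_t_session1=group_t,
        activation_masks=activation,
        overlap_roi=overlap,
        icc_maps=icc_maps_,
        mvicc_table=mvicc_table,
        violation_table=violation_table,
        comparisons=comparisons,
        manifest=manifest,
        cluster_tables=cluster_tables,
        diagnostics_frame=pd.concat(diag_frames, ignore_index=True),
    )
    if out is not None and write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        results.write(out)
    return results


class DiskCohort:
    """Cohort interface over data laid out on disk (as written by Cohort.write)."""

    def __init__(self, root, geometry, schedule, subjects, tr_seconds) -> None:
        self.root = Path(root)
        self.geometry = geometry
        self.schedule = schedule
        self._subjects = subjects
        self.tr_seconds = tr_seconds
        self.sessions = (1, 2)

    @property
    def subjects(self) -> list:
        return list(self._subjects)

    def __len__(self) -> int:
        return 2 * len(self._subjects)

    def get_run(self, subject_id: int, session_id: int) -> BoldRun:
        sub_dir = self.root / f"sub-{subject_id + 1:02d}" / f"ses-{session_id}"
        data, affine = bio.load_nifti(sub_dir / "bold.nii.gz")
        motion_path = sub_dir / "motion.txt"
        if not motion_path.exists():
            raise FileNotFoundError(
                f"missing motion file for sub-{subject_id + 1:02d} ses-{session_id}"
            )
        motion = bio.read_motion(motion_path, data.shape[-1])
        return BoldRun(
            data=np.asarray(data, dtype=float),
            tr_seconds=self.tr_seconds,
            subject_id=subject_id,
            session_id=session_id,
            motion=motion,
            affine=affine,
        )

    def runs(self):
        for subject in self._subjects:
            for session in self.sessions:
                yield self.get_run(subject, session)


def load_real_inputs(root, tr_seconds: float | None = None) -> DiskCohort:
    """Load study inputs (NIfTI runs, events TSV, motion text, masks) from disk.

    Expects the layout written by ``Cohort.write``: an ``events.tsv``, a
    ``masks/labels.nii.gz`` tissue-label image, and per-run
    ``sub-XX/ses-Y/{bold.nii.gz,motion.txt}``. Every subject must have both
    sessions; orphans are reported. The events span must fit inside each run.
    """
    root = Path(root)
    events_path = root / "events.tsv"
    if not events_path.exists():
        raise FileNotFoundError(f"no events.tsv under {root}")
    schedule = EventSchedule.from_tsv(events_path)
    labels, affine = bio.load_nifti(root / "masks" / "labels.nii.gz")
    labels = np.asarray(labels, dtype=np.int16)
    highvar_path = root / "masks" / "highvar.nii.gz"
    if highvar_path.exists():
        highvar = np.asarray(bio.load_nifti(highvar_path)[0], dtype=bool)
    else:
        highvar = np.zeros(labels.shape, dtype=bool)
    geometry = PhantomGeometry(
        shape=labels.shape,
        voxel_size=float(abs(affine[0, 0])),
        region_labels=labels,
        brain_mask=labels > 0,
        highvar_mask=highvar,
    )
    config_path = root / "config.json"
    if tr_seconds is None:
        if config_path.exists():
            tr_seconds = SimulationConfig.from_json(config_path.read_text()).tr_seconds
        else:
            raise ValueError("tr_seconds not given and no config.json found")

    found: dict[int, set] = {}
    for sub_dir in sorted(root.glob("sub-*")):
        sid = int(sub_dir.name.split("-")[1]) - 1
        for ses_dir in sorted(sub_dir.glob("ses-*")):
            found.setdefault(sid, set()).add(int(ses_dir.name.split("-")[1]))
    if not found:
        raise FileNotFoundError(f"no sub-*/ses-* runs under {root}")
    orphans = sorted(s for s, sessions in found.items() if sessions != {1, 2})
    if orphans:
        raise ValueError(
            "subjects present in only one session: "
            + ", ".join(f"sub-{s + 1:02d}" for s in orphans)
        )
    cohort = DiskCohort(root, geometry, schedule, sorted(found), tr_seconds)
    probe = cohort.get_run(cohort.subjects[0], 1)
    if schedule.span > probe.n_volumes * tr_seconds:
        raise ValueError(
            f"events span {schedule.span:.1f}s exceeds run length "
            f"{probe.n_volumes * tr_seconds:.1f}s"
        )
    return cohort
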