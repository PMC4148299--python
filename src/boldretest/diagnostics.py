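"""Per-voxel residual assumption tests and violation summaries.

Three classical checks of GLM error assumptions, applied voxelwise to the
(whitened) residuals of each fitted run:

* normality — Shapiro-Wilk;
* homoscedasticity — Breusch-Pagan (n R^2 of the auxiliary regression of the
  squared residuals on the design, chi-square with one df per non-intercept
  column);
* independence — Durbin-Watson, with a two-sided p-value from a normal
  approximation whose mean and variance are the *exact* small-sample moments
  of d given the design (computed from the residual projection matrix).

A violation is a p-value below alpha (0.05 by default); proportions are
reported raw, with no across-voxel multiplicity correction, because the
summary of interest is the violation rate itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiagnosticReport",
    "shapiro_wilk",
    "breusch_pagan",
    "durbin_watson",
    "dw_design_moments",
    "run_diagnostics",
    "summarize_violations",
]

ASSUMPTIONS = ("normality", "homoscedasticity", "independence")


@dataclass
class DiagnosticReport:
    """Assumption-test p-values for the voxels of one fitted run."""

    p_normality: np.ndarray
    p_homoscedasticity: np.ndarray
    p_independence: np.ndarray
    alpha: float = 0.05
    pipeline_name: str = ""
    subject_id: int | None = None
    session_id: int | None = None
    voxel_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ASSUMPTIONS:
            p = getattr(self, f"p_{name}")
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"p_{name} outside [0, 1]")

    @property
    def violated_normality(self) -> np.ndarray:
        return self.p_normality < self.alpha

    @property
    def violated_homoscedasticity(self) -> np.ndarray:
        return self.p_homoscedasticity < self.alpha

    @property
    def violated_independence(self) -> np.ndarray:
        return self.p_independence < self.alpha

    def to_frame(self) -> pd.DataFrame:
        n = len(self.p_normality)
        return pd.DataFrame(
            {
                "pipeline": [self.pipeline_name] * n,
                "subject": [self.subject_id] * n,
                "session": [self.session_id] * n,
                "voxel": (
                    self.voxel_indices
                    if self.voxel_indices is not None
                    else np.arange(n)
                ),
                "p_normality": self.p_normality,
                "p_homoscedasticity": self.p_homoscedasticity,
                "p_independence": self.p_independence,
            }
        )


def shapiro_wilk(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one residual series (3 <= n <= 5000)."""
    x = np.asarray(residuals, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single residual series")
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant residual series")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def breusch_pagan(residuals: np.ndarray, design: np.ndarray) -> tuple[float, float]:
    """Breusch-Pagan LM statistic and p-value for one residual series.

    LM = n * R^2 of the auxiliary regression of squared residuals on the
    design (an intercept is appended if absent); the reference distribution is
    chi-square with df = number of non-intercept columns.
    """
    e = np.asarray(residuals, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != e.shape[0]:
        raise ValueError("design rows must match residual length")
    X = _with_intercept(X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient auxiliary design")
    lm, p = _bp_core(e[:, None], X)
    return float(lm[0]), float(p[0])


def _with_intercept(X: np.ndarray) -> np.ndarray:
    col_const = np.all(X == X[0], axis=0) & (X[0] != 0)
    if col_const.any():
        return X
    return np.column_stack([X, np.ones(X.shape[0])])


def _bp_core(resid: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Breusch-Pagan over the columns of ``resid`` (T x V)."""
    n, p = X.shape
    z = resid ** 2
    zc = z - z.mean(axis=0)
    beta = np.linalg.lstsq(X, z, rcond=None)[0]
    rss = np.sum((z - X @ beta) ** 2, axis=0)
    tss = np.sum(zc ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    lm = n * r2
    df = p - 1
    pval = stats.chi2.sf(lm, df)
    pval = np.where(tss > 0, pval, 1.0)
    return lm, pval


def dw_design_moments(design: np.ndarray) -> tuple[float, float]:
    """Exact null mean and SD of the Durbin-Watson d for a given design.

    With residual-maker M = I - X(X'X)^-1 X' and first-difference quadratic
    form A, d = u'MAMu / u'Mu. Its exact moments under iid normal errors
    follow from the eigenvalues of MAM restricted to the residual space:
    E d = tr(B)/nu and E d^2 = (2 tr(B^2) + tr(B)^2) / (nu (nu + 2)),
    with B = MAM and nu = n - rank(X).
    """
    X = np.asarray(design, dtype=float)
    n = X.shape[0]
    rank = np.linalg.matrix_rank(X)
    nu = n - rank
    if nu < 2:
        raise ValueError("not enough error degrees of freedom for DW moments")
    A = 2.0 * np.eye(n)
    A[0, 0] = A[-1, -1] = 1.0
    idx = np.arange(n - 1)
    A[idx, idx + 1] = -1.0
    A[idx + 1, idx] = -1.0
    M = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    B = M @ A @ M
    tr_b = np.trace(B)
    tr_b2 = np.sum(B * B.T)
    mean = tr_b / nu
    second = (2.0 * tr_b2 + tr_b ** 2) / (nu * (nu + 2.0))
    var = max(second - mean ** 2, 1e-12)
    return float(mean), float(np.sqrt(var))


def durbin_watson(
    residuals: np.ndarray, design: np.ndarray | None = None
) -> tuple[float, float]:
    """Durbin-Watson d and a two-sided normal-approximation p-value.

    Without a design, the large-sample reference N(2, 4/n) is used; with one,
    the exact design-conditional moments from :func:`dw_design_moments`.
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim != 1:
        raise ValueError("expected a single residual series")
    if e.size < 3:
        raise ValueError("need at least three residuals")
    den = float(np.sum(e ** 2))
    if den == 0.0:
        raise ValueError("constant (all-zero) residual series")
    d = float(np.sum(np.diff(e) ** 2) / den)
    if design is None:
        mean, sd = 2.0, np.sqrt(4.0 / e.size)
    else:
        mean, sd = dw_design_moments(design)
    p = 2.0 * stats.norm.sf(abs(d - mean) / sd)
    return d, float(min(p, 1.0))


def run_diagnostics(
    fit,
    voxel_columns: np.ndarray | None = None,
    alpha: float = 0.05,
    pipeline_name: str = "",
    subject_id: int | None = None,
    session_id: int | None = None,
) -> DiagnosticReport:
    """All three assumption tests over the voxels of one GlmFit.

    ``voxel_columns`` selects columns of the fitted data matrix (defaults to
    all). Tests run on the model's own residuals on the scale the model was
    fitted: for a prewhitened fit these are the whitened residuals, so a
    successful whitening step passes the independence check and any remaining
    structure flags misspecification. To diagnose unwhitened residuals, fit
    with ``prewhiten_data=False``.
    """
    resid = fit.residuals
    X = fit.whitened_design
    if voxel_columns is not None:
        resid = resid[:, voxel_columns]
    n_vox = resid.shape[1]

    p_norm = np.empty(n_vox)
    for v in range(n_vox):
        p_norm[v] = stats.shapiro(resid[:, v]).pvalue

    Xa = _with_intercept(X)
    _, p_het = _bp_core(resid, Xa)

    den = np.sum(resid ** 2, axis=0)
    num = np.sum(np.diff(resid, axis=0) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    mean, sd = dw_design_moments(X)
    p_ind = np.minimum(2.0 * stats.norm.sf(np.abs(d - mean) / sd), 1.0)

    return DiagnosticReport(
        p_normality=p_norm,
        p_homoscedasticity=p_het,
        p_independence=p_ind,
        alpha=alpha,
        pipeline_name=pipeline_name,
        subject_id=subject_id,
        session_id=session_id,
        voxel_indices=voxel_columns,
    )


def summarize_violations(reports: list) -> pd.DataFrame:
    """Violation proportions per pipeline and assumption across reports.

    The denominator for each pipeline x assumption cell is the total number of
    (subject, session, voxel) fits contributing to it. All reports must share
    one alpha.
    """
    if not reports:
        raise ValueError("no diagnostic reports to summarize")
    alphas = {r.alpha for r in reports}
    if len(alphas) != 1:
        raise ValueError(f"mixed alpha levels across reports: {sorted(alphas)}")
    rows = {}
    for report in reports:
        key = report.pipeline_name
        cell = rows.setdefault(key, {a: [0, 0] for a in ASSUMPTIONS})
        for a in ASSUMPTIONS:
            flags = getattr(report, f"violated_{a}")
            cell[a][0] += int(flags.sum())
            cell[a][1] += int(flags.size)
    table = pd.DataFrame(
        {
            a: {pipe: rows[pipe][a][0] / rows[pipe][a][1] for pipe in rows}
            for a in ASSUMPTIONS
        }
    )
    table.index.name = "pipeline"
    return table
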