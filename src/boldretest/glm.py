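"""Prewhitened voxelwise general linear models.

The noise model is global AR(1) + white noise, handled in two passes in the
spirit of Cochrane-Orcutt: an ordinary least-squares fit yields residuals, the
lag-1 autocorrelation is pooled over all in-mask voxels into a single global
estimate, both sides of the model are prewhitened by the inverse square root
of the implied AR(1) correlation matrix, and the model is refit by least
squares. High-pass filtering is handled by drift columns inside the same
linear model, so there is exactly one linear system per voxel.

`VoxelwiseGLM` is the model object (data + design); `fit()` returns a
`GlmFit` results object carrying betas, the contrast estimate and t-map,
whitened residuals and degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as slinalg

from .design import DesignMatrix

__all__ = [
    "GlmFit",
    "VoxelwiseGLM",
    "estimate_global_ar1",
    "prewhiten",
    "fit_voxelwise",
]


def estimate_global_ar1(residuals: np.ndarray, design: np.ndarray | None = None) -> float:
    """Pooled lag-1 autocorrelation of (time x voxel) residuals.

    Sums the lag-1 cross-products and squared residuals across all voxels
    before taking the ratio; the result is clipped to (-0.99, 0.99).

    Least-squares residuals are a projection of the errors, which biases
    their lag-1 autocorrelation (drift and other smooth regressors soak up
    low-frequency power). When ``design`` is given, the raw pooled estimate
    is corrected by inverting the map rho -> E[pooled residual lag-1 | X]
    computed from the design's projection matrix, so the returned value
    estimates the AR(1) parameter of the *errors*, not of the residuals.
    """
    e = np.asarray(residuals, dtype=float)
    if e.ndim == 1:
        e = e[:, None]
    if e.shape[0] < 3:
        raise ValueError("need at least three time points to estimate AR(1)")
    e = e - e.mean(axis=0)
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise ValueError("constant residual series: autocorrelation undefined")
    num = float(np.sum(e[1:] * e[:-1]))
    raw = float(np.clip(num / denom, -0.99, 0.99))
    if design is None:
        return raw
    return _invert_residual_ar1(raw, np.asarray(design, dtype=float))


def expected_residual_ar1(rho: float, X: np.ndarray) -> float:
    """E[pooled lag-1 autocorrelation of OLS residuals] under AR(1) errors.

    With hat matrix H = X (X'X)^-1 X', residual maker M = I - H, AR(1)
    correlation matrix S and the symmetric lag-1 form L (ones on the first
    off-diagonals, halved), the expectation of the pooled ratio statistic is
    approximated by the ratio of expectations

        tr(L M S M) / tr(M S M)

    evaluated with O(T^2 p) matrix products.
    """
    T, p = X.shape
    k_inv = np.linalg.inv(X.T @ X)
    lags = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    S = rho ** lags if rho != 0.0 else np.eye(T)
    SX = S @ X
    XtSX = X.T @ SX
    # L X with L = 0.5 * (first off-diagonals)
    LX = np.zeros_like(X)
    LX[:-1] += 0.5 * X[1:]
    LX[1:] += 0.5 * X[:-1]
    XtLX = X.T @ LX
    tr_LS = (T - 1) * rho
    tr_LHS = np.trace(k_inv @ (SX.T @ LX))
    tr_LHSH = np.trace(XtLX @ k_inv @ XtSX @ k_inv)
    num = tr_LS - 2.0 * tr_LHS + tr_LHSH
    den = T - np.trace(k_inv @ XtSX)
    return float(num / den)


def _invert_residual_ar1(raw: float, X: np.ndarray, n_steps: int = 3) -> float:
    """Secant inversion of ``expected_residual_ar1`` around the raw estimate."""
    rho0 = raw
    g0 = expected_residual_ar1(rho0, X)
    rho1 = float(np.clip(rho0 + (raw - g0), -0.99, 0.99))
    for _ in range(n_steps - 1):
        g1 = expected_residual_ar1(rho1, X)
        if abs(g1 - g0) < 1e-12:
            break
        rho2 = rho1 + (raw - g1) * (rho1 - rho0) / (g1 - g0)
        rho0, g0, rho1 = rho1, g1, float(np.clip(rho2, -0.99, 0.99))
    return float(np.clip(rho1, -0.99, 0.99))


def prewhiten(
    design: np.ndarray, data: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the inverse square root of the AR(1) correlation matrix.

    Row 0 is scaled by sqrt(1 - rho^2); row t becomes ``y_t - rho * y_{t-1}``.
    At rho = 0 the inputs are returned unchanged (same objects).
    """
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    if rho == 0.0:
        return design, data
    X = np.asarray(design, dtype=float)
    Y = np.asarray(data, dtype=float)
    Xw = np.empty_like(X)
    Yw = np.empty_like(Y)
    scale = np.sqrt(1.0 - rho ** 2)
    Xw[0] = scale * X[0]
    Yw[0] = scale * Y[0]
    Xw[1:] = X[1:] - rho * X[:-1]
    Yw[1:] = Y[1:] - rho * Y[:-1]
    return Xw, Yw


def _check_full_rank(X: np.ndarray, labels: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = slinalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = sorted(labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol)
        raise ValueError(f"rank-deficient design; collinear columns involve {bad}")


@dataclass
class GlmFit:
    """Results of a voxelwise GLM fit (statsmodels-style results object)."""

    betas: np.ndarray           # (p, V)
    contrast_value: np.ndarray | None
    t_value: np.ndarray | None
    residuals: np.ndarray       # (T, V), whitened scale
    sigma2: np.ndarray          # (V,)
    df_error: int
    rho_hat: float
    design: DesignMatrix
    whitened_design: np.ndarray

    def contrast(self, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Contrast estimate and t-value per voxel for arbitrary weights."""
        c = np.asarray(weights, dtype=float)
        if c.shape != (self.betas.shape[0],):
            raise ValueError("contrast length must equal the number of regressors")
        effect = c @ self.betas
        Xw = self.whitened_design
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        var_factor = float(c @ xtx_inv @ c)
        se = np.sqrt(self.sigma2 * var_factor)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / se, np.nan)
        return effect, t

    def summary(self) -> str:
        lines = [
            "Voxelwise GLM (AR(1) prewhitened least squares)",
            f"  voxels fitted     : {self.betas.shape[1]}",
            f"  regressors        : {self.betas.shape[0]}",
            f"  volumes           : {self.residuals.shape[0]}",
            f"  error df          : {self.df_error}",
            f"  global AR(1) rho  : {self.rho_hat:+.4f}",
            f"  median sigma^2    : {np.median(self.sigma2):.4f}",
        ]
        if self.t_value is not None:
            lines.append(f"  median |t|        : {np.median(np.abs(self.t_value)):.3f}")
        return "\n".join(lines)


class VoxelwiseGLM:
    """Mass-univariate GLM of a (time x voxel) data matrix against a design."""

    def __init__(self, endog: np.ndarray, design: DesignMatrix) -> None:
        endog = np.asarray(endog, dtype=float)
        if endog.ndim == 1:
            endog = endog[:, None]
        if endog.shape[0] != design.n_volumes:
            raise ValueError("data rows must equal design rows")
        self.endog = endog
        self.design = design

    def fit(
        self,
        contrast_weights: np.ndarray | None = None,
        prewhiten_data: bool = True,
    ) -> GlmFit:
        X = self.design.values
        Y = self.endog
        _check_full_rank(X, self.design.labels)
        beta0 = np.linalg.solve(X.T @ X, X.T @ Y)
        resid0 = Y - X @ beta0
        rho = estimate_global_ar1(resid0, design=X) if prewhiten_data else 0.0
        Xw, Yw = prewhiten(X, Y, rho)
        betas = np.linalg.solve(Xw.T @ Xw, Xw.T @ Yw)
        resid = Yw - Xw @ betas
        df = int(Y.shape[0] - np.linalg.matrix_rank(Xw))
        sigma2 = np.sum(resid ** 2, axis=0) / df
        fit = GlmFit(
            betas=betas,
            contrast_value=None,
            t_value=None,
            residuals=resid,
            sigma2=sigma2,
            df_error=df,
            rho_hat=rho,
            design=self.design,
            whitened_design=Xw if rho != 0.0 else X,
        )
        if contrast_weights is not None:
            fit.contrast_value, fit.t_value = fit.contrast(contrast_weights)
        return fit


def fit_voxelwise(
    design: DesignMatrix,
    data,
    contrast_weights: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    prewhiten_data: bool = True,
) -> GlmFit:
    """Fit the voxelwise GLM to a BoldRun (within ``mask``) or a data matrix."""
    if hasattr(data, "timeseries"):
        if mask is None:
            raise ValueError("fitting a BoldRun requires a brain mask")
        Y = data.timeseries(mask)
    else:
        Y = np.asarray(data, dtype=float)
    model = VoxelwiseGLM(Y, design)
    return model.fit(contrast_weights=contrast_weights, prewhiten_data=prewhiten_data)
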