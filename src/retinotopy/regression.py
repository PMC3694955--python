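"""Local-linear kernel regression with cross-validated bandwidth.

Experimental topographic maps are point sets (retinal position, SC
position).  They are smoothed with a Gaussian-kernel local-linear
estimator whose bandwidth is selected by the Kullback-Leibler-motivated
AIC criterion (statsmodels' ``KernelReg`` with ``bw="aic"``; the
least-squares cross-validation alternative is available but markedly
less stable).  The pointwise standard error of the mean comes from the
hat rows of the smoother: the local-linear fit at x0 is a linear
combination sum_i l_i(x0) y_i, so its variance is the hat-row-weighted
sum of the per-point noise variances, estimated by HC3
leverage-corrected squared residuals (heteroscedasticity-consistent,
which matters where the response is clamped at an axis boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.kernel_regression import KernelReg

__all__ = ["LocalLinearFit", "loclin_fit"]


def _hat_row(x0: float, x: np.ndarray, h: float) -> np.ndarray:
    """Weights l(x0) such that the local-linear fit is l(x0) @ y."""
    w = np.exp(-0.5 * ((x - x0) / h) ** 2)
    d = x - x0
    s1 = np.sum(w * d)
    s2 = np.sum(w * d * d)
    b = w * (s2 - d * s1)
    denom = np.sum(b)
    if denom <= 0 or not np.isfinite(denom):
        raise FloatingPointError("degenerate local-linear system")
    return b / denom


@dataclass
class LocalLinearFit:
    """A fitted local-linear regression of SC position on retinal position."""

    x: np.ndarray
    y: np.ndarray
    bandwidth: float
    sigma2: float        # pooled residual variance, df-corrected
    resid2: np.ndarray   # leverage-corrected squared residuals (HC3)
    x_min: float
    x_max: float

    def __call__(self, x0):
        """Fitted SC position at retinal position(s) ``x0``."""
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        out = np.array([_hat_row(v, self.x, self.bandwidth) @ self.y
                        for v in x0])
        return out if out.size > 1 else float(out[0])

    def stderr(self, x0):
        """Estimated standard error of the fitted mean at ``x0``.

        Heteroscedasticity-consistent sandwich form: the hat-row weights
        are applied to the squared residuals, so locally noisier data
        (e.g. where the response is clamped at an axis boundary) yields
        locally wider errors instead of polluting a pooled variance.
        """
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        out = np.array([
            np.sqrt(np.sum(_hat_row(v, self.x, self.bandwidth) ** 2
                           * self.resid2))
            for v in x0])
        return out if out.size > 1 else float(out[0])

    def in_support(self, x0) -> np.ndarray:
        """Whether ``x0`` lies inside the convex hull of the data x."""
        x0 = np.asarray(x0, dtype=float)
        return (x0 >= self.x_min) & (x0 <= self.x_max)


def loclin_fit(x, y, bandwidth: float | None = None,
               selector: str = "aic") -> LocalLinearFit:
    """Fit a local-linear regression with a cross-validated bandwidth.

    Parameters
    ----------
    x, y
        Map points: retinal positions and SC positions (n >= 5, the x
        values must not be all equal).
    bandwidth
        Optional fixed bandwidth; by default the AIC-based selector
        chooses it (``selector="cv_ls"`` switches to least-squares
        cross-validation).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 points to fit a map")
    if np.ptp(x) <= 0:
        raise ValueError("degenerate x spread")
    if bandwidth is None:
        if selector not in ("aic", "cv_ls"):
            raise ValueError(f"unknown bandwidth selector {selector!r}")
        kr = KernelReg(y, x, var_type="c", reg_type="ll", bw=selector)
        bandwidth = float(kr.bw[0])
    if not np.isfinite(bandwidth) or bandwidth <= 0:
        raise ValueError(f"invalid bandwidth {bandwidth}")
    # effective degrees of freedom: nu1 = tr(L), nu2 = tr(L'L)
    hat = np.array([_hat_row(v, x, bandwidth) for v in x])
    fitted = hat @ y
    nu1 = float(np.trace(hat))
    nu2 = float(np.sum(hat * hat))
    df = max(x.size - 2.0 * nu1 + nu2, 1.0)
    # HC3-style leverage correction: the smoother partially absorbs the
    # noise at each data point, deflating raw residuals by (1 - h_ii)
    leverage = np.clip(np.diag(hat), 0.0, 0.9)
    resid2 = ((y - fitted) / (1.0 - leverage)) ** 2
    sigma2 = float(np.sum((y - fitted) ** 2) / df)
    return LocalLinearFit(x=x, y=y, bandwidth=float(bandwidth), sigma2=sigma2,
                          resid2=resid2,
                          x_min=float(x.min()), x_max=float(x.max()))
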