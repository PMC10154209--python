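"""Degree-1 LOESS (tricube-weighted local linear regression) with a band.

Written here rather than delegated because the trajectory pipeline needs the
smoother evaluated on an arbitrary stage grid *with* a pointwise variance
band, which the usual lowess routines do not expose.  At each evaluation
point the fit is a weighted least-squares line over the ``ceil(span * n)``
nearest observations with tricube weights; the pointwise standard error is
``sigma_hat * ||l(x0)||`` where ``l(x0)`` is the equivalent kernel and
``sigma_hat**2`` the residual variance of the smoother at the data points.

With span 1.0 on exactly linear data the fit reproduces the ordinary
least-squares line (any weighting is irrelevant when the line interpolates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class LoessFit:
    x_eval: np.ndarray
    fitted: np.ndarray
    se: np.ndarray

    def confidence_band(self, level: float = 0.95):
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.fitted - z * self.se, self.fitted + z * self.se


def _equivalent_kernel(x: np.ndarray, x0: float, span: float) -> np.ndarray:
    """Weights l such that fit(x0) = l @ y, for a degree-1 local fit."""
    n = x.size
    q = max(2, int(np.ceil(span * n)))
    q = min(q, n)
    d = np.abs(x - x0)
    dq = np.partition(d, q - 1)[q - 1]
    if dq == 0:
        # all neighbors sit on x0 (heavily tied covariate): local mean
        mask = d == 0
        l = np.zeros(n)
        l[mask] = 1.0 / mask.sum()
        return l
    mask = d <= dq
    u = d[mask] / dq
    w = np.clip(1 - u**3, 0, None) ** 3
    if w.sum() == 0:  # numerical guard; fall back to nearest point
        w = (u == u.min()).astype(float)
    xm = x[mask]
    # weighted linear fit: l = e0' (X'WX)^{-1} X'W with X = [1, x - x0]
    xc = xm - x0
    s0 = w.sum()
    s1 = (w * xc).sum()
    s2 = (w * xc * xc).sum()
    det = s0 * s2 - s1 * s1
    lm = np.empty_like(w)
    if det <= 1e-12 * max(s0 * s2, 1e-300):
        lm = w / s0  # degenerate design: local weighted mean
    else:
        # first row of the 2x2 inverse applied to X'W
        lm = (s2 * w - s1 * w * xc) / det
    l = np.zeros(n)
    l[mask] = lm
    return l


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
) -> LoessFit:
    """Fit y on x locally and evaluate on ``x_eval``.

    Parameters
    ----------
    x, y
        Observations; NaNs are dropped pairwise.
    x_eval
        Evaluation grid.
    span
        Fraction of observations in each local neighborhood, in (0, 1].
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("loess requires at least 2 observations")
    if np.unique(x).size < 2:
        raise ValueError("loess requires at least 2 distinct x values")
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))

    # residual variance from the smoother at the observed points
    fitted_at_obs = np.array([_equivalent_kernel(x, xi, span) @ y for xi in x])
    resid = y - fitted_at_obs
    dof = max(x.size - 2, 1)
    sigma2 = float(resid @ resid) / dof

    fitted = np.empty(x_eval.size)
    se = np.empty(x_eval.size)
    for j, x0 in enumerate(x_eval):
        l = _equivalent_kernel(x, float(x0), span)
        fitted[j] = l @ y
        se[j] = np.sqrt(sigma2 * (l @ l))
    return LoessFit(x_eval=x_eval, fitted=fitted, se=se)
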