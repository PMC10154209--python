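"""Stage-indexed biomarker trajectories: standardization, 0-10 abnormality
scaling, LOESS curves over the stage axis, cognitive composites.

Every biomarker is z-standardized against the cognitively unimpaired older
adults (the cohort's reference population, irrespective of their stage),
oriented so that larger means more abnormal, and min-max mapped onto a
common 0-10 scale with 10 the maximum observed abnormality.  Curves are
LOESS fits over the Braak stage index 0-6 — an ordered severity axis, not
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .loess import LoessFit, loess
from .stats import StageComparison, compare_stages

STAGE_GRID = np.arange(7, dtype=float)

#: biomarkers whose *low* values are abnormal; everything else is higher-is-abnormal
LOWER_IS_ABNORMAL = frozenset(
    {
        "csf_ab42_ab40_ratio",
        "csf_ab42",
        "hippocampal_volume_adj",
        "mmse",
        "moca",
        "memory",
        "executive",
        "language",
        "visuospatial",
    }
)

#: neuropsychological test -> cognitive domain
DEFAULT_DOMAIN_MAP: Dict[str, List[str]] = {
    "memory": [
        "logical_memory_immediate",
        "logical_memory_delayed",
        "ravlt_immediate",
        "ravlt_delayed",
    ],
    "language": ["category_fluency", "boston_naming"],
    "visuospatial": ["borb"],
    "executive": ["trails_b_time", "digit_span_backward", "letter_fluency"],
}

#: tests where a *larger* raw score is worse; sign-flipped before averaging
NEGATIVE_TESTS = frozenset({"trails_b_time"})


def default_direction(biomarker: str) -> str:
    return "lower" if biomarker in LOWER_IS_ABNORMAL else "higher"


def zscore_to_reference(values, reference_mask) -> np.ndarray:
    """Standardize a column by the mean/s.d. of the reference subjects.

    The reference is the cognitively unimpaired older adults; their own
    z-scores then have mean 0 and s.d. 1 by construction.  Missing values
    propagate.  Requires >= 2 nonmissing reference values and nonzero s.d.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("reference_mask must align with values")
    ref = values[mask]
    ref = ref[~np.isnan(ref)]
    if ref.size < 2:
        raise ValueError("need at least 2 nonmissing reference values")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("reference standard deviation is zero")
    return (values - ref.mean()) / sd


def build_domain_composites(
    test_scores: pd.DataFrame,
    reference_mask,
    domain_map: Optional[Dict[str, List[str]]] = None,
    negative_tests: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Cognitive domain composites: mean of available within-domain z-scores.

    Raw test scores are z-transformed against the reference subjects;
    timed tests listed in ``negative_tests`` (trail-making B by default) are
    sign-flipped so higher always means better before averaging.  A subject
    missing every test in a domain gets a missing composite.
    """
    domain_map = DEFAULT_DOMAIN_MAP if domain_map is None else domain_map
    negative = NEGATIVE_TESTS if negative_tests is None else frozenset(negative_tests)
    out = pd.DataFrame(index=test_scores.index)
    for domain, tests in domain_map.items():
        cols = []
        for test in tests:
            if test not in test_scores.columns:
                continue
            z = zscore_to_reference(test_scores[test].to_numpy(dtype=float), reference_mask)
            if test in negative:
                z = -z
            cols.append(z)
        if not cols:
            out[domain] = np.nan
            continue
        stacked = np.vstack(cols)
        counts = (~np.isnan(stacked)).sum(axis=0)
        sums = np.nansum(stacked, axis=0)
        out[domain] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def scale_to_abnormality(values, direction: str = "higher") -> np.ndarray:
    """Orient and min-max map a column onto the common 0-10 abnormality scale.

    ``direction='lower'`` flips the sign first (e.g. Abeta42/40 ratio, MMSE,
    hippocampal volume), so the most abnormal observation always maps to 10.
    """
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    values = np.asarray(values, dtype=float)
    oriented = -values if direction == "lower" else values
    finite = oriented[~np.isnan(oriented)]
    if finite.size < 2 or finite.max() == finite.min():
        raise ValueError("scaling requires at least 2 distinct values")
    return 10.0 * (oriented - finite.min()) / (finite.max() - finite.min())


class AbnormalityScaler(BaseEstimator, TransformerMixin):
    """Fit/transform version of the 0-10 abnormality scaling.

    Parameters
    ----------
    direction : {'higher', 'lower'}
        Orientation; 'lower' markers are sign-flipped before scaling.
    """

    def __init__(self, direction: str = "higher"):
        self.direction = direction

    def fit(self, X, y=None):
        if self.direction not in ("higher", "lower"):
            raise ValueError("direction must be 'higher' or 'lower'")
        X = np.asarray(X, dtype=float).ravel()
        oriented = -X if self.direction == "lower" else X
        finite = oriented[~np.isnan(oriented)]
        if finite.size < 2 or finite.max() == finite.min():
            raise ValueError("scaling requires at least 2 distinct values")
        self.min_ = float(finite.min())
        self.max_ = float(finite.max())
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).ravel()
        oriented = -X if self.direction == "lower" else X
        return 10.0 * (oriented - self.min_) / (self.max_ - self.min_)


class StageTrajectorySmoother(BaseEstimator):
    """LOESS smoother of a biomarker over the Braak stage axis.

    ``fit(stages, values)`` stores the smoother inputs; ``predict(grid)``
    evaluates the local-linear tricube fit; ``fitted`` attributes expose the
    default stage-grid curve and its pointwise 95% band.
    """

    def __init__(self, span: float = 0.75):
        self.span = span

    def fit(self, X, y):
        stages = np.asarray(X, dtype=float).ravel()
        values = np.asarray(y, dtype=float).ravel()
        fit = loess(stages, values, STAGE_GRID, span=self.span)
        self._x = stages
        self._y = values
        self.grid_ = fit.x_eval
        self.curve_ = fit.fitted
        self.se_ = fit.se
        self.band_ = fit.confidence_band(0.95)
        return self

    def predict(self, X):
        fit = loess(self._x, self._y, np.asarray(X, dtype=float).ravel(), span=self.span)
        return fit.fitted


def fit_stage_trajectory(values, stages, span: float = 0.75) -> LoessFit:
    """LOESS curve of ``values`` over the stage grid 0..6 with a 95% band."""
    return loess(np.asarray(stages, float), np.asarray(values, float), STAGE_GRID, span=span)


@dataclass
class TrajectoryResult:
    """One biomarker's stage-indexed curve, scaled curve and group contrasts."""

    biomarker: str
    direction: str
    grid: np.ndarray
    fitted: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    scaled_curve: np.ndarray
    comparison: StageComparison

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.grid,
                "fitted_z": self.fitted,
                "band_low": self.band_low,
                "band_high": self.band_high,
                "scaled_0_10": self.scaled_curve,
            }
        )


def analyze_trajectory(
    values,
    stages,
    reference_mask,
    biomarker: str,
    direction: Optional[str] = None,
    span: float = 0.75,
    n_mc: int = 50_000,
    rng: Optional[np.random.Generator] = None,
) -> TrajectoryResult:
    """Full per-biomarker pipeline: z-score, LOESS, 0-10 scaling, contrasts.

    ``values`` are raw biomarker measurements; ``stages`` the assigned Braak
    stages; ``reference_mask`` flags the CU older adults used for
    standardization.  Group contrasts (Brown-Forsythe omnibus + Dunnett-style
    stage-vs-0) are computed on the z-scores.
    """
    direction = default_direction(biomarker) if direction is None else direction
    z = zscore_to_reference(values, reference_mask)
    comparison = compare_stages(z, np.asarray(stages), n_mc=n_mc, rng=rng)
    fit = fit_stage_trajectory(z, stages, span=span)
    lo, hi = fit.confidence_band(0.95)
    scaled = scale_to_abnormality(z, direction=direction)
    scaled_fit = fit_stage_trajectory(scaled, stages, span=span)
    scaled_curve = np.clip(scaled_fit.fitted, 0.0, 10.0)
    return TrajectoryResult(
        biomarker=biomarker,
        direction=direction,
        grid=fit.x_eval,
        fitted=fit.fitted,
        band_low=lo,
        band_high=hi,
        scaled_curve=scaled_curve,
        comparison=comparison,
    )


def cdr_stage_table(cdr, stages) -> pd.DataFrame:
    """Counts of Clinical Dementia Rating values within each Braak stage."""
    return pd.crosstab(
        pd.Series(np.asarray(stages), name="stage"),
        pd.Series(np.asarray(cdr), name="cdr"),
    )


def half_max_stage(grid: np.ndarray, curve: np.ndarray) -> float:
    """Stage index where a curve first crosses half of its own dynamic range.

    Linear interpolation between grid points; NaN when the curve never
    crosses (e.g. flat curves).
    """
    grid = np.asarray(grid, float)
    curve = np.asarray(curve, float)
    target = curve.min() + 0.5 * (curve.max() - curve.min())
    if curve.max() == curve.min():
        return float("nan")
    for i in range(1, curve.size):
        if curve[i - 1] < target <= curve[i]:
            frac = (target - curve[i - 1]) / (curve[i] - curve[i - 1])
            return float(grid[i - 1] + frac * (grid[i] - grid[i - 1]))
    if curve[0] >= target:
        return float(grid[0])
    return float("nan")
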