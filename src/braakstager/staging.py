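"""Tau-PET cutoff calibration and hierarchical Braak stage assignment.

A subject-visit is staged from its six stage-composite tau-PET SUVRs.  Each
composite is compared against a stage-specific abnormality cutoff calibrated
as ``mean + k * sd`` (k = 2.5 by default) of a cognitively unimpaired
young-adult sample, in whom tau pathology is assumed absent.  The assigned
stage is the *latest* (highest) stage whose composite exceeds its cutoff,
or 0 when none does.  A positivity pattern is called conformant when it is a
prefix pattern — every stage up to the assigned one positive, every later
stage negative — the hierarchical signature of the Braak model.

The calibrate/assign pair is exposed as a scikit-learn style estimator
(:class:`BraakStager`) so it composes with sklearn pipelines; the
module-level functions are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .atlas import N_STAGES

SUVR_COLUMNS = [f"suvr_braak{i}" for i in range(1, N_STAGES + 1)]


@dataclass
class StageCutoffs:
    """Six stage-specific SUVR abnormality thresholds with provenance."""

    thresholds: np.ndarray
    k_sd: float
    n_calibration: int
    calibration_means: np.ndarray
    calibration_sds: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.calibration_means = np.asarray(self.calibration_means, dtype=float)
        self.calibration_sds = np.asarray(self.calibration_sds, dtype=float)
        for name in ("thresholds", "calibration_means", "calibration_sds"):
            arr = getattr(self, name)
            if arr.shape != (N_STAGES,):
                raise ValueError(f"{name} must have shape ({N_STAGES},), got {arr.shape}")
        if self.n_calibration < 2:
            raise ValueError("n_calibration must be >= 2")
        if np.any(self.calibration_sds < 0):
            raise ValueError("calibration_sds must be nonnegative")
        expected = self.calibration_means + self.k_sd * self.calibration_sds
        if not np.array_equal(expected, self.thresholds):
            raise ValueError("thresholds must equal calibration_means + k_sd * calibration_sds")


@dataclass
class StageAssignment:
    """Assigned Braak stage with the per-stage positivity pattern."""

    stage: int
    positivity: np.ndarray
    conformant: bool
    meta_roi_positive: Optional[bool] = None

    def __post_init__(self) -> None:
        self.positivity = np.asarray(self.positivity, dtype=bool)
        if self.positivity.shape != (N_STAGES,):
            raise ValueError(f"positivity must have shape ({N_STAGES},)")
        if not 0 <= self.stage <= N_STAGES:
            raise ValueError(f"stage must be in 0..{N_STAGES}, got {self.stage}")


@dataclass
class AmyloidStatus:
    """Amyloid-beta positivity from PET and/or the CSF Abeta42/Abeta40 ratio."""

    pet_positive: Optional[bool] = None
    csf_positive: Optional[bool] = None
    pet_threshold: float = 1.55
    csf_ratio_threshold: float = 0.068


class BraakStager(BaseEstimator):
    """Stage subject-visits from tau-PET stage-composite SUVRs.

    ``fit`` calibrates the six abnormality cutoffs on a young-control
    calibration sample (``mean + k_sd * sd``, sample s.d. with n-1
    denominator); ``predict`` returns the assigned stage (0..6) and
    ``transform`` the boolean per-stage positivity matrix.

    Parameters
    ----------
    k_sd : float, default=2.5
        Standard-deviation multiplier for the cutoff rule.

    Attributes
    ----------
    calibration_means_ : ndarray of shape (6,)
    calibration_sds_ : ndarray of shape (6,)
    thresholds_ : ndarray of shape (6,)
    n_calibration_ : int
    """

    def __init__(self, k_sd: float = 2.5):
        self.k_sd = k_sd

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _as_suvr_matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in SUVR_COLUMNS if c not in X.columns]
            if missing:
                raise ValueError(f"missing stage-composite columns: {missing}")
            X = X[SUVR_COLUMNS].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.ndim != 2 or X.shape[1] != N_STAGES:
            raise ValueError(f"expected (n, {N_STAGES}) SUVR matrix, got shape {X.shape}")
        if np.isnan(X).any():
            bad = np.where(np.isnan(X).any(axis=1))[0]
            raise ValueError(
                f"missing stage-composite SUVR in rows {bad.tolist()}; staging requires "
                "a complete six-vector (no imputation)"
            )
        if not np.all(np.isfinite(X)) or np.any(X <= 0):
            raise ValueError("stage-composite SUVRs must be finite and > 0")
        return X

    def fit(self, X, y=None) -> "BraakStager":
        """Calibrate cutoffs from a (n, 6) calibration SUVR matrix (n >= 2)."""
        X = self._as_suvr_matrix(X)
        if X.shape[0] < 2:
            raise ValueError("calibration requires at least 2 records (s.d. undefined)")
        # sort each column so the reduction order is canonical: permuting the
        # calibration records can then never change the thresholds, bit for bit
        Xs = np.sort(X, axis=0)
        self.calibration_means_ = Xs.mean(axis=0)
        self.calibration_sds_ = Xs.std(axis=0, ddof=1)
        self.thresholds_ = self.calibration_means_ + self.k_sd * self.calibration_sds_
        self.n_calibration_ = int(X.shape[0])
        return self

    @property
    def cutoffs_(self) -> StageCutoffs:
        self._check_fitted()
        return StageCutoffs(
            thresholds=self.thresholds_,
            k_sd=self.k_sd,
            n_calibration=self.n_calibration_,
            calibration_means=self.calibration_means_,
            calibration_sds=self.calibration_sds_,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "thresholds_"):
            raise AttributeError("BraakStager is not fitted; call fit() first")

    def transform(self, X) -> np.ndarray:
        """Boolean (n, 6) positivity matrix: composite strictly above cutoff."""
        self._check_fitted()
        X = self._as_suvr_matrix(X)
        return X > self.thresholds_

    def predict(self, X) -> np.ndarray:
        """Assigned stage per row: latest positive stage, 0 when none."""
        pos = self.transform(X)
        return _stages_from_positivity(pos)

    def assign(self, X) -> list:
        """Full :class:`StageAssignment` per row."""
        pos = self.transform(X)
        stages = _stages_from_positivity(pos)
        return [
            StageAssignment(
                stage=int(s),
                positivity=p,
                conformant=_is_prefix_pattern(p, int(s)),
            )
            for s, p in zip(stages, pos)
        ]


def _stages_from_positivity(pos: np.ndarray) -> np.ndarray:
    idx = np.arange(1, N_STAGES + 1)
    return np.where(pos.any(axis=1), (pos * idx).max(axis=1), 0).astype(int)


def _is_prefix_pattern(pos: np.ndarray, stage: int) -> bool:
    # stage is already the last positive index, so entries beyond it are
    # false by construction; conformance reduces to the prefix being full
    return bool(pos[:stage].all())


# -- module-level wrappers ------------------------------------------------


def calibrate_cutoffs(calibration_suvr, k_sd: float = 2.5) -> StageCutoffs:
    """Cutoffs = mean + k_sd * sample s.d. per stage on young controls."""
    return BraakStager(k_sd=k_sd).fit(calibration_suvr).cutoffs_


def assign_stage(
    stage_suvr: Sequence[float],
    cutoffs: StageCutoffs,
    meta_roi_suvr: Optional[float] = None,
    meta_roi_threshold: Optional[float] = None,
) -> StageAssignment:
    """Assign one subject-visit the latest stage with an abnormal composite."""
    stager = BraakStager(k_sd=cutoffs.k_sd)
    stager.thresholds_ = cutoffs.thresholds
    stager.calibration_means_ = cutoffs.calibration_means
    stager.calibration_sds_ = cutoffs.calibration_sds
    stager.n_calibration_ = cutoffs.n_calibration
    assignment = stager.assign(np.asarray(stage_suvr, dtype=float))[0]
    if meta_roi_suvr is not None:
        assignment.meta_roi_positive = meta_roi_positivity(meta_roi_suvr, meta_roi_threshold)
    return assignment


def classify_amyloid(
    amyloid_suvr: Optional[float] = None,
    csf_ab42: Optional[float] = None,
    csf_ab40: Optional[float] = None,
    pet_threshold: float = 1.55,
    csf_ratio_threshold: float = 0.068,
) -> AmyloidStatus:
    """Dichotomize amyloid-beta burden from PET and/or CSF.

    PET positivity is a strict ``SUVR > pet_threshold``; CSF positivity is a
    strict ``Abeta42/Abeta40 < csf_ratio_threshold`` (a *low* ratio indicates
    amyloid pathology).  A modality with missing inputs yields ``None``.
    """

    def _missing(x) -> bool:
        return x is None or (isinstance(x, float) and np.isnan(x))

    pet = None
    if not _missing(amyloid_suvr):
        pet = bool(float(amyloid_suvr) > pet_threshold)
    csf = None
    if not _missing(csf_ab42) and not _missing(csf_ab40):
        if float(csf_ab40) <= 0:
            raise ValueError("csf_ab40 must be > 0")
        csf = bool(float(csf_ab42) / float(csf_ab40) < csf_ratio_threshold)
    if pet is None and csf is None:
        raise ValueError("amyloid classification needs at least one modality (PET or CSF)")
    return AmyloidStatus(
        pet_positive=pet,
        csf_positive=csf,
        pet_threshold=pet_threshold,
        csf_ratio_threshold=csf_ratio_threshold,
    )


def meta_roi_positivity(meta_roi_suvr: float, threshold: Optional[float]) -> bool:
    """Temporal meta-ROI positivity (strict ``>``); the threshold is user-supplied."""
    if threshold is None:
        raise ValueError(
            "no temporal meta-ROI threshold configured; supply a validated cutoff "
            "for your tracer via the config (key: meta_roi_threshold)"
        )
    if not threshold > 0:
        raise ValueError(f"meta-ROI threshold must be > 0, got {threshold}")
    return bool(float(meta_roi_suvr) > threshold)


def stage_table(
    cohort: pd.DataFrame,
    cutoffs: StageCutoffs,
    meta_roi_threshold: Optional[float] = None,
    pet_threshold: float = 1.55,
    csf_ratio_threshold: float = 0.068,
) -> pd.DataFrame:
    """Stage every row of a cohort table; returns an assignments table.

    Output columns: subject_id, visit, diagnosis (if present), stage,
    pos_braak1..6, conformant, meta_roi_positive, amyloid_pet_positive,
    amyloid_csf_positive.
    """
    stager = BraakStager(k_sd=cutoffs.k_sd)
    stager.thresholds_ = cutoffs.thresholds
    stager.calibration_means_ = cutoffs.calibration_means
    stager.calibration_sds_ = cutoffs.calibration_sds
    stager.n_calibration_ = cutoffs.n_calibration
    pos = stager.transform(cohort)
    stages = _stages_from_positivity(pos)

    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "visit": cohort["visit"].to_numpy(),
        }
    )
    if "diagnosis" in cohort.columns:
        out["diagnosis"] = cohort["diagnosis"].to_numpy()
    out["stage"] = stages
    for i in range(N_STAGES):
        out[f"pos_braak{i + 1}"] = pos[:, i]
    out["conformant"] = [
        _is_prefix_pattern(p, int(s)) for p, s in zip(pos, stages)
    ]
    if meta_roi_threshold is not None and "suvr_meta_roi" in cohort.columns:
        out["meta_roi_positive"] = (
            cohort["suvr_meta_roi"].to_numpy(dtype=float) > meta_roi_threshold
        )
    pet_pos = []
    csf_pos = []
    ab42 = cohort["csf_ab42"] if "csf_ab42" in cohort.columns else None
    ab40 = cohort["csf_ab40"] if "csf_ab40" in cohort.columns else None
    for i in range(len(cohort)):
        suvr = cohort["suvr_amyloid"].iloc[i] if "suvr_amyloid" in cohort.columns else None
        a42 = ab42.iloc[i] if ab42 is not None else None
        a40 = ab40.iloc[i] if ab40 is not None else None
        try:
            status = classify_amyloid(
                suvr,
                a42,
                a40,
                pet_threshold=pet_threshold,
                csf_ratio_threshold=csf_ratio_threshold,
            )
        except ValueError:
            # row with no amyloid measurement at all: leave both flags missing
            status = AmyloidStatus(None, None, pet_threshold, csf_ratio_threshold)
        pet_pos.append(status.pet_positive)
        csf_pos.append(status.csf_positive)
    out["amyloid_pet_positive"] = pet_pos
    out["amyloid_csf_positive"] = csf_pos
    return out
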