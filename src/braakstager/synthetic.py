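"""Seeded synthetic cohorts with the stage-dependent structure of the
Alzheimer biomarker cascade.

The generator emulates a tau-PET staging study: a young-control calibration
sample, a cross-sectional cohort (cognitively unimpaired older adults, MCI
and Alzheimer's clinical syndrome) and 1- and 2-year follow-up tau-PET
visits.  Each subject carries a hidden true Braak stage; stage-composite
SUVRs are drawn so that composites for stages at or below the true stage
come from an abnormal distribution and later stages from the unaffected
baseline distribution — hierarchical by construction.  Amyloid burden rises
with stage and plateaus from stage IV; CSF pTau species switch on around
stage II-III and plateau late (plasma pTau231 does not); memory declines
from stage II, global cognition from stage IV; CDR worsens with stage.
Follow-up stages evolve by a per-year stay/advance kernel in which
amyloid-negative subjects at or beyond the gate stage (III) never advance.

All stage-conditional means are explicit config defaults chosen to encode
these qualitative orderings, not fits to any real distribution.  A single
seed drives independent named substreams, so adding a channel never perturbs
the draws of existing channels.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import N_STAGES

TRUTH_COLUMNS = ["true_stage", "true_amyloid_positive"]

FLUID_COLUMNS = [
    "csf_ptau181",
    "csf_ptau217",
    "csf_ptau231",
    "csf_ptau235",
    "csf_neurogranin",
    "csf_snap25",
    "plasma_ptau181",
    "plasma_ptau231",
    "plasma_nfl",
    "hippocampal_volume_adj",
]

TEST_COLUMNS = [
    "logical_memory_immediate",
    "logical_memory_delayed",
    "ravlt_immediate",
    "ravlt_delayed",
    "category_fluency",
    "boston_naming",
    "borb",
    "trails_b_time",
    "digit_span_backward",
    "letter_fluency",
]


def _stage_curve(values: List[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (7,):
        raise ValueError("stage-conditional curves need 7 values (stages 0..6)")
    return arr


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-cohort generator.  ``seed`` is mandatory."""

    seed: int

    # group sizes (study-sized defaults)
    n_cu: int = 179
    n_mci: int = 80
    n_ad: int = 65
    n_calibration: int = 200

    # follow-up design: 140 one-year + 84 two-year scans, 65 subjects with both
    n_followup_1y: int = 140
    n_followup_2y: int = 84
    n_followup_both: int = 65

    # true-stage priors per diagnosis group (stages 0..6)
    stage_prior_by_dx: Dict[str, List[float]] = field(
        default_factory=lambda: {
            "CU": [0.60, 0.18, 0.12, 0.06, 0.03, 0.01, 0.00],
            "MCI": [0.10, 0.15, 0.20, 0.25, 0.15, 0.10, 0.05],
            "AD": [0.00, 0.02, 0.05, 0.13, 0.20, 0.30, 0.30],
        }
    )

    # tau-PET regional model (dimensionless SUVR)
    baseline_suvr_mean: float = 1.00
    baseline_suvr_sd: float = 0.035
    abnormal_suvr_mean: float = 1.60
    abnormal_suvr_sd: float = 0.12
    abnormal_stage_increment: float = 0.08  # composite keeps rising after onset

    # temporal meta-ROI
    meta_roi_mean_by_stage: List[float] = field(
        default_factory=lambda: [1.00, 1.08, 1.20, 1.45, 1.80, 2.30, 2.80]
    )
    meta_roi_cv: float = 0.10
    meta_roi_threshold: float = 1.24

    # amyloid model: positivity mixing at early stages, plateau from stage IV
    amyloid_p_pos_by_stage: List[float] = field(
        default_factory=lambda: [0.30, 0.60, 0.80, 0.97, 1.00, 1.00, 1.00]
    )
    amyloid_pos_suvr_by_stage: List[float] = field(
        default_factory=lambda: [1.80, 2.00, 2.20, 2.35, 2.45, 2.45, 2.45]
    )
    amyloid_neg_suvr_mean: float = 1.30
    amyloid_suvr_sd: float = 0.12
    csf_ratio_pos_mean: float = 0.045
    csf_ratio_neg_mean: float = 0.090
    csf_ratio_cv: float = 0.15
    csf_ab40_mean: float = 12_000.0
    csf_ab40_sd: float = 2_500.0

    # fluid model: reference-scale mean/sd plus a z-mean curve over stage.
    # Orderings encoded: pTau231/217 earliest CSF onset, pTau181 largest late
    # increase, CSF species plateau at V-VI, plasma pTau231 keeps rising.
    fluid_base: Dict[str, List[float]] = field(
        default_factory=lambda: {
            "csf_ptau181": [25.0, 10.0],
            "csf_ptau217": [2.5, 1.0],
            "csf_ptau231": [12.0, 5.0],
            "csf_ptau235": [8.0, 3.0],
            "csf_neurogranin": [160.0, 60.0],
            "csf_snap25": [6.0, 2.0],
            "plasma_ptau181": [12.0, 4.0],
            "plasma_ptau231": [10.0, 4.0],
            "plasma_nfl": [18.0, 7.0],
            "hippocampal_volume_adj": [3.54, 0.41],
        }
    )
    fluid_z_by_stage: Dict[str, List[float]] = field(
        default_factory=lambda: {
            "csf_ptau231": [0.0, 0.0, 0.8, 2.5, 3.5, 3.8, 3.9],
            "csf_ptau217": [0.0, 0.0, 0.6, 2.3, 3.4, 3.7, 3.8],
            "csf_ptau235": [0.0, 0.0, 0.4, 1.8, 2.8, 3.1, 3.2],
            "csf_ptau181": [0.0, 0.0, 0.4, 2.0, 3.6, 4.2, 4.4],
            "csf_neurogranin": [0.0, 0.1, 0.4, 1.0, 1.8, 2.2, 2.4],
            "csf_snap25": [0.0, 0.1, 0.4, 1.0, 1.7, 2.1, 2.3],
            "plasma_ptau231": [0.0, 0.0, 0.5, 1.2, 2.0, 2.8, 3.6],
            "plasma_ptau181": [0.0, 0.0, 0.1, 0.4, 1.2, 1.8, 2.4],
            "plasma_nfl": [0.0, 0.1, 0.3, 0.7, 1.2, 1.8, 2.2],
            "hippocampal_volume_adj": [0.0, -0.1, -0.5, -1.2, -1.8, -2.2, -2.5],
        }
    )
    fluid_noise_cv: float = 0.15

    # cognition model: memory onset stage II, global cognition onset stage IV
    cognitive_z_by_stage: Dict[str, List[float]] = field(
        default_factory=lambda: {
            "memory": [0.0, -0.1, -0.8, -1.5, -2.2, -2.8, -3.2],
            "executive": [0.0, 0.0, -0.1, -0.5, -1.0, -1.8, -2.4],
            "language": [0.0, 0.0, 0.0, -0.3, -0.8, -1.5, -2.2],
            "visuospatial": [0.0, 0.0, 0.0, -0.2, -0.6, -1.3, -2.0],
        }
    )
    mmse_mean_by_stage: List[float] = field(
        default_factory=lambda: [29.1, 29.0, 28.8, 28.0, 26.5, 23.0, 19.0]
    )
    moca_mean_by_stage: List[float] = field(
        default_factory=lambda: [27.5, 27.3, 27.0, 26.0, 24.0, 20.0, 16.0]
    )
    mmse_sd: float = 1.2
    cdr_probs_by_stage: List[Dict[float, float]] = field(
        default_factory=lambda: [
            {0.0: 0.95, 0.5: 0.05},
            {0.0: 0.95, 0.5: 0.05},
            {0.0: 0.90, 0.5: 0.10},
            {0.0: 0.15, 0.5: 0.75, 1.0: 0.10},
            {0.0: 0.05, 0.5: 0.75, 1.0: 0.18, 2.0: 0.02},
            {0.5: 0.35, 1.0: 0.50, 2.0: 0.15},
            {0.5: 0.05, 1.0: 0.45, 2.0: 0.40, 3.0: 0.10},
        ]
    )

    # transition kernel (per year, identical across stages); amyloid gate
    stay_prob: float = 0.92
    advance_prob: float = 0.08
    regress_prob: float = 0.00
    gate_stage: int = 3

    # autosomal-dominant subsample for the years-to-onset analysis
    n_psen1: int = 14
    eyo_intercept: float = -12.0
    eyo_slope: float = 3.0
    eyo_sd: float = 2.0

    # misclassification jitter: per-subject probability of one composite
    # drawn from the wrong (other-regime) distribution, breaking hierarchy
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for dx, prior in self.stage_prior_by_dx.items():
            p = np.asarray(prior, dtype=float)
            if p.shape != (7,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"stage prior for {dx!r} must be 7 nonnegative probs summing to 1")
        total = self.stay_prob + self.advance_prob + self.regress_prob
        if not np.isclose(total, 1.0):
            raise ValueError(f"transition kernel row must sum to 1, got {total}")
        if not 0 <= self.jitter <= 1:
            raise ValueError("jitter must be in [0, 1]")

    def with_overrides(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _rng(seed: int, channel: str) -> np.random.Generator:
    """Independent per-channel substream keyed by a stable hash of the name."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(channel.encode())])
    )


def _lognormal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Positive draws with exactly the requested mean and s.d."""
    mean = np.broadcast_to(np.asarray(mean, float), size).copy()
    sd = np.broadcast_to(np.asarray(sd, float), size)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(size)
    return mean * np.exp(sigma * z - sigma**2 / 2)


def _truncnorm(rng, mean, sd, low, high, size) -> np.ndarray:
    a = (low - np.asarray(mean, float)) / sd
    b = (high - np.asarray(mean, float)) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


# -- SUVR machinery -------------------------------------------------------


def _composite_means(cfg: GeneratorConfig, true_stage: np.ndarray) -> np.ndarray:
    """(n, 6) composite SUVR means given each subject's true stage."""
    n = true_stage.size
    means = np.full((n, N_STAGES), cfg.baseline_suvr_mean)
    for s in range(1, N_STAGES + 1):
        affected = true_stage >= s
        means[affected, s - 1] = cfg.abnormal_suvr_mean + cfg.abnormal_stage_increment * (
            true_stage[affected] - s
        )
    return means


def _draw_suvr(cfg: GeneratorConfig, true_stage: np.ndarray, rng, jitter_rng=None) -> np.ndarray:
    n = true_stage.size
    means = _composite_means(cfg, true_stage)
    sds = np.where(
        means > cfg.baseline_suvr_mean, cfg.abnormal_suvr_sd, cfg.baseline_suvr_sd
    )
    suvr = _lognormal(rng, means, sds, (n, N_STAGES))
    if jitter_rng is not None and cfg.jitter > 0:
        hit = jitter_rng.random(n) < cfg.jitter
        which = jitter_rng.integers(0, N_STAGES, size=n)
        for i in np.where(hit)[0]:
            s = which[i]
            if true_stage[i] >= s + 1:  # affected composite dragged to baseline
                suvr[i, s] = _lognormal(
                    jitter_rng, cfg.baseline_suvr_mean, cfg.baseline_suvr_sd, ()
                )
            else:  # spared composite pushed into the abnormal regime
                suvr[i, s] = _lognormal(
                    jitter_rng, cfg.abnormal_suvr_mean, cfg.abnormal_suvr_sd, ()
                )
    return suvr


# -- public generators ----------------------------------------------------


def generate_calibration_sample(cfg: GeneratorConfig, n: Optional[int] = None) -> pd.DataFrame:
    """Cognitively unimpaired young adults: every composite from the
    unaffected baseline distribution.  Used to calibrate the cutoffs."""
    n = cfg.n_calibration if n is None else int(n)
    if n < 2:
        raise ValueError("calibration sample needs n >= 2")
    rng = _rng(cfg.seed, "calibration")
    suvr = _lognormal(rng, cfg.baseline_suvr_mean, cfg.baseline_suvr_sd, (n, N_STAGES))
    df = pd.DataFrame(suvr, columns=[f"suvr_braak{i}" for i in range(1, N_STAGES + 1)])
    df.insert(0, "subject_id", [f"CAL{i:04d}" for i in range(n)])
    df.insert(1, "visit", "baseline")
    df.insert(2, "diagnosis", "CU_young")
    df.insert(3, "age_years", np.round(_truncnorm(rng, 23.0, 2.5, 18, 30, n), 1))
    df["suvr_meta_roi"] = _lognormal(rng, cfg.meta_roi_mean_by_stage[0], cfg.meta_roi_cv, n)
    df["suvr_amyloid"] = _lognormal(rng, 1.2, 0.08, n)
    return df


def generate_cross_section(cfg: GeneratorConfig) -> pd.DataFrame:
    """Baseline visit for the full cohort, hidden truth columns included."""
    groups = [("CU", cfg.n_cu), ("MCI", cfg.n_mci), ("AD", cfg.n_ad)]
    diagnosis = np.concatenate([[dx] * n for dx, n in groups])
    n = diagnosis.size
    if n == 0:
        raise ValueError("empty cohort: all group sizes are zero")

    stage_rng = _rng(cfg.seed, "true_stage")
    true_stage = np.concatenate(
        [
            stage_rng.choice(7, size=cnt, p=np.asarray(cfg.stage_prior_by_dx[dx], float))
            for dx, cnt in groups
            if cnt
        ]
    ).astype(int)

    age_rng = _rng(cfg.seed, "age")
    age_params = {"CU": (71.1, 7.2), "MCI": (70.3, 8.1), "AD": (66.7, 9.8)}
    age = np.empty(n)
    for dx, _ in groups:
        m = diagnosis == dx
        mu, sd = age_params[dx]
        age[m] = _truncnorm(age_rng, mu, sd, 50, 95, int(m.sum()))
    age = np.round(age, 1)

    suvr = _draw_suvr(cfg, true_stage, _rng(cfg.seed, "tau_suvr"), _rng(cfg.seed, "jitter"))
    meta = _lognormal(
        _rng(cfg.seed, "meta_roi"),
        np.asarray(cfg.meta_roi_mean_by_stage)[true_stage],
        cfg.meta_roi_cv * np.asarray(cfg.meta_roi_mean_by_stage)[true_stage],
        n,
    )

    amy_rng = _rng(cfg.seed, "amyloid")
    p_pos = np.asarray(cfg.amyloid_p_pos_by_stage)[true_stage]
    true_amyloid = amy_rng.random(n) < p_pos
    amy_mean = np.where(
        true_amyloid,
        np.asarray(cfg.amyloid_pos_suvr_by_stage)[true_stage],
        cfg.amyloid_neg_suvr_mean,
    )
    suvr_amyloid = _lognormal(amy_rng, amy_mean, cfg.amyloid_suvr_sd, n)
    ab40 = _lognormal(amy_rng, cfg.csf_ab40_mean, cfg.csf_ab40_sd, n)
    ratio_mean = np.where(true_amyloid, cfg.csf_ratio_pos_mean, cfg.csf_ratio_neg_mean)
    ratio = _lognormal(amy_rng, ratio_mean, cfg.csf_ratio_cv * ratio_mean, n)
    ab42 = ratio * ab40

    df = pd.DataFrame(
        {
            "subject_id": [f"SUBJ{i:04d}" for i in range(n)],
            "visit": "baseline",
            "diagnosis": diagnosis,
            "age_years": age,
        }
    )
    for i in range(N_STAGES):
        df[f"suvr_braak{i + 1}"] = suvr[:, i]
    df["suvr_meta_roi"] = meta
    df["suvr_amyloid"] = suvr_amyloid
    df["csf_ab42"] = ab42
    df["csf_ab40"] = ab40

    for name in FLUID_COLUMNS:
        base_mean, base_sd = cfg.fluid_base[name]
        z = np.asarray(cfg.fluid_z_by_stage[name])[true_stage]
        mean = base_mean + z * base_sd
        df[name] = _lognormal(_rng(cfg.seed, f"fluid/{name}"), mean, cfg.fluid_noise_cv * mean, n)

    cog_rng = _rng(cfg.seed, "cognition")
    domain_of = {
        t: d
        for d, tests in {
            "memory": TEST_COLUMNS[:4],
            "language": TEST_COLUMNS[4:6],
            "visuospatial": TEST_COLUMNS[6:7],
            "executive": TEST_COLUMNS[7:10],
        }.items()
        for t in tests
    }
    for test in TEST_COLUMNS:
        z = np.asarray(cfg.cognitive_z_by_stage[domain_of[test]])[true_stage]
        if test == "trails_b_time":  # timed test: worse performance = longer time
            df[test] = _truncnorm(cog_rng, 80.0 - 30.0 * z, 20.0, 10.0, 400.0, n)
        else:
            df[test] = _truncnorm(cog_rng, 50.0 + 10.0 * z, 10.0, 0.0, 100.0, n)
    df["mmse"] = np.round(
        _truncnorm(cog_rng, np.asarray(cfg.mmse_mean_by_stage)[true_stage], cfg.mmse_sd, 0, 30, n)
    ).astype(int)
    df["moca"] = np.round(
        _truncnorm(cog_rng, np.asarray(cfg.moca_mean_by_stage)[true_stage], 1.6, 0, 30, n)
    ).astype(int)
    cdr = np.empty(n)
    for i, t in enumerate(true_stage):
        probs = cfg.cdr_probs_by_stage[t]
        cdr[i] = cog_rng.choice(list(probs.keys()), p=list(probs.values()))
    df["cdr"] = cdr

    psen_rng = _rng(cfg.seed, "psen1")
    carriers = psen_rng.choice(n, size=min(cfg.n_psen1, n), replace=False)
    is_carrier = np.zeros(n, dtype=bool)
    is_carrier[carriers] = True
    df["psen1_carrier"] = is_carrier
    eyo = cfg.eyo_intercept + cfg.eyo_slope * true_stage + psen_rng.normal(0, cfg.eyo_sd, n)
    parental_onset = np.where(is_carrier, np.round(age - eyo, 1), np.nan)
    df["parental_onset_age"] = parental_onset

    df["true_stage"] = true_stage
    df["true_amyloid_positive"] = true_amyloid
    return df


def _advance_stage(cfg: GeneratorConfig, stage: int, amyloid_pos: bool, u: float) -> int:
    """One kernel step; amyloid-negative subjects at/after the gate stay put."""
    if stage >= N_STAGES:
        return stage
    if not amyloid_pos and stage >= cfg.gate_stage:
        return stage
    if u < cfg.advance_prob:
        return stage + 1
    if u < cfg.advance_prob + cfg.regress_prob:
        return max(stage - 1, 0)
    return stage


def generate_longitudinal(cfg: GeneratorConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Follow-up visits (year1 and/or year2) for a cross-sectional cohort.

    Follow-up true stages evolve by the per-year kernel conditioned on the
    (baseline, time-invariant) true amyloid state; all measured channels are
    regenerated at the new true stage.
    """
    for col in TRUTH_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing ground-truth column {col!r}")
    n = len(cohort)
    n_both = min(cfg.n_followup_both, cfg.n_followup_1y, cfg.n_followup_2y)
    n_unique = cfg.n_followup_1y + cfg.n_followup_2y - n_both
    if n_unique > n:  # small cohorts: shrink the design proportionally
        scale = n / n_unique
        n1 = int(round(cfg.n_followup_1y * scale))
        n2 = int(round(cfg.n_followup_2y * scale))
        n_both = min(int(round(n_both * scale)), n1, n2)
        n_unique = min(n, n1 + n2 - n_both)
    else:
        n1, n2 = cfg.n_followup_1y, cfg.n_followup_2y

    pick_rng = _rng(cfg.seed, "followup_selection")
    unique_idx = pick_rng.choice(n, size=n_unique, replace=False)
    set_1y = set(unique_idx[:n1].tolist())
    set_2y = set(unique_idx[n_unique - n2 :].tolist()) if n2 else set()

    kern_rng = _rng(cfg.seed, "transitions")
    rows = []
    for idx in sorted(set_1y | set_2y):
        base = cohort.iloc[idx]
        t0 = int(base["true_stage"])
        apos = bool(base["true_amyloid_positive"])
        t1 = _advance_stage(cfg, t0, apos, kern_rng.random())
        if idx in set_1y:
            rows.append((idx, "year1", 1, t1))
        if idx in set_2y:
            t2 = _advance_stage(cfg, t1, apos, kern_rng.random())
            rows.append((idx, "year2", 2, t2))
    if not rows:
        raise ValueError("follow-up design selected no subjects")

    idxs = np.array([r[0] for r in rows])
    visits = [r[1] for r in rows]
    years = np.array([r[2] for r in rows])
    new_stage = np.array([r[3] for r in rows], dtype=int)

    suvr = _draw_suvr(cfg, new_stage, _rng(cfg.seed, "tau_suvr/followup"),
                      _rng(cfg.seed, "jitter/followup"))
    meta_means = np.asarray(cfg.meta_roi_mean_by_stage)[new_stage]
    meta = _lognormal(
        _rng(cfg.seed, "meta_roi/followup"), meta_means, cfg.meta_roi_cv * meta_means, len(rows)
    )
    amy_rng = _rng(cfg.seed, "amyloid/followup")
    apos_arr = cohort["true_amyloid_positive"].to_numpy()[idxs].astype(bool)
    amy_mean = np.where(
        apos_arr, np.asarray(cfg.amyloid_pos_suvr_by_stage)[new_stage], cfg.amyloid_neg_suvr_mean
    )
    suvr_amyloid = _lognormal(amy_rng, amy_mean, cfg.amyloid_suvr_sd, len(rows))

    out = pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy()[idxs],
            "visit": visits,
            "diagnosis": cohort["diagnosis"].to_numpy()[idxs],
            "age_years": np.round(cohort["age_years"].to_numpy()[idxs] + years, 1),
        }
    )
    for i in range(N_STAGES):
        out[f"suvr_braak{i + 1}"] = suvr[:, i]
    out["suvr_meta_roi"] = meta
    out["suvr_amyloid"] = suvr_amyloid
    out["true_stage"] = new_stage
    out["true_amyloid_positive"] = apos_arr
    return out


def pipeline_view(df: pd.DataFrame) -> pd.DataFrame:
    """Drop the hidden ground-truth columns (the pipeline-facing export)."""
    return df.drop(columns=[c for c in TRUTH_COLUMNS if c in df.columns])
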