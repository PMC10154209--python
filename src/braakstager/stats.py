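"""Statistical engine: heteroscedastic ANOVA, many-to-one contrasts, chi2,
proportion comparisons and the symptom-onset (EYO) analyses.

Group comparisons across Braak stages use the Brown-Forsythe ANOVA (the F*
statistic on group means that does not pool variances) because stage groups
have grossly unequal spreads, followed by Dunnett-style many-to-one contrasts
of every stage against stage 0.  Each contrast uses a Welch t statistic with
Satterthwaite degrees of freedom; the familywise adjustment evaluates the
null distribution of the maximum |T| over the correlated contrast vector
(correlation induced by the shared stage-0 control) by seeded Monte Carlo.
With a single contrast there is no multiplicity and the adjusted p equals
the Welch p exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class BrownForsytheResult:
    statistic: float
    df_num: float
    df_den: float
    pvalue: float


def brown_forsythe_anova(groups: Sequence[np.ndarray]) -> BrownForsytheResult:
    """Brown-Forsythe F* test for equality of group means under unequal variances.

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, with Satterthwaite
    denominator degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.size for g in groups])
    if np.any(n < 2):
        raise ValueError("every group needs at least 2 observations")
    N = n.sum()
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    grand = float(np.concatenate(groups).mean())
    num = float(np.sum(n * (m - grand) ** 2))
    den_terms = (1 - n / N) * v
    den = float(den_terms.sum())
    if den == 0:
        raise ValueError("all groups have zero variance")
    F = num / den
    c = den_terms / den
    df_num = k - 1
    df_den = 1.0 / float(np.sum(c**2 / (n - 1)))
    p = float(sps.f.sf(F, df_num, df_den))
    return BrownForsytheResult(statistic=F, df_num=df_num, df_den=df_den, pvalue=p)


def dunnett_contrasts(
    groups: Sequence[np.ndarray],
    n_mc: int = 50_000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Many-to-one contrasts of groups[1:] vs the control groups[0].

    Per contrast: Welch t with Satterthwaite df, unadjusted two-sided p, and
    a familywise-adjusted p from the Monte-Carlo distribution of max |T|
    across contrasts (product-correlation structure lambda_i lambda_j from
    the shared control).  ``rng`` seeds the draws; pass one for reproducible
    adjusted p values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2:
        raise ValueError("need a control group and at least one comparison group")
    n = np.array([g.size for g in groups])
    if np.any(n < 2):
        raise ValueError("every group needs at least 2 observations")
    rng = np.random.default_rng(rng)

    control = groups[0]
    v0 = control.var(ddof=1) / control.size
    est, tval, df, p_unadj = [], [], [], []
    for g in groups[1:]:
        vi = g.var(ddof=1) / g.size
        diff = g.mean() - control.mean()
        se = np.sqrt(v0 + vi)
        t = diff / se
        # Welch-Satterthwaite degrees of freedom
        d = (v0 + vi) ** 2 / (
            v0**2 / (control.size - 1) + vi**2 / (g.size - 1)
        )
        est.append(diff)
        tval.append(t)
        df.append(d)
        p_unadj.append(2 * sps.t.sf(abs(t), d))
    est = np.array(est)
    tval = np.array(tval)
    df = np.array(df)
    p_unadj = np.array(p_unadj)
    k = len(est)

    if k == 1:
        p_adj = p_unadj.copy()
    else:
        vi = np.array([g.var(ddof=1) / g.size for g in groups[1:]])
        lam = np.sqrt(v0 / (v0 + vi))
        z0 = rng.standard_normal(n_mc)
        e = rng.standard_normal((n_mc, k))
        x = lam * z0[:, None] + np.sqrt(1 - lam**2) * e
        u = rng.chisquare(df, size=(n_mc, k)) / df
        max_t = np.abs(x / np.sqrt(u)).max(axis=1)
        p_adj = np.array([(max_t >= abs(t)).mean() for t in tval])
        p_adj = np.minimum(np.maximum(p_adj, p_unadj), 1.0)

    return pd.DataFrame(
        {
            "estimate": est,
            "t": tval,
            "df": df,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
        }
    )


@dataclass
class StageComparison:
    """Omnibus test plus per-stage contrasts against stage 0."""

    omnibus: BrownForsytheResult
    contrasts: pd.DataFrame  # indexed by stage
    stages: np.ndarray
    group_sizes: np.ndarray


def compare_stages(
    values,
    stages,
    n_mc: int = 50_000,
    rng: Optional[np.random.Generator] = None,
    min_group_size: int = 2,
) -> StageComparison:
    """Compare a biomarker across Braak stages with stage 0 as reference.

    Missing values are dropped pairwise.  Stages with fewer than
    ``min_group_size`` usable observations are excluded (except stage 0,
    whose absence is an error).
    """
    values = np.asarray(values, dtype=float)
    stages = np.asarray(stages)
    keep = ~np.isnan(values)
    values, stages = values[keep], stages[keep]
    levels = np.unique(stages)
    if 0 not in levels:
        raise ValueError("reference group (stage 0) is empty")
    usable = [s for s in levels if (stages == s).sum() >= min_group_size]
    if 0 not in usable:
        raise ValueError(f"reference group (stage 0) has < {min_group_size} observations")
    if len(usable) < 2:
        raise ValueError("need at least 2 stage groups with enough observations")
    groups = [values[stages == s] for s in usable]
    omnibus = brown_forsythe_anova(groups)
    contrasts = dunnett_contrasts(groups, n_mc=n_mc, rng=rng)
    contrasts.index = pd.Index([int(s) for s in usable[1:]], name="stage")
    return StageComparison(
        omnibus=omnibus,
        contrasts=contrasts,
        stages=np.array(usable),
        group_sizes=np.array([g.size for g in groups]),
    )


def assumption_diagnostics(groups: Sequence[np.ndarray]) -> dict:
    """Normality (Anderson-Darling per group) and equal-s.d. (Bartlett) checks.

    Diagnostics only; the pipeline proceeds with the heteroscedasticity-robust
    omnibus regardless of the outcome.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    ad = [sps.anderson(g, dist="norm", method="interpolate") for g in groups]
    bart_stat, bart_p = sps.bartlett(*groups)
    return {
        "anderson_darling_statistics": [float(a.statistic) for a in ad],
        "bartlett_statistic": float(bart_stat),
        "bartlett_pvalue": float(bart_p),
    }


def compare_positivity_proportions(
    binary_status,
    stages,
    stage_pairs: Sequence[Tuple[int, int]],
) -> pd.DataFrame:
    """Pearson chi-square (uncorrected) on the 2x2 table for each stage pair.

    Each pair compares the proportion positive between two stages.  A zero
    row/column margin makes the chi-square statistic undefined; an error
    suggests an exact test instead.
    """
    binary_status = np.asarray(binary_status)
    stages = np.asarray(stages)
    keep = pd.notna(binary_status)
    binary_status = binary_status[keep].astype(bool)
    stages = stages[keep]
    rows = []
    for a, b in stage_pairs:
        table = np.array(
            [
                [
                    int((binary_status & (stages == s)).sum()),
                    int((~binary_status & (stages == s)).sum()),
                ]
                for s in (a, b)
            ]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError(
                f"zero margin in 2x2 table for stages {a} vs {b}; "
                "use an exact test (not implemented)"
            )
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        rows.append({"stage_a": a, "stage_b": b, "chi2": float(chi2), "pvalue": float(p)})
    return pd.DataFrame(rows)


def compute_eyo(age_years, parental_onset_age):
    """Estimated years to symptom onset: participant age minus parental onset age.

    Negative values are years *before* the expected onset.  Missing parental
    onset propagates to a missing EYO.  Vectorized over array inputs.
    """
    age = np.asarray(age_years, dtype=float)
    onset = np.asarray(parental_onset_age, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(age[~np.isnan(age)] <= 0) or np.any(onset[~np.isnan(onset)] <= 0):
            raise ValueError("ages must be positive")
    out = age - onset
    return float(out) if out.ndim == 0 else out


def eyo_stage_association(
    eyo,
    stages,
    n_permutations: int = 5_000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Spearman trend between EYO and stage with a seeded permutation p value.

    Returns (rho, p).  p = (1 + #{|rho_perm| >= |rho|}) / (n_permutations + 1).
    """
    eyo = np.asarray(eyo, dtype=float)
    stages = np.asarray(stages, dtype=float)
    keep = ~(np.isnan(eyo) | np.isnan(stages))
    eyo, stages = eyo[keep], stages[keep]
    if eyo.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(stages).size < 2:
        raise ValueError("stage column is constant")
    rng = np.random.default_rng(rng)
    rho = float(sps.spearmanr(eyo, stages).statistic)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(stages)
        r = sps.spearmanr(eyo, perm).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return rho, float(p)
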