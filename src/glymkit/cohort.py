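"""Synthetic two-visit mTBI / control cohort with known effect structure.

The generator draws a cross-sectional control group and a longitudinal mTBI
group (14Day and 6-12Mon visits) whose marginal marker distributions and
cross-correlations mirror the effect structure the statistics battery is
built to detect:

* log white-matter ePVS burden is linear in age (and group), so ePVS rises
  with age with a log-normal spread;
* the ALPS index declines linearly with age;
* the total symptom count is Poisson with a log-link on WM-ePVS burden;
* the chronic (6-12Mon) memory-problem flag follows a logistic model on
  education, CT/MRI findings and the acute WM-ePVS and ALPS markers;
* per-subject 6-12Mon/14Day ratios of ALPS and PSQI are drawn with a fixed
  negative correlation (better sleep tracks rising glymphatic activity);
* BG-ePVS burden carries a subject random intercept and a visit effect,
  giving the linear mixed model a known target.

All default coefficients are generator defaults calibrated once against the
control-group marginals the tool is meant to emulate (WM-ePVS ~ 0.40 +/-
0.18 %, ALPS ~ 1.51 +/- 0.12, PSQI ~ 6.5 +/- 3.5); they are not estimates
of any real cohort.  PSQI is kept continuous so stored visit ratios retain
their target correlation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COHORT_COLUMNS, MEMORY_ITEM_INDEX, N_RPQ_ITEMS, RPQ_COLUMNS

__all__ = ["CohortGenSpec", "make_synthetic_cohort"]

_REF_AGE = 40.0  # years; centering age keeps intercepts interpretable


@dataclass
class CohortGenSpec:
    """Generative coefficients for the synthetic cohort."""

    n_control: int = 37
    n_mtbi: int = 44
    age_range: tuple[float, float] = (18.0, 60.0)
    # log WM-ePVS model: log(wm) = gamma_0 + gamma_age*(age-40) + gamma_group*mTBI + N(0, wm_sd)
    gamma_0: float = -1.008
    gamma_age: float = 0.023  # per year; reproduces r ~ 0.65 with age
    gamma_group: float = 0.0
    wm_log_sd: float = 0.326
    # ALPS model: alps = beta_0 + beta_age*(age-40) + N(0, alps_sd)
    beta_0: float = 1.51
    beta_age: float = -0.00366  # per year; reproduces r ~ -0.37 with age
    alps_sd: float = 0.1115
    # symptom count: n_symptoms ~ Poisson(exp(eta_0 + eta_wm*wm + eta_group*mTBI))
    eta_0: float = 0.714
    eta_wm: float = 1.2  # per percent burden
    eta_group: float = 0.72
    # chronic memory-problem logit on (education, CT/MRI, acute WM-ePVS, acute ALPS)
    delta_0: float = -11.2
    delta_edu: float = -0.2367
    delta_ct: float = -1.6464
    delta_wm: float = 3.5513
    delta_alps: float = 9.3073
    # acute memory-problem logit (WM-ePVS only)
    delta14_0: float = -0.42
    delta14_wm: float = 1.2
    # visit-ratio coupling (6-12Mon / 14Day)
    rho_ratio: float = -0.42
    alps_ratio_sd: float = 0.08
    psqi_ratio_sd: float = 0.30
    # BG-ePVS longitudinal model: bg = bg_0 + visit_effect*late + b_i + eps
    bg_0: float = 0.50
    visit_effect_bg: float = 0.10
    tau: float = 0.25  # subject random-intercept sd
    bg_resid_sd: float = 0.12
    # nuisance marginals
    education_mean: float = 14.5
    education_sd: float = 2.8
    psqi_mean: float = 6.5
    psqi_sd: float = 3.5
    p_male: float = 0.5
    p_ct_positive: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_mtbi < 0:
            raise ValueError("cohort sizes must be >= 0")
        if abs(self.rho_ratio) > 1:
            raise ValueError("|rho_ratio| must be <= 1")
        for name in ("wm_log_sd", "alps_sd", "alps_ratio_sd", "psqi_ratio_sd",
                     "tau", "bg_resid_sd", "education_sd", "psqi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rpq_items(rng, n_symp: int, memory_flag: bool) -> np.ndarray:
    """One row of 22 RPQ item ratings consistent with (n_symptoms, memory flag)."""
    items = np.zeros(N_RPQ_ITEMS, dtype=int)
    n_symp = int(min(max(n_symp, 1 if memory_flag else 0), N_RPQ_ITEMS))
    if n_symp > 0:
        pool = np.arange(N_RPQ_ITEMS)
        if memory_flag:
            others = np.delete(pool, MEMORY_ITEM_INDEX)
            chosen = np.concatenate(
                [[MEMORY_ITEM_INDEX], rng.choice(others, size=n_symp - 1, replace=False)]
            )
        else:
            others = np.delete(pool, MEMORY_ITEM_INDEX)
            chosen = rng.choice(others, size=min(n_symp, others.size), replace=False)
        items[chosen] = rng.choice([2, 3, 4], size=chosen.size, p=[0.5, 0.35, 0.15])
    # sub-threshold ratings on a few remaining items
    rest = np.where(items == 0)[0]
    if memory_flag is False:
        # memory item may still be rated 0 or 1, never >= 2
        pass
    sub = rest[rng.random(rest.size) < 0.25]
    items[sub] = 1
    return items


def make_synthetic_cohort(spec: CohortGenSpec) -> pd.DataFrame:
    """Generate the cohort table (one row per subject-visit), deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []

    def base_subject(group: str, sid: str) -> dict:
        age = rng.uniform(*spec.age_range)
        return {
            "subject_id": sid,
            "group": group,
            "age": age,
            "sex": int(rng.random() < spec.p_male),
            "education": float(
                np.clip(rng.normal(spec.education_mean, spec.education_sd), 9, 24)
            ),
        }

    def markers(age: float, is_mtbi: bool) -> tuple[float, float]:
        logwm = (
            spec.gamma_0
            + spec.gamma_age * (age - _REF_AGE)
            + (spec.gamma_group if is_mtbi else 0.0)
            + rng.normal(0.0, spec.wm_log_sd)
        )
        alps = (
            spec.beta_0
            + spec.beta_age * (age - _REF_AGE)
            + rng.normal(0.0, spec.alps_sd)
        )
        return float(np.exp(logwm)), float(max(alps, 0.5))

    def symptoms(wm: float, is_mtbi: bool) -> int:
        mu = np.exp(
            spec.eta_0 + spec.eta_wm * wm + (spec.eta_group if is_mtbi else 0.0)
        )
        return int(min(rng.poisson(mu), N_RPQ_ITEMS))

    def row_from(sub, visit, wm, bg, alps, psqi, n_symp, memory_flag, gcs, ct):
        items = _rpq_items(rng, n_symp, memory_flag)
        rec = dict(sub)
        rec.update(
            visit=visit,
            gcs=gcs,
            ct_or_mri_positive=ct,
            rpq_total=int(items.sum()),
            n_symptoms=int(np.sum(items >= 2)),
            memory_problem=int(items[MEMORY_ITEM_INDEX] >= 2),
            psqi=float(np.clip(psqi, 0.1, 21.0)),
            wm_epvs=wm,
            bg_epvs=float(max(bg, 0.01)),
            alps_index=alps,
        )
        for col, val in zip(RPQ_COLUMNS, items):
            rec[col] = int(val)
        return rec

    # controls: one visit
    for i in range(spec.n_control):
        sub = base_subject("control", f"C{i:04d}")
        wm, alps = markers(sub["age"], is_mtbi=False)
        bg = spec.bg_0 + rng.normal(0.0, spec.tau) + rng.normal(0.0, spec.bg_resid_sd)
        psqi = rng.normal(spec.psqi_mean, spec.psqi_sd)
        n_symp = symptoms(wm, is_mtbi=False)
        mem = rng.random() < _sigmoid(spec.delta14_0 + spec.delta14_wm * wm - 1.2)
        rows.append(row_from(sub, "control", wm, bg, alps, psqi, n_symp, mem, np.nan, 0))

    # mTBI: two visits sharing a subject random intercept
    for i in range(spec.n_mtbi):
        sub = base_subject("mTBI", f"P{i:04d}")
        gcs = int(rng.choice([13, 14, 15], p=[0.05, 0.2, 0.75]))
        ct = int(rng.random() < spec.p_ct_positive)
        wm14, alps14 = markers(sub["age"], is_mtbi=True)
        b_i = rng.normal(0.0, spec.tau)
        bg14 = spec.bg_0 + b_i + rng.normal(0.0, spec.bg_resid_sd)
        bg6m = spec.bg_0 + spec.visit_effect_bg + b_i + rng.normal(0.0, spec.bg_resid_sd)
        psqi14 = float(np.clip(rng.normal(spec.psqi_mean, spec.psqi_sd), 0.5, 21.0))
        # correlated visit ratios: higher ALPS ratio <-> lower PSQI ratio
        z = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, spec.rho_ratio], [spec.rho_ratio, 1.0]]
        )
        alps_ratio = 1.0 + spec.alps_ratio_sd * z[0]
        psqi_ratio = max(1.0 + spec.psqi_ratio_sd * z[1], 0.05)
        alps6m = alps14 * alps_ratio
        psqi6m = psqi14 * psqi_ratio
        wm6m = float(np.exp(np.log(wm14) + rng.normal(0.0, 0.05)))

        n14 = symptoms(wm14, is_mtbi=True)
        n6m = symptoms(wm6m, is_mtbi=True)
        mem14 = rng.random() < _sigmoid(spec.delta14_0 + spec.delta14_wm * wm14)
        lp = (
            spec.delta_0
            + spec.delta_edu * sub["education"]
            + spec.delta_ct * ct
            + spec.delta_wm * wm14
            + spec.delta_alps * alps14
        )
        mem6m = rng.random() < _sigmoid(lp)

        rows.append(row_from(sub, "14Day", wm14, bg14, alps14, psqi14, n14, mem14, gcs, ct))
        rows.append(row_from(sub, "6-12Mon", wm6m, bg6m, alps6m, psqi6m, n6m, mem6m, gcs, ct))

    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return df


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))
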