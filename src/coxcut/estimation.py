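"""Effect estimation: adjusted rates, covariate screening, final Cox
models with a two-period treatment effect, and the IPW sensitivity
analysis.

Annual event rates are reported per 100 person-years of first-event
follow-up, adjusted over age-band x sex strata by combining
stratum-specific rates with total-person-time weights (Mantel–Haenszel
style standardization).  Covariates enter the final model when their
age/sex-adjusted hazard ratio is significant at the screening level, they
are complete (no missing data), and they sit on a configured
clinically-eligible allow-list.  The propensity-score sensitivity analysis
weights each subject by the inverse probability of the treatment actually
received (optionally stabilized by the marginal arm probability) and
refits the split Cox model with case weights and a robust sandwich
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survival_core import CoxFit, cox_fit, expand_time_split

DEFAULT_AGE_BANDS = ((0, 59), (60, 69), (70, 79), (80, 200))

# clinically-eligible confounders for the final model (judgment is not
# computable; this allow-list is configuration)
DEFAULT_CLINICAL_ALLOWLIST = (
    "insulin", "clopidogrel", "alzheimer", "cancer", "depression",
    "parkinson", "prior_hospitalization",
)

DEFAULT_SCREEN_CANDIDATES = (
    "dep_quintile", "dur_2_5", "dur_5_10", "dur_10p",
    "metformin", "sulfa", "glitazone", "oad_other", "insulin",
    "alzheimer", "cancer", "depression", "parkinson",
    "betablocker", "arb", "ace", "diuretic", "ccb", "antihtn_other",
    "antiplatelet", "aspirin", "clopidogrel", "prior_hospitalization",
)


# ---------------------------------------------------------------------------
# Mantel–Haenszel adjusted annual event rates

@dataclass
class MHRateResult:
    rates: dict            # arm -> adjusted rate per 100 person-years
    ci: dict               # arm -> (low, high)
    p_value: float         # two-sided, on the adjusted rate difference
    strata: pd.DataFrame   # per-stratum events / person-years by arm


def _stratum_labels(rows: pd.DataFrame, age_bands) -> pd.Series:
    age = rows["age"].to_numpy()
    band = np.full(len(rows), -1)
    for k, (lo, hi) in enumerate(age_bands):
        band[(age >= lo) & (age <= hi)] = k
    if (band < 0).any():
        raise ValueError("age outside every configured band")
    return pd.Series([f"{b}|{m}" for b, m in zip(band, rows["male"])],
                     index=rows.index)


def mh_adjusted_rates(rows: pd.DataFrame,
                      age_bands=DEFAULT_AGE_BANDS,
                      annualization: int = 365,
                      arm_col: str = "arm_fibrate") -> MHRateResult:
    """Age- and sex-adjusted annual event rates per arm.

    Stratum-specific incidence rates (events / person-years) are combined
    with the stratum's total person-time (both arms) as weight, so both
    arms are standardized to the same stratum structure; confidence
    intervals use a normal approximation on the log rate and the
    comparison p-value a normal approximation on the weighted rate
    difference.  Strata with zero person-time in either arm are dropped
    with a warning.
    """
    df = rows.copy()
    df["_stratum"] = _stratum_labels(df, age_bands)
    df["_py"] = df["followup_days"] / annualization
    g = (df.groupby(["_stratum", arm_col])
         .agg(events=("event", "sum"), py=("_py", "sum")).unstack(fill_value=0))
    events = g["events"]
    py = g["py"]
    usable = (py > 0).all(axis=1)
    if not usable.all():
        warnings.warn(f"dropping {int((~usable).sum())} stratum(s) with zero "
                      "person-time in an arm")
        events, py = events[usable], py[usable]
    if not usable.any():
        raise ValueError("no stratum with person-time in both arms")

    w = py.sum(axis=1)           # total person-years per stratum
    W = w.sum()
    rates, ci, var = {}, {}, {}
    for arm in events.columns:
        lam = events[arm] / py[arm]
        r = float((w * lam).sum() / W)
        v = float(((w / W) ** 2 * events[arm] / py[arm] ** 2).sum())
        rates[arm] = 100.0 * r
        var[arm] = (100.0 ** 2) * v
        if r > 0 and v > 0:
            se_log = np.sqrt(v) / r
            ci[arm] = (100.0 * r * np.exp(-1.96 * se_log),
                       100.0 * r * np.exp(1.96 * se_log))
        else:
            ci[arm] = (0.0, np.nan)
    a0, a1 = sorted(events.columns)
    z = (rates[a1] - rates[a0]) / np.sqrt(var[a1] + var[a0])
    p = float(2.0 * stats.norm.sf(abs(z)))
    strata = pd.concat({"events": events, "person_years": py}, axis=1)
    return MHRateResult(rates=rates, ci=ci, p_value=p, strata=strata)


# ---------------------------------------------------------------------------
# Univariate screening (age/sex-adjusted HR per candidate)

def screen_covariates(rows: pd.DataFrame, candidates=DEFAULT_SCREEN_CANDIDATES,
                      alpha: float = 0.05,
                      clinical_allowlist=DEFAULT_CLINICAL_ALLOWLIST,
                      ties: str = "efron"):
    """Age/sex-adjusted Cox screen of candidate confounders.

    A candidate is selected when its adjusted HR is significant at
    ``alpha``, the covariate is complete (no missing values), and it is on
    the clinically-eligible allow-list.  Returns ``(selected, report)``
    where the report covers every candidate.
    """
    base = rows.copy()
    base["age_c"] = base["age"] - 65.0
    cp = expand_time_split(base, "arm_fibrate", [])
    recs = []
    for cand in candidates:
        complete = cand in rows.columns and not rows[cand].isna().any()
        hr = lo = hi = p = np.nan
        note = ""
        if cand not in rows.columns:
            note = "absent"
        else:
            sub = cp if complete else cp[cp[cand].notna()]
            try:
                fit = cox_fit(sub, ["age_c", "male", cand], ties=ties)
                info = fit[cand]
                hr, lo, hi, p = (info["hr"], info["ci_low"], info["ci_high"],
                                 info["p"])
                if not fit.converged:
                    note = "unscreenable: no convergence"
            except (ValueError, np.linalg.LinAlgError) as err:
                note = f"unscreenable: {err}"
        eligible = cand in clinical_allowlist
        selected = (note == "" and complete and eligible
                    and np.isfinite(p) and p < alpha)
        if note == "" and not complete:
            note = "missing data"
        recs.append((cand, hr, lo, hi, p, complete, eligible, selected, note))
    report = pd.DataFrame(recs, columns=[
        "candidate", "hr", "hr_ci_low", "hr_ci_high", "p",
        "complete", "clinically_eligible", "selected", "note"])
    return list(report.loc[report.selected, "candidate"]), report


# ---------------------------------------------------------------------------
# Final nested models (crude / age-sex / fully adjusted)

def _as_cutoffs(cutoff_day):
    if cutoff_day is None:
        return []
    if np.isscalar(cutoff_day):
        return [float(cutoff_day)]
    return [float(c) for c in cutoff_day]


def fit_final_models(rows: pd.DataFrame, cutoff_day,
                     selected_covariates, ties: str = "efron"
                     ) -> dict[str, CoxFit]:
    """The three nested models with the treatment split at the cut-off.

    'crude' holds only the interval copies of the arm variable; 'agesex'
    adds continuous age and sex; 'full' adds the screened covariates (when
    none were selected it equals 'agesex' exactly).
    """
    cutoffs = _as_cutoffs(cutoff_day)
    base = rows.copy()
    base["age_c"] = base["age"] - 65.0
    cp = expand_time_split(base, "arm_fibrate", cutoffs)
    arm_terms = [f"arm_fibrate_p{k + 1}" for k in range(len(cutoffs) + 1)]
    models = {
        "crude": arm_terms,
        "agesex": arm_terms + ["age_c", "male"],
        "full": arm_terms + ["age_c", "male"] + list(selected_covariates),
    }
    return {name: cox_fit(cp, covs, ties=ties)
            for name, covs in models.items()}


# ---------------------------------------------------------------------------
# IPW propensity-score sensitivity analysis

@dataclass
class PropensityWeights:
    propensity: np.ndarray      # P(fibrate | covariates)
    prob_received: np.ndarray   # P(received arm | covariates)
    weight: np.ndarray
    stabilized: bool
    flagged_extreme: np.ndarray  # prob_received outside [0.01, 0.99]
    balance: pd.DataFrame        # SMD before/after weighting


def standardized_mean_differences(rows: pd.DataFrame, covariates,
                                  weights=None,
                                  arm_col: str = "arm_fibrate") -> pd.Series:
    """|SMD| per covariate between arms, optionally under weights."""
    w = np.ones(len(rows)) if weights is None else np.asarray(weights, float)
    arm = rows[arm_col].to_numpy()
    out = {}
    for cov in covariates:
        x = rows[cov].to_numpy(dtype=float)
        stats_ = []
        for a in (1, 0):
            m, ww = x[arm == a], w[arm == a]
            mu = np.average(m, weights=ww)
            va = np.average((m - mu) ** 2, weights=ww)
            stats_.append((mu, va))
        (m1, v1), (m0, v0) = stats_
        denom = np.sqrt((v1 + v0) / 2.0)
        out[cov] = abs(m1 - m0) / denom if denom > 0 else 0.0
    return pd.Series(out, name="smd")


def ipw_cox(rows: pd.DataFrame, covariates, cutoff_day,
            stabilized: bool = True, truncate_percentile: float | None = None,
            ties: str = "breslow"):
    """Inverse-probability-of-treatment-weighted split Cox fit.

    Fits a logistic propensity model of the arm on the covariates, weights
    each subject by 1 / P(arm received | covariates) (times the marginal
    arm probability when stabilized), and refits the Cox model with the
    treatment variable split at ``cutoff_day`` using case weights and a
    robust variance.  Subjects with estimated probability of the received
    arm outside [0.01, 0.99] are flagged; optional symmetric truncation
    clips weights at the given upper percentile.  Returns
    ``(CoxFit, PropensityWeights)``.
    """
    covariates = list(covariates)
    sub = rows.copy()
    if sub[covariates].isna().any().any():
        raise ValueError("ipw_cox requires complete covariates")
    if "age" in covariates:
        sub["age"] = sub["age"] - 65.0   # centered, as in the outcome model
    X = sm.add_constant(sub[covariates].astype(float), has_constant="add")
    arm = sub["arm_fibrate"].to_numpy()
    model = sm.Logit(arm, X)
    ps = np.clip(model.fit(disp=0).predict(X), 1e-12, 1 - 1e-12)
    prob_received = np.where(arm == 1, ps, 1.0 - ps)
    weight = 1.0 / prob_received
    if stabilized:
        marginal = arm.mean()
        weight *= np.where(arm == 1, marginal, 1.0 - marginal)
    flagged = (prob_received < 0.01) | (prob_received > 0.99)
    if truncate_percentile is not None:
        cap = np.percentile(weight, truncate_percentile)
        weight = np.minimum(weight, cap)

    balance = pd.DataFrame({
        "smd_unweighted": standardized_mean_differences(sub, covariates),
        "smd_weighted": standardized_mean_differences(sub, covariates,
                                                      weights=weight),
    })
    pw = PropensityWeights(propensity=ps, prob_received=prob_received,
                           weight=weight, stabilized=stabilized,
                           flagged_extreme=flagged, balance=balance)

    sub = sub.assign(ipw_weight=weight)
    cp = expand_time_split(sub, "arm_fibrate", _as_cutoffs(cutoff_day))
    arm_terms = [f"arm_fibrate_p{k + 1}"
                 for k in range(len(_as_cutoffs(cutoff_day)) + 1)]
    fit = cox_fit(cp, arm_terms, ties=ties, weight_col="ipw_weight",
                  robust=True)
    return fit, pw
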