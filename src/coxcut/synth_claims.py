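"""Synthetic claims generator for a new-user lipid-lowering cohort study.

Emulates the structure of French national claims (drug reimbursements,
hospital discharges, deaths) for diabetic, hypertensive patients at high
cardiovascular risk who initiate fibrate or statin monotherapy.  Treatment
choice is confounded (logistic on baseline covariates, intercept calibrated
to a target fibrate share) and outcomes follow a piecewise-exponential law
whose treatment hazard ratio changes at configurable cut-off days, so every
downstream stage can be tested against known ground truth.

Time is measured in integer days from a study epoch (day 0 = opening of the
inclusion window).  Defaults mirror a 548-day inclusion window with
administrative follow-up ending at day 913 (~30 months), a 913-day washout
lookback, and a two-period treatment effect (HR 0.95 before day 540, 1.73
after).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

# ---------------------------------------------------------------------------
# Study-clock constants (integer days)

DAYS_PER_YEAR = 365
WASHOUT_DAYS = 913          # "30 months" of lookback
INDEX_WINDOW = (0, 548)     # 18-month inclusion window
ADMIN_END_DAY = 913         # administrative end of follow-up

# Code classes understood by the cohort builder
LIPID_CLASSES = ("statin", "fibrate")
OAD_CLASSES = ("oad_metformin", "oad_sulfa", "oad_glitazone", "oad_other")
ANTIHTN_PREFIX = "antihypertensive_"
CV_EVENT_PREFIX = "cv_event_"

# Baseline covariate marginals for the simulated population (high-CV-risk
# diabetic new users of lipid-lowering drugs).
DEFAULT_PREVALENCE: dict[str, float] = {
    "metformin": 0.641,
    "sulfa": 0.420,
    "glitazone": 0.073,
    "oad_other": 0.177,
    "insulin": 0.077,
    "alzheimer": 0.0085,
    "cancer": 0.013,
    "depression": 0.108,
    "parkinson": 0.0051,
    "betablocker": 0.217,
    "arb": 0.219,
    "ace": 0.183,
    "diuretic": 0.052,
    "ccb": 0.266,
    "antihtn_other": 0.530,
    "aspirin": 0.160,
    "clopidogrel": 0.031,
    "prior_hospitalization": 0.176,
}

AGE_BANDS = ((50, 59), (60, 69), (70, 79), (80, 94))
AGE_BAND_PROBS = (0.158, 0.434, 0.305, 0.103)
FEMALE_SHARE = 0.476              # women only appear in the 60+ bands
DURATION_BANDS = ("<2", "2-5", "5-10", "10+")
DURATION_PROBS = (0.289, 0.237, 0.253, 0.221)
DEPRIVATION_PROBS = (0.228, 0.185, 0.162, 0.193, 0.232)

# Log-odds of receiving a fibrate (vs statin).  Signs/magnitudes reproduce
# the typical channeling pattern: fibrate users are younger, more often
# women and depressed, less exposed to insulin, metformin, antiplatelets and
# most antihypertensives.
DEFAULT_PROPENSITY: dict[str, float] = {
    "age_c": -0.0075,         # per year, centered at 65
    "male": -0.045,
    "metformin": -0.13,
    "oad_other": -0.115,
    "insulin": -0.19,
    "depression": 0.13,
    "betablocker": 0.065,
    "arb": -0.07,
    "ace": -0.13,
    "ccb": -0.095,
    "aspirin": -0.15,
    "clopidogrel": -0.19,
}

# Log hazard ratios on the composite outcome (all-cause death, ischemic
# stroke, MI, above-ankle amputation).
DEFAULT_LOG_HAZARDS: dict[str, float] = {
    "age_c": math.log(1.07),
    "male": math.log(1.61),
    "insulin": math.log(1.65),
    "depression": math.log(1.42),
    "alzheimer": math.log(2.46),
    "cancer": math.log(2.29),
    "parkinson": math.log(2.67),
    "clopidogrel": math.log(1.44),
    "ccb": math.log(1.14),
    "prior_hospitalization": math.log(1.17),
    "dur_5_10": math.log(1.20),
    "dur_10p": math.log(1.52),
}

# Two-period generating truth: null-ish effect early, harmful effect late.
DEFAULT_SCHEDULE = (
    (0, 540, math.log(0.95)),
    (540, math.inf, math.log(1.73)),
)

EVENT_TYPES = ("death", "stroke", "mi", "amputation")
EVENT_TYPE_PROBS = (0.460, 0.270, 0.2583, 0.0117)

AGE_CENTER = 65.0

# Designed protocol violations and their default shares of n_subjects.
EXCLUSION_RULES = ("prior_lipid", "prior_cv_event", "underage",
                   "single_reimbursement", "non_gp")
DEFAULT_EXCLUSION_FRACTIONS: dict[str, float] = {
    "prior_lipid": 0.02,
    "prior_cv_event": 0.02,
    "underage": 0.01,
    "single_reimbursement": 0.02,
    "non_gp": 0.01,
}


@dataclass
class GeneratorConfig:
    """Ground-truth configuration of the synthetic claims generator.

    ``baseline_hazard`` is in events per person-day for the reference
    subject (age 65, female, no comedication/comorbidity, statin arm); the
    default is calibrated so the overall annual event rate is ~2.2%/year
    under the default covariate mix.  ``treatment_log_hr_schedule`` is a
    list of ``(start_day, end_day, log_hr)`` intervals, contiguous from 0.
    """

    n_subjects: int = 10_000
    study_window: tuple[int, int] = INDEX_WINDOW
    fibrate_share_target: float = 0.128
    propensity_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPENSITY))
    baseline_hazard: float = 2.0e-5
    covariate_log_hazards: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_HAZARDS))
    treatment_log_hr_schedule: tuple = DEFAULT_SCHEDULE
    censor_admin_day: int = ADMIN_END_DAY
    random_censor_rate: float | None = None   # per-day; None = admin only
    missing_deprivation_rate: float = 0.09
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    exclusion_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_FRACTIONS))
    refill_interval_days: int = 30
    monthly_persistence: float = 0.92
    switch_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not (0.0 < self.fibrate_share_target < 1.0):
            raise ValueError("fibrate_share_target must lie strictly in (0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be strictly positive")
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study_window must be a non-empty (start, end)")
        if self.censor_admin_day <= self.study_window[1]:
            raise ValueError("censor_admin_day must fall after the index window")
        validate_schedule(self.treatment_log_hr_schedule)
        if self.random_censor_rate is not None and self.random_censor_rate <= 0:
            raise ValueError("random_censor_rate must be positive or None")
        if not (0.0 <= self.missing_deprivation_rate < 1.0):
            raise ValueError("missing_deprivation_rate must lie in [0, 1)")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def validate_schedule(schedule) -> None:
    """Intervals must start at 0, be contiguous, non-overlapping, and
    cover [0, inf)."""
    if not schedule:
        raise ValueError("treatment_log_hr_schedule is empty")
    if schedule[0][0] != 0:
        raise ValueError("treatment_log_hr_schedule must start at day 0")
    for (s0, e0, _), (s1, _, _) in zip(schedule, schedule[1:]):
        if e0 != s1:
            raise ValueError("treatment_log_hr_schedule intervals must be "
                             "contiguous and non-overlapping")
        if e0 <= s0:
            raise ValueError("treatment_log_hr_schedule intervals must have "
                             "positive length")
    if not math.isinf(schedule[-1][1]):
        raise ValueError("last schedule interval must extend to infinity")


# ---------------------------------------------------------------------------
# Population

# Covariate columns carried on the truth/analysis tables, in output order.
BINARY_COVARIATES = tuple(DEFAULT_PREVALENCE)
DURATION_DUMMIES = ("dur_2_5", "dur_5_10", "dur_10p")


def generate_population(config: GeneratorConfig):
    """Draw demographics, baseline covariates, and confounded treatment arms.

    Returns ``(demographics, truth)``: ``demographics`` has one row per
    subject (subject_id, sex, birth_year, deprivation_quintile with NaN for
    missing); ``truth`` carries the full covariate matrix, the assigned arm
    and the index day — ground truth for tests only, never an input to the
    cohort builder.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    band = rng.choice(len(AGE_BANDS), size=n, p=AGE_BAND_PROBS)
    lo = np.array([b[0] for b in AGE_BANDS])
    hi = np.array([b[1] for b in AGE_BANDS])
    age = rng.integers(lo[band], hi[band] + 1)
    # women only appear from 60 up; share among 60+ chosen so the overall
    # female share matches FEMALE_SHARE
    p_female_60p = FEMALE_SHARE / (1.0 - AGE_BAND_PROBS[0])
    male = np.where(band == 0, 1, (rng.random(n) >= p_female_60p).astype(int))

    cov = {"age": age.astype(float), "male": male}
    for name, prev in config.prevalence.items():
        cov[name] = (rng.random(n) < prev).astype(int)

    dur = rng.choice(len(DURATION_BANDS), size=n, p=DURATION_PROBS)
    cov["dur_band"] = np.array(DURATION_BANDS)[dur]
    cov["dur_2_5"] = (dur == 1).astype(int)
    cov["dur_5_10"] = (dur == 2).astype(int)
    cov["dur_10p"] = (dur == 3).astype(int)

    quintile = rng.choice(np.arange(1, 6), size=n, p=DEPRIVATION_PROBS).astype(float)
    quintile[rng.random(n) < config.missing_deprivation_rate] = np.nan
    cov["dep_quintile"] = quintile

    lp = _linear_predictor(cov, config.propensity_coefficients)
    intercept = _calibrate_intercept(lp, config.fibrate_share_target)
    fibrate = (rng.random(n) < expit(intercept + lp)).astype(int)

    index_day = rng.integers(config.study_window[0],
                             config.study_window[1] + 1, size=n)
    subject_id = np.array([f"S{i:07d}" for i in range(n)])

    truth = pd.DataFrame({"subject_id": subject_id,
                          "arm": np.where(fibrate == 1, "fibrate", "statin"),
                          "arm_fibrate": fibrate,
                          "index_day": index_day,
                          **cov})
    demographics = pd.DataFrame({
        "subject_id": subject_id,
        "sex": np.where(male == 1, "M", "F"),
        "birth_year": 2008 + index_day // DAYS_PER_YEAR - age,
        "deprivation_quintile": quintile,
    })
    return demographics, truth


def _linear_predictor(cov: dict, coefficients: dict[str, float]) -> np.ndarray:
    n = len(cov["age"])
    lp = np.zeros(n)
    for name, beta in coefficients.items():
        if beta == 0.0:
            continue
        if name == "age_c":
            lp += beta * (np.asarray(cov["age"], dtype=float) - AGE_CENTER)
        else:
            if name not in cov:
                raise KeyError(f"unknown covariate in coefficients: {name!r}")
            lp += beta * np.asarray(cov[name], dtype=float)
    return lp


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Root-find the logistic intercept so E[expit(c + lp)] = target."""
    def gap(c):
        return float(np.mean(expit(c + lp))) - target
    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"cannot calibrate intercept to fibrate share {target}")
    return brentq(gap, lo, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# Outcomes: piecewise-exponential simulation with exact inversion

def simulate_outcomes(truth: pd.DataFrame, config: GeneratorConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw event/censor days (relative to each subject's index day).

    The subject hazard at follow-up time t is
    ``baseline_hazard * exp(sum covariate effects + treatment log HR at t)``;
    the cumulative hazard is piecewise linear, so a unit-exponential draw is
    inverted in closed form.  Censoring is the earlier of the administrative
    end and (optionally) an independent exponential censoring time.
    """
    validate_schedule(config.treatment_log_hr_schedule)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(truth)

    cov = {c: truth[c].to_numpy() for c in truth.columns
           if c not in ("subject_id", "arm", "dur_band")}
    cov["age"] = truth["age"].to_numpy()
    mult = np.exp(_linear_predictor(cov, config.covariate_log_hazards))
    fibrate = truth["arm_fibrate"].to_numpy()

    e_draw = rng.exponential(size=n)
    t_event = np.full(n, np.inf)
    cum = np.zeros(n)
    remaining = np.ones(n, dtype=bool)
    for (s, e, g) in config.treatment_log_hr_schedule:
        rate = config.baseline_hazard * mult * np.where(fibrate == 1,
                                                        math.exp(g), 1.0)
        seg_len = (e - s) if not math.isinf(e) else np.inf
        seg_cum = rate * seg_len
        inside = remaining & (e_draw < cum + seg_cum)
        t_event[inside] = s + (e_draw[inside] - cum[inside]) / rate[inside]
        remaining &= ~inside
        if math.isinf(e):
            break
        cum = cum + seg_cum

    admin = (config.censor_admin_day - truth["index_day"].to_numpy()).astype(float)
    censor = admin.copy()
    if config.random_censor_rate is not None:
        censor = np.minimum(censor, rng.exponential(
            1.0 / config.random_censor_rate, size=n))
    censor = np.maximum(np.floor(censor), 1.0)

    event_day = np.ceil(t_event)
    event = (event_day <= censor).astype(int)
    etype = np.where(
        event == 1,
        rng.choice(np.array(EVENT_TYPES), size=n, p=EVENT_TYPE_PROBS),
        "none")

    out = truth.copy()
    out["true_event_day"] = np.where(event == 1, event_day, np.nan)
    out["true_censor_day"] = censor.astype(int)
    out["event"] = event
    out["event_type"] = etype
    out["followup_days"] = np.where(event == 1, event_day, censor).astype(int)
    return out


def generate_analysis_table(config: GeneratorConfig):
    """One-call generator of a ready-to-model analysis table.

    Bypasses the claims stream (statistical modules are testable without the
    cohort builder).  Returns ``(analysis, truth)`` where ``analysis`` has
    the analytic columns the estimation modules consume and ``truth`` keeps
    the generating ground truth.
    """
    _, truth = generate_population(config)
    truth = simulate_outcomes(truth, config)
    cols = (["subject_id", "arm", "arm_fibrate", "index_day",
             "followup_days", "event", "event_type", "age", "male",
             "dep_quintile", "dur_band"]
            + list(DURATION_DUMMIES) + list(BINARY_COVARIATES))
    analysis = truth[cols].copy()
    analysis["antiplatelet"] = ((analysis["aspirin"] == 1)
                                | (analysis["clopidogrel"] == 1)).astype(int)
    return analysis, truth


# ---------------------------------------------------------------------------
# Claims stream

_COMED_CODE = {
    "metformin": "oad_metformin", "sulfa": "oad_sulfa",
    "glitazone": "oad_glitazone", "oad_other": "oad_other",
    "insulin": "insulin",
    "betablocker": ANTIHTN_PREFIX + "betablocker",
    "arb": ANTIHTN_PREFIX + "arb", "ace": ANTIHTN_PREFIX + "ace",
    "diuretic": ANTIHTN_PREFIX + "diuretic", "ccb": ANTIHTN_PREFIX + "ccb",
    "antihtn_other": ANTIHTN_PREFIX + "other",
    "aspirin": "aspirin", "clopidogrel": "clopidogrel",
}
_COMORBIDITY = ("alzheimer", "cancer", "depression", "parkinson")

# days before index at which the first disease-defining drug appears, per
# designed diabetes-duration band (bands >= 5y are lookback-truncated)
_DURATION_FIRST_OAD = {"<2": 500, "2-5": 850, "5-10": 913, "10+": 913}


def generate_claims(demographics: pd.DataFrame, truth: pd.DataFrame,
                    config: GeneratorConfig) -> pd.DataFrame:
    """Materialize the claims stream implied by the generated ground truth.

    Designed-includable subjects satisfy every inclusion rule by
    construction (two GP index reimbursements, >=3 oral-antidiabetic and
    >=3 antihypertensive reimbursements inside a one-year span of the
    lookback, no prior lipid drug or cardiovascular hospitalization);
    designed-excluded subjects violate exactly one configured rule.
    Returns a table of (subject_id, day, record_type, code_class,
    prescriber) sorted by subject and day.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    n = len(truth)

    design = np.array(["include"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for rule in EXCLUSION_RULES:
        k = int(round(config.exclusion_fractions.get(rule, 0.0) * n))
        design[order[pos:pos + k]] = rule
        pos += k

    sid = truth["subject_id"].to_numpy()
    index_day = truth["index_day"].to_numpy()
    arm = truth["arm"].to_numpy()
    fup = truth["followup_days"].to_numpy()
    event = truth["event"].to_numpy()
    etype = truth["event_type"].to_numpy()
    dur_band = truth["dur_band"].to_numpy()
    flags = {name: truth[name].to_numpy() for name in
             list(_COMED_CODE) + list(_COMORBIDITY) + ["prior_hospitalization"]}

    recs_sid, recs_day, recs_type, recs_code, recs_rx = [], [], [], [], []

    def add(s, day, rtype, code, rx="na"):
        recs_sid.append(s); recs_day.append(int(day))
        recs_type.append(rtype); recs_code.append(code); recs_rx.append(rx)

    for i in range(n):
        s, idx, a = sid[i], int(index_day[i]), arm[i]
        rule = design[i]

        # --- index drug stream -------------------------------------------
        rx = "other" if rule == "non_gp" else "gp"
        add(s, idx, "drug", a, rx)
        if rule != "single_reimbursement":
            add(s, idx + config.refill_interval_days, "drug", a, rx)
            # refills while persistent, capped at event/censor
            day = idx + 2 * config.refill_interval_days
            stop = idx + int(fup[i])
            while day < stop and rng.random() < config.monthly_persistence:
                add(s, day, "drug", a, "gp")
                day += config.refill_interval_days
            if a == "fibrate" and rng.random() < config.switch_fraction:
                sw = idx + int(rng.integers(60, max(61, int(fup[i]) + 1)))
                if sw < stop:
                    add(s, sw, "drug", "statin", "gp")

        if rule == "prior_lipid":
            # opposite class so the washout violation cannot merge into the
            # index run itself
            add(s, idx - 100, "drug",
                "statin" if a == "fibrate" else "fibrate", "gp")
        if rule == "prior_cv_event":
            add(s, idx - 200, "hospital", CV_EVENT_PREFIX + "stroke")

        # --- disease-defining and comedication streams -------------------
        got_oad = got_htn = False
        for name, code in _COMED_CODE.items():
            if flags[name][i] != 1:
                continue
            k = int(rng.integers(3, 6))
            days = np.sort(rng.choice(DAYS_PER_YEAR, size=k, replace=False)) \
                + idx - DAYS_PER_YEAR
            for d in days:
                add(s, d, "drug", code, "gp")
            got_oad |= code in OAD_CLASSES
            got_htn |= code.startswith(ANTIHTN_PREFIX)
        first_oad = idx - _DURATION_FIRST_OAD[dur_band[i]]
        add(s, first_oad, "drug", "oad_metformin", "gp")
        if not got_oad:
            # diabetes qualification clustered at disease onset so the
            # derived duration band stays consistent with the design
            for d in (first_oad + 80, first_oad + 160):
                add(s, d, "drug", "oad_metformin", "gp")
        if not got_htn:
            for d in (idx - 800, idx - 700, idx - 600):
                add(s, d, "drug", ANTIHTN_PREFIX + "other", "gp")

        for name in _COMORBIDITY:
            if flags[name][i] == 1:
                add(s, idx - int(rng.integers(1, DAYS_PER_YEAR)),
                    "drug", f"comorbidity_{name}", "gp")
        if flags["prior_hospitalization"][i] == 1:
            add(s, idx - int(rng.integers(1, DAYS_PER_YEAR)),
                "hospital", "hospital_any")

        # --- outcome ------------------------------------------------------
        if event[i] == 1:
            d = idx + int(fup[i])
            if etype[i] == "death":
                add(s, d, "death", "death")
            else:
                add(s, d, "hospital", CV_EVENT_PREFIX + etype[i])

    claims = pd.DataFrame({"subject_id": recs_sid, "day": recs_day,
                           "record_type": recs_type, "code_class": recs_code,
                           "prescriber": recs_rx})
    claims = claims.sort_values(["subject_id", "day"],
                                kind="stable").reset_index(drop=True)
    truth = truth.copy()
    truth["design_group"] = design

    # age/sex exclusion: realized through demographics, handled by caller
    return claims, truth


def apply_designed_demographic_exclusions(demographics: pd.DataFrame,
                                          truth: pd.DataFrame) -> pd.DataFrame:
    """Make 'underage' designed subjects violate the age/sex threshold."""
    demo = demographics.set_index("subject_id")
    under = truth.loc[truth["design_group"] == "underage", "subject_id"]
    male = truth.set_index("subject_id")["male"]
    idx_year = 2008 + truth.set_index("subject_id")["index_day"] // DAYS_PER_YEAR
    for s in under:
        age = 45 if male[s] == 1 else 55
        demo.loc[s, "birth_year"] = int(idx_year[s]) - age
    return demo.reset_index()


def write_tables(outdir, demographics, claims, truth=None) -> dict:
    """Write the generator outputs as UTF-8 comma-separated tables.

    The truth table is ground truth for recovery tests only and is written
    under a name flagging that status.
    """
    import pathlib
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"demographics": outdir / "demographics.csv",
             "claims": outdir / "claims.csv"}
    demographics.to_csv(paths["demographics"], index=False)
    claims.to_csv(paths["claims"], index=False)
    if truth is not None:
        paths["truth"] = outdir / "subject_truth.TEST_ONLY.csv"
        truth.to_csv(paths["truth"], index=False)
    return paths
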