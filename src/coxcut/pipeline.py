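"""One-command orchestration: simulate -> build cohort -> find cut-off ->
estimate, with a reproducibility manifest and a human-readable report.

Every stage writes delimited text tables under the output directory; the
manifest records the config snapshot, seeds, stage timings, SHA-256
digests of every output file and library versions, so a run can be
replayed and byte-compared.  Attrition counts are logged after every
filter because the cohort's audit trail is the flow chart.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_builder import (CENSORING_RULES, EligibilityCriteria,
                             apply_censoring, apply_inclusion,
                             derive_covariates, derive_outcome,
                             identify_initiators)
from .cutoff_search import CutoffGrid, bootstrap_select
from .estimation import (DEFAULT_CLINICAL_ALLOWLIST,
                         DEFAULT_SCREEN_CANDIDATES, fit_final_models,
                         ipw_cox, mh_adjusted_rates, screen_covariates)
from .survival_core import km_estimate
from .synth_claims import (ADMIN_END_DAY, GeneratorConfig,
                           apply_designed_demographic_exclusions,
                           generate_claims, generate_population,
                           simulate_outcomes, write_tables)

log = logging.getLogger("coxcut")

ENDPOINTS = {
    "composite": ("death", "stroke", "mi", "amputation"),
    "no_amputation": ("death", "stroke", "mi"),
}

IPW_COVARIATES = ("age", "male", "insulin", "depression", "metformin",
                  "aspirin", "clopidogrel", "ace", "ccb", "arb",
                  "betablocker", "oad_other")


def default_config() -> dict:
    return {
        "generator": {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in asdict(GeneratorConfig()).items()},
        "cohort": {"gap_days": 183, "admin_end_day": ADMIN_END_DAY},
        "cutoff": {"B": 500, "month_days": 30, "n_intervals_max": 3,
                   "min_events_per_interval_per_arm": 5},
        "estimation": {"alpha": 0.05,
                       "screen_candidates": list(DEFAULT_SCREEN_CANDIDATES),
                       "clinical_allowlist": list(DEFAULT_CLINICAL_ALLOWLIST)},
        "run": {"rules": ["itt", "persistence", "switch"],
                "endpoints": ["composite", "no_amputation"]},
    }


REQUIRED_KEYS = (("generator", "n_subjects"), ("run", "rules"))


def validate_config(cfg: dict) -> dict:
    """Merge over defaults and fail loudly on unknown/missing keys."""
    base = default_config()
    for section, keys in cfg.items():
        if section not in base:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(keys, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key in keys:
            if key not in base[section]:
                raise ValueError(f"unknown config key {section}.{key}")
    for section, key in REQUIRED_KEYS:
        if key not in cfg.get(section, {}):
            raise ValueError(f"missing required config key: {section}.{key}")
    merged = copy.deepcopy(base)
    for section, keys in cfg.items():
        merged[section].update(keys)
    for rule in merged["run"]["rules"]:
        if rule not in CENSORING_RULES:
            raise ValueError(f"unknown censoring rule {rule!r}")
    for ep in merged["run"]["endpoints"]:
        if ep not in ENDPOINTS:
            raise ValueError(f"unknown endpoint variant {ep!r}")
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _generator_config(cfg: dict) -> GeneratorConfig:
    kw = dict(cfg["generator"])
    kw["study_window"] = tuple(kw["study_window"])
    kw["treatment_log_hr_schedule"] = tuple(
        (s, (np.inf if e in (None, "inf", ".inf") else e), g)
        for s, e, g in kw["treatment_log_hr_schedule"])
    return GeneratorConfig(**kw)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)   # path -> sha256
    versions: dict = field(default_factory=dict)

    def digest(self, path: pathlib.Path) -> None:
        h = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = h

    def save(self, path: pathlib.Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _versions() -> dict:
    import lifelines
    import matplotlib
    import scipy
    import statsmodels
    return {"coxcut": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "lifelines": lifelines.__version__,
            "statsmodels": statsmodels.__version__,
            "matplotlib": matplotlib.__version__}


def _model_table(models: dict, ipw_fit=None) -> pd.DataFrame:
    recs = []
    for name, fit in models.items():
        lo, hi = fit.ci
        for k, cov in enumerate(fit.names):
            recs.append((name, cov, fit.coef[k], fit.hr[k], lo[k], hi[k],
                         fit.p[k], fit.loglik, fit.converged))
    if ipw_fit is not None:
        lo, hi = ipw_fit.ci
        for k, cov in enumerate(ipw_fit.names):
            recs.append(("ipw", cov, ipw_fit.coef[k], ipw_fit.hr[k], lo[k],
                         hi[k], ipw_fit.p[k], ipw_fit.loglik,
                         ipw_fit.converged))
    return pd.DataFrame(recs, columns=["model", "covariate", "coef", "hr",
                                       "hr_ci_low", "hr_ci_high", "p",
                                       "loglik", "converged"])


def run_pipeline(config: dict | str | pathlib.Path, out_dir,
                 seed: int | None = None) -> RunManifest:
    """Execute every stage for each requested censoring rule and endpoint.

    ``seed`` overrides the generator seed (stage seeds derive from it).
    Raises on invalid config before writing anything.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    if seed is not None:
        config["generator"]["seed"] = int(seed)

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen_cfg = _generator_config(config)
    manifest = RunManifest(config=config,
                           seeds={"generator": gen_cfg.seed,
                                  "bootstrap": gen_cfg.seed + 10_000},
                           versions=_versions())

    def stage(name):
        t0 = time.time()
        def done():
            manifest.timings[name] = round(time.time() - t0, 3)
            log.info("stage %s finished in %.1fs", name, time.time() - t0)
        return done

    # -- simulate ----------------------------------------------------------
    done = stage("simulate")
    demographics, truth = generate_population(gen_cfg)
    truth = simulate_outcomes(truth, gen_cfg)
    claims, truth = generate_claims(demographics, truth, gen_cfg)
    demographics = apply_designed_demographic_exclusions(demographics, truth)
    paths = write_tables(out, demographics, claims, truth)
    log.info("simulated %d subjects, %d claims", len(truth), len(claims))
    done()

    # -- cohorts -----------------------------------------------------------
    done = stage("build_cohort")
    criteria = EligibilityCriteria()
    # inclusion and covariates are rule/endpoint-invariant: build once
    cand = identify_initiators(claims, criteria)
    skel, attrition = apply_inclusion(cand, claims, demographics, criteria)
    skel = derive_covariates(skel, claims, demographics, criteria)
    cohorts = {}
    for ep in config["run"]["endpoints"]:
        with_outcome = derive_outcome(skel, claims,
                                      config["cohort"]["admin_end_day"],
                                      ENDPOINTS[ep])
        for rule in config["run"]["rules"]:
            rows = apply_censoring(with_outcome, claims, rule,
                                   config["cohort"]["gap_days"])
            cohorts[(rule, ep)] = rows
            log.info("cohort %s/%s: %d subjects, %d events", rule, ep,
                     len(rows), rows["event"].sum())
    primary = cohorts[("itt", "composite")]
    attrition.to_csv(out / "attrition.csv", index=False)
    primary.to_csv(out / "analysis_itt_composite.csv", index=False)
    done()

    # -- cut-off search (primary cohort) -----------------------------------
    done = stage("find_cutoff")
    grid = CutoffGrid(
        month_length_days=config["cutoff"]["month_days"],
        n_intervals_max=config["cutoff"]["n_intervals_max"],
        min_events_per_interval_per_arm=config["cutoff"][
            "min_events_per_interval_per_arm"])
    search = bootstrap_select(primary, grid, B=config["cutoff"]["B"],
                              seed=manifest.seeds["bootstrap"])
    cutoff = search.selected
    prof = search.table.drop(columns=["boot_logliks", "betas"])
    prof.to_csv(out / "cutoff_profile.csv", index=False)
    manifest.seeds["selected_cutoff"] = list(cutoff)
    log.info("selected cut-off %s (%s)", cutoff, search.verdict)
    done()

    # -- estimation --------------------------------------------------------
    done = stage("estimate")
    alpha = config["estimation"]["alpha"]
    selected, screen_report = screen_covariates(
        primary, config["estimation"]["screen_candidates"], alpha=alpha,
        clinical_allowlist=config["estimation"]["clinical_allowlist"])
    screen_report.to_csv(out / "screen_report.csv", index=False)
    log.info("screened covariates -> %s", selected)

    for (rule, ep), rows in cohorts.items():
        models = fit_final_models(rows, cutoff, selected)
        ipw_fit = None
        if rule == "itt" and ep == "composite":
            ipw_fit, pw = ipw_cox(rows, list(IPW_COVARIATES), cutoff)
            pw.balance.to_csv(out / "ipw_balance.csv")
        table = _model_table(models, ipw_fit)
        table.to_csv(out / f"models_{rule}_{ep}.csv", index=False)

    mh = mh_adjusted_rates(primary)
    pd.DataFrame({
        "arm": ["statin", "fibrate"],
        "adjusted_rate_per_100py": [mh.rates[0], mh.rates[1]],
        "ci_low": [mh.ci[0][0], mh.ci[1][0]],
        "ci_high": [mh.ci[0][1], mh.ci[1][1]],
        "p_value": [mh.p_value] * 2,
    }).to_csv(out / "mh_rates.csv", index=False)
    done()

    # -- plots and manifest -------------------------------------------------
    done = stage("render")
    _plot_km(primary, out / "km_curves.png")
    _plot_profile(prof, cutoff, out / "likelihood_profile.png")
    done()
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.digest(p)
    manifest.save(out / "manifest.json")
    return manifest


def _plot_km(rows, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in km_estimate(rows, group_by="arm"):
        ax.step(np.concatenate([[0], curve.days]),
                np.concatenate([[1.0], curve.survival]),
                where="post", label=str(curve.label))
    ax.set_xlabel("days since initiation")
    ax.set_ylabel("event-free survival")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_profile(prof: pd.DataFrame, cutoff, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    two = prof[(prof["n_intervals"] == 2) & prof["feasible"]]
    import ast
    days = [c[0] if isinstance(c, tuple) else ast.literal_eval(str(c))[0]
            for c in two["cutoffs"]]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(days, two["loglik"], "o-", label="observed log-likelihood")
    ax.plot(days, two["median_boot_loglik"], "s--",
            label="median bootstrap log-likelihood")
    if cutoff and len(cutoff) == 1:
        ax.axvline(cutoff[0], color="k", ls=":", label="selected cut-off")
    ax.set_xlabel("cut-off day")
    ax.set_ylabel("log partial likelihood")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Report rendering

def render_report(out_dir) -> str:
    """Assemble a markdown summary from the stage outputs.

    Sections: cohort flow chart, Kaplan–Meier curves, likelihood profile,
    and the hazard-ratio tables (numbers taken verbatim from the stage
    tables).  Missing primary outputs raise; missing sensitivity variants
    are marked 'not run'.
    """
    out = pathlib.Path(out_dir)
    parts = ["# Cohort analysis report\n"]

    attr_path = out / "attrition.csv"
    if not attr_path.exists():
        raise FileNotFoundError("attrition.csv missing — cohort stage not run")
    attrition = pd.read_csv(attr_path)
    parts.append("## Cohort flow chart\n")
    parts.append(attrition.to_string(index=False))
    parts.append("")

    parts.append("## Event-free survival (Kaplan–Meier)\n")
    km = out / "km_curves.png"
    parts.append(f"![KM curves]({km.name})" if km.exists()
                 else "not run")
    parts.append("")

    parts.append("## Cut-off likelihood profile\n")
    prof_path = out / "cutoff_profile.csv"
    if not prof_path.exists():
        raise FileNotFoundError("cutoff_profile.csv missing — cut-off stage "
                                "not run")
    prof = pd.read_csv(prof_path)
    feas = prof[prof["feasible"]]
    best = feas.loc[feas["median_boot_loglik"].idxmax()]
    parts.append(f"Selected cut-off: {best['cutoffs']} "
                 f"(median bootstrap log-likelihood "
                 f"{best['median_boot_loglik']:.4f})")
    parts.append("")

    parts.append("## Hazard-ratio models\n")
    for rule in CENSORING_RULES:
        for ep in ENDPOINTS:
            path = out / f"models_{rule}_{ep}.csv"
            parts.append(f"### {rule} / {ep}\n")
            if path.exists():
                table = pd.read_csv(path)
                arm = table[table["covariate"].str.startswith("arm_")]
                parts.append(arm.to_string(
                    index=False, float_format=lambda v: format(v, ".17g")))
            else:
                parts.append("not run")
            parts.append("")

    mh_path = out / "mh_rates.csv"
    if mh_path.exists():
        parts.append("## Adjusted annual event rates\n")
        parts.append(pd.read_csv(mh_path).to_string(index=False))
        parts.append("")

    report = "\n".join(parts)
    (out / "report.md").write_text(report)
    return report
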