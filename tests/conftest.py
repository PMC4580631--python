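import numpy as np
import pandas as pd
import pytest

from coxcut.synth_claims import (GeneratorConfig, generate_analysis_table,
                                 generate_claims, generate_population,
                                 simulate_outcomes)


@pytest.fixture(scope="session")
def small_analysis():
    """A modest simulated cohort for estimator-level tests."""
    analysis, _ = generate_analysis_table(GeneratorConfig(n_subjects=3000,
                                                          seed=11))
    return analysis


@pytest.fixture(scope="session")
def small_claims():
    """A small generated claims stream with its ground truth."""
    cfg = GeneratorConfig(n_subjects=400, seed=21)
    demographics, truth = generate_population(cfg)
    truth = simulate_outcomes(truth, cfg)
    claims, truth = generate_claims(demographics, truth, cfg)
    return claims, demographics, truth, cfg


def _records(subject, *recs):
    """(day, record_type, code_class[, prescriber]) tuples -> rows."""
    rows = []
    for rec in recs:
        day, rtype, code = rec[:3]
        rx = rec[3] if len(rec) > 3 else "gp"
        rows.append((subject, day, rtype, code, rx))
    return rows


def _qualification(subject, idx):
    """Enough OAD + antihypertensive claims to satisfy inclusion."""
    return _records(
        subject,
        (idx - 300, "drug", "oad_metformin"),
        (idx - 250, "drug", "oad_metformin"),
        (idx - 200, "drug", "oad_metformin"),
        (idx - 320, "drug", "antihypertensive_other"),
        (idx - 270, "drug", "antihypertensive_other"),
        (idx - 220, "drug", "antihypertensive_other"),
    )


@pytest.fixture(scope="session")
def ten_subject_fixture():
    """Hand-enumerated ten-subject claims fixture.

    Designed verdicts:
      S01 statin 10/40, male 62          -> initiator, included, no event
      S02 single fibrate                  -> not an initiator
      S03 prior statin at day -100        -> not an initiator (washout)
      S04 first reimbursement not GP      -> not an initiator
      S05 prior stroke at day -200        -> initiator, excluded (prior CV)
      S06 male aged exactly 50            -> included; stroke day 110 then
                                             death day 210 -> event=stroke,
                                             follow-up 100
      S07 female aged 59                  -> initiator, excluded (age)
      S08 statin+fibrate on index day     -> combination, not monotherapy
      S09 statin 10 then 200 (gap 190)    -> not an initiator (gap > 120)
      S10 fibrate 0/30, stroke day 400,
          switch to statin day 100        -> included; ITT fup 400 event 1;
                                             persistence truncates at 213,
                                             switch at 283 (event 0 both)
    """
    rows = []
    rows += _records("S01", (10, "drug", "statin"), (40, "drug", "statin"))
    rows += _qualification("S01", 10)
    rows += _records("S02", (20, "drug", "fibrate"))
    rows += _qualification("S02", 20)
    rows += _records("S03", (-100, "drug", "statin"), (10, "drug", "statin"),
                     (40, "drug", "statin"))
    rows += _qualification("S03", 10)
    rows += _records("S04", (10, "drug", "statin", "other"),
                     (40, "drug", "statin"))
    rows += _qualification("S04", 10)
    rows += _records("S05", (-200, "hospital", "cv_event_stroke", "na"),
                     (10, "drug", "fibrate"), (40, "drug", "fibrate"))
    rows += _qualification("S05", 10)
    rows += _records("S06", (10, "drug", "statin"), (40, "drug", "statin"),
                     (-90, "drug", "oad_sulfa"), (-60, "drug", "oad_sulfa"),
                     (110, "hospital", "cv_event_stroke", "na"),
                     (210, "death", "death", "na"))
    rows += _qualification("S06", 10)
    rows += _records("S07", (10, "drug", "fibrate"), (40, "drug", "fibrate"))
    rows += _qualification("S07", 10)
    rows += _records("S08", (10, "drug", "statin"), (10, "drug", "fibrate"),
                     (40, "drug", "statin"))
    rows += _qualification("S08", 10)
    rows += _records("S09", (10, "drug", "statin"), (200, "drug", "statin"))
    rows += _qualification("S09", 10)
    rows += _records("S10", (0, "drug", "fibrate"), (30, "drug", "fibrate"),
                     (100, "drug", "statin"),
                     (400, "hospital", "cv_event_stroke", "na"))
    rows += _qualification("S10", 0)
    claims = pd.DataFrame(rows, columns=["subject_id", "day", "record_type",
                                         "code_class", "prescriber"])
    claims = claims.sort_values(["subject_id", "day"],
                                kind="stable").reset_index(drop=True)

    ages = {"S01": 62, "S02": 62, "S03": 62, "S04": 62, "S05": 62,
            "S06": 50, "S07": 59, "S08": 62, "S09": 62, "S10": 62}
    sexes = {s: "M" for s in ages}
    sexes["S07"] = "F"
    demographics = pd.DataFrame({
        "subject_id": list(ages),
        "sex": [sexes[s] for s in ages],
        "birth_year": [2008 - a for s, a in ages.items()],
        "deprivation_quintile": 1.0,
    })
    expected = {
        "initiators": {"S01": ("statin", 10), "S05": ("fibrate", 10),
                       "S06": ("statin", 10), "S07": ("fibrate", 10),
                       "S10": ("fibrate", 0)},
        "included": {"S01", "S06", "S10"},
    }
    return claims, demographics, expected
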