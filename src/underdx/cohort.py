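"""Synthetic administrative-claims cohorts with an underreported exposure.

The generator emulates a 1-year retrospective cohort of adult patients in an
integrated health-care system: one row per patient with a hospital-admission
indicator, a hierarchically exclusive reported serious-mental-illness (SMI)
category, demographics (age, gender, race, Hispanic ethnicity), and a physical
comorbidity count (Selim index, 0-30 chronic conditions).

The key structural feature is that the recorded schizophrenia diagnosis R is
an *underreport* of a latent true status D:

    D ~ Bernoulli(theta)            true 1-year prevalence
    R | D ~ Bernoulli(s * D)        s = sensitivity; specificity is perfect,
                                    so R = 1 implies D = 1

Admission is generated from a logistic model driven by the TRUE status D (not
R), so that fitting on R alone understates or distorts the exposure effect —
the situation the misclassification model corrects. Patients without a
recorded schizophrenia code receive one of {bipolar, ptsd, mdd, none}.

Covariates are drawn independently at configurable margins; the joint
covariate structure of real claims data (age-comorbidity correlation, etc.)
is deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

SMI_CATEGORIES = ("schizophrenia", "bipolar", "ptsd", "mdd", "none")
RACE_CATEGORIES = ("white", "black", "other")

#: Mandatory cohort columns, in canonical file order.
REQUIRED_COLUMNS = ("admission", "reported_smi", "age_years", "female",
                    "race", "hispanic", "selim")
#: Present only for simulated cohorts (latent truth is unobservable in claims).
TRUTH_COLUMN = "true_schizophrenia"

#: Fixed predictor order of the design matrix (intercept implicit).
PREDICTOR_ORDER = ("schizophrenia", "bipolar", "ptsd", "mdd", "age_decades",
                   "female", "black", "other_race", "hispanic", "selim")

SELIM_MAX = 30


class CohortValidationError(ValueError):
    """A cohort table violates the record invariants."""


def _default_smi_mix() -> dict[str, float]:
    # Reported non-schizophrenia category frequencies among the 87,806 - 114
    # patients without a schizophrenia code in the reference cohort.
    other = 87_806 - 114
    return {"bipolar": 412 / other, "ptsd": 82 / other, "mdd": 5_793 / other}


def _default_coefficients() -> dict[str, float]:
    # Generating log-odds anchored to the reference study's fitted odds
    # ratios so simulated cohorts are qualitatively realistic.
    ors = {"schizophrenia": 1.87, "bipolar": 1.73, "ptsd": 1.52, "mdd": 1.28,
           "age_decades": 1.03, "female": 1.31, "black": 1.07,
           "other_race": 0.83, "hispanic": 1.09, "selim": 1.35}
    out = {k: float(np.log(v)) for k, v in ors.items()}
    out["intercept"] = -3.0
    return out


@dataclass
class CohortParams:
    """Generating parameters; defaults reproduce the reference cohort margins.

    ``theta_true`` and ``sensitivity_true`` default to the low-sensitivity
    scenario (0.20% prevalence, 65% sensitivity), which yields an expected
    0.13% documented prevalence — about 114 reported cases at the default n.
    """

    n_patients: int = 87_806
    theta_true: float = 0.0020
    sensitivity_true: float = 0.65
    smi_mix: dict[str, float] = field(default_factory=_default_smi_mix)
    age_mean: float = 52.7
    age_sd: float = 18.9
    age_min: float = 18.0
    age_max: float = 103.0
    p_female: float = 50_359 / 87_806
    race_probs: dict[str, float] = field(default_factory=lambda: {
        "white": 62_394 / 87_806, "black": 5_816 / 87_806, "other": 19_596 / 87_806})
    p_hispanic: float = 4_763 / 87_806
    selim_mean: float = 1.7
    selim_sd: float = 1.8
    outcome_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        probs = {"theta_true": self.theta_true,
                 "sensitivity_true": self.sensitivity_true,
                 "p_female": self.p_female, "p_hispanic": self.p_hispanic,
                 **{f"smi_mix[{k}]": v for k, v in self.smi_mix.items()},
                 **{f"race_probs[{k}]": v for k, v in self.race_probs.items()}}
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if sum(self.smi_mix.values()) > 1.0 + 1e-12:
            raise ValueError("smi_mix probabilities exceed 1")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValueError("race_probs must sum to 1")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.selim_sd ** 2 <= self.selim_mean:
            raise ValueError("selim variance must exceed its mean "
                             "(negative-binomial overdispersion)")
        missing = set(PREDICTOR_ORDER) | {"intercept"}
        missing -= set(self.outcome_coefficients)
        if missing:
            raise ValueError(f"outcome_coefficients missing terms: {sorted(missing)}")


def _truncnorm_parent_params(mean: float, sd: float, lo: float, hi: float
                             ) -> tuple[float, float]:
    """Parent (loc, scale) whose [lo, hi]-truncated normal has the given
    mean and sd, so the generated margin matches the target moments rather
    than the parent's. Falls back to (mean, sd) if the solve fails."""
    from scipy.optimize import fsolve

    def eqs(p):
        loc, scale = p
        scale = abs(scale)
        m, v = truncnorm.stats((lo - loc) / scale, (hi - loc) / scale,
                               loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol, info, ok, _ = fsolve(eqs, [mean, sd], full_output=True)
    if ok != 1 or not np.all(np.isfinite(sol)):
        return mean, sd
    return float(sol[0]), float(abs(sol[1]))


def predictor_matrix(cohort: pd.DataFrame, exposure: str = "reported"
                     ) -> tuple[np.ndarray, list[str]]:
    """The n x 10 predictor matrix in canonical column order (no intercept).

    ``exposure`` selects what fills the schizophrenia column: the recorded
    code (``"reported"``) or the latent truth (``"true"``, simulated cohorts
    only). Reference categories: male, White, non-Hispanic, no SMI code.
    """
    if exposure == "reported":
        scz = (cohort["reported_smi"] == "schizophrenia").to_numpy(float)
    elif exposure == "true":
        if TRUTH_COLUMN not in cohort.columns:
            raise ValueError(
                "exposure='true' requires the true_schizophrenia column, which "
                "only simulated cohorts carry")
        scz = cohort[TRUTH_COLUMN].to_numpy(float)
    else:
        raise ValueError(f"exposure must be 'reported' or 'true', got {exposure!r}")
    smi = cohort["reported_smi"]
    race = cohort["race"]
    cols = {
        "schizophrenia": scz,
        "bipolar": (smi == "bipolar").to_numpy(float),
        "ptsd": (smi == "ptsd").to_numpy(float),
        "mdd": (smi == "mdd").to_numpy(float),
        "age_decades": cohort["age_years"].to_numpy(float) / 10.0,
        "female": cohort["female"].to_numpy(float),
        "black": (race == "black").to_numpy(float),
        "other_race": (race == "other").to_numpy(float),
        "hispanic": cohort["hispanic"].to_numpy(float),
        "selim": cohort["selim"].to_numpy(float),
    }
    X = np.column_stack([cols[name] for name in PREDICTOR_ORDER])
    return X, list(PREDICTOR_ORDER)


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort; a fixed seed gives byte-identical output.

    Both the latent truth D (``true_schizophrenia``) and the reported code R
    (``reported_smi == "schizophrenia"``) are retained; admission is generated
    from D, never from R.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    d = rng.random(n) < params.theta_true
    r = d & (rng.random(n) < params.sensitivity_true)

    reported = np.empty(n, dtype=object)
    reported[r] = "schizophrenia"
    others = ~r
    mix_names = ["bipolar", "ptsd", "mdd"]
    mix_p = np.array([params.smi_mix[k] for k in mix_names])
    cats = np.array(mix_names + ["none"], dtype=object)
    p = np.append(mix_p, 1.0 - mix_p.sum())
    reported[others] = rng.choice(cats, size=int(others.sum()), p=p)

    loc, scale = _truncnorm_parent_params(params.age_mean, params.age_sd,
                                          params.age_min, params.age_max)
    age = truncnorm.rvs((params.age_min - loc) / scale,
                        (params.age_max - loc) / scale,
                        loc=loc, scale=scale, size=n, random_state=rng)

    female = (rng.random(n) < params.p_female).astype(int)
    race = rng.choice(np.array(RACE_CATEGORIES, dtype=object), size=n,
                      p=[params.race_probs[k] for k in RACE_CATEGORIES])
    hispanic = (rng.random(n) < params.p_hispanic).astype(int)

    var = params.selim_sd ** 2
    nb_r = params.selim_mean ** 2 / (var - params.selim_mean)
    nb_p = nb_r / (nb_r + params.selim_mean)
    selim = rng.negative_binomial(nb_r, nb_p, size=n)
    over = selim > SELIM_MAX  # truncate the (tiny) right tail by redrawing
    while over.any():
        selim[over] = rng.negative_binomial(nb_r, nb_p, size=int(over.sum()))
        over = selim > SELIM_MAX

    cohort = pd.DataFrame({
        "admission": np.zeros(n, dtype=int),
        "reported_smi": reported,
        TRUTH_COLUMN: d.astype(int),
        "age_years": age,
        "female": female,
        "race": race,
        "hispanic": hispanic,
        "selim": selim.astype(int),
    })
    X, names = predictor_matrix(cohort, exposure="true")
    beta = np.array([params.outcome_coefficients[k] for k in names])
    eta = params.outcome_coefficients["intercept"] + X @ beta
    cohort["admission"] = (rng.random(n) < expit(eta)).astype(int)
    return cohort


# --- validation and delimited-text I/O --------------------------------------

def _bad_rows(msg: str, mask: np.ndarray) -> str:
    rows = np.flatnonzero(mask)
    shown = ", ".join(map(str, rows[:5])) + (", ..." if rows.size > 5 else "")
    return f"{msg} (rows {shown})"


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the record invariants; raise CohortValidationError citing rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortValidationError(f"missing mandatory columns: {missing}")
    problems: list[str] = []
    for col in ("admission", "female", "hispanic"):
        bad = ~cohort[col].isin([0, 1]).to_numpy()
        if bad.any():
            problems.append(_bad_rows(f"{col} must be 0/1", bad))
    bad = ~cohort["reported_smi"].isin(SMI_CATEGORIES).to_numpy()
    if bad.any():
        problems.append(_bad_rows(
            f"reported_smi must be one of {SMI_CATEGORIES}", bad))
    bad = ~cohort["race"].isin(RACE_CATEGORIES).to_numpy()
    if bad.any():
        problems.append(_bad_rows(f"race must be one of {RACE_CATEGORIES}", bad))
    age = cohort["age_years"].to_numpy(float)
    bad = ~np.isfinite(age) | (age < 18.0)
    if bad.any():
        problems.append(_bad_rows("age_years must be finite and >= 18 "
                                  "(adult cohort)", bad))
    selim = cohort["selim"].to_numpy()
    bad = (selim < 0) | (selim > SELIM_MAX) | (selim != np.floor(selim))
    if bad.any():
        problems.append(_bad_rows(f"selim must be an integer in [0, {SELIM_MAX}]", bad))
    if TRUTH_COLUMN in cohort.columns:
        d = cohort[TRUTH_COLUMN].to_numpy()
        bad = ~np.isin(d, (0, 1))
        if bad.any():
            problems.append(_bad_rows(f"{TRUTH_COLUMN} must be 0/1", bad))
        else:
            # perfect specificity: a recorded schizophrenia code cannot be a
            # false positive
            bad = (cohort["reported_smi"] == "schizophrenia").to_numpy() & (d == 0)
            if bad.any():
                problems.append(_bad_rows(
                    "reported schizophrenia with true_schizophrenia = 0 "
                    "violates perfect specificity", bad))
    if problems:
        raise CohortValidationError("; ".join(problems))


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort as UTF-8 CSV with a header row, one patient per row."""
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path, validate: bool = True,
                extra_columns: str = "ignore") -> pd.DataFrame:
    """Read a cohort CSV.

    ``extra_columns`` is ``"ignore"`` (drop unknown columns, the default) or
    ``"keep"`` (preserve them at the end of the frame).
    """
    if extra_columns not in ("ignore", "keep"):
        raise ValueError("extra_columns must be 'ignore' or 'keep'")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing mandatory columns: {missing}")
    known = [c for c in (*REQUIRED_COLUMNS[:2], TRUTH_COLUMN, *REQUIRED_COLUMNS[2:])
             if c in df.columns]
    if extra_columns == "ignore":
        df = df[known]
    else:
        extras = [c for c in df.columns if c not in known]
        df = df[known + extras]
    if validate:
        validate_cohort(df)
    return df
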