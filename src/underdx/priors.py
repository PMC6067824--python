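"""Prior construction for the underdiagnosis-adjusted admission model.

Two pieces of external knowledge enter the model through priors:

* the true 1-year period prevalence of schizophrenia among treatment-seeking
  patients (theta), elicited as a Beta(1, b) distribution because the
  prevalence is known a priori to be small;
* the sensitivity of the administrative diagnosis (s = 1 - lambda, where
  lambda is the underdiagnosis rate), elicited as a beta distribution by
  matching a scenario mean with a fixed prior effective sample size
  (alpha + beta), interpreted as pseudo-observations of diagnostic accuracy.

The prevalence scenarios themselves come from an explicit arithmetic chain:
a national prevalence is discounted for homelessness (patients with no
contact with the system) and treatment adherence to yield the prevalence one
could *observe* in claims; the shortfall of the documented prevalence
relative to that observable prevalence is the presumed underdiagnosis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) distribution used for probabilities (theta, s)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"beta shapes must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def ess(self) -> float:
        """Prior effective sample size alpha + beta."""
        return self.alpha + self.beta


@dataclass(frozen=True)
class NormalPrior:
    """Normal prior parameterized by mean and VARIANCE (not precision)."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def precision(self) -> float:
        return 1.0 / self.variance


@dataclass(frozen=True)
class ScenarioPrior:
    """A full prior specification for one sensitivity scenario.

    ``coefficient_prior`` is shared by the exposure effect and the covariate
    coefficients; the intercept gets its own, mildly informative, prior.
    """

    name: str
    prevalence_prior: BetaPrior
    sensitivity_prior: BetaPrior
    intercept_prior: NormalPrior = NormalPrior(-3.0, 10.0)
    coefficient_prior: NormalPrior = NormalPrior(0.0, 10_000.0)

    @property
    def underdiagnosis_mean(self) -> float:
        """Prior mean of lambda = 1 - s."""
        return 1.0 - self.sensitivity_prior.mean


@dataclass(frozen=True)
class PrevalenceChain:
    """Arithmetic from national prevalence to an expected observable rate.

    Input fractions (all probabilities):

    national_prevalence   1-year prevalence in the general population
    homeless_fraction     fraction of true cases with no system contact
    adherence_fraction    fraction of in-care cases attending visits
    documented_prevalence prevalence actually coded in the records

    Derived (filled by :func:`derive_prevalence_chain`):

    treated_prevalence        national x (1 - homeless)
    observable_prevalence     treated x adherence
    underreporting_gap        observable - documented (absolute)
    sensitivity               documented / observable
    underdiagnosis_rate       1 - sensitivity (lambda)
    """

    national_prevalence: float = 0.005
    homeless_fraction: float = 0.20
    adherence_fraction: float = 0.50
    documented_prevalence: float = 0.0013
    treated_prevalence: float | None = None
    observable_prevalence: float | None = None
    underreporting_gap: float | None = None
    sensitivity: float | None = None
    underdiagnosis_rate: float | None = None


def derive_prevalence_chain(chain: PrevalenceChain) -> PrevalenceChain:
    """Fill the derived fields of a :class:`PrevalenceChain`.

    Raises
    ------
    ValueError
        If an input fraction is outside [0, 1], or the observable prevalence
        is zero while the documented prevalence is not (sensitivity undefined).
    """
    for name in ("national_prevalence", "homeless_fraction",
                 "adherence_fraction", "documented_prevalence"):
        v = getattr(chain, name)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    treated = chain.national_prevalence * (1.0 - chain.homeless_fraction)
    observable = treated * chain.adherence_fraction
    if observable == 0.0 and chain.documented_prevalence > 0.0:
        raise ValueError("observable prevalence is zero but documented prevalence "
                         "is positive: sensitivity undefined")
    sens = 1.0 if observable == 0.0 else chain.documented_prevalence / observable
    return replace(
        chain,
        treated_prevalence=treated,
        observable_prevalence=observable,
        underreporting_gap=observable - chain.documented_prevalence,
        sensitivity=sens,
        underdiagnosis_rate=1.0 - sens,
    )


def elicit_sensitivity_prior(mean: float, ess: float = 30.0) -> BetaPrior:
    """Beta prior for diagnostic sensitivity by mean / effective-sample-size matching.

    alpha = mean * ess and beta = (1 - mean) * ess, so the returned prior has
    exactly the requested mean and alpha + beta = ess. The default ess of 30
    pseudo-observations is mildly informative.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if not ess > 0:
        raise ValueError(f"ess must be positive, got {ess}")
    return BetaPrior(alpha=mean * ess, beta=(1.0 - mean) * ess)


def elicit_prevalence_prior(mean: float, alpha_fixed: float = 1.0,
                            round_shape: bool = False) -> BetaPrior:
    """Beta(alpha_fixed, b) prior for a small prevalence, matched by mean.

    With alpha fixed (default 1, appropriate when the prevalence is known to
    be small), b = alpha_fixed * (1 - mean) / mean gives a prior whose mean is
    exactly ``mean``. With ``round_shape=True`` the second shape is truncated
    to an integer, the convention used when such priors are reported in print
    (e.g. mean 0.0017 -> Beta(1, 587) rather than Beta(1, 587.235...)).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if not alpha_fixed > 0:
        raise ValueError(f"alpha_fixed must be positive, got {alpha_fixed}")
    b = alpha_fixed * (1.0 - mean) / mean
    if round_shape:
        b = float(math.floor(b))
    return BetaPrior(alpha=alpha_fixed, beta=b)


#: (name, prevalence mean, sensitivity mean) of the three reference scenarios.
REFERENCE_SCENARIO_SPECS = (
    ("low", 0.0020, 0.65),
    ("moderate", 0.0017, 0.76),
    ("high", 0.0015, 0.87),
)


def reference_scenarios() -> dict[str, ScenarioPrior]:
    """The three built-in sensitivity scenarios.

    low      theta = 0.20%, s = 65%  -> theta ~ Beta(1, 499),  s ~ Beta(19.5, 10.5)
    moderate theta = 0.17%, s = 76%  -> theta ~ Beta(1, 587),  s ~ Beta(22.8, 7.2)
    high     theta = 0.15%, s = 87%  -> theta ~ Beta(1, 665),  s ~ Beta(26.1, 3.9)

    All share an intercept prior Normal(-3, variance 10) and coefficient
    priors Normal(0, variance 10,000). Sensitivity priors all carry a prior
    effective sample size of 30.
    """
    out: dict[str, ScenarioPrior] = {}
    for name, theta_mean, s_mean in REFERENCE_SCENARIO_SPECS:
        out[name] = ScenarioPrior(
            name=name,
            prevalence_prior=elicit_prevalence_prior(theta_mean, round_shape=True),
            sensitivity_prior=elicit_sensitivity_prior(s_mean, ess=30.0),
        )
    return out


# --- scenario (de)serialization -------------------------------------------

def scenario_to_dict(s: ScenarioPrior) -> dict:
    return {
        "name": s.name,
        "theta_prior": {"alpha": s.prevalence_prior.alpha, "beta": s.prevalence_prior.beta},
        "s_prior": {"alpha": s.sensitivity_prior.alpha, "beta": s.sensitivity_prior.beta},
        "intercept_prior": {"mean": s.intercept_prior.mean, "variance": s.intercept_prior.variance},
        "coef_prior": {"mean": s.coefficient_prior.mean, "variance": s.coefficient_prior.variance},
    }


def scenario_from_dict(d: dict) -> ScenarioPrior:
    return ScenarioPrior(
        name=d["name"],
        prevalence_prior=BetaPrior(**d["theta_prior"]),
        sensitivity_prior=BetaPrior(**d["s_prior"]),
        intercept_prior=NormalPrior(**d["intercept_prior"]),
        coefficient_prior=NormalPrior(**d["coef_prior"]),
    )


def write_scenario(s: ScenarioPrior, path: str | Path) -> None:
    Path(path).write_text(json.dumps(scenario_to_dict(s), indent=2) + "\n")


def read_scenario(path: str | Path) -> ScenarioPrior:
    return scenario_from_dict(json.loads(Path(path).read_text()))
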