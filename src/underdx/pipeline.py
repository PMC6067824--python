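"""End-to-end orchestration: simulate -> describe -> fit -> compare -> report.

Produces a comparison table shaped like the reference study's results table:
one row per predictor, a classical (maximum likelihood) odds-ratio column
block, and one odds-ratio column block per Bayesian sensitivity scenario.
Every artifact is stamped with a hash of the run configuration and the seed,
and a MANIFEST.json records completeness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import mcmc, naive
from .cohort import CohortParams, PREDICTOR_ORDER
from .descriptives import summarize_table1
from .priors import ScenarioPrior, reference_scenarios, scenario_to_dict

log = logging.getLogger("underdx")

PREDICTOR_LABELS = {
    "schizophrenia": "Schizophrenia", "bipolar": "Bipolar disorder",
    "ptsd": "PTSD", "mdd": "MDD", "age_decades": "Age (decade effect)",
    "female": "Female", "black": "Black race", "other_race": "Other race",
    "hispanic": "Hispanic", "selim": "Selim Physical",
}


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor (R-hat) for one parameter.

    ``chains`` is an (n_chains, length) array. The default is the classic
    non-split two-chain formula sqrt(((n-1)/n W + B/n) / W); ``split=True``
    halves each chain first, which also detects within-chain trends.
    Raises ValueError with fewer than 2 chains, length < 10, or zero
    within-chain variance everywhere.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    if split:
        half = x.shape[1] // 2
        x = np.vstack([x[:, :half], x[:, half:2 * half]])
    m, n = x.shape
    if n < 2:
        raise ValueError("chains too short for R-hat (need length >= 2)")
    means = x.mean(axis=1)
    w = float(x.var(axis=1, ddof=1).mean())
    if w == 0.0:
        raise ValueError("zero within-chain variance in every chain: R-hat undefined")
    b_over_n = float(means.var(ddof=1))
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def compare_models(naive_table: pd.DataFrame,
                   bayes_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Signed percent change of each Bayesian OR versus the classical OR.

    Convention: 100 * (OR_bayes - OR_classical) / OR_classical, so negative
    values mean the adjusted model attenuates the association.
    """
    base = naive_table.set_index("term")
    preds = [t for t in base.index if t != "intercept"]
    out = pd.DataFrame(index=preds)
    out.index.name = "term"
    for name, table in bayes_tables.items():
        tb = table.set_index("term")
        missing = [t for t in preds if t not in tb.index]
        if missing:
            raise ValueError(f"scenario {name!r} lacks predictors: {missing}")
        out[f"{name}_pct_change"] = 100.0 * (
            tb.loc[preds, "or_"] - base.loc[preds, "or_"]) / base.loc[preds, "or_"]
    return out.reset_index()


@dataclass
class RunConfig:
    """One pipeline run: a cohort source, scenarios, and an MCMC protocol."""

    cohort_path: str | None = None
    cohort_params: CohortParams | None = None
    scenarios: list = field(default_factory=lambda: ["low", "moderate", "high"])
    mcmc: mcmc.McmcConfig = field(default_factory=mcmc.McmcConfig)
    outdir: str | Path = "underdx_run"
    make_plots: bool = True

    def resolved_scenarios(self) -> list[ScenarioPrior]:
        known = reference_scenarios()
        out = []
        for s in self.scenarios:
            if isinstance(s, ScenarioPrior):
                out.append(s)
            elif s in known:
                out.append(known[s])
            else:
                raise ValueError(f"unknown scenario {s!r}; expected one of "
                                 f"{sorted(known)} or a ScenarioPrior")
        if not out:
            raise ValueError("at least one scenario is required")
        return out

    def to_dict(self) -> dict:
        return {
            "cohort_path": self.cohort_path,
            "cohort_params": dataclasses.asdict(self.cohort_params)
            if self.cohort_params else None,
            "scenarios": [scenario_to_dict(s) if isinstance(s, ScenarioPrior) else s
                          for s in self.scenarios],
            "mcmc": dataclasses.asdict(self.mcmc),
            "outdir": str(self.outdir),
            "make_plots": self.make_plots,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ScenarioReport:
    """Predictor-by-model odds-ratio comparison (classical + Bayesian blocks)."""

    frame: pd.DataFrame
    scenario_names: list[str]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def to_text(self) -> str:
        blocks = ["classical"] + self.scenario_names
        disp = pd.DataFrame({"Predictor": self.frame["predictor"]})
        for b in blocks:
            disp[b] = [
                f"{o:.2f} [{lo:.2f}, {hi:.2f}]"
                for o, lo, hi in zip(self.frame[f"{b}_or"],
                                     self.frame[f"{b}_ci_low"],
                                     self.frame[f"{b}_ci_high"])]
        return disp.to_string(index=False)


def _report_frame(naive_table: pd.DataFrame,
                  bayes_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    rows = {"predictor": [PREDICTOR_LABELS[t] for t in PREDICTOR_ORDER],
            "term": list(PREDICTOR_ORDER)}
    nb = naive_table.set_index("term")
    rows["classical_or"] = nb.loc[list(PREDICTOR_ORDER), "or_"].to_numpy()
    rows["classical_ci_low"] = nb.loc[list(PREDICTOR_ORDER), "ci_low"].to_numpy()
    rows["classical_ci_high"] = nb.loc[list(PREDICTOR_ORDER), "ci_high"].to_numpy()
    for name, table in bayes_tables.items():
        tb = table.set_index("term")
        rows[f"{name}_or"] = tb.loc[list(PREDICTOR_ORDER), "or_"].to_numpy()
        rows[f"{name}_ci_low"] = tb.loc[list(PREDICTOR_ORDER), "ci_low"].to_numpy()
        rows[f"{name}_ci_high"] = tb.loc[list(PREDICTOR_ORDER), "ci_high"].to_numpy()
    return pd.DataFrame(rows)


def _plot_diagnostics(draws: mcmc.PosteriorDraws, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3))
    for c in range(draws.n_chains):
        axes[0].plot(draws.beta1[c], lw=0.4, label=f"chain {c}")
    axes[0].set_title("beta1 trace")
    axes[0].legend(fontsize=7)
    axes[1].hist(draws.pooled("beta1"), bins=60, density=True)
    axes[1].set_title("beta1 posterior density")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> ScenarioReport:
    """Run the whole analysis and write artifacts under ``config.outdir``.

    Stages: cohort (simulated and written, or loaded), Table-1 style
    descriptive report, classical fit, one MCMC run per scenario (draws and
    R-hat persisted, optional trace/density plot), and the final comparison
    report as CSV and aligned text. Any stage error aborts with a
    stage-named message; the MANIFEST marks the run incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.mcmc.seed}
    manifest = {"stamp": stamp, "complete": False, "artifacts": [],
                "config": config.to_dict()}

    def save_manifest() -> None:
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    def artifact(name: str) -> Path:
        manifest["artifacts"].append(name)
        return outdir / name

    stage = "setup"
    save_manifest()
    try:
        stage = "cohort"
        if (config.cohort_path is None) == (config.cohort_params is None):
            raise ValueError("exactly one of cohort_path / cohort_params required")
        if config.cohort_params is not None:
            log.info("simulating cohort (n=%d)", config.cohort_params.n_patients)
            cohort = cohort_mod.generate_cohort(config.cohort_params)
            cohort_mod.write_cohort(cohort, artifact("cohort.csv"))
        else:
            log.info("reading cohort from %s", config.cohort_path)
            cohort = cohort_mod.read_cohort(config.cohort_path)

        stage = "describe"
        summary = summarize_table1(cohort)
        summary.to_csv(artifact("table1.csv"))
        manifest["artifacts"].append("table1.tests.csv")
        artifact("table1.txt").write_text(summary.to_text() + "\n")

        stage = "fit-naive"
        fit = naive.fit_logistic(naive.build_design(cohort, exposure="reported"))
        naive.write_coefficient_table(fit.table, artifact("classical_fit.csv"))
        log.info("classical fit converged in %d iterations", fit.n_iter)

        stage = "fit-bayes"
        bayes_tables: dict[str, pd.DataFrame] = {}
        rhat_rows = []
        for scenario in config.resolved_scenarios():
            log.info("sampling scenario %s", scenario.name)
            draws = mcmc.sample_posterior(cohort, scenario, config.mcmc)
            mcmc.write_draws(draws, artifact(f"draws_{scenario.name}.csv"))
            bayes_tables[scenario.name] = mcmc.summarize_posterior(draws)
            bayes_tables[scenario.name].to_csv(
                artifact(f"posterior_{scenario.name}.csv"), index=False)
            if draws.n_chains >= 2:
                for p in ("beta0", "beta1", "theta", "s"):
                    arr = getattr(draws, p)
                    rhat_rows.append((scenario.name, p, gelman_rubin(arr)))
            if config.make_plots:
                _plot_diagnostics(draws, artifact(f"diag_{scenario.name}.png"))

        stage = "diagnostics"
        if rhat_rows:
            pd.DataFrame(rhat_rows, columns=["scenario", "parameter", "rhat"]
                         ).to_csv(artifact("rhat.csv"), index=False)

        stage = "report"
        report = ScenarioReport(frame=_report_frame(fit.table, bayes_tables),
                                scenario_names=list(bayes_tables))
        report.to_csv(artifact("scenario_report.csv"))
        header = (f"# config {stamp['config_hash']} seed {stamp['seed']}\n")
        artifact("scenario_report.txt").write_text(header + report.to_text() + "\n")
        changes = compare_models(fit.table, bayes_tables)
        changes.to_csv(artifact("pct_change.csv"), index=False)

        manifest["complete"] = True
        save_manifest()
        return report
    except Exception as e:
        manifest["failed_stage"] = stage
        save_manifest()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
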