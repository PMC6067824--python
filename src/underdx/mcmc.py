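"""Bayesian logistic regression with an underreported binary exposure.

The model: admission A_i ~ Bernoulli(p_i) with

    logit(p_i) = beta0 + beta1 * D_i + beta' X_i,

where D_i is the latent TRUE exposure (schizophrenia), D_i ~ Bernoulli(theta),
and the recorded code R_i is an imperfect report with sensitivity s and
perfect specificity:

    R_i | D_i ~ Bernoulli(s * D_i)        (R_i = 1 implies D_i = 1)

Inference is a systematic-scan Metropolis-within-Gibbs sampler with
data augmentation:

1. latent truth: for every unreported patient (R_i = 0), D_i is redrawn from
   its exact conditional P(D_i = 1 | R_i = 0, A_i, X_i, params); reported
   patients keep D_i = 1 (no false positives);
2. prevalence theta: conjugate beta update given the current D;
3. sensitivity s: conjugate beta update from the true cases only
   (reported vs unreported among D = 1);
4. coefficients (beta0, beta1, beta): coordinate-wise Gaussian random-walk
   Metropolis on the conditional log-posterior given D; proposal scales are
   adapted during burn-in only and frozen afterwards, preserving the
   stationary target.

The coefficient sweep exploits sparsity: a proposal on a binary predictor
changes the linear predictor only where that predictor is non-zero, so the
log-likelihood difference is accumulated over that support with cached
per-row log-normalizer terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .naive import DesignMatrix, build_design
from .priors import BetaPrior, ScenarioPrior


@dataclass
class ModelParams:
    """One point in the parameter space of the misclassification model."""

    beta0: float
    beta1: float
    beta: np.ndarray  # length J = 9 covariate coefficients
    theta: float
    s: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not (0.0 < self.theta < 1.0 and 0.0 < self.s < 1.0):
            raise ValueError("theta and s must lie strictly in (0, 1)")


@dataclass
class McmcConfig:
    """Sampler protocol. Defaults: two chains, 10,000 burn-in, 50,000 draws."""

    n_chains: int = 2
    burn_in: int = 10_000
    n_samples: int = 50_000
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 100
    target_accept: float = 0.30
    initial_scale: float | None = None  # overrides the information-based default
    store_latent: bool = False  # keep the full latent trace (tiny cohorts only)

    def validate(self) -> None:
        for name in ("n_chains", "burn_in", "n_samples", "thin", "adapt_interval"):
            if getattr(self, name) < 1 and name != "burn_in":
                raise ValueError(f"{name} must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class PosteriorDraws:
    """Retained MCMC samples, one array block per chain.

    ``latent_count`` is the per-iteration number of imputed true cases among
    the unreported (R = 0) patients; the full latent vector is not stored.
    """

    beta0: np.ndarray        # (chains, kept)
    beta1: np.ndarray        # (chains, kept)
    beta: np.ndarray         # (chains, kept, J)
    theta: np.ndarray        # (chains, kept)
    s: np.ndarray            # (chains, kept)
    latent_count: np.ndarray  # (chains, kept) ints
    coef_names: list[str]
    scenario_name: str = "custom"
    config: McmcConfig | None = None
    latent: np.ndarray | None = None  # (chains, kept, n) when store_latent
    accept_rate: np.ndarray | None = None  # (chains, n_coef) post-burn-in MH rates

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    def pooled(self, param: str) -> np.ndarray:
        """Draws for one parameter pooled across chains.

        ``param`` is one of beta0, beta1, theta, s, lambda, latent_count, or a
        covariate coefficient name.
        """
        if param == "lambda":
            return 1.0 - self.s.ravel()
        if param in ("beta0", "beta1", "theta", "s", "latent_count"):
            return getattr(self, param).reshape(-1)
        j = self.coef_names.index(param)
        return self.beta[:, :, j].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: chain, iter, beta0, beta1, covariates, theta, s, latent_count."""
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame({"chain": c, "iter": np.arange(self.beta0.shape[1]),
                               "beta0": self.beta0[c], "beta1": self.beta1[c]})
            for j, name in enumerate(self.coef_names):
                df[name] = self.beta[c, :, j]
            df["theta"] = self.theta[c]
            df["s"] = self.s[c]
            df["latent_count"] = self.latent_count[c]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def write_draws(draws: PosteriorDraws, path: str | Path) -> None:
    draws.to_frame().to_csv(path, index=False)


# --- component updates -------------------------------------------------------

def latent_posterior_prob(theta: float, s: float, lik1, lik0):
    """P(D = 1 | R = 0, A, X, params) for an unreported patient.

    ``lik1`` and ``lik0`` are the Bernoulli likelihoods of the observed
    admission under D = 1 and D = 0. By Bayes' rule with P(R=0 | D=1) = 1 - s
    and P(R=0 | D=0) = 1:

        theta (1 - s) lik1 / (theta (1 - s) lik1 + (1 - theta) lik0)
    """
    w1 = theta * (1.0 - s) * np.asarray(lik1, dtype=float)
    w0 = (1.0 - theta) * np.asarray(lik0, dtype=float)
    out = w1 / (w1 + w0)
    return float(out) if out.ndim == 0 else out


def theta_posterior(d: np.ndarray, prior: BetaPrior) -> BetaPrior:
    """Conjugate posterior of the prevalence given the latent truth vector."""
    d = np.asarray(d)
    nd = int(d.sum())
    return BetaPrior(prior.alpha + nd, prior.beta + d.size - nd)


def gibbs_update_theta(d: np.ndarray, prior: BetaPrior,
                       rng: np.random.Generator) -> float:
    post = theta_posterior(d, prior)
    return float(rng.beta(post.alpha, post.beta))


def s_posterior(d: np.ndarray, r: np.ndarray, prior: BetaPrior) -> BetaPrior:
    """Conjugate posterior of the sensitivity; only true cases inform it."""
    d = np.asarray(d).astype(bool)
    r = np.asarray(r).astype(bool)
    if (r & ~d).any():
        raise RuntimeError("inconsistent latent state: R = 1 with D = 0 "
                           "violates perfect specificity")
    reported_true = int((r & d).sum())
    missed_true = int((~r & d).sum())
    return BetaPrior(prior.alpha + reported_true, prior.beta + missed_true)


def gibbs_update_s(d: np.ndarray, r: np.ndarray, prior: BetaPrior,
                   rng: np.random.Generator) -> float:
    post = s_posterior(d, r, prior)
    return float(rng.beta(post.alpha, post.beta))


def _prepare_columns(A: np.ndarray, X9: np.ndarray):
    """Sparse/dense descriptors (idx, values, sum A*x) for the MH sweep.

    Entry 0 is the intercept, entry 1 a placeholder for the dynamic exposure
    column D (rebuilt each scan), entries 2.. the static covariates.
    """
    n = A.size
    cols: list[tuple] = [(None, None, float(A.sum()))]  # intercept: x = 1 dense
    cols.append(None)  # exposure D, dynamic
    for j in range(X9.shape[1]):
        col = X9[:, j]
        idx = np.flatnonzero(col)
        ax = float(A @ col)
        if idx.size > 0.6 * n:
            cols.append((None, col, ax))
        else:
            cols.append((idx, col[idx].astype(float), ax))
    return cols


def _coef_scan(c, eta, L, cols, prior_mean, prior_prec, scales,
               rng: np.random.Generator) -> np.ndarray:
    """One coordinate-wise random-walk Metropolis sweep over the coefficients.

    Mutates ``c`` (coefficient vector), ``eta`` (linear predictor) and ``L``
    (cached log(1 + exp(eta)) per row) in place; returns the acceptance mask.
    Each coordinate's acceptance ratio uses the exact Bernoulli log-likelihood
    difference plus the normal prior ratio (symmetric proposal).
    """
    k = c.size
    deltas = rng.standard_normal(k) * scales
    logu = np.log(rng.random(k))
    accepted = np.zeros(k, dtype=bool)
    for j in range(k):
        delta = deltas[j]
        idx, xval, ax = cols[j]
        if idx is None:
            eta_new = eta + delta if xval is None else eta + delta * xval
            L_new = np.logaddexp(0.0, eta_new)
            dll = delta * ax - L_new.sum() + L.sum()
        else:
            eta_new = eta[idx] + delta * xval
            L_new = np.logaddexp(0.0, eta_new)
            dll = delta * ax - L_new.sum() + L[idx].sum()
        new = c[j] + delta
        dlp = 0.5 * prior_prec[j] * ((c[j] - prior_mean[j]) ** 2
                                     - (new - prior_mean[j]) ** 2)
        if logu[j] < dll + dlp:
            c[j] = new
            if idx is None:
                eta[:] = eta_new
                L[:] = L_new
            else:
                eta[idx] = eta_new
                L[idx] = L_new
            accepted[j] = True
    return accepted


def update_coefficients(design: DesignMatrix, d: np.ndarray,
                        scenario: ScenarioPrior, current: ModelParams,
                        rng: np.random.Generator,
                        scales: np.ndarray | float = 0.05) -> ModelParams:
    """One MH transition of (beta0, beta1, beta) given the latent truth.

    The exposure column of ``design`` is replaced by ``d``. Detailed balance
    holds coordinate-wise (symmetric Gaussian proposals, exact accept ratio).
    """
    A = design.y
    X9 = design.X[:, 1:]
    d = np.asarray(d, dtype=float).ravel()
    if d.size != A.size:
        raise ValueError("latent vector and design are not conformable")
    c = np.concatenate([[current.beta0, current.beta1], current.beta])
    cols = _prepare_columns(A, X9)
    idx_d = np.flatnonzero(d)
    cols[1] = (idx_d, np.ones(idx_d.size), float(A[idx_d].sum()))
    eta = c[0] + X9 @ c[2:] + c[1] * d
    if not np.isfinite(eta).all():
        raise ValueError("non-finite log-posterior at the current state")
    L = np.logaddexp(0.0, eta)
    pm = np.concatenate([[scenario.intercept_prior.mean],
                         np.full(c.size - 1, scenario.coefficient_prior.mean)])
    pprec = np.concatenate([[scenario.intercept_prior.precision],
                            np.full(c.size - 1, scenario.coefficient_prior.precision)])
    scales = np.broadcast_to(np.asarray(scales, dtype=float), c.shape).copy()
    _coef_scan(c, eta, L, cols, pm, pprec, scales, rng)
    return ModelParams(beta0=float(c[0]), beta1=float(c[1]), beta=c[2:].copy(),
                       theta=current.theta, s=current.s)


# --- full sampler -------------------------------------------------------------

def _initial_state(chain: int, scenario: ScenarioPrior, n_coef: int):
    """Chain 0 starts at prior means / zeros; odd chains are overdispersed."""
    tp, sp = scenario.prevalence_prior, scenario.sensitivity_prior
    c = np.zeros(n_coef)
    c[0] = scenario.intercept_prior.mean
    if chain % 2 == 1:
        signs = np.where(np.arange(n_coef) % 2 == 0, 0.5, -0.5)
        c = c + signs
        theta = float(beta_dist.ppf(0.9, tp.alpha, tp.beta))
        s = float(beta_dist.ppf(0.1, sp.alpha, sp.beta))
    else:
        theta, s = tp.mean, sp.mean
    return c, theta, s


def _run_chain(A, X9, R, scenario: ScenarioPrior, config: McmcConfig,
               chain: int, fix_coefficients: ModelParams | None):
    rng = np.random.default_rng([config.seed, chain])
    n = A.size
    idx_r0 = np.flatnonzero(~R)
    a_r0 = A[idx_r0]
    n_r1 = int(R.sum())
    n_coef = 2 + X9.shape[1]

    c, theta, s = _initial_state(chain, scenario, n_coef)
    if fix_coefficients is not None:
        c = np.concatenate([[fix_coefficients.beta0, fix_coefficients.beta1],
                            fix_coefficients.beta])
    D = R.copy()

    cols = _prepare_columns(A, X9)
    pm = np.concatenate([[scenario.intercept_prior.mean],
                         np.full(n_coef - 1, scenario.coefficient_prior.mean)])
    pprec = np.concatenate([[scenario.intercept_prior.precision],
                            np.full(n_coef - 1, scenario.coefficient_prior.precision)])
    # information-based starting scales, adapted during burn-in
    ss = np.empty(n_coef)
    ss[0] = n
    ss[1] = max(theta * n, 1.0)
    ss[2:] = np.maximum((X9 ** 2).sum(axis=0), 1.0)
    scales = 2.4 / np.sqrt(0.25 * ss + pprec)
    if config.initial_scale is not None:
        scales = np.full(n_coef, config.initial_scale)

    tp, sp = scenario.prevalence_prior, scenario.sensitivity_prior
    kept = (config.n_samples + config.thin - 1) // config.thin
    out = {k: np.empty((kept,)) for k in ("beta0", "beta1", "theta", "s")}
    out_beta = np.empty((kept, n_coef - 2))
    out_latent = np.empty(kept, dtype=int)
    out_d = np.empty((kept, n), dtype=np.int8) if config.store_latent else None

    acc_count = np.zeros(n_coef)
    acc_total = 0
    acc_post = np.zeros(n_coef)  # post-burn-in acceptance (frozen scales)
    base = None
    if fix_coefficients is not None:
        base = c[0] + X9 @ c[2:]

    total = config.burn_in + config.n_samples
    for t in range(total):
        if fix_coefficients is None:
            base = c[0] + X9 @ c[2:]
        # 1. latent truth for the unreported patients
        eta0 = base[idx_r0]
        p1 = expit(eta0 + c[1])
        p0 = expit(eta0)
        lik1 = np.where(a_r0 == 1, p1, 1.0 - p1)
        lik0 = np.where(a_r0 == 1, p0, 1.0 - p0)
        prob = latent_posterior_prob(theta, s, lik1, lik0)
        D[idx_r0] = rng.random(idx_r0.size) < prob
        nd = int(D.sum())
        # 2. prevalence (conjugate)
        theta = rng.beta(tp.alpha + nd, tp.beta + n - nd)
        # 3. sensitivity (conjugate; reported vs missed true cases)
        s = rng.beta(sp.alpha + n_r1, sp.beta + (nd - n_r1))
        # 4. coefficients (random-walk MH given D)
        if fix_coefficients is None:
            d_float = D.astype(float)
            eta = base + c[1] * d_float
            L = np.logaddexp(0.0, eta)
            idx_d = np.flatnonzero(D)
            cols[1] = (idx_d, np.ones(idx_d.size), float(A[idx_d].sum()))
            acc = _coef_scan(c, eta, L, cols, pm, pprec, scales, rng)
            if t >= config.burn_in:
                acc_post += acc
            if t < config.burn_in:
                acc_count += acc
                acc_total += 1
                if acc_total == config.adapt_interval:
                    rate = acc_count / acc_total
                    scales *= np.exp(rate - config.target_accept)
                    # ceiling ~ an RW scale adequate even for a coefficient
                    # the data barely constrain (prior sd up to 100)
                    np.clip(scales, 1e-5, 1e3, out=scales)
                    acc_count[:] = 0
                    acc_total = 0
        if t >= config.burn_in and (t - config.burn_in) % config.thin == 0:
            k = (t - config.burn_in) // config.thin
            out["beta0"][k] = c[0]
            out["beta1"][k] = c[1]
            out_beta[k] = c[2:]
            out["theta"][k] = theta
            out["s"][k] = s
            out_latent[k] = nd - n_r1
            if out_d is not None:
                out_d[k] = D
    return out, out_beta, out_latent, out_d, acc_post / config.n_samples


def sample_posterior(cohort: pd.DataFrame, scenario: ScenarioPrior,
                     config: McmcConfig | None = None,
                     fix_coefficients: ModelParams | None = None
                     ) -> PosteriorDraws:
    """Run the full data-augmentation sampler on a cohort.

    ``fix_coefficients`` holds (beta0, beta1, beta) at the given values and
    skips their update — useful for validating the latent/conjugate blocks
    against exhaustive enumeration on tiny cohorts.

    Reproducibility: draws are a deterministic function of (config.seed,
    chain index).
    """
    config = config or McmcConfig()
    config.validate()
    design = build_design(cohort, exposure="reported")
    A = design.y.astype(int)
    R = design.X[:, 0].astype(bool)
    X9 = design.X[:, 1:]
    coef_names = design.names[1:]

    blocks = [_run_chain(A, X9, R, scenario, config, chain, fix_coefficients)
              for chain in range(config.n_chains)]
    return PosteriorDraws(
        beta0=np.stack([b[0]["beta0"] for b in blocks]),
        beta1=np.stack([b[0]["beta1"] for b in blocks]),
        beta=np.stack([b[1] for b in blocks]),
        theta=np.stack([b[0]["theta"] for b in blocks]),
        s=np.stack([b[0]["s"] for b in blocks]),
        latent_count=np.stack([b[2] for b in blocks]),
        coef_names=list(coef_names),
        scenario_name=scenario.name,
        config=config,
        latent=np.stack([b[3] for b in blocks]) if config.store_latent else None,
        accept_rate=np.stack([b[4] for b in blocks]),
    )


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Posterior summary table, chains pooled.

    Coefficient rows are summarized on the odds-ratio scale: ``or_`` is the
    posterior mean of exp(draws) and the interval the equal-tailed percentile
    interval of exp(draws). ``estimate``/``se`` are the posterior mean/sd on
    the log-odds scale. theta, s and lambda rows are summarized on the
    probability scale (``or_`` left blank), latent_count on the count scale.
    """
    if draws.beta0.size == 0:
        raise ValueError("empty draws")
    lo, hi = 100 * (0.5 - level / 2), 100 * (0.5 + level / 2)
    rows = []
    coef_terms = [("intercept", draws.pooled("beta0")),
                  ("schizophrenia", draws.pooled("beta1"))]
    coef_terms += [(name, draws.pooled(name)) for name in draws.coef_names]
    for term, x in coef_terms:
        ex = np.exp(x)
        rows.append((term, "odds_ratio", x.mean(), x.std(ddof=1), ex.mean(),
                     np.percentile(ex, lo), np.percentile(ex, hi), level))
    for term in ("theta", "s", "lambda", "latent_count"):
        x = draws.pooled(term).astype(float)
        rows.append((term, "probability" if term != "latent_count" else "count",
                     x.mean(), x.std(ddof=1), np.nan,
                     np.percentile(x, lo), np.percentile(x, hi), level))
    return pd.DataFrame(rows, columns=["term", "scale", "estimate", "se", "or_",
                                       "ci_low", "ci_high", "level"])
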