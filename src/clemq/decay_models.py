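"""Kinetic models of age-dependent secretory-granule turnover.

Pulse-chase labeling marks the cohort of insulin granules synthesized in a
short window; the labeled fraction ``y(t)`` of all granules is then followed
as the cohort ages.  Three nested decay models describe the fate of the
cohort:

* **Model 1** — simple exponential consumption from birth,
  ``y(t) = a * exp(-t / tau)``.
* **Model 2** — a lag of duration ``delta`` during which the pool is stable,
  followed by exponential decay with time constant ``tau``:
  ``y(t) = a`` for ``t <= delta``, else ``a * exp(-(t - delta) / tau)``.
* **Model 3** — slow decay (time constant ``tau1``) up to ``delta``, then
  fast decay (``tau2 = tau``), continuous at the breakpoint.

Fits are weighted maximum likelihood with per-point Gaussian errors whose
standard deviations are the observed SEMs.  The log-likelihood is kept in
weighted-residual form (no ``-sum(log(sigma * sqrt(2*pi)))`` constant):
only likelihood *differences* between models fitted to the same data are
meaningful, which is all that model comparison needs.

Model comparison offers straight likelihood ratios and a Laplace
approximation of the marginal evidence over a uniform prior box, combined
with a uniform model prior into posterior model probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import qmc

__all__ = [
    "GranuleAgeObservation",
    "DecayParams",
    "DecayModelFit",
    "ModelComparison",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "eval_decay_model",
    "log_likelihood",
    "fit_decay_model",
    "compare_models",
    "half_life",
]


@dataclass(frozen=True)
class GranuleAgeObservation:
    """Labeled-granule fraction at one cohort age.

    Parameters
    ----------
    t : float
        Granule age in days (the 5-8 h group is encoded as 0.27 d).
    y : float
        Labeled fraction, dimensionless in [0, 1].
    sem : float
        Standard error of ``y`` across replicate experiments.
    n_replicates : int
        Number of replicate experiments behind ``y``.
    n_cells : int
        Total number of cells counted.
    """

    t: float
    y: float
    sem: float
    n_replicates: int = 1
    n_cells: int = 0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"age must be non-negative, got t={self.t}")
        if not 0.0 <= self.y <= 1.0:
            raise ValueError(f"labeled fraction must lie in [0, 1], got {self.y}")
        if self.n_replicates > 1 and not self.sem > 0:
            raise ValueError("sem must be positive when n_replicates > 1")


# Free-parameter layout per model, in fit order.
PARAM_NAMES: dict[int, tuple[str, ...]] = {
    1: ("a", "tau"),
    2: ("a", "delta", "tau"),
    3: ("a", "delta", "tau1", "tau"),
}

# Uniform prior box; also the optimizer's search region and the Laplace
# evidence prior volume.  Generous physical ranges around plausible fits.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (1e-6, 0.2),
    "delta": (0.0, 10.0),
    "tau": (0.05, 50.0),
    "tau1": (0.05, 50.0),
}


@dataclass(frozen=True)
class DecayParams:
    """Parameter set of one decay model.

    ``delta`` is ignored by model 1 (fixed at 0), ``tau1`` only applies to
    model 3, where ``tau`` plays the role of the fast time constant tau2.
    """

    model_id: int
    a: float
    tau: float
    delta: float = 0.0
    tau1: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        if not self.a > 0:
            raise ValueError("plateau fraction a must be positive")
        if not self.tau > 0:
            raise ValueError("time constant tau must be positive")
        if self.delta < 0:
            raise ValueError("lag duration delta must be non-negative")
        if self.model_id == 3 and (self.tau1 is None or not self.tau1 > 0):
            raise ValueError("model 3 requires a positive slow time constant tau1")

    def free_values(self) -> np.ndarray:
        """Free parameters in the canonical fit order for this model."""
        vals = {"a": self.a, "delta": self.delta, "tau1": self.tau1, "tau": self.tau}
        return np.array([vals[name] for name in PARAM_NAMES[self.model_id]], float)

    @staticmethod
    def from_free_values(model_id: int, theta: np.ndarray) -> "DecayParams":
        kw = dict(zip(PARAM_NAMES[model_id], np.asarray(theta, float)))
        return DecayParams(model_id=model_id, **kw)


def eval_decay_model(params: DecayParams, t):
    """Evaluate the labeled fraction ``y(t)`` for one model.

    Accepts scalar or array ``t`` (days, non-negative).  Models 2 and 3 are
    continuous at the lag breakpoint and ``y(0) = a`` for every model.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("granule age t must be non-negative")
    a, tau, delta = params.a, params.tau, params.delta
    if params.model_id == 1:
        y = a * np.exp(-t_arr / tau)
    elif params.model_id == 2:
        y = np.where(t_arr <= delta, a, a * np.exp(-(t_arr - delta) / tau))
    else:
        tau1 = params.tau1
        slow = a * np.exp(-t_arr / tau1)
        fast = a * math.exp(-delta / tau1) * np.exp(-(t_arr - delta) / tau)
        y = np.where(t_arr <= delta, slow, fast)
    return y if y.ndim else float(y)


def log_likelihood(obs: list[GranuleAgeObservation], params: DecayParams) -> float:
    """Weighted-residual log-likelihood ``-0.5 * sum(((y - f)/sem)^2)``.

    Higher is better.  The Gaussian normalization constant is deliberately
    omitted; see the module docstring.
    """
    if not obs:
        raise ValueError("need at least one observation")
    t = np.array([o.t for o in obs])
    y = np.array([o.y for o in obs])
    sem = np.array([o.sem for o in obs])
    if np.any(sem <= 0):
        raise ValueError("all observations must have sem > 0")
    resid = (y - eval_decay_model(params, t)) / sem
    return float(-0.5 * np.sum(resid**2))


@dataclass
class DecayModelFit:
    """Result of fitting one decay model to an observation set."""

    params: DecayParams
    std_errors: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    n_obs: int
    converged: bool
    at_boundary: bool = False
    observations: tuple[GranuleAgeObservation, ...] = field(default_factory=tuple)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.params.model_id]

    def to_dict(self) -> dict:
        names = self.param_names
        return {
            "model_id": self.params.model_id,
            "params": dict(zip(names, self.params.free_values().tolist())),
            "std_errors": dict(zip(names, np.asarray(self.std_errors).tolist())),
            "covariance": np.asarray(self.covariance).tolist(),
            "log_likelihood": float(self.log_likelihood),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "at_boundary": bool(self.at_boundary),
        }


def _neg_loglik(theta: np.ndarray, model_id: int, t, y, sem) -> float:
    try:
        p = DecayParams.from_free_values(model_id, theta)
    except ValueError:
        return 1e30
    f = eval_decay_model(p, t)
    return float(0.5 * np.sum(((y - f) / sem) ** 2))


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 0.05) -> np.ndarray:
    """Central finite-difference Hessian.

    The default step is deliberately coarse: the lag-model likelihood has
    slope kinks where the lag crosses an observed age, and curvature probed
    at machine scale right on a kink reports spuriously tight errors.  A
    step at the scale of the parameter (5%) measures the curvature that
    actually shapes the 1-2 SE region.
    """
    k = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-3)
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                fp = fun(x + _unit(k, i, h[i]))
                fm = fun(x - _unit(k, i, h[i]))
                hess[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                fpp = fun(x + _unit(k, i, h[i]) + _unit(k, j, h[j]))
                fpm = fun(x + _unit(k, i, h[i]) - _unit(k, j, h[j]))
                fmp = fun(x - _unit(k, i, h[i]) + _unit(k, j, h[j]))
                fmm = fun(x - _unit(k, i, h[i]) - _unit(k, j, h[j]))
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def _unit(k: int, i: int, scale: float) -> np.ndarray:
    e = np.zeros(k)
    e[i] = scale
    return e


def _heuristic_starts(model_id: int, t, y, lo, hi) -> list[np.ndarray]:
    """Data-driven starting points: plateau from the early points, decay
    time from a log-linear fit to the tail, and (for the lag models) a lag
    candidate at each interior observed age.  Deterministic."""
    order = np.argsort(t)
    t_s, y_s = t[order], np.maximum(y[order], 1e-9)
    a0 = float(np.clip(y_s[:2].mean(), lo[0], hi[0]))
    tail = slice(max(len(t_s) - 3, 0), None)
    slope = np.polyfit(t_s[tail], np.log(y_s[tail]), 1)[0]
    tau0 = float(np.clip(-1.0 / slope if slope < 0 else 5.0, 0.06, hi[-1]))
    starts: list[np.ndarray] = []
    if model_id == 1:
        starts.append(np.array([a0, tau0]))
    elif model_id == 2:
        for delta0 in t_s[:-1]:
            starts.append(np.array([a0, float(np.clip(delta0, 0.0, 10.0)), tau0]))
    else:
        for delta0 in t_s[:-1]:
            starts.append(np.array([a0, float(np.clip(delta0, 0.0, 10.0)), hi[2] * 0.99, tau0]))
        starts.append(np.array([a0, 0.0, tau0, tau0]))
    return starts


def _eval_many(model_id: int, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Vectorized model evaluation: theta (n, k), t (m,) -> y (n, m)."""
    th = {name: theta[:, i : i + 1] for i, name in enumerate(PARAM_NAMES[model_id])}
    t = t[None, :]
    if model_id == 1:
        return th["a"] * np.exp(-t / th["tau"])
    if model_id == 2:
        return np.where(
            t <= th["delta"],
            th["a"],
            th["a"] * np.exp(-(t - th["delta"]) / th["tau"]),
        )
    slow = th["a"] * np.exp(-t / th["tau1"])
    fast = (
        th["a"]
        * np.exp(-th["delta"] / th["tau1"])
        * np.exp(-(t - th["delta"]) / th["tau"])
    )
    return np.where(t <= th["delta"], slow, fast)


def _posterior_moments(
    model_id: int,
    theta_hat: np.ndarray,
    cov0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    sem: np.ndarray,
    seed: int,
    n_samples: int = 8192,
) -> np.ndarray | None:
    """Posterior covariance under the uniform box prior.

    Importance sampling with a Gaussian proposal centered at the optimum,
    twice the curvature-based spread (clipped to the box scale), weights
    ``L(theta) * 1_box / q(theta)``.  Returns ``None`` when the effective
    sample size is too small to trust.
    """
    k = theta_hat.size
    sd0 = np.sqrt(np.abs(np.diag(cov0)))
    sd0 = np.clip(np.nan_to_num(sd0, nan=0.0), 1e-4 * (hi - lo), 0.25 * (hi - lo))
    prop_cov = np.diag((2.0 * sd0) ** 2)
    # keep curvature-implied correlations when they are usable
    if np.all(np.isfinite(cov0)):
        d = np.sqrt(np.abs(np.diag(cov0)))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov0 / np.outer(d, d)
        if np.all(np.isfinite(corr)):
            cand = (2.0 * sd0)[:, None] * corr * (2.0 * sd0)[None, :]
            if np.all(np.linalg.eigvalsh(0.5 * (cand + cand.T)) > 0):
                prop_cov = 0.5 * (cand + cand.T)
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_normal(theta_hat, prop_cov, size=n_samples, method="cholesky")
    inside = np.all((samples >= lo) & (samples <= hi), axis=1)
    if inside.sum() < 50:
        return None
    samples = samples[inside]
    resid = (y[None, :] - _eval_many(model_id, samples, t)) / sem[None, :]
    nll = 0.5 * np.sum(resid**2, axis=1)
    diff = samples - theta_hat
    chol = np.linalg.cholesky(prop_cov)
    z = np.linalg.solve(chol, diff.T)
    log_q = -0.5 * np.sum(z**2, axis=0)
    log_w = -(nll - nll.min()) - log_q
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    ess = 1.0 / np.sum(w**2)
    if ess < 50:
        return None
    mean = w @ samples
    centered = samples - mean
    cov = (w[:, None] * centered).T @ centered
    return 0.5 * (cov + cov.T)


def fit_decay_model(
    obs: list[GranuleAgeObservation],
    model_id: int,
    init: DecayParams | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> DecayModelFit:
    """Fit one decay model by weighted maximum likelihood.

    Runs bounded Nelder-Mead from ``n_starts`` Sobol points inside the
    parameter box plus deterministic data-driven starts (and ``init`` if
    given); the best optimum wins.  Parameter uncertainties are posterior
    moments under the uniform prior box (seeded importance sampling around
    the optimum); the inverse observed information from a finite-difference
    Hessian serves as the proposal scale and as fallback.  The lag-model
    likelihood is kinked where the lag crosses an observed age, so pure
    curvature errors there are optimistic — the posterior moments are the
    calibrated uncertainty.  Parameters resting on a box edge are flagged
    ``at_boundary``.

    Raises ``ValueError`` when the data cannot identify the model
    (observations <= free parameters).
    """
    if model_id not in PARAM_NAMES:
        raise ValueError(f"model_id must be 1, 2 or 3, got {model_id}")
    names = PARAM_NAMES[model_id]
    k = len(names)
    if len(obs) <= k:
        raise ValueError(
            f"model {model_id} has {k} free parameters but only "
            f"{len(obs)} observations were given; need more observations "
            "than parameters"
        )
    t = np.array([o.t for o in obs])
    y = np.array([o.y for o in obs])
    sem = np.array([o.sem for o in obs])
    if np.any(sem <= 0):
        raise ValueError("all observations must have sem > 0")

    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])
    # log-spacing for the scale-like parameters keeps starts sensible
    # across the wide tau range
    log_scale = np.array([n in ("tau", "tau1") for n in names])

    sobol = qmc.Sobol(d=k, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # Sobol balance only matters for integration, not start dispersion
        warnings.simplefilter("ignore", UserWarning)
        u = sobol.random(n_starts)
    starts = np.where(
        log_scale,
        np.exp(np.log(np.maximum(lo, 1e-8)) + u * (np.log(hi) - np.log(np.maximum(lo, 1e-8)))),
        lo + u * (hi - lo),
    )
    start_list = [starts[i] for i in range(n_starts)]
    start_list.extend(_heuristic_starts(model_id, t, y, lo, hi))
    if init is not None:
        if init.model_id != model_id:
            raise ValueError("init parameters belong to a different model")
        start_list.insert(0, np.clip(init.free_values(), lo, hi))

    fun = lambda th: _neg_loglik(th, model_id, t, y, sem)  # noqa: E731
    best = None
    any_success = False
    for x0 in start_list:
        res = optimize.minimize(
            fun,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    theta = np.clip(best.x, lo, hi)
    at_boundary = bool(np.any(np.isclose(theta, lo, atol=1e-9)) or np.any(np.isclose(theta, hi, rtol=1e-9)))

    hess = _fd_hessian(fun, theta)
    try:
        cov = np.linalg.inv(hess)
        ok = np.all(np.isfinite(cov)) and np.all(np.diag(cov) > 0)
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        cov = np.linalg.pinv(hess)
        cov = 0.5 * (cov + cov.T)
    post_cov = _posterior_moments(model_id, theta, cov, lo, hi, t, y, sem, seed=seed + 7919)
    if post_cov is not None:
        cov = post_cov
    # directions the data leave flat (degenerate curvature at a box edge)
    # get prior-scale variance rather than a meaningless negative one
    diag = np.diag(cov).copy()
    bad = ~np.isfinite(diag) | (diag <= 0)
    if bad.any():
        cov = cov.copy()
        width = hi - lo
        for i in np.where(bad)[0]:
            cov[i, :] = 0.0
            cov[:, i] = 0.0
            cov[i, i] = (width[i] / math.sqrt(2 * math.pi)) ** 2
        diag = np.diag(cov).copy()
    std = np.sqrt(diag)

    params = DecayParams.from_free_values(model_id, theta)
    return DecayModelFit(
        params=params,
        std_errors=std,
        covariance=0.5 * (cov + cov.T),
        log_likelihood=-float(best.fun),
        n_obs=len(obs),
        converged=any_success and np.all(np.isfinite(std)),
        at_boundary=at_boundary,
        observations=tuple(obs),
    )


@dataclass
class ModelComparison:
    """Pairwise probability ratios and posterior model probabilities."""

    fits: list[DecayModelFit]
    pairwise_ratios: np.ndarray
    posterior_probs: np.ndarray
    method: str
    log_scores: np.ndarray

    def ratio(self, model_i: int, model_j: int) -> float:
        """Probability ratio of ``model_i`` relative to ``model_j``."""
        ids = [f.params.model_id for f in self.fits]
        return float(self.pairwise_ratios[ids.index(model_i), ids.index(model_j)])

    def best_model(self) -> int:
        ids = np.array([f.params.model_id for f in self.fits])
        order = np.lexsort((ids, -self.posterior_probs))
        return int(ids[order[0]])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "model_ids": [f.params.model_id for f in self.fits],
            "log_scores": self.log_scores.tolist(),
            "pairwise_ratios": self.pairwise_ratios.tolist(),
            "posterior_probs": self.posterior_probs.tolist(),
        }


def _laplace_log_evidence(fit: DecayModelFit) -> float:
    """Box-aware Laplace approximation of the log marginal likelihood.

    Standard Laplace: ``log Z ~= logL* + (k/2) log(2 pi) + 0.5 log det(cov)
    - log V_prior`` with a uniform prior over the parameter box.  Because
    the prior is bounded, the Gaussian mass along any parameter cannot
    exceed the box width; each marginal sigma is therefore truncated at
    ``width / sqrt(2 pi)`` (a direction the data leave flat then
    contributes the prior mass, factor 1, rather than a spurious factor
    > 1), while the correlation determinant is retained.  With no
    truncation this is exactly the standard Laplace formula.
    """
    names = PARAM_NAMES[fit.params.model_id]
    widths = np.array([PARAM_BOUNDS[n][1] - PARAM_BOUNDS[n][0] for n in names])
    cov = np.asarray(fit.covariance)
    sigma = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError(
            f"model {fit.params.model_id}: covariance has a non-positive "
            "diagonal; cannot form a Laplace evidence"
        )
    corr = cov / np.outer(sigma, sigma)
    sign, logdet_corr = np.linalg.slogdet(corr)
    if sign <= 0:
        # near-singular correlation (collinear parameters): clip the
        # spectrum rather than refuse; the evidence is an approximation
        eigvals = np.clip(np.linalg.eigvalsh(0.5 * (corr + corr.T)), 1e-6, None)
        logdet_corr = float(np.sum(np.log(eigvals)))
    s = np.minimum(sigma, widths / math.sqrt(2 * math.pi))
    return float(
        fit.log_likelihood
        + np.sum(np.log(np.sqrt(2 * math.pi) * s))
        + 0.5 * logdet_corr
        - np.sum(np.log(widths))
    )


def compare_models(fits: list[DecayModelFit], method: str = "likelihood_ratio") -> ModelComparison:
    """Compare fitted models on the same data under a uniform model prior.

    ``likelihood_ratio`` scores each model by its maximized log-likelihood;
    ``laplace_evidence`` by the Laplace-approximated log evidence over the
    uniform prior box, which penalizes extra parameters by their posterior
    volume.  Pairwise ratios are ``exp(score_i - score_j)`` and posterior
    probabilities the softmax of the scores.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ref = fits[0].observations
    for f in fits[1:]:
        same = len(f.observations) == len(ref) and all(
            a.t == b.t and a.y == b.y and a.sem == b.sem
            for a, b in zip(f.observations, ref)
        )
        if ref and f.observations and not same:
            raise ValueError("fits were made on differing observation sets")
    if method == "likelihood_ratio":
        scores = np.array([f.log_likelihood for f in fits])
    elif method == "laplace_evidence":
        scores = np.array([_laplace_log_evidence(f) for f in fits])
    else:
        raise ValueError(f"unknown method {method!r}")
    ratios = np.exp(scores[:, None] - scores[None, :])
    shifted = scores - scores.max()
    probs = np.exp(shifted) / np.sum(np.exp(shifted))
    return ModelComparison(
        fits=list(fits),
        pairwise_ratios=ratios,
        posterior_probs=probs,
        method=method,
        log_scores=scores,
    )


def half_life(params: DecayParams) -> float:
    """Age (days) at which the labeled pool falls to half its plateau.

    Model 1: ``ln(2) * tau``.  Model 2: ``delta + ln(2) * tau``.  Model 3 is
    solved piecewise: if the slow phase alone reaches ``a/2`` before
    ``delta`` (i.e. ``tau1 * ln 2 <= delta``) the half-life lies in the slow
    branch at ``tau1 * ln 2``; otherwise it lies in the fast branch at
    ``delta + tau * (ln 2 - delta / tau1)``.
    """
    if not params.tau > 0:
        raise ValueError("time constant tau must be positive")
    ln2 = math.log(2.0)
    if params.model_id == 1:
        return ln2 * params.tau
    if params.model_id == 2:
        return params.delta + ln2 * params.tau
    tau1 = params.tau1
    if tau1 * ln2 <= params.delta:
        return tau1 * ln2
    return params.delta + params.tau * (ln2 - params.delta / tau1)
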