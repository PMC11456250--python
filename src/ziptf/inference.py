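"""Bayesian CP tensor factorization by stochastic variational inference.

The model: a non-negative rank-R CP decomposition whose reconstruction
``lambda_I = sum_r prod_k a^(k)[i_k, r]`` parameterizes the mean of an
observation model for each tensor entry.  Supported observation models:

``zip``
    Zero-inflated Poisson: a mixture of a point mass at zero (probability p
    of "extra" zeros, shared across entries through a logit-normal gate) and
    Poisson(lambda_I).  The model of choice for sparse scRNA-seq-derived
    count tensors where dropout inflates the zero fraction.
``gamma_poisson``
    Plain Poisson likelihood with Gamma factor priors (Bayesian Poisson
    tensor factorization).
``truncated_gaussian``
    Normal(lambda_I, tau) truncated to [0, inf) with a learned global scale
    tau; a configurable Gaussian baseline.

Factors carry entrywise Gamma(alpha^(k), beta^(k)) priors and a fully
factorized mean-field variational family: Gamma(gamma^(k), delta^(k)) per
factor entry plus a Normal(mu_bar, sigma_bar) over the gate logit.  The ELBO
is maximized by stochastic gradient ascent with Monte-Carlo gradients taken
pathwise through the Gamma samples (implicit reparameterization: the sample's
derivative with respect to the shape comes from differentiating the Gamma CDF)
and Adam-style adaptive steps on unconstrained log-parameters, which keeps
every variational parameter strictly positive.

A closed-form coordinate-ascent (CAVI) solver for the Gamma-Poisson model is
also provided (:func:`cavi_gptf_fit`); it is deterministic given its
initialization and serves as an independent reference for the stochastic
optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .tensors import CountTensor, CPFactors, explained_variance, khatri_rao, reconstruct

__all__ = [
    "ModelSpec",
    "VariationalState",
    "FitResult",
    "zip_log_pmf",
    "log_joint",
    "elbo_estimate",
    "fit",
    "point_estimate",
    "geometric_point_estimate",
    "cavi_gptf_fit",
]

_NOISE_MODELS = ("zip", "gamma_poisson", "truncated_gaussian")


@dataclass
class ModelSpec:
    """Observation model, rank and prior hyperparameters for one fit.

    ``prior_shape``/``prior_rate`` may be scalars (shared across modes) or
    per-mode sequences.  For the ZIP gate, ``gate_prior_mean``/``gate_prior_sd``
    parameterize the Normal prior on the gate logit; ``gate_mode`` selects one
    global gate (default) or one gate per index of the last mode (per-gene).
    """

    noise_model: str = "zip"
    rank: int = 1
    prior_shape: float | tuple = 1.0
    prior_rate: float | tuple = 0.3
    gate_prior_mean: float = 0.0
    gate_prior_sd: float = 1.0
    gate_mode: str = "global"
    tg_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.gate_prior_sd <= 0:
            raise ValueError("gate_prior_sd must be positive")
        if self.gate_mode not in ("global", "per_gene"):
            raise ValueError("gate_mode must be 'global' or 'per_gene'")
        for name in ("prior_shape", "prior_rate"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")

    def mode_prior(self, n_modes: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-mode (shape, rate) arrays of length ``n_modes``."""
        shp = np.broadcast_to(np.asarray(self.prior_shape, float), (n_modes,))
        rate = np.broadcast_to(np.asarray(self.prior_rate, float), (n_modes,))
        return np.array(shp), np.array(rate)


@dataclass
class VariationalState:
    """Mean-field variational parameters and the recorded ELBO trace."""

    gamma: list[np.ndarray]
    delta: list[np.ndarray]
    gate_mean: np.ndarray | float | None = None
    gate_sd: np.ndarray | float | None = None
    elbo_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        for g, d in zip(self.gamma, self.delta):
            if np.any(g <= 0) or np.any(d <= 0):
                raise ValueError("variational shapes/rates must be positive")
        if self.gate_sd is not None and np.any(np.asarray(self.gate_sd) <= 0):
            raise ValueError("gate_sd must be positive")


@dataclass
class FitResult:
    """Point estimate (variational means), full state and fit diagnostics."""

    point_estimate: CPFactors
    state: VariationalState
    spec: ModelSpec
    explained_variance: float
    seed: int
    converged: bool
    n_iter: int

    @property
    def elbo_trace(self) -> np.ndarray:
        return self.state.elbo_trace


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def poisson_log_pmf(x, lam):
    """Poisson log-pmf with the log-gamma continuous extension in x."""
    x = np.asarray(x, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return x * np.log(lam) - lam - special.gammaln(x + 1.0)


def zip_log_pmf(x, lam, p):
    """Zero-inflated Poisson log-pmf.

    ``log[ p*1{x=0} + (1-p)*exp(-lam)*lam^x/x! ]`` with the factorial evaluated
    through log-gamma, so non-integer x (CPM-normalized data) is accepted as a
    continuous extension.
    """
    x = np.asarray(x, dtype=float)
    lam = np.asarray(lam, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be positive")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    pois = poisson_log_pmf(x, lam)
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_1mp = np.log1p(-p)
    # x == 0: logaddexp(log p, log(1-p) - lam); x > 0: log(1-p) + pois
    zero_branch = np.logaddexp(log_p, log_1mp - lam)
    out = np.where(x == 0, zero_branch, log_1mp + pois)
    return out if out.ndim else float(out)


def _tg_log_pdf(x, lam, tau):
    """Normal(lam, tau) truncated to [0, inf) log-density."""
    z = (x - lam) / tau
    log_norm = special.log_ndtr(lam / tau)  # P(X >= 0)
    return -0.5 * z * z - math.log(tau) - 0.5 * math.log(2 * math.pi) - log_norm


def log_joint(
    factors: CPFactors,
    gate: float | None,
    x: CountTensor | np.ndarray,
    spec: ModelSpec,
) -> float:
    """Log of the joint density: factor priors + gate prior + likelihood.

    ``gate`` is the extra-zero probability p in (0, 1) (ZIP only; pass None
    otherwise).  Raises if any term is non-finite.
    """
    data = x.data if isinstance(x, CountTensor) else np.asarray(x, dtype=float)
    for k, f in enumerate(factors.factors):
        if np.any(f <= 0):
            raise ValueError(f"factor {k} must be strictly positive")
    shp, rate = spec.mode_prior(factors.order)
    prior = 0.0
    for k, f in enumerate(factors.factors):
        prior += float(
            np.sum(special.xlogy(shp[k] - 1.0, f) - rate[k] * f)
            + f.size * (shp[k] * math.log(rate[k]) - special.gammaln(shp[k]))
        )
    if not np.isfinite(prior):
        raise ValueError("non-finite factor prior log-density")
    lam = reconstruct(factors).data
    lam = np.clip(lam, 1e-12, None)
    if spec.noise_model == "zip":
        if gate is None or not (0.0 < gate < 1.0):
            raise ValueError("zip model requires a gate probability in (0, 1)")
        zeta = math.log(gate / (1.0 - gate))
        prior += float(
            -0.5 * ((zeta - spec.gate_prior_mean) / spec.gate_prior_sd) ** 2
            - math.log(spec.gate_prior_sd)
            - 0.5 * math.log(2 * math.pi)
        )
        lik = float(np.sum(zip_log_pmf(data, lam, gate)))
    elif spec.noise_model == "gamma_poisson":
        lik = float(np.sum(poisson_log_pmf(data, lam)))
    else:
        lik = float(np.sum(_tg_log_pdf(data, lam, spec.tg_scale)))
    if not np.isfinite(lik):
        raise ValueError("non-finite observation log-likelihood")
    return prior + lik


# ---------------------------------------------------------------------------
# variational machinery
# ---------------------------------------------------------------------------


def point_estimate(state: VariationalState) -> CPFactors:
    """Arithmetic variational means ``E[a] = gamma / delta`` as CP factors."""
    return CPFactors([g / d for g, d in zip(state.gamma, state.delta)])


def geometric_point_estimate(state: VariationalState) -> CPFactors:
    """Geometric variational means ``exp(psi(gamma)) / delta`` (CAVI companion)."""
    return CPFactors(
        [np.exp(special.psi(g)) / d for g, d in zip(state.gamma, state.delta)]
    )


def _gamma_entropy(g, d):
    return g - np.log(d) + special.gammaln(g) + (1.0 - g) * special.psi(g)


def _safe_ev(x: CountTensor, est: CPFactors) -> float:
    """Explained variance vs the input; NaN for an all-zero input tensor."""
    if float(np.sum(x.data * x.data)) == 0.0:
        return float("nan")
    return explained_variance(x, reconstruct(est))


def _mode_unfold(t: np.ndarray, k: int) -> np.ndarray:
    return np.moveaxis(t, k, 0).reshape(t.shape[k], -1)


def _lambda_from(zs: list[np.ndarray]) -> np.ndarray:
    """Dense reconstruction from per-mode factor samples."""
    kr = khatri_rao(zs[1:])
    return (zs[0] @ kr.T).reshape(tuple(z.shape[0] for z in zs))


def _mttkrp(t: np.ndarray, zs: list[np.ndarray], k: int) -> np.ndarray:
    """Matricized-tensor-times-Khatri-Rao product for mode k."""
    others = [zs[m] for m in range(len(zs)) if m != k]
    return _mode_unfold(t, k) @ khatri_rao(others)


def elbo_estimate(
    state: VariationalState,
    x: CountTensor,
    spec: ModelSpec,
    n_samples: int = 100,
    seed: int = 0,
) -> float:
    """Monte-Carlo ELBO: average of ``log p(x, z) - log q(z)`` over z ~ q."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_samples)
    for s in range(n_samples):
        zs, logq = [], 0.0
        for g, d in zip(state.gamma, state.delta):
            z = np.clip(rng.gamma(g) / d, 1e-12, None)
            logq += float(
                np.sum(
                    special.xlogy(g - 1.0, z) - d * z + special.xlogy(g, d)
                    - special.gammaln(g)
                )
            )
            zs.append(z)
        gate = None
        if spec.noise_model == "zip":
            mu = float(np.asarray(state.gate_mean).ravel()[0])
            sd = float(np.asarray(state.gate_sd).ravel()[0])
            zeta = mu + sd * rng.standard_normal()
            gate = 1.0 / (1.0 + math.exp(-np.clip(zeta, -30, 30)))
            logq += float(
                -0.5 * ((zeta - mu) / sd) ** 2
                - math.log(sd)
                - 0.5 * math.log(2 * math.pi)
            )
        vals[s] = log_joint(CPFactors(zs), gate, x, spec) - logq
    est = float(np.mean(vals))
    if not np.isfinite(est):
        raise ValueError("non-finite ELBO estimate")
    return est


def _dgamma_sample_dshape(t: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Implicit-reparameterization derivative of a Gamma(g, 1) draw w.r.t. g.

    ``dz/dg = -(dF/dg)(t; g) / pdf(t; g)`` with dF/dg by central difference of
    the regularized lower incomplete gamma function.
    """
    h = np.maximum(1e-6, 1e-5 * g)
    dF = (special.gammainc(g + h, t) - special.gammainc(g - h, t)) / (2.0 * h)
    log_pdf = special.xlogy(g - 1.0, t) - t - special.gammaln(g)
    pdf = np.exp(np.clip(log_pdf, -700, 700))
    out = np.where(pdf > 1e-290, -dF / np.where(pdf > 1e-290, pdf, 1.0), 0.0)
    # cap pathological values from vanishing densities in the far tails
    return np.clip(out, -1e6, 1e6)


class _Adam:
    def __init__(self, lr: float):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for key, grad in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(grad)
                self.v[key] = np.zeros_like(grad)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * grad
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * grad * grad
            params[key] += (
                self.lr * (self.m[key] / b1t) / (np.sqrt(self.v[key] / b2t) + self.eps)
            )


def fit(
    x: CountTensor,
    spec: ModelSpec,
    max_iter: int = 1000,
    seed: int = 0,
    init: CPFactors | None = None,
    init_mode: int | None = None,
    n_mc_samples: int = 2,
    step_size: float = 0.2,
    tol: float = 0.0,
    min_iter: int = 100,
    freeze_init: bool = False,
    elbo_window: int = 25,
    step_decay: float = 0.03,
) -> FitResult:
    """Fit the Bayesian CP model by stochastic gradient ascent on the ELBO.

    Parameters
    ----------
    x
        Non-negative data tensor (counts, or CPM-normalized values; the
        Poisson/ZIP likelihoods use their continuous log-gamma extension).
    spec
        Observation model, rank and priors.
    max_iter, step_size, n_mc_samples
        Optimization budget, Adam step size and Monte-Carlo samples per step.
    seed
        Fully determines initialization and every Monte-Carlo draw.
    init, init_mode
        Optional fixed initial guess for one mode's variational means (the
        consensus refit path).  ``init_mode`` defaults to the last mode.
        ``freeze_init=True`` keeps that mode fixed instead of optimizing it.
    tol, min_iter, elbo_window
        Optional early stopping: with ``tol > 0``, stop once the
        ``elbo_window``-iteration moving average of the ELBO changes by less
        than ``tol`` in relative terms.  The default ``tol=0`` runs the full
        ``max_iter`` budget, which keeps run length (and hence the decayed
        step schedule) identical across restarts of a consensus ensemble.
    step_decay
        The Adam step size decays exponentially to ``step_size * step_decay``
        over ``max_iter`` iterations (a diminishing-step schedule; the
        stochastic gradient cannot settle under a constant step).

    Returns
    -------
    FitResult with the arithmetic-mean point estimate, the variational state
    (including the ELBO trace) and the explained variance against ``x``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if isinstance(x, np.ndarray):
        x = CountTensor(x)
    data = x.data
    dims = data.shape
    N = len(dims)
    R = spec.rank
    shp, rate = spec.mode_prior(N)
    rng = np.random.default_rng(seed)
    is_zero = data == 0
    lgamma_x = special.gammaln(data + 1.0)

    if init is not None:
        if init_mode is None:
            init_mode = N - 1
        if init.shape[init_mode] != dims[init_mode] or init.rank != R:
            raise ValueError("init factors do not match spec/tensor shape")

    # initialization: variational means drawn from the prior and rescaled so
    # the initial reconstruction matches the data mean (or a fixed init)
    prior_mean_prod = float(np.prod(shp / rate))
    data_mean = max(float(data.mean()), 1e-12)
    init_scale = (data_mean / max(R * prior_mean_prod, 1e-300)) ** (1.0 / N)
    log_g, log_d = [], []
    for k in range(N):
        if init is not None and k == init_mode:
            mean = np.clip(init.factors[init_mode], 1e-6, None)
            conc = 10.0
        else:
            mean = init_scale * np.clip(
                rng.gamma(shp[k], 1.0 / rate[k], size=(dims[k], R)), 1e-3, None
            )
            conc = 2.0
        log_g.append(np.full((dims[k], R), np.log(conc)))
        log_d.append(np.log(conc / mean))

    gate_shape = (dims[-1],) if spec.gate_mode == "per_gene" else ()
    params = {f"lg{k}": log_g[k] for k in range(N)}
    params.update({f"ld{k}": log_d[k] for k in range(N)})
    if spec.noise_model == "zip":
        params["gmu"] = np.zeros(gate_shape)
        params["gls"] = np.full(gate_shape, math.log(0.5))
    if spec.noise_model == "truncated_gaussian":
        # tau is a point parameter updated in closed form; start at the
        # residual scale of the mean-matched init rather than spec.tg_scale
        params["ltau"] = float(
            0.5 * math.log(max(float(np.var(data)), spec.tg_scale**2, 1e-12))
        )

    opt = _Adam(step_size)
    S = max(1, int(n_mc_samples))
    trace = []
    converged = False
    n_done = max_iter
    frozen = {f"lg{init_mode}", f"ld{init_mode}"} if (init is not None and freeze_init) else set()

    decay = max(min(step_decay, 1.0), 1e-6)
    for it in range(max_iter):
        opt.lr = step_size * decay ** (it / max(max_iter - 1, 1))
        g_list = [np.exp(np.clip(params[f"lg{k}"], -7, 16)) for k in range(N)]
        d_list = [np.exp(np.clip(params[f"ld{k}"], -20, 20)) for k in range(N)]

        grads = {key: 0.0 for key in params if key != "ltau"}
        elbo_mc = 0.0
        for _ in range(S):
            # --- sample factors pathwise ---
            zs, ts = [], []
            for k in range(N):
                t = np.clip(rng.gamma(g_list[k]), 1e-12, None)
                ts.append(t)
                zs.append(t / d_list[k])
            lam = np.clip(_lambda_from(zs), 1e-10, None)

            # --- likelihood value and d loglik / d lambda ---
            if spec.noise_model == "zip":
                mu_g = params["gmu"]
                sd_g = np.exp(np.clip(params["gls"], -10, 5))
                eps = rng.standard_normal(gate_shape) if gate_shape else rng.standard_normal()
                zeta = np.clip(mu_g + sd_g * eps, -30, 30)
                p = 1.0 / (1.0 + np.exp(-zeta))
                exp_neg = np.exp(-np.clip(lam, None, 700.0))
                denom = p + (1.0 - p) * exp_neg
                dldlam = np.where(is_zero, -(1.0 - p) * exp_neg / denom, data / lam - 1.0)
                ll = np.where(
                    is_zero,
                    np.log(denom),
                    np.log1p(-p) + special.xlogy(data, lam) - lam - lgamma_x,
                )
                elbo_mc += float(np.sum(ll))
                # gate gradient: d loglik / dp, then through the sigmoid
                dldp = np.where(is_zero, (1.0 - exp_neg) / denom, -1.0 / (1.0 - p))
                if gate_shape:
                    g_p = dldp.reshape(-1, dims[-1]).sum(axis=0)
                else:
                    g_p = float(np.sum(dldp))
                g_zeta = g_p * p * (1.0 - p) - (zeta - spec.gate_prior_mean) / spec.gate_prior_sd**2
                elbo_mc += float(
                    np.sum(
                        -0.5 * ((zeta - spec.gate_prior_mean) / spec.gate_prior_sd) ** 2
                        - math.log(spec.gate_prior_sd)
                        - 0.5 * math.log(2 * math.pi)
                    )
                )
                grads["gmu"] = grads["gmu"] + g_zeta / S
                grads["gls"] = grads["gls"] + (g_zeta * eps * sd_g) / S
            elif spec.noise_model == "gamma_poisson":
                dldlam = data / lam - 1.0
                ll = special.xlogy(data, lam) - lam - lgamma_x
                elbo_mc += float(np.sum(ll))
            else:  # truncated gaussian
                tau = float(np.exp(np.clip(params["ltau"], -10, 12)))
                zscore = (data - lam) / tau
                alpha = lam / tau
                log_norm = special.log_ndtr(alpha)
                # hazard of the truncation normalizer
                haz = np.exp(
                    -0.5 * alpha * alpha - 0.5 * math.log(2 * math.pi) - log_norm
                )
                dldlam = zscore / tau - haz / tau
                ll = (
                    -0.5 * zscore * zscore
                    - math.log(tau)
                    - 0.5 * math.log(2 * math.pi)
                    - log_norm
                )
                elbo_mc += float(np.sum(ll))
                # closed-form scale update (smoothed): tau^2 <- mean residual^2;
                # a gradient step on tau couples badly with the factor scale
                resid2 = float(np.mean((data - lam) ** 2))
                new_ltau = 0.5 * math.log(max(resid2, 1e-20))
                params["ltau"] = 0.95 * params["ltau"] + 0.05 * new_ltau

            # --- factor gradients: chain rule through the Gamma samples ---
            for k in range(N):
                if f"lg{k}" in frozen:
                    continue
                g_z = _mttkrp(dldlam, zs, k)
                g_z += (shp[k] - 1.0) / zs[k] - rate[k]  # Gamma prior term
                dz_dg = _dgamma_sample_dshape(ts[k], g_list[k]) / d_list[k]
                grads[f"lg{k}"] = grads[f"lg{k}"] + (g_z * dz_dg * g_list[k]) / S
                grads[f"ld{k}"] = grads[f"ld{k}"] + (-g_z * zs[k]) / S
            # prior log-density value (for the ELBO trace)
            for k in range(N):
                elbo_mc += float(
                    np.sum(special.xlogy(shp[k] - 1.0, zs[k]) - rate[k] * zs[k])
                    + zs[k].size * (shp[k] * math.log(rate[k]) - special.gammaln(shp[k]))
                )

        # --- analytic entropy of q and its gradients ---
        elbo = elbo_mc / S
        for k in range(N):
            elbo += float(np.sum(_gamma_entropy(g_list[k], d_list[k])))
            if f"lg{k}" not in frozen:
                dH_dg = 1.0 + (1.0 - g_list[k]) * special.polygamma(1, g_list[k])
                grads[f"lg{k}"] = grads[f"lg{k}"] + dH_dg * g_list[k]
                grads[f"ld{k}"] = grads[f"ld{k}"] - 1.0
        if spec.noise_model == "zip":
            sd_g = np.exp(np.clip(params["gls"], -10, 5))
            elbo += float(np.sum(np.log(sd_g) + 0.5 * math.log(2 * math.pi * math.e)))
            grads["gls"] = grads["gls"] + 1.0

        if not np.isfinite(elbo):
            raise FloatingPointError(f"non-finite ELBO at iteration {it}")
        trace.append(elbo)

        for key in frozen:
            grads.pop(key, None)
        opt.step(params, grads)

        # optional convergence check: relative change of the moving-average ELBO
        w = elbo_window
        if tol > 0 and it + 1 >= max(min_iter, 2 * w):
            recent = np.mean(trace[-w:])
            prev = np.mean(trace[-2 * w : -w])
            if abs(recent - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                n_done = it + 1
                break

    gamma = [np.exp(np.clip(params[f"lg{k}"], -7, 16)) for k in range(N)]
    delta = [np.exp(np.clip(params[f"ld{k}"], -20, 20)) for k in range(N)]
    gate_mean = gate_sd = None
    if spec.noise_model == "zip":
        gate_mean = params["gmu"] if gate_shape else float(params["gmu"])
        gate_sd = (
            np.exp(np.clip(params["gls"], -10, 5))
            if gate_shape
            else float(np.exp(np.clip(params["gls"], -10, 5)))
        )
    state = VariationalState(gamma, delta, gate_mean, gate_sd, np.asarray(trace))
    est = point_estimate(state)
    ev = _safe_ev(x, est)
    final_spec = spec
    if spec.noise_model == "truncated_gaussian":
        final_spec = replace(spec, tg_scale=float(np.exp(params["ltau"])))
    return FitResult(est, state, final_spec, ev, seed, converged, n_done)


# ---------------------------------------------------------------------------
# CAVI for the Gamma-Poisson model (deterministic oracle)
# ---------------------------------------------------------------------------


def cavi_gptf_fit(
    x: CountTensor,
    spec: ModelSpec,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    update_beta: bool = True,
) -> FitResult:
    """Coordinate-ascent variational inference for Gamma-Poisson CP factorization.

    Uses the prior convention ``a ~ Gamma(alpha, alpha * beta^(k))`` with
    ``E[a] = 1/beta^(k)``; ``spec.prior_shape`` supplies alpha (scalar).  The
    multinomial-augmentation updates set the variational shapes from
    responsibilities built on geometric expectations and the rates from
    arithmetic expectations; ``update_beta`` applies the empirical-Bayes rate
    update ``beta^(k) = 1 / sum_jr E[a^(k)_jr]`` after each sweep.  The
    algorithm is deterministic given the (seeded) initialization, and its
    ELBO (the multinomial-augmented bound) is non-decreasing across sweeps for
    fixed hyperparameters.
    """
    if isinstance(x, np.ndarray):
        x = CountTensor(x)
    if spec.noise_model != "gamma_poisson":
        raise ValueError("cavi_gptf_fit requires noise_model='gamma_poisson'")
    data = x.data
    if np.any(data < 0) or not np.allclose(data, np.round(data)):
        raise ValueError("CAVI path requires non-negative integer counts")
    dims = data.shape
    N = len(dims)
    R = spec.rank
    alpha = float(np.atleast_1d(np.asarray(spec.prior_shape, float))[0])
    rng = np.random.default_rng(seed)

    # beta init so the prior mean 1/beta matches the data scale per mode
    scale_guess = (max(data.mean(), 1e-6) / R) ** (1.0 / N)
    beta = np.full(N, 1.0 / max(scale_guess, 1e-6))
    gamma = [alpha * (1.0 + 0.1 * rng.random((dims[k], R))) for k in range(N)]
    delta = [
        alpha * beta[k] * (1.0 + 0.1 * rng.random((dims[k], R))) for k in range(N)
    ]

    lgamma_x = float(np.sum(special.gammaln(data + 1.0)))
    subs = "".join(chr(ord("a") + k) for k in range(N))
    ein_g = ",".join(f"{c}r" for c in subs) + f"->{subs}r"

    def expectations():
        E = [g / d for g, d in zip(gamma, delta)]
        G = [np.exp(special.psi(g)) / d for g, d in zip(gamma, delta)]
        return E, G

    def elbo_value(E, G):
        # multinomial-augmented bound with optimal responsibilities
        gprod = np.einsum(ein_g, *G)
        s = np.clip(gprod.sum(axis=-1), 1e-300, None)
        term_data = float(np.sum(special.xlogy(data, s)))
        colsums = [e.sum(axis=0) for e in E]
        total = float(np.sum(np.prod(np.stack(colsums), axis=0)))
        val = term_data - total - lgamma_x
        for k in range(N):
            Elog = special.psi(gamma[k]) - np.log(delta[k])
            val += float(
                np.sum(
                    alpha * math.log(alpha * beta[k])
                    - special.gammaln(alpha)
                    + (alpha - 1.0) * Elog
                    - alpha * beta[k] * E[k]
                )
            )
            val += float(np.sum(_gamma_entropy(gamma[k], delta[k])))
        return val

    trace = []
    converged = False
    n_done = max_iter
    for it in range(max_iter):
        for k in range(N):
            E, G = expectations()
            gprod = np.einsum(ein_g, *G)  # dims x R
            s = np.clip(gprod.sum(axis=-1, keepdims=True), 1e-300, None)
            resp = gprod / s
            weighted = data[..., None] * resp
            axes = tuple(a for a in range(N) if a != k)
            gamma[k] = alpha + weighted.sum(axis=axes)
            colsums = [E[m].sum(axis=0) for m in range(N) if m != k]
            delta[k] = alpha * beta[k] + np.prod(np.stack(colsums), axis=0)[None, :]
            delta[k] = np.broadcast_to(delta[k], gamma[k].shape).copy()
        if update_beta:
            E, _ = expectations()
            for k in range(N):
                beta[k] = 1.0 / max(float(np.sum(E[k])), 1e-300)
        E, G = expectations()
        trace.append(elbo_value(E, G))
        if it >= 1:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                n_done = it + 1
                break

    state = VariationalState(gamma, delta, None, None, np.asarray(trace))
    est = point_estimate(state)
    return FitResult(est, state, spec, _safe_ev(x, est), seed, converged, n_done)
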