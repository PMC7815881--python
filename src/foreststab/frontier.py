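"""Maximum size-density frontier: Bayesian 99th-percentile quantile regression.

The frontier N_max(S̄) = a · S̄^r bounds stems per hectare from above as a
power law in mean tree basal area; self-thinning stands ride along it. It is
estimated in log-log space as a high conditional quantile of log TPH given
log S̄, using the asymmetric-Laplace (AL) working likelihood for quantile
level τ (default 0.99), with the intercept (log a) and slope (r) varying by
forest community type as exchangeable deviations around population-level
fixed effects (a random slope/intercept model).

Priors: intercept normal(7, 1) and slope normal(−0.8025, 0.1) by default —
the Reineke-type expectation that maximum density scales roughly as mean
basal area to the −0.8025 with a maximum near e^7 ≈ 1100 stems/ha at
S̄ = 1 m²; half-normal(1) on the between-type deviation scales, and
half-Cauchy(1) on the AL scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import EnsembleResult, run_ensemble
from .inventory import ValidationError


@dataclass
class FrontierSettings:
    """MCMC and prior configuration for the frontier fit."""

    tau: float = 0.99
    prior_intercept: tuple[float, float] = (7.0, 1.0)
    prior_slope: tuple[float, float] = (-0.8025, 0.1)
    re_sd_scale: float = 1.0  # half-normal scale on between-type deviations
    nwalkers: int = 48
    nsteps: int = 4000
    burn: int | None = None
    n_chains: int = 4
    n_draws: int = 5000
    seed: int = 0


@dataclass
class SizeDensityModel:
    """Fitted frontier: posterior draws for per-type (log a_i, r_i).

    ``draws`` holds ``b0``/``b1`` (fixed effects, shape (n,)), ``u0``/``u1``
    (per-type deviations, shape (n, T)), and the scale parameters. Point
    predictions use posterior medians.
    """

    tau: float
    types: list[int]
    draws: dict[str, np.ndarray]
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._type_index = {t: i for i, t in enumerate(self.types)}
        self._median_cache: dict = {}

    # -- per-type parameter access -----------------------------------------
    def log_a_draws(self, forest_type: int | None = None) -> np.ndarray:
        if forest_type is None or forest_type not in self._type_index:
            return self.draws["b0"]
        return self.draws["b0"] + self.draws["u0"][:, self._type_index[forest_type]]

    def r_draws(self, forest_type: int | None = None) -> np.ndarray:
        if forest_type is None or forest_type not in self._type_index:
            return self.draws["b1"]
        return self.draws["b1"] + self.draws["u1"][:, self._type_index[forest_type]]

    def log_a(self, forest_type: int | None = None) -> float:
        key = ("log_a", forest_type if forest_type in self._type_index else None)
        if key not in self._median_cache:
            self._median_cache[key] = float(np.median(self.log_a_draws(forest_type)))
        return self._median_cache[key]

    def r(self, forest_type: int | None = None) -> float:
        key = ("r", forest_type if forest_type in self._type_index else None)
        if key not in self._median_cache:
            self._median_cache[key] = float(np.median(self.r_draws(forest_type)))
        return self._median_cache[key]

    def is_known_type(self, forest_type: int) -> bool:
        return forest_type in self._type_index

    def summary(self) -> pd.DataFrame:
        rows = [{
            "forest_type": t,
            "log_a_median": self.log_a(t),
            "a_median": math.exp(self.log_a(t)),
            "r_median": self.r(t),
            "log_a_sd": float(np.std(self.log_a_draws(t), ddof=1)),
            "r_sd": float(np.std(self.r_draws(t), ddof=1)),
        } for t in self.types]
        return pd.DataFrame(rows)

    @classmethod
    def from_parameters(
        cls,
        a: float | dict[int, float],
        r: float | dict[int, float],
        tau: float = 0.99,
    ) -> "SizeDensityModel":
        """Point-mass model from known parameters (ground truth, examples).

        Scalars give a single-curve model applied to every type; dicts give
        per-type curves keyed by forest-type code.
        """
        if isinstance(a, dict) != isinstance(r, dict):
            raise ValueError("a and r must both be scalars or both be dicts")
        if isinstance(a, dict):
            types = sorted(a)
            log_a = np.array([math.log(a[t]) for t in types])
            r_arr = np.array([r[t] for t in types])
            b0, b1 = log_a.mean(), r_arr.mean()
            u0, u1 = log_a - b0, r_arr - b1
        else:
            types, b0, b1 = [], math.log(a), float(r)
            u0 = u1 = np.zeros(0)
        one = np.ones(1)
        return cls(
            tau=tau,
            types=types,
            draws={
                "b0": b0 * one, "b1": b1 * one,
                "u0": u0[None, :], "u1": u1[None, :],
                "sigma0": 0 * one, "sigma1": 0 * one, "sigma_al": 0 * one,
            },
        )


def predict_nmax(model: SizeDensityModel, forest_type: int | None, s_bar: float) -> float:
    """Maximum stems/ha for mean tree basal area ``s_bar`` (m²), a_i·s_bar^r_i.

    Unknown forest types fall back to the population-level (fixed effects)
    curve; the model records them in ``model.warnings``.
    """
    if not (s_bar > 0):
        raise ValueError(f"s_bar must be > 0, got {s_bar}")
    if forest_type is not None and not model.is_known_type(forest_type):
        note = f"unknown forest type {forest_type}: population-level curve used"
        if note not in model.warnings:
            model.warnings.append(note)
    return math.exp(model.log_a(forest_type)) * s_bar ** model.r(forest_type)


def fit_frontier(
    stands: pd.DataFrame, settings: FrontierSettings | None = None
) -> SizeDensityModel:
    """Fit the τ-quantile size-density frontier to stand summaries.

    ``stands`` needs columns ``forest_type``, ``tph``, ``mean_tree_ba`` (one
    row per training stand). Non-convergence (split-R̂ > 1.05) does not raise;
    the returned model is flagged with ``converged=False`` and a warning.
    """
    settings = settings or FrontierSettings()
    required = {"forest_type", "tph", "mean_tree_ba"}
    missing = required - set(stands.columns)
    if missing:
        raise ValidationError(f"stand table missing columns {sorted(missing)}")
    stands = stands.dropna(subset=["tph", "mean_tree_ba"])
    if (stands["tph"] <= 0).any() or (stands["mean_tree_ba"] <= 0).any():
        raise ValidationError("all training stands need tph > 0 and mean_tree_ba > 0")

    y = np.log(stands["tph"].to_numpy(dtype=float))
    x = np.log(stands["mean_tree_ba"].to_numpy(dtype=float))
    types = sorted(int(t) for t in stands["forest_type"].unique())
    g = stands["forest_type"].map({t: i for i, t in enumerate(types)}).to_numpy()
    T, n = len(types), y.size
    tau = settings.tau
    m0, s0 = settings.prior_intercept
    m1, s1 = settings.prior_slope
    re_scale = settings.re_sd_scale

    # Reparametrisation for sampling efficiency: the covariate is centred
    # (xc = x − x̄ decorrelates intercept and slope at extreme quantiles) and
    # the type deviations are non-centred (u = σ·ũ avoids the funnel when
    # between-type variation is small). The prior still applies to the
    # intercept at S̄ = 1, i.e. to b0 = c0 − b1·x̄.
    xbar = float(x.mean())
    xc = x - xbar

    # parameter vector: [c0, b1, log_sig0, log_sig1, log_sig_al, ũ0 (T), ũ1 (T)]
    # Hard support bounds keep the sampler finite when the AL scale collapses
    # (data with little or no scatter below the frontier).
    def log_prob(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        ok = (np.abs(theta[:, :2]).max(axis=1) < 1e3) \
            & (theta[:, 2:5] > -25).all(axis=1) & (theta[:, 2:5] < 10).all(axis=1)
        theta = np.where(ok[:, None], theta, 0.0)
        c0, b1 = theta[:, 0], theta[:, 1]
        sig0 = np.exp(theta[:, 2])
        sig1 = np.exp(theta[:, 3])
        sig = np.exp(theta[:, 4])
        u0 = sig0[:, None] * theta[:, 5:5 + T]
        u1 = sig1[:, None] * theta[:, 5 + T:5 + 2 * T]
        mu = (c0[:, None] + u0[:, g]) + (b1[:, None] + u1[:, g]) * xc[None, :]
        res = y[None, :] - mu
        rho = res * (tau - (res < 0))
        ll = n * np.log(tau * (1 - tau) / sig) - rho.sum(axis=1) / sig
        b0 = c0 - b1 * xbar
        lp = (
            -0.5 * ((b0 - m0) / s0) ** 2
            - 0.5 * ((b1 - m1) / s1) ** 2
            # half-normal(re_scale) on sig0/sig1, log-scale Jacobian included
            - 0.5 * (sig0 / re_scale) ** 2 + theta[:, 2]
            - 0.5 * (sig1 / re_scale) ** 2 + theta[:, 3]
            # half-Cauchy(1) on the AL scale
            - np.log1p(sig ** 2) + theta[:, 4]
            - 0.5 * (theta[:, 5:] ** 2).sum(axis=1)
        )
        return np.where(ok, ll + lp, -np.inf)

    init = np.zeros(5 + 2 * T)
    b0_init, b1_init = _init_quantile_line(y, x, tau, fallback=(m0, m1))
    init[0], init[1] = b0_init + b1_init * xbar, b1_init
    init[2] = init[3] = math.log(0.05)
    init[4] = math.log(max(np.std(y) / 10, 1e-3))
    scale = np.full(init.size, 0.05)
    scale[5:] = 0.3

    res: EnsembleResult = run_ensemble(
        log_prob,
        init,
        init_scale=scale,
        nwalkers=max(settings.nwalkers, 2 * init.size + 2),
        nsteps=settings.nsteps,
        burn=settings.burn,
        n_chains=settings.n_chains,
        n_draws=settings.n_draws,
        seed=settings.seed,
    )
    d = res.draws
    sig0_d, sig1_d = np.exp(d[:, 2]), np.exp(d[:, 3])
    u0_c = sig0_d[:, None] * d[:, 5:5 + T]  # centred-covariate intercept devs
    u1_d = sig1_d[:, None] * d[:, 5 + T:5 + 2 * T]
    b1_d = d[:, 1]
    b0_d = d[:, 0] - b1_d * xbar
    draws = {
        "b0": b0_d, "b1": b1_d,
        "sigma0": sig0_d, "sigma1": sig1_d,
        "sigma_al": np.exp(d[:, 4]),
        # per-type deviations on the original (S̄ = 1) intercept scale
        "u0": u0_c - u1_d * xbar, "u1": u1_d,
    }
    names = (["b0", "b1", "log_sigma0", "log_sigma1", "log_sigma_al"]
             + [f"u0[{t}]" for t in types] + [f"u1[{t}]" for t in types])
    rhat = {nm: float(r) for nm, r in zip(names, res.rhat)}
    model = SizeDensityModel(
        tau=tau, types=types, draws=draws, rhat=rhat, converged=res.converged
    )
    if not res.converged:
        worst = max(rhat.values())
        model.warnings.append(f"MCMC non-convergence: max split-Rhat {worst:.3f} > 1.05")
    for t in types:
        if model.r(t) >= 0:
            model.warnings.append(
                f"fit-quality failure: posterior median slope for type {t} is >= 0"
            )
    return model


def _init_quantile_line(y, x, tau, fallback):
    """Pooled frequentist τ-quantile line for walker initialisation."""
    try:
        import statsmodels.api as sm

        fit = sm.QuantReg(y, sm.add_constant(x)).fit(q=tau)
        b0, b1 = float(fit.params[0]), float(fit.params[1])
        if np.isfinite(b0) and np.isfinite(b1):
            return b0, b1
    except Exception:
        pass
    return fallback
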