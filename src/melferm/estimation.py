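"""Parameter estimation from observation tables.

Two routes, mirroring how the model constants were obtained in practice:

- direct regression estimators for yields and maximum specific rates
  (growth rate from an exponential window, yields from substrate/biomass
  changes, q_max from a regression of consumption rates on biomass);
- simulation-based weighted least squares for the affinity and inhibition
  constants, which are not directly observable: a derivative-free local
  search (Nelder-Mead in log-parameter space) with deterministic
  multi-start minimizes the scaled sum of squared deviations between the
  simulated trajectory and the observed species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import analytics
from .params import GrowthParameters, ProductionParameters
from .simulate import ProcessConfig, Trajectory, simulate_process

__all__ = ["FitSpec", "FitResult", "fit_yields_direct", "fit_model",
           "profile_objective", "OBJECTIVE_SPECIES"]

#: species an observation table can constrain, mapped to trajectory columns
OBJECTIVE_SPECIES = {
    "c_x": "c_x_total",
    "c_gluc": "c_gluc",
    "c_nano3": "c_nano3",
    "c_oil": "c_oil",
    "c_fa": "c_fa",
    "c_mel": "c_mel",
}

_GROWTH_FIELDS = {f.name for f in fields(GrowthParameters)}
_PROD_FIELDS = {f.name for f in fields(ProductionParameters)}


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``free`` names the kinetic parameters to estimate; ``bounds`` maps each
    free name to a positive (lo, hi) interval; ``fixed`` overrides default
    parameter values without fitting them.  ``weights`` are per-species
    multipliers on the scaled squared residuals.
    """

    free: tuple[str, ...]
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    species: tuple[str, ...] = ("c_x", "c_gluc", "c_nano3", "c_oil", "c_fa", "c_mel")
    weights: dict = field(default_factory=dict)
    n_starts: int = 5
    max_iter: int = 400
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "free", tuple(self.free))
        known = _GROWTH_FIELDS | _PROD_FIELDS
        for name in list(self.free) + list(self.fixed):
            if name not in known:
                raise ValueError(f"unknown kinetic parameter {name!r}")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi < math.inf):
                raise ValueError(f"bounds for {name!r} must be finite and positive")

    def bounds_for(self, name: str, default: float) -> tuple[float, float]:
        return self.bounds.get(name, (default / 100.0, default * 100.0))


@dataclass
class FitResult:
    """Outcome of a simulation-based fit."""

    estimates: dict
    objective: float
    converged: bool
    n_eval: int
    residual_rmse: dict
    trajectory: Trajectory
    stderr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.objective < 0:
            raise ValueError("objective must be non-negative")


def apply_parameters(config: ProcessConfig, values: dict) -> ProcessConfig:
    """Return a config with the named kinetic parameters replaced."""
    g = {k: v for k, v in values.items() if k in _GROWTH_FIELDS}
    p = {k: v for k, v in values.items() if k in _PROD_FIELDS}
    out = config
    if g:
        out = out.replace(growth=out.growth.replace(**g))
    if p:
        out = out.replace(production=out.production.replace(**p))
    return out


def _default_value(config: ProcessConfig, name: str) -> float:
    if name in _GROWTH_FIELDS:
        return getattr(config.growth, name)
    return getattr(config.production, name)


def _species_scales(obs: pd.DataFrame, species) -> dict:
    scales = {}
    for s in species:
        if s not in obs.columns:
            continue
        vals = obs[s].dropna()
        if len(vals) == 0:
            continue
        scale = float(vals.abs().max())
        scales[s] = scale if scale > 0 else 1.0
    return scales


def residual_vector(config: ProcessConfig, obs: pd.DataFrame,
                    species, scales: dict, weights: dict | None = None) -> np.ndarray:
    """Scaled, weighted residuals of a forward simulation against a table."""
    weights = weights or {}
    traj = simulate_process(config).frame
    t_sim = traj["t_h"].to_numpy()
    parts = []
    for s in species:
        if s not in scales or s not in obs.columns:
            continue
        col = OBJECTIVE_SPECIES[s]
        mask = obs[s].notna()
        t_obs = obs.loc[mask, "t_h"].to_numpy(dtype=float)
        y_obs = obs.loc[mask, s].to_numpy(dtype=float)
        y_sim = np.interp(t_obs, t_sim, traj[col].to_numpy())
        w = math.sqrt(weights.get(s, 1.0))
        parts.append(w * (y_sim - y_obs) / scales[s])
    if not parts:
        raise ValueError("no observed species overlap the simulated species")
    return np.concatenate(parts)


def objective_function(config: ProcessConfig, obs: pd.DataFrame, spec: FitSpec):
    """Build the scalar SSE objective over the spec's free parameters."""
    scales = _species_scales(obs, spec.species)
    base = apply_parameters(config, spec.fixed)

    def fun(values: dict) -> float:
        cfg = apply_parameters(base, values)
        r = residual_vector(cfg, obs, spec.species, scales, spec.weights)
        return float(r @ r)

    return fun, scales


def fit_model(obs: pd.DataFrame, config: ProcessConfig, spec: FitSpec) -> FitResult:
    """Weighted least-squares fit of the named kinetic parameters.

    Nelder-Mead in log-parameter space with ``n_starts`` deterministic
    restarts (seeded perturbations of the default values); the best
    converged solution is returned, or the best-so-far flagged
    unconverged.  With zero free parameters the result is the plain SSE
    of the forward simulation.
    """
    fun, scales = objective_function(config, obs, spec)
    base = apply_parameters(config, spec.fixed)
    n_eval = 0

    def counted(values):
        nonlocal n_eval
        n_eval += 1
        return fun(values)

    if not spec.free:
        obj = counted({})
        traj = simulate_process(base)
        return FitResult({}, obj, True, n_eval,
                         _rmse_by_species(base, obs, spec, scales), traj)

    names = list(spec.free)
    defaults = np.array([_default_value(config, n) for n in names])
    bounds = [spec.bounds_for(n, d) for n, d in zip(names, defaults)]
    log_lo = np.log([b[0] for b in bounds])
    log_hi = np.log([b[1] for b in bounds])

    def scalar_obj(z):
        z = np.clip(z, log_lo, log_hi)
        return counted(dict(zip(names, np.exp(z))))

    rng = np.random.default_rng(spec.seed)
    z0_base = np.log(np.clip(defaults, np.exp(log_lo), np.exp(log_hi)))
    best = None
    for start in range(spec.n_starts):
        z0 = z0_base if start == 0 else np.clip(
            z0_base + rng.normal(0.0, 0.5, size=len(names)), log_lo, log_hi)
        res = optimize.minimize(
            scalar_obj, z0, method="Nelder-Mead",
            options={"maxiter": spec.max_iter, "xatol": 1e-6, "fatol": spec.tol},
        )
        if best is None or res.fun < best.fun:
            best = res
    z_opt = np.clip(best.x, log_lo, log_hi)
    estimates = dict(zip(names, np.exp(z_opt)))
    cfg_opt = apply_parameters(base, estimates)
    traj = simulate_process(cfg_opt)
    stderr = _gauss_newton_stderr(cfg_opt, obs, spec, scales, names, np.exp(z_opt))
    return FitResult(
        estimates=estimates,
        objective=float(best.fun),
        converged=bool(best.success),
        n_eval=n_eval,
        residual_rmse=_rmse_by_species(cfg_opt, obs, spec, scales),
        trajectory=traj,
        stderr=stderr,
    )


def _rmse_by_species(config, obs, spec, scales) -> dict:
    out = {}
    for s in spec.species:
        if s not in scales:
            continue
        r = residual_vector(config, obs, (s,), scales, spec.weights)
        out[s] = float(np.sqrt(np.mean(r**2)) * scales[s])
    return out


def _gauss_newton_stderr(config, obs, spec, scales, names, theta) -> dict:
    """Approximate standard errors from a finite-difference Jacobian."""
    try:
        r0 = residual_vector(config, obs, spec.species, scales, spec.weights)
        J = np.empty((len(r0), len(names)))
        for j, (name, val) in enumerate(zip(names, theta)):
            h = max(1e-6, 1e-4 * abs(val))
            cfg = apply_parameters(config, {name: val + h})
            J[:, j] = (residual_vector(cfg, obs, spec.species, scales,
                                       spec.weights) - r0) / h
        dof = max(len(r0) - len(names), 1)
        sigma2 = float(r0 @ r0) / dof
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        return {n: float(np.sqrt(max(cov[i, i], 0.0)))
                for i, n in enumerate(names)}
    except Exception:  # singular/failed simulations: report no stderr
        return {n: float("nan") for n in names}


def profile_objective(obs: pd.DataFrame, config: ProcessConfig,
                      name: str, grid, spec: FitSpec | None = None) -> np.ndarray:
    """Objective along a one-parameter grid with everything else fixed."""
    spec = spec or FitSpec(free=(name,))
    fun, _ = objective_function(config, obs, spec)
    return np.array([fun({name: float(v)}) for v in grid])


def fit_yields_direct(obs: pd.DataFrame, windows: dict) -> dict:
    """Direct regression estimators for growth yields and maximum rates.

    ``windows`` maps names to (t0, t1) tuples; recognised keys are
    ``"exponential"`` (window of unrestricted exponential growth, used for
    mu_max) and ``"growth"`` (whole growth phase, used for the yields and
    the q_max regressions of consumption rate against biomass).  Requires
    at least three offline samples per window.
    """
    out = {}
    t = obs["t_h"].to_numpy(dtype=float)
    for key in ("exponential", "growth"):
        if key not in windows:
            raise ValueError(f"missing window {key!r}")
        w = windows[key]
        n = int(((t >= w[0]) & (t <= w[1]) & obs["c_x"].notna()).sum())
        if n < 3:
            raise ValueError(f"window {key!r} has {n} biomass samples, need >= 3")

    mask_x = obs["c_x"].notna()
    mu = analytics.specific_growth_rate_obs(
        t[mask_x], obs.loc[mask_x, "c_x"], windows["exponential"])
    out["mu_max"] = mu.value

    for subst, label in (("c_gluc", "gluc"), ("c_nano3", "nano3")):
        mask_s = obs[subst].notna()
        est = analytics.consumption_rate_and_yield(
            t[mask_s], obs.loc[mask_s, subst],
            t[mask_x], obs.loc[mask_x, "c_x"], windows["growth"])
        out[f"Y_x_{label}"] = est["Y_X_S"].value
        # q_max from the regression of consumption rate against biomass
        tw = t[mask_s & ((t >= windows["growth"][0]) & (t <= windows["growth"][1]))]
        cs = obs.loc[mask_s & (t >= windows["growth"][0]) & (t <= windows["growth"][1]),
                     subst].to_numpy(dtype=float)
        cx = np.interp(tw, t[mask_x], obs.loc[mask_x, "c_x"].to_numpy(dtype=float))
        rates = -np.diff(cs) / np.diff(tw)
        cx_mid = 0.5 * (cx[1:] + cx[:-1])
        if len(rates) >= 2 and np.ptp(cx_mid) > 0:
            res = stats.linregress(cx_mid, rates)
            out[f"q_max_{label}"] = res.slope
        else:
            out[f"q_max_{label}"] = float(np.mean(rates / cx_mid))
    return out
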