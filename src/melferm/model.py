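"""Model/Results front-end for fitting the process model to data.

`MELProcessModel` pairs an observation table with a process configuration
and a fit specification; `fit()` returns a `MELProcessResults` carrying the
parameter estimates, their approximate standard errors, residual
diagnostics, the trajectory at the optimum and a printable summary table.
Forward simulation and plotting hang off both objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import FitResult, FitSpec, apply_parameters, fit_model, profile_objective
from .simulate import ProcessConfig, Trajectory, simulate_process

__all__ = ["MELProcessModel", "MELProcessResults"]


class MELProcessModel:
    """Two-phase fermentation model bound to an observation table.

    Parameters
    ----------
    observations : pandas.DataFrame
        Observation table (columns ``t_h`` plus any of ``c_x``, ``c_gluc``,
        ``c_nano3``, ``c_oil``, ``c_fa``, ``c_mel``).
    config : ProcessConfig
        Process configuration (initial state, phase timings, feeds,
        default kinetic parameters).
    free : sequence of str, optional
        Kinetic parameters to estimate; the rest stay at their configured
        values.  With no free parameters, ``fit`` just scores the forward
        simulation.
    """

    def __init__(self, observations: pd.DataFrame, config: ProcessConfig,
                 free=(), bounds=None, fixed=None, weights=None,
                 species=None, n_starts: int = 5):
        if "t_h" not in observations.columns:
            raise ValueError("observation table needs a 't_h' column")
        self.observations = observations.reset_index(drop=True)
        self.config = config
        kwargs = dict(free=tuple(free), bounds=bounds or {}, fixed=fixed or {},
                      weights=weights or {}, n_starts=n_starts)
        if species is not None:
            kwargs["species"] = tuple(species)
        self.spec = FitSpec(**kwargs)

    @classmethod
    def from_csv(cls, path, config: ProcessConfig, **kwargs) -> "MELProcessModel":
        from .io import read_observations
        return cls(read_observations(path), config, **kwargs)

    def fit(self, seed: int = 0) -> "MELProcessResults":
        """Estimate the free parameters; deterministic for a given seed."""
        spec = FitSpec(**{**self.spec.__dict__, "seed": seed,
                          "free": self.spec.free})
        raw = fit_model(self.observations, self.config, spec)
        return MELProcessResults(self, raw)

    def simulate(self, **param_overrides) -> Trajectory:
        """Forward-simulate the configured process, optionally overriding parameters."""
        return simulate_process(apply_parameters(self.config, param_overrides))

    def profile(self, name: str, grid) -> np.ndarray:
        """Objective values along a one-parameter grid (identifiability check)."""
        return profile_objective(self.observations, self.config, name, grid,
                                 spec=self.spec)


class MELProcessResults:
    """Fit results: estimates, uncertainties, diagnostics, summary."""

    def __init__(self, model: MELProcessModel, raw: FitResult):
        self.model = model
        self._raw = raw
        self.params = pd.Series(raw.estimates, dtype=float)
        self.bse = pd.Series(raw.stderr, dtype=float).reindex(self.params.index)
        self.objective = raw.objective
        self.converged = raw.converged
        self.n_eval = raw.n_eval
        self.residual_rmse = pd.Series(raw.residual_rmse, dtype=float)
        self.trajectory = raw.trajectory

    @property
    def config_at_optimum(self) -> ProcessConfig:
        return apply_parameters(
            apply_parameters(self.model.config, self.model.spec.fixed),
            dict(self.params))

    def simulate(self) -> Trajectory:
        """Forward simulation at the fitted parameter values."""
        return simulate_process(self.config_at_optimum)

    def summary(self) -> str:
        """Printable fit summary (estimates, stderr, residual RMSE)."""
        lines = []
        lines.append("MEL fermentation process model fit")
        lines.append("=" * 54)
        lines.append(f"process:      {self.model.config.name}")
        lines.append(f"objective:    {self.objective:.6g}")
        lines.append(f"converged:    {self.converged}")
        lines.append(f"evaluations:  {self.n_eval}")
        if len(self.params):
            lines.append("-" * 54)
            lines.append(f"{'parameter':<16}{'estimate':>12}{'std err':>12}")
            for name, value in self.params.items():
                se = self.bse.get(name, float('nan'))
                lines.append(f"{name:<16}{value:>12.5g}{se:>12.3g}")
        if len(self.residual_rmse):
            lines.append("-" * 54)
            lines.append("residual RMSE by species (original units):")
            for name, value in self.residual_rmse.items():
                lines.append(f"  {name:<10}{value:>10.4g}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot(self, species=("c_x", "c_gluc", "c_nano3", "c_oil", "c_fa", "c_mel"),
             ax=None):
        """Overlay observations and the fitted trajectory (needs matplotlib)."""
        import matplotlib.pyplot as plt

        from .estimation import OBJECTIVE_SPECIES
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        traj = self.trajectory.frame
        obs = self.model.observations
        for s in species:
            if s not in obs.columns:
                continue
            col = OBJECTIVE_SPECIES[s]
            line, = ax.plot(traj["t_h"], traj[col], label=s)
            m = obs[s].notna()
            ax.plot(obs.loc[m, "t_h"], obs.loc[m, s], "o", ms=3,
                    color=line.get_color())
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (g/L)")
        ax.legend(fontsize=8)
        return ax
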