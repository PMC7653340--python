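"""Statsmodels-style front end to the ensemble TI estimator.

:class:`ThermodynamicIntegration` wraps an :class:`~ties_kit.analysis.EnsembleGrid`
(or a tidy DataFrame of samples) and ``fit()`` returns a
:class:`TIEstimatorResults` carrying the estimate, its uncertainty, the
per-window diagnostics table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .analysis import (
    DvdlSeries,
    EnsembleGrid,
    FreeEnergyResult,
    integrate_stochastic,
    lambda_stats,
)
from .schedule import LambdaSchedule

__all__ = ["ThermodynamicIntegration", "TIEstimatorResults"]


class ThermodynamicIntegration:
    """Estimate ΔG_alch from an ensemble of per-λ ∂V/∂λ series.

    Parameters
    ----------
    grid
        The replicas × λ-windows ensemble for one environment.
    equilibration_discard
        Fraction of each series dropped from the front before averaging
        (default 0: callers are expected to pass production-only data).
    """

    def __init__(self, grid: EnsembleGrid, equilibration_discard: float = 0.0):
        if not 0.0 <= equilibration_discard < 1.0:
            raise ValueError("equilibration_discard must lie in [0, 1)")
        self.grid = grid
        self.equilibration_discard = equilibration_discard

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        environment: str = "aqueous",
        schedule: LambdaSchedule | None = None,
        sample_interval: float = 1.0,
        equilibration_discard: float = 0.0,
    ) -> "ThermodynamicIntegration":
        """Build the model from a tidy frame with columns
        ``lambda``, ``replica``, ``dvdl`` (ordered within each group)."""
        required = {"lambda", "replica", "dvdl"}
        if not required <= set(data.columns):
            raise ValueError(f"data needs columns {sorted(required)}")
        series = [
            DvdlSeries(
                lambda_value=float(lam),
                replica_id=str(rep),
                samples=grp["dvdl"].to_numpy(),
                sample_interval=sample_interval,
            )
            for (lam, rep), grp in data.groupby(["lambda", "replica"], sort=True)
        ]
        if schedule is None:
            lams = sorted(data["lambda"].unique())
            schedule = LambdaSchedule(values=tuple(lams))
        grid = EnsembleGrid(environment=environment, schedule=schedule, series=series)
        return cls(grid, equilibration_discard=equilibration_discard)

    def window_stats(self):
        """Per-window :class:`~ties_kit.analysis.LambdaStats`, in λ order."""
        return [
            lambda_stats(self.grid, lam, self.equilibration_discard)
            for lam in self.grid.schedule
        ]

    def fit(
        self,
        method: str = "trapezoid_propagated",
        n_boot: int = 1000,
        seed: int | None = None,
    ) -> "TIEstimatorResults":
        """Run the stochastic integration and return the results object."""
        stats = self.window_stats()
        fe = integrate_stochastic(
            stats,
            self.grid.schedule,
            method=method,
            n_boot=n_boot,
            seed=seed,
            environment=self.grid.environment,
        )
        table = pd.DataFrame(
            {
                "lambda": [s.lambda_value for s in stats],
                "mean_dvdl": [s.mean for s in stats],
                "stderr": [s.stderr for s in stats],
                "n_replicas": [s.n_replicas for s in stats],
            }
        )
        return TIEstimatorResults(
            delta_g=fe.delta_g,
            sigma=fe.sigma,
            environment=fe.environment,
            method=fe.method,
            model=self,
            lambda_table=table,
        )


@dataclass
class TIEstimatorResults(FreeEnergyResult):
    """Fitted ΔG_alch with diagnostics.

    Subclasses :class:`~ties_kit.analysis.FreeEnergyResult`, so it plugs
    directly into :func:`~ties_kit.analysis.ddg_cycle`.
    """

    model: ThermodynamicIntegration | None = None
    lambda_table: pd.DataFrame | None = None

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Normal-theory (1 − alpha) confidence interval for ΔG."""
        z = float(sps.norm.ppf(1.0 - alpha / 2.0))
        return (self.delta_g - z * self.sigma, self.delta_g + z * self.sigma)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        head = [
            "Ensemble thermodynamic integration",
            "==================================",
            f"environment   : {self.environment}",
            f"method        : {self.method}",
            f"dG_alch       : {self.delta_g:+.4f} kcal/mol",
            f"sigma (1 s.d.): {self.sigma:.4f} kcal/mol",
            f"95% CI        : [{lo:+.4f}, {hi:+.4f}] kcal/mol",
            "",
            "per-window <dV/dlambda> (kcal/mol)",
            "----------------------------------",
        ]
        body = self.lambda_table.to_string(
            index=False, float_format=lambda v: f"{v:9.4f}"
        ) if self.lambda_table is not None else "(no diagnostics)"
        return "\n".join(head) + "\n" + body
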