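"""Synthetic ∂V/∂λ ensembles and benchmarks with known ground truth.

Real ensemble-TI data are replica time series of ∂V/∂λ whose window means
drift smoothly with λ and whose samples are autocorrelated within a replica
but independent across replicas.  The generator emulates exactly that
structure: the window mean follows a polynomial m(λ) (so the true
ΔG = ∫₀¹ m dλ is available in closed form), and each replica series is a
stationary Gaussian AR(1) process around m(λ) with a chosen marginal
standard deviation.  It reproduces none of the physics — no force field,
no protein, no water — only the statistical shape the estimator has to
cope with, which is what makes estimator calibration testable.

Defaults mirror the production protocol: 5 replicas per window, the
13-window λ grid, 400 samples per replica (a 4 ns production sampled every
10 ps), a per-sample spread of 2 kcal/mol and mild autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .analysis import DvdlSeries, EnsembleGrid, RelativeBindingResult, write_dvdl_tsv
from .schedule import LambdaSchedule, default_schedule

__all__ = [
    "SyntheticSpec",
    "true_delta_g",
    "generate_ensemble",
    "generate_benchmark",
    "write_ensemble",
]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic ensemble with known true ΔG.

    ``mean_coefficients`` are ascending polynomial coefficients of m(λ) in
    kcal/mol; ``noise_sd`` is the stationary per-sample standard deviation;
    ``ar1_coefficient`` the lag-1 autocorrelation within a replica.
    """

    mean_coefficients: tuple[float, ...] = (2.0, -1.0, 3.0, -2.0)
    noise_sd: float = 2.0
    ar1_coefficient: float = 0.5
    n_replicas: int = 5
    samples_per_replica: int = 400
    schedule: LambdaSchedule = field(default_factory=default_schedule)
    sample_interval: float = 10.0  # ps
    environment: str = "aqueous"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.n_replicas < 1 or self.samples_per_replica < 1:
            raise ValueError("need at least one replica and one sample")

    def mean_at(self, lam: float) -> float:
        return float(
            sum(c * lam**k for k, c in enumerate(self.mean_coefficients))
        )


def true_delta_g(spec: SyntheticSpec) -> float:
    """Closed-form ∫₀¹ m(λ) dλ = Σ cₖ / (k + 1)."""
    return float(sum(c / (k + 1) for k, c in enumerate(spec.mean_coefficients)))


def _ar1_series(
    rng: np.random.Generator, n_series: int, n_samples: int, sd: float, phi: float
) -> np.ndarray:
    """Stationary AR(1) rows: marginal sd ``sd``, lag-1 correlation ``phi``."""
    if sd == 0.0:
        return np.zeros((n_series, n_samples))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=(n_series, n_samples))
    x0 = rng.normal(0.0, sd, size=(n_series, 1))
    # y[t] = phi*y[t-1] + eps[t], initialized from the stationary marginal
    y, _ = lfilter([1.0], [1.0, -phi], eps, axis=1, zi=phi * x0)
    return y


def generate_ensemble(spec: SyntheticSpec) -> EnsembleGrid:
    """Draw a full replicas × λ-windows ensemble, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    series: list[DvdlSeries] = []
    for lam in spec.schedule:
        noise = _ar1_series(
            rng,
            spec.n_replicas,
            spec.samples_per_replica,
            spec.noise_sd,
            spec.ar1_coefficient,
        )
        m = spec.mean_at(lam)
        for rep in range(spec.n_replicas):
            series.append(
                DvdlSeries(
                    lambda_value=lam,
                    replica_id=f"rep{rep + 1:02d}",
                    samples=m + noise[rep],
                    sample_interval=spec.sample_interval,
                )
            )
    return EnsembleGrid(
        environment=spec.environment, schedule=spec.schedule, series=series
    )


def generate_benchmark(
    n_pairs: int = 17,
    ddg_range: tuple[float, float] = (-3.0, 3.0),
    calc_noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[RelativeBindingResult], "pd.DataFrame"]:
    """A multi-pair benchmark with known 'experimental' values.

    The experimental ΔΔG of each pair is drawn uniformly over ``ddg_range``
    (kcal/mol — a few kcal/mol is the span of a typical congeneric series);
    the calculated value is the experimental one plus Gaussian noise of sd
    ``calc_noise_sd``.  Returns the calculated results and the experimental
    table they are to be benchmarked against.
    """
    import pandas as pd

    if n_pairs < 2:
        raise ValueError("a benchmark needs at least two pairs")
    rng = np.random.default_rng(seed)
    lo, hi = ddg_range
    expt_vals = rng.uniform(lo, hi, size=n_pairs)
    calc_vals = expt_vals + rng.normal(0.0, calc_noise_sd, size=n_pairs)
    labels = [f"pair{k + 1:02d}" for k in range(n_pairs)]
    calc = [
        RelativeBindingResult(ddg=float(c), sigma=calc_noise_sd, pair_label=lbl)
        for c, lbl in zip(calc_vals, labels)
    ]
    expt = pd.DataFrame({"pair_label": labels, "ddg_expt": expt_vals})
    return calc, expt


def write_ensemble(grid: EnsembleGrid, outdir: str | Path) -> list[Path]:
    """Write every series of a grid as TSV files (one per replica/window)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in grid.series:
        p = outdir / f"l{s.lambda_value:.3f}_{s.replica_id}.tsv"
        write_dvdl_tsv(s, p)
        paths.append(p)
    return paths
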