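"""Ensemble TI analysis: per-window statistics, stochastic integration,
thermodynamic-cycle ΔΔG and benchmark statistics.

The estimator treats ΔG = ∫₀¹ ⟨∂V/∂λ⟩ dλ as a stochastic integral: the
integrand at each λ window is estimated by the mean of independent replica
time-averages, the integral by trapezoidal quadrature over the λ grid, and
its 1-σ uncertainty either by propagating the inter-replica standard errors
through the quadrature weights or by a seeded bootstrap over replica means.
Replica means — not pooled samples — are the unit of error estimation:
replicas differ only in their initial velocities and are therefore
independent by construction, so within-series autocorrelation cannot bias
the standard error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, SchemaError
from .schedule import LambdaSchedule

__all__ = [
    "DvdlSeries",
    "EnsembleGrid",
    "LambdaStats",
    "FreeEnergyResult",
    "RelativeBindingResult",
    "BenchmarkReport",
    "read_dvdl_tsv",
    "write_dvdl_tsv",
    "read_namd_ti",
    "lambda_stats",
    "trapezoid_weights",
    "integrate_stochastic",
    "ddg_cycle",
    "benchmark",
    "plot_benchmark",
]

logger = logging.getLogger(__name__)

BOUND = "bound"
AQUEOUS = "aqueous"
_ENVIRONMENTS = (BOUND, AQUEOUS)

_LAM_TOL = 1e-9  # two λ values closer than this refer to the same window


@dataclass
class DvdlSeries:
    """One replica's ∂V/∂λ time series at one λ window (kcal/mol)."""

    lambda_value: float
    replica_id: str
    samples: np.ndarray
    sample_interval: float  # ps

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("a dV/dλ series must be non-empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("a dV/dλ series must be finite throughout")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive (ps)")
        self.lambda_value = float(self.lambda_value)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class EnsembleGrid:
    """Replicas × λ-windows of ∂V/∂λ series for one environment."""

    environment: str
    schedule: LambdaSchedule
    series: list[DvdlSeries]

    def __post_init__(self) -> None:
        if self.environment not in _ENVIRONMENTS:
            raise ValueError(f"environment must be one of {_ENVIRONMENTS}")
        missing = [lam for lam in self.schedule if not self._at(lam)]
        if missing:
            raise CoverageError(
                f"no replicas at lambda value(s) {missing} in {self.environment} grid"
            )

    def _at(self, lam: float) -> list[DvdlSeries]:
        return [s for s in self.series if abs(s.lambda_value - lam) <= _LAM_TOL]

    def replicas_at(self, lam: float) -> list[DvdlSeries]:
        out = self._at(lam)
        if not out:
            raise CoverageError(f"no series at lambda={lam}")
        return out

    @property
    def replica_counts(self) -> dict[float, int]:
        return {lam: len(self._at(lam)) for lam in self.schedule}


@dataclass
class LambdaStats:
    """Ensemble statistics of ⟨∂V/∂λ⟩ at one window.

    ``stderr`` is the standard error of the mean of the replica means; with
    a single replica no ensemble error estimate exists and ``stderr`` is
    reported as 0 with ``no_ensemble_error`` set.
    """

    lambda_value: float
    mean: float
    stderr: float
    n_replicas: int
    no_ensemble_error: bool = False
    replica_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


@dataclass
class FreeEnergyResult:
    """ΔG of one alchemical leg with its 1-σ uncertainty (kcal/mol)."""

    delta_g: float
    sigma: float
    environment: str | None = None
    method: str = "trapezoid_propagated"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class RelativeBindingResult:
    """ΔΔG of one ligand pair via the thermodynamic cycle (kcal/mol)."""

    ddg: float
    sigma: float
    pair_label: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# dV/dλ I/O


def write_dvdl_tsv(series: DvdlSeries, path: str | Path) -> None:
    """Write one series in the toolkit's TSV dialect."""
    lines = [
        f"#lambda={series.lambda_value!r}",
        f"#replica={series.replica_id}",
        f"#interval_ps={float(series.sample_interval)!r}",
        "step\tdvdl",
    ]
    lines += [f"{k}\t{float(v)!r}" for k, v in enumerate(series.samples)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dvdl_tsv(path: str | Path) -> DvdlSeries:
    """Read one series from the TSV dialect.

    Mandatory metadata lines: ``#lambda=``, ``#replica=``, ``#interval_ps=``;
    then a ``step<TAB>dvdl`` header and numeric rows.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    samples: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = val.strip()
            continue
        if line.startswith("step"):
            continue
        cols = line.split("\t")
        try:
            samples.append(float(cols[1]))
        except (IndexError, ValueError) as exc:
            raise SchemaError(
                f"{path}: line {lineno}: expected 'step<TAB>dvdl', got {line!r}"
            ) from exc
    for key in ("lambda", "replica", "interval_ps"):
        if key not in meta:
            raise SchemaError(f"{path}: missing mandatory metadata line '#{key}='")
    return DvdlSeries(
        lambda_value=float(meta["lambda"]),
        replica_id=meta["replica"],
        samples=np.asarray(samples),
        sample_interval=float(meta["interval_ps"]),
    )


def read_namd_ti(path: str | Path, sample_interval: float = 1.0) -> list[DvdlSeries]:
    """Parse a NAMD-style TI output file into one series per λ block.

    The dialect: ``#NEW TI WINDOW: LAMBDA <x>`` opens a block; data lines
    are tagged ``TI:`` and carry ``step, elec dV/dλ, elec avg, vdW dV/dλ,
    vdW avg``.  Electrostatic and van der Waals components are summed into a
    total ∂V/∂λ per record.  A truncated trailing record is skipped with a
    logged warning.
    """
    path = Path(path)
    blocks: list[tuple[float, list[float]]] = []
    current: list[float] | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#NEW TI WINDOW:"):
            try:
                lam = float(line.rsplit("LAMBDA", 1)[1])
            except (IndexError, ValueError) as exc:
                raise SchemaError(f"{path}: line {lineno}: bad window header {line!r}") from exc
            current = []
            blocks.append((lam, current))
        elif line.startswith("TI:"):
            if current is None:
                raise SchemaError(
                    f"{path}: line {lineno}: TI record before any window header"
                )
            tok = line.split()
            # full record: TI: step, elec dV/dλ, elec avg, vdW dV/dλ, vdW avg
            try:
                if len(tok) < 6:
                    raise ValueError("short record")
                current.append(float(tok[2]) + float(tok[4]))  # elec + vdW
            except (IndexError, ValueError):
                logger.warning("%s: line %d: skipping truncated TI record %r", path, lineno, line)
    blocks = [(lam, vals) for lam, vals in blocks if vals]
    if not blocks:
        raise SchemaError(f"{path}: no TI records found")
    return [
        DvdlSeries(
            lambda_value=lam,
            replica_id=f"{path.stem}_w{k}",
            samples=np.asarray(vals),
            sample_interval=sample_interval,
        )
        for k, (lam, vals) in enumerate(blocks)
    ]


# ---------------------------------------------------------------------------
# estimation


def lambda_stats(
    grid: EnsembleGrid, lam: float, equilibration_discard: float = 0.0
) -> LambdaStats:
    """Ensemble mean and standard error of ⟨∂V/∂λ⟩ at one window.

    Each replica is reduced to the time-mean of its post-discard samples;
    the window mean is the average of replica means and the standard error
    their standard deviation over √n.
    """
    if not 0.0 <= equilibration_discard < 1.0:
        raise ValueError("equilibration_discard must lie in [0, 1)")
    reps = grid.replicas_at(lam)
    means = []
    for s in reps:
        start = int(math.floor(equilibration_discard * s.n_samples))
        means.append(float(np.mean(s.samples[start:])))
    means = np.asarray(means)
    n = means.size
    if n == 1:
        return LambdaStats(
            lambda_value=float(lam),
            mean=float(means[0]),
            stderr=0.0,
            n_replicas=1,
            no_ensemble_error=True,
            replica_means=means,
        )
    return LambdaStats(
        lambda_value=float(lam),
        mean=float(np.mean(means)),
        stderr=float(np.std(means, ddof=1) / math.sqrt(n)),
        n_replicas=n,
        replica_means=means,
    )


def trapezoid_weights(lambdas: Sequence[float]) -> np.ndarray:
    """Quadrature weights w such that ∫ f dλ ≈ Σ wᵢ f(λᵢ) (trapezoid rule)."""
    lam = np.asarray(lambdas, dtype=float)
    w = np.zeros_like(lam)
    d = np.diff(lam)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def integrate_stochastic(
    stats: Iterable[LambdaStats],
    schedule: LambdaSchedule,
    method: str = "trapezoid_propagated",
    n_boot: int = 1000,
    seed: int | None = None,
    environment: str | None = None,
) -> FreeEnergyResult:
    """ΔG and its 1-σ uncertainty from per-window ensemble statistics.

    The integral is trapezoidal quadrature of the window means over λ.  With
    ``method="trapezoid_propagated"`` the variance is Σ wᵢ² sᵢ² for weights
    w and window standard errors s; with ``method="bootstrap"`` the replica
    means at each window are resampled with replacement ``n_boot`` times
    (seeded) and the standard deviation of the resampled integrals is
    reported, with the per-window deviations rescaled by √(n/(n−1)) to
    undo the small-ensemble bias of the plug-in bootstrap.
    """
    if method not in ("trapezoid_propagated", "bootstrap"):
        raise ValueError(f"unknown method {method!r}")
    entries = sorted(stats, key=lambda s: s.lambda_value)
    lams = [s.lambda_value for s in entries]
    for a, b in zip(lams, lams[1:]):
        if abs(a - b) <= _LAM_TOL:
            raise ValueError(f"duplicate lambda entry at {a}")
    want = list(schedule)
    if len(entries) != len(want) or any(
        abs(a - b) > _LAM_TOL for a, b in zip(lams, want)
    ):
        missing = [lam for lam in want if all(abs(lam - a) > _LAM_TOL for a in lams)]
        raise CoverageError(
            f"stats do not cover the schedule; missing lambda value(s) {missing}"
        )
    w = trapezoid_weights(want)
    means = np.asarray([s.mean for s in entries])
    delta_g = float(w @ means)
    if method == "trapezoid_propagated":
        stderrs = np.asarray([s.stderr for s in entries])
        sigma = float(np.sqrt(np.sum(w**2 * stderrs**2)))
    else:
        for s in entries:
            if s.replica_means is None:
                raise ValueError("bootstrap needs replica means on every LambdaStats")
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        reps = [np.asarray(s.replica_means) for s in entries]
        # plug-in bootstrap of a mean of n replicas underestimates its sd by
        # sqrt((n-1)/n); rescale the per-window deviations to remove the bias
        scale = np.array(
            [math.sqrt(r.size / (r.size - 1)) if r.size > 1 else 1.0 for r in reps]
        )
        for b in range(n_boot):
            resampled = np.array(
                [float(np.mean(rng.choice(r, size=r.size, replace=True))) for r in reps]
            )
            draws[b] = w @ (means + scale * (resampled - means))
        sigma = float(np.std(draws, ddof=1))
    return FreeEnergyResult(
        delta_g=delta_g, sigma=sigma, environment=environment, method=method
    )


def ddg_cycle(aq: FreeEnergyResult, bound: FreeEnergyResult, pair_label: str = "") -> RelativeBindingResult:
    """Close the thermodynamic cycle: ΔΔG = ΔG_alch(aqueous) − ΔG_alch(bound).

    Uncertainties of the two legs are independent and combine in quadrature.
    """
    if aq.environment != AQUEOUS:
        raise ValueError(f"first argument must be the aqueous leg, got {aq.environment!r}")
    if bound.environment != BOUND:
        raise ValueError(f"second argument must be the bound leg, got {bound.environment!r}")
    return RelativeBindingResult(
        ddg=aq.delta_g - bound.delta_g,
        sigma=math.hypot(aq.sigma, bound.sigma),
        pair_label=pair_label,
    )


# ---------------------------------------------------------------------------
# benchmark statistics


@dataclass
class BenchmarkReport:
    """Agreement statistics between calculated and experimental ΔΔG."""

    pairs: pd.DataFrame  # pair_label, ddg_calc, ddg_expt, sigma
    pearson_r: float
    spearman_rs: float
    mse: float  # kcal²/mol²
    rmse: float  # kcal/mol
    fit_slope: float
    fit_intercept: float
    mse_units: str = "kcal^2 mol^-2"

    def summary(self) -> str:
        n = len(self.pairs)
        return "\n".join(
            [
                f"Benchmark over {n} ligand pairs",
                f"  Pearson r   : {self.pearson_r:7.4f}",
                f"  Spearman rs : {self.spearman_rs:7.4f}",
                f"  MSE         : {self.mse:7.4f} {self.mse_units}",
                f"  RMSE        : {self.rmse:7.4f} kcal/mol",
                f"  best fit    : ddg_calc = {self.fit_slope:.4f} * ddg_expt "
                f"{self.fit_intercept:+.4f}",
            ]
        )


def benchmark(
    calc: Sequence[RelativeBindingResult],
    expt: pd.DataFrame | Sequence[tuple[str, float]],
    mse_units: str = "kcal^2 mol^-2",
) -> BenchmarkReport:
    """Compare calculated ΔΔG against an experimental table.

    ``expt`` is a DataFrame with columns ``pair_label`` and ``ddg_expt`` (or
    an iterable of such tuples).  Labels must match one-to-one; orphans on
    either side are an error.  ``mse_units`` only relabels the printed MSE
    units (some reports quote MSE in kcal/mol); the number itself is always
    the mean squared residual.
    """
    from scipy import stats as sps

    if not isinstance(expt, pd.DataFrame):
        expt = pd.DataFrame(expt, columns=["pair_label", "ddg_expt"])
    calc_map = {c.pair_label: c for c in calc}
    if len(calc_map) != len(calc):
        raise ValueError("duplicate pair labels in calculated results")
    expt_labels = list(expt["pair_label"])
    if len(set(expt_labels)) != len(expt_labels):
        raise ValueError("duplicate pair labels in experimental table")
    orphans = sorted(set(calc_map) ^ set(expt_labels))
    if orphans:
        raise ValueError(f"unmatched pair label(s): {orphans}")
    rows = [
        (lbl, calc_map[lbl].ddg, float(e), calc_map[lbl].sigma)
        for lbl, e in zip(expt["pair_label"], expt["ddg_expt"])
    ]
    df = pd.DataFrame(rows, columns=["pair_label", "ddg_calc", "ddg_expt", "sigma"])
    x = df["ddg_expt"].to_numpy()
    y = df["ddg_calc"].to_numpy()
    resid = y - x
    mse = float(np.mean(resid**2))
    pear = float(sps.pearsonr(x, y).statistic)
    spear = float(sps.spearmanr(x, y).statistic)
    fit = sps.linregress(x, y)
    return BenchmarkReport(
        pairs=df,
        pearson_r=pear,
        spearman_rs=spear,
        mse=mse,
        rmse=float(math.sqrt(mse)),
        fit_slope=float(fit.slope),
        fit_intercept=float(fit.intercept),
        mse_units=mse_units,
    )


def plot_benchmark(report: BenchmarkReport, path: str | Path | None = None):
    """Scatter of calculated vs experimental ΔΔG with error bars, the line
    of best fit and the identity line.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.pairs
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.errorbar(
        df["ddg_expt"], df["ddg_calc"], yerr=df["sigma"], fmt="o", color="k",
        ecolor="gray", capsize=2, label="ligand pairs",
    )
    lo = float(min(df["ddg_expt"].min(), df["ddg_calc"].min())) - 0.5
    hi = float(max(df["ddg_expt"].max(), df["ddg_calc"].max())) + 0.5
    xs = np.linspace(lo, hi, 2)
    ax.plot(xs, xs, "--", color="gray", lw=1, label="identity")
    ax.plot(
        xs, report.fit_slope * xs + report.fit_intercept, color="tab:blue",
        lw=1.5, label="best fit",
    )
    ax.set_xlabel(r"$\Delta\Delta G_{\mathrm{expt}}$ (kcal/mol)")
    ax.set_ylabel(r"$\Delta\Delta G_{\mathrm{calc}}$ (kcal/mol)")
    ax.set_title(f"r = {report.pearson_r:.2f}, RMSE = {report.rmse:.2f} kcal/mol")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
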