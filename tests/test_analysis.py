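"""TI estimation: per-window statistics, stochastic integration, the
thermodynamic cycle and benchmark statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from ties_kit import (
    DvdlSeries,
    EnsembleGrid,
    FreeEnergyResult,
    LambdaSchedule,
    LambdaStats,
    RelativeBindingResult,
    ThermodynamicIntegration,
    benchmark,
    ddg_cycle,
    default_schedule,
    integrate_stochastic,
    lambda_stats,
    read_dvdl_tsv,
    read_namd_ti,
    trapezoid_weights,
    write_dvdl_tsv,
)
from ties_kit.errors import CoverageError, SchemaError


def grid_from_replica_means(means_by_lambda, n_samples=10, environment="aqueous"):
    """Grid whose replica time series are constant at given replica means."""
    lams = tuple(sorted(means_by_lambda))
    series = [
        DvdlSeries(lam, f"rep{k}", np.full(n_samples, m), 1.0)
        for lam in lams
        for k, m in enumerate(means_by_lambda[lam])
    ]
    return EnsembleGrid(
        environment=environment, schedule=LambdaSchedule(values=lams), series=series
    )


class TestDvdlTsv:
    def test_small_file_mean(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(
            "#lambda=0.5\n#replica=r1\n#interval_ps=10\nstep\tdvdl\n"
            "0\t1.0\n1\t2.0\n2\t3.0\n"
        )
        s = read_dvdl_tsv(p)
        assert s.lambda_value == 0.5
        assert float(np.mean(s.samples)) == pytest.approx(2.0)

    def test_missing_lambda_metadata(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("#replica=r1\n#interval_ps=10\nstep\tdvdl\n0\t1.0\n")
        with pytest.raises(SchemaError, match="#lambda="):
            read_dvdl_tsv(p)

    def test_non_numeric_sample_names_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("#lambda=0.5\n#replica=r1\n#interval_ps=10\nstep\tdvdl\n0\toops\n")
        with pytest.raises(SchemaError, match="line 5"):
            read_dvdl_tsv(p)

    def test_round_trip(self, tmp_path):
        s = DvdlSeries(0.3, "rep7", np.random.default_rng(0).normal(size=50), 2.0)
        p = tmp_path / "s.tsv"
        write_dvdl_tsv(s, p)
        back = read_dvdl_tsv(p)
        assert back.lambda_value == s.lambda_value
        assert back.replica_id == s.replica_id
        assert back.sample_interval == s.sample_interval
        np.testing.assert_array_equal(back.samples, s.samples)


class TestNamdTi:
    def _write(self, path, blocks, truncate=False):
        lines = []
        for lam, rows in blocks:
            lines.append(f"#NEW TI WINDOW: LAMBDA {lam}")
            for step, elec, vdw in rows:
                lines.append(f"TI:  {step}  {elec}  {elec}  {vdw}  {vdw}")
        if truncate:
            lines.append("TI:  999  1.5")
        path.write_text("\n".join(lines) + "\n")

    def test_two_window_fixture(self, tmp_path):
        p = tmp_path / "out.alch"
        self._write(
            p,
            [
                (0.0, [(10, 1.0, 0.5), (20, 2.0, 0.5)]),
                (0.5, [(10, -1.0, 1.0), (20, -3.0, 1.0)]),
            ],
        )
        series = read_namd_ti(p)
        assert [s.lambda_value for s in series] == [0.0, 0.5]
        # elec + vdW summed per record
        assert float(np.mean(series[0].samples)) == pytest.approx(2.0)
        assert float(np.mean(series[1].samples)) == pytest.approx(-1.0)

    def test_truncated_final_record_is_skipped(self, tmp_path, caplog):
        p = tmp_path / "out.alch"
        self._write(p, [(0.0, [(10, 1.0, 0.0), (20, 3.0, 0.0)])], truncate=True)
        with caplog.at_level("WARNING"):
            series = read_namd_ti(p)
        assert series[0].n_samples == 2
        assert "truncated" in caplog.text

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "out.alch"
        p.write_text("")
        with pytest.raises(SchemaError, match="no TI records"):
            read_namd_ti(p)


class TestLambdaStats:
    def test_hand_arithmetic_five_replicas(self):
        grid = grid_from_replica_means({0.0: [1, 2, 3, 4, 5], 1.0: [1, 2, 3, 4, 5]})
        st = lambda_stats(grid, 0.0)
        assert st.mean == pytest.approx(3.0)
        # sd(1..5) = sqrt(2.5); stderr = sqrt(2.5)/sqrt(5) = 0.70711
        assert st.stderr == pytest.approx(math.sqrt(2.5) / math.sqrt(5), abs=1e-10)
        assert st.stderr == pytest.approx(0.7071, abs=1e-4)
        assert st.n_replicas == 5

    def test_identical_replicas_zero_stderr(self):
        grid = grid_from_replica_means({0.0: [2, 2, 2], 1.0: [2, 2, 2]})
        assert lambda_stats(grid, 0.0).stderr == 0.0

    def test_single_replica_flagged(self):
        grid = grid_from_replica_means({0.0: [2.0], 1.0: [2.0]})
        st = lambda_stats(grid, 0.0)
        assert st.stderr == 0.0 and st.no_ensemble_error

    def test_equilibration_discard_windows_the_series(self):
        samples = np.r_[np.zeros(5), np.ones(5)]  # mean over last 5 is 1
        grid = EnsembleGrid(
            environment="aqueous",
            schedule=LambdaSchedule(values=(0.0, 1.0)),
            series=[
                DvdlSeries(0.0, "r1", samples, 1.0),
                DvdlSeries(1.0, "r1", samples, 1.0),
            ],
        )
        assert lambda_stats(grid, 0.0, equilibration_discard=0.5).mean == pytest.approx(1.0)
        assert lambda_stats(grid, 0.0).mean == pytest.approx(0.5)


class TestIntegrateStochastic:
    def test_default_grid_trapezoid_weights_hand_computed(self):
        w = trapezoid_weights(default_schedule().values)
        expected = [0.025, 0.05, 0.075, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.075, 0.05, 0.025]
        np.testing.assert_allclose(w, expected, atol=1e-15)
        assert w.sum() == pytest.approx(1.0)

    def test_constant_integrand(self):
        sched = default_schedule()
        stats = [LambdaStats(lam, 2.0, 0.0, 5) for lam in sched]
        res = integrate_stochastic(stats, sched)
        assert res.delta_g == pytest.approx(2.0, abs=1e-12)
        assert res.sigma == 0.0

    def test_quadratic_integrand_matches_trapezoid_oracle(self):
        """6λ² on the 13-point grid: equals an independent trapezoid oracle
        exactly; differs from the analytic 2.0 only by the coarse-grid
        quadrature error, which a fine grid drives to zero."""
        sched = default_schedule()
        lams = np.array(sched.values)
        stats = [LambdaStats(lam, 6 * lam**2, 0.0, 5) for lam in sched]
        res = integrate_stochastic(stats, sched)
        oracle_coarse = np.trapezoid(6 * lams**2, lams)
        assert res.delta_g == pytest.approx(oracle_coarse, abs=1e-13)
        fine = np.linspace(0, 1, 10**6)
        oracle_fine = np.trapezoid(6 * fine**2, fine)
        assert oracle_fine == pytest.approx(2.0, abs=1e-9)
        assert res.delta_g - 2.0 == pytest.approx(oracle_coarse - 2.0, abs=1e-13)
        assert abs(res.delta_g - 2.0) > 0  # the coarse error is real but computable

    def test_uniform_stderr_propagates_through_weights(self):
        sched = default_schedule()
        s = 0.4
        stats = [LambdaStats(lam, 0.0, s, 5) for lam in sched]
        res = integrate_stochastic(stats, sched)
        w = trapezoid_weights(sched.values)
        assert res.sigma == pytest.approx(s * math.sqrt(float(np.sum(w**2))), abs=1e-12)

    def test_linearity_in_the_integrand(self):
        sched = default_schedule()
        rng = np.random.default_rng(5)
        means = rng.normal(size=13)
        base = integrate_stochastic(
            [LambdaStats(l, m, 0.0, 5) for l, m in zip(sched, means)], sched
        ).delta_g
        scaled = integrate_stochastic(
            [LambdaStats(l, 3 * m, 0.0, 5) for l, m in zip(sched, means)], sched
        ).delta_g
        shifted = integrate_stochastic(
            [LambdaStats(l, m + 1.0, 0.0, 5) for l, m in zip(sched, means)], sched
        ).delta_g
        assert scaled == pytest.approx(3 * base, abs=1e-12)
        assert shifted == pytest.approx(base + 1.0, abs=1e-12)

    def test_missing_window_is_coverage_error(self):
        sched = default_schedule()
        stats = [LambdaStats(lam, 1.0, 0.0, 5) for lam in sched.values[:-1]]
        with pytest.raises(CoverageError, match="1.0"):
            integrate_stochastic(stats, sched)

    def test_duplicate_window_rejected(self):
        sched = LambdaSchedule(values=(0.0, 0.5, 1.0))
        stats = [LambdaStats(l, 1.0, 0.0, 5) for l in (0.0, 0.5, 0.5, 1.0)]
        with pytest.raises(ValueError, match="duplicate"):
            integrate_stochastic(stats, sched)

    def test_bootstrap_agrees_with_propagation_for_gaussian_replicas(self):
        """With replica means that are iid Gaussian, the bootstrap sigma and
        the propagated sigma estimate the same quantity (within Monte-Carlo
        error at B = 10^4)."""
        sched = default_schedule()
        rng = np.random.default_rng(42)
        means_by_lambda = {lam: rng.normal(1.0, 0.5, size=5) for lam in sched}
        grid = grid_from_replica_means(means_by_lambda)
        # grid schedule equals default values
        stats = [lambda_stats(grid, lam) for lam in sched]
        prop = integrate_stochastic(stats, sched)
        boot = integrate_stochastic(stats, sched, method="bootstrap", n_boot=10**4, seed=1)
        assert boot.delta_g == pytest.approx(prop.delta_g, abs=1e-12)
        assert boot.sigma == pytest.approx(prop.sigma, rel=0.10)


class TestDdgCycle:
    def test_cycle_arithmetic(self):
        aq = FreeEnergyResult(5.0, 0.0, environment="aqueous")
        bo = FreeEnergyResult(3.0, 0.0, environment="bound")
        res = ddg_cycle(aq, bo, pair_label="p")
        assert res.ddg == pytest.approx(2.0) and res.sigma == 0.0

    def test_three_four_five_quadrature(self):
        aq = FreeEnergyResult(0.0, 0.3, environment="aqueous")
        bo = FreeEnergyResult(0.0, 0.4, environment="bound")
        assert ddg_cycle(aq, bo).sigma == pytest.approx(0.5, abs=1e-12)

    def test_antisymmetry_under_direction_reversal(self):
        aq = FreeEnergyResult(1.7, 0.2, environment="aqueous")
        bo = FreeEnergyResult(-0.4, 0.3, environment="bound")
        fwd = ddg_cycle(aq, bo)
        rev = ddg_cycle(
            FreeEnergyResult(-aq.delta_g, aq.sigma, environment="aqueous"),
            FreeEnergyResult(-bo.delta_g, bo.sigma, environment="bound"),
        )
        assert rev.ddg == pytest.approx(-fwd.ddg)
        assert rev.sigma == pytest.approx(fwd.sigma)

    def test_environment_mix_up_rejected(self):
        aq = FreeEnergyResult(0.0, 0.1, environment="aqueous")
        bo = FreeEnergyResult(0.0, 0.1, environment="bound")
        with pytest.raises(ValueError):
            ddg_cycle(bo, aq)
        with pytest.raises(ValueError):
            ddg_cycle(aq, aq)


def independent_benchmark_oracle(calc, expt):
    """Formula-level re-implementation of the report statistics in plain
    numpy (ranks by double argsort; normal-equation least squares)."""
    x = np.asarray(expt, dtype=float)
    y = np.asarray(calc, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))

    def ranks(v):
        out = np.empty(len(v))
        out[np.argsort(v)] = np.arange(1, len(v) + 1)
        return out

    rx, ry = ranks(x), ranks(y)
    rxc, ryc = rx - rx.mean(), ry - ry.mean()
    rs = float((rxc @ ryc) / math.sqrt((rxc @ rxc) * (ryc @ ryc)))
    mse = float(np.mean((y - x) ** 2))
    slope = float((xc @ yc) / (xc @ xc))
    intercept = float(y.mean() - slope * x.mean())
    return r, rs, mse, math.sqrt(mse), slope, intercept


class TestBenchmark:
    def _results(self, values):
        return [
            RelativeBindingResult(float(v), 0.1, pair_label=f"p{k}")
            for k, v in enumerate(values)
        ]

    def _table(self, values):
        return pd.DataFrame(
            {"pair_label": [f"p{k}" for k in range(len(values))], "ddg_expt": values}
        )

    def test_identity_gives_perfect_statistics(self):
        vals = [0.5, -1.0, 2.0, 1.5, -0.2]
        rep = benchmark(self._results(vals), self._table(vals))
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rs == pytest.approx(1.0)
        assert rep.rmse == 0.0 and rep.mse == 0.0

    def test_sign_flip_gives_perfect_anticorrelation(self):
        vals = np.array([0.5, -1.0, 2.0, 1.5, -0.2])
        rep = benchmark(self._results(-vals), self._table(vals))
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_rmse_squared_equals_mse(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=17)
        c = e + rng.normal(0, 1.0, size=17)
        rep = benchmark(self._results(c), self._table(e))
        assert rep.rmse**2 == pytest.approx(rep.mse, abs=1e-12)

    def test_matches_independent_formula_oracle(self):
        rng = np.random.default_rng(123)
        e = rng.uniform(-3, 3, size=17)
        c = e + rng.normal(0, 1.0, size=17)
        rep = benchmark(self._results(c), self._table(e))
        r, rs, mse, rmse, slope, intercept = independent_benchmark_oracle(c, e)
        assert rep.pearson_r == pytest.approx(r, abs=1e-10)
        assert rep.spearman_rs == pytest.approx(rs, abs=1e-10)
        assert rep.mse == pytest.approx(mse, abs=1e-10)
        assert rep.rmse == pytest.approx(rmse, abs=1e-10)
        assert rep.fit_slope == pytest.approx(slope, abs=1e-10)
        assert rep.fit_intercept == pytest.approx(intercept, abs=1e-10)

    def test_unmatched_label_lists_the_orphan(self):
        calc = self._results([1.0, 2.0])
        table = self._table([1.0, 2.0]).replace({"p1": "zz"})
        with pytest.raises(ValueError, match="p1"):
            benchmark(calc, table)

    def test_summary_mentions_key_statistics(self):
        vals = [0.5, -1.0, 2.0]
        text = benchmark(self._results(vals), self._table(vals)).summary()
        assert "Pearson" in text and "RMSE" in text


class TestModelFrontEnd:
    def test_from_dataframe_and_fit(self):
        sched = LambdaSchedule(values=(0.0, 0.5, 1.0))
        rows = []
        for lam, mean in zip(sched, (1.0, 2.0, 3.0)):
            for rep in range(3):
                for _ in range(4):
                    rows.append({"lambda": lam, "replica": f"r{rep}", "dvdl": mean})
        model = ThermodynamicIntegration.from_dataframe(pd.DataFrame(rows), schedule=sched)
        res = model.fit()
        assert res.delta_g == pytest.approx(2.0)  # trapezoid of 1,2,3 on 0,.5,1
        assert res.sigma == 0.0
        assert res.environment == "aqueous"

    def test_summary_and_conf_int(self):
        grid = grid_from_replica_means({0.0: [1, 2, 3], 1.0: [3, 4, 5]})
        res = ThermodynamicIntegration(grid).fit()
        lo, hi = res.conf_int()
        assert lo < res.delta_g < hi
        text = res.summary()
        assert "dG_alch" in text and "per-window" in text

    def test_plugs_into_cycle(self):
        aq = ThermodynamicIntegration(
            grid_from_replica_means({0.0: [1, 1], 1.0: [1, 1]}, environment="aqueous")
        ).fit()
        bo = ThermodynamicIntegration(
            grid_from_replica_means({0.0: [0.5, 0.5], 1.0: [0.5, 0.5]}, environment="bound")
        ).fit()
        assert ddg_cycle(aq, bo).ddg == pytest.approx(0.5)
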