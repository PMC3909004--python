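"""Sweeps, closed-form oracles, thresholds, recovery pairing and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from abxward import (
    EpiParams,
    IntegrationSettings,
    PharmacodynamicParams,
    SweepSpec,
    analytic_equilibrium,
    find_dominance_threshold,
    recovery_vs_xhat,
    sweep,
)
from abxward.cli import main
from abxward.config import ConfigError, Scenario, load_scenario

EPI = EpiParams()
PDP = PharmacodynamicParams()


class TestAnalyticEquilibrium:
    @pytest.mark.parametrize(
        "strategy, omega, expected",
        [
            ("NONE", 0.5, 0.0),
            ("CONTROL", 0.5, 0.5),
            ("SINGLE", 0.5, 0.25 / 0.9),           # 27.78%
            ("COCKTAIL_CMB", 0.0, 0.25 / 0.9),
            ("COCKTAIL_SEP", 1.0, (0.25 + 5.0 / 12.0) / 0.9),  # 74.07%
        ],
    )
    def test_closed_forms(self, strategy, omega, expected):
        assert analytic_equilibrium(strategy, omega, EPI, PDP) == pytest.approx(
            expected, abs=1e-6
        )

    def test_fluctuating_regimens_have_no_closed_form(self):
        assert analytic_equilibrium("CYCLING", 0.5, EPI, PDP) is None
        assert analytic_equilibrium("MIXING", 0.5, EPI, PDP) is None

    def test_explicit_dominant_overrides_exclusion_rule(self):
        # forcing the sensitive strain under SINGLE gives its own threshold
        # the MIC floor leaves G_S a hair above phi_min, hence the 1e-7 slack
        val = analytic_equilibrium("SINGLE", 0.5, EPI, PDP, dominant="S")
        assert val == pytest.approx(0.5, abs=1e-7)


@pytest.fixture(scope="module")
def small_table():
    spec = SweepSpec(
        strategies=("NONE", "SINGLE", "COCKTAIL_SEP"),
        omegas=(0.0, 0.5, 1.0),
        pis=(5.0,),
    )
    return sweep(spec, EPI, PDP)


class TestSweep:

    def test_shape_and_flags(self, small_table):
        assert len(small_table) == 9
        assert small_table["converged"].all()

    def test_none_row_fully_infected(self, small_table):
        none = small_table[small_table.strategy == "NONE"]
        assert np.allclose(none["x_hat"], 0.0, atol=1e-6)

    def test_single_independent_of_tradeoff(self, small_table):
        single = small_table[small_table.strategy == "SINGLE"]["x_hat"]
        assert single.max() - single.min() < 1e-9
        assert single.iloc[0] == pytest.approx(0.25 / 0.9, abs=1e-6)

    def test_separate_cocktail_rises_with_tradeoff(self, small_table):
        sep = small_table[small_table.strategy == "COCKTAIL_SEP"].sort_values("omega")
        assert sep["x_hat"].is_monotonic_increasing

    def test_deterministic(self):
        spec = SweepSpec(strategies=("CONTROL",), omegas=(0.2, 0.8), pis=(5.0,))
        t1 = sweep(spec, EPI, PDP)
        t2 = sweep(spec, EPI, PDP)
        pd.testing.assert_frame_equal(t1, t2)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SweepSpec(omegas=(0.0, 1.5))
        with pytest.raises(ValueError):
            SweepSpec(pis=(0.0,))


class TestThreshold:
    def test_combined_cocktail_switch_to_sensitive(self):
        """The suppressive cocktail stops selecting for double resistance at
        a strong tradeoff and the sensitive strain takes over."""
        res = find_dominance_threshold("COCKTAIL_CMB", tolerance=0.005)
        assert res.width <= 0.005
        assert res.from_strain == ("R3",)
        assert res.to_strain == ("S",)
        assert res.omega_star == pytest.approx(0.86, abs=0.01)

    def test_no_switch_reported_explicitly(self):
        res = find_dominance_threshold("NONE")
        assert res.omega_star is None
        assert res.from_strain == ("S",)


class TestRecoveryPairs:
    def test_positive_association_for_separate_cocktail(self):
        spec = SweepSpec(strategies=("COCKTAIL_SEP",), omegas=(0.0, 0.4, 0.8), pis=())
        table = sweep(spec, EPI, PDP)
        assoc = recovery_vs_xhat(table)
        row = assoc.iloc[0]
        assert row["association"] == "positive"
        assert row["spearman_rho"] > 0

    def test_single_point_series_undefined(self):
        spec = SweepSpec(strategies=("CONTROL",), omegas=(0.5,), pis=())
        assoc = recovery_vs_xhat(sweep(spec, EPI, PDP))
        assert assoc.iloc[0]["association"] == "undefined"


class TestConfigAndCli:
    def test_scenario_roundtrip(self, tmp_path):
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            "strategy: {name: CYCLING, pi: 25}\n"
            "omega: 0.75\n"
            "epi: {cost_c: 0.2}\n"
            "integration: {dt: 0.5}\n"
        )
        sc = load_scenario(cfg)
        assert sc.schedule.name == "CYCLING" and sc.schedule.period_pi == 25
        assert sc.epi.cost_c == 0.2 and sc.epi.beta == 1.0
        assert sc.settings.dt == 0.5
        assert sc.strains[3].mic_a == pytest.approx(60.0)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigError):
            Scenario.from_dict({"strategy": {"name": "BOGUS"}})
        with pytest.raises(ConfigError):
            Scenario.from_dict({"omega": 3.0})

    def test_cli_run_writes_json(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["run", "--strategy", "CONTROL", "--omega", "0.5",
                   "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads((tmp_path / "result.json").read_text())
        assert payload["x_hat"] == pytest.approx(0.5, abs=1e-6)
        assert payload["parameters"]["epi"]["beta"] == 1.0

    def test_cli_sweep_and_figure3(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["sweep", "--strategies", "CONTROL,COCKTAIL_SEP",
                   "--omega-step", "0.5", "--pis", "5", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        table = pd.read_csv(tmp_path / "sweep.csv")
        assert len(table) == 6
        result = runner.invoke(
            main, ["figure3", "--sweep-csv", str(tmp_path / "sweep.csv"),
                   "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        assoc = pd.read_csv(tmp_path / "recovery_association.csv")
        assert set(assoc["strategy"]) == {"CONTROL", "COCKTAIL_SEP"}

    def test_cli_threshold(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["threshold", "--strategy", "COCKTAIL_CMB",
                   "--tolerance", "0.02", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads((tmp_path / "threshold_cocktail_cmb.json").read_text())
        assert payload["omega_star"] == pytest.approx(0.86, abs=0.02)
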