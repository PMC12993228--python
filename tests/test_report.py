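"""Report pipeline, percentage arithmetic and the CLI."""

import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner

from pharmstock import (
    DegenerateInputError,
    RunConfig,
    SyntheticConfig,
    generate_ledger,
    percent,
    run_analysis,
    write_ledger,
)
from pharmstock.cli import main as cli_main


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(2490, 10541, 23.6), (8051, 10541, 76.4), (1, 3, 33.3), (1, 8, 12.5)],
    )
    def test_examples(self, num, den, expected):
        assert percent(num, den, 1) == expected

    def test_half_up_not_bankers(self):
        assert percent(25, 1000, 1) == 2.5
        assert percent(5, 2000, 1) == 0.3  # 0.25 rounds up, not to even

    def test_zero_denominator(self):
        with pytest.raises(DegenerateInputError):
            percent(1, 0)


@pytest.fixture(scope="module")
def ledger_path(tmp_path_factory) -> Path:
    p = tmp_path_factory.mktemp("data") / "ledger.csv"
    write_ledger(generate_ledger(SyntheticConfig(n_products=600, seed=8)), p)
    return p


class TestRunAnalysis:
    def test_bundle_contents_and_consistency(self, ledger_path, tmp_path):
        out = tmp_path / "rep"
        summary = run_analysis(RunConfig(input_path=ledger_path, output_dir=out))
        for name in (
            "abc_summary.csv", "fsn_summary.csv", "hmlp_summary.csv",
            "medical_matrix.csv", "non_medical_matrix.csv",
            "medical_categories.csv", "non_medical_categories.csv",
            "members.csv", "labels.csv", "turnover.csv", "summary.json", "run.log",
        ):
            assert (out / name).exists(), name
        assert summary == json.loads((out / "summary.json").read_text())
        # joining the member file reproduces the matrix cell counts
        members = pd.read_csv(out / "members.csv")
        mat = pd.read_csv(out / "medical_matrix.csv").set_index("class")
        med = members[members["sector"] == "medical"]
        for r in "ABC":
            for c in "FSN":
                got = len(med[(med["row_label"] == r) & (med["col_label"] == c)])
                assert got == mat.loc[r, c]
        # category counts conserve the sector sizes
        assert sum(summary["medical_categories"].values()) == summary["n_medical"]
        assert sum(summary["non_medical_categories"].values()) == summary["n_non_medical"]

    def test_percentage_columns_sum_to_100(self, ledger_path, tmp_path):
        run_analysis(RunConfig(input_path=ledger_path, output_dir=tmp_path / "r"))
        for name in ("abc_summary.csv", "fsn_summary.csv", "hmlp_summary.csv"):
            df = pd.read_csv(tmp_path / "r" / name)
            assert abs(round(float(df["pct_items"].sum()), 1) - 100.0) <= 0.1

    def test_missing_balances_degrades_gracefully(self, tmp_path):
        ds = generate_ledger(SyntheticConfig(n_products=60, seed=10))
        for r in ds.records:
            r.opening_balance = None
            r.closing_balance = None
        p = tmp_path / "nobal.csv"
        write_ledger(ds, p)
        out = tmp_path / "rep"
        run_analysis(RunConfig(input_path=p, output_dir=out))
        assert not (out / "turnover.csv").exists()
        assert "turnover table skipped" in (out / "run.log").read_text()

    def test_sector_scope_recomputes_labels(self, ledger_path, tmp_path):
        pooled = run_analysis(
            RunConfig(input_path=ledger_path, output_dir=tmp_path / "a")
        )
        per_sector = run_analysis(
            RunConfig(input_path=ledger_path, output_dir=tmp_path / "b",
                      label_scope="sector")
        )
        # both conserve sector sizes even though cell allocations differ
        assert sum(pooled["medical_categories"].values()) == sum(
            per_sector["medical_categories"].values()
        )

    def test_failure_removes_partial_outputs(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("product_id,product_name\nP1,x\n")
        out = tmp_path / "rep"
        with pytest.raises(Exception):
            run_analysis(RunConfig(input_path=p, output_dir=out))
        assert not any(out.glob("*.csv"))


class TestCli:
    def test_synth_then_classify(self, tmp_path):
        runner = CliRunner()
        led = tmp_path / "led.csv"
        r = runner.invoke(cli_main, ["synth", "--n", "200", "--seed", "3",
                                     "--out", str(led)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["classify", "--input", str(led),
                                     "--out", str(tmp_path / "rep")])
        assert r.exit_code == 0, r.output
        assert "analysed 200 products" in r.output
        assert (tmp_path / "rep" / "summary.json").exists()

    def test_validation_error_exit_code(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("product_id,product_name\nP1,x\n")
        runner = CliRunner()
        r = runner.invoke(cli_main, ["classify", "--input", str(p),
                                     "--out", str(tmp_path / "rep")])
        assert r.exit_code == 2

    def test_config_file_overrides(self, tmp_path):
        runner = CliRunner()
        led = tmp_path / "led.csv"
        runner.invoke(cli_main, ["synth", "--n", "100", "--seed", "4",
                                 "--out", str(led)])
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("fsn_fast_min_rate: 2.0\nfsn_slow_min_rate: 0.5\n")
        r = runner.invoke(cli_main, ["classify", "--input", str(led),
                                     "--out", str(tmp_path / "rep"),
                                     "--config", str(cfg)])
        assert r.exit_code == 0, r.output
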