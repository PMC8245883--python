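"""Parameter validation, config loading, CSV round trips, CLI, manifests."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from telosim import (
    CohortParams,
    load_config,
    read_cohort_csv,
    signature_stats,
    simulate_cohort,
    simulate_true_cohort,
    write_cohort_csv,
)
from telosim.cli import main
from telosim.io import sha256_file


class TestParams:
    def test_defaults(self, defaults):
        assert defaults.mean_baseline_kb == 7.0
        assert defaults.sd_baseline_kb == pytest.approx(0.4524)
        assert defaults.mean_change_kb == -0.19
        assert defaults.sd_change_kb == 0.17
        assert defaults.followup_years == 6.6
        assert defaults.validity_r_baseline == defaults.validity_r_followup == 0.875
        assert defaults.exposure_fraction == 0.0

    def test_unrounded_change_sd_accepted(self):
        assert CohortParams(sd_change_kb=0.1683).sd_change_kb == 0.1683

    def test_replace_revalidates(self, defaults):
        with pytest.raises(ValueError):
            defaults.replace(exposure_fraction=1.5)

    def test_derived_moments(self, defaults):
        assert defaults.mean_followup_kb == pytest.approx(6.81)
        assert defaults.sd_followup_kb == pytest.approx(np.hypot(0.4524, 0.17))


class TestConfig:
    def test_empty_config_gives_defaults(self, tmp_path, defaults):
        path = tmp_path / "empty.json"
        path.write_text("")
        assert load_config(path) == defaults

    def test_round_trip(self, tmp_path, defaults):
        path = tmp_path / "conf.json"
        path.write_text(json.dumps(defaults.model_dump()))
        assert load_config(path) == defaults

    def test_yaml_config(self, tmp_path):
        path = tmp_path / "conf.yaml"
        path.write_text("n_individuals: 50\nvalidity_r_baseline: 0.9\n")
        params = load_config(path)
        assert params.n_individuals == 50
        assert params.validity_r_baseline == 0.9

    def test_out_of_range_value_names_field_and_bound(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"validity_r_baseline": 1.2}')
        with pytest.raises(ValueError, match="validity_r_baseline"):
            load_config(path)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"valdity_r": 0.9}')
        with pytest.raises(ValueError, match="valdity_r"):
            load_config(path)


class TestCohortCSV:
    def test_round_trip_is_exact(self, tmp_path, defaults):
        cohort = simulate_cohort(defaults, seed=77)
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        loaded = read_cohort_csv(path)
        for field in (
            "ids", "true_baseline_kb", "true_change_kb",
            "true_followup_kb", "proxy_baseline", "proxy_followup",
        ):
            assert np.array_equal(getattr(cohort, field), getattr(loaded, field)), field
        assert np.array_equal(cohort.exposed, loaded.exposed)

    def test_truth_only_round_trip(self, tmp_path, defaults):
        cohort = simulate_true_cohort(defaults, seed=77)
        path = tmp_path / "truth.csv"
        write_cohort_csv(cohort, path)
        loaded = read_cohort_csv(path)
        assert not loaded.has_proxy
        with pytest.raises(ValueError, match="proxy"):
            signature_stats(loaded)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_cohort_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,exposed,true_baseline_kb\n0,0,7.1\n")
        with pytest.raises(ValueError, match="true_change_kb"):
            read_cohort_csv(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,exposed,true_baseline_kb,true_change_kb,true_followup_kb\n"
            "0,0,7.1,-0.2,6.9\n"
            "1,0,oops,-0.2,6.9\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            read_cohort_csv(path)


class TestCLI:
    def test_simulate_writes_cohort_and_manifest(self, tmp_path):
        out = tmp_path / "cohort.csv"
        result = CliRunner().invoke(
            main, ["simulate", "--seed", "3", "--n", "30", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        cohort = read_cohort_csv(out)
        assert cohort.n == 30 and cohort.has_proxy
        manifest = json.loads((tmp_path / "cohort.csv.manifest.json").read_text())
        assert manifest["seed"] == 3
        assert manifest["output_digests"]["cohort.csv"] == sha256_file(out)

    def test_simulate_is_reproducible_byte_for_byte(self, tmp_path):
        digests = []
        for name in ("a.csv", "b.csv"):
            out = tmp_path / name
            res = CliRunner().invoke(main, ["simulate", "--seed", "5", "--out", str(out)])
            assert res.exit_code == 0
            digests.append(sha256_file(out))
        assert digests[0] == digests[1]

    def test_signatures_on_user_cohort(self, tmp_path, defaults):
        csv = tmp_path / "cohort.csv"
        write_cohort_csv(simulate_cohort(defaults, seed=1), csv)
        out = tmp_path / "sig.json"
        res = CliRunner().invoke(
            main, ["signatures", "--cohort", str(csv), "--seed", "0", "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        assert -1 <= payload["r_methods_change"] <= 1

    def test_signature_study_cli(self, tmp_path):
        out = tmp_path / "study.json"
        res = CliRunner().invoke(
            main,
            ["signatures", "--reps", "20", "--n", "20", "--seed", "2", "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        assert payload["n_replicates"] == 20
        assert "r_methods_change" in payload["medians"]

    def test_power_cli(self, tmp_path):
        out = tmp_path / "power.csv"
        res = CliRunner().invoke(
            main,
            ["power", "--n-grid", "20,50", "--reps", "30", "--seed", "4",
             "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        df = pd.read_csv(out)
        assert len(df) == 12  # 3 strategies x 2 assays x 2 sample sizes

    def test_stats_compare_corr_cli(self):
        res = CliRunner().invoke(
            main, ["stats", "compare-corr", "--r1", "0.90", "--n1", "20",
                   "--r2", "0.48", "--n2", "20"]
        )
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert payload["z"] == pytest.approx(2.77, abs=0.005)

    def test_stats_icc_cli(self, tmp_path):
        table = tmp_path / "icc.csv"
        table.write_text("1.0,1.1\n2.0,2.1\n3.0,2.9\n")
        res = CliRunner().invoke(main, ["stats", "icc", "--table", str(table)])
        assert res.exit_code == 0, res.output
        assert json.loads(res.output)["icc"] > 0.9
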