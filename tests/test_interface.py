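import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from beaconloc import MotionModel, RunConfig, run_filter
from beaconloc import io as bio
from beaconloc.cli import main
from beaconloc.floorplan import example_map_path
from beaconloc.plotting import lasagna_table, plot_confusion, plot_lasagna, plot_tracking


# ---------------------------------------------------------------- round trips

def test_rssi_roundtrip(tmp_path, trial1_noisy):
    p = tmp_path / "rssi.csv"
    bio.write_rssi_csv(trial1_noisy.rssi_samples, p)
    streams = bio.read_rssi_csv(p, t0=bio.DEFAULT_T0)
    assert list(streams) == ["R1"]
    got = streams["R1"]
    assert len(got) == len(trial1_noisy.rssi_samples)
    for a, b in zip(got, trial1_noisy.rssi_samples):
        assert (a.t_index, a.beacon_id) == (b.t_index, b.beacon_id)
        assert a.rssi == pytest.approx(b.rssi)


def test_steps_and_truth_roundtrip(tmp_path, trial1_noisy):
    sp = tmp_path / "steps.csv"
    bio.write_steps_csv(trial1_noisy.steps, sp)
    back = bio.read_steps_csv(sp)["R1"]
    assert [(s.t_index, s.steps) for s in back] == [
        (s.t_index, s.steps) for s in trial1_noisy.steps
    ]
    tp = tmp_path / "truth.csv"
    bio.write_truth_csv(trial1_noisy.truth, tp)
    truth = bio.read_truth_csv(tp)
    assert truth.area_ids == trial1_noisy.truth.area_ids


def test_accel_roundtrip(tmp_path, trial1_noisy):
    p = tmp_path / "accel.csv"
    sub = {k: v[:3000] for k, v in trial1_noisy.accel.items()}
    bio.write_accel_csv(sub, p)
    back = bio.read_accel_csv(p)
    assert np.allclose(back["az"], sub["az"], atol=1e-6)
    assert np.allclose(back["t"], sub["t"], atol=1e-3)


def test_trace_roundtrip(tmp_path, trial1_noisy, example_map):
    beacons, _, graph = example_map
    t = trial1_noisy
    trace = run_filter(graph, beacons, MotionModel("model3"), t.rssi_samples,
                       t.steps, n_epochs=t.truth.n_epochs)
    p = tmp_path / "trace.csv"
    bio.write_trace_csv(trace, p, include_probs=True)
    df = bio.read_trace_csv(p)
    assert len(df) == trace.n_epochs
    assert df["map_area_smoothed"].tolist() == trace.smoothed_area_ids()
    assert f"prob_{graph.area_ids[0]}" in df.columns


def test_malformed_timestamp_cites_line(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(
        "timestamp,receiver_id,beacon_id,rssi_dbm\n"
        "2018-01-01T00:00:00Z,R1,b1,-50\n"
        "not-a-time,R1,b1,-55\n"
    )
    with pytest.raises(bio.SchemaError, match=r"\[3\]"):
        bio.read_rssi_csv(p)


def test_missing_column_named(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("timestamp,receiver_id\n2018-01-01T00:00:00Z,R1\n")
    with pytest.raises(bio.SchemaError, match="beacon_id"):
        bio.read_rssi_csv(p)


def test_read_streams_shares_one_epoch_grid(tmp_path, trial1_noisy):
    # even if the RSSI stream starts late (dropout at epoch 0), the shared
    # grid anchored on the steps file keeps both streams aligned
    rp, sp = tmp_path / "rssi.csv", tmp_path / "steps.csv"
    late = [s for s in trial1_noisy.rssi_samples if s.t_index >= 2]
    bio.write_rssi_csv(late, rp)
    bio.write_steps_csv(trial1_noisy.steps, sp)
    streams = bio.read_streams(rp, sp)
    assert streams["rssi"]["R1"][0].t_index == 2
    assert streams["steps"]["R1"][0].t_index == 0


def test_mixed_receivers_partitioned(tmp_path):
    p = tmp_path / "rssi.csv"
    p.write_text(
        "timestamp,receiver_id,beacon_id,rssi_dbm\n"
        "2018-01-01T00:00:00Z,R1,b1,-50\n"
        "2018-01-01T00:00:00Z,R2,b1,-60\n"
        "2018-01-01T00:00:10Z,R1,b2,-70\n"
    )
    streams = bio.read_rssi_csv(p)
    assert sorted(streams) == ["R1", "R2"]
    assert len(streams["R1"]) == 2 and len(streams["R2"]) == 1
    assert streams["R1"][1].t_index == 1


# ---------------------------------------------------------------- config

def test_runconfig_defaults_match_operating_point():
    cfg = RunConfig()
    assert cfg.epoch_s == 10.0
    assert cfg.min_run == 2
    assert cfg.rssi_near_dbm == -45.0
    assert cfg.rssi_cutoff_dbm == -90.0
    assert cfg.corridor_weight == 1.0


def test_runconfig_yaml_override(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text("corridor_weight: 0.5\nmin_run: 3\n")
    cfg = RunConfig.from_yaml(p, model_id="model2")
    assert cfg.corridor_weight == 0.5
    assert cfg.min_run == 3
    assert cfg.model_id == "model2"
    with pytest.raises(ValueError, match="unknown"):
        RunConfig.from_yaml(None, bogus=1)


# ---------------------------------------------------------------- plots

def test_lasagna_orderings():
    areas = ["R1"] * 6 + ["C1"] * 2 + ["R2"] * 4
    levels = ["low"] * 6 + ["high"] * 2 + ["low"] * 2 + ["middle"] * 2
    tab = lasagna_table(areas, levels, ordering="absolute")
    totals = tab.sum(axis=1)
    assert totals.tolist() == sorted(totals.tolist(), reverse=True)
    assert tab.index[0] == "R1"
    tab_rel = lasagna_table(areas, levels, ordering="relative")
    frac_low = (tab_rel["low"] / tab_rel.sum(axis=1)).tolist()
    assert frac_low == sorted(frac_low, reverse=True)
    tab_route = lasagna_table(areas, levels, ordering="route")
    assert tab_route.index.tolist() == ["R1", "C1", "R2"]
    with pytest.raises(ValueError, match="ordering"):
        lasagna_table(areas, levels, ordering="sideways")


def test_lasagna_single_area_single_level():
    tab = lasagna_table(["R1"] * 4, ["low"] * 4)
    assert (tab.to_numpy() > 0).sum() == 1
    assert tab.loc["R1", "low"] == 40.0


def test_plot_files_created(tmp_path, trial1_noisy, example_map):
    beacons, _, graph = example_map
    t = trial1_noisy
    trace = run_filter(graph, beacons, MotionModel("model3"), t.rssi_samples,
                       t.steps, n_epochs=t.truth.n_epochs)
    from beaconloc import confusion

    p1 = plot_tracking(trace, t.truth, tmp_path / "track.png")
    p2 = plot_confusion(confusion(trace, t.truth), tmp_path / "cm.png")
    levels = ["low"] * trace.n_epochs
    p3 = plot_lasagna(trace, levels, tmp_path / "lasagna.png")
    for p in (p1, p2, p3):
        assert p.exists() and p.stat().st_size > 0


def test_empty_trace_plot_does_not_crash(tmp_path):
    from beaconloc import GroundTruthTrace

    out = plot_tracking([], GroundTruthTrace(area_ids=[]), tmp_path / "empty.png")
    assert out.exists()


# ---------------------------------------------------------------- CLI pipeline

def test_cli_pipeline_smoke(tmp_path):
    runner = CliRunner()
    d = tmp_path / "trial"
    res = runner.invoke(main, ["simulate", "--map", str(example_map_path()),
                               "--trial", "3", "--seed", "5",
                               "--out-dir", str(d)])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["localize", "--map", str(example_map_path()),
                               "--model", "model3", "--w", "1.0",
                               "--rssi", str(d / "rssi.csv"),
                               "--steps", str(d / "steps.csv"),
                               "--out", str(d / "trace.csv")])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["classify-activity", "--accel", str(d / "accel.csv"),
                               "--out", str(d / "activity.csv"), "--seed", "0"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(main, ["evaluate", "--trace", str(d / "trace.csv"),
                               "--truth", str(d / "truth.csv"),
                               "--out", str(d / "report.json")])
    assert res.exit_code == 0, res.output
    report = json.loads((d / "report.json").read_text())
    assert report["error_report"]["nontransition_error_pct"] < 15.0
    for kind, extra in [("tracking", ["--truth", str(d / "truth.csv")]),
                        ("confusion", ["--truth", str(d / "truth.csv"),
                                       "--variant", "nontransition"]),
                        ("lasagna", ["--activity", str(d / "activity.csv")])]:
        res = runner.invoke(main, ["plot", "--kind", kind,
                                   "--trace", str(d / "trace.csv"),
                                   "--out", str(d / f"{kind}.png")] + extra)
        assert res.exit_code == 0, res.output
        assert (d / f"{kind}.png").exists()


def test_cli_validation_exit_code(tmp_path):
    runner = CliRunner()
    bad = tmp_path / "bad.yaml"
    bad.write_text("areas: []\nbeacons: []\nedges: []\n")
    out = tmp_path / "x"
    res = runner.invoke(main, ["simulate", "--map", str(bad), "--trial", "1",
                               "--out-dir", str(out)])
    assert res.exit_code == 1
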