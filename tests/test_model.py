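"""Model/Results facade, pipeline orchestration and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from delaynet import (
    ConductionDelayModel,
    KuramotoConfig,
    PipelineConfig,
    SynthConfig,
    run_pipeline,
)
from delaynet.cli import main as cli_main
from delaynet.errors import ConfigError
from delaynet.plotting import plot_sweep

CFG = SynthConfig(n_rois=24, seed=3)


@pytest.fixture(scope="module")
def results():
    return ConductionDelayModel.from_synthetic(CFG).fit()


def test_fit_results_surface(results):
    assert results.group.n_rois == 24
    assert results.group.n_edges > 10
    assert results.implied_velocity == pytest.approx(
        1 / results.regression.slope)
    assert 0 <= results.regression.r_squared <= 1
    assert set(results.edges.columns) >= {"length_m", "diameter_um",
                                          "gratio", "velocity_m_per_s",
                                          "delay_s"}
    text = results.summary()
    assert "implied velocity" in text and "R^2" in text


def test_constant_velocity_network_consistency(results):
    net_cv = results.constant_velocity_network()
    sel = results.group.adjacency
    np.testing.assert_allclose(
        net_cv.tau[sel],
        results.group.length[sel] / results.implied_velocity, rtol=1e-12)
    np.testing.assert_array_equal(net_cv.coupling, sel)


def test_compare_paths(results):
    cmp = results.compare_paths()
    n = results.group.n_rois
    assert cmp.sp_estimated.shape == (n, n)
    assert cmp.bc_estimated.shape == (n,)
    assert np.all((cmp.bc_estimated >= 0) & (cmp.bc_estimated <= 1))
    assert set(cmp.blocks["block"]) == {"LH", "RH", "inter", "SC"}
    fin = np.isfinite(cmp.percent_diff)
    off = ~np.eye(n, dtype=bool)
    # sign convention: negative where constant-velocity paths are shorter
    est, cv = cmp.sp_estimated[fin & off], cmp.sp_constant[fin & off]
    d = cmp.percent_diff[fin & off]
    np.testing.assert_allclose(d, 100 * (cv - est) / est, rtol=1e-12)


def test_kuramoto_sweep_from_results(results):
    cfg = KuramotoConfig(t_end=0.3, window=(0.1, 0.25), n_runs=2,
                         couplings=np.array([0.5, 8.0]), seed=0)
    sw_est = results.kuramoto_sweep(cfg, condition="estimated")
    sw_cv = results.kuramoto_sweep(cfg, condition="constant")
    assert sw_est.synchrony.shape == (2, 2)
    frame = sw_est.to_frame()
    assert list(frame.columns)[0] == "coupling"
    axes = plot_sweep(sw_est, sw_cv)
    assert len(axes) == 2
    with pytest.raises(ValueError):
        results.kuramoto_sweep(cfg, condition="bogus")


def _tiny_pipeline_config(outdir, seed=1):
    return PipelineConfig(
        synth=SynthConfig(n_rois=20, edge_density=0.4),
        kuramoto=KuramotoConfig(t_end=0.3, window=(0.1, 0.25), n_runs=2,
                                couplings=np.array([0.5, 8.0])),
        full_protocol=True,  # use the tiny explicit grid above as-is
        outdir=str(outdir), seed=seed,
    )


def test_pipeline_end_to_end(tmp_path):
    cfg = _tiny_pipeline_config(tmp_path / "out")
    report = run_pipeline(cfg)
    for key in ("config_hash", "seed", "network", "regression", "graph",
                "kuramoto"):
        assert key in report
    for fname in ("report.json", "regression.json", "summary_stats.json",
                  "sp_diff_percent.csv", "betweenness.csv",
                  "sweep_estimated.csv", "sweep_constant.csv",
                  "group_delay.csv", "group_provenance.csv"):
        assert (tmp_path / "out" / fname).exists()
    # determinism: identical report on re-run
    report2 = run_pipeline(_tiny_pipeline_config(tmp_path / "out2"))
    r1 = json.loads((tmp_path / "out" / "report.json").read_text())
    r2 = json.loads((tmp_path / "out2" / "report.json").read_text())
    assert r1 == r2


def test_pipeline_config_validation():
    cfg = PipelineConfig(min_subjects=20)  # synthetic default has 14 subjects
    with pytest.raises(ConfigError):
        cfg.validate()
    with pytest.raises(ConfigError):
        PipelineConfig.from_dict({"bogus_key": 1})


def test_cli_simulate_and_build(tmp_path):
    runner = CliRunner()
    res = runner.invoke(cli_main, [
        "simulate", "--out", str(tmp_path / "stack"), "--seed", "2",
        "--n-rois", "16", "--n-subjects", "10", "--edge-density", "0.5"])
    assert res.exit_code == 0, res.output
    res = runner.invoke(cli_main, [
        "build-network", str(tmp_path / "stack"),
        "--out", str(tmp_path / "grp")])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "grp" / "group_delay.csv").exists()
    assert (tmp_path / "grp" / "delay_network" / "tau.csv").exists()


def test_cli_run_all_with_config(tmp_path):
    config_yaml = tmp_path / "cfg.yaml"
    config_yaml.write_text(
        "synth:\n  n_rois: 20\n  edge_density: 0.4\n"
        "kuramoto:\n  t_end: 0.3\n  window: [0.1, 0.25]\n  n_runs: 2\n"
        "  couplings: [0.5, 8.0]\n"
        "full_protocol: true\n"
    )
    runner = CliRunner()
    res = runner.invoke(cli_main, [
        "run-all", "--out", str(tmp_path / "out"), "--seed", "4",
        "--config", str(config_yaml)])
    assert res.exit_code == 0, res.output
    report = json.loads((tmp_path / "out" / "report.json").read_text())
    assert report["seed"] == 4
    assert report["network"]["n_rois"] == 20
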