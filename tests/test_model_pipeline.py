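"""Cohort model, dataset round-trip, pipeline orchestration and CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import msgrad as mg
from msgrad import io as mio
from msgrad.cli import main as cli_main
from msgrad.pipeline import RunConfig, run_pipeline, simulate_dataset


def test_model_recovers_planted_axis(fitted_cohort, truth100):
    g1 = fitted_cohort.component_scores(0)
    r = np.corrcoef(g1.mean(axis=0), truth100.contrast_vector)[0, 1]
    assert abs(r) > 0.8
    # sign convention: the primary-proxy community sits on the positive end
    assert r > 0


def test_model_scan_table_shapes(fitted_cohort, small_cohort):
    scans, _ = small_cohort
    tab = fitted_cohort.scan_table
    assert len(tab) == len(scans)
    for col in ("g1_range", "g1_sd", "g1_explanation_ratio", "dispersion",
                "mean_eccentricity"):
        assert np.isfinite(tab[col]).all()
    assert (tab["dispersion"] > 0).all()
    assert fitted_cohort.overall_template.k == 10


def test_model_age_effect_interface(fitted_cohort):
    eff = fitted_cohort.age_effect("dispersion")
    assert set(eff) >= {"delta_adj_r2", "p", "full", "reduced"}
    assert -1 <= eff["delta_adj_r2"] <= 1
    assert 0 <= eff["p"] <= 1
    assert "adj R2" in eff["full"].summary()


def test_cohort_io_roundtrip(tmp_path, parcels100, small_cohort):
    scans, truth = small_cohort
    mio.write_cohort(tmp_path / "ds", parcels100, scans[:3], truth=truth)
    parcels2, scans2, phen = mio.read_cohort(tmp_path / "ds")
    assert np.allclose(parcels2.coords, parcels100.coords)
    assert np.array_equal(parcels2.community, parcels100.community)
    assert len(scans2) == 3
    for a, b in zip(scans[:3], scans2):
        assert a.scan_id == b.scan_id
        assert np.allclose(a.gd, b.gd, atol=1e-9)
        assert np.allclose(a.ts, b.ts)
        assert np.allclose(a.behavior, b.behavior, atol=1e-9)
    truth_json = json.loads((tmp_path / "ds" / "truth.json").read_text())
    assert truth_json["age_slope"] == truth.age_slope


def test_gmt_roundtrip(tmp_path):
    sets = {"setA": ["g1", "g2", "g3"], "setB": ["g4", "g5"]}
    mio.write_gmt(tmp_path / "sets.gmt", sets)
    back = mio.read_gmt(tmp_path / "sets.gmt")
    assert back == sets
    (tmp_path / "bad.gmt").write_text("only_name\tdesc\n")
    with pytest.raises(ValueError):
        mio.read_gmt(tmp_path / "bad.gmt")


@pytest.fixture(scope="module")
def pipeline_runs(tmp_path_factory):
    """Two identical end-to-end runs on a small simulated dataset."""
    root = tmp_path_factory.mktemp("pipe")
    ds = simulate_dataset(root / "ds", n_nodes=60, n_communities=3,
                          n_subjects=14, n_genes=60, n_signal_genes=6, seed=5)
    sets = {"planted": [f"gene_{i}" for i in range(6)],
            "other": [f"gene_{i}" for i in range(30, 45)]}
    mio.write_gmt(root / "sets.gmt", sets)
    cfg = dict(dataset=str(ds), seed=3, n_components=5,
               bins=(6.0, 9.0, 11.0, 14.0), n_surrogates=50,
               plsc_n_perm=50, plsc_n_boot=20, plsc_cv=False,
               plsr_n_boot=30, gene_sets=str(root / "sets.gmt"))
    out1 = run_pipeline(RunConfig(out=str(root / "run1"), **cfg))
    out2 = run_pipeline(RunConfig(out=str(root / "run2"), **cfg))
    return out1, out2


def test_pipeline_produces_all_stage_outputs(pipeline_runs):
    out1, _ = pipeline_runs
    for f in ("metrics.tsv", "gradient_scores_g1.tsv", "age_effects_global.tsv",
              "age_effects_g1.tsv", "contributions.tsv", "coupling.tsv",
              "differentiation.tsv", "structure_function.json", "saliences.tsv",
              "perm.json", "genes_ranked.tsv", "enrichment.tsv", "manifest.json"):
        assert (out1 / f).exists(), f
    manifest = json.loads((out1 / "manifest.json").read_text())
    assert set(manifest["stages"]) >= {"load", "gradients", "age_effects",
                                       "coupling", "plsc", "plsr", "enrich"}
    assert manifest["config"]["seed"] == 3


def test_pipeline_deterministic_under_same_seed(pipeline_runs):
    out1, out2 = pipeline_runs
    m1 = json.loads((out1 / "manifest.json").read_text())
    m2 = json.loads((out2 / "manifest.json").read_text())
    assert m1["outputs"] == m2["outputs"]       # identical content hashes


def test_pipeline_skips_gene_stages_without_genes(tmp_path):
    ds = simulate_dataset(tmp_path / "ds", n_nodes=60, n_communities=3,
                          n_subjects=14, seed=6)
    (ds / "genes.tsv").unlink()
    out = run_pipeline(RunConfig(dataset=str(ds), out=str(tmp_path / "run"),
                                 seed=1, n_components=5,
                                 bins=(6.0, 9.0, 11.0, 14.0),
                                 n_surrogates=30, plsc_n_perm=20,
                                 plsc_n_boot=0, plsc_cv=False,
                                 contributions=False))
    manifest = json.loads((out / "manifest.json").read_text())
    assert "plsr" not in manifest["stages"]
    assert not (out / "genes_ranked.tsv").exists()
    assert (out / "coupling.tsv").exists()


def test_run_config_yaml_validation(tmp_path):
    (tmp_path / "cfg.yaml").write_text(
        "dataset: ds\nout: run\nseed: 2\nbins: [6, 10, 14]\n")
    cfg = RunConfig.from_yaml(tmp_path / "cfg.yaml")
    assert cfg.bins == (6, 10, 14) and cfg.seed == 2
    (tmp_path / "bad.yaml").write_text("dataset: ds\nout: run\nbogus_key: 1\n")
    with pytest.raises(ValueError, match="bogus_key"):
        RunConfig.from_yaml(tmp_path / "bad.yaml")


def test_cli_simulate_and_prep(tmp_path):
    runner = CliRunner()
    res = runner.invoke(cli_main, [
        "simulate", "--out", str(tmp_path / "ds"), "--n-nodes", "40",
        "--n-communities", "2", "--n-subjects", "12", "--n-genes", "30",
        "--n-signal-genes", "3", "--seed", "4",
    ])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "ds" / "parcels.tsv").exists()
    phen = pd.read_csv(tmp_path / "ds" / "phenotypes.tsv", sep="\t")
    assert {"subject_id", "scan_id", "age", "sex", "motion"} <= set(phen.columns)

    res = runner.invoke(cli_main, [
        "prep", "--dataset", str(tmp_path / "ds"), "--out", str(tmp_path / "prep"),
    ])
    assert res.exit_code == 0, res.output
    first_scan = sorted((tmp_path / "prep").iterdir())[0]
    m = mio.read_matrix_tsv(first_scan / "gd_normalized.tsv")
    assert m.min() >= 0 and m.max() <= 1
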