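"""Run orchestration: a structured config drives the full analysis.

``run_pipeline`` executes the stages in dependency order — simulate/load →
feature prep + gradients → global measures → age effects → feature
contributions → structure–function coupling → PLSC → gene PLSR (+ optional
enrichment) — writing every output as TSV/JSON into a run directory together
with a manifest (config snapshot, seeds, file hashes, stage wall-times).
Stages whose inputs are absent (e.g., no gene matrix) are skipped cleanly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .age import AgeModelSpec
from .coupling import (
    differentiation_distance, fc_gradient, nodal_coupling, participation_coefficient,
)
from .gradients import DEFAULT_AGE_BINS, feature_contribution, diffusion_map
from .features import prepare_features
from .metrics import gradient_space
from .model import MultiscaleGradientModel
from .multivariate import GenePLS, PLSC, enrichment_with_surrogate_null, plsc_cross_validate
from .nulls import make_surrogates, surrogate_corr_test
from .synthetic import default_truth, make_parcels, simulate_cohort, simulate_gene_matrix

__all__ = ["RunConfig", "run_pipeline", "simulate_dataset"]


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    dataset: str                            # path of the dataset directory
    out: str                                # run directory
    seed: int = 0
    n_components: int = 10
    alpha: float = 0.5
    bins: tuple = DEFAULT_AGE_BINS
    age_k: int = 3
    random_intercept: bool = True
    covariates: tuple = ("sex", "motion")
    n_surrogates: int = 200
    plsc_n_perm: int = 1000
    plsc_n_boot: int = 200
    plsc_cv: bool = True
    plsr_n_boot: int = 500
    gene_sets: str | None = None            # optional GMT path
    contributions: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bins" in raw:
            raw["bins"] = tuple(raw["bins"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def simulate_dataset(
    out,
    n_nodes: int = 100,
    n_communities: int = 4,
    n_subjects: int = 60,
    n_genes: int = 200,
    n_signal_genes: int = 20,
    age_slope: float = 0.05,
    seed: int = 0,
) -> Path:
    """Simulate and write a complete synthetic dataset directory."""
    parcels = make_parcels(n_nodes, n_communities, seed=seed)
    truth = default_truth(parcels, age_slope=age_slope, seed=seed)
    scans, truth = simulate_cohort(parcels, truth, n_subjects=n_subjects, seed=seed)
    genes, signal = simulate_gene_matrix(
        parcels, truth, n_genes=n_genes, n_signal_genes=n_signal_genes, seed=seed + 1
    )
    mio.write_cohort(out, parcels, scans, truth=truth, genes=genes, signal_genes=signal)
    return Path(out)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory (with manifest.json)."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    dataset = Path(config.dataset)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {}, "outputs": {},
    }
    t_all = time.time()

    def stage(name):
        manifest["stages"][name] = {"start": time.time() - t_all}

    def done(name, *paths):
        manifest["stages"][name]["seconds"] = round(
            time.time() - t_all - manifest["stages"][name]["start"], 3
        )
        for p in paths:
            manifest["outputs"][str(Path(p).relative_to(out))] = _sha256(Path(p))

    stage("load")
    parcels, scans, phen = mio.read_cohort(dataset)
    distance = parcels.distance()
    done("load")

    stage("gradients")
    model = MultiscaleGradientModel(
        scans, parcels, n_components=config.n_components,
        alpha=config.alpha, bins=config.bins,
    )
    res = model.fit()
    metrics_path = out / "metrics.tsv"
    res.scan_table.to_csv(metrics_path, sep="\t", index=False, float_format="%.10g")
    g1 = res.component_scores(0)
    g1_path = out / "gradient_scores_g1.tsv"
    pd.DataFrame(g1, index=res.scan_table["scan_id"]).to_csv(
        g1_path, sep="\t", float_format="%.10g"
    )
    done("gradients", metrics_path, g1_path)

    spec = AgeModelSpec(k=config.age_k, random_intercept=config.random_intercept,
                        covariates=tuple(config.covariates))

    stage("age_effects")
    global_rows = []
    for measure in ("g1_range", "g1_sd", "dispersion", "mean_eccentricity"):
        eff = res.age_effect(measure, spec)
        global_rows.append({"measure": measure,
                            "delta_adj_r2": eff["delta_adj_r2"], "p": eff["p"]})
    glob_path = out / "age_effects_global.tsv"
    pd.DataFrame(global_rows).to_csv(glob_path, sep="\t", index=False,
                                     float_format="%.10g")
    node_eff = res.nodewise_age_effects(0, spec)
    node_path = out / "age_effects_g1.tsv"
    node_eff.to_csv(node_path, sep="\t", index=False, float_format="%.10g")
    done("age_effects", glob_path, node_path)

    if config.contributions:
        stage("contributions")
        mean_fs = {
            kind: np.mean([prepare_features(s.gd, s.mpc_profiles, s.ts)[kind].values
                           for s in scans], axis=0)
            for kind in ("GD", "MPC", "TS")
        }
        per_feature = {
            kind: diffusion_map(_feature_affinity(mean_fs[kind]),
                                k=config.n_components, alpha=config.alpha)
            for kind in mean_fs
        }
        contrib = feature_contribution(
            res.overall_template, per_feature, distance=distance,
            n_surrogates=config.n_surrogates, seed=config.seed,
        )
        c_path = out / "contributions.tsv"
        contrib.to_csv(c_path, sep="\t", index=False, float_format="%.10g")
        done("contributions", c_path)

    stage("coupling")
    mean_fc = np.mean([s.fc for s in scans], axis=0)
    fgrad = fc_gradient(mean_fc, k=config.n_components, alpha=config.alpha)
    mean_aff = res.mean_affinity()
    rho = nodal_coupling(mean_aff, mean_fc)
    pac_s = participation_coefficient(mean_aff * (1 - np.eye(len(rho))), parcels.community)
    pac_f = participation_coefficient(np.maximum(mean_fc, 0) * (1 - np.eye(len(rho))),
                                      parcels.community)
    coup_path = out / "coupling.tsv"
    pd.DataFrame({
        "node": np.arange(len(rho)), "coupling_rho": rho,
        "pac_structural": pac_s, "pac_functional": pac_f,
        "fc_g1": fgrad.components[:, 0],
    }).to_csv(coup_path, sep="\t", index=False, float_format="%.10g")
    diff_path = out / "differentiation.tsv"
    differentiation_distance(
        gradient_space(res.overall_template), parcels.community
    ).to_csv(diff_path, sep="\t", index=False, float_format="%.10g")
    # spatial correlation of structural g1 with the functional gradient
    ens = make_surrogates(res.overall_template.components[:, 0], distance,
                          n=config.n_surrogates, seed=config.seed + 11)
    sf = surrogate_corr_test(res.overall_template.components[:, 0],
                             fgrad.components[:, 0], ens)
    sf_path = out / "structure_function.json"
    sf_path.write_text(json.dumps(
        {"r_g1_fcg1": sf["r"], "p_surrogate": sf["p_surrogate"]}, indent=1))
    done("coupling", coup_path, diff_path, sf_path)

    stage("plsc")
    beh_cols = [c for c in res.scan_table.columns if c.startswith("beh_")]
    plsc_paths = []
    if beh_cols:
        subj = res.scan_table.groupby("subject_id").first().reset_index()
        # brain variables: per-subject first-scan g1 node scores
        sid_order = {s: i for i, s in enumerate(res.scan_table["scan_id"])}
        X = np.array([g1[sid_order[s]] for s in subj["scan_id"]])
        Y = subj[beh_cols].to_numpy(dtype=float)
        plsc = PLSC(X, Y).fit(n_perm=config.plsc_n_perm,
                              n_boot=config.plsc_n_boot, seed=config.seed + 21)
        sal_path = out / "saliences.tsv"
        pd.DataFrame(plsc.V, columns=[f"lc{j+1}" for j in range(plsc.V.shape[1])]).to_csv(
            sal_path, sep="\t", index=False, float_format="%.10g")
        perm_path = out / "perm.json"
        payload = {"singular_values": plsc.singular_values.tolist(),
                   "perm_p": plsc.perm_p.tolist()}
        if config.plsc_cv and X.shape[0] >= 25:
            cv = plsc_cross_validate(X, Y, n_perm=200, seed=config.seed + 22)
            payload["cv_mean_r"] = cv["mean_r"]
            payload["cv_perm_p"] = cv.get("perm_p")
        perm_path.write_text(json.dumps(payload, indent=1))
        plsc_paths = [sal_path, perm_path]
    done("plsc", *plsc_paths)

    genes_path = dataset / "genes.tsv"
    if genes_path.exists():
        stage("plsr")
        genes = mio.read_matrix_tsv(genes_path)
        effect = node_eff["delta_adj_r2"].to_numpy(dtype=float)
        effect = np.nan_to_num(effect)
        gres = GenePLS(effect, genes).fit(n_boot=config.plsr_n_boot,
                                          seed=config.seed + 31)
        gene_names = np.array([f"gene_{g}" for g in range(genes.shape[1])])
        ranked = pd.DataFrame({
            "gene": gene_names,
            "weight": gres.gene_weights,
            "bootstrap_z": gres.bootstrap_z,
        }).sort_values("bootstrap_z", ascending=False)
        gr_path = out / "genes_ranked.tsv"
        ranked.to_csv(gr_path, sep="\t", index=False, float_format="%.10g")
        done("plsr", gr_path)

        if config.gene_sets:
            stage("enrich")
            sets = mio.read_gmt(config.gene_sets)
            pos, _ = gres.top_sets(gene_names)
            enr = enrichment_with_surrogate_null(
                pos, sets, background=gene_names,
                effect_map=effect, genes_matrix=genes, gene_names=gene_names,
                distance=distance, n_surr=min(config.n_surrogates, 200),
                seed=config.seed + 41,
            )
            e_path = out / "enrichment.tsv"
            enr.to_csv(e_path, sep="\t", index=False, float_format="%.10g")
            done("enrich", e_path)

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _feature_affinity(values: np.ndarray):
    from .gradients import normalized_angle_affinity
    return normalized_angle_affinity(values)
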