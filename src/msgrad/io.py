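"""Plain-text I/O: TSV matrices, cohort layouts, GMT gene sets.

All matrices are written as tab-separated text with a ``node_id`` header
column, rows in node-id order, so every stage can be inspected and diffed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ParcelSet, PlantedTruth, ScanRecord

__all__ = [
    "write_matrix_tsv", "read_matrix_tsv", "write_parcels", "read_parcels",
    "write_cohort", "read_cohort", "read_gmt", "write_gmt",
]


def write_matrix_tsv(path, values: np.ndarray, colnames=None) -> None:
    values = np.asarray(values)
    if colnames is None:
        colnames = [f"n{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, columns=list(colnames))
    df.insert(0, "node_id", np.arange(values.shape[0]))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=["node_id"]).to_numpy(dtype=float)


def write_parcels(path, parcels: ParcelSet) -> None:
    df = pd.DataFrame({
        "node_id": np.arange(parcels.n_nodes),
        "x": parcels.coords[:, 0],
        "y": parcels.coords[:, 1],
        "z": parcels.coords[:, 2],
        "hemisphere": parcels.hemisphere,
        "community": parcels.community,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_parcels(path) -> ParcelSet:
    df = pd.read_csv(path, sep="\t")
    return ParcelSet(
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=df["hemisphere"].to_numpy(),
        community=df["community"].to_numpy(dtype=int),
    )


def write_cohort(
    root,
    parcels: ParcelSet,
    scans: list[ScanRecord],
    truth: PlantedTruth | None = None,
    genes: np.ndarray | None = None,
    signal_genes: np.ndarray | None = None,
) -> None:
    """Write a full synthetic dataset under ``root``.

    Layout: ``parcels.tsv``, ``phenotypes.tsv`` (with behavior columns),
    ``scans/<scan_id>/{gd,profiles,ts,fc}.tsv``, optional ``genes.tsv`` and
    ``truth.json``.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_parcels(root / "parcels.tsv", parcels)
    rows = []
    for s in scans:
        row = {"subject_id": s.subject_id, "scan_id": s.scan_id, "age": s.age,
               "sex": s.sex, "motion": s.motion}
        for b, v in enumerate(s.behavior):
            row[f"beh_{b}"] = v
        rows.append(row)
        sdir = root / "scans" / s.scan_id
        sdir.mkdir(parents=True, exist_ok=True)
        write_matrix_tsv(sdir / "gd.tsv", s.gd)
        write_matrix_tsv(sdir / "profiles.tsv", s.mpc_profiles,
                         colnames=[f"depth_{d}" for d in range(s.mpc_profiles.shape[1])])
        write_matrix_tsv(sdir / "ts.tsv", s.ts)
        write_matrix_tsv(sdir / "fc.tsv", s.fc)
    pd.DataFrame(rows).to_csv(root / "phenotypes.tsv", sep="\t", index=False,
                              float_format="%.10g")
    if genes is not None:
        write_matrix_tsv(root / "genes.tsv", genes,
                         colnames=[f"gene_{g}" for g in range(genes.shape[1])])
    if truth is not None:
        payload = {
            "age_slope": truth.age_slope,
            "autocorr_length": truth.autocorr_length,
            "seed": truth.seed,
            "behavior_weights": truth.behavior_weights.tolist(),
            "contrast_vector": truth.contrast_vector.tolist(),
            "gene_effect_map": truth.gene_effect_map.tolist(),
        }
        if signal_genes is not None:
            payload["signal_genes"] = np.flatnonzero(signal_genes).tolist()
        (root / "truth.json").write_text(json.dumps(payload, indent=1))


def read_cohort(root) -> tuple[ParcelSet, list[ScanRecord], pd.DataFrame]:
    """Read a dataset written by :func:`write_cohort`."""
    root = Path(root)
    parcels = read_parcels(root / "parcels.tsv")
    phen = pd.read_csv(root / "phenotypes.tsv", sep="\t")
    beh_cols = [c for c in phen.columns if c.startswith("beh_")]
    scans = []
    for _, row in phen.iterrows():
        sdir = root / "scans" / str(row["scan_id"])
        scans.append(ScanRecord(
            subject_id=str(row["subject_id"]),
            scan_id=str(row["scan_id"]),
            age=float(row["age"]),
            sex=int(row["sex"]),
            motion=float(row["motion"]),
            gd=read_matrix_tsv(sdir / "gd.tsv"),
            mpc_profiles=read_matrix_tsv(sdir / "profiles.tsv"),
            ts=read_matrix_tsv(sdir / "ts.tsv"),
            fc=read_matrix_tsv(sdir / "fc.tsv"),
            behavior=row[beh_cols].to_numpy(dtype=float),
        ))
    return parcels, scans, phen


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(path, gene_sets: dict[str, list[str]], description: str = "-") -> None:
    lines = [
        "\t".join([name, description] + list(members))
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
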