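"""Functional gradients, structure–function coupling and modular measures.

The functional connectivity (FC) matrix is sparsified row-wise (top 10% of
edges per row), turned into a normalized-angle affinity and embedded with the
same diffusion-map machinery as the structural features; its first component
is the primary-to-transmodal functional hierarchy proxy.  Nodal coupling is
the Spearman correlation between a node's multiscale structural affinity
profile and its FC profile; the participation coefficient quantifies how a
node's strength is spread across communities; differentiation distance
summarizes within/between-community separation in the 2-D gradient space.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gradients import AffinityMatrix, GradientSet, diffusion_map, normalized_angle_affinity
from .metrics import GradientSpace2D

__all__ = [
    "threshold_fc_rows", "fc_gradient", "nodal_coupling",
    "participation_coefficient", "differentiation_distance",
]


def threshold_fc_rows(fc: np.ndarray, top_fraction: float = 0.10) -> np.ndarray:
    """Keep the largest ``top_fraction`` of off-diagonal entries per row.

    The result is used asymmetrically as row profiles; entries below a row's
    threshold become 0.  Rows with fewer positive entries than the quota keep
    what exists, with a warning.
    """
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    k_keep = max(1, int(round(top_fraction * (n - 1))))
    out = np.zeros_like(fc)
    short_rows = []
    for i in range(n):
        row = fc[i].copy()
        row[i] = -np.inf
        idx = np.argpartition(row, -k_keep)[-k_keep:]
        kept = row[idx]
        pos = kept > 0
        if pos.sum() < k_keep:
            short_rows.append(i)
        out[i, idx] = np.maximum(kept, 0.0)
    if short_rows:
        warnings.warn(
            f"{len(short_rows)} row(s) had fewer than {k_keep} positive edges; "
            "kept what exists"
        )
    return out


def fc_gradient(fc: np.ndarray, k: int = 10, top_fraction: float = 0.10,
                alpha: float = 0.5) -> GradientSet:
    """Functional gradient: row-top-10% FC -> normalized angle -> diffusion map."""
    profiles = threshold_fc_rows(fc, top_fraction)
    aff = normalized_angle_affinity(profiles, source="fc")
    return diffusion_map(aff, k=k, alpha=alpha)


def nodal_coupling(ms_affinity: AffinityMatrix | np.ndarray, fc: np.ndarray) -> np.ndarray:
    """Per-node Spearman correlation of structural and functional profiles.

    For node ``i``: Spearman rho between row ``i`` of the fused multiscale
    affinity and row ``i`` of FC, excluding the self-entry in both.  Constant
    rows yield NaN (recorded missing).
    """
    a = np.asarray(getattr(ms_affinity, "values", ms_affinity), dtype=float)
    f = np.asarray(fc, dtype=float)
    if a.shape != f.shape:
        raise ValueError("affinity and FC must share the node set")
    n = a.shape[0]
    rho = np.full(n, np.nan)
    keep = ~np.eye(n, dtype=bool)
    for i in range(n):
        x, y = a[i, keep[i]], f[i, keep[i]]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho[i] = stats.spearmanr(x, y).statistic
    return rho


def participation_coefficient(w: np.ndarray, communities: np.ndarray) -> np.ndarray:
    """Participation coefficient ``1 - sum_s (k_is / k_i)^2`` on nonnegative weights.

    Nodes with zero total strength get 0.  Negative weights are invalid
    (rectify FC to its positive part before calling).
    """
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("participation coefficient requires nonnegative weights")
    labels = np.asarray(communities)
    cats = np.unique(labels)
    strength = w.sum(axis=1)
    frac_sq = np.zeros(w.shape[0])
    safe = np.where(strength > 0, strength, 1.0)
    for c in cats:
        k_is = w[:, labels == c].sum(axis=1)
        frac_sq += (k_is / safe) ** 2
    pac = 1.0 - frac_sq
    pac[strength == 0] = 0.0
    return pac


def differentiation_distance(
    space: GradientSpace2D, communities: np.ndarray
) -> pd.DataFrame:
    """Mean pairwise Euclidean distance within and between communities.

    Distances are taken in the 2-D gradient space (components 1 and 3);
    returns a long-format table with one row per community pair (including
    within pairs) and the mean distance.
    """
    labels = np.asarray(communities)
    cats = np.unique(labels)
    if cats.size < 2:
        raise ValueError("need at least 2 communities")
    pts = space.points
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    rows = []
    for a_i, ca in enumerate(cats):
        ia = np.flatnonzero(labels == ca)
        for cb in cats[a_i:]:
            ib = np.flatnonzero(labels == cb)
            if ca == cb:
                if ia.size < 2:
                    mean = 0.0
                else:
                    sub = d[np.ix_(ia, ia)]
                    mean = float(sub[np.triu_indices(ia.size, k=1)].mean())
            else:
                mean = float(d[np.ix_(ia, ib)].mean())
            rows.append({
                "community_a": ca, "community_b": cb,
                "kind": "within" if ca == cb else "between",
                "mean_distance": mean,
            })
    return pd.DataFrame(rows)
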