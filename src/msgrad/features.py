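"""Preparation of the three multiscale structural features.

Raw payloads become three normalized symmetric matrices on a common [0, 1]
range: microstructure profile covariance (MPC) from cortical depth profiles,
log-transformed tract strength (TS), and inverted geodesic distance (GD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "FeatureMatrix", "DepthProfileSet", "compute_mpc", "log_transform_ts",
    "rank_normalize_rescale", "prepare_features",
]

_R_CLIP = 1.0 - 1e-12


@dataclass
class FeatureMatrix:
    """One symmetric node×node structural feature with a validity mask."""

    values: np.ndarray
    kind: str                   # 'GD' | 'MPC' | 'TS'
    mask: np.ndarray            # boolean, entries treated as present

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("feature matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("feature matrix must be symmetric")
        self.values = v
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class DepthProfileSet:
    """Node×depth intensity profiles sampled on ordered intracortical surfaces."""

    intensities: np.ndarray     # (N, D)

    def __post_init__(self):
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 2 or x.shape[1] < 3:
            raise ValueError("need a node×depth matrix with >= 3 depths")
        if not np.all(np.isfinite(x)):
            raise ValueError("profiles must be finite")
        self.intensities = x


def compute_mpc(profiles: DepthProfileSet | np.ndarray) -> FeatureMatrix:
    """Microstructure profile covariance.

    For every node pair, the partial Pearson correlation of the two depth
    profiles controlling for the cortex-mean profile (both profiles are
    residualized on the mean profile across nodes, then correlated).  Negative
    partial correlations are set to zero and the result is transformed
    elementwise by ``r -> ln((1 + r) / (1 - r))`` (twice the Fisher z), with r
    clipped to ``1 - 1e-12`` beforehand.  The diagonal is zero.

    Nodes with zero residual variance get an all-zero row/column and a warning.
    """
    if not isinstance(profiles, DepthProfileSet):
        profiles = DepthProfileSet(np.asarray(profiles, dtype=float))
    x = profiles.intensities
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    mean_profile = x.mean(axis=0)

    # residualize each profile on [1, mean_profile] across depths
    g = np.column_stack([np.ones_like(mean_profile), mean_profile])
    coef, *_ = np.linalg.lstsq(g, x.T, rcond=None)
    resid = x.T - g @ coef               # (D, N)

    norms = np.linalg.norm(resid, axis=0)
    degenerate = norms < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} node(s) with zero residual profile "
            "variance; their MPC rows are set to 0"
        )
    safe = np.where(degenerate, 1.0, norms)
    u = resid / safe
    r = u.T @ u
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0

    r = np.clip(r, 0.0, _R_CLIP)         # threshold negatives at zero, clip at 1
    mpc = np.log((1.0 + r) / (1.0 - r))
    np.fill_diagonal(mpc, 0.0)
    mpc = (mpc + mpc.T) / 2.0
    mask = mpc != 0.0
    return FeatureMatrix(values=mpc, kind="MPC", mask=mask)


def log_transform_ts(counts: FeatureMatrix | np.ndarray) -> FeatureMatrix:
    """``ln(1 + x)`` on nonzero streamline counts; zeros stay zero and unmasked."""
    if isinstance(counts, FeatureMatrix):
        values = counts.values
    else:
        values = np.asarray(counts, dtype=float)
    if (values < 0).any():
        raise ValueError("streamline counts must be nonnegative")
    mask = values != 0
    out = np.where(mask, np.log1p(values), 0.0)
    np.fill_diagonal(out, 0.0)
    np.fill_diagonal(mask, False)
    return FeatureMatrix(values=out, kind="TS", mask=mask)


def rank_normalize_rescale(m: FeatureMatrix, invert: bool = False) -> FeatureMatrix:
    """Rank-normalize masked entries and min-max rescale them to [0, 1].

    Ranking uses average ties on the upper triangle and is mirrored for
    symmetry.  With ``invert`` (used for GD) the rescaled value ``v`` becomes
    ``1 - v`` so that proximity maps to high affinity.  Unmasked entries stay 0.
    """
    n = m.n_nodes
    iu = np.triu_indices(n, k=1)
    mask_u = m.mask[iu]
    vals = m.values[iu][mask_u]
    if vals.size < 2:
        raise ValueError("need at least 2 masked entries to rank-normalize")
    if np.ptp(vals) == 0:
        warnings.warn("all masked values identical; mapping all to 0.5")
        scaled = np.full(vals.shape, 0.5)
    else:
        ranks = rankdata(vals, method="average")
        scaled = (ranks - ranks.min()) / (ranks.max() - ranks.min())
    if invert:
        scaled = 1.0 - scaled
    flat = np.zeros(iu[0].shape)
    flat[mask_u] = scaled
    out = np.zeros((n, n))
    out[iu] = flat
    out = out + out.T
    new_mask = np.zeros((n, n), dtype=bool)
    new_mask[iu] = mask_u
    new_mask = new_mask | new_mask.T
    return FeatureMatrix(values=out, kind=m.kind, mask=new_mask)


def prepare_features(
    gd: np.ndarray,
    profiles: np.ndarray | DepthProfileSet,
    ts: np.ndarray,
) -> dict[str, FeatureMatrix]:
    """Full per-scan preparation: MPC, log-TS, inverted GD, all rank-rescaled.

    Returns a dict with keys 'GD', 'MPC', 'TS' of normalized FeatureMatrix on
    the shared [0, 1] range.
    """
    gd = np.asarray(gd, dtype=float)
    gd_fm = FeatureMatrix(values=gd, kind="GD", mask=gd != 0)
    mpc = compute_mpc(profiles)
    ts_fm = log_transform_ts(ts)
    return {
        "GD": rank_normalize_rescale(gd_fm, invert=True),
        "MPC": rank_normalize_rescale(mpc),
        "TS": rank_normalize_rescale(ts_fm),
    }
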