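"""Affinity construction, diffusion-map embedding and gradient alignment.

The multiscale affinity fuses the three normalized feature matrices by
horizontally concatenating each node's rows and measuring normalized-angle
similarity between the concatenated profiles.  Diffusion map embedding with
anisotropy ``alpha = 0.5`` turns the affinity into a small set of gradients
ordered by the connectivity variance they explain; Procrustes rotation aligns
individual gradients to group templates so they are comparable across scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AffinityMatrix", "GradientSet", "normalized_angle_affinity",
    "build_multiscale_affinity", "diffusion_map", "procrustes_align",
    "group_template", "feature_contribution", "DEFAULT_AGE_BINS",
]

#: age-bin edges for the six developmental groups 6–7, 8, 9, 10, 11, 12–13
DEFAULT_AGE_BINS = (6.0, 8.0, 9.0, 10.0, 11.0, 12.0, 14.0)


@dataclass
class AffinityMatrix:
    """Symmetric node×node affinity in [0, 1] with unit diagonal."""

    values: np.ndarray
    kernel: str = "normalized_angle"
    source: str = "multiscale"      # 'multiscale' | 'fc' | 'msn'

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("affinity values must lie in [0, 1]")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Node×k embedding with eigenvalues and explanation ratios.

    ``explanation_ratio`` is each retained eigenvalue divided by the sum of
    all non-trivial positive eigenvalues of the diffusion operator
    (``eigenvalue_sum``), so the ratios of the retained components sum to at
    most one.
    """

    components: np.ndarray          # (N, k)
    eigenvalues: np.ndarray         # (k,), descending
    eigenvalue_sum: float           # sum over all non-trivial positive eigenvalues
    alpha: float = 0.5
    alignment_ref: str | None = None

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted in descending order")

    @property
    def n_nodes(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    @property
    def explanation_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalue_sum


def normalized_angle_affinity(profiles: np.ndarray, source: str = "multiscale") -> AffinityMatrix:
    """Normalized-angle similarity between row profiles.

    ``affinity(i, j) = 1 - arccos(cos_sim(p_i, p_j)) / pi`` with cosine
    similarity clipped to [-1, 1].  The diagonal is forced to 1.
    """
    p = np.asarray(profiles, dtype=float)
    norms = np.linalg.norm(p, axis=1)
    bad = np.flatnonzero(norms < 1e-300)
    if bad.size:
        raise ValueError(f"zero-norm profile(s) at node(s) {bad.tolist()}")
    u = p / norms[:, None]
    cos = np.clip(u @ u.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = (aff + aff.T) / 2.0
    np.fill_diagonal(aff, 1.0)
    return AffinityMatrix(values=aff, source=source)


def build_multiscale_affinity(gd, mpc, ts) -> AffinityMatrix:
    """Fuse the three normalized features into one normalized-angle affinity.

    Each node's profile is the concatenation of its GD, MPC and TS rows
    (length 3N); inputs must already be rank-normalized and rescaled.
    """
    mats = [np.asarray(getattr(m, "values", m), dtype=float) for m in (gd, mpc, ts)]
    n = mats[0].shape[0]
    if any(m.shape != (n, n) for m in mats):
        raise ValueError("feature matrices must share the same node set")
    profiles = np.hstack(mats)
    return normalized_angle_affinity(profiles, source="multiscale")


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-magnitude entry is positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] *= -1.0
    return out


def diffusion_map(aff: AffinityMatrix | np.ndarray, k: int = 10, alpha: float = 0.5) -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    Standard construction: degree-normalize ``W`` by ``D^-a W D^-a``,
    row-normalize to a Markov matrix, eigendecompose, drop the trivial
    constant eigenvector and return the next ``k`` right eigenvectors scaled
    by ``lambda / (1 - lambda)`` (the automatic diffusion-time convention).
    Components are deterministic up to the fixed sign convention.
    """
    w = np.asarray(getattr(aff, "values", aff), dtype=float)
    n = w.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp} components with sizes "
            f"{sizes.tolist()}"
        )
    d = w.sum(axis=1)
    if alpha != 0:
        inv_da = d ** (-alpha)
        w1 = w * np.outer(inv_da, inv_da)
    else:
        w1 = w
    d1 = w1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    s = w1 * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # right eigenvectors of the Markov matrix P = D1^-1 W1
    psi = evecs * inv_sqrt[:, None]
    # normalize against the trivial (constant) eigenvector
    psi = psi / psi[:, [0]]
    lam = evals[1:]
    nontrivial_sum = float(np.sum(lam[lam > 0]))
    lam_k = lam[:k]
    scale = lam_k / (1.0 - lam_k)
    comps = _fix_signs(psi[:, 1:k + 1] * scale)
    return GradientSet(
        components=comps,
        eigenvalues=lam_k,
        eigenvalue_sum=nontrivial_sum,
        alpha=alpha,
    )


def procrustes_align(source: GradientSet, target: GradientSet) -> GradientSet:
    """Orthogonal Procrustes alignment of ``source`` onto ``target``.

    Rotation + reflection, no scaling; eigenvalues and explanation ratios are
    carried through unchanged.
    """
    if source.components.shape != target.components.shape:
        raise ValueError("gradient sets must share node count and k")
    m = source.components.T @ target.components
    u, _, vt = np.linalg.svd(m)
    rot = u @ vt
    aligned = source.components @ rot
    return replace(source, components=aligned, alignment_ref="target")


def _mean_features(feature_sets: list[dict]) -> dict:
    kinds = feature_sets[0].keys()
    out = {}
    for kind in kinds:
        vals = np.mean([np.asarray(fs[kind].values) for fs in feature_sets], axis=0)
        out[kind] = vals
    return out


def group_template(
    feature_sets: list[dict],
    ages: np.ndarray,
    bins: tuple[float, ...] = DEFAULT_AGE_BINS,
    k: int = 10,
    alpha: float = 0.5,
) -> tuple[dict[int, GradientSet], GradientSet, np.ndarray]:
    """Age-binned and overall group templates from per-scan normalized features.

    Scans are grouped into age bins; each bin's element-wise mean feature
    matrices are fused and embedded, and the bin template is Procrustes-aligned
    to the all-scan template.  Returns ``(bin_templates, overall, bin_index)``
    where ``bin_index[i]`` is the bin of scan ``i``.
    """
    ages = np.asarray(ages, dtype=float)
    edges = np.asarray(bins, dtype=float)
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        labels = [f"[{edges[b]}, {edges[b+1]})" for b in empty]
        raise ValueError(f"empty age bin(s): {labels}")

    def embed(fsets):
        mean = _mean_features(fsets)
        aff = build_multiscale_affinity(mean["GD"], mean["MPC"], mean["TS"])
        return diffusion_map(aff, k=k, alpha=alpha)

    overall = embed(feature_sets)
    templates = {}
    for b in range(len(edges) - 1):
        members = [feature_sets[i] for i in np.flatnonzero(idx == b)]
        templates[b] = procrustes_align(embed(members), overall)
    return templates, overall, idx


def _partial_corr(x: np.ndarray, y: np.ndarray, controls: np.ndarray) -> float:
    """Partial Pearson correlation of x and y given control columns."""
    z = np.column_stack([np.ones(len(x)), controls])
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return 0.0
    return float(rx @ ry / denom)


def feature_contribution(
    multiscale: GradientSet,
    per_feature: dict[str, GradientSet],
    distance: np.ndarray | None = None,
    n_surrogates: int = 1000,
    n_components: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Contribution of each feature's gradients to the multiscale gradients.

    For each multiscale component and each feature's top components, the
    partial Pearson correlation controlling for the other two features'
    corresponding components.  Significance, when a distance matrix is given,
    comes from variogram-matched surrogates of the multiscale component
    (two-sided, default 1,000 surrogate maps).
    """
    from .nulls import make_surrogates

    kinds = list(per_feature)
    rows = []
    rng_seed = seed
    for m in range(min(n_components, multiscale.k)):
        ms = multiscale.components[:, m]
        ens = None
        if distance is not None:
            ens = make_surrogates(ms, distance, n=n_surrogates, seed=rng_seed + m)
        for kind in kinds:
            others = [k2 for k2 in kinds if k2 != kind]
            for c in range(min(n_components, per_feature[kind].k)):
                y = per_feature[kind].components[:, c]
                controls = np.column_stack(
                    [per_feature[o].components[:, c] for o in others]
                )
                r = _partial_corr(ms, y, controls)
                p = np.nan
                if ens is not None:
                    null = np.array(
                        [_partial_corr(s, y, controls) for s in ens.maps]
                    )
                    p = (1 + np.sum(np.abs(null) >= abs(r))) / (len(null) + 1)
                rows.append(
                    {"ms_component": m + 1, "feature": kind,
                     "feature_component": c + 1, "partial_r": r, "p_surrogate": p}
                )
    return pd.DataFrame(rows)
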