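"""Multivariate inference: PLSC, gene-expression PLSR, enrichment, MSN.

Partial least squares correlation (PLSC) extracts latent components linking
brain variables to behavior by singular value decomposition of the
behavior–brain cross-covariance ``R = Yᵀ X``; permutation tests the singular
values, bootstrap flags stable loadings, and repeated k-fold cross-validation
guards against optimistic in-sample effect sizes.  PLS regression relates a
spatial effect map to a region×gene expression matrix, with bootstrap Z
scores ranking genes and a spatially constrained surrogate null correcting
the subsequent over-representation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .nulls import make_surrogates

__all__ = [
    "PLSC", "PLSCResults", "plsc_cross_validate", "GenePLS", "GenePLSResults",
    "enrichment_with_surrogate_null", "MorphProfile", "morph_pca_and_msn",
]


def _zscore_cols(a: np.ndarray, label: str) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scoring; constant columns are dropped with a warning."""
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s) from {label}")
    z = (a[:, keep] - a[:, keep].mean(axis=0)) / sd[keep]
    return z, keep


@dataclass
class PLSCResults:
    """Latent components of a brain–behavior PLSC fit."""

    singular_values: np.ndarray     # (L,), descending
    U: np.ndarray                   # behavior saliences (q, L), unit columns
    V: np.ndarray                   # brain saliences (p, L), unit columns
    brain_scores: np.ndarray        # Lx = X V
    behavior_scores: np.ndarray     # Ly = Y U
    brain_loadings: np.ndarray      # corr(raw X col, Lx component)
    behavior_loadings: np.ndarray
    perm_p: np.ndarray | None
    bootstrap_keep_brain: np.ndarray | None     # loading CI excludes 0
    bootstrap_keep_behavior: np.ndarray | None
    x_keep: np.ndarray = field(repr=False, default=None)
    y_keep: np.ndarray = field(repr=False, default=None)

    @property
    def explained_covariance(self) -> np.ndarray:
        s2 = self.singular_values ** 2
        return s2 / s2.sum()

    def summary(self) -> str:
        lines = ["PLSC latent components", "=" * 46,
                 f"{'LC':>3} {'singular':>10} {'cov %':>8} {'perm p':>8}"]
        for i, s in enumerate(self.singular_values):
            p = f"{self.perm_p[i]:.4f}" if self.perm_p is not None else "   -"
            lines.append(
                f"{i + 1:>3} {s:>10.4f} {100 * self.explained_covariance[i]:>7.1f}% {p:>8}"
            )
        return "\n".join(lines)


class PLSC:
    """Partial least squares correlation of brain (X) and behavior (Y).

    Columns are z-scored internally; the latent structure is the SVD of
    ``R = Yᵀ X``.  ``fit`` adds permutation p-values per component (row
    shuffling of Y) and bootstrap stability flags for the loadings.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same subjects")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 subjects")
        self.X_raw, self.Y_raw = X, Y
        self.Xz, self.x_keep = _zscore_cols(X, "X")
        self.Yz, self.y_keep = _zscore_cols(Y, "Y")

    @staticmethod
    def _svd(Xz, Yz):
        r = Yz.T @ Xz
        u, s, vt = np.linalg.svd(r, full_matrices=False)
        return u, s, vt.T

    def fit(self, n_perm: int = 1000, n_boot: int = 1000, seed: int = 0,
            perm_align: bool = False) -> PLSCResults:
        """Fit with permutation and bootstrap inference.

        ``perm_align`` projects each permuted cross-covariance onto the
        original singular structure (Procrustes realignment) before reading
        off the null singular values; the default compares singular values
        component-wise without realignment.
        """
        if 0 < n_perm < 100:
            warnings.warn("n_perm < 100 gives a coarse permutation p-value")
        rng = np.random.default_rng(seed)
        u, s, v = self._svd(self.Xz, self.Yz)
        lx = self.Xz @ v
        ly = self.Yz @ u

        def loadings(raw, keep, scores):
            raw = raw[:, keep]
            out = np.empty((raw.shape[1], scores.shape[1]))
            for j in range(scores.shape[1]):
                sc = scores[:, j]
                out[:, j] = [
                    np.corrcoef(raw[:, c], sc)[0, 1] if raw[:, c].std() > 0 else 0.0
                    for c in range(raw.shape[1])
                ]
            return out

        brain_load = loadings(self.X_raw, self.x_keep, lx)
        behav_load = loadings(self.Y_raw, self.y_keep, ly)

        perm_p = None
        if n_perm:
            null = np.empty((n_perm, s.size))
            for b in range(n_perm):
                yz = self.Yz[rng.permutation(self.Yz.shape[0])]
                r_perm = yz.T @ self.Xz
                if perm_align:
                    # Procrustes-rotate the permuted singular structure onto
                    # the original before reading off singular values
                    up, sp, vpt = np.linalg.svd(r_perm, full_matrices=False)
                    wn, _, wpt = np.linalg.svd(v.T @ vpt.T)
                    rot = wpt.T @ wn.T
                    null[b] = np.linalg.norm((vpt.T * sp) @ rot, axis=0)
                else:
                    null[b] = np.linalg.svd(r_perm, compute_uv=False)[: s.size]
            perm_p = (1.0 + (null >= s[None, :]).sum(axis=0)) / (n_perm + 1.0)

        keep_b = keep_y = None
        if n_boot:
            nsub = self.Xz.shape[0]
            bl = np.empty((n_boot,) + brain_load.shape)
            yl = np.empty((n_boot,) + behav_load.shape)
            for b in range(n_boot):
                idx = rng.integers(0, nsub, nsub)
                xz, _ = _zscore_cols(self.X_raw[idx][:, self.x_keep], "Xb")
                yz, _ = _zscore_cols(self.Y_raw[idx][:, self.y_keep], "Yb")
                if xz.shape[1] != self.Xz.shape[1] or yz.shape[1] != self.Yz.shape[1]:
                    bl[b] = brain_load
                    yl[b] = behav_load
                    continue
                ub, sb, vb = self._svd(xz, yz)
                # sign-align bootstrap saliences to the original by cosine
                for j in range(sb.size):
                    c = u[:, j] @ ub[:, j] + v[:, j] @ vb[:, j]
                    if c < 0:
                        ub[:, j] *= -1
                        vb[:, j] *= -1
                bl[b] = loadings(self.X_raw[idx], self.x_keep, xz @ vb)
                yl[b] = loadings(self.Y_raw[idx], self.y_keep, yz @ ub)
            lo_b, hi_b = np.percentile(bl, [2.5, 97.5], axis=0)
            lo_y, hi_y = np.percentile(yl, [2.5, 97.5], axis=0)
            keep_b = (lo_b > 0) | (hi_b < 0)
            keep_y = (lo_y > 0) | (hi_y < 0)

        return PLSCResults(
            singular_values=s, U=u, V=v, brain_scores=lx, behavior_scores=ly,
            brain_loadings=brain_load, behavior_loadings=behav_load,
            perm_p=perm_p, bootstrap_keep_brain=keep_b,
            bootstrap_keep_behavior=keep_y,
            x_keep=self.x_keep, y_keep=self.y_keep,
        )


def plsc_cross_validate(
    X: np.ndarray,
    Y: np.ndarray,
    n_iter: int = 10,
    n_folds: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    component: int = 0,
) -> dict:
    """Out-of-sample PLSC: repeated k-fold composite-score correlation.

    Per fold the saliences are fit on the training subjects (with training
    z-scoring) and applied to the held-out subjects; the test-set Pearson r
    between brain and behavior composites is averaged over folds and
    iterations.  Significance permutes the held-out behavior rows, building a
    null of mean test r.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n < 25:
        raise ValueError("need at least 25 subjects for 5-fold cross-validation")
    rng = np.random.default_rng(seed)
    rs = []
    null_rs = np.zeros(n_perm) if n_perm else None
    n_cells = 0
    for _ in range(n_iter):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        for test_idx in folds:
            if test_idx.size < 3:
                raise ValueError("fold smaller than 3 subjects")
            train_idx = np.setdiff1d(perm, test_idx)
            xm, xs = X[train_idx].mean(0), X[train_idx].std(0)
            ym, ys = Y[train_idx].mean(0), Y[train_idx].std(0)
            xs = np.where(xs > 0, xs, 1.0)
            ys = np.where(ys > 0, ys, 1.0)
            xz_tr = (X[train_idx] - xm) / xs
            yz_tr = (Y[train_idx] - ym) / ys
            u, s, v = PLSC._svd(xz_tr, yz_tr)
            xz_te = (X[test_idx] - xm) / xs
            yz_te = (Y[test_idx] - ym) / ys
            lx = xz_te @ v[:, component]
            ly = yz_te @ u[:, component]
            if lx.std() == 0 or ly.std() == 0:
                continue
            rs.append(np.corrcoef(lx, ly)[0, 1])
            if n_perm:
                for b in range(n_perm):
                    lyp = ly[rng.permutation(ly.size)]
                    null_rs[b] += np.corrcoef(lx, lyp)[0, 1]
            n_cells += 1
    mean_r = float(np.mean(rs))
    out = {"mean_r": mean_r, "fold_r": np.array(rs)}
    if n_perm and n_cells:
        null_mean = null_rs / n_cells
        out["perm_p"] = float((1 + np.sum(null_mean >= mean_r)) / (n_perm + 1))
        out["null_mean_r"] = null_mean
    return out


@dataclass
class GenePLSResults:
    """PLS regression of a spatial effect map on gene expression."""

    component_scores: np.ndarray            # (N, n_components)
    explained_variance_of_response: np.ndarray
    gene_weights: np.ndarray                # PLS1 weight per gene
    bootstrap_z: np.ndarray | None          # weight / bootstrap SD
    top_positive: np.ndarray                # gene indices, top 10% by Z
    top_negative: np.ndarray

    def top_sets(self, gene_names=None):
        pos, neg = self.top_positive, self.top_negative
        if gene_names is not None:
            gene_names = np.asarray(gene_names)
            return gene_names[pos], gene_names[neg]
        return pos, neg


class GenePLS:
    """PLS regression of one response map on a region×gene matrix.

    Gene columns are z-scored internally; weights come from the first
    component (PLS1).  ``fit`` adds bootstrap Z scores (weight divided by its
    SD over region-resampling bootstrap, default 1,000 draws) and the top-10%
    positive and negative gene sets.
    """

    def __init__(self, effect_map: np.ndarray, genes: np.ndarray):
        y = np.asarray(effect_map, dtype=float)
        g = np.asarray(genes, dtype=float)
        if g.shape[0] != y.size:
            raise ValueError("effect map and gene matrix must share regions")
        if y.size < 20:
            warnings.warn("fewer than 20 regions: PLS weights will be unstable")
        self.y = y
        self.genes = g
        sd = g.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        self._mean = g.mean(axis=0)
        self.Gz = (g - self._mean) / self._sd

    def _weights(self, Gz, y, n_components=1):
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Gz, y - y.mean())
        return pls

    def fit(self, n_components: int = 3, n_boot: int = 1000, seed: int = 0,
            top_fraction: float = 0.10) -> GenePLSResults:
        rng = np.random.default_rng(seed)
        n_components = min(n_components, self.y.size - 1, self.Gz.shape[1])
        pls = self._weights(self.Gz, self.y, n_components)
        scores = pls.x_scores_
        yc = self.y - self.y.mean()
        tss = float(yc @ yc)
        evr = np.empty(n_components)
        prev = 0.0
        for c in range(1, n_components + 1):
            sub = PLSRegression(n_components=c, scale=False).fit(self.Gz, yc)
            pred = sub.predict(self.Gz).ravel()
            r2 = 1.0 - np.sum((yc - pred) ** 2) / tss
            evr[c - 1] = r2 - prev
            prev = r2
        w1 = pls.x_weights_[:, 0]
        # orient PLS1 so its score correlates positively with the response
        if np.corrcoef(scores[:, 0], yc)[0, 1] < 0:
            w1 = -w1
            scores = scores.copy()
            scores[:, 0] *= -1

        z = None
        if n_boot:
            n = self.y.size
            boots = np.empty((n_boot, w1.size))
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                gb = self.Gz[idx]
                yb = self.y[idx]
                if yb.std() == 0:
                    boots[b] = w1
                    continue
                wb = self._weights(gb, yb).x_weights_[:, 0]
                if wb @ w1 < 0:
                    wb = -wb
                boots[b] = wb
            sd = boots.std(axis=0)
            z = w1 / np.where(sd > 0, sd, np.inf)
        rank_by = z if z is not None else w1
        n_top = max(1, int(round(top_fraction * w1.size)))
        order = np.argsort(rank_by)
        top_neg = order[:n_top][rank_by[order[:n_top]] < 0]
        top_pos = order[-n_top:][rank_by[order[-n_top:]] > 0]
        return GenePLSResults(
            component_scores=scores,
            explained_variance_of_response=evr,
            gene_weights=w1,
            bootstrap_z=z,
            top_positive=np.sort(top_pos),
            top_negative=np.sort(top_neg),
        )


def _hypergeom_p(overlap: int, n_background: int, n_set: int, n_list: int) -> float:
    return float(stats.hypergeom.sf(overlap - 1, n_background, n_set, n_list))


def enrichment_with_surrogate_null(
    gene_list,
    gene_sets: dict,
    background,
    effect_map: np.ndarray | None = None,
    genes_matrix: np.ndarray | None = None,
    gene_names=None,
    distance: np.ndarray | None = None,
    n_surr: int = 1000,
    side: str = "positive",
    top_fraction: float = 0.10,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation with a spatial-autocorrelation-aware null.

    Per gene set: hypergeometric tail p of the overlap with ``gene_list``
    against ``background``, Benjamini–Hochberg FDR across sets, and — when an
    effect map, gene matrix and distance matrix are supplied — a surrogate
    null: each variogram-matched surrogate of the effect map is pushed through
    PLSR, its top genes are re-tested, and a set counts as significant only if
    the real p lies below the 5th percentile of its surrogate p distribution.
    Sets with no overlap with the background are skipped.
    """
    background = list(background)
    bg = set(background)
    gene_list = [g for g in gene_list if g in bg]
    n_bg, n_list = len(bg), len(gene_list)
    rows = []
    kept_sets = {}
    for name, members in gene_sets.items():
        members_bg = bg.intersection(members)
        if not members_bg:
            continue
        kept_sets[name] = members_bg
        overlap = len(members_bg.intersection(gene_list))
        rows.append({"set": name, "n_set": len(members_bg), "overlap": overlap,
                     "p_hyper": _hypergeom_p(overlap, n_bg, len(members_bg), n_list)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_fdr"] = multipletests(df["p_hyper"], method="fdr_bh")[1]

    if effect_map is not None and genes_matrix is not None and distance is not None:
        if gene_names is None:
            raise ValueError("gene_names required for the surrogate null")
        gene_names = np.asarray(gene_names)
        ens = make_surrogates(np.asarray(effect_map, float), distance, n=n_surr, seed=seed)
        null_p = {name: np.empty(n_surr) for name in kept_sets}
        for b, smap in enumerate(ens.maps):
            res = GenePLS(smap, genes_matrix).fit(n_components=1, n_boot=0)
            idx = res.top_positive if side == "positive" else res.top_negative
            surr_list = set(gene_names[idx]) & bg
            for name, members_bg in kept_sets.items():
                ov = len(members_bg & surr_list)
                null_p[name][b] = _hypergeom_p(ov, n_bg, len(members_bg), len(surr_list))
        ranks = []
        sig = []
        for _, row in df.iterrows():
            null = null_p[row["set"]]
            frac_below = float(np.mean(row["p_hyper"] > null))
            ranks.append(frac_below)
            sig.append(row["p_hyper"] < np.percentile(null, 100 * alpha)
                       and row["p_hyper"] < alpha)
        df["p_surrogate_rank"] = ranks
        df["significant"] = sig
    return df


@dataclass
class MorphProfile:
    """Morphometric PCA and similarity network for one subject."""

    features: np.ndarray            # (N, F) raw features
    pc1: np.ndarray                 # (N,) first principal axis scores
    explained_variance_ratio: np.ndarray
    msn: np.ndarray                 # (N, N) inter-node feature correlation, zero diagonal


def morph_pca_and_msn(features: np.ndarray) -> MorphProfile:
    """PCA of node×feature morphometry and the morphometric similarity network.

    Features are z-scored per column (constant columns dropped with a
    warning); PC1's sign is fixed so its correlation with the first retained
    feature is nonnegative.  MSN(i, j) is the Pearson correlation of the two
    nodes' z-scored feature vectors; the diagonal is zeroed.
    """
    f = np.asarray(features, dtype=float)
    if f.shape[0] < 6:
        raise ValueError("need at least 6 nodes")
    z, keep = _zscore_cols(f, "morphometric features")
    cov = z.T @ z / (z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    pc1 = z @ evecs[:, 0]
    first = z[:, 0]
    if np.corrcoef(pc1, first)[0, 1] < 0:
        pc1 = -pc1
    msn = np.corrcoef(z)
    np.fill_diagonal(msn, 0.0)
    return MorphProfile(
        features=f, pc1=pc1,
        explained_variance_ratio=evals / evals.sum(),
        msn=msn,
    )
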