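"""Penalized-spline mixed models for developmental trajectories.

The model family is an additive mixed model: a response per scan is modeled
as a smooth function of age (cubic regression spline, maximum basis
complexity ``k``, second-derivative penalty, smoothing chosen by restricted
maximum likelihood), linear covariates (sex, motion), and a per-subject
random intercept for longitudinal designs.  The age effect size is the
signed change in adjusted R² between the full model and a reduced model
without the age term (``ΔAdj R²``), with the sign taken from the age
coefficient of the equivalent linear model.

Implementation notes
--------------------
The spline wiggle is reparameterized (Demmler–Reinsch) so that the penalty
is an identity ridge, which turns the penalized spline plus random intercept
into a linear mixed model with two iid variance components.  REML is
maximized over the two log variance ratios with the error variance profiled
out; all matrix work happens on precomputed cross-products so that fitting
many nodes on the same design is cheap.

The smooth-term p-value is a Wald test on the age coefficients (linear +
wiggly) using the Bayesian posterior covariance of the penalized fit, with
the effective degrees of freedom of the age block as the reference
chi-squared df.  This is an approximation: calibration (near-uniform null
p-values), not numerical identity with any particular package, is the
contract, and is verified by simulation in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AgeModelSpec", "SplineAgeModel", "AgeModelResults", "delta_adj_r2",
    "nodewise_age_effects", "cubic_regression_spline",
]


@dataclass(frozen=True)
class AgeModelSpec:
    """Configuration of the age model.

    ``k`` is the maximum basis complexity of the age smooth (default 3, i.e.
    a linear trend plus one penalized wiggle direction); ``random_intercept``
    toggles the per-subject random effect (off for cross-sectional cohorts).
    """

    k: int = 3
    random_intercept: bool = True
    covariates: tuple[str, ...] = ("sex", "motion")
    include_age: bool = True

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("k must be >= 3")


def cubic_regression_spline(x: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cardinal natural cubic spline basis and its curvature penalty.

    Returns ``(B, S)`` where ``B[i, j]`` is the j-th cardinal basis function
    (value 1 at knot j, 0 at the others) evaluated at ``x[i]`` and ``S`` is
    the k×k integrated-squared-second-derivative penalty.  Outside the knot
    range the spline continues linearly (natural boundary conditions).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = knots.size
    if k < 3:
        raise ValueError("need at least 3 knots")
    h = np.diff(knots)
    # D maps basis coefficients to interior second derivatives; B_mat weights them
    D = np.zeros((k - 2, k))
    B_mat = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B_mat[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B_mat[i, i + 1] = B_mat[i + 1, i] = h[i + 1] / 6.0
    F_int = np.linalg.solve(B_mat, D)          # (k-2, k): second derivatives at interior knots
    S = D.T @ F_int                            # curvature penalty
    S = (S + S.T) / 2.0
    Ffull = np.vstack([np.zeros(k), F_int, np.zeros(k)])   # natural: zero at boundaries

    xc = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, xc, side="right") - 1, 0, k - 2)
    hj = h[j]
    am = (knots[j + 1] - xc) / hj
    ap = (xc - knots[j]) / hj
    cm = ((knots[j + 1] - xc) ** 3 / hj - hj * (knots[j + 1] - xc)) / 6.0
    cp = ((xc - knots[j]) ** 3 / hj - hj * (xc - knots[j])) / 6.0
    B = np.zeros((x.size, k))
    rows = np.arange(x.size)
    B[rows, j] += am
    B[rows, j + 1] += ap
    B += cm[:, None] * Ffull[j] + cp[:, None] * Ffull[j + 1]
    # linear extrapolation beyond the boundary knots
    below = x < knots[0]
    above = x > knots[-1]
    if below.any() or above.any():
        eps = 1e-6 * (knots[-1] - knots[0])
        for sel, x0, sgn in ((below, knots[0], 1.0), (above, knots[-1], -1.0)):
            if not sel.any():
                continue
            b0, _ = cubic_regression_spline(np.array([x0, x0 + sgn * eps]), knots)
            slope = sgn * (b0[1] - b0[0]) / eps
            B[sel] = b0[0] + (x[sel] - x0)[:, None] * slope
    return B, S


def _design(
    y: np.ndarray, phen: pd.DataFrame, spec: AgeModelSpec
) -> dict:
    """Assemble fixed, wiggly and subject design blocks from a phenotype table."""
    n = len(y)
    age = phen["age"].to_numpy(dtype=float)
    cols = [np.ones(n)]
    names = ["intercept"]
    for c in spec.covariates:
        v = phen[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"covariate {c!r} has non-finite values")
        cols.append(v - v.mean())
        names.append(c)
    age_cols: list[int] = []
    Zw = np.zeros((n, 0))
    knots = None
    if spec.include_age:
        uniq = np.unique(age)
        if uniq.size < 2:
            raise ValueError("need at least 2 distinct ages")
        if spec.k > uniq.size:
            raise ValueError(f"k={spec.k} exceeds the number of distinct ages")
        qs = np.linspace(0, 1, spec.k)
        knots = np.quantile(uniq, qs)
        B, S = cubic_regression_spline(age, knots)
        evals, evecs = np.linalg.eigh(S)
        pos = evals > evals.max() * 1e-10
        Zw = B @ evecs[:, pos] / np.sqrt(evals[pos])   # penalty becomes identity
        age_cols.append(len(cols))
        cols.append(age - age.mean())
        names.append("age")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design")
    subj = None
    Zs = np.zeros((n, 0))
    if spec.random_intercept:
        subj, subj_idx = np.unique(phen["subject_id"].to_numpy(), return_inverse=True)
        Zs = np.zeros((n, subj.size))
        Zs[np.arange(n), subj_idx] = 1.0
    return {
        "X": X, "names": names, "age_col": age_cols[0] if age_cols else None,
        "Zw": Zw, "Zs": Zs, "subjects": subj, "knots": knots, "age": age,
        "Zs_index": subj_idx if spec.random_intercept else None,
    }


class _REMLWorkspace:
    """Cross-products shared across responses on one design."""

    def __init__(self, X, Zw, Zs):
        self.X, self.Zw, self.Zs = X, Zw, Zs
        self.Z = np.hstack([Zw, Zs])
        self.qw, self.qs = Zw.shape[1], Zs.shape[1]
        self.ZtZ = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ X
        self.XtX = X.T @ X
        self.n, self.p = X.shape

    def crossprods(self, y):
        return self.Z.T @ y, self.X.T @ y, float(y @ y)

    def _gvec(self, theta):
        g = np.empty(self.qw + self.qs)
        i = 0
        if self.qw:
            g[: self.qw] = np.exp(theta[i])
            i += 1
        if self.qs:
            g[self.qw:] = np.exp(theta[i])
        return g

    def neg2_reml(self, theta, Zty, Xty, yty):
        g = self._gvec(theta)
        q = g.size
        n, p = self.n, self.p
        if q:
            gs = np.sqrt(g)
            M = np.eye(q) + gs[:, None] * self.ZtZ * gs[None, :]
            try:
                L = np.linalg.cholesky(M)
            except np.linalg.LinAlgError:
                return np.inf
            logdetV = 2.0 * np.log(np.diag(L)).sum()
            GZtX = gs[:, None] * self.ZtX
            GZty = gs * Zty
            W = np.linalg.solve(L, np.hstack([GZtX, GZty[:, None]]))
            A = self.XtX - W[:, :p].T @ W[:, :p]
            Xvy = Xty - W[:, :p].T @ W[:, p]
            yvy = yty - W[:, p] @ W[:, p]
        else:
            logdetV = 0.0
            A = self.XtX
            Xvy = Xty
            yvy = yty
        try:
            La = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return np.inf
        beta = np.linalg.solve(La.T, np.linalg.solve(La, Xvy))
        quad = max(yvy - Xvy @ beta, 1e-300)
        sigma2 = quad / (n - p)
        return (
            (n - p) * np.log(sigma2) + logdetV
            + 2.0 * np.log(np.diag(La)).sum() + (n - p)
        )

    def solve(self, theta, y):
        """Penalized LS solution, covariance and edf at fixed variance ratios."""
        g = self._gvec(theta)
        C = np.hstack([self.X, self.Z])
        d = np.concatenate([np.zeros(self.p), np.where(g > 0, 1.0 / np.maximum(g, 1e-300), np.inf)])
        d = np.where(np.isfinite(d), d, 1e12)
        H = C.T @ C + np.diag(d)
        Hinv = np.linalg.inv(H)
        delta = Hinv @ (C.T @ y)
        fitted = C @ delta
        rss = float(np.sum((y - fitted) ** 2))
        edf_i = np.einsum("ij,ji->i", Hinv, C.T @ C)
        edf = float(edf_i.sum())
        sigma2 = rss / max(self.n - edf, 1.0)
        Vp = sigma2 * Hinv                     # Bayesian posterior covariance
        # marginal fit: fixed effects + smooth, excluding subject BLUPs, as in
        # the GAMM convention where the random effect lives in the mixed layer
        pm = self.p + self.qw
        fitted_marginal = C[:, :pm] @ delta[:pm]
        rss_m = float(np.sum((y - fitted_marginal) ** 2))
        edf_m = float(edf_i[:pm].sum())
        return {
            "delta": delta, "fitted": fitted, "rss": rss, "edf": edf,
            "edf_i": edf_i, "sigma2": sigma2, "Vp": Vp,
            "fitted_marginal": fitted_marginal, "rss_marginal": rss_m,
            "edf_marginal": edf_m,
        }


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _whiten_by_subject(y, X, subj_idx, tau):
    """Apply V^{-1/2} for V = I + tau * Zs Zs' (blockwise closed form)."""
    if tau <= 0:
        return y, X
    counts = np.bincount(subj_idx)
    a = ((1.0 + tau * counts) ** -0.5 - 1.0) / counts   # per-subject shrink
    def apply(v):
        v = np.asarray(v, dtype=float)
        if v.ndim == 1:
            sums = np.bincount(subj_idx, weights=v)
            return v + a[subj_idx] * sums[subj_idx]
        out = np.empty_like(v)
        for j in range(v.shape[1]):
            out[:, j] = apply(v[:, j])
        return out
    return apply(y), apply(X)


@dataclass
class AgeModelResults:
    """Fit of a penalized-spline age model."""

    fittedvalues: np.ndarray
    adj_r2: float
    p_smooth: float
    edf: float
    edf_age: float
    sigma2: float
    variance_ratios: dict[str, float]
    params: np.ndarray
    model: "SplineAgeModel" = field(repr=False)
    _solution: dict = field(repr=False, default=None)

    def trajectory(self, age_grid: np.ndarray | None = None, n_points: int = 50) -> pd.DataFrame:
        """Fitted age trajectory with covariates at reference (mean) levels."""
        m = self.model
        if not m.spec.include_age:
            raise ValueError("model has no age term")
        age = m._d["age"]
        if age_grid is None:
            age_grid = np.linspace(age.min(), age.max(), n_points)
        B, S = cubic_regression_spline(age_grid, m._d["knots"])
        evals, evecs = np.linalg.eigh(S)
        pos = evals > evals.max() * 1e-10
        Zw_grid = B @ evecs[:, pos] / np.sqrt(evals[pos])
        p = m._ws.p
        beta = self._solution["delta"][:p]
        bw = self._solution["delta"][p:p + m._ws.qw]
        intercept = beta[m._d["names"].index("intercept")]
        lin = beta[m._d["age_col"]] * (age_grid - age.mean())
        fit = intercept + lin + Zw_grid @ bw
        return pd.DataFrame({"age": age_grid, "fit": fit})

    def summary(self) -> str:
        lines = [
            "Penalized-spline age model",
            "=" * 40,
            f"n obs:            {self.model._ws.n}",
            f"adj R2:           {self.adj_r2:.4f}",
            f"edf (total):      {self.edf:.2f}",
            f"edf (age smooth): {self.edf_age:.2f}",
            f"p (age smooth):   {self.p_smooth:.4g}",
            f"sigma2:           {self.sigma2:.4g}",
        ]
        for k, v in self.variance_ratios.items():
            lines.append(f"var ratio {k}: {v:.4g}")
        return "\n".join(lines)


class SplineAgeModel:
    """Additive mixed model of one response against age.

    Parameters
    ----------
    y : (n_scans,) response.
    phenotypes : DataFrame with columns ``age``, ``subject_id`` and the linear
        covariates named in ``spec`` (default ``sex`` and ``motion``).
    spec : AgeModelSpec.
    """

    def __init__(self, y, phenotypes: pd.DataFrame, spec: AgeModelSpec | None = None):
        self.y = np.asarray(y, dtype=float)
        self.phenotypes = phenotypes.reset_index(drop=True)
        if len(self.y) != len(self.phenotypes):
            raise ValueError("response and phenotype table length mismatch")
        self.spec = spec or AgeModelSpec()
        self._d = _design(self.y, self.phenotypes, self.spec)
        self._ws = _REMLWorkspace(self._d["X"], self._d["Zw"], self._d["Zs"])

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, spec: AgeModelSpec | None = None):
        return cls(data[response].to_numpy(dtype=float), data, spec)

    def fit(self) -> AgeModelResults:
        ws = self._ws
        y = self.y
        Zty, Xty, yty = ws.crossprods(y)
        n_theta = int(ws.qw > 0) + int(ws.qs > 0)
        if n_theta:
            obj = lambda th: ws.neg2_reml(th, Zty, Xty, yty)
            res = optimize.minimize(
                obj, np.zeros(n_theta), method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
            )
            theta = np.clip(res.x, -25.0, 25.0)
        else:
            theta = np.zeros(0)
        sol = ws.solve(theta, y)
        self._fitted_tau_subject = float(np.exp(theta[-1])) if ws.qs else 0.0
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss <= 0:
            adj_r2, p_smooth, edf_age = 0.0, 1.0, 0.0
        else:
            # adjusted R² of the marginal (fixed + smooth) fit: subject BLUPs
            # are excluded so the reduced model cannot absorb the age signal
            adj_r2 = 1.0 - (
                sol["rss_marginal"] / max(ws.n - sol["edf_marginal"], 1.0)
            ) / (tss / (ws.n - 1))
            p_smooth, edf_age = self._smooth_test(sol)
        ratios = {}
        i = 0
        if ws.qw:
            ratios["spline"] = float(np.exp(theta[i])); i += 1
        if ws.qs:
            ratios["subject"] = float(np.exp(theta[i]))
        return AgeModelResults(
            fittedvalues=sol["fitted_marginal"],
            adj_r2=float(adj_r2),
            p_smooth=float(p_smooth),
            edf=sol["edf"],
            edf_age=edf_age,
            sigma2=sol["sigma2"],
            variance_ratios=ratios,
            params=sol["delta"][:ws.p],
            model=self,
            _solution=sol,
        )

    def _smooth_test(self, sol) -> tuple[float, float]:
        """ANOVA comparing full and reduced models: F-test on the age block.

        The age columns (linear + wiggly) are tested unpenalized; for
        longitudinal designs the responses and design are first whitened by
        the REML-estimated subject variance (GLS), which keeps the test
        exactly F-distributed in the cross-sectional case and approximately
        so in the mixed case.
        """
        if not self.spec.include_age:
            return 1.0, 0.0
        ws = self._ws
        idx = [self._d["age_col"]] + list(range(ws.p, ws.p + ws.qw))
        edf_age = float(np.clip(sol["edf_i"][idx].sum(), 1.0, len(idx)))

        y = self.y
        Xf = np.hstack([ws.X, ws.Zw])               # full marginal design
        if ws.qs:
            tau = self._fitted_tau_subject
            y, Xf = _whiten_by_subject(y, Xf, self._d["Zs_index"], tau)
        keep = [c for c in range(Xf.shape[1]) if c not in idx]
        rss_f = _ols_rss(Xf, y)
        rss_r = _ols_rss(Xf[:, keep], y)
        q_age = len(idx)
        dfd = ws.n - Xf.shape[1] - (1 if ws.qs else 0)
        if dfd <= 0 or rss_f <= 0:
            return 1.0, edf_age
        f_stat = ((rss_r - rss_f) / q_age) / (rss_f / dfd)
        p = float(stats.f.sf(max(f_stat, 0.0), q_age, dfd))
        return p, edf_age


def _linear_age_sign(y: np.ndarray, phen: pd.DataFrame, spec: AgeModelSpec) -> float:
    """Sign of the age coefficient in the equivalent linear (OLS) model."""
    n = len(y)
    cols = [np.ones(n), phen["age"].to_numpy(dtype=float)]
    for c in spec.covariates:
        cols.append(phen[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return 1.0 if beta[1] >= 0 else -1.0


def delta_adj_r2(
    full: AgeModelResults, reduced: AgeModelResults, linear_sign: float
) -> float:
    """Signed age effect: |adjR²_full − adjR²_reduced| with the linear-model sign."""
    if full.model._ws.n != reduced.model._ws.n:
        raise ValueError("full and reduced fits use different observations")
    return float(abs(full.adj_r2 - reduced.adj_r2) * (1.0 if linear_sign >= 0 else -1.0))


def fit_age_effect(
    y: np.ndarray, phenotypes: pd.DataFrame, spec: AgeModelSpec | None = None
) -> dict:
    """Full/reduced fits and the signed ΔAdj R² for one response."""
    spec = spec or AgeModelSpec()
    y = np.asarray(y, dtype=float)
    if np.std(y) < 1e-300:
        return {"delta_adj_r2": 0.0, "p": 1.0, "full": None, "reduced": None}
    full = SplineAgeModel(y, phenotypes, spec).fit()
    red_spec = AgeModelSpec(
        k=spec.k, random_intercept=spec.random_intercept,
        covariates=spec.covariates, include_age=False,
    )
    reduced = SplineAgeModel(y, phenotypes, red_spec).fit()
    sign = _linear_age_sign(y, phenotypes, spec)
    return {
        "delta_adj_r2": delta_adj_r2(full, reduced, sign),
        "p": full.p_smooth,
        "full": full,
        "reduced": reduced,
    }


def nodewise_age_effects(
    component_scores: np.ndarray,
    phenotypes: pd.DataFrame,
    spec: AgeModelSpec | None = None,
    alpha: float = 0.05,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Per-node age effects with Bonferroni correction.

    ``component_scores`` is scan×node.  Returns a DataFrame with columns
    ``node``, ``delta_adj_r2``, ``p``, ``significant`` (Bonferroni at
    ``alpha``); failed node fits are recorded with NaN, not fatal.
    """
    scores = np.asarray(component_scores, dtype=float)
    n_nodes = scores.shape[1]
    rows = []
    thr = alpha / n_nodes
    for j in range(n_nodes):
        try:
            eff = fit_age_effect(scores[:, j], phenotypes, spec)
            d, p = eff["delta_adj_r2"], eff["p"]
        except Exception as exc:   # keep going; record the failure
            warnings.warn(f"node {j}: age-model fit failed ({exc})")
            d, p = np.nan, np.nan
        rows.append({
            "node": j, "delta_adj_r2": d, "p": p,
            "significant": bool(p < thr) if np.isfinite(p) else False,
        })
    return pd.DataFrame(rows)
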