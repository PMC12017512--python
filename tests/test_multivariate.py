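"""PLSC, cross-validation, gene PLSR, enrichment, morphometric PCA/MSN."""

import numpy as np
import pytest
from scipy import stats

import msgrad as mg
from msgrad.multivariate import _hypergeom_p


def planted_latent(n, p, q, noise, rng):
    t = rng.standard_normal(n)
    vx = rng.standard_normal(p); vx /= np.linalg.norm(vx)
    vy = rng.standard_normal(q); vy /= np.linalg.norm(vy)
    X = np.outer(t, vx) + noise * rng.standard_normal((n, p))
    Y = np.outer(t, vy) + noise * rng.standard_normal((n, q))
    return X, Y, vx, vy


def test_plsc_perfect_latent():
    rng = np.random.default_rng(0)
    X, Y, vx, vy = planted_latent(40, 15, 3, 0.0, rng)
    res = mg.PLSC(X, Y).fit(n_perm=199, n_boot=0, seed=1)
    r = np.corrcoef(res.brain_scores[:, 0], res.behavior_scores[:, 0])[0, 1]
    assert abs(r) == pytest.approx(1.0, abs=1e-8)
    assert res.perm_p[0] == pytest.approx(1.0 / 200.0)


def test_plsc_invariants():
    rng = np.random.default_rng(1)
    X, Y, *_ = planted_latent(50, 12, 4, 0.8, rng)
    m = mg.PLSC(X, Y)
    res = m.fit(n_perm=0, n_boot=0)
    s = res.singular_values
    assert np.all(np.diff(s) <= 1e-12)
    assert np.allclose(np.linalg.norm(res.U, axis=0), 1.0, atol=1e-10)
    assert np.allclose(np.linalg.norm(res.V, axis=0), 1.0, atol=1e-10)
    assert np.allclose(res.brain_scores, m.Xz @ res.V, atol=1e-10)
    assert np.allclose(res.behavior_scores, m.Yz @ res.U, atol=1e-10)
    # conservation: sum of squared singular values = ||R||_F^2
    R = m.Yz.T @ m.Xz
    assert np.sum(s ** 2) == pytest.approx(np.linalg.norm(R) ** 2, rel=1e-8)


def test_plsc_rotated_permutation_variant():
    """The Procrustes-rotated permutation null is exposed behind a flag and
    detects a strong planted latent just like the default null."""
    rng = np.random.default_rng(12)
    X, Y, *_ = planted_latent(60, 10, 3, 0.1, rng)
    res = mg.PLSC(X, Y).fit(n_perm=199, n_boot=0, seed=1, perm_align=True)
    assert res.perm_p[0] == pytest.approx(1.0 / 200.0)
    assert ((res.perm_p >= 0) & (res.perm_p <= 1)).all()


def test_plsc_constant_column_dropped():
    rng = np.random.default_rng(2)
    X, Y, *_ = planted_latent(30, 6, 3, 0.5, rng)
    X[:, 2] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        res = mg.PLSC(X, Y).fit(n_perm=0, n_boot=0)
    assert res.brain_loadings.shape[0] == 5


def test_plsc_bootstrap_flags_real_latent():
    rng = np.random.default_rng(3)
    X, Y, vx, _ = planted_latent(80, 10, 3, 0.3, rng)
    res = mg.PLSC(X, Y).fit(n_perm=0, n_boot=200, seed=4)
    strong = np.abs(vx) > np.percentile(np.abs(vx), 70)
    assert res.bootstrap_keep_brain[strong, 0].mean() > 0.8


def test_plsc_needs_enough_subjects():
    rng = np.random.default_rng(4)
    with pytest.raises(ValueError):
        mg.PLSC(rng.normal(size=(5, 3)), rng.normal(size=(5, 2)))


def test_cross_validation_recovery_and_null():
    rng = np.random.default_rng(5)
    X, Y, *_ = planted_latent(100, 10, 3, 0.05, rng)
    cv = mg.plsc_cross_validate(X, Y, n_iter=2, n_folds=5, n_perm=99, seed=6)
    assert cv["mean_r"] > 0.95
    assert cv["perm_p"] == pytest.approx(1.0 / 100.0)
    # null: mean test r is centered on zero across replicates
    means = []
    for rep in range(25):
        r2 = np.random.default_rng(600 + rep)
        Xn = r2.normal(size=(200, 10))
        Yn = r2.normal(size=(200, 3))
        means.append(mg.plsc_cross_validate(Xn, Yn, n_iter=2, n_folds=5,
                                            n_perm=0, seed=rep)["mean_r"])
    assert abs(np.mean(means)) < 0.05
    with pytest.raises(ValueError):
        mg.plsc_cross_validate(X[:20], Y[:20], n_perm=0)


def test_gene_pls_perfect_predictor_has_top_z():
    rng = np.random.default_rng(8)
    genes = rng.standard_normal((60, 30))
    y = genes[:, 4].copy()
    res = mg.GenePLS(y, genes).fit(n_boot=100, seed=9)
    assert np.argmax(np.abs(res.bootstrap_z)) == 4
    assert 4 in res.top_positive


def test_gene_pls_null_explained_variance_tracks_overfitting_baseline():
    """Null in-sample PLS1 R² concentrates near p/(p+n) and stays small
    when regions comfortably outnumber genes."""
    rng = np.random.default_rng(9)
    evs = []
    for rep in range(5):
        genes = rng.standard_normal((200, 40))
        y = rng.standard_normal(200)
        res = mg.GenePLS(y, genes).fit(n_components=1, n_boot=0)
        evs.append(res.explained_variance_of_response[0])
    assert np.mean(evs) < 0.2
    assert np.mean(evs) == pytest.approx(40 / 240, abs=0.08)


def test_gene_pls_top_fraction_and_disjoint_sets():
    rng = np.random.default_rng(10)
    genes = rng.standard_normal((80, 200))
    y = rng.standard_normal(80)
    res = mg.GenePLS(y, genes).fit(n_boot=50, seed=11)
    assert len(res.top_positive) <= 20 and len(res.top_negative) <= 20
    assert not set(res.top_positive) & set(res.top_negative)
    names = np.array([f"g{i}" for i in range(200)])
    pos, neg = res.top_sets(names)
    assert all(n.startswith("g") for n in np.concatenate([pos, neg]))


def test_hypergeometric_closed_form_toy():
    # 20-gene background, 5-gene set, list of 5 equal to the set
    import math
    p = _hypergeom_p(5, 20, 5, 5)
    expect = 1.0 / math.comb(20, 5)
    assert p == pytest.approx(expect, rel=1e-10)
    assert _hypergeom_p(0, 20, 5, 5) == pytest.approx(1.0)


def test_enrichment_table_and_random_list_uniform():
    rng = np.random.default_rng(11)
    background = [f"g{i}" for i in range(200)]
    sets = {f"set{k}": list(rng.choice(background, 20, replace=False))
            for k in range(20)}
    ps = []
    for rep in range(20):
        lst = list(np.random.default_rng(rep).choice(background, 20, replace=False))
        df = mg.enrichment_with_surrogate_null(lst, sets, background)
        ps.extend(df["p_hyper"].tolist())
    ps = np.asarray(ps)
    assert 0.3 < np.mean(ps) < 0.7          # roughly uniform null
    assert (df.columns[:4] == ["set", "n_set", "overlap", "p_hyper"]).all()
    assert "p_fdr" in df


def test_enrichment_surrogate_null_flags_specific_association(sphere200):
    """A set tied to the effect map specifically (not via shared smoothness)
    survives the surrogate correction; the correction itself guards smooth
    confounds, so a weakly-autocorrelated effect map is the clean test bed."""
    from msgrad.synthetic import truth_with

    parcels, d, _ = sphere200
    rng = np.random.default_rng(12)
    rough = rng.standard_normal(200)
    truth = truth_with(mg.default_truth(parcels, seed=12),
                       gene_effect_map=rough, autocorr_length=0.05)
    genes, is_sig = mg.simulate_gene_matrix(parcels, truth, n_genes=120,
                                            n_signal_genes=12, seed=13,
                                            noise_sd=0.6)
    names = np.array([f"g{i}" for i in range(120)])
    res = mg.GenePLS(truth.gene_effect_map, genes).fit(n_boot=0)
    pos, _ = res.top_sets(names)
    sets = {
        "planted": list(names[is_sig]),
        "random": list(np.random.default_rng(14).choice(names, 12, replace=False)),
    }
    df = mg.enrichment_with_surrogate_null(
        pos, sets, background=names, effect_map=truth.gene_effect_map,
        genes_matrix=genes, gene_names=names, distance=d, n_surr=60, seed=15,
    ).set_index("set")
    planted = df.loc["planted"]
    assert planted["p_hyper"] < 1e-4
    assert bool(planted["significant"])
    assert not bool(df.loc["random"]["significant"])


def test_morph_pca_rank_one_and_oracle():
    rng = np.random.default_rng(16)
    v = rng.standard_normal(40)
    feats = np.outer(v, rng.uniform(0.5, 2.0, 5))
    prof = mg.morph_pca_and_msn(feats)
    r = abs(np.corrcoef(prof.pc1, v)[0, 1])
    assert r == pytest.approx(1.0, abs=1e-10)
    assert prof.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)
    # oracle: eigendecomposition of the 5x5 covariance of z-scored features
    feats = rng.standard_normal((40, 5))
    prof = mg.morph_pca_and_msn(feats)
    z = (feats - feats.mean(0)) / feats.std(0)
    evals, evecs = np.linalg.eigh(np.cov(z.T))
    pc1 = z @ evecs[:, -1]
    assert min(np.abs(np.corrcoef(prof.pc1, pc1)[0, 1]), 1.0) == pytest.approx(1.0, abs=1e-10)
    assert np.corrcoef(prof.pc1, z[:, 0])[0, 1] >= 0    # sign convention


def test_msn_identical_feature_vectors():
    rng = np.random.default_rng(17)
    feats = rng.standard_normal((10, 5))
    feats[1] = feats[0] * 1.0
    prof = mg.morph_pca_and_msn(feats)
    z = (feats - feats.mean(0)) / feats.std(0)
    expect = np.corrcoef(z[0], z[1])[0, 1]
    assert prof.msn[0, 1] == pytest.approx(expect)
    assert np.allclose(np.diag(prof.msn), 0.0)
    with pytest.raises(ValueError):
        mg.morph_pca_and_msn(feats[:4])
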