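"""Affinity kernel, diffusion-map embedding, Procrustes alignment, templates."""

import numpy as np
import pytest
from scipy.linalg import eigh

import msgrad as mg
from msgrad.gradients import DEFAULT_AGE_BINS, group_template


def random_affinity(n, rng):
    w = rng.uniform(0.05, 1.0, (n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return w


def diffusion_oracle(w, k, alpha):
    """Independent dense generalized-eigenproblem construction."""
    d = w.sum(axis=1)
    w1 = w * np.outer(d ** -alpha, d ** -alpha)
    d1 = w1.sum(axis=1)
    evals, evecs = eigh(w1, np.diag(d1))       # generalized: W1 v = lam D1 v
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = evecs / evecs[:, [0]]                # trivial eigenvector -> 1
    lam = evals[1:k + 1]
    return psi[:, 1:k + 1] * (lam / (1 - lam)), evals[1:]


def align_signs(a, b):
    signs = np.sign(np.einsum("ij,ij->j", a, b))
    signs[signs == 0] = 1.0
    return a * signs


def test_affinity_trivial_values():
    profiles = np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0], [0.0, 0.0, 3.0]])
    aff = mg.normalized_angle_affinity(profiles)
    assert aff.values[0, 1] == pytest.approx(1.0)       # parallel profiles
    assert aff.values[0, 2] == pytest.approx(0.5)       # orthogonal profiles
    assert np.allclose(np.diag(aff.values), 1.0)


def test_affinity_matches_double_loop_oracle():
    rng = np.random.default_rng(0)
    profiles = rng.uniform(0.0, 1.0, (10, 30)) + 0.01
    aff = mg.normalized_angle_affinity(profiles)
    for i in range(10):
        for j in range(10):
            cos = profiles[i] @ profiles[j] / (
                np.linalg.norm(profiles[i]) * np.linalg.norm(profiles[j])
            )
            expect = 1.0 - np.arccos(np.clip(cos, -1, 1)) / np.pi
            if i == j:
                expect = 1.0
            assert abs(aff.values[i, j] - expect) < 1e-12


def test_affinity_zero_norm_profile_rejected():
    profiles = np.ones((4, 6))
    profiles[2] = 0.0
    with pytest.raises(ValueError, match="node.*2"):
        mg.normalized_angle_affinity(profiles)


def test_multiscale_affinity_concatenates_rows(small_cohort):
    scans, _ = small_cohort
    fs = mg.prepare_features(scans[0].gd, scans[0].mpc_profiles, scans[0].ts)
    aff = mg.build_multiscale_affinity(fs["GD"], fs["MPC"], fs["TS"])
    profiles = np.hstack([fs["GD"].values, fs["MPC"].values, fs["TS"].values])
    oracle = mg.normalized_angle_affinity(profiles)
    assert np.allclose(aff.values, oracle.values, atol=1e-14)


@pytest.mark.parametrize("n", [30, 40, 50])
def test_diffusion_map_matches_dense_oracle(n):
    rng = np.random.default_rng(n)
    w = random_affinity(n, rng)
    g = mg.diffusion_map(w, k=5, alpha=0.5)
    oracle, lam_all = diffusion_oracle(w, 5, 0.5)
    aligned = align_signs(oracle, g.components)
    assert np.allclose(aligned, g.components, atol=1e-8)
    assert np.allclose(g.eigenvalues, lam_all[:5], atol=1e-10)


def test_diffusion_default_alpha_is_half():
    import inspect
    assert inspect.signature(mg.diffusion_map).parameters["alpha"].default == 0.5


def test_diffusion_block_structure_separated_by_sign():
    n = 12
    w = np.full((n, n), 0.01)
    w[:6, :6] = 0.9
    w[6:, 6:] = 0.9
    np.fill_diagonal(w, 1.0)
    g = mg.diffusion_map(w, k=3)
    s = np.sign(g.components[:, 0])
    assert len(set(s[:6])) == 1 and len(set(s[6:])) == 1 and s[0] != s[6]


def test_diffusion_disconnected_graph_raises():
    w = np.zeros((6, 6))
    w[:3, :3] = 1.0
    w[3:, 3:] = 1.0
    with pytest.raises(ValueError, match="disconnected"):
        mg.diffusion_map(w, k=2)


def test_explanation_ratios_descending_and_bounded():
    rng = np.random.default_rng(7)
    g = mg.diffusion_map(random_affinity(40, rng), k=8)
    er = g.explanation_ratio
    assert np.all(np.diff(er) <= 1e-12)
    assert er.sum() <= 1.0 + 1e-12
    assert np.allclose(er, g.eigenvalues / g.eigenvalue_sum, atol=1e-10)


def test_procrustes_identity_and_reflection():
    rng = np.random.default_rng(1)
    g = mg.diffusion_map(random_affinity(20, rng), k=4)
    same = mg.procrustes_align(g, g)
    assert np.allclose(same.components, g.components, atol=1e-10)
    flipped = mg.GradientSet(
        components=g.components * np.array([-1, 1, 1, 1]),
        eigenvalues=g.eigenvalues, eigenvalue_sum=g.eigenvalue_sum,
    )
    back = mg.procrustes_align(flipped, g)
    assert np.allclose(back.components, g.components, atol=1e-10)


def test_procrustes_recovers_orthogonal_mixing():
    rng = np.random.default_rng(2)
    g = mg.diffusion_map(random_affinity(25, rng), k=4)
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    target = mg.GradientSet(
        components=g.components @ q,
        eigenvalues=g.eigenvalues, eigenvalue_sum=g.eigenvalue_sum,
    )
    aligned = mg.procrustes_align(g, target)
    assert np.allclose(aligned.components, target.components, atol=1e-10)
    assert np.array_equal(aligned.eigenvalues, g.eigenvalues)
    with pytest.raises(ValueError):
        mg.procrustes_align(
            g, mg.GradientSet(components=g.components[:, :2],
                              eigenvalues=g.eigenvalues[:2],
                              eigenvalue_sum=g.eigenvalue_sum),
        )


def test_pipeline_invariant_to_component_sign_flips(small_cohort, parcels100):
    """Post-alignment output does not depend on raw embedding sign choices."""
    scans, _ = small_cohort
    fs = mg.prepare_features(scans[0].gd, scans[0].mpc_profiles, scans[0].ts)
    aff = mg.build_multiscale_affinity(fs["GD"], fs["MPC"], fs["TS"])
    tmpl = mg.diffusion_map(aff, k=6)
    g = mg.diffusion_map(aff, k=6)
    forced = mg.GradientSet(
        components=g.components * np.array([-1, 1, -1, 1, -1, 1]),
        eigenvalues=g.eigenvalues, eigenvalue_sum=g.eigenvalue_sum,
    )
    a = mg.procrustes_align(g, tmpl)
    b = mg.procrustes_align(forced, tmpl)
    assert np.allclose(a.components, b.components, atol=1e-8)


def test_default_age_bins():
    assert DEFAULT_AGE_BINS == (6.0, 8.0, 9.0, 10.0, 11.0, 12.0, 14.0)
    assert len(DEFAULT_AGE_BINS) - 1 == 6


def test_group_template_single_and_identical_scans(small_cohort):
    scans, _ = small_cohort
    fs = mg.prepare_features(scans[0].gd, scans[0].mpc_profiles, scans[0].ts)
    # one scan per bin: bin template equals that scan's gradients up to alignment
    templates, overall, idx = group_template(
        [fs, fs], ages=np.array([6.5, 9.5]), bins=(6.0, 8.0, 14.0), k=5
    )
    solo = mg.diffusion_map(
        mg.build_multiscale_affinity(fs["GD"], fs["MPC"], fs["TS"]), k=5
    )
    aligned = mg.procrustes_align(solo, overall)
    for b in templates:
        assert np.allclose(templates[b].components, aligned.components, atol=1e-8)
    # identical scans in a bin: template equals any member
    templates2, _, _ = group_template(
        [fs, fs, fs], ages=np.array([6.5, 6.6, 9.5]), bins=(6.0, 8.0, 14.0), k=5
    )
    assert np.allclose(templates2[0].components, aligned.components, atol=1e-8)


def test_group_template_empty_bin_raises(small_cohort):
    scans, _ = small_cohort
    fs = mg.prepare_features(scans[0].gd, scans[0].mpc_profiles, scans[0].ts)
    with pytest.raises(ValueError, match="empty age bin"):
        group_template([fs], ages=np.array([6.5]), bins=(6.0, 8.0, 14.0), k=5)


def test_feature_contribution_identical_gradient_dominates():
    rng = np.random.default_rng(3)
    n = 60
    base = mg.diffusion_map(random_affinity(n, rng), k=3)
    noise = {
        "GD": base,
        "MPC": mg.GradientSet(components=rng.normal(size=(n, 3)),
                              eigenvalues=np.array([3.0, 2.0, 1.0]),
                              eigenvalue_sum=10.0),
        "TS": mg.GradientSet(components=rng.normal(size=(n, 3)),
                             eigenvalues=np.array([3.0, 2.0, 1.0]),
                             eigenvalue_sum=10.0),
    }
    table = mg.feature_contribution(base, noise, distance=None, n_components=1)
    gd_r = table.query("feature == 'GD' and feature_component == 1")["partial_r"].iloc[0]
    assert gd_r > 0.99
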