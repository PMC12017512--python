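"""Synthetic longitudinal cohort with planted developmental effects.

The generator emulates the inputs of a multiscale structural connectome study
of school-age development: a spherical parcellation standing in for a cortical
atlas, per-scan structural features (geodesic distance, cortical depth
intensity profiles, streamline counts), a functional connectivity matrix,
behavior scores, and a spatially autocorrelated region×gene expression matrix.

A ``PlantedTruth`` object holds the ground truth every downstream stage is
tested against: a smooth primary-vs-transmodal contrast map whose expression
in the microstructure profiles scales linearly with age, per-subject random
intercepts, behavior scores linearly coupled to the realized contrast
amplitude, and a target map for gene-association tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ParcelSet", "PlantedTruth", "SubjectState", "ScanRecord",
    "make_parcels", "default_truth", "simulate_scan", "simulate_cohort",
    "simulate_gene_matrix", "great_circle_distance",
]

#: default proportions of subjects with 1, 2 and 3 scans, mirroring an
#: accelerated-longitudinal design (159/83/39 of 281 subject slots).
DEFAULT_SCAN_DISTRIBUTION = {1: 0.57, 2: 0.30, 3: 0.13}

DEFAULT_AGE_RANGE = (6.0, 14.0)


@dataclass(frozen=True)
class ParcelSet:
    """A spherical parcellation: node coordinates, hemispheres, communities."""

    coords: np.ndarray          # (N, 3) unit vectors
    hemisphere: np.ndarray      # (N,) 'L' / 'R'
    community: np.ndarray       # (N,) integer labels 0..C-1

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_communities(self) -> int:
        return int(self.community.max()) + 1

    def distance(self) -> np.ndarray:
        """Pairwise great-circle distances (radians on the unit sphere)."""
        return great_circle_distance(self.coords)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted developmental effect.

    Parameters
    ----------
    contrast_vector : (N,) zero-mean, unit-variance spatial contrast whose
        amplitude in the depth profiles grows with age.
    age_slope : per-year relative growth of the contrast amplitude (1/year).
    behavior_weights : (B,) linear weights mapping the realized per-scan
        contrast amplitude to behavior scores.
    gene_effect_map : (N,) planted spatial target for gene-association tests.
    autocorr_length : range parameter of the spatial autocorrelation used for
        gene maps (radians, same units as inter-node great-circle distance).
    """

    contrast_vector: np.ndarray
    age_slope: float
    behavior_weights: np.ndarray
    gene_effect_map: np.ndarray
    autocorr_length: float
    seed: int
    # noise / scale knobs of the feature model
    profile_signal: float = 1.0     # amplitude of the contrast in depth profiles
    profile_noise: float = 0.45     # iid noise sd on profile intensities
    subject_sd: float = 0.10        # sd of per-subject random intercept (amplitude units)
    gd_jitter: float = 0.01         # positive jitter on geodesic distances
    ts_scale: float = 30.0          # expected streamline count at distance 0
    ts_decay: float = 0.5           # exponential distance-decay length (radians)
    ts_dispersion: float = 2.0      # negative-binomial shape (smaller = more dispersed)
    community_bonus: float = 0.5    # relative within-community streamline bonus
    fc_noise: float = 0.10          # noise sd added before the monotone FC transform
    fc_community: float = 0.15      # community block signal in FC
    behavior_noise: float = 0.5     # sd of behavior score noise
    n_depths: int = 12

    def __post_init__(self):
        if self.autocorr_length <= 0:
            raise ValueError("autocorr_length must be positive")
        c = np.asarray(self.contrast_vector, dtype=float)
        if abs(c.mean()) > 1e-8 or abs(c.std() - 1.0) > 1e-8:
            raise ValueError("contrast_vector must have zero mean and unit variance")


@dataclass(frozen=True)
class SubjectState:
    """Per-subject latent state shared by all of the subject's scans."""

    subject_id: str
    intercept: float    # random offset of the contrast amplitude
    sex: int            # 0 / 1


@dataclass
class ScanRecord:
    """One scan's raw feature payloads plus phenotype covariates."""

    subject_id: str
    scan_id: str
    age: float
    sex: int
    motion: float
    gd: np.ndarray               # (N, N) symmetric nonnegative, zero diagonal
    mpc_profiles: np.ndarray     # (N, D) depth intensity profiles
    ts: np.ndarray               # (N, N) symmetric integer counts
    fc: np.ndarray               # (N, N) correlation matrix
    behavior: np.ndarray         # (B,) scores


def great_circle_distance(coords: np.ndarray) -> np.ndarray:
    """Pairwise arc length between unit vectors (radians)."""
    dots = np.clip(coords @ coords.T, -1.0, 1.0)
    d = np.arccos(dots)
    np.fill_diagonal(d, 0.0)
    return d


def make_parcels(n_nodes: int, n_communities: int, seed: int = 0) -> ParcelSet:
    """Fibonacci-spiral parcellation of the unit sphere.

    Hemispheres are split by the sign of the x coordinate; communities are
    contiguous latitude bands of (near-)equal size, playing the role of
    intrinsic functional networks.  Deterministic for a given seed (the seed
    rotates the spiral's azimuthal phase).
    """
    if n_nodes < 4 * n_communities:
        raise ValueError(
            f"n_nodes={n_nodes} too small for n_communities={n_communities}: "
            "need n_nodes >= 4 * n_communities"
        )
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * math.pi)
    i = np.arange(n_nodes)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_nodes
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i + phase
    coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)

    hemisphere = np.where(coords[:, 0] < 0, "L", "R")

    # contiguous latitude bands with equal-count split; community 0 is the
    # top band (the positive pole of the default planted contrast)
    order = np.argsort(-coords[:, 2], kind="stable")
    community = np.empty(n_nodes, dtype=int)
    for c, chunk in enumerate(np.array_split(order, n_communities)):
        community[chunk] = c
    return ParcelSet(coords=coords, hemisphere=hemisphere, community=community)


def default_truth(
    parcels: ParcelSet,
    age_slope: float = 0.05,
    behavior_weights: np.ndarray | None = None,
    autocorr_length: float = 0.3,
    seed: int = 0,
    **overrides,
) -> PlantedTruth:
    """Build the default planted truth for a parcellation.

    The contrast vector is the standardized latitude (z coordinate), so the
    planted primary-vs-transmodal axis runs pole to pole and aligns with the
    community bands.  The gene-effect map reuses the same axis, mimicking the
    situation where the developmental effect map is itself the target of the
    gene-association analysis.
    """
    z = parcels.coords[:, 2].astype(float)
    contrast = (z - z.mean()) / z.std()
    if behavior_weights is None:
        behavior_weights = np.array([1.0, -0.6])
    return PlantedTruth(
        contrast_vector=contrast,
        age_slope=float(age_slope),
        behavior_weights=np.asarray(behavior_weights, dtype=float),
        gene_effect_map=contrast.copy(),
        autocorr_length=float(autocorr_length),
        seed=int(seed),
        **overrides,
    )


def _depth_shape(n_depths: int) -> tuple[np.ndarray, np.ndarray]:
    """Cortex-mean depth profile and the contrast's depth loading pattern."""
    d = np.linspace(0.0, 1.0, n_depths)
    base = 1.5 - 0.8 * d                # mean intensity decays toward white matter
    loading = np.linspace(-1.0, 1.0, n_depths)  # contrast tilts the profile
    return base, loading


def amplitude(truth: PlantedTruth, age: float, subject_intercept: float = 0.0) -> float:
    """Realized contrast amplitude of a scan: 1 + age·slope + subject offset."""
    return 1.0 + truth.age_slope * age + subject_intercept


def simulate_scan(
    parcels: ParcelSet,
    truth: PlantedTruth,
    age: float,
    subject_state: SubjectState,
    rng: np.random.Generator | None = None,
    scan_id: str = "s0",
) -> ScanRecord:
    """Simulate one scan's full feature payload.

    * GD: great-circle distance plus small symmetric positive jitter.
    * Depth profiles: mean depth shape plus the planted contrast scaled by
      ``1 + age·age_slope + subject intercept`` times a depth-loading pattern,
      plus iid Gaussian noise.  Nodes at the same end of the contrast thus have
      correlated residual profiles, which MPC picks up.
    * TS: negative-binomial streamline counts whose expectation decays
      exponentially with distance, with a within-community bonus.
    * FC: noisy monotone (tanh) transform of a fused structural similarity
      plus a community block signal; unit diagonal.
    * Behavior: ``behavior_weights`` times the realized contrast amplitude plus
      Gaussian noise.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n = parcels.n_nodes
    d = parcels.distance()

    jit = rng.uniform(0.0, truth.gd_jitter, size=(n, n))
    jit = (jit + jit.T) / 2.0
    gd = d + jit
    np.fill_diagonal(gd, 0.0)

    amp = amplitude(truth, age, subject_state.intercept)
    base, loading = _depth_shape(truth.n_depths)
    signal = truth.profile_signal * amp * np.outer(truth.contrast_vector, loading)
    profiles = base[None, :] + signal + rng.normal(0.0, truth.profile_noise, size=(n, truth.n_depths))

    same_comm = parcels.community[:, None] == parcels.community[None, :]
    mu = truth.ts_scale * np.exp(-d / truth.ts_decay) * (1.0 + truth.community_bonus * same_comm)
    # negative binomial with shape r: p = r / (r + mu)
    r_shape = truth.ts_dispersion
    p = r_shape / (r_shape + mu)
    counts = rng.negative_binomial(r_shape, p)
    ts = np.triu(counts, 1)
    ts = ts + ts.T

    z = amp * truth.contrast_vector
    struct_sim = np.exp(-d / truth.ts_decay) + 0.15 * np.outer(z, z) / max(1.0, np.abs(z).max() ** 2)
    noise = rng.normal(0.0, truth.fc_noise, size=(n, n))
    fc = np.tanh(struct_sim + truth.fc_community * same_comm + (noise + noise.T) / 2.0)
    np.fill_diagonal(fc, 1.0)

    behavior = truth.behavior_weights * amp + rng.normal(
        0.0, truth.behavior_noise, size=truth.behavior_weights.shape
    )
    motion = float(rng.gamma(2.0, 0.05))

    return ScanRecord(
        subject_id=subject_state.subject_id,
        scan_id=scan_id,
        age=float(age),
        sex=subject_state.sex,
        motion=motion,
        gd=gd,
        mpc_profiles=profiles,
        ts=ts,
        fc=fc,
        behavior=behavior,
    )


def simulate_cohort(
    parcels: ParcelSet,
    truth: PlantedTruth,
    n_subjects: int,
    scans_per_subject_distribution: dict[int, float] | None = None,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    seed: int | None = None,
) -> tuple[list[ScanRecord], PlantedTruth]:
    """Simulate an accelerated-longitudinal cohort.

    Subjects receive 1–3 scans; within-subject age increments are at least
    0.5 year.  A per-subject random intercept enters the contrast amplitude of
    every feature, so the mixed model's random effect is identifiable.
    """
    if n_subjects < 10:
        raise ValueError("n_subjects must be >= 10")
    dist = scans_per_subject_distribution or DEFAULT_SCAN_DISTRIBUTION
    ks = sorted(dist)
    probs = np.array([dist[k] for k in ks], dtype=float)
    probs = probs / probs.sum()
    lo, hi = age_range
    max_scans = max(ks)
    if hi - lo < 0.5 * (max_scans - 1):
        raise ValueError(
            f"age range {age_range} cannot accommodate {max_scans} scans "
            "with 0.5-year minimum increments"
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    scans: list[ScanRecord] = []
    for s in range(n_subjects):
        n_scans = int(rng.choice(ks, p=probs))
        gaps = rng.uniform(0.5, 1.5, size=n_scans - 1)
        # shrink gaps if the range cannot hold them
        total = gaps.sum()
        if total > hi - lo:
            gaps *= (hi - lo) / total * 0.99
            if n_scans > 1 and gaps.min() < 0.5:
                raise ValueError("infeasible age increments for the given age range")
        first = rng.uniform(lo, hi - gaps.sum())
        ages = first + np.concatenate([[0.0], np.cumsum(gaps)])
        state = SubjectState(
            subject_id=f"sub-{s:04d}",
            intercept=float(rng.normal(0.0, truth.subject_sd)),
            sex=int(rng.integers(0, 2)),
        )
        for t, age in enumerate(ages):
            scans.append(
                simulate_scan(
                    parcels, truth, age, state, rng=rng,
                    scan_id=f"sub-{s:04d}_ses-{t}",
                )
            )
    return scans, truth


def simulate_gene_matrix(
    parcels: ParcelSet,
    truth: PlantedTruth,
    n_genes: int,
    n_signal_genes: int,
    seed: int | None = None,
    signal_loading: float = 0.8,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Region×gene expression with spatially autocorrelated columns.

    Signal genes are ``loading · gene_effect_map`` plus a Gaussian random
    field with exponential covariance of range ``autocorr_length`` on the
    sphere; null genes are pure autocorrelated noise.  Returns the (N, G)
    matrix and a boolean mask of the signal genes.
    """
    if n_signal_genes >= n_genes:
        raise ValueError("n_signal_genes must be < n_genes")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = parcels.n_nodes
    d = parcels.distance()
    cov = np.exp(-d / truth.autocorr_length) + 1e-8 * np.eye(n)
    chol = np.linalg.cholesky(cov)
    field_noise = chol @ rng.standard_normal((n, n_genes)) * noise_sd
    genes = field_noise
    is_signal = np.zeros(n_genes, dtype=bool)
    is_signal[:n_signal_genes] = True
    genes[:, is_signal] += signal_loading * truth.gene_effect_map[:, None]
    return genes, is_signal


def truth_with(truth: PlantedTruth, **kwargs) -> PlantedTruth:
    """Return a copy of ``truth`` with fields replaced."""
    return replace(truth, **kwargs)
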