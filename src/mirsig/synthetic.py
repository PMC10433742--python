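"""Synthetic expression data with the exact structure the pipeline assumes.

The generator emulates a miR-mimic transfection microarray experiment: three
groups (negative-control mimic and two miR mimics, n = 6 each), five planted
clusters of co-expressed genes whose group shift patterns mirror the C1–C5
archetypes (down in A; up in B; down in both; up in both; up in A / down in
B), gene-level variances drawn from a scaled inverse chi-square law so that
empirical-Bayes shrinkage is recoverable, target-list membership enriched in
the planted clusters at known fold, optional smooth monotone per-sample
distortions to exercise LOWESS correction, and an external cohort whose two
sample subpopulations differ on the signature genes.

For cluster genes, x_gj = mu_g + a_g*(pattern_c[group(j)] + cofactor_sd*z_cj)
+ eps_gj, with z_cj a per-sample latent factor shared across the cluster and
a_g > 0 per-gene loadings; background genes are mu_g + eps_gj. Noise is
eps_gj ~ N(0, sigma_g^2), sigma_g^2 ~ s0_sq*d0/chi2(d0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TargetCollection
from .matrix import ExpressionMatrix

#: log2 microarray-like dynamic range for baseline means mu_g
MU_RANGE = (4.0, 12.0)


@dataclass
class ClusterSpec:
    """One planted co-expression cluster.

    ``pattern`` is the mean log2 shift per group (control first, always 0);
    ``loading_sd`` spreads the per-gene effect loadings a_g around 1
    (0 = homogeneous loadings, the default: with the heavy-tailed variance
    prior, cluster recovery under the fractional tree cut is already at its
    testable boundary, so extra loading heterogeneity is opt-in);
    ``cofactor_sd`` sets the strength of the shared within-cluster latent
    factor that makes member genes correlate beyond their group shifts.
    """

    size: int
    pattern: tuple[float, ...]
    loading_sd: float = 0.0
    cofactor_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("cluster size must be >= 2")
        if self.pattern[0] != 0:
            raise ValueError("pattern for the control (first) group must be 0")


@dataclass
class DistortionSpec:
    """Smooth monotone per-sample intensity distortion
    y = x + c1_j*(x − x̄_j) + c2_j*(x − x̄_j)², with |c1| ≤ c1_max and
    |c2| ∈ [c2_min, c2_max] (random sign). The defaults keep the transform
    monotone on the [4, 12] log2 range while planting an M-vs-A trend of
    amplitude ≥ 0.3."""

    c1_max: float = 0.05
    c2_min: float = 0.02
    c2_max: float = 0.03


@dataclass
class TargetSpec:
    """One target list: baseline membership probability plus per-cluster
    enrichment folds φ_c (cluster id → fold; membership probability becomes
    min(1, φ_c·background_rate) inside cluster c)."""

    name: str
    background_rate: float
    fold: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")
        if any(phi < 0 for phi in self.fold.values()):
            raise ValueError("enrichment folds must be >= 0")


def default_clusters(size: int = 400) -> list[ClusterSpec]:
    """Five clusters mirroring the C1–C5 shift archetypes (groups:
    control, mimic A, mimic B)."""
    patterns = [
        (0.0, -1.0, 0.0),  # down in A only
        (0.0, 0.0, 1.0),   # up in B only
        (0.0, -1.0, -1.0), # down in both
        (0.0, 1.0, 1.0),   # up in both
        (0.0, 1.0, -1.0),  # opposite directions
    ]
    return [ClusterSpec(size=size, pattern=p) for p in patterns]


def default_target_specs() -> list[TargetSpec]:
    """Two miR-style target lists, each enriched in the clusters its mimic
    shifts, at 4-fold over a 10% background rate."""
    return [
        TargetSpec("targets_A", 0.1, {1: 4.0, 3: 4.0, 4: 4.0, 5: 4.0}),
        TargetSpec("targets_B", 0.1, {2: 4.0, 3: 4.0, 4: 4.0, 5: 4.0}),
    ]


@dataclass
class SyntheticConfig:
    n_genes: int = 12000
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [("control", 6), ("mimicA", 6), ("mimicB", 6)]
    )
    clusters: list[ClusterSpec] = field(default_factory=default_clusters)
    eb_prior: tuple[float, float] = (4.0, 0.05)  # (d0, s0_sq)
    distortion: DistortionSpec | None = None
    #: None = the default miR-style lists, with folds trimmed to the clusters present
    target_specs: list[TargetSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_specs is None:
            n = len(self.clusters)
            self.target_specs = [
                TargetSpec(s.name, s.background_rate,
                           {c: f for c, f in s.fold.items() if c <= n})
                for s in default_target_specs()
            ]
        total = sum(c.size for c in self.clusters)
        if self.n_genes < total:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than total cluster size {total}"
            )
        d0, s0_sq = self.eb_prior
        if d0 <= 0 or s0_sq <= 0:
            raise ValueError("eb_prior components must be positive")
        for spec in self.target_specs:
            for cid in spec.fold:
                if not 1 <= cid <= len(self.clusters):
                    raise ValueError(f"target spec {spec.name!r}: unknown cluster {cid}")
        for c in self.clusters:
            if len(c.pattern) != len(self.groups):
                raise ValueError("cluster pattern length must equal group count")


@dataclass
class SyntheticDataset:
    matrix: ExpressionMatrix
    truth_clusters: pd.Series  # gene -> cluster id (0 = background)
    truth_targets: TargetCollection
    truth_variances: pd.Series  # gene -> sigma^2


# ---------------------------------------------------------------------------


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset under the stated generative model; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    sample_ids, group_labels = [], []
    for label, n in config.groups:
        if n < 1:
            raise ValueError(f"group {label!r} has no samples")
        sample_ids += [f"{label}_{i + 1}" for i in range(n)]
        group_labels += [label] * n
    n_samples = len(sample_ids)
    group_of = np.array(
        [list(dict(config.groups)).index(g) for g in group_labels]
    )

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    mu = rng.uniform(*MU_RANGE, size=n_genes)
    d0, s0_sq = config.eb_prior
    sigma2 = s0_sq * d0 / rng.chisquare(d0, size=n_genes)

    # cluster gene positions: scattered over the chip for realism
    truth = np.zeros(n_genes, dtype=int)
    total = sum(c.size for c in config.clusters)
    positions = rng.choice(n_genes, size=total, replace=False)
    offset = 0
    for cid, spec in enumerate(config.clusters, start=1):
        truth[positions[offset : offset + spec.size]] = cid
        offset += spec.size

    X = mu[:, None] + rng.normal(0.0, np.sqrt(sigma2)[:, None], size=(n_genes, n_samples))
    for cid, spec in enumerate(config.clusters, start=1):
        idx = np.flatnonzero(truth == cid)
        loadings = np.abs(rng.normal(1.0, spec.loading_sd, size=len(idx)))
        loadings = np.maximum(loadings, 0.1)
        z = rng.standard_normal(n_samples)
        pattern = np.asarray(spec.pattern)[group_of]
        X[idx] += loadings[:, None] * (pattern + spec.cofactor_sd * z)[None, :]

    if config.distortion is not None:
        X = _apply_distortion(X, config.distortion, rng)

    values = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    matrix = ExpressionMatrix(values, groups)
    targets = generate_target_lists(
        pd.Series(truth, index=gene_ids), config.target_specs, rng
    )
    return SyntheticDataset(
        matrix=matrix,
        truth_clusters=pd.Series(truth, index=gene_ids, name="cluster"),
        truth_targets=targets,
        truth_variances=pd.Series(sigma2, index=gene_ids, name="sigma2"),
    )


def _apply_distortion(
    X: np.ndarray, spec: DistortionSpec, rng: np.random.Generator
) -> np.ndarray:
    n_samples = X.shape[1]
    c1 = rng.uniform(-spec.c1_max, spec.c1_max, size=n_samples)
    c2 = rng.uniform(spec.c2_min, spec.c2_max, size=n_samples)
    c2 *= rng.choice([-1.0, 1.0], size=n_samples)
    centered = X - X.mean(axis=0)[None, :]
    return X + c1[None, :] * centered + c2[None, :] * centered**2


def generate_target_lists(
    truth_clusters: pd.Series,
    target_specs: list[TargetSpec],
    seed,
) -> TargetCollection:
    """Bernoulli target membership: rate background_rate outside clusters,
    min(1, φ_c·background_rate) inside cluster c."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = truth_clusters.to_numpy()
    n_clusters = int(truth.max()) if len(truth) else 0
    sets: dict[str, set[str]] = {}
    for spec in target_specs:
        for cid in spec.fold:
            if cid > n_clusters:
                raise ValueError(f"target spec {spec.name!r}: unknown cluster {cid}")
        rates = np.full(len(truth), spec.background_rate)
        for cid, phi in spec.fold.items():
            rates[truth == cid] = min(1.0, phi * spec.background_rate)
        member = rng.random(len(truth)) < rates
        sets[spec.name] = set(truth_clusters.index[member])
    return TargetCollection(sets, background=set(truth_clusters.index))


def generate_external_cohort(
    signature_genes,
    n_samples_per_branch: int = 20,
    effect: float = 2.0,
    n_extra_genes: int = 2000,
    eb_prior: tuple[float, float] = (4.0, 0.05),
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """An external cohort with two sample subpopulations differing on the
    signature genes by ±effect/2 mean log2 shift; all other genes are
    independent noise. Returns (matrix, truth branch labels)."""
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise ValueError("signature is empty")
    if n_samples_per_branch < 2:
        raise ValueError("need at least 2 samples per branch")
    rng = np.random.default_rng(seed)
    gene_ids = signature_genes + [f"BG{i:05d}" for i in range(n_extra_genes)]
    n_genes = len(gene_ids)
    n_samples = 2 * n_samples_per_branch
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    branch = np.array([0] * n_samples_per_branch + [1] * n_samples_per_branch)
    # shuffle so branch is not confounded with sample order
    rng.shuffle(branch)
    d0, s0_sq = eb_prior
    mu = rng.uniform(*MU_RANGE, size=n_genes)
    sigma2 = s0_sq * d0 / rng.chisquare(d0, size=n_genes)
    X = mu[:, None] + rng.normal(0.0, np.sqrt(sigma2)[:, None], size=(n_genes, n_samples))
    shift = np.where(branch == 0, -effect / 2.0, effect / 2.0)
    sign = rng.choice([-1.0, 1.0], size=len(signature_genes))
    X[: len(signature_genes)] += sign[:, None] * shift[None, :]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=gene_ids, columns=sample_ids))
    truth = pd.Series(
        np.where(branch == 0, "B1", "B2"), index=sample_ids, name="branch"
    )
    return matrix, truth
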