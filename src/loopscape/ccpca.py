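"""Contact-contact PCA (ccPCA), free-energy landscapes and OPTICS clustering.

The ccPCA workflow characterises how one chain samples binding
configurations on another:

1. Build an equal-size heavy-atom *contact mesh* across the two chains:
   the smaller chain contributes all m heavy atoms, the larger chain m
   atoms picked with a uniform stride, and the feature set is the m x m
   cross product of mesh pairs.
2. Collect the per-frame Euclidean distance of every mesh pair into a
   feature matrix (frames x pairs, Angstrom).
3. Fit a PCA on the centred (unscaled) features and project frames onto
   the leading two components.
4. Convert the 2D score histogram into a Gibbs free-energy landscape by
   Boltzmann inversion, dG = -R T ln(P / max P), so the modal bin sits at
   dG = 0 and rarer states climb uphill.
5. Cluster the scores with OPTICS (xi extraction) and summarise each
   cluster's occluding-loop state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import OPTICS

from .contact_analysis import FrameFilter
from .ensemble_io import StructureEnsemble, Topology
from .errors import InputError
from .loop_state import DistanceTrace
from .presets import DEFAULT_TEMPERATURE, GAS_CONSTANT_KJ

__all__ = [
    "ContactMesh",
    "FeatureMatrix",
    "PCAModel",
    "FreeEnergyLandscape",
    "ClusterResult",
    "ClusterStateSummary",
    "build_contact_mesh",
    "compute_features",
    "fit_pca",
    "free_energy_landscape",
    "cluster_scores",
    "cluster_state_summary",
    "default_min_samples",
]


@dataclass
class ContactMesh:
    """Equal-size atom meshes on two chains plus the pair list between them."""

    mesh_a: np.ndarray  # global atom indices, size m
    mesh_b: np.ndarray  # global atom indices, size m
    pair_list: np.ndarray  # (n_pairs, 2) indices INTO mesh_a / mesh_b
    cap: int | None
    seed: int
    chain_a: str = "A"
    chain_b: str = "B"

    @property
    def m(self) -> int:
        return len(self.mesh_a)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_list)


@dataclass
class FeatureMatrix:
    """Frames x mesh-pair distance matrix (Angstrom)."""

    values: np.ndarray
    frame_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("feature matrix must be 2D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputError("features must be finite non-negative distances")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PCAModel:
    """Centred PCA fit: leading components, scores and variance accounting.

    ``components`` holds the retained directions (rows, in original feature
    space including dropped zero-variance columns as zeros);
    ``explained_variance_all`` covers every component so that its sum equals
    the total feature variance.  Component signs are fixed so each
    component's largest-magnitude loading is positive.
    """

    mean: np.ndarray
    components: np.ndarray  # (n_retained, n_features)
    explained_variance: np.ndarray  # retained components
    scores: np.ndarray  # (n_frames, n_retained)
    frame_ids: np.ndarray
    explained_variance_all: np.ndarray = field(default=None)  # type: ignore[assignment]
    components_all: np.ndarray = field(default=None)  # type: ignore[assignment]
    dropped_columns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.explained_variance_all.sum()
        if total == 0:
            return np.zeros_like(self.explained_variance)
        return self.explained_variance / total


@dataclass
class FreeEnergyLandscape:
    """Gibbs free-energy surface over a 2D PC-score histogram.

    ``delta_g`` is in kJ/mol, zero at the modal bin; ``empty_mask`` marks
    bins with zero probability (their energy is undefined, not infinite).
    """

    edges_pc1: np.ndarray
    edges_pc2: np.ndarray
    probability: np.ndarray
    delta_g: np.ndarray
    empty_mask: np.ndarray
    gas_constant: float
    temperature: float

    @property
    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            0.5 * (self.edges_pc1[:-1] + self.edges_pc1[1:]),
            0.5 * (self.edges_pc2[:-1] + self.edges_pc2[1:]),
        )


@dataclass
class ClusterResult:
    """OPTICS clustering of PC scores.

    ``labels`` are per-frame cluster ids (densest-first is not implied;
    ids are assigned in descending cluster size), -1 marks noise.  Each
    cluster records its member frame positions and a representative: the
    member nearest the cluster centroid in score space.
    """

    labels: np.ndarray
    clusters: list[tuple[int, np.ndarray, int]]  # (id, members, representative)
    optics_min_samples: int
    optics_xi: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def noise_positions(self) -> np.ndarray:
        return np.flatnonzero(self.labels == -1)


@dataclass
class ClusterStateSummary:
    """Per-cluster occluding-loop statistics (distances in Angstrom)."""

    cluster_ids: np.ndarray
    mean_distance: np.ndarray
    sd_distance: np.ndarray
    open_fraction: np.ndarray
    member_count: np.ndarray
    threshold: float


def _heavy_atoms_of_chain(topology: Topology, chain: str) -> np.ndarray:
    """Heavy-atom indices of a chain, ordered by (residue_number, atom_name)."""
    records = [
        a for a in topology.atoms if a.chain_id == chain and a.is_heavy
    ]
    records.sort(key=lambda a: (a.residue_number, a.atom_name))
    return np.array([a.atom_index for a in records], dtype=int)


def build_contact_mesh(
    topology: Topology,
    chain_a: str,
    chain_b: str,
    cap: int | None = None,
    seed: int = 0,
) -> ContactMesh:
    """Build the equal-size inter-chain mesh and its pair list.

    m is the heavy-atom count of the smaller chain, which contributes all
    its atoms; the larger chain contributes every k-th heavy atom with
    k = floor(n_large / m), truncated to the first m.  The pair list is the
    full m x m cross product, or a seeded uniform subsample of size ``cap``.
    """
    heavy_a = _heavy_atoms_of_chain(topology, chain_a)
    heavy_b = _heavy_atoms_of_chain(topology, chain_b)
    if heavy_a.size == 0 or heavy_b.size == 0:
        raise InputError(
            f"chain {chain_a if heavy_a.size == 0 else chain_b!r} has no heavy atoms"
        )

    if heavy_a.size <= heavy_b.size:
        small, large = heavy_a, heavy_b
        small_is_a = True
    else:
        small, large = heavy_b, heavy_a
        small_is_a = False
    m = small.size
    stride = large.size // m
    strided = large[::stride][:m]
    mesh_a, mesh_b = (small, strided) if small_is_a else (strided, small)

    full = m * m
    ii, jj = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    pair_list = np.column_stack([ii.ravel(), jj.ravel()])
    if cap is not None and cap < full:
        if cap < 1:
            raise InputError("cap must be at least 1")
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(full, size=cap, replace=False))
        pair_list = pair_list[chosen]

    return ContactMesh(
        mesh_a=mesh_a,
        mesh_b=mesh_b,
        pair_list=pair_list,
        cap=cap,
        seed=seed,
        chain_a=chain_a,
        chain_b=chain_b,
    )


def compute_features(
    ensemble: StructureEnsemble,
    mesh: ContactMesh,
    frame_filter: FrameFilter | None = None,
) -> FeatureMatrix:
    """Collect per-frame mesh-pair distances into a feature matrix."""
    coords = ensemble.coordinates
    if frame_filter is not None:
        if len(frame_filter.keep) != ensemble.n_frames:
            raise InputError("frame filter length does not match ensemble")
        pos = frame_filter.positions()
        if pos.size == 0:
            raise InputError("frame filter keeps zero frames")
        coords = coords[pos]
        frame_ids = ensemble.frame_ids[pos]
    else:
        frame_ids = ensemble.frame_ids

    a = coords[:, mesh.mesh_a[mesh.pair_list[:, 0]], :]
    b = coords[:, mesh.mesh_b[mesh.pair_list[:, 1]], :]
    values = np.linalg.norm(a - b, axis=2)
    return FeatureMatrix(values=values, frame_ids=np.asarray(frame_ids))


def fit_pca(features: FeatureMatrix, n_components: int = 2) -> PCAModel:
    """PCA on centred, unscaled features via singular-value decomposition.

    Features share units (Angstrom) so no per-column scaling is applied.
    Zero-variance columns are dropped before the fit and recorded; their
    loadings are reported as 0.  Signs follow the largest-loading-positive
    convention so scores are reproducible across linear-algebra backends.
    """
    X = features.values
    n, d = X.shape
    if n < 2:
        raise InputError("PCA requires at least 2 frames")
    if n_components > min(n - 1, d):
        raise InputError(
            f"n_components={n_components} exceeds min(rows-1, columns)="
            f"{min(n - 1, d)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    keep = np.flatnonzero(np.ptp(Xc, axis=0) > 0)
    dropped = np.setdiff1d(np.arange(d), keep)
    Xk = Xc[:, keep]
    if Xk.shape[1] == 0:
        raise InputError("all feature columns have zero variance")

    U, s, Vt = np.linalg.svd(Xk, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    explained_all = s**2 / (n - 1)
    scores_all = U * s

    components_full = np.zeros((Vt.shape[0], d))
    components_full[:, keep] = Vt
    return PCAModel(
        mean=mean,
        components=components_full[:n_components],
        explained_variance=explained_all[:n_components],
        scores=scores_all[:, :n_components],
        frame_ids=np.asarray(features.frame_ids),
        explained_variance_all=explained_all,
        components_all=components_full,
        dropped_columns=dropped,
    )


def free_energy_landscape(
    scores: np.ndarray,
    bins: int = 100,
    temperature: float = DEFAULT_TEMPERATURE,
    gas_constant: float = GAS_CONSTANT_KJ,
) -> FreeEnergyLandscape:
    """Boltzmann-invert the 2D score histogram: dG = -R T ln(P / max P).

    The histogram spans the observed score range per axis, expanded by 1%
    padding (0.5 A fallback for a degenerate zero-range axis).  Energies
    are defined only on occupied bins; ``empty_mask`` flags the rest.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise InputError("scores must be a frames x 2 array")
    if scores.shape[0] < 1:
        raise InputError("at least one score row required")
    if not np.all(np.isfinite(scores)):
        raise InputError("scores contain non-finite values")
    if bins < 2:
        raise InputError("bins must be >= 2")
    if temperature <= 0:
        raise InputError("temperature must be positive")

    ranges = []
    for axis in (0, 1):
        lo, hi = scores[:, axis].min(), scores[:, axis].max()
        pad = 0.01 * (hi - lo)
        if pad == 0:
            pad = 0.5
        ranges.append((lo - pad, hi + pad))

    counts, edges1, edges2 = np.histogram2d(
        scores[:, 0], scores[:, 1], bins=bins, range=ranges
    )
    probability = counts / counts.sum()
    empty = probability == 0
    p_max = probability.max()
    delta_g = np.zeros_like(probability)
    occupied = ~empty
    # ln(max/P) keeps the modal bin at exactly +0.0
    delta_g[occupied] = gas_constant * temperature * np.log(
        p_max / probability[occupied]
    )
    delta_g[empty] = np.nan
    return FreeEnergyLandscape(
        edges_pc1=edges1,
        edges_pc2=edges2,
        probability=probability,
        delta_g=delta_g,
        empty_mask=empty,
        gas_constant=gas_constant,
        temperature=temperature,
    )


def default_min_samples(n_frames: int) -> int:
    """OPTICS min_samples default: max(20, 2.5% of frames).

    Smaller values make the xi extraction report spurious leaf clusters
    inside a single density mode (observable already on two clean,
    well-separated Gaussian blobs), so the default is deliberately on the
    smooth side; pass ``min_samples`` explicitly to resolve finer
    substructure.
    """
    return max(20, n_frames // 40)


def cluster_scores(
    scores: np.ndarray, min_samples: int, xi: float = 0.15
) -> ClusterResult:
    """OPTICS xi-clustering of 2D PC scores.

    Clusters are relabelled in descending size order (0 = largest); noise
    keeps label -1.  Each cluster's representative is the member frame
    whose score is nearest the member centroid (ties: lowest position).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise InputError("scores must be 2D")
    if min_samples < 2:
        raise InputError("min_samples must be >= 2")
    if not 0 < xi < 1:
        raise InputError("xi must lie in (0, 1)")
    if scores.shape[0] < min_samples:
        raise InputError(
            f"{scores.shape[0]} frames < min_samples={min_samples}"
        )

    optics = OPTICS(min_samples=min_samples, xi=xi, cluster_method="xi")
    raw = optics.fit_predict(scores)

    ids, sizes = np.unique(raw[raw >= 0], return_counts=True)
    # descending size, ties by original id for determinism
    order = np.lexsort((ids, -sizes))
    labels = np.full_like(raw, -1)
    clusters: list[tuple[int, np.ndarray, int]] = []
    for new_id, k in enumerate(order):
        members = np.flatnonzero(raw == ids[k])
        labels[members] = new_id
        centroid = scores[members].mean(axis=0)
        dist = np.linalg.norm(scores[members] - centroid, axis=1)
        rep = int(members[np.argmin(dist)])  # argmin takes first on ties
        clusters.append((new_id, members, rep))

    return ClusterResult(
        labels=labels,
        clusters=clusters,
        optics_min_samples=min_samples,
        optics_xi=xi,
    )


def cluster_state_summary(
    clusters: ClusterResult,
    trace: DistanceTrace,
    threshold: float,
) -> ClusterStateSummary:
    """Mean/SD COM distance and open fraction per cluster.

    ``trace`` must be aligned with the frames that were clustered (same
    order and length).  SD is the sample standard deviation (ddof=1; 0 for
    singleton clusters).
    """
    if len(trace) != len(clusters.labels):
        raise InputError(
            f"trace length {len(trace)} does not match clustered frame "
            f"count {len(clusters.labels)}"
        )
    ids, means, sds, opens, counts = [], [], [], [], []
    for cid, members, _rep in clusters.clusters:
        d = trace.values[members]
        ids.append(cid)
        means.append(float(d.mean()))
        sds.append(float(d.std(ddof=1)) if len(d) > 1 else 0.0)
        opens.append(float(np.mean(d > threshold)))
        counts.append(len(members))
    return ClusterStateSummary(
        cluster_ids=np.array(ids, dtype=int),
        mean_distance=np.array(means),
        sd_distance=np.array(sds),
        open_fraction=np.array(opens),
        member_count=np.array(counts, dtype=int),
        threshold=float(threshold),
    )
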