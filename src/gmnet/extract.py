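"""Single-subject grey matter network extraction.

A subject's grey matter density volume is tiled into non-overlapping
3x3x3-voxel cubes (the nodes — an atlas-free parcellation that keeps the
spatial intensity pattern of each small region intact).  Connectivity is the
Pearson correlation of the 27 corresponding voxel intensities between any two
cubes.  Cubes are connected when their correlation exceeds a subject-specific
cutoff calibrated by a random permutation scheme so that the expected number
of supra-threshold connections arising by chance stays at or below a stated
fraction (default 5%) of all retained connections.

The permutation null shuffles voxel intensities *within* each cube, which
preserves every cube's marginal intensity distribution while destroying the
voxel-to-voxel spatial correspondence that genuine structural similarity
produces.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.io import mmread, mmwrite

from .volume import GreyMatterVolume

__all__ = [
    "NodeSet",
    "SimilarityMatrix",
    "ThresholdResult",
    "BinaryNetwork",
    "cube_low_corners",
    "partition_cubes",
    "compute_similarity",
    "permutation_threshold",
    "binarize",
    "extract_network",
    "save_network",
    "load_network",
]

CUBE_EDGE = 3
CUBE_VOXELS = CUBE_EDGE**3


def cube_low_corners(shape: tuple[int, int, int]) -> np.ndarray:
    """Low-corner voxel coordinates (x, y, z) of all full 3x3x3 cubes.

    The tiling starts at voxel (0, 0, 0); trailing partial slabs are
    discarded.  Cubes are ordered lexicographically by (z, y, x) of the low
    corner — this fixed order defines node identity everywhere downstream.
    """
    ncx, ncy, ncz = (s // CUBE_EDGE for s in shape)
    iz, iy, ix = np.meshgrid(np.arange(ncz), np.arange(ncy), np.arange(ncx), indexing="ij")
    return np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()]) * CUBE_EDGE


def _cube_intensity_matrix(data: np.ndarray) -> np.ndarray:
    """All full cubes' intensities as an (n_cubes, 27) matrix in canonical
    node order, each row flattened in local (x, y, z) C-order."""
    ncx, ncy, ncz = (s // CUBE_EDGE for s in data.shape)
    arr = data[: ncx * 3, : ncy * 3, : ncz * 3].reshape(ncx, 3, ncy, 3, ncz, 3)
    # (ix,lx,iy,ly,iz,lz) -> (iz,iy,ix,lx,ly,lz): cube order (z,y,x), local C-order
    return arr.transpose(4, 2, 0, 1, 3, 5).reshape(-1, CUBE_VOXELS)


@dataclass
class NodeSet:
    """Nodes of one subject's network: 3x3x3 grey matter cubes.

    ``cube_index_coords`` holds the 0-based (x, y, z) voxel coordinates of
    each cube's low corner; ``intensities`` the 27 voxel densities per node.
    """

    cube_index_coords: np.ndarray
    intensities: np.ndarray
    volume_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.cube_index_coords = np.asarray(self.cube_index_coords, dtype=int).reshape(-1, 3)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1, CUBE_VOXELS)
        if len(self.cube_index_coords) != len(self.intensities):
            raise ValueError("coordinate and intensity row counts differ")

    @property
    def n_nodes(self) -> int:
        return len(self.intensities)


@dataclass
class SimilarityMatrix:
    """Symmetric node-by-node Pearson correlation matrix."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Upper-triangle (i < j) similarity values: one per node pair."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu]


@dataclass
class ThresholdResult:
    """Outcome of the permutation calibration."""

    cutoff: float
    flagged_empty: bool
    null_max: float
    null_min: float
    n_real_connections: int
    expected_spurious: float
    spurious_rate: float
    n_permutations: int


@dataclass
class BinaryNetwork:
    """Undirected, unweighted grey matter network over cube nodes."""

    adjacency: np.ndarray
    cube_index_coords: np.ndarray | None = None
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        adj = adj.astype(bool)
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adjacency = adj

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def to_networkx(self):
        import networkx as nx

        g = nx.from_numpy_array(self.adjacency.astype(np.uint8))
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


def partition_cubes(volume: GreyMatterVolume, min_gm_fraction: float = 0.0) -> NodeSet:
    """Tile the volume into 3x3x3 cubes and keep those containing grey matter.

    A cube becomes a node iff its mean density passes ``min_gm_fraction``;
    with the default 0 the bound is exclusive, i.e. any nonzero grey matter
    qualifies.  Tiling starts at voxel (0,0,0) and trailing partial slabs
    are dropped.
    """
    if any(s < CUBE_EDGE for s in volume.shape):
        raise ValueError(
            f"volume shape {volume.shape} is smaller than one {CUBE_EDGE}^3 cube in some axis"
        )
    intensities = _cube_intensity_matrix(volume.data)
    coords = cube_low_corners(volume.shape)
    means = intensities.mean(axis=1)
    keep = means > 0 if min_gm_fraction == 0 else means >= min_gm_fraction
    return NodeSet(coords[keep], intensities[keep], volume_shape=volume.shape)


def _row_standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm so Z @ Z.T is the Pearson matrix.

    Returns (Z, zero_variance_mask); zero-variance rows become all-zero so
    their correlations with everything are defined as 0.
    """
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero_var = norms < 1e-300
    safe = np.where(zero_var, 1.0, norms)
    return centered / safe[:, None], zero_var


def _rotation_index_maps() -> list[np.ndarray]:
    """Column index maps for the 48 axis-aligned rotations/reflections of a
    3x3x3 cube (the full octahedral symmetry group, including reflections)."""
    base = np.arange(CUBE_VOXELS).reshape(3, 3, 3)
    maps = set()
    for perm in itertools.permutations(range(3)):
        for flips in itertools.product([False, True], repeat=3):
            a = np.transpose(base, perm)
            for ax, f in enumerate(flips):
                if f:
                    a = np.flip(a, axis=ax)
            maps.add(tuple(a.ravel()))
    return [np.asarray(m) for m in sorted(maps)]


_ROTATION_MAPS = _rotation_index_maps()


def compute_similarity(nodes: NodeSet, maximize_over_rotations: bool = False) -> SimilarityMatrix:
    """Pairwise Pearson correlation of cube intensity vectors.

    Entry (i, j) correlates the 27 corresponding voxel intensities of cubes
    i and j.  With ``maximize_over_rotations`` the correlation is maximized
    over the 48 axis-aligned rotations/reflections of one cube, matching the
    orientation-invariant variant of the similarity measure.  Zero-variance
    cubes correlate 0 with everything (a warning is emitted).
    """
    if nodes.n_nodes < 2:
        raise ValueError("need at least 2 nodes to compute similarity")
    z, zero_var = _row_standardize(nodes.intensities)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} cube(s) have zero intensity variance; "
            "their correlations are defined as 0"
        )
    if maximize_over_rotations:
        s = z @ z.T
        for idx in _ROTATION_MAPS:
            np.maximum(s, z @ z[:, idx].T, out=s)
        s = np.maximum(s, s.T)  # group closure makes this exact; guard float noise
    else:
        s = z @ z.T
        s = (s + s.T) / 2.0
    np.clip(s, -1.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s)


def permutation_threshold(
    similarity: SimilarityMatrix,
    nodes: NodeSet,
    spurious_rate: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ThresholdResult:
    """Calibrate the connection cutoff by within-cube permutation.

    Null similarity values are generated by randomly permuting the voxel
    intensities within every cube and recomputing all pairwise correlations,
    ``n_permutations`` times.  The returned cutoff is the smallest value c
    such that, for c and every stricter candidate, the expected number of
    null pairs exceeding c is at most ``spurious_rate`` times the number of
    real pairs exceeding c — i.e. at most that fraction of retained
    connections is expected to be spurious.  Ties resolve to the stricter
    (higher) cutoff; edges later use a strictly-greater comparison.

    When no candidate satisfies the bound (e.g. a pure-noise volume whose
    real similarities match the null) the null maximum is returned and the
    network is flagged as empty at calibration.
    """
    if not 0.0 < spurious_rate <= 1.0:
        raise ValueError("spurious_rate must lie in (0, 1]")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if similarity.n_nodes != nodes.n_nodes:
        raise ValueError("similarity and node set sizes differ")

    rng = np.random.default_rng(seed)
    x = nodes.intensities
    n = nodes.n_nodes
    iu = np.triu_indices(n, k=1)
    null_vals = np.empty((n_permutations, len(iu[0])), dtype=np.float32)
    for p in range(n_permutations):
        perm = rng.permuted(x, axis=1)
        z, _ = _row_standardize(perm)
        null_vals[p] = (z @ z.T)[iu]
    null_sorted = np.sort(null_vals.ravel()).astype(float)
    null_max = float(null_sorted[-1])
    null_min = float(null_sorted[0])

    real_sorted = np.sort(similarity.offdiag_values())
    n_real_total = len(real_sorted)

    if spurious_rate >= 1.0:
        # degenerate bound: every pair above the weakest null value connects
        return ThresholdResult(
            cutoff=null_min,
            flagged_empty=False,
            null_max=null_max,
            null_min=null_min,
            n_real_connections=n_real_total
            - int(np.searchsorted(real_sorted, null_min, side="right")),
            expected_spurious=float(len(null_sorted) - 1) / n_permutations,
            spurious_rate=spurious_rate,
            n_permutations=n_permutations,
        )

    candidates = np.unique(real_sorted[real_sorted >= null_min])
    candidates = np.append(candidates, null_min)
    # place candidates infinitesimally below the observed values so the
    # strictly-greater edge rule keeps each value at its own threshold
    candidates = np.nextafter(np.unique(candidates)[::-1], -np.inf)  # strictest first

    real_above = n_real_total - np.searchsorted(real_sorted, candidates, side="right")
    null_above = (
        len(null_sorted) - np.searchsorted(null_sorted, candidates, side="right")
    ) / n_permutations
    satisfied = null_above <= spurious_rate * real_above

    def real_count(c: float) -> int:
        return n_real_total - int(np.searchsorted(real_sorted, c, side="right"))

    def null_expected(c: float) -> float:
        above = len(null_sorted) - int(np.searchsorted(null_sorted, c, side="right"))
        return above / n_permutations

    # walk down from the strictest candidate while the bound keeps holding:
    # the cutoff is the smallest value of the contiguous satisfying run.
    # Isolated satisfying points further down are sampling flukes of the
    # noise tail; accepting them would systematically admit extra spurious
    # connections.
    if not satisfied[0]:
        cutoff = None
    else:
        stop = np.argmin(satisfied) if not satisfied.all() else len(satisfied)
        cutoff = float(candidates[stop - 1])

    if cutoff is None:
        warnings.warn(
            "no cutoff satisfies the spurious-connection bound; "
            "network flagged empty at calibration"
        )
        return ThresholdResult(
            cutoff=null_max,
            flagged_empty=True,
            null_max=null_max,
            null_min=null_min,
            n_real_connections=real_count(null_max),
            expected_spurious=null_expected(null_max),
            spurious_rate=spurious_rate,
            n_permutations=n_permutations,
        )
    return ThresholdResult(
        cutoff=cutoff,
        flagged_empty=False,
        null_max=null_max,
        null_min=null_min,
        n_real_connections=real_count(cutoff),
        expected_spurious=null_expected(cutoff),
        spurious_rate=spurious_rate,
        n_permutations=n_permutations,
    )


def binarize(similarity: SimilarityMatrix, cutoff: float) -> BinaryNetwork:
    """Connect node pairs whose similarity strictly exceeds the cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    adj = similarity.values > cutoff
    np.fill_diagonal(adj, False)
    return BinaryNetwork(adjacency=adj, threshold_used=float(cutoff))


@dataclass
class ExtractionResult:
    network: BinaryNetwork
    nodes: NodeSet
    similarity: SimilarityMatrix
    threshold: ThresholdResult


def extract_network(
    volume: GreyMatterVolume,
    min_gm_fraction: float = 0.0,
    spurious_rate: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    maximize_over_rotations: bool = False,
) -> ExtractionResult:
    """Full extraction: cubes -> similarity -> calibrated threshold -> graph."""
    nodes = partition_cubes(volume, min_gm_fraction=min_gm_fraction)
    if nodes.n_nodes == 0:
        raise ValueError("volume contains no grey matter cubes; nothing to extract")
    sim = compute_similarity(nodes, maximize_over_rotations=maximize_over_rotations)
    thr = permutation_threshold(
        sim, nodes, spurious_rate=spurious_rate, n_permutations=n_permutations, seed=seed
    )
    net = binarize(sim, thr.cutoff)
    net.cube_index_coords = nodes.cube_index_coords
    return ExtractionResult(network=net, nodes=nodes, similarity=sim, threshold=thr)


def save_network(network: BinaryNetwork, adjacency_path, coords_path=None) -> None:
    """Write the adjacency as Matrix Market sparse plus a node-coordinate TSV.

    Coordinates are 0-based voxel indices of each cube's low corner.
    """
    mmwrite(str(adjacency_path), sparse.coo_matrix(network.adjacency.astype(np.int8)))
    if coords_path is not None and network.cube_index_coords is not None:
        header = "# node coordinates: 0-based voxel index of 3x3x3 cube low corner\nx\ty\tz\n"
        rows = "\n".join("\t".join(map(str, c)) for c in network.cube_index_coords)
        with open(coords_path, "w") as fh:
            fh.write(header + rows + "\n")


def load_network(adjacency_path, coords_path=None) -> BinaryNetwork:
    adj = np.asarray(mmread(str(adjacency_path)).todense()).astype(bool)
    coords = None
    if coords_path is not None:
        coords = np.loadtxt(str(coords_path), skiprows=2, dtype=int).reshape(-1, 3)
    return BinaryNetwork(adjacency=adj, cube_index_coords=coords)
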