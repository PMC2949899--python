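"""Inner distances: shortest paths constrained to the shape's volume.

The inner distance d_I(x, y) between two boundary points is the length
of the shortest path connecting them that stays inside the shape.  On a
voxel model it is approximated by the shortest-path metric of the graph
whose nodes are ALL object voxels (interior included — paths may cut
through the volume, which distinguishes the inner distance from a
surface geodesic) and whose edges join 26-adjacent object voxels with
Euclidean step weights (spacing * {1, sqrt 2, sqrt 3}).  Exact shortest
paths come from Dijkstra's algorithm, one single-source pass per
landmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import squareform, pdist

from .sampling import SamplePointSet
from .voxel import VolumetricModel

__all__ = [
    "VoxelGraph",
    "PairwiseDistanceMatrix",
    "build_voxel_graph",
    "inner_distance_matrix",
    "euclidean_distance_matrix",
    "DisconnectedSamplesError",
]

# the 13 offsets lexicographically above (0,0,0); the other 13 by symmetry
_HALF_OFFSETS = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) > (0, 0, 0)
    ],
    dtype=np.int64,
)


class DisconnectedSamplesError(ValueError):
    """Samples fall in different connected components of the voxel graph.

    The inner distance is undefined (infinite) across components; the
    Gaussian kernel downstream cannot absorb infinities, so this is a
    hard error.  ``partition`` maps component label -> sample positions.
    """

    def __init__(self, partition: dict[int, list[int]]):
        self.partition = partition
        sizes = {int(k): len(v) for k, v in partition.items()}
        super().__init__(
            "sample points span multiple connected components of the object "
            f"(component -> sample count: {sizes}); restrict sampling to one "
            "component or regenerate the shape"
        )


@dataclass
class VoxelGraph:
    """Weighted 26-adjacency graph over the object voxels of a model."""

    adjacency: csr_matrix
    node_indices: np.ndarray  # (N, 3) lattice indices, lexicographic
    model: VolumetricModel

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def node_id_of(self, lattice_index: np.ndarray) -> int:
        """Graph node id of a lattice index; raises if not an object voxel."""
        key = tuple(int(v) for v in lattice_index)
        nid = self._lookup().get(key)
        if nid is None:
            raise KeyError(f"{key} is not an object voxel of this model")
        return nid

    def _lookup(self) -> dict[tuple[int, int, int], int]:
        if not hasattr(self, "_node_lookup"):
            self._node_lookup = {
                tuple(idx): i for i, idx in enumerate(map(tuple, self.node_indices))
            }
        return self._node_lookup


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric n x n matrix of nonnegative lengths in world units.

    ``kind`` tags the metric: inner | diffusion | euclidean | geodesic.
    """

    values: np.ndarray
    kind: str
    sample_ref: SamplePointSet | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        """All n(n-1)/2 unordered off-diagonal values (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def build_voxel_graph(model: VolumetricModel) -> VoxelGraph:
    """Build the weighted 26-adjacency graph over all object voxels.

    Nodes are ordered lexicographically by lattice index; edge weights
    are Euclidean step lengths in world units.
    """
    if model.is_empty():
        raise ValueError("cannot build a graph for an empty model")
    grid = model.grid.astype(bool)
    nodes = np.argwhere(grid)
    node_id = -np.ones(grid.shape, dtype=np.int64)
    node_id[tuple(nodes.T)] = np.arange(len(nodes))

    rows, cols, data = [], [], []
    for off in _HALF_OFFSETS:
        src = nodes
        dst = nodes + off
        ok = ((dst >= 0) & (dst < np.asarray(grid.shape))).all(axis=1)
        src, dst = src[ok], dst[ok]
        hit = grid[tuple(dst.T)]
        src, dst = src[hit], dst[hit]
        if len(src) == 0:
            continue
        w = model.spacing * float(np.sqrt((off * off).sum()))
        i = node_id[tuple(src.T)]
        j = node_id[tuple(dst.T)]
        rows.append(i)
        cols.append(j)
        data.append(np.full(len(i), w))

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        d = np.concatenate(data)
        # symmetrize
        adjacency = csr_matrix(
            (np.concatenate([d, d]), (np.concatenate([r, c]), np.concatenate([c, r]))),
            shape=(len(nodes), len(nodes)),
        )
    else:
        adjacency = csr_matrix((len(nodes), len(nodes)))
    return VoxelGraph(adjacency=adjacency, node_indices=nodes, model=model)


def _sample_node_ids(graph: VoxelGraph, samples: SamplePointSet) -> np.ndarray:
    boundary_idx = np.argwhere(
        _boundary_mask(graph.model)
    )  # same lexicographic order as extract_boundary
    lattice = boundary_idx[samples.source_indices]
    return np.array([graph.node_id_of(ix) for ix in lattice], dtype=np.int64)


def _boundary_mask(model: VolumetricModel) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    obj = model.grid.astype(bool)
    return obj & ~binary_erosion(obj, structure=np.ones((3, 3, 3), dtype=bool))


def inner_distance_matrix(
    graph: VoxelGraph, samples: SamplePointSet
) -> PairwiseDistanceMatrix:
    """Exact all-pairs shortest-path lengths between landmark voxels.

    One single-source Dijkstra per landmark over the full object-voxel
    graph.  Raises :class:`DisconnectedSamplesError` when landmarks sit
    in different connected components.
    """
    sources = _sample_node_ids(graph, samples)
    dist = dijkstra(graph.adjacency, directed=False, indices=sources)
    D = dist[:, sources]
    if not np.isfinite(D).all():
        _, labels = connected_components(graph.adjacency, directed=False)
        partition: dict[int, list[int]] = {}
        for pos, nid in enumerate(sources):
            partition.setdefault(int(labels[nid]), []).append(pos)
        raise DisconnectedSamplesError(partition)
    D = (D + D.T) / 2.0  # Dijkstra is exact; this only removes float round-off
    np.fill_diagonal(D, 0.0)
    return PairwiseDistanceMatrix(values=D, kind="inner", sample_ref=samples)


def euclidean_distance_matrix(samples: SamplePointSet) -> PairwiseDistanceMatrix:
    """Straight-line world distances between landmarks (rigid baseline)."""
    if samples.n < 2:
        raise ValueError("need at least 2 samples")
    D = squareform(pdist(samples.points))
    return PairwiseDistanceMatrix(values=D, kind="euclidean", sample_ref=samples)
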