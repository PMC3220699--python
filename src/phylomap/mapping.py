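"""Phylogenomic map construction: from profile matrix to labelled mountains.

Proteins whose phylogenetic profiles rise and fall together across a genome
panel are inferred to share evolutionary history.  The map is built in four
steps:

1. Spearman rank correlation between every pair of protein profiles
   (average ranks for ties — the zero cells of a thresholded profile matrix
   are heavily tied, so the tie rule matters).
2. Sparsification to each protein's top-k positively correlated partners
   (k = 50 by default), symmetrized by union.
3. A deterministic 2D embedding: classical multidimensional scaling on
   graph shortest-path distances (edge length 1 - rho) provides the initial
   placement, refined by Fruchterman-Reingold spring iterations weighted by
   rho.  Connected components are laid out in disjoint bounding boxes.
4. Mountain detection: an isotropic Gaussian kernel density estimate on a
   grid, watershed basins grown from local density maxima above a floor;
   under-populated basins are merged into the nearest surviving basin.
   Labels are ordered by descending member count; 0 means unassigned plain.

Every step is deterministic given the embedding seed and invariant to the
order in which proteins are supplied (computations run in lexicographic
protein-id order internally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .profiles import ProfileMatrix

__all__ = [
    "CorrelateGraph",
    "EmbeddingResult",
    "MountainMap",
    "spearman_matrix",
    "topk_correlates",
    "embed",
    "detect_mountains",
    "build_mountain_map",
]


# ---------------------------------------------------------------------------
# Spearman correlation of profiles
# ---------------------------------------------------------------------------

def spearman_matrix(matrix: ProfileMatrix) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between protein profiles.

    Rows are rank-transformed (average ranks on ties) and the product-moment
    correlation of the ranks is taken.  Constant rows have undefined rank
    correlation; their entries are recorded as 0 with a warning.  The
    diagonal is set to NaN so self-correlation is never mistaken for a
    correlate.
    """
    if matrix.n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    if matrix.n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    ranks = np.apply_along_axis(rankdata, 1, matrix.scores)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        ids = [p for p, c in zip(matrix.protein_ids, constant) if c]
        warnings.warn(
            f"{constant.sum()} constant profile row(s) have undefined rank "
            f"correlation, recorded as 0: {ids[:5]}...",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    rho = unit @ unit.T
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, np.nan)
    return pd.DataFrame(rho, index=matrix.protein_ids,
                        columns=matrix.protein_ids)


# ---------------------------------------------------------------------------
# top-k correlate graph
# ---------------------------------------------------------------------------

@dataclass
class CorrelateGraph:
    """Union-symmetrized top-k positive-correlation graph.

    ``graph`` is an undirected networkx graph whose edges carry the Spearman
    rho; isolated proteins (no positive correlate) are retained as nodes and
    flagged in ``isolated``.
    """

    graph: nx.Graph
    k: int
    isolated: frozenset[str] = frozenset()

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)


def topk_correlates(rho: pd.DataFrame, k: int = 50) -> CorrelateGraph:
    """Retain, per protein, its k strongest strictly positive correlates.

    Ties at the cutoff break by lexicographically smaller partner id.  The
    directed top-k lists are symmetrized by union: an edge survives if
    either endpoint ranks the other.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = list(rho.index)
    values = rho.to_numpy()
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    order = np.argsort(ids)  # iterate lexicographically for determinism
    id_rank = {pid: i for i, pid in enumerate(sorted(ids))}
    for i in order:
        row = values[i]
        candidates = [
            (-row[j], id_rank[ids[j]], j)
            for j in np.flatnonzero(row > 0)
            if j != i
        ]
        candidates.sort()
        for _, _, j in candidates[:k]:
            a, b = ids[i], ids[j]
            if not graph.has_edge(a, b):
                graph.add_edge(a, b, rho=float(values[i, j]))
    isolated = frozenset(n for n in graph.nodes if graph.degree(n) == 0)
    return CorrelateGraph(graph=graph, k=k, isolated=isolated)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    node_ids: list[str]
    coords: np.ndarray  # (n, 2)
    converged: bool

    def as_dict(self) -> dict[str, np.ndarray]:
        return {nid: self.coords[i] for i, nid in enumerate(self.node_ids)}


def _classical_mds(dist: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) MDS to 2D from a squared-distance matrix."""
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:2]
    pos = vecs[:, idx] * np.sqrt(np.maximum(vals[idx], 0.0))
    if pos.shape[1] < 2:
        pos = np.hstack([pos, np.zeros((n, 2 - pos.shape[1]))])
    return pos


def _spring_refine(
    pos: np.ndarray,
    edge_i: np.ndarray,
    edge_j: np.ndarray,
    weight: np.ndarray,
    n_iter: int,
    tol: float,
) -> tuple[np.ndarray, bool]:
    """Fruchterman-Reingold refinement with rho-weighted attraction."""
    n = pos.shape[0]
    if n <= 2:
        return pos, True
    pos = pos.copy()
    span = np.ptp(pos, axis=0).max() or 1.0
    k = span / np.sqrt(n)
    temp = 0.1 * span
    cooling = temp / (n_iter + 1)
    converged = False
    for _ in range(n_iter):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # repulsion k^2/d between all pairs
        force = (delta / dist[..., None]) * (k * k / dist)[..., None]
        disp = force.sum(axis=1)
        # attraction w * d^2 / k along edges
        if edge_i.size:
            evec = pos[edge_i] - pos[edge_j]
            edist = np.maximum(np.linalg.norm(evec, axis=-1), 1e-9)
            pull = (evec / edist[:, None]) * (
                weight * edist**2 / k
            )[:, None]
            np.add.at(disp, edge_i, -pull)
            np.add.at(disp, edge_j, pull)
        length = np.maximum(np.linalg.norm(disp, axis=-1), 1e-12)
        step = disp / length[:, None] * np.minimum(length, temp)[:, None]
        pos += step
        temp = max(temp - cooling, 1e-4 * span)
        if np.abs(step).max() < tol:
            converged = True
            break
    return pos, converged


def embed(
    cgraph: CorrelateGraph,
    seed: int = 0,
    n_iter: int = 60,
    tol: float = 1e-6,
) -> EmbeddingResult:
    """Assign each protein an (x, y) coordinate.

    Per connected component: classical MDS on shortest-path distances (edge
    length 1 - rho) initializes the layout, then spring iterations refine
    it.  Components are normalized to boxes scaled by the square root of
    their size and shelf-packed into disjoint bounding boxes, largest
    first.  Deterministic given ``seed`` (used only to jitter coincident
    initial positions) and independent of node insertion order.
    """
    graph = cgraph.graph
    node_ids = list(graph.nodes)
    coords = {}
    rng = np.random.default_rng(seed)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    all_converged = True
    gap = 0.5
    sizes = [np.sqrt(len(c) / len(node_ids)) for c in components]
    shelf_width = max(max(sizes) + gap,
                      np.sqrt(sum((s + gap) ** 2 for s in sizes)))
    x_offset, y_offset, shelf_height = 0.0, 0.0, 0.0
    for comp in components:
        n = len(comp)
        if n == 1:
            pos = np.zeros((1, 2))
        else:
            sub = graph.subgraph(comp)
            for a, b, data in sub.edges(data=True):
                data["length"] = max(1.0 - data["rho"], 1e-3)
            index = {nid: i for i, nid in enumerate(comp)}
            dist = np.zeros((n, n))
            for src, lengths in nx.shortest_path_length(sub, weight="length"):
                i = index[src]
                for dst, d in lengths.items():
                    dist[i, index[dst]] = d
            pos = _classical_mds(dist)
            # break exact coincidence so spring forces are defined
            pos += rng.normal(scale=1e-6 * (np.ptp(dist) or 1.0), size=pos.shape)
            edges = list(sub.edges(data="rho"))
            edge_i = np.array([index[a] for a, _, _ in edges], dtype=int)
            edge_j = np.array([index[b] for _, b, _ in edges], dtype=int)
            weight = np.array([w for _, _, w in edges], dtype=float)
            pos, ok = _spring_refine(pos, edge_i, edge_j, weight, n_iter, tol)
            all_converged &= ok
        # normalize into a box scaled by sqrt(component size), shelf-pack
        scale = np.sqrt(n / len(node_ids))
        span = np.ptp(pos, axis=0)
        extent = span.max() or 1.0
        pos = (pos - pos.min(axis=0)) / extent * scale
        if x_offset > 0 and x_offset + scale > shelf_width:
            x_offset = 0.0
            y_offset += shelf_height + gap
            shelf_height = 0.0
        pos[:, 0] += x_offset
        pos[:, 1] += y_offset
        x_offset += scale + gap
        shelf_height = max(shelf_height, scale)
        for nid, xy in zip(comp, pos):
            coords[nid] = xy
    arr = np.array([coords[nid] for nid in node_ids])
    return EmbeddingResult(node_ids=node_ids, coords=arr,
                           converged=all_converged)


# ---------------------------------------------------------------------------
# mountain detection
# ---------------------------------------------------------------------------

@dataclass
class MountainMap:
    """Coordinates, density and mountain label per protein.

    ``mountain_id`` 0 means unassigned plain; positive labels are ordered by
    descending member count.  ``summaries`` has one row per mountain with
    member count and peak density.
    """

    protein_ids: list[str]
    coords: np.ndarray
    density: np.ndarray
    mountain_id: np.ndarray
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)

    def members(self, mountain: int) -> list[str]:
        return [
            pid for pid, m in zip(self.protein_ids, self.mountain_id)
            if m == mountain
        ]

    @property
    def n_mountains(self) -> int:
        return int(self.mountain_id.max(initial=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "density": self.density,
                "mountain_id": self.mountain_id,
            }
        )


def _auto_bandwidth(coords: np.ndarray, grid_size: int) -> float:
    """Default kernel width: scaled median nearest-neighbour distance.

    The nearest-neighbour scale tracks within-cluster point spacing, so the
    kernel smooths over sampling noise inside a cluster without bridging
    distinct clusters (whose separation is set by the layout, typically an
    order of magnitude larger).  Variance-based rules (Scott/Silverman)
    over-smooth badly here because the map extent reflects between-cluster
    layout, not cluster width.  The width is floored at 1.5 grid cells so
    tightly coincident clusters still register on the evaluation grid.
    """
    extent = float(np.ptp(coords, axis=0).max())
    if extent == 0:
        return 1e-3
    from scipy.spatial import cKDTree

    nn = cKDTree(coords).query(coords, k=2)[0][:, 1]
    positive = nn[nn > 1e-9]
    h = 1.75 * float(np.median(positive)) if positive.size else 0.0
    return max(h, 1.5 * extent / grid_size)


def _scott_bandwidth(coords: np.ndarray) -> float:
    n = coords.shape[0]
    sigma = coords.std(axis=0, ddof=1).mean()
    if sigma == 0:
        sigma = 1e-3
    return float(sigma * n ** (-1.0 / 6.0))


def _merge_shallow_basins(
    basins: np.ndarray,
    grid_density: np.ndarray,
    peaks: np.ndarray,
    point_basin: np.ndarray,
    persistence_ratio: float = 0.8,
    max_spurious_members: int = 15,  # detect_mountains passes 3 * min_members
) -> tuple[np.ndarray, np.ndarray]:
    """Merge watershed basins that look like sampling artifacts.

    A finite sample from one mountain can split its density estimate into
    several modes.  Such spurious modes are recognizable by two traits
    together: the saddle between the basins is nearly as high as the weaker
    peak (low topological persistence) and the weaker basin holds few
    proteins.  Adjacent basins are merged when the saddle exceeds
    ``persistence_ratio`` of the lower peak AND the smaller basin has at
    most ``max_spurious_members`` members; well-populated mountains are
    kept apart even when their flanks touch.  Merges apply highest
    saddle-ratio first until none qualifies.
    """
    peak_height = {
        label: float(grid_density[i, j])
        for label, (i, j) in enumerate(peaks, start=1)
    }
    point_basin = point_basin.copy()
    while True:
        counts = {
            int(b): int(c)
            for b, c in zip(*np.unique(point_basin[point_basin > 0],
                                       return_counts=True))
        }
        saddles: dict[tuple[int, int], float] = {}
        for axis in (0, 1):
            a = basins if axis == 0 else basins.T
            z = grid_density if axis == 0 else grid_density.T
            left, right = a[:-1, :], a[1:, :]
            both = (left > 0) & (right > 0) & (left != right)
            heights = np.minimum(z[:-1, :], z[1:, :])
            for la, lb, s in zip(left[both], right[both], heights[both]):
                key = (int(min(la, lb)), int(max(la, lb)))
                if s > saddles.get(key, -np.inf):
                    saddles[key] = float(s)
        candidates = [
            (s / min(peak_height[a], peak_height[b]), a, b)
            for (a, b), s in saddles.items()
            if min(counts.get(a, 0), counts.get(b, 0))
            <= max_spurious_members
        ]
        candidates = [c for c in candidates if c[0] >= persistence_ratio]
        if not candidates:
            return basins, point_basin
        _, a, b = max(candidates)
        # absorb the lower-peaked basin into the higher-peaked one
        keep, drop = (a, b) if peak_height[a] >= peak_height[b] else (b, a)
        basins = np.where(basins == drop, keep, basins)
        point_basin = np.where(point_basin == drop, keep, point_basin)


def detect_mountains(
    embedding: EmbeddingResult,
    bandwidth: float | str = "auto",
    min_members: int = 5,
    density_floor: float | None = None,
    grid_size: int = 128,
) -> MountainMap:
    """Detect density mountains on the embedded map.

    An isotropic Gaussian KDE is evaluated on a ``grid_size`` x ``grid_size``
    grid; watershed basins are grown from local density maxima restricted to
    cells above ``density_floor`` (default: 5% of the peak density).  Basins
    with fewer than ``min_members`` proteins are merged into the surviving
    basin with the nearest peak when that peak lies within four bandwidths
    (fringe basins of the same mountain), and left unassigned otherwise.
    ``bandwidth`` is "auto" (a fraction of the map extent), "scott", or an
    absolute kernel width.
    """
    coords = embedding.coords
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty embedding")
    if bandwidth == "auto":
        h = _auto_bandwidth(coords, grid_size)
    elif bandwidth == "scott":
        h = _scott_bandwidth(coords)
    else:
        h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    lo = coords.min(axis=0) - 3 * h
    hi = coords.max(axis=0) + 3 * h
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    grid_pts = np.stack([xx.ravel(), yy.ravel()], axis=1)

    def kde(points: np.ndarray) -> np.ndarray:
        # isotropic Gaussian kernel, chunked over evaluation points
        out = np.empty(points.shape[0])
        norm = 1.0 / (n * 2 * np.pi * h * h)
        for s in range(0, points.shape[0], 4096):
            block = points[s:s + 4096]
            d2 = ((block[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
            out[s:s + 4096] = np.exp(-d2 / (2 * h * h)).sum(axis=1) * norm
        return out

    grid_density = kde(grid_pts).reshape(grid_size, grid_size)
    point_density = kde(coords)

    floor = (
        0.05 * grid_density.max() if density_floor is None else density_floor
    )
    mask = grid_density >= floor
    if not mask.any():
        warnings.warn("all density below floor: zero mountains", stacklevel=2)
        return MountainMap(
            protein_ids=embedding.node_ids,
            coords=coords,
            density=point_density,
            mountain_id=np.zeros(n, dtype=int),
            summaries=pd.DataFrame(
                columns=["mountain_id", "n_members", "peak_density"]
            ),
        )

    peaks = peak_local_max(
        grid_density, labels=mask.astype(int), exclude_border=False
    )
    markers = np.zeros_like(grid_density, dtype=int)
    for label, (i, j) in enumerate(peaks, start=1):
        markers[i, j] = label
    basins = watershed(-grid_density, markers=markers, mask=mask)

    # map each protein to its grid cell's basin
    ix = np.clip(np.searchsorted(gx, coords[:, 0]) - 1, 0, grid_size - 1)
    iy = np.clip(np.searchsorted(gy, coords[:, 1]) - 1, 0, grid_size - 1)
    raw = basins[ix, iy]
    basins, raw = _merge_shallow_basins(
        basins, grid_density, peaks, raw,
        max_spurious_members=3 * min_members,
    )

    # merge under-populated fringe basins into the nearest surviving basin
    counts = pd.Series(raw[raw > 0]).value_counts()
    big = sorted(b for b, c in counts.items() if c >= min_members)
    peak_xy = {
        label: np.array([gx[i], gy[j]])
        for label, (i, j) in enumerate(peaks, start=1)
    }
    merged = raw.copy()
    merge_radius = 4.0 * h
    for b in sorted(counts.index):
        if counts[b] >= min_members:
            continue
        target = 0
        if big:
            nearest = min(
                big,
                key=lambda t: float(np.linalg.norm(peak_xy[t] - peak_xy[b])),
            )
            if np.linalg.norm(peak_xy[nearest] - peak_xy[b]) <= merge_radius:
                target = nearest
        merged[raw == b] = target

    # relabel by descending member count (ties: higher peak density, id)
    final_counts = pd.Series(merged[merged > 0]).value_counts()
    ordered = sorted(
        final_counts.index,
        key=lambda b: (
            -final_counts[b],
            -float(grid_density[tuple(peaks[b - 1])]),
            b,
        ),
    )
    relabel = {old: new for new, old in enumerate(ordered, start=1)}
    mountain_id = np.array([relabel.get(b, 0) for b in merged], dtype=int)

    summaries = pd.DataFrame(
        {
            "mountain_id": [relabel[b] for b in ordered],
            "n_members": [int(final_counts[b]) for b in ordered],
            "peak_density": [
                float(grid_density[tuple(peaks[b - 1])]) for b in ordered
            ],
        }
    ).sort_values("mountain_id", ignore_index=True)

    return MountainMap(
        protein_ids=embedding.node_ids,
        coords=coords,
        density=point_density,
        mountain_id=mountain_id,
        summaries=summaries,
    )


def build_mountain_map(
    matrix: ProfileMatrix,
    k: int = 50,
    seed: int = 0,
    bandwidth: float | str = "auto",
    min_members: int = 5,
    density_floor: float | None = None,
    n_iter: int = 60,
) -> MountainMap:
    """Full pipeline: Spearman -> top-k graph -> embedding -> mountains."""
    rho = spearman_matrix(matrix)
    cgraph = topk_correlates(rho, k=k)
    embedding = embed(cgraph, seed=seed, n_iter=n_iter)
    return detect_mountains(
        embedding,
        bandwidth=bandwidth,
        min_members=min_members,
        density_floor=density_floor,
    )
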