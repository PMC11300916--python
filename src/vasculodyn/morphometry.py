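"""Skeleton-graph morphometry of pseudo-vascular network images.

Transforms a well-quadrant image into a one-pixel-wide skeleton graph and
computes the 20 named "vectorial objects" used to parameterise a network:
counts of extremities, nodes/junctions, segments, branches, meshes and
pieces; lengths of the various edge classes; mesh areas; and two derived
ratios (mean mesh size, mesh index).

Terminology (graph of the skeleton):

* extremity      — degree-1 skeleton pixel (a free tube end);
* junction pixel — skeleton pixel with >= 3 neighbours;
* node           — an 8-connected cluster of junction pixels, merged;
* segment        — edge joining two nodes;
* branch         — edge joining a node to an extremity;
* isolated segment — edge joining two extremities (detached tube);
* mesh           — enclosed background region bounded by skeleton;
* master subgraph — the 2-core of the network graph, i.e. what remains
  after iteratively pruning all degree-<2 vertices: the mesh-supporting
  scaffold of the network.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _sk_skeletonize

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

#: The 20 vectorial objects, in canonical export order.
OBJECT_NAMES: tuple[str, ...] = (
    "nb_extremities",
    "nb_nodes",
    "nb_junctions",
    "nb_master_junctions",
    "nb_segments",
    "nb_master_segments",
    "nb_branches",
    "nb_isolated_segments",
    "nb_pieces",
    "nb_meshes",
    "tot_length",
    "tot_segments_length",
    "tot_branches_length",
    "tot_isolated_branches_length",
    "tot_master_segments_length",
    "tot_branching_length",
    "branching_interval",
    "tot_mesh_area",
    "mean_mesh_size",
    "mesh_index",
)

#: Objects dominated by detached debris (unattached cells, matrix
#: macromolecules); excluded from scoring by default.
DEFAULT_EXCLUDED: tuple[str, ...] = ("nb_isolated_segments", "nb_pieces")


class NoContrastError(ValueError):
    """Raised when a grayscale frame is constant and cannot be thresholded."""


@dataclass
class AnalysisFrame:
    """One well-quadrant image with its acquisition geometry.

    ``crop_px`` is the side of the central square retained for analysis;
    cropping removes the gel meniscus at the well periphery, whose
    viscoelastic edge suppresses tube formation and distorts features.
    """

    image: np.ndarray
    pixel_size_um: float = 2.82
    crop_px: int = 1000

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class Edge:
    """A traced skeleton path between two anchors (pixel coordinates)."""

    path: list[tuple[int, int]]
    kind: str  # 'segment' | 'branch' | 'isolated_segment'
    length_um: float
    node_ids: tuple[int | None, int | None]  # node index or None for an extremity/loop anchor
    is_loop: bool = False


@dataclass
class NetworkGraph:
    """Planar skeleton graph: merged nodes, polyline edges, meshes."""

    nodes: list[list[tuple[int, int]]]          # junction-pixel clusters
    edges: list[Edge]
    n_components: int                           # skeleton pieces, incl. isolated pixels
    mesh_areas_um2: list[float]
    mesh_pixel_counts: list[int]
    extremities: list[tuple[int, int]]
    junction_pixel_count: int
    master_edge_idx: set[int] = field(default_factory=set)
    master_node_idx: set[int] = field(default_factory=set)
    pixel_size_um: float = 2.82
    shape: tuple[int, int] = (0, 0)

    @property
    def n_meshes(self) -> int:
        return len(self.mesh_areas_um2)


# ---------------------------------------------------------------------------
# Preprocessing and skeletonisation
# ---------------------------------------------------------------------------

def _central_crop(image: np.ndarray, crop_px: int) -> np.ndarray:
    h, w = image.shape
    side = min(crop_px, h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return image[r0:r0 + side, c0:c0 + side]


def preprocess(frame: AnalysisFrame, saturation: float = 0.35) -> np.ndarray:
    """Central crop, contrast stretch and Otsu threshold.

    ``saturation`` is the percentage of pixels saturated at *each* tail of
    the intensity histogram before thresholding.  A boolean (or two-valued)
    input is treated as an already segmented mask and passes through the
    crop unchanged.
    """
    image = np.asarray(frame.image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    image = _central_crop(image, frame.crop_px)
    if image.dtype == bool:
        return image.copy()
    uniq = np.unique(image)
    if uniq.size <= 2 and image.dtype.kind in "iu":
        return image > uniq.min()
    img = image.astype(float)
    lo, hi = np.percentile(img, [saturation, 100.0 - saturation])
    if hi <= lo:
        raise NoContrastError("image has no usable contrast")
    stretched = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    thr = threshold_otsu(stretched)
    return stretched > thr


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to a one-pixel-wide, 8-connected skeleton."""
    return _sk_skeletonize(np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _neighbours(coords: set[tuple[int, int]], p: tuple[int, int]) -> list[tuple[int, int]]:
    r, c = p
    return [(r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in coords]


def _path_length(path: Sequence[tuple[int, int]], pixel_size_um: float) -> float:
    steps = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        steps += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return steps * pixel_size_um


def _mesh_regions(skel: np.ndarray) -> tuple[list[float], list[int]]:
    """Enclosed background regions (4-connected), by border flood fill.

    Background is labelled with 4-connectivity — the dual of the
    8-connected foreground — and any region not reaching the image border
    is a mesh.  Mesh area counts background pixels only.
    """
    background = ~skel
    labels, n = ndimage.label(background, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return [], []
    border = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    border_set = set(border.tolist()) - {0}
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    sizes = [int(counts[lab]) for lab in range(1, n + 1) if lab not in border_set]
    return sizes, sizes


def build_graph(skeleton: np.ndarray, pixel_size_um: float = 2.82) -> NetworkGraph:
    """Trace a 1-px skeleton into nodes, polyline edges and meshes.

    Pixels are classified by 8-neighbour count (1 extremity, 2 slab,
    >= 3 junction); adjacent junction pixels merge into single nodes;
    maximal slab runs become edges with geometric arc length (diagonal
    steps count sqrt(2) pixels).  Multiple direct pixel adjacencies
    between the same two node clusters collapse to one edge (they are one
    physical junction contact).  The master subgraph is the 2-core.
    """
    skel = np.asarray(skeleton, dtype=bool)
    rr, cc = np.nonzero(skel)
    coords: set[tuple[int, int]] = set(zip(rr.tolist(), cc.tolist()))

    deg = {p: len(_neighbours(coords, p)) for p in coords}
    extremities = sorted(p for p, d in deg.items() if d == 1)
    junction_px = {p for p, d in deg.items() if d >= 3}

    # merge adjacent junction pixels into node clusters
    node_of: dict[tuple[int, int], int] = {}
    nodes: list[list[tuple[int, int]]] = []
    for p in sorted(junction_px):
        if p in node_of:
            continue
        cluster = []
        queue = deque([p])
        node_of[p] = len(nodes)
        while queue:
            q = queue.popleft()
            cluster.append(q)
            for nb in _neighbours(coords, q):
                if nb in junction_px and nb not in node_of:
                    node_of[nb] = len(nodes)
                    queue.append(nb)
        nodes.append(sorted(cluster))

    terminal = junction_px | set(extremities)
    edges: list[Edge] = []
    visited_slab: set[tuple[int, int]] = set()
    direct_cluster_pairs: set[frozenset] = set()

    def _anchor(p: tuple[int, int]) -> int | None:
        return node_of.get(p)

    def _add_edge(path: list[tuple[int, int]], is_loop: bool = False) -> None:
        a, b = path[0], path[-1]
        na, nb = _anchor(a), _anchor(b)
        if is_loop:
            kind = "segment"
        elif na is not None and nb is not None:
            kind = "segment"
        elif na is None and nb is None:
            kind = "isolated_segment"
        else:
            kind = "branch"
        edges.append(Edge(path=path, kind=kind,
                          length_um=_path_length(path, pixel_size_um),
                          node_ids=(na, nb), is_loop=is_loop))

    for p in sorted(terminal):
        for q in sorted(_neighbours(coords, p)):
            if q in terminal:
                pa, qa = _anchor(p), _anchor(q)
                if pa is not None and pa == qa:
                    continue  # intra-cluster adjacency
                key = frozenset((("n", pa) if pa is not None else ("e", p),
                                 ("n", qa) if qa is not None else ("e", q)))
                if key in direct_cluster_pairs:
                    continue
                direct_cluster_pairs.add(key)
                _add_edge([p, q])
            else:
                if q in visited_slab:
                    continue
                path = [p, q]
                visited_slab.add(q)
                prev, cur = p, q
                while True:
                    nxt_candidates = [r for r in _neighbours(coords, cur) if r != prev]
                    nxt = nxt_candidates[0]
                    path.append(nxt)
                    if nxt in terminal:
                        break
                    if nxt in visited_slab:  # closed back onto the start pixel region
                        break
                    visited_slab.add(nxt)
                    prev, cur = cur, nxt
                _add_edge(path)

    # pure slab cycles (rings with no junction): trace closed loops
    for p in sorted(coords):
        if p in terminal or p in visited_slab or deg[p] != 2:
            continue
        start = p
        visited_slab.add(p)
        nbs = sorted(_neighbours(coords, p))
        path = [p, nbs[0]]
        visited_slab.add(nbs[0])
        prev, cur = p, nbs[0]
        while True:
            nxt = [r for r in _neighbours(coords, cur) if r != prev][0]
            path.append(nxt)
            if nxt == start:
                break
            visited_slab.add(nxt)
            prev, cur = cur, nxt
        _add_edge(path, is_loop=True)

    # connected components of the skeleton (8-connected), incl. isolated pixels
    _, n_components = ndimage.label(skel, structure=np.ones((3, 3), dtype=int))

    mesh_sizes, _ = _mesh_regions(skel)
    mesh_areas = sorted(s * pixel_size_um**2 for s in mesh_sizes)

    graph = NetworkGraph(
        nodes=nodes,
        edges=edges,
        n_components=int(n_components),
        mesh_areas_um2=mesh_areas,
        mesh_pixel_counts=sorted(mesh_sizes),
        extremities=extremities,
        junction_pixel_count=len(junction_px),
        pixel_size_um=pixel_size_um,
        shape=skel.shape,
    )
    _mark_master(graph)
    return graph


def _mark_master(graph: NetworkGraph) -> None:
    """2-core of the network multigraph: iteratively strip degree-<2
    vertices.  Extremity anchors always prune away; closed loops survive
    as self-loops (degree 2)."""
    # vertex keys: ('n', node_id) or ('e', pixel); loops anchor to ('l', idx)
    adjacency: dict[tuple, list[int]] = {}
    endpoints: list[tuple[tuple, tuple]] = []
    for idx, e in enumerate(graph.edges):
        if e.is_loop:
            a = b = ("l", idx)
        else:
            na, nb = e.node_ids
            a = ("n", na) if na is not None else ("e", e.path[0])
            b = ("n", nb) if nb is not None else ("e", e.path[-1])
        endpoints.append((a, b))
        adjacency.setdefault(a, []).append(idx)
        if b != a:
            adjacency.setdefault(b, []).append(idx)

    alive_edges = set(range(len(graph.edges)))

    def _vdeg(v: tuple) -> int:
        d = 0
        for idx in adjacency.get(v, ()):
            if idx in alive_edges:
                a, b = endpoints[idx]
                d += 2 if a == b else 1
        return d

    changed = True
    while changed:
        changed = False
        for v in list(adjacency):
            if 0 < _vdeg(v) < 2:
                for idx in list(adjacency[v]):
                    if idx in alive_edges:
                        alive_edges.discard(idx)
                        changed = True
    graph.master_edge_idx = alive_edges
    graph.master_node_idx = {
        v[1] for v, idxs in adjacency.items()
        if v[0] == "n" and any(i in alive_edges for i in idxs)
    }


# ---------------------------------------------------------------------------
# Feature registry and extraction
# ---------------------------------------------------------------------------

def _edge_lengths(graph: NetworkGraph, kind: str | None = None, master: bool | None = None) -> float:
    total = 0.0
    for idx, e in enumerate(graph.edges):
        if kind is not None and e.kind != kind:
            continue
        if master is True and idx not in graph.master_edge_idx:
            continue
        total += e.length_um
    return total


def _registry() -> dict[str, Callable[[NetworkGraph, float], float]]:
    return {
        "nb_extremities": lambda g, a: len(g.extremities),
        "nb_nodes": lambda g, a: len(g.nodes),
        "nb_junctions": lambda g, a: g.junction_pixel_count,
        "nb_master_junctions": lambda g, a: len(g.master_node_idx),
        "nb_segments": lambda g, a: sum(1 for e in g.edges if e.kind == "segment"),
        "nb_master_segments": lambda g, a: sum(
            1 for i, e in enumerate(g.edges) if e.kind == "segment" and i in g.master_edge_idx),
        "nb_branches": lambda g, a: sum(1 for e in g.edges if e.kind == "branch"),
        "nb_isolated_segments": lambda g, a: sum(1 for e in g.edges if e.kind == "isolated_segment"),
        "nb_pieces": lambda g, a: g.n_components,
        "nb_meshes": lambda g, a: g.n_meshes,
        "tot_length": lambda g, a: _edge_lengths(g),
        "tot_segments_length": lambda g, a: _edge_lengths(g, kind="segment"),
        "tot_branches_length": lambda g, a: _edge_lengths(g, kind="branch"),
        "tot_isolated_branches_length": lambda g, a: _edge_lengths(g, kind="isolated_segment"),
        "tot_master_segments_length": lambda g, a: _edge_lengths(g, kind="segment", master=True),
        "tot_branching_length": lambda g, a: _edge_lengths(g) - _edge_lengths(g, kind="isolated_segment"),
        "branching_interval": lambda g, a: (
            _edge_lengths(g, kind="segment", master=True) / len(g.master_node_idx)
            if g.master_node_idx else 0.0),
        "tot_mesh_area": lambda g, a: sum(g.mesh_areas_um2),
        "mean_mesh_size": lambda g, a: (sum(g.mesh_areas_um2) / g.n_meshes) if g.n_meshes else 0.0,
        "mesh_index": lambda g, a: (sum(g.mesh_areas_um2) / a) if a > 0 else 0.0,
    }


#: Default object registry: name -> callable(graph, analysed_area_um2).
DEFAULT_REGISTRY = _registry()


def extract(graph: NetworkGraph, analysed_area_um2: float,
            registry: Mapping[str, Callable[[NetworkGraph, float], float]] | None = None,
            ) -> dict[str, float]:
    """Compute the vectorial objects of a network graph.

    Returns an ordered mapping of the 20 named features (or of a
    user-supplied registry overriding individual definitions).  Counts are
    returned as floats for table homogeneity; an empty graph yields an
    all-zero vector.
    """
    reg = dict(DEFAULT_REGISTRY)
    if registry:
        unknown = set(registry) - set(OBJECT_NAMES)
        if unknown:
            raise KeyError(f"unknown object definitions: {sorted(unknown)}")
        reg.update(registry)
    return {name: float(fn(graph, analysed_area_um2)) for name, fn in reg.items()}


def extract_from_image(image: np.ndarray, pixel_size_um: float = 2.82,
                       crop_px: int = 1000, saturation: float = 0.35,
                       registry=None) -> dict[str, float]:
    """Full per-image pipeline: preprocess -> skeletonise -> graph -> features."""
    frame = AnalysisFrame(image=image, pixel_size_um=pixel_size_um, crop_px=crop_px)
    mask = preprocess(frame, saturation=saturation)
    skel = skeletonize(mask)
    graph = build_graph(skel, pixel_size_um=pixel_size_um)
    area = mask.shape[0] * mask.shape[1] * pixel_size_um**2
    return extract(graph, area, registry=registry)


def exclude_objects(table: pd.DataFrame,
                    exclusion_list: Iterable[str] = DEFAULT_EXCLUDED) -> pd.DataFrame:
    """Drop outlier-prone objects from a long-format feature table.

    The default removes the two debris-sensitive counts (isolated
    segments, pieces), leaving 18 objects for scoring.
    """
    exclusion = list(exclusion_list)
    unknown = set(exclusion) - set(OBJECT_NAMES)
    if unknown:
        raise KeyError(f"unknown object name(s) in exclusion list: {sorted(unknown)}")
    out = table[~table["object"].isin(exclusion)].copy()
    if out.empty and not table.empty:
        logger.warning("exclusion list removed every object from the table")
    return out
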