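"""Synthetic pseudo-vascular networks with exact ground truth.

Two generators stand in for the microscopy side of a tube-formation assay:

* :func:`generate_network_image` rasterises a random Voronoi tessellation
  clipped to the image frame.  Cells seeded on a basement-membrane gel
  organise into interconnected polygonal networks; a clipped Voronoi diagram
  has the same qualitative topology (convex meshes bounded by thin tubes)
  while every count — meshes, extremities, junctions, components — is known
  exactly from the vector geometry before rasterisation.

* :func:`generate_trajectory_dataset` draws multi-well, multi-replicate
  object time series from known cubic mean trajectories with additive
  Gaussian well-level intercepts and observation noise, the generative
  counterpart of the cubic time-course model fitted downstream.

Ground truth is always computed on the vector geometry (never on pixels),
so the rasteriser can be tested against an independent oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, box
from shapely.ops import polygonize, unary_union
from skimage.draw import line as _draw_line
from skimage.morphology import dilation, disk


class DegenerateGeometryError(ValueError):
    """Raised when a tessellation cannot be resolved at the requested
    image size and stroke width (vertices or faces closer than the
    rasteriser can keep apart)."""


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of one synthetic binary network image.

    ``pixel_size_um`` mirrors the acquisition scale of a 4x phase-contrast
    live-cell imager (2.82 um per pixel).  ``n_seeds`` controls mesh count
    and size; ``stroke_px`` is the rendered tube thickness; a fraction of
    edges can be dropped to emulate partially dissolved networks.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 2.82
    n_seeds: int = 12
    stroke_px: int = 3
    dropout_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 64 or w < 64:
            raise ValueError("image_size_px must be at least (64, 64)")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1]")
        if self.stroke_px < 1:
            raise ValueError("stroke_px must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class GroundTruthTopology:
    """Exact counts and measures of the un-rasterised vector network."""

    n_meshes: int
    n_extremities: int
    n_junction_nodes: int
    n_components: int
    mesh_areas_um2: list[float]
    edge_lengths_um: list[float]

    def __post_init__(self) -> None:
        if len(self.mesh_areas_um2) != self.n_meshes:
            raise ValueError("mesh_areas_um2 must have length n_meshes")


# ---------------------------------------------------------------------------
# Vector geometry
# ---------------------------------------------------------------------------

def _sample_seeds(rng: np.random.Generator, n: int, w: float, h: float) -> np.ndarray:
    """Near-Poisson-disk seed points: uniform draws with a minimum pairwise
    separation, so Voronoi cells are comparably sized, as observed meshes are."""
    margin = 0.05 * min(w, h)
    d_min = 0.55 * min(w, h) / math.sqrt(n)
    pts: list[tuple[float, float]] = []
    for _ in range(4000 * n):
        p = (margin + rng.uniform() * (w - 2 * margin),
             margin + rng.uniform() * (h - 2 * margin))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= d_min**2 for q in pts):
            pts.append(p)
            if len(pts) == n:
                return np.asarray(pts)
    raise DegenerateGeometryError(
        f"could not place {n} seeds with separation {d_min:.1f}px in a "
        f"{w:.0f}x{h:.0f} frame"
    )


def _voronoi_segments(seeds: np.ndarray, w: float, h: float) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Voronoi ridges between seed cells, clipped to the frame rectangle.

    Four distant ghost seeds bound every real cell, so all ridges between
    real seeds are finite; ridges involving a ghost lie far outside the
    frame and are discarded by the clip.
    """
    from scipy.spatial import Voronoi

    far = 100.0 * max(w, h)
    cx, cy = w / 2.0, h / 2.0
    ghosts = np.array([[cx - far, cy], [cx + far, cy], [cx, cy - far], [cx, cy + far]])
    vor = Voronoi(np.vstack([seeds, ghosts]))
    n_real = len(seeds)
    frame = box(0.0, 0.0, w - 1.0, h - 1.0)
    segments = []
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n_real or q >= n_real:
            continue
        if -1 in verts:  # unbounded ridge: cannot happen with ghosts, but be safe
            continue
        a, b = vor.vertices[verts[0]], vor.vertices[verts[1]]
        clipped = LineString([a, b]).intersection(frame)
        if clipped.is_empty or clipped.geom_type != "LineString":
            continue
        (x0, y0), (x1, y1) = clipped.coords[0], clipped.coords[-1]
        if math.hypot(x1 - x0, y1 - y0) < 1e-9:
            continue
        segments.append(((x0, y0), (x1, y1)))
    return segments


def _segment_graph(segments) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for (a, b) in segments:
        ka = (round(a[0], 6), round(a[1], 6))
        kb = (round(b[0], 6), round(b[1], 6))
        g.add_edge(ka, kb, length=math.hypot(b[0] - a[0], b[1] - a[1]))
    return g


def _topology_from_graph(g: nx.MultiGraph, pixel_size_um: float) -> GroundTruthTopology:
    v = g.number_of_nodes()
    e = g.number_of_edges()
    c = nx.number_connected_components(g) if v else 0
    n_meshes = e - v + c  # bounded faces of a planar graph (Euler)
    degs = dict(g.degree())
    lines = [LineString([u, w]) for u, w, _ in g.edges(keys=True)]
    polys = list(polygonize(unary_union(lines))) if lines else []
    if len(polys) != n_meshes:  # pragma: no cover - internal consistency
        raise AssertionError("polygonised face count disagrees with Euler count")
    return GroundTruthTopology(
        n_meshes=n_meshes,
        n_extremities=sum(1 for d in degs.values() if d == 1),
        n_junction_nodes=sum(1 for d in degs.values() if d >= 3),
        n_components=c,
        mesh_areas_um2=sorted(p.area * pixel_size_um**2 for p in polys),
        edge_lengths_um=sorted(d["length"] * pixel_size_um for *_, d in g.edges(data=True)),
    )


def _validate_geometry(g: nx.MultiGraph, stroke_px: int) -> None:
    """Reject geometries the rasteriser cannot keep apart.

    Checks: vertex pair separation, vertex to non-incident edge clearance,
    and a positive interior for every bounded face after accounting for the
    stroke.  Voronoi faces are convex so a non-empty negative buffer
    guarantees interior background pixels survive the stroke.
    """
    clearance = stroke_px + 3.0
    nodes = list(g.nodes())
    for a, b in itertools.combinations(nodes, 2):
        if math.hypot(a[0] - b[0], a[1] - b[1]) < clearance:
            raise DegenerateGeometryError("vertices closer than raster clearance")
    edges = [(u, w) for u, w, _ in g.edges(keys=True)]
    lines = [LineString([u, w]) for u, w in edges]
    for n in nodes:
        for (u, w), ln in zip(edges, lines):
            if n in (u, w):
                continue
            if ln.distance(Point(n)) < clearance:
                raise DegenerateGeometryError("vertex too close to a non-incident edge")
    if lines:
        for poly in polygonize(unary_union(lines)):
            if poly.buffer(-(stroke_px / 2.0 + 2.5)).is_empty:
                raise DegenerateGeometryError("face too thin to resolve at this stroke")


def _rasterize(g: nx.MultiGraph, shape: tuple[int, int], stroke_px: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for u, v, _ in g.edges(keys=True):
        r0, c0 = int(round(u[1])), int(round(u[0]))
        r1, c1 = int(round(v[1])), int(round(v[0]))
        rr, cc = _draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True
    if stroke_px > 1:
        mask = dilation(mask, disk(stroke_px // 2))
    return _fill_raster_slivers(mask, stroke_px)


def _fill_raster_slivers(mask: np.ndarray, stroke_px: int) -> np.ndarray:
    """Fill sub-face-size enclosed background slivers.

    Where two strokes meet at a shallow angle the integer rasterisation can
    enclose a few stray background pixels.  The geometry validation
    guarantees every true face contains a disc of radius stroke/2 + 2.5 px,
    so enclosed regions smaller than (stroke+1)^2 pixels cannot be faces
    and are filled.
    """
    threshold = (stroke_px + 1) ** 2
    labels, n = ndimage.label(~mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n == 0:
        return mask
    border = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])).tolist()) - {0}
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    out = mask.copy()
    for lab in range(1, n + 1):
        if lab not in border and counts[lab] < threshold:
            out[labels == lab] = True
    return out


def generate_network_image(spec: SyntheticNetworkSpec) -> tuple[np.ndarray, GroundTruthTopology]:
    """Generate one binary network mask plus exact vector-geometry truth.

    Returns a boolean ``(H, W)`` mask (foreground = network) and the
    :class:`GroundTruthTopology` of the clipped tessellation after edge
    dropout.  Identical specs produce bit-identical outputs.

    Raises
    ------
    DegenerateGeometryError
        If ``n_seeds`` is too large for the frame to resolve distinct
        edges at ``stroke_px``.
    """
    h, w = spec.image_size_px
    rng = np.random.default_rng(spec.rng_seed)
    if spec.n_seeds == 1:
        # a single frame-clipped cell has no interior walls
        segments = []
    else:
        seeds = _sample_seeds(rng, spec.n_seeds, float(w), float(h))
        segments = _voronoi_segments(seeds, float(w), float(h))
    g = _segment_graph(segments)
    if spec.dropout_fraction > 0 and g.number_of_edges():
        all_edges = sorted(g.edges(keys=True))
        n_remove = int(round(spec.dropout_fraction * len(all_edges)))
        order = rng.permutation(len(all_edges))
        for i in order[:n_remove]:
            g.remove_edge(*all_edges[i])
        g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    if g.number_of_edges():
        _validate_geometry(g, spec.stroke_px)
    topo = _topology_from_graph(g, spec.pixel_size_um)
    mask = _rasterize(g, (h, w), spec.stroke_px)
    return mask, topo


# ---------------------------------------------------------------------------
# Network degradation
# ---------------------------------------------------------------------------

def degrade_network(mask: np.ndarray, removal_fraction: float, rng_seed: int = 0) -> np.ndarray:
    """Erase a fraction of skeleton segments from a binary network mask.

    Emulates network dissolution.  Segments are ordered by a seed-fixed
    random permutation and the first ``round(f * n)`` are erased, so the
    removal sets are nested: foreground count is non-increasing in
    ``removal_fraction`` and ``f = 0`` returns the mask unchanged.  Each
    removed segment is painted out at its local tube thickness (from the
    distance transform), sparing pixels that kept segments still claim.
    """
    if not 0.0 <= removal_fraction <= 1.0:
        raise ValueError("removal_fraction must lie in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if removal_fraction == 0.0:
        return mask.copy()
    if removal_fraction == 1.0:
        return np.zeros_like(mask)

    from . import morphometry

    skel = morphometry.skeletonize(mask)
    graph = morphometry.build_graph(skel, pixel_size_um=1.0)
    n_edges = len(graph.edges)
    if n_edges == 0:
        return mask.copy()
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n_edges)
    n_remove = int(round(removal_fraction * n_edges))
    removed = set(order[:n_remove].tolist())

    dist = ndimage.distance_transform_edt(mask)
    removed_paint = np.zeros_like(mask)
    kept_paint = np.zeros_like(mask)
    for idx, edge in enumerate(graph.edges):
        target = removed_paint if idx in removed else kept_paint
        for (r, c) in edge.path:
            rad = int(math.ceil(dist[r, c])) + 1
            rr0, rr1 = max(0, r - rad), min(mask.shape[0], r + rad + 1)
            cc0, cc1 = max(0, c - rad), min(mask.shape[1], c + rad + 1)
            yy, xx = np.ogrid[rr0:rr1, cc0:cc1]
            target[rr0:rr1, cc0:cc1] |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
    out = mask & ~(removed_paint & ~kept_paint)
    return out


# ---------------------------------------------------------------------------
# Trajectory datasets
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryDesign:
    """Generative design for multi-well object time series.

    ``true_beta`` maps ``(cell_line, object)`` to the cubic coefficients
    ``(b0, b1, b2, b3)`` of the mean trajectory; ``time_window`` maps each
    cell line to its analysis window ``(t_l, t_u)`` in hours.  Each well
    receives one Gaussian intercept per object (scale ``well_effect_sd``)
    shared by its technical replicates; observation noise is i.i.d. with
    scale ``noise_sd``.  Four replicates per well mirror the four imaged
    quadrants of a culture well.
    """

    cell_lines: list[str]
    objects: list[str]
    true_beta: dict[tuple[str, str], tuple[float, float, float, float]]
    time_window: dict[str, tuple[float, float]]
    n_timepoints: int = 13
    n_wells: int = 9
    n_replicates: int = 4
    well_effect_sd: float = 0.5
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_lines or not self.objects:
            raise ValueError("cell_lines and objects must be non-empty")
        if self.n_wells < 2 or self.n_replicates < 1 or self.n_timepoints < 2:
            raise ValueError("need n_wells >= 2, n_replicates >= 1, n_timepoints >= 2")
        if self.well_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for line in self.cell_lines:
            t_l, t_u = self.time_window[line]
            if not t_l < t_u:
                raise ValueError(f"time window for {line!r} must satisfy t_l < t_u")
            for obj in self.objects:
                if (line, obj) not in self.true_beta:
                    raise ValueError(f"true_beta missing entry for {(line, obj)!r}")


def generate_trajectory_dataset(design: TrajectoryDesign) -> pd.DataFrame:
    """Draw a long-format feature table from the cubic generative model.

    Columns: ``cell_line, well, quadrant, time_h, object, value`` — the
    same layout the image-analysis stage exports.  Deterministic given
    ``design.rng_seed``.
    """
    rng = np.random.default_rng(design.rng_seed)
    rows = []
    for line in design.cell_lines:
        t_l, t_u = design.time_window[line]
        times = np.linspace(t_l, t_u, design.n_timepoints)
        for well_i in range(design.n_wells):
            well = f"W{well_i + 1}"
            for obj in design.objects:
                b0, b1, b2, b3 = design.true_beta[(line, obj)]
                mean = b0 + b1 * times + b2 * times**2 + b3 * times**3
                well_effect = rng.normal(0.0, design.well_effect_sd) if design.well_effect_sd > 0 else 0.0
                for rep_i in range(design.n_replicates):
                    quadrant = f"Q{rep_i + 1}"
                    noise = (rng.normal(0.0, design.noise_sd, size=times.shape)
                             if design.noise_sd > 0 else np.zeros_like(times))
                    vals = mean + well_effect + noise
                    rows.extend(
                        (line, well, quadrant, float(t), obj, float(v))
                        for t, v in zip(times, vals)
                    )
    return pd.DataFrame(rows, columns=["cell_line", "well", "quadrant", "time_h", "object", "value"])


def example_design(rng_seed: int = 0) -> TrajectoryDesign:
    """A small three-line design with distinct trajectory shapes, handy for
    demonstrations and end-to-end runs."""
    lines = ["alpha", "beta", "gamma"]
    objects = ["nb_meshes", "tot_length", "nb_extremities"]
    windows = {"alpha": (8.0, 20.0), "beta": (10.0, 30.0), "gamma": (17.0, 29.0)}
    beta: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    shapes = {
        "alpha": {"nb_meshes": (20.0, 2.0, -0.08, 0.0),
                  "tot_length": (400.0, 10.0, -0.5, 0.0),
                  "nb_extremities": (60.0, -2.0, 0.05, 0.0)},
        "beta": {"nb_meshes": (35.0, -0.5, 0.0, 0.0),
                 "tot_length": (600.0, -6.0, 0.0, 0.0),
                 "nb_extremities": (40.0, 0.5, 0.0, 0.0)},
        "gamma": {"nb_meshes": (5.0, 1.5, 0.0, -0.002),
                  "tot_length": (300.0, 4.0, 0.1, -0.005),
                  "nb_extremities": (80.0, -3.0, 0.06, 0.0)},
    }
    for line in lines:
        for obj in objects:
            beta[(line, obj)] = shapes[line][obj]
    return TrajectoryDesign(
        cell_lines=lines, objects=objects, true_beta=beta, time_window=windows,
        rng_seed=rng_seed,
    )
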