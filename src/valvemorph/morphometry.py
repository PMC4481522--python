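"""Skeleton-graph morphometry of valve silica patterns.

A thinned valve pattern is turned into a graph whose vertices are
junctions (pixels where three or more silica ribs meet, merged into one
vertex when adjacent) and extremities (free rib tips), and whose edges
are the pixel polylines between them.  Enclosed background regions —
areas fully surrounded by silica — are the pattern's *meshes*.  From
graph and meshes a fixed 22-feature morphometric vector is computed per
image, in the style of angiogenesis-network quantification tools.

Pixel adjacency is 8-connected, except that a diagonal link between two
pixels that also share a foreground orthogonal neighbor is dropped: such
links are redundant for connectivity and would otherwise create
zero-area triangular cycles that break the planar Euler relation
``n_meshes = E - V + C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .imageprep import BinaryMask, SkeletonMask, count_holes

SQRT2 = math.sqrt(2.0)

_ORTH = [(-1, 0), (1, 0), (0, -1), (0, 1)]
_DIAG = [(-1, -1), (-1, 1), (1, -1), (1, 1)]


@dataclass(frozen=True)
class Vertex:
    id: int
    kind: str  # "junction" | "extremity" | "cycle"
    anchor: tuple[int, int]  # representative pixel, row-major minimal
    pixels: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class Edge:
    id: int
    endpoints: tuple[int, int]  # vertex ids (u <= v)
    kind: str  # "branch" | "segment" | "isolated"
    polyline: tuple[tuple[int, int], ...]
    length_px: float


@dataclass
class SkeletonGraph:
    vertices: list[Vertex]
    edges: list[Edge]
    n_components: int
    pixel_size_um: float = 1.0

    @property
    def n_junctions(self) -> int:
        return sum(v.kind == "junction" for v in self.vertices)

    @property
    def n_extremities(self) -> int:
        return sum(v.kind == "extremity" for v in self.vertices)

    def total_length_px(self) -> float:
        return float(sum(e.length_px for e in self.edges))

    def cyclomatic_number(self) -> int:
        """E - V + C: number of independent cycles of the graph."""
        return len(self.edges) - len(self.vertices) + self.n_components


@dataclass
class MeshSet:
    """Bounded faces of the pattern: background regions enclosed by silica."""

    areas_px2: list[int]
    pixel_size_um: float = 1.0

    @property
    def n_meshes(self) -> int:
        return len(self.areas_px2)

    @property
    def total_area_px2(self) -> float:
        return float(sum(self.areas_px2))

    def areas_um2(self) -> np.ndarray:
        return np.asarray(self.areas_px2, float) * self.pixel_size_um**2


@dataclass
class ValveAnnotation:
    """Manual per-valve annotations that are inputs, not detected."""

    rimoportulae_count: int = 0
    valve_area_um2: float | None = None

    def __post_init__(self) -> None:
        if self.rimoportulae_count < 0:
            raise ValueError("rimoportulae_count must be >= 0")


FEATURE_NAMES = [
    "n_extremities",
    "n_nodes",
    "n_junctions",
    "n_master_junctions",
    "n_segments",
    "n_master_segments",
    "n_branches",
    "n_isolated",
    "total_segment_length",
    "total_master_segment_length",
    "total_branch_length",
    "total_isolated_length",
    "total_length",
    "mean_segment_length",
    "mean_branch_length",
    "branching_interval",
    "n_meshes",
    "total_mesh_area",
    "mean_mesh_area",
    "mesh_index",
    "valve_diameter_um",
    "rimoportulae_per_area",
]


@dataclass
class FeatureVector:
    """The 22 morphometric features of one valve image.

    Lengths are in micrometres, areas in square micrometres; counts are
    non-negative integers.  ``total_length`` is the sum of segment,
    branch and isolated lengths; ``mesh_index`` is total skeleton length
    per mesh and ``branching_interval`` total length per junction.
    """

    n_extremities: int = 0
    n_nodes: int = 0
    n_junctions: int = 0
    n_master_junctions: int = 0
    n_segments: int = 0
    n_master_segments: int = 0
    n_branches: int = 0
    n_isolated: int = 0
    total_segment_length: float = 0.0
    total_master_segment_length: float = 0.0
    total_branch_length: float = 0.0
    total_isolated_length: float = 0.0
    total_length: float = 0.0
    mean_segment_length: float = 0.0
    mean_branch_length: float = 0.0
    branching_interval: float = 0.0
    n_meshes: int = 0
    total_mesh_area: float = 0.0
    mean_mesh_area: float = 0.0
    mesh_index: float = 0.0
    valve_diameter_um: float = 0.0
    rimoportulae_per_area: float = 0.0

    def to_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


def _pixel_adjacency(sk: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    """Reduced 8-adjacency: diagonal links with a shared orthogonal
    foreground neighbor are dropped (they are connectivity-redundant)."""
    pix = set(map(tuple, np.argwhere(sk)))
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for p in pix:
        r, c = p
        nbrs = []
        for dr, dc in _ORTH:
            q = (r + dr, c + dc)
            if q in pix:
                nbrs.append(q)
        for dr, dc in _DIAG:
            q = (r + dr, c + dc)
            if q in pix and (r + dr, c) not in pix and (r, c + dc) not in pix:
                nbrs.append(q)
        adj[p] = nbrs
    return adj


def build_skeleton_graph(sk: SkeletonMask) -> SkeletonGraph:
    """Build the junction/extremity graph of a thin skeleton.

    Junction pixels (>= 3 reduced-adjacency neighbors) that touch are
    merged into a single junction vertex.  Edge polylines carry their
    length measured along the pixel chain with diagonal steps counted as
    sqrt(2).  A component that is a pure cycle (no junction, no
    extremity) gets an anchor vertex of kind "cycle" carrying a
    self-loop edge, so the Euler relation stays exact.  Vertices and
    edges are ordered row-major by anchor pixel, making the result
    deterministic.
    """
    mask = np.asarray(sk.pixels, bool)
    adj = _pixel_adjacency(mask)
    if not adj:
        return SkeletonGraph([], [], 0, sk.pixel_size_um)
    deg = {p: len(ns) for p, ns in adj.items()}

    # --- junction clusters -------------------------------------------------
    junction_pix = {p for p, d in deg.items() if d >= 3}
    cluster_of: dict[tuple[int, int], int] = {}
    clusters: list[list[tuple[int, int]]] = []
    for p in sorted(junction_pix):
        if p in cluster_of:
            continue
        stack, comp = [p], []
        cluster_of[p] = len(clusters)
        while stack:
            q = stack.pop()
            comp.append(q)
            for w in adj[q]:
                if w in junction_pix and w not in cluster_of:
                    cluster_of[w] = len(clusters)
                    stack.append(w)
        clusters.append(sorted(comp))

    vertices: list[Vertex] = []
    vertex_of: dict[tuple[int, int], int] = {}
    for comp in sorted(clusters, key=lambda c: c[0]):
        vid = len(vertices)
        vertices.append(Vertex(vid, "junction", comp[0], tuple(comp)))
        for q in comp:
            vertex_of[q] = vid
    for p in sorted(p for p, d in deg.items() if d <= 1):
        vid = len(vertices)
        vertices.append(Vertex(vid, "extremity", p, (p,)))
        vertex_of[p] = vid

    # --- trace edges -------------------------------------------------------
    edges: list[Edge] = []
    seen_interior: set[tuple[int, int]] = set()
    seen_direct: set[frozenset] = set()

    def add_edge(u: int, v: int, poly: list[tuple[int, int]], length: float) -> None:
        a, b = (u, v) if u <= v else (v, u)
        edges.append(Edge(len(edges), (a, b), "", tuple(poly), length))

    for start in sorted(vertex_of):
        u = vertex_of[start]
        for nxt in adj[start]:
            if nxt in vertex_of:
                # direct vertex-vertex adjacency (no interior pixels)
                if vertex_of[nxt] == u and vertex_of[start] == vertex_of[nxt] and nxt != start:
                    continue  # intra-cluster link
                key = frozenset((start, nxt))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                if vertex_of[nxt] == u:
                    continue
                step = 1.0 if start[0] == nxt[0] or start[1] == nxt[1] else SQRT2
                add_edge(u, vertex_of[nxt], [start, nxt], step)
                continue
            if nxt in seen_interior:
                continue
            # walk the degree-2 chain
            poly = [start, nxt]
            length = 1.0 if start[0] == nxt[0] or start[1] == nxt[1] else SQRT2
            prev, cur = start, nxt
            while cur not in vertex_of:
                seen_interior.add(cur)
                nbrs = [w for w in adj[cur] if w != prev]
                if not nbrs:
                    break  # dangling chain end (shouldn't happen on thin input)
                w = nbrs[0]
                length += 1.0 if cur[0] == w[0] or cur[1] == w[1] else SQRT2
                poly.append(w)
                prev, cur = cur, w
            if cur in vertex_of:
                add_edge(u, vertex_of[cur], poly, length)
            else:
                add_edge(u, u, poly, length)

    # --- pure cycles (components with no vertex pixel) ---------------------
    visited = set(vertex_of) | seen_interior
    for v in vertices:
        visited.update(v.pixels)
    remaining = sorted(set(adj) - visited)
    while remaining:
        anchor = remaining[0]
        vid = len(vertices)
        vertices.append(Vertex(vid, "cycle", anchor, (anchor,)))
        poly = [anchor]
        length = 0.0
        prev, cur = None, anchor
        while True:
            nbrs = [w for w in adj[cur] if w != prev]
            if not nbrs:
                break
            w = nbrs[0]
            length += 1.0 if cur[0] == w[0] or cur[1] == w[1] else SQRT2
            poly.append(w)
            prev, cur = cur, w
            if cur == anchor:
                break
        edges.append(Edge(len(edges), (vid, vid), "isolated", tuple(poly), length))
        remaining = sorted(set(remaining) - set(poly))

    # --- classify edges ----------------------------------------------------
    kind_of = {v.id: v.kind for v in vertices}
    classified: list[Edge] = []
    for e in edges:
        if e.kind:  # cycle edges already tagged
            classified.append(e)
            continue
        ka, kb = kind_of[e.endpoints[0]], kind_of[e.endpoints[1]]
        if ka == "junction" and kb == "junction":
            kind = "segment"
        elif "junction" in (ka, kb):
            kind = "branch"
        else:
            kind = "isolated"
        classified.append(Edge(e.id, e.endpoints, kind, e.polyline, e.length_px))

    # --- faces enclosed entirely by one junction cluster -------------------
    # A dense cluster can itself surround background; represent each such
    # hole as a zero-length self-loop so E - V + C still counts all faces.
    for v in vertices:
        if v.kind != "junction" or len(v.pixels) < 8:
            continue
        rs = [p[0] for p in v.pixels]
        cs = [p[1] for p in v.pixels]
        sub = np.zeros((max(rs) - min(rs) + 3, max(cs) - min(cs) + 3), bool)
        for r, c in v.pixels:
            sub[r - min(rs) + 1, c - min(cs) + 1] = True
        for _ in range(count_holes(sub)):
            classified.append(
                Edge(len(classified), (v.id, v.id), "segment", (v.anchor,), 0.0)
            )

    # --- connected components over the pixel graph -------------------------
    lab, n_comp = ndimage.label(mask, structure=np.ones((3, 3), bool))
    # isolated single pixels with no edges still count as components
    return SkeletonGraph(vertices, classified, int(n_comp), sk.pixel_size_um)


def detect_meshes(sk: SkeletonMask) -> MeshSet:
    """Find meshes: 4-connected background regions not touching the border.

    The mesh area is the enclosed background pixel count — "silica
    surrounding an area" — converted to square micrometres downstream.
    """
    mask = np.asarray(sk.pixels, bool)
    lab, n = ndimage.label(~mask)  # 4-connected background
    if n == 0:
        return MeshSet([], sk.pixel_size_um)
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border = set(int(b) for b in border if b > 0)
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    areas = [int(counts[i]) for i in range(1, n + 1) if i not in border]
    return MeshSet(sorted(areas, reverse=True), sk.pixel_size_um)


def estimate_valve_diameter(valve_mask: BinaryMask) -> float:
    """Equivalent-area diameter (um) of the mask's convex hull.

    The diameter of the circle whose area equals the convex hull of the
    foreground; for a filled disc this is its true diameter.
    """
    m = np.asarray(valve_mask.pixels, bool)
    if not m.any():
        raise ValueError("empty mask")
    hull = convex_hull_image(m)
    area_px2 = float(hull.sum())
    d_px = 2.0 * math.sqrt(area_px2 / math.pi)
    return d_px * valve_mask.pixel_size_um


def compute_features(
    g: SkeletonGraph,
    m: MeshSet,
    ann: ValveAnnotation | None = None,
    valve_mask: BinaryMask | None = None,
) -> FeatureVector:
    """Assemble the 22-feature vector from graph, meshes and annotations.

    Master junctions are junctions with >= 3 incident junction-junction
    segments; master segments join two master junctions.  Lengths are
    converted to micrometres with the skeleton's pixel size.
    """
    if valve_mask is not None and valve_mask.pixel_size_um != g.pixel_size_um:
        raise ValueError("pixel size mismatch between skeleton graph and valve mask")
    px = g.pixel_size_um
    ann = ann or ValveAnnotation()

    segs = [e for e in g.edges if e.kind == "segment"]
    branches = [e for e in g.edges if e.kind == "branch"]
    isolated = [e for e in g.edges if e.kind == "isolated"]

    seg_count_at: dict[int, int] = {}
    for e in segs:
        for vid in set(e.endpoints):
            seg_count_at[vid] = seg_count_at.get(vid, 0) + (
                2 if e.endpoints[0] == e.endpoints[1] else 1
            )
    master = {vid for vid, k in seg_count_at.items() if k >= 3}
    master_segs = [e for e in segs if set(e.endpoints) <= master]

    tot_seg = sum(e.length_px for e in segs) * px
    tot_branch = sum(e.length_px for e in branches) * px
    tot_iso = sum(e.length_px for e in isolated) * px
    total = tot_seg + tot_branch + tot_iso

    n_j = g.n_junctions
    n_e = g.n_extremities
    n_meshes = m.n_meshes
    mesh_area = m.total_area_px2 * px**2

    diam = estimate_valve_diameter(valve_mask) if valve_mask is not None else 0.0
    valve_area = ann.valve_area_um2
    if valve_area is None:
        valve_area = math.pi * (diam / 2.0) ** 2 if diam > 0 else 0.0
    rpa = ann.rimoportulae_count / valve_area if valve_area > 0 else 0.0

    return FeatureVector(
        n_extremities=n_e,
        n_nodes=n_j + n_e,
        n_junctions=n_j,
        n_master_junctions=len(master),
        n_segments=len(segs),
        n_master_segments=len(master_segs),
        n_branches=len(branches),
        n_isolated=len(isolated),
        total_segment_length=tot_seg,
        total_master_segment_length=sum(e.length_px for e in master_segs) * px,
        total_branch_length=tot_branch,
        total_isolated_length=tot_iso,
        total_length=total,
        mean_segment_length=tot_seg / len(segs) if segs else 0.0,
        mean_branch_length=tot_branch / len(branches) if branches else 0.0,
        branching_interval=total / max(n_j, 1),
        n_meshes=n_meshes,
        total_mesh_area=mesh_area,
        mean_mesh_area=mesh_area / n_meshes if n_meshes else 0.0,
        mesh_index=total / max(n_meshes, 1),
        valve_diameter_um=diam,
        rimoportulae_per_area=rpa,
    )
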