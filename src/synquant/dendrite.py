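"""Dendrite tracing, length measurement, SWC import/export and Sholl analysis.

Tracing is a morphological-skeleton stand-in for interactive tracing
software: the cell-fill mask is skeletonized, converted to a pixel graph
and decomposed into branch polylines; diagonal steps count as sqrt(2)
pixels.  Sholl intersections are counted exactly as segment-circle
crossings on the vectorized trace, at concentric radii in 10 μm steps
from the soma centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from . import stats as sqstats


def _polyline_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


@dataclass
class DendriteTrace:
    """Vector trace of a dendritic arbor.

    ``polylines`` are (N, 2) arrays of (row, col) coordinates in μm; each
    polyline is an unbranched chain, the union forms the arbor.
    ``total_length`` is the sum of all segment lengths.
    """

    polylines: list[np.ndarray]
    soma_center: tuple[float, float]
    total_length: float = field(default=0.0)
    source: str = "traced"

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=float).reshape(-1, 2) for p in self.polylines]
        length = sum(_polyline_length(p) for p in self.polylines)
        if self.total_length == 0.0:
            self.total_length = length
        elif abs(self.total_length - length) > 1e-6:
            raise ValueError(
                f"total_length {self.total_length} inconsistent with polylines ({length})"
            )

    @property
    def max_extent(self) -> float:
        """Largest distance of any trace vertex from the soma (μm)."""
        c = np.asarray(self.soma_center)
        return max(
            (float(np.max(np.linalg.norm(p - c, axis=1))) for p in self.polylines if len(p)),
            default=0.0,
        )


@dataclass
class ShollProfile:
    """Intersection counts at concentric radii (arithmetic progression)."""

    radii: np.ndarray
    intersections: np.ndarray
    step: float = 10.0


# ---------------------------------------------------------------------------
# tracing

def _skeleton_graph(skel: np.ndarray, pixel_size: float) -> nx.Graph:
    """8-connected pixel graph of a skeleton; edge weights in μm."""
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pixels:
        g.add_node((r, c))
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
            nb = (r + dr, c + dc)
            if nb in pixels:
                w = pixel_size * (math.sqrt(2.0) if dr and dc else 1.0)
                g.add_edge((r, c), nb, weight=w)
    return g


def _graph_to_polylines(g: nx.Graph, pixel_size: float) -> list[np.ndarray]:
    """Decompose a tree graph into unbranched polylines between junctions/tips."""
    polylines: list[np.ndarray] = []
    done: set[frozenset] = set()
    breakpoints = [n for n in g if g.degree(n) != 2]
    for start in breakpoints:
        for nb in g.neighbors(start):
            if frozenset((start, nb)) in done:
                continue
            path = [start, nb]
            done.add(frozenset((start, nb)))
            while g.degree(path[-1]) == 2:
                nxt = next(n for n in g.neighbors(path[-1]) if n != path[-2])
                done.add(frozenset((path[-1], nxt)))
                path.append(nxt)
            polylines.append(np.asarray(path, dtype=float) * pixel_size)
    if not polylines and g.number_of_edges():  # pure cycle: break it at an arbitrary node
        cyc = nx.find_cycle(g)
        pts = [e[0] for e in cyc] + [cyc[-1][1]]
        polylines.append(np.asarray(pts, dtype=float) * pixel_size)
    return polylines


def trace_dendrites(cell_fill_mask: np.ndarray, pixel_size: float) -> DendriteTrace:
    """Skeletonize the largest component of the cell-fill mask into a trace.

    The soma centre is the centre of the maximal disk inscribed in the
    mask (argmax of the Euclidean distance transform).  Spurious pixel
    cycles of the 8-connected skeleton graph are removed by a minimum
    spanning tree before branch decomposition.
    """
    mask = np.asarray(cell_fill_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cell-fill mask is empty; nothing to trace")
    labeled = measure.label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labeled.ravel())[1:]) + 1
    comp = labeled == largest
    edt = ndimage.distance_transform_edt(comp)
    soma_px = np.unravel_index(int(np.argmax(edt)), edt.shape)
    skel = morphology.skeletonize(comp)
    g = _skeleton_graph(skel, pixel_size)
    if g.number_of_edges() == 0:
        raise ValueError("skeleton degenerate (single pixel); mask too small to trace")
    tree = nx.minimum_spanning_tree(g, weight="weight")
    polylines = _graph_to_polylines(tree, pixel_size)
    soma = (float(soma_px[0]) * pixel_size, float(soma_px[1]) * pixel_size)
    return DendriteTrace(polylines=polylines, soma_center=soma, source="traced")


# ---------------------------------------------------------------------------
# SWC import/export

def import_trace(path: str | Path) -> DendriteTrace:
    """Read an SWC morphology file into a trace (2D projection: x->col, y->row).

    Length is reconstructed from parent-child records (3D distance if z is
    used); the soma is the first type-1 node, falling back to the root.
    """
    path = Path(path)
    nodes: dict[int, tuple[float, float, float, int, int]] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"{path}:{line_no}: malformed SWC record {line!r}")
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z = (float(v) for v in parts[2:5])
            parent = int(parts[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{line_no}: malformed SWC record {line!r}") from exc
        nodes[nid] = (x, y, z, ntype, parent)
    if not nodes:
        raise ValueError(f"{path}: empty SWC file")
    for nid, (_, _, _, _, parent) in nodes.items():
        if parent != -1 and parent not in nodes:
            raise ValueError(f"{path}: node {nid} references missing parent {parent}")

    children: dict[int, list[int]] = {nid: [] for nid in nodes}
    roots = []
    for nid, (_, _, _, _, parent) in nodes.items():
        if parent == -1:
            roots.append(nid)
        else:
            children[parent].append(nid)

    def pt(nid: int) -> tuple[float, float]:
        x, y, _, _, _ = nodes[nid]
        return (y, x)  # (row, col) in μm

    length = 0.0
    for nid, (x, y, z, _, parent) in nodes.items():
        if parent != -1:
            px, py, pz, _, _ = nodes[parent]
            length += math.dist((x, y, z), (px, py, pz))

    # chain decomposition: breakpoints are roots and nodes of degree != 2
    def degree(nid: int) -> int:
        return len(children[nid]) + (0 if nodes[nid][4] == -1 else 1)

    polylines: list[np.ndarray] = []
    breakpoints = [nid for nid in nodes if degree(nid) != 2 or nodes[nid][4] == -1]
    for bp in breakpoints:
        for child in children[bp]:
            chain = [bp, child]
            while degree(chain[-1]) == 2 and children[chain[-1]]:
                chain.append(children[chain[-1]][0])
            polylines.append(np.asarray([pt(n) for n in chain], dtype=float))

    soma_nodes = [nid for nid, v in nodes.items() if v[3] == 1]
    soma_id = soma_nodes[0] if soma_nodes else roots[0]
    return DendriteTrace(polylines=polylines, soma_center=pt(soma_id), source="imported")


def export_trace(trace: DendriteTrace, path: str | Path) -> None:
    """Write a trace as SWC (type 1 soma node, type 3 dendrite nodes)."""
    path = Path(path)
    lines = ["# SWC export; coordinates in μm (x=col, y=row, z=0)"]
    index: dict[tuple[float, float], int] = {}
    nid = 1
    sr, sc = trace.soma_center
    lines.append(f"1 1 {sc:.10g} {sr:.10g} 0.0 1.0 -1")
    index[(round(sr, 9), round(sc, 9))] = 1
    nid = 2
    for poly in trace.polylines:
        parent = -1
        for i, (r, c) in enumerate(poly):
            key = (round(float(r), 9), round(float(c), 9))
            if key in index:
                parent = index[key]
                continue
            lines.append(f"{nid} 3 {c:.10g} {r:.10g} 0.0 0.5 {parent}")
            index[key] = nid
            parent = nid
            nid += 1
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sholl

def _segment_circle_crossings(p0, p1, center, r: float) -> int:
    """Number of transversal intersections of segment p0->p1 with circle(center, r).

    Roots are counted in the half-open parameter interval [0, 1) so that a
    crossing exactly at a shared polyline vertex is counted once; tangency
    (double root) is ignored.
    """
    d = p1 - p0
    f = p0 - center
    a = float(d @ d)
    if a == 0.0:
        return 0
    b = 2.0 * float(f @ d)
    c = float(f @ f) - r * r
    disc = b * b - 4.0 * a * c
    if disc <= 1e-12 * max(1.0, b * b):
        return 0
    sq = math.sqrt(disc)
    count = 0
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if 0.0 <= t < 1.0:
            count += 1
    return count


def sholl(trace: DendriteTrace, step: float = 10.0) -> ShollProfile:
    """Sholl profile: intersections with concentric circles every ``step`` μm.

    Radii start at ``step`` and extend to the first radius beyond the
    maximal branch extent (which therefore records zero intersections).
    """
    if step <= 0:
        raise ValueError("Sholl step must be positive")
    if trace.soma_center is None:
        raise ValueError("trace has no soma centre")
    center = np.asarray(trace.soma_center, dtype=float)
    n_radii = int(math.floor(trace.max_extent / step)) + 1
    radii = step * np.arange(1, n_radii + 1, dtype=float)
    counts = np.zeros(n_radii, dtype=int)
    for poly in trace.polylines:
        for p0, p1 in zip(poly[:-1], poly[1:]):
            for i, r in enumerate(radii):
                counts[i] += _segment_circle_crossings(p0, p1, center, float(r))
    return ShollProfile(radii=radii, intersections=counts, step=step)


def profile_table(profiles: list[ShollProfile]) -> pd.DataFrame:
    """Per-radius table of intersection counts, one column per cell."""
    if not profiles:
        raise ValueError("no profiles")
    step = profiles[0].step
    max_len = max(len(p.radii) for p in profiles)
    radii = step * np.arange(1, max_len + 1)
    data = {"radius_um": radii}
    for i, p in enumerate(profiles):
        col = np.zeros(max_len, dtype=int)
        col[: len(p.intersections)] = p.intersections
        data[f"cell_{i}"] = col
    return pd.DataFrame(data)


def compare_sholl(
    profiles_a: list[ShollProfile],
    profiles_b: list[ShollProfile],
    names: tuple[str, str] = ("a", "b"),
) -> tuple[sqstats.StatReport, pd.DataFrame]:
    """K-S test on pooled intersection-count distributions of two groups.

    Also returns a per-radius summary table (group means ± SEM) on the
    union radii grid, profiles padded with zeros beyond their extent.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("both groups need at least one profile")
    ta, tb = profile_table(profiles_a), profile_table(profiles_b)
    pooled_a = np.concatenate([p.intersections for p in profiles_a])
    pooled_b = np.concatenate([p.intersections for p in profiles_b])
    report = sqstats.ks_two_sample(pooled_a, pooled_b, names=names)
    report.test = "sholl_ks"
    max_len = max(len(ta), len(tb))
    step = profiles_a[0].step
    rows = []
    for k in range(max_len):
        row = {"radius_um": step * (k + 1)}
        for name, tab, profs in ((names[0], ta, profiles_a), (names[1], tb, profiles_b)):
            vals = (
                tab.iloc[k, 1:].to_numpy(dtype=float)
                if k < len(tab)
                else np.zeros(len(profs))
            )
            row[f"mean_{name}"] = float(vals.mean())
            row[f"sem_{name}"] = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append(row)
    return report, pd.DataFrame(rows)
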