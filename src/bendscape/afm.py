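"""AFM height-map analysis: flattening, molecule tracing and per-molecule metrics.

The stage mirrors a standard single-molecule AFM workflow for surface-deposited
DNA: images are flattened line-by-line plus a global second-order surface fit,
scarred scan lines are repaired, molecules are segmented by height threshold and
skeletonised to one-pixel contours, and each contour yields dimensional metrics
(contour length, end-to-end distance, radius of gyration) and a single bend
angle measured around the highest point along the contour (the bound protein,
when present).

Conventions: heights in nm, coordinates row-major with origin at the top-left
pixel, 0-based; trace points are reported in nm. The bend angle is 0 deg for
straight DNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "AFMImage",
    "MoleculeTrace",
    "TraceMetrics",
    "ClusterVolume",
    "preprocess",
    "segment_and_trace",
    "filter_by_contour_length",
    "trace_metrics",
    "measure_bend_angle",
    "cluster_volumes",
]


@dataclass
class AFMImage:
    """A calibrated AFM height map.

    Parameters
    ----------
    heights
        2D array of heights in nm.
    pixel_nm
        Lateral size of one pixel in nm.
    provenance
        Free-text metadata (instrument, generator parameters, ...).
    """

    heights: np.ndarray
    pixel_nm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


@dataclass
class MoleculeTrace:
    """Ordered skeleton contour of one traced molecule.

    ``points`` are (x, y) positions in nm along the path (x = column
    direction, y = row direction); ``heights`` are the image heights
    sampled at each path pixel. ``pixels`` keeps the raw (row, col)
    path for provenance. ``n_endpoints`` counts skeleton endpoints of
    the source component; components with more than 4 endpoints are
    treated as aggregates downstream.
    """

    points: np.ndarray
    heights: np.ndarray
    mask_id: int
    pixel_nm: float
    pixels: np.ndarray = field(default=None, repr=False)
    n_endpoints: int = 2
    #: full skeleton pixel graph with sub-pixel node positions (nm) in the
    #: "pos_nm" node attribute; present for image-derived traces and used
    #: by the bend-angle stage to handle folded molecules whose arms merge
    #: near the apex.
    graph: Optional[nx.Graph] = field(default=None, repr=False)
    #: sub-pixel position (nm) of the highest feature of the source
    #: component (the bound protein, when present).
    apex_nm: Optional[np.ndarray] = field(default=None, repr=False)
    apex_px: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a trace needs at least 2 points")
        if len(self.points) != len(self.heights):
            raise ValueError("points and heights must have equal length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_aggregate(self) -> bool:
        return self.n_endpoints > 4


@dataclass
class TraceMetrics:
    """Dimensional metrics of a traced molecule."""

    contour_length_nm: float
    end_to_end_nm: float
    radius_of_gyration_nm: float
    nm_per_bp: Optional[float] = None
    bend_angle_deg: Optional[float] = None
    peak_index: Optional[int] = None


@dataclass
class ClusterVolume:
    """Zero-basis volume of one segmented cluster."""

    mask_id: int
    pixel_count: int
    volume_nm3: float


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _robust_sigma(values: np.ndarray) -> float:
    """Noise scale from the median absolute deviation."""
    med = np.median(values)
    return 1.4826 * np.median(np.abs(values - med))


def _background_polyfit_row(row: np.ndarray, order: int = 1) -> np.ndarray:
    """Fit a low-order polynomial to the background pixels of one scan line.

    Pixels well above the row median (molecules) are excluded by an
    initial quartile cut followed by one re-fit on small residuals.
    """
    x = np.arange(row.size)
    cut = np.quantile(row, 0.75)
    mask = row <= cut
    if mask.sum() < order + 1:
        mask = np.ones_like(mask)
    coef = np.polyfit(x[mask], row[mask], order)
    resid = row - np.polyval(coef, x)
    sigma = _robust_sigma(resid[mask])
    if sigma > 0:
        mask2 = np.abs(resid) < 3 * sigma
        if mask2.sum() >= order + 1:
            coef = np.polyfit(x[mask2], row[mask2], order)
    return np.polyval(coef, x)


def _fit_global_quadratic(heights: np.ndarray) -> np.ndarray:
    """Least-squares second-order surface over background pixels."""
    rows, cols = heights.shape
    r, c = np.mgrid[0:rows, 0:cols]
    r = (r - rows / 2) / rows
    c = (c - cols / 2) / cols
    design = np.stack(
        [np.ones_like(r), r, c, r * c, r**2, c**2], axis=-1
    ).reshape(-1, 6)
    h = heights.ravel()
    mask = h <= np.quantile(h, 0.75)
    coef, *_ = np.linalg.lstsq(design[mask], h[mask], rcond=None)
    return (design @ coef).reshape(heights.shape)


def _detect_scar_rows(heights: np.ndarray, nsigma: float = 5.0,
                      min_run: int = 10) -> list[int]:
    """Rows deviating from BOTH neighbours by > nsigma*sigma over a run.

    A scar is a scan-line artifact: a contiguous stretch of pixels in one
    row offset from the rows above and below.
    """
    rows = heights.shape[0]
    diffs = np.abs(np.diff(heights, axis=0))
    sigma = _robust_sigma(diffs)
    if sigma == 0:
        sigma = 1e-12
    scars = []
    for i in range(1, rows - 1):
        dev = np.minimum(np.abs(heights[i] - heights[i - 1]),
                         np.abs(heights[i] - heights[i + 1]))
        flag = dev > nsigma * sigma
        # longest run of consecutive flagged pixels
        run = best = 0
        for f in flag:
            run = run + 1 if f else 0
            best = max(best, run)
        if best >= min_run:
            scars.append(i)
    return scars


def preprocess(image: AFMImage, scar_nsigma: float = 5.0,
               scar_min_run: int = 10) -> AFMImage:
    """Flatten an AFM image and repair scarred scan lines.

    Applies, in order: per-row linear background subtraction (fit against
    background pixels), a global second-order polynomial surface
    subtraction, scar detection/repair by interpolation from the adjacent
    rows, and a final background-median shift so that the substrate sits
    at ~0 nm.
    """
    h = image.heights
    if h.shape[0] < 8 or h.shape[1] < 8:
        raise ValueError("image too small to preprocess (min 8x8)")
    flat = np.empty_like(h)
    for i in range(h.shape[0]):
        flat[i] = h[i] - _background_polyfit_row(h[i], order=1)
    flat = flat - _fit_global_quadratic(flat)
    for i in _detect_scar_rows(flat, nsigma=scar_nsigma, min_run=scar_min_run):
        flat[i] = 0.5 * (flat[i - 1] + flat[i + 1])
    background = flat[flat <= np.quantile(flat, 0.75)]
    flat = flat - np.median(background)
    return AFMImage(flat, image.pixel_nm, provenance=image.provenance + "|preprocessed")


# ---------------------------------------------------------------------------
# Segmentation and tracing
# ---------------------------------------------------------------------------

_STEP_WEIGHTS = {(0, 1): 1.0, (0, -1): 1.0, (1, 0): 1.0, (-1, 0): 1.0,
                 (1, 1): math.sqrt(2), (1, -1): math.sqrt(2),
                 (-1, 1): math.sqrt(2), (-1, -1): math.sqrt(2)}


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton; edge weights in pixels."""
    g = nx.Graph()
    pix = np.argwhere(skel)
    pixset = {tuple(p) for p in pix}
    for p in map(tuple, pix):
        g.add_node(p)
        for (dr, dc), w in _STEP_WEIGHTS.items():
            q = (p[0] + dr, p[1] + dc)
            if q in pixset:
                g.add_edge(p, q, weight=w)
    return g


def _longest_endpoint_path(g: nx.Graph) -> Optional[list[tuple[int, int]]]:
    """Longest (by path length in px) shortest path between skeleton endpoints.

    Skeleton branches are pruned by keeping only the single longest
    end-to-end route through the pixel graph. Returns None for closed
    loops (no endpoints).
    """
    endpoints = sorted(n for n in g.nodes if g.degree(n) == 1)
    if not endpoints:
        return None
    best_len, best_path = -1.0, None
    for i, src in enumerate(endpoints):
        lengths, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in endpoints[i + 1:]:
            if dst in lengths and lengths[dst] > best_len:
                best_len, best_path = lengths[dst], paths[dst]
    return best_path


def _subpixel_centroid(h: np.ndarray, r: int, c: int, win: int = 2) -> np.ndarray:
    """Height-squared-weighted centroid of a window; displacement <= 1 px.

    The tip PSF leaves ridges and blobs with smooth profiles whose local
    centroid locates the underlying feature well below the pixel size.
    """
    r0, r1 = max(0, r - win), min(h.shape[0], r + win + 1)
    c0, c1 = max(0, c - win), min(h.shape[1], c + win + 1)
    w = np.clip(h[r0:r1, c0:c1], 0.0, None) ** 2
    if w.sum() <= 0:
        return np.array([float(r), float(c)])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = np.clip((w * rr).sum() / w.sum() - r, -1.0, 1.0)
    dc = np.clip((w * cc).sum() / w.sum() - c, -1.0, 1.0)
    return np.array([r + dr, c + dc])


def _extend_path_ends(path: list[tuple[int, int]], mask: np.ndarray,
                      max_steps: int = 3) -> list[tuple[int, int]]:
    """Grow the path ends along their local direction while inside the mask.

    Thinning erodes roughly half a ridge width from each molecule end;
    walking outward through the remaining foreground recovers it.
    """
    path = list(path)
    for _ in range(2):
        path.reverse()
        for _ in range(max_steps):
            tail = np.asarray(path[-1])
            back = np.asarray(path[-min(3, len(path))])
            d = tail - back
            step = np.sign(d).astype(int)
            if not step.any():
                break
            nxt = (int(tail[0] + step[0]), int(tail[1] + step[1]))
            if (not (0 <= nxt[0] < mask.shape[0] and 0 <= nxt[1] < mask.shape[1])
                    or not mask[nxt] or nxt in path[-3:]):
                break
            path.append(nxt)
    return path


def segment_and_trace(image: AFMImage,
                      height_threshold: Optional[float] = None,
                      min_pixels: int = 6,
                      closing_iterations: int = 1) -> list[MoleculeTrace]:
    """Segment molecules above a height threshold and trace their contours.

    The threshold defaults to Otsu's value on the preprocessed height
    histogram, floored at 3 robust noise sigmas above the background
    median (Otsu alone underestimates badly on sparse fields whose
    histogram is dominated by substrate noise). One binary closing pass
    repairs single-pixel dropouts in thin ridges. Each connected component
    is skeletonised; branches are pruned to the longest
    endpoint-to-endpoint path; closed loops are skipped with a log entry.
    Path points are ordered from the endpoint with the smaller (row, col)
    and carry the local image height. The full skeleton graph, sub-pixel
    node positions and the component's apex (highest feature) are attached
    for the angle stage.
    """
    h = image.heights
    if height_threshold is None:
        floor = float(np.median(h) + 3.0 * _robust_sigma(h))
        height_threshold = max(float(filters.threshold_otsu(h)), floor)
    fg = h > height_threshold
    if closing_iterations:
        # drop isolated noise specks before closing can inflate them
        fg = morphology.remove_small_objects(fg, max_size=2, connectivity=2)
        fg = ndimage.binary_closing(fg, structure=np.ones((3, 3)),
                                    iterations=closing_iterations)
    labels = measure.label(fg, connectivity=2)
    traces: list[MoleculeTrace] = []
    for region in measure.regionprops(labels):
        if region.num_pixels < min_pixels:
            continue
        mask = labels == region.label
        skel = morphology.skeletonize(mask)
        if skel.sum() < 2:
            continue
        g = _skeleton_graph(skel)
        n_endpoints = sum(1 for n in g.nodes if g.degree(n) == 1)
        path = _longest_endpoint_path(g)
        if path is None:
            logger.info("component %d is a closed loop; skipped", region.label)
            continue
        if len(path) < 2:
            continue
        path = _extend_path_ends(path, mask)
        if path[0] > path[-1]:
            path = path[::-1]
        pixels = np.array(path)
        # points in nm as (x, y) = (col, row) * pixel size
        points = pixels[:, ::-1].astype(float) * image.pixel_nm
        heights = h[pixels[:, 0], pixels[:, 1]]
        for node in g.nodes:
            g.nodes[node]["pos_nm"] = (
                _subpixel_centroid(h, *node)[::-1] * image.pixel_nm)
        rr, cc = np.nonzero(mask)
        k = int(np.argmax(h[rr, cc]))
        apex_px = (int(rr[k]), int(cc[k]))
        apex_nm = _subpixel_centroid(h, *apex_px)[::-1] * image.pixel_nm
        traces.append(MoleculeTrace(points=points, heights=heights,
                                    mask_id=int(region.label),
                                    pixel_nm=image.pixel_nm,
                                    pixels=pixels, n_endpoints=n_endpoints,
                                    graph=g, apex_nm=apex_nm, apex_px=apex_px))
    return traces


def filter_by_contour_length(traces: Sequence[MoleculeTrace],
                             expected_nm: float
                             ) -> tuple[list[MoleculeTrace], list[MoleculeTrace]]:
    """Keep traces whose contour length is within 50% of the expected value.

    The bounds [0.5*expected, 1.5*expected] are inclusive. Objects outside
    the window (debris, aggregates, spot-like deposits) are returned in the
    discarded list so the discard fraction can be reported.
    """
    if expected_nm <= 0:
        raise ValueError("expected_nm must be positive")
    kept, discarded = [], []
    for t in traces:
        L = contour_length(t.points)
        (kept if 0.5 * expected_nm <= L <= 1.5 * expected_nm else discarded).append(t)
    return kept, discarded


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def contour_length(points: np.ndarray) -> float:
    """Summed segment length along an ordered polyline."""
    points = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def radius_of_gyration(points: np.ndarray) -> float:
    """RMS distance of polyline points from their centroid."""
    points = np.asarray(points, dtype=float)
    centred = points - points.mean(axis=0)
    return float(np.sqrt((centred**2).sum(axis=1).mean()))


def trace_metrics(trace: MoleculeTrace, n_bp: Optional[int] = None) -> TraceMetrics:
    """Contour length, end-to-end distance and radius of gyration of a trace.

    With a known base-pair count the calibration nm/bp is also reported.
    """
    pts = trace.points
    L = contour_length(pts)
    e2e = float(np.linalg.norm(pts[-1] - pts[0]))
    rg = radius_of_gyration(pts)
    return TraceMetrics(
        contour_length_nm=L,
        end_to_end_nm=e2e,
        radius_of_gyration_nm=rg,
        nm_per_bp=(L / n_bp) if n_bp else None,
    )


def _angle_between_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _measure_bend_angle_path(trace: MoleculeTrace, window_px: int,
                             arm_px: int) -> tuple[float, int]:
    """Pure path-index heuristic on the ordered trace points."""
    half = (window_px - 1) // 2
    i = int(np.argmax(trace.heights))
    lo = i - half - arm_px
    hi = i + half + arm_px
    if lo < 0 or hi > len(trace) - 1:
        raise ValueError(
            f"peak at index {i} too close to a trace end for arms of {arm_px} px"
        )
    p = trace.points
    v_left = p[i - half] - p[i - half - arm_px]
    v_right = p[i + half + arm_px] - p[i + half]
    # 0 deg = straight: arms pointing the same way along the contour
    theta = _angle_between_deg(v_left, v_right)
    return theta, i


def _measure_bend_angle_graph(trace: MoleculeTrace, window_px: int,
                              arm_px: int) -> tuple[float, int]:
    """Vertex-anchored variant using the full skeleton graph.

    Sharply bent molecules fold back on themselves: near the apex the two
    DNA arms merge into one thick region whose skeleton runs along the
    bisector, so path points adjacent to the peak no longer lie on either
    arm. Anchoring both arm chords at the sub-pixel apex (the bound
    protein, which sits exactly on the kink vertex) and taking the chord
    endpoints past the node where the two arm branches diverge makes the
    measurement exact for straight arms at any fold angle, and reduces to
    the plain path heuristic for open molecules.
    """
    g = trace.graph
    half = (window_px - 1) // 2
    steps = half + arm_px
    apex_node = min(g.nodes,
                    key=lambda n: (n[0] - trace.apex_px[0]) ** 2
                    + (n[1] - trace.apex_px[1]) ** 2)
    dist, paths = nx.single_source_dijkstra(g, apex_node, weight="weight")
    endpoints = sorted(n for n in g.nodes
                       if g.degree(n) == 1 and n != apex_node and n in dist)
    if len(endpoints) < 2:
        raise ValueError("apex too close to a molecule end; angle undefined")
    end_a = max(endpoints, key=lambda n: dist[n])
    path_a = paths[end_a]

    def fork_index(path_b):
        k = 0
        while k < min(len(path_a), len(path_b)) and path_a[k] == path_b[k]:
            k += 1
        return k - 1

    best_b, best_past = None, -1.0
    for n in endpoints:
        if n == end_a:
            continue
        fi = fork_index(paths[n])
        past = dist[n] - dist[paths[n][fi]]
        if past > best_past:
            best_past, best_b = past, n
    if best_b is None or best_past < 2.0:
        raise ValueError("no second arm found from the apex; angle undefined")
    path_b = paths[best_b]
    fi = fork_index(path_b)

    def chord(path, fork_i):
        j = min(fork_i + steps, len(path) - 1)
        if j <= 0:
            raise ValueError("arm too short to measure")
        return g.nodes[path[j]]["pos_nm"] - trace.apex_nm

    v_a = chord(path_a, fi)
    v_b = chord(path_b, fi)
    # chords both point away from the vertex: straight DNA -> 180 deg apart
    theta = 180.0 - _angle_between_deg(v_a, v_b)
    d2 = ((trace.pixels - np.asarray(apex_node)) ** 2).sum(axis=1)
    return theta, int(np.argmin(d2))


def measure_bend_angle(trace: MoleculeTrace, window_px: int = 3,
                       arm_px: int = 4) -> tuple[float, int]:
    """One bend angle per molecule, measured around the highest contour point.

    The peak i identifies the bound protein when present (ties: smallest
    index). A window of ``window_px`` points centred on i ({i-1, i, i+1}
    for the default 3) is excluded and arm vectors span the next
    ``arm_px`` path points either side:
    v_left = p[i-1] - p[i-1-arm], v_right = p[i+1+arm] - p[i+1];
    the returned angle between the arm vectors is 0 deg for straight DNA.

    Traces carrying their skeleton graph (image-derived traces) use the
    vertex-anchored variant of the same 4-px-arm heuristic, which stays
    accurate when sharply folded arms merge near the apex; hand-built
    polyline traces use the pure path-index formula.

    Raises ``ValueError`` when the peak sits too close to a contour end
    for both arms to fit; such molecules are excluded from angle
    statistics.
    """
    if trace.graph is not None and trace.apex_nm is not None:
        return _measure_bend_angle_graph(trace, window_px, arm_px)
    return _measure_bend_angle_path(trace, window_px, arm_px)


# ---------------------------------------------------------------------------
# Cluster volumes
# ---------------------------------------------------------------------------

def cluster_volumes(image: AFMImage, masks: np.ndarray,
                    min_pixels: int = 6) -> list[ClusterVolume]:
    """Zero-basis volume of each labelled cluster.

    ``masks`` is an integer label image (0 = background). The zero basis
    is the post-flattening zero plane: negative heights do not subtract
    (clipped to 0). Clusters smaller than ``min_pixels`` are dropped.
    """
    h = np.maximum(image.heights, 0.0)
    area = image.pixel_nm**2
    out = []
    for lab in np.unique(masks):
        if lab == 0:
            continue
        sel = masks == lab
        npx = int(sel.sum())
        if npx < min_pixels:
            continue
        out.append(ClusterVolume(mask_id=int(lab), pixel_count=npx,
                                 volume_nm3=float(h[sel].sum() * area)))
    return out
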