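"""Detection and measurement of filopodia-like processes and arborization.

The segmentation strategy: smooth + threshold the image, then separate the
cell body (soma / dendrites / broad structures) from thin appendages with a
morphological opening whose radius equals half the process-width ceiling.
Everything the opening removes and that touches the body is a candidate
process; each is skeletonized and measured.  Processes are identified by
their *attachment* (the interface where they meet the body), so two
protrusions whose tips merge still count as two.

The branching-area index reproduces a high-pass + median filtering pipeline:
the image minus a wide Gaussian blur, a 3x3 median, a threshold, and the
percentage of the non-soma field above threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, skeletonize

from .types import BranchingIndex, CalibratedImage, Filopodium, LengthHistogram

#: processes wider than this are lamellipodia-like, not filopodia-like
WIDTH_MAX_UM = 1.0
#: minimum protrusion length; suppresses skeletonization spurs
MIN_LENGTH_UM = 0.5

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _segment_mask(img: CalibratedImage, smooth_sigma_um: float = 0.15) -> np.ndarray:
    """Foreground mask by smoothing + two-pass thresholding (as in edge
    detection, but with a narrow kernel so thin processes survive)."""
    if not np.any(img.pixels > 0):
        raise ValueError("empty image: nothing to segment")
    smoothed = ndimage.gaussian_filter(img.pixels, smooth_sigma_um / img.pixel_size_um)
    thr = threshold_otsu(smoothed)
    above = smoothed > thr
    if not above.any() or above.all():
        raise ValueError("thresholding failed to separate signal from background")
    thr = 0.5 * (np.median(smoothed[above]) + np.median(smoothed[~above]))
    return smoothed > thr


def _skeleton_tree(skel_pts) -> tuple[dict, dict]:
    """8-connected adjacency of a set of skeleton pixels."""
    skel_set = set(skel_pts)
    adj = {p: [] for p in skel_set}
    for p in skel_set:
        for dr, dc in _NEIGHBORS:
            q = (p[0] + dr, p[1] + dc)
            if q in skel_set:
                adj[p].append(q)
    return adj, skel_set


def _geodesics_from(root, adj):
    """Euclidean-weighted shortest distances and parents from ``root`` over
    a skeleton adjacency (Dijkstra on a near-tree graph)."""
    import heapq

    dist = {root: 0.0}
    parent = {root: None}
    heap = [(0.0, root)]
    while heap:
        d, p = heapq.heappop(heap)
        if d > dist.get(p, np.inf):
            continue
        for q in adj[p]:
            nd = d + np.hypot(q[0] - p[0], q[1] - p[1])
            if nd < dist.get(q, np.inf):
                dist[q] = nd
                parent[q] = p
                heapq.heappush(heap, (nd, q))
    return dist, parent


def _cluster_points(points, px: float, link_um: float = 0.3):
    """Greedy single-linkage clustering of a few pixel coordinates."""
    labels = [-1] * len(points)
    nlab = 0
    for i, p in enumerate(points):
        if labels[i] >= 0:
            continue
        labels[i] = nlab
        stack = [i]
        while stack:
            j = stack.pop()
            for k, q in enumerate(points):
                if labels[k] < 0 and np.hypot(points[j][0] - q[0], points[j][1] - q[1]) * px <= link_um:
                    labels[k] = nlab
                    stack.append(k)
        nlab += 1
    return labels, nlab


def _chord_length_px(path, chord: int = 4) -> float:
    """Polyline length through every ``chord``-th skeleton point; resampling
    removes the staircase overestimate of raw 8-connected chains."""
    if len(path) < 2:
        return 0.0
    pts = np.asarray(path, dtype=float)
    idx = list(range(0, len(pts), chord))
    if idx[-1] != len(pts) - 1:
        idx.append(len(pts) - 1)
    sub = pts[idx]
    return float(np.sum(np.hypot(*np.diff(sub, axis=0).T)))


def segment_processes(img: CalibratedImage, smooth_sigma_um: float = 0.15,
                      width_max_um: float = WIDTH_MAX_UM,
                      min_length_um: float = MIN_LENGTH_UM):
    """Segment an image into body and thin processes.

    Returns ``(body_mask, processes, skeleton)`` where ``processes`` is a
    list of :class:`Filopodium` and ``skeleton`` the skeleton of the full
    foreground mask.  The body is the morphological opening of the mask
    with a disk of radius ``width_max_um / 2``.

    Processes are extracted on the skeleton of the full mask: skeleton
    pixels whose local width (twice the in-mask distance transform) is at
    least ``width_max_um`` form the thick backbone (soma, dendrites, broad
    lamellipodia-like structures); the remaining thin skeleton pixels form
    branches.  Every thin-branch endpoint at a geodesic distance of at
    least ``min_length_um`` beyond the parent's edge is one process,
    traced back to its anchor on the backbone.  Counting per endpoint
    keeps protrusions separate even when their bases fuse into locally
    thick blobs or their tips cross, which a component-per-process rule
    would merge.  The process length is the geodesic anchor-to-tip arc
    minus the parent's local half width, i.e. length is measured from the
    parent's edge.
    """
    px = img.pixel_size_um
    mask = _segment_mask(img, smooth_sigma_um)
    open_radius = max(1, int(round(width_max_um / 2.0 / px)))
    body = ndimage.binary_opening(mask, structure=disk(open_radius))
    if not body.any():
        raise ValueError("no body structure found after opening")
    skeleton = skeletonize(mask)
    edt_in_mask = ndimage.distance_transform_edt(mask) * px

    skel_pts = [tuple(p) for p in np.argwhere(skeleton)]
    adj, _ = _skeleton_tree(skel_pts)
    half_ceiling = width_max_um / 2.0
    thin = {p for p in skel_pts if edt_in_mask[p] < half_ceiling}

    # anchors: backbone pixels adjacent to a thin branch
    anchors = [p for p in skel_pts if p not in thin and any(q in thin for q in adj[p])]
    if not anchors:
        return body, [], skeleton

    # multi-source Dijkstra from all anchors over the thin subgraph
    import heapq

    dist: dict = {}
    parent: dict = {}
    source: dict = {}
    heap = []
    for k, a in enumerate(anchors):
        dist[a] = 0.0
        parent[a] = None
        source[a] = k
        heap.append((0.0, a))
    heapq.heapify(heap)
    while heap:
        d, pnt = heapq.heappop(heap)
        if d > dist.get(pnt, np.inf):
            continue
        for q in adj[pnt]:
            if q not in thin:
                continue
            nd = d + np.hypot(q[0] - pnt[0], q[1] - pnt[1])
            if nd < dist.get(q, np.inf):
                dist[q] = nd
                parent[q] = pnt
                source[q] = source[pnt]
                heapq.heappush(heap, (nd, q))

    endpoints = [p for p in thin if len(adj[p]) <= 1 and p in dist]
    # bridges: a protrusion whose tip touches another branch has no free
    # endpoint of its own.  Where the geodesic front of such an "orphan"
    # anchor meets another front, emit one pseudo-tip at the deepest point
    # of the orphan's claimed region.
    endpoint_sources = {source[p] for p in endpoints}
    ridge_best: dict = {}
    for p in thin:
        if p not in dist:
            continue
        for q in adj[p]:
            if q in thin and q in dist and source[q] != source[p]:
                for x in (p, q):
                    if source[x] not in endpoint_sources:
                        key = source[x]
                        if key not in ridge_best or dist[x] > ridge_best[key][0]:
                            ridge_best[key] = (dist[x], x)
    endpoints.extend(tip for _, tip in ridge_best.values()
                     if tip not in endpoints)

    processes: list[Filopodium] = []
    for tip in endpoints:
        path = []
        node = tip
        while node is not None:
            path.append(node)
            node = parent.get(node)
        path.reverse()  # anchor -> tip
        anchor = path[0]
        # the parent's edge: where the branch leaves the opened body; the
        # skeleton tip sits ~half a cap radius short of the mask tip, so
        # add the local in-mask EDT at the tip back
        inside = [i for i, pnt in enumerate(path) if body[pnt]]
        att_idx = inside[-1] if inside else 0
        length = _chord_length_px(path[att_idx:]) * px + float(edt_in_mask[path[-1]])
        if length < min_length_um:
            continue  # skeletonization spur or cap taper
        thin_path = [p for p in path if p in thin]
        width = 2.0 * float(np.median([edt_in_mask[p] for p in (thin_path or path)]))
        if width >= width_max_um:
            continue
        attachment = path[att_idx]
        processes.append(Filopodium(
            path_px=np.asarray(path, dtype=float),
            length_um=length,
            attachment_px=(float(attachment[0]), float(attachment[1])),
            attachment_on_parent_px=(float(anchor[0]), float(anchor[1])),
            mean_width_um=width,
        ))
    return body, processes, skeleton


def measure_lengths(processes) -> list[float]:
    """Geodesic lengths (um) of detected processes."""
    return [p.length_um for p in processes]


def classify_lengths(lengths, bin_edges_um: tuple[float, float] = (4.0, 8.0)) -> LengthHistogram:
    """Bin process lengths into <4, [4, 8) and >=8 um groups.

    Bins are lower-edge inclusive (a length of exactly 4.0 falls in the
    middle group).  An empty input yields an all-zero histogram with a
    warning rather than an error.
    """
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("lengths must be >= 0")
    lo, hi = bin_edges_um
    if arr.size == 0:
        warnings.warn("no processes to classify; returning all-zero histogram")
        return LengthHistogram(bin_edges_um, np.zeros(3, dtype=int), np.zeros(3))
    counts = np.array([
        int(np.count_nonzero(arr < lo)),
        int(np.count_nonzero((arr >= lo) & (arr < hi))),
        int(np.count_nonzero(arr >= hi)),
    ])
    percentages = 100.0 * counts / counts.sum()
    return LengthHistogram(bin_edges_um, counts, percentages)


def _project_to_polyline(point, polyline):
    """(distance, arc position) of the closest approach of point to polyline."""
    p = np.asarray(point, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    best = (np.inf, 0.0)
    arc = 0.0
    for i in range(len(poly) - 1):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        L2 = float(ab @ ab)
        t = 0.0 if L2 == 0 else float(np.clip((p - a) @ ab / L2, 0.0, 1.0))
        proj = a + t * ab
        d = float(np.hypot(*(p - proj)))
        if d < best[0]:
            best = (d, arc + t * np.sqrt(L2))
        arc += np.sqrt(L2)
    return best


def count_filopodia_per_selection(dendrite_path_px, processes, pixel_size_um: float,
                                  tol_um: float = 0.5,
                                  expected_length_um: float = 20.0) -> int:
    """Count processes attached along a ~20 um dendrite selection.

    ``dendrite_path_px`` is a polyline on the dendrite centreline; a
    process counts when its parent-centreline attachment lies within
    ``tol_um`` of the path.  ``processes`` may be detected
    :class:`Filopodium` objects or generator-truth records (anything with
    an ``attachment_on_parent_px`` or ``attachment_centerline_px``).
    """
    poly = np.asarray(dendrite_path_px, dtype=float)
    length = float(np.sum(np.hypot(*np.diff(poly, axis=0).T))) * pixel_size_um
    if expected_length_um is not None and abs(length - expected_length_um) > 0.5:
        raise ValueError(
            f"selection length {length:.2f} um is not {expected_length_um} +- 0.5 um")
    total_arc = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
    count = 0
    for proc in processes:
        att = getattr(proc, "attachment_on_parent_px", None)
        if att is None:
            att = getattr(proc, "attachment_centerline_px")
        d, arc = _project_to_polyline(att, poly)
        # attachments clamped to the window ends lie beyond the selection
        if d * pixel_size_um <= tol_um and 0.0 < arc < total_arc:
            count += 1
    return count


def _point_at_arc(polyline: np.ndarray, cum_um: np.ndarray, s_um: float) -> np.ndarray:
    """Interpolated point at arc position ``s_um`` along a polyline whose
    cumulative vertex arc lengths (um) are ``cum_um``."""
    i = int(np.clip(np.searchsorted(cum_um, s_um) - 1, 0, len(polyline) - 2))
    span = cum_um[i + 1] - cum_um[i]
    frac = 0.0 if span == 0 else (s_um - cum_um[i]) / span
    return polyline[i] + frac * (polyline[i + 1] - polyline[i])


def sample_dendrite_selections(truth, n: int, seed: int,
                               length_um: float = 20.0):
    """Seeded 20 um windows along a synthetic neuron's dendrite centrelines.

    Returns a list of polylines (pixel coordinates).  Windows are drawn
    uniformly over dendrite arc length from paths long enough to hold one.
    """
    rng = np.random.default_rng(seed)
    px = truth.pixel_size_um
    eligible = []
    for path in truth.dendrite_paths_px:
        p = np.asarray(path, dtype=float)
        seg = np.hypot(*np.diff(p, axis=0).T) * px
        total = float(seg.sum())
        if total >= length_um:
            eligible.append((p, np.concatenate([[0.0], np.cumsum(seg)]), total))
    if not eligible:
        raise ValueError("no dendrite long enough for a selection")
    weights = np.array([max(t - length_um, 1e-9) for _, _, t in eligible])
    weights = weights / weights.sum()
    selections = []
    for _ in range(n):
        p, cum, total = eligible[rng.choice(len(eligible), p=weights)]
        start = rng.uniform(0.0, total - length_um)
        end = start + length_um
        sub = [_point_at_arc(p, cum, start)]
        inner = (cum > start) & (cum < end)
        sub.extend(p[inner])
        sub.append(_point_at_arc(p, cum, end))
        selections.append(np.asarray(sub))
    return selections


def branching_area_index(img: CalibratedImage, soma_mask: np.ndarray,
                         sigma_highpass_um: float = 2.0,
                         median_size: int = 3) -> BranchingIndex:
    """Percentage of the non-soma field occupied by thresholded branches.

    Pipeline: high-pass (image minus a Gaussian blur of ``sigma_highpass_um``),
    3x3 median filter, Otsu threshold, soma pixels removed from both
    numerator and denominator.
    """
    if soma_mask.all():
        raise ValueError("soma mask covers the whole image")
    px = img.pixel_size_um
    highpass = img.pixels - ndimage.gaussian_filter(img.pixels, sigma_highpass_um / px)
    filtered = ndimage.median_filter(highpass, size=median_size)
    if np.ptp(filtered) == 0:
        return BranchingIndex(0.0, 0, int((~soma_mask).sum()), True, float("nan"))
    thr = threshold_otsu(filtered)
    branches = (filtered > thr) & ~soma_mask
    total = int((~soma_mask).sum())
    value = 100.0 * branches.sum() / total
    return BranchingIndex(float(value), int(branches.sum()), total, True, float(thr))
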