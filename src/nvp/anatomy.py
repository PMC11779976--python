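"""Ex vivo vascular morphometry from post-mortem z-stacks.

Chain: candidate auto-thresholds (IsoData/"Default", Huang, Huang2, Li) with
a deterministic segmentation score replacing the blinded human choice ->
3D medial-axis skeleton with branch points and total centreline length ->
Euclidean-distance-map radius at each skeleton point -> length density
(mm vessel per mm^3, optionally filtered by diameter), pericyte density,
and capillary diameter as a function of along-skeleton distance from the
pericyte soma.

Huang's fuzzy-entropy threshold (and its shifted-membership variant,
"Huang2") is implemented here because no installed library provides it;
IsoData and Li come from scikit-image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra, \
    minimum_spanning_tree
from skimage.filters import threshold_isodata, threshold_li

from nvp.core import AnatomyStack, PericyteSet, SkeletonModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# thresholding


def _huang(img: np.ndarray, shift: bool = False) -> float:
    """Huang & Wang fuzzy-entropy threshold on a 256-bin histogram.

    With ``shift`` the membership midpoint is moved half a bin (the
    "Huang2" variant): small, deterministic change in how boundary grey
    levels are attributed to foreground vs background.
    """
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return lo
    hist, edges = np.histogram(img, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * centers)
    total, totalx = cw[-1], cwx[-1]
    c = hi - lo
    best_t, best_s = 0, np.inf
    for t in range(256):
        if cw[t] == 0 or cw[t] == total:
            continue
        mu0 = cwx[t] / cw[t]
        mu1 = (totalx - cwx[t]) / (total - cw[t])
        mu = np.where(np.arange(256) <= t, mu0, mu1)
        off = 0.5 * (edges[1] - edges[0]) if shift else 0.0
        member = 1.0 / (1.0 + np.abs(centers - mu + off) / c)
        member = np.clip(member, 1e-12, 1 - 1e-12)
        s = np.sum(w * (-member * np.log(member)
                        - (1 - member) * np.log(1 - member)))
        if s < best_s:
            best_s, best_t = s, t
    return float(centers[best_t])


THRESHOLD_METHODS = {
    "Default": lambda img: float(threshold_isodata(img)),
    "Huang": lambda img: _huang(img, shift=False),
    "Huang2": lambda img: _huang(img, shift=True),
    "Li": lambda img: float(threshold_li(img)),
}


def _segmentation_score(mask: np.ndarray) -> float:
    """Deterministic segmentation quality: foreground connectivity divided
    by boundary roughness.

    connectivity = fraction of foreground in the largest component;
    roughness = fraction of foreground voxels touching background
    (6-neighbourhood surface fraction).  Smooth, connected tubes score
    high; speckle scores low.
    """
    fg = int(mask.sum())
    if fg == 0:
        return -np.inf
    labels, n = ndimage.label(mask)
    largest = ndimage.sum(mask, labels, index=np.arange(1, n + 1)).max()
    connectivity = largest / fg
    eroded = ndimage.binary_erosion(mask)
    surface = fg - int(eroded.sum())
    roughness = max(surface / fg, 1e-6)
    return float(connectivity / roughness)


def threshold_stack(stack: AnatomyStack, smooth_sigma: float = 1.0,
                    methods: dict | None = None) -> tuple[np.ndarray, str]:
    """Binarize a stack, choosing among candidate auto-threshold methods.

    The stack is lightly Gaussian-denoised, each candidate threshold is
    computed and applied, and the mask with the best deterministic
    segmentation score is returned together with the chosen method name
    (logged).  The choice replaces a blinded per-image human judgement with
    a reproducible rule.

    Raises if every method yields an all-background mask.  Warns if the
    winning mask covers most of the volume (likely inverted contrast).
    """
    methods = methods or THRESHOLD_METHODS
    # denoise only for threshold *selection*; apply to the raw stack so the
    # blur does not dilate the segmented tubes
    img = ndimage.gaussian_filter(stack.data, smooth_sigma)
    best = None
    for name, fn in methods.items():
        try:
            t = fn(img)
        except Exception:  # degenerate histogram for this method
            continue
        mask = stack.data > t
        if not mask.any():
            continue
        score = _segmentation_score(mask)
        if best is None or score > best[0]:
            best = (score, name, mask)
    if best is None:
        raise ValueError("all candidate thresholds produced empty masks")
    score, name, mask = best
    if mask.mean() > 0.5:
        warnings.warn("foreground covers most of the volume; check image "
                      "polarity (vessels should be bright)", stacklevel=2)
    log.info("threshold_stack chose %s (score %.3g, %.1f%% foreground)",
             name, score, 100 * mask.mean())
    return mask, name


# ---------------------------------------------------------------------------
# skeleton & graph


def _skeleton_graph(coords: np.ndarray, voxel_size: tuple):
    """Sparse weighted adjacency between 26-neighbouring skeleton voxels;
    edge weights are anisotropic physical distances in um."""
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    vz = np.asarray(voxel_size)
    rows, cols, w = [], [], []
    offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
            for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    for i, c in enumerate(map(tuple, coords)):
        for off in offs:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None and j > i:
                d = float(np.linalg.norm(np.array(off) * vz))
                rows.append(i)
                cols.append(j)
                w.append(d)
    n = len(coords)
    return coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()


def _foreground_graph(mask: np.ndarray, voxel_size: tuple):
    """Vectorized 26-neighbour adjacency over all foreground voxels.

    Returns (coords (n,3), symmetric csr graph of physical distances)."""
    coords = np.argwhere(mask)
    idx_vol = np.full(mask.shape, -1, dtype=np.int64)
    idx_vol[tuple(coords.T)] = np.arange(len(coords))
    vz = np.asarray(voxel_size)
    rows, cols, w = [], [], []
    offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)]
    offs = [o for o in offs if o > (0, 0, 0)]  # half the offsets; symmetrize
    for off in offs:
        src = tuple(slice(max(-o, 0), mask.shape[k] - max(o, 0))
                    for k, o in enumerate(off))
        dst = tuple(slice(max(o, 0), mask.shape[k] + min(o, 0) or None)
                    for k, o in enumerate(off))
        a = idx_vol[src].ravel()
        b = idx_vol[dst].ravel()
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        d = float(np.linalg.norm(np.asarray(off) * vz))
        rows.append(a[ok])
        cols.append(b[ok])
        w.append(np.full(int(ok.sum()), d))
    n = len(coords)
    g = coo_matrix((np.concatenate(w), (np.concatenate(rows),
                                        np.concatenate(cols))),
                   shape=(n, n)).tocsr()
    return coords, g + g.T


def _trace_centerlines(mask: np.ndarray, voxel_size: tuple,
                       penalty_strength: float = 50.0,
                       penalty_power: float = 4.0) -> np.ndarray:
    """Centreline voxels of a tube network by distance-field-guided
    geodesic path peeling.

    Per connected component: edge weights through the foreground graph are
    inflated near the vessel wall (by the Euclidean distance field), so
    shortest paths hug the tube centre.  Starting from the geodesically
    farthest voxel pair, paths are traced to the farthest not-yet-covered
    voxel; each traced path voxel covers a ball of its local vessel radius;
    tracing repeats until the whole component is covered.  Robust on
    anisotropic, noisy-edged tubes.
    """
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    coords, graph = _foreground_graph(mask, voxel_size)
    n = len(coords)
    edt_fg = edt[tuple(coords.T)]
    edt_max = max(edt_fg.max(), 1e-9)
    # per-node wall penalty -> per-edge multiplier (mean of endpoints)
    node_pen = penalty_strength * (1.0 - edt_fg / edt_max) ** penalty_power
    g = graph.tocoo()
    pen_w = g.data * (1.0 + 0.5 * (node_pen[g.row] + node_pen[g.col]))
    pen_graph = coo_matrix((pen_w, (g.row, g.col)), shape=(n, n)).tocsr()

    n_comp, labels = connected_components(graph, directed=False)
    vz = np.asarray(voxel_size)
    is_skel = np.zeros(n, dtype=bool)
    covered = np.zeros(n, dtype=bool)
    idx_vol = np.full(mask.shape, -1, dtype=np.int64)
    idx_vol[tuple(coords.T)] = np.arange(n)

    def cover_path(path_nodes):
        for p in path_nodes:
            r = max(float(edt_fg[p]) * 1.5, 1.5 * float(vz.max()))
            c = coords[p]
            half = np.ceil(r / vz).astype(int)
            lo = np.maximum(c - half, 0)
            hi = np.minimum(c + half + 1, mask.shape)
            box = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            d2 = sum(((box[k] - c[k]) * vz[k]) ** 2 for k in range(3))
            inside = d2 <= r * r
            ids = idx_vol[box[0][inside], box[1][inside], box[2][inside]]
            covered[ids[ids >= 0]] = True

    for comp in range(n_comp):
        members = np.where(labels == comp)[0]
        if len(members) == 1:
            is_skel[members] = True
            covered[members] = True
            continue
        # two-pass farthest point: root = one geodesic extremity
        d0 = dijkstra(pen_graph, directed=False, indices=members[0])
        d0[~np.isfinite(d0)] = -1
        root = int(np.argmax(np.where(labels == comp, d0, -1)))
        dist, pred = dijkstra(pen_graph, directed=False, indices=root,
                              return_predecessors=True)
        comp_mask = labels == comp
        for _ in range(len(members)):  # safety bound
            cand = comp_mask & ~covered & np.isfinite(dist)
            if not cand.any():
                break
            target = int(np.argmax(np.where(cand, dist, -np.inf)))
            path = []
            node = target
            while node >= 0 and not (is_skel[node] and path):
                path.append(node)
                if is_skel[node]:
                    break
                node = pred[node]
            is_skel[path] = True
            cover_path(path)
    return coords[is_skel]


def skeleton_3d(mask: np.ndarray, voxel_size: tuple) -> SkeletonModel:
    """Centreline skeleton of a binary vessel mask.

    Centrelines are traced with a distance-field-guided geodesic path
    peeler (:func:`_trace_centerlines`), which follows the ridge of the
    Euclidean distance field through each tube.  Total centreline length
    (um) is the sum of edge lengths of the minimum spanning tree over
    26-adjacent skeleton voxels with anisotropic voxel scaling (the MST
    avoids double-counting staircase diagonals).  Branch points are
    skeleton voxels with >= 3 skeleton neighbours.
    """
    if not np.any(mask):
        raise ValueError("empty mask; nothing to skeletonize")
    coords = _trace_centerlines(mask, voxel_size)
    if len(coords) == 0:
        raise ValueError("skeletonization produced no points")
    graph = _skeleton_graph(coords, voxel_size)
    sym = graph + graph.T
    degree = np.asarray((sym > 0).sum(axis=1)).ravel()
    branch = np.where(degree >= 3)[0]
    mst = minimum_spanning_tree(sym)
    raw_len = float(mst.sum())
    # voxel paths overestimate oblique centrelines (staircase effect);
    # measure length on lightly smoothed branch polylines instead
    smooth_len = _smoothed_tree_length(mst, coords, voxel_size)
    total_len = smooth_len if smooth_len > 0 else raw_len
    model = SkeletonModel(points=coords.astype(float),
                          branch_points=branch,
                          total_length_um=total_len)
    model.graph = sym  # adjacency reused by path-distance profiles
    share = _per_point_length(mst, len(coords))
    if raw_len > 0:
        share = share * (total_len / raw_len)
    model.per_point_length = share
    return model


def _smoothed_tree_length(mst, coords: np.ndarray, voxel_size: tuple,
                          window: int = 5) -> float:
    """Total length of the skeleton tree measured on branch polylines
    smoothed with a short moving average (endpoints kept fixed)."""
    vz = np.asarray(voxel_size)
    pts_um = coords * vz
    m = (mst + mst.T).tocsr()
    n = m.shape[0]
    indptr, indices = m.indptr, m.indices
    deg = np.diff(indptr)
    anchors = set(np.where(deg != 2)[0])
    if not anchors:  # single closed loop or single path of deg-2 nodes
        anchors = {0}
    visited_edges = set()
    total = 0.0
    for a in anchors:
        for b in indices[indptr[a]:indptr[a + 1]]:
            if (a, b) in visited_edges:
                continue
            path = [a, b]
            visited_edges.add((a, b))
            visited_edges.add((b, a))
            prev, node = a, b
            while node not in anchors:
                nbrs = [x for x in indices[indptr[node]:indptr[node + 1]]
                        if x != prev]
                if not nbrs:
                    break
                prev, node = node, nbrs[0]
                visited_edges.add((prev, node))
                visited_edges.add((node, prev))
                path.append(node)
            total += _polyline_length(pts_um[path], window)
    return total


def _polyline_length(pts: np.ndarray, window: int) -> float:
    if len(pts) < 2:
        return 0.0
    if len(pts) > window >= 3:
        kernel = np.ones(window) / window
        sm = np.empty_like(pts)
        for k in range(pts.shape[1]):
            padded = np.pad(pts[:, k], window // 2, mode="edge")
            sm[:, k] = np.convolve(padded, kernel, mode="valid")
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def _per_point_length(mst, n: int) -> np.ndarray:
    """Length share per skeleton point: half of each incident MST edge."""
    share = np.zeros(n)
    m = mst.tocoo()
    for i, j, d in zip(m.row, m.col, m.data):
        share[i] += d / 2.0
        share[j] += d / 2.0
    return share


def branch_point_clusters(skeleton: SkeletonModel) -> int:
    """Number of spatially contiguous branch-point clusters (adjacent
    branch voxels at a junction count once)."""
    if len(skeleton.branch_points) == 0:
        return 0
    pts = skeleton.points[skeleton.branch_points].astype(int)
    vol_shape = pts.max(axis=0) + 2
    vol = np.zeros(vol_shape, dtype=bool)
    vol[tuple(pts.T)] = True
    _, n = ndimage.label(vol, structure=np.ones((3, 3, 3)))
    return int(n)


# ---------------------------------------------------------------------------
# radii, densities, profiles


def radii_from_distance_map(mask: np.ndarray, skeleton: SkeletonModel,
                            voxel_size: tuple) -> np.ndarray:
    """Radius (um) at each skeleton point from the anisotropy-aware
    Euclidean distance transform of the mask.  Points outside the mask are
    flagged NaN."""
    dt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    pts = skeleton.points.astype(int)
    r = dt[tuple(pts.T)]
    r = np.where(r > 0, r, np.nan)
    if np.any(~np.isfinite(r)):
        log.warning("%d skeleton points fall outside the mask",
                    int(np.sum(~np.isfinite(r))))
    return r


def vessel_density(skeleton: SkeletonModel, volume_mm3: float,
                   radii_um: np.ndarray | None = None,
                   max_diameter_um: float | None = None) -> float:
    """Vessel length density in mm per mm^3.

    With a diameter filter, only skeleton length belonging to points whose
    diameter (2 x distance-map radius) is below ``max_diameter_um`` counts
    (the capillary-density readout uses < 7 um).
    """
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    if max_diameter_um is None:
        length_um = skeleton.total_length_um
    else:
        if radii_um is None:
            raise ValueError("diameter filter requires per-point radii")
        keep = np.isfinite(radii_um) & (2.0 * radii_um < max_diameter_um)
        length_um = float(skeleton.per_point_length[keep].sum())
    return (length_um / 1000.0) / volume_mm3


@dataclass
class PericyteDensity:
    per_mm_vessel: float
    per_mm3: float
    n_counted: int
    n_excluded: int


def snap_somata(somata: PericyteSet, skeleton: SkeletonModel,
                voxel_size: tuple, capture_radius_um: float = 5.0) -> PericyteSet:
    """Assign each soma to its nearest skeleton point; somata farther than
    ``capture_radius_um`` from any skeleton point are excluded (index -1)."""
    pts_um = skeleton.points * np.asarray(voxel_size)
    nearest = np.full(len(somata), -1, dtype=int)
    for i, pos in enumerate(somata.positions_um):
        d = np.linalg.norm(pts_um - pos, axis=1)
        j = int(np.argmin(d))
        if d[j] <= capture_radius_um:
            nearest[i] = j
        else:
            log.warning("soma %d is %.1f um from the skeleton; excluded",
                        i, d[j])
    return PericyteSet(positions_um=somata.positions_um,
                       nearest_skeleton_index=nearest)


def pericyte_density(somata: PericyteSet, skeleton: SkeletonModel,
                     volume_mm3: float, voxel_size: tuple,
                     capture_radius_um: float = 5.0) -> PericyteDensity:
    """Pericyte counts normalized both per mm of vessel and per mm^3."""
    snapped = somata if somata.nearest_skeleton_index is not None else \
        snap_somata(somata, skeleton, voxel_size, capture_radius_um)
    counted = int(np.sum(snapped.nearest_skeleton_index >= 0))
    excluded = len(snapped) - counted
    length_mm = skeleton.total_length_um / 1000.0
    if length_mm <= 0 or volume_mm3 <= 0:
        raise ValueError("need positive vessel length and volume")
    return PericyteDensity(per_mm_vessel=counted / length_mm,
                           per_mm3=counted / volume_mm3,
                           n_counted=counted, n_excluded=excluded)


def diameter_vs_soma_distance(skeleton: SkeletonModel, radii_um: np.ndarray,
                              somata: PericyteSet, voxel_size: tuple,
                              bin_width_um: float = 2.0,
                              max_dist_um: float = 50.0,
                              capture_radius_um: float = 5.0) -> pd.DataFrame:
    """Mean vessel diameter as a function of along-skeleton path distance
    from the nearest pericyte soma.

    Each skeleton point within ``max_dist_um`` (path distance through the
    skeleton graph) of a soma contributes its diameter (2 x radius) to the
    distance bin it falls in; points are assigned to their nearest soma by
    path distance.  Bin 0 contains the soma itself; distances are unsigned
    (capillary profiles are reported symmetrically around the soma).

    Returns a tidy frame: bin_lo_um, bin_center_um, mean_diameter_um, n.
    """
    snapped = somata if somata.nearest_skeleton_index is not None else \
        snap_somata(somata, skeleton, voxel_size, capture_radius_um)
    sources = snapped.nearest_skeleton_index
    sources = sources[sources >= 0]
    if len(sources) == 0:
        raise ValueError("no soma lies within the capture radius of the "
                         "skeleton; profile empty")
    graph = getattr(skeleton, "graph", None)
    if graph is None:
        graph = _skeleton_graph(skeleton.points.astype(int), voxel_size)
        graph = graph + graph.T
    dist = dijkstra(graph, directed=False, indices=sources, limit=max_dist_um)
    # nearest soma per skeleton point (by path distance)
    mind = dist.min(axis=0)
    ok = np.isfinite(mind) & np.isfinite(radii_um)
    edges = np.arange(0.0, max_dist_um + bin_width_um, bin_width_um)
    which = np.digitize(mind[ok], edges) - 1
    dia = 2.0 * radii_um[ok]
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append({
            "bin_lo_um": edges[b],
            "bin_center_um": edges[b] + bin_width_um / 2.0,
            "mean_diameter_um": float(dia[sel].mean()) if sel.any() else np.nan,
            "n": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def soma_assignment(skeleton: SkeletonModel, somata: PericyteSet,
                    voxel_size: tuple, max_dist_um: float = 50.0) -> np.ndarray:
    """Index of the path-nearest soma per skeleton point (-1 beyond
    max_dist)."""
    sources = somata.nearest_skeleton_index
    valid = np.where(sources >= 0)[0]
    graph = getattr(skeleton, "graph", None)
    if graph is None:
        graph = _skeleton_graph(skeleton.points.astype(int), voxel_size)
        graph = graph + graph.T
    dist = dijkstra(graph, directed=False, indices=sources[valid],
                    limit=max_dist_um)
    out = np.full(len(skeleton.points), -1, dtype=int)
    finite_any = np.isfinite(dist).any(axis=0)
    arg = np.argmin(np.where(np.isfinite(dist), dist, np.inf), axis=0)
    out[finite_any] = valid[arg[finite_any]]
    return out
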