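"""In vivo image quantification.

Two measurement chains:

* diametry — skeletonize the mean image of a vessel movie, then for every
  frame sample intensity profiles perpendicular to the centreline at each
  skeleton point and take the average full width at half maximum (FWHM);
* velocimetry — estimate red-blood-cell velocity from the slope of streaks
  in a line-scan kymograph via the radon transform (the angle maximizing
  the variance of the projections).

Movies are assumed motion-registered; :func:`register_movie` provides an
optional integer-shift cross-correlation aligner for lightly drifting data.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.transform import radon

from nvp.core import DiameterTrace, Kymograph, SkeletonModel, VelocityTrace, VesselMovie

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# skeleton


def skeletonize_2d(mean_image: np.ndarray, pixel_size: float,
                   tangent_window: int = 5) -> SkeletonModel:
    """Extract the centreline of the dominant bright vessel in an image.

    Otsu-thresholds the image, keeps the largest connected foreground
    component, thins it to a one-pixel skeleton, orders the skeleton points
    along the path, and fits per-point unit tangents by local principal
    direction over a ``tangent_window``-point neighbourhood.
    """
    img = np.asarray(mean_image, dtype=float)
    thresh = threshold_otsu(img)
    mask = img > thresh
    if not mask.any():
        raise ValueError(
            f"no foreground above Otsu threshold {thresh:.3g}; "
            "cannot skeletonize")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        log.warning("found %d foreground components; keeping largest "
                    "(%d of %d px)", n, int(sizes.max()), int(sizes.sum()))
        mask = labels == keep
    skel = skeletonize(mask)
    pts = np.argwhere(skel)  # (y, x)
    if len(pts) == 0:
        raise ValueError("skeletonization produced no points")
    pts = _order_path(pts)
    tangents = _local_tangents(pts, tangent_window)
    return SkeletonModel(points=pts.astype(float), tangents=tangents)


def _order_path(pts: np.ndarray) -> np.ndarray:
    """Order skeleton pixels along the path by nearest-neighbour walking
    from an endpoint (point with only one neighbour within sqrt(2))."""
    pset = {tuple(p) for p in pts}
    neigh = {}
    for p in map(tuple, pts):
        nb = []
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy or dx) and (p[0] + dy, p[1] + dx) in pset:
                    nb.append((p[0] + dy, p[1] + dx))
        neigh[p] = nb
    ends = [p for p, nb in neigh.items() if len(nb) == 1]
    start = ends[0] if ends else tuple(pts[0])
    ordered, seen = [start], {start}
    while True:
        nxt = [q for q in neigh[ordered[-1]] if q not in seen]
        if not nxt:
            break
        ordered.append(nxt[0])
        seen.add(nxt[0])
    # fall back: append any stragglers (loops / side branches) unordered
    for p in map(tuple, pts):
        if p not in seen:
            ordered.append(p)
    return np.array(ordered)


def _local_tangents(pts: np.ndarray, window: int) -> np.ndarray:
    """Per-point unit tangent from the principal direction of a local
    window of ordered skeleton points."""
    n = len(pts)
    half = max(window // 2, 1)
    tangents = np.zeros((n, 2))
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = pts[lo:hi].astype(float)
        if len(seg) < 2:
            tangents[i] = (0.0, 1.0)
            continue
        seg = seg - seg.mean(axis=0)
        _, _, vt = np.linalg.svd(seg, full_matrices=False)
        tangents[i] = vt[0] / np.linalg.norm(vt[0])
    return tangents


# ---------------------------------------------------------------------------
# FWHM


def fwhm(profile: np.ndarray, pixel_size: float,
         baseline_frac: float = 0.10) -> float:
    """Full width at half maximum of an intensity profile, in um.

    The baseline is the mean of the outer ``baseline_frac`` of samples on
    each side; the half-maximum level is baseline + (peak - baseline)/2.
    The width is the distance between the two half-maximum crossings
    flanking the global peak.  Sub-pixel localization uses a cubic-spline
    interpolant of the profile: the peak is refined on the spline and each
    crossing is root-found within its bracketing sample interval (linear
    interpolation is noticeably biased for peaks only 1-2 samples wide).
    Returns NaN if the profile has no crossing on either side (vessel
    clipped by the sampling window).

    Invariant to translation and to positive rescaling of the intensities.
    """
    from scipy.interpolate import CubicSpline

    y = np.asarray(profile, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("profile must have at least 5 samples")
    if not np.all(np.isfinite(y)):
        return float("nan")
    n_edge = max(int(round(baseline_frac * n)), 1)
    baseline = 0.5 * (y[:n_edge].mean() + y[-n_edge:].mean())
    if y.max() <= baseline:
        return float("nan")

    up = 8  # spline upsampling factor for sub-pixel crossings
    xf = np.linspace(0.0, n - 1.0, (n - 1) * up + 1)
    yf = CubicSpline(np.arange(n), y)(xf)
    ipk = int(np.argmax(yf))
    half = baseline + (yf[ipk] - baseline) / 2.0
    above = yf > half

    below_left = np.where(~above[: ipk + 1])[0]
    if len(below_left) == 0:
        return float("nan")
    i = below_left[-1]
    left = xf[i] + (half - yf[i]) / (yf[i + 1] - yf[i]) * (xf[i + 1] - xf[i])

    below_right = np.where(~above[ipk:])[0]
    if len(below_right) == 0:
        return float("nan")
    j = ipk + below_right[0]
    right = xf[j - 1] + (yf[j - 1] - half) / (yf[j - 1] - yf[j]) * (xf[j] - xf[j - 1])
    return float((right - left) * pixel_size)


def _sample_profile(frame: np.ndarray, point: np.ndarray, normal: np.ndarray,
                    half_len_px: float, step: float = 0.5) -> np.ndarray:
    """Bilinear samples along the perpendicular through ``point``."""
    offsets = np.arange(-half_len_px, half_len_px + step, step)
    ys = point[0] + offsets * normal[0]
    xs = point[1] + offsets * normal[1]
    return ndimage.map_coordinates(frame, [ys, xs], order=1, mode="nearest"), step


def diameter_trace(movie: VesselMovie, skeleton: SkeletonModel,
                   profile_halfwidth: float = 20.0,
                   min_valid_fraction: float = 0.5,
                   point_stride: int = 1,
                   running_window: int = 5) -> DiameterTrace:
    """Per-frame vessel diameter: mean FWHM over skeleton-perpendicular
    profiles.

    Profiles are averaged over a running window of ``running_window``
    adjacent skeleton points before the FWHM is taken — along a locally
    straight vessel the geometry is shared while the noise is independent,
    so the average suppresses spurious sub-half-maximum dips without
    blurring the cross-section.

    profile_halfwidth: half-length of each perpendicular profile in um
    (default 20 um, i.e. 2x a typical max pial diameter).  Frames where
    fewer than ``min_valid_fraction`` of profiles yield a valid FWHM are
    flagged invalid (NaN with a reason code).  ``point_stride`` subsamples
    the skeleton (every k-th point) to trade precision of the per-frame
    average for speed on long recordings.
    """
    if len(skeleton) == 0:
        raise ValueError("skeleton is empty")
    half_px = profile_halfwidth / movie.pixel_size
    normals = np.stack([-skeleton.tangents[:, 1], skeleton.tangents[:, 0]], axis=1)
    # profiles may extend past the frame (sampled with edge padding); the
    # per-profile FWHM validity check catches genuinely clipped vessels
    pts = skeleton.points[::max(point_stride, 1)]
    nrm = normals[::max(point_stride, 1)]

    values = np.full(movie.n_frames, np.nan)
    n_valid = np.zeros(movie.n_frames, dtype=int)
    reasons: list = [None] * movie.n_frames
    step = 0.5  # px
    offsets = np.arange(-half_px, half_px + step, step)
    # precompute all sampling coordinates: (n_points, n_offsets)
    ys = pts[:, 0:1] + offsets[None, :] * nrm[:, 0:1]
    xs = pts[:, 1:2] + offsets[None, :] * nrm[:, 1:2]
    coords = np.stack([ys.ravel(), xs.ravel()])
    px_step = step * movie.pixel_size
    win = max(int(running_window), 1)
    for f in range(movie.n_frames):
        prof = ndimage.map_coordinates(movie.data[f], coords, order=1,
                                       mode="nearest").reshape(len(pts), -1)
        if win > 1 and len(prof) > 1:
            kernel = np.ones(min(win, len(prof)))
            kernel /= kernel.sum()
            prof = ndimage.convolve1d(prof, kernel, axis=0, mode="nearest")
        widths = np.array([fwhm(pr, px_step) for pr in prof])
        good = np.isfinite(widths)
        n_valid[f] = int(good.sum())
        if good.sum() >= min_valid_fraction * len(pts):
            values[f] = widths[good].mean()
        else:
            reasons[f] = "too_few_valid_points"
    return DiameterTrace(values=values, frame_rate=movie.frame_rate,
                         n_valid_points=n_valid, reasons=reasons)


# ---------------------------------------------------------------------------
# radon velocimetry


def rbcv_radon(kymo: Kymograph, window_len: int = 128,
               window_overlap: float = 0.5, angle_step: float = 0.25,
               quality_floor_factor: float = 2.0,
               shuffle_seed: int = 0) -> VelocityTrace:
    """Red-blood-cell velocity per analysis window via the radon transform.

    For each window of ``window_len`` lines, the angle that maximizes the
    variance of the radon projections gives the streak slope.  With rows as
    time and columns as space, a displacement of u pixels per line appears
    at angle theta with u = tan(theta), so

        velocity [mm/s] = pixel_size * line_rate * tan(theta) / 1000

    Sign convention: displacement toward increasing position index is
    positive.  Quality per window is the normalized variance contrast
    max(var)/median(var); windows whose contrast falls below
    ``quality_floor_factor`` times the contrast of the same window with its
    lines randomly permuted (which destroys streak alignment) are flagged
    invalid.
    """
    if window_len < 64:
        raise ValueError("window_len must be >= 64 lines")
    data = kymo.data
    n_lines = data.shape[0]
    hop = max(int(round(window_len * (1.0 - window_overlap))), 1)
    starts = list(range(0, n_lines - window_len + 1, hop))
    if not starts:
        raise ValueError("kymograph shorter than one analysis window")

    theta = np.arange(angle_step, 180.0, angle_step)
    rng = np.random.default_rng(shuffle_seed)
    values, centers, quality, valid = [], [], [], []
    for s in starts:
        win = data[s:s + window_len].astype(float)
        if np.ptp(win) == 0:  # blank / saturated
            values.append(np.nan)
            centers.append((s + window_len / 2) / kymo.line_rate)
            quality.append(0.0)
            valid.append(False)
            continue
        perm = rng.permutation(window_len)
        contrast, best = _radon_contrast(win, theta)
        null_contrast, _ = _radon_contrast(win[perm], theta)
        q = contrast / max(null_contrast, 1e-12)
        ok = contrast >= quality_floor_factor * null_contrast
        if ok:
            u = _refine_slope(win, math.tan(math.radians(best)))
            v_mm_s = u * kymo.pixel_size * kymo.line_rate / 1000.0
            values.append(v_mm_s)
        else:
            values.append(np.nan)
        centers.append((s + window_len / 2) / kymo.line_rate)
        quality.append(q)
        valid.append(ok)
    return VelocityTrace(values=np.array(values),
                         window_centers=np.array(centers),
                         quality=np.array(quality),
                         valid=np.array(valid))


def _shear_score(win: np.ndarray, u: float, oversample: int = 2) -> float:
    """Alignment score of the window sheared by slope u (px/line): variance
    of the column means after shifting each line by -u * (t - t_center).

    Equivalent to the radon projection at angle atan(u) but evaluated on
    the full rectangular window (no circular crop), parameterized directly
    in displacement, and accumulated on an ``oversample``-times finer
    column grid (a 1-px projection grid aliases streaks of ~1 px width).
    """
    n_t, n_x = win.shape
    t = np.arange(n_t) - (n_t - 1) / 2.0
    xf = np.arange(0.0, n_x - 1.0, 1.0 / oversample)
    xs = xf[None, :] + u * t[:, None]
    xi = np.floor(xs).astype(int)
    frac = xs - xi
    valid = (xi >= 0) & (xi + 1 <= n_x - 1)
    xi_c = np.clip(xi, 0, n_x - 2)
    rows = np.broadcast_to(np.arange(n_t)[:, None], xs.shape)
    sheared = (1 - frac) * win[rows, xi_c] + frac * win[rows, xi_c + 1]
    acc = np.where(valid, sheared, 0.0).sum(axis=0)
    cnt = valid.sum(axis=0)
    ok = cnt >= 0.9 * n_t
    if ok.sum() < 8 * oversample:
        return float("nan")
    return float(np.var(acc[ok] / cnt[ok]))


def _refine_slope(win: np.ndarray, u0: float) -> float:
    """Sub-grid streak slope from the coarse radon estimate.

    Steep streaks (|u| > 1 px/line) are refined on the transposed window,
    where they run near-vertical and every streak spans the full window.
    In the working frame |u| <= 1 and the coarse radon angle grid already
    localizes the slope to ~0.01 absolute, so a single fine shear-score
    sweep suffices; the estimate is the centroid of the squared
    above-baseline score lobe (robust to plateau noise).
    """
    transpose = abs(u0) > 1.0
    w = win.T if transpose else win
    u = (1.0 / u0) if transpose else u0
    grid = np.linspace(u - 0.02, u + 0.02, 41)
    scores = np.array([_shear_score(w, g) for g in grid])
    if not np.all(np.isnan(scores)):
        base = np.nanmedian(scores)
        lobe = np.where(np.isnan(scores), 0.0,
                        np.clip(scores - base, 0.0, None)) ** 2
        if lobe.sum() > 0:
            u = float((grid * lobe).sum() / lobe.sum())
        else:
            u = float(grid[int(np.nanargmax(scores))])
    return (1.0 / u) if transpose else u


def _radon_variance(win: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Variance of radon projections per angle (circle-masked square)."""
    w = win - win.mean()
    n = min(w.shape)
    sq = w[:n, :n] if w.shape[0] >= w.shape[1] else w[:, :n][:n]
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= c ** 2
    sq = np.where(mask, sq, 0.0)
    import warnings

    with warnings.catch_warnings():
        # boundary pixels of our inscribed-circle mask sit exactly on
        # skimage's reconstruction circle; harmless
        warnings.filterwarnings("ignore", message=".*reconstruction circle.*")
        sino = radon(sq, theta=theta, circle=True)
    return sino.var(axis=0)


def _radon_contrast(win: np.ndarray, theta: np.ndarray) -> tuple[float, float]:
    """Variance contrast of radon projections and the best angle."""
    var = _radon_variance(win, theta)
    med = np.median(var)
    if med <= 0:
        return 0.0, float(theta[0])
    best = float(theta[int(np.argmax(var))])
    return float(var.max() / med), best


# ---------------------------------------------------------------------------
# calibre classification


def classify_vessel(diameter: float, superficial: bool) -> str:
    """Classify a vessel by calibre.

    < 7 um -> capillary; > 12 um and superficial -> pial; everything else
    (including exactly 7 or 12 um, and deep large vessels) -> intermediate.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if diameter < 7.0:
        return "capillary"
    if diameter > 12.0:
        if superficial:
            return "pial"
        log.warning("vessel of %.1f um is not superficial; classifying as "
                    "intermediate", diameter)
        return "intermediate"
    return "intermediate"


# ---------------------------------------------------------------------------
# optional registration shim


def register_movie(movie: VesselMovie, reference: np.ndarray | None = None,
                   max_shift: int = 10) -> VesselMovie:
    """Integer-shift cross-correlation registration of each frame to the
    mean image (or a supplied reference).  A convenience for lightly
    drifting recordings; inputs are normally assumed pre-registered."""
    ref = movie.mean_image() if reference is None else np.asarray(reference)
    ref0 = ref - ref.mean()
    out = np.empty_like(movie.data)
    for i, frame in enumerate(movie.data):
        f0 = frame - frame.mean()
        corr = ndimage.correlate(f0, ref0, mode="constant")
        # search a bounded neighbourhood around zero shift
        cy, cx = np.array(corr.shape) // 2
        sl = corr[cy - max_shift:cy + max_shift + 1,
                  cx - max_shift:cx + max_shift + 1]
        dy, dx = np.unravel_index(np.argmax(sl), sl.shape)
        shift = (max_shift - dy, max_shift - dx)
        out[i] = np.roll(frame, shift, axis=(0, 1))
    return VesselMovie(data=out, pixel_size=movie.pixel_size,
                       frame_rate=movie.frame_rate)
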