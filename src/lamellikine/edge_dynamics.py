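"""Leading-edge morphodynamics.

Segments single-channel time-lapse movies, maps signed edge-normal velocity
along the cell boundary, and computes lamellipodium metrics: protrusion
speed in a cone about the migration direction, its standard deviation
(stability), the longest uninterrupted protruding arc, the protrusion
length distribution, curved-ROI centerline length, width, and
intensity/area ratios.

Velocity sign convention: for a boundary point of frame ``t`` the signed
normal velocity is ``-SDF_{t+1}(p) / frame_interval`` where the signed
distance field of frame ``t+1`` is negative inside its mask — growth gives
positive velocity.  The last frame carries no velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform
from skimage import exposure, measure

__all__ = [
    "MaskMovie",
    "EdgeProfile",
    "LamelliMetrics",
    "EdgeDynamicsError",
    "preprocess_and_segment",
    "edge_velocity",
    "cone_speed",
    "protrusion_stability",
    "longest_uninterrupted_run",
    "protrusion_length_distribution",
    "curve_length",
    "lamellipodium_morphometrics",
]


class EdgeDynamicsError(ValueError):
    pass


@dataclass
class MaskMovie:
    """Binary masks per frame plus the calibration needed downstream."""

    masks: np.ndarray              # (T, H, W) bool
    pixel_size: float              # um/px
    frame_interval: float          # seconds
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise EdgeDynamicsError("masks must be a (T, H, W) stack")
        for t, m in enumerate(self.masks):
            if not m.any():
                raise EdgeDynamicsError(f"frame {t}: empty mask")

    @property
    def n_frames(self) -> int:
        return len(self.masks)

    def areas(self) -> np.ndarray:
        """Mask area per frame in um^2."""
        return self.masks.sum(axis=(1, 2)) * self.pixel_size ** 2


@dataclass
class EdgeProfile:
    """Arc-length-parameterised signed normal velocity along the boundary.

    One entry per frame that has a successor: ordered boundary points (um),
    cumulative arc length (um), signed normal velocity per point (um/min,
    protrusion positive), plus per-frame centroid and smoothed migration
    direction (unit vector, or NaN when the centroid is stationary).
    """

    boundaries: list[np.ndarray]       # each (n_i, 2) as (x, y) um
    arc_lengths: list[np.ndarray]      # each (n_i,) cumulative um, starts at 0
    velocities: list[np.ndarray]       # each (n_i,) um/min
    centroids: np.ndarray              # (T, 2) um — all frames
    migration_dirs: np.ndarray         # (T-1, 2) unit vectors or NaN
    pixel_size: float
    frame_interval: float              # seconds

    @property
    def n_frames(self) -> int:
        return len(self.boundaries)

    def perimeter(self, t: int) -> float:
        pts = self.boundaries[t]
        closed = np.vstack([pts, pts[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


@dataclass
class LamelliMetrics:
    length: float                  # um
    width: float                   # um
    area: float                    # um^2
    length_per_area: float         # 1/um
    intensity_per_area: float      # a.u. / um^2


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def preprocess_and_segment(
    movie: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    *,
    blur_sigma: float = 1.0,
    percentiles: tuple[float, float] = (1.0, 99.5),
    threshold: float | None = None,
) -> tuple[MaskMovie, np.ndarray]:
    """Segment a single-channel movie into one foreground component per frame.

    Per frame: percentile contrast stretch to [0, 1], Gaussian blur,
    histogram matching to frame 0 (bleach correction), then a global Otsu
    threshold derived from frame 0 and propagated to all frames; the largest
    connected component is kept and holes are filled.  Returns the mask
    movie and the masked contrast-enhanced (unblurred) movie used as PIV
    input.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise EdgeDynamicsError("movie must be a (T, H, W) stack with >= 2 frames")

    enhanced = np.empty_like(movie)
    smoothed = np.empty_like(movie)
    for t, frame in enumerate(movie):
        lo, hi = np.percentile(frame, percentiles)
        if hi <= lo:
            raise EdgeDynamicsError(f"frame {t}: constant intensity, cannot segment")
        stretched = np.clip((frame - lo) / (hi - lo), 0.0, 1.0)
        enhanced[t] = stretched
        smoothed[t] = ndimage.gaussian_filter(stretched, blur_sigma)
    for t in range(1, len(smoothed)):
        smoothed[t] = exposure.match_histograms(smoothed[t], smoothed[0])

    if threshold is None:
        from skimage.filters import threshold_otsu
        threshold = float(threshold_otsu(smoothed[0]))

    masks = np.zeros(movie.shape, dtype=bool)
    for t, frame in enumerate(smoothed):
        fg = frame > threshold
        if not fg.any():
            raise EdgeDynamicsError(f"frame {t}: empty foreground after threshold")
        labels, n = ndimage.label(fg)
        if n > 1:
            sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
            fg = labels == (1 + int(np.argmax(sizes)))
        masks[t] = ndimage.binary_fill_holes(fg)

    mm = MaskMovie(masks, pixel_size, frame_interval, provenance={
        "blur_sigma": blur_sigma, "percentiles": list(percentiles),
        "threshold": threshold,
    })
    return mm, enhanced * masks


# ---------------------------------------------------------------------------
# Edge velocity profiling
# ---------------------------------------------------------------------------

def _main_contour(mask: np.ndarray) -> np.ndarray:
    """Longest closed iso-contour of a binary mask, as (row, col) points.

    The mask is zero-padded first so objects touching the image border still
    yield a closed contour.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = [c - 1.0 for c in measure.find_contours(padded, 0.5)]
    if not contours:
        raise EdgeDynamicsError("mask has no boundary contour")
    contour = max(contours, key=len)
    # drop the duplicated closing point
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if len(contour) < 3:
        raise EdgeDynamicsError("degenerate boundary (< 3 points)")
    return contour


def _orient_ccw_image(contour_rc: np.ndarray) -> np.ndarray:
    """Counter-clockwise traversal with the image y-axis pointing down."""
    x, y = contour_rc[:, 1], contour_rc[:, 0]
    # shoelace in image coords (y down): positive area = clockwise on screen
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return contour_rc[::-1] if area2 > 0 else contour_rc


def _roll_to_origin(contour_rc: np.ndarray) -> np.ndarray:
    start = int(np.argmin(np.hypot(contour_rc[:, 0], contour_rc[:, 1])))
    return np.roll(contour_rc, -start, axis=0)


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance to the mask boundary in px, negative inside the mask."""
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return outside - inside


def _smooth_contour(contour: np.ndarray, window: int = 5) -> np.ndarray:
    """Circular moving average along a closed contour (kills pixel staircase)."""
    if window <= 1 or len(contour) <= window:
        return contour
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.vstack([contour[-pad:], contour, contour[:pad]])
    sm = np.column_stack([
        np.convolve(ext[:, k], kernel, mode="valid") for k in range(2)
    ])
    return sm


def _point_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from each point to a closed polyline, sub-pixel accurate.

    Candidate segments are found through a KD-tree on the polyline vertices;
    the exact point-segment distance is then minimised over the segments
    adjacent to the nearest vertices.
    """
    from scipy.spatial import cKDTree

    m = len(polyline)
    tree = cKDTree(polyline)
    k = min(6, m)
    _, idx = tree.query(points, k=k)
    idx = np.atleast_2d(idx)
    seg_a = polyline
    seg_b = np.roll(polyline, -1, axis=0)
    out = np.empty(len(points))
    for i, (p, nearest) in enumerate(zip(points, idx)):
        segs = np.unique(np.concatenate([nearest % m, (nearest - 1) % m]))
        a, b = seg_a[segs], seg_b[segs]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.maximum(denom, 1e-12),
                    0.0, 1.0)
        proj = a + t[:, None] * ab
        out[i] = np.sqrt(np.min(np.sum((p - proj) ** 2, axis=1)))
    return out


def _smooth_directions(displacements: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average of centroid displacement, normalised per frame.

    Frames where the smoothed displacement vanishes get NaN direction.
    """
    n = len(displacements)
    out = np.full((n, 2), np.nan)
    half = window // 2
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        v = displacements[lo:hi].mean(axis=0)
        norm = np.linalg.norm(v)
        if norm > 0:
            out[t] = v / norm
    return out


def edge_velocity(masks: MaskMovie, smooth_window: int = 5) -> EdgeProfile:
    """Signed edge-normal velocity along the boundary of each frame.

    For every boundary point of frame ``t`` the velocity is the signed
    distance to the frame ``t+1`` boundary divided by the frame interval
    (negative inside the next mask, so growth gives positive velocity),
    converted to um/min.  Contours are lightly smoothed along their length
    (``smooth_window`` points) to suppress pixel staircase noise.
    """
    from matplotlib.path import Path as _MplPath

    if masks.n_frames < 2:
        raise EdgeDynamicsError("need >= 2 frames")
    ps, fi = masks.pixel_size, masks.frame_interval

    boundaries, arcs, velocities = [], [], []
    centroids = np.array([ndimage.center_of_mass(m) for m in masks.masks])[:, ::-1] * ps
    for t in range(masks.n_frames - 1):
        contour = _smooth_contour(
            _roll_to_origin(_orient_ccw_image(_main_contour(masks.masks[t]))),
            smooth_window)
        next_contour = _smooth_contour(_main_contour(masks.masks[t + 1]),
                                       smooth_window)
        dist = _point_polyline_distance(contour, next_contour)
        inside = _MplPath(next_contour).contains_points(contour)
        vel = np.where(inside, dist, -dist) * ps / (fi / 60.0)
        vel[np.abs(vel) < 1e-9] = 0.0  # points on the next boundary: no motion
        pts_xy = contour[:, ::-1] * ps
        seg = np.linalg.norm(np.diff(pts_xy, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        boundaries.append(pts_xy)
        arcs.append(arc)
        velocities.append(vel)

    disp = np.diff(centroids, axis=0)
    dirs = _smooth_directions(disp)
    return EdgeProfile(boundaries, arcs, velocities, centroids, dirs, ps, fi)


# ---------------------------------------------------------------------------
# Cone metrics
# ---------------------------------------------------------------------------

def _cone_samples(profile: EdgeProfile, t: int, cone_deg: float) -> np.ndarray:
    """Velocity samples of frame t whose boundary direction from the centroid
    lies within +/- cone_deg/2 of the migration direction; None if undefined."""
    direction = profile.migration_dirs[t]
    if not np.all(np.isfinite(direction)):
        return None
    rel = profile.boundaries[t] - profile.centroids[t]
    norms = np.linalg.norm(rel, axis=1)
    ok = norms > 0
    cosang = np.full(len(rel), -np.inf)
    cosang[ok] = rel[ok] @ direction / norms[ok]
    in_cone = cosang >= np.cos(np.deg2rad(cone_deg) / 2.0)
    return profile.velocities[t][in_cone]


def cone_speed(profile: EdgeProfile, cone_deg: float = 60.0) -> np.ndarray:
    """Per-frame mean protrusion speed in a cone about the migration direction.

    Frames with an undefined migration direction (stationary centroid) or an
    empty cone yield NaN and are skipped by downstream means.
    """
    out = np.full(profile.n_frames, np.nan)
    for t in range(profile.n_frames):
        samples = _cone_samples(profile, t, cone_deg)
        if samples is not None and len(samples):
            out[t] = float(samples.mean())
    return out


def protrusion_stability(profile: EdgeProfile, cone_deg: float = 60.0,
                         mode: str = "pooled") -> float:
    """S.D. of cone speed samples — the stability measure.

    ``mode="pooled"`` (default) pools the per-point cone samples across all
    frames; ``mode="frame_means"`` takes the S.D. of the per-frame mean cone
    speeds instead.
    """
    if mode not in ("pooled", "frame_means"):
        raise EdgeDynamicsError(f"unknown stability mode {mode!r}")
    if mode == "frame_means":
        speeds = cone_speed(profile, cone_deg)
        speeds = speeds[np.isfinite(speeds)]
        if len(speeds) < 2:
            raise EdgeDynamicsError("fewer than 2 frames with a defined cone")
        return float(np.std(speeds, ddof=1))
    pooled = [s for t in range(profile.n_frames)
              if (s := _cone_samples(profile, t, cone_deg)) is not None and len(s)]
    if not pooled or sum(len(s) for s in pooled) < 2:
        raise EdgeDynamicsError("fewer than 2 cone speed samples")
    return float(np.std(np.concatenate(pooled), ddof=1))


# ---------------------------------------------------------------------------
# Protruding runs
# ---------------------------------------------------------------------------

def _runs_for_frame(arc: np.ndarray, vel: np.ndarray, perimeter: float,
                    v_min: float) -> list[float]:
    """Arc lengths of maximal contiguous stretches with vel > v_min (circular)."""
    protruding = vel > v_min
    n = len(protruding)
    if not protruding.any():
        return []
    # arc element owned by point i: distance to the next point (with wrap)
    seg = np.empty(n)
    seg[:-1] = np.diff(arc)
    seg[-1] = perimeter - arc[-1]
    if protruding.all():
        return [perimeter]
    # rotate so the sequence starts at a non-protruding point; runs then never wrap
    start = int(np.argmin(protruding))
    p = np.roll(protruding, -start)
    s = np.roll(seg, -start)
    runs, acc = [], 0.0
    for flag, length in zip(p, s):
        if flag:
            acc += length
        elif acc > 0:
            runs.append(acc)
            acc = 0.0
    if acc > 0:
        runs.append(acc)
    return runs


def longest_uninterrupted_run(profile: EdgeProfile,
                              v_min: float = 0.0) -> tuple[np.ndarray, float]:
    """Longest contiguous protruding arc per frame (um) and its track mean.

    A boundary point is protruding when its velocity exceeds ``v_min``;
    contiguity wraps around the closed boundary.
    """
    per_frame = np.zeros(profile.n_frames)
    for t in range(profile.n_frames):
        runs = _runs_for_frame(profile.arc_lengths[t], profile.velocities[t],
                               profile.perimeter(t), v_min)
        per_frame[t] = max(runs) if runs else 0.0
    return per_frame, float(per_frame.mean())


def protrusion_length_distribution(profile: EdgeProfile,
                                   v_min: float = 0.0) -> np.ndarray:
    """Every contiguous protruding arc length, all frames pooled (um)."""
    out = []
    for t in range(profile.n_frames):
        out.extend(_runs_for_frame(profile.arc_lengths[t], profile.velocities[t],
                                   profile.perimeter(t), v_min))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Curved-ROI length and morphometrics
# ---------------------------------------------------------------------------

def _max_separation_pair(points: np.ndarray) -> tuple[int, int]:
    """Indices of the two points with the largest separation (ties: lexicographic)."""
    if len(points) > 10:
        hull = ConvexHull(points)
        cand = hull.vertices
    else:
        cand = np.arange(len(points))
    sub = points[cand]
    d = squareform(pdist(sub))
    best = np.argwhere(d == d.max())
    # lexicographic tie-break on the original indices
    pairs = sorted((min(cand[i], cand[j]), max(cand[i], cand[j]))
                   for i, j in best if i < j)
    return pairs[0]


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an open polyline at n points equally spaced in arc length."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] == 0:
        return np.tile(points[0], (n, 1))
    s = np.linspace(0.0, arc[-1], n)
    return np.column_stack([np.interp(s, arc, points[:, k]) for k in range(2)])


def centerline(mask_or_points, pixel_size: float = 1.0,
               n_samples: int = 200) -> np.ndarray:
    """Centerline of an elongated object, in um.

    Endpoints are the max-separation boundary pair; the boundary is split
    into the two arcs joining them, each re-parameterised to normalised arc
    length on a common grid, and averaged pointwise.  For shapes without a
    unique endpoint pair (e.g. a circle) ties are broken lexicographically,
    giving a documented half-perimeter-like result.
    """
    if isinstance(mask_or_points, np.ndarray) and mask_or_points.ndim == 2 \
            and mask_or_points.dtype == bool:
        contour = _main_contour(mask_or_points)
    else:
        contour = np.asarray(mask_or_points, dtype=float)
        if contour.ndim != 2 or len(contour) < 3:
            raise EdgeDynamicsError("need >= 3 boundary points")
    i, j = _max_separation_pair(contour)
    if i > j:
        i, j = j, i
    arc_a = contour[i:j + 1]
    arc_b = np.vstack([contour[j:], contour[:i + 1]])[::-1]  # also i -> j
    a = _resample_polyline(arc_a, n_samples)
    b = _resample_polyline(arc_b, n_samples)
    return 0.5 * (a + b)[:, ::-1] * pixel_size  # (row,col) -> (x,y) um


def curve_length(mask_or_points, pixel_size: float = 1.0) -> float:
    """Centerline length (um) of a curved object — endpoint/side-average method."""
    line = centerline(mask_or_points, pixel_size)
    return float(np.sum(np.linalg.norm(np.diff(line, axis=0), axis=1)))


def _width_at(mask: np.ndarray, point_px: np.ndarray, normal: np.ndarray,
              step: float = 0.25, max_steps: int = 4000) -> float:
    """Extent of the mask along +/- normal from a centerline point, in px."""
    def reach(direction):
        r = 0.0
        for k in range(1, max_steps):
            p = point_px + direction * (k * step)
            if not (0 <= p[0] < mask.shape[0] - 1 and 0 <= p[1] < mask.shape[1] - 1):
                break
            val = ndimage.map_coordinates(mask.astype(float), p[:, None], order=1)[0]
            if val < 0.5:
                break
            r = k * step
        return r
    return reach(normal) + reach(-normal)


def lamellipodium_morphometrics(
    cell_mask: np.ndarray,
    lamellipodium_mask: np.ndarray,
    intensity: np.ndarray,
    pixel_size: float,
    n_width_points: int = 10,
) -> LamelliMetrics:
    """Length, width, area and intensity metrics of a lamellipodium band.

    Length is the centerline length; width is the mean mask extent along the
    local centerline normal at ``n_width_points`` equally spaced centerline
    points; areas are in um^2.  Intensity normalisation against a control
    group is a separate, downstream step.
    """
    if not lamellipodium_mask.any():
        raise EdgeDynamicsError("empty lamellipodium mask")
    if np.any(lamellipodium_mask & ~cell_mask):
        raise EdgeDynamicsError("lamellipodium mask must lie inside the cell mask")

    line_um = centerline(lamellipodium_mask, pixel_size)
    length = float(np.sum(np.linalg.norm(np.diff(line_um, axis=0), axis=1)))

    line_px = line_um[:, ::-1] / pixel_size  # (row, col)
    idx = np.linspace(0, len(line_px) - 1, n_width_points + 2)[1:-1].astype(int)
    widths = []
    for i in idx:
        lo, hi = max(0, i - 2), min(len(line_px) - 1, i + 2)
        tangent = line_px[hi] - line_px[lo]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        normal = np.array([-tangent[1], tangent[0]]) / norm
        widths.append(_width_at(lamellipodium_mask, line_px[i], normal))
    width = float(np.mean(widths)) * pixel_size if widths else 0.0

    area = float(lamellipodium_mask.sum()) * pixel_size ** 2
    cell_area = float(cell_mask.sum()) * pixel_size ** 2
    total_intensity = float(intensity[lamellipodium_mask].sum())
    return LamelliMetrics(
        length=length,
        width=width,
        area=cell_area,
        length_per_area=length / cell_area,
        intensity_per_area=total_intensity / area,
    )
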