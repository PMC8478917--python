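"""Cross-correlation PIV of intracellular flow and assembly-rate computation.

A sparse grid of displacement vectors is estimated per frame pair by
zero-normalised (Pearson) template matching of a source box against a
larger search box in the next frame; vectors below a correlation threshold
are dropped.  Sparse vectors are interpolated to a dense spatiotemporal
field by normalised convolution with truncated Gaussian kernels in space
and time, from which per-frame and per-cell flow speeds are computed.  The
assembly rate combines flow speed with edge protrusion speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import match_template

__all__ = [
    "PIVParams",
    "SparseVectors",
    "FlowPIVError",
    "piv_frame_pair",
    "piv_movie",
    "interpolate_dense",
    "mean_flow_speed",
    "assembly_rate",
    "truncate_movie",
]


class FlowPIVError(ValueError):
    pass


def _odd_px(size_um: float, pixel_size: float) -> int:
    """Convert a box size in um to the nearest odd pixel count >= 3."""
    px = max(3, int(round(size_um / pixel_size)))
    return px if px % 2 == 1 else px + 1


@dataclass(frozen=True)
class PIVParams:
    """PIV geometry and interpolation parameters (um / seconds).

    Defaults follow the analysis settings: source box 0.3 um, search box
    0.5 um, grid step 0.2 um, correlation threshold 0.5, spatial kernel
    3 um (sigma 0.5 um), temporal kernel 15 s (sigma 6 s).
    """

    pixel_size: float              # um/px
    frame_interval: float          # seconds
    source_box: float = 0.3
    search_box: float = 0.5
    grid_step: float = 0.2
    corr_threshold: float = 0.5
    spatial_kernel_size: float = 3.0
    spatial_sigma: float = 0.5
    temporal_kernel_size: float = 15.0
    temporal_sigma: float = 6.0
    subpixel: bool = True

    def __post_init__(self) -> None:
        if self.search_box <= self.source_box:
            raise FlowPIVError("search_box must exceed source_box")
        if not 0.0 < self.corr_threshold < 1.0:
            raise FlowPIVError("corr_threshold must lie in (0, 1)")
        if self.spatial_kernel_size < self.spatial_sigma \
                or self.temporal_kernel_size < self.temporal_sigma:
            raise FlowPIVError("kernel sizes must be >= their sigmas")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise FlowPIVError("pixel_size and frame_interval must be positive")

    @property
    def source_px(self) -> int:
        return _odd_px(self.source_box, self.pixel_size)

    @property
    def search_px(self) -> int:
        px = _odd_px(self.search_box, self.pixel_size)
        return max(px, self.source_px + 2)

    @property
    def reach_px(self) -> int:
        """Maximum displacement magnitude per axis, px."""
        return (self.search_px - self.source_px) // 2

    @property
    def grid_px(self) -> int:
        return max(1, int(round(self.grid_step / self.pixel_size)))


@dataclass
class SparseVectors:
    """Sparse PIV vectors of one frame pair.

    Positions are grid-node centres in px (row, col); displacements in px
    (drow, dcol); ``corr`` is the peak Pearson coefficient; ``valid`` marks
    vectors that passed the correlation threshold and had a well-defined
    source patch.
    """

    frame: int
    positions: np.ndarray          # (n, 2) px
    displacements: np.ndarray      # (n, 2) px
    corr: np.ndarray               # (n,)
    valid: np.ndarray              # (n,) bool
    params: PIVParams = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        ps = self.params.pixel_size
        return pd.DataFrame({
            "frame": self.frame,
            "x_um": self.positions[:, 1] * ps,
            "y_um": self.positions[:, 0] * ps,
            "dx_um": self.displacements[:, 1] * ps,
            "dy_um": self.displacements[:, 0] * ps,
            "corr": self.corr,
            "valid": self.valid,
        })


def _gaussian_subpixel(c_minus: float, c_peak: float, c_plus: float) -> float:
    """Three-point Gaussian peak interpolation offset in (-0.5, 0.5)."""
    eps = 1e-12
    lm, lp, lc = (np.log(max(c_minus, eps)), np.log(max(c_plus, eps)),
                  np.log(max(c_peak, eps)))
    denom = 2.0 * lm - 4.0 * lc + 2.0 * lp
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    off = (lm - lp) / denom
    return float(np.clip(off, -0.5, 0.5))


def piv_frame_pair(frame_t: np.ndarray, frame_t1: np.ndarray,
                   mask_t: np.ndarray, params: PIVParams,
                   frame_index: int = 0) -> SparseVectors:
    """Estimate sparse displacement vectors between two frames.

    Grid nodes are spaced ``grid_step`` starting at the mask bounding-box
    corner; a node contributes only when its source box lies entirely inside
    both the image and the mask.  The best match maximises the Pearson
    coefficient over every candidate offset inside the search box; ties are
    broken by smallest displacement magnitude, then row-major order.
    Zero-variance source patches are marked invalid.
    """
    frame_t = np.asarray(frame_t, dtype=float)
    frame_t1 = np.asarray(frame_t1, dtype=float)
    if frame_t.shape != frame_t1.shape:
        raise FlowPIVError("frames must share a shape")
    H, W = frame_t.shape
    src, srch = params.source_px, params.search_px
    hs, hr = src // 2, params.reach_px

    rows_any = np.any(mask_t, axis=1)
    cols_any = np.any(mask_t, axis=0)
    if not rows_any.any():
        raise FlowPIVError("empty mask")
    r0, c0 = int(np.argmax(rows_any)), int(np.argmax(cols_any))
    r1 = H - int(np.argmax(rows_any[::-1]))
    c1 = W - int(np.argmax(cols_any[::-1]))

    positions, disps, corrs, valids = [], [], [], []
    for r in range(r0, r1, params.grid_px):
        for c in range(c0, c1, params.grid_px):
            if r - hs < 0 or r + hs >= H or c - hs < 0 or c + hs >= W:
                continue
            if not mask_t[r - hs:r + hs + 1, c - hs:c + hs + 1].all():
                continue
            # pad the search by one pixel beyond the reach when the image
            # allows, so the sub-pixel fit has neighbours even at the reach
            pad = 1 if params.subpixel else 0
            hrp = hr + pad
            if (r - hs - hrp < 0 or c - hs - hrp < 0
                    or r + hs + hrp + 1 > H or c + hs + hrp + 1 > W):
                hrp, pad = hr, 0
            rr0, rr1 = r - hs - hrp, r + hs + hrp + 1
            cc0, cc1 = c - hs - hrp, c + hs + hrp + 1
            if rr0 < 0 or cc0 < 0 or rr1 > H or cc1 > W:
                continue
            source = frame_t[r - hs:r + hs + 1, c - hs:c + hs + 1]
            positions.append((r, c))
            if source.std() == 0:
                disps.append((0.0, 0.0))
                corrs.append(np.nan)
                valids.append(False)
                continue
            search = frame_t1[rr0:rr1, cc0:cc1]
            cc = match_template(search, source)        # (2hrp+1, 2hrp+1)
            cc = np.where(np.isfinite(cc), cc, -np.inf)
            # the accepted integer peak must lie within the reach
            inner = cc[pad:cc.shape[0] - pad, pad:cc.shape[1] - pad] \
                if pad else cc
            peak = float(inner.max())
            if not np.isfinite(peak):
                disps.append((0.0, 0.0))
                corrs.append(np.nan)
                valids.append(False)
                continue
            cand = np.argwhere(inner >= peak - 1e-12)
            offsets = cand - hr
            mags = np.sum(offsets ** 2, axis=1)
            best = cand[np.lexsort((cand[:, 1], cand[:, 0], mags))[0]]
            drow, dcol = (best - hr).astype(float)
            if params.subpixel:
                br, bc = best + pad     # index into the padded surface
                if 0 < br < cc.shape[0] - 1 and np.all(np.isfinite(cc[br - 1:br + 2, bc])):
                    drow += _gaussian_subpixel(cc[br - 1, bc], cc[br, bc], cc[br + 1, bc])
                if 0 < bc < cc.shape[1] - 1 and np.all(np.isfinite(cc[br, bc - 1:bc + 2])):
                    dcol += _gaussian_subpixel(cc[br, bc - 1], cc[br, bc], cc[br, bc + 1])
                drow = float(np.clip(drow, -hr, hr))
                dcol = float(np.clip(dcol, -hr, hr))
            disps.append((drow, dcol))
            corrs.append(float(peak))
            valids.append(bool(peak >= params.corr_threshold))

    n = len(positions)
    return SparseVectors(
        frame=frame_index,
        positions=np.asarray(positions, dtype=float).reshape(n, 2),
        displacements=np.asarray(disps, dtype=float).reshape(n, 2),
        corr=np.asarray(corrs, dtype=float),
        valid=np.asarray(valids, dtype=bool),
        params=params,
    )


def piv_movie(movie: np.ndarray, masks: np.ndarray,
              params: PIVParams) -> list[SparseVectors]:
    """PIV over all consecutive frame pairs of a movie."""
    if len(movie) < 2:
        raise FlowPIVError("need >= 2 frames")
    return [
        piv_frame_pair(movie[t], movie[t + 1], masks[t], params, frame_index=t)
        for t in range(len(movie) - 1)
    ]


# ---------------------------------------------------------------------------
# Dense interpolation
# ---------------------------------------------------------------------------

def _truncated_gaussian(size_phys: float, sigma_phys: float,
                        unit: float) -> np.ndarray:
    """1-D Gaussian kernel truncated at +/- size/2 (physical units), renormalised."""
    half = max(1, int(round(size_phys / 2.0 / unit)))
    x = np.arange(-half, half + 1) * unit
    k = np.exp(-0.5 * (x / sigma_phys) ** 2)
    return k / k.sum()


def interpolate_dense(sparse_layers: list[SparseVectors], shape: tuple[int, int],
                      params: PIVParams) -> np.ndarray:
    """Dense velocity field (um/min) by spatiotemporal normalised convolution.

    Valid sparse vectors are scattered onto a (T, H, W) grid; the weighted
    vector sum and the weight sum are convolved with the same separable
    truncated Gaussian kernels (spatial and temporal) and divided, so a
    uniform sparse field is reproduced exactly.  Pixels with zero total
    weight are NaN.  Returns an array of shape (T, H, W, 2) holding
    (vy, vx).
    """
    from scipy.ndimage import convolve1d

    if not sparse_layers:
        raise FlowPIVError("no sparse layers")
    p = params
    T = max(layer.frame for layer in sparse_layers) + 1
    H, W = shape
    num = np.zeros((T, H, W, 2))
    den = np.zeros((T, H, W))
    n_valid = 0
    for layer in sparse_layers:
        sel = layer.valid
        n_valid += int(sel.sum())
        pos = np.rint(layer.positions[sel]).astype(int)
        for (r, c), d in zip(pos, layer.displacements[sel]):
            num[layer.frame, r, c] += d
            den[layer.frame, r, c] += 1.0
    if n_valid == 0:
        raise FlowPIVError("no valid vectors to interpolate")

    ks = _truncated_gaussian(p.spatial_kernel_size, p.spatial_sigma, p.pixel_size)
    kt = _truncated_gaussian(p.temporal_kernel_size, p.temporal_sigma,
                             p.frame_interval)

    def blur(a):
        a = convolve1d(a, ks, axis=1, mode="constant")
        a = convolve1d(a, ks, axis=2, mode="constant")
        if len(kt) > 1:
            a = convolve1d(a, kt, axis=0, mode="constant")
        return a

    den_b = blur(den)
    num_b = np.stack([blur(num[..., k]) for k in range(2)], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        field_px = num_b / den_b[..., None]
    field_px[den_b <= 1e-12] = np.nan
    # px/frame -> um/min
    return field_px * p.pixel_size / (p.frame_interval / 60.0)


# ---------------------------------------------------------------------------
# Flow statistics
# ---------------------------------------------------------------------------

def mean_flow_speed(dense_field: np.ndarray,
                    masks: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-frame and per-cell mean flow speed (um/min) over masked pixels."""
    if not np.asarray(masks).any():
        raise FlowPIVError("empty mask")
    T = len(dense_field)
    per_frame = np.full(T, np.nan)
    for t in range(T):
        mag = np.linalg.norm(dense_field[t], axis=-1)
        sel = masks[t] & np.isfinite(mag)
        if sel.any():
            per_frame[t] = float(mag[sel].mean())
    finite = per_frame[np.isfinite(per_frame)]
    if len(finite) == 0:
        raise FlowPIVError("no masked pixels with interpolated flow")
    return per_frame, float(finite.mean())


def assembly_rate(flow_speed: float, protrusion_speed: float) -> float:
    """F-actin assembly rate: |flow| + |protrusion| (um/min)."""
    return abs(flow_speed) + abs(protrusion_speed)


def truncate_movie(
    stack: np.ndarray,
    masks: np.ndarray,
    *,
    min_area_fraction: float = 0.5,
    border_budget_px: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Drop trailing frames once the mask collapses or leaves the field.

    Truncation occurs at the first frame whose mask area falls below
    ``min_area_fraction`` of the first frame's, or whose border-touching
    pixel count exceeds ``border_budget_px``.  Returns the trimmed stack and
    masks plus a decision log.
    """
    masks = np.asarray(masks, dtype=bool)
    area0 = masks[0].sum()
    if area0 == 0:
        raise FlowPIVError("first frame has an empty mask")
    cut = len(masks)
    reason = None
    for t in range(len(masks)):
        area = masks[t].sum()
        border = (masks[t][0].sum() + masks[t][-1].sum()
                  + masks[t][:, 0].sum() + masks[t][:, -1].sum())
        if area < min_area_fraction * area0:
            cut, reason = t, f"area collapse at frame {t}"
            break
        if border > border_budget_px:
            cut, reason = t, f"mask touches border at frame {t}"
            break
    if cut == 0:
        raise FlowPIVError(f"all frames rejected: {reason}")
    log = {"n_input": len(masks), "n_kept": cut, "reason": reason,
           "min_area_fraction": min_area_fraction,
           "border_budget_px": border_budget_px}
    return stack[:cut], masks[:cut], log
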