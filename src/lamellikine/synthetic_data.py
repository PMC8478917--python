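"""Synthetic data generators with attached ground truth.

Every generator is deterministic under its seed and returns a
:class:`GroundTruth` record carrying the generating parameters and the
derived true values that the recovery tests compare against:

* :func:`simulate_crw` — correlated random walk tracks (lognormal step
  speeds, von Mises turning angles, additive Gaussian positional noise);
* :func:`replicate_observations` — repeated noisy observations of one true
  track, for the usable-time-interval procedure;
* :func:`synth_flow_movie` — a textured band translating rigidly at a
  prescribed retrograde flow speed while its outer edge protrudes;
* :func:`synth_edge_movie` — a disc-like cell protruding within an angular
  sector and retracting elsewhere;
* :func:`synth_tcspc` — mono-exponential photon-count decays with Poisson
  noise for donor-only and quenched pixel populations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .track_metrics import Track

__all__ = [
    "CRWParams",
    "FlowMovieParams",
    "TCSPCParams",
    "GroundTruth",
    "SyntheticDataError",
    "simulate_crw",
    "replicate_observations",
    "synth_flow_movie",
    "synth_edge_movie",
    "synth_tcspc",
]

# kappa at or above this is treated as the no-turning limit
KAPPA_DEGENERATE = 1e6


class SyntheticDataError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters plus derived true values for a synthetic artifact."""

    generator: str
    params: dict
    truth: dict
    warnings: tuple = ()

    def to_json(self, path) -> None:
        def _default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            raise TypeError(f"not JSON-serialisable: {type(obj)}")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, default=_default, indent=1)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise SyntheticDataError(msg)


def _finite(*values: float) -> bool:
    return all(np.isfinite(v) for v in values)


# ---------------------------------------------------------------------------
# Correlated random walk
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CRWParams:
    """Correlated-random-walk parameters.

    Step speeds are lognormal with the stated mean/sd (um/min); headings
    evolve by von Mises turning angles with concentration ``kappa`` (0 gives
    an uncorrelated walk); the observed track adds isotropic Gaussian
    positional noise of sd ``noise_sd`` um per coordinate.
    """

    n_frames: int = 100
    frame_interval: float = 5.0     # minutes
    speed_mean: float = 0.5         # um/min
    speed_sd: float = 0.2           # um/min
    kappa: float = 1.0
    noise_sd: float = 0.0           # um
    seed: int = 0

    def __post_init__(self) -> None:
        _require(_finite(self.frame_interval, self.speed_mean, self.speed_sd,
                         self.kappa, self.noise_sd), "non-finite parameter")
        _require(self.n_frames >= 2, "n_frames must be >= 2")
        _require(self.frame_interval > 0, "frame_interval must be positive")
        _require(self.speed_mean > 0, "speed_mean must be positive")
        _require(self.speed_sd >= 0, "speed_sd must be non-negative")
        _require(self.kappa >= 0, "kappa must be non-negative")
        _require(self.noise_sd >= 0, "noise_sd must be non-negative")


def _lognormal_steps(rng: np.random.Generator, mean: float, sd: float,
                     n: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and sd."""
    if sd == 0.0:
        return np.full(n, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _crw_true_positions(params: CRWParams, rng: np.random.Generator) -> np.ndarray:
    n_steps = params.n_frames - 1
    step_mean = params.speed_mean * params.frame_interval
    step_sd = params.speed_sd * params.frame_interval
    lengths = _lognormal_steps(rng, step_mean, step_sd, n_steps)
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    if params.kappa >= KAPPA_DEGENERATE:
        turns = np.zeros(n_steps - 1)
    elif params.kappa == 0.0:
        turns = rng.uniform(-np.pi, np.pi, size=n_steps - 1)
    else:
        turns = rng.vonmises(0.0, params.kappa, size=n_steps - 1)
    headings = theta0 + np.concatenate([[0.0], np.cumsum(turns)])
    steps = lengths[:, None] * np.column_stack([np.cos(headings), np.sin(headings)])
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


def simulate_crw(params: CRWParams) -> tuple[Track, GroundTruth]:
    """Simulate one correlated random walk; return (observed track, ground truth).

    The observed track equals the true positions plus i.i.d. Gaussian noise of
    sd ``noise_sd`` per coordinate; the ground truth carries the noise-free
    positions and the full parameter record.
    """
    rng = np.random.default_rng(params.seed)
    true_pos = _crw_true_positions(params, rng)
    noise = rng.normal(0.0, params.noise_sd, size=true_pos.shape) \
        if params.noise_sd > 0 else np.zeros_like(true_pos)
    times = np.arange(params.n_frames) * params.frame_interval
    observed = Track(f"crw-{params.seed}", times, true_pos + noise)
    truth = GroundTruth(
        generator="simulate_crw",
        params=dataclasses.asdict(params),
        truth={
            "true_positions": true_pos,
            "true_mean_speed": params.speed_mean,
            "times": times,
        },
    )
    return observed, truth


def simulate_crw_population(params: CRWParams, n_tracks: int) -> list[Track]:
    """Simulate ``n_tracks`` independent walks, seeds split from ``params.seed``."""
    seeds = np.random.SeedSequence(params.seed).spawn(n_tracks)
    tracks = []
    for i, ss in enumerate(seeds):
        p = dataclasses.replace(params, seed=int(ss.generate_state(1)[0] % (2 ** 31)))
        track, _ = simulate_crw(p)
        tracks.append(Track(f"crw-{params.seed}-{i}", track.times, track.positions))
    return tracks


def replicate_observations(truth: Track, noise_sd: float, n_replicates: int,
                           seed: int = 0) -> list[Track]:
    """Independent noisy observations of the same noise-free track."""
    _require(n_replicates >= 2, "n_replicates must be >= 2")
    _require(noise_sd >= 0 and np.isfinite(noise_sd), "noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=truth.positions.shape) \
            if noise_sd > 0 else np.zeros_like(truth.positions)
        out.append(Track(f"{truth.cell_id}-rep{r}", truth.times.copy(),
                         truth.positions + noise))
    return out


# ---------------------------------------------------------------------------
# Retrograde-flow movie
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowMovieParams:
    """Parameters of the textured flow movie.

    The texture band translates rigidly downward (+y, "into the cell") at
    ``flow_speed`` while the band's top edge advances upward (-y) at
    ``protrusion_speed``.  ``band_depth`` is the band depth in um.
    """

    shape: tuple[int, int] = (128, 128)   # (H, W) px
    pixel_size: float = 0.05              # um/px
    frame_interval: float = 3.22          # seconds
    n_frames: int = 20
    flow_speed: float = 1.5               # um/min
    protrusion_speed: float = 0.0         # um/min
    texture_grain: float = 2.0            # px
    texture_contrast: float = 1.0
    noise_sd: float = 0.02                # intensity units
    band_depth: float = 4.0               # um
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.flow_speed >= 0, "flow_speed must be >= 0")
        _require(self.band_depth > 0, "band_depth must be positive")
        _require(self.texture_grain >= 1.0, "texture_grain must be >= 1 px")
        _require(self.pixel_size > 0 and self.frame_interval > 0,
                 "pixel_size and frame_interval must be positive")
        _require(self.n_frames >= 2, "need >= 2 frames")

    @property
    def flow_px_per_frame(self) -> float:
        return self.flow_speed / 60.0 * self.frame_interval / self.pixel_size

    @property
    def protrusion_px_per_frame(self) -> float:
        return self.protrusion_speed / 60.0 * self.frame_interval / self.pixel_size


def _filtered_noise_texture(rng: np.random.Generator, shape: tuple[int, int],
                            grain: float, contrast: float) -> np.ndarray:
    """Gaussian-filtered white noise, softly rescaled to [0, 1] then contrast-scaled."""
    raw = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(raw, sigma=grain, mode="wrap")
    tex = (tex - tex.mean()) / (tex.std() + 1e-12)
    # soft squash keeps values in a bounded range without hard clipping
    tex = 0.5 * (1.0 + np.tanh(tex))
    return 0.5 + contrast * (tex - 0.5)


def _fourier_shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Sub-pixel periodic shift of a 2-D image (rows, cols)."""
    f = np.fft.fft2(image)
    return np.real(np.fft.ifft2(ndimage.fourier_shift(f, shift)))


def synth_flow_movie(params: FlowMovieParams) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Synthesize a flow movie; returns (movie, masks, ground truth).

    The interior texture translates rigidly by Fourier shift (no
    interpolation blur); per-frame sensor noise is re-drawn independently.
    The mask marks the band.  The ground truth stores the per-frame true
    displacement vector in um (dx, dy; +y is the flow direction).
    """
    H, W = params.shape
    rng = np.random.default_rng(params.seed)
    base = _filtered_noise_texture(rng, (H, W), params.texture_grain,
                                   params.texture_contrast)
    dpx = params.flow_px_per_frame
    ppx = params.protrusion_px_per_frame
    edge0 = max(2.0, 0.2 * H)  # initial top edge row of the band
    depth_px = params.band_depth / params.pixel_size

    movie = np.empty((params.n_frames, H, W), dtype=np.float32)
    masks = np.zeros((params.n_frames, H, W), dtype=bool)
    rows = np.arange(H)[:, None]
    for t in range(params.n_frames):
        shift_rows = dpx * t
        if abs(shift_rows - round(shift_rows)) < 1e-12:
            tex = np.roll(base, int(round(shift_rows)), axis=0)
        else:
            tex = _fourier_shift(base, (shift_rows, 0.0))
        edge = edge0 - ppx * t
        band = (rows >= edge) & (rows < edge + depth_px)
        mask = np.broadcast_to(band, (H, W)).copy()
        frame = np.where(mask, tex, 0.0)
        if params.noise_sd > 0:
            frame = frame + rng.normal(0.0, params.noise_sd, size=frame.shape)
        movie[t] = frame
        masks[t] = mask

    disp_um = np.tile([0.0, params.flow_speed / 60.0 * params.frame_interval],
                      (params.n_frames - 1, 1))
    warnings = []
    default_reach_um = (0.5 - 0.3) / 2.0
    if params.flow_speed / 60.0 * params.frame_interval > default_reach_um:
        warnings.append(
            "per-frame displacement exceeds the default PIV search reach "
            f"({default_reach_um} um)"
        )
    truth = GroundTruth(
        generator="synth_flow_movie",
        params=dataclasses.asdict(params),
        truth={
            "displacement_um_per_frame": disp_um,
            "flow_speed": params.flow_speed,
            "protrusion_speed": params.protrusion_speed,
            "flow_direction": [0.0, 1.0],
            "flow_px_per_frame": dpx,
        },
        warnings=tuple(warnings),
    )
    return movie, masks, truth


# ---------------------------------------------------------------------------
# Sector edge movie
# ---------------------------------------------------------------------------

def synth_edge_movie(
    arc_protruding: float,
    edge_speed: float,
    retraction_speed: float = 0.0,
    *,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.2,
    frame_interval: float = 5.0,       # seconds
    n_frames: int = 10,
    radius: float = 20.0,              # um
    sector_center_deg: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Disc-like cell protruding within an angular sector, retracting elsewhere.

    The boundary advances radially at ``edge_speed`` (um/min) inside a
    contiguous sector of ``arc_protruding`` degrees centred on
    ``sector_center_deg`` (0 deg = +x) and retracts at ``retraction_speed``
    elsewhere.  Returns (mask stack, ground truth); the ground truth stores
    the true protruding arc length per frame.
    """
    _require(0 < arc_protruding <= 360, "arc_protruding must be in (0, 360]")
    _require(edge_speed >= 0 and retraction_speed >= 0, "speeds must be >= 0")
    H, W = shape
    total_retract = retraction_speed / 60.0 * frame_interval * (n_frames - 1)
    if total_retract >= radius:
        raise SyntheticDataError("retraction collapses the cell (self-intersection)")

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W]
    r_px = np.hypot(yy - cy, xx - cx)
    ang = np.arctan2(yy - cy, xx - cx)
    center = np.deg2rad(sector_center_deg)
    half = np.deg2rad(arc_protruding) / 2.0
    dang = np.angle(np.exp(1j * (ang - center)))
    in_sector = np.abs(dang) <= half

    masks = np.zeros((n_frames, H, W), dtype=bool)
    arc_lengths = np.empty(n_frames)
    for t in range(n_frames):
        minutes = frame_interval / 60.0 * t
        r_pro = radius + edge_speed * minutes
        r_ret = radius - retraction_speed * minutes
        r_map = np.where(in_sector, r_pro, r_ret) / pixel_size
        if np.max(r_map) >= min(cy, cx):
            raise SyntheticDataError("protrusion grows past the field of view")
        masks[t] = r_px <= r_map
        arc_lengths[t] = np.deg2rad(arc_protruding) * r_pro

    truth = GroundTruth(
        generator="synth_edge_movie",
        params={
            "arc_protruding": arc_protruding, "edge_speed": edge_speed,
            "retraction_speed": retraction_speed, "shape": list(shape),
            "pixel_size": pixel_size, "frame_interval": frame_interval,
            "n_frames": n_frames, "radius": radius,
            "sector_center_deg": sector_center_deg, "seed": seed,
        },
        truth={
            "protruding_arc_um": arc_lengths,
            "edge_speed": edge_speed,
            "retraction_speed": retraction_speed,
            "sector_center_deg": sector_center_deg,
        },
    )
    return masks, truth


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TCSPCParams:
    """Parameters of the synthetic TCSPC stack.

    Each pixel holds photon counts per time bin drawn from
    ``Poisson(A * exp(-t / tau) + background_rate)``, with ``tau`` equal to
    ``tau_quenched`` for a random fraction ``fraction_quenched`` of pixels
    and ``tau_donor`` elsewhere.
    """

    shape: tuple[int, int] = (32, 32)
    n_bins: int = 64
    bin_width: float = 0.2            # ns
    tau_donor: float = 4.0            # ns
    tau_quenched: float = 3.0         # ns
    fraction_quenched: float = 0.0
    photons_per_pixel: float = 1e4
    background_rate: float = 0.0      # counts/bin
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.tau_donor > 0 and self.tau_quenched > 0, "lifetimes must be positive")
        _require(self.tau_quenched <= self.tau_donor, "tau_quenched must be <= tau_donor")
        _require(0.0 <= self.fraction_quenched <= 1.0, "fraction_quenched in [0, 1]")
        _require(self.photons_per_pixel > 0, "photons_per_pixel must be positive")
        _require(self.background_rate >= 0, "background_rate must be >= 0")
        if self.n_bins * self.bin_width < 3.0 * self.tau_donor:
            raise SyntheticDataError(
                "time span must cover >= 3 x tau_donor (unfittable tail otherwise)"
            )


def expected_decay(tau: float, n_bins: int, bin_width: float,
                   total_photons: float, background_rate: float = 0.0) -> np.ndarray:
    """Noiseless expected counts per bin for a mono-exponential decay.

    The amplitude is chosen so the expected total (decay + background) equals
    ``total_photons``.
    """
    t = (np.arange(n_bins) + 0.5) * bin_width
    shape = np.exp(-t / tau)
    signal = total_photons - background_rate * n_bins
    _require(signal > 0, "background exceeds the photon budget")
    return signal * shape / shape.sum() + background_rate


def synth_tcspc(params: TCSPCParams) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize a TCSPC stack of shape (n_bins, H, W) with its true tau map."""
    H, W = params.shape
    rng = np.random.default_rng(params.seed)
    quenched = rng.random((H, W)) < params.fraction_quenched
    tau_map = np.where(quenched, params.tau_quenched, params.tau_donor)

    stack = np.empty((params.n_bins, H, W), dtype=np.int64)
    for tau in np.unique(tau_map):
        sel = tau_map == tau
        lam = expected_decay(tau, params.n_bins, params.bin_width,
                             params.photons_per_pixel, params.background_rate)
        stack[:, sel] = rng.poisson(lam[:, None], size=(params.n_bins, int(sel.sum())))

    truth = GroundTruth(
        generator="synth_tcspc",
        params=dataclasses.asdict(params),
        truth={
            "tau_map": tau_map,
            "quenched_mask": quenched,
            "true_efficiency": 1.0 - params.tau_quenched / params.tau_donor,
        },
    )
    return stack, truth
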