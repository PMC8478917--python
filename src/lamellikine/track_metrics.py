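"""Track-based migration statistics.

Implements interval-based speed and persistence measures for cell
trajectories: displacement sampling at a *usable time interval* ``delta_t``,
Mean Track Speed (MTS), Mean Track Persistence (MTP) over windows
``Delta_t = TR * delta_t``, the mean persistence profile, mean square
displacement, directionality ratio over time and direction autocorrelation.

Conventions
-----------
* Positions are in micrometres, times in minutes, everywhere after
  ingestion.  Pixel/frame conversion happens only in :func:`read_tracks`.
* Displacement intervals and persistence windows are non-overlapping and
  anchored at the first frame; trailing incomplete intervals/windows are
  discarded.
* MSD uses overlapping pairs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "PersistenceParams",
    "TrackStats",
    "TrackMetricsError",
    "read_tracks",
    "write_tracks",
    "read_fiji_manual_tracking",
    "interval_displacements",
    "mean_track_speed",
    "directionality_ratio",
    "mean_track_persistence",
    "usable_time_interval",
    "persistence_profile",
    "mean_square_displacement",
    "directionality_ratio_over_time",
    "direction_autocorrelation",
]


class TrackMetricsError(ValueError):
    """Raised for invalid tracks, parameters or undefined results."""


@dataclass(frozen=True)
class Track:
    """One cell's time-ordered positions in physical units.

    Parameters
    ----------
    cell_id : str
        Identifier of the tracked cell.
    times : ndarray, shape (n,)
        Time stamps in minutes, strictly increasing with uniform spacing.
    positions : ndarray, shape (n, 2)
        (x, y) coordinates in micrometres.
    """

    cell_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or len(times) < 2:
            raise TrackMetricsError(
                f"track {self.cell_id!r}: need >= 2 time points, got {times.size}"
            )
        if positions.shape != (len(times), 2):
            raise TrackMetricsError(
                f"track {self.cell_id!r}: positions shape {positions.shape} "
                f"does not match {len(times)} time points"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(positions))):
            raise TrackMetricsError(f"track {self.cell_id!r}: non-finite values")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise TrackMetricsError(f"track {self.cell_id!r}: times not strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise TrackMetricsError(f"track {self.cell_id!r}: non-uniform time spacing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    @property
    def frame_interval(self) -> float:
        """Spacing between consecutive time points, in minutes."""
        return float(self.times[1] - self.times[0])

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def transformed(self, scale: float = 1.0, rotation: float = 0.0,
                    offset: Sequence[float] = (0.0, 0.0)) -> "Track":
        """Return a rigidly transformed (and optionally scaled) copy."""
        c, s = np.cos(rotation), np.sin(rotation)
        rot = np.array([[c, -s], [s, c]])
        pos = scale * self.positions @ rot.T + np.asarray(offset, dtype=float)
        return Track(self.cell_id, self.times.copy(), pos)


@dataclass(frozen=True)
class PersistenceParams:
    """Parameters of the persistence computation.

    ``delta_t`` is the usable time interval (minutes; an integer multiple of
    the frame interval) and ``TR`` the Time Ratio, so the persistence window
    is ``Delta_t = TR * delta_t``.  ``alpha_mode`` selects the normalisation:
    ``"raw"`` reports the plain mean directionality ratio (a straight path
    already scores 1); ``"affine_rw"`` maps the score affinely so a straight
    path scores 1 and a pure random walk baseline scores 0.  The baseline is
    either a number in [0, 1] or ``"monte_carlo"``, in which case it is
    estimated by re-drawing the track's own step lengths with uniform random
    headings ``mc_reps`` times.
    """

    delta_t: float
    TR: int = 4
    alpha_mode: str = "raw"
    rw_baseline: float | str = "monte_carlo"
    mc_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_t <= 0:
            raise TrackMetricsError("delta_t must be positive")
        if int(self.TR) != self.TR or self.TR < 1:
            raise TrackMetricsError("TR must be an integer >= 1")
        if self.alpha_mode not in ("raw", "affine_rw"):
            raise TrackMetricsError(f"unknown alpha_mode {self.alpha_mode!r}")
        if isinstance(self.rw_baseline, str):
            if self.rw_baseline != "monte_carlo":
                raise TrackMetricsError("rw_baseline must be a number or 'monte_carlo'")
        elif not 0.0 <= float(self.rw_baseline) < 1.0:
            raise TrackMetricsError("numeric rw_baseline must lie in [0, 1)")

    @property
    def window_length(self) -> float:
        """The persistence window ``Delta_t = TR * delta_t``, in minutes."""
        return self.TR * self.delta_t


@dataclass
class TrackStats:
    """Per-track interval statistics."""

    cell_id: str
    displacements: np.ndarray        # d_n, um
    window_net: np.ndarray           # D_N, um
    window_path: np.ndarray          # sum of d_n per window, um
    mts: float                       # um/min
    mtp: float                       # dimensionless
    n_intervals: int = field(init=False)
    n_windows: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_intervals = len(self.displacements)
        self.n_windows = len(self.window_net)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = ["track_id", "frame", "x_px", "y_px"]


def _tracks_from_table(table: pd.DataFrame, frame_interval: float,
                       pixel_size: float) -> list[Track]:
    tracks: list[Track] = []
    for track_id, grp in table.groupby("track_id", sort=True):
        if grp.duplicated(subset="frame").any():
            raise TrackMetricsError(f"track {track_id!r}: duplicate (track, frame) rows")
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise TrackMetricsError(f"track {track_id!r}: missing frames within track")
        times = frames.astype(float) * frame_interval
        pos = grp[["x_px", "y_px"]].to_numpy(dtype=float) * pixel_size
        tracks.append(Track(str(track_id), times, pos))
    return tracks


def read_tracks(path, frame_interval: float, pixel_size: float) -> list[Track]:
    """Read the tracking-CSV dialect: header, columns (track_id, frame, x_px, y_px).

    Frames are 0-based and must be contiguous within a track.  Positions are
    converted from pixels to micrometres by ``pixel_size``.
    """
    if frame_interval <= 0 or pixel_size <= 0:
        raise TrackMetricsError("frame_interval and pixel_size must be positive")
    table = pd.read_csv(path)
    missing = [c for c in _CANONICAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrackMetricsError(f"missing columns {missing} in {path}")
    for col in ("frame", "x_px", "y_px"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            # +2: header line and 1-based file rows
            row = int(bad.idxmax()) + 2
            raise TrackMetricsError(f"non-numeric value in column {col!r} at file row {row}")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise TrackMetricsError(f"empty value in column {col!r} at file row {row}")
        table[col] = numeric
    return _tracks_from_table(table, frame_interval, pixel_size)


def write_tracks(tracks: Iterable[Track], path, pixel_size: float) -> None:
    """Write tracks in the canonical tracking-CSV dialect (inverse of read_tracks)."""
    rows = []
    for tr in tracks:
        frames = np.rint(tr.times / tr.frame_interval).astype(int)
        for f, (x, y) in zip(frames, tr.positions / pixel_size):
            rows.append((tr.cell_id, f, x, y))
    pd.DataFrame(rows, columns=_CANONICAL_COLUMNS).to_csv(path, index=False)


def read_fiji_manual_tracking(path, frame_interval: float, pixel_size: float) -> list[Track]:
    """Reader shim for the Fiji Manual Tracking export.

    Accepts the plugin's CSV (extra leading index column; columns
    ``Track n°``, ``Slice n°`` with 1-based slices, ``X``, ``Y``) and
    normalises it to the canonical 0-based dialect.  This shim is the only
    place 1-based frames exist.
    """
    raw = pd.read_csv(path)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key.startswith("track"):
            rename[col] = "track_id"
        elif key.startswith("slice"):
            rename[col] = "frame"
        elif key == "x":
            rename[col] = "x_px"
        elif key == "y":
            rename[col] = "y_px"
    raw = raw.rename(columns=rename)
    missing = [c for c in _CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise TrackMetricsError(f"missing columns {missing} in Fiji export {path}")
    table = raw[_CANONICAL_COLUMNS].copy()
    table["frame"] = table["frame"].astype(int) - 1
    buf = io.StringIO()
    table.to_csv(buf, index=False)
    buf.seek(0)
    return read_tracks(buf, frame_interval, pixel_size)


# ---------------------------------------------------------------------------
# Interval statistics
# ---------------------------------------------------------------------------

def _interval_multiple(track: Track, delta_t: float) -> int:
    k = delta_t / track.frame_interval
    if abs(k - round(k)) > 1e-9 * max(1.0, abs(k)):
        raise TrackMetricsError(
            f"delta_t={delta_t} is not an integer multiple of the frame "
            f"interval {track.frame_interval}"
        )
    return int(round(k))


def _sampled_positions(track: Track, delta_t: float) -> np.ndarray:
    """Positions decimated to delta_t spacing, anchored at the first frame."""
    k = _interval_multiple(track, delta_t)
    return track.positions[::k]


def interval_displacements(track: Track, delta_t: float) -> np.ndarray:
    """Non-overlapping consecutive displacement magnitudes ``d_n`` at ``delta_t``.

    The displacement ``d_n = |p_{nk+k} - p_{nk}|`` where ``k`` is the number
    of frames per interval.  Trailing remainder frames are discarded.
    """
    sampled = _sampled_positions(track, delta_t)
    if len(sampled) < 2:
        return np.empty(0)
    return np.linalg.norm(np.diff(sampled, axis=0), axis=1)


def mean_track_speed(track: Track, delta_t: float) -> float:
    """Mean Track Speed: average of ``d_n / delta_t`` over the whole track (um/min)."""
    d = interval_displacements(track, delta_t)
    if len(d) == 0:
        raise TrackMetricsError(
            f"track {track.cell_id!r}: no complete interval of {delta_t} min"
        )
    return float(np.mean(d)) / delta_t


def directionality_ratio(window_positions: np.ndarray) -> float:
    """Directionality ratio of one window: net displacement / path length.

    ``window_positions`` are the sampled points of one persistence window,
    shape (TR + 1, 2).  By convention a window with zero path length scores 1
    (a cell that never moved made no directional errors).
    """
    window_positions = np.asarray(window_positions, dtype=float)
    if window_positions.ndim != 2 or len(window_positions) < 2:
        raise TrackMetricsError("window must contain >= 2 sampled points")
    steps = np.linalg.norm(np.diff(window_positions, axis=0), axis=1)
    path = float(steps.sum())
    if path == 0.0:
        return 1.0
    net = float(np.linalg.norm(window_positions[-1] - window_positions[0]))
    return net / path


def _window_ratios(track: Track, delta_t: float, TR: int) -> np.ndarray:
    sampled = _sampled_positions(track, delta_t)
    n_windows = (len(sampled) - 1) // TR
    if n_windows < 1:
        raise TrackMetricsError(
            f"track {track.cell_id!r}: no complete window of {TR}x{delta_t} min"
        )
    return np.array([
        directionality_ratio(sampled[i * TR:(i + 1) * TR + 1])
        for i in range(n_windows)
    ])


def _monte_carlo_baseline(d_n: np.ndarray, TR: int, mc_reps: int,
                          seed: int) -> float:
    """Mean DR of random walks built from the track's own step lengths.

    Each replicate re-draws headings uniformly and shuffles the step-length
    sequence, then applies the same non-overlapping windowing.
    """
    rng = np.random.default_rng(seed)
    n_windows = len(d_n) // TR
    usable = d_n[: n_windows * TR]
    ratios = np.empty(mc_reps)
    for r in range(mc_reps):
        steps = rng.permutation(usable)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=len(steps))
        vec = steps[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(vec, axis=0)])
        ratios[r] = np.mean([
            directionality_ratio(pos[i * TR:(i + 1) * TR + 1])
            for i in range(n_windows)
        ])
    return float(ratios.mean())


def mean_track_persistence(track: Track, params: PersistenceParams) -> float:
    """Mean Track Persistence: normalised mean directionality ratio over windows.

    Windows span ``Delta_t = TR * delta_t``, are consecutive and
    non-overlapping; an incomplete final window is discarded.  In
    ``alpha_mode="raw"`` the raw mean DR is returned (alpha = 1).  In
    ``alpha_mode="affine_rw"`` the score is mapped affinely so that a
    straight path scores exactly 1 and the random-walk baseline scores 0.
    """
    ratios = _window_ratios(track, params.delta_t, params.TR)
    raw = float(ratios.mean())
    if params.alpha_mode == "raw":
        return raw
    if params.rw_baseline == "monte_carlo":
        d_n = interval_displacements(track, params.delta_t)
        baseline = _monte_carlo_baseline(d_n, params.TR, params.mc_reps, params.seed)
    else:
        baseline = float(params.rw_baseline)
    if baseline >= 1.0:
        raise TrackMetricsError("random-walk baseline >= 1; affine map undefined")
    return (raw - baseline) / (1.0 - baseline)


def track_stats(track: Track, params: PersistenceParams) -> TrackStats:
    """Convenience bundle of d_n, D_N, MTS and MTP for one track."""
    d_n = interval_displacements(track, params.delta_t)
    sampled = _sampled_positions(track, params.delta_t)
    n_windows = (len(sampled) - 1) // params.TR
    net = np.array([
        np.linalg.norm(sampled[(i + 1) * params.TR] - sampled[i * params.TR])
        for i in range(n_windows)
    ])
    path = np.array([
        d_n[i * params.TR:(i + 1) * params.TR].sum() for i in range(n_windows)
    ])
    return TrackStats(
        cell_id=track.cell_id,
        displacements=d_n,
        window_net=net,
        window_path=path,
        mts=mean_track_speed(track, params.delta_t),
        mtp=mean_track_persistence(track, params),
    )


# ---------------------------------------------------------------------------
# Usable time interval
# ---------------------------------------------------------------------------

def usable_time_interval(
    replicates: Sequence[Track],
    threshold: float = 0.10,
    candidate_multiples: Sequence[int] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Smallest displacement-sampling multiple at which positional error is small.

    The per-coordinate positional error is the RMS deviation of replicate
    coordinates about their per-time-point mean; the error of a displacement
    measurement (a difference of two noisy points) is ``sqrt(2)`` times that.
    For each candidate multiple ``k`` the ratio of this error scale to the
    mean displacement ``d_n`` at ``delta_t = k * frame_interval`` is computed;
    the smallest ``k`` with ratio below ``threshold`` is returned together
    with the full diagnostic table (columns: k, delta_t, mean_dn, error,
    ratio, accepted).
    """
    if len(replicates) < 2:
        raise TrackMetricsError("need >= 2 replicate tracks")
    t0 = replicates[0].times
    for tr in replicates[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
            raise TrackMetricsError("replicates must share timestamps")
    if candidate_multiples is None:
        candidate_multiples = range(1, 11)
    candidates = sorted(int(k) for k in candidate_multiples)
    if not candidates or candidates[0] < 1:
        raise TrackMetricsError("candidate multiples must be positive integers")

    stack = np.stack([tr.positions for tr in replicates])      # (R, T, 2)
    dev = stack - stack.mean(axis=0, keepdims=True)
    # per-time-point RMS over replicates and coordinates, then mean over time
    sigma_coord = float(np.mean(np.sqrt(np.mean(dev ** 2, axis=(0, 2)))))
    error_scale = np.sqrt(2.0) * sigma_coord

    fi = replicates[0].frame_interval
    rows = []
    chosen = None
    for k in candidates:
        dt = k * fi
        d_all = np.concatenate([
            interval_displacements(tr, dt) for tr in replicates
        ])
        if len(d_all) == 0:
            rows.append((k, dt, np.nan, error_scale, np.inf, False))
            continue
        mean_d = float(d_all.mean())
        ratio = error_scale / mean_d if mean_d > 0 else np.inf
        ok = ratio < threshold
        rows.append((k, dt, mean_d, error_scale, ratio, ok))
        if ok and chosen is None:
            chosen = dt
    table = pd.DataFrame(
        rows, columns=["k", "delta_t", "mean_dn", "error", "ratio", "accepted"]
    )
    if chosen is None:
        raise TrackMetricsError(
            "no candidate multiple satisfies the error threshold; ratio table:\n"
            + table.to_string(index=False)
        )
    return chosen, table


# ---------------------------------------------------------------------------
# Population curves
# ---------------------------------------------------------------------------

def persistence_profile(
    tracks: Sequence[Track],
    TR: int,
    delta_t_grid: Sequence[float],
    alpha_mode: str = "raw",
    rw_baseline: float | str = "monte_carlo",
    mc_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Population-mean MTP for each ``delta_t`` in the grid, at fixed TR.

    Tracks lacking a complete window at a given ``delta_t`` are excluded there;
    exclusion counts are reported.  Columns: delta_t, mean_mtp, n_tracks,
    n_excluded.
    """
    if len(delta_t_grid) == 0:
        raise TrackMetricsError("empty delta_t grid")
    rows = []
    for dt in delta_t_grid:
        values = []
        excluded = 0
        for tr in tracks:
            try:
                params = PersistenceParams(
                    delta_t=dt, TR=TR, alpha_mode=alpha_mode,
                    rw_baseline=rw_baseline, mc_reps=mc_reps, seed=seed,
                )
                values.append(mean_track_persistence(tr, params))
            except TrackMetricsError:
                excluded += 1
        if not values:
            raise TrackMetricsError(f"delta_t={dt}: no track has a complete window")
        rows.append((dt, float(np.mean(values)), len(values), excluded))
    return pd.DataFrame(rows, columns=["delta_t", "mean_mtp", "n_tracks", "n_excluded"])


def mean_square_displacement(
    tracks: Sequence[Track],
    max_lag: int,
    slope_lags: tuple[int, int] = (1, 10),
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """MSD versus lag using overlapping pairs.

    Returns (population table with columns lag, time, msd, n_pairs;
    per-track MSD matrix of shape (n_tracks, max_lag); log-log slope fitted
    over the inclusive lag range ``slope_lags``).
    """
    if any(max_lag >= tr.n_frames for tr in tracks):
        raise TrackMetricsError("max_lag must be smaller than the shortest track")
    per_track = np.full((len(tracks), max_lag), np.nan)
    counts = np.zeros(max_lag, dtype=int)
    sums = np.zeros(max_lag)
    for i, tr in enumerate(tracks):
        for lag in range(1, max_lag + 1):
            sq = np.sum((tr.positions[lag:] - tr.positions[:-lag]) ** 2, axis=1)
            per_track[i, lag - 1] = sq.mean()
            sums[lag - 1] += sq.sum()
            counts[lag - 1] += len(sq)
    lags = np.arange(1, max_lag + 1)
    fi = tracks[0].frame_interval
    pop = pd.DataFrame({
        "lag": lags,
        "time": lags * fi,
        "msd": sums / counts,
        "n_pairs": counts,
    })
    lo, hi = slope_lags
    sel = (pop["lag"] >= lo) & (pop["lag"] <= hi) & (pop["msd"] > 0)
    if sel.sum() >= 2:
        slope = float(np.polyfit(np.log(pop.loc[sel, "lag"]),
                                 np.log(pop.loc[sel, "msd"]), 1)[0])
    else:
        slope = np.nan
    return pop, per_track, slope


def directionality_ratio_over_time(tracks: Sequence[Track]) -> pd.DataFrame:
    """Mean of (net displacement from origin / cumulative path length) per time.

    Uses every frame; population mean at each elapsed time over the tracks
    still long enough.  Columns: time, mean_ratio, n_tracks.
    """
    n_steps = max(tr.n_frames for tr in tracks) - 1
    fi = tracks[0].frame_interval
    rows = []
    for step in range(1, n_steps + 1):
        vals = []
        for tr in tracks:
            if step >= tr.n_frames:
                continue
            seg = tr.positions[: step + 1]
            path = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
            net = float(np.linalg.norm(seg[-1] - seg[0]))
            vals.append(1.0 if path == 0 else net / path)
        rows.append((step * fi, float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["time", "mean_ratio", "n_tracks"])


def direction_autocorrelation(
    tracks: Sequence[Track],
    delta_t: float,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Mean cosine between displacement directions at increasing lag.

    Displacements are sampled at ``delta_t`` exactly as in
    :func:`interval_displacements`; zero-length displacements are skipped and
    their count reported.  Columns: lag, autocorr, n_pairs, n_skipped.
    """
    unit_vectors = []
    skipped = 0
    for tr in tracks:
        sampled = _sampled_positions(tr, delta_t)
        vec = np.diff(sampled, axis=0)
        norm = np.linalg.norm(vec, axis=1)
        keep = norm > 0
        skipped += int(np.sum(~keep))
        uv = np.full_like(vec, np.nan)
        uv[keep] = vec[keep] / norm[keep, None]
        unit_vectors.append(uv)
    n_max = max(len(uv) for uv in unit_vectors)
    if max_lag is None:
        max_lag = n_max - 1
    if all(np.all(np.isnan(uv)) for uv in unit_vectors):
        raise TrackMetricsError("all displacements have zero length")
    rows = []
    for lag in range(1, max_lag + 1):
        cosines = []
        for uv in unit_vectors:
            if lag >= len(uv):
                continue
            dots = np.sum(uv[lag:] * uv[:-lag], axis=1)
            cosines.append(dots[np.isfinite(dots)])
        all_cos = np.concatenate(cosines) if cosines else np.empty(0)
        rows.append((lag, float(all_cos.mean()) if len(all_cos) else np.nan,
                     len(all_cos), skipped))
    return pd.DataFrame(rows, columns=["lag", "autocorr", "n_pairs", "n_skipped"])
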