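"""Synthetic swarm time-lapse generator with ground truth.

Generates movies that emulate the statistical structure of the tdTomato
channel of a developing *Myxococcus xanthus* swarm imaged at 1 frame/min:

* a sparse population of labeled gliding rods that move along their body
  axis and reverse direction with exponential waiting times;
* stream lanes — elongated regions where rods align to the lane tangent,
  reverse less often, and where the unlabeled majority population shows up
  as an elevated, anisotropic, co-moving background texture;
* nascent aggregates — compact disks where rods stall and intensity ramps
  up over ~10 frames.

Every movie carries exact ground truth (per-frame stream masks, aggregate
events, full tracks) so each downstream analysis stage can be validated.
Lane recruitment is kinematic (orientation snapping); no rod-rod collision
forces are modeled — the target is the statistics the detector assumes,
not swarm physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .stack import ImageStack

__all__ = [
    "StreamLane",
    "AggregateSpec",
    "SwarmConfig",
    "SyntheticMovie",
    "simulate_swarm",
    "render_frame",
    "default_stream_lanes",
    "default_aggregate_events",
]


@dataclass
class StreamLane:
    """A stream lane: centerline polyline (px), full width (px), active span."""

    polyline: list[tuple[float, float]]
    width_px: float
    onset_frame: int
    end_frame: int


@dataclass
class AggregateSpec:
    """A nascent aggregate: center (x, y) px, radius px, onset frame."""

    center_px: tuple[float, float]
    radius_px: float
    onset_frame: int


@dataclass
class SwarmConfig:
    """Parameters of one synthetic movie.

    Defaults follow the study conditions the pipeline assumes: 400 px crops,
    1 frame/min, ~5 h movies, gliding speed ~3 um/min and reversals every
    ~8 min, 7 x 0.7 um rods rendered on a 16-bit background.
    """

    image_size: int = 400
    um_per_px: float = 0.65
    frame_interval_min: float = 1.0
    n_frames: int = 310
    n_cells: int = 400
    cell_length_um: float = 7.0
    cell_width_um: float = 0.7
    speed_um_per_min: float = 3.0
    reversal_period_min: float = 8.0
    scenario: str = "random"  # random | streams | streams_then_aggregates | aggregates_only
    stream_lanes: list[StreamLane] = field(default_factory=list)
    aggregate_events: list[AggregateSpec] = field(default_factory=list)
    # rendering
    background_level: float = 500.0
    cell_amplitude: float = 4000.0
    lane_boost: float = 900.0
    lane_texture_amp: float = 450.0
    aggregate_amplitude: float = 15000.0
    aggregate_ramp_frames: int = 10
    # motion
    pre_stream_speed_factor: float = 0.3
    orientation_jitter_rad: float = 0.12
    lane_jitter_rad: float = 0.06
    lane_reversal_factor: float = 0.2
    noise_sd: float = 40.0
    rng_seed: int = 0

    _SCENARIOS = ("random", "streams", "streams_then_aggregates", "aggregates_only")

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.n_frames < 35:
            raise ValueError(
                "n_frames must be >= 35 (one 30-frame analysis window plus a "
                "5-frame persistence window)"
            )
        if self.scenario not in self._SCENARIOS:
            raise ValueError(f"scenario must be one of {self._SCENARIOS}")
        if self.scenario in ("streams", "streams_then_aggregates") and not self.stream_lanes:
            self.stream_lanes = default_stream_lanes(self.image_size, self.n_frames)
        if self.scenario in ("streams_then_aggregates", "aggregates_only") and not self.aggregate_events:
            onset = 0 if self.scenario == "aggregates_only" else int(0.75 * self.n_frames)
            self.aggregate_events = default_aggregate_events(self.image_size, onset)
        for lane in self.stream_lanes:
            for x, y in lane.polyline:
                if not (0 <= x <= self.image_size and 0 <= y <= self.image_size):
                    raise ValueError("lane polyline vertex outside the frame")
            if lane.onset_frame >= self.n_frames:
                raise ValueError("lane onset frame beyond movie end")
        for agg in self.aggregate_events:
            x, y = agg.center_px
            r = agg.radius_px
            if not (0 <= x - r and x + r <= self.image_size and 0 <= y - r and y + r <= self.image_size):
                raise ValueError("aggregate disk extends outside the frame")
            if agg.onset_frame >= self.n_frames:
                raise ValueError("aggregate onset frame beyond movie end")

    @property
    def speed_px_per_frame(self) -> float:
        return self.speed_um_per_min * self.frame_interval_min / self.um_per_px

    @property
    def cell_length_px(self) -> float:
        return self.cell_length_um / self.um_per_px

    @property
    def cell_width_px(self) -> float:
        return self.cell_width_um / self.um_per_px

    def to_dict(self) -> dict:
        return asdict(self)


def default_stream_lanes(image_size: int, n_frames: int) -> list[StreamLane]:
    """Three parallel lanes spanning the frame, ~10% of the frame wide each.

    Combined they cover roughly a third of the field of view, comparable to
    the stream coverage a swarm reaches at the height of the stream phase.
    Lanes switch on after an initial dispersed phase and stay active for
    most of the movie.
    """
    s = image_size
    onset = max(0, n_frames // 6)
    end = int(0.9 * n_frames)
    width = 0.10 * s
    lanes = []
    for frac in (0.25, 0.52, 0.78):
        y = frac * s
        lanes.append(StreamLane([(0.0, y), (float(s), y)], width, onset, end))
    return lanes


def default_aggregate_events(image_size: int, onset_frame: int) -> list[AggregateSpec]:
    s = image_size
    r = 0.045 * s
    return [
        AggregateSpec((0.32 * s, 0.36 * s), r, onset_frame),
        AggregateSpec((0.70 * s, 0.66 * s), r, min(onset_frame + 15, onset_frame + 15)),
    ]


@dataclass
class SyntheticMovie:
    """A rendered movie plus the exact ground truth it was built from."""

    stack: ImageStack
    truth_stream_masks: np.ndarray  # (T, H, W) bool
    truth_aggregate_events: list[AggregateSpec]
    tracks: pd.DataFrame  # cell_id, frame, x_px, y_px, orientation_rad
    config: SwarmConfig

    def write(self, out_dir: str | Path) -> None:
        """Write movie TIFF, per-frame truth-mask PNGs, track CSV, config JSON."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.stack.save_tiff(out / "movie.tif")
        mask_dir = out / "truth_masks"
        mask_dir.mkdir(exist_ok=True)
        for t in range(self.truth_stream_masks.shape[0]):
            iio.imwrite(
                mask_dir / f"stream_{t:04d}.png",
                (self.truth_stream_masks[t] * 255).astype(np.uint8),
            )
        self.tracks.to_csv(out / "tracks.csv", index=False)
        cfg = self.config.to_dict()
        (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))


# ---------------------------------------------------------------------------
# lane geometry


def _polyline_uv(polyline: np.ndarray, shape: tuple[int, int]):
    """Arclength coordinate U, signed perpendicular distance V, and tangent
    angle of the nearest polyline segment, per pixel."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    best_d2 = np.full((h, w), np.inf)
    U = np.zeros((h, w))
    V = np.zeros((h, w))
    tang = np.zeros((h, w))
    arclen = 0.0
    for (x0, y0), (x1, y1) in zip(polyline[:-1], polyline[1:]):
        dx, dy = x1 - x0, y1 - y0
        seg_len = float(np.hypot(dx, dy))
        if seg_len == 0:
            continue
        tx, ty = dx / seg_len, dy / seg_len
        px, py = xx - x0, yy - y0
        t = np.clip(px * tx + py * ty, 0.0, seg_len)
        cx, cy = x0 + t * tx, y0 + t * ty
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        U[closer] = (arclen + t)[closer]
        # signed distance: positive on the left of the tangent
        V[closer] = ((xx - cx) * (-ty) + (yy - cy) * tx)[closer]
        tang[closer] = np.arctan2(dy, dx)
        arclen += seg_len
    return U, V, tang, np.sqrt(best_d2)


def lane_mask(lane: StreamLane, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of a lane's interior (distance to centerline <= width/2)."""
    poly = np.asarray(lane.polyline, dtype=float)
    _, _, _, dist = _polyline_uv(poly, shape)
    return dist <= lane.width_px / 2.0


class _LaneField:
    """Precomputed rasters and drifting texture for one lane."""

    def __init__(self, lane: StreamLane, config: SwarmConfig, rng: np.random.Generator):
        self.lane = lane
        shape = (config.image_size, config.image_size)
        poly = np.asarray(lane.polyline, dtype=float)
        U, V, tang, dist = _polyline_uv(poly, shape)
        self.mask = dist <= lane.width_px / 2.0
        self.tangent = tang
        half = lane.width_px / 2.0
        active_frames = max(1, lane.end_frame - lane.onset_frame)
        total_len = float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
        drift = config.speed_px_per_frame
        n_u = int(np.ceil(total_len + drift * active_frames)) + 8
        n_v = int(np.ceil(lane.width_px)) + 4
        # anisotropic co-moving texture: long correlation along the lane,
        # short across it — dim aligned unlabeled cells streaming past
        tex = rng.standard_normal((n_u, n_v))
        tex = gaussian_filter(tex, sigma=(8.0, 1.2), mode="wrap")
        tex /= tex.std() + 1e-12
        self.texture = tex
        self._U = U
        self._V = V + half + 2.0
        self._drift = drift
        self._n_u = n_u

    def active(self, frame: int) -> bool:
        return self.lane.onset_frame <= frame <= self.lane.end_frame

    def background(self, frame: int, config: SwarmConfig) -> np.ndarray:
        """Additive background contribution of this lane at a frame."""
        out = np.zeros(self.mask.shape, dtype=np.float64)
        if not self.active(frame):
            return out
        u = (self._U[self.mask] - self._drift * (frame - self.lane.onset_frame)) % self._n_u
        v = np.clip(self._V[self.mask], 0, self.texture.shape[1] - 1)
        vals = map_coordinates(self.texture, [u, v], order=1, mode="wrap")
        out[self.mask] = config.lane_boost + config.lane_texture_amp * vals
        return out


# ---------------------------------------------------------------------------
# rendering


def _rod_kernel_params(config: SwarmConfig) -> tuple[float, float, int]:
    sigma_long = config.cell_length_px / 4.0
    sigma_short = max(config.cell_width_px / 4.0, 0.4)
    half = int(np.ceil(2.5 * sigma_long)) + 1
    return sigma_long, sigma_short, half


def render_frame(
    agent_states: np.ndarray,
    background_field: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame: anisotropic rod kernels over a background field.

    ``agent_states`` is an (N, 3) array of columns (x_px, y_px,
    orientation_rad). Each rod is an anisotropic Gaussian of length
    ``cell_length_px`` and width ``cell_width_px`` aligned with its
    orientation, added to the background; Gaussian noise (sd ``noise_sd``,
    truncated at 0) is added last and the result clipped to uint16 range.
    Agents partially outside the frame are clipped, not an error.
    """
    frame = np.asarray(background_field, dtype=np.float64).copy()
    h, w = frame.shape
    sigma_l, sigma_s, half = _rod_kernel_params(config)
    states = np.atleast_2d(np.asarray(agent_states, dtype=float))
    if states.size:
        for x, y, phi in states:
            cx, cy = int(round(x)), int(round(y))
            x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
            y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
            if x0 >= x1 or y0 >= y1:
                continue
            ys, xs = np.mgrid[y0:y1, x0:x1]
            dx, dy = xs - x, ys - y
            u = dx * np.cos(phi) + dy * np.sin(phi)
            v = -dx * np.sin(phi) + dy * np.cos(phi)
            frame[y0:y1, x0:x1] += config.cell_amplitude * np.exp(
                -(u**2 / (2 * sigma_l**2) + v**2 / (2 * sigma_s**2))
            )
    if config.noise_sd > 0 and rng is not None:
        frame += rng.normal(0.0, config.noise_sd, size=frame.shape)
    return np.clip(frame, 0, np.iinfo(np.uint16).max).astype(np.uint16)


# ---------------------------------------------------------------------------
# simulation


def _aggregate_disk(agg: AggregateSpec, shape: tuple[int, int]) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - agg.center_px[0]) ** 2 + (yy - agg.center_px[1]) ** 2 <= agg.radius_px**2


def simulate_swarm(config: SwarmConfig) -> SyntheticMovie:
    """Run the agent simulation and render the movie.

    Deterministic given ``config.rng_seed``: identical configs produce
    bit-identical movies, truth masks and tracks.
    """
    rng = np.random.default_rng(config.rng_seed)
    s = config.image_size
    shape = (s, s)
    lanes = [_LaneField(lane, config, rng) for lane in config.stream_lanes]
    agg_disks = [_aggregate_disk(a, shape) for a in config.aggregate_events]

    # a movie with no background left would starve the threshold optimizers
    occupied = np.zeros(shape, dtype=bool)
    for lf in lanes:
        occupied |= lf.mask
    for d in agg_disks:
        occupied |= d
    if occupied.all():
        raise ValueError(
            "lane and aggregate geometry covers the whole frame; "
            "threshold optimization needs a background region"
        )

    n = config.n_cells
    x = rng.uniform(0, s - 1, n)
    y = rng.uniform(0, s - 1, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    step = config.speed_px_per_frame
    # dispersed pre-stream rods glide slowly; the swarm speeds up when
    # streams switch on
    first_onset = min((l.onset_frame for l in config.stream_lanes), default=0)
    p_rev = 1.0 - np.exp(-config.frame_interval_min / config.reversal_period_min)

    frames = np.empty((config.n_frames, s, s), dtype=np.uint16)
    truth = np.zeros((config.n_frames, s, s), dtype=bool)
    track_rows = np.empty((config.n_frames * n, 5), dtype=np.float64)

    base = np.full(shape, config.background_level, dtype=np.float64)
    for t in range(config.n_frames):
        background = base.copy()
        for lf in lanes:
            background += lf.background(t, config)
            if lf.active(t):
                truth[t] |= lf.mask
        stalled = np.zeros(n, dtype=bool)
        for agg, disk in zip(config.aggregate_events, agg_disks):
            if t >= agg.onset_frame:
                ramp = min(1.0, (t - agg.onset_frame + 1) / config.aggregate_ramp_frames)
                background[disk] += ramp * config.aggregate_amplitude
                d2 = (x - agg.center_px[0]) ** 2 + (y - agg.center_px[1]) ** 2
                stalled |= d2 <= agg.radius_px**2

        ix = np.clip(np.round(x).astype(int), 0, s - 1)
        iy = np.clip(np.round(y).astype(int), 0, s - 1)
        in_lane = np.zeros(n, dtype=bool)
        lane_tangent = np.zeros(n)
        for lf in lanes:
            if lf.active(t):
                hit = lf.mask[iy, ix] & ~in_lane
                in_lane |= hit
                lane_tangent[hit] = lf.tangent[iy[hit], ix[hit]]

        # nematic snapping: adopt the lane tangent in the direction closer
        # to the current heading, with reduced jitter and reversal rate
        if in_lane.any():
            tgt = lane_tangent[in_lane]
            cur = phi[in_lane]
            flip = np.cos(cur - tgt) < 0
            tgt = np.where(flip, tgt + np.pi, tgt)
            phi[in_lane] = tgt + rng.normal(0, config.lane_jitter_rad, int(in_lane.sum()))
        jitter = rng.normal(0, config.orientation_jitter_rad, n)
        phi[~in_lane] += jitter[~in_lane]

        rev_draw = rng.uniform(0, 1, n)
        p = np.where(in_lane, p_rev * config.lane_reversal_factor, p_rev)
        phi = np.where(rev_draw < p, phi + np.pi, phi)

        states = np.column_stack([x, y, phi])
        frames[t] = render_frame(states, background, config, rng)
        track_rows[t * n : (t + 1) * n, 0] = np.arange(n)
        track_rows[t * n : (t + 1) * n, 1] = t
        track_rows[t * n : (t + 1) * n, 2] = x
        track_rows[t * n : (t + 1) * n, 3] = y
        track_rows[t * n : (t + 1) * n, 4] = phi % (2 * np.pi)

        step_t = step * (config.pre_stream_speed_factor if t < first_onset else 1.0)
        move = np.where(stalled, 0.0, step_t)
        x = x + move * np.cos(phi)
        y = y + move * np.sin(phi)
        # reflect at the frame boundary, reversing the bounced component
        bounce_x = (x < 0) | (x > s - 1)
        bounce_y = (y < 0) | (y > s - 1)
        x = np.clip(np.where(bounce_x, np.where(x < 0, -x, 2 * (s - 1) - x), x), 0, s - 1)
        y = np.clip(np.where(bounce_y, np.where(y < 0, -y, 2 * (s - 1) - y), y), 0, s - 1)
        phi = np.where(bounce_x, np.pi - phi, phi)
        phi = np.where(bounce_y, -phi, phi)

    tracks = pd.DataFrame(
        track_rows, columns=["cell_id", "frame", "x_px", "y_px", "orientation_rad"]
    )
    tracks["cell_id"] = tracks["cell_id"].astype(int)
    tracks["frame"] = tracks["frame"].astype(int)

    stack = ImageStack(
        frames, frame_interval_min=config.frame_interval_min, um_per_px=config.um_per_px
    )
    return SyntheticMovie(
        stack=stack,
        truth_stream_masks=truth,
        truth_aggregate_events=list(config.aggregate_events),
        tracks=tracks,
        config=config,
    )
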