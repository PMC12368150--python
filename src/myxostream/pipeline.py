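"""End-to-end orchestration: movie -> stream masks -> aggregate statistics.

The pipeline chains the library stages in the order the analysis assumes:
(optional) simulation -> persistence imaging -> (optional) threshold
optimization on calibration frames -> stream-mask series -> aggregate
detection -> band/outside stream proportions -> track displacement
summary. Every run writes a JSON manifest with all parameters so a rerun
with the same config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregates import detect_aggregates, make_partition, paired_comparison, stream_proportions
from .features import density_field, local_orientation, optical_flow_speed, order_parameter
from .masks import ThresholdSet, fov_percentage, stream_series
from .persistence import equalize, make_windows, persistence_stack
from .stack import ImageStack
from .synthetic import SwarmConfig, simulate_swarm
from .tracks import displacement_summary, read_tracks

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "optimize_thresholds"]


@dataclass
class PipelineConfig:
    """Inputs and parameters of one pipeline run.

    Exactly one of ``movie_path`` and ``simulation`` must be given.
    ``thresholds`` may be supplied directly; otherwise they are optimized
    on calibration frames drawn from the movie itself.
    """

    out_dir: str | Path = "pipeline_out"
    movie_path: str | Path | None = None
    simulation: SwarmConfig | None = None
    tracks_path: str | Path | None = None
    thresholds: ThresholdSet | None = None
    persistence_window: int = 5
    analysis_window: int = 30
    stride_min: float = 5.0
    calibration_frames: list[int] | None = None  # persistence-frame indices
    agg_intensity_min: float = 0.98
    agg_area_min_px: int = 150  # aggregates are compact disks, not streak clusters
    agg_persistence_frames: int = 10
    band_dilation_px: int = 20
    stream_lead_min: float = 15.0
    flow_radius: int = 7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if (self.movie_path is None) == (self.simulation is None):
            raise ValueError("supply exactly one of movie_path or simulation")


def optimize_thresholds(
    pstack, calibration_indices: list[int], aggregate_indices: list[int] | None = None,
    flow_radius: int = 7,
) -> ThresholdSet:
    """Optimize a full ThresholdSet on calibration persistence frames.

    Speed and alignment sweeps use stream-phase frames; the density upper
    bound uses aggregate-containing frames when available, otherwise it is
    left permissive (1.1, above the equalized-intensity range).
    """
    from .optimize import optimize_density, sweep_alignment, sweep_speed

    speed_fields, align_fields, density_fields = [], [], []
    shape = pstack.frames.shape[1:]
    for idx in calibration_indices:
        a, b = pstack.frames[idx], pstack.frames[min(idx + 1, len(pstack) - 1)]
        speed_fields.append(optical_flow_speed(a, b, radius=flow_radius).magnitude)
        align_fields.append(order_parameter(local_orientation(a), out_shape=shape).S)
        density_fields.append(density_field(a).rho)
    speed = sweep_speed(speed_fields)
    align = sweep_alignment(align_fields)
    if aggregate_indices:
        agg_fields = [density_field(pstack.frames[i]).rho for i in aggregate_indices]
        from .optimize import optimize_density as _od

        density_min, density_max = _od(density_fields, agg_fields)
    else:
        from .optimize import _after_drop

        grid = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 10)
        lows = [v for f in density_fields if (v := _after_drop(f, grid, 1.0)) is not None]
        density_min = float(np.mean(lows)) if lows else 0.05
        density_max = 1.1
    return ThresholdSet(
        speed_min=speed.chosen,
        align_min=align.chosen,
        density_min=density_min,
        density_max=density_max,
    )


def _nearest_window_index(timestamps: np.ndarray, target_min: float) -> int:
    return int(np.argmin(np.abs(timestamps - target_min)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the report bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "rng_seed": config.rng_seed}

    movie = None
    if config.simulation is not None:
        movie = simulate_swarm(config.simulation)
        stack = movie.stack
        manifest["input"] = {"simulation": config.simulation.to_dict()}
    else:
        stack = ImageStack.from_tiff(config.movie_path)
        manifest["input"] = {"movie_path": str(config.movie_path)}

    pstack = equalize(persistence_stack(stack, config.persistence_window))
    windows = make_windows(pstack, config.analysis_window, config.stride_min)

    thresholds = config.thresholds
    if thresholds is None:
        cal = config.calibration_frames
        if cal is None:
            # default calibration: three frames from the middle of the movie,
            # where streams (if any) are active
            mid = len(pstack) // 2
            cal = [max(0, mid - 10), mid, min(len(pstack) - 2, mid + 10)]
        thresholds = optimize_thresholds(pstack, cal, flow_radius=config.flow_radius)
    manifest["thresholds"] = thresholds.to_dict()
    manifest["analysis"] = {
        "persistence_window": config.persistence_window,
        "analysis_window": config.analysis_window,
        "stride_min": config.stride_min,
        "n_windows": len(windows),
        "flow_radius": config.flow_radius,
    }

    series = stream_series(pstack, windows, thresholds, flow_radius=config.flow_radius)
    fov_df = pd.DataFrame(
        {
            "timestamp_min": series.timestamps_min,
            "fov_percent_speed": series.fov_percent_speed,
            "fov_percent_align": series.fov_percent_align,
            "fov_percent_density": series.fov_percent_density,
            "fov_percent_stream": series.fov_percent,
        }
    )
    fov_df.to_csv(out / "fov_series.csv", index=False)
    manifest["peak_stream_time_min"] = series.peak_time_min
    manifest["peak_stream_fov_percent"] = float(series.fov_percent.max())

    events = detect_aggregates(
        pstack.frames,
        intensity_min=config.agg_intensity_min,
        area_min_px=config.agg_area_min_px,
        persistence_min_frames=config.agg_persistence_frames,
        frame_interval_min=pstack.frame_interval_min,
    )
    # onset reported in absolute movie time (persistence frame 0 is centered
    # on input frame window_len//2)
    for ev in events:
        ev.onset_min = pstack.time_min(ev.onset_frame)
    ev_rows = [
        {
            "focal_id": i,
            "onset_min": ev.onset_min,
            "area_px": ev.area_px,
            "centroid_x_px": ev.centroid_px[0],
            "centroid_y_px": ev.centroid_px[1],
        }
        for i, ev in enumerate(events)
    ]
    pd.DataFrame(ev_rows).to_csv(out / "aggregate_events.csv", index=False)
    manifest["n_aggregates"] = len(events)
    if events:
        manifest["first_aggregate_onset_min"] = float(events[0].onset_min)

    prop_rows = []
    results = []
    shape = pstack.frames.shape[1:]
    for i, ev in enumerate(events):
        part = make_partition(events, i, shape, dilation_px=config.band_dilation_px)
        target = ev.onset_min - config.stream_lead_min
        w_idx = _nearest_window_index(series.timestamps_min, target)
        res = stream_proportions(
            series.masks[w_idx].pixels, part, stream_time_min=float(series.timestamps_min[w_idx])
        )
        results.append(res)
        prop_rows.append(
            {
                "focal_id": i,
                "onset_min": ev.onset_min,
                "p_band": res.p_band,
                "p_outside": res.p_outside,
                "stream_time_min": res.stream_time_min,
                "defined": res.defined,
            }
        )
    pd.DataFrame(prop_rows).to_csv(out / "stream_proportions.csv", index=False)
    if sum(r.defined for r in results) >= 2:
        cmp = paired_comparison(results)
        manifest["paired_comparison"] = {
            "n_band_higher": cmp.n_band_higher,
            "n_outside_higher": cmp.n_outside_higher,
            "n_ties": cmp.n_ties,
            "t_statistic": cmp.t_statistic,
            "p_value": cmp.p_value,
        }

    tracks = None
    if movie is not None:
        tracks = movie.tracks
    elif config.tracks_path is not None:
        tracks = read_tracks(config.tracks_path)
    if tracks is not None:
        t_end = events[0].onset_min if events else stack.time_min(len(stack) - 1)
        summ = displacement_summary(
            tracks,
            t_end_min=t_end,
            um_per_px=stack.um_per_px,
            frame_interval_min=stack.frame_interval_min,
        )
        manifest["displacement"] = {
            "t_end_min": t_end,
            "mean_um": summ.mean_um,
            "sd_um": summ.sd_um,
            "mean_cell_lengths": summ.mean_cell_lengths,
            "n_tracks": summ.n_tracks,
        }

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True, default=float)
    manifest["checksum"] = hashlib.sha256(manifest_text.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=float))
    return manifest
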