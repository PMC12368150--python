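# myxostream

Quantitative stream detection for *Myxococcus xanthus* swarm time-lapse
movies.

Starving *M. xanthus* swarms develop **streams** — elongated lanes where
cells are nematically aligned, moving, at elevated local density, and
persistent in place — before they build the nascent aggregates that mature
into fruiting bodies. `myxostream` turns a fluorescence time-lapse of a
sparsely labeled subpopulation (1 frame/min) into:

1. **persistence images** — 5-frame pixelwise sums that render each
   gliding cell as a streak, histogram-equalized to [0, 1];
2. **feature fields** per analysis timepoint — dense optical-flow speed
   (iterative Lucas–Kanade), windowed-FFT nematic orientation θ (15-px
   windows, 70% overlap) with the scalar order parameter
   S = √(⟨cos 2θ⟩² + ⟨sin 2θ⟩²) over 5×5 window neighborhoods, and
   Gaussian-smoothed density (σ = 10 px);
3. a binary **stream mask**: speed ≥ s_min ∧ S ≥ a_min ∧
   ρ ∈ [ρ_min, ρ_max], kept only where it holds in ≥ half of a 30-frame
   analysis window (the 15-of-30 persistence rule), with %FOV coverage
   traces and threshold-optimization sweeps to pick the cutoffs from
   calibration frames;
4. **aggregate statistics**: intensity-threshold detection of nascent
   aggregates, a 20-px dilation band around each, and the co-localization
   pair
   P(stream | band) = |S_stream ∩ S_band| / |S_band| vs
   P(stream | outside) = |S_stream ∩ S_outside| / |S_outside|
   evaluated 15 min before onset, with a paired t-test across aggregates;
5. **track metrics**: net displacement (µm and cell lengths) from track
   tables;
6. a **synthetic swarm generator** (gliding, reversing rods; stream lanes;
   aggregates) with exact ground-truth masks, events, and tracks, so every
   stage is testable end to end.

Intended for researchers analyzing myxobacterial development movies or
benchmarking swarm-pattern detectors on synthetic data.

## Worked example

Simulate a 200×200 px, 100-frame movie with two stream lanes (active from
frame 20) and one aggregate appearing at frame 70, then run the full
pipeline — persistence imaging, threshold optimization on mid-movie
calibration frames, stream-mask series, aggregate detection, band/outside
proportions, and track displacement:

```python
from myxostream import PipelineConfig, SwarmConfig, run_pipeline
from myxostream.synthetic import StreamLane, AggregateSpec

config = PipelineConfig(
    out_dir="demo",
    simulation=SwarmConfig(
        image_size=200, n_frames=100, n_cells=150,
        scenario="streams_then_aggregates",
        stream_lanes=[StreamLane([(0, 60), (200, 60)], 24, 20, 99),
                      StreamLane([(0, 140), (200, 140)], 24, 24, 99)],
        aggregate_events=[AggregateSpec((100, 100), 10, 70)],
        rng_seed=42),
    rng_seed=42)
manifest = run_pipeline(config)
```

Selected manifest output:

```
peak_stream_time_min        81.5
peak_stream_fov_percent     37.1
n_aggregates                1
first_aggregate_onset_min   71.0
displacement.mean_um        46.4    (6.6 cell lengths, n=150 tracks)
thresholds                  speed_min=0.1 align_min=0.25
                            density_min=0.5 density_max=1.1
```

Reading: stream coverage peaks at 37% of the FOV at T = 81.5 min (the
lanes cover ~23% of the frame; coverage above that reflects streaky
off-lane motion passing the permissive optimized thresholds); the one
aggregate is detected at T = 71 min, one frame after its constructed
onset; cells netted 46 µm (6.6 × 7 µm cell lengths) between the movie
start and aggregate initiation. `demo/stream_proportions.csv` holds the
per-aggregate pair — here P(stream|band) = 0.09 vs
P(stream|outside) = 0.31, i.e. no stream enrichment at this aggregate,
whose band lies between the two lanes:

```
focal_id  onset_min  p_band    p_outside  stream_time_min
0         71.0       0.091640  0.312354   56.5
```

The same stages are available from the shell:

```bash
myxostream simulate --scenario streams --seed 3 --out movie_dir
myxostream run-all --scenario streams_then_aggregates --seed 3 --out out_dir
myxostream optimize --movie movie_dir/movie.tif --calibration 55,70,85 --out thresholds.json
myxostream mask --movie movie_dir/movie.tif --thresholds thresholds.json --out masks/
myxostream tracks --tracks movie_dir/tracks.csv --t-end-min 60
```

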