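# colonyttc

Quantifying rhythmic respiratory activity in expanding colony biofilms
from time-lapse images.

## The problem

Colony biofilms grown on agar amended with TTC
(2,3,5-triphenyltetrazolium chloride) report their respiratory activity
visually: reducing the dye deposits a red formazan precipitate, so local
red intensity tracks local electron-transport activity. Because a colony
expands radially, distance from the center encodes age — the biomass at
radius *r* formed when the advancing edge reached *r*. Under cycling
conditions (alternating light/dark intervals, optionally with a small
temperature swing), such colonies develop concentric rings of differing
TTC reduction: the condition prevailing when a zone of biomass forms sets
("entrenches") its reduction capacity, which then stays fixed while
conditions keep cycling.

`colonyttc` implements the image-analysis pipeline for such movies, and a
synthetic movie generator embodying the entrenchment model so every stage
can be validated against known ground truth:

1. **Segmentation** — from the final frame, background statistics of the
   agar area; rays scanned from the agar toward the colony mark the
   boundary at the first pixel deviating more than *k* = 3 SD from the
   agar mean; the boundary intensity becomes the threshold; each pixel's
   **birth time** is the first frame in which it reached that threshold.
2. **Ring dynamics** — cohorts of pixels born in one window ("rings of
   growth"), their mean-intensity traces and reduction rates, kymographs
   along a radius, radial profiles, and the **lagged edge trace**: for
   each cohort of newly detected edge pixels, the mean intensity 12 h
   after first detection — the primary oscillation readout.
3. **Rhythm statistics** — removal of the first and last peaks, linear
   detrending, amplitude (half the peak-to-trough range of the
   residuals), dominant period (first significant positive
   autocorrelation peak), and unpaired Welch *t* comparison of
   amplitudes between conditions.
4. **Synthetic movies** — a disk growing at constant radial speed *v*
   over a noisy agar background; a pixel born at time *t*₀ under schedule
   condition *c* accumulates signal `A_c · (1 − exp(−(t − t₀)/τ))`, with
   `A_dark > A_light` fixed at birth. Ground truth (per-pixel birth time
   and condition) is returned alongside the movie.

## Worked example

```python
from colonyttc import (make_schedule, SimulationParams, simulate_movie,
                       segment_movie, edge_trace_lagged)
from colonyttc.workflows import lagged_edge_rhythm

# six days of 12 h light / 12 h dark at 25/23 degC, frames every 30 min
schedule = make_schedule(period_h=24, light_fraction=0.5, total_h=144,
                         temp_light=25, temp_dark=23)
params = SimulationParams(seed=1)          # 881x881 px, edge speed 3 px/h
stack, truth = simulate_movie(params, schedule)

birth_map, agar = segment_movie(stack)     # 3-SD boundary -> threshold -> births
print(f"agar {agar.mean:.1f} +- {agar.sd:.2f}, threshold {birth_map.threshold:.1f}")

edge, rhythm = lagged_edge_rhythm(stack, birth_map, lag_h=12)
print(f"amplitude {rhythm.amplitude:.1f}, period {rhythm.period_h} h")
```

Output:

```
agar 20.0 +- 1.00, threshold 26.4
amplitude 25.6, period 24.0 h
```

The threshold sits ~3 SD above the agar mean of 20; the lagged edge
trace alternates between light-born (~69) and dark-born (~108) readouts,
giving a detrended amplitude of ~26 intensity units, and its dominant
period recovers the 24-h forcing period of the schedule exactly.

The same steps run from the shell:

```sh
colonyttc simulate --period-h 24 --total-h 144 --seed 1 --out run/sim
colonyttc analyze --movie run/sim/movie.tiff --schedule run/sim/schedule.csv --out run/out
```

## Analysis scripts

`analysis/` holds numbered drivers that narrate the full study on
synthetic data and write tables/figures under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_movies.py` | renders the standard, shortened- and prolonged-cycle scenarios; ring geometry table |
| `02_segment_birth_times.py` | segmentation audit: agar stats, threshold, detection delays, label recovery |
| `03_ring_dynamics.py` | cohort traces, final values, lagged edge trace, kymograph, radial profile |
| `04_rhythm_periods.py` | period recovery for the three cycling regimes |
| `05_amplitude_comparison.py` | light-only vs combined cycling amplitudes, Welch test |

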