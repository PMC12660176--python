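# quantalmap

Single-synapse functional imaging analysis for *Drosophila* larval
neuromuscular junctions (NMJs), for labs doing quantal imaging and
photoconversion pulse-chase experiments.

A motoneuron terminal holds hundreds of presynaptic active zones (AZs), each
opposed by a postsynaptic glutamate-receptor density (PSD). Their evoked
release probabilities span a ~50-fold range, and part of that heterogeneity
is synapse *age*: AZs mature over days, accumulating scaffold proteins and
Ca²⁺ channels. `quantalmap` implements the full analysis chain used to
measure this:

- **Quantal Pr mapping** — detect single-vesicle GCaMP flashes in an 8 Hz
  movie during 1 Hz nerve stimulation, assign each flash to the nearest AZ
  ROI within 0.8 µm, call frames with ≥ 3 simultaneous events *evoked*, and
  compute per-AZ `Pr = evoked events / stimulations` plus a spontaneous rate
  (events/min).
- **Puncta morphometrics** — max-project confocal Z-stacks, detect
  fluorescent puncta above a robust threshold, and quantify centroid, area,
  sum/mean intensity, pairwise colocalization deficits, AZ–PSD opposition
  pairing, and densities per 10 µm² of NMJ area.
- **Synapse time-stamping** — classify PSDs old/new from two-color
  photoconvertible receptor labels (red = pool present at conversion,
  green = delivered later), normalize red intensity per NMJ (brightest
  PSD = 1.0), and relate age to Pr, spontaneous rate, and bouton position.
- **Protein turnover** — percent of photoconverted signal remaining after a
  chase and the implied half-life, `T½ = dt·ln2 / ln(S₀/S₁)` under
  first-order decay (a fractional-loss-rate and a linear model are also
  provided), plus new-protein accumulation and paired Ca²⁺-influx fold
  changes.
- **Synthetic NMJ generator** — ground-truth geometries (boutons, AZ/PSD
  pairs, per-AZ Pr, spontaneous rates, ages, Cac occupancy), rendered puncta
  stacks, quantal movies with a true event log, and photoconversion series
  with known half-life, so every estimator is tested against known truth.

## Worked example

```python
import numpy as np
from quantalmap import (make_geometry, MovieSpec, simulate_quantal_movie,
                        ROISet, map_movie, pearson_r, report,
                        simulate_photoconversion_series, estimate_turnover)

gt = make_geometry(5, 10,  # 5 boutons x 10 AZs
                   pr_distribution=("uniform", {"low": 0.02, "high": 0.5}),
                   seed=1)
movie, _, info = simulate_quantal_movie(gt, MovieSpec(duration=300.0), seed=2)
rois = ROISet(np.arange(gt.n_az), gt.az_centroids)
rmap, events = map_movie(movie, rois, gt.pixel_size,
                         info["n_stimulations"], info["duration"])
est = report.roi_values(rmap, rois)
print(f"{len(events)} events detected over {info['n_stimulations']} stimuli")
print(f"true-vs-estimated Pr: r = {pearson_r(gt.true_pr, est):.3f}, "
      f"MAE = {np.abs(gt.true_pr - est).mean():.3f}")
print(rmap.table.head(3).to_string(index=False))

series = simulate_photoconversion_series(gt, half_life_days=2.2,
                                         timepoints=[0, 1], seed=3)
res = estimate_turnover(series, gt.pixel_size)
print(f"red signal remaining after 1 d: {res.remaining_pct:.1f}% "
      f"-> half-life {res.half_life:.2f} d (true 2.2 d)")
```

Output:

```
3459 events detected over 300 stimuli
true-vs-estimated Pr: r = 0.992, MAE = 0.015
 roi_id  evoked_count       pr  spont_count  spont_rate  capped
      0            70 0.233333            4         0.8   False
      1            98 0.326667            3         0.6   False
      2            35 0.116667            5         1.0   False
red signal remaining after 1 d: 72.5% -> half-life 2.16 d (true 2.2 d)
```

The 50 simulated AZs had release probabilities drawn from U(0.02, 0.5); the
detected release map recovers them with r = 0.992 and a mean absolute error
of 0.015 — within binomial counting noise for 300 stimuli. The pulse-chase
recovers a 2.2 d half-life from two noisy image stacks one day apart.

A command-line interface mirrors the pipeline stages
(`quantalmap simulate | detect | map-pr | timestamp | turnover | report`);
`quantalmap report config.yaml` runs the whole chain and writes events and
release-map CSVs, a Pr heatmap PNG, and a JSON run log that records every
parameter and seed needed to reproduce the outputs bit-for-bit.

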