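# cpforage

Analysis toolkit for **foraging consistency of central-place foragers** —
built around multi-trip GPS deployments of Adélie penguins (*Pygoscelis
adeliae*) during chick rearing, where successive colony-to-colony trips under
a shifting sea-ice scape raise two questions:

1. **How repeatable is an individual's foraging behaviour?** For each trip
   the package computes four effort parameters — total duration, total path
   distance, maximal distance from the colony, and the bearing to the most
   distal point — and estimates the population-level repeatability of each
   with a Gaussian random-intercept mixed model,

   R = σ²_A / (σ²_A + σ²),

   where σ²_A is the between-individual and σ² the within-individual
   (residual) variance. Fixed effects (year × days since the peak hatching
   date) are selected backwards by AIC; "adjusted" R conditions on them,
   "non-adjusted" R uses the intercept-only model; uncertainty comes from a
   parametric bootstrap.

2. **How faithful is a bird to its foraging sites?** Trips are pooled onto a
   normalized profile (percent of trip duration elapsed vs. percent of
   maximal colony distance) and a continuous two-breakpoint piecewise-linear
   regression locates the central foraging phase as population fractions
   (f₁, f₂) of trip duration. Fidelity between consecutive trips of the same
   bird is the **nearest-neighbour distance (NND)**: the mean, over the
   focal trip's central-phase fixes, of the great-circle distance to the
   nearest fix of the previous trip's central phase. Low NND = high
   fidelity. NND is then modelled against year, within-season timing, and
   sea-ice concentration (mean over the trip pair and between-trip change)
   in the annually prospected area, via linear models with Tukey-adjusted
   year contrasts and a penalized-spline mixed model.

Around this core the package provides GPS track QC (speed filter, duplicate
removal, trip splitting by colony radius, virtual completion of truncated
recordings, 20-min resampling), daily sea-ice raster handling at two grid
scales with per-fix extraction and regional averaging, and a synthetic
study generator that emulates every input with known ground truth.

## Worked example

Simulate a 20-bird study and run every stage:

```bash
cpforage run-all --out demo --seed 11
cat demo/report.txt
```

```
cpforage run (config fc32a85d6480, seed 11)
cohort: 19 individuals, 49 trips (2.58 +/- 1.07 trips/bird)
phase breakpoints: f1=30.5%, f2=69.0% of trip duration
R[total_duration, adjusted] = 0.663 (high)
R[total_duration, non-adjusted] = 0.663 (high)
R[total_distance, adjusted] = 0.266 (moderate)
R[total_distance, non-adjusted] = 0.266 (moderate)
R[max_distance, adjusted] = 0.255 (moderate)
R[max_distance, non-adjusted] = 0.255 (moderate)
R[bearing_folded, adjusted] = 0.857 (high)
R[bearing_folded, non-adjusted] = 0.857 (high)
R[central_phase_sic, adjusted] = 0.830 (high)
R[central_phase_sic, non-adjusted] = 0.997 (high)
fidelity records: 30, mean NND 1.83 km
```

Reading this: the generator placed the true phase boundaries at 30% and 70%
of trip duration and the pooled changepoint fit recovered 30.5%/69.0%; each
`R[...]` line is one trait's repeatability with its category (low < 0.25 ≤
moderate ≤ 0.5 < high); the mean NND across the 30 consecutive-trip pairs
summarizes site fidelity (these simulated birds share a per-bird foraging
patch, hence the small value). Stage artifacts (`trip_metrics.csv`,
`fidelity.csv`, `repeatability.csv`, `nnd_year_model.csv`, ...) land in
`demo/`. The same stages are available individually (`cpforage qc`,
`cpforage phases`, ...) and as library functions:

```python
from cpforage import io_qc, phase_segmentation, site_fidelity, synthetic_data

sim = synthetic_data.simulate_cohort(synthetic_data.SimConfig(n_birds=20, seed=1))
trips = io_qc.qc_cohort(sim.tracks, sim.nest_checks)
profile = phase_segmentation.normalize_trips(trips, (140.01, -66.66))
model = phase_segmentation.fit_three_segment(profile)   # -> f1, f2
records = site_fidelity.fidelity_table(trips, model)
```

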