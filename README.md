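# holorough

Real-time, label-free monitoring of nanoparticle (NP) uptake by adherent
cells from quantitative phase time-lapse imaging (digital holographic
microscopy, DHM), via per-cell surface-roughness kurtosis.

When an NP adsorbs to a cell membrane it locally perturbs the optical path
length (OPL) map that DHM reconstructs.  The intra-cell height texture —
after removing the gross cell shape — becomes transiently heavy-tailed, so
the roughness kurtosis

    Rku = mean(z⁴) / Rq⁴,   Rq = sqrt(mean(z²)),   z = detrended OPL

rises above its baseline (≈3 for Gaussian texture) and returns as
internalisation completes.  The width of that kurtosis peak is the
internalisation time; skewness (Rsk = mean(z³)/Rq³) is tracked as a
negative control, since it shows no uptake signal.  The phase delay behind
the OPL maps follows Φ = (2π/λ)·n·x.

The package provides, as a tested library plus CLI:

- **phantom** — a synthetic DHM time-lapse generator with per-cell ground
  truth: OPL domes with membrane-fluctuation and static internal texture,
  uptake events with known onset/duration, and control, fixed-cell,
  t=0-peak and cell-death scenarios, all deterministic per seed;
- **segmentation** — automatic thresholding of each frame, region
  cleanup, greedy nearest-centroid tracking, and cell-death flagging;
- **roughness** — polynomial detrending and Rq/Rsk/Rku time series per
  tracked cell;
- **kinetics** — robust baseline, single-peak detection, the curation
  rules (no peak / peak at t=0 / death before uptake / outlier roughness),
  onset alignment, cohort mean ± SEM profiles, internalisation-time
  statistics and between-group fold changes;
- **interface** — TIFF + JSON sidecar stack I/O, CSV/JSON reports, and a
  `holorough` CLI (`simulate`, `analyze`, `report`, `demo`).

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Simulate and analyse a complete experiment — a 40-cell no-NP control field
plus two NP-treated groups whose uptake events last 7.2 and 6.2 min on
average, each with a five-cell uptake cohort and exemplars of every
rejection class:

```sh
$ holorough demo --out demo_run --seed 0
group control: accepted 1 of 40
group np_slow: accepted 5 of 10
group np_fast: accepted 5 of 10
np_slow vs np_fast: 1.1-fold increase

$ holorough report --run demo_run
group control: 1/40 cells accepted; onset 33.5 min, width 4.0 min
  rejected: {'no_peak': 39}
group np_slow: 5/10 cells accepted; onset 14.1 min, width 7.8 min
  rejected: {'pre_uptake_death': 2, 'no_peak': 2, 't0_peak': 1}
group np_fast: 5/10 cells accepted; onset 15.9 min, width 8.4 min
  rejected: {'t0_peak': 1, 'pre_uptake_death': 2, 'no_peak': 2}
np_slow vs np_fast: 1.1-fold increase (7.8 -> 8.4 min)
```

Reading the output: in `np_slow`, five cells showed a single significant
kurtosis peak and were onset-aligned into the cohort; NP adsorption began
on average 14.1 min after exposure and internalisation took 7.8 min
(generator ground truth: onsets 15 ± 3 min, durations 7.2 ± 1.5 min).  The
cells that died before uptake, peaked already at t = 0, or never peaked
were excluded with the reasons shown.  The lone control acceptance is a
kurtosis-noise false positive — controls are allowed up to ~5% of cells —
and with n = 1 it is excluded from group comparisons.  At five cells per
cohort the 1-min true difference between the groups is at the edge of
resolution, so the per-seed fold change scatters around 1; the
`aligned_profile_<group>.csv` files contain the mean ± SEM kurtosis
profiles (columns `aligned_time_min, mean_rku, sem_rku, n_contributing`)
with the event onset at time 0.

The same pipeline runs on real stacks: `holorough analyze --config
run.yaml`, where the config lists per-group TIFF stacks (32-bit float,
one page per frame) with JSON metadata sidecars (`pixel_pitch_um`,
`frame_interval_min`, `wavelength_nm`).

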