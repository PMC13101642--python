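# Methods

`holorough` analyses time-lapse quantitative phase imaging (digital
holographic microscopy, DHM) of adherent cells to monitor nanoparticle (NP)
uptake in real time, and ships a synthetic phantom generator so the whole
pipeline can be exercised and validated without instrument data.

## The measurement model

DHM reconstructs, per pixel, the optical path length (OPL) through the
specimen.  For a slab of thickness x and refractive-index contrast n the
phase delay is Φ = (2π/λ)·n·x; the package stores frames as OPL in
nanometres and converts to phase only through `phase_shift`.  Working in
OPL sidesteps an ambiguity in the slab formula — whether n denotes the
absolute index or the contrast against the medium — because the roughness
statistics used downstream (skewness, kurtosis) are scale-invariant, so any
λ- or n-dependent rescaling cancels.

For every segmented cell at every frame the intra-cell OPL values are
detrended by a least-squares polynomial surface (order 2 by default; orders
0–2 supported), removing the gross dome shape of the cell, and the residual
"texture" is summarised by surface-metrology moment descriptors computed
with population normalisation:

    Rq  = sqrt(mean(z²))          RMS roughness (nm)
    Rsk = mean(z³) / Rq³          roughness skewness
    Rku = mean(z⁴) / Rq⁴          roughness kurtosis (Gaussian surface → 3)

Raw (non-excess) kurtosis is used, matching the ISO surface-texture
convention.  The Pearson bound Rku ≥ Rsk² + 1 holds for every sample, and
regions with Rq = 0 or fewer than 6 pixels (the order-2 fit's solvability
limit) are masked, not errors.

NP adsorption at the membrane adds localized OPL perturbations whose tails
fatten the intra-cell height distribution: kurtosis rises, then returns to
baseline as internalisation completes.  The internalisation time is read
off as the width of that kurtosis peak.  Skewness is computed and reported
but never used for detection: in the recordings this channel shows no
uptake peak, and the pipeline preserves that asymmetry (see below).

## Event detection and curation

Per-cell kurtosis series are modelled as baseline + transient:

- **Baseline**: median of the valid points; noise scale σ = 1.4826·MAD.
  Both are robust to one event occupying ≲40% of the series.
- **Candidates**: local maxima standing at least k·σ (default k = 5) above
  the baseline level whose contiguous run above `level + σ` spans at least
  2 frames.  Candidates sharing a run are one peak.  If several distinct
  candidates survive, the most prominent is kept and the cell is flagged —
  single discrete events are the expected biology, so multiplicity is an
  anomaly, not something to average.
- **Onset / end**: the last upward and first downward crossings of
  `level + σ` around the peak.  The crossing time inside the bracketing
  frame interval is taken at the interval midpoint by default: for events
  whose rise saturates within one frame interval, linear interpolation
  lands almost a full frame early on each side (it follows the segment
  toward the sub-threshold frame), while the midpoint is at most half a
  frame off for any signal shape.  Linear interpolation
  (`crossing_estimate="linear"`) and a full-width-at-half-maximum width
  (`width_method="fwhm"`) are available since the field does not agree on a
  single convention.
- **Verdicts** follow the curation used on real recordings, with fixed
  precedence: cells that die before any event onset are discarded first,
  then cells already peaking at the first frame, then outliers (baseline
  level, or series maximum measured *outside* detected event windows,
  above 5× the cohort median of the same statistic — an uptake peak is not
  evidence of an abnormal cell), then cells with no significant peak.
  Everything else is accepted with exactly one event.

Accepted cells are onset-aligned (each series shifted so its onset maps to
time 0), averaged point-wise into a mean ± SEM profile (SEM = sd/√n,
reported only where ≥2 cells contribute), and summarised by mean onset,
mean width, and per-cell widths.  Between-group comparison reports the
fold change of mean widths (larger over smaller, with direction, rounded
to one decimal as in the primary report; exact values retained).  Group
comparisons require n ≥ 2 per cohort.

## The phantom generator

The generator emulates the statistical structure of the study's recordings
— it is a benchmark with ground truth, not an optical simulation.  No
hologram formation, PSF or phase unwrapping is modelled; cells are rendered
directly as OPL maps at the instrument's geometry (default 1024×1024 px at
1.22 µm/px ≈ 1.25 mm × 1.25 mm, one frame per minute for an hour — note the
published imaged area is also quoted as 1.558 mm², a discrepancy the
package does not resolve).

Each cell is:

- a **paraboloidal dome**, peak OPL 300–500 nm over an elliptical footprint
  of 13–18 px semi-axes (MCF-7-scale adherent cells).  The paraboloid is an
  exact quadratic, so detrending removes it exactly and the roughness
  series see only texture;
- **frozen internal texture** (6 nm RMS, 1 px correlation): a static,
  symmetric Gaussian random field standing in for organelles and other
  structure that does not fluctuate frame-to-frame;
- **membrane fluctuation** (4 nm RMS, 1 px correlation): a Gaussian random
  field refreshed by an AR(1) update with a 3-frame time constant;
- optional **uptake event**: a cluster of 4 Gaussian spots (σ = 1.2 px) in
  the inner 0.4-ellipse of the footprint — particle-aggregate bumps and
  endocytic pits of alternating sign — whose height follows an asymmetric
  raised-cosine envelope over [onset, onset + duration] (rise fraction
  0.55, so a 7.2-min event starting at 15 min peaks near 19 min).

Two generator choices deserve emphasis because they encode the observable
the module exists to emulate:

1. **Fourth-root envelope coupling.**  The excess kurtosis induced by a
   small spot on Gaussian texture grows with the *fourth power* of the
   relative spot height, so spots scaled linearly by the envelope would
   yield kurtosis excursions confined to a narrow core of the event
   support.  Spot heights therefore scale with env(t)^¼: the kurtosis
   profile — the quantity the instrument plots — then follows the envelope
   itself, and injected durations are recoverable from peak widths.
2. **Skewness-neutral perturbations.**  Bump and pit weights are solved
   per event (a cubic root-solve) so that the *detrended* spot pattern has
   exactly zero third moment on the cell's footprint.  The event then
   registers in kurtosis but not skewness, reproducing the empirical
   channel asymmetry; the residual stochastic leak through the texture
   cross-term is below the detection threshold for ≳98% of event cells
   and absent in controls.

Fates mirror the curation taxonomy: `normal` (may carry one event),
`quiescent` (control behaviour), `t0_peak` (event already at its maximum
at frame 0, via a degenerate zero-rise envelope), `dying` (dome collapses
exponentially, τ = 2 min, after a ground-truth death time) and `fixed`
(membrane fluctuation damped to 0.3×).  Damping is observable in the
kurtosis series because the frozen texture is static: with the dynamic
field attenuated, each frame's moments are dominated by the same frozen
surface and the series' temporal variance collapses.  A purely Gaussian
dynamic field alone would make kurtosis scale-free and damping invisible —
the static component is what gives the fixed-cell control its signature.

The default scene is a single uptake experiment: 40 cells, of which 5
interact with NPs (onsets 15 ± 3 min, durations 7.2 ± 1.5 min clipped to
2–9 min, spot amplitude 230 nm), one peaks at t = 0, three die, and the
rest are quiescent.  Event amplitude is deliberately high (a magnetite
aggregate has refractive index ≫ cell): tall spots saturate the kurtosis
response, which sharpens event edges and *reduces* the skewness leak
(cross-terms decay as 1/amplitude).  Pit depth never exceeds the local
dome height, keeping OPL non-negative.

Determinism: one root seed; per-cell child streams keyed by cell id for
parameters, fluctuation, and static texture, so adding a cell never
changes another cell's noise; a separate stream for background.  Identical
(config, seed) gives bit-identical stacks.

## Segmentation and tracking

Frames are thresholded automatically.  The default is a robust background
rule — median + max(5·1.4826·MAD, 6% of the robust foreground height) —
computed on a lightly smoothed copy (σ = 1.5 px); Otsu, Li and triangle
thresholds are selectable but Otsu in particular misplaces the threshold
mid-dome when foreground occupies a small area fraction.  Holes are
filled, regions under 50 px dropped, and touching regions can be split by
distance-transform watershed (off by default; phantom scenes are placed
without overlap).  Intensity summaries always come from the raw frame.

Tracking is greedy nearest-centroid linking under a 15 px displacement
bound with up to 2 missed frames — cells are near-stationary at one frame
per minute, so global assignment would add complexity without benefit.
Cell death is flagged when region area *or* mean OPL stays below half its
initial-window median for 2 consecutive frames; the criterion is the
package's own, since the source protocol states the exclusion but not the
rule.

## What the phantoms do not emulate

No diffraction or speckle, no cell motility, division or shape change, no
NP diffusion kinetics before membrane contact (onset is a free parameter),
no multi-event cells by default, and no instrument-specific segmentation
or smoothing.  Absolute Rku/Rsk values from the instrument's software are
therefore not comparable; only the temporal peak structure (onset, width,
return to baseline) and the relative behaviour of controls, fixed cells
and uptake cohorts carry over.  Passing the validation suite shows the
pipeline recovers known kinetics from data with the *statistical* structure
of DHM recordings; it does not certify performance on any particular
instrument's output.

## Problem sizes and numerical choices

Validation simulations run on 512 px fields (a quarter of the default
area, same cell density and cadence); pilot checks showed identical
behaviour at 1024 px at four times the cost.  Key tolerances: descriptor
agreement with brute-force moments to 1e-12 relative (residuals are
pre-scaled by their maximum to avoid under/overflow); detrend residuals
zero-mean to 1e-9 relative; placement retries capped at 200 per cell with
a capacity error naming the achieved count; Rsk/Rku flagged undefined (not
raised) on constant regions.  Report values are rounded to one decimal;
CSV artifacts keep full precision.  The analysis path contains no
randomness: re-running a configuration is byte-identical.

## Known limitations

Sub-cadence events (≲2 min at the 1-min frame interval) are detected in
only ~90% of cells — their above-threshold span cannot always cover two
frames, the same resolution limit the original protocol reports.  Width
estimates quantise to the frame grid (midpoint convention), so individual
widths carry ±0.5 min discretisation error.  The false-positive allowance
on controls (≲5% of cells per hour-long recording) is driven by the heavy
right tail of sample kurtosis on spatially correlated texture; cohorts of
tens of cells therefore usually contain 0–2 spurious acceptances, which
onset alignment dilutes but does not remove.
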