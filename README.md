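# cardiomea

Analysis of microelectrode-array (MEA) recordings of cardiomyocyte
monolayers: beat detection, per-beat spatial electrophysiology maps,
pacemaker-origin estimation, pacemaker-translocation statistics, and
heavy-tailed distribution comparison — as a headless, tested Python library
with a thin command-line interface and a synthetic recording generator that
provides ground truth for every estimator.

## Who this is for

Stem-cell-derived cardiomyocyte cultures (hESC-CM / hiPSC-CM) plated on
planar MEAs produce extracellular *field potentials*: one sharp R-wave-like
spike per beat followed by a slower repolarization (T) wave, recorded
simultaneously on 60 or 120 electrodes at known positions (200 µm pitch).
From the relative timing and shape of these signals across the array one can
quantify where a beat originates (the pacemaker region), how fast it
propagates, how long repolarization takes, and whether the pacemaker is
spatially stable over time — all of which bear on culture maturity and
system dynamics.

## What it computes

Per beat *b* and electrode *e*, with R-peak time `t(e, b)`:

- **Time lag (pacemaker) map** — `lag(e, b) = t(e, b) − min_e t(e, b)`;
  the pacemaker electrode reads exactly 0 ms.
- **LAT** — local activation time, the instant of the maximal negative
  derivative (intrinsicoid deflection) after the R peak, normalized per beat
  like the time lag.
- **dV/dt_max** — maximum upstroke slope before the R peak (backward finite
  differences, µV/ms).
- **Conduction velocity** — `CV(e) = distance(ref, e) / ΔLAT(e)` from the
  per-beat zero-LAT reference electrode, µm/ms.
- **Amplitude** (positive + negative excursion, µV), **beat intervals** (ms)
  and **FPD** — field potential duration, R peak to T-wave endpoint, where
  the endpoint maximizes the trapezoid area
  `A(x_i) = ½ (y_m − y_i)(2 x_r − x_i − x_m)` anchored at the T-wave's
  steepest-descent point `(x_m, y_m)` and a distal fixed point `(x_r, y_r)`.
- **Pacemaker origin** — bounded nonlinear least-squares fit of a circle
  `r = √((x−h)² + (y−k)²)` to the richest lag isochrone; `(h, k)` estimates
  the origin.
- **Translocations** — jumps of the per-beat pacemaker location exceeding
  500 µm delimit *quiescent periods* (censored: first closed period and the
  trailing open period are dropped).
- **Heavy-tail statistics** — MLE fits of power law, doubly truncated power
  law `p(x) ∝ x^(−α) e^(−λx)`, log-normal, exponential and stretched
  exponential above a KS-minimizing cutoff `x_min`, compared pairwise by the
  normalized (Vuong) log-likelihood ratio.
- **Property–distance regression** — each property against distance from
  the fitted origin (OLS; saturating exponential for CV), ranked by R².

## Worked example

```bash
python examples/01_simulate_and_map.py
```

```
beats detected:        6
electrodes included:   120 / 120
beat rate:             40.00 bpm (simulated: 40.00)
max time lag:          4.59 ms
median CV:             302.6 um/ms (simulated: 300)
median dV/dt_max:      69.2 uV/ms
median amplitude:      396 uV
```

A radial wave from electrode F7 at 300 µm/ms is simulated with noise,
detected, and mapped: the beat rate and median conduction velocity recover
the simulation's parameters, and the maximum time lag (≈4.6 ms) is the array
diagonal divided by the wave speed. The other examples cover origin
estimation (`02`), translocations and heavy tails (`03`), FPD (`04`) and
batch analysis plus workbook export (`05`).

The same workflow is available from the shell:

```bash
cardiomea simulate --out rec.txt --noise-sigma 30 --seed 1
cardiomea compute --input rec.txt --out results.xlsx --filter lowpass:100
cardiomea translocations --input rec.txt --threshold-um 500
```

`compute` writes a multi-tab `.xlsx` workbook (one tab per property, plus a
parameter-provenance tab).

## Input format

Recordings are column-wise ASCII exports: first column time in ms,
then one voltage column (µV) per electrode in acquisition channel order
(column 2 ↔ electrode F7 on the 120-electrode layout). Electrode layouts
ship as editable CSV tables (`src/cardiomea/layouts/`); new geometries can
be registered at run time via `cardiomea.register_layout`.
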