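# decellmon

Monitoring analytics for perfusion decellularization: an optical phantom
simulator, an image-based process monitor with an automatic stopping rule,
and plateau endpoint detection for spectrophotometric concentration series.

## The problem

Whole-organ decellularization perfuses a detergent (e.g. SDS) through an
organ's vasculature until all cellular material is stripped from the
extracellular matrix. Deciding *when the process is finished* is the
operational question: stopping early leaves cells behind, stopping late
degrades the scaffold. Two complementary endpoint signals are used here:

1. **Optical monitoring.** The chamber is backlit with a green (~530 nm) LED
   panel and photographed on a time-lapse. By the Beer–Lambert law the
   transmitted intensity through the tissue (or a dye-filled phantom) is
   `I = I0 · 10^(−ε·l·c)`, so as pigment washes out the region of interest
   (ROI) brightens. The *process variable* is the mean grayscale of a fixed
   ROI, as a percentage of 255.
2. **Release kinetics.** DNA and protein released into the chamber fluid
   accumulate toward a stationary plateau `C(t) = C∞·(1 − e^(−t/τ))`;
   the endpoint is where consecutive measurements stop changing.

`decellmon` is aimed at bioprocess/tissue-engineering labs who want these
analytics as tested, scriptable components rather than rig-bound software —
plus a physics-based synthetic data generator so the whole chain can be
validated without hardware.

## The models and detectors

**Phantom** (`decellmon.phantom`): a well-stirred dye reservoir of volume
`V` (mL) fed water at `Q` (mL/h) dilutes as `c(t) = c0·e^(−Q·t/(60·V))`
(`t` in minutes). Composed with Beer–Lambert optics the noise-free ROI
intensity is a Gompertz (S-shaped) curve
`I(t) = I0·10^(−ε·l·c0·exp(−Q·t/(60·V)))`.

**Stopping rule** (`decellmon.monitor`): per frame, convert to grayscale
(green channel for RGB), take the exact ROI mean, rescale to percent,
Gaussian-smooth the trace (σ = 2 samples, reflect padding), and stop at the
first frame where the last `N = 10` smoothed values satisfy
`max − min ≤ (k/100)·mean` with `k = 3 %`.

**Endpoint detection** (`decellmon.endpoint`): successive differences
`d_i = |c_i − c_{i−1}|`; the plateau onset is the first sample `i` with
`m = 3` consecutive differences `d_i, …, d_{i+m−1}` all at or below
`ε = 2 %` of the series' full range. Control-vs-treatment comparisons report
the relative time saving `(t_ctrl − t_treat)/t_ctrl × 100`.

## Worked example

Generate the calibrated demonstration fixtures and compare the two lots:

```bash
$ decellmon make-fixtures --out demo_fx
discoloration_stop600: V=120.08 mL, stop at 600 min
discoloration_stop420: V=73.23 mL, stop at 420 min
lot endpoints: control 630 min, treatment 450 min

$ decellmon compare demo_fx/lot_control.csv demo_fx/lot_treatment.csv
control endpoint: 630 min
treatment endpoint: 450 min
time reduction: 28.57% (rounded: 29%)
```

The first two lines report monitored discoloration runs whose stopping rule
fires at 600 min (control) and 420 min (a faster, e.g. vibration-assisted,
run) — a 30 % monitored time reduction; the reservoir volumes shown are the
calibrated free parameter producing those endpoints at 50 mL/h. The lot
comparison detects the DNA-release plateau onsets at 630 and 450 min, a
reduction that rounds to 29 %.

A full seeded session (simulate → monitor → sample → compare, with frames,
`data.txt`, plots, manifest and report under an ISO-8601 directory):

```bash
decellmon run-all --seed 1 --out runs
```

The Python API mirrors the CLI: see `simulate_discoloration_run`,
`run_monitor`, `detect_endpoint` and `compare_lots`.

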