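# Methods

## Sensing model

One reading is a CIE-Lab triple (L: luminance 0–100; a: green–red
−128…127; b: blue–yellow −128…127) integrated over a circular measuring
spot. Everything upstream of the Lab triple — interference filters, XYZ
normalization, optics — is outside the package: `labweed` consumes Lab
directly.

The central modeling assumption, stated once and used everywhere, is
**area-weighted linear mixing**: a plant covering fraction f of the spot
produces, per channel,

    ch_MA = (1 − f) · ch_BG + f · ch_Obj

where BG is the plant-free background and Obj the plant color. This is
what ties the statistical existence rule to the minimum-coverage model:
under linear mixing the channel shift at coverage f is exactly
f · |ch_Obj − ch_BG|, so the smallest detectable coverage is the fraction
at which that shift reaches the rule's boundary σ_BG + σ_Obj. The test
suite asserts this consistency to 1e−9 for every packaged background ×
green × channel combination.

Linear mixing ignores specular effects, shadowing, dew optics and any
non-uniform sensitivity across the spot.

## Detectors

All detectors compare a reading against the *calibrated background*
(mean, per-channel σ), never against absolute color values.

* **ΔE detector** — fires when the Euclidean distance between reading and
  background mean strictly exceeds a threshold. The ΔE interpretation
  scale (six categories from "no to almost no difference" below 0.5 to "a
  different color" above 5.0) is exposed for reporting; intervals are
  half-open [lower, upper), last category unbounded, so the mapping is
  total and deterministic.
* **Channel detector** — strict thresholds per channel (ΔL, Δa, Δb, and
  optionally the virtual channel d = |a − b|), combined with *any*
  (default) or *all*.
* **Statistical existence rule** — fires when, in at least one of L, a, b,
  the absolute deviation from the background mean is **≥** the summed
  standard deviations of background and object. The inclusive boundary is
  deliberate and differs from the strict threshold detectors; both
  conventions are documented constants, and the distinction only matters
  on a measure-zero boundary set.
* **Multistage differentiation** — (1) flag suspicious readings with ΔE,
  (2) inspect individual channels, (3) attribute the flagged reading to a
  green tone. Step 3 is formalized as direction matching: the observed
  offset v = reading − background mean is compared to each candidate
  direction u_g = green mean − background mean by cosine similarity, and
  the best-scoring tone wins. Under noise-free linear mixing v = f · u_g,
  so the result is independent of plant size — the motivation for
  comparing channels "relative to each other". The d channel can be
  appended as a fourth vector component but is off by default, being a
  function of a and b. Exact ties (beyond 1e−12) raise an explicit
  ambiguity error rather than picking arbitrarily.

Per-channel differences are computed as absolute differences (the square
root of the squared difference), keeping ΔL, Δa, Δb on the same scale as
ΔE so that one threshold vocabulary (e.g. "ΔE > 5, Δa > 2") applies
across detectors, and making ΔE² = ΔL² + Δa² + Δb² hold exactly. The
coverage denominator is likewise the absolute mean difference — the only
form dimensionally consistent with the existence rule.

## Coverage model parameters

    A_ch = 100 · (σ_ch,BG + σ_ch,Obj) / |ch_Obj − ch_BG|    [percent of spot]

* `A > 100` means "not detectable on this channel even at full coverage";
  coinciding means give the +inf sentinel (with a warning, not an
  exception, so whole-table sweeps survive degenerate cells).
* The **d channel** analog uses |a − b| of each side's means and the
  conservative propagation σ_d = σ_a + σ_b (an upper bound on the
  standard deviation of a − b regardless of the a/b correlation; no
  empirical d-noise is available).
* `min_plant_area(A, spot)` converts coverage to absolute plant area,
  (A/100) · π(d/2)², reported to one decimal. At the reference spot
  diameters of 5 and 10 cm (≈20 and ≈80 cm²), 3% coverage corresponds to
  0.6 and 2.4 cm².

## Reference databases

Ten plant-free backgrounds (seven anthropogenic, three natural) with
per-channel mean and σ, and four green tones with mean/median/min/max,
ship as JSON fixtures transcribed verbatim from the original
characterization measurements (>500 readings per background). Points a
user should know:

* **Green-tone σ is not part of the source data.** Where a σ is needed
  (statistical rule, coverage model, simulator noise) the quarter-range
  convention σ = |max − min| / 4 per channel is applied — a standard
  small-sample range approximation. It is a convention, not measured
  ground truth: coverage predictions for the a, b and d channels inherit
  its uncertainty, while the luminance column for the brightest tone is
  corroborated by six independently published cells that the model
  reproduces exactly at one-decimal rounding.
* **Transcription suspects are flagged, not corrected.** Green 2's
  a-channel range (−16.83 … −25.60) does not bracket its mean (−26.18);
  Green 3's L and b ranges are identical (both 32.95 … 34.47), suggesting
  a copying slip; several negative-channel min/max pairs are printed in
  reversed order (harmless to the quarter range, which uses |max − min|).
  These cells carry `suspect-*` flags in the fixtures and surface as
  warnings when constructed fresh.
* Calibration (`summarize` / `calibrate_background`) uses the sample
  standard deviation (n − 1 denominator), appropriate for the short
  calibration streams taken in the field, and requires ≥ 2 readings.
* Lab values outside nominal ranges are accepted with a warning: sensor
  drift should degrade gracefully, not crash the sprayer pipeline.

## Simulator

`scene_sim` emulates the moving sensor carrier: a spot of diameter 5 cm
(default) travels a 150 cm track at 0.1 m/s, sampling at 10 Hz — one
reading per centimeter, 150 readings in 15 s. Disc-shaped objects of
chosen green tones sit on the track; per reading,

* the exact circle–circle intersection (lens formula) of spot and each
  object gives the coverage fraction (summed over objects, capped at 1;
  the largest-overlap object supplies the tone — per-reading multi-green
  color mixing is deliberately out of scope),
* the Lab value is the linear mixture plus Gaussian channel noise with
  σ(f) = (1 − f)·σ_BG + f·σ_Obj — the simplest interpolation consistent
  with both endpoints,
* ground truth (coverage fraction, tone label) is recorded alongside.

One seeded generator (numpy PCG64) drives all noise; an identical scene
specification yields a bit-identical transect. What the simulator does
*not* emulate: sun/shadow illumination changes, dew optics, real leaf
shapes and orientations, carrier vibration, and spatial noise
correlation (readings are independent draws). Passing simulated tests
therefore demonstrates the correctness and internal consistency of the
algorithms under the stated statistical model of each surface, not field
performance under uncontrolled illumination.

`evaluate_detection` scores a decision stream against ground truth:
reading-level confusion counts at a coverage cutoff (default 0, i.e. any
geometric overlap counts as a positive reading), plus object-level
detection (an object counts as found if at least one of its overlapping
readings fires).

## Numerical choices and degenerate inputs

* Circle overlap is the closed-form lens area with cosines clipped to
  [−1, 1] against rounding at tangency; the result is clipped to
  [0, π·r_min²]. The implementation is validated against a seeded
  Monte-Carlo rejection-sampling oracle (10⁶ points per configuration,
  configurations with ≥15% overlap of the smaller disc so the sampling
  error stays ~4σ inside the 1% comparison tolerance).
* With both σ = 0 the existence rule degenerates: the inclusive boundary
  then fires on *any* reading, including one exactly equal to the
  background mean. Kept as the rule's literal reading; real calibrations
  have σ > 0.
* Simulation sizes in the test suite (150-reading transects, 100 noise
  seeds, 200 classification trials per tone, 10⁴-draw calibration
  recovery) were chosen to put Monte-Carlo standard errors well inside
  the asserted margins while keeping the default suite around ten
  seconds.

## Known limitations

* Full regeneration of the published coverage grid is impossible: the
  green-tone σ values behind it were never published. Only the six
  luminance cells for the brightest tone are claimed (and reproduced
  exactly); remaining cells are model outputs under the quarter-range
  convention and deviate from the printed grid.
* The classifier's separability is bounded by geometry: tones whose
  difference directions from a given background are nearly colinear
  (e.g. the two brightest tones seen from grassland, cosine ≈ 0.96)
  cannot be reliably distinguished under realistic noise at small
  coverage, regardless of implementation.
* Detection probability as a continuous function of coverage is not
  modeled — only the threshold coverage, as in the underlying model.
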