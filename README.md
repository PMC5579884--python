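# labweed

True-color (CIE-Lab) plant recognition for precision spot spraying.

A point-spectral true-color sensor reads one Lab triple per circular
measuring spot (~20 cm² at 5 cm diameter) as it moves along a transect over
soil, pavement or grassland. A weed partially covering the spot shifts the
reading away from the plant-free background color. `labweed` implements the
evaluation side of such a sensor-valve-nozzle system for agronomists and
agricultural engineers:

* **Color-difference detectors** — the total difference
  ΔE = √(ΔL² + Δa² + Δb²) between a reading and the calibrated background
  mean, per-channel thresholds on ΔL, Δa, Δb, and a virtual channel
  d = |a − b|;
* **Statistical existence rule** — a plant exists if, in at least one
  channel, |ch_MA − ch_BG| ≥ σ_ch,BG + σ_ch,Obj (reading vs. background
  mean, summed noise of background and object);
* **Minimum-coverage model** — the smallest detectable plant fraction of
  the spot per background × green tone × channel,
  A_ch = 100 · (σ_ch,BG + σ_ch,Obj) / |ch_Obj − ch_BG| percent,
  which follows from the existence rule under area-weighted linear color
  mixing;
* **Multistage crop/weed differentiation** — flag suspicious readings with
  ΔE, then attribute them to a reference green tone by matching the
  *direction* of the Lab offset (cosine similarity), which is independent
  of plant size under linear mixing;
* **Spray decision modes** — positive recognition (spray on any detection)
  and negative recognition (spray unless the crop is detected);
* **Transect simulator** — disc-shaped plants on a noisy background swept
  by a circular spot (exact circle–circle overlap, seeded Gaussian channel
  noise, ground-truth coverage per reading), replacing the field hardware
  for testing and tuning.

Packaged reference databases cover ten plant-free backgrounds (seven
anthropogenic: pavings, asphalt, gravel, stone, chippings, sand; three
natural: arable land, grassland, dewy grassland) and four green color
tones from bright to dark.

## Worked example

```python
import labweed as lw

db = lw.default_database()
field = db.surface("Arable land")
g1 = db.green("Green 1")

# How much of the spot must a bright-green plant cover to be detectable
# on bare arable land via luminance?
cell = lw.required_coverage(field, g1, "L")
print(f"required coverage on {cell.background} / channel {cell.channel}: {cell.A:.1f}%")
print(f"= plant area {lw.min_plant_area(cell.A, lw.SpotGeometry(5.0))} cm^2 in a 5 cm spot")

# Simulate a paved-ground transect with four small plants and detect them.
paving = db.surface("Grey paving stones")
objects = tuple(
    lw.SceneObject(center_x=30.0 * (i + 1), center_y=0.0, radius=1.0,
                   green=db.green(f"Green {i + 1}"))
    for i in range(4)
)
spec = lw.SceneSpec(background=paving, objects=objects, seed=42)
tr = lw.make_transect(spec)
thr = lw.Thresholds(t_dE=5.0)
decisions = [lw.detect_delta_e(c, paving.stats, thr) for c in tr.colors()]
m = lw.evaluate_detection(decisions, tr)
print(f"objects detected: {m.objects_detected}/{m.objects_total}, "
      f"false positives: {m.fp}, precision: {m.precision:.2f}")

# Which green tone is the flagged reading at x = 60 cm?
best, score = lw.classify_green(tr.colors()[60], paving.stats, list(db.greens))
print(f"reading at x=60 cm attributed to {best.name} (cosine score {score:.3f})")
```

Output:

```
required coverage on Arable land / channel L: 0.5%
= plant area 0.1 cm^2 in a 5 cm spot
objects detected: 4/4, false positives: 0, precision: 1.00
reading at x=60 cm attributed to Green 2 (cosine score 0.995)
```

A bright green plant needs to cover only 0.5% of the spot (about 0.1 cm²)
to stand out from bare arable land in luminance — soil without vegetation
is the easiest background. On grey paving, a ΔE threshold of 5 finds all
four 1 cm-radius plants with no false alarms, and the direction-matching
classifier attributes the reading over the second object to its true tone.

## Command line

```sh
labweed calibrate readings.csv --name "my field" --category natural --out mydb.json
labweed detect readings.csv --background "Arable land" --preset paved --mode positive --out decisions.csv
labweed coverage-table --out coverage.csv
labweed simulate scene.json --seed 7 --out transect.csv
```

Threshold presets `paved` (ΔE > 5, ΔL > 5, Δa/Δb > 2), `wheat` (ΔE > 12)
and `grassland-dock` (ΔE > 7) carry the scenario-specific values for paved
ground, a young wheat stand and dock on grassland.

## Caveats

The green-tone references ship without measured standard deviations; the
quarter-range convention σ = (max − min)/4 is applied where σ is needed.
Coverage predictions for channels a, b and d therefore depend on that
convention — see `docs/methods.md` for the model's assumptions and known
transcription issues in the reference tables.
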