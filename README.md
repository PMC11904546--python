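# craniometrics

Landmark-based 3D craniometry for craniosynostosis follow-up: anatomical
reference frames, 12-layer head slicing, vault symmetry and aesthetic
indices, calibrated 2D cephalometrics, age-adjusted outcome statistics and
KIDSCREEN-52 quality-of-life scoring — with a synthetic head generator
whose expected measurements are known in closed form.

## Who this is for

Clinical researchers and engineers working with 3D photogrammetry of
infant heads (scaphocephaly, trigonocephaly, anterior plagiocephaly) who
need objective, reproducible indices to quantify pre- and postoperative
skull shape, and the surrounding bookkeeping: radiograph distance/ratio
catalogues, group comparisons adjusted for age, and quality-of-life sum
scores.

## The model in brief

From five facial landmarks a right-handed anatomical frame is built:
origin at the tragus midpoint, Y anterior toward the canthus midpoint,
X the midsagittal-plane normal (lateral), Z = X × Y (superior). The head
above the base plane is cut into 12 equal layers; layer 0 (face/base band)
is excluded and layers 1–11 analysed. Per slice k with AP extent
`length_k` and ML extent `width_k`:

* cranial index `CI = mean_k( 100 · width_k / length_k )`
* cranial length/width = `max_k length_k`, `max_k width_k`
* diagonals A/B: chords through the slice centroid at ±30° off the AP
  axis; asymmetry = |A − B|
* quadrant volumes `Q1..Q4` (anterior R/L, posterior R/L) = contour pieces
  cut by the midsagittal and coronal planes, × layer thickness, in ml
* `ASR = min(Q1,Q2)/max(Q1,Q2)`, `PSR = min(Q3,Q4)/max(Q3,Q4)` (1 =
  perfect symmetry; reciprocal convention selectable)
* frontal angle at the nasion between the lateral-orbit rays; per-side
  frontoparietal angles at the nasion between the same-side lateral-orbit
  and parietal rays (axial projection).

Group comparisons fit `value = b0 + b1·group + b2·age` by least squares
(ANCOVA) and label p values in four tiers (<0.01 highly significant,
<0.05 significant, <0.1 mildly significant, otherwise not).
See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

```bash
craniometrics generate --preset scaphocephaly --out head.ply --landmarks-out lm.json
craniometrics measure --mesh head.ply --landmarks lm.json --out record.csv
```

`record.csv` holds the per-subject value vector (90+ named values). The
headline rows for the scaphocephaly exemplar:

```
name,value,units,layer
cranial_length_cm,19.998618125915527,cm,
cranial_width_cm,11.999546527862549,cm,
cranial_index_pct,70.01059541652623,%,
asr,0.9999259362943456,,
frontal_angle_deg,153.0,deg,
```

A long (20 cm), narrow (12 cm) head with a slice-averaged cranial index of
70 — the classic scaphocephalic pattern (a control head scores ~88) — and
perfect anterior symmetry (ASR 1). The same library calls are available in
Python:

```python
from craniometrics import load_preset, generate_head, measure_all

mesh, landmarks = generate_head(load_preset("anterior_plagiocephaly"))
record = measure_all(mesh, landmarks)
print(round(record["asr"], 3))          # 0.8   (flattened side / bossed side)
print(round(record["frontoparietal_angle_mean_deg"], 1))  # 134.0
```

Radiograph tables, cohort comparisons and questionnaire scoring follow the
same pattern via `craniometrics measure2d`, `craniometrics compare` and
`craniometrics score-qol` (see `--help` on each command).

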