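# rootplan

CT-based morphometry and quantitative graft planning for valve-sparing
aortic root replacement (David reimplantation).

During reimplantation the surgeon must decide, before or on the table, the
tube-graft size, how far to plicate its bottom and distal ends, and where —
horizontally along the graft circumference and vertically above the annular
plane — to fix the three valve commissures. `rootplan` turns 3D landmark
coordinates exported from a CT workstation (the ordered annulus contour,
the three cusp nadirs, the three commissure apices, per-cusp geometric and
effective heights) into those numbers, and provides the method-comparison
statistics (ICC, Bland–Altman, absolute error / error rate) used to
validate automated landmark measurements against expert readers.

## The measurements and rules

With the virtual basal ring (VBR) plane fitted through the three cusp
nadirs and the annulus contour projected onto it:

- **Estimated VBR diameter** — the ring treated as a circle, sized as the
  mean of the area-equivalent and perimeter-equivalent diameters,
  ½·(2·√(A/π) + P/π); the **ellipticity index** (major/minor
  centroid-through chord, > 1.2 = oval) flags non-circular rings.
- **Commissure circle area** CCA = π·R², R the circumradius of the three
  commissure apices; **intercommissural distances** a, b, c are the 3D
  chords between adjacent commissures; **commissural height** d is each
  apex's perpendicular distance from the VBR plane.
- **Cusp angles** α, β, γ = 360°·(a, b, c)/(a+b+c) place the commissures
  around the graft; on a 34 mm graft one degree is π·34/360 ≈ 0.3 mm of
  circumference.
- **Predicted commissural height** f = √(d² + e²) with
  e = √(CCA/π) − VBR/2, the radial offset the commissure loses when pulled
  onto the straight graft wall.
- **Cusp coaptation height** cCH = gH − VBR/2; if the measured VBR exceeds
  30 mm or regurgitation is more than mild, the planned VBR is reduced by
  2–4 mm (default 3) before sizing.
- **Graft plan** — graft 6–8 mm over the planned VBR (inventory
  30/32/34 mm), bottom plicated to planned VBR + 4 mm, commissural heights
  expressed in ~1.5 mm fabric crimps, sinotubular junction plicated back to
  the planned VBR in three equal inter-commissural panels.

A parametric synthetic-root generator (elliptical ring, commissures on a
cylinder, smooth contour noise, rigid transforms) provides geometry with
exact analytic ground truth, so the whole pipeline is testable without any
patient data.

## Worked example

Generate a circular reference root (ring diameter 28 mm, commissure circle
radius 20.58 mm, commissural heights 22.6/23.0/24.9 mm), measure it, and
plan the graft:

```sh
rootplan simulate --n 1 --seed 11 --preset circle --out-dir demo
rootplan measure --in demo/root_000.json --out demo/measurements.json
rootplan plan --in demo/measurements.json --out demo/plan.json
```

which prints:

```
estimated VBR diameter 28.0 mm, ellipticity index 1.00, CCA 1333.8 mm2
Graft plan
----------
planned VBR diameter : 28.0 mm
graft size           : 34 mm
graft bottom         : plicate to 32.0 mm
STJ plication        : to 28.0 mm (18.9 mm circumference, 6.3 mm/panel)

commissure  angle     arc      predicted CH   crimps
   NL         0.0°     0.0 mm    23.5 mm      16
   LR       114.6°    34.0 mm    23.9 mm      16
   RN       238.9°    70.9 mm    25.8 mm      17

cusp coaptation height: L 4.6 mm  R 4.0 mm  N 6.7 mm
```

Reading: the 28 mm ring takes a 34 mm graft (28 + 6); its bottom is
plicated to 32 mm. The three commissures are marked 0, 34.0 and 70.9 mm
along the graft circumference and fixed 23.5/23.9/25.8 mm above the
basal suture line — about 16, 16 and 17 fabric crimps. All cusps retain
≥ 4 mm of coaptation reserve, so no warning is raised.

The `agree` subcommand takes a long-format CSV (`case_id, parameter,
rater, value`, two raters) and writes per-parameter agreement reports
(AE, ER, ICC(2,1) with 95% CI, Bland–Altman limits, fixed-error p).

## Layout

- `src/rootplan/root_measure.py` — landmark geometry → measurements
- `src/rootplan/graft_planner.py` — measurements → graft plan
- `src/rootplan/agreement_stats.py` — two-rater method comparison
- `src/rootplan/synthetic_roots.py` — parametric generator + ground truth
- `src/rootplan/io.py`, `src/rootplan/cli.py` — formats and the
  `measure | plan | agree | simulate` CLI
- `docs/methods.md` — model, conventions, numerical choices, limitations
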