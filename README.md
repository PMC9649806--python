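# osteosim

3D virtual medial open-wedge high tibial osteotomy (MOWHTO) simulation on
synthetic proximal tibiae, with posterior-tibial-slope (PTS) morphometry
and the associated repeated-measures statistics.

The package reproduces, end to end, the dose-response between the
sagittal osteotomy inclination angle and the change in posterior tibial
slope:

1. **synthetic tibiae** — parametric, watertight triangulated proximal
   tibia + shaft models with named anatomical landmarks, built from
   stacked convex cross-sections (anteriorly narrow, posteriorly wide,
   medially deep) with a metaphyseal flare; per-subject size/shape
   variation and a randomized rigid pose (`osteosim.synthetic`);
2. **anatomical frame** — joint plane from three plateau landmarks,
   mediolateral x-axis from best-fit circles on the medial/lateral
   plateau margins, true-lateral orthographic projection
   (`osteosim.frame`);
3. **virtual osteotomy** — P1 (anteromedial start, 3.5 cm below the
   medial plateau end), P2 (hinge: 1.0 cm medial to the lateral cortex,
   1.5 cm below the joint surface, at the AP articular midpoint), P3
   (posteromedial cortex placed so the projected P1-P3 line makes a
   prescribed signed inclination angle with the medial plateau line);
   watertight plane split; wedge opening about an in-plane hinge axis
   through P2 solved so the anterior/posterior gap ratio is 0.67 and the
   coronal correction matches the prescribed correction angle; closure
   (restoration) round trip (`osteosim.osteotomy`, `osteosim.mesh`);
4. **measurement** — PTS as the angle between the medial plateau line
   and the perpendicular to the shaft-bisecting axis in true-lateral
   view (`osteosim.measure`);
5. **statistics** — repeated-measures ANOVA with Mauchly's test and
   Huynh-Feldt correction, Bonferroni pairwise comparisons, paired
   t-tests vs. pre-op, and a REML linear mixed model (random intercept;
   independent or AR(1) residuals; AIC/BIC selection)
   (`osteosim.stats`);
6. **experiment driver / CLI** — one-command reproduction of the
   30-subject x 13-angle experiment (`osteosim.experiment`,
   `osteosim.cli`).

## CLI

```sh
osteosim all --seed 1 --out results/run1          # full experiment
osteosim all --seed 1 --n-subjects 5 --angles=-10,0,10 --out results/small
osteosim generate --seed 1 --export-meshes ply --out results/meshes
osteosim stats --out results/run1                  # re-run stats stage only
```

Stages (`generate` / `osteotomize` / `measure` / `stats` / `all`) share
an output directory and a YAML config (`--config cfg.yaml`; see
`ExperimentConfig.to_dict()` for the schema). Every output CSV carries
the config hash in a header comment; fixed seed implies byte-identical
outputs.

Outputs include the long-format subject x angle table
(`long_table.csv`), per-angle slope summaries
(`table_slope_by_angle.csv`), ANOVA/pairwise/paired-test tables, the
mixed-model slopes (`lmm_slopes.csv`) and scatter/CI data
(+ `--plot` for a PNG).

## Conventions

- Units: mm and degrees; right-handed coordinates.
- Inclination angle: signed angle between the projected P1-P3 line and
  the medial plateau line; positive = anterior part of the cut inclined
  distally (P3 moves proximally).
- PTS: positive when the plateau slopes posteriorly-distally.
- Frame: x medial-to-lateral, y anterior, z = x cross y (proximal on
  right-side, distal on left-side models); measurements use the
  side-independent `proximal_dir` (joint-plane normal).
- Gaps are measured at P1/P3 perpendicular to the distal cut plane;
  for an in-plane axis u through P2 the gap is `(n x u).(q - P2) sin(phi)`.
- The analysis long table adds a small seeded Normal "reading" error
  (default SD 0.35 deg, `reading_sd`, 0 disables) to the geometric
  measurements, emulating manual measurement on captured images;
  geometric (noise-free) values are kept alongside in `outcomes.csv`.
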