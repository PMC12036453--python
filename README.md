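# stiflemorph

Mesh-based morphometry of rodent knee (stifle) ligaments and menisci, with a
seeded synthetic-geometry generator and the nonparametric statistical battery
used for cohort comparisons.

## What it does

- **Ligament CSA** — converts a tissue STL to a surface point cloud, aligns
  the longitudinal axis to z by principal components, sections it at the
  species slice increment (0.1 mm rat / 0.05 mm mouse), takes the projected
  2D convex-hull area per slice, and averages the slices in the middle 50%
  of the axial extent (the midsubstance), excluding the flared insertions.
- **Meniscus regional heights/widths** — rotates the meniscus to an anatomic
  frame, takes the middle three coronal slices at the central body and the
  middle three sagittal slices at each horn, measures ten equally spaced
  stations per slice (slice value = station maximum), and averages three
  slices per region.
- **Footprint normalization** — tibial plateau area from a single-slice
  voxel mask (count × in-plane voxel area) or a planar trace (shoelace),
  and ligament CSA as a percent of it.
- **Statistics** — Shapiro–Wilk/Bartlett gating, tie-corrected
  Kruskal–Wallis with pairwise post hoc tests (rank-sum + Bonferroni, or
  Tukey on ranks), aligned-rank-transform two-way factorial ANOVA,
  Wilcoxon rank-sum (exact for small n), Bland–Altman limits of agreement,
  two-way absolute-agreement single-measure ICC, and mean ± SD summaries.
- **Synthetic cohorts** — ligament tubes with exact section-polygon areas,
  C-shaped wedge menisci with prescribed regional height/width fields, and
  plateau masks, all seeded and with an exact ground-truth table, at rat
  and mouse scales.

All coordinates are millimetres; STL files are assumed mm.

## CLI

```bash
# generate a seeded synthetic cohort (STL + plateau masks + truth.csv)
stiflemorph simulate --species rat --n 10 --seed 7 --out cohort/

# measure
stiflemorph ligament --stl 'cohort/*_ACL.stl' --species rat --out acl.csv
stiflemorph meniscus --stl 'cohort/*_MEN.stl' --species rat --out menisci.csv
stiflemorph footprint --mask 'cohort/*_PLATEAU.csv' --out footprints.csv
stiflemorph normalize --ligament-csv acl.csv --footprint-csv footprints.csv --out norm.csv

# stats + summary on a long-format table
stiflemorph stats --table measurements_long.csv --design oneway_ligament --out stats.json
stiflemorph report --table measurements_long.csv --out summary.csv

# everything end to end, reproducibly (manifest with checksums)
stiflemorph run-all --species rat --n 10 --seed 7 --out run/
```

`run-all` is deterministic: identical config + seed produce byte-identical
CSV/JSON outputs.

## Layout

```
src/stiflemorph/
  mesh_io.py    STL + voxel-mask I/O, welded point clouds
  synthetic.py  seeded generators with exact ground truth, species presets
  ligament.py   axis alignment, slicing, hull CSA, midsubstance averaging
  meniscus.py   anatomic frame, region slices, station heights/widths
  footprint.py  plateau area (mask/trace) and CSA normalization
  stats.py      KW / ART / rank-sum / Bland–Altman / ICC / summaries
  cli.py        typer CLI and end-to-end orchestration
```
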