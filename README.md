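# sgquant

Quantitative image analysis of secretory-granule (SG) partitioning and
exocytosis in dividing neuroendocrine cells (PC12-type), built for three
measurements that together describe what happens to hormone-storing
granules during mitosis:

1. **Cortical localization** — the fraction of granules whose centroid
   lies within a 500-nm shell of the plasma membrane (the operational
   definition of a *morphologically docked* granule), computed per cell
   from a digitized membrane outline and granule centroids, and compared
   between stage classes (interphase vs metaphase) with a pooled
   two-sample Student's t-test on the per-cell percentages.
2. **Surface exocytosis** — semi-automatic densitometry of surface-exposed
   secretogranin II (SgII) immunostain: cells are segmented from a uniform
   WGA membrane stain by marker-controlled watershed, the outer borders of
   cell clusters are dilated by 3 px to each side into a 7-px surface
   ribbon, the mean SgII intensity in the ribbon is background-corrected
   against unstimulated control cells, and each cell is classified as a
   *responder* iff its corrected mean is positive. Population summaries
   report the responder percentage per stage class and the
   metaphase/interphase relative intensity.
3. **Granule transport** — Laplacian-of-Gaussian punctum detection,
   greedy mutual-nearest-neighbour track linking, directed-motion
   classification (straightness ≥ 0.8 over ≥ 4 frames), mean velocity in
   μm/s (path length over duration), and track–microtubule colocalization
   against a filament skeleton via a distance transform.

Because no raw imaging data accompany the study this package reproduces,
every analysis ships with a seeded synthetic generator
(`sgquant.synth`) that emulates the relevant image structure — clustered
cells with bright closed membrane rings, punctate surface signal on
responder cells only, EM-style granule point sets with a controllable
cortical fraction, directed tracks with localization noise — together
with exact ground truth. Named presets pin the generators at the study's
measured parameter values (70%/13% cortical fractions, 227/376 fixture
granule totals, 0.81/0.67 responder probabilities, 0.61 metaphase
intensity factor, 0.23/0.34 μm/s velocities), so every headline number is
checked by parameter recovery.

## Worked example

```python
from sgquant.synth import presets, generate_em_scene
from sgquant.cortical import cortical_fraction, compare_groups

interphase = generate_em_scene(presets.get("em_interphase", n_cells=3, seed=1))
metaphase = generate_em_scene(presets.get("em_metaphase", n_cells=3, seed=2))
res_i = [cortical_fraction(s, shell_thickness_nm=500.0) for s in interphase]
res_m = [cortical_fraction(s, shell_thickness_nm=500.0) for s in metaphase]
for r in res_i + res_m:
    print(f"{r.stage_class:<10} cell {r.cell_id}: "
          f"{r.n_cortical}/{r.n_total} cortical ({100*r.fraction:.1f}%)")
comp = compare_groups(res_i, res_m)
print(f"t = {comp.t:.2f}, df = {comp.df}, p = {comp.p:.2e}")
```

prints

```
interphase cell 1: 47/75 cortical (62.7%)
interphase cell 2: 55/75 cortical (73.3%)
interphase cell 3: 50/75 cortical (66.7%)
metaphase  cell 1: 19/125 cortical (15.2%)
metaphase  cell 2: 12/125 cortical (9.6%)
metaphase  cell 3: 11/125 cortical (8.8%)
t = 15.21, df = 4, p = 1.09e-04
```

Interphase cells keep roughly 70% of their granules within the cortical
shell; in metaphase that collapses to near 13%, and with only three cells
per group the pooled t-test already separates the conditions decisively.

The exocytosis pipeline runs the same way from Python
(`sgquant.pipeline.run_exocytosis`) or from the shell:

```sh
sgquant simulate fluor --preset fluor_stimulated --seed 7 --out stim/
sgquant simulate fluor --preset fluor_control --seed 8 --out ctrl/
sgquant quantify-surface --scene stim/scene.tif --control ctrl/scene.tif --out results/
```

`sgquant simulate em|tracks`, `sgquant cortical` and `sgquant run
--config run.yaml` cover the other stages; every preset field can be
overridden with `--set field=value`, and every output embeds the config
hash of the run that produced it.

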