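# ommech

Quantitative analysis of AFM force spectroscopy, AFM topography and dynamic
light scattering (DLS) for synthetic bacterial outer-membrane models —
supported DMPC bilayers, LPS-doped and OM-protein-reinforced membranes, and
LPS vesicles — together with synthetic-data generators that emulate each
sample class with known ground truth.

## Who this is for

Membrane biophysicists who record force–distance curves, height images and
correlograms on supported lipid bilayers (SLBs) and want a reproducible,
scriptable pipeline for the standard readouts:

* **Force spectroscopy** (`ommech.forcespec`) — median filtering and baseline
  removal, contact-point estimation, breakthrough (membrane-rupture) step
  detection with the conventional 0.1 nN / 0.1 nm gates, rupture-force and
  rupture-thickness measurement, α/β/γ population classification, batch
  summaries and 2D force–thickness scatter maps.
* **Topography** (`ommech.imagetex`) — scan-line artifact removal (per-row
  polynomial leveling iterated against a multi-plateau height model), phase
  segmentation by multi-Otsu thresholds, coverage fractions, RMS roughness
  R_q, height profiles, stripe-texture periodicity by windowed 2D FFT, and
  vesicle sizing by the equal-area disc diameter at half-maximal height.
* **DLS** (`ommech.dlsinv`) — the Siegert / Stokes–Einstein forward model
  g₂(τ) = 1 + β|Σᵢ wᵢ e^(−q²Dᵢτ)|², with D = k_BT/(3πηd) and
  q = 4πn·sin(θ/2)/λ, and a maximum-entropy (MEM) inversion of measured
  correlograms to intensity-weighted particle-size distributions.
* **Synthetic data** (`ommech.synthgen`) — piecewise-elastic approach curves
  with stochastic breakthroughs per membrane scenario, height maps with
  multi-level phases, rough LPS domains, periodic stripes, vesicle caps and
  scan-line artifacts, and correlograms from known size distributions; every
  artifact ships with a truth record and regenerates bit-identically from an
  integer seed.

The rupture-step detector, the leveling scheme, the cap-sizing convention and
the MEM solver are the substantive parts; everything else rides on numpy,
scipy, scikit-image, pandas, scikit-learn, tifffile, click and PyYAML.

## Worked example

Simulate a 400-curve LPS-DMPC batch (a low-force oligosaccharide layer in
95% of curves, then the bilayer proper), detect and classify the rupture
events, and summarise:

```python
from ommech import synthgen, forcespec

preset = synthgen.get_force_preset("LPS-DMPC")
curves, truths = synthgen.gen_force_batch(preset, 400, seed=3, noise_sd=0.05)
results = forcespec.analyze_batch(curves, min_force=0.1, min_thickness=0.1)
forcespec.classify_events(results)
s = forcespec.summarize_curves(results, batch="LPS-DMPC")
print(f"mean final rupture force: {s['mean_final_rupture_force']:.2f} "
      f"+/- {s['sd_final_rupture_force']:.2f} nN")
print(f"mean step count:          {s['mean_step_count']:.2f}")
print(f"beta-without-alpha:       {s['frac_beta_without_alpha']:.3f}")
for name, pop in s["populations"].items():
    print(f"population {name}: n={pop['count']}, "
          f"<F>={pop['mean_force']:.2f} nN, <t>={pop['mean_thickness']:.2f} nm")
```

prints

```
mean final rupture force: 1.37 +/- 0.47 nN
mean step count:          1.90
beta-without-alpha:       0.082
population alpha: n=360, <F>=0.52 nN, <t>=3.10 nm
population beta: n=392, <F>=1.36 nN, <t>=5.10 nm
population gamma: n=8, <F>=2.00 nN, <t>=5.35 nm
```

i.e. the batch recovers the generator's final rupture force (1.4 ± 0.5 nN),
its two-step piercing signature (initial low-force α events followed by the
bilayer β rupture), and the small fraction of curves where the bilayer
ruptures without a preceding α step.

The same stages are available from the shell:

```bash
ommech simulate --preset LPS-DMPC -n 400 --seed 3 --out runs/sim
ommech analyze-fs --curves runs/sim/curves_LPS-DMPC.tsv --out runs/fs
ommech analyze-image --map map.tif --flatten-order 1 --out runs/img
ommech analyze-dls --corr corr.tsv --grid 1:1000:60log --out runs/dls
ommech run-all --out runs/full --seed 1
```

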