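# cristamorph

Morphometry of mitochondrial cristae in electron tomograms.

Cardiomyocyte mitochondria pack their inner membrane into *cristae* whose
architecture — flat lamellar plates about 20 nm apart, worm-like tubes
50–90 nm across, "transitional" rows of small 30–60 nm tubes, or mixtures —
sets how much ATP-producing membrane fits into a given organelle volume and
how fast metabolites diffuse in and out of the crista compartments.
`cristamorph` is a tested, scriptable pipeline for quantifying that
architecture from 3-D tomographic slabs and traced 2-D contours, aimed at
electron-microscopy groups who today do these measurements with a chain of
interactive tools.

The package computes, per mitochondrial profile and per crista:

* **A_MIT**, **AR** — cross-section area and aspect ratio
  (longest/shortest dimension) of the profile;
* **L_CRIS/A_MIT** and **L_IM/A_MIT** — crista and inner-membrane densities
  (µm⁻¹), with membrane folding **L_CRIS/L_IM**;
* **S_CRIS**, **V_CRIS**, **S/V** — per-crista membrane area, enclosed
  volume and surface-to-volume ratio from triangulated meshes, with
  slab-sealing caps tagged and excluded from native membrane area (for long
  tubes of diameter D, S/V → 4/D; for plate compartments separated by D,
  S/V → 2/D);
* crista-junction openings (count, size, round vs slot) and fenestrations
  (count by surface genus, width by maximal inscribed circle);
* rule-based morphology (Lam / Tub / Trans / Mix), cell-location
  (interfibrillar / subsarcolemmal / other by 50 nm proximity) and
  crista-swelling flags;
* group statistics: contingency tables, class means ± SD, pooled two-tailed
  t-tests, scatter exports.

Because tomograms of this kind are rarely public, the package includes a
first-class synthetic phantom generator (`cristamorph.phantom`) that renders
all four crista morphologies inside an outer-membrane/IBM envelope with
analytic ground truth — every stage of the pipeline is validated by
recovering known geometry from corrupted phantoms.  `docs/methods.md`
describes the models, conventions and limitations.

## Worked example

```python
from cristamorph import PhantomSpec, generate_phantom, corrupt
from cristamorph.config import PipelineConfig
from cristamorph.pipeline import run_pipeline

config = PipelineConfig(
    phantom=dict(morphology_class="lamellar", voxel_size=2.5,
                 slab_thickness_nm=150.0, envelope_semi_axes=(220.0, 220.0),
                 crista_params={"n_plates": 4}),
    seed=11,
)
report = run_pipeline(config)
print(report["morphology"],
      report["stages"]["simulate"]["crista_density_3d_um"],
      report["crista_density_3d_um"])
```

prints

```
Lam 19.20064648421677 18.661198649779113
```

— the phantom was built with four lamellar plates (an analytic crista
density of 19.2 µm⁻¹ of membrane area per mitochondrial volume), corrupted
with blur and noise, and the full pipeline (rolling slice average,
anisotropic diffusion, Hessian membrane enhancement, thresholding,
compartment recovery, marching-cubes meshing) classified the profile as
lamellar and recovered the density within 3 %.  The report embeds the
effective configuration and every stage's parameters, so each number is
traceable to parameters + seed.

The same stages are available as a CLI for file-based work
(`cristamorph simulate | enhance | segment | measure | classify | stats |
run`), reading and writing MRC volumes, OBJ/PLY meshes, contour JSON, IMOD
ASCII point listings and CSV record tables.

## Analysis scripts

The numbered scripts under `analysis/` run the package's benchmark studies
and write their tables under `results/`:

1. `01_simulate_phantoms.py` — one reference phantom per morphology class;
2. `02_profile_morphometry.py` — 2-D profile metrics, classification and
   group statistics over a 40-phantom cohort (the lamellar phantoms carry
   roughly twice the crista density of the tubular ones);
3. `03_density_recovery.py` — full-pipeline recovery of 12 prescribed
   crista densities spanning ~10–38 µm⁻¹;
4. `04_classification.py` — classification accuracy on clean contours and
   on noisy volumes;
5. `05_crista_3d_structure.py` — S/V limits, fenestration and junction
   recovery.

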