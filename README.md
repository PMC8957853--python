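# cytomap

Probabilistic cytoarchitectonic maps and stereological volumetry of paired
subcortical nuclei — the medial and lateral geniculate bodies (MGB, LGB) of
the metathalamus — reconstructed from serial histological delineations.

Postmortem volumetry studies delineate a nucleus on sparse serial sections
(every *k*-th section of thickness *T*), estimate its volume by Cavalieri's
principle, correct for tissue shrinkage, normalise by brain volume, test
group effects by Monte-Carlo permutation, and superimpose the spatially
normalised delineations of a cohort into voxel-wise overlap ("probability")
maps. The raw delineations behind published studies are rarely reusable, so
this package pairs the full analysis pipeline with a synthetic cohort
generator whose nuclei are ellipsoids with closed-form volumes — every
estimator can be validated against analytic ground truth.

It is aimed at researchers in quantitative neuroanatomy and at method
developers who need a testbed for stereology, label-volume reconstruction
and atlas-building code.

## The quantities computed

* **Cavalieri volume** from profile areas `A_i` on sections a distance
  `d = k·T` apart: `V = d · Σᵢ Aᵢ` (unbiased under systematic sampling).
* **Shrinkage correction** `V_corr = V_raw · f`, with `f ≥ 1` the per-brain
  volumetric shrinkage factor of histological processing (e.g. 1.931 for a
  whole-brain histological dataset), and **normalisation**
  `p = V_corr / V_brain`.
* **Permutation tests** for hemisphere, sex and their interaction on the
  normalised volumes: observed contrast `C = mean(g₁) − mean(g₂)`, null by
  random relabeling, `p = (1 + #{C_null ≥ C}) / (1 + n_iter)`; plus a
  paired two-sided *t*-test comparing the two nuclei.
* **Probability maps**: after affine transport of each subject's
  reconstructed delineation into a common reference grid,
  `percent(v) = round(100 · n_covering(v) / n)`, with centre-of-mass
  reporting per hemisphere in mm.
* **Surface meshes** by marching cubes, smoothed along vertex normals,
  with enclosed volume from the divergence theorem as a cross-check on
  voxel counts.

## Worked example

```bash
cytomap pipeline run --config config/default.yaml --out out/
```

simulates ten subjects (5 female / 5 male, ~two-fold volume variability,
coronal sections on a 0.3 mm sampling lattice), and writes `volumes.csv`,
permutation and t-test JSONs, two probability maps with centres of mass,
and per-structure surface meshes. With the default seed the cohort means of
the shrinkage-corrected Cavalieri estimates are

```
structure   left   right   (mm^3)
MGB        134.6   134.7
LGB        168.3   168.4
```

i.e. bilateral MGB 269.3 ± 39.1 mm³ and LGB 336.7 ± 49.2 mm³. The paired
t-test on the bilateral volumes gives t(9) = −21.3, p ≈ 5e−9 — the MGB is
generated smaller than the LGB and the pipeline recovers that ordering —
while hemisphere, sex and interaction permutation tests stay at chance
(e.g. hemisphere on the MGB: C = −1.9e−8, p = 0.997 at 10⁴ iterations),
matching the null generator. Centres of mass land on the generating
geometry, e.g. right MGB at (15, −25, −8) mm. Every estimate can be
compared against `out/cohort/ground_truth.csv`; on the default cohort the
mean relative error of the corrected Cavalieri volumes is below 1%.

Library use mirrors the CLI:

```python
from cytomap import (CohortSpec, generate_cohort, slice_volume,
                     cavalieri_volume, correct_shrinkage)

records, volumes, truth = generate_cohort(CohortSpec(seed=0))
stack = slice_volume(volumes[0], labels=[1, 2, 3], thickness=0.1,
                     interval=3, hemisphere="left", structure="MGB")
v = correct_shrinkage(cavalieri_volume(stack), records[0].shrinkage_factor)
```

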