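# mcshape

Shape radiomics of the Meckel cave (MC) — the dural recess in the middle
cranial fossa that houses the trigeminal ganglion. In primary trigeminal
neuralgia (PTN), morphometry of the MC (in particular its *flatness*) has
been proposed as an etiological factor alongside neurovascular contact
(NVC). `mcshape` provides the three pieces needed to study that question
quantitatively and to validate the whole chain without access to clinical
MRI data:

1. **Feature extraction** — the ten standard 3D shape features of a binary
   segmentation mask: voxel volume, surface area, maximum 3D (Feret)
   diameter, maximum 2D diameters in the axial/coronal/sagittal planes,
   major/minor/least axis lengths, and flatness.
2. **Synthetic cohorts** — bilateral ellipsoid phantoms with known ground
   truth and configurable group/side/NVC effects, emulating a 115-patient
   PTN + 46-control study design.
3. **Statistics** — the full bilateral-morphometry battery: exact binomial
   laterality test, paired side comparisons, OLS group contrasts, Kendall
   tau-b correlation screen, demographics, NVC cross-tabs, and the no-NVC
   subgroup analysis, emitted as four CSV tables plus figures.

## The features

For a mask with occupied voxels of volume $V_k$ and a triangulated surface
mesh with triangles $(a_i, b_i, c_i)$:

$$V_{voxel} = \sum_{k=1}^{N_v} V_k, \qquad
  A = \sum_{i=1}^{N_f} \tfrac12 \lVert (b_i - a_i) \times (c_i - a_i) \rVert$$

The maximum 3D diameter is the largest pairwise Euclidean distance between
surface-mesh vertices (computed on the convex hull, which provably attains
the all-pairs maximum); the 2D diameters drop one grid axis first. Axis
lengths derive from the eigenvalues $\lambda_{major} \ge \lambda_{minor}
\ge \lambda_{least}$ of the population covariance of occupied voxel-center
coordinates:

$$\text{axis length} = 4\sqrt{\lambda}, \qquad
  \text{flatness} = \sqrt{\lambda_{least} / \lambda_{major}} \in [0, 1]$$

Flatness is 1 for a sphere and 0 for a flat (single-slice) object; for a
solid ellipsoid with semi-axes $a \ge b \ge c$ it converges to $c/a$.

## Worked example

Simulate a 60 + 20 subject cohort with the default affected-side flatness
deficit of 0.02, extract all features, and run the battery:

```sh
mc-shape demo --out demo_example --seed 42 --n-ptn 60 --n-hc 20 --spacing 0.5
```

The flatness rows of the resulting `table2.csv`:

```
 feature                    comparison  n_a  n_b   mean_a     sd_a   mean_b     sd_b  statistic  p_value
Flatness HC both sides vs PTN affected   40   60 0.396038 0.059330 0.389578 0.058422  -0.538279 0.591605
Flatness    PTN affected vs unaffected   60   60 0.389578 0.058422 0.414860 0.050159  -2.961485 0.004406
Flatness             PTN left vs right   60   60 0.417978 0.049836 0.386461 0.057143   3.853900 0.000289
Flatness              HC left vs right   20   20 0.403731 0.061105 0.388344 0.058025   1.127891 0.273408
```

Read: the affected side is flatter than the unaffected side (mean flatness
0.390 vs 0.415, paired t, p = 0.004) and the right side is flatter than the
left in the patient group (p = 0.0003) — the generator injected exactly
these effects (deficit 0.02 on the affected side, left/right means
0.41/0.39), and the pipeline recovers them. The output directory also holds
`table1.csv` (demographics with chi-square/t/binomial tests), `table3.csv`
(NVC pattern cross-tab), `table4.csv` (no-NVC subgroup), `features.csv`,
box-plot figures, and a `run.log` recording version, seed, and config hash.

Library use mirrors the CLI:

```python
from mcshape import PhantomSpec, make_phantom, extract_all

mask = make_phantom(PhantomSpec(semi_axes=(10, 10, 10), spacing=(0.5,) * 3))
print(extract_all(mask).as_dict())
# voxel_volume 4175.1 (4/3*pi*10^3 = 4188.8), surface_area 1250.1
# (4*pi*10^2 = 1256.6), flatness 1.0, ...
```

Masks are ordinary NIfTI-1 files (`mc-shape features --mask roi.nii.gz`);
cohort manifests are CSV/TSV with columns `subject_id, group,
affected_side, nvc_left, nvc_right, mask_left, mask_right`.

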