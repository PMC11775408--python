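# lesionshape

3D morphometry of segmented brain lesions, built for the question of how
MRI acquisition resolution changes what we measure about glioma
T2-hyperintense areas (non-enhancing tumour, oedema and gliosis, which
appear as one bright region on T2-weighted images).

Given binary lesion masks in NIfTI format, the package computes per-lesion
volume and convex-hull shape markers; given a paired cohort — every lesion
segmented once on a high-quality scan (7 T-like, sub-millimetre isotropic)
and once on a routine clinical scan (fine in-plane grid, 3–5 mm slices) —
it runs the paired nonparametric comparison between the two conditions.
Because no public dataset of such pairs exists, a synthetic-data module
generates ground-truth lesions with controllable complexity and simulates
both acquisitions of each one, so the whole pipeline is testable end to
end and the resolution effect can be studied in silico.

## Markers

For a lesion with surface area `A` (mm², marching-cubes mesh of the
largest 26-connected component on an isotropic analysis grid), enclosed
volume `V`, and convex hull with area `A_H` and volume `V_H`:

* **volume** (mL) — voxel count x voxel volume, summed over *all*
  components (shape markers use the largest component only);
* **convexity** `C = A_H / A` — 1 for convex bodies, small for folded
  surfaces;
* **solidity** `S = V / V_H` — 1 for solid convex bodies, small for
  concave or tendrilled shapes;
* **concavity index** `CI = 2 − (C + S) / 2` — 1 at the convex limit,
  larger for more complex lesions;
* **fractal dimension** `FD` — box-counting dimension of the lesion
  boundary (dyadic box sizes, least-squares slope of log N(s) vs log s);
  ≈ 2 for smooth surfaces.

Cohort statistics: median (IQR) per condition, two-sided Wilcoxon
signed-rank test per marker (exact p by full sign enumeration up to
n = 25, normal approximation with tie and continuity correction beyond),
Bland–Altman limits of agreement, and a sensitivity re-analysis excluding
subjects with lesions below 10 cm³ in either condition.

## Worked example

```sh
python examples/resolution_degradation.py
```

generates one fissured lesion with low-contrast tract extensions,
observes it with both scanner models, and prints:

```
marker                truth   7T-like  clinical
volume (mL)           12.083    11.738    10.421
convexity              0.829     0.878     0.944
solidity               0.409     0.404     0.677
concavity index        1.381     1.359     1.190
fractal dim.           2.109     2.075     2.051
components                 1         1         2
```

The 7 T-like arm tracks the ground truth; the clinical arm fills in the
narrow surface fissures (higher convexity/solidity, lower concavity index
and fractal dimension), loses the faint cross-midline bridge (the
component count rises as its far end detaches), and under-reads the
volume. `examples/ball_shape_markers.py` shows the convex calibration
case and `examples/paired_cohort_comparison.py` the cohort-level test.

The same pipeline is available as a thin CLI:

```sh
lesionshape synth   --out cohort --n 28 --scenario default --seed 1
lesionshape markers --manifest cohort/manifest.csv --out cohort
lesionshape compare --out cohort --threshold-cm3 10
```

which writes `markers.csv`, a summary `report.csv` (one row per marker:
medians, IQRs, Wilcoxon W and p, Bland–Altman band), a sensitivity
report, and per-marker Bland–Altman tables. Reports are byte-identical
across reruns of the same seed.

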