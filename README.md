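# petcoreg

Digital-phantom analysis of how **rigid PET/CT coregistration perturbs PET
quantification** — for nuclear-medicine physicists and quantitative-imaging
researchers who need to know when "just rigidly aligning" PET to a CT changes
the numbers they report.

## The problem

After rigid (rotation + translation) alignment, coregistered PET is saved in
the CT geometry by **trilinear interpolation**: each output voxel is a convex
combination of the eight nearest input voxels. That resampling alone changes
lesion metrics:

* **SUVmax** — the interpolated maximum can only decrease
  (max<sub>out</sub> ≤ max<sub>in</sub>), and it drops most when the shift is
  near half a voxel; a shift by a whole-voxel multiple interpolates nothing
  and changes nothing.
* **MTV** (metabolic tumor volume, ml) — threshold segmentation at a fraction
  of the maximum moves with the depressed maximum, so volumes drift, most
  strongly on coarse 5-mm-slice CT ("CT5") and barely on 1-mm CT ("CT1").
* **TLG** = MTV × SUVmean inherits both effects.

`petcoreg` rebuilds this chain in silico — lesion phantoms with analytic
ground truth, mutual-information rigid registration with fast/slow sampling
modes, trilinear resampling onto the scanner CT grids, four threshold
segmentation methods (fixed T40/T50/T60 and a background-adapted
volume-reproducing adaptive threshold AT), and the paired agreement
statistics (Wilcoxon signed-rank, Bland-Altman 95 % limits of agreement) —
so every deviation can be traced to its mechanism. See `docs/methods.md` for
the model details.

## Worked example

Compare a necrotic lesion with a volume-matched homogeneous twin, both
shifted by half a slice on the 5-mm CT grid:

```console
$ petcoreg hetero
       lesion  d_suvmax_pct  d_mtv_pct  d_tlg_pct
  homogeneous     -2.106854   0.896861  -7.165002
heterogeneous     -6.117879   9.193777  -3.432074
```

The homogeneous lesion's maximum sits on a stable plateau: SUVmax dips only
−2.1 % and MTV moves +0.9 %. The necrotic lesion's maximum sits on a thin
rim that interpolation flattens: SUVmax drops −6.1 %, the 40 %-of-max
threshold drops with it, and the segmented volume balloons by +9.2 % — the
heterogeneity-amplification pattern seen in patient data.

The same library drives a full synthetic cohort study from Python:

```python
from petcoreg import CohortSpec, StudyConfig, run_study

res = run_study(StudyConfig(cohort=CohortSpec(n_lesions=28, seed=1), seed=1))
at = res.records[res.records.method == "AT"]
for grid in ("CT1", "CT5"):
    sub = at[at.grid == grid]
    print(grid, round(sub.d_mtv_pct.abs().median(), 2),
          round(sub.d_suvmax_pct.abs().median(), 2))
```

```
CT1 1.77 0.62
CT5 4.5 1.2
```

Median unsigned deviations of MTV and SUVmax are several-fold larger on the
5-mm grid than on the 1-mm grid — resampling onto coarse slices, not the
registration itself, drives the error.

Other subcommands: `simulate` (phantom + pseudo-CT as NIfTI, truth as CSV),
`register` (MI rigid registration, fast/slow), `resample`, `segment`,
`quantify`, `study` (full pipeline with CSV tables and run log), `sweep`
(sub-voxel shift sweep).

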