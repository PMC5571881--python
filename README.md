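# ironmark

Analysis pipeline for USPIO-enhanced MRI surveillance of abdominal aortic
aneurysms (AAA): voxelwise T2\* relaxometry, rigid pre/post-contrast
registration, a threshold/cluster rule for calling mural USPIO enhancement,
and the survival statistics that relate enhancement to aneurysm growth and
clinical outcome.

## The problem

Ultrasmall superparamagnetic particles of iron oxide (USPIO) are taken up by
tissue-resident macrophages. Where they accumulate in the aneurysm wall they
shorten the gradient-echo decay constant T2\*, so comparing T2\* maps
acquired before and 24–36 h after infusion localises cellular inflammation.
The pipeline implements the full chain a surveillance study needs:

1. **Relaxometry** — the signal in each voxel decays as
   S(TE) = S₀·exp(−TE/T2\*); a weighted log-linear least-squares fit
   (weights ∝ S², offsetting the log transform's variance distortion)
   yields voxelwise T2\*, S₀ and fit quality.
2. **Registration** — a 6-degree-of-freedom rigid, multi-resolution,
   intensity-based alignment of the post-contrast visit onto the
   pre-contrast grid (SimpleITK backend).
3. **Enhancement call** — percent change 100·(T2\*pre − T2\*post)/T2\*pre
   per wall voxel; a patient is *enhanced* when a connected cluster of
   ≥ 10 voxels each changes by ≥ 71%, *indeterminate* when too much of the
   wall ROI is unusable.
4. **Growth** — per-patient ordinary-least-squares slope of serial
   ultrasound anteroposterior diameter on time (mm/yr), with a multiple
   regression of slope on smoking, diameter, blood pressure and enhancement.
5. **Outcomes** — two-proportion comparisons (pooled-z test, unpooled Wald
   CI), Kaplan–Meier curves and the log-rank test, Cox proportional hazards
   (hand-written Newton maximisation of the Efron partial likelihood),
   Harrell's c-statistic, the category-free net reclassification index with
   a seeded bootstrap, and the events-based sample-size planner.

Since no patient data are deposited, a first-class synthetic module supplies
(a) a concentric-ellipsoid aneurysm phantom (lumen / intraluminal thrombus /
wall) with mono-exponential decay, focal post-contrast T2\* reduction,
inter-visit rigid motion and Rician magnitude noise, and (b) a clinical
cohort generator calibrated to the published summary statistics (baseline
diameter 49.6 ± 7.7 mm, growth 2.8 ± 2.4 mm/yr, diameter hazard ratio
1.077/mm, smoking hazard ratio 1.464, ultrasound CV 3.5%). Ground truth is
retained everywhere so each stage can be scored against it.

## Worked example

```python
import ironmark as im

# enhancement call on a synthetic phantom pair
call, truth = im.classify_phantom_patient(im.PhantomSpec(seed=1))
print("status:", call.status)
print("largest cluster:", call.largest_cluster, "voxels;",
      "suprathreshold:", call.suprathreshold_voxels)

# printed-count statistic
pc = im.two_proportion_compare(69, 146, 68, 191)
print("difference %.1f%% (95%% CI %.1f-%.1f), p=%.4f"
      % (100*pc.diff, 100*pc.ci_low, 100*pc.ci_high, pc.p_value))
```

prints

```
status: enhanced
largest cluster: 19 voxels; suprathreshold: 19
difference 11.7% (95% CI 1.1-22.2), p=0.0308
```

The phantom carried a wall lesion (post-contrast T2\* at 20% of its
pre-contrast value), and the full chain — fit both visits, register,
resample, threshold, cluster — recovers it as a 19-voxel suprathreshold
cluster, above the 10-voxel rule. The proportion comparison contrasts
69/146 primary endpoints in enhanced against 68/191 in non-enhanced
patients: an 11.7 percentage-point absolute difference whose 95% interval
excludes zero.

The same stages are exposed as a CLI:

```sh
ironmark simulate phantom --out phantom/ --seed 3
ironmark t2star --in phantom/pre.nii.gz --mask phantom/wall.nii.gz --out t2_pre.nii.gz
ironmark t2star --in phantom/post.nii.gz --out t2_post.nii.gz
ironmark register --fixed phantom/pre.nii.gz --moving phantom/post.nii.gz --out xform.json
ironmark classify --pre t2_pre.nii.gz --post t2_post.nii.gz --xform xform.json \
    --wall phantom/wall.nii.gz --out call.json
ironmark run --n 6 --seed 7 --out results/   # full synthetic study
```

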