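# refclust

Data-driven **reference-cluster (RC) intensity normalization** for brain
FDG-PET group studies, with the full analysis pipeline around it: synthetic
phantoms with known ground truth, classical reference normalizations, a
voxel-wise GLM with permutation family-wise-error control, cluster-extent
inference, and split-half cross-validated patient/control classification.

## The problem

PET uptake images are non-quantitative: each subject's image carries an
arbitrary global scale, so group analyses require intensity normalization —
division by a reference value such as the mean of a cerebellar or
sensorimotor VOI, or the cerebral global mean (CGM, SPM's two-pass rule:
the mean of voxels above one-eighth of the whole-volume mean). In
neurodegeneration this choice is not innocuous. Patients' regional
hypometabolism depresses their own global mean, so CGM scaling both
*underestimates* true deficits and manufactures *apparent hypermetabolism* in
spared tissue; even a-priori reference VOIs may be partially diseased.

The RC method turns the CGM artifact into a tool: on CGM-normalized data, the
patients > controls contrast highlights exactly the most-preserved tissue.
Thresholding that contrast at escalating voxel-level FWE levels
(0.05, 0.01, … 10⁻⁶) until one coherent cluster dominates yields a
disease-specific, data-driven reference region. Normalizing to the RC
enlarges the detectable hypometabolic pattern and improves single-subject
discrimination, including when the RC from one center is applied to data
acquired at another.

Because no clinical cohorts ship with this package, a first-class synthetic
module generates smoothed PET-like two-center cohorts in which patients carry
a multiplicative frontal/anterior-temporal deficit, heterogeneous diffuse
cortical involvement, and a truly spared cerebellar parcel — so every stage
of the pipeline can be scored against ground truth. See `docs/methods.md` for
the generative model and all statistical details.

## Worked example

Derive an RC on a simulated center-1-like cohort (42 controls, 41 patients,
32³ grid) and compare normalization schemes:

```python
import refclust as rc

vols, manifest, truth = rc.preset_cohort("center1", seed=1)
design = rc.build_design(manifest)          # [1, group, age-centered, sex]

# reference cluster from the increase contrast on CGM-normalized data
cgm = rc.normalize_cohort(vols, rc.ReferenceSpec("cgm"))
region = rc.derive_reference_cluster(cgm, design, atlas=truth.parcellation)

# detection + classification per scheme, features from the cerebellar pattern
parc = truth.parcellation
cbl = rc.ReferenceSpec("roi", rc.mask_from_labels(
    parc, [parc.id_of("cerebellum"), parc.id_of("vermis")]), "cbl")
pattern = rc.cluster_inference(rc.normalize_cohort(vols, cbl), design,
                               "decrease", n_perm=500, seed=2).mask()
for name, ref in [("cgm", rc.ReferenceSpec("cgm")), ("cbl", cbl),
                  ("rc", rc.ReferenceSpec("roi", region.mask, "rc"))]:
    nvols = rc.normalize_cohort(vols, ref)
    cs = rc.cluster_inference(nvols, design, "decrease", n_perm=500, seed=2)
    feats = rc.extract_pattern_means(nvols, pattern, manifest)
    dist = rc.split_half_cv(feats["mean_uptake"].to_numpy(),
                            manifest.group_indicator, n_rep=5000, seed=3)
```

Output:

```
RC: 2650 voxels at voxel-FWE alpha=0.05, Dice vs true preserved parcel = 0.79
cgm: extent  4956 voxels, peak t  12.6, accuracy 86.5% (sens 87.3%, spec 85.8%)
cbl: extent  9422 voxels, peak t  17.4, accuracy 96.1% (sens 96.7%, spec 95.6%)
 rc: extent  9635 voxels, peak t  16.0, accuracy 94.7% (sens 94.3%, spec 95.0%)
```

Reading the numbers: the escalation recovered a 2650-voxel reference cluster
that overlaps the truly spared cerebellar parcel (Dice 0.79). Under CGM
normalization the detected hypometabolic pattern is roughly half the size it
has under cerebellar or RC normalization (4956 vs ~9500 voxels) — the
underestimation artifact — and split-half accuracy drops by about ten points.
RC and full-cerebellar normalization perform similarly here because the
phantom's cerebellar VOI is only mildly contaminated; the RC's advantage is
that it finds the spared subregion without an atlas or prior.

## Command line

The `refclust` CLI wraps the same stages:

```bash
refclust simulate  --preset center1 --n-controls 20 --n-patients 20 --seed 1 --out sim/
refclust derive-rc --manifest sim/manifest.csv --seed 2 --out rc.nii.gz
refclust normalize --manifest sim/manifest.csv --ref roi --mask rc.nii.gz --out norm/
refclust detect    --manifest norm/manifest.csv --contrast decrease --nperm 2000 --seed 3 --out det/
refclust evaluate  --manifest norm/manifest.csv --pattern det/pattern_decrease.nii.gz --nrep 5000 --seed 4 --out cv.csv
refclust run       --config study.yaml    # full two-cohort study
```

`refclust run` executes the complete cross-center design (simulate both
cohorts, derive the RC on cohort A, apply it to cohort B, detect, classify,
compare) from a single YAML config with one master seed; rerunning the same
config reproduces the report byte for byte.

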