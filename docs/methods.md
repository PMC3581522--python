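# Methods

`refclust` implements data-driven reference-cluster (RC) intensity
normalization for brain FDG-PET group studies, together with the surrounding
pipeline needed to exercise and validate it: a synthetic phantom with known
ground truth, classical reference normalizations, a voxel-wise GLM with
permutation family-wise-error (FWE) control, and split-half cross-validated
classification. This note describes the models, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Intensity normalization

PET uptake images are non-quantitative; subject i's image is only defined up
to a global scale g_i. All analyses therefore work on ratio images

    y(v) = u(v) * target / R(u),

where R is the reference value: the mean over a reference region of interest
(ROI), or the cerebral global mean (CGM) computed with the classical two-pass
rule — first the mean m0 of all finite voxels, then the mean of voxels above
m0/8, which drops extracerebral background. The default target is 1.0, making
normalized images dimensionless; every downstream statistic is scale-free, so
the choice of target is cosmetic. NaN marks out-of-brain voxels and is ignored
by every reduction. Normalization is exactly idempotent and invariant to
rescaling of the input; both properties are asserted in the test suite at
1e-12/1e-10 relative tolerance.

The scientific problem with CGM normalization in neurodegeneration is that the
global mean is itself depressed by the disease. Dividing by it (i) shrinks the
apparent regional deficit ("underestimation") and (ii) manufactures apparent
hypermetabolism in spared regions ("overcorrection"). The RC method turns the
second artifact into a tool: the patients-greater-than-controls contrast on
CGM-normalized data highlights exactly the most-preserved tissue, which is
then used as the reference region.

## Voxel-wise GLM and FWE control

At each in-mask voxel we fit ordinary least squares with design
[1, group, age − mean(age), sex] (constant covariate columns are dropped and
recorded), and test the one-sided contrasts "decrease" (−1 on group) and
"increase" (+1) with t = c'b / sqrt(σ² c'(X'X)⁻¹c), df = n − rank(X). The
analysis mask is the set of voxels finite in every subject, optionally
intersected with a user mask. Voxels with zero residual variance (relative
tolerance 1e-10 of the data scale) receive a ±inf sentinel and are excluded
from null distributions. The implementation is vectorized across voxels and is
verified against per-voxel statsmodels OLS to 1e-8 on random problems.

FWE control uses the max-statistic permutation test: group labels are permuted
across subjects (covariates stay attached to their subjects), and the null
distribution of the maximum t over the mask gives the (1−α) critical value.
When there are at most n_perm distinct relabelings the enumeration is
exhaustive — on 3v3 problems the permutation p-values equal exact enumeration,
which is asserted in the tests. The identity labeling is always part of the
null set, keeping the test exact (rejection rate floor(α(n+1)−1)/n ≤ α). X'X
is inverted with a pseudoinverse because a permuted group column may
legitimately coincide with the binary sex covariate. Bonferroni over in-mask
voxels is available as a parametric fallback and is the default wherever
quantiles beyond the permutation resolution are needed (see the RC grid
below). Random-field-theory correction is deliberately not implemented: it
needs smoothness estimation that ratio phantoms do not constrain, while the
permutation test is exact under exchangeability.

Cluster-extent inference forms clusters at an uncorrected voxel threshold
(default p = .001, Student quantile at the model df) using 18-connectivity
(6 and 26 available), then keeps clusters whose extent exceeds the permutation
null of the maximum cluster size at the chosen level (default 0.05) *and*
reaches the reporting minimum k_min (default 100 voxels, non-strict ≥ with a
strict flag). k_min is a reporting filter, not part of the error control: the
calibration experiments therefore run with k_min = 0, and both the voxel-level
and cluster-level tests reject on 3–7.5% of null cohorts at α = 0.05.

## Reference-cluster derivation

On CGM-normalized data the increase contrast is thresholded at voxel-level FWE
α walking a descending grid (0.05, 0.01, 10⁻³ … 10⁻⁶). The walk stops at the
first level whose largest connected component is (a) at least min_size voxels
(default 50 at desk scale) and (b) coherent. Two coherence rules are
implemented:

* connectedness (default): the largest component holds ≥ 90% of all
  suprathreshold voxels;
* anatomical (used whenever a parcellation is available, as in the pipeline):
  ≥ 60% of the largest component lies within a single atlas parcel.

The anatomical rule operationalizes "most of the cluster volume assignable to
one specific region". It matters in practice: on smoothed images the
suprathreshold set at lenient thresholds is one huge 18-connected blob, so the
connectedness rule can stop the escalation before the cluster has purified to
the truly spared region; the anatomical rule keeps escalating until it has.
The full escalation path (per-level α, threshold, suprathreshold count,
largest component, fractions) is recorded as provenance and exported alongside
the RC mask, so a derived RC can be shipped to and audited at another site.
Because the grid reaches α = 10⁻⁶, thresholds are computed by Bonferroni by
default — a permutation null cannot resolve quantiles below 1/(n_perm+1) at
any practical n_perm; a permutation mode is available for grids it can
resolve. On null data no level yields a coherent cluster and the derivation
raises, which the pipeline converts into a three-scheme comparison with a
warning.

## Classification

Per subject the feature is the mean normalized uptake over a pattern mask,
by default the hypometabolic pattern detected under cerebellar normalization
(a widely used reference standard), with the all-scheme overlap pattern as a
second configuration. A single-feature logistic regression is fit by
Newton/IRLS with a ridge of 1e-8 on the slope — negligible at feature scale 1
but sufficient to keep perfectly separated training sets finite — and
evaluated by stratified split-half cross-validation: each class is halved at
random (odd counts send the extra subject to training), the model is fit on
the training halves, and accuracy, sensitivity and specificity are computed on
the held-out halves; the default is 5000 repetitions. Scheme comparisons use
independent-sample t-tests on the repetition distributions with Bonferroni
correction over pairs. Treating 5000 resampled accuracies as independent
samples is anticonservative — the repetitions share subjects — and is kept
deliberately because it is the field's procedure for this design; p-values
from it should be read as descriptive.

One estimand subtlety: "pure-noise features classify at chance" is true only
in expectation across datasets. Any single finite sample has a chance
feature–label association that within-sample cross-validation retains (a
single 20v20 noise draw can cross-validate at 60%). Chance level is therefore
estimated as the mean over independent noise datasets (25 × 200 repetitions).

## The synthetic phantom

The phantom emulates spatially normalized, 12-mm-smoothed FDG-PET volumes
(2 mm voxels, default 32³ desk-scale grid; all properties tested are
resolution-independent) of a two-center patients-vs-controls study in a
disease with extensive frontal/anterior-temporal hypometabolism. Geometric
parcels inside an ellipsoidal brain — frontal, anterior temporal,
sensorimotor, occipital, cerebellum, vermis (a superior-medial wedge; the
cerebellar hemispheres connect beneath it), other — carry baseline uptake
values around 50 arbitrary units. Subject images are built multiplicatively
and then Gaussian-smoothed (normalized convolution inside the brain mask,
kernel truncated at 4 SD, emulating scanner PSF + preprocessing smoothing as
one effective kernel):

    value(v) = g_s · r_{s,p(v)} · baseline(p(v)) · f_{s,p(v)} + noise(v)

* g_s ~ LogNormal(0, 0.10): per-subject global scale (injected dose,
  sensitivity). Exactly cancelled by any ratio normalization.
* r_{s,p} ~ LogNormal(0, σ_p): between-subject regional variability, with
  cortical σ_p = 0.05 and cerebellar σ_p = 0.015–0.02. Cortical uptake varies
  considerably more across healthy subjects than cerebellar uptake — the
  classical reason cerebellum is used as a reference at all. Without this
  asymmetry the global mean, which averages regional fluctuations away, would
  be an unrealistically clean reference and no normalization scheme could
  outperform it.
* f_{s,p}: deficit factors. Controls have 1 everywhere. For a patient with
  core deficit d = 1 − hypometabolism_factor (default factor 0.85; the strong
  phantom used in recovery tests uses 0.8): affected parcels get 1 − s_core·d,
  the preserved cerebellum exactly 1, and the remaining parcels
  1 − s·share_p·d with shares vermis 0.8, sensorimotor 0.15,
  occipital/other 0.35. s_core ~ LogNormal(0, 0.2) scales the core deficit;
  the mild widespread cortical involvement uses an independent
  s_diffuse ~ LogNormal(0, 0.6), encoding the strong clinical heterogeneity of
  the disease analog; the vermis share follows s_core (remote diaschisis-like
  depression tracks the core pathology). Because all deficits are multiples of
  d, factor = 1.0 gives an exact exchangeable null — the calibration
  experiments rely on this.
* noise(v) ~ N(0, 1.5) before smoothing (center 2: 2.5, plus 1.3× regional
  variability, 0.9× baselines, σ_g = 0.15 — protocol differences without
  physics).

The diffuse-involvement term is what makes global-mean normalization fail for
classification the way it does on real data: each patient's own global mean is
depressed by a patient-specific amount only partially correlated with the
pattern deficit, which both compresses the patient–control gap and adds
patient-side variance to CGM-normalized features. In a phantom without it (all
deficits proportional, homogeneous regional noise) CGM normalization
classifies as well as the RC, because the global mean shares the pattern's
noise — a useful negative result about ratio phantoms in general.

Cohort simulation draws ages from N(62, 9) clipped to [40, 90] and sex
Bernoulli(1/2); per-subject RNG streams are spawned from one seed, so cohorts
are bit-for-bit reproducible. Presets mirror a large cohort (42 controls / 41
patients) and a small one (13/11).

What the phantom does not model: PET physics (attenuation, scatter,
reconstruction), anatomical realism, atrophy/partial-volume effects,
multi-subtype disease heterogeneity, or spatially structured inter-subject
gradients. Passing tests show the pipeline's statistical machinery is correct
and that the RC mechanism behaves directionally as on real data; they do not
certify clinical accuracy values.

## Pipeline and reproducibility

`run_study` executes: simulate cohorts A and B → derive the RC on
CGM-normalized cohort A (increase contrast) → normalize both cohorts by CGM,
cerebellar VOI (hemispheres + vermis, as an atlas VOI would be), sensorimotor
VOI, and the cohort-A RC (cross-center application) → decrease/increase
cluster inference per scheme and cohort → evaluation patterns (per-cohort
cerebellar-scheme pattern; cohort-A all-scheme overlap) → split-half CV per
scheme → pairwise comparisons. Every stochastic stage derives its seed
deterministically from the single config seed (CRC-keyed SeedSequence), all
intermediates are persisted (masks, t-map patterns, CV distributions, JSON
report), and two runs of the same config produce byte-identical reports — an
asserted acceptance property.

Default problem sizes are desk-scale by design: 32³ grids, preset cohort
sizes, 500–2000 permutations, 5000 CV repetitions; calibration experiments use
24³ grids with 10v10 cohorts and 400 permutations over 400 null cohorts.

## Known limitations

* Bonferroni thresholds in the RC escalation are conservative relative to the
  random-field correction used by SPM on smooth images; at desk scale this
  shifts the achieved escalation level, not the mechanism.
* The strict/non-strict reading of the extent filter "k > 100" is ambiguous;
  the default is ≥ 100 with a strict flag.
* The RC and the full cerebellar VOI discriminate nearly equally on the
  phantom (as their real-data gap is also modest); the phantom robustly
  reproduces the RC-vs-CGM and CBL-vs-CGM advantages, not a strict RC > CBL
  classification ordering.
* Independent-sample t-tests on CV repetitions are anticonservative (see
  above).
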