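"""Synthetic two-center FDG-PET-like cohorts with known ground truth.

The phantom emulates spatially normalized, heavily smoothed uptake images of a
patients-vs-controls study in a disease with extensive frontal/anterior-temporal
hypometabolism.  Each subject's image is built multiplicatively:

    value(v) = g_s * r_{s,parcel(v)} * baseline(parcel(v)) * f_{s,parcel}(group) + noise(v)

then Gaussian-smoothed inside an ellipsoidal brain mask (normalized convolution,
so the brain edge does not bleed towards zero) and set to NaN outside.  Here
``g_s`` is a per-subject global scale (log-normal) and ``r_{s,p}`` a per-subject
per-parcel variability term (log-normal).  The deficit factor ``f_{s,p}`` is 1
for controls everywhere; for a patient with core deficit d = 1 - hypometabolism
factor it is

    affected parcels:   1 - s_core * d
    preserved parcel:   1 (exactly)
    other parcels:      1 - s * share_p * d

with ``s_core`` and ``s_diffuse`` independent log-normal per-patient severity
scalars; ``s`` is ``s_core`` for parcels whose involvement is a remote
(diaschisis-like) effect of the core pathology — by default the vermis — and
``s_diffuse`` for the mild widespread cortical involvement.  The diffuse term encodes the clinical heterogeneity of the disease
analog: patients differ strongly in how much mild, widespread cortical
involvement accompanies the core frontal/anterior-temporal deficit.  That
involvement depresses each patient's own global mean by a patient-specific
amount, which is what degrades global-mean normalization relative to a compact
preserved reference.  Setting hypometabolism_factor to 1 switches every deficit
off, giving an exact group-exchangeable null.

Because deficits and scales are multiplicative, normalization to a truly
preserved region cancels ``g_s`` exactly, which gives downstream stages clean
closed-form oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, MaskVolume, VolumeImage, CohortManifest, _default_affine

PARCELS = ("frontal", "anterior_temporal", "sensorimotor", "occipital",
           "cerebellum", "vermis", "other")
LABEL_TABLE = {i + 1: name for i, name in enumerate(PARCELS)}

_DEF_BASELINES = {
    "frontal": 52.0, "anterior_temporal": 50.0, "sensorimotor": 54.0,
    "occipital": 55.0, "cerebellum": 48.0, "vermis": 48.0, "other": 50.0,
}
# Diffuse-involvement shares: each non-affected, non-preserved parcel carries
# this fraction of the core deficit in patients (scaled by the per-patient
# diffuse severity).  The disease analog depresses most of the cortex mildly
# and the vermis substantially, leaving the cerebellar hemispheres untouched.
_DEF_DEFICIT_SHARE = {
    "vermis": 0.8, "sensorimotor": 0.15, "occipital": 0.35, "other": 0.35,
}

# Between-subject variability of parcel-mean uptake (sd of the log).  Cortical
# uptake varies considerably more across healthy subjects than cerebellar
# uptake — the classic rationale for cerebellar reference regions.
_DEF_REGIONAL_SIGMA = {
    "frontal": 0.05, "anterior_temporal": 0.05, "sensorimotor": 0.05,
    "occipital": 0.05, "other": 0.05, "cerebellum": 0.015, "vermis": 0.02,
}


@dataclass
class PhantomParams:
    """Generator settings; defaults are the study conditions the phantom encodes."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 2.0                       # mm
    baselines: dict[str, float] = field(default_factory=lambda: dict(_DEF_BASELINES))
    hypometabolism_factor: float = 0.85
    affected: tuple[str, ...] = ("frontal", "anterior_temporal")
    preserved: tuple[str, ...] = ("cerebellum",)
    deficit_share: dict[str, float] = field(
        default_factory=lambda: dict(_DEF_DEFICIT_SHARE))
    # parcels whose shared deficit tracks the core severity (diaschisis-like
    # remote depression) instead of the independent diffuse involvement
    core_linked: tuple[str, ...] = ("vermis",)
    subject_scale_sigma: float = 0.10             # sigma of log global scale
    regional_sigma: float | dict[str, float] = field(
        default_factory=lambda: dict(_DEF_REGIONAL_SIGMA))  # log per-parcel jitter sd
    core_severity_sigma: float = 0.2              # sigma of log core deficit severity
    diffuse_severity_sigma: float = 0.6           # sigma of log diffuse involvement
    noise_sd: float = 1.5                         # additive, pre-smoothing, uptake units
    smoothing_fwhm: float = 12.0                  # mm
    smooth: bool = True

    def __post_init__(self) -> None:
        if self.hypometabolism_factor <= 0:
            raise ValueError("hypometabolism_factor must be > 0")
        if any(s < 0 for s in self.deficit_share.values()):
            raise ValueError("deficit shares must be >= 0")
        if set(self.affected) & set(self.preserved):
            raise ValueError("affected and preserved parcels overlap")
        unknown = (set(self.affected) | set(self.preserved)
                   | set(self.deficit_share) | set(self.core_linked)) - set(PARCELS)
        if isinstance(self.regional_sigma, dict):
            unknown |= set(self.regional_sigma) - set(PARCELS)
        if unknown:
            raise ValueError(f"unknown parcels: {sorted(unknown)}")
        fwhm_vox = self.smoothing_fwhm / self.voxel_size
        if self.smooth and fwhm_vox >= 3 and min(self.shape) < 16:
            raise ValueError("grid too small for this smoothing kernel (need >=16 per axis)")

    def regional_sigmas(self) -> np.ndarray:
        """Per-parcel jitter sd, ordered as PARCELS."""
        if isinstance(self.regional_sigma, dict):
            return np.array([self.regional_sigma.get(p, 0.0) for p in PARCELS])
        return np.full(len(PARCELS), float(self.regional_sigma))

    @property
    def sigma_voxels(self) -> float:
        return self.smoothing_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / self.voxel_size

    def patient_factor(self, parcel: str, s_core: float = 1.0,
                       s_diffuse: float = 1.0) -> float:
        """Multiplicative uptake factor of one parcel for a patient with the
        given severity scalars (controls have factor 1 everywhere)."""
        d = 1.0 - self.hypometabolism_factor
        if parcel in self.affected:
            return 1.0 - s_core * d
        if parcel in self.preserved:
            return 1.0
        s = s_core if parcel in self.core_linked else s_diffuse
        return 1.0 - s * self.deficit_share.get(parcel, 0.0) * d


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: parcellation plus the masks every stage is scored against."""

    parcellation: LabelVolume
    affected_mask: MaskVolume
    preserved_mask: MaskVolume
    brain_mask: MaskVolume
    subject_scales: dict[str, float] = field(default_factory=dict)


# Two "center" presets differing in noise level, between-subject variability and
# baseline vector, emulating different acquisition protocols without physics.
CENTER_PRESETS: dict[str, dict] = {
    "center1": dict(noise_sd=1.5, subject_scale_sigma=0.10,
                    regional_sigma=dict(_DEF_REGIONAL_SIGMA),
                    baselines=dict(_DEF_BASELINES),
                    n_controls=42, n_patients=41),
    "center2": dict(noise_sd=2.5, subject_scale_sigma=0.15,
                    regional_sigma={k: 1.3 * v for k, v in _DEF_REGIONAL_SIGMA.items()},
                    baselines={k: 0.9 * v for k, v in _DEF_BASELINES.items()},
                    n_controls=13, n_patients=11),
}


def preset_params(name: str, **overrides) -> PhantomParams:
    """PhantomParams for one center preset; cohort sizes live in CENTER_PRESETS."""
    if name not in CENTER_PRESETS:
        raise KeyError(f"unknown preset '{name}' (have {sorted(CENTER_PRESETS)})")
    p = {k: v for k, v in CENTER_PRESETS[name].items()
         if k not in ("n_controls", "n_patients")}
    p.update(overrides)
    return PhantomParams(**p)


def make_parcellation(params: PhantomParams) -> PhantomTruth:
    """Deterministic geometric parcellation inside an ellipsoidal brain.

    Axes are (x: left-right, y: posterior-anterior, z: inferior-superior).  The
    cerebellum analog sits inferior-posterior (about 15% of the brain, with a
    medial vermis strip); the affected frontal + anterior-temporal block covers
    the anterior ~40%, a superior central strip is the sensorimotor analog and
    the posterior cap the occipital analog.
    """
    shape = tuple(params.shape)
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.46 * np.asarray(shape)
    ix = np.indices(shape, dtype=float)
    xn, yn, zn = [(ix[i] - center[i]) / semi[i] for i in range(3)]
    brain = xn ** 2 + yn ** 2 + zn ** 2 <= 1.0

    cere_zone = (zn < -0.30) & (yn < 0.05)
    # superior-medial wedge; the hemispheres stay connected underneath it
    vermis = cere_zone & (np.abs(xn) < 0.16) & (zn > -0.52)
    cerebellum = cere_zone & ~vermis
    rest = ~cere_zone
    frontal = rest & (yn > 0.22) & (zn > -0.30)
    anterior_temporal = rest & (yn > 0.02) & (zn <= -0.30)
    occipital = rest & ~frontal & ~anterior_temporal & (yn < -0.50)
    sensorimotor = (rest & ~frontal & ~anterior_temporal & ~occipital
                    & (zn > 0.45) & (np.abs(yn) <= 0.22))

    labels = np.zeros(shape, dtype=int)
    for name, region in (("frontal", frontal), ("anterior_temporal", anterior_temporal),
                         ("sensorimotor", sensorimotor), ("occipital", occipital),
                         ("cerebellum", cerebellum), ("vermis", vermis)):
        labels[brain & region] = PARCELS.index(name) + 1
    labels[brain & (labels == 0)] = PARCELS.index("other") + 1

    affine = _default_affine(params.voxel_size)
    parc = LabelVolume(labels, dict(LABEL_TABLE), affine)
    for name in set(params.affected) | set(params.preserved):
        if not np.any(labels == parc.id_of(name)):
            raise ValueError(f"parcel '{name}' does not fit this grid")

    def union(names: tuple[str, ...]) -> MaskVolume:
        return MaskVolume(np.isin(labels, [parc.id_of(n) for n in names]), affine)

    return PhantomTruth(parcellation=parc,
                        affected_mask=union(params.affected),
                        preserved_mask=union(params.preserved),
                        brain_mask=MaskVolume(brain, affine))


def _smooth_in_brain(vals: np.ndarray, brain: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Normalized convolution: Gaussian smoothing that never mixes in out-of-brain zeros."""
    num = ndimage.gaussian_filter(np.where(brain, vals, 0.0), sigma_vox, truncate=4.0)
    den = ndimage.gaussian_filter(brain.astype(float), sigma_vox, truncate=4.0)
    out = np.full(vals.shape, np.nan)
    out[brain] = num[brain] / den[brain]
    return out


def _render_subject(truth: PhantomTruth, params: PhantomParams, group: str,
                    rng: np.random.Generator) -> tuple[VolumeImage, float]:
    if group not in ("control", "patient"):
        raise ValueError(f"group must be 'control'/'patient', got {group!r}")
    labels = truth.parcellation.data
    brain = truth.brain_mask.data
    # draws happen in a fixed order for both groups so streams stay aligned
    scale = float(np.exp(rng.normal(0.0, params.subject_scale_sigma)))
    jitter = np.exp(rng.normal(0.0, 1.0, size=len(PARCELS)) * params.regional_sigmas())
    s_core = float(np.exp(rng.normal(0.0, params.core_severity_sigma)))
    s_diffuse = float(np.exp(rng.normal(0.0, params.diffuse_severity_sigma)))

    vals = np.zeros(labels.shape)
    for lid, name in LABEL_TABLE.items():
        f = params.patient_factor(name, s_core, s_diffuse) if group == "patient" else 1.0
        vals[labels == lid] = scale * jitter[lid - 1] * params.baselines[name] * f
    if params.noise_sd > 0:
        vals = vals + np.where(brain, rng.normal(0.0, params.noise_sd, labels.shape), 0.0)
    if params.smooth:
        out = _smooth_in_brain(vals, brain, params.sigma_voxels)
    else:
        out = np.where(brain, vals, np.nan)
    return VolumeImage(out, truth.brain_mask.affine.copy()), scale


def simulate_subject(truth: PhantomTruth, params: PhantomParams, group: str,
                     rng: np.random.Generator) -> VolumeImage:
    """One smoothed subject volume; NaN outside the brain."""
    img, _ = _render_subject(truth, params, group, rng)
    return img


def simulate_cohort(params: PhantomParams, n_controls: int, n_patients: int,
                    seed: int) -> tuple[list[VolumeImage], CohortManifest, PhantomTruth]:
    """Simulate a full cohort: ages ~ N(62, 9) clipped to [40, 90], sex ~ Bernoulli(1/2).

    Reproducible bit-for-bit for a fixed seed; controls come first in the
    manifest, then patients.
    """
    if n_controls < 2 or n_patients < 2:
        raise ValueError("need at least 2 subjects per group")
    truth = make_parcellation(params)
    rng = np.random.default_rng(seed)
    n = n_controls + n_patients
    groups = ["control"] * n_controls + ["patient"] * n_patients
    ids = [f"c{i:03d}" for i in range(n_controls)] + [f"p{i:03d}" for i in range(n_patients)]
    ages = np.clip(rng.normal(62.0, 9.0, size=n), 40.0, 90.0)
    sexes = rng.integers(0, 2, size=n)
    streams = rng.spawn(n)

    volumes: list[VolumeImage] = []
    for sid, grp, stream in zip(ids, groups, streams):
        img, scale = _render_subject(truth, params, grp, stream)
        truth.subject_scales[sid] = scale
        volumes.append(img)

    import pandas as pd
    manifest = CohortManifest(pd.DataFrame(
        {"id": ids, "group": groups, "age": ages, "sex": sexes, "path": [""] * n}))
    return volumes, manifest, truth


def preset_cohort(name: str, seed: int, n_controls: int | None = None,
                  n_patients: int | None = None, **param_overrides):
    """Simulate a cohort from a named center preset (sizes default to the preset's)."""
    params = preset_params(name, **param_overrides)
    nc = CENTER_PRESETS[name]["n_controls"] if n_controls is None else n_controls
    np_ = CENTER_PRESETS[name]["n_patients"] if n_patients is None else n_patients
    return simulate_cohort(params, nc, np_, seed)
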