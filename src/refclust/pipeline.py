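"""Full study orchestration: two cohorts, four normalization schemes, detection,
reference-cluster derivation on cohort A applied to cohort B, and classification.

Stage order mirrors the cross-center design the package implements:

1. simulate (or load) cohorts A and B;
2. normalize cohort A to the cerebral global mean and derive the reference
   cluster (RC) from the increase contrast;
3. normalize both cohorts by each scheme — CGM, cerebellar VOI, sensorimotor
   VOI, RC (the RC always comes from cohort A, emulating cross-center use);
4. run decrease and increase cluster inference per scheme and cohort;
5. build evaluation patterns (the cerebellar-scheme hypometabolic pattern of
   each cohort, plus the all-scheme overlap of cohort A);
6. split-half cross-validated logistic classification per scheme;
7. pairwise comparison of the accuracy distributions.

Every stochastic stage draws its seed deterministically from the single config
seed, so a rerun with the same config reproduces the report bit for bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as cls
from . import glm
from . import normalization as norm
from . import phantom
from .volumes import MaskVolume, assert_same_grid, dice, read_mask, write_volume

SCHEMES = ("cgm", "cbl", "smc", "rc")


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed derived from the global seed."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class CohortSpec:
    preset: str = "center1"
    n_controls: int | None = None
    n_patients: int | None = None
    hypometabolism_factor: float | None = None
    shape: tuple[int, int, int] | None = None

    def overrides(self) -> dict:
        out = {}
        if self.hypometabolism_factor is not None:
            out["hypometabolism_factor"] = self.hypometabolism_factor
        if self.shape is not None:
            out["shape"] = tuple(self.shape)
        return out


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "refclust_out"
    cohort_a: CohortSpec = field(default_factory=lambda: CohortSpec("center1"))
    cohort_b: CohortSpec = field(default_factory=lambda: CohortSpec("center2"))
    forming_p: float = 0.001
    k_min: int = 100
    cluster_alpha: float = 0.05
    n_perm: int = 500
    connectivity: int = 18
    rc_alphas: tuple[float, ...] = glm.DEFAULT_ALPHA_GRID
    rc_coherence: float = 0.9
    rc_min_size: int = 50
    rc_method: str = "bonferroni"
    rc_use_atlas: bool = True   # anatomical coherence via the phantom parcellation
    rc_atlas_fraction: float = 0.6
    n_rep: int = 5000
    save_volumes: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("cohort_a", "cohort_b"):
            if key in d and isinstance(d[key], dict):
                d[key] = CohortSpec(**d[key])
        if "rc_alphas" in d:
            d["rc_alphas"] = tuple(float(a) for a in d["rc_alphas"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def export_rc(region: glm.ReferenceRegion, path: str | Path) -> None:
    """Write the RC as a binary NIfTI mask plus a JSON provenance sidecar, so
    other installations can reuse it to normalize new data."""
    if region.mask.n_voxels == 0:
        raise ValueError("reference region is empty")
    path = Path(path)
    write_volume(region.mask, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    with open(str(sidecar) + ".json", "w") as fh:
        json.dump(_jsonable(region.provenance), fh, indent=2, sort_keys=True)


def load_rc(path: str | Path) -> glm.ReferenceRegion:
    path = Path(path)
    mask = read_mask(path)
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return glm.ReferenceRegion(mask, prov)


def _scheme_reference(scheme: str, truth: phantom.PhantomTruth,
                      rc_mask: MaskVolume | None) -> norm.ReferenceSpec:
    parc = truth.parcellation
    if scheme == "cgm":
        return norm.ReferenceSpec("cgm", name="cgm")
    if scheme == "cbl":  # full cerebellar VOI: hemispheres + vermis, as an atlas VOI would
        from .volumes import mask_from_labels
        ids = [parc.id_of("cerebellum"), parc.id_of("vermis")]
        return norm.ReferenceSpec("roi", mask_from_labels(parc, ids), name="cbl")
    if scheme == "smc":
        from .volumes import mask_from_labels
        return norm.ReferenceSpec("roi", mask_from_labels(parc, [parc.id_of("sensorimotor")]),
                                  name="smc")
    if scheme == "rc":
        if rc_mask is None:
            raise ValueError("no reference cluster available")
        return norm.ReferenceSpec("roi", rc_mask, name="rc")
    raise ValueError(f"unknown scheme {scheme!r}")


def run_study(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the study report (also written to
    ``out_dir/report.json`` together with masks, t-maps and distribution CSVs)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    report: dict = {"seed": config.seed, "warnings": warnings, "cohorts": {},
                    "software": {"package": "refclust", "version": "0.1.0"}}

    # ---- stage 1: cohorts -------------------------------------------------
    cohorts = {}
    for key, spec in (("a", config.cohort_a), ("b", config.cohort_b)):
        seed = stage_seed(config.seed, f"simulate_{key}")
        vols, manifest, truth = phantom.preset_cohort(
            spec.preset, seed=seed, n_controls=spec.n_controls,
            n_patients=spec.n_patients, **spec.overrides())
        design = glm.build_design(manifest)
        cohorts[key] = {"volumes": vols, "manifest": manifest, "truth": truth,
                        "design": design, "preset": spec.preset}
        manifest.to_csv(out / f"cohort_{key}_manifest.csv")
        if config.save_volumes:
            vdir = out / f"cohort_{key}_volumes"
            vdir.mkdir(exist_ok=True)
            for sid, v in zip(manifest.table["id"], vols):
                write_volume(v, vdir / f"{sid}.nii.gz")

    # ---- stage 2: reference cluster on cohort A --------------------------
    a = cohorts["a"]
    cgm_a = norm.normalize_cohort(a["volumes"], norm.ReferenceSpec("cgm", name="cgm"))
    rc_region = None
    try:
        rc_region = glm.derive_reference_cluster(
            cgm_a, a["design"], alphas=config.rc_alphas,
            coherence_fraction=config.rc_coherence, min_size=config.rc_min_size,
            method=config.rc_method, n_perm=config.n_perm,
            seed=stage_seed(config.seed, "derive_rc"),
            connectivity=config.connectivity,
            atlas=a["truth"].parcellation if config.rc_use_atlas else None,
            atlas_fraction=config.rc_atlas_fraction)
        export_rc(rc_region, out / "rc_mask.nii.gz")
        report["rc"] = {
            "found": True, "size": rc_region.provenance["size"],
            "alpha_achieved": rc_region.provenance["alpha_achieved"],
            "fraction_in_largest": rc_region.provenance["fraction_in_largest"],
            "dice_vs_preserved": dice(rc_region.mask, a["truth"].preserved_mask),
            "escalation_path": rc_region.provenance["escalation_path"],
        }
    except glm.NoReferenceClusterError as exc:
        warnings.append(f"reference cluster derivation failed: {exc}; "
                        "continuing with three schemes")
        report["rc"] = {"found": False}

    schemes = list(SCHEMES) if rc_region is not None else ["cgm", "cbl", "smc"]
    rc_mask = rc_region.mask if rc_region is not None else None

    # ---- stages 3-4: normalization + detection ----------------------------
    normalized: dict[str, dict[str, list]] = {}
    patterns: dict[str, dict[str, MaskVolume]] = {}
    for key, coh in cohorts.items():
        if rc_mask is not None:
            assert_same_grid(coh["volumes"][0], rc_mask)
        normalized[key] = {}
        patterns[key] = {}
        det_report = {}
        for scheme in schemes:
            ref = _scheme_reference(scheme, coh["truth"], rc_mask)
            nvols = norm.normalize_cohort(coh["volumes"], ref)
            normalized[key][scheme] = nvols
            det_report[scheme] = {}
            for direction in ("decrease", "increase"):
                cs = glm.cluster_inference(
                    nvols, coh["design"], contrast=direction,
                    forming_p=config.forming_p, k_min=config.k_min,
                    cluster_alpha=config.cluster_alpha, n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"detect_{key}_{scheme}_{direction}"),
                    connectivity=config.connectivity)
                det_report[scheme][direction] = {
                    "extent": cs.total_extent,
                    "n_clusters": len(cs.clusters),
                    "peak_t": cs.peak_t,
                    "forming_threshold": cs.forming_threshold,
                    "size_threshold": cs.size_threshold,
                }
                if direction == "decrease":
                    pat = cs.mask()
                    patterns[key][scheme] = pat
                    write_volume(pat, out / f"pattern_{key}_{scheme}_decrease.nii.gz")
        report["cohorts"][key] = {
            "preset": coh["preset"],
            "n_controls": coh["manifest"].n_controls,
            "n_patients": coh["manifest"].n_patients,
            "detection": det_report,
        }

    # ---- stage 5: evaluation patterns -------------------------------------
    eval_patterns: dict[str, dict[str, MaskVolume]] = {"a": {}, "b": {}}
    for key in cohorts:
        pat = patterns[key].get("cbl")
        if pat is not None and pat.n_voxels > 0:
            eval_patterns[key]["cbl_pattern"] = pat
        else:
            warnings.append(f"cohort {key}: empty cerebellar-scheme hypometabolic "
                            "pattern; classification on it skipped")
    try:
        nonempty = [patterns["a"][s] for s in schemes if patterns["a"][s].n_voxels > 0]
        if len(nonempty) == len(schemes):
            overlap = cls.pattern_overlap(nonempty)
            write_volume(overlap, out / "pattern_a_overlap.nii.gz")
            for key in cohorts:
                eval_patterns[key]["overlap_pattern"] = overlap
        else:
            warnings.append("overlap pattern skipped: some schemes detected nothing")
    except cls.ClassificationError as exc:
        warnings.append(f"overlap pattern skipped: {exc}")

    # ---- stages 6-7: classification ---------------------------------------
    for key, coh in cohorts.items():
        cls_report = {}
        for pat_name, pat in eval_patterns[key].items():
            dists = []
            per_scheme = {}
            for scheme in schemes:
                feats = cls.extract_pattern_means(normalized[key][scheme], pat,
                                                  coh["manifest"])
                dist = cls.split_half_cv(
                    feats["mean_uptake"].to_numpy(), coh["manifest"].group_indicator,
                    n_rep=config.n_rep,
                    seed=stage_seed(config.seed, f"cv_{key}_{pat_name}_{scheme}"),
                    name=scheme)
                dist.to_frame().to_csv(out / f"cv_{key}_{pat_name}_{scheme}.csv",
                                       index=False)
                dists.append(dist)
                per_scheme[scheme] = dist.summary()
            comparisons = cls.compare_distributions(dists)
            cls_report[pat_name] = {
                "schemes": per_scheme,
                "comparisons": comparisons.to_dict(orient="records"),
                "sensitivity_vs_specificity": [cls.compare_sens_spec(d) for d in dists],
            }
        report["cohorts"][key]["classification"] = cls_report

    report = _jsonable(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
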