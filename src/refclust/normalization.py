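"""Intensity normalization of uptake volumes to a reference value.

Non-quantitative PET images are only comparable across subjects after division
by a reference: the cerebral global mean (CGM, the classic SPM two-pass mean/8
rule), an a-priori region of interest (cerebellum, sensorimotor cortex), or a
data-driven reference cluster.  Normalization is a pure ratio operation:
``out = img * target / reference_value`` with target defaulting to 1 so all
downstream statistics are scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import MaskVolume, RefclustError, VolumeImage, assert_same_grid


class NormalizationError(RefclustError):
    pass


@dataclass
class ReferenceSpec:
    """Which reference to scale to: kind='cgm' (global mean) or kind='roi' (mask mean)."""

    kind: str
    mask: MaskVolume | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("cgm", "roi"):
            raise ValueError(f"kind must be 'cgm' or 'roi', got {self.kind!r}")
        if self.kind == "roi":
            if self.mask is None:
                raise ValueError("roi reference requires a mask")
            if self.mask.n_voxels < 1:
                raise NormalizationError("roi reference mask is empty")
        if not self.name:
            self.name = self.kind


@dataclass
class NormalizedVolume:
    image: VolumeImage
    reference: ReferenceSpec
    reference_value: float
    target: float


def spm_global_mean(img: VolumeImage) -> float:
    """Two-pass global mean: mean m0 of all finite voxels, then the mean of
    voxels exceeding m0/8 (drops extracerebral background)."""
    vals = img.data[np.isfinite(img.data)]
    if vals.size == 0:
        raise NormalizationError("volume has no finite voxels")
    m0 = vals.mean()
    above = vals[vals > m0 / 8.0]
    if above.size == 0:
        raise NormalizationError("no voxel exceeds mean/8; degenerate volume")
    return float(above.mean())


def roi_mean(img: VolumeImage, mask: MaskVolume) -> float:
    """Arithmetic mean of finite voxels inside the mask."""
    assert_same_grid(img, mask)
    vals = img.data[mask.data & np.isfinite(img.data)]
    if vals.size == 0:
        raise NormalizationError("mask covers no finite voxels")
    return float(vals.mean())


def reference_value(img: VolumeImage, ref: ReferenceSpec) -> float:
    if ref.kind == "cgm":
        return spm_global_mean(img)
    return roi_mean(img, ref.mask)


def normalize(img: VolumeImage, ref: ReferenceSpec, target: float = 1.0) -> NormalizedVolume:
    """Rescale so the reference mean equals ``target`` exactly."""
    value = reference_value(img, ref)
    if value <= 0:
        raise NormalizationError(
            f"non-positive reference value {value:g} for reference '{ref.name}'")
    out = img.with_data(img.data * (target / value))
    return NormalizedVolume(image=out, reference=ref, reference_value=value, target=target)


def normalize_cohort(volumes: list[VolumeImage], ref: ReferenceSpec,
                     target: float = 1.0) -> list[NormalizedVolume]:
    return [normalize(v, ref, target) for v in volumes]
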