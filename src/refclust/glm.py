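"""Voxel-wise group GLM, permutation FWE control, cluster inference, and the
data-driven reference-cluster escalation.

The model at every voxel v is ordinary least squares

    y_v = X b + e,   X = [1, group, age - mean(age), sex],
    t_v = c'b / sqrt(sigma2_v * c'(X'X)^{-1} c),   df = n - rank(X),

with one-sided contrasts run separately: ``decrease`` (c puts -1 on the group
indicator; positive t means patients lower) and ``increase`` (+1).  Family-wise
error is controlled by the max-statistic permutation test — group labels are
permuted across subjects while age/sex stay attached to their subjects — or by
Bonferroni over in-mask voxels.  Cluster-extent inference forms clusters at an
uncorrected voxel p (default .001), keeps clusters whose extent both reaches
the reporting minimum k_min and exceeds the permutation null of maximum cluster
size at the chosen FWE level.

The reference cluster is derived from the *increase* contrast on global-mean
normalized data: relative preservation masquerades as hypermetabolism after
global normalization, so the most-preserved region is the last surviving
coherent cluster as the voxel-FWE threshold escalates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .normalization import NormalizedVolume
from .volumes import MaskVolume, RefclustError, VolumeImage, assert_same_grid


class DesignError(RefclustError):
    pass


class InferenceError(RefclustError):
    pass


class NoReferenceClusterError(RefclustError):
    """Escalation found no coherent suprathreshold cluster (expected under null data)."""


# --------------------------------------------------------------------------- design


@dataclass
class DesignMatrix:
    """Per-cohort model matrix with named columns; 'group' is the tested column."""

    matrix: np.ndarray
    columns: list[str]
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if n <= p:
            raise DesignError(f"need more subjects ({n}) than design columns ({p})")
        if np.linalg.matrix_rank(self.matrix) < p:
            raise DesignError("design matrix is rank deficient")
        if "group" not in self.columns:
            raise DesignError("design has no 'group' column")
        g = self.matrix[:, self.columns.index("group")]
        if not np.all(np.isin(g, (0.0, 1.0))) or len(np.unique(g)) < 2:
            raise DesignError("group column must contain both 0 and 1")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def group_col(self) -> int:
        return self.columns.index("group")

    def contrast(self, direction: str) -> np.ndarray:
        """'decrease': patients < controls; 'increase': patients > controls."""
        c = np.zeros(len(self.columns))
        if direction == "decrease":
            c[self.group_col] = -1.0
        elif direction == "increase":
            c[self.group_col] = 1.0
        else:
            raise ValueError(f"direction must be 'decrease'/'increase', got {direction!r}")
        return c


def build_design(manifest) -> DesignMatrix:
    """[1, group(patient=1), age - mean(age), sex]; constant covariates are dropped."""
    df = manifest.table
    group = manifest.group_indicator.astype(float)
    age = df["age"].to_numpy(float)
    sex = df["sex"].to_numpy(float)
    cols = [np.ones_like(group), group]
    names = ["intercept", "group"]
    dropped = []
    for name, col in (("age", age - age.mean()), ("sex", sex)):
        if np.ptp(col) == 0:
            dropped.append(name)
        else:
            cols.append(col)
            names.append(name)
    return DesignMatrix(np.column_stack(cols), names, dropped)


# --------------------------------------------------------------------------- fitting


def _as_data(vol) -> np.ndarray:
    if isinstance(vol, NormalizedVolume):
        return vol.image.data
    if isinstance(vol, VolumeImage):
        return vol.data
    return np.asarray(vol, dtype=float)


def _as_image(vol) -> VolumeImage:
    return vol.image if isinstance(vol, NormalizedVolume) else vol


def stack_cohort(volumes, mask: MaskVolume | None = None):
    """Stack subject volumes into Y (n x V) over the analysis mask.

    The analysis mask is the set of voxels finite in every subject, optionally
    intersected with a user-supplied brain mask.
    """
    imgs = [_as_image(v) for v in volumes]
    for img in imgs[1:]:
        assert_same_grid(imgs[0], img)
    data = np.stack([im.data for im in imgs])
    analysis = np.all(np.isfinite(data), axis=0)
    if mask is not None:
        assert_same_grid(imgs[0], mask)
        analysis &= mask.data
    if not analysis.any():
        raise InferenceError("analysis mask is empty")
    Y = data[:, analysis]
    return Y, MaskVolume(analysis, imgs[0].affine.copy())


def _t_from_Y(Y: np.ndarray, X: np.ndarray, c: np.ndarray):
    """Vectorized OLS t-statistics for one contrast; returns (t, df, beta, sigma2)."""
    n, p = X.shape
    # pinv: a permuted group column may collide with a binary covariate
    XtXinv = np.linalg.pinv(X.T @ X)
    beta = XtXinv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    cvar = float(c @ XtXinv @ c)
    num = c @ beta
    # zero residual variance up to floating-point noise relative to data scale
    scale = np.max(np.abs(Y), axis=0, initial=0.0)
    tiny = (1e-10 * scale) ** 2
    zero = sigma2 <= tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(sigma2 * cvar)
    if zero.any():  # +-inf sentinel where the effect is nonzero with no residual noise
        sigma2 = sigma2.copy()
        sigma2[zero] = 0.0
        eff = np.where(np.abs(num[zero]) > 1e-10 * scale[zero], np.sign(num[zero]), 0.0)
        t[zero] = np.where(eff > 0, np.inf, np.where(eff < 0, -np.inf, 0.0))
    return t, df, beta, sigma2


@dataclass
class TStatResult:
    t_map: np.ndarray            # 3D, NaN outside analysis mask
    df: int
    beta: np.ndarray             # p x V over the analysis mask
    sigma2_map: np.ndarray       # 3D, NaN outside analysis mask
    analysis_mask: MaskVolume
    contrast: np.ndarray
    zero_variance_mask: np.ndarray  # 3D bool

    @property
    def t_values(self) -> np.ndarray:
        return self.t_map[self.analysis_mask.data]


def fit_glm(volumes, design: DesignMatrix, contrast="decrease",
            mask: MaskVolume | None = None) -> TStatResult:
    """Per-voxel OLS t-map for one directional contrast."""
    Y, analysis = stack_cohort(volumes, mask)
    if Y.shape[0] != design.n:
        raise DesignError(f"{Y.shape[0]} volumes but design has {design.n} rows")
    c = design.contrast(contrast) if isinstance(contrast, str) else np.asarray(contrast, float)
    t, df, beta, sigma2 = _t_from_Y(Y, design.matrix, c)
    shape = analysis.data.shape
    t_map = np.full(shape, np.nan)
    t_map[analysis.data] = t
    s_map = np.full(shape, np.nan)
    s_map[analysis.data] = sigma2
    zv = np.zeros(shape, bool)
    zv[analysis.data] = sigma2 <= 0
    return TStatResult(t_map, df, beta, s_map, analysis, c, zv)


# --------------------------------------------------------------------- permutations


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _group_relabelings(group: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Permuted group vectors: exhaustive if there are at most n_perm distinct
    assignments of the patient labels, else the identity plus random draws."""
    n = group.size
    k = int(group.sum())
    n_distinct = math.comb(n, k)
    if n_distinct <= n_perm:
        out = np.zeros((n_distinct, n), dtype=float)
        for i, idx in enumerate(itertools.combinations(range(n), k)):
            out[i, list(idx)] = 1.0
        return out, True
    out = np.empty((n_perm, n), dtype=float)
    out[0] = group
    for i in range(1, n_perm):
        out[i] = group[rng.permutation(n)]
    return out, False


@dataclass
class PermutationNull:
    """Max-statistic null distributions over group-label permutations."""

    max_t: np.ndarray
    max_cluster: np.ndarray | None
    exhaustive: bool

    @property
    def n(self) -> int:
        return self.max_t.size


def permutation_threshold(null: np.ndarray, alpha: float) -> float:
    """Critical value: reject when the observed statistic strictly exceeds it.

    Equivalent to p = #{null >= obs}/n <= alpha with the identity labeling
    included in the null set, which keeps the test exact."""
    n = null.size
    k = int(np.floor(alpha * n))
    if k < 1:
        raise InferenceError(
            f"{n} permutations cannot resolve alpha={alpha:g}; use method='bonferroni'")
    return float(np.sort(null)[n - k])


def _null_distributions(Y, design: DesignMatrix, c, n_perm, rng,
                        forming_t: float | None = None,
                        analysis: MaskVolume | None = None,
                        connectivity: int = 18) -> PermutationNull:
    X = design.matrix.copy()
    gcol = design.group_col
    labelings, exhaustive = _group_relabelings(X[:, gcol].copy(), n_perm, rng)
    struct = _structure(connectivity)
    shape = analysis.data.shape if analysis is not None else None
    max_t = np.empty(len(labelings))
    max_sz = np.zeros(len(labelings)) if forming_t is not None else None
    for i, g in enumerate(labelings):
        X[:, gcol] = g
        t, _, _, sigma2 = _t_from_Y(Y, X, c)
        valid = sigma2 > 0
        max_t[i] = t[valid].max() if valid.any() else -np.inf
        if forming_t is not None:
            supra = np.zeros(shape, bool)
            supra[analysis.data] = (t > forming_t) & valid
            if supra.any():
                lab, nlab = ndimage.label(supra, structure=struct)
                if nlab:
                    max_sz[i] = np.bincount(lab.ravel())[1:].max()
    return PermutationNull(max_t, max_sz, exhaustive)


def voxel_fwe_threshold(volumes, design: DesignMatrix, contrast="increase",
                        alpha: float = 0.05, method: str = "permutation",
                        n_perm: int = 1000, seed: int | None = None,
                        mask: MaskVolume | None = None) -> float:
    """t-threshold controlling FWE at alpha over the analysis mask (one-sided)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    Y, analysis = stack_cohort(volumes, mask)
    c = design.contrast(contrast) if isinstance(contrast, str) else np.asarray(contrast, float)
    df = design.n - design.matrix.shape[1]
    if method == "bonferroni":
        V = int(analysis.data.sum())
        return float(stats.t.isf(alpha / V, df))
    if method != "permutation":
        raise ValueError("method must be 'permutation' or 'bonferroni'")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for permutation FWE")
    null = _null_distributions(Y, design, c, n_perm, np.random.default_rng(seed))
    return permutation_threshold(null.max_t, alpha)


# ------------------------------------------------------------------------- clusters


@dataclass
class Cluster:
    voxels: np.ndarray           # (k, 3) integer voxel coordinates
    size: int
    peak_t: float | None = None
    peak_ijk: tuple[int, int, int] | None = None


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    forming_threshold: float | None
    connectivity: int
    shape: tuple[int, int, int]
    affine: np.ndarray
    df: int | None = None
    size_threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def total_extent(self) -> int:
        return int(sum(cl.size for cl in self.clusters))

    @property
    def peak_t(self) -> float | None:
        peaks = [cl.peak_t for cl in self.clusters if cl.peak_t is not None]
        return max(peaks) if peaks else None

    def mask(self) -> MaskVolume:
        m = np.zeros(self.shape, bool)
        for cl in self.clusters:
            m[tuple(cl.voxels.T)] = True
        return MaskVolume(m, self.affine.copy())


def connected_components(binary, connectivity: int = 18, t_map=None,
                         affine=None) -> ClusterSet:
    """Maximal connected components of a binary mask, sizes sorted descending."""
    if isinstance(binary, MaskVolume):
        arr, aff = binary.data, binary.affine
    else:
        arr, aff = np.asarray(binary, bool), (np.eye(4) if affine is None else affine)
    lab, nlab = ndimage.label(arr, structure=_structure(connectivity))
    clusters = []
    for lid in range(1, nlab + 1):
        vox = np.argwhere(lab == lid)
        peak_t = peak_ijk = None
        if t_map is not None:
            vals = np.abs(t_map[tuple(vox.T)])
            j = int(np.argmax(vals))
            peak_t, peak_ijk = float(t_map[tuple(vox[j])]), tuple(int(x) for x in vox[j])
        clusters.append(Cluster(vox, len(vox), peak_t, peak_ijk))
    clusters.sort(key=lambda cl: cl.size, reverse=True)
    return ClusterSet(clusters, None, connectivity, arr.shape, np.asarray(aff, float))


def filter_clusters(cs: ClusterSet, k_min: int, size_threshold: float | None = None,
                    strict_extent: bool = False) -> ClusterSet:
    """Keep clusters meeting the reporting minimum and (if given) the FWE size cut."""
    def keep(cl: Cluster) -> bool:
        ok = cl.size > k_min if strict_extent else cl.size >= k_min
        if size_threshold is not None:
            ok = ok and cl.size > size_threshold
        return ok

    out = [cl for cl in cs.clusters if keep(cl)]
    return ClusterSet(out, cs.forming_threshold, cs.connectivity, cs.shape, cs.affine,
                      cs.df, size_threshold, dict(cs.provenance))


def cluster_inference(volumes, design: DesignMatrix, contrast="decrease",
                      forming_p: float = 0.001, k_min: int = 100,
                      cluster_alpha: float = 0.05, n_perm: int = 1000,
                      seed: int | None = None, connectivity: int = 18,
                      mask: MaskVolume | None = None,
                      strict_extent: bool = False) -> ClusterSet:
    """Cluster-extent inference: form clusters at uncorrected voxel p, then keep
    those exceeding the permutation null of maximum cluster size at cluster_alpha
    (and the reporting extent minimum k_min)."""
    Y, analysis = stack_cohort(volumes, mask)
    if Y.shape[0] != design.n:
        raise DesignError(f"{Y.shape[0]} volumes but design has {design.n} rows")
    c = design.contrast(contrast) if isinstance(contrast, str) else np.asarray(contrast, float)
    t, df, _, sigma2 = _t_from_Y(Y, design.matrix, c)
    forming_t = float(stats.t.isf(forming_p, df))

    null = _null_distributions(Y, design, c, n_perm, np.random.default_rng(seed),
                               forming_t=forming_t, analysis=analysis,
                               connectivity=connectivity)
    size_thr = permutation_threshold(null.max_cluster, cluster_alpha)

    supra = np.zeros(analysis.data.shape, bool)
    supra[analysis.data] = (t > forming_t) & (sigma2 > 0)
    t_map = np.full(analysis.data.shape, np.nan)
    t_map[analysis.data] = t
    cs = connected_components(supra, connectivity, t_map=t_map, affine=analysis.affine)
    cs.forming_threshold = forming_t
    cs.df = df
    cs.provenance = {
        "forming_p": forming_p, "cluster_alpha": cluster_alpha, "k_min": k_min,
        "n_perm": int(null.n), "exhaustive": null.exhaustive, "seed": seed,
        "max_t_null": null.max_t, "max_cluster_null": null.max_cluster,
        "observed_max_t": float(np.nanmax(t_map)) if np.isfinite(t_map).any() else None,
    }
    return filter_clusters(cs, k_min, size_thr, strict_extent)


# ----------------------------------------------------------------- reference cluster

DEFAULT_ALPHA_GRID = (0.05, 0.01, 1e-3, 1e-4, 1e-5, 1e-6)


@dataclass
class ReferenceRegion:
    """Data-driven reference mask with its escalation provenance."""

    mask: MaskVolume
    provenance: dict


def derive_reference_cluster(volumes, design: DesignMatrix,
                             alphas=DEFAULT_ALPHA_GRID,
                             coherence_fraction: float = 0.9, min_size: int = 50,
                             method: str = "bonferroni", n_perm: int = 2000,
                             seed: int | None = None, connectivity: int = 18,
                             mask: MaskVolume | None = None,
                             atlas=None, atlas_fraction: float = 0.6) -> ReferenceRegion:
    """Escalate the voxel-FWE threshold on the increase contrast of global-mean
    normalized data until the result is dominated by one coherent cluster.

    Stops at the first (most lenient) level whose largest connected component
    has at least ``min_size`` voxels and is coherent.  Coherence means: the
    largest component holds at least ``coherence_fraction`` of all
    suprathreshold voxels, or — when a parcellation ``atlas`` (LabelVolume) is
    given — that at least ``atlas_fraction`` of the largest component's volume
    lies in a single atlas parcel, mirroring escalation "until most of the
    cluster volume can be assigned to one anatomical region".  Raises
    NoReferenceClusterError if no level qualifies — the expected outcome on
    null data.
    """
    alphas = sorted(alphas, reverse=True)
    Y, analysis = stack_cohort(volumes, mask)
    if Y.shape[0] != design.n:
        raise DesignError(f"{Y.shape[0]} volumes but design has {design.n} rows")
    c = design.contrast("increase")
    t, df, _, sigma2 = _t_from_Y(Y, design.matrix, c)
    V = int(analysis.data.sum())

    if method == "permutation":
        null = _null_distributions(Y, design, c, n_perm, np.random.default_rng(seed))
        thresholds = [permutation_threshold(null.max_t, a) for a in alphas]
    elif method == "bonferroni":
        thresholds = [float(stats.t.isf(a / V, df)) for a in alphas]
    else:
        raise ValueError("method must be 'permutation' or 'bonferroni'")

    path = []
    for alpha, thr in zip(alphas, thresholds):
        supra = np.zeros(analysis.data.shape, bool)
        supra[analysis.data] = (t > thr) & (sigma2 > 0)
        total = int(supra.sum())
        step = {"alpha": alpha, "threshold": thr, "n_suprathreshold": total,
                "largest": 0, "fraction": 0.0}
        if not total:
            path.append(step)
            continue
        cs = connected_components(supra, connectivity, affine=analysis.affine)
        largest = cs.clusters[0]
        m = np.zeros(analysis.data.shape, bool)
        m[tuple(largest.voxels.T)] = True
        step["largest"] = largest.size
        step["fraction"] = largest.size / total
        if atlas is not None:
            labels = atlas.data[m]
            labels = labels[labels > 0]
            if labels.size:
                counts = np.bincount(labels)
                dom = int(np.argmax(counts))
                step["dominant_parcel"] = atlas.label_table.get(dom, str(dom))
                step["dominant_fraction"] = counts[dom] / largest.size
            else:
                step["dominant_parcel"], step["dominant_fraction"] = None, 0.0
            coherent = step["dominant_fraction"] >= atlas_fraction
        else:
            coherent = step["fraction"] >= coherence_fraction
        path.append(step)
        if coherent and largest.size >= min_size:
            prov = {"alpha_achieved": alpha, "threshold": thr, "size": largest.size,
                    "fraction_in_largest": step["fraction"], "df": df,
                    "method": method, "connectivity": connectivity,
                    "n_voxels_tested": V, "seed": seed,
                    "coherence_rule": "atlas" if atlas is not None else "connectedness",
                    "escalation_path": path}
            if atlas is not None:
                prov["dominant_parcel"] = step["dominant_parcel"]
                prov["dominant_fraction"] = step["dominant_fraction"]
            return ReferenceRegion(MaskVolume(m, analysis.affine.copy()), prov)
    raise NoReferenceClusterError(
        f"no reference cluster found (escalation path: {path})")
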