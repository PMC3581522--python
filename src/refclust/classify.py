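"""Patient/control discrimination from the detected hypometabolic pattern.

For each subject the feature is the mean normalized uptake inside a pattern
mask (typically the hypometabolic pattern detected with cerebellar
normalization).  Discrimination is a single-feature logistic regression
evaluated by repeated stratified split-half cross-validation: each class is
randomly halved (the extra subject of an odd class goes to training), the model
is fit on the training halves and accuracy/sensitivity/specificity are scored
on the held-out halves.  Accuracy distributions from different normalization
schemes are compared with independent-sample t-tests under Bonferroni
correction — the same (anticonservative on resampled values) procedure the
field uses for this design, reported as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import roi_mean
from .volumes import MaskVolume, RefclustError, assert_same_grid


class ClassificationError(RefclustError):
    pass


def extract_pattern_means(volumes, pattern: MaskVolume, manifest) -> pd.DataFrame:
    """Per-subject mean normalized uptake inside the pattern mask."""
    if pattern.n_voxels == 0:
        raise ClassificationError("pattern mask is empty")
    if len(volumes) != manifest.n:
        raise ClassificationError("volume count does not match manifest")
    imgs = [v.image if hasattr(v, "image") else v for v in volumes]
    feats = [roi_mean(img, pattern) for img in imgs]
    return pd.DataFrame({"id": manifest.table["id"].to_numpy(),
                         "group": manifest.table["group"].to_numpy(),
                         "mean_uptake": feats})


def pattern_overlap(patterns: list[MaskVolume]) -> MaskVolume:
    """Voxel-wise AND of two or more pattern masks."""
    if len(patterns) < 2:
        raise ValueError("need at least two masks")
    for m in patterns[1:]:
        assert_same_grid(patterns[0], m)
    out = patterns[0].data.copy()
    for m in patterns[1:]:
        out &= m.data
    if not out.any():
        raise ClassificationError("patterns have empty intersection")
    return MaskVolume(out, patterns[0].affine.copy())


@dataclass
class LogisticModel:
    intercept: float
    slope: float

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        eta = np.clip(self.intercept + self.slope * np.asarray(x, float), -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) > 0.5).astype(int)


def fit_logistic(features, labels, ridge: float = 1e-8, max_iter: int = 50,
                 tol: float = 1e-10) -> LogisticModel:
    """Maximum-likelihood logistic fit by Newton/IRLS with a tiny ridge on the
    slope so perfectly separated training sets still converge to a stable,
    correctly-oriented boundary."""
    x = np.asarray(features, float)
    y = np.asarray(labels, float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ClassificationError("training labels must contain both classes")
    b = np.zeros(2)
    X = np.column_stack([np.ones_like(x), x])
    pen = np.array([0.0, ridge])
    for _ in range(max_iter):
        eta = np.clip(X @ b, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-12)
        grad = X.T @ (y - p) - pen * b
        H = (X * w[:, None]).T @ X + np.diag(np.maximum(pen, 1e-12))
        step = np.linalg.solve(H, grad)
        b += step
        if np.max(np.abs(step)) < tol:
            break
    return LogisticModel(float(b[0]), float(b[1]))


@dataclass
class AccuracyDistribution:
    """Split-half accuracy/sensitivity/specificity across repetitions."""

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_rep: int
    seed: int | None
    name: str = ""

    def summary(self) -> dict:
        return {m: {"mean": float(getattr(self, m).mean()),
                    "sd": float(getattr(self, m).std(ddof=1))}
                for m in ("accuracy", "sensitivity", "specificity")}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rep": np.arange(self.n_rep),
                             "accuracy": self.accuracy,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


def split_half_cv(features, labels, n_rep: int = 5000, seed: int | None = None,
                  stratified: bool = True, name: str = "") -> AccuracyDistribution:
    """Repeated stratified split-half cross-validation of the 1-feature model.

    labels: 1 = patient (sensitivity), 0 = control (specificity).
    """
    x = np.asarray(features, float)
    y = np.asarray(labels, int)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    if len(idx0) < 2 or len(idx1) < 2:
        raise ClassificationError("need at least 2 subjects per class")
    rng = np.random.default_rng(seed)
    acc = np.empty(n_rep)
    sens = np.empty(n_rep)
    spec = np.empty(n_rep)
    for r in range(n_rep):
        if stratified:
            p1 = rng.permutation(idx1)
            p0 = rng.permutation(idx0)
            h1 = -(-len(p1) // 2)  # odd counts: extra subject to training
            h0 = -(-len(p0) // 2)
            train = np.concatenate([p1[:h1], p0[:h0]])
            test = np.concatenate([p1[h1:], p0[h0:]])
        else:
            perm = rng.permutation(len(y))
            h = -(-len(y) // 2)
            train, test = perm[:h], perm[h:]
            if len(set(y[train])) < 2 or len(test) == 0:
                acc[r] = sens[r] = spec[r] = np.nan
                continue
        model = fit_logistic(x[train], y[train])
        pred = model.predict(x[test])
        correct = pred == y[test]
        acc[r] = correct.mean()
        t1 = y[test] == 1
        t0 = ~t1
        sens[r] = correct[t1].mean() if t1.any() else np.nan
        spec[r] = correct[t0].mean() if t0.any() else np.nan
    return AccuracyDistribution(acc, sens, spec, n_rep, seed, name)


def _ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Independent-sample t-test robust to (near-)constant arrays."""
    if np.var(a) + np.var(b) < 1e-16:
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else \
            (np.inf if a.mean() > b.mean() else -np.inf, 0.0)
    with warnings.catch_warnings():
        # scipy warns about moment precision on ceiling-valued distributions
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def compare_distributions(dists: list[AccuracyDistribution], alpha: float = 0.05,
                          metric: str = "accuracy") -> pd.DataFrame:
    """Pairwise independent-sample t-tests between schemes, Bonferroni over pairs."""
    if len(dists) < 2:
        raise ValueError("need at least two distributions")
    n_rep = {d.n_rep for d in dists}
    if len(n_rep) != 1:
        raise ClassificationError("distributions have mismatched n_rep")
    pairs = [(i, j) for i in range(len(dists)) for j in range(i + 1, len(dists))]
    rows = []
    for i, j in pairs:
        a, b = getattr(dists[i], metric), getattr(dists[j], metric)
        if np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = _ttest(a, b)
        p_bonf = min(1.0, p * len(pairs))
        rows.append({"a": dists[i].name or str(i), "b": dists[j].name or str(j),
                     "metric": metric, "mean_a": float(np.mean(a)),
                     "mean_b": float(np.mean(b)), "t": float(t), "p": float(p),
                     "p_bonferroni": p_bonf, "significant": p_bonf < alpha})
    return pd.DataFrame(rows)


def compare_sens_spec(dist: AccuracyDistribution, alpha: float = 0.05) -> dict:
    """Within one scheme: is sensitivity lower/higher than specificity?"""
    t, p = _ttest(dist.sensitivity, dist.specificity)
    return {"scheme": dist.name, "t": float(t), "p": float(p),
            "significant": p < alpha,
            "sensitivity_mean": float(dist.sensitivity.mean()),
            "specificity_mean": float(dist.specificity.mean())}
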