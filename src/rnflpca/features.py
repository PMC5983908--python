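"""Eigen-feature extraction from standardized thickness maps.

Each registered, standardized scan is a point in pixel space; principal
component analysis finds the orthonormal spatial modes ("RNFL features")
that explain the major directions of variation. A scan is then the mean
map plus a weighted sum of features, and the weight vector is the scan's
low-dimensional structural representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class PCAFeatureModel:
    """Top-K orthonormal component maps with variance fractions.

    ``mean`` and ``components`` live on the (H, W) grid in standardized
    units; components have unit norm and are sign-canonicalized so the
    largest-|loading| pixel of each is positive.
    """

    mean: np.ndarray                 # (H, W)
    components: np.ndarray           # (K, H, W)
    variance_fraction: np.ndarray    # (K,) of the total variance
    n_fitted: int

    @property
    def k(self) -> int:
        return self.components.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean.shape  # type: ignore[return-value]

    def components_flat(self) -> np.ndarray:
        return self.components.reshape(self.k, -1)


def fit_pca(stack: np.ndarray, k: int = 10) -> PCAFeatureModel:
    """Fit the top-``k`` eigen-features of an ``(n, H, W)`` standardized stack.

    Uses a deterministic full SVD (equivalent to eigendecomposition of the
    sample covariance via the Gram duality when pixels >> scans). NaN pixels
    are imputed with 0, the standardized mean.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n, H, W)")
    n, h, w = stack.shape
    if not 1 <= k <= min(n - 1, h * w):
        raise ValueError(f"k={k} outside [1, min(n-1, n_pixels)]")
    x = np.nan_to_num(stack.reshape(n, -1), nan=0.0)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(x)
    comps = pca.components_
    # sign canonicalization: largest |loading| positive
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return PCAFeatureModel(mean=pca.mean_.reshape(h, w),
                           components=comps.reshape(k, h, w),
                           variance_fraction=pca.explained_variance_ratio_.copy(),
                           n_fitted=n)


def project(values: np.ndarray, model: PCAFeatureModel) -> np.ndarray:
    """Feature weights ``w_k = <map - mean, component_k>``.

    Accepts one (H, W) map or an (n, H, W) stack; NaN pixels are imputed
    with 0 before projection.
    """
    v = np.asarray(values, dtype=float)
    single = v.ndim == 2
    v = v.reshape(1, *v.shape) if single else v
    if v.shape[-2:] != model.shape:
        raise ValueError("map shape does not match the feature model")
    x = np.nan_to_num(v.reshape(v.shape[0], -1), nan=0.0)
    x = x - model.mean.reshape(1, -1)
    w = x @ model.components_flat().T
    return w[0] if single else w


def reconstruct(weights: np.ndarray, model: PCAFeatureModel) -> np.ndarray:
    """Map (stack) reconstructed as mean + sum_k w_k * component_k."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if w.shape[1] != model.k:
        raise ValueError("weight vector length does not match K")
    flat = model.mean.reshape(1, -1) + w @ model.components_flat()
    out = flat.reshape(-1, *model.shape)
    return out[0] if np.ndim(weights) == 1 else out


def feature_change_map(model: PCAFeatureModel, k: int,
                       quantile: float = 0.9) -> np.ndarray:
    """Binary mask of the pixels a feature loads on most strongly.

    Pixels whose |loading| exceeds the given quantile of the component's
    |loading| distribution — the "areas of greatest associated change"
    rendering of a feature.
    """
    if not 0 <= k < model.k:
        raise ValueError(f"component index {k} out of range")
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    a = np.abs(model.components[k])
    if quantile == 0.0:
        return np.ones_like(a, dtype=bool)
    thr = np.quantile(a, quantile)
    return a > thr
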