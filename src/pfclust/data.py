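"""Datasets, synthetic generators, and image <-> feature conversion.

Everything the algorithms and scores need is constructible offline:

* :func:`load_x12` — a frozen 12-point benchmark of two symmetric
  5-point clusters plus two outliers, with known ideal centroids, the
  classic stress test for outlier sensitivity of fuzzy clustering;
* :func:`make_blobs` — seeded Gaussian clusters with optional uniform
  gross outliers;
* :func:`make_phantom` — a piecewise-constant 2-D phantom of nested
  regions (background / CSF / GM / WM analog) with additive Gaussian
  noise expressed as a percentage of the intensity range, emulating the
  noise sweeps of simulated brain-MRI repositories;
* raster-order flattening of 2-D/3-D grayscale images to per-pixel
  feature vectors and back, with optional masks;
* CSV / PNG / TIFF / NIfTI readers and writers.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import as_feature_matrix

__all__ = [
    "LabeledDataset",
    "load_x12",
    "make_blobs",
    "make_phantom",
    "image_to_features",
    "features_to_labelmap",
    "read_features_csv",
    "write_features_csv",
    "read_labels_csv",
    "write_labels_csv",
    "read_image",
    "write_label_image",
]

# Twelve points: two symmetric five-point clusters on the x-axis plus a
# central point and a remote outlier at (0, 10). Ideal centroids sit at
# (+-3.14, 0); the outliers are deliberately unlabeled.
_X12 = np.array(
    [
        [-5.00, 0.00],
        [-3.34, 1.67],
        [-3.34, 0.00],
        [-3.34, -1.67],
        [-1.67, 0.00],
        [1.67, 0.00],
        [3.34, 1.67],
        [3.34, 0.00],
        [3.34, -1.67],
        [5.00, 0.00],
        [0.00, 0.00],
        [0.00, 10.00],
    ]
)
_X12_IDEAL = np.array([[-3.14, 0.0], [3.14, 0.0]])
_X12_LABELS = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, -1, -1])


@dataclasses.dataclass
class LabeledDataset:
    """A feature matrix with optional ground truth.

    ``labels`` uses -1 for unlabeled objects (e.g. injected outliers).
    """

    X: np.ndarray
    labels: Optional[np.ndarray] = None
    true_centers: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = as_feature_matrix(self.X)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
            if self.labels.size != self.X.shape[0]:
                raise ValueError("labels length must match number of rows in X")


def load_x12() -> LabeledDataset:
    """The frozen 12-point two-cluster benchmark with two outliers."""
    return LabeledDataset(
        X=_X12.copy(), labels=_X12_LABELS.copy(), true_centers=_X12_IDEAL.copy()
    )


def make_blobs(
    K: int = 2,
    n_per_cluster: int = 100,
    centers: Optional[Sequence[Sequence[float]]] = None,
    spread: float = 0.5,
    n_outliers: int = 0,
    outlier_box: Sequence[Sequence[float]] = ((-20.0, 20.0), (-20.0, 20.0)),
    seed: Optional[int] = None,
) -> LabeledDataset:
    """Isotropic Gaussian clusters plus uniform gross outliers.

    Parameters
    ----------
    K : int
        Number of clusters.
    n_per_cluster : int
        Points drawn per cluster.
    centers : sequence of length-q sequences, optional
        True cluster means; defaults to K points evenly spaced on the
        x-axis between -3 and 3 in 2-D.
    spread : float
        Isotropic Gaussian standard deviation of each cluster.
    n_outliers : int
        Uniform draws from ``outlier_box``, labeled -1.
    outlier_box : sequence of (low, high) pairs, one per feature.
    seed : int, optional
        Seeds the generator; identical arguments + seed give identical
        datasets.
    """
    if K < 1 or n_per_cluster < 1:
        raise ValueError("K and n_per_cluster must be positive")
    if n_outliers < 0:
        raise ValueError("n_outliers must be nonnegative")
    if centers is None:
        xs = np.linspace(-3.0, 3.0, K) if K > 1 else np.array([0.0])
        centers = np.column_stack([xs, np.zeros(K)])
    C = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if C.shape[0] != K:
        raise ValueError(f"expected {K} centers, got {C.shape[0]}")
    if spread < 0:
        raise ValueError("spread must be nonnegative")
    rng = np.random.default_rng(seed)
    parts, labels = [], []
    for j in range(K):
        parts.append(C[j] + spread * rng.standard_normal((n_per_cluster, C.shape[1])))
        labels.append(np.full(n_per_cluster, j))
    if n_outliers:
        box = np.asarray(outlier_box, dtype=np.float64)
        if box.shape != (C.shape[1], 2):
            raise ValueError("outlier_box needs one (low, high) pair per feature")
        parts.append(rng.uniform(box[:, 0], box[:, 1], size=(n_outliers, C.shape[1])))
        labels.append(np.full(n_outliers, -1))
    return LabeledDataset(
        X=np.vstack(parts), labels=np.concatenate(labels), true_centers=C.copy()
    )


def make_phantom(
    shape: Sequence[int] = (64, 64),
    tissue_means: Sequence[float] = (0.05, 0.35, 0.65, 0.95),
    noise_pct: float = 0.0,
    seed: Optional[int] = None,
    radii: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nested-disc 2-D phantom with percent-scaled Gaussian noise.

    Region k (0 = background, increasing inward) takes intensity
    ``tissue_means[k]``; with four means the rings mimic a
    background/CSF/GM/WM slice. Additive Gaussian noise has standard
    deviation ``noise_pct`` percent of the full intensity range
    (``max(means) - min(means)``), mirroring the percent convention of
    simulated brain-MRI noise sweeps.

    Parameters
    ----------
    shape : (H, W)
    tissue_means : sequence of floats, one per region, outermost first.
    noise_pct : float
        Noise level in percent of the intensity range (0 disables).
    seed : int, optional
    radii : sequence of floats, optional
        Region boundary radii as fractions of the half-extent, strictly
        decreasing, one per interior region. The default spaces them so
        the interior regions have comparable pixel counts (as GM and WM
        do in a real brain slice) rather than the vanishing areas that
        equal radial spacing would give.

    Returns
    -------
    (image, labels)
        Float image and integer ground-truth label map, same shape.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 2 or min(shape) < 4:
        raise ValueError("shape must be 2-D and at least 4 x 4")
    means = np.asarray(tissue_means, dtype=np.float64)
    T = means.size
    if T < 2:
        raise ValueError("need at least two tissue means")
    if radii is None:
        # equal-area rings inside an outer disc of radius 0.9:
        # r_k = 0.9 * sqrt((T - k) / (T - 1)), k = 1 .. T-1
        ks = np.arange(1, T)
        radii = 0.9 * np.sqrt((T - ks) / (T - 1.0))
    radii = np.asarray(radii, dtype=np.float64)
    if radii.size != T - 1 or np.any(np.diff(radii) >= 0) or np.any(radii <= 0):
        raise ValueError("radii must be strictly decreasing positive fractions, one per interior region")
    if noise_pct < 0:
        raise ValueError("noise_pct must be nonnegative")

    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx) / (min(H, W) / 2.0)
    labels = np.zeros(shape, dtype=np.int64)
    for k, rad in enumerate(radii, start=1):
        labels[r <= rad] = k
    image = means[labels]
    if noise_pct > 0:
        rng = np.random.default_rng(seed)
        sigma = (noise_pct / 100.0) * (means.max() - means.min())
        image = image + sigma * rng.standard_normal(shape)
    return image, labels


def image_to_features(
    image: np.ndarray, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Flatten a grayscale image (any dimensionality) to an N x 1
    feature matrix in raster (row-major) order.

    A multi-channel image (trailing channel axis flagged by ``ndim`` of
    the mask, or an explicit last axis when ``image.ndim == mask.ndim +
    1``) yields one column per channel. Positions where ``mask`` is
    False are excluded.
    """
    image = np.asarray(image, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape == image.shape:
            flat = image.reshape(-1, 1)
            keep = mask.reshape(-1)
        elif image.ndim == mask.ndim + 1 and image.shape[:-1] == mask.shape:
            flat = image.reshape(-1, image.shape[-1])
            keep = mask.reshape(-1)
        else:
            raise ValueError(
                f"mask shape {mask.shape} incompatible with image shape {image.shape}"
            )
        return flat[keep]
    return image.reshape(-1, 1)


def features_to_labelmap(
    labels: np.ndarray,
    shape: Sequence[int],
    mask: Optional[np.ndarray] = None,
    background_label: int = -1,
) -> np.ndarray:
    """Reshape per-pixel labels back to image geometry (raster order).

    With a ``mask``, labels fill only the True positions and everything
    else receives ``background_label``.
    """
    labels = np.asarray(labels).ravel()
    shape = tuple(int(s) for s in shape)
    if mask is None:
        if labels.size != int(np.prod(shape)):
            raise ValueError(
                f"{labels.size} labels cannot fill an image of shape {shape}"
            )
        return labels.reshape(shape)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match {shape}")
    if labels.size != int(mask.sum()):
        raise ValueError("label count does not match number of unmasked positions")
    out = np.full(shape, background_label, dtype=labels.dtype)
    out[mask] = labels
    return out


# ---------------------------------------------------------------------------
# File I/O

def read_features_csv(path) -> np.ndarray:
    """Read an all-numeric CSV (header row optional) as a feature matrix."""
    path = Path(path)
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = not bool(first.iloc[0].map(_is_number).all())
    df = pd.read_csv(path, header=0 if has_header else None)
    return as_feature_matrix(df.to_numpy(dtype=np.float64), str(path))


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_features_csv(path, X: np.ndarray, header: bool = False) -> None:
    X = as_feature_matrix(X)
    df = pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
    df.to_csv(path, index=False, header=header)


def read_labels_csv(path) -> np.ndarray:
    df = pd.read_csv(path, header=None)
    return df.to_numpy().ravel().astype(np.int64)


def write_labels_csv(path, labels: np.ndarray) -> None:
    pd.DataFrame(np.asarray(labels).ravel()).to_csv(path, index=False, header=False)


def read_image(path) -> np.ndarray:
    """Read a grayscale image: PNG/TIFF via imageio, NIfTI via nibabel."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    import imageio.v3 as iio

    img = iio.imread(path).astype(np.float64)
    if img.ndim == 3 and img.shape[-1] in (3, 4):  # collapse RGB(A) to gray
        img = img[..., :3].mean(axis=-1)
    return img


def write_label_image(path, labels: np.ndarray) -> None:
    """Write an integer label map as an image (PNG/TIFF) or NIfTI."""
    path = Path(path)
    labels = np.asarray(labels)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(labels.astype(np.int16), np.eye(4)), str(path))
        return
    import imageio.v3 as iio

    if labels.min() < 0 or labels.max() > 255:
        raise ValueError("label image values must fit in uint8")
    iio.imwrite(path, labels.astype(np.uint8))
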