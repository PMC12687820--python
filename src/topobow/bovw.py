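"""Bag-of-visual-words encoding with SURF-style local features.

Interest points are detected on the gray channel as maxima of the
box-filter determinant-of-Hessian response computed on an integral image
(``skimage.feature.blob_doh``), across scales covering roughly three
octaves.  Each keypoint gets an upright 64-dimensional descriptor: Haar
wavelet responses (dx, dy, filter size 2s) are sampled on a 20x20 grid of
step s covering a 20s-square window, Gaussian-weighted, and accumulated as
(sum dx, sum |dx|, sum dy, sum |dy|) over a 4x4 grid of subregions; the
result is L2-normalized and zero descriptors are discarded.

Descriptors from the training images of a fold are clustered into a
K = 150 visual vocabulary by mini-batch k-means (k-means++ init, seeded),
and every image is then encoded as the L1-normalized histogram of
nearest-centroid assignments — its distribution over visual words.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import blob_doh
from sklearn.cluster import MiniBatchKMeans

from .preprocess import ImageRecord

K_WORDS = 150
DESCRIPTOR_DIM = 64

#: detector defaults: scales spanning ~3 octaves, response threshold set
#: so that a typical phantom/histology image yields tens to hundreds of
#: keypoints.
MIN_SIGMA = 2.0
MAX_SIGMA = 16.0
NUM_SIGMA = 8
DOH_THRESHOLD = 0.002


@dataclass(frozen=True)
class DescriptorSet:
    """Local descriptors of one image: (N, 64) rows, unit L2 norm."""

    image_id: str
    descriptors: np.ndarray
    keypoints: np.ndarray  # (N, 3) rows of (y, x, sigma)


@dataclass(frozen=True)
class VisualVocabulary:
    """K visual words (cluster centroids) fitted on training descriptors."""

    centroids: np.ndarray  # (K, 64)
    seed: int
    n_descriptors: int
    training_ids: frozenset = field(default_factory=frozenset)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def save(self, path) -> None:
        np.savez(path, centroids=self.centroids, seed=self.seed,
                 n_descriptors=self.n_descriptors,
                 training_ids=np.array(sorted(self.training_ids), dtype=object))

    @classmethod
    def load(cls, path) -> "VisualVocabulary":
        with np.load(path, allow_pickle=True) as z:
            return cls(centroids=z["centroids"], seed=int(z["seed"]),
                       n_descriptors=int(z["n_descriptors"]),
                       training_ids=frozenset(z["training_ids"].tolist()))


def _integral(img: np.ndarray) -> np.ndarray:
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    ii[1:, 1:] = img.cumsum(axis=0).cumsum(axis=1)
    return ii


def _box_sum(ii: np.ndarray, y0, x0, y1, x1) -> np.ndarray:
    """Sum of img[y0:y1, x0:x1] from the integral image (vectorized)."""
    h, w = ii.shape[0] - 1, ii.shape[1] - 1
    y0 = np.clip(y0, 0, h); y1 = np.clip(y1, 0, h)
    x0 = np.clip(x0, 0, w); x1 = np.clip(x1, 0, w)
    return ii[y1, x1] - ii[y0, x1] - ii[y1, x0] + ii[y0, x0]


def _descriptor(ii: np.ndarray, y: float, x: float, s: float) -> np.ndarray:
    """Upright 64-d Haar descriptor at keypoint (y, x) with scale s."""
    step = max(1, int(round(s)))
    # 20x20 sample grid centered on the keypoint, spacing = scale
    offs = (np.arange(20) - 9.5) * step
    sy = np.rint(y + offs[:, None] + np.zeros((1, 20))).astype(int)
    sx = np.rint(x + np.zeros((20, 1)) + offs[None, :]).astype(int)
    h = step  # Haar half-size: filters are 2s x 2s
    dx = (_box_sum(ii, sy - h, sx, sy + h, sx + h)
          - _box_sum(ii, sy - h, sx - h, sy + h, sx))
    dy = (_box_sum(ii, sy, sx - h, sy + h, sx + h)
          - _box_sum(ii, sy - h, sx - h, sy, sx + h))
    g = np.exp(-(offs[:, None] ** 2 + offs[None, :] ** 2) / (2 * (3.3 * step) ** 2))
    dx = dx * g
    dy = dy * g
    feat = np.empty(DESCRIPTOR_DIM)
    k = 0
    for by in range(4):
        for bx in range(4):
            px = dx[5 * by:5 * by + 5, 5 * bx:5 * bx + 5]
            py = dy[5 * by:5 * by + 5, 5 * bx:5 * bx + 5]
            feat[k:k + 4] = (px.sum(), np.abs(px).sum(), py.sum(), np.abs(py).sum())
            k += 4
    return feat


def detect_and_describe(record: ImageRecord, threshold: float = DOH_THRESHOLD,
                        min_sigma: float = MIN_SIGMA, max_sigma: float = MAX_SIGMA,
                        num_sigma: int = NUM_SIGMA) -> DescriptorSet:
    """Detect blob keypoints on the gray channel and describe each one.

    An image with no detectable structure (e.g. a constant plane) yields a
    valid empty DescriptorSet.
    """
    gray = record.channels["gray"].astype(float) / 255.0
    blobs = blob_doh(gray, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=num_sigma, threshold=threshold)
    ii = _integral(gray)
    h, w = gray.shape
    descs, kept = [], []
    for y, x, sigma in blobs:
        # keypoints need support inside the image; box responses right at
        # the border are clipped and unreliable
        if not (sigma <= y <= h - 1 - sigma and sigma <= x <= w - 1 - sigma):
            continue
        d = _descriptor(ii, y, x, sigma)
        norm = np.linalg.norm(d)
        if norm > 0:
            descs.append(d / norm)
            kept.append((y, x, sigma))
    if descs:
        D = np.vstack(descs)
        kp = np.array(kept)
    else:
        D = np.empty((0, DESCRIPTOR_DIM))
        kp = np.empty((0, 3))
    return DescriptorSet(image_id=record.id, descriptors=D, keypoints=kp)


def stack_descriptors(descriptor_sets) -> np.ndarray:
    mats = [ds.descriptors for ds in descriptor_sets if len(ds.descriptors)]
    if not mats:
        return np.empty((0, DESCRIPTOR_DIM))
    return np.vstack(mats)


def fit_vocabulary(descriptor_sets, k: int = K_WORDS, seed: int = 0,
                   batch_size: int = 1024, max_iter: int = 100) -> VisualVocabulary:
    """Cluster training descriptors into a K-word visual vocabulary.

    Mini-batch k-means with k-means++ initialization; deterministic for a
    fixed seed.  Random reassignment of sparse clusters is disabled so the
    fitted objective never drifts above the k-means++ solution (and the
    degenerate n == k case stays at its exact optimum).  The vocabulary
    records the ids of the images it was fitted on so downstream code can
    verify fold isolation.
    """
    X = stack_descriptors(descriptor_sets)
    if len(X) < k:
        raise ValueError(
            f"need at least {k} descriptors to fit a {k}-word vocabulary, "
            f"got {len(X)}; add training images or reduce k"
        )
    km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3,
                         batch_size=batch_size, max_iter=max_iter,
                         reassignment_ratio=0.0)
    km.fit(X)
    return VisualVocabulary(
        centroids=km.cluster_centers_.copy(), seed=seed, n_descriptors=len(X),
        training_ids=frozenset(ds.image_id for ds in descriptor_sets),
    )


def kmeans_objective(descriptor_sets, centroids: np.ndarray) -> float:
    """Sum of squared distances from each descriptor to its nearest word."""
    X = stack_descriptors(descriptor_sets)
    if len(X) == 0:
        return 0.0
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


@dataclass(frozen=True)
class BovwHistogram:
    """Visual-word histogram of one image (length K)."""

    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or np.any(v < 0):
            raise ValueError("histogram must be 1-D and nonnegative")
        object.__setattr__(self, "values", v)


def encode_histogram(descriptors: DescriptorSet, vocab: VisualVocabulary,
                     normalize: bool = True) -> BovwHistogram:
    """Assign each descriptor to its nearest visual word and histogram.

    Ties break to the lowest centroid index.  An empty descriptor set
    encodes as the all-zero histogram (the image stays classifiable
    through its topological block).
    """
    X = descriptors.descriptors
    k = vocab.k
    if len(X) == 0:
        return BovwHistogram(values=np.zeros(k), normalized=normalize)
    if X.shape[1] != vocab.centroids.shape[1]:
        raise ValueError(
            f"descriptor width {X.shape[1]} != vocabulary width "
            f"{vocab.centroids.shape[1]}"
        )
    d2 = ((X[:, None, :] - vocab.centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    counts = np.bincount(assign, minlength=k).astype(float)
    if normalize:
        counts /= counts.sum()
    return BovwHistogram(values=counts, normalized=normalize)


def feature_names(k: int = K_WORDS) -> list[str]:
    return [f"bovw_{j}" for j in range(k)]
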