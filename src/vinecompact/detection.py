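"""Cluster-candidate extraction and bag-of-visual-words filtering.

The grape layer of the segmentation is opened with a radius-3 disk, each
8-connected component becomes a candidate bounding box, and every candidate
sub-image is summarised as a histogram of local-descriptor assignments to a
k-means codebook (bag of visual words).  An RBF-kernel support vector
machine then keeps "cluster" candidates and discards grape-coloured
non-cluster objects.

Local descriptors
-----------------
The descriptors are 64-dimensional, upright, SURF-style blob features:
keypoints come from a determinant-of-Hessian blob detector and each
keypoint's scale-adapted patch is summarised on a 4x4 grid of Haar-wavelet
response sums (sum dx, sum |dx|, sum dy, sum |dy| per cell), L2-normalised.
Detector parameters are part of the descriptor contract and are recorded
with the codebook; any 64-d blob descriptor can stand behind the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.color import rgb2gray
from skimage.feature import blob_doh
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk as disk_footprint
from skimage.morphology import opening
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.svm import SVC

from .colorseg import SegmentationMap

__all__ = [
    "BoVWHistogram",
    "CandidateBox",
    "ClusterClassifier",
    "Codebook",
    "DEFAULT_BOX_CONSTRAINT",
    "DEFAULT_KERNEL_SCALE",
    "build_codebook",
    "candidate_boxes",
    "detect_clusters",
    "encode_bovw",
    "grape_mask",
    "local_descriptors",
    "morph_open",
    "train_cluster_classifier",
]

#: Tuned SVM operating point (Bayesian optimisation over [1e-3, 1e3] for
#: both hyperparameters).
DEFAULT_BOX_CONSTRAINT = 1.4654
DEFAULT_KERNEL_SCALE = 24.628

DESCRIPTOR_DIM = 64
DEFAULT_MIN_AREA = 100


def grape_mask(segmap: SegmentationMap) -> np.ndarray:
    """Binary mask that is true exactly where the label is "grape"."""
    return segmap.labels == segmap.class_names.index("grape")


def morph_open(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening with a disk of the given radius (pixels at
    Euclidean distance <= radius from the centre).  Removes objects smaller
    than the element; the result is a subset of the input."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return opening(np.asarray(mask, bool), disk_footprint(radius))


@dataclass
class CandidateBox:
    """A cluster candidate: the minimal bounding box of one connected
    component of the opened grape mask, with its crops."""

    box: tuple[int, int, int, int]  # row_min, col_min, row_max, col_max incl.
    sub_image: np.ndarray
    sub_mask: np.ndarray


def candidate_boxes(
    mask: np.ndarray,
    image: np.ndarray | None = None,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[CandidateBox]:
    """One candidate per 8-connected component of ``mask``.

    Components with fewer than ``min_area`` pixels are dropped (tiny
    residues the opening did not clear).  Candidates are ordered row-major
    by box origin, so the output is deterministic.
    """
    mask = np.asarray(mask, bool)
    labelled = cc_label(mask, connectivity=2)
    out = []
    for region in regionprops(labelled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox  # half-open
        sub_mask = labelled[r0:r1, c0:c1] == region.label
        sub_image = image[r0:r1, c0:c1] if image is not None else None
        out.append(
            CandidateBox(box=(r0, c0, r1 - 1, c1 - 1), sub_image=sub_image,
                         sub_mask=sub_mask)
        )
    out.sort(key=lambda c: (c.box[0], c.box[1]))
    return out


# ---------------------------------------------------------------------------
# local descriptors

#: Default determinant-of-Hessian detector parameters; part of the
#: descriptor contract recorded in the model archive.
DETECTOR_DEFAULTS = {"min_sigma": 2.0, "max_sigma": 10.0, "num_sigma": 9,
                     "threshold": 0.002}

_PATCH_GRID = 20  # resampled patch side; 4x4 cells of 5x5 samples


def local_descriptors(sub_image: np.ndarray, **detector_params) -> np.ndarray:
    """Upright 64-d SURF-style descriptors for a sub-image.

    Returns an (n, 64) float array (possibly empty).  Images smaller than
    16x16 yield an empty set rather than an error.  Deterministic for fixed
    input and parameters.
    """
    sub_image = np.asarray(sub_image)
    params = {**DETECTOR_DEFAULTS, **detector_params}
    if sub_image.ndim == 3:
        gray = rgb2gray(sub_image)
    else:
        gray = sub_image.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
    h, w = gray.shape
    if h < 16 or w < 16:
        return np.empty((0, DESCRIPTOR_DIM))
    blobs = blob_doh(gray, **params)  # rows of (row, col, sigma)
    if blobs.shape[0] == 0:
        return np.empty((0, DESCRIPTOR_DIM))
    descriptors = []
    for row, col, sigma in blobs:
        half = max(8, int(round(5.0 * sigma)))
        patch = _extract_patch(gray, row, col, half)
        patch = resize(patch, (_PATCH_GRID, _PATCH_GRID), order=1,
                       anti_aliasing=False, preserve_range=True)
        dy, dx = np.gradient(patch)
        desc = np.empty(DESCRIPTOR_DIM)
        i = 0
        for by in range(4):
            for bx in range(4):
                cy, cx = slice(5 * by, 5 * by + 5), slice(5 * bx, 5 * bx + 5)
                desc[i:i + 4] = (dx[cy, cx].sum(), np.abs(dx[cy, cx]).sum(),
                                 dy[cy, cx].sum(), np.abs(dy[cy, cx]).sum())
                i += 4
        norm = np.linalg.norm(desc)
        if norm > 1e-12:
            descriptors.append(desc / norm)
    if not descriptors:
        return np.empty((0, DESCRIPTOR_DIM))
    return np.asarray(descriptors)


def _extract_patch(gray, row, col, half):
    r, c = int(round(row)), int(round(col))
    h, w = gray.shape
    pad_top = max(0, half - r)
    pad_left = max(0, half - c)
    pad_bottom = max(0, r + half + 1 - h)
    pad_right = max(0, c + half + 1 - w)
    if pad_top or pad_left or pad_bottom or pad_right:
        gray = np.pad(gray, ((pad_top, pad_bottom), (pad_left, pad_right)),
                      mode="reflect")
        r += pad_top
        c += pad_left
    return gray[r - half:r + half + 1, c - half:c + half + 1]


# ---------------------------------------------------------------------------
# codebook and histograms


@dataclass
class Codebook:
    """k-means centroids over local descriptors ("codewords")."""

    centroids: np.ndarray  # (k, 64)
    training_seed: int
    detector_params: dict = field(default_factory=lambda: dict(DETECTOR_DEFAULTS))

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def build_codebook(descriptor_sets, k: int = 100, seed: int = 0) -> Codebook:
    """Cluster pooled descriptors into a k-word codebook.

    Uses k-means++ initialisation with a fixed seed; the k-means objective
    is non-increasing over iterations by construction of the algorithm.
    """
    pool = [np.asarray(d) for d in descriptor_sets if np.asarray(d).size]
    if not pool:
        raise ValueError("no descriptors supplied")
    stacked = np.vstack(pool)
    if stacked.shape[0] < k:
        raise ValueError(
            f"need at least k={k} descriptors, got {stacked.shape[0]}"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(stacked)
    return Codebook(centroids=km.cluster_centers_.copy(), training_seed=seed)


@dataclass
class BoVWHistogram:
    """Counts of descriptors assigned to each codeword."""

    counts: np.ndarray  # (k,) non-negative ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def encode_bovw(descriptors: np.ndarray, codebook: Codebook) -> BoVWHistogram:
    """Assign each descriptor to its Euclidean-nearest centroid (ties to the
    lowest centroid index) and return the count histogram.  The counts sum
    to the number of descriptors."""
    descriptors = np.asarray(descriptors)
    k = codebook.k
    if descriptors.size == 0:
        return BoVWHistogram(counts=np.zeros(k, dtype=int))
    if descriptors.ndim != 2 or descriptors.shape[1] != DESCRIPTOR_DIM:
        raise ValueError(f"descriptors must be (n, {DESCRIPTOR_DIM})")
    nearest = np.argmin(cdist(descriptors, codebook.centroids), axis=1)
    return BoVWHistogram(counts=np.bincount(nearest, minlength=k))


# ---------------------------------------------------------------------------
# cluster / non-cluster classifier


@dataclass
class ClusterClassifier:
    """RBF-kernel SVM over BoVW histograms.

    ``kernel_scale`` follows the K(x, x') = exp(-||x - x'||^2 / scale^2)
    convention, i.e. gamma = 1 / kernel_scale^2.  Label order is
    ("cluster", "non-cluster"); the decision score is positive for
    "cluster".  The support data is exposed so the decision function can be
    re-evaluated without the fitting library.
    """

    box_constraint: float
    kernel_scale: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    k: int
    normalize: bool = False
    label_order: tuple[str, str] = ("cluster", "non-cluster")

    def decision_scores(self, histograms) -> np.ndarray:
        x = _histogram_matrix(histograms, self.k, self.normalize)
        gamma = 1.0 / self.kernel_scale**2
        kmat = np.exp(-gamma * cdist(x, self.support_vectors, "sqeuclidean"))
        return kmat @ self.dual_coef + self.intercept

    def predict(self, histograms) -> np.ndarray:
        """Boolean array: True where the candidate is predicted "cluster"."""
        return self.decision_scores(histograms) > 0


def _histogram_matrix(histograms, k, normalize):
    rows = []
    for h in histograms:
        counts = h.counts if isinstance(h, BoVWHistogram) else np.asarray(h)
        if counts.shape != (k,):
            raise ValueError(f"histogram length {counts.shape} != codebook k={k}")
        counts = counts.astype(float)
        if normalize and counts.sum() > 0:
            counts = counts / counts.sum()
        rows.append(counts)
    return np.asarray(rows)


def train_cluster_classifier(
    histograms,
    labels,
    box_constraint: float = DEFAULT_BOX_CONSTRAINT,
    kernel_scale: float = DEFAULT_KERNEL_SCALE,
    *,
    normalize: bool = False,
) -> ClusterClassifier:
    """Fit the soft-margin RBF SVM on BoVW histograms.

    ``labels`` may be the strings "cluster"/"non-cluster" or booleans (True
    = cluster).  Histograms enter as raw counts by default ("the number of
    occurrences of every codeword"); ``normalize`` switches to L1-normalised
    frequencies for scale-sensitive use.
    """
    if box_constraint <= 0 or kernel_scale <= 0:
        raise ValueError("box_constraint and kernel_scale must be positive")
    y = np.asarray(
        [1 if (lab is True or lab == "cluster") else 0 for lab in labels]
    )
    if np.unique(y).size < 2:
        raise ValueError("both 'cluster' and 'non-cluster' labels required")
    k = (histograms[0].counts if isinstance(histograms[0], BoVWHistogram)
         else np.asarray(histograms[0])).shape[0]
    x = _histogram_matrix(histograms, k, normalize)
    svc = SVC(C=box_constraint, kernel="rbf", gamma=1.0 / kernel_scale**2)
    svc.fit(x, y)
    # sklearn's decision is positive for class 1 = "cluster" here
    return ClusterClassifier(
        box_constraint=box_constraint,
        kernel_scale=kernel_scale,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        k=k,
        normalize=normalize,
    )


def detect_clusters(
    image: np.ndarray,
    segmap: SegmentationMap,
    codebook: Codebook,
    classifier: ClusterClassifier,
    *,
    opening_radius: int = 3,
    min_area: int = DEFAULT_MIN_AREA,
) -> tuple[list[CandidateBox], np.ndarray]:
    """Full detection pipeline: grape mask -> radius-3 opening -> candidate
    boxes -> BoVW encoding -> SVM filter.

    Returns the candidates predicted "cluster" and their decision scores.
    Candidates touching the image border are retained (partial clusters
    count as positives).
    """
    if codebook.k != classifier.k:
        raise ValueError(
            f"codebook k={codebook.k} != classifier k={classifier.k}"
        )
    mask = morph_open(grape_mask(segmap), opening_radius)
    cands = candidate_boxes(mask, image=image, min_area=min_area)
    if not cands:
        return [], np.empty(0)
    hists = [
        encode_bovw(
            local_descriptors(c.sub_image, **codebook.detector_params), codebook
        )
        for c in cands
    ]
    scores = classifier.decision_scores(hists)
    kept = [c for c, s in zip(cands, scores) if s > 0]
    return kept, scores[scores > 0]
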