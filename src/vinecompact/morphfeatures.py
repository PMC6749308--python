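"""Cluster-mask refinement and the 14 morphological compactness features.

Refinement (six steps, applied to the grape/rachis layers of a detected
cluster crop):

1. combine the grape and rachis layers;
2. open the grape layer with a radius-2 disk;
3. open the rachis layer with a radius-2 disk;
4. mask A = largest 8-connected component of the opened grape+rachis union;
5. mask B = union of the convex hulls of each grape connected component
   (grouped berries on compact clusters, single berries on loose ones);
6. keep grape and rachis pixels that are in A and inside B, plus rachis
   pixels in A outside B that 8-connect at least two grape components
   (the stem segments bridging separate berry groups).

The 14 features computed from the refined mask quantify hole fraction,
grape/rachis composition, width profile along the major axis, roundness and
relative size; they are the inputs of the compactness regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes
from skimage.measure import label as cc_label
from skimage.measure import perimeter_crofton
from skimage.morphology import convex_hull_image
from skimage.transform import rotate as _rotate_image

from .detection import CandidateBox, morph_open

__all__ = [
    "CompactnessFeatures",
    "FEATURE_NAMES",
    "NoClusterContentError",
    "RefinedClusterMask",
    "band_width",
    "batch_r_aom",
    "compactness_features",
    "grape_perimeter",
    "refine_cluster_mask",
    "rotate_major_axis",
]

FEATURE_NAMES: tuple[str, ...] = (
    "AH", "AB", "AR", "W25", "W50", "W75", "RatioRG", "RDGrape", "CSFGrape",
    "AS", "RatioW75_W25", "RR_in", "RR_out", "R_AoM",
)


class NoClusterContentError(RuntimeError):
    """The grape layer is empty after opening; the candidate is skipped."""


@dataclass
class RefinedClusterMask:
    """Final grape+rachis mask of one cluster after the 6-step refinement."""

    grape: np.ndarray
    rachis: np.ndarray
    convex_hull: np.ndarray
    provenance: CandidateBox | None = None

    @property
    def foreground(self) -> np.ndarray:
        return self.grape | self.rachis


def refine_cluster_mask(
    grape: np.ndarray,
    rachis: np.ndarray,
    provenance: CandidateBox | None = None,
    opening_radius: int = 2,
) -> RefinedClusterMask:
    """Apply the 6-step refinement to a cluster crop's grape/rachis layers.

    Raises
    ------
    NoClusterContentError
        If no grape pixels survive the opening.
    """
    grape = np.asarray(grape, bool)
    rachis = np.asarray(rachis, bool)
    if grape.shape != rachis.shape:
        raise ValueError("grape and rachis crops must have the same shape")
    g = morph_open(grape, opening_radius)
    r = morph_open(rachis, opening_radius) & ~g
    if not g.any():
        raise NoClusterContentError("no grape pixels survive the opening")

    union = g | r
    comp = cc_label(union, connectivity=2)
    largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
    mask_a = comp == largest

    grape_comp = cc_label(g, connectivity=2)
    mask_b = np.zeros_like(g)
    for lab in range(1, grape_comp.max() + 1):
        mask_b |= _component_hull(grape_comp == lab)

    final_grape = g & mask_a  # grape pixels lie inside their own hulls
    final_rachis = r & mask_a & mask_b
    # bridging rachis: outside the hull union but connecting >= 2 grape
    # components (8-connectivity)
    outside = r & mask_a & ~mask_b
    if outside.any():
        out_comp = cc_label(outside, connectivity=2)
        for lab in range(1, out_comp.max() + 1):
            piece = out_comp == lab
            touched = np.unique(grape_comp[binary_dilation(piece, _SQUARE3)])
            if (touched > 0).sum() >= 2:
                final_rachis |= piece

    fg = final_grape | final_rachis
    hull = convex_hull_image(fg) if fg.any() else np.zeros_like(fg)
    return RefinedClusterMask(
        grape=final_grape, rachis=final_rachis, convex_hull=hull,
        provenance=provenance,
    )


_SQUARE3 = np.ones((3, 3), bool)


def _component_hull(mask):
    # convex_hull_image on a single component; guard 1-px components
    if mask.sum() < 3:
        return mask.copy()
    return convex_hull_image(mask)


def rotate_major_axis(mask: np.ndarray) -> np.ndarray:
    """Rotate a binary mask so its principal axis is vertical.

    The axis is the leading eigenvector of the second central moments of
    the foreground coordinates.  Resampling is nearest-neighbour with a 0.5
    re-binarisation threshold.  Orientation is made deterministic by
    flipping, if needed, so the foreground centroid falls in the lower half
    of the bounding box (clusters hang shoulder-down).

    Raises
    ------
    ValueError
        For fewer than 3 foreground pixels or a collinear foreground.
    """
    mask = np.asarray(mask, bool)
    rows, cols = np.nonzero(mask)
    if rows.size < 3:
        raise ValueError("need at least 3 foreground pixels")
    coords = np.column_stack([rows, cols]).astype(float)
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12:  # collinear foreground
        raise ValueError("foreground is collinear; principal axis undefined")
    major = evecs[:, np.argmax(evals)]  # (d_row, d_col) of the long axis
    angle = np.degrees(np.arctan2(major[1], major[0]))  # from the row axis
    rotated = _rotate_image(
        mask.astype(float), -angle, resize=True, order=0, preserve_range=True
    ) > 0.5
    rr = np.nonzero(rotated)[0]
    if rr.size == 0:  # pragma: no cover - rotation preserves pixels
        return rotated
    mid = (rr.min() + rr.max()) / 2.0
    if rr.mean() < mid:
        rotated = rotated[::-1].copy()
    return rotated


def band_width(rotated_mask: np.ndarray, fraction: float, tol: float = 0.05):
    """Mean row width in the band at ``fraction`` of the cluster length.

    Rows whose normalised position along the length (0 at the top row of
    the foreground) lies within ``fraction +/- tol`` contribute their width
    ``max_col - min_col + 1``; the mean over contributing rows is returned.

    Raises
    ------
    ValueError
        If no foreground rows fall in the band.
    """
    mask = np.asarray(rotated_mask, bool)
    rows = np.nonzero(mask.any(axis=1))[0]
    if rows.size == 0:
        raise ValueError("mask is empty")
    top, bottom = rows.min(), rows.max()
    length = bottom - top + 1
    if length == 1:
        pos = np.zeros(1)
    widths = []
    for row in rows:
        pos = (row - top) / max(length - 1, 1)
        if fraction - tol <= pos <= fraction + tol:
            cols = np.nonzero(mask[row])[0]
            widths.append(cols.max() - cols.min() + 1)
    if not widths:
        raise ValueError(f"no foreground rows in band {fraction}+/-{tol}")
    return float(np.mean(widths))


def grape_perimeter(grape: np.ndarray) -> float:
    """Boundary length of the grape mask (holes included).

    Uses the 4-direction Crofton estimator, which recovers the true
    perimeter of a digitised disk within about 1% at radii of tens of
    pixels; a naive pixel-edge count would overestimate a circle's
    perimeter by a factor of 4/pi and distort every roundness value.
    """
    grape = np.asarray(grape, bool)
    if not grape.any():
        return 0.0
    return float(perimeter_crofton(grape, directions=4))


@dataclass
class CompactnessFeatures:
    """The 14 compactness features plus raw measurements for inspection."""

    AH: float
    AB: float
    AR: float
    W25: float
    W50: float
    W75: float
    RatioRG: float
    RDGrape: float
    CSFGrape: float
    AS: float
    RatioW75_W25: float
    RR_in: float
    RR_out: float
    R_AoM: float
    # raw measurements (not part of the 14-vector)
    raw_widths: dict = field(default_factory=dict)
    areas: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def compactness_features(
    refined: RefinedClusterMask, mean_cluster_area: float
) -> CompactnessFeatures:
    """Compute the 14-feature vector from a refined cluster mask.

    Widths (W25/W50/W75 and the maximum width in AS) are measured on the
    rotated mask and divided by the cluster length, so the width block is
    camera-distance free; the raw pixel widths are kept in ``raw_widths``.
    ``mean_cluster_area`` is the average refined-cluster area of the set,
    the denominator of the relative-size feature R_AoM.

    With no rachis pixels: AR = RatioRG = RR_in = RR_out = 0 by convention.
    """
    if mean_cluster_area <= 0:
        raise ValueError("mean_cluster_area must be positive")
    grape = refined.grape
    rachis = refined.rachis
    a_grape = int(grape.sum())
    a_rachis = int(rachis.sum())
    if a_grape == 0:
        raise ValueError("refined mask has zero grape area")
    fg = refined.foreground
    hull = refined.convex_hull if refined.convex_hull.any() else convex_hull_image(fg)
    a_hull = int(hull.sum())
    a_fg = a_grape + a_rachis

    ah = (a_hull - a_fg) / a_hull
    ab = a_grape / a_fg
    ar = a_rachis / a_fg
    ratio_rg = a_rachis / a_grape

    rotated = rotate_major_axis(fg)
    rows = np.nonzero(rotated.any(axis=1))[0]
    length = int(rows.max() - rows.min() + 1)
    raw = {}
    for name, f in (("W25", 0.25), ("W50", 0.50), ("W75", 0.75)):
        raw[name] = band_width(rotated, f)
    row_widths = [
        np.ptp(np.nonzero(rotated[row])[0]) + 1 for row in rows
    ]
    max_width = float(np.max(row_widths))
    w25, w50, w75 = (raw[n] / length for n in ("W25", "W50", "W75"))

    perim = grape_perimeter(grape)
    rd = 4.0 * np.pi * a_grape / perim**2
    csf = perim**2 / a_grape
    aspect = max_width / length
    ratio_w = raw["W75"] / raw["W25"] if raw["W25"] > 0 else np.inf

    if a_rachis > 0:
        filled = binary_fill_holes(grape)
        holes = filled & ~grape
        rr_in = int((rachis & holes).sum()) / a_rachis
        rr_out = 1.0 - rr_in
    else:
        rr_in = rr_out = 0.0

    return CompactnessFeatures(
        AH=float(ah), AB=float(ab), AR=float(ar),
        W25=float(w25), W50=float(w50), W75=float(w75),
        RatioRG=float(ratio_rg), RDGrape=float(rd), CSFGrape=float(csf),
        AS=float(aspect), RatioW75_W25=float(ratio_w),
        RR_in=float(rr_in), RR_out=float(rr_out),
        R_AoM=float(a_fg / mean_cluster_area),
        raw_widths={**raw, "max_width": max_width, "length": float(length)},
        areas={"grape": a_grape, "rachis": a_rachis, "hull": a_hull},
    )


def batch_r_aom(cluster_areas) -> np.ndarray:
    """Each area divided by the arithmetic mean of the list; the relative
    cluster sizes of one image set.  Their mean is 1 by construction."""
    areas = np.asarray(cluster_areas, dtype=float)
    if areas.size == 0:
        raise ValueError("need at least one cluster area")
    return areas / areas.mean()
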