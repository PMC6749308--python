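"""Synthetic canopy scenes with known cluster packing density.

No public image set exists for the field conditions this package targets,
so this module generates seeded stand-ins: night-time canopy scenes where
every pixel belongs to one of the seven canopy classes (grape, rachis, trunk,
shoot, leaf, gap, trellis), clusters are unions of berry disks grown on a
rachis skeleton with a controllable packing density, and the exact class map
is returned alongside the rendered image.

Design of the colour model
--------------------------
Each class renders as an isotropic Gaussian colour blob in RGB.  The class
means are pairwise separated by at least 60 grey levels in at least one
channel, so pixelwise colour classes are separable by construction and a
colour-only segmenter can be tested for *recovery* rather than for robustness
to colour overlap (which synthetic scenes cannot speak to).

Packing density
---------------
``packing_density`` of a cluster is measured, not prescribed: the fraction of
the convex hull of the berry-disk union that the union covers.  Loose
clusters are sparse chains of berries on the rachis skeleton enclosing large
holes; compact clusters are densified until the measured fraction reaches the
target.  The OIV-scale proxy is the fixed bijection
``compactness_proxy = 1 + 8 * packing_density``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import convex_hull_image, disk as disk_footprint
from scipy.ndimage import binary_dilation

__all__ = [
    "CLASS_NAMES",
    "CLASS_COLOR_MEANS",
    "ClusterRecord",
    "FeatureTargetSet",
    "SceneGenerationError",
    "SyntheticScene",
    "compactness_proxy_from_density",
    "generate_cluster_crop",
    "generate_feature_target_set",
    "generate_noncluster_crop",
    "generate_scene",
    "sample_labeled_pixels",
    "write_scene",
]

#: Fixed class order used everywhere (truth maps, palettes, model outputs).
CLASS_NAMES: tuple[str, ...] = (
    "grape",
    "rachis",
    "trunk",
    "shoot",
    "leaf",
    "gap",
    "trellis",
)

#: Mean RGB colour per class; pairwise >= 60 grey levels apart in >= 1 channel.
CLASS_COLOR_MEANS: dict[str, tuple[int, int, int]] = {
    "grape": (60, 10, 70),
    "rachis": (180, 160, 80),
    "trunk": (120, 70, 30),
    "shoot": (100, 200, 100),
    "leaf": (20, 110, 30),
    "gap": (5, 5, 5),
    "trellis": (200, 200, 200),
}

#: Per-channel colour standard deviation (grey levels).
DEFAULT_COLOR_SIGMA = 8.0

#: Background mixture over non-cluster pixels, in class order
#: (trunk, shoot, leaf, gap, trellis).
DEFAULT_BACKGROUND_MIXTURE: dict[str, float] = {
    "trunk": 0.10,
    "shoot": 0.12,
    "leaf": 0.45,
    "gap": 0.26,
    "trellis": 0.07,
}

DEFAULT_BERRY_RADIUS = 5
_RACHIS_HALF_WIDTH = 3  # rachis stroke radius -> 7 px wide, survives r=2 opening
_CHAIN_SPACING = 1.4  # berry-centre spacing along chains, in radii; keeps the
# necks between consecutive berries thick enough to survive a radius-3 opening


class SceneGenerationError(RuntimeError):
    """Raised when a scene cannot be generated as requested."""


def compactness_proxy_from_density(packing_density) -> np.ndarray | float:
    """Fixed bijection from packing density in [0, 1] to the OIV span [1, 9]."""
    return 1.0 + 8.0 * np.asarray(packing_density, dtype=float)


@dataclass(frozen=True)
class ClusterRecord:
    """Ground truth for one planted cluster."""

    box: tuple[int, int, int, int]  # row_min, col_min, row_max, col_max inclusive
    packing_density: float
    n_berries: int
    rachis_fraction: float
    compactness_proxy: float


@dataclass
class SyntheticScene:
    """A rendered canopy image with its exact per-pixel class map."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: np.ndarray  # (H, W) uint8, values index CLASS_NAMES
    clusters: list[ClusterRecord]
    seed: int
    class_names: tuple[str, ...] = CLASS_NAMES

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape


@dataclass(frozen=True)
class FeatureTargetSet:
    """Synthetic 14-feature vectors with ratings driven by a 1-d latent."""

    features: np.ndarray  # (n, 14)
    targets: np.ndarray  # (n,) in [1, 9]
    clean_targets: np.ndarray  # noise-free targets before clipping
    latent: np.ndarray  # (n,) the underlying compactness latent in [0, 1]


# ---------------------------------------------------------------------------
# cluster drawing


def _skeleton_segments(cy, cx, ry, rx, rng):
    """Rachis skeleton: vertical main stem, a stem stub above the berry
    region, two exposed shoulder arms near the top, and interior branches."""
    segments = []
    top = (cy - int(0.85 * ry), cx)
    bottom = (cy + int(0.75 * ry), cx)
    segments.append((top, bottom))
    # stem stub above the berry region (ends up outside the cluster hull)
    stub_top = (cy - ry - int(0.65 * ry), cx)
    segments.append((stub_top, top))
    # shoulder arms: exposed rachis where berries are sparse
    for side in (-1, 1):
        arm_end = (top[0] + int(0.25 * ry), cx + side * int(0.8 * rx))
        segments.append((top, arm_end))
    for _ in range(2):
        t = rng.uniform(0.25, 0.85)
        sy = int(top[0] + t * (bottom[0] - top[0]))
        side = 1 if rng.random() < 0.5 else -1
        length = rng.uniform(0.4, 0.9) * rx
        dy = int(rng.uniform(0.1, 0.5) * length)
        end = (sy + dy, cx + side * int(length))
        segments.append(((sy, cx), end))
    return segments


def _draw_segments(mask, segments):
    for (r0, c0), (r1, c1) in segments:
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        mask[rr[ok], cc[ok]] = True


def _chain_centres(segments, spacing, rng):
    """Berry centres strung along line segments at a fixed spacing."""
    centres = []
    for (r0, c0), (r1, c1) in segments:
        length = float(np.hypot(r1 - r0, c1 - c0))
        n = max(2, int(length / spacing) + 1)
        for t in np.linspace(0.0, 1.0, n):
            jitter = rng.uniform(-1.0, 1.0, size=2)
            centres.append((r0 + t * (r1 - r0) + jitter[0], c0 + t * (c1 - c0) + jitter[1]))
    return centres


def _ring_centres(cy, cx, ry, rx, spacing, arc_fraction, rng):
    """Berry centres along an elliptical arc (gap centred at the bottom),
    touching-chain spacing; the loosest connected layout the raster allows."""
    a, b = max(ry - 2, 4), max(rx - 2, 4)
    # approximate perimeter, then walk the arc at uniform angular steps
    perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    n = max(6, int(arc_fraction * perimeter / spacing))
    span = arc_fraction * 2 * np.pi
    # angle measured from the top (-pi/2), symmetric sweep leaving the gap at
    # the bottom of the ellipse
    angles = -np.pi / 2 + np.linspace(-span / 2, span / 2, n)
    centres = []
    for ang in angles:
        jitter = rng.uniform(-1.0, 1.0, size=2)
        centres.append(
            (cy + a * np.sin(ang) + jitter[0], cx + b * np.cos(ang) + jitter[1])
        )
    return centres


def _measure_density(berry_mask) -> float:
    area = int(berry_mask.sum())
    if area == 0:
        return 0.0
    hull = convex_hull_image(berry_mask)
    return area / int(hull.sum())


def _grow_cluster(shape, cy, cx, ry, rx, target_density, berry_radius, rng):
    """Grow a connected union of berry disks on a rachis skeleton until the
    measured hull-coverage reaches ``target_density``.

    Returns (berry_mask, rachis_mask, centres).
    """
    h, w = shape
    segments = _skeleton_segments(cy, cx, ry, rx, rng)
    rachis = np.zeros(shape, bool)
    _draw_segments(rachis, segments)
    rachis = binary_dilation(rachis, disk_footprint(_RACHIS_HALF_WIDTH))

    r = berry_radius
    # loose base layout: berries chained along an elliptical arc plus the main
    # stem; the arc maximises hull area per berry, which is what keeps the
    # achievable packing density low while the grape union stays connected
    arc_fraction = float(np.clip(target_density / 0.5, 0.75, 1.0))
    centres = _ring_centres(cy, cx, ry, rx, _CHAIN_SPACING * r, arc_fraction, rng)
    if target_density >= 0.45:
        centres += _chain_centres(segments[:1], _CHAIN_SPACING * r, rng)
    berries = np.zeros(shape, bool)
    for yc, xc in centres:
        rr, cc = draw_disk((yc, xc), r, shape=shape)
        berries[rr, cc] = True

    density = _measure_density(berries)
    pts = np.array(centres, dtype=float)
    attempts = 0
    max_attempts = 6000
    while density < target_density and attempts < max_attempts:
        added = 0
        while added < 8 and attempts < max_attempts:
            attempts += 1
            anchor = pts[rng.integers(len(pts))]
            ang = rng.uniform(0.0, 2 * np.pi)
            dist = rng.uniform(1.15 * r, 1.6 * r)
            cand = anchor + dist * np.array([np.sin(ang), np.cos(ang)])
            dy, dx = cand[0] - cy, cand[1] - cx
            if (dy / (ry + 2)) ** 2 + (dx / (rx + 2)) ** 2 > 1.0:
                continue
            if np.min(np.sum((pts - cand) ** 2, axis=1)) < (1.1 * r) ** 2:
                continue
            rr, cc = draw_disk((cand[0], cand[1]), r, shape=shape)
            berries[rr, cc] = True
            pts = np.vstack([pts, cand])
            added += 1
        density = _measure_density(berries)
    return berries, rachis, pts


def _background_truth(h, w, mixture, rng):
    """Quantile-sliced smooth random field: exact class fractions (within one
    pixel) with spatially coherent regions."""
    names = [n for n in CLASS_NAMES if n in mixture]
    fracs = np.array([mixture[n] for n in names], dtype=float)
    if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
        raise ValueError("background mixture must be non-negative and sum to 1")
    field_ = gaussian_filter(rng.normal(size=(h, w)), sigma=14.0)
    order = np.argsort(field_, axis=None, kind="stable")
    truth = np.empty(h * w, dtype=np.uint8)
    counts = np.floor(np.cumsum(fracs) * h * w + 0.5).astype(int)
    start = 0
    for name, stop in zip(names, counts):
        truth[order[start:stop]] = CLASS_NAMES.index(name)
        start = stop
    truth[order[start:]] = CLASS_NAMES.index(names[-1])
    return truth.reshape(h, w)


def _render(truth, sigma, rng):
    """Sample per-pixel colours from the class Gaussians."""
    h, w = truth.shape
    means = np.array([CLASS_COLOR_MEANS[n] for n in CLASS_NAMES], dtype=float)
    img = means[truth] + rng.normal(scale=sigma, size=(h, w, 3))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_scene(
    width: int,
    height: int,
    n_clusters: int,
    density_range: tuple[float, float] = (0.2, 0.95),
    seed: int = 0,
    *,
    berry_radius: int = DEFAULT_BERRY_RADIUS,
    color_sigma: float = DEFAULT_COLOR_SIGMA,
    background_mixture: dict[str, float] | None = None,
    cluster_ry: tuple[int, int] = (30, 40),
    cluster_rx: tuple[int, int] = (22, 30),
    n_distractors: int = 0,
) -> SyntheticScene:
    """Generate a synthetic canopy scene with ``n_clusters`` planted clusters.

    Cluster target densities are evenly spaced across ``density_range`` so a
    multi-cluster scene spans the requested compactness span; the recorded
    ``packing_density`` is the measured hull coverage actually achieved.
    Regeneration with identical arguments is bit-identical.

    Raises
    ------
    SceneGenerationError
        If the requested clusters cannot be placed without overlap.
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    lo, hi = density_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("density_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    mixture = background_mixture or DEFAULT_BACKGROUND_MIXTURE
    truth = _background_truth(height, width, mixture, rng)

    targets = np.linspace(lo, hi, n_clusters) if n_clusters else np.empty(0)
    placed_boxes: list[tuple[int, int, int, int]] = []
    clusters: list[ClusterRecord] = []
    for target in targets:
        # loose clusters are straggly: more hull area per berry, so the
        # ellipse grows as the target density drops
        scale = 1.0 + 0.55 * (1.0 - float(target))
        ry = int(round(scale * rng.integers(cluster_ry[0], cluster_ry[1] + 1)))
        rx = int(round(scale * rng.integers(cluster_rx[0], cluster_rx[1] + 1)))
        pad_top = ry + int(0.55 * ry) + berry_radius + 2
        pad = berry_radius + 2
        if (pad_top + 1 >= height - ry - pad - 1
                or rx + pad + 1 >= width - rx - pad - 1):
            raise SceneGenerationError(
                f"canvas {height}x{width} too small for a cluster of "
                f"semi-axes ({ry}, {rx})"
            )
        placed = False
        for _ in range(300):
            cy = int(rng.integers(pad_top + 1, height - ry - pad - 1))
            cx = int(rng.integers(rx + pad + 1, width - rx - pad - 1))
            box_guess = (cy - pad_top, cx - rx - pad, cy + ry + pad, cx + rx + pad)
            if any(_boxes_overlap(box_guess, b, margin=4) for b in placed_boxes):
                continue
            berries, rachis, pts = _grow_cluster(
                truth.shape, cy, cx, ry, rx, float(target), berry_radius, rng
            )
            density = _measure_density(berries)
            rachis &= ~berries
            fg = berries | rachis
            rows, cols = np.nonzero(fg)
            box = (int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
            if any(_boxes_overlap(box, b, margin=4) for b in placed_boxes):
                continue
            truth[berries] = CLASS_NAMES.index("grape")
            truth[rachis] = CLASS_NAMES.index("rachis")
            clusters.append(
                ClusterRecord(
                    box=box,
                    packing_density=float(density),
                    n_berries=int(len(pts)),
                    rachis_fraction=float(rachis.sum() / fg.sum()),
                    compactness_proxy=float(compactness_proxy_from_density(density)),
                )
            )
            placed_boxes.append(box)
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                f"could not place cluster {len(clusters) + 1} of {n_clusters} "
                f"on a {height}x{width} canvas without overlap"
            )
    # grape-coloured non-cluster objects: the false positives a colour-only
    # segmentation hands to the detector (berry-free blobs and stripes)
    grape_idx = CLASS_NAMES.index("grape")
    for _ in range(n_distractors):
        side = int(rng.integers(56, 80))
        for _ in range(300):
            r0 = int(rng.integers(1, height - side - 1))
            c0 = int(rng.integers(1, width - side - 1))
            box = (r0, c0, r0 + side - 1, c0 + side - 1)
            if any(_boxes_overlap(box, b, margin=4) for b in placed_boxes):
                continue
            patch = np.zeros((side, side), bool)
            if rng.random() < 0.5:
                field_ = gaussian_filter(rng.normal(size=(side, side)), sigma=10.0)
                patch = field_ > np.quantile(field_, 0.55)
            else:
                ang = rng.uniform(0.2, 1.3)
                yy, xx = np.mgrid[0:side, 0:side]
                patch = ((yy * np.sin(ang) + xx * np.cos(ang)) % 30) < 12
            truth[r0:r0 + side, c0:c0 + side][patch] = grape_idx
            placed_boxes.append(box)
            break
        else:
            raise SceneGenerationError(
                "could not place a grape-coloured distractor without overlap"
            )
    image = _render(truth, color_sigma, rng)
    return SyntheticScene(image=image, truth=truth, clusters=clusters, seed=seed)


def _boxes_overlap(a, b, margin=0) -> bool:
    return not (
        a[2] + margin < b[0]
        or b[2] + margin < a[0]
        or a[3] + margin < b[1]
        or b[3] + margin < a[1]
    )


def sample_labeled_pixels(
    scene: SyntheticScene, per_class: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``per_class`` labelled pixel coordinates per class, without
    replacement, emulating the manual labelling of training pixels.

    Returns ``(coords, labels)`` where ``coords`` is (n, 2) int rows of
    (row, col) and ``labels`` the class index per coordinate.

    Raises
    ------
    ValueError
        If a class is absent or has fewer than ``per_class`` pixels; the
        message names the class.
    """
    rng = np.random.default_rng(seed)
    coords_all = []
    labels_all = []
    for idx, name in enumerate(CLASS_NAMES):
        rows, cols = np.nonzero(scene.truth == idx)
        if rows.size < per_class:
            raise ValueError(
                f"class {name!r} has {rows.size} pixels, need {per_class}"
            )
        pick = rng.choice(rows.size, size=per_class, replace=False)
        coords_all.append(np.column_stack([rows[pick], cols[pick]]))
        labels_all.append(np.full(per_class, idx, dtype=np.uint8))
    return np.concatenate(coords_all), np.concatenate(labels_all)


# ---------------------------------------------------------------------------
# detector training crops


def _candidate_style_crop(truth, rng, sigma=DEFAULT_COLOR_SIGMA):
    """Render a mini-scene and crop it the way the detection stage crops
    candidates: bounding box of the largest 8-connected grape component
    after a radius-3 opening."""
    from skimage.measure import label as _cc_label, regionprops as _regionprops
    from skimage.morphology import opening as _opening

    image = _render(truth, sigma, rng)
    mask = _opening(truth == CLASS_NAMES.index("grape"), disk_footprint(3))
    labelled = _cc_label(mask, connectivity=2)
    regions = _regionprops(labelled)
    if not regions:
        return image
    region = max(regions, key=lambda reg: reg.area)
    r0, c0, r1, c1 = region.bbox
    return image[r0:r1, c0:c1]


def generate_cluster_crop(
    density: float, seed: int = 0, size: tuple[int, int] = (130, 110)
) -> np.ndarray:
    """A candidate-style berry-textured crop: one cluster on leaf/gap
    background, cropped to the opened grape component's bounding box."""
    rng = np.random.default_rng(seed)
    h, w = size
    truth = _background_truth(h, w, {"leaf": 0.6, "gap": 0.4}, rng)
    cy, cx = h // 2 + 4, w // 2
    ry = min(int(0.32 * h), 40)
    rx = min(int(0.36 * w), 30)
    berries, rachis, _ = _grow_cluster(
        truth.shape, cy, cx, ry, rx, density, DEFAULT_BERRY_RADIUS, rng
    )
    rachis &= ~berries
    truth[berries] = CLASS_NAMES.index("grape")
    truth[rachis] = CLASS_NAMES.index("rachis")
    return _candidate_style_crop(truth, rng)


def generate_noncluster_crop(
    seed: int = 0, size: tuple[int, int] = (130, 110), kind: str | None = None
) -> np.ndarray:
    """A candidate-style grape-coloured but berry-free crop: the false
    positives a colour-only segmentation hands to the detector (smooth
    blobs, stripes, hollow rings), cropped like a real candidate."""
    rng = np.random.default_rng(seed)
    kinds = ("blob", "stripe", "ring")
    kind = kind or kinds[int(rng.integers(len(kinds)))]
    if kind not in kinds:
        raise ValueError(f"kind must be one of {kinds}")
    h, w = size
    truth = _background_truth(h, w, {"leaf": 0.6, "gap": 0.4}, rng)
    mask = np.zeros((h, w), bool)
    grape = CLASS_NAMES.index("grape")
    if kind == "blob":
        field_ = gaussian_filter(rng.normal(size=(h, w)), sigma=12.0)
        mask = field_ > np.quantile(field_, 0.7)
    elif kind == "stripe":
        ang = rng.uniform(0.3, 1.2)
        yy, xx = np.mgrid[0:h, 0:w]
        phase = yy * np.sin(ang) + xx * np.cos(ang)
        mask = (phase % 34) < 13
    else:  # hollow ring, e.g. a looped cane of grape-like colour
        yy, xx = np.mgrid[0:h, 0:w]
        r_out = rng.uniform(0.30, 0.42) * min(h, w)
        rad = np.hypot(yy - h / 2, xx - w / 2)
        mask = (rad < r_out) & (rad > r_out - rng.uniform(8, 14))
    truth[mask] = grape
    return _candidate_style_crop(truth, rng)


# ---------------------------------------------------------------------------
# feature/target sets for the rating regressor

_N_FEATURES = 14


def _latent_embedding_coefficients():
    # fixed, seed-independent embedding of the latent into 14 dimensions
    rng = np.random.default_rng(20190902)
    amp = rng.uniform(0.3, 1.2, size=_N_FEATURES)
    freq = rng.uniform(0.8, 2.6, size=_N_FEATURES)
    phase = rng.uniform(0.0, 2 * np.pi, size=_N_FEATURES)
    slope = rng.uniform(-1.0, 1.0, size=_N_FEATURES)
    # first coordinate strictly monotone in the latent so features determine it
    amp[0], freq[0], phase[0], slope[0] = 0.0, 1.0, 0.0, 1.0
    return amp, freq, phase, slope


def generate_feature_target_set(
    n: int, noise_sd: float = 0.3, seed: int = 0
) -> FeatureTargetSet:
    """Synthetic 14-feature vectors whose targets follow a smooth monotone
    function of a scalar latent plus Gaussian rating noise, clipped to [1, 9].

    With ``noise_sd=0`` the targets are an exact deterministic function of
    the features (the first feature equals the latent).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n)
    amp, freq, phase, slope = _latent_embedding_coefficients()
    features = slope * t[:, None] + amp * np.sin(freq * t[:, None] + phase)
    clean = 1.0 + 8.0 * t
    noise = rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    targets = np.clip(clean + noise, 1.0, 9.0)
    return FeatureTargetSet(
        features=features, targets=targets, clean_targets=clean, latent=t
    )


# ---------------------------------------------------------------------------
# on-disk format


def read_scene(scene_dir) -> SyntheticScene:
    """Read a scene written by :func:`write_scene`."""
    d = Path(scene_dir)
    image = np.asarray(Image.open(d / "image.png").convert("RGB"))
    truth = np.asarray(Image.open(d / "truth.png")).astype(np.uint8)
    clusters = []
    with open(d / "clusters.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            clusters.append(
                ClusterRecord(
                    box=(int(row["row_min"]), int(row["col_min"]),
                         int(row["row_max"]), int(row["col_max"])),
                    packing_density=float(row["packing_density"]),
                    n_berries=int(row["n_berries"]),
                    rachis_fraction=float(row["rachis_fraction"]),
                    compactness_proxy=float(row["compactness_proxy"]),
                )
            )
    return SyntheticScene(image=image, truth=truth, clusters=clusters, seed=-1)


def write_scene(scene: SyntheticScene, out_dir) -> None:
    """Write image.png (RGB), truth.png (indexed, palette in class order) and
    clusters.csv (one row per ClusterRecord) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(scene.image, mode="RGB").save(out / "image.png")
    pal_img = Image.fromarray(scene.truth, mode="P")
    palette = []
    for name in CLASS_NAMES:
        palette.extend(CLASS_COLOR_MEANS[name])
    pal_img.putpalette(palette)
    pal_img.save(out / "truth.png")
    with open(out / "clusters.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "row_min",
                "col_min",
                "row_max",
                "col_max",
                "packing_density",
                "n_berries",
                "rachis_fraction",
                "compactness_proxy",
            ]
        )
        for c in scene.clusters:
            writer.writerow(
                [*c.box, f"{c.packing_density:.6f}", c.n_berries,
                 f"{c.rachis_fraction:.6f}", f"{c.compactness_proxy:.6f}"]
            )
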