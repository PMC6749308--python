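"""End-to-end orchestration: segment -> detect -> refine -> features -> rate.

This module wires the stage modules together the way the field workflow
runs them: a per-image-set segmentation model, a detector trained on
candidates automatically extracted from training scenes and labelled
against the known cluster boxes, per-cluster feature extraction with the
set-level mean area for the relative-size feature, and the GP rating model.

Model archives are plain JSON (arrays inlined) so that retraining with
identical inputs and seeds reproduces byte-identical files; wall-clock
information goes to the log, never into an output file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import colorseg, compactness, detection, morphfeatures
from .fixtures import CLASS_NAMES, SyntheticScene

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "box_iou",
    "compute_cluster_features",
    "augment_detector_crops",
    "extract_detection_training_set",
    "load_model",
    "run_pipeline",
    "save_model",
    "train_all",
    "train_detector",
    "train_segmentation",
]

logger = logging.getLogger("vinecompact")

ARCHIVE_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the method's tuned defaults."""

    class_order: tuple[str, ...] = CLASS_NAMES
    candidate_opening_radius: int = 3
    refine_opening_radius: int = 2
    min_candidate_area: int = detection.DEFAULT_MIN_AREA
    codebook_k: int = 100
    svm_box_constraint: float = detection.DEFAULT_BOX_CONSTRAINT
    svm_kernel_scale: float = detection.DEFAULT_KERNEL_SCALE
    gpr_sigma: float = compactness.DEFAULT_GPR_SIGMA
    gpr_kernel_scale: float = compactness.DEFAULT_GPR_KERNEL_SCALE
    #: margin (px) added around a candidate box when cropping the
    #: segmentation layers for refinement, so stem rachis just outside the
    #: grape bounding box is retained
    crop_margin: int = 12
    #: box-IoU threshold against a true cluster box above which an extracted
    #: candidate is labelled "cluster" during detector training
    detector_label_iou: float = 0.3
    labeled_pixels_per_class: int = 500
    #: detector training-set size per class; scene-extracted candidates are
    #: topped up with generated candidate-style crops to this count (the
    #: reference workflow trains on 300 "cluster" + 300 "non-cluster"
    #: sub-images)
    detector_crops_per_class: int = 300
    cv_scheme: str = "stratified-k-fold"
    cv_folds: int = 10
    seeds: dict = field(
        default_factory=lambda: {
            "labeling": 0, "codebook": 0, "cv": 0, "detector_crops": 0
        }
    )

    def __post_init__(self) -> None:
        if self.candidate_opening_radius < 1 or self.refine_opening_radius < 1:
            raise ValueError("opening radii must be >= 1")
        if self.codebook_k < 1:
            raise ValueError("codebook_k must be >= 1")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["class_order"] = list(self.class_order)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["class_order"] = tuple(data["class_order"])
        return cls(**data)


@dataclass
class RunManifest:
    """Deterministic record of a pipeline run: config snapshot, software
    version, per-stage record counts, seeds and every output file."""

    config: dict
    version: str
    stage_counts: dict
    seeds: dict
    outputs: list

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), sort_keys=True, indent=1, default=str)
        )


# ---------------------------------------------------------------------------
# model archives


def _encode_arrays(arrays: dict) -> dict:
    return {
        name: {"shape": list(np.asarray(a).shape), "data": np.asarray(a).ravel().tolist()}
        for name, a in arrays.items()
    }


def _decode_arrays(blob: dict) -> dict:
    return {
        name: np.asarray(spec["data"], dtype=float).reshape(spec["shape"])
        for name, spec in blob.items()
    }


def save_model(path, kind: str, metadata: dict, arrays: dict) -> None:
    """Write a model archive: JSON with schema version, kind, scalar
    metadata and named float arrays."""
    doc = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "kind": kind,
        "metadata": metadata,
        "arrays": _encode_arrays(arrays),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path):
    """Load a model archive and rebuild the in-memory model object."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != ARCHIVE_SCHEMA_VERSION:
        raise ValueError(f"unsupported archive schema in {path}")
    kind = doc["kind"]
    meta = doc["metadata"]
    arrays = _decode_arrays(doc["arrays"])
    if kind == "segmentation-mlr":
        return colorseg.MLRModel(
            class_names=tuple(meta["class_names"]),
            reference_class=meta["reference_class"],
            coefficients=arrays["coefficients"],
            feature_mean=arrays["feature_mean"],
            feature_scale=arrays["feature_scale"],
        )
    if kind == "detector":
        codebook = detection.Codebook(
            centroids=arrays["centroids"],
            training_seed=int(meta["codebook_seed"]),
            detector_params=meta["detector_params"],
        )
        classifier = detection.ClusterClassifier(
            box_constraint=meta["box_constraint"],
            kernel_scale=meta["kernel_scale"],
            support_vectors=arrays["support_vectors"],
            dual_coef=arrays["dual_coef"],
            intercept=meta["intercept"],
            k=int(meta["k"]),
            normalize=bool(meta["normalize"]),
        )
        return codebook, classifier
    if kind == "compactness-gpr":
        return compactness.train_gpr(
            arrays["train_features_raw"],
            arrays["train_targets"],
            sigma=meta["sigma"],
            kernel_scale=meta["kernel_scale"],
            signal_variance=meta["signal_variance"],
            basis=meta["basis"],
        )
    raise ValueError(f"unknown model kind {kind!r}")


def save_segmentation_model(path, model: colorseg.MLRModel) -> None:
    save_model(
        path,
        "segmentation-mlr",
        {
            "class_names": list(model.class_names),
            "reference_class": model.reference_class,
        },
        {
            "coefficients": model.coefficients,
            "feature_mean": model.feature_mean,
            "feature_scale": model.feature_scale,
        },
    )


def save_detector_model(path, codebook, classifier) -> None:
    save_model(
        path,
        "detector",
        {
            "codebook_seed": codebook.training_seed,
            "detector_params": codebook.detector_params,
            "box_constraint": classifier.box_constraint,
            "kernel_scale": classifier.kernel_scale,
            "intercept": classifier.intercept,
            "k": classifier.k,
            "normalize": classifier.normalize,
        },
        {
            "centroids": codebook.centroids,
            "support_vectors": classifier.support_vectors,
            "dual_coef": classifier.dual_coef,
        },
    )


def save_gpr_model(path, model: compactness.GPRModel, raw_features, targets) -> None:
    save_model(
        path,
        "compactness-gpr",
        {
            "sigma": model.sigma,
            "kernel_scale": model.kernel_scale,
            "signal_variance": model.signal_variance,
            "basis": model.basis,
        },
        {
            "train_features_raw": np.asarray(raw_features, float),
            "train_targets": np.asarray(targets, float),
        },
    )


# ---------------------------------------------------------------------------
# training stages


def train_segmentation(features, labels, config: PipelineConfig) -> colorseg.MLRModel:
    """Fit the per-set segmentation model from labelled pixel features."""
    return colorseg.train_mlr(features, labels, class_names=config.class_order)


def box_iou(a, b) -> float:
    """Intersection-over-union of two inclusive (r0, c0, r1, c1) boxes."""
    r0, c0 = max(a[0], b[0]), max(a[1], b[1])
    r1, c1 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0, r1 - r0 + 1) * max(0, c1 - c0 + 1)
    area_a = (a[2] - a[0] + 1) * (a[3] - a[1] + 1)
    area_b = (b[2] - b[0] + 1) * (b[3] - b[1] + 1)
    return inter / (area_a + area_b - inter)


def extract_detection_training_set(
    scenes, seg_model: colorseg.MLRModel, config: PipelineConfig
):
    """Extract candidate sub-images from training scenes and label them
    "cluster"/"non-cluster" against the scenes' true cluster boxes.

    Mirrors the field workflow, where training sub-images were extracted
    automatically from the segmentation of the training set and labelled by
    hand; here the known cluster boxes stand in for the manual labels
    (IoU >= ``detector_label_iou`` with any true box, or containment of the
    candidate inside a true box, counts as "cluster").
    """
    crops, labels = [], []
    for scene in scenes:
        seg = colorseg.segment(seg_model, scene.image)
        mask = detection.morph_open(
            detection.grape_mask(seg), config.candidate_opening_radius
        )
        for cand in detection.candidate_boxes(
            mask, image=scene.image, min_area=config.min_candidate_area
        ):
            best = max(
                (box_iou(cand.box, rec.box) for rec in scene.clusters),
                default=0.0,
            )
            crops.append(cand.sub_image)
            labels.append("cluster" if best >= config.detector_label_iou else "non-cluster")
    return crops, labels


def augment_detector_crops(crops, labels, config: PipelineConfig):
    """Top up the detector training set with generated candidate-style
    crops until each class reaches ``detector_crops_per_class``."""
    from . import fixtures

    base_seed = int(config.seeds.get("detector_crops", 0))
    target = config.detector_crops_per_class
    crops, labels = list(crops), list(labels)
    n_cluster = sum(1 for l in labels if l == "cluster")
    n_non = len(labels) - n_cluster
    need_c = max(0, target - n_cluster)
    need_n = max(0, target - n_non)
    rng = np.random.default_rng(base_seed)
    densities = np.linspace(0.25, 0.95, max(need_c, 1))
    for i in range(need_c):
        size = (int(rng.integers(100, 170)), int(rng.integers(85, 140)))
        crops.append(
            fixtures.generate_cluster_crop(
                float(densities[i]), seed=base_seed + i, size=size
            )
        )
        labels.append("cluster")
    for i in range(need_n):
        size = (int(rng.integers(100, 170)), int(rng.integers(85, 140)))
        crops.append(
            fixtures.generate_noncluster_crop(
                seed=base_seed + 100_000 + i, size=size
            )
        )
        labels.append("non-cluster")
    return crops, labels


def train_detector(crops, labels, config: PipelineConfig):
    """Build the codebook and the cluster/non-cluster SVM from labelled
    training crops.  Returns ``(codebook, classifier)``.

    Raises
    ------
    ValueError
        If only one label class is present or there are fewer descriptors
        than codewords.
    """
    descriptor_sets = [detection.local_descriptors(c) for c in crops]
    codebook = detection.build_codebook(
        descriptor_sets, k=config.codebook_k, seed=config.seeds.get("codebook", 0)
    )
    histograms = [detection.encode_bovw(d, codebook) for d in descriptor_sets]
    classifier = detection.train_cluster_classifier(
        histograms,
        labels,
        box_constraint=config.svm_box_constraint,
        kernel_scale=config.svm_kernel_scale,
    )
    return codebook, classifier


#: Codebook sizes of the original detection sweep.
CODEBOOK_K_GRID = (10, 50, 100, 150, 200)


def sweep_codebook_size(crops, labels, config: PipelineConfig,
                        k_grid=CODEBOOK_K_GRID) -> int:
    """Pick the codebook size with the best held-out detection AUC.

    A seeded quarter of the crops is held out; for each k in the grid a
    codebook and SVM are fitted on the rest and scored on the held-out
    crops.  Ties break to the smaller k.
    """
    from .metrics import auc

    rng = np.random.default_rng(config.seeds.get("cv", 0))
    n = len(crops)
    order = rng.permutation(n)
    n_test = max(2, n // 4)
    test_idx = set(order[:n_test].tolist())
    y = np.array([1 if l == "cluster" else 0 for l in labels])
    if y[list(test_idx)].min() == y[list(test_idx)].max():
        raise ValueError("held-out crops contain a single class")
    descriptors = [detection.local_descriptors(c) for c in crops]
    train_idx = [i for i in range(n) if i not in test_idx]
    best_k, best_auc = None, -np.inf
    for k in k_grid:
        codebook = detection.build_codebook(
            [descriptors[i] for i in train_idx], k=k,
            seed=config.seeds.get("codebook", 0),
        )
        hists = [detection.encode_bovw(descriptors[i], codebook)
                 for i in train_idx]
        classifier = detection.train_cluster_classifier(
            hists, [labels[i] for i in train_idx],
            box_constraint=config.svm_box_constraint,
            kernel_scale=config.svm_kernel_scale,
        )
        test_hists = [detection.encode_bovw(descriptors[i], codebook)
                      for i in sorted(test_idx)]
        score = auc(classifier.decision_scores(test_hists),
                    y[sorted(test_idx)])
        logger.info("codebook sweep: k=%d AUC=%.4f", k, score)
        if score > best_auc:
            best_k, best_auc = k, score
    return int(best_k)


def train_compactness(
    features,
    ratings,
    config: PipelineConfig,
    *,
    optimize_budget: int = 0,
    cv_folds: int = 5,
    seed: int = 0,
) -> compactness.GPRModel:
    """Fit the GP rating model; with ``optimize_budget`` > 0 the sigma and
    kernel-scale hyperparameters are tuned by Bayesian optimisation of the
    cross-validated RMSE inside the method's search ranges, otherwise the
    tuned values from the config are used verbatim."""
    features = np.asarray(features, float)
    ratings = np.asarray(ratings, float)
    sigma, kernel_scale = config.gpr_sigma, config.gpr_kernel_scale
    if optimize_budget > 0:
        from .metrics import CVPlan, make_cv_folds

        folds = make_cv_folds(
            CVPlan(scheme="stratified-k-fold", k=cv_folds, seed=seed),
            features.shape[0],
        )

        def objective(params):
            errors = []
            for train_idx, test_idx in folds:
                model = compactness.train_gpr(
                    features[train_idx], ratings[train_idx],
                    sigma=params["sigma"], kernel_scale=params["kernel_scale"],
                )
                _, _, raw = compactness.predict_compactness(model, features[test_idx])
                errors.append(np.mean((raw - ratings[test_idx]) ** 2))
            return float(np.sqrt(np.mean(errors)))

        space = compactness.HyperparameterSearchSpace(
            bounds=compactness.GPR_SEARCH_SPACE.bounds,
            log_scale=compactness.GPR_SEARCH_SPACE.log_scale,
            budget=optimize_budget,
            seed=seed,
        )
        best, _ = compactness.optimize_hyperparameters(space, objective)
        sigma, kernel_scale = best["sigma"], best["kernel_scale"]
    return compactness.train_gpr(features, ratings, sigma=sigma, kernel_scale=kernel_scale)


# ---------------------------------------------------------------------------
# inference stages

_FEATURE_COLUMNS = list(morphfeatures.FEATURE_NAMES)
_RAW_COLUMNS = ["raw_W25", "raw_W50", "raw_W75", "raw_max_width", "raw_length",
                "area_grape", "area_rachis", "area_hull"]
_BOX_COLUMNS = ["row_min", "col_min", "row_max", "col_max"]


def compute_cluster_features(
    image,
    segmap: colorseg.SegmentationMap,
    boxes,
    config: PipelineConfig,
    image_name: str = "",
    mean_cluster_area: float | None = None,
) -> pd.DataFrame:
    """Refine each detected cluster and compute its 14-feature row.

    The relative-size feature divides each cluster's area by
    ``mean_cluster_area`` when given (a training-set mean), otherwise by the
    mean refined area of the current batch.  Candidates whose grape layer
    vanishes under the opening are skipped with a log entry.
    """
    grape_idx = config.class_order.index("grape")
    rachis_idx = config.class_order.index("rachis")
    h, w = segmap.labels.shape
    refined_list, kept_boxes = [], []
    for box in boxes:
        r0, c0, r1, c1 = box
        m = config.crop_margin
        rr0, cc0 = max(0, r0 - m), max(0, c0 - m)
        rr1, cc1 = min(h - 1, r1 + m), min(w - 1, c1 + m)
        crop = segmap.labels[rr0:rr1 + 1, cc0:cc1 + 1]
        try:
            refined = morphfeatures.refine_cluster_mask(
                crop == grape_idx,
                crop == rachis_idx,
                opening_radius=config.refine_opening_radius,
            )
        except morphfeatures.NoClusterContentError as exc:
            logger.warning("skipping candidate %s of %s: %s", box, image_name, exc)
            continue
        refined_list.append(refined)
        kept_boxes.append(box)
    if not refined_list:
        return pd.DataFrame(
            columns=["image", *_BOX_COLUMNS, *_FEATURE_COLUMNS, *_RAW_COLUMNS]
        )
    areas = [int(r.foreground.sum()) for r in refined_list]
    denom = float(mean_cluster_area) if mean_cluster_area else float(np.mean(areas))
    rows = []
    for refined, box in zip(refined_list, kept_boxes):
        feats = morphfeatures.compactness_features(refined, mean_cluster_area=denom)
        row = {"image": image_name}
        row.update(dict(zip(_BOX_COLUMNS, box)))
        for name in _FEATURE_COLUMNS:
            row[name] = getattr(feats, name)
        row.update(
            {
                "raw_W25": feats.raw_widths["W25"],
                "raw_W50": feats.raw_widths["W50"],
                "raw_W75": feats.raw_widths["W75"],
                "raw_max_width": feats.raw_widths["max_width"],
                "raw_length": feats.raw_widths["length"],
                "area_grape": feats.areas["grape"],
                "area_rachis": feats.areas["rachis"],
                "area_hull": feats.areas["hull"],
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    images,
    seg_model: colorseg.MLRModel,
    codebook: detection.Codebook,
    classifier: detection.ClusterClassifier,
    gpr_model: compactness.GPRModel,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run segment -> detect -> features -> rate over named images.

    Parameters
    ----------
    images : iterable of (name, (H, W, 3) uint8 array)

    Returns
    -------
    (predictions, stage_counts)
        ``predictions`` has one row per rated cluster with the box, the 14
        features, the clamped rating, the raw rating and its SD.  An image
        with no detections contributes no rows (a warning is logged).
    """
    all_rows = []
    counts = {"images": 0, "candidates": 0, "detections": 0, "rated": 0}
    for name, image in images:
        counts["images"] += 1
        seg = colorseg.segment(seg_model, image)
        kept, scores = detection.detect_clusters(
            image, seg, codebook, classifier,
            opening_radius=config.candidate_opening_radius,
            min_area=config.min_candidate_area,
        )
        counts["detections"] += len(kept)
        if not kept:
            logger.warning("no clusters detected in %s", name)
            continue
        table = compute_cluster_features(
            image, seg, [c.box for c in kept], config, image_name=name
        )
        if table.empty:
            continue
        feats = table[_FEATURE_COLUMNS].to_numpy()
        mean, sd, raw = compactness.predict_compactness(gpr_model, feats)
        table = table.assign(rating=mean, rating_raw=raw, rating_sd=sd)
        all_rows.append(table)
        counts["rated"] += len(table)
    if all_rows:
        predictions = pd.concat(all_rows, ignore_index=True)
    else:
        predictions = pd.DataFrame(
            columns=["image", *_BOX_COLUMNS, *_FEATURE_COLUMNS, *_RAW_COLUMNS,
                     "rating", "rating_raw", "rating_sd"]
        )
    return predictions, counts


def train_all(
    train_scenes: list[SyntheticScene],
    config: PipelineConfig,
    out_dir,
    *,
    ratings_by_scene: list[np.ndarray] | None = None,
    optimize_budget: int = 0,
    k_sweep: tuple[int, ...] | None = None,
):
    """Train all three models from labelled training scenes and write the
    archives plus a manifest.

    Pixel labels are sampled from the scenes' truth maps; the detector is
    trained on auto-extracted candidates; the GP model on the features of
    the "cluster" candidates matched to their true records, rated by
    ``ratings_by_scene`` (one array per scene, one rating per cluster
    record) or by the scenes' own compactness proxies when omitted.

    ``k_sweep`` evaluates the detector for each codebook size in the grid
    (e.g. :data:`CODEBOOK_K_GRID`) on a held-out quarter of the crops and
    keeps the AUC-best size before the final fit on all crops.
    """
    from . import fixtures
    from ._version_util import package_version

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label_seed = config.seeds.get("labeling", 0)
    coords_all, labels_all = [], []
    for i, scene in enumerate(train_scenes):
        coords, labels = fixtures.sample_labeled_pixels(
            scene, config.labeled_pixels_per_class, seed=label_seed + i
        )
        feats = colorseg.pixel_features(scene.image, coords)
        coords_all.append(feats)
        labels_all.append(labels)
    seg_model = train_segmentation(
        np.vstack(coords_all), np.concatenate(labels_all), config
    )
    save_segmentation_model(out / "seg.model", seg_model)

    crops, crop_labels = extract_detection_training_set(
        train_scenes, seg_model, config
    )
    crops, crop_labels = augment_detector_crops(crops, crop_labels, config)
    if k_sweep:
        config.codebook_k = sweep_codebook_size(crops, crop_labels, config,
                                                k_sweep)
        logger.info("codebook sweep selected k=%d", config.codebook_k)
    codebook, classifier = train_detector(crops, crop_labels, config)
    save_detector_model(out / "det.model", codebook, classifier)

    # features + ratings for the GP stage
    feature_rows, ratings = [], []
    for i, scene in enumerate(train_scenes):
        seg = colorseg.segment(seg_model, scene.image)
        kept, _ = detection.detect_clusters(
            scene.image, seg, codebook, classifier,
            opening_radius=config.candidate_opening_radius,
            min_area=config.min_candidate_area,
        )
        table = compute_cluster_features(
            scene.image, seg, [c.box for c in kept], config,
            image_name=f"scene{i}",
        )
        for _, row in table.iterrows():
            box = tuple(int(row[c]) for c in _BOX_COLUMNS)
            ious = [box_iou(box, rec.box) for rec in scene.clusters]
            if not ious or max(ious) < config.detector_label_iou:
                continue
            j = int(np.argmax(ious))
            if ratings_by_scene is not None:
                ratings.append(float(ratings_by_scene[i][j]))
            else:
                ratings.append(float(scene.clusters[j].compactness_proxy))
            feature_rows.append(row[_FEATURE_COLUMNS].to_numpy(dtype=float))
    if len(feature_rows) < 2:
        raise ValueError("too few matched clusters to train the rating model")
    features = np.vstack(feature_rows)
    gpr = train_compactness(
        features, np.asarray(ratings), config, optimize_budget=optimize_budget
    )
    save_gpr_model(out / "gpr.model", gpr, features, np.asarray(ratings))

    manifest = RunManifest(
        config=asdict(config),
        version=package_version(),
        stage_counts={
            "labeled_pixels": int(sum(len(l) for l in labels_all)),
            "training_crops": len(crops),
            "cluster_crops": int(sum(1 for l in crop_labels if l == "cluster")),
            "gpr_training_clusters": len(ratings),
        },
        seeds=dict(config.seeds),
        outputs=["seg.model", "det.model", "gpr.model"],
    )
    manifest.write(out / "manifest.json")
    return seg_model, (codebook, classifier), gpr
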