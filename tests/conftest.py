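"""Shared fixtures: synthetic scenes, trained pipeline models, and a full
CLI verb chain executed twice for byte-determinism checks.

The heavier artefacts (a labelled scene, a trained segmentation model, the
fully trained pipeline, the CLI chain) are session-scoped so the detection,
feature, end-to-end and determinism tests share one training run each.
"""

import logging
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from vinecompact import colorseg, fixtures, pipeline
from vinecompact.cli import main as cli_main

logging.getLogger("vinecompact").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scene():
    """A 480x480 scene with four clusters spanning the density range."""
    return fixtures.generate_scene(480, 480, 4, (0.2, 0.95), seed=42)


@pytest.fixture(scope="session")
def labeled_pixels(scene):
    coords, labels = fixtures.sample_labeled_pixels(scene, 500, seed=1)
    feats = colorseg.pixel_features(scene.image, coords)
    return feats, labels


@pytest.fixture(scope="session")
def seg_model(labeled_pixels):
    feats, labels = labeled_pixels
    return colorseg.train_mlr(feats, labels)


@pytest.fixture(scope="session")
def pipeline_config():
    return pipeline.PipelineConfig()


@pytest.fixture(scope="session")
def trained_models(tmp_path_factory, pipeline_config):
    """Segmentation + detector + rating models trained on six scenes with
    grape-coloured distractors, at the method's 300/300 detector-crop and
    500-pixel-per-class training sizes."""
    train_scenes = [
        fixtures.generate_scene(480, 480, 3, (0.2, 0.95), seed=500 + i,
                                n_distractors=2)
        for i in range(6)
    ]
    out = tmp_path_factory.mktemp("models")
    seg, (codebook, classifier), gpr = pipeline.train_all(
        train_scenes, pipeline_config, out
    )
    return {
        "seg": seg,
        "codebook": codebook,
        "classifier": classifier,
        "gpr": gpr,
        "dir": out,
        "train_scenes": train_scenes,
    }


# ---------------------------------------------------------------------------
# CLI chain: every verb run twice with identical inputs and seeds


def _run_cli(args):
    result = CliRunner().invoke(cli_main, args, catch_exceptions=False)
    assert result.exit_code == 0, result.output
    return result


@pytest.fixture(scope="session")
def cli_workspace(tmp_path_factory):
    """Scenes on disk, a labels CSV, a ratings CSV and a small config for
    exercising the CLI."""
    root = tmp_path_factory.mktemp("cli")
    _run_cli([
        "simulate", "--out", str(root / "scenes"), "--n-scenes", "3",
        "--width", "420", "--height", "420", "--clusters-per-scene", "2",
        "--distractors", "1", "--seed", "70",
    ])
    rows = []
    for sdir in sorted((root / "scenes").iterdir()):
        scene = fixtures.read_scene(sdir)
        coords, labels = fixtures.sample_labeled_pixels(scene, 120, seed=1)
        for (r, c), lab in zip(coords, labels):
            rows.append({"image_path": str(sdir / "image.png"),
                         "row": int(r), "col": int(c), "class": int(lab)})
    pd.DataFrame(rows).to_csv(root / "labels.csv", index=False)

    images = root / "images"
    images.mkdir()
    rrows = []
    for sdir in sorted((root / "scenes").iterdir()):
        shutil.copy(sdir / "image.png", images / f"{sdir.name}.png")
        scene = fixtures.read_scene(sdir)
        for rec in scene.clusters:
            rrows.append({"image_path": str(images / f"{sdir.name}.png"),
                          "row_min": rec.box[0], "col_min": rec.box[1],
                          "row_max": rec.box[2], "col_max": rec.box[3],
                          "rating": rec.compactness_proxy})
    pd.DataFrame(rrows).to_csv(root / "ratings.csv", index=False)

    (root / "config.yaml").write_text("\n".join([
        f"class_order: {list(fixtures.CLASS_NAMES)}",
        "candidate_opening_radius: 3",
        "refine_opening_radius: 2",
        "min_candidate_area: 100",
        "codebook_k: 40",
        "svm_box_constraint: 1.4654",
        "svm_kernel_scale: 24.628",
        "gpr_sigma: 0.83194",
        "gpr_kernel_scale: 91.5821",
        "crop_margin: 12",
        "detector_label_iou: 0.3",
        "labeled_pixels_per_class: 120",
        "detector_crops_per_class: 40",
        "cv_scheme: stratified-k-fold",
        "cv_folds: 10",
        "seeds: {labeling: 0, codebook: 0, cv: 0, detector_crops: 0}",
    ]))
    return root


@pytest.fixture(scope="session")
def cli_chain(cli_workspace):
    """Run every CLI verb twice with identical inputs/seeds; record whether
    each verb's outputs were byte-identical, plus first-run paths."""
    ws = str(cli_workspace)
    cfg = ["--config", f"{ws}/config.yaml"]
    identical: dict[str, bool] = {}

    def twice(name, args, outputs):
        produced = []
        for tag in ("r1", "r2"):
            tagged = [a.replace("@TAG@", tag) for a in args]
            _run_cli(tagged)
            produced.append([Path(o.replace("@TAG@", tag)) for o in outputs])
        identical[name] = all(
            a.read_bytes() == b.read_bytes() for a, b in zip(*produced)
        )
        return [str(p) for p in produced[0]]

    twice("simulate",
          ["simulate", "--out", f"{ws}/sim_@TAG@", "--n-scenes", "1",
           "--width", "420", "--height", "420", "--clusters-per-scene", "1",
           "--seed", "3"],
          [f"{ws}/sim_@TAG@/scene_000/image.png",
           f"{ws}/sim_@TAG@/scene_000/truth.png",
           f"{ws}/sim_@TAG@/scene_000/clusters.csv"])

    [seg_model] = twice(
        "train-seg",
        ["train-seg", "--labels", f"{ws}/labels.csv", *cfg,
         "--out", f"{ws}/seg_@TAG@.model"],
        [f"{ws}/seg_@TAG@.model"])

    twice("segment",
          ["segment", "--model", seg_model, "--images", f"{ws}/images",
           "--out", f"{ws}/seg_out_@TAG@"],
          [f"{ws}/seg_out_@TAG@/scene_000_seg.png",
           f"{ws}/seg_out_@TAG@/scene_002_seg.png"])

    [det_model] = twice(
        "train-detector",
        ["train-detector", "--scenes", f"{ws}/scenes",
         "--seg-model", seg_model, "--k", "40", *cfg,
         "--out", f"{ws}/det_@TAG@.model"],
        [f"{ws}/det_@TAG@.model"])

    [detections] = twice(
        "detect",
        ["detect", "--seg-model", seg_model, "--det-model", det_model,
         "--images", f"{ws}/images", *cfg,
         "--out", f"{ws}/detections_@TAG@.csv"],
        [f"{ws}/detections_@TAG@.csv"])

    [features] = twice(
        "features",
        ["features", "--seg-model", seg_model, "--detections", detections,
         "--images", f"{ws}/images", *cfg,
         "--out", f"{ws}/features_@TAG@.csv"],
        [f"{ws}/features_@TAG@.csv"])

    [gpr_model] = twice(
        "train-compactness",
        ["train-compactness", "--features", features,
         "--ratings", f"{ws}/ratings.csv", "--no-optimize", *cfg,
         "--out", f"{ws}/gpr_@TAG@.model"],
        [f"{ws}/gpr_@TAG@.model"])

    [predictions] = twice(
        "predict",
        ["predict", "--model", gpr_model, "--features", features,
         "--out", f"{ws}/predictions_@TAG@.csv"],
        [f"{ws}/predictions_@TAG@.csv"])

    twice("evaluate",
          ["evaluate", "--predictions", predictions,
           "--ratings", f"{ws}/ratings.csv", "--out", f"{ws}/eval_@TAG@.csv"],
          [f"{ws}/eval_@TAG@.csv"])

    models = Path(ws) / "models"
    models.mkdir(exist_ok=True)
    shutil.copy(seg_model, models / "seg.model")
    shutil.copy(det_model, models / "det.model")
    shutil.copy(gpr_model, models / "gpr.model")
    twice("run",
          ["run", "--models", str(models), "--images", f"{ws}/images", *cfg,
           "--out", f"{ws}/run_@TAG@"],
          [f"{ws}/run_@TAG@/predictions.csv", f"{ws}/run_@TAG@/manifest.json"])

    return {
        "identical": identical,
        "paths": {
            "detections": detections,
            "features": features,
            "predictions": predictions,
            "workspace": ws,
        },
    }
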