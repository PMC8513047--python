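"""End-to-end orchestration: image in, decision image and reports out.

The deployment flow mirrors field use of the tool: segment the grains in a
new image, extract the nine descriptors, score them with a trained network,
and draw each grain's predicted class id at its centroid ("decision
image").  When ground truth is available, per-class accuracies and their
arithmetic mean are reported in the standard per-class layout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from . import features as feat
from . import segmentation as seg
from . import synthetic as syn
from .specs import ClassSpec, default_class_specs

logger = logging.getLogger("ricemorph")


@dataclass
class DeploymentResult:
    """Predictions, decision image and (optional) accuracy for one image."""

    predictions: pd.DataFrame  # grain_id, centroid, predicted class, score
    annotated_image: np.ndarray
    per_class_accuracy: dict[int, float] | None = None
    mean_accuracy: float | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(
    out_dir: str | Path,
    specs: Sequence[ClassSpec] | None = None,
    n_images_per_class: int = 1,
    grains_per_image: int = 20,
    image_size: tuple[int, int] = (768, 768),
    touching_fraction: float = 0.0,
    seed: int = 0,
) -> dict:
    """Render per-class scenes, write PNG + truth sidecars and a manifest.

    One scene contains grains of a single class (mirroring one capture per
    rice type); ``n_images_per_class`` replicate scenes are rendered per
    class with derived per-scene seeds.  Returns the manifest, which lists
    every written file with its seed and content hash.
    """
    specs = list(specs) if specs is not None else default_class_specs()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    n_truth = 0
    for spec in specs:
        for rep in range(n_images_per_class):
            scene_seed = seed * 100003 + spec.class_id * 101 + rep
            scene = syn.render_grain_scene(
                [spec],
                n_per_class=grains_per_image,
                image_size=image_size,
                touching_fraction=touching_fraction,
                seed=scene_seed,
            )
            stem = f"{spec.abbreviation}_{rep:02d}"
            png = out / f"{stem}.png"
            truth = out / f"{stem}.truth.json"
            syn.save_scene(scene, png, truth)
            n_truth += scene.n_grains
            entries.append(
                {
                    "image": png.name,
                    "truth": truth.name,
                    "class_id": spec.class_id,
                    "seed": scene_seed,
                    "n_grains": scene.n_grains,
                    "sha256_image": _sha256(png),
                }
            )
            logger.info("rendered %s: %d grains", png.name, scene.n_grains)
    manifest = {
        "seed": seed,
        "n_scenes": len(entries),
        "n_truth_records": n_truth,
        "files": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def match_truth_classes(
    table: pd.DataFrame, truth: "list[syn.GrainTruth]", max_dist: float = 5.0
) -> pd.DataFrame:
    """Fill class_id by matching extracted centroids to ground-truth centers."""
    out = table.copy()
    centers = np.array([g.center for g in truth])
    classes = np.array([g.class_id for g in truth])
    for i, row in out.iterrows():
        d = np.hypot(
            centers[:, 0] - row["centroid_row"], centers[:, 1] - row["centroid_col"]
        )
        j = int(np.argmin(d))
        if d[j] <= max_dist:
            out.at[i, "class_id"] = int(classes[j])
    return out


def run_extract(
    image_paths: Sequence[str | Path],
    polarity: str = "auto",
    min_area: int = seg.DEFAULT_MIN_AREA,
    use_truth_sidecars: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Segment and extract features from each image into one combined table.

    APIdx is normalized per image (the batch is one image's grains).  When a
    ``<stem>.truth.json`` sidecar exists next to an image, class labels are
    filled from it by centroid matching.  Unreadable or failing files are
    reported in the returned failure list; the run continues.
    """
    from PIL import Image

    frames = []
    failures = []
    for path in image_paths:
        path = Path(path)
        try:
            image = np.asarray(Image.open(path).convert("RGB"))
            regions = seg.label_grains(image, polarity=polarity, min_area=min_area)
            table = feat.extract_features(image, regions)
            table["image_id"] = path.stem
            sidecar = path.with_suffix("").with_suffix(".truth.json")
            if use_truth_sidecars and not sidecar.exists():
                sidecar = path.parent / (path.stem + ".truth.json")
            if use_truth_sidecars and sidecar.exists():
                table = match_truth_classes(table, syn.load_truth(sidecar))
            frames.append(table)
            logger.info("%s: %d grains extracted", path.name, len(table))
        except Exception as exc:  # per-file failure policy: log and continue
            failures.append(f"{path}: {exc}")
            logger.warning("failed on %s: %s", path, exc)
    if not frames:
        return pd.DataFrame(), failures
    return pd.concat(frames, ignore_index=True), failures


def run_train(
    table: pd.DataFrame,
    n_hidden: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    config: clf.BRConfig | None = None,
    trim: bool = False,
    out_dir: str | Path | None = None,
    class_labels: dict[int, str] | None = None,
) -> tuple[clf.NetworkModel, pd.DataFrame, dict[str, clf.EvalReport]]:
    """Split, (optionally) trim, train with Bayesian regularization, report.

    Returns the model, a three-row stage report (Training / Testing /
    Overall with n, accuracy, error, MSE) and the underlying EvalReports.
    """
    drop = [c for c in ("centroid_row", "centroid_col", "image_id") if c in table]
    table = table.drop(columns=drop)
    unlabeled = table["class_id"].isna()
    if unlabeled.any():
        logger.warning("dropping %d unlabeled rows", int(unlabeled.sum()))
        table = table[~unlabeled]
    if table["class_id"].nunique() < 2:
        raise ValueError("training requires at least two classes")
    if trim:
        report = clf.neuron_trimming(table, seeds=[seed], config=config)
        n_hidden = report.recommended_n_hidden
        logger.info("neuron trimming recommends %d hidden neurons", n_hidden)
    train, test = clf.split_dataset(table, train_fraction, seed=seed)
    model = clf.train_br(train, n_hidden=n_hidden, config=config, seed=seed)
    if class_labels:
        model.class_labels = {
            int(k): v for k, v in class_labels.items() if int(k) in model.class_ids
        }
    else:
        model.class_labels = {
            s.class_id: s.abbreviation
            for s in default_class_specs()
            if s.class_id in model.class_ids
        }
    reports = {
        "training": clf.evaluate(model, train, "training"),
        "testing": clf.evaluate(model, test, "testing"),
    }
    overall_acc = clf.combine_stage_accuracies(
        [(r.n, r.accuracy) for r in reports.values()]
    )
    stage_rows = [
        reports["training"].summary_row(),
        reports["testing"].summary_row(),
        {
            "stage": "overall",
            "n": len(table),
            "accuracy_pct": round(overall_acc, 1),
            "error_pct": round(100.0 - overall_acc, 1),
            "mse": None,
        },
    ]
    report_frame = pd.DataFrame(stage_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.save(out / "model.json")
        report_frame.to_csv(out / "stage_report.csv", index=False)
        for name, rep in reports.items():
            rows = []
            for cid, pts in rep.roc.items():
                for fpr, tpr in pts:
                    rows.append({"class_id": cid, "fpr": fpr, "tpr": tpr})
            pd.DataFrame(rows).to_csv(out / f"roc_{name}.csv", index=False)
    return model, report_frame, reports


def _annotate(image: np.ndarray, predictions: pd.DataFrame) -> np.ndarray:
    """Draw each grain's predicted class id at its centroid."""
    from PIL import Image, ImageDraw

    img = Image.fromarray(image).convert("RGB")
    draw = ImageDraw.Draw(img)
    for _, row in predictions.iterrows():
        xy = (row["centroid_col"], row["centroid_row"])
        text = str(int(row["predicted_class"]))
        draw.text(xy, text, fill=(255, 0, 0), anchor="mm")
    return np.asarray(img)


def run_deploy(
    image: str | Path | np.ndarray,
    model: clf.NetworkModel | str | Path,
    truth: "list[syn.GrainTruth] | None" = None,
    polarity: str = "auto",
    min_area: int = seg.DEFAULT_MIN_AREA,
) -> DeploymentResult:
    """Deployment: segment -> extract -> predict -> annotate one image."""
    if not isinstance(model, clf.NetworkModel):
        model = clf.NetworkModel.load(model)
    if not isinstance(image, np.ndarray):
        from PIL import Image

        image = np.asarray(Image.open(image).convert("RGB"))
    try:
        regions = seg.label_grains(image, polarity=polarity, min_area=min_area)
    except seg.DegenerateThresholdError:
        logger.warning("uniform image, nothing to segment; empty result")
        return DeploymentResult(
            predictions=pd.DataFrame(), annotated_image=image.copy()
        )
    if regions.n_grains == 0:
        logger.warning("no grains detected; empty deployment result")
        return DeploymentResult(
            predictions=pd.DataFrame(), annotated_image=image.copy()
        )
    table = feat.extract_features(image, regions)
    scored = clf.predict(model, table)
    predictions = pd.DataFrame(
        {
            "grain_id": table["grain_id"],
            "centroid_row": table["centroid_row"],
            "centroid_col": table["centroid_col"],
            "predicted_class": scored["predicted_class"],
            "score": scored[
                [f"score_{c}" for c in model.class_ids]
            ].max(axis=1),
        }
    )
    per_class = None
    mean_acc = None
    if truth is not None:
        matched = match_truth_classes(table, truth)
        ok = matched["class_id"].notna()
        true_ids = matched.loc[ok, "class_id"].astype(int)
        pred_ids = predictions.loc[ok, "predicted_class"].astype(int)
        per_class = {}
        for cid in sorted(true_ids.unique()):
            sel = true_ids == cid
            per_class[int(cid)] = 100.0 * float((pred_ids[sel] == cid).mean())
        mean_acc = float(np.mean(list(per_class.values())))
    return DeploymentResult(
        predictions=predictions,
        annotated_image=_annotate(image, predictions),
        per_class_accuracy=per_class,
        mean_accuracy=mean_acc,
    )


def deployment_table(
    per_class_accuracy: dict[int, float],
    class_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-class deployment accuracies with an arithmetic-mean footer row."""
    labels = class_labels or {}
    rows = [
        {
            "sample": labels.get(cid, str(cid)),
            "class_id": cid,
            "accuracy_pct": acc,
        }
        for cid, acc in sorted(per_class_accuracy.items())
    ]
    mean = float(np.mean([r["accuracy_pct"] for r in rows]))
    rows.append({"sample": "Mean", "class_id": None, "accuracy_pct": round(mean, 1)})
    return pd.DataFrame(rows)
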