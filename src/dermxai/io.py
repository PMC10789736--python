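"""Readers and writers: PNG images and masks, CSV annotation tables,
JSON manifests, and explanation overlays.

On disk a dataset is::

    <dir>/
      manifest.json            # generator config + ontology + layout
      annotations.csv          # one row per image, one column per criterion
      images/<image_id>.png
      lesions/<image_id>.png   # 8-bit lesion segmentation (0/255)
      masks/<image_id>__<criterion_id>.png   # only present criteria

Annotation CSVs from other sources are accepted by
:func:`load_annotation_table` as long as they carry the required columns;
rows sharing an ``image_id`` with different ``rater_id`` values are merged
per image with union labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from dermxai.ontology import DiagnosisClass, Ontology, default_ontology
from dermxai.synthetic import AnnotatedSample, DatasetBundle, GeneratorConfig

REQUIRED_COLUMNS = ("image_id", "lesion_id", "patient_id", "diagnosis", "split")
_META_COLUMNS = set(REQUIRED_COLUMNS) | {"rater_id", "artifact"}


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------


def _to_uint8(img01):
    return (np.clip(img01, 0, 1) * 255).round().astype(np.uint8)


def write_dataset(bundle: DatasetBundle, out_dir) -> Path:
    """Write a bundle as PNGs + annotations.csv + manifest.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "lesions").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    rows = []
    for s in bundle.samples:
        iio.imwrite(out / "images" / f"{s.image_id}.png", _to_uint8(s.image))
        iio.imwrite(
            out / "lesions" / f"{s.image_id}.png",
            (s.lesion_mask.astype(np.uint8) * 255),
        )
        for cid, m in s.characteristic_masks.items():
            iio.imwrite(
                out / "masks" / f"{s.image_id}__{cid}.png",
                ((m > 0.5).astype(np.uint8) * 255),
            )
        row = {
            "image_id": s.image_id,
            "lesion_id": s.lesion_id,
            "patient_id": s.patient_id,
            "diagnosis": s.diagnosis.value,
            "split": s.split,
            "artifact": s.artifact or "",
        }
        for cid in bundle.ontology.ids:
            row[cid] = int(s.labels[bundle.ontology.index_of(cid)])
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "annotations.csv", index=False)

    cfg = asdict(bundle.config)
    cfg["image_size"] = list(bundle.config.image_size)
    cfg["criteria_subset"] = list(bundle.config.criteria_subset)
    manifest = {
        "format": "dermxai-dataset-v1",
        "config": cfg,
        "ontology": json.loads(bundle.ontology.to_json()),
        "n_samples": bundle.N,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_dataset(path) -> DatasetBundle:
    """Load a dataset bundle written by :func:`write_dataset`."""
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    ontology = Ontology.from_json(json.dumps(manifest["ontology"]))
    cfg = dict(manifest["config"])
    cfg["image_size"] = tuple(cfg["image_size"])
    cfg["criteria_subset"] = tuple(cfg["criteria_subset"])
    config = GeneratorConfig(**cfg)
    table = pd.read_csv(root / "annotations.csv", keep_default_na=False)

    samples = []
    for _, row in table.iterrows():
        image_id = row["image_id"]
        img = iio.imread(root / "images" / f"{image_id}.png").astype(np.float32) / 255.0
        lesion = iio.imread(root / "lesions" / f"{image_id}.png") > 127
        masks = {}
        labels = np.zeros(len(ontology), dtype=np.int8)
        for cid in ontology.ids:
            if cid in row and int(row[cid]) == 1:
                m = iio.imread(root / "masks" / f"{image_id}__{cid}.png") > 127
                masks[cid] = m.astype(np.float32)
                labels[ontology.index_of(cid)] = 1
        samples.append(
            AnnotatedSample(
                image=img,
                lesion_mask=lesion,
                characteristic_masks=masks,
                labels=labels,
                diagnosis=DiagnosisClass(row["diagnosis"]),
                lesion_id=row["lesion_id"],
                patient_id=row["patient_id"],
                split=row["split"],
                image_id=image_id,
                artifact=(row.get("artifact") or None),
            )
        )
    return DatasetBundle(samples=samples, ontology=ontology, config=config)


# ---------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------


@dataclass
class AnnotationIndex:
    """Validated per-image annotation index.

    ``table`` has one row per image with union-merged multi-hot labels;
    ``rater_sets`` maps image id -> {rater id -> set of criterion ids} for
    inter-rater analyses.
    """

    table: pd.DataFrame
    rater_sets: dict
    criterion_columns: list


def load_annotation_table(path, ontology: Ontology | None = None) -> AnnotationIndex:
    """Read and validate an annotation CSV.

    Required columns: image_id, lesion_id, patient_id, diagnosis, split and
    one column per criterion id; optional rater_id. Rows sharing an
    image_id (multiple raters) are merged per image by label union.
    """
    ontology = ontology or default_ontology()
    df = pd.read_csv(path, keep_default_na=False)
    if df.empty:
        raise SchemaError("annotation table is empty")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    crit_cols = [c for c in df.columns if c not in _META_COLUMNS]
    unknown = [c for c in crit_cols if c not in ontology]
    if unknown:
        raise SchemaError(f"unknown criterion column(s): {unknown}")
    if not crit_cols:
        raise SchemaError("no criterion columns found")

    rater_sets: dict = {}
    if "rater_id" in df.columns:
        for (image_id, rater), grp in df.groupby(["image_id", "rater_id"]):
            labels = {c for c in crit_cols if int(grp.iloc[0][c]) == 1}
            rater_sets.setdefault(image_id, {})[str(rater)] = labels

    agg = {c: "max" for c in crit_cols}  # union merge of multi-hot labels
    for col in ("lesion_id", "patient_id", "diagnosis", "split"):
        agg[col] = "first"
    merged = df.groupby("image_id", as_index=False).agg(agg)
    return AnnotationIndex(table=merged, rater_sets=rater_sets, criterion_columns=crit_cols)


# ---------------------------------------------------------------------
# explanation overlay
# ---------------------------------------------------------------------


def save_explanation_overlay(image, explanation, path) -> Path:
    """Write the image with white polygon outlines over the found regions.

    Only the polygon outlines are drawn — the lesion itself stays fully
    visible under the explanation.
    """
    if not explanation.regions:
        raise ValueError("explanation has no regions to draw")
    img = Image.fromarray(_to_uint8(np.asarray(image)))
    drawer = ImageDraw.Draw(img)
    for cid, region in explanation.regions.items():
        for poly in region["polygons"]:
            pts = [(float(x), float(y)) for x, y in np.asarray(poly)]
            if len(pts) >= 2:
                drawer.line(pts + [pts[0]], fill=(255, 255, 255), width=1)
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    img.save(out)
    return out
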