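"""CSV / JSON interchange.

Annotation CSV (one row per annotated shape):
    scene_id, role {mjvb_rect|mnvb_oval}, cx, cy, width, height, angle_deg, label
Feature CSV:
    scene_id, <nine features in canonical order>, label
Contour CSV (one file per contour):
    point_index, x, y
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .vbfeatures import (
    FEATURE_NAMES,
    FeatureVector,
    OvalAnnotation,
    RectAnnotation,
    SceneAnnotation,
)

ANNOTATION_COLUMNS = ["scene_id", "role", "cx", "cy", "width", "height", "angle_deg", "label"]


def write_annotations(scenes: list[SceneAnnotation], path) -> None:
    rows = []
    for scene in scenes:
        for rect in scene.mjvb_rects:
            rows.append({"scene_id": scene.scene_id, "role": "mjvb_rect",
                         "cx": rect.centre[0], "cy": rect.centre[1],
                         "width": rect.width, "height": rect.height,
                         "angle_deg": 0.0, "label": scene.label or ""})
        for oval in scene.mnvb_ovals:
            rows.append({"scene_id": scene.scene_id, "role": "mnvb_oval",
                         "cx": oval.centre[0], "cy": oval.centre[1],
                         "width": 2 * oval.semi_axes[0], "height": 2 * oval.semi_axes[1],
                         "angle_deg": math.degrees(oval.angle), "label": scene.label or ""})
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path) -> list[SceneAnnotation]:
    df = pd.read_csv(path, dtype={"scene_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV {path} is missing columns: {sorted(missing)}")
    scenes = []
    for scene_id, grp in df.groupby("scene_id", sort=True):
        rects, ovals, label = [], [], None
        for _, row in grp.iterrows():
            if isinstance(row["label"], str) and row["label"]:
                label = row["label"]
            if row["role"] == "mjvb_rect":
                rects.append(RectAnnotation(centre=(row["cx"], row["cy"]),
                                            width=row["width"], height=row["height"]))
            elif row["role"] == "mnvb_oval":
                ovals.append(OvalAnnotation(centre=(row["cx"], row["cy"]),
                                            semi_axes=(row["width"] / 2, row["height"] / 2),
                                            angle=math.radians(row["angle_deg"])))
            else:
                raise ValueError(f"scene {scene_id}: unknown role {row['role']!r}")
        if len(rects) != 2:
            raise ValueError(f"scene {scene_id}: expected exactly 2 mjvb_rect rows, got {len(rects)}")
        scenes.append(SceneAnnotation(mjvb_rects=tuple(rects), mnvb_ovals=ovals,
                                      label=label, scene_id=str(scene_id)))
    return scenes


def write_contour(contour: np.ndarray, path) -> None:
    pts = np.asarray(contour, dtype=float)
    pd.DataFrame({"point_index": np.arange(len(pts)), "x": pts[:, 0], "y": pts[:, 1]}).to_csv(
        path, index=False
    )


def read_contour(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("point_index", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"contour CSV {path} is missing column {col!r}")
    df = df.sort_values("point_index")
    return df[["x", "y"]].to_numpy(dtype=float)


def find_scene_contours(contours_dir, scene_id: str) -> list[np.ndarray]:
    """Contours named ``<scene_id>_mjvb0.csv`` / ``<scene_id>_mjvb1.csv``."""
    out = []
    for i in range(2):
        p = Path(contours_dir) / f"{scene_id}_mjvb{i}.csv"
        if p.exists():
            out.append(read_contour(p))
    return out


def write_features(table: pd.DataFrame, path) -> None:
    cols = ["scene_id", *FEATURE_NAMES, "label"]
    table.to_csv(path, index=False, columns=[c for c in cols if c in table.columns])


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature CSV {path} is missing columns: {sorted(missing)}")
    return df


def feature_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = [str(v) for v in df["label"]] if "label" in df.columns else [""] * len(df)
    return X, labels


def feature_vector_row(fv: FeatureVector, scene_id: str) -> dict:
    row = {"scene_id": scene_id}
    row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
    row["label"] = fv.label or ""
    return row
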