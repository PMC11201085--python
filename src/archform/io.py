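"""File input/output: meshes, landmark tables, shape tables, model JSON.

Conventions: coordinates are mm in a right-handed frame with +z toward the
crowns; tables are UTF-8 comma-separated CSV with a header row and '.'
decimals; reports and models are JSON at full double precision.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import DentalMesh
from .shape_stats import ArchClusterModel

logger = logging.getLogger("archform")

LANDMARK_COLUMNS = ["subject_id", "jaw", "tooth_label", "point_role", "x", "y", "z"]


class IOError_(ValueError):
    pass


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def read_mesh(path, jaw: str = "mandible") -> DentalMesh:
    """Load a PLY/STL/OBJ cast surface (coordinates assumed mm).

    STL stores triangle soup; duplicate vertices are merged on load so the
    connectivity-based pipeline sees a proper shared-vertex mesh.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"mesh file not found: {path}")
    if path.suffix.lower() not in (".ply", ".stl", ".obj"):
        raise IOError_(f"unsupported mesh format: {path.suffix}")
    loaded = trimesh.load(str(path), force="mesh")
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise IOError_(f"no triangulated surface in {path}")
    loaded.merge_vertices()
    return DentalMesh(
        vertices=np.asarray(loaded.vertices, float),
        faces=np.asarray(loaded.faces, np.int64),
        jaw=jaw,
    )


def write_mesh(mesh: DentalMesh, path, binary: bool = True) -> None:
    """Write a cast as PLY (binary little-endian by default) or STL/OBJ."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if path.suffix.lower() == ".ply":
        data = tm.export(file_type="ply", encoding="binary" if binary else "ascii")
    else:
        data = tm.export(file_type=path.suffix.lower().lstrip("."))
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def landmarks_to_frame(landmarks, subject_id, jaw: str) -> pd.DataFrame:
    pts = landmarks.points
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "jaw": jaw,
            "tooth_label": list(landmarks.tooth_labels) or [f"T{i+1}" for i in range(len(pts))],
            "point_role": list(landmarks.roles) or [""] * len(pts),
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
        }
    )


def shape_table(subject_ids, jaw, source, vectors: np.ndarray) -> pd.DataFrame:
    """Shape-vector table: subject_id, jaw, source, v1..vm."""
    v = np.atleast_2d(np.asarray(vectors, float))
    df = pd.DataFrame(v, columns=[f"v{i + 1}" for i in range(v.shape[1])])
    df.insert(0, "source", source)
    df.insert(0, "jaw", jaw)
    df.insert(0, "subject_id", subject_ids)
    return df


def read_shape_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"subject_id", "source"}
    if not needed.issubset(set(df.columns)):
        raise IOError_(f"shape table missing columns {needed - set(df.columns)}")
    return df


def shape_vectors_from_table(df: pd.DataFrame, source: str) -> tuple[np.ndarray, list]:
    sub = df[df["source"] == source].sort_values("subject_id")
    cols = [c for c in sub.columns if c.startswith("v") and c[1:].isdigit()]
    return sub[cols].to_numpy(float), sub["subject_id"].tolist()


# ---------------------------------------------------------------------------
# models and manifests
# ---------------------------------------------------------------------------


def model_to_dict(model: ArchClusterModel) -> dict:
    return {
        "k": int(model.k),
        "centers": model.centers.tolist(),
        "labels": model.labels.tolist(),
        "member_distances": model.member_distances.tolist(),
        "mu": model.mu.tolist(),
        "sigma": model.sigma.tolist(),
        "wss_curve": {str(k): v for k, v in model.wss_curve.items()},
    }


def model_from_dict(d: dict) -> ArchClusterModel:
    return ArchClusterModel(
        k=int(d["k"]),
        centers=np.asarray(d["centers"], float),
        labels=np.asarray(d["labels"], int),
        member_distances=np.asarray(d["member_distances"], float),
        mu=np.asarray(d["mu"], float),
        sigma=np.asarray(d["sigma"], float),
        wss_curve={int(k): float(v) for k, v in d.get("wss_curve", {}).items()},
    )


def write_results(objects: dict, out_dir, config=None, seed=None) -> dict:
    """Write result objects and a reproducibility manifest.

    ``objects`` maps file names to DataFrames (written as CSV) or
    JSON-serializable objects (written as JSON).  The manifest lists files,
    the config hash and the seed, so a logged run is reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, obj in objects.items():
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True)
        files.append(name)
        logger.info("wrote %s", path)
    from archform import __version__

    manifest = {
        "schema_version": 1,
        "archform_version": __version__,
        "files": sorted(files),
        "config_digest": config.digest() if config is not None else None,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
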