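"""Readers and writers for the package's file surfaces.

Case tables and cohorts are CSV (comma-separated, UTF-8, header row, "."
decimal point); configuration is YAML; reports and manifests are JSON
with deterministic key order; images are single-channel PNG/TIFF (8- or
16-bit), optionally DICOM for pixel data + pixel spacing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .validation import (
    BONE_ROSTER,
    BoneAssessment,
    ImageAssessment,
    STATUSES,
    ValidationConfig,
    ValidationError,
)

CASE_COLUMNS = ["image_id", "sex", "bone_id", "bone_age_y", "appearance_score"]


class ParseError(ValueError):
    """Schema violation in an input table, naming row and column."""


@dataclass(frozen=True)
class CaseInput:
    """One image's raw per-bone inputs, before validation."""

    image_id: str
    sex: str
    bones: tuple[BoneAssessment, ...]
    sharpness: float | None = None


def _fail(row: int, column: str, message: str) -> None:
    raise ParseError(f"row {row}, column {column!r}: {message}")


def read_case_table(
    path: str | Path, sharpness: str | Path | dict | None = None
) -> list[CaseInput]:
    """Read a per-bone case table (one row per bone).

    Columns: image_id, sex, bone_id, bone_age_y, appearance_score, and
    optionally a per-image ``sharpness`` column (constant within an
    image).  Alternatively ``sharpness`` may be a companion CSV with
    columns image_id, sharpness, or a mapping.  Row numbers in error
    messages are 1-based data rows (the header is row 0).
    """
    df = pd.read_csv(path, dtype={"image_id": str, "sex": str, "bone_id": str})
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")

    sharp_map: dict[str, float] = {}
    if isinstance(sharpness, dict):
        sharp_map = {str(k): float(v) for k, v in sharpness.items()}
    elif sharpness is not None:
        sdf = pd.read_csv(sharpness, dtype={"image_id": str})
        if "image_id" not in sdf.columns or "sharpness" not in sdf.columns:
            raise ParseError("sharpness table needs columns image_id, sharpness")
        sharp_map = dict(zip(sdf["image_id"], sdf["sharpness"].astype(float)))

    cases: list[CaseInput] = []
    for image_id, group in df.groupby("image_id", sort=False):
        bones: list[BoneAssessment] = []
        seen: set[str] = set()
        sexes = set(group["sex"])
        if len(sexes) != 1 or sexes - {"male", "female"}:
            _fail(int(group.index[0]) + 1, "sex",
                  f"image {image_id!r} must have one sex, male or female")
        for idx, row in group.iterrows():
            rownum = int(idx) + 1
            bone_id = row["bone_id"]
            if bone_id not in BONE_ROSTER:
                _fail(rownum, "bone_id", f"unknown bone {bone_id!r}")
            if bone_id in seen:
                _fail(rownum, "bone_id",
                      f"duplicate bone {bone_id!r} in image {image_id!r}")
            seen.add(bone_id)
            age = row["bone_age_y"]
            if not np.isfinite(age) or age < 0:
                _fail(rownum, "bone_age_y", f"must be finite and >= 0, got {age!r}")
            score = row["appearance_score"]
            if not np.isfinite(score) or not 0 <= score <= 1:
                _fail(rownum, "appearance_score",
                      f"must be in [0, 1], got {score!r}")
            bones.append(
                BoneAssessment(
                    bone_id=bone_id,
                    bone_age=float(age),
                    appearance_score=float(score),
                )
            )
        sharp = None
        if "sharpness" in group.columns and group["sharpness"].notna().any():
            vals = set(group["sharpness"].dropna().astype(float))
            if len(vals) != 1:
                _fail(int(group.index[0]) + 1, "sharpness",
                      f"image {image_id!r} has conflicting sharpness values")
            sharp = vals.pop()
        if image_id in sharp_map:
            sharp = sharp_map[image_id]
        cases.append(
            CaseInput(
                image_id=str(image_id),
                sex=str(group["sex"].iloc[0]),
                bones=tuple(bones),
                sharpness=sharp,
            )
        )
    return cases


def read_roi_table(path: str | Path) -> list[tuple[float, float, float, float]]:
    """Edge ROI segments: CSV with columns x0, y0, x1, y1 (pixels, 0-based)."""
    df = pd.read_csv(path)
    missing = [c for c in ("x0", "y0", "x1", "y1") if c not in df.columns]
    if missing:
        raise ParseError(f"ROI table missing columns: {missing}")
    return [tuple(map(float, r)) for r in df[["x0", "y0", "x1", "y1"]].to_numpy()]


def read_image(path: str | Path, pixel_spacing_mm: float | None = None):
    """Read a grayscale PNG/TIFF (or DICOM) image as a float array.

    Returns ``(image, pixel_spacing_mm)``; for DICOM files the pixel
    spacing is taken from the header unless overridden.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        img = ds.pixel_array.astype(float)
        if pixel_spacing_mm is None and "PixelSpacing" in ds:
            pixel_spacing_mm = float(ds.PixelSpacing[0])
    else:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        if img.shape[2] not in (1, 3, 4):
            raise ParseError("unsupported image layout")
        img = img[..., 0] if img.shape[2] == 1 else img[..., :3].mean(axis=2)
    return img, (0.1 if pixel_spacing_mm is None else pixel_spacing_mm)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image as 16-bit grayscale PNG/TIFF (rescaled to range)."""
    import imageio.v3 as iio

    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 65535).astype(np.uint16))


# --- reports ---------------------------------------------------------------

def assessment_record(assessment: ImageAssessment) -> dict:
    """JSON-ready record of one validated image (years to 2 decimals)."""
    final = assessment.final_bone_age
    return {
        "image_id": assessment.image_id,
        "sex": assessment.sex,
        "status": assessment.status,
        "final_bone_age_y": None if final is None else round(final, 2),
        "accepted_bone_count": len(assessment.accepted_bones),
        "sharpness": assessment.sharpness,
        "bones": [
            {
                "bone_id": b.bone_id,
                "bone_age_y": round(b.bone_age, 2),
                "accepted": b.accepted,
                "rejection_reason": b.rejection_reason,
            }
            for b in assessment.bones
        ],
    }


def write_report(
    assessments: Iterable[ImageAssessment | dict],
    path: str | Path,
    format: str = "json",
) -> None:
    """Write validation results as JSON (nested) or CSV (one row per bone)."""
    records = [
        a if isinstance(a, dict) else assessment_record(a) for a in assessments
    ]
    for r in records:
        if r["status"] not in STATUSES:
            raise ValidationError(f"invalid status {r['status']!r}")
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    elif format == "csv":
        rows = []
        for r in records:
            base = {k: r[k] for k in
                    ("image_id", "sex", "status", "final_bone_age_y",
                     "accepted_bone_count", "sharpness")}
            for b in r["bones"]:
                rows.append({**base, **b})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> list[dict]:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "json":
        return json.loads(path.read_text())
    if format != "csv":
        raise ValueError(f"unknown report format {format!r}")
    df = pd.read_csv(path, dtype={"image_id": str, "sex": str})
    records = []
    for image_id, g in df.groupby("image_id", sort=False):
        first = g.iloc[0]
        final = first["final_bone_age_y"]
        sharp = first["sharpness"]
        records.append({
            "image_id": str(image_id),
            "sex": str(first["sex"]),
            "status": str(first["status"]),
            "final_bone_age_y": None if pd.isna(final) else float(final),
            "accepted_bone_count": int(first["accepted_bone_count"]),
            "sharpness": None if pd.isna(sharp) else float(sharp),
            "bones": [
                {
                    "bone_id": str(b["bone_id"]),
                    "bone_age_y": float(b["bone_age_y"]),
                    "accepted": bool(b["accepted"]),
                    "rejection_reason": str(b["rejection_reason"]),
                }
                for _, b in g.iterrows()
            ],
        })
    return records


# --- configuration and manifest --------------------------------------------

class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None) -> ValidationConfig:
    """Load a :class:`ValidationConfig` from a YAML mapping."""
    if path is None:
        return ValidationConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    known = set(ValidationConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return ValidationConfig(**data)
    except (ValidationError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class RunManifest:
    """Provenance record: identical inputs + config + seed give an
    identical ``manifest_hash`` (the timestamp is excluded from it)."""

    tool_version: str
    config_hash: str
    input_hashes: tuple[tuple[str, str], ...]
    seed: int | None
    timestamp: str

    @property
    def manifest_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.tool_version.encode())
        h.update(self.config_hash.encode())
        for name, digest in self.input_hashes:
            h.update(name.encode())
            h.update(digest.encode())
        h.update(str(self.seed).encode())
        return h.hexdigest()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_hashes"] = [list(p) for p in self.input_hashes]
        d["manifest_hash"] = self.manifest_hash
        return d


def build_manifest(
    config: ValidationConfig | dict | None,
    input_paths: Sequence[str | Path] = (),
    seed: int | None = None,
) -> RunManifest:
    cfg = asdict(config) if isinstance(config, ValidationConfig) else (config or {})
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    hashes = tuple(
        (Path(p).name, hashlib.sha256(Path(p).read_bytes()).hexdigest())
        for p in input_paths
    )
    return RunManifest(
        tool_version=__version__,
        config_hash=cfg_hash,
        input_hashes=hashes,
        seed=seed,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
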