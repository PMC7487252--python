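"""File formats: annotation/detection CSV, PNG images, YAML config,
weights bundles, and the structured run log.

All CSV readers validate headers and report malformed rows with their
line number; every writer's output is re-parseable by the corresponding
reader (lossless round-trip).
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image

from .calibration import Calibration, Micrograph, StomaAnnotation
from .detection import Detection, DetectionConfig, DetectionSet
from .patches import PatchConfig

__all__ = [
    "ANNOTATION_HEADER", "DETECTION_HEADER", "RunConfig", "RunLog",
    "read_annotations", "write_annotations",
    "read_detections", "write_detections",
    "read_images", "read_image", "write_png",
    "save_weights", "load_weights",
]

ANNOTATION_HEADER = ["image_id", "x_px", "y_px", "length_px"]
DETECTION_HEADER = ["image_id", "x_px", "y_px", "confidence", "cluster_size"]


class FormatError(ValueError):
    """Malformed CSV or config input."""


def _check_header(row: list[str], expected: list[str], path) -> None:
    if [c.strip() for c in row] != expected:
        raise FormatError(
            f"{path}: unknown header {row!r}; expected columns {expected}")


def read_annotations(path) -> list[StomaAnnotation]:
    """Read ground-truth stoma annotations; empty length_px defaults to 120."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            _check_header(next(reader), ANNOTATION_HEADER, path)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header") from None
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                length = float(row[3]) if len(row) > 3 and row[3].strip() else 120.0
                ann = StomaAnnotation(row[0], float(row[1]), float(row[2]), length)
            except (IndexError, ValueError) as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
            out.append(ann)
    return out


def write_annotations(path, anns: Sequence[StomaAnnotation]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANNOTATION_HEADER)
        for a in anns:
            w.writerow([a.image_id, f"{a.x_px:.6g}", f"{a.y_px:.6g}",
                        f"{a.length_px:.6g}"])


def read_detections(path) -> list[DetectionSet]:
    """Read detections grouped per image (order of first appearance)."""
    groups: dict[str, DetectionSet] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            _check_header(next(reader), DETECTION_HEADER, path)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header") from None
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                det = Detection(float(row[1]), float(row[2]),
                                float(row[3]), int(row[4]))
            except (IndexError, ValueError) as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
            groups.setdefault(row[0], DetectionSet(row[0])).detections.append(det)
    return list(groups.values())


def write_detections(path, dets: DetectionSet | Sequence[DetectionSet]) -> None:
    sets = [dets] if isinstance(dets, DetectionSet) else list(dets)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DETECTION_HEADER)
        for ds in sets:
            for d in ds.detections:
                w.writerow([ds.image_id, f"{d.x_px:.6f}", f"{d.y_px:.6f}",
                            f"{d.confidence:.6f}", d.cluster_size])


def read_image(path, calibration: Calibration | None = None) -> Micrograph:
    """Load one PNG/TIFF as an 8-bit micrograph rescaled to [0, 1]."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("L" if im.mode in ("1", "I", "I;16", "F") else "RGB")
        arr = np.asarray(im)
    return Micrograph(path.stem, arr, calibration)


def read_images(directory, calibration: Calibration | None = None
                ) -> list[Micrograph]:
    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF images found in {directory}")
    return [read_image(p, calibration) for p in paths]


def write_png(path, m: Micrograph) -> None:
    arr = np.clip(np.round(m.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path, format="PNG")


# -- weights bundle ------------------------------------------------------

def save_weights(path, clf) -> None:
    """Save fitted classifier weights (.npz) plus a JSON sidecar recording
    the architecture and input normalization."""
    path = Path(path)
    np.savez(path, *clf.net_.get_weights())
    sidecar = {
        "architecture": clf.architecture,
        "dropout_rate": clf.dropout_rate,
        "random_state": clf.random_state,
        "normalization": "pixel/255 to [0,1]; grayscale replicated to 3 channels",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_weights(path):
    from .classify import PatchCNNClassifier

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    clf = PatchCNNClassifier(architecture=sidecar["architecture"],
                             dropout_rate=sidecar.get("dropout_rate", 0.5),
                             random_state=sidecar.get("random_state", 0))
    clf.initialize()
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        clf.net_.set_weights([z[k] for k in z.files])
    return clf


# -- run configuration ---------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults match the published
    workflow where it states values (120-px patches, τ = 0.7, Table-style
    Adam hyperparameters per architecture)."""

    calibration: Calibration = field(default_factory=Calibration.default)
    patch: PatchConfig = field(default_factory=PatchConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    architecture: str = "basic_shallow"
    stoma_major_axis_px: tuple[float, float] = (60.0, 90.0)
    epochs: int | None = None
    batch_size: int | None = None
    learning_rate: float | None = None
    neg_pos_ratio: float = 6.0
    match_radius_px: float = 60.0
    seed: int = 0
    n_train_images: int = 8
    n_eval_images: int = 6
    n_stomata: int = 25
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calibration"] = dataclasses.asdict(self.calibration)
        d["patch"] = dataclasses.asdict(self.patch)
        d["detection"] = dataclasses.asdict(self.detection)
        d["stoma_major_axis_px"] = list(self.stoma_major_axis_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "calibration" in d:
            d["calibration"] = Calibration(**d["calibration"])
        if "patch" in d:
            d["patch"] = PatchConfig(**d["patch"])
        if "detection" in d:
            d["detection"] = DetectionConfig(**d["detection"])
        if "stoma_major_axis_px" in d:
            d["stoma_major_axis_px"] = tuple(d["stoma_major_axis_px"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunLog:
    """Append-only machine-readable log; one JSON record per invocation."""

    path: Path

    def append(self, stage: str, **fields) -> None:
        rec = {
            "timestamp": datetime.datetime.now(datetime.timezone.utc)
            .isoformat(timespec="seconds"),
            "stage": stage,
            **fields,
        }
        self.path = Path(self.path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")
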