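"""On-disk formats: behavioral trial CSV, IDX / PNG image stores, run configuration.

All writers and readers are exact inverses of each other: a trial
table survives a write/read cycle field-for-field, and 8-bit images
survive pixel-exactly in both the IDX dialect (big-endian ubyte
tensors, magic 2051 for images and 2049 for labels, the MNIST layout)
and the one-PNG-per-instance directory layout.  Instance indexing on
disk is 0-based, pixels row-major with the origin at top-left.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .synthetic_data import CohortParams, TrialRecord

logger = logging.getLogger("glyphcurate")

TRIAL_COLUMNS = ["participant_id", "trial_index", "instance_id",
                 "true_class", "response_class", "rt_sec", "correct"]

IDX_IMAGES_MAGIC = 2051
IDX_LABELS_MAGIC = 2049


class ParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def trials_csv_text(records) -> str:
    """The trial table as CSV text (exact float round-trip via repr)."""
    df = pd.DataFrame([{
        "participant_id": r.participant_id,
        "trial_index": r.trial_index,
        "instance_id": r.instance_id,
        "true_class": r.true_class,
        "response_class": r.response_class,
        "rt_sec": repr(r.rt),
        "correct": int(r.correct),
    } for r in records], columns=TRIAL_COLUMNS)
    return df.to_csv(index=False)


def write_trials(records, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(trials_csv_text(records))


def read_trials(path) -> list:
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != TRIAL_COLUMNS:
        raise SchemaError(f"{path}: expected columns {TRIAL_COLUMNS}, got {list(df.columns)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            rt = float(row.rt_sec)
            if rt <= 0:
                raise ValueError("rt_sec must be positive")
            rec = TrialRecord(
                participant_id=str(row.participant_id),
                trial_index=int(row.trial_index),
                instance_id=str(row.instance_id),
                true_class=int(row.true_class),
                response_class=int(row.response_class),
                rt=rt,
                correct=bool(int(row.correct)),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Image stores
# ---------------------------------------------------------------------------

@dataclass
class ImageStore:
    """Ordered collection of same-sized labeled 8-bit grayscale images."""

    ids: list
    labels: np.ndarray   # int array, shape (N,)
    pixels: np.ndarray   # float array in [0, 1], shape (N, H, W)

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise FormatError("duplicate instance ids in store")
        if self.pixels.ndim != 3 or len(self.ids) != self.pixels.shape[0]:
            raise FormatError("pixels must be (N, H, W) matching ids")

    @property
    def shape(self):
        return self.pixels.shape[1:]

    @classmethod
    def from_instances(cls, instances) -> "ImageStore":
        shapes = {inst.pixels.shape for inst in instances}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent image sizes: {sorted(shapes)}")
        return cls(
            ids=[inst.instance_id for inst in instances],
            labels=np.array([inst.class_label for inst in instances], dtype=int),
            pixels=np.stack([inst.pixels for inst in instances]),
        )


def _write_idx_tensor(path: Path, arr: np.ndarray, magic: int) -> None:
    with open(path, "wb") as fh:
        fh.write(struct.pack(">HBB", 0, 0x08, arr.ndim))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(arr.astype(np.uint8).tobytes())


def _read_idx_tensor(path: Path) -> np.ndarray:
    raw = Path(path).read_bytes()
    zero, dtype_code, ndim = struct.unpack(">HBB", raw[:4])
    if zero != 0 or dtype_code != 0x08:
        raise FormatError(f"{path}: not an unsigned-byte IDX file")
    shape = struct.unpack(f">{ndim}I", raw[4:4 + 4 * ndim])
    data = np.frombuffer(raw[4 + 4 * ndim:], dtype=np.uint8)
    if data.size != int(np.prod(shape)):
        raise FormatError(f"{path}: payload size does not match header shape {shape}")
    return data.reshape(shape)


def write_images(store: ImageStore, path, dialect: str = "idx") -> None:
    """Write an image store as IDX ubyte tensors or per-class PNG directories."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pix8 = np.rint(np.clip(store.pixels, 0, 1) * 255).astype(np.uint8)
    if dialect == "idx":
        _write_idx_tensor(path / "images-idx3-ubyte", pix8, IDX_IMAGES_MAGIC)
        _write_idx_tensor(path / "labels-idx1-ubyte",
                          store.labels.astype(np.uint8), IDX_LABELS_MAGIC)
        (path / "ids.txt").write_text("\n".join(store.ids) + "\n")
    elif dialect == "png_dirs":
        for i, iid in enumerate(store.ids):
            cls_dir = path / f"class_{int(store.labels[i])}"
            cls_dir.mkdir(exist_ok=True)
            Image.fromarray(pix8[i], mode="L").save(cls_dir / f"{iid}.png")
    else:
        raise FormatError(f"unsupported image dialect: {dialect}")


def read_images(path, dialect: str = "idx") -> ImageStore:
    path = Path(path)
    if dialect == "idx":
        pix8 = _read_idx_tensor(path / "images-idx3-ubyte")
        if pix8.ndim != 3:
            raise FormatError(f"{path}: image tensor must be 3-dimensional")
        labels = _read_idx_tensor(path / "labels-idx1-ubyte").astype(int)
        ids_file = path / "ids.txt"
        if ids_file.exists():
            ids = ids_file.read_text().splitlines()
        else:
            ids = [f"idx{i:05d}" for i in range(pix8.shape[0])]
        return ImageStore(ids=ids, labels=labels, pixels=pix8.astype(float) / 255.0)
    if dialect == "png_dirs":
        ids, labels, imgs = [], [], []
        for cls_dir in sorted(path.glob("class_*")):
            label = int(cls_dir.name.split("_", 1)[1])
            for png in sorted(cls_dir.glob("*.png")):
                arr = np.asarray(Image.open(png).convert("L"))
                ids.append(png.stem)
                labels.append(label)
                imgs.append(arr.astype(float) / 255.0)
        if not imgs:
            raise FormatError(f"{path}: no class_*/ PNG files found")
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise FormatError(f"{path}: inconsistent image sizes: {sorted(shapes)}")
        return ImageStore(ids=ids, labels=np.array(labels), pixels=np.stack(imgs))
    raise FormatError(f"unsupported image dialect: {dialect}")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All knobs of a full synthetic replication run.

    Defaults reproduce the behavioral design: 4 classes, 20 instances
    per class seen twice (160 trials), a 75% accuracy filter, curated
    sets of 5 per class, the 9-shift x 3-rotation augmentation, and
    the fixed network training protocol (64 epochs, batch 64, Adam
    with step size 0.005).  ``epochs_override`` / ``ensemble_size``
    allow explicitly scaled-down runs and are logged when used.
    """

    n_classes: int = 4
    n_per_class: int = 20
    repeats: int = 2
    n_participants: int = 50
    deform_scale: float = 11.0
    deform_dispersion: float | None = 2.5
    sigma_tau: float = 7.5
    image_size: int = 28
    min_accuracy: float = 0.75
    exp3_min_accuracy: float = 0.50
    k_per_class: int = 5
    augment_enabled: bool = True
    n_test_per_class: int = 50
    epochs: int = 64
    batch_size: int = 64
    learning_rate: float = 0.005
    dropout: float = 0.5
    ensemble_size: int = 100
    epochs_override: int | None = None
    ensemble_override: int | None = None
    seed: int = 0
    out_dir: str = "runs/default"
    cohort: CohortParams = field(default_factory=CohortParams)

    def __post_init__(self):
        for name in ("n_classes", "n_per_class", "repeats", "n_participants",
                     "k_per_class", "n_test_per_class", "epochs", "batch_size",
                     "ensemble_size", "image_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("min_accuracy", "exp3_min_accuracy"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigError("dropout must be in [0, 1)")
        for name in ("epochs_override", "ensemble_override"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ConfigError(f"{name} must be positive when set")

    @property
    def effective_epochs(self) -> int:
        if self.epochs_override is not None:
            logger.warning("epochs overridden: %d (protocol value %d)",
                           self.epochs_override, self.epochs)
            return self.epochs_override
        return self.epochs

    @property
    def effective_ensemble(self) -> int:
        if self.ensemble_override is not None:
            logger.warning("ensemble size overridden: %d (protocol value %d)",
                           self.ensemble_override, self.ensemble_size)
            return self.ensemble_override
        return self.ensemble_size

    @property
    def curated_set_size(self) -> int:
        return self.n_classes * self.k_per_class


class ConfigError(ValueError):
    pass


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; unset fields take documented defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config fields: {sorted(unknown)}")
    if "cohort" in data and isinstance(data["cohort"], dict):
        data["cohort"] = CohortParams(**{k: tuple(v) for k, v in data["cohort"].items()})
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(config: RunConfig, path) -> None:
    data = {f.name: getattr(config, f.name) for f in fields(RunConfig)}
    data["cohort"] = {k: list(v) for k, v in vars(config.cohort).items()}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
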