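"""Dataset conventions: folder-per-variety image layout, the
``particle-grain-angle`` filename grammar, deterministic 8:1:1 splitting and
image preprocessing.

Filenames encode three dash- or underscore-separated integers; the third is
the shooting angle (1 = groin up, crease visible; 2 = groin down).  The
split allocation per class of size n is

    train = floor(0.8 n) + 1,   val = floor(0.1 n),   test = n - train - val,

the deterministic rule that reproduces every row of the published partition
table (801/100/99 for n = 1000, 804/100/100 for n = 1004).  Membership
within a class is a seeded shuffle, so the counts are fixed but the
assignment varies with the seed.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ANGLE_NAMES",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "SeedImageRecord",
    "SplitSpec",
    "ArraySplits",
    "parse_filename",
    "format_filename",
    "scan_dataset",
    "allocate_split",
    "split_dataset",
    "preprocess",
    "load_image",
    "load_split_arrays",
    "write_manifest",
    "read_manifest",
]

ANGLE_NAMES = {1: "groin-up", 2: "groin-down"}
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}

# per-channel normalisation defaults (the ubiquitous ImageNet statistics)
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

_STEM_RE = re.compile(r"^(\d+)[-_](\d+)[-_](\d+)$")


@dataclass(frozen=True)
class SeedImageRecord:
    """One image: its variety, grain identity, shooting angle, location and
    (once assigned) split membership."""

    variety_label: str
    particle_id: int
    grain_index: int
    angle: int  # 1 = groin up, 2 = groin down
    path: str
    split: str | None = None

    def __post_init__(self):
        if self.angle not in ANGLE_NAMES:
            raise ValueError(f"angle must be 1 or 2, got {self.angle}")
        if self.split not in (None, "train", "val", "test"):
            raise ValueError(f"invalid split {self.split!r}")

    @property
    def angle_name(self) -> str:
        return ANGLE_NAMES[self.angle]


@dataclass(frozen=True)
class SplitSpec:
    """8:1:1 split specification: the allocation rule is fixed; the seed
    controls which images land in which split.  ``group_by_grain`` keeps both
    shooting angles of a physical grain in the same split (leakage-free
    evaluation; off by default, mirroring the published random split)."""

    seed: int = 0
    group_by_grain: bool = False


def parse_filename(name: str) -> tuple[tuple[int, int], str]:
    """Parse an image filename stem into ``((particle_id, grain_index),
    angle_name)``; e.g. ``"78-3-1"`` -> ``((78, 3), "groin-up")``.

    Dash and underscore separators are both accepted.
    """
    stem = Path(name).stem
    match = _STEM_RE.match(stem)
    if not match:
        raise ValueError(
            f"filename {name!r} does not match the particle-grain-angle grammar")
    particle, grain, angle = (int(g) for g in match.groups())
    if angle not in ANGLE_NAMES:
        raise ValueError(f"filename {name!r} has invalid shooting angle {angle} "
                         "(expected 1 = groin up or 2 = groin down)")
    return (particle, grain), ANGLE_NAMES[angle]


def format_filename(particle_id: int, grain_index: int, angle: int,
                    extension: str = ".png") -> str:
    """Inverse of :func:`parse_filename` for valid records."""
    if angle not in ANGLE_NAMES:
        raise ValueError(f"angle must be 1 or 2, got {angle}")
    return f"{particle_id}-{grain_index}-{angle}{extension}"


def scan_dataset(root_dir) -> tuple[list[SeedImageRecord], dict[str, int]]:
    """Walk a folder-per-variety tree into records plus per-class counts.

    Records are ordered deterministically (class name, then filename) so the
    result is independent of filesystem enumeration order.  Non-image files
    are skipped with a warning; an empty class folder is an error.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class folders")
    records: list[SeedImageRecord] = []
    counts: dict[str, int] = {}
    for class_dir in class_dirs:
        files = sorted(p for p in class_dir.iterdir() if p.is_file())
        class_records = []
        for f in files:
            if f.suffix.lower() not in IMAGE_EXTENSIONS:
                warnings.warn(f"skipping non-image file {f}")
                continue
            (particle, grain), angle_name = parse_filename(f.name)
            angle = {v: k for k, v in ANGLE_NAMES.items()}[angle_name]
            class_records.append(SeedImageRecord(
                variety_label=class_dir.name, particle_id=particle,
                grain_index=grain, angle=angle, path=str(f)))
        if not class_records:
            raise ValueError(f"class folder {class_dir} contains no images")
        records.extend(class_records)
        counts[class_dir.name] = len(class_records)
    return records, counts


def allocate_split(n: int) -> tuple[int, int, int]:
    """Per-class (train, val, test) counts under the 8:1:1 allocation rule."""
    if n < 3:
        raise ValueError(f"class size must be >= 3 to split, got {n}")
    train = int(np.floor(0.8 * n)) + 1
    val = int(np.floor(0.1 * n))
    test = n - train - val
    if test < 0:
        raise ValueError(f"allocation rule yields a negative test count for n={n}")
    return train, val, test


def split_dataset(records: list[SeedImageRecord],
                  spec: SplitSpec) -> list[SeedImageRecord]:
    """Assign every record to exactly one of train/val/test.

    Classes are processed in sorted label order with a per-class seeded
    shuffle, so membership is a pure function of the records and the seed.
    With ``group_by_grain`` the shuffle is over whole grains and each grain's
    images go to one split (counts may then deviate from the rule by at most
    one grain's worth of images per boundary).
    """
    by_class: dict[str, list[SeedImageRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.variety_label, []).append(rec)
    rng = np.random.default_rng(spec.seed)
    out: list[SeedImageRecord] = []
    for label in sorted(by_class):
        recs = sorted(by_class[label], key=lambda r: Path(r.path).name)
        n = len(recs)
        n_train, n_val, _ = allocate_split(n)
        if spec.group_by_grain:
            grains: dict[tuple[int, int], list[SeedImageRecord]] = {}
            for rec in recs:
                grains.setdefault((rec.particle_id, rec.grain_index), []).append(rec)
            keys = sorted(grains)
            rng.shuffle(keys)
            assigned = 0
            for key in keys:
                group = grains[key]
                if assigned < n_train:
                    split = "train"
                elif assigned < n_train + n_val:
                    split = "val"
                else:
                    split = "test"
                out.extend(replace(r, split=split) for r in group)
                assigned += len(group)
        else:
            order = rng.permutation(n)
            for pos, idx in enumerate(order):
                if pos < n_train:
                    split = "train"
                elif pos < n_train + n_val:
                    split = "val"
                else:
                    split = "test"
                out.append(replace(recs[idx], split=split))
    return out


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def load_image(path) -> np.ndarray:
    """Decode an image file to an (H, W, 3) uint8 array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise ValueError(f"cannot decode image {path}: {exc}") from exc


def _to_float_hwc(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    return arr.astype(np.float32)


def _resize(arr: np.ndarray, size: int) -> np.ndarray:
    im = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8))
    return np.asarray(im.resize((size, size), Image.BILINEAR)).astype(np.float32) / 255.0


def preprocess(image, split: str, input_size: int = 224,
               mean=IMAGENET_MEAN, std=IMAGENET_STD,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Turn one RGB image into a normalised (3, S, S) float32 array.

    Training images get a seeded random resized crop (area scale 0.75-1.0,
    mild aspect jitter) before normalisation; validation and test images are
    simply resized.  The crop is kept gentle because the subject is a single
    centred grain that must stay inside the frame.  ``image`` may be a path,
    a PIL image or an (H, W, 3) array (uint8 in [0, 255] or float in [0, 1]).
    """
    if isinstance(image, (str, Path)):
        image = load_image(image)
    arr = _to_float_hwc(image)
    h, w = arr.shape[:2]
    if split == "train":
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = rng.uniform(0.75, 1.0)
        ratio = rng.uniform(0.85, 1.18)
        area = scale * h * w
        ch = min(h, max(1, int(round(np.sqrt(area / ratio)))))
        cw = min(w, max(1, int(round(np.sqrt(area * ratio)))))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        arr = arr[top:top + ch, left:left + cw]
        arr = _resize(arr, input_size)
    elif split in ("val", "test"):
        if arr.shape[0] != input_size or arr.shape[1] != input_size:
            arr = _resize(arr, input_size)
    else:
        raise ValueError(f"unknown split {split!r}")
    mean = np.asarray(mean, dtype=np.float32)
    std = np.asarray(std, dtype=np.float32)
    arr = (arr - mean) / std
    return np.ascontiguousarray(arr.transpose(2, 0, 1))


@dataclass
class ArraySplits:
    """Materialised (X, y) arrays per split plus the label vocabulary."""

    train: tuple[np.ndarray, np.ndarray]
    val: tuple[np.ndarray, np.ndarray] | None
    test: tuple[np.ndarray, np.ndarray]
    class_names: list[str]


def load_split_arrays(records: list[SeedImageRecord], input_size: int,
                      mean=IMAGENET_MEAN, std=IMAGENET_STD,
                      seed: int = 0) -> ArraySplits:
    """Load and preprocess all split-assigned records into arrays.

    Training crops are drawn from a generator seeded with ``seed``, so the
    materialised arrays are deterministic.
    """
    class_names = sorted({r.variety_label for r in records})
    label_index = {name: i for i, name in enumerate(class_names)}
    rng = np.random.default_rng(seed)
    arrays: dict[str, tuple[list, list]] = {s: ([], []) for s in ("train", "val", "test")}
    for rec in sorted(records, key=lambda r: (r.variety_label, Path(r.path).name)):
        if rec.split is None:
            raise ValueError(f"record {rec.path} has no split assignment")
        xs, ys = arrays[rec.split]
        xs.append(preprocess(rec.path, rec.split, input_size, mean, std, rng))
        ys.append(label_index[rec.variety_label])

    def pack(split: str):
        xs, ys = arrays[split]
        if not xs:
            return None
        return np.stack(xs), np.asarray(ys, dtype=np.int64)

    train, val, test = pack("train"), pack("val"), pack("test")
    if train is None or test is None:
        raise ValueError("both train and test splits must be non-empty")
    return ArraySplits(train=train, val=val, test=test, class_names=class_names)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["path", "class", "particle_id", "grain_index", "angle", "split"]


def write_manifest(records: list[SeedImageRecord], path) -> None:
    """Write records as a CSV manifest (path, class, particle_id,
    grain_index, angle, split)."""
    rows = [{
        "path": r.path, "class": r.variety_label, "particle_id": r.particle_id,
        "grain_index": r.grain_index, "angle": r.angle,
        "split": r.split if r.split is not None else "",
    } for r in records]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> list[SeedImageRecord]:
    """Read a manifest CSV back into records (lossless round trip)."""
    df = pd.read_csv(path, dtype={"class": str}, keep_default_na=False)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    records = []
    for row in df.to_dict("records"):
        split = row["split"] if row["split"] else None
        records.append(SeedImageRecord(
            variety_label=str(row["class"]), particle_id=int(row["particle_id"]),
            grain_index=int(row["grain_index"]), angle=int(row["angle"]),
            path=str(row["path"]), split=split))
    return records
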