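"""Image loading and preparation.

Every downstream stage of the pipeline operates on an :class:`ImageRecord`:
four 2-D intensity planes (gray, red, green, blue) at a fixed working
resolution, plus an optional binary label.  Grayscale is derived from RGB
with ITU-R BT.601 luminance weights; resizing is bilinear.  All intensities
are 8-bit (0-255).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

TARGET_SIZE = 224
CHANNELS = ("gray", "red", "green", "blue")

#: ITU-R BT.601 luminance weights for R, G, B.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageRecord:
    """One preprocessed image: four channel planes plus an optional label.

    Invariants: all four channel grids share the same square shape and hold
    integer intensities in [0, 255]; ``gray`` is the BT.601 luminance of
    (red, green, blue), rounded to the nearest integer.
    """

    id: str
    channels: dict[str, np.ndarray]
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ValueError(f"ImageRecord {self.id!r} missing channels: {missing}")
        shapes = {c: self.channels[c].shape for c in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes disagree: {shapes}")
        for c in CHANNELS:
            a = self.channels[c]
            if a.min() < 0 or a.max() > 255:
                raise ValueError(f"channel {c!r} outside [0, 255]")

    @property
    def size(self) -> int:
        return self.channels["gray"].shape[0]


def record_from_rgb(rgb: np.ndarray, id: str = "", label: int | None = None,
                    meta: dict | None = None) -> ImageRecord:
    """Build an ImageRecord from an (H, W, 3) uint8 RGB array (no resize)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {rgb.shape}")
    gray = np.rint(rgb.astype(np.float64) @ _LUMA).clip(0, 255).astype(np.uint8)
    channels = {
        "gray": gray,
        "red": rgb[:, :, 0].astype(np.uint8),
        "green": rgb[:, :, 1].astype(np.uint8),
        "blue": rgb[:, :, 2].astype(np.uint8),
    }
    return ImageRecord(id=id, channels=channels, label=label, meta=meta or {})


def load_and_prepare(path: str | os.PathLike, target_size: int = TARGET_SIZE,
                     label: int | None = None) -> ImageRecord:
    """Read a PNG/TIFF raster, resize to ``target_size`` square, split channels.

    Grayscale inputs are promoted to RGB by replication.  Resizing is
    bilinear with intensities rounded back to integers; an input already at
    the target size passes through unchanged.
    """
    try:
        with Image.open(path) as im:
            im.load()
            img = im
            if img.mode not in ("RGB", "L"):
                img = img.convert("RGB")
            arr = np.asarray(img)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    if arr.size == 0 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError(f"zero-area image: {os.fspath(path)!r}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[:2] != (target_size, target_size):
        resized = Image.fromarray(arr).resize(
            (target_size, target_size), resample=Image.BILINEAR
        )
        arr = np.asarray(resized)
    arr = np.rint(arr.astype(np.float64)).clip(0, 255).astype(np.uint8)
    return record_from_rgb(arr, id=os.fspath(path), label=label)


def read_manifest(path: str | os.PathLike) -> list[tuple[str, int]]:
    """Read a ``path,label`` CSV manifest into ordered (path, label) pairs.

    Fails fast: an empty manifest, a missing column, a non-binary label or a
    dangling image path each raise ``ValueError`` naming the offending rows.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, OSError) as exc:
        raise ValueError(f"cannot read manifest {os.fspath(path)!r}: {exc}") from exc
    for col in ("path", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest {os.fspath(path)!r} missing column {col!r}")
    if len(df) == 0:
        raise ValueError(f"manifest {os.fspath(path)!r} has no rows")
    labels = pd.to_numeric(df["label"], errors="coerce")
    bad = df.index[~labels.isin([0, 1])].tolist()
    if bad:
        raise ValueError(f"non-binary labels at manifest rows {bad}")
    base = os.path.dirname(os.fspath(path))
    records: list[tuple[str, int]] = []
    dangling: list[int] = []
    for i, row in df.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        if not os.path.exists(p):
            dangling.append(i)
        records.append((p, int(labels[i])))
    if dangling:
        raise ValueError(f"manifest image paths do not exist at rows {dangling}")
    return records
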