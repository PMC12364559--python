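"""Frame-sequence, annotation and manifest I/O.

Conventions used throughout the package:

* Frames are ``h x w x 3`` float arrays, channel order RGB, values in
  ``[0, 1]``. 8-bit image files map to floats by ``value / 255`` (16-bit
  by ``value / 65535``), so a saturated channel is exactly 1.0.
* Bounding boxes are stored center-normalized in YOLO text form
  (``class cx cy w h``) and converted to 0-based, half-open pixel
  corners ``(x1, y1, x2, y2)`` with x right / y down, so that
  ``width = x2 - x1`` holds exactly on integer boxes.
* A :class:`DatasetManifest` links each labelled image to its position
  inside a surrounding sequence (a video or an ordered burst folder) —
  the piece of bookkeeping that makes movement measures computable for
  labelled frames.

PNG folders are the canonical lossless container; video decoding is
delegated to imageio and carries no bit-exactness guarantee.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.transform import resize as _sk_resize

__all__ = [
    "FrameSequence",
    "Annotation",
    "ManifestEntry",
    "DatasetManifest",
    "read_sequence",
    "write_sequence",
    "read_annotations",
    "write_annotations",
    "resize_with_annotations",
]

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
_VIDEO_EXTS = {".mp4", ".avi", ".mov", ".mkv"}


class MissingFrameError(ValueError):
    """A requested frame index does not exist in the source."""


@dataclass
class FrameSequence:
    """An ordered stack of RGB frames with its position in the source.

    Parameters
    ----------
    frames
        Array of shape ``(n, h, w, 3)``, floats in ``[0, 1]``.
    frame_index_origin
        Source index of ``frames[0]``; lets callers address frames by
        their index in the full video/burst rather than the loaded slice.
    source_id
        Identifier of the originating video or folder.
    frame_interval
        Seconds between consecutive frames, if known.
    """

    frames: np.ndarray
    frame_index_origin: int = 0
    source_id: str = ""
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must have shape (n, h, w, 3), got {self.frames.shape}")
        if self.frames.size and (self.frames.min() < 0.0 or self.frames.max() > 1.0):
            raise ValueError("frame values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def last_index(self) -> int:
        """Source index of the last loaded frame (inclusive)."""
        return self.frame_index_origin + self.n_frames - 1

    def frame(self, t: int, boundary: str = "strict") -> np.ndarray:
        """Frame at *source* index ``t``.

        ``boundary='clamp'`` substitutes the nearest loaded frame when
        ``t`` falls outside the loaded window; ``'strict'`` raises.
        """
        i = t - self.frame_index_origin
        if 0 <= i < self.n_frames:
            return self.frames[i]
        if boundary == "clamp":
            return self.frames[min(max(i, 0), self.n_frames - 1)]
        raise MissingFrameError(
            f"frame {t} outside loaded window "
            f"[{self.frame_index_origin}, {self.last_index}] of '{self.source_id}'"
        )


@dataclass
class Annotation:
    """A ground-truth box: class id plus center-normalized geometry."""

    class_id: int
    cx: float
    cy: float
    bw: float
    bh: float
    image_ref: str = ""

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")
        x1, y1 = self.cx - self.bw / 2, self.cy - self.bh / 2
        x2, y2 = self.cx + self.bw / 2, self.cy + self.bh / 2
        eps = 1e-9
        if not (-eps <= x1 and x2 <= 1 + eps and -eps <= y1 and y2 <= 1 + eps):
            raise ValueError(f"box {self} extends outside the unit square")

    def to_corners(self, height: int, width: int) -> tuple[float, float, float, float]:
        """Half-open pixel corners ``(x1, y1, x2, y2)``."""
        return (
            (self.cx - self.bw / 2) * width,
            (self.cy - self.bh / 2) * height,
            (self.cx + self.bw / 2) * width,
            (self.cy + self.bh / 2) * height,
        )

    @staticmethod
    def from_corners(
        class_id: int, x1: float, y1: float, x2: float, y2: float, height: int, width: int, image_ref: str = ""
    ) -> "Annotation":
        return Annotation(
            class_id=class_id,
            cx=(x1 + x2) / 2 / width,
            cy=(y1 + y2) / 2 / height,
            bw=(x2 - x1) / width,
            bh=(y2 - y1) / height,
            image_ref=image_ref,
        )


@dataclass
class ManifestEntry:
    image_id: str
    sequence: str
    frame_index: int
    split: str

    def __post_init__(self) -> None:
        if self.split not in {"train", "val", "test"}:
            raise ValueError(f"split must be train/val/test, got {self.split!r}")


@dataclass
class DatasetManifest:
    """Links labelled images to their surrounding sequences and splits."""

    classes: list[str]
    entries: list[ManifestEntry]
    sequences_root: str = "sequences"
    labels_root: str = "labels_src"

    def __post_init__(self) -> None:
        ids = [e.image_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image ids in manifest")

    def by_split(self, split: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.split == split]

    def save(self, path: str | Path) -> None:
        data = {
            "classes": list(self.classes),
            "sequences_root": self.sequences_root,
            "labels_root": self.labels_root,
            "entries": [
                {"image_id": e.image_id, "sequence": e.sequence, "frame_index": e.frame_index, "split": e.split}
                for e in self.entries
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @staticmethod
    def load(path: str | Path) -> "DatasetManifest":
        data = yaml.safe_load(Path(path).read_text())
        return DatasetManifest(
            classes=list(data["classes"]),
            sequences_root=data.get("sequences_root", "sequences"),
            labels_root=data.get("labels_root", "labels_src"),
            entries=[ManifestEntry(**e) for e in data["entries"]],
        )


# ---------------------------------------------------------------------------
# sequences


def _to_float(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _indexed_files(folder: Path) -> list[tuple[int, Path]]:
    files = sorted(p for p in folder.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
    if not files:
        raise IOError(f"no image files in {folder}")
    indexed = []
    for pos, p in enumerate(files):
        m = re.search(r"(\d+)$", p.stem)
        indexed.append((int(m.group(1)) if m else pos, p))
    indices = [i for i, _ in indexed]
    if len(set(indices)) != len(indices):  # numeric suffixes not unique -> positional
        indexed = list(enumerate(files))
    return indexed


def read_sequence(
    path: str | Path,
    window: tuple[int, int] | None = None,
    frame_interval: float | None = None,
) -> FrameSequence:
    """Load a frame sequence from an image folder or a video file.

    ``window=(first, last)`` selects source frame indices inclusively.
    For folders, a trailing integer in each file stem is taken as the
    source index (``frame_000042.png`` -> 42); a gap inside the window
    raises :class:`MissingFrameError` naming the missing index.
    """
    path = Path(path)
    if path.is_dir():
        indexed = {i: p for i, p in _indexed_files(path)}
        if window is None:
            window = (min(indexed), max(indexed))
        first, last = window
        frames = []
        for i in range(first, last + 1):
            if i not in indexed:
                raise MissingFrameError(f"frame index {i} missing from {path}")
            frames.append(_to_float(iio.imread(indexed[i])))
        return FrameSequence(
            frames=np.stack(frames),
            frame_index_origin=first,
            source_id=path.name,
            frame_interval=frame_interval,
        )
    if path.suffix.lower() in _VIDEO_EXTS:
        try:
            raw = iio.imread(path, plugin="pyav")
        except Exception as exc:  # pragma: no cover - codec availability varies
            raise IOError(f"cannot decode video {path}: {exc}") from exc
        frames = [_to_float(f) for f in raw]
        first, last = window if window is not None else (0, len(frames) - 1)
        if not (0 <= first <= last < len(frames)):
            raise MissingFrameError(f"window {window} outside video of {len(frames)} frames")
        return FrameSequence(
            frames=np.stack(frames[first : last + 1]),
            frame_index_origin=first,
            source_id=path.stem,
            frame_interval=frame_interval,
        )
    raise IOError(f"{path} is neither an image folder nor a recognised video file")


def write_sequence(seq: FrameSequence, folder: str | Path, bit_depth: int = 8) -> list[Path]:
    """Write frames as ``frame_NNNNNN.png`` numbered by source index.

    8-bit output quantizes to 1/255 steps; values that are already
    multiples of 1/255 (anything loaded from 8-bit files) round-trip
    bit-exactly. Pass ``bit_depth=16`` for finer quantization.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    if bit_depth == 8:
        scale, dtype = 255, np.uint8
    elif bit_depth == 16:
        scale, dtype = 65535, np.uint16
    else:
        raise ValueError("bit_depth must be 8 or 16")
    paths = []
    for offset in range(seq.n_frames):
        idx = seq.frame_index_origin + offset
        out = folder / f"frame_{idx:06d}.png"
        iio.imwrite(out, np.round(seq.frames[offset] * scale).astype(dtype))
        paths.append(out)
    return paths


# ---------------------------------------------------------------------------
# annotations (YOLO text dialect)


def _parse_box_lines(path: Path, expect_score: bool) -> list[tuple[int, float, float, float, float, float | None]]:
    rows: list[tuple[int, float, float, float, float, float | None]] = []
    bad: list[int] = []
    text = path.read_text() if path.exists() else ""
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) not in (5, 6):
            bad.append(lineno)
            continue
        try:
            cls = int(tokens[0])
            cx, cy, bw, bh = (float(v) for v in tokens[1:5])
            score = float(tokens[5]) if len(tokens) == 6 else None
        except ValueError:
            bad.append(lineno)
            continue
        x1, y1, x2, y2 = cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2
        eps = 1e-9
        if cls < 0 or not (-eps <= x1 and x2 <= 1 + eps and -eps <= y1 and y2 <= 1 + eps):
            bad.append(lineno)
            continue
        if expect_score and score is not None and not (0.0 <= score <= 1.0):
            bad.append(lineno)
            continue
        rows.append((cls, cx, cy, bw, bh, score))
    if bad:
        raise ValueError(f"{path}: invalid annotation lines {bad}")
    return rows


def read_annotations(path: str | Path, image_ref: str = "") -> list[Annotation]:
    """Parse a YOLO label file (``class cx cy w h`` per line).

    Lines with a trailing sixth token (a confidence score, as written by
    detectors) are accepted; the score is ignored here — use
    :func:`motionaug.evaluation.read_detections` to keep it.
    """
    path = Path(path)
    ref = image_ref or path.stem
    return [
        Annotation(class_id=cls, cx=cx, cy=cy, bw=bw, bh=bh, image_ref=ref)
        for cls, cx, cy, bw, bh, _ in _parse_box_lines(path, expect_score=False)
    ]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    lines = [f"{a.class_id} {a.cx:.6f} {a.cy:.6f} {a.bw:.6f} {a.bh:.6f}" for a in annotations]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def resize_with_annotations(
    image: np.ndarray,
    annotations: Sequence[Annotation],
    target: tuple[int, int],
) -> tuple[np.ndarray, list[Annotation]]:
    """Resample ``image`` to ``target=(H, W)``.

    Normalized boxes are scale-free, so the annotations pass through
    unchanged (copies are returned). Resampling is bilinear with
    anti-aliasing on downscale.
    """
    h, w = target
    if h <= 0 or w <= 0:
        raise ValueError(f"target must be positive, got {target}")
    out = _sk_resize(image, (h, w), order=1, anti_aliasing=None, preserve_range=True)
    return np.clip(out, 0.0, 1.0), [replace(a) for a in annotations]
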