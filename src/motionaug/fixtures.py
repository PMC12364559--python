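"""Synthetic frame sequences with exact ground-truth boxes.

Monitoring footage is awkward test data: real sequences are huge and
their "true" motion is unknown. These fixtures render small scenes —
a static or drifting background, one or more moving shapes, optional
underwater colour cast or monochrome night rendering, i.i.d. Gaussian
pixel noise — where every object's bounding box is known exactly at
every frame. Trajectories are per-frame integer displacements, so box
positions follow by plain arithmetic and tests can assert them exactly.

The emulated regimes: underwater video (red channel strongly absorbed
by the water column), camera-trap night bursts (R=G=B infrared frames),
and sensor noise. Nothing here attempts photorealism; the point is
known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from motionaug.sequence_io import (
    Annotation,
    DatasetManifest,
    FrameSequence,
    ManifestEntry,
    write_annotations,
    write_sequence,
)

__all__ = ["ObjectSpec", "SceneSpec", "generate_sequence", "render_monochrome", "write_fixture_dataset"]

# ITU-R BT.601 luma weights; documented so tests can apply them by hand
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class ObjectSpec:
    """One moving shape.

    ``position`` is the top-left pixel of the bounding box at frame 0;
    ``trajectory`` gives integer (dx, dy) displacements applied between
    consecutive frames (length >= n_frames - 1; a short list repeats its
    last element). ``contrast`` is the declared minimum absolute mean
    difference between object and background colour, validated at render
    time.
    """

    size: tuple[int, int]  # (w, h) pixels
    colour: tuple[float, float, float]
    position: tuple[int, int] = (0, 0)  # (x, y) top-left at frame 0
    trajectory: list[tuple[int, int]] = field(default_factory=list)
    shape: str = "rectangle"
    contrast: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in {"rectangle", "ellipse"}:
            raise ValueError(f"shape must be rectangle or ellipse, got {self.shape!r}")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if min(self.size) < 1:
            raise ValueError("object size must be >= 1 pixel")

    def positions(self, n_frames: int) -> list[tuple[int, int]]:
        """Top-left box corner per frame, by cumulative displacement."""
        out = [self.position]
        traj = list(self.trajectory) or [(0, 0)]
        for i in range(n_frames - 1):
            dx, dy = traj[min(i, len(traj) - 1)]
            x, y = out[-1]
            out.append((x + dx, y + dy))
        return out


@dataclass
class SceneSpec:
    """Full description of a synthetic scene."""

    height: int = 64
    width: int = 64
    n_frames: int = 5
    background: str = "uniform"  # uniform | gradient | textured
    background_colour: tuple[float, float, float] = (0.3, 0.3, 0.3)
    colour_cast: str = "none"  # none | underwater | monochrome
    red_cast_factor: float = 0.1  # underwater: red channel multiplier
    noise_sd: float = 0.0
    objects: list[ObjectSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if not 0.0 <= self.noise_sd <= 0.2:
            raise ValueError("noise_sd must lie in [0, 0.2]")
        if self.background not in {"uniform", "gradient", "textured"}:
            raise ValueError(f"unknown background {self.background!r}")
        if self.colour_cast not in {"none", "underwater", "monochrome"}:
            raise ValueError(f"unknown colour_cast {self.colour_cast!r}")
        if self.colour_cast == "underwater" and not 0.0 <= self.red_cast_factor <= 0.2:
            raise ValueError("red_cast_factor must lie in [0, 0.2]")


def _render_background(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    base = np.asarray(spec.background_colour, dtype=np.float64)
    if spec.background == "uniform":
        return np.broadcast_to(base, (h, w, 3)).copy()
    if spec.background == "gradient":
        ramp = np.linspace(0.0, 0.3, w)[None, :, None]
        grad = np.clip(base[None, None, :] * (1.0 - ramp) + ramp * 0.8, 0.0, 1.0)
        return np.broadcast_to(grad, (h, w, 3)).copy()
    # textured: smooth random field, frozen across frames
    field_ = rng.normal(0.0, 1.0, size=(h // 4 + 2, w // 4 + 2, 3))
    from scipy.ndimage import zoom

    tex = zoom(field_, (h / field_.shape[0], w / field_.shape[1], 1), order=1)[:h, :w]
    return np.clip(base[None, None, :] + 0.15 * tex, 0.0, 1.0)


def _object_mask(obj: ObjectSpec, x: int, y: int, h: int, w: int) -> np.ndarray:
    ow, oh = obj.size
    mask = np.zeros((h, w), dtype=bool)
    if obj.shape == "rectangle":
        mask[y : y + oh, x : x + ow] = True
    else:  # ellipse inscribed in the box
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = x + (ow - 1) / 2, y + (oh - 1) / 2
        mask = ((xx - cx) / (ow / 2)) ** 2 + ((yy - cy) / (oh / 2)) ** 2 <= 1.0
    return mask


def generate_sequence(spec: SceneSpec) -> tuple[FrameSequence, list[list[Annotation]]]:
    """Render a scene; return the sequence and per-frame ground truth.

    Deterministic given ``spec.seed``. The returned boxes are the tight
    bounds of the rendered object pixels (for rectangles, identical to
    the specified geometry). Raises ``ValueError`` if any object leaves
    the frame at any time.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    background = _render_background(spec, rng)
    bg_mean = float(background.mean())

    per_object_positions = [obj.positions(spec.n_frames) for obj in spec.objects]
    for obj, positions in zip(spec.objects, per_object_positions):
        ow, oh = obj.size
        for t, (x, y) in enumerate(positions):
            if x < 0 or y < 0 or x + ow > w or y + oh > h:
                raise ValueError(
                    f"object {obj.size} at frame {t} has box ({x},{y})-({x + ow},{y + oh}) outside {w}x{h} frame"
                )
        got = abs(float(np.mean(obj.colour)) - bg_mean)
        if got + 1e-12 < obj.contrast:
            raise ValueError(f"object contrast {got:.3f} below declared minimum {obj.contrast}")

    frames = np.empty((spec.n_frames, h, w, 3), dtype=np.float64)
    annotations: list[list[Annotation]] = []
    for t in range(spec.n_frames):
        frame = background.copy()
        boxes: list[Annotation] = []
        for k, (obj, positions) in enumerate(zip(spec.objects, per_object_positions)):
            x, y = positions[t]
            mask = _object_mask(obj, x, y, h, w)
            frame[mask] = obj.colour
            ys, xs = np.nonzero(mask)
            boxes.append(
                Annotation.from_corners(
                    class_id=k,
                    x1=float(xs.min()),
                    y1=float(ys.min()),
                    x2=float(xs.max() + 1),
                    y2=float(ys.max() + 1),
                    height=h,
                    width=w,
                    image_ref=f"frame_{t:06d}",
                )
            )
        frames[t] = frame
        annotations.append(boxes)

    if spec.colour_cast == "underwater":
        frames[..., 0] *= spec.red_cast_factor
    elif spec.colour_cast == "monochrome":
        luma = frames @ LUMA_WEIGHTS
        frames = np.repeat(luma[..., None], 3, axis=-1)

    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)

    seq = FrameSequence(
        frames=np.clip(frames, 0.0, 1.0),
        frame_index_origin=0,
        source_id=f"synthetic_seed{spec.seed}",
    )
    return seq, annotations


def render_monochrome(seq: FrameSequence) -> FrameSequence:
    """Replace each frame with its luma replicated across R, G and B.

    Emulates infrared night shots where all three channels carry the
    same signal. Idempotent: grey input is returned unchanged in value.
    """
    luma = seq.frames @ LUMA_WEIGHTS
    return FrameSequence(
        frames=np.repeat(luma[..., None], 3, axis=-1),
        frame_index_origin=seq.frame_index_origin,
        source_id=seq.source_id,
        frame_interval=seq.frame_interval,
    )


def write_fixture_dataset(
    spec: SceneSpec,
    out_dir: str | Path,
    labelled_frames: list[int] | None = None,
    splits: dict[int, str] | None = None,
    class_names: list[str] | None = None,
) -> DatasetManifest:
    """Render a scene to disk in the same layout real data uses.

    Writes the sequence as a numbered PNG folder, one YOLO label file
    per labelled frame, and a YAML manifest resolving each labelled
    image to its frame index — so the augmentation pipeline can be
    exercised end to end without any real footage.
    """
    out_dir = Path(out_dir)
    seq, anns = generate_sequence(spec)
    seq_name = "seq_000"
    write_sequence(seq, out_dir / "sequences" / seq_name)

    if labelled_frames is None:
        labelled_frames = list(range(seq.n_frames))
    labels_dir = out_dir / "labels_src"
    labels_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for t in labelled_frames:
        image_id = f"{seq_name}_f{t:06d}"
        write_annotations(anns[t], labels_dir / f"{image_id}.txt")
        entries.append(
            ManifestEntry(
                image_id=image_id,
                sequence=seq_name,
                frame_index=t,
                split=(splits or {}).get(t, "train"),
            )
        )
    if class_names is None:
        class_names = [f"object_{k}" for k in range(max(1, len(spec.objects)))]
    manifest = DatasetManifest(classes=class_names, entries=entries, sequences_root="sequences")
    manifest.save(out_dir / "manifest.yaml")
    return manifest
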