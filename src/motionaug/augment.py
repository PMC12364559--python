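"""Fold movement measures back into three-channel images.

Detectors built for still images take exactly three input layers, so
movement information has to displace or compress colour. Three
strategies are provided:

``all``
    Replace the whole image with the 3-layer movement measure.
``red``
    Replace only the red layer with a 1-layer movement measure. Under
    water the red part of the spectrum is absorbed first, so for marine
    footage this discards channels that carried little signal anyway.
``pca``
    Compress the three colour layers to two via principal component
    analysis with whitening — fitted once per dataset on pooled pixels
    from the training split — and put the movement layer in the freed
    channel (red := movement, green/blue := whitened PC scores).

Whitened PC scores are unbounded, but stored images must live in
[0, 1]; each component is therefore passed through an affine range map
fitted so that 99.5% of the sampled training scores land inside [0, 1],
then clipped. The map is part of the persisted model, so augmentation
is bit-reproducible.

Labels never change: movement augmentation recolours pixels but moves
nothing, so the box geometry of every annotation is preserved verbatim.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from motionaug.motion import (
    MotionMap,
    background_subtract_fd,
    background_subtract_knn,
    collapse_layers,
    flow_field,
    flow_to_layers,
    frame_difference_abs,
    frame_difference_dir,
)
from motionaug.sequence_io import DatasetManifest, FrameSequence, read_sequence

__all__ = [
    "PCAColorModel",
    "AugmentedImage",
    "fit_pca_color",
    "apply_pca_color",
    "augment_replace_all",
    "augment_replace_red",
    "augment_pca",
    "motion_layers_for_config",
    "augment_dataset",
]


class DegenerateVarianceError(ValueError):
    """The pooled pixel matrix has (near-)zero variance along the top component."""


@dataclass
class PCAColorModel:
    """Fitted 3 -> 2 colour compression (PCA + whitening + range map).

    ``components`` rows are the top-2 principal directions of the pooled
    ``h*w*n_t x 3`` pixel matrix, each oriented so its largest-magnitude
    coefficient is positive (eigenvector sign is otherwise arbitrary).
    ``whitening_scale[i] = 1/sqrt(var_i)`` rescales scores to unit
    variance; a component with negligible variance gets scale 0 and maps
    to the constant 0.5. ``range_lo``/``range_hi`` are the 0.25th and
    99.75th percentiles of the whitened training scores; the stored
    layer is ``clip((score - lo) / (hi - lo))``.
    """

    mean: np.ndarray  # (3,)
    components: np.ndarray  # (2, 3)
    whitening_scale: np.ndarray  # (2,)
    range_lo: np.ndarray  # (2,)
    range_hi: np.ndarray  # (2,)
    n_images_sampled: int
    seed: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64).reshape(3)
        self.components = np.asarray(self.components, dtype=np.float64).reshape(2, 3)
        self.whitening_scale = np.asarray(self.whitening_scale, dtype=np.float64).reshape(2)
        self.range_lo = np.asarray(self.range_lo, dtype=np.float64).reshape(2)
        self.range_hi = np.asarray(self.range_hi, dtype=np.float64).reshape(2)

    def whiten(self, pixels: np.ndarray) -> np.ndarray:
        """Centred, projected, whitened scores for an (..., 3) array."""
        return ((pixels - self.mean) @ self.components.T) * self.whitening_scale

    def range_map(self, scores: np.ndarray) -> np.ndarray:
        span = self.range_hi - self.range_lo
        out = np.empty_like(scores)
        for i in range(2):
            if span[i] > 1e-12:
                out[..., i] = (scores[..., i] - self.range_lo[i]) / span[i]
            else:
                out[..., i] = 0.5
        return np.clip(out, 0.0, 1.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "components": self.components.tolist(),
                "whitening_scale": self.whitening_scale.tolist(),
                "range_lo": self.range_lo.tolist(),
                "range_hi": self.range_hi.tolist(),
                "n_images_sampled": self.n_images_sampled,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "PCAColorModel":
        d = json.loads(text)
        return PCAColorModel(
            mean=d["mean"],
            components=d["components"],
            whitening_scale=d["whitening_scale"],
            range_lo=d["range_lo"],
            range_hi=d["range_hi"],
            n_images_sampled=d["n_images_sampled"],
            seed=d["seed"],
        )


@dataclass
class AugmentedImage:
    """A 3-layer image combining colour and movement, with provenance."""

    values: np.ndarray
    mode: str  # all | red | pca
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[-1] != 3:
            raise ValueError(f"augmented image must be (h, w, 3), got {self.values.shape}")


def fit_pca_color(
    train_frames: Sequence[np.ndarray],
    n_t: int | None = None,
    seed: int = 0,
) -> PCAColorModel:
    """Fit the per-dataset colour compression on training frames only.

    ``n_t`` frames are sampled without replacement (default: all frames,
    capped at 500); their pixels are pooled into one ``N x 3`` matrix
    and the top-2 principal directions extracted with whitening.
    Deterministic given ``seed``. Raises
    :class:`DegenerateVarianceError` when pixels are (near-)constant.
    """
    from sklearn.decomposition import PCA

    frames = list(train_frames)
    if not frames:
        raise ValueError("need at least one training frame")
    if n_t is None:
        n_t = min(len(frames), 500)
    n_t = min(n_t, len(frames))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(frames), size=n_t, replace=False))
    pixels = np.concatenate([np.asarray(frames[i], dtype=np.float64).reshape(-1, 3) for i in chosen])

    total_var = float(pixels.var(axis=0, ddof=1).sum())
    if total_var < 1e-12:
        raise DegenerateVarianceError("pooled pixels are constant; PCA is undefined")

    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(pixels)
    components = pca.components_.copy()
    variances = pca.explained_variance_.copy()
    if variances[0] < 1e-12 * total_var:
        raise DegenerateVarianceError("top principal component has negligible variance")

    # deterministic sign: largest-|coefficient| entry positive
    for i in range(2):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0

    scale = np.where(variances > 1e-12 * total_var, 1.0 / np.sqrt(np.maximum(variances, 1e-300)), 0.0)
    scores = ((pixels - pca.mean_) @ components.T) * scale
    lo = np.percentile(scores, 0.25, axis=0)
    hi = np.percentile(scores, 99.75, axis=0)
    return PCAColorModel(
        mean=pca.mean_,
        components=components,
        whitening_scale=scale,
        range_lo=lo,
        range_hi=hi,
        n_images_sampled=n_t,
        seed=seed,
    )


def apply_pca_color(model: PCAColorModel, frame: np.ndarray) -> np.ndarray:
    """Compress an (h, w, 3) frame to the (h, w, 2) stored PC layers."""
    frame = np.asarray(frame, dtype=np.float64)
    return model.range_map(model.whiten(frame))


# ---------------------------------------------------------------------------
# channel assembly


def _check_shapes(frame: np.ndarray, motion: MotionMap, want_layers: int) -> None:
    if motion.n_layers != want_layers:
        raise ValueError(f"need a {want_layers}-layer motion map, got {motion.n_layers}")
    if motion.values.shape[:2] != frame.shape[:2]:
        raise ValueError(f"shape mismatch: frame {frame.shape[:2]} vs motion {motion.values.shape[:2]}")


def augment_replace_all(frame: np.ndarray, motion3: MotionMap) -> AugmentedImage:
    """Use the 3-layer movement measure as the whole image."""
    frame = np.asarray(frame, dtype=np.float64)
    _check_shapes(frame, motion3, 3)
    return AugmentedImage(
        values=motion3.values.copy(),
        mode="all",
        provenance={"method": motion3.method, "params": motion3.params},
    )


def augment_replace_red(frame: np.ndarray, motion1: MotionMap) -> AugmentedImage:
    """Movement into the red layer; green and blue pass through untouched."""
    frame = np.asarray(frame, dtype=np.float64)
    _check_shapes(frame, motion1, 1)
    out = frame.copy()
    out[..., 0] = motion1.values
    return AugmentedImage(
        values=out,
        mode="red",
        provenance={"method": motion1.method, "params": motion1.params},
    )


def augment_pca(frame: np.ndarray, motion1: MotionMap, model: PCAColorModel) -> AugmentedImage:
    """Red := movement; green/blue := the two whitened PC colour layers."""
    if not isinstance(model, PCAColorModel):
        raise ValueError("augment_pca requires a fitted PCAColorModel")
    frame = np.asarray(frame, dtype=np.float64)
    _check_shapes(frame, motion1, 1)
    pc = apply_pca_color(model, frame)
    out = np.empty_like(frame)
    out[..., 0] = motion1.values
    out[..., 1] = pc[..., 0]
    out[..., 2] = pc[..., 1]
    return AugmentedImage(
        values=out,
        mode="pca",
        provenance={"method": motion1.method, "params": motion1.params, "pca_seed": model.seed},
    )


# ---------------------------------------------------------------------------
# dataset-level pipeline


def motion_layers_for_config(seq: FrameSequence, t: int, config) -> MotionMap:
    """Compute the motion map a config calls for, in the layer count its mode needs.

    ``mode='all'`` needs 3 layers (flow is HSV-encoded, the KNN mask is
    replicated); ``'red'``/``'pca'`` need 1 layer (frame-differencing
    maps are collapsed by averaging, flow keeps magnitude only, the KNN
    mask is used as-is).
    """
    method = config.method
    want3 = config.mode == "all"
    if method == "fd":
        fn = frame_difference_abs if config.approach == "fd_a" else frame_difference_dir
        m = fn(seq, t, dt=config.dt, upsilon=config.upsilon)
        return m if want3 else collapse_layers(m)
    if method == "bs_fd":
        m = background_subtract_fd(seq, t, n_b=config.n_b, dt_b=config.dt_b, upsilon=config.upsilon)
        return m if want3 else collapse_layers(m)
    if method == "bs_knn":
        m = background_subtract_knn(seq, t)
        if want3:
            return MotionMap(values=np.repeat(m.values[..., None], 3, axis=-1), method=m.method, params=m.params)
        return m
    if method == "flow":
        fl = flow_field(seq, t, dt=config.dt, estimator=config.estimator or "block_match")
        return flow_to_layers(fl, mode="hsv3" if want3 else "magnitude1")
    raise ValueError(f"unknown motion method {method!r}")


def _boundary_hits(seq: FrameSequence, t: int, config) -> int:
    lo, hi = seq.frame_index_origin, seq.last_index
    needed: list[int] = []
    if config.method == "fd":
        needed = [t - config.dt, t + config.dt]
    elif config.method == "bs_fd":
        needed = [t - i * config.dt_b for i in range(1, config.n_b + 1)]
    elif config.method == "flow":
        needed = [t + config.dt]
    elif config.method == "bs_knn":
        return 0  # buffer shrinks rather than clamps
    return sum(1 for i in needed if i < lo or i > hi)


def augment_dataset(
    manifest: DatasetManifest,
    config,
    data_root: str | Path,
    out_dir: str | Path,
    strict: bool = False,
) -> dict:
    """Produce a movement-augmented copy of a labelled dataset.

    For every manifest entry the surrounding sequence is loaded, the
    configured movement measure computed at the labelled frame, and the
    augmented image written under ``out_dir/images/<split>/``; the label
    file is byte-copied to ``out_dir/labels/<split>/`` (augmentation
    never moves boxes). ``config.method='raw'`` copies the source frame
    verbatim. A ``pca`` mode fits the colour model on train-split frames
    only and persists it as JSON next to the images.

    Returns a summary dict; a JSON-lines run log at
    ``out_dir/runlog.jsonl`` records the config, the PCA fit audit and
    per-image boundary-policy hits. With ``strict=False`` per-image
    failures are collected and reported; ``strict=True`` re-raises.
    """
    data_root = Path(data_root)
    out_dir = Path(out_dir)
    seq_root = data_root / manifest.sequences_root
    labels_root = data_root / manifest.labels_root

    sequences: dict[str, FrameSequence] = {}

    def get_seq(name: str) -> FrameSequence:
        if name not in sequences:
            sequences[name] = read_sequence(seq_root / name)
        return sequences[name]

    log_records: list[dict] = [{"event": "config", "config": config.to_dict(), "seed": config.seed}]

    model: PCAColorModel | None = None
    if config.mode == "pca":
        train_entries = manifest.by_split("train")
        if not train_entries:
            raise ValueError("pca mode needs at least one train-split image to fit the colour model")
        train_frames = [get_seq(e.sequence).frame(e.frame_index, "strict") for e in train_entries]
        model = fit_pca_color(train_frames, seed=config.seed)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "pca_model.json").write_text(model.to_json())
        log_records.append(
            {
                "event": "pca_fit",
                "images": [e.image_id for e in train_entries],
                "splits": sorted({e.split for e in train_entries}),
                "n_images_sampled": model.n_images_sampled,
            }
        )

    errors: list[dict] = []
    n_written = 0
    for entry in manifest.entries:
        img_out = out_dir / "images" / entry.split / f"{entry.image_id}.png"
        lbl_out = out_dir / "labels" / entry.split / f"{entry.image_id}.txt"
        img_out.parent.mkdir(parents=True, exist_ok=True)
        lbl_out.parent.mkdir(parents=True, exist_ok=True)
        try:
            seq = get_seq(entry.sequence)
            t = entry.frame_index
            frame = seq.frame(t, "strict")
            if config.method == "raw":
                src = seq_root / entry.sequence / f"frame_{t:06d}.png"
                if src.exists():
                    shutil.copyfile(src, img_out)  # byte-identical copy
                else:
                    _write_png(img_out, frame)
                hits = 0
            else:
                motion = motion_layers_for_config(seq, t, config)
                if config.mode == "all":
                    aug = augment_replace_all(frame, motion)
                elif config.mode == "red":
                    aug = augment_replace_red(frame, motion)
                else:
                    aug = augment_pca(frame, motion, model)
                _write_png(img_out, aug.values)
                hits = _boundary_hits(seq, t, config)
            shutil.copyfile(labels_root / f"{entry.image_id}.txt", lbl_out)
            log_records.append(
                {"event": "image", "image_id": entry.image_id, "split": entry.split, "boundary_hits": hits}
            )
            n_written += 1
        except Exception as exc:
            if strict:
                raise
            errors.append({"image_id": entry.image_id, "error": str(exc)})
            log_records.append({"event": "error", "image_id": entry.image_id, "error": str(exc)})

    _write_dataset_yaml(out_dir, manifest.classes)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "runlog.jsonl", "w") as fh:
        for rec in log_records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return {"n_written": n_written, "errors": errors, "out_dir": str(out_dir)}


def _write_png(path: Path, values: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.round(np.clip(values, 0.0, 1.0) * 255).astype(np.uint8))


def _write_dataset_yaml(out_dir: Path, classes: Sequence[str]) -> None:
    import yaml

    data = {
        "path": ".",
        "train": "images/train",
        "val": "images/val",
        "test": "images/test",
        "names": {i: c for i, c in enumerate(classes)},
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "dataset.yaml").write_text(yaml.safe_dump(data, sort_keys=False))
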