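r"""Per-frame movement measures.

All measures read from a :class:`~motionaug.sequence_io.FrameSequence`
and return a :class:`MotionMap` whose values live in ``[0, 1]`` so they
can stand in directly for colour channels.

Three-frame differencing
    The absolute form averages the frame of interest's deviation from
    both temporal neighbours::

        FD_a = clip(v * 1/2 (|F_t - F_{t-dt}| + |F_t - F_{t+dt}|))

    The directional form keeps the sign of the change, centred at 0.5 so
    that values above 0.5 mean a channel is increasing from the left
    neighbour and below 0.5 decreasing::

        FD_d = clip(1/2 + v/4 [(F_t - F_{t-dt}) + (F_{t+dt} - F_{t-dt})])

    ``v`` (upsilon) amplifies weak motion signals; results are truncated
    to the normalised colour range after scaling.

Background subtraction
    A background estimate F_b is the pixelwise mean of ``n_b`` historic
    frames spaced ``dt_b`` apart, which averages transient foreground
    out; movement is the signed distance from it, again centred::

        F_b   = 1/n_b sum_{i=1..n_b} F_{t - i dt_b}
        BS_FD = clip(1/2 + v/2 (F_t - F_b))

    A simplified per-pixel K-nearest-neighbour classifier is also
    provided: a pixel is foreground when the majority of its k nearest
    RGB samples in its own history buffer lie beyond a distance
    threshold. This deliberately omits spatial neighbourhoods and
    foreground resampling used by full production implementations.

Optical flow
    A dense displacement field between frames ``t`` and ``t + dt``
    (forward by default), decomposed into magnitude ``r = sqrt(vx^2 +
    vy^2)`` and direction ``theta = atan2(vy, vx) in [0, 2pi)``.
    Estimation is pluggable: ``block_match`` is a built-in exhaustive
    SSD block search on a coarse grid, bilinearly upsampled — slow but
    dependency-free and exactly specified; ``farneback`` delegates to
    OpenCV when that library is importable.

Boundary policy: the first/last ``dt`` frames of a sequence lack a
neighbour, and early frames lack background history. The default
``clamp`` policy substitutes the nearest existing frame so every
labelled frame can be augmented; ``strict`` raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from motionaug.sequence_io import FrameSequence

__all__ = [
    "MotionMap",
    "FlowField",
    "EstimatorUnavailableError",
    "frame_difference_abs",
    "frame_difference_dir",
    "background_frame",
    "background_subtract_fd",
    "background_subtract_knn",
    "flow_field",
    "flow_to_layers",
    "collapse_layers",
]


class EstimatorUnavailableError(RuntimeError):
    """The requested optical-flow estimator cannot run in this environment."""


@dataclass
class MotionMap:
    """A per-pixel movement measure with its provenance.

    ``values`` has shape ``(h, w)`` or ``(h, w, 3)``, clipped to [0, 1].
    ``method`` is one of ``fd_a, fd_d, bs_fd, bs_knn, flow``; ``params``
    records the tuple that produced it (dt, upsilon, n_b, dt_b,
    estimator) so augmented images are fully reproducible.
    """

    values: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3) or (self.values.ndim == 3 and self.values.shape[-1] != 3):
            raise ValueError(f"motion map must be (h,w) or (h,w,3), got {self.values.shape}")
        if self.values.size and (self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12):
            raise ValueError("motion map values must lie in [0, 1]")

    @property
    def n_layers(self) -> int:
        return 1 if self.values.ndim == 2 else 3

    def save(self, path: str | Path) -> None:
        """Persist as PNG plus a JSON sidecar recording method and params.

        Single-layer maps are stored as 16-bit greyscale; 3-layer maps
        as 8-bit RGB (the PNG encoder has no 16-bit RGB mode). The
        sidecar records the bit depth so quantization is explicit.
        """
        import imageio.v3 as iio
        import json

        path = Path(path)
        if self.n_layers == 1:
            bit_depth = 16
            iio.imwrite(path, np.round(self.values * 65535).astype(np.uint16))
        else:
            bit_depth = 8
            iio.imwrite(path, np.round(self.values * 255).astype(np.uint8))
        sidecar = {
            "method": self.method,
            "params": self.params,
            "n_layers": self.n_layers,
            "bit_depth": bit_depth,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


@dataclass
class FlowField:
    """Dense displacement field (pixels per dt frames)."""

    vx: np.ndarray
    vy: np.ndarray
    dt: int = 1
    estimator: str = "block_match"

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=np.float64)
        self.vy = np.asarray(self.vy, dtype=np.float64)
        if self.vx.shape != self.vy.shape or self.vx.ndim != 2:
            raise ValueError("vx and vy must be matching 2-D arrays")

    @property
    def r(self) -> np.ndarray:
        """Flow magnitude, >= 0."""
        return np.hypot(self.vx, self.vy)

    @property
    def theta(self) -> np.ndarray:
        """Flow direction in [0, 2pi), measured from +x towards +y."""
        return np.mod(np.arctan2(self.vy, self.vx), 2 * np.pi)


# ---------------------------------------------------------------------------
# frame differencing


def frame_difference_abs(
    seq: FrameSequence, t: int, dt: int, upsilon: float = 1.0, boundary: str = "clamp"
) -> MotionMap:
    """Three-frame absolute difference, scaled by upsilon and truncated."""
    _check_params(dt, upsilon)
    f_t = seq.frame(t, boundary)
    f_prev = seq.frame(t - dt, boundary)
    f_next = seq.frame(t + dt, boundary)
    values = upsilon * 0.5 * (np.abs(f_t - f_prev) + np.abs(f_t - f_next))
    return MotionMap(
        values=np.clip(values, 0.0, 1.0),
        method="fd_a",
        params={"dt": dt, "upsilon": upsilon, "t": t, "boundary": boundary},
    )


def frame_difference_dir(
    seq: FrameSequence, t: int, dt: int, upsilon: float = 1.0, boundary: str = "clamp"
) -> MotionMap:
    """Three-frame directional difference centred at 0.5.

    Values above 0.5 mark a channel increasing from frame t-dt (through
    t to t+dt), below 0.5 decreasing; 0.5 exactly means no change.
    """
    _check_params(dt, upsilon)
    f_t = seq.frame(t, boundary)
    f_prev = seq.frame(t - dt, boundary)
    f_next = seq.frame(t + dt, boundary)
    values = 0.5 + (upsilon / 4.0) * ((f_t - f_prev) + (f_next - f_prev))
    return MotionMap(
        values=np.clip(values, 0.0, 1.0),
        method="fd_d",
        params={"dt": dt, "upsilon": upsilon, "t": t, "boundary": boundary},
    )


def _check_params(dt: int, upsilon: float) -> None:
    if dt < 1:
        raise ValueError(f"dt must be >= 1 frame, got {dt}")
    if upsilon < 0:
        raise ValueError(f"upsilon must be >= 0, got {upsilon}")


# ---------------------------------------------------------------------------
# background subtraction


def background_frame(seq: FrameSequence, t: int, n_b: int, dt_b: int, boundary: str = "clamp") -> np.ndarray:
    """Mean of the n_b frames at t - i*dt_b (i = 1..n_b).

    Averaging historic frames suppresses transient foreground objects,
    leaving an estimate of the static background. Under ``strict``
    boundary policy an error reports how many frames are available.
    """
    if n_b < 1:
        raise ValueError(f"n_b must be >= 1, got {n_b}")
    if dt_b < 1:
        raise ValueError(f"dt_b must be >= 1, got {dt_b}")
    if boundary == "strict":
        earliest = t - n_b * dt_b
        if earliest < seq.frame_index_origin:
            avail = (t - seq.frame_index_origin) // dt_b
            raise ValueError(
                f"background needs {n_b} frames spaced {dt_b} before frame {t}; only {avail} available"
            )
    acc = np.zeros_like(seq.frame(t, "clamp"))
    for i in range(1, n_b + 1):
        acc += seq.frame(t - i * dt_b, boundary)
    return acc / n_b


def background_subtract_fd(
    seq: FrameSequence, t: int, n_b: int, dt_b: int, upsilon: float = 1.0, boundary: str = "clamp"
) -> MotionMap:
    """Signed distance from the averaged background, centred at 0.5."""
    if upsilon < 0:
        raise ValueError(f"upsilon must be >= 0, got {upsilon}")
    f_b = background_frame(seq, t, n_b, dt_b, boundary)
    values = 0.5 + (upsilon / 2.0) * (seq.frame(t, boundary) - f_b)
    return MotionMap(
        values=np.clip(values, 0.0, 1.0),
        method="bs_fd",
        params={"n_b": n_b, "dt_b": dt_b, "upsilon": upsilon, "t": t, "boundary": boundary},
    )


def background_subtract_knn(
    seq: FrameSequence,
    t: int,
    history: int = 50,
    k: int = 3,
    dist_threshold: float = 0.08,
    boundary: str = "clamp",
) -> MotionMap:
    """Per-pixel KNN foreground mask (binary, single layer).

    Each pixel keeps a buffer of its own values over the ``history``
    frames preceding t. The pixel is classed foreground (1) when the
    majority of its k nearest samples — Euclidean distance in RGB — lie
    farther than ``dist_threshold``. Under ``clamp`` the buffer shrinks
    to the frames actually available; ``strict`` raises if fewer than
    ``history`` frames precede t.
    """
    if history < 1 or k < 1:
        raise ValueError("history and k must be >= 1")
    if dist_threshold < 0:
        raise ValueError("dist_threshold must be >= 0")
    available = t - seq.frame_index_origin
    if available < history:
        if boundary == "strict" or available < 1:
            raise ValueError(f"KNN needs {history} frames before frame {t}; only {available} available")
        history = available
    k = min(k, history)

    current = seq.frame(t, boundary)  # (h, w, 3)
    buffer = np.stack([seq.frame(t - i, boundary) for i in range(1, history + 1)])  # (n, h, w, 3)
    dists = np.sqrt(np.sum((buffer - current[None]) ** 2, axis=-1))  # (n, h, w)
    nearest = np.sort(dists, axis=0)[:k]  # k smallest per pixel
    n_far = np.sum(nearest > dist_threshold, axis=0)
    mask = (n_far * 2 > k).astype(np.float64)
    return MotionMap(
        values=mask,
        method="bs_knn",
        params={"history": history, "k": k, "dist_threshold": dist_threshold, "t": t, "boundary": boundary},
    )


# ---------------------------------------------------------------------------
# optical flow


def _luma(frame: np.ndarray) -> np.ndarray:
    return frame @ np.array([0.299, 0.587, 0.114])


def _block_match(
    prev: np.ndarray,
    nxt: np.ndarray,
    radius: int = 4,
    block_radius: int = 3,
    grid_step: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive SSD block matching on a coarse grid, upsampled.

    For each grid point the patch of half-width ``block_radius`` around
    it in ``prev`` is compared (mean squared difference over the valid
    overlap) against every integer displacement within ``radius`` in
    ``nxt``; ties prefer the smaller displacement, so static input
    yields exactly zero flow. The sparse field is then bilinearly
    interpolated to full resolution.
    """
    from scipy.interpolate import RegularGridInterpolator

    h, w = prev.shape
    gy = np.arange(grid_step // 2, h, grid_step)
    gx = np.arange(grid_step // 2, w, grid_step)
    vx_grid = np.zeros((len(gy), len(gx)))
    vy_grid = np.zeros((len(gy), len(gx)))

    # candidate displacements ordered by magnitude, zero first (tie-break)
    cand = [(dy, dx) for dy in range(-radius, radius + 1) for dx in range(-radius, radius + 1)]
    cand.sort(key=lambda d: (d[0] ** 2 + d[1] ** 2, d))

    for iy, cy in enumerate(gy):
        y0, y1 = max(cy - block_radius, 0), min(cy + block_radius + 1, h)
        for ix, cx in enumerate(gx):
            x0, x1 = max(cx - block_radius, 0), min(cx + block_radius + 1, w)
            patch = prev[y0:y1, x0:x1]
            best_cost, best = np.inf, (0, 0)
            for dy, dx in cand:
                ty0, ty1 = y0 + dy, y1 + dy
                tx0, tx1 = x0 + dx, x1 + dx
                # shrink to the overlap valid in both frames
                oy0, oy1 = max(ty0, 0) - dy, min(ty1, h) - dy
                ox0, ox1 = max(tx0, 0) - dx, min(tx1, w) - dx
                if oy1 - oy0 < 2 or ox1 - ox0 < 2:
                    continue
                a = prev[oy0:oy1, ox0:ox1]
                b = nxt[oy0 + dy : oy1 + dy, ox0 + dx : ox1 + dx]
                cost = np.mean((a - b) ** 2)
                if cost < best_cost - 1e-15:  # strict improvement keeps the tie-break
                    best_cost, best = cost, (dy, dx)
            vy_grid[iy, ix], vx_grid[iy, ix] = best

    if len(gy) == 1 or len(gx) == 1:  # degenerate grid: constant fill
        return (np.full((h, w), vx_grid.flat[0]), np.full((h, w), vy_grid.flat[0]))
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.column_stack(
        [np.clip(yy.ravel(), gy[0], gy[-1]), np.clip(xx.ravel(), gx[0], gx[-1])]
    )
    vx = RegularGridInterpolator((gy, gx), vx_grid)(pts).reshape(h, w)
    vy = RegularGridInterpolator((gy, gx), vy_grid)(pts).reshape(h, w)
    return vx, vy


def _farneback(prev: np.ndarray, nxt: np.ndarray, **kwargs) -> tuple[np.ndarray, np.ndarray]:
    try:
        import cv2
    except ImportError as exc:
        raise EstimatorUnavailableError(
            "the 'farneback' estimator requires OpenCV (cv2), which is not importable; "
            "use estimator='block_match' instead"
        ) from exc
    flow = cv2.calcOpticalFlowFarneback(
        (prev * 255).astype(np.uint8),
        (nxt * 255).astype(np.uint8),
        None,
        pyr_scale=kwargs.get("pyr_scale", 0.5),
        levels=kwargs.get("levels", 3),
        winsize=kwargs.get("winsize", 15),
        iterations=kwargs.get("iterations", 3),
        poly_n=kwargs.get("poly_n", 5),
        poly_sigma=kwargs.get("poly_sigma", 1.2),
        flags=0,
    )
    return flow[..., 0].astype(np.float64), flow[..., 1].astype(np.float64)


_ESTIMATORS: dict[str, Callable] = {"block_match": _block_match, "farneback": _farneback}


def flow_field(
    seq: FrameSequence,
    t: int,
    dt: int = 1,
    estimator: str = "block_match",
    direction: str = "forward",
    boundary: str = "clamp",
    **estimator_kwargs,
) -> FlowField:
    """Dense optical flow between frame t and its dt-neighbour.

    ``direction='forward'`` compares t -> t+dt (default), ``'backward'``
    t-dt -> t. Matching runs on luma.
    """
    if dt < 1:
        raise ValueError(f"dt must be >= 1, got {dt}")
    if estimator not in _ESTIMATORS:
        raise EstimatorUnavailableError(f"unknown estimator {estimator!r}; available: {sorted(_ESTIMATORS)}")
    if direction == "forward":
        a, b = seq.frame(t, boundary), seq.frame(t + dt, boundary)
    elif direction == "backward":
        a, b = seq.frame(t - dt, boundary), seq.frame(t, boundary)
    else:
        raise ValueError(f"direction must be forward or backward, got {direction!r}")
    vx, vy = _ESTIMATORS[estimator](_luma(a), _luma(b), **estimator_kwargs)
    return FlowField(vx=vx, vy=vy, dt=dt, estimator=estimator)


def flow_to_layers(flow: FlowField, mode: str = "magnitude1", r_max: float | None = None) -> MotionMap:
    """Encode a flow field as colour-range layers.

    ``magnitude1``: one layer, clip(r / r_max). ``hsv3``: direction as
    hue, clip(r / r_max) as value, full saturation, converted to RGB —
    so still pixels are black whatever their (undefined) direction.
    ``r_max`` defaults to the 99th percentile of r over the frame, which
    resists single-pixel outliers; a frame with no flow maps to zeros.
    """
    r = flow.r
    if r_max is None:
        r_max = float(np.percentile(r, 99.0))
    elif r_max <= 0:
        raise ValueError(f"r_max must be > 0, got {r_max}")
    scaled = np.clip(r / r_max, 0.0, 1.0) if r_max > 1e-12 else np.zeros_like(r)
    if mode == "magnitude1":
        values = scaled
    elif mode == "hsv3":
        from skimage.color import hsv2rgb

        hsv = np.stack([flow.theta / (2 * np.pi), np.ones_like(scaled), scaled], axis=-1)
        values = np.clip(hsv2rgb(hsv), 0.0, 1.0)
    else:
        raise ValueError(f"mode must be magnitude1 or hsv3, got {mode!r}")
    return MotionMap(
        values=values,
        method="flow",
        params={"dt": flow.dt, "estimator": flow.estimator, "mode": mode, "r_max": r_max},
    )


def collapse_layers(m: MotionMap) -> MotionMap:
    """Average a 3-layer map into one layer (range is preserved)."""
    if m.n_layers != 3:
        raise ValueError(f"collapse_layers requires a 3-layer map, got {m.n_layers}")
    return MotionMap(values=m.values.mean(axis=-1), method=m.method, params={**m.params, "collapsed": True})
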