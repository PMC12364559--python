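"""Independent reference implementations used to check the package.

Everything here is written as plain scalar loops (or from-scratch
re-computation per cutoff for the PR curve), deliberately sharing no
code with the package, so that agreement is evidence of correctness
rather than of shared bugs.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# motion measures: per-pixel/per-channel scalar loops


def fd_abs_loop(frames: np.ndarray, t: int, dt: int, upsilon: float) -> np.ndarray:
    n, h, w, _ = frames.shape
    clamp = lambda i: min(max(i, 0), n - 1)
    out = np.zeros((h, w, 3))
    for y in range(h):
        for x in range(w):
            for c in range(3):
                a = frames[clamp(t - dt), y, x, c]
                b = frames[clamp(t), y, x, c]
                d = frames[clamp(t + dt), y, x, c]
                v = upsilon * 0.5 * (abs(b - a) + abs(b - d))
                out[y, x, c] = min(max(v, 0.0), 1.0)
    return out


def fd_dir_loop(frames: np.ndarray, t: int, dt: int, upsilon: float) -> np.ndarray:
    n, h, w, _ = frames.shape
    clamp = lambda i: min(max(i, 0), n - 1)
    out = np.zeros((h, w, 3))
    for y in range(h):
        for x in range(w):
            for c in range(3):
                a = frames[clamp(t - dt), y, x, c]
                b = frames[clamp(t), y, x, c]
                d = frames[clamp(t + dt), y, x, c]
                v = 0.5 + (upsilon / 4.0) * ((b - a) + (d - a))
                out[y, x, c] = min(max(v, 0.0), 1.0)
    return out


def background_frame_loop(frames: np.ndarray, t: int, n_b: int, dt_b: int) -> np.ndarray:
    n, h, w, _ = frames.shape
    clamp = lambda i: min(max(i, 0), n - 1)
    out = np.zeros((h, w, 3))
    for y in range(h):
        for x in range(w):
            for c in range(3):
                s = 0.0
                for i in range(1, n_b + 1):
                    s += frames[clamp(t - i * dt_b), y, x, c]
                out[y, x, c] = s / n_b
    return out


def bs_fd_loop(frames: np.ndarray, t: int, n_b: int, dt_b: int, upsilon: float) -> np.ndarray:
    n, h, w, _ = frames.shape
    clamp = lambda i: min(max(i, 0), n - 1)
    fb = background_frame_loop(frames, t, n_b, dt_b)
    out = np.zeros((h, w, 3))
    for y in range(h):
        for x in range(w):
            for c in range(3):
                v = 0.5 + (upsilon / 2.0) * (frames[clamp(t), y, x, c] - fb[y, x, c])
                out[y, x, c] = min(max(v, 0.0), 1.0)
    return out


def knn_loop(frames: np.ndarray, t: int, history: int, k: int, dist_threshold: float) -> np.ndarray:
    n, h, w, _ = frames.shape
    history = min(history, t)
    k = min(k, history)
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            dists = []
            for i in range(1, history + 1):
                d = math.sqrt(sum((frames[t - i, y, x, c] - frames[t, y, x, c]) ** 2 for c in range(3)))
                dists.append(d)
            dists.sort()
            far = sum(1 for d in dists[:k] if d > dist_threshold)
            out[y, x] = 1.0 if far * 2 > k else 0.0
    return out


def luma_loop(frame: np.ndarray) -> np.ndarray:
    h, w, _ = frame.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            out[y, x] = 0.299 * frame[y, x, 0] + 0.587 * frame[y, x, 1] + 0.114 * frame[y, x, 2]
    return out


def block_match_loop(
    prev: np.ndarray, nxt: np.ndarray, radius: int, block_radius: int, grid_step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar re-derivation of the exhaustive SSD block matcher."""
    h, w = prev.shape
    gy = list(range(grid_step // 2, h, grid_step))
    gx = list(range(grid_step // 2, w, grid_step))
    vxg = [[0.0] * len(gx) for _ in gy]
    vyg = [[0.0] * len(gx) for _ in gy]
    cand = sorted(
        ((dy, dx) for dy in range(-radius, radius + 1) for dx in range(-radius, radius + 1)),
        key=lambda d: (d[0] ** 2 + d[1] ** 2, d),
    )
    for iy, cy in enumerate(gy):
        for ix, cx in enumerate(gx):
            y0, y1 = max(cy - block_radius, 0), min(cy + block_radius + 1, h)
            x0, x1 = max(cx - block_radius, 0), min(cx + block_radius + 1, w)
            best_cost, best = float("inf"), (0, 0)
            for dy, dx in cand:
                oy0 = max(y0 + dy, 0) - dy
                oy1 = min(y1 + dy, h) - dy
                ox0 = max(x0 + dx, 0) - dx
                ox1 = min(x1 + dx, w) - dx
                if oy1 - oy0 < 2 or ox1 - ox0 < 2:
                    continue
                s, cnt = 0.0, 0
                for yy in range(oy0, oy1):
                    for xx in range(ox0, ox1):
                        diff = prev[yy, xx] - nxt[yy + dy, xx + dx]
                        s += diff * diff
                        cnt += 1
                cost = s / cnt
                if cost < best_cost - 1e-15:
                    best_cost, best = cost, (dy, dx)
            vyg[iy][ix], vxg[iy][ix] = best

    def interp(grid_vals):
        out = np.zeros((h, w))
        for y in range(h):
            for x in range(w):
                fy = min(max(y, gy[0]), gy[-1])
                fx = min(max(x, gx[0]), gx[-1])
                # locate cell
                j = min(int((fy - gy[0]) / grid_step), len(gy) - 2) if len(gy) > 1 else 0
                i = min(int((fx - gx[0]) / grid_step), len(gx) - 2) if len(gx) > 1 else 0
                if len(gy) == 1 and len(gx) == 1:
                    out[y, x] = grid_vals[0][0]
                    continue
                if len(gy) == 1:
                    t = (fx - gx[i]) / (gx[i + 1] - gx[i])
                    out[y, x] = (1 - t) * grid_vals[0][i] + t * grid_vals[0][i + 1]
                    continue
                if len(gx) == 1:
                    u = (fy - gy[j]) / (gy[j + 1] - gy[j])
                    out[y, x] = (1 - u) * grid_vals[j][0] + u * grid_vals[j + 1][0]
                    continue
                u = (fy - gy[j]) / (gy[j + 1] - gy[j])
                t = (fx - gx[i]) / (gx[i + 1] - gx[i])
                out[y, x] = (
                    (1 - u) * (1 - t) * grid_vals[j][i]
                    + (1 - u) * t * grid_vals[j][i + 1]
                    + u * (1 - t) * grid_vals[j + 1][i]
                    + u * t * grid_vals[j + 1][i + 1]
                )
        return out

    if len(gy) == 1 or len(gx) == 1:
        return (np.full((h, w), vxg[0][0]), np.full((h, w), vyg[0][0]))
    return interp(vxg), interp(vyg)


def collapse_loop(values: np.ndarray) -> np.ndarray:
    h, w, _ = values.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            out[y, x] = (values[y, x, 0] + values[y, x, 1] + values[y, x, 2]) / 3.0
    return out


# ---------------------------------------------------------------------------
# PCA application: per-pixel loop


def pca_apply_loop(model, frame: np.ndarray) -> np.ndarray:
    h, w, _ = frame.shape
    out = np.zeros((h, w, 2))
    for y in range(h):
        for x in range(w):
            for i in range(2):
                s = 0.0
                for c in range(3):
                    s += (frame[y, x, c] - model.mean[c]) * model.components[i, c]
                s *= model.whitening_scale[i]
                span = model.range_hi[i] - model.range_lo[i]
                v = (s - model.range_lo[i]) / span if span > 1e-12 else 0.5
                out[y, x, i] = min(max(v, 0.0), 1.0)
    return out


# ---------------------------------------------------------------------------
# evaluation: exhaustive brute-force AP / mAP


def _iou_loop(a, b) -> float:
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    inter = iw * ih if (iw > 0 and ih > 0) else 0.0
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def _greedy_flags(dets, gts, thresh):
    """dets: [(score, image_ref, box)] in canonical order; gts: [(image_ref, box)]."""
    taken = set()
    flags = []
    for _, ref, box in dets:
        best_iou, best_j = 0.0, -1
        for j, (gref, gbox) in enumerate(gts):
            if gref != ref or j in taken:
                continue
            v = _iou_loop(box, gbox)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= thresh:
            taken.add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return flags


def ap_bruteforce(dets, gts, thresh) -> float:
    """AP by recomputing precision/recall from scratch at every cutoff.

    ``dets``: list of (score, image_ref, box); ``gts``: list of
    (image_ref, box) for a single class. All-point interpolation:
    sum over recall increments of the max precision at or beyond them.
    """
    n_gt = len(gts)
    order = sorted(range(len(dets)), key=lambda i: -dets[i][0])  # stable, input order on ties
    canonical = [dets[i] for i in order]
    points = []  # (recall, precision) at each top-k cutoff, matched from scratch
    for k in range(1, len(canonical) + 1):
        flags = _greedy_flags(canonical[:k], gts, thresh)
        tp = sum(flags)
        points.append((tp / n_gt, tp / k))
    ap = 0.0
    prev_r = 0.0
    for idx, (r, _) in enumerate(points):
        if r > prev_r:
            best_p = max(p for rr, p in points[idx:] if rr >= r)
            ap += (r - prev_r) * best_p
            prev_r = r
    return ap


def map_bruteforce(dets, gts, thresholds):
    """dets: [(class, score, ref, box)], gts: [(class, ref, box)] -> dict thr -> mAP."""
    classes = sorted({c for c, _, _ in gts})
    out = {}
    for thr in thresholds:
        aps = []
        for cls in classes:
            cd = [(s, r, b) for c, s, r, b in dets if c == cls]
            cg = [(r, b) for c, r, b in gts if c == cls]
            aps.append(ap_bruteforce(cd, cg, thr))
        out[thr] = sum(aps) / len(aps)
    return out
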