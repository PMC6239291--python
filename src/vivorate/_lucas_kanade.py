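"""Sparse pyramidal Lucas-Kanade point tracking.

Classic iterative Lucas-Kanade on a Gaussian pyramid, compiled with numba
(the per-frame, per-point inner loops are far too fine-grained for
vectorized numpy). Intensity and gradient windows are sampled bilinearly;
gradients are central differences per pyramid level. A point fails when
its structure tensor is near-singular (flat patch), when the solver
diverges or leaves the image, or when backward re-tracking lands more
than a threshold away from where the point started (forward-backward
consistency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass
class LKParams:
    window: int = 21          # odd window edge, px
    levels: int = 3           # pyramid levels (1 = no pyramid)
    max_iters: int = 30
    tol: float = 1e-3         # convergence threshold on the update, px
    min_eigenvalue: float = 1e-4  # reject flat windows (normalized tensor)


@njit(cache=True)
def _refl(i: int, n: int) -> int:
    """Mirror-reflect an index into [0, n)."""
    if i < 0:
        return -i
    if i >= n:
        return 2 * n - 2 - i
    return i


@njit(cache=True, fastmath=True)
def _blur_downsample(src, dst):
    """5-tap Gaussian blur ([1,4,6,4,1]/16, mirror edges) then 2x decimate."""
    hs, ws = src.shape
    hd, wd = dst.shape
    tmp = np.empty((hs, ws))
    for i in range(hs):
        for j in range(ws):
            acc = 6.0 * src[i, j]
            acc += 4.0 * (src[i, _refl(j - 1, ws)] + src[i, _refl(j + 1, ws)])
            acc += src[i, _refl(j - 2, ws)] + src[i, _refl(j + 2, ws)]
            tmp[i, j] = acc / 16.0
    for i in range(hd):
        si = 2 * i
        for j in range(wd):
            sj = 2 * j
            acc = 6.0 * tmp[si, sj]
            acc += 4.0 * (tmp[_refl(si - 1, hs), sj] + tmp[_refl(si + 1, hs), sj])
            acc += tmp[_refl(si - 2, hs), sj] + tmp[_refl(si + 2, hs), sj]
            dst[i, j] = acc / 16.0


@njit(cache=True, fastmath=True)
def _gradients(img, gr, gc):
    h, w = img.shape
    for i in range(h):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < h - 1 else h - 1
        denom_r = 2.0 if 0 < i < h - 1 else 1.0
        for j in range(w):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < w - 1 else w - 1
            denom_c = 2.0 if 0 < j < w - 1 else 1.0
            gr[i, j] = (img[ip, j] - img[im, j]) / denom_r
            gc[i, j] = (img[i, jp] - img[i, jm]) / denom_c


@njit(cache=True, fastmath=True)
def _build_pyramid(frame, scale, shapes, offs, buf_img, buf_gr, buf_gc):
    n_levels = shapes.shape[0]
    h0, w0 = shapes[0, 0], shapes[0, 1]
    img0 = buf_img[offs[0] : offs[1]].reshape(h0, w0)
    for i in range(h0):
        for j in range(w0):
            img0[i, j] = frame[i, j] * scale
    for lv in range(1, n_levels):
        src = buf_img[offs[lv - 1] : offs[lv]].reshape(shapes[lv - 1, 0], shapes[lv - 1, 1])
        dst = buf_img[offs[lv] : offs[lv + 1]].reshape(shapes[lv, 0], shapes[lv, 1])
        _blur_downsample(src, dst)
    for lv in range(n_levels):
        h, w = shapes[lv, 0], shapes[lv, 1]
        img = buf_img[offs[lv] : offs[lv + 1]].reshape(h, w)
        gr = buf_gr[offs[lv] : offs[lv + 1]].reshape(h, w)
        gc = buf_gc[offs[lv] : offs[lv + 1]].reshape(h, w)
        _gradients(img, gr, gc)


@njit(cache=True, fastmath=True, inline="always")
def _bil(img, r, c):
    r0 = int(np.floor(r))
    c0 = int(np.floor(c))
    fr = r - r0
    fc = c - c0
    return (
        img[r0, c0] * (1.0 - fr) * (1.0 - fc)
        + img[r0, c0 + 1] * (1.0 - fr) * fc
        + img[r0 + 1, c0] * fr * (1.0 - fc)
        + img[r0 + 1, c0 + 1] * fr * fc
    )


@njit(cache=True, fastmath=True)
def _lk_point(
    buf_img_p, buf_gr_p, buf_gc_p, buf_img_c, shapes, offs,
    n_levels, pr, pc, window, max_iters, tol, min_eig_thresh,
):
    """Track one point between two cached pyramids.

    Returns (new_row, new_col, ok).
    """
    half = window // 2
    margin = half + 2.0
    gr_acc = 0.0  # accumulated displacement at the current level scale
    gc_acc = 0.0
    ok = True
    tmpl = np.empty((window, window))
    tgr = np.empty((window, window))
    tgc = np.empty((window, window))

    for lv in range(n_levels - 1, -1, -1):
        scale = 2.0**lv
        prl = pr / scale
        pcl = pc / scale
        h, w = shapes[lv, 0], shapes[lv, 1]
        if not (margin <= prl <= h - 1 - margin and margin <= pcl <= w - 1 - margin):
            if lv == 0:
                ok = False
            else:
                gr_acc *= 2.0
                gc_acc *= 2.0
            continue
        img_p = buf_img_p[offs[lv] : offs[lv + 1]].reshape(h, w)
        gr_p = buf_gr_p[offs[lv] : offs[lv + 1]].reshape(h, w)
        gc_p = buf_gc_p[offs[lv] : offs[lv + 1]].reshape(h, w)
        img_c = buf_img_c[offs[lv] : offs[lv + 1]].reshape(h, w)

        grr = 0.0
        gcc = 0.0
        grc = 0.0
        for a in range(window):
            ra = prl + a - half
            for b in range(window):
                cb = pcl + b - half
                tmpl[a, b] = _bil(img_p, ra, cb)
                gva = _bil(gr_p, ra, cb)
                gvb = _bil(gc_p, ra, cb)
                tgr[a, b] = gva
                tgc[a, b] = gvb
                grr += gva * gva
                gcc += gvb * gvb
                grc += gva * gvb
        det = grr * gcc - grc * grc
        trace = grr + gcc
        disc = trace * trace - 4.0 * det
        if disc < 0.0:
            disc = 0.0
        min_eig = 0.5 * (trace - np.sqrt(disc))
        if min_eig / (window * window) < min_eig_thresh or det <= 0.0:
            if lv == 0:
                ok = False
            else:
                gr_acc *= 2.0
                gc_acc *= 2.0
            continue

        vr = gr_acc
        vc = gc_acc
        for _ in range(max_iters):
            qr = prl + vr
            qc = pcl + vc
            if not (margin <= qr <= h - 1 - margin and margin <= qc <= w - 1 - margin):
                if lv == 0:
                    ok = False
                break
            br = 0.0
            bc = 0.0
            for a in range(window):
                ra = qr + a - half
                for b in range(window):
                    diff = tmpl[a, b] - _bil(img_c, ra, qc + b - half)
                    br += tgr[a, b] * diff
                    bc += tgc[a, b] * diff
            dr = (gcc * br - grc * bc) / det
            dc = (grr * bc - grc * br) / det
            vr += dr
            vc += dc
            if np.sqrt(vr * vr + vc * vc) > window:
                ok = False
                break
            if np.sqrt(dr * dr + dc * dc) < tol:
                break
        if not ok:
            break
        gr_acc = vr
        gc_acc = vc
        if lv > 0:
            gr_acc *= 2.0
            gc_acc *= 2.0

    nr = pr + gr_acc
    nc = pc + gc_acc
    h0, w0 = shapes[0, 0], shapes[0, 1]
    lim = half + 1.0
    if not (lim <= nr <= h0 - 1 - lim and lim <= nc <= w0 - 1 - lim):
        ok = False
    return nr, nc, ok


@njit(cache=True, fastmath=True)
def _track_kernel(
    frames, scale, seeds, window, n_levels, max_iters, tol, min_eig, fb_thresh
):
    n_frames = frames.shape[0]
    h0, w0 = frames.shape[1], frames.shape[2]
    n = seeds.shape[0]
    positions = np.full((n_frames, n, 2), np.nan)
    valid = np.zeros((n_frames, n), np.bool_)

    shapes = np.empty((n_levels, 2), np.int64)
    offs = np.empty(n_levels + 1, np.int64)
    h, w = h0, w0
    total = 0
    used_levels = 0
    for lv in range(n_levels):
        shapes[lv, 0] = h
        shapes[lv, 1] = w
        offs[lv] = total
        total += h * w
        used_levels += 1
        if min(h, w) < 16:
            break
        h //= 2
        w //= 2
    offs[used_levels] = total
    shapes = shapes[:used_levels]
    offs = offs[: used_levels + 1]

    buf_img = np.empty((2, total))
    buf_gr = np.empty((2, total))
    buf_gc = np.empty((2, total))
    prev = 0
    _build_pyramid(frames[0], scale, shapes, offs, buf_img[prev], buf_gr[prev], buf_gc[prev])

    half = window // 2
    lim = half + 1.0
    cur_r = np.empty(n)
    cur_c = np.empty(n)
    alive = np.zeros(n, np.bool_)
    for k in range(n):
        cur_r[k] = seeds[k, 0]
        cur_c[k] = seeds[k, 1]
        if lim <= cur_r[k] <= h0 - 1 - lim and lim <= cur_c[k] <= w0 - 1 - lim:
            alive[k] = True
            positions[0, k, 0] = cur_r[k]
            positions[0, k, 1] = cur_c[k]
            valid[0, k] = True

    for i in range(1, n_frames):
        curr = 1 - prev
        _build_pyramid(frames[i], scale, shapes, offs, buf_img[curr], buf_gr[curr], buf_gc[curr])
        for k in range(n):
            if not alive[k]:
                continue
            nr, nc, okf = _lk_point(
                buf_img[prev], buf_gr[prev], buf_gc[prev], buf_img[curr],
                shapes, offs, used_levels, cur_r[k], cur_c[k],
                window, max_iters, tol, min_eig,
            )
            if okf:
                # Backward check starts from the known displacement: one level.
                br, bc, okb = _lk_point(
                    buf_img[curr], buf_gr[curr], buf_gc[curr], buf_img[prev],
                    shapes, offs, 1, nr, nc, window, max_iters, tol, min_eig,
                )
                fb = np.sqrt((br - cur_r[k]) ** 2 + (bc - cur_c[k]) ** 2)
                okf = okb and fb <= fb_thresh
            if okf:
                cur_r[k] = nr
                cur_c[k] = nc
                positions[i, k, 0] = nr
                positions[i, k, 1] = nc
                valid[i, k] = True
            else:
                alive[k] = False
        prev = curr

    return positions, valid


def track_points(
    frames: np.ndarray,
    seeds: np.ndarray,
    params: LKParams | None = None,
    fb_threshold: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Track seed points through a frame stack with forward-backward checks.

    Parameters
    ----------
    frames
        (n_frames, h, w) grayscale stack (uint8 or float in [0, 1]).
    seeds
        (N, 2) (row, col) positions in frame 0.
    fb_threshold
        A point is invalidated when re-tracking it backwards lands more
        than this many pixels from where it started. Points, once lost,
        stay lost (no re-acquisition), preserving waveform phase.

    Returns
    -------
    positions : (n_frames, N, 2) sub-pixel positions (NaN once lost).
    valid : (n_frames, N) boolean validity.
    """
    params = params or LKParams()
    if params.window % 2 != 1 or params.window < 5:
        raise ValueError("window must be odd and >= 5")
    frames = np.ascontiguousarray(frames)
    scale = 1.0 / 255.0 if (frames.dtype == np.uint8 or frames.max() > 1.5) else 1.0
    seeds = np.ascontiguousarray(np.asarray(seeds, dtype=np.float64))
    if seeds.ndim != 2 or seeds.shape[1] != 2:
        raise ValueError("seeds must be an (N, 2) array of (row, col) positions")
    return _track_kernel(
        frames,
        scale,
        seeds,
        int(params.window),
        int(params.levels),
        int(params.max_iters),
        float(params.tol),
        float(params.min_eigenvalue),
        float(fb_threshold),
    )
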