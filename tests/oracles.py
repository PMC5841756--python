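"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, exhaustive
searches, priority-queue flooding — and shares no code with the package.
"""

from __future__ import annotations

import heapq

import numpy as np


def _otsu_objectives(image: np.ndarray, nbins: int = 256):
    image = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(image, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    thresholds, objectives = [], []
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        thresholds.append(centers[k - 1])
        objectives.append(w0 * w1 * (mu0 - mu1) ** 2)
    return np.asarray(thresholds), np.asarray(objectives)


def otsu_brute_force(image: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive between-class-variance maximizer over histogram bins."""
    thresholds, objectives = _otsu_objectives(image, nbins)
    return thresholds[np.argmax(objectives)]


def otsu_objective_at(image: np.ndarray, t: float, nbins: int = 256) -> float:
    """Between-class variance of the split at threshold ``t`` on the same
    histogram the brute-force search uses."""
    thresholds, objectives = _otsu_objectives(image, nbins)
    idx = np.searchsorted(thresholds, t, side="right") - 1
    idx = int(np.clip(idx, 0, len(objectives) - 1))
    return objectives[idx]


def distance_exhaustive(mask: np.ndarray) -> np.ndarray:
    """Per-foreground-pixel minimum Euclidean distance to any background pixel."""
    mask = np.asarray(mask, dtype=bool)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    for r, c in np.argwhere(mask):
        d2 = (bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2
        out[r, c] = np.sqrt(d2.min())
    return out


def dilate_loops(mask: np.ndarray, se: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    h = se // 2
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            r0, r1 = max(0, r - h), min(rows, r + h + 1)
            c0, c1 = max(0, c - h), min(cols, c + h + 1)
            out[r, c] = mask[r0:r1, c0:c1].any()
    return out


def erode_loops(mask: np.ndarray, se: int) -> np.ndarray:
    # out-of-bounds counts as background (finite-set semantics)
    mask = np.asarray(mask, dtype=bool)
    h = se // 2
    out = np.zeros_like(mask)
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr in range(-h, h + 1):
                for dc in range(-h, h + 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols) or not mask[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def close_loops(mask: np.ndarray, se: int) -> np.ndarray:
    """Closing of the finite foreground set via explicit loops on a padded grid."""
    pad = se
    padded = np.pad(np.asarray(mask, dtype=bool), pad)
    closed = erode_loops(dilate_loops(padded, se), se)
    return closed[pad:-pad, pad:-pad]


def open_loops(mask: np.ndarray, se: int) -> np.ndarray:
    pad = se
    padded = np.pad(np.asarray(mask, dtype=bool), pad)
    opened = dilate_loops(erode_loops(padded, se), se)
    return opened[pad:-pad, pad:-pad]


def hminima_reconstruction(surface: np.ndarray, h: float) -> np.ndarray:
    """Extended minima by brute-force morphological reconstruction by erosion.

    The h-minima transform is the reconstruction-by-erosion of
    ``surface + h`` above ``surface``; the extended minima are the regional
    minima of that transform (4-connectivity plateaus).
    """
    f = np.asarray(surface, dtype=float)
    rec = f + h
    while True:
        # erosion over the 4-neighbourhood + centre, then pointwise max with f
        padded = np.pad(rec, 1, mode="edge")
        eroded = np.minimum.reduce([
            padded[1:-1, 1:-1], padded[:-2, 1:-1], padded[2:, 1:-1],
            padded[1:-1, :-2], padded[1:-1, 2:],
        ])
        new = np.maximum(f, eroded)
        if np.array_equal(new, rec):
            break
        rec = new
    return regional_minima(rec)


def regional_minima(surface: np.ndarray) -> np.ndarray:
    """Connected plateaus strictly below all neighbouring pixels (8-conn)."""
    f = np.asarray(surface, dtype=float)
    rows, cols = f.shape
    minima = np.ones_like(f, dtype=bool)
    # flood equal-valued plateaus; a plateau fails if any member has a
    # strictly lower neighbour
    visited = np.zeros_like(minima)
    for r in range(rows):
        for c in range(cols):
            if visited[r, c]:
                continue
            stack = [(r, c)]
            plateau = []
            visited[r, c] = True
            is_min = True
            while stack:
                pr, pc = stack.pop()
                plateau.append((pr, pc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = pr + dr, pc + dc
                        if not (0 <= rr < rows and 0 <= cc < cols):
                            continue
                        if f[rr, cc] == f[r, c]:
                            if not visited[rr, cc]:
                                visited[rr, cc] = True
                                stack.append((rr, cc))
                        elif f[rr, cc] < f[r, c]:
                            is_min = False
            for pr, pc in plateau:
                minima[pr, pc] = is_min
    return minima


def flood_watershed(relief: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Priority-flood watershed with 4-connectivity and ridge pixels = 0.

    Pixels are assigned the label of their first-arriving flood; a pixel
    whose already-assigned neighbours carry two distinct labels when it is
    reached becomes a ridge pixel (label 0, excluded from both basins).
    """
    relief = np.asarray(relief, dtype=float)
    labels = np.asarray(markers, dtype=int).copy()
    rows, cols = relief.shape
    nbrs = ((-1, 0), (1, 0), (0, -1), (0, 1))
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    state = labels.copy()  # 0 = unassigned, >0 label, -1 ridge
    for r, c in np.argwhere(labels > 0):
        heapq.heappush(heap, (relief[r, c], counter, r, c))
        counter += 1
    queued = labels > 0
    while heap:
        _, _, r, c = heapq.heappop(heap)
        if state[r, c] == 0:
            seen = {state[rr, cc] for dr, dc in nbrs
                    if 0 <= (rr := r + dr) < rows and 0 <= (cc := c + dc) < cols
                    and state[rr, cc] > 0}
            if len(seen) == 1:
                state[r, c] = seen.pop()
            elif len(seen) > 1:
                state[r, c] = -1
                continue  # ridges do not propagate
            else:
                continue
        for dr, dc in nbrs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and not queued[rr, cc]:
                queued[rr, cc] = True
                heapq.heappush(heap, (relief[rr, cc], counter, rr, cc))
                counter += 1
    return np.where(state == -1, 0, state)


def lowess_reference(y: np.ndarray, frac: float, iterations: int = 3) -> np.ndarray:
    """Cleveland's robust locally weighted linear regression, explicit loops.

    x is taken as 0..n-1.  Tricube distance weights over the ``k`` nearest
    points with k = round(frac * n); ``iterations`` bisquare robustness
    passes with scale 6 * median |residual|.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    x = np.arange(n, dtype=float)
    k = max(2, int(round(frac * n)))
    delta = np.ones(n)
    fit = np.empty(n)
    for _ in range(iterations + 1):
        for i in range(n):
            d = np.abs(x - x[i])
            idx = np.argsort(d, kind="stable")[:k]
            dmax = d[idx].max()
            if dmax == 0:
                fit[i] = y[i]
                continue
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.clip(w, 0, None) * delta[idx]
            sw = w.sum()
            if sw <= 0:
                fit[i] = y[i]
                continue
            xm = (w * x[idx]).sum() / sw
            ym = (w * y[idx]).sum() / sw
            sxx = (w * (x[idx] - xm) ** 2).sum()
            if sxx <= 1e-12:
                fit[i] = ym
            else:
                b = (w * (x[idx] - xm) * (y[idx] - ym)).sum() / sxx
                fit[i] = ym + b * (x[i] - xm)
        resid = y - fit
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        delta = np.clip(1 - (resid / (6.0 * s)) ** 2, 0, 1) ** 2
    return fit
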