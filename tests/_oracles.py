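"""Brute-force reference implementations used as independent test oracles."""

import math

import numpy as np

from synquant.dendrite import DendriteTrace


def flood_fill_count(mask: np.ndarray) -> int:
    """Count 8-connected components by explicit stack-based flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
    return count


def pixel_loop_and(*masks):
    """Per-pixel conjunction by explicit loops."""
    h, w = masks[0].shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            out[r, c] = all(m[r, c] for m in masks)
    return out


def star_trace(k=4, length=35.0, center=(50.0, 50.0)):
    """k straight branches radiating from a soma."""
    c = np.asarray(center)
    polys = []
    for i in range(k):
        ang = 2 * math.pi * i / k + 0.1
        tip = c + length * np.array([math.sin(ang), math.cos(ang)])
        polys.append(np.stack([c, tip]))
    return DendriteTrace(polylines=polys, soma_center=tuple(c))


def dense_sampling_sholl(trace, step=10.0, ds=0.01):
    """Sholl oracle: sample each polyline at ds μm spacing and count sign
    changes of (distance to soma - r) along consecutive samples."""
    c = np.asarray(trace.soma_center)
    n_radii = int(math.floor(trace.max_extent / step)) + 1
    radii = step * np.arange(1, n_radii + 1)
    counts = np.zeros(n_radii, dtype=int)
    for poly in trace.polylines:
        seglens = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        total = seglens.sum()
        n = max(2, int(total / ds))
        ts = np.linspace(0, total, n)
        cum = np.concatenate([[0], np.cumsum(seglens)])
        pts = []
        for t in ts:
            i = min(np.searchsorted(cum, t, side="right") - 1, len(seglens) - 1)
            f = (t - cum[i]) / seglens[i] if seglens[i] else 0.0
            pts.append(poly[i] + f * (poly[i + 1] - poly[i]))
        d = np.linalg.norm(np.asarray(pts) - c, axis=1)
        for j, r in enumerate(radii):
            sign = np.sign(d - r)
            counts[j] += int(np.sum(np.abs(np.diff(sign)) == 2))
    return radii, counts
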