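"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid numpy vectorization and the package's
own code paths: plain Python loops and BFS flood fill, so they can serve
as ground truth for the fast implementations.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from endocoloc import MultiChannelImage


def make_image(rng: np.random.Generator, shape=(16, 16), bit_depth=8, p_zero=0.35,
               source_id="test") -> MultiChannelImage:
    """Random integer image with a controllable fraction of zero pixels."""
    hi = (1 << bit_depth) - 1
    channels = {}
    for role in ("probe", "pfak", "rab5"):
        vals = rng.integers(1, hi + 1, size=shape)
        vals[rng.random(shape) < p_zero] = 0
        channels[role] = vals.astype(np.uint16 if bit_depth > 8 else np.uint8)
    return MultiChannelImage(bit_depth=bit_depth, source_id=source_id, **channels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


# ---------------------------------------------------------------- oracles

def brute_effective(img: MultiChannelImage, threshold=0):
    """Triple-loop effective-pixel detection."""
    h, w = img.shape
    flags = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            ok = True
            for role in ("probe", "pfak", "rab5"):
                if img.channel(role)[r, c] <= threshold:
                    ok = False
            flags[r, c] = ok
    return flags


def brute_counts(img: MultiChannelImage, threshold=0):
    """Per-channel positive counts and n0 by explicit loops."""
    h, w = img.shape
    n0 = n_r = n_g = n_b = 0
    for r in range(h):
        for c in range(w):
            pr, pf, rb = int(img.probe[r, c]), int(img.pfak[r, c]), int(img.rab5[r, c])
            n_b += pr > threshold
            n_r += pf > threshold
            n_g += rb > threshold
            n0 += (pr > threshold) and (pf > threshold) and (rb > threshold)
    return n0, n_r, n_g, n_b


def flood_fill_components(flags: np.ndarray, connectivity: int):
    """BFS connected components in raster order; returns list of pixel sets."""
    h, w = flags.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(flags, dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if not flags[r, c] or seen[r, c]:
                continue
            comp = set()
            queue = deque([(r, c)])
            seen[r, c] = True
            while queue:
                cr, cc = queue.popleft()
                comp.add((cr, cc))
                for dr, dc in nbrs:
                    nr, nc = cr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and flags[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        queue.append((nr, nc))
            components.append(comp)
    return components
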