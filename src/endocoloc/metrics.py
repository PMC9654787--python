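"""Pixel-level colocalization statistics.

The triple-colocalization unit is the *effective pixel*: a pixel whose
intensity strictly exceeds a threshold in all three channels at once
(probe, pFAK and Rab5).  With N0 the effective-pixel count and N_R, N_G,
N_B the single-channel positive-pixel counts (pFAK, Rab5 and probe
respectively, after the red/green/blue pseudo-color convention), the
colocalization rate indices are N0/N_R, N0/N_G and N0/N_B.

The default threshold is 0 — the strict ``> 0`` rule — which is exact on
synthetic images with zero background but degenerate on real micrographs
with nonzero background; the threshold is therefore configurable
everywhere.  Pairwise colocalization is reported as both Pearson
correlation and Manders overlap coefficients, with explicitly labeled
columns, since either convention is common in the field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from skimage.draw import line as _digital_line

from .io import ROLES, MultiChannelImage

__all__ = [
    "EffectiveMask",
    "ColocCounts",
    "PairwiseColoc",
    "effective_mask",
    "coloc_counts",
    "pairwise_coloc",
    "line_profile",
]


@dataclass
class EffectiveMask:
    """Boolean grid marking pixels positive in all three channels.

    ``flags[r, c]`` is True iff every channel intensity at (r, c) strictly
    exceeds ``threshold``.
    """

    flags: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {self.flags.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape

    @property
    def n_effective(self) -> int:
        return int(self.flags.sum())


@dataclass
class ColocCounts:
    """Effective-pixel and per-channel positive counts with rate indices.

    ``n0`` counts triple-positive (effective) pixels; ``n_r``, ``n_g`` and
    ``n_b`` count pixels above threshold in the pFAK, Rab5 and probe
    channels.  Rates ``n0 / n_x`` are ``None`` when the denominator is
    zero — never silently 0 or 1.
    """

    n0: int
    n_r: int
    n_g: int
    n_b: int
    rate_r: Optional[float]
    rate_g: Optional[float]
    rate_b: Optional[float]
    threshold: float = 0.0
    source_id: str = ""

    def as_record(self) -> dict:
        return {
            "source_id": self.source_id,
            "n0": self.n0,
            "n_r": self.n_r,
            "n_g": self.n_g,
            "n_b": self.n_b,
            "rate_r": np.nan if self.rate_r is None else self.rate_r,
            "rate_g": np.nan if self.rate_g is None else self.rate_g,
            "rate_b": np.nan if self.rate_b is None else self.rate_b,
            "threshold": self.threshold,
        }


@dataclass
class PairwiseColoc:
    """Pearson and Manders coefficients between two channels.

    ``pearson`` is ``None`` when either channel has zero variance in
    scope.  ``manders_a`` is the fraction of channel-a intensity lying in
    pixels where channel b exceeds ``manders_threshold`` (and vice versa);
    a Manders value is ``None`` when its channel carries zero total
    intensity in scope.
    """

    channel_a: str
    channel_b: str
    pearson: Optional[float]
    manders_a: Optional[float]
    manders_b: Optional[float]
    n_pixels: int
    manders_threshold: float = 0.0
    masked: bool = False


def effective_mask(img: MultiChannelImage, threshold: float = 0) -> EffectiveMask:
    """Flag pixels whose intensity exceeds ``threshold`` in all three channels."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if threshold >= (1 << img.bit_depth):
        raise ValueError(
            f"threshold {threshold} is at or above the intensity ceiling for "
            f"bit_depth {img.bit_depth}; the mask would be empty by construction"
        )
    flags = (img.probe > threshold) & (img.pfak > threshold) & (img.rab5 > threshold)
    return EffectiveMask(flags=flags, threshold=threshold)


def coloc_counts(img: MultiChannelImage, threshold: float = 0) -> ColocCounts:
    """Count effective and single-channel positive pixels and form rate indices.

    The same strict ``> threshold`` rule applies to the triple criterion
    and to each single channel, over the whole frame.
    """
    mask = effective_mask(img, threshold)
    n0 = mask.n_effective
    n_r = int((img.pfak > threshold).sum())
    n_g = int((img.rab5 > threshold).sum())
    n_b = int((img.probe > threshold).sum())

    def rate(denom: int) -> Optional[float]:
        return None if denom == 0 else n0 / denom

    return ColocCounts(
        n0=n0,
        n_r=n_r,
        n_g=n_g,
        n_b=n_b,
        rate_r=rate(n_r),
        rate_g=rate(n_g),
        rate_b=rate(n_b),
        threshold=threshold,
        source_id=img.source_id,
    )


def pairwise_coloc(
    img: MultiChannelImage,
    a: str,
    b: str,
    mask: Optional[EffectiveMask] = None,
    manders_threshold: float = 0,
) -> PairwiseColoc:
    """Pearson and Manders colocalization between channels ``a`` and ``b``.

    With ``mask`` given, only flagged pixels are in scope; otherwise the
    whole frame.  Pearson is computed over the in-scope intensity pairs;
    Manders_a sums a-intensity where ``b > manders_threshold`` and divides
    by the total in-scope a-intensity (symmetrically for Manders_b).
    """
    if a == b:
        raise ValueError(f"channels must differ, got {a!r} twice")
    if a not in ROLES or b not in ROLES:
        raise ValueError(f"unknown channel role in ({a!r}, {b!r}); expected {ROLES}")
    arr_a = img.channel(a).astype(np.float64)
    arr_b = img.channel(b).astype(np.float64)
    if mask is not None:
        if mask.shape != img.shape:
            raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
        arr_a = arr_a[mask.flags]
        arr_b = arr_b[mask.flags]
    else:
        arr_a = arr_a.ravel()
        arr_b = arr_b.ravel()

    n = arr_a.size
    pearson: Optional[float] = None
    if n >= 2 and arr_a.std() > 0 and arr_b.std() > 0:
        pearson = float(stats.pearsonr(arr_a, arr_b).statistic)

    total_a = arr_a.sum()
    total_b = arr_b.sum()
    manders_a = None if total_a == 0 else float(arr_a[arr_b > manders_threshold].sum() / total_a)
    manders_b = None if total_b == 0 else float(arr_b[arr_a > manders_threshold].sum() / total_b)

    return PairwiseColoc(
        channel_a=a,
        channel_b=b,
        pearson=pearson,
        manders_a=manders_a,
        manders_b=manders_b,
        n_pixels=int(n),
        manders_threshold=manders_threshold,
        masked=mask is not None,
    )


def line_profile(
    img: MultiChannelImage,
    start: tuple[int, int],
    end: tuple[int, int],
    channels: Sequence[str] = ROLES,
) -> dict[str, np.ndarray]:
    """Sample channel intensities along the digital line from start to end.

    Uses Bresenham pixel stepping (no interpolation), both endpoints
    inclusive, so the returned values are raw grid integers.  All
    requested channels share the same pixel set, hence the same length.
    """
    (r0, c0), (r1, c1) = start, end
    h, w = img.shape
    for r, c in (start, end):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"endpoint ({r}, {c}) outside image of shape {img.shape}")
    rows, cols = _digital_line(int(r0), int(c0), int(r1), int(c1))
    return {role: img.channel(role)[rows, cols].copy() for role in channels}
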