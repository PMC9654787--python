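"""Synthetic three-channel micrographs with known ground truth.

Real images behind the analysis are not publicly deposited, so every
pipeline stage is exercised on simulated micrographs that emulate their
stated geometry: a 512 x 512 px frame of punctate endosomal signal in
three channels (probe, pFAK, Rab5) at 12-bit depth.  Each punctum is an
isotropic Gaussian spot (sd = radius / 2, truncated at 3 sd) with a
channel-membership set: a configurable fraction ``f_triple`` of puncta
carry all three channels (triple-colocalized endosomal platforms),
two-channel and single-channel fractions cover the rest.  For puncta
carrying both probe and pFAK, the pFAK peak is coupled to the probe peak
through the quadratic intensity model

    pfak_peak = a0 + a1 * probe_peak + a2 * probe_peak**2 + N(0, sd) ,

with default coefficients (125.86, 0.346, -2.99e-5) and noise sd 20, so
the generating model is known exactly and end-to-end coefficient
recovery can be tested.  Rab5 peaks are independent.  Punctum centers sit
on the integer pixel grid, so each peak intensity is realized exactly at
one pixel and per-punctum peaks are recoverable from the rendered image.

All randomness flows from a single seed: the dataset generator draws one
sub-seed per image from the master generator, and within an image the
same generator is used first for punctum sampling and then for
background noise, so every artifact is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import MultiChannelImage, write_image

__all__ = [
    "SimulationConfig",
    "Punctum",
    "GroundTruth",
    "sample_puncta",
    "render_image",
    "simulate_image",
    "generate_dataset",
]

_PAIR_KEYS = ("probe_pfak", "probe_rab5", "pfak_rab5")
_SINGLE_KEYS = ("probe", "pfak", "rab5")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic micrograph generator.

    ``f_triple`` plus the two-channel fractions must not exceed 1; the
    remainder is split equally over the three single-channel classes.
    Intensity distributions are uniform over (low, high) peak intensity.
    ``min_spacing``, when set, enforces a minimum center-to-center
    distance so puncta render as separate islands.
    """

    width: int = 512
    height: int = 512
    bit_depth: int = 12
    n_puncta: float = 40.0  # Poisson mean per image
    radius_range: tuple[float, float] = (2.0, 5.0)
    f_triple: float = 0.6
    f_pairs: dict = field(
        default_factory=lambda: {"probe_pfak": 0.1, "probe_rab5": 0.1, "pfak_rab5": 0.05}
    )
    probe_intensity_dist: tuple[float, float] = (200.0, 4000.0)
    pfak_coupling: tuple[float, float, float] = (125.86, 0.346, -2.99e-5)
    pfak_noise_sd: float = 20.0
    rab5_intensity_dist: tuple[float, float] = (200.0, 4000.0)
    background_level: float = 0.0
    background_noise_sd: float = 0.0
    min_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        pairs = {k: float(self.f_pairs.get(k, 0.0)) for k in _PAIR_KEYS}
        unknown = set(self.f_pairs) - set(_PAIR_KEYS)
        if unknown:
            raise ValueError(f"unknown f_pairs keys {sorted(unknown)}; expected {_PAIR_KEYS}")
        self.f_pairs = pairs
        fractions = [self.f_triple, *pairs.values()]
        if any(f < 0 or f > 1 for f in fractions):
            raise ValueError("membership fractions must lie in [0, 1]")
        if sum(fractions) > 1 + 1e-9:
            raise ValueError(f"f_triple + sum(f_pairs) = {sum(fractions):.4f} exceeds 1")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid radius_range {self.radius_range}")
        margin = _margin(hi)
        if 2 * margin >= min(self.width, self.height):
            raise ValueError(
                f"infeasible margin: max radius {hi} needs {margin} px on each side "
                f"of a {self.height}x{self.width} image"
            )

    @property
    def f_singles(self) -> float:
        return max(0.0, 1.0 - self.f_triple - sum(self.f_pairs.values()))

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    def membership_classes(self) -> list[tuple[frozenset, float]]:
        """(membership set, probability) pairs summing to 1."""
        classes = [(frozenset(("probe", "pfak", "rab5")), self.f_triple)]
        for key in _PAIR_KEYS:
            classes.append((frozenset(key.split("_")), self.f_pairs[key]))
        single = self.f_singles / 3.0
        for key in _SINGLE_KEYS:
            classes.append((frozenset((key,)), single))
        return classes

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["radius_range"] = list(self.radius_range)
        d["probe_intensity_dist"] = list(self.probe_intensity_dist)
        d["pfak_coupling"] = list(self.pfak_coupling)
        d["rab5_intensity_dist"] = list(self.rab5_intensity_dist)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("radius_range", "probe_intensity_dist", "pfak_coupling", "rab5_intensity_dist"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Punctum:
    row: int
    col: int
    radius: float
    membership: frozenset
    peaks: dict  # role -> float peak intensity; only member roles present

    def as_record(self) -> dict:
        return {
            "row": self.row,
            "col": self.col,
            "radius": self.radius,
            "membership": "+".join(sorted(self.membership)),
            "peak_probe": self.peaks.get("probe", np.nan),
            "peak_pfak": self.peaks.get("pfak", np.nan),
            "peak_rab5": self.peaks.get("rab5", np.nan),
        }


@dataclass
class GroundTruth:
    """Simulator truth table: puncta with memberships and peak intensities."""

    puncta: list[Punctum]
    config: SimulationConfig
    expected_residual_sd: float

    @property
    def n_triple(self) -> int:
        return sum(1 for p in self.puncta if len(p.membership) == 3)

    def to_frame(self) -> pd.DataFrame:
        cols = ["row", "col", "radius", "membership", "peak_probe", "peak_pfak", "peak_rab5"]
        return pd.DataFrame([p.as_record() for p in self.puncta], columns=cols)


def _margin(radius: float) -> int:
    # spots are truncated at 3 sd = 1.5 * radius
    return int(math.ceil(1.5 * radius))


def _quadratic(coef: tuple[float, float, float], x: float) -> float:
    a0, a1, a2 = coef
    return a0 + a1 * x + a2 * x * x


def sample_puncta(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Draw punctum count, positions, memberships and peak intensities.

    The count is Poisson(``n_puncta``); centers are uniform on the pixel
    grid with enough margin that the truncated spot fits in the frame;
    memberships are multinomial over the configured classes.  Peak
    intensities are clipped to [1, 2**bit_depth - 1]: a punctum that is a
    member of a channel is by definition detectable there.
    """
    n = int(rng.poisson(config.n_puncta))
    classes = config.membership_classes()
    probs = np.array([p for _, p in classes])
    probs = probs / probs.sum()
    lo_r, hi_r = config.radius_range
    max_i = float(config.max_intensity)

    centers: list[tuple[int, int]] = []
    puncta: list[Punctum] = []
    for _ in range(n):
        radius = float(rng.uniform(lo_r, hi_r))
        m = _margin(radius)
        for _attempt in range(1000):
            row = int(rng.integers(m, config.height - m))
            col = int(rng.integers(m, config.width - m))
            if config.min_spacing is None:
                break
            if all(
                (row - r0) ** 2 + (col - c0) ** 2 >= config.min_spacing**2 for r0, c0 in centers
            ):
                break
        else:
            raise RuntimeError(
                f"could not place punctum with min_spacing={config.min_spacing} after 1000 attempts"
            )
        centers.append((row, col))

        membership = classes[rng.choice(len(classes), p=probs)][0]
        peaks: dict[str, float] = {}
        if "probe" in membership:
            peaks["probe"] = float(rng.uniform(*config.probe_intensity_dist))
        if "pfak" in membership:
            if "probe" in membership:
                mean = _quadratic(config.pfak_coupling, peaks["probe"])
                peaks["pfak"] = mean + float(rng.normal(0.0, config.pfak_noise_sd))
            else:
                peaks["pfak"] = float(rng.uniform(*config.probe_intensity_dist))
        if "rab5" in membership:
            peaks["rab5"] = float(rng.uniform(*config.rab5_intensity_dist))
        peaks = {k: float(np.clip(v, 1.0, max_i)) for k, v in peaks.items()}
        puncta.append(Punctum(row=row, col=col, radius=radius, membership=membership, peaks=peaks))

    return GroundTruth(puncta=puncta, config=config, expected_residual_sd=config.pfak_noise_sd)


def render_image(
    truth: GroundTruth,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
    source_id: str = "sim",
) -> MultiChannelImage:
    """Render the truth table into a quantized three-channel image.

    Each punctum adds ``peak * exp(-d^2 / (2 sd^2))`` (sd = radius / 2,
    zero beyond 3 sd) to its member channels; overlapping puncta add.
    Gaussian background noise (if configured) requires ``rng``.  The
    result is clipped to the intensity range and rounded to integers.
    """
    config = config or truth.config
    shape = (config.height, config.width)
    acc = {role: np.zeros(shape, dtype=np.float64) for role in _SINGLE_KEYS}

    for p in truth.puncta:
        sd = p.radius / 2.0
        m = _margin(p.radius)
        rows = np.arange(p.row - m, p.row + m + 1)
        cols = np.arange(p.col - m, p.col + m + 1)
        d2 = (rows[:, None] - p.row) ** 2 + (cols[None, :] - p.col) ** 2
        kernel = np.exp(-d2 / (2.0 * sd * sd))
        kernel[d2 > (3.0 * sd) ** 2] = 0.0
        r0, r1 = max(rows[0], 0), min(rows[-1] + 1, shape[0])
        c0, c1 = max(cols[0], 0), min(cols[-1] + 1, shape[1])
        kr = slice(r0 - rows[0], kernel.shape[0] - (rows[-1] + 1 - r1))
        kc = slice(c0 - cols[0], kernel.shape[1] - (cols[-1] + 1 - c1))
        for role, peak in p.peaks.items():
            acc[role][r0:r1, c0:c1] += peak * kernel[kr, kc]

    if config.background_level:
        for role in acc:
            acc[role] += config.background_level
    if config.background_noise_sd > 0:
        if rng is None:
            raise ValueError("background_noise_sd > 0 requires an rng for reproducible noise")
        for role in _SINGLE_KEYS:
            acc[role] += rng.normal(0.0, config.background_noise_sd, shape)

    max_i = config.max_intensity
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    channels = {
        role: np.clip(np.rint(acc[role]), 0, max_i).astype(dtype) for role in _SINGLE_KEYS
    }
    return MultiChannelImage(bit_depth=config.bit_depth, source_id=source_id, **channels)


def simulate_image(
    config: SimulationConfig, seed: int, source_id: str = "sim"
) -> tuple[MultiChannelImage, GroundTruth]:
    """Sample and render one image from a single seed."""
    rng = np.random.default_rng(seed)
    truth = sample_puncta(config, rng)
    img = render_image(truth, config, rng, source_id=source_id)
    return img, truth


def generate_dataset(
    config: SimulationConfig,
    n_images: int = 22,
    out_dir: str | Path = ".",
    seed: int = 0,
) -> dict:
    """Write a reproducible dataset: TIFFs, truth CSVs and a manifest.

    The default of 22 images mirrors the pooled-analysis size used for
    the intensity model.  One sub-seed per image is drawn from the master
    seed and recorded in the manifest, so rerunning from the manifest
    reproduces every file bit-for-bit.
    """
    out_dir = Path(out_dir)
    if not out_dir.exists():
        raise FileNotFoundError(f"output directory does not exist: {out_dir}")
    master = np.random.default_rng(seed)
    image_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_images)]

    entries = []
    for i, img_seed in enumerate(image_seeds):
        source_id = f"sim_{i:03d}"
        img, truth = simulate_image(config, img_seed, source_id=source_id)
        img_path = out_dir / f"{source_id}.tif"
        truth_path = out_dir / f"{source_id}_truth.csv"
        write_image(img, img_path)
        truth.to_frame().to_csv(truth_path, index=False)
        entries.append(
            {
                "source_id": source_id,
                "seed": img_seed,
                "image": img_path.name,
                "truth": truth_path.name,
                "n_puncta": len(truth.puncta),
                "n_triple": truth.n_triple,
            }
        )

    manifest = {"config": config.to_dict(), "seed": int(seed), "n_images": n_images, "images": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
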