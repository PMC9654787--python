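"""End-to-end run orchestration: simulate/load -> mask -> counts -> islands
-> pairs -> fit -> report.

A run is configured by :class:`RunConfig` (from Python or YAML), is fully
deterministic given its seed, and writes ``counts.csv``, ``islands.csv``,
``pairs.csv``, ``fit.json`` and ``report.json`` to the output directory.
The intensity fit defaults to per-island peak pairing (``fit_unit =
"island_max"``): each colocation island contributes one (max probe, max
pFAK) pair.  Under the generative spot model both channels of a punctum
share the same spatial kernel, so raw pixel pairs mix the peak coupling
with a common attenuation factor, while the island peak estimates the
punctum peak directly; pixel-level and island-mean pairing remain
available as options.

``compare_groups`` contrasts a rate index between two runs (e.g. model
vs control cells) with a seeded permutation test over image labels —
labeled as such, since the original comparison's test is unnamed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import MultiChannelImage, read_image, write_pixel_table
from .islands import find_islands, island_stats
from .metrics import coloc_counts, effective_mask
from .model import (
    correlation_report,
    extract_pairs,
    fit_quadratic,
    pool_pairs,
)
from .simulate import SimulationConfig, simulate_image

__all__ = ["RunConfig", "RunReport", "run_pipeline", "compare_groups", "fold_change", "load_run_config"]

logger = logging.getLogger("endocoloc")

_FIT_UNITS = ("pixel", "island_mean", "island_max")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``images`` (paths to existing micrographs) or
    ``simulation`` (a :class:`SimulationConfig`) must be supplied.
    """

    images: Optional[Sequence[str]] = None
    simulation: Optional[SimulationConfig] = None
    n_images: int = 22
    channel_map: Optional[dict] = None
    threshold: float = 0.0
    connectivity: int = 8
    min_island_size: int = 1
    fit_degree: int = 2
    fit_unit: str = "island_max"
    permutations: int = 9999
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.images is None) == (self.simulation is None):
            raise ValueError("exactly one of images / simulation must be supplied")
        if self.fit_unit not in _FIT_UNITS:
            raise ValueError(f"fit_unit must be one of {_FIT_UNITS}, got {self.fit_unit!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        if self.images is not None:
            d["images"] = [str(p) for p in self.images]
        return d

    def analysis_dict(self) -> dict:
        """Config dict without ``out_dir`` — the fields the numbers depend on."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.analysis_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All per-image and pooled outputs of one run, JSON-serializable."""

    counts: pd.DataFrame
    islands: pd.DataFrame
    pairs: pd.DataFrame
    fit: Optional[dict]
    correlation: Optional[dict]
    notes: list[str]
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "per_image": self.counts.to_dict(orient="records"),
            "n_islands": int(len(self.islands)),
            "n_pairs": int(len(self.pairs)),
            "fit": self.fit,
            "correlation": self.correlation,
            "notes": self.notes,
            "provenance": self.provenance,
        }


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file mirroring its fields."""
    d = yaml.safe_load(Path(path).read_text())
    if d.get("simulation") is not None:
        d["simulation"] = SimulationConfig.from_dict(d["simulation"])
    return RunConfig(**d)


def _load_inputs(config: RunConfig) -> list[MultiChannelImage]:
    if config.simulation is not None:
        master = np.random.default_rng(config.seed)
        seeds = master.integers(0, 2**31 - 1, size=config.n_images)
        return [
            simulate_image(config.simulation, int(s), source_id=f"sim_{i:03d}")[0]
            for i, s in enumerate(seeds)
        ]
    return [read_image(p, channel_map=config.channel_map) for p in config.images]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and assemble a :class:`RunReport`.

    Any stage failure is re-raised with the stage name and offending
    input; an empty effective-pixel set is not a failure — the fit is
    skipped and the reason recorded in the report notes.
    """
    notes: list[str] = []
    t0 = time.perf_counter()

    stage = "load"
    try:
        images = _load_inputs(config)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("stage load: %d image(s) in %.2fs", len(images), time.perf_counter() - t0)

    count_rows, island_frames, pair_frames = [], [], []
    for img in images:
        stage = f"analyze:{img.source_id}"
        try:
            t1 = time.perf_counter()
            mask = effective_mask(img, config.threshold)
            counts = coloc_counts(img, config.threshold)
            count_rows.append(counts.as_record())
            islands = island_stats(
                find_islands(mask, config.connectivity, config.min_island_size), img
            )
            frame = islands.to_frame()
            if len(frame):
                frame.insert(0, "source_id", img.source_id)
            island_frames.append(frame)

            if config.fit_unit == "pixel":
                pairs = extract_pairs(img, mask, islands)
            else:
                col = "max" if config.fit_unit == "island_max" else "mean"
                pairs = pd.DataFrame(
                    {
                        "n_aie": [getattr(isl, f"{col}_probe") for isl in islands],
                        "n_pfak": [getattr(isl, f"{col}_pfak") for isl in islands],
                        "source_id": img.source_id,
                        "island_id": pd.array(
                            [isl.island_id for isl in islands], dtype="Int64"
                        ),
                    }
                )
            pair_frames.append(pairs)
            logger.info(
                "stage %s: n0=%d, %d island(s), %d pair(s) in %.2fs",
                stage, counts.n0, len(islands), len(pairs), time.perf_counter() - t1,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage {stage!r} failed on input {img.source_id!r}: {exc}") from exc

    counts_frame = pd.DataFrame(count_rows)
    islands_frame = (
        pd.concat(island_frames, ignore_index=True) if island_frames else pd.DataFrame()
    )
    pooled = pool_pairs(pair_frames)

    stage = "fit"
    fit_dict = correlation = None
    if len(pooled) == 0:
        notes.append("no effective pixels: intensity fit skipped")
    else:
        try:
            fit = fit_quadratic(pooled, degree=config.fit_degree)
            fit_dict = fit.as_dict()
            correlation = correlation_report(
                pooled, fit, n_permutations=config.permutations, seed=config.seed
            )
        except ValueError as exc:
            notes.append(f"intensity fit skipped: {exc}")
    logger.info("stage fit: %s", fit_dict or notes[-1:])

    provenance = {
        "config": config.analysis_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    report = RunReport(
        counts=counts_frame,
        islands=islands_frame,
        pairs=pooled,
        fit=fit_dict,
        correlation=correlation,
        notes=notes,
        provenance=provenance,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pixel_table(counts_frame, out / "counts.csv")
        write_pixel_table(
            islands_frame if len(islands_frame) else pd.DataFrame(columns=["island_id"]),
            out / "islands.csv",
        )
        write_pixel_table(pooled, out / "pairs.csv")
        (out / "fit.json").write_text(json.dumps({"fit": fit_dict, "correlation": correlation}, indent=1))
        (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=1))
        logger.info("wrote outputs to %s", out)

    logger.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return report


def _rates(report: RunReport, statistic: str) -> np.ndarray:
    if statistic not in ("rate_r", "rate_g", "rate_b"):
        raise ValueError(f"statistic must be a rate index, got {statistic!r}")
    values = report.counts[statistic].to_numpy(dtype=float)
    return values[~np.isnan(values)]


def compare_groups(
    report_a: RunReport,
    report_b: RunReport,
    statistic: str = "rate_b",
    n_permutations: int = 9999,
    seed: int = 0,
) -> dict:
    """Compare a colocalization rate index between two runs.

    Returns per-group means, their difference (a minus b), and a
    two-sided permutation p-value obtained by shuffling image labels.
    The p-value is ``None`` when either group has fewer than 2 images.
    """
    a = _rates(report_a, statistic)
    b = _rates(report_b, statistic)
    if a.size == 0 or b.size == 0:
        raise ValueError("both reports must contain at least one image with a defined rate")
    diff = float(a.mean() - b.mean())
    result = {
        "statistic": statistic,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "difference": diff,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "n_permutations": int(n_permutations),
        "permutation_p": None,
    }
    if a.size < 2 or b.size < 2:
        return result
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        d = perm[: a.size].mean() - perm[a.size :].mean()
        if abs(d) >= abs(diff) - 1e-12:
            hits += 1
    result["permutation_p"] = (1 + hits) / (n_permutations + 1)
    return result


def fold_change(value: float, baseline: float) -> float:
    """Ratio of ``value`` to a positive ``baseline`` (e.g. absorbance gain)."""
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    if value < 0:
        raise ValueError(f"value must be >= 0, got {value}")
    return value / baseline
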