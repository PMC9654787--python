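"""Probe-vs-pFAK intensity model over effective pixels.

At every effective pixel the probe intensity (horizontal axis) and the
pFAK intensity (vertical axis) form one observation; observations are
pooled across images and a quadratic is fit by ordinary least squares,

    pFAK = a0 + a1 * probe + a2 * probe**2 .

Intensities are unitless confocal counts and are not normalized before
fitting, so the fit is scale-agnostic.  Inference is deliberately
non-parametric: coefficient standard errors come from a case-resampling
bootstrap, and the positive-correlation claim is tested by a seeded
permutation of the response, because per-pixel observations within one
punctum are spatially dependent and a parametric t-test on r would
overstate the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import MultiChannelImage
from .islands import IslandSet
from .metrics import EffectiveMask

__all__ = [
    "PAIR_COLUMNS",
    "IntensityFit",
    "extract_pairs",
    "pool_pairs",
    "fit_quadratic",
    "predict_pfak",
    "bootstrap_coefficient_se",
    "correlation_report",
]

#: Schema of an intensity-pair table.
PAIR_COLUMNS = ("n_aie", "n_pfak", "source_id", "island_id")


@dataclass
class IntensityFit:
    """Coefficients and diagnostics of the quadratic intensity model.

    ``a2`` is 0.0 for a degree-1 fit.  ``pearson_r`` is ``None`` when
    either variable has zero variance.
    """

    a0: float
    a1: float
    a2: float
    degree: int
    n_points: int
    r2: float
    pearson_r: Optional[float]
    residual_sd: float

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2][: self.degree + 1])

    def as_dict(self) -> dict:
        return {
            "a0": self.a0,
            "a1": self.a1,
            "a2": self.a2,
            "degree": self.degree,
            "n_points": self.n_points,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
            "residual_sd": self.residual_sd,
        }


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "n_aie": pd.Series(dtype=np.int64),
            "n_pfak": pd.Series(dtype=np.int64),
            "source_id": pd.Series(dtype=object),
            "island_id": pd.Series(dtype="Int64"),
        }
    )


def extract_pairs(
    img: MultiChannelImage,
    mask: EffectiveMask,
    islands: Optional[IslandSet] = None,
) -> pd.DataFrame:
    """One (probe, pFAK) intensity pair per effective pixel.

    Rows appear in raster order.  With ``islands`` supplied each pair is
    annotated with the id of the island containing its pixel (pandas
    nullable Int64; <NA> without islands).
    """
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    rows, cols = np.nonzero(mask.flags)
    pairs = _empty_pairs()
    if rows.size == 0:
        return pairs
    pairs = pd.DataFrame(
        {
            "n_aie": img.probe[rows, cols].astype(np.int64),
            "n_pfak": img.pfak[rows, cols].astype(np.int64),
            "source_id": img.source_id,
            "island_id": pd.array([pd.NA] * rows.size, dtype="Int64"),
        }
    )
    if islands is not None:
        label_img = islands.label_image()
        pairs["island_id"] = pd.array(label_img[rows, cols], dtype="Int64")
    return pairs


def pool_pairs(per_image_pairs: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-image pair tables, preserving source_id and order."""
    frames = [f for f in per_image_pairs]
    if not frames:
        return _empty_pairs()
    return pd.concat(frames, ignore_index=True)


def _design(x: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(x, degree + 1, increasing=True)


def fit_quadratic(pairs: pd.DataFrame, degree: int = 2) -> IntensityFit:
    """Ordinary least squares of pFAK intensity on powers of probe intensity.

    Requires at least ``degree + 1`` pairs with at least ``degree + 1``
    distinct probe values; otherwise the design is rank-deficient and a
    ``ValueError`` is raised.
    """
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    x = np.asarray(pairs["n_aie"], dtype=np.float64)
    y = np.asarray(pairs["n_pfak"], dtype=np.float64)
    n = x.size
    n_distinct = np.unique(x).size
    if n < degree + 1 or n_distinct < degree + 1:
        raise ValueError(
            f"rank-deficient design: need >= {degree + 1} pairs with >= {degree + 1} "
            f"distinct probe intensities, got n={n} with {n_distinct} distinct"
        )
    X = _design(x, degree)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    pearson = None
    if x.std() > 0 and y.std() > 0:
        pearson = float(stats.pearsonr(x, y).statistic)
    coef = np.zeros(3)
    coef[: degree + 1] = beta
    return IntensityFit(
        a0=float(coef[0]),
        a1=float(coef[1]),
        a2=float(coef[2]),
        degree=degree,
        n_points=int(n),
        r2=r2,
        pearson_r=pearson,
        residual_sd=float(np.sqrt(ss_res / n)),
    )


def predict_pfak(fit: IntensityFit, n_aie):
    """Predicted pFAK intensity a0 + a1*x + a2*x**2 at probe intensity x."""
    x = np.asarray(n_aie, dtype=np.float64)
    out = fit.a0 + fit.a1 * x + fit.a2 * x**2
    return float(out) if np.isscalar(n_aie) or out.ndim == 0 else out


def bootstrap_coefficient_se(
    pairs: pd.DataFrame,
    degree: int = 2,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Case-resampling bootstrap standard errors of the fit coefficients.

    Returns an array of length ``degree + 1``.  Resamples pairs with
    replacement; replicates whose resample is rank-deficient are redrawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(pairs["n_aie"], dtype=np.float64)
    y = np.asarray(pairs["n_pfak"], dtype=np.float64)
    n = x.size
    if n < degree + 1:
        raise ValueError(f"need at least {degree + 1} pairs to bootstrap")
    betas = np.empty((n_boot, degree + 1))
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, n)
        xs = x[idx]
        if np.unique(xs).size < degree + 1:
            continue
        X = _design(xs, degree)
        betas[done], *_ = np.linalg.lstsq(X, y[idx], rcond=None)
        done += 1
    return betas.std(axis=0, ddof=1)


def correlation_report(
    pairs: pd.DataFrame,
    fit: IntensityFit,
    n_permutations: int = 9999,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Summary of the probe/pFAK correlation with a permutation p-value.

    The null shuffles the pFAK values against the probe values
    (label-exchange); the p-value is one-sided for positive correlation,
    ``(1 + #{r_perm >= r_obs}) / (B + 1)``.  A constant channel yields a
    ``None`` correlation and p-value.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(pairs)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(pairs["n_aie"], dtype=np.float64)
    y = np.asarray(pairs["n_pfak"], dtype=np.float64)
    per_image = pairs.groupby("source_id", sort=False).size().to_dict()

    report = {
        "pearson_r": fit.pearson_r,
        "permutation_p": None,
        "n_permutations": int(n_permutations),
        "n_points": int(len(pairs)),
        "per_image_counts": per_image,
        "r2": fit.r2,
    }
    if fit.pearson_r is None:
        return report

    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    r_obs = (xc @ yc) / denom
    hits = 0
    for _ in range(n_permutations):
        r_perm = (xc @ rng.permutation(yc)) / denom
        if r_perm >= r_obs - 1e-12:
            hits += 1
    report["permutation_p"] = (1 + hits) / (n_permutations + 1)
    return report
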