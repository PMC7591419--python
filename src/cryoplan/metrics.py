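"""Volumetric and surface validation metrics between a reference ablation
zone S and a simulated zone Sigma.

Volumetric overlap:

    DSC = 2|S ∩ Σ| / (|S| + |Σ|)      symmetric Dice coefficient
    TO  = |S ∩ Σ| / |S|               target overlap ("sensitivity");
                                       low values mean S is underestimated
    PPV = |S ∩ Σ| / |Σ|               positive predictive value;
                                       low values mean S is overestimated

Surface agreement is the absolute average error (AAE): the mean
symmetric distance between the face-boundary voxel centres of the two
masks, in mm.

Each ratio is rated on the ordinal scale excellent (>= 0.8), good
([0.7, 0.8)), adequate ([0.6, 0.7)), inadequate ([0.5, 0.6)), poor
(< 0.5); a perfect value of 1.0 rates excellent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .zones import AblationMask, boundary_voxels

__all__ = [
    "RATING_LEVELS",
    "ValidationResult",
    "dsc",
    "target_overlap",
    "ppv",
    "aae",
    "rate",
    "metrics_from_volumes",
    "metrics_from_masks",
    "summarize_cohort",
]

#: ordinal rating levels, worst to best
RATING_LEVELS = ("poor", "inadequate", "adequate", "good", "excellent")

#: lower bin edges for (inadequate, adequate, good, excellent)
_RATING_EDGES = (0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class ValidationResult:
    """All metrics for one case. ``aae_mm`` is None for volumes-only input."""

    vol_S_cm3: float
    vol_Sigma_cm3: float
    vol_overlap_cm3: float
    dsc: float
    to: float
    ppv: float
    aae_mm: float | None
    rating_dsc: str
    rating_to: str
    rating_ppv: str

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(S: AblationMask, Sigma: AblationMask) -> None:
    if not S.grid.same_geometry(Sigma.grid):
        raise ValueError(
            f"masks live on different grids: {S.grid} vs {Sigma.grid}"
        )


def dsc(S: AblationMask, Sigma: AblationMask) -> float:
    """Dice similarity coefficient 2|S ∩ Σ|/(|S| + |Σ|)."""
    _check_pair(S, Sigma)
    nS, nSig = S.count, Sigma.count
    if nS + nSig == 0:
        raise ValueError("DSC undefined: both masks are empty")
    overlap = int(np.logical_and(S.voxels, Sigma.voxels).sum())
    return 2.0 * overlap / (nS + nSig)


def target_overlap(S: AblationMask, Sigma: AblationMask) -> float:
    """Target overlap |S ∩ Σ|/|S|; low values mean S is underestimated."""
    _check_pair(S, Sigma)
    nS = S.count
    if nS == 0:
        raise ValueError("target overlap undefined: reference mask S is empty")
    return int(np.logical_and(S.voxels, Sigma.voxels).sum()) / nS


def ppv(S: AblationMask, Sigma: AblationMask) -> float:
    """Positive predictive value |S ∩ Σ|/|Σ|; low values mean S is overestimated."""
    _check_pair(S, Sigma)
    nSig = Sigma.count
    if nSig == 0:
        raise ValueError("PPV undefined: simulated mask Sigma is empty")
    return int(np.logical_and(S.voxels, Sigma.voxels).sum()) / nSig


def aae(S: AblationMask, Sigma: AblationMask) -> float:
    """Absolute average error: mean symmetric surface distance in mm.

    Boundary voxels (6-connectivity face boundary) of each mask are
    taken as surface point sets at their voxel centres; each point
    contributes its Euclidean distance to the nearest point of the other
    surface, and the mean is taken over both directions weighted by
    point counts.
    """
    _check_pair(S, Sigma)
    if S.is_empty() or Sigma.is_empty():
        raise ValueError("AAE undefined for an empty mask")
    pts_S = S.grid.voxel_centers_mm(boundary_voxels(S))
    pts_Sig = Sigma.grid.voxel_centers_mm(boundary_voxels(Sigma))
    d_S, _ = cKDTree(pts_Sig).query(pts_S)
    d_Sig, _ = cKDTree(pts_S).query(pts_Sig)
    return float((d_S.sum() + d_Sig.sum()) / (len(d_S) + len(d_Sig)))


def rate(value: float) -> str:
    """Ordinal rating of an overlap ratio in [0, 1]."""
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"overlap ratios lie in [0, 1], got {value}")
    level = 0
    for edge in _RATING_EDGES:
        if value >= edge:
            level += 1
    return RATING_LEVELS[level]


def _result_from_volumes(
    vol_S: float, vol_Sigma: float, vol_overlap: float, aae_mm: float | None
) -> ValidationResult:
    d = 2.0 * vol_overlap / (vol_S + vol_Sigma)
    to = vol_overlap / vol_S
    p = vol_overlap / vol_Sigma
    return ValidationResult(
        vol_S_cm3=vol_S,
        vol_Sigma_cm3=vol_Sigma,
        vol_overlap_cm3=vol_overlap,
        dsc=d,
        to=to,
        ppv=p,
        aae_mm=aae_mm,
        rating_dsc=rate(d),
        rating_to=rate(to),
        rating_ppv=rate(p),
    )


def metrics_from_volumes(
    vol_S_cm3: float, vol_Sigma_cm3: float, vol_overlap_cm3: float
) -> ValidationResult:
    """Compute the volumetric metrics from printed volumes alone.

    Useful for consistency checks when only case volumes are reported;
    the surface metric needs masks and is left as None.
    """
    if vol_S_cm3 <= 0 or vol_Sigma_cm3 <= 0:
        raise ValueError("volumes must be positive")
    if not (0.0 <= vol_overlap_cm3 <= min(vol_S_cm3, vol_Sigma_cm3)):
        raise ValueError(
            f"overlap {vol_overlap_cm3} cm3 exceeds a mask volume "
            f"(S={vol_S_cm3}, Sigma={vol_Sigma_cm3})"
        )
    return _result_from_volumes(vol_S_cm3, vol_Sigma_cm3, vol_overlap_cm3, None)


def metrics_from_masks(S: AblationMask, Sigma: AblationMask) -> ValidationResult:
    """Full validation of a mask pair: volumes, DSC/TO/PPV, AAE, ratings."""
    _check_pair(S, Sigma)
    if S.is_empty() or Sigma.is_empty():
        raise ValueError("validation requires two non-empty masks")
    vv = S.grid.voxel_volume_cm3
    overlap = int(np.logical_and(S.voxels, Sigma.voxels).sum())
    return _result_from_volumes(
        S.count * vv, Sigma.count * vv, overlap * vv, aae(S, Sigma)
    )


def summarize_cohort(results: list[ValidationResult]) -> pd.DataFrame:
    """Cohort summary: mean/SD per metric plus per-rating-bin counts.

    SD is the sample standard deviation (ddof=1); 0 for a single case.
    Returns a tidy frame indexed by metric with columns ``mean``, ``sd``
    and one ``n_<rating>`` / ``pct_<rating>`` pair per ordinal level.
    """
    if not results:
        raise ValueError("cannot summarise an empty cohort")
    n = len(results)
    rows = {}
    for metric in ("dsc", "to", "ppv"):
        values = np.array([getattr(r, metric) for r in results], dtype=float)
        ratings = [getattr(r, f"rating_{metric}") for r in results]
        row = {
            "mean": values.mean(),
            "sd": values.std(ddof=1) if n > 1 else 0.0,
        }
        for level in RATING_LEVELS:
            c = ratings.count(level)
            row[f"n_{level}"] = c
            row[f"pct_{level}"] = 100.0 * c / n
        rows[metric] = row
    aae_vals = np.array(
        [r.aae_mm for r in results if r.aae_mm is not None], dtype=float
    )
    if aae_vals.size:
        rows["aae_mm"] = {
            "mean": aae_vals.mean(),
            "sd": aae_vals.std(ddof=1) if aae_vals.size > 1 else 0.0,
        }
    for vol in ("vol_S_cm3", "vol_Sigma_cm3"):
        values = np.array([getattr(r, vol) for r in results], dtype=float)
        rows[vol] = {
            "mean": values.mean(),
            "sd": values.std(ddof=1) if n > 1 else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
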