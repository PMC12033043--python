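"""Ambit assignment, prediction merging, cost function and quality metrics.

Observed Bragg spots get disjoint circular neighborhoods ("ambits") of
radius r_a; every predicted reflection whose centroid falls strictly inside
an ambit contributes to that spot, all others are "no hits".  The cost
function combines intensity residuals over matched spots, optionally the
intensity of unmatched predictions, and position residuals:

    S = S(I, hits) + w2 * S(I, nohits) + wP * S(P)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "ReducedData",
    "AmbitAssignment",
    "CostBreakdown",
    "ControlParams",
    "default_ambit_radius",
    "assign_predictions",
    "merge_assigned",
    "cost_function",
    "quality_metrics",
]


@dataclass(frozen=True)
class ReducedData:
    """Observed spot list of one image: ids, detector coordinates (pixels)
    and integrated intensities (arbitrary units, > 0)."""

    spot_ids: tuple
    xy: np.ndarray          # (N, 2) float
    intensity: np.ndarray   # (N,)
    in_mask: np.ndarray = None

    def __post_init__(self):
        xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        I = np.asarray(self.intensity, dtype=float)
        if len(xy) != len(I) or len(xy) != len(self.spot_ids):
            raise ValueError("spot_ids, xy and intensity lengths differ")
        if len(set(self.spot_ids)) != len(self.spot_ids):
            raise ValueError("spot_ids must be unique within an image")
        if np.any(I <= 0):
            raise ValueError("observed intensities must be > 0")
        mask = self.in_mask
        mask = np.zeros(len(I), dtype=bool) if mask is None \
            else np.asarray(mask, dtype=bool)
        object.__setattr__(self, "xy", xy)
        object.__setattr__(self, "intensity", I)
        object.__setattr__(self, "in_mask", mask)

    def __len__(self):
        return len(self.intensity)

    def active(self) -> "ReducedData":
        """Spots outside the detector mask."""
        if not self.in_mask.any():
            return self
        keep = ~self.in_mask
        return ReducedData(tuple(s for s, k in zip(self.spot_ids, keep) if k),
                           self.xy[keep], self.intensity[keep])


def default_ambit_radius(spots: ReducedData) -> float:
    """Largest radius with pairwise disjoint ambits: half the minimum
    pairwise spot distance."""
    if len(spots) < 2:
        raise ValueError(
            "default ambit radius needs >= 2 spots; set the ambit explicitly")
    return float(pdist(spots.xy).min() / 2.0)


@dataclass(frozen=True)
class AmbitAssignment:
    """Partition of prediction indices into per-spot sets and no-hits."""

    r_a: float
    J_io: tuple            # tuple of np.ndarray, one per spot
    J_nohits: np.ndarray
    n_predictions: int

    def counts(self) -> np.ndarray:
        return np.array([len(j) for j in self.J_io])


def assign_predictions(pred_xy: np.ndarray, spots: ReducedData, r_a: float,
                       pred_masked: np.ndarray | None = None) -> AmbitAssignment:
    """Assign predictions to spot ambits (strict inequality, Euclidean).

    ``r_a`` is clipped down to the non-overlap maximum with a warning.
    Predictions flagged in ``pred_masked`` are discarded (they belong to
    neither an ambit nor the no-hits set of the cost function).
    """
    pred_xy = np.atleast_2d(np.asarray(pred_xy, dtype=float))
    n_pred = len(pred_xy)
    if len(spots) >= 2:
        r_max = default_ambit_radius(spots)
        if r_a > r_max:
            logger.warning("ambit radius %.3g overlaps; clipped to %.3g",
                           r_a, r_max)
            r_a = r_max
    alive = np.ones(n_pred, dtype=bool)
    if pred_masked is not None:
        alive &= ~np.asarray(pred_masked, dtype=bool)
    J_io: list[np.ndarray] = [np.empty(0, dtype=int) for _ in range(len(spots))]
    if n_pred and len(spots) and alive.any():
        tree = cKDTree(spots.xy)
        dist, nearest = tree.query(pred_xy)
        hit = alive & (dist < r_a)          # strict: dist == r_a is no hit
        for s in range(len(spots)):
            J_io[s] = np.flatnonzero(hit & (nearest == s))
        nohits = np.flatnonzero(alive & ~hit)
    else:
        nohits = np.flatnonzero(alive)
    return AmbitAssignment(r_a=float(r_a), J_io=tuple(J_io),
                           J_nohits=nohits, n_predictions=int(alive.sum()))


@dataclass(frozen=True)
class MergedSpots:
    """Per observed spot: summed intensity and intensity-weighted centroid."""

    I_clc: np.ndarray
    xy_clc: np.ndarray        # NaN where unmatched
    matched: np.ndarray       # bool


def merge_assigned(assignment: AmbitAssignment, pred_xy: np.ndarray,
                   pred_I: np.ndarray) -> MergedSpots:
    n = len(assignment.J_io)
    I_clc = np.zeros(n)
    xy_clc = np.full((n, 2), np.nan)
    matched = np.zeros(n, dtype=bool)
    for s, J in enumerate(assignment.J_io):
        if len(J) == 0:
            continue
        Is = pred_I[J]
        tot = Is.sum()
        I_clc[s] = tot
        if tot > 0:
            xy_clc[s] = (pred_xy[J] * Is[:, None]).sum(axis=0) / tot
            matched[s] = True
    return MergedSpots(I_clc=I_clc, xy_clc=xy_clc, matched=matched)


@dataclass(frozen=True)
class ControlParams:
    """Control parameters of one setting (resolution range, ambit, cost
    weights and model flags)."""

    dmin: float = 0.5
    dmax: float = math.inf
    ambit: float | None = None      # pixels; None = automatic maximum
    mask: bool = False
    target: str = "I"               # "I" or "sqrt(I)"
    pos_weight: float = 0.0         # w_P
    fpred_weight: float = 0.0       # w2
    aniso: bool = False
    tilt_use: bool = False
    k0_corr: bool = False
    omg_corr: bool = False

    def __post_init__(self):
        if self.target not in ("I", "sqrt(I)"):
            raise ValueError(f"target must be 'I' or 'sqrt(I)', got {self.target!r}")
        if self.pos_weight < 0 or self.fpred_weight < 0:
            raise ValueError("weights must be >= 0")
        if not 0 < self.dmin < self.dmax:
            raise ValueError("need 0 < dmin < dmax")


@dataclass(frozen=True)
class CostBreakdown:
    S_I_hits: float
    S_I_nohits: float
    S_P: float
    target: str
    w_P: float
    w2: float
    residuals_I: np.ndarray = field(repr=False, default=None)
    residuals_P: np.ndarray = field(repr=False, default=None)

    @property
    def S_total(self) -> float:
        return self.S_I_hits + self.w2 * self.S_I_nohits + self.w_P * self.S_P


def cost_function(merged: MergedSpots, spots: ReducedData,
                  assignment: AmbitAssignment, pred_I: np.ndarray,
                  control: ControlParams) -> CostBreakdown:
    """Evaluate the combined intensity+position cost for one image.

    target="I": residuals (I_clc - I_obs) weighted by I_obs^(-1/2);
    target="sqrt(I)": residuals (sqrt(I_clc) - sqrt(I_obs)), whose no-hit
    limit is the plain predicted intensity.  Unmatched spots contribute
    r_a^2 to the position sum.
    """
    I_obs = spots.intensity
    I_clc = merged.I_clc
    if control.target == "I":
        res_I = (I_clc - I_obs) * I_obs ** -0.25
        S_nohits = float(np.sum(pred_I[assignment.J_nohits] ** 2))
    else:
        res_I = np.sqrt(I_clc) - np.sqrt(I_obs)
        S_nohits = float(np.sum(pred_I[assignment.J_nohits]))
    S_hits = float(np.sum(res_I ** 2))
    d2 = np.where(merged.matched,
                  np.sum((merged.xy_clc - spots.xy) ** 2, axis=1),
                  assignment.r_a ** 2)
    S_P = float(np.sum(d2))
    return CostBreakdown(S_I_hits=S_hits, S_I_nohits=S_nohits, S_P=S_P,
                         target=control.target, w_P=control.pos_weight,
                         w2=control.fpred_weight, residuals_I=res_I,
                         residuals_P=np.sqrt(d2))


def quality_metrics(merged: MergedSpots, spots: ReducedData) -> dict:
    """Linear-scale R factors and matched fraction.

    R_I = sum |k I_clc - I_obs| / sum I_obs with k the least-squares scale
    over matched spots; R_sqrtI is the analogue on square roots.  Returns
    ``{"reason": ...}`` entries when undefined (no matched spots).
    """
    m = merged.matched & (merged.I_clc > 0)
    out = {"matched_fraction": float(np.mean(merged.matched))
           if len(spots) else 0.0}
    if not m.any():
        out.update(R_I=None, R_sqrtI=None, reason="no matched spots")
        return out
    Ic, Io = merged.I_clc[m], spots.intensity[m]
    k = float(np.dot(Ic, Io) / np.dot(Ic, Ic))
    out["R_I"] = float(np.sum(np.abs(k * Ic - Io)) / np.sum(Io))
    sc, so = np.sqrt(Ic), np.sqrt(Io)
    ks = float(np.dot(sc, so) / np.dot(sc, sc))
    out["R_sqrtI"] = float(np.sum(np.abs(ks * sc - so)) / np.sum(so))
    return out
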