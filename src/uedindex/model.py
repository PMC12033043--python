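"""Nonlinear least-squares refinement of a diffraction-pattern model.

`PatternModel` couples observed reduced data (one image or a tilt series)
with a crystal structure and a starting setting; `fit` minimizes the
combined intensity+position cost over a chosen set of free parameters by
trust-region least squares, re-assigning predictions to spot ambits at
every evaluation.  The returned `PatternFitResults` carries the parameter
listing before/after, the cost breakdown, R factors and the per-spot
decomposition into contributing reflections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .crystal import CrystalStructure, reflection_table
from .geometry import OrientationAngles
from .matching import (AmbitAssignment, ControlParams, CostBreakdown,
                       ReducedData, assign_predictions, cost_function,
                       default_ambit_radius, merge_assigned, quality_metrics)
from .workbench import DetectorMask, Setting, predict_setting

__all__ = ["PatternModel", "PatternFitResults", "geofit", "per_spot_report"]


# ---------------------------------------------------------------------------
# Parameter registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Param:
    name: str
    get: callable              # Setting -> float
    set: callable              # (Setting, float) -> Setting
    lo: float = -np.inf
    hi: float = np.inf
    scale: float = 1.0         # typical magnitude (trust-region x_scale)
    step: float = 1e-6         # forward-difference step (absolute)
    multi_image_only: bool = False


def _set_model(s: Setting, **kw) -> Setting:
    return replace(s, model=s.model.update(**kw))


def _set_ori(which):
    def setter(s, v):
        o = s.model.orientation
        kw = {"theta": o.theta, "phi": o.phi, "psi": o.psi}
        kw[which] = v
        if which == "theta":
            kw["theta"] = min(max(v, 0.0), 180.0)
        return _set_model(s, orientation=OrientationAngles(**kw))
    return setter


def _set_mos_iso(s, v):
    return _set_model(s, mosaicity=replace(s.model.mosaicity,
                                           sigma_iso_deg=v))


def _mos_vec(i, kind):
    def getter(s):
        m = s.model.mosaicity
        return (m.sigmas_deg if kind == "sig" else m.euler_deg)[i]

    def setter(s, v):
        m = s.model.mosaicity
        vals = list(m.sigmas_deg if kind == "sig" else m.euler_deg)
        vals[i] = v
        key = "sigmas_deg" if kind == "sig" else "euler_deg"
        return _set_model(s, mosaicity=replace(m, **{key: tuple(vals)}))
    return getter, setter


def _shp_vec(i, kind):
    def getter(s):
        m = s.model.shape
        return (m.sigmas if kind == "sig" else m.euler_deg)[i]

    def setter(s, v):
        m = s.model.shape
        vals = list(m.sigmas if kind == "sig" else m.euler_deg)
        vals[i] = v
        key = "sigmas" if kind == "sig" else "euler_deg"
        return _set_model(s, shape=replace(m, **{key: tuple(vals)}))
    return getter, setter


def _tilt_corr(i, kind):
    def getter(s):
        t = s.model.tilt
        return (t.scale_corrections if kind == "scale"
                else t.omega_corrections)[i]

    def setter(s, v):
        t = s.model.tilt
        vals = list(t.scale_corrections if kind == "scale"
                    else t.omega_corrections)
        vals[i] = v
        key = ("scale_corrections" if kind == "scale"
               else "omega_corrections")
        return _set_model(s, tilt=replace(t, **{key: tuple(vals)}))
    return getter, setter


def parameter_registry(setting: Setting, n_images: int = 1) -> dict:
    """Fittable parameters for this setting (mirrors the model-parameter
    table: orientation, beam center, magnification, image rotation,
    distortion, mosaicity, shape, scale, B factor, per-image corrections;
    the tilt-axis direction is never fittable)."""
    m = setting.model
    reg: list[_Param] = [
        _Param("theta", lambda s: s.model.orientation.theta,
               _set_ori("theta"), 0.0, 180.0, 1.0, 1e-3),
        _Param("phi", lambda s: s.model.orientation.phi,
               _set_ori("phi"), -np.inf, np.inf, 1.0, 1e-3),
        _Param("psi", lambda s: s.model.orientation.psi,
               _set_ori("psi"), -np.inf, np.inf, 1.0, 1e-3),
        _Param("beam_center_x", lambda s: s.model.beam_center[0],
               lambda s, v: _set_model(s, beam_center=(v, s.model.beam_center[1])),
               -np.inf, np.inf, 10.0, 1e-3),
        _Param("beam_center_y", lambda s: s.model.beam_center[1],
               lambda s, v: _set_model(s, beam_center=(s.model.beam_center[0], v)),
               -np.inf, np.inf, 10.0, 1e-3),
        _Param("magnification", lambda s: s.model.magnification,
               lambda s, v: _set_model(s, magnification=v),
               1e-6, np.inf, 1.0, 1e-6),
        _Param("image_rotation", lambda s: s.model.image_rotation_deg,
               lambda s, v: _set_model(s, image_rotation_deg=v),
               -np.inf, np.inf, 1.0, 1e-3, multi_image_only=True),
        _Param("distortion_eps", lambda s: s.model.distortion_eps,
               lambda s, v: _set_model(s, distortion_eps=v),
               -0.2, 0.2, 0.01, 1e-6),
        _Param("distortion_phi0", lambda s: s.model.distortion_phi0_deg,
               lambda s, v: _set_model(s, distortion_phi0_deg=v),
               -np.inf, np.inf, 10.0, 1e-3),
        _Param("scale", lambda s: s.model.scale,
               lambda s, v: _set_model(s, scale=v),
               1e-12, np.inf, max(abs(m.scale), 1.0), 1e-6),
        _Param("b_factor", lambda s: s.model.b_factor,
               lambda s, v: _set_model(s, b_factor=v),
               -np.inf, np.inf, 1.0, 1e-6),
    ]
    if m.mosaicity.mode == "isotropic":
        reg.append(_Param("sigma_mos",
                          lambda s: s.model.mosaicity.sigma_iso_deg,
                          _set_mos_iso, 0.0, np.inf, 1.0, 1e-3))
    else:
        for i in range(3):
            g, st = _mos_vec(i, "sig")
            reg.append(_Param(f"mos_sig{i + 1}", g, st, 0.0, np.inf, 1.0, 1e-3))
            g, st = _mos_vec(i, "eul")
            reg.append(_Param(f"mos_eul{i + 1}", g, st, -np.inf, np.inf,
                              10.0, 1e-3))
    if m.shape.mode == "standard":
        reg.append(_Param("sigma_shp", lambda s: s.model.shape.sigma_shp,
                          lambda s, v: _set_model(
                              s, shape=replace(s.model.shape, sigma_shp=v)),
                          0.0, np.inf, max(m.shape.sigma_shp, 1e-3), 1e-6))
        reg.append(_Param("shape_tilt", lambda s: s.model.shape.tilt_deg,
                          lambda s, v: _set_model(
                              s, shape=replace(s.model.shape, tilt_deg=v)),
                          -90.0, 90.0, 1.0, 1e-3))
        reg.append(_Param("shape_azimuth", lambda s: s.model.shape.azimuth_deg,
                          lambda s, v: _set_model(
                              s, shape=replace(s.model.shape, azimuth_deg=v)),
                          -np.inf, np.inf, 10.0, 1e-3))
    else:
        for i in range(3):
            g, st = _shp_vec(i, "sig")
            reg.append(_Param(f"shp_sig{i + 1}", g, st, 0.0, np.inf,
                              max(max(m.shape.sigmas), 1e-3), 1e-6))
            g, st = _shp_vec(i, "eul")
            reg.append(_Param(f"shp_eul{i + 1}", g, st, -np.inf, np.inf,
                              10.0, 1e-3))
    if m.tilt is not None and n_images > 1:
        for i in range(1, n_images):
            g, st = _tilt_corr(i, "scale")
            reg.append(_Param(f"scale_corr_{i + 1}", g, st, 1e-6, np.inf,
                              1.0, 1e-6, multi_image_only=True))
            g, st = _tilt_corr(i, "omega")
            reg.append(_Param(f"omega_corr_{i + 1}", g, st, -np.inf, np.inf,
                              0.1, 1e-3, multi_image_only=True))
    return {p.name: p for p in reg}


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PatternModel:
    """Diffraction-pattern model bound to observed data.

    Parameters
    ----------
    data : ReducedData or list of ReducedData
        Observed spot lists (one per image of a tilt series).
    structure : CrystalStructure
    setting : Setting
        Starting model + control parameters.
    mask : DetectorMask, optional
    """

    def __init__(self, data, structure: CrystalStructure, setting: Setting,
                 mask: DetectorMask | None = None):
        self.datasets = [data] if isinstance(data, ReducedData) else list(data)
        if not self.datasets:
            raise ValueError("no reduced data given")
        n_img = len(self.datasets)
        if n_img > 1 and setting.model.tilt is None:
            raise ValueError("multi-image data needs a TiltState in the model")
        if setting.model.tilt is not None and \
                setting.model.tilt.n_images != n_img:
            raise ValueError("tilt state image count != number of data sets")
        self.structure = structure
        self.setting = setting
        self.mask = mask
        self._refl = reflection_table(structure, setting.control.dmin,
                                      setting.control.dmax)
        if self.mask is not None and setting.control.mask:
            self.datasets = [self._strip_masked(d) for d in self.datasets]
        self._r_a = [setting.control.ambit or default_ambit_radius(d)
                     for d in self.datasets]

    @classmethod
    def from_project(cls, project, setting: Setting | None = None):
        setting = setting or (project.settings[-1] if project.settings
                              else Setting())
        data = [project.reduced_data(i) for i in range(project.n_images)]
        return cls(data, project.structure(), setting, mask=project.mask())

    def _strip_masked(self, d: ReducedData) -> ReducedData:
        inside = self.mask.contains(d.xy)
        keep = ~inside
        return ReducedData(tuple(s for s, k in zip(d.spot_ids, keep) if k),
                           d.xy[keep], d.intensity[keep])

    # -- evaluation ---------------------------------------------------------

    def _evaluate(self, setting: Setting):
        """Predictions, assignments, merges and cost for every image."""
        ctrl = setting.control
        out = []
        for img, (spots, r_a) in enumerate(zip(self.datasets, self._r_a)):
            pred = predict_setting(setting, self.structure, image_index=img,
                                   refl_cache=self._refl)
            geom = setting.model.geometry()
            xy = pred.detector_xy(geom)
            masked = None
            if ctrl.mask and self.mask is not None:
                masked = self.mask.contains(xy)
            assignment = assign_predictions(xy, spots, r_a, pred_masked=masked)
            merged = merge_assigned(assignment, xy, pred.intensity)
            cost = cost_function(merged, spots, assignment, pred.intensity,
                                 ctrl)
            out.append({"pred": pred, "xy": xy, "assignment": assignment,
                        "merged": merged, "cost": cost, "spots": spots})
        return out

    def cost(self, setting: Setting | None = None) -> CostBreakdown:
        evals = self._evaluate(setting or self.setting)
        if len(evals) == 1:
            return evals[0]["cost"]
        c0 = evals[0]["cost"]
        return CostBreakdown(
            S_I_hits=sum(e["cost"].S_I_hits for e in evals),
            S_I_nohits=sum(e["cost"].S_I_nohits for e in evals),
            S_P=sum(e["cost"].S_P for e in evals),
            target=c0.target, w_P=c0.w_P, w2=c0.w2)

    def _residuals(self, setting: Setting) -> np.ndarray:
        ctrl = setting.control
        parts = []
        for e in self._evaluate(setting):
            cost = e["cost"]
            parts.append(cost.residuals_I)
            if ctrl.pos_weight > 0:
                parts.append(math.sqrt(ctrl.pos_weight) * cost.residuals_P)
            if ctrl.fpred_weight > 0:
                I_nohit = e["pred"].intensity[e["assignment"].J_nohits]
                if ctrl.target == "I":
                    parts.append(math.sqrt(ctrl.fpred_weight) * I_nohit)
                else:
                    parts.append(np.sqrt(ctrl.fpred_weight * I_nohit))
        return np.concatenate(parts) if parts else np.zeros(0)

    # -- fitting ------------------------------------------------------------

    def fit(self, free=("theta", "phi", "psi"), max_iter: int = 200,
            verbose: bool = False) -> "PatternFitResults":
        """Refine the named free parameters; all others stay fixed.

        Uses trust-region-reflective least squares with forward-difference
        Jacobian; bounds keep sigmas >= 0 and the scale > 0.  The ambit
        assignment is recomputed at every residual evaluation, so the cost
        is piecewise smooth; the trust region handles the seams.
        """
        registry = parameter_registry(self.setting, len(self.datasets))
        unknown = [n for n in free if n not in registry]
        if unknown:
            raise ValueError(
                f"unknown/unavailable fit parameters: {unknown}; "
                f"available: {sorted(registry)}")
        params = [registry[n] for n in free]
        single = len(self.datasets) == 1
        bad = [p.name for p in params if p.multi_image_only and single]
        if bad:
            raise ValueError(
                f"parameters {bad} cannot be fitted in a single-image project")
        cost_before = self.cost()

        if not params:
            return PatternFitResults(
                model=self, setting_before=self.setting,
                setting_after=self.setting, free_names=(),
                cost_before=cost_before, cost_after=cost_before,
                n_iterations=0, converged=True, message="nothing to fit")

        x0 = np.array([p.get(self.setting) for p in params])

        def apply(x) -> Setting:
            s = self.setting
            for p, v in zip(params, x):
                s = p.set(s, float(v))
            return s

        def fun(x):
            return self._residuals(apply(x))

        lo = np.array([p.lo for p in params])
        hi = np.array([p.hi for p in params])
        x0 = np.clip(x0, lo, hi)
        diff_step = np.array([p.step / max(abs(v), p.scale)
                              for p, v in zip(params, x0)])
        res = least_squares(
            fun, x0, bounds=(lo, hi), method="trf", jac="2-point",
            diff_step=diff_step,
            x_scale=np.array([p.scale for p in params]),
            ftol=1e-10, xtol=1e-10, gtol=1e-12, max_nfev=max_iter * (len(x0) + 1),
            verbose=2 if verbose else 0)
        setting_after = apply(res.x)
        cost_after = self.cost(setting_after)
        if cost_after.S_total > cost_before.S_total:
            # never report an uphill step (can only happen through
            # assignment changes right at a seam)
            setting_after, cost_after = self.setting, cost_before
        return PatternFitResults(
            model=self, setting_before=self.setting,
            setting_after=setting_after, free_names=tuple(free),
            cost_before=cost_before, cost_after=cost_after,
            n_iterations=int(res.nfev), converged=bool(res.status > 0),
            message=str(res.message))


@dataclass
class PatternFitResults:
    """Results of a pattern-model refinement."""

    model: PatternModel
    setting_before: Setting
    setting_after: Setting
    free_names: tuple
    cost_before: CostBreakdown
    cost_after: CostBreakdown
    n_iterations: int
    converged: bool
    message: str

    def quality(self, image_index: int = 0) -> dict:
        e = self.model._evaluate(self.setting_after)[image_index]
        return quality_metrics(e["merged"], e["spots"])

    def parameter_table(self) -> pd.DataFrame:
        reg = parameter_registry(self.setting_before,
                                 len(self.model.datasets))
        rows = []
        for name, p in reg.items():
            rows.append({"parameter": name,
                         "free": name in self.free_names,
                         "before": p.get(self.setting_before),
                         "after": p.get(self.setting_after)})
        return pd.DataFrame(rows)

    def per_spot_report(self, image_index: int = 0,
                        max_contributions: int = 5) -> pd.DataFrame:
        """Per-spot decomposition: up to five strongest contributing
        reflections per observed spot (strongest first) plus a remainder
        aggregate; spots sorted by descending observed intensity."""
        e = self.model._evaluate(self.setting_after)[image_index]
        return per_spot_report(e["spots"], e["assignment"], e["merged"],
                               e["pred"], e["xy"], max_contributions)

    def summary(self) -> str:
        b, a = self.cost_before, self.cost_after
        q = self.quality()
        lines = [
            "Pattern model refinement",
            "=" * 60,
            f"images: {len(self.model.datasets)}   "
            f"spots: {sum(len(d) for d in self.model.datasets)}   "
            f"free parameters: {len(self.free_names)}",
            f"converged: {self.converged} ({self.message}); "
            f"{self.n_iterations} residual evaluations",
            "",
            f"{'':24s}{'before':>14s}{'after':>14s}",
            f"{'S(I,hits)':24s}{b.S_I_hits:14.6g}{a.S_I_hits:14.6g}",
            f"{'S(I,nohits)':24s}{b.S_I_nohits:14.6g}{a.S_I_nohits:14.6g}",
            f"{'S(P)':24s}{b.S_P:14.6g}{a.S_P:14.6g}",
            f"{'S total':24s}{b.S_total:14.6g}{a.S_total:14.6g}",
            "",
            f"R_I = {q.get('R_I')!r}   R_sqrtI = {q.get('R_sqrtI')!r}   "
            f"matched = {q['matched_fraction']:.3f}",
            "",
            "parameters (* = fitted):",
        ]
        for _, row in self.parameter_table().iterrows():
            star = "*" if row["free"] else " "
            lines.append(f"  {star} {row['parameter']:18s}"
                         f"{row['before']:14.6g}{row['after']:14.6g}")
        return "\n".join(lines)


def per_spot_report(spots: ReducedData, assignment: AmbitAssignment,
                    merged, pred, pred_xy,
                    max_contributions: int = 5) -> pd.DataFrame:
    """Long-format decomposition table (see PatternFitResults docstring)."""
    order = np.argsort(-spots.intensity)
    rows = []
    for s in order:
        J = assignment.J_io[s]
        base = {
            "spot_id": spots.spot_ids[s],
            "x_obs": spots.xy[s, 0], "y_obs": spots.xy[s, 1],
            "I_obs": spots.intensity[s],
            "x_clc": merged.xy_clc[s, 0], "y_clc": merged.xy_clc[s, 1],
            "I_clc": merged.I_clc[s],
        }
        if len(J) == 0:
            rows.append({**base, "rank": 0, "hkl": None, "I_contrib": 0.0,
                         "e_mos": np.nan, "e_shp": np.nan})
            continue
        sub = J[np.argsort(-pred.intensity[J])]
        top = sub[:max_contributions]
        for rank, j in enumerate(top, 1):
            rows.append({**base, "rank": rank,
                         "hkl": tuple(int(v) for v in pred.hkl[j]),
                         "I_contrib": pred.intensity[j],
                         "e_mos": pred.e_mos[j], "e_shp": pred.e_shp[j]})
        if len(sub) > max_contributions:
            rest = sub[max_contributions:]
            rows.append({**base, "rank": max_contributions + 1,
                         "hkl": "remainder",
                         "I_contrib": pred.intensity[rest].sum(),
                         "e_mos": np.nan, "e_shp": np.nan})
    return pd.DataFrame(rows)


def geofit(setting: Setting, data, structure: CrystalStructure,
           free=("theta", "phi", "psi"), mask=None,
           **kw) -> PatternFitResults:
    """Functional wrapper: build a PatternModel and fit it."""
    return PatternModel(data, structure, setting, mask=mask).fit(free=free, **kw)
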