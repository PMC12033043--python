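"""High-level indexing workflow: grid search plus staged refinement.

This chains the two core tools the way an interactive session would:
orientation grid search, export of the best candidates, a coarse
orientation/scale fit, then a full refinement on the sqrt-intensity target
with a position weight balancing the intensity and position parts of the
cost at the hand-over point.
"""

from __future__ import annotations

from dataclasses import replace

from .matching import ReducedData
from .model import PatternFitResults, PatternModel, parameter_registry
from .search import SO3Grid, gridscan, top_orientations
from .workbench import Setting

__all__ = ["refine_orientation", "index_pattern"]


def refine_orientation(setting: Setting, spots: ReducedData, structure,
                       mask=None, extra_free=("sigma_mos", "scale",
                                              "b_factor")) -> PatternFitResults:
    """Two-stage orientation refinement.

    Stage 1 fits orientation and scale on the setting's own target with no
    position weight; stage 2 switches to target sqrt(I) and a position
    weight w_P = S(I)/S(P) evaluated at the stage-1 solution, freeing the
    orientation plus ``extra_free``.
    """
    r1 = PatternModel(spots, structure, setting, mask=mask).fit(
        free=("theta", "phi", "psi", "scale"))
    s1 = r1.setting_after
    probe = PatternModel(spots, structure,
                         replace(s1, control=replace(
                             s1.control, target="sqrt(I)", pos_weight=1.0)),
                         mask=mask)
    cb = probe.cost()
    w_p = cb.S_I_hits / max(cb.S_P, 1e-12)
    s2 = replace(s1, control=replace(s1.control, target="sqrt(I)",
                                     pos_weight=w_p))
    free = ("theta", "phi", "psi") + tuple(
        n for n in extra_free if n in parameter_registry(s2, 1))
    return PatternModel(spots, structure, s2, mask=mask).fit(free=free)


def index_pattern(setting: Setting, spots: ReducedData, structure, *,
                  nside: int = 16, psi_step_deg: float = 1.0,
                  n_candidates: int = 2, scan_dmin: float | None = None,
                  mask=None) -> PatternFitResults:
    """Grid-scan all orientations, refine the best candidates, return the
    refinement with the lowest total cost."""
    grid = SO3Grid(nside=nside, psi_step_deg=psi_step_deg)
    fmap = gridscan(setting, spots, structure, grid=grid, dmin=scan_dmin,
                    mask=mask)
    candidates = top_orientations(fmap, setting, n=n_candidates)
    best: PatternFitResults | None = None
    for cand in candidates:
        fit = refine_orientation(cand, spots, structure, mask=mask)
        if best is None or \
                fit.cost_after.S_total < best.cost_after.S_total:
            best = fit
    return best
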