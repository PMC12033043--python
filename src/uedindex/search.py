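"""Exhaustive orientation search on a HEALPix x Psi grid.

The orientation of the crystal is parameterized by the beam direction in
the crystal frame (two polar angles, sampled at HEALPix pixel centers) and
a rotation Psi of the crystal about the beam (sampled in fixed steps).  For
every orientation a figure of merit (FOM) scores the match between the
predicted and observed pattern; the scan is resumable and its visit order
covers the sphere quasi-uniformly so a partial scan is already informative.

Key speedup: for a fixed beam direction, changing Psi rotates the predicted
pattern rigidly about the beam center (before distortion) and leaves
intensities and excitation errors unchanged, so reflections are predicted
once per direction and only re-projected per Psi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import healpix
from .geometry import OrientationAngles, orientation_matrix
from .matching import (ControlParams, ReducedData, assign_predictions,
                       default_ambit_radius, merge_assigned)
from .predict import predict_arrays
from .workbench import Setting, predict_setting
from .crystal import reflection_table

__all__ = ["SO3Grid", "FOMMap", "build_grid", "fom", "gridscan",
           "top_orientations"]


@dataclass(frozen=True)
class SO3Grid:
    """HEALPix beam directions x uniform Psi steps."""

    nside: int = 64
    psi_step_deg: float = 1.0
    visit_order: np.ndarray = field(repr=False, default=None)
    directions: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if 360.0 % self.psi_step_deg:
            raise ValueError("psi_step must divide 360")
        order = healpix.hierarchical_order(self.nside)
        dirs = healpix.pix2vec_nest(self.nside, order)
        object.__setattr__(self, "visit_order", order)
        object.__setattr__(self, "directions", dirs)

    @property
    def n_directions(self) -> int:
        return healpix.npix(self.nside)

    @property
    def n_psi(self) -> int:
        return int(round(360.0 / self.psi_step_deg))

    @property
    def n_orientations(self) -> int:
        return self.n_directions * self.n_psi

    def angles(self, i: int) -> tuple[float, float]:
        """(theta, phi) in degrees of visit entry i."""
        d = self.directions[i]
        return (math.degrees(math.acos(max(-1.0, min(1.0, d[2])))),
                math.degrees(math.atan2(d[1], d[0])) % 360.0)


def build_grid(nside: int = 64, psi_step_deg: float = 1.0) -> SO3Grid:
    return SO3Grid(nside=nside, psi_step_deg=psi_step_deg)


@dataclass
class FOMMap:
    """Per-direction maximum FOM over Psi, in grid visit order."""

    grid: SO3Grid
    fom: np.ndarray          # NaN where not yet evaluated
    psi_best: np.ndarray
    n_evaluated: int = 0

    @classmethod
    def empty(cls, grid: SO3Grid) -> "FOMMap":
        n = grid.n_directions
        return cls(grid=grid, fom=np.full(n, np.nan),
                   psi_best=np.full(n, np.nan), n_evaluated=0)

    def save(self, path) -> None:
        """Resumable checkpoint: '# key value' header plus TSV rows
        (visit_index, nested_pixel, fom, psi_deg) of evaluated entries."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# nside {self.grid.nside}\n")
            fh.write(f"# psi_step_deg {self.grid.psi_step_deg}\n")
            fh.write("visit_index\tnested_pixel\tfom\tpsi_deg\n")
            for i in np.flatnonzero(~np.isnan(self.fom)):
                fh.write(f"{i}\t{self.grid.visit_order[i]}\t"
                         f"{self.fom[i]:.10g}\t{self.psi_best[i]:.4f}\n")

    @classmethod
    def load(cls, path, grid: SO3Grid | None = None) -> "FOMMap":
        header = {}
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    k, v = line[1:].split()
                    header[k] = float(v)
                elif not line.startswith("visit_index"):
                    rows.append(line.split())
        g = grid or SO3Grid(nside=int(header["nside"]),
                            psi_step_deg=header["psi_step_deg"])
        if g.nside != int(header["nside"]) or \
                g.psi_step_deg != header["psi_step_deg"]:
            raise ValueError("checkpoint grid spec mismatch")
        m = cls.empty(g)
        for i, _pix, f, p in rows:
            m.fom[int(i)] = float(f)
            m.psi_best[int(i)] = float(p)
        m.n_evaluated = int((~np.isnan(m.fom)).sum())
        return m


def _filter_spots_by_resolution(spots: ReducedData, model, dmin: float,
                                dmax: float) -> ReducedData:
    """Keep spots whose detector radius maps into [dmin, dmax] (gnomonic
    small-angle inversion, distortion ignored for the filter)."""
    bc = np.asarray(model.beam_center, dtype=float)
    r_mm = np.linalg.norm(spots.xy - bc, axis=1) * model.pixel_size_mm
    theta = 0.5 * np.arctan2(r_mm, model.camera_length_mm)
    h = 2.0 * np.sin(theta) / model.wavelength_A
    with np.errstate(divide="ignore"):
        d = np.where(h > 0, 1.0 / np.maximum(h, 1e-12), np.inf)
    keep = (d >= dmin) & (d <= dmax)
    if keep.all():
        return spots
    return ReducedData(
        spot_ids=tuple(s for s, k in zip(spots.spot_ids, keep) if k),
        xy=spots.xy[keep], intensity=spots.intensity[keep])


def _ragged_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenation of arange(s, s+c) for each (s, c), without Python loops."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=int)
    cum = np.cumsum(counts)
    return (np.arange(total) - np.repeat(cum - counts, counts)
            + np.repeat(starts, counts))


def _fom_from_merged(I_clc_per_spot, I_obs, total_clc) -> float:
    """Normalized sqrt-overlap FOM in [0, 1]."""
    if total_clc <= 0:
        return 0.0
    num = np.sqrt(I_clc_per_spot * I_obs).sum()
    den = math.sqrt(total_clc * I_obs.sum())
    return float(num / den) if den > 0 else 0.0


def fom(setting: Setting, spots: ReducedData, structure,
        mask=None) -> float:
    """Figure of merit of one setting against one observed pattern.

    FOM = sum_io sqrt(I_clc,io I_obs,io) / sqrt(sum_all I_clc sum_io I_obs):
    1 for a perfect proportional match with no stray predictions, 0 when
    nothing matches.
    """
    pred = predict_setting(setting, structure)
    geom = setting.model.geometry()
    xy = pred.detector_xy(geom)
    masked = None
    if setting.control.mask and mask is not None:
        masked = mask.contains(xy)
        spots = spots.active()
    r_a = setting.control.ambit or default_ambit_radius(spots)
    assignment = assign_predictions(xy, spots, r_a, pred_masked=masked)
    merged = merge_assigned(assignment, xy, pred.intensity)
    total = pred.intensity.sum() if masked is None \
        else pred.intensity[~masked].sum()
    return _fom_from_merged(merged.I_clc, spots.intensity, total)


def gridscan(setting: Setting, spots: ReducedData, structure, *,
             grid: SO3Grid | None = None, n_directions: int | None = None,
             dmin: float | None = None, dmax: float | None = None,
             mask=None, resume: FOMMap | None = None,
             progress: bool = False) -> FOMMap:
    """Scan beam directions (HEALPix visit order) x Psi for the best FOM.

    All parameters except the orientation and the resolution range come
    from ``setting``; ``dmin``/``dmax`` override the setting's resolution
    limits for the scan.  ``resume`` continues a previous partial map.
    """
    grid = grid or SO3Grid()
    ctrl = setting.control
    dmin = ctrl.dmin if dmin is None else dmin
    dmax = ctrl.dmax if dmax is None else dmax
    control = ControlParams(dmin=dmin, dmax=dmax, ambit=ctrl.ambit,
                            mask=ctrl.mask, target=ctrl.target,
                            aniso=ctrl.aniso, tilt_use=ctrl.tilt_use)
    hkl, hv, hl, F2 = reflection_table(structure, dmin, dmax)
    if len(hl) == 0:
        raise ValueError("no reflections in the scan resolution range")
    if ctrl.mask and mask is not None:
        spots = spots.active()
    spots = _filter_spots_by_resolution(spots, setting.model, dmin, dmax)
    if len(spots) == 0:
        raise ValueError("no spots in the scan resolution range")
    r_a = ctrl.ambit or default_ambit_radius(spots)
    if len(spots) >= 2:
        r_a = min(r_a, default_ambit_radius(spots))
    I_obs = spots.intensity
    sqrt_obs_sum = I_obs.sum()

    m = setting.model
    geom = m.geometry()
    n_psi = grid.n_psi
    psi_step_rad = math.radians(grid.psi_step_deg)
    # spot polar coordinates about the beam center
    bc = np.asarray(m.beam_center, dtype=float)
    dxy = spots.xy - bc
    r_s = np.linalg.norm(dxy, axis=1)
    az_s = np.arctan2(dxy[:, 1], dxy[:, 0])
    sort_s = np.argsort(r_s)
    r_s_sorted = r_s[sort_s]
    eps = abs(m.distortion_eps)
    rot_rad = math.radians(m.image_rotation_deg)
    px = m.pixel_size_mm

    fmap = resume if resume is not None else FOMMap.empty(grid)
    n_want = grid.n_directions if n_directions is None else \
        min(n_directions, grid.n_directions)
    todo = [i for i in range(n_want) if np.isnan(fmap.fom[i])]
    for i in todo:
        theta, phi = grid.angles(i)
        R0 = orientation_matrix(OrientationAngles(theta, phi, 0.0))
        pred = predict_arrays(hkl, hv, hl, F2, R=R0, geom=geom,
                              mos=m.mosaicity, shape=m.shape, beam=m.beam,
                              aniso=ctrl.aniso, scale=m.scale,
                              b_global=m.b_factor, tilt=m.tilt,
                              tilt_use=ctrl.tilt_use)
        if len(pred) == 0:
            fmap.fom[i] = 0.0
            fmap.psi_best[i] = 0.0
            continue
        total_clc = pred.intensity.sum()
        sel = pred.intensity > 1e-7 * total_clc
        r_p = pred.r_mm[sel] / px               # pixel radius, pre-distortion
        az_p = pred.az[sel]
        I_p = pred.intensity[sel]
        # candidate (prediction, spot) pairs by radius annulus
        slack = r_a + eps * r_p + 1.0
        lo = np.searchsorted(r_s_sorted, r_p - slack)
        hi = np.searchsorted(r_s_sorted, r_p + slack)
        npair = hi - lo
        if npair.sum() == 0:
            fmap.fom[i] = 0.0
            fmap.psi_best[i] = 0.0
            continue
        p_ix = np.repeat(np.arange(len(r_p)), npair)
        s_ix = sort_s[_ragged_ranges(lo, npair)]
        # psi window: chord distance < r_a (+distortion margin) about
        # psi0 = az_spot - az_pred - image_rotation
        rp, rs = r_p[p_ix], r_s[s_ix]
        ra_eff = r_a + eps * rp + 1.0
        carg = (rp ** 2 + rs ** 2 - ra_eff ** 2) / \
            np.maximum(2.0 * rp * rs, 1e-12)
        dmax_ang = np.arccos(np.clip(carg, -1.0, 1.0))
        psi0 = az_s[s_ix] - az_p[p_ix] - rot_rad
        k0 = np.ceil((psi0 - dmax_ang) / psi_step_rad).astype(int)
        k1 = np.floor((psi0 + dmax_ang) / psi_step_rad).astype(int)
        nwin = np.maximum(k1 - k0 + 1, 0)
        ok = nwin > 0
        if not ok.any():
            fmap.fom[i] = 0.0
            fmap.psi_best[i] = 0.0
            continue
        p2, s2, k0, nwin = p_ix[ok], s_ix[ok], k0[ok], nwin[ok]
        flat_p = np.repeat(np.arange(len(p2)), nwin)
        kk = _ragged_ranges(k0, nwin) % n_psi
        # exact strict-ambit test at each candidate (pair, psi)
        psi_val = kk * psi_step_rad
        azf = az_p[p2[flat_p]] + psi_val + rot_rad
        rr = r_p[p2[flat_p]]
        if eps:
            rr = rr * (1.0 + m.distortion_eps * np.cos(
                2.0 * (azf - math.radians(m.distortion_phi0_deg))))
        xx = rr * np.cos(azf)
        yy = rr * np.sin(azf)
        sp = s2[flat_p]
        d2 = (xx - dxy[sp, 0]) ** 2 + (yy - dxy[sp, 1]) ** 2
        hit = d2 < r_a * r_a
        if mask is not None and ctrl.mask:
            hit &= ~mask.contains(
                np.stack([xx + bc[0], yy + bc[1]], axis=1))
        keys = kk[hit] * len(spots) + sp[hit]
        I_clc = np.bincount(keys, weights=I_p[p2[flat_p[hit]]],
                            minlength=n_psi * len(spots))
        I_clc = I_clc.reshape(n_psi, len(spots))
        foms = np.sqrt(I_clc * I_obs).sum(axis=1) / \
            math.sqrt(total_clc * sqrt_obs_sum)
        j = int(np.argmax(foms))
        fmap.fom[i] = float(foms[j])
        fmap.psi_best[i] = float(j * grid.psi_step_deg)
        if progress and (i + 1) % 200 == 0:
            print(f"  gridscan: {i + 1}/{n_want} directions")
    fmap.n_evaluated = int((~np.isnan(fmap.fom)).sum())
    return fmap


def top_orientations(fmap: FOMMap, setting: Setting, n: int = 10,
                     min_sep_deg: float = 12.0) -> list[Setting]:
    """Greedy export of the best directions, at least ``min_sep_deg`` apart.

    Each exported setting carries the direction's best Psi.  Inversion
    mates are not deduplicated (for centrosymmetric intensities both score
    alike); they simply appear as separate map maxima.
    """
    from dataclasses import replace
    done = np.flatnonzero(~np.isnan(fmap.fom))
    if len(done) == 0:
        raise ValueError("FOM map is empty")
    order = done[np.argsort(-fmap.fom[done])]
    dirs = fmap.grid.directions
    chosen: list[int] = []
    cos_sep = math.cos(math.radians(min_sep_deg))
    for i in order:
        if len(chosen) >= n:
            break
        if min_sep_deg > 0 and any(
                np.dot(dirs[i], dirs[j]) > cos_sep for j in chosen):
            continue
        chosen.append(int(i))
    out = []
    for rank, i in enumerate(chosen, 1):
        theta, phi = fmap.grid.angles(i)
        ori = OrientationAngles(theta, phi, float(fmap.psi_best[i]))
        out.append(replace(
            setting, id=f"{setting.id}-top{rank:02d}",
            model=replace(setting.model, orientation=ori),
            note=f"gridscan FOM={fmap.fom[i]:.4f}"))
    return out


def fom_map_plot(fmap: FOMMap, path) -> None:
    """Write upper/lower hemisphere Lambert equal-area FOM maps as a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    d = fmap.grid.directions
    f = fmap.fom
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5))
    for ax, upper in zip(axes, (True, False)):
        sel = (d[:, 2] >= 0) if upper else (d[:, 2] < 0)
        sel &= ~np.isnan(f)
        z = np.abs(d[sel, 2])
        r = np.sqrt(2.0 * (1.0 - z))  # Lambert equal-area
        ax.scatter(r * np.cos(np.arctan2(d[sel, 1], d[sel, 0])),
                   r * np.sin(np.arctan2(d[sel, 1], d[sel, 0])),
                   c=f[sel], s=4, cmap="gray_r", vmin=0,
                   vmax=np.nanmax(f) if np.isfinite(np.nanmax(f)) else 1)
        ax.set_title("upper hemisphere" if upper else "lower hemisphere")
        ax.set_aspect("equal")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
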