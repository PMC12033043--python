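"""Project and settings management, reduced-data I/O, simulation outputs
and the synthetic-fixture generator.

A *setting* is one complete parameter set (model + control) describing a
candidate interpretation of a diffraction pattern; a *project* bundles the
reduced data, the crystal structure (CIF) and a growing table of settings.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crystal
from .crystal import CrystalStructure, parse_cif, reflection_table
from .geometry import (DetectorGeometry, OrientationAngles, TiltState,
                       electron_energy_kev, electron_wavelength,
                       orientation_matrix)
from .matching import (ControlParams, ReducedData, assign_predictions,
                       default_ambit_radius, merge_assigned)
from .predict import PredictionArrays, predict_arrays, predictions_to_spots
from .profiles import BeamModel, MosaicityModel, ShapeTransform

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "ModelParams",
    "Setting",
    "Project",
    "SyntheticTruth",
    "DetectorMask",
    "read_reduced_data",
    "write_reduced_data",
    "simulate_pattern",
    "simulate_image",
    "make_synthetic_project",
    "save_settings",
    "load_settings",
]


@dataclass(frozen=True)
class ModelParams:
    """All model parameters of a setting.

    Primary fields are stored; the redundant pairs (energy <-> wavelength,
    camera length <-> magnification) are exposed as properties and stay
    consistent through :meth:`update`.
    """

    energy_kev: float = 90.0
    detector_distance_mm: float = 450.0
    camera_length_mm: float = 450.0
    pixel_size_mm: float = 0.055
    beam_center: tuple = (256.0, 256.0)
    image_rotation_deg: float = 0.0
    distortion_eps: float = 0.0
    distortion_phi0_deg: float = 0.0
    orientation: OrientationAngles = field(
        default_factory=lambda: OrientationAngles(0.0, 0.0, 0.0))
    mosaicity: MosaicityModel = field(default_factory=MosaicityModel)
    shape: ShapeTransform = field(default_factory=ShapeTransform)
    beam: BeamModel = field(default_factory=BeamModel)
    scale: float = 1.0
    b_factor: float = 0.0
    tilt: TiltState | None = None

    @property
    def wavelength_A(self) -> float:
        return electron_wavelength(self.energy_kev)

    @property
    def magnification(self) -> float:
        return self.camera_length_mm / self.detector_distance_mm

    def update(self, **kwargs) -> "ModelParams":
        """Edit parameters, keeping redundant values consistent: setting
        ``wavelength_A`` adjusts the energy; setting ``magnification``
        adjusts the camera length."""
        kw = dict(kwargs)
        if "wavelength_A" in kw:
            kw["energy_kev"] = electron_energy_kev(kw.pop("wavelength_A"))
        if "magnification" in kw:
            mag = kw.pop("magnification")
            L = kw.get("detector_distance_mm", self.detector_distance_mm)
            kw["camera_length_mm"] = mag * L
        return replace(self, **kw)

    def geometry(self) -> DetectorGeometry:
        return DetectorGeometry(
            pixel_size_mm=self.pixel_size_mm,
            camera_length_mm=self.camera_length_mm,
            detector_distance_mm=self.detector_distance_mm,
            wavelength_A=self.wavelength_A,
            beam_center=tuple(self.beam_center),
            image_rotation_deg=self.image_rotation_deg,
            distortion_eps=self.distortion_eps,
            distortion_phi0_deg=self.distortion_phi0_deg,
        )


@dataclass(frozen=True)
class Setting:
    """One parameter set: model + control parameters plus a note."""

    id: str = "00001"
    model: ModelParams = field(default_factory=ModelParams)
    control: ControlParams = field(default_factory=ControlParams)
    note: str = ""


# ---------------------------------------------------------------------------
# Detector mask
# ---------------------------------------------------------------------------

class DetectorMask:
    """Masked detector regions: a bitmap (nonzero = masked) and/or simple
    region specs (circles and axis-aligned rectangles, pixel units)."""

    def __init__(self, bitmap: np.ndarray | None = None, regions=()):
        self.bitmap = None if bitmap is None else np.asarray(bitmap) != 0
        self.regions = list(regions)

    @classmethod
    def from_png(cls, path) -> "DetectorMask":
        from PIL import Image
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(bitmap=arr)

    def to_png(self, path) -> None:
        from PIL import Image
        if self.bitmap is None:
            raise ValueError("no bitmap to write")
        Image.fromarray((self.bitmap * 255).astype(np.uint8)).save(path)

    def contains(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.zeros(len(xy), dtype=bool)
        if self.bitmap is not None:
            h, w = self.bitmap.shape
            xi = np.round(xy[:, 0]).astype(int)
            yi = np.round(xy[:, 1]).astype(int)
            inside = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            out[inside] = self.bitmap[yi[inside], xi[inside]]
        for spec in self.regions:
            kind = spec[0]
            if kind == "circle":
                _, cx, cy, r = spec
                out |= (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 <= r * r
            elif kind == "rect":
                _, x0, y0, x1, y1 = spec
                out |= ((xy[:, 0] >= x0) & (xy[:, 0] <= x1)
                        & (xy[:, 1] >= y0) & (xy[:, 1] <= y1))
            else:
                raise ValueError(f"unknown mask region kind {kind!r}")
        return out


# ---------------------------------------------------------------------------
# Reduced data I/O (tab-separated, '#' comments, UTF-8)
# ---------------------------------------------------------------------------

def read_reduced_data(path) -> ReducedData:
    """Read a reduced-data table (columns id, x, y, I; extras ignored,
    sigma(I) parsed but not used).  Rows with I <= 0 are dropped with a
    logged report of their row numbers."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("id", "x", "y", "I"):
        if col not in df.columns:
            raise ValueError(f"reduced data misses required column {col!r}")
    if "sigI" in df.columns:
        logger.warning("sigma(I) column present in %s but ignored", path)
    bad = df.index[df["I"] <= 0].tolist()
    if bad:
        logger.warning("rejected %d rows with I <= 0 (rows %s)", len(bad), bad)
        df = df.drop(index=bad)
    if df.empty:
        raise ValueError("no valid spots in reduced data")
    return ReducedData(spot_ids=tuple(str(s) for s in df["id"]),
                       xy=df[["x", "y"]].to_numpy(float),
                       intensity=df["I"].to_numpy(float))


def write_reduced_data(spots: ReducedData, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tx\ty\tI\n")
        for sid, (x, y), I in zip(spots.spot_ids, spots.xy, spots.intensity):
            fh.write(f"{sid}\t{x:.8f}\t{y:.8f}\t{I:.12g}\n")


# ---------------------------------------------------------------------------
# Prediction / simulation from a setting
# ---------------------------------------------------------------------------

def _reflections_for(structure: CrystalStructure, control: ControlParams):
    return reflection_table(structure, control.dmin, control.dmax)


def predict_setting(setting: Setting, structure: CrystalStructure,
                    image_index: int = 0,
                    refl_cache=None) -> PredictionArrays:
    """Run the prediction engine for one setting (one image)."""
    m = setting.model
    hkl, hv, hl, F2 = (refl_cache if refl_cache is not None
                       else _reflections_for(structure, setting.control))
    R = orientation_matrix(m.orientation)
    return predict_arrays(hkl, hv, hl, F2, R=R, geom=m.geometry(),
                          mos=m.mosaicity, shape=m.shape, beam=m.beam,
                          aniso=setting.control.aniso, scale=m.scale,
                          b_global=m.b_factor, tilt=m.tilt,
                          image_index=image_index,
                          tilt_use=setting.control.tilt_use)


def simulate_pattern(setting: Setting, structure: CrystalStructure,
                     merge: bool = False, spots: ReducedData | None = None,
                     mask: DetectorMask | None = None, image_index: int = 0):
    """Predicted pattern for a setting: raw reflections, or merged per-ambit
    against an observed spot list (requires ``spots`` when ``merge``)."""
    pred = predict_setting(setting, structure, image_index)
    geom = setting.model.geometry()
    keep = pred.intensity > 0
    if not merge:
        sub = PredictionArrays(*(getattr(pred, f)[keep] for f in
                                 ("index", "hkl", "r_mm", "az", "intensity",
                                  "e_mos", "e_shp", "partiality")))
        return predictions_to_spots(sub, geom)
    if spots is None:
        raise ValueError("merging requires an observed spot list")
    xy = pred.detector_xy(geom)
    masked = None
    if setting.control.mask and mask is not None:
        masked = mask.contains(xy)
        spots = spots.active()
    r_a = setting.control.ambit or default_ambit_radius(spots)
    assignment = assign_predictions(xy, spots, r_a, pred_masked=masked)
    return merge_assigned(assignment, xy, pred.intensity)


#: detector point-spread floor (pixels) so that rendered Gaussian spots
#: integrate correctly on the pixel grid
PSF_FLOOR_PX = 0.7


def simulate_image(setting: Setting, structure: CrystalStructure,
                   image_shape: tuple, image_index: int = 0,
                   mask: DetectorMask | None = None) -> np.ndarray:
    """Render a simulated diffraction image (always anisotropic modeling).

    Each prediction becomes a 2-D Gaussian whose covariance combines the
    detector-plane projection of its reciprocal-space profile, the
    divergence footprint (sigma_divg * L_eff) and a radial bandwidth smear;
    the pixel sum over a spot equals its predicted intensity within the 4
    sigma truncation error.
    """
    ny, nx = image_shape
    m = setting.model
    bcx, bcy = m.beam_center
    if not (0 <= bcx < nx and 0 <= bcy < ny):
        raise ValueError("image_shape does not contain the beam center")
    ctrl = setting.control
    aniso_setting = setting if ctrl.aniso else \
        replace(setting, control=replace(ctrl, aniso=True))
    shape_model = m.shape
    if shape_model.mode == "standard" and not ctrl.aniso:
        # embed the relrod as a rank-1 covariance; engine handles it
        pass
    pred = predict_setting(aniso_setting, structure, image_index)
    geom = m.geometry()
    xy = pred.detector_xy(geom)
    img = np.zeros((ny, nx))
    L = m.camera_length_mm
    lam = m.wavelength_A
    px = m.pixel_size_mm
    # reciprocal-space transverse width -> detector mm: d(x_mm) ~ L*lam*d(g)
    sig_recip = np.sqrt(np.maximum(pred.e_shp * 0 + _transverse_var(setting, structure, pred), 0.0))
    for (x, y), I, s_r, r_px in zip(xy, pred.intensity, sig_recip,
                                    np.hypot(xy[:, 0] - bcx, xy[:, 1] - bcy)):
        if I <= 0 or not np.isfinite(x):
            continue
        sig_px = math.hypot(s_r * L * lam / px, m.beam.sigma_divg * L / px)
        var_iso = sig_px ** 2 + PSF_FLOOR_PX ** 2
        # radial bandwidth smear: delta_r / r = delta_k / k
        var_rad = (m.beam.sigma_bwdth * r_px) ** 2
        ux, uy = ((x - bcx) / r_px, (y - bcy) / r_px) if r_px > 1e-9 else (1.0, 0.0)
        C = np.array([[var_iso + var_rad * ux * ux, var_rad * ux * uy],
                      [var_rad * ux * uy, var_iso + var_rad * uy * uy]])
        _render_gaussian(img, x, y, C, I)
    if mask is not None:
        yy, xx = np.mgrid[0:ny, 0:nx]
        inside = mask.contains(np.stack([xx.ravel(), yy.ravel()], axis=1))
        img.ravel()[inside] = 0.0
    return img


def _transverse_var(setting, structure, pred) -> np.ndarray:
    """Isotropized transverse reciprocal-space variance per prediction
    (mosaic tangent spread plus shape), a deliberate simplification for
    rendering only."""
    m = setting.model
    hkl, hv, hl, F2 = _reflections_for(structure, setting.control)
    h = hl[pred.index]
    sig_mos = np.sqrt(np.trace(m.mosaicity.cov_omega()) / 3.0)
    shp = m.shape
    if shp.mode == "standard":
        sig_shp2 = shp.sigma_shp ** 2 / 3.0
    else:
        sig_shp2 = np.trace(shp.cov()) / 3.0
    return (h * sig_mos) ** 2 + sig_shp2


def _render_gaussian(img, x, y, C, I, nsig=4.0):
    ny, nx = img.shape
    w, _ = np.linalg.eigh(C)
    ext = nsig * math.sqrt(max(w[-1], 1e-12))
    x0, x1 = max(0, int(x - ext)), min(nx - 1, int(x + ext) + 1)
    y0, y1 = max(0, int(y - ext)), min(ny - 1, int(y + ext) + 1)
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1) - x
    ys = np.arange(y0, y1 + 1) - y
    X, Y = np.meshgrid(xs, ys)
    Ci = np.linalg.inv(C)
    Q = Ci[0, 0] * X * X + 2 * Ci[0, 1] * X * Y + Ci[1, 1] * Y * Y
    patch = np.exp(-0.5 * Q)
    patch[Q > nsig * nsig] = 0.0
    dens = I * patch / (2.0 * math.pi * math.sqrt(np.linalg.det(C)))
    img[y0:y1 + 1, x0:x1 + 1] += dens


# ---------------------------------------------------------------------------
# Settings / project serialization (YAML, versioned)
# ---------------------------------------------------------------------------

def _model_to_dict(m: ModelParams) -> dict:
    d = {
        "energy_kev": m.energy_kev,
        "detector_distance_mm": m.detector_distance_mm,
        "camera_length_mm": m.camera_length_mm,
        "pixel_size_mm": m.pixel_size_mm,
        "beam_center": list(m.beam_center),
        "image_rotation_deg": m.image_rotation_deg,
        "distortion_eps": m.distortion_eps,
        "distortion_phi0_deg": m.distortion_phi0_deg,
        "orientation": [m.orientation.theta, m.orientation.phi,
                        m.orientation.psi],
        "mosaicity": {"mode": m.mosaicity.mode,
                      "sigma_iso_deg": m.mosaicity.sigma_iso_deg,
                      "sigmas_deg": list(m.mosaicity.sigmas_deg),
                      "euler_deg": list(m.mosaicity.euler_deg)},
        "shape": {"mode": m.shape.mode, "sigma_shp": m.shape.sigma_shp,
                  "tilt_deg": m.shape.tilt_deg,
                  "azimuth_deg": m.shape.azimuth_deg,
                  "sigmas": list(m.shape.sigmas),
                  "euler_deg": list(m.shape.euler_deg)},
        "beam": {"sigma_divg": m.beam.sigma_divg,
                 "sigma_bwdth": m.beam.sigma_bwdth},
        "scale": m.scale,
        "b_factor": m.b_factor,
    }
    if m.tilt is not None:
        d["tilt"] = {"omega_axis_deg": m.tilt.omega_axis_deg,
                     "omega_angles": list(m.tilt.omega_angles),
                     "scale_corrections": list(m.tilt.scale_corrections),
                     "omega_corrections": list(m.tilt.omega_corrections)}
    return d


_MODEL_KEYS = set(_model_to_dict(ModelParams()).keys()) | {"tilt"}


def _model_from_dict(d: dict) -> ModelParams:
    unknown = set(d) - _MODEL_KEYS
    if unknown:
        raise ValueError(f"unknown model parameter fields: {sorted(unknown)}")
    d = dict(d)
    ori = d.pop("orientation")
    mos = d.pop("mosaicity")
    shp = d.pop("shape")
    beam = d.pop("beam")
    tilt = d.pop("tilt", None)
    bc = d.pop("beam_center")
    return ModelParams(
        orientation=OrientationAngles(*ori),
        mosaicity=MosaicityModel(mode=mos["mode"],
                                 sigma_iso_deg=mos["sigma_iso_deg"],
                                 sigmas_deg=tuple(mos["sigmas_deg"]),
                                 euler_deg=tuple(mos["euler_deg"])),
        shape=ShapeTransform(mode=shp["mode"], sigma_shp=shp["sigma_shp"],
                             tilt_deg=shp["tilt_deg"],
                             azimuth_deg=shp["azimuth_deg"],
                             sigmas=tuple(shp["sigmas"]),
                             euler_deg=tuple(shp["euler_deg"])),
        beam=BeamModel(**beam),
        beam_center=tuple(bc),
        tilt=None if tilt is None else TiltState(
            omega_axis_deg=tilt["omega_axis_deg"],
            omega_angles=tuple(tilt["omega_angles"]),
            scale_corrections=tuple(tilt["scale_corrections"]),
            omega_corrections=tuple(tilt["omega_corrections"])),
        **d)


_CONTROL_KEYS = {"dmin", "dmax", "ambit", "mask", "target", "pos_weight",
                 "fpred_weight", "aniso", "tilt_use", "k0_corr", "omg_corr"}


def _control_to_dict(c: ControlParams) -> dict:
    d = {k: getattr(c, k) for k in _CONTROL_KEYS}
    if math.isinf(d["dmax"]):
        d["dmax"] = "inf"
    return d


def _control_from_dict(d: dict) -> ControlParams:
    unknown = set(d) - _CONTROL_KEYS
    if unknown:
        raise ValueError(f"unknown control parameter fields: {sorted(unknown)}")
    d = dict(d)
    if d.get("dmax") == "inf":
        d["dmax"] = math.inf
    return ControlParams(**d)


def setting_to_dict(s: Setting) -> dict:
    return {"id": s.id, "note": s.note, "model": _model_to_dict(s.model),
            "control": _control_to_dict(s.control)}


def setting_from_dict(d: dict) -> Setting:
    unknown = set(d) - {"id", "note", "model", "control"}
    if unknown:
        raise ValueError(f"unknown setting fields: {sorted(unknown)}")
    return Setting(id=str(d["id"]), note=d.get("note", ""),
                   model=_model_from_dict(d["model"]),
                   control=_control_from_dict(d["control"]))


def save_settings(settings, path, run_history=()) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "settings": [setting_to_dict(s) for s in settings],
           "run_history": list(run_history)}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_settings(path):
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    ver = doc.get("schema_version")
    if ver != SCHEMA_VERSION:
        raise ValueError(
            f"settings schema version {ver!r} != {SCHEMA_VERSION}; migrate first")
    settings = [setting_from_dict(d) for d in doc.get("settings", [])]
    return settings, doc.get("run_history", [])


@dataclass
class Project:
    """A work unit: reduced data (one or more images), the CIF, optional
    images and mask, a settings table and a run history."""

    root: Path
    reduced_data_paths: list
    cif_path: Path
    image_paths: list = field(default_factory=list)
    mask_path: Path | None = None
    settings: list = field(default_factory=list)
    run_history: list = field(default_factory=list)

    def __post_init__(self):
        if self.image_paths and \
                len(self.image_paths) != len(self.reduced_data_paths):
            raise ValueError("image list must match reduced-data list length")

    @property
    def n_images(self) -> int:
        return len(self.reduced_data_paths)

    def structure(self) -> CrystalStructure:
        return parse_cif(Path(self.cif_path).read_text())

    def reduced_data(self, image_index: int = 0) -> ReducedData:
        return read_reduced_data(self.reduced_data_paths[image_index])

    def mask(self) -> DetectorMask | None:
        if self.mask_path is None:
            return None
        return DetectorMask.from_png(self.mask_path)

    def next_setting_id(self) -> str:
        return f"{len(self.settings) + 1:05d}"

    def add_setting(self, setting: Setting, provenance: str = "") -> Setting:
        setting = replace(setting, id=self.next_setting_id())
        self.settings.append(setting)
        if provenance:
            self.run_history.append(
                {"setting": setting.id, "provenance": provenance})
        return setting

    def save(self) -> None:
        root = Path(self.root)
        root.mkdir(parents=True, exist_ok=True)

        def rel(p):
            p = Path(p)
            try:
                return str(p.relative_to(root))
            except ValueError:
                return str(p.resolve())
        doc = {"schema_version": SCHEMA_VERSION,
               "reduced_data": [rel(p) for p in self.reduced_data_paths],
               "cif": rel(self.cif_path),
               "images": [rel(p) for p in self.image_paths],
               "mask": None if self.mask_path is None else rel(self.mask_path)}
        with open(root / "project.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)
        save_settings(self.settings, root / "settings.yaml", self.run_history)

    @classmethod
    def load(cls, root) -> "Project":
        root = Path(root)
        with open(root / "project.yaml", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("project schema version mismatch; migrate first")
        settings, history = ([], [])
        if (root / "settings.yaml").exists():
            settings, history = load_settings(root / "settings.yaml")
        return cls(root=root,
                   reduced_data_paths=[root / p for p in doc["reduced_data"]],
                   cif_path=root / doc["cif"],
                   image_paths=[root / p for p in doc.get("images", [])],
                   mask_path=None if doc.get("mask") is None
                   else root / doc["mask"],
                   settings=settings, run_history=history)


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

#: toy triclinic P-1 molecular cell written by the fixture generator
TOY_CIF = """\
data_synthetic_toy
# synthetic structure written by the fixture generator (not a real compound)
_cell_length_a    11.20
_cell_length_b     8.70
_cell_length_c    14.90
_cell_angle_alpha 90.50
_cell_angle_beta 102.30
_cell_angle_gamma 94.10
loop_
_symmetry_equiv_pos_as_xyz
'x,y,z'
'-x,-y,-z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
_atom_site_B_iso_or_equiv
S1 S 0.1230 0.2210 0.0870 1.0 1.5
S2 S 0.3470 0.6120 0.2290 1.0 1.8
O1 O 0.2050 0.4480 0.3610 1.0 2.0
N1 N 0.4210 0.1340 0.4060 1.0 2.2
C1 C 0.0580 0.3870 0.1980 1.0 2.5
C2 C 0.2760 0.0690 0.3140 1.0 2.5
C3 C 0.4830 0.3310 0.1220 1.0 2.8
"""


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating setting plus noise model for a synthetic project."""

    setting: Setting
    intensity_noise: float = 0.1    # sigma of log-normal multiplicative noise
    centroid_jitter: float = 0.3    # pixels
    detection_threshold: float = 0.005  # fraction of strongest spot
    seed: int = 0
    image_shape: tuple = (512, 512)


def default_truth_setting(orientation=(62.0, 137.0, 48.0),
                          sigma_mos_deg: float = 2.0) -> Setting:
    """The study conditions emulated by the fixture: a 90 keV beam, a thin
    plate-like sample (thickness 400 A) with 2 degrees of isotropic
    mosaicity, mild divergence and bandwidth."""
    from .profiles import shape_sigma_from_size
    _, sigma_q = shape_sigma_from_size("plate", 400.0)
    model = ModelParams(
        energy_kev=90.0,
        orientation=OrientationAngles(*orientation),
        mosaicity=MosaicityModel(mode="isotropic", sigma_iso_deg=sigma_mos_deg),
        shape=ShapeTransform(mode="standard", sigma_shp=sigma_q),
        beam=BeamModel(sigma_divg=3e-4, sigma_bwdth=5e-4),
        scale=100.0,
    )
    control = ControlParams(dmin=1.0, dmax=math.inf, aniso=True)
    return Setting(id="00001", model=model, control=control, note="truth")


def _cluster_predictions(xy, I, radius_px: float):
    """Greedy clustering of predicted reflections into spots (strongest
    first; members within ``radius_px`` of the seed)."""
    from scipy.spatial import cKDTree
    order = np.argsort(-I)
    tree = cKDTree(xy)
    taken = np.zeros(len(I), dtype=bool)
    clusters = []
    for i in order:
        if taken[i] or I[i] <= 0:
            continue
        members = [j for j in tree.query_ball_point(xy[i], radius_px)
                   if not taken[j]]
        taken[members] = True
        clusters.append(np.array(members, dtype=int))
    return clusters


def make_synthetic_project(truth: SyntheticTruth, out_dir,
                           with_mask: bool = False,
                           with_image: bool = True) -> Project:
    """Write a complete synthetic project (CIF, reduced data, optional
    rendered image and beamstop mask, hidden truth file)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    (out / "structure.cif").write_text(TOY_CIF, encoding="utf-8")
    structure = parse_cif(TOY_CIF)

    setting = truth.setting
    pred = predict_setting(setting, structure)
    geom = setting.model.geometry()
    xy = pred.detector_xy(geom)
    ny, nx = truth.image_shape
    on_det = ((xy[:, 0] >= 0) & (xy[:, 0] < nx)
              & (xy[:, 1] >= 0) & (xy[:, 1] < ny))
    xy, I = xy[on_det], pred.intensity[on_det]
    clusters = _cluster_predictions(xy, I, radius_px=6.0)
    cen = np.array([(xy[c] * I[c, None]).sum(axis=0) / I[c].sum()
                    for c in clusters if I[c].sum() > 0])
    if len(cen) == 0:
        raise RuntimeError("synthetic truth produced no spots")
    # iterate to an ambit-consistent spot list: the written reduced data
    # must equal the ambit-merged simulation exactly in the noise-free case
    def merge_to_fixpoint(cen):
        for _ in range(50):
            probe = ReducedData(tuple(f"p{i}" for i in range(len(cen))), cen,
                                np.ones(len(cen)))
            r_a = default_ambit_radius(probe) if len(cen) >= 2 else 6.0
            assignment = assign_predictions(xy, probe, r_a)
            merged = merge_assigned(assignment, xy, I)
            keep = merged.matched & (merged.I_clc > 0)
            new_cen = merged.xy_clc[keep]
            moved = (np.inf if len(new_cen) != len(cen)
                     else float(np.abs(new_cen - cen).max()))
            cen, Is = new_cen, merged.I_clc[keep]
            if moved < 1e-12:
                return cen, Is
        return cen, Is

    for _ in range(10):
        cen, Is = merge_to_fixpoint(cen)
        keep = Is >= truth.detection_threshold * Is.max()
        if keep.all():
            break
        cen = cen[keep]
    order = np.argsort(-Is)
    cen, Is = cen[order], Is[order]
    xs, ys = cen[:, 0], cen[:, 1]
    if truth.intensity_noise > 0:
        Is = Is * np.exp(rng.normal(0.0, truth.intensity_noise, len(Is)))
    if truth.centroid_jitter > 0:
        xs = xs + rng.normal(0.0, truth.centroid_jitter, len(xs))
        ys = ys + rng.normal(0.0, truth.centroid_jitter, len(ys))
    mask = None
    mask_path = None
    if with_mask:
        mask = DetectorMask(regions=[("circle",
                                      setting.model.beam_center[0],
                                      setting.model.beam_center[1], 18.0)])
        bitmap = np.zeros(truth.image_shape, dtype=bool)
        yy, xx = np.mgrid[0:ny, 0:nx]
        bitmap |= mask.contains(
            np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(ny, nx)
        mask = DetectorMask(bitmap=bitmap)
        mask_path = out / "mask.png"
        mask.to_png(mask_path)
        keep = ~mask.contains(np.stack([xs, ys], axis=1))
        xs, ys, Is = xs[keep], ys[keep], Is[keep]
    reduced = ReducedData(
        spot_ids=tuple(f"s{i:04d}" for i in range(len(Is))),
        xy=np.stack([xs, ys], axis=1), intensity=Is)
    write_reduced_data(reduced, out / "reduced_data.tsv")
    image_paths = []
    if with_image:
        import tifffile
        img = simulate_image(setting, structure, truth.image_shape, mask=mask)
        tifffile.imwrite(out / "image.tiff", img.astype(np.float32))
        image_paths = [out / "image.tiff"]
    with open(out / "truth.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({"schema_version": SCHEMA_VERSION,
                        "seed": truth.seed,
                        "intensity_noise": truth.intensity_noise,
                        "centroid_jitter": truth.centroid_jitter,
                        "setting": setting_to_dict(truth.setting)},
                       fh, sort_keys=True)
    project = Project(root=out,
                      reduced_data_paths=[out / "reduced_data.tsv"],
                      cif_path=out / "structure.cif",
                      image_paths=image_paths, mask_path=mask_path,
                      settings=[], run_history=[])
    project.save()
    return project


def load_truth(project_dir) -> SyntheticTruth:
    with open(Path(project_dir) / "truth.yaml", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return SyntheticTruth(setting=setting_from_dict(doc["setting"]),
                          intensity_noise=doc["intensity_noise"],
                          centroid_jitter=doc["centroid_jitter"],
                          seed=doc["seed"])
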