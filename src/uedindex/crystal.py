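"""Crystal structures, reciprocal lattices and kinematical structure factors.

The diffraction model works entirely from a known crystal structure (CIF
input).  This module parses the CIF, expands the asymmetric unit to P1,
builds real/reciprocal bases (crystallographic convention, no 2*pi), and
evaluates electron structure-factor magnitudes |F_hkl|^2 with the 5-Gaussian
electron scattering-factor parameterization for neutral atoms.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "UnitCell",
    "AtomSite",
    "CrystalStructure",
    "ScatteringTable",
    "Reflection",
    "CifParseError",
    "parse_cif",
    "reciprocal_basis",
    "d_spacing",
    "electron_form_factor",
    "structure_factor_sq",
    "generate_reflections",
]

#: positional tolerance (fractional) for deduplicating symmetry-expanded sites
SITE_DEDUP_TOL = 1e-4


class CifParseError(ValueError):
    """Raised when a CIF lacks required items or cannot be interpreted."""


@dataclass(frozen=True)
class UnitCell:
    """Unit cell with real and reciprocal bases.

    ``real_basis`` rows are the a, b, c vectors in Angstrom;
    ``recip_basis`` rows are a*, b*, c* in 1/Angstrom with
    ``real_basis @ recip_basis.T == I`` (no 2*pi factor).
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    real_basis: np.ndarray = field(repr=False, default=None)
    recip_basis: np.ndarray = field(repr=False, default=None)
    volume: float = 0.0

    @classmethod
    def from_parameters(cls, a, b, c, alpha, beta, gamma) -> "UnitCell":
        for name, v in (("a", a), ("b", b), ("c", c)):
            if v <= 0:
                raise ValueError(f"cell length {name} must be positive, got {v}")
        for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            if not 0 < v < 180:
                raise ValueError(f"cell angle {name} out of (0, 180): {v}")
        al, be, ga = np.radians([alpha, beta, gamma])
        # standard crystallographic real basis: a along x, b in xy-plane
        av = np.array([a, 0.0, 0.0])
        bv = np.array([b * math.cos(ga), b * math.sin(ga), 0.0])
        cx = math.cos(be)
        cy = (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz2 = 1.0 - cx * cx - cy * cy
        if cz2 <= 0:
            raise ValueError("degenerate cell: angles are metrically impossible")
        cv = np.array([c * cx, c * cy, c * math.sqrt(cz2)])
        real = np.vstack([av, bv, cv])
        vol = float(np.linalg.det(real))
        if vol <= 1e-9:
            raise ValueError("degenerate cell: volume ~ 0")
        recip = np.linalg.inv(real).T  # rows a*, b*, c*
        obj = cls(a, b, c, alpha, beta, gamma)
        object.__setattr__(obj, "real_basis", real)
        object.__setattr__(obj, "recip_basis", recip)
        object.__setattr__(obj, "volume", vol)
        return obj


@dataclass(frozen=True)
class AtomSite:
    """One atom of the P1-expanded cell (fractional coordinates)."""

    label: str
    element_or_ion: str
    frac_xyz: tuple
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self):
        if not 0 <= self.occupancy <= 1:
            raise ValueError(f"occupancy out of [0,1]: {self.occupancy}")
        if self.b_iso < 0:
            raise ValueError(f"negative b_iso: {self.b_iso}")


@dataclass(frozen=True)
class CrystalStructure:
    cell: UnitCell
    sites: tuple
    source_symops: tuple = ()

    def __post_init__(self):
        if not self.sites:
            raise ValueError("structure has no atom sites")


class ScatteringTable:
    """Five-Gaussian electron scattering factors f(s) = sum a_i exp(-b_i s^2).

    Coefficients come from the electron scattering-factor table bundled with
    gemmi (neutral atoms).  Ion symbols such as ``Fe2+`` fall back to the
    neutral atom with a logged warning.
    """

    _ION_RE = re.compile(r"^([A-Z][a-z]?)(\d*[+-])?$")

    def __init__(self):
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def coefficients(self, symbol: str) -> tuple[np.ndarray, np.ndarray]:
        if symbol in self._cache:
            return self._cache[symbol]
        m = self._ION_RE.match(symbol)
        if not m:
            raise KeyError(f"unknown element/ion symbol: {symbol!r}")
        elem_name, charge = m.groups()
        el = gemmi.Element(elem_name)
        if el.atomic_number == 0:
            raise KeyError(f"unknown element/ion symbol: {symbol!r}")
        if charge:
            logger.warning(
                "no electron form-factor entry for ion %r; using neutral %s",
                symbol, elem_name,
            )
        coef = el.c4322
        a = np.asarray(coef.a, dtype=float)
        b = np.asarray(coef.b, dtype=float)
        if not a.any():
            raise KeyError(f"no scattering coefficients for {symbol!r}")
        self._cache[symbol] = (a, b)
        return a, b


_DEFAULT_TABLE = ScatteringTable()


def electron_form_factor(symbol: str, s, table: ScatteringTable | None = None):
    """Electron scattering amplitude f(s) in Angstrom at s = sin(theta)/lambda.

    Accepts scalar or array ``s`` (1/Angstrom, >= 0).
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("s = sin(theta)/lambda must be >= 0")
    a, b = (table or _DEFAULT_TABLE).coefficients(symbol)
    f = (a * np.exp(-b * np.atleast_1d(s)[..., None] ** 2)).sum(axis=-1)
    return f.reshape(s.shape) if s.shape else float(f[0])


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Rows a*, b*, c* (1/Angstrom); real_basis @ recip_basis.T = identity."""
    return cell.recip_basis.copy()


def d_spacing(cell: UnitCell, hkl) -> float:
    """d-spacing 1/|h a* + k b* + l c*| in Angstrom."""
    hkl = np.asarray(hkl, dtype=float)
    if not np.any(hkl):
        raise ValueError("d-spacing undefined for (0,0,0)")
    return float(1.0 / np.linalg.norm(hkl @ cell.recip_basis))


@dataclass(frozen=True)
class Reflection:
    hkl: tuple
    h_vec_crystal: np.ndarray
    h_len: float
    d: float
    F2: float


def _to_float(block: gemmi.cif.Block, tag: str):
    v = block.find_value(tag)
    if v is None:
        return None
    return gemmi.cif.as_number(v)


def parse_cif(cif_text: str, table: ScatteringTable | None = None) -> CrystalStructure:
    """Parse CIF text into a P1-expanded :class:`CrystalStructure`.

    Symmetry operators (``_symmetry_equiv_pos_as_xyz`` or
    ``_space_group_symop_operation_xyz``) are applied and duplicate sites
    within ``SITE_DEDUP_TOL`` (fractional) are removed.  ``U_iso`` is
    converted to ``B_iso`` via B = 8 pi^2 U.
    """
    try:
        doc = gemmi.cif.read_string(cif_text)
        block = doc.sole_block()
    except Exception as exc:
        raise CifParseError(f"CIF syntax error: {exc}") from exc

    missing = [t for t in ("_cell_length_a", "_cell_length_b", "_cell_length_c")
               if block.find_value(t) is None]
    if missing:
        raise CifParseError(f"CIF lacks cell items: {', '.join(missing)}")

    small = gemmi.make_small_structure_from_block(block)
    if not small.sites:
        raise CifParseError("CIF contains no atom sites")
    cell = UnitCell.from_parameters(
        _to_float(block, "_cell_length_a"),
        _to_float(block, "_cell_length_b"),
        _to_float(block, "_cell_length_c"),
        _to_float(block, "_cell_angle_alpha") or 90.0,
        _to_float(block, "_cell_angle_beta") or 90.0,
        _to_float(block, "_cell_angle_gamma") or 90.0,
    )

    tab = table or _DEFAULT_TABLE
    sites: list[AtomSite] = []
    seen: list[np.ndarray] = []
    for src in small.sites:
        symbol = src.type_symbol or src.label
        tab.coefficients(symbol)  # raises KeyError for unknown symbols
        b_iso = src.u_iso * 8.0 * math.pi ** 2 if src.u_iso else 0.0
        for op in (small.symops or ["x,y,z"]):
            gop = gemmi.Op(op)
            fx = np.array(gop.apply_to_xyz([src.fract.x, src.fract.y, src.fract.z]))
            fx %= 1.0
            if any(np.linalg.norm((fx - p + 0.5) % 1.0 - 0.5) < SITE_DEDUP_TOL
                   for p in seen):
                continue
            seen.append(fx)
            sites.append(AtomSite(
                label=src.label, element_or_ion=symbol, frac_xyz=tuple(fx),
                occupancy=src.occ if src.occ else 1.0, b_iso=b_iso,
            ))
    return CrystalStructure(cell=cell, sites=tuple(sites),
                            source_symops=tuple(small.symops or ["x,y,z"]))


def structure_factor_sq(structure: CrystalStructure, refl: Reflection,
                        table: ScatteringTable | None = None) -> float:
    """|F_hkl|^2 for one reflection (kinematical, real scattering factors)."""
    F2 = _structure_factors_sq(structure,
                               np.asarray([refl.hkl], dtype=float),
                               np.asarray([refl.h_len]), table)
    return float(F2[0])


def _structure_factors_sq(structure, hkl_arr, h_len_arr, table=None):
    """Vectorized |F|^2 over an (N,3) hkl array with matching |h| values."""
    tab = table or _DEFAULT_TABLE
    s = h_len_arr / 2.0  # sin(theta)/lambda
    F = np.zeros(len(hkl_arr), dtype=complex)
    # group sites by (element, b_iso, occupancy) to share form-factor evaluations
    groups: dict[tuple, list] = {}
    for site in structure.sites:
        groups.setdefault((site.element_or_ion, site.b_iso, site.occupancy),
                          []).append(site.frac_xyz)
    for (symbol, b_iso, occ), positions in groups.items():
        f = electron_form_factor(symbol, s, tab) * occ * np.exp(-b_iso * s ** 2)
        pos = np.asarray(positions)           # (M,3)
        phase = np.exp(2j * np.pi * (hkl_arr @ pos.T))  # (N,M)
        F += f * phase.sum(axis=1)
    return (F * F.conj()).real


def generate_reflections(structure: CrystalStructure, dmin: float,
                         dmax: float = math.inf,
                         table: ScatteringTable | None = None) -> list[Reflection]:
    """All reflections with dmin <= d <= dmax, |F|^2 attached.

    Deterministic order: ascending |h| (= 1/d), then lexicographic hkl.
    """
    if not 0 < dmin < dmax:
        raise ValueError(f"need 0 < dmin < dmax, got dmin={dmin}, dmax={dmax}")
    cell = structure.cell
    hmax = 1.0 / dmin
    # conservative index bounds from the real cell edge lengths
    lengths = np.linalg.norm(cell.real_basis, axis=1)
    bounds = np.ceil(hmax * lengths).astype(int)
    rng = [np.arange(-b, b + 1) for b in bounds]
    H = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    vecs = H @ cell.recip_basis
    hlen = np.linalg.norm(vecs, axis=1)
    keep = (hlen <= hmax + 1e-12) & (hlen >= (0.0 if math.isinf(dmax) else 1.0 / dmax) - 1e-12)
    H, vecs, hlen = H[keep], vecs[keep], hlen[keep]
    order = np.lexsort((H[:, 2], H[:, 1], H[:, 0], np.round(hlen, 12)))
    H, vecs, hlen = H[order], vecs[order], hlen[order]
    F2 = _structure_factors_sq(structure, H.astype(float), hlen, table)
    return [
        Reflection(hkl=tuple(int(i) for i in h), h_vec_crystal=v,
                   h_len=float(hl), d=float(1.0 / hl), F2=float(f2))
        for h, v, hl, f2 in zip(H, vecs, hlen, F2)
    ]


def reflection_table(structure: CrystalStructure, dmin: float,
                     dmax: float = math.inf,
                     table: ScatteringTable | None = None):
    """Array form of :func:`generate_reflections` used by the fast engine.

    Returns (hkl (N,3) int, h_vec_crystal (N,3), h_len (N,), F2 (N,)).
    """
    refls = generate_reflections(structure, dmin, dmax, table)
    if not refls:
        z = np.zeros((0, 3))
        return z.astype(int), z, np.zeros(0), np.zeros(0)
    hkl = np.array([r.hkl for r in refls], dtype=int)
    vecs = np.array([r.h_vec_crystal for r in refls])
    hlen = np.array([r.h_len for r in refls])
    F2 = np.array([r.F2 for r in refls])
    return hkl, vecs, hlen, F2
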