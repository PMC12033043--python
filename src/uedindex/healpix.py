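"""Minimal HEALPix pixel-center math (NESTED scheme), vectorized.

Only what the SO(3) orientation grid needs: pixel-center directions of the
equal-area Hierarchical Equal Area isoLatitude Pixelation of the sphere for
nside a power of two, plus a coarse-to-fine visit order so that a partial
scan still covers the sphere quasi-uniformly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["npix", "pix2ang_nest", "pix2vec_nest", "hierarchical_order"]

_JRLL = np.array([2, 2, 2, 2, 3, 3, 3, 3, 4, 4, 4, 4])
_JPLL = np.array([1, 3, 5, 7, 0, 2, 4, 6, 1, 3, 5, 7])


def _check_nside(nside: int) -> None:
    if nside < 1 or (nside & (nside - 1)) != 0:
        raise ValueError(f"nside must be a power of 2, got {nside}")


def npix(nside: int) -> int:
    _check_nside(nside)
    return 12 * nside * nside


def _compress_bits(v: np.ndarray) -> np.ndarray:
    """Keep even-position bits of v and pack them (inverse of interleave)."""
    v = v & np.uint64(0x5555555555555555)
    v = (v | (v >> np.uint64(1))) & np.uint64(0x3333333333333333)
    v = (v | (v >> np.uint64(2))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    v = (v | (v >> np.uint64(4))) & np.uint64(0x00FF00FF00FF00FF)
    v = (v | (v >> np.uint64(8))) & np.uint64(0x0000FFFF0000FFFF)
    v = (v | (v >> np.uint64(16))) & np.uint64(0x00000000FFFFFFFF)
    return v


def pix2ang_nest(nside: int, ipix) -> tuple[np.ndarray, np.ndarray]:
    """NESTED pixel index -> (theta, phi) of the pixel center, radians."""
    _check_nside(nside)
    ipix = np.asarray(ipix, dtype=np.uint64)
    n2 = np.uint64(nside * nside)
    face = (ipix // n2).astype(np.int64)
    p = ipix % n2
    ix = _compress_bits(p).astype(np.int64)
    iy = _compress_bits(p >> np.uint64(1)).astype(np.int64)

    jr = _JRLL[face] * nside - ix - iy - 1  # ring index 1..4*nside-1
    nr = np.full_like(jr, nside)
    z = np.empty(jr.shape, dtype=float)
    kshift = np.zeros_like(jr)

    north = jr < nside
    south = jr > 3 * nside
    eq = ~(north | south)
    nr[north] = jr[north]
    z[north] = 1.0 - nr[north] ** 2 / (3.0 * nside ** 2)
    nr[south] = 4 * nside - jr[south]
    z[south] = -1.0 + nr[south] ** 2 / (3.0 * nside ** 2)
    z[eq] = (2 * nside - jr[eq]) * 2.0 / (3.0 * nside)
    kshift[eq] = (jr[eq] - nside) & 1

    jp = (_JPLL[face] * nr + ix - iy + 1 + kshift) // 2
    jp = np.where(jp > 4 * nr, jp - 4 * nr, jp)
    jp = np.where(jp < 1, jp + 4 * nr, jp)
    phi = (jp - (kshift + 1) * 0.5) * (np.pi / (2.0 * nr))
    return np.arccos(np.clip(z, -1.0, 1.0)), phi


def pix2vec_nest(nside: int, ipix) -> np.ndarray:
    """NESTED pixel index -> unit vector(s), shape (..., 3)."""
    theta, phi = pix2ang_nest(nside, ipix)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def hierarchical_order(nside: int) -> np.ndarray:
    """NESTED pixel indices ordered coarse-to-fine.

    Bit-reversing the in-face nested index makes any prefix of the sequence
    sample each base face quasi-uniformly; faces are interleaved so that a
    partial scan covers the whole sphere.
    """
    _check_nside(nside)
    k2 = 2 * int(nside).bit_length() - 2  # bits of the in-face index
    n2 = nside * nside
    p = np.arange(n2, dtype=np.uint64)
    rev = np.zeros_like(p)
    for b in range(k2):
        rev |= ((p >> np.uint64(b)) & np.uint64(1)) << np.uint64(k2 - 1 - b)
    order_in_face = np.argsort(rev, kind="stable")
    faces = np.arange(12, dtype=np.uint64) * np.uint64(n2)
    # interleave: one pixel per face, then the next, ...
    return (faces[None, :] + order_in_face[:, None].astype(np.uint64)).ravel()
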