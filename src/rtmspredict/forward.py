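"""Single-sphere EEG forward model and equivalent-dipole fitting.

The head is a homogeneous conducting sphere.  The surface potential of a
current dipole ``p`` at eccentricity ``b`` is the Legendre expansion

    V = 1/(4 pi sigma R^2) * sum_n (2n+1)/n * (b/R)^(n-1)
        * [ n p_r P_n(cos g) + (p . t_hat) sin(g) P_n'(cos g) ]

where ``g`` is the angle between dipole and electrode directions, ``p_r`` the
radial moment component and ``t_hat`` the tangential unit vector at the
dipole pointing toward the electrode.  The ``(2n+1)/n`` factor is the
boundary correction of the insulating sphere; for a dipole at the centre the
series collapses to the exact ``3 (p . e_hat) / (4 pi sigma R^2)``.

Dipole fitting inverts the model with the moment solved linearly at each
candidate location: a cached coarse grid scan followed by a shrinking local
grid search, all evaluated with a location-batched lead field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SIGMA_S_PER_MM = 0.33e-3  # brain conductivity, S/mm
_N_TERMS = 60
_MAX_ECC = 0.95  # dipoles are kept strictly inside the sphere

_GRID_CACHE: dict = {}


class DegenerateMapError(ValueError):
    """Raised when a scalp map carries no energy to fit a dipole to."""


def sphere_leadfield_batch(
    elec_pos: np.ndarray,
    locs: np.ndarray,
    head_radius: float,
    average_reference: bool = True,
) -> np.ndarray:
    """Lead fields for many dipole locations at once.

    Returns an (n_locs, n_electrodes, 3) array; slice ``[l, :, k]`` is the
    potential pattern of a unit moment along axis ``k`` at location ``l``.
    With ``average_reference`` each pattern's mean is removed, matching
    average-referenced data and ICA scalp maps.
    """
    elec_pos = np.asarray(elec_pos, dtype=float)
    locs = np.atleast_2d(np.asarray(locs, dtype=float))
    R = float(head_radius)
    b = np.linalg.norm(locs, axis=1)
    over = b > _MAX_ECC * R
    if over.any():
        locs = locs.copy()
        locs[over] *= (_MAX_ECC * R / b[over])[:, None]
        b = np.minimum(b, _MAX_ECC * R)
    e_hat = elec_pos / np.linalg.norm(elec_pos, axis=1, keepdims=True)  # (E,3)
    k0 = 1.0 / (4.0 * np.pi * SIGMA_S_PER_MM * R**2)
    nL, nE = len(locs), len(e_hat)

    central = b < 1e-9
    r0_hat = np.where(central[:, None], [0.0, 0.0, 1.0], locs / np.maximum(b, 1e-30)[:, None])
    x = np.clip(r0_hat @ e_hat.T, -1.0, 1.0)  # (L,E) cos g
    sin_g = np.sqrt(np.maximum(1.0 - x**2, 0.0))
    t_hat = e_hat[None, :, :] - x[:, :, None] * r0_hat[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_hat = t_hat / sin_g[:, :, None]
    t_hat[sin_g < 1e-9] = 0.0

    ecc = (b / R)[:, None]  # (L,1)
    P_nm1 = np.ones_like(x)  # P_0
    P_n = x.copy()  # P_1
    rad = np.zeros_like(x)
    tan = np.zeros_like(x)
    scale = np.ones_like(ecc)  # ecc^(n-1)
    inv_sin = np.zeros_like(x)
    np.divide(1.0, sin_g, out=inv_sin, where=sin_g >= 1e-9)
    for n in range(1, _N_TERMS + 1):
        c_n = (2 * n + 1) / n * scale
        rad += c_n * n * P_n
        tan += c_n * (n * (P_nm1 - x * P_n) * inv_sin)
        P_nm1, P_n = P_n, ((2 * n + 1) * x * P_n - n * P_nm1) / (n + 1)
        scale = scale * ecc
        if scale.max() < 1e-9:
            break
    L = k0 * (rad[:, :, None] * r0_hat[:, None, :] + tan[:, :, None] * t_hat)
    if central.any():  # exact closed form for a dipole at the centre
        L[central] = 3.0 * k0 * np.broadcast_to(e_hat, (int(central.sum()), nE, 3))
    if average_reference:
        L = L - L.mean(axis=1, keepdims=True)
    return L


def sphere_leadfield(
    elec_pos: np.ndarray,
    loc: np.ndarray,
    head_radius: float,
    average_reference: bool = True,
) -> np.ndarray:
    """Lead-field matrix (n_electrodes x 3) of a single dipole at ``loc`` (mm)."""
    return sphere_leadfield_batch(elec_pos, np.asarray(loc)[None, :], head_radius,
                                  average_reference)[0]


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.c_[np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]


def _residuals(lfs: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-moment residual ||w - L q||^2 per location (normal equations)."""
    G = np.einsum("lej,lek->ljk", lfs, lfs)
    rhs = np.einsum("lej,e->lj", lfs, w)
    G = G + 1e-12 * np.trace(G, axis1=1, axis2=2)[:, None, None] * np.eye(3)
    q = np.linalg.solve(G, rhs[:, :, None])[:, :, 0]
    res = float(w @ w) - np.einsum("lj,lj->l", q, rhs)
    return res, q


def _coarse_grid(elec_pos: np.ndarray, head_radius: float) -> tuple[np.ndarray, np.ndarray]:
    key = (elec_pos.tobytes(), float(head_radius))
    if key not in _GRID_CACHE:
        dirs = _fibonacci_sphere(72)
        shells = np.array([0.2, 0.4, 0.6, 0.75, 0.88]) * head_radius * _MAX_ECC
        pts = np.concatenate([r * dirs for r in shells] + [np.zeros((1, 3))])
        _GRID_CACHE[key] = (pts, sphere_leadfield_batch(elec_pos, pts, head_radius))
    return _GRID_CACHE[key]


@dataclass(frozen=True)
class DipoleFit:
    location: np.ndarray  # mm
    moment: np.ndarray
    gof: float  # 1 - residual variance fraction


_OFFSETS = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).reshape(3, -1).T


def fit_dipole(
    scalp_map: np.ndarray,
    elec_pos: np.ndarray,
    head_radius: float,
) -> DipoleFit:
    """Least-squares single equivalent dipole for a scalp map.

    Requires at least 8 electrodes.  Raises :class:`DegenerateMapError` on an
    all-zero map.  ``gof`` below ~0.9 flags maps a single dipole cannot
    explain (e.g. symmetric bilateral patterns).
    """
    w = np.asarray(scalp_map, dtype=float)
    if len(w) < 8:
        raise ValueError("dipole fitting needs at least 8 electrodes")
    w = w - w.mean()
    nrm2 = float(w @ w)
    if nrm2 < 1e-30:
        raise DegenerateMapError("all-zero scalp map has no equivalent dipole")

    elec_pos = np.asarray(elec_pos, dtype=float)
    pts, lfs = _coarse_grid(elec_pos, head_radius)
    res, _ = _residuals(lfs, w)
    loc = pts[int(np.argmin(res))]

    for spacing in (12.0, 6.0, 3.0, 1.5, 0.75, 0.35):
        cand = loc + spacing * _OFFSETS
        r = np.linalg.norm(cand, axis=1)
        outside = r > _MAX_ECC * head_radius
        cand[outside] *= (_MAX_ECC * head_radius / r[outside])[:, None]
        L = sphere_leadfield_batch(elec_pos, cand, head_radius)
        res, q = _residuals(L, w)
        best = int(np.argmin(res))
        loc = cand[best]
    return DipoleFit(location=loc, moment=q[best], gof=1.0 - res[best] / nrm2)
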