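"""Volume conditioning: rolling slice averages, edge-preserving diffusion,
and multiscale Hessian membrane enhancement.

The enhancement stage follows the Frangi construction — Gaussian-scale
Hessian, eigenvalues sorted by magnitude |l1| <= |l2| <= |l3|, a geometry
term times a second-order structure term, maximum over scales — in two
flavours: a *tubular* (vesselness) measure rewarding l2 ~ l3 << 0, l1 ~ 0,
and a *planar* ("sheetness") measure rewarding l3 << 0, l1 ~ l2 ~ 0, since
cristae are plates as well as tubes.  Both assume bright membranes; stained
membranes are dark, so a polarity option inverts the input first.

Scales are physical (nm) and converted to voxels internally, so parameter
files transfer across tomograms with different pixel sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["FilterParams", "rolling_average", "anisotropic_diffusion",
           "membrane_filter"]


@dataclass
class FilterParams:
    """Tunable parameters of the conditioning stages.

    rolling_window   : odd number of adjacent z-slices averaged (default 3).
    ad_iterations    : Perona-Malik iterations (0 = identity).
    ad_kappa         : conductance edge threshold, in intensity units.
    ad_step          : explicit time step; must be <= 1/6 + epsilon in 3-D
                       (we enforce <= 0.25 per the looser classic bound and
                       default to 1/6).
    frangi_scales_nm : Gaussian scales of the Hessian, in nm.
    frangi_alpha/beta: plate-vs-line and blob sensitivity constants.
    frangi_c         : structure sensitivity; None = half max Hessian norm.
    structure_mode   : "tubular" (vesselness) or "planar" (sheetness).
    polarity         : "bright" if membranes are bright; "dark" inverts.
    """

    rolling_window: int = 3
    ad_iterations: int = 5
    ad_kappa: float = 0.1
    ad_step: float = 1.0 / 6.0
    frangi_scales_nm: tuple[float, ...] = (3.0, 4.5, 6.0)
    frangi_alpha: float = 0.5
    frangi_beta: float = 0.5
    frangi_c: float | None = None
    structure_mode: str = "planar"
    polarity: str = "bright"

    def __post_init__(self) -> None:
        if self.rolling_window < 1 or self.rolling_window % 2 == 0:
            raise ValueError("rolling_window must be odd and >= 1")
        if self.ad_step > 0.25:
            raise ValueError("ad_step > 0.25 is unstable for the 3-D "
                             "explicit scheme")
        if len(self.frangi_scales_nm) < 1:
            raise ValueError("at least one Hessian scale is required")
        if any(s <= 0 for s in self.frangi_scales_nm):
            raise ValueError("scales must be positive")
        if self.structure_mode not in ("tubular", "planar"):
            raise ValueError("structure_mode must be 'tubular' or 'planar'")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")


def rolling_average(vol: Volume, window: int = 3) -> Volume:
    """Average every ``window`` adjacent z-slices (centered; truncated at
    the slab faces), the standard noise-reduction step before slice-based
    tracing."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > vol.data.shape[0]:
        raise ValueError("window larger than number of slices")
    if window == 1:
        return vol.copy()
    half = window // 2
    nz = vol.data.shape[0]
    csum = np.cumsum(vol.data, axis=0, dtype=np.float64)
    csum = np.concatenate([np.zeros_like(csum[:1]), csum], axis=0)
    out = np.empty_like(vol.data)
    for i in range(nz):
        lo, hi = max(0, i - half), min(nz, i + half + 1)
        out[i] = ((csum[hi] - csum[lo]) / (hi - lo)).astype(np.float32)
    return Volume(out, vol.voxel_size)


def anisotropic_diffusion(vol: Volume, params: FilterParams) -> Volume:
    """Perona-Malik diffusion with exponential conductance
    g(|grad I|) = exp(-(|grad I|/kappa)^2), explicit 6-neighbour scheme,
    Neumann boundaries.  The flux form conserves the global mean."""
    if params.ad_iterations < 0:
        raise ValueError("iterations must be >= 0")
    u = vol.data.astype(np.float32).copy()
    kappa = float(params.ad_kappa)
    dt = float(params.ad_step)
    for _ in range(params.ad_iterations):
        total = np.zeros_like(u)
        for axis in range(3):
            d_fwd = np.diff(u, axis=axis)
            g = np.exp(-(d_fwd / kappa) ** 2)
            flux = g * d_fwd
            pad = [(0, 0)] * 3
            pad[axis] = (1, 0)
            fwd = np.pad(flux, pad)        # flux entering from the + side
            pad[axis] = (0, 1)
            bwd = np.pad(flux, pad)        # flux leaving to the - side
            total += fwd - bwd
        # note sign: du/dt = div(g grad u); fwd-bwd above is -div, so flip
        u -= dt * total
    return Volume(u, vol.voxel_size)


def _hessian_eigvals_abs_sorted(vol: np.ndarray, sigma_vox: float
                                ) -> tuple[np.ndarray, ...]:
    """Eigenvalues of the scale-normalised Gaussian Hessian, sorted by
    |l1| <= |l2| <= |l3|, via the closed-form (Cardano) solution for
    symmetric 3x3 matrices — far faster than batched ``eigvalsh`` on
    multi-million-voxel grids."""
    norm = np.float32(sigma_vox ** 2)          # gamma-normalisation
    g = ndimage.gaussian_filter(vol.astype(np.float32, copy=False),
                                sigma_vox, mode="nearest")
    gz, gy, gx = np.gradient(g)
    del g
    a, d, f = (h * norm for h in np.gradient(gz))
    del gz
    hy = np.gradient(gy)
    b, e = hy[1] * norm, hy[2] * norm
    del gy, hy
    c = np.gradient(gx, axis=2) * norm
    del gx
    # characteristic polynomial of [[a,d,f],[d,b,e],[f,e,c]] via Cardano
    q = (a + b + c) / 3.0
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 \
        + 2 * (d ** 2 + e ** 2 + f ** 2)
    p = np.sqrt(np.maximum(p2 / 6.0, np.float32(1e-30)))
    del p2
    with np.errstate(divide="ignore", invalid="ignore"):
        b11, b22, b33 = (a - q) / p, (b - q) / p, (c - q) / p
        b12, b23, b13 = d / p, e / p, f / p
        detB = (b11 * (b22 * b33 - b23 ** 2)
                - b12 * (b12 * b33 - b23 * b13)
                + b13 * (b12 * b23 - b22 * b13))
    del a, b, c, d, e, f, b11, b22, b33, b12, b23, b13
    r = np.clip(detB / 2.0, -1.0, 1.0)
    del detB
    phi = np.arccos(r) / 3.0
    del r
    e1 = q + 2 * p * np.cos(phi)
    e3 = q + 2 * p * np.cos(phi + np.float32(2 * np.pi / 3.0))
    e2 = 3 * q - e1 - e3
    del q, p, phi
    # sort the three eigenvalue fields by |.| with a swap network (cheaper
    # in memory than stack + argsort on large grids)

    def _ordered(lo, hi):
        swap = np.abs(lo) > np.abs(hi)
        return np.where(swap, hi, lo), np.where(swap, lo, hi)

    e1, e2 = _ordered(e1, e2)
    e2, e3 = _ordered(e2, e3)
    e1, e2 = _ordered(e1, e2)
    return e1, e2, e3


def membrane_filter(vol: Volume, params: FilterParams) -> Volume:
    """Multiscale Hessian membrane enhancement, response in [0, 1].

    ``tubular`` mode is the classic vesselness (bright ridges need
    l2 ~ l3 << 0, l1 ~ 0); ``planar`` mode is a sheetness measure (bright
    plates need l3 << 0, |l1|, |l2| small).  The per-voxel response is the
    maximum over the requested physical scales.
    """
    if len(params.frangi_scales_nm) < 1:
        raise ValueError("at least one scale required")
    data = vol.data.astype(np.float32)
    if params.polarity == "dark":
        data = -data
    alpha, beta = params.frangi_alpha, params.frangi_beta
    best = np.zeros_like(data)
    for scale_nm in params.frangi_scales_nm:
        sigma_vox = scale_nm / vol.voxel_size
        l1, l2, l3 = _hessian_eigvals_abs_sorted(data, sigma_vox)
        S = np.sqrt(l1 ** 2 + l2 ** 2 + l3 ** 2)
        smax = float(S.max())
        # a (near-)uniform volume has only round-off curvature: no response
        if smax < 1e-6 * max(1.0, float(np.abs(data).max())):
            continue
        c = params.frangi_c
        if c is None:
            c = 0.5 * smax
        structure = 1.0 - np.exp(-(S ** 2) / (2 * c ** 2))
        a2, a3 = np.abs(l2), np.abs(l3)
        with np.errstate(divide="ignore", invalid="ignore"):
            if params.structure_mode == "tubular":
                ra = np.where(a3 > 0, a2 / a3, 0.0)
                rb = np.where(a2 * a3 > 0, np.abs(l1) / np.sqrt(a2 * a3), 0.0)
                resp = ((1.0 - np.exp(-(ra ** 2) / (2 * alpha ** 2)))
                        * np.exp(-(rb ** 2) / (2 * beta ** 2)) * structure)
                resp = np.where(l2 < 0, resp, 0.0)
            else:
                # plates: dominant l3 < 0, the other two comparatively flat
                r_sheet = np.where(a3 > 0, a2 / a3, 0.0)
                r_blob = np.where(a3 > 0,
                                  np.sqrt(np.abs(l1 * l2)) / a3, 0.0)
                resp = (np.exp(-(r_sheet ** 2) / (2 * alpha ** 2))
                        * np.exp(-(r_blob ** 2) / (2 * beta ** 2)) * structure)
            resp = np.where(l3 < 0, resp, 0.0)
        np.maximum(best, resp.astype(np.float32), out=best)
    return Volume(np.clip(best, 0.0, 1.0), vol.voxel_size)
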