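"""Synthetic tomogram phantoms of cardiomyocyte mitochondria.

Real tomographic slabs of heart-muscle mitochondria show four crista
morphologies: flat lamellar plates whose membranes sit ~20 nm apart (often
fenestrated with 20-80 nm holes), worm-like tubes 50-90 nm in diameter,
"transitional" parallel rows of small 30-60 nm tubes, and mixtures of two
morphologies in adjacent regions.  This module builds such geometry
analytically inside an outer-membrane / inner-boundary-membrane envelope,
renders it as a membrane-density volume at a chosen voxel size, intersects
the membrane midsurfaces with tomographic slices to produce traced-contour
sets, and reports closed-form ground truth (areas, volumes, counts) so that
every downstream measurement stage can be validated against known answers.

Conventions
-----------
* Axes are (z, y, x); z is the slab normal.  Physical coordinate =
  voxel index * voxel_size (voxel centres), so the slab spans
  ``[0, (nz-1)*voxel_size]`` in z.
* Membranes are rendered as solid shells of finite thickness (default 6 nm)
  centred on the compartment midsurface; stained bilayers image with a
  finite width and marching cubes needs a two-sided density feature.
* Crista "solids" are the intracristal compartments bounded by the membrane
  midsurface; ground-truth surface areas are midsurface areas of the
  slab-clipped compartments, with the slab caps excluded ("native" area).
* Lamellar cristae traced in cross-section contribute their compartment
  outline, i.e. the classic pair of parallel lines plus end arcs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import box as shp_box, Polygon
from shapely.ops import unary_union
from skimage import measure

from .contours import Contour, ContourSet
from .volume import Volume

__all__ = [
    "PhantomSpec", "GroundTruth", "PhantomSolids",
    "generate_phantom", "phantom_solids", "corrupt",
    "lamellar_params_for_density",
]

MORPHOLOGY_CLASSES = ("lamellar", "tubular", "transitional", "mixed")

_DEFAULT_PARAMS = {
    "lamellar": dict(
        n_plates=8,
        separation_nm=20.0,           # membrane pair separation
        plate_margin_nm=35.0,         # gap between plate end and IBM
        edge_margin_nm=60.0,          # keep outermost plates off the IBM
        n_fenestrations_per_plate=0,
        fenestration_diameter_range_nm=(20.0, 80.0),
        n_swollen=0,                  # cristae with a locally swollen span
        swelling_multiplier=3.0,      # swollen separation / nominal
        swollen_length_fraction=0.5,
        junction_necks=False,
        junction_neck_diameter_nm=(15.0, 40.0),
        junction_neck_shape="round",      # or "slot"
        junction_slot_length_nm=70.0,
    ),
    "tubular": dict(
        n_tubes=12,
        diameter_range_nm=(50.0, 90.0),
        step_nm=20.0,
        n_steps_range=(25, 55),
        max_turn_rad=0.25,
        z_wander=0.3,                 # damping of the z component of steps
        z_seed_band=(0.30, 0.70),     # fraction of slab where tubes start
        n_vesicles=0,
        vesicle_diameter_range_nm=(70.0, 90.0),
    ),
    "transitional": dict(
        n_rows=6,
        tube_diameter_range_nm=(30.0, 60.0),
        row_margin_nm=45.0,
        edge_margin_nm=70.0,
        tube_gap_nm=18.0,
        elongated_fraction=0.25,
        elongated_length_range_nm=(80.0, 160.0),
    ),
    "mixed": dict(
        classes=("lamellar", "tubular"),
    ),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic mitochondrion phantom.

    ``envelope_semi_axes`` are the outer-membrane semi-axes (y, x) in nm of
    a cylinder whose axis is the slab normal; the IBM sits ``ibm_offset_nm``
    inside it.  ``crista_params`` overrides per-class defaults (see
    ``_DEFAULT_PARAMS``).  Identical spec + seed gives bit-identical output.
    """

    morphology_class: str = "lamellar"
    voxel_size: float = 1.8
    slab_thickness_nm: float = 250.0
    envelope_semi_axes: tuple[float, float] = (380.0, 380.0)
    ibm_offset_nm: float = 15.0
    membrane_thickness_nm: float = 6.0
    contrast: float = 1.0
    noise_sigma: float = 0.25
    blur_sigma_nm: float = 2.0
    seed: int = 0
    crista_params: dict = field(default_factory=dict)
    pad_nm: float = 20.0
    contour_slices: str = "central"   # "central" or "all"

    def __post_init__(self) -> None:
        if self.morphology_class not in MORPHOLOGY_CLASSES:
            raise ValueError(f"unknown morphology class {self.morphology_class!r}")
        for name in ("voxel_size", "slab_thickness_nm", "ibm_offset_nm",
                     "membrane_thickness_nm", "contrast"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if min(self.envelope_semi_axes) <= 0:
            raise ValueError("envelope semi-axes must be strictly positive")
        if self.noise_sigma < 0 or self.blur_sigma_nm < 0:
            raise ValueError("noise/blur sigmas must be >= 0")
        if self.membrane_thickness_nm < self.voxel_size:
            warnings.warn("membrane thinner than one voxel; rendering will be "
                          "sub-voxel", stacklevel=2)
        merged = dict(_DEFAULT_PARAMS[self.morphology_class])
        unknown = set(self.crista_params) - set(merged)
        if unknown:
            raise ValueError(f"unknown crista_params keys: {sorted(unknown)}")
        merged.update(self.crista_params)
        self.crista_params = merged
        self._validate_class_ranges()

    def _validate_class_ranges(self) -> None:
        p = self.crista_params
        if self.morphology_class == "tubular":
            lo, hi = p["diameter_range_nm"]
            if not (50.0 <= lo <= hi <= 90.0):
                raise ValueError("tubular diameters must lie within 50-90 nm")
        if self.morphology_class == "transitional":
            lo, hi = p["tube_diameter_range_nm"]
            if not (30.0 <= lo <= hi <= 60.0):
                raise ValueError("transitional tube diameters must lie within 30-60 nm")
        if self.morphology_class == "lamellar":
            lo, hi = p["fenestration_diameter_range_nm"]
            if not (20.0 <= lo <= hi <= 80.0):
                raise ValueError("fenestration diameters must lie within 20-80 nm")
            r_in = min(self.envelope_semi_axes) - self.ibm_offset_nm
            if p["n_plates"] * p["separation_nm"] > 2 * r_in:
                raise ValueError("envelope too small for the requested number of "
                                 "plates at this separation")

    # derived geometry ------------------------------------------------------
    @property
    def ibm_semi_axes(self) -> tuple[float, float]:
        a, b = self.envelope_semi_axes
        return (a - self.ibm_offset_nm, b - self.ibm_offset_nm)

    def grid_shape(self) -> tuple[int, int, int]:
        a, b = self.envelope_semi_axes
        nz = int(round(self.slab_thickness_nm / self.voxel_size)) + 1
        ny = int(round(2 * (a + self.pad_nm) / self.voxel_size)) + 1
        nx = int(round(2 * (b + self.pad_nm) / self.voxel_size)) + 1
        return nz, ny, nx

    def center_yx(self) -> tuple[float, float]:
        _, ny, nx = self.grid_shape()
        return ((ny - 1) / 2 * self.voxel_size, (nx - 1) / 2 * self.voxel_size)


def lamellar_params_for_density(density_um_inv: float,
                                spec_like: PhantomSpec | None = None,
                                **spec_kwargs) -> PhantomSpec:
    """Build a lamellar spec whose prescribed 2-D crista density
    (L_CRIS/A_MIT) is approximately ``density_um_inv``.

    For plates at pitch p traced as compartment outlines, the density tends
    to 2/p independent of the envelope radius, so the plate count is chosen
    as the available diameter divided by 2/density.
    """
    base = spec_like or PhantomSpec(morphology_class="lamellar", **spec_kwargs)
    sep = base.crista_params["separation_nm"]
    n_max = int(2 * min(base.ibm_semi_axes)
                / (sep + base.membrane_thickness_nm + 4))

    def _spec_for(n: int) -> PhantomSpec:
        params = dict(base.crista_params)
        params["n_plates"] = n
        kw = dict(spec_kwargs)
        kw.update(morphology_class="lamellar", crista_params=params,
                  seed=base.seed)
        for name in ("voxel_size", "slab_thickness_nm", "envelope_semi_axes",
                     "ibm_offset_nm", "membrane_thickness_nm", "contrast",
                     "noise_sigma", "blur_sigma_nm", "contour_slices"):
            kw.setdefault(name, getattr(base, name))
        return PhantomSpec(**kw)

    # the 2/pitch rule ignores plate-end margins and count quantisation, so
    # scan the plate count against the exact analytic density instead
    best_n, best_err = 1, np.inf
    for n in range(1, max(n_max, 2)):
        _, _, truth = generate_phantom(_spec_for(n), render_volume=False)
        err = abs(truth.crista_density_2d_um - density_um_inv)
        if err < best_err:
            best_n, best_err = n, err
    return _spec_for(best_n)


# ---------------------------------------------------------------------------
# geometry primitives (all coordinates in nm)
# ---------------------------------------------------------------------------

@dataclass
class _Plate:
    """A lamellar crista compartment: a box of separation ``sep`` (y extent)
    centred at y=yc, spanning x in [x0, x1] and the whole slab in z.
    ``holes``: (x, z, diameter) fenestrations punched along y.
    ``swollen_span``: optional (x0, x1, swollen_sep)."""
    yc: float
    x0: float
    x1: float
    sep: float
    holes: list = field(default_factory=list)
    swollen_span: tuple | None = None
    necks: list = field(default_factory=list)  # (end:+1/-1, z, d, shape)

    @property
    def length(self) -> float:
        return self.x1 - self.x0


@dataclass
class _Tube:
    """A worm-like crista tube: capsule chain around ``centerline`` (N,3)
    z,y,x points with diameter ``d``.  A single point is a vesicle."""
    centerline: np.ndarray
    d: float


@dataclass
class _VTube:
    """A vertical tube (axis = z, spanning the slab) at (yc, xc)."""
    yc: float
    xc: float
    d: float


@dataclass
class _Geometry:
    plates: list = field(default_factory=list)
    tubes: list = field(default_factory=list)
    vtubes: list = field(default_factory=list)
    # bookkeeping: one crista = one entry of (kind, index)
    order: list = field(default_factory=list)


def _build_lamellar(spec: PhantomSpec, rng: np.random.Generator,
                    x_range: tuple[float, float] | None = None) -> _Geometry:
    p = spec.crista_params
    cy, cx = spec.center_yx()
    a_in, b_in = spec.ibm_semi_axes
    r_avail = a_in - p["edge_margin_nm"]
    n = int(p["n_plates"])
    sep = float(p["separation_nm"])
    geo = _Geometry()
    if n == 0:
        return geo
    pitch = 2 * r_avail / n
    h = spec.slab_thickness_nm
    swollen_ids = rng.choice(n, size=min(int(p["n_swollen"]), n), replace=False)
    for j in range(n):
        # sub-voxel jitter decorrelates plate faces from the voxel lattice:
        # exactly aligned faces would otherwise bias voxelized widths by
        # half a voxel (ground truth is translation invariant, so the
        # jitter costs nothing)
        yc = cy + (j - (n - 1) / 2) * pitch \
            + float(rng.uniform(-0.5, 0.5)) * spec.voxel_size
        frac = (abs(yc - cy) + sep / 2) / a_in
        half = b_in * np.sqrt(max(1.0 - frac ** 2, 0.0))
        half -= p["plate_margin_nm"]
        if half <= 2 * sep:
            continue
        x0, x1 = cx - half, cx + half
        if x_range is not None:
            x0, x1 = max(x0, x_range[0]), min(x1, x_range[1])
            if x1 - x0 <= 2 * sep:
                continue
        plate = _Plate(yc=yc, x0=x0, x1=x1, sep=sep)
        # fenestrations: non-overlapping holes through the plate
        n_fen = int(p["n_fenestrations_per_plate"])
        lo, hi = p["fenestration_diameter_range_nm"]
        placed: list[tuple[float, float, float]] = []
        attempts = 0
        while len(placed) < n_fen and attempts < 200:
            attempts += 1
            d = float(rng.uniform(lo, hi))
            xh = float(rng.uniform(x0 + d / 2 + 15, x1 - d / 2 - 15))
            zh = float(rng.uniform(d / 2 + 12, h - d / 2 - 12))
            if all(np.hypot(xh - xo, zh - zo) > (d + do) / 2 + 12
                   for xo, zo, do in placed):
                placed.append((xh, zh, d))
        plate.holes = placed
        if j in swollen_ids:
            span = p["swollen_length_fraction"] * (x1 - x0)
            xs0 = float(rng.uniform(x0, x1 - span))
            plate.swollen_span = (xs0, xs0 + span,
                                  sep * p["swelling_multiplier"])
        if p["junction_necks"]:
            shape = p["junction_neck_shape"]
            dlo, dhi = p["junction_neck_diameter_nm"]
            for end in (-1, +1):
                if shape == "slot":
                    d = float(p["junction_slot_length_nm"])
                else:
                    d = float(rng.uniform(dlo, dhi))
                zc = float(rng.uniform(0.3 * h, 0.7 * h))
                plate.necks.append((end, zc, d, shape))
        geo.plates.append(plate)
        geo.order.append(("plate", len(geo.plates) - 1))
    return geo


def _build_tubular(spec: PhantomSpec, rng: np.random.Generator,
                   x_range: tuple[float, float] | None = None) -> _Geometry:
    p = spec.crista_params
    cy, cx = spec.center_yx()
    a_in, b_in = spec.ibm_semi_axes
    r_in = min(a_in, b_in)
    h = spec.slab_thickness_nm
    t = spec.membrane_thickness_nm
    geo = _Geometry()
    occupied: list[tuple[np.ndarray, float]] = []  # (points, radius+clearance)

    def inside(pt: np.ndarray, rad: float) -> bool:
        z, y, x = pt
        if not (rad + t <= z <= h - rad - t):
            return False
        m = rad + t + 6
        if ((y - cy) / (a_in - m)) ** 2 + ((x - cx) / (b_in - m)) ** 2 > 1.0:
            return False
        if x_range is not None and not (x_range[0] + rad <= x <= x_range[1] - rad):
            return False
        return True

    def clashes(pt: np.ndarray, rad: float, own: list[np.ndarray]) -> bool:
        for pts, orad in occupied:
            if np.min(np.linalg.norm(pts - pt, axis=1)) < rad + orad + t + 4:
                return True
        if len(own) > 6:
            prev = np.asarray(own[:-6])
            if np.min(np.linalg.norm(prev - pt, axis=1)) < 2 * rad + t:
                return True
        return False

    n_wanted = int(p["n_tubes"])
    attempts_left = 4 * n_wanted
    while len(geo.tubes) < n_wanted and attempts_left > 0:
        attempts_left -= 1
        d = float(rng.uniform(*p["diameter_range_nm"]))
        rad = d / 2
        # seed point + direction; z biased toward the slab centre so the
        # central analysis slice samples the tubes
        band = p["z_seed_band"]
        z_lo = max(rad + t, band[0] * h)
        z_hi = min(h - rad - t, band[1] * h)
        for _try in range(80):
            pt = np.array([rng.uniform(min(z_lo, z_hi), max(z_lo, z_hi)),
                           cy + rng.uniform(-0.75, 0.75) * a_in,
                           (cx if x_range is None else np.mean(x_range))
                           + rng.uniform(-0.7, 0.7)
                           * (b_in if x_range is None
                              else (x_range[1] - x_range[0]) / 2)])
            if inside(pt, rad) and not clashes(pt, rad, []):
                break
        else:
            continue
        direc = rng.standard_normal(3)
        direc[0] *= p["z_wander"]
        direc /= np.linalg.norm(direc)
        n_steps = int(rng.integers(*p["n_steps_range"]))
        pts = [pt.copy()]
        for _step in range(n_steps):
            ok = False
            for _try in range(20):
                # widen the turn search when boxed in, so walks bend away
                # from obstacles instead of terminating
                turn = rng.standard_normal(3) * p["max_turn_rad"] \
                    * (1.0 + 0.25 * _try)
                turn[0] *= p["z_wander"]
                new_dir = direc + turn
                new_dir /= np.linalg.norm(new_dir)
                cand = pts[-1] + new_dir * p["step_nm"]
                if inside(cand, rad) and not clashes(cand, rad, pts):
                    ok = True
                    break
            if not ok:
                break
            direc = new_dir
            pts.append(cand)
        if len(pts) >= 6:
            arr = np.asarray(pts)
            geo.tubes.append(_Tube(arr, d))
            geo.order.append(("tube", len(geo.tubes) - 1))
            occupied.append((arr, rad))
    lo, hi = p["vesicle_diameter_range_nm"]
    for _ in range(int(p["n_vesicles"])):
        d = float(rng.uniform(lo, hi))
        for _try in range(80):
            pt = np.array([rng.uniform(d / 2 + t, h - d / 2 - t),
                           cy + rng.uniform(-0.6, 0.6) * a_in,
                           cx + rng.uniform(-0.6, 0.6) * b_in])
            if inside(pt, d / 2) and not clashes(pt, d / 2, []):
                geo.tubes.append(_Tube(pt[None, :], d))
                geo.order.append(("tube", len(geo.tubes) - 1))
                occupied.append((pt[None, :], d / 2))
                break
    return geo


def _build_transitional(spec: PhantomSpec, rng: np.random.Generator,
                        x_range: tuple[float, float] | None = None) -> _Geometry:
    p = spec.crista_params
    cy, cx = spec.center_yx()
    a_in, b_in = spec.ibm_semi_axes
    h = spec.slab_thickness_nm
    geo = _Geometry()
    n_rows = int(p["n_rows"])
    r_avail = a_in - p["edge_margin_nm"]
    pitch = 2 * r_avail / max(n_rows, 1)
    lo, hi = p["tube_diameter_range_nm"]
    for k in range(n_rows):
        yr = cy + (k - (n_rows - 1) / 2) * pitch
        frac = (abs(yr - cy) + hi / 2) / a_in
        half = b_in * np.sqrt(max(1.0 - frac ** 2, 0.0))
        half -= p["row_margin_nm"]
        if half <= hi:
            continue
        x0, x1 = cx - half, cx + half
        if x_range is not None:
            x0, x1 = max(x0, x_range[0]), min(x1, x_range[1])
            if x1 - x0 <= hi:
                continue
        x = x0
        while True:
            d = float(rng.uniform(lo, hi))
            if rng.uniform() < p["elongated_fraction"]:
                ln = float(rng.uniform(*p["elongated_length_range_nm"]))
                if x + ln > x1:
                    break
                zc = h / 2 + float(rng.uniform(-0.15, 0.15)) * h
                cl = np.array([[zc, yr, x + d / 2], [zc, yr, x + ln - d / 2]])
                geo.tubes.append(_Tube(cl, d))
                geo.order.append(("tube", len(geo.tubes) - 1))
                x += ln + p["tube_gap_nm"]
            else:
                if x + d > x1:
                    break
                geo.vtubes.append(_VTube(yr, x + d / 2, d))
                geo.order.append(("vtube", len(geo.vtubes) - 1))
                x += d + p["tube_gap_nm"]
    return geo


def _build_geometry(spec: PhantomSpec, rng: np.random.Generator) -> _Geometry:
    cls = spec.morphology_class
    if cls == "mixed":
        sub = spec.crista_params["classes"]
        cy, cx = spec.center_yx()
        _a_in, b_in = spec.ibm_semi_axes
        gap = 30.0
        left = (cx - b_in, cx - gap)
        right = (cx + gap, cx + b_in)
        geo = _Geometry()
        for sub_cls, xr in zip(sub, (left, right)):
            sub_spec = PhantomSpec(
                morphology_class=sub_cls, voxel_size=spec.voxel_size,
                slab_thickness_nm=spec.slab_thickness_nm,
                envelope_semi_axes=spec.envelope_semi_axes,
                ibm_offset_nm=spec.ibm_offset_nm,
                membrane_thickness_nm=spec.membrane_thickness_nm,
                contrast=spec.contrast, seed=spec.seed, pad_nm=spec.pad_nm)
            # balance the two half-regions by traced membrane length:
            # lamellar packs ~2x the length per area of tubes, so thin the
            # plates more aggressively than the tube population
            pp = sub_spec.crista_params
            factors = {"n_plates": 0.35, "n_tubes": 1.6, "n_rows": 0.7}
            for key, fac in factors.items():
                if key in pp:
                    pp[key] = max(2, int(np.ceil(pp[key] * fac)))
            if "z_wander" in pp:
                # keep the worm tubes near the central plane so the half
                # regions stay comparable on the analysis slice
                pp["z_wander"] = 0.15
                pp["z_seed_band"] = (0.42, 0.58)
            builder = {"lamellar": _build_lamellar, "tubular": _build_tubular,
                       "transitional": _build_transitional}[sub_cls]
            sub_geo = builder(sub_spec, rng, x_range=xr)
            for kind, idx in sub_geo.order:
                store = getattr(geo, {"plate": "plates", "tube": "tubes",
                                      "vtube": "vtubes"}[kind])
                src = getattr(sub_geo, {"plate": "plates", "tube": "tubes",
                                        "vtube": "vtubes"}[kind])
                store.append(src[idx])
                geo.order.append((kind, len(store) - 1))
        return geo
    builder = {"lamellar": _build_lamellar, "tubular": _build_tubular,
               "transitional": _build_transitional}[cls]
    return builder(spec, rng)


# ---------------------------------------------------------------------------
# signed-distance rendering
# ---------------------------------------------------------------------------

def _plate_sdf(plate: _Plate, z: np.ndarray, y: np.ndarray, x: np.ndarray,
               slab_h: float) -> np.ndarray:
    """SDF of the plate compartment on a broadcastable (z,y,x) grid.
    The plate spans the full slab in z (the slab faces clip it)."""

    def box_sdf(xc, hx, yc, hy) -> np.ndarray:
        dx = np.abs(x - xc) - hx
        dy = np.abs(y - yc) - hy
        dz = np.maximum(-z, z - slab_h)
        outside = np.sqrt(np.maximum(dx, 0) ** 2 + np.maximum(dy, 0) ** 2
                          + np.maximum(dz, 0) ** 2)
        inside = np.minimum(np.maximum(np.maximum(dx, dy), dz), 0)
        return outside + inside

    xc = (plate.x0 + plate.x1) / 2
    sdf = box_sdf(xc, plate.length / 2, plate.yc, plate.sep / 2)
    if plate.swollen_span is not None:
        xs0, xs1, ssep = plate.swollen_span
        sdf = np.minimum(sdf, box_sdf((xs0 + xs1) / 2, (xs1 - xs0) / 2,
                                      plate.yc, ssep / 2))
    for (xh, zh, d) in plate.holes:
        hole = np.sqrt((x - xh) ** 2 + (z - zh) ** 2) - d / 2
        sdf = np.maximum(sdf, -hole)
    for (end, zc, d, shape) in plate.necks:
        xa = plate.x1 if end > 0 else plate.x0
        # half-infinite capsule along x from the plate end outward
        # (the IBM midsurface clips it later)
        dxn = np.where((x - xa) * end > 0, 0.0, np.abs(x - xa))
        if shape == "slot":
            dyn = np.abs(y - plate.yc) - 0.0
            dzn = np.maximum(np.abs(z - zc) - (d / 2 - plate.sep / 2), 0.0)
            neck = np.sqrt(dxn ** 2 + dyn ** 2 + dzn ** 2) - plate.sep / 2
        else:
            neck = np.sqrt(dxn ** 2 + (y - plate.yc) ** 2
                           + (z - zc) ** 2) - d / 2
        sdf = np.minimum(sdf, neck)
    return sdf


def _tube_min_dist(tube: _Tube, dist: np.ndarray, voxel: float,
                   pad_nm: float) -> None:
    """Update a full-grid centreline-distance field in place, segment by
    segment on local bounding blocks."""
    nz, ny, nx = dist.shape
    cl = tube.centerline
    segs = [(cl[i], cl[i + 1]) for i in range(len(cl) - 1)] or [(cl[0], cl[0])]
    for a, b in segs:
        lo = np.minimum(a, b) - pad_nm
        hi = np.maximum(a, b) + pad_nm
        i0 = np.maximum(np.floor(lo / voxel).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / voxel).astype(int) + 1, [nz, ny, nx])
        if np.any(i0 >= i1):
            continue
        zz = (np.arange(i0[0], i1[0]) * voxel)[:, None, None]
        yy = (np.arange(i0[1], i1[1]) * voxel)[None, :, None]
        xx = (np.arange(i0[2], i1[2]) * voxel)[None, None, :]
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.sqrt((zz - a[0]) ** 2 + (yy - a[1]) ** 2 + (xx - a[2]) ** 2)
        else:
            tpar = ((zz - a[0]) * ab[0] + (yy - a[1]) * ab[1]
                    + (xx - a[2]) * ab[2]) / denom
            tpar = np.clip(tpar, 0.0, 1.0)
            d = np.sqrt((zz - (a[0] + tpar * ab[0])) ** 2
                        + (yy - (a[1] + tpar * ab[1])) ** 2
                        + (xx - (a[2] + tpar * ab[2])) ** 2)
        blk = dist[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.minimum(blk, d, out=blk)


def _shell_intensity(absdist: np.ndarray, half_t: float, voxel: float
                     ) -> np.ndarray:
    """Partial-volume membrane intensity from |distance to midsurface|."""
    return np.clip((half_t - absdist) / voxel + 0.5, 0.0, 1.0)


@dataclass
class PhantomSolids:
    """Rendered boolean/label fields of a phantom (same grid as its Volume).

    ``crista_labels``: int16, 0 background, 1..K compartment solids in the
    order of ``GroundTruth.cristae``.  ``membrane``: float in [0,1], the
    noiseless membrane-density map.  ``om_shell``/``ibm_shell``: envelope
    membrane masks.
    """
    crista_labels: np.ndarray
    membrane: np.ndarray
    om_shell: np.ndarray
    ibm_shell: np.ndarray
    voxel_size: float


def _render(spec: PhantomSpec, geo: _Geometry) -> PhantomSolids:
    nz, ny, nx = spec.grid_shape()
    voxel = spec.voxel_size
    cy, cx = spec.center_yx()
    half_t = spec.membrane_thickness_nm / 2
    h = spec.slab_thickness_nm

    membrane = np.zeros((nz, ny, nx), dtype=np.float32)
    labels = np.zeros((nz, ny, nx), dtype=np.int16)

    # envelope: radial field in the xy plane (circular or elliptical)
    yy = (np.arange(ny) * voxel)[:, None] - cy
    xx = (np.arange(nx) * voxel)[None, :] - cx
    a_om, b_om = spec.envelope_semi_axes
    a_ibm, b_ibm = spec.ibm_semi_axes
    if abs(a_om - b_om) < 1e-9:
        d_om = np.hypot(yy, xx) - a_om
        d_ibm = np.hypot(yy, xx) - a_ibm
    else:
        f = np.sqrt((yy / a_om) ** 2 + (xx / b_om) ** 2)
        grad = np.sqrt((yy / a_om ** 2) ** 2 + (xx / b_om ** 2) ** 2)
        d_om = (f - 1.0) / np.maximum(grad, 1e-12)
        f2 = np.sqrt((yy / a_ibm) ** 2 + (xx / b_ibm) ** 2)
        grad2 = np.sqrt((yy / a_ibm ** 2) ** 2 + (xx / b_ibm ** 2) ** 2)
        d_ibm = (f2 - 1.0) / np.maximum(grad2, 1e-12)
    om_2d = _shell_intensity(np.abs(d_om), half_t, voxel)
    ibm_2d = _shell_intensity(np.abs(d_ibm), half_t, voxel)
    membrane += np.broadcast_to(np.maximum(om_2d, ibm_2d), (nz, ny, nx))
    np.clip(membrane, 0, 1, out=membrane)
    om_shell = np.broadcast_to(np.abs(d_om) <= half_t, (nz, ny, nx)).copy()
    ibm_shell = np.broadcast_to(np.abs(d_ibm) <= half_t, (nz, ny, nx)).copy()

    ibm_clip_2d = d_ibm  # >0 outside the IBM midsurface

    label = 0
    for kind, idx in geo.order:
        label += 1
        if kind == "plate":
            plate = geo.plates[idx]
            # local block
            width = plate.sep if plate.swollen_span is None \
                else max(plate.sep, plate.swollen_span[2])
            neck_reach = 80.0 if plate.necks else 0.0
            y0 = plate.yc - width / 2 - half_t - 3 * voxel
            y1 = plate.yc + width / 2 + half_t + 3 * voxel
            x0 = plate.x0 - half_t - 3 * voxel - neck_reach
            x1 = plate.x1 + half_t + 3 * voxel + neck_reach
            j0 = max(int(y0 / voxel), 0); j1 = min(int(np.ceil(y1 / voxel)) + 1, ny)
            i0 = max(int(x0 / voxel), 0); i1 = min(int(np.ceil(x1 / voxel)) + 1, nx)
            zz = (np.arange(nz) * voxel)[:, None, None]
            yyb = (np.arange(j0, j1) * voxel)[None, :, None]
            xxb = (np.arange(i0, i1) * voxel)[None, None, :]
            sdf = _plate_sdf(plate, zz, yyb, xxb, h)
            if plate.necks:
                # clip the compartment at the IBM midsurface so the neck
                # opens onto the inner boundary membrane
                sdf = np.maximum(sdf, ibm_clip_2d[None, j0:j1, i0:i1])
            inten = _shell_intensity(np.abs(sdf), half_t, voxel)
            blk = membrane[:, j0:j1, i0:i1]
            np.maximum(blk, inten, out=blk)
            lab_blk = labels[:, j0:j1, i0:i1]
            lab_blk[sdf <= 0] = label
        elif kind == "tube":
            tube = geo.tubes[idx]
            dist = np.full((nz, ny, nx), np.inf, dtype=np.float32)
            _tube_min_dist(tube, dist, voxel,
                           pad_nm=tube.d / 2 + half_t + 3 * voxel)
            sdf = dist - tube.d / 2
            sel = np.isfinite(sdf)
            inten = np.zeros_like(dist)
            inten[sel] = _shell_intensity(np.abs(sdf[sel]), half_t, voxel)
            np.maximum(membrane, inten, out=membrane)
            labels[sdf <= 0] = label
        elif kind == "vtube":
            vt = geo.vtubes[idx]
            d2 = np.hypot(yy - (vt.yc - cy), xx - (vt.xc - cx)) - vt.d / 2
            inten2d = _shell_intensity(np.abs(d2), half_t, voxel)
            np.maximum(membrane, np.broadcast_to(inten2d, (nz, ny, nx)),
                       out=membrane)
            labels[np.broadcast_to(d2 < 0, (nz, ny, nx))] = label
    membrane *= spec.contrast
    return PhantomSolids(labels, membrane, om_shell, ibm_shell, voxel)


# ---------------------------------------------------------------------------
# contours and ground truth
# ---------------------------------------------------------------------------

def _ellipse_polyline(cy: float, cx: float, a: float, b: float,
                      n: int = 256) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + b * np.cos(th), cy + a * np.sin(th)])


def _plate_slice_polygons(plate: _Plate, z0: float) -> list[Polygon]:
    """Cross-section of the plate compartment with slice z=z0 (shapely
    polygons in (x, y) nm)."""
    parts = [shp_box(plate.x0, plate.yc - plate.sep / 2,
                     plate.x1, plate.yc + plate.sep / 2)]
    if plate.swollen_span is not None:
        xs0, xs1, ssep = plate.swollen_span
        parts.append(shp_box(xs0, plate.yc - ssep / 2, xs1, plate.yc + ssep / 2))
    poly = unary_union(parts)
    for (xh, zh, d) in plate.holes:
        dz = abs(z0 - zh)
        if dz < d / 2:
            c = np.sqrt((d / 2) ** 2 - dz ** 2)
            poly = poly.difference(
                shp_box(xh - c, plate.yc - plate.sep, xh + c,
                        plate.yc + plate.sep))
    if poly.is_empty:
        return []
    return list(poly.geoms) if poly.geom_type == "MultiPolygon" else [poly]


def _tube_slice_contours(geo: _Geometry, spec: PhantomSpec, z0: float,
                         refine: int = 2) -> list[np.ndarray]:
    """Midsurface intersections of worm tubes with slice z=z0, via
    sub-pixel contouring of the analytic distance field on a refined grid."""
    out: list[np.ndarray] = []
    voxel = spec.voxel_size / refine
    _, ny, nx = spec.grid_shape()
    for tube in geo.tubes:
        cl = tube.centerline
        rad = tube.d / 2
        if len(cl) == 1:
            dz = abs(z0 - cl[0][0])
            if dz < rad:
                c = np.sqrt(rad ** 2 - dz ** 2)
                th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
                out.append(np.column_stack([cl[0][2] + c * np.cos(th),
                                            cl[0][1] + c * np.sin(th)]))
            continue
        near = np.abs(cl[:, 0] - z0) < rad + spec.crista_params.get("step_nm", 20.0)
        if not near.any():
            continue
        lo = cl[near].min(axis=0)[1:] - rad - 4 * voxel
        hi = cl[near].max(axis=0)[1:] + rad + 4 * voxel
        j0, i0 = np.maximum(np.floor(lo / voxel).astype(int), 0)
        j1 = min(int(np.ceil(hi[0] / voxel)) + 1, ny * refine)
        i1 = min(int(np.ceil(hi[1] / voxel)) + 1, nx * refine)
        yy = (np.arange(j0, j1) * voxel)[:, None]
        xx = (np.arange(i0, i1) * voxel)[None, :]
        dist = np.full((j1 - j0, i1 - i0), np.inf)
        for a, b in zip(cl[:-1], cl[1:]):
            ab = b - a
            denom = float(ab @ ab)
            tpar = ((z0 - a[0]) * ab[0] + (yy - a[1]) * ab[1]
                    + (xx - a[2]) * ab[2]) / denom
            tpar = np.clip(tpar, 0, 1)
            d = np.sqrt((z0 - (a[0] + tpar * ab[0])) ** 2
                        + (yy - (a[1] + tpar * ab[1])) ** 2
                        + (xx - (a[2] + tpar * ab[2])) ** 2)
            np.minimum(dist, d, out=dist)
        fld = dist - rad
        if fld.min() > 0:
            continue
        for c in measure.find_contours(fld, 0.0):
            closed = np.allclose(c[0], c[-1])
            pts = np.column_stack([(c[:, 1] + i0) * voxel,
                                   (c[:, 0] + j0) * voxel])
            if closed:
                pts = pts[:-1]
            if len(pts) >= 3:
                out.append(pts)
    return out


def _slice_contours(spec: PhantomSpec, geo: _Geometry, z0: float
                    ) -> list[Contour]:
    cy, cx = spec.center_yx()
    a_om, b_om = spec.envelope_semi_axes
    a_ibm, b_ibm = spec.ibm_semi_axes
    cons = [
        Contour(z0, "OM", _ellipse_polyline(cy, cx, a_om, b_om), closed=True),
        Contour(z0, "IBM", _ellipse_polyline(cy, cx, a_ibm, b_ibm), closed=True),
    ]
    for plate in geo.plates:
        for poly in _plate_slice_polygons(plate, z0):
            xy = np.asarray(poly.exterior.coords)[:-1]
            cons.append(Contour(z0, "crista", xy, closed=True))
    for pts in _tube_slice_contours(geo, spec, z0):
        cons.append(Contour(z0, "crista", pts, closed=True))
    for vt in geo.vtubes:
        th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([vt.xc + vt.d / 2 * np.cos(th),
                               vt.yc + vt.d / 2 * np.sin(th)])
        cons.append(Contour(z0, "crista", pts, closed=True))
    return cons


def _ellipse_perimeter(a: float, b: float) -> float:
    if abs(a - b) < 1e-12:
        return 2 * np.pi * a
    # Ramanujan II approximation, error < 1e-6 for mild eccentricity
    hh = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * hh / (10 + np.sqrt(4 - 3 * hh)))


@dataclass
class GroundTruth:
    """Closed-form truth for a phantom: per-crista 3-D quantities, per-slice
    2-D trace quantities, and labels.  Areas in nm^2, volumes nm^3, lengths
    nm, on the slab-clipped geometry; crista areas are native (slab caps
    excluded)."""
    morphology: str
    cristae: list[dict]
    per_slice: dict          # z -> dict(L_CRIS_nm, L_IBM_nm, L_OM_nm, A_MIT_nm2)
    A_MIT_nm2: float
    V_MIT_nm3: float
    n_cristae: int
    swollen: bool
    crista_density_2d_um: float   # central slice L_CRIS/A_MIT
    crista_density_3d_um: float   # sum S_native / V_MIT
    seed: int

    def to_json(self, path: str | Path) -> None:
        rec = asdict(self)
        rec["per_slice"] = {f"{z:.6f}": v for z, v in self.per_slice.items()}
        Path(path).write_text(json.dumps(rec))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        rec = json.loads(Path(path).read_text())
        rec["per_slice"] = {float(z): v for z, v in rec["per_slice"].items()}
        return cls(**rec)


def _plate_truth(plate: _Plate, h: float) -> dict:
    """Native midsurface area and compartment volume of a slab-spanning,
    possibly fenestrated / swollen plate."""
    L, w = plate.length, plate.sep
    if plate.swollen_span is None:
        faces = 2 * L * h
        rims = 2 * w * h
        vol = L * w * h
    else:
        xs0, xs1, sw = plate.swollen_span
        ls = min(xs1, plate.x1) - max(xs0, plate.x0)
        faces = 2 * L * h            # y-offset does not change face area
        rims = 2 * w * h + 2 * 2 * ((sw - w) / 2) * h  # end rims + 2 steps x2
        # clamp: if swollen span reaches an end, that end rim is taller
        vol = L * w * h + ls * (sw - w) * h
    hole_area = sum(2 * np.pi * (d / 2) ** 2 for *_xz, d in plate.holes)
    rim_area = sum(np.pi * d * w for *_xz, d in plate.holes)
    hole_vol = sum(np.pi * (d / 2) ** 2 * w for *_xz, d in plate.holes)
    necks = []
    neck_area = 0.0
    for (_end, _zc, d, shape) in plate.necks:
        necks.append({"size_nm": d, "shape": shape})
    return {
        "kind": "plate",
        "S_native_nm2": faces + rims - hole_area + rim_area + neck_area,
        "V_nm3": vol - hole_vol,
        "n_fenestrations": len(plate.holes),
        "fen_widths_nm": [d for *_xz, d in plate.holes],
        "n_junctions": len(necks),
        "junctions": necks,
        "spans_slab": True,
    }


def _tube_truth(tube: _Tube) -> dict:
    cl = tube.centerline
    d = tube.d
    if len(cl) == 1:
        area = np.pi * d ** 2
        vol = np.pi * d ** 3 / 6
        length = 0.0
    else:
        length = float(np.linalg.norm(np.diff(cl, axis=0), axis=1).sum())
        area = np.pi * d * length + np.pi * d ** 2      # lateral + 2 hemi caps
        vol = np.pi * (d / 2) ** 2 * length + np.pi * d ** 3 / 6
    return {
        "kind": "tube" if len(cl) > 1 else "vesicle",
        "S_native_nm2": float(area), "V_nm3": float(vol),
        "centerline_length_nm": length,
        "n_fenestrations": 0, "fen_widths_nm": [],
        "n_junctions": 0, "junctions": [],
        "spans_slab": False,
    }


def _vtube_truth(vt: _VTube, h: float) -> dict:
    return {
        "kind": "vtube",
        "S_native_nm2": float(np.pi * vt.d * h),
        "V_nm3": float(np.pi * (vt.d / 2) ** 2 * h),
        "n_fenestrations": 0, "fen_widths_nm": [],
        "n_junctions": 0, "junctions": [],
        "spans_slab": True,
    }


def _ground_truth(spec: PhantomSpec, geo: _Geometry,
                  contour_zs: list[float],
                  contour_sets: dict[float, list[Contour]]) -> GroundTruth:
    h = spec.slab_thickness_nm
    a_ibm, b_ibm = spec.ibm_semi_axes
    a_om, b_om = spec.envelope_semi_axes
    A_mit = np.pi * a_ibm * b_ibm
    V_mit = A_mit * h
    cristae = []
    for kind, idx in geo.order:
        if kind == "plate":
            cristae.append(_plate_truth(geo.plates[idx], h))
        elif kind == "tube":
            cristae.append(_tube_truth(geo.tubes[idx]))
        else:
            cristae.append(_vtube_truth(geo.vtubes[idx], h))
    per_slice = {}
    for z0 in contour_zs:
        cons = contour_sets[z0]
        L_cris = sum(c.length() for c in cons if c.label == "crista")
        per_slice[z0] = {
            "L_CRIS_nm": L_cris,
            "L_IBM_nm": _ellipse_perimeter(a_ibm, b_ibm),
            "L_OM_nm": _ellipse_perimeter(a_om, b_om),
            "A_MIT_nm2": A_mit,
        }
    zc = contour_zs[len(contour_zs) // 2]
    dens2d = per_slice[zc]["L_CRIS_nm"] / A_mit * 1000.0  # um^-1
    s_total = sum(c["S_native_nm2"] for c in cristae)
    dens3d = s_total / V_mit * 1000.0
    swollen = any(p.swollen_span is not None for p in geo.plates)
    return GroundTruth(
        morphology=spec.morphology_class, cristae=cristae,
        per_slice=per_slice, A_MIT_nm2=float(A_mit), V_MIT_nm3=float(V_mit),
        n_cristae=len(cristae), swollen=swollen,
        crista_density_2d_um=float(dens2d), crista_density_3d_um=float(dens3d),
        seed=spec.seed)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, render_volume: bool = True
                     ) -> tuple[Volume | None, ContourSet, GroundTruth]:
    """Generate (noiseless Volume, ContourSet, GroundTruth) for a spec.

    ``render_volume=False`` skips voxel rendering (contours and truth only),
    which is much faster when only 2-D analyses are needed.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _build_geometry(spec, rng)
    nz = spec.grid_shape()[0]
    zs_all = [i * spec.voxel_size for i in range(nz)]
    if spec.contour_slices == "all":
        contour_zs = zs_all
    else:
        contour_zs = [zs_all[len(zs_all) // 2]]
    contour_sets = {z0: _slice_contours(spec, geo, z0) for z0 in contour_zs}
    cset = ContourSet([c for z0 in contour_zs for c in contour_sets[z0]],
                      mito_id=f"{spec.morphology_class}-{spec.seed}")
    truth = _ground_truth(spec, geo, contour_zs, contour_sets)
    vol = None
    if render_volume:
        solids = _render(spec, geo)
        vol = Volume(solids.membrane, spec.voxel_size)
    return vol, cset, truth


def phantom_solids(spec: PhantomSpec) -> PhantomSolids:
    """Render the phantom's compartment label field and membrane masks
    (deterministic for a given spec + seed; same geometry as
    ``generate_phantom``)."""
    rng = np.random.default_rng(spec.seed)
    geo = _build_geometry(spec, rng)
    return _render(spec, geo)


def corrupt(vol: Volume, noise_sigma: float, blur_sigma_nm: float,
            seed: int) -> Volume:
    """Gaussian blur (sigma in nm) then additive Gaussian noise, emulating
    stain/optics blur and detection noise.  Dimensions and voxel size are
    preserved; sigma 0 disables the corresponding step."""
    if noise_sigma < 0 or blur_sigma_nm < 0:
        raise ValueError("sigmas must be >= 0")
    data = vol.data
    if blur_sigma_nm > 0:
        data = ndimage.gaussian_filter(data, blur_sigma_nm / vol.voxel_size,
                                       mode="reflect")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.standard_normal(data.shape).astype(np.float32) \
            * noise_sigma
    return Volume(np.asarray(data, dtype=np.float32), vol.voxel_size)
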