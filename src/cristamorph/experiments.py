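"""Validation experiments: each function runs one self-contained study on
synthetic data with known truth and returns its summary numbers.

These are the package's benchmark suite — mesh accuracy on analytic solids,
the surface-to-volume limits of tubes and plates, end-to-end crista-density
recovery, classification accuracy, fenestration/junction recovery, and the
statistical machinery checks.  The numbered scripts under ``analysis/``,
the acceptance tests and ``scripts/acceptance.py`` all drive these same
functions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.integrate import quad
from scipy.special import gammaln

from .classify import (ClassifyConfig, classify_contours,
                       polylines_from_mask)
from .config import _MORPH_DEFAULTS, _SEG_DEFAULTS
from .imageproc import FilterParams
from .morphometry3d import (detect_fenestrations, detect_junctions,
                            mesh_area, mesh_volume, sv_ratio)
from .phantom import PhantomSpec, corrupt, generate_phantom, phantom_solids
from .pipeline import classify_central_slice, enhance_volume, \
    segment_and_measure
from .segmentation import LabelVolume, extract_mesh, seal_mesh
from .stats import unpaired_t
from .volume import Volume

__all__ = [
    "analytic_solid_suite", "sv_limit_suite", "density_recovery_sweep",
    "classification_benchmark", "fenestration_suite", "junction_suite",
    "ttest_oracle_suite", "folding_density_sweep", "PHANTOM_CONDITIONS",
]

# standard phantom conditions of the benchmark studies (nm / nm / nm)
PHANTOM_CONDITIONS = dict(voxel_size=2.5, slab_thickness_nm=200.0)
CLASS_ENVELOPES = {"lamellar": (260.0, 260.0), "tubular": (260.0, 260.0),
                   "transitional": (260.0, 260.0), "mixed": (260.0, 420.0)}


# ---------------------------------------------------------------------------
# mesh accuracy on analytic solids
# ---------------------------------------------------------------------------

def _mesh_of_mask(mask: np.ndarray, voxel: float = 1.0):
    (_k, mesh), = extract_mesh(LabelVolume(mask.astype(np.uint8), voxel))
    return mesh


def analytic_solid_suite() -> dict:
    """Mesh area/volume errors (percent) for a sphere, cube and cylinder
    voxelized at 1 nm, against their closed forms."""
    out = {}
    c, r = 40.31, 30.0
    zz, yy, xx = np.meshgrid(*(np.arange(81),) * 3, indexing="ij")
    mesh = _mesh_of_mask((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
                         <= r ** 2)
    out["sphere_area_err_pct"] = 100 * abs(
        mesh_area(mesh) * 1e6 / (4 * np.pi * r ** 2) - 1)
    out["sphere_volume_err_pct"] = 100 * abs(
        mesh_volume(mesh) * 1e9 / (4 / 3 * np.pi * r ** 3) - 1)

    side = 101.0
    zz, yy, xx = np.meshgrid(*(np.arange(121),) * 3, indexing="ij")
    mesh = _mesh_of_mask((np.abs(zz - 60) <= 50) & (np.abs(yy - 60) <= 50)
                         & (np.abs(xx - 60) <= 50))
    out["cube_area_err_pct"] = 100 * abs(
        mesh_area(mesh) * 1e6 / (6 * side ** 2) - 1)
    out["cube_volume_err_pct"] = 100 * abs(
        mesh_volume(mesh) * 1e9 / side ** 3 - 1)

    R, L = 20.0, 121.0
    zz, yy, xx = np.meshgrid(np.arange(161), np.arange(61), np.arange(61),
                             indexing="ij")
    mesh = _mesh_of_mask(((yy - 30.2) ** 2 + (xx - 30.2) ** 2 <= R ** 2)
                         & (np.abs(zz - 80) <= 60))
    a_true = 2 * np.pi * R * L + 2 * np.pi * R ** 2
    out["cylinder_area_err_pct"] = 100 * abs(mesh_area(mesh) * 1e6 / a_true
                                             - 1)
    out["cylinder_volume_err_pct"] = 100 * abs(
        mesh_volume(mesh) * 1e9 / (np.pi * R ** 2 * L) - 1)
    return out


# ---------------------------------------------------------------------------
# S/V limits
# ---------------------------------------------------------------------------

def _sealed_slab_cylinder(d_nm: float, slab_nm: float = 1000.0):
    r = d_nm / 2
    n = int(2 * r + 14)
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (yy - n / 2 + 0.3) ** 2 + (xx - n / 2 + 0.3) ** 2 <= r ** 2
    mask = np.broadcast_to(disk, (int(slab_nm) + 1, n, n)).copy()
    mesh = _mesh_of_mask(mask)
    return seal_mesh(mesh, (0.0, slab_nm))


def _sealed_slab_plate(sep_nm: float, face_nm: float = 450.0):
    w = int(sep_nm)
    mask = np.zeros((int(face_nm) + 1, w + 24, int(face_nm) + 21),
                    dtype=bool)
    mask[:, 12:12 + w, 10:10 + int(face_nm)] = True
    mesh = _mesh_of_mask(mask)
    return seal_mesh(mesh, (0.0, face_nm))


def sv_limit_suite() -> dict:
    """Native surface-to-volume ratios of a sealed long tube (D = 20 nm,
    limit 4/D = 200 um^-1) and a sealed plate compartment (20 nm wall
    separation, limit 2/D = 100 um^-1), plus the tube>plate ordering over
    D in {20, 50, 80} nm."""
    out = {}
    out["cylinder_sv_um"] = sv_ratio(_sealed_slab_cylinder(20.0))
    out["plate_sv_um"] = sv_ratio(_sealed_slab_plate(20.0))
    ordering = True
    for d in (20.0, 50.0, 80.0):
        cyl = sv_ratio(_sealed_slab_cylinder(d, slab_nm=300.0))
        plate = sv_ratio(_sealed_slab_plate(d, face_nm=300.0))
        ordering &= cyl > plate
    out["cylinder_above_plate_all_d"] = bool(ordering)
    return out


# ---------------------------------------------------------------------------
# end-to-end density recovery
# ---------------------------------------------------------------------------

DENSITY_SWEEP = [
    # (envelope semi-axis nm, n_plates): 12 prescribed crista densities
    # covering ~10-38 um^-1 (bracketing tubular 11-14 and lamellar 27-33)
    (300.0, 3), (320.0, 4), (300.0, 4), (300.0, 5), (300.0, 6),
    (320.0, 7), (300.0, 7), (300.0, 8), (300.0, 9), (320.0, 10),
    (300.0, 10), (300.0, 11),
]


def _segmentation_profile_density(enhanced: Volume, seg: dict,
                                  z_trim: int) -> float:
    """2-D crista density (L_CRIS/A_MIT, um^-1) measured from the segmented
    central slice: crista membrane midlines by skeletonization, profile
    area from the recovered IBM interior."""
    part = seg["partition"]
    data = enhanced.data[z_trim:-z_trim] if z_trim > 0 else enhanced.data
    crista_mem = (data > seg["threshold"]) & ~part.om_mask & ~part.ibm_mask
    zc = crista_mem.shape[0] // 2
    voxel = enhanced.voxel_size
    polys = polylines_from_mask(crista_mem[zc], voxel)
    length = 0.0
    for pts, closed in polys:
        length += float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        if closed:
            length += float(np.linalg.norm(pts[-1] - pts[0]))
    area = float(part.ibm_interior[zc].sum()) * voxel ** 2
    return length / area * 1000.0


def density_recovery_sweep(seed: int = 1) -> list[dict]:
    """Run the full image pipeline (corrupt, condition, segment, mesh,
    measure) on 12 lamellar phantoms of prescribed density and report
    prescribed vs recovered 2-D and 3-D densities."""
    results = []
    for i, (env, n_plates) in enumerate(DENSITY_SWEEP):
        spec = PhantomSpec(morphology_class="lamellar",
                           envelope_semi_axes=(env, env),
                           seed=seed * 1000 + i,
                           crista_params={"n_plates": n_plates},
                           **PHANTOM_CONDITIONS)
        vol, _cset, truth = generate_phantom(spec)
        noisy = corrupt(vol, spec.noise_sigma * spec.contrast,
                        spec.blur_sigma_nm, seed=seed * 1000 + 500 + i)
        enhanced = enhance_volume(noisy, FilterParams())
        seg = segment_and_measure(enhanced, dict(_SEG_DEFAULTS),
                                  dict(_MORPH_DEFAULTS))
        dens2d = _segmentation_profile_density(enhanced, seg,
                                               _SEG_DEFAULTS["z_trim"])
        results.append({
            "prescribed_2d_um": truth.crista_density_2d_um,
            "prescribed_3d_um": truth.crista_density_3d_um,
            "recovered_2d_um": dens2d,
            "recovered_3d_um": seg["crista_density_3d_um"],
            "n_cristae_true": truth.n_cristae,
            "n_cristae_found": seg["n_cristae"],
        })
    return results


# ---------------------------------------------------------------------------
# classification benchmark
# ---------------------------------------------------------------------------

def classification_benchmark(seed: int = 1, noise_factor: float = 0.0,
                             n_per_class: int = 10) -> dict:
    """Classify ``n_per_class`` phantoms per morphology class.

    ``noise_factor`` = 0 classifies the exact traced contours; > 0 runs the
    image route on volumes corrupted with that noise (in units of membrane
    contrast): enhancement, thresholding and skeleton tracing of a central
    sub-slab.
    """
    want = {"lamellar": "Lam", "tubular": "Tub", "transitional": "Trans",
            "mixed": "Mix"}
    n_ok, n_tot = 0, 0
    confusion: dict[str, dict[str, int]] = {}
    for cls, target in want.items():
        for k in range(n_per_class):
            spec = PhantomSpec(morphology_class=cls,
                               envelope_semi_axes=CLASS_ENVELOPES[cls],
                               seed=seed * 100 + k, **PHANTOM_CONDITIONS)
            if noise_factor == 0.0:
                _, cset, _ = generate_phantom(spec, render_volume=False)
                label, _scores = classify_contours(cset)
            else:
                vol, _cset, _ = generate_phantom(spec)
                noisy = corrupt(vol, noise_factor * spec.contrast,
                                spec.blur_sigma_nm,
                                seed=seed * 100 + 50 + k)
                zc = noisy.data.shape[0] // 2
                crop = Volume(noisy.data[zc - 8:zc + 9].copy(),
                              noisy.voxel_size)
                enhanced = enhance_volume(crop, FilterParams())
                label, _scores, _sw = classify_central_slice(
                    enhanced, dict(_SEG_DEFAULTS), ClassifyConfig())
            confusion.setdefault(target, {}).setdefault(label, 0)
            confusion[target][label] += 1
            n_ok += label == target
            n_tot += 1
    return {"accuracy_pct": 100.0 * n_ok / n_tot, "n": n_tot,
            "confusion": confusion}


# ---------------------------------------------------------------------------
# fenestration / junction recovery
# ---------------------------------------------------------------------------

def _crista_mesh(spec: PhantomSpec, sealed: bool = True):
    solids = phantom_solids(spec)
    (_k, mesh), = extract_mesh(LabelVolume(solids.crista_labels,
                                           solids.voxel_size))
    if sealed:
        nz = solids.crista_labels.shape[0]
        mesh = seal_mesh(mesh, (0.0, (nz - 1) * solids.voxel_size))
    return mesh, solids


def fenestration_suite(seed: int = 2) -> dict:
    """Recover hole counts and widths of fenestrated plates (40 nm trio and
    the 20/80 nm range endpoints), with the Euler-characteristic genus."""
    out = {}
    for tag, (lo, hi, n) in (("40nm", (40.0, 40.0, 3)),
                             ("endpoints", (20.0, 80.0, 2))):
        spec = PhantomSpec(
            morphology_class="lamellar", voxel_size=2.0,
            slab_thickness_nm=250.0, envelope_semi_axes=(300.0, 300.0),
            seed=seed, crista_params={
                "n_plates": 1, "n_fenestrations_per_plate": n,
                "fenestration_diameter_range_nm": (lo, hi)})
        _, _, truth = generate_phantom(spec, render_volume=False)
        mesh, _ = _crista_mesh(spec)
        widths, mean, genus = detect_fenestrations(mesh)
        gt = sorted(truth.cristae[0]["fen_widths_nm"], reverse=True)
        out[tag] = {
            "n_true": len(gt), "n_found": len(widths), "genus": genus,
            "true_widths_nm": gt, "found_widths_nm": widths,
            "mean_width_nm": mean, "true_mean_nm": float(np.mean(gt)),
        }
    return out


def junction_suite(seed: int = 4) -> dict:
    """Recover junction-opening counts, sizes and shapes for round necks
    (30 nm) and slot necks (70 x 20 nm)."""
    out = {}
    for tag, params in (("round", {"junction_neck_diameter_nm":
                                   (30.0, 30.0)}),
                        ("slot", {"junction_neck_shape": "slot"})):
        spec = PhantomSpec(
            morphology_class="lamellar", voxel_size=2.0,
            slab_thickness_nm=150.0, envelope_semi_axes=(240.0, 240.0),
            seed=seed,
            crista_params={"n_plates": 1, "junction_necks": True, **params})
        _, _, truth = generate_phantom(spec, render_volume=False)
        mesh, solids = _crista_mesh(spec, sealed=False)
        shape = solids.crista_labels.shape
        voxel = solids.voxel_size
        cy = (shape[1] - 1) / 2 * voxel
        cx = (shape[2] - 1) / 2 * voxel
        yy, xx = np.meshgrid(np.arange(shape[1]) * voxel,
                             np.arange(shape[2]) * voxel, indexing="ij")
        inner = np.hypot(yy - cy, xx - cx) <= min(spec.ibm_semi_axes)
        ibm_mask = np.broadcast_to(inner, shape).astype(np.uint8)
        (_k, ibm_mesh), = extract_mesh(LabelVolume(ibm_mask, voxel))
        js = detect_junctions(mesh, ibm_mesh, contact_tol=10.0)
        out[tag] = {
            "n_true": truth.cristae[0]["n_junctions"], "n_found": len(js),
            "true_sizes_nm": [j["size_nm"]
                              for j in truth.cristae[0]["junctions"]],
            "found": [{"shape": j.shape, "size_nm": j.size_nm,
                       "width_nm": j.width_nm} for j in js],
        }
    return out


# ---------------------------------------------------------------------------
# statistics machinery
# ---------------------------------------------------------------------------

def t_pvalue_by_integration(t: float, df: float) -> float:
    """Two-tailed p-value by numerical quadrature of the t density."""
    lognorm = gammaln((df + 1) / 2) - gammaln(df / 2) \
        - 0.5 * np.log(df * np.pi)

    def pdf(x):
        return np.exp(lognorm - (df + 1) / 2 * np.log1p(x * x / df))

    tail, _err = quad(pdf, abs(t), np.inf)
    return 2 * tail


def ttest_oracle_suite(seed: int = 1, reps: int = 2000, n: int = 10) -> dict:
    """Agreement of the pooled t-test with a numerical-integration oracle,
    and its null calibration (type-I error at alpha = 0.05)."""
    res = unpaired_t([1.0, 2.0, 3.0, 4.0, 5.0], [2.0, 3.0, 4.0, 5.0, 6.0])
    p_oracle = t_pvalue_by_integration(res.t, res.df)
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((reps, n))
    b = rng.standard_normal((reps, n))
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    sp = np.sqrt(((n - 1) * va + (n - 1) * vb) / (2 * n - 2))
    t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2 / n))
    p = 2 * sps.t.sf(np.abs(t), 2 * n - 2)
    return {
        "t": res.t, "p": res.p, "p_oracle": p_oracle,
        "p_abs_err": abs(res.p - p_oracle),
        "type1_error_rate": float(np.mean(p < 0.05)),
        "reps": reps,
    }


def folding_density_sweep(seed: int = 1, n_range=range(2, 12)) -> dict:
    """Crista density vs inner-membrane folding (L_CRIS/L_IM) across a
    lamellar plate-count sweep; reports the Spearman correlation."""
    from .morphometry2d import profile_metrics
    dens, fold = [], []
    for n in n_range:
        spec = PhantomSpec(morphology_class="lamellar",
                           envelope_semi_axes=(300.0, 300.0),
                           seed=seed * 10 + n,
                           crista_params={"n_plates": n},
                           **PHANTOM_CONDITIONS)
        _, cset, _ = generate_phantom(spec, render_volume=False)
        m = profile_metrics(cset)
        dens.append(m.crista_density)
        fold.append(m.folding)
    rho, _p = sps.spearmanr(fold, dens)
    return {"spearman_rho": float(rho), "density_um": dens, "folding": fold,
            "n": len(dens)}
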