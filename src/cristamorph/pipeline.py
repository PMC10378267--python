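"""End-to-end pipeline: phantom/tomogram -> conditioned volume ->
membrane segmentation -> compartments -> meshes -> morphometrics ->
classification, with a provenance-complete report.

Stage order follows tomography practice: rolling slice averages, anisotropic
diffusion, Hessian membrane enhancement, thresholding, connected components
and compartment recovery, marching-cubes meshing with slab sealing, then the
2-D/3-D morphometry and the rule-based classification.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
from scipy import ndimage

from . import __version__
from .classify import (ClassifyConfig, classify_morphology,
                       extract_slice_features, flag_swollen,
                       polylines_from_mask)
from .config import PipelineConfig
from .imageproc import (FilterParams, anisotropic_diffusion, membrane_filter,
                        rolling_average)
from .morphometry3d import crista_density_3d, crista_metrics, mesh_volume
from .phantom import PhantomSpec, corrupt, generate_phantom
from .segmentation import (LabelVolume, binarize, extract_mesh,
                           partition_mitochondrion, seal_mesh)
from .volume import Volume, read_mrc

__all__ = ["run_pipeline", "enhance_volume", "segment_and_measure",
           "classify_central_slice"]

log = logging.getLogger(__name__)


def enhance_volume(vol: Volume, params: FilterParams) -> Volume:
    """Conditioning chain: rolling average -> anisotropic diffusion ->
    multiscale membrane enhancement."""
    out = rolling_average(vol, params.rolling_window)
    out = anisotropic_diffusion(out, params)
    return membrane_filter(out, params)


def _binary_close(mask: np.ndarray, iters: int) -> np.ndarray:
    if iters <= 0:
        return mask
    return ndimage.binary_closing(mask, iterations=iters)


def segment_and_measure(enhanced: Volume, seg_cfg: dict, morph_cfg: dict
                        ) -> dict:
    """Threshold, recover compartments, mesh and measure them.

    Returns the per-crista records, the 3-D crista density, the recovered
    mitochondrial volume, and the membrane mask pieces needed downstream.
    """
    binary = binarize(enhanced, method=seg_cfg["method"],
                      threshold=seg_cfg["threshold"])
    mask = _binary_close(binary.data > 0, seg_cfg["close_iters"])
    # the outermost slices lose membrane response to filter boundary
    # effects, which would leak every compartment into the exterior; the
    # analysed slab is trimmed accordingly (density metrics are intensive,
    # so a slightly thinner slab changes nothing systematic)
    trim = int(seg_cfg.get("z_trim", 0))
    if trim > 0:
        mask = mask[trim:-trim]
    lv = LabelVolume(mask.astype(np.uint8), enhanced.voxel_size,
                     threshold=binary.threshold)
    part = partition_mitochondrion(
        lv, membrane_thickness_nm=morph_cfg["membrane_thickness_nm"],
        min_ics_voxels=seg_cfg["min_ics_voxels"])
    voxel = enhanced.voxel_size
    nz = mask.shape[0]
    slab = (0.0, (nz - 1) * voxel)

    solids = LabelVolume(part.crista_solids, voxel)
    records = []
    crista_meshes = []
    if solids.n_labels > 0:
        for k, mesh in extract_mesh(solids):
            sealed = seal_mesh(mesh, slab)
            if not sealed.is_watertight:
                log.warning("crista %d not watertight after sealing; skipped",
                            k)
                continue
            rec = crista_metrics(
                k, sealed, with_fenestrations=morph_cfg["with_fenestrations"])
            records.append(rec)
            crista_meshes.append(sealed)

    env = LabelVolume(part.ibm_interior.astype(np.uint8), voxel)
    (_k, env_mesh), = extract_mesh(env)
    env_mesh = seal_mesh(env_mesh, slab)
    v_mit = mesh_volume(env_mesh)
    density = crista_density_3d(crista_meshes, env_mesh) if crista_meshes \
        else 0.0
    return {
        "threshold": binary.threshold,
        "foreground_fraction": lv.foreground_fraction(),
        "n_cristae": len(records),
        "crista_records": records,
        "crista_meshes": crista_meshes,
        "V_MIT_um3": v_mit,
        "crista_density_3d_um": density,
        "partition": part,
    }


def _hull_filter(polylines, margin_nm: float = 30.0):
    """Drop polylines hugging the convex hull of all traced points (the
    envelope membranes), keeping interior cristae."""
    from shapely.geometry import MultiPoint, Point
    all_pts = np.vstack([p for p, _ in polylines])
    hull = MultiPoint([tuple(p) for p in all_pts]).convex_hull
    boundary = hull.exterior if hull.geom_type == "Polygon" else hull
    kept = []
    for pts, closed in polylines:
        step = max(len(pts) // 24, 1)
        d = np.median([boundary.distance(Point(p)) for p in pts[::step]])
        if d > margin_nm:
            kept.append((pts, closed))
    return kept


def classify_central_slice(enhanced: Volume, seg_cfg: dict,
                           classify_cfg: ClassifyConfig,
                           crista_mask_2d: np.ndarray | None = None
                           ) -> tuple[str, dict, bool]:
    """Classify morphology from the segmented central slice.

    If a crista-only membrane mask is supplied (from compartment recovery)
    it is used directly; otherwise the slice is thresholded and the envelope
    membranes are removed by a convex-hull proximity filter.
    Returns (label, scores, swollen_flag).
    """
    voxel = enhanced.voxel_size
    if crista_mask_2d is None:
        binary = binarize(enhanced, method=seg_cfg["method"],
                          threshold=seg_cfg["threshold"])
        mask = _binary_close(binary.data > 0, seg_cfg["close_iters"])
        slice_mask = mask[mask.shape[0] // 2]
        polylines = polylines_from_mask(slice_mask, voxel)
        polylines = _hull_filter(polylines) if polylines else polylines
    else:
        polylines = polylines_from_mask(crista_mask_2d, voxel)
    feats = extract_slice_features(polylines, classify_cfg)
    label, scores = classify_morphology(feats, classify_cfg)
    return label, scores, flag_swollen(feats.pair_profiles, classify_cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline per the config and return the report.

    The report embeds the effective configuration, the package version and
    every stage's key numbers; identical config (seed included) gives an
    identical report.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    report: dict = {"version": __version__, "config": config.to_dict(),
                    "stages": {}}

    try:
        if config.phantom is not None:
            spec = PhantomSpec(**{**config.phantom, "seed": config.seed})
            vol, cset, truth = generate_phantom(spec)
            report["stages"]["simulate"] = {
                "morphology": truth.morphology,
                "n_cristae": truth.n_cristae,
                "crista_density_2d_um": truth.crista_density_2d_um,
                "crista_density_3d_um": truth.crista_density_3d_um,
            }
            vol = corrupt(vol, spec.noise_sigma * spec.contrast,
                          spec.blur_sigma_nm, seed=config.seed + 1)
        else:
            vol = read_mrc(config.input_volume)
            cset = None
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    try:
        params = FilterParams(**config.filters)
        enhanced = enhance_volume(vol, params)
        report["stages"]["enhance"] = {"params": asdict(params)}
    except Exception as exc:
        raise RuntimeError(f"stage 'enhance' failed: {exc}") from exc

    try:
        seg = segment_and_measure(enhanced, config.segmentation,
                                  config.morphometry)
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed: {exc}") from exc
    report["stages"]["segment"] = {
        "threshold": seg["threshold"],
        "foreground_fraction": seg["foreground_fraction"],
        "n_cristae": seg["n_cristae"],
    }
    report["V_MIT_um3"] = seg["V_MIT_um3"]
    report["crista_density_3d_um"] = seg["crista_density_3d_um"]
    report["crista_records"] = [
        {k: v for k, v in asdict(r).items() if k != "junctions"}
        for r in seg["crista_records"]]

    try:
        part = seg["partition"]
        trim = int(config.segmentation.get("z_trim", 0))
        data = enhanced.data[trim:-trim] if trim > 0 else enhanced.data
        crista_mem = (data > seg["threshold"]) \
            & ~part.om_mask & ~part.ibm_mask
        nz = crista_mem.shape[0]
        ccfg = ClassifyConfig(**config.classify)
        label, scores, swollen = classify_central_slice(
            enhanced, config.segmentation, ccfg,
            crista_mask_2d=crista_mem[nz // 2])
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
    report["morphology"] = label
    report["morphology_scores"] = scores
    report["swollen"] = bool(swollen)
    return report
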