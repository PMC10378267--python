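"""From enhanced volumes to labeled membranes, compartments and meshes.

The route mirrors semi-automated tomogram segmentation practice: threshold
the membrane-enhanced volume, split the foreground into connected membrane
components, recover the *compartments* the membranes bound (intracristal
spaces, intermembrane space, matrix) by labeling the complement, and extract
triangulated surfaces with marching cubes.

Meshing runs on the signed Euclidean distance field of each binary
component rather than on the raw mask: the zero level set of the distance
field interpolates the boundary at sub-voxel precision, which keeps surface
areas of smooth solids accurate to ~1% without any mesh post-processing.

Cristae that reach the top/bottom of the tomographic slab come out of
marching cubes with open boundary loops at the slab faces; ``seal_mesh``
caps those loops with triangle fans and *tags the cap triangles*, so that
downstream area accounting can report native membrane area and artificial
cap area separately (sealing inflates raw areas).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .volume import Volume

__all__ = ["LabelVolume", "binarize", "components", "extract_mesh",
           "seal_mesh", "partition_mitochondrion", "MitoPartition",
           "cap_face_mask"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class LabelVolume:
    """Integer component labels per voxel; 0 = background."""

    data: np.ndarray
    voxel_size: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3-D")

    @property
    def n_labels(self) -> int:
        return int(self.data.max())

    def foreground_fraction(self) -> float:
        return float(np.count_nonzero(self.data)) / self.data.size


def binarize(vol: Volume, method: str = "otsu",
             threshold: float | None = None,
             roi: np.ndarray | None = None) -> LabelVolume:
    """Threshold a (typically membrane-enhanced) volume into a binary mask.

    ``otsu`` picks the threshold from the intensity histogram inside the
    optional ROI; ``fixed`` requires an explicit value.  Raises if the
    foreground comes out empty, with a histogram summary to help diagnose.
    """
    data = vol.data
    sel = data[roi] if roi is not None else data.ravel()
    if method == "otsu":
        thr = float(threshold_otsu(sel))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown binarize method {method!r}")
    fg = data > thr
    if roi is not None:
        fg &= roi
    if not fg.any():
        qs = np.percentile(data, [0, 25, 50, 75, 100])
        raise ValueError(
            "empty foreground at threshold "
            f"{thr:.4g}; intensity quartiles min={qs[0]:.4g} q25={qs[1]:.4g} "
            f"median={qs[2]:.4g} q75={qs[3]:.4g} max={qs[4]:.4g}")
    return LabelVolume(fg.astype(np.uint8), vol.voxel_size, threshold=thr)


def components(binary: LabelVolume, min_size: int = 0) -> LabelVolume:
    """26-connected components of a binary mask, size-filtered and
    relabeled 1..K by descending voxel count (thin membranes fragment under
    6-connectivity, hence 26)."""
    mask = binary.data > 0
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return LabelVolume(lab.astype(np.int32), binary.voxel_size)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= max(min_size, 1))
    order = keep[np.argsort(sizes[keep])[::-1]]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    return LabelVolume(remap[lab], binary.voxel_size)


def _signed_distance(mask: np.ndarray, voxel: float,
                     smooth_vox: float = 0.7) -> np.ndarray:
    """Signed distance to the mask boundary in nm (negative inside).

    The discrete EDT is quantized to voxel-centre distances, which leaves a
    bumpy zero level set on curved boundaries and inflates marching-cubes
    areas by several percent; a one-voxel Gaussian smoothing of the field
    removes the staircase while moving the boundary by O(voxel^2/r)."""
    d_out = ndimage.distance_transform_edt(~mask, sampling=voxel)
    d_in = ndimage.distance_transform_edt(mask, sampling=voxel)
    field = (d_out - d_in).astype(np.float32)
    if smooth_vox > 0:
        field = ndimage.gaussian_filter(field, smooth_vox, mode="nearest")
    return field


def _as_mesh(verts: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.merge_vertices()
    mesh.update_faces(mesh.nondegenerate_faces())
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def extract_mesh(labels: LabelVolume, isolevel: float = 0.5,
                 smooth_iters: int = 0) -> list[tuple[int, trimesh.Trimesh]]:
    """Marching-cubes surface of every labeled component, in nm coordinates.

    Binary/label input is meshed at the zero level of its signed distance
    field (sub-voxel boundary placement); a float field in [0,1] can instead
    be meshed directly at ``isolevel`` by wrapping it in a LabelVolume with
    a single pseudo-label.  Components touching the volume boundary yield
    open boundary loops (flagged via ``mesh.is_watertight``), which
    ``seal_mesh`` can cap.
    """
    if not 0 < isolevel < 1:
        raise ValueError("isolevel must lie in (0, 1)")
    voxel = labels.voxel_size
    out: list[tuple[int, trimesh.Trimesh]] = []
    n = labels.n_labels
    if n == 0:
        raise ValueError("no surface: label volume is empty")
    objects = ndimage.find_objects(labels.data)
    for k in range(1, n + 1):
        sl = objects[k - 1]
        if sl is None:
            continue
        # pad the crop but never past the full-volume boundary, so slab
        # clipping is preserved while interior components close properly
        pad_sl = tuple(
            slice(max(s.start - 2, 0), min(s.stop + 2, dim))
            for s, dim in zip(sl, labels.data.shape))
        mask = labels.data[pad_sl] == k
        if mask.sum() < 4:
            continue
        field = _signed_distance(mask, voxel)
        verts, faces, _normals, _vals = measure.marching_cubes(
            field, level=0.0, spacing=(voxel,) * 3)
        offset = np.array([s.start for s in pad_sl], dtype=float) * voxel
        verts = verts + offset
        mesh = _as_mesh(verts, faces)
        if smooth_iters > 0:
            trimesh.smoothing.filter_taubin(mesh, iterations=smooth_iters)
        mesh.metadata["component"] = k
        mesh.metadata["cap_faces"] = np.zeros(len(mesh.faces), dtype=bool)
        out.append((k, mesh))
    if not out:
        raise ValueError("no surface: all components below minimum size")
    return out


def _boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Directed vertex-index loops of the open boundary.

    Boundary edges (used by exactly one face) are kept in their face-winding
    direction, so a consistently wound surface yields directed cycles; caps
    built against the reversed direction then share the surface's winding.
    """
    directed = mesh.edges                       # per-face, directed
    order = np.lexsort(np.sort(directed, axis=1).T[::-1])
    srt = np.sort(directed, axis=1)[order]
    # count occurrences of each undirected edge
    uniq, inv, counts = np.unique(srt, axis=0, return_inverse=True,
                                  return_counts=True)
    single = counts == 1
    keep = single[inv]
    boundary = directed[order][keep]
    if len(boundary) == 0:
        return []
    nxt = {int(a): int(b) for a, b in boundary}
    seen: set[int] = set()
    loops = []
    for start in list(nxt):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start and cur not in seen and cur in nxt:
            loop.append(cur)
            seen.add(cur)
            cur = nxt[cur]
        if len(loop) >= 3:
            loops.append(np.asarray(loop))
    return loops


def cap_face_mask(mesh: trimesh.Trimesh) -> np.ndarray:
    """Boolean per-face mask of sealing caps (all-False if never sealed)."""
    mask = mesh.metadata.get("cap_faces")
    if mask is None or len(mask) != len(mesh.faces):
        return np.zeros(len(mesh.faces), dtype=bool)
    return np.asarray(mask, dtype=bool)


def seal_mesh(mesh: trimesh.Trimesh, slab_z_range: tuple[float, float],
              tol: float | None = None) -> trimesh.Trimesh:
    """Cap open boundary loops lying at the slab faces with triangle fans.

    Returns a new mesh whose ``metadata['cap_faces']`` marks the artificial
    cap triangles (sealing adds membrane surface that is not real membrane,
    so area accounting must be able to exclude it).  Loops not at a slab
    face are left open and reported via a warning.  Already-watertight
    meshes are returned unchanged.
    """
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh
    z0, z1 = slab_z_range
    if tol is None:
        tol = 0.02 * (z1 - z0) + 1e-9
    verts = mesh.vertices.copy()
    new_faces = []
    skipped = 0
    for loop in loops:
        zs = verts[loop, 0]
        at_bottom = np.all(np.abs(zs - z0) <= tol)
        at_top = np.all(np.abs(zs - z1) <= tol)
        if not (at_bottom or at_top):
            skipped += 1
            continue
        center = verts[loop].mean(axis=0)
        ci = len(verts)
        verts = np.vstack([verts, center[None, :]])
        # fan against the directed boundary so the cap shares the native
        # winding (each boundary edge a->b is traversed b->a by its cap)
        for i in range(len(loop)):
            a, b = int(loop[i]), int(loop[(i + 1) % len(loop)])
            new_faces.append([ci, b, a])
    if skipped:
        warnings.warn(f"{skipped} boundary loop(s) not at a slab face were "
                      "left open", stacklevel=2)
    if not new_faces:
        return mesh
    faces = np.vstack([mesh.faces, np.asarray(new_faces)])
    sealed = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    cap = np.zeros(len(faces), dtype=bool)
    cap[len(mesh.faces):] = True
    prev = cap_face_mask(mesh)
    cap[:len(prev)] |= prev
    sealed.metadata["cap_faces"] = cap
    sealed.metadata["component"] = mesh.metadata.get("component")
    if sealed.is_watertight and sealed.volume < 0:
        sealed.invert()
    return sealed


# ---------------------------------------------------------------------------
# compartment recovery ("onion peeling" of the membrane topology)
# ---------------------------------------------------------------------------

@dataclass
class MitoPartition:
    """Compartments recovered from a binary membrane mask.

    ``crista_solids``: int32 labels of intracristal compartments, dilated to
    the membrane midsurface (labels 1..K, descending size).
    ``ibm_interior``: everything enclosed by the IBM midsurface (for V_MIT).
    ``om_mask``/``ibm_mask``: the envelope membrane shells.
    """
    crista_solids: np.ndarray
    ibm_interior: np.ndarray
    om_mask: np.ndarray
    ibm_mask: np.ndarray
    voxel_size: float


def _adjacent_labels(region: np.ndarray, labels: np.ndarray) -> set[int]:
    ring = ndimage.binary_dilation(region, structure=_STRUCT6) & ~region
    return set(np.unique(labels[ring])) - {0}


def partition_mitochondrion(membrane: LabelVolume,
                            membrane_thickness_nm: float = 6.0,
                            min_ics_voxels: int = 60) -> MitoPartition:
    """Recover the compartment structure bounded by segmented membranes.

    Peels the topology from the outside in: the complement component that
    touches the lateral (x/y) image border is the exterior; the membrane
    adjacent to it is the outer membrane; the cavity inside that is the
    intermembrane space; the next membrane inward is the inner boundary
    membrane; the large cavity inside it is the matrix; the remaining
    enclosed cavities are intracristal spaces, one per crista.  Each
    intracristal space is grown by half a membrane thickness so that the
    compartment boundary lies on the membrane *midsurface*, matching the
    convention used for ground-truth areas.
    """
    mask = membrane.data > 0
    voxel = membrane.voxel_size
    mem_lab, _ = ndimage.label(mask, structure=_STRUCT26)
    cav_lab, n_cav = ndimage.label(~mask, structure=_STRUCT6)
    if n_cav < 3:
        raise ValueError("membrane mask does not enclose any compartments")

    border = np.zeros_like(mask)
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    exterior_ids = set(np.unique(cav_lab[border])) - {0}
    exterior = np.isin(cav_lab, list(exterior_ids))

    om_ids = _adjacent_labels(exterior, mem_lab)
    om_mask = np.isin(mem_lab, list(om_ids))
    ims_ids = _adjacent_labels(om_mask, cav_lab) - exterior_ids
    if not ims_ids:
        raise ValueError("no intermembrane space found inside the outer "
                         "membrane")
    ims = np.isin(cav_lab, list(ims_ids))
    ibm_ids = _adjacent_labels(ims, mem_lab) - om_ids
    ibm_mask = np.isin(mem_lab, list(ibm_ids))

    interior_ids = (set(range(1, n_cav + 1)) - exterior_ids - ims_ids)
    sizes = np.bincount(cav_lab.ravel(), minlength=n_cav + 1)
    if not interior_ids:
        raise ValueError("no matrix compartment found inside the IBM")
    matrix_id = max(interior_ids, key=lambda i: sizes[i])
    ics_ids = [i for i in interior_ids
               if i != matrix_id and sizes[i] >= min_ics_voxels]
    ics_ids.sort(key=lambda i: -sizes[i])

    ics = np.zeros(mask.shape, dtype=np.int32)
    for new, old in enumerate(ics_ids, start=1):
        ics[cav_lab == old] = new

    # grow intracristal spaces to the membrane midsurface
    half_t = membrane_thickness_nm / 2.0
    if ics_ids:
        dist, (iz, iy, ix) = ndimage.distance_transform_edt(
            ics == 0, sampling=voxel, return_indices=True)
        grow = dist <= half_t
        crista_solids = np.zeros_like(ics)
        crista_solids[grow] = ics[iz[grow], iy[grow], ix[grow]]
    else:
        crista_solids = ics

    crista_membranes = mask & ~om_mask & ~ibm_mask
    core = (cav_lab == matrix_id) | (ics > 0) | crista_membranes
    dist_core = ndimage.distance_transform_edt(~core, sampling=voxel)
    ibm_interior = core | (dist_core <= half_t)

    return MitoPartition(crista_solids, ibm_interior, om_mask, ibm_mask,
                         voxel)
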