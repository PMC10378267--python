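"""Rule-based crista-morphology and cell-location classification.

Morphology classes, with their 2-D central-slice signatures:

* ``Lam`` (lamellar)     — pairs of straight or gently curved parallel
  membrane lines about 20 nm apart;
* ``Tub`` (tubular)      — worm-like tube sections, 50-90 nm across;
* ``Trans`` (transitional) — rows of small (30-60 nm) circular/elongated
  sections, at least three per collinear row;
* ``Mix``                — two morphologies in roughly equal, spatially
  disjoint regions.

The classifier scores each class as the fraction of total crista membrane
length carrying that class's signature and applies dominance thresholds
(0.6 for a single class, 0.35 each for a mixture).  All numeric thresholds
live in ``ClassifyConfig`` — human classification by eye has no published
numbers, so these are explicit, logged package defaults.

Two feature paths feed the same rules: traced contour sets (clean
polylines), or a segmented membrane mask of the central slice, which is
skeletonized into midline polylines first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .contours import Contour, ContourSet
from .morphometry2d import _min_rect_sides

__all__ = ["ClassifyConfig", "SliceFeatures", "extract_slice_features",
           "polylines_from_mask", "classify_morphology", "classify_location",
           "flag_swollen", "MORPHOLOGY_LABELS", "LOCATION_LABELS"]

log = logging.getLogger(__name__)

MORPHOLOGY_LABELS = ("Lam", "Tub", "Trans", "Mix")
LOCATION_LABELS = ("Interfib", "Subsarc", "Other")


@dataclass
class ClassifyConfig:
    """Thresholds of the morphology rules (all lengths nm)."""

    pair_band_nm: tuple[float, float] = (12.0, 28.0)   # 20 +/- 8
    tub_width_nm: tuple[float, float] = (45.0, 95.0)   # 50-90 + tolerance
    trans_width_nm: tuple[float, float] = (25.0, 65.0) # 30-60 + tolerance
    dominance: float = 0.6
    mix_floor: float = 0.35
    mix_min_score: float = 0.15     # raw floor for the minority class
    row_min_sections: int = 3
    row_tol_nm: float = 20.0
    row_max_gap_nm: float = 130.0   # rows are dense: centroid spacing bound
    sample_ds_nm: float = 4.0
    min_segment_len_nm: float = 20.0
    pair_min_elongation: float = 2.5
    swelling_nominal_nm: float = 20.0
    swelling_multiplier: float = 2.0
    swelling_min_fraction: float = 0.25


# ---------------------------------------------------------------------------
# polyline utilities
# ---------------------------------------------------------------------------

def _resample(points: np.ndarray, closed: bool, ds: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Even arc-length resampling; returns (samples, unit tangents)."""
    pts = np.vstack([points, points[:1]]) if closed else points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < ds:
        return pts[:1], np.array([[1.0, 0.0]])
    n = max(int(total / ds), 2)
    si = np.linspace(0, total, n, endpoint=not closed)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    samples = np.column_stack([x, y])
    tang = np.gradient(samples, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.maximum(norm, 1e-12)
    return samples, tang


@dataclass
class SliceFeatures:
    """Per-slice crista features feeding the morphology rules."""

    n_segments: int
    total_len_nm: float
    lam_len_nm: float
    tub_len_nm: float
    trans_len_nm: float
    lam_points: np.ndarray          # sample points carrying the Lam signature
    tub_points: np.ndarray
    trans_points: np.ndarray
    pair_profiles: list[np.ndarray] # per candidate crista: separations (nm)

    def scores(self) -> dict[str, float]:
        t = max(self.total_len_nm, 1e-9)
        return {"Lam": self.lam_len_nm / t, "Tub": self.tub_len_nm / t,
                "Trans": self.trans_len_nm / t}


def _rows_membership(centroids: np.ndarray, cfg: ClassifyConfig) -> np.ndarray:
    """Boolean mask: which sections belong to the *parallel rows* pattern.

    A row is a dense collinear run of >= ``row_min_sections`` section
    centroids (within ``row_tol_nm`` laterally, neighbour gaps under
    ``row_max_gap_nm``); the transitional signature is rows in parallel, so
    a row only counts when a second, distinct row runs within ~20 degrees
    of it.  Candidate directions come from centroid pairs, which keeps the
    construction rotation invariant.
    """
    n = len(centroids)
    member = np.zeros(n, dtype=bool)
    if n < 2 * cfg.row_min_sections:
        return member
    rows: dict[frozenset, np.ndarray] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = centroids[j] - centroids[i]
            norm = np.linalg.norm(d)
            if norm < 1e-9:
                continue
            u = d / norm
            rel = centroids - centroids[i]
            perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
            on_line = np.flatnonzero(perp <= cfg.row_tol_nm)
            if len(on_line) < cfg.row_min_sections:
                continue
            # a row is a *dense* run: split at large gaps along the line
            proj = rel[on_line] @ u
            order = np.argsort(proj)
            ids = on_line[order]
            gaps = np.diff(proj[order])
            run = [ids[0]]

            def _flush(run_ids):
                if len(run_ids) >= cfg.row_min_sections:
                    rows[frozenset(int(r) for r in run_ids)] = u

            for g, nxt in zip(gaps, ids[1:]):
                if g <= cfg.row_max_gap_nm:
                    run.append(nxt)
                else:
                    _flush(run)
                    run = [nxt]
            _flush(run)
    # keep only rows supported by a distinct, roughly parallel partner row
    row_list = [(set(ids), u) for ids, u in rows.items()]
    cos_tol = np.cos(np.deg2rad(12.0))
    for k, (ids_k, u_k) in enumerate(row_list):
        for m, (ids_m, u_m) in enumerate(row_list):
            if m == k:
                continue
            if abs(float(u_k @ u_m)) < cos_tol:
                continue
            if len(ids_k & ids_m) > min(len(ids_k), len(ids_m)) // 2:
                continue        # mostly the same sections, not a second row
            member[list(ids_k)] = True
            break
    return member


def extract_slice_features(polylines: list[tuple[np.ndarray, bool]],
                           cfg: ClassifyConfig | None = None
                           ) -> SliceFeatures:
    """Compute the class signatures from crista polylines of one slice.

    ``polylines``: list of (points_nm, closed).  The paired-parallel
    signature is measured point-wise: a sample is *paired* when its nearest
    roughly antiparallel, laterally displaced neighbour (excluding its own
    local arc) sits within the 20 +/- 8 nm band.
    """
    cfg = cfg or ClassifyConfig()
    ds = cfg.sample_ds_nm
    segs = []
    for pts, closed in polylines:
        if len(pts) < 2:
            continue
        samples, tang = _resample(np.asarray(pts, float), closed, ds)
        length = ds * len(samples)
        if length < cfg.min_segment_len_nm:
            continue
        try:
            long_s, short_s = _min_rect_sides(samples)
        except ValueError:
            continue
        segs.append(dict(samples=samples, tang=tang, closed=closed,
                         length=length, long=long_s, short=short_s,
                         centroid=samples.mean(axis=0)))
    n_seg = len(segs)
    if n_seg == 0:
        return SliceFeatures(0, 0.0, 0.0, 0.0, 0.0, np.empty((0, 2)),
                             np.empty((0, 2)), np.empty((0, 2)), [])
    total_len = sum(s["length"] for s in segs)

    # ---- pairing: stack all samples -------------------------------------
    P = np.vstack([s["samples"] for s in segs])
    T = np.vstack([s["tang"] for s in segs])
    seg_id = np.concatenate([np.full(len(s["samples"]), k)
                             for k, s in enumerate(segs)])
    arc = np.concatenate([np.arange(len(s["samples"])) * ds for s in segs])
    diff = P[:, None, :] - P[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(dist, np.inf)
    # same-segment neighbours along the arc are not partners
    same = seg_id[:, None] == seg_id[None, :]
    arc_sep = np.abs(arc[:, None] - arc[None, :])
    dist[same & (arc_sep < 30.0)] = np.inf
    # partners must be near-antiparallel and laterally displaced
    t_dot = np.abs(np.einsum("ik,jk->ij", T, T))
    with np.errstate(invalid="ignore", divide="ignore"):
        along = np.abs(np.einsum("ijk,ik->ij", diff, T)) / np.maximum(dist, 1e-12)
    dist[(t_dot < 0.85) | (along > 0.5)] = np.inf
    partner = dist.min(axis=1)

    lo, hi = cfg.pair_band_nm
    paired = (partner >= lo) & (partner <= hi)

    # ---- per-segment classification --------------------------------------
    lam_len = tub_len = trans_len = 0.0
    lam_pts, tub_pts, trans_pts = [], [], []
    pair_profiles = []
    # candidate "circular/elongated sections" for tub / trans rules
    trans_candidates = []
    offset = 0
    for k, s in enumerate(segs):
        ns = len(s["samples"])
        sel = slice(offset, offset + ns)
        frac_paired = float(np.mean(paired[sel]))
        elong = s["long"] / max(s["short"], 1e-9)
        # section width: the local across-section membrane distance (median
        # partner distance) — robust for curved worm sections whose bounding
        # rectangle is much wider than the tube; bounding-rectangle width is
        # the fallback when pairing finds nothing
        prof_all = partner[sel]
        finite = prof_all[np.isfinite(prof_all)]
        if len(finite) >= 0.25 * ns:
            width = float(np.median(finite))
        else:
            width = s["short"]
        # tube sections are closed rings/worm outlines, but noise can break
        # a traced ring into open arcs: those still pair across the tube at
        # ~D, and unlike a widowed straight membrane line they keep a
        # two-dimensional footprint (bounding-rectangle width)
        ringlike = s["closed"] or s["short"] >= 30.0
        is_tub = (ringlike
                  and cfg.tub_width_nm[0] <= width <= cfg.tub_width_nm[1])
        if frac_paired >= 0.6 and elong >= cfg.pair_min_elongation:
            lam_len += s["length"]
            lam_pts.append(s["samples"])
        if elong >= cfg.pair_min_elongation and frac_paired >= 0.1:
            # membrane-pair separation profile for swelling detection; the
            # segment must show *some* nominal pairing to count as a
            # membrane pair at all (tube sections never do), but the
            # profile keeps the distances outside the band — that is where
            # swelling lives
            prof = partner[sel]
            prof = prof[np.isfinite(prof)]
            if len(prof):
                pair_profiles.append(prof)
        if is_tub:
            tub_len += s["length"]
            tub_pts.append(s["samples"])
        if s["closed"] and cfg.trans_width_nm[0] <= width <= cfg.trans_width_nm[1]:
            trans_candidates.append((k, s))
        offset += ns

    if trans_candidates:
        cents = np.vstack([s["centroid"] for _k, s in trans_candidates])
        member = _rows_membership(cents, cfg)
        for m, (_k, s) in zip(member, trans_candidates):
            if m:
                trans_len += s["length"]
                trans_pts.append(s["samples"])

    def _stack(chunks):
        return np.vstack(chunks) if chunks else np.empty((0, 2))

    return SliceFeatures(n_seg, total_len, lam_len, tub_len, trans_len,
                         _stack(lam_pts), _stack(tub_pts), _stack(trans_pts),
                         pair_profiles)


def _disjoint(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two point clouds occupy spatially separate regions: their
    means, projected on the axis joining them, differ by more than the sum
    of the projected spreads."""
    if len(a) == 0 or len(b) == 0:
        return False
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    axis = mu_b - mu_a
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return False
    axis = axis / norm
    pa, pb = a @ axis, b @ axis
    return abs(pa.mean() - pb.mean()) > (pa.std() + pb.std())


def classify_morphology(features: SliceFeatures,
                        cfg: ClassifyConfig | None = None
                        ) -> tuple[str, dict[str, float]]:
    """Assign Lam / Tub / Trans / Mix from slice features.

    Returns ``(label, per-class scores)``; fewer than 3 crista sections is
    ``"unclassifiable"``.  A tie between dominant classes goes to the larger
    score (logged).
    """
    cfg = cfg or ClassifyConfig()
    scores = features.scores()
    if features.n_segments < 3:
        return "unclassifiable", scores
    # a genuine mixture — two morphologies each above the floor, living in
    # spatially disjoint regions — beats single-class dominance: a
    # half-lamellar/half-tubular profile must not be called Lam just
    # because plates pack more membrane length than tubes do.  For a pure
    # class the co-scoring signatures share the same sections, so the
    # disjointness guard fails and dominance decides.
    clouds = {"Lam": features.lam_points, "Tub": features.tub_points,
              "Trans": features.trans_points}
    ranked = sorted(scores, key=scores.get, reverse=True)
    k1, k2 = ranked[0], ranked[1]
    # the 0.35 floor is taken between the two competing classes (oblique /
    # grazing sections carry no class signature and would otherwise dilute
    # both fractions)
    pair_total = scores[k1] + scores[k2]
    if (pair_total > 0 and scores[k2] >= cfg.mix_min_score
            and scores[k2] / pair_total >= cfg.mix_floor
            and _disjoint(clouds[k1], clouds[k2])):
        return "Mix", scores
    dominant = {k: v for k, v in scores.items() if v >= cfg.dominance}
    if dominant:
        if len(dominant) > 1:
            log.info("dominance tie %s; taking the larger score", dominant)
        return max(dominant, key=dominant.get), scores
    best = max(scores, key=scores.get)
    if scores[best] > 0:
        log.info("no dominant class; falling back to largest score %s=%.2f",
                 best, scores[best])
        return best, scores
    return "unclassifiable", scores


def classify_contours(cset: ContourSet, slice_z: float | None = None,
                      cfg: ClassifyConfig | None = None
                      ) -> tuple[str, dict[str, float]]:
    """Morphology classification straight from a traced contour set."""
    if slice_z is None:
        slice_z = cset.central_slice()
    polylines = [(c.points, c.closed)
                 for c in cset.on_slice(slice_z, "crista")]
    return classify_morphology(extract_slice_features(polylines, cfg), cfg)


# ---------------------------------------------------------------------------
# skeleton path: features from a segmented membrane slice
# ---------------------------------------------------------------------------

_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def polylines_from_mask(mask: np.ndarray, voxel_size: float,
                        min_len_nm: float = 15.0
                        ) -> list[tuple[np.ndarray, bool]]:
    """Skeletonize a binary membrane slice into midline polylines (nm).

    Membrane bars reduce to open lines, tube rings to closed loops — the
    same primitives a human tracer would draw.  Paths are walked between
    skeleton endpoints/branch points; pure cycles are returned closed.
    """
    skel = skeletonize(mask.astype(bool))
    pix = {tuple(p) for p in np.argwhere(skel)}
    if not pix:
        return []
    nbrs = {p: [q for q in ((p[0] + dy, p[1] + dx) for dy, dx in _NB8)
                if q in pix] for p in pix}
    degree = {p: len(v) for p, v in nbrs.items()}
    nodes = {p for p, d in degree.items() if d != 2}
    used = set()
    paths: list[tuple[list, bool]] = []

    def walk(start, first):
        path = [start, first]
        used.add((start, first))
        used.add((first, start))
        cur, prev = first, start
        while cur not in nodes:
            nxt = [q for q in nbrs[cur] if q != prev]
            if not nxt:
                break
            step = nxt[0]
            if (cur, step) in used:
                break
            used.add((cur, step))
            used.add((step, cur))
            prev, cur = cur, step
            path.append(cur)
        return path

    for p in sorted(nodes):
        for q in nbrs[p]:
            if (p, q) not in used:
                paths.append((walk(p, q), False))
    # remaining degree-2 pixels form pure cycles
    visited = {pt for path, _ in paths for pt in path}
    for p in sorted(pix - visited - nodes):
        if p in visited:
            continue
        cyc = walk(p, nbrs[p][0])
        visited.update(cyc)
        paths.append((cyc, True))

    out = []
    for path, closed in paths:
        pts = np.asarray(path, dtype=float)[:, ::-1] * voxel_size  # (x, y)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        if seg >= min_len_nm:
            out.append((pts, closed))
    return out


def classify_slice_mask(mask: np.ndarray, voxel_size: float,
                        cfg: ClassifyConfig | None = None
                        ) -> tuple[str, dict[str, float]]:
    """Morphology classification of a segmented central-slice membrane mask
    (envelope membranes should be removed first)."""
    polylines = polylines_from_mask(mask, voxel_size)
    return classify_morphology(extract_slice_features(polylines, cfg), cfg)


# ---------------------------------------------------------------------------
# location and swelling
# ---------------------------------------------------------------------------

def classify_location(mito_outline_nm: np.ndarray,
                      myofibril_mask: np.ndarray | None,
                      sarcolemma_mask: np.ndarray | None,
                      voxel_size: float = 1.8,
                      proximity_nm: float = 50.0) -> str:
    """Interfibrillar / subsarcolemmal / other by <50 nm proximity.

    Masks are 2-D boolean images on the same grid convention as the outline
    (nm = index * voxel_size, (y, x) order).  Interfibrillar takes
    precedence when both rules fire.  With no masks at all the call returns
    "Other" with a warning.
    """
    if myofibril_mask is None and sarcolemma_mask is None:
        log.warning("no myofibril/sarcolemma masks; location set to Other")
        return "Other"

    def min_dist(mask: np.ndarray) -> float:
        if mask is None or not mask.any():
            return np.inf
        dist = ndimage.distance_transform_edt(~mask, sampling=voxel_size)
        iy = np.clip(np.round(mito_outline_nm[:, 1] / voxel_size).astype(int),
                     0, mask.shape[0] - 1)
        ix = np.clip(np.round(mito_outline_nm[:, 0] / voxel_size).astype(int),
                     0, mask.shape[1] - 1)
        return float(dist[iy, ix].min())

    if min_dist(myofibril_mask) < proximity_nm:
        return "Interfib"
    if min_dist(sarcolemma_mask) < proximity_nm:
        return "Subsarc"
    return "Other"


def flag_swollen(pair_profiles: list[np.ndarray],
                 cfg: ClassifyConfig | None = None) -> bool:
    """True if any crista's membrane-pair separation exceeds twice the
    nominal 20 nm over at least a quarter of its length."""
    cfg = cfg or ClassifyConfig()
    thr = cfg.swelling_nominal_nm * cfg.swelling_multiplier
    for prof in pair_profiles:
        prof = np.asarray(prof)
        prof = prof[np.isfinite(prof)]
        if len(prof) == 0:
            continue
        if np.mean(prof > thr) >= cfg.swelling_min_fraction:
            return True
    return False
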