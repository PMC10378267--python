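"""Traced-membrane contour sets.

A ``ContourSet`` is the in-memory form of a manual (or synthetic) tracing
session: per z-slice polylines in nm, each labeled by membrane class
(``crista``, ``IBM`` or ``OM``).  Crista membranes seen in cross-section are
traced as the full outline of the crista compartment, so a flat lamellar
crista contributes the classic pair of parallel lines (plus its short end
arcs) to the trace length — the pair-tracing convention used throughout.

JSON serialisation is a flat list of records
``{"slice_z": float, "label": str, "closed": bool, "polyline": [[x, y], ...]}``
with coordinates in nm, plus top-level metadata.

A reader for IMOD ASCII model listings (``imodinfo -a`` style
object/contour/point output) is provided since real tracings are made in
IMOD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Contour", "ContourSet", "read_imod_ascii"]

VALID_LABELS = ("crista", "IBM", "OM", "myofibril", "sarcolemma")


@dataclass
class Contour:
    """One traced polyline on one slice; coordinates in nm."""

    slice_z: float
    label: str
    points: np.ndarray  # (N, 2) x,y in nm
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be (N, 2)")
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown contour label {self.label!r}")

    def length(self) -> float:
        """Arc length in nm (closing segment included for closed contours)."""
        pts = self.points
        if len(pts) < 2:
            return 0.0
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        if self.closed:
            seg += float(np.linalg.norm(pts[-1] - pts[0]))
        return float(seg)


@dataclass
class ContourSet:
    """All traced contours of one tomogram / one mitochondrion."""

    contours: list[Contour] = field(default_factory=list)
    mito_id: str = "mito"

    def slices(self) -> list[float]:
        return sorted({c.slice_z for c in self.contours})

    def on_slice(self, slice_z: float, label: str | None = None,
                 tol: float = 1e-6) -> list[Contour]:
        out = [c for c in self.contours if abs(c.slice_z - slice_z) <= tol]
        if label is not None:
            out = [c for c in out if c.label == label]
        return out

    def central_slice(self) -> float:
        zs = self.slices()
        if not zs:
            raise ValueError("empty contour set")
        return zs[len(zs) // 2]

    # ---- JSON round trip -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        rec = {
            "mito_id": self.mito_id,
            "units": "nm",
            "contours": [
                {
                    "slice_z": c.slice_z,
                    "label": c.label,
                    "closed": c.closed,
                    "polyline": c.points.tolist(),
                }
                for c in self.contours
            ],
        }
        Path(path).write_text(json.dumps(rec))

    @classmethod
    def from_json(cls, path: str | Path) -> "ContourSet":
        rec = json.loads(Path(path).read_text())
        contours = [
            Contour(r["slice_z"], r["label"], np.asarray(r["polyline"], dtype=float),
                    bool(r.get("closed", False)))
            for r in rec["contours"]
        ]
        return cls(contours, rec.get("mito_id", "mito"))


def read_imod_ascii(path: str | Path, voxel_size: float = 1.8,
                    label_map: dict[str, str] | None = None) -> ContourSet:
    """Parse an IMOD ASCII model point listing into a ContourSet.

    Expects the object/contour/point layout of ``imodinfo -a`` output::

        object 0 2 0
        contour 0 0 5
        12.0 34.0 40
        ...

    Object names (``name`` lines) are mapped to membrane labels through
    ``label_map`` (defaults: name containing 'crista' -> crista, 'ibm' ->
    IBM, 'om'/'outer' -> OM).  Point coordinates are pixel units and are
    scaled by ``voxel_size`` to nm; the z of a contour is the (common) pixel
    z of its points.
    """
    label_map = label_map or {}
    contours: list[Contour] = []
    cur_label = "crista"
    cur_pts: list[list[float]] = []
    cur_z = 0.0

    def _flush() -> None:
        nonlocal cur_pts
        if len(cur_pts) >= 2:
            pts = np.asarray(cur_pts, dtype=float) * voxel_size
            contours.append(Contour(cur_z * voxel_size, cur_label, pts))
        cur_pts = []

    def _name_to_label(name: str) -> str:
        if name in label_map:
            return label_map[name]
        low = name.lower()
        if "crista" in low or "cris" in low:
            return "crista"
        if "ibm" in low or "inner" in low:
            return "IBM"
        if "om" in low or "outer" in low:
            return "OM"
        return "crista"

    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "object":
            _flush()
        elif parts[0] == "name":
            cur_label = _name_to_label(" ".join(parts[1:]))
        elif parts[0] == "contour":
            _flush()
        else:
            try:
                x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
            except (ValueError, IndexError):
                continue
            cur_pts.append([x, y])
            cur_z = z
    _flush()
    return ContourSet(contours, Path(path).stem)
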