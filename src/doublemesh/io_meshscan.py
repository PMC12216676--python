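"""On-disk dialects for mesh scans, heat maps, crystal maps and reports.

The per-cell spot lists travel as JSON lines: a header object on the first
line (format tag, version, detector and scan geometry, cell count) followed
by one object per grid cell.  Heat maps and crystal maps are plain TSV
matrices (rows = vertical grid axis ``v``, columns = rotation-axis grid
axis ``u``), matching the orientation in which mesh scans are displayed;
the crystal map carries a JSON sidecar with per-label region metadata.
All writers are deterministic; readers reject malformed or truncated files
with the offending line number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import DetectorGeometry, ScanGeometry

__all__ = [
    "FORMAT_TAG",
    "FORMAT_VERSION",
    "MeshScanParseError",
    "GridCellRecord",
    "MeshScan",
    "read_meshscan",
    "write_meshscan",
    "write_heatmap",
    "write_crystal_map",
    "write_match_report",
]

FORMAT_TAG = "doublemesh-meshscan"
FORMAT_VERSION = 1

MULTIPATTERN_LABEL = 999


class MeshScanParseError(ValueError):
    """Malformed mesh-scan file; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class GridCellRecord:
    """One grid cell: indices, diffraction score and its spot list.

    ``spots`` is an ``(n, 4)`` float array with columns
    (x_px, y_px, intensity, background).  A score of zero means the cell
    is treated as containing no crystal diffraction.
    """

    iu: int
    iv: int
    cell_score: float
    spots: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))

    def __post_init__(self) -> None:
        self.spots = np.asarray(self.spots, dtype=float).reshape(-1, 4)
        if self.cell_score < 0:
            raise ValueError(f"cell_score must be >= 0, got {self.cell_score}")


@dataclass
class MeshScan:
    """A full mesh scan: geometry, detector and the dense cell grid."""

    geometry: ScanGeometry
    detector: DetectorGeometry
    cells: list[GridCellRecord]

    def __post_init__(self) -> None:
        g = self.geometry
        if len(self.cells) != g.n_u * g.n_v:
            raise ValueError(
                f"expected {g.n_u * g.n_v} cells, got {len(self.cells)}"
            )
        self._index = {(c.iu, c.iv): c for c in self.cells}
        if len(self._index) != len(self.cells):
            raise ValueError("duplicate cell indices")
        for c in self.cells:
            if not (0 <= c.iu < g.n_u and 0 <= c.iv < g.n_v):
                raise ValueError(f"cell ({c.iu}, {c.iv}) outside grid")

    def cell(self, iu: int, iv: int) -> GridCellRecord:
        return self._index[(iu, iv)]

    def score_matrix(self) -> np.ndarray:
        """(n_v, n_u) matrix of cell scores."""
        m = np.zeros((self.geometry.n_v, self.geometry.n_u))
        for c in self.cells:
            m[c.iv, c.iu] = c.cell_score
        return m


def _geometry_header(scan: MeshScan) -> dict:
    det, g = scan.detector, scan.geometry
    return {
        "format": FORMAT_TAG,
        "version": FORMAT_VERSION,
        "n_cells": len(scan.cells),
        "detector": {
            "wavelength_A": det.wavelength,
            "distance_mm": det.distance,
            "beam_centre_px": list(det.beam_centre),
            "pixel_size_mm": det.pixel_size,
            "detector_shape_px": list(det.detector_shape),
        },
        "geometry": {
            "omega_deg": g.omega,
            "grid_origin_mm": list(g.grid_origin),
            "step_mm": g.step,
            "n_u": g.n_u,
            "n_v": g.n_v,
        },
    }


def write_meshscan(scan: MeshScan, path: str | Path) -> None:
    """Write a scan in the JSON-lines dialect (header + one line per cell)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps(_geometry_header(scan), sort_keys=True) + "\n")
        for c in sorted(scan.cells, key=lambda c: (c.iu, c.iv)):
            rec = {
                "iu": c.iu,
                "iv": c.iv,
                "score": c.cell_score,
                "spots": [[float(x) for x in row] for row in c.spots],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_meshscan(path: str | Path) -> MeshScan:
    """Read a scan written by :func:`write_meshscan`; strict and lossless."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise MeshScanParseError("empty file", 1)
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise MeshScanParseError(f"bad header JSON: {exc}", 1) from exc
    if header.get("format") != FORMAT_TAG:
        raise MeshScanParseError(f"unknown format {header.get('format')!r}", 1)
    if header.get("version") != FORMAT_VERSION:
        raise MeshScanParseError(f"unsupported version {header.get('version')!r}", 1)
    try:
        det = DetectorGeometry(
            wavelength=header["detector"]["wavelength_A"],
            distance=header["detector"]["distance_mm"],
            beam_centre=tuple(header["detector"]["beam_centre_px"]),
            pixel_size=header["detector"]["pixel_size_mm"],
            detector_shape=tuple(header["detector"]["detector_shape_px"]),
        )
        geo = ScanGeometry(
            omega=header["geometry"]["omega_deg"],
            grid_origin=tuple(header["geometry"]["grid_origin_mm"]),
            step=header["geometry"]["step_mm"],
            n_u=header["geometry"]["n_u"],
            n_v=header["geometry"]["n_v"],
        )
        n_cells = header["n_cells"]
    except (KeyError, TypeError) as exc:
        raise MeshScanParseError(f"incomplete header: {exc}", 1) from exc
    cells = []
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
            cells.append(
                GridCellRecord(
                    iu=obj["iu"],
                    iv=obj["iv"],
                    cell_score=obj["score"],
                    spots=np.array(obj["spots"], dtype=float).reshape(-1, 4),
                )
            )
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise MeshScanParseError(f"bad cell record: {exc}", ln) from exc
    if len(cells) != n_cells:
        raise MeshScanParseError(
            f"truncated file: header promises {n_cells} cells, found {len(cells)}",
            len(lines),
        )
    return MeshScan(geometry=geo, detector=det, cells=cells)


def write_heatmap(scan: MeshScan, path: str | Path) -> None:
    """Tab-separated (n_v, n_u) matrix of per-cell diffraction scores."""
    np.savetxt(Path(path), scan.score_matrix(), delimiter="\t", fmt="%.6g")


def write_crystal_map(
    regions,
    scan: MeshScan,
    path: str | Path,
    multipattern_cells=(),
) -> None:
    """Integer crystal map (TSV) plus a JSON sidecar of region metadata.

    Labels: 0 = no diffraction, 999 = cells with overlapping diffraction
    patterns, 1..K = crystals ranked by diffraction strength.  The sidecar
    ``<path>.json`` lists centroid (mm), extents (mm), integral score and
    recommended beam size per label.
    """
    path = Path(path)
    labels = np.zeros((scan.geometry.n_v, scan.geometry.n_u), dtype=int)
    for iu, iv in multipattern_cells:
        labels[iv, iu] = MULTIPATTERN_LABEL
    for region in regions:
        for iu, iv in region.cells:
            labels[iv, iu] = region.label
    np.savetxt(path, labels, delimiter="\t", fmt="%d")
    sidecar = {
        str(r.label): {
            "centroid_mm": [float(x) for x in r.centroid],
            "extents_mm": [float(x) for x in r.extents],
            "integral_score": float(r.integral_score),
            "beam_size_um": float(r.beam_size),
            "n_cells": len(r.cells),
        }
        for r in regions
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def write_match_report(matches, path: str | Path) -> None:
    """JSON report of cross-scan match results.

    One entry per evaluated candidate pair: region labels, best check()
    score, binary decision, triangulated 3D position and the recommended
    beam size for collection.
    """
    report = {
        "matches": [
            {
                "rank": m.rank,
                "region_scan1": m.pair.region_a.label,
                "region_scan2": m.pair.region_b.label,
                "max_score": float(m.max_score),
                "matched": bool(m.matched),
                "position_mm": {
                    "x": m.position.x,
                    "y": m.position.y,
                    "z": m.position.z,
                },
                "beam_size_um": float(m.beam_size),
                "integral_score": float(m.integral_score),
            }
            for m in matches
        ]
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
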