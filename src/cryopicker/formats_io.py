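"""Readers and writers for the external formats the picking pipeline touches.

Micrographs travel as 2-D MRC maps (MRC2014, via gemmi), ground-truth and
predicted coordinates as EMAN-style ``.box`` files (lower-left corner +
box size), merged picks as a RELION-style STAR loop block, and training
labels as COCO JSON.

One coordinate convention holds everywhere: 0-based pixel indices with the
origin at the top-left of the pixel grid, x = column (rightward),
y = row (downward). Reconstruction suites that index from the bottom-left
can be accommodated with the ``flip_y`` writer flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Micrograph",
    "ParticleAnnotation",
    "AnnotationSet",
    "StarRecord",
    "read_mrc",
    "write_mrc",
    "write_box_file",
    "read_box_file",
    "write_star",
    "read_star",
    "build_coco",
    "parse_coco",
]

PARTICLE_CATEGORY_ID = 1  # single category: every annotated object is a particle

# MRC modes this package accepts (integer and float micrographs)
_SUPPORTED_MODES = {0, 1, 2, 6}


@dataclass
class Micrograph:
    """A single 2-D cryo-EM image.

    Attributes
    ----------
    id : str
        Identifier, by convention the file stem.
    pixels : ndarray, shape (H0, W0)
        Intensities, row-major; finite.
    pixel_size : float or None
        Physical sampling in Angstrom per pixel, when the header carries it.
    """

    id: str
    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"micrograph must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph contains non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ParticleAnnotation:
    """One ground-truth particle: center, box size and category."""

    particle_id: int
    micrograph_id: str
    cx: float
    cy: float
    bw: float
    bh: float
    category: int = PARTICLE_CATEGORY_ID

    def __post_init__(self):
        if self.bw <= 0 or self.bh <= 0:
            raise ValueError("box width/height must be positive")


@dataclass
class AnnotationSet:
    """Annotations for a split: micrograph descriptors + particle records."""

    micrographs: list[tuple[str, int, int]]  # (id, H0, W0)
    annotations: list[ParticleAnnotation] = field(default_factory=list)
    split_tag: str = "train"

    def __post_init__(self):
        if self.split_tag not in {"train", "validation", "test"}:
            raise ValueError(f"unknown split tag {self.split_tag!r}")
        ids = {m[0] for m in self.micrographs}
        for a in self.annotations:
            if a.micrograph_id not in ids:
                raise ValueError(f"annotation references unknown micrograph {a.micrograph_id!r}")
        pids = [a.particle_id for a in self.annotations]
        if len(pids) != len(set(pids)):
            raise ValueError("particle_ids are not unique")


@dataclass
class StarRecord:
    """One row of the merged picks table: micrograph, center, confidence."""

    micrograph_id: str
    x: float
    y: float
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


# ---------------------------------------------------------------------------
# MRC
# ---------------------------------------------------------------------------

def read_mrc(path: str | Path) -> Micrograph:
    """Read a single-frame 2-D MRC micrograph.

    The pixel size is taken from the header voxel spacing when the header
    declares a non-zero cell; 3-D volumes and movie stacks are rejected.
    """
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"not a readable MRC file: {path} ({exc})") from exc
    mode = m.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise ValueError(f"unsupported MRC mode {mode} in {path}")
    arr = np.array(m.grid, copy=True)
    # stored as (nx, ny, nz) with nz = 1 for a single frame
    if arr.ndim != 3 or arr.shape[2] != 1:
        raise ValueError(
            f"expected a 2-D micrograph (nz=1), found grid shape {arr.shape} in {path}"
        )
    pixels = arr[:, :, 0].T.astype(np.float64)  # -> (H0, W0) = (ny, nx), row-major
    pixel_size = None
    spacing = m.grid.spacing
    if spacing[0] > 0:
        pixel_size = round(float(spacing[0]), 6)
    return Micrograph(id=path.stem, pixels=pixels, pixel_size=pixel_size)


def write_mrc(m: Micrograph, path: str | Path) -> None:
    """Write a 2-D micrograph as a mode-2 (float32) MRC map."""
    path = Path(path)
    h0, w0 = m.pixels.shape
    grid_arr = np.ascontiguousarray(m.pixels.T[:, :, None], dtype=np.float32)  # (nx, ny, 1)
    out = gemmi.Ccp4Map()
    out.grid = gemmi.FloatGrid(grid_arr)
    apix = m.pixel_size if m.pixel_size else 1.0
    out.grid.unit_cell = gemmi.UnitCell(w0 * apix, h0 * apix, apix, 90.0, 90.0, 90.0)
    out.update_ccp4_header()
    out.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# .box files (EMAN dialect: x_min  y_min  w  h, tab separated, integers)
# ---------------------------------------------------------------------------

def write_box_file(particles, path: str | Path, box_size: int, flip_y: int | None = None) -> None:
    """Write scored picks of ONE micrograph as an EMAN-style box file.

    Each record is the lower-left (in image convention: top-left) corner of
    a ``box_size`` square centred on the pick: ``x_min = cx - box_size/2``,
    ``y_min = cy - box_size/2``. ``flip_y``, when set to the micrograph
    height, mirrors y for suites that index from the bottom edge.
    """
    particles = list(particles)
    mids = {p.micrograph_id for p in particles}
    if len(mids) > 1:
        raise ValueError(f"box file must hold one micrograph, got {sorted(mids)}")
    lines = []
    for p in particles:
        cy = (flip_y - 1) - p.cy if flip_y is not None else p.cy
        x_min = int(round(p.cx - box_size / 2.0))
        y_min = int(round(cy - box_size / 2.0))
        lines.append(f"{x_min}\t{y_min}\t{box_size}\t{box_size}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_box_file(path: str | Path) -> list[tuple[float, float, float, float]]:
    """Read an EMAN-style box file; returns (x_min, y_min, w, h) tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed box record: {line!r}")
        out.append(tuple(float(v) for v in parts[:4]))
    return out


# ---------------------------------------------------------------------------
# STAR (minimal RELION-style loop block)
# ---------------------------------------------------------------------------

_STAR_COLUMNS = (
    "_rlnMicrographName",
    "_rlnCoordinateX",
    "_rlnCoordinateY",
    "_rlnAutopickFigureOfMerit",
)
_STAR_DECIMALS = 6


def write_star(records, path: str | Path) -> None:
    """Write pick records as a STAR file with one ``data_particles`` loop.

    Coordinates are written at fixed precision so that a write/read round
    trip reproduces the records exactly.
    """
    lines = ["data_particles", "", "loop_"]
    lines += [f"{col} #{i + 1}" for i, col in enumerate(_STAR_COLUMNS)]
    for r in records:
        lines.append(
            f"{r.micrograph_id}\t{r.x:.{_STAR_DECIMALS}f}\t{r.y:.{_STAR_DECIMALS}f}\t"
            f"{r.score:.{_STAR_DECIMALS}f}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_star(path: str | Path) -> list[StarRecord]:
    """Read a STAR file written by :func:`write_star`."""
    lines = Path(path).read_text().splitlines()
    columns: list[str] = []
    records: list[StarRecord] = []
    in_loop = False
    for line in lines:
        s = line.strip()
        if not s or s.startswith("data_"):
            continue
        if s == "loop_":
            in_loop = True
            columns = []
            continue
        if in_loop and s.startswith("_"):
            columns.append(s.split()[0])
            continue
        if in_loop:
            vals = s.split()
            if len(vals) != len(columns):
                raise ValueError(f"row has {len(vals)} fields, loop declares {len(columns)}")
            row = dict(zip(columns, vals))
            records.append(
                StarRecord(
                    micrograph_id=row["_rlnMicrographName"],
                    x=float(row["_rlnCoordinateX"]),
                    y=float(row["_rlnCoordinateY"]),
                    score=float(row["_rlnAutopickFigureOfMerit"]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------

def build_coco(annotations: AnnotationSet) -> str:
    """Serialize an :class:`AnnotationSet` as COCO detection JSON.

    Boxes are stored COCO-style as ``[x_min, y_min, bw, bh]`` with
    ``area = bw * bh``; a single ``particle`` category is declared.
    """
    mic_index = {mid: i + 1 for i, (mid, _, _) in enumerate(annotations.micrographs)}
    images = [
        {"id": mic_index[mid], "file_name": f"{mid}.mrc", "height": int(h), "width": int(w)}
        for (mid, h, w) in annotations.micrographs
    ]
    annos = []
    for a in annotations.annotations:
        if a.micrograph_id not in mic_index:
            raise ValueError(f"annotation references unknown micrograph {a.micrograph_id!r}")
        annos.append(
            {
                "id": int(a.particle_id),
                "image_id": mic_index[a.micrograph_id],
                "category_id": int(a.category),
                "bbox": [a.cx - a.bw / 2.0, a.cy - a.bh / 2.0, a.bw, a.bh],
                "area": a.bw * a.bh,
                "iscrowd": 0,
            }
        )
    doc = {
        "info": {"description": f"particle annotations ({annotations.split_tag} split)"},
        "images": images,
        "annotations": annos,
        "categories": [
            {"id": PARTICLE_CATEGORY_ID, "name": "particle", "supercategory": "particle"}
        ],
        "split": annotations.split_tag,
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def parse_coco(text: str) -> AnnotationSet:
    """Invert :func:`build_coco`."""
    doc = json.loads(text)
    images = sorted(doc["images"], key=lambda e: e["id"])
    id_to_name = {e["id"]: Path(e["file_name"]).stem for e in images}
    micrographs = [(Path(e["file_name"]).stem, e["height"], e["width"]) for e in images]
    annos = []
    for a in doc["annotations"]:
        x_min, y_min, bw, bh = a["bbox"]
        annos.append(
            ParticleAnnotation(
                particle_id=a["id"],
                micrograph_id=id_to_name[a["image_id"]],
                cx=x_min + bw / 2.0,
                cy=y_min + bh / 2.0,
                bw=bw,
                bh=bh,
                category=a["category_id"],
            )
        )
    return AnnotationSet(
        micrographs=micrographs, annotations=annos, split_tag=doc.get("split", "train")
    )
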