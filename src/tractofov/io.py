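"""Tractogram file I/O: TRK, TCK, VTK legacy polydata, and VTP.

TRK/TCK go through ``nibabel.streamlines``.  The VTK legacy and VTP
(XML polydata) readers/writers are minimal ASCII implementations covering
the polyline subset those formats use for tractography.

Per-streamline integer tract labels are embedded where the format allows
(TRK ``data_per_streamline``, VTK/VTP cell data) and otherwise written to a
sidecar TSV ``<stem>.labels.tsv`` with columns ``index<TAB>label``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import nibabel as nib
import numpy as np

from .tractogram import LabeledTractogram

__all__ = [
    "read_tractogram",
    "write_tractogram",
    "read_labels_tsv",
    "write_labels_tsv",
    "UnsupportedFormatError",
]

LABEL_KEY = "tract_label"
SUPPORTED = {".trk", ".tck", ".vtk", ".vtp"}


class UnsupportedFormatError(ValueError):
    """Raised for a tractogram file extension we cannot parse."""


def _sidecar(path: Path) -> Path:
    return path.parent / (path.stem + ".labels.tsv")


def _read_label_tsv(path: Path, n: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("index"):
                continue
            idx, lab = line.split("\t")
            rows.append((int(idx), int(lab)))
    if len(rows) != n:
        raise ValueError(f"label sidecar has {len(rows)} rows for {n} streamlines")
    labels = np.empty(n, dtype=int)
    for idx, lab in rows:
        labels[idx] = lab
    return labels


def _write_label_tsv(path: Path, labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("index\tlabel\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{int(lab)}\n")


def read_tractogram(
    path, labels_path=None, subject_id: str | None = None
) -> LabeledTractogram:
    """Read a tractogram (and labels, if present) from a supported file.

    Label lookup order: explicit ``labels_path``, labels embedded in the
    file, then the default sidecar ``<stem>.labels.tsv`` next to it.
    """
    path = Path(path)
    if path.suffix.lower() not in SUPPORTED:
        raise UnsupportedFormatError(f"unsupported tractogram format: {path.suffix!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    suffix = path.suffix.lower()
    labels: np.ndarray | None = None
    if suffix in (".trk", ".tck"):
        tf = nib.streamlines.load(str(path))
        streamlines = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
        dps = tf.tractogram.data_per_streamline
        if LABEL_KEY in dps and len(streamlines):
            labels = np.asarray(dps[LABEL_KEY], dtype=float).reshape(-1).astype(int)
    elif suffix == ".vtk":
        streamlines, labels = _read_vtk_legacy(path)
    else:
        streamlines, labels = _read_vtp(path)

    if labels_path is not None:
        labels = _read_label_tsv(Path(labels_path), len(streamlines))
    elif labels is None and _sidecar(path).exists():
        labels = _read_label_tsv(_sidecar(path), len(streamlines))

    return LabeledTractogram(
        streamlines=streamlines,
        labels=labels,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_tractogram(t: LabeledTractogram, path) -> None:
    """Write a tractogram to TRK/TCK/VTK/VTP, embedding labels where possible.

    TCK cannot carry per-streamline scalars, so labels go to the sidecar
    TSV there; a sidecar is also written alongside every format for easy
    tabular access.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in SUPPORTED:
        raise UnsupportedFormatError(f"unsupported tractogram format: {path.suffix!r}")
    path.parent.mkdir(parents=True, exist_ok=True)

    if suffix in (".trk", ".tck"):
        dps = {}
        if t.labels is not None and suffix == ".trk" and len(t):
            dps[LABEL_KEY] = t.labels.astype(np.float64).reshape(-1, 1)
        tractogram = nib.streamlines.Tractogram(
            list(t.streamlines), data_per_streamline=dps, affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(tractogram, str(path))
    elif suffix == ".vtk":
        _write_vtk_legacy(t, path)
    else:
        _write_vtp(t, path)

    if t.labels is not None:
        _write_label_tsv(_sidecar(path), t.labels)


def read_labels_tsv(path, n: int | None = None) -> np.ndarray:
    """Per-streamline labels from an ``index<TAB>label`` sidecar table."""
    path = Path(path)
    if n is None:
        with open(path) as fh:
            n = sum(
                1 for line in fh
                if line.strip() and not line.startswith(("#", "index"))
            )
    return _read_label_tsv(path, n)


def write_labels_tsv(path, labels) -> None:
    _write_label_tsv(Path(path), np.asarray(labels, dtype=int))


# ---------------------------------------------------------------------------
# VTK legacy polydata (ASCII)

def _write_vtk_legacy(t: LabeledTractogram, path: Path) -> None:
    pts = t.concatenated_points()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ntractogram\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        counts = [len(s) for s in t.streamlines]
        size = sum(c + 1 for c in counts)
        fh.write(f"LINES {len(counts)} {size}\n")
        offset = 0
        for c in counts:
            fh.write(" ".join([str(c)] + [str(offset + i) for i in range(c)]) + "\n")
            offset += c
        if t.labels is not None and len(t):
            fh.write(f"CELL_DATA {len(counts)}\n")
            fh.write(f"SCALARS {LABEL_KEY} int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(v)) for v in t.labels) + "\n")


def _read_vtk_legacy(path: Path):
    tokens = path.read_text().split("\n", 2)[2].split()  # skip the 2 header lines
    it = iter(tokens)
    points = None
    lines: list[np.ndarray] = []
    labels = None
    for tok in it:
        up = tok.upper()
        if up == "POINTS":
            n = int(next(it))
            next(it)  # dtype
            flat = np.array([float(next(it)) for _ in range(3 * n)])
            points = flat.reshape(n, 3)
        elif up == "LINES":
            m = int(next(it))
            size = int(next(it))
            cells = [int(next(it)) for _ in range(size)]
            i = 0
            for _ in range(m):
                c = cells[i]
                idx = cells[i + 1 : i + 1 + c]
                lines.append(points[idx])
                i += c + 1
        elif up == "SCALARS":
            next(it)  # array name
            next(it)  # dtype; optional component count falls through the loop
        elif up == "LOOKUP_TABLE":
            next(it)  # table name
            vals = [int(next(it)) for _ in range(len(lines))]
            labels = np.asarray(vals, dtype=int)
    if points is None:
        raise ValueError(f"{path}: no POINTS section found")
    return lines, labels


# ---------------------------------------------------------------------------
# VTP (XML polydata, ASCII)

def _write_vtp(t: LabeledTractogram, path: Path) -> None:
    pts = t.concatenated_points()
    counts = np.array([len(s) for s in t.streamlines], dtype=int)
    offsets = np.cumsum(counts)
    root = ET.Element("VTKFile", type="PolyData", version="0.1")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        poly, "Piece", NumberOfPoints=str(len(pts)), NumberOfLines=str(len(counts))
    )
    points_el = ET.SubElement(piece, "Points")
    arr = ET.SubElement(
        points_el, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    arr.text = " ".join(f"{v:.6f}" for v in pts.ravel())
    lines_el = ET.SubElement(piece, "Lines")
    conn = ET.SubElement(lines_el, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = " ".join(str(i) for i in range(len(pts)))
    offs = ET.SubElement(lines_el, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(str(int(o)) for o in offsets)
    if t.labels is not None and len(t):
        cd = ET.SubElement(piece, "CellData")
        lab = ET.SubElement(cd, "DataArray", type="Int32", Name=LABEL_KEY, format="ascii")
        lab.text = " ".join(str(int(v)) for v in t.labels)
    ET.ElementTree(root).write(path, xml_declaration=True)


def _read_vtp(path: Path):
    root = ET.parse(path).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTP polydata file")

    def _floats(el):
        return np.array([float(v) for v in (el.text or "").split()])

    pts_el = piece.find("./Points/DataArray")
    points = _floats(pts_el).reshape(-1, 3)
    conn = offsets = None
    for el in piece.findall("./Lines/DataArray"):
        if el.get("Name") == "connectivity":
            conn = _floats(el).astype(int)
        elif el.get("Name") == "offsets":
            offsets = _floats(el).astype(int)
    lines: list[np.ndarray] = []
    if conn is not None and offsets is not None:
        start = 0
        for end in offsets:
            lines.append(points[conn[start:end]])
            start = end
    labels = None
    for el in piece.findall("./CellData/DataArray"):
        if el.get("Name") == LABEL_KEY:
            labels = _floats(el).astype(int)
    return lines, labels
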