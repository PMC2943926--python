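"""Reading and writing the TPS digitizing format and the pipeline's tabular outputs.

The TPS format is the plain-text landmark file emitted by the tps-suite
digitizers (tps-DIG and relatives): per-specimen blocks headed by ``LM=k``,
optionally followed by ``CURVES=n`` / ``POINTS=m`` outline blocks and
``KEY=value`` metadata lines (``ID=``, ``IMAGE=``, ``SCALE=`` ...).  Keys are
matched case-insensitively and CRLF line endings are tolerated, since files in
the wild vary.  Unrecognized keys are preserved verbatim so that reading and
re-writing a file is lossless.

``SCALE=`` factors are applied at read time (coordinates multiplied by the
factor) and divided back out on write, so the stored representation always
carries physical units while round-trips are exact.

Also here: the core coordinate containers (:class:`Polyline`,
:class:`Configuration`, :class:`SpecimenRecord`), Newick serialization of
UPGMA phenograms, and CSV I/O for distance matrices and score tables.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Polyline",
    "Configuration",
    "SpecimenRecord",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "newick_string",
    "write_newick",
    "read_distance_csv",
    "write_distance_csv",
    "write_scores_csv",
    "read_labels_csv",
    "write_labels_csv",
    "attach_labels",
]


class TPSParseError(ValueError):
    """Malformed TPS input; carries the 1-based line number of the offense."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclasses.dataclass
class Polyline:
    """An ordered 2-D digitized curve, open or closed.

    A closed polyline does *not* repeat its first vertex at the end: closure
    is implicit in the flag. Consecutive duplicate vertices are rejected.
    """

    vertices: np.ndarray  # (n, 2) float
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if v.shape[0] < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive duplicate vertices are forbidden")
        if self.closed and np.array_equal(v[0], v[-1]):
            raise ValueError(
                "closed polyline must not repeat its first vertex at the end"
            )
        self.vertices = v

    def __len__(self) -> int:
        return self.vertices.shape[0]


@dataclasses.dataclass
class Configuration:
    """A fixed-length ordered set of k 2-D (semi)landmarks for one specimen."""

    points: np.ndarray  # (k, 2) float
    specimen_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if p.shape[0] < 3:
            raise ValueError("a configuration needs at least 3 landmarks")
        if np.allclose(p, p[0]):
            raise ValueError("all landmarks coincide")
        self.points = p

    @property
    def k(self) -> int:
        return self.points.shape[0]


#: recognized metadata keys mapped onto SpecimenRecord fields
_FIELD_KEYS = {"ID", "IMAGE", "SCALE", "GENUS", "SPECIES", "STATUS"}


@dataclasses.dataclass
class SpecimenRecord:
    """One digitized specimen: landmarks and/or outline curves plus metadata."""

    specimen_id: str = ""
    genus: str = ""
    species: str = ""
    status: str | None = None  # "extant" | "fossil"
    landmarks: Configuration | None = None
    curves: list[Polyline] = dataclasses.field(default_factory=list)
    scale: float | None = None  # units per pixel, already applied to coords
    image_name: str | None = None
    metadata: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.landmarks is None and not self.curves:
            raise ValueError("record needs landmarks or at least one curve")
        if self.scale is not None and not self.scale > 0:
            raise ValueError("SCALE must be positive")
        if self.status is not None and self.status not in ("extant", "fossil"):
            raise ValueError(f"unknown status {self.status!r}")


# ---------------------------------------------------------------------------
# TPS parsing
# ---------------------------------------------------------------------------

_KEY_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)=(.*)$")


def _parse_point(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TPSParseError(f"expected 'x y' coordinate pair, got {line!r}", lineno)
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise TPSParseError(f"non-numeric coordinate in {line!r}", lineno) from None


def _read_points(lines: list[str], start: int, m: int, what: str) -> tuple[np.ndarray, int]:
    pts = np.empty((m, 2))
    for j in range(m):
        idx = start + j
        if idx >= len(lines) or _KEY_RE.match(lines[idx].strip()):
            raise TPSParseError(
                f"{what}: expected {m} coordinate lines, found {j}", idx + 1
            )
        pts[j] = _parse_point(lines[idx].strip(), idx + 1)
    return pts, start + m


def read_tps(path: str | Path) -> list[SpecimenRecord]:
    """Parse a TPS file into a list of :class:`SpecimenRecord`.

    Records are delimited by ``LM=`` headers.  ``LM=k`` is followed by *k*
    coordinate lines; ``CURVES=n`` introduces *n* blocks each headed by
    ``POINTS=m``.  Coordinates are multiplied by ``SCALE=`` when present.
    A curve whose final vertex repeats its first is stored closed, with the
    duplicate stripped.
    """
    text = Path(path).read_text()
    lines = text.replace("\r\n", "\n").replace("\r", "\n").split("\n")

    # locate LM= headers
    headers: list[int] = []
    for i, raw in enumerate(lines):
        m = _KEY_RE.match(raw.strip())
        if m and m.group(1).upper() == "LM":
            headers.append(i)
    first = next((i for i, raw in enumerate(lines) if raw.strip()), None)
    if first is not None and (not headers or headers[0] != first):
        raise TPSParseError("content before any LM= header", first + 1)
    records: list[SpecimenRecord] = []
    for bi, h in enumerate(headers):
        end = headers[bi + 1] if bi + 1 < len(headers) else len(lines)
        records.append(_parse_block(lines, h, end))
    return records


def _parse_int(value: str, key: str, lineno: int) -> int:
    try:
        n = int(value)
    except ValueError:
        raise TPSParseError(f"{key}= value {value!r} is not an integer", lineno) from None
    if n < 0:
        raise TPSParseError(f"{key}= value must be nonnegative", lineno)
    return n


def _parse_block(lines: list[str], start: int, end: int) -> SpecimenRecord:
    m = _KEY_RE.match(lines[start].strip())
    assert m is not None
    k = _parse_int(m.group(2).strip(), "LM", start + 1)
    i = start + 1
    landmarks_raw, i = _read_points(lines, i, k, "LM block") if k else (None, i)

    curves_raw: list[np.ndarray] = []
    fields: dict[str, str] = {}
    meta: dict[str, str] = {}
    while i < end:
        raw = lines[i].strip()
        if not raw:
            i += 1
            continue
        km = _KEY_RE.match(raw)
        if not km:
            raise TPSParseError(f"unexpected line {raw!r}", i + 1)
        key, value = km.group(1).upper(), km.group(2).strip()
        if key == "CURVES":
            ncurves = _parse_int(value, "CURVES", i + 1)
            i += 1
            for _ in range(ncurves):
                if i >= end:
                    raise TPSParseError("missing POINTS= block for declared curve", i + 1)
                pm = _KEY_RE.match(lines[i].strip())
                if not pm or pm.group(1).upper() != "POINTS":
                    raise TPSParseError(
                        f"expected POINTS= header, got {lines[i].strip()!r}", i + 1
                    )
                npts = _parse_int(pm.group(2).strip(), "POINTS", i + 1)
                pts, i = _read_points(lines, i + 1, npts, "POINTS block")
                curves_raw.append(pts)
        elif key in _FIELD_KEYS:
            fields[key] = value
            i += 1
        else:
            meta[key] = value
            i += 1

    scale: float | None = None
    if "SCALE" in fields:
        try:
            scale = float(fields["SCALE"])
        except ValueError:
            raise TPSParseError(
                f"non-numeric SCALE= value {fields['SCALE']!r}", start + 1
            ) from None

    factor = scale if scale is not None else 1.0
    landmarks = None
    if landmarks_raw is not None and len(landmarks_raw):
        landmarks = Configuration(landmarks_raw * factor, fields.get("ID", ""))

    curves = []
    for pts in curves_raw:
        closed = len(pts) > 2 and np.array_equal(pts[0], pts[-1])
        if closed:
            pts = pts[:-1]
        curves.append(Polyline(pts * factor, closed=closed))

    status = fields.get("STATUS", "").lower() or None
    return SpecimenRecord(
        specimen_id=fields.get("ID", ""),
        genus=fields.get("GENUS", ""),
        species=fields.get("SPECIES", ""),
        status=status,
        landmarks=landmarks,
        curves=curves,
        scale=scale,
        image_name=fields.get("IMAGE") or None,
        metadata=meta,
    )


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_tps(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write records as a TPS file re-readable by :func:`read_tps`.

    Coordinates are emitted at full precision, divided by the record's scale
    factor (so ``SCALE=`` semantics round-trip); closed curves are written
    with their first vertex repeated at the end.
    """
    out: list[str] = []
    for rec in records:
        inv = 1.0 / rec.scale if rec.scale is not None else 1.0
        k = rec.landmarks.k if rec.landmarks is not None else 0
        out.append(f"LM={k}")
        if rec.landmarks is not None:
            for x, y in rec.landmarks.points * inv:
                out.append(f"{_fmt(x)} {_fmt(y)}")
        if rec.curves:
            out.append(f"CURVES={len(rec.curves)}")
            for c in rec.curves:
                pts = c.vertices * inv
                if c.closed:
                    pts = np.vstack([pts, pts[:1]])
                out.append(f"POINTS={len(pts)}")
                for x, y in pts:
                    out.append(f"{_fmt(x)} {_fmt(y)}")
        if rec.image_name:
            out.append(f"IMAGE={rec.image_name}")
        if rec.specimen_id:
            out.append(f"ID={rec.specimen_id}")
        if rec.scale is not None:
            out.append(f"SCALE={_fmt(rec.scale)}")
        if rec.genus:
            out.append(f"GENUS={rec.genus}")
        if rec.species:
            out.append(f"SPECIES={rec.species}")
        if rec.status:
            out.append(f"STATUS={rec.status}")
        for key, value in rec.metadata.items():
            out.append(f"{key}={value}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]':;,]")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree) -> str:
    """Serialize an :class:`~gryllomorph.phenetics.UltrametricTree` to Newick.

    Branch lengths are height differences, so every root-to-leaf path equals
    the tree height.
    """
    n = len(tree.leaves)
    if n == 1:
        return _newick_label(tree.leaves[0]) + ";"
    # node id -> (newick fragment without branch length, height)
    nodes: dict[int, tuple[str, float]] = {
        i: (_newick_label(lab), 0.0) for i, lab in enumerate(tree.leaves)
    }
    nid = n
    for a, b, h in tree.merges:
        (sa, ha), (sb, hb) = nodes.pop(a), nodes.pop(b)
        frag = f"({sa}:{_fmt(h - ha)},{sb}:{_fmt(h - hb)})"
        nodes[nid] = (frag, h)
        nid += 1
    (root, _), = nodes.values()
    return root + ";"


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_distance_csv(distmat, path: str | Path) -> None:
    """Square CSV with a header row/column of labels."""
    df = pd.DataFrame(distmat.d, index=list(distmat.labels), columns=list(distmat.labels))
    df.to_csv(path, float_format="%.12g")


def read_distance_csv(path: str | Path):
    from .phenetics import DistanceMatrix

    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(labels=[str(c) for c in df.columns], d=df.to_numpy(dtype=float))


def write_scores_csv(
    labels: Sequence[str], scores: np.ndarray, path: str | Path, prefix: str = "RW"
) -> None:
    cols = [f"{prefix}{j + 1}" for j in range(scores.shape[1])]
    df = pd.DataFrame(scores, index=list(labels), columns=cols)
    df.index.name = "specimen_id"
    df.to_csv(path, float_format="%.12g")


def write_labels_csv(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "genus": r.genus,
            "species": r.species,
            "status": r.status or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, dtype=str).fillna("")
    return {row["specimen_id"]: dict(row) for _, row in df.iterrows()}


def attach_labels(
    records: Iterable[SpecimenRecord], labels: Mapping[str, Mapping[str, str]]
) -> None:
    """Fill genus/species/status on records in place from a labels table."""
    for rec in records:
        row = labels.get(rec.specimen_id)
        if row is None:
            continue
        rec.genus = row.get("genus", rec.genus)
        rec.species = row.get("species", rec.species)
        rec.status = row.get("status") or rec.status
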