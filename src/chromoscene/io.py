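"""Readers and writers for structure and annotation file formats.

Structure formats
-----------------
* ``.3dg`` — tab-separated (chromosome, bin-start, x, y, z), the format
  of published single-cell diploid genome models.  Files carry no
  resolution, so the bin width is inferred as the minimum positive gap
  between consecutive bin starts per chromosome (robust to gaps in the
  model); an explicit hint overrides.
* generic XYZ tables — any delimited file with a header, via a
  role -> column mapping.
* TSV / Arrow IPC (Feather) — the package's own persisted form; Arrow
  round-trips bit-exactly, TSV to 9 significant digits.

Annotation formats
------------------
* BED3–BED6 (already 0-based half-open, kept as-is).
* GTF (1-based inclusive, converted to 0-based half-open on ingest).

GFF3 and PDB ingestion are deliberately unsupported in this version
rather than silently misparsed.
"""

from __future__ import annotations

import json
import logging
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.feather as feather

from .core import (
    InputError,
    RESERVED_COLUMNS,
    Structure,
    ValidationError,
    make_structure,
)
from .encode import ResolvedScene

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised on a malformed input line; message carries the line number."""


# ---------------------------------------------------------------------
# Structures


def read_3dg(path, resolution_hint: int | None = None) -> Structure:
    """Read a ``.3dg`` structure file.

    Columns: chromosome, bin start (bp), x, y, z; tab-separated, ``#``
    starts a comment line.  Bins become ``[position, position + r)``
    where ``r`` is ``resolution_hint`` or the inferred minimum positive
    gap between consecutive positions within a chromosome.

    Raises :class:`ParseError` on non-numeric fields (with line number)
    and :class:`~chromoscene.core.ValidationError` on duplicate
    (chromosome, position) rows.
    """
    path = Path(path)
    chroms: list[str] = []
    positions: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >= 5 tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                pos = int(float(parts[1]))
                x, y, z = (float(v) for v in parts[2:5])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-numeric coordinate in {parts[1:5]}"
                ) from None
            chroms.append(parts[0])
            positions.append(pos)
            xyz.append((x, y, z))
    if not chroms:
        raise ParseError(f"{path.name}: no data lines")

    df = pd.DataFrame(
        {"chrom": chroms, "pos": positions}
    )
    if df.duplicated(["chrom", "pos"]).any():
        dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
        raise ValidationError(
            f"duplicate (chrom, position) entry {dup['chrom']}:{dup['pos']}"
        )

    if resolution_hint is not None:
        r = int(resolution_hint)
    else:
        gaps = []
        for c, grp in df.groupby("chrom", sort=False):
            d = np.diff(np.sort(grp["pos"].to_numpy()))
            gaps.extend(d[d > 0])
        r = int(min(gaps)) if gaps else 1
        if not gaps:
            logger.warning(
                "%s: cannot infer resolution (no consecutive positions); "
                "using 1 bp",
                path.name,
            )

    arr = np.asarray(xyz, dtype=float)
    start = np.asarray(positions, dtype=np.int64)
    return make_structure(
        arr,
        genomic={"chrom": chroms, "start": start, "end": start + r},
        id=path.stem,
    )


def read_xyz_table(
    path,
    colmap: dict[str, str],
    delimiter: str = ",",
    id: str | None = None,
) -> Structure:
    """Read a generic delimited XYZ table with a header row.

    ``colmap`` maps roles to column names and must cover at least
    ``x, y, z``; ``chrom, start, end`` are optional (synthetic 1-bp bins
    are used when absent).  Unmapped columns become extra data columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter)
    missing_roles = [r for r in ("x", "y", "z") if r not in colmap]
    if missing_roles:
        raise InputError(f"colmap must map roles {missing_roles}")
    absent = [c for c in colmap.values() if c not in df.columns]
    if absent:
        raise InputError(
            f"mapped column(s) {absent} not in file; available headers: "
            f"{list(df.columns)}"
        )
    coords = df[[colmap["x"], colmap["y"], colmap["z"]]].to_numpy(dtype=float)
    genomic = None
    if all(r in colmap for r in ("chrom", "start", "end")):
        genomic = {
            "chrom": df[colmap["chrom"]].astype(str),
            "start": df[colmap["start"]],
            "end": df[colmap["end"]],
        }
    mapped = set(colmap.values())
    extra = {
        c: df[c].to_numpy() for c in df.columns if c not in mapped
    }
    return make_structure(
        coords, genomic=genomic, extra=extra or None, id=id or path.stem
    )


# ---------------------------------------------------------------------
# Annotations

_STRANDS = {"+", "-", "."}


def read_bed(path) -> pd.DataFrame:
    """Read BED3–BED6 into a feature table (0-based half-open, as BED is).

    Columns of the result: ``chrom, start, end`` plus ``name, score,
    strand`` when present.  ``track``/``browser``/``#`` lines are
    skipped.  ``start >= end`` raises :class:`ParseError` with the line
    number.
    """
    path = Path(path)
    rows = []
    ncols = 3
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (
                not line.strip()
                or line.startswith(("#", "track", "browser"))
            ):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: BED needs >= 3 columns"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ParseError(
                    f"{path.name}:{lineno}: start {start} >= end {end}"
                )
            name = parts[3] if len(parts) > 3 else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError:
                    raise ParseError(
                        f"{path.name}:{lineno}: non-numeric score {parts[4]!r}"
                    ) from None
            strand = parts[5] if len(parts) > 5 else None
            if strand is not None and strand not in _STRANDS:
                raise ParseError(
                    f"{path.name}:{lineno}: strand must be one of "
                    f"{sorted(_STRANDS)}, got {strand!r}"
                )
            rows.append((parts[0], start, end, name, score, strand))
            ncols = max(ncols, len(parts))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    if ncols <= 3:
        df = df[["chrom", "start", "end"]]
    elif ncols == 4:
        df = df[["chrom", "start", "end", "name"]]
    elif ncols == 5:
        df = df[["chrom", "start", "end", "name", "score"]]
    return df


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(
    path,
    feature_filter: str | None = None,
    attribute_key: str = "gene_id",
) -> pd.DataFrame:
    """Read a 9-column GTF into a feature table.

    GTF coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention as ``(start - 1, end)``.
    Rows whose feature type differs from ``feature_filter`` (e.g.
    ``"gene"``) are dropped when a filter is given.  The feature name is
    taken from ``attribute_key`` in the attribute field; a malformed
    attribute field keeps the feature with an empty name and logs a
    warning.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(
                    f"{path.name}:{lineno}: GTF needs 9 tab-separated columns"
                )
            chrom, _source, feature, start, end, score, strand = parts[:7]
            if feature_filter is not None and feature != feature_filter:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            attrs = dict(_GTF_ATTR_RE.findall(parts[8]))
            name = attrs.get(attribute_key, "")
            if not attrs and parts[8].strip():
                logger.warning(
                    "%s:%d: malformed attribute field %r; keeping feature "
                    "with empty name",
                    path.name,
                    lineno,
                    parts[8][:60],
                )
            score_v = None if score in (".", "") else float(score)
            strand_v = strand if strand in _STRANDS else "."
            rows.append((chrom, start_i - 1, end_i, name, score_v, strand_v))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


# ---------------------------------------------------------------------
# Persistence of structures and resolved scenes

_META_ID = b"chromoscene.id"
_META_RES = b"chromoscene.resolution"
_META_SYN = b"chromoscene.synthetic"


def _format_float(v: float) -> str:
    """10-significant-digit decimal; positional notation below 1e6.

    Ten digits keep the worst-case relative round-trip error below
    5e-10 regardless of the leading mantissa digit.
    """
    s = f"{v:.10g}"
    if "e" in s or "E" in s:
        if abs(v) < 1e6:
            s = np.format_float_positional(
                v, precision=10, unique=False, fractional=False, trim="-"
            )
    return s


def write_structure(s: Structure, path, format: str = "arrow") -> None:
    """Persist a structure as ``arrow`` (Feather, lossless) or ``tsv``.

    The TSV form has a header row (chrom, start, end, x, y, z, extras),
    '.' decimal separator, no scientific notation below 1e6, and '\\n'
    newlines, so files diff deterministically.  Arrow round-trips
    bit-exactly including the structure id and resolution (stored as
    schema metadata).
    """
    path = Path(path)
    cols = list(RESERVED_COLUMNS) + s.extra_columns
    bins = s.bins[cols]
    if format == "arrow":
        table = pa.Table.from_pandas(bins, preserve_index=False)
        meta = {
            _META_ID: s.id.encode(),
            _META_RES: str(
                s.resolution if s.resolution is not None else "unknown"
            ).encode(),
            _META_SYN: str(int(s.synthetic_coordinates)).encode(),
        }
        feather.write_feather(
            table.replace_schema_metadata(meta), path, compression="uncompressed"
        )
    elif format == "tsv":
        with open(path, "w", newline="\n") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in bins.itertuples(index=False):
                out = []
                for v in row:
                    if isinstance(v, (float, np.floating)):
                        out.append(_format_float(float(v)))
                    else:
                        out.append(str(v))
                fh.write("\t".join(out) + "\n")
    else:
        raise InputError(f"unknown format {format!r}; use 'arrow' or 'tsv'")


def read_structure(path, format: str | None = None) -> Structure:
    """Read back a structure written by :func:`write_structure`.

    ``format`` defaults by extension (``.tsv`` -> tsv, else arrow).
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix == ".tsv" else "arrow"
    if format == "arrow":
        table = feather.read_table(path)
        meta = table.schema.metadata or {}
        bins = table.to_pandas()
        res = meta.get(_META_RES, b"unknown").decode()
        return Structure(
            id=meta.get(_META_ID, path.stem.encode()).decode(),
            bins=bins,
            resolution=None if res == "unknown" else int(res),
            synthetic_coordinates=bool(int(meta.get(_META_SYN, b"0"))),
        )
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        extras = {
            c: df[c].to_numpy()
            for c in df.columns
            if c not in RESERVED_COLUMNS
        }
        return make_structure(
            coords,
            genomic={
                "chrom": df["chrom"].astype(str),
                "start": df["start"],
                "end": df["end"],
            },
            extra=extras or None,
            id=path.stem,
        )
    raise InputError(f"unknown format {format!r}; use 'arrow' or 'tsv'")


def write_resolved(scene: ResolvedScene, path) -> None:
    """Persist a resolved scene: Arrow table + JSON sidecar for links.

    The per-bin attributes go into a Feather table at ``path``; the link
    segments and radii into ``<path>.links.json`` beside it.
    """
    path = Path(path)
    table = pa.table(
        {
            "structure_id": pa.array([str(v) for v in scene.structure_ids]),
            "x": scene.positions[:, 0],
            "y": scene.positions[:, 1],
            "z": scene.positions[:, 2],
            "mark": pa.array([str(v) for v in scene.marks]),
            "radius": scene.radii,
            "r": scene.rgba[:, 0],
            "g": scene.rgba[:, 1],
            "b": scene.rgba[:, 2],
            "a": scene.rgba[:, 3],
        }
    )
    feather.write_feather(table, path, compression="uncompressed")
    sidecar = {
        "links": scene.links.tolist(),
        "link_radii": scene.link_radii.tolist(),
    }
    with open(str(path) + ".links.json", "w") as fh:
        json.dump(sidecar, fh)


def read_resolved(path) -> ResolvedScene:
    """Read back a resolved scene written by :func:`write_resolved`."""
    path = Path(path)
    df = feather.read_table(path).to_pandas()
    sidecar_path = str(path) + ".links.json"
    links = np.empty((0, 2, 3))
    link_radii = np.empty((0,))
    if os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        if sidecar["links"]:
            links = np.asarray(sidecar["links"], dtype=float)
            link_radii = np.asarray(sidecar["link_radii"], dtype=float)
    return ResolvedScene(
        structure_ids=df["structure_id"].to_numpy(dtype=object),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        marks=df["mark"].to_numpy(dtype=object),
        radii=df["radius"].to_numpy(dtype=float),
        rgba=df[["r", "g", "b", "a"]].to_numpy(dtype=np.uint8),
        links=links,
        link_radii=link_radii,
    )
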