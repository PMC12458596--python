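"""Semantic and spatial filtering of 3D genome structures.

Two families of selections are supported and freely composable:

* **genomic** — a set of intervals (a range string like
  ``"chr1:0-2,000,000"`` or a BED-style table) selects every bin whose
  interval overlaps a query interval by at least one base pair
  (half-open intersection);
* **spatial** — a spherical neighborhood of a point or genomic locus,
  or a cutting plane keeping one half-space (cross-sections).

All selections return a :class:`BinMask` — one boolean per bin plus a
provenance string describing the query — which supports boolean algebra
(``&``, ``|``, ``~``) and can be applied back onto the structure.
Linear scans are deliberate: structures at desk scale (10^3–10^5 bins)
need no spatial index.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InputError, Structure, as_rangeset, infer_resolution


class RangeSyntaxError(ValueError):
    """Raised when a range query string cannot be parsed."""


@dataclass(frozen=True)
class PlaneSpec:
    """Half-space filter: plane with unit-normal direction and offset.

    ``offset`` is the signed distance of the plane from the origin along
    the unit normal.  ``keep_side="positive"`` keeps points with signed
    value ``v = n̂·p − offset >= 0``; ``"negative"`` keeps ``v < 0``.
    Ties (v = 0) always go to the positive side so the two sides
    partition any structure exactly.
    """

    normal: tuple[float, float, float]
    offset: float = 0.0
    keep_side: str = "positive"

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,) or not np.isfinite(n).all() or np.linalg.norm(n) == 0:
            raise InputError("plane normal must be a finite non-zero 3-vector")
        if self.keep_side not in ("positive", "negative"):
            raise InputError("keep_side must be 'positive' or 'negative'")


@dataclass(frozen=True)
class SphereSpec:
    """Spherical neighborhood: closed ball of ``radius`` spatial units.

    ``center`` is either an XYZ point (3 reals) or a genomic locus
    ``(chrom, position)``; a locus resolves to the stored point of the
    bin whose interval contains the position (no interpolation).
    """

    center: tuple
    radius: float

    def __post_init__(self):
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise InputError("sphere radius must be a positive real")
        if len(self.center) not in (2, 3):
            raise InputError("center must be (x, y, z) or (chrom, position)")


@dataclass
class BinMask:
    """Boolean selection over the bins of one named structure."""

    values: np.ndarray
    structure_id: str
    provenance: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_selected(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "BinMask") -> "BinMask":
        return combine(self, other, "and")

    def __or__(self, other: "BinMask") -> "BinMask":
        return combine(self, other, "or")

    def __invert__(self) -> "BinMask":
        return invert(self)

    def __repr__(self) -> str:
        return (
            f"<BinMask on {self.structure_id!r}: {self.n_selected}/"
            f"{len(self)} bins; {self.provenance}>"
        )


# ---------------------------------------------------------------------
# Range-query string grammar:  chrom[:start-end][, ...]
# Numbers may contain thousands-commas and k/M/G suffixes; a bare
# chromosome name selects the whole chromosome.

_QUERY_RE = re.compile(
    r"\s*(?P<chrom>[^:,\s]+)"
    r"(?:\s*:\s*(?P<start>[\d,\.]+[kKmMgG]?)\s*-\s*(?P<end>[\d,\.]+[kKmMgG]?))?"
    r"\s*(?:,|$)"
)

_SUFFIX = {"k": 1_000, "m": 1_000_000, "g": 1_000_000_000}


def _parse_bp(token: str, query: str, pos: int) -> int:
    mult = 1
    if token and token[-1].lower() in _SUFFIX:
        mult = _SUFFIX[token[-1].lower()]
        token = token[:-1]
    token = token.replace(",", "")
    try:
        value = float(token) * mult
    except ValueError:
        raise RangeSyntaxError(
            f"cannot parse number {token!r} at position {pos} in {query!r}"
        ) from None
    if value != int(value):
        raise RangeSyntaxError(
            f"{token!r} at position {pos} does not resolve to whole base pairs"
        )
    return int(value)


def parse_range_query(query: str) -> pd.DataFrame:
    """Parse a range query string into a (chrom, start, end) table.

    Grammar: comma-separated ``chrom[:start-end]`` terms.  ``start`` and
    ``end`` are base-pair numbers, optionally with thousands-commas or a
    k/M/G suffix (``"chr1:0-2M"``).  A bare chromosome selects the whole
    chromosome, encoded here as the interval ``[0, 2^62)``.

    Raises :class:`RangeSyntaxError` naming the failing position.
    """
    rows = []
    pos = 0
    if not query.strip():
        raise RangeSyntaxError("empty range query")
    while pos < len(query):
        m = _QUERY_RE.match(query, pos)
        if not m or m.end() == pos:
            raise RangeSyntaxError(
                f"syntax error at position {pos} in {query!r}"
            )
        chrom = m.group("chrom")
        if m.group("start") is not None:
            start = _parse_bp(m.group("start"), query, m.start("start"))
            end = _parse_bp(m.group("end"), query, m.start("end"))
            if end <= start:
                raise RangeSyntaxError(
                    f"interval end {end} <= start {start} in {query!r}"
                )
        else:
            start, end = 0, 2**62
        rows.append((chrom, start, end))
        pos = m.end()
    return as_rangeset(rows)


# ---------------------------------------------------------------------
# Selections


def select_by_ranges(s: Structure, query) -> BinMask:
    """Select bins whose interval overlaps any query interval.

    ``query`` is a range string (see :func:`parse_range_query`) or a
    BED-style table of intervals.  Overlap is half-open: a bin
    ``[0, 100)`` and a query ``[100, 200)`` touch but do not overlap.
    Chromosome names are matched as exact strings.  A query chromosome
    absent from the structure yields no selections and a warning, not an
    error — the same range can then be applied across structures.
    """
    if isinstance(query, str):
        ranges = parse_range_query(query)
        prov = f"range {query!r}"
    else:
        ranges = as_rangeset(query)
        prov = f"ranges ({len(ranges)} intervals)"

    chrom = s.bins["chrom"].to_numpy()
    start = s.bins["start"].to_numpy()
    end = s.bins["end"].to_numpy()
    mask = np.zeros(len(s.bins), dtype=bool)
    present = set(chrom)
    for c, qs, qe in ranges.itertuples(index=False):
        if c not in present:
            warnings.warn(
                f"query chromosome {c!r} not in structure {s.id!r}",
                stacklevel=2,
            )
            continue
        mask |= (chrom == c) & (start < qe) & (end > qs)
    return BinMask(mask, s.id, prov)


def locus_point(s: Structure, chrom: str, position: int) -> np.ndarray:
    """XYZ of the bin whose interval contains ``chrom:position``.

    Raises :class:`LookupError` when no bin covers the locus.
    """
    b = s.bins
    hit = (b["chrom"] == chrom) & (b["start"] <= position) & (position < b["end"])
    idx = np.flatnonzero(hit.to_numpy())
    if idx.size == 0:
        raise LookupError(f"no bin covers locus {chrom}:{position}")
    return b.iloc[idx[0]][["x", "y", "z"]].to_numpy(dtype=float)


def select_sphere(s: Structure, spec: SphereSpec) -> BinMask:
    """Select bins inside the closed ball of ``spec.radius`` around the center."""
    if len(spec.center) == 2:
        chrom, position = spec.center
        center = locus_point(s, str(chrom), int(position))
        prov = f"sphere r={spec.radius} @ {chrom}:{position}"
    else:
        center = np.asarray(spec.center, dtype=float)
        prov = f"sphere r={spec.radius} @ {tuple(center)}"
    d = np.linalg.norm(s.coords() - center, axis=1)
    return BinMask(d <= spec.radius, s.id, prov)


def select_cutting_plane(s: Structure, spec: PlaneSpec) -> BinMask:
    """Select bins on one side of a plane (cross-section filter)."""
    n = np.asarray(spec.normal, dtype=float)
    n_hat = n / np.linalg.norm(n)
    v = s.coords() @ n_hat - spec.offset
    mask = v >= 0 if spec.keep_side == "positive" else v < 0
    prov = f"plane n={tuple(spec.normal)} offset={spec.offset} side={spec.keep_side}"
    return BinMask(mask, s.id, prov)


def slab(s: Structure, normal, center_offset: float, thickness: float) -> BinMask:
    """Finite-thickness cross-section: intersection of two half-spaces.

    Convenience composition for the common "slice through the nucleus"
    view; equivalent to two :func:`select_cutting_plane` calls combined
    with AND.
    """
    half = thickness / 2.0
    lo = select_cutting_plane(
        s, PlaneSpec(normal, center_offset - half, "positive")
    )
    hi = select_cutting_plane(
        s, PlaneSpec(normal, center_offset + half, "negative")
    )
    return combine(lo, hi, "and")


# ---------------------------------------------------------------------
# Mask algebra


def combine(a: BinMask, b: BinMask, op: str) -> BinMask:
    """Elementwise boolean combination of two masks on one structure."""
    if len(a) != len(b):
        raise InputError(
            f"mask length mismatch: {len(a)} vs {len(b)}"
        )
    if a.structure_id != b.structure_id:
        raise InputError(
            f"masks belong to different structures: "
            f"{a.structure_id!r} vs {b.structure_id!r}"
        )
    if op == "and":
        values = a.values & b.values
    elif op == "or":
        values = a.values | b.values
    elif op == "and-not":
        values = a.values & ~b.values
    else:
        raise InputError(f"unknown mask operator {op!r}")
    prov = f"({a.provenance}) {op.upper()} ({b.provenance})"
    return BinMask(values, a.structure_id, prov)


def invert(a: BinMask) -> BinMask:
    return BinMask(~a.values, a.structure_id, f"NOT ({a.provenance})")


def apply_mask(s: Structure, m: BinMask) -> Structure:
    """Subset a structure to the masked bins.

    Row order and extra columns are preserved; the resolution is
    re-inferred from the surviving bins.  The result may have zero bins
    (a representable state that :func:`chromoscene.core.validate` flags).
    """
    if len(m) != len(s.bins):
        raise InputError(
            f"mask length {len(m)} does not match structure with {len(s.bins)} bins"
        )
    if m.structure_id != s.id:
        raise InputError(
            f"mask was made for {m.structure_id!r}, not {s.id!r}"
        )
    bins = s.bins.loc[m.values].reset_index(drop=True)
    widths = (bins["end"] - bins["start"]).to_numpy()
    return Structure(
        id=s.id,
        bins=bins,
        resolution=infer_resolution(widths),
        synthetic_coordinates=s.synthetic_coordinates,
    )
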