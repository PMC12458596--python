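"""Columnar data model for 3D genome structures.

A structure is, at heart, a list of XYZ coordinates in which every point
("bin") may additionally carry a genomic interval and arbitrary per-bin
data columns.  The model is a plain pandas DataFrame with six reserved
columns — ``chrom, start, end, x, y, z`` — followed by any number of
extra columns.  Genomic coordinates are 0-based half-open throughout;
format readers convert on ingest.

Structures whose points have no genomic coordinates get synthetic 1-bp
bins ``[i, i+1)`` on the pseudo-chromosome ``"chr?"`` so that every
downstream operation (selection, aggregation, encoding) is total.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved bin-table column names, in canonical order.
RESERVED_COLUMNS = ("chrom", "start", "end", "x", "y", "z")

#: Pseudo-chromosome used for structures without genomic coordinates.
SYNTHETIC_CHROM = "chr?"


class InputError(ValueError):
    """Raised for malformed arguments (shape mismatches, bad names)."""


class ValidationError(ValueError):
    """Raised when data violates a bin-table invariant."""


@dataclass(frozen=True)
class Violation:
    """One broken bin-table invariant, locating the offending row."""

    invariant: str
    row: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = "" if self.row is None else f" (row {self.row})"
        return f"{self.invariant}{where}: {self.message}"


@dataclass
class Structure:
    """A 3D genome structure: a bin table plus identity and resolution.

    Parameters
    ----------
    id : str
        Name of the structure (used in scenes and masks).
    bins : pandas.DataFrame
        Bin table with the reserved columns ``chrom, start, end, x, y, z``
        and optional extra columns.
    resolution : int or None
        Genomic width of a bin in bp; ``None`` means unknown.
    synthetic_coordinates : bool
        True when the genomic columns are the synthetic 1-bp fallback.
    """

    id: str
    bins: pd.DataFrame
    resolution: int | None = None
    synthetic_coordinates: bool = False

    # -- conveniences -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.bins["chrom"]))

    @property
    def extra_columns(self) -> list[str]:
        return [c for c in self.bins.columns if c not in RESERVED_COLUMNS]

    def coords(self) -> np.ndarray:
        """The n x 3 coordinate matrix as float64."""
        return self.bins[["x", "y", "z"]].to_numpy(dtype=float)

    def __repr__(self) -> str:
        res = "unknown" if self.resolution is None else f"{self.resolution} bp"
        return (
            f"<Structure {self.id!r}: {self.n_bins} bins, "
            f"{len(self.chromosomes)} chromosome(s), resolution {res}>"
        )


@dataclass
class Scene:
    """An ordered list of structures, each paired with its view config.

    The pair list is what a renderer (or here: the exporter) consumes.
    Structures are treated as living in independent coordinate frames;
    aligning them is the caller's business.
    """

    pairs: list[tuple["Structure", object]] = field(default_factory=list)

    def add(self, structure: Structure, view_config) -> "Scene":
        from .encode import validate_config  # local import: avoid cycle

        validate_config(view_config, structure)
        self.pairs.append((structure, view_config))
        return self

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------
# RangeSet


def as_rangeset(ranges) -> pd.DataFrame:
    """Coerce interval-like input to a (chrom, start, end) DataFrame.

    Accepts a DataFrame with at least ``chrom/start/end`` columns (BED-style
    capitalization ``Chromosome/Start/End`` is also recognized), or an
    iterable of ``(chrom, start, end)`` tuples.  Intervals may be unsorted
    and may overlap; each must satisfy ``end > start``.
    """
    if isinstance(ranges, pd.DataFrame):
        cols = {c.lower(): c for c in ranges.columns}
        try:
            chrom = cols.get("chrom") or cols["chromosome"]
            start, end = cols["start"], cols["end"]
        except KeyError as exc:
            raise InputError(
                f"range table needs chrom/start/end columns, got {list(ranges.columns)}"
            ) from exc
        out = pd.DataFrame(
            {
                "chrom": ranges[chrom].astype(str).to_numpy(),
                "start": ranges[start].to_numpy(dtype=np.int64),
                "end": ranges[end].to_numpy(dtype=np.int64),
            }
        )
    else:
        rows = list(ranges)
        out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out["chrom"] = out["chrom"].astype(str)
        out["start"] = out["start"].astype(np.int64)
        out["end"] = out["end"].astype(np.int64)
    bad = np.flatnonzero((out["end"] <= out["start"]).to_numpy())
    if bad.size:
        raise ValidationError(f"range row {bad[0]}: end must exceed start")
    return out


# ---------------------------------------------------------------------
# Construction and validation


def infer_resolution(widths_or_structure) -> int | None:
    """Modal bin width in bp; ties broken toward the smallest width.

    Accepts a :class:`Structure` or a sequence of widths.  Returns ``None``
    ("unknown") only when there are no bins to measure.  The smallest-width
    tie-break keeps downstream binning conservative and deterministic.
    """
    if isinstance(widths_or_structure, Structure):
        b = widths_or_structure.bins
        widths = (b["end"] - b["start"]).to_numpy()
    else:
        widths = np.asarray(list(widths_or_structure))
    if widths.size == 0:
        return None
    counts = Counter(int(w) for w in widths)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def _sorted_per_chrom(bins: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by start within each chromosome, chrom blocks kept."""
    order = dict((c, i) for i, c in enumerate(dict.fromkeys(bins["chrom"])))
    key = bins["chrom"].map(order)
    return (
        bins.assign(_k=key)
        .sort_values(["_k", "start"], kind="stable")
        .drop(columns="_k")
        .reset_index(drop=True)
    )


def make_structure(
    coords,
    genomic: Mapping[str, Sequence] | pd.DataFrame | None = None,
    extra: Mapping[str, Sequence] | None = None,
    id: str = "structure",
) -> Structure:
    """Build a :class:`Structure` from a coordinate matrix and columns.

    Parameters
    ----------
    coords : array-like, shape (n, 3)
        XYZ positions, one row per bin.  Must be finite.
    genomic : mapping or DataFrame with ``chrom``, ``start``, ``end``, optional
        Genomic intervals per bin.  When omitted, synthetic 1-bp bins
        ``[i, i+1)`` on chromosome ``"chr?"`` are used.
    extra : mapping of name -> column, optional
        Additional per-bin data columns (numeric or categorical).
    id : str
        Structure identifier.

    Raises
    ------
    InputError
        On shape mismatch between ``coords`` and any column, or reserved
        names used as extra columns.
    ValidationError
        On non-finite coordinates (names the first offending row) or
        invalid genomic intervals.
    """
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise InputError(f"coords must be n x 3, got shape {xyz.shape}")
    n = xyz.shape[0]
    if n < 1:
        raise InputError("structure needs at least one bin")
    bad = np.flatnonzero(~np.isfinite(xyz).all(axis=1))
    if bad.size:
        raise ValidationError(f"non-finite coordinate at row {bad[0]}")

    synthetic = genomic is None
    if synthetic:
        g = pd.DataFrame(
            {
                "chrom": np.repeat(SYNTHETIC_CHROM, n),
                "start": np.arange(n, dtype=np.int64),
                "end": np.arange(1, n + 1, dtype=np.int64),
            }
        )
    else:
        g = pd.DataFrame(genomic).reset_index(drop=True)
        missing = [c for c in ("chrom", "start", "end") if c not in g.columns]
        if missing:
            raise InputError(f"genomic columns missing {missing}")
        if len(g) != n:
            raise InputError(
                f"genomic columns have {len(g)} rows, coords have {n}"
            )
        g = pd.DataFrame(
            {
                "chrom": g["chrom"].astype(str).to_numpy(),
                "start": g["start"].to_numpy(dtype=np.int64),
                "end": g["end"].to_numpy(dtype=np.int64),
            }
        )

    bins = g.assign(x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2])
    if extra:
        for name, col in extra.items():
            if name in RESERVED_COLUMNS:
                raise InputError(f"extra column name {name!r} is reserved")
            if name in bins.columns:
                raise InputError(f"duplicate extra column {name!r}")
            arr = np.asarray(col)
            if arr.shape[0] != n:
                raise InputError(
                    f"extra column {name!r} has {arr.shape[0]} rows, expected {n}"
                )
            bins[name] = arr
    bins = _sorted_per_chrom(bins)

    s = Structure(
        id=id,
        bins=bins,
        resolution=infer_resolution(
            (bins["end"] - bins["start"]).to_numpy()
        ),
        synthetic_coordinates=synthetic,
    )
    problems = validate(s)
    if problems:
        raise ValidationError("; ".join(str(p) for p in problems))
    return s


def validate(s: Structure) -> list[Violation]:
    """Check every bin-table invariant; return violations, never raise.

    An empty list means the structure is valid.  A 0-bin structure (legal
    output of masking) is flagged here rather than rejected elsewhere.
    """
    out: list[Violation] = []
    b = s.bins
    if len(b) == 0:
        out.append(Violation("n>=1", None, "bin table is empty"))
        return out
    for c in RESERVED_COLUMNS:
        if c not in b.columns:
            out.append(Violation("columns", None, f"missing column {c!r}"))
    if out:
        return out

    xyz = b[["x", "y", "z"]].to_numpy(dtype=float)
    for r in np.flatnonzero(~np.isfinite(xyz).all(axis=1)):
        out.append(Violation("finite-xyz", int(r), "non-finite coordinate"))

    start = b["start"].to_numpy()
    end = b["end"].to_numpy()
    for r in np.flatnonzero(end <= start):
        out.append(Violation("end>start", int(r), f"[{start[r]},{end[r]})"))

    chrom = b["chrom"].to_numpy()
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        st, en = start[idx], end[idx]
        for k in np.flatnonzero(np.diff(st) < 0):
            out.append(
                Violation("sorted", int(idx[k + 1]), f"{c}: start decreases")
            )
        # overlap check on the sorted view so one bad sort is one violation
        o = np.argsort(st, kind="stable")
        for k in np.flatnonzero(en[o][:-1] > st[o][1:]):
            out.append(
                Violation(
                    "non-overlap",
                    int(idx[o[k + 1]]),
                    f"{c}: [{st[o][k]},{en[o][k]}) overlaps [{st[o][k+1]},{en[o][k+1]})",
                )
            )

    extras = [c for c in b.columns if c not in RESERVED_COLUMNS]
    seen = set()
    for c in extras:
        if c in seen:
            out.append(Violation("unique-extras", None, f"duplicate column {c!r}"))
        seen.add(c)

    if s.resolution is not None:
        modal = infer_resolution(end - start)
        if modal != s.resolution:
            out.append(
                Violation(
                    "resolution",
                    None,
                    f"stated {s.resolution} != modal width {modal}",
                )
            )
    return out


def rename_chroms(s: Structure, mapping: Mapping[str, str]) -> Structure:
    """Return a structure with chromosome names mapped through ``mapping``.

    Chromosome matching everywhere else is by exact string — no silent
    "chr1" vs "1" aliasing — so renaming is explicit and auditable.
    Names absent from the mapping are kept verbatim (this includes
    haplotype-tagged names like ``"1(pat)"`` from diploid models).
    """
    bins = s.bins.copy()
    bins["chrom"] = bins["chrom"].map(lambda c: mapping.get(c, c))
    bins = _sorted_per_chrom(bins)
    return replace(s, bins=bins)
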