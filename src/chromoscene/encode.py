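"""Grammar-of-graphics layer: view configs and their resolution.

A :class:`ViewConfig` declares how bins become marks: the mark geometry
(``sphere`` or ``box``), a color channel, a scale (radius) channel and
whether genomically consecutive bins are connected by links.  Channels
are either constants or :class:`FieldEncoding`\\ s that map a per-bin
data column — or one of the pseudo-fields ``"coordinate"``
(per-chromosome bin index) and ``"chrom"`` — through a colormap or a
radius range.

:func:`resolve` materializes a config against a structure into a
:class:`ResolvedScene`: concrete per-bin positions, mark types, radii
and RGBA colors, plus link segments — everything an exporter or
renderer needs, with no further defaults to fill in.

Numerical conventions (chosen for bit-reproducibility): interpolation
happens in plain RGB with stops equally spaced on [0, 1]; values
outside the domain are clamped, not rejected; interpolated channels are
rounded half-up to integers in [0, 255].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional, Union

import numpy as np
from matplotlib.colors import to_rgba
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import colormaps
from .core import RESERVED_COLUMNS, Structure

#: Pseudo-fields available to encodings on any structure.
PSEUDO_FIELDS = ("coordinate", "chrom")

RGB = tuple[int, int, int]


class ConfigError(ValueError):
    """Raised for an invalid view config (schema or semantics)."""


class FieldEncoding(BaseModel):
    """Maps a per-bin field through a colormap (color) or range (scale).

    Parameters
    ----------
    field : str
        Column name on the structure, or a pseudo-field: ``"coordinate"``
        (bin index within its chromosome) or ``"chrom"``.
    kind : {"continuous", "categorical"}
        Continuous encodings interpolate; categorical ones cycle a palette
        by order of first appearance.
    colormap : str or list of RGB triples
        For color channels.  A registry name (``"viridis-8"``,
        ``"greys-2"``, ``"category-12"``) or explicit stops.
    range : (rmin, rmax)
        For scale channels: radii at the domain endpoints; rmin must be
        positive (marks need positive radii).
    domain : (lo, hi), optional
        Field values mapped to the channel endpoints; defaults to the
        observed min/max.  Out-of-domain values are clamped.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    field: str
    kind: Literal["continuous", "categorical"] = "continuous"
    colormap: Optional[Union[str, list[RGB]]] = None
    range: Optional[tuple[float, float]] = None
    domain: Optional[tuple[float, float]] = None

    @field_validator("colormap")
    @classmethod
    def _stops_enough(cls, v):
        if isinstance(v, list) and len(v) < 1:
            raise ValueError("colormap needs at least one stop")
        return v

    @model_validator(mode="after")
    def _check(self):
        if self.range is not None:
            rmin, rmax = self.range
            if rmin > rmax:
                raise ValueError(f"range rmin {rmin} > rmax {rmax}")
            if rmin <= 0:
                raise ValueError("range rmin must be positive (radii are)")
        if self.domain is not None:
            lo, hi = self.domain
            if not lo < hi:
                raise ValueError(f"domain needs lo < hi, got [{lo}, {hi}]")
        return self

    def stops(self) -> list[RGB]:
        """Resolve the colormap to explicit stops for this encoding's kind."""
        cm = self.colormap
        if cm is None:
            cm = "category-12" if self.kind == "categorical" else "viridis-8"
        if isinstance(cm, str):
            if self.kind == "categorical":
                return colormaps.get_categorical(cm)
            return colormaps.get_continuous(cm)
        stops = [tuple(int(c) for c in stop) for stop in cm]
        if self.kind == "continuous" and len(stops) < 2:
            raise ConfigError("continuous colormap needs >= 2 stops")
        return stops


class ViewConfig(BaseModel):
    """Declarative visual encoding for one structure.

    Unknown keys are rejected (strict schema) so channel-name typos fail
    loudly instead of silently rendering defaults.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    mark: Literal["sphere", "box"] = "sphere"
    color: Union[FieldEncoding, str] = "#1f77b4"
    scale: Optional[Union[FieldEncoding, float]] = None
    links: bool = False

    @field_validator("color")
    @classmethod
    def _color_parses(cls, v):
        if isinstance(v, str):
            parse_css_color(v)  # raises ConfigError on junk
        return v

    @field_validator("scale")
    @classmethod
    def _scale_positive(cls, v):
        if isinstance(v, (int, float)) and not v > 0:
            raise ValueError(f"constant scale must be > 0, got {v}")
        return v

    @classmethod
    def from_json(cls, text: str) -> "ViewConfig":
        return cls.model_validate_json(text)

    def to_json(self) -> str:
        return self.model_dump_json(exclude_none=True)


@dataclass
class ResolvedScene:
    """Fully materialized visual attributes, ready for export.

    One row per bin: position, mark type, radius and RGBA color, plus
    the id of the owning structure (scenes may concatenate several).
    ``links`` holds one (2, 3) point pair per link segment with a
    matching per-segment ``link_radii`` entry.
    """

    structure_ids: np.ndarray  # (n,) str
    positions: np.ndarray  # (n, 3) float
    marks: np.ndarray  # (n,) str, "sphere" | "box"
    radii: np.ndarray  # (n,) float > 0
    rgba: np.ndarray  # (n, 4) uint8
    links: np.ndarray = dc_field(
        default_factory=lambda: np.empty((0, 2, 3), dtype=float)
    )
    link_radii: np.ndarray = dc_field(
        default_factory=lambda: np.empty((0,), dtype=float)
    )

    def __post_init__(self):
        n = len(self.positions)
        if not (
            len(self.structure_ids) == len(self.marks) == len(self.radii)
            == len(self.rgba) == n
        ):
            raise ConfigError("resolved channels disagree on bin count")
        if n and not (self.radii > 0).all():
            raise ConfigError("resolved radii must all be positive")
        self.rgba = np.asarray(self.rgba, dtype=np.uint8)
        if len(self.links) != len(self.link_radii):
            raise ConfigError("links and link_radii disagree on count")

    @property
    def n_marks(self) -> int:
        return len(self.positions)

    @property
    def n_links(self) -> int:
        return len(self.links)

    @staticmethod
    def concatenate(scenes: list["ResolvedScene"]) -> "ResolvedScene":
        return ResolvedScene(
            structure_ids=np.concatenate([s.structure_ids for s in scenes]),
            positions=np.concatenate([s.positions for s in scenes]),
            marks=np.concatenate([s.marks for s in scenes]),
            radii=np.concatenate([s.radii for s in scenes]),
            rgba=np.concatenate([s.rgba for s in scenes]),
            links=np.concatenate(
                [s.links for s in scenes]
            ) if any(s.n_links for s in scenes) else np.empty((0, 2, 3)),
            link_radii=np.concatenate([s.link_radii for s in scenes]),
        )


# ---------------------------------------------------------------------
# Channel mapping primitives


def parse_css_color(color: str) -> np.ndarray:
    """CSS color string (hex or named) -> RGBA uint8 (alpha 255 unless given)."""
    try:
        r, g, b, a = to_rgba(color)
    except ValueError:
        raise ConfigError(f"cannot parse color {color!r}") from None
    return _round_half_up(np.array([r, g, b, a]) * 255.0)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(np.asarray(x, dtype=float) + 0.5), 0, 255).astype(
        np.uint8
    )


def _domain(values: np.ndarray, enc: FieldEncoding) -> tuple[float, float]:
    if enc.domain is not None:
        return enc.domain
    return float(np.min(values)), float(np.max(values))


def _normalize(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def map_color(values, enc: FieldEncoding) -> np.ndarray:
    """Continuous color mapping: values -> (n, 4) RGBA uint8.

    ``t = clamp((v - lo) / (hi - lo), 0, 1)`` indexes a piecewise-linear
    ramp through the colormap stops, equally spaced on [0, 1]; domain
    endpoints hit the first/last stop exactly.  A degenerate domain
    (all values equal, no explicit domain) maps everything to the first
    stop with a warning.
    """
    v = np.asarray(values, dtype=float)
    stops = np.asarray(enc.stops(), dtype=float)
    lo, hi = _domain(v, enc)
    out = np.empty((len(v), 4), dtype=np.uint8)
    out[:, 3] = 255
    if lo == hi:
        warnings.warn(
            f"degenerate color domain [{lo}, {hi}]; mapping all bins to the "
            "first stop",
            stacklevel=2,
        )
        out[:, :3] = _round_half_up(np.tile(stops[0], (len(v), 1)))
        return out
    t = _normalize(v, lo, hi)
    pos = t * (len(stops) - 1)
    i = np.minimum(pos.astype(int), len(stops) - 2)
    frac = (pos - i)[:, None]
    rgb = stops[i] * (1.0 - frac) + stops[i + 1] * frac
    out[:, :3] = _round_half_up(rgb)
    return out


def map_scale(values, enc: FieldEncoding) -> np.ndarray:
    """Scale mapping: values -> radii in ``[rmin, rmax]``.

    ``radius = rmin + clamp((v - lo)/(hi - lo), 0, 1) * (rmax - rmin)``;
    a degenerate domain collapses every radius to rmin.
    """
    if enc.range is None:
        raise ConfigError(
            f"scale encoding on field {enc.field!r} needs a [rmin, rmax] range"
        )
    rmin, rmax = enc.range
    v = np.asarray(values, dtype=float)
    lo, hi = _domain(v, enc)
    if lo == hi:
        return np.full(len(v), float(rmin))
    return rmin + _normalize(v, lo, hi) * (rmax - rmin)


def map_categorical(values, palette) -> np.ndarray:
    """Categorical color mapping: labels -> (n, 4) RGBA uint8.

    Categories are ordered by first appearance in ``values``; the
    palette is cycled (``palette[index % len(palette)]``).
    """
    palette = list(palette)
    if not palette:
        raise ConfigError("categorical palette must have >= 1 colors")
    labels = list(values)
    order = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
    out = np.empty((len(labels), 4), dtype=np.uint8)
    out[:, 3] = 255
    pal = np.asarray(palette, dtype=np.uint8)
    idx = np.array([order[lab] % len(pal) for lab in labels], dtype=int)
    if len(labels):
        out[:, :3] = pal[idx]
    return out


def default_radius(s: Structure) -> float:
    """Half the median distance between genomically consecutive bins.

    Gives marks that touch but rarely interpenetrate along the fiber.
    Falls back to 1.0 when no consecutive pair exists (single-bin
    structures).
    """
    xyz = s.coords()
    chrom = s.bins["chrom"].to_numpy()
    dists = []
    for c in dict.fromkeys(chrom):
        idx = np.flatnonzero(chrom == c)
        if len(idx) > 1:
            d = np.linalg.norm(np.diff(xyz[idx], axis=0), axis=1)
            dists.append(d)
    if not dists:
        return 1.0
    return 0.5 * float(np.median(np.concatenate(dists)))


# ---------------------------------------------------------------------
# Config validation and resolution


def field_values(s: Structure, name: str) -> np.ndarray:
    """Per-bin values of a column or pseudo-field of the structure."""
    if name == "coordinate":
        chrom = s.bins["chrom"].to_numpy()
        out = np.empty(len(chrom), dtype=float)
        for c in dict.fromkeys(chrom):
            idx = np.flatnonzero(chrom == c)
            out[idx] = np.arange(len(idx))
        return out
    if name == "chrom":
        return s.bins["chrom"].to_numpy()
    if name in s.bins.columns:
        return s.bins[name].to_numpy()
    raise ConfigError(
        f"field {name!r} not on structure {s.id!r}; available: "
        f"{list(s.bins.columns) + list(PSEUDO_FIELDS)}"
    )


def validate_config(vc: ViewConfig, s: Structure) -> None:
    """Raise :class:`ConfigError` unless ``vc`` is resolvable against ``s``."""
    for channel in (vc.color, vc.scale):
        if isinstance(channel, FieldEncoding):
            field_values(s, channel.field)  # raises if absent
            channel.stops()  # raises on unknown colormap name
    if isinstance(vc.scale, FieldEncoding) and vc.scale.range is None:
        raise ConfigError("scale encoding needs a [rmin, rmax] range")


def _link_pairs(s: Structure) -> np.ndarray:
    """Index pairs (i, i+1) of genomically adjacent bins per chromosome.

    Adjacency means ``end_i == start_{i+1}``; a gap in the model breaks
    the chain, and no link ever spans chromosomes.
    """
    chrom = s.bins["chrom"].to_numpy()
    start = s.bins["start"].to_numpy()
    end = s.bins["end"].to_numpy()
    same = chrom[:-1] == chrom[1:]
    adjacent = end[:-1] == start[1:]
    i = np.flatnonzero(same & adjacent)
    return np.stack([i, i + 1], axis=1) if i.size else np.empty((0, 2), int)


def resolve(s: Structure, vc: ViewConfig) -> ResolvedScene:
    """Materialize a view config against a structure.

    Constant channels broadcast over bins; field channels are mapped via
    :func:`map_color` / :func:`map_scale` / :func:`map_categorical`.
    Resolution is deterministic: equal inputs give byte-identical
    output.
    """
    validate_config(vc, s)
    n = s.n_bins
    xyz = s.coords()

    if isinstance(vc.color, FieldEncoding):
        values = field_values(s, vc.color.field)
        if vc.color.kind == "categorical":
            rgba = map_categorical(values, vc.color.stops())
        else:
            rgba = map_color(values, vc.color)
    else:
        rgba = np.tile(parse_css_color(vc.color), (n, 1))

    if vc.scale is None:
        radii = np.full(n, default_radius(s))
    elif isinstance(vc.scale, FieldEncoding):
        radii = map_scale(field_values(s, vc.scale.field), vc.scale)
    else:
        radii = np.full(n, float(vc.scale))

    if vc.links:
        pairs = _link_pairs(s)
        links = xyz[pairs] if len(pairs) else np.empty((0, 2, 3))
        link_radii = np.full(len(pairs), 0.25 * default_radius(s))
    else:
        links = np.empty((0, 2, 3))
        link_radii = np.empty((0,))

    return ResolvedScene(
        structure_ids=np.full(n, s.id, dtype=object),
        positions=xyz,
        marks=np.full(n, vc.mark, dtype=object),
        radii=radii,
        rgba=rgba,
        links=links,
        link_radii=link_radii,
    )


def resolve_scene(scene) -> ResolvedScene:
    """Resolve every (structure, view config) pair and concatenate."""
    if not scene.pairs:
        raise ConfigError("scene is empty")
    return ResolvedScene.concatenate(
        [resolve(s, vc) for s, vc in scene.pairs]
    )
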