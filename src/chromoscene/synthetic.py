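"""Simulated genome structures and annotations with planted structure.

The generator emulates the gross geometry of published single-cell 3D
genome models: each chromosome is a confined random walk — fixed step
length, rejection-sampled to stay inside a spherical "nucleus" — with
bins at a fixed genomic resolution.  It is a fixture generator, not a
chromatin mechanics model: there is no self-avoidance, no territory
formation, no Hi-C contact generation.

Annotations come with a planted radial density gradient: per-bin
feature counts are Poisson with mean ``lambda * exp(-gamma * d / R)``,
where ``d`` is the bin's distance to the structure centroid.  With
``gamma > 0`` feature-dense bins concentrate in the interior — the
planted signal that aggregation + radial-position analysis must
recover; with ``gamma = 0`` density is uniform and no radial trend
exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import radial_position
from .core import Structure, make_structure

#: Baseline Poisson mean for features per bin.
FEATURE_RATE = 2.0

_MAX_REJECT = 10_000


class SimulationError(RuntimeError):
    """Raised when rejection sampling cannot keep the walk confined."""


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated structure + annotation set.

    Parameters
    ----------
    n_chroms : int
        Number of chromosomes ("chr1" .. "chrN").
    bins_per_chrom : int
        Bins (walk steps + 1) per chromosome; >= 2.
    resolution : int
        Genomic bin width in bp.
    step_length : float
        Spatial distance between consecutive bins (model units).
        Must satisfy ``step_length < 2 * confinement_radius`` or no
        confined step exists.
    confinement_radius : float
        Radius R of the spherical nucleus; all points stay inside.
    seed : int
        Seed for all randomness; equal seeds give identical output.
    density_gradient : float
        gamma >= 0; feature-density decay per unit radial distance
        (in units of R).  0 means uniform density.
    """

    n_chroms: int = 4
    bins_per_chrom: int = 100
    resolution: int = 100_000
    step_length: float = 1.0
    confinement_radius: float = 5.0
    seed: int = 42
    density_gradient: float = 0.0

    def __post_init__(self):
        if self.n_chroms < 1 or self.bins_per_chrom < 2:
            raise ValueError("need n_chroms >= 1 and bins_per_chrom >= 2")
        if self.resolution < 1:
            raise ValueError("resolution must be a positive bp count")
        if not 0 < self.step_length < 2 * self.confinement_radius:
            raise ValueError("need 0 < step_length < 2 * confinement_radius")
        if self.density_gradient < 0:
            raise ValueError("density_gradient must be >= 0")


def _uniform_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:  # rejection from the bounding cube; P(accept) ~ 0.52
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) <= radius:
            return p


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_structure(spec: SimSpec, id: str = "sim") -> Structure:
    """Confined fixed-step random walk per chromosome.

    Each chromosome starts uniformly inside the ball of radius R; each
    step has exactly ``step_length`` and is re-drawn (up to 10^4 times)
    if its endpoint would leave the ball.
    """
    rng = np.random.default_rng(spec.seed)
    R, ell = spec.confinement_radius, spec.step_length
    chroms, starts, coords = [], [], []
    for c in range(spec.n_chroms):
        name = f"chr{c + 1}"
        p = _uniform_in_ball(rng, R)
        pts = [p]
        for _ in range(spec.bins_per_chrom - 1):
            for _attempt in range(_MAX_REJECT):
                q = pts[-1] + ell * _unit_vector(rng)
                if np.linalg.norm(q) <= R:
                    pts.append(q)
                    break
            else:
                raise SimulationError(
                    f"could not confine step on {name} after {_MAX_REJECT} tries"
                )
        coords.append(np.asarray(pts))
        chroms.extend([name] * spec.bins_per_chrom)
        starts.extend(
            int(i) * spec.resolution for i in range(spec.bins_per_chrom)
        )
    starts = np.asarray(starts, dtype=np.int64)
    return make_structure(
        np.concatenate(coords),
        genomic={
            "chrom": chroms,
            "start": starts,
            "end": starts + spec.resolution,
        },
        id=id,
    )


def simulate_features(s: Structure, spec: SimSpec) -> pd.DataFrame:
    """Unit-length features with the planted radial density gradient.

    Per bin, a Poisson(lambda * exp(-gamma * d / R)) number of features
    (lambda = 2) is placed as 1-bp intervals uniformly inside the bin.
    Deterministic given ``spec.seed`` (a stream separate from the walk,
    so structure and features are independently reproducible).
    """
    rng = np.random.default_rng([spec.seed, 1])
    radial = radial_position(s, "_radial").bins["_radial"].to_numpy()
    mean = FEATURE_RATE * np.exp(
        -spec.density_gradient * radial / spec.confinement_radius
    )
    counts = rng.poisson(mean)
    rows = []
    k = 0
    for (_, bin_row), c in zip(s.bins.iterrows(), counts):
        if c == 0:
            continue
        starts = rng.integers(bin_row["start"], bin_row["end"], size=c)
        for st in np.sort(starts):
            rows.append(
                (bin_row["chrom"], int(st), int(st) + 1, f"feat{k}", None, ".")
            )
            k += 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def write_gtf(features: pd.DataFrame, path, feature_type: str = "gene") -> None:
    """Write a feature table as a minimal GTF (1-based inclusive).

    The inverse of :func:`chromoscene.io.read_gtf` for simulated
    annotations: internal 0-based half-open ``[start, end)`` becomes
    printed ``start+1 .. end``.
    """
    with open(path, "w", newline="\n") as fh:
        for row in features.itertuples(index=False):
            score = "." if row.score is None or pd.isna(row.score) else str(row.score)
            strand = row.strand if row.strand in ("+", "-") else "."
            name = row.name if row.name else "unnamed"
            fh.write(
                f"{row.chrom}\tsim\t{feature_type}\t{row.start + 1}\t{row.end}"
                f"\t{score}\t{strand}\t.\tgene_id \"{name}\";\n"
            )


def write_3dg(s: Structure, path) -> None:
    """Write a structure in ``.3dg`` form (chrom, bin start, x, y, z)."""
    with open(path, "w", newline="\n") as fh:
        for row in s.bins.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.x:.9g}\t{row.y:.9g}"
                f"\t{row.z:.9g}\n"
            )
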