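# Methods

## Data model

A 3D genome structure is a columnar bin table with six reserved
columns — `chrom` (string), `start`/`end` (integer bp), `x`/`y`/`z`
(finite reals in arbitrary model units) — plus any number of named
per-bin data columns. Invariants enforced by `validate`: every column
has the same row count, `end > start` per bin, bins are sorted and
pairwise non-overlapping within a chromosome, coordinates are finite,
and extra column names are unique and non-reserved. `validate` returns
violation descriptors (invariant name + row) rather than raising, so a
broken file can be diagnosed in one pass.

**Coordinate convention.** Genomic coordinates are 0-based half-open
everywhere inside the package; readers convert on ingest (GTF's
1-based inclusive `start..end` becomes `[start−1, end)`; BED passes
through unchanged). Half-open semantics are load-bearing: a bin
`[0, 100)` and an interval `[100, 200)` share no base pair and
therefore never select or aggregate.

**Structures without genomic coordinates.** Many simulation outputs
are bare point lists. These get synthetic 1-bp bins `[i, i+1)` on the
pseudo-chromosome `"chr?"`, which keeps every downstream operation
total (range selection on `"chr?"` addresses bins by index).

**Resolution** is the modal bin width; ties break toward the smallest
width, which keeps any later binning conservative (a smaller bin never
silently swallows annotation mass from its neighbor). After masking,
resolution is re-inferred from the surviving bins.

**Chromosome names** are matched as exact strings — no `chr1` ↔ `1`
aliasing, because silent aliasing corrupts selections; `rename_chroms`
makes the mapping explicit. Haplotype-tagged names from diploid models
(`"1(pat)"`) are kept verbatim.

## Selection

Three operators produce boolean `BinMask`s with a provenance string
recording the generating query:

- **Ranges** — a bin is selected when its interval overlaps any query
  interval by ≥ 1 bp (no minimum-overlap fraction). The query grammar
  is `chrom[:start-end]`, comma-separated, with thousands-commas and
  k/M/G suffixes; a bare chromosome selects it whole. A query
  chromosome absent from the structure yields an empty selection plus
  a warning rather than an error, so one query can be mapped across an
  ensemble of structures.
- **Spheres** — closed ball (`distance ≤ r`). A genomic-locus center
  resolves to the stored point of the bin containing the locus; no
  interpolation model is assumed.
- **Cutting planes** — half-space keep on the signed value
  `v = n̂·p − offset`, with ties (`v = 0`) assigned to the positive
  side so the two sides of any plane partition the structure exactly.
  The common finite-thickness cross-section is provided as `slab`, the
  AND of two opposing half-spaces, rather than as a primitive.

Masks form a boolean algebra (`and`, `or`, `and-not`, `invert`) whose
provenance records the expression tree. All predicates are linear
scans: at desk scale (10³–10⁵ bins) a spatial index would add
complexity without measurable benefit.

## Encoding grammar

A `ViewConfig` declares mark type (`sphere`/`box`), a color channel, a
scale channel and a links flag. Channels are constants (CSS color
string; positive radius) or field encodings over a data column or the
pseudo-fields `coordinate` (per-chromosome bin index) and `chrom`.
The JSON schema is strict — unknown keys are rejected — so channel
typos fail loudly.

Numerical conventions, chosen for bit-reproducibility:

- normalize `t = clamp((v − lo)/(hi − lo), 0, 1)`, domain defaulting
  to the observed min/max; out-of-domain values clamp rather than
  error (robust for exploratory use);
- continuous color interpolates piecewise-linearly between stops
  equally spaced on [0, 1], in plain RGB (perceptual spaces are
  deferred; plain RGB is exactly reproducible and oracle-friendly);
  domain endpoints therefore hit the first/last stop *exactly*;
- interpolated channels round half-up to integers in [0, 255];
- scale maps to `rmin + t·(rmax − rmin)` with `rmin > 0` required;
- a degenerate domain (all values equal) maps color to the first stop
  with a warning, scale to `rmin`;
- categorical colors follow first-appearance order and cycle the
  palette modulo its length.

Built-in maps (`viridis-8`, `greys-2`, the 12-color `category-12`
palette) are embedded as RGB constants in `colormaps.py`.

When no scale channel is given, marks get the **default radius**: half
the median distance between genomically consecutive bins on the same
chromosome (so marks touch along the fiber without gross overlap),
falling back to 1.0 for single-bin structures. Link segments connect
bins that are genomically adjacent (`end_i == start_{i+1}`) within a
chromosome — a gap in the model breaks the chain and no link spans
chromosomes — and are given radius 0.25 × the default radius.

A useful consequence of the clamp mapping: with a scale encoding on,
the total mark volume never exceeds the constant-`rmax` volume, so
scaling doubles as an occlusion-reduction device.

## Aggregation

`bin_features` adds a numeric column per bin from an interval table:
`count` (features with non-empty half-open intersection), `coverage`
(length of the union of clipped intersections divided by bin width, in
[0, 1]; overlapping features are unioned, not double-counted) and
`score_mean` (mean score of overlapping features; empty bins get 0
plus a companion `<col>_missing` flag). Strand is ignored — density is
aggregated irrespective of orientation — and bins with no features get
0, not NaN, so the column is directly encodable. Both `count` and
`coverage` are provided because "gene density" is used in both senses;
they differ when genes are long relative to bins.

`radial_position` is the Euclidean distance of each bin to the
unweighted centroid of all bin points; interior enrichment of a signal
shows up as a negative correlation between the signal and this
statistic.

## Scene export

Spheres tessellate as icospheres (uniform triangles; `20·4^s` faces at
subdivision `s`, default 2, refused above 5 as a mesh-size guard),
boxes as 12-triangle cuboids with edge `2·radius`, links as 8-sided
cylinders. Vertex colors carry the mark RGBA. Ascii PLY is the
colored-mesh format (diff-able, trivially round-tripped); OBJ is
geometry-only, as the format has no per-vertex colors. `scene_bounds`
is computed analytically (point bounding box inflated by the maximum
radius) because tessellation vertices of a low-subdivision icosphere
lie strictly inside the circumscribed sphere and would understate the
true bounds.

The PNG preview projects orthographically along a view direction and
draws marks as filled discs back-to-front by projected depth
(painter's algorithm; ties broken by stable sort order). Rasterization
is pure array arithmetic into a framebuffer and the PNG encoder embeds
no timestamps, so identical inputs give byte-identical files.

## Synthetic structures

`simulate_structure` generates one confined random walk per
chromosome: a uniformly drawn start inside the ball of radius *R*,
fixed step length ℓ with uniformly random direction, and rejection of
steps leaving the ball (bounded at 10⁴ retries per step). Defaults:
4 chromosomes × 100 bins at 100 kb, ℓ = 1, R = 5 — i.e. chains long
enough to explore the volume, with ℓ/R small enough that confinement
matters. The walk is *not* self-avoiding and has no chromosome
territories, loop extrusion or contact structure: it emulates only the
geometry needed to exercise selection, aggregation, encoding and
export. Passing tests therefore demonstrate correctness of those
operations, not biological realism of any structure.

`simulate_features` plants a radial density gradient: per-bin feature
counts are Poisson with mean `λ·exp(−γ·d/R)` (λ = 2, `d` the bin's
radial position), placed as 1-bp intervals uniformly inside the bin.
γ = 0 gives uniform density (the null); larger γ concentrates features
in the interior, giving a recoverable negative count-vs-radial
correlation. The feature stream is seeded separately from the walk so
structure and annotation are independently reproducible. The committed
example fixture uses seed 42 with γ = 2 (γ = 5 at the fixture's small
size yields too few features to illustrate the workflow).

## Problem sizes and statistical checks

Oracle-equivalence checks run on 100 random structures of up to 1000
bins against deliberately naive per-element scans. Sign-recovery rates
use 100 replicates of 2-chromosome × 60-bin structures (seconds of
runtime; a decile-based depletion check uses the generator's 4 × 100
defaults, since an 8-bin decile is too noisy). The γ = 0 null is
asserted as a negative-sign rate in [0.30, 0.70] — ±4σ around the fair
coin over 100 replicates. The Monte-Carlo recovery of the planted
Poisson means uses 10³ replicates, where the expected mean absolute
error (≈ 0.8·√(λ/10³)) is comfortably below the 0.06 assertion.

## Known limitations

- GFF3 and PDB-style structure files are unsupported (documented
  rather than misparsed); no bigWig/bigBed, no network fetching.
- Structures in a scene are treated as independent coordinate frames;
  no alignment is attempted.
- No opacity/visibility channels, per-mark orientation or text labels;
  cube edge = 2 × radius is this package's convention, as no standard
  exists.
- Interpolation in RGB can pass through desaturated midpoints for
  widely separated hues; use more stops if that matters.
- The preview renderer draws flat discs — no lighting, no
  perspective — and is meant for orientation checks, not figures.
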