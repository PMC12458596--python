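"""Genomic-range and spatial selections against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromoscene import (
    PlaneSpec,
    SphereSpec,
    apply_mask,
    combine,
    invert,
    make_structure,
    parse_range_query,
    select_by_ranges,
    select_cutting_plane,
    select_sphere,
    slab,
)
from chromoscene.core import InputError, as_rangeset
from chromoscene.select import RangeSyntaxError, locus_point
from conftest import random_structure


# ---------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive)


def overlap_oracle(s, ranges):
    out = np.zeros(s.n_bins, dtype=bool)
    for i, bin_row in s.bins.iterrows():
        for q in ranges.itertuples(index=False):
            if (
                bin_row["chrom"] == q.chrom
                and bin_row["start"] < q.end
                and q.start < bin_row["end"]
            ):
                out[i] = True
    return out


def sphere_oracle(s, center, radius):
    out = np.zeros(s.n_bins, dtype=bool)
    for i, p in enumerate(s.coords()):
        if sum((a - b) ** 2 for a, b in zip(p, center)) ** 0.5 <= radius:
            out[i] = True
    return out


def plane_oracle(s, normal, offset, side):
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    out = np.zeros(s.n_bins, dtype=bool)
    for i, p in enumerate(s.coords()):
        v = float(np.dot(n, p)) - offset
        out[i] = (v >= 0) if side == "positive" else (v < 0)
    return out


# ---------------------------------------------------------------------


class TestRangeQueryParsing:
    @pytest.mark.parametrize(
        "query, expected",
        [
            ("chr1:0-2000000", [("chr1", 0, 2_000_000)]),
            ("chr1:0-2,000,000", [("chr1", 0, 2_000_000)]),
            ("chr1:0-2M", [("chr1", 0, 2_000_000)]),
            ("chr1:500k-1.5M", [("chr1", 500_000, 1_500_000)]),
            ("chr1:1G-2G", [("chr1", 10**9, 2 * 10**9)]),
            (
                "chr1:0-100, chr2:50-150",
                [("chr1", 0, 100), ("chr2", 50, 150)],
            ),
        ],
    )
    def test_grammar(self, query, expected):
        parsed = parse_range_query(query)
        assert list(parsed.itertuples(index=False, name=None)) == expected

    def test_bare_chromosome_selects_everything(self, chr1_structure):
        assert select_by_ranges(chr1_structure, "chr1").values.all()

    @pytest.mark.parametrize(
        "bad", ["", "chr1:200-100", "chr1:abc-def", "chr1:0-1.7"]
    )
    def test_syntax_errors(self, bad):
        with pytest.raises(RangeSyntaxError):
            parse_range_query(bad)


class TestSelectByRanges:
    def test_both_bins_overlap(self, chr1_structure):
        m = select_by_ranges(chr1_structure, "chr1:50-150")
        assert list(m.values) == [True, True, False, False, False]

    def test_half_open_touching_does_not_select(self):
        s = make_structure(
            [[0, 0, 0]],
            genomic={"chrom": ["chr1"], "start": [0], "end": [100]},
        )
        assert not select_by_ranges(s, "chr1:100-200").values.any()

    def test_absent_chromosome_warns_empty(self, chr1_structure):
        with pytest.warns(UserWarning, match="chrX"):
            m = select_by_ranges(chr1_structure, "chrX:0-100")
        assert not m.values.any()

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            s = random_structure(rng, n_chroms=3, bins_per_chrom=40)
            ranges = as_rangeset(
                [
                    (
                        f"chr{rng.integers(1, 5)}",
                        int(lo := rng.integers(0, 3900)),
                        int(lo + rng.integers(1, 800)),
                    )
                    for _ in range(10)
                ]
            )
            got = select_by_ranges(s, ranges).values
            assert np.array_equal(got, overlap_oracle(s, ranges))

    def test_split_interval_invariance(self, rng):
        """[a, c) selects the same bins as [a, b) OR [b, c)."""
        s = random_structure(rng, n_chroms=1, bins_per_chrom=60)
        whole = select_by_ranges(s, as_rangeset([("chr1", 500, 4500)]))
        split = select_by_ranges(
            s, as_rangeset([("chr1", 500, 2000), ("chr1", 2000, 4500)])
        )
        assert np.array_equal(whole.values, split.values)

    def test_same_query_same_binning_same_pattern(self, rng):
        """One RangeSet applied across equally binned structures."""
        a = random_structure(rng, id="a")
        b = random_structure(rng, id="b")  # same binning, other coords
        q = as_rangeset([("chr1", 300, 1200), ("chr2", 0, 700)])
        assert np.array_equal(
            select_by_ranges(a, q).values, select_by_ranges(b, q).values
        )


class TestSelectSphere:
    def test_closed_ball_boundary(self):
        s = make_structure([[0.5, 0, 0], [1.0, 0, 0], [1.5, 0, 0]])
        m = select_sphere(s, SphereSpec(center=(0, 0, 0), radius=1.0))
        assert list(m.values) == [True, True, False]

    def test_huge_radius_selects_all(self, rng):
        s = random_structure(rng)
        m = select_sphere(s, SphereSpec(center=(0, 0, 0), radius=1e12))
        assert m.values.all()

    def test_genomic_locus_center(self, chr1_structure):
        m = select_sphere(
            chr1_structure, SphereSpec(center=("chr1", 250), radius=1.0)
        )
        # bin [200,300) sits at x=2; neighbors at x=1 and x=3 are inside
        assert list(m.values) == [False, True, True, True, False]

    def test_uncovered_locus_raises(self, chr1_structure):
        with pytest.raises(LookupError, match="chr1:9999"):
            locus_point(chr1_structure, "chr1", 9999)

    def test_matches_brute_force(self, rng):
        s = random_structure(rng, n_chroms=1, bins_per_chrom=500)
        for _ in range(20):
            center = rng.normal(size=3)
            radius = float(rng.uniform(0.1, 3.0))
            got = select_sphere(
                s, SphereSpec(center=tuple(center), radius=radius)
            ).values
            assert np.array_equal(got, sphere_oracle(s, center, radius))

    def test_radius_monotonicity(self, rng):
        s = random_structure(rng)
        small = select_sphere(s, SphereSpec(center=(0, 0, 0), radius=0.5))
        big = select_sphere(s, SphereSpec(center=(0, 0, 0), radius=2.0))
        assert (big.values | ~small.values).all()  # small => big


class TestCuttingPlane:
    def test_keeps_positive_x(self, rng):
        s = random_structure(rng)
        m = select_cutting_plane(s, PlaneSpec(normal=(1, 0, 0)))
        assert np.array_equal(m.values, s.coords()[:, 0] >= 0)

    def test_two_sides_partition(self, rng):
        s = random_structure(rng)
        spec = PlaneSpec(normal=(1, 1, 1), offset=0.3)
        pos = select_cutting_plane(s, spec)
        neg = select_cutting_plane(
            s, PlaneSpec(normal=(1, 1, 1), offset=0.3, keep_side="negative")
        )
        assert (pos.values ^ neg.values).all()

    def test_matches_brute_force(self, rng):
        s = random_structure(rng, n_chroms=1, bins_per_chrom=300)
        for _ in range(20):
            normal = tuple(rng.normal(size=3))
            offset = float(rng.normal())
            got = select_cutting_plane(
                s, PlaneSpec(normal=normal, offset=offset)
            ).values
            assert np.array_equal(
                got, plane_oracle(s, normal, offset, "positive")
            )

    def test_zero_normal_rejected(self):
        with pytest.raises(InputError):
            PlaneSpec(normal=(0, 0, 0))

    def test_slab_is_two_plane_intersection(self, rng):
        s = random_structure(rng)
        m = slab(s, (0, 0, 1), center_offset=0.0, thickness=1.0)
        z = s.coords()[:, 2]
        assert np.array_equal(m.values, (z >= -0.5) & (z < 0.5))


class TestMaskAlgebra:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_boolean_laws(self, seed):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, n_chroms=1, bins_per_chrom=30)
        a = select_cutting_plane(s, PlaneSpec(normal=tuple(rng.normal(size=3))))
        b = select_sphere(
            s, SphereSpec(center=tuple(rng.normal(size=3)), radius=1.0)
        )
        assert not combine(a, invert(a), "and").values.any()
        assert combine(a, invert(a), "or").values.all()
        # De Morgan
        assert np.array_equal(
            invert(combine(a, b, "and")).values,
            combine(invert(a), invert(b), "or").values,
        )
        assert np.array_equal(
            combine(a, b, "and-not").values, (a.values & ~b.values)
        )

    def test_length_mismatch_rejected(self, rng, chr1_structure):
        s = random_structure(rng)
        a = select_cutting_plane(s, PlaneSpec(normal=(1, 0, 0)))
        b = select_cutting_plane(chr1_structure, PlaneSpec(normal=(1, 0, 0)))
        with pytest.raises(InputError):
            combine(a, b, "and")

    def test_provenance_records_expression(self, chr1_structure):
        a = select_by_ranges(chr1_structure, "chr1:0-100")
        expr = combine(invert(a), a, "or")
        assert "NOT" in expr.provenance and "OR" in expr.provenance


class TestApplyMask:
    def test_identity_and_empty(self, chr1_structure):
        all_true = select_by_ranges(chr1_structure, "chr1")
        same = apply_mask(chr1_structure, all_true)
        assert same.bins.equals(chr1_structure.bins)
        none = apply_mask(chr1_structure, invert(all_true))
        assert none.n_bins == 0 and none.resolution is None

    def test_idempotent_and_extras_carried(self, rng):
        s = random_structure(rng)
        s.bins["gc"] = rng.uniform(size=s.n_bins)
        m = select_cutting_plane(s, PlaneSpec(normal=(0, 1, 0)))
        once = apply_mask(s, m)
        again = apply_mask(once, select_by_ranges(once, "chr1,chr2"))
        assert once.bins.equals(again.bins)
        assert "gc" in once.bins.columns

    def test_resolution_reinferred(self, rng):
        s = make_structure(
            rng.normal(size=(3, 3)),
            genomic={"chrom": ["chr1"] * 3, "start": [0, 100, 200],
                     "end": [100, 200, 250]},
        )
        assert s.resolution == 100
        m = select_by_ranges(s, "chr1:100-250")
        assert apply_mask(s, m).resolution == 50

    def test_foreign_mask_rejected(self, rng, chr1_structure):
        s = random_structure(rng)
        m = select_cutting_plane(s, PlaneSpec(normal=(1, 0, 0)))
        with pytest.raises(InputError):
            apply_mask(chr1_structure, m)
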