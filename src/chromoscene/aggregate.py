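"""Aggregation of interval annotations into structure bins.

The canonical workflow: load gene annotations from a GTF, count how
many genes overlap each bin of the structure (bins at the structure's
resolution), and encode that density as color and/or mark scale.  Three
aggregation modes are provided because "gene density" can mean either a
feature count or a covered fraction of the bin, and scored features
(e.g. BED score) support a mean.

Also provides the radial-position statistic — distance of each bin to
the centroid of the structure — which is what claims like "gene-rich
regions concentrate in the interior" quantify.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .core import InputError, RESERVED_COLUMNS, Structure, ValidationError

AGGREGATION_MODES = ("count", "coverage", "score_mean")


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length of the union of half-open intervals (sweep over sorted)."""
    order = np.argsort(starts, kind="stable")
    total = 0
    cur_s = cur_e = None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return int(total)


def bin_features(
    s: Structure,
    features: pd.DataFrame,
    mode: str = "count",
    out_column: str = "density",
) -> Structure:
    """Aggregate a feature table into the bins of a structure.

    Parameters
    ----------
    s : Structure
    features : DataFrame
        Feature table with ``chrom, start, end`` (0-based half-open) and,
        for ``score_mean``, a numeric ``score`` column.  Strand is
        ignored: density is aggregated irrespective of orientation.
    mode : {"count", "coverage", "score_mean"}
        * ``count`` — number of features whose half-open intersection
          with the bin is non-empty (a feature touching the bin boundary
          does not count);
        * ``coverage`` — length of the union of the clipped feature
          intervals divided by the bin width, in [0, 1];
        * ``score_mean`` — mean score over overlapping features; bins
          with no overlapping feature get 0 and are flagged in a
          companion boolean column ``<out_column>_missing``.
    out_column : str
        Name of the added numeric column; must not be reserved or
        already present.

    Returns a new Structure; the input is left untouched.  Bins with no
    features get 0 (not NaN) for count/coverage so the column is
    directly encodable.
    """
    if mode not in AGGREGATION_MODES:
        raise InputError(f"mode must be one of {AGGREGATION_MODES}, got {mode!r}")
    if out_column in RESERVED_COLUMNS:
        raise InputError(f"out_column {out_column!r} is a reserved name")
    if out_column in s.bins.columns:
        raise InputError(f"column {out_column!r} already on structure {s.id!r}")
    if mode == "score_mean" and "score" not in features.columns:
        raise InputError("score_mean needs a 'score' column on the features")

    f_chrom = features["chrom"].astype(str).to_numpy()
    f_start = features["start"].to_numpy(dtype=np.int64)
    f_end = features["end"].to_numpy(dtype=np.int64)
    if np.any(f_end <= f_start):
        raise ValidationError("feature table has rows with end <= start")
    scores = (
        features["score"].to_numpy(dtype=float)
        if "score" in features.columns
        else None
    )

    bins = s.bins
    b_chrom = bins["chrom"].to_numpy()
    b_start = bins["start"].to_numpy()
    b_end = bins["end"].to_numpy()
    n = len(bins)

    values = np.zeros(n, dtype=float)
    missing = np.zeros(n, dtype=bool)

    for c in dict.fromkeys(b_chrom):
        fsel = f_chrom == c
        fs, fe = f_start[fsel], f_end[fsel]
        sc = scores[fsel] if scores is not None else None
        bidx = np.flatnonzero(b_chrom == c)
        if fs.size == 0:
            missing[bidx] = True
            continue
        for i in bidx:
            # half-open overlap: feature ∩ bin non-empty
            hit = (fs < b_end[i]) & (fe > b_start[i])
            k = int(hit.sum())
            if mode == "count":
                values[i] = k
            elif mode == "coverage":
                if k:
                    clip_s = np.maximum(fs[hit], b_start[i])
                    clip_e = np.minimum(fe[hit], b_end[i])
                    values[i] = _union_length(clip_s, clip_e) / (
                        b_end[i] - b_start[i]
                    )
            else:  # score_mean
                if k:
                    values[i] = float(np.mean(sc[hit]))
                else:
                    missing[i] = True

    new_bins = bins.copy()
    new_bins[out_column] = values
    if mode == "score_mean":
        new_bins[out_column + "_missing"] = missing
    return replace(s, bins=new_bins)


def radial_position(s: Structure, out_column: str = "radial") -> Structure:
    """Add the distance of each bin to the centroid of all bin points.

    The centroid is the unweighted mean of the XYZ coordinates.  Small
    radial position = interior of the structure; large = periphery.
    """
    if out_column in RESERVED_COLUMNS:
        raise InputError(f"out_column {out_column!r} is a reserved name")
    if out_column in s.bins.columns:
        raise InputError(f"column {out_column!r} already on structure {s.id!r}")
    xyz = s.coords()
    if len(xyz) == 0:
        raise InputError("structure has no bins")
    centroid = xyz.mean(axis=0)
    new_bins = s.bins.copy()
    new_bins[out_column] = np.linalg.norm(xyz - centroid, axis=1)
    return replace(s, bins=new_bins)
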