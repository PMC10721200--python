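"""Differential z-score contact maps and virtual 4C track extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import BinTable, GenomicInterval
from .matrix import ContactMatrix

__all__ = ["DiffMap", "Virtual4CTrack", "differential_zscore_map", "virtual_4c"]


@dataclass
class DiffMap:
    """Standardized difference between two balanced contact maps.

    For each region the entry-wise difference a - b over upper-triangle
    entries valid in both inputs is standardized:
    z = (diff - mean(diff)) / sd(diff), population sd.  Entries missing in
    either input are NaN.  ``degenerate`` flags regions where sd(diff) = 0
    (identical inputs), for which z is identically 0.
    """

    bin_table: BinTable
    z: list[np.ndarray]
    n_valid: list[int]
    degenerate: list[bool]


@dataclass
class Virtual4CTrack:
    """One bait bin's matrix row as a smoothed 1-D interaction track."""

    bin_table: BinTable
    region_index: int
    bait_bin: int  # index within the region
    values: np.ndarray
    smooth_bins: int


def differential_zscore_map(
    a: ContactMatrix, b: ContactMatrix, pool: str = "region", ddof: int = 0
) -> DiffMap:
    """Express the difference of two balanced maps as z-scores.

    Standardization is pooled per captured region by default (regions
    differ in decay regime); ``pool='all'`` standardizes over all regions
    jointly.  ``ddof=0`` gives the population standard deviation.
    """
    if a.bin_table != b.bin_table:
        raise ValueError("inputs have different bin tables")
    if pool not in ("region", "all"):
        raise ValueError("pool must be 'region' or 'all'")
    diffs, valids = [], []
    for ma, mb, va, vb in zip(a.matrices, b.matrices, a.valid, b.valid):
        diff = ma - mb
        both = np.outer(va & vb, va & vb) & np.isfinite(diff)
        diffs.append(diff)
        valids.append(both)

    def _standardize(diff, mask):
        n = diff.shape[0]
        iu = np.triu_indices(n)
        sel = mask[iu]
        vals = diff[iu][sel]
        return vals

    if pool == "all":
        pooled = np.concatenate(
            [_standardize(d, m) for d, m in zip(diffs, valids)]
        )
        mu = pooled.mean() if pooled.size else 0.0
        sd = pooled.std(ddof=ddof) if pooled.size else 0.0
        stats_per_region = [(mu, sd, pooled.size)] * len(diffs)
    else:
        stats_per_region = []
        for d, m in zip(diffs, valids):
            vals = _standardize(d, m)
            mu = vals.mean() if vals.size else 0.0
            sd = vals.std(ddof=ddof) if vals.size else 0.0
            stats_per_region.append((mu, sd, vals.size))

    zs, ns, degen = [], [], []
    for d, m, (mu, sd, n_valid) in zip(diffs, valids, stats_per_region):
        z = np.full(d.shape, np.nan)
        if sd > 0:
            z[m] = (d[m] - mu) / sd
            degen.append(False)
        else:
            z[m] = 0.0
            degen.append(True)
        zs.append(z)
        ns.append(int(n_valid))
    return DiffMap(a.bin_table, zs, ns, degen)


def running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean, truncated at the ends, NaN-excluded.

    The value at position j is the mean of the available (finite) values in
    the centered window of ``window`` positions, clipped to the array; a
    window with no finite values yields NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    n = values.size
    out = np.full(n, np.nan)
    for j in range(n):
        seg = values[max(0, j - half) : min(n, j + half + 1)]
        finite = seg[np.isfinite(seg)]
        if finite.size:
            out[j] = finite.mean()
    return out


def virtual_4c(
    matrix: ContactMatrix,
    bait: GenomicInterval,
    smooth_bins: int = 3,
    mask_bait: bool = False,
) -> Virtual4CTrack:
    """Extract the bait bin's row as a smoothed interaction track.

    The bait bin is the bin containing the bait interval's midpoint.  The
    row is smoothed with a centered running mean of ``smooth_bins`` bins,
    truncated at region edges.  ``mask_bait`` drops the bait's self-contact
    before smoothing.
    """
    if matrix.kind == "raw":
        raise ValueError("virtual_4c expects a balanced matrix")
    bt = matrix.bin_table
    global_bin = bt.bin_index(bait.chrom, bait.midpoint)
    if global_bin is None:
        raise ValueError(
            f"bait {bait.chrom}:{bait.start}-{bait.end} outside all regions"
        )
    r = bt.region_of_bin(global_bin)
    local = global_bin - bt.region_slice(r).start
    row = matrix.matrices[r][local].astype(float).copy()
    if mask_bait:
        row[local] = np.nan
    smoothed = running_mean(row, smooth_bins) if smooth_bins > 1 else row
    return Virtual4CTrack(bt, r, local, smoothed, smooth_bins)
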