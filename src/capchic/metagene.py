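"""Intragene compaction scores, gene-body signal summaries, and pileups.

A gene's intragene compaction score is the median observed/expected contact
over all pairs of distinct bins inside the gene body — a proxy for how much
the transcription unit folds on itself.  These scores are related to
ChIP/RNA signal medians over the gene body, compared between cell types as
log2 ratios, and visualized as expression-stratified metagene pileups in
which every gene is rescaled to a common pseudo-size with fixed flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .insulation import insulation_spearman
from .intervals import GenomicInterval
from .matrix import ContactMatrix

__all__ = [
    "GeneModel",
    "SignalTrack",
    "PileupStack",
    "intragene_score",
    "gene_signal_median",
    "build_gene_score_table",
    "correlate_scores_signals",
    "differential_compaction",
    "stratified_pileup",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if self.expression < 0:
            raise ValueError("expression must be >= 0")


@dataclass
class SignalTrack:
    """A bedGraph-style signal track (e.g. CPM-normalized ChIP or RNA)."""

    name: str
    data: pd.DataFrame  # columns: chrom, start, end, value

    def rebin(self, chrom: str, start: int, end: int, bin_bp: int) -> np.ndarray:
        """Coverage-weighted mean per fixed genomic bin over [start, end).

        Bins tile the genome from coordinate 0 at ``bin_bp``; uncovered
        sequence contributes value 0 with its full weight.
        """
        first = (start // bin_bp) * bin_bp
        edges = np.arange(first, end + bin_bp, bin_bp)
        n = len(edges) - 1
        acc = np.zeros(n)
        sub = self.data[self.data["chrom"] == chrom]
        s_arr = sub["start"].to_numpy()
        e_arr = sub["end"].to_numpy()
        v_arr = sub["value"].to_numpy()
        keep = (e_arr > first) & (s_arr < edges[-1])
        for s, e, v in zip(s_arr[keep], e_arr[keep], v_arr[keep]):
            lo = max(0, int((max(s, first) - first) // bin_bp))
            hi = min(n - 1, int((min(e, edges[-1]) - 1 - first) // bin_bp))
            for k in range(lo, hi + 1):
                overlap = min(e, edges[k + 1]) - max(s, edges[k])
                if overlap > 0:
                    acc[k] += v * overlap
        return acc / bin_bp


@dataclass
class PileupStack:
    """Median O/E image over scaled gene coordinates for one gene group."""

    label: str
    image: np.ndarray  # square, side = 2*flank_bins + pseudo_bins
    n_genes: int
    flank_bins: int
    pseudo_bins: int


def _gene_bins(
    oe: ContactMatrix, gene: GeneModel
) -> tuple[int, int, int] | None:
    """(region, first local bin, last local bin + 1) of bins whose midpoint
    lies inside the gene, or None when the gene misses matrix coverage."""
    bt = oe.bin_table
    mids = bt.bin_midpoints()
    chroms = bt.bin_chroms()
    mask = (
        (chroms == gene.interval.chrom)
        & (mids >= gene.interval.start)
        & (mids < gene.interval.end)
    )
    hits = np.flatnonzero(mask)
    if hits.size == 0:
        return None
    regions = {bt.region_of_bin(i) for i in hits}
    if len(regions) > 1:
        logger.warning("gene %s spans multiple regions; skipped", gene.gene_id)
        return None
    r = regions.pop()
    offset = bt.region_slice(r).start
    return r, min(hits) - offset, max(hits) - offset + 1


def intragene_score(
    oe: ContactMatrix,
    gene: GeneModel,
    min_bins: int = 10,
    include_diagonal: bool = False,
) -> float | None:
    """Median O/E over all unordered pairs of distinct bins in the gene.

    The diagonal is excluded by default (dominated by self-ligation).
    Returns None when the gene covers fewer than ``min_bins`` bins or lies
    outside matrix coverage.
    """
    loc = _gene_bins(oe, gene)
    if loc is None:
        logger.info("gene %s outside matrix coverage", gene.gene_id)
        return None
    r, g0, g1 = loc
    if g1 - g0 < min_bins:
        return None
    sub = oe.matrices[r][g0:g1, g0:g1]
    k = 0 if include_diagonal else 1
    iu = np.triu_indices(sub.shape[0], k=k)
    vals = sub[iu]
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if vals.size else None


def gene_signal_median(
    track: SignalTrack, gene: GeneModel, bin_bp: int = 10_000
) -> float | None:
    """Median rebinned signal over the fixed bins overlapping the gene."""
    iv = gene.interval
    if len(iv) <= 0:
        return None
    values = track.rebin(iv.chrom, iv.start, iv.end, bin_bp)
    return float(np.median(values)) if values.size else None


def build_gene_score_table(
    oe: ContactMatrix,
    genes: list[GeneModel],
    tracks: dict[str, SignalTrack] | None = None,
    min_bins: int = 10,
    signal_bin_bp: int = 10_000,
) -> pd.DataFrame:
    """Per-gene intragene score, expression, bin count and signal medians."""
    rows = []
    for gene in genes:
        loc = _gene_bins(oe, gene)
        n_bins = (loc[2] - loc[1]) if loc else 0
        row = {
            "gene_id": gene.gene_id,
            "expression": gene.expression,
            "n_bins": n_bins,
            "intragene_score": intragene_score(oe, gene, min_bins=min_bins),
        }
        for name, track in (tracks or {}).items():
            row[f"signal_{name}"] = gene_signal_median(track, gene, signal_bin_bp)
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_scores_signals(table: pd.DataFrame, track_name: str) -> dict:
    """Spearman correlation of intragene score with a gene-body signal."""
    col = f"signal_{track_name}"
    sub = table.dropna(subset=["intragene_score", col])
    return insulation_spearman(sub["intragene_score"], sub[col])


def differential_compaction(
    table_a: pd.DataFrame, table_b: pd.DataFrame, track_name: str
) -> tuple[pd.DataFrame, dict]:
    """Per-gene log2 ratios of compaction and signal between two cell types.

    Genes are matched by id; genes with a nonpositive or missing score or
    signal in either table are dropped (count logged).  Returns the ratio
    table and the Spearman statistics of score ratio vs signal ratio.
    """
    col = f"signal_{track_name}"
    merged = table_a.merge(table_b, on="gene_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared genes between the two tables")
    needed = [f"intragene_score_{s}" for s in "ab"] + [f"{col}_{s}" for s in "ab"]
    ok = np.ones(len(merged), dtype=bool)
    for c in needed:
        ok &= merged[c].notna().to_numpy() & (merged[c].fillna(0) > 0).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("differential_compaction: dropped %d genes", n_dropped)
    sub = merged[ok]
    out = pd.DataFrame(
        {
            "gene_id": sub["gene_id"],
            "log2_score_ratio": np.log2(
                sub["intragene_score_a"] / sub["intragene_score_b"]
            ),
            "log2_signal_ratio": np.log2(sub[f"{col}_a"] / sub[f"{col}_b"]),
        }
    )
    stats = insulation_spearman(out["log2_score_ratio"], out["log2_signal_ratio"])
    stats["n_dropped"] = n_dropped
    return out, stats


def _rescale_operator(g: int, p: int) -> np.ndarray:
    """Area-weighted averaging operator mapping g gene bins to p pseudo-bins.

    W[k, j] is the fractional overlap of pseudo-bin k (width g/p in gene-bin
    units) with gene bin j, normalized so each row sums to 1; conserves the
    mean signal (no interpolation).
    """
    W = np.zeros((p, g))
    width = g / p
    for k in range(p):
        lo, hi = k * width, (k + 1) * width
        for j in range(int(np.floor(lo)), min(g, int(np.ceil(hi)))):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                W[k, j] = overlap / width
    return W


def _weighted_transform(M: np.ndarray, T: np.ndarray) -> np.ndarray:
    """T M T' with missing-value-aware weight renormalization."""
    mask = np.isfinite(M).astype(float)
    num = T @ np.nan_to_num(M) @ T.T
    den = T @ mask @ T.T
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    # restore exact values where weights were complete (den == 1 row sums)
    return out


def gene_pileup_image(
    oe: ContactMatrix,
    gene: GeneModel,
    pseudo_bins: int = 10,
    flank_bins: int = 40,
) -> np.ndarray | None:
    """One gene's scaled O/E submatrix: flank + pseudo-gene + flank per axis.

    The gene segment of each axis is rescaled to ``pseudo_bins`` by
    area-weighted block averaging; flanks are taken bin-for-bin.  Both axes
    are flipped for minus-strand genes so the 5' end is leftmost.  Pixels
    beyond matrix bounds are NaN.
    """
    loc = _gene_bins(oe, gene)
    if loc is None:
        return None
    r, g0, g1 = loc
    g = g1 - g0
    n = oe.matrices[r].shape[0]
    lo, hi = g0 - flank_bins, g1 + flank_bins
    side = 2 * flank_bins + g
    M = np.full((side, side), np.nan)
    src_lo, src_hi = max(lo, 0), min(hi, n)
    dst_lo, dst_hi = src_lo - lo, src_hi - lo
    M[dst_lo:dst_hi, dst_lo:dst_hi] = oe.matrices[r][src_lo:src_hi, src_lo:src_hi]
    if gene.interval.strand == "-":
        M = M[::-1, ::-1]
    f = flank_bins
    T = np.zeros((2 * f + pseudo_bins, side))
    T[:f, :f] = np.eye(f)
    T[f : f + pseudo_bins, f : f + g] = _rescale_operator(g, pseudo_bins)
    T[f + pseudo_bins :, f + g :] = np.eye(f)
    return _weighted_transform(M, T)


def stratified_pileup(
    oe: ContactMatrix,
    genes: list[GeneModel],
    n_groups: int = 4,
    pseudo_bins: int = 10,
    flank_bins: int = 40,
    min_bins: int = 10,
) -> list[PileupStack]:
    """Expression-stratified metagene pileups of O/E submatrices.

    Genes covering >= ``min_bins`` bins are split into ``n_groups``
    expression groups (Q1 = lowest ... Qn = highest; ties broken by gene_id
    order); each group's stack is the per-pixel median over its genes'
    scaled images.  Empty groups yield an all-NaN stack with n_genes = 0.
    """
    eligible = []
    for gene in genes:
        loc = _gene_bins(oe, gene)
        if loc and (loc[2] - loc[1]) >= min_bins:
            eligible.append(gene)
    eligible.sort(key=lambda gm: (gm.expression, gm.gene_id))
    groups = np.array_split(np.arange(len(eligible)), n_groups)
    side = 2 * flank_bins + pseudo_bins
    stacks = []
    for q, idx in enumerate(groups, start=1):
        images = []
        for i in idx:
            img = gene_pileup_image(oe, eligible[i], pseudo_bins, flank_bins)
            if img is not None:
                images.append(img)
        if images:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                image = np.nanmedian(np.stack(images), axis=0)
        else:
            logger.warning("pileup group Q%d has no eligible genes", q)
            image = np.full((side, side), np.nan)
        stacks.append(PileupStack(f"Q{q}", image, len(images), flank_bins, pseudo_bins))
    return stacks
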