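"""Readers and writers for the pipeline's on-disk formats.

Canonical formats are plain text: FASTA (genome), BED/BED6 (intervals,
boundaries), bedGraph (tracks, insulation), 4-column pairs text, and a
matrix bundle of sparse-triplet TSV + bin-table BED + JSON metadata.
Called-boundary spreadsheets (one locus per row, one score column per cell
type, NA where not called) are read through pandas/openpyxl.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .insulation import Boundary, BoundarySet, InsulationProfile
from .intervals import BinTable, GenomicInterval
from .matrix import ContactMatrix, DecayProfile
from .metagene import GeneModel, SignalTrack
from .preprocess import ContactPair

__all__ = [
    "read_fasta",
    "read_intervals",
    "write_intervals",
    "read_bedgraph",
    "write_bedgraph",
    "read_pairs",
    "write_pairs",
    "read_matrix_bundle",
    "write_matrix_bundle",
    "write_decay_profile",
    "read_genes",
    "write_insulation_bedgraph",
    "write_boundaries_bed",
    "read_supplementary_boundaries",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_intervals(path) -> list[GenomicInterval]:
    """BED (3-6 columns) to 0-based half-open intervals, strand honored."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                strand = fields[5] if len(fields) >= 6 else "."
                intervals.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    return intervals


def write_intervals(intervals: list[GenomicInterval], path, names=None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            name = names[k] if names else f"iv{k}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bedgraph(path, name: str = "") -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return SignalTrack(name or Path(path).stem, df)


def write_bedgraph(track: SignalTrack, path) -> None:
    track.data.to_csv(path, sep="\t", header=False, index=False)


def read_genes(path) -> list[GeneModel]:
    """BED6 + expression column (col 7) to gene models."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ValueError(f"{path}:{lineno}: need BED6 + expression column")
            genes.append(
                GeneModel(
                    f[3],
                    GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    float(f[6]),
                )
            )
    return genes


def write_genes(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}"
                f"\t{g.expression:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Pairs text: chrom1 pos1 chrom2 pos2, 1-based on disk, '#' comments


def read_pairs(path) -> list[ContactPair]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            pairs.append(
                ContactPair.make(f[0], int(f[1]) - 1, f[2], int(f[3]) - 1)
            )
    return pairs


def write_pairs(pairs: list[ContactPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom1\tpos1\tchrom2\tpos2 (1-based)\n")
        for p in pairs:
            fh.write(f"{p.chrom1}\t{p.pos1 + 1}\t{p.chrom2}\t{p.pos2 + 1}\n")


# ---------------------------------------------------------------------------
# Matrix bundle: <stem>.bins.bed, <stem>.triplet.tsv, <stem>.json


def write_matrix_bundle(matrix: ContactMatrix, stem) -> None:
    stem = Path(stem)
    bt = matrix.bin_table
    with open(stem.with_suffix(".bins.bed"), "w") as fh:
        for i, b in enumerate(bt.bins):
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{i}\n")
    with open(stem.with_suffix(".triplet.tsv"), "w") as fh:
        fh.write("bin1_id\tbin2_id\tvalue\n")
        for r, m in enumerate(matrix.matrices):
            offset = bt.region_slice(r).start
            iu = np.triu_indices(m.shape[0])
            for i, j in zip(*iu):
                v = m[i, j]
                if np.isfinite(v) and v != 0:
                    fh.write(f"{offset + i}\t{offset + j}\t{float(v)!r}\n")
    meta = {
        "resolution": bt.resolution,
        "kind": matrix.kind,
        "regions": [
            {"chrom": r.chrom, "start": r.start, "end": r.end} for r in bt.regions
        ],
        "valid": [v.tolist() for v in matrix.valid],
        "weights": None
        if matrix.weights is None
        else [[None if not np.isfinite(x) else x for x in w] for w in matrix.weights],
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_matrix_bundle(stem) -> ContactMatrix:
    stem = Path(stem)
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    bt = BinTable(
        meta["resolution"],
        [GenomicInterval(r["chrom"], r["start"], r["end"]) for r in meta["regions"]],
    )
    fill = 0.0 if meta["kind"] == "raw" else np.nan
    mats = [
        np.full((bt.region_n_bins(r), bt.region_n_bins(r)), fill)
        for r in range(bt.n_regions)
    ]
    df = pd.read_csv(stem.with_suffix(".triplet.tsv"), sep="\t")
    for b1, b2, v in zip(df["bin1_id"], df["bin2_id"], df["value"]):
        b1, b2 = int(b1), int(b2)
        if b2 < b1:  # canonicalize to upper triangle
            b1, b2 = b2, b1
        if b1 >= bt.n_bins or b2 >= bt.n_bins:
            raise ValueError(f"triplet references missing bin id {max(b1, b2)}")
        r = bt.region_of_bin(b1)
        if bt.region_of_bin(b2) != r:
            raise ValueError("triplet entry spans regions")
        off = bt.region_slice(r).start
        mats[r][b1 - off, b2 - off] = v
        mats[r][b2 - off, b1 - off] = v
    valid = [np.asarray(v, dtype=bool) for v in meta["valid"]]
    weights = None
    if meta["weights"] is not None:
        weights = [
            np.array([np.nan if x is None else x for x in w]) for w in meta["weights"]
        ]
    return ContactMatrix(bt, mats, valid, weights, meta["kind"])


def write_decay_profile(decay: DecayProfile, path) -> None:
    pd.DataFrame(
        {
            "separation_bp": decay.separations_bp,
            "median": decay.median,
            "q25": decay.iqr_lo,
            "q75": decay.iqr_hi,
        }
    ).to_csv(path, sep="\t", index=False)


def write_insulation_bedgraph(profile: InsulationProfile, path) -> None:
    bt = profile.bin_table
    with open(path, "w") as fh:
        for r, scores in enumerate(profile.scores):
            off = bt.region_slice(r).start
            for i, s in enumerate(scores):
                if np.isfinite(s):
                    b = bt.bins[off + i]
                    fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{float(s)!r}\n")


def write_boundaries_bed(bset: BoundarySet, path) -> None:
    with open(path, "w") as fh:
        for k, b in enumerate(bset.boundaries):
            windows = ",".join(str(w) for w in sorted(b.supporting_windows))
            fh.write(
                f"{b.interval.chrom}\t{b.interval.start}\t{b.interval.end}"
                f"\t{bset.cell_type or 'boundary'}_{k}\t{b.score:.4f}\t."
                f"\t{windows}\n"
            )


# ---------------------------------------------------------------------------
# Called-boundary spreadsheet (per-locus rows, per-cell-type score columns)


def read_supplementary_boundaries(
    path, cell_types: tuple[str, ...] = ("ESC", "DN3", "DP")
) -> tuple[dict[str, BoundarySet], int]:
    """Read a called-boundary workbook into per-cell-type boundary sets.

    The sheet is expected to have chromosome/start/end columns plus one
    column per cell type holding the boundary score, with NA where that
    boundary was not called in that cell type.  Cell-type columns are
    auto-detected by case-insensitive name matching.  Returns the boundary
    sets and the total number of usable rows.
    """
    df = pd.read_excel(path, engine="openpyxl")
    cols = {str(c).strip().lower(): c for c in df.columns}

    def _find(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    chrom_col = _find("chrom", "chromosome", "chr", "seqnames")
    start_col = _find("start", "begin")
    end_col = _find("end", "stop")
    if chrom_col is None or start_col is None or end_col is None:
        raise ValueError("could not locate chrom/start/end columns")
    ct_cols = {}
    for ct in cell_types:
        for low, orig in cols.items():
            if ct.lower() == low or low.startswith(ct.lower()):
                ct_cols[ct] = orig
                break
    if not ct_cols:
        raise ValueError(f"no cell-type columns matching {cell_types} found")
    sets = {ct: BoundarySet(ct, []) for ct in ct_cols}
    n_rows = 0
    for idx, row in df.iterrows():
        try:
            iv = GenomicInterval(
                str(row[chrom_col]), int(row[start_col]), int(row[end_col])
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {idx + 2}: unparseable locus: {exc}") from exc
        any_called = False
        for ct, col in ct_cols.items():
            v = row[col]
            if pd.isna(v) or str(v).strip().upper() == "NA":
                continue
            try:
                score = float(v)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {idx + 2}, column {col!r}: unparseable score {v!r}"
                ) from exc
            sets[ct].boundaries.append(Boundary(iv, score))
            any_called = True
        if any_called:
            n_rows += 1
        else:
            import logging

            logging.getLogger(__name__).warning(
                "row %d: boundary called in no cell type; skipped", idx + 2
            )
    return sets, n_rows
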