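"""In-silico digestion, capture-probe design, pair filtering and binning.

Mirrors the upstream steps of a Capture Hi-C experiment: the genome is cut
in silico at every recognition-site occurrence (DpnII / GATC by default,
cutting 5' of the site), probe-bearing fragments are selected by length,
GC content, mappability and proximity to target genes, and read pairs are
filtered (self-ligations, PCR duplicates, off-target capture) before being
accumulated into fixed-bin contact matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import BinTable, GenomicInterval
from .matrix import ContactMatrix

__all__ = [
    "RestrictionFragment",
    "ContactPair",
    "FilterReport",
    "digest_genome",
    "mappability_from_kmer_uniqueness",
    "design_capture_probes",
    "filter_pairs",
    "bin_pairs",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class RestrictionFragment:
    interval: GenomicInterval
    fragment_id: int
    gc_fraction: float
    mappable_fraction: float = 1.0


@dataclass(frozen=True)
class ContactPair:
    """A ligation read pair; mates stored in canonical order.

    Canonical order (lexicographic chrom, then position) makes duplicate
    detection independent of the order mates appeared in the input.
    """

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    fragment1_id: int | None = None
    fragment2_id: int | None = None

    @staticmethod
    def make(chrom1: str, pos1: int, chrom2: str, pos2: int) -> "ContactPair":
        if (chrom1, pos1) <= (chrom2, pos2):
            return ContactPair(chrom1, pos1, chrom2, pos2)
        return ContactPair(chrom2, pos2, chrom1, pos1)


@dataclass
class FilterReport:
    n_input: int = 0
    n_self_ligation: int = 0
    n_duplicate: int = 0
    n_outside_capture: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq)


def digest_genome(
    genome: dict[str, str], site: str = "GATC"
) -> list[RestrictionFragment]:
    """Cut every sequence at each occurrence of ``site``.

    The cut is placed at the 5' start of the recognition site (DpnII cuts
    5' of GATC, leaving the site on the downstream fragment).  Fragments
    tile each chromosome without gaps; ids are per-chromosome ordinals.
    """
    site = site.upper()
    if not site or any(c not in "ACGT" for c in site):
        raise ValueError(f"invalid recognition site {site!r}")
    fragments: list[RestrictionFragment] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for i, c in enumerate(seq):
            if c not in "ACGTN":
                raise ValueError(
                    f"non-ACGTN character {c!r} at {chrom}:{i}"
                )
        cuts = [0]
        start = seq.find(site)
        while start != -1:
            if start != 0:
                cuts.append(start)
            start = seq.find(site, start + 1)
        cuts.append(len(seq))
        for frag_id, (a, b) in enumerate(zip(cuts[:-1], cuts[1:])):
            fragments.append(
                RestrictionFragment(
                    GenomicInterval(chrom, a, b),
                    fragment_id=frag_id,
                    gc_fraction=_gc_fraction(seq[a:b]),
                )
            )
    return fragments


def mappability_from_kmer_uniqueness(
    genome: dict[str, str], fragments: list[RestrictionFragment], k: int = 50
) -> list[RestrictionFragment]:
    """Score fragments by exact k-mer uniqueness within the supplied genome.

    A position is mappable when the k-mer starting there occurs exactly once
    in the genome (counting both strands).  This is a stand-in for
    read-mapper-based mappability, suitable for synthetic genomes.
    """
    counts: dict[str, int] = {}
    for seq in genome.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            rc = kmer.translate(_COMPLEMENT)[::-1]
            key = min(kmer, rc)
            counts[key] = counts.get(key, 0) + (2 if kmer == rc else 1)
    out = []
    for frag in fragments:
        seq = genome[frag.interval.chrom].upper()
        starts = range(
            frag.interval.start, min(frag.interval.end, len(seq) - k + 1)
        )
        n_pos = 0
        n_unique = 0
        for i in starts:
            kmer = seq[i : i + k]
            rc = kmer.translate(_COMPLEMENT)[::-1]
            n_pos += 1
            if counts.get(min(kmer, rc), 0) == 1:
                n_unique += 1
        frac = n_unique / n_pos if n_pos else 0.0
        out.append(
            RestrictionFragment(
                frag.interval, frag.fragment_id, frag.gc_fraction, frac
            )
        )
    return out


def design_capture_probes(
    fragments: list[RestrictionFragment],
    targets: list[GenomicInterval],
    min_len: int = 140,
    gc_range: tuple[float, float] = (0.20, 0.80),
    min_mappable: float = 0.80,
    probe_len: int = 120,
    flank: int = 600_000,
) -> list[GenomicInterval]:
    """Select probe-bearing fragments and emit capture oligo intervals.

    A fragment is retained when its length is >= ``min_len``, its GC
    fraction lies in ``gc_range`` (inclusive), its mappable fraction is
    >= ``min_mappable``, and it lies within ``flank`` of a target.  Two
    probes of ``probe_len`` nt are placed flush with the fragment ends
    (the sequence directly adjacent to the restriction sites); a single
    centered probe is emitted when the fragment is too short for two.
    """
    expanded = [t.expand(flank) for t in targets]
    probes: list[GenomicInterval] = []
    for frag in fragments:
        iv = frag.interval
        if len(iv) < min_len:
            continue
        if not (gc_range[0] <= frag.gc_fraction <= gc_range[1]):
            continue
        if frag.mappable_fraction < min_mappable:
            continue
        if not any(t.overlaps(iv) for t in expanded):
            continue
        if len(iv) >= 2 * probe_len:
            probes.append(GenomicInterval(iv.chrom, iv.start, iv.start + probe_len))
            probes.append(GenomicInterval(iv.chrom, iv.end - probe_len, iv.end))
        elif len(iv) >= probe_len:
            mid = (iv.start + iv.end) // 2
            probes.append(
                GenomicInterval(iv.chrom, mid - probe_len // 2, mid - probe_len // 2 + probe_len)
            )
        else:
            logger.warning(
                "fragment %s:%d-%d shorter than probe length; centered probe clipped",
                iv.chrom, iv.start, iv.end,
            )
            probes.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return probes


def _fragment_lookup(fragments: list[RestrictionFragment]):
    """Per-chromosome sorted fragment boundaries for O(log n) assignment."""
    by_chrom: dict[str, list[RestrictionFragment]] = {}
    for frag in fragments:
        by_chrom.setdefault(frag.interval.chrom, []).append(frag)
    index: dict[str, tuple[np.ndarray, list[RestrictionFragment]]] = {}
    for chrom, frags in by_chrom.items():
        frags.sort(key=lambda f: f.interval.start)
        starts = np.array([f.interval.start for f in frags])
        index[chrom] = (starts, frags)
    return index


def assign_fragment(index, chrom: str, pos: int) -> RestrictionFragment:
    if chrom not in index:
        raise ValueError(f"no fragments on chromosome {chrom!r}")
    starts, frags = index[chrom]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i < 0 or pos >= frags[i].interval.end:
        raise ValueError(f"position {chrom}:{pos} not covered by any fragment")
    return frags[i]


def filter_pairs(
    pairs: list[ContactPair],
    fragments: list[RestrictionFragment],
    capture_regions: list[GenomicInterval] | None = None,
    capture_rule: str = "midpoint",
) -> tuple[list[ContactPair], FilterReport]:
    """Remove self-ligations, PCR duplicates and off-target pairs, in order.

    Self-ligation: both mates fall in the same restriction fragment on the
    same chromosome.  Duplicate: identical canonical (chrom1, pos1, chrom2,
    pos2); the first occurrence is kept.  Capture filter (when
    ``capture_regions`` given): both mates' fragments must belong to a
    capture region, judged by fragment midpoint (default) or any-overlap
    (``capture_rule='overlap'``).
    """
    if capture_rule not in ("midpoint", "overlap"):
        raise ValueError("capture_rule must be 'midpoint' or 'overlap'")
    index = _fragment_lookup(fragments)
    report = FilterReport(n_input=len(pairs))
    seen: set[tuple] = set()
    kept: list[ContactPair] = []
    for pair in pairs:
        pair = ContactPair.make(pair.chrom1, pair.pos1, pair.chrom2, pair.pos2)
        f1 = assign_fragment(index, pair.chrom1, pair.pos1)
        f2 = assign_fragment(index, pair.chrom2, pair.pos2)
        if pair.chrom1 == pair.chrom2 and f1.fragment_id == f2.fragment_id:
            report.n_self_ligation += 1
            continue
        key = (pair.chrom1, pair.pos1, pair.chrom2, pair.pos2)
        if key in seen:
            report.n_duplicate += 1
            continue
        seen.add(key)
        if capture_regions is not None:
            def _in_capture(frag: RestrictionFragment) -> bool:
                if capture_rule == "midpoint":
                    mid = frag.interval.midpoint
                    return any(
                        r.contains(frag.interval.chrom, mid) for r in capture_regions
                    )
                return any(r.overlaps(frag.interval) for r in capture_regions)

            if not (_in_capture(f1) and _in_capture(f2)):
                report.n_outside_capture += 1
                continue
        kept.append(
            ContactPair(
                pair.chrom1, pair.pos1, pair.chrom2, pair.pos2,
                f1.fragment_id, f2.fragment_id,
            )
        )
    report.n_kept = len(kept)
    return kept, report


def bin_pairs(pairs: list[ContactPair], bin_table: BinTable) -> ContactMatrix:
    """Accumulate filtered pairs into symmetric per-region count matrices.

    Each pair increments exactly one unordered bin pair; pairs whose mates
    fall in different regions (or outside all regions) raise, since the
    capture filter should already have removed them.
    """
    mats = [
        np.zeros((bin_table.region_n_bins(r), bin_table.region_n_bins(r)))
        for r in range(bin_table.n_regions)
    ]
    for pair in pairs:
        b1 = bin_table.bin_index(pair.chrom1, pair.pos1)
        b2 = bin_table.bin_index(pair.chrom2, pair.pos2)
        if b1 is None or b2 is None:
            raise ValueError(
                f"pair {pair.chrom1}:{pair.pos1}-{pair.chrom2}:{pair.pos2} "
                "falls outside the bin table; capture filtering should have removed it"
            )
        r1 = bin_table.region_of_bin(b1)
        r2 = bin_table.region_of_bin(b2)
        if r1 != r2:
            raise ValueError("pair spans two capture regions; filtering bug")
        s = bin_table.region_slice(r1)
        i, j = b1 - s.start, b2 - s.start
        mats[r1][i, j] += 1
        if i != j:
            mats[r1][j, i] += 1
    return ContactMatrix(bin_table, mats, kind="raw")
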