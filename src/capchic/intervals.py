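"""Genomic coordinate primitives shared by every pipeline stage.

All coordinates are 0-based, half-open ``[start, end)``.  Pairs files on
disk use 1-based positions and are converted on read (see :mod:`capchic.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["GenomicInterval", "BinTable"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : chromosome / contig name
    start : first base, inclusive, >= 0
    end : one past the last base
    strand : ``'+'``, ``'-'`` or ``'.'`` (unstranded, the default)
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def expand(self, pad: int) -> "GenomicInterval":
        """Symmetrically extend by ``pad`` bases (clipped at 0)."""
        return replace(self, start=max(0, self.start - pad), end=self.end + pad)


@dataclass
class BinTable:
    """Fixed-size binning of one or more genomic regions.

    Each region is tiled independently at ``resolution``; the last bin of a
    region may be shorter.  Bin indices are global (region-concatenated) and
    map bijectively to (region, offset).
    """

    resolution: int
    regions: list[GenomicInterval]
    bins: list[GenomicInterval] = field(init=False)
    _region_starts: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.bins = []
        self._region_starts = []
        for region in self.regions:
            self._region_starts.append(len(self.bins))
            pos = region.start
            while pos < region.end:
                end = min(pos + self.resolution, region.end)
                self.bins.append(GenomicInterval(region.chrom, pos, end))
                pos = end
        self._region_starts.append(len(self.bins))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_slice(self, region_index: int) -> slice:
        """Global bin-index slice covering one region."""
        return slice(
            self._region_starts[region_index], self._region_starts[region_index + 1]
        )

    def region_n_bins(self, region_index: int) -> int:
        s = self.region_slice(region_index)
        return s.stop - s.start

    def region_of_bin(self, bin_index: int) -> int:
        for r in range(self.n_regions):
            s = self.region_slice(r)
            if s.start <= bin_index < s.stop:
                return r
        raise IndexError(f"bin index {bin_index} out of range")

    def bin_index(self, chrom: str, pos: int) -> int | None:
        """Global index of the bin containing (chrom, pos), or None."""
        for r, region in enumerate(self.regions):
            if region.contains(chrom, pos):
                offset = (pos - region.start) // self.resolution
                return self._region_starts[r] + offset
        return None

    def bin_midpoints(self) -> "np.ndarray":
        """Midpoint coordinate of every bin (cached)."""
        import numpy as np

        if not hasattr(self, "_midpoints"):
            self._midpoints = np.array([b.midpoint for b in self.bins])
        return self._midpoints

    def bin_chroms(self) -> "np.ndarray":
        """Chromosome name of every bin (cached)."""
        import numpy as np

        if not hasattr(self, "_chroms"):
            self._chroms = np.array([b.chrom for b in self.bins])
        return self._chroms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinTable):
            return NotImplemented
        return self.resolution == other.resolution and self.regions == other.regions
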