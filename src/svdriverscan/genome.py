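"""Genome model, coordinate conventions and genomic binning.

All coordinates are stored 0-based half-open (BED/BEDPE native).  A
:class:`GenomeDef` is the single source of truth for chromosome names and
lengths; every other object refers to positions on it.  Bins produced by
:func:`make_bins` form a partition of the genome: every position belongs to
exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SV_CLASSES = ("DEL", "DUP", "INV", "TRA", "unknown")
VAR_TYPES = ("SNV", "INS", "DEL")


class ParameterError(ValueError):
    """Invalid parameter passed to a toolkit operation."""


@dataclass(frozen=True)
class GenomeDef:
    """Ordered chromosome names with their lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ParameterError("names and lengths differ in count")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ParameterError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ParameterError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeDef":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def length_of(self, chrom: str) -> int:
        return self.lengths[chrom]

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))


@dataclass(frozen=True)
class GenomicBin:
    """Fixed-width genome tile; the unit of breakpoint-recurrence testing.

    ``eligible_bases`` is the number of positions in the bin with
    sufficient mappability to be eligible for breakpoint detection; it acts
    as the exposure of the bin in the background model.
    """

    chrom: str
    start: int
    end: int
    eligible_bases: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ParameterError(f"bad bin interval {self.chrom}:{self.start}-{self.end}")
        if not (0 <= self.eligible_bases <= self.end - self.start):
            raise ParameterError("eligible_bases outside [0, bin length]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int
    sample_id: str
    orientation: str = "unknown"  # {+, -, unknown}; unused by statistics

    def __post_init__(self):
        if not self.sample_id:
            raise ParameterError("sample_id must be non-empty")


@dataclass(frozen=True)
class Rearrangement:
    """A somatic structural variant: two breakpoints in one sample.

    Canonical order bp1 <= bp2 in genome order is enforced at construction
    given a genome (or lexicographic chromosome order otherwise).
    """

    bp1: Breakpoint
    bp2: Breakpoint
    sv_class: str = "unknown"

    def __post_init__(self):
        if self.bp1.sample_id != self.bp2.sample_id:
            raise ParameterError("both breakpoints must share a sample_id")
        if self.sv_class not in SV_CLASSES:
            raise ParameterError(f"unknown SV class {self.sv_class!r}")

    @property
    def sample_id(self) -> str:
        return self.bp1.sample_id

    @property
    def intra(self) -> bool:
        return self.bp1.chrom == self.bp2.chrom

    @property
    def distance(self) -> Optional[int]:
        """|pos2 - pos1|; defined only for intra-chromosomal events."""
        if not self.intra:
            return None
        return abs(self.bp2.pos - self.bp1.pos)

    @classmethod
    def canonical(cls, bp1: Breakpoint, bp2: Breakpoint, sv_class: str = "unknown",
                  genome: Optional[GenomeDef] = None) -> "Rearrangement":
        if genome is not None:
            order = {c: i for i, c in enumerate(genome.chrom_names)}
            k1 = (order[bp1.chrom], bp1.pos)
            k2 = (order[bp2.chrom], bp2.pos)
        else:
            k1 = (bp1.chrom, bp1.pos)
            k2 = (bp2.chrom, bp2.pos)
        if k2 < k1:
            bp1, bp2 = bp2, bp1
        return cls(bp1, bp2, sv_class)


@dataclass(frozen=True)
class MutationRecord:
    """A somatic SNV or small indel with annotations used by post-filtering."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    var_type: str = "SNV"
    indel_length: int = 0
    signature_fractions: tuple = ()  # ((name, fraction), ...)
    in_mappable: bool = True
    in_palindrome: bool = False

    def __post_init__(self):
        if self.var_type not in VAR_TYPES:
            raise ParameterError(f"unknown var_type {self.var_type!r}")
        if self.var_type != "SNV" and self.indel_length < 1:
            raise ParameterError("indel_length must be >= 1 for indels")
        for _, f in self.signature_fractions:
            if not (0.0 <= f <= 1.0):
                raise ParameterError("signature fractions must lie in [0,1]")

    def signature_fraction(self, name: str) -> float:
        for n, f in self.signature_fractions:
            if n == name:
                return f
        return 0.0

    @staticmethod
    def classify_alleles(ref: str, alt: str) -> tuple[str, int]:
        """var_type and indel length from allele strings (length difference)."""
        d = len(alt) - len(ref)
        if d == 0:
            return "SNV", 0
        return ("INS", d) if d > 0 else ("DEL", -d)


@dataclass
class Element:
    """A named genomic element as a set of non-overlapping intervals."""

    id: str
    intervals: list[tuple[str, int, int]]
    element_type: str = "custom"

    def __post_init__(self):
        self.intervals = normalize_intervals(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in self.intervals)


def normalize_intervals(ivals: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals (idempotent)."""
    out: list[tuple[str, int, int]] = []
    for c, s, e in sorted(ivals):
        if s >= e:
            raise ParameterError(f"empty interval {c}:{s}-{e}")
        if out and out[-1][0] == c and s <= out[-1][2]:
            pc, ps, pe = out[-1]
            out[-1] = (pc, ps, max(pe, e))
        else:
            out.append((c, s, e))
    return out


@dataclass
class CovariateTrack:
    """Per-bin numeric values aligned to a binning of a GenomeDef."""

    name: str
    values: np.ndarray
    mask: np.ndarray = None  # True where missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ParameterError("mask and values must have the same shape")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ParameterError("unmasked values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def make_bins(genome: GenomeDef, width: int,
              mappability: Optional[CovariateTrack] = None) -> list[GenomicBin]:
    """Tile every chromosome left to right with ``width``-bp bins.

    The last bin of each chromosome may be shorter.  When a mappability
    track is given its value per bin is interpreted as the eligible
    fraction of the bin; otherwise every base is eligible.
    """
    if width <= 0:
        raise ParameterError("bin width must be positive")
    bins: list[GenomicBin] = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        for start in range(0, length, width):
            end = min(start + width, length)
            bins.append(GenomicBin(chrom, start, end, end - start))
    if mappability is not None:
        if len(mappability) != len(bins):
            raise ParameterError(
                f"mappability track has {len(mappability)} values for {len(bins)} bins")
        frac = np.clip(np.where(mappability.mask, 1.0, mappability.values), 0.0, 1.0)
        bins = [GenomicBin(b.chrom, b.start, b.end, int(round(f * b.length)))
                for b, f in zip(bins, frac)]
    return bins


class BinIndex:
    """Constant-time position -> bin-index lookup for a genome tiling."""

    def __init__(self, bins: Sequence[GenomicBin]):
        self.bins = list(bins)
        self._starts: dict[str, np.ndarray] = {}
        self._offsets: dict[str, int] = {}
        self._ends: dict[str, int] = {}
        for i, b in enumerate(self.bins):
            if b.chrom not in self._offsets:
                self._offsets[b.chrom] = i
                self._starts[b.chrom] = []
            self._starts[b.chrom].append(b.start)
            self._ends[b.chrom] = b.end
        for c in self._starts:
            self._starts[c] = np.asarray(self._starts[c])

    def __len__(self) -> int:
        return len(self.bins)

    def bin_of(self, chrom: str, pos: int) -> Optional[int]:
        """Index of the bin containing (chrom, pos); None if off-genome."""
        starts = self._starts.get(chrom)
        if starts is None or pos < 0 or pos >= self._ends[chrom]:
            return None
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        return self._offsets[chrom] + j
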