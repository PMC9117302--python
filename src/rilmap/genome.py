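"""Physical-coordinate genome representation.

All downstream stages (curation, recombination matrices, QTL intervals,
co-location arithmetic) share one coordinate convention defined here:

* base-pair positions are 1-based and inclusive;
* the megabase unit of a bp position is ``ceil(bp / 1e6)`` (1-based);
* Mbp intervals are inclusive of both endpoint units, so an interval
  spanning units ``start..end`` covers ``end - start + 1`` megabase units.

A chromosome can be split at a breakpoint into a pseudo-chromosome, the
device used to analyse a translocated segment as if it were a separate
chromosome while *preserving* the original bp coordinates on the detached
part.  ``GenomeLayout`` therefore stores chromosomes as coordinate spans
``[start, end]`` rather than bare lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

MBP = 1_000_000


def mbp_unit(bp: int) -> int:
    """1-based megabase unit owning a 1-based bp position."""
    if bp < 1:
        raise ValueError(f"bp positions are 1-based; got {bp}")
    return -(-bp // MBP)


@dataclass(frozen=True)
class ChromosomeSpan:
    """A (possibly pseudo-) chromosome occupying bp ``[start, end]``.

    ``source`` records which original chromosome the coordinates refer to,
    so positions can be located by either their original or current name.
    """

    name: str
    start: int
    end: int
    source: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid span for {self.name}: [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def unit_start(self) -> int:
        return mbp_unit(self.start)

    @property
    def unit_end(self) -> int:
        return mbp_unit(self.end)

    @property
    def n_units(self) -> int:
        return self.unit_end - self.unit_start + 1

    def contains(self, bp: int) -> bool:
        return self.start <= bp <= self.end


class GenomeLayout:
    """Ordered set of named chromosome spans with unique names."""

    def __init__(self, chromosomes: Iterable) -> None:
        spans: list[ChromosomeSpan] = []
        for item in chromosomes:
            if isinstance(item, ChromosomeSpan):
                spans.append(item)
            else:
                name, length = item
                length = int(length)
                if length <= 0:
                    raise ValueError(f"chromosome {name} has non-positive length {length}")
                spans.append(ChromosomeSpan(str(name), 1, length, str(name)))
        names = [s.name for s in spans]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if not spans:
            raise ValueError("layout needs at least one chromosome")
        self.spans: tuple[ChromosomeSpan, ...] = tuple(spans)
        self._by_name = {s.name: s for s in self.spans}

    # -- basic introspection -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.spans]

    @property
    def total_size(self) -> int:
        """Total genome size in bp (conserved under splits)."""
        return sum(s.length for s in self.spans)

    @property
    def total_units(self) -> int:
        """Total number of 1 Mbp units across all spans."""
        return sum(s.n_units for s in self.spans)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ChromosomeSpan:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __len__(self) -> int:
        return len(self.spans)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeLayout) and self.spans == other.spans

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self.spans)} chromosomes, {self.total_size:,} bp)"

    # -- operations ----------------------------------------------------------

    def split_segment(self, source_chrom: str, breakpoint: int, new_name: str) -> "GenomeLayout":
        """Detach positions ``>= breakpoint`` of ``source_chrom`` into ``new_name``.

        Original bp coordinates are preserved on the pseudo-chromosome, so
        total genome size is unchanged.  The breakpoint must lie strictly
        inside the chromosome so that both parts are non-empty.
        """
        span = self[source_chrom]
        if new_name in self._by_name:
            raise ValueError(f"chromosome {new_name!r} already exists")
        if not (span.start < breakpoint <= span.end):
            raise ValueError(
                f"breakpoint {breakpoint} not strictly inside {source_chrom} "
                f"[{span.start}, {span.end}]"
            )
        head = ChromosomeSpan(span.name, span.start, breakpoint - 1, span.source)
        tail = ChromosomeSpan(new_name, breakpoint, span.end, span.source)
        out = []
        for s in self.spans:
            if s.name == source_chrom:
                out.extend([head, tail])
            else:
                out.append(s)
        return GenomeLayout(out)

    def locate(self, chromosome: str, bp: int) -> tuple[str, int]:
        """Map a position to its owning span (after any splits) and Mbp unit.

        ``chromosome`` may be the original (pre-split) name or a current
        span name; the bp coordinate disambiguates between split parts.
        """
        candidates = [
            s for s in self.spans if (s.name == chromosome or s.source == chromosome)
        ]
        if not candidates:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        for s in candidates:
            if s.contains(bp):
                return s.name, mbp_unit(bp)
        raise ValueError(f"position {chromosome}:{bp} is outside the layout")

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Read a two-column tab-delimited file: name, length_bp."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed layout line: {line!r}")
                chroms.append((fields[0], int(fields[1])))
        return cls(chroms)

    @classmethod
    def from_gff3(cls, path) -> "GenomeLayout":
        """Build a layout from GFF3 ``##sequence-region`` header lines."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, seqid, start, end = line.split()[:4]
                    if int(start) != 1:
                        raise ValueError(
                            f"sequence-region for {seqid} does not start at 1"
                        )
                    chroms.append((seqid, int(end)))
        if not chroms:
            raise ValueError(f"no ##sequence-region lines in {path}")
        return cls(chroms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.spans:
                fh.write(f"{s.name}\t{s.length}\n")


@dataclass(frozen=True)
class Interval:
    """Inclusive Mbp interval ``[start, end]`` on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("Mbp units are 1-based")

    @property
    def width(self) -> int:
        """Width in Mbp units, inclusive of both endpoints."""
        return self.end - self.start + 1

    def contains_unit(self, chromosome: str, unit: int) -> bool:
        return chromosome == self.chromosome and self.start <= unit <= self.end

    def validate(self, layout: GenomeLayout) -> None:
        span = layout[self.chromosome]
        if self.start < span.unit_start or self.end > span.unit_end:
            raise ValueError(
                f"interval {self} outside {self.chromosome} units "
                f"[{span.unit_start}, {span.unit_end}]"
            )


# Default bundled layout: 21 chromosomes named chr{1..7}{A,C,D}.  Hexaploid
# oat pseudomolecule sizes are not individually published, so these are
# plausible per-chromosome sizes (C-genome chromosomes largest) chosen to sum
# to the published cumulative size of 10,272 Mbp; supply your own layout for
# real data.
_DEFAULT_OAT_MBP = {
    "chr1A": 526, "chr2A": 490, "chr3A": 502, "chr4A": 470,
    "chr5A": 420, "chr6A": 460, "chr7A": 520,
    "chr1C": 527, "chr2C": 530, "chr3C": 570, "chr4C": 545,
    "chr5C": 555, "chr6C": 560, "chr7C": 540,
    "chr1D": 460, "chr2D": 450, "chr3D": 440, "chr4D": 430,
    "chr5D": 420, "chr6D": 357, "chr7D": 500,
}


def default_oat_layout() -> GenomeLayout:
    """21-chromosome hexaploid oat layout totalling 10,272 Mbp."""
    order = [f"chr{i}{g}" for i in range(1, 8) for g in "ACD"]
    layout = GenomeLayout([(name, _DEFAULT_OAT_MBP[name] * MBP) for name in order])
    assert layout.total_size == 10_272 * MBP
    return layout


def toy_layout(n_chromosomes: int = 2, length_mbp: int = 100,
               prefix: str = "chr") -> GenomeLayout:
    """Small uniform layout for tests and examples."""
    return GenomeLayout(
        [(f"{prefix}{i + 1}", length_mbp * MBP) for i in range(n_chromosomes)]
    )
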