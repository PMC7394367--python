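"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). SAM's
1-based POS is converted on ingest and nowhere else.

Formats handled here: SAM/BAM alignments (via pysam), UCSC chrom.sizes
tables, BED3+ peak files, WashU ``longrange`` interaction text, the calls
TSV, and the QC report JSON.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TYPE_CHECKING

import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .significance import InteractionCall

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "AlignedEnd",
    "UnmappedRecord",
    "AlignmentSet",
    "read_alignments",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "write_longrange",
    "read_longrange",
    "write_calls_tsv",
    "write_qc_json",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def validate_against(self, sizes: "ChromSizes") -> None:
        if self.chrom not in sizes:
            raise ValueError(f"chromosome {self.chrom!r} not in sizes table")
        if self.end > sizes[self.chrom]:
            raise ValueError(
                f"interval end {self.end} exceeds {self.chrom} length "
                f"{sizes[self.chrom]}"
            )


class ChromSizes:
    """Ordered chromosome name -> length (bp) mapping."""

    def __init__(self, sizes: Iterable[tuple[str, int]] | dict[str, int]):
        items = sizes.items() if isinstance(sizes, dict) else list(sizes)
        self._sizes: dict[str, int] = {}
        for name, length in items:
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"non-positive length for {name!r}: {length}")
            self._sizes[name] = int(length)
        if not self._sizes:
            raise ValueError("empty chromosome sizes table")

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChromSizes):
            return NotImplemented
        return self._sizes == other._sizes

    def items(self) -> Iterable[tuple[str, int]]:
        return self._sizes.items()

    def names(self) -> list[str]:
        return list(self._sizes)


@dataclass(frozen=True)
class AlignedEnd:
    """One mapped single-end alignment (0-based leftmost position)."""

    read_id: str
    chrom: str
    pos: int
    strand: str
    mapq: int
    rescued: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"MAPQ out of range: {self.mapq}")
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")


@dataclass(frozen=True)
class UnmappedRecord:
    read_id: str
    seq: str


@dataclass
class AlignmentSet:
    """Result of reading one mate file: mapped ends plus unmapped records."""

    ends: list[AlignedEnd] = field(default_factory=list)
    unmapped: list[UnmappedRecord] = field(default_factory=list)
    chrom_sizes: ChromSizes | None = None

    @property
    def n_mapped(self) -> int:
        return len(self.ends)

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def read_alignments(path: str, keep_unmapped: bool = True) -> AlignmentSet:
    """Read a SAM/BAM file of single-end alignments.

    Returns one :class:`AlignedEnd` per mapped primary alignment; secondary
    and supplementary records are skipped. Unmapped records are collected
    (with sequence, for junction-trimming rescue) when ``keep_unmapped``.

    Raises ``ValueError`` if the header carries no sequence dictionary,
    which is required to cross-check chromosome sizes downstream.
    """
    result = AlignmentSet()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        if not fh.header.get("SQ"):
            raise ValueError(f"{path}: SAM header has no @SQ sequence dictionary")
        result.chrom_sizes = ChromSizes(
            (sq["SN"], sq["LN"]) for sq in fh.header["SQ"]
        )
        for rec in fh:
            if rec.is_unmapped:
                if keep_unmapped:
                    result.unmapped.append(
                        UnmappedRecord(rec.query_name, rec.query_sequence or "")
                    )
                else:
                    result.unmapped.append(UnmappedRecord(rec.query_name, ""))
                continue
            if rec.is_secondary or rec.is_supplementary:
                continue
            result.ends.append(
                AlignedEnd(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    pos=rec.reference_start,  # pysam already 0-based
                    strand="-" if rec.is_reverse else "+",
                    mapq=rec.mapping_quality,
                )
            )
    return result


def read_chrom_sizes(path: str) -> ChromSizes:
    """Read a two-column UCSC chrom.sizes TSV."""
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((fields[0], int(fields[1])))
    return ChromSizes(pairs)


def write_chrom_sizes(sizes: ChromSizes, path: str) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file into 0-based half-open intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _format_score(bf: float) -> str:
    return str(round(bf, 2))


def write_longrange(calls: "Iterable[InteractionCall]", path: str) -> None:
    """Write calls as WashU longrange text.

    One line per call: ``chrom  start  end  chrom2:start2-end2,score`` with
    the Bayes factor (rounded to 2 decimals) as score, sorted by anchor
    chromosome then start.
    """
    rows = []
    for call in calls:
        a = call.bait.interval
        b = call.target
        rows.append(
            (a.chrom, a.start, a.end, f"{b.chrom}:{b.start}-{b.end}",
             _format_score(call.bayes_factor))
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for chrom, start, end, partner, score in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{partner},{score}\n")


_LONGRANGE_PARTNER = re.compile(r"^([^:]+):(\d+)-(\d+),(.+)$")


def read_longrange(path: str) -> list[tuple[GenomicInterval, GenomicInterval, float]]:
    """Parse a longrange file back into (anchor, partner, score) triples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            m = _LONGRANGE_PARTNER.match(fields[3])
            if m is None:
                raise ValueError(f"{path}:{lineno}: bad partner field {fields[3]!r}")
            anchor = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            partner = GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)))
            out.append((anchor, partner, float(m.group(4))))
    return out


_CALLS_HEADER = [
    "bait_chrom", "bait_start", "bait_end",
    "target_chrom", "target_start", "target_end",
    "kind", "d", "count", "p_left", "p_survival", "bayes_factor", "significant",
]


def write_calls_tsv(calls: "Iterable[InteractionCall]", path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALLS_HEADER) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        c.bait.interval.chrom,
                        c.bait.interval.start,
                        c.bait.interval.end,
                        c.target.chrom,
                        c.target.start,
                        c.target.end,
                        c.kind,
                        c.distance_d if c.distance_d is not None else "NA",
                        c.count,
                        f"{c.p_left:.6g}",
                        f"{c.p_survival:.6g}",
                        f"{c.bayes_factor:.6g}",
                        int(c.significant),
                    )
                )
                + "\n"
            )


def write_qc_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
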