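"""PET classification, genome binning at bait resolution, and QC metrics.

Every PET falls into exactly one category relative to the bait: both ends
inside (self-ligated, dropped from calling), one end inside (the
interaction evidence, intra- or inter-chromosomal), or neither end inside
(background noise retained for model fitting). Bait-linked PETs are then
accumulated into per-bin contact counts: bait-sized bins on the bait
chromosome, 1 Mb bins elsewhere.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .bait_definition import BaitRegion
from .genomic_io import AlignedEnd, ChromSizes, GenomicInterval
from .read_processing import PET

logger = logging.getLogger(__name__)

__all__ = [
    "BinGrid",
    "ContactVector",
    "classify_pets",
    "bin_contacts",
    "qc_summary",
    "INTER_BIN_SIZE",
]

INTER_BIN_SIZE = 1_000_000


@dataclass
class BinGrid:
    """Fixed tiling of the genome anchored at coordinate 0.

    The bait chromosome is tiled in steps of the bait size ``l``; the bait
    interval replaces the bins it overlaps (it is its own bin, and the
    clipped remainders of its flanking bins count as distance d = 1).
    Other chromosomes are tiled at 1 Mb for inter-chromosomal calls.
    """

    chrom_sizes: ChromSizes
    bait: BaitRegion
    inter_bin_size: int = INTER_BIN_SIZE

    def __post_init__(self) -> None:
        if self.bait.chrom not in self.chrom_sizes:
            raise ValueError(f"bait chromosome {self.bait.chrom!r} not in sizes")
        self.bait.interval.validate_against(self.chrom_sizes)

    @property
    def bin_size(self) -> int:
        return self.bait.size_l

    @property
    def bait_chrom(self) -> str:
        return self.bait.chrom

    def n_intra_bins(self) -> int:
        """Number of regular (pre-bait-replacement) bins on the bait chromosome."""
        length = self.chrom_sizes[self.bait_chrom]
        return -(-length // self.bin_size)

    def bait_bin_indices(self) -> range:
        """Regular bin indices the bait interval overlaps."""
        l = self.bin_size
        return range(self.bait.interval.start // l, (self.bait.interval.end - 1) // l + 1)

    def intra_bin_interval(self, index: int) -> GenomicInterval:
        l = self.bin_size
        length = self.chrom_sizes[self.bait_chrom]
        return GenomicInterval(self.bait_chrom, index * l, min((index + 1) * l, length))

    def intra_bin(self, pos: int) -> tuple[GenomicInterval, int]:
        """Map a non-bait position on the bait chromosome to (bin, d).

        d is the distance multiplier: bin-centre distance to the bait
        centre in units of ``l``, rounded to the nearest integer, floored
        at 1. Bait-flanking partial bins (clipped by the bait) get d = 1.
        """
        bait_iv = self.bait.interval
        if bait_iv.contains(pos):
            raise ValueError("position lies inside the bait; not a contact bin")
        l = self.bin_size
        length = self.chrom_sizes[self.bait_chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {self.bait_chrom}")
        i = pos // l
        start, end = i * l, min((i + 1) * l, length)
        raw = GenomicInterval(self.bait_chrom, start, end)
        if raw.overlaps(bait_iv):
            if pos < bait_iv.start:
                clipped = GenomicInterval(self.bait_chrom, start, bait_iv.start)
            else:
                clipped = GenomicInterval(self.bait_chrom, bait_iv.end, end)
            return clipped, 1
        d = max(1, round(abs(raw.center - bait_iv.center) / l))
        return raw, d

    def inter_bin(self, chrom: str, pos: int) -> GenomicInterval:
        if chrom not in self.chrom_sizes:
            raise KeyError(chrom)
        length = self.chrom_sizes[chrom]
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom}")
        j = pos // self.inter_bin_size
        return GenomicInterval(
            chrom, j * self.inter_bin_size, min((j + 1) * self.inter_bin_size, length)
        )


@dataclass
class ContactVector:
    """Per-bin PET counts linking each bin to the bait."""

    intra: dict[GenomicInterval, int] = field(default_factory=dict)
    intra_d: dict[GenomicInterval, int] = field(default_factory=dict)
    inter: dict[GenomicInterval, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.intra.values()) + sum(self.inter.values())


def _nonbait_end(pet: PET, bait: BaitRegion) -> AlignedEnd:
    iv = bait.interval
    in1 = pet.end1.chrom == iv.chrom and iv.contains(pet.end1.pos)
    return pet.end2 if in1 else pet.end1


def classify_pets(pets: list[PET], bait: BaitRegion) -> tuple[list[PET], Counter]:
    """Assign each PET its category relative to the bait interval.

    Membership uses the end's leftmost mapped position (half-open test).
    Returns the relabelled PETs and a category tally.
    """
    iv = bait.interval
    out = []
    tally: Counter = Counter()
    for pet in pets:
        in1 = pet.end1.chrom == iv.chrom and iv.contains(pet.end1.pos)
        in2 = pet.end2.chrom == iv.chrom and iv.contains(pet.end2.pos)
        if in1 and in2:
            cat = "self_ligated"
        elif in1 or in2:
            cat = "bait_intra" if pet.is_intra else "bait_inter"
        else:
            cat = "background_intra" if pet.is_intra else "background_inter"
        tally[cat] += 1
        out.append(pet.with_category(cat))
    return out, tally


def bin_contacts(pets: list[PET], grid: BinGrid) -> ContactVector:
    """Accumulate bait-linked PETs into per-bin contact counts."""
    cv = ContactVector()
    for pet in pets:
        if pet.category == "bait_intra":
            end = _nonbait_end(pet, grid.bait)
            bin_iv, d = grid.intra_bin(end.pos)
            cv.intra[bin_iv] = cv.intra.get(bin_iv, 0) + 1
            cv.intra_d[bin_iv] = d
        elif pet.category == "bait_inter":
            end = _nonbait_end(pet, grid.bait)
            if end.chrom not in grid.chrom_sizes:
                logger.warning("dropping PET on unknown chromosome %s", end.chrom)
                continue
            bin_iv = grid.inter_bin(end.chrom, end.pos)
            cv.inter[bin_iv] = cv.inter.get(bin_iv, 0) + 1
    return cv


_QC_DISTANCE_FOCUS = 1_000_000  # +/- window of the intra distance summary


def qc_summary(
    pets: list[PET],
    bait: BaitRegion,
    alignment_stats: dict | None = None,
    histogram_bin: int = 100_000,
) -> dict:
    """Build the QC report from classified PETs.

    Reports category counts and percentages (one decimal, over the
    bait-linked total), the intra-chromosomal distance summary focused on
    +/- 1 Mb around the bait, 5'/3' directional counts with their fold
    ratio (two decimals), and per-chromosome inter-chromosomal counts.
    """
    tally = Counter(p.category for p in pets)
    n_self = tally.get("self_ligated", 0)
    n_intra = tally.get("bait_intra", 0)
    n_inter = tally.get("bait_inter", 0)
    total = n_self + n_intra + n_inter

    report: dict = {
        "alignment": alignment_stats,
        "total_pets": total,
        "background_pets": {
            "intra": tally.get("background_intra", 0),
            "inter": tally.get("background_inter", 0),
        },
        "categories": {
            "counts": {
                "self_ligated": n_self,
                "bait_intra": n_intra,
                "bait_inter": n_inter,
            },
        },
    }
    if total == 0:
        logger.warning("QC on zero bait-linked PETs")
        report["categories"]["percent"] = None
        report["intra"] = None
        report["inter"] = None
        return report

    report["categories"]["percent"] = {
        "self_ligated": round(100.0 * n_self / total, 1),
        "bait_intra": round(100.0 * n_intra / total, 1),
        "bait_inter": round(100.0 * n_inter / total, 1),
    }

    center = bait.interval.center
    distances = [
        _nonbait_end(p, bait).pos - center
        for p in pets
        if p.category == "bait_intra"
    ]
    within = sum(1 for dist in distances if abs(dist) <= _QC_DISTANCE_FOCUS)
    downstream = sum(1 for dist in distances if dist > 0)
    upstream = sum(1 for dist in distances if dist < 0)
    hist: dict[str, int] = {}
    for dist in distances:
        if abs(dist) > _QC_DISTANCE_FOCUS:
            key = "beyond"
        else:
            lo = int(dist // histogram_bin) * histogram_bin
            key = f"{lo}:{lo + histogram_bin}"
        hist[key] = hist.get(key, 0) + 1
    report["intra"] = {
        "n": n_intra,
        "within_1mb": within,
        "within_1mb_percent": round(100.0 * within / n_intra, 2) if n_intra else None,
        "downstream": downstream,
        "upstream": upstream,
        "downstream_upstream_fold": (
            round(downstream / upstream, 2) if upstream else None
        ),
        "distance_histogram": dict(sorted(hist.items())),
    }

    per_chrom: Counter = Counter(
        _nonbait_end(p, bait).chrom for p in pets if p.category == "bait_inter"
    )
    report["inter"] = {"n": n_inter, "per_chrom": dict(sorted(per_chrom.items()))}
    return report
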