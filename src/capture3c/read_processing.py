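"""Read rescue, quality filtering, mate pairing and PCR de-duplication.

Turns two single-end alignment sets (one per mate) into a clean set of
paired-end tags (PETs). Unmapped reads that contain a DpnII ``GATC``
junction can be rescued by keeping their longest fragment; remapping is
delegated to an external aligner or, in synthetic mode, to a lookup of
pre-aligned rescue records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .genomic_io import AlignedEnd, UnmappedRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PET",
    "TrimResult",
    "trim_at_dpnii",
    "filter_mapq",
    "pair_ends",
    "dedup_pets",
    "rescue_unmapped",
    "write_pet_table",
    "read_pet_table",
    "CATEGORIES",
]

DPNII_SITE = "GATC"
CATEGORIES = (
    "unclassified",
    "self_ligated",
    "bait_intra",
    "bait_inter",
    "background_intra",
    "background_inter",
)


@dataclass(frozen=True)
class PET:
    """A paired-end tag: two aligned ends in canonical (chrom, pos) order."""

    end1: AlignedEnd
    end2: AlignedEnd
    category: str = "unclassified"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown PET category {self.category!r}")

    @property
    def read_id(self) -> str:
        return self.end1.read_id

    @property
    def is_intra(self) -> bool:
        return self.end1.chrom == self.end2.chrom

    def with_category(self, category: str) -> "PET":
        return replace(self, category=category)

    @property
    def dedup_key(self) -> tuple:
        return (
            self.end1.chrom, self.end1.pos, self.end1.strand,
            self.end2.chrom, self.end2.pos, self.end2.strand,
        )


def make_pet(end1: AlignedEnd, end2: AlignedEnd, category: str = "unclassified") -> PET:
    """Build a PET with ends in canonical (chrom, pos) order."""
    if (end2.chrom, end2.pos) < (end1.chrom, end1.pos):
        end1, end2 = end2, end1
    return PET(end1, end2, category)


@dataclass(frozen=True)
class TrimResult:
    fragment: str
    offset: int
    kept: bool


def trim_at_dpnii(seq: str, min_fragment: int = 20, keep_site: bool = True) -> TrimResult:
    """Split ``seq`` at every DpnII site and return the longest fragment.

    DpnII cuts 5' of GATC, so each fragment after the first starts with the
    site (``keep_site=True``); with ``keep_site=False`` the site itself is
    dropped from downstream fragments. Ties go to the 5'-most fragment.
    ``kept`` requires fragment length strictly greater than ``min_fragment``.
    """
    if not seq:
        return TrimResult("", 0, False)
    cut_points = []
    i = seq.find(DPNII_SITE)
    while i != -1:
        cut_points.append(i)
        i = seq.find(DPNII_SITE, i + 1)
    starts = [0]
    for cp in cut_points:
        if cp > 0:  # a site at position 0 does not create an empty fragment
            starts.append(cp)
    fragments = []
    for j, s in enumerate(starts):
        e = starts[j + 1] if j + 1 < len(starts) else len(seq)
        frag = seq[s:e]
        off = s
        if not keep_site and s != 0 and frag.startswith(DPNII_SITE):
            frag = frag[len(DPNII_SITE):]
            off = s + len(DPNII_SITE)
        fragments.append((frag, off))
    best_frag, best_off = max(fragments, key=lambda fo: len(fo[0]))
    # max() is stable only for strict maxima; enforce 5'-most on ties
    best_len = len(best_frag)
    for frag, off in fragments:
        if len(frag) == best_len:
            best_frag, best_off = frag, off
            break
    return TrimResult(best_frag, best_off, len(best_frag) > min_fragment)


def filter_mapq(ends: Iterable[AlignedEnd], threshold: int = 30) -> list[AlignedEnd]:
    """Keep only ends with MAPQ strictly greater than ``threshold``."""
    return [e for e in ends if e.mapq > threshold]


_MATE_SUFFIXES = ("/1", "/2")


def canonical_read_id(read_id: str) -> str:
    """Strip mate suffixes (/1, /2) and trailing space-comments."""
    rid = read_id.split(" ", 1)[0].split("\t", 1)[0]
    for suffix in _MATE_SUFFIXES:
        if rid.endswith(suffix):
            return rid[: -len(suffix)]
    return rid


def _index_by_read_id(ends: Iterable[AlignedEnd]) -> dict[str, AlignedEnd]:
    index: dict[str, AlignedEnd] = {}
    dups = 0
    for end in ends:
        rid = canonical_read_id(end.read_id)
        if rid in index:
            dups += 1
            continue  # keep first occurrence
        index[rid] = end
    if dups:
        logger.warning("dropped %d duplicate read ids within one mate file", dups)
    return index


def pair_ends(
    ends1: Iterable[AlignedEnd], ends2: Iterable[AlignedEnd]
) -> tuple[list[PET], int]:
    """Pair mates by read id; returns (PETs, orphan count).

    Read ids present in only one input are orphans. PET ends are stored in
    canonical (chrom, pos) order.
    """
    idx1 = _index_by_read_id(ends1)
    idx2 = _index_by_read_id(ends2)
    shared = [rid for rid in idx1 if rid in idx2]
    orphans = (len(idx1) - len(shared)) + (len(idx2) - len(shared))
    pets = [make_pet(idx1[rid], idx2[rid]) for rid in shared]
    return pets, orphans


def dedup_pets(pets: Iterable[PET], use_strand: bool = True) -> list[PET]:
    """Drop PCR duplicates: PETs with identical positions at both ends.

    The duplicate key is (chrom, pos, strand) of both ends; set
    ``use_strand=False`` for a position-only key. The first PET per key is
    retained; output is sorted by key for determinism.
    """
    seen: dict[tuple, PET] = {}
    for pet in pets:
        key = pet.dedup_key
        if not use_strand:
            key = (key[0], key[1], key[3], key[4])
        if key not in seen:
            seen[key] = pet
    return [seen[k] for k in sorted(seen)]


def rescue_unmapped(
    unmapped: Iterable[UnmappedRecord],
    remapped: Mapping[str, AlignedEnd],
    min_fragment: int = 20,
) -> list[AlignedEnd]:
    """Rescue unmapped reads whose longest GATC fragment exceeds the cutoff.

    ``remapped`` maps canonical read id -> the alignment of the trimmed
    fragment (produced by an external aligner, or by the simulator in
    synthetic mode). Reads whose trim is not kept, or with no remap record,
    are dropped. Rescued ends are flagged so QC can report the rescue rate.
    """
    rescued = []
    for rec in unmapped:
        trim = trim_at_dpnii(rec.seq, min_fragment=min_fragment)
        if not trim.kept:
            continue
        hit = remapped.get(canonical_read_id(rec.read_id))
        if hit is None:
            continue
        rescued.append(replace(hit, rescued=True))
    return rescued


_PET_HEADER = [
    "read_id",
    "chrom1", "pos1", "strand1", "mapq1",
    "chrom2", "pos2", "strand2", "mapq2",
    "category",
]


def write_pet_table(pets: Iterable[PET], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PET_HEADER) + "\n")
        for p in pets:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        p.read_id,
                        p.end1.chrom, p.end1.pos, p.end1.strand, p.end1.mapq,
                        p.end2.chrom, p.end2.pos, p.end2.strand, p.end2.mapq,
                        p.category,
                    )
                )
                + "\n"
            )


def read_pet_table(path: str) -> list[PET]:
    pets = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PET_HEADER:
            raise ValueError(f"{path}: unexpected PET table header")
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_PET_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_PET_HEADER)} columns")
            end1 = AlignedEnd(f[0], f[1], int(f[2]), f[3], int(f[4]))
            end2 = AlignedEnd(f[0], f[5], int(f[6]), f[7], int(f[8]))
            pets.append(PET(end1, end2, f[9]))
    return pets


def process_alignments(
    ends1: Iterable[AlignedEnd],
    ends2: Iterable[AlignedEnd],
    min_mapq: int = 30,
) -> tuple[list[PET], dict]:
    """Filter, pair and de-duplicate two mate alignment streams.

    Returns the deduplicated PET list and a stats dict for QC. Rescued ends
    should already be merged into the inputs (quality filtering is applied
    after merging originals with rescues).
    """
    ends1 = list(ends1)
    ends2 = list(ends2)
    kept1 = filter_mapq(ends1, min_mapq)
    kept2 = filter_mapq(ends2, min_mapq)
    pets, orphans = pair_ends(kept1, kept2)
    deduped = dedup_pets(pets)
    stats = {
        "input_ends": [len(ends1), len(ends2)],
        "mapq_filtered_ends": [len(kept1), len(kept2)],
        "paired_pets": len(pets),
        "orphans": orphans,
        "dedup_pets": len(deduped),
        "duplicate_pets_removed": len(pets) - len(deduped),
    }
    return deduped, stats
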