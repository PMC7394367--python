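"""Synthetic capture-3C library generator with a full truth table.

Emits PET sets (and optionally SAM files) with the statistical structure
the calling model assumes: a dominant self-ligation bulk, distance-decaying
overdispersed intra-chromosomal bin-pair noise, sparse uniform
inter-chromosomal noise, spiked true interactions, PCR duplicates, and
chimeric unmapped reads carrying a GATC junction. Every read is labelled in
the truth table, so each pipeline stage can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .genomic_io import AlignedEnd, ChromSizes, GenomicInterval
from .read_processing import PET, make_pet

__all__ = [
    "SimConfig",
    "TruthTable",
    "default_intra_truth",
    "simulate_pets",
    "simulate_sam",
]

_SEQ_ALPHABET = np.array(list("ACT"))  # G-free so fragments carry no GATC


def default_intra_truth(
    d_max: int = 8, r: float = 2.0, mu0: float = 0.4
) -> dict[int, tuple[float, float]]:
    """Decaying per-distance NB truth: mean mu0/d at separation d, shared r."""
    truth = {}
    for d in range(1, d_max + 1):
        mu = mu0 / d
        truth[d] = (r, mu / (r + mu))  # mean = r p/(1-p)  =>  p = mu/(r+mu)
    return truth


@dataclass
class SimConfig:
    seed: int
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000
        }
    )
    bait_chrom: str = "chr1"
    bait_start: int = 5_000_000
    bait_width: int = 2_500
    n_pets: int = 12_000  # bait-linked PETs (self + intra + inter)
    self_fraction: float = 0.985
    intra_fraction: float = 0.010
    inter_fraction: float = 0.005
    # background-noise truth (per bin-pair contact counts on the bait chromosome)
    intra_truth: dict[int, tuple[float, float]] = field(
        default_factory=default_intra_truth
    )
    pooled_truth: tuple[float, float] = (1.0, 0.05)
    pooled_d_range: tuple[int, int] = (9, 40)
    inter_noise_rate: dict[str, float] = field(
        default_factory=lambda: {"chr2": 800.0, "chr3": 800.0}
    )
    # spiked true interactions: (target interval, extra PET count)
    spikes: list[tuple[GenomicInterval, int]] = field(default_factory=list)
    intra_decay_scale: float = 400_000.0  # bp, for bait-linked intra placement
    downstream_bias: float = 0.5
    duplication_rate: float = 0.0
    chimera_fraction: float = 0.0
    read_length: int = 50
    mapq_high: int = 42
    mapq_low: int = 10
    mapq_low_prob: float = 0.1

    def __post_init__(self) -> None:
        fracs = (self.self_fraction, self.intra_fraction, self.inter_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0 + 1e-9:
            raise ValueError("category fractions must lie in [0,1] and sum <= 1")
        if self.bait_chrom not in self.chrom_sizes:
            raise ValueError("bait chromosome missing from chrom_sizes")
        bait = self.bait_interval
        for iv, _count in self.spikes:
            if iv.overlaps(bait):
                raise ValueError(f"spiked bin {iv} overlaps the bait region")
            if iv.chrom not in self.chrom_sizes:
                raise ValueError(f"spiked bin chromosome {iv.chrom!r} unknown")

    @property
    def bait_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.bait_chrom, self.bait_start, self.bait_start + self.bait_width
        )

    @property
    def sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_sizes)


@dataclass
class TruthTable:
    categories: dict[str, str]  # read_id -> true category
    spiked_bins: list[GenomicInterval]
    intra_truth: dict[int, tuple[float, float]]
    pooled_truth: tuple[float, float]
    inter_noise_rate: dict[str, float]
    duplicate_of: dict[str, str] = field(default_factory=dict)
    # read_id -> (mate, true alignment) for reads emitted as unmapped chimeras
    chimeras: dict[tuple[str, int], AlignedEnd] = field(default_factory=dict)

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cat in self.categories.values():
            out[cat] = out.get(cat, 0) + 1
        return out

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcategory\tduplicate_of\n")
            for rid, cat in self.categories.items():
                fh.write(f"{rid}\t{cat}\t{self.duplicate_of.get(rid, '')}\n")


class _PetFactory:
    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.counter = 0

    def next_id(self) -> str:
        self.counter += 1
        return f"SIM{self.counter:08d}"

    def end(self, read_id: str, chrom: str, pos: int) -> AlignedEnd:
        strand = "+" if self.rng.random() < 0.5 else "-"
        mapq = (
            self.config.mapq_low
            if self.rng.random() < self.config.mapq_low_prob
            else self.config.mapq_high
        )
        return AlignedEnd(read_id, chrom, int(pos), strand, mapq)

    def pet(self, chrom1: str, pos1: int, chrom2: str, pos2: int) -> PET:
        rid = self.next_id()
        return make_pet(self.end(rid, chrom1, pos1), self.end(rid, chrom2, pos2))


def _uniform_in(rng: np.random.Generator, iv: GenomicInterval) -> int:
    return int(rng.integers(iv.start, iv.end))


def simulate_pets(config: SimConfig) -> tuple[list[PET], TruthTable]:
    """Draw a full PET library plus its truth table. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    factory = _PetFactory(config, rng)
    bait = config.bait_interval
    sizes = config.sizes
    bait_len = sizes[config.bait_chrom]
    l = config.bait_width

    pets: list[PET] = []
    categories: dict[str, str] = {}

    def add(pet: PET, category: str) -> None:
        pets.append(pet)
        categories[pet.read_id] = category

    rest = max(0.0, 1.0 - config.self_fraction - config.intra_fraction - config.inter_fraction)
    n_self, n_intra, n_inter, _ = rng.multinomial(
        config.n_pets,
        [config.self_fraction, config.intra_fraction, config.inter_fraction, rest],
    )

    for _ in range(n_self):
        add(
            factory.pet(
                bait.chrom, _uniform_in(rng, bait), bait.chrom, _uniform_in(rng, bait)
            ),
            "self_ligated",
        )

    center = bait.center
    for _ in range(n_intra):
        while True:
            sign = 1 if rng.random() < config.downstream_bias else -1
            dist = rng.exponential(config.intra_decay_scale) + l
            pos = int(center + sign * dist)
            if 0 <= pos < bait_len and not bait.contains(pos):
                break
        add(factory.pet(bait.chrom, _uniform_in(rng, bait), bait.chrom, pos), "bait_intra")

    other_chroms = [c for c in sizes if c != config.bait_chrom]
    for _ in range(n_inter):
        chrom = other_chroms[int(rng.integers(len(other_chroms)))]
        pos = int(rng.integers(0, sizes[chrom]))
        add(factory.pet(bait.chrom, _uniform_in(rng, bait), chrom, pos), "bait_inter")

    # intra background: iid NB counts per ordered bin pair at each separation
    n_bins = bait_len // l
    bait_bins = set(range(bait.start // l, (bait.end - 1) // l + 1))
    strata = [(d, r, p) for d, (r, p) in sorted(config.intra_truth.items())]
    lo, hi = config.pooled_d_range
    strata += [(d, *config.pooled_truth) for d in range(lo, hi + 1)]
    for d, r, p in strata:
        starts = np.array(
            [b for b in range(n_bins - d) if b not in bait_bins and (b + d) not in bait_bins]
        )
        if len(starts) == 0:
            continue
        counts = rng.negative_binomial(r, 1.0 - p, size=len(starts))
        for b, k in zip(starts[counts > 0], counts[counts > 0]):
            for _ in range(int(k)):
                pos1 = int(rng.integers(b * l, (b + 1) * l))
                pos2 = int(rng.integers((b + d) * l, (b + d + 1) * l))
                add(factory.pet(bait.chrom, pos1, bait.chrom, pos2), "background_intra")

    # inter background: Poisson totals, ends uniform (bait interval avoided)
    for chrom, rate in config.inter_noise_rate.items():
        if chrom == config.bait_chrom or chrom not in sizes:
            raise ValueError(f"bad inter_noise_rate chromosome {chrom!r}")
        n_c = int(rng.poisson(rate))
        for _ in range(n_c):
            while True:
                pos1 = int(rng.integers(0, bait_len))
                if not bait.contains(pos1):
                    break
            pos2 = int(rng.integers(0, sizes[chrom]))
            add(factory.pet(bait.chrom, pos1, chrom, pos2), "background_inter")

    # spiked true interactions last (extra PETs on top of the noise library,
    # so adding spikes leaves the noise stream of a given seed untouched)
    for iv, count in config.spikes:
        cat = "bait_intra" if iv.chrom == bait.chrom else "bait_inter"
        for _ in range(count):
            add(
                factory.pet(bait.chrom, _uniform_in(rng, bait), iv.chrom, _uniform_in(rng, iv)),
                cat,
            )

    truth = TruthTable(
        categories=categories,
        spiked_bins=[iv for iv, _ in config.spikes],
        intra_truth=dict(config.intra_truth),
        pooled_truth=config.pooled_truth,
        inter_noise_rate=dict(config.inter_noise_rate),
    )

    # PCR duplicates: exact positional copies under fresh read ids
    n_dup = int(round(config.duplication_rate * len(pets)))
    if n_dup:
        originals = list(pets)
        for idx in rng.integers(0, len(originals), size=n_dup):
            src = originals[int(idx)]
            rid = factory.next_id()
            dup = PET(
                AlignedEnd(rid, src.end1.chrom, src.end1.pos, src.end1.strand, src.end1.mapq),
                AlignedEnd(rid, src.end2.chrom, src.end2.pos, src.end2.strand, src.end2.mapq),
            )
            pets.append(dup)
            categories[rid] = categories[src.read_id]
            truth.duplicate_of[rid] = src.read_id

    return pets, truth


def _sam_header(sizes: ChromSizes) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in sizes.items()],
        }
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_SEQ_ALPHABET, size=length))


def _mapped_record(
    header: pysam.AlignmentHeader, end: AlignedEnd, read_length: int
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = end.read_id
    a.flag = 16 if end.strand == "-" else 0
    a.reference_id = header.get_tid(end.chrom)
    a.reference_start = end.pos
    a.mapping_quality = end.mapq
    a.cigartuples = [(0, read_length)]
    return a


def _unmapped_record(
    header: pysam.AlignmentHeader, read_id: str, seq: str
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = read_id
    a.flag = 4
    a.query_sequence = seq
    return a


def simulate_sam(
    pets: list[PET],
    config: SimConfig,
    sam1: str,
    sam2: str,
    rescue_sam1: str | None = None,
    rescue_sam2: str | None = None,
    truth: TruthTable | None = None,
) -> None:
    """Write the two mate SAM files (plus rescue SAMs for chimeric reads).

    A ``chimera_fraction`` of ends is emitted unmapped with sequence
    fragA + GATC + fragB; the longer fragment corresponds to the end's true
    locus, whose alignment is written to the per-mate rescue SAM (standing
    in for the external remapping step). Deterministic per config seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    header = _sam_header(config.sizes)
    rl = config.read_length
    short_len = max(1, min(15, rl // 4))
    long_len = max(rl - short_len - 4, 21)  # rescuable by construction

    with pysam.AlignmentFile(sam1, "w", header=header) as out1, pysam.AlignmentFile(
        sam2, "w", header=header
    ) as out2:
        res1 = pysam.AlignmentFile(rescue_sam1, "w", header=header) if rescue_sam1 else None
        res2 = pysam.AlignmentFile(rescue_sam2, "w", header=header) if rescue_sam2 else None
        try:
            for pet in pets:
                for mate, end, out, res in (
                    (1, pet.end1, out1, res1),
                    (2, pet.end2, out2, res2),
                ):
                    if config.chimera_fraction and rng.random() < config.chimera_fraction:
                        seq = (
                            _random_seq(rng, short_len)
                            + "GATC"
                            + _random_seq(rng, long_len - 4)
                        )
                        out.write(_unmapped_record(header, end.read_id, seq))
                        if res is not None:
                            res.write(_mapped_record(header, end, long_len))
                        if truth is not None:
                            truth.chimeras[(end.read_id, mate)] = end
                    else:
                        out.write(_mapped_record(header, end, rl))
        finally:
            if res1 is not None:
                res1.close()
            if res2 is not None:
                res2.close()
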