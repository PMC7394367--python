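"""End-to-end orchestration: PETs -> classification -> backgrounds -> calls."""

from __future__ import annotations

from dataclasses import dataclass, field

from .background_models import (
    DEFAULT_D_MAX,
    DEFAULT_N_PAIRS,
    IntraBackground,
    InterBackground,
    build_inter_background,
    build_intra_background,
)
from .bait_definition import BaitRegion
from .genomic_io import ChromSizes
from .pet_classification import BinGrid, ContactVector, bin_contacts, classify_pets, qc_summary
from .read_processing import PET
from .significance import CallingConfig, InteractionCall, call_interactions

__all__ = ["PipelineResult", "run_calling"]


@dataclass
class PipelineResult:
    pets: list[PET]
    grid: BinGrid
    contacts: ContactVector
    intra_background: IntraBackground
    inter_background: InterBackground | None
    calls: list[InteractionCall]
    qc: dict = field(default_factory=dict)


def run_calling(
    pets: list[PET],
    bait: BaitRegion,
    chrom_sizes: ChromSizes,
    config: CallingConfig = CallingConfig(),
    seed: int = 0,
    n_pairs: int = DEFAULT_N_PAIRS,
    d_max_bp: int = DEFAULT_D_MAX,
    max_pooled_d: int | None = None,
    alignment_stats: dict | None = None,
) -> PipelineResult:
    """Classify deduplicated PETs, fit backgrounds and call interactions."""
    classified, _tally = classify_pets(pets, bait)
    grid = BinGrid(chrom_sizes, bait)
    contacts = bin_contacts(classified, grid)
    intra_bg = build_intra_background(
        classified, grid, d_max_bp=d_max_bp, n=n_pairs, seed=seed,
        max_pooled_d=max_pooled_d,
    )
    inter_bg = (
        build_inter_background(classified, chrom_sizes, grid, n=n_pairs, seed=seed)
        if len(chrom_sizes) >= 2
        else None
    )
    calls = call_interactions(contacts, bait, intra_bg, inter_bg, config)
    qc = qc_summary(classified, bait, alignment_stats=alignment_stats)
    return PipelineResult(classified, grid, contacts, intra_bg, inter_bg, calls, qc)
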