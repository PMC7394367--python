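"""Interaction significance: left-tail P-values and Bayes factors.

The significance of an observed bait-to-bin count x is measured against
the fitted noise model as the left-tail probability p_left = P(X < x):
LARGER p_left means the observation is further into the upper tail of the
noise and hence MORE significant (the inverse of the usual P-value
convention; the conventional survival probability P(X >= x) is reported
alongside). The decision statistic is a Bayes factor built from p_left
and the prior odds:

    BF = prior_odds * p_left / (1 - p_left)

With the default prior odds 0.001 and threshold 20, a call is significant
exactly when P(X >= x) < 1/20001 (about 5e-5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .bait_definition import BaitRegion
from .background_models import IntraBackground, InterBackground, NBParams
from .genomic_io import GenomicInterval
from .pet_classification import ContactVector

logger = logging.getLogger(__name__)

__all__ = [
    "CallingConfig",
    "InteractionCall",
    "left_tail_p",
    "survival_p",
    "bayes_factor",
    "call_interactions",
    "BF_CAP",
]

BF_CAP = 1e12


@dataclass(frozen=True)
class CallingConfig:
    prior_odds: float = 0.001  # P(H1)/P(H0)
    bf_threshold: float = 20.0
    min_count: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.prior_odds <= 1:
            raise ValueError("prior_odds must be in (0, 1]")
        if self.bf_threshold <= 0:
            raise ValueError("bf_threshold must be positive")


@dataclass(frozen=True)
class InteractionCall:
    bait: BaitRegion
    target: GenomicInterval
    kind: str  # intra | inter
    distance_d: int | None
    count: int
    p_left: float
    p_survival: float
    bayes_factor: float
    significant: bool
    background_ref: str


def left_tail_p(x: int, model: NBParams) -> float:
    """P(X < x) under the background model.

    x = 0 is the empty event (p_left = 0). A degenerate (all-zero)
    background gives p_left = 1 for any positive count.
    """
    if x < 0:
        raise ValueError("count must be non-negative")
    if x == 0:
        return 0.0
    if model.degenerate:
        return 1.0
    return float(model.cdf(x - 1))


def survival_p(x: int, model: NBParams) -> float:
    """P(X >= x) under the background model (conventional upper tail)."""
    if x < 0:
        raise ValueError("count must be non-negative")
    if x == 0:
        return 1.0
    if model.degenerate:
        return 0.0
    return float(model.sf(x - 1))


def bayes_factor(p_left: float, config: CallingConfig = CallingConfig()) -> float:
    """BF = prior_odds * p_left / (1 - p_left), capped at ``BF_CAP``."""
    if not 0.0 <= p_left <= 1.0:
        raise ValueError("p_left must be in [0, 1]")
    if p_left >= 1.0:
        return BF_CAP
    bf = config.prior_odds * p_left / (1.0 - p_left)
    return min(bf, BF_CAP)


def _make_call(
    bait: BaitRegion,
    target: GenomicInterval,
    kind: str,
    d: int | None,
    count: int,
    model: NBParams,
    config: CallingConfig,
    ref: str,
) -> InteractionCall:
    p_lo = left_tail_p(count, model)
    p_hi = survival_p(count, model)
    bf = bayes_factor(p_lo, config)
    if model.degenerate:
        logger.warning(
            "degenerate background %s: count %d at %s:%d-%d is maximally "
            "significant; background is likely under-sampled",
            ref, count, target.chrom, target.start, target.end,
        )
    return InteractionCall(
        bait=bait,
        target=target,
        kind=kind,
        distance_d=d,
        count=count,
        p_left=p_lo,
        p_survival=p_hi,
        bayes_factor=bf,
        significant=bf > config.bf_threshold,
        background_ref=ref,
    )


def call_interactions(
    contacts: ContactVector,
    bait: BaitRegion,
    intra_bg: IntraBackground | None,
    inter_bg: InterBackground | None,
    config: CallingConfig = CallingConfig(),
) -> list[InteractionCall]:
    """Evaluate every contacted bin against its background model.

    Intra bins use the model of their distance stratum (pooled beyond the
    cutoff); inter bins use the target chromosome's model. Bins whose model
    is missing get a null-statistics call and a warning. Calls are sorted
    by Bayes factor descending, then position.
    """
    calls: list[InteractionCall] = []
    if intra_bg is not None:
        for bin_iv, count in contacts.intra.items():
            if count < config.min_count:
                continue
            d = contacts.intra_d[bin_iv]
            model = intra_bg.model_for(d)
            ref = f"intra:d={d}" if d * intra_bg.l <= intra_bg.d_max_bp else "intra:pooled"
            calls.append(_make_call(bait, bin_iv, "intra", d, count, model, config, ref))
    if inter_bg is not None:
        for bin_iv, count in contacts.inter.items():
            if count < config.min_count:
                continue
            model = inter_bg.model_for(bin_iv.chrom)
            if model is None:
                logger.warning("no background model for chromosome %s", bin_iv.chrom)
                calls.append(
                    InteractionCall(
                        bait, bin_iv, "inter", None, count,
                        float("nan"), float("nan"), float("nan"), False,
                        f"inter:{bin_iv.chrom}:missing",
                    )
                )
                continue
            calls.append(
                _make_call(
                    bait, bin_iv, "inter", None, count, model, config,
                    f"inter:{bin_iv.chrom}",
                )
            )
    calls.sort(
        key=lambda c: (
            -(c.bayes_factor if c.bayes_factor == c.bayes_factor else -1.0),
            c.target.chrom,
            c.target.start,
        )
    )
    return calls
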