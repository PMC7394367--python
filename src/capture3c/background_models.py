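"""Distance-stratified negative-binomial noise models.

Random ligation noise is modelled as a family of negative binomials over
contact counts between randomly sampled bin pairs: one model per distance
stratum ``d`` (bin separation in units of the bait size ``l``) up to a
distance cutoff, a pooled model beyond it, and one model per chromosome
pair for inter-chromosomal contacts.

Parameterization (used everywhere in this package)::

    P(X = x) = C(x + r - 1, x) * (1 - p)^r * p^x

so mean = r p/(1-p), variance = r p/(1-p)^2 and variance/mean = 1/(1-p),
which exceeds 1 for any p in (0, 1). SciPy's ``nbinom`` uses the success
probability of the *failure* term; the conversion (scipy p = 1 - p) is
confined to this module.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .genomic_io import ChromSizes
from .pet_classification import BinGrid
from .read_processing import PET

logger = logging.getLogger(__name__)

__all__ = [
    "NBParams",
    "IntraBackground",
    "InterBackground",
    "fit_nb",
    "sample_intra_pairs",
    "build_intra_background",
    "build_inter_background",
    "DEFAULT_D_MAX",
    "DEFAULT_N_PAIRS",
]

DEFAULT_D_MAX = 20_000  # bp; per-distance models for d*l <= this, pooled beyond
DEFAULT_N_PAIRS = 10_000
DEFAULT_MIN_OBS = 30


@dataclass(frozen=True)
class NBParams:
    """Fitted background distribution in the (r, p) parameterization.

    ``fit_method`` is one of ``mle``, ``moments``, ``poisson_fallback``
    (underdispersed sample; ``p -> 0`` limit, pmf = Poisson(``mu``)) or
    ``degenerate`` (all-zero sample; point mass at zero).
    """

    r: float
    p: float
    fit_method: str
    n_obs: int
    mu: float = 0.0  # Poisson-fallback mean; unused otherwise

    def __post_init__(self) -> None:
        if self.fit_method in ("mle", "moments"):
            if not (self.r > 0 and 0 < self.p < 1):
                raise ValueError(f"invalid NB parameters r={self.r}, p={self.p}")

    @property
    def degenerate(self) -> bool:
        return self.fit_method == "degenerate"

    @property
    def mean(self) -> float:
        if self.degenerate:
            return 0.0
        if self.fit_method == "poisson_fallback":
            return self.mu
        return self.r * self.p / (1.0 - self.p)

    @property
    def variance(self) -> float:
        if self.degenerate:
            return 0.0
        if self.fit_method == "poisson_fallback":
            return self.mu
        return self.r * self.p / (1.0 - self.p) ** 2

    @property
    def var_mean_ratio(self) -> float:
        if self.degenerate or self.fit_method == "poisson_fallback":
            return 1.0
        return 1.0 / (1.0 - self.p)

    def _frozen(self):
        if self.fit_method == "poisson_fallback":
            return stats.poisson(self.mu)
        return stats.nbinom(self.r, 1.0 - self.p)

    def pmf(self, x) -> np.ndarray | float:
        if self.degenerate:
            return np.where(np.asarray(x) == 0, 1.0, 0.0)
        return self._frozen().pmf(x)

    def cdf(self, x) -> np.ndarray | float:
        """P(X <= x)."""
        if self.degenerate:
            return np.where(np.asarray(x) >= 0, 1.0, 0.0)
        return self._frozen().cdf(x)

    def sf(self, x) -> np.ndarray | float:
        """P(X > x)."""
        if self.degenerate:
            return np.where(np.asarray(x) >= 0, 0.0, 1.0)
        return self._frozen().sf(x)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "fit_method": self.fit_method,
            "n_obs": self.n_obs,
            "mu": self.mu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NBParams":
        return cls(d["r"], d["p"], d["fit_method"], d["n_obs"], d.get("mu", 0.0))


def _nb_negloglik(log_r: float, logit_p: float, values: np.ndarray, weights: np.ndarray) -> float:
    r = math.exp(log_r)
    p = 1.0 / (1.0 + math.exp(-logit_p))
    ll = weights @ stats.nbinom.logpmf(values, r, 1.0 - p)
    return -float(ll)


def fit_nb(counts: Sequence[int], min_n: int = DEFAULT_MIN_OBS) -> NBParams:
    """Fit NB(r, p) to a count sample by maximum likelihood.

    Initialized from the method of moments (p0 = 1 - mean/var,
    r0 = mean (1-p0)/p0). Underdispersed samples (variance <= mean) get a
    Poisson fallback; all-zero samples a degenerate point mass at zero.
    Falls back to the moment estimates if the optimizer does not converge.
    """
    x = np.asarray(counts, dtype=np.int64)
    if len(x) < min_n:
        raise ValueError(
            f"need at least {min_n} observations to fit background, got {len(x)}; "
            "sample more pairs"
        )
    if (x < 0).any():
        raise ValueError("negative counts")
    mean = float(x.mean())
    if mean == 0.0:
        logger.warning("all-zero background sample: degenerate model")
        return NBParams(0.0, 0.0, "degenerate", len(x))
    var = float(x.var(ddof=1))
    if var <= mean:
        return NBParams(0.0, 0.0, "poisson_fallback", len(x), mu=mean)
    p0 = 1.0 - mean / var
    r0 = mean * (1.0 - p0) / p0
    values, weights = np.unique(x, return_counts=True)
    weights = weights.astype(float)
    res = optimize.minimize(
        lambda t: _nb_negloglik(t[0], t[1], values, weights),
        x0=[math.log(r0), math.log(p0 / (1.0 - p0))],
        method="Nelder-Mead",
        options={"fatol": 1e-8, "xatol": 1e-10, "maxiter": 5000},
    )
    if not res.success:
        logger.warning("NB MLE did not converge; using moment estimates")
        return NBParams(r0, p0, "moments", len(x))
    r_hat = math.exp(res.x[0])
    p_hat = 1.0 / (1.0 + math.exp(-res.x[1]))
    return NBParams(r_hat, p_hat, "mle", len(x))


@dataclass
class IntraBackground:
    """Per-distance NB models on the bait chromosome plus a pooled model."""

    l: int
    d_max_bp: int
    per_d: dict[int, NBParams]
    pooled: NBParams
    seed: int
    fallback_ds: list[int] = field(default_factory=list)

    def model_for(self, d: int) -> NBParams:
        if d * self.l <= self.d_max_bp and d in self.per_d:
            return self.per_d[d]
        return self.pooled

    def to_dict(self) -> dict:
        return {
            "l": self.l,
            "d_max_bp": self.d_max_bp,
            "per_d": {str(d): m.to_dict() for d, m in self.per_d.items()},
            "pooled": self.pooled.to_dict(),
            "seed": self.seed,
            "fallback_ds": self.fallback_ds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntraBackground":
        return cls(
            d["l"],
            d["d_max_bp"],
            {int(k): NBParams.from_dict(v) for k, v in d["per_d"].items()},
            NBParams.from_dict(d["pooled"]),
            d["seed"],
            list(d.get("fallback_ds", [])),
        )


@dataclass
class InterBackground:
    """One NB model per (bait chromosome, other chromosome) pair."""

    bait_chrom: str
    bin_size: int
    models: dict[str, NBParams]
    seed: int

    def model_for(self, chrom: str) -> NBParams | None:
        return self.models.get(chrom)

    def to_dict(self) -> dict:
        return {
            "bait_chrom": self.bait_chrom,
            "bin_size": self.bin_size,
            "models": {c: m.to_dict() for c, m in self.models.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InterBackground":
        return cls(
            d["bait_chrom"],
            d["bin_size"],
            {c: NBParams.from_dict(v) for c, v in d["models"].items()},
            d["seed"],
        )


def save_backgrounds(intra: IntraBackground, inter: InterBackground, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"intra": intra.to_dict(), "inter": inter.to_dict()}, fh, indent=2)
        fh.write("\n")


def load_backgrounds(path: str) -> tuple[IntraBackground, InterBackground]:
    with open(path) as fh:
        d = json.load(fh)
    return IntraBackground.from_dict(d["intra"]), InterBackground.from_dict(d["inter"])


def _intra_pair_counts(pets: Iterable[PET], grid: BinGrid) -> Counter:
    """Counts of background-intra PETs per ordered regular-bin pair."""
    l = grid.bin_size
    chrom = grid.bait_chrom
    counts: Counter = Counter()
    for pet in pets:
        if pet.category != "background_intra":
            continue
        if pet.end1.chrom != chrom:
            continue
        i, j = sorted((pet.end1.pos // l, pet.end2.pos // l))
        counts[(i, j)] += 1
    return counts


def _candidate_starts(n_bins: int, d: int, bait_idx: set[int]) -> np.ndarray:
    starts = np.arange(0, n_bins - d)
    if bait_idx:
        bad = np.fromiter(bait_idx, dtype=np.int64)
        mask = ~(np.isin(starts, bad) | np.isin(starts + d, bad))
        starts = starts[mask]
    return starts


def sample_intra_pairs(
    pets: Iterable[PET],
    grid: BinGrid,
    d: int,
    n: int = DEFAULT_N_PAIRS,
    rng: np.random.Generator | None = None,
    pair_counts: Counter | None = None,
) -> np.ndarray:
    """Sample n bin pairs at separation d and return their contact counts.

    Pairs (b, b+d) are drawn uniformly over the bait chromosome, excluding
    any pair touching a bait-overlapped bin; sampled with replacement when
    fewer than ``n`` candidate pairs exist. Returns an empty array when no
    candidate pair exists at this separation.
    """
    if rng is None:
        rng = np.random.default_rng()
    if pair_counts is None:
        pair_counts = _intra_pair_counts(pets, grid)
    starts = _candidate_starts(grid.n_intra_bins(), d, set(grid.bait_bin_indices()))
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64)
    chosen = rng.choice(starts, size=n, replace=len(starts) < n)
    return np.fromiter(
        (pair_counts.get((b, b + d), 0) for b in chosen), dtype=np.int64, count=n
    )


def build_intra_background(
    pets: Iterable[PET],
    grid: BinGrid,
    d_max_bp: int = DEFAULT_D_MAX,
    n: int = DEFAULT_N_PAIRS,
    seed: int = 0,
    min_obs: int = DEFAULT_MIN_OBS,
    max_pooled_d: int | None = None,
) -> IntraBackground:
    """Fit the per-distance and pooled intra-chromosomal noise models.

    One NB fit per separation d with d*l <= ``d_max_bp``; a single pooled
    fit over pairs drawn at uniformly random separations beyond the cutoff
    (up to ``max_pooled_d``, default the chromosome extent). Strata with
    fewer than ``min_obs`` sampled pairs fall back to the pooled model.
    """
    rng = np.random.default_rng(seed)
    pets = list(pets)
    pair_counts = _intra_pair_counts(pets, grid)
    l = grid.bin_size
    n_bins = grid.n_intra_bins()
    bait_idx = set(grid.bait_bin_indices())
    d_model_max = d_max_bp // l

    per_d: dict[int, NBParams] = {}
    fallback_ds: list[int] = []
    for d in range(1, d_model_max + 1):
        counts = sample_intra_pairs(pets, grid, d, n=n, rng=rng, pair_counts=pair_counts)
        if len(counts) < min_obs:
            logger.warning("distance stratum d=%d has no candidate pairs; pooled", d)
            fallback_ds.append(d)
            continue
        per_d[d] = fit_nb(counts, min_n=min_obs)

    hi = max_pooled_d if max_pooled_d is not None else n_bins - 1
    pooled_ds = [
        d
        for d in range(d_model_max + 1, hi + 1)
        if len(_candidate_starts(n_bins, d, bait_idx)) > 0
    ]
    if pooled_ds:
        ds = rng.choice(np.asarray(pooled_ds), size=n, replace=True)
        pooled_counts = np.empty(n, dtype=np.int64)
        for k, d in enumerate(ds):
            starts = _candidate_starts(n_bins, int(d), bait_idx)
            b = int(rng.choice(starts))
            pooled_counts[k] = pair_counts.get((b, b + int(d)), 0)
        pooled = fit_nb(pooled_counts, min_n=min_obs)
    else:
        logger.warning("no pair candidates beyond cutoff: degenerate pooled model")
        pooled = NBParams(0.0, 0.0, "degenerate", 0)

    return IntraBackground(l, d_max_bp, per_d, pooled, seed, fallback_ds)


def build_inter_background(
    pets: Iterable[PET],
    chrom_sizes: ChromSizes,
    grid: BinGrid,
    n: int = DEFAULT_N_PAIRS,
    seed: int = 0,
    min_obs: int = DEFAULT_MIN_OBS,
) -> InterBackground:
    """Fit one NB noise model per (bait chromosome, other chromosome) pair.

    Chromosomes are tiled at 1 Mb; ``n`` random bin pairs are drawn per
    chromosome (one bin on the bait chromosome, excluding the bin(s)
    overlapping the bait, one on the other chromosome) and the
    background-inter PETs linking each pair are counted and fitted.
    """
    if len(chrom_sizes) < 2:
        raise ValueError("inter-chromosomal background needs >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    bait_chrom = grid.bait_chrom
    bsz = grid.inter_bin_size

    # background-inter PETs with one end on the bait chromosome, indexed by
    # (bait-chrom bin, other chrom, other bin)
    link_counts: Counter = Counter()
    for pet in pets:
        if pet.category != "background_inter":
            continue
        e1, e2 = pet.end1, pet.end2
        if e1.chrom == bait_chrom:
            bait_end, other_end = e1, e2
        elif e2.chrom == bait_chrom:
            bait_end, other_end = e2, e1
        else:
            continue
        link_counts[(bait_end.pos // bsz, other_end.chrom, other_end.pos // bsz)] += 1

    n_bait_bins = -(-chrom_sizes[bait_chrom] // bsz)
    bait_mb = {
        grid.bait.interval.start // bsz,
        (grid.bait.interval.end - 1) // bsz,
    }
    allowed = np.array([i for i in range(n_bait_bins) if i not in bait_mb])

    models: dict[str, NBParams] = {}
    for chrom in chrom_sizes:
        if chrom == bait_chrom:
            continue
        n_other = -(-chrom_sizes[chrom] // bsz)
        i_draw = rng.choice(allowed, size=n, replace=True)
        j_draw = rng.integers(0, n_other, size=n)
        counts = np.fromiter(
            (link_counts.get((int(i), chrom, int(j)), 0) for i, j in zip(i_draw, j_draw)),
            dtype=np.int64,
            count=n,
        )
        models[chrom] = fit_nb(counts, min_n=min_obs)
    return InterBackground(bait_chrom, bsz, models, seed)
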