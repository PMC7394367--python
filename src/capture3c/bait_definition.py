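"""Bait-region definition from local read-depth enrichment.

The bait (the dCas9/sgRNA-captured interval) sets the intra-chromosomal
bin size ``l``. When no external peak BED is supplied, the bait is grown
outward from the sgRNA target site over every position whose smoothed
depth exceeds the local background, with a hard extent cap and a fixed-size
fallback when there is no enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .genomic_io import AlignedEnd, GenomicInterval

__all__ = [
    "BaitRegion",
    "DepthTrack",
    "build_depth_track",
    "local_background",
    "smoothed_depth",
    "define_bait",
    "bait_from_interval",
]

DEFAULT_BACKGROUND_WINDOW = 100_000
DEFAULT_SMOOTH_HALFWIN = 50
DEFAULT_MAX_EXTENT = 20_000
DEFAULT_FALLBACK_SIZE = 2_000
MIN_BAIT_SIZE = 200


@dataclass(frozen=True)
class BaitRegion:
    interval: GenomicInterval
    target_site: int
    source: str  # heuristic | external_bed | fixed

    def __post_init__(self) -> None:
        if not self.interval.contains(self.target_site):
            raise ValueError("target_site must lie within the bait interval")
        if self.source not in ("heuristic", "external_bed", "fixed"):
            raise ValueError(f"unknown bait source {self.source!r}")

    @property
    def size_l(self) -> int:
        return len(self.interval)

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class DepthTrack:
    """Per-base read depth over a window of one chromosome."""

    chrom: str
    origin: int
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if (self.depth < 0).any():
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)

    @property
    def end(self) -> int:
        return self.origin + len(self.depth)

    def contains(self, pos: int) -> bool:
        return self.origin <= pos < self.end

    def _slice(self, start: int, end: int) -> np.ndarray:
        """Depth over genomic [start, end) clipped to track bounds."""
        lo = max(start, self.origin) - self.origin
        hi = min(end, self.end) - self.origin
        return self.depth[lo:hi]


def build_depth_track(
    ends: Iterable[AlignedEnd],
    window: GenomicInterval,
    fragment_length: int = 50,
) -> DepthTrack:
    """Count reads covering each base of ``window``.

    Each end is extended to ``fragment_length`` bases from its leftmost
    mapped position (a stand-in for the aligned span, which single-end
    records do not carry here).
    """
    n = len(window)
    diff = np.zeros(n + 1, dtype=float)
    for end in ends:
        if end.chrom != window.chrom:
            continue
        s = max(end.pos, window.start) - window.start
        e = min(end.pos + fragment_length, window.end) - window.start
        if e <= 0 or s >= n or e <= s:
            continue
        diff[s] += 1
        diff[e] -= 1
    return DepthTrack(window.chrom, window.start, np.cumsum(diff[:-1]))


def local_background(
    track: DepthTrack, target_site: int, window: int = DEFAULT_BACKGROUND_WINDOW
) -> float:
    """Mean depth of the ``window``-bp region centred on the target site.

    The window is clipped to the track (and hence chromosome) bounds; the
    mean is over the available bases only.
    """
    if not track.contains(target_site):
        raise ValueError("target_site outside depth track")
    half = window // 2
    values = track._slice(target_site - half, target_site + half)
    return float(values.mean()) if len(values) else 0.0


def smoothed_depth(
    track: DepthTrack, pos: int, halfwin: int = DEFAULT_SMOOTH_HALFWIN
) -> float:
    """Mean depth over [pos - halfwin, pos + halfwin] inclusive, clipped."""
    if not track.contains(pos):
        raise ValueError("pos outside depth track")
    values = track._slice(pos - halfwin, pos + halfwin + 1)
    return float(values.mean()) if len(values) else 0.0


def _smoothed_track(track: DepthTrack, halfwin: int) -> np.ndarray:
    """Vectorized smoothed_depth at every track position (same clipping)."""
    n = len(track.depth)
    cum = np.concatenate(([0.0], np.cumsum(track.depth)))
    idx = np.arange(n)
    lo = np.maximum(idx - halfwin, 0)
    hi = np.minimum(idx + halfwin + 1, n)
    return (cum[hi] - cum[lo]) / (hi - lo)


def define_bait(
    track: DepthTrack,
    target_site: int,
    window: int = DEFAULT_BACKGROUND_WINDOW,
    halfwin: int = DEFAULT_SMOOTH_HALFWIN,
    max_extent: int = DEFAULT_MAX_EXTENT,
    fallback_size: int | None = DEFAULT_FALLBACK_SIZE,
    min_bait_size: int = MIN_BAIT_SIZE,
    gap_tolerance: int = 0,
) -> BaitRegion:
    """Grow the bait outward from the target site over enriched positions.

    A position is enriched when its smoothed depth strictly exceeds the
    local background mean. Extension in each direction stops at the first
    run of more than ``gap_tolerance`` consecutive failing positions, or at
    ``max_extent`` from the target site. If the resulting interval is
    narrower than ``min_bait_size``, a fixed ``fallback_size`` interval
    centred on the target site is returned instead (source ``fixed``);
    with ``fallback_size=None`` that situation is an error.
    """
    if not track.contains(target_site):
        raise ValueError("target_site outside depth track")
    background = local_background(track, target_site, window)
    smoothed = _smoothed_track(track, halfwin)
    t = target_site - track.origin

    def extend(direction: int) -> int:
        offset = 0
        gap = 0
        last_good = 0
        while offset < max_extent:
            i = t + direction * (offset + 1)
            if i < 0 or i >= len(smoothed):
                break
            if smoothed[i] > background:
                offset += 1
                last_good = offset
                gap = 0
            else:
                gap += 1
                if gap > gap_tolerance:
                    break
                offset += 1
        return last_good

    enriched_at_target = smoothed[t] > background
    if enriched_at_target:
        left = extend(-1)
        right = extend(+1)
        start = target_site - left
        end = target_site + right + 1
        if end - start >= min_bait_size:
            return BaitRegion(
                GenomicInterval(track.chrom, start, end), target_site, "heuristic"
            )
    if fallback_size is None:
        raise ValueError("no bait signal at target site and fallback disabled")
    half = fallback_size // 2
    start = max(target_site - half, 0)
    end = start + fallback_size
    return BaitRegion(GenomicInterval(track.chrom, start, end), target_site, "fixed")


def bait_from_interval(interval: GenomicInterval, target_site: int | None = None) -> BaitRegion:
    """Build a bait from an external peak interval (e.g. a MACS2 BED)."""
    if target_site is None:
        target_site = (interval.start + interval.end) // 2
    return BaitRegion(interval, target_site, "external_bed")
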