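"""Breadth of coverage: the fraction of a transcript's coding bases whose
per-locus read depth meets a threshold.

For a transcript with 300 coding bases of which 270 have depth >= 10, the
breadth of coverage at 10x is 270/300 = 0.90.  The comparison is ``depth >= t``
(a locus with "t or more reads" counts as covered); a strict ``>`` variant is
available through the ``cmp`` switch for auditing.  Breadth is computed per
transcript (per CCDS id), never as a fused gene-level union, and is
non-increasing as the threshold ladder ascends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .depth_io import DepthTrack, depth_over
from .gene_models import TranscriptModel

__all__ = [
    "DEFAULT_LADDER",
    "ThresholdLadder",
    "BreadthProfile",
    "breadth_of_coverage",
    "breadth_profile",
]

#: The standard ladder of per-locus depth thresholds (read depths in x).
DEFAULT_LADDER: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 50, 100)


@dataclass(frozen=True)
class ThresholdLadder:
    """Strictly increasing, non-empty list of positive depth thresholds."""

    thresholds: tuple[int, ...] = DEFAULT_LADDER

    def __post_init__(self) -> None:
        t = tuple(int(x) for x in self.thresholds)
        if not t:
            raise ValueError("threshold ladder must be non-empty")
        if t[0] < 1:
            raise ValueError("thresholds must be positive read depths")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {t}")
        object.__setattr__(self, "thresholds", t)

    def __iter__(self):
        return iter(self.thresholds)

    def __len__(self) -> int:
        return len(self.thresholds)


@dataclass(frozen=True)
class BreadthProfile:
    """Per-threshold breadth of one sample over one transcript."""

    sample_id: str
    ccds_id: str
    breadths: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, b in self.breadths.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"breadth at {t}x out of [0,1]: {b}")


def breadth_of_coverage(
    track: DepthTrack, model: TranscriptModel, t: int, cmp: str = "ge"
) -> float:
    """Fraction of *model*'s coding bases with depth ``>= t`` in *track*.

    Parameters
    ----------
    track : DepthTrack
        One sample's per-base depth.
    model : TranscriptModel
        Canonical transcript; its coding length is the denominator.
    t : int
        Per-locus depth threshold (>= 1).
    cmp : {"ge", "gt"}
        Covered-locus comparison; ``ge`` (depth >= t) is the standard
        definition, ``gt`` provided for auditability.
    """
    if t < 1:
        raise ValueError(f"threshold must be >= 1, got {t}")
    if cmp not in ("ge", "gt"):
        raise ValueError(f"cmp must be 'ge' or 'gt', got {cmp!r}")
    total = model.coding_length
    if total == 0:
        raise ValueError(f"{model.ccds_id}: zero coding length, cannot form a proportion")
    covered = 0
    for iv, depth in depth_over(track, model.coding_intervals):
        if (depth >= t) if cmp == "ge" else (depth > t):
            covered += iv.length
    return covered / total


def breadth_profile(
    track: DepthTrack,
    model: TranscriptModel,
    ladder: ThresholdLadder | Sequence[int] = DEFAULT_LADDER,
    cmp: str = "ge",
) -> BreadthProfile:
    """Breadth at every rung of the threshold ladder, in one interval pass."""
    if not isinstance(ladder, ThresholdLadder):
        ladder = ThresholdLadder(tuple(ladder))
    total = model.coding_length
    if total == 0:
        raise ValueError(f"{model.ccds_id}: zero coding length, cannot form a proportion")
    covered = {t: 0 for t in ladder}
    for iv, depth in depth_over(track, model.coding_intervals):
        for t in ladder:
            if (depth >= t) if cmp == "ge" else (depth > t):
                covered[t] += iv.length
            else:
                break  # ladder ascends; higher rungs cannot pass either
    return BreadthProfile(
        sample_id=track.sample_id,
        ccds_id=model.ccds_id,
        breadths={t: covered[t] / total for t in ladder},
    )
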