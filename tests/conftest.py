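"""Shared fixtures and brute-force oracles for the test suite.

The oracles deliberately work per base on dense numpy arrays — slow but
obviously correct — so the interval-arithmetic implementation is always
checked against an independent counting path.
"""

from __future__ import annotations

import numpy as np
import pytest

from wescover.depth_io import ChromRuns, DepthTrack
from wescover.gene_models import GenomicInterval, TranscriptModel


def dense_depth(track: DepthTrack, chrom: str, lo: int, hi: int) -> np.ndarray:
    """Per-position depth array over [lo, hi), built run by run."""
    arr = np.zeros(hi - lo, dtype=np.int64)
    cr = track.runs.get(chrom)
    if cr is None:
        return arr
    for s, e, d in zip(cr.starts, cr.ends, cr.depths):
        a, b = max(int(s), lo), min(int(e), hi)
        if a < b:
            arr[a - lo : b - lo] = d
    return arr


def breadth_oracle(track: DepthTrack, model: TranscriptModel, t: int) -> float:
    """Dense per-base counting oracle for breadth of coverage."""
    covered = 0
    total = 0
    for iv in model.coding_intervals:
        arr = dense_depth(track, model.chrom, iv.start, iv.end)
        covered += int((arr >= t).sum())
        total += iv.length
    return covered / total


def make_track(sample_id: str, chrom: str, triples: list[tuple[int, int, int]]) -> DepthTrack:
    """Build a DepthTrack from (start, end, depth) triples on one chromosome."""
    triples = sorted(triples)
    track = DepthTrack(sample_id)
    track.runs[chrom] = ChromRuns(
        np.array([t[0] for t in triples], dtype=np.int64),
        np.array([t[1] for t in triples], dtype=np.int64),
        np.array([t[2] for t in triples], dtype=np.int64),
    )
    track.validate()
    return track


def random_track(rng: np.random.Generator, chrom: str = "1", span: int = 2000,
                 max_depth: int = 40, sample_id: str = "S") -> DepthTrack:
    """Random non-overlapping depth runs over [0, span)."""
    triples = []
    pos = int(rng.integers(0, 20))
    while pos < span - 1:
        length = int(rng.integers(1, 60))
        end = min(pos + length, span)
        depth = int(rng.integers(0, max_depth + 1))
        if depth > 0:
            triples.append((pos, end, depth))
        pos = end + int(rng.integers(0, 30))
    if not triples:
        triples = [(0, 1, 1)]
    return make_track(sample_id, chrom, triples)


def random_model(rng: np.random.Generator, chrom: str = "1", span: int = 2000,
                 ccds_id: str = "CCDS1.1") -> TranscriptModel:
    """Random multi-exon transcript with disjoint exons inside [0, span)."""
    intervals = []
    pos = int(rng.integers(0, 50))
    for _ in range(int(rng.integers(1, 6))):
        if pos >= span - 2:
            break
        length = int(rng.integers(1, 200))
        end = min(pos + length, span)
        intervals.append(GenomicInterval(chrom, pos, end))
        pos = end + int(rng.integers(1, 100))
    if not intervals:
        intervals = [GenomicInterval(chrom, 0, 10)]
    return TranscriptModel(ccds_id, "GENE", chrom, "+", tuple(intervals))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def worked_example():
    from wescover.synth import generate_worked_example

    return generate_worked_example()
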