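"""Per-sample read-depth tracks as run-length intervals.

A :class:`DepthTrack` stores, per chromosome, sorted non-overlapping runs
``(start, end, depth)``.  Any position not covered by a run has depth 0 by
contract; readers never materialize zero runs, but :func:`depth_over` does,
so query results always partition the query bases exactly.

Readers accept 4-column BedGraph (0-based half-open) and the samtools-depth
3-column TSV (1-based positions).  Gzipped inputs are handled transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np

from .gene_models import GenomicInterval, normalize_chrom

__all__ = ["DepthTrack", "read_bedgraph", "read_depth_tsv", "depth_over", "write_bedgraph"]


@dataclass
class ChromRuns:
    """Run-length depth on one chromosome: parallel arrays sorted by start."""

    starts: np.ndarray  # int64
    ends: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)


@dataclass
class DepthTrack:
    sample_id: str
    runs: dict[str, ChromRuns] = field(default_factory=dict)

    def depth_at(self, chrom: str, pos: int) -> int:
        """Depth at a single 0-based position (0 where no run covers it)."""
        cr = self.runs.get(normalize_chrom(chrom))
        if cr is None or len(cr.starts) == 0:
            return 0
        i = int(np.searchsorted(cr.starts, pos, side="right")) - 1
        if i >= 0 and cr.ends[i] > pos:
            return int(cr.depths[i])
        return 0

    def validate(self) -> None:
        for chrom, cr in self.runs.items():
            if np.any(cr.depths < 0):
                raise ValueError(f"{self.sample_id}/{chrom}: negative depth")
            if np.any(cr.ends <= cr.starts):
                raise ValueError(f"{self.sample_id}/{chrom}: empty run")
            if np.any(cr.starts[1:] < cr.ends[:-1]):
                raise ValueError(f"{self.sample_id}/{chrom}: overlapping runs")


def _open_lines(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _assemble(sample_id: str, rows: dict[str, list[tuple[int, int, int]]]) -> DepthTrack:
    track = DepthTrack(sample_id)
    for chrom, triples in rows.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        depths = np.array([t[2] for t in triples], dtype=np.int64)
        if len(starts) > 1:
            collide = np.nonzero(starts[1:] < ends[:-1])[0]
            if collide.size:
                i = int(collide[0])
                raise ValueError(
                    f"{sample_id}/{chrom}: overlapping depth lines "
                    f"[{starts[i]},{ends[i]}) and [{starts[i+1]},{ends[i+1]})"
                )
        track.runs[chrom] = ChromRuns(starts, ends, depths)
    return track


def read_bedgraph(source: str | Path | TextIO, sample_id: str) -> DepthTrack:
    """Read a 4-column BedGraph (chrom, start, end, depth) into a track.

    Depth values must be non-negative integers; overlapping lines raise a
    ``ValueError`` naming the first collision.
    """
    rows: dict[str, list[tuple[int, int, int]]] = {}
    handle = _open_lines(source)
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith(("track", "browser", "#")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"line {lineno}: BedGraph needs 4 columns")
        chrom = normalize_chrom(f[0])
        start, end = int(f[1]), int(f[2])
        depth = int(float(f[3]))
        if depth < 0:
            raise ValueError(f"line {lineno}: negative depth {depth}")
        if end <= start:
            raise ValueError(f"line {lineno}: end <= start")
        # zero-depth lines are kept so overlaps with them are still detected
        rows.setdefault(chrom, []).append((start, end, depth))
    return _assemble(sample_id, rows)


def read_depth_tsv(source: str | Path | TextIO, sample_id: str) -> DepthTrack:
    """Read a samtools-depth TSV (chrom, 1-based pos, depth) into a track.

    Consecutive equal-depth positions are collapsed to runs; positions must
    be strictly increasing within a chromosome.
    """
    rows: dict[str, list[tuple[int, int, int]]] = {}
    handle = _open_lines(source)
    cur_chrom: str | None = None
    run_start = run_end = run_depth = 0
    last_pos: dict[str, int] = {}

    def flush() -> None:
        if cur_chrom is not None and run_depth > 0:
            rows.setdefault(cur_chrom, []).append((run_start, run_end, run_depth))
        elif cur_chrom is not None:
            rows.setdefault(cur_chrom, [])

    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        chrom = normalize_chrom(f[0])
        pos0 = int(f[1]) - 1  # 1-based -> 0-based
        depth = int(f[2])
        if depth < 0:
            raise ValueError(f"line {lineno}: negative depth {depth}")
        if chrom in last_pos and chrom != cur_chrom:
            raise ValueError(f"line {lineno}: chromosome {chrom} appears twice non-contiguously")
        if chrom == cur_chrom and pos0 <= last_pos.get(chrom, -1):
            raise ValueError(f"line {lineno}: non-monotone position {pos0 + 1} on {chrom}")
        if chrom == cur_chrom and pos0 == run_end and depth == run_depth:
            run_end = pos0 + 1
        else:
            flush()
            cur_chrom, run_start, run_end, run_depth = chrom, pos0, pos0 + 1, depth
        last_pos[chrom] = pos0
    flush()
    return _assemble(sample_id, rows)


def depth_over(
    track: DepthTrack, intervals: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, int]]:
    """Depth runs restricted to the union of *intervals*.

    Returned runs partition the query bases exactly, in coordinate order;
    positions with no depth data are materialized as explicit depth-0 runs.
    A chromosome absent from the track yields all-zero runs.
    """
    out: list[tuple[GenomicInterval, int]] = []
    for iv in intervals:
        chrom = normalize_chrom(iv.chrom)
        cr = track.runs.get(chrom)
        if cr is None or len(cr.starts) == 0:
            out.append((GenomicInterval(chrom, iv.start, iv.end), 0))
            continue
        pos = iv.start
        # first run that could overlap [iv.start, iv.end)
        i = int(np.searchsorted(cr.ends, iv.start, side="right"))
        while pos < iv.end:
            if i >= len(cr.starts) or cr.starts[i] >= iv.end:
                out.append((GenomicInterval(chrom, pos, iv.end), 0))
                break
            s, e, d = int(cr.starts[i]), int(cr.ends[i]), int(cr.depths[i])
            if s > pos:
                out.append((GenomicInterval(chrom, pos, s), 0))
                pos = s
            cut = min(e, iv.end)
            out.append((GenomicInterval(chrom, pos, cut), d))
            pos = cut
            i += 1
    return out


def write_bedgraph(track: DepthTrack, dest: str | Path | TextIO) -> None:
    """Write a track as 4-column BedGraph, coalescing equal-depth adjacent runs."""
    own = not hasattr(dest, "write")
    handle = open(dest, "w") if own else dest  # type: ignore[arg-type]
    try:
        for chrom in sorted(track.runs):
            cr = track.runs[chrom]
            prev: list | None = None
            for s, e, d in zip(cr.starts, cr.ends, cr.depths):
                if prev is not None and prev[1] == s and prev[2] == d:
                    prev[1] = e
                    continue
                if prev is not None:
                    handle.write(f"{chrom}\t{prev[0]}\t{prev[1]}\t{prev[2]}\n")
                prev = [int(s), int(e), int(d)]
            if prev is not None:
                handle.write(f"{chrom}\t{prev[0]}\t{prev[1]}\t{prev[2]}\n")
    finally:
        if own:
            handle.close()
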