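"""Transcript coding models from CCDS text dumps and BED files.

All coordinates are stored 0-based, half-open ([start, end)), the BED
convention.  The CCDS text dump lists ``cds_locations`` as 0-based
inclusive-inclusive pairs; they are converted at parse time and never
touched again.  Chromosome names are normalized by stripping a leading
``chr`` so that GRCh37-style (``1``) and GRCh38-style (``chr1``) inputs
interoperate.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, TextIO

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "normalize_chrom",
    "merge_intervals",
    "coding_length",
    "parse_ccds",
    "parse_bed",
    "write_bed12",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome name."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Sort, merge overlapping and coalesce adjacent intervals.

    The union of covered bases is preserved exactly.  Intervals sharing a
    boundary (``end == next.start``) are coalesced into one.  All intervals
    must lie on a single chromosome.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"merge_intervals requires a single chromosome, got {sorted(chroms)}")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:  # overlap or adjacency
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class TranscriptModel:
    """One CCDS transcript: merged coding intervals on a single chromosome.

    Coding intervals are canonicalized on construction: sorted, disjoint,
    adjacency-coalesced, so no base is ever double-counted.
    """

    ccds_id: str
    gene_symbol: str
    chrom: str
    strand: str
    coding_intervals: tuple[GenomicInterval, ...]
    assembly_tag: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        chrom = normalize_chrom(self.chrom)
        ivs = tuple(
            merge_intervals([replace(iv, chrom=normalize_chrom(iv.chrom)) for iv in self.coding_intervals])
        )
        if not ivs:
            raise ValueError(f"{self.ccds_id}: transcript has no coding intervals")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "coding_intervals", ivs)

    @property
    def coding_length(self) -> int:
        return sum(iv.length for iv in self.coding_intervals)


def coding_length(model: TranscriptModel) -> int:
    """Total number of distinct coding bases in the model."""
    return model.coding_length


# --- CCDS text dump -------------------------------------------------------

_CCDS_LOCATIONS = re.compile(r"^\[(.*)\]$")


def _open_text(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        import gzip

        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def parse_ccds(
    source: str | Path | TextIO,
    accepted_status: Iterable[str] = ("Public",),
    assembly_tag: str = "",
) -> list[TranscriptModel]:
    """Parse a CCDS text dump into transcript models.

    The dump is tab-separated with a single ``#``-prefixed header naming at
    least ``chromosome``, ``gene``, ``ccds_id``, ``ccds_status``,
    ``cds_strand`` and ``cds_locations``.  ``cds_locations`` holds a
    bracketed, comma-separated list of ``from-to`` pairs, 0-based inclusive
    on both ends; withdrawn rows carry ``-`` and are skipped.  Only rows
    whose status is in *accepted_status* are kept (default ``{"Public"}``).

    Raises ``ValueError`` on a malformed location list (naming the line
    number) or on a duplicate ``ccds_id``.
    """
    accepted = set(accepted_status)
    handle = _open_text(source)
    header = handle.readline().rstrip("\n")
    if not header.startswith("#"):
        raise ValueError("CCDS dump must start with a '#' header line")
    columns = [c.strip() for c in header.lstrip("#").split("\t")]
    try:
        idx = {name: columns.index(name) for name in
               ("chromosome", "gene", "ccds_id", "ccds_status", "cds_strand", "cds_locations")}
    except ValueError as exc:
        raise ValueError(f"CCDS header missing required column: {exc}") from exc

    models: list[TranscriptModel] = []
    seen: set[str] = set()
    for lineno, line in enumerate(handle, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        status = fields[idx["ccds_status"]].strip()
        locations = fields[idx["cds_locations"]].strip()
        ccds_id = fields[idx["ccds_id"]].strip()
        if locations == "-":  # withdrawn / no CDS annotated
            continue
        if status not in accepted:
            continue
        if ccds_id in seen:
            raise ValueError(f"line {lineno}: duplicate ccds_id {ccds_id!r}")
        seen.add(ccds_id)
        m = _CCDS_LOCATIONS.match(locations)
        if m is None:
            raise ValueError(f"line {lineno}: malformed cds_locations {locations!r}")
        chrom = normalize_chrom(fields[idx["chromosome"]])
        intervals = []
        for pair in m.group(1).split(","):
            pair = pair.strip()
            try:
                lo_s, hi_s = pair.split("-")
                lo, hi = int(lo_s), int(hi_s)
            except ValueError:
                raise ValueError(f"line {lineno}: malformed cds_locations pair {pair!r}") from None
            # inclusive-inclusive in the dump -> half-open internally
            intervals.append(GenomicInterval(chrom, lo, hi + 1))
        models.append(
            TranscriptModel(
                ccds_id=ccds_id,
                gene_symbol=fields[idx["gene"]].strip(),
                chrom=chrom,
                strand=fields[idx["cds_strand"]].strip(),
                coding_intervals=tuple(intervals),
                assembly_tag=assembly_tag,
            )
        )
    return models


# --- BED ------------------------------------------------------------------


def parse_bed(
    source: str | Path | TextIO,
    format: str = "bed12",
    assembly_tag: str = "",
) -> list[TranscriptModel]:
    """Parse BED6 exon lists or BED12 transcript lines into transcript models.

    ``bed6_exons`` groups rows by the name column: each distinct name becomes
    one model whose intervals are the grouped rows (the name doubles as both
    ccds_id and gene symbol, split on ``|`` as ``ccds_id|gene`` when present).
    ``bed12`` expands blockStarts/blockSizes relative to chromStart.
    """
    if format not in ("bed6_exons", "bed12"):
        raise ValueError(f"unknown BED format {format!r}")
    handle = _open_text(source)
    if format == "bed12":
        models = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"line {lineno}: BED12 requires 12 columns, got {len(f)}")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            strand = f[5] if f[5] in ("+", "-") else "+"
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if not (len(sizes) == len(starts) == block_count):
                raise ValueError(
                    f"line {lineno}: blockCount {block_count} inconsistent with "
                    f"{len(sizes)} sizes / {len(starts)} starts"
                )
            ccds_id, _, gene = name.partition("|")
            intervals = tuple(
                GenomicInterval(chrom, start + bs, start + bs + sz)
                for bs, sz in zip(starts, sizes)
            )
            models.append(
                TranscriptModel(ccds_id, gene or ccds_id, chrom, strand, intervals, assembly_tag)
            )
        return models

    # bed6_exons: group rows by name, preserving first-seen order
    groups: dict[str, dict] = {}
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("track", "browser", "#")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ValueError(f"line {lineno}: BED6 exon rows need at least 4 columns")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        if end <= start:
            raise ValueError(f"line {lineno}: end <= start")
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
        g = groups.setdefault(name, {"chrom": chrom, "strand": strand, "intervals": []})
        g["intervals"].append(GenomicInterval(chrom, start, end))
    models = []
    for name, g in groups.items():
        ccds_id, _, gene = name.partition("|")
        models.append(
            TranscriptModel(ccds_id, gene or ccds_id, g["chrom"], g["strand"],
                            tuple(g["intervals"]), assembly_tag)
        )
    return models


def write_bed12(models: Iterable[TranscriptModel], dest: str | Path | TextIO) -> None:
    """Write canonical models as BED12 (name = ``ccds_id|gene_symbol``)."""
    own = not hasattr(dest, "write")
    handle = open(dest, "w") if own else dest  # type: ignore[arg-type]
    try:
        for m in models:
            start = m.coding_intervals[0].start
            end = m.coding_intervals[-1].end
            sizes = ",".join(str(iv.length) for iv in m.coding_intervals)
            starts = ",".join(str(iv.start - start) for iv in m.coding_intervals)
            handle.write(
                "\t".join(
                    [
                        m.chrom,
                        str(start),
                        str(end),
                        f"{m.ccds_id}|{m.gene_symbol}",
                        "0",
                        m.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(m.coding_intervals)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            handle.close()
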