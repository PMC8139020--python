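"""Seeded synthetic WES cohorts: depth tracks, gene models, sample sheets
and panel registries, with controllable population structure.

The depth model emulates exome capture behaviour at the exon level: each
sample draws a per-exon depth from a gamma-mixed (negative-binomial-style)
distribution around the population's capture mean, constant within the exon
apart from small positional jitter, with a per-exon dropout probability
under which the exon yields zero depth.  This reproduces the key phenomenon
the breadth metric exists for — individual exons left uncovered even when
the sample's average read depth is high — with very few parameters.

Randomness is structured so cohorts are stable under edits: every sample
derives its own stream from ``(seed, sample_id)``, so adding or removing a
sample never perturbs any other sample's data.  Same seed, same bytes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import SampleSheet
from .depth_io import ChromRuns, DepthTrack, write_bedgraph
from .gene_models import GenomicInterval, TranscriptModel, write_bed12
from .panels import PanelRecord, PanelRegistry, write_registry_tsv

__all__ = [
    "PopulationCapture",
    "CohortSpec",
    "generate_cohort",
    "generate_gene_models",
    "generate_registry",
    "generate_worked_example",
    "write_cohort",
    "DEFAULT_POPULATIONS",
]

#: Continental population labels used for stratified cohorts.
DEFAULT_POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")


@dataclass(frozen=True)
class PopulationCapture:
    """Capture model for one population.

    mean_depth
        Expected per-exon read depth (x).  60x is a typical mid-2010s WES
        target and leaves breadth responsive across the 5x-100x ladder.
    dispersion
        Gamma-mixing dispersion of the per-exon mean; 0.3 spreads exon
        depths realistically without making dropout dominate.
    dropout_prob
        Probability an exon fails capture outright (depth 0); a few percent
        mirrors the sporadic bait failures seen in real exomes.
    exon_means : optional
        Per-exon override of mean_depth, keyed ``(ccds_id, exon_index)``.
    exon_dropout : optional
        Per-exon override of dropout_prob, same key.
    """

    mean_depth: float = 60.0
    dispersion: float = 0.3
    dropout_prob: float = 0.02
    exon_means: Mapping[tuple[str, int], float] = field(default_factory=dict)
    exon_dropout: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Specification for one synthetic cohort."""

    n_samples: Mapping[str, int]  # population label -> sample count
    models: tuple[TranscriptModel, ...]
    capture: Mapping[str, PopulationCapture]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples:
            raise ValueError("cohort needs at least one population")
        for pop, n in self.n_samples.items():
            if n < 1:
                raise ValueError(f"population {pop!r} needs >= 1 sample")
            if pop not in self.capture:
                raise ValueError(f"no capture model for population {pop!r}")
        if not self.models:
            raise ValueError("cohort needs at least one gene model")


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # one documented stream per sample: adding a sample never perturbs others
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(sample_id.encode())]))


def _simulate_track(
    sample_id: str, spec: CohortSpec, cap: PopulationCapture
) -> DepthTrack:
    rng = _sample_rng(spec.seed, sample_id)
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for model in spec.models:
        for ei, iv in enumerate(model.coding_intervals):
            mean = float(cap.exon_means.get((model.ccds_id, ei), cap.mean_depth))
            drop = float(cap.exon_dropout.get((model.ccds_id, ei), cap.dropout_prob))
            if rng.random() < drop or mean == 0.0:
                continue  # dropout exon: no reads, depth 0 by absence
            # gamma-mixed exon mean (negative-binomial-style overdispersion)
            shape = 1.0 / max(cap.dispersion, 1e-9)
            exon_mean = rng.gamma(shape, mean / shape)
            # piecewise-constant depth with ±10% positional jitter, ~20 bp chunks
            pos = iv.start
            while pos < iv.end:
                end = min(pos + 20, iv.end)
                depth = int(round(exon_mean * (1.0 + rng.uniform(-0.1, 0.1))))
                if depth > 0:
                    per_chrom.setdefault(model.chrom, []).append((pos, end, depth))
                pos = end
    track = DepthTrack(sample_id)
    for chrom, triples in per_chrom.items():
        triples.sort()
        track.runs[chrom] = ChromRuns(
            np.array([t[0] for t in triples], dtype=np.int64),
            np.array([t[1] for t in triples], dtype=np.int64),
            np.array([t[2] for t in triples], dtype=np.int64),
        )
    track.validate()
    return track


def generate_cohort(spec: CohortSpec) -> tuple[list[DepthTrack], SampleSheet]:
    """Generate one depth track per sample plus the matching sample sheet.

    Deterministic given ``spec.seed``; sample ids are ``<POP>_<k>``.
    Tracks satisfy every DepthTrack invariant (validated on generation).
    """
    tracks: list[DepthTrack] = []
    sheet: dict[str, str] = {}
    for pop in sorted(spec.n_samples):
        cap = spec.capture[pop]
        for k in range(spec.n_samples[pop]):
            sid = f"{pop}_{k:03d}"
            tracks.append(_simulate_track(sid, spec, cap))
            sheet[sid] = pop
    return tracks, SampleSheet(sheet)


def generate_gene_models(
    n_genes: int = 10,
    seed: int = 0,
    chrom: str = "1",
    exons_per_gene: tuple[int, int] = (2, 8),
    exon_length: tuple[int, int] = (60, 300),
    intron_length: tuple[int, int] = (200, 2000),
) -> list[TranscriptModel]:
    """Fabricate plausible multi-exon transcript models on one chromosome."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6D6F64]))
    models = []
    cursor = 10_000
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        intervals = []
        for _ in range(n_ex):
            length = int(rng.integers(exon_length[0], exon_length[1] + 1))
            intervals.append(GenomicInterval(chrom, cursor, cursor + length))
            cursor += length + int(rng.integers(intron_length[0], intron_length[1] + 1))
        models.append(
            TranscriptModel(
                ccds_id=f"CCDS{g + 1}.1",
                gene_symbol=f"GENE{g + 1}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                coding_intervals=tuple(intervals),
                assembly_tag="synthetic",
            )
        )
        cursor += 5_000
    return models


def generate_registry(
    models: Sequence[TranscriptModel], seed: int = 0, tests_per_gene: int = 2
) -> PanelRegistry:
    """Fabricate a panel registry covering the given genes.

    Each gene appears in ``tests_per_gene`` single-gene tests plus one
    shared multi-gene panel, so every gene is queryable by symbol,
    phenotype and panel name.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x726567]))
    registry = PanelRegistry()
    tid = 1
    for m in models:
        for j in range(tests_per_gene):
            registry.add(
                PanelRecord(
                    test_id=f"GTR{tid:06d}",
                    test_name=f"{m.gene_symbol} sequencing panel v{j + 1}",
                    clia_certified=bool(rng.random() < 0.6),
                    gtr_phenotypes=(f"{m.gene_symbol}-related disorder",),
                    hpo_terms=((f"HP:{int(rng.integers(1, 9999999)):07d}",
                                f"Phenotype of {m.gene_symbol}"),),
                    gene_symbols=(m.gene_symbol,),
                )
            )
            tid += 1
    registry.add(
        PanelRecord(
            test_id=f"GTR{tid:06d}",
            test_name="Comprehensive multi-gene panel",
            clia_certified=True,
            gtr_phenotypes=("Syndromic presentation",),
            hpo_terms=(("HP:0000001", "All"),),
            gene_symbols=tuple(m.gene_symbol for m in models),
        )
    )
    return registry


def generate_worked_example() -> tuple[DepthTrack, TranscriptModel, dict[int, float]]:
    """A worked three-exon gene with known breadths at 3x and 5x.

    The 300-bp gene has regions totalling 270 bp where every locus carries
    3 or more reads (so breadth(3) = 270/300 = 0.90) of which a 150-bp
    sub-region carries 5 or more (breadth(5) = 150/300 = 0.50); the
    remaining 30 bp sit at depth 1.  The expected breadths are returned
    alongside the track and model.
    """
    chrom = "1"
    exons = (
        GenomicInterval(chrom, 1000, 1100),
        GenomicInterval(chrom, 1500, 1600),
        GenomicInterval(chrom, 2000, 2100),
    )
    model = TranscriptModel("CCDSWEX.1", "WEX", chrom, "+", exons, "worked-example")
    # region A: exon1 fully at depth 5 (100 bp, >=5 and >=3)
    # region C continues: first 50 bp of exon2 at depth 5 (total >=5: 150 bp)
    # region B: rest of exon2 and 70 bp of exon3 at depth 3 (>=3 total: 270 bp)
    # final 30 bp of exon3 at depth 1 (covered by reads, below both cutoffs)
    triples = [
        (1000, 1100, 5),
        (1500, 1550, 5),
        (1550, 1600, 3),
        (2000, 2070, 3),
        (2070, 2100, 1),
    ]
    track = DepthTrack("wex_sample")
    track.runs[chrom] = ChromRuns(
        np.array([t[0] for t in triples], dtype=np.int64),
        np.array([t[1] for t in triples], dtype=np.int64),
        np.array([t[2] for t in triples], dtype=np.int64),
    )
    track.validate()
    expected = {3: 270 / 300, 5: 150 / 300}
    return track, model, expected


def write_cohort(
    tracks: Sequence[DepthTrack],
    sheet: SampleSheet,
    models: Sequence[TranscriptModel],
    registry: PanelRegistry,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write a cohort in the exact dialects the readers consume.

    BedGraph per sample under ``depth/``, sample sheet TSV, BED12 gene
    models, registry TSV.  Returns the paths written.
    """
    from .cohort import write_sample_sheet

    out = Path(outdir)
    (out / "depth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tr in tracks:
        p = out / "depth" / f"{tr.sample_id}.bedgraph"
        write_bedgraph(tr, p)
        paths[tr.sample_id] = p
    paths["sample_sheet"] = out / "samples.tsv"
    write_sample_sheet(sheet, paths["sample_sheet"])
    paths["models"] = out / "models.bed12"
    write_bed12(models, paths["models"])
    paths["registry"] = out / "registry.tsv"
    write_registry_tsv(registry, paths["registry"])
    return paths
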