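"""Gene panel test registry: loading, querying, and panel recommendations.

The registry is a TSV snapshot in the shape of the NIH Genetic Testing
Registry: one row per registered test, linking the test to its phenotypes,
HPO terms and gene content.  Query modes mirror a coverage-browser UI:
exact (case-insensitive) gene symbol, substring match on GTR phenotype,
HPO phenotype, or panel test name.

Recommendations apply a single rule per (gene, transcript, threshold): if
the cohort mean breadth falls strictly below the adequacy cutoff (default
0.90 at 20x), targeted panel testing should be considered and every
registered test covering the gene is attached; genes with no registered
test are flagged ``no_panel_available``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pandas as pd

from .cohort import CohortSummary

__all__ = [
    "PanelRecord",
    "PanelRegistry",
    "Recommendation",
    "load_registry",
    "query",
    "recommend",
    "write_recommendations_tsv",
    "write_recommendations_json",
    "DEFAULT_CUTOFF",
    "DEFAULT_THRESHOLD",
]

#: Adequacy cutoff on cohort mean breadth below which panels are suggested.
DEFAULT_CUTOFF = 0.90
#: Default per-locus depth threshold for the adequacy decision (20x gives
#: ~99% SNV sensitivity in standard WES practice).
DEFAULT_THRESHOLD = 20

_HPO_ID = re.compile(r"^HP:\d{7}$")

REGISTRY_COLUMNS = [
    "test_id",
    "test_name",
    "clia_certified",
    "gtr_phenotypes",
    "hpo_terms",
    "gene_symbols",
]


@dataclass(frozen=True)
class PanelRecord:
    test_id: str
    test_name: str
    clia_certified: bool
    gtr_phenotypes: tuple[str, ...]
    hpo_terms: tuple[tuple[str, str], ...]  # (HP:NNNNNNN, label)
    gene_symbols: tuple[str, ...]


@dataclass
class PanelRegistry:
    records: dict[str, PanelRecord] = field(default_factory=dict)
    rejected: int = 0  # rows dropped during load (bad HPO id / empty genes)
    _by_gene: dict[str, list[str]] = field(default_factory=dict)

    def add(self, rec: PanelRecord) -> None:
        if rec.test_id in self.records:
            raise ValueError(f"duplicate test_id {rec.test_id!r}")
        self.records[rec.test_id] = rec
        for g in rec.gene_symbols:
            self._by_gene.setdefault(g.upper(), []).append(rec.test_id)

    def tests_for_gene(self, gene: str) -> list[PanelRecord]:
        ids = self._by_gene.get(gene.upper(), [])
        return [self.records[i] for i in sorted(ids)]

    def __len__(self) -> int:
        return len(self.records)


def _split_list(cell: str) -> list[str]:
    cell = (cell or "").strip()
    if not cell or cell == "-":
        return []
    return [x.strip() for x in cell.split("|") if x.strip()]


def load_registry(source: str | Path | TextIO) -> PanelRegistry:
    """Load a registry TSV into an indexed :class:`PanelRegistry`.

    Columns: test_id, test_name, clia_certified (true/false), gtr_phenotypes,
    hpo_terms, gene_symbols; list-valued columns are ``|``-delimited and HPO
    terms are written ``HP:NNNNNNN=Label``.  Rows with a malformed HPO id or
    an empty gene list are rejected (counted, warned), a duplicate test_id
    is an error.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry TSV missing columns: {missing}")
    registry = PanelRegistry()
    for _, row in df.iterrows():
        genes = tuple(_split_list(row["gene_symbols"]))
        hpo: list[tuple[str, str]] = []
        bad = False
        for item in _split_list(row["hpo_terms"]):
            hid, _, label = item.partition("=")
            hid = hid.strip()
            if not _HPO_ID.match(hid):
                bad = True
                break
            hpo.append((hid, label.strip()))
        if bad or not genes:
            registry.rejected += 1
            continue
        registry.add(
            PanelRecord(
                test_id=row["test_id"].strip(),
                test_name=row["test_name"].strip(),
                clia_certified=row["clia_certified"].strip().lower() in ("true", "1", "yes"),
                gtr_phenotypes=tuple(_split_list(row["gtr_phenotypes"])),
                hpo_terms=tuple(hpo),
                gene_symbols=genes,
            )
        )
    if registry.rejected:
        warnings.warn(f"registry: rejected {registry.rejected} malformed row(s)", stacklevel=2)
    return registry


def write_registry_tsv(registry: PanelRegistry, dest: str | Path) -> None:
    rows = []
    for tid in sorted(registry.records):
        r = registry.records[tid]
        rows.append(
            {
                "test_id": r.test_id,
                "test_name": r.test_name,
                "clia_certified": str(r.clia_certified).lower(),
                "gtr_phenotypes": "|".join(r.gtr_phenotypes),
                "hpo_terms": "|".join(f"{h}={lab}" for h, lab in r.hpo_terms),
                "gene_symbols": "|".join(r.gene_symbols),
            }
        )
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(dest, sep="\t", index=False)


QUERY_MODES = ("gene", "gtr_phenotype", "hpo_phenotype", "panel_name")


def query(
    registry: PanelRegistry, mode: str, term: str
) -> list[tuple[str, list[PanelRecord]]]:
    """Resolve a query term to genes and their matching panel records.

    ``gene`` does exact case-insensitive symbol matching; the phenotype and
    panel-name modes match case-insensitive substrings.  Results are
    (gene_symbol, records) pairs, genes deduplicated and lexicographically
    ordered; no match returns an empty list.
    """
    if mode not in QUERY_MODES:
        raise ValueError(f"mode must be one of {QUERY_MODES}, got {mode!r}")
    needle = term.strip().lower()
    matched: dict[str, set[str]] = {}  # gene -> test ids

    def hit(rec: PanelRecord) -> bool:
        if mode == "gene":
            return any(g.lower() == needle for g in rec.gene_symbols)
        if mode == "panel_name":
            return needle in rec.test_name.lower()
        if mode == "gtr_phenotype":
            return any(needle in p.lower() for p in rec.gtr_phenotypes)
        return any(
            needle in lab.lower() or needle == hid.lower() for hid, lab in rec.hpo_terms
        )

    for rec in registry.records.values():
        if not hit(rec):
            continue
        if mode == "gene":
            genes = [g for g in rec.gene_symbols if g.lower() == needle]
        else:
            genes = list(rec.gene_symbols)
        for g in genes:
            matched.setdefault(g.upper(), set()).add(rec.test_id)
    return [
        (g, [registry.records[t] for t in sorted(matched[g])]) for g in sorted(matched)
    ]


@dataclass(frozen=True)
class Recommendation:
    gene_symbol: str
    ccds_id: str
    threshold: int
    cohort_mean_breadth: float
    verdict: str  # wes_adequate | consider_panel
    panel_tests: tuple[str, ...]  # matching test ids
    no_panel_available: bool = False
    locus_fraction_mean: float | None = None


def recommend(
    summary: CohortSummary,
    registry: PanelRegistry,
    threshold: int = DEFAULT_THRESHOLD,
    cutoff: float = DEFAULT_CUTOFF,
    locus_means: Mapping[str, float] | None = None,
) -> list[Recommendation]:
    """Flag transcripts whose cohort mean breadth falls below the cutoff.

    ``consider_panel`` iff mean breadth < cutoff (strict: a mean exactly at
    the cutoff is adequate).  Every flagged gene carries all registry tests
    covering it; flagged genes with no registered test are marked
    ``no_panel_available``.  Raises if the threshold was not summarized.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    available = summary.thresholds()
    if threshold not in available:
        raise ValueError(
            f"threshold {threshold} not in summary; available: {available}"
        )
    sub = summary.table[summary.table["threshold"] == threshold]
    out = []
    for _, row in sub.iterrows():
        mean = float(row["global_mean"])
        flagged = mean < cutoff
        tests = registry.tests_for_gene(str(row["gene_symbol"])) if flagged else []
        lf = (locus_means or {}).get(str(row["ccds_id"]))
        out.append(
            Recommendation(
                gene_symbol=str(row["gene_symbol"]),
                ccds_id=str(row["ccds_id"]),
                threshold=threshold,
                cohort_mean_breadth=mean,
                verdict="consider_panel" if flagged else "wes_adequate",
                panel_tests=tuple(t.test_id for t in tests),
                no_panel_available=bool(flagged and not tests),
                locus_fraction_mean=lf,
            )
        )
    out.sort(key=lambda r: (r.cohort_mean_breadth, r.ccds_id))
    return out


def _rec_row(r: Recommendation) -> dict:
    return {
        "gene_symbol": r.gene_symbol,
        "ccds_id": r.ccds_id,
        "threshold": r.threshold,
        "cohort_mean_breadth": r.cohort_mean_breadth,
        "locus_fraction_mean": "" if r.locus_fraction_mean is None else r.locus_fraction_mean,
        "verdict": r.verdict,
        "panel_tests": "|".join(r.panel_tests),
        "no_panel_available": str(r.no_panel_available).lower(),
    }


def write_recommendations_tsv(recs: Iterable[Recommendation], dest: str | Path) -> None:
    pd.DataFrame([_rec_row(r) for r in recs]).to_csv(
        dest, sep="\t", index=False, float_format="%.10g"
    )


def write_recommendations_json(recs: Iterable[Recommendation], dest: str | Path) -> None:
    payload = []
    for r in recs:
        d = _rec_row(r)
        d["panel_tests"] = list(r.panel_tests)
        d["locus_fraction_mean"] = r.locus_fraction_mean
        d["no_panel_available"] = r.no_panel_available
        payload.append(d)
    with open(dest, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
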