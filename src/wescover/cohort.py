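"""Cohort aggregation: population-stratified breadth summaries, comparison
tests, and the per-locus cohort coverage metric.

Per (transcript, threshold), the module computes the global mean/min/max of
per-sample breadths, per-population means, and three comparisons across
population groups: one-way ANOVA on means, pairwise two-sample
Kolmogorov-Smirnov on distributions, and Tukey's HSD on pairwise mean
differences.  Tests run on the per-sample breadth values; no
multiple-testing correction across genes is applied — callers see raw
p-values, matching common coverage-report practice.

Degenerate inputs (all breadths identical, typical at breadth = 1.0 for
well-covered genes) yield flagged NaN results rather than exceptions so
exome-wide batch runs never abort.

The per-locus metric mirrors the gnomAD coverage summary: at each coding
position, the fraction of cohort samples whose depth meets the threshold;
its gene-level mean equals the sample-mean of breadths exactly (both average
the same sample x position indicator matrix).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .breadth import BreadthProfile, ThresholdLadder
from .depth_io import DepthTrack, depth_over
from .gene_models import TranscriptModel

__all__ = [
    "SampleSheet",
    "CohortSummary",
    "LocusFractionTrack",
    "read_sample_sheet",
    "summarize_cohort",
    "anova_populations",
    "ks_pairwise",
    "tukey_hsd",
    "locus_fraction",
    "read_locus_fraction_tsv",
    "write_summary_tsv",
    "write_pairwise_tsv",
    "profiles_to_frame",
    "frame_to_profiles",
]


@dataclass(frozen=True)
class SampleSheet:
    """Mapping sample_id -> population label (e.g. AFR/AMR/EAS/EUR/SAS)."""

    population: dict[str, str]

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError("sample sheet is empty")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.population.values()))

    def samples_in(self, pop: str) -> list[str]:
        return sorted(s for s, p in self.population.items() if p == pop)


def read_sample_sheet(source: str | Path | TextIO) -> SampleSheet:
    """Read a 2-column TSV (sample_id, population); a header row is optional."""
    df = pd.read_csv(source, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("sample sheet needs 2 columns: sample_id, population")
    first = str(df.iloc[0, 0]).lower()
    if first in ("sample", "sample_id"):
        df = df.iloc[1:]
    ids = df.iloc[:, 0].tolist()
    if len(ids) != len(set(ids)):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in sheet: {dupes}")
    return SampleSheet(dict(zip(ids, df.iloc[:, 1].tolist())))


def write_sample_sheet(sheet: SampleSheet, dest: str | Path) -> None:
    with open(dest, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s in sorted(sheet.population):
            fh.write(f"{s}\t{sheet.population[s]}\n")


# --- statistical comparisons ---------------------------------------------


def anova_populations(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across population groups.

    Returns ``(F, p)`` with F on (k-1, N-k) degrees of freedom.  When both
    the between- and within-group variance are zero (every observation
    identical) the statistic is undefined and ``(nan, nan)`` is returned as
    a flagged degenerate result.  Identical groups with internal spread give
    ``F = 0, p = 1``.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:  # zero total variance: F is 0/0
        return (float("nan"), float("nan"))
    with warnings.catch_warnings():
        # singleton groups give a flagged NaN result, not a warning storm
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return (float(f), float(p))


def ks_pairwise(
    groups: Mapping[str, Sequence[float]], method: str = "asymp"
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov test for every population pair.

    D is the sup of the absolute ECDF difference; p-values use the
    asymptotic two-sample formula by default.  Returns a long DataFrame with
    columns (pop_a, pop_b, ks_D, ks_p, unreliable) where ``unreliable``
    marks pairs in which either group has a single observation.
    """
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
            # singleton groups are legal but flagged unreliable below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ks_2samp(xa, xb, method=method)
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "ks_D": float(res.statistic),
                "ks_p": float(res.pvalue),
                "unreliable": bool(len(xa) < 2 or len(xb) < 2),
            }
        )
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "ks_D", "ks_p", "unreliable"])


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey's Honest Significant Difference test over all population pairs.

    Adjusted p-values come from the studentized range distribution with the
    pooled within-group variance.  Returns a long DataFrame with columns
    (pop_a, pop_b, mean_diff, tukey_p) where mean_diff = mean(a) - mean(b).
    Zero pooled within-group variance is degenerate: differences are still
    reported, p-values are NaN (or 1.0 when all means coincide).
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("Tukey HSD requires at least 2 groups")
    k = len(arrays)
    means = [float(a.mean()) for a in arrays]
    ns = [len(a) for a in arrays]
    # pooled within-group variance (Tukey-Kramer for unequal group sizes;
    # singleton groups contribute nothing to the variance estimate)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    dof = sum(n - 1 for n in ns)
    degenerate = dof <= 0 or ss_within == 0.0
    s2 = ss_within / dof if dof > 0 else float("nan")
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        if degenerate:
            p = 1.0 if diff == 0.0 else float("nan")
        else:
            se = np.sqrt(s2 / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se if se > 0 else float("inf")
            with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.studentized_range.sf(q, k, dof))
        rows.append(
            {"pop_a": names[i], "pop_b": names[j], "mean_diff": diff, "tukey_p": p}
        )
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "mean_diff", "tukey_p"])


# --- cohort summary -------------------------------------------------------


@dataclass
class CohortSummary:
    """Per (ccds_id, threshold) cohort statistics.

    ``table`` has one row per (gene_symbol, ccds_id, threshold) with
    global_mean/global_min/global_max, one ``mean_<POP>`` column per
    population, and anova_F/anova_p.  ``pairwise`` is long-format with the
    KS and Tukey results per population pair.
    """

    table: pd.DataFrame
    pairwise: pd.DataFrame
    populations: list[str] = field(default_factory=list)

    def thresholds(self) -> list[int]:
        return sorted(int(t) for t in self.table["threshold"].unique())


def profiles_to_frame(profiles: Iterable[BreadthProfile]) -> pd.DataFrame:
    """Long-format DataFrame (sample_id, ccds_id, threshold, breadth)."""
    rows = [
        {"sample_id": p.sample_id, "ccds_id": p.ccds_id, "threshold": t, "breadth": b}
        for p in profiles
        for t, b in sorted(p.breadths.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "ccds_id", "threshold", "breadth"])


def frame_to_profiles(df: pd.DataFrame) -> list[BreadthProfile]:
    out = []
    for (sample, ccds), grp in df.groupby(["sample_id", "ccds_id"], sort=True):
        out.append(
            BreadthProfile(
                sample_id=str(sample),
                ccds_id=str(ccds),
                breadths={int(t): float(b) for t, b in zip(grp["threshold"], grp["breadth"])},
            )
        )
    return out


def summarize_cohort(
    profiles: Iterable[BreadthProfile],
    sheet: SampleSheet,
    ladder: ThresholdLadder | Sequence[int] | None = None,
    gene_symbols: Mapping[str, str] | None = None,
) -> CohortSummary:
    """Aggregate per-sample breadth profiles into a cohort summary.

    Every profiled sample must appear in the sheet.  Rows of the summary
    table are sorted ascending by global mean (worst-covered transcripts
    first), matching the standard report ordering.  *gene_symbols* maps
    ccds_id -> symbol for the report; absent ids fall back to the ccds_id.
    """
    df = profiles_to_frame(profiles)
    if df.empty:
        raise ValueError("no breadth profiles supplied")
    missing = sorted(set(df["sample_id"]) - set(sheet.population))
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    if ladder is not None:
        ladder = ladder if isinstance(ladder, ThresholdLadder) else ThresholdLadder(tuple(ladder))
        df = df[df["threshold"].isin(set(ladder.thresholds))]
    pops = sheet.populations
    df = df.assign(population=df["sample_id"].map(sheet.population))

    table_rows = []
    pair_rows = []
    for (ccds, thr), grp in df.groupby(["ccds_id", "threshold"], sort=True):
        vals = grp["breadth"].to_numpy(dtype=float)
        groups = {
            pop: sub["breadth"].to_numpy(dtype=float)
            for pop, sub in grp.groupby("population", sort=True)
        }
        row: dict = {
            "gene_symbol": (gene_symbols or {}).get(str(ccds), str(ccds)),
            "ccds_id": ccds,
            "threshold": int(thr),
            "global_mean": float(vals.mean()),
            "global_min": float(vals.min()),
            "global_max": float(vals.max()),
        }
        for pop in pops:
            row[f"mean_{pop}"] = float(groups[pop].mean()) if pop in groups else float("nan")
        if len(groups) >= 2:
            f, p = anova_populations(groups)
        else:
            f, p = float("nan"), float("nan")
        row["anova_F"], row["anova_p"] = f, p
        table_rows.append(row)
        if len(groups) >= 2:
            ks = ks_pairwise(groups)
            tk = tukey_hsd(groups)
            merged = ks.merge(tk, on=["pop_a", "pop_b"])
            merged.insert(0, "ccds_id", ccds)
            merged.insert(1, "threshold", int(thr))
            pair_rows.append(merged)

    table = pd.DataFrame(table_rows).sort_values(
        ["threshold", "global_mean", "ccds_id"], kind="mergesort"
    ).reset_index(drop=True)
    pairwise = (
        pd.concat(pair_rows, ignore_index=True)
        if pair_rows
        else pd.DataFrame(
            columns=["ccds_id", "threshold", "pop_a", "pop_b", "ks_D", "ks_p",
                     "unreliable", "mean_diff", "tukey_p"]
        )
    )
    return CohortSummary(table=table, pairwise=pairwise, populations=pops)


def write_summary_tsv(summary: CohortSummary, dest: str | Path) -> None:
    summary.table.to_csv(dest, sep="\t", index=False, float_format="%.10g")


def write_pairwise_tsv(summary: CohortSummary, dest: str | Path) -> None:
    summary.pairwise.to_csv(dest, sep="\t", index=False, float_format="%.10g")


# --- per-locus cohort metric (gnomAD-style) -------------------------------


@dataclass
class LocusFractionTrack:
    """Per coding position: fraction of samples at or above the threshold.

    ``positions`` are the model's coding positions in coordinate order;
    ``fractions`` aligns with them; ``gene_mean`` is the mean fraction over
    all coding positions, the gene-level cohort coverage value.
    """

    ccds_id: str
    threshold: int
    positions: np.ndarray
    fractions: np.ndarray
    gene_mean: float


def locus_fraction(
    tracks: Sequence[DepthTrack], model: TranscriptModel, t: int, cmp: str = "ge"
) -> LocusFractionTrack:
    """Fraction of cohort samples whose depth meets *t* at each coding locus."""
    if not tracks:
        raise ValueError("locus_fraction requires at least one depth track")
    total = model.coding_length
    if total == 0:
        raise ValueError(f"{model.ccds_id}: zero coding length")
    positions = np.concatenate(
        [np.arange(iv.start, iv.end, dtype=np.int64) for iv in model.coding_intervals]
    )
    offsets = {}
    off = 0
    for iv in model.coding_intervals:
        offsets[iv.start] = off
        off += iv.length
    counts = np.zeros(total, dtype=np.int64)
    for track in tracks:
        for iv_run, depth in depth_over(track, model.coding_intervals):
            ok = (depth >= t) if cmp == "ge" else (depth > t)
            if not ok:
                continue
            # locate run within the flattened coding coordinate space
            for iv in model.coding_intervals:
                if iv.start <= iv_run.start and iv_run.end <= iv.end:
                    lo = offsets[iv.start] + (iv_run.start - iv.start)
                    counts[lo : lo + iv_run.length] += 1
                    break
    fractions = counts / len(tracks)
    return LocusFractionTrack(
        ccds_id=model.ccds_id,
        threshold=t,
        positions=positions,
        fractions=fractions,
        gene_mean=float(fractions.mean()),
    )


def read_locus_fraction_tsv(
    source: str | Path | TextIO, ccds_id: str = "", threshold: int = 0
) -> LocusFractionTrack:
    """Import an externally computed per-locus summary.

    Expects a 2-column TSV (1-based position, fraction of samples at or
    above the depth threshold), the shape of public cohort coverage
    summaries, so externally published per-locus metrics can be displayed
    alongside cohort-computed ones.
    """
    df = pd.read_csv(source, sep="\t", header=None, comment="#",
                     names=["position", "fraction"])
    fr = df["fraction"].to_numpy(dtype=float)
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("locus fractions must lie in [0, 1]")
    return LocusFractionTrack(
        ccds_id=ccds_id,
        threshold=threshold,
        positions=df["position"].to_numpy(dtype=np.int64) - 1,
        fractions=fr,
        gene_mean=float(fr.mean()) if len(fr) else float("nan"),
    )


def write_locus_fraction_tsv(lft: LocusFractionTrack, dest: str | Path) -> None:
    with open(dest, "w") as fh:
        fh.write("#position_1based\tfraction\n")
        for pos, fr in zip(lft.positions, lft.fractions):
            fh.write(f"{pos + 1}\t{fr:.10g}\n")
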