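"""Cohort summaries, the three population-comparison tests, and the
per-locus cohort coverage metric."""

import io
import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import make_track, random_model, random_track
from wescover.breadth import BreadthProfile, breadth_of_coverage
from wescover.cohort import (
    SampleSheet,
    anova_populations,
    frame_to_profiles,
    ks_pairwise,
    locus_fraction,
    profiles_to_frame,
    read_locus_fraction_tsv,
    read_sample_sheet,
    summarize_cohort,
    tukey_hsd,
)
from wescover.gene_models import GenomicInterval, TranscriptModel


def profile(sample, ccds="C.1", **breadths):
    return BreadthProfile(sample, ccds, {int(k[1:]): v for k, v in breadths.items()})


class TestSummarize:
    def test_global_mean_min_max(self):
        profs = [profile("a", t20=0.8), profile("b", t20=0.9), profile("c", t20=1.0)]
        sheet = SampleSheet({"a": "EUR", "b": "EUR", "c": "AFR"})
        s = summarize_cohort(profs, sheet)
        row = s.table.iloc[0]
        assert row["global_mean"] == pytest.approx(0.9)
        assert row["global_min"] == 0.8
        assert row["global_max"] == 1.0
        assert row["mean_EUR"] == pytest.approx(0.85)
        assert row["mean_AFR"] == 1.0

    def test_single_population_mean_equals_global(self):
        profs = [profile("a", t20=0.7), profile("b", t20=0.9)]
        s = summarize_cohort(profs, SampleSheet({"a": "EUR", "b": "EUR"}))
        row = s.table.iloc[0]
        assert row["mean_EUR"] == row["global_mean"]
        assert np.isnan(row["anova_F"])  # one group: no comparison possible

    def test_missing_sample_listed_in_error(self):
        profs = [profile("a", t20=0.7), profile("zz", t20=0.9)]
        with pytest.raises(ValueError, match="zz"):
            summarize_cohort(profs, SampleSheet({"a": "EUR"}))

    def test_five_population_means_match_group_averages(self, rng):
        pops = ["AFR", "AMR", "EAS", "EUR", "SAS"]
        sheet, profs, by_pop = {}, [], {p: [] for p in pops}
        for p in pops:
            for k in range(6):
                sid = f"{p}{k}"
                b = float(rng.uniform(0.5, 1.0))
                sheet[sid] = p
                profs.append(profile(sid, t20=b))
                by_pop[p].append(b)
        s = summarize_cohort(profs, SampleSheet(sheet))
        row = s.table.iloc[0]
        for p in pops:
            assert row[f"mean_{p}"] == pytest.approx(np.mean(by_pop[p]))
        assert row["global_min"] <= min(row[f"mean_{p}"] for p in pops)
        assert row["global_max"] >= max(row[f"mean_{p}"] for p in pops)
        f, pval = stats.f_oneway(*[np.array(by_pop[p]) for p in pops])
        assert row["anova_F"] == pytest.approx(f)
        assert row["anova_p"] == pytest.approx(pval)

    def test_rows_sorted_ascending_by_global_mean(self):
        profs = [profile("a", t20=0.95), profile("a", ccds="C.2", t20=0.4),
                 profile("b", t20=0.85), profile("b", ccds="C.2", t20=0.5)]
        s = summarize_cohort(profs, SampleSheet({"a": "EUR", "b": "AFR"}))
        means = s.table["global_mean"].tolist()
        assert means == sorted(means)

    def test_sample_sheet_round_trip(self, tmp_path):
        from wescover.cohort import write_sample_sheet

        sheet = SampleSheet({"s1": "AFR", "s2": "EUR"})
        path = tmp_path / "sheet.tsv"
        write_sample_sheet(sheet, path)
        assert read_sample_sheet(path).population == sheet.population

    def test_profiles_frame_round_trip(self):
        profs = [profile("a", t5=1.0, t20=0.8), profile("b", t5=0.9, t20=0.7)]
        back = frame_to_profiles(profiles_to_frame(profs))
        assert {(p.sample_id, tuple(sorted(p.breadths.items()))) for p in back} == \
               {(p.sample_id, tuple(sorted(p.breadths.items()))) for p in profs}


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        f, p = anova_populations({"a": [0.1, 0.2], "b": [0.1, 0.2]})
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_k2_reduces_to_t_squared(self, rng):
        """For two groups the ANOVA F equals the square of the pooled-variance
        two-sample t statistic."""
        for _ in range(10):
            x = rng.normal(0.8, 0.05, size=12)
            y = rng.normal(0.75, 0.08, size=9)
            f, p = anova_populations({"x": x, "y": y})
            t, pt = stats.ttest_ind(x, y, equal_var=True)
            assert f == pytest.approx(t**2, abs=1e-10)
            assert p == pytest.approx(pt, abs=1e-10)

    def test_zero_total_variance_flagged_not_raised(self):
        f, p = anova_populations({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        assert np.isnan(f) and np.isnan(p)

    def test_invariant_under_shift_and_scale(self, rng):
        groups = {p: rng.normal(0.5, 0.1, size=8) for p in "abc"}
        f0, _ = anova_populations(groups)
        f_shift, _ = anova_populations({k: v + 0.17 for k, v in groups.items()})
        f_scale, _ = anova_populations({k: v * 3.5 for k, v in groups.items()})
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)

    def test_null_simulation_rejects_at_alpha(self):
        """Identical populations: ANOVA p < 0.05 in about 5% of replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = {p: rng.normal(0.9, 0.05, size=10) for p in
                      ("AFR", "AMR", "EAS", "EUR", "SAS")}
            _, p = anova_populations(groups)
            rejections += p < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestKS:
    def test_identical_samples_have_zero_distance(self):
        df = ks_pairwise({"a": [0.1, 0.5, 0.9], "b": [0.1, 0.5, 0.9]})
        assert df["ks_D"].tolist() == [0.0]

    def test_disjoint_supports_have_distance_one(self):
        df = ks_pairwise({"a": [0.0, 0.1], "b": [0.9, 1.0]})
        assert df["ks_D"].tolist() == [1.0]

    def test_single_observation_group_flagged_unreliable(self):
        df = ks_pairwise({"a": [0.5], "b": [0.4, 0.6]})
        assert bool(df["unreliable"].iloc[0])

    def test_random_pairs_match_brute_force_ecdf_sup(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 1, size=int(rng.integers(3, 15)))
            y = rng.uniform(0, 1, size=int(rng.integers(3, 15)))
            df = ks_pairwise({"x": x, "y": y})
            pooled = np.concatenate([x, y])
            d_brute = max(
                abs((x <= v).mean() - (y <= v).mean()) for v in pooled
            )
            assert df["ks_D"].iloc[0] == pytest.approx(d_brute, abs=1e-12)

    def test_all_pairs_present_for_five_groups(self, rng):
        groups = {p: rng.uniform(0, 1, 5) for p in ("AFR", "AMR", "EAS", "EUR", "SAS")}
        df = ks_pairwise(groups)
        assert len(df) == len(list(itertools.combinations(range(5), 2)))


class TestTukey:
    def test_identical_groups_all_p_one_diff_zero(self):
        df = tukey_hsd({"a": [0.5, 0.6], "b": [0.5, 0.6], "c": [0.5, 0.6]})
        assert (df["mean_diff"] == 0.0).all()
        assert (df["tukey_p"] > 0.999).all()

    def test_k2_collapses_to_unadjusted_two_sample_test(self, rng):
        """With two means the studentized range reduces to |t|*sqrt(2): the
        adjusted p equals the plain two-sample equal-variance t-test p."""
        for _ in range(10):
            x = rng.normal(0.8, 0.05, size=10)
            y = rng.normal(0.7, 0.05, size=12)
            df = tukey_hsd({"x": x, "y": y})
            _, pt = stats.ttest_ind(x, y, equal_var=True)
            assert df["tukey_p"].iloc[0] == pytest.approx(pt, abs=1e-8)

    def test_monotone_shift_gives_signed_differences(self):
        groups = {"a": [0.5, 0.52], "b": [0.6, 0.62], "c": [0.7, 0.72]}
        df = tukey_hsd(groups).set_index(["pop_a", "pop_b"])
        assert df.loc[("a", "b"), "mean_diff"] < 0
        assert df.loc[("a", "c"), "mean_diff"] < 0
        assert df.loc[("b", "c"), "mean_diff"] < 0

    def test_degenerate_variance_flagged(self):
        df = tukey_hsd({"a": [1.0, 1.0], "b": [0.9, 0.9]})
        assert np.isnan(df["tukey_p"].iloc[0])
        assert df["mean_diff"].iloc[0] == pytest.approx(0.1)


class TestLocusFraction:
    def test_half_covered_cohort(self):
        model = TranscriptModel("C.1", "G", "1", "+", (GenomicInterval("1", 0, 100),))
        full = make_track("full", "1", [(0, 100, 50)])
        none = make_track("none", "1", [(0, 100, 1)])
        lft = locus_fraction([full, none], model, 20)
        assert (lft.fractions == 0.5).all()
        assert lft.gene_mean == 0.5

    def test_single_sample_collapses_to_indicator(self, rng):
        model = random_model(rng, span=600)
        track = random_track(rng, span=600)
        lft = locus_fraction([track], model, 10)
        assert set(np.unique(lft.fractions)) <= {0.0, 1.0}
        assert lft.gene_mean == pytest.approx(breadth_of_coverage(track, model, 10))

    def test_exchange_identity_with_mean_breadth(self, rng):
        """The gene-level mean of per-locus sample fractions equals the
        sample-mean of breadths: both average one indicator matrix."""
        for _ in range(10):
            model = random_model(rng, span=800)
            tracks = [random_track(rng, span=800, sample_id=f"S{i}") for i in range(7)]
            t = int(rng.integers(1, 40))
            lft = locus_fraction(tracks, model, t)
            mean_breadth = np.mean([breadth_of_coverage(tr, model, t) for tr in tracks])
            assert lft.gene_mean == pytest.approx(mean_breadth, abs=1e-12)

    def test_locus_fraction_tsv_round_trip(self, tmp_path, rng):
        from wescover.cohort import write_locus_fraction_tsv

        model = random_model(rng, span=500)
        tracks = [random_track(rng, span=500, sample_id=f"S{i}") for i in range(3)]
        lft = locus_fraction(tracks, model, 10)
        path = tmp_path / "lf.tsv"
        write_locus_fraction_tsv(lft, path)
        back = read_locus_fraction_tsv(path, ccds_id=lft.ccds_id, threshold=10)
        assert np.array_equal(back.positions, lft.positions)
        assert np.allclose(back.fractions, lft.fractions)
        assert back.gene_mean == pytest.approx(lft.gene_mean)
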