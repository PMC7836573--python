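"""Abundance profiles, mock scoring, rarefaction and cross-method comparison."""

import math

import numpy as np
import pytest

from amplicon16s.classify import ReadClassification
from amplicon16s.profile_eval import (
    AbundanceProfile,
    accumulation_curve,
    ambiguous_fraction,
    build_profile,
    compare_methods,
    conditional_species_profile,
    depth_correlation,
    filter_low_abundance,
    score_mock,
)
from amplicon16s.simulate import Community, SimTruth


def _sp(read_id, taxon):
    return ReadClassification(read_id, taxon, "species", "species_level", 100)


def _genus(read_id, taxon):
    return ReadClassification(read_id, taxon, "genus", "ambiguous_lca", 100)


def _uncls(read_id):
    return ReadClassification(read_id, None, None, "unclassified")


class TestBuildProfile:
    def test_species_split(self, toy_taxonomy):
        cls = [_sp(f"r{i}", "100") for i in range(6)] + [
            _sp(f"s{i}", "102") for i in range(4)
        ]
        prof = build_profile(cls, toy_taxonomy, "species")
        assert prof.percent("100") == pytest.approx(60.0)
        assert prof.percent("102") == pytest.approx(40.0)
        assert prof.unassigned_count == 0

    def test_genus_level_read_unassigned_at_species(self, toy_taxonomy):
        cls = [_sp("r1", "100"), _genus("r2", "50")]
        genus_prof = build_profile(cls, toy_taxonomy, "genus")
        sp_prof = build_profile(cls, toy_taxonomy, "species")
        assert genus_prof.counts["50"] == 2
        assert sp_prof.counts == {"100": 1}
        assert sp_prof.unassigned_count == 1
        # unfiltered percentages + unassigned fraction account for 100%
        total_pct = sum(sp_prof.percentages.values()) + 100 * sp_prof.unassigned_count / sp_prof.total_classified
        assert total_pct == pytest.approx(100.0)

    def test_matches_brute_force_tally(self, toy_taxonomy):
        rng = np.random.default_rng(31)
        taxa = ["100", "101", "102", "103", "110"]
        cls = [
            _sp(f"r{i}", taxa[rng.integers(len(taxa))]) for i in range(200)
        ] + [_uncls(f"u{i}") for i in range(10)]
        prof = build_profile(cls, toy_taxonomy, "genus")
        oracle = {}
        for c in cls:
            if c.status != "species_level":
                continue
            g = toy_taxonomy.rollup(c.taxon_id, "genus")
            oracle[g] = oracle.get(g, 0) + 1
        assert prof.counts == oracle
        assert prof.total_classified == 200

    def test_unknown_rank(self, toy_taxonomy):
        with pytest.raises(ValueError):
            build_profile([], toy_taxonomy, "tribe")


class TestLowAbundanceFilter:
    def test_strict_threshold_at_20k_reads(self, toy_taxonomy):
        cls = (
            [_sp(f"a{i}", "100") for i in range(19997)]
            + [_sp("b0", "101")]  # 1 read = 0.005% -> removed
            + [_sp("c0", "102"), _sp("c1", "102")]  # 2 reads = 0.01% -> kept
        )
        prof = build_profile(cls, toy_taxonomy, "species")
        filt = filter_low_abundance(prof, 0.01)
        assert "101" not in filt.counts and "102" in filt.counts
        assert filt.filtered

    def test_zero_threshold_is_identity(self, toy_taxonomy):
        prof = build_profile([_sp("r", "100")], toy_taxonomy, "species")
        assert filter_low_abundance(prof, 0.0).counts == prof.counts

    def test_negative_threshold_raises(self, toy_taxonomy):
        prof = build_profile([], toy_taxonomy, "species")
        with pytest.raises(ValueError):
            filter_low_abundance(prof, -1.0)

    def test_never_increases_counts(self, toy_taxonomy):
        rng = np.random.default_rng(5)
        cls = [_sp(f"r{i}", rng.choice(["100", "101", "102"])) for i in range(500)]
        prof = build_profile(cls, toy_taxonomy, "species")
        filt = filter_low_abundance(prof, 0.5)
        assert all(filt.counts[t] == prof.counts[t] for t in filt.counts)
        assert set(filt.counts) <= set(prof.counts)


class TestConditionalProfile:
    def test_even_species_within_genus(self, toy_taxonomy):
        cls = [_sp(f"a{i}", "100") for i in range(5)] + [
            _sp(f"b{i}", "101") for i in range(5)
        ]
        prof = conditional_species_profile(cls, toy_taxonomy, "50")
        assert prof.percent("100") == pytest.approx(50.0)
        assert prof.percent("101") == pytest.approx(50.0)

    def test_other_genus_excluded(self, toy_taxonomy):
        cls = [_sp("a", "100"), _sp("b", "102")]
        prof = conditional_species_profile(cls, toy_taxonomy, "50")
        assert prof.total_classified == 1 and "102" not in prof.counts

    def test_remainder_bucket_counts_genus_lca_reads(self, toy_taxonomy):
        cls = [_sp("a", "100"), _genus("b", "50"), _genus("c", "50")]
        prof = conditional_species_profile(cls, toy_taxonomy, "50")
        assert prof.unassigned_count == 2

    def test_non_genus_target_rejected(self, toy_taxonomy):
        with pytest.raises(ValueError):
            conditional_species_profile([], toy_taxonomy, "100")


def _truth(pairs):
    return SimTruth({rid: (taxon, "none") for rid, taxon in pairs}, Community(()))


class TestScoreMock:
    def test_all_correct(self, toy_taxonomy):
        cls = [_sp(f"r{i}", "100") for i in range(10)]
        truth = _truth([(f"r{i}", "100") for i in range(10)])
        rep = score_mock(cls, truth, toy_taxonomy, "species")
        assert (rep.correct_pct, rep.misclassified_pct, rep.unclassified_pct) == (
            100.0, 0.0, 0.0,
        )

    def test_one_unexpected_genus_at_genus_rank(self, toy_taxonomy):
        cls = [_sp(f"r{i}", "100") for i in range(9)] + [_sp("r9", "102")]
        truth = _truth([(f"r{i}", "100") for i in range(10)])
        rep = score_mock(cls, truth, toy_taxonomy, "genus")
        assert rep.correct_pct == pytest.approx(90.0)
        assert rep.misclassified_pct == pytest.approx(10.0)
        assert rep.unclassified_pct == pytest.approx(0.0)

    def test_genus_lca_read_is_unclassified_at_species(self, toy_taxonomy):
        cls = [_sp("r0", "100"), _genus("r1", "50")]
        truth = _truth([("r0", "100"), ("r1", "101")])
        rep = score_mock(cls, truth, toy_taxonomy, "species")
        assert rep.unclassified_pct == pytest.approx(50.0)
        rep_g = score_mock(cls, truth, toy_taxonomy, "genus")
        assert rep_g.correct_pct == pytest.approx(100.0)

    def test_matches_confusion_tally_and_sums_to_100(self, toy_taxonomy):
        rng = np.random.default_rng(17)
        taxa = ["100", "101", "102", "103"]
        cls, pairs = [], []
        for i in range(50):
            true = taxa[rng.integers(4)]
            roll = rng.random()
            if roll < 0.6:
                cls.append(_sp(f"r{i}", true))
            elif roll < 0.8:
                cls.append(_sp(f"r{i}", taxa[rng.integers(4)]))
            elif roll < 0.9:
                cls.append(_genus(f"r{i}", "50"))
            else:
                cls.append(_uncls(f"r{i}"))
            pairs.append((f"r{i}", true))
        truth = _truth(pairs)
        rep = score_mock(cls, truth, toy_taxonomy, "species")
        n_corr = sum(
            1 for c, (_, t) in zip(cls, pairs)
            if c.taxon_id is not None
            and toy_taxonomy.rollup(c.taxon_id, "species") == t
        )
        n_uncls = sum(
            1 for c in cls
            if c.taxon_id is None
            or toy_taxonomy.rollup(c.taxon_id, "species") is None
        )
        assert rep.correct_pct == pytest.approx(100 * n_corr / 50)
        assert rep.unclassified_pct == pytest.approx(100 * n_uncls / 50)
        assert rep.correct_pct + rep.misclassified_pct + rep.unclassified_pct == pytest.approx(100.0)

    def test_per_genus_species_accuracy(self, toy_taxonomy):
        # genus-correct reads: 3 of Streptococcus (2 right species), 1 genus-level
        cls = [
            _sp("r0", "100"), _sp("r1", "100"), _sp("r2", "101"), _genus("r3", "50"),
            _sp("r4", "102"),
        ]
        truth = _truth(
            [("r0", "100"), ("r1", "100"), ("r2", "100"), ("r3", "100"), ("r4", "102")]
        )
        rep = score_mock(cls, truth, toy_taxonomy, "species")
        assert rep.per_genus_species_accuracy["50"] == pytest.approx(100 * 2 / 4)
        assert rep.per_genus_species_accuracy["51"] == pytest.approx(100.0)

    def test_missing_truth_raises(self, toy_taxonomy):
        with pytest.raises(ValueError):
            score_mock([_sp("r0", "100")], _truth([]), toy_taxonomy, "species")


class TestAmbiguousFraction:
    def test_basic_ratio(self):
        cls = [_sp(f"r{i}", "100") for i in range(20)] + [
            _genus(f"g{i}", "50") for i in range(5)
        ]
        assert ambiguous_fraction(cls) == pytest.approx(20.0)

    def test_all_species_level(self):
        assert ambiguous_fraction([_sp("r", "100")]) == 0.0

    def test_empty_is_nan(self):
        assert math.isnan(ambiguous_fraction([_uncls("r")]))


class TestAccumulationCurve:
    def _cls(self):
        # 300 reads: 100 each of three species
        return (
            [_sp(f"a{i}", "100") for i in range(100)]
            + [_sp(f"b{i}", "101") for i in range(100)]
            + [_sp(f"c{i}", "102") for i in range(100)]
        )

    def test_full_depth_exact_and_sd_zero(self, toy_taxonomy):
        tab = accumulation_curve(self._cls(), toy_taxonomy, [300], n_reps=5, seed=1)
        assert tab.mean_species.iloc[0] == 3.0
        assert tab.sd_species.iloc[0] == 0.0

    def test_monotone_in_depth(self, toy_taxonomy):
        tab = accumulation_curve(
            self._cls(), toy_taxonomy, [1, 3, 10, 50, 300], n_reps=20, seed=2
        )
        means = tab.mean_species.to_numpy()
        assert (np.diff(means) >= 0).all()

    def test_matches_hypergeometric_expectation(self, toy_taxonomy):
        # E[detected] = 3 * (1 - C(200, d)/C(300, d)) for uniform 100/100/100
        depths = [1, 2, 5, 10, 25]
        n_reps = 200
        tab = accumulation_curve(
            self._cls(), toy_taxonomy, depths, n_reps=n_reps, seed=3
        )
        for d, mean, sd in tab.itertuples(index=False):
            expect = 3 * (1 - math.comb(200, d) / math.comb(300, d))
            se = max(sd, 1e-9) / math.sqrt(n_reps)
            assert abs(mean - expect) < max(4 * se, 0.05)

    def test_depth_beyond_total_raises(self, toy_taxonomy):
        with pytest.raises(ValueError):
            accumulation_curve(self._cls(), toy_taxonomy, [301], seed=0)


class TestDepthCorrelation:
    def test_two_taxon_vectors_fully_correlated(self, toy_taxonomy):
        cls = [_sp(f"a{i}", "100") for i in range(300)] + [
            _sp(f"b{i}", "101") for i in range(200)
        ]
        r = depth_correlation(cls, toy_taxonomy, 100, 400, seed=4)
        assert r == pytest.approx(1.0)

    def test_single_taxon_is_nan(self, toy_taxonomy):
        cls = [_sp(f"a{i}", "100") for i in range(50)]
        assert math.isnan(depth_correlation(cls, toy_taxonomy, 10, 40, seed=0))

    def test_bad_depths(self, toy_taxonomy):
        cls = [_sp(f"a{i}", "100") for i in range(50)]
        with pytest.raises(ValueError):
            depth_correlation(cls, toy_taxonomy, 40, 10, seed=0)
        with pytest.raises(ValueError):
            depth_correlation(cls, toy_taxonomy, 10, 100, seed=0)


class TestCompareMethods:
    def _prof(self, counts, total):
        return AbundanceProfile("genus", counts, total)

    def test_identical_profiles_r_one(self):
        p = self._prof({"50": 60, "51": 40}, 100)
        _, rmat = compare_methods({"a": p, "b": p})
        assert rmat.loc["a", "b"] == pytest.approx(1.0)

    def test_disjoint_taxa_hand_pearson(self):
        pa = self._prof({"t1": 60, "t2": 40}, 100)
        pb = self._prof({"t3": 70, "t4": 30}, 100)
        _, rmat = compare_methods({"a": pa, "b": pb})
        # x = [60,40,0,0], y = [0,0,70,30]: r = -2500 / sqrt(2700*3300)
        assert rmat.loc["a", "b"] == pytest.approx(-2500 / math.sqrt(2700 * 3300))

    def test_row_bound_and_long_format(self):
        pa = self._prof({f"t{i}": i + 1 for i in range(30)}, 465)
        pb = self._prof({f"u{i}": i + 1 for i in range(30)}, 465)
        long, _ = compare_methods({"a": pa, "b": pb}, top_n=15)
        taxa = long.taxon_id.unique()
        assert len(taxa) <= 15 * 2
        assert set(long.columns) == {"sample", "taxon_id", "percent"}

    def test_mixed_ranks_rejected(self):
        pa = AbundanceProfile("genus", {"t": 1}, 1)
        pb = AbundanceProfile("species", {"t": 1}, 1)
        with pytest.raises(ValueError):
            compare_methods({"a": pa, "b": pb})
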