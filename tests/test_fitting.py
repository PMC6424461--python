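"""Binning, RMSD minimization, mixtures, bootstrap and robustness checks."""

import warnings

import numpy as np
import pytest

from multihit import (
    ModelParams,
    MutationCountCohort,
    SimulationSpec,
    bin_model,
    bin_observed,
    bootstrap_hit_ci,
    fit_mixture,
    fit_single,
    prob_any_combination,
    rmsd,
    sample_cohort,
    sensitivity_G,
    subsample_stability,
)


def _cohort(counts):
    return MutationCountCohort(cancer_type="test", counts=np.asarray(counts))


class TestBinObserved:
    def test_even_spread(self):
        b = bin_observed(_cohort([50, 150, 250]))
        assert b.percentages[:3] == pytest.approx([100 / 3] * 3)
        assert b.percentages[3:].sum() == 0

    def test_boundary_is_inclusive(self):
        # a count of exactly 100 belongs to the first bin (0-100)
        b = bin_observed(_cohort([100, 100, 200]))
        assert b.percentages[0] == pytest.approx(200 / 3)
        assert b.percentages[1] == pytest.approx(100 / 3)

    def test_overflow_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="hypermutator"):
            b = bin_observed(_cohort([5100]))
        assert b.n_samples_included == 0
        assert b.n_samples_excluded_overflow == 1

    def test_percentages_sum_to_100(self, brca_like_cohort):
        b = bin_observed(brca_like_cohort)
        assert b.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            bin_observed(_cohort([]))


class TestBinModel:
    def test_total_mass_conserved(self, default_G):
        p = ModelParams(G=default_G, h=3, k=9e14)
        b = bin_model(p)
        assert b.percentages.sum() == pytest.approx(
            100 * prob_any_combination(p, b.m_max), abs=1e-9
        )

    def test_toy_bins_match_enumeration(self):
        # G=3, h=2, k=1 with bins {0..2} and {3, 4}: P_k(2)=2/9, P_k(4)=50/81
        b = bin_model(ModelParams(G=3, h=2, k=1), bin_width=2, n_bins=2)
        assert b.percentages[0] == pytest.approx(100 * 2 / 9, abs=1e-10)
        assert b.percentages[1] == pytest.approx(100 * (50 / 81 - 2 / 9), abs=1e-10)

    def test_unreachable_hits_give_empty_bins(self):
        b = bin_model(ModelParams(G=100, h=20, k=1), bin_width=1, n_bins=10)
        assert np.all(b.percentages == 0)


class TestRmsd:
    def test_identical_is_zero(self, brca_like_cohort):
        b = bin_observed(brca_like_cohort)
        assert rmsd(b, b) == 0.0

    def test_hand_computed_value(self):
        a = bin_observed(_cohort([50]))
        b = bin_observed(_cohort([150]))
        # two bins differ by 100 points each over 50 bins
        assert rmsd(a, b) == pytest.approx(np.sqrt(2 * 100.0**2 / 50))
        assert rmsd(a, b) == pytest.approx(20.0)
        assert rmsd(b, a) == rmsd(a, b)

    def test_binning_mismatch_rejected(self):
        a = bin_observed(_cohort([50]), n_bins=50)
        b = bin_observed(_cohort([50]), n_bins=40)
        with pytest.raises(ValueError):
            rmsd(a, b)


class TestFitSingle:
    def test_recovers_three_hit_model(self, default_G, brca_like_cohort):
        fit = fit_single(brca_like_cohort, G=default_G)
        assert fit.best.h == 3
        # true k = 9e14 recovered within about one mantissa step
        assert 0.75 <= fit.best.k / 9e14 <= 1.35
        assert fit.rmsd_percent < 2.0
        assert set(fit.per_h_best) == set(range(1, 10))

    def test_recovers_two_hit_model(self, default_G):
        cohort = sample_cohort(
            SimulationSpec(
                components=(ModelParams(G=default_G, h=2, k=2e9),), n_samples=500, seed=21
            )
        )
        assert fit_single(cohort, G=default_G).best.h == 2

    def test_invariant_to_sample_order(self, default_G, brca_like_cohort):
        rng = np.random.default_rng(0)
        perm = rng.permutation(brca_like_cohort.n)
        shuffled = MutationCountCohort(
            cancer_type="x",
            counts=brca_like_cohort.counts[perm],
            sample_ids=[f"R{i}" for i in range(brca_like_cohort.n)],
        )
        a, b = fit_single(brca_like_cohort, G=default_G), fit_single(shuffled, G=default_G)
        assert (a.best.h, a.best.k, a.rmsd_percent) == (b.best.h, b.best.k, b.rmsd_percent)

    def test_small_cohort_warns(self, default_G):
        cohort = _cohort([100, 900, 1100, 1500] * 10)
        with pytest.warns(UserWarning, match="robust"):
            fit_single(cohort, G=default_G)

    def test_empty_cohort_rejected(self, default_G):
        with pytest.raises(ValueError):
            fit_single(_cohort([]), G=default_G)


class TestFitMixture:
    def test_mixture_mass_is_weighted_mean(self, default_G):
        pa = bin_model(ModelParams(G=default_G, h=3, k=3e14))
        pb = bin_model(ModelParams(G=default_G, h=8, k=8e39))
        mix = 0.5 * pa.percentages + 0.5 * pb.percentages
        assert mix[10] == pytest.approx((pa.percentages[10] + pb.percentages[10]) / 2)

    def test_beats_single_fit_on_pure_cohort(self, default_G, brca_like_cohort):
        single = fit_single(brca_like_cohort, G=default_G)
        mix = fit_mixture(brca_like_cohort, G=default_G)
        assert mix.rmsd_percent <= single.rmsd_percent + 0.2
        assert mix.hi < mix.hj
        assert mix.a_percent in set(range(10, 100, 10))

    def test_empty_grids_rejected(self, default_G, brca_like_cohort):
        with pytest.raises(ValueError):
            fit_mixture(brca_like_cohort, G=default_G, h_pairs=[])
        with pytest.raises(ValueError):
            fit_mixture(brca_like_cohort, G=default_G, a_grid=[])
        with pytest.raises(ValueError):
            fit_mixture(brca_like_cohort, G=default_G, h_pairs=[(5, 3)])


class TestBootstrap:
    def test_degenerate_cohort_gives_point_interval(self, default_G):
        cohort = sample_cohort(
            SimulationSpec(
                components=(ModelParams(G=default_G, h=3, k=9e14),),
                n_samples=3000,
                seed=2,
            )
        )
        lo, hi = bootstrap_hit_ci(cohort, G=default_G, n_boot=50, seed=0)
        assert (lo, hi) == (3, 3)

    def test_interval_contains_true_h(self, default_G, brca_like_cohort):
        lo, hi = bootstrap_hit_ci(brca_like_cohort, G=default_G, n_boot=200, seed=0)
        assert lo <= 3 <= hi

    def test_deterministic_given_seed(self, default_G, brca_like_cohort):
        a = bootstrap_hit_ci(brca_like_cohort, G=default_G, n_boot=100, seed=7)
        b = bootstrap_hit_ci(brca_like_cohort, G=default_G, n_boot=100, seed=7)
        assert a == b

    def test_coverage_over_replications(self, default_G):
        true = ModelParams(G=default_G, h=3, k=9e14)
        covered = 0
        for seed in range(10):
            cohort = sample_cohort(
                SimulationSpec(components=(true,), n_samples=500, seed=100 + seed)
            )
            lo, hi = bootstrap_hit_ci(cohort, G=default_G, n_boot=100, seed=seed)
            covered += lo <= true.h <= hi
        assert covered >= 9

    def test_zero_replicates_rejected(self, default_G, brca_like_cohort):
        with pytest.raises(ValueError):
            bootstrap_hit_ci(brca_like_cohort, G=default_G, n_boot=0)


class TestRobustness:
    def test_subsample_keeps_h(self, default_G, brca_like_cohort):
        report = subsample_stability(
            brca_like_cohort, G=default_G, fraction=0.8, n_reps=10, seed=5
        )
        assert report.h_always_unchanged

    def test_full_fraction_is_identity(self, default_G, brca_like_cohort):
        report = subsample_stability(
            brca_like_cohort, G=default_G, fraction=1.0, n_reps=2, seed=5
        )
        assert report.replicates["delta_rmsd"].abs().max() == 0.0
        assert report.replicates["k_unchanged"].all()

    def test_tiny_subset_rejected(self, default_G):
        with pytest.raises(ValueError):
            subsample_stability(_cohort([100, 200]), G=default_G, fraction=0.5)

    def test_sensitivity_to_G_factor_eight(self, default_G, brca_like_cohort):
        results = sensitivity_G(brca_like_cohort, G_factors=(1.0, 8.0), G_base=default_G)
        assert results[1.0].best.h == results[8.0].best.h

    def test_factor_one_matches_plain_fit(self, default_G, brca_like_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = fit_single(brca_like_cohort, G=default_G)
        results = sensitivity_G(brca_like_cohort, G_factors=(1.0,), G_base=default_G)
        assert results[1.0].best == plain.best
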