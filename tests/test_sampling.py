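"""Subsampling: hypergeometric occurrence, sampled moments, posteriors."""

import itertools
import math

import numpy as np
import pytest

from conftest import (
    compositions,
    exact_sampled_moments,
    multinomial_pmf,
    random_probability_vector,
    subset_poisson_binomial,
)
from pubrep.errors import ConfigurationError, InvalidInputError
from pubrep.overlap import overlap_observed
from pubrep.repertoire import CloneAbundance, CloneProbabilities, Cohort
from pubrep.richness import richness_moments_p, richness_observed
from pubrep.sampling import (
    SampleConfiguration,
    group_sample_occurrence,
    log_binomial_ratio,
    posterior_expected_richness,
    sample_occurrence,
    sampled_moments_p,
    sampled_occurrence_p,
    sampled_overlap_moments_n,
    sampled_overlap_pmf,
    sampled_richness_moments_n,
)


def n_cohort(counts_list, sample_sizes=None):
    return Cohort(
        members=tuple(CloneAbundance(np.asarray(c)) for c in counts_list),
        sample_sizes=None if sample_sizes is None else tuple(sample_sizes),
    )


class TestLogBinomialRatio:
    def test_examples(self):
        assert log_binomial_ratio(4, 2, 2) == pytest.approx(math.log(1 / 6))
        assert log_binomial_ratio(9, 0, 4) == 0.0
        assert log_binomial_ratio(9, 3, 0) == 0.0
        assert log_binomial_ratio(5, 3, 3) == -math.inf

    def test_matches_comb_ratio(self, rng):
        for _ in range(30):
            N = int(rng.integers(2, 60))
            n = int(rng.integers(0, N + 1))
            S = int(rng.integers(0, N + 1))
            expected = (
                math.log(math.comb(N - n, S) / math.comb(N, S))
                if S <= N - n
                else -math.inf
            )
            assert log_binomial_ratio(N, n, S) == pytest.approx(
                expected, abs=1e-10
            )

    def test_range_validation(self):
        with pytest.raises(InvalidInputError):
            log_binomial_ratio(4, 5, 2)
        with pytest.raises(InvalidInputError):
            log_binomial_ratio(4, 1, 5)


class TestSampleOccurrence:
    def test_single_clone_example(self):
        # 6 two-cell subsets of 4 labeled cells; clone i (2 cells) missed
        # by exactly one subset.
        assert sample_occurrence((4, 2), 2) == pytest.approx(5 / 6)

    def test_pair_example(self):
        # Subsets containing a cell of each type: 4 of 6.
        assert sample_occurrence((4, 2), [2, 2]) == pytest.approx(2 / 3)

    def test_complete_sampling(self):
        assert sample_occurrence((7, 7), 3) == pytest.approx(1.0)
        assert sample_occurrence((7, 7), [3, 4]) == pytest.approx(1.0)

    def test_matches_subset_enumeration(self):
        """sigma_i and sigma_ij vs direct enumeration of labeled subsets."""
        parent = (3, 2, 1)  # N = 6
        N = sum(parent)
        cells = [i for i, n in enumerate(parent) for _ in range(n)]
        for S in (1, 2, 4):
            subsets = list(itertools.combinations(range(N), S))
            present_i = sum(
                1 for sub in subsets if any(cells[c] == 0 for c in sub)
            ) / len(subsets)
            present_ij = sum(
                1
                for sub in subsets
                if any(cells[c] == 0 for c in sub)
                and any(cells[c] == 1 for c in sub)
            ) / len(subsets)
            assert sample_occurrence((N, S), parent[0]) == pytest.approx(
                present_i, abs=1e-12
            )
            assert sample_occurrence(
                (N, S), [parent[0], parent[1]]
            ) == pytest.approx(present_ij, abs=1e-12)


class TestGroupSampleOccurrence:
    def test_two_member_example(self):
        cohort = n_cohort([[1, 1], [1, 1]], sample_sizes=[1, 1])
        # Each one-cell sample misses clone 1 w.p. 1/2.
        assert group_sample_occurrence(cohort, 0) == pytest.approx(0.75)

    def test_absent_everywhere(self):
        cohort = n_cohort([[0, 2], [0, 3]], sample_sizes=[1, 1])
        assert group_sample_occurrence(cohort, 0) == 0.0

    def test_complete_sampling_in_one_member(self):
        cohort = n_cohort([[1, 1], [0, 2]], sample_sizes=[2, 2])
        assert group_sample_occurrence(cohort, 0) == pytest.approx(1.0)

    def test_requires_sample_sizes(self):
        cohort = n_cohort([[1, 1]])
        with pytest.raises(ConfigurationError):
            group_sample_occurrence(cohort, 0)


class TestSampledRichness:
    def test_complete_sampling_is_deterministic(self):
        cohort = n_cohort([[2, 0, 3]], sample_sizes=[5])
        s = sampled_richness_moments_n(cohort)
        assert s.mean == pytest.approx(2.0)
        assert s.variance == pytest.approx(0.0, abs=1e-10)

    def test_two_clone_enumeration(self):
        # counts (2,2), S=2: of the 6 subsets, 4 contain both clones.
        cohort = n_cohort([[2, 2]], sample_sizes=[2])
        s = sampled_richness_moments_n(cohort)
        assert s.mean == pytest.approx(5 / 3)
        assert s.second_moment == pytest.approx(5 / 3 + 2 * (2 / 3))
        assert s.variance == pytest.approx(2 / 9)

    @pytest.mark.parametrize(
        "counts,S", [((3, 2, 1), 2), ((1, 1, 2), 3), ((4, 1), 2)]
    )
    def test_individual_matches_enumeration(self, counts, S):
        mean, second = exact_sampled_moments([counts], [S], "richness")
        cohort = n_cohort([counts], sample_sizes=[S])
        s = sampled_richness_moments_n(cohort)
        assert s.mean == pytest.approx(mean, abs=1e-10)
        assert s.second_moment == pytest.approx(second, abs=1e-10)

    def test_group_matches_enumeration(self):
        counts = [(2, 1, 1), (0, 2, 2)]
        Ss = [2, 3]
        mean, second = exact_sampled_moments(counts, Ss, "group_richness")
        s = sampled_richness_moments_n(
            n_cohort(counts, sample_sizes=Ss), group=True
        )
        assert s.mean == pytest.approx(mean, abs=1e-10)
        assert s.second_moment == pytest.approx(second, abs=1e-10)

    def test_group_flag_required_for_multimember(self):
        cohort = n_cohort([[1, 1], [1, 1]], sample_sizes=[1, 1])
        with pytest.raises(InvalidInputError):
            sampled_richness_moments_n(cohort)

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = np.array([5, 3, 2, 1, 1, 4, 2, 2])
        S, reps = 6, 100_000
        draws = rng.multivariate_hypergeometric(counts, S, size=reps)
        values = np.count_nonzero(draws, axis=1)
        s = sampled_richness_moments_n(
            n_cohort([counts], sample_sizes=[S])
        )
        se = values.std(ddof=1) / math.sqrt(reps)
        assert abs(s.mean - values.mean()) < 4 * se


class TestSampledOverlap:
    def test_two_member_single_cell_samples(self):
        cohort = n_cohort([[1, 1], [1, 1]], sample_sizes=[1, 1])
        s = sampled_overlap_moments_n(cohort)
        assert s.mean == pytest.approx(0.5)

    def test_complete_sampling_recovers_observed(self):
        counts = [(2, 0, 1, 3), (1, 1, 0, 2)]
        cohort = n_cohort(counts, sample_sizes=[6, 4])
        s = sampled_overlap_moments_n(cohort)
        assert s.mean == pytest.approx(overlap_observed(n_cohort(counts)))
        assert s.variance == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize(
        "counts,Ss",
        [
            ([(2, 1, 1), (1, 2, 1)], (2, 2)),
            ([(3, 1), (1, 3)], (2, 3)),
        ],
    )
    def test_matches_enumeration(self, counts, Ss):
        mean, second = exact_sampled_moments(counts, list(Ss), "overlap")
        s = sampled_overlap_moments_n(n_cohort(counts, sample_sizes=Ss))
        assert s.mean == pytest.approx(mean, abs=1e-10)
        assert s.second_moment == pytest.approx(second, abs=1e-10)

    def test_mean_nondecreasing_in_sample_size(self):
        counts = [(10, 5, 3, 2), (4, 6, 2, 8)]
        observed = overlap_observed(n_cohort(counts))
        means = []
        for S in (1, 5, 10, 15, 20):
            s = sampled_overlap_moments_n(
                n_cohort(counts, sample_sizes=[S, S])
            )
            means.append(s.mean)
            assert s.mean <= observed + 1e-12
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))


class TestSampledOverlapPMF:
    def test_point_mass_at_complete_sampling(self):
        counts = [(2, 1, 0), (1, 2, 3)]
        cohort = n_cohort(counts, sample_sizes=[3, 6])
        pmf = sampled_overlap_pmf(cohort)
        k = overlap_observed(n_cohort(counts))
        assert pmf.mass[k] == pytest.approx(1.0)

    def test_mean_agrees_with_moment_formula(self, rng):
        counts = [
            rng.integers(0, 6, size=10),
            rng.integers(0, 6, size=10),
        ]
        counts = [np.maximum(c, 0) for c in counts]
        cohort = n_cohort(counts, sample_sizes=[5, 5])
        pmf = sampled_overlap_pmf(cohort)
        s = sampled_overlap_moments_n(cohort)
        assert pmf.mean == pytest.approx(s.mean, abs=1e-9)

    def test_matches_subset_oracle_on_success_probs(self):
        from pubrep.sampling import sampled_overlap_success_probs

        counts = [(1, 2, 1, 3, 1, 2, 1, 1, 2, 1)] * 2
        cohort = n_cohort(counts, sample_sizes=[4, 6])
        probs = sampled_overlap_success_probs(cohort)
        pmf = sampled_overlap_pmf(cohort)
        np.testing.assert_allclose(
            pmf.mass, subset_poisson_binomial(probs.tolist()), atol=1e-12
        )


class TestSampledOccurrenceP:
    def test_single_member_forms(self):
        assert sampled_occurrence_p([0.5], 2) == pytest.approx(0.75)
        assert sampled_occurrence_p([0.5], 0) == 0.0
        assert sampled_occurrence_p([(0.5, 0.5)], 2) == pytest.approx(0.5)

    def test_group_forms(self):
        assert sampled_occurrence_p([0.5, 0.5], [1, 1], group=True) == (
            pytest.approx(0.75)
        )

    def test_pair_matches_multinomial_enumeration(self, rng):
        p = random_probability_vector(rng, 3)
        for S in (1, 2, 4):
            exact = sum(
                multinomial_pmf(c, p)
                for c in compositions(S, 3)
                if c[0] >= 1 and c[1] >= 1
            )
            assert sampled_occurrence_p(
                [(p[0], p[1])], S
            ) == pytest.approx(exact, abs=1e-12)


class TestSampledMomentsP:
    def test_overlap_two_single_draws(self):
        cohort = Cohort(
            members=(CloneProbabilities(np.array([0.5, 0.5])),) * 2,
            population_sizes=(100, 100),
            sample_sizes=(1, 1),
        )
        s = sampled_moments_p(cohort, "overlap")
        assert s.mean == pytest.approx(0.5)

    def test_richness_reduces_to_unsampled_form_with_s(self, rng):
        p = random_probability_vector(rng, 6)
        cohort = Cohort(
            members=(CloneProbabilities(p),),
            population_sizes=(500,),
            sample_sizes=(40,),
        )
        s = sampled_moments_p(cohort, "richness")
        ref = richness_moments_p(CloneProbabilities(p), 40)
        assert s.mean == pytest.approx(ref.mean, abs=1e-12)
        assert s.variance == pytest.approx(ref.variance, abs=1e-12)

    def test_unknown_statistic_rejected(self):
        cohort = Cohort(
            members=(CloneProbabilities(np.array([1.0])),),
            population_sizes=(5,),
            sample_sizes=(2,),
        )
        with pytest.raises(InvalidInputError):
            sampled_moments_p(cohort, "simpson")


class TestConjugacy:
    def test_two_stage_equals_one_stage_sampling(self, rng):
        """Multinomial(N) then hypergeometric(S) ~ multinomial(S).

        Compare both empirical distributions over full sample
        configurations against the exact multinomial(S) pmf, cellwise
        within 4 binomial standard errors.
        """
        omega, N, S, reps = 3, 6, 3, 50_000
        p = np.array([0.5, 0.3, 0.2])
        two_stage = np.empty((reps, omega), dtype=np.int64)
        populations = rng.multinomial(N, p, size=reps)
        for r in range(reps):
            two_stage[r] = rng.multivariate_hypergeometric(populations[r], S)
        one_stage = rng.multinomial(S, p, size=reps)
        outcomes = list(compositions(S, omega))
        for c in outcomes:
            exact = multinomial_pmf(c, p)
            se = math.sqrt(exact * (1 - exact) / reps)
            f_two = np.mean(np.all(two_stage == np.array(c), axis=1))
            f_one = np.mean(np.all(one_stage == np.array(c), axis=1))
            assert abs(f_two - exact) < 4 * se + 1e-12
            assert abs(f_one - exact) < 4 * se + 1e-12


class TestPosteriorRichness:
    def test_two_clone_example(self):
        # One of two cells sampled, clone 2 unseen: the unsampled cell is
        # clone 2 with probability 1/2.
        sample = SampleConfiguration(np.array([1, 0]), parent_size=2)
        probs = CloneProbabilities(np.array([0.5, 0.5]))
        assert posterior_expected_richness(sample, probs, 2) == pytest.approx(
            1.5
        )

    def test_complete_sample_recovers_observed(self):
        sample = SampleConfiguration(np.array([2, 0, 1]), parent_size=3)
        probs = CloneProbabilities(np.array([0.3, 0.4, 0.3]))
        assert posterior_expected_richness(sample, probs, 3) == pytest.approx(
            2.0
        )

    def test_all_clones_observed_gives_omega(self):
        sample = SampleConfiguration(np.array([1, 1]), parent_size=10)
        probs = CloneProbabilities(np.array([0.5, 0.5]))
        assert posterior_expected_richness(sample, probs, 10) == pytest.approx(
            2.0
        )

    def test_bounds(self, rng):
        omega = 6
        p = random_probability_vector(rng, omega)
        for _ in range(10):
            N = int(rng.integers(5, 50))
            S = int(rng.integers(0, N + 1))
            s = rng.multinomial(S, p)
            sample = SampleConfiguration(s, parent_size=N)
            value = posterior_expected_richness(
                sample, CloneProbabilities(p), N
            )
            observed = int(np.count_nonzero(s))
            assert observed - 1e-9 <= value <= omega + 1e-9

    def test_sample_larger_than_population_rejected(self):
        sample = SampleConfiguration(np.array([3, 2]), parent_size=5)
        with pytest.raises(InvalidInputError):
            posterior_expected_richness(
                sample, CloneProbabilities(np.array([0.5, 0.5])), 4
            )


class TestReductionAtFullSampling:
    def test_sampled_quantities_reduce_to_unsampled(self):
        """At S = N every sigma collapses onto the deterministic count."""
        counts = [(3, 0, 2), (1, 1, 1)]
        full = n_cohort(counts, sample_sizes=[5, 3])
        assert group_sample_occurrence(full, 0) == 1.0
        r = sampled_richness_moments_n(full, group=True)
        assert r.mean == pytest.approx(3.0)
        assert r.variance == pytest.approx(0.0, abs=1e-10)
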