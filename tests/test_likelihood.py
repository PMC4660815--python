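"""Unit and property tests for the closed-form marginal likelihood layer."""

import itertools

import numpy as np
import pytest

from bhit.data import Column, MixedDataset
from bhit.likelihood import (
    count_combinations,
    dirichlet_multinomial_log_marginal,
    group_log_marginal,
    joint_log_likelihood,
    normal_invchisq_log_marginal,
    normal_invchisq_posterior,
    normal_inverse_wishart_log_marginal,
)
from bhit.partition import Partition, iter_set_partitions
from bhit.priors import DirichletPrior, NormalInvChisqPrior, PriorConfig


def polya_urn_log_prob(codes, alphas):
    """Independent oracle: sequential Polya-urn probability of an observed
    category sequence under Dirichlet-multinomial exchangeability."""
    alphas = np.asarray(alphas, dtype=float)
    counts = np.zeros_like(alphas)
    logp = 0.0
    for c in codes:
        logp += np.log((alphas[c] + counts[c]) / (alphas.sum() + counts.sum()))
        counts[c] += 1
    return logp


def nix_chain_rule_log_prob(values, prior):
    """Independent oracle: chain rule of Student-t posterior predictives."""
    from scipy import stats

    cur = prior
    logp = 0.0
    for y in values:
        scale = np.sqrt(cur.sigma0_sq * (1.0 + 1.0 / cur.kappa0))
        logp += stats.t.logpdf(y, df=cur.nu0, loc=cur.mu0, scale=scale)
        post = normal_invchisq_posterior(np.array([y]), cur)
        cur = NormalInvChisqPrior(post.mu_n, post.kappa_n, post.nu_n, post.sigma_n_sq)
    return logp


class TestCountCombinations:
    def _ds(self, cols):
        return MixedDataset(cols)

    def test_two_binary_columns(self):
        ds = self._ds(
            [
                Column("a", "discrete", "genotype", [0, 0, 0], 2),
                Column("b", "discrete", "genotype", [0, 1, 0], 2),
            ]
        )
        counts, clusters = count_combinations(ds, [0, 1])
        assert counts.tolist() == [2, 1, 0, 0]
        assert clusters.tolist() == [0, 1, 0]

    def test_single_genotype_column(self):
        ds = self._ds([Column("a", "discrete", "genotype", [2, 2, 1], 3)])
        counts, _ = count_combinations(ds, [0])
        assert counts.tolist() == [0, 1, 2]

    def test_single_row(self):
        ds = self._ds([Column("a", "discrete", "genotype", [1], 3)])
        counts, _ = count_combinations(ds, [0])
        assert counts.tolist() == [0, 1, 0]

    def test_continuous_column_rejected(self):
        ds = self._ds([Column("y", "continuous", "phenotype", [0.5, 1.0])])
        with pytest.raises(ValueError, match="continuous"):
            count_combinations(ds, [0])


class TestDirichletMultinomial:
    def test_hand_computed_values(self):
        # two categories, one observation each, flat prior: 1/2 * 1/3
        assert dirichlet_multinomial_log_marginal([1, 1], [1, 1]) == pytest.approx(
            np.log(1 / 6), abs=1e-12
        )
        # both observations in the first category: 1/2 * 2/3
        assert dirichlet_multinomial_log_marginal([2, 0], [1, 1]) == pytest.approx(
            np.log(1 / 3), abs=1e-12
        )

    def test_empty_data_has_probability_one(self):
        assert dirichlet_multinomial_log_marginal([0, 0, 0], [0.5, 1.0, 2.0]) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_multinomial_log_marginal([1, 1], [1, 0])
        with pytest.raises(ValueError):
            dirichlet_multinomial_log_marginal([1, 1, 1], [1, 1])

    def test_matches_polya_urn_oracle_on_random_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            c = int(rng.integers(2, 5))
            n = int(rng.integers(1, 9))
            alphas = rng.uniform(0.2, 3.0, size=c)
            codes = rng.integers(0, c, size=n)
            counts = np.bincount(codes, minlength=c)
            ours = dirichlet_multinomial_log_marginal(counts, alphas)
            assert ours == pytest.approx(polya_urn_log_prob(codes, alphas), abs=1e-10)

    def test_total_probability_over_sequences_is_one(self):
        # summing the sequence probability over every possible data sequence
        # of length n must give 1 (n <= 4, up to 3 categories)
        rng = np.random.default_rng(3)
        for c, n in [(2, 3), (3, 3), (2, 4), (3, 4)]:
            alphas = rng.uniform(0.3, 2.5, size=c)
            total = 0.0
            for seq in itertools.product(range(c), repeat=n):
                counts = np.bincount(seq, minlength=c)
                total += np.exp(dirichlet_multinomial_log_marginal(counts, alphas))
            # each count vector appears multinomial(n; counts) times among
            # sequences and the marginal is per-sequence, so the plain sum is 1
            assert total == pytest.approx(1.0, abs=1e-10)


class TestNormalInvChisqPosterior:
    def test_no_data_returns_prior(self):
        p = NormalInvChisqPrior(2.0, 1.5, 3.0, 0.7)
        post = normal_invchisq_posterior(np.array([]), p)
        assert (post.mu_n, post.kappa_n, post.nu_n, post.sigma_n_sq) == (2.0, 1.5, 3.0, 0.7)
        assert post.n == 0

    def test_single_observation_at_prior_mean(self):
        p = NormalInvChisqPrior(mu0=1.0, kappa0=1.0, nu0=2.0, sigma0_sq=0.5)
        post = normal_invchisq_posterior(np.array([1.0]), p)
        assert post.mu_n == pytest.approx(1.0)
        assert post.kappa_n == 2.0
        assert post.nu_n == 3.0
        # (nu0 sigma0^2 + 0 + 0) / nu_n
        assert post.sigma_n_sq == pytest.approx(2.0 * 0.5 / 3.0)

    def test_hand_evaluated_two_point_update(self):
        p = NormalInvChisqPrior(mu0=0.0, kappa0=1.0, nu0=1.0, sigma0_sq=1.0)
        post = normal_invchisq_posterior(np.array([0.0, 2.0]), p)
        assert post.ybar == 1.0
        assert post.s_sq == pytest.approx(2.0)
        assert post.mu_n == pytest.approx(2 / 3)
        assert post.kappa_n == 3.0
        assert post.nu_n == 3.0
        assert post.sigma_n_sq == pytest.approx(11 / 9)


class TestNormalInvChisqMarginal:
    def test_empty_vector_is_log_one(self):
        p = NormalInvChisqPrior(0.0, 1.0, 1.0, 1.0)
        assert normal_invchisq_log_marginal(np.array([]), p) == 0.0

    def test_single_point_closed_form(self):
        # y=0 under the unit prior: Student-t_1(0, scale^2=2) density at 0
        p = NormalInvChisqPrior(0.0, 1.0, 1.0, 1.0)
        expected = np.log(1.0 / (np.pi * np.sqrt(2.0)))
        assert normal_invchisq_log_marginal(np.array([0.0]), p) == pytest.approx(
            expected, abs=1e-10
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(9)
        p0 = NormalInvChisqPrior(0.5, 2.0, 3.0, 1.2)
        pc = NormalInvChisqPrior(0.5 + 10.0, 2.0, 3.0, 1.2)
        a = normal_invchisq_log_marginal(v, p0)
        b = normal_invchisq_log_marginal(v + 10.0, pc)
        assert a == pytest.approx(b, abs=1e-9)

    def test_matches_chain_rule_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            n = int(rng.integers(1, 21))
            prior = NormalInvChisqPrior(
                mu0=float(rng.normal()),
                kappa0=float(rng.uniform(0.3, 4.0)),
                nu0=float(rng.uniform(0.5, 5.0)),
                sigma0_sq=float(rng.uniform(0.3, 3.0)),
            )
            v = rng.normal(size=n) * 2.0
            ours = normal_invchisq_log_marginal(v, prior)
            assert ours == pytest.approx(nix_chain_rule_log_prob(v, prior), abs=1e-8)


class TestNormalInverseWishart:
    def test_dimension_one_reduces_to_normal_invchisq(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(12)
        p = NormalInvChisqPrior(0.3, 1.5, 2.0, 0.8)
        a = normal_invchisq_log_marginal(v, p)
        b = normal_inverse_wishart_log_marginal(
            v[:, None], np.array([0.3]), 1.5, 2.0, np.array([[2.0 * 0.8]])
        )
        assert a == pytest.approx(b, abs=1e-9)

    def test_independent_columns_nearly_factorize_at_large_n(self):
        # with weak priors and independent data the joint NIW marginal should
        # approach the sum of the 1-D marginals (correlation estimate ~ 0)
        rng = np.random.default_rng(8)
        Y = rng.standard_normal((4000, 2))
        p = NormalInvChisqPrior(0.0, 1.0, 1.0, 1.0)
        joint = normal_inverse_wishart_log_marginal(
            Y, np.zeros(2), 1.0, 2.0, np.diag([1.0, 1.0])
        )
        marg = sum(normal_invchisq_log_marginal(Y[:, j], p) for j in range(2))
        assert abs(joint - marg) < 25.0  # O(log n) Occam terms only


class TestGroupAndJointLikelihood:
    def _mixed_ds(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 2, 30)
        y = rng.standard_normal(30) + d
        return MixedDataset(
            [
                Column("d", "discrete", "genotype", d, 2),
                Column("y", "continuous", "phenotype", y),
            ]
        )

    def test_mixed_group_is_discrete_plus_clustered_continuous(self):
        ds = self._mixed_ds()
        priors = PriorConfig.empirical(ds)
        counts, clusters = count_combinations(ds, [0])
        disc_part = dirichlet_multinomial_log_marginal(
            counts, priors.dirichlet.resolve(ds, [0])
        )
        y = ds.columns[1].values
        p = priors.for_column(ds, 1)
        cont_part = sum(
            normal_invchisq_log_marginal(y[clusters == m], p)
            for m in range(2)
        )
        assert group_log_marginal(ds, [0, 1], priors) == pytest.approx(
            disc_part + cont_part, abs=1e-9
        )

    def test_continuous_singleton_equals_direct_marginal(self):
        ds = self._mixed_ds()
        priors = PriorConfig.empirical(ds)
        direct = normal_invchisq_log_marginal(
            ds.columns[1].values, priors.for_column(ds, 1)
        )
        assert group_log_marginal(ds, [1], priors) == pytest.approx(direct, abs=1e-10)

    def test_all_singletons_is_sum_of_column_marginals(self, toy3):
        ds, priors = toy3
        total = sum(group_log_marginal(ds, [i], priors) for i in range(3))
        assert joint_log_likelihood(ds, Partition.singletons(3), priors) == pytest.approx(
            total, abs=1e-9
        )

    def test_bell3_enumeration_matches_group_recomputation(self, dependent3):
        ds, priors = dependent3
        for p in iter_set_partitions(3):
            expected = sum(group_log_marginal(ds, list(g), priors) for g in p.groups())
            assert joint_log_likelihood(ds, p, priors) == pytest.approx(expected, abs=1e-9)

    def test_argmax_partition_is_dependent_grouping(self, dependent3):
        ds, priors = dependent3
        parts = list(iter_set_partitions(3))
        lls = [joint_log_likelihood(ds, p, priors) for p in parts]
        best = parts[int(np.argmax(lls))]
        assert best.indicators == (1, 1, 1)

    def test_invariance_under_group_relabeling(self, dependent3):
        ds, priors = dependent3
        a = joint_log_likelihood(ds, Partition((1, 2, 1)), priors)
        b = joint_log_likelihood(ds, Partition((2, 1, 2)), priors)
        assert a == pytest.approx(b, abs=1e-12)

    def test_invariance_under_row_permutation(self, dependent3):
        ds, priors = dependent3
        rng = np.random.default_rng(9)
        perm = rng.permutation(ds.n_samples)
        ds2 = ds.subset_rows(perm)
        priors2 = PriorConfig.empirical(ds2)
        p = Partition((1, 1, 2))
        assert joint_log_likelihood(ds, p, priors) == pytest.approx(
            joint_log_likelihood(ds2, p, priors2), abs=1e-8
        )

    def test_noise_singleton_adds_exactly_its_marginal(self, dependent3):
        ds, _ = dependent3
        rng = np.random.default_rng(13)
        noise = Column("Z", "continuous", "phenotype", rng.standard_normal(ds.n_samples))
        ds2 = MixedDataset(ds.columns + [noise])
        priors2 = PriorConfig.empirical(ds2)
        base = joint_log_likelihood(ds2.subset_columns([0, 1, 2]), Partition((1, 1, 1)), priors2)
        with_noise = joint_log_likelihood(ds2, Partition((1, 1, 1, 2)), priors2)
        noise_marg = group_log_marginal(ds2, [3], priors2)
        assert with_noise == pytest.approx(base + noise_marg, abs=1e-9)

    def test_finite_for_large_combination_spaces(self):
        rng = np.random.default_rng(14)
        cols = [
            Column(f"g{j}", "discrete", "genotype", rng.integers(0, 3, 500), 3)
            for j in range(10)
        ]
        ds = MixedDataset(cols)
        priors = PriorConfig.empirical(ds)
        val = group_log_marginal(ds, list(range(10)), priors)  # c_h = 3^10
        assert np.isfinite(val)

    def test_maf_informed_alphas_sum_to_alpha0_and_use_hwe(self):
        ds = MixedDataset(
            [
                Column("g1", "discrete", "genotype", [0, 1, 2], 3),
                Column("g2", "discrete", "genotype", [0, 0, 1], 3),
            ]
        )
        prior = DirichletPrior("maf_informed", alpha0=2.0, maf=0.25)
        alphas = prior.resolve(ds, [0, 1])
        assert alphas.shape == (9,)
        assert alphas.sum() == pytest.approx(2.0)
        # first cell = alpha0 * P(major-hom)^2 under HWE
        assert alphas[0] == pytest.approx(2.0 * (0.75**2) ** 2)

    def test_partition_length_mismatch_rejected(self, toy3):
        ds, priors = toy3
        with pytest.raises(ValueError):
            joint_log_likelihood(ds, Partition((1, 2)), priors)
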