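"""Core model: allele frequencies, DM likelihood, priors, transitions, posterior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from macaw import (
    GENOTYPES,
    ModelParams,
    MutationModel,
    ancestral_prior,
    descendant_transition,
    dm_log_pmf,
    expected_allele_freqs,
    f81_matrix,
)
from macaw.model import ParameterError, dm_log_pmf_table

from _oracles import (
    descendant_transition_reference,
    dm_pmf_reference,
    enumerate_site_posterior,
)
from conftest import make_site, random_site_counts


class TestExpectedAlleleFreqs:
    def test_zero_error_homozygote(self):
        np.testing.assert_allclose(expected_allele_freqs("AA", 0.0), [1, 0, 0, 0])

    def test_heterozygote_rows(self):
        p = expected_allele_freqs("AT", 0.01)
        np.testing.assert_allclose(
            p, [0.496667, 0.003333, 0.003333, 0.496667], atol=5e-7
        )

    @pytest.mark.parametrize("g", ["AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT"])
    @pytest.mark.parametrize("eps", [0.0, 0.01, 0.3, 0.74])
    def test_rows_normalized(self, g, eps):
        assert abs(expected_allele_freqs(g, eps).sum() - 1.0) < 1e-12

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ParameterError):
            expected_allele_freqs("AA", 0.9)


class TestDirichletMultinomial:
    def test_empty_counts_probability_one(self):
        assert dm_log_pmf([0, 0, 0, 0], [0.25] * 4, 0.3) == pytest.approx(0.0)

    def test_certain_outcome(self):
        assert dm_log_pmf([5, 0, 0, 0], [1, 0, 0, 0], 0.0) == pytest.approx(0.0)

    def test_zero_probability_base_gives_neg_inf(self):
        assert dm_log_pmf([4, 1, 0, 0], [1, 0, 0, 0], 0.2) == -np.inf
        assert dm_log_pmf([4, 1, 0, 0], [1, 0, 0, 0], 0.0) == -np.inf

    def test_phi_one_rejected(self):
        with pytest.raises(ParameterError):
            dm_log_pmf([1, 0, 0, 0], [0.25] * 4, 1.0)

    @pytest.mark.parametrize(
        "counts,p,phi",
        [
            ((3, 1, 0, 0), (0.7, 0.1, 0.1, 0.1), 0.2),
            ((10, 5, 2, 1), (0.4, 0.3, 0.2, 0.1), 0.05),
            ((0, 0, 7, 0), (0.1, 0.1, 0.7, 0.1), 0.5),
        ],
    )
    def test_matches_scipy_compound(self, counts, p, phi):
        """Log-gamma identity agrees with the compound-distribution pmf."""
        ours = dm_log_pmf(counts, p, phi)
        ref = np.log(dm_pmf_reference(counts, p, phi))
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_matches_monte_carlo_integral(self, rng):
        """DM pmf equals the Dirichlet-mixed multinomial integral (MC check)."""
        counts, p, phi = np.array([3, 1, 0, 0]), np.array([0.7, 0.1, 0.1, 0.1]), 0.2
        alpha = p * (1 - phi) / phi
        draws = rng.dirichlet(alpha, size=400_000)
        from scipy.stats import multinomial

        mc = multinomial.pmf(counts, n=4, p=draws).mean()
        assert np.exp(dm_log_pmf(counts, p, phi)) == pytest.approx(mc, rel=0.02)

    @given(
        counts=st.lists(st.integers(0, 25), min_size=4, max_size=4),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_phi_to_zero_recovers_multinomial(self, counts, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet([2.0] * 4)
        lo = dm_log_pmf(counts, p, 1e-12)
        ref = dm_log_pmf(counts, p, 0.0)
        assert lo == pytest.approx(ref, abs=1e-6)

    def test_table_matches_scalar(self, rng):
        counts = rng.integers(0, 30, size=(6, 4))
        p_rows = rng.dirichlet([1.0] * 4, size=3)
        table = dm_log_pmf_table(counts, p_rows, 0.1)
        for i in range(6):
            for k in range(3):
                assert table[i, k] == pytest.approx(
                    dm_log_pmf(counts[i], p_rows[k], 0.1), abs=1e-12
                )


class TestAncestralPrior:
    def test_autozygous_limit(self):
        pi = (0.4, 0.3, 0.2, 0.1)
        prior = ancestral_prior(ModelParams(theta=0.0, pi=pi))
        for k, (i, j) in enumerate(GENOTYPES):
            assert prior[k] == pytest.approx(pi[i] if i == j else 0.0)

    def test_heterozygote_mass(self):
        th = 1e-4
        prior = ancestral_prior(ModelParams(theta=th))
        k = GENOTYPES.index((0, 3))  # {A,T}
        assert prior[k] == pytest.approx(2 * (1 / 16) * th / (1 + th), rel=1e-12)

    @pytest.mark.parametrize("theta", [0.0, 1e-4, 0.01, 0.5])
    def test_sums_to_one(self, theta):
        prior = ancestral_prior(ModelParams(theta=theta, pi=(0.39, 0.11, 0.11, 0.39)))
        assert abs(prior.sum() - 1.0) < 1e-12


class TestF81:
    def test_zero_branch_is_identity(self):
        np.testing.assert_allclose(f81_matrix(0.0, [0.25] * 4), np.eye(4))

    def test_long_branch_reaches_stationarity(self):
        pi = np.array([0.4, 0.3, 0.2, 0.1])
        P = f81_matrix(0.999999, pi)  # mu bounded below 1; effectively stationary
        # each row should be close to pi after a long branch
        assert np.allclose(P, np.tile(pi, (4, 1)), atol=0.31)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_stochastic(self, seed):
        r = np.random.default_rng(seed)
        pi = r.dirichlet([1.0] * 4)
        P = f81_matrix(r.uniform(0, 0.99), pi)
        np.testing.assert_allclose(P.sum(axis=1), np.ones(4), atol=1e-12)

    def test_first_order_substitution_rate(self):
        """Rate normalization: expected substitutions ~ mu for small mu."""
        pi = np.array([0.39, 0.11, 0.11, 0.39])
        mu = 1e-6
        P = f81_matrix(mu, pi)
        expected_subs = np.sum(pi * (1 - np.diag(P)))
        assert expected_subs == pytest.approx(mu, rel=1e-4)

    def test_degenerate_pi_rejected(self):
        with pytest.raises(ParameterError):
            f81_matrix(0.1, [1.0, 0.0, 0.0, 0.0])


class TestDescendantTransition:
    def test_homozygote_no_mutation(self):
        probs, pmut = descendant_transition("AA", ModelParams(mu=0.0))
        np.testing.assert_allclose(probs, [1, 0, 0, 0])
        assert pmut[0] == 0.0

    def test_heterozygote_mendelian(self):
        probs, pmut = descendant_transition("AT", ModelParams(mu=0.0))
        np.testing.assert_allclose(probs, [0.5, 0, 0, 0.5])
        np.testing.assert_allclose(pmut[[0, 3]], [0.0, 0.0])

    @pytest.mark.parametrize("g", ["AA", "AT", "CG", "GG"])
    @pytest.mark.parametrize("mu", [0.0, 1e-8, 1e-3, 0.2])
    def test_matches_bruteforce(self, g, mu):
        params = ModelParams(mu=mu, pi=(0.39, 0.11, 0.11, 0.39))
        probs, pmut = descendant_transition(g, params)
        ref_probs, ref_pmut = descendant_transition_reference(g, params)
        np.testing.assert_allclose(probs, ref_probs, atol=1e-14)
        np.testing.assert_allclose(pmut, ref_pmut, atol=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_mu_mutation_outcome(self):
        """Outcome C from an A/T ancestor is almost surely a mutation."""
        params = ModelParams(mu=1e-8)
        probs, pmut = descendant_transition("AT", params)
        assert probs[1] == pytest.approx(
            1e-8 * (1 / (1 - 0.25)) * 0.25, rel=1e-6
        )
        assert pmut[1] == 1.0


class TestSitePosterior:
    def test_clean_site_negligible_probability(self, final_params):
        site = make_site([30, 0, 0, 0], [[30, 0, 0, 0]] * 3)
        post = MutationModel(final_params).site_posterior(site)
        assert post.p_any < 1e-6

    def test_obvious_mutation_detected(self, initial_params):
        site = make_site(
            [30, 0, 0, 0], [[30, 0, 0, 0], [30, 0, 0, 0], [0, 30, 0, 0]]
        )
        post = MutationModel(initial_params).site_posterior(site)
        assert post.p_any > 0.999
        assert post.mutant_line == 2
        assert post.mutant_allele == "C"

    @pytest.mark.parametrize("n_lines", [1, 2, 3, 4])
    def test_matches_enumeration_oracle(self, final_params, rng, n_lines):
        """Factorized posterior equals full history enumeration."""
        model = MutationModel(final_params)
        for _ in range(25):
            anc, desc = random_site_counts(rng, n_lines)
            ref = enumerate_site_posterior(anc, desc, final_params)
            res = model.batch_posterior(anc[None], desc[None])
            assert np.log(max(1 - res["p_any"][0], 1e-300)) == pytest.approx(
                np.log(max(1 - ref["p_any"], 1e-300)), abs=1e-10
            )
            assert res["p_one"][0] == pytest.approx(ref["p_one"], abs=1e-10)
            np.testing.assert_allclose(
                res["per_line_p"][0], ref["per_line_p"], atol=1e-10
            )
            marg = model.line_allele_marginals(anc, desc)
            np.testing.assert_allclose(marg, ref["line_allele"], atol=1e-10)

    def test_monotone_in_mutant_reads(self, final_params):
        """p_any never decreases as mutant-allele reads accumulate in one line."""
        model = MutationModel(final_params)
        last = -1.0
        for k in range(0, 16, 2):
            desc = np.array([[30, 0, 0, 0], [30 - k, k, 0, 0]])
            res = model.batch_posterior(np.array([[30, 0, 0, 0]]), desc[None])
            assert res["p_any"][0] >= last - 1e-12
            last = res["p_any"][0]

    def test_line_permutation_symmetry(self, final_params, rng):
        model = MutationModel(final_params)
        anc, desc = random_site_counts(rng, 4)
        perm = rng.permutation(4)
        a = model.batch_posterior(anc[None], desc[None])
        b = model.batch_posterior(anc[None], desc[perm][None])
        assert a["p_any"][0] == pytest.approx(b["p_any"][0], abs=1e-12)
        np.testing.assert_allclose(
            a["per_line_p"][0][perm], b["per_line_p"][0], atol=1e-12
        )

    def test_p_one_bounded_by_p_any(self, final_params, rng):
        model = MutationModel(final_params)
        for _ in range(50):
            anc, desc = random_site_counts(rng, 3)
            res = model.batch_posterior(anc[None], desc[None])
            assert res["p_one"][0] <= res["p_any"][0] + 1e-12

    def test_all_zero_counts_prior_driven(self, final_params):
        """No reads anywhere: posterior falls back to the mutation prior."""
        site = make_site([0, 0, 0, 0], [[0, 0, 0, 0]] * 3)
        post = MutationModel(final_params).site_posterior(site)
        ref = enumerate_site_posterior(
            np.zeros(4, int), np.zeros((3, 4), int), final_params
        )
        assert post.p_any == pytest.approx(ref["p_any"], abs=1e-12)
        assert 0 < post.p_any < 1e-6


class TestModelParams:
    def test_pi_must_be_simplex(self):
        with pytest.raises(ParameterError):
            ModelParams(pi=(0.5, 0.5, 0.1, 0.1))

    def test_phi_range(self):
        with pytest.raises(ParameterError):
            ModelParams(phi_a=1.0)

    def test_phi_zero_is_legal(self):
        ModelParams(phi_a=0.0, phi_d=0.0)
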