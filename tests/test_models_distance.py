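"""Substitution models, ML pairwise distances, AICc model selection.

Independent oracles: matrix-exponential transition probabilities (scipy
``expm`` vs the closed form), quadrature for the discrete-gamma category
means, a site-by-site likelihood summation, closed-form JC69/K80 distances,
and a brute-force grid search for the HKY+G+I distance.
"""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from barcodeid.models_distance import (HKY_COI_DEFAULT, DistanceMatrix,
                                       ModelFit, SubstitutionModel,
                                       avg_species_distance,
                                       discrete_gamma_rates, distance_matrix,
                                       estimate_model_params, kappa_to_tratio,
                                       ml_pair_distance, model_label,
                                       pair_loglik, select_model_aicc,
                                       transition_matrix, tratio_to_kappa)
from barcodeid.synthetic_data import sim_alignment, sim_species_tree

JC = SubstitutionModel(family="JC69")


def rate_matrix(model):
    """Explicit normalized HKY rate matrix (oracle route)."""
    f = model.freqs
    kappa = model.kappa
    purine = {0, 2}
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i in purine) == (j in purine)
            Q[i, j] = (kappa if transition else 1.0) * f[j]
        Q[i, i] = -Q[i].sum()
    scale = -np.dot(f, np.diag(Q))
    return Q / scale


def oracle_site_prob(model, x, y, t):
    """P(x, y | t) by expm, mixing gamma categories and invariant sites."""
    f = model.freqs
    rates = model.category_rates
    Q = rate_matrix(model)
    p = 0.0
    if model.p_inv and x == y:
        p += model.p_inv * f[x]
    for r in rates:
        P = expm(Q * t * r)
        p += (1.0 - model.p_inv) / len(rates) * f[x] * P[x, y]
    return p


class TestKappaConversion:
    def test_uniform_frequencies(self):
        assert tratio_to_kappa(0.5, (0.25,) * 4) == pytest.approx(1.0)

    def test_printed_parameters_round_trip(self):
        f = HKY_COI_DEFAULT.base_freqs
        kappa = tratio_to_kappa(6.1561, f)
        assert kappa_to_tratio(kappa, f) == pytest.approx(6.1561, abs=1e-9)

    def test_random_round_trips(self, rng):
        for _ in range(100):
            f = rng.dirichlet([5, 5, 5, 5])
            R = rng.uniform(0.1, 10)
            assert kappa_to_tratio(tratio_to_kappa(R, f), f) == \
                pytest.approx(R, abs=1e-9)

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            tratio_to_kappa(2.0, (0.5, 0.5, 0.0, 0.0))


class TestTransitionMatrix:
    @pytest.mark.parametrize("model", [JC, HKY_COI_DEFAULT,
                                       SubstitutionModel(family="K80", tratio=3.0),
                                       SubstitutionModel(family="F81",
                                                         base_freqs=(0.4, 0.3, 0.2, 0.1))])
    def test_stochastic_and_detailed_balance(self, model):
        for t in (0.0, 0.05, 0.3, 2.0):
            P = transition_matrix(model, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
            f = model.freqs
            assert np.allclose(f[:, None] * P, (f[:, None] * P).T, atol=1e-12)

    def test_t_zero_is_identity(self):
        assert np.allclose(transition_matrix(HKY_COI_DEFAULT, 0.0), np.eye(4))

    def test_long_branch_reaches_stationarity(self):
        P = transition_matrix(HKY_COI_DEFAULT, 500.0)
        for row in P:
            assert np.allclose(row, HKY_COI_DEFAULT.freqs, atol=1e-6)

    def test_jc_closed_form(self):
        P = transition_matrix(JC, 0.1)
        expected = 0.25 * (1 - np.exp(-4 * 0.1 / 3))
        assert P[0, 1] == pytest.approx(expected, abs=1e-9)
        assert P[0, 1] == pytest.approx(0.031206, abs=1e-6)

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 1.5])
    def test_matches_expm_oracle(self, t):
        model = HKY_COI_DEFAULT.with_params(gamma_shape=None, ncat=1, p_inv=0.0)
        P = transition_matrix(model, t)
        P_oracle = expm(rate_matrix(model) * t)
        assert np.allclose(P, P_oracle, atol=1e-10)


class TestDiscreteGamma:
    def test_single_category(self):
        assert discrete_gamma_rates(0.5, 1).tolist() == [1.0]

    def test_large_alpha_homogeneous(self):
        rates = discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    def test_printed_shape_against_quadrature(self):
        alpha, ncat = 0.8490, 4
        rates = discrete_gamma_rates(alpha, ncat)
        assert np.all(np.diff(rates) > 0)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha,
                               scale=1 / alpha)
        edges[-1] = np.inf
        for i in range(ncat):
            num, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1 / alpha),
                          edges[i], edges[i + 1])
            assert rates[i] == pytest.approx(num * ncat, rel=1e-6)


class TestPairLoglik:
    def test_identical_sequences_at_zero(self):
        s = "ACGTACGTAC" * 2
        ll = pair_loglik(s, s, 0.0, HKY_COI_DEFAULT)
        f = dict(zip("ACGT", HKY_COI_DEFAULT.freqs))
        expected = sum(np.log(f[c]) for c in s)
        assert ll == pytest.approx(expected, abs=1e-9)

    def test_symmetric_in_arguments(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), 60))
        s2 = "".join(rng.choice(list("ACGT"), 60))
        assert pair_loglik(s1, s2, 0.07, HKY_COI_DEFAULT) == \
            pytest.approx(pair_loglik(s2, s1, 0.07, HKY_COI_DEFAULT), abs=1e-9)

    def test_against_site_by_site_oracle(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), 20))
        s2 = "".join(rng.choice(list("ACGT"), 20))
        t = 0.05
        idx = {c: i for i, c in enumerate("ACGT")}
        expected = sum(np.log(oracle_site_prob(HKY_COI_DEFAULT, idx[a], idx[b], t))
                       for a, b in zip(s1, s2))
        assert pair_loglik(s1, s2, t, HKY_COI_DEFAULT) == \
            pytest.approx(expected, rel=1e-9)

    def test_pairwise_deletion(self):
        ll_full = pair_loglik("ACGT", "ACGT", 0.1, JC)
        ll_gap = pair_loglik("ACGT-N", "ACGTAC", 0.1, JC)
        assert ll_full == pytest.approx(ll_gap)

    def test_no_shared_sites_rejected(self):
        with pytest.raises(ValueError):
            pair_loglik("NNNN", "ACGT", 0.1, JC)


class TestMLPairDistance:
    def test_identical_is_exactly_zero(self, rng):
        s = "".join(rng.choice(list("ACGT"), 650))
        assert ml_pair_distance(s, s, HKY_COI_DEFAULT) == 0.0

    def test_jc_analytic_formula_property(self, rng):
        """1,000 random pairs: JC ML distance equals -3/4 ln(1 - 4p/3)."""
        n_sites = 500
        max_err = 0.0
        for _ in range(1000):
            ndiff = rng.integers(1, int(0.7 * n_sites * 0.75))
            p = ndiff / n_sites
            s1 = "A" * n_sites
            # transversion-balanced difference pattern is irrelevant for JC
            s2 = ("C" * (ndiff // 2) + "G" * (ndiff - ndiff // 2)
                  + "A" * (n_sites - ndiff))
            d = ml_pair_distance(s1, s2, JC)
            expected = -0.75 * np.log(1 - 4 * p / 3)
            max_err = max(max_err, abs(d - expected))
        assert max_err < 1e-6

    def test_k80_analytic_formula(self):
        n = 200
        s1 = "A" * n
        s2 = "G" * 20 + "C" * 5 + "T" * 5 + "A" * 170  # P=0.10, Q=0.05
        P_, Q_ = 0.10, 0.05
        a1 = -np.log(1 - 2 * P_ - Q_)
        a2 = -np.log(1 - 2 * Q_)
        kappa_hat = 2 * a1 / a2 - 1
        model = SubstitutionModel(family="K80",
                                  tratio=kappa_to_tratio(kappa_hat, (0.25,) * 4))
        d = ml_pair_distance(s1, s2, model)
        assert d == pytest.approx(0.5 * a1 + 0.25 * a2, abs=1e-6)
        assert d == pytest.approx(0.17018, abs=1e-5)

    def test_hky_uniform_frequencies_nests_k80(self, rng):
        for _ in range(20):
            s1 = "".join(rng.choice(list("ACGT"), 400))
            muts = dict(A="G", G="A", C="T", T="C")
            s2 = "".join(muts[c] if rng.random() < 0.08 else c for c in s1)
            k80 = SubstitutionModel(family="K80", tratio=2.5)
            hky = SubstitutionModel(family="HKY85", base_freqs=(0.25,) * 4,
                                    tratio=2.5)
            assert ml_pair_distance(s1, s2, hky) == \
                pytest.approx(ml_pair_distance(s1, s2, k80), abs=1e-6)

    def test_grid_search_oracle_hky_gi(self, rng):
        """Toy pairs under the full +G+I model vs a 1e-4 grid search."""
        model = HKY_COI_DEFAULT
        for _ in range(5):
            s1 = "".join(rng.choice(list("ACGT"), 60,
                                    p=model.freqs))
            s2 = "".join(rng.choice(list("ACGT"), 60, p=model.freqs))
            d = ml_pair_distance(s1, s2, model)
            grid = np.arange(0.0, 10.0, 1e-4)
            from barcodeid.models_distance import _loglik_from_counts, pair_counts
            counts = pair_counts(s1, s2)
            ll = _loglik_from_counts(counts, model, grid)
            d_grid = grid[np.argmax(ll)]
            assert d == pytest.approx(d_grid, abs=2e-4)

    def test_p_inv_inflates_distance(self):
        s1 = "A" * 90 + "C" * 10
        s2 = "A" * 80 + "G" * 10 + "C" * 10
        base = HKY_COI_DEFAULT.with_params(p_inv=0.0)
        more = HKY_COI_DEFAULT.with_params(p_inv=0.486)
        assert ml_pair_distance(s1, s2, more) > ml_pair_distance(s1, s2, base)


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        dm = distance_matrix(["a", "b"], ["ACGTAC", "ACGTAC"], JC)
        assert np.all(dm.values == 0.0)

    def test_equal_sequences_equal_distances(self, rng):
        s1 = "".join(rng.choice(list("ACGT"), 300))
        s2 = "".join(rng.choice(list("ACGT"), 300))
        dm = distance_matrix(["a", "b", "c"], [s1, s2, s2], JC)
        assert dm.get("a", "b") == pytest.approx(dm.get("a", "c"), abs=1e-9)
        assert dm.get("b", "c") == 0.0

    def test_symmetry_and_zero_diagonal(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(5)]
        dm = distance_matrix(list("abcde"), seqs, HKY_COI_DEFAULT)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_disjoint_pair_flagged_missing(self):
        with pytest.warns(UserWarning, match="missing"):
            dm = distance_matrix(
                ["a", "b"],
                ["ACGT" + "?" * 4, "????" + "ACGT"], JC)
        assert dm.missing[0, 1]


class TestAvgSpeciesDistance:
    def _dm(self, labels, values):
        return DistanceMatrix(labels, np.array(values))

    def test_arithmetic_mean(self):
        dm = self._dm(["q", "m1", "m2"],
                      [[0, 0.001, 0.003], [0.001, 0, 0], [0.003, 0, 0]])
        means = avg_species_distance("q", dm, {"m1": "S one", "m2": "S one"})
        assert means == {"S one": pytest.approx(0.002)}

    def test_zero_distance_species(self):
        dm = self._dm(["q", "m1"], [[0, 0], [0, 0]])
        assert avg_species_distance("q", dm, {"m1": "S"}) == {"S": 0.0}

    def test_congener_profile_of_a_spurdog_sample(self):
        """A query equidistant from several congeners resolves to the one
        with the smallest mean distance (the shortspine-spurdog pattern)."""
        members = {
            "Squalus mitsukurii": [0.0009, 0.0009],
            "Squalus cf. megalops": [0.0027],
            "Squalus montalbani": [0.0043, 0.0043],
            "Squalus chloroculus": [0.0058],
            "Squalus cf. mitsukurii": [0.0088],
        }
        labels = ["q"]
        species_map = {}
        dists = []
        for sp, ds in members.items():
            for i, d in enumerate(ds):
                lab = f"{sp}#{i}"
                labels.append(lab)
                species_map[lab] = sp
                dists.append(d)
        n = len(labels)
        values = np.zeros((n, n))
        values[0, 1:] = dists
        values[1:, 0] = dists
        means = avg_species_distance("q", self._dm(labels, values), species_map)
        assert means["Squalus mitsukurii"] == pytest.approx(0.0009)
        assert means["Squalus cf. megalops"] == pytest.approx(0.0027)
        assert means["Squalus montalbani"] == pytest.approx(0.0043)
        assert means["Squalus chloroculus"] == pytest.approx(0.0058)
        assert means["Squalus cf. mitsukurii"] == pytest.approx(0.0088)
        assert min(means, key=means.get) == "Squalus mitsukurii"


class TestEstimateAndSelect:
    def test_aicc_formula(self):
        assert ModelFit.aicc_value(-100.0, 4, 100) == \
            pytest.approx(200 + 8 + 2 * 4 * 5 / 95)

    def test_equal_loglik_prefers_fewer_params(self):
        # AICc is monotone in k at fixed loglik
        assert ModelFit.aicc_value(-50, 1, 500) < ModelFit.aicc_value(-50, 4, 500)

    def test_jc_data_recovers_neutral_tratio(self):
        tree = sim_species_tree(8, seed=21, target_mean_distance=0.4)
        db = sim_alignment(tree, JC, n_sites=2000, n_per_species=1,
                           intra_divergence=0.0, seed=21, coding=False)
        fit = estimate_model_params([r.accession for r in db.records],
                                    [r.aligned_seq for r in db.records],
                                    "HKY85")
        assert fit.model.tratio == pytest.approx(0.5, abs=0.1)
        assert np.allclose(fit.model.freqs, 0.25, atol=0.02)

    def test_gamma_shape_recovery_within_half(self):
        tree = sim_species_tree(10, seed=9, target_mean_distance=0.6)
        gen = SubstitutionModel(family="HKY85",
                                base_freqs=HKY_COI_DEFAULT.base_freqs,
                                tratio=6.1561, gamma_shape=0.85, ncat=4)
        db = sim_alignment(tree, gen, n_sites=2000, n_per_species=1,
                           intra_divergence=0.0, seed=9, coding=False)
        fit = estimate_model_params([r.accession for r in db.records],
                                    [r.aligned_seq for r in db.records],
                                    "HKY85", with_G=True)
        assert abs(fit.model.gamma_shape - 0.85) / 0.85 < 0.5

    def test_identical_alignment_degenerate_contract(self):
        seqs = ["ACGTACGTACGTACGTACGT" * 10] * 4
        fit = estimate_model_params(list("abcd"), seqs, "HKY85", with_I=True)
        assert fit.model.p_inv > 0.9  # hits the upper search bound
        assert np.all(fit.branch_lengths == 0.0)


class TestParameterRecovery:
    def test_distance_recovery_and_rmse_scaling(self, rng):
        """Mean ML distance within 10% of truth; RMSE shrinks with sites."""
        model = HKY_COI_DEFAULT
        from barcodeid.models_distance import _ml_t_from_counts
        idx_rates = model.category_rates
        rmse_by_sites = {}
        for n_sites in (500, 2000):
            errs = []
            for t_true in (0.01, 0.05, 0.15):
                ests = []
                for rep in range(40):
                    r = np.random.default_rng(1000 + rep + int(t_true * 1e4) + n_sites)
                    inv = r.random(n_sites) < model.p_inv
                    cats = r.integers(0, model.ncat, n_sites)
                    rates = idx_rates[cats]
                    rates[inv] = 0.0
                    x = r.choice(4, size=n_sites, p=model.freqs)
                    y = x.copy()
                    for rate in np.unique(rates):
                        if rate == 0:
                            continue
                        sel = rates == rate
                        P = transition_matrix(model, t_true, rate)
                        probs = P[x[sel]]
                        u = r.random(sel.sum())
                        y[sel] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
                    counts = np.zeros((4, 4))
                    np.add.at(counts, (x, y), 1)
                    ests.append(float(_ml_t_from_counts(counts, model)))
                mean_est = np.mean(ests)
                assert abs(mean_est - t_true) / t_true < 0.10
                errs.extend((np.array(ests) - t_true) ** 2)
            rmse_by_sites[n_sites] = np.sqrt(np.mean(errs))
        assert rmse_by_sites[2000] < rmse_by_sites[500]
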