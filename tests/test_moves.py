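"""MCMC proposal mechanics: the rate move's rescaling and Jacobian, bounds,
reflection, and prior-only marginals."""

import math

import numpy as np
import pytest
from scipy.stats import gamma, ks_2samp

from mscdate import GammaPrior, LocusAlignment, load_species_tree
from mscdate import _kernels
from mscdate.mcmc import McmcConfig, MscMcmc, PriorSet
from mscdate.stats import bactrian_laplace, reflect

from oracles import mu_move_logdet_fd


def fig2_like_setup(tau=1.0):
    """One dated population: tips at 0.1/0.3/0.5; nested nodes above them."""
    st = load_species_tree("(A,B)AB;", {"A": 0.2, "B": 0.2, "AB": 0.2}, {"AB": tau})
    from mscdate.genetree import GeneTree

    a, b = st.index["A"], st.index["B"]
    age = np.zeros(7)
    age[:4] = [0.1, 0.3, 0.5, 0.0]  # three dated A tips + one B tip
    parent = np.array([4, 4, 5, 6, 5, 6, -1])
    left = np.array([-1, -1, -1, -1, 0, 4, 5])
    right = np.array([-1, -1, -1, -1, 1, 2, 3])
    age[4] = 0.6  # joins ts1, ts2 -> b = 0.3
    age[5] = 0.8  # joins all three -> b = 0.5
    age[6] = 1.4  # root coalescence above tau
    gt = GeneTree(4, parent, left, right, age, [a, a, a, b])
    gt.assign_populations(st)
    return st, gt


class TestMuRescale:
    def test_halving_mu_rescales_oldest_descendant_ages(self):
        """mu/mu* = 2: b1 = 0.3 -> b1* = 0.15 and b2 = 0.5 -> b2* = 0.25."""
        st, gt = fig2_like_setup()
        mu = 1e-4
        ys = gt.age[: gt.n_tips] / mu
        b = np.empty(gt.n_nodes)
        _kernels.oldest_descendant_ages(gt.n_tips, gt.left, gt.right, gt.age, b)
        assert b[4] == pytest.approx(0.3)
        assert b[5] == pytest.approx(0.5)
        age_new = np.empty_like(gt.age)
        dated = np.array([st.labels[p] == "A" for p in range(st.n_nodes)])
        ok, logj = _kernels.mu_rescale_ages(
            gt.n_tips, gt.parent, gt.age, age_new, gt.pop, ys, mu / 2, 0.5,
            dated, st.parent, st.tau,
        )
        assert ok
        b_new = np.empty(gt.n_nodes)
        _kernels.oldest_descendant_ages(gt.n_tips, gt.left, gt.right, age_new, b_new)
        assert b_new[4] == pytest.approx(0.15)
        assert b_new[5] == pytest.approx(0.25)
        # tips land exactly on ys * mu*
        assert np.allclose(age_new[:3], gt.age[:3] / 2)
        # Jacobian term: sum log (tau - b*)/(tau - b)
        tau = 1.0
        expected = math.log((tau - 0.15) / (tau - 0.3)) + math.log((tau - 0.25) / (tau - 0.5))
        assert logj == pytest.approx(expected, abs=1e-12)
        # relative position h is preserved for each rescaled node
        for v, bo, bn in ((4, 0.3, 0.15), (5, 0.5, 0.25)):
            h_old = (tau - gt.age[v]) / (tau - bo)
            h_new = (tau - age_new[v]) / (tau - bn)
            assert h_new == pytest.approx(h_old, abs=1e-12)

    def test_identity_move_is_exact_noop(self):
        st, gt = fig2_like_setup()
        mu = 1e-4
        ys = gt.age[: gt.n_tips] / mu
        dated = np.array([st.labels[p] == "A" for p in range(st.n_nodes)])
        age_new = np.empty_like(gt.age)
        ok, logj = _kernels.mu_rescale_ages(
            gt.n_tips, gt.parent, gt.age, age_new, gt.pop, ys, mu, 1.0,
            dated, st.parent, st.tau,
        )
        assert ok and logj == 0.0
        assert np.array_equal(age_new, gt.age)

    def test_tip_rescale_forward_reverse_jacobian_is_one(self):
        """Eq-10-style tip-age rescale: |d ts*/d ts| * |d ts/d ts*| = 1."""
        for c in (0.5, 1.7, 3.0):
            k = 5
            log_fwd = k * math.log(c)
            log_rev = k * math.log(1.0 / c)
            assert log_fwd + log_rev == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_log_ratio_matches_finite_difference_jacobian(self, seed):
        """The analytic c * prod (tau-b*)/(tau-b) matches the numerical
        determinant of the full (mu, t1..tn) transformation."""
        rng = np.random.default_rng(seed)
        tau = 1.0
        mu = 10 ** rng.uniform(-5, -3)
        c = math.exp(rng.uniform(-0.4, 0.4))
        ys_tips = np.sort(rng.uniform(0.05, 0.6, size=3)) / mu

        def b_fn(tip_ages):
            return np.array([max(tip_ages[0], tip_ages[1]), max(tip_ages)])

        b_old = b_fn(ys_tips * mu)
        t_nodes = np.array([
            rng.uniform(b_old[0] + 0.01, tau - 0.2),
            rng.uniform(max(b_old[1], 0.61) + 0.01, tau - 0.05),
        ])
        t_nodes[1] = max(t_nodes[1], t_nodes[0] + 0.01)
        b_new = b_old * c
        analytic = math.log(c) + np.sum(np.log((tau - b_new) / (tau - b_old)))
        numeric = mu_move_logdet_fd(mu, c, ys_tips, t_nodes, b_fn, tau)
        assert analytic == pytest.approx(numeric, abs=1e-6)

    def test_mu_upper_bound_rules(self, symmetric4):
        priors = PriorSet(GammaPrior(10, 100.0), GammaPrior(10, 1e8), GammaPrior(8, 2000.0))
        labels = ["a1", "b1", "c1", "d1"]
        aln = LocusAlignment.from_strings(labels, ["ACGT"] * 4)
        imap = dict(zip(labels, "ABCD"))
        # one dated sample: bound = tau_parent / ys
        eng = MscMcmc(symmetric4, [aln], imap, {"a1": 50_000.0}, priors,
                      McmcConfig(burnin=0, nsample=1), np.random.default_rng(0))
        assert eng.mu_upper_bound() == pytest.approx(0.007 / 50_000.0)
        # two dated populations: the global bound is the minimum
        eng2 = MscMcmc(symmetric4, [aln], imap, {"a1": 50_000.0, "c1": 50_000.0},
                       priors, McmcConfig(burnin=0, nsample=1), np.random.default_rng(0))
        assert eng2.mu_upper_bound() == pytest.approx(min(0.007, 0.004) / 50_000.0)
        # all contemporary: the configured ceiling applies
        eng3 = MscMcmc(symmetric4, [aln], imap, {}, priors,
                       McmcConfig(burnin=0, nsample=1), np.random.default_rng(0))
        assert eng3.mu_upper_bound() == eng3.mu_ceiling


class TestReflection:
    def test_values_inside_are_unchanged(self):
        assert reflect(0.5, 0.0, 1.0) == 0.5

    def test_reflects_at_both_bounds(self):
        assert reflect(1.2, 0.0, 1.0) == pytest.approx(0.8)
        assert reflect(-0.3, 0.0, 1.0) == pytest.approx(0.3)
        # multiple folds
        assert reflect(2.5, 0.0, 1.0) == pytest.approx(0.5)

    def test_one_sided_reflection(self):
        assert reflect(-0.2, 0.0, math.inf) == pytest.approx(0.2)
        assert reflect(1.4, -math.inf, 1.0) == pytest.approx(0.6)

    def test_symmetry_of_the_folded_kernel(self):
        """reflect is an involution on pre-images: folding x and its mirror
        2*lo - x lands on the same point."""
        for x in (1.3, -0.7, 2.9):
            assert reflect(x, 0.0, 1.0) == pytest.approx(reflect(-x, 0.0, 1.0))

    def test_bactrian_laplace_unit_variance(self):
        rng = np.random.default_rng(11)
        x = bactrian_laplace(rng, 0.95, 200_000)
        assert abs(x.mean()) < 0.01
        assert x.var() == pytest.approx(1.0, abs=0.02)


class TestPriorOnlyMarginals:
    def test_theta_matches_gamma_prior(self, symmetric4):
        """Sampling with the likelihood off: theta marginals follow Gamma."""
        priors = PriorSet(GammaPrior(10, 100.0), GammaPrior(10, 1e8), GammaPrior(8, 2000.0))
        labels = ["a1", "b1", "c1", "d1"]
        aln = LocusAlignment.from_strings(labels, ["ACGT" * 5] * 4)
        imap = dict(zip(labels, "ABCD"))
        eng = MscMcmc(symmetric4, [aln], imap, {}, priors,
                      McmcConfig(burnin=500, nsample=2000, sampfreq=3, usedata=False),
                      np.random.default_rng(5))
        tr = eng.run()
        ref = gamma.rvs(8.0, scale=1 / 2000.0, size=20_000,
                        random_state=np.random.default_rng(1))
        for pop in ("A", "ABCD"):
            stat = ks_2samp(tr[f"theta_{pop}"], ref).statistic
            assert stat < 0.06, f"theta_{pop} deviates from its prior (KS={stat:.3f})"

    def test_tau_never_violates_sample_bound(self, symmetric4):
        """The divergence time above a dated population stays above the
        oldest sample age in substitution units throughout the chain."""
        priors = PriorSet(GammaPrior(10, 100.0), GammaPrior(10, 1e8), GammaPrior(8, 2000.0))
        labels = ["a1", "b1", "c1", "d1"]
        aln = LocusAlignment.from_strings(labels, ["ACGT" * 5] * 4)
        imap = dict(zip(labels, "ABCD"))
        dates = {"a1": 40_000.0}
        eng = MscMcmc(symmetric4, [aln], imap, dates, priors,
                      McmcConfig(burnin=300, nsample=600, usedata=False, check_every=300),
                      np.random.default_rng(6))
        tr = eng.run()
        assert np.all(tr["tau_AB"] > 40_000.0 * tr["mu"])

    def test_caches_stay_consistent_with_data(self, symmetric4, rng):
        """Acceptance decisions use cached terms; periodic full recomputes
        must agree exactly (this run raises on drift)."""
        from conftest import random_gene_tree
        from mscdate.simulate import simulate_alignment

        priors = PriorSet(GammaPrior(10, 100.0), GammaPrior(10, 1e8), GammaPrior(8, 2000.0))
        labels = [f"{s}1" for s in "ABCD"]
        alns = []
        for _ in range(3):
            gt = random_gene_tree(symmetric4, 1, rng, max_age_frac=0.3)
            gt.tip_labels = labels
            alns.append(simulate_alignment(gt, 150, rng))
        imap = dict(zip(labels, "ABCD"))
        dates = {"A1": 30_000.0}
        eng = MscMcmc(symmetric4, alns, imap, dates, priors,
                      McmcConfig(burnin=150, nsample=150, usedata=True, check_every=60),
                      np.random.default_rng(8))
        eng.run()  # raises AssertionError on any cache drift
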