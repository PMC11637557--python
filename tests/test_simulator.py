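"""Serial-coalescent simulator: distributional checks and design handling."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from mscdate import load_species_tree, sample_genealogy, simulate_alignment
from mscdate.simulate import DESIGN_NAMES, get_design, replicate_study


def one_pop_tree(theta):
    # unbounded single population: the root is the sampled population
    return load_species_tree("(A,B)AB;", {"A": theta, "B": theta, "AB": theta}, {"AB": 1e6})


class TestPairCoalescentLaw:
    N = 30_000

    def _pair_times(self, theta, ts2, rng):
        st = one_pop_tree(theta)
        a = st.index["A"]
        sp = np.array([a, a])
        ts = np.array([0.0, ts2])
        out = np.empty(self.N)
        for i in range(self.N):
            gt = sample_genealogy(st, sp, ts, rng)
            out[i] = gt.age[2]
        return out

    def test_contemporary_pair_mean_theta_over_two(self, rng):
        theta = 0.02
        t = self._pair_times(theta, 0.0, rng)
        se = theta / 2 / math.sqrt(self.N)
        assert abs(t.mean() - theta / 2) < 3 * se

    def test_serial_pair_exponential_after_second_sample(self, rng):
        """No coalescence before ts2; T - ts2 is Exponential(2/theta)."""
        theta = 0.02
        ts2 = 0.005
        t = self._pair_times(theta, ts2, rng)
        assert t.min() > ts2
        excess = t - ts2
        se = theta / 2 / math.sqrt(self.N)
        assert abs(excess.mean() - theta / 2) < 3 * se
        stat = kstest(excess, "expon", args=(0, theta / 2)).pvalue
        assert stat > 0.01

    def test_single_sample_passes_through(self, rng):
        st = load_species_tree("(A,B)AB;", {"A": 0.01, "B": 0.01, "AB": 0.01}, {"AB": 0.004})
        sp = np.array([st.index["A"], st.index["B"]])
        gt = sample_genealogy(st, sp, np.array([0.001, 0.0]), rng)
        # the single A lineage cannot coalesce below tau_AB
        assert gt.age[2] > 0.004


class TestSequenceSimulation:
    def test_zero_branch_copies_parent(self, rng):
        st = one_pop_tree(0.02)
        a = st.index["A"]
        gt = sample_genealogy(st, np.array([a, a]), np.zeros(2), rng)
        gt.age[2] = max(gt.age[:2])  # zero both branches
        aln = simulate_alignment(gt, 300, rng)
        assert aln.codes[0].tolist() == aln.codes[1].tolist()

    def test_expected_divergence_matches_jc(self, rng):
        st = one_pop_tree(0.02)
        a = st.index["A"]
        gt = sample_genealogy(st, np.array([a, a]), np.zeros(2), rng)
        t_total = 2 * float(gt.age[2])
        L = 60_000
        aln = simulate_alignment(gt, L, rng)
        p_expected = 0.75 * (1 - math.exp(-4 * t_total / 3))
        p_obs = np.mean(aln.codes[0] != aln.codes[1])
        se = math.sqrt(p_expected * (1 - p_expected) / L)
        assert abs(p_obs - p_expected) < 3 * se

    def test_saturation_limit(self, rng):
        st = one_pop_tree(50.0)  # enormous theta: huge coalescent times
        a = st.index["A"]
        gt = sample_genealogy(st, np.array([a, a]), np.zeros(2), rng)
        aln = simulate_alignment(gt, 50_000, rng)
        p_obs = np.mean(aln.codes[0] != aln.codes[1])
        assert abs(p_obs - 0.75) < 0.01


class TestDesigns:
    def test_known_names(self):
        assert set(DESIGN_NAMES) == {
            "nuclear_extinct", "mito_extinct", "recent_divergence", "dates_ignored"
        }
        with pytest.raises(ValueError):
            get_design("nope")

    def test_nuclear_extinct_conditions(self):
        d = get_design("nuclear_extinct")
        assert d.tau_years == {"ABCD": 10e6, "AB": 7e6, "CD": 4e6}
        assert d.mu == 1e-9
        assert d.n_loci == 2000 and d.length == 1000
        extinct = {s.species: s for s in d.schedule if s.age_range}
        assert set(extinct) == {"A", "C"}
        assert extinct["A"].age_range == (5000.0, 50_000.0)
        st = d.species_tree()
        assert st.tau[st.index["ABCD"]] == pytest.approx(0.01)

    def test_extinction_floor_respected(self, rng):
        reps = replicate_study("nuclear_extinct", 2, rng, n_loci=1, length=10)
        for ds in reps:
            for lab, ys in ds.truth["dates_true"].items():
                if ds.imap[lab] in ("A", "C"):
                    assert ys >= 5000.0
                else:
                    assert ys == 0.0

    def test_dates_shared_across_replicates_for_nuclear(self, rng):
        reps = replicate_study("nuclear_extinct", 2, rng, n_loci=1, length=10)
        assert reps[0].dates == reps[1].dates

    def test_dates_redrawn_for_recent_divergence(self, rng):
        reps = replicate_study("recent_divergence", 2, rng, n_loci=1, length=10)
        assert reps[0].dates != reps[1].dates
        # ages bounded by the population divergence times (in years)
        for ds in reps:
            for lab, ys in ds.dates.items():
                bound = 5000.0 if ds.imap[lab] in ("A", "B") else 13_000.0
                assert 0.0 <= ys <= bound

    def test_dates_ignored_zeroes_analysis_dates_only(self, rng):
        ds = replicate_study("dates_ignored", 1, rng, n_loci=1, length=10)[0]
        assert all(v == 0.0 for v in ds.dates.values())
        assert any(v > 0.0 for v in ds.truth["dates_true"].values())

    def test_same_seed_identical_output(self):
        a = replicate_study("recent_divergence", 1, np.random.default_rng(9), n_loci=2, length=50)[0]
        b = replicate_study("recent_divergence", 1, np.random.default_rng(9), n_loci=2, length=50)[0]
        assert a.dates == b.dates
        for x, y in zip(a.alignments, b.alignments):
            assert x.labels == y.labels
            assert np.array_equal(x.codes, y.codes)

    def test_smoke_single_replicate_single_locus(self, rng):
        ds = replicate_study("mito_extinct", 1, rng, n_loci=1, length=100)[0]
        assert len(ds.alignments) == 1
        assert ds.alignments[0].n_seq == 40  # 10 haploid individuals x 4 species
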