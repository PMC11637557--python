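"""Gene-tree density under the MSC with dated tips, against independent oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mscdate import (
    GeneTree,
    build_epochs,
    gene_tree_log_density,
    load_species_tree,
    population_log_density,
    root_population_log_density,
)
from mscdate import _kernels

from conftest import random_gene_tree
from oracles import msc_log_density_oracle


def pair_tree(ts1, ts2, t_coal, species, st):
    """Two tips in one population coalescing at t_coal."""
    a = st.index[species]
    age = np.array([ts1, ts2, t_coal])
    gt = GeneTree(2, [2, 2, -1], [-1, -1, 0], [-1, -1, 1], age, [a, a])
    gt.assign_populations(st)
    return gt


class TestPairFormulas:
    def test_serial_pair_density_matches_exponential(self):
        """Two lineages sampled at 0 and 0.001 coalescing at 0.003 with
        theta = 0.01: density is (2/theta) exp(-(2/theta)(t - ts2))."""
        st = load_species_tree(
            "(A,B)AB;", {"A": 0.01, "B": 0.01, "AB": 0.01}, {"AB": 0.005}
        )
        gt = pair_tree(0.0, 0.001, 0.003, "A", st)
        part = build_epochs(st.index["A"], gt, st)
        expected = math.log((2 / 0.01) * math.exp(-(2 / 0.01) * (0.003 - 0.001)))
        assert population_log_density(part, 0.01) == pytest.approx(expected, abs=1e-12)

    def test_single_lineage_population_log_one(self, symmetric4):
        st = symmetric4
        a, b = st.index["A"], st.index["B"]
        age = np.array([0.002, 0.0, 0.008])
        gt = GeneTree(2, [2, 2, -1], [-1, -1, 0], [-1, -1, 1], age, [a, b])
        gt.assign_populations(st)
        assert population_log_density(build_epochs(a, gt, st), 0.01) == 0.0
        assert population_log_density(build_epochs(b, gt, st), 0.01) == 0.0

    def test_root_pair_exponential(self):
        """Two lineages entering the root at tau, coalescing tau + w later."""
        st = load_species_tree(
            "(A,B)AB;", {"A": 0.02, "B": 0.02, "AB": 0.02}, {"AB": 0.004}
        )
        a, b = st.index["A"], st.index["B"]
        w = 0.0035
        age = np.array([0.0, 0.0, 0.004 + w])
        gt = GeneTree(2, [2, 2, -1], [-1, -1, 0], [-1, -1, 1], age, [a, b])
        gt.assign_populations(st)
        part = build_epochs(st.root, gt, st)
        expected = math.log((2 / 0.02) * math.exp(-(2 / 0.02) * w))
        assert root_population_log_density(part, 0.02) == pytest.approx(expected, abs=1e-12)

    def test_root_single_lineage_log_one(self):
        st = load_species_tree("(A,B)AB;", {"A": 0.01, "B": 0.01, "AB": 0.01}, {"AB": 0.004})
        gt = pair_tree(0.0, 0.001, 0.003, "A", st)
        assert root_population_log_density(build_epochs(st.root, gt, st), 0.01) == 0.0


class TestOracleEquivalence:
    def test_contemporary_random_trees(self, symmetric4, rng):
        """All tips at age 0: the density equals the standard MSC density
        computed by an independent edge-overlap integration."""
        for _ in range(100):
            n = int(rng.integers(1, 3))  # 4 or 8 tips total
            gt = random_gene_tree(symmetric4, n, rng)
            ref = msc_log_density_oracle(gt, symmetric4)
            assert gene_tree_log_density(gt, symmetric4) == pytest.approx(ref, abs=1e-10)

    def test_dated_random_trees(self, symmetric4, rng):
        for _ in range(50):
            gt = random_gene_tree(symmetric4, 2, rng, max_age_frac=0.5)
            ref = msc_log_density_oracle(gt, symmetric4)
            assert gene_tree_log_density(gt, symmetric4) == pytest.approx(ref, abs=1e-10)

    def test_fast_kernel_matches_reference(self, asymmetric4, rng):
        """The compiled per-population kernel agrees with the epoch-based path."""
        st = asymmetric4
        sp_is_tip = np.asarray([st.is_tip(i) for i in range(st.n_nodes)])
        for _ in range(30):
            gt = random_gene_tree(st, 2, rng, max_age_frac=0.4)
            out = np.zeros(st.n_nodes)
            ok = _kernels.msc_log_density_pops(
                gt.n_tips, gt.age, gt.base, gt.tip_species, st.parent, st.tau,
                st.theta, sp_is_tip, st._desc, st.root,
                np.arange(st.n_nodes, dtype=np.int64), out,
            )
            assert ok
            assert out.sum() == pytest.approx(gene_tree_log_density(gt, st), abs=1e-9)


class TestProperties:
    def test_pair_density_normalizes(self):
        """For 2 serial samples in an unbounded population the implied
        density of the coalescent time integrates to one over (ts2, inf)."""
        theta = 0.05
        st = load_species_tree("(A,B)AB;", {"A": theta, "B": theta, "AB": theta}, {"AB": 100.0})
        ts2 = 0.01

        def dens(t):
            gt = pair_tree(0.0, ts2, t, "A", st)
            part = build_epochs(st.index["A"], gt, st)
            return math.exp(population_log_density(part, theta))

        total, err = quad(dens, ts2, np.inf)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_zero_waiting_time_finite(self):
        st = load_species_tree("(A,B)AB;", {"A": 0.01, "B": 0.01, "AB": 0.01}, {"AB": 0.005})
        gt = pair_tree(0.0, 0.001, 0.001, "A", st)  # coalesces at the instant of sampling
        part = build_epochs(st.index["A"], gt, st)
        assert population_log_density(part, 0.01) == pytest.approx(math.log(2 / 0.01))

    def test_exchangeable_simultaneous_tips(self, symmetric4, rng):
        gt = random_gene_tree(symmetric4, 3, rng)  # all contemporary
        base = gene_tree_log_density(gt, symmetric4)
        # swap two same-species contemporary tips' positions in the topology
        a = symmetric4.index["A"]
        i, j = [int(v) for v in np.flatnonzero(gt.tip_species == a)[:2]]
        for arr in (gt.parent,):
            arr[i], arr[j] = arr[j], arr[i]
        for v in range(gt.n_tips, gt.n_nodes):
            if gt.left[v] == i:
                gt.left[v] = j
            elif gt.left[v] == j:
                gt.left[v] = i
            if gt.right[v] == i:
                gt.right[v] = j
            elif gt.right[v] == j:
                gt.right[v] = i
        assert gene_tree_log_density(gt, symmetric4) == pytest.approx(base, abs=1e-12)

    def test_uncoalesced_root_rejected(self):
        st = load_species_tree("(A,B)AB;", {"A": 0.01, "B": 0.01, "AB": 0.01}, {"AB": 0.004})
        a, b = st.index["A"], st.index["B"]
        # a "gene tree" whose root coalescence is missing cannot be built as a
        # binary tree; instead check theta <= 0 and bad partitions error out
        gt = pair_tree(0.0, 0.001, 0.003, "A", st)
        part = build_epochs(a, gt, st)
        with pytest.raises(ValueError):
            population_log_density(part, -1.0)
        with pytest.raises(ValueError):
            root_population_log_density(part, 0.01)  # not the root partition
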