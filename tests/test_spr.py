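"""Date-aware gene-tree SPR: reattachment bounds and feasibility."""

import numpy as np
import pytest

from mscdate import GammaPrior, LocusAlignment, load_species_tree
from mscdate import _kernels
from mscdate.genetree import GeneTree
from mscdate.mcmc import McmcConfig, MscMcmc, PriorSet


def fig3_engine():
    """Two species: A sampled at ts1 < ts2, B once; t1 joins the A samples."""
    st = load_species_tree("(A,B)AB;", {"A": 0.05, "B": 0.05, "AB": 0.05}, {"AB": 1.0})
    labels = ["a_young", "a_old", "b1"]
    aln = LocusAlignment.from_strings(labels, ["ACGTACGT"] * 3)
    imap = {"a_young": "A", "a_old": "A", "b1": "B"}
    mu = 1e-5
    ts1, ts2 = 0.1, 0.4
    dates = {"a_young": ts1 / mu, "a_old": ts2 / mu}
    priors = PriorSet(GammaPrior(4.0, 4.0), GammaPrior(10.0, 1e6), GammaPrior(4.0, 100.0))
    eng = MscMcmc(st, [aln], imap, dates, priors,
                  McmcConfig(burnin=0, nsample=1, usedata=False, mu_ceiling=1e-5 * 1.0001),
                  np.random.default_rng(1))
    # pin the exact configuration: mu, gene tree with t1 in A and root above tau
    eng.mu = mu
    gt = eng.gtrees[0]
    a, b = st.index["A"], st.index["B"]
    order = {lab: i for i, lab in enumerate(gt.tip_labels)}
    age = gt.age
    age[order["a_young"]] = ts1
    age[order["a_old"]] = ts2
    age[order["b1"]] = 0.0
    # topology: (a_young, a_old) at t1 = 0.6 inside A; root at 1.5 in AB
    i, j, k = order["a_young"], order["a_old"], order["b1"]
    gt.left[3], gt.right[3] = i, j
    gt.parent[i] = gt.parent[j] = 3
    gt.left[4], gt.right[4] = 3, k
    gt.parent[3] = 4
    gt.parent[k] = 4
    gt.parent[4] = -1
    gt.root = 4
    age[3] = 0.6
    age[4] = 1.5
    gt.assign_populations(st)
    eng._full_recompute()
    return eng, st, gt, order


class TestFig3Scenarios:
    def test_prune_youngest_sample_bound_is_next_sample_age(self):
        """No branch exists between ts1 and ts2 (the remaining A lineage only
        starts at ts2), so the reversible reattachment floor is ts2: every
        proposed time has at least one feasible branch."""
        eng, st, gt, order = fig3_engine()
        u = order["a_young"]
        w, in_sub, remroot, p, lo = eng._spr_detach(gt, u)
        assert lo == pytest.approx(0.4)

    def test_no_branch_between_ts1_and_ts2_rejects(self):
        """A reattachment time below ts2 has no feasible branch: the only
        other A lineage starts at ts2 and the B lineage is another population."""
        eng, st, gt, order = fig3_engine()
        u = order["a_young"]
        w, in_sub, remroot, p, lo = eng._spr_detach(gt, u)
        cand = np.empty(gt.n_nodes, dtype=np.int64)
        kn = _kernels.spr_candidates(
            gt.n_nodes, w.parent, w.age, w.base, in_sub, p, remroot,
            int(gt.base[u]), 0.25, eng.sp_parent, st.tau, cand,
        )
        assert kn == 0
        # above ts2 the a_old branch is available
        kn2 = _kernels.spr_candidates(
            gt.n_nodes, w.parent, w.age, w.base, in_sub, p, remroot,
            int(gt.base[u]), 0.7, eng.sp_parent, st.tau, cand,
        )
        assert kn2 >= 1

    def test_prune_older_sample_always_has_a_branch(self):
        eng, st, gt, order = fig3_engine()
        u = order["a_old"]
        w, in_sub, remroot, p, lo = eng._spr_detach(gt, u)
        assert lo == pytest.approx(0.4)  # its own age; a_young remains in A
        cand = np.empty(gt.n_nodes, dtype=np.int64)
        for t in (0.45, 0.8, 1.2):
            kn = _kernels.spr_candidates(
                gt.n_nodes, w.parent, w.age, w.base, in_sub, p, remroot,
                int(gt.base[u]), t, eng.sp_parent, st.tau, cand,
            )
            assert kn >= 1

    def test_prune_sole_b_lineage_bound_is_tau(self):
        eng, st, gt, order = fig3_engine()
        u = order["b1"]
        w, in_sub, remroot, p, lo = eng._spr_detach(gt, u)
        assert lo == pytest.approx(1.0)  # the speciation time: B has no other nodes

    def test_feasibility_respects_populations(self):
        """Below tau the pruned B lineage can never join an A branch."""
        eng, st, gt, order = fig3_engine()
        u = order["b1"]
        w, in_sub, remroot, p, lo = eng._spr_detach(gt, u)
        cand = np.empty(gt.n_nodes, dtype=np.int64)
        kn = _kernels.spr_candidates(
            gt.n_nodes, w.parent, w.age, w.base, in_sub, p, remroot,
            int(gt.base[u]), 0.5, eng.sp_parent, st.tau, cand,
        )
        assert kn == 0
        kn2 = _kernels.spr_candidates(
            gt.n_nodes, w.parent, w.age, w.base, in_sub, p, remroot,
            int(gt.base[u]), 1.1, eng.sp_parent, st.tau, cand,
        )
        assert kn2 >= 1


class TestTwoTipTree:
    def test_topology_never_changes(self, rng):
        st = load_species_tree("(A,B)AB;", {"A": 0.05, "B": 0.05, "AB": 0.05}, {"AB": 0.1})
        labels = ["a1", "b1"]
        aln = LocusAlignment.from_strings(labels, ["ACGTACGTACGT"] * 2)
        priors = PriorSet(GammaPrior(4.0, 40.0), GammaPrior(10.0, 1e6), GammaPrior(4.0, 80.0))
        eng = MscMcmc(st, [aln], {"a1": "A", "b1": "B"}, {}, priors,
                      McmcConfig(burnin=0, nsample=1, usedata=False),
                      np.random.default_rng(2))
        gt0 = eng.gtrees[0]
        tips = {int(gt0.left[gt0.root]), int(gt0.right[gt0.root])}
        for _ in range(200):
            eng.propose_spr(0)
        gt = eng.gtrees[0]
        assert {int(gt.left[gt.root]), int(gt.right[gt.root])} == tips
        gt.validate(st)
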