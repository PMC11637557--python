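"""Strict-clock JC likelihood: closed forms, matrix exponential, pruning."""

import math

import numpy as np
import pytest

from mscdate import LocusAlignment, jc_transition_matrix, pruning_log_likelihood
from mscdate.genetree import GeneTree
from mscdate.likelihood import _site_log_likelihoods_numpy, tip_partials

from oracles import jc_matrix_expm, jc_pair_site_likelihood


class TestTransitionMatrix:
    def test_zero_branch_is_identity(self):
        assert np.allclose(jc_transition_matrix(0.0), np.eye(4))

    def test_long_branch_is_stationary(self):
        assert np.allclose(jc_transition_matrix(1e3), np.full((4, 4), 0.25))

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 2.0])
    def test_matches_matrix_exponential(self, t):
        assert np.allclose(jc_transition_matrix(t), jc_matrix_expm(t), atol=1e-12)

    def test_rows_sum_to_one(self):
        P = jc_transition_matrix(0.37)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            jc_transition_matrix(-0.1)


def pair_gene_tree(t1, t2, t_root, labels=("x", "y")):
    age = np.array([t1, t2, t_root])
    return GeneTree(2, [2, 2, -1], [-1, -1, 0], [-1, -1, 1], age, [0, 0], labels)


class TestPruning:
    @pytest.mark.parametrize("seed", range(10))
    def test_two_sequence_closed_form(self, seed):
        """Random patterns and branch lengths against the pairwise JC formula."""
        rng = np.random.default_rng(seed)
        t1, t2 = rng.uniform(0, 0.02, 2)
        t_root = max(t1, t2) + rng.uniform(0.001, 0.3)
        n_sites = 40
        bases = "ACGT"
        s1 = "".join(rng.choice(list(bases), n_sites))
        s2 = "".join(rng.choice(list(bases), n_sites))
        aln = LocusAlignment.from_strings(["x", "y"], [s1, s2])
        gt = pair_gene_tree(t1, t2, t_root)
        got = pruning_log_likelihood(aln, gt)
        t_total = (t_root - t1) + (t_root - t2)
        expected = sum(
            math.log(jc_pair_site_likelihood(t_total, a == b))
            for a, b in zip(s1, s2)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_empty_alignment_log_one(self):
        aln = LocusAlignment.from_strings(["x", "y"], ["", ""])
        assert pruning_log_likelihood(aln, pair_gene_tree(0, 0, 0.1)) == 0.0

    def test_pulley_root_slide_invariance(self):
        """Sliding the root along its two branches (total path fixed) does not
        change the likelihood of a reversible model."""
        rng = np.random.default_rng(3)
        s1 = "".join(rng.choice(list("ACGT"), 60))
        s2 = "".join(rng.choice(list("ACGT"), 60))
        aln = LocusAlignment.from_strings(["x", "y"], [s1, s2])
        ref = None
        for t_root in (0.05, 0.1, 0.2):
            # keep total path = 0.4 by moving tip ages with the root
            t1 = t_root - 0.2 if t_root >= 0.2 else 0.0
            t2 = 0.0 if t_root >= 0.2 else 0.2 - t_root  # t_total stays 0.4 - 2*0
            gt = pair_gene_tree(t1, t2, t_root + 0.2 if t_root < 0.2 else t_root + 0.2)
            t_total = (gt.age[2] - t1) + (gt.age[2] - t2)
            got = pruning_log_likelihood(aln, gt)
            expected = sum(
                math.log(jc_pair_site_likelihood(t_total, a == b))
                for a, b in zip(s1, s2)
            )
            assert got == pytest.approx(expected, abs=1e-10)

    def test_compression_bit_identical(self, symmetric4, rng):
        from conftest import random_gene_tree
        from mscdate.simulate import simulate_alignment

        gt = random_gene_tree(symmetric4, 2, rng, max_age_frac=0.3)
        aln = simulate_alignment(gt, 500, rng)
        a = pruning_log_likelihood(aln, gt, compress=True)
        b = pruning_log_likelihood(aln, gt, compress=False)
        assert a == b  # bit identical by contract

    def test_numba_and_numpy_paths_agree(self, symmetric4, rng):
        from conftest import random_gene_tree
        from mscdate.simulate import simulate_alignment

        for _ in range(5):
            gt = random_gene_tree(symmetric4, 3, rng, max_age_frac=0.3)
            aln = simulate_alignment(gt, 200, rng)
            a = pruning_log_likelihood(aln, gt, engine="numba")
            b = pruning_log_likelihood(aln, gt, engine="numpy")
            assert a == pytest.approx(b, abs=1e-9)

    def test_ambiguity_bound(self):
        """Replacing a site state with N gives a site likelihood at least the
        max over concrete states (the all-ones partial dominates)."""
        gt = pair_gene_tree(0.0, 0.0, 0.05)
        best = -np.inf
        for b in "ACGT":
            aln = LocusAlignment.from_strings(["x", "y"], ["A", b])
            best = max(best, pruning_log_likelihood(aln, gt))
        aln_n = LocusAlignment.from_strings(["x", "y"], ["A", "N"])
        assert pruning_log_likelihood(aln_n, gt) >= best - 1e-12

    def test_label_mismatch_rejected(self):
        aln = LocusAlignment.from_strings(["x", "z"], ["A", "C"])
        with pytest.raises(ValueError, match="labels"):
            pruning_log_likelihood(aln, pair_gene_tree(0, 0, 0.1))

    def test_finite_and_continuous_in_branch_length(self):
        rng = np.random.default_rng(7)
        s1 = "".join(rng.choice(list("ACGT"), 30))
        s2 = "".join(rng.choice(list("ACGT"), 30))
        aln = LocusAlignment.from_strings(["x", "y"], [s1, s2])
        vals = []
        for t in np.linspace(0.01, 1.0, 40):
            vals.append(pruning_log_likelihood(aln, pair_gene_tree(0, 0, t)))
        vals = np.asarray(vals)
        assert np.all(np.isfinite(vals))
        # steep but continuous near t -> 0; smooth on the flatter part
        assert np.max(np.abs(np.diff(vals[10:]))) < 1.0


class TestAlignmentContainer:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            LocusAlignment.from_strings(["x", "y"], ["AC", "A"])

    def test_unknown_character_rejected(self):
        with pytest.raises(ValueError, match="nucleotide"):
            LocusAlignment.from_strings(["x"], ["AZ"])

    def test_iupac_codes_accepted_as_partials(self):
        aln = LocusAlignment.from_strings(["x"], ["RYN-"])
        part = tip_partials(aln.codes)
        assert part[0, :, 0].tolist() == [1, 0, 1, 0]  # R = A/G
        assert part[0, :, 3].tolist() == [1, 1, 1, 1]  # gap = missing
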