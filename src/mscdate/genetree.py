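"""Per-locus gene genealogies with dated tips.

A ``GeneTree`` is a rooted binary tree over sequences.  Tips carry a species
(tip population) assignment and an age ``ts`` in expected substitutions/site
(``ts = ys * mu``).  Internal nodes are coalescent events; every node is
assigned to the species-tree population whose time interval contains its age
along the lineage's ancestral path.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .species import SpeciesTree

__all__ = ["GeneTree"]


class GeneTree:
    """Array-backed rooted binary genealogy.

    Nodes ``0..n_tips-1`` are tips; ``n_tips..2*n_tips-2`` are coalescences.
    ``base[v]`` is the species-tree MRCA of the species of v's descendant
    tips; ``pop[v]`` the population containing v at its age.
    """

    __slots__ = (
        "n_tips",
        "parent",
        "left",
        "right",
        "age",
        "base",
        "pop",
        "tip_species",
        "tip_labels",
        "root",
    )

    def __init__(
        self,
        n_tips: int,
        parent: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        age: np.ndarray,
        tip_species: np.ndarray,
        tip_labels: Optional[Sequence[str]] = None,
    ):
        self.n_tips = int(n_tips)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.age = np.asarray(age, dtype=np.float64)
        self.tip_species = np.asarray(tip_species, dtype=np.int64)
        self.tip_labels = list(tip_labels) if tip_labels is not None else [
            f"seq{i}" for i in range(n_tips)
        ]
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("gene tree must have exactly one root")
        self.root = int(roots[0])
        self.base = np.full(self.n_nodes, -1, dtype=np.int64)
        self.pop = np.full(self.n_nodes, -1, dtype=np.int64)

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    def postorder(self) -> np.ndarray:
        order = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                order.append(v)
            elif v < self.n_tips:
                order.append(v)
            else:
                stack.append((v, True))
                stack.append((int(self.right[v]), False))
                stack.append((int(self.left[v]), False))
        return np.asarray(order, dtype=np.int64)

    def copy(self) -> "GeneTree":
        gt = GeneTree.__new__(GeneTree)
        gt.n_tips = self.n_tips
        gt.parent = self.parent.copy()
        gt.left = self.left.copy()
        gt.right = self.right.copy()
        gt.age = self.age.copy()
        gt.tip_species = self.tip_species
        gt.tip_labels = self.tip_labels
        gt.root = self.root
        gt.base = self.base.copy()
        gt.pop = self.pop.copy()
        return gt

    # -- species-tree annotation -------------------------------------------

    def assign_populations(self, stree: SpeciesTree) -> None:
        """Recompute ``base`` and ``pop`` for all nodes from ages and topology."""
        for v in self.postorder():
            if v < self.n_tips:
                self.base[v] = self.tip_species[v]
            else:
                self.base[v] = stree.mrca(
                    int(self.base[self.left[v]]), int(self.base[self.right[v]])
                )
            self.pop[v] = stree.pop_at(int(self.base[v]), float(self.age[v]))

    def update_node_pop(self, v: int, stree: SpeciesTree) -> None:
        self.pop[v] = stree.pop_at(int(self.base[v]), float(self.age[v]))

    def oldest_descendant_tip_age(self) -> np.ndarray:
        """Per node, the age of the oldest tip in its subtree (b_i of the mu move)."""
        b = np.zeros(self.n_nodes)
        for v in self.postorder():
            if v < self.n_tips:
                b[v] = self.age[v]
            else:
                b[v] = max(b[self.left[v]], b[self.right[v]])
        return b

    # -- validation --------------------------------------------------------

    def validate(self, stree: SpeciesTree, check_pops: bool = True) -> None:
        """Raise ValueError on any ordering or population-interval violation."""
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and not self.age[p] > self.age[v]:
                raise ValueError(
                    f"node {p} (age {self.age[p]:g}) not older than child {v} "
                    f"(age {self.age[v]:g})"
                )
        if check_pops:
            for v in range(self.n_nodes):
                q = int(self.pop[v])
                if q < 0:
                    raise ValueError("populations not assigned; call assign_populations")
                lo = float(stree.tau[q])
                hi = stree.parent_tau(q)
                age = float(self.age[v])
                if not (lo <= age < hi or (math.isinf(hi) and age >= lo)):
                    raise ValueError(
                        f"node {v} age {age:g} outside population interval "
                        f"[{lo:g}, {hi:g}) of {stree.labels[q]}"
                    )
                if not stree.in_subtree(q, int(self.base[v])):
                    raise ValueError("population assignment inconsistent with base")

    def branch_length(self, v: int) -> float:
        p = self.parent[v]
        if p < 0:
            return 0.0
        return float(self.age[p] - self.age[v])

    def __repr__(self):
        return f"GeneTree(n_tips={self.n_tips}, root_age={self.age[self.root]:.6g})"
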