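"""Species tree, sampling design, priors and unit conventions.

The multispecies coalescent (MSC) embeds per-locus gene genealogies inside a
fixed, rooted, binary species tree.  Every population (tip or ancestral) has a
mutation-scaled size ``theta = 4 N g mu`` and every internal node a divergence
time ``tau``, both measured in expected substitutions per site (the mutational
time scale).  Calendar time appears only at the I/O boundary: a sample taken
``ys`` years before present sits at height ``ts = ys * mu`` on the mutational
scale, where ``mu`` is the substitution rate per site per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "GammaPrior",
    "SpeciesTree",
    "SampleSet",
    "load_species_tree",
    "validate_dates_against_tree",
    "years_to_dist",
    "dist_to_years",
]


def years_to_dist(years, mu: float):
    """Convert an age in years before present to expected substitutions/site."""
    return years * mu


def dist_to_years(dist, mu: float):
    """Convert a height in expected substitutions/site to years before present."""
    return dist / mu


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior; mean = shape/rate, variance = shape/rate**2."""

    shape: float
    rate: float

    def __post_init__(self):
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("gamma prior requires shape > 0 and rate > 0")

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def var(self) -> float:
        return self.shape / self.rate**2

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        a, b = self.shape, self.rate
        return a * math.log(b) - gammaln(a) + (a - 1.0) * math.log(x) - b * x

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


class SpeciesTreeError(ValueError):
    pass


class SpeciesTree:
    """Fixed rooted binary species tree with divergence times and population sizes.

    Nodes are indexed 0..n-1 with tips first.  ``tau`` is 0 for tips and the
    divergence time (substitutions/site) for internal nodes; ``theta`` is the
    population size parameter for every population.  A population ``p`` spans
    the time interval ``[tau[p], tau[parent[p]])`` (the root is unbounded
    above).
    """

    def __init__(
        self,
        labels: Sequence[str],
        parent: Sequence[int],
        children: Sequence[tuple],
        tau: Sequence[float],
        theta: Sequence[float],
    ):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = [tuple(c) for c in children]
        self.tau = np.asarray(tau, dtype=np.float64)
        self.theta = np.asarray(theta, dtype=np.float64)
        self.n_nodes = len(self.labels)
        roots = [i for i in range(self.n_nodes) if self.parent[i] < 0]
        if len(roots) != 1:
            raise SpeciesTreeError("tree must have exactly one root")
        self.root = roots[0]
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.index) != self.n_nodes:
            raise SpeciesTreeError("duplicate node labels")
        self._validate()
        self._postorder = self._compute_postorder()
        # descendant membership matrix: desc[p, q] == True iff q is in subtree(p)
        self._desc = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for p in self._postorder:
            self._desc[p, p] = True
            for c in self.children[p]:
                self._desc[p] |= self._desc[c]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick_text: str,
        theta,
        tau=None,
        root_age: Optional[float] = None,
    ) -> "SpeciesTree":
        """Parse a rooted binary Newick topology and attach parameters.

        ``theta`` may be a mapping label -> value or a single value for all
        populations.  ``tau`` is a mapping label -> divergence time; if None,
        ``root_age`` must be given and internal times are spaced by node
        level below the root (a starting state, not an estimate).
        """
        import dendropy

        dtree = dendropy.Tree.get(data=newick_text, schema="newick")
        dnodes = [nd for nd in dtree.postorder_node_iter()]
        for nd in dnodes:
            nch = len(nd.child_nodes())
            if nch not in (0, 2):
                raise SpeciesTreeError("species tree must be rooted and binary")
        # tips first, then internals (postorder among internals keeps children first)
        tips = [nd for nd in dnodes if nd.is_leaf()]
        internals = [nd for nd in dnodes if not nd.is_leaf()]
        order = tips + internals
        idx = {id(nd): i for i, nd in enumerate(order)}

        def _label(nd) -> str:
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise SpeciesTreeError("every tip must be labelled")
                return nd.taxon.label
            if nd.label:
                return nd.label
            parts = sorted(lf.taxon.label for lf in nd.leaf_iter())
            return "".join(parts)

        labels = [_label(nd) for nd in order]
        parent = [-1] * len(order)
        children = [tuple()] * len(order)
        for nd in order:
            if nd.parent_node is not None:
                parent[idx[id(nd)]] = idx[id(nd.parent_node)]
            if not nd.is_leaf():
                children[idx[id(nd)]] = tuple(idx[id(c)] for c in nd.child_nodes())
        if tau is None:
            if root_age is None or root_age <= 0:
                raise SpeciesTreeError("either tau assignments or a positive root_age required")
            level = [0] * len(order)
            for i in range(len(order)):
                if children[i]:
                    level[i] = 1 + max(level[c] for c in children[i])
            root_level = max(level)
            tau = {
                labels[i]: root_age * level[i] / root_level
                for i in range(len(order))
                if children[i]
            }
        tau_arr = []
        theta_arr = []
        for i, lab in enumerate(labels):
            if children[i]:
                if lab not in tau:
                    raise SpeciesTreeError(f"no divergence time for population {lab!r}")
                tau_arr.append(float(tau[lab]))
            else:
                tau_arr.append(0.0)
            th = theta if not isinstance(theta, Mapping) else theta.get(lab)
            if th is None:
                raise SpeciesTreeError(f"no theta for population {lab!r}")
            theta_arr.append(float(th))
        return cls(labels, parent, children, tau_arr, theta_arr)

    # -- validation --------------------------------------------------------

    def _validate(self):
        for i in range(self.n_nodes):
            nch = len(self.children[i])
            if nch not in (0, 2):
                raise SpeciesTreeError("species tree must be binary")
            if nch == 0:
                if self.tau[i] != 0.0:
                    raise SpeciesTreeError("tip populations must have tau == 0")
            else:
                if self.tau[i] <= 0.0:
                    raise SpeciesTreeError("internal tau must be > 0")
                for c in self.children[i]:
                    if self.children[c] and self.tau[c] >= self.tau[i]:
                        raise SpeciesTreeError(
                            f"tau of {self.labels[c]!r} must be younger than its "
                            f"parent {self.labels[i]!r}"
                        )
        if np.any(self.theta <= 0.0):
            raise SpeciesTreeError("all theta must be > 0")

    # -- topology helpers --------------------------------------------------

    def _compute_postorder(self):
        order, stack, seen = [], [self.root], []
        # iterative postorder
        visit = [(self.root, False)]
        while visit:
            node, done = visit.pop()
            if done:
                order.append(node)
            else:
                visit.append((node, True))
                for c in self.children[node]:
                    visit.append((c, False))
        return np.asarray(order, dtype=np.int64)

    @property
    def postorder(self) -> np.ndarray:
        return self._postorder

    def is_tip(self, p: int) -> bool:
        return not self.children[p]

    @property
    def tips(self):
        return [i for i in range(self.n_nodes) if self.is_tip(i)]

    def parent_tau(self, p: int) -> float:
        """Upper boundary time of population p (inf for the root)."""
        q = self.parent[p]
        return math.inf if q < 0 else float(self.tau[q])

    def in_subtree(self, p: int, q: int) -> bool:
        return bool(self._desc[p, q])

    def mrca(self, a: int, b: int) -> int:
        anc = set()
        x = a
        while x >= 0:
            anc.add(x)
            x = self.parent[x]
        x = b
        while x not in anc:
            x = self.parent[x]
        return x

    def pop_at(self, base: int, age: float) -> int:
        """Population occupied at height ``age`` by a lineage rooted in ``base``."""
        p = base
        while self.parent[p] >= 0 and self.tau[self.parent[p]] <= age:
            p = self.parent[p]
        return p

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(
            self.labels, self.parent.copy(), self.children, self.tau.copy(), self.theta.copy()
        )

    def __repr__(self):
        return f"SpeciesTree(n_tips={len(self.tips)}, root={self.labels[self.root]!r})"


@dataclass
class SampleSet:
    """Maps sequence labels to tip populations and ages in years before present."""

    species_of: dict  # label -> species label
    age_ybp: dict  # label -> ys >= 0

    def __post_init__(self):
        for lab, ys in self.age_ybp.items():
            if not math.isfinite(ys) or ys < 0:
                raise ValueError(f"sample {lab!r} has invalid age {ys!r}")
        missing = set(self.age_ybp) - set(self.species_of)
        if missing:
            raise ValueError(f"samples without species assignment: {sorted(missing)}")

    @property
    def labels(self):
        return list(self.species_of)

    def ts(self, label: str, mu: float) -> float:
        return self.age_ybp.get(label, 0.0) * mu

    def max_age_by_species(self) -> dict:
        out: dict = {}
        for lab, sp in self.species_of.items():
            ys = self.age_ybp.get(lab, 0.0)
            out[sp] = max(out.get(sp, 0.0), ys)
        return out


def load_species_tree(
    newick_text: str,
    theta_assignments: Mapping[str, float],
    tau_assignments: Mapping[str, float],
) -> SpeciesTree:
    """Parse a rooted binary Newick string and attach (tau, theta) parameters."""
    return SpeciesTree.from_newick(newick_text, theta_assignments, tau_assignments)


def validate_dates_against_tree(samples: SampleSet, tree: SpeciesTree, mu: float):
    """Check ts = ys*mu < tau(parent) for every dated sample.

    Returns ``(ok, diagnostics)`` where diagnostics lists violating samples.
    Samples must be assigned to tip populations of the species tree.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    diagnostics = []
    for lab, sp in samples.species_of.items():
        if sp not in tree.index:
            raise ValueError(f"sample {lab!r} assigned to unknown population {sp!r}")
        p = tree.index[sp]
        if not tree.is_tip(p):
            raise ValueError(
                f"sample {lab!r} assigned to ancestral population {sp!r}; "
                "only tip populations may be sampled"
            )
        ts = samples.ts(lab, mu)
        bound = tree.parent_tau(p)
        if ts >= bound:
            diagnostics.append(
                f"sample {lab!r}: ts = {ts:g} >= tau_parent({sp}) = {bound:g}"
            )
    return (not diagnostics), diagnostics
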