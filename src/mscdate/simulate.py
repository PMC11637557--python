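"""Simulation of gene trees and sequences under the MSC with dated tips.

Gene trees are generated backwards in time.  Within each population,
lineages become active at their sampling ages; while ``k >= 2`` lineages are
active the waiting time to the next coalescence is exponential with rate
``k(k-1)/theta`` (mutational time scale), truncated by memorylessness at the
next sample-activation or population-boundary event.  Survivors merge into
the parent population at its divergence time; the root population coalesces
to a single lineage.  Sequences then evolve by Jukes-Cantor down the tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genetree import GeneTree
from .likelihood import LocusAlignment
from .species import GammaPrior, SpeciesTree, load_species_tree

__all__ = [
    "sample_genealogy",
    "simulate_gene_tree",
    "simulate_alignment",
    "IndividualSchedule",
    "SimulationDesign",
    "ReplicateDataset",
    "get_design",
    "replicate_study",
    "DESIGN_NAMES",
]


def sample_genealogy(
    stree: SpeciesTree,
    tip_species: Sequence[int],
    tip_ts: Sequence[float],
    rng: np.random.Generator,
    tip_labels: Optional[Sequence[str]] = None,
) -> GeneTree:
    """Simulate one gene tree for tips with ages ``tip_ts`` (substitution units)."""
    tip_species = np.asarray(tip_species, dtype=np.int64)
    tip_ts = np.asarray(tip_ts, dtype=np.float64)
    n_tips = len(tip_species)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes, dtype=np.float64)
    age[:n_tips] = tip_ts
    nxt = n_tips

    for p in range(stree.n_nodes):
        ts = tip_ts[tip_species == p]
        if len(ts) and np.max(ts) >= stree.parent_tau(p):
            raise ValueError("sample age at or beyond the population's parent tau")

    survivors: Dict[int, List[int]] = {}
    for p in stree.postorder:
        p = int(p)
        lo = float(stree.tau[p])
        hi = stree.parent_tau(p)
        theta = float(stree.theta[p])
        cur: List[int] = []
        for c in stree.children[p]:
            cur.extend(survivors.pop(c))
        pending: List[Tuple[float, int]] = []
        if stree.is_tip(p):
            tips_here = np.flatnonzero(tip_species == p)
            pending = sorted((float(tip_ts[i]), int(i)) for i in tips_here)
        t = lo
        idx = 0
        while True:
            k = len(cur)
            t_next = pending[idx][0] if idx < len(pending) else hi
            if k >= 2:
                w = rng.exponential(theta / (k * (k - 1)))
                if t + w < t_next:
                    i = int(rng.integers(k))
                    j = int(rng.integers(k - 1))
                    if j >= i:
                        j += 1
                    a, b = cur[i], cur[j]
                    v = nxt
                    nxt += 1
                    left[v], right[v] = a, b
                    parent[a] = parent[b] = v
                    age[v] = t + w
                    cur = [x for x in cur if x not in (a, b)]
                    cur.append(v)
                    t = t + w
                    continue
            if idx < len(pending):
                t = t_next
                cur.append(pending[idx][1])
                idx += 1
            else:
                break
        survivors[p] = cur
    gt = GeneTree(n_tips, parent, left, right, age, tip_species, tip_labels)
    gt.assign_populations(stree)
    return gt


def simulate_gene_tree(design: "SimulationDesign", locus: int, rng: np.random.Generator) -> GeneTree:
    """One gene tree under a design (dates drawn fresh; convenience entry point)."""
    stree = design.species_tree()
    labels, species, ys = design.draw_sample_ages(rng)
    sp_idx = np.asarray([stree.index[s] for s in species])
    return sample_genealogy(stree, sp_idx, np.asarray(ys) * design.mu, rng, labels)


def simulate_alignment(gene_tree: GeneTree, length: int, rng: np.random.Generator) -> LocusAlignment:
    """Evolve JC sequences down the gene tree; root drawn uniform over ACGT."""
    if length < 0:
        raise ValueError("length must be >= 0")
    gt = gene_tree
    seqs = np.empty((gt.n_nodes, length), dtype=np.int8)
    seqs[gt.root] = rng.integers(0, 4, size=length)
    for v in gt.postorder()[::-1]:
        v = int(v)
        if v == gt.root:
            continue
        par = int(gt.parent[v])
        b = float(gt.age[par] - gt.age[v])
        p_same = 0.25 + 0.75 * math.exp(-4.0 * b / 3.0)
        child = seqs[par].copy()
        mut = rng.random(length) >= p_same
        nmut = int(mut.sum())
        if nmut:
            child[mut] = (child[mut] + rng.integers(1, 4, size=nmut)) % 4
        seqs[v] = child
    codes = (1 << seqs[: gt.n_tips].astype(np.uint8)).astype(np.uint8)
    return LocusAlignment(list(gt.tip_labels), codes)


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndividualSchedule:
    """Sampling plan for one tip species: individuals, sequences each, ages."""

    species: str
    n_individuals: int
    copies: int  # sequences per individual (2 = phased diploid, 1 = haploid)
    age_range: Optional[Tuple[float, float]] = None  # ybp; None = contemporary


@dataclass(frozen=True)
class SimulationDesign:
    """A complete simulation study condition (tree, rates, sampling, priors)."""

    name: str
    newick: str
    tau_years: Dict[str, float]
    mu: float
    theta: Dict[str, float]
    schedule: Tuple[IndividualSchedule, ...]
    n_loci: int
    length: int
    redraw_dates_each_replicate: bool
    priors: Dict[str, GammaPrior]
    zero_dates_in_analysis: bool = False

    def species_tree(self) -> SpeciesTree:
        tau = {k: v * self.mu for k, v in self.tau_years.items()}
        return load_species_tree(self.newick, self.theta, tau)

    def draw_base_uniforms(self, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        """One U(0,1) draw per individual, in individual order.

        Drawing per individual in order makes sampling designs nested: a
        schedule with more individuals extends the smaller one's dates.
        """
        return {
            sch.species: rng.random(sch.n_individuals) for sch in self.schedule
        }

    def ages_from_uniforms(self, u: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
        out = {}
        for sch in self.schedule:
            if sch.age_range is None:
                out[sch.species] = np.zeros(sch.n_individuals)
            else:
                lo, hi = sch.age_range
                out[sch.species] = lo + (hi - lo) * u[sch.species]
        return out

    def draw_sample_ages(self, rng: np.random.Generator):
        """(labels, species, ages_ybp) per sequence, dates shared within individuals."""
        ages = self.ages_from_uniforms(self.draw_base_uniforms(rng))
        labels: List[str] = []
        species: List[str] = []
        ys: List[float] = []
        for sch in self.schedule:
            for i in range(sch.n_individuals):
                for c in range(sch.copies):
                    suffix = "ab"[c] if sch.copies > 1 else ""
                    labels.append(f"{sch.species}{i + 1}{suffix}")
                    species.append(sch.species)
                    ys.append(float(ages[sch.species][i]))
        return labels, species, ys


@dataclass
class ReplicateDataset:
    """Simulated multi-locus dataset plus the generating truth."""

    alignments: List[LocusAlignment]
    imap: Dict[str, str]
    dates: Dict[str, float]
    truth: Dict[str, object]
    design: SimulationDesign


_SYM4 = "((A,B)AB,(C,D)CD)ABCD;"


def _uniform_theta(value: float) -> Dict[str, float]:
    return {k: value for k in ("A", "B", "C", "D", "AB", "CD", "ABCD")}


def _nuclear_extinct(theta: float = 1e-4, age_hi: float = 50_000.0) -> SimulationDesign:
    theta_prior = GammaPrior(2.0, 2.0 / theta)
    return SimulationDesign(
        name="nuclear_extinct",
        newick=_SYM4,
        tau_years={"ABCD": 10e6, "AB": 7e6, "CD": 4e6},
        mu=1e-9,
        theta=_uniform_theta(theta),
        schedule=(
            IndividualSchedule("A", 3, 2, (5_000.0, age_hi)),
            IndividualSchedule("B", 3, 2, None),
            IndividualSchedule("C", 3, 2, (5_000.0, age_hi)),
            IndividualSchedule("D", 3, 2, None),
        ),
        n_loci=2000,
        length=1000,
        redraw_dates_each_replicate=False,
        priors={
            "tau_root": GammaPrior(10.0, 1000.0),
            "mu": GammaPrior(10.0, 1e10),
            "theta": theta_prior,
        },
    )


def _mito_extinct(theta: float = 2.5e-3) -> SimulationDesign:
    rate = 2.5 / theta
    return SimulationDesign(
        name="mito_extinct",
        newick=_SYM4,
        tau_years={"ABCD": 10e6, "AB": 7e6, "CD": 4e6},
        mu=1e-8,
        theta=_uniform_theta(theta),
        schedule=(
            IndividualSchedule("A", 10, 1, (5_000.0, 50_000.0)),
            IndividualSchedule("B", 10, 1, None),
            IndividualSchedule("C", 10, 1, (5_000.0, 50_000.0)),
            IndividualSchedule("D", 10, 1, None),
        ),
        n_loci=1,
        length=16_000,
        redraw_dates_each_replicate=False,
        priors={
            "tau_root": GammaPrior(4.0, 400.0),
            "mu": GammaPrior(10.0, 1e9),
            "theta": GammaPrior(2.5, rate),
        },
    )


def _recent_divergence(theta: float = 1e-4) -> SimulationDesign:
    return SimulationDesign(
        name="recent_divergence",
        newick=_SYM4,
        tau_years={"ABCD": 20_000.0, "AB": 5_000.0, "CD": 13_000.0},
        mu=1e-9,
        theta=_uniform_theta(theta),
        schedule=(
            IndividualSchedule("A", 3, 2, (0.0, 5_000.0)),
            IndividualSchedule("B", 3, 2, (0.0, 5_000.0)),
            IndividualSchedule("C", 3, 2, (0.0, 13_000.0)),
            IndividualSchedule("D", 3, 2, (0.0, 13_000.0)),
        ),
        n_loci=2000,
        length=1000,
        redraw_dates_each_replicate=True,
        priors={
            "tau_root": GammaPrior(20.0, 1e6),
            "mu": GammaPrior(10.0, 1e10),
            "theta": GammaPrior(10.0, 10.0 / theta),
        },
    )


DESIGN_NAMES = ("nuclear_extinct", "mito_extinct", "recent_divergence", "dates_ignored")


def get_design(name: str, **overrides) -> SimulationDesign:
    """Named study condition; overrides may change n_loci, length, theta, etc."""
    theta = overrides.pop("theta", None)
    if name == "nuclear_extinct":
        d = _nuclear_extinct(**({"theta": theta} if theta else {}))
    elif name == "mito_extinct":
        d = _mito_extinct(**({"theta": theta} if theta else {}))
    elif name == "recent_divergence":
        d = _recent_divergence(**({"theta": theta} if theta else {}))
    elif name == "dates_ignored":
        d = _recent_divergence(**({"theta": theta} if theta else {}))
        d = replace(d, name="dates_ignored", zero_dates_in_analysis=True)
    else:
        raise ValueError(f"unknown design {name!r}; choose from {DESIGN_NAMES}")
    if overrides:
        d = replace(d, **overrides)
    return d


def replicate_study(
    design_name,
    reps: int,
    rng: np.random.Generator,
    **overrides,
) -> List[ReplicateDataset]:
    """Simulate ``reps`` datasets under a named design (or a design object).

    When the design does not redraw dates each replicate, one set of uniform
    draws is made up front and reused, so all replicates share the same
    sampling dates (and the dates are shared across loci either way).
    """
    design = (
        design_name
        if isinstance(design_name, SimulationDesign)
        else get_design(design_name, **overrides)
    )
    stree = design.species_tree()
    shared_u = None if design.redraw_dates_each_replicate else design.draw_base_uniforms(rng)

    out: List[ReplicateDataset] = []
    for _ in range(reps):
        u = design.draw_base_uniforms(rng) if shared_u is None else shared_u
        ages = design.ages_from_uniforms(u)
        labels, species, ys = [], [], []
        for sch in design.schedule:
            for i in range(sch.n_individuals):
                for c in range(sch.copies):
                    suffix = "ab"[c] if sch.copies > 1 else ""
                    labels.append(f"{sch.species}{i + 1}{suffix}")
                    species.append(sch.species)
                    ys.append(float(ages[sch.species][i]))
        sp_idx = np.asarray([stree.index[s] for s in species])
        ts = np.asarray(ys) * design.mu
        alignments = []
        for _l in range(design.n_loci):
            gt = sample_genealogy(stree, sp_idx, ts, rng, labels)
            alignments.append(simulate_alignment(gt, design.length, rng))
        dates = dict(zip(labels, ys))
        if design.zero_dates_in_analysis:
            dates = {k: 0.0 for k in dates}
        truth = {
            "mu": design.mu,
            "tau_years": dict(design.tau_years),
            "tau": {k: v * design.mu for k, v in design.tau_years.items()},
            "theta": dict(design.theta),
            "dates_true": dict(zip(labels, ys)),
        }
        out.append(
            ReplicateDataset(
                alignments=alignments,
                imap=dict(zip(labels, species)),
                dates=dates,
                truth=truth,
                design=design,
            )
        )
    return out
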