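"""Gene-tree density under the MSC with serially sampled tips.

The density of a gene tree given the species tree is a product over
populations.  Within a population, the distinct sampling times
``ts_1 < ... < ts_E`` split its time interval into ``E + 1`` epochs inside
which no lineages are added and the lineage count can only decrease by
coalescence.  Each coalescence that takes the count from ``j`` to ``j - 1``
after waiting ``t_{i,j}`` contributes ``(2/theta) exp(-j(j-1)/theta t_{i,j})``
and the lineages surviving an epoch contribute the no-coalescence probability
``exp(-n(n-1)/theta * remaining)``.  The root population has no upper
boundary and all remaining lineages coalesce there.

This module is the clear, reference implementation; :mod:`mscdate._kernels`
provides an equivalent fast path used inside the MCMC loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .genetree import GeneTree
from .species import SpeciesTree

__all__ = [
    "EpochPartition",
    "build_epochs",
    "population_log_density",
    "root_population_log_density",
    "gene_tree_log_density",
]


@dataclass
class EpochPartition:
    """Per-population epoch bookkeeping.

    ``sample_times``/``sample_counts`` are the distinct sampling times
    ``ts_1..ts_E`` and multiplicities ``m_i`` (ties merged).  ``n`` holds the
    surviving lineage counts ``n_0..n_E`` (``n_0`` is the number of lineages
    entering at the start boundary: 0 for tip populations, the merged
    survivors of the two daughters otherwise) plus, for non-root populations,
    the count surviving to the end boundary.  ``waiting[i-1]`` lists the
    coalescent waiting times ``t_{i,j}`` of epoch ``i`` in event order
    (``j`` decreasing from the epoch's entering count).
    """

    pop: int
    start: float
    end: Optional[float]  # None for the root population
    sample_times: List[float]
    sample_counts: List[int]
    n: List[int]
    waiting: List[List[float]]

    @property
    def n_epochs(self) -> int:
        return len(self.sample_times) + 1

    def lineages_entering(self, i: int) -> int:
        """Lineages entering epoch i (1-based): n_{i-1} + m_{i-1}."""
        m_prev = 0 if i == 1 else self.sample_counts[i - 2]
        return self.n[i - 1] + m_prev


def build_epochs(pop: int, gene_tree: GeneTree, species_tree: SpeciesTree) -> EpochPartition:
    """Partition population ``pop`` of the species tree into sampling epochs.

    The gene tree must have populations assigned
    (:meth:`GeneTree.assign_populations`).  Tied sampling ages are merged
    into a single epoch boundary with summed multiplicity.
    """
    gt, st = gene_tree, species_tree
    lo = float(st.tau[pop])
    hi = st.parent_tau(pop)
    is_root = pop == st.root

    if np.any(gt.base < 0):
        gt.assign_populations(st)

    # sampling events: tips of this (tip) population
    if st.is_tip(pop):
        ts = np.sort(gt.age[: gt.n_tips][gt.tip_species == pop])
        entering = 0
    else:
        ts = np.asarray([], dtype=float)
        # lineages entering at lo: tips below minus coalescences below lo
        t_count = int(np.sum(st._desc[pop, gt.tip_species]))
        coal_base = gt.base[gt.n_tips :]
        coal_age = gt.age[gt.n_tips :]
        c_count = int(np.sum(st._desc[pop, coal_base] & (coal_age < lo)))
        entering = t_count - c_count

    if len(ts) and (ts[0] < lo or ts[-1] >= hi):
        raise ValueError(
            f"sample age outside population interval [{lo:g}, {hi:g}) "
            f"of {st.labels[pop]}"
        )
    uniq, counts = np.unique(ts, return_counts=True)
    sample_times = [float(t) for t in uniq]
    sample_counts = [int(c) for c in counts]

    coal = np.sort(gt.age[gt.n_tips :][gt.pop[gt.n_tips :] == pop])
    if len(coal) and (coal[0] < lo or (not is_root and coal[-1] >= hi)):
        raise ValueError(
            f"node age outside population interval [{lo:g}, {hi:g}) of {st.labels[pop]}"
        )

    boundaries = [lo] + sample_times + ([] if is_root else [hi])
    n = [entering]
    waiting: List[List[float]] = []
    k = entering
    ci = 0
    for i in range(1, len(boundaries) + (1 if is_root else 0)):
        if i >= 2:
            k += sample_counts[i - 2]
        t_prev = boundaries[i - 1]
        t_end = boundaries[i] if i < len(boundaries) else math.inf
        cursor = t_prev
        w: List[float] = []
        # coalescences in [t_prev, t_end); an event exactly at a sampling
        # time occurs after those samples join (a zero-length waiting time)
        while ci < len(coal) and coal[ci] < t_end:
            if coal[ci] < t_prev:
                raise ValueError("coalescent time before its epoch")
            if k < 2:
                raise ValueError(
                    f"coalescence with {k} lineage(s) in population {st.labels[pop]}"
                )
            w.append(float(coal[ci] - cursor))
            cursor = float(coal[ci])
            k -= 1
            ci += 1
        waiting.append(w)
        n.append(k)
    if is_root:
        if k != 1 and entering + sum(sample_counts) > 0:
            raise ValueError("lineages left uncoalesced in the root population")
        n.pop()  # no surviving count is defined past the open-ended epoch
    return EpochPartition(
        pop=pop,
        start=lo,
        end=None if is_root else float(hi),
        sample_times=sample_times,
        sample_counts=sample_counts,
        n=n,
        waiting=waiting,
    )


def _epoch_terms(part: EpochPartition, theta: float, i: int, t_end: float) -> float:
    """Log contribution of epoch i: coalescences then the survival tail."""
    k = part.lineages_entering(i)
    w = part.waiting[i - 1]
    logp = 0.0
    elapsed = 0.0
    for t in w:
        logp += math.log(2.0 / theta) - (k * (k - 1) / theta) * t
        elapsed += t
        k -= 1
    t_start = part.start if i == 1 else part.sample_times[i - 2]
    logp += -(k * (k - 1) / theta) * (t_end - (t_start + elapsed))
    return logp


def population_log_density(partition: EpochPartition, theta: float) -> float:
    """Log density of the gene tree segment in a non-root population."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if partition.end is None:
        raise ValueError("use root_population_log_density for the root population")
    E = len(partition.sample_times)
    logp = 0.0
    for i in range(1, E + 2):
        t_end = partition.sample_times[i - 1] if i <= E else partition.end
        logp += _epoch_terms(partition, theta, i, t_end)
    return logp


def root_population_log_density(partition: EpochPartition, theta: float) -> float:
    """Log density for the root population, whose final epoch is unbounded."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if partition.end is not None:
        raise ValueError("partition is not for the root population")
    E = len(partition.sample_times)
    logp = 0.0
    for i in range(1, E + 1):
        logp += _epoch_terms(partition, theta, i, partition.sample_times[i - 1])
    # final open-ended epoch: every remaining lineage coalesces
    k = partition.lineages_entering(E + 1)
    w = partition.waiting[E]
    if k != len(w) + 1 and k > 0:
        raise ValueError("lineages left uncoalesced in the root population")
    for t in w:
        logp += math.log(2.0 / theta) - (k * (k - 1) / theta) * t
        k -= 1
    return logp


def gene_tree_log_density(gene_tree: GeneTree, species_tree: SpeciesTree) -> float:
    """Log prior density of a full gene tree: product over populations."""
    gene_tree.assign_populations(species_tree)
    gene_tree.validate(species_tree)
    logp = 0.0
    for pop in range(species_tree.n_nodes):
        part = build_epochs(pop, gene_tree, species_tree)
        theta = float(species_tree.theta[pop])
        if pop == species_tree.root:
            logp += root_population_log_density(part, theta)
        else:
            logp += population_log_density(part, theta)
    return logp
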