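"""Validation toolkit: effective-prior rejection sampling, Bayesian
simulation, and coverage experiments.

Fixed tip dates truncate the user-specified gamma priors on the divergence
times and the substitution rate: the sampler can only visit states with
``ys * mu < tau`` for every dated sample, so the *effective* prior differs
from the nominal one.  The rejection samplers here draw exactly from that
effective prior on four-tip trees and serve as the independent reference
for run-under-the-prior MCMC checks.  Bayesian simulation draws parameters
from the (effective) prior, simulates data, re-infers with the same priors
and checks that the average posterior reproduces the prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetree import GeneTree
from .mcmc import McmcConfig, MscMcmc, PriorSet, Trace
from .simulate import ReplicateDataset, SimulationDesign, replicate_study, sample_genealogy, simulate_alignment
from .species import GammaPrior, SpeciesTree, load_species_tree
from .stats import effective_sample_size, hpd_interval

__all__ = [
    "EffectivePriorSample",
    "rejection_sample_prior",
    "tree_shape_newick",
    "BayesSimReport",
    "bayesian_simulation",
    "coverage_experiment",
    "run_design_replicates",
]

_SHAPES = {
    "symmetric4": "((A,B)AB,(C,D)CD)ABCD;",
    "asymmetric4": "(((A,B)AB,C)ABC,D)ABCD;",
}


def tree_shape_newick(tree_shape: str) -> str:
    if tree_shape not in _SHAPES:
        raise ValueError(f"tree_shape must be one of {sorted(_SHAPES)}")
    return _SHAPES[tree_shape]


@dataclass
class EffectivePriorSample:
    """Accepted draws of (mu, taus) under the date-truncated prior."""

    tree_shape: str
    mu: np.ndarray
    tau: Dict[str, np.ndarray]  # per internal node label, includes the root
    acceptance_rate: float

    @property
    def n(self) -> int:
        return len(self.mu)


def rejection_sample_prior(
    tree_shape: str,
    tip_dates: Dict[str, Sequence[float]],
    priors: PriorSet,
    n: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000_000,
) -> EffectivePriorSample:
    """Sample the effective prior of (mu, taus) for a fixed four-tip tree.

    ``tip_dates`` maps tip species to their sample ages in ybp.  For each
    attempt a rate is drawn from its prior, the root age from its prior and
    the non-root internal ages uniformly on (0, root age) -- rank-ordered on
    the asymmetric shape, independent on the symmetric shape.  A draw is
    rejected if any node is younger than the (rate-scaled) sample dates in a
    daughter population.
    """
    if tree_shape not in _SHAPES:
        raise ValueError(f"tree_shape must be one of {sorted(_SHAPES)}")
    max_age = {sp: (max(ages) if len(np.atleast_1d(ages)) else 0.0)
               for sp, ages in tip_dates.items()}
    for sp in ("A", "B", "C", "D"):
        max_age.setdefault(sp, 0.0)

    batch = max(1024, min(65536, 4 * n))
    kept_mu: List[np.ndarray] = []
    kept_tau: Dict[str, List[np.ndarray]] = {}
    accepted = 0
    attempted = 0
    while accepted < n:
        if attempted >= max_attempts:
            raise RuntimeError(
                "rejection sampler made no progress: priors are incompatible "
                f"with the tip dates (accepted {accepted}/{n} after {attempted} tries)"
            )
        m = min(batch, max_attempts - attempted)
        attempted += m
        mu = priors.mu.sample(rng, m)
        root = priors.tau_root.sample(rng, m)
        u1 = rng.uniform(0.0, root)
        u2 = rng.uniform(0.0, root)
        if tree_shape == "asymmetric4":
            t_ab = np.minimum(u1, u2)
            t_abc = np.maximum(u1, u2)
            ok = (
                (t_ab > mu * max(max_age["A"], max_age["B"]))
                & (t_abc > mu * max_age["C"])
                & (root > mu * max_age["D"])
            )
            tau_draw = {"AB": t_ab, "ABC": t_abc, "ABCD": root}
        else:
            ok = (
                (u1 > mu * max(max_age["A"], max_age["B"]))
                & (u2 > mu * max(max_age["C"], max_age["D"]))
            )
            tau_draw = {"AB": u1, "CD": u2, "ABCD": root}
        kept_mu.append(mu[ok])
        for k, v in tau_draw.items():
            kept_tau.setdefault(k, []).append(v[ok])
        accepted += int(ok.sum())

    mu_all = np.concatenate(kept_mu)[:n]
    tau_all = {k: np.concatenate(v)[:n] for k, v in kept_tau.items()}
    return EffectivePriorSample(
        tree_shape=tree_shape,
        mu=mu_all,
        tau=tau_all,
        acceptance_rate=accepted / attempted,
    )


# ---------------------------------------------------------------------------
# Bayesian simulation (average posterior == prior)
# ---------------------------------------------------------------------------


@dataclass
class BayesSimReport:
    """Pooled posteriors from replicate analyses plus prior references.

    ``posteriors[param]`` has one row of posterior draws per converged
    replicate; ``references[param]`` is a large sample (or exact quantile
    function) from the prior / effective prior.
    """

    posteriors: Dict[str, np.ndarray]
    references: Dict[str, np.ndarray]
    n_replicates: int
    n_excluded: int

    def pooled(self, param: str) -> np.ndarray:
        return self.posteriors[param].ravel()

    def qq_table(
        self,
        param: str,
        n_percentiles: int = 99,
        n_boot: int = 400,
        level: float = 0.999,
        rng: Optional[np.random.Generator] = None,
    ) -> pd.DataFrame:
        """Pooled-posterior vs prior quantiles with a replicate bootstrap band."""
        rng = rng or np.random.default_rng(0)
        qs = np.arange(1, n_percentiles + 1) / (n_percentiles + 1) * 100.0
        draws = self.posteriors[param]
        ref_q = np.percentile(self.references[param], qs)
        pooled_q = np.percentile(draws.ravel(), qs)
        R = draws.shape[0]
        boot = np.empty((n_boot, len(qs)))
        for b in range(n_boot):
            idx = rng.integers(0, R, size=R)
            boot[b] = np.percentile(draws[idx].ravel(), qs)
        a = (1.0 - level) / 2.0
        lo = np.quantile(boot, a, axis=0)
        hi = np.quantile(boot, 1.0 - a, axis=0)
        return pd.DataFrame(
            {
                "percentile": qs,
                "posterior_q": pooled_q,
                "prior_q": ref_q,
                "band_lo": lo,
                "band_hi": hi,
                "within": (ref_q >= lo) & (ref_q <= hi),
            }
        )

    def fraction_within(self, param: str, **kw) -> float:
        t = self.qq_table(param, **kw)
        return float(t["within"].mean())


def bayesian_simulation(
    R: int,
    rng: np.random.Generator,
    n_loci: int = 100,
    length: int = 1000,
    n_per_species: int = 5,
    age_range: Tuple[float, float] = (0.0, 50_000.0),
    priors: Optional[PriorSet] = None,
    mcmc: Optional[McmcConfig] = None,
    ess_min: float = 40.0,
    n_reference: int = 200_000,
) -> BayesSimReport:
    """Draw parameters from the (effective) prior, simulate, re-infer, pool.

    Uses the four-tip symmetric tree with ``n_per_species`` sequences per
    species and sample ages drawn once from U(age_range) and shared by all
    replicates.  Replicates whose chains fail the ESS threshold on mu and
    the root age are excluded from the pooled posterior.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    priors = priors or PriorSet(
        tau_root=GammaPrior(10.0, 100.0),
        mu=GammaPrior(10.0, 1e8),
        theta=GammaPrior(8.0, 2000.0),
    )
    mcmc = mcmc or McmcConfig(burnin=500, nsample=500, sampfreq=2, ages_per_locus=3)
    newick = _SHAPES["symmetric4"]
    species = ("A", "B", "C", "D")
    pops = ("A", "B", "C", "D", "AB", "CD", "ABCD")

    ages = {sp: rng.uniform(age_range[0], age_range[1], size=n_per_species)
            for sp in species}
    labels, sp_of, ys = [], {}, {}
    for sp in species:
        for i in range(n_per_species):
            lab = f"{sp}{i + 1}"
            labels.append(lab)
            sp_of[lab] = sp
            ys[lab] = float(ages[sp][i])

    reference = rejection_sample_prior(
        "symmetric4", {sp: ages[sp] for sp in species}, priors, n_reference, rng
    )

    params = ["mu", "tau_ABCD", "tau_AB", "tau_CD"] + [f"theta_{p}" for p in pops]
    post: Dict[str, List[np.ndarray]] = {k: [] for k in params}
    n_excluded = 0
    for _r in range(R):
        draw = rejection_sample_prior(
            "symmetric4", {sp: ages[sp] for sp in species}, priors, 1, rng
        )
        mu = float(draw.mu[0])
        tau = {k: float(v[0]) for k, v in draw.tau.items()}
        theta = {p: float(priors.theta.sample(rng)) for p in pops}
        stree = load_species_tree(newick, theta, tau)
        sp_idx = np.asarray([stree.index[sp_of[lab]] for lab in labels])
        ts = np.asarray([ys[lab] for lab in labels]) * mu
        alns = []
        for _l in range(n_loci):
            gt = sample_genealogy(stree, sp_idx, ts, rng, labels)
            alns.append(simulate_alignment(gt, length, rng))
        seed = int(rng.integers(2**31))
        import dataclasses

        cfg_r = dataclasses.replace(mcmc, mu_init=mu)
        engine = MscMcmc(stree, alns, sp_of, ys, priors, cfg_r, np.random.default_rng(seed))
        trace = engine.run()
        if (
            effective_sample_size(trace["mu"]) < ess_min
            or effective_sample_size(trace["tau_ABCD"]) < ess_min
        ):
            n_excluded += 1
            continue
        for k in params:
            post[k].append(trace[k])

    posteriors = {k: np.asarray(v) for k, v in post.items() if v}
    references: Dict[str, np.ndarray] = {
        "mu": reference.mu,
        "tau_ABCD": reference.tau["ABCD"],
        "tau_AB": reference.tau["AB"],
        "tau_CD": reference.tau["CD"],
    }
    theta_ref = priors.theta.sample(rng, n_reference)
    for p in pops:
        references[f"theta_{p}"] = theta_ref
    return BayesSimReport(
        posteriors=posteriors,
        references=references,
        n_replicates=len(next(iter(posteriors.values()))),
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# coverage experiments
# ---------------------------------------------------------------------------


def run_design_replicates(
    design: SimulationDesign,
    reps: int,
    rng: np.random.Generator,
    mcmc: Optional[McmcConfig] = None,
) -> List[Tuple[ReplicateDataset, Trace]]:
    """Simulate ``reps`` datasets under a design and analyze each by MCMC."""
    mcmc = mcmc or McmcConfig(burnin=500, nsample=750, sampfreq=2, ages_per_locus=3)
    priors = PriorSet.from_dict(design.priors)
    datasets = replicate_study(design, reps, rng)
    out = []
    for ds in datasets:
        stree = design.species_tree()
        seed = int(rng.integers(2**31))
        engine = MscMcmc(
            stree, ds.alignments, ds.imap, ds.dates, priors, mcmc,
            np.random.default_rng(seed),
        )
        out.append((ds, engine.run()))
    return out


def coverage_experiment(
    design_name,
    reps: int,
    rng: np.random.Generator,
    mcmc: Optional[McmcConfig] = None,
    **design_overrides,
) -> pd.DataFrame:
    """95% HPD coverage of the true parameters across replicate analyses.

    Returns one row per parameter (divergence times in years and in
    substitutions, the mutation rate, the population sizes) with the
    coverage fraction and the mean posterior mean.
    """
    from .simulate import get_design

    design = (
        design_name
        if isinstance(design_name, SimulationDesign)
        else get_design(design_name, **design_overrides)
    )
    results = run_design_replicates(design, reps, rng, mcmc)

    rows = []
    params: Dict[str, float] = {}
    first_trace = results[0][1]
    truth = results[0][0].truth
    for node, ty in truth["tau_years"].items():
        if f"tau_years_{node}" in first_trace.columns:
            params[f"tau_years_{node}"] = float(ty)
        if f"tau_{node}" in first_trace.columns:
            params[f"tau_{node}"] = float(truth["tau"][node])
    params["mu"] = float(truth["mu"])
    for pop, th in truth["theta"].items():
        if f"theta_{pop}" in first_trace.columns:
            params[f"theta_{pop}"] = float(th)

    for name, true_val in params.items():
        hits = 0
        means = []
        for _ds, trace in results:
            lo, hi = hpd_interval(trace[name], 0.95)
            if lo <= true_val <= hi:
                hits += 1
            means.append(float(np.mean(trace[name])))
        rows.append(
            {
                "parameter": name,
                "truth": true_val,
                "coverage": hits / len(results),
                "n": len(results),
                "mean_posterior_mean": float(np.mean(means)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
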