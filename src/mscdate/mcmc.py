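"""Metropolis-Hastings sampler for the MSC with dated tips.

The sampler targets the joint posterior of the substitution rate ``mu``, the
species divergence times ``tau``, the population sizes ``theta`` and the
per-locus gene trees, proportional to

    f(G | tau, theta) * P(X | G) * f(mu) f(tau) f(theta)

All times are kept in expected substitutions/site; sample ages in years are
fixed and enter through ``ts = ys * mu``.  Because the tip ages move with
``mu``, the rate move jointly rescales tip ages and the coalescent times
inside dated tip populations, with the Hastings factor
``c * prod_i (tau - b_i*) / (tau - b_i)`` where ``b_i`` is the age of the
oldest sample below node ``i``.  The classical mixing move (scale all times,
divide the rate) is incompatible with fixed calendar tip dates and is not
used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .genetree import GeneTree
from .likelihood import LocusAlignment, compress_patterns, tip_partials
from .simulate import sample_genealogy
from .species import GammaPrior, SpeciesTree
from .stats import bactrian_laplace, effective_sample_size, hpd_interval, reflect

__all__ = ["PriorSet", "McmcConfig", "Trace", "MscMcmc", "run_mcmc"]


@dataclass(frozen=True)
class PriorSet:
    """Gamma priors for the root age, substitution rate and population sizes.

    Non-root divergence times are i.i.d. uniform on (0, tau_root) subject to
    the topology's ordering constraints.
    """

    tau_root: GammaPrior
    mu: GammaPrior
    theta: GammaPrior

    @classmethod
    def from_dict(cls, d) -> "PriorSet":
        return cls(tau_root=d["tau_root"], mu=d["mu"], theta=d["theta"])


@dataclass
class McmcConfig:
    burnin: int = 2000
    nsample: int = 2000
    sampfreq: int = 2
    usedata: bool = True
    bactrian_m: float = 0.95
    mu_min: float = 1e-13
    mu_ceiling: Optional[float] = None  # default: 1e4 x prior mean
    tau_ceiling: Optional[float] = None  # default: 10 x root-age prior mean
    age_ceiling: Optional[float] = None  # default: 100 x tau ceiling
    tune_target: float = 0.30
    tune_interval: int = 100
    spr_per_locus: int = 1
    ages_per_locus: Optional[int] = None  # None = all internal nodes
    mu_repeats: int = 1
    tau_repeats: int = 1
    theta_repeats: int = 1
    mu_init: Optional[float] = None  # default: the prior mean
    check_every: int = 0  # if > 0, verify caches every k iterations
    eps: Optional[Dict[str, float]] = None


@dataclass
class Trace:
    """Posterior samples: one row per recorded iteration."""

    columns: Dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    @property
    def names(self) -> List[str]:
        return list(self.columns)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.columns.values())))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.columns)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, x in self.columns.items():
            lo, hi = hpd_interval(x, 0.95)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(np.mean(x)),
                    "median": float(np.median(x)),
                    "hpd2.5": lo,
                    "hpd97.5": hi,
                    "ess": effective_sample_size(x),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


class _Locus:
    __slots__ = (
        "labels", "tip_species", "ys", "tip_part", "weights", "site_out",
        "anchor_ys", "anchor_off", "part", "saved", "saved_idx", "cache_ok",
        "age_buf",
    )

    def __init__(self, labels, tip_species, ys, tip_part, weights):
        self.labels = labels
        self.tip_species = tip_species
        self.ys = ys
        self.tip_part = tip_part
        self.weights = weights
        self.site_out = np.empty(tip_part.shape[2])
        # shared conditional-likelihood cache, built lazily
        n_tips = tip_part.shape[0]
        n_nodes = 2 * n_tips - 1
        P = tip_part.shape[2]
        self.part = np.empty((n_nodes, 4, P))
        self.saved = np.empty((max(n_tips - 1, 1), 4, P))
        self.saved_idx = np.empty(max(n_tips - 1, 1), dtype=np.int64)
        self.cache_ok = False
        self.age_buf = np.empty(n_nodes)


class MscMcmc:
    """MCMC sampler over (mu, tau, theta, gene trees) for fixed data.

    Parameters
    ----------
    stree:
        Species tree fixing the topology; its tau/theta values, when
        positive, seed the initial state.
    alignments:
        One :class:`LocusAlignment` per locus.
    imap:
        sequence label -> species label.
    dates:
        sequence label -> age in years before present (missing = 0).
    """

    MOVE_CLASSES = ("mu", "muaux", "tau", "theta", "thetascale", "spr", "age")

    def __init__(
        self,
        stree: SpeciesTree,
        alignments: Sequence[LocusAlignment],
        imap: Dict[str, str],
        dates: Dict[str, float],
        priors: PriorSet,
        config: Optional[McmcConfig] = None,
        rng=None,
    ):
        self.cfg = config or McmcConfig()
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.priors = priors
        self.stree = stree.copy()
        st = self.stree
        self.n_pops = st.n_nodes
        self.internals = [int(i) for i in st.postorder if not st.is_tip(int(i))]
        self.sp_parent = st.parent
        self.sp_is_tip = np.asarray([st.is_tip(i) for i in range(st.n_nodes)])
        self.desc = st._desc
        if not alignments:
            raise ValueError("at least one locus is required")

        self.loci: List[_Locus] = []
        self.max_ys = np.zeros(self.n_pops)
        for aln in alignments:
            sp_idx = []
            ys = []
            for lab in aln.labels:
                if lab not in imap:
                    raise ValueError(f"sequence {lab!r} missing from the species map")
                sp = imap[lab]
                if sp not in st.index:
                    raise ValueError(f"unknown species {sp!r} for sequence {lab!r}")
                p = st.index[sp]
                if not st.is_tip(p):
                    raise ValueError(f"sequence {lab!r} assigned to ancestral population")
                sp_idx.append(p)
                y = float(dates.get(lab, 0.0))
                if y < 0 or not math.isfinite(y):
                    raise ValueError(f"invalid age for {lab!r}")
                ys.append(y)
                self.max_ys[p] = max(self.max_ys[p], y)
            pats, weights, _ = compress_patterns(aln.codes)
            self.loci.append(
                _Locus(
                    list(aln.labels),
                    np.asarray(sp_idx, dtype=np.int64),
                    np.asarray(ys, dtype=np.float64),
                    tip_partials(pats),
                    weights,
                )
            )
        self.dated_pop = self.max_ys > 0.0
        self.any_dated = bool(np.any(self.dated_pop))
        # per-locus sample-age anchors per population (for the stretch move)
        for loc in self.loci:
            anchors = []
            off = [0]
            for p in range(self.n_pops):
                vals = np.unique(loc.ys[loc.tip_species == p]) if self.dated_pop[p] else np.asarray([])
                anchors.extend(float(v) for v in vals if v > 0)
                off.append(len(anchors))
            loc.anchor_ys = np.asarray(anchors, dtype=np.float64)
            loc.anchor_off = np.asarray(off, dtype=np.int64)

        cfg = self.cfg
        self.mu_ceiling = cfg.mu_ceiling or priors.mu.mean * 1e4
        self.tau_ceiling = cfg.tau_ceiling or 10.0 * priors.tau_root.mean
        self.age_ceiling = cfg.age_ceiling or 100.0 * self.tau_ceiling

        self.eps = {
            "mu": 0.4,
            "muaux": 0.4,
            "theta": 0.6,
            "thetascale": 0.5,
            "spr": 0.3 * priors.tau_root.mean,
            "age": 0.2 * priors.tau_root.mean,
        }
        # divergence times and population sizes get per-node/per-population
        # tuned step sizes: their scales can differ by orders of magnitude
        for p in self.internals:
            self.eps[f"tau_{p}"] = 0.15 * priors.tau_root.mean
        for p in range(self.n_pops):
            self.eps[f"theta_{p}"] = 0.6
            self.eps[f"thetascale_{p}"] = 0.5
        if cfg.eps:
            for k, v in cfg.eps.items():
                if k == "tau":
                    for p in self.internals:
                        self.eps[f"tau_{p}"] = v
                elif k in ("theta", "thetascale"):
                    for p in range(self.n_pops):
                        self.eps[f"{k}_{p}"] = v
                    self.eps[k] = v
                else:
                    self.eps[k] = v
        self.acc_n = {k: 0 for k in self.eps}
        self.try_n = {k: 0 for k in self.eps}

        self._init_params()
        self._init_gene_trees()
        self.dens = np.zeros((len(self.loci), self.n_pops))
        self.lik = np.zeros(len(self.loci))
        self._last_cnt = np.zeros(len(self.loci), dtype=np.int64)
        self._full_recompute()

    # ------------------------------------------------------------------
    # initialization
    # ------------------------------------------------------------------

    def _init_params(self):
        st = self.stree
        pr = self.priors
        self.theta = np.full(self.n_pops, pr.theta.mean)
        for p in range(self.n_pops):
            if st.theta[p] > 0:
                self.theta[p] = float(st.theta[p])
        have_tau = all(st.tau[p] > 0 for p in self.internals)
        if not have_tau:
            level = np.zeros(self.n_pops, dtype=int)
            for p in st.postorder:
                p = int(p)
                if not st.is_tip(p):
                    level[p] = 1 + max(level[c] for c in st.children[p])
            root_level = level[st.root]
            for p in self.internals:
                st.tau[p] = pr.tau_root.mean * level[p] / root_level
        self.mu = self.cfg.mu_init if self.cfg.mu_init else pr.mu.mean
        bound = self.mu_upper_bound()
        if self.mu >= bound:
            self.mu = 0.5 * bound
        self.mu = max(self.mu, self.cfg.mu_min)

    def _init_gene_trees(self):
        st = self.stree
        init_tree = st.copy()
        init_tree.theta[:] = self.theta
        self.gtrees: List[GeneTree] = []
        for loc in self.loci:
            gt = sample_genealogy(
                init_tree, loc.tip_species, loc.ys * self.mu, self.rng, loc.labels
            )
            self.gtrees.append(gt)

    # ------------------------------------------------------------------
    # cached targets
    # ------------------------------------------------------------------

    def _density_vec(self, gt: GeneTree, pops: np.ndarray, out: np.ndarray) -> bool:
        return _kernels.msc_log_density_pops(
            gt.n_tips,
            gt.age,
            gt.base,
            gt.tip_species,
            self.sp_parent,
            self.stree.tau,
            self.theta,
            self.sp_is_tip,
            self.desc,
            self.stree.root,
            pops,
            out,
        )

    def _locus_loglik(self, l: int, gt: GeneTree):
        if not self.cfg.usedata:
            return True, 0.0
        loc = self.loci[l]
        return _kernels.locus_log_likelihood(
            gt.n_tips, gt.left, gt.right, gt.age, gt.root, loc.tip_part,
            loc.weights, loc.site_out,
        )

    def _ensure_cache(self, l: int):
        """Build the locus's partial-likelihood cache if it is stale."""
        loc = self.loci[l]
        if loc.cache_ok:
            return
        gt = self.gtrees[l]
        lik = _kernels.full_partials_loglik(
            gt.n_tips, gt.left, gt.right, gt.age, gt.root, loc.tip_part,
            loc.weights, loc.part,
        )
        if math.isnan(lik):
            raise RuntimeError(f"zero likelihood at locus {l}")
        loc.cache_ok = True
        self.lik[l] = lik

    def _path_eval(self, l: int, gt, age_new, changed):
        """Proposed-likelihood evaluation via path update of the cache.

        Leaves the cache reflecting ``age_new``; the caller must either keep
        the proposal or call :meth:`_path_restore`.  Returns the proposed
        log likelihood (or None for an invalid state).
        """
        loc = self.loci[l]
        self._ensure_cache(l)
        saved_age = gt.age
        gt.age = age_new
        cnt, lik = _kernels.path_update_loglik(
            gt.n_tips, gt.left, gt.right, gt.parent, gt.age, gt.root,
            loc.weights, loc.part, changed, len(changed), loc.saved, loc.saved_idx,
        )
        gt.age = saved_age
        self._last_cnt[l] = cnt
        if math.isnan(lik):
            self._path_restore(l)
            return None
        return float(lik)

    def _path_restore(self, l: int):
        loc = self.loci[l]
        _kernels.restore_partial_rows(loc.part, loc.saved, loc.saved_idx, self._last_cnt[l])

    def _full_recompute(self):
        self._all_pops = np.arange(self.n_pops, dtype=np.int64)
        for l, gt in enumerate(self.gtrees):
            gt.assign_populations(self.stree)
            self.loci[l].cache_ok = False
            out = np.zeros(self.n_pops)
            if not self._density_vec(gt, self._all_pops, out):
                raise RuntimeError(f"invalid initial gene tree at locus {l}")
            self.dens[l] = out
            ok, lik = self._locus_loglik(l, gt)
            if not ok:
                raise RuntimeError(f"invalid likelihood at locus {l}")
            self.lik[l] = lik

    def log_prior_params(self) -> float:
        pr = self.priors
        st = self.stree
        lp = pr.mu.logpdf(self.mu) + pr.tau_root.logpdf(float(st.tau[st.root]))
        n_extra = len(self.internals) - 1
        if n_extra > 0:
            lp += n_extra * (-math.log(float(st.tau[st.root])))
        for p in range(self.n_pops):
            lp += pr.theta.logpdf(float(self.theta[p]))
        return lp

    def log_posterior(self) -> float:
        return float(self.dens.sum() + self.lik.sum() + self.log_prior_params())

    def _verify_caches(self, tol: float = 1e-6):
        dens_old = self.dens.copy()
        lik_old = self.lik.copy()
        pops_old = [gt.pop.copy() for gt in self.gtrees]
        self._full_recompute()
        if not np.allclose(dens_old, self.dens, rtol=tol, atol=tol):
            raise AssertionError("cached gene-tree densities drifted")
        if not np.allclose(lik_old, self.lik, rtol=tol, atol=tol):
            raise AssertionError("cached likelihoods drifted")
        for old, gt in zip(pops_old, self.gtrees):
            if not np.array_equal(old, gt.pop):
                raise AssertionError("cached population assignments drifted")
            gt.validate(self.stree)

    # ------------------------------------------------------------------
    # proposals
    # ------------------------------------------------------------------

    def mu_upper_bound(self) -> float:
        """min over dated tip populations of tau_parent / oldest sample age."""
        bound = self.mu_ceiling
        for p in np.flatnonzero(self.max_ys > 0):
            bound = min(bound, self.stree.parent_tau(int(p)) / self.max_ys[p])
        return bound

    def propose_mu(self) -> bool:
        self.try_n["mu"] += 1
        cfg = self.cfg
        ub = self.mu_upper_bound()
        lb = cfg.mu_min
        x = float(bactrian_laplace(self.rng, cfg.bactrian_m))
        y = reflect(math.log(self.mu) + self.eps["mu"] * x, math.log(lb), math.log(ub))
        mu_new = math.exp(y)
        c = mu_new / self.mu
        logc = math.log(c)
        delta = self.priors.mu.logpdf(mu_new) - self.priors.mu.logpdf(self.mu)

        if not self.any_dated:
            if math.log(self.rng.random()) < delta + logc:
                self.mu = mu_new
                self.acc_n["mu"] += 1
                return True
            return False

        dated_idx = np.flatnonzero(self.dated_pop).astype(np.int64)
        logj_total = 0.0
        new_ages = []
        new_rows = []
        new_liks = []
        for l, gt in enumerate(self.gtrees):
            loc = self.loci[l]
            age_new = np.empty_like(gt.age)
            ok, logj = _kernels.mu_rescale_ages(
                gt.n_tips, gt.parent, gt.age, age_new, gt.pop, loc.ys, mu_new, c,
                self.dated_pop, self.sp_parent, self.stree.tau,
            )
            if not ok:
                return False
            logj_total += logj
            out = self.dens[l].copy()
            gt_age_saved = gt.age
            gt.age = age_new  # temporarily view proposed ages
            okd = self._density_vec(gt, dated_idx, out)
            if okd:
                okl, lik_new = self._locus_loglik(l, gt)
            gt.age = gt_age_saved
            if not okd or not okl:
                return False
            delta += float(out[dated_idx].sum() - self.dens[l][dated_idx].sum())
            delta += lik_new - self.lik[l]
            new_ages.append(age_new)
            new_rows.append(out)
            new_liks.append(lik_new)

        log_alpha = delta + logc + logj_total
        if math.log(self.rng.random()) < log_alpha:
            self.mu = mu_new
            for l, gt in enumerate(self.gtrees):
                gt.age[:] = new_ages[l]
                self.dens[l] = new_rows[l]
                self.lik[l] = new_liks[l]
                self.loci[l].cache_ok = False
            self.acc_n["mu"] += 1
            return True
        return False

    def propose_mu_aux(self) -> bool:
        """Auxiliary rate move with a monotone stretch of dated-population ages.

        Complements :meth:`propose_mu`: the published rescale keeps each
        node's position relative to its oldest descendant sample, but with
        many loci some pair of nested nodes inverts for all but tiny rate
        changes, trapping the rate in a micro-step random walk.  This move
        instead maps each dated population's interval (0, tau) onto itself
        piecewise-linearly with the sample ages as anchors, which preserves
        order by construction; the Hastings factor is c times the product
        of segment slopes (the map's Jacobian).
        """
        if not self.any_dated:
            return False
        self.try_n["muaux"] += 1
        cfg = self.cfg
        ub = self.mu_upper_bound()
        lb = cfg.mu_min
        x = float(bactrian_laplace(self.rng, cfg.bactrian_m))
        y = reflect(math.log(self.mu) + self.eps["muaux"] * x, math.log(lb), math.log(ub))
        mu_new = math.exp(y)
        logc = y - math.log(self.mu)
        delta = self.priors.mu.logpdf(mu_new) - self.priors.mu.logpdf(self.mu)
        dated_idx = np.flatnonzero(self.dated_pop).astype(np.int64)
        logj_total = 0.0
        new_ages = []
        new_rows = []
        new_liks = []
        for l, gt in enumerate(self.gtrees):
            loc = self.loci[l]
            age_new = np.empty_like(gt.age)
            logj = _kernels.mu_stretch_ages(
                gt.n_tips, gt.age, age_new, gt.pop, loc.ys, self.mu, mu_new,
                self.dated_pop, self.sp_parent, self.stree.tau,
                loc.anchor_ys, loc.anchor_off,
            )
            logj_total += logj
            saved = gt.age
            gt.age = age_new
            out = self.dens[l].copy()
            okd = self._density_vec(gt, dated_idx, out)
            okl, lik_new = self._locus_loglik(l, gt) if okd else (False, 0.0)
            gt.age = saved
            if not (okd and okl):
                return False
            delta += float(out[dated_idx].sum() - self.dens[l][dated_idx].sum())
            delta += lik_new - self.lik[l]
            new_ages.append(age_new)
            new_rows.append(out)
            new_liks.append(lik_new)
        if math.log(self.rng.random()) < delta + logc + logj_total:
            self.mu = mu_new
            for l, gt in enumerate(self.gtrees):
                gt.age[:] = new_ages[l]
                self.dens[l] = new_rows[l]
                self.lik[l] = new_liks[l]
                self.loci[l].cache_ok = False
            self.acc_n["muaux"] += 1
            return True
        return False

    def propose_tau(self, p: int) -> bool:
        """Divergence-time move with rubber-band rescaling of gene node ages.

        The window proposal reflects tau_p into (L, U) where L is the oldest
        of the daughter divergence times and the daughter populations' sample
        ages (in substitutions) and U is the parent divergence time (a large
        ceiling for the root).  Gene-tree nodes in the two daughter
        populations with ages in (L, tau_old) are rescaled into (L, tau*);
        nodes in population p are rescaled into (tau*, U) -- for the root
        they are translated by tau* - tau_old.  Ages never cross the moving
        boundary, so population assignments are unchanged and the move is
        reversible with Jacobian rb^n_below * ra^n_above.
        """
        key = f"tau_{p}"
        self.try_n[key] += 1
        st = self.stree
        is_root = p == st.root
        L = 0.0
        for ch in st.children[p]:
            L = max(L, float(st.tau[ch]), self.max_ys[ch] * self.mu)
        U = self.tau_ceiling if is_root else float(st.tau[st.parent[p]])
        if U <= L:
            return False
        t_old = float(st.tau[p])
        x = float(bactrian_laplace(self.rng, self.cfg.bactrian_m))
        t_new = reflect(t_old + self.eps[key] * x, L, U)
        if t_new == t_old:
            return False
        rb = (t_new - L) / (t_old - L)
        ra = 1.0 if is_root else (U - t_new) / (U - t_old)
        children = st.children[p]
        pops_aff = np.asarray([p, *children], dtype=np.int64)

        n_below = 0
        n_above = 0
        new_ages = []
        changed = []
        for gt in self.gtrees:
            age_new = np.empty_like(gt.age)
            ok, nb, na = _kernels.tau_rubber_ages(
                gt.n_tips, gt.parent, gt.age, age_new, gt.pop,
                children[0], children[1], p, L, U, t_old, t_new, is_root,
            )
            if not ok:
                return False
            n_below += nb
            n_above += na
            changed.append(bool(nb or na))
            new_ages.append(age_new)

        st.tau[p] = t_new
        delta = n_below * math.log(rb) + (0.0 if is_root else n_above * math.log(ra))
        new_rows = []
        new_liks = []
        evaluated = []
        for l, gt in enumerate(self.gtrees):
            saved = gt.age
            gt.age = new_ages[l]
            out = self.dens[l].copy()
            okd = self._density_vec(gt, pops_aff, out)
            gt.age = saved
            lik_new = self.lik[l]
            if okd and self.cfg.usedata and changed[l]:
                moved = np.flatnonzero(new_ages[l] != gt.age).astype(np.int64)
                lik_new = self._path_eval(l, gt, new_ages[l], moved)
                if lik_new is not None:
                    evaluated.append(l)
            if not okd or lik_new is None:
                st.tau[p] = t_old
                for j in evaluated:
                    self._path_restore(j)
                return False
            delta += float(out[pops_aff].sum() - self.dens[l][pops_aff].sum())
            delta += lik_new - self.lik[l]
            new_rows.append(out)
            new_liks.append(lik_new)
        if is_root:
            pr = self.priors.tau_root
            delta += pr.logpdf(t_new) - pr.logpdf(t_old)
            n_extra = len(self.internals) - 1
            if n_extra > 0:
                delta += n_extra * (math.log(t_old) - math.log(t_new))
        if math.log(self.rng.random()) < delta:
            for l, gt in enumerate(self.gtrees):
                gt.age[:] = new_ages[l]
                self.dens[l] = new_rows[l]
                self.lik[l] = new_liks[l]
            self.acc_n[key] += 1
            return True
        st.tau[p] = t_old
        for j in evaluated:
            self._path_restore(j)
        return False

    def propose_theta(self, p: int) -> bool:
        key = f"theta_{p}"
        self.try_n[key] += 1
        x = float(bactrian_laplace(self.rng, self.cfg.bactrian_m))
        y_old = math.log(float(self.theta[p]))
        y = reflect(y_old + self.eps[key] * x, math.log(1e-10), math.inf)
        th_new = math.exp(y)
        th_old = float(self.theta[p])
        self.theta[p] = th_new
        pops_aff = np.asarray([p], dtype=np.int64)
        delta = self.priors.theta.logpdf(th_new) - self.priors.theta.logpdf(th_old)
        delta += y - y_old  # Jacobian of the log-scale walk
        new_rows = []
        for l, gt in enumerate(self.gtrees):
            out = self.dens[l].copy()
            if not self._density_vec(gt, pops_aff, out):
                self.theta[p] = th_old
                return False
            delta += float(out[p] - self.dens[l][p])
            new_rows.append(out)
        if math.log(self.rng.random()) < delta:
            for l in range(len(self.gtrees)):
                self.dens[l] = new_rows[l]
            self.acc_n[key] += 1
            return True
        self.theta[p] = th_old
        return False

    def propose_theta_scale(self, p: int) -> bool:
        """Joint move on (theta_p, coalescent times inside population p).

        A plain theta update mixes poorly because theta's conditional given
        the gene trees is tight; scaling the within-population waiting times
        together with theta walks along the (theta, times) ridge.  The age
        map is t -> lo + c (t - lo) for nodes in population p (lo is the
        population's start time), with Jacobian c^n; rejected if a scaled
        age reaches the population's end boundary or inverts an unscaled
        neighbour.
        """
        key = f"thetascale_{p}"
        self.try_n[key] += 1
        st = self.stree
        # anchor at the population's oldest sample age: nodes below it stay
        # put, so fixed tips can never be crossed by the scaling
        lo = max(float(st.tau[p]), float(self.max_ys[p]) * self.mu)
        hi = st.parent_tau(p)
        x = float(bactrian_laplace(self.rng, self.cfg.bactrian_m))
        y_old = math.log(float(self.theta[p]))
        y = reflect(y_old + self.eps[key] * x, math.log(1e-10), math.inf)
        c = math.exp(y - y_old)
        th_new = math.exp(y)
        th_old = float(self.theta[p])
        theta_prop = self.theta.copy()
        theta_prop[p] = th_new
        n_scaled = 0
        delta = self.priors.theta.logpdf(th_new) - self.priors.theta.logpdf(th_old)
        new_liks = []
        new_dens_p = []
        evaluated = []
        usedata = self.cfg.usedata
        ok_all = True
        for l, gt in enumerate(self.gtrees):
            loc = self.loci[l]
            if usedata:
                self._ensure_cache(l)
            ok, ns, cnt, lik_new, dens_p = _kernels.theta_scale_eval(
                gt.n_tips, gt.left, gt.right, gt.parent, gt.age, loc.age_buf,
                gt.base, gt.pop, gt.root, gt.tip_species, self.sp_parent,
                self.stree.tau, theta_prop, self.sp_is_tip, self.desc,
                self.stree.root, p, lo, hi, c, usedata, loc.weights,
                loc.part, loc.saved, loc.saved_idx,
            )
            if not ok:
                ok_all = False
                break
            if usedata and ns > 0:
                self._last_cnt[l] = cnt
                evaluated.append(l)
            else:
                lik_new = self.lik[l]
            n_scaled += ns
            delta += float(dens_p - self.dens[l][p]) + lik_new - self.lik[l]
            new_liks.append(lik_new)
            new_dens_p.append(float(dens_p))
        if ok_all:
            delta += (n_scaled + 1) * (y - y_old)  # age-map Jacobian + log-walk
            if math.log(self.rng.random()) < delta:
                self.theta[p] = th_new
                for l, gt in enumerate(self.gtrees):
                    gt.age[:] = self.loci[l].age_buf
                    self.dens[l][p] = new_dens_p[l]
                    self.lik[l] = new_liks[l]
                self.acc_n[key] += 1
                return True
        for j in evaluated:
            self._path_restore(j)
        return False

    def gibbs_theta(self, p: int) -> None:
        """Exact Gibbs update of theta_p from its full conditional.

        theta enters only the coalescent density: with a Gamma(a, b) prior
        and per-population statistics (n_coal, S = sum k(k-1) dt), the full
        conditional is proportional to theta^(a - n_coal - 1)
        exp(-b theta - S/theta), a generalized inverse Gaussian, sampled
        directly (plain gamma when the population holds no lineage pairs).
        Node ages are untouched, so the likelihood is unchanged.
        """
        st = self.stree
        nc_tot = 0
        S_tot = 0.0
        stats = []
        for gt in self.gtrees:
            nc, S = _kernels.msc_suffstats_pop(
                gt.n_tips, gt.age, gt.base, gt.tip_species, self.sp_parent,
                st.tau, self.sp_is_tip, self.desc, st.root, p,
            )
            stats.append((nc, S))
            nc_tot += nc
            S_tot += S
        a = self.priors.theta.shape
        b = self.priors.theta.rate
        if S_tot <= 0.0:
            if nc_tot == 0:
                th_new = float(self.rng.gamma(a, 1.0 / b))
            else:  # coalescences with zero elapsed time: degenerate, skip
                return
        else:
            from scipy.stats import geninvgauss

            pgig = a - nc_tot
            bgig = 2.0 * math.sqrt(S_tot * b)
            scale = math.sqrt(S_tot / b)
            th_new = float(
                geninvgauss.rvs(pgig, bgig, scale=scale, random_state=self.rng)
            )
        if not (th_new > 0.0 and math.isfinite(th_new)):
            return
        self.theta[p] = th_new
        log_half_theta = math.log(2.0 / th_new)
        for l, (nc, S) in enumerate(stats):
            self.dens[l][p] = nc * log_half_theta - S / th_new

    def _update_base_path(self, gt: GeneTree, v: int):
        st = self.stree
        while v >= 0:
            if v >= gt.n_tips:
                gt.base[v] = st.mrca(int(gt.base[gt.left[v]]), int(gt.base[gt.right[v]]))
            gt.pop[v] = st.pop_at(int(gt.base[v]), float(gt.age[v]))
            v = int(gt.parent[v])

    def _spr_detach(self, gt: GeneTree, u: int):
        """Prune the subtree rooted at u from a working copy of the tree.

        Returns ``(w, in_sub, remroot, p, lo)`` where ``w`` is the spliced
        copy (u detached, its old parent ``p`` dangling), ``remroot`` the
        root of the remaining tree and ``lo`` the lower reattachment bound:
        the pruned node's age or, if higher, the earliest time at which any
        outside branch can co-occur with the pruned lineage.  The floor
        depends only on the pruned configuration and is always at or below
        the current attachment time, which keeps the reflected reattachment
        proposal reversible (a bound at the divergence time of the youngest
        ancestral population *owning* outside nodes is not: an outside
        lineage may traverse a population without owning a node there).
        """
        st = self.stree
        n_nodes = gt.n_nodes
        p = int(gt.parent[u])
        g = int(gt.parent[p])
        s = int(gt.left[p]) if int(gt.right[p]) == u else int(gt.right[p])

        in_sub = np.zeros(n_nodes, dtype=bool)
        stack = [u]
        while stack:
            v = stack.pop()
            in_sub[v] = True
            if v >= gt.n_tips:
                stack.append(int(gt.left[v]))
                stack.append(int(gt.right[v]))

        w = gt.copy()
        if g >= 0:
            if int(w.left[g]) == p:
                w.left[g] = s
            else:
                w.right[g] = s
            w.parent[s] = g
            remroot = w.root
            self._update_base_path(w, g)
        else:
            w.parent[s] = -1
            w.root = s
            remroot = s
        w.parent[u] = -1

        floor = _kernels.spr_time_floor(
            n_nodes, w.parent, w.age, w.base, in_sub, p, remroot,
            int(w.base[u]), self.sp_parent, st.tau, self.desc,
        )
        lo = max(float(gt.age[u]), float(floor))
        return w, in_sub, remroot, p, lo

    def propose_spr(self, l: int) -> bool:
        """Date-aware subtree prune and regraft on the gene tree of locus l."""
        gt = self.gtrees[l]
        n_nodes = gt.n_nodes
        if gt.n_tips < 2:
            return False
        self.try_n["spr"] += 1
        st = self.stree
        rng = self.rng
        u = int(rng.integers(n_nodes - 1))
        if u >= gt.root:
            u += 1  # uniform over nodes except the root
        w, in_sub, remroot, p, lo = self._spr_detach(gt, u)
        hi = self.age_ceiling
        if hi <= lo:
            return False
        t_old = float(gt.age[p])
        x = float(bactrian_laplace(rng, self.cfg.bactrian_m))
        t_new = reflect(t_old + self.eps["spr"] * x, lo, hi)
        if t_new <= float(gt.age[u]):
            return False

        cand = np.empty(n_nodes, dtype=np.int64)
        base_u = int(gt.base[u])
        kn = _kernels.spr_candidates(
            n_nodes, w.parent, w.age, w.base, in_sub, p, remroot, base_u,
            t_new, self.sp_parent, st.tau, cand,
        )
        if kn == 0:
            return False
        cand2 = np.empty(n_nodes, dtype=np.int64)
        ko = _kernels.spr_candidates(
            n_nodes, w.parent, w.age, w.base, in_sub, p, remroot, base_u,
            t_old, self.sp_parent, st.tau, cand2,
        )
        if ko == 0:  # cannot happen for a valid state; guard anyway
            return False
        target = int(cand[rng.integers(kn)])

        w.age[p] = t_new
        w.parent[u] = p
        w.left[p] = u
        w.right[p] = target
        if target == remroot and t_new > float(w.age[remroot]):
            w.parent[target] = p
            w.parent[p] = -1
            w.root = p
        else:
            gpar = int(w.parent[target])
            w.parent[target] = p
            w.parent[p] = gpar
            if int(w.left[gpar]) == target:
                w.left[gpar] = p
            else:
                w.right[gpar] = p
        self._update_base_path(w, p)

        out = np.zeros(self.n_pops)
        if not self._density_vec(w, self._all_pops, out):
            return False
        ok, lik_new = self._locus_loglik(l, w)
        if not ok:
            return False
        delta = float(out.sum() - self.dens[l].sum()) + (lik_new - self.lik[l])
        log_alpha = delta + math.log(kn) - math.log(ko)
        if math.log(rng.random()) < log_alpha:
            self.gtrees[l] = w
            self.dens[l] = out
            self.lik[l] = lik_new
            self.loci[l].cache_ok = False
            self.acc_n["spr"] += 1
            return True
        return False

    def propose_ages(self, l: int) -> int:
        """Sliding-window updates of internal node ages (batched per locus)."""
        gt = self.gtrees[l]
        n_int = gt.n_tips - 1
        if n_int == 0:
            return 0
        k = self.cfg.ages_per_locus or n_int
        if k >= n_int:
            nodes = gt.n_tips + self.rng.permutation(n_int)
        else:
            nodes = gt.n_tips + self.rng.integers(0, n_int, size=k)
        nodes = nodes.astype(np.int64)
        steps = self.eps["age"] * bactrian_laplace(self.rng, self.cfg.bactrian_m, len(nodes))
        urand = self.rng.random(len(nodes))
        loc = self.loci[l]
        n_acc, newlik = _kernels.age_sweep(
            gt.n_tips, gt.left, gt.right, gt.parent, gt.age, gt.base, gt.pop,
            gt.root, gt.tip_species, self.sp_parent, self.stree.tau, self.theta,
            self.sp_is_tip, self.desc, self.stree.root, loc.tip_part, loc.weights,
            self.cfg.usedata, nodes, steps, urand, self.age_ceiling,
            self.dens[l], float(self.lik[l]), loc.part, loc.cache_ok,
            loc.saved, loc.saved_idx,
        )
        if self.cfg.usedata:
            loc.cache_ok = True
        if n_acc < 0:
            raise RuntimeError(f"zero likelihood at locus {l}")
        self.lik[l] = newlik
        self.acc_n["age"] += int(n_acc)
        self.try_n["age"] += len(nodes)
        return int(n_acc)

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------

    def sweep(self):
        for _ in range(self.cfg.mu_repeats):
            self.propose_mu()
            self.propose_mu_aux()
        for _ in range(self.cfg.tau_repeats):
            for p in self.internals:
                self.propose_tau(p)
        for p in range(self.n_pops):
            self.propose_theta(p)
            self.gibbs_theta(p)
        for _ in range(self.cfg.theta_repeats):
            for p in range(self.n_pops):
                self.propose_theta_scale(p)
        for l in range(len(self.loci)):
            for _ in range(self.cfg.spr_per_locus):
                self.propose_spr(l)
            self.propose_ages(l)

    def _tune(self):
        for k in list(self.eps):
            if self.try_n[k] == 0:
                continue
            rate = self.acc_n[k] / self.try_n[k]
            self.eps[k] *= math.exp(1.5 * (rate - self.cfg.tune_target))
            self.eps[k] = min(max(self.eps[k], 1e-10), 1e6)
            self.acc_n[k] = 0
            self.try_n[k] = 0

    def acceptance_rates(self) -> Dict[str, float]:
        out = {}
        for cls in self.MOVE_CLASSES:
            acc = sum(v for k, v in self.acc_n.items() if k.split("_")[0] == cls)
            tries = sum(v for k, v in self.try_n.items() if k.split("_")[0] == cls)
            out[cls] = acc / tries if tries else math.nan
        return out

    def param_names(self) -> List[str]:
        st = self.stree
        names = ["mu"]
        names += [f"tau_{st.labels[p]}" for p in self.internals]
        names += [f"tau_years_{st.labels[p]}" for p in self.internals]
        names += [f"theta_{st.labels[p]}" for p in range(self.n_pops)]
        names += ["lnL", "lnprior"]
        return names

    def _record(self, store: List[List[float]]):
        st = self.stree
        row = [self.mu]
        row += [float(st.tau[p]) for p in self.internals]
        row += [float(st.tau[p]) / self.mu for p in self.internals]
        row += [float(self.theta[p]) for p in range(self.n_pops)]
        row += [float(self.lik.sum()), float(self.dens.sum() + self.log_prior_params())]
        store.append(row)

    def run(self, progress: bool = False) -> Trace:
        cfg = self.cfg
        for it in range(cfg.burnin):
            self.sweep()
            if cfg.tune_interval and (it + 1) % cfg.tune_interval == 0:
                self._tune()
        for k in list(self.eps):  # freeze step sizes after burn-in
            self.acc_n[k] = 0
            self.try_n[k] = 0
        rows: List[List[float]] = []
        total = cfg.nsample * cfg.sampfreq
        for it in range(total):
            self.sweep()
            if (it + 1) % cfg.sampfreq == 0:
                self._record(rows)
            if cfg.check_every and (it + 1) % cfg.check_every == 0:
                self._verify_caches()
        arr = np.asarray(rows)
        names = self.param_names()
        return Trace({name: arr[:, j].copy() for j, name in enumerate(names)})


def run_mcmc(
    stree: SpeciesTree,
    alignments: Sequence[LocusAlignment],
    imap: Dict[str, str],
    dates: Dict[str, float],
    priors: PriorSet,
    config: Optional[McmcConfig] = None,
    seed: int = 0,
) -> Trace:
    """Convenience wrapper: build the sampler and run it to a Trace."""
    engine = MscMcmc(stree, alignments, imap, dates, priors, config, np.random.default_rng(seed))
    return engine.run()
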