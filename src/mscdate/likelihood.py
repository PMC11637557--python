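"""Strict-clock Jukes-Cantor likelihood of a locus alignment given its gene tree.

Branch lengths are differences of node ages in expected substitutions/site,
so tips sampled at different calendar times automatically have shorter
root-to-tip paths.  The likelihood is computed by Felsenstein pruning with
uniform (1/4) root base frequencies; gaps and IUPAC ambiguity codes
contribute all-ones partials (treated as missing data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .genetree import GeneTree

__all__ = [
    "LocusAlignment",
    "jc_transition_matrix",
    "jc_expected_distance",
    "pruning_log_likelihood",
]

# IUPAC nucleotide codes as A/C/G/T bit masks
IUPAC = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "X": 15, "-": 15, "?": 15,
}


@dataclass
class LocusAlignment:
    """Sequences x sites nucleotide matrix, encoded as IUPAC bit masks."""

    labels: list
    codes: np.ndarray  # (n_seq, n_sites) uint8

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise ValueError("codes must be (n_seq, n_sites) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels within a locus")

    @property
    def n_seq(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_strings(cls, labels: Sequence[str], seqs: Sequence[str]) -> "LocusAlignment":
        if len(labels) != len(seqs):
            raise ValueError("labels and sequences differ in number")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("sequences have unequal lengths")
        n_sites = lengths.pop() if lengths else 0
        codes = np.empty((len(seqs), n_sites), dtype=np.uint8)
        for i, s in enumerate(seqs):
            for j, ch in enumerate(s.upper()):
                code = IUPAC.get(ch)
                if code is None:
                    raise ValueError(f"unknown nucleotide character {ch!r} in {labels[i]!r}")
                codes[i, j] = code
        return cls(list(labels), codes)

    def to_strings(self) -> list:
        rev = {}
        for ch, code in IUPAC.items():
            if ch not in ("U", "X", "?", "-"):
                rev.setdefault(code, ch)
        rev[15] = "N"
        return ["".join(rev[c] for c in row) for row in self.codes]


def jc_transition_matrix(t: float) -> np.ndarray:
    """JC69 transition probabilities after branch length t (substitutions/site)."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = math.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    P = np.full((4, 4), diff)
    np.fill_diagonal(P, same)
    return P


def jc_expected_distance(t: float) -> float:
    """Expected proportion of differing sites between ends of a path of length t."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def tip_partials(codes: np.ndarray) -> np.ndarray:
    """(n_seq, 4, n_cols) conditional likelihoods of observed tip states."""
    n, P = codes.shape
    part = np.zeros((n, 4, P), dtype=np.float64)
    for x in range(4):
        part[:, x, :] = (codes & (1 << x)) > 0
    return part


def compress_patterns(codes: np.ndarray):
    """Collapse identical site columns; returns (patterns, weights, inverse)."""
    pats, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return pats.T.copy(), counts.astype(np.float64), inverse


def _site_log_likelihoods_numpy(gt: GeneTree, tip_part: np.ndarray) -> np.ndarray:
    """Reference NumPy pruning; same arithmetic as the compiled kernel."""
    n_nodes = gt.n_nodes
    P = tip_part.shape[2]
    part = np.empty((n_nodes, 4, P))
    part[: gt.n_tips] = tip_part
    logscale = np.zeros(P)
    for v in gt.postorder():
        if v < gt.n_tips:
            continue
        prod = None
        for c in (int(gt.left[v]), int(gt.right[v])):
            b = float(gt.age[v] - gt.age[c])
            if b < 0:
                raise ValueError("negative branch length")
            e = math.exp(-4.0 * b / 3.0)
            a = 0.25 * (1.0 - e)
            trans = a * part[c].sum(axis=0)[None, :] + e * part[c]
            prod = trans if prod is None else prod * trans
        mx = prod.max(axis=0)
        if np.any(mx <= 0):
            raise ValueError("zero site likelihood")
        part[v] = prod / mx
        logscale += np.log(mx)
    return np.log(0.25 * part[gt.root].sum(axis=0)) + logscale


def site_log_likelihoods(
    gt: GeneTree, tip_part: np.ndarray, engine: str = "numba"
) -> np.ndarray:
    if engine == "numba" and _kernels.HAVE_NUMBA:
        out = np.empty(tip_part.shape[2])
        ok = _kernels.jc_site_log_likelihoods(
            gt.n_tips, gt.left, gt.right, gt.age, gt.root, tip_part, out
        )
        if not ok:
            raise ValueError("negative branch length or zero site likelihood")
        return out
    return _site_log_likelihoods_numpy(gt, tip_part)


def pruning_log_likelihood(
    alignment: LocusAlignment,
    gene_tree: GeneTree,
    compress: bool = True,
    engine: str = "numba",
) -> float:
    """Log likelihood of the alignment given the gene tree under JC69.

    Sequence labels are the join key: the alignment rows are matched to the
    gene-tree tips by label.  Site-pattern compression is an internal detail;
    the result is bit-identical with and without it (per-site terms are
    expanded back to site order before summation).
    """
    order = _match_labels(alignment, gene_tree)
    codes = alignment.codes[order]
    if alignment.n_sites == 0:
        return 0.0
    if compress:
        pats, _, inverse = compress_patterns(codes)
        col = site_log_likelihoods(gene_tree, tip_partials(pats), engine)
        per_site = col[inverse]
    else:
        per_site = site_log_likelihoods(gene_tree, tip_partials(codes), engine)
    return float(np.sum(per_site))


def _match_labels(alignment: LocusAlignment, gene_tree: GeneTree) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(alignment.labels)}
    if set(pos) != set(gene_tree.tip_labels):
        raise ValueError("alignment labels do not match gene-tree tips")
    return np.asarray([pos[lab] for lab in gene_tree.tip_labels], dtype=np.int64)
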