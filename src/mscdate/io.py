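"""File formats: multi-locus PHYLIP, FASTA, date/Imap tables, configs, traces.

Sequence labels are the join key across the alignment, the
individual-to-species map ("Imap") and the tip-date table; no positional
matching is done.  All readers validate eagerly and report line numbers.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .likelihood import LocusAlignment
from .mcmc import McmcConfig, PriorSet, Trace
from .species import GammaPrior, SpeciesTree
from .stats import effective_sample_size, hpd_interval

__all__ = [
    "read_alignments",
    "write_alignments",
    "read_dates",
    "write_dates",
    "read_imap",
    "write_imap",
    "RunConfig",
    "read_config",
    "write_trace",
    "read_trace",
    "write_summary",
]


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def read_alignments(path) -> List[LocusAlignment]:
    """Read loci from a multi-locus PHYLIP file or a directory of FASTA files.

    The PHYLIP variant is sequential with repeated ``nseq nsites`` blocks;
    the first whitespace-separated token of each sequence line is the label
    and the remaining tokens are concatenated into the sequence.
    """
    path = Path(path)
    if path.is_dir():
        return _read_fasta_dir(path)
    return _read_phylip_multi(path)


def _read_phylip_multi(path: Path) -> List[LocusAlignment]:
    lines = path.read_text().splitlines()
    loci: List[LocusAlignment] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{i}: expected 'nseq nsites' header, got {line!r}")
        try:
            nseq, nsites = int(parts[0]), int(parts[1])
        except ValueError:
            raise FormatError(f"{path}:{i}: malformed block header {line!r}") from None
        labels, seqs = [], []
        while len(labels) < nseq:
            if i >= n_lines:
                raise FormatError(f"{path}: unexpected end of file inside a locus block")
            row = lines[i].strip()
            i += 1
            if not row or row.startswith("#"):
                continue
            toks = row.split()
            if len(toks) < 2:
                raise FormatError(f"{path}:{i}: expected 'label sequence', got {row!r}")
            labels.append(toks[0])
            seqs.append("".join(toks[1:]))
        for lab, s in zip(labels, seqs):
            if len(s) != nsites:
                raise FormatError(
                    f"{path}: sequence {lab!r} has {len(s)} sites, header says {nsites}"
                )
        try:
            loci.append(LocusAlignment.from_strings(labels, seqs))
        except ValueError as e:
            raise FormatError(f"{path}: {e}") from None
    if not loci:
        raise FormatError(f"{path}: no loci found")
    return loci


def _read_fasta_dir(path: Path) -> List[LocusAlignment]:
    from Bio import SeqIO

    files = sorted(
        f for f in path.iterdir() if f.suffix.lower() in (".fa", ".fasta", ".fna")
    )
    if not files:
        raise FormatError(f"{path}: no FASTA files found")
    loci = []
    for f in files:
        labels, seqs = [], []
        for rec in SeqIO.parse(str(f), "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq))
        if not labels:
            raise FormatError(f"{f}: empty FASTA file")
        try:
            loci.append(LocusAlignment.from_strings(labels, seqs))
        except ValueError as e:
            raise FormatError(f"{f}: {e}") from None
    return loci


def write_alignments(loci: List[LocusAlignment], path) -> None:
    """Write loci as sequential multi-locus PHYLIP."""
    with open(path, "w") as fh:
        for aln in loci:
            fh.write(f"{aln.n_seq} {aln.n_sites}\n")
            for lab, seq in zip(aln.labels, aln.to_strings()):
                fh.write(f"{lab}  {seq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# two-column tables
# ---------------------------------------------------------------------------


def _read_two_columns(path, what: str) -> List[Tuple[str, str, int]]:
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 2:
                raise FormatError(f"{path}:{ln}: expected two columns in {what}")
            rows.append((toks[0], toks[1], ln))
    if not rows:
        raise FormatError(f"{path}: empty {what}")
    return rows


def read_dates(path) -> Dict[str, float]:
    """Tip-date table: sequence label, age in years before present."""
    out: Dict[str, float] = {}
    for lab, val, ln in _read_two_columns(path, "date table"):
        try:
            age = float(val)
        except ValueError:
            raise FormatError(f"{path}:{ln}: age {val!r} is not a number") from None
        if not math.isfinite(age) or age < 0:
            raise FormatError(f"{path}:{ln}: age must be finite and >= 0")
        if lab in out:
            raise FormatError(f"{path}:{ln}: duplicate label {lab!r}")
        out[lab] = age
    return out


def write_dates(dates: Dict[str, float], path) -> None:
    with open(path, "w") as fh:
        for lab, age in dates.items():
            fh.write(f"{lab}\t{age:g}\n")


def read_imap(path) -> Dict[str, str]:
    """Imap table: sequence (or individual) label, species label."""
    out: Dict[str, str] = {}
    for lab, sp, ln in _read_two_columns(path, "Imap"):
        if lab in out:
            raise FormatError(f"{path}:{ln}: duplicate label {lab!r}")
        out[lab] = sp
    return out


def write_imap(imap: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for lab, sp in imap.items():
            fh.write(f"{lab}\t{sp}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Inference run settings parsed from a key = value config file."""

    seqfile: str
    imapfile: str
    treefile: Optional[str] = None
    tree: Optional[str] = None  # inline newick
    datefile: Optional[str] = None
    tauprior: GammaPrior = GammaPrior(2.0, 200.0)
    thetaprior: GammaPrior = GammaPrior(2.0, 2000.0)
    muprior: GammaPrior = GammaPrior(2.0, 2e9)
    burnin: int = 2000
    nsample: int = 2000
    sampfreq: int = 2
    seed: int = 1
    usedata: bool = True
    finetune: Optional[Dict[str, float]] = None

    def priors(self) -> PriorSet:
        return PriorSet(tau_root=self.tauprior, mu=self.muprior, theta=self.thetaprior)

    def mcmc_config(self) -> McmcConfig:
        return McmcConfig(
            burnin=self.burnin,
            nsample=self.nsample,
            sampfreq=self.sampfreq,
            usedata=self.usedata,
            eps=self.finetune,
        )

    def newick(self, base_dir: Optional[Path] = None) -> str:
        if self.tree:
            return self.tree
        if not self.treefile:
            raise FormatError("config must set either 'tree' or 'treefile'")
        p = Path(self.treefile)
        if base_dir and not p.is_absolute():
            p = base_dir / p
        return p.read_text()


def read_config(path) -> RunConfig:
    path = Path(path)
    kv: Dict[str, str] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{ln}: expected 'key = value'")
            key, val = (x.strip() for x in line.split("=", 1))
            if not key or not val:
                raise FormatError(f"{path}:{ln}: empty key or value")
            kv[key.lower()] = val

    def _prior(key: str, default: GammaPrior) -> GammaPrior:
        if key not in kv:
            return default
        toks = kv.pop(key).split()
        if len(toks) != 2:
            raise FormatError(f"{path}: {key} must be 'alpha beta'")
        return GammaPrior(float(toks[0]), float(toks[1]))

    required = ("seqfile", "imapfile")
    for k in required:
        if k not in kv:
            raise FormatError(f"{path}: missing required key {k!r}")
    cfg = RunConfig(seqfile=kv.pop("seqfile"), imapfile=kv.pop("imapfile"))
    cfg.treefile = kv.pop("treefile", None)
    cfg.tree = kv.pop("tree", None)
    cfg.datefile = kv.pop("datefile", None)
    cfg.tauprior = _prior("tauprior", cfg.tauprior)
    cfg.thetaprior = _prior("thetaprior", cfg.thetaprior)
    cfg.muprior = _prior("muprior", cfg.muprior)
    for k, cast in (("burnin", int), ("nsample", int), ("sampfreq", int), ("seed", int)):
        if k in kv:
            setattr(cfg, k, cast(kv.pop(k)))
    if "usedata" in kv:
        cfg.usedata = kv.pop("usedata") not in ("0", "false", "no")
    if "finetune" in kv:
        toks = kv.pop("finetune").split()
        names = ("mu", "tau", "theta", "spr", "age")
        cfg.finetune = {n: float(v) for n, v in zip(names, toks)}
    if kv:
        raise FormatError(f"{path}: unknown keys {sorted(kv)}")
    return cfg


# ---------------------------------------------------------------------------
# traces and summaries
# ---------------------------------------------------------------------------


def write_trace(trace: Trace, path) -> None:
    df = trace.to_dataframe()
    df.insert(0, "sample", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trace(path) -> Trace:
    df = pd.read_csv(path, sep="\t")
    df = df.drop(columns=[c for c in ("sample",) if c in df.columns])
    return Trace({c: df[c].to_numpy(dtype=float) for c in df.columns})


def write_summary(trace: Trace, path) -> None:
    """Posterior mean, median, 95% HPD and ESS per parameter, as TSV."""
    trace.summary().to_csv(path, sep="\t", float_format="%.10g")
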