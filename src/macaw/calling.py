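"""Mutation calling: apply the probabilistic model across sites with filters.

A site is emitted when its posterior probability of at least one mutation
exceeds the probability threshold (default 0.1, ``all_sites`` mode emits
everything), and *passes* when additionally the most probable mutant
allele in the most probable mutant line is supported by at least
``min_strand`` reads in both the forward and reverse orientation — the
strand filter that removes low-coverage and strand-biased artifacts
typical of mismapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_MIN_STRAND,
    DEFAULT_PROB_THRESHOLD,
    ModelParams,
    MutationModel,
    SitePosterior,
    argmax_line_allele,
    BASE_INDEX,
)
from .tally import SiteRecord, Tally


@dataclass
class MutationCall:
    """One candidate mutation with posterior evidence and filter verdicts."""

    chrom: str
    pos: int
    ref: str
    posterior: SitePosterior
    fwd_support: int
    rev_support: int
    pass_prob: bool
    pass_strand: bool
    multi_flag: bool

    @property
    def verdict(self) -> bool:
        return self.pass_prob and self.pass_strand

    @property
    def mutant_line(self):
        return self.posterior.mutant_line

    @property
    def mutant_allele(self):
        return self.posterior.mutant_allele


def flag_multi_mutation_sites(posterior: SitePosterior, fraction: float = 0.5,
                              floor: float = 1e-12) -> bool:
    """True when most of the mutation signal involves >1 mutation.

    In an MA experiment multiple mutations at one site are vanishingly
    unlikely, so a large gap between P(>=1 mutation) and P(exactly 1)
    marks probable systematic error (shared mismapping across lines).
    """
    gap = posterior.p_any - posterior.p_one
    return gap / max(posterior.p_any, floor) > fraction


def call_sites(
    data: Tally | Iterable[SiteRecord],
    params: ModelParams,
    threshold: float = DEFAULT_PROB_THRESHOLD,
    min_strand: int = DEFAULT_MIN_STRAND,
    all_sites: bool = False,
    multi_fraction: float = 0.5,
    chunk: int = 8192,
) -> Iterator[MutationCall]:
    """Run the probabilistic caller over a tally.

    Yields a :class:`MutationCall` for every site with ``p_any >
    threshold`` (every site when ``all_sites``).  Strand support is
    counted for the mutant allele in the mutant line only.
    """
    if not isinstance(data, Tally):
        data = Tally.from_records(data)
    model = MutationModel(params)
    anc = data.anc_collapsed()
    desc = data.desc_collapsed()
    S = len(data)
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        res = model.batch_posterior(anc[lo:hi], desc[lo:hi], extras=all_sites)
        if all_sites:
            idx = np.arange(lo, hi)
        else:
            idx = lo + np.nonzero(res["p_any"] > threshold)[0]
            if len(idx):
                det = model.batch_posterior(anc[idx], desc[idx])
        for k, i in enumerate(idx):
            if all_sites:
                p_one = float(res["p_one"][i - lo])
                per_line = res["per_line_p"][i - lo]
            else:
                p_one = float(det["p_one"][k])
                per_line = det["per_line_p"][k]
            post = SitePosterior(
                p_any=float(res["p_any"][i - lo]),
                p_one=p_one,
                per_line_p=per_line,
            )
            marg = model.line_allele_marginals(anc[i], desc[i])
            post.mutant_line, post.mutant_allele = argmax_line_allele(marg)
            if post.mutant_line is not None:
                b = BASE_INDEX[post.mutant_allele]
                fwd = int(data.desc_fwd[i, post.mutant_line, b])
                rev = int(data.desc_rev[i, post.mutant_line, b])
            else:
                fwd = rev = 0
            yield MutationCall(
                chrom=str(data.chrom[i]),
                pos=int(data.pos[i]),
                ref=str(data.ref[i]),
                posterior=post,
                fwd_support=fwd,
                rev_support=rev,
                pass_prob=post.p_any > threshold,
                pass_strand=fwd >= min_strand and rev >= min_strand,
                multi_flag=flag_multi_mutation_sites(post, multi_fraction),
            )


def calls_to_frame(calls: Iterable[MutationCall],
                   line_labels: list[str] | None = None) -> pd.DataFrame:
    """Tabulate calls into the output TSV schema."""
    rows = []
    for c in calls:
        line = c.mutant_line
        if line_labels is not None and line is not None:
            line = line_labels[line]
        rows.append(
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "p_any": c.posterior.p_any,
                "p_one": c.posterior.p_one,
                "mutant_line": line if line is not None else ".",
                "mutant_allele": c.mutant_allele or ".",
                "fwd_support": c.fwd_support,
                "rev_support": c.rev_support,
                "multi_flag": c.multi_flag,
                "verdict": "PASS" if c.verdict else "FAIL",
            }
        )
    cols = [
        "chrom", "pos", "ref", "p_any", "p_one", "mutant_line",
        "mutant_allele", "fwd_support", "rev_support", "multi_flag", "verdict",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_vcf(calls: Iterable[MutationCall], path,
              line_labels: list[str] | None = None) -> None:
    """Minimal VCF-like export: ALT is the mutant allele, INFO the posteriors."""
    fh = open(path, "w") if isinstance(path, (str, bytes)) else path
    close = isinstance(path, (str, bytes))
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PANY,Number=1,Type=Float,Description="P(>=1 mutation)">\n')
        fh.write('##INFO=<ID=PONE,Number=1,Type=Float,Description="P(exactly 1 mutation)">\n')
        fh.write('##INFO=<ID=LINE,Number=1,Type=String,Description="Mutant line">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            line = c.mutant_line
            if line_labels is not None and line is not None:
                line = line_labels[line]
            alt = c.mutant_allele or "."
            filt = "PASS" if c.verdict else "strand" if c.pass_prob else "prob"
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{alt}\t.\t{filt}\t"
                f"PANY={c.posterior.p_any:.6g};PONE={c.posterior.p_one:.6g};LINE={line}\n"
            )
    finally:
        if close:
            fh.close()
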