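"""Consensus-based mutation calling: the classical MA-line approach.

Each line's consensus base at a site must be supported by strictly more
than 80% of that line's reads and by at least three reads on each strand;
otherwise the line is *undetermined* there.  A mutation is called when
exactly one line's consensus differs from the unanimous consensus of all
the remaining lines.  This count-level caller is deliberately independent
of the probabilistic model and serves as a conservative co-caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .model import BASES
from .tally import SiteRecord, StrandedBaseCount, Tally


@dataclass
class ConsensusCall:
    """Per-site consensus verdict."""

    chrom: str
    pos: int
    ref: str
    line_consensus: list[str | None]   # per descendant, None = undetermined
    ancestor_consensus: str | None
    mutant_line: int | None            # 0-based descendant index
    mutant_allele: str | None

    @property
    def called(self) -> bool:
        return self.mutant_line is not None


def line_consensus(count: StrandedBaseCount, min_fraction: float = 0.8,
                   min_strand: int = 3) -> str | None:
    """Consensus base of one sample at one site, or None if undetermined.

    The top base must hold strictly more than ``min_fraction`` of the
    sample's reads and have at least ``min_strand`` forward and reverse
    reads.  Ties for the top base are undetermined.
    """
    tot = count.collapsed()
    depth = int(tot.sum())
    if depth == 0:
        return None
    b = int(np.argmax(tot))
    if np.sum(tot == tot[b]) > 1:
        return None
    if tot[b] <= min_fraction * depth:
        return None
    if count.fwd[b] < min_strand or count.rev[b] < min_strand:
        return None
    return BASES[b]


def consensus_call(site: SiteRecord, include_ancestor: bool = True,
                   min_fraction: float = 0.8, min_strand: int = 3) -> ConsensusCall:
    """Call a mutation when one line's consensus differs from all the rest.

    The remaining lines (plus the ancestor when ``include_ancestor``) must
    all be determined and unanimous; any undetermined line, more than one
    deviant line, or disagreement among the rest yields no call.
    """
    if len(site.descendants) < 3:
        raise ValueError("consensus calling needs at least 3 descendant lines")
    desc_cons = [line_consensus(d, min_fraction, min_strand) for d in site.descendants]
    anc_cons = line_consensus(site.ancestor, min_fraction, min_strand)
    call = ConsensusCall(
        chrom=site.chrom, pos=site.pos, ref=site.ref,
        line_consensus=desc_cons, ancestor_consensus=anc_cons,
        mutant_line=None, mutant_allele=None,
    )
    voters = list(desc_cons)
    if include_ancestor:
        voters.append(anc_cons)
    if any(v is None for v in voters):
        return call
    distinct = set(voters)
    if len(distinct) != 2:
        return call
    # exactly one descendant line must carry the minority base, alone
    counts = {b: voters.count(b) for b in distinct}
    minority = min(distinct, key=lambda b: counts[b])
    if counts[minority] != 1:
        return call
    if include_ancestor and anc_cons == minority:
        return call  # deviant voter is the ancestor, not a descendant
    idx = desc_cons.index(minority)
    call.mutant_line = idx
    call.mutant_allele = minority
    return call


def consensus_call_sites(data: Tally | Iterable[SiteRecord],
                         include_ancestor: bool = True,
                         min_fraction: float = 0.8,
                         min_strand: int = 3) -> Iterator[ConsensusCall]:
    """Apply :func:`consensus_call` across a tally, yielding calls only."""
    records = data.records() if isinstance(data, Tally) else data
    for rec in records:
        c = consensus_call(rec, include_ancestor, min_fraction, min_strand)
        if c.called:
            yield c


def consensus_to_frame(calls: Iterable[ConsensusCall],
                       line_labels: list[str] | None = None) -> pd.DataFrame:
    """Tabulate consensus calls with the shared caller TSV schema."""
    rows = []
    for c in calls:
        line = c.mutant_line
        if line_labels is not None and line is not None:
            line = line_labels[line]
        rows.append(
            {
                "chrom": c.chrom, "pos": c.pos, "ref": c.ref,
                "p_any": np.nan, "p_one": np.nan,
                "mutant_line": line if line is not None else ".",
                "mutant_allele": c.mutant_allele or ".",
                "fwd_support": np.nan, "rev_support": np.nan,
                "multi_flag": False,
                "verdict": "PASS" if c.called else "FAIL",
                "method": "consensus",
            }
        )
    cols = ["chrom", "pos", "ref", "p_any", "p_one", "mutant_line",
            "mutant_allele", "fwd_support", "rev_support", "multi_flag",
            "verdict", "method"]
    return pd.DataFrame(rows, columns=cols)
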