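"""Callable-site estimation: the denominator of the mutation rate.

A site counts as *callable* in a descendant line if a mutation there
would have been detected had one occurred.  This is measured by
simulating a full-frequency mutation in that line — shuffling the line's
base-count vector so the dominant allele's reads land on a different
base, preserving the site's depth and noise profile — recomputing the
mutation posterior, and applying the caller's criteria: the site is
missing from the line if the shuffled-count mutation probability is below
the threshold or the most probable mutant allele lacks ``min_strand``
reads in either orientation.

The default shuffle is the deterministic cyclic label shift
A->C->G->T->A applied to each strand separately; a seeded
random-permutation mode is provided as an alternative interpretation.
Ancestor counts are never shuffled — mutations are simulated in
descendants only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd


from .model import (
    BASES,
    _lse,
    DEFAULT_MIN_STRAND,
    DEFAULT_PROB_THRESHOLD,
    ModelParams,
    MutationModel,
    _exclusive_logsum,
)
from .tally import SiteRecord, StrandedBaseCount, Tally

#: cyclic label shift A->C->G->T->A: SHIFT[b] is where base b's reads go
SHIFT = np.array([1, 2, 3, 0])
#: inverse map: shuffled counts of base b came from base INV_SHIFT[b]
INV_SHIFT = np.array([3, 0, 1, 2])


@dataclass
class CallabilityResult:
    """Per-line callable-site counts and genome proportions."""

    line_labels: list[str]
    callable_sites: np.ndarray      # (n,) int
    proportions: np.ndarray         # (n,) callable / genome_size
    genome_size: int
    assayed_sites: int
    mask: np.ndarray | None = None  # (S, n) bool, True = callable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "line": self.line_labels,
                "callable_sites": self.callable_sites,
                "proportion": self.proportions,
            }
        )


def shuffle_counts(count: StrandedBaseCount,
                   rng: np.random.Generator | None = None) -> StrandedBaseCount:
    """Relocate base labels to simulate a full-frequency mutation.

    Deterministic cyclic shift by default (A->C->G->T->A on both
    strands); pass ``rng`` for a random non-identity permutation instead.
    Applying the default shift four times is the identity.
    """
    if rng is None:
        perm = SHIFT
    else:
        while True:
            perm = rng.permutation(4)
            if not np.array_equal(perm, np.arange(4)):
                break
    fwd = np.zeros(4, dtype=np.int64)
    rev = np.zeros(4, dtype=np.int64)
    fwd[perm] = count.fwd
    rev[perm] = count.rev
    return StrandedBaseCount(fwd, rev)


def _callable_mask(
    model: MutationModel,
    tally: Tally,
    threshold: float,
    min_strand: int,
    chunk: int = 4096,
) -> np.ndarray:
    """(S, n) boolean callability mask, fully vectorized.

    Relies on a symmetry of the haploid expected-frequency vectors: the
    DM likelihood of cyclically shuffled counts against outcome ``b``
    equals the likelihood of the original counts against outcome
    ``INV_SHIFT[b]``, so no second likelihood pass is needed.
    """
    S, n = len(tally), tally.n_lines
    anc = tally.anc_collapsed()
    desc = tally.desc_collapsed()
    out = np.zeros((S, n), dtype=bool)
    la_all = model.ancestor_loglik(anc)
    ld_u, lS_u, lN_u, _, inv = model.line_term_tables(desc)
    # shuffled-count likelihoods come free: the cyclic label shift of the
    # counts equals a cyclic permutation of the outcome axis (the haploid
    # expected-frequency vectors are label-symmetric)
    ld_shuf_u = ld_u[:, INV_SHIFT]
    x = ld_shuf_u[:, None, :]
    sS_u = _lse(x + model.lt_tot[None, :, :], axis=-1)   # (U, 10)
    sN_u = _lse(x + model.lt_stay[None, :, :], axis=-1)
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        sub = inv[lo:hi]                                      # (C, n)
        lS = lS_u[sub].transpose(0, 2, 1)                     # (C, 10, n)
        lN = lN_u[sub].transpose(0, 2, 1)
        logw = model.log_prior[None, :] + la_all[lo:hi]       # (C, 10)
        exclS = _exclusive_logsum(lS, axis=2)                 # (C, 10, n)
        exclN = _exclusive_logsum(lN, axis=2)
        rows = np.arange(hi - lo)
        for j in range(n):
            sS = sS_u[sub[:, j]]                              # (C, 10)
            sN = sN_u[sub[:, j]]
            logZ = _lse(logw + exclS[:, :, j] + sS, axis=1)
            logPno = _lse(logw + exclN[:, :, j] + sN, axis=1)
            with np.errstate(invalid="ignore"):
                p_any = -np.expm1(np.minimum(logPno - logZ, 0.0))
            # most probable mutant allele in the shuffled (focal) line
            lj = (
                logw[:, :, None]
                + exclS[:, :, j, None]
                + model.lt_mut[None, :, :]
                + ld_shuf_u[sub[:, j]][:, None, :]
            )                                                 # (C, 10, 4)
            marg = _lse(lj, axis=1)                      # (C, 4)
            allele = np.argmax(marg, axis=1)
            src = INV_SHIFT[allele]  # original base whose reads now sit on `allele`
            fwd_sup = tally.desc_fwd[lo:hi, j, :][rows, src]
            rev_sup = tally.desc_rev[lo:hi, j, :][rows, src]
            out[lo:hi, j] = (
                ~(p_any < threshold)
                & (fwd_sup >= min_strand)
                & (rev_sup >= min_strand)
            )
    return out


def is_callable(
    site: SiteRecord,
    line_index: int,
    params: ModelParams,
    threshold: float = DEFAULT_PROB_THRESHOLD,
    min_strand: int = DEFAULT_MIN_STRAND,
) -> bool:
    """Would a mutation in this line at this site have been detected?

    Shuffles only the focal line's counts, recomputes the posterior and
    applies the probability and strand-support criteria.
    """
    tally = Tally.from_records([site])
    model = MutationModel(params)
    mask = _callable_mask(model, tally, threshold, min_strand)
    return bool(mask[0, line_index])


def callable_summary(
    data: Tally | Iterable[SiteRecord],
    params: ModelParams,
    genome_size: int,
    threshold: float = DEFAULT_PROB_THRESHOLD,
    min_strand: int = DEFAULT_MIN_STRAND,
    keep_mask: bool = False,
) -> CallabilityResult:
    """Per-line callable-site counts and proportions of the genome.

    Sites absent from the tally are not callable, so ``genome_size``
    (total reference sites) sets the proportion denominator.
    """
    if not isinstance(data, Tally):
        data = Tally.from_records(data)
    if genome_size < len(data):
        raise ValueError("genome_size must be >= number of assayed sites")
    model = MutationModel(params)
    mask = _callable_mask(model, data, threshold, min_strand)
    counts = mask.sum(axis=0)
    return CallabilityResult(
        line_labels=data.line_labels,
        callable_sites=counts,
        proportions=counts / float(genome_size),
        genome_size=int(genome_size),
        assayed_sites=len(data),
        mask=mask if keep_mask else None,
    )


def noncallable_bed(tally: Tally, mask: np.ndarray, line_index: int):
    """Yield BED intervals (0-based half-open) of non-callable sites for a line."""
    start = None
    prev_pos = None
    prev_chrom = None
    for i in range(len(tally)):
        chrom, pos = tally.chrom[i], int(tally.pos[i])
        bad = not mask[i, line_index]
        contiguous = chrom == prev_chrom and prev_pos is not None and pos == prev_pos + 1
        if start is not None and (not bad or not contiguous):
            yield (prev_chrom, start - 1, prev_pos)
            start = None
        if bad and start is None:
            start = pos
        prev_chrom, prev_pos = chrom, pos
    if start is not None:
        yield (prev_chrom, start - 1, prev_pos)
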