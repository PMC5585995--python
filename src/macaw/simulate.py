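"""Synthetic MA-experiment data generated under the detection model itself.

The generator is the generative cascade read forward: draw the ancestral
diploid genotype from the finite-sites prior (heterozygosity ``theta``,
composition ``pi``); for each descendant line transmit one ancestral
allele with probability 1/2 and substitute it under F81 with the
experiment-long ``mu``; draw per-sample depths from a negative-binomial
(mean depth with a dispersion knob — real coverage is overdispersed
relative to Poisson); draw base counts from the Dirichlet-multinomial
around the genotype's expected base frequencies (``epsilon`` errors,
``phi_a`` for the pooled-ancestor library, ``phi_d`` per descendant);
and split each base's reads between strands binomially.

The reference base is taken to be the ancestor's canonical first allele,
mimicking an ancestor-derived reference assembly.  A truth table of all
mutation events (site, line, from/to allele) is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import BASES, GENOTYPES, ModelParams, ancestral_prior, f81_matrix
from .tally import Tally


@dataclass
class SimConfig:
    """Configuration of one synthetic experiment.

    ``depth_dispersion`` is the negative-binomial size parameter k
    (variance = m + m^2/k); ``strand_bias`` is the probability a read is
    on the forward strand.  A fixed ``seed`` fixes the output exactly.
    """

    n_sites: int
    n_lines: int = 8
    params: ModelParams = field(default_factory=ModelParams)
    mean_depth: float = 47.0
    depth_dispersion: float = 20.0
    strand_bias: float = 0.5
    seed: int = 0
    chrom: str = "sim"

    def __post_init__(self):
        if self.n_sites < 1 or self.n_lines < 1:
            raise ValueError("need at least one site and one line")
        if self.mean_depth < 0 or self.depth_dispersion <= 0:
            raise ValueError("bad depth model")
        if not 0 < self.strand_bias < 1:
            raise ValueError("strand_bias must lie in (0, 1)")


def _draw_depths(rng, mean, k, shape):
    if mean == 0:
        return np.zeros(shape, dtype=np.int64)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=shape)


def _dm_counts(rng, depth, p_expected, phi):
    """Dirichlet-multinomial draws: depth (...,), p_expected (..., 4)."""
    if phi == 0.0:
        return rng.multinomial(depth, p_expected)
    omega = (1.0 - phi) / phi
    alpha = p_expected * omega
    g = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    tot = g.sum(axis=-1, keepdims=True)
    # degenerate all-zero draws: fall back to the expected proportions
    safe = np.where(tot > 0, g, p_expected)
    probs = safe / safe.sum(axis=-1, keepdims=True)
    return rng.multinomial(depth, probs)


def simulate_experiment(config: SimConfig) -> tuple[Tally, pd.DataFrame]:
    """Generate a tally and its truth table under the stated model.

    Returns ``(tally, truth)`` where ``truth`` has one row per mutation
    event with columns site (0-based index), chrom, pos, line (label),
    from_allele, to_allele.
    """
    rng = np.random.default_rng(config.seed)
    par = config.params
    S, n = config.n_sites, config.n_lines

    prior = ancestral_prior(par)
    g_idx = rng.choice(len(GENOTYPES), size=S, p=prior)
    g_pairs = np.asarray(GENOTYPES)[g_idx]                       # (S, 2)

    pick = rng.integers(0, 2, size=(S, n))
    transmitted = g_pairs[np.arange(S)[:, None], pick]           # (S, n)

    P = f81_matrix(par.mu, par.pi_array)
    cum = np.cumsum(P, axis=1)
    u = rng.random((S, n))
    outcome = (u[:, :, None] > cum[transmitted][:, :, :-1]).sum(axis=2)

    eps = par.epsilon
    # expected base frequencies: ancestor from the diploid genotype,
    # descendants from their haploid outcome
    p_anc = np.full((S, 4), eps / 3.0)
    homo = g_pairs[:, 0] == g_pairs[:, 1]
    rows = np.arange(S)
    p_anc[rows[homo], g_pairs[homo, 0]] = 1.0 - eps
    p_anc[rows[~homo], g_pairs[~homo, 0]] = 0.5 - eps / 3.0
    p_anc[rows[~homo], g_pairs[~homo, 1]] = 0.5 - eps / 3.0
    p_desc = np.full((S, n, 4), eps / 3.0)
    np.put_along_axis(p_desc, outcome[:, :, None], 1.0 - eps, axis=2)

    anc_depth = _draw_depths(rng, config.mean_depth, config.depth_dispersion, S)
    desc_depth = _draw_depths(rng, config.mean_depth, config.depth_dispersion, (S, n))

    anc_counts = _dm_counts(rng, anc_depth, p_anc, par.phi_a)
    desc_counts = _dm_counts(rng, desc_depth, p_desc, par.phi_d)

    anc_fwd = rng.binomial(anc_counts, config.strand_bias)
    desc_fwd = rng.binomial(desc_counts, config.strand_bias)

    labels = ["ancestor"] + [f"L{i+1}" for i in range(n)]
    ref = np.array([BASES[b] for b in g_pairs[:, 0]], dtype=object)
    pos = np.arange(1, S + 1)
    tally = Tally(
        chrom=np.full(S, config.chrom, dtype=object),
        pos=pos,
        ref=ref,
        anc_fwd=anc_fwd,
        anc_rev=anc_counts - anc_fwd,
        desc_fwd=desc_fwd,
        desc_rev=desc_counts - desc_fwd,
        samples=labels,
    )

    mut_site, mut_line = np.nonzero(outcome != transmitted)
    truth = pd.DataFrame(
        {
            "site": mut_site,
            "chrom": config.chrom,
            "pos": pos[mut_site],
            "line": [labels[1 + j] for j in mut_line],
            "line_index": mut_line,
            "from_allele": [BASES[b] for b in transmitted[mut_site, mut_line]],
            "to_allele": [BASES[b] for b in outcome[mut_site, mut_line]],
        }
    )
    return tally, truth


def inject_anomaly(
    tally: Tally,
    lines: list[str],
    noise_fraction: float,
    seed: int = 0,
) -> Tally:
    """Add correlated low-frequency non-reference reads to the named lines.

    Emulates the signature of a contaminated / anomalous line pair: at
    every site a shared non-reference base receives ``Binomial(depth,
    noise_fraction)`` extra reads in each named line (the same alt base
    across those lines, making the noise correlated between them).
    """
    if not 0 <= noise_fraction <= 1:
        raise ValueError("noise_fraction must lie in [0, 1]")
    idx = [tally.line_labels.index(l) for l in lines]
    desc_fwd = tally.desc_fwd.copy()
    desc_rev = tally.desc_rev.copy()
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        S = len(tally)
        ref_idx = np.array([
            "ACGT".index(r) if r in "ACGT" else 0 for r in tally.ref
        ])
        alt = (ref_idx + rng.integers(1, 4, size=S)) % 4
        for j in idx:
            depth = tally.desc_fwd[:, j, :].sum(1) + tally.desc_rev[:, j, :].sum(1)
            extra = rng.binomial(depth, noise_fraction)
            add_fwd = rng.binomial(extra, 0.5)
            rows = np.arange(S)
            desc_fwd[rows, j, alt] += add_fwd
            desc_rev[rows, j, alt] += extra - add_fwd
    return Tally(
        chrom=tally.chrom.copy(), pos=tally.pos.copy(), ref=tally.ref.copy(),
        anc_fwd=tally.anc_fwd.copy(), anc_rev=tally.anc_rev.copy(),
        desc_fwd=desc_fwd, desc_rev=desc_rev, samples=list(tally.samples),
    )
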