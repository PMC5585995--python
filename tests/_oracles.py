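"""Independent brute-force oracles used only by the tests.

These deliberately avoid the factorized production code paths: the
posterior oracle enumerates every history (ancestral genotype x per-line
transmitted allele x per-line outcome) explicitly and sums joint
probabilities over the full outer-product grid.
"""

from __future__ import annotations

from functools import reduce

import numpy as np
from scipy.stats import dirichlet_multinomial, multinomial

from macaw.model import (
    GENOTYPES,
    ModelParams,
    ancestral_prior,
    expected_allele_freqs,
    f81_matrix,
)


def dm_pmf_reference(counts, p, phi):
    """DM pmf via scipy (or multinomial at phi=0); linear scale."""
    counts = np.asarray(counts, dtype=int)
    n = int(counts.sum())
    if n == 0:
        return 1.0
    if phi == 0:
        return float(multinomial.pmf(counts, n=n, p=np.asarray(p)))
    alpha = np.asarray(p, dtype=float) * (1 - phi) / phi
    keep = alpha > 0
    if np.any(~keep & (counts > 0)):
        return 0.0
    return float(dirichlet_multinomial.pmf(counts[keep], alpha[keep], n=n))


def enumerate_site_posterior(anc_counts, desc_counts, params: ModelParams):
    """Exact posterior by full history enumeration.

    ``anc_counts`` (4,) and ``desc_counts`` (n, 4) are collapsed counts.
    Returns dict with p_any, p_one, per_line_p (n,), line_allele (n, 4)
    and log_Z.
    """
    desc_counts = np.asarray(desc_counts)
    n = desc_counts.shape[0]
    prior = ancestral_prior(params)
    F = f81_matrix(params.mu, np.asarray(params.pi))
    eps = params.epsilon
    p_hap = [expected_allele_freqs((b, b), eps) for b in range(4)]

    # per-line genotype likelihoods are history-independent: cache them
    lik = np.array(
        [[dm_pmf_reference(desc_counts[i], p_hap[b], params.phi_d)
          for b in range(4)] for i in range(n)]
    )

    total = 0.0
    no_mut = 0.0
    one_mut = 0.0
    per_line = np.zeros(n)
    line_allele = np.zeros((n, 4))
    for k, (g1, g2) in enumerate(GENOTYPES):
        wa = prior[k] * dm_pmf_reference(
            anc_counts, expected_allele_freqs((g1, g2), eps), params.phi_a
        )
        if wa == 0.0:
            continue
        # per line: 8 history options (transmitted allele a, outcome b)
        opts_p, opts_mut, opts_b = [], [], []
        for i in range(n):
            p_i, m_i, b_i = [], [], []
            for a in (g1, g2):
                for b in range(4):
                    p_i.append(0.5 * F[a, b] * lik[i, b])
                    m_i.append(a != b)
                    b_i.append(b)
            opts_p.append(np.array(p_i))
            opts_mut.append(np.array(m_i))
            opts_b.append(np.array(b_i))
        joint = reduce(np.multiply.outer, opts_p)       # (8,)*n grid
        grids = np.meshgrid(*opts_mut, indexing="ij")
        nmut = sum(g.astype(int) for g in grids)
        total += wa * joint.sum()
        no_mut += wa * joint[nmut == 0].sum()
        one_mut += wa * joint[nmut == 1].sum()
        for i in range(n):
            sel = grids[i]
            per_line[i] += wa * joint[sel].sum()
            bg = np.meshgrid(*opts_b, indexing="ij")[i]
            for b in range(4):
                line_allele[i, b] += wa * joint[sel & (bg == b)].sum()
    return {
        "p_any": 1.0 - no_mut / total,
        "p_one": one_mut / total,
        "per_line_p": per_line / total,
        "line_allele": line_allele / total,
        "log_Z": np.log(total),
        "log_no_mut": np.log(no_mut) if no_mut > 0 else -np.inf,
    }


def descendant_transition_reference(ga, params: ModelParams):
    """Brute-force 2-allele x 4-outcome enumeration of the transition."""
    from macaw.model import _as_genotype

    g1, g2 = _as_genotype(ga)
    F = f81_matrix(params.mu, np.asarray(params.pi))
    probs = np.zeros(4)
    mut_mass = np.zeros(4)
    for a in (g1, g2):
        for b in range(4):
            probs[b] += 0.5 * F[a, b]
            if a != b:
                mut_mass[b] += 0.5 * F[a, b]
    with np.errstate(invalid="ignore"):
        p_mut = np.where(probs > 0, mut_mass / probs, 1.0)
    return probs, p_mut
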