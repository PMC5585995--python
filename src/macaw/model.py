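"""Probabilistic model for de novo mutation detection in MA experiments.

A mutation-accumulation (MA) experiment propagates descendant lines from a
single ancestor through repeated single-cell bottlenecks, then sequences
each line.  For one reference site the observed data are base-count vectors
(number of A, C, G, T reads) for the ancestor sample and each of *n*
descendant samples.  Everything between the ancestral genotype and the
read counts — inheritance, mutation, sequencing error — is hidden, so a
mutation call is made by summing over every *history*: a joint assignment
of the ancestral diploid genotype, the allele each line inherited, and the
(haploid) genotype each line ended up with.

For a history ``h`` the joint probability factorizes as::

    P(R, h) = P(G_A) * P(R_A | G_A) * prod_i P(G_i | G_A) * P(R_i | G_i)

with

* ``P(G_A)``       — finite-sites prior over the 10 diploid genotypes,
  parameterized by heterozygosity ``theta`` and base composition ``pi``;
* ``P(R | G)``     — Dirichlet-multinomial (DM) genotype likelihood with
  per-base error ``epsilon`` and overdispersion ``phi`` (``phi = 0``
  recovers the multinomial);
* ``P(G_i | G_A)`` — equal-probability transmission of one ancestral
  allele followed by F81 substitution with experiment-long rate ``mu``.

The posterior probability that a site carries at least one (or exactly
one) mutation is the ratio of history sums restricted to mutation-bearing
histories over the total, evaluated in log space.  The implementation
factorizes the per-line sums so cost is O(10 * 4 * n) per site but is
provably identical to full enumeration (tested against a brute-force
oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the 10 unordered diploid genotypes in canonical (A<C<G<T) order
GENOTYPES: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(4) for j in range(i, 4)
)
GENOTYPE_LABELS = tuple(BASES[i] + BASES[j] for i, j in GENOTYPES)


class ParameterError(ValueError):
    """A model parameter is outside its legal domain."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the mutation-detection model.

    Parameters
    ----------
    theta
        Expected proportion of ancestral sites that are heterozygous.
    phi_a, phi_d
        Overdispersion of the DM read-count model for the ancestor
        (pooled genomic-exclusion libraries) and descendants, in [0, 1).
    pi
        Equilibrium nucleotide frequencies (A, C, G, T).
    mu
        Experiment-long mutation probability per site (the F81 branch
        weight covering the whole propagation period).
    epsilon
        Per-base sequencing-error probability.
    """

    theta: float = 1e-4
    phi_a: float = 0.03
    phi_d: float = 0.01
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mu: float = 1e-8
    epsilon: float = 0.01

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,):
            raise ParameterError("pi must have four entries (A, C, G, T)")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ParameterError("pi entries must be > 0 and sum to 1")
        object.__setattr__(self, "pi", tuple(float(x) for x in pi))
        if self.theta < 0:
            raise ParameterError("theta must be >= 0")
        for name in ("phi_a", "phi_d", "mu"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ParameterError(f"{name} must lie in [0, 1)")
        if not 0 <= self.epsilon < 0.75:
            raise ParameterError("epsilon must lie in [0, 0.75)")

    @property
    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: parameter profiles used for the two analysis phases of a typical run.
#: ``mapq_contract`` documents the upstream read-filtering contract
#: (applied at pileup generation, not inside the model).
PRESETS: dict[str, dict] = {
    "initial": {
        "params": ModelParams(phi_a=0.001, phi_d=0.001),
        "mapq_contract": 13,
        "strand_filter": False,
    },
    "final": {
        "params": ModelParams(phi_a=0.03, phi_d=0.01),
        "mapq_contract": 25,
        "strand_filter": True,
    },
}

DEFAULT_PROB_THRESHOLD = 0.1
DEFAULT_MIN_STRAND = 3


# ---------------------------------------------------------------------------
# Elementary model components
# ---------------------------------------------------------------------------

def expected_allele_freqs(genotype, epsilon: float) -> np.ndarray:
    """Expected read-base frequencies for a genotype under error rate epsilon.

    ``genotype`` is a pair of base indices/letters (diploid) or a single
    base (haploid, treated as homozygous).  Returns a length-4 simplex
    vector: ``1 - eps`` for a homozygous match, ``1/2 - eps/3`` for each
    heterozygous match and ``eps/3`` for a mismatch.
    """
    if not 0 <= epsilon < 0.75:
        raise ParameterError("epsilon must lie in [0, 0.75)")
    g1, g2 = _as_genotype(genotype)
    p = np.full(4, epsilon / 3.0)
    if g1 == g2:
        p[g1] = 1.0 - epsilon
    else:
        p[g1] = 0.5 - epsilon / 3.0
        p[g2] = 0.5 - epsilon / 3.0
    return p


def _as_genotype(genotype) -> tuple[int, int]:
    """Normalize a genotype argument to a canonical pair of base indices."""
    if isinstance(genotype, str):
        idx = sorted(BASE_INDEX[b] for b in genotype.upper())
        if len(idx) == 1:
            idx = idx * 2
    else:
        try:
            g1, g2 = genotype
        except TypeError:
            g1 = g2 = genotype
        idx = sorted(
            BASE_INDEX[g] if isinstance(g, str) else int(g) for g in (g1, g2)
        )
    if len(idx) != 2 or not all(0 <= i < 4 for i in idx):
        raise ValueError(f"not a genotype: {genotype!r}")
    return idx[0], idx[1]


def dm_log_pmf(counts, p, phi: float) -> float:
    """Log pmf of the Dirichlet-multinomial in mean/overdispersion form.

    ``p`` holds the expected base proportions and ``phi`` in [0, 1) the
    overdispersion; the Dirichlet concentration is ``p * (1-phi)/phi``.
    At ``phi = 0`` the analytic multinomial limit is returned.  A zero
    ``p_b`` with a positive count gives ``-inf`` rather than an error.
    """
    out = dm_log_pmf_table(np.asarray(counts), np.asarray(p, float)[None, :], phi)
    return float(out[0])


def dm_log_pmf_table(counts: np.ndarray, p_rows: np.ndarray, phi: float) -> np.ndarray:
    """Vectorized DM log pmf: counts (..., 4) against p_rows (K, 4) -> (..., K)."""
    if not 0 <= phi < 1:
        raise ParameterError("phi must lie in [0, 1)")
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative base counts")
    n_tot = counts.sum(axis=-1)
    coef = gammaln(n_tot + 1.0) - gammaln(counts + 1.0).sum(axis=-1)
    c = counts[..., None, :]  # (..., 1, 4) against (K, 4)
    if phi == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.log(p_rows)
            terms = np.where(c == 0, 0.0, c * logp)
        return coef[..., None] + terms.sum(axis=-1)
    omega = (1.0 - phi) / phi
    alpha = p_rows * omega  # (K, 4)
    zero = alpha == 0.0
    alpha_safe = np.where(zero, 1.0, alpha)
    if omega > 1e6:
        # gammaln differences cancel catastrophically for huge omega;
        # counts are integers, so use the exact rising-factorial series
        # gammaln(a+r) - gammaln(a) = sum_{k<r} log(a+k)
        maxc = int(n_tot.max()) if n_tot.size else 0
        terms = np.zeros(np.broadcast_shapes(c.shape, alpha.shape))
        body = np.zeros_like(n_tot)
        for k in range(maxc):
            terms += np.where(c > k, np.log(alpha_safe + k), 0.0)
            body -= np.where(n_tot > k, np.log(omega + k), 0.0)
    else:
        terms = gammaln(alpha_safe + c) - gammaln(alpha_safe)
        body = gammaln(omega) - gammaln(omega + n_tot)
    terms = np.where(zero & (c > 0), -np.inf, np.where(zero, 0.0, terms))
    return coef[..., None] + body[..., None] + terms.sum(axis=-1)


def ancestral_prior(params: ModelParams) -> np.ndarray:
    """Prior over the 10 diploid genotypes (finite-sites, parent-independent).

    Homozygote {b,b}: ``pi_b/(1+theta) + pi_b^2*theta/(1+theta)``;
    heterozygote {b1,b2}: ``2*pi_b1*pi_b2*theta/(1+theta)``.  ``1/(1+theta)``
    is the probability the ancestor is autozygous at the site.
    """
    pi = params.pi_array
    th = params.theta
    out = np.empty(len(GENOTYPES))
    for k, (i, j) in enumerate(GENOTYPES):
        if i == j:
            out[k] = pi[i] / (1 + th) + pi[i] ** 2 * th / (1 + th)
        else:
            out[k] = 2 * pi[i] * pi[j] * th / (1 + th)
    return out


def f81_matrix(mu: float, pi) -> np.ndarray:
    """Rate-normalized F81 transition matrix over branch weight ``mu``.

    ``P[i, j] = exp(-beta*mu)*delta_ij + (1 - exp(-beta*mu))*pi_j`` with
    ``beta = 1/(1 - sum(pi^2))`` so that ``mu`` equals the expected number
    of substitutions per site to first order.
    """
    pi = np.asarray(pi, dtype=float)
    if not 0 <= mu < 1:
        raise ParameterError("mu must lie in [0, 1)")
    denom = 1.0 - np.sum(pi**2)
    if denom <= 0:
        raise ParameterError("degenerate pi: sum(pi^2) must be < 1")
    beta = 1.0 / denom
    e = np.exp(-beta * mu)
    return e * np.eye(4) + (1.0 - e) * pi[None, :]


def descendant_transition(ga, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of a descendant's haploid genotype given the ancestor.

    One ancestral allele is transmitted with probability 1/2 each, then
    substituted under F81 with the experiment-long ``mu``.  Returns
    ``(probs, p_mut)`` where ``probs[b] = P(G_i = b | G_A)`` and
    ``p_mut[b]`` is the probability, conditional on outcome ``b``, that
    the transmitted allele differed from ``b`` (i.e. a mutation occurred
    in that line).
    """
    g1, g2 = _as_genotype(ga)
    P = f81_matrix(params.mu, params.pi_array)
    probs = 0.5 * P[g1] + 0.5 * P[g2]
    stay = np.zeros(4)
    for a in (g1, g2):
        stay[a] += 0.5 * P[a, a]
    mut = probs - stay
    with np.errstate(divide="ignore", invalid="ignore"):
        p_mut = np.where(probs > 0, mut / probs, 1.0)
    return probs, np.clip(p_mut, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Site posterior engine
# ---------------------------------------------------------------------------

@dataclass
class SitePosterior:
    """Posterior summary of mutation evidence at one site."""

    p_any: float
    p_one: float
    per_line_p: np.ndarray
    mutant_line: int | None = None   # 0-based index into the descendant list
    mutant_allele: str | None = None

    def __post_init__(self):
        self.per_line_p = np.asarray(self.per_line_p, dtype=float)


def _unique_count_rows(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate (M, 4) count rows; returns (unique_rows, inverse_index)."""
    counts = np.ascontiguousarray(np.asarray(counts, dtype=np.int64))
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("expected an (M, 4) count array")
    if counts.size and counts.max() >= 1 << 15:
        uniq, inv = np.unique(counts, axis=0, return_inverse=True)
        return uniq, inv.ravel()
    key = counts @ np.array([1 << 45, 1 << 30, 1 << 15, 1], dtype=np.int64)
    _, first, inv = np.unique(key, return_index=True, return_inverse=True)
    return counts[first], inv


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    """Lean log-sum-exp reduction (hot path; -inf safe, no NaN inputs)."""
    m = np.max(x, axis=axis)
    m_safe = np.where(np.isneginf(m), 0.0, m)
    with np.errstate(invalid="ignore"):
        out = m_safe + np.log(
            np.sum(np.exp(x - np.expand_dims(m_safe, axis)), axis=axis)
        )
    return np.where(np.isneginf(m), -np.inf, out)


def _exclusive_logsum(x: np.ndarray, axis: int) -> np.ndarray:
    """Sum of log-terms over ``axis`` excluding each element, -inf safe."""
    neg = np.isneginf(x)
    xz = np.where(neg, 0.0, x)
    tot = xz.sum(axis=axis, keepdims=True)
    cnt = neg.sum(axis=axis, keepdims=True)
    excl = tot - xz
    out = np.where(cnt == 0, excl, np.where((cnt == 1) & neg, excl, -np.inf))
    return out


class MutationModel:
    """Precomputed tables + vectorized posterior evaluation for one Θ.

    The heavy per-site work is done on arrays of sites at once; the
    per-site :meth:`site_posterior` is a batch of one.
    """

    def __init__(self, params: ModelParams):
        self.params = params
        eps = params.epsilon
        self.p_geno = np.stack(
            [expected_allele_freqs(g, eps) for g in GENOTYPES]
        )  # (10, 4)
        self.p_hap = np.stack(
            [expected_allele_freqs((b, b), eps) for b in range(4)]
        )  # (4, 4)
        with np.errstate(divide="ignore"):
            self.log_prior = np.log(ancestral_prior(params))  # (10,)
        P = f81_matrix(params.mu, params.pi_array)
        # transmission-resolved outcome weights per ancestral genotype:
        #   t_stay[g, b] — transmitted allele equals outcome b
        #   t_mut[g, b]  — transmitted allele differed from outcome b
        t_stay = np.zeros((len(GENOTYPES), 4))
        t_mut = np.zeros((len(GENOTYPES), 4))
        for k, (g1, g2) in enumerate(GENOTYPES):
            for a in (g1, g2):
                t_stay[k, a] += 0.5 * P[a, a]
                t_mut[k] += 0.5 * P[a]
                t_mut[k, a] -= 0.5 * P[a, a]
        with np.errstate(divide="ignore"):
            self.lt_stay = np.log(t_stay)
            self.lt_mut = np.log(np.clip(t_mut, 0.0, None))
            self.lt_tot = np.log(t_stay + np.clip(t_mut, 0.0, None))

    # -- likelihood tables ---------------------------------------------------

    def ancestor_loglik(self, anc_counts: np.ndarray) -> np.ndarray:
        """(S, 4) collapsed ancestor counts -> (S, 10) genotype log likelihoods."""
        uniq, inv = _unique_count_rows(np.asarray(anc_counts))
        return dm_log_pmf_table(uniq, self.p_geno, self.params.phi_a)[inv]

    def descendant_loglik(self, desc_counts: np.ndarray) -> np.ndarray:
        """(S, n, 4) collapsed descendant counts -> (S, n, 4) outcome log likelihoods."""
        desc_counts = np.asarray(desc_counts)
        uniq, inv = _unique_count_rows(desc_counts.reshape(-1, 4))
        table = dm_log_pmf_table(uniq, self.p_hap, self.params.phi_d)
        return table[inv].reshape(desc_counts.shape[:-1] + (4,))

    def line_term_tables(self, desc_counts: np.ndarray):
        """Unique-vector per-line history sums.

        Read-count vectors repeat heavily across a genome, so the per-line
        sums over (transmitted allele, outcome) are computed once per
        distinct 4-vector.  Returns ``(ld_u, lS_u, lN_u, lM_u, inv)``:
        ``ld_u`` (U, 4) outcome log likelihoods and (U, 10) per-genotype
        log sums over all / no-mutation / mutation histories, with ``inv``
        of shape (S, n) mapping observations to unique rows.
        """
        desc_counts = np.asarray(desc_counts)
        uniq, inv = _unique_count_rows(desc_counts.reshape(-1, 4))
        ld_u = dm_log_pmf_table(uniq, self.p_hap, self.params.phi_d)  # (U, 4)
        x = ld_u[:, None, :]
        lS_u = _lse(x + self.lt_tot[None, :, :], axis=-1)        # (U, 10)
        lN_u = _lse(x + self.lt_stay[None, :, :], axis=-1)
        lM_u = _lse(x + self.lt_mut[None, :, :], axis=-1)
        return ld_u, lS_u, lN_u, lM_u, inv.reshape(desc_counts.shape[:-1])

    def line_terms(self, ld: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-line history sums from descendant log likelihoods.

        ``ld`` is (S, n, 4).  Returns ``(lS, lN, lM)``, each (S, 10, n):
        log of the per-line sum over (transmitted allele, outcome) of all
        histories / no-mutation histories / mutation histories.
        """
        x = ld[:, None, :, :]  # (S, 1, n, 4)
        lS = _lse(x + self.lt_tot[None, :, None, :], axis=-1)
        lN = _lse(x + self.lt_stay[None, :, None, :], axis=-1)
        lM = _lse(x + self.lt_mut[None, :, None, :], axis=-1)
        return lS, lN, lM

    def batch_posterior(
        self,
        anc_counts: np.ndarray,
        desc_counts: np.ndarray,
        chunk: int = 16384,
        extras: bool = True,
    ) -> dict[str, np.ndarray]:
        """Posterior summaries for S sites at once.

        Parameters are collapsed (strand-summed) count arrays: ancestor
        (S, 4) and descendants (S, n, 4).  Returns arrays ``p_any``,
        ``p_one`` (S,) and ``per_line_p`` (S, n); with ``extras=False``
        only ``p_any`` is computed (cheap candidate screening).
        """
        anc_counts = np.asarray(anc_counts)
        desc_counts = np.asarray(desc_counts)
        S = anc_counts.shape[0]
        la_all = self.ancestor_loglik(anc_counts)
        _, lS_u, lN_u, lM_u, inv = self.line_term_tables(desc_counts)
        p_any = np.empty(S)
        p_one = np.empty(S) if extras else None
        per_line = np.empty(desc_counts.shape[:2]) if extras else None
        for lo in range(0, S, chunk):
            hi = min(lo + chunk, S)
            sub = inv[lo:hi]
            lS = lS_u[sub].transpose(0, 2, 1)   # (C, 10, n)
            lN = lN_u[sub].transpose(0, 2, 1)
            if not extras:
                logw = self.log_prior[None, :] + la_all[lo:hi]
                logZ = _lse(logw + lS.sum(axis=2), axis=1)
                logPno = _lse(logw + lN.sum(axis=2), axis=1)
                with np.errstate(invalid="ignore"):
                    p_any[lo:hi] = np.clip(
                        -np.expm1(np.minimum(logPno - logZ, 0.0)), 0.0, 1.0
                    )
                continue
            lM = lM_u[sub].transpose(0, 2, 1)
            res = self._combine(la_all[lo:hi], lS, lN, lM)
            p_any[lo:hi] = res["p_any"]
            p_one[lo:hi] = res["p_one"]
            per_line[lo:hi] = res["per_line_p"]
        return {"p_any": p_any, "p_one": p_one, "per_line_p": per_line}

    def _combine(self, la, lS, lN, lM) -> dict[str, np.ndarray]:
        """Fold per-genotype/per-line sums into posterior probabilities."""
        logw = self.log_prior[None, :] + la  # (S, 10)
        totS = lS.sum(axis=2)
        totN = lN.sum(axis=2)
        logZ = _lse(logw + totS, axis=1)
        logPno = _lse(logw + totN, axis=1)
        with np.errstate(invalid="ignore"):
            p_any = -np.expm1(np.minimum(logPno - logZ, 0.0))
        exclN = _exclusive_logsum(lN, axis=2)
        exclS = _exclusive_logsum(lS, axis=2)
        lone = _lse(logw[:, :, None] + lM + exclN, axis=(1, 2))
        p_one = np.exp(np.minimum(lone - logZ, 0.0))
        lmarg = _lse(logw[:, :, None] + lM + exclS, axis=1)  # (S, n)
        per_line = np.exp(np.minimum(lmarg - logZ[:, None], 0.0))
        p_one = np.minimum(p_one, p_any)
        return {
            "p_any": np.clip(p_any, 0.0, 1.0) + 0.0,  # normalize -0.0
            "p_one": np.clip(p_one, 0.0, 1.0),
            "per_line_p": np.clip(per_line, 0.0, 1.0),
            "logZ": logZ,
            "logw": logw,
            "exclS": exclS,
        }

    def line_allele_marginals(
        self, anc_counts: np.ndarray, desc_counts: np.ndarray
    ) -> np.ndarray:
        """(n, 4) posterior probability that line i mutated to allele b (one site)."""
        la = self.ancestor_loglik(anc_counts[None, :])
        ld = self.descendant_loglik(desc_counts[None, :, :])
        lS, lN, lM = self.line_terms(ld)
        res = self._combine(la, lS, lN, lM)
        logw, exclS, logZ = res["logw"], res["exclS"], res["logZ"]
        # log joint(g, i, b) = logw[g] + excl-lines[g, i] + t_mut[g, b] + ld[i, b]
        lj = (
            logw[0, :, None, None]
            + exclS[0, :, :, None]
            + self.lt_mut[:, None, :]
            + ld[0][None, :, :]
        )
        marg = np.exp(np.minimum(_lse(lj, axis=0) - logZ[0], 0.0))
        return marg

    def site_posterior(self, site, params=None) -> SitePosterior:
        """Full posterior for one :class:`~macaw.tally.SiteRecord`."""
        anc = np.asarray(site.ancestor.collapsed(), dtype=float)
        desc = np.stack([d.collapsed() for d in site.descendants]).astype(float)
        res = self.batch_posterior(anc[None, :], desc[None, :, :])
        marg = self.line_allele_marginals(anc, desc)
        line, allele = argmax_line_allele(marg)
        return SitePosterior(
            p_any=float(res["p_any"][0]),
            p_one=float(res["p_one"][0]),
            per_line_p=res["per_line_p"][0],
            mutant_line=line,
            mutant_allele=allele,
        )


def argmax_line_allele(marg: np.ndarray) -> tuple[int | None, str | None]:
    """Argmax of an (n, 4) line/allele marginal.

    Ties break lexicographically on base (A<C<G<T) then lowest line index.
    Returns (None, None) when the marginal carries no mass at all.
    """
    if not np.any(marg > 0):
        return None, None
    flat = np.argmax(marg.T)  # base-major: smallest base, then smallest line
    b, i = divmod(int(flat), marg.shape[0])
    return i, BASES[b]


def site_posterior(site, params: ModelParams) -> SitePosterior:
    """Convenience wrapper: build a :class:`MutationModel` and evaluate one site."""
    return MutationModel(params).site_posterior(site)
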