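import numpy as np
import pytest

from macaw import ModelParams, SiteRecord, StrandedBaseCount


@pytest.fixture
def final_params():
    return ModelParams(phi_a=0.03, phi_d=0.01, epsilon=0.01, mu=1e-8, theta=1e-4)


@pytest.fixture
def initial_params():
    return ModelParams(phi_a=0.001, phi_d=0.001, epsilon=0.01, mu=1e-8, theta=1e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


def make_count(fwd, rev=None):
    fwd = np.asarray(fwd, dtype=int)
    rev = fwd.copy() if rev is None else np.asarray(rev, dtype=int)
    return StrandedBaseCount(fwd, rev)


def make_site(anc, descendants, chrom="scf_1", pos=1, ref="A"):
    return SiteRecord(
        chrom=chrom, pos=pos, ref=ref,
        ancestor=anc if isinstance(anc, StrandedBaseCount) else make_count(anc),
        descendants=[
            d if isinstance(d, StrandedBaseCount) else make_count(d)
            for d in descendants
        ],
    )


def random_site_counts(rng, n_lines, max_depth=40, dirty=0.3):
    """Random collapsed counts for oracle comparisons: mostly one dominant
    base per sample with occasional scattered minor counts."""
    anc = np.zeros(4, dtype=int)
    dom = rng.integers(0, 4)
    anc[dom] = rng.integers(5, max_depth)
    if rng.random() < dirty:
        anc[rng.integers(0, 4)] += rng.integers(0, 6)
    desc = np.zeros((n_lines, 4), dtype=int)
    for i in range(n_lines):
        d = dom if rng.random() < 0.8 else rng.integers(0, 4)
        desc[i, d] = rng.integers(0, max_depth)
        if rng.random() < dirty:
            desc[i, rng.integers(0, 4)] += rng.integers(0, 6)
    return anc, desc
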