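import itertools

import numpy as np
import pytest
from scipy.stats import binom

from beastie.io_counts import GeneObservation, HetSite


def make_gene(counts, alts, phases, pi=None, gene_id="g", spacing=200):
    """Assemble a GeneObservation from parallel per-site vectors."""
    sites = [
        HetSite("chr1", 1000 + spacing * i, "A", "G", int(n), int(x), int(ph))
        for i, (n, x, ph) in enumerate(zip(counts, alts, phases))
    ]
    return GeneObservation(gene_id, sites, pi)


def brute_force_likelihood(gene: GeneObservation, p: float) -> float:
    """Independent oracle: enumerate all 2^(n-1) phasings explicitly.

    The reference site (highest coverage, first on ties) is pinned to its
    predicted phase; every other site's parity is enumerated; each parity
    vector is weighted by its chain of stay/flip probabilities.
    """
    N = gene.total_counts
    X = gene.alt_counts
    ph = gene.phases
    pi = gene.pi
    n = gene.n
    r = int(np.argmax(N))
    total = 0.0
    for par in itertools.product((0, 1), repeat=n):
        if par[r] != 0:
            continue
        w = 1.0
        for i in range(n - 1):
            w *= pi[i] if par[i] != par[i + 1] else 1.0 - pi[i]
        like = 1.0
        for i in range(n):
            q = p if (ph[i] ^ par[i]) == 0 else 1.0 - p
            like *= binom.pmf(X[i], N[i], q)
        total += w * like
    return total


def random_gene(rng, n_max=10, depth_max=30):
    n = int(rng.integers(1, n_max + 1))
    N = rng.integers(1, depth_max, n)
    X = np.array([rng.integers(0, Ni + 1) for Ni in N])
    ph = rng.integers(0, 2, n)
    pi = rng.uniform(0.0, 0.5, max(n - 1, 0))
    return make_gene(N, X, ph, pi)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
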