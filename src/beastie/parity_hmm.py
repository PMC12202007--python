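"""Marginal likelihood over phasings via the even/odd switch-parity HMM.

A gene's allelic counts are modelled site-by-site with binomial emissions
whose success probability is either ``p`` (alternate allele on the maternal
chromosome) or ``1 - p``.  The true phasing of each heterozygous site is
unknown; what is known is a *predicted* phasing together with a per-adjacent-
pair switching-error rate ``pi[i]``.  Because a switching error flips the
phase of every downstream site, the only latent quantity that matters at
site ``i`` is the *parity* (even/odd) of the number of switching errors
between the reference site and ``i``.  A two-state inhomogeneous Markov
chain over this parity lets the sum over all ``2**(n-1)`` phasings be
computed in O(n) time.

The reference site is the site with the highest coverage (ties broken by
lowest position); its parity is fixed to "even", i.e. its predicted phase is
taken at face value.  The chain runs outward from the reference site in both
directions with stay probability ``1 - pi[i]`` and flip probability
``pi[i]`` between adjacent sites.

Conventions: ``phase == 0`` means the alternate allele lies on the maternal
copy, so alternate-allele counts have success probability ``p``; parity
"odd" flips the effective phase.  Because maternal/paternal labels are
arbitrary, any consistent convention yields the same likelihood
(``L(p; X) == L(1 - p; N - X)``).
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np
from scipy.stats import binom

if TYPE_CHECKING:  # pragma: no cover
    from .io_counts import GeneObservation, HetSite

__all__ = [
    "site_emission",
    "marginal_likelihood",
    "log_marginal_likelihood",
    "loglik_grid",
    "reference_index",
]


def reference_index(total_counts: np.ndarray) -> int:
    """Index of the reference (anchor) site: highest coverage, first on ties.

    Sites are position-sorted, so ``argmax`` (which returns the first
    maximum) implements the lowest-position tie-break.
    """
    return int(np.argmax(total_counts))


def site_emission(site: "HetSite", p: float, parity: str) -> float:
    """Binomial emission probability of one site's counts given a parity state.

    Parameters
    ----------
    site : HetSite
    p : maternal expression proportion, in (0, 1).
    parity : "even" or "odd" — parity of switching errors between this site
        and the reference site.  Even keeps the predicted phase; odd flips it.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if parity not in ("even", "odd"):
        raise ValueError(f"parity must be 'even' or 'odd', got {parity!r}")
    eff_phase = site.predicted_phase if parity == "even" else 1 - site.predicted_phase
    q = p if eff_phase == 0 else 1.0 - p
    return float(binom.pmf(site.alt_count, site.total_count, q))


def _forward(emit, n: int, pi: np.ndarray, ref: int) -> np.ndarray:
    """Forward recursion anchored at ``ref`` (parity even), in scaled linear
    space for speed, returning log values.

    ``emit(j)`` yields ``(e_j, o_j, m_j)``: the even/odd emission of site j
    rescaled by their elementwise maximum (so one of the two is exactly 1)
    and the log of that scale.  The running state vector is renormalized
    after every step with all scale factors re-accumulated in log space, so
    the recursion does not underflow even at very deep counts.
    """
    stay = 1.0 - pi
    flip = pi
    e_r, o_r, m_r = emit(ref)
    # Reference parity is fixed to even: its emission is a common constant.
    with np.errstate(divide="ignore"):
        log_out = m_r + np.log(e_r)

    def sweep(idx, pair_of):
        a_even = np.ones_like(log_out)
        a_odd = np.zeros_like(log_out)
        scale = np.zeros_like(log_out)
        for j in idx:
            e_j, o_j, m_j = emit(j)
            s, f = stay[pair_of(j)], flip[pair_of(j)]
            n_even = (a_even * s + a_odd * f) * e_j
            n_odd = (a_even * f + a_odd * s) * o_j
            z = n_even + n_odd
            np.maximum(z, 1e-300, out=z)
            a_even = n_even / z
            a_odd = n_odd / z
            scale += np.log(z) + m_j
        with np.errstate(divide="ignore"):
            return scale + np.log(a_even + a_odd)

    right = sweep(range(ref + 1, n), lambda j: j - 1)
    left = sweep(range(ref - 1, -1, -1), lambda j: j)
    return log_out + right + left


def loglik_grid(
    alt_counts: np.ndarray,
    total_counts: np.ndarray,
    phases: np.ndarray,
    pi: np.ndarray,
    p: np.ndarray,
) -> np.ndarray:
    """Vectorized log marginal likelihood over a grid of p values.

    Parameters
    ----------
    alt_counts : array (..., n) — alternate-allele counts per site; leading
        axes batch independent count realisations over the same site layout.
    total_counts : array (n,) — per-site depths (shared across the batch,
        so the reference site is common).
    phases : array broadcastable to ``alt_counts`` — predicted phases.
    pi : array (n - 1,) — adjacent-pair switching-error rates in [0, 0.5].
    p : array (K,) — candidate maternal proportions, each in (0, 1).

    Returns
    -------
    array (..., K) of log likelihoods, each summed over all phasings.
    """
    alt = np.asarray(alt_counts)
    tot = np.asarray(total_counts)
    phases = np.asarray(phases)
    pi = np.atleast_1d(np.asarray(pi, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    n = alt.shape[-1]
    if tot.ndim != 1 or tot.shape[0] != n:
        raise ValueError("total_counts must be 1-D with one entry per site")
    if n > 1 and pi.shape[-1] != n - 1:
        raise ValueError("pi must have length n - 1")
    if np.any((pi < 0) | (pi > 0.5)):
        raise ValueError("switching-error rates must lie in [0, 0.5]")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p values must lie in (0, 1)")
    ref = reference_index(tot)

    if alt.ndim > 1 and np.issubdtype(alt.dtype, np.integer) and tot.max() <= 4096:
        # Batched integer counts at modest depth: tabulate the scaled pmf
        # once per distinct depth and gather per site, instead of
        # materializing emissions for every (replicate, site, grid) triple.
        ph_b = np.broadcast_to(phases, alt.shape)
        tabs = {}
        for d in np.unique(tot):
            xs = np.arange(d + 1)[:, None]
            tab_p = binom.logpmf(xs, d, p)
            tab_q = binom.logpmf(xs, d, 1.0 - p)
            m = np.maximum(tab_p, tab_q)
            tabs[int(d)] = (np.exp(tab_p - m), np.exp(tab_q - m), m)

        def emit(j):
            e_p, e_q, m = tabs[int(tot[j])]
            x = alt[..., j]
            ph0 = (ph_b[..., j] == 0)[..., None]
            return (
                np.where(ph0, e_p[x], e_q[x]),
                np.where(ph0, e_q[x], e_p[x]),
                m[x],
            )

    else:
        lp_mat = binom.logpmf(alt[..., :, None], tot[:, None], p)
        lq_mat = binom.logpmf(alt[..., :, None], tot[:, None], 1.0 - p)
        # phase 0 -> alt on maternal -> success prob p under even parity.
        ph0 = phases[..., :, None] == 0
        loge = np.where(ph0, lp_mat, lq_mat)
        logo = np.where(ph0, lq_mat, lp_mat)
        m_all = np.maximum(loge, logo)
        e_all = np.exp(loge - m_all)
        o_all = np.exp(logo - m_all)

        def emit(j):
            return e_all[..., j, :], o_all[..., j, :], m_all[..., j, :]

    return _forward(emit, n, pi, ref)


def log_marginal_likelihood(gene: "GeneObservation", p: float) -> float:
    """Log of :func:`marginal_likelihood` (log-space forward recursion)."""
    if gene.n == 0:
        raise ValueError("cannot compute likelihood of a gene with no sites")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    out = loglik_grid(
        gene.alt_counts, gene.total_counts, gene.phases,
        gene.pi if gene.n > 1 else np.empty(0), np.array([p]),
    )
    return float(out[0])


def marginal_likelihood(gene: "GeneObservation", p: float) -> float:
    """Likelihood of a gene's counts at maternal proportion p, summed over
    all phasings consistent with the switching-error rates."""
    return float(np.exp(log_marginal_likelihood(gene, p)))
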