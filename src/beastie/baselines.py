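"""Baseline gene-level ASE callers: MajorSite, NaiveSum, pseudo-phasing.

Each reduces a gene to a single binomial test of allelic balance:

* MajorSite uses only the deepest site (information at other sites is
  discarded).
* NaiveSum aggregates counts across sites onto haplotypes using the
  predicted phasing at face value — any switching error sums incorrect
  counts together.
* Pseudo-phasing assigns the higher-count allele at every site to the same
  haplotype.  Under the null this systematically manufactures imbalance and
  inflates type-I error, which is why it is off by default.

P-values come from the exact two-sided binomial test against 1/2 ("minlike"
two-sided convention: sum of all outcome probabilities no larger than the
observed one).  The ROC score is -log10 p (larger = more evidence of ASE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .io_counts import GeneObservation

__all__ = ["BaselineScore", "major_site", "naive_sum", "pseudo_phase"]


@dataclass(frozen=True)
class BaselineScore:
    gene_id: str
    method: str
    statistic: float  # estimated haplotype-1 allelic ratio
    pvalue: float

    @property
    def score(self) -> float:
        """ROC score, -log10 p."""
        return -np.log10(self.pvalue)


def _binom_score(gene_id: str, method: str, k: int, n: int) -> BaselineScore:
    pval = binomtest(k, n, 0.5).pvalue
    return BaselineScore(gene_id, method, k / n, pval)


def major_site(gene: GeneObservation) -> BaselineScore:
    """Test allelic balance at the single deepest site (ties: lowest position)."""
    if gene.n == 0:
        raise ValueError(f"{gene.gene_id}: gene has no sites")
    idx = int(np.argmax(gene.total_counts))
    s = gene.sites[idx]
    return _binom_score(gene.gene_id, "MajorSite", s.alt_count, s.total_count)


def naive_sum(gene: GeneObservation) -> BaselineScore:
    """Aggregate counts onto haplotype 1 using the predicted phasing as-is."""
    if gene.n == 0:
        raise ValueError(f"{gene.gene_id}: gene has no sites")
    alt = gene.alt_counts
    tot = gene.total_counts
    hap1 = int(np.sum(np.where(gene.phases == 0, alt, tot - alt)))
    return _binom_score(gene.gene_id, "NaiveSum", hap1, int(tot.sum()))


def pseudo_phase(gene: GeneObservation) -> BaselineScore:
    """Assign the majority allele of every site to haplotype 1 (ties: the
    alternate allele).  Anti-conservative under the null; kept for the
    type-I-error comparison only."""
    if gene.n == 0:
        raise ValueError(f"{gene.gene_id}: gene has no sites")
    alt = gene.alt_counts
    tot = gene.total_counts
    ref = tot - alt
    hap1 = int(np.sum(np.where(alt >= ref, alt, ref)))
    return _binom_score(gene.gene_id, "PseudoPhase", hap1, int(tot.sum()))
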