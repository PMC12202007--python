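"""Synthetic gene generator with known ASE effect and phasing corruption.

Each simulated gene has ``n_hets`` heterozygous sites.  The true haplotype
carrying the alternate allele is drawn uniformly per site; alternate counts
are Binomial(N_i, p) or Binomial(N_i, 1 - p) accordingly, with
p = θ / (1 + θ).  The *predicted* phasing handed to downstream methods is
the true relative phasing corrupted by a switch process: between each
adjacent pair of sites, with probability ``switch_rate`` all downstream
predicted phases flip — exactly the error mode of statistical phasers.

Defaults mirror the benchmark conditions used throughout: 10 het sites per
gene, fixed per-site depth, θ = 0.5 positives against θ = 1 nulls, and
switch rates of a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .io_counts import GeneObservation, HetSite

__all__ = ["SimConfig", "GeneTruth", "simulate_gene", "simulate_cohort",
           "simulate_odd_switch_cohort", "write_truth_tsv"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings for one cohort."""

    n_genes: int = 1000
    n_hets: int = 10
    depth: int = 10
    theta: float = 0.5
    switch_rate: float = 0.05
    seed: int = 0
    depth_model: str = "fixed"  # "fixed" | "poisson"
    spacing: int = 500  # bp between adjacent synthetic sites

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_hets < 1 or self.depth < 1 or self.spacing < 1:
            raise ValueError("n_genes, n_hets, depth and spacing must be positive")
        if not 0.0 <= self.switch_rate <= 0.5:
            raise ValueError("switch_rate must lie in [0, 0.5]")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError("depth_model must be 'fixed' or 'poisson'")


@dataclass
class GeneTruth:
    """Ground truth stored alongside each simulated gene."""

    gene_id: str
    theta: float
    true_phases: np.ndarray  # 0 = alt allele on maternal copy
    switch_positions: np.ndarray  # indices i of switched pairs (i, i+1)


def _draw_switches(n_pairs: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    return rng.random(n_pairs) < rate


def simulate_gene(
    cfg: SimConfig,
    rng: np.random.Generator,
    gene_id: str = "gene",
    theta: Optional[float] = None,
    switches: Optional[np.ndarray] = None,
) -> Tuple[GeneObservation, GeneTruth]:
    """Simulate one gene; returns the observation (with *predicted* phasing)
    and its truth record.

    ``theta``/``switches`` override the config for cohort construction.
    """
    theta = cfg.theta if theta is None else theta
    p = theta / (1.0 + theta)
    n = cfg.n_hets
    if cfg.depth_model == "poisson":
        depths = np.maximum(rng.poisson(cfg.depth, size=n), 1)
    else:
        depths = np.full(n, cfg.depth)
    true_phases = rng.integers(0, 2, size=n)
    # phase 0 -> alt on maternal -> alt counts at success prob p
    q = np.where(true_phases == 0, p, 1.0 - p)
    alt = rng.binomial(depths, q)
    if switches is None:
        switches = _draw_switches(n - 1, cfg.switch_rate, rng)
    parity = np.concatenate([[0], np.cumsum(switches.astype(int)) % 2])
    predicted = true_phases ^ parity
    positions = 1000 + cfg.spacing * np.arange(n)
    sites = [
        HetSite("chrSim", int(positions[i]), "A", "G",
                int(depths[i]), int(alt[i]), int(predicted[i]))
        for i in range(n)
    ]
    obs = GeneObservation(gene_id, sites, None)
    truth = GeneTruth(gene_id, theta, true_phases, np.nonzero(switches)[0])
    return obs, truth


def simulate_cohort(cfg: SimConfig) -> Tuple[List[GeneObservation], np.ndarray, List[GeneTruth]]:
    """A labeled cohort: ``n_genes`` positives at cfg.theta and ``n_genes``
    negatives at θ = 1, sharing depth, site count and switch rate.

    Returns (genes, labels, truths); label 1 marks the ASE-positive class.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes: List[GeneObservation] = []
    truths: List[GeneTruth] = []
    labels = np.concatenate([np.ones(cfg.n_genes, int), np.zeros(cfg.n_genes, int)])
    for i in range(cfg.n_genes):
        g, t = simulate_gene(cfg, rng, gene_id=f"pos{i:05d}")
        genes.append(g)
        truths.append(t)
    for i in range(cfg.n_genes):
        g, t = simulate_gene(cfg, rng, gene_id=f"neg{i:05d}", theta=1.0)
        genes.append(g)
        truths.append(t)
    return genes, labels, truths


def _per_pair_rate_for_odd(target: float, n_pairs: int) -> float:
    """Per-pair switch probability s such that, conditional on an odd total
    number of switches among ``n_pairs`` i.i.d. Bernoulli(s) draws, the
    marginal per-pair switch rate equals ``target``.

    P(pair flipped | odd total) = s (1 + (1-2s)^(k-1)) / (1 - (1-2s)^k).
    """
    if n_pairs == 1:
        return 1.0  # conditioning on odd forces the single pair to flip

    def gap(s):
        r = 1.0 - 2.0 * s
        return s * (1.0 + r ** (n_pairs - 1)) / (1.0 - r ** n_pairs) - target

    # conditional rate at s -> 0 tends to 1/n_pairs; below that it is infeasible
    if target <= 1.0 / n_pairs:
        raise ValueError(
            f"odd-parity conditioning cannot give marginal rate below 1/{n_pairs}"
        )
    return brentq(gap, 1e-9, 0.5 - 1e-9)


def simulate_odd_switch_cohort(cfg: SimConfig) -> Tuple[List[GeneObservation], np.ndarray, List[GeneTruth]]:
    """Like :func:`simulate_cohort` but every gene carries an ODD number of
    switch errors (the hardest regime for phasing-naive aggregation: an odd
    parity guarantees at least part of the gene is mis-phased).

    Switch patterns are rejection-sampled to odd parity, with the per-pair
    rate calibrated so the marginal pair-level switch rate still equals
    ``cfg.switch_rate``.
    """
    if cfg.n_hets < 2:
        raise ValueError("odd-switch cohorts need at least 2 het sites")
    s = _per_pair_rate_for_odd(cfg.switch_rate, cfg.n_hets - 1)
    rng = np.random.default_rng(cfg.seed)

    def odd_switches():
        while True:
            sw = _draw_switches(cfg.n_hets - 1, s, rng)
            if sw.sum() % 2 == 1:
                return sw

    genes: List[GeneObservation] = []
    truths: List[GeneTruth] = []
    labels = np.concatenate([np.ones(cfg.n_genes, int), np.zeros(cfg.n_genes, int)])
    for i in range(cfg.n_genes):
        g, t = simulate_gene(cfg, rng, gene_id=f"pos{i:05d}", switches=odd_switches())
        genes.append(g)
        truths.append(t)
    for i in range(cfg.n_genes):
        g, t = simulate_gene(cfg, rng, gene_id=f"neg{i:05d}", theta=1.0,
                             switches=odd_switches())
        genes.append(g)
        truths.append(t)
    return genes, labels, truths


def write_truth_tsv(truths: List[GeneTruth], path) -> None:
    import pandas as pd

    rows = [
        (t.gene_id, t.theta,
         "".join(map(str, t.true_phases)),
         ",".join(map(str, t.switch_positions)) or ".")
        for t in truths
    ]
    pd.DataFrame(rows, columns=["gene_id", "theta", "true_phase", "switch_positions"]).to_csv(
        path, sep="\t", index=False
    )
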