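"""Domain types and file I/O: phased VCF, per-site count tables, results.

Also implements the count-level quality steps applied before inference:
site thinning (so no two sites fall within a read length, which would
double-count reads spanning both) and a genotyping-error filter (monoallelic
counts at high depth are far more often genotyping mistakes than true
mono-allelic expression).

Coordinates are 1-based internally (as in VCF); gene intervals are
half-open ``[start, end)`` in 0-based BED convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HetSite",
    "GeneObservation",
    "read_gene_map",
    "read_phased_vcf",
    "thin_sites",
    "filter_genotyping_errors",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_results_tsv",
    "read_results_tsv",
]

COUNTS_COLUMNS = ["gene_id", "chrom", "pos", "ref", "alt", "totalCount", "altCount", "phase", "pi"]
RESULTS_COLUMNS = [
    "gene_id", "n_hets", "total_reads", "theta_median", "log2_theta",
    "abs_log2_theta", "ci_lower", "ci_upper", "pvalue", "fdr", "ase_call",
]


@dataclass(frozen=True)
class HetSite:
    """One exonic heterozygous SNV with allelic read counts.

    ``predicted_phase`` is 0 when the alternate allele is predicted to lie on
    haplotype 1 (the first field of a phased GT), 1 when on haplotype 2.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    total_count: int
    alt_count: int
    predicted_phase: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not 0 <= self.alt_count <= self.total_count:
            raise ValueError(
                f"require 0 <= alt_count <= total_count, got {self.alt_count}/{self.total_count}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.predicted_phase not in (0, 1):
            raise ValueError("predicted_phase must be 0 or 1")


@dataclass
class GeneObservation:
    """Ordered heterozygous sites of one gene plus switching-error rates.

    ``pi[i]`` is the probability of a phasing switch error between adjacent
    sites ``i`` and ``i + 1``; it may be None until populated (from SELR
    predictions, user input, or a fixed default).
    """

    gene_id: str
    sites: List[HetSite] = field(default_factory=list)
    pi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        positions = [s.pos for s in self.sites]
        chroms = {s.chrom for s in self.sites}
        if len(chroms) > 1:
            raise ValueError(f"{self.gene_id}: sites span multiple chromosomes")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"{self.gene_id}: sites must be strictly increasing in position")
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)
            if len(self.pi) != max(self.n - 1, 0):
                raise ValueError(f"{self.gene_id}: pi must have length n - 1")
            if np.any((self.pi < 0) | (self.pi > 0.5)):
                raise ValueError(f"{self.gene_id}: pi values must lie in [0, 0.5]")

    @property
    def n(self) -> int:
        return len(self.sites)

    @property
    def total_counts(self) -> np.ndarray:
        return np.array([s.total_count for s in self.sites], dtype=np.int64)

    @property
    def alt_counts(self) -> np.ndarray:
        return np.array([s.alt_count for s in self.sites], dtype=np.int64)

    @property
    def phases(self) -> np.ndarray:
        return np.array([s.predicted_phase for s in self.sites], dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def with_pi(self, pi) -> "GeneObservation":
        """Copy of this gene with the switching-error vector replaced.

        A scalar is broadcast to every adjacent pair.
        """
        pi = np.asarray(pi, dtype=float)
        if pi.ndim == 0:
            pi = np.full(max(self.n - 1, 0), float(pi))
        return GeneObservation(self.gene_id, list(self.sites), pi)


def read_gene_map(path) -> Dict[str, tuple]:
    """Read a gene annotation map: ``gene_id -> (chrom, start, end)``.

    Accepts BED (chrom, start, end, name; 0-based half-open) or a
    two-column TSV ``gene_id <TAB> chrom:start-end`` (also half-open).
    """
    out: Dict[str, tuple] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4 and fields[1].isdigit():
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            elif len(fields) == 2:
                name = fields[0]
                chrom, rng = fields[1].split(":")
                start_s, end_s = rng.split("-")
                start, end = int(start_s), int(end_s)
            else:
                raise ValueError(f"unrecognized gene-map line: {line!r}")
            out[name] = (chrom, start, end)
    return out


def read_phased_vcf(vcf_path, sample: str, gene_map: Dict[str, tuple]) -> Dict[str, GeneObservation]:
    """Extract phased heterozygous biallelic SNVs per gene from a VCF.

    Only records with a phased heterozygous genotype ("0|1" or "1|0") are
    retained; GT "1|0" gives predicted_phase 0 (alt on haplotype 1), "0|1"
    gives 1.  Unphased heterozygous records ("0/1") are counted and skipped
    with a warning, never silently phased.  Allelic counts are left at zero:
    counting reads from alignments is upstream of this tool.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    if sample not in vf.header.samples:
        raise ValueError(f"sample {sample!r} not present in {vcf_path}")
    n_unphased = 0
    n_malformed = 0
    parsed: List[HetSite] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue
        call = rec.samples[sample]
        gt = call.get("GT")
        if gt is None or len(gt) != 2 or None in gt:
            n_malformed += 1
            continue
        if set(gt) != {0, 1}:
            continue  # homozygous genotype
        if not call.phased:
            n_unphased += 1
            continue
        phase = 0 if gt == (1, 0) else 1
        parsed.append(HetSite(rec.chrom, rec.pos, rec.ref, rec.alts[0], 0, 0, phase))
    genes: Dict[str, GeneObservation] = {}
    for gene_id, (chrom, start, end) in gene_map.items():
        sites = sorted(
            (s for s in parsed if s.chrom == chrom and start < s.pos <= end),
            key=lambda s: s.pos,
        )
        genes[gene_id] = GeneObservation(gene_id, sites)
    if n_unphased or n_malformed:
        warnings.warn(
            f"skipped {n_unphased} unphased and {n_malformed} malformed genotypes",
            stacklevel=2,
        )
    return genes


def thin_sites(sites: Sequence[HetSite], read_length: int) -> List[HetSite]:
    """Greedily drop sites so that no two retained sites are within a read
    length of each other (avoids double-counting reads that span both).

    Sites are considered in descending total count (ties: lower position
    first); each is kept iff it is at least ``read_length`` away from every
    site already kept.  Output is position-sorted and independent of the
    input ordering.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    order = sorted(sites, key=lambda s: (-s.total_count, s.pos))
    kept: List[HetSite] = []
    for cand in order:
        if all(abs(cand.pos - k.pos) >= read_length or cand.chrom != k.chrom for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda s: (s.chrom, s.pos))


def filter_genotyping_errors(
    gene: GeneObservation,
    min_depth: int = 1,
    max_monoallelic_depth: Optional[int] = 20,
) -> GeneObservation:
    """Drop sites whose counts look like genotyping errors.

    A site with zero reads on one allele despite deep coverage
    (``>= max_monoallelic_depth``) is more plausibly a mislabelled homozygous
    site than true mono-allelic expression, and is removed.  Sites below
    ``min_depth`` total reads are removed.  Pass ``max_monoallelic_depth=None``
    to disable the monoallelic rule.  The surviving ``pi`` entries are
    dropped entirely (adjacency changes), so ``pi`` must be re-derived.
    """
    if min_depth < 0 or (max_monoallelic_depth is not None and max_monoallelic_depth < 0):
        raise ValueError("thresholds must be non-negative")
    kept = []
    for s in gene.sites:
        if s.total_count < min_depth:
            continue
        if (
            max_monoallelic_depth is not None
            and s.total_count >= max_monoallelic_depth
            and s.alt_count in (0, s.total_count)
        ):
            continue
        kept.append(s)
    return GeneObservation(gene.gene_id, kept, None)


def read_counts_tsv(path) -> List[GeneObservation]:
    """Read a per-site counts table into GeneObservation records.

    Columns: ``gene_id chrom pos ref alt totalCount altCount phase [pi]``;
    the optional ``pi`` column holds the switching-error rate between a row
    and the next row of the same gene (empty on each gene's last row).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in COUNTS_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise ValueError(f"counts TSV missing columns: {missing}")
    genes: List[GeneObservation] = []
    for gene_id, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("pos")
        sites = [
            HetSite(str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                    int(r.totalCount), int(r.altCount), int(r.phase))
            for r in sub.itertuples()
        ]
        pi = None
        if "pi" in sub.columns:
            vals = sub["pi"].to_numpy(dtype=float)[:-1]
            if len(vals) == 0 or not np.any(np.isnan(vals)):
                pi = vals
        genes.append(GeneObservation(str(gene_id), sites, pi))
    return genes


def write_counts_tsv(genes: Sequence[GeneObservation], path) -> None:
    rows = []
    for g in genes:
        for i, s in enumerate(g.sites):
            pi_val = ""
            if g.pi is not None and i < g.n - 1:
                pi_val = f"{g.pi[i]:.10g}"
            rows.append(
                (g.gene_id, s.chrom, s.pos, s.ref_allele, s.alt_allele,
                 s.total_count, s.alt_count, s.predicted_phase, pi_val)
            )
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


def write_results_tsv(results, path) -> None:
    """Write per-gene inference results; floats keep 12 significant digits so
    a round-trip read reproduces values to at least 10 significant digits."""
    rows = [
        (r.gene_id, r.n_hets, r.total_reads, r.theta_median, r.log2_theta,
         r.abs_log2_theta, r.ci_lower, r.ci_upper, r.pvalue, r.fdr, r.ase_call)
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
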