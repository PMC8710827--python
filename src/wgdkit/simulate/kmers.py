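"""Synthetic k-mer depth histograms for genome-size estimation.

Two modes. ``mixture`` composes the expected histogram directly: a main
peak at the effective per-copy k-mer coverage, a heterozygous peak at half
that depth (k-mers overlapping a heterozygous site exist in one haplotype
only, at twice the distinct-k-mer count), and error k-mers piled at depth 1.
``reads`` simulates shotgun reads from a random diploid genome, injects
errors and counts canonical k-mers for real; it is the slower, assumption-free
cross-check of the analytic mixture and only suits sub-megabase genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..kmer import KmerHistogram, count_kmers

_BASES = np.array(list("ACGT"))


@dataclass
class KmerScenario:
    genome_size_bp: int
    coverage: float
    error_rate: float = 0.0
    heterozygosity: float = 0.0
    k: int = 17
    read_length: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.k < 11 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 11")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.coverage < 5:
            warnings.warn("coverage < 5: error and coverage peaks may merge",
                          stacklevel=2)

    @property
    def effective_depth(self) -> float:
        """Per-copy k-mer depth: base coverage thinned by errors and read ends."""
        return (self.coverage * (1.0 - self.error_rate) ** self.k
                * (self.read_length - self.k + 1) / self.read_length)


def simulate_kmer_histogram(scenario: KmerScenario, mode: str = "mixture") -> KmerHistogram:
    if mode == "mixture":
        return _mixture_histogram(scenario)
    if mode == "reads":
        return _read_histogram(scenario)
    raise ValueError(f"unknown mode {mode!r}")


def _mixture_histogram(scenario: KmerScenario) -> KmerHistogram:
    c = scenario.effective_depth
    n_loci = scenario.genome_size_bp  # ~ one distinct k-mer locus per position
    p_het = 1.0 - (1.0 - scenario.heterozygosity) ** scenario.k
    n_hom = n_loci * (1.0 - p_het)
    n_het = 2.0 * n_loci * p_het  # each het locus yields two haplotype-specific k-mers
    max_depth = int(np.ceil(c + 6 * np.sqrt(c))) + 2
    depths = np.arange(1, max_depth + 1)
    expected = (n_hom * stats.poisson.pmf(depths, c)
                + n_het * stats.poisson.pmf(depths, c / 2.0))
    # error k-mers: nearly all unique; one read error spoils up to k k-mers
    n_err = scenario.genome_size_bp * scenario.coverage * scenario.error_rate * scenario.k
    expected[0] += n_err
    counts = np.rint(expected).astype(np.int64)
    return KmerHistogram(k=scenario.k,
                         counts={int(d): int(n) for d, n in zip(depths, counts) if n > 0})


def _read_histogram(scenario: KmerScenario) -> KmerHistogram:
    rng = np.random.default_rng(scenario.seed)
    G = scenario.genome_size_bp
    if G > 2_000_000:
        raise ValueError("reads mode is for small genomes (<= 2 Mb); use mixture mode")
    hap1 = rng.integers(0, 4, size=G, dtype=np.int8)
    hap2 = hap1.copy()
    n_het = rng.binomial(G, scenario.heterozygosity)
    if n_het:
        pos = rng.choice(G, size=n_het, replace=False)
        hap2[pos] = (hap2[pos] + rng.integers(1, 4, size=n_het)) % 4
    L = scenario.read_length
    n_reads = int(round(scenario.coverage * G / L))
    reads = []
    for h in (hap1, hap2):
        starts = rng.integers(0, G - L + 1, size=n_reads // 2)
        for s in starts:
            read = h[s:s + L].copy()
            n_err = rng.binomial(L, scenario.error_rate)
            if n_err:
                epos = rng.choice(L, size=n_err, replace=False)
                read[epos] = (read[epos] + rng.integers(1, 4, size=n_err)) % 4
            reads.append("".join(_BASES[read]))
    return count_kmers(reads, scenario.k)
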