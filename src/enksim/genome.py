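"""Genetic map, meiosis under the Haldane model, crossing, SSD + DH.

The genome is 10 chromosomes of 1 Morgan each, with 50 loci per chromosome
evenly spaced at positions (j - 0.5)/50 Morgan (500 loci total). Meiosis
follows the Haldane mapping function: crossover counts are Poisson with mean
equal to the chromosome length in Morgan, crossover positions are uniform,
there is no interference, and chromosomes assort independently.

Recombinant inbred lines are derived from an F1 by three generations of
single seed descent selfing followed by one doubled-haploidy step, which
removes all residual heterozygosity.

Populations of lines are represented as haplotype arrays; the batched
functions (`gametes_batch`, `self_batch`, `ssd_dh_batch`) are what the
breeding engine uses, while `meiosis`/`make_cross`/`ssd_then_dh` provide the
single-individual interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from enksim.exceptions import ConfigurationError


@dataclass(frozen=True)
class GenomeMap:
    n_chromosomes: int = 10
    n_loci_per_chrom: int = 50
    chrom_length: float = 1.0  # Morgan
    positions: np.ndarray = field(init=False, repr=False)  # within-chromosome, Morgan

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.n_loci_per_chrom < 1:
            raise ConfigurationError("map dimensions must be positive")
        j = np.arange(self.n_loci_per_chrom)
        pos = (j + 0.5) / self.n_loci_per_chrom * self.chrom_length
        object.__setattr__(self, "positions", pos)

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.n_loci_per_chrom

    def chrom_slice(self, c: int) -> slice:
        return slice(c * self.n_loci_per_chrom, (c + 1) * self.n_loci_per_chrom)

    def locus_table(self):
        """(chromosome, position-Morgan) pairs for all loci in genome order."""
        chrom = np.repeat(np.arange(self.n_chromosomes), self.n_loci_per_chrom)
        pos = np.tile(self.positions, self.n_chromosomes)
        return chrom, pos


@dataclass
class Individual:
    """A diploid individual as a pair of binary haplotypes."""

    hap_a: np.ndarray
    hap_b: np.ndarray

    def __post_init__(self):
        self.hap_a = np.asarray(self.hap_a, dtype=np.uint8)
        self.hap_b = np.asarray(self.hap_b, dtype=np.uint8)
        if self.hap_a.shape != self.hap_b.shape:
            raise ConfigurationError("haplotypes must have equal length")

    @property
    def dosage(self) -> np.ndarray:
        return (self.hap_a + self.hap_b).astype(np.int64)

    @property
    def is_homozygous(self) -> bool:
        return bool((self.hap_a == self.hap_b).all())


def gametes_batch(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per row of a batch of individuals.

    ``hap_a`` and ``hap_b`` are (B, n_loci) arrays. Per chromosome the number
    of crossovers is Poisson(length), positions are uniform, and the starting
    parental phase is equiprobable.
    """
    B, n = hap_a.shape
    nc, nl, L = gmap.n_chromosomes, gmap.n_loci_per_chrom, gmap.chrom_length
    counts = rng.poisson(L, size=(B, nc))
    starts = rng.integers(0, 2, size=(B, nc))
    m = int(counts.max()) if B else 0
    if m > 0:
        x = rng.uniform(0.0, L, size=(B, nc, m))
        valid = np.arange(m)[None, None, :] < counts[:, :, None]
        # bin each crossover to the first locus at or beyond it, then a
        # cumulative sum gives the number of crossovers before every locus
        k = np.searchsorted(gmap.positions, x[valid])
        row, chrom, _ = np.nonzero(valid)
        flat = (row * nc + chrom) * (nl + 1) + k
        delta = np.bincount(flat, minlength=B * nc * (nl + 1)).reshape(
            B, nc, nl + 1
        )
        phase = (starts[:, :, None] + delta.cumsum(axis=2)[:, :, :nl]) % 2
    else:
        phase = np.broadcast_to(starts[:, :, None] % 2, (B, nc, nl))
    phase = phase.reshape(B, n)
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8, copy=False)


def meiosis(ind: Individual, gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete (binary haplotype) from one individual."""
    return gametes_batch(ind.hap_a[None, :], ind.hap_b[None, :], gmap, rng)[0]


def make_cross(
    p1: Individual, p2: Individual, gmap: GenomeMap, rng: np.random.Generator
) -> Individual:
    """F1 offspring: one meiosis from each parent."""
    return Individual(meiosis(p1, gmap, rng), meiosis(p2, gmap, rng))


def self_batch(hap_a, hap_b, gmap, rng):
    """Self-fertilize each individual once, keeping one offspring each."""
    return gametes_batch(hap_a, hap_b, gmap, rng), gametes_batch(hap_a, hap_b, gmap, rng)


def ssd_dh_batch(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
    n_ssd: int = 3,
) -> np.ndarray:
    """Recombinant inbred lines from a batch of F1s.

    ``n_ssd`` generations of single seed descent selfing, then one doubled
    haploid per plant. Returns the (B, n_loci) haplotype of each fully
    homozygous line.
    """
    a, b = hap_a, hap_b
    for _ in range(n_ssd):
        a, b = self_batch(a, b, gmap, rng)
    return gametes_batch(a, b, gmap, rng)


def ssd_then_dh(
    f1: Individual, gmap: GenomeMap, rng: np.random.Generator, n_ssd: int = 3
) -> Individual:
    """Single-individual SSD + DH; the result is homozygous at every locus."""
    hap = ssd_dh_batch(f1.hap_a[None, :], f1.hap_b[None, :], gmap, rng, n_ssd)[0]
    return Individual(hap, hap.copy())


def dosage_frame(haplotypes: np.ndarray, gmap: GenomeMap):
    """Lines x loci dosage table with a (chromosome, position) header.

    ``haplotypes`` is the (n_lines, n_loci) haplotype matrix of homozygous
    lines (dosage = 2 * haplotype).
    """
    import pandas as pd

    chrom, pos = gmap.locus_table()
    cols = [f"chr{c + 1}_{p:.3f}" for c, p in zip(chrom, pos)]
    return pd.DataFrame(2 * haplotypes.astype(np.int64), columns=cols)
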