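"""Stochastic generation of the inbred founder population.

The base population is 1,000 fully homozygous lines whose genotypes satisfy
two target properties: (i) minor allele frequencies uniform on [0.35, 0.50]
and (ii) expected pairwise linkage disequilibrium between loci ``t`` Morgan
apart of r^2 = 0.5 * 2^(-t / 0.1), decaying within chromosomes and absent
across chromosomes.

Generation mechanism: per chromosome, line haplotypes are thresholded
realizations of a stationary Gaussian process along the map. The latent
autocorrelation rho(t) is calibrated numerically (via the bivariate normal
orthant probability, evaluated with Owen's T function) so that the expected
squared correlation of the thresholded binary indicators — averaged over the
allele-frequency distribution and random allele labeling — matches the target
r^2 curve at every inter-locus distance. The resulting correlation matrix is
eigenvalue-clipped to the nearest PSD matrix if needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import ndtr, ndtri, owens_t

from enksim.exceptions import ConfigurationError
from enksim.genome import GenomeMap


@dataclass(frozen=True)
class BasePopulationSpec:
    n_lines: int = 1000
    ld_at_zero: float = 0.5
    ld_halving_distance: float = 0.1  # Morgan
    maf_low: float = 0.35
    maf_high: float = 0.50

    def __post_init__(self):
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ConfigurationError("need 0 < maf_low <= maf_high <= 0.5")
        if not 0 < self.ld_at_zero <= 1:
            raise ConfigurationError("ld_at_zero must be in (0, 1]")
        if self.ld_halving_distance <= 0:
            raise ConfigurationError("ld_halving_distance must be > 0")

    def target_r2(self, t):
        """Expected r^2 between loci ``t`` Morgan apart."""
        return self.ld_at_zero * 2.0 ** (-np.asarray(t, dtype=float) / self.ld_halving_distance)


def _bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Owen (1956) formula; valid here because the thresholds used are never 0.
    """
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    rho = np.asarray(rho, float)
    denom = np.sqrt(np.maximum(1.0 - rho**2, 1e-300))
    ah = (k - rho * h) / (h * denom)
    ak = (h - rho * k) / (k * denom)
    beta = np.where(h * k > 0, 0.0, 0.5)
    return (
        0.5 * (ndtr(h) + ndtr(k))
        - owens_t(h, ah)
        - owens_t(k, ak)
        - beta
    )


def _indicator_r2(h, k, rho):
    """Squared correlation of threshold indicators under latent correlation rho."""
    p = ndtr(h)
    q = ndtr(k)
    p11 = _bvn_cdf(h, k, rho)
    r = (p11 - p * q) / np.sqrt(p * (1 - p) * q * (1 - q))
    return r**2


@lru_cache(maxsize=32)
def _latent_correlations(
    distances: tuple, ld_at_zero: float, halving: float, maf_low: float, maf_high: float
) -> np.ndarray:
    """Latent Gaussian correlation for each map distance.

    Solves, per distance, for rho >= 0 such that the mean indicator r^2 —
    averaged over a quadrature grid of threshold pairs from the MAF
    distribution and over random allele labeling (sign of rho) — equals the
    target r^2 curve.
    """
    d = np.asarray(distances, dtype=float)
    target = ld_at_zero * 2.0 ** (-d / halving)
    # quadrature over allele-frequency pairs (midpoint rule, 4 x 4)
    grid = maf_low + (maf_high - maf_low) * (np.arange(4) + 0.5) / 4
    P, Q = np.meshgrid(grid, grid)
    h = ndtri(P.ravel())
    k = ndtri(Q.ravel())

    def mean_r2(rho_scalar):
        r2p = _indicator_r2(h, k, rho_scalar)
        r2m = _indicator_r2(h, k, -rho_scalar)
        return 0.5 * (r2p.mean() + r2m.mean())

    out = np.empty(d.size)
    for i, tgt in enumerate(target):
        lo, hi = 0.0, 0.9999
        if mean_r2(hi) <= tgt:
            out[i] = hi
            continue
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if mean_r2(mid) < tgt:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi)
    return out


def _chromosome_correlation_matrix(spec: BasePopulationSpec, gmap: GenomeMap):
    pos = gmap.positions
    dist = np.abs(pos[:, None] - pos[None, :])
    uniq = np.unique(dist[dist > 0])
    rho_u = _latent_correlations(
        tuple(np.round(uniq, 12)),
        spec.ld_at_zero,
        spec.ld_halving_distance,
        spec.maf_low,
        spec.maf_high,
    )
    lookup = dict(zip(np.round(uniq, 12), rho_u))
    R = np.ones_like(dist)
    nz = dist > 0
    R[nz] = np.vectorize(lambda t: lookup[round(t, 12)])(dist[nz])
    # clip to PSD if the assembled matrix is slightly indefinite
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-10:
        w = np.maximum(w, 1e-10)
        R = (V * w) @ V.T
        s = np.sqrt(np.diag(R))
        R = R / np.outer(s, s)
    return np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))


def simulate_base_population(
    spec: BasePopulationSpec, gmap: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """Generate the founder lines as a (n_lines, n_loci) haplotype matrix.

    Lines are fully homozygous, so the returned binary haplotypes double as
    genotypes (dosage = 2 * haplotype). Chromosomes are generated
    independently; within a chromosome, loci follow the calibrated latent
    Gaussian process thresholded at per-locus allele-frequency quantiles.
    """
    chol = _chromosome_correlation_matrix(spec, gmap)
    n, m = spec.n_lines, gmap.n_loci_per_chrom
    maf = rng.uniform(spec.maf_low, spec.maf_high, size=gmap.n_loci)
    # random allele labeling: the '1' allele is the minor one with prob 1/2
    p1 = np.where(rng.random(gmap.n_loci) < 0.5, maf, 1.0 - maf)
    haps = np.empty((n, gmap.n_loci), dtype=np.uint8)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        z = rng.standard_normal((n, m)) @ chol.T
        haps[:, sl] = (z < ndtri(p1[sl])[None, :]).astype(np.uint8)
    return haps


@dataclass(frozen=True)
class PopulationPartition:
    """Assignment of founder lines to heterotic groups and subpopulations."""

    heterotic_group: np.ndarray  # 1 or 2, per line
    subpopulation: np.ndarray  # program index 0..n_programs-1, per line

    def members(self, group: int, subpop: int) -> np.ndarray:
        return np.flatnonzero(
            (self.heterotic_group == group) & (self.subpopulation == subpop)
        )

    def to_frame(self):
        """Partition table: one row per line (line_id, group, subpopulation)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "line_id": np.arange(self.heterotic_group.size),
                "group": self.heterotic_group,
                "subpopulation": self.subpopulation,
            }
        )


def partition_population(
    n_lines: int, n_programs: int, rng: np.random.Generator
) -> PopulationPartition:
    """Random split into two equal heterotic groups and equal subpopulations.

    Subpopulation ``i`` of group 1 is paired with subpopulation ``i`` of group
    2 to form breeding program ``i``.
    """
    if n_lines % 2:
        raise ConfigurationError("n_lines must be even")
    half = n_lines // 2
    if half % n_programs:
        raise ConfigurationError(
            f"group size {half} not divisible by {n_programs} programs"
        )
    perm = rng.permutation(n_lines)
    group = np.empty(n_lines, dtype=np.int64)
    group[perm[:half]] = 1
    group[perm[half:]] = 2
    sub = np.empty(n_lines, dtype=np.int64)
    per = half // n_programs
    for g, idx in ((1, perm[:half]), (2, perm[half:])):
        sub[idx] = np.repeat(np.arange(n_programs), per)
    return PopulationPartition(group, sub)


def mean_r2_by_distance(haps: np.ndarray, gmap: GenomeMap, n_bins: int = 20):
    """Binned mean pairwise r^2 within chromosomes vs map distance.

    ``haps`` is a lines x loci matrix of homozygous-line haplotypes (allele
    indicators). Pairs involving a monomorphic locus are skipped. Returns
    (bin centers, mean r^2 per bin).
    """
    edges = np.linspace(0.0, gmap.chrom_length, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for c in range(gmap.n_chromosomes):
        sl = gmap.chrom_slice(c)
        X = haps[:, sl].astype(float)
        sd = X.std(axis=0)
        poly = sd > 0
        if poly.sum() < 2:
            continue
        Xp = X[:, poly]
        pos = gmap.positions[poly]
        C = np.corrcoef(Xp, rowvar=False) ** 2
        iu = np.triu_indices(Xp.shape[1], k=1)
        d = np.abs(pos[iu[0]] - pos[iu[1]])
        r2 = C[iu]
        which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
        np.add.at(sums, which, r2)
        np.add.at(counts, which, 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        return centers, np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def fit_ld_decay(centers: np.ndarray, mean_r2: np.ndarray, max_distance: float = 0.5):
    """Fit r^2(t) = a * 2^(-t/b) to binned mean r^2; returns (a, b).

    Linear least squares on log2 of the binned means. Bins beyond
    ``max_distance`` are excluded: there the true r^2 falls below the
    finite-sample noise floor (~1/n_lines) and would bias the log fit.
    """
    ok = np.isfinite(mean_r2) & (mean_r2 > 0) & (centers <= max_distance)
    y = np.log2(mean_r2[ok])
    A = np.vstack([np.ones(ok.sum()), -centers[ok]]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a = 2.0 ** coef[0]
    b = 1.0 / coef[1] if coef[1] != 0 else np.inf
    return float(a), float(b)
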