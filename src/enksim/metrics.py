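"""Quantitative- and population-genetic statistics recorded per breeding cycle.

%GCA        proportion of general-combining-ability variance in the total
            genetic variance of the testcross factorial (two-way
            random-effects decomposition, Henderson method 3)
GCA corr.   transferability of GCA effects across programs: correlation of a
            line's regular (noisy) GCA with its noiseless testcross mean on
            foreign testers
Fst         global differentiation among subpopulations within a heterotic
            group (heterozygosity-ratio estimator over polymorphic loci)
UW          fraction of loci with minor allele frequency below 5%
            ("U-shapedness" of the allele-frequency spectrum)
Ne          constant effective population size from temporal allele-frequency
            change of the pooled heterotic group
top-rank stability  probability across simulation replicates that the
            top-ranked program repeats from one cycle to the next
"""

from __future__ import annotations

import numpy as np

from enksim.exceptions import ConfigurationError, DegenerateDataError

UW_THRESHOLD = 0.05
NE_CAP_DEFAULT = 1e6


# ---------------------------------------------------------------------------
# %GCA: two-way random-effects variance decomposition
# ---------------------------------------------------------------------------

def _span_basis(W):
    """Orthonormal basis of the column span of W (rank-revealing QR)."""
    from scipy.linalg import qr

    Q, R, _ = qr(W, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(W.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return Q[:, :rank], rank


def _projection_trace(X, Q):
    """tr(X' P X) for the projection onto the span of the orthonormal Q."""
    return float(((Q.T @ X) ** 2).sum())


def _sse(y, Q):
    # explicit residual: the difference-of-squares form loses all precision
    # when the genetic variance is many orders below the mean value
    resid = y - Q @ (Q.T @ y)
    return float(resid @ resid)


def pct_gca(parents1, parents2, values) -> float:
    """GCA fraction of total genetic variance from an incomplete factorial.

    Fits the two-way random-effects decomposition ``value = mu + gca1(parent1)
    + gca2(parent2) + sca`` to the (true, noiseless) testcross hybrid values by
    Henderson's method 3 and returns ``(V1 + V2) / (V1 + V2 + Vsca)``.
    Negative component estimates are truncated at zero. Exactly additive
    tables give exactly 1 regardless of design imbalance.
    """
    p1 = np.asarray(parents1)
    p2 = np.asarray(parents2)
    y = np.asarray(values, dtype=float)
    if y.size != p1.size or y.size != p2.size:
        raise ConfigurationError("parents and values must have equal length")
    u1, i1 = np.unique(p1, return_inverse=True)
    u2, i2 = np.unique(p2, return_inverse=True)
    if u1.size < 2 or u2.size < 2:
        raise DegenerateDataError("need at least 2 levels per parent factor")
    # variance indistinguishable from float rounding of the mean level is no
    # genetic signal: the decomposition is undefined, not zero
    if np.var(y) <= (1e-12 * max(1.0, abs(y.mean()))) ** 2:
        raise DegenerateDataError("zero total variance in testcross values")
    n = y.size
    X1 = np.zeros((n, u1.size))
    X1[np.arange(n), i1] = 1.0
    X2 = np.zeros((n, u2.size))
    X2[np.arange(n), i2] = 1.0
    one = np.ones((n, 1))
    Qf, rank_f = _span_basis(np.hstack([one, X1, X2]))
    sse_f = _sse(y, Qf)
    if n == rank_f:
        raise DegenerateDataError("saturated design: SCA not estimable")
    v_sca = sse_f / (n - rank_f)

    def component(XA, other):
        Qr, rank_r = _span_basis(np.hstack([one, other]))
        R = _sse(y, Qr) - sse_f
        denom = _projection_trace(XA, Qf) - _projection_trace(XA, Qr)
        if denom <= 0:
            return 0.0
        return max(0.0, (R - v_sca * (rank_f - rank_r)) / denom)

    v1 = component(X1, X2)
    v2 = component(X2, X1)
    v_sca = max(0.0, v_sca)
    total = v1 + v2 + v_sca
    if total == 0:
        raise DegenerateDataError("all variance components estimated as zero")
    return (v1 + v2) / total


# ---------------------------------------------------------------------------
# GCA correlation
# ---------------------------------------------------------------------------

def gca_correlation(own_observed_gca, foreign_testcross_means) -> float:
    """Pearson correlation between regular (noisy) GCA and foreign-tester means."""
    a = np.asarray(own_observed_gca, dtype=float)
    b = np.asarray(foreign_testcross_means, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ConfigurationError("need equal-length vectors of >= 3 lines")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("zero variance in GCA values")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def fst_global(subpop_dosages) -> float:
    """Global Fst among subpopulations (heterozygosity-ratio estimator).

    ``subpop_dosages`` is a sequence of (lines x loci) dosage matrices, one
    per subpopulation. Over loci polymorphic in the pooled sample,
    ``Fst = 1 - mean_l(H_S) / mean_l(H_T)`` with ``H_S`` the average
    subpopulation expected heterozygosity and ``H_T`` the expected
    heterozygosity at the unweighted mean allele frequency.
    """
    mats = [np.asarray(m) for m in subpop_dosages]
    if len(mats) < 2:
        raise ConfigurationError("need at least 2 subpopulations")
    freqs = np.stack([m.mean(axis=0) / 2.0 for m in mats])  # (S, L)
    pbar = freqs.mean(axis=0)
    poly = (pbar > 0) & (pbar < 1)
    if not poly.any():
        raise DegenerateDataError("no polymorphic loci in the pooled sample")
    hs = (2.0 * freqs * (1.0 - freqs)).mean(axis=0)[poly]
    ht = (2.0 * pbar * (1.0 - pbar))[poly]
    return float(1.0 - hs.mean() / ht.mean())


# ---------------------------------------------------------------------------
# UW: U-shapedness of the allele frequency spectrum
# ---------------------------------------------------------------------------

def uw_proportion(dosages) -> float:
    """Fraction of loci with minor allele frequency below 5% (fixed loci count)."""
    m = np.asarray(dosages)
    if m.size == 0:
        raise ConfigurationError("empty subpopulation")
    p = m.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return float((maf < UW_THRESHOLD).mean())


# ---------------------------------------------------------------------------
# Effective population size (temporal method)
# ---------------------------------------------------------------------------

def effective_population_size(freq_trajectory, ne_cap: float = NE_CAP_DEFAULT) -> float:
    """Constant-Ne estimate from temporal allele-frequency change.

    ``freq_trajectory`` is a (generations x loci) matrix of population allele
    frequencies. For every one-generation transition the standardized change
    ``F = (p' - p)^2 / (p (1 - p))`` is averaged over loci segregating at the
    earlier generation; under constant-size drift ``E[F] = 1 / (2 Ne)``, so
    the estimate is ``1 / (2 mean(F))``. The estimate is capped at ``ne_cap``
    when no drift signal is present.
    """
    traj = np.asarray(freq_trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 2:
        raise ConfigurationError("need frequencies for at least 2 generations")
    num = 0.0
    cnt = 0
    for t in range(traj.shape[0] - 1):
        p, q = traj[t], traj[t + 1]
        seg = (p > 0) & (p < 1)
        if not seg.any():
            continue
        f = (q[seg] - p[seg]) ** 2 / (p[seg] * (1.0 - p[seg]))
        num += f.sum()
        cnt += int(seg.sum())
    if cnt == 0:
        raise DegenerateDataError("no segregating loci in any transition")
    fbar = num / cnt
    if fbar <= 0:
        return float(ne_cap)
    return float(min(1.0 / (2.0 * fbar), ne_cap))


# ---------------------------------------------------------------------------
# Top-rank stability
# ---------------------------------------------------------------------------

def top_rank_stability(top_program_by_cycle, smooth: bool = False,
                       span: float = 0.3) -> np.ndarray:
    """Per-cycle probability that the top-ranked program repeats.

    ``top_program_by_cycle`` is a (replicates x cycles) integer array of the
    identity of the top-ranked program. Entry ``c`` of the result is the
    fraction of replicates with the same top program in cycles ``c`` and
    ``c - 1``; entry 0 is NaN. With ``smooth=True`` the series is smoothed by
    local regression (lowess, the given span).
    """
    tops = np.asarray(top_program_by_cycle)
    if tops.ndim != 2 or tops.shape[1] < 2:
        raise ConfigurationError("need >= 2 cycles of rank history")
    rep = (tops[:, 1:] == tops[:, :-1]).mean(axis=0)
    out = np.concatenate([[np.nan], rep])
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        x = np.arange(1, out.size)
        sm = lowess(out[1:], x, frac=span, return_sorted=False)
        out = np.concatenate([[np.nan], sm])
    return out
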