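"""Genotype likelihoods, posteriors, and expected allelic dosage.

In an autopolyploid of ploidy x, a biallelic genotype is the alternate copy
count g in 0..x.  From per-sample read counts we compute beta-binomial
genotype likelihoods, combine them with a binomial population prior whose
allele frequency is estimated by EM, and summarize each genotype as its
posterior mean, the allelic dosage E[G] = sum_g g P(G=g).  Dosage carries
genotype uncertainty into every downstream statistic instead of forcing a
hard call.  Two imputation schemes fill missing data: per-chromosome-copy
Bernoulli draws at the site frequency (for allele-count statistics) and
method-of-moments Beta draws at the population-frequency level (for
ordination inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import betabinom, binom

from .svio import SampleInfo, SVRecord


def genotype_likelihoods(
    ref_reads: int,
    alt_reads: int,
    ploidy: int,
    error_rate: float = 0.01,
    rho: float = 0.01,
) -> np.ndarray:
    """Likelihood L(g) of each genotype g = 0..ploidy given read counts.

    L(g) = BetaBinomial(alt | depth, mean g/x adjusted by the sequencing
    error rate, overdispersion rho); rho = 0 degenerates to the Binomial.
    """
    if rho >= 1 or rho < 0:
        raise ValueError("rho must lie in [0, 1)")
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be >= 0")
    depth = ref_reads + alt_reads
    g = np.arange(ploidy + 1)
    frac = g / ploidy
    mean = frac * (1.0 - error_rate) + (1.0 - frac) * error_rate
    mean = np.clip(mean, 1e-9, 1.0 - 1e-9)
    if rho == 0:
        return binom.pmf(alt_reads, depth, mean)
    a = mean * (1.0 - rho) / rho
    b = (1.0 - mean) * (1.0 - rho) / rho
    return betabinom.pmf(alt_reads, depth, a, b)


def likelihood_matrix(
    record: SVRecord | "object",
    samples: Sequence[SampleInfo],
    error_rate: float = 0.01,
    rho: float = 0.01,
    max_ploidy: int | None = None,
) -> np.ndarray:
    """Per-sample likelihood vectors for one variant, padded to max ploidy.

    Rows are samples; entries beyond a sample's ploidy are 0.  Missing
    samples get an all-NaN row.
    """
    if rho >= 1 or rho < 0:
        raise ValueError("rho must lie in [0, 1)")
    x = np.array([s.ploidy for s in samples])
    xmax = max_ploidy or int(x.max())
    g = np.arange(xmax + 1)
    frac = np.where(g[None, :] <= x[:, None], g[None, :] / x[:, None], 0.0)
    mean = np.clip(frac * (1.0 - error_rate) + (1.0 - frac) * error_rate, 1e-9, 1 - 1e-9)
    depth = (record.ref_reads + record.alt_reads)[:, None]
    alt = np.asarray(record.alt_reads)[:, None]
    if rho == 0:
        L = binom.pmf(alt, depth, mean)
    else:
        a = mean * (1.0 - rho) / rho
        b = (1.0 - mean) * (1.0 - rho) / rho
        L = betabinom.pmf(alt, depth, a, b)
    L[g[None, :] > x[:, None]] = 0.0
    L[np.asarray(record.missing, dtype=bool)] = np.nan
    return L


@dataclass
class GenotypePosterior:
    """Per-sample genotype posterior vectors for one variant.

    ``probs[j, g]`` is P(G_j = g | reads); entries beyond sample j's ploidy
    are zero.  ``freq`` is the EM estimate of the site allele frequency.
    """

    probs: np.ndarray
    ploidy: np.ndarray
    missing: np.ndarray
    freq: float

    def __post_init__(self) -> None:
        ok = ~self.missing
        if ok.any():
            sums = self.probs[ok].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("posterior rows must sum to 1")


def genotype_posteriors(
    likelihoods: np.ndarray,
    ploidy: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GenotypePosterior:
    """Binomial-prior posteriors with EM-estimated site allele frequency.

    The prior is P(G=g) = Binomial(x_j, q); q is updated as the expected
    alternate-copy count over total chromosomes (a fixed-point EM), stopping
    at |dq| < tol.  The observed-data log-likelihood is checked to be
    non-decreasing each iteration.
    """
    L = np.asarray(likelihoods, dtype=float)
    n, width = L.shape
    x = np.asarray(ploidy)
    missing = np.all(np.isnan(L), axis=1) | np.all(np.nan_to_num(L) == 0, axis=1)
    if missing.all():
        raise ValueError("no non-missing samples at this site")
    gvals = np.arange(width)
    # binomial coefficient table per sample row
    prior_support = gvals[None, :] <= x[:, None]

    q = 0.5
    last_ll = -np.inf
    for _ in range(max_iter):
        prior = _binomial_prior(x, width, q)
        w = np.where(prior_support, np.nan_to_num(L) * prior, 0.0)
        norm = w.sum(axis=1, keepdims=True)
        site_ll = np.log(np.clip(norm[~missing, 0], 1e-300, None)).sum()
        assert site_ll >= last_ll - 1e-9, "EM log-likelihood decreased"
        last_ll = site_ll
        post = np.divide(w, norm, out=np.zeros_like(w), where=norm > 0)
        eg = (post[~missing] * gvals[None, :]).sum(axis=1)
        q_new = float(eg.sum() / x[~missing].sum())
        q_new = min(max(q_new, 1e-9), 1.0 - 1e-9)
        if abs(q_new - q) < tol:
            q = q_new
            break
        q = q_new
    prior = _binomial_prior(x, width, q)
    w = np.where(prior_support, np.nan_to_num(L) * prior, 0.0)
    norm = w.sum(axis=1, keepdims=True)
    post = np.divide(w, norm, out=np.zeros_like(w), where=norm > 0)
    post[missing] = 0.0
    return GenotypePosterior(probs=post, ploidy=x, missing=missing, freq=q)


def _binomial_prior(x: np.ndarray, width: int, q: float) -> np.ndarray:
    g = np.arange(width)
    return binom.pmf(g[None, :], np.asarray(x)[:, None], q)


def expected_dosage(posterior: GenotypePosterior) -> np.ndarray:
    """Allelic dosage E[G] = sum_g g P(G=g) per sample (NaN where missing)."""
    g = np.arange(posterior.probs.shape[1])
    eg = (posterior.probs * g[None, :]).sum(axis=1)
    eg = eg.astype(float)
    eg[posterior.missing] = np.nan
    return eg


@dataclass
class DosageMatrix:
    """Variants x samples expected genotypes with a missing mask."""

    dosage: np.ndarray
    missing: np.ndarray
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        ok = ~self.missing
        d = self.dosage[ok]
        hi = np.broadcast_to(self.ploidy[None, :], self.dosage.shape)[ok]
        if np.any(d < -1e-9) or np.any(d > hi + 1e-9):
            raise ValueError("dosage outside [0, ploidy]")


def dosage_matrix(
    records: Sequence[SVRecord],
    samples: Sequence[SampleInfo],
    error_rate: float = 0.01,
    rho: float = 0.01,
) -> DosageMatrix:
    """Full likelihood -> EM posterior -> dosage pipeline over a call set."""
    x = np.array([s.ploidy for s in samples])
    xmax = int(x.max())
    dos = np.zeros((len(records), len(samples)))
    miss = np.zeros_like(dos, dtype=bool)
    for i, rec in enumerate(records):
        L = likelihood_matrix(rec, samples, error_rate, rho, max_ploidy=xmax)
        post = genotype_posteriors(L, x)
        dos[i] = np.nan_to_num(expected_dosage(post))
        miss[i] = post.missing
    return DosageMatrix(dosage=dos, missing=miss, ploidy=x)


def modal_genotypes(
    records: Sequence[SVRecord],
    samples: Sequence[SampleInfo],
    error_rate: float = 0.01,
    rho: float = 0.01,
) -> np.ndarray:
    """Maximum-posterior genotype calls (-1 where missing)."""
    x = np.array([s.ploidy for s in samples])
    xmax = int(x.max())
    out = np.full((len(records), len(samples)), -1, dtype=int)
    for i, rec in enumerate(records):
        L = likelihood_matrix(rec, samples, error_rate, rho, max_ploidy=xmax)
        post = genotype_posteriors(L, x)
        calls = np.argmax(post.probs, axis=1)
        calls[post.missing] = -1
        out[i] = calls
    return out


# ---------------------------------------------------------------------------
# imputation


def impute_missing_alleles(
    dosage_col: np.ndarray,
    missing: np.ndarray,
    ploidy: np.ndarray,
    freq: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fill missing samples with per-chromosome-copy Bernoulli(freq) draws.

    Site missingness above 20% is an error: such sites should have been
    removed by the call-set filters.  Non-missing entries are untouched.
    """
    missing = np.asarray(missing, dtype=bool)
    if missing.mean() > 0.2 + 1e-12:
        raise ValueError(
            f"site missingness {missing.mean():.0%} exceeds 20%; filter first"
        )
    out = np.array(dosage_col, dtype=float)
    idx = np.flatnonzero(missing)
    if idx.size:
        out[idx] = rng.binomial(ploidy[idx], freq)
    return out


@dataclass
class PopulationFrequencyMatrix:
    """Variants x populations alternate-allele frequencies.

    ``chrom_counts`` holds per-population chromosome totals (sum of sample
    ploidies); ``missing`` marks populations with no genotyped samples.
    """

    freqs: np.ndarray
    missing: np.ndarray
    populations: list[str]
    chrom_counts: np.ndarray

    def __post_init__(self) -> None:
        ok = ~self.missing
        f = self.freqs[ok]
        if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise ValueError("frequencies outside [0, 1]")


def population_frequencies(
    dm: DosageMatrix, samples: Sequence[SampleInfo]
) -> PopulationFrequencyMatrix:
    """p = sum(E[G]) / sum(ploidy) over each population's non-missing samples."""
    pops = list(dict.fromkeys(s.population for s in samples))
    pop_of = np.array([pops.index(s.population) for s in samples])
    x = dm.ploidy
    n_var = dm.dosage.shape[0]
    freqs = np.zeros((n_var, len(pops)))
    missing = np.zeros((n_var, len(pops)), dtype=bool)
    chrom_counts = np.zeros(len(pops), dtype=int)
    for j, pop in enumerate(pops):
        cols = pop_of == j
        chrom_counts[j] = x[cols].sum()
        ok = ~dm.missing[:, cols]
        num = np.where(ok, dm.dosage[:, cols], 0.0).sum(axis=1)
        den = (ok * x[cols][None, :]).sum(axis=1)
        empty = den == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[:, j] = np.where(empty, 0.0, num / np.maximum(den, 1))
        missing[:, j] = empty
    return PopulationFrequencyMatrix(freqs, missing, pops, chrom_counts)


def impute_population_frequencies_beta(
    pfm: PopulationFrequencyMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Fill missing population frequencies with method-of-moments Beta draws.

    For each variant, nu = m(1-m)/v - 1 from the non-missing mean m and
    variance v gives Beta(m*nu, (1-m)*nu).  When the variance is too large
    for a valid Beta (nu <= 0), draws fall back to resampling the observed
    non-missing values.
    """
    freqs = np.array(pfm.freqs, dtype=float)
    for i in range(freqs.shape[0]):
        miss = pfm.missing[i]
        if not miss.any():
            continue
        obs = freqs[i, ~miss]
        if obs.size == 0:
            raise ValueError(f"variant {i}: all populations missing")
        if obs.size < 2 or obs.var() == 0:
            freqs[i, miss] = obs.mean()
            continue
        m, v = obs.mean(), obs.var()
        nu = m * (1.0 - m) / v - 1.0
        if nu <= 0:
            freqs[i, miss] = rng.choice(obs, size=int(miss.sum()), replace=True)
        else:
            freqs[i, miss] = rng.beta(m * nu, (1.0 - m) * nu, size=int(miss.sum()))
    return freqs
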