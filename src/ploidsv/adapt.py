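"""Genotype-environment association, ploidy-specific SVs, and sweep signals.

The GEA scan scores each variant against each bioclimatic variable with a
closed-form Zellner g-prior Bayes factor computed on population allele
frequencies whitened by a population-structure covariance (so shared
drift does not masquerade as climate association):

    BF = (1 + g)^((n-2)/2) / (1 + g (1 - R^2))^((n-1)/2),   g = n,

reported in decibans, dB = 10 log10 BF; each scan is repeated with jittered
frequencies and the median dB over runs is thresholded at dB >= 10.  These
are stand-in scores with the same interface and decision rule as an MCMC
GEA, not reproductions of one, and outputs label them as such
(`gea_method = "gprior-bf"`).

Sweep signals are a composite likelihood ratio contrasting the folded SFS
inside a 20 kb window around an SV against the genome-wide background
spectrum, aggregated per SV as the maximum over that ploidy group's
populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GEA_METHOD = "gprior-bf"
OUTLIER_DB = 10.0


# ---------------------------------------------------------------------------
# GEA scan


@dataclass
class GEAResult:
    """Per-variant Bayes factors in decibans.

    ``db[v, e]`` is the median-over-runs dB for variant v and environment
    variable e; ``median_db`` is the max over variables (the quantity
    thresholded for outlier status).
    """

    db: np.ndarray
    variables: list[str]
    variant_ids: list[str]
    n_runs: int
    method: str = GEA_METHOD

    @property
    def median_db(self) -> np.ndarray:
        return self.db.max(axis=1)

    @property
    def best_variable(self) -> np.ndarray:
        return np.asarray(self.variables, dtype=object)[np.argmax(self.db, axis=1)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.db, columns=self.variables)
        df.insert(0, "variant", self.variant_ids)
        df["median_db"] = self.median_db
        df["best_variable"] = self.best_variable
        df["outlier"] = self.median_db >= OUTLIER_DB
        df.attrs["gea_method"] = self.method
        return df


def gprior_bf_db(r2: np.ndarray, n: int) -> np.ndarray:
    """Deciban g-prior Bayes factor for a one-predictor regression, g = n."""
    g = float(n)
    r2 = np.clip(np.asarray(r2, dtype=float), 0.0, 1.0 - 1e-12)
    log10_bf = ((n - 2) / 2.0) * np.log10(1.0 + g) - ((n - 1) / 2.0) * np.log10(
        1.0 + g * (1.0 - r2)
    )
    return 10.0 * log10_bf


def population_covariance_from_freqs(freqs: np.ndarray,
                                     shrinkage: float = 0.1,
                                     maf_min: float = 0.05) -> np.ndarray:
    """Population covariance estimated from allele frequencies of (neutral)
    markers, in the style of structure-aware association models.

    Rows of ``freqs`` are variants, columns populations.  Variants below
    ``maf_min`` are excluded first (rare variants contribute near-spike
    standardized rows that make the estimate singular, and structure
    covariances are conventionally built from common, pruned markers).
    Each remaining variant is centered at its across-population mean and
    scaled by the binomial standard deviation sqrt(p(1-p)); the pops x pops
    covariance of these standardized vectors is shrunk toward a scaled
    identity so downstream Cholesky whitening stays well-conditioned.
    """
    Y = np.asarray(freqs, dtype=float)
    pbar = Y.mean(axis=1)
    ok = (pbar > maf_min) & (pbar < 1 - maf_min)
    if ok.sum() < 2:
        ok = (pbar > 0) & (pbar < 1)
    Y = Y[ok]
    pbar = pbar[ok]
    M = (Y - pbar[:, None]) / np.sqrt(pbar * (1 - pbar))[:, None]
    omega = M.T @ M / M.shape[0]
    n = omega.shape[0]
    # centering each variant at its across-population mean makes the
    # constant vector a null direction of the raw estimate; it carries no
    # between-population contrast, so restore it to the bulk eigenvalue
    # level rather than letting the whitener amplify it
    vals, vecs = np.linalg.eigh(omega)
    ones = np.ones(n) / np.sqrt(n)
    j = int(np.argmax(np.abs(vecs.T @ ones)))
    if abs(vecs[:, j] @ ones) > 0.9:
        vals[j] = float(np.median(np.delete(vals, j)))
    omega = (vecs * vals) @ vecs.T
    target = (np.trace(omega) / n) * np.eye(n)
    omega = (1 - shrinkage) * omega + shrinkage * target
    vals = np.linalg.eigvalsh(omega)
    if vals.min() <= 0:
        omega += (abs(vals.min()) + 1e-8 * max(vals.max(), 1.0)) * np.eye(n)
    return omega


def _whitener(omega: np.ndarray) -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    vals = np.linalg.eigvalsh((omega + omega.T) / 2.0)
    if vals.min() <= 0:
        raise ValueError(
            f"covariance is not positive definite (smallest eigenvalue {vals.min():.3g})"
        )
    return np.linalg.cholesky(omega)


def gea_scan(
    freqs: np.ndarray,
    env: pd.DataFrame | np.ndarray,
    omega: np.ndarray | None = None,
    n_runs: int = 10,
    seed: int = 0,
    variant_ids: Sequence[str] | None = None,
    jitter_sd: float = 1e-3,
) -> GEAResult:
    """Structure-corrected Bayes-factor scan of variants x environments.

    ``freqs`` is variants x populations (pre-filtered to MAF > 0.05 and
    <= 20% missing, then imputed); ``env`` is populations x variables;
    ``omega`` a population covariance from neutral, linkage-pruned markers
    (identity if omitted: whitening with I is a no-op).  Runs differ only
    in a small seeded frequency jitter; the median dB across runs is kept.
    """
    Y = np.asarray(freqs, dtype=float)
    if isinstance(env, pd.DataFrame):
        variables = list(env.columns)
        X = env.to_numpy(dtype=float)
    else:
        X = np.asarray(env, dtype=float)
        variables = [f"env{j + 1}" for j in range(X.shape[1])]
    n_var, n_pop = Y.shape
    if X.shape[0] != n_pop:
        raise ValueError("environment table and frequency matrix disagree on populations")
    if omega is None:
        omega = np.eye(n_pop)
    L = _whitener(omega)

    # center/standardize across populations first, then whiten by L^-1
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    zc = np.linalg.solve(L, Z)
    zss = (zc**2).sum(axis=0)
    rng = np.random.default_rng(seed)
    db_runs = np.empty((n_runs, n_var, X.shape[1]))
    for run in range(n_runs):
        Yr = Y + rng.normal(0.0, jitter_sd, size=Y.shape)
        Yr = Yr - Yr.mean(axis=1, keepdims=True)
        Yc = np.linalg.solve(L, Yr.T).T
        yss = (Yc**2).sum(axis=1)
        cross = Yc @ zc
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = cross**2 / np.outer(yss, zss)
        r2 = np.nan_to_num(r2)
        db_runs[run] = gprior_bf_db(r2, n_pop)
    db = np.median(db_runs, axis=0)
    ids = list(variant_ids) if variant_ids is not None else [f"v{i}" for i in range(n_var)]
    return GEAResult(db=db, variables=variables, variant_ids=ids, n_runs=n_runs)


def call_outliers(gea: GEAResult, threshold: float = OUTLIER_DB) -> np.ndarray:
    """Outlier mask: median-over-runs dB >= threshold on >= 1 variable
    (the threshold is inclusive)."""
    return gea.median_db >= threshold


# ---------------------------------------------------------------------------
# ploidy-specific SVs


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for table [[a, b], [c, d]].

    Computed by enumerating the hypergeometric distribution of the top-left
    cell at fixed margins and summing probabilities <= that of the observed
    table.
    """
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class PloidySpecificResult:
    table: pd.DataFrame  # per variant: common/specific flags per group
    proportions: dict[str, float]
    counts: dict[str, tuple[int, int]]  # group -> (specific, common)
    fisher_p: float


def ploidy_specific(
    freqs: np.ndarray,
    chrom_counts: np.ndarray,
    group_of_pop: np.ndarray,
    groups: tuple[str, str] = ("diploid", "tetraploid"),
    maf: float = 0.05,
    variant_ids: Sequence[str] | None = None,
    zero_copy_tol: float = 0.5,
) -> PloidySpecificResult:
    """Classify variants as ploidy-specific and compare groups.

    A variant is *common* in a group when its within-group MAF exceeds
    ``maf``; it is *group-specific* when additionally the alternate-allele
    count in the other group is zero (fewer than ``zero_copy_tol`` expected
    copies, absorbing dosage noise).  Proportions are specific / common per
    group, and the 2x2 (specific, non-specific common) x group table is
    tested with the enumerated two-sided Fisher exact test.
    """
    Y = np.asarray(freqs, dtype=float)
    gop = np.asarray(group_of_pop)
    flags = {}
    counts = {}
    proportions = {}
    for me, other in (groups, groups[::-1]):
        mine = gop == me
        theirs = gop == other
        if not mine.any() or not theirs.any():
            raise ValueError(f"group {me!r} or {other!r} has no populations")
        nm = chrom_counts[mine].sum()
        p_me = (Y[:, mine] * chrom_counts[mine]).sum(axis=1) / nm
        common = np.minimum(p_me, 1 - p_me) > maf
        alt_other = (Y[:, theirs] * chrom_counts[theirs]).sum(axis=1)
        specific = common & (alt_other < zero_copy_tol)
        flags[me] = (common, specific)
        n_spec, n_common = int(specific.sum()), int(common.sum())
        counts[me] = (n_spec, n_common - n_spec)
        proportions[me] = n_spec / n_common if n_common else np.nan
    a, b = counts[groups[0]]
    c, d = counts[groups[1]]
    p = fisher_exact_2x2(a, b, c, d)
    ids = list(variant_ids) if variant_ids is not None else [f"v{i}" for i in range(Y.shape[0])]
    table = pd.DataFrame({"variant": ids})
    for gname, (common, specific) in flags.items():
        table[f"common_{gname}"] = common
        table[f"specific_{gname}"] = specific
    return PloidySpecificResult(table=table, proportions=proportions, counts=counts, fisher_p=p)


# ---------------------------------------------------------------------------
# sweep CLR


def sweep_clr(window_minor_counts: np.ndarray, background: np.ndarray,
              min_snps: int = 5) -> float:
    """Composite likelihood ratio of a window SFS against the background.

    ``window_minor_counts`` are folded minor-allele counts (1..n/2) of the
    SNPs in the window; ``background`` are background class probabilities
    over the same bins.  CLR = 2 * sum_sites [log p_hat - log q] with p_hat
    the within-window multinomial MLE, clipped at 0.  A background class
    with zero probability but window occupancy triggers add-one smoothing
    of the background (logged).
    """
    counts = np.asarray(window_minor_counts, dtype=int)
    if counts.size < min_snps:
        raise ValueError(f"window has {counts.size} SNPs; need >= {min_snps}")
    q = np.asarray(background, dtype=float)
    k = q.size
    if counts.min() < 1 or counts.max() > k:
        raise ValueError("window minor counts outside background bins")
    occ = np.bincount(counts - 1, minlength=k).astype(float)[:k]
    if np.any((q <= 0) & (occ > 0)):
        logger.warning("background class with zero probability occupied: add-one smoothing")
        q = q * counts.size + 1.0
    q = q / q.sum()
    S = occ.sum()
    p_hat = occ / S
    nz = occ > 0
    clr = 2.0 * float(np.sum(occ[nz] * (np.log(p_hat[nz]) - np.log(q[nz]))))
    return max(clr, 0.0)


def background_sfs(minor_counts: np.ndarray, n_chrom: int) -> np.ndarray:
    """Folded background class probabilities from genome-wide minor counts."""
    counts = np.asarray(minor_counts, dtype=int)
    k = n_chrom // 2
    occ = np.bincount(counts - 1, minlength=k).astype(float)[:k]
    if occ.sum() == 0:
        raise ValueError("empty background spectrum")
    return occ / occ.sum()


@dataclass
class SweepResult:
    """Per-SV, per-population CLR and the per-SV maximum over populations."""

    per_population: pd.DataFrame  # sv, population, clr
    max_clr: pd.Series  # indexed by sv id
    excluded: list[str]  # SVs with no SNPs in radius


def max_clr_per_sv(
    sv_table: pd.DataFrame,
    snp_table: pd.DataFrame,
    snp_minor_counts: dict[str, np.ndarray],
    backgrounds: dict[str, np.ndarray],
    populations: Sequence[str],
    radius: int = 20_000,
    min_snps: int = 5,
) -> SweepResult:
    """Aggregate window CLRs per SV as the max over eligible populations.

    ``sv_table`` needs columns id / chrom / pos / end; ``snp_table`` chrom /
    pos.  ``snp_minor_counts[pop]`` holds folded minor counts per SNP (0 =
    monomorphic in that population, excluded from windows), ``backgrounds``
    the per-population background spectra.  Populations should be
    pre-filtered to sample size >= 6.  SVs whose windows hold fewer than
    ``min_snps`` SNPs in every population are flagged and excluded.
    """
    rows = []
    excluded = []
    snp_chrom = snp_table["chrom"].to_numpy()
    snp_pos = snp_table["pos"].to_numpy()
    for sv in sv_table.itertuples():
        near = (snp_chrom == sv.chrom) & (
            (np.abs(snp_pos - sv.pos) <= radius) | (np.abs(snp_pos - sv.end) <= radius)
        )
        idx = np.flatnonzero(near)
        best = None
        for pop in populations:
            counts = snp_minor_counts[pop][idx]
            counts = counts[counts > 0]
            if counts.size < min_snps:
                continue
            clr = sweep_clr(counts, backgrounds[pop], min_snps)
            rows.append((sv.id, pop, clr))
            best = clr if best is None else max(best, clr)
        if best is None:
            excluded.append(sv.id)
    per_pop = pd.DataFrame(rows, columns=["sv", "population", "clr"])
    max_clr = per_pop.groupby("sv")["clr"].max() if len(per_pop) else pd.Series(dtype=float)
    return SweepResult(per_population=per_pop, max_clr=max_clr, excluded=excluded)


# ---------------------------------------------------------------------------
# outlier comparisons


@dataclass
class OutlierComparison:
    spearman_rho: float
    spearman_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    n_outlier: int
    n_background: int


def compare_outliers(max_clr: np.ndarray, median_db: np.ndarray,
                     outlier: np.ndarray) -> OutlierComparison:
    """Association between sweep and GEA signals on common variants.

    Spearman rank correlation (average ranks on ties) between per-SV max
    CLR and median dB, plus a two-sided Wilcoxon rank-sum test (normal
    approximation with tie correction) of outlier vs non-outlier CLRs.
    """
    clr = np.asarray(max_clr, dtype=float)
    db = np.asarray(median_db, dtype=float)
    out = np.asarray(outlier, dtype=bool)
    if clr.size < 3:
        raise ValueError("need >= 3 variants for comparisons")
    rho, rho_p = stats.spearmanr(clr, db)
    if out.any() and (~out).any():
        w = stats.mannwhitneyu(
            clr[out], clr[~out], alternative="two-sided", method="asymptotic"
        )
        w_stat, w_p = float(w.statistic), float(w.pvalue)
    else:
        w_stat, w_p = np.nan, np.nan
    return OutlierComparison(
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        wilcoxon_stat=w_stat,
        wilcoxon_p=w_p,
        n_outlier=int(out.sum()),
        n_background=int((~out).sum()),
    )
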