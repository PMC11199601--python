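"""Mixed-ploidy population-genetic statistics.

Folded allele-frequency spectra and Tajima's D per feature class, pairwise
nucleotide diversity, a ploidy-generalized covariance for PCA

    C_ij = (1/m) * sum_s (g_is/x_i - p_s)(g_js/x_j - p_s) / (p_s(1-p_s)),

Hudson's F_ST as a ratio of averages, isolation-by-distance with a seeded
Mantel test, and F81 sequence divergence with the K/2 / mu insertion-time
transform.  Because polyploid genotype calls are uncertain, allele counts
enter the AFS as rounded sums of expected dosage; strata of unequal
chromosome count are never pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# folded AFS


@dataclass
class FoldedAFS:
    """Minor-allele-count histogram over bins 1..floor(n/2).

    ``n_chrom`` is the total chromosome count of the (single-n) stratum;
    ``counts[j-1]`` holds the number of variants with minor count j.
    """

    n_chrom: int
    counts: np.ndarray
    label: str = "all"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != self.n_chrom // 2:
            raise ValueError(
                f"expected {self.n_chrom // 2} bins for n={self.n_chrom}, "
                f"got {len(self.counts)}"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative AFS counts")

    @property
    def segregating_sites(self) -> float:
        return float(self.counts.sum())

    def without_singletons(self) -> "FoldedAFS":
        counts = self.counts.copy()
        counts[0] = 0
        return FoldedAFS(self.n_chrom, counts, self.label)


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Ties round away from the floor (0.5 -> 1), unlike numpy banker's rounding."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def allele_counts(
    dosage: np.ndarray, missing: np.ndarray, ploidy: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int]:
    """Integer alternate-allele counts per variant and the chromosome total.

    Missing entries are imputed per chromosome copy (Bernoulli at the
    non-missing dosage frequency) when an RNG is supplied; otherwise sites
    must be complete.  Counts are rounded half-up from the dosage sum; a
    per-variant log entry notes discrepancies above 0.25 copies.
    """
    from .dosage import impute_missing_alleles

    d = np.array(dosage, dtype=float)
    n_chrom = int(ploidy.sum())
    n_var = d.shape[0]
    counts = np.zeros(n_var)
    for i in range(n_var):
        miss = missing[i]
        if miss.any():
            if rng is None:
                raise ValueError("missing data present: supply an RNG for imputation")
            ok = ~miss
            p = d[i, ok].sum() / ploidy[ok].sum()
            row = impute_missing_alleles(d[i], miss, ploidy, p, rng)
        else:
            row = d[i]
        total = row.sum()
        c = float(round_half_up(total))
        if abs(c - total) > 0.25:
            logger.debug("variant %d: rounded %0.3f -> %d", i, total, int(c))
        counts[i] = c
    return counts, n_chrom


def folded_afs(
    dosage: np.ndarray,
    missing: np.ndarray,
    ploidy: np.ndarray,
    label: str = "all",
    rng: np.random.Generator | None = None,
) -> FoldedAFS:
    """Fold rounded dosage-sum allele counts into a minor-allele histogram.

    Monomorphic variants (count 0 or n) are excluded; a count of exactly
    n/2 lands in the top bin once.
    """
    counts, n = allele_counts(dosage, missing, ploidy, rng)
    minor = np.minimum(counts, n - counts)
    minor = minor[(counts > 0) & (counts < n)]
    hist = np.bincount(minor.astype(int), minlength=n // 2 + 1)[1 : n // 2 + 1]
    return FoldedAFS(n, hist.astype(float), label)


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaResult:
    D: float | None
    pi: float
    S: float
    n_chrom: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.D is not None


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def afs_pi(afs: FoldedAFS) -> float:
    """Mean pairwise diversity from a folded spectrum.

    A site with minor count j contributes 2j(n-j)/(n(n-1)); each folded bin
    (including the n/2 bin) is counted exactly once.
    """
    n = afs.n_chrom
    j = np.arange(1, n // 2 + 1)
    return float(np.sum(afs.counts * 2.0 * j * (n - j) / (n * (n - 1.0))))


def tajimas_d(afs: FoldedAFS, exclude_singletons: bool = False) -> TajimaResult:
    """Tajima's D from a folded spectrum, with optional singleton exclusion.

    Singletons (minor count 1) are dropped from both S and pi before
    applying the same formula.  Returns an undefined-with-reason result
    rather than raising when S = 0 or the spectrum is too sparse.
    """
    if exclude_singletons:
        afs = afs.without_singletons()
    n = afs.n_chrom
    S = afs.segregating_sites
    pi = afs_pi(afs)
    if S == 0:
        return TajimaResult(None, pi, S, n, reason="no segregating sites")
    if S < 3:
        return TajimaResult(None, pi, S, n, reason=f"only {S:g} segregating sites")
    k = _tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1.0)
    if var <= 0:
        return TajimaResult(None, pi, S, n, reason="non-positive variance")
    D = (pi - S / k["a1"]) / np.sqrt(var)
    return TajimaResult(float(D), pi, S, n)


def neutral_folded_expectation(n: int, S: float) -> np.ndarray:
    """Expected folded spectrum under the standard neutral model.

    eta_j proportional to 1/j + 1/(n-j) for j < n/2 and 1/j for j = n/2
    (the two unfolded classes coincide there), scaled to total S.
    """
    j = np.arange(1, n // 2 + 1)
    w = 1.0 / j + 1.0 / (n - j)
    if n % 2 == 0:
        w[-1] = 1.0 / j[-1]
    return S * w / w.sum()


# ---------------------------------------------------------------------------
# nucleotide diversity


def nucleotide_diversity(freqs: np.ndarray, n_chrom: int, callable_sites: int) -> float:
    """pi = sum over polymorphic sites of 2p(1-p) n/(n-1), per callable site."""
    if callable_sites <= 0:
        raise ValueError("callable_sites must be positive")
    p = np.asarray(freqs, dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p) * n_chrom / (n_chrom - 1.0)) / callable_sites)


# ---------------------------------------------------------------------------
# ploidy-aware covariance and PCA


def ploidy_covariance(
    dosage: np.ndarray, missing: np.ndarray, ploidy: np.ndarray
) -> np.ndarray:
    """Genetic covariance between individuals, normalized per copy.

    Each site contributes (g_i/x_i - p)(g_j/x_j - p) / (p(1-p)), averaged
    over the m sites where both individuals are genotyped.  Sites fixed in
    the sample (p in {0, 1}) are excluded; a pair with no shared sites is
    an error.
    """
    d = np.asarray(dosage, dtype=float)
    miss = np.asarray(missing, dtype=bool)
    x = np.asarray(ploidy, dtype=float)
    ok = ~miss
    with np.errstate(invalid="ignore"):
        p = np.where(ok, d, 0.0).sum(axis=1) / (ok * x[None, :]).sum(axis=1)
    seg = (p > 0) & (p < 1)
    if not seg.any():
        raise ValueError("no segregating sites for covariance")
    d, okv, p = d[seg], ok[seg], p[seg]
    w = (d / x[None, :] - p[:, None]) / np.sqrt(p * (1.0 - p))[:, None]
    w = np.where(okv, w, 0.0)
    m = okv.astype(float).T @ okv.astype(float)
    if np.any(m == 0):
        raise ValueError("some individual pairs share no genotyped sites")
    return (w.T @ w) / m


def pca(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a covariance matrix.

    Returns (components, explained) with columns ordered by decreasing
    eigenvalue; each component's sign is fixed so its largest-magnitude
    loading is positive.  Explained proportions use the total absolute
    eigenvalue mass.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("covariance matrix contains non-finite entries")
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    total = np.abs(vals).sum()
    explained = np.abs(vals) / total if total > 0 else np.full_like(vals, 1.0 / len(vals))
    return vecs, explained


# ---------------------------------------------------------------------------
# F_ST and isolation by distance


@dataclass
class FstResult:
    fst: float | None
    numerator: float
    denominator: float
    reason: str | None = None


def hudson_fst(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray | int, n2: np.ndarray | int
) -> FstResult:
    """Hudson's F_ST as a ratio of averages over sites.

    Per site: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    D = p1(1-p2) + p2(1-p1); F_ST = sum(N)/sum(D).
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("allele counts must be >= 2 per site")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    N, D = float(num.sum()), float(den.sum())
    if D == 0:
        return FstResult(None, N, D, reason="zero denominator (no variation)")
    return FstResult(N / D, N, D)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371.0088 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def mantel_test(
    dist_a: np.ndarray, dist_b: np.ndarray, permutations: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Seeded Mantel correlation between two distance matrices.

    Pearson correlation over the upper triangles; the null distribution
    permutes rows/columns of the second matrix jointly.
    """
    A = np.asarray(dist_a, dtype=float)
    B = np.asarray(dist_b, dtype=float)
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    r_obs = np.corrcoef(A[iu], B[iu])[0, 1]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        r = np.corrcoef(A[iu], B[perm][:, perm][iu])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + permutations)
    return float(r_obs), float(p)


def isolation_by_distance(
    fst_matrix: np.ndarray,
    populations: Sequence[str],
    ploidy_of_pop: dict[str, int],
    lon: np.ndarray,
    lat: np.ndarray,
    permutations: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Per-pair (distance, F_ST, ploidy-pair class) table plus Mantel test.

    Pairs are classed diploid / tetraploid / between by their populations'
    ploidies (higher ploidies fall in 'between' unless equal).
    """
    n = len(populations)
    if n < 3:
        raise ValueError("need >= 3 populations")
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    dist = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    rows = []
    names = {2: "diploid", 4: "tetraploid", 6: "hexaploid", 8: "octoploid"}
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = ploidy_of_pop[populations[i]], ploidy_of_pop[populations[j]]
            klass = names.get(xi, "other") if xi == xj else "between"
            rows.append(
                (populations[i], populations[j], float(dist[i, j]),
                 float(fst_matrix[i, j]), klass)
            )
    pairs = pd.DataFrame(rows, columns=["pop1", "pop2", "distance_km", "fst", "pair_class"])
    r, p = mantel_test(dist, np.asarray(fst_matrix, dtype=float), permutations, seed)
    return pairs, r, p


# ---------------------------------------------------------------------------
# F81 divergence and insertion times

_VALID_BASES = set("ACGT")


def f81_distance(seq1: str, seq2: str) -> float:
    """F81 sequence divergence K = -B ln(1 - p/B).

    B = 1 - sum(pi_a^2) from the pooled base composition of the pair; sites
    with a gap or ambiguity in either sequence are excluded pairwise.
    Raises when the mismatch proportion reaches saturation (p >= B).
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    a1 = np.frombuffer(seq1.upper().encode(), dtype="S1")
    a2 = np.frombuffer(seq2.upper().encode(), dtype="S1")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    valid = np.isin(a1, bases) & np.isin(a2, bases)
    if not valid.any():
        raise ValueError("no comparable sites after pairwise deletion")
    a1, a2 = a1[valid], a2[valid]
    pooled = np.concatenate([a1, a2])
    freqs = np.array([(pooled == b).mean() for b in bases])
    B = 1.0 - float(np.sum(freqs**2))
    p = float((a1 != a2).mean())
    if p == 0:
        return 0.0
    if p >= B:
        raise ValueError(
            f"mismatch proportion p={p:.4f} at or beyond saturation (B={B:.4f}); "
            "distance is undefined"
        )
    return float(-B * np.log(1.0 - p / B))


@dataclass(frozen=True)
class InsertionTimeEstimate:
    K: float
    mu: float
    T: float


def insertion_time(K: float, mu: float = 6.95e-9) -> InsertionTimeEstimate:
    """Insertion age T = (K/2) / mu in years.

    The default rate is the A. thaliana per-generation mutation rate
    (6.95e-9 substitutions per site), used as a per-year rate.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if K < 0:
        raise ValueError("K must be >= 0")
    return InsertionTimeEstimate(K=K, mu=mu, T=(K / 2.0) / mu)
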