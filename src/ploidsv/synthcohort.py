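"""Synthetic mixed-ploidy cohorts with known ground truth.

Generates every input the pipeline consumes: gene models and a feature
partition, sample sheets with ploidy levels 2-8 on a European-style
lon/lat domain, hierarchically drifted SV and SNP allele frequencies with
optional feature-dependent thinning, recessive-masking excess and
climate-driven clines, beta-binomial read counts over true genotypes,
per-site conservation scores, occurrence records and gridded environments.

The statistical structure emulated is that of a long-read SV survey of an
autopolyploid plant complex: exonic SVs are depleted by purifying
selection, polyploids accumulate an excess of very rare exonic variants
because extra chromosome copies mask recessive effects, and a subset of
variants track bioclimatic gradients.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .svio import (
    FeatureMap,
    Gene,
    SampleInfo,
    SNPRecord,
    SVRecord,
    build_feature_map,
)

N_ENV_VARS = 11
ENV_VARS = tuple(f"bio_{i + 1}" for i in range(N_ENV_VARS))

# fixed angles mixing the two latent spatial gradients into the 11
# bioclimatic variables; a narrow fan keeps the variables strongly
# inter-correlated (pairwise r >= cos(pi/8) ~ 0.92 before noise), as real
# bioclim layers are, so the 11-variable scan behaves like ~2 effective tests
_ENV_ANGLES = np.linspace(0.0, np.pi / 8, N_ENV_VARS)

# anchors of the sampling domain (roughly the European range)
_LON_RANGE = (-10.0, 30.0)
_LAT_RANGE = (42.0, 70.0)


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Per-operation RNG stream derived from the root seed and a stage tag."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Distances are bp, depths are reads.  ``causal_slope`` is the logit-scale
    shift in population allele frequency per standard deviation of the causal
    environmental variable.  ``exon_thinning`` is the retention probability of
    exonic SV placements (1 = no selection against exonic SVs).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 20
    flank_bp: int = 1000
    n_populations_per_ploidy: dict[int, int] = field(default_factory=lambda: {2: 24, 4: 24})
    samples_per_population: int = 6
    n_svs: int = 2000
    n_snps: int = 2000
    exon_thinning: float = 1.0
    masking_scenario: str = "off"
    masking_excess: float = 0.5
    constraint_purge: float = 0.0
    sv_restricted_tetraploid: float = 0.15
    sv_restricted_diploid: float = 0.05
    n_causal_svs: int = 0
    causal_slope: float = 1.5
    depth_mean: float = 40.0
    overdispersion_rho: float = 0.01
    error_rate: float = 0.01
    missing_rate: float = 0.05
    env_noise_sd: float = 0.1
    drift_concentration: float = 20.0
    group_divergence_sd: float = 0.5
    global_beta: tuple[float, float] = (0.3, 0.3)

    def __post_init__(self) -> None:
        counts = [
            self.n_chromosomes,
            self.chrom_length,
            self.n_genes,
            self.samples_per_population,
            self.n_svs,
            self.n_snps,
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if not (0 < self.exon_thinning <= 1):
            raise ValueError("exon_thinning must lie in (0, 1]")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not (0 <= self.overdispersion_rho < 1):
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if self.masking_scenario not in ("off", "on"):
            raise ValueError("masking_scenario must be 'off' or 'on'")
        if self.n_causal_svs > self.n_svs:
            raise ValueError("n_causal_svs cannot exceed n_svs")
        for x in self.n_populations_per_ploidy:
            if x not in (2, 4, 6, 8):
                raise ValueError(f"unsupported ploidy {x}")


@dataclass
class TruthTable:
    """Ground truth for one simulated cohort.

    ``sv`` / ``snp`` hold per-variant metadata (position, feature class,
    causal flag and environmental variable); ``sv_freqs`` / ``snp_freqs``
    are variants x populations true alternate-allele frequencies;
    ``gene_constraint`` maps gene id -> true conservation level (z-scale).
    """

    sv: pd.DataFrame
    sv_freqs: np.ndarray
    snp: pd.DataFrame
    snp_freqs: np.ndarray
    populations: list[str]
    gene_constraint: pd.Series

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "populations": list(self.populations),
            "sv": self.sv.to_dict(orient="list"),
            "sv_freqs": np.round(self.sv_freqs, 6).tolist(),
            "snp": self.snp.to_dict(orient="list"),
            "snp_freqs": np.round(self.snp_freqs, 6).tolist(),
            "gene_constraint": {k: float(v) for k, v in self.gene_constraint.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, default_flow_style=None)


# ---------------------------------------------------------------------------
# annotation


def _partition_lengths(total: int, parts: int, min_len: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Random integer composition of ``total`` into ``parts`` pieces >= min_len."""
    if total < parts * min_len:
        raise ValueError(f"cannot split {total} bp into {parts} pieces of >= {min_len}")
    extra = rng.multinomial(total - parts * min_len, np.full(parts, 1.0 / parts))
    return extra + min_len


def simulate_annotation(config: SimConfig) -> tuple[list[Gene], dict[str, int], FeatureMap]:
    """Place non-overlapping multi-exon genes and derive the feature map.

    Genes are spread round-robin over chromosomes, each inside its own slot
    with room for the flanks; placement failure raises an error naming the
    constraint.  Returns (genes, chromosome lengths, feature map).
    """
    rng = _rng(config.seed, "annotation")
    chrom_lengths = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    chroms = list(chrom_lengths)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    genes: list[Gene] = []
    gid = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        slot = config.chrom_length // k
        for j in range(k):
            slot_start = j * slot
            placed = False
            for _ in range(100):
                glen = int(rng.integers(1200, 2401))
                lo = slot_start + config.flank_bp
                hi = slot_start + slot - config.flank_bp - glen
                if hi < lo:
                    continue
                start0 = int(rng.integers(lo, hi + 1))
                n_ex = int(rng.integers(2, 5))
                pieces = _partition_lengths(glen, 2 * n_ex - 1, 60, rng)
                exons = []
                cursor = start0
                for p, plen in enumerate(pieces):
                    if p % 2 == 0:
                        exons.append((cursor + 1, cursor + int(plen)))
                    cursor += int(plen)
                gid += 1
                genes.append(
                    Gene(f"gene{gid:04d}", chrom, start0 + 1, start0 + glen, tuple(exons))
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place gene {gid + 1} on {chrom}: slot of {slot} bp "
                    f"cannot hold a gene plus {config.flank_bp} bp flanks"
                )
    fm = build_feature_map(genes, chrom_lengths, config.flank_bp)
    return genes, chrom_lengths, fm


# ---------------------------------------------------------------------------
# populations and environments


def _env_from_coords(lon: np.ndarray, lat: np.ndarray, noise_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """11 bioclim-like variables: fixed linear map of lon/lat plus iid noise."""
    g1 = (np.asarray(lon, float) - np.mean(_LON_RANGE)) / (np.ptp(_LON_RANGE) / 4)
    g2 = (np.asarray(lat, float) - np.mean(_LAT_RANGE)) / (np.ptp(_LAT_RANGE) / 4)
    base = np.outer(g1, np.cos(_ENV_ANGLES)) + np.outer(g2, np.sin(_ENV_ANGLES))
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, size=base.shape)
    return base


def simulate_populations(config: SimConfig) -> tuple[list[SampleInfo], pd.DataFrame]:
    """Populations on a lon/lat grid with 11 correlated environment variables.

    Returns the sample sheet and a population table (population, ploidy,
    lon, lat, bio_1..bio_11).
    """
    rng = _rng(config.seed, "populations")
    pops = []
    for x in sorted(config.n_populations_per_ploidy):
        for i in range(config.n_populations_per_ploidy[x]):
            pops.append((f"p{x}x_{i + 1:02d}", x))
    n = len(pops)
    lon = rng.uniform(*_LON_RANGE, size=n)
    lat = rng.uniform(*_LAT_RANGE, size=n)
    env = _env_from_coords(lon, lat, config.env_noise_sd, rng)
    env_df = pd.DataFrame(env, columns=list(ENV_VARS))
    env_df.insert(0, "population", [p for p, _ in pops])
    env_df.insert(1, "ploidy", [x for _, x in pops])
    env_df.insert(2, "lon", lon)
    env_df.insert(3, "lat", lat)

    samples = []
    sid = 0
    for (pop, x), lo, la in zip(pops, lon, lat):
        for _ in range(config.samples_per_population):
            sid += 1
            samples.append(SampleInfo(f"S{sid:04d}", pop, x, float(lo), float(la)))
    return samples, env_df


def simulate_env_grid(
    config: SimConfig, n_lon: int = 20, n_lat: int = 20, future_shift: dict[str, float] | None = None
) -> pd.DataFrame:
    """Gridded environment table over the sampling domain.

    ``future_shift`` adds a constant to named variables, emulating a
    projected climate (e.g. uniform warming of temperature-like variables).
    """
    rng = _rng(config.seed, "env_grid")
    lon = np.linspace(*_LON_RANGE, n_lon)
    lat = np.linspace(*_LAT_RANGE, n_lat)
    LO, LA = np.meshgrid(lon, lat)
    env = _env_from_coords(LO.ravel(), LA.ravel(), config.env_noise_sd, rng)
    df = pd.DataFrame(env, columns=list(ENV_VARS))
    df.insert(0, "pixel", [f"px{i:04d}" for i in range(len(df))])
    df.insert(1, "lon", LO.ravel())
    df.insert(2, "lat", LA.ravel())
    if future_shift:
        for var, delta in future_shift.items():
            if var not in df.columns:
                raise ValueError(f"unknown environment variable {var!r}")
            df[var] = df[var] + delta
    return df


def simulate_occurrences(config: SimConfig, env_df: pd.DataFrame,
                         per_population: int = 5) -> pd.DataFrame:
    """Occurrence records scattered around the population locations."""
    rng = _rng(config.seed, "occurrences")
    lon = np.repeat(env_df["lon"].to_numpy(), per_population) + rng.normal(0, 1.0, len(env_df) * per_population)
    lat = np.repeat(env_df["lat"].to_numpy(), per_population) + rng.normal(0, 0.7, len(env_df) * per_population)
    return pd.DataFrame({"lon": lon, "lat": lat})


# ---------------------------------------------------------------------------
# variant truth


def _hierarchical_freqs(n_var: int, pop_ploidy: np.ndarray, config: SimConfig,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Global U-shaped frequencies and Beta-drifted population frequencies.

    Between the global frequency and the population draw sits a per-variant,
    per-ploidy-group logit-normal deviation (``group_divergence_sd``):
    diploid and polyploid lineages are genuinely differentiated, which is
    what the structure-correction covariance in the association scan is
    meant to absorb.
    """
    n_pop = len(pop_ploidy)
    a, b = config.global_beta
    q = rng.beta(a, b, size=n_var)
    q = np.clip(q, 0.005, 0.995)
    groups = np.unique(pop_ploidy)
    mean = np.tile(logit(q)[:, None], (1, n_pop))
    if config.group_divergence_sd > 0 and len(groups) > 1:
        for g in groups:
            shift = rng.normal(0.0, config.group_divergence_sd, size=n_var)
            mean[:, pop_ploidy == g] += shift[:, None]
    qpop = expit(mean)
    kappa = config.drift_concentration
    p = rng.beta(qpop * kappa, (1.0 - qpop) * kappa)
    return q, np.clip(p, 0.0, 1.0)


def simulate_sv_truth(
    config: SimConfig,
    fm: FeatureMap,
    genes: Sequence[Gene],
    samples: Sequence[SampleInfo],
    env_df: pd.DataFrame,
) -> TruthTable:
    """Draw SV and SNP ground truth conditioned on annotation and cohort.

    SV candidate positions are uniform over the genome; exonic placements
    are retained with probability ``exon_thinning`` (feature-dependent
    deficit).  Population frequencies follow the hierarchical
    Beta(global)-Beta(drift) model; causal SVs get a logit-scale shift of
    ``causal_slope`` x the standardized causal environment variable; under
    ``masking_scenario='on'`` a fraction ``masking_excess`` of exonic SVs
    receives a very-low-frequency point mass (one expected copy per two
    cohorts) in ploidy > 2 populations, emulating recessive masking; with
    ``constraint_purge`` > 0, exonic SVs in strongly conserved genes are
    purged from diploid populations with probability increasing in gene
    constraint.
    """
    rng = _rng(config.seed, "truth")
    pops = env_df["population"].tolist()
    pop_ploidy = env_df["ploidy"].to_numpy()
    n_pop = len(pops)
    chroms = list(fm.chrom_lengths)
    clen = np.array([fm.chrom_lengths[c] for c in chroms])

    # per-gene true conservation level (z-scale)
    gene_levels = pd.Series(
        rng.normal(0.0, 1.0, size=len(genes)), index=[g.gene_id for g in genes]
    )
    gene_lookup = {
        g.chrom: [] for g in genes
    }
    for g in genes:
        gene_lookup[g.chrom].append(g)

    def containing_gene(chrom: str, pos0: int) -> str | None:
        for g in gene_lookup.get(chrom, []):
            if g.start - 1 <= pos0 < g.end:
                return g.gene_id
        return None

    # --- SV placement with exonic thinning
    rows = []
    guard = 0
    while len(rows) < config.n_svs and guard < 50 * config.n_svs:
        guard += 1
        ci = int(rng.integers(len(chroms)))
        chrom = chroms[ci]
        svlen = int(np.round(np.exp(rng.uniform(np.log(50), np.log(5000)))))
        svtype = "INS" if rng.random() < 0.5 else "DEL"
        pos0 = int(rng.integers(0, clen[ci] - (1 if svtype == "INS" else svlen)))
        end0 = pos0 + 1 if svtype == "INS" else pos0 + svlen
        # the true class is the class at the start breakpoint; the deletion
        # span may still cross boundaries, where span-based classification
        # will resolve by precedence instead
        klass = fm.classify(chrom, pos0, pos0 + 1)
        if klass == "exon" and rng.random() > config.exon_thinning:
            continue
        gene_id = containing_gene(chrom, pos0) if klass in ("exon", "intron") else None
        spans = fm.classify(chrom, pos0, end0) != klass
        rows.append((chrom, pos0 + 1, end0 if svtype == "DEL" else pos0 + 1,
                     svtype, svlen, klass, gene_id, spans))
    sv = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "end", "svtype", "svlen", "feature", "gene_id",
                 "spans_boundary"],
    )
    sv.insert(0, "id", [f"sv{i + 1:05d}" for i in range(len(sv))])
    n_sv = len(sv)

    q_sv, sv_freqs = _hierarchical_freqs(n_sv, pop_ploidy, config, rng)

    # --- causal climate clines
    causal = np.zeros(n_sv, dtype=bool)
    causal_env = np.full(n_sv, "", dtype=object)
    if config.n_causal_svs > 0:
        eligible = np.flatnonzero((q_sv >= 0.15) & (q_sv <= 0.85))
        if len(eligible) < config.n_causal_svs:
            raise ValueError("not enough mid-frequency SVs for the causal set")
        chosen = rng.choice(eligible, size=config.n_causal_svs, replace=False)
        causal[chosen] = True
        env_mat = env_df[list(ENV_VARS)].to_numpy()
        z = (env_mat - env_mat.mean(axis=0)) / env_mat.std(axis=0)
        for i in chosen:
            v = int(rng.integers(N_ENV_VARS))
            causal_env[i] = ENV_VARS[v]
            mean = expit(logit(np.clip(q_sv[i], 0.01, 0.99)) + config.causal_slope * z[:, v])
            kappa = config.drift_concentration
            sv_freqs[i] = rng.beta(mean * kappa, (1.0 - mean) * kappa)
    sv["causal"] = causal
    sv["causal_env"] = causal_env

    # --- ploidy-restricted SVs: present in one ploidy group only (new SVs
    # arising after the WGD, or lost from one lineage); polyploids carry more
    restricted = np.full(n_sv, "", dtype=object)
    dip_pops = np.flatnonzero(pop_ploidy == 2)
    tet_pops = np.flatnonzero(pop_ploidy > 2)
    if len(dip_pops) and len(tet_pops):
        u = rng.random(n_sv)
        tet_only = u < config.sv_restricted_tetraploid
        dip_only = (u >= config.sv_restricted_tetraploid) & (
            u < config.sv_restricted_tetraploid + config.sv_restricted_diploid
        )
        sv_freqs[np.ix_(np.flatnonzero(tet_only), dip_pops)] = 0.0
        sv_freqs[np.ix_(np.flatnonzero(dip_only), tet_pops)] = 0.0
        restricted[tet_only] = "tetraploid"
        restricted[dip_only] = "diploid"
    sv["restricted_to"] = restricted

    # --- recessive-masking excess of rare exonic SVs in polyploids
    if config.masking_scenario == "on":
        poly = pop_ploidy > 2
        chrom_counts = np.array(
            [pop_ploidy[j] * config.samples_per_population for j in range(n_pop)]
        )
        n_chrom_poly = int(chrom_counts[poly].sum())
        exonic = np.flatnonzero(sv["feature"].to_numpy() == "exon")
        hit = exonic[rng.random(len(exonic)) < config.masking_excess]
        sv_freqs[np.ix_(hit, np.flatnonzero(poly))] = 1.0 / (2.0 * n_chrom_poly)
        sv["masked_excess"] = np.isin(np.arange(n_sv), hit)
    else:
        sv["masked_excess"] = False

    # --- constraint-dependent purging from diploids
    if config.constraint_purge > 0:
        from scipy.stats import norm

        dip = np.flatnonzero(pop_ploidy == 2)
        for i in range(n_sv):
            gid = sv.at[i, "gene_id"]
            if sv.at[i, "feature"] != "exon" or gid is None:
                continue
            p_purge = config.constraint_purge * norm.cdf(gene_levels[gid])
            if rng.random() < p_purge:
                sv_freqs[i, dip] = 0.0

    # --- SNP truth (uniform positions, no feature bias)
    snp_ci = rng.integers(len(chroms), size=config.n_snps)
    snp_pos = rng.integers(1, clen[snp_ci] + 1)
    order = np.lexsort((snp_pos, snp_ci))
    snp = pd.DataFrame(
        {
            "id": [f"snp{i + 1:05d}" for i in range(config.n_snps)],
            "chrom": [chroms[i] for i in snp_ci[order]],
            "pos": snp_pos[order],
        }
    )
    _, snp_freqs = _hierarchical_freqs(config.n_snps, pop_ploidy, config, rng)

    return TruthTable(
        sv=sv,
        sv_freqs=sv_freqs,
        snp=snp,
        snp_freqs=snp_freqs,
        populations=pops,
        gene_constraint=gene_levels,
    )


# ---------------------------------------------------------------------------
# genotypes and read counts


def simulate_genotypes(
    freqs: np.ndarray, samples: Sequence[SampleInfo], populations: Sequence[str],
    rng: np.random.Generator
) -> np.ndarray:
    """True genotypes g ~ Binomial(ploidy, population frequency)."""
    pop_index = {p: j for j, p in enumerate(populations)}
    cols = np.array([pop_index[s.population] for s in samples])
    x = np.array([s.ploidy for s in samples])
    return rng.binomial(x[None, :], freqs[:, cols])


def _beta_binomial(n: np.ndarray, mean: np.ndarray, rho: float,
                   rng: np.random.Generator) -> np.ndarray:
    if rho == 0:
        return rng.binomial(n, mean)
    a = mean * (1.0 - rho) / rho
    b = (1.0 - mean) * (1.0 - rho) / rho
    pi = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
    return rng.binomial(n, pi)


def simulate_read_counts(
    truth: TruthTable, samples: Sequence[SampleInfo], config: SimConfig
) -> tuple[list[SVRecord], list[SNPRecord]]:
    """Beta-binomial read counts over true genotypes, as VCF-ready records.

    Per sample: depth ~ Poisson(depth_mean); alt reads ~ BetaBinomial(depth,
    g/x adjusted by the error rate, overdispersion rho); a ``missing_rate``
    fraction of calls is masked.  The written GT is the true genotype (the
    generator emulates a caller that got the genotype right; downstream
    dosage estimation never uses GT).
    """
    rng = _rng(config.seed, "reads")
    x = np.array([s.ploidy for s in samples])
    e = config.error_rate

    def _records(table: pd.DataFrame, freqs: np.ndarray, kind: str):
        g = simulate_genotypes(freqs, samples, truth.populations, rng)
        out = []
        for i, row in enumerate(table.itertuples()):
            depth = rng.poisson(config.depth_mean, size=len(samples))
            frac = g[i] / x
            mean = frac * (1.0 - e) + (1.0 - frac) * e
            alt = _beta_binomial(depth, mean, config.overdispersion_rho, rng)
            missing = (rng.random(len(samples)) < config.missing_rate) | (depth == 0)
            if kind == "sv":
                out.append(
                    SVRecord(
                        id=row.id, chrom=row.chrom, pos=int(row.pos), end=int(row.end),
                        svtype=row.svtype, svlen=int(row.svlen),
                        qual=float(np.round(rng.uniform(25, 60), 1)),
                        ref_reads=depth - alt, alt_reads=alt,
                        missing=missing, gt=g[i].astype(int),
                    )
                )
            else:
                out.append(
                    SNPRecord(
                        id=row.id, chrom=row.chrom, pos=int(row.pos), ref="A", alt="T",
                        qual=float(np.round(rng.uniform(50, 500), 1)),
                        info={"MQ": 60.0, "MQRankSum": 0.0, "QD": 25.0, "FS": 1.0,
                              "ReadPosRankSum": 0.0},
                        ref_reads=depth - alt, alt_reads=alt, missing=missing,
                        gt=g[i].astype(int),
                        gq=np.full(len(samples), 99, dtype=int),
                    )
                )
        return out

    sv_records = _records(truth.sv, truth.sv_freqs, "sv")
    snp_records = _records(truth.snp, truth.snp_freqs, "snp")
    return sv_records, snp_records


# ---------------------------------------------------------------------------
# conservation scores


def simulate_conservation(
    genes: Sequence[Gene], truth: TruthTable, config: SimConfig
) -> pd.DataFrame:
    """Per-exonic-site conservation scores with per-site maxima.

    Each coding site of a gene with true constraint level c gets a per-site
    maximum possible score (the attainable range varies between sites, as it
    does when the score depends on local alignment depth) and a raw score
    max * sigmoid(c + noise), so normalized scores live in (0, 1) and the
    per-gene median tracks sigmoid(c).
    """
    rng = _rng(config.seed, "conservation")
    rows_chrom, rows_pos, rows_score, rows_max, rows_gene = [], [], [], [], []
    for g in genes:
        level = float(truth.gene_constraint[g.gene_id])
        for es, ee in g.exons:
            n = ee - es + 1
            site_max = rng.uniform(1.5, 4.0, size=n)
            frac = expit(level + rng.normal(0.0, 0.5, size=n))
            rows_chrom.extend([g.chrom] * n)
            rows_pos.extend(range(es, ee + 1))
            rows_score.extend(site_max * frac)
            rows_max.extend(site_max)
            rows_gene.extend([g.gene_id] * n)
    return pd.DataFrame(
        {
            "chrom": rows_chrom,
            "pos": rows_pos,
            "score": np.round(rows_score, 4),
            "max_score": np.round(rows_max, 4),
            "gene_id": rows_gene,
        }
    )


# ---------------------------------------------------------------------------
# divergent sequence pairs (TE insertion-time emulation)

_BASES = np.array(list("ACGT"))


def simulate_divergent_pair(
    length: int,
    T: float,
    mu: float = 6.95e-9,
    seed: int = 0,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[str, str]:
    """A sequence and its relative diverged for T years at rate mu.

    Substitutions follow an F81 process with stationary ``base_freqs``,
    scaled so the expected number of substitutions per site between the two
    sequences is K = 2*T*mu.  Raises once K approaches saturation (observed
    divergence indistinguishable from the stationary mismatch rate B).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    pi = np.asarray(base_freqs, dtype=float)
    pi = pi / pi.sum()
    B = 1.0 - np.sum(pi**2)
    K = 2.0 * T * mu
    if K >= -B * np.log(1e-4):
        raise ValueError(
            f"expected divergence K={K:.3g} is beyond the F81 saturation bound "
            f"for B={B:.3g}; the distance is unidentifiable"
        )
    rng = _rng(seed, "divergent_pair")
    anc = rng.choice(4, size=length, p=pi)
    # tip-to-tip transition over total path length 2T:
    # stay with prob e^(-K/B), otherwise redraw from the stationary mix
    stay = np.exp(-K / B)
    redraw = rng.random(length) >= stay
    der = anc.copy()
    der[redraw] = rng.choice(4, size=int(redraw.sum()), p=pi)
    return "".join(_BASES[anc]), "".join(_BASES[der])


# ---------------------------------------------------------------------------
# table writers


def write_env_table(env_df: pd.DataFrame, path) -> None:
    env_df.to_csv(path, sep="\t", index=False)


def write_conservation_table(cons_df: pd.DataFrame, path) -> None:
    cons_df.to_csv(path, sep="\t", index=False)
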