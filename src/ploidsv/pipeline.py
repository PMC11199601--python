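"""End-to-end orchestration: simulate -> filter -> dosage -> statistics ->
adaptation scan -> climatic landscape, from one YAML config, with a
provenance manifest of content digests so identical configs reproduce
identical outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, adapt, climscape, dosage, featcons, popgen, svio, synthcohort
from .synthcohort import ENV_VARS, SimConfig

logger = logging.getLogger(__name__)

#: small cohort that exercises every stage in well under a minute
DEMO_CONFIG = {
    "seed": 7,
    "n_chromosomes": 2,
    "chrom_length": 300_000,
    "n_genes": 12,
    "n_populations_per_ploidy": {2: 10, 4: 10},
    "samples_per_population": 6,
    "n_svs": 400,
    "n_snps": 400,
    "exon_thinning": 0.5,
    "masking_scenario": "on",
    "n_causal_svs": 20,
}


def load_config(path: str | Path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimConfig:
    valid = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "n_populations_per_ploidy" in raw:
        raw = dict(raw)
        raw["n_populations_per_ploidy"] = {
            int(k): int(v) for k, v in raw["n_populations_per_ploidy"].items()
        }
    if "global_beta" in raw:
        raw["global_beta"] = tuple(raw["global_beta"])
    return SimConfig(**raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: SimConfig) -> str:
    canon = yaml.safe_dump(asdict(config), sort_keys=True, default_flow_style=None)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: SimConfig, out_dir: str | Path) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Stage outputs are plain-text tables under ``out_dir``; ``summary.json``
    aggregates the headline analyses (diversity and Tajima's D per ploidy,
    feature enrichment per ploidy group, GEA outlier counts,
    ploidy-specific proportions, sweep/GEA association, RDA variance
    decomposition and the SV-vs-SNP climatic-distance summary).
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "ploidsv",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    prior = None
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        try:
            prior = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prior = None

    def record_stage(name: str, files: list[Path]) -> None:
        manifest["stages"][name] = {f.name: _digest(f) for f in files}

    def stage_cached(name: str, files: list[str]) -> bool:
        if prior is None or prior.get("config_hash") != manifest["config_hash"]:
            return False
        saved = prior.get("stages", {}).get(name)
        if saved is None or set(saved) != set(files):
            return False
        return all((out / f).exists() and _digest(out / f) == h for f, h in saved.items())

    # ---- stage: simulate ------------------------------------------------
    genes, chrom_lengths, fm = synthcohort.simulate_annotation(config)
    samples, env_df = synthcohort.simulate_populations(config)
    truth = synthcohort.simulate_sv_truth(config, fm, genes, samples, env_df)
    sim_files = [
        "genes.gff3", "samples.tsv", "populations.tsv", "sv.vcf", "snp.vcf",
        "conservation.tsv", "env_grid.tsv", "env_grid_future.tsv",
        "occurrences.tsv", "truth.yaml",
    ]
    if stage_cached("simulate", sim_files):
        logger.info("simulate stage cached; reusing outputs")
        manifest["stages"]["simulate"] = prior["stages"]["simulate"]
    else:
        sv_records, snp_records = synthcohort.simulate_read_counts(truth, samples, config)
        svio.write_gff3(genes, chrom_lengths, out / "genes.gff3")
        svio.write_sample_sheet(samples, out / "samples.tsv")
        synthcohort.write_env_table(env_df, out / "populations.tsv")
        svio.write_sv_vcf(sv_records, samples, out / "sv.vcf", chrom_lengths)
        svio.write_snp_vcf(snp_records, samples, out / "snp.vcf", chrom_lengths)
        cons = synthcohort.simulate_conservation(genes, truth, config)
        synthcohort.write_conservation_table(cons, out / "conservation.tsv")
        grid_now = synthcohort.simulate_env_grid(config)
        grid_fut = synthcohort.simulate_env_grid(
            config, future_shift={v: 0.5 for v in ENV_VARS[:4]}
        )
        grid_now.to_csv(out / "env_grid.tsv", sep="\t", index=False)
        grid_fut.to_csv(out / "env_grid_future.tsv", sep="\t", index=False)
        occ = synthcohort.simulate_occurrences(config, env_df)
        occ.to_csv(out / "occurrences.tsv", sep="\t", index=False)
        truth.to_yaml(out / "truth.yaml")
        record_stage("simulate", [out / f for f in sim_files])

    # ---- stage: read + filter ------------------------------------------
    samples = svio.read_sample_sheet(out / "samples.tsv")
    genes, chrom_lengths = svio.read_gff3(out / "genes.gff3")
    fm = svio.build_feature_map(genes, chrom_lengths, config.flank_bp)
    sv_records = svio.read_sv_vcf(out / "sv.vcf", samples)
    snp_records = svio.read_snp_vcf(out / "snp.vcf", samples)
    sv_kept, sv_stats = svio.filter_svs(sv_records, samples)
    snp_kept, snp_stats = svio.hard_filter_snps(snp_records, samples)

    # ---- stage: dosage --------------------------------------------------
    sv_dm = dosage.dosage_matrix(sv_kept, samples,
                                 config.error_rate, config.overdispersion_rho)
    snp_dm = dosage.dosage_matrix(snp_kept, samples,
                                  config.error_rate, config.overdispersion_rho)
    sv_pfm = dosage.population_frequencies(sv_dm, samples)
    snp_pfm = dosage.population_frequencies(snp_dm, samples)
    pd.DataFrame(sv_dm.dosage, columns=[s.sample for s in samples]).to_csv(
        out / "sv_dosage.tsv", sep="\t", index=False
    )
    with open(out / "dosage_params.json", "w") as fh:
        json.dump({"error_rate": config.error_rate,
                   "rho": config.overdispersion_rho}, fh)

    summary: dict = {
        "n_samples": len(samples),
        "sv_filter": sv_stats,
        "snp_filter": snp_stats,
    }

    # ---- stage: population statistics -----------------------------------
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 901]))
    x = svio.ploidies(samples)
    sv_class = np.array([featcons.classify_sv(r, fm) for r in sv_kept])
    afs_summary = {}
    for level in sorted({s.ploidy for s in samples}):
        cols = x == level
        sub_x = x[cols]
        for feature in ("exon", "intergenic", "all"):
            sel = slice(None) if feature == "all" else np.flatnonzero(sv_class == feature)
            dos = sv_dm.dosage[sel][:, cols]
            mis = sv_dm.missing[sel][:, cols]
            ok = mis.mean(axis=1) <= 0.2
            afs = popgen.folded_afs(dos[ok], mis[ok], sub_x, label=feature, rng=rng)
            for excl in (False, True):
                res = popgen.tajimas_d(afs, exclude_singletons=excl)
                afs_summary[f"{level}x_{feature}_{'noS' if excl else 'full'}"] = {
                    "D": res.D, "S": res.S,
                }
    summary["tajima_by_class"] = afs_summary

    # ---- stage: enrichment and constraint --------------------------------
    enrich = {}
    for level in sorted({s.ploidy for s in samples}):
        cols = x == level
        present = np.array(
            [
                (np.nan_to_num(r_dos) > 0.5).any()
                for r_dos in np.where(sv_dm.missing, 0, sv_dm.dosage)[:, cols]
            ]
        )
        res = featcons.feature_enrichment(sv_class[present], fm, seed=config.seed)
        enrich[f"{level}x"] = res.table.to_dict(orient="records")
    summary["enrichment"] = enrich

    cons = pd.read_csv(out / "conservation.tsv", sep="\t")
    constraint = featcons.gene_constraint(cons)
    constraint.table.to_csv(out / "gene_constraint.tsv", sep="\t", index=False)

    # ---- stage: GEA + sweeps ---------------------------------------------
    env_pop = pd.read_csv(out / "populations.tsv", sep="\t")
    env_mat = env_pop[list(ENV_VARS)]
    snp_keep = svio.ld_prune(snp_dm.dosage, x, missing=snp_dm.missing)
    if len(snp_keep) >= 2:
        C = popgen.ploidy_covariance(
            snp_dm.dosage[snp_keep], snp_dm.missing[snp_keep], x
        )
        omega = _population_covariance(C, samples, sv_pfm.populations)
    else:
        omega = np.eye(len(sv_pfm.populations))
    maf = np.minimum(sv_pfm.freqs, 1 - sv_pfm.freqs)
    pop_w = sv_pfm.chrom_counts / sv_pfm.chrom_counts.sum()
    overall_maf = np.minimum((sv_pfm.freqs * pop_w).sum(axis=1),
                             1 - (sv_pfm.freqs * pop_w).sum(axis=1))
    usable = (overall_maf > 0.05) & (sv_pfm.missing.mean(axis=1) <= 0.2)
    freqs = dosage.impute_population_frequencies_beta(
        dosage.PopulationFrequencyMatrix(
            sv_pfm.freqs[usable], sv_pfm.missing[usable],
            sv_pfm.populations, sv_pfm.chrom_counts,
        ),
        rng,
    )
    ids = [r.id for r, u in zip(sv_kept, usable) if u]
    gea = adapt.gea_scan(freqs, env_mat, omega, seed=config.seed, variant_ids=ids)
    gea.to_frame().to_csv(out / "gea.tsv", sep="\t", index=False)
    outliers = adapt.call_outliers(gea)
    summary["gea"] = {
        "method": gea.method,
        "n_tested": int(usable.sum()),
        "n_outliers": int(outliers.sum()),
    }

    pop_ploidy = env_pop.set_index("population")["ploidy"]
    group_of_pop = np.array(
        ["diploid" if pop_ploidy[p] == 2 else "tetraploid" if pop_ploidy[p] == 4
         else "higher" for p in sv_pfm.populations]
    )
    if {"diploid", "tetraploid"} <= set(group_of_pop):
        ps = adapt.ploidy_specific(
            sv_pfm.freqs[usable], sv_pfm.chrom_counts, group_of_pop, variant_ids=ids
        )
        summary["ploidy_specific"] = {
            "proportions": ps.proportions, "fisher_p": ps.fisher_p,
        }

    sweep_summary = _sweeps(samples, snp_kept, snp_dm, sv_kept, usable,
                            gea, outliers, sv_pfm, out)
    if sweep_summary:
        summary["sweeps"] = sweep_summary

    # ---- stage: landscape -------------------------------------------------
    try:
        summary["landscape"] = _landscape(config, out, env_pop, freqs, snp_pfm,
                                          gea, outliers, rng)
    except ValueError as exc:
        summary["landscape"] = {"skipped": str(exc)}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonify)
    record_stage("analyze", [out / "summary.json", out / "gea.tsv"])
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _population_covariance(C: np.ndarray, samples, populations,
                           shrinkage: float = 0.2) -> np.ndarray:
    """Aggregate an individual covariance to populations (pairwise means),
    shrunk toward a scaled identity so whitening stays well-conditioned
    (a raw block-mean estimate can be near-singular, and whitening with a
    near-singular matrix lets one tiny eigendirection dominate every
    whitened vector)."""
    pop_of = np.array([s.population for s in samples])
    n = len(populations)
    omega = np.zeros((n, n))
    for i, a in enumerate(populations):
        for j, b in enumerate(populations):
            omega[i, j] = C[np.ix_(pop_of == a, pop_of == b)].mean()
    omega = (omega + omega.T) / 2
    target = (np.trace(omega) / n) * np.eye(n)
    omega = (1 - shrinkage) * omega + shrinkage * target
    vals = np.linalg.eigvalsh(omega)
    if vals.min() <= 0:
        omega += (abs(vals.min()) + 1e-6 * max(vals.max(), 1.0)) * np.eye(n)
    return omega


def _sweeps(samples, snp_kept, snp_dm, sv_kept, usable, gea, outliers,
            sv_pfm, out: Path):
    from collections import Counter

    pop_sizes = Counter(s.population for s in samples)
    eligible = [p for p in sv_pfm.populations if pop_sizes[p] >= 6]
    if not eligible:
        return None
    x = np.array([s.ploidy for s in samples])
    pop_of = np.array([s.population for s in samples])
    minor = {}
    backgrounds = {}
    for pop in eligible:
        cols = pop_of == pop
        dos = snp_dm.dosage[:, cols]
        mis = snp_dm.missing[:, cols]
        n_chrom = int(x[cols].sum())
        counts = popgen.round_half_up(np.where(mis, 0, dos).sum(axis=1)).astype(int)
        counts = np.minimum(counts, n_chrom - counts)
        if (counts > 0).sum() == 0:
            continue
        minor[pop] = counts
        backgrounds[pop] = adapt.background_sfs(counts[counts > 0], n_chrom)
    eligible = [p for p in eligible if p in backgrounds]
    if not eligible:
        return None
    used = [r for r, u in zip(sv_kept, usable) if u]
    sv_table = pd.DataFrame(
        {
            "id": [r.id for r in used],
            "chrom": [r.chrom for r in used],
            "pos": [r.pos for r in used],
            "end": [r.end for r in used],
        }
    )
    snp_table = pd.DataFrame(
        {"chrom": [r.chrom for r in snp_kept], "pos": [r.pos for r in snp_kept]}
    )
    sweep = adapt.max_clr_per_sv(sv_table, snp_table, minor, backgrounds, eligible)
    sweep.per_population.to_csv(out / "sweep_clr.tsv", sep="\t", index=False)
    clr = sweep.max_clr.reindex(sv_table["id"])
    ok = clr.notna().to_numpy()
    if ok.sum() < 3:
        return {"n_svs_scored": int(ok.sum())}
    comp = adapt.compare_outliers(
        clr.to_numpy()[ok], gea.median_db[ok], outliers[ok]
    )
    return {
        "n_svs_scored": int(ok.sum()),
        "spearman_rho": comp.spearman_rho,
        "spearman_p": comp.spearman_p,
        "wilcoxon_p": comp.wilcoxon_p,
    }


def _landscape(config, out: Path, env_pop, sv_freqs, snp_pfm, gea, outliers, rng):
    env_mat = env_pop[list(ENV_VARS)]
    if outliers.sum() >= 2:
        Y_sv = sv_freqs[outliers]
    else:
        Y_sv = sv_freqs
    snp_freqs = dosage.impute_population_frequencies_beta(snp_pfm, rng)
    model_sv = climscape.fit_rda(Y_sv.T, env_mat)
    model_snp = climscape.fit_rda(snp_freqs.T, env_mat)
    grid = pd.read_csv(out / "env_grid.tsv", sep="\t")
    grid_fut = pd.read_csv(out / "env_grid_future.tsv", sep="\t")
    idx_sv = climscape.adaptive_index(model_sv, grid)
    idx_snp = climscape.adaptive_index(model_snp, grid)
    dist = climscape.climatic_distance(idx_sv, idx_snp)
    dist.to_csv(out / "climatic_distance.tsv", sep="\t", index=False)
    offset = climscape.future_offset(model_sv, grid, grid_fut)
    offset.to_csv(out / "future_offset.tsv", sep="\t", index=False)
    coords = env_pop[["lon", "lat"]].to_numpy()
    n = len(env_pop)
    geo = climscape.geo_pcoa(
        coords[:, 0], coords[:, 1], n_coords=max(1, min(10, n - 14))
    )
    try:
        decomp = climscape.partial_rda_decomposition(
            Y_sv.T,
            {
                "climate": env_mat,
                "geography": geo,
                "ploidy": env_pop["ploidy"].to_numpy(dtype=float)[:, None],
            },
        )
    except ValueError as exc:
        decomp = {"skipped": str(exc)}
    return {
        "rda_r2_sv": model_sv.r2,
        "rda_r2_snp": model_snp.r2,
        "mean_climatic_distance": float(dist["normalized_distance"].mean()),
        "mean_future_offset": float(offset["offset"].mean()),
        "variance_decomposition": decomp,
    }
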