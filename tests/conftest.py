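import numpy as np
import pytest

from ploidsv import svio, synthcohort as sc


@pytest.fixture(scope="session")
def small_config():
    return sc.SimConfig(
        seed=11,
        n_populations_per_ploidy={2: 4, 4: 4},
        samples_per_population=4,
        n_svs=120,
        n_snps=80,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One fully simulated small cohort shared across read-only tests."""
    cfg = small_config
    genes, chrom_lengths, fm = sc.simulate_annotation(cfg)
    samples, env = sc.simulate_populations(cfg)
    truth = sc.simulate_sv_truth(cfg, fm, genes, samples, env)
    sv_records, snp_records = sc.simulate_read_counts(truth, samples, cfg)
    return {
        "config": cfg,
        "genes": genes,
        "chrom_lengths": chrom_lengths,
        "fm": fm,
        "samples": samples,
        "env": env,
        "truth": truth,
        "sv_records": sv_records,
        "snp_records": snp_records,
    }


def make_samples(ploidies, population="pop1"):
    """Quick sample sheet for unit tests."""
    return [
        svio.SampleInfo(f"s{i}", population if isinstance(population, str) else population[i],
                        int(x), 0.0, 50.0)
        for i, x in enumerate(ploidies)
    ]


def make_sv(n_samples=4, svtype="INS", pos=100, svlen=100, qual=30.0, **kw):
    """Minimal SVRecord with benign per-sample data."""
    end = pos if svtype == "INS" else pos + svlen - 1
    defaults = dict(
        id=kw.pop("id", "sv1"),
        chrom=kw.pop("chrom", "chr1"),
        pos=pos,
        end=kw.pop("end", end),
        svtype=svtype,
        svlen=svlen,
        qual=qual,
        ref_reads=kw.pop("ref_reads", np.full(n_samples, 20)),
        alt_reads=kw.pop("alt_reads", np.full(n_samples, 20)),
        missing=kw.pop("missing", np.zeros(n_samples, dtype=bool)),
        gt=kw.pop("gt", np.ones(n_samples, dtype=int)),
    )
    defaults.update(kw)
    return svio.SVRecord(**defaults)
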