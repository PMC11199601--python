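"""SV feature enrichment and gene-constraint summaries.

Under a uniform null, SVs fall into genomic feature classes in proportion
to the bp each class covers; observed/expected ratios (log2) with
percentile-bootstrap CIs quantify depletion or excess per class.  Gene
constraint summarizes per-site conservation scores, normalized by the
per-site attainable maximum, to a per-gene median that is standardized to
median 0 / MAD 1 across genes (MAD unscaled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .svio import FEATURE_CLASSES, FeatureMap, SVRecord

logger = logging.getLogger(__name__)


def classify_sv(sv: SVRecord, fm: FeatureMap) -> str:
    """Feature class of one SV (INS = breakpoint, DEL = span), resolved by
    precedence exon > intron > flank > intergenic."""
    if not sv.analyzable:
        raise ValueError(f"{sv.id}: svtype {sv.svtype} is not analyzable")
    start, end = sv.interval()
    return fm.classify(sv.chrom, start, end)


@dataclass
class EnrichmentResult:
    """Observed vs expected SV counts per feature class, with bootstrap CIs.

    ``table`` columns: feature, observed, expected, log2_ratio, ci_lo,
    ci_hi, zero_corrected.  Expected counts are N_sv * bp_share and sum to
    the observed total.
    """

    table: pd.DataFrame
    n_boot: int
    seed: int

    def __getitem__(self, feature: str) -> pd.Series:
        return self.table.set_index("feature").loc[feature]


def _log2_ratio(obs: np.ndarray, exp: np.ndarray, corrected: np.ndarray) -> np.ndarray:
    o = np.where(corrected, obs + 0.5, obs)
    e = np.where(corrected, exp + 0.5, exp)
    with np.errstate(divide="ignore"):
        return np.log2(o / e)


def feature_enrichment(
    classes: Sequence[str],
    fm: FeatureMap,
    n_boot: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """log2 observed/expected SV counts per feature class with 95% CIs.

    ``classes`` are per-SV feature labels (see :func:`classify_sv`).  The
    CI comes from resampling SVs with replacement ``n_boot`` times (as the
    class label is the only SV property used, this is a multinomial draw on
    the observed class proportions).  Classes with zero observations get a
    0.5 continuity correction and are flagged.
    """
    if fm.genome_bp <= 0:
        raise ValueError("feature map has no positive totals")
    labels = np.asarray(list(classes))
    unknown = set(labels) - set(FEATURE_CLASSES)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    obs = np.array([(labels == c).sum() for c in FEATURE_CLASSES], dtype=float)
    n_sv = float(obs.sum())
    if n_sv == 0:
        raise ValueError("no SVs to test")
    share = np.array([fm.class_bp[c] / fm.genome_bp for c in FEATURE_CLASSES])
    exp = n_sv * share
    corrected = obs == 0
    if corrected.any():
        logger.warning(
            "zero observed SVs in %s: applying 0.5 continuity correction",
            [c for c, z in zip(FEATURE_CLASSES, corrected) if z],
        )
    point = _log2_ratio(obs, exp, corrected)

    rng = np.random.default_rng(seed)
    boot_counts = rng.multinomial(int(n_sv), obs / n_sv, size=n_boot).astype(float)
    boot_corr = boot_counts == 0
    boot = _log2_ratio(boot_counts, np.broadcast_to(exp, boot_counts.shape), boot_corr)
    lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)

    table = pd.DataFrame(
        {
            "feature": list(FEATURE_CLASSES),
            "observed": obs.astype(int),
            "expected": exp,
            "log2_ratio": point,
            "ci_lo": lo,
            "ci_hi": hi,
            "zero_corrected": corrected,
        }
    )
    return EnrichmentResult(table=table, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# conservation


def normalize_conservation(score: np.ndarray, max_score: np.ndarray) -> np.ndarray:
    """Scale per-site scores by the per-site attainable maximum.

    Values above 1 (possible under rate variation) are clipped to 1;
    negative scores pass through unclipped.  Sites with non-positive maxima
    are dropped with a log entry.
    """
    score = np.asarray(score, dtype=float)
    max_score = np.asarray(max_score, dtype=float)
    bad = max_score <= 0
    if bad.any():
        logger.warning("skipping %d sites with non-positive max score", int(bad.sum()))
    out = np.minimum(score[~bad] / max_score[~bad], 1.0)
    return out


@dataclass
class GeneConstraint:
    """Per-gene conservation: raw medians and median-0 / MAD-1 standardized."""

    table: pd.DataFrame  # gene_id, median_score, standardized

    def standardized(self, gene_id: str) -> float:
        return float(self.table.set_index("gene_id").loc[gene_id, "standardized"])


def gene_constraint(site_table: pd.DataFrame) -> GeneConstraint:
    """Gene-level constraint from per-site (gene_id, score, max_score) rows.

    Each gene's value is the median normalized score over its coding sites;
    values are then standardized across genes to median 0 and unscaled MAD 1.
    Zero MAD across genes is an error (degenerate standardization).
    """
    required = {"gene_id", "score", "max_score"}
    if not required.issubset(site_table.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    ok = site_table["max_score"] > 0
    if not ok.all():
        logger.warning("skipping %d sites with non-positive max score", int((~ok).sum()))
    df = site_table.loc[ok].copy()
    df["normalized"] = np.minimum(df["score"] / df["max_score"], 1.0)
    med = df.groupby("gene_id")["normalized"].median()
    center = med.median()
    mad = (med - center).abs().median()
    if mad == 0:
        raise ValueError("MAD across genes is zero; constraint cannot be standardized")
    table = pd.DataFrame(
        {
            "gene_id": med.index,
            "median_score": med.to_numpy(),
            "standardized": ((med - center) / mad).to_numpy(),
        }
    ).reset_index(drop=True)
    return GeneConstraint(table=table)


def constraint_by_ploidy(
    sv_genes: dict[str, Sequence[str]],
    constraints: GeneConstraint,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Median standardized constraint of genes hit by exonic SVs, per group.

    ``sv_genes`` maps a ploidy-group label to the gene ids hit by that
    group's exonic SVs (one entry per SV, so recurrently hit genes weigh
    more).  The 95% CI is a percentile bootstrap over SVs.
    """
    lookup = constraints.table.set_index("gene_id")["standardized"]
    rng = np.random.default_rng(seed)
    rows = []
    for group, genes in sv_genes.items():
        vals = lookup.reindex(list(genes)).dropna().to_numpy()
        if vals.size == 0:
            raise ValueError(f"group {group!r} has no exonic SVs hitting scored genes")
        point = float(np.median(vals))
        if vals.size == 1:
            lo = hi = point
        else:
            idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
            boots = np.median(vals[idx], axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((group, vals.size, point, float(lo), float(hi)))
    return pd.DataFrame(
        rows, columns=["group", "n_svs", "median_constraint", "ci_lo", "ci_hi"]
    )
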