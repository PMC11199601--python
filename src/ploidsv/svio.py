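"""Readers, writers, and filtering rules for SV / SNP call sets and annotations.

Internal coordinates are 0-based half-open; VCF and GFF3 positions (1-based,
inclusive) are converted at the boundary.  Insertions are treated as 1-bp
point events at their breakpoint, deletions as the breakpoint span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: feature classes in precedence order (highest first)
FEATURE_CLASSES = ("exon", "intron", "flank", "intergenic")
_CLASS_CODE = {name: i for i, name in enumerate(FEATURE_CLASSES)}

ANALYZABLE_SVTYPES = ("INS", "DEL")


# ---------------------------------------------------------------------------
# sample sheets


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced individual: cohort membership and geography."""

    sample: str
    population: str
    ploidy: int
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4, 6, 8):
            raise ValueError(
                f"ploidy must be an even level in 2..8, got {self.ploidy} "
                f"for sample {self.sample}"
            )


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "population", "ploidy", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleInfo(str(r.sample), str(r.population), int(r.ploidy), float(r.lon), float(r.lat))
        for r in df.itertuples()
    ]


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [s.sample for s in samples],
            "population": [s.population for s in samples],
            "ploidy": [s.ploidy for s in samples],
            "lon": [s.lon for s in samples],
            "lat": [s.lat for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def ploidies(samples: Sequence[SampleInfo]) -> np.ndarray:
    return np.array([s.ploidy for s in samples], dtype=int)


# ---------------------------------------------------------------------------
# variant records


@dataclass
class SVRecord:
    """One insertion or deletion with per-sample read support.

    ``pos`` and ``end`` are 1-based inclusive; for insertions ``end == pos``.
    ``gt`` holds the caller's alternate-copy count per sample (-1 = missing).
    """

    id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    qual: float
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    missing: np.ndarray
    gt: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.svlen < 1:
            raise ValueError(f"{self.id}: svlen must be >= 1, got {self.svlen}")
        if self.svtype == "DEL" and self.end - self.pos + 1 != self.svlen:
            raise ValueError(
                f"{self.id}: DEL must satisfy end - pos + 1 == svlen "
                f"({self.end} - {self.pos} + 1 != {self.svlen})"
            )
        if self.svtype == "INS" and self.end != self.pos:
            raise ValueError(f"{self.id}: INS must have end == pos")

    @property
    def analyzable(self) -> bool:
        return self.svtype in ANALYZABLE_SVTYPES

    @property
    def depth(self) -> np.ndarray:
        return self.ref_reads + self.alt_reads

    def interval(self) -> tuple[int, int]:
        """Feature-assignment interval, 0-based half-open."""
        if self.svtype == "INS":
            return self.pos - 1, self.pos
        return self.pos - 1, self.end

    @property
    def support(self) -> int:
        """Read support: alt reads in the strongest carrier sample."""
        return int(np.max(self.alt_reads, initial=0))

    @property
    def support_total(self) -> int:
        """Total depth in the strongest carrier sample."""
        if self.alt_reads.size == 0:
            return 0
        i = int(np.argmax(self.alt_reads))
        return int(self.ref_reads[i] + self.alt_reads[i])


@dataclass
class SNPRecord:
    """One biallelic SNP with caller annotations and per-sample calls."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    info: dict
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    missing: np.ndarray
    gt: np.ndarray | None = None
    gq: np.ndarray | None = None

    @property
    def depth(self) -> np.ndarray:
        return self.ref_reads + self.alt_reads


# ---------------------------------------------------------------------------
# VCF IO (pysam)

_SV_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (alt copy count over ploidy)">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
]


def _check_samples(vcf_samples: Sequence[str], samples: Sequence[SampleInfo]) -> None:
    want = [s.sample for s in samples]
    if list(vcf_samples) != want:
        extra = sorted(set(vcf_samples) - set(want))
        absent = sorted(set(want) - set(vcf_samples))
        raise ValueError(
            f"VCF / sample-sheet mismatch: VCF-only={extra}, sheet-only={absent}"
        )


def _info_get(rec, key, default=None):
    # pysam raises instead of returning a default when the key is not in
    # the header at all
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _gt_string(g: int, ploidy: int) -> str:
    if g < 0:
        return "/".join(["."] * ploidy)
    return "/".join(["1"] * g + ["0"] * (ploidy - g))


def read_sv_vcf(path: str | Path, samples: Sequence[SampleInfo]) -> list[SVRecord]:
    """Read an SV VCF into normalized :class:`SVRecord` objects.

    Unknown SVTYPEs are retained but flagged non-analyzable; deletions with
    only an END annotation get ``svlen`` reconstructed as ``end - pos + 1``.
    """
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        _check_samples(list(vf.header.samples), samples)
        for i, rec in enumerate(vf):
            svtype = str(_info_get(rec, "SVTYPE", "UNK"))
            svlen = _info_get(rec, "SVLEN")
            if svlen is not None:
                svlen = abs(int(svlen))
            if svtype == "INS":
                end = rec.pos
                svlen = svlen or 1
            elif svtype == "DEL" and svlen is not None:
                # htslib rewrites the END info key, so trust SVLEN instead
                end = rec.pos + svlen - 1
            else:
                end = int(_info_get(rec, "END", rec.stop))
                svlen = svlen or (end - rec.pos + 1)
            n = len(samples)
            ref_reads = np.zeros(n, dtype=int)
            alt_reads = np.zeros(n, dtype=int)
            missing = np.zeros(n, dtype=bool)
            gt = np.full(n, -1, dtype=int)
            for j, s in enumerate(samples):
                sdata = rec.samples[s.sample]
                ad = sdata.get("AD")
                if ad is None or ad[0] is None:
                    missing[j] = True
                    continue
                ref_reads[j], alt_reads[j] = int(ad[0]), int(ad[1])
                alleles = sdata.get("GT")
                if alleles is None or all(a is None for a in alleles):
                    gt[j] = -1
                    missing[j] = True
                else:
                    gt[j] = sum(1 for a in alleles if a == 1)
            records.append(
                SVRecord(
                    id=rec.id or f"sv{i}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    end=int(end),
                    svtype=svtype,
                    svlen=max(svlen, 1),
                    qual=_read_qual(rec.qual),
                    ref_reads=ref_reads,
                    alt_reads=alt_reads,
                    missing=missing,
                    gt=gt,
                )
            )
    return records


def _read_qual(q) -> float:
    # htslib keeps QUAL as float32; undo the precision loss for text round trips
    return float(f"{q:.6g}") if q is not None else 0.0


def write_sv_vcf(
    records: Sequence[SVRecord],
    samples: Sequence[SampleInfo],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    header = pysam.VariantHeader()
    for line in _SV_HEADER_LINES:
        header.add_line(line)
    chroms: dict[str, int] = dict(chrom_lengths or {})
    for rec in records:
        chroms.setdefault(rec.chrom, 0)
        chroms[rec.chrom] = max(chroms[rec.chrom], rec.end + 1)
    for chrom, length in chroms.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in samples:
        header.add_sample(s.sample)
    with open(path, "w") as out:
        out.write(str(header))
        for rec in records:
            info = f"SVTYPE={rec.svtype};SVLEN={rec.svlen};END={rec.end}"
            fields = [
                rec.chrom,
                str(rec.pos),
                rec.id,
                "N",
                f"<{rec.svtype}>",
                f"{rec.qual:g}",
                "PASS",
                info,
                "GT:AD:DP",
            ]
            for j, s in enumerate(samples):
                if rec.missing[j]:
                    fields.append(f"{_gt_string(-1, s.ploidy)}:.,.:.")
                else:
                    g = int(rec.gt[j]) if rec.gt is not None else -1
                    dp = int(rec.ref_reads[j] + rec.alt_reads[j])
                    fields.append(
                        f"{_gt_string(g, s.ploidy)}:{int(rec.ref_reads[j])},"
                        f"{int(rec.alt_reads[j])}:{dp}"
                    )
            out.write("\t".join(fields) + "\n")


_SNP_INFO_FIELDS = ("MQ", "MQRankSum", "QD", "FS", "ReadPosRankSum")

_SNP_HEADER_LINES = [
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
    '##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand bias">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]


def read_snp_vcf(path: str | Path, samples: Sequence[SampleInfo]) -> list[SNPRecord]:
    records: list[SNPRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        _check_samples(list(vf.header.samples), samples)
        for i, rec in enumerate(vf):
            n = len(samples)
            ref_reads = np.zeros(n, dtype=int)
            alt_reads = np.zeros(n, dtype=int)
            missing = np.zeros(n, dtype=bool)
            gt = np.full(n, -1, dtype=int)
            gq = np.full(n, -1, dtype=int)
            for j, s in enumerate(samples):
                sdata = rec.samples[s.sample]
                ad = sdata.get("AD")
                if ad is None or ad[0] is None:
                    missing[j] = True
                    continue
                ref_reads[j], alt_reads[j] = int(ad[0]), int(ad[1])
                alleles = sdata.get("GT")
                if alleles is None or all(a is None for a in alleles):
                    missing[j] = True
                else:
                    gt[j] = sum(1 for a in alleles if a == 1)
                q = sdata.get("GQ")
                gq[j] = int(q) if q is not None else -1
            info = {k: float(rec.info[k]) for k in _SNP_INFO_FIELDS if k in rec.info}
            records.append(
                SNPRecord(
                    id=rec.id or f"snp{i}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else "N",
                    qual=_read_qual(rec.qual),
                    info={k: float(f"{v:.6g}") for k, v in info.items()},
                    ref_reads=ref_reads,
                    alt_reads=alt_reads,
                    missing=missing,
                    gt=gt,
                    gq=gq,
                )
            )
    return records


def write_snp_vcf(
    records: Sequence[SNPRecord],
    samples: Sequence[SampleInfo],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    header = pysam.VariantHeader()
    for line in _SNP_HEADER_LINES:
        header.add_line(line)
    chroms: dict[str, int] = dict(chrom_lengths or {})
    for rec in records:
        chroms.setdefault(rec.chrom, 0)
        chroms[rec.chrom] = max(chroms[rec.chrom], rec.pos + 1)
    for chrom, length in chroms.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    for s in samples:
        header.add_sample(s.sample)
    with open(path, "w") as out:
        out.write(str(header))
        for rec in records:
            info = ";".join(f"{k}={v:g}" for k, v in rec.info.items()) or "."
            fields = [
                rec.chrom,
                str(rec.pos),
                rec.id,
                rec.ref,
                rec.alt,
                f"{rec.qual:g}",
                "PASS",
                info,
                "GT:AD:DP:GQ",
            ]
            for j, s in enumerate(samples):
                if rec.missing[j]:
                    fields.append(f"{_gt_string(-1, s.ploidy)}:.,.:.:.")
                else:
                    g = int(rec.gt[j]) if rec.gt is not None else -1
                    dp = int(rec.ref_reads[j] + rec.alt_reads[j])
                    q = int(rec.gq[j]) if rec.gq is not None else 99
                    fields.append(
                        f"{_gt_string(g, s.ploidy)}:{int(rec.ref_reads[j])},"
                        f"{int(rec.alt_reads[j])}:{dp}:{q}"
                    )
            out.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# SV filters


@dataclass(frozen=True)
class SVFilterRules:
    """Hard filters for long-read SV call sets.

    The depth floor is 5 reads per haploid genome copy, matching the 10-read
    diploid and 20-read tetraploid floors and extending them to x = 6, 8.
    """

    min_len: int = 50
    max_len: int = 100_000
    min_qual: float = 20.0
    max_missing: float = 0.2
    depth_per_copy: int = 5
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must lie in [0, 1]")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("need 1 <= min_len <= max_len")


def filter_svs(
    records: Sequence[SVRecord],
    samples: Sequence[SampleInfo],
    rules: SVFilterRules = SVFilterRules(),
) -> tuple[list[SVRecord], dict[str, int]]:
    """Apply type / length / quality / reference-support / missingness filters.

    Samples below the ploidy-specific depth floor are marked missing before
    the per-site missingness rule is applied.  Returns the retained records
    (with updated missing masks) and a counter of removals per rule.
    """
    x = ploidies(samples)
    floor = rules.depth_per_copy * x
    ref_idx = None
    if rules.reference_sample is not None:
        names = [s.sample for s in samples]
        if rules.reference_sample not in names:
            raise ValueError(f"reference sample {rules.reference_sample!r} not in sheet")
        ref_idx = names.index(rules.reference_sample)

    kept: list[SVRecord] = []
    stats = {
        "input": len(records),
        "svtype": 0,
        "length": 0,
        "quality": 0,
        "reference_support": 0,
        "missingness": 0,
    }
    for rec in records:
        if not rec.analyzable:
            stats["svtype"] += 1
            continue
        if not (rules.min_len <= rec.svlen <= rules.max_len):
            stats["length"] += 1
            continue
        if rec.qual < rules.min_qual:
            stats["quality"] += 1
            continue
        if ref_idx is not None and rec.gt is not None and rec.gt[ref_idx] > 0:
            stats["reference_support"] += 1
            continue
        missing = rec.missing | (rec.depth < floor)
        if missing.mean() > rules.max_missing:
            stats["missingness"] += 1
            continue
        kept.append(replace(rec, missing=missing))
    stats["retained"] = len(kept)
    logger.info("filter_svs: %s", stats)
    return kept, stats


def filter_pangenome_candidates(
    records: Sequence[SVRecord],
    min_support: int = 4,
    min_support_ratio: float = 0.1,
    min_len: int = 50,
    max_len: int = 100_000,
    min_qual: float = 20.0,
) -> list[SVRecord]:
    """Select SVs eligible for pangenome-graph construction.

    Requires read support >= 4 in the strongest carrier, supporting-read
    proportion >= 0.1 of that carrier's depth, length in [50 bp, 100 kb],
    and variant quality >= 20.
    """
    kept = []
    for rec in records:
        if not rec.analyzable:
            continue
        if not (min_len <= rec.svlen <= max_len) or rec.qual < min_qual:
            continue
        total = rec.support_total
        if rec.support < min_support or total == 0:
            continue
        if rec.support / total < min_support_ratio:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# SNP hard filters


@dataclass(frozen=True)
class SNPFilterRules:
    min_mq: float = 40.0
    min_mq_rank_sum: float = -12.5
    min_qd: float = 2.0
    max_fs: float = 60.0
    min_read_pos_rank_sum: float = -8.0
    min_gq: int = 15
    depth_ratio: float = 1.6


def hard_filter_snps(
    records: Sequence[SNPRecord],
    samples: Sequence[SampleInfo],
    rules: SNPFilterRules = SNPFilterRules(),
) -> tuple[list[SNPRecord], dict[str, int]]:
    """GATK-style site filters plus per-genotype depth / quality masking.

    Site annotations that are absent pass the corresponding rule (logged).
    Genotypes with depth >= ``depth_ratio`` x that sample's mean depth across
    all input sites, or GQ below ``min_gq``, are marked missing.
    """
    if records:
        depths = np.array([r.depth for r in records], dtype=float)
        miss = np.array([r.missing for r in records])
        depths[miss] = np.nan
        with np.errstate(invalid="ignore"):
            mean_depth = np.nanmean(depths, axis=0)
        mean_depth = np.nan_to_num(mean_depth, nan=np.inf)
    stats = {"input": len(records), "site_filtered": 0, "genotypes_masked": 0}
    absent_logged = set()
    kept: list[SNPRecord] = []
    for rec in records:
        checks = (
            ("MQ", lambda v: v >= rules.min_mq),
            ("MQRankSum", lambda v: v >= rules.min_mq_rank_sum),
            ("QD", lambda v: v >= rules.min_qd),
            ("FS", lambda v: v < rules.max_fs),
            ("ReadPosRankSum", lambda v: v >= rules.min_read_pos_rank_sum),
        )
        ok = True
        for key, test in checks:
            if key not in rec.info:
                if key not in absent_logged:
                    logger.warning("annotation %s absent; rule passes by default", key)
                    absent_logged.add(key)
                continue
            if not test(rec.info[key]):
                ok = False
                break
        if not ok:
            stats["site_filtered"] += 1
            continue
        missing = rec.missing.copy()
        high_depth = rec.depth >= rules.depth_ratio * mean_depth
        missing |= high_depth
        if rec.gq is not None:
            missing |= (rec.gq >= 0) & (rec.gq < rules.min_gq)
        stats["genotypes_masked"] += int((missing & ~rec.missing).sum())
        kept.append(replace(rec, missing=missing))
    stats["retained"] = len(kept)
    logger.info("hard_filter_snps: %s", stats)
    return kept, stats


# ---------------------------------------------------------------------------
# gene models and feature maps


@dataclass(frozen=True)
class Gene:
    """A gene model: 1-based inclusive span with 1-based inclusive exons."""

    gene_id: str
    chrom: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon [{s},{e}] outside gene span "
                    f"[{self.start},{self.end}]"
                )


def write_gff3(
    genes: Sequence[Gene], chrom_lengths: dict[str, int], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for chrom, length in chrom_lengths.items():
            out.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            out.write(
                f"{g.chrom}\tploidsv\tgene\t{g.start}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.exons):
                out.write(
                    f"{g.chrom}\tploidsv\texon\t{s}\t{e}\t.\t+\t.\t"
                    f"ID={g.gene_id}.exon{k + 1};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> tuple[list[Gene], dict[str, int]]:
    """Read gene models and ##sequence-region chromosome lengths."""
    import gffutils

    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                chrom_lengths[chrom] = int(end)
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            (e.start, e.end) for e in db.children(g, featuretype="exon", order_by="start")
        )
        genes.append(Gene(g.id, g.seqid, g.start, g.end, exons))
    return genes, chrom_lengths


class FeatureMap:
    """Precedence-resolved partition of the genome into feature classes.

    Stores, per chromosome, sorted non-overlapping 0-based half-open
    intervals labeled exon / intron / flank / intergenic, plus per-class
    bp totals.  The partition property is asserted on construction.
    """

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 chrom_lengths: dict[str, int]):
        self.intervals = intervals
        self.chrom_lengths = dict(chrom_lengths)
        self.class_bp = {name: 0 for name in FEATURE_CLASSES}
        for chrom, (starts, ends, labels) in intervals.items():
            if starts.size == 0:
                raise ValueError(f"{chrom}: empty interval set")
            if starts[0] != 0 or ends[-1] != chrom_lengths[chrom]:
                raise ValueError(f"{chrom}: intervals do not span the chromosome")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"{chrom}: intervals do not partition the chromosome")
            for code, name in enumerate(FEATURE_CLASSES):
                sel = labels == code
                self.class_bp[name] += int((ends[sel] - starts[sel]).sum())
        total = sum(self.class_bp.values())
        expected = sum(chrom_lengths.values())
        assert total == expected, f"class totals {total} != genome length {expected}"

    @property
    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def classify(self, chrom: str, start: int, end: int) -> str:
        """Class of a 0-based half-open query; precedence exon > intron >
        flank > intergenic when the query spans several classes."""
        if chrom not in self.intervals:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_lengths[chrom] or end <= start:
            raise ValueError(
                f"query [{start},{end}) outside chromosome {chrom} "
                f"of length {self.chrom_lengths[chrom]}"
            )
        starts, ends, labels = self.intervals[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return FEATURE_CLASSES[int(labels[lo:hi].min())]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as out:
            for chrom, (starts, ends, labels) in self.intervals.items():
                for s, e, lab in zip(starts, ends, labels):
                    out.write(f"{chrom}\t{s}\t{e}\t{FEATURE_CLASSES[lab]}\n")


def build_feature_map(
    genes: Sequence[Gene],
    chrom_lengths: dict[str, int],
    flank_bp: int = 1000,
) -> FeatureMap:
    """Partition the genome into exon / intron / flank / intergenic.

    Flanks extend up to ``flank_bp`` from gene boundaries; overlaps resolve
    by precedence exon > intron > flank > intergenic (so flanks of adjacent
    genes merge and never double-count, and exons within flanks stay exons).
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
        if g.end > chrom_lengths[g.chrom]:
            raise ValueError(f"gene {g.gene_id} extends past chromosome end")
        by_chrom.setdefault(g.chrom, []).append(g)

    intervals = {}
    inter = _CLASS_CODE["intergenic"]
    for chrom, length in chrom_lengths.items():
        paint = np.full(length, inter, dtype=np.int8)
        for g in by_chrom.get(chrom, []):
            s0, e0 = g.start - 1, g.end
            fs, fe = max(0, s0 - flank_bp), min(length, e0 + flank_bp)
            np.minimum(paint[fs:s0], _CLASS_CODE["flank"], out=paint[fs:s0])
            np.minimum(paint[e0:fe], _CLASS_CODE["flank"], out=paint[e0:fe])
            np.minimum(paint[s0:e0], _CLASS_CODE["intron"], out=paint[s0:e0])
        for g in by_chrom.get(chrom, []):
            for es, ee in g.exons:
                paint[es - 1 : ee] = _CLASS_CODE["exon"]
        breaks = np.flatnonzero(np.diff(paint)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [length]))
        intervals[chrom] = (starts, ends, paint[starts].astype(np.int8))
    return FeatureMap(intervals, chrom_lengths)


# ---------------------------------------------------------------------------
# LD pruning


def dosage_maf(dosages: np.ndarray, ploidy: np.ndarray, missing: np.ndarray | None = None
               ) -> np.ndarray:
    """Minor-allele frequency per variant from dosage-summed allele counts
    over non-missing samples."""
    d = np.asarray(dosages, dtype=float)
    if missing is None:
        missing = np.zeros(d.shape, dtype=bool)
    ok = ~missing
    with np.errstate(invalid="ignore"):
        p = np.where(ok, d, 0.0).sum(axis=1) / (ok * ploidy[None, :]).sum(axis=1)
    return np.minimum(p, 1.0 - p)


def ld_prune(
    dosages: np.ndarray,
    ploidy: np.ndarray,
    r2_max: float = 0.1,
    window: int = 100,
    maf_min: float = 0.05,
    missing: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy left-to-right LD pruning on genotype dosages.

    Variants below ``maf_min`` are dropped first.  Scanning the survivors in
    order, a variant is dropped if its squared Pearson correlation with any
    retained variant at most ``window`` positions earlier exceeds ``r2_max``.
    Returns indices (into the input) of retained variants.
    """
    d = np.asarray(dosages, dtype=float)
    n_var = d.shape[0]
    if missing is None:
        missing = np.zeros(d.shape, dtype=bool)
    maf = dosage_maf(d, ploidy, missing)
    candidates = np.flatnonzero(maf > maf_min - 1e-12)
    # missing entries excluded pairwise via masked correlations
    dm = np.where(missing, np.nan, d)

    kept: list[int] = []
    kept_pos: list[int] = []  # candidate-sequence positions of kept variants
    for pos, idx in enumerate(candidates):
        drop = False
        for kpos, kidx in zip(reversed(kept_pos), reversed(kept)):
            if pos - kpos >= window:
                break
            a, b = dm[idx], dm[kidx]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 3:
                continue
            va, vb = a[ok], b[ok]
            sa, sb = va.std(), vb.std()
            if sa == 0 or sb == 0:
                continue
            r = np.mean((va - va.mean()) * (vb - vb.mean())) / (sa * sb)
            if r * r > r2_max:
                drop = True
                break
        if not drop:
            kept.append(int(idx))
            kept_pos.append(pos)
    return np.array(kept, dtype=int)
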