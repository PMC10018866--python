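"""Post-filtering and QC summaries for bisulfite genotype calls.

Bisulfite conversion erodes half the information at C/T and G/A sites, so
raw genotypes from a bisulfite-aware caller need aggressive post-hoc
filtering.  The rule set applied here:

- ``low_gq``       genotype quality <= 20
- ``max_depth``    sequencing depth > 250x (collapsed repeats)
- ``strand_bias``  caller strand-bias score > -0.02 (more negative = less
                   biased, per the upstream caller's convention)
- ``mq0``          depth > 40x with > 10% of reads at mapping quality 0
- ``gq_by_depth``  genotype quality / depth < 1
- ``snp_cluster``  another SNP within +-10 bp (both records fail)

A record PASSes iff no rule fails.  The module also applies the standard
post-imputation gate (biallelic, MAF > 1%, imputation R^2 > 0.3) and
computes Ti/Tv and genotype-concordance summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

RULE_LOW_GQ = "low_gq"
RULE_MAX_DEPTH = "max_depth"
RULE_STRAND_BIAS = "strand_bias"
RULE_MQ0 = "mq0"
RULE_GQ_BY_DEPTH = "gq_by_depth"
RULE_SNP_CLUSTER = "snp_cluster"
PASS = "PASS"

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class VariantError(ValueError):
    """Invalid variant input."""


@dataclass
class FilterThresholds:
    """Post-processing filter thresholds (defaults match common practice)."""

    gq_min: float = 20.0
    max_depth: float = 250.0
    sb_max: float = -0.02
    mq0_depth: float = 40.0
    mq0_frac: float = 0.1
    gq_over_depth_min: float = 1.0
    cluster_window: int = 10


@dataclass
class VariantRecord:
    """One genotype call with the QC annotations the filters consume."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_alleles: Tuple[str, ...]
    genotype: Tuple[int, int]
    genotype_quality: Optional[float] = None
    depth: Optional[float] = None
    strand_bias_score: Optional[float] = None
    mq0_fraction: Optional[float] = None
    info: Dict[str, float] = field(default_factory=dict)
    filter_status: List[str] = field(default_factory=list)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def passes(self) -> bool:
        return self.filter_status == [PASS]


def postprocess_filters(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> List[VariantRecord]:
    """Annotate every record with each failed rule; PASS iff none fail.

    Records must be sorted by (chromosome, position).  A rule whose
    annotation is missing on a record is skipped for that record, with a
    warning counted once per rule.
    """
    th = thresholds or FilterThresholds()
    keys = [(r.chromosome, r.position) for r in records]
    if keys != sorted(keys):
        raise VariantError("records must be sorted by chromosome, position")

    skipped: Dict[str, int] = {}

    def _missing(rule: str) -> None:
        skipped[rule] = skipped.get(rule, 0) + 1

    for i, rec in enumerate(records):
        failed: List[str] = []
        if rec.genotype_quality is None:
            _missing(RULE_LOW_GQ)
        elif rec.genotype_quality <= th.gq_min:
            failed.append(RULE_LOW_GQ)
        if rec.depth is None:
            _missing(RULE_MAX_DEPTH)
        elif rec.depth > th.max_depth:
            failed.append(RULE_MAX_DEPTH)
        if rec.strand_bias_score is None:
            _missing(RULE_STRAND_BIAS)
        elif rec.strand_bias_score > th.sb_max:
            failed.append(RULE_STRAND_BIAS)
        if rec.depth is None or rec.mq0_fraction is None:
            _missing(RULE_MQ0)
        elif rec.depth > th.mq0_depth and rec.mq0_fraction > th.mq0_frac:
            failed.append(RULE_MQ0)
        if rec.genotype_quality is None or rec.depth is None or rec.depth == 0:
            _missing(RULE_GQ_BY_DEPTH)
        elif rec.genotype_quality / rec.depth < th.gq_over_depth_min:
            failed.append(RULE_GQ_BY_DEPTH)
        # proximity: any other record within +-window on the same chromosome
        near = False
        for j in (i - 1, i + 1):
            if 0 <= j < len(records):
                other = records[j]
                if (
                    other.chromosome == rec.chromosome
                    and abs(other.position - rec.position) <= th.cluster_window
                ):
                    near = True
        if near:
            failed.append(RULE_SNP_CLUSTER)
        rec.filter_status = failed if failed else [PASS]
    for rule, n in skipped.items():
        warnings.warn(f"rule {rule}: annotation missing on {n} record(s), skipped")
    return list(records)


def imputation_qc_filter(
    records: Iterable[VariantRecord],
    maf_min: float = 0.01,
    r2_min: float = 0.3,
    biallelic_only: bool = True,
    maf_key: str = "MAF",
    r2_key: str = "R2",
    stats: Optional[Dict[str, int]] = None,
) -> List[VariantRecord]:
    """Post-imputation gate: biallelic, MAF > maf_min, R^2 > r2_min.

    Records lacking the MAF or R^2 annotation are dropped and counted in
    ``stats['missing_annotation']``.
    """
    if stats is None:
        stats = {}
    stats.setdefault("missing_annotation", 0)
    kept = []
    for rec in records:
        if biallelic_only and not rec.is_biallelic:
            continue
        maf = rec.info.get(maf_key)
        r2 = rec.info.get(r2_key)
        if maf is None or r2 is None:
            stats["missing_annotation"] += 1
            continue
        if maf > maf_min and r2 > r2_min:
            kept.append(rec)
    return kept


def titv_ratio(records: Iterable[VariantRecord]) -> float:
    """Transitions (A<->G, C<->T) over transversions, biallelic SNVs only."""
    ti = tv = 0
    for rec in records:
        if not (rec.is_snv and rec.is_biallelic):
            continue
        sub = (rec.ref_allele.upper(), rec.alt_alleles[0].upper())
        if sub in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        raise VariantError("zero transversions: Ti/Tv undefined")
    return ti / tv


def genotype_concordance(
    test: Iterable[VariantRecord],
    truth: Iterable[VariantRecord],
    mask: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Dict:
    """Genotype-level concordance of a test call set against a truth set.

    Sites are matched on (chromosome, position, ref, sorted alts).  A
    matched site is concordant when the unordered genotypes agree.
    Sensitivity = truth variant sites recovered with matching genotype /
    truth variant sites; precision = test variant sites whose truth
    genotype matches / test variant sites.  ``mask`` is an optional list of
    confident regions (chrom, start0, end0) restricting the comparison.
    """

    def in_mask(rec: VariantRecord) -> bool:
        if mask is None:
            return True
        return any(
            rec.chromosome == c and s < rec.position <= e for c, s, e in mask
        )

    def key(rec: VariantRecord):
        return (
            rec.chromosome,
            rec.position,
            rec.ref_allele,
            tuple(sorted(rec.alt_alleles)),
        )

    test_map = {key(r): r for r in test if in_mask(r)}
    truth_map = {key(r): r for r in truth if in_mask(r)}
    shared = set(test_map) & set(truth_map)

    confusion: Dict[Tuple[str, str], int] = {}

    def gt_class(rec: VariantRecord) -> str:
        g = tuple(sorted(rec.genotype))
        if g == (0, 0):
            return "hom_ref"
        if g[0] == g[1]:
            return "hom_alt"
        return "het"

    n_concordant = 0
    for k in shared:
        a, b = test_map[k], truth_map[k]
        ca, cb = gt_class(a), gt_class(b)
        confusion[(ca, cb)] = confusion.get((ca, cb), 0) + 1
        if tuple(sorted(a.genotype)) == tuple(sorted(b.genotype)):
            n_concordant += 1

    truth_var = {k for k, r in truth_map.items() if gt_class(r) != "hom_ref"}
    test_var = {k for k, r in test_map.items() if gt_class(r) != "hom_ref"}
    recovered = {
        k
        for k in truth_var & test_var
        if tuple(sorted(test_map[k].genotype)) == tuple(sorted(truth_map[k].genotype))
    }
    metrics = {
        "n_sites_compared": len(shared),
        "genotype_concordance_fraction": (
            n_concordant / len(shared) if shared else None
        ),
        "sensitivity": len(recovered) / len(truth_var) if truth_var else None,
        "precision": len(recovered) / len(test_var) if test_var else None,
        "confusion": {f"{a}|{b}": n for (a, b), n in sorted(confusion.items())},
        "defined": bool(shared),
    }
    return metrics


# ---------------------------------------------------------------------------
# VCF I/O

VCF_ANNOT_KEYS = {"sb": "SBS", "mq0f": "MQ0F", "maf": "MAF", "r2": "R2"}


def read_vcf(path: str, keys: Optional[Dict[str, str]] = None) -> List[VariantRecord]:
    """Load VariantRecords from a VCF via cyvcf2.

    GQ and DP are taken from the first sample's FORMAT fields when present,
    falling back to INFO; strand bias / MQ0 fraction / MAF / R^2 come from
    INFO under the (configurable) keys SBS, MQ0F, MAF, R2.
    """
    from cyvcf2 import VCF

    k = dict(VCF_ANNOT_KEYS)
    if keys:
        k.update(keys)
    out = []
    vcf = VCF(path)
    has_samples = len(vcf.samples) > 0
    for v in vcf:
        gq = dp = None
        gt = (0, 1)
        if has_samples:
            try:
                gq = float(v.format("GQ")[0][0]) if v.format("GQ") is not None else None
            except (TypeError, IndexError):
                gq = None
            try:
                dp = float(v.format("DP")[0][0]) if v.format("DP") is not None else None
            except (TypeError, IndexError):
                dp = None
            g = v.genotypes[0][:2]
            gt = (int(g[0]), int(g[1]))
        if dp is None and v.INFO.get("DP") is not None:
            dp = float(v.INFO.get("DP"))
        info = {}
        for key in (k["maf"], k["r2"]):
            val = v.INFO.get(key)
            if val is not None:
                info[key if key in ("MAF", "R2") else key] = float(val)
        sb = v.INFO.get(k["sb"])
        mq0f = v.INFO.get(k["mq0f"])
        # cyvcf2 reports PASS (and '.') as None
        filt = [PASS] if v.FILTER is None else v.FILTER.split(";")
        out.append(
            VariantRecord(
                chromosome=v.CHROM,
                position=v.POS,
                ref_allele=v.REF,
                alt_alleles=tuple(v.ALT),
                genotype=gt,
                genotype_quality=gq,
                depth=dp,
                strand_bias_score=float(sb) if sb is not None else None,
                mq0_fraction=float(mq0f) if mq0f is not None else None,
                info=info,
                filter_status=filt,
            )
        )
    vcf.close()
    return out


VCF_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Sequencing depth">',
    '##INFO=<ID=SBS,Number=1,Type=Float,Description="Strand bias score (more negative = less biased)">',
    '##INFO=<ID=MQ0F,Number=1,Type=Float,Description="Fraction of reads with mapping quality 0">',
    '##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">',
    '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R-squared">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]

FILTER_DESCRIPTIONS = {
    RULE_LOW_GQ: "Genotype quality <= 20",
    RULE_MAX_DEPTH: "Sequencing depth > 250",
    RULE_STRAND_BIAS: "Strand bias score > -0.02",
    RULE_MQ0: "Depth > 40 and MQ0 fraction > 0.1",
    RULE_GQ_BY_DEPTH: "Genotype quality / depth < 1",
    RULE_SNP_CLUSTER: "Another SNP within +-10bp",
}


def write_vcf(
    records: Sequence[VariantRecord],
    path: str,
    contigs: Optional[Dict[str, int]] = None,
    sample: str = "SAMPLE",
) -> None:
    """Write VariantRecords to an uncompressed VCF 4.2 text file (pysam)."""
    import pysam

    header = pysam.VariantHeader()
    for line in VCF_HEADER_LINES:
        header.add_line(line)
    for rule, desc in FILTER_DESCRIPTIONS.items():
        header.add_line(f'##FILTER=<ID={rule},Description="{desc}">')
    chroms = (
        contigs
        if contigs is not None
        else {r.chromosome: None for r in records}
    )
    for chrom, length in chroms.items():
        if length:
            header.add_line(f"##contig=<ID={chrom},length={length}>")
        else:
            header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            r = out.new_record(
                contig=rec.chromosome,
                start=rec.position - 1,
                stop=rec.position - 1 + len(rec.ref_allele),
                alleles=(rec.ref_allele, *rec.alt_alleles),
            )
            if rec.depth is not None:
                r.info["DP"] = int(round(rec.depth))
            if rec.strand_bias_score is not None:
                r.info["SBS"] = rec.strand_bias_score
            if rec.mq0_fraction is not None:
                r.info["MQ0F"] = rec.mq0_fraction
            for key in ("MAF", "R2"):
                if key in rec.info:
                    r.info[key] = rec.info[key]
            r.samples[sample]["GT"] = rec.genotype
            if rec.genotype_quality is not None:
                r.samples[sample]["GQ"] = int(round(rec.genotype_quality))
            if rec.depth is not None:
                r.samples[sample]["DP"] = int(round(rec.depth))
            if rec.filter_status:
                for f in rec.filter_status:
                    r.filter.add(f)
            out.write(r)
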