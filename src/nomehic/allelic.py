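"""Long-range allele-specific GCH footprint calling.

A read pair whose SNP-overlapping end ("SNP anchor") carries one allele of
a heterozygous SNP tags the whole molecule — including its distal mate end
(">20 kb away, the "non-SNP anchor") — with that allele.  Pooling GCH
methylated/unmethylated calls by allele at each anchor gives two 2x2
tables per SNP; Fisher's exact test plus Benjamini-Hochberg FDR (applied
separately per anchor class) then classifies each locus:

- Group 1 — allelic footprint difference at both anchors (FDR < 0.05 twice),
- Group 2 — only at the SNP anchor (SNP FDR < 0.05, distal FDR > 0.95),
- Group 3 — only at the distal anchor (distal FDR < 0.05, SNP FDR > 0.95).

Bisulfite conversion makes some allele assignments unsafe: on an OT read
every unmethylated C reads as T, so C/T SNPs cannot be assigned from OT
reads; symmetrically G/A SNPs cannot be assigned from OB reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from nomehic import contexts
from nomehic.bsreads import AlignedEnd, LinkedReadPair

REF = "REF"
ALT = "ALT"
UNASSIGNABLE = "UNASSIGNABLE"

GROUP1 = "GROUP1"
GROUP2 = "GROUP2"
GROUP3 = "GROUP3"
NONE = "NONE"

DEFAULT_MIN_DIST = 20_000
DEFAULT_MIN_COV = 2
DEFAULT_MIN_GCH = 1
DEFAULT_FDR_SIG = 0.05
DEFAULT_FDR_NULL = 0.95


class AllelicError(ValueError):
    """Invalid input to an allele-specific operation."""


@dataclass(frozen=True)
class HetSNP:
    """A biallelic heterozygous single-nucleotide variant."""

    chromosome: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    phased: bool = False

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise AllelicError("ref and alt alleles identical")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise AllelicError("only single-nucleotide variants supported")

    @property
    def position0(self) -> int:
        return self.position - 1


@dataclass
class AllelicLocus:
    """Per-SNP allelic footprint tables and test results.

    Tables are [allele x (methylated, unmethylated)] GCH counts, rows
    ordered (REF, ALT), pooled over reads.
    """

    snp: HetSNP
    snp_anchor_table: np.ndarray
    nonsnp_anchor_table: np.ndarray
    n_ref_reads: int
    n_alt_reads: int
    p_snp: Optional[float] = None
    p_nonsnp: Optional[float] = None
    fdr_snp: Optional[float] = None
    fdr_nonsnp: Optional[float] = None
    group: str = NONE
    tested: bool = True


def load_het_snps(path: str) -> List[HetSNP]:
    """Heterozygous biallelic SNVs from a VCF (cyvcf2)."""
    from cyvcf2 import VCF

    snps = []
    vcf = VCF(path)
    has_samples = len(vcf.samples) > 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            continue
        if has_samples:
            gt = v.genotypes[0][:2]
            if len(set(gt)) < 2:
                continue  # homozygous
            phased = bool(v.genotypes[0][-1])
        else:
            phased = False
        snps.append(HetSNP(v.CHROM, v.POS, v.REF, v.ALT[0], phased))
    vcf.close()
    return snps


def assign_allele(
    end: AlignedEnd, snp: HetSNP, min_base_quality: int = 5
) -> str:
    """Assign a read end to REF/ALT at a heterozygous SNP.

    Returns UNASSIGNABLE when the allele pair is confounded by bisulfite
    conversion on the end's strand ({C,T} on OT, {G,A} on OB), when the
    base matches neither allele, or when base quality is too low.
    """
    obs = end.base_at(snp.position0)
    if obs is None:
        raise AllelicError(
            f"read does not cover SNP at {snp.chromosome}:{snp.position}"
        )
    alleles = {snp.ref_allele.upper(), snp.alt_allele.upper()}
    if end.conversion_strand == "OT" and alleles == {"C", "T"}:
        return UNASSIGNABLE
    if end.conversion_strand == "OB" and alleles == {"G", "A"}:
        return UNASSIGNABLE
    base, qual = obs
    if qual <= min_base_quality:
        return UNASSIGNABLE
    if base == snp.ref_allele.upper():
        return REF
    if base == snp.alt_allele.upper():
        return ALT
    return UNASSIGNABLE


def _gch_counts(end: AlignedEnd) -> Tuple[int, int]:
    meth, total = end.summarize(frozenset({contexts.GCH}))
    return meth, total


def build_allelic_tables(
    pairs: Iterable[LinkedReadPair],
    het_snps: Sequence[HetSNP],
    min_dist: int = DEFAULT_MIN_DIST,
    min_cov_per_allele: int = DEFAULT_MIN_COV,
    min_gch_per_end: int = DEFAULT_MIN_GCH,
    min_mapq: int = 30,
    min_base_quality: int = 5,
) -> List[AllelicLocus]:
    """Pool per-allele GCH counts at SNP and distal anchors for each SNP.

    A pair contributes to a SNP when exactly one end covers the SNP
    position (that end is the SNP anchor), the mate lies more than
    ``min_dist`` bp from the SNP on the same chromosome, the allele is
    assignable, and both ends carry at least ``min_gch_per_end`` GCH calls.
    Loci with fewer than ``min_cov_per_allele`` reads for either allele are
    returned untested.
    """
    pair_list = [p for p in pairs if min(p.end1.mapq, p.end2.mapq) > min_mapq]

    # one pass over pairs, binary-searching SNP positions per chromosome
    by_chrom_pos: Dict[str, np.ndarray] = {}
    by_chrom_snps: Dict[str, List[HetSNP]] = {}
    for snp in het_snps:
        by_chrom_snps.setdefault(snp.chromosome, []).append(snp)
    for chrom, snps in by_chrom_snps.items():
        snps.sort(key=lambda s: s.position)
        by_chrom_pos[chrom] = np.array([s.position0 for s in snps])

    # per SNP: [meth_snp, unmeth_snp, meth_dist, unmeth_dist] per allele + read counts
    acc: Dict[HetSNP, Dict[str, List[int]]] = {}
    nreads_acc: Dict[HetSNP, Dict[str, int]] = {}

    def _snps_hit(chrom: str, start: int, end: int) -> List[HetSNP]:
        pos = by_chrom_pos.get(chrom)
        if pos is None:
            return []
        lo, hi = np.searchsorted(pos, (start, end))
        return by_chrom_snps[chrom][lo:hi]

    for p in pair_list:
        for snp_end, mate in ((p.end1, p.end2), (p.end2, p.end1)):
            for snp in _snps_hit(snp_end.chromosome, snp_end.start, snp_end.end):
                pos0 = snp.position0
                if (
                    mate.chromosome == snp.chromosome
                    and mate.start <= pos0 < mate.end
                ):
                    continue  # both ends cover the SNP: no distal anchor
                if mate.chromosome != snp.chromosome:
                    continue
                mate_dist = min(abs(mate.start - pos0), abs(mate.end - 1 - pos0))
                if mate_dist <= min_dist:
                    continue
                allele = assign_allele(snp_end, snp, min_base_quality)
                if allele == UNASSIGNABLE:
                    continue
                ms, ts = _gch_counts(snp_end)
                md, td = _gch_counts(mate)
                if ts < min_gch_per_end or td < min_gch_per_end:
                    continue
                counts = acc.setdefault(
                    snp, {REF: [0, 0, 0, 0], ALT: [0, 0, 0, 0]}
                )
                nreads = nreads_acc.setdefault(snp, {REF: 0, ALT: 0})
                c = counts[allele]
                c[0] += ms
                c[1] += ts - ms
                c[2] += md
                c[3] += td - md
                nreads[allele] += 1

    loci: List[AllelicLocus] = []
    for snp in het_snps:
        if snp not in acc:
            continue
        counts = acc[snp]
        nreads = nreads_acc[snp]
        snp_table = np.array(
            [[counts[REF][0], counts[REF][1]], [counts[ALT][0], counts[ALT][1]]]
        )
        dist_table = np.array(
            [[counts[REF][2], counts[REF][3]], [counts[ALT][2], counts[ALT][3]]]
        )
        tested = nreads[REF] >= min_cov_per_allele and nreads[ALT] >= min_cov_per_allele
        loci.append(
            AllelicLocus(
                snp=snp,
                snp_anchor_table=snp_table,
                nonsnp_anchor_table=dist_table,
                n_ref_reads=nreads[REF],
                n_alt_reads=nreads[ALT],
                tested=tested,
            )
        )
    return loci


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table.

    Sums the hypergeometric probabilities of all tables, at the observed
    margins, no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise AllelicError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or (t < 0).any():
            raise AllelicError("counts must be nonnegative integers")
        t = np.round(t).astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise AllelicError("p-values must lie in [0, 1]")
    # floor exact zeros at the smallest positive float so BH ordering is stable
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj


def test_loci(loci: Sequence[AllelicLocus]) -> List[AllelicLocus]:
    """Fisher p-values and per-anchor-class BH FDR over all tested loci."""
    tested = [loc for loc in loci if loc.tested]
    for loc in tested:
        loc.p_snp = fisher_exact_2x2(loc.snp_anchor_table)
        loc.p_nonsnp = fisher_exact_2x2(loc.nonsnp_anchor_table)
    if tested:
        fdr_s = bh_fdr([loc.p_snp for loc in tested])
        fdr_d = bh_fdr([loc.p_nonsnp for loc in tested])
        for loc, fs, fd in zip(tested, fdr_s, fdr_d):
            loc.fdr_snp = float(fs)
            loc.fdr_nonsnp = float(fd)
    return list(loci)


def classify_allelic_groups(
    loci: Sequence[AllelicLocus],
    fdr_sig: float = DEFAULT_FDR_SIG,
    fdr_null: float = DEFAULT_FDR_NULL,
) -> List[AllelicLocus]:
    """Label each tested locus GROUP1/GROUP2/GROUP3/NONE.

    GROUP1: FDR < fdr_sig at both anchors.  GROUP2: significant only at the
    SNP anchor with clearly-null distal FDR (> fdr_null).  GROUP3: the
    mirror image.  Everything else (including ambiguous middle-ground FDRs)
    is NONE.
    """
    for loc in loci:
        if not loc.tested:
            loc.group = NONE
            continue
        if loc.fdr_snp is None or loc.fdr_nonsnp is None:
            raise AllelicError("FDR missing: run test_loci first")
        fs, fd = loc.fdr_snp, loc.fdr_nonsnp
        if fs < fdr_sig and fd < fdr_sig:
            loc.group = GROUP1
        elif fs < fdr_sig and fd > fdr_null:
            loc.group = GROUP2
        elif fd < fdr_sig and fs > fdr_null:
            loc.group = GROUP3
        else:
            loc.group = NONE
    return list(loci)


def run_allelic_analysis(
    pairs: Iterable[LinkedReadPair],
    het_snps: Sequence[HetSNP],
    min_dist: int = DEFAULT_MIN_DIST,
    min_cov_per_allele: int = DEFAULT_MIN_COV,
    min_gch_per_end: int = DEFAULT_MIN_GCH,
    fdr_sig: float = DEFAULT_FDR_SIG,
    fdr_null: float = DEFAULT_FDR_NULL,
) -> List[AllelicLocus]:
    """Tables -> Fisher tests -> BH FDR -> group labels, in one call."""
    loci = build_allelic_tables(
        pairs,
        het_snps,
        min_dist=min_dist,
        min_cov_per_allele=min_cov_per_allele,
        min_gch_per_end=min_gch_per_end,
    )
    test_loci(loci)
    return classify_allelic_groups(loci, fdr_sig=fdr_sig, fdr_null=fdr_null)


def loci_to_dataframe(loci: Sequence[AllelicLocus]) -> pd.DataFrame:
    rows = []
    for loc in loci:
        s, d = loc.snp_anchor_table, loc.nonsnp_anchor_table
        rows.append(
            {
                "chrom": loc.snp.chromosome,
                "pos": loc.snp.position,
                "ref": loc.snp.ref_allele,
                "alt": loc.snp.alt_allele,
                "n_ref_reads": loc.n_ref_reads,
                "n_alt_reads": loc.n_alt_reads,
                "snp_ref_meth": s[0, 0],
                "snp_ref_unmeth": s[0, 1],
                "snp_alt_meth": s[1, 0],
                "snp_alt_unmeth": s[1, 1],
                "dist_ref_meth": d[0, 0],
                "dist_ref_unmeth": d[0, 1],
                "dist_alt_meth": d[1, 0],
                "dist_alt_unmeth": d[1, 1],
                "p_snp": loc.p_snp,
                "p_nonsnp": loc.p_nonsnp,
                "fdr_snp": loc.fdr_snp,
                "fdr_nonsnp": loc.fdr_nonsnp,
                "tested": loc.tested,
                "group": loc.group,
            }
        )
    return pd.DataFrame(rows)
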