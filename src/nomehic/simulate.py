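"""Synthetic bisulfite Hi-C data with known truth.

Generates, deterministically under a seed: an i.i.d. reference genome, a
set of cis loop-anchor pairs separated by more than the long-range
threshold, and aligned bisulfite-converted read pairs emitted directly as
SAM records (the toolkit's scope starts after alignment, so no aligner is
in the loop).

The generative model per molecule: a latent open/closed accessibility
state is drawn at each of the two anchors from a bivariate Bernoulli with
marginal ``pi_open`` and correlation ``rho_latent``; each GCH site covered
by an end is methylated with probability ``p_open`` or ``p_closed``
according to that end's state; HCG sites carry endogenous methylation at
``endo_hcg_meth``; WCH/CCH cytosines are unmethylated.  Bisulfite
chemistry is then applied on the molecule's conversion strand (OT or OB,
equiprobable): unmethylated cytosines convert to T (or G to A on OB)
except with probability ``conversion_failure``; sequencing errors
substitute random bases at rate ``sequencing_error``.

Allele-specific loci plant a heterozygous A/T SNP (assignable on either
conversion strand) inside one anchor and make the per-site GCH emission
probability allele-dependent at the SNP anchor, the distal anchor, or
both, matching the three long-range allele-specific footprint groups; the
unaffected anchor emits i.i.d. at the marginal accessibility level, so
its allelic contrast is exactly null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from nomehic import contexts, variants
from nomehic.bsreads import AnchorPairSet
from nomehic.contexts import (
    ContextIndex,
    GenomeSequence,
    LABEL_CODE,
    build_context_index,
)
from nomehic.variants import VariantRecord


class SimulationError(ValueError):
    """Infeasible or invalid simulation request."""


@dataclass
class AllelicPlanItem:
    """One batch of planted allele-specific loci.

    ``group`` is GROUP1/GROUP2/GROUP3 (which anchors carry the allelic
    open-probability difference) or NONE (null locus, no effect).
    ``p_hi``/``p_lo`` are the per-site GCH open probabilities of the two
    alleles at affected anchors.
    """

    group: str
    n_loci: int
    p_hi: float = 0.9
    p_lo: float = 0.1
    reads_per_allele: int = 50


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a desk-scale bisulfite Hi-C experiment: human-like GC
    content (0.42), 1 kb loop anchors separated by just over 20 kb (the
    long-range threshold), 150 bp reads, moderately coordinated
    accessibility (rho_latent 0.6) with well-separated emission
    probabilities (0.8 open vs 0.2 closed), 75% endogenous CpG methylation,
    0.5% bisulfite conversion failure and 0.1% sequencing error.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    gc_fraction: float = 0.42
    n_anchor_pairs: int = 20
    anchor_span: int = 1_000
    min_anchor_separation: int = 20_001
    n_pairs_per_anchor: int = 100
    n_local_pairs_per_anchor: int = 0
    read_length: int = 150
    rho_latent: float = 0.6
    pi_open: float = 0.5
    p_open: float = 0.8
    p_closed: float = 0.2
    endo_hcg_meth: float = 0.75
    conversion_failure: float = 0.005
    sequencing_error: float = 0.001
    chromosome: str = "chr1"
    base_quality: int = 40
    allelic_plan: List[AllelicPlanItem] = field(default_factory=list)


@dataclass
class TruthBundle:
    """Ground truth for every emitted molecule and planted locus."""

    molecules: pd.DataFrame
    loci: pd.DataFrame
    config: SimulationConfig


@dataclass
class SimulatedDataset:
    genome: GenomeSequence
    index: ContextIndex
    anchors: AnchorPairSet
    reads: List[pysam.AlignedSegment]
    header: pysam.AlignmentHeader
    het_snps: List
    truth: TruthBundle

    def write(self, outdir: str) -> None:
        """Write reference.fa, anchors.bedpe, reads.sam, hets.vcf, truth/."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.genome.to_fasta(os.path.join(outdir, "reference.fa"))
        self.anchors.to_bedpe(os.path.join(outdir, "anchors.bedpe"))
        write_sam(self.reads, self.header, os.path.join(outdir, "reads.sam"))
        if self.het_snps:
            from nomehic.variants import write_vcf

            recs = [
                VariantRecord(
                    chromosome=s.chromosome,
                    position=s.position,
                    ref_allele=s.ref_allele,
                    alt_alleles=(s.alt_allele,),
                    genotype=(0, 1),
                )
                for s in self.het_snps
            ]
            write_vcf(recs, os.path.join(outdir, "hets.vcf"), self.genome.lengths)
        tdir = os.path.join(outdir, "truth")
        os.makedirs(tdir, exist_ok=True)
        self.truth.molecules.to_csv(
            os.path.join(tdir, "molecules.tsv"), sep="\t", index=False
        )
        self.truth.loci.to_csv(os.path.join(tdir, "loci.tsv"), sep="\t", index=False)


def simulate_reference(
    length: int, gc_fraction: float, seed: int, chromosome: str = "chr1"
) -> GenomeSequence:
    """I.i.d. reference with P(G) = P(C) = gc_fraction / 2."""
    if length <= 0:
        raise SimulationError("length must be positive")
    if not 0 < gc_fraction < 1:
        raise SimulationError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p_at = (1 - gc_fraction) / 2
    p_gc = gc_fraction / 2
    bases = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8),
        size=length,
        p=[p_at, p_gc, p_gc, p_at],
    )
    return GenomeSequence({chromosome: bases.tobytes().decode("ascii")})


def simulate_anchor_pairs(
    genome: GenomeSequence,
    n: int,
    span: int,
    min_separation: int,
    seed: int,
    index: Optional[ContextIndex] = None,
    min_gch_per_anchor: int = 3,
) -> AnchorPairSet:
    """Place n non-overlapping cis anchor pairs, paired anchors > min_separation apart.

    The chromosome is tiled into n equal blocks, one pair per block with
    seeded jitter.  When a context index is supplied, anchors with fewer
    than ``min_gch_per_anchor`` GCH sites on either strand are re-jittered
    (up to 20 attempts) so every read window can yield footprint calls.
    """
    chrom = max(genome.lengths, key=genome.lengths.get)
    length = genome.lengths[chrom]
    block = length // n
    need = 2 * span + min_separation + 2
    if block < need:
        raise SimulationError(
            f"cannot pack {n} anchor pairs of span {span} with separation "
            f"{min_separation} into {length} bp"
        )
    rng = np.random.default_rng(seed)
    slack = block - need
    jmax = max(1, slack // 2)

    def gch_ok(start: int) -> bool:
        if index is None:
            return True
        for strand in ("+", "-"):
            pos, codes = index.sites_in_window(chrom, start, start + span, strand)
            if (codes == LABEL_CODE["GCH"]).sum() < min_gch_per_anchor:
                return False
        return True

    rows = []
    for i in range(n):
        base = i * block
        for attempt in range(20):
            start_a = base + int(rng.integers(0, jmax))
            start_b = start_a + span + min_separation + 1 + int(rng.integers(0, jmax))
            if gch_ok(start_a) and gch_ok(start_b):
                break
        else:
            warnings.warn(f"anchor pair {i}: GCH-poor placement retained")
        rows.append((chrom, start_a, start_a + span, chrom, start_b, start_b + span))
    return AnchorPairSet.from_records(rows)


def bivariate_bernoulli_probs(pi: float, rho: float) -> np.ndarray:
    """Joint pmf [p00, p01, p10, p11] with equal marginals pi, correlation rho."""
    if not 0 < pi < 1:
        raise SimulationError("pi_open must lie in (0, 1)")
    p11 = pi * pi + rho * pi * (1 - pi)
    p10 = p01 = pi - p11
    p00 = 1 - 2 * pi + p11
    probs = np.array([p00, p01, p10, p11])
    if (probs < -1e-12).any():
        raise SimulationError(
            f"rho_latent={rho} infeasible for pi_open={pi} (negative cell probability)"
        )
    return np.clip(probs, 0, 1)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class _Emitter:
    """Vectorized read emission against a reference and context index."""

    def __init__(self, genome: GenomeSequence, index: ContextIndex, cfg: SimulationConfig):
        self.cfg = cfg
        self.index = index
        self.seq = {
            c: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for c, s in genome.sequences.items()
        }
        # label code -> methylation probability, per latent state
        endo = cfg.endo_hcg_meth
        self.prob_open = np.zeros(len(contexts.LABELS))
        self.prob_closed = np.zeros(len(contexts.LABELS))
        for lab, code in LABEL_CODE.items():
            if lab == "GCH":
                self.prob_open[code] = cfg.p_open
                self.prob_closed[code] = cfg.p_closed
            elif lab in ("WCG", "CCG", "GCG"):
                # GCG carries endogenous CpG methylation too; it is excluded
                # downstream precisely because the signals mix there
                self.prob_open[code] = endo
                self.prob_closed[code] = endo

    def emit(
        self,
        chrom: str,
        start: int,
        state: float,
        strand_conv: str,
        rng: np.random.Generator,
        snp: Optional[Tuple[int, str]] = None,
        gch_prob: Optional[float] = None,
    ) -> Tuple[str, int]:
        """Emit one read; returns (sequence, n_unconverted_wch).

        By default GCH methylation follows the binary latent ``state``
        (p_open / p_closed).  When ``gch_prob`` is given, GCH sites are
        instead i.i.d. Bernoulli(gch_prob) — the emission mode used at
        planted allele-specific loci, where the effect size is the per-site
        open probability itself.  ``snp`` optionally substitutes an allele
        base at a forward coordinate before errors are applied.
        """
        cfg = self.cfg
        read = self.seq[chrom][start : start + cfg.read_length].copy()
        strand = "+" if strand_conv == "OT" else "-"
        pos, codes = self.index.sites_in_window(
            chrom, start, start + cfg.read_length, strand
        )
        n_fail_wch = 0
        if len(pos):
            if gch_prob is not None:
                probs = self.prob_open.copy()
                probs[LABEL_CODE["GCH"]] = gch_prob
                probs = probs[codes]
            else:
                probs = (self.prob_open if state else self.prob_closed)[codes]
            meth = rng.random(len(pos)) < probs
            unconverted = ~meth & (rng.random(len(pos)) < cfg.conversion_failure)
            keep_base = meth | unconverted
            qp = pos - start
            converted_base = ord("T") if strand == "+" else ord("A")
            read[qp[~keep_base]] = converted_base
            n_fail_wch = int(
                (unconverted & (codes == LABEL_CODE["WCH"])).sum()
            )
        if snp is not None:
            spos, base = snp
            read[spos - start] = ord(base)
        if cfg.sequencing_error > 0:
            err = rng.random(cfg.read_length) < cfg.sequencing_error
            n_err = int(err.sum())
            if n_err:
                # substitute a uniformly chosen *different* base
                shift = rng.integers(1, 4, size=n_err)
                cur = np.searchsorted(_BASES, read[err])
                read[err] = _BASES[(cur + shift) % 4]
        return read.tobytes().decode("ascii"), n_fail_wch


def _make_segment(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    start: int,
    seq: str,
    is_read1: bool,
    conv: str,
    mate_chrom: str,
    mate_start: int,
    base_quality: int,
    mapq: int = 60,
    duplicate: bool = False,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    flag = 0x1 | 0x2 | (0x40 if is_read1 else 0x80)
    if duplicate:
        flag |= 0x400
    a.flag = flag
    a.reference_id = header.get_tid(chrom)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = [(0, len(seq))]
    a.next_reference_id = header.get_tid(mate_chrom)
    a.next_reference_start = mate_start
    a.query_qualities = pysam.qualitystring_to_array(
        chr(base_quality + 33) * len(seq)
    )
    a.set_tag("XG", "CT" if conv == "OT" else "GA")
    return a


def simulate_linked_readpairs(
    config: SimulationConfig,
    genome: Optional[GenomeSequence] = None,
    anchors: Optional[AnchorPairSet] = None,
    index: Optional[ContextIndex] = None,
) -> SimulatedDataset:
    """Full dataset: reference, anchors, reads, planted loci, truth tables."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if genome is None:
        genome = simulate_reference(
            cfg.genome_length, cfg.gc_fraction, cfg.seed, cfg.chromosome
        )
    if index is None:
        index = build_context_index(genome)
    n_allelic = sum(item.n_loci for item in cfg.allelic_plan)
    n_total_anchor_pairs = cfg.n_anchor_pairs + n_allelic
    if anchors is None:
        anchors = simulate_anchor_pairs(
            genome,
            n_total_anchor_pairs,
            cfg.anchor_span,
            cfg.min_anchor_separation,
            cfg.seed + 1,
            index=index,
        )
    elif len(anchors) < n_total_anchor_pairs:
        raise SimulationError(
            f"allelic plan needs {n_total_anchor_pairs} anchor pairs, got {len(anchors)}"
        )

    header = pysam.AlignmentHeader.from_references(
        list(genome.lengths), list(genome.lengths.values())
    )
    emitter = _Emitter(genome, index, cfg)
    joint = bivariate_bernoulli_probs(cfg.pi_open, cfg.rho_latent)

    reads: List[pysam.AlignedSegment] = []
    mol_rows = []
    loci_rows = []
    het_snps: List = []
    mol_id = 0

    def place(start_lo: int, start_hi: int) -> int:
        return int(rng.integers(start_lo, max(start_lo + 1, start_hi)))

    def emit_pair(apair, s1, s2, kind, allele="", snp=None, locus_id="",
                  q1=None, q2=None):
        nonlocal mol_id
        conv = "OT" if rng.random() < 0.5 else "OB"
        chrom = apair.chrom1
        if snp is not None:
            spos = snp[0]
            lo = max(apair.start1, spos - cfg.read_length + 1)
            hi = min(spos, apair.end1 - cfg.read_length) + 1
            start1 = place(lo, hi)
        else:
            start1 = place(apair.start1, apair.end1 - cfg.read_length + 1)
        start2 = place(apair.start2, apair.end2 - cfg.read_length + 1)
        name = f"mol{mol_id}"
        seq1, w1 = emitter.emit(chrom, start1, s1, conv, rng, snp=snp, gch_prob=q1)
        seq2, w2 = emitter.emit(apair.chrom2, start2, s2, conv, rng, gch_prob=q2)
        reads.append(
            _make_segment(
                header, name, chrom, start1, seq1, True, conv,
                apair.chrom2, start2, cfg.base_quality,
            )
        )
        reads.append(
            _make_segment(
                header, name, apair.chrom2, start2, seq2, False, conv,
                chrom, start1, cfg.base_quality,
            )
        )
        mol_rows.append(
            (name, kind, apair.id, float(s1), float(s2), conv, allele, locus_id, w1, w2)
        )
        mol_id += 1

    anchor_rows = list(anchors.rows.itertuples())

    # plain long-range molecules with correlated latent states
    for apair in anchor_rows[: cfg.n_anchor_pairs]:
        states = rng.choice(4, size=cfg.n_pairs_per_anchor, p=joint)
        for st in states:
            emit_pair(apair, st >> 1, st & 1, "long")
        # optional short-range molecules confined to anchor A: one shared state
        for _ in range(cfg.n_local_pairs_per_anchor):
            nonlocal_state = int(rng.random() < cfg.pi_open)
            conv = "OT" if rng.random() < 0.5 else "OB"
            chrom = apair.chrom1
            s1 = place(apair.start1, apair.end1 - cfg.read_length + 1)
            s2 = place(apair.start1, apair.end1 - cfg.read_length + 1)
            name = f"mol{mol_id}"
            q1, w1 = emitter.emit(chrom, s1, nonlocal_state, conv, rng)
            q2, w2 = emitter.emit(chrom, s2, nonlocal_state, conv, rng)
            reads.append(
                _make_segment(header, name, chrom, s1, q1, True, conv, chrom, s2,
                              cfg.base_quality)
            )
            reads.append(
                _make_segment(header, name, chrom, s2, q2, False, conv, chrom, s1,
                              cfg.base_quality)
            )
            mol_rows.append(
                (name, "local", apair.id, nonlocal_state, nonlocal_state, conv,
                 "", "", w1, w2)
            )
            mol_id += 1

    # allele-specific loci on the remaining anchor pairs
    locus_anchor_iter = iter(anchor_rows[cfg.n_anchor_pairs :])
    seq_arr = {c: np.frombuffer(s.encode(), dtype=np.uint8) for c, s in genome.sequences.items()}
    locus_n = 0
    for item in cfg.allelic_plan:
        for _ in range(item.n_loci):
            apair = next(locus_anchor_iter)
            # SNP site: an A or T inside anchor A (assignable on either strand),
            # placed so a full read window fits around it
            arr = seq_arr[apair.chrom1]
            lo = apair.start1 + 1
            hi = apair.end1 - cfg.read_length
            cand = np.flatnonzero(
                (arr[lo:hi] == ord("A")) | (arr[lo:hi] == ord("T"))
            )
            if len(cand) == 0:
                raise SimulationError("no A/T base available for SNP placement")
            spos = int(lo + rng.choice(cand))
            ref_base = chr(arr[spos])
            alt_base = "T" if ref_base == "A" else "A"
            locus_id = f"locus{locus_n}"
            from nomehic.allelic import HetSNP

            het_snps.append(
                HetSNP(apair.chrom1, spos + 1, ref_base, alt_base)
            )
            loci_rows.append(
                (locus_id, apair.id, apair.chrom1, spos + 1, ref_base, alt_base,
                 item.group, item.p_hi, item.p_lo, item.reads_per_allele)
            )
            # effects are per-site GCH open probabilities; the anchor without
            # a planted effect emits at the marginal accessibility level
            q_neutral = cfg.pi_open * cfg.p_open + (1 - cfg.pi_open) * cfg.p_closed
            for allele, p_eff in (("REF", item.p_hi), ("ALT", item.p_lo)):
                base = ref_base if allele == "REF" else alt_base
                if item.group == "GROUP1":
                    q1 = q2 = p_eff
                elif item.group == "GROUP2":
                    q1, q2 = p_eff, q_neutral
                elif item.group == "GROUP3":
                    q1, q2 = q_neutral, p_eff
                else:  # NONE: null locus
                    q1 = q2 = q_neutral
                for _ in range(item.reads_per_allele):
                    emit_pair(
                        apair, q1, q2, "allelic", allele=allele,
                        snp=(spos, base), locus_id=locus_id,
                        q1=q1, q2=q2,
                    )
            locus_n += 1

    molecules = pd.DataFrame(
        mol_rows,
        columns=[
            "mol_id", "kind", "anchor_pair_id", "state1", "state2",
            "conversion_strand", "allele", "locus_id", "wch_failures1",
            "wch_failures2",
        ],
    )
    loci = pd.DataFrame(
        loci_rows,
        columns=[
            "locus_id", "anchor_pair_id", "chrom", "pos", "ref", "alt",
            "group", "p_hi", "p_lo", "reads_per_allele",
        ],
    )
    return SimulatedDataset(
        genome=genome,
        index=index,
        anchors=anchors,
        reads=reads,
        header=header,
        het_snps=het_snps,
        truth=TruthBundle(molecules=molecules, loci=loci, config=cfg),
    )


def plant_allelic_loci(
    config: SimulationConfig,
    plan: Sequence[AllelicPlanItem],
) -> SimulatedDataset:
    """Dataset consisting only of planted allele-specific loci."""
    cfg = replace(config, allelic_plan=list(plan), n_anchor_pairs=0)
    return simulate_linked_readpairs(cfg)


def write_sam(
    reads: Sequence[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str,
) -> None:
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in reads:
            out.write(r)


def simulate_variant_table(
    seed: int = 0, chromosome: str = "chr1"
) -> Tuple[List[VariantRecord], Dict[int, List[str]]]:
    """Crafted genotype records exercising each post-filter rule exactly once.

    Returns (records, truth) where truth maps position -> expected FILTER
    list.  Twelve records: five clean PASS calls (spanning transition and
    transversion substitutions), one failure per single-record rule, and a
    clustered pair failing the proximity rule.
    """
    rng = np.random.default_rng(seed)

    def clean(pos, ref, alt, gt=(0, 1)):
        return VariantRecord(
            chromosome=chromosome,
            position=pos,
            ref_allele=ref,
            alt_alleles=(alt,),
            genotype=gt,
            genotype_quality=float(50 + rng.integers(0, 30)),
            depth=float(30 + rng.integers(0, 15)),
            strand_bias_score=-0.5,
            mq0_fraction=0.0,
        )

    records = [
        clean(1_000, "A", "G"),
        clean(5_000, "C", "T", gt=(1, 1)),
        clean(9_000, "G", "A"),
        clean(13_000, "T", "C"),
        clean(17_000, "A", "C"),
    ]
    truth: Dict[int, List[str]] = {r.position: [variants.PASS] for r in records}

    r = clean(25_000, "A", "G")
    r.genotype_quality = 15.0
    r.depth = 10.0
    records.append(r)
    truth[r.position] = [variants.RULE_LOW_GQ]

    r = clean(29_000, "C", "A")
    r.depth = 300.0
    r.genotype_quality = 400.0
    records.append(r)
    truth[r.position] = [variants.RULE_MAX_DEPTH]

    r = clean(33_000, "G", "C")
    r.strand_bias_score = -0.01
    records.append(r)
    truth[r.position] = [variants.RULE_STRAND_BIAS]

    r = clean(37_000, "T", "A")
    r.depth = 50.0
    r.genotype_quality = 60.0
    r.mq0_fraction = 0.2
    records.append(r)
    truth[r.position] = [variants.RULE_MQ0]

    r = clean(41_000, "A", "T")
    r.genotype_quality = 30.0
    r.depth = 40.0
    records.append(r)
    truth[r.position] = [variants.RULE_GQ_BY_DEPTH]

    r1 = clean(45_000, "C", "G")
    r2 = clean(45_006, "T", "G")
    records.extend([r1, r2])
    truth[r1.position] = [variants.RULE_SNP_CLUSTER]
    truth[r2.position] = [variants.RULE_SNP_CLUSTER]

    records.sort(key=lambda rec: (rec.chromosome, rec.position))
    return records, truth
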