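"""Per-read methylation calling and linked-pair filtering.

Takes aligned, duplicate-marked bisulfite-converted read pairs (SAM/BAM)
and produces, per retained pair, context-resolved methylation calls on
each end plus a pair class (cis long-range / cis short-range / trans).

Filters applied, in order, mirror standard bisulfite Hi-C practice:
mapping quality > 30 on both ends, PCR duplicates dropped, reads with
incomplete bisulfite conversion (methylated WCH above a threshold)
dropped, base quality > 5 per methylation call.  Pairs spanning more than
20 kb are classed as long-range and are the unit of the downstream
concordance and allele-specific analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from nomehic import contexts
from nomehic.contexts import ContextIndex, LABELS

CIS_LONG = "CIS_LONG"
CIS_SHORT = "CIS_SHORT"
TRANS = "TRANS"

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 5
DEFAULT_LONG_RANGE = 20_000
DEFAULT_MAX_METH_WCH = 3
DEFAULT_CONVERSION_TAG = "XG"


class ReadError(ValueError):
    """Malformed or unusable alignment record."""


@dataclass(frozen=True)
class MethylCall:
    """One cytosine observation on one read end."""

    chromosome: str
    position: int  # 0-based forward coordinate
    strand: str  # context strand, '+' or '-'
    label: str  # context label (GCG calls are excluded from summaries)
    methylated: bool
    base_quality: int


@dataclass
class AlignedEnd:
    """One aligned read end with its methylation calls.

    ``conversion_strand`` is OT (original top: reports forward-strand
    cytosines as C/T) or OB (original bottom: reports minus-strand
    cytosines, seen as G/A at forward-strand G positions).
    """

    chromosome: str
    start: int
    end: int
    mapq: int
    conversion_strand: str
    duplicate_flag: bool = False
    calls: List[MethylCall] = field(default_factory=list)
    query_sequence: Optional[str] = None
    query_qualities: Optional[Sequence[int]] = None
    aligned_ref_to_query: Optional[Dict[int, int]] = None

    def base_at(self, pos: int) -> Optional[Tuple[str, int]]:
        """Read base and quality at a reference position, or None."""
        if self.aligned_ref_to_query is None or self.query_sequence is None:
            return None
        q = self.aligned_ref_to_query.get(pos)
        if q is None:
            return None
        qual = self.query_qualities[q] if self.query_qualities is not None else 60
        return self.query_sequence[q], qual

    def summarize(self, labels: frozenset) -> Tuple[int, int]:
        """(methylated, total) over calls whose label is in ``labels``."""
        total = meth = 0
        for c in self.calls:
            if c.label in labels:
                total += 1
                meth += c.methylated
        return meth, total


@dataclass
class LinkedReadPair:
    """Two aligned ends from one DNA molecule."""

    name: str
    end1: AlignedEnd
    end2: AlignedEnd
    pair_class: str
    separation: Optional[int]  # outermost span, cis pairs only

    def ends(self) -> Tuple[AlignedEnd, AlignedEnd]:
        return self.end1, self.end2


@dataclass
class AnchorPairSet:
    """Paired loop-anchor intervals from a BEDPE file (0-based, half-open)."""

    rows: pd.DataFrame  # chrom1,start1,end1,chrom2,start2,end2,id

    @classmethod
    def from_bedpe(cls, path: str) -> "AnchorPairSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(6),
            names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
            dtype={"chrom1": str, "chrom2": str},
        )
        df["id"] = [f"ap{i}" for i in range(len(df))]
        return cls(df)

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, int, int, str, int, int]]
    ) -> "AnchorPairSet":
        df = pd.DataFrame(
            list(records),
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        df["id"] = [f"ap{i}" for i in range(len(df))]
        return cls(df)

    def __len__(self) -> int:
        return len(self.rows)

    def anchors(self) -> pd.DataFrame:
        """All distinct single anchors (both sides), with ids."""
        a = self.rows[["chrom1", "start1", "end1"]].rename(
            columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
        )
        b = self.rows[["chrom2", "start2", "end2"]].rename(
            columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
        )
        anchors = pd.concat([a, b], ignore_index=True).drop_duplicates()
        anchors = anchors.sort_values(["chrom", "start"]).reset_index(drop=True)
        anchors["anchor_id"] = [f"a{i}" for i in range(len(anchors))]
        return anchors

    def to_bedpe(self, path: str) -> None:
        self.rows[
            ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "id"]
        ].to_csv(path, sep="\t", index=False, header=False)


def _conversion_strand_from_read(
    read: pysam.AlignedSegment, tag: str = DEFAULT_CONVERSION_TAG
) -> str:
    """OT/OB from the aligner's conversion tag (values CT/GA or OT/OB)."""
    if not read.has_tag(tag):
        raise ReadError(f"read {read.query_name}: missing conversion tag {tag}")
    val = str(read.get_tag(tag)).upper()
    if val in ("CT", "OT"):
        return "OT"
    if val in ("GA", "OB"):
        return "OB"
    raise ReadError(f"read {read.query_name}: unknown conversion tag value {val!r}")


def infer_conversion_strand(
    read: pysam.AlignedSegment, reference: "contexts.GenomeSequence"
) -> str:
    """Infer OT/OB by counting C->T vs G->A mismatches against the reference.

    A fully converted top-strand read shows reference Cs as Ts; a
    bottom-strand read shows reference Gs as As.  The majority pattern wins.
    """
    seq = read.query_sequence
    refseq = reference.sequences[read.reference_name]
    ct = ga = 0
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        rb, qb = refseq[rpos], seq[qpos]
        if rb == "C" and qb == "T":
            ct += 1
        elif rb == "G" and qb == "A":
            ga += 1
    if ct == ga:
        raise ReadError(
            f"read {read.query_name}: conversion strand not inferable (C>T={ct}, G>A={ga})"
        )
    return "OT" if ct > ga else "OB"


def call_read_methylation(
    read: pysam.AlignedSegment,
    conversion_strand: str,
    index: ContextIndex,
    min_base_quality: int = DEFAULT_MIN_BASEQ,
) -> List[MethylCall]:
    """Context-resolved methylation calls for one aligned read end.

    OT reads report forward-strand reference cytosines: read C = methylated
    (protected from conversion), read T = unmethylated; other bases are
    skipped (mismatch/SNV).  OB reads report minus-strand cytosines at
    forward-strand G positions: read G = methylated, read A = unmethylated.
    Calls at or below ``min_base_quality`` are dropped.  GCG-context calls
    are retained in the list but carry the GCG label so downstream
    summaries exclude them.
    """
    if conversion_strand not in ("OT", "OB"):
        raise ReadError(f"unknown conversion strand {conversion_strand!r}")
    chrom = read.reference_name
    seq = read.query_sequence
    quals = read.query_qualities
    strand = "+" if conversion_strand == "OT" else "-"
    meth_base, unmeth_base = ("C", "T") if strand == "+" else ("G", "A")

    calls: List[MethylCall] = []
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        label_code_arrs = index.sites_in_window(chrom, rpos, rpos + 1, strand)
        if len(label_code_arrs[0]) == 0:
            continue
        label = LABELS[label_code_arrs[1][0]]
        qb = seq[qpos]
        qual = quals[qpos] if quals is not None else 60
        if qual <= min_base_quality:
            continue
        if qb == meth_base:
            methylated = True
        elif qb == unmeth_base:
            methylated = False
        else:
            continue
        calls.append(MethylCall(chrom, rpos, strand, label, methylated, qual))
    return calls


def _call_fast(
    read: pysam.AlignedSegment,
    conversion_strand: str,
    index: ContextIndex,
    min_base_quality: int,
) -> List[MethylCall]:
    """Vectorized calling for gapless (single-M CIGAR) alignments."""
    chrom = read.reference_name
    start = read.reference_start
    strand = "+" if conversion_strand == "OT" else "-"
    pos, codes = index.sites_in_window(chrom, start, read.reference_end, strand)
    if len(pos) == 0:
        return []
    seq = np.frombuffer(read.query_sequence.encode(), dtype=np.uint8)
    qp = pos - start
    bases = seq[qp]
    quals = read.query_qualities
    q = (
        np.asarray(quals, dtype=np.int16)[qp]
        if quals is not None
        else np.full(len(qp), 60, dtype=np.int16)
    )
    meth_b, unmeth_b = (ord("C"), ord("T")) if strand == "+" else (ord("G"), ord("A"))
    keep = (q > min_base_quality) & ((bases == meth_b) | (bases == unmeth_b))
    return [
        MethylCall(chrom, int(p), strand, LABELS[c], bool(b == meth_b), int(qq))
        for p, c, b, qq in zip(pos[keep], codes[keep], bases[keep], q[keep])
    ]


def call_end(
    read: pysam.AlignedSegment,
    index: ContextIndex,
    min_base_quality: int = DEFAULT_MIN_BASEQ,
    conversion_tag: str = DEFAULT_CONVERSION_TAG,
    reference: Optional["contexts.GenomeSequence"] = None,
    keep_sequence: bool = True,
) -> AlignedEnd:
    """Build an AlignedEnd (with methylation calls) from one SAM record."""
    if read.is_unmapped:
        raise ReadError(f"read {read.query_name}: unmapped")
    try:
        cs = _conversion_strand_from_read(read, conversion_tag)
    except ReadError:
        if reference is None:
            raise
        cs = infer_conversion_strand(read, reference)
    cigar = read.cigartuples
    gapless = cigar is not None and len(cigar) == 1 and cigar[0][0] == 0
    if gapless:
        calls = _call_fast(read, cs, index, min_base_quality)
        ref2query = None
        if keep_sequence:
            ref2query = {
                read.reference_start + i: i for i in range(read.query_length)
            }
    else:
        calls = call_read_methylation(read, cs, index, min_base_quality)
        ref2query = (
            {r: q for q, r in read.get_aligned_pairs(matches_only=True)}
            if keep_sequence
            else None
        )
    return AlignedEnd(
        chromosome=read.reference_name,
        start=read.reference_start,
        end=read.reference_end,
        mapq=read.mapping_quality,
        conversion_strand=cs,
        duplicate_flag=read.is_duplicate,
        calls=calls,
        query_sequence=read.query_sequence if keep_sequence else None,
        query_qualities=(
            list(read.query_qualities)
            if keep_sequence and read.query_qualities is not None
            else None
        ),
        aligned_ref_to_query=ref2query,
    )


def is_incompletely_converted(
    calls: Iterable[MethylCall], max_methylated_wch: int = DEFAULT_MAX_METH_WCH
) -> bool:
    """True if the read looks unconverted: >= threshold methylated WCH calls.

    WCH cytosines (W=A/T, H=A/C/T) carry neither endogenous CpG methylation
    nor GpC enzyme signal, so apparent methylation there marks bisulfite
    conversion failure.  CCH sites are not counted: residual CpC
    methyltransferase activity makes them unreliable for this check.
    """
    n = sum(1 for c in calls if c.label == contexts.WCH and c.methylated)
    return n >= max_methylated_wch


def classify_pair(end1: AlignedEnd, end2: AlignedEnd, long_range: int = DEFAULT_LONG_RANGE):
    """Pair class and separation; separation is the outermost span (cis)."""
    if end1.chromosome != end2.chromosome:
        return TRANS, None
    sep = max(end1.end, end2.end) - min(end1.start, end2.start)
    return (CIS_LONG if sep > long_range else CIS_SHORT), sep


def load_linked_pairs(
    alignments: Iterable[pysam.AlignedSegment],
    index: ContextIndex,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_base_quality: int = DEFAULT_MIN_BASEQ,
    long_range: int = DEFAULT_LONG_RANGE,
    drop_duplicates: bool = True,
    conversion_filter: bool = True,
    max_methylated_wch: int = DEFAULT_MAX_METH_WCH,
    conversion_tag: str = DEFAULT_CONVERSION_TAG,
    reference: Optional["contexts.GenomeSequence"] = None,
    keep_sequence: bool = True,
    stats: Optional[Dict[str, int]] = None,
) -> List[LinkedReadPair]:
    """Join mates by name and apply the pair-level filters.

    A pair is retained only if both ends exceed ``min_mapq``, neither is a
    PCR duplicate (when ``drop_duplicates``), and neither end fails the
    incomplete-conversion check (when ``conversion_filter``).  Secondary
    and supplementary records are ignored.  Unmated reads are skipped and
    counted in ``stats``.
    """
    if stats is None:
        stats = {}
    stats.setdefault("unmated", 0)
    stats.setdefault("fail_mapq", 0)
    stats.setdefault("fail_duplicate", 0)
    stats.setdefault("fail_conversion", 0)
    stats.setdefault("retained", 0)

    by_name: Dict[str, pysam.AlignedSegment] = {}
    pairs: List[LinkedReadPair] = []
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        mate = by_name.pop(read.query_name, None)
        if mate is None:
            by_name[read.query_name] = read
            continue
        r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
        if min(r1.mapping_quality, r2.mapping_quality) <= min_mapq:
            stats["fail_mapq"] += 1
            continue
        if drop_duplicates and (r1.is_duplicate or r2.is_duplicate):
            stats["fail_duplicate"] += 1
            continue
        e1 = call_end(r1, index, min_base_quality, conversion_tag, reference, keep_sequence)
        e2 = call_end(r2, index, min_base_quality, conversion_tag, reference, keep_sequence)
        if conversion_filter and (
            is_incompletely_converted(e1.calls, max_methylated_wch)
            or is_incompletely_converted(e2.calls, max_methylated_wch)
        ):
            stats["fail_conversion"] += 1
            continue
        pair_class, sep = classify_pair(e1, e2, long_range)
        pairs.append(LinkedReadPair(r1.query_name, e1, e2, pair_class, sep))
        stats["retained"] += 1
    stats["unmated"] += len(by_name)
    return pairs


def load_linked_pairs_from_path(path: str, index: ContextIndex, **kwargs):
    """`load_linked_pairs` over a SAM/BAM file path."""
    with pysam.AlignmentFile(path, check_sq=False) as af:
        return load_linked_pairs(af, index, **kwargs)


def _overlaps(end: AlignedEnd, chrom: str, start: int, stop: int) -> bool:
    return end.chromosome == chrom and end.start < stop and end.end > start


def assign_pairs_to_anchor_pairs(
    pairs: Iterable[LinkedReadPair],
    anchors: AnchorPairSet,
    first_match_only: bool = False,
) -> Dict[str, List[LinkedReadPair]]:
    """Assign CIS_LONG pairs to BEDPE rows: one end in each anchor.

    Either orientation counts.  A pair overlapping multiple rows is assigned
    to every matching row unless ``first_match_only``.
    """
    trees: Dict[str, IntervalTree] = {}
    for _, row in anchors.rows.iterrows():
        trees.setdefault(row.chrom1, IntervalTree()).addi(
            row.start1, row.end1, (row.id, "A")
        )
        trees.setdefault(row.chrom2, IntervalTree()).addi(
            row.start2, row.end2, (row.id, "B")
        )
    assigned: Dict[str, List[LinkedReadPair]] = {
        rid: [] for rid in anchors.rows["id"]
    }
    for pair in pairs:
        if pair.pair_class != CIS_LONG:
            continue
        hits1 = {
            iv.data
            for iv in trees.get(pair.end1.chromosome, IntervalTree()).overlap(
                pair.end1.start, pair.end1.end
            )
        }
        hits2 = {
            iv.data
            for iv in trees.get(pair.end2.chromosome, IntervalTree()).overlap(
                pair.end2.start, pair.end2.end
            )
        }
        matched = set()
        for rid, side in hits1:
            other = "B" if side == "A" else "A"
            if (rid, other) in hits2:
                matched.add(rid)
        for rid in sorted(matched):
            assigned[rid].append(pair)
            if first_match_only:
                break
    return assigned


def pairs_to_dataframe(
    pairs: Iterable[LinkedReadPair], context: str = "GCH"
) -> pd.DataFrame:
    """Per-pair summary table (one row per pair, both-end counts)."""
    labels = contexts.expand_labels([context])
    rows = []
    for p in pairs:
        m1, t1 = p.end1.summarize(labels)
        m2, t2 = p.end2.summarize(labels)
        rows.append(
            (
                p.name,
                p.end1.chromosome,
                p.end1.start,
                p.end1.end,
                p.end2.chromosome,
                p.end2.start,
                p.end2.end,
                p.pair_class,
                m1,
                t1,
                m2,
                t2,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "chrom1",
            "start1",
            "end1",
            "chrom2",
            "start2",
            "end2",
            "class",
            f"{context}_meth1",
            f"{context}_total1",
            f"{context}_meth2",
            f"{context}_total2",
        ],
    )


def per_site_methylation(
    pairs: Iterable[LinkedReadPair], labels: Iterable[str] = ("GCH",)
) -> pd.DataFrame:
    """Pooled per-site methylation table (bedGraph-compatible columns)."""
    lab = contexts.expand_labels(labels)
    acc: Dict[Tuple[str, int, str], List[int]] = {}
    for p in pairs:
        for end in p.ends():
            for c in end.calls:
                if c.label in lab:
                    key = (c.chromosome, c.position, c.strand)
                    meth, tot = acc.get(key, (0, 0))
                    acc[key] = (meth + c.methylated, tot + 1)
    rows = [
        (chrom, pos, pos + 1, meth / tot, meth, tot, strand)
        for (chrom, pos, strand), (meth, tot) in sorted(acc.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "fraction", "methylated", "total", "strand"],
    )
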