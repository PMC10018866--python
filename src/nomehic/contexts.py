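"""Strand-aware cytosine-context indexing and reference utilities.

Bisulfite footprinting assays distinguish cytosines by their immediate
neighbours.  With an exogenous GpC methyltransferase in play, the useful
partition of reference cytosines is:

- ``GCH`` — preceded by G, not followed by G: reports enzyme accessibility.
- ``HCG`` = ``WCG`` ∪ ``CCG`` — not preceded by G, followed by G: reports
  endogenous CpG methylation (``WCG`` when preceded by A/T, ``CCG`` by C).
- ``GCG`` — both flanks G: ambiguous between the two signals, excluded.
- ``HCH`` = ``WCH`` ∪ ``CCH`` — neither flank informative; residual
  methylation at ``WCH`` flags incomplete bisulfite conversion.

Cytosines on the minus strand (a forward-strand G) are classified on the
reverse complement and reported at the forward coordinate of the G with
strand ``-``.  All coordinates are 0-based, half-open; 1-based coordinates
appear only at SAM/VCF boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd
from pyfaidx import Fasta

# Context label vocabulary.  HCG and HCH are derived unions, not stored.
GCG = "GCG"
GCH = "GCH"
WCG = "WCG"
CCG = "CCG"
WCH = "WCH"
CCH = "CCH"
UNCLASSIFIED = "UNCLASSIFIED"

LABELS: Tuple[str, ...] = (GCG, GCH, WCG, CCG, WCH, CCH, UNCLASSIFIED)
LABEL_CODE: Dict[str, int] = {lab: i for i, lab in enumerate(LABELS)}
HCG_LABELS = frozenset({WCG, CCG})
HCH_LABELS = frozenset({WCH, CCH})

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ContextError(ValueError):
    """Invalid input to a context operation."""


def _complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass
class GenomeSequence:
    """Uppercase reference sequences over the {A,C,G,T,N} alphabet."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            if set(seq) - _VALID:
                # IUPAC ambiguity codes are collapsed to N: contexts through
                # an ambiguous base are undefined anyway.
                seq = "".join(b if b in _VALID else "N" for b in seq)
            cleaned[name] = seq
        self.sequences = cleaned

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        with Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as out:
            for name, seq in self.sequences.items():
                out.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    out.write(seq[i : i + width] + "\n")

    def gc_fraction(self, chrom: str | None = None) -> float:
        seqs = [self.sequences[chrom]] if chrom else self.sequences.values()
        gc = total = 0
        for seq in seqs:
            gc += seq.count("G") + seq.count("C")
            total += len(seq) - seq.count("N")
        if total == 0:
            raise ContextError("no non-N bases")
        return gc / total


def classify_cytosine(prev_base: str, next_base: str) -> str:
    """Classify a cytosine by its 5' and 3' neighbours on the same strand.

    Returns one of GCG, GCH, WCG, CCG, WCH, CCH, or UNCLASSIFIED when a
    flank is N (the context is undefined).
    """
    if prev_base not in _VALID or next_base not in _VALID:
        raise ContextError(f"invalid nucleotide: {prev_base!r}/{next_base!r}")
    if prev_base == "N" or next_base == "N":
        return UNCLASSIFIED
    if prev_base == "G":
        return GCG if next_base == "G" else GCH
    if next_base == "G":
        return CCG if prev_base == "C" else WCG
    return CCH if prev_base == "C" else WCH


# int8 codes used by the vectorized classifier; must agree with classify_cytosine
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
    return table[arr]


def _classify_vector(prev: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Vectorized classify_cytosine over coded flank arrays."""
    out = np.empty(prev.shape, dtype=np.int8)
    is_n = (prev == 4) | (nxt == 4)
    prev_g = prev == 2
    next_g = nxt == 2
    prev_c = prev == 1
    out[:] = LABEL_CODE[WCH]
    out[prev_c] = LABEL_CODE[CCH]
    out[next_g & ~prev_c] = LABEL_CODE[WCG]
    out[next_g & prev_c] = LABEL_CODE[CCG]
    out[prev_g] = LABEL_CODE[GCH]
    out[prev_g & next_g] = LABEL_CODE[GCG]
    out[is_n] = LABEL_CODE[UNCLASSIFIED]
    return out


@dataclass
class ContextIndex:
    """Every reference cytosine, both strands, with its context label.

    Per (chromosome, strand) the index stores a sorted position array and a
    parallel int8 label-code array; minus-strand entries sit at the forward
    coordinate of the G.
    """

    positions: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)
    labels: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)

    def chromosomes(self) -> List[str]:
        return sorted({chrom for chrom, _ in self.positions})

    def lookup(self, chrom: str, pos: int, strand: str) -> str | None:
        """Label at a forward coordinate on a strand, or None if not a C."""
        key = (chrom, strand)
        if key not in self.positions:
            return None
        arr = self.positions[key]
        i = np.searchsorted(arr, pos)
        if i < len(arr) and arr[i] == pos:
            return LABELS[self.labels[key][i]]
        return None

    def sites_in_window(
        self, chrom: str, start: int, end: int, strand: str
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Positions and label codes on a strand within [start, end)."""
        key = (chrom, strand)
        if key not in self.positions:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
        arr = self.positions[key]
        lo, hi = np.searchsorted(arr, (start, end))
        return arr[lo:hi], self.labels[key][lo:hi]

    def __iter__(self) -> Iterator[Tuple[str, int, str, str]]:
        """Entries sorted by (chromosome, position, strand)."""
        for chrom in self.chromosomes():
            merged: List[Tuple[int, str, str]] = []
            for strand in ("+", "-"):
                key = (chrom, strand)
                if key in self.positions:
                    for pos, code in zip(self.positions[key], self.labels[key]):
                        merged.append((int(pos), strand, LABELS[code]))
            merged.sort(key=lambda t: (t[0], t[1]))
            for pos, strand, label in merged:
                yield chrom, pos, strand, label

    def count(self, labels: Iterable[str], both_strands: bool = True) -> int:
        codes = {LABEL_CODE[lab] for lab in labels}
        total = 0
        for (chrom, strand), arr in self.labels.items():
            if not both_strands and strand != "+":
                continue
            total += int(np.isin(arr, list(codes)).sum())
        return total

    def label_counts(self, strand: str | None = None) -> Dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for (chrom, st), arr in self.labels.items():
            if strand is not None and st != strand:
                continue
            binc = np.bincount(arr, minlength=len(LABELS))
            for lab, code in LABEL_CODE.items():
                counts[lab] += int(binc[code])
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        rows = list(self)
        df = pd.DataFrame(rows, columns=["chrom", "start", "strand", "label"])
        df["end"] = df["start"] + 1
        return df[["chrom", "start", "end", "label", "strand"]]

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, header=False)


def build_context_index(genome: GenomeSequence) -> ContextIndex:
    """Classify every cytosine on both strands of a genome.

    Forward-strand Cs use flanks (seq[i-1], seq[i+1]); a forward-strand G is
    a minus-strand C classified on the reverse complement, i.e. with flanks
    (complement(seq[i+1]), complement(seq[i-1])).  Chromosome-edge cytosines
    have an undefined flank and are UNCLASSIFIED.
    """
    if not genome.sequences:
        raise ContextError("empty genome")
    index = ContextIndex()
    for chrom, seq in genome.sequences.items():
        coded = _encode(seq)
        n = len(coded)
        if n == 0:
            continue
        # pad with N so edge cytosines classify as UNCLASSIFIED
        padded = np.concatenate(([4], coded, [4])).astype(np.int8)
        prev, this, nxt = padded[:-2], padded[1:-1], padded[2:]
        fwd = np.flatnonzero(this == 1)  # C
        if len(fwd):
            index.positions[(chrom, "+")] = fwd.astype(np.int64)
            index.labels[(chrom, "+")] = _classify_vector(prev[fwd], nxt[fwd])
        rev = np.flatnonzero(this == 2)  # G = minus-strand C
        if len(rev):
            comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G
            index.positions[(chrom, "-")] = rev.astype(np.int64)
            index.labels[(chrom, "-")] = _classify_vector(
                comp[nxt[rev]], comp[prev[rev]]
            )
    return index


def expand_labels(labels: Iterable[str]) -> frozenset:
    """Expand the derived unions HCG and HCH into their atomic labels."""
    out = set()
    for lab in labels:
        if lab == "HCG":
            out |= HCG_LABELS
        elif lab == "HCH":
            out |= HCH_LABELS
        elif lab in LABEL_CODE:
            out.add(lab)
        else:
            raise ContextError(f"unknown context label: {lab}")
    return frozenset(out)


def context_density(
    index: ContextIndex,
    labels: Iterable[str] | str,
    genome_length: int,
    both_strands: bool = True,
) -> float:
    """Genome bp per site of the given context(s): lower = denser.

    A value of 13.0 means one matching site every 13 bp.  ``labels`` may
    include the unions "HCG"/"HCH".  Both strands are counted by default.
    """
    if genome_length <= 0:
        raise ContextError("genome_length must be positive")
    if isinstance(labels, str):
        labels = [labels]
    n = index.count(expand_labels(labels), both_strands=both_strands)
    if n == 0:
        raise ContextError("no sites with requested labels: density undefined")
    return genome_length / n


def convert_reference(genome: GenomeSequence, mode: str) -> GenomeSequence:
    """In-silico bisulfite conversion of the reference.

    ``CT`` replaces every C with T (fully converted top strand); ``GA``
    replaces every G with A (bottom strand as seen on forward coordinates).
    """
    if mode == "CT":
        table = str.maketrans("C", "T")
    elif mode == "GA":
        table = str.maketrans("G", "A")
    else:
        raise ContextError(f"mode must be CT or GA, got {mode!r}")
    return GenomeSequence({c: s.translate(table) for c, s in genome.sequences.items()})


def orient_compartment_eigenvector(
    eigenvector: Sequence[float], gc_per_bin: Sequence[float]
) -> np.ndarray:
    """Orient a compartment eigenvector so A (positive) tracks high GC.

    The first eigenvector of a Hi-C observed/expected correlation matrix has
    an arbitrary sign; by convention the gene-rich, high-GC A compartment is
    positive.  If the eigenvector correlates negatively with per-bin GC
    content the sign is flipped; NaN bins are excluded from the correlation
    but preserved in the output.
    """
    eig = np.asarray(eigenvector, dtype=float)
    gc = np.asarray(gc_per_bin, dtype=float)
    if eig.shape != gc.shape or eig.ndim != 1 or len(eig) < 2:
        raise ContextError("eigenvector and GC vectors must be equal-length, n >= 2")
    mask = ~(np.isnan(eig) | np.isnan(gc))
    if mask.sum() < 2:
        raise ContextError("fewer than 2 non-missing bins: orientation undefined")
    e, g = eig[mask], gc[mask]
    if np.ptp(g) == 0 or np.ptp(e) == 0:
        raise ContextError("constant GC or eigenvector: orientation undefined")
    r = np.corrcoef(e, g)[0, 1]
    return -eig if r < 0 else eig.copy()
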