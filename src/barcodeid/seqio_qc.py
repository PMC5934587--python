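"""Read/write sequence data, quality trimming, two-read consensus assembly,
and screening for nuclear mitochondrial pseudogenes (Numts).

A Sanger-style barcode sample arrives as a forward/reverse read pair with
per-base Phred qualities. Low-quality stretches are trimmed (at read ends)
or masked to N (internally, preserving codon coordinates), the two strands
are merged into a consensus with quality-weighted conflict resolution, and
the result is screened for the hallmarks of a Numt: internal stop codons
under the vertebrate mitochondrial code, or frame-disrupting alignment gaps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Data import IUPACData
from Bio.Seq import Seq

__all__ = [
    "QualityRead",
    "ConsensusRecord",
    "NumtReport",
    "AssemblyError",
    "trim_low_quality",
    "assemble_consensus",
    "numt_screen",
    "read_fastq_pairs",
    "read_fasta_records",
    "write_consensus_fasta",
]

IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

_AMBIG = {frozenset(v): k for k, v in IUPACData.ambiguous_dna_values.items()
          if k not in ("X",)}

# expected barcode length window; the COI amplicon runs ~650 bp and usable
# fragments below ~150 bp carry too little signal
LENGTH_WARN_RANGE = (150, 700)


class AssemblyError(ValueError):
    """Raised when a read pair cannot be merged into a consensus."""


@dataclass
class QualityRead:
    """One sequencing read: bases, per-base Phred qualities, orientation."""

    read_id: str
    bases: str
    quals: list
    orientation: str = "forward"
    trimmed_ranges: list = field(default_factory=list)

    def __post_init__(self):
        self.bases = self.bases.upper()
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores")
        bad = set(self.bases) - IUPAC_ALPHABET
        if bad:
            raise ValueError(f"read {self.read_id!r}: non-IUPAC characters {sorted(bad)}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if any(q < 0 for q in self.quals):
            raise ValueError("Phred scores must be >= 0")

    def __len__(self):
        return len(self.bases)

    def reverse_complement(self) -> "QualityRead":
        return QualityRead(
            read_id=self.read_id,
            bases=str(Seq(self.bases).reverse_complement()),
            quals=list(reversed(self.quals)),
            orientation="forward" if self.orientation == "reverse" else "reverse",
            trimmed_ranges=list(self.trimmed_ranges),
        )


@dataclass
class ConsensusRecord:
    """Assembled (or pre-assembled) barcode sequence for one sample."""

    sample_id: str
    sequence: str
    ambiguity_count: int = 0
    trimmed_ranges: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        lo, hi = LENGTH_WARN_RANGE
        if self.sequence and not (lo <= len(self.sequence) <= hi):
            warnings.warn(
                f"{self.sample_id}: consensus length {len(self.sequence)} outside "
                f"the typical barcode window [{lo}, {hi}]")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class NumtReport:
    """Outcome of screening one sequence for Numt hallmarks."""

    sample_id: str
    best_frame: int
    internal_stop_count: int
    gap_disruption: bool

    @property
    def passed(self) -> bool:
        return self.internal_stop_count == 0 and not self.gap_disruption


def _low_quality_runs(quals, min_run: int, q_threshold: int):
    """Maximal runs of >= min_run contiguous bases below the threshold."""
    runs = []
    start = None
    for i, q in enumerate(quals):
        if q < q_threshold:
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and len(quals) - start >= min_run:
        runs.append((start, len(quals)))
    return runs


def trim_low_quality(read: QualityRead, min_run: int = 5,
                     q_threshold: int = 20) -> QualityRead:
    """Remove or mask low-quality stretches of a read.

    A maximal run of at least ``min_run`` contiguous bases with Phred
    quality below ``q_threshold`` is excised together with everything
    distal to it when it touches a read end; internal runs are masked to N
    (coordinates preserved so downstream codon structure survives). The
    operation is idempotent.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    if len(read) == 0:
        return read

    runs = _low_quality_runs(read.quals, min_run, q_threshold)
    start, end = 0, len(read)
    trimmed = []
    internal = []
    for (a, b) in runs:
        if a == 0:
            start = max(start, b)
            trimmed.append((0, b))
        elif b == len(read):
            end = min(end, a)
            trimmed.append((a, len(read)))
        else:
            internal.append((a, b))
    if start >= end:
        return QualityRead(read.read_id, "", [], read.orientation,
                           trimmed_ranges=[(0, len(read))])
    bases = list(read.bases)
    for (a, b) in internal:
        if a >= start and b <= end:
            for i in range(a, b):
                bases[i] = "N"
    return QualityRead(
        read_id=read.read_id,
        bases="".join(bases[start:end]),
        quals=list(read.quals[start:end]),
        orientation=read.orientation,
        trimmed_ranges=trimmed,
    )


def _ambiguity_code(b1: str, b2: str) -> str:
    if "N" in (b1, b2):
        return "N"
    # expand any input ambiguity codes to their base sets first
    expanded = frozenset().union(*(frozenset(IUPACData.ambiguous_dna_values[b])
                                   for b in (b1, b2)))
    return _AMBIG.get(expanded, "N")


def _overlap_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    a.end_gap_score = 0  # free end gaps: overlap alignment
    return a


def assemble_consensus(fwd: QualityRead, rev: QualityRead,
                       min_overlap: int = 50,
                       similar_q_delta: int = 10,
                       sample_id: str | None = None) -> ConsensusRecord:
    """Merge a forward/reverse read pair into a consensus sequence.

    The reverse read is reverse-complemented, the two reads are joined by
    an overlap (free-end-gap) alignment, and each overlapping column is
    resolved in favor of the higher-quality base; where the two strands
    disagree at similar quality (|dQ| < ``similar_q_delta``) the IUPAC
    two-base ambiguity code is emitted instead. Non-overlapping flanks come
    from whichever read covers them.
    """
    if rev.orientation == "reverse":
        rev = rev.reverse_complement()
    if fwd.orientation == "reverse":
        fwd = fwd.reverse_complement()
    if len(fwd) == 0 or len(rev) == 0:
        raise AssemblyError(f"empty read in pair ({fwd.read_id}, {rev.read_id})")

    aligner = _overlap_aligner()
    aln = next(iter(aligner.align(fwd.bases, rev.bases)))
    row_f, row_r = str(aln[0]), str(aln[1])

    overlap_cols = sum(1 for a, b in zip(row_f, row_r) if a != "-" and b != "-")
    if overlap_cols < min_overlap:
        raise AssemblyError(
            f"reads {fwd.read_id!r} and {rev.read_id!r} overlap over "
            f"{overlap_cols} columns (< {min_overlap})")

    out = []
    ambiguity = 0
    i_f = i_r = 0
    for a, b in zip(row_f, row_r):
        if a != "-" and b != "-":
            qa, qb = fwd.quals[i_f], rev.quals[i_r]
            if a == b:
                out.append(a)
            elif abs(qa - qb) >= similar_q_delta:
                out.append(a if qa > qb else b)
            else:
                out.append(_ambiguity_code(a, b))
            i_f += 1
            i_r += 1
        elif a != "-":
            out.append(a)
            i_f += 1
        else:
            out.append(b)
            i_r += 1
    seq = "".join(out)
    ambiguity = sum(1 for c in seq if c not in "ACGT")
    return ConsensusRecord(
        sample_id=sample_id or fwd.read_id,
        sequence=seq,
        ambiguity_count=ambiguity,
        trimmed_ranges=list(fwd.trimmed_ranges) + list(rev.trimmed_ranges),
    )


def numt_screen(sequence: str, aligned: str | None = None,
                sample_id: str = "") -> NumtReport:
    """Screen a barcode sequence for Numt hallmarks.

    All three forward frames are translated with the vertebrate
    mitochondrial genetic code (NCBI table 2, in which AGA/AGG are stops);
    the reading frame is taken to be the one minimizing internal stop
    codons. A stop in the final complete codon is not counted as internal.
    If an aligned form is supplied, any gap run whose length is not a
    multiple of 3 flags frame disruption.
    """
    seq = sequence.upper().replace("-", "").replace("?", "")
    if len(seq) < 3:
        raise ValueError("sequence must be at least one codon long")
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters {sorted(bad)}")

    best_frame, best_stops = 0, None
    for frame in range(3):
        sub = seq[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate(table=2))
        internal = aa[:-1].count("*")  # terminal stop codon is not internal
        if best_stops is None or internal < best_stops:
            best_frame, best_stops = frame, internal

    gap_disruption = False
    if aligned is not None:
        for m in re.finditer(r"-+", aligned):
            if (m.end() - m.start()) % 3 != 0:
                gap_disruption = True
                break

    return NumtReport(
        sample_id=sample_id,
        best_frame=best_frame,
        internal_stop_count=best_stops or 0,
        gap_disruption=gap_disruption,
    )


def read_fastq_pairs(path) -> list:
    """Load Sanger FASTQ (Phred+33) into QualityReads.

    Reads whose id ends in ``/1``/``_F`` are oriented forward, ``/2``/``_R``
    reverse; consecutive records are paired in file order.
    """
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        rid = rec.id
        orientation = "reverse" if rid.endswith(("/2", "_R")) else "forward"
        reads.append(QualityRead(
            read_id=rid,
            bases=str(rec.seq),
            quals=list(rec.letter_annotations["phred_quality"]),
            orientation=orientation,
        ))
    return [(reads[i], reads[i + 1]) for i in range(0, len(reads) - 1, 2)]


def read_fasta_records(path) -> list:
    """Load pre-assembled barcode sequences as ConsensusRecords."""
    return [ConsensusRecord(sample_id=rec.id, sequence=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_consensus_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.sample_id}\n{rec.sequence}\n")


def qc_report_rows(records, numt_reports=None) -> list:
    """TSV-ready QC rows: sample, length, ambiguities, numt pass, trims."""
    rows = []
    numt_reports = numt_reports or {}
    for rec in records:
        numt = numt_reports.get(rec.sample_id)
        rows.append({
            "sample_id": rec.sample_id,
            "length": rec.length,
            "ambiguity_count": rec.ambiguity_count,
            "numt_pass": "" if numt is None else str(numt.passed).lower(),
            "trimmed_ranges": ";".join(f"{a}-{b}" for a, b in rec.trimmed_ranges),
        })
    return rows
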