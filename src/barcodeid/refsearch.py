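"""Reference database handling, local-alignment top-hit search, and
candidate-set construction for barcode identification.

The search is an exact affine-gap Smith-Waterman over every reference on
both query strands (a desk-scale database makes exactness affordable), with
BLAST-style reporting: percent identity over alignment columns and percent
coverage over the query. The candidate set for distance-based assignment is
the top hit's whole genus — every congeneric species, including
open-nomenclature entries such as "Sphyrna sp." — with 2-8 reference
sequences drawn per species, mirroring how curated barcode reference sets
are assembled.

Reference FASTA headers follow the dialect ``>accession|species|genus``
with spaces in species names written as underscores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Data import IUPACData
from Bio.Seq import Seq

from .seqio_qc import ConsensusRecord

__all__ = [
    "TaxonRef",
    "ReferenceDB",
    "HitReport",
    "DEFAULT_SCORING",
    "local_align",
    "search_top_hits",
    "build_candidate_db",
    "thread_query_onto_alignment",
]

#: BLASTn-like scoring: match +2, mismatch -3, affine gap cost 5 + 2*length
DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": 5, "gap_extend": 2}

_BASE_SETS = {b: frozenset(IUPACData.ambiguous_dna_values[b])
              for b in IUPACData.ambiguous_dna_values if b != "X"}


def _compatible(a: str, b: str) -> bool:
    """True when two IUPAC symbols can denote the same base (N never does)."""
    if a == "N" or b == "N":
        return False
    sa, sb = _BASE_SETS.get(a), _BASE_SETS.get(b)
    return bool(sa and sb and (sa & sb))


@dataclass(frozen=True)
class TaxonRef:
    """One species-labeled reference barcode in the shared alignment."""

    accession: str
    species: str
    genus: str
    aligned_seq: str
    source_flags: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "aligned_seq", self.aligned_seq.upper())
        if len(self.ungapped) < 100:
            raise ValueError(
                f"{self.accession}: ungapped reference length "
                f"{len(self.ungapped)} < 100")

    @property
    def ungapped(self) -> str:
        return self.aligned_seq.replace("-", "").replace("?", "")


@dataclass
class ReferenceDB:
    """Aligned, species-labeled reference barcodes with a taxonomy index."""

    records: list

    def __post_init__(self):
        if not self.records:
            raise ValueError("reference database is empty")
        lengths = {len(r.aligned_seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"records disagree on alignment length: {sorted(lengths)}")

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].aligned_seq)

    @property
    def taxonomy(self) -> dict:
        tax: dict = {}
        for r in self.records:
            tax.setdefault(r.genus, set()).add(r.species)
        return tax

    @property
    def species(self) -> set:
        return {r.species for r in self.records}

    def records_for_species(self, species: str) -> list:
        return [r for r in self.records if r.species == species]

    def genus_of(self, species: str) -> str:
        for r in self.records:
            if r.species == species:
                return r.genus
        raise KeyError(
            f"species {species!r} not in database; known species: "
            f"{sorted(self.species)}")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDB":
        records = []
        with open(path) as fh:
            header, chunks = None, []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if header is not None:
                        records.append(cls._parse(header, "".join(chunks)))
                    header, chunks = line[1:], []
                elif line:
                    chunks.append(line)
            if header is not None:
                records.append(cls._parse(header, "".join(chunks)))
        return cls(records)

    @staticmethod
    def _parse(header: str, seq: str) -> TaxonRef:
        parts = header.split("|")
        if len(parts) < 3:
            raise ValueError(
                f"reference header {header!r} not in 'accession|species|genus' form")
        acc, species, genus = parts[0], parts[1].replace("_", " "), parts[2]
        flags = frozenset(parts[3].split(",")) if len(parts) > 3 and parts[3] else frozenset()
        return TaxonRef(accession=acc, species=species, genus=genus,
                        aligned_seq=seq, source_flags=flags)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                sp = r.species.replace(" ", "_")
                flags = "," .join(sorted(r.source_flags))
                suffix = f"|{flags}" if flags else ""
                fh.write(f">{r.accession}|{sp}|{r.genus}{suffix}\n{r.aligned_seq}\n")


@dataclass
class HitReport:
    """One local-alignment hit, with BLAST-style percent statistics."""

    query_id: str
    subject_accession: str
    subject_species: str
    score: int
    pct_identity: float
    pct_coverage: float
    query_span: tuple
    subject_span: tuple
    strand: str = "+"


def _make_aligner(scoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring["match"]
    a.mismatch_score = scoring["mismatch"]
    # Biopython charges open_gap_score for the first gap position, so a
    # length-L gap costs open + extend*L under the stated convention
    a.open_gap_score = -(scoring["gap_open"] + scoring["gap_extend"])
    a.extend_gap_score = -scoring["gap_extend"]
    return a


def _ambiguity_matrix(scoring):
    from Bio.Align import substitution_matrices
    letters = "ACGTRYSWKMBDHVN"
    m = substitution_matrices.Array(letters, dims=2)
    for x in letters:
        for y in letters:
            if x in "ACGT" and x == y:
                m[x, y] = scoring["match"]
            elif _compatible(x, y):
                m[x, y] = scoring["match"]
            else:
                m[x, y] = scoring["mismatch"]
    return m


def local_align(query: str, subject: str, scoring=None,
                query_id: str = "query", subject_accession: str = "",
                subject_species: str = "", strand: str = "+") -> HitReport:
    """Optimal affine-gap local alignment of two ungapped sequences.

    Percent identity counts identical (or compatibly ambiguous, non-N)
    columns over all alignment columns, gap columns included; percent
    coverage is the aligned fraction of the *query*. Ambiguous bases score
    as mismatches except against a compatible partner; N never matches.
    """
    scoring = scoring or DEFAULT_SCORING
    if not query or not subject:
        raise ValueError("empty sequence")
    if scoring["gap_open"] <= 0 or scoring["gap_extend"] <= 0:
        raise ValueError("gap penalties must be positive")
    query = query.upper()
    subject = subject.upper()
    aligner = _make_aligner(scoring)
    if set(query + subject) - set("ACGT"):
        aligner.substitution_matrix = _ambiguity_matrix(scoring)
    aln = next(iter(aligner.align(subject, query)))
    row_s, row_q = str(aln[0]), str(aln[1])
    ncols = len(row_s)
    ident = sum(1 for a, b in zip(row_s, row_q)
                if a != "-" and b != "-" and (a == b if a in "ACGT" and b in "ACGT"
                                              else _compatible(a, b)))
    blocks = aln.aligned  # [[subject segments], [query segments]]
    s_span = (int(blocks[0][0][0]), int(blocks[0][-1][1]))
    q_span = (int(blocks[1][0][0]), int(blocks[1][-1][1]))
    return HitReport(
        query_id=query_id,
        subject_accession=subject_accession,
        subject_species=subject_species,
        score=int(aln.score),
        pct_identity=100.0 * ident / ncols,
        pct_coverage=100.0 * (q_span[1] - q_span[0]) / len(query),
        query_span=q_span,
        subject_span=s_span,
        strand=strand,
    )


def search_top_hits(query: ConsensusRecord, db: ReferenceDB, k: int = 5,
                    scoring=None) -> list:
    """Rank every reference by optimal local-alignment score to the query.

    Both query strands are searched and the better strand reported. Hits
    are sorted by score descending, ties broken by percent identity and
    then accession. Returns the top ``k`` full HitReports.

    A score-only pass ranks all records first; full alignments (identity,
    coverage, spans) are then computed for every record tied into the top
    ``k`` by score, which cannot change the ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scoring = scoring or DEFAULT_SCORING
    qseq = query.sequence.upper()
    if not qseq:
        raise ValueError(f"query {query.sample_id!r} is empty")
    strands = {"+": qseq, "-": str(Seq(qseq).reverse_complement())}
    aligner = _make_aligner(scoring)
    ambiguous_q = bool(set(qseq) - set("ACGT"))
    amb_matrix = _ambiguity_matrix(scoring)

    scored = []
    for rec in db.records:
        subject = rec.ungapped
        use_matrix = ambiguous_q or bool(set(subject) - set("ACGT"))
        a = aligner
        if use_matrix:
            a = _make_aligner(scoring)
            a.substitution_matrix = amb_matrix
        best = None
        for strand, s in strands.items():
            sc = a.score(subject, s)
            if best is None or sc > best[0]:
                best = (sc, strand)
        scored.append((best[0], best[1], rec))

    scored.sort(key=lambda x: -x[0])
    cutoff = scored[min(k, len(scored)) - 1][0]
    hits = []
    for sc, strand, rec in scored:
        if sc < cutoff:
            break
        hits.append(local_align(
            strands[strand], rec.ungapped, scoring,
            query_id=query.sample_id, subject_accession=rec.accession,
            subject_species=rec.species, strand=strand))
    hits.sort(key=lambda h: (-h.score, -h.pct_identity, h.subject_accession))
    return hits[:k]


def build_candidate_db(top_hit_species: str, db: ReferenceDB,
                       n_min: int = 2, n_max: int = 8,
                       seed: int = 0) -> ReferenceDB:
    """Candidate reference set: the top hit's entire genus, subsampled.

    Every species keyed to the top hit's genus is retained (including
    open-nomenclature entries); species with more than ``n_min`` records
    are subsampled uniformly at random to between ``n_min`` and ``n_max``
    records. Deterministic for a given seed.
    """
    if not (1 <= n_min <= n_max):
        raise ValueError("need 1 <= n_min <= n_max")
    genus = db.genus_of(top_hit_species)
    rng = np.random.default_rng(seed)
    chosen = []
    for species in sorted(db.taxonomy[genus]):
        recs = sorted(db.records_for_species(species), key=lambda r: r.accession)
        if len(recs) <= n_min:
            chosen.extend(recs)
            continue
        n_keep = min(int(rng.integers(n_min, n_max + 1)), len(recs))
        idx = rng.choice(len(recs), size=n_keep, replace=False)
        chosen.extend(recs[i] for i in sorted(idx))
    return ReferenceDB(chosen)


def _semiglobal_aligner(scoring) -> Align.PairwiseAligner:
    a = _make_aligner(scoring)
    a.mode = "global"
    a.end_gap_score = 0  # free end gaps: the query may cover part of the ref
    return a


def thread_query_onto_alignment(query: ConsensusRecord, db: ReferenceDB,
                                scoring=None) -> str:
    """Map a query into the reference alignment's coordinate system.

    The query is aligned globally (free end gaps) to its best-scoring
    ungapped reference, then projected through that reference's gap pattern.
    Columns the query does not cover are filled with '?'; query insertions
    relative to the reference cannot be represented and are dropped. A
    projection covering fewer than 100 columns triggers a warning.
    """
    scoring = scoring or DEFAULT_SCORING
    hits = search_top_hits(query, db, k=1, scoring=scoring)
    best = hits[0]
    ref = next(r for r in db.records if r.accession == best.subject_accession)
    qseq = query.sequence.upper()
    if best.strand == "-":
        qseq = str(Seq(qseq).reverse_complement())

    aligner = _semiglobal_aligner(scoring)
    if set(qseq + ref.ungapped) - set("ACGT"):
        aligner.substitution_matrix = _ambiguity_matrix(scoring)
    aln = next(iter(aligner.align(ref.ungapped, qseq)))
    row_ref, row_q = str(aln[0]), str(aln[1])

    # per ungapped-reference position, the query character aligned to it
    per_ref_pos = []
    for a, b in zip(row_ref, row_q):
        if a != "-":
            per_ref_pos.append(b if b != "-" else None)
    # trim the free-end-gap flanks: leading/trailing unaligned positions are
    # uncovered, interior deletions are real gaps relative to the reference
    first = next((i for i, c in enumerate(per_ref_pos) if c is not None), None)
    last = next((i for i in range(len(per_ref_pos) - 1, -1, -1)
                 if per_ref_pos[i] is not None), None)

    out = []
    ref_pos = 0
    covered = 0
    for col in ref.aligned_seq:
        if col in "-?":
            # a reference gap column: inside the covered span it stays a gap,
            # outside it is simply uncovered
            inside = first is not None and first < ref_pos <= (last if last is not None else -1)
            out.append("-" if inside else "?")
            continue
        c = per_ref_pos[ref_pos]
        if c is None:
            out.append("-" if first is not None and first <= ref_pos <= last else "?")
        else:
            out.append(c)
            covered += 1
        ref_pos += 1
    if covered < 100:
        warnings.warn(
            f"query {query.sample_id!r} covers only {covered} alignment columns")
    return "".join(out)
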