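"""Sequence and annotation I/O, composition and ORF utilities.

Coordinates follow the convention of organelle-genome tables: external
coordinates are 1-based inclusive; every internal computation uses 0-based
half-open offsets.  Circular genomes are handled by virtual doubling capped
at a single wrap, so a feature may cross the origin at most once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")


class SeqioError(ValueError):
    """Malformed input (FASTA/GFF parse problems, bad coordinates, alphabet)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a frame-0 nucleotide sequence with the standard genetic code.

    Plant mitochondria use the standard (NCBI table 1) code.
    """
    return str(Seq(seq).translate(table=1))


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with a circularity flag."""

    id: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Extract ``[start..end]`` (1-based inclusive).

        On circular sequences a span with ``start > end`` wraps through the
        origin; at most one wrap is allowed.
        """
        n = len(self.seq)
        if not (1 <= start <= n and 1 <= end <= n):
            raise SeqioError(
                f"span [{start}..{end}] out of bounds for {self.id!r} (length {n})"
            )
        if start <= end:
            return self.seq[start - 1 : end]
        if not self.circular:
            raise SeqioError(
                f"span [{start}..{end}] wraps the origin but {self.id!r} is linear"
            )
        return self.seq[start - 1 :] + self.seq[:end]


@dataclass
class GeneAnnotation:
    """A typed gene model with exon spans on a genome.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted in
    transcription order along the forward strand.  A wrap-around exon on a
    circular genome is written with ``start > end``.
    """

    gene_id: str
    feature_type: str  # mRNA | tRNA | rRNA | pseudogene
    strand: str  # '+' | '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    copy_index: int = 1

    FEATURE_TYPES = ("mRNA", "tRNA", "rRNA", "pseudogene")

    def __post_init__(self) -> None:
        if self.feature_type not in self.FEATURE_TYPES:
            raise SeqioError(f"unknown feature type {self.feature_type!r}")
        if self.strand not in "+-":
            raise SeqioError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise SeqioError(f"gene {self.gene_id!r} has no exons")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def span(self) -> tuple[int, int]:
        """Outermost (start, end) over all exons (ignores wrap-around)."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def length(self, genome_length: int | None = None) -> int:
        total = 0
        for s, e in self.exons:
            if s <= e:
                total += e - s + 1
            else:
                if genome_length is None:
                    raise SeqioError("wrap-around exon needs genome_length")
                total += (genome_length - s + 1) + e
        return total


@dataclass(frozen=True)
class CompositionReport:
    counts: dict[str, int]
    fractions: dict[str, float]
    gc: float
    length: int


class OrfSpan(NamedTuple):
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    strand: str
    frame: int  # 0..2, offset within the strand-local sequence
    length: int  # nucleotides including the stop codon


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _clean_sequence(raw: str, rec_id: str, n_mask: bool) -> str:
    seq = raw.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        if n_mask:
            seq = re.sub(f"[^{''.join(sorted(VALID_BASES))}]", "N", seq)
        else:
            raise SeqioError(
                f"record {rec_id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
    return seq


def read_fasta(path, circular: bool = False, n_mask: bool = False) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased on load.  Characters outside A/C/G/T/N are
    rejected, or replaced by N when ``n_mask`` is set.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(rec.id, _clean_sequence(str(rec.seq), rec.id, n_mask), circular)
        )
    if not records:
        raise SeqioError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write (id, sequence) pairs as FASTQ with a constant quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# GFF3 / TSV annotation interchange
# ---------------------------------------------------------------------------

_GFF_TYPE = {"mRNA": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "pseudogene"}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}


def write_gff3(annotations: Sequence[GeneAnnotation], seq_id: str, path) -> None:
    """Write annotations as GFF3, one row per exon.

    Wrap-around exons (start > end on a circular genome) are encoded with
    their literal coordinates plus an ``is_circular=true`` attribute, the
    convention used by several organelle annotation tools.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            uid = f"{ann.gene_id}.{ann.copy_index}"
            for i, (s, e) in enumerate(ann.exons, start=1):
                attrs = f"ID={uid}.exon{i};Parent={uid};gene={ann.gene_id};copy={ann.copy_index}"
                if s > e:
                    attrs += ";is_circular=true"
                fh.write(
                    "\t".join(
                        [
                            seq_id,
                            "mitokit",
                            _GFF_TYPE[ann.feature_type],
                            str(s),
                            str(e),
                            ".",
                            ann.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gff3(path) -> list[GeneAnnotation]:
    genes: dict[str, GeneAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise SeqioError(f"malformed GFF3 line {lineno}: expected 9 columns")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype not in _GFF_TYPE_REV:
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gene = attr.get("gene", attr.get("ID", f"gene{lineno}"))
            copy = int(attr.get("copy", 1))
            uid = f"{gene}.{copy}"
            exon = (int(start), int(end))
            if uid not in genes:
                genes[uid] = GeneAnnotation(gene, _GFF_TYPE_REV[ftype], strand, [exon], copy)
            else:
                genes[uid].exons.append(exon)
    return list(genes.values())


# ---------------------------------------------------------------------------
# Composition / CDS / ORFs
# ---------------------------------------------------------------------------


def base_composition(rec: SequenceRecord) -> CompositionReport:
    """Exact base counts and fractions; GC = (G+C) / (A+C+G+T).

    N bases are excluded from the denominator.  An all-N (or empty) sequence
    has no defined composition and raises.
    """
    counts = {b: rec.seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise SeqioError(f"composition undefined for {rec.id!r}: no A/C/G/T bases")
    fractions = {b: c / total for b, c in counts.items()}
    gc = (counts["G"] + counts["C"]) / total
    return CompositionReport(counts=counts, fractions=fractions, gc=gc, length=len(rec.seq))


def extract_cds(genome: SequenceRecord, ann: GeneAnnotation) -> str:
    """Concatenate a gene's exons in transcription order.

    Exons are given on the forward strand; minus-strand genes are
    reverse-complemented after concatenation (exon list is stored in forward
    order, i.e. transcription order for ``+`` and reverse for ``-``).
    """
    if ann.feature_type != "mRNA":
        raise SeqioError(f"extract_cds expects an mRNA feature, got {ann.feature_type}")
    parts = [genome.slice(s, e) for s, e in ann.exons]
    cds = "".join(parts)
    if ann.strand == "-":
        cds = revcomp(cds)
    return cds


def find_orfs(rec: SequenceRecord, min_len: int = 102) -> list[OrfSpan]:
    """Find complete ORFs (ATG .. in-frame stop) on both strands.

    One ORF is reported per stop codon and frame: it runs from the first
    in-frame ATG after the previous in-frame stop to the stop codon
    (inclusive).  ``min_len`` counts the stop codon and must be a multiple
    of 3; the default keeps ORFs of at least 34 codons.  Coordinates are
    1-based inclusive on the forward strand.
    """
    if min_len % 3 != 0:
        raise SeqioError("min_len must be a multiple of 3")
    n = len(rec.seq)
    orfs: list[OrfSpan] = []
    for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
        for frame in range(3):
            start_codon: int | None = None  # 0-based offset of current candidate ATG
            for pos in range(frame, n - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start_codon is not None:
                        length = pos + 3 - start_codon
                        if length >= min_len:
                            if strand == "+":
                                s, e = start_codon + 1, pos + 3
                            else:
                                s, e = n - (pos + 3) + 1, n - start_codon
                            orfs.append(OrfSpan(s, e, strand, frame, length))
                    start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    orfs.sort()
    return orfs


# ---------------------------------------------------------------------------
# Annotation transfer by homology
# ---------------------------------------------------------------------------


def transfer_annotation(
    target: SequenceRecord,
    reference_genes: Sequence[SequenceRecord],
    min_identity: float = 0.7,
    min_coverage: float = 0.7,
    feature_type: str = "mRNA",
    k: int = 9,
) -> list[GeneAnnotation]:
    """Map reference gene sequences onto a genome by local alignment.

    Each reference gene is aligned with the shared seed-and-extend aligner;
    hits with identity and reference coverage at or above the cut-offs become
    single-exon annotations.  Overlapping calls are resolved by score
    (best-scoring call wins; lower-scoring calls overlapping it are dropped).
    """
    from mitokit.align import KmerIndex, local_align

    if not reference_genes:
        raise SeqioError("reference gene set is empty")
    index = KmerIndex.build(target, k=k)
    calls: list[tuple[float, GeneAnnotation]] = []
    for gene in reference_genes:
        hits = local_align(gene.seq, index, min_score=max(2 * k, 20))
        for hit in hits:
            coverage = (hit.q_span[1] - hit.q_span[0] + 1) / len(gene.seq)
            if hit.identity >= min_identity and coverage >= min_coverage:
                ann = GeneAnnotation(
                    gene_id=gene.id,
                    feature_type=feature_type,
                    strand=hit.strand,
                    exons=[hit.t_span],
                )
                calls.append((hit.score, ann))
    calls.sort(key=lambda x: -x[0])
    kept: list[GeneAnnotation] = []
    for _, ann in calls:
        s, e = ann.span()
        overlap = any(
            not (e < k_ann.span()[0] or s > k_ann.span()[1]) for k_ann in kept
        )
        if not overlap:
            kept.append(ann)
    # re-number copies of the same gene
    by_gene: dict[str, int] = {}
    kept.sort(key=lambda a: a.span())
    for ann in kept:
        by_gene[ann.gene_id] = by_gene.get(ann.gene_id, 0) + 1
        ann.copy_index = by_gene[ann.gene_id]
    return kept
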