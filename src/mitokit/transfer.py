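"""Mitochondrion-plastid homologous-fragment detection (MTPT analysis).

Plastid-derived sequences residing in a mitochondrial genome are detected as
local alignments between the two organelle genomes with identity >= 70% and
E-value <= 1e-5, the conventional thresholds for this analysis.  Fragments
are annotated with any overlapping genes on either genome and summarized
(count, total/longest/shortest length, merged genome coverage).  The module
also emits raw cross-genome match sets suitable for dot-plot rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from mitokit.align import KmerIndex, local_align
from mitokit.seqio import GeneAnnotation, SequenceRecord


@dataclass(frozen=True)
class HomologFragment:
    identity: float  # percent, 0-100
    length: int  # aligned length, bp
    mismatches: int
    gap_opens: int
    q_span: tuple[int, int]  # plastid (query) coordinates, ascending
    s_span: tuple[int, int]  # mitochondrial (subject) coordinates, ascending
    strand: str
    evalue: float
    genes_cp: tuple[str, ...] = ()
    genes_mt: tuple[str, ...] = ()


@dataclass(frozen=True)
class TransferSummary:
    count: int
    total_bp: int
    longest: int
    shortest: int
    coverage_query: float | None = None  # merged fraction of the cp genome
    coverage_subject: float | None = None
    empty: bool = False


def find_homologous_fragments(
    cp: SequenceRecord,
    mt: SequenceRecord,
    evalue: float = 1e-5,
    min_identity: float = 70.0,
    k: int = 11,
    min_score: int = 25,
) -> list[HomologFragment]:
    """Homologous fragments between a plastid (query) and mito (subject) genome.

    Both orientations are searched; hits are filtered by E-value and percent
    identity and sorted by length descending.
    """
    if not cp.seq or not mt.seq:
        raise ValueError("both genomes must be non-empty")
    index = KmerIndex.build(mt, k=k)
    hits = local_align(cp.seq, index, min_score=min_score, query_id=cp.id)
    fragments = []
    for h in hits:
        if h.evalue > evalue or 100.0 * h.identity < min_identity:
            continue
        fragments.append(
            HomologFragment(
                identity=round(100.0 * h.identity, 3),
                length=h.aligned_length,
                mismatches=h.mismatches,
                gap_opens=h.gap_opens,
                q_span=h.q_span,
                s_span=h.t_span,
                strand=h.strand,
                evalue=h.evalue,
            )
        )
    fragments.sort(key=lambda f: (-f.length, f.q_span))
    return fragments


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return not (a[1] < b[0] or b[1] < a[0])


def assign_genes_to_fragments(
    fragments: Sequence[HomologFragment],
    cp_annotations: Sequence[GeneAnnotation] = (),
    mt_annotations: Sequence[GeneAnnotation] = (),
) -> list[HomologFragment]:
    """List every annotation overlapping a fragment span by >= 1 bp.

    Partial gene overlaps count: transferred fragments frequently carry only
    part of a gene.
    """
    out = []
    for f in fragments:
        genes_cp = tuple(
            a.gene_id
            for a in cp_annotations
            if any(_spans_overlap(f.q_span, (s, e)) for s, e in a.exons if s <= e)
        )
        genes_mt = tuple(
            a.gene_id
            for a in mt_annotations
            if any(_spans_overlap(f.s_span, (s, e)) for s, e in a.exons if s <= e)
        )
        out.append(
            HomologFragment(
                identity=f.identity,
                length=f.length,
                mismatches=f.mismatches,
                gap_opens=f.gap_opens,
                q_span=f.q_span,
                s_span=f.s_span,
                strand=f.strand,
                evalue=f.evalue,
                genes_cp=genes_cp,
                genes_mt=genes_mt,
            )
        )
    return out


def merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent 1-based inclusive spans."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def fragment_summary(
    fragments: Sequence[HomologFragment],
    cp_length: int | None = None,
    mt_length: int | None = None,
) -> TransferSummary:
    """Count, total/longest/shortest aligned length, merged coverage fractions.

    Total length is the plain sum of aligned lengths (near-duplicate hits
    mediated by inverted repeats are counted separately, as published tables
    do); coverage fractions merge overlapping spans first.
    """
    if not fragments:
        return TransferSummary(0, 0, 0, 0, empty=True)
    lengths = [f.length for f in fragments]
    cov_q = cov_s = None
    if cp_length:
        cov_q = sum(e - s + 1 for s, e in merge_spans([f.q_span for f in fragments])) / cp_length
    if mt_length:
        cov_s = sum(e - s + 1 for s, e in merge_spans([f.s_span for f in fragments])) / mt_length
    return TransferSummary(
        count=len(fragments),
        total_bp=sum(lengths),
        longest=max(lengths),
        shortest=min(lengths),
        coverage_query=cov_q,
        coverage_subject=cov_s,
    )


def cross_genome_matches(
    genome_a: SequenceRecord,
    genome_b: SequenceRecord,
    min_len: int = 100,
    k: int = 11,
) -> list[dict]:
    """All local matches >= ``min_len`` between two genomes, for dot-plots.

    Rows carry (a_start, a_end, b_start, b_end, strand, identity); inverted
    matches have descending b coordinates, the usual dot-plot convention.
    """
    if not genome_a.seq or not genome_b.seq:
        raise ValueError("both genomes must be non-empty")
    index = KmerIndex.build(genome_b, k=k)
    rows = []
    for h in local_align(genome_a.seq, index, min_score=min(min_len, 100), query_id=genome_a.id):
        if h.aligned_length < min_len:
            continue
        bs, be = h.t_span
        if h.strand == "-":
            bs, be = be, bs
        rows.append(
            {
                "a_start": h.q_span[0],
                "a_end": h.q_span[1],
                "b_start": bs,
                "b_end": be,
                "strand": h.strand,
                "identity": round(100.0 * h.identity, 3),
            }
        )
    rows.sort(key=lambda r: (r["a_start"], r["b_start"]))
    return rows


def fragments_to_tsv(fragments: Sequence[HomologFragment]) -> str:
    """Table-style TSV: identity, length, mismatches, gaps, spans, genes."""
    lines = [
        "identity\tlength\tmismatches\tgap_opens\tq_start\tq_end\ts_start\ts_end\tgenes_cp\tgenes_mt"
    ]
    for f in fragments:
        lines.append(
            f"{f.identity}\t{f.length}\t{f.mismatches}\t{f.gap_opens}"
            f"\t{f.q_span[0]}\t{f.q_span[1]}\t{f.s_span[0]}\t{f.s_span[1]}"
            f"\t{';'.join(f.genes_cp)}\t{';'.join(f.genes_mt)}"
        )
    return "\n".join(lines) + "\n"
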