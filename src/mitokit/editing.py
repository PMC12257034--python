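"""C-to-U RNA-editing site calling and hydropathy-effect classification.

Plant mitochondrial transcripts undergo cytidine-to-uridine editing.  Sites
are called from RNA reads aligned to the coding sequences: a pileup position
whose reference base is C and whose T fraction reaches the calling thresholds
becomes a candidate site.  Each site is annotated with its codon context and
the amino-acid change, and classified by the hydropathy transition of the
residues before and after editing.

The hydropathy dichotomy used here assigns
``{R, K, D, E, N, Q, H, S, T, Y, C, G}`` to the hydrophilic class and
``{A, V, L, I, P, F, M, W}`` to the hydrophobic class, with stop ('*') as
its own outcome; this follows the sign of the Kyte-Doolittle scale with
glycine and cysteine grouped as hydrophilic, the grouping standard in
organelle RNA-editing reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from mitokit.align import KmerIndex, local_align, pileup
from mitokit.codons import CODON_TO_AA
from mitokit.seqio import SequenceRecord

HYDROPHILIC = frozenset("RKDENQHSTYCG")
HYDROPHOBIC = frozenset("AVLIPFMW")

CATEGORIES = (
    "hydrophilic-hydrophilic",
    "hydrophilic-hydrophobic",
    "hydrophilic-stop",
    "hydrophobic-hydrophilic",
    "hydrophobic-hydrophobic",
    "hydrophobic-stop",
)


class EditingError(ValueError):
    pass


@dataclass(frozen=True)
class EditingSite:
    gene_id: str
    cds_position: int  # 1-based position in the CDS
    codon_index: int  # 1-based codon number
    codon_position: int  # 1, 2 or 3
    ref_codon: str
    edited_codon: str
    aa_before: str
    aa_after: str  # '*' for stop gain
    depth: int
    edit_fraction: float
    category: str
    start_gain: bool = False  # ACG -> ATG at codon 1
    stop_gain: bool = False


def classify_hydropathy_transition(aa_before: str, aa_after: str) -> str:
    """Category of an amino-acid change under the hydropathy dichotomy."""

    def side(aa: str) -> str:
        if aa == "*":
            return "stop"
        if aa in HYDROPHILIC:
            return "hydrophilic"
        if aa in HYDROPHOBIC:
            return "hydrophobic"
        raise EditingError(f"unknown amino-acid symbol {aa!r}")

    before = side(aa_before)
    if before == "stop":
        raise EditingError("editing cannot start from a stop codon")
    return f"{before}-{side(aa_after)}"


def annotate_editing_effect(
    gene_id: str,
    cds: str,
    cds_position: int,
    depth: int = 0,
    edit_fraction: float = 1.0,
    mode: str = "C2U",
) -> EditingSite:
    """Attach codon context and amino-acid effect to a raw site call."""
    if not 1 <= cds_position <= len(cds):
        raise EditingError(f"position {cds_position} outside CDS of length {len(cds)}")
    codon_index = (cds_position - 1) // 3 + 1
    codon_position = (cds_position - 1) % 3 + 1
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    if len(ref_codon) < 3:
        raise EditingError(f"position {cds_position} falls in an incomplete terminal codon")
    if mode == "C2U" and ref_codon[codon_position - 1] != "C":
        raise EditingError(
            f"reference base at CDS position {cds_position} is "
            f"{ref_codon[codon_position - 1]}, not C"
        )
    edited = ref_codon[: codon_position - 1] + "T" + ref_codon[codon_position:]
    aa_before = CODON_TO_AA[ref_codon]
    aa_after = CODON_TO_AA[edited]
    return EditingSite(
        gene_id=gene_id,
        cds_position=cds_position,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        edited_codon=edited,
        aa_before=aa_before,
        aa_after=aa_after,
        depth=depth,
        edit_fraction=edit_fraction,
        category=classify_hydropathy_transition(aa_before, aa_after),
        start_gain=(codon_index == 1 and ref_codon == "ACG" and edited == "ATG"),
        stop_gain=(aa_before != "*" and aa_after == "*"),
    )


def call_editing_sites(
    rna_reads: Sequence[tuple[str, str]],
    cds_set: Mapping[str, str],
    min_depth: int = 5,
    min_fraction: float = 0.1,
    mode: str = "C2U",
    k: int = 11,
) -> list[EditingSite]:
    """Call candidate editing sites from RNA reads aligned to CDS sequences.

    Reads are aligned to each CDS with the shared aligner; at every pileup
    column with reference C (in ``"C2U"`` mode) and depth >= ``min_depth``,
    a site is called when T-count / depth >= ``min_fraction``.  In mode
    ``"any"`` the reference-C restriction is lifted and the most frequent
    non-reference base defines the edit.
    """
    if mode not in ("C2U", "any"):
        raise EditingError(f"unknown mode {mode!r}")
    targets = [SequenceRecord(gene, cds) for gene, cds in cds_set.items()]
    targets = [t for t in targets if len(t.seq) >= k]
    if not targets:
        return []
    index = KmerIndex.build(targets, k=k)
    all_hits = []
    for rid, seq in rna_reads:
        hits = local_align(seq, index, min_score=min(len(seq) // 2, 30), query_id=rid)
        if hits:
            all_hits.append(hits[0])  # best placement only
    sites: list[EditingSite] = []
    for target in targets:
        hits = [h for h in all_hits if h.target_id == target.id]
        if not hits:
            continue
        for col in pileup(hits, target):
            if col.depth < min_depth:
                continue
            if mode == "C2U":
                if col.ref_base != "C":
                    continue
                alt_count = col.counts["T"]
            else:
                alts = {b: c for b, c in col.counts.items() if b != col.ref_base and b != "-"}
                alt_base = max(alts, key=lambda b: (alts[b], b))
                alt_count = alts[alt_base]
            fraction = alt_count / col.depth
            if fraction >= min_fraction and alt_count > 0:
                sites.append(
                    annotate_editing_effect(
                        target.id,
                        target.seq,
                        col.position,
                        depth=col.depth,
                        edit_fraction=fraction,
                        mode=mode,
                    )
                )
    sites.sort(key=lambda s: (s.gene_id, s.cds_position))
    return sites


def editing_summary(
    sites: Iterable[EditingSite] | Iterable[tuple[str, str, int]],
) -> dict:
    """Category and codon-transition breakdown of editing sites.

    Accepts either :class:`EditingSite` objects or pre-counted
    ``(ref_codon, edited_codon, count)`` rows (the form in which published
    editing tables are transcribed).  Returns per-category counts and
    percentages (2 d.p.), the per-codon-transition breakdown, and per-gene
    site counts where gene information is available.
    """
    transition_counts: dict[tuple[str, str], int] = {}
    gene_counts: dict[str, int] = {}
    for item in sites:
        if isinstance(item, EditingSite):
            key = (item.ref_codon, item.edited_codon)
            transition_counts[key] = transition_counts.get(key, 0) + 1
            gene_counts[item.gene_id] = gene_counts.get(item.gene_id, 0) + 1
        else:
            ref, edited, count = item
            key = (ref.upper(), edited.upper())
            transition_counts[key] = transition_counts.get(key, 0) + count
    if not transition_counts:
        raise EditingError("no editing sites to summarize")
    category_counts = {cat: 0 for cat in CATEGORIES}
    transitions = []
    for (ref, edited), count in sorted(transition_counts.items()):
        aa_before = CODON_TO_AA[ref]
        aa_after = CODON_TO_AA[edited]
        cat = classify_hydropathy_transition(aa_before, aa_after)
        category_counts[cat] += count
        transitions.append(
            {
                "ref_codon": ref,
                "edited_codon": edited,
                "aa_before": aa_before,
                "aa_after": aa_after,
                "category": cat,
                "count": count,
            }
        )
    total = sum(category_counts.values())
    categories = {
        cat: {"count": c, "percent": round(100.0 * c / total, 2)}
        for cat, c in category_counts.items()
    }
    return {
        "total": total,
        "categories": categories,
        "transitions": transitions,
        "per_gene": dict(sorted(gene_counts.items())),
    }
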