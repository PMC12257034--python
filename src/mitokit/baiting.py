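"""Iterative mitochondrial-read extraction (baiting).

Long reads are first screened against a panel of conserved mitochondrial
core genes: any read with a core-gene alignment longer than 50 bp is a
candidate, and the best candidates (many distinct genes hit, high summed
gene coverage) seed the recruited set.  Recruitment then iterates: every
unrecruited read is aligned to the current recruited set and added when it
shares an overlap alignment longer than the overlap threshold (1 kb by
default) at >= 85% identity, until a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from mitokit.align import KmerIndex, local_align
from mitokit.seqio import SequenceRecord


@dataclass
class SeedSet:
    read_ids: list[str]
    per_read: dict[str, dict]  # read id -> {n_genes, coverage}
    iteration: int = 0


@dataclass
class BaitingResult:
    recruited: list[str]
    iterations: int
    per_iteration_counts: list[int]
    converged: bool
    gene_coverage: dict[str, float] = field(default_factory=dict)


def select_seed_reads(
    reads: Sequence[tuple[str, str]],
    core_genes: Sequence[SequenceRecord],
    min_hit_length: int = 50,
    seed_fraction: float = 0.2,
    k: int = 11,
) -> SeedSet:
    """Screen reads against core genes and pick the best as seeds.

    Candidates have at least one core-gene alignment strictly longer than
    ``min_hit_length``.  Reads hitting >= 2 distinct core genes are always
    seeds; otherwise the top ``seed_fraction`` of candidates by summed gene
    coverage is retained.
    """
    if not core_genes:
        raise ValueError("core gene set is empty")
    index = KmerIndex.build(list(core_genes), k=k)
    gene_lengths = {g.id: len(g.seq) for g in core_genes}
    candidates: dict[str, dict] = {}
    for rid, seq in reads:
        hits = [
            h
            for h in local_align(seq, index, min_score=25, query_id=rid)
            if h.aligned_length > min_hit_length
        ]
        if not hits:
            continue
        genes = {h.target_id for h in hits}
        coverage = sum(
            (h.t_span[1] - h.t_span[0] + 1) / gene_lengths[h.target_id] for h in hits
        )
        candidates[rid] = {"n_genes": len(genes), "coverage": coverage}
    if not candidates:
        warnings.warn("no candidate reads hit any core gene", stacklevel=2)
        return SeedSet(read_ids=[], per_read={})
    multi = [rid for rid, c in candidates.items() if c["n_genes"] >= 2]
    if multi:
        seeds = multi
    else:
        ranked = sorted(
            candidates, key=lambda r: (-candidates[r]["coverage"], r)
        )
        seeds = ranked[: max(1, int(round(seed_fraction * len(ranked))))]
    return SeedSet(read_ids=sorted(seeds), per_read=candidates)


def recruit_reads_iterative(
    reads: Sequence[tuple[str, str]],
    seeds: SeedSet,
    min_overlap: int = 1000,
    min_identity: float = 0.85,
    max_iter: int = 20,
    k: int = 11,
) -> BaitingResult:
    """Grow the recruited read set by overlap alignment until a fixed point.

    Each round indexes the recruited reads and aligns every unrecruited read
    against them; a read joins when it has an alignment longer than
    ``min_overlap`` at identity >= ``min_identity``.  The recruited set grows
    monotonically, so the loop halts (or is cut at ``max_iter`` with a
    convergence flag).
    """
    if not seeds.read_ids:
        raise ValueError("seed set is empty")
    read_map = dict(reads)
    recruited: set[str] = set(seeds.read_ids)
    counts: list[int] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        pool = [rid for rid, _ in reads if rid not in recruited]
        if not pool:
            converged = True
            break
        targets = [SequenceRecord(rid, read_map[rid]) for rid in sorted(recruited)]
        index = KmerIndex.build(targets, k=k)
        newly: list[str] = []
        for rid in pool:
            hits = local_align(
                read_map[rid], index, min_score=int(min_overlap * 0.5), query_id=rid
            )
            for h in hits:
                if h.aligned_length > min_overlap and h.identity >= min_identity:
                    newly.append(rid)
                    break
        counts.append(len(newly))
        if not newly:
            converged = True
            break
        recruited.update(newly)
    return BaitingResult(
        recruited=sorted(recruited),
        iterations=iteration,
        per_iteration_counts=counts,
        converged=converged,
    )
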