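"""Repeat landscapes of a genome: SSRs, tandem repeats, dispersed repeats.

Three detectors with the thresholds conventional for plant organelle
genomes:

* :func:`find_ssrs` — perfect microsatellites with MISA-style class minima
  (unit length 1-6, minimum repeat numbers 10/5/4/3/3/3 by default);
* :func:`find_tandem_repeats` — approximate tandem arrays up to 2 kb period,
  reported with period, fractional copy number and percent match against the
  array consensus (match +2, mismatch -7, indel -7, minimum score 50);
* :func:`find_dispersed_repeats` — pairs of similar loci (direct or
  inverted) found by genome self-comparison, at least 30 bp and
  E-value <= 1e-5, with tandem/SSR loci excluded.

All reported coordinates are 1-based inclusive.  Scans run on the linear
sequence; origin-crossing repeats of a circular genome are not merged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mitokit.align import KmerIndex, local_align
from mitokit.seqio import SequenceRecord

DEFAULT_MIN_REPEATS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


class RepeatError(ValueError):
    pass


@dataclass(frozen=True)
class SSRRecord:
    motif: str  # unit string as found on the forward strand
    unit_length: int
    repeat_count: int
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    copy_number: float
    percent_match: float  # 0-100, locus vs consensus
    consensus: str
    start: int
    end: int
    score: int


@dataclass(frozen=True)
class DispersedRepeat:
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    kind: str  # 'direct' | 'inverted'
    length: int
    identity: float
    evalue: float


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_ssrs(
    seq: str | SequenceRecord,
    min_repeats: Mapping[int, int] = DEFAULT_MIN_REPEATS,
) -> list[SSRRecord]:
    """Perfect SSRs: maximal exact tandem runs of a primitive 1-6 bp unit.

    A run is reported once, at the unit length of its primitive period, with
    the motif as it reads from the run start.  Trailing partial units are not
    counted (``end - start + 1 == unit_length * repeat_count``).
    Interruptions terminate a run.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.seq
    if set(min_repeats) != {1, 2, 3, 4, 5, 6}:
        raise RepeatError("min_repeats must cover unit lengths 1-6")
    n = len(seq)
    records: list[SSRRecord] = []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for u in range(1, 7):
        if n < 2 * u:
            continue
        eq = arr[: n - u] == arr[u:]
        # maximal True runs in eq: positions j with seq[j] == seq[j+u]
        boundaries = np.flatnonzero(np.diff(eq.view(np.int8), prepend=0, append=0))
        # boundaries come in (run_start, run_end) pairs
        for a, b in zip(boundaries[::2], boundaries[1::2]):
            region_len = (b - a) + u  # tandem region seq[a : b + u]
            count = region_len // u
            if count < min_repeats[u]:
                continue
            motif = seq[a : a + u]
            if not _is_primitive(motif):
                continue
            records.append(
                SSRRecord(
                    motif=motif,
                    unit_length=u,
                    repeat_count=int(count),
                    start=int(a) + 1,
                    end=int(a) + u * int(count),
                )
            )
    records.sort(key=lambda r: (r.start, r.unit_length))
    return records


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------


def _consensus_and_matches(seq: str, start: int, end: int, period: int) -> tuple[str, int]:
    """Majority-vote consensus unit of seq[start:end] and matches to its tiling."""
    locus = np.frombuffer(seq[start:end].encode(), dtype=np.uint8)
    n = len(locus)
    rows = -(-n // period)
    mat = np.full((rows, period), 0, dtype=np.uint8)
    mat.ravel()[:n] = locus
    valid = np.zeros((rows, period), dtype=bool)
    valid.ravel()[:n] = True
    # per-column counts for each base; ties broken towards the smaller letter
    best_count = np.zeros(period, dtype=np.int32)
    consensus = np.zeros(period, dtype=np.uint8)
    for b in b"ACGT":
        cnt = ((mat == b) & valid).sum(axis=0)
        better = cnt > best_count
        best_count[better] = cnt[better]
        consensus[better] = b
    matches = int(((mat == consensus[None, :]) & valid).sum())
    return consensus.tobytes().decode(), matches


def find_tandem_repeats(
    seq: str | SequenceRecord,
    match: int = 2,
    mismatch: int = 7,
    indel: int = 7,
    min_score: int = 50,
    max_period: int = 2000,
    min_copy: float = 1.9,
    min_percent_match: float = 80.0,
    k: int = 7,
) -> list[TandemRepeat]:
    """Approximate tandem arrays detected by k-mer self-distance voting.

    Candidate periods come from pairs of identical k-mers at distance
    d <= ``max_period``; each candidate locus is extended along the period-d
    self-match with an x-drop criterion (+match / -mismatch), reduced to its
    primitive period, scored against the majority-vote consensus
    (substitution-only wrap-around model: ``score = match*m - mismatch*x``),
    and reported when score >= ``min_score``, copy number >= ``min_copy`` and
    percent match >= ``min_percent_match``.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.seq
    n = len(seq)
    if min(match, mismatch, indel, min_score, max_period) <= 0:
        raise RepeatError("tandem-repeat parameters must be positive")
    # vote collection: consecutive occurrences of the same k-mer
    kmers: dict[str, int] = {}
    votes: set[tuple[int, int]] = set()  # (pos of first occurrence, distance)
    last_pos: dict[str, int] = {}
    for i in range(max(0, n - k + 1)):
        kmer = seq[i : i + k]
        if kmer in last_pos:
            d = i - last_pos[kmer]
            if d <= max_period:
                votes.add((last_pos[kmer], d))
        last_pos[kmer] = i
    reported: list[TandemRepeat] = []
    covered: list[tuple[int, int, int]] = []  # (start0, end0, period)
    xdrop = 3 * mismatch
    for pos, d in sorted(votes, key=lambda v: (v[1], v[0])):
        if any(s <= pos and pos + d <= e for s, e, _ in covered):
            continue
        # extend the period-d self-match around pos with x-drop
        a = pos
        best = score = 0
        best_a = a
        j = pos
        while j - 1 >= 0 and j - 1 + d < n:
            j -= 1
            score += match if seq[j] == seq[j + d] else -mismatch
            if score > best:
                best, best_a = score, j
            elif best - score > xdrop:
                break
        a = best_a
        b = pos
        best = score = 0
        best_b = b
        j = pos
        while j + d < n:
            score += match if seq[j] == seq[j + d] else -mismatch
            j += 1
            if score > best:
                best, best_b = score, j
            elif best - score > xdrop:
                break
        b = best_b  # self-match holds (approximately) on [a, b); locus is [a, b + d)
        end = b + d
        locus_len = end - a
        # a locus whose primitive period is p < d votes at distance p itself
        # (consecutive k-mer occurrences), so only the voted period is tested;
        # the covered-locus check above keeps the smallest period's report
        period = d
        if locus_len / period < min_copy:
            continue
        consensus, m = _consensus_and_matches(seq, a, end, period)
        pm = 100.0 * m / locus_len
        sc = match * m - mismatch * (locus_len - m)
        if pm < min_percent_match or sc < min_score:
            continue
        copy = round(locus_len / period, 1)
        reported.append(
            TandemRepeat(
                period=period,
                copy_number=copy,
                percent_match=round(pm),
                consensus=consensus,
                start=a + 1,
                end=end,
                score=sc,
            )
        )
        covered.append((a, end, period))
    reported.sort(key=lambda r: (r.start, r.period))
    # drop loci nested inside an already-reported locus with the same period
    out: list[TandemRepeat] = []
    for r in reported:
        if any(
            o.start <= r.start and r.end <= o.end and o is not r and o.period <= r.period
            for o in reported
        ):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------


def find_dispersed_repeats(
    seq: str | SequenceRecord,
    min_len: int = 30,
    word_size: int = 7,
    evalue: float = 1e-5,
    exclude: Sequence[tuple[int, int]] | None = None,
    min_score: int | None = None,
) -> list[DispersedRepeat]:
    """Dispersed (interspersed) repeats by genome self-comparison.

    The genome is aligned against itself with the shared seed-and-extend
    aligner at the given word size.  The trivial self-diagonal is excluded,
    symmetric duplicates (a,b)/(b,a) are collapsed, and hits overlapping
    ``exclude`` spans (detected tandem/SSR loci) are removed.  Hits must be
    at least ``min_len`` long with E-value <= ``evalue``.
    """
    rec = seq if isinstance(seq, SequenceRecord) else SequenceRecord("self", seq)
    if len(rec.seq) <= min_len:
        raise RepeatError("sequence shorter than min_len")
    index = KmerIndex.build(rec, k=word_size, occ_cap=400)
    hits = local_align(
        rec.seq,
        index,
        min_score=min_score if min_score is not None else max(min_len // 2, 2 * word_size),
        min_diag_sep=min_len,  # near-diagonal self-similarity is tandem, not dispersed
        query_id=rec.id,
    )
    exclude = list(exclude or [])
    results: list[DispersedRepeat] = []
    seen: set[tuple[tuple[int, int], tuple[int, int], str]] = set()
    for hit in hits:
        if hit.aligned_length < min_len or hit.evalue > evalue:
            continue
        a, b = hit.q_span, hit.t_span
        kind = "direct" if hit.strand == "+" else "inverted"
        if a == b:  # self-hit (palindrome centre or residual diagonal)
            continue
        key = (min(a, b), max(a, b), kind)
        if key in seen:
            continue
        if any(_overlaps(a, x) or _overlaps(b, x) for x in exclude):
            continue
        seen.add(key)
        results.append(
            DispersedRepeat(
                span_a=key[0],
                span_b=key[1],
                kind=kind,
                length=hit.aligned_length,
                identity=hit.identity,
                evalue=hit.evalue,
            )
        )
    results.sort(key=lambda r: (-r.length, r.span_a))
    return results


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return not (a[1] < b[0] or b[1] < a[0])


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

_CLASS_NAMES = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer", 5: "pentamer", 6: "hexamer"}


def ssr_class_summary(class_counts: Mapping[int, int]) -> dict:
    """Per-unit-length SSR counts and percentage shares (1 d.p.)."""
    total = sum(class_counts.values())
    classes = {}
    for u in range(1, 7):
        count = class_counts.get(u, 0)
        share = round(100.0 * count / total, 1) if total else None
        classes[_CLASS_NAMES[u]] = {"count": count, "percent": share}
    return {"total": total, "classes": classes}


def repeat_summary(
    ssrs: Sequence[SSRRecord] | Mapping[int, int],
    tandems: Sequence[TandemRepeat] = (),
    dispersed: Sequence[DispersedRepeat] = (),
    genome_length: int | None = None,
) -> dict:
    """Aggregate repeat statistics for one genome.

    ``ssrs`` may be SSR records or precomputed per-unit-length counts.
    Percentages are ``None`` (undefined) when there are no SSRs.
    """
    if isinstance(ssrs, Mapping):
        class_counts = dict(ssrs)
    else:
        class_counts = {u: 0 for u in range(1, 7)}
        for r in ssrs:
            class_counts[r.unit_length] += 1
    summary = {"ssr": ssr_class_summary(class_counts)}
    if tandems:
        lengths = [t.end - t.start + 1 for t in tandems]
        summary["tandem"] = {
            "count": len(tandems),
            "period_range": (min(t.period for t in tandems), max(t.period for t in tandems)),
            "length_range": (min(lengths), max(lengths)),
            "min_percent_match": min(t.percent_match for t in tandems),
        }
    else:
        summary["tandem"] = {"count": 0}
    if dispersed:
        total_bp = sum(d.length for d in dispersed)
        summary["dispersed"] = {
            "count": len(dispersed),
            "total_bp": total_bp,
            "genome_fraction": (total_bp / genome_length) if genome_length else None,
        }
    else:
        summary["dispersed"] = {"count": 0, "total_bp": 0, "genome_fraction": 0.0}
    return summary
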