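"""Synthetic organelle-genome data with machine-readable ground truth.

Generates every input the analysis pipeline consumes — a circular
mitochondrial genome with planted SSRs, tandem arrays and dispersed repeat
pairs; annotated protein-coding genes with controllable codon usage; long
DNA reads with nuclear/plastid contaminants; RNA reads carrying planted
C-to-U edits; diverged homolog sets with planned synonymous/nonsynonymous
distances; and a plastid genome containing degraded copies of mitochondrial
segments — together with a :class:`SyntheticTruth` object recording the
exact coordinates and parameters of everything planted.

Design notes: the background sequence is drawn i.i.d. per base at the GC
target and rejection-resampled wherever it would trip the repeat detectors,
giving a clean negative background; reads are error-free by default with an
optional uniform substitution rate; divergence is planted codon-aware so the
expected corrected distances match the plan.  Default parameters model a
deeply sequenced plant mitogenome study scaled to a 50 kb genome: GC 0.458,
30x long-read depth, 30% contaminant reads, 20x RNA depth with editing
fraction 0.8, and homolog divergence Ks = 0.2 / Ka = 0.02.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from mitokit.codons import ALL_CODONS, CODON_TO_AA
from mitokit.evolution import is_transition
from mitokit.repeats import DEFAULT_MIN_REPEATS, find_ssrs, find_tandem_repeats
from mitokit.seqio import GeneAnnotation, SequenceRecord, revcomp

BASES = "ACGT"
_NONSTOP = [c for c in ALL_CODONS if CODON_TO_AA[c] != "*"]
_STOPS = [c for c in ALL_CODONS if CODON_TO_AA[c] == "*"]


class GeneratorError(ValueError):
    pass


class PlanningError(GeneratorError):
    """Planted feature spans overlap."""


class CapacityError(GeneratorError):
    """Genome too short for the requested plan."""


@dataclass
class ReadProfile:
    mean_length: int = 3000
    sd_length: int = 800
    min_length: int = 500
    depth: float = 30.0
    contaminant_fraction: float = 0.3
    error_rate: float = 0.0
    rna_depth: int = 20
    rna_read_length: int = 150
    edit_fraction: float = 0.8


@dataclass
class GeneratorConfig:
    """Everything the generator needs; identical config => identical bytes."""

    seed: int = 0
    genome_length: int = 50_000
    gc_target: float = 0.458
    n_genes: int = 8
    gene_length: int = 1200  # CDS length incl. stop, multiple of 3
    # (motif, copies, start) — start is 1-based or None for auto-placement
    ssr_plan: list[tuple[str, int, int | None]] | None = None
    # (unit, copies, start)
    tandem_plan: list[tuple[str, int, int | None]] | None = None
    # (length, kind) with kind in {'direct', 'inverted'}
    dispersed_plan: list[tuple[int, str]] | None = None
    # (gene index, codon index, codon position 1-3); None -> auto plan
    edit_plan: list[tuple[int, int, int]] | None = None
    # (length bp, identity fraction)
    transfer_plan: list[tuple[int, float]] | None = None
    read_profile: ReadProfile = field(default_factory=ReadProfile)
    # species -> (Ks, Ka)
    divergence_plan: dict[str, tuple[float, float]] | None = None
    codon_weights: dict[str, float] | None = None
    edits_per_gene: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise GeneratorError("gc_target must be in (0, 1)")
        if self.gene_length % 3 != 0:
            raise GeneratorError("gene_length must be a multiple of 3")
        if self.ssr_plan is None:
            self.ssr_plan = [
                ("A", 12, None), ("T", 11, None), ("C", 10, None),
                ("AG", 6, None), ("AT", 7, None), ("CT", 5, None), ("TA", 5, None),
                ("AAG", 5, None), ("TCT", 4, None),
                ("AAAG", 4, None), ("TTCT", 3, None),
                ("ATAAG", 3, None), ("AATAGA", 3, None),
            ]
        if self.tandem_plan is None:
            self.tandem_plan = [
                ("GGTTCGATTCCA", 3, None),       # period 12
                ("CCGGCGCAGGCTCAGCAGGAGGGG", 3, None),  # period 24
                ("AATATCATGATCGGGTCGACCAGGCCAGATCATGAGTGA", 2, None),  # period 39
                ("GCTTGAACCGTGTCATCGTACGTTGAAAACCCGTGCCATCGTACGTTGGTTCAAGTCTGGTAATGGCGGAAGA", 2, None),  # period 73
            ]
        if self.dispersed_plan is None:
            self.dispersed_plan = [(200, "direct"), (150, "inverted"), (80, "direct")]
        if self.transfer_plan is None:
            self.transfer_plan = [(500, 1.0), (300, 0.9), (200, 0.85), (100, 0.85)]
        if self.divergence_plan is None:
            self.divergence_plan = {"relative_1": (0.2, 0.02)}


@dataclass
class SyntheticTruth:
    """Ground truth for one generated dataset; JSON round-trippable."""

    genome_id: str = "synthetic_mito"
    genome_length: int = 0
    ssrs: list[dict] = field(default_factory=list)
    tandems: list[dict] = field(default_factory=list)
    dispersed: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    edits: list[dict] = field(default_factory=list)
    transfers: list[dict] = field(default_factory=list)
    read_origins: dict[str, str] = field(default_factory=dict)
    divergence: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        return cls(**json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def to_bed(self) -> str:
        """BED (0-based half-open) of all planted genome features."""
        rows = []
        for kind, items in (
            ("ssr", self.ssrs), ("tandem", self.tandems),
            ("gene", self.genes), ("transfer_source", self.transfers),
        ):
            for it in items:
                name = it.get("motif") or it.get("unit") or it.get("gene_id") or kind
                start = it.get("start") or it.get("mt_start")
                end = it.get("end") or it.get("mt_end")
                rows.append(f"{self.genome_id}\t{start - 1}\t{end}\t{kind}:{name}")
        for it in self.dispersed:
            for a, b in (("start_a", "end_a"), ("start_b", "end_b")):
                rows.append(
                    f"{self.genome_id}\t{it[a] - 1}\t{it[b]}\tdispersed:{it['kind']}"
                )
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# background sequence
# ---------------------------------------------------------------------------


def _base_probs(gc: float) -> list[float]:
    return [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=_base_probs(gc))


def _repeat_hits(seq: str) -> list[tuple[int, int]]:
    """0-based spans of any SSR or tandem hit at detection thresholds."""
    spans = [(r.start - 1, r.end) for r in find_ssrs(seq, DEFAULT_MIN_REPEATS)]
    spans += [(t.start - 1, t.end) for t in find_tandem_repeats(seq)]
    return spans


def clean_background(rng: np.random.Generator, length: int, gc: float) -> str:
    """i.i.d. background, rejection-resampled until repeat-free.

    Windows around any SSR/tandem hit are redrawn; the loop converges fast
    because such hits are rare in i.i.d. sequence at these thresholds.
    """
    arr = _random_bases(rng, length, gc)
    for _ in range(100):
        spans = _repeat_hits(arr.tobytes().decode())
        if not spans:
            return arr.tobytes().decode()
        for s, e in spans:
            a, b = max(0, s - 5), min(length, e + 5)
            arr[a:b] = _random_bases(rng, b - a, gc)
    raise GeneratorError("background cleanup did not converge")


# ---------------------------------------------------------------------------
# gene / CDS construction
# ---------------------------------------------------------------------------


def _draw_codons(
    rng: np.random.Generator,
    n: int,
    weights: dict[str, float] | None,
) -> list[str]:
    codons = _NONSTOP
    if weights:
        w = np.array([weights.get(c, 1.0) for c in codons], dtype=float)
    else:
        w = np.ones(len(codons))
    w = w / w.sum()
    idx = rng.choice(len(codons), size=n, p=w)
    return [codons[i] for i in idx]


def make_cds(
    rng: np.random.Generator,
    length: int,
    edits: Sequence[tuple[int, int]] = (),
    codon_weights: dict[str, float] | None = None,
) -> str:
    """Random in-frame CDS: ATG, non-stop body, terminal stop.

    ``edits`` are (codon_index, codon_position) pairs (1-based) that must
    carry a C so a C-to-U edit can be planted there; the codon drawn for such
    a position is constrained to have C there and to stay non-stop after the
    edit.  The CDS is regenerated codon-wise wherever it would trip the SSR
    detector, keeping gene interiors repeat-free.
    """
    n_codons = length // 3
    if n_codons < 4:
        raise GeneratorError("CDS too short")
    body = _draw_codons(rng, n_codons - 2, codon_weights)
    for codon_index, codon_position in edits:
        if not 2 <= codon_index <= n_codons - 1:
            raise GeneratorError(
                f"edit codon index {codon_index} outside CDS body (2..{n_codons - 1})"
            )
        pool = [
            c
            for c in _NONSTOP
            if c[codon_position - 1] == "C"
            and CODON_TO_AA[c[: codon_position - 1] + "T" + c[codon_position:]] != "*"
        ]
        body[codon_index - 2] = pool[int(rng.integers(len(pool)))]
    stop = _STOPS[int(rng.integers(len(_STOPS)))]
    planted = {ci for ci, _ in edits}
    for _ in range(50):
        cds = "ATG" + "".join(body) + stop
        hits = find_ssrs(cds, DEFAULT_MIN_REPEATS)
        if not hits:
            return cds
        for h in hits:
            lo, hi = (h.start - 1) // 3, (h.end - 1) // 3
            for ci in range(max(lo, 1), min(hi + 1, n_codons - 1)):
                if (ci + 1) not in planted:  # don't disturb edit codons
                    body[ci - 1] = _draw_codons(rng, 1, codon_weights)[0]
    raise GeneratorError("CDS cleanup did not converge")


# ---------------------------------------------------------------------------
# feature placement
# ---------------------------------------------------------------------------


class _Placer:
    """Non-overlapping placement of feature spans with a safety margin."""

    def __init__(self, rng: np.random.Generator, genome_length: int, margin: int = 30):
        self.rng = rng
        self.n = genome_length
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []  # 0-based half-open

    def _free(self, start: int, end: int) -> bool:
        m = self.margin
        return 0 <= start and end <= self.n and not any(
            not (end + m <= s or e + m <= start) for s, e in self.occupied
        )

    def reserve(self, start: int, length: int) -> int:
        """Reserve [start, start+length); raises on overlap."""
        if not self._free(start, start + length):
            raise PlanningError(
                f"planned span {start + 1}..{start + length} overlaps another feature"
            )
        self.occupied.append((start, start + length))
        return start

    def place(self, length: int) -> int:
        for _ in range(500):
            start = int(self.rng.integers(self.margin, self.n - length - self.margin))
            if self._free(start, start + length):
                self.occupied.append((start, start + length))
                return start
        raise CapacityError(
            f"genome of {self.n} bp cannot accommodate a {length} bp feature"
        )


def _guard_base(rng: np.random.Generator, *avoid: str) -> str:
    pool = [b for b in BASES if b not in avoid]
    return pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------


def generate_genome(
    config: GeneratorConfig,
) -> tuple[SequenceRecord, list[GeneAnnotation], SyntheticTruth]:
    """Build the synthetic circular mitogenome, annotations and truth."""
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    features_bp = (
        config.n_genes * config.gene_length
        + sum(len(m) * c for m, c, _ in config.ssr_plan)
        + sum(len(u) * c for u, c, _ in config.tandem_plan)
        + 2 * sum(length for length, _ in config.dispersed_plan)
    )
    if features_bp > 0.7 * n:
        raise CapacityError(
            f"plan needs {features_bp} bp of features; genome of {n} bp is too short"
        )
    background = clean_background(rng, n, config.gc_target)
    seq = list(background)
    placer = _Placer(rng, n)
    truth = SyntheticTruth(genome_length=n)

    # --- edits grouped per gene (auto plan if none given)
    if config.edit_plan is None:
        edit_plan = []
        n_codons = config.gene_length // 3
        lo = config.read_profile.rna_read_length // 3 + 2
        hi = n_codons - config.read_profile.rna_read_length // 3 - 2
        for g in range(min(5, config.n_genes)):
            span = max(config.edits_per_gene, hi - lo)
            picks = rng.choice(span, size=config.edits_per_gene, replace=False)
            for j in sorted(int(p) for p in picks):
                codon_position = 1 + int(rng.integers(2))  # positions 1 or 2
                edit_plan.append((g, lo + j, codon_position))
    else:
        edit_plan = list(config.edit_plan)
    edits_by_gene: dict[int, list[tuple[int, int]]] = {}
    for g, ci, cp in edit_plan:
        edits_by_gene.setdefault(g, []).append((ci, cp))
    for g, lst in edits_by_gene.items():
        if len({ci for ci, _ in lst}) != len(lst):
            raise PlanningError(f"two edits in the same codon of gene {g}")

    # --- genes
    annotations: list[GeneAnnotation] = []
    for g in range(config.n_genes):
        cds = make_cds(
            rng, config.gene_length, edits_by_gene.get(g, ()), config.codon_weights
        )
        start0 = placer.place(len(cds))
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cds if strand == "+" else revcomp(cds)
        seq[start0 : start0 + len(cds)] = genomic
        gene_id = f"gene{g + 1:02d}"
        annotations.append(
            GeneAnnotation(gene_id, "mRNA", strand, [(start0 + 1, start0 + len(cds))])
        )
        truth.genes.append(
            {
                "gene_id": gene_id,
                "start": start0 + 1,
                "end": start0 + len(cds),
                "strand": strand,
                "cds": cds,
            }
        )
        for ci, cp in sorted(edits_by_gene.get(g, ())):
            cds_pos = (ci - 1) * 3 + cp
            truth.edits.append(
                {
                    "gene_id": gene_id,
                    "codon_index": ci,
                    "codon_position": cp,
                    "cds_position": cds_pos,
                    "ref_codon": cds[(ci - 1) * 3 : ci * 3],
                }
            )

    # --- SSRs
    for motif, copies, start1 in config.ssr_plan:
        motif = motif.upper()
        run = motif * copies
        start0 = placer.reserve(start1 - 1, len(run)) if start1 else placer.place(len(run))
        seq[start0 : start0 + len(run)] = run
        u = len(motif)
        if start0 > 0:
            seq[start0 - 1] = _guard_base(rng, motif[-1])
        if start0 + len(run) < n:
            seq[start0 + len(run)] = _guard_base(rng, motif[0])
        truth.ssrs.append(
            {
                "motif": motif,
                "unit_length": u,
                "copies": copies,
                "start": start0 + 1,
                "end": start0 + len(run),
            }
        )

    # --- tandem repeats
    for unit, copies, start1 in config.tandem_plan:
        unit = unit.upper()
        run = unit * copies
        start0 = placer.reserve(start1 - 1, len(run)) if start1 else placer.place(len(run))
        seq[start0 : start0 + len(run)] = run
        if start0 > 0:
            seq[start0 - 1] = _guard_base(rng, unit[-1])
        if start0 + len(run) < n:
            seq[start0 + len(run)] = _guard_base(rng, unit[0])
        truth.tandems.append(
            {
                "unit": unit,
                "period": len(unit),
                "copies": copies,
                "start": start0 + 1,
                "end": start0 + len(run),
            }
        )

    # --- dispersed repeat pairs (copy a clean background stretch)
    for length, kind in config.dispersed_plan:
        if kind not in ("direct", "inverted"):
            raise GeneratorError(f"dispersed repeat kind must be direct/inverted, not {kind!r}")
        a0 = placer.place(length)
        b0 = placer.place(length)
        segment = "".join(seq[a0 : a0 + length])
        copy = segment if kind == "direct" else revcomp(segment)
        seq[b0 : b0 + length] = copy
        (a0, b0) = sorted((a0, b0))
        truth.dispersed.append(
            {
                "kind": kind,
                "length": length,
                "start_a": a0 + 1,
                "end_a": a0 + length,
                "start_b": b0 + 1,
                "end_b": b0 + length,
            }
        )

    genome = SequenceRecord("synthetic_mito", "".join(seq), circular=True)
    truth.genome_id = genome.id
    _verify_planted(genome, truth)
    return genome, annotations, truth


def _verify_planted(genome: SequenceRecord, truth: SyntheticTruth) -> None:
    """Every planted feature must be recoverable verbatim at its coordinates."""
    for s in truth.ssrs:
        if genome.slice(s["start"], s["end"]) != s["motif"] * s["copies"]:
            raise GeneratorError(f"planted SSR corrupted at {s['start']}")
    for t in truth.tandems:
        if genome.slice(t["start"], t["end"]) != t["unit"] * t["copies"]:
            raise GeneratorError(f"planted tandem repeat corrupted at {t['start']}")
    for d in truth.dispersed:
        a = genome.slice(d["start_a"], d["end_a"])
        b = genome.slice(d["start_b"], d["end_b"])
        if (d["kind"] == "direct" and a != b) or (
            d["kind"] == "inverted" and a != revcomp(b)
        ):
            raise GeneratorError("planted dispersed repeat corrupted")


def generate_reads(
    genome: SequenceRecord,
    annotations: Sequence[GeneAnnotation],
    truth: SyntheticTruth,
    profile: ReadProfile | None = None,
    seed: int = 1,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Long DNA reads (with contaminants) and RNA reads (with planted edits).

    DNA reads are sampled uniformly from the circular genome (wrap-around
    allowed) to the target depth; contaminant reads are i.i.d. random
    sequence labelled nuclear or plastid.  RNA reads tile each coding
    sequence to the RNA depth, carrying C->T at each planted edit site with
    probability ``edit_fraction`` per read.  Read origins go into
    ``truth.read_origins``.
    """
    if not genome.seq:
        raise GeneratorError("empty genome")
    profile = profile or ReadProfile()
    if profile.depth <= 0:
        raise GeneratorError("depth must be positive")
    rng = np.random.default_rng(seed)
    n = len(genome.seq)
    doubled = genome.seq + genome.seq  # circular sampling
    n_mito = int(math.ceil(profile.depth * n / profile.mean_length))
    dna_reads: list[tuple[str, str]] = []
    for i in range(n_mito):
        length = int(
            np.clip(
                rng.normal(profile.mean_length, profile.sd_length),
                profile.min_length,
                n,
            )
        )
        start = int(rng.integers(n))
        read = doubled[start : start + length]
        if profile.error_rate > 0:
            read = _add_errors(rng, read, profile.error_rate)
        rid = f"mito_read_{i + 1:05d}"
        dna_reads.append((rid, read))
        truth.read_origins[rid] = "mito"
    cf = profile.contaminant_fraction
    if not 0 <= cf < 1:
        raise GeneratorError("contaminant fraction must be in [0, 1)")
    n_cont = int(round(n_mito * cf / (1 - cf))) if cf > 0 else 0
    for i in range(n_cont):
        length = int(
            np.clip(
                rng.normal(profile.mean_length, profile.sd_length),
                profile.min_length,
                n,
            )
        )
        origin = "nuclear" if i % 2 == 0 else "plastid"
        read = _random_bases(rng, length, 0.36 if origin == "nuclear" else 0.38)
        rid = f"{origin}_read_{i + 1:05d}"
        dna_reads.append((rid, read.tobytes().decode()))
        truth.read_origins[rid] = origin
    # RNA reads over each CDS
    rna_reads: list[tuple[str, str]] = []
    edits_by_gene: dict[str, list[dict]] = {}
    for e in truth.edits:
        edits_by_gene.setdefault(e["gene_id"], []).append(e)
    gene_cds = {g["gene_id"]: g["cds"] for g in truth.genes}
    rl = profile.rna_read_length
    for gene_id, cds in gene_cds.items():
        L = len(cds)
        read_len = min(rl, L)
        n_reads = int(math.ceil(profile.rna_depth * L / read_len))
        sites = [e["cds_position"] for e in edits_by_gene.get(gene_id, [])]
        for i in range(n_reads):
            start = int(rng.integers(L - read_len + 1)) if L > read_len else 0
            read = list(cds[start : start + read_len])
            for pos in sites:
                idx = pos - 1 - start
                if 0 <= idx < read_len and rng.random() < profile.edit_fraction:
                    read[idx] = "T"
            rid = f"rna_{gene_id}_{i + 1:04d}"
            rna_reads.append((rid, "".join(read)))
            truth.read_origins[rid] = f"rna:{gene_id}"
    return dna_reads, rna_reads


def _add_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    arr = list(read)
    for pos in np.flatnonzero(rng.random(len(arr)) < rate):
        arr[pos] = _guard_base(rng, arr[pos])
    return "".join(arr)


# ---------------------------------------------------------------------------
# homolog sets with planned divergence
# ---------------------------------------------------------------------------


def _per_alternative_rate(d: float) -> float:
    """Per-alternative substitution probability whose K2P-corrected distance
    equals ``d`` under uniform choice among the three alternatives
    (inverse Jukes-Cantor: u = (1 - exp(-4 d / 3)) / 4)."""
    return (1.0 - math.exp(-4.0 * d / 3.0)) / 4.0


def diverge_cds(
    rng: np.random.Generator, cds: str, ks: float, ka: float
) -> tuple[str, dict]:
    """Codon-aware mutated copy with expected Ks/Ka matching the plan.

    Every site considers its three alternative bases; synonymous
    alternatives (with respect to the current codon) are drawn with the
    synonymous per-alternative rate and nonsynonymous ones with the
    nonsynonymous rate.  Changes creating stop codons are skipped.  At most
    one substitution per site.  Realized synonymous/nonsynonymous
    substitution counts are returned alongside.
    """
    if len(cds) % 3 != 0:
        raise GeneratorError("CDS length must be a multiple of 3")
    for d, name in ((ks, "Ks"), (ka, "Ka")):
        if d < 0 or d > 0.75:
            raise GeneratorError(f"requested {name}={d} out of range [0, 0.75] (saturating)")
    u_s = _per_alternative_rate(ks)
    u_a = _per_alternative_rate(ka)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    n_syn = n_nonsyn = 0
    out: list[str] = []
    for codon in codons:
        aa = CODON_TO_AA[codon]
        if aa == "*":
            out.append(codon)
            continue
        current = codon
        for p in range(3):
            alts = [b for b in BASES if b != current[p]]
            probs = []
            for b in alts:
                cand = current[:p] + b + current[p + 1 :]
                if CODON_TO_AA[cand] == "*":
                    probs.append(0.0)
                elif CODON_TO_AA[cand] == CODON_TO_AA[current]:
                    probs.append(u_s)
                else:
                    probs.append(u_a)
            r = rng.random()
            acc = 0.0
            for b, pr in zip(alts, probs):
                acc += pr
                if r < acc:
                    cand = current[:p] + b + current[p + 1 :]
                    if CODON_TO_AA[cand] == CODON_TO_AA[current]:
                        n_syn += 1
                    else:
                        n_nonsyn += 1
                    current = cand
                    break
        out.append(current)
    realized = {
        "planned_ks": ks,
        "planned_ka": ka,
        "syn_substitutions": n_syn,
        "nonsyn_substitutions": n_nonsyn,
    }
    return "".join(out), realized


def generate_homolog_set(
    cds: str,
    divergence_plan: dict[str, tuple[float, float]],
    seed: int = 2,
) -> tuple[dict[str, str], dict[str, dict]]:
    """Diverged per-species copies of one CDS plus realized-truth records."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise GeneratorError("CDS length must be a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if any(CODON_TO_AA[c] == "*" for c in codons[:-1]):
        raise GeneratorError("CDS has internal stop codons")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    truth: dict[str, dict] = {}
    for species in sorted(divergence_plan):
        ks, ka = divergence_plan[species]
        mutated, realized = diverge_cds(rng, cds, ks, ka)
        out[species] = mutated
        truth[species] = realized
    return out, truth


# ---------------------------------------------------------------------------
# plastid genome with planted transfers
# ---------------------------------------------------------------------------


def generate_plastid_with_transfers(
    mito: SequenceRecord,
    transfer_plan: Sequence[tuple[int, float]],
    plastid_length: int = 30_000,
    gc_target: float = 0.38,
    seed: int = 3,
) -> tuple[SequenceRecord, list[dict]]:
    """Plastid genome containing degraded copies of mitochondrial segments.

    Each plan entry (length, identity) copies a random mitochondrial segment
    into the plastid background with substitutions at rate ``1 - identity``.
    Truth records both coordinate spans and the realized identity.
    """
    rng = np.random.default_rng(seed)
    for length, identity in transfer_plan:
        if length < 30:
            raise GeneratorError(f"transfer length {length} < 30 bp")
        if identity < 0.5 or identity > 1.0:
            raise GeneratorError(f"transfer identity {identity} out of range [0.5, 1]")
    background = _random_bases(rng, plastid_length, gc_target).tobytes().decode()
    seq = list(background)
    mt_placer = _Placer(rng, len(mito.seq))
    cp_placer = _Placer(rng, plastid_length)
    records: list[dict] = []
    for length, identity in transfer_plan:
        mt0 = mt_placer.place(length)
        segment = list(mito.seq[mt0 : mt0 + length])
        n_sub = 0
        for pos in np.flatnonzero(rng.random(length) < 1.0 - identity):
            segment[pos] = _guard_base(rng, segment[pos])
            n_sub += 1
        cp0 = cp_placer.place(length)
        seq[cp0 : cp0 + length] = segment
        records.append(
            {
                "length": length,
                "planned_identity": identity,
                "realized_identity": (length - n_sub) / length,
                "mismatches": n_sub,
                "mt_start": mt0 + 1,
                "mt_end": mt0 + length,
                "cp_start": cp0 + 1,
                "cp_end": cp0 + length,
            }
        )
    plastid = SequenceRecord("synthetic_plastid", "".join(seq), circular=True)
    return plastid, records
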