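"""Codon-level selection and diversity statistics.

Implements the LWL (Li-Wu-Luo) family of Ka/Ks estimators based on
0-, 2- and 4-fold degenerate site classes with Kimura two-parameter
corrections, plus nucleotide diversity (pi) and shared-CDS selection for
phylogenetic matrices.

Method outline
--------------
Sites of each codon are classified by degeneracy (number of the three
possible single-base changes that preserve the amino acid: 0 -> 0-fold,
3 -> 4-fold, otherwise 2-fold).  Site totals ``L0, L2, L4`` average the two
sequences.  For each differing codon pair, all minimal substitution pathways
are enumerated (pathways through stop codons are excluded unless all are);
each step is counted as a transition or transversion at the site class of
the changed position, split half-and-half between the two flanking codons'
classes.  Per class i, transition (A_i) and transversion (B_i) distances use
the Kimura two-parameter correction, K_i = A_i + B_i.

* LWL assumes transitions at 2-fold sites are synonymous and counts 1/3 of
  every 2-fold site as synonymous:
  ``Ks = (L2*A2 + L4*K4) / (L2/3 + L4)``,
  ``Ka = (L0*K0 + L2*B2) / (L0 + 2*L2/3)``.
* MLWL replaces 1/3 with ``kappa/(kappa+2)`` where kappa is the
  transition/transversion rate ratio estimated at 4-fold sites (the neutral
  proxy; falls back to all sites), and handles 2-fold sites whose synonymous
  changes are transversions (e.g. the third position of ATA/Ile or the first
  of AGA/Arg) by exchanging the roles of the A and B distances there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner

from mitokit.codons import ALL_CODONS, CODON_TO_AA

BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class EvolutionError(ValueError):
    pass


class SaturationError(EvolutionError):
    """Distances too large for the K2P correction; carries partial output."""

    def __init__(self, message: str, partial: dict):
        super().__init__(message)
        self.partial = partial


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def classify_site_degeneracy(codon: str, position: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position.

    The class counts how many of the three possible substitutions at that
    position preserve the amino acid: none -> 0-fold, all -> 4-fold,
    otherwise 2-fold (three-fold cases fold into the 2-fold class, the LWL
    convention).  Stop codons are flagged by raising: they carry no
    degeneracy classes and are excluded from site counts upstream.
    """
    codon = codon.upper()
    if position not in (1, 2, 3):
        raise EvolutionError("position must be 1, 2 or 3")
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        raise EvolutionError(f"invalid codon {codon!r}")
    if aa == "*":
        raise EvolutionError(f"stop codon {codon} has no degeneracy class")
    p = position - 1
    n_syn = 0
    for b in BASES:
        if b == codon[p]:
            continue
        alt = codon[:p] + b + codon[p + 1 :]
        if CODON_TO_AA[alt] == aa:
            n_syn += 1
    if n_syn == 0:
        return 0
    if n_syn == 3:
        return 4
    return 2


def _site_key(codon: str, position: int) -> str:
    """Fine-grained site class: '0', '4', '2n' or '2i'.

    A 2-fold site is 'inverse' ('2i') when none of its synonymous single
    changes is a transition — there, transversions play the synonymous role.
    """
    deg = classify_site_degeneracy(codon, position)
    if deg != 2:
        return str(deg)
    p = position - 1
    aa = CODON_TO_AA[codon]
    for b in BASES:
        if b == codon[p]:
            continue
        alt = codon[:p] + b + codon[p + 1 :]
        if CODON_TO_AA[alt] == aa and is_transition(codon[p], b):
            return "2n"
    return "2i"


@dataclass
class CodonAlignment:
    """Two CDS sequences aligned codon-wise, gap codon columns removed."""

    codons1: list[str]
    codons2: list[str]

    def __post_init__(self) -> None:
        if len(self.codons1) != len(self.codons2):
            raise EvolutionError("codon lists differ in length")

    def __len__(self) -> int:
        return len(self.codons1)


@dataclass(frozen=True)
class KaKsResult:
    gene_id: str
    method: str
    L0: float
    L2: float
    L4: float
    A: dict[str, float]  # per-class transition distances
    B: dict[str, float]  # per-class transversion distances
    Ka: float
    Ks: float
    kappa: float | None
    codons: int
    # raw fractional site and substitution counts per fine class
    # ('0', '2n', '2i', '4'): sites, transitions, transversions
    sites: dict[str, float] | None = None
    transitions: dict[str, float] | None = None
    transversions: dict[str, float] | None = None

    @property
    def ratio(self) -> float | None:
        if self.Ks > 0:
            return self.Ka / self.Ks
        return None


@dataclass(frozen=True)
class PiResult:
    gene_id: str
    n_sequences: int
    sites: float  # mean pairwise sites compared
    pi: float


def codon_align(cds1: str, cds2: str, gene_id: str = "gene") -> CodonAlignment:
    """Codon-aware pairwise alignment via protein-level global alignment.

    Proteins are aligned with identity scoring (match +1, mismatch 0, gap
    open -8, gap extend -1) and the alignment is back-threaded to codons;
    columns with a gap in either sequence are dropped.  Terminal stop codons
    are trimmed beforehand.
    """
    for name, cds in (("first", cds1), ("second", cds2)):
        if len(cds) % 3 != 0:
            raise EvolutionError(f"{name} CDS length not a multiple of 3")
    c1 = [cds1[i : i + 3].upper() for i in range(0, len(cds1), 3)]
    c2 = [cds2[i : i + 3].upper() for i in range(0, len(cds2), 3)]
    if c1 and CODON_TO_AA.get(c1[-1]) == "*":
        c1 = c1[:-1]
    if c2 and CODON_TO_AA.get(c2[-1]) == "*":
        c2 = c2[:-1]
    p1 = "".join(CODON_TO_AA.get(c, "X") for c in c1)
    p2 = "".join(CODON_TO_AA.get(c, "X") for c in c2)
    if p1 == p2 or len(p1) == len(p2):
        return CodonAlignment(c1, c2)
    aligner = PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-8,
        extend_gap_score=-1,
    )
    aln = aligner.align(p1, p2)[0]
    keep1: list[str] = []
    keep2: list[str] = []
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        keep1.extend(c1[s1:e1])
        keep2.extend(c2[s2:e2])
    return CodonAlignment(keep1, keep2)


def _pathway_substitutions(c1: str, c2: str) -> dict[tuple[str, str], float]:
    """Average transition/transversion counts per fine site class over all
    minimal substitution pathways between two codons.

    Returns counts keyed by (kind, class) with kind in {'s', 'v'}; each step
    is split 0.5/0.5 between the classes of the two codons flanking it.
    Pathways passing through a stop codon are excluded when any stop-free
    pathway exists.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    paths: list[tuple[bool, list[tuple[str, str, int]]]] = []
    for order in permutations(diff):
        cur = c1
        steps: list[tuple[str, str, int]] = []
        clean = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            steps.append((cur, nxt, p))
            if CODON_TO_AA[nxt] == "*":
                clean = False
            cur = nxt
        paths.append((clean, steps))
    usable = [steps for clean, steps in paths if clean] or [steps for _, steps in paths]
    weight = 1.0 / len(usable)
    counts: dict[tuple[str, str], float] = {}
    for steps in usable:
        for before, after, p in steps:
            kind = "s" if is_transition(before[p], after[p]) else "v"
            for flank in (before, after):
                if CODON_TO_AA[flank] == "*":
                    continue  # stop codons carry no site class
                key = (kind, _site_key(flank, p + 1))
                counts[key] = counts.get(key, 0.0) + 0.5 * weight
    return counts


def _k2p(P: float, Q: float) -> tuple[float, float]:
    """Kimura two-parameter transition (A) and transversion (B) distances."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("K2P saturation")
    A = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    B = 0.5 * math.log(1.0 / w2)
    return A, B


def compute_kaks(
    aln: CodonAlignment,
    method: str = "MLWL",
    gene_id: str = "gene",
) -> KaKsResult:
    """LWL or MLWL Ka/Ks on a gap-free codon alignment (>= 10 codons)."""
    if method not in ("LWL", "MLWL"):
        raise EvolutionError(f"unknown method {method!r}")
    pairs = [
        (a, b)
        for a, b in zip(aln.codons1, aln.codons2)
        if CODON_TO_AA.get(a, "*") != "*" and CODON_TO_AA.get(b, "*") != "*"
        and set(a + b) <= set(BASES)
    ]
    if len(pairs) < 10:
        raise EvolutionError(f"need >= 10 comparable gap-free codons, have {len(pairs)}")
    L: dict[str, float] = {"0": 0.0, "2n": 0.0, "2i": 0.0, "4": 0.0}
    S: dict[str, float] = dict(L)  # transitions per class
    V: dict[str, float] = dict(L)  # transversions per class
    for a, b in pairs:
        for pos in (1, 2, 3):
            L[_site_key(a, pos)] += 0.5
            L[_site_key(b, pos)] += 0.5
        if a != b:
            for (kind, cls), x in _pathway_substitutions(a, b).items():
                (S if kind == "s" else V)[cls] += x
    # per-class K2P distances (merged 2-fold for LWL, split for MLWL)
    def class_dist(l: float, s: float, v: float, cls: str) -> tuple[float, float]:
        if l == 0:
            return 0.0, 0.0
        try:
            return _k2p(s / l, v / l)
        except ValueError:
            raise SaturationError(
                f"saturated distances at {cls}-fold sites",
                {"L": L, "S": S, "V": V, "gene_id": gene_id},
            ) from None

    L2 = L["2n"] + L["2i"]
    A: dict[str, float] = {}
    B: dict[str, float] = {}
    A["0"], B["0"] = class_dist(L["0"], S["0"], V["0"], "0")
    A["4"], B["4"] = class_dist(L["4"], S["4"], V["4"], "4")
    K4 = A["4"] + B["4"]
    K0 = A["0"] + B["0"]
    if method == "LWL":
        A["2"], B["2"] = class_dist(L2, S["2n"] + S["2i"], V["2n"] + V["2i"], "2")
        ks_num = L2 * A["2"] + L["4"] * K4
        ks_den = L2 / 3.0 + L["4"]
        ka_num = L["0"] * K0 + L2 * B["2"]
        ka_den = L["0"] + 2.0 * L2 / 3.0
        kappa = None
    else:
        A["2n"], B["2n"] = class_dist(L["2n"], S["2n"], V["2n"], "2n")
        A["2i"], B["2i"] = class_dist(L["2i"], S["2i"], V["2i"], "2i")
        # kappa from 4-fold (neutral) sites; fall back to all sites
        if S["4"] + V["4"] > 0 and V["4"] > 0:
            kappa = 2.0 * S["4"] / V["4"]
        else:
            s_tot, v_tot = sum(S.values()), sum(V.values())
            kappa = (2.0 * s_tot / v_tot) if v_tot > 0 else 1.0
        rho = kappa / (kappa + 2.0)
        ks_num = L["2n"] * A["2n"] + L["2i"] * B["2i"] + L["4"] * K4
        ks_den = rho * L["2n"] + (1.0 - rho) * L["2i"] + L["4"]
        ka_num = L["0"] * K0 + L["2n"] * B["2n"] + L["2i"] * A["2i"]
        ka_den = L["0"] + (1.0 - rho) * L["2n"] + rho * L["2i"]
    Ks = ks_num / ks_den if ks_den > 0 else 0.0
    Ka = ka_num / ka_den if ka_den > 0 else 0.0
    return KaKsResult(
        gene_id=gene_id,
        method=method,
        L0=L["0"],
        L2=L2,
        L4=L["4"],
        A=A,
        B=B,
        Ka=Ka,
        Ks=Ks,
        kappa=kappa,
        codons=len(pairs),
        sites=dict(L),
        transitions=dict(S),
        transversions=dict(V),
    )


def kaks_from_cds(
    cds1: str, cds2: str, method: str = "MLWL", gene_id: str = "gene"
) -> KaKsResult:
    """Convenience wrapper: codon-align two CDS then compute Ka/Ks."""
    return compute_kaks(codon_align(cds1, cds2), method=method, gene_id=gene_id)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

_GAPLIKE = set("-N")


def nucleotide_diversity(
    sequences: Sequence[str], gene_id: str = "gene"
) -> PiResult:
    """Nucleotide diversity: average pairwise difference per site.

    ``pi = sum_{i<j} d_ij / C(n,2)`` with ``d_ij`` the proportion of
    differing positions among sites where both sequences have an unambiguous
    base (pairwise gap deletion).  Sequences must be aligned (equal length).
    """
    seqs = [s.upper() for s in sequences]
    n = len(seqs)
    if n < 2:
        raise EvolutionError("nucleotide diversity needs >= 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise EvolutionError("sequences must be aligned to equal length")
    total_d = 0.0
    total_sites = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            sites = diffs = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in _GAPLIKE or b in _GAPLIKE:
                    continue
                sites += 1
                if a != b:
                    diffs += 1
            if sites == 0:
                raise EvolutionError(f"no comparable sites between sequences {i} and {j}")
            total_d += diffs / sites
            total_sites += sites
            n_pairs += 1
    return PiResult(
        gene_id=gene_id,
        n_sequences=n,
        sites=total_sites / n_pairs,
        pi=total_d / n_pairs,
    )


def shared_cds_selection(
    presence: Mapping[str, Mapping[str, int]] | "object",
    threshold: float = 0.7,
) -> list[str]:
    """Genes present in at least ``ceil(threshold * n_species)`` species.

    ``presence`` is a gene -> {species: 0/1} mapping or a pandas DataFrame
    (genes as rows, species as columns, binary entries).  Returns the
    retained gene names sorted alphabetically.
    """
    try:  # accept a DataFrame without importing pandas eagerly
        rows = {gene: dict(presence.loc[gene]) for gene in presence.index}  # type: ignore[union-attr]
    except AttributeError:
        rows = {g: dict(sp) for g, sp in presence.items()}
    if not rows:
        raise EvolutionError("empty presence matrix")
    n_species = len(next(iter(rows.values())))
    if n_species == 0:
        raise EvolutionError("presence matrix has no species")
    needed = math.ceil(threshold * n_species)
    kept = [
        gene
        for gene, sp in rows.items()
        if sum(1 for v in sp.values() if v) >= needed
    ]
    return sorted(kept)


# full degeneracy table, occasionally useful for inspection/tests
DEGENERACY_TABLE = {
    codon: tuple(classify_site_degeneracy(codon, p) for p in (1, 2, 3))
    for codon in ALL_CODONS
    if CODON_TO_AA[codon] != "*"
}
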