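"""Codon counting, relative synonymous codon usage (RSCU) and bias summaries.

RSCU of a codon c encoding amino acid a is

    RSCU(c) = (n_c / N_a) * f_a

where ``n_c`` is the observed count of c, ``N_a`` the total count over all
synonymous codons of a, and ``f_a`` the family size (number of codon types
encoding a).  RSCU = 1 for every codon under uniform usage within its family.
The three stop codons are treated as one 3-codon family (reported as ``*``),
the convention of organelle codon-usage tables that list "Ter" among the
amino acids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from mitokit.seqio import translate

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]
CODON_TO_AA = {c: translate(c) for c in ALL_CODONS}  # stop -> '*'
AA_FAMILIES: dict[str, list[str]] = {}
for _c, _aa in CODON_TO_AA.items():
    AA_FAMILIES.setdefault(_aa, []).append(_c)
FAMILY_SIZE = {aa: len(cods) for aa, cods in AA_FAMILIES.items()}


class CodonError(ValueError):
    pass


@dataclass(frozen=True)
class CodonCounts:
    counts: dict[str, int]  # all 64 codons
    total: int
    include_stop: bool
    genetic_code: int = 1


@dataclass(frozen=True)
class RSCUEntry:
    codon: str
    amino_acid: str  # one-letter, '*' for stop
    family_size: int
    count: int
    rscu: float | None  # None when the family is unobserved (undefined, not 0)


def count_codons(
    cds_set: Iterable[str],
    include_stop: bool = True,
    deduplicate: bool = True,
) -> CodonCounts:
    """Frame-0 codon counts over a set of coding sequences.

    ``deduplicate`` drops exact duplicate sequences ("unique CDS"), so
    identical gene copies are counted once.  A CDS whose length is not a
    multiple of 3 is rejected; an internal stop codon triggers a warning but
    is counted as-is, since C-to-U editing may resolve it at the RNA level.
    """
    counts = {c: 0 for c in ALL_CODONS}
    seen: set[str] = set()
    total = 0
    for idx, cds in enumerate(cds_set):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise CodonError(f"CDS #{idx} length {len(cds)} is not a multiple of 3")
        if deduplicate:
            if cds in seen:
                continue
            seen.add(cds)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for j, codon in enumerate(codons):
            if CODON_TO_AA.get(codon) == "*" and j < len(codons) - 1:
                warnings.warn(
                    f"internal stop codon {codon} at codon {j + 1} of CDS #{idx}; "
                    "counted as-is (may be resolved by RNA editing)",
                    stacklevel=2,
                )
            if codon in counts:
                if CODON_TO_AA[codon] == "*" and not include_stop:
                    continue
                counts[codon] += 1
                total += 1
    return CodonCounts(counts=counts, total=total, include_stop=include_stop)


def compute_rscu(counts: CodonCounts) -> list[RSCUEntry]:
    """RSCU per codon; families with zero usage yield ``rscu=None``."""
    entries: list[RSCUEntry] = []
    for aa, family in sorted(AA_FAMILIES.items()):
        n_aa = sum(counts.counts[c] for c in family)
        for codon in family:
            if n_aa == 0:
                rscu = None
            else:
                rscu = (counts.counts[codon] / n_aa) * len(family)
            entries.append(
                RSCUEntry(
                    codon=codon,
                    amino_acid=aa,
                    family_size=len(family),
                    count=counts.counts[codon],
                    rscu=rscu,
                )
            )
    return entries


def rscu_bias_summary(entries: Sequence[RSCUEntry]) -> dict:
    """Third-position composition of preferred codons and amino-acid usage.

    Preferred codons are those with RSCU > 1.  The report partitions them by
    third-position base (A/U together, then G, then C, the usual statement of
    A/U-ending bias) and lists amino-acid usage counts.
    """
    preferred = [e for e in entries if e.rscu is not None and e.rscu > 1]
    n_pref = len(preferred)
    end_au = [e for e in preferred if e.codon[2] in "AT"]
    end_g = [e for e in preferred if e.codon[2] == "G"]
    end_c = [e for e in preferred if e.codon[2] == "C"]
    aa_counts: dict[str, int] = {}
    for e in entries:
        aa_counts[e.amino_acid] = aa_counts.get(e.amino_acid, 0) + e.count
    total = sum(aa_counts.values())
    ranked = sorted(aa_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "n_preferred": n_pref,
        "preferred_ending_AU": {
            "count": len(end_au),
            "percent": round(100.0 * len(end_au) / n_pref) if n_pref else None,
        },
        "preferred_ending_G": {
            "count": len(end_g),
            "percent": round(100.0 * len(end_g) / n_pref, 2) if n_pref else None,
        },
        "preferred_ending_C": {
            "count": len(end_c),
            "percent": round(100.0 * len(end_c) / n_pref, 2) if n_pref else None,
        },
        "amino_acid_usage": [
            {
                "amino_acid": aa,
                "count": c,
                "percent": round(100.0 * c / total, 2) if total else None,
            }
            for aa, c in ranked
        ],
    }


def check_start_stop(cds_set: Mapping[str, str] | Iterable[tuple[str, str]]) -> list[dict]:
    """First/last codon per gene; flags non-ATG starts as candidate edits.

    An ACG start is the classic signature of a start codon created by C-to-U
    editing at the second base (ACG -> AUG on the transcript).
    """
    items = cds_set.items() if isinstance(cds_set, Mapping) else cds_set
    rows = []
    for gene, cds in items:
        cds = cds.upper()
        if len(cds) < 6 or len(cds) % 3 != 0:
            raise CodonError(f"gene {gene!r}: CDS must be in frame with >= 2 codons")
        start, stop = cds[:3], cds[-3:]
        rows.append(
            {
                "gene": gene,
                "start_codon": start,
                "stop_codon": stop.replace("T", "U"),
                "canonical_start": start == "ATG",
                "editing_created_start": start == "ACG",
                "stop_is_terminator": CODON_TO_AA.get(stop) == "*",
            }
        )
    return rows


def rscu_table(entries: Sequence[RSCUEntry]) -> str:
    """TSV rendering (codon, amino acid, count, RSCU to 2 d.p.)."""
    lines = ["codon\tamino_acid\tcount\trscu"]
    for e in entries:
        rscu = "NA" if e.rscu is None else f"{e.rscu:.2f}"
        lines.append(f"{e.codon}\t{e.amino_acid}\t{e.count}\t{rscu}")
    return "\n".join(lines) + "\n"
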