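"""Site degeneracy, LWL/MLWL Ka/Ks, nucleotide diversity, shared-CDS picks."""

import itertools
import math
import random
import warnings
from fractions import Fraction

import numpy as np
import pytest

from mitokit.evolution import (
    EvolutionError,
    classify_site_degeneracy,
    codon_align,
    compute_kaks,
    kaks_from_cds,
    nucleotide_diversity,
    shared_cds_selection,
)
from mitokit.synthetic import generate_homolog_set, make_cds

BASES = "ACGT"
_TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _translate(codon):
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


class TestDegeneracy:
    @pytest.mark.parametrize(
        "codon,pos,expected",
        [("GGG", 3, 4), ("ATG", 1, 0), ("ATG", 3, 0), ("ATA", 3, 2), ("TTA", 1, 2)],
    )
    def test_known_sites(self, codon, pos, expected):
        assert classify_site_degeneracy(codon, pos) == expected

    def test_full_table_equals_single_change_enumeration(self):
        for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
            if _translate(codon) == "*":
                with pytest.raises(EvolutionError):
                    classify_site_degeneracy(codon, 1)
                continue
            for pos in (1, 2, 3):
                n_syn = sum(
                    _translate(codon[: pos - 1] + b + codon[pos:]) == _translate(codon)
                    for b in BASES
                    if b != codon[pos - 1]
                )
                expected = 0 if n_syn == 0 else (4 if n_syn == 3 else 2)
                assert classify_site_degeneracy(codon, pos) == expected


def _oracle_counts(c1, c2):
    """Independent pathway enumeration with exact rational arithmetic."""
    from mitokit.evolution import _site_key  # classification shared; counting independent

    diff = [p for p in range(3) if c1[p] != c2[p]]
    all_paths = []
    for order in itertools.permutations(diff):
        cur, steps, clean = c1, [], True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            steps.append((cur, nxt, p))
            if _translate(nxt) == "*":
                clean = False
            cur = nxt
        all_paths.append((clean, steps))
    usable = [s for ok, s in all_paths if ok] or [s for _, s in all_paths]
    S, V = {}, {}
    for steps in usable:
        for before, after, p in steps:
            kind = S if (before[p], after[p]) in _TS else V
            for flank in (before, after):
                if _translate(flank) == "*":
                    continue
                key = _site_key(flank, p + 1)
                kind[key] = kind.get(key, Fraction(0)) + Fraction(1, 2 * len(usable))
    return S, V


class TestComputeKaks:
    def test_identical_sequences(self):
        cds = make_cds(np.random.default_rng(0), 300)
        r = kaks_from_cds(cds, cds)
        assert r.Ka == 0.0 and r.Ks == 0.0 and r.ratio is None

    def test_single_fourfold_substitution_synonymous_only(self):
        rng = np.random.default_rng(1)
        cds = "ATG" + "GGA" * 100 + "TAA"
        mutated = cds[:35] + "G" + cds[36:]  # GGA -> GGG at one third position
        r = kaks_from_cds(cds, mutated)
        assert r.Ka == 0.0 and r.Ks > 0.0

    def test_site_and_substitution_counts_equal_oracle(self):
        rng = random.Random(2)
        stops = {"TAA", "TAG", "TGA"}
        for trial in range(60):
            n = rng.randrange(10, 31)
            c1 = [c for c in ("".join(rng.choice(BASES) for _ in range(3)) for _ in range(n))]
            c2 = []
            for c in c1:
                m = list(c)
                for p in range(3):
                    if rng.random() < 0.15:
                        m[p] = rng.choice(BASES)
                c2.append("".join(m))
            pairs = [
                (a, b) for a, b in zip(c1, c2) if a not in stops and b not in stops
            ]
            if len(pairs) < 10:
                continue
            aln = codon_align(
                "".join(a for a, _ in pairs), "".join(b for _, b in pairs)
            )
            try:
                r = compute_kaks(aln, method="LWL")
            except EvolutionError:
                continue
            S_exp, V_exp = {}, {}
            for a, b in pairs:
                if a == b:
                    continue
                S, V = _oracle_counts(a, b)
                for k, v in S.items():
                    S_exp[k] = S_exp.get(k, Fraction(0)) + v
                for k, v in V.items():
                    V_exp[k] = V_exp.get(k, Fraction(0)) + v
            for cls in ("0", "2n", "2i", "4"):
                assert r.transitions[cls] == pytest.approx(float(S_exp.get(cls, 0)), abs=1e-9)
                assert r.transversions[cls] == pytest.approx(float(V_exp.get(cls, 0)), abs=1e-9)

    def test_site_totals_average_three_per_codon(self):
        cds = make_cds(np.random.default_rng(3), 600)
        mutated, _ = generate_homolog_set(cds, {"s": (0.1, 0.01)}, seed=4)
        r = kaks_from_cds(cds, mutated["s"])
        assert r.L0 + r.L2 + r.L4 == pytest.approx(3 * r.codons)

    def test_planted_divergence_recovered_within_20_percent(self):
        cds = make_cds(np.random.default_rng(5), 9999)
        copies, _ = generate_homolog_set(cds, {"s": (0.2, 0.02)}, seed=6)
        r = kaks_from_cds(cds, copies["s"], method="MLWL")
        assert abs(r.Ks - 0.2) / 0.2 < 0.2
        assert abs(r.Ka - 0.02) / 0.02 < 0.2

    def test_symmetry(self):
        cds = make_cds(np.random.default_rng(7), 900)
        copies, _ = generate_homolog_set(cds, {"s": (0.15, 0.03)}, seed=8)
        fwd = kaks_from_cds(cds, copies["s"])
        rev = kaks_from_cds(copies["s"], cds)
        assert fwd.Ka == pytest.approx(rev.Ka, abs=1e-12)
        assert fwd.Ks == pytest.approx(rev.Ks, abs=1e-12)

    def test_mlwl_equals_lwl_without_special_sites_and_kappa_one(self):
        # codons whose 2-fold sites are all transition-synonymous; one
        # transition and two transversions keep the observed ratio at 1:2
        c1 = ["GAA", "TTT", "AAA", "GAT", "CAA", "TGT", "CAT", "AAG", "GAC", "TTC", "GAA", "AAA"]
        c2 = list(c1)
        c2[0] = "GAG"   # A->G transition (syn, 2-fold)
        c2[1] = "TTA"   # T->A transversion at pos 3 (Phe->Leu, nonsyn 2-fold)
        c2[2] = "AAT"   # A->T transversion at pos 3 (Lys->Asn, nonsyn 2-fold)
        from mitokit.evolution import CodonAlignment

        aln = CodonAlignment(c1, c2)
        lwl = compute_kaks(aln, method="LWL")
        mlwl = compute_kaks(aln, method="MLWL")
        assert lwl.sites["2i"] == 0
        assert mlwl.kappa == pytest.approx(1.0)
        assert mlwl.Ks == pytest.approx(lwl.Ks, abs=1e-12)
        assert mlwl.Ka == pytest.approx(lwl.Ka, abs=1e-12)

    def test_agreement_with_independent_lwl_implementation(self):
        # cross-check against Biopython's LWL85 estimator on a diverged pair
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        cds = make_cds(np.random.default_rng(9), 6000)
        copies, _ = generate_homolog_set(cds, {"s": (0.2, 0.02)}, seed=10)
        ours = kaks_from_cds(cds, copies["s"], method="LWL")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(
                CodonSeq(cds[:-3]), CodonSeq(copies["s"][: len(cds) - 3]), method="LWL85"
            )
        assert ours.Ka == pytest.approx(dn, rel=0.05, abs=0.002)
        assert ours.Ks == pytest.approx(ds, rel=0.08)

    def test_too_few_codons_rejected(self):
        with pytest.raises(EvolutionError):
            kaks_from_cds("ATGAAA", "ATGAAA")


class TestNucleotideDiversity:
    def test_identical_pair_zero(self):
        assert nucleotide_diversity(["ACGTACGT", "ACGTACGT"]).pi == 0.0

    def test_one_difference_in_100_sites(self):
        a = "A" * 100
        b = "A" * 50 + "C" + "A" * 49
        assert nucleotide_diversity([a, b]).pi == pytest.approx(0.01)

    def test_five_sequences_equal_hand_enumeration(self):
        rng = random.Random(11)
        seqs = []
        base = "".join(rng.choice(BASES) for _ in range(200))
        for _ in range(5):
            s = list(base)
            for _ in range(rng.randrange(0, 8)):
                s[rng.randrange(200)] = rng.choice(BASES)
            if rng.random() < 0.5:
                s[rng.randrange(200)] = "-"  # alignment gap
            seqs.append("".join(s))
        expected = Fraction(0)
        n_pairs = 0
        for i in range(5):
            for j in range(i + 1, 5):
                sites = diffs = 0
                for a, b in zip(seqs[i], seqs[j]):
                    if a in "-N" or b in "-N":
                        continue
                    sites += 1
                    diffs += a != b
                expected += Fraction(diffs, sites)
                n_pairs += 1
        got = nucleotide_diversity(seqs)
        assert got.pi == pytest.approx(float(expected / n_pairs), abs=1e-12)
        assert got.n_sequences == 5

    def test_invariant_under_reordering_and_column_permutation(self):
        rng = random.Random(12)
        seqs = ["ACGTACGTAC", "ACGAACGTAC", "ACGTACGTCC"]
        base = nucleotide_diversity(seqs).pi
        assert nucleotide_diversity(seqs[::-1]).pi == pytest.approx(base)
        perm = rng.sample(range(10), 10)
        permuted = ["".join(s[i] for i in perm) for s in seqs]
        assert nucleotide_diversity(permuted).pi == pytest.approx(base)

    def test_single_sequence_rejected(self):
        with pytest.raises(EvolutionError):
            nucleotide_diversity(["ACGT"])


class TestSharedCds:
    def test_70_percent_threshold(self):
        species = [f"sp{i}" for i in range(25)]
        presence = {
            "kept": {s: 1 if i < 18 else 0 for i, s in enumerate(species)},  # 72%
            "dropped": {s: 1 if i < 17 else 0 for i, s in enumerate(species)},  # 68%
        }
        assert shared_cds_selection(presence) == ["kept"]

    def test_all_present_all_kept(self):
        presence = {g: {"a": 1, "b": 1} for g in ["x", "y", "z"]}
        assert shared_cds_selection(presence) == ["x", "y", "z"]

    def test_pandas_dataframe_accepted(self):
        import pandas as pd

        df = pd.DataFrame(
            {"sp1": [1, 0], "sp2": [1, 1], "sp3": [1, 0]}, index=["atp6", "sdh3"]
        )
        assert shared_cds_selection(df) == ["atp6"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(EvolutionError):
            shared_cds_selection({})
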