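"""Repeat detectors against brute-force oracles and planted truth."""

import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from mitokit.repeats import (
    DEFAULT_MIN_REPEATS,
    RepeatError,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    repeat_summary,
    ssr_class_summary,
)
from mitokit.seqio import revcomp


def _primitive(m):
    return all(m != m[:p] * (len(m) // p) for p in range(1, len(m)) if len(m) % p == 0)


def ssr_oracle(seq, min_repeats=DEFAULT_MIN_REPEATS):
    """Regex brute force over every primitive motif present in the sequence."""
    out = set()
    for u in range(1, 7):
        mr = min_repeats[u]
        motifs = {seq[i : i + u] for i in range(len(seq) - u + 1)}
        for m in motifs:
            if len(m) != u or not _primitive(m):
                continue
            # lookahead keeps overlapping runs visible (adjacent runs of
            # different phase can share positions)
            for match in re.finditer(f"(?=((?:{re.escape(m)}){{{mr},}}))", seq):
                s, e = match.start(), match.start() + len(match.group(1))
                e = s + u * ((e - s) // u)
                # keep only maximal runs (no period-u extension to the left)
                if s > 0 and seq[s - 1] == seq[s + u - 1]:
                    continue
                out.add((s + 1, e, m))
    return out


class TestFindSsrs:
    def test_monomer_at_threshold(self):
        (r,) = find_ssrs("G" + "A" * 10 + "G")
        assert (r.motif, r.repeat_count, r.start, r.end) == ("A", 10, 2, 11)

    def test_monomer_below_threshold(self):
        assert find_ssrs("G" + "A" * 9 + "G") == []

    def test_dimer_at_threshold(self):
        (r,) = find_ssrs("G" + "AT" * 5 + "G")
        assert (r.motif, r.unit_length, r.repeat_count) == ("AT", 2, 5)

    def test_dimer_run_not_duplicated_as_tetramer(self):
        records = find_ssrs("G" + "AT" * 8 + "G")
        assert len(records) == 1 and records[0].unit_length == 2

    def test_partial_trailing_unit_dropped(self):
        (r,) = find_ssrs("G" + "CAT" * 4 + "CA" + "GG")
        assert (r.motif, r.repeat_count) == ("CAT", 4)
        assert r.end - r.start + 1 == 12

    def test_span_revalidates_as_tandem(self):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(5000)) + "TTCT" * 6
        for r in find_ssrs(seq):
            assert seq[r.start - 1 : r.end] == r.motif * r.repeat_count

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_regex_oracle_random_20kb(self, seed):
        rng = random.Random(seed)
        # AT-rich alphabet bias raises the chance of real runs
        seq = "".join(rng.choice("AACGTT") for _ in range(20_000))
        got = {(r.start, r.end, r.motif) for r in find_ssrs(seq)}
        assert got == ssr_oracle(seq)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="AT", min_size=0, max_size=60))
    def test_equals_regex_oracle_adversarial_at_strings(self, seq):
        got = {(r.start, r.end, r.motif) for r in find_ssrs(seq)}
        assert got == ssr_oracle(seq)

    def test_thresholds_must_cover_all_classes(self):
        with pytest.raises(RepeatError):
            find_ssrs("ACGT", {1: 10})


class TestFindTandemRepeats:
    def test_perfect_pentamer_array(self):
        seq = "ACGTGCGG" + "TATAA" * 12 + "GGCCTGCA"
        (t,) = find_tandem_repeats(seq)
        assert (t.period, t.copy_number, t.percent_match) == (5, 12.0, 100)
        assert t.end - t.start + 1 == 5 * 12

    def test_perfect_six_copy_pentamer(self):
        seq = "CCGGACGC" + "ATTAA" * 6 + "GCGTCAGG"
        (t,) = find_tandem_repeats(seq)
        assert (t.period, t.copy_number, t.percent_match) == (5, 6.0, 100)

    def test_degraded_array_reported_with_percent_match(self):
        unit = "GATTCCCTTCCGCTAT"
        locus = unit + unit[:3] + "A" + unit[4:]  # one substitution in copy 2
        seq = "ACGTACTGCCGGAT" + locus + "CATGCCGGAATCAG"
        (t,) = find_tandem_repeats(seq, min_score=40)
        assert t.period == 16
        assert 90 <= t.percent_match < 100

    def test_low_score_array_not_reported(self):
        # 2 copies of a 10-mer: maximum consensus score 40 < 50
        seq = "ACGTGTCCAT" + "GATCCGTAAC" * 2 + "TTAGCGGACA"
        assert find_tandem_repeats(seq) == []

    def test_planted_perfect_arrays_recovered_exactly(self, study):
        truth = study["truth"]
        found = {
            (t.start, t.end, t.period, t.copy_number)
            for t in find_tandem_repeats(study["genome"].seq)
        }
        planted = {
            (t["start"], t["end"], t["period"], float(t["copies"]))
            for t in truth.tandems
        }
        assert found == planted  # exact recovery, zero false positives


class TestFindDispersedRepeats:
    def test_planted_pairs_recovered(self, study):
        truth = study["truth"]
        genome = study["genome"]
        ssrs = find_ssrs(genome.seq)
        tandems = find_tandem_repeats(genome.seq)
        exclude = [(r.start, r.end) for r in ssrs] + [(t.start, t.end) for t in tandems]
        found = find_dispersed_repeats(genome.seq, exclude=exclude)
        assert len(found) == len(truth.dispersed)
        for planted in truth.dispersed:
            span_a = (planted["start_a"], planted["end_a"])
            hit = next(
                d
                for d in found
                if d.span_a[0] <= span_a[1] and span_a[0] <= d.span_a[1]
            )
            assert hit.kind == planted["kind"]
            assert hit.length >= planted["length"]
            assert hit.identity > 0.95

    def test_short_duplication_not_reported(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(6000))
        segment = seq[1000:1025]  # 25 bp duplicate, below the 30 bp floor
        seq = seq[:4000] + segment + seq[4025:]
        hits = find_dispersed_repeats(seq)
        assert all(d.length >= 30 for d in hits)
        assert not any(
            d.span_a == (1001, 1025) or d.span_b == (4001, 4025) for d in hits
        )

    def test_strand_symmetry_under_reverse_complement(self):
        rng = random.Random(2)
        seq = list("".join(rng.choice("ACGT") for _ in range(8000)))
        seg = "".join(seq[500:700])
        seq[3000:3200] = seg  # direct pair
        seq[6000:6200] = revcomp("".join(seq[1000:1200]))  # inverted pair
        seq = "".join(seq)
        fwd = find_dispersed_repeats(seq)
        rev = find_dispersed_repeats(revcomp(seq))
        assert sorted(d.kind for d in fwd) == sorted(d.kind for d in rev)
        n = len(seq)
        mirrored = {
            (n - d.span_b[1] + 1, n - d.span_b[0] + 1, d.kind) for d in rev
        }
        assert {(d.span_a[0], d.span_a[1], d.kind) for d in fwd} == mirrored

    def test_sequence_shorter_than_min_len_rejected(self):
        with pytest.raises(RepeatError):
            find_dispersed_repeats("ACGT", min_len=30)


class TestRepeatSummary:
    def test_published_class_counts(self):
        summary = ssr_class_summary({1: 29, 2: 70, 3: 37, 4: 98, 5: 16, 6: 4})
        assert summary["total"] == 254
        assert summary["classes"]["tetramer"]["percent"] == 38.6
        assert summary["classes"]["dimer"]["percent"] == 27.6

    def test_single_ssr_full_share(self):
        summary = ssr_class_summary({2: 1})
        assert summary["classes"]["dimer"]["percent"] == 100.0

    def test_zero_ssrs_percent_undefined_not_crash(self):
        summary = ssr_class_summary({})
        assert summary["total"] == 0
        assert summary["classes"]["monomer"]["percent"] is None

    def test_planted_plan_counts_exact(self, study):
        truth = study["truth"]
        ssrs = find_ssrs(study["genome"].seq)
        summary = repeat_summary(ssrs, genome_length=len(study["genome"].seq))
        expected = {}
        for s in truth.ssrs:
            expected[s["unit_length"]] = expected.get(s["unit_length"], 0) + 1
        for u, name in ((1, "monomer"), (2, "dimer"), (3, "trimer"),
                        (4, "tetramer"), (5, "pentamer"), (6, "hexamer")):
            assert summary["ssr"]["classes"][name]["count"] == expected.get(u, 0)
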