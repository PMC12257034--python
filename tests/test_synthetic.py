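"""Generator contracts: determinism, plan echo, truth integrity, sampling laws."""

import json
import math

import numpy as np
import pytest

from mitokit.seqio import revcomp, translate
from mitokit.synthetic import (
    CapacityError,
    GeneratorConfig,
    GeneratorError,
    PlanningError,
    ReadProfile,
    SyntheticTruth,
    diverge_cds,
    generate_genome,
    generate_homolog_set,
    generate_plastid_with_transfers,
    generate_reads,
    make_cds,
)


class TestGenerateGenome:
    def test_plan_echo_at_fixed_position(self):
        cfg = GeneratorConfig(
            seed=0, genome_length=5000, n_genes=0,
            ssr_plan=[("AT", 6, 100)], tandem_plan=[], dispersed_plan=[],
            edit_plan=[], transfer_plan=[],
        )
        genome, _, truth = generate_genome(cfg)
        assert genome.seq[99:111] == "AT" * 6  # [100..111] 1-based inclusive
        assert truth.ssrs[0]["start"] == 100 and truth.ssrs[0]["end"] == 111

    def test_same_seed_identical_output(self):
        a, _, _ = generate_genome(GeneratorConfig(seed=5))
        b, _, _ = generate_genome(GeneratorConfig(seed=5))
        assert a.seq == b.seq

    def test_different_seed_different_output(self):
        a, _, _ = generate_genome(GeneratorConfig(seed=5))
        b, _, _ = generate_genome(GeneratorConfig(seed=6))
        assert a.seq != b.seq

    def test_truth_lists_every_planted_ssr(self):
        plan = [("A", 10 + i % 3, None) for i in range(25)] + [
            ("AG", 5 + i % 3, None) for i in range(25)
        ]
        cfg = GeneratorConfig(seed=7, ssr_plan=plan, tandem_plan=[], dispersed_plan=[])
        _, _, truth = generate_genome(cfg)
        assert len(truth.ssrs) == 50

    def test_planted_features_recoverable_by_coordinates(self, study):
        genome, truth = study["genome"], study["truth"]
        for s in truth.ssrs:
            assert genome.slice(s["start"], s["end"]) == s["motif"] * s["copies"]
        for t in truth.tandems:
            assert genome.slice(t["start"], t["end"]) == t["unit"] * t["copies"]
        for g in truth.genes:
            span = genome.slice(g["start"], g["end"])
            cds = span if g["strand"] == "+" else revcomp(span)
            assert cds == g["cds"]

    def test_genes_translate_cleanly(self, study):
        for g in study["truth"].genes:
            protein = translate(g["cds"])
            assert protein.startswith("M")
            assert protein.endswith("*") and "*" not in protein[:-1]

    def test_overlapping_plan_spans_rejected(self):
        cfg = GeneratorConfig(
            seed=8, genome_length=5000, n_genes=0,
            ssr_plan=[("A", 10, 100), ("AG", 5, 105)],
            tandem_plan=[], dispersed_plan=[], edit_plan=[],
        )
        with pytest.raises(PlanningError):
            generate_genome(cfg)

    def test_genome_too_short_rejected(self):
        cfg = GeneratorConfig(seed=9, genome_length=3000)
        with pytest.raises(CapacityError):
            generate_genome(cfg)

    def test_gc_target_validated(self):
        with pytest.raises(GeneratorError):
            GeneratorConfig(gc_target=1.2)

    def test_background_gc_near_target(self, study):
        from mitokit.seqio import base_composition

        gc = base_composition(study["genome"]).gc
        assert abs(gc - study["config"].gc_target) < 0.02


class TestTruthSerialization:
    def test_json_round_trip_lossless(self, study):
        truth = study["truth"]
        back = SyntheticTruth.from_json(truth.to_json())
        assert back == truth

    def test_bed_export_covers_all_features(self, study):
        truth = study["truth"]
        lines = [l for l in truth.to_bed().splitlines() if l]
        expected = (
            len(truth.ssrs) + len(truth.tandems) + len(truth.genes)
            + 2 * len(truth.dispersed)
        )
        assert len(lines) == expected
        for line in lines:
            chrom, start, end, _ = line.split("\t")
            assert 0 <= int(start) < int(end) <= truth.genome_length


class TestGenerateReads:
    def test_zero_contamination_all_mito(self):
        cfg = GeneratorConfig(
            seed=10, genome_length=20_000, n_genes=2,
            read_profile=ReadProfile(depth=3, contaminant_fraction=0.0),
        )
        genome, anns, truth = generate_genome(cfg)
        dna, _ = generate_reads(genome, anns, truth, cfg.read_profile, seed=11)
        assert all(truth.read_origins[r] == "mito" for r, _ in dna)

    def test_depth_expectation_within_10_percent(self, study):
        profile = study["config"].read_profile
        origins = study["truth"].read_origins
        mito_bases = sum(
            len(s) for r, s in study["dna_reads"] if origins[r] == "mito"
        )
        target = profile.depth * len(study["genome"].seq)
        assert abs(mito_bases - target) / target < 0.10

    def test_contaminant_fraction_respected(self, study):
        origins = study["truth"].read_origins
        dna = study["dna_reads"]
        n_cont = sum(1 for r, _ in dna if origins[r] != "mito")
        assert abs(n_cont / len(dna) - 0.3) < 0.03

    def test_full_edit_fraction_all_reads_carry_t(self):
        cfg = GeneratorConfig(
            seed=12, genome_length=20_000, n_genes=1,
            edit_plan=[(0, 60, 2)],
            read_profile=ReadProfile(depth=1, rna_depth=20, edit_fraction=1.0),
        )
        genome, anns, truth = generate_genome(cfg)
        _, rna = generate_reads(genome, anns, truth, cfg.read_profile, seed=13)
        cds = truth.genes[0]["cds"]
        pos = truth.edits[0]["cds_position"]
        covering = 0
        for rid, seq in rna:
            for start in range(len(cds) - len(seq) + 1):
                ref = cds[start : start + len(seq)]
                if sum(a != b for a, b in zip(ref, seq)) <= 2 and start <= pos - 1 < start + len(seq):
                    covering += 1
                    assert seq[pos - 1 - start] == "T"
                    break
        assert covering >= 10

    def test_empty_genome_rejected(self, study):
        from mitokit.seqio import SequenceRecord

        with pytest.raises(GeneratorError):
            generate_reads(SequenceRecord("x", ""), [], SyntheticTruth())


class TestHomologSet:
    def test_zero_divergence_identity(self):
        cds = make_cds(np.random.default_rng(14), 600)
        copies, truth = generate_homolog_set(cds, {"s": (0.0, 0.0)}, seed=15)
        assert copies["s"] == cds
        assert truth["s"]["syn_substitutions"] == 0

    def test_synonymous_only_preserves_protein(self):
        cds = make_cds(np.random.default_rng(16), 3000)
        copies, truth = generate_homolog_set(cds, {"s": (0.3, 0.0)}, seed=17)
        assert copies["s"] != cds
        assert translate(copies["s"]) == translate(cds)
        assert truth["s"]["nonsyn_substitutions"] == 0

    def test_realized_counts_within_3_sd_of_binomial(self):
        cds = make_cds(np.random.default_rng(18), 9999)
        ks, ka = 0.2, 0.02
        copies, truth = generate_homolog_set(cds, {"s": (ks, ka)}, seed=19)
        diffs = sum(a != b for a, b in zip(cds, copies["s"]))
        realized = truth["s"]["syn_substitutions"] + truth["s"]["nonsyn_substitutions"]
        assert diffs == realized
        # crude binomial envelope on the total substitution count: per-site
        # change probability is bounded by the planned per-alternative rates
        from mitokit.synthetic import _per_alternative_rate

        u_s, u_a = _per_alternative_rate(ks), _per_alternative_rate(ka)
        n = len(cds)
        lo = n * u_a * 3 * 0.2
        hi = n * u_s * 3 * 1.2
        assert lo < realized < hi

    def test_saturating_divergence_rejected(self):
        cds = make_cds(np.random.default_rng(20), 300)
        with pytest.raises(GeneratorError):
            generate_homolog_set(cds, {"s": (0.8, 0.0)}, seed=21)

    def test_internal_stop_rejected(self):
        with pytest.raises(GeneratorError):
            generate_homolog_set("ATGTAACCCTAA", {"s": (0.1, 0.0)}, seed=22)


class TestPlastidTransfers:
    def test_exact_transfer_verbatim_substring(self, study):
        exact = [r for r in study["transfer_truth"] if r["planned_identity"] == 1.0]
        for rec in exact:
            segment = study["genome"].slice(rec["mt_start"], rec["mt_end"])
            assert segment in study["plastid"].seq

    def test_realized_identity_within_3_sd(self, study):
        for rec in study["transfer_truth"]:
            if rec["planned_identity"] == 1.0:
                assert rec["realized_identity"] == 1.0
                continue
            p = 1 - rec["planned_identity"]
            n = rec["length"]
            sd = math.sqrt(n * p * (1 - p))
            assert abs(rec["mismatches"] - n * p) <= 3 * sd

    def test_empty_plan_no_shared_30mers(self):
        cfg = GeneratorConfig(seed=23, genome_length=10_000, n_genes=1)
        genome, _, _ = generate_genome(cfg)
        plastid, recs = generate_plastid_with_transfers(genome, [], plastid_length=10_000, seed=24)
        assert recs == []
        k = 30
        mito_kmers = {genome.seq[i : i + k] for i in range(len(genome.seq) - k + 1)}
        cp_kmers = {plastid.seq[i : i + k] for i in range(len(plastid.seq) - k + 1)}
        assert not (mito_kmers & cp_kmers)

    def test_out_of_range_plans_rejected(self, study):
        with pytest.raises(GeneratorError):
            generate_plastid_with_transfers(study["genome"], [(20, 1.0)])
        with pytest.raises(GeneratorError):
            generate_plastid_with_transfers(study["genome"], [(100, 0.4)])
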