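"""Shared fixtures: one synthetic study bundle generated per session."""

from __future__ import annotations

import pytest

from mitokit.baiting import recruit_reads_iterative, select_seed_reads
from mitokit.seqio import SequenceRecord
from mitokit.synthetic import (
    GeneratorConfig,
    generate_genome,
    generate_plastid_with_transfers,
    generate_reads,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 50 kb genome, plants, reads, plastid."""
    cfg = GeneratorConfig(seed=1)
    genome, annotations, truth = generate_genome(cfg)
    dna, rna = generate_reads(genome, annotations, truth, cfg.read_profile, seed=2)
    plastid, transfers = generate_plastid_with_transfers(
        genome, cfg.transfer_plan, seed=3
    )
    return {
        "config": cfg,
        "genome": genome,
        "annotations": annotations,
        "truth": truth,
        "dna_reads": dna,
        "rna_reads": rna,
        "plastid": plastid,
        "transfer_truth": transfers,
    }


@pytest.fixture(scope="session")
def baiting_run(study):
    """Seed selection + iterative recruitment on the default read pool.

    Session-scoped because recruitment is the most expensive single
    computation in the suite.
    """
    truth = study["truth"]
    core = [SequenceRecord(g["gene_id"], g["cds"]) for g in truth.genes[:5]]
    seeds = select_seed_reads(study["dna_reads"], core)
    result = recruit_reads_iterative(study["dna_reads"], seeds)
    return {"seeds": seeds, "result": result, "core": core}
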