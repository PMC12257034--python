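"""Pipeline orchestration: run every analysis stage over a JSON config.

The config supplies input paths and per-stage parameter blocks whose
defaults are the conventional thresholds of organelle-genome studies
(core-gene hit > 50 bp, recruitment overlap > 1 kb, ORF >= 102 bp, SSR
minima 10/5/4/3/3/3, tandem scoring 2/7/7 with minimum score 50 and maximum
period 2000, dispersed repeats >= 30 bp at word size 7 and E <= 1e-5,
transfer detection E <= 1e-5 at identity >= 70%, shared-CDS threshold 0.7).
Stages with missing optional inputs are skipped with an explicit log entry.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from mitokit import seqio
from mitokit.baiting import recruit_reads_iterative, select_seed_reads
from mitokit.codons import check_start_stop, compute_rscu, count_codons, rscu_bias_summary, rscu_table
from mitokit.editing import call_editing_sites, editing_summary
from mitokit.evolution import kaks_from_cds, nucleotide_diversity
from mitokit.repeats import find_dispersed_repeats, find_ssrs, find_tandem_repeats, repeat_summary
from mitokit.transfer import (
    assign_genes_to_fragments,
    cross_genome_matches,
    find_homologous_fragments,
    fragment_summary,
    fragments_to_tsv,
)

logger = logging.getLogger("mitokit")

DEFAULT_PARAMS = {
    "baiting": {"min_hit_length": 50, "min_overlap": 1000},
    "orfs": {"min_len": 102},
    "ssr": {"min_repeats": {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}},
    "tandem": {"match": 2, "mismatch": 7, "indel": 7, "min_score": 50, "max_period": 2000},
    "dispersed": {"min_len": 30, "word_size": 7, "evalue": 1e-5},
    "editing": {"min_depth": 5, "min_fraction": 0.1, "mode": "C2U"},
    "kaks": {"method": "MLWL"},
    "transfer": {"evalue": 1e-5, "min_identity": 70.0},
    "shared_cds": {"threshold": 0.7},
}


@dataclass
class PipelineConfig:
    out_dir: str
    genome: str | None = None
    annotations: str | None = None  # GFF3
    cds: str | None = None  # multi-FASTA of coding sequences
    dna_reads: str | None = None  # FASTQ
    rna_reads: str | None = None
    core_genes: str | None = None  # FASTA
    plastid: str | None = None
    homolog_dir: str | None = None  # directory of per-gene multi-FASTA
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def param(self, stage: str, key: str):
        return self.params.get(stage, {}).get(key, DEFAULT_PARAMS[stage][key])


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in dependency order; returns the consolidated report.

    Every stage writes its own TSV/JSON artifacts under ``out_dir`` and the
    consolidated report goes to ``report.json``.  Missing optional inputs
    skip their stage (recorded in the report), never crash it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            stage: {k: config.param(stage, k) for k in DEFAULT_PARAMS[stage]}
            for stage in DEFAULT_PARAMS
        },
        "seed": config.seed,
        "stages": {},
    }

    genome = None
    if config.genome:
        genome = seqio.read_fasta(config.genome, circular=True)[0]
        comp = seqio.base_composition(genome)
        report["stages"]["genome"] = {
            "id": genome.id,
            "length": comp.length,
            "gc_percent": round(100 * comp.gc, 2),
            "base_percent": {b: round(100 * f, 2) for b, f in comp.fractions.items()},
        }
    else:
        report["stages"]["genome"] = "skipped: no genome input"
        logger.warning("genome stage skipped (no input)")

    annotations = seqio.read_gff3(config.annotations) if config.annotations else []

    # ----- repeats
    if genome:
        ssrs = find_ssrs(genome.seq, {int(k): v for k, v in config.param("ssr", "min_repeats").items()})
        tnd = config.param("tandem", "min_score")
        tandems = find_tandem_repeats(
            genome.seq,
            match=config.param("tandem", "match"),
            mismatch=config.param("tandem", "mismatch"),
            indel=config.param("tandem", "indel"),
            min_score=tnd,
            max_period=config.param("tandem", "max_period"),
        )
        exclude = [(r.start, r.end) for r in ssrs] + [(t.start, t.end) for t in tandems]
        dispersed = find_dispersed_repeats(
            genome.seq,
            min_len=config.param("dispersed", "min_len"),
            word_size=config.param("dispersed", "word_size"),
            evalue=config.param("dispersed", "evalue"),
            exclude=exclude,
        )
        _write(out / "ssr.tsv", "\n".join(
            ["motif\tunit_length\trepeat_count\tstart\tend"]
            + [f"{r.motif}\t{r.unit_length}\t{r.repeat_count}\t{r.start}\t{r.end}" for r in ssrs]
        ) + "\n")
        _write(out / "tandem.tsv", "\n".join(
            ["no\tsize\tcopy\trepeat_sequence\tpercent_matches\tstart\tend"]
            + [
                f"{i}\t{t.period}\t{t.copy_number}\t{t.consensus}\t{t.percent_match:.0f}\t{t.start}\t{t.end}"
                for i, t in enumerate(tandems, 1)
            ]
        ) + "\n")
        _write(out / "dispersed.tsv", "\n".join(
            ["start_a\tend_a\tstart_b\tend_b\tkind\tlength\tidentity"]
            + [
                f"{d.span_a[0]}\t{d.span_a[1]}\t{d.span_b[0]}\t{d.span_b[1]}\t{d.kind}\t{d.length}\t{d.identity:.3f}"
                for d in dispersed
            ]
        ) + "\n")
        report["stages"]["repeats"] = repeat_summary(ssrs, tandems, dispersed, len(genome.seq))
    else:
        report["stages"]["repeats"] = "skipped: no genome input"

    # ----- coding sequences
    cds_map: dict[str, str] = {}
    if config.cds:
        cds_map = {r.id: r.seq for r in seqio.read_fasta(config.cds)}
    elif genome and annotations:
        for ann in annotations:
            if ann.feature_type == "mRNA":
                cds_map[f"{ann.gene_id}.{ann.copy_index}"] = seqio.extract_cds(genome, ann)

    if cds_map:
        counts = count_codons(cds_map.values())
        entries = compute_rscu(counts)
        _write(out / "rscu.tsv", rscu_table(entries))
        report["stages"]["codon_usage"] = {
            "total_codons": counts.total,
            "bias": rscu_bias_summary(entries),
            "start_stop": check_start_stop(cds_map),
        }
    else:
        report["stages"]["codon_usage"] = "skipped: no CDS available"
        logger.warning("codon-usage stage skipped (no CDS)")

    # ----- RNA editing
    if config.rna_reads and cds_map:
        reads = seqio.read_fastq(config.rna_reads)
        sites = call_editing_sites(
            reads,
            cds_map,
            min_depth=config.param("editing", "min_depth"),
            min_fraction=config.param("editing", "min_fraction"),
            mode=config.param("editing", "mode"),
        )
        _write(out / "editing_sites.tsv", "\n".join(
            ["gene\tcds_position\tref_codon\tedited_codon\taa_change\tcategory\tdepth\tfraction"]
            + [
                f"{s.gene_id}\t{s.cds_position}\t{s.ref_codon}\t{s.edited_codon}"
                f"\t{s.aa_before}>{s.aa_after}\t{s.category}\t{s.depth}\t{s.edit_fraction:.3f}"
                for s in sites
            ]
        ) + "\n")
        report["stages"]["rna_editing"] = (
            editing_summary(sites) if sites else {"total": 0, "categories": {}}
        )
    else:
        report["stages"]["rna_editing"] = "skipped: no RNA reads"
        logger.warning("RNA-editing stage skipped (no RNA reads)")

    # ----- read baiting
    if config.dna_reads and config.core_genes:
        reads = seqio.read_fastq(config.dna_reads)
        core = seqio.read_fasta(config.core_genes)
        seeds = select_seed_reads(
            reads, core, min_hit_length=config.param("baiting", "min_hit_length")
        )
        if seeds.read_ids:
            result = recruit_reads_iterative(
                reads, seeds, min_overlap=config.param("baiting", "min_overlap")
            )
            read_map = dict(reads)
            seqio.write_fastq(
                [(rid, read_map[rid]) for rid in result.recruited], out / "recruited.fastq"
            )
            report["stages"]["baiting"] = {
                "n_reads": len(reads),
                "n_seeds": len(seeds.read_ids),
                "n_recruited": len(result.recruited),
                "iterations": result.iterations,
                "per_iteration": result.per_iteration_counts,
                "converged": result.converged,
            }
        else:
            report["stages"]["baiting"] = {"n_reads": len(reads), "n_seeds": 0}
    else:
        report["stages"]["baiting"] = "skipped: no DNA reads / core genes"
        logger.warning("baiting stage skipped")

    # ----- Ka/Ks and pi over homolog sets
    if config.homolog_dir and Path(config.homolog_dir).is_dir():
        rows = []
        pi_rows = []
        for fa in sorted(Path(config.homolog_dir).glob("*.fasta")):
            recs = seqio.read_fasta(fa)
            gene = fa.stem
            ref = recs[0]
            for other in recs[1:]:
                r = kaks_from_cds(
                    ref.seq, other.seq, method=config.param("kaks", "method"),
                    gene_id=f"{gene}:{ref.id}-{other.id}",
                )
                rows.append(r)
            if len(recs) >= 2 and len({len(r.seq) for r in recs}) == 1:
                pi_rows.append(nucleotide_diversity([r.seq for r in recs], gene_id=gene))
        _write(out / "kaks.tsv", "\n".join(
            ["gene\tmethod\tL0\tL2\tL4\tKa\tKs\tKaKs"]
            + [
                f"{r.gene_id}\t{r.method}\t{r.L0:.2f}\t{r.L2:.2f}\t{r.L4:.2f}"
                f"\t{r.Ka:.6f}\t{r.Ks:.6f}\t"
                + (f"{r.ratio:.6f}" if r.ratio is not None else "NA")
                for r in rows
            ]
        ) + "\n")
        _write(out / "pi.tsv", "\n".join(
            ["gene\tn\tsites\tpi"]
            + [f"{p.gene_id}\t{p.n_sequences}\t{p.sites:.1f}\t{p.pi:.6f}" for p in pi_rows]
        ) + "\n")
        report["stages"]["evolution"] = {
            "n_pairs": len(rows),
            "kaks": [
                {"gene": r.gene_id, "Ka": r.Ka, "Ks": r.Ks, "ratio": r.ratio} for r in rows
            ],
            "pi": [{"gene": p.gene_id, "pi": p.pi} for p in pi_rows],
        }
    else:
        report["stages"]["evolution"] = "skipped: no homolog sets"
        logger.warning("evolution stage skipped")

    # ----- mito-plastid transfer
    if config.plastid and genome:
        cp = seqio.read_fasta(config.plastid, circular=True)[0]
        fragments = find_homologous_fragments(
            cp,
            genome,
            evalue=config.param("transfer", "evalue"),
            min_identity=config.param("transfer", "min_identity"),
        )
        fragments = assign_genes_to_fragments(fragments, [], annotations)
        _write(out / "transfer.tsv", fragments_to_tsv(fragments))
        matches = cross_genome_matches(cp, genome, min_len=100)
        _write(out / "dotplot.tsv", "\n".join(
            ["a_start\ta_end\tb_start\tb_end\tstrand\tidentity"]
            + [
                f"{m['a_start']}\t{m['a_end']}\t{m['b_start']}\t{m['b_end']}\t{m['strand']}\t{m['identity']}"
                for m in matches
            ]
        ) + "\n")
        summary = fragment_summary(fragments, cp_length=len(cp.seq), mt_length=len(genome.seq))
        report["stages"]["transfer"] = {
            "count": summary.count,
            "total_bp": summary.total_bp,
            "longest": summary.longest,
            "shortest": summary.shortest,
            "coverage_cp": summary.coverage_query,
            "coverage_mt": summary.coverage_subject,
        }
    else:
        report["stages"]["transfer"] = "skipped: no plastid genome"
        logger.warning("transfer stage skipped")

    _write(out / "report.json", json.dumps(report, indent=1, sort_keys=True))
    return report


def configure_logging(verbose: bool = False, log_file: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
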