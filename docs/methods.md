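# Methods

This note documents the models, algorithms and numerical choices behind
mitokit, and what the synthetic-data tests do and do not establish about
real data.

## Shared local aligner

All homology-based stages (annotation transfer, read baiting, RNA-read
pileup, dispersed repeats, plastid-transfer detection, dot-plots) use one
seed-and-extend aligner:

1. exact k-mer index over the target(s), k = 11 by default (7 for the
   dispersed-repeat self-scan, 9 for short gene probes); k-mers occurring
   more than 200 times are masked;
2. seeds grouped into clusters within a diagonal band (±32) and chained
   along the query (gap ≤ 120 bp); a cluster needs two seeds unless the
   query is shorter than 2k, and anchor coordinates come only from
   diagonals carrying at least `max(2, dominant/8)` seeds — chance seed
   pairs near a real hit otherwise drag the anchors into flanking sequence;
3. ungapped x-drop extension (x = 20) at both cluster ends; if the cluster
   spans one diagonal the alignment is the direct base-by-base comparison,
   otherwise the region is re-aligned with a banded edit-distance alignment
   (edlib) capped at 35 % edits;
4. the resulting column path is trimmed to its best-scoring contiguous
   window (match +1, mismatch −2, gap open −5, gap extend −2 per base), so
   emitted hits are local in the Smith–Waterman sense without a full DP;
5. E-values follow Karlin–Altschul, E = K·m·n·e^(−λS), with λ = 1.28 and
   K = 0.46, the published constants for +1/−2 nucleotide scoring.  Only
   the threshold (E ≤ 10⁻⁵) is conventional in this analysis; the constants
   are this package's documented choice.

Guarantees tested: any exact shared substring of length ≥ 2k−1 yields a
hit; identities of planted homologies are recovered within ~2 points; the
aligner is query/target symmetric in score and spans.  This aligner is a
heuristic: it does not promise full Smith–Waterman optimality, and
alignments dominated by indels (beyond the 35 % edit cap) are not found.

## Repeats

**SSRs.** Maximal exact tandem runs of a primitive (non-self-repetitive)
1–6 bp unit, with class minima 10/5/4/3/3/3 repeats — the standard
MISA-style parameterization for organelle genomes.  A run is reported once,
at its primitive period, with the motif as read from the run start on the
forward strand (no canonical-strand collapsing: A and T runs are distinct
classes).  Trailing partial units are dropped, so `end − start + 1 =
unit × count` always holds.  Compound/interrupted SSR merging is not
implemented; an interruption terminates a run.  The scanner is
property-tested against an exhaustive regex oracle.

**Tandem repeats.** Candidate periods come from pairs of identical 7-mers
at distance d ≤ 2000; each candidate is extended along the period-d
self-match with an x-drop rule, then scored against the majority-vote
consensus of its unit columns: score = 2·matches − 7·mismatches, reported
when score ≥ 50, copy number ≥ 1.9 and percent match ≥ 80.  This maps the
classic tandem-repeat-finder parameter set (2 7 7 … 50 2000) onto a
deterministic consensus-alignment model rather than its stochastic scoring
— a simplification: indels inside arrays are not modelled, and the copy
number is the locus length over the period rounded to one decimal.  A locus
whose primitive period p divides the voted distance votes at p itself, so
reports use the smallest explaining period.  The detector recovers all
planted perfect arrays (period ≤ 100, ≥ 3 copies, locus long enough to
score ≥ 50) at exact period and integer copy number with zero false
positives on clean background.

**Dispersed repeats.** Genome self-comparison with the shared aligner at
word size 7; seeds within 30 diagonals of the main diagonal are excluded
(near-diagonal self-similarity is tandem structure, not a dispersed
repeat), symmetric (a,b)/(b,a) duplicates are collapsed, hits overlapping
detected SSR/tandem loci are removed, and hits must be ≥ 30 bp with
E ≤ 10⁻⁵.  Both direct and inverted orientations are reported; detection is
strand-symmetric under reverse complement.

Repeat scans run on the linear sequence; repeats crossing the origin of a
circular genome are out of scope.

## Codon usage

RSCU(c) = (n_c / N_aa) · f_aa over unique coding sequences (exact-sequence
de-duplication, so identical gene copies count once), standard genetic code
(NCBI table 1 — plant mitochondria use the standard code).  The three stop
codons form one 3-codon family, matching usage tables that report "Ter"
among the amino acids.  Families with zero usage yield undefined (not zero)
RSCU.  Internal stop codons warn but are counted, since C-to-U editing can
resolve them at the transcript level.  Σ RSCU over a nonzero family equals
the family size to 10⁻⁹, and RSCU is invariant under count rescaling.

## C-to-U RNA editing

RNA reads are aligned to the coding sequences (best placement per read) and
piled up; a column with reference C, depth ≥ 5 and T fraction ≥ 0.1 becomes
a site (`mode="any"` lifts the C restriction).  Defaults are this package's
choice — variant-calling thresholds for this step are rarely stated in
organelle studies.  Each site carries its codon context, amino-acid change,
start-gain (ACG → ATG at codon 1) and stop-gain flags, and a hydropathy
category.  The hydropathy dichotomy is hydrophilic = {R K D E N Q H S T Y
C G}, hydrophobic = {A V L I P F M W}, stop separate; the classification of
C, W, G and the other residues follows the convention of published
organelle editing tables and the Kyte–Doolittle sign for residues those
tables omit (K, D, E, N, G → hydrophilic).  Calling is monotone in both
thresholds, and on error-free synthetic reads with edit fraction 0.8 at
20× RNA depth the caller attains recall 1.0 with zero false positives.

Sites are reported in CDS coordinates; the editing caller is the single
editing engine of the package (no sequence-motif prediction).

## Ka/Ks (LWL and MLWL)

Codon sites are classed by degeneracy: the number of the three possible
substitutions preserving the amino acid (0 → non-degenerate, 3 → 4-fold,
else 2-fold; 3-fold sites fold into the 2-fold class).  Site totals average
the two sequences.  For each differing codon pair all minimal substitution
pathways are enumerated (pathways through stops excluded unless all are —
then all count); each step is a transition or transversion at the changed
position, split half-and-half between the flanking codons' site classes.
Per class, Kimura two-parameter distances A (transitions) and B
(transversions) are computed; saturation (non-positive log argument) raises
an error carrying the raw counts.

* LWL: Ks = (L₂A₂ + L₄K₄)/(L₂/3 + L₄), Ka = (L₀K₀ + L₂B₂)/(L₀ + 2L₂/3).
* MLWL: the 1/3 weight becomes κ/(κ+2), with κ (the transition/transversion
  rate ratio) estimated from 4-fold sites — the neutral proxy, chosen here
  so that selection acting on 2-fold sites does not bias κ — falling back
  to all sites when 4-fold sites carry no substitutions.  2-fold sites
  whose synonymous changes are transversions (e.g. ATA third position, AGA
  first position) are tracked as a separate class with the roles of A and B
  exchanged.  With no such sites and κ = 1, MLWL reduces exactly to LWL
  (asserted in tests).

Homolog pairs are codon-aligned via protein-level global alignment
(identity scoring, gap −8/−1) back-threaded to codons; gap columns are
dropped.  Pairs need ≥ 10 comparable codons.  Ka/Ks is reported only when
Ks > 0 (otherwise the ratio is undefined/NA).  The implementation's site
and substitution counts equal an independent pathway-enumeration oracle on
random codon pairs, and LWL agrees with an independent LWL implementation
(Biopython's) on diverged 6 kb sequences to within a few percent — residual
differences trace to pathway-weighting conventions at multi-hit codons.

**π.** Average pairwise difference per site with pairwise deletion of
gap/N columns, over all C(n,2) pairs of an aligned set.

## Plastid-transfer detection

Plastid (query) vs mitochondrial (subject) genome with the shared aligner;
fragments must reach identity ≥ 70 % (identity = matches/aligned-length,
the BLAST "Identical" semantics) and E ≤ 10⁻⁵.  Any annotation overlapping
a fragment span by ≥ 1 bp is listed on its side (transferred fragments
often carry partial genes).  The summary keeps near-duplicate hits distinct
(inverted-repeat-mediated copies are real biology) but merges overlapping
spans for genome-coverage fractions.  Transfer *direction* is narrative in
the literature, not computable from two genomes; the package only labels
fragments by overlapping genes.

## Read baiting

Candidates need one core-gene alignment strictly longer than 50 bp.  Reads
hitting ≥ 2 distinct core genes always seed; otherwise the top 20 % of
candidates by summed gene coverage do — a concrete ranking for the
qualitative "more genes, more complete coverage" seed rule.  Recruitment
adds any read with an overlap alignment > 1 kb at identity ≥ 0.85 (the
identity floor prevents low-complexity chaining; length alone is the
conventional threshold) and iterates to a fixed point (cap 20 rounds,
flagged if hit).  Recruitment is monotone in the set and anti-monotone in
the overlap threshold.  Note that reads shorter than the overlap threshold
can never be recruited, so perfect recall requires read length above it.

## Synthetic data generator

The generator emulates a deeply sequenced plant mitogenome study at
test-tractable scale.  Defaults: 50 kb circular genome at GC 0.458, 8
single-exon protein-coding genes of 1200 bp, 13 SSRs across all six unit
classes, four perfect tandem arrays (periods 12–73, sized to exceed the
reporting score), three dispersed pairs (direct and inverted, 80–200 bp),
20 C-to-U edit sites at edit fraction 0.8, 30× long-read depth (mean
3 kb, normal sd 800, minimum 500) with 30 % contaminant reads, 20× RNA
depth at 150 bp, homolog divergence Ks = 0.2 / Ka = 0.02, and four plastid
transfers (100–500 bp at identity 0.85–1.0).

Key mechanisms:

* **Clean background.** i.i.d. bases at the GC target, rejection-resampled
  wherever the SSR or tandem detector fires, so planted features are the
  only repeats; gene bodies are regenerated codon-wise under the same rule.
  Guard bases at feature boundaries stop runs from extending into flanks.
* **Reads.** Sampled uniformly from the doubled (circular) genome;
  error-free by default with an optional uniform substitution rate — read
  filtering is upstream of this package's scope, so its tests should not
  depend on an error model.  Contaminants are i.i.d. sequence labelled
  nuclear/plastid.  RNA reads tile each CDS; each read covering a planted
  site carries the T independently with the edit fraction.  Planted sites
  are kept one read-length inside the CDS so they reach full depth.
* **Divergence planting.** Each site considers its three alternative bases;
  synonymous alternatives are substituted with per-alternative probability
  u(d) = (1 − e^(−4d/3))/4 for d = Ks and nonsynonymous ones for d = Ka
  (changes creating stops skipped, one substitution per site).  u inverts
  the K2P correction under uniform alternative choice, so the expected
  *corrected* distances match the plan; requested d > 0.75 is rejected as
  saturating.  MLWL recovers the planted (0.2, 0.02) within a few percent
  on a 10 kb CDS.
* **Transfers.** Mito segments copied into a plastid background with
  binomial substitutions at 1 − identity; identity < 0.5 is rejected as
  undetectable by design thresholds.
* **Truth.** Everything planted is recorded with coordinates and
  round-trips losslessly through JSON (plus BED export); identical
  configuration and seed give byte-identical outputs.

**What passing does not show.** The generator has no structural variation,
no chimeric or quality-degraded reads, no heteroplasmy, no compound SSRs,
no indel divergence between homologs, and contaminants share no homology
with the genome.  Real organelle data violate all of these; the synthetic
closure demonstrates correctness of the algorithms under their stated
models, not robustness to real-world noise.

## Problem sizes and reproducibility

Test and demonstration problem sizes are chosen for fast, deterministic
runs: 50 kb genomes, 30× depth (~700 long reads), 10 kb CDS for divergence
recovery, 20 kb sequences for oracle-equivalence scans, and a few dozen
random replicates per property.  All randomness flows through explicit
integer seeds (numpy `default_rng` / `random.Random`); reruns are
byte-identical.  The published-table reproduction targets
(`scripts/acceptance.py`) are deterministic recomputations and take well
under a second.

## Known limitations

* Origin-crossing repeats on circular genomes are not merged.
* The ORF finder reports one ORF per stop (first in-frame ATG after the
  previous stop); nested ATGs are not reported separately.
* The tandem detector's consensus model has no indels, so highly degraded
  arrays (percent match near the floor with indels) are found by the
  dispersed/self-alignment machinery instead, if at all.
* MLWL's κ needs observed 4-fold substitutions; for very close pairs it
  falls back to the all-site estimate, which selection can bias.
* The aligner's E-values use fixed Karlin–Altschul constants for +1/−2
  scoring even for gapped hits; they are a filter, not a calibrated
  significance measure.
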