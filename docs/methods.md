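# Methods

`mirreg` infers which microRNAs a transcription factor (TF) regulates, from
ChIP-Seq peak calls. The premise: a TF-bound site driving a miRNA's
transcription should appear as a called peak inside the miRNA's upstream
regulatory region, and true binding peaks differ from spurious ones in
reproducible ways — stronger peak statistics, open chromatin, a binding
motif under the summit, cross-species conservation, and proximity to the
precursor. The package turns those signals into a high-confidence edge set
by combining a rank-aggregation route with a positive-unlabeled classifier.

## Regulatory regions

MicroRNA transcription start sites are largely unmapped (the primary
transcript is degraded during maturation), so the regulatory region of an
intergenic miRNA is approximated by a fixed upstream window anchored at the
precursor's strand-aware 5' end: 700 kb for mouse, 1000 kb for human.
Rationale for the length: published miRNA TSS predictions place promoters up
to roughly 680 kb upstream. If a protein-coding gene intrudes into the
window, the region is truncated at the nearest intervening gene boundary
(the gene's own strand is ignored), so an emitted region never overlaps an
annotated gene. Windows are clipped at the chromosome ends. Only intergenic
miRNAs are processed — a precursor overlapping a protein-coding gene is
assumed co-regulated with its host and excluded. "Upstream" is interpreted
strand-aware (5' on the miRNA's own strand), matching promoter biology;
only miRNA-vs-protein-coding-gene overlap truncates windows, not other
miRNAs.

All coordinates are handled as 0-based half-open internally; GFF3 input is
converted on read. Overlap everywhere means >= 1 bp and ignores strand.

## Candidate peaks and features

A peak becomes a candidate for a miRNA when its **summit** (not the whole
interval) lies inside the miRNA's region: the summit is the point estimate
of the binding site and every downstream feature is summit-anchored. A peak
whose summit lies in two overlapping regions yields one candidate per
region.

Seven features per candidate, in fixed column order:

| feature            | source                                        | direction |
|--------------------|-----------------------------------------------|-----------|
| `tags`             | read count in the peak (peak caller)          | higher    |
| `neg_log10_p`      | peak significance, -log10 p                   | higher    |
| `fold_enrichment`  | enrichment over local background              | higher    |
| `distance_bp`      | summit to precursor 5' end                    | lower     |
| `dnase_flag`       | >=1 bp overlap with concordant DNase peaks    | higher    |
| `motif_score`      | max PWM log-odds in a 200-bp summit window    | higher    |
| `conservation_flag`| lifted peak inside a homologous human region  | higher    |

DNase concordance replaces M-A replicate renormalization with a
deterministic rule — keep every replicate-1 interval overlapping some
replicate-2 interval by >= 1 bp — because only the replicate intersection
matters downstream.

Motif scoring: JASPAR count matrices are converted to base-2 log-odds with
the pseudocount (default 0.8) distributed by the background (default
uniform), a probability floor of 1e-4 keeps scores finite, both strands are
scanned (TF binding is strand-agnostic), and positions holding N contribute
0 (the background expectation). The window is the 200 bp centered on the
summit, clipped at chromosome ends; a window shorter than the motif drops
the candidate with a warning.

Conservation: the peak interval is looked up in a liftOver-style mapping
table (exact interval match); the lifted interval's **midpoint** must fall
inside the 1000-kb regulatory region of a human miRNA recorded as the
homolog of the candidate's miRNA. Midpoint rather than whole-interval
containment tolerates indel-bearing maps. Unmapped peaks are not conserved.

Features are min-max normalized per column to [0, 1]
(`x' = (x - min) / (max - min)`). A constant column maps to all zeros: it is
uninformative, and zero keeps output deterministic. Whether the classifier
sees raw or normalized values cannot affect the rank route — the map is
monotone per column — and this invariance is asserted in the tests.

## Mean reciprocal rank (MRR)

Within each miRNA's candidate group, every feature is ranked by competition
ranking (ties share the minimal integer rank, "1, 2, 2, 4"; integer ranks
are required by the reciprocal), and each candidate is summarized by

    MRR = (1/N) * sum_i 1 / rank_i,    N = 7 features.

The group's best peak is the MRR maximum; exact ties go to the candidate
nearer the precursor, residual ties to the lexicographically smallest peak
id (determinism). The miRNAs themselves are then ranked by recomputing the
per-feature ranks across the pool of chosen peaks — within-group MRRs are
not comparable across groups of different sizes, so the ranks must be
re-pooled.

## Transductive PU learning

Known TF targets supply positive examples — each known-positive miRNA is
represented by its MRR-chosen peak (protein-coding-gene-derived positives
can be appended as extra feature rows, rescaled by the candidate matrix's
raw min/max). Every other candidate peak is unlabeled, and the task is
transductive: label that very pool.

The learner is a class-weighted linear soft-margin SVM (positives weighted
`class_weight_ratio` = 10 versus unit-weight unlabeled examples — the
biased-SVM heuristic) refined by label switching: fit with the unlabeled
pool at -1, score the pool, relabel the top k as +1, refit, and repeat to a
fixed point (cap 50 iterations). The positive-fraction parameter p fixes

    k = max(1, round(p * U)),  U = #unlabeled

exactly, by thresholding at the k-th largest decision score (identifier
ties break lexicographically). Rounding is half-up; the floor of 1 avoids
empty predictions at small U; `k >= U` is refused. The solver is
deterministic given the data order, so a seed reproduces labels and scores
bit-for-bit.

p is swept over 0.05 to 0.95 in steps of 0.05 (19 fits). The **robust
positives** are the across-sweep intersection of positive-labeled
identifiers — examples predicted positive at *every* p — and a miRNA is
robustly positive when at least one of its peaks is. This intersection is
the false-positive-minimizing step: its size is bounded by the smallest
per-p set (about `round(0.05 * U)`).

Hyperparameter notes: `unlabeled_weight` (default 1.0) scales unlabeled
examples' misclassification cost; values below 1 damp the influence of
pseudo-labels on the margin at large p (as transductive SVMs do by costing
unlabeled errors less) but weaken the separation of the bulk at small p. On
the recovery benchmark below, uniform weighting was the best overall
compromise and is the default.

Evaluation harnesses: `evaluate` reports recall (fraction of known
positives predicted positive) and removal rate (fraction of the unlabeled
pool predicted negative). `holdout_experiment` moves 10/30/50/70/90% of the
positives into the unlabeled pool and measures recall on the moved-out
examples — held-out rather than training positives, whose recall would be
trivially inflated. `cross_validate` does the same fold-wise (default 5
folds) and averages per p. All randomness flows from one seed.

## The merge

With P = |robust positive miRNAs|, the final edges are the intersection of
the robust positives with the top-P miRNAs of the MRR ranking. Known
positive (training) miRNAs are excluded from both sides first: they are
inputs, not findings, and because their true peaks dominate the top of the
MRR list they would otherwise crowd novel discoveries out of the top-P
window. The complete ranking, training miRNAs included, is still written as
an artifact. Each edge carries the miRNA's chosen peak and its MRR as
supporting evidence. Every pipeline run writes a manifest (input SHA-256
hashes, parameters, seed); identical inputs and seed reproduce every output
byte-for-byte.

## The synthetic world

`mirreg.simulate` writes a complete, self-consistent input bundle — genome
FASTA, miRNA GFF3, gene BED, narrowPeak, two DNase BED replicates, JASPAR
PFM, liftover and homology tables, expression list, positives TSV — with
planted truth. Defaults: 2 chromosomes x 5 Mb, 20 miRNAs (2 buried in
genes, 2 unexpressed), 8 truly bound, ~8 decoy peaks per region, and half
of the true targets disclosed as known positives.

Each miRNA occupies its own slot with a protein-coding "insulator" gene
placed just upstream, so each 700-kb window truncates to a 150-250 kb
region and neighboring regions never overlap — a true peak can only be a
candidate for its own miRNA, keeping the planted edge set well-posed.
True peaks draw tags (negative binomial, mean 30, size 10), fold enrichment
(log-normal, median 5) and -log10 p (5 + exponential(3)) shifted upward by
2 pooled standard deviations each; they carry a planted motif consensus at
the summit with probability 0.9 (asserted during generation to outscore
the 95th percentile of background windows), sit in replicate-concordant
open chromatin with probability 0.9 (vs 0.2 for decoys), are conserved with
probability 0.8 (vs 0.1), and sit near the precursor (exponential, scale
20 kb) while decoys are uniform over the region. Heavy-tailed families were
chosen for realism; all parameters live in `SimulationConfig`.

The matched null world (`null_bundle`) keeps the "true" labels but removes
every difference — zero shifts, equalized probabilities, no motifs, uniform
distances — and is used to verify the pipeline does not manufacture signal:
the robust positives' hit rate must be statistically indistinguishable from
the unlabeled base rate.

What the simulator does **not** emulate: read-level noise, fragment-length
artifacts, mappability and GC structure, correlated features, realistic
genome composition, or imperfect liftover geometry. A green recovery test
therefore establishes that the algorithmic chain is correct and sensitive
at the stated effect sizes — not that the method meets any particular
performance on real data.

## Verified behavior (computed by the test suite)

On 50 bundles at the stated defaults (seeds 0-49), the final edge set
recovers the discoverable planted edges with median recall 1.0 and median
precision 0.8; on 20 matched null bundles the robust-positive hit rate is
indistinguishable from the base rate (binomial test, alpha 0.01). Single-p
labelings occasionally drop a true peak (the label-switching fixed point is
not globally stable), which the across-p intersection inherits; this is the
dominant source of missed edges.

## Known limitations

- The liftover lookup requires exact interval identity; split or partial
  maps are treated as unmapped.
- narrowPeak files carry no tag counts; without a companion column the tags
  feature is constant and normalizes to zero (warned).
- MACS-xls summit columns are assumed absolute 1-based positions.
- The learner is linear; no kernels, no probability calibration, no bagging
  (the unlabeled pool here is similar in size to the positive set, which
  makes bagging PU unattractive).
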