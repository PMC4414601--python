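# mirreg

Inference of transcription-factor→microRNA regulatory relationships from
ChIP-Seq peak calls.

## The problem

Which miRNAs does a given TF regulate? miRNA transcription start sites are
largely unmapped — the primary transcript is degraded during maturation —
so binding sites must be sought in large approximate regulatory regions
(hundreds of kb upstream of the precursor), where most called peaks are
spurious. `mirreg` is for computational biologists who have MACS-style peak
calls plus the standard supporting data (DNase-Seq peaks, a genome FASTA, a
JASPAR motif, a cross-species liftover, a miRNA homology table, a handful
of known targets) and want a high-confidence TF→miRNA edge list rather than
a raw peak list.

## The method

1. **Regulatory regions.** For each expressed intergenic miRNA, a
   strand-aware upstream window (700 kb mouse / 1000 kb human) anchored at
   the precursor 5′ end, truncated at the nearest intervening
   protein-coding gene.
2. **Candidates + seven features.** Peaks whose summit falls in a region
   become candidates, described by tag count, −log10 p, fold enrichment,
   summit-to-precursor distance, open-chromatin flag (≥1 bp overlap with
   replicate-concordant DNase peaks), max PWM log-odds over a 200-bp
   summit-centered window (both strands), and a conservation flag (lifted
   peak midpoint inside a homologous human miRNA's region). Features are
   min–max normalized per column:

       x′ = (x − x_min) / (x_max − x_min) ∈ [0, 1].

3. **Mean reciprocal rank.** Within each miRNA's candidate group, features
   are competition-ranked and aggregated as

       MRR = (1/N) Σᵢ 1/rankᵢ,  N = 7;

   the best peak per miRNA is the MRR maximum (ties → nearer peak), and
   miRNAs are then ranked by re-pooled MRR of their chosen peaks.
4. **Transductive PU learning.** Known targets' chosen peaks are the only
   labeled (positive) examples; all other candidate peaks are unlabeled. A
   class-weighted linear SVM with label-switching refinement labels exactly
   `k = max(1, round(p·U))` unlabeled peaks positive; p is swept over
   0.05…0.95 (step 0.05) and the **robust positives** are the miRNAs
   predicted positive at every p.
5. **Merge.** With P robust positives, the final edges are their
   intersection with the top-P miRNAs of the MRR ranking (known training
   positives excluded from both sides — they are inputs, not findings).

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Everything runs on synthetic bundles with planted truth — no downloads:

```python
from mirreg.simulate import SimulationConfig, simulate_bundle, bundle_config
from mirreg.pipeline import run_pipeline

paths, truth = simulate_bundle(SimulationConfig(seed=7), "demo/bundle")
print("known positives:", sorted(truth.known_positive_mirnas))
print("planted targets:", sorted(truth.true_mirnas))
res = run_pipeline(bundle_config(paths), "demo/out", seed=7)
print(res.edges.to_string(index=False))
```

prints

```
known positives: ['mmu-mir-15', 'mmu-mir-18', 'mmu-mir-7', 'mmu-mir-9']
planted targets: ['mmu-mir-10', 'mmu-mir-11', 'mmu-mir-13', 'mmu-mir-15',
                  'mmu-mir-16', 'mmu-mir-18', 'mmu-mir-7', 'mmu-mir-9']
tf   mirna_id   peak_id      mrr  robust
TF mmu-mir-13 peak_0074 0.548980    True
TF mmu-mir-16 peak_0096 0.546429    True
TF mmu-mir-11 peak_0057 0.480952    True
```

The simulator planted 8 true targets and disclosed 4 of them as training
positives; the 4 discoverable ones are mir-10/11/13/16. The pipeline
reports three edges, all of them planted (precision 1.0, recall 0.75 on
this seed). Each edge's `mrr` is the chosen peak's re-pooled mean
reciprocal rank, and `robust` records that the miRNA survived the whole
p sweep. All stage tables (regions, candidates, feature matrices, chosen
peaks, per-p labels, ranking, edges, manifest with input hashes) land in
`demo/out/`.

The same pipeline is scriptable from the shell:

```bash
mirreg simulate --outdir demo/bundle --seed 7
mirreg run --config demo/config.yaml --outdir demo/out --seed 7
```

with a YAML config naming the input files and any non-default parameters
(window sizes, p grid, SVM settings).

The PU learner is also usable on its own, statsmodels-style:

```python
from mirreg.pu import TransductivePU, PUDataset
model = TransductivePU(PUDataset(positives, unlabeled), seed=0)
results = model.fit(p=0.10)      # PUResults: labels, scores, summary()
sweep = model.sweep()            # 19 labelings across the default grid
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic bundle at the given seed, runs the full
pipeline end to end, prints the edge count and recovery of the planted
truth, and writes the result JSON.
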