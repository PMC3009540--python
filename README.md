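# anchormotif

De novo discovery of **anchored protein sorting motifs** from labelled
protein sequence sets — including impure ones.

Many sorting/targeting signals (the twin-arginine `RR` of Tat substrates,
the `NPxY` internalisation motif of LDL-receptor tails) share one shape: a
short, highly conserved **anchor** of 2–5 residues embedded in a longer,
weakly conserved **motif region** whose signal is physicochemical
(hydrophobicity, charge) rather than positional identity.  Alignment-based
motif finders struggle with this shape.  `anchormotif` instead frames
discovery as classification: given a *positive* set of proteins believed
to share a sorting destination and a *negative* background set, it

1. extracts K-residue N-/C-terminal segments and reduces redundancy by
   greedy identity clustering (threshold 0.8 by default);
2. enumerates gap-tolerant anchor patterns
   `<aa>{n} <gap min..max> <aa>{m}` and ranks them by positive-set support;
3. optionally runs **iterative false-positive removal**: a width-W window
   is seated at each sequence's anchor, a two-class positional naive Bayes
   model is retrained as the window slides outward residue by residue, and
   sequences whose average window posterior (before their first run of 3
   consecutive scores < 0.85) stays below 0.85 are dropped — repeating
   until the positive set stabilises;
4. determines motif boundaries by sliding a window outward from the anchor
   and reading off where 5-fold cross-validated min(precision, recall)
   falls below 0.5;
5. reports each motif's **motif score** `min(precision, recall)` — robust
   to class imbalance — its position weight matrix, consensus, and
   **information content** `IC = Σ_j (log2 20 − H_j)` in bits.

The positional naive Bayes window model treats each window column as an
independent categorical variable over the 20 amino acids with Laplace
smoothing α; `X` (ambiguity) contributes a flat 1/20 likelihood to both
classes.  Negative training windows are anchor-aligned wherever the
background sequence happens to contain the anchor and randomly placed
otherwise, so a motif cannot score merely by containing its own anchor.

## Worked example

Generate a synthetic positive set (60 sequences of length 200, each
carrying a 20-residue implant: a central `AA` anchor with 9-residue
hydrophobic flanks at a random position within the first 100 residues)
plus an i.i.d. background set, then discover:

```python
from anchormotif import ImplantSpec, generate_background, implant, write_fasta
from anchormotif.alphabet import HYDROPHOBIC

pos = generate_background(60, 200, seed=100, label="positive", prefix="pos")
pos, truth = implant(pos, ImplantSpec(flank_alphabet=HYDROPHOBIC, true_ratio=1.0, seed=101))
neg = generate_background(60, 200, seed=102, label="negative", prefix="neg")
write_fasta(pos, "pos.fa"); write_fasta(neg, "neg.fa")
```

```
$ anchormotif discover --pos pos.fa --neg neg.fa --no-redundancy \
      --min-support 0.5 --top-k 3 --seed 1 --out out/
Anchored motif discovery results
========================================================================
positives: 60  negatives: 60  ends: N  K: 200
window: 10  folds: 5  removal: on (threshold 0.85)  boundary threshold: 0.5  seed: 1
------------------------------------------------------------------------
rank end   anchor   L n_inst  score IC(bits)  consensus
   1   N       AA  31     57  0.950    44.84  xxxxxxxxxxxxxxAAxxxxxxxxxxxxxxx
   2   N       VL  24     47  0.830    29.34  xxxxxxxxVLxxxxxxxxxxxxxx
   3   N       LL  30     43  0.792    31.94  xxxxxxxxxxxxxxxxLLxxxxxxxxxxxx
```

The implanted `AA` anchor ranks first: a 31-residue region around it
separates positives from background with cross-validated
min(precision, recall) = 0.95, and its information content (44.8 bits)
reflects the two fully conserved anchor columns (log2 20 ≈ 4.32 bits each)
plus the restricted hydrophobic flank columns.  `VL` and `LL` are echoes
of the same implant (frequent dipeptides *inside* the hydrophobic flanks).
Lowercase `x` marks consensus columns without a majority residue.  The
output directory holds `anchors.tsv`, `removal_audit.tsv`, `motifs.json`,
`motifs.meme` (MEME minimal format, ready for logo tools) and
`run_log.json`.

The same pipeline is available as a library via
`MotifDiscovery(positives, negatives, PipelineConfig(...)).fit()`, which
returns a results object with `.motifs`, `.summary()`, and `.save()`.

## Synthetic benchmark

`anchormotif benchmark --config configs/benchmark_default.yaml --out bench/`
sweeps implant purity (the fraction of positive sequences that truly carry
a motif) from 10% to 100%, with and without false-positive removal, on
219 positive / 220 negative sequences, and writes per-replicate records
and a mean ± sd summary.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the benchmark datasets from scratch (3 replicates per
condition) and recomputes the headline quantities: mean motif score for
hydrophobic and hydrophobic+charged implants at 100% purity, the
with/without-removal contrast at 40% purity, the 10%-purity degradation
floor, and the information content of the purified full-purity motif.
Runtime is well under a minute.
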