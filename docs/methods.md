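# Methods

## Problem setting and model

Input is a positive set `P` of proteins presumed to share a sorting
destination and a negative background set `N`.  The target signal is an
*anchored motif*: a short conserved anchor (e.g. `AA`, `RR`, `NPxY`)
inside a longer region whose conservation is distributional (residues
drawn from a restricted physicochemical alphabet) rather than positional.
Discovery is cast as classification: a motif model is good exactly to the
extent that windows extracted under it separate `P` from `N`.

### Window classifier

The core statistical object is a two-class naive Bayes model over
fixed-width sequence windows in which each window column `j` is an
independent categorical variable over the 20 amino acids:

    P(w | class) = prod_j  theta_class[j, w_j]

with Laplace-smoothed estimates
`theta[j, a] = (count(j, a) + alpha) / (n_j + 20 alpha)` (default
`alpha = 1`; `n_j` counts non-`X` observations at column `j`), class
priors proportional to class sizes, and all products carried in log space
(no underflow for widths into the hundreds).  `X` contributes likelihood
1/20 to both classes, i.e. no evidence.  A positional model (not a
bag-of-residues composition model) is required because boundary
determination needs column-level localisation.

Classifier quality is always summarised as **min(precision, recall)** of
the motif class under stratified k-fold cross-validation (default 5
folds, posterior threshold 0.5, counts pooled over folds).  The minimum
of precision and recall is insensitive to class imbalance; pooling keeps
the estimate stable for small classes.

### Window seating for negatives

At every stage, background sequences that *contain* the anchor contribute
anchor-aligned windows, and only anchor-free sequences contribute
randomly placed windows.  This choice is load-bearing: if negatives were
always random windows, the anchor literal itself (present by construction
in every positive window) would give the classifier ~5 nats of log-odds
and every anchored candidate would score ~1.0 regardless of whether any
conserved flank exists.  Seating anchored negatives cancels the anchor
columns between classes, so the score measures the flanks — which is what
a motif score is supposed to mean.  The residual anchor signal (anchors
occur in only ~2/3 of background sequences at realistic compositions)
explains the near-chance floor (~0.55) observed for nearly-pure-noise
positive sets.

### False-positive removal

Positive sets assembled from localisation annotations are impure.  For a
candidate anchor the removal loop is:

1. Seat a width-W window (default W = 10) at each positive sequence's
   chosen anchor occurrence.  Multiple occurrences: the first iteration
   uses the left-most; afterwards the occurrence with the highest seat
   posterior under the current model wins (ties go left).
2. Train the window model (positives: seated windows; negatives as above)
   and record each positive sequence's motif-class posterior.
3. Slide the window one residue at a time, first leftward then rightward
   from the seat, retraining at every offset and re-scoring.
4. A sequence's trajectory in a direction ends at its first run of
   `consecutive_low` (default 3) successive posteriors below
   `score_threshold` (default 0.85), or at the segment edge.
5. Average each sequence's posteriors *before* that terminating run
   (the seat score is always included; if the run starts immediately, the
   mean is the seat score).  Sequences with mean < `score_threshold` are
   removed.
6. Repeat from (1) until no removal or `max_iterations` (default 10).

Averaging only the pre-run prefix matters: averaging over *all* visited
windows would mix in the inevitable ~0.5 posteriors far from the motif
and push every sequence — including true ones — below 0.85, emptying the
set even at 100% purity.  Removing every positive raises an error rather
than silently returning an empty motif.

### Boundary determination

For each direction, the candidate boundary at distance `d` is the residue
`anchor_start − d` (left) or `anchor_end − 1 + d` (right), and the test
window of width W is **centred on that residue**.  At each distance a
fresh model is trained and cross-validated; extension stops at the first
distance whose min(precision, recall) drops below `accuracy_threshold`
(default 0.5), and the boundary is the outermost passing residue
(capped at `max_extension` = 50).  If even the anchor seat fails, the
anchor is rejected (no motif).  Centring is the one unstated geometric
convention with real leverage: edge-aligned variants give detected
lengths of ~21 (window held outside the candidate) or ~41 (held inside)
on the full-purity benchmark, while centring gives ~29–31, matching the
expected shape (implant length + a few residues per side).  Even so the
scan is statistically sharp — with ~200 windows per class a *single*
conserved column keeps the CV score above 0.5 — so measured
over-extension is ~5–6 residues per side rather than 3–4; see
limitations.

### Motif summary statistics

The boundary-delimited, anchor-aligned instances define the motif:

* **motif score** — CV min(precision, recall) of instances vs equal-width
  background windows (anchored negatives aligned to the same frame);
* **PWM** — observed column frequencies (`X` excluded), consensus letter
  per column when a majority residue exists, lowercase `x` otherwise;
* **information content** — `IC = Σ_j (log2 20 − H_j)` bits, observed
  frequencies, no pseudocount, `0·log 0 := 0`; an all-`X` column
  contributes 0 bits.

## Synthetic benchmark (what the generator emulates)

`generate_background` draws i.i.d. sequences from a fixed
vertebrate-average amino-acid composition (Robinson–Robinson
frequencies).  `implant` overwrites, in a seeded uniformly chosen subset
of `round(true_ratio × N_pos)` positives, a 20-residue block — 9 flank
residues, the `AA` anchor, 9 flank residues — at a uniform start within
the first 100 N-terminal residues.  Flank residues are i.i.d. from the
background composition restricted to a named alphabet and renormalised:
hydrophobic `{V,I,L,M,F,W,C}` or hydrophobic+charged
`{V,I,L,M,F,W,C} ∪ {K,R,D,E}`.  Substitution (not insertion) keeps every
sequence at length 200 and terminal coordinates stable.  Default sizes
are 219 positives / 220 negatives; 3 replicates by default (10 for the
full protocol).  Replicate seeds depend only on the global seed and the
replicate index, so removal-on/removal-off condition pairs see byte-
identical datasets.

What the generator does **not** emulate: real proteomes' positional
composition gradients (initiator methionine, signal-peptide composition),
sequence redundancy and phylogenetic correlation (hence redundancy
reduction is skipped for synthetic runs), length variation, and multiple
motif occurrences per sequence.  A green benchmark therefore establishes
that the algorithm recovers implanted anchored motifs under the stated
noise model — not performance on curated Swiss-Prot sets, which users can
still run through the FASTA CLI.

## Numerical and design choices

* Coordinates are 0-based, half-open throughout.
* Identity for redundancy reduction: global alignment (match 1,
  mismatch 0, linear gap −1), identity = identical columns / alignment
  length including gaps; a `denominator="shorter"` switch gives the
  CD-HIT convention.  Clustering is greedy longest-first (ties by id),
  which makes it deterministic and idempotent.
* Anchor enumeration counts per-sequence support (not total occurrences)
  as the ranking key — a sorting signal occurs once or twice per protein,
  so support resists repeat-rich outliers; ties break lexicographically.
  Default support cutoff 0.30 of positives; instantiation spaces above
  10^7 raise a resource error.
* All randomness flows from one global seed through CRC32-based stage
  derivation (`derive_seed`), so every stage is independently
  reproducible and reruns are byte-identical (`motifs.json` rounds floats
  to 9 decimals).
* Degenerate inputs: single-class training, windows wider than a segment,
  fewer instances than folds, and empty anchor tables all raise typed
  errors; the CLI maps "no motif" to exit status 2, errors to 1.

## Known limitations

* Detected motif length over-extends by ~5–6 residues per side at full
  purity (the classifier stays above a 0.5 CV threshold down to a single
  conserved column).  Interval recovery remains good (Jaccard ≥ 0.6
  against ground truth); raise `accuracy_threshold` if tighter boundaries
  matter more than sensitivity.
* At very low purity (≤10%) the seat window can fail the threshold on
  noise and a replicate legitimately reports "not found".
* The window model ignores inter-column dependence; strongly gapped or
  variable-length motif regions are represented only through the anchor's
  gap range.
* Information content uses no small-sample correction and no background
  relative-entropy weighting; with ~200 instances the bias is small, but
  IC values from few instances are inflated.
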