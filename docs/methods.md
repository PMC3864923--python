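# Methods

## Problem and model

Intrinsically disordered regions are stretches of a protein chain that do
not adopt a stable fold; operationally, a residue is *disordered* (label D)
when it belongs to a run of at least four consecutive residues without
atomic coordinates in the crystal structure, and *ordered* (O) otherwise.
The toolkit treats disorder prediction as independent binary classification
of residues: each residue is encoded by a concatenation of feature-function
outputs and scored by an ensemble of extremely randomized trees whose
leaves store the empirical disordered proportion of the training residues
they receive.  The ensemble probability is the mean of the per-tree leaf
proportions; a calibrated threshold θ turns probabilities into O/D calls.

Residues are described by the primary sequence plus three per-residue
annotation tracks, each a probability table p(i, l):

| track | labels | semantics |
|-------|--------|-----------|
| `aa`  | 20 amino acids | one-hot sequence identity ('X' rows are all-zero) |
| `pssm`| 20 amino acids + gap | PSI-BLAST log-odds, logistic-scaled to (0,1) |
| `ss3` | H, E, C | predicted secondary structure (one-hot) |
| `sa`  | B, E | predicted burial at a 25% exposure cut (one-hot) |

The gap column of `pssm` is constant 0: ASCII profiles carry 20 log-odds
columns, and a zero column can never win an argmax.  The scaling function
is the logistic 1/(1+e^-x), the canonical squashing for raw log-odds; it is
replaceable through the `squash` hook of `scale_pssm`.

## Feature functions

Twelve parameterized families map (protein, position) to a fixed-length
vector; five read the sequence alone (protein length, cysteine count,
20-bin composition histogram, absolute and relative position), seven read
an annotation track.  Windowed families use odd W and offsets −K..K with
K=(W−1)/2, except the local histogram whose published size grid
(10,20,…,90) is even: it uses offsets −⌊(W−1)/2⌋..⌊W/2⌋ and divides by W,
with one extra feature carrying the out-of-bounds fraction.

The *separation profile window* is the distinctive encoding.  For every
label l it lays out, centred on the residue of interest, the distances (in
sequence positions) to the K nearest residues carrying l on the N-terminal
side (farthest of the K in the outermost slot) and on the C-terminal side
(nearest first), with the centre slot 0 when the residue itself carries l
and otherwise the distance to the nearest l on either side.  When a side
has fewer than K residues with l, missing slots are filled with the
farthest same-label distance available on that side; a side (or the whole
chain) with no l at all is filled with the protein length n, the maximal
possible separation.  Applied to the `sa` track this makes the distance to
the nearest buried residue — and, through the two sides combined, the
length of the surrounding exposed run — directly available to the learner.

Argmax ties on probabilistic tracks break toward the earliest label in
canonical order.  Dimeric histograms use products of consecutive-residue
probabilities, which reduces to exact dimer frequencies on one-hot tracks
and degrades gracefully on probabilistic ones.

The default selection grid enumerates 109 candidates: the 5 sequence-level
families plus, per annotation, the global histogram, 9 local-histogram
sizes, 5 local-window sizes, 5 separation-profile sizes, the dimeric global
histogram and 5 dimeric local sizes.  The labeled-segments window is
implemented and tested but excluded from the default grid (it can be added
explicitly); including it would enumerate 129 candidates.

## Learner and selection

The base learner is scikit-learn's `ExtraTreesClassifier` configured to the
extremely-randomized-trees contract: every tree sees all training samples
(no bootstrap), K random splits are examined per node, trees are fully
developed (`min_samples_split=2`, no depth limit), and class-proportion
leaves provide probabilities.  K defaults to √d of the current total
feature count and is recomputed whenever the encoding changes; T=1000
trees is the full-scale default.

Feature-function subsets are scored by cross-validated AUC.  Folds are
drawn at the **protein** level — windowed features of neighbouring residues
are nearly identical, so residue-level folds would leak — and fold draws
are re-drawn (bounded retries) until every test fold contains both classes,
because the AUC of a single-class fold is undefined.  The greedy forward
wrapper starts from the empty set and at each iteration adds the candidate
whose augmented encoding maximizes the mean fold AUC; all candidates within
one iteration share the same fold draw (paired comparison), per-iteration
fold seeds derive from the master seed, and ties break toward the earliest
candidate in grid order.  For large corpora the per-fold training residues
can be subsampled (seeded) through `max_train_residues`; test folds are
always scored in full.

Threshold calibration follows an 80/20 protocol: the ensemble is fitted on
80% of the training proteins and θ maximizes balanced accuracy over the
held-out 20%, scanning 0, 1 and midpoints of consecutive sorted unique
probabilities, ties toward the smallest cut (favouring sensitivity).

## Evaluation

With disordered residues as positives: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), balanced accuracy their mean, precision TP/(TP+FP), F-measure
the harmonic mean of precision and sensitivity, and the rank-based AUC
(probability a random disordered residue outranks a random ordered one,
ties ½ — identical to the trapezoidal ROC area).  0/0 ratios are reported
as 0 with a degenerate flag rather than raised.  Bootstrap uncertainty
resamples proteins: with fraction < 1, subsampling without replacement;
with fraction = 1, classical bootstrap with replacement.  Percentages in
composition tables are rendered round-half-up to 2 decimals.

## Synthetic corpus generator

The generator produces corpora with the statistical structure of X-ray
disorder datasets so the whole pipeline is testable offline:

* lengths log-normal (median ≈210, mean ≈245) clipped to [30, 800];
* a stationary two-state buried/exposed Markov chain (`p_buried` 0.5,
  self-transition `rho_sa` 0.78);
* secondary structure drawn per residue, coil-enriched where exposed
  (0.72 vs 0.35);
* disorder sampled from a logistic model on the **latent** accessibility
  chain: β₀ + β_dist·(distance to nearest buried) + β_run·(length of the
  surrounding exposed run) + β_coil·coil, with β=(0.8, 0.7, 0.8); runs
  shorter than four are then erased per the labelling rule.  The run-length
  term makes whole long exposed loops disordered together, the mechanism
  that renders two-sided separation distances informative;
* β₀ is calibrated by bisection so the post-erasure disorder rate matches
  the 6.5% target: a pilot corpus (≥40k residues) shares its random draws
  across candidate intercepts, making the achieved rate monotone in β₀;
* amino-acid composition inside disordered runs mixes in a disorder-prone
  low-complexity profile (P, E, S, Q, K, G, A);
* raw PSSM rows are sharply conserved at the true residue in ordered
  stretches and flat in disordered ones, integer log-odds in [−10, 13];
* the emitted `sa`/`ss3` tracks are noisy predictions of the latent state
  (flip probabilities 0.02 and 0.08), and 30% of pssm rows swap their
  conservation regime — mimicking the imperfection of predicted
  annotations and keeping held-out AUC in a realistic 0.90–0.95 band
  rather than at 1.0.

Under these defaults a 300-protein corpus shows ≈6–7% disordered residues,
a disorder-vs-distance-to-buried profile that rises monotonically and
crosses 0.5 around 5–6 residues, ≈69% coil among disordered residues, and
lower profile conservation inside disorder — the qualitative fingerprints
the generator is asked to emulate.  What it does **not** emulate: real
evolutionary profiles, homology structure, inter-protein redundancy, or
CASP target composition.  Passing selection-recovery tests therefore shows
that the wrapper finds planted accessibility-proximity signal under
realistic noise, not that the same encodings would be selected on any
particular experimental corpus.

## Problem sizes and numerical choices

The selection-recovery study (tests and the acceptance script) runs the
wrapper on 300-protein corpora with shorter chains (log-normal median ≈60,
clipped to [30, 120]), T=100 trees, 5-fold protein-level CV, the
20-candidate reduced grid, and a seeded 1500-residue training subsample
per fold, over 10 corpus seeds.  These sizes keep a full 10-seed study in
a few minutes on one CPU while leaving every signal parameter at its
default; the full-scale settings (T=1000, 10 folds, 109 candidates, no
subsampling) remain available through the same interfaces.

Other numerical conventions: positions are 1-based at every interface and
0-based internally; disorder regions are 1-based inclusive intervals;
greedy ties use a 1e-12 epsilon so floating-point noise cannot overturn
the earliest-candidate rule; fold and iteration RNG streams derive from
(master seed, iteration) pairs so runs are bit-reproducible end to end.

## Known limitations

* The generator's annotation noise is i.i.d. per residue; real secondary
  structure and accessibility predictors make spatially correlated errors.
* The logistic disorder model has no protein-level random effects, so
  between-protein heterogeneity is milder than in curated corpora.
* `labels_local_hist` with even W is asymmetric by one position toward the
  C-terminus; results for the published even grid sizes depend on that
  convention.
* Bootstrap replicates that happen to be single-class are re-drawn rather
  than imputed, which slightly biases the sd downward on tiny corpora.
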