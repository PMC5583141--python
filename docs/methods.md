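# Methods

## Model

The sequence model is a stacked GRU over a data-derived token vocabulary.
SMILES strings are tokenized by single characters except for the
two-character halogens `Cl`/`Br` and square-bracket atom environments
(`[nH]`, `[O-]`, …), each one token. Two control tokens are appended to the
vocabulary: GO (always the first input) and EOS (terminates an episode).
Regular tokens are ordered lexicographically with GO and EOS pinned last, so
a vocabulary built from the same corpus is bit-identical across runs and
corpus permutations.

At each step the network consumes the previous token (one-hot) and emits a
softmax distribution over the vocabulary. The GRU update is the standard
`z/r/n` form with the reset gate applied to the hidden contribution of the
candidate state. The update-gate bias is initialised positive ("forget
bias"), biasing the cell toward carrying state early in training. The
likelihood of a sequence is the product of realised step probabilities,
EOS included; padding after EOS is masked out of every sum.

The network, backpropagation through time and the optimizers are written
directly on NumPy arrays. One backward primitive computes the gradient of
`Σ_b w_b · NLL(A_b)` for arbitrary per-sequence weights `w`; every training
cost in the package is expressed through it:

| cost | per-sequence weight `w_b` (batch mean) |
|---|---|
| maximum likelihood | `1/B` |
| augmented-likelihood agent | `2(log P_U − log P_A)/B` |
| action-basis | identical to the agent weight (the printed stepwise form sums to the same sequence quantity) |
| REINFORCE, reward `S` | `S/B` (ascent on the gain `S·Σ log π`) |
| REINFORCE, reward `S + log P_prior` | `(log P_prior + σS)/B` |

Correctness of the backward pass is asserted against central finite
differences in float64 (`tests/test_seq_model.py`); the equivalence of the
squared-disagreement gradient with the REINFORCE surrogate
`r·log P_A`, `r = [log P_U − log P_A]²/log P_A`, is likewise checked by
finite differences.

## Training recipes and parameters

* **Prior (MLE).** Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), initial learning rate
  1e-3 multiplied by 0.98 every 100 steps, batches of 128 drawn with
  replacement, gradients value-clipped elementwise to [−3, 3]. Full-scale
  architecture: 3×1024 GRU, update-gate bias 5, 50k steps. Desk-scale
  recipe used throughout the tests: 2×128 GRU, update-gate bias 1.0,
  1000 steps. The bias-5 initialisation needs tens of thousands of steps to
  relax and measurably throttles a 1000-step run (sampled validity 0.07 vs
  0.94+ with bias ≤ 2 on the toy corpus), so the scaled-down recipe uses
  the conventional bias of 1; both are plain constructor arguments.
* **Agent (policy gradient).** Plain SGD, on-policy batches of 128 sampled
  episodes, same clipping. Learning rate 5e-4 (augmented-likelihood and
  action-basis) or 1e-4 (both REINFORCE variants). Default σ per task:
  2 (sulphur avoidance), 8 (action basis), 12–15 (similarity), 7 (activity).
  Batch cost is the mean over episodes, keeping learning rates comparable
  across batch sizes. Invalid and duplicate sampled SMILES remain in the
  batch and are scored like any other episode — the scoring functions are
  total, and scoring invalid strings (0 or −1 by task) is itself the
  pressure toward syntactic validity.
* **Sampling** is multinomial at temperature 1, starting from GO, stopping
  at EOS or at `max_length` (default 140 tokens; truncation is flagged on
  the episode, not an error).

## Scoring functions

All scorers map any string to [−1, 1]. Sulphur avoidance: +1 valid and
sulphur-free, 0 invalid, −1 valid with sulphur (decided on parsed atoms, so
`Cl` text can never read as sulphur). Capped similarity:
`S = −1 + 2·min(J, k)/k` on FCFP4 fingerprints; gains beyond similarity `k`
earn nothing. Activity: `S = −1 + 2·P_active` from the QSAR model below.
Invalid strings score −1 for the similarity scorer, matching the stated
convention of the activity task; the sulphur task's own definition (0)
takes precedence there.

Fingerprints are RDKit Morgan fingerprints kept as unhashed
identifier→count maps: ECFP6 (radius 3, atom-type invariants) and FCFP4
(radius 2, feature invariants). Similarity is the count (multiset) Jaccard
`Σ min/Σ max`, which reduces to on-bit `|∩|/|∪|` for binary vectors; the
count form is what reproduces the reference Celecoxib/des-methyl FCFP4
value of 0.87 (the binary form gives 0.91). For the SVM the sparse
identifiers are folded modulo 2048 into binary vectors (a fixed-length
input is required; 2048 bits is the common folding width).

## QSAR protocol

Actives are Butina-clustered (RDKit sphere exclusion) on ECFP6 Jaccard
similarity with cutoff 0.4 — members sit at similarity > 0.4 from their
centroid. Clusters, sorted by descending size, are dealt out in cycles of
4 to test, 4 to validation and 16 to training, giving the 1/6–1/6–4/6
cluster split with no cluster straddling sets; inactives are split randomly
at the same ratios. The classifier is a Gaussian-kernel SVM; C and γ come
from a grid search (powers of two, 2⁻⁸…2⁸) maximising validation ROC-AUC,
scored on the decision function with a precomputed-kernel trick (pairwise
squared distances computed once, one `exp` per γ), ties broken toward
smaller C then smaller γ. The winner is refit with probability estimates;
`P_active` is used uncalibrated beyond the fitting procedure's own Platt
step. Training rows are sorted canonically before fitting so predictions
are invariant to input order (Platt's internal cross-validation otherwise
depends on row order). The fraction of inactives falling inside active
clusters is reported as a diagnostic, not used as a filter.

## Synthetic data

Two generators make the package testable at desk scale; both are
deterministic per seed and both emit only RDKit-valid SMILES.

* **Toy corpus** (`make_toy_corpus`): molecules assembled from fragment
  families (plain chains, ether/amine-rich chains, aromatic and saturated
  ring systems with linkers), 10–25 heavy atoms — the floor matches the
  full-scale corpus restraint of 10–50 heavy atoms, the ceiling is halved
  for desk scale. A configurable fraction (default 0.30) contains at least
  one sulphur atom (thioether, sulfonyl, or a thiophene/thiane ring).
* **Activity dataset** (`make_synthetic_activity_dataset`): actives are
  decorated members of a configurable number of scaffold families, each
  carrying one of three planted pharmacophore-like fragments (sulfonamide,
  pyridyl amide, N-methylpiperazine); inactives are random molecules
  verified by substructure search to carry none. Duplicates are removed
  per label.

What these emulate — and what they do not: the toy corpus reproduces the
*format* and coarse statistics (size range, heteroatom and organosulphur
prevalence, ring content) of a drug-like corpus, but its chemistry is
grammar-generated and far simpler than ChEMBL's; the activity dataset has a
planted, perfectly clean structure–activity rule, unlike assay data with
label noise and activity cliffs. Passing tests therefore demonstrate that
the machinery (likelihood training, anchored policy gradients, cluster
splitting, grid search) behaves as designed, not that full-scale chemistry
results are reproduced at these sizes.

## Study sizes used by tests and the acceptance script

Toy corpus 5,000 molecules; prior 2×128 GRU, 1000 MLE steps; episodic agent
500 steps at σ=2; REINFORCE baseline 1000 steps (the reference length for
the sulphur-avoidance comparison); evaluation samples of 12,800 sequences; Markov
recovery on 3,000 sequences from a 4-state chain (800 MLE steps, 1×32 GRU);
QSAR on 300 actives / 900 inactives. These sizes were chosen once as the
package's desk-scale study conditions.

## Numerical choices and degenerate inputs

Log-softmax uses max-subtraction; network arithmetic runs in float32 with
float64 accumulation of sequence log-likelihoods (float64 throughout when
parameters are cast, as the gradient tests do). Butina ties follow RDKit's
deterministic ordering; vocabulary serialisation preserves token order
verbatim. Empty corpora, single-class activity sets, out-of-range scores,
mismatched fingerprint kinds, unclosed brackets and over-long sequences
raise informative errors rather than propagating silently. A NaN/Inf
gradient aborts agent training with a diagnostic. With σ=0 the episodic
gradient vanishes identically at initialisation, so the agent stays
bit-identical to the prior — used as an anchoring check.

## Known limitations

* The desk-scale REINFORCE baseline drifts toward repetitive plain carbon
  chains (its unique-sequence fraction decays monotonically with training:
  0.96 → 0.92 → 0.82 → 0.73 → 0.52 over 500/1000/2000/3000/5000 steps at
  the reference learning rate of 1e-4, versus 0.98 for the episodic agent,
  with `CCCCCCCCCC`-type chains dominating the samples), but with
  batch-mean gradients the decay is slow: a ≥50% uniqueness collapse takes
  several thousand steps at this scale rather than the full-scale 1000.
  The qualitative contrast is robust; the collapse depth at 1000 steps
  is not.
* Fingerprint identifiers are unhashed; memory grows with corpus size
  (irrelevant at these scales).
* No beam search, nucleus sampling, entropy regularisation (it is known to
  hurt SMILES validity), experience replay, or multi-parameter composite
  scoring.
* `P_active` inherits whatever calibration the SVM's Platt step provides;
  no further calibration is attempted.
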