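# Methods

## Model

The package models the transcriptional response of a cell line to small-
molecule perturbations with two coupled trainable modules.

**Drug module.** Given a sample × drug dose matrix `X` (doses scaled as
`log10(µM + 1)`), the signal placed on the signaling network's drug-target
nodes is

    S = bn(X · (Wsim ⊙ Wdrug)) · WDT

`Wsim` is the frozen pairwise Tanimoto similarity of the drugs' binary
fingerprints (ECFP4-style, 2048 bits when derived from SMILES; synthetic
fixtures use shorter vectors).  `Wdrug` is a trainable d×d scaler
initialized at the identity; its off-diagonal entries, gated by chemical
similarity, let a drug borrow the target profile of chemically similar
drugs — this is the mechanism by which unknown drug-target interactions are
inferred.  `bn` is batch normalization per drug channel (momentum 0.6,
running statistics updated in training only; "momentum" weights the new
batch statistic, i.e. `running ← 0.4·running + 0.6·batch`), followed in
training by dropout at rate 0.1.  `WDT` is sparse: one trainable weight per
known prior drug-target interaction, initialized at `sign × 0.1`.  Keeping
`WDT` on the prior support is essential: the anti-zero term of its
regularizer (below) has an interior minimum near |w| ≈ 0.7 and would drag
dense, fit-irrelevant entries off zero, producing spurious attribution on
targets with no downstream influence.

An L2 penalty `λDT · Σ(Wdrug − I)²` controls how much similarity-mediated
inference is allowed.  `λDT = 0` is unconstrained; `λDT = ∞` is implemented
by freezing `Wdrug` at the identity, in which case the module degenerates
exactly to `S = X · WDT` when batch normalization is bypassed.  Default
`λDT = 5e-3`.

**Signaling module.** Signals are scattered onto the nodes of a trimmed
prior-knowledge signaling network (PKN) and iterated to steady state:

    h ← mml(W·h + b + u),   at most 120 steps,

with early exit when the max-abs state change drops below 1e-8 (the
120-step cap is the contract; the early-exit tolerance is a numerical
choice).  `W` has one trainable weight per signed PKN edge, `b` is a
trainable bias, and states start at 1e-3 (TF nodes at 0.5).  The activation
`mml` is Michaelis–Menten-like: `0.01·x` for `x < 0`, identity on
`[0, 0.5]`, `1 − 0.25/x` above — continuous, monotone, saturating at 1.
The leak (0.01) and knot (0.5) are configurable so a different convention
is a config change, not a rewrite.  TF activity is the steady state of each
TF node times a trainable projection weight (centered at 1.2 by its
regularizer).

**Loss.** Training minimizes

    loss = fitLoss + signConstraint + biasLoss + NetWeightLoss + DTLoss
         + DTregularization + 1e-3·spectralRadiusLoss + stateLoss
         + projectionLoss

- `fitLoss`: MSE of predicted vs observed TF activity over the batch.
- `signConstraint = 0.1·Σ|w|` over edges whose learned sign contradicts the
  prior sign (zero weight is not a violation).
- `NetWeightLoss`/`DTLoss = 1e-6·Σ(w² + 1/(w² + 0.5))`: L2 plus a term that
  keeps weights from sticking at zero.
- `DTregularization = λDT·Σ(Wdrug − I)²`.
- `spectralRadiusLoss = 1e10·(e^{10ρ} − 1)` when the steady-state Jacobian's
  spectral radius ρ exceeds `targetρ = e^{ln(1e-6)/120} ≈ 0.8913`, else 0
  (an always-on barrier would never reach zero).  ρ is estimated per batch
  sample by 50 seeded power-iteration steps on `diag(mml′(z))·W` at the
  cached final preactivation `z`; the batch maximum enters the loss.
- `stateLoss`: squared deviations of each node's across-condition mean,
  variance, max and min from those of uniform[0, 0.99]; a node whose max
  state is negative has its contribution multiplied by 10.  The stored
  value already carries the 1e-5 coefficient.
- `biasLoss = 1e-6·Σb²`, `projectionLoss = 1e-6·Σ(wp − 1.2)²`.

Optimization is Adam under a one-cycle schedule: linear warm-up over the
first 40% of steps from 1e-8 to 2e-3, then cosine decay back to 1e-8.
Batches (default 25) are sampled without replacement, reshuffled per epoch,
all seeded.  The default epoch budget is 5000; the synthetic studies below
use 1000, which is past convergence at their problem size.

The whole model is implemented on a small reverse-mode automatic-
differentiation engine over numpy arrays (`drugsignet.autodiff`), giving
exact gradients through the batch norm, the 120-step recurrence and the
spectral-radius power iteration; gradient correctness is tested against
central finite differences.

## Network trimming

Before model construction the PKN is restricted to nodes lying on a
directed path from some drug-target node to some TF (reachability ignores
edge signs), removing also nodes whose only in- and out-edge is a self-
loop, iterating to a fixed point.  Targets and TFs that fall off are
reported so callers can drop the affected drugs/TF columns.  Node order is
preserved, keeping weight-matrix indices stable.

## Drug-target interaction inference

Integrated gradients attribute each target's signal to the drug's dose
(baseline 0).  The eval-mode drug module is affine in the dose, so the
attribution has a closed form — effective weight × dose — which any path-
integral step count reproduces; a generic trapezoid path integral (default
64 steps) covers nonlinear heads and is checked against dense quadrature.

A per-drug cutoff on |score| comes from an error curve: candidate
interactions are masked cumulatively in ascending |score| order (ties
broken lexically), where masking an interaction zeroes that target's
signal column for the drug's samples; the cutoff is the first |score|
whose cumulative removal raises the model's MAE (all TFs, or one focal TF)
by ≥ 25% over the unmasked model.  Interactions with |score| ≥ cutoff are
inferred; an exactly zero score is never inferred (it carries no
drug-specific signal — without this rule, the fact that batch-norm offsets
give every prior-target column a baseline contribution would let a zero-
cutoff drag in the entire row).  A flat curve yields no inferred
interactions, not an error.  Ensemble confidence is the fraction of
independently trained models inferring the interaction.

Evaluation against a truth table uses the full drug × target universe with
"negative = not in the truth set" (true negatives are operationally
unknowable), exact one-tailed binomial comparison of accuracy against the
no-information rate, precision/recall/F1, the G-mean of sensitivity and
specificity, the new-discovery rate (inferred pairs outside the prior over
all inferred) and the TPR over prior interactions.

## Off-target interpretation

ΔTF is the difference between ensemble-mean predictions with the full drug
signal and with the signal masked to each drug's known (prior) targets.
Flagging requires an extreme activity (≥ 0.75 or ≤ 0.25), |ΔTF| ≥ 0.2, and
per-TF performance gates (mean of train/validation r ≥ 0.5 and validation
r > 0.4); all thresholds are configurable — one analysis in the source
lineage used a 0.6 mean-performance gate, which callers can set.

Node/edge importance for a drug→TF effect scales the drug's signal by 11
fractions spanning [0, 1], sums the focal TF's activity over those
artificial conditions as the objective, and backpropagates:
`score_b = |db| × (max − min of the node's steady state across fractions)`,
`score_w = |dw| × |w|`.  The sensitivity range is computed on node
*states*: input rows are zero off the target nodes, and the state range is
what distinguishes interior nodes that actually transmit the perturbation.

MoA pruning removes the lowest-importance node (then edge) one at a time —
single removals keep the procedure deterministic — cleaning after each
removal (drop disconnected parts, nodes unreachable from the retained
targets, nodes that cannot reach the TF) and undoing any removal that would
disconnect the last target.  Ensemble consensus keeps nodes/edges present
in ≥ 50% of member subnetworks; if that disconnects all targets, the target
threshold is relaxed and the TF re-connected through the union path with
the highest summed edge frequency.  "Simplest paths" are shortest directed
paths by edge count (ties by summed edge frequency, then lexically).

In-silico knockouts add a strongly negative value (default −10, on the
input scale) to a node's input and re-propagate, optionally combined with
full / on-target-only / off-target-only drug signal.

## TF-activity QC

Replicated activity matrices pass two permutation filters before median
merging: (1) per TF, a one-tailed two-sample Kolmogorov–Smirnov test that
the within-replicate variances are stochastically smaller than variances
from randomly regrouped rows (100 permutations preserving the group-size
structure; drop at p > 0.05); (2) per sample, the mean pairwise Pearson r
of its replicates is compared to 1000 random same-size signature subsets,
with p the fraction of null draws at least as large (no smoothing);
singleton groups are kept as-is.  On null data the sample filter retains
≈ α of samples, which the suite verifies by Monte-Carlo.

## Synthetic study design

The generators define the study conditions:

- **Network**: 40 nodes (10 drug targets, 12 TFs), forward edge density
  0.08, 70% activating signs; construction repairs reachability so trimming
  is the identity.  The generator can add feedback edges that close real
  cycles (`feedback_fraction`), and cyclic dynamics are exercised by the
  propagation and spectral-radius tests; the reference recovery study uses
  an acyclic truth (`feedback_fraction = 0`) because at desk scale feedback
  lets the shared recurrent network absorb individual interaction effects,
  making the recovery target non-identifiable — a statement about the study
  design, not about the model, which handles loops.
- **Ground truth**: edge weights follow prior signs; when cycles push the
  linear-regime spectral radius over 0.8·targetρ, only edges inside
  strongly connected components are rescaled (feed-forward edges carry no
  eigenvalue mass and keep their strength).  Biases are U(0.1, 0.4) so
  nodes carry basal activity — without basal tone an inhibitory drug-target
  interaction has no observable effect and could be neither recovered nor
  meaningfully withheld.  Each of 10 drugs gets 1–3 true targets drawn from
  (target, sign) combinations whose single-interaction effect on some TF is
  ≥ 0.25 at the standard doses with signal gain 2 (verified by paired
  noiseless simulation) — interactions must stand clearly above the noise
  floor for their removal to be detectable by the 25% error criterion;
  weak targets remain in the universe as true negatives.  One interaction
  (from a multi-target drug, preferring targets shared with another drug)
  is withheld from the disclosed prior as the planted off-target.
- **Fingerprints**: 256 bits, 40 set per drug; drugs sharing targets share
  60% of set bits, and the planted drug specifically shares bits with a
  drug whose *disclosed* prior carries the planted target, so similarity
  can mediate recovery.
- **Dataset**: 5 doses per drug (0.1, 0.3, 1, 3, 10 µM), Gaussian noise
  sd 0.05, activities clipped to [0, 1].  Five-dose response curves are
  what make the planted interaction identifiable: with fewer doses the
  shared signaling network can absorb the residual during long training.

What the fixture does *not* emulate: transcript-level measurement, plate
and batch structure, regulon-based TF-activity inference, cell-line
heterogeneity, or a realistic prior-knowledge error rate.  Passing the
recovery study therefore shows the machinery is correct and identifiable
under well-specified conditions, not that real perturbation screens will
reach the same operating point.  A misspecification probe is available by
simulating with one activation convention and fitting with another (the
activation parameters are configurable).

## Numerical choices and degenerate inputs

- Early-exit tolerance 1e-8 on the max-abs state change; convergence flags
  are reported per sample, and non-finite states raise with the iteration.
- Power iteration: 50 steps, seeded start vector; the dense-eigenvalue
  oracle is used in tests (agreement ≤ 1e-6 on ≤ 50-node graphs).
- A single-condition batch skips the variance term of stateLoss (warned).
- Tanimoto of two all-zero fingerprints raises rather than returning 0.
- Chemically dissimilar splits operate on connected components of the
  "similarity ≥ threshold" graph (a test drug must be dissimilar from
  *every* train drug, so components cannot be split); the achieved test
  fraction is reported and may undershoot.  Default threshold 0.5, the
  stricter end of the conventional 0.5–0.6 band.
- Training divergence (non-finite loss) restores the last good snapshot
  (taken every 10 epochs) instead of failing.
- A drug and a TF may coincide on one node; nothing forbids it.

## Known limitations

- The models are dataset-specific; transferring a drug module across
  datasets is supported only through the frozen-drug-module protocol.
- The drug module is linear in dose by design; nonlinear encoders are out
  of scope.
- The interaction universe is the predefined drug × target space; targets
  absent from every drug's prior can never receive signal (sparse WDT) and
  are reported at frequency 0.
- Checkpoints store dense JSON arrays — fine at network scale of a few
  hundred nodes, not tuned for genome-scale graphs.
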