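# Methods

## The statistical model

The package operates downstream of a six-class presynapse classifier. Its
error model is a row-stochastic confusion matrix `C[y, ŷ] = P(predicted ŷ |
true y)` estimated on a held-out labeled test set, at two levels: per-synapse
(used for confidence scoring) and per-neuron (used for hemilineage
inference). The canonical label order everywhere is (gaba, acetylcholine,
glutamate, serotonin, octopamine, dopamine).

**Neuron calls.** Under Dale's law a neuron releases one small-molecule
transmitter, so a neuron's transmitter is the majority vote of its filtered
presynapse predictions. The call is *uncertain* when the difference between
the top and second vote fractions is below 0.10 (the "<10%" rule, read as
percentage points of presynapse share), when the top vote is exactly tied, or
when fewer than `min_presynapses` (default 100; 30 for test-set-style
analyses) presynapses survive filtering. The margin rule is applied to the
same synapse set used for the vote. Confidence is the mean of `C[ŷ_n, ŷ_s]`
over the neuron's synapses — algebraically the winner's confusion row dotted
with the vote-fraction vector — so it lives between the smallest and largest
entries of the winner's row and equals the winner's recall for a homogeneous
neuron.

**Filtering.** Detection-score thresholds are strict ("above 50" → `>`),
distance thresholds inclusive ("no less than 15 µm" → `≥`). Rows lacking an
optional compartment or distance column pass those specific checks, so the
pipeline degrades gracefully on minimal tables; `FilterPolicy(strict=True)`
rejects them instead. Each rule's removal count is reported and logged. Two
call columns are produced, mirroring the released-data convention: `top_nt`
(vote after the detection threshold only) and `conf_nt` (vote after full
filtering).

**Entropies.** For hemilineage h with member neurons N_h,
`H(N_h) = −Σ_y p_h(y) log₆ p_h(y)` with p_h the empirical distribution of
neuron-level winners, and `H(S_h)` the unweighted mean over members of the
per-neuron synapse-label entropy `H(S_n)`. Base-6 logarithms put both in
[0, 1]; `0·log 0 := 0`. Uncertain winners are excluded from p_h (they are not
elements of the label space); the exclusion count is reported. Quadrant
labels use the 25th/75th percentiles (linear interpolation between order
statistics) of each entropy over the eligible hemilineages (> 10 neurons,
each with > 30 presynapses). Precedence: `synapse_multimodal` when
H(S_h) ≥ q75; else `neuron_segregated` when H(N_h) ≥ q75 and H(S_h) ≤ q25;
else `homogeneous` when both ≤ q25; else `intermediate`. "High"/"low" also
require clearing the opposite quartile so a degenerate spread (q25 = q75)
places everything in the middle band.

**Hemilineage Bayes factors.** Conditional on a hemilineage expressing the
transmitter subset S (|S| = m), each neuron's true transmitter is uniform on
S and its observed winner is drawn from that transmitter's confusion row,
independently across neurons. With flat priors over the C(6,m) subsets:

    p(ŷ | m) = C(6,m)⁻¹ Σ_{S} Π_j ( Σ_{y∈S} C[y, ŷ_j] / m ).

Since the likelihood depends only on winner counts, each subset contributes
`Σ_ŷ n_ŷ log q_S(ŷ)` with `q_S` the subset-mixed row, and subsets combine by
log-sum-exp — all accumulation is in natural-log space, so a hemilineage of
1,000 neurons evaluates without underflow. Pairwise Bayes factors are
`K_{m1,m2} = p(ŷ|m1)/p(ŷ|m2)` (+∞ when only the denominator model is
impossible; both impossible is an undefined comparison and raises). The
summary statistic is the one-vs-rest factor `K_{m,¬m} = p(ŷ|m)/Σ_{n≠m}
p(ŷ|n)` with the rest summed unweighted over the five other counts; m ranges
over 1..6. Evidence classes: decisive K ≥ 10², strong ≥ 10^1.5, good ≥ 10,
substantial ≥ 10^0.5, else none (inclusive bounds). Uncertain winners are
dropped before inference and counted.

**Smoothing prior.** A finite test set makes the literal C overconfident —
zero entries would make some observations impossible. Additive smoothing
`C̃(α) = (C + α)/(1 + 6α)` interpolates between the observed matrix (α = 0)
and uniform 1/6 (α → ∞). α is given a shifted exponential prior
`p(α) = λ e^{−λ(α−ε)}` on [ε, ∞), and C is replaced entrywise by its
expectation E[C̃(α)] before the likelihood is evaluated (entrywise, not a
full marginalization of the likelihood over α). Because
`C̃(α) = 1/6 + (C − 1/6)/(1 + 6α)` is affine in C, the expectation needs only
the scalar shrinkage factor `g(λ, ε) = E[1/(1 + 6α)]`, computed by adaptive
quadrature after the substitution `u = e^{−λ(α−ε)}` mapping the tail to
(0, 1]; the result is row-stochastic exactly, and the quadrature is validated
against a 10⁶-draw Monte-Carlo average of smoothed matrices in the tests. λ
has an operational reading through the expected average accuracy
`c_exp = 1/6 + (mean diag C − 1/6)·g(λ, ε)`: λ → 0 gives chance (1/6), λ → ∞
the ε-smoothed test-set accuracy; `solve_lambda_for_accuracy` inverts this
strictly increasing map by bisection on log λ (the λ = 16 ↔ c_exp pairing
depends on which confusion matrix is used, so the utility is exposed rather
than a constant). Defaults: λ = 16, ε = 1e-3 (the analysis only requires
0 < ε ≪ 1; 1e-3 keeps minimal smoothing well below any realistic off-diagonal
rate while still forbidding exact zeros).

**Consistency.** Homolog pairs are compared by call agreement and by KL
divergence between 6-class synapse-level distributions — the mean per-synapse
score vector when scores exist, else label frequencies with a pseudo-count of
1 per class. KL is natural-log; since the direction of comparison is a
convention, the symmetrized variant ½[KL(a‖b) + KL(b‖a)] is the default in
reports. When a target class has zero support, a 1e-9 uniform smoothing is
applied (flagged by construction: exact inputs stay exact).

## The synthetic generator

`simulate_study` emulates the statistical structure of real classifier
output tables, not their biology or geometry:

- per-synapse labels are i.i.d. draws from the synapse confusion row of the
  neuron's true transmitter — the exact assumption the Bayes model makes;
- synapse counts per neuron are lognormal parameterized by median (default
  202, the FAFB-style median; 386 would be HemiBrain-style) and log-SD
  (default 0.9, giving a heavy upper tail);
- hemilineages draw m_true ∈ {1, 2, 3} with probabilities (0.88, 0.10, 0.02),
  echoing the observed rarity of multi-transmitter hemilineages, and assign
  neuron shares (1.0), (0.7, 0.3), (0.6, 0.3, 0.1) by largest-remainder
  allocation; an optional "first-born deviant" flips the first neuron to a
  transmitter outside the set;
- 32% of emitted presynapses are false detections (the human-validated error
  rate for auto-detected presynapses), with labels from a configurable
  contamination distribution (default uniform; octopamine-skewed presets can
  be built by passing `contamination_probs`);
- detection scores come from two truncated normals on [0, 250]: true
  detections ~ TN(95, 42), false ~ TN(30, 40), chosen so the standard
  threshold of 50 removes 13.2% of true and 60.1% of false detections
  (matching the ~13%/~60% anchors); false detections also preferentially
  receive soma/primary-dendrite compartments and sub-threshold distances so
  every filter rule is exercised;
- compartments are axonal with probability 0.76 (the typical axonal share of
  presynapses), dendritic otherwise;
- optional mirrored left-hemisphere homologs re-sample synapses
  independently, so homolog agreement is a genuine replicate comparison.

All randomness flows from one integer seed through named per-stage
substreams (`SeedSequence` spawn keys), so identical configs give
byte-identical tables.

What the generator does **not** model: spatial synapse positions beyond the
scalar distances the filters need, morphology, correlated (non-i.i.d.)
prediction errors within a neuron or neighborhood, dataset-specific score
dialects beyond an affine change of scale, and co-transmission. Passing
tests therefore demonstrate correctness of the statistical machinery under
its own assumptions, not classifier performance on real brains — the
headline per-synapse/per-neuron accuracies of the real system require the EM
volumes and trained network and are out of scope here.

## Problem sizes and numerical choices

- The parameter-recovery experiment (`experiments.recovery_study`, analysis
  script 06, and the acceptance battery) uses 100 hemilineages per condition,
  30 neurons × 200 synapses each, diagonal-0.9 confusion, λ = 16, ε = 1e-3 —
  small enough to run in seconds, large enough that recovery rates are
  stable. Observed: 100% for m = 1 and 100% for balanced m = 2 at these
  settings.
- Quadrature tolerance for g(λ, ε) is 1e-12 absolute/relative with failure
  raised above 1e-8 estimated error; confusion-matrix row sums are validated
  to 1e-9; brentq on log₁₀ λ runs at xtol 1e-12.
- Ties: exact vote ties → "uncertain"; cell-type modal ties → "uncertain";
  ranking ties → canonical label order, flagged.
- Degenerate inputs raise informative errors rather than returning NaN: zero
  synapses (votes, entropies), all-uncertain hemilineages, zero count rows
  with β = 0, both-impossible Bayes comparisons.

## Known limitations

- A minority transmitter carried by ~10% of a hemilineage's neurons is often
  absorbed into a smaller m (the subset-mixture likelihood trades the extra
  component against the 1/m dilution); the default three-transmitter split
  (0.6, 0.3, 0.1) is regularly inferred as m = 2. This mirrors the intrinsic
  identifiability limit of the model, not a bug.
- The entrywise expectation of C̃ is a deliberate simplification (the full
  marginal over α does not factorize across neurons); it follows the model
  as specified.
- Eligibility for entropy quadrants is strict (> 10 neurons, every counted
  neuron > 30 presynapses), so small simulated studies often have too few
  eligible hemilineages for quadrant labels; the pipeline then reports
  entropies without quadrants.
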