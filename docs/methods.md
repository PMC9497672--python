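# Methods

## Information estimation

All information quantities are plug-in (maximum-likelihood) estimates on
empirical contingency tables, in bits (log base 2), with `0·log 0 := 0`.
Selection outcomes are invariant to the logarithm base: every greedy
criterion and the MILP objective are positively homogeneous in the MI
values, so a base change rescales scores uniformly without reordering them
(this is enforced as a test property).

Continuous predictors are reduced to categories by equal-frequency
(quantile) binning with `n_bins = 5` by default. Bin boundaries are taken
from quantiles of the *distinct* values, so identical inputs can never
straddle a boundary and the coding is deterministic. Columns with at most
`continuity_threshold = 20` distinct values are treated as already
categorical and encoded unchanged. Both choices follow standard practice
in the MI-filter literature; no bias correction (Miller–Madow, shrinkage)
or continuous estimator (k-NN, kernel) is applied — small-sample MI of
irrelevant columns is therefore slightly positive, which the transfer
network tolerates because such supplies are dominated by real signal.
Missing values are rejected rather than silently dropped: imputation is
the caller's responsibility and doing it implicitly would change the
estimand.

The three-way interaction information uses the convention
`I(X;Y;Z) = I(X;Y) − I(X;Y|Z)` (positive = redundancy, negative =
synergy; the XOR triple attains −1 bit). Conventions differ across the
literature; under the opposite sign the MRI criterion's correction term
would flip, so the convention is fixed here and tested for permutation
symmetry.

## The transfer network and bounds

`U` is the symmetric pairwise-MI matrix with an exactly zero diagonal;
`b_i = I(f_i;C)` the supply vector. The "infinite" capacities of the arcs
into the drain D and target T are represented by the finite
`big_M = Σ b_i`: no feasible flow can exceed total supply, so this is
capacity-equivalent and keeps solver matrices finite and well-scaled.

The per-terminal bound is precomputed as

    k_i = min( b_i + Σ top(P−1){U_ji : j ≠ i},  b_i + Σ top(P−1){b_j : j ≠ i} ).

The maxima are taken over *all* other features rather than only the
unselected ones (which are unknown before solving); a superset can only
raise a maximum, so `k_i` remains a valid upper bound while staying
precomputable. Validity is verified by exhaustive enumeration on small
instances.

## The MILP and its completion

The selection model is a gated maximum flow: continuous arc flows
`x_ij, x_iD, x_iT ≥ 0`, binaries `y` (selected set, `Σy = P`) and `v`
(terminal, `Σv = 1`, `v ≤ y`), flow balance `out − in = b_i` at every
feature node, and the gates `x_ij ≤ U_ij y_i`, `x_ij ≤ U_ij y_j`,
`x_iT ≤ big_M v_i`, `x_iT ≤ k_i`. The gating constraints linking `y` to
the flows are the minimal linear coupling that makes the selection
variables govern the flow problem: information moves only between selected
features and exits only at the terminal, while unselected supply drains to
D, keeping the model feasible for every input. Multi-hop relays among
selected features are deliberately permitted — flow balance allows them
naturally and forbidding them would require extra constraints with no
modelling justification; the exhaustive oracle implements identical
semantics, so the two routes are comparable.

Only the gated form of the terminal constraint is kept; an ungated
`x_iT ≤ E` companion would be vacuous once E is any constant ≥ big_M.
The bound `k` is applied per terminal (`x_iT ≤ k_i`) rather than as one
scalar, matching how it is derived.

Solving uses HiGHS branch-and-bound through `scipy.optimize.milp` with a
relative-gap termination criterion (default `mip_gap = 0.05`; tests use
0). Any backend exposing a relative gap and a time limit would satisfy the
interface. The absolute-gap criterion is disabled so the relative gap
alone governs termination, and when gap 0 is requested the solver's
feasibility tolerances are tightened to 1e−9 — proof-quality optimality is
the point of a zero gap, and default tolerances let incumbents overshoot
the true optimum by about 1e−6. At positive gaps the solver defaults
stand: there the incumbent is only claimed to be within the gap factor. Binaries are recovered by thresholding at 0.5; a reported gap
≤ 1e−6 is labelled `optimal`, otherwise `gap_reached`. Ties among optimal
subsets: the solver's incumbent is accepted; the oracle breaks ties by
lexicographically smallest subset then smallest terminal, and equivalence
checks compare objectives, not subsets.

The exhaustive oracle enumerates every P-subset and terminal (capped at
20,000 subsets) and solves each induced max-flow problem with networkx —
an implementation fully independent of the MILP path.

## Greedy baselines

One engine realizes all seven forward methods as (β rule, g function)
pairs; scores compose the mi_core primitives, with joint terms like
`I(f; C, f_i)` computed through an explicit joint variable. The CIFE and
IGFS g-functions are implemented exactly as tabulated in the method family
(`g_CIFE = I(f_i; C, f)`, `g_IGFS = I(f; C, f_i)`) even though some cited
originals use different forms; fidelity to the tabulated family wins.
β rules with `1/|SEL|` are undefined at the first pick, where the penalty
sum is empty anyway, so the first pick is always `argmax I(C;f)`. MIFS-U's
`I(f_i;C)/H(f_i)` term is defined as 0 for a constant selected feature
(both MI factors vanish). Ties break to the smallest feature index.
Selecting m of n features costs exactly `(2n−m+1)m/2` criterion
evaluations, which the engine records.

## Synthetic data

The generator plants three feature roles against a categorical class with
`n_classes` balanced levels:

- **informative**: `x = class_signal · c + N(0,1)` — adjacent class means
  separated by `class_signal` within-class standard deviations
  (default 2.0, a clearly-informative but non-trivial signal; at 2σ a
  single feature is far from separating the classes on its own);
- **redundant**: an informative parent plus `N(0, redundancy_noise²)`
  (default 0.5 — a strongly but not perfectly correlated copy), parents
  assigned round-robin;
- **noise**: `N(0,1)`, independent of the class.

Defaults (5 informative, 5 redundant, 40 noise, 500 rows, 2 classes)
emulate the relevant/redundant/irrelevant mixtures and
observations-to-features regimes that real tabular benchmarks stress.
What the generator does *not* emulate: heavy-tailed or categorical raw
predictors, class imbalance, label noise, and feature interactions that
are informative only jointly (XOR-type synergy); passing recovery tests
therefore demonstrates behaviour under class-conditionally independent
Gaussian signal, not under adversarial dependence structures. A
characteristic behaviour worth knowing: because a redundant twin of the
terminal has a very high-capacity arc into it, the MILP often spends one
of its P slots on that twin — planted-recovery checks ask for ≥ 4 of 5
informative features for exactly this reason.

## Benchmark protocol

Subsets are scored by stratified 5-fold cross-validated accuracy under
four off-the-shelf classifier families (k-NN, Gaussian naive Bayes, linear
SVM, LDA) with library-default hyperparameters, a fixed fold seed, and the
mean over families as the summary; methods are ranked in descending
accuracy per (classifier, P) cell with ties sharing the better rank. The
validation scheme is a design choice — stratified CV is standard and
deterministic given the seed. Failures of a single (method, P) cell are
recorded and do not abort the sweep. The observations-to-features ratio is
recorded as metadata only.

## Problem sizes and numerical choices

Verification runs use random networks with n ∈ 4–8 and P ∈ 1–4, where
exhaustive enumeration is the independent ground truth, plus the 50-feature
planted fixture for recovery and benchmarking; these sizes make every
claim checkable by brute force while exercising all code paths. Feasibility
tolerance in solution validation is 1e−6 (solver-level accuracy);
information identities are asserted to 1e−12 (pure floating-point error).
Degenerate inputs: a zero-supply network yields objective 0 with an
arbitrary feasible selection; constant features are legal everywhere and
carry zero information.

## Known limitations

- The plug-in estimator is biased upward for small samples; supplies of
  pure-noise features are small but positive.
- The MILP grows as O(n²) variables and constraints; no sparsification of
  U is attempted, so very high-dimensional inputs need the gap and time
  limits.
- The terminal-twin effect above means the selected set is not always the
  ground-truth-informative set even when recovery is otherwise perfect.
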