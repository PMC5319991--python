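# Methods

## Model

The predictor scores a microbe–disease pair by aggregating over every
cycle-free path that connects them in a heterogeneous network built from
three relations: known associations (weight 1), microbe–microbe GIP-kernel
similarity and disease–disease GIP-kernel similarity. Its assumptions are
those of guilt-by-association profile methods generally: (i) diseases with
similar microbe profiles are similar, and vice versa for microbes; (ii) a
pair connected by many short, heavy paths is more likely a true
association; (iii) the known catalogue, though incomplete, is reliable. The
model uses no information source other than Y, so it inherits Y's biases —
heavily studied diseases and microbes have richer profiles and score
systematically higher — and it cannot say anything about a microbe or
disease with no known association at all (its interaction profile is empty
and contributes no similarity signal).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `L` | 3 | maximum path length (edges); runtime and score mass both grow with L |
| `alpha` | 2.26 | decay exponent in S(p) = (Πw)^(α·len); larger α suppresses long/weak paths |
| `T` | 0.0 | similarity-edge threshold in [0,1]; association edges are immune |
| `gamma_prime_m`, `gamma_prime_d` | 1.0 | GIP bandwidth numerators; the effective γ divides them by the mean squared profile norm |

`L = 3` keeps enumeration exact yet tractable at catalogue scale while
still letting the model traverse one similarity edge on each side of a
known association (microbe → similar microbe → disease → similar disease);
`alpha = 2.26` follows the convention of closely related path-based
association predictors. `T = 0` is the conservative default: thresholding
only removes information, and with the exponential decay already
penalising weak edges, pruning is a runtime optimisation rather than a
modelling choice. All four are surfaced in the config and echoed into every
artifact, because a reported AUC is uninterpretable without them.

## Numerical choices

* **Integer kernel arithmetic.** Binary profiles make squared norms and
  squared distances integers; both are computed as integer matrices
  (`P Pᵀ`) before the single `exp`, so KM/KD are exactly symmetric with an
  exactly unit diagonal, bit-for-bit reproducible across runs.
* **Degenerate profiles.** A node that loses its last association during
  cross-validation keeps a well-defined (all-zero) profile; only a network
  with *no* associations at all leaves the bandwidth undefined and raises.
* **Two path engines, one contract.** The reference engine is the
  recursive depth-first search (mark on entry, unmark on return,
  neighbours in ascending node order, hence lexicographic path order). For
  `L ≤ 3` the full score matrix is instead computed in closed form: the
  sum of `(Πw)^(αk)` over length-k *walks* is an entry of the k-th power of
  the elementwise-powered weight matrix `B_k = W∘^(αk)`, and with a zero
  diagonal the only non-simple walks of length ≤ 3 revisit an endpoint, so
  they are subtracted exactly (inclusion–exclusion, with the doubly
  counted m→d→m→d walk restored). This reduces full-matrix prediction to a
  handful of dense matrix products and is what makes leave-one-out
  protocols — hundreds of full kernel/network/score recomputations —
  run in seconds at the 292×39 scale. The two engines agree to 1e-10
  against a permutation brute-force oracle in the test suite; the closed
  form uses a different (but fixed and deterministic) summation order than
  the lexicographic DFS sum. Tiny negative inclusion–exclusion residue
  (below 1e-15, from float cancellation) is clamped to 0 so the "score 0
  iff no path" invariant holds.
* **Ranking and ties.** A held-out pair's rank against its candidate set
  uses mid-ranks for ties, so the AUC equals the tie-corrected
  Mann–Whitney statistic. Score-table ties are broken by (disease,
  microbe) name order for byte-stable output.
* **One ROC construction for unequal candidate sets.** Local LOOCV ranks
  each test pair against a different number of candidates, so every test
  round is reduced to its normalised exceedance x = (rank−1)/n_candidates
  ∈ [0,1]; the pooled ROC is the staircase of the empirical CDF of x over
  a uniform false-positive axis, and its trapezoidal area equals
  mean(1−x) exactly. For shared candidate sets (global LOOCV, k-fold) this
  is precisely the Mann–Whitney AUC. Exceedances are sorted before
  averaging so the statistic is invariant to record order, which makes
  k-fold with singleton folds reproduce the global-LOOCV AUC exactly.
* **Candidate sets.** Global protocols rank against all pairs unverified
  in the *original* matrix, fixed across rounds. Local LOOCV ranks against
  the test disease's other unconfirmed microbes; a disease with no
  unconfirmed microbes forces rank 1 with an empty candidate set (its
  exceedance is 0).
* **k-fold granularity.** Kernels are recomputed once per fold (all fold
  pairs removed together), not per test pair — the fold is the training /
  test split. `auc_sd` is the sample standard deviation (ddof = 1) over
  repeats.

## Synthetic data

The generator plants a bipartite block model: round-robin community
assignment (deterministic block sizes), within-community association
probability `p_in`, cross-community `p_out`, and a repair step that gives
every empty row/column one within-community association (a node with no
associations is invisible to profile similarity). `p_in = p_out` yields the
density-matched no-signal null.

Defaults are a reduced study of 100 microbes × 20 diseases, 4 communities,
`p_in = 0.5`, `p_out = 0.005` (≈260 associations). Chosen by calibration
simulation before the test suite was frozen: per-node degrees (≈13 per
disease, ≈2.6 per microbe) then sit near the real 292×39/450-association
catalogue's (11.5 and 1.5), and the planted signal is cleanly separated
from the null. At smaller sizes (e.g. 60×12) the null AUC itself is
unstable across seeds (observed 0.47–0.85): the method's degree bias does
not average out over a handful of diseases. Two null behaviours are worth
knowing: the null AUC sits slightly *below* 0.5 (holding out an edge weakens
the test pair's own profiles, an anti-signal the candidates don't suffer),
and single-seed null AUCs still scatter by a few hundredths, so the
acceptance test brackets the 5-seed mean. The `hmdad-scale` preset (292 ×
39, `p_in = 0.12`, `p_out = 0.005`) lands 436–490 associations across seeds,
matching the real catalogue's size and sparsity for runtime/integration
testing.

What the generator does **not** emulate: real taxonomic name structure,
heavy-tailed per-disease degree distributions, multi-scale community
overlap, or curation noise (false positives in Y). Passing the synthetic
benchmarks therefore shows the pipeline recovers planted profile-sharing
structure — not that it attains any particular AUC on the real catalogue,
where degree heterogeneity is stronger and community structure fuzzier.

## Problem sizes used in checks

The acceptance script runs the full protocol stack on the default 100×20
fixture (LOOCV over ≈260 rounds, 5-fold CV with 25 repeats), plus a
full-scale 292×39 global LOOCV (≈450–490 rounds); the whole script
completes in well under a minute on one CPU, which is also why the test
suite can afford end-to-end protocol runs rather than mocks.

## Known limitations

* Cold start: new microbes/diseases without associations cannot be scored
  meaningfully (empty profiles).
* Degree bias: profile-derived similarity systematically favours
  well-annotated nodes; null AUCs quantify this.
* Exact enumeration only: no sampling approximation is provided, so
  runtime grows quickly with `L > 3` on dense networks (the closed form
  stops at 3; DFS handles larger L at small scale).
* Names are opaque strings; entries curated at different taxonomic ranks
  are distinct nodes.
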