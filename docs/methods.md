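# Methods

## Scope and model

`bidicore` estimates a weighted directed functional network from multi-trial
time series and exactly decomposes it into bidirectionally inseparable
cores. The package operates on plain delimited-text matrices; upstream
imaging concerns (file formats, parcellation, nuisance regression) are out
of scope, as are spatially autocorrelated null maps and meta-analytic maps,
which require external data.

### Preprocessing

Each (trial, node) series is z-scored, then band-pass filtered with a
zero-phase (forward–backward) Butterworth filter. Defaults: band
0.008–0.08 Hz, order 2, sampling interval 0.72 s — the standard
resting-state fMRI regime. Zero-phase filtering is used because phase
distortion would bias lagged-regression estimates; the effective magnitude
response is the squared filter magnitude, which the tests verify against
the analytic response on pure sinusoids. Constant series are rejected with
the offending trial and node named.

### Directed edge weights (NDTE)

For each ordered pair (X, Y) a bivariate VAR(T) (default T = 10) is fitted
by ordinary least squares with an intercept, pooling trials as independent
realizations: each trial contributes its own lagged rows and the first T
frames of each trial are never used as responses, so no lag crosses a trial
boundary. The nested univariate AR(T) of the target is fitted on the same
response rows. Under the linear-Gaussian model the information quantities
are log variance ratios:

- TE(X→Y) = ½ ln(σ²_reduced / σ²_full)
- I(Y_{i+1}; Y^i) = ½ ln(Var(Y) / σ²_reduced)
- normalization = ½ ln(Var(Y) / σ²_full) = TE + I(Y_{i+1}; Y^i)
- NDTE F_XY = TE / normalization.

All variances use the maximum-likelihood convention (SSR / n_eff) over the
same rows, so SSR_full ≤ SSR_reduced ≤ SST holds exactly and the bounds
TE ≥ 0 and 0 ≤ F_XY ≤ 1 are structural. If the normalization is zero
(target unpredictable and independent) F_XY is defined as 0 with a logged
warning. Note that for *raw* white-noise inputs the sample NDTE is a ratio
of two vanishing noise terms and does not concentrate at 0; the estimator
is intended for preprocessed (autocorrelated) series, where the target's
self-prediction anchors the denominator. A Levinson-type recursion could
replace OLS here; OLS is used because both are consistent for stable VARs
and OLS keeps the nested-variance comparison exact in sample.

### Edge significance and density

Surrogate source series are generated by block permutation within each
trial: contiguous blocks (default size 10, matching the VAR order) are
reordered uniformly at random, preserving within-block autocorrelation
while destroying cross-series coupling. A trailing short block is treated
as one extra block, so no samples are dropped. 100 surrogate NDTE values
per edge feed a Gaussian-kernel density estimate (Silverman bandwidth, IQR
variant); the p-value is the analytic upper-tail mass of the mixture at the
observed NDTE — one-sided, because only excess predictability is evidence
of influence. Degenerate surrogate sets fall back to the empirical rank
p-value. Edges are kept if p < α/m with α = 0.05 and m the number of
ordered pairs (Bonferroni), then the strongest edges are retained to a
target density (0.05 / 0.10 / 0.20 are the conventional choices; ties at
the cutoff break lexicographically by (source, target) for
reproducibility). Under an independent-series null the test is calibrated
but mildly conservative (observed rejection ≈ 0.03–0.04 at α = 0.05 over
200 replicates) because kernel smoothing fattens the surrogate tail.

Randomness is fully reproducible: every surrogate stream is seeded by the
tuple (run seed, source index, target index, surrogate index), so per-edge
results are independent of iteration order and identical inputs plus an
identical seed give bit-identical networks.

### Exact core extraction

The strength of bidirectional connections across a bipartition is
min(w(V_L→V_R), w(V_R→V_L)); the min-cut weight w^mc of a (sub)graph is its
minimum over all bipartitions, with w^mc = 0 for single nodes. A complex is
an induced subgraph with w^mc > 0 strictly greater than the w^mc of every
induced strict supergraph. Coreness k_v is the largest w^mc over complexes
containing v (equivalently, over all subnetworks containing v), and 0 for
nodes in no complex.

Two exactness facts drive the implementation:

1. *Min-cut.* min over bipartitions of min(fwd, bwd) equals
   min_{∅≠S⊊V} w(S→V∖S): every bipartition contributes both of its directed
   cuts, so the objective's minimum is the global minimum **directed** cut.
   That is found exactly with 2(n−1) max-flow computations against a fixed
   source (networkx preflow-push). This route was chosen after verifying
   numerically that the min(fwd, bwd) objective is *not* submodular, so
   pendant-pair (Queyranne-style) minimization carries no guarantee here.
   Below `brute_force_limit` nodes (default 15) all 2^(n−1) − 1 bipartitions
   are enumerated instead; the two paths are tested for equality.

2. *Hierarchy.* If S straddles a min-cut (L, R) of its parent, the induced
   bipartition (S∩L, S∩R) crosses via subsets of the parent's crossing
   edges in each direction, so w^mc_{G[S]} ≤ w^mc_parent. Since a complex
   must strictly exceed every superset — in particular every ancestor — no
   complex straddles any ancestor's min-cut. Recursive min-cut bisection
   therefore visits every complex, and a visited subset is a complex iff its
   w^mc strictly exceeds all its ancestors' (checked with relative tolerance
   1e-9; ties within tolerance do not qualify, the strict-inequality reading
   of the definition). If the whole graph's w^mc is 0 it is not a complex
   and the recursion simply continues into both sides of the zero cut.

Brute-force enumeration of the definition over all induced subgraphs is the
correctness contract, tested on 100 random digraphs with n ≤ 8 and grid
weights chosen to produce exact ties.

### Comparison metrics

- *Direction-ignored cores*: run the same extraction on W′ = (W + Wᵀ)/2;
  the simple-sum cut measure with its ½ factor is exactly the bidirectional
  strength of the symmetrized network.
- *Weighted degree*: sum of incident edge weights, directions ignored.
- *s-core*: iterative peeling of a symmetric network at increasing strength
  levels; levels are the distinct strengths encountered during peeling
  (parameter-free, exact), and a node's s-coreness is the largest level it
  survives.
- *Functional rich club*: G_FRIC(k) = within-subset weight + subset
  out-strength − subset in-strength, with a demo routine that exhaustively
  finds the largest subset scoring in the top 5% of its size class (small
  graphs only; the enumeration is exponential by construction).
- Cross-condition aggregation mirrors the coreness convention: divide by
  the per-condition maximum, then (optionally weighted) average — weights
  support pre-averaging paired resting sessions into one condition.

### Statistics

Pearson correlations carry BCa bootstrap 95% CIs (default 10,000 joint
pair resamples; bias correction from the fraction of replicates below r,
acceleration from jackknife skewness). Degenerate cases — zero-spread
bootstrap distributions or an infinite bias z-score — fall back to the
percentile interval with a logged warning, since BCa is undefined there.
Monte-Carlo coverage at ρ = 0.5, n = 200 is 93–97% over 500 replicates.
The regression confidence band implements
ŷ ± t_{0.975, n−2} · s_err · sqrt(1/n + (x−x̄)²/Σ(x_i−x̄)²) exactly, and the
one-way ANOVA reports F, p, and η² = SS_between/SS_total.

## Synthetic data

The generators are pure functions of their specs (seed included) and define
the study conditions for every test:

- `fig1d_like`: reciprocal quartet at weight 3, attached node at weight 2,
  feedforward ring plus one-way periphery–core links at weight 3. The
  periphery is deliberately wired densely enough (heavy one-way receivers
  and senders) that symmetrization pulls it into the top core, reproducing
  the qualitative contrast between the bidirectional and direction-blind
  analyses. The exact weights are this package's choice; only the
  qualitative hierarchy is meaningful.
- `two_modules`: two reciprocal triangles joined by one reciprocal bridge —
  the global-structure contrast case (two equal top cores).
- `random_digraph`: seeded weights on the {0, 0.1, …, 1.0} grid at 70%
  density, chosen so exact ties exercise tolerance handling.
- VAR simulation: Z_t = A Z_{t−1} + ε_t with unit-variance innovations and
  a burn-in of max(50, 10 × lag span) discarded so trials start at the
  stationary distribution (verified against the discrete-Lyapunov
  covariance). The planted-core benchmark couples nodes 0 and 1
  reciprocally at 0.4 with a feedforward chain over the remaining nodes,
  20 trials × 500 frames — at this strength the full pipeline recovers the
  pair as the strongest complex in ≥ 90% of seeds. Only lag-1 structure is
  planted even though estimation uses T = 10, keeping the analytic
  covariance oracles tractable while exercising the full lag depth.

What the generators do **not** emulate: hemodynamic convolution,
measurement noise spectra, physiological confounds, spatial autocorrelation
between parcels. Passing tests therefore demonstrate correctness of the
estimators and the exact search under the stated generative model, not
robustness to fMRI-specific artifacts.

## Numerical choices and limitations

- Residual variances use SSR/n_eff; rank-deficient designs fall back to
  pseudo-inverse solutions with a logged warning.
- Negative sample TE (impossible here by nesting, possible if callers mix
  sample ranges) is clipped to 0 and logged.
- mc-weight comparisons use relative tolerance 1e-9; edge weights serialize
  with 17 significant digits and are re-read with round-trip float parsing,
  so write-then-read reproduces objects exactly.
- Whether thresholded edge weights should be NDTE values or binarized
  significance is ambiguous in the estimation literature; NDTE values are
  used because downstream cuts need weights.
- The per-target normalization (reduced AR fit and Var(Y)) is computed from
  pooled-trial fits, not per-trial-then-averaged.
- Test and benchmark problem sizes (5-node pipelines, n ≤ 8 oracle graphs,
  200-replicate calibrations) are chosen so the whole suite runs on a
  single CPU in minutes while still pinning every exactness and calibration
  claim; the algorithms themselves scale to hundreds of nodes via the
  max-flow path.
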