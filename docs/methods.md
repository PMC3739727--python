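# Methods

This note documents the models, conventions and numerical choices behind
`cppspace`, and what the synthetic benchmarks do and do not demonstrate.

## Structures

Peptides enter as one-letter sequences restricted to the 20 standard amino
acids; anything else must be supplied as an SDF record. Structures are built
with RDKit's sequence builder in the neutral, non-amidated form — free
N-terminal amine, free C-terminal carboxylic acid — as the most fundamental
representation of the chain, with all hydrogens explicit. No pH-dependent
protonation is applied: the descriptor families capture charge-relevant
chemistry through element patterns and atomic-property weights, and an
*in vacuo* neutral convention keeps the structure independent of an assumed
medium. Condensation is checked by formula conservation (an *n*-mer's atoms
equal the residue sums minus (n−1)·H₂O).

Conformers come from distance-geometry embedding (ETKDGv3, fixed random
seed) followed by MMFF94 minimization. This is a deliberate, documented
substitution for legacy molecular-mechanics engines: 3D descriptor *values*
are conformer-dependent and will not bit-match numbers produced by other
geometry programs. All 3D checks in the test suite are therefore
property-based (closed forms, brute-force oracles, rigid-body invariance)
rather than value-matching. Embedding retries with derived seeds before
failing, and determinism under a fixed seed is asserted.

Topological distances are bond-count shortest paths over the
hydrogen-depleted graph. Restricting the full-molecule distance matrix to
heavy atoms is exact because hydrogens are leaves and never carry a shortest
path.

## Descriptors

Graph conventions follow the published definitions of each family: Geary
autocorrelations and the pattern/topological counts operate on the
H-depleted graph; 3D-MoRSE, WHIM and the constitutional scalars on the full
H-explicit structure. Atomic weights (mass, van der Waals volume, Sanderson
electronegativity, polarizability) are shipped as a CSV data file and always
used carbon-scaled, so w(C) = 1 for every scheme.

* **Geary** `GATS_k(w)` = mean squared weight difference over ordered atom
  pairs at lag *k* (halved, per-pair), divided by the sample variance
  (ddof=1) of the weights. Undefined (NaN) when no pair sits at the lag or
  the weights are constant — notably the unit-weight scheme, which is why
  the default grid computes GATS only for the four weighted schemes
  (lags 1–8).
* **3D-MoRSE** `Mor_s(w) = Σ_{i<j} w_i w_j sinc(s·r_ij)` with
  `s = signal − 1` in Å⁻¹ over signals 1–32 and all five schemes. Signal 1
  reduces to the closed form `[(Σw)² − Σw²]/2`.
* **WHIM symmetry** `G_m(w)`: atoms are scored along principal axis *m* of
  the weight-normalized covariance of centered coordinates;
  `γ_m = 1/(1+H)` where `H` is the information content of the split into
  centro-paired (`n_s`) and unpaired (`n_a = A − n_s`) atoms,
  `H = −(n_s/A)log₂(n_s/A) − n_a(1/A)log₂(1/A)` with zero-count terms
  dropped. The pairing tolerance on scores defaults to 0.15 Å (the handbook
  definitions leave it unspecified; 0.15 Å is small against bond lengths but
  tolerant of minimization jitter) and is configurable. Axes whose
  eigenvalue vanishes (beyond the geometric rank, e.g. the second axis of a
  linear molecule) yield NaN.
* **Pattern counts**: `B04[N-N]` flags an N,N pair at topological distance
  4 (present in asparagine and histidine); `T(N.S)` sums distances over all
  N,S pairs; `nCt` counts sp³ carbons with exactly three carbon neighbours
  and one hydrogen; `nROR` counts oxygens single-bonded to two sp³
  non-carbonyl carbons; `nRCONHR` counts secondary-amide motifs, one per
  amide nitrogen — an *n*-mer of standard residues scores one per backbone
  peptide bond, excluding bonds to proline (tertiary amide) and the primary
  side-chain amides of asparagine/glutamine.

Undefined cells are NaN end to end and serialized as `NA`; downstream
preprocessing drops any column containing one rather than imputing. The
default grid yields 8·4 + 32·5 + 3·5 + 7 = 214 named columns.

## CP-response

Records are first collapsed within (study, peptide, concentration) to the
maximal response over time, then concentration-normalized (concentrations
canonicalized to µM). Dispatch per study: direct penetratin ratio where
penetratin was measured; otherwise the bridged route through the
positive control with the most supporting ratios (ties alphabetical), using
response factors computed as medians of per-study control/penetratin ratios;
otherwise the unit-matched route against the global median penetratin
normalized response for that unit (the unit string is the matching key).
Studies lacking any usable route leave the peptide flagged uncomputable
rather than dropped. Multiple concentrations of one peptide within a study
produce per-record CP values that are medianed within the study before the
cross-study median — keeping the linearity assumption local to each study.

Consequences asserted in the suite: study-scale invariance of the direct
and bridged routes, global unit-scale invariance of the unit-matched route,
and the exact identity CP(penetratin) = 1.

## Chemical space

Reduction drops NaN-containing and constant columns, then greedily prunes
later columns correlated above |r| = 0.95 with an earlier kept column —
keeping the earlier column makes the scan deterministic and the output order
a subsequence of the input. Z-scaling uses sample statistics (ddof = 1).

PCA eigen-decomposes the covariance of the scaled matrix via SVD. The
predictive ability Q² uses row-wise 7-fold cross-validation with a seeded
fold assignment: for component *j*, PRESS_j is the residual of held-out rows
reconstructed from *j* loadings fit without them, referenced to the in-model
residual after j−1 components, and cumulative Q²_k = 1 − Π PRESS_j/SS_j.
When the matrix is exactly rank-k the ratio saturates at 1 beyond rank.
"Predicted variation" of a variable — the feature-selection statistic,
thresholded at 0.30 — is implemented as the fraction of that variable's
variance explained by the retained components; this is one natural reading
of a per-variable model statistic, and the alternative (per-variable Q²)
could be substituted behind the same interface.

Clustering is UPGMA on Euclidean distances (SciPy linkage), cut by cluster
count; the dendrogram exports to Newick with branch lengths equal to
merge-height differences. An O(n³) brute-force average-linkage oracle in the
test suite confirms identical merge sequences for all small instances.

## QSPR

Grubbs screening is iterative and two-sided: remove the single most extreme
point while `G = max|x−x̄|/s` exceeds
`G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²))`, `t` the upper α/(2n) t-quantile
with n−2 df; stop otherwise or below n = 3. Outliers are removed once, on
the raw median CP-responses, before any model fit; the count removed is
reported, never assumed.

Stepwise MLR adds, at each iteration, the excluded column with the smallest
partial-F p-value and then removes included columns whose p ≥ 0.10, to a
fixed point. Because the forward step selects the *minimum* p over all
candidates, comparing that minimum against 0.05 directly would admit a
pure-noise predictor far more often than the nominal level (about 40% with
ten candidates). The entry threshold is therefore Bonferroni-corrected by
the number of candidates examined, which restores the nominal admission
rate; `entry_correction="none"` recovers the uncorrected classic behaviour.
Near-collinear candidates (tolerance 1 − R² against the included set below
1e−4) are refused, forward search stops once the residual is numerically
zero, and repeated selection states terminate the loop with a cycle flag.
The response is modeled untransformed by default (a log10 option exists).

Robustness analysis refits the model on ten responses multiplied by
i.i.d. Uniform(0.90, 1.10) noise (replicate seeds derived from the master
seed by fixed offsets) and counts retention over the 11 models; the robust
set keeps descriptors retained in more than half. The report lists *all*
counts with the rule-passing subset marked, so near-majority descriptors
remain visible. Raising the majority threshold can only shrink the set, and
zero-width noise makes every replicate identical to the base — both asserted.

## Synthetic data

The uptake generator emulates a multi-study literature compilation: true
relative uptake log-uniform over [0.001, 3] (three orders of magnitude, with
the reference pinned at 1), study-specific multiplicative scales built from
a per-unit base level times a log-normal study effect, incubation
concentrations drawn from the printed literature set (0.01–1600 µM),
heterogeneous unit/technique labels, and a configurable design of
penetratin-bearing / alternative-control / control-free studies
(default 60/25/15%). Noise is multiplicative log-normal (σ = 0.3 in the
benchmark), consistent with positive responses and inter-laboratory
variation. By construction the normalization assumptions hold exactly:
responses are linear in concentration, there is no time effect beyond the
collapsed maximum, and no cell-line or label effect. Passing recovery tests
therefore demonstrates correctness of the estimator under its own
assumptions — not robustness to assumption violations (saturating uptake,
thresholds, cell-line specificity), which real data will show.

The QSPR generator draws standard-normal descriptor columns (optionally
with a correlated pair to exercise pruning) and a sparse linear response;
the noise is calibrated from the requested population R² via the signal
variance Σβ².

Benchmark problem sizes (30 studies × ~12 peptides for response recovery;
150 × 50 with 3 true predictors for selection recovery; n ≤ 8 for the
clustering oracle, 100 instances) were chosen as the smallest scales at
which the statistical claims are meaningful and stable across seeds.

## Known limitations

* 3D descriptor values depend on the conformer engine; only their invariance
  and oracle properties are portable across programs.
* The WHIM symmetry formula has minor variants across handbook editions; the
  implemented form is stated above and the tolerance is exposed.
* The unit-matched CP route inherits between-study scale noise that the
  direct and bridged routes cancel; its estimates are accordingly noisier.
* Hydrogen weights are not folded into heavy atoms for the 2D
  autocorrelations (plain H-depletion).
* The author-class keyword map is a small editable table; real literature
  phrasing is far more varied.
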