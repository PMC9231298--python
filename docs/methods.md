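# Methods

## Scope and data model

The package rebuilds a descriptor-based regression pipeline for BRD-4
inhibition: curated SMILES/IC50 tables in, a small multi-linear model
over interpretable structural descriptors out, plus the published
seven-descriptor model as a fixed predictor. Activities live on the
pIC50 scale (molar −log10; `pIC50 = 9 − log10 IC50[nM]`), the range of
interest spanning roughly 4.8 (15 µM) to 9 (1 nM).

## Curation

Curation removes, in order: unparseable SMILES; multi-fragment inputs
and molecules containing elements outside an organic allow-list
(H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I); records without a usable
activity (missing, non-numeric, or comparator-qualified values such as
">10000"); and duplicates by canonical, stereo-aware SMILES. Duplicate
groups with consistent activity (pIC50 agreeing to 1e-6) keep their
first record; groups with conflicting activities are discarded
entirely — conflicting measurements are ambiguous, and keeping either
would be arbitrary. Multi-fragment salts are discarded rather than
desalted: the salt form was measured, the parent was not. The
curation ledger always balances (`n_output = n_input − Σ removals`)
and curation is idempotent.

## Geometry

Only `com_*` descriptors need 3D coordinates. User-supplied SDF (V2000)
conformers are used verbatim when present; otherwise a seeded ETKDGv3
distance-geometry embedding with MMFF94 relaxation (UFF fallback)
provides a deterministic conformer. This is a generic geometry
convention, not a quantum-chemical optimisation; `com_*` values are
therefore convention-dependent, every prediction records its geometry
provenance (`sdf` vs `embedded`), and embedded-geometry predictions
should be read as approximate in that one descriptor.

## Atom typing and descriptors

Typing operates on the hydrogen-suppressed graph under RDKit's default
aromaticity model (recorded implicitly by the RDKit dependency pin).
The rules that the original descriptor software leaves implicit are
fixed here explicitly:

- sp³ carbon: non-aromatic carbon with ≥1 bond, all bonds single (an
  isolated atom carries no hybridisation evidence);
- planar nitrogen: aromatic, double-bonded, or conjugated (bonded to
  an aromatic atom or a carbonyl carbon);
- lipophilic: carbon with only carbon heavy neighbours, or Cl/Br/I;
- acceptor: N/O excluding cations, amide/thioamide N, and
  pyrrole-type aromatic N–H; donor: N/O bearing ≥1 H;
- sulfone sulfur: S with exactly two S=O double bonds and two single
  bonds.

Pair-frequency descriptors `f<source><target><k>B` count *target*
atoms whose nearest source atom (bond-count shortest path, the atom
excluded from its own source set) is at exactly `k` bonds. This
nearest-source reading implements the exclusion behaviour the
descriptor names imply: a target with any closer source does not
count, and a target with no source within `k` bonds does not count.
Distances across disconnected fragments are infinite. `com_<el>_<r>A`
uses a mass-weighted center of mass over all atoms including explicit
hydrogens and a closed shell (≤ r). `Saturated_Carbo_Rings` counts
SSSR rings that are all-carbon, non-aromatic, all-single-bond, so
fused decalin contributes two and envelope rings are not
double-counted.

## Pruning, splitting, selection

Pruning removes columns whose most frequent value occupies more than
98% of molecules, then enforces pairwise |Pearson R| ≤ 0.95 by a
canonical greedy pass ordered by |correlation with y| (descending,
ties lexicographic by name) — so the survivor set is independent of
input column order and each violating pair keeps its more predictive
member.

Splitting is a seeded permutation with round-half-up on the training
fraction (980 molecules at 80% give 784/196).

Subset selection is a genetic algorithm over fixed-size descriptor
subsets with Q²_LOO fitness (closed-form PRESS via the hat matrix;
leverages at 1 raise rather than silently blow up). Operators:
tournament selection (size 3), uniform crossover sampling the union of
parent genes while preserving shared genes, point mutation swapping
one descriptor, elitism 1 (making best fitness monotone), and one
random-immigrant individual per generation to keep exploration alive
after convergence. Defaults: population 50, crossover 0.8, mutation
0.1, a 10,000-generation cap with early stop after 50 stall
generations. All randomness flows from a single integer seed; a rerun
is bit-identical.

Model size is the breaking point: the GA is run once per size 1..max,
and the chosen size is the smallest `s` with `Q²(s+1) − Q²(s) < δ`
(δ = 0.01 by default — a verbal plateau rule made numeric; with δ = 1
the rule degenerates to univariate, which is intended).

## Validation

- Fit: R² = 1 − RSS/TSS; R²adj; RMSE with denominator n; MAE;
  s = √(RSS/(n−p−1)); F = (R²/p)/((1−R²)/(n−p−1)); Lin's CCC with
  population moments. RMSE(n) and s(n−p−1) are both reported because
  the two conventions are both in circulation and differ visibly at
  n in the hundreds.
- LOO: Q²_LOO, RMSE_cv, MAE_cv and CCC_cv from the closed-form LOO
  predictions.
- LMO: each iteration leaves out a fraction (default 30%, 1000
  iterations), refits, and accumulates left-out PRESS and TSS (about
  the retained mean); the score is 1 − ΣPRESS/ΣTSS pooled over
  iterations. Pooling, rather than averaging per-iteration ratios, is
  what makes the statistic converge to Q²_LOO as the left-out block
  shrinks to one molecule; degenerate refits (a count descriptor
  constant in a subsample) are skipped.
- Y-scrambling (default 300 iterations): mean R² and Q²_LOO after
  permuting activities; for noise data the scrambled mean R² sits near
  p/(n−1).
- External: Q²F1 (training-mean reference), Q²F2 (external mean),
  Q²F3 (per-point training variance), R²ex (squared Pearson), CCCex,
  RMSE/MAE. Q²F1 ≥ Q²F2 holds identically.
- Applicability domain: leverages from the training X'X with
  intercept, h* = 3(p+1)/n, standardized residuals against the
  training s, outliers at |standardized residual| > 3. Training
  leverages sum to p+1.

## The packaged model

The shipped predictor (`assets/model_a.json`) holds the published
intercept 4.27, the seven coefficients (+0.093 fsp3CringC2B, +0.108
com_C_4A, +0.391 Saturated_Carbo_Rings, +0.428 fsulfonSaroC8B, +0.625
flipoacc3B, +0.921 fsp3OaroN6B, −0.367 fplaNN4B), their standard
errors, n_training = 785 and h* = 0.031. It is evaluated exactly as
printed and never refitted. Its original training set and PM3
geometries are not distributed, so per-molecule reproduction of the
original predictions is out of scope; what the package guarantees is
exact evaluation of the equation and faithful recomputation of its
descriptor semantics.

## Synthetic data: what it emulates, what it does not

The generator assembles molecules from a fragment library
(`assets/fragments.json`: ten scaffold templates × twenty-one
substituents, spanning sulfones, alkoxy groups, N-heterocycles,
amines, saturated carbocycles, halogens) by seeded random combination,
deduplicated on canonical SMILES. Activities are generated directly on
the pIC50 scale as a known linear model over descriptors the package
itself computes, plus Gaussian noise — defaults: n = 200, planted
descriptors fsp3CringC2B/flipoacc3B/fplaNN4B with coefficients
0.40/0.62/−0.37 (the scale of the packaged model's stronger terms),
intercept 4.27, noise σ = 0.1. The candidate pool for selection
studies holds 30 columns (27 typed pair frequencies, the ring count,
and two sparse published descriptors).

This emulates the *statistical* structure of the problem — integer
count descriptors with realistic sparsity and inter-correlation, a
low-dimensional linear signal buried in a redundant pool — and
supports exact parameter-recovery tests. It does not emulate real
BRD-4 structure–activity: real activity is not exactly linear in any
descriptor subset, real noise is not Gaussian-homoscedastic, and real
chemistry is far more diverse. Passing recovery tests therefore
demonstrates correctness of the machinery, not predictivity on new
chemistry.

Decoy columns (`make_decoy_pool`) stress pruning: exact duplicates
(named to lose the lexicographic tie-break, since an exact duplicate
ties its source on |corr to y|), 99.5%-constant columns, and scaled
pure-noise columns.

## Numerical choices and problem sizes

OLS via `numpy.linalg.lstsq` with rank checks naming collinear
columns; standard errors from s²(X'X)⁻¹; leverages via QR. Duplicate
activity tolerance 1e-6 pIC50. Recovery studies run 20 seeded
replicates of the full generate → featurize → prune → breaking-point
chain at n = 200 with the GA at its default population/patience and a
400-generation cap — at these pool sizes the search converges long
before the cap, and the whole study completes in about a minute.

## Known limitations

- Descriptor values depend on the aromaticity model and on the typing
  rules above; other descriptor software will differ at the margins.
- `com_*` descriptors inherit conformer-generation convention;
  user SDF geometries are the only way to pin them.
- The GA is stochastic; reproducibility is per-seed, and for very
  large pools the returned subset is a best-found, not a certified
  optimum.
- Q²_LMO uses pooled aggregation; implementations that average
  per-iteration ratios will report slightly different values on the
  same data.
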