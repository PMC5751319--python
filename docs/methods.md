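# Methods

## Model

Given N labeled feature vectors in C classes, kernel discriminant analysis
(KDA) seeks directions in the Gaussian-kernel feature space that maximize
between-class over within-class scatter. All computation happens through
the N×N Gram matrix `K[i, j] = exp(-||x_i - x_j||² / s²)`: with `M_i` the
class-mean kernel column, `M` the grand-mean column and `K_i` the N×N_i
block of kernel values against class i,

    M̃ = Σ_i N_i (M_i − M)(M_i − M)ᵀ
    L̃ = Σ_i K_i (E − (1/N_i) 1) K_iᵀ

and the coefficient matrix `alpha` (N×d, d ≤ C−1) collects the top-d
generalized eigenvectors of (M̃, L̃). A sample projects to
`t(x) = alphaᵀ [K(x, x_j)]_j`, and because the Gaussian kernel gives
`K(x, x) = 1`, the squared distance from φ(x) to the discriminant subspace
— the kernel reconstruction error — is simply `RE(x) = 1 − ||t(x)||²`
once the columns of `alpha` are orthonormal in the kernel metric.

The kernel is implemented as `exp(-||·||²/s²)` with no factor 2 in the
denominator; the alternative `exp(-||·||²/(2s²))` differs only by a √2
rescaling of the candidate grid.

## Scale selection

The selector treats scale choice as a novelty-detection calibration. From
the largest class it extracts:

- the centroid c, the per-sample distances to c, and their median m;
- a neighborhood radius ε = mean distance of each class member to its u-th
  nearest neighbor in the *full* dataset (u = 8 by default).

A sample is **edge** if its distance to c strictly exceeds m *and* its
ε-neighborhood contains other-class samples; **internal** if its distance
is strictly below m *and* its ε-neighborhood is pure. Both rules are
strict, so samples can be unassigned; they belong to neither set. Because
the far/near test uses the median distance to the centroid rather than
local tangent-plane geometry, a class lying on a spherical shell does not
degenerate to "everything is edge" — at most the half beyond the median
can qualify.

For each candidate scale s the KDA model is fitted on the full labeled
dataset (KDA needs ≥ 2 classes, so the largest class alone cannot be the
fit set) and the objective

    f(s) = ( ‖RE(edge)‖∞ − ‖RE(internal)‖∞ ) / std(RE(internal))

is evaluated, with the sample standard deviation (n−1 denominator). The
selected scale is the argmax; ties and the degenerate std = 0 case resolve
toward the smallest scale (std = 0 candidates are excluded with a
warning). The selector therefore costs |S| KDA fits and zero classifier
runs, versus grid search's |S| fits plus |S| leave-one-out KNN passes —
that call-count contract is asserted in the tests rather than wall-clock
time, which is hardware-dependent.

### Parameters

| parameter | default | meaning |
|---|---|---|
| candidate set S | 0.1, 0.2, 0.3, 0.4, 1, 2, 3, 4 | Gaussian scales searched (same units as the feature space) |
| d | C − 1 | retained discriminant directions, 1 ≤ d ≤ C−1 |
| u | 8 | neighbor count defining ε; accuracy is insensitive to u in 6..10 |
| k (KNN) | 20 | neighbors in the Euclidean majority vote (5 in the small demos) |
| μ (ridge) | 1e-8·tr(L̃)/N, floor 1e-12 | regularization of L̃, which has rank ≤ N−C |

## Feature encodings

PSI-BLAST ASCII profiles are parsed into L×20 score tables (first
log-odds block only; column order taken from the file header, canonical
order ARNDCQEGHILKMFPSTWYV otherwise).

**PsePSSM** (20·(1+ξmax) features, 1000 at the default ξmax = 49): column
means M̄_j plus, per lag ξ, the mean squared difference
G_jξ = (1/(L−ξ)) Σ_i (M_ij − M_(i+ξ)j)². The ξ = 0 lag block is identically
zero and is identified with the mean block, which is what makes the total
1000 rather than 1020. Scores enter raw by default; an optional logistic
squashing flag exists for experimentation.

**PSSM-S** (220 = 20+20+80+100): only the block names and sizes are fixed
by convention, so the block formulas are this package's documented choice:
AAO = amino-acid occurrence frequencies of the profile's consensus sequence
(row argmax, ties to the lowest column); PSSM-AAO = column means; PSSM-SD =
per column, the L-normalized 1-based positions where the running sum of
absolute scores first reaches 25% and 50% of the column total, walked from
each terminus (4 per column); PSSM-SAC = mean-centered auto covariance at
lags 1..5 per column. Profiles must satisfy L > 5 (largest lag), with
L ≥ 20 recommended.

## Evaluation

Leave-one-out ("jackknife") cross-validation with a Euclidean KNN
classifier. `strict` mode refits KDA inside every fold (statistically
correct, the default); `fast` mode fits KDA once and leaves only the KNN
vote out-of-fold — it is the per-candidate score inside grid search and is
much cheaper; the two agree on well-separated data. KNN tie handling is
deterministic: equal distances keep training order, tied votes go to the
tied class seen earliest among the ordered neighbors.

Per class (one-vs-rest): MCC in [−1, 1], sensitivity TP/(TP+FN),
specificity TN/(TN+FP), and pooled overall accuracy Q = Σ_k TP_k / N. A
zero denominator leaves the value undefined; it is reported as `-`, never
as a number. A nonstandard specificity variant TN/(TP+FP) is available
behind a flag for fidelity experiments but can exceed 1 and is not the
default.

## Synthetic data

The generators emulate the geometric regimes the method is designed for,
not protein biology:

- `make_blobs` — isotropic Gaussian classes on a regular simplex (the
  linearly separable control);
- `make_rings` — concentric noisy shells; default radii (1, 2) with noise
  0.2 put the class boundaries in contact, which is the precondition of
  the edge rule (widely separated rings have no samples with mixed
  neighborhoods and hence no edge set). At noise 0 in 3-D this produces
  the degenerate all-points-on-a-sphere configuration; the `shell` preset
  uses radii (1, 1.6) so the shells are adjacent;
- `make_pssm` — uniform integer scores in [−10, 13], the typical
  PSI-BLAST log-odds range (configurable; no claim of evolutionary
  realism);
- presets `gp-*-like` / `gn-*-like` — small datasets with the class counts
  and feature dimensions (4 or 8 classes; 1000 or 220 features) of the
  Gram-positive/Gram-negative subcellular-localization benchmarks.

Everything is a pure function of its seed. Passing tests on these
generators demonstrates the algebra, the selection logic and the agreement
between the two selectors at small scale; it does not certify accuracy on
real PSSM features, which have class imbalance and correlation structure
the generators do not model. Reproducing benchmark-level accuracies would
additionally require the external datasets and PSI-BLAST profile
generation, which are outside this package's scope.

## Numerical choices

- L̃ is PSD with rank ≤ N−C, so the generalized eigenproblem is solved
  against L̃ + μI via `scipy.linalg.eigh`; μ defaults to 1e-8·tr(L̃)/N with
  an absolute floor of 1e-12 (at very large scales L̃ → 0 and the Cholesky
  factorization needs a strictly positive-definite matrix).
- Eigenvalues of (M̃, L̃+μI) are real and non-negative up to 1e-8; the top
  d are retained in descending order.
- `alpha` is re-orthonormalized by Gram–Schmidt in the kernel metric after
  the solve (generalized eigenvectors are L̃+μI-orthogonal, not
  K-orthonormal, and the identity RE = 1 − ||t||² requires an orthonormal
  basis). Column signs are fixed by making the first non-negligible
  coefficient positive. The leading direction is unchanged by this, so
  Rayleigh-quotient optimality is preserved.
- Reconstruction errors are clamped to [0, 1]; a violation above 1e-8 is
  logged before clamping.
- A single-sample class is allowed in the fit: its within-class block is
  identically zero.
- Degenerate selection inputs raise: an empty edge or internal set (the
  objective is undefined), u outside (0, pool size), d outside [1, C−1].

## Known limitations

- The edge/internal rules presuppose classes whose boundaries touch at the
  scale ε; on data with large inter-class gaps the edge set is empty and
  the selector reports an error rather than guessing.
- `fast` jackknife mode lets the KDA fit see the held-out sample; it is an
  optimistic score and is used only where the per-candidate comparison
  needs to be cheap and consistent across candidates.
- PSSM-S block formulas follow this package's documented defaults; other
  implementations of the same 220-feature layout may differ in the
  segmentation percentages and lag count (both are configurable).
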