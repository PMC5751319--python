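# kdaloc

Gaussian kernel discriminant analysis (KDA) for protein subcellular
localization, with a fast, reconstruction-error-based method for choosing
the Gaussian kernel scale parameter.

## The problem

Predicting where a protein functions inside the cell from its sequence is a
standard proteomics task: encode each protein as a fixed-length feature
vector (here, PSSM-derived encodings), reduce the dimension, and classify.
The feature vectors are high-dimensional (1000 for PsePSSM, 220 for PSSM-S)
and not linearly separable, so a *kernel* discriminant analysis is used:
Fisher discriminant analysis performed implicitly in the feature space of
the Gaussian kernel

```
K(x, y) = exp(-||x - y||² / s²)
```

The discriminant directions w_k = Σ_j a_jk φ(x_j) solve the kernelized
Fisher problem

```
max J(a) = (aᵀ M̃ a) / (aᵀ L̃ a)
M̃ = Σ_i N_i (M_i − M)(M_i − M)ᵀ        (between-class scatter)
L̃ = Σ_i K_i (E − (1/N_i) 1) K_iᵀ       (within-class scatter)
```

retaining at most C−1 directions for C classes. Performance depends
strongly on the scale `s`. Grid search finds a good `s` but runs the whole
classifier once per candidate. This package implements a cheaper selector:
split the largest class into **internal** samples (near the class centroid,
pure neighborhoods) and **edge** samples (far from the centroid, mixed
neighborhoods), and pick the `s` that maximizes

```
f(s) = ( max RE(edge) − max RE(internal) ) / std(RE(internal))
```

where `RE(x) = 1 − ||t(x)||²` is the kernel reconstruction error of `x`
under the fitted KDA subspace — a good scale separates boundary samples
from interior samples without ever running a classifier.

## Worked example

Run the end-to-end pipeline on a built-in synthetic dataset of two noisy
concentric rings (60 samples, 2 classes — not linearly separable, so the
kernel reduction is doing real work):

```sh
kdaloc run --preset demo-rings --method both --d 1 --knn-k 5 --seed 0 --report demo.json
```

which logs (abridged):

```
INFO kdaloc.selection: scale 0.1    f(s)=-1.61051
INFO kdaloc.selection: scale 1      f(s)=-1.11155
INFO kdaloc.selection: scale 4      f(s)=3.95373
INFO kdaloc: proposed method selected s=4
INFO kdaloc.selection: scale 0.1    jackknife accuracy 1.0000
INFO kdaloc: grid search selected s=0.1
INFO kdaloc: proposed: s*=4, Q=1.0000
INFO kdaloc: grid: s*=0.1, Q=1.0000
```

Reading this: the reconstruction-error objective `f(s)` peaks at `s = 4`,
so the proposed selector picks that scale after 8 KDA fits and **zero**
classifier runs. Grid search evaluates leave-one-out KNN accuracy at every
candidate (all reach 1.0 here) and returns the smallest tied scale. Both
choices give the same downstream jackknife accuracy `Q = 1.0000` with
per-class sensitivity/specificity/MCC of 1.0 in `demo.json` — the two
selectors agree on the metric that matters while the proposed one skips
the `|S|` jackknife passes.

The individual stages are also available as subcommands — `simulate`,
`extract-features` (PSI-BLAST ASCII PSSM → PsePSSM/PSSM-S TSV),
`select-param`, `reduce`, `evaluate` — and as library functions
(`kdaloc.fit_kda`, `kdaloc.select_scale`, `kdaloc.jackknife`, ...).

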