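# Methods

`deraml` models how point mutations shift the substrate specificity of
2-deoxy-D-ribose 5-phosphate aldolase (DERA) and ranks combinatorial
variants for a specificity switch: gaining acetaldehyde self-aldol
activity (ACET) while losing activity on the natural phosphorylated
substrate (DRP). This note records the model, its parameters, and the
numerical choices, in enough detail to reimplement the package.

## Variant representation and contact graph

A variant is a set of point mutations at pairwise-distinct residue
positions (`C47V/G204A/S239D`); the empty set is the wild type. The
protein structure enters through a residue contact graph: one node per
residue, represented by its C-beta atom (C-alpha for glycine), with an
edge between residues whose representative atoms lie within a distance
threshold (default 8.0 Å, a conventional C-beta contact cutoff giving
mean contact degrees around 10). Graphs come from a PDB file
(`read_structure`) or from a generator of compact self-avoiding chains
(`generate_toy_structure`, below).

## Variant kernel

Similarity between two variants `u`, `v` over a graph with node set `V`
and contact edges `E` is

    k_raw(u, v) = (1 − λ) Σ_{i∈V} s(a_i, b_i)
                +  λ      Σ_{(i,j)∈E} s(a_i, b_i) · s(a_j, b_j)

where `a_i`, `b_i` are the amino acids of `u` and `v` at position `i`
(wild type where unmutated) and `s` is a 20×20 substitution similarity.
The node term scores per-position conservation; the edge term scores
conservation of contacting pairs, so mutations at interacting residues
matter more than isolated ones. `λ` (`edge_mix`, default 0.5) balances
the two. The kernel is cosine-normalized,
`k = k_raw(u,v) / sqrt(k_raw(u,u) k_raw(v,v))`, so every variant has
self-similarity exactly 1.

Because variants differ from the wild type at ≤ 3 positions, `k_raw` is
evaluated as the wild-type value plus corrections restricted to mutated
positions and their contact edges; Gram and cross-Gram matrices use a
vectorized grouped form of the same identity. Cost is independent of
protein length after a one-time precomputation, and the delta path is
tested to agree with the naive full sum to 1e-10.

## Substitution models

Seven similarity matrices are packaged (`load_substitution_models`):

- **identity** — Kronecker delta (pure mutation-count kernel).
- **exchangeability** — BLOSUM62, affinely rescaled to [0, 1].
- **interaction** — the Johnson–Overington matrix, rescaled to [0, 1].
- **contact_energy** — Gaussian radial similarity over the Miyazawa
  contact-energy scale.
- **packing_volume** — radial similarity over Zamyatnin residue volumes.
- **hydrophobicity** — radial similarity over the Kyte–Doolittle scale.
- **charge** — radial similarity over formal side-chain charge
  (D, E = −1; K, R = +1; H = +0.1).

Radial similarities are `exp(−(p_i − p_j)² / 2σ²)` with `σ` the standard
deviation of the scale, so "one typical property step" costs a fixed
similarity drop regardless of the scale's units. Matrix-derived models
are projected to the positive semidefinite cone by eigenvalue clipping
(tolerance 1e-8). Normalized Gram matrices are likewise clipped and then
cosine-renormalized — a congruence transform, which preserves positive
semidefiniteness and restores the exact unit diagonal.

## Specificity model: multiple kernel learning GP

One Gaussian-process regressor per substrate is trained on wild-type-
relative activities `y` (wild type ≡ 1). The covariance is

    K̃ = τ² Σ_m w_m K_m + σ² I,   w on the probability simplex,

over the packaged kernels. The weights `w`, signal variance `τ²` and
noise variance `σ²` maximize the exact log marginal likelihood, using
exponentiated-gradient ascent on `w` (multiplicative updates keep `w` on
the simplex and drive uninformative kernels toward zero, so kernel
selection is emergent) and log-space gradient ascent on the variances,
under one shared backtracking line search — every accepted step
increases the objective, so the recorded trace is monotone. Defaults: 5
seeded multi-starts (uniform weights plus Dirichlet draws), ≤ 500
iterations, relative tolerance 1e-8, noise floor 1e-6 (configurable;
pinning the noise at a lower floor makes the posterior mean interpolate
the training data, which the acceptance suite exploits). Targets are
replicate-averaged per variant; an optional `log1p` transform is
available for heavy-tailed activities.

Predictions use the standard GP posterior; since kernels have unit
diagonal, the latent predictive variance is `τ² − k*ᵀ K̃⁻¹ k*`, clipped
at zero with a warning if rounding drives it negative. Models serialize
to JSON (weights, hyperparameters, dual coefficients); the Cholesky
factor is rebuilt from the training Gram matrices on load.

Generalization is measured by variant-level k-fold cross-validation
(default 10 folds): folds partition variants, all hyperparameters and
kernel weights are re-learned on each training split, and held-out
Pearson correlation is reported per substrate (`None` when held-out
targets are constant, rather than a spurious 0).

## Screening

`enumerate_candidates` generates every variant of 1–3 library mutations
at distinct positions (deterministic order; measured variants
excludable), and `count_candidates` gives the closed-form count — sums
of per-position multiplicity products over position subsets. For the
default 69-mutations-over-24-positions library this is 50,232
candidates, the "tens of thousands" regime of a real combinatorial
screen. Candidates are ranked by the specificity-shift score: predicted
ACET activity minus predicted DRP activity, ties broken by canonical
variant string; `select_top` takes the manual-review shortlist.

## Synthetic data

The generators emulate a three-round mutagenesis study: 69 single
mutants over 24 positions (default partition 21×3 + 3×2), 62
double/triple combinations (~70/30 mix) — 131 training variants —
measured on DRP, DR and ACET screens.

- **Toy structures** are compact self-avoiding chains: step 3.8 Å,
  excluded volume 3.5 Å, confined to a sphere of radius `3.3 n^{1/3}` so
  the fold is globular and contact density protein-like.
- **GP-drawn landscapes** (`SpecificityOracle`) are exact draws of a
  latent `f` with covariance `signal_sd² Σ w_m K_m`, sampled lazily via
  conditional distributions so any finite query set is a draw from the
  correct joint; activity is `max(0, 1 + f − f(WT))`, anchoring the wild
  type at exactly 1. Known `w` makes kernel-weight recovery scoreable.
- **Additive landscapes** assign each library mutation a per-substrate
  effect; activity is `max(0, 1 + Σ effects)`. The planted screening
  landscape designates 5 mutations with ACET +0.5, DRP −0.4, DR −0.35
  each (their 10 triples are the planted positives, reaching the
  two-to-threefold ACET gain with abolished DRP activity that a real
  specificity switch shows); all other mutations get small random
  background effects, mildly deleterious on the natural substrate.
- **Measurements** add Gaussian noise (default sd 0.1) on the relative-
  activity scale, clipped at 0, with round labels by mutation count.
- **Absorbance traces** follow `A(t) = A₀ exp(−kt)` with
  `k = ε l v₀ / A₀` and `v₀` the molar NADH consumption rate implied by
  the planted specific activity; the default duration ends at ~10% NADH
  consumption (capped at 600 s) so the initial-rate window is
  near-linear.

What the generators deliberately do not emulate: real epistasis beyond
the kernel's edge term, substrate-inhibition or lag kinetics, plate
effects or systematic assay drift, and the actual DERA sequence —
structures and libraries are seeded random stand-ins with the study's
shape, not its content.

## Assay reduction

`initial_rate` fits a least-squares line to the first fraction of a
trace (default 10%, minimum 3 points) or to the longest prefix with
R² ≥ 0.99; the slope is sign-flipped, and a rising trace yields 0 with a
warning rather than a negative activity. `specific_activity` applies
Beer–Lambert (ε = 6220 M⁻¹cm⁻¹ for NADH at 340 nm; path length and
enzyme concentration are required, not defaulted, because they are
instrument- and prep-specific), divides by the NADH-per-event
stoichiometry, and returns turnovers min⁻¹. `relative_to_wt` divides by
the wild-type activity. Round-tripping a noiseless simulated trace
recovers the planted relative activity to well under 2% (the ~0.5%
window-curvature bias cancels in the wild-type ratio).

## Verification

The acceptance suite (`tests/test_acceptance.py`, reproducible via
`scripts/acceptance.py`) checks: GP interpolation at a pinned noise
floor (≤ 1e-6), agreement of posterior mean/variance with an independent
dense closed-form evaluation (≤ 1e-10), kernel symmetry and positive
semidefiniteness across 50 random variant sets (min eigenvalue ≥ −1e-8),
recovery of planted kernel weights [0.7, 0.3, 0, 0] from n = 120 noisy
observations over a weakly-correlated kernel quartet (contact_energy,
packing_volume, charge, identity — near-collinear pairs like
exchangeability/interaction are not mutually identifiable at this n),
recovery of ≥ 8/10 planted specificity switches in a top-50 shortlist
from ~50,000 candidates, exact enumeration counts against brute force,
assay round-trip fidelity, and the 69/24/62/131 study-design counts.

## Limitations

- The kernel sees only mutated positions and pairwise contacts; higher-
  order epistasis and long-range conformational effects are invisible.
- MKL weight recovery requires kernels with distinguishable Grams;
  reported weights over near-collinear kernels are not unique even when
  predictions are.
- At realistic noise (sd ≈ 0.1–0.3) held-out correlations on 131
  variants are modest (~0.6–0.75 on favorable landscapes); the model
  ranks candidates, it does not predict activities precisely.
- Synthetic benchmarks certify the machinery, not biological accuracy on
  real DERA data.
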