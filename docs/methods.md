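# Methods

## Chemical-space enumeration

The space is a union of *accessible* molecules (purchasable cores) and
*generated* molecules produced by three one-step couplings between a core
handle and a substituent handle:

| reaction | core handle | substituent handle |
|---|---|---|
| amide formation | carboxylic acid (free acid) | primary/secondary amine |
| esterification | carboxylic acid | alcohol / phenol |
| Williamson ether | hydroxyl **or** alkyl halide | alkyl halide **or** alcohol |

The ether coupling is enumerated in both orientations and the products
deduplicated, because either partner may carry the halide. Free acids are
assumed on the acid side (acid chlorides would give the same products with
a different leaving group). Substituents are restricted to MW < 200 g/mol
(average atomic masses, strict inequality).

Two site modes exist because symmetric tetra-arm TPP cores can react at
one or all arms. `all_sites` (default) applies the transform repeatedly
until no core handle remains — matching one-pot syntheses run to full
conversion with excess substituent — while `single_site` emits one product
per distinct reactive site. Products failing valence sanitization are
logged and dropped rather than aborting a batch; all products are
canonicalized and deduplicated by canonical SMILES, so enumeration is
order-independent.

## Neighbor graph and coverage

Molecules are encoded as hashed ECFP6 (Morgan radius 3) fingerprints,
2048 bits by default. Bit identities are hash-dependent, so all contracts
are stated on distances and coverage, never on individual bits. The
Tanimoto distance d = 1 − |a∩b|/|a∪b| with the convention d = 0 for two
empty fingerprints (identical empties; logged). Neighborhood is
d_ij < D_TH, strictly; D_TH defaults to 0.3. Every molecule is its own
neighbor whenever D_TH > 0, which matters at small budgets: a single pick
always covers at least itself.

Coverage of a selected set is the weighted fraction of the space within
one hop (order 1) of the set, or two hops (order 2, "neighbors of
neighbors"). The order-1 cover function is a weighted set cover —
monotone and submodular — which is what justifies greedy maximization.
Distance matrices are stored dense (float32); at the intended scale
(≤ 10⁴ molecules) this is at most a few hundred MB and a few seconds of
BLAS time.

## Greedy penalized selection

The selector keeps three disjoint bookkeeping sets: evaluated molecules,
covered molecules (anything within D_TH of an evaluated molecule) and the
rest. A candidate's score is the weight of its *uncovered* neighbors minus
λ·W_tot times the penalized weight of its neighbors, with penalty 1 on
evaluated molecules and λ = 1 by default. Because the reward term is
always < W_tot, a single evaluated neighbor (penalty W_tot) dominates any
reward: the selector never re-enters a neighborhood that already contains
an evaluated molecule while fresh regions remain. Weights, penalties and λ
are all injectable for generality.

Ties in the argmax are broken deterministically: lowest index in
canonical-SMILES lexicographic order when structures are available,
otherwise lowest index. The greedy loop is vectorized (two matrix–vector
products per pick) and is verified pick-for-pick against an exhaustive
brute-force argmax in the tests.

Baselines:

* **random** — a seeded uniform permutation prefix (equivalent to ranking
  by i.i.d. uniform priority draws);
* **uncertainty sampling** — at each step, the Gaussian-process posterior
  variance given the evaluated set, with a Tanimoto-similarity kernel
  k = 1 − d on the fingerprints, unit prior variance, jitter 10⁻⁶, no
  hyperparameter optimization, and first pick = the molecule with maximal
  summed distance to all others. This is one concrete reading of
  "GP-based least-confident selection"; the kernel and seeding rule are
  isolated so they can be swapped. Posterior variance depends only on the
  evaluated *inputs*, so no measured response is needed. The factor is
  maintained by a streaming Cholesky update, O(|E|·n) per step, so long
  rankings never re-factorize the kernel.

Benchmark curves report both coverage orders side by side; the objective
itself optimizes the order-1 cover while the headline benchmark uses
order-2, and since the two orders genuinely differ, both are always
emitted rather than choosing one.

## Spectrum reduction

Fitting happens on the wavelength axis in a configurable Soret window
(default 380–470 nm; the weaker Q band near 520 nm is excluded). A
single Gaussian h·exp(−(λ−μ)²/2σ²) fitted by least squares gives
λ_max = μ, Intensity = h and FWHM = 2√(2 ln 2)·σ. Area comes from a
two-Gaussian fit (main + shoulder, the shoulder constrained ≥ 3 nm to the
blue via a nonnegative-offset parametrization and initialized 15 nm blue
at 30 % height): Area = h·FWHM·√(π/(4 ln 2)) of the *main* component.
Because a main+shoulder split is unidentifiable when one Gaussian already
explains the band, the two-component area is adopted only when it reduces
the RMS residual by ≥ 30 % and keeps the main component tallest;
otherwise the single-fit area is used (for a true single peak the two
coincide).

No-peak criterion (three clauses, all configurable): fitted height below
5× the RMS fit residual, height below an absolute floor of 0.005
absorbance, or convergence failure / center pinned at the window edge.
Additionally the fitted width must be resolvable — σ at least 1.5 nm and
1.5 grid steps — since an unconstrained fit can collapse onto a single
noise spike and report a sub-grid "peak". FWHM is stored in nm with an
eV conversion helper (E = 1239.842/λ).

Relative indicators are per molecule over its solvent series:
FWHM_r = FWHM_min/FWHM, Area_r = Area/Area_max, computed over solvents
with a found peak; no-peak pairs get (0, 0), and a molecule with no peak
anywhere gets all zeros plus a warning. Both are invariant to rescaling a
molecule's absorbances (concentration changes).

Categorization runs K-means (K = 5, 10 restarts, fixed seed) on the
(FWHM_r, Area_r) points of peak-found pairs; clusters map to categories
0–4 by ascending centroid coordinate sum, no-peak pairs are forced to
category 0, and good solvent = category ∈ {3, 4}. An `include_no_peak`
switch lets the (0, 0) points participate in clustering instead, since
either convention is defensible. The centroid-sum ordering is this
package's deterministic replacement for a manual category assignment.

## Solubility models

Pair features are molecule-block ⊕ solvent-block, either hashed ECFP6 bits
(1024 per block by default) or an open 2-D descriptor set (MW, AMW, nH,
H %, logP, molar refractivity, TPSA, Labute ASA and related; constant
columns droppable). Commercial descriptor suites are out of scope; the
open set covers the same families of variables (size, hydrogen content,
partition, volume/surface). Identical solvent blocks — possible with
coarse fingerprints for small solvents — are detected and reported.

The protocol: for each of n_iterations (default 100) iterations, a fresh
random 80/20 split, grid search by 5-fold CV on the training part over
n_estimators ∈ {100, 300, 500} × max_depth ∈ {2…10}, refit of the best
model, and train/test metrics (accuracy/precision/recall/F1 with
positive = good solvent; R²/MAE for regression). CV selects by accuracy
(classification) or negative MAE (regression). Per-iteration seeds are
base seed + iteration index; single-class training splits are resampled
and logged. Grid search runs per iteration by default, with a run-once
switch for speed.

Feature relevance is a Boruta-style procedure implemented in-package: each
of n_trials forests sees the real features plus a permuted shadow copy of
every feature; a feature scores a hit when its importance beats the best
shadow, and a two-sided binomial test at α = 0.05 against p = 0.5 labels
features confirmed / rejected / tentative.

## Synthetic data

* **Clustered spaces** — k prototypes of n_on random on-bits (n_on = 64 of
  nbits = 512 by default); members flip every bit independently with
  probability `intra_cluster_flip`. At the default flip rate 0.05 this
  puts within-cluster distances near 0.45 and between-cluster distances
  near 0.9, so the generator's default D_TH is 0.5 — chosen once so that
  planted clusters are neighbor-connected and distinct clusters are not.
  Explicit (e.g. disjoint-support) prototypes can be passed for
  guaranteed-separation constructions. Synthetic spaces are raw
  fingerprint spaces with no SMILES, decoupling selector tests from
  chemistry parsing; a ~20-molecule substituted-benzene fixture covers
  end-to-end runs needing real structures.
* **Spectra** — sums of Gaussians plus i.i.d. noise on a 350–700 nm, 1 nm
  grid; ground-truth indicators are computed analytically from the
  tallest component. The panel generator emulates the full 15 × 16
  molecule × solvent design with 25 planted insoluble (flat) pairs and
  three solubility regimes (aggregated-broad, less-soluble-small,
  sharp-and-large), with a blue shoulder on half the soluble pairs.
* **Label tables** — pair features (molecule bits ⊕ random solvent bits),
  a linear rule score squashed through a logistic to produce
  FWHM_r/Area_r in [0, 1], fixed thresholds {0.2, 0.4, 0.6, 0.8} for
  categories, and independent label flips at a chosen noise rate.

What the generators deliberately do *not* model: real aggregate exciton
physics (spectra are ideal Gaussians), solvent chemistry (synthetic
solvent blocks are random bits), and the size/heterogeneity of a real
enumerated library. Passing tests therefore demonstrate the correctness
of the algorithms under their stated assumptions, not instrument-level
performance on measured spectra.

## Problem sizes and numerical choices

The test suite and the acceptance script run the selector checks on
random spaces of up to 64 molecules (oracle equivalence), 10⁴ random set
triples (submodularity), and 500-molecule/20-cluster benchmark spaces;
the ML protocol runs its 100 iterations with the reduced grid
n_estimators ∈ {100}, max_depth ∈ {4, 8} (the defaults remain the full
grids). Fit tolerances in tests follow the generator's analytic truth:
0.5 nm in λ_max and 5 % in FWHM/Area at SNR 50. Greedy ties resolve as
described above; K-means uses a fixed seed and 10 restarts; GP jitter is
10⁻⁶ with a degenerate-kernel (all-identical fingerprints) abort.

## Known limitations

* Reaction templates cover the three named couplings only; multistep
  chemistry, metal substitution and synthesizability scoring are out of
  scope.
* The uncertainty-sampling baseline is one defensible concretization of a
  GP least-confident selector; different kernels or seed picks change its
  curve, though not the qualitative benchmark outcome.
* Wavelength-axis fitting is used throughout; fitting on the energy axis
  would shift FWHM values slightly for broad bands (the eV helper exists
  for such comparisons).
* The descriptor mode is an open stand-in for commercial descriptor
  suites; numerical feature values differ even where the variable
  families correspond.
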