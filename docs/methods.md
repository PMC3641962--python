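# Methods

This note documents the models, formulas, parameter choices and known
limitations of the `bcrpsvm` pipeline.

## The classification problem

Wild-type BCRP (ABCG2) actively transports a chemically diverse set of
small molecules. Given a molecule's 3D structure, the pipeline predicts
"substrate" vs "non-substrate" from numeric molecular descriptors with a
soft-margin kernel SVM. Position-482 BCRP mutants transport additional
compounds (e.g. rhodamine 123); models built with this package target the
wild-type phenotype only in the sense that the label table defines the
classes — the code is agnostic to how labels were assigned.

## Molecule model and I/O

A molecule is an ordered atom list (element symbol, pinned standard atomic
weight, 3D coordinates in Å) plus an integer-order bond list. Parsing and
writing of V2000 SDF and SMILES are delegated to RDKit; everything
downstream operates on plain arrays. Choices:

* **Atomic masses** are pinned in-repo (`masses.py`, abridged CIAAW
  standard atomic weights) so mass-weighted descriptors are bit-stable
  across toolkit upgrades.
* **Hydrogens** are kept when present in the file; SMILES-derived
  structures get explicit hydrogens. AAC counts all atoms, hydrogens
  included, the usual convention for composition information indices.
* **SMILES structures carry no geometry.** The library marks them 2D-only
  and refuses 3D descriptors instead of silently embedding a conformation:
  an embedded geometry is a modelling decision the caller should make
  explicitly, and descriptor values depend on it.
* **Disconnected structures** (salts) raise an error by default;
  `largest_fragment()` is the explicit opt-in to keep the largest covalent
  fragment. Whether counter-ions should be stripped is dataset policy, not
  something the library guesses.

## Descriptors

Only the five descriptors of the final substrate model are computed
natively; any other descriptor enters through table ingestion. Definitions
follow the standard descriptor-handbook formulas:

* `AAC = −Σ_g (n_g/n)·log2(n_g/n)` over element types (bits).
* `SPH = 3λ₃/(λ₁+λ₂+λ₃)`, eigenvalues (descending) of the unweighted
  covariance of atom-centred coordinates; 0 for planar/linear, 1 for
  isotropic geometries. Coincident atoms are a degenerate-geometry error.
* `Mor(s) = Σ_{i<j} wᵢwⱼ·sin(s·r_ij)/(s·r_ij)`, with the summand defined
  as `wᵢwⱼ` at `s·r_ij = 0`. Signal number k maps to `s = k − 1` Å⁻¹ on
  the conventional Mor01..Mor32 grid (Mor17 → 16, Mor25 → 24).
* `R_lag = Σ_{i<j, d_topo=lag} √(hᵢhⱼ)/r_ij · wᵢwⱼ`, leverages
  `hᵢ = H_ii` of the molecular influence matrix `H = M(MᵀM)⁻¹Mᵀ`
  (M = centred coordinates). For rank-deficient geometry (planar/linear)
  the Moore–Penrose pseudo-inverse is used.
* Mass weights are carbon-scaled: `wᵢ = mᵢ/m_C`.

These are faithful to the published formulas but will **not** match any
specific commercial descriptor package bit-for-bit (different geometry
optimizers, hydrogen switches, and numeric conventions); every native
descriptor is instead verified against independent brute-force oracles and
rigid-motion/reordering invariance in the test suite.

## Elimination, scaling and selection

* Sparsity rule: drop columns with strictly more than 80% exact zeros
  (descriptor exports emit literal zeros; an |x| ≤ ε variant is
  available). Variation rule: drop columns whose sample SD is below 3% of
  their range; constants always go. "SD below 3%" is inherently ambiguous
  (3% of what?); SD relative to range is the unit-free reading adopted
  here, and the threshold is configurable. Both rules are per-column
  predicates, so their order cannot change the outcome; the canonical
  order (sparsity, then variation) is still fixed and recorded.
* Filtering is applied to the modelling set once before splitting, the
  natural reading of the method order; a strict per-split mode refits the
  filters on each training split.
* Scaling is per-column min–max to [−1, 1], fitted on training rows only
  and applied without clipping elsewhere, the libsvm convention.
* F-score uses the `fselect.py` definition (pooled-mean numerator, summed
  within-class sample variances). A perfect zero-variance separator maps
  to an explicit +∞ sentinel. Correlation pruning is a single greedy pass
  in descending F (ties broken by name): a candidate is dropped when it
  correlates at |r| ≥ 0.9 with an already-retained feature. Greedy forward
  addition adds one feature per rank step and stops at the first *strict*
  decrease of the validation accuracy (plateaus continue); the minimum
  selected set size is 1, flagged when the first feature already scores
  below the majority-class baseline.
* The selection-time validation accuracy is a 3-fold stratified CV on the
  training split with a fixed moderate SVM (C = 1, γ = 1/(p·Var(X)));
  using the test set here would leak.

## SVM and grid search

The quadratic program is solved by scikit-learn's libsvm binding; the
kernel mathematics, the dual-form decision function evaluated from stored
support vectors, and the plain-text model file are owned by this package,
so a saved model predicts without a refit and the decision path is
independently checkable against the solver. Grid search is exhaustive over
C ∈ 2^{−5,−3,…,15} and γ ∈ 2^{−15,−13,…,3} (the conventional coarse grid;
the original protocol does not state its ranges) with 5-fold stratified
CV, folds fixed per call and shared across the grid. Ties prefer smaller
C, then smaller γ — the least complex model. A decision value of exactly 0
maps to the substrate class (documented, configurable at the call site).

## The multi-run protocol

Each run draws an independent unstratified random split (|train| =
⌊fraction·n⌋; 223 compounds at 0.75 give 167/56), then fits scaling,
ranking, pruning, greedy selection and grid search strictly inside the
training split, and finally evaluates on train/test/external. "100 runs"
is interpreted as 100 independent splits with full re-selection and
re-tuning per run — the most conservative reading. Per-run seeds derive
from the base seed via a seed sequence, so reports are byte-identical
across repeats. Failure policy: failed runs are recorded and skipped;
more than 10% failures aborts.

Best-model selection ranks runs by (|ACC_train − ACC_test|, number of
selected features, run index). External performance is deliberately
excluded: the rule exists to penalize overfitting, and consulting the
external set would silently turn it into a second test set.

To keep the greedy stage bounded on plateaus, the protocol caps the
candidate list at the 30 top-ranked survivors per run (configurable).

## Synthetic data

The generator emulates the statistical structure of a descriptor table for
a two-class compound collection — by default 164 substrates vs 99
non-substrates, 5 informative descriptors among 95 noise ones, with a
223/40 modelling/external layout (139/84 and 25/15 per class):

* informative columns: unit-variance draws, positive class shifted by δ
  within-class SDs (default δ = 3, a clearly learnable but not trivial
  separation);
* noise columns: class-independent unit-variance draws;
* correlated duplicates: informative columns plus jitter at 12% of the
  column's spread (sample |r| ≈ 0.993). The jitter is deliberately not
  microscopic: a duplicate must be a *strictly noisier* copy so that the
  F-score penalty of its inflated within-class variance dominates sampling
  noise and pruning reliably drops the copy rather than the original;
* zero-inflated columns: an exact planted count of zeros (default 90%),
  the sparsity filter's designated prey;
* borderline compounds: an optional fraction of rows drawn from the
  midpoint mixture N(δ/2, 1) on every informative column while keeping
  their true label — irreducible error by construction, mimicking the
  region where substrate and non-substrate profiles are too similar to
  separate;
* a heavy-tailed (Student-t₃) option to stress the min–max scaler.

What passing tests on this generator do **not** show: real descriptor
tables have correlated blocks, skewed and discrete columns, and
label noise whose structure is unknown; synthetic results bound the
pipeline's correctness, not its real-world accuracy.

A fixed set of seven toy molecules with exact hand-written coordinates
(methane, water, staggered ethane, planar benzene, linear CO₂, acetone,
isobutylene) anchors the descriptor oracles.

## Numerical and edge-case choices

* Metric denominators of zero yield explicit undefined markers, never a
  silent 0; an option coerces undefined MCC to 0 for the other common
  convention. Display rounding is 1 decimal for percentages, 3 for MCC;
  raw values are always retained.
* Spherosity eigenvalues are clipped at 0 before the ratio; leverages are
  clipped at 0 before the square root (both guard against −1e−17-type
  round-off).
* Grid-search fold counts reduce automatically (never below 2) when the
  minority class is smaller than the requested fold count.
* Problem sizes in the test suite: the full protocol is exercised at 100
  runs on the 263-compound analog; subsidiary property tests use smaller
  class sizes and reduced grids, which changes nothing structurally.

## Known limitations

* Descriptor values are geometry-dependent; structures optimized with a
  different force field give different 3D descriptor values, and no
  attempt is made to reproduce any particular optimizer.
* Only the five final-model descriptors are computed natively; pipelines
  over full commercial descriptor sets must ingest exported tables.
* No probability calibration, multi-class support, ROC analysis, or
  wrapper-based (GA) feature selection.
* The mean-accuracy tables of any specific historical compound collection
  are not reproducible without that collection's exact structures and
  descriptor software; the protocol's correctness is instead established
  on synthetic data with known ground truth.
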