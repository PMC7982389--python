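# Methods

This note documents the models and procedures `potbench` implements, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real data.

## Curation model

Raw input is a delimited table of (compound_id, smiles, target_id, Ki) rows,
Ki in nM by default (`CurationConfig.units` accepts M…pM; the conversion to
molar happens before the log). Replicates for one (compound, target) pair
are aggregated by geometric mean — equivalently, pKi is the arithmetic mean
of −log₁₀ Ki[M] — and accepted only if

1. max(Ki)/min(Ki) ≤ 10 ("same order of magnitude", inclusive boundary; the
   boundary convention is ours, exposed as `max_ki_ratio`), and
2. the aggregated pKi is strictly greater than 5 (pKi = 5.0 is rejected as
   borderline-active; applied to single measurements too).

Rejection by default removes only the offending (compound, target)
annotation; `rejection_scope="compound"` removes every annotation of an
affected compound instead — the stricter reading of "the compounds were
omitted". Activity classes are then filtered to ≥ 50 compounds spanning
≥ 2 analog series (both configurable); the filter is idempotent and drops
orphaned compounds from the matrix index. Provenance-level curation
(assay confidence, binding vs functional, organism) is the data provider's
job; this package validates structure only.

## Fingerprints

Morgan/circular features at radius 2 (bond diameter 4) with RDKit's default
atom invariants stand in for proprietary ECFP4 variants; bit-level identity
with any particular in-house implementation is neither possible nor needed,
since every model in the benchmark consumes the same representation.
Folding is modulo-1024 presence bits (no counts). The Tanimoto coefficient
on folded bits is used directly as the SVR kernel; it is positive
semi-definite on binary vectors (checked numerically in the tests). The
all-zero/all-zero case is defined as similarity 1.0 — identical objects —
and cannot occur for real molecules, which always produce at least one
feature.

## Analog series

Single-cut MMP fragmentation: every acyclic single bond between two heavy
atoms is cut; the larger fragment is the core, the smaller the substituent
(both canonical SMILES with one numbered attachment point). Equal-sized
halves emit both orientations so that symmetric molecules still match.
Substituents are capped at 13 heavy atoms (standard MMP convention,
configurable); hydrogens never count as substituents. Two compounds form an
MMP iff they share at least one identical core string; analog series are
the connected components of the resulting network, with the
lexicographically smallest member id as the deterministic series id.
Double/triple cuts and retrosynthetic (RECAP/BRICS) fragmentation are out
of scope.

## Splitting

Four strategies crossing assignment unit (compound vs whole series) with
scope (per target vs global). No canonical train/test ratio exists for this
protocol, so `test_fraction` is explicit everywhere (default 0.2). Series
are sampled uniformly and whole series moved to the test side until the
compound-count fraction is first met or exceeded, always keeping at least
one unit per side; the realized fraction is therefore within one series of
the request. Targets whose annotated compounds form a single series (AS
strategies), or whose annotations land entirely on one side of a global
split, are skipped with a warning record rather than silently compound-
split. Trials are seed offsets: trial i uses entropy (seed, i). The
training-label mask admits (c, t) iff the annotation exists and c is in
t's training set — so a compound testing for one target has that target's
label masked even while training for others. `leakage_audit` re-checks
every invariant from scratch and is run by the tests, the acceptance script
and the CLI.

## Models

RFR and SVR fitting is delegated to scikit-learn; the Tanimoto kernel is
precomputed. SVR optimizes only the cost C over
{0.001, 0.01, 0.1, 1, 10, 100} with ε fixed at the solver default 0.1. RFR
uses 500 trees, MSE splits, and searches min_samples_split {2, 8, 16},
min_samples_leaf {1, 5, 10}, max_features {sqrt, log2}.

The feed-forward networks are implemented directly on NumPy arrays with
explicit backpropagation: ReLU hidden layers, linear output (one neuron per
target), Adam, inverted dropout, optional batch normalization, mini-batch
training up to 200 epochs. The training loss is the masked MSE — mean of
squared errors over masked-in (compound, target) entries only — whose
gradient is identically zero at masked-out positions; this is the property
that lets one network train on a 99%-missing label matrix, and it is
verified both analytically and end-to-end (perturbing masked-out labels
leaves the fit bit-for-bit unchanged). Early termination holds out 10% of
the training rows, stops after 10 epochs without validation improvement and
restores the best weights; data sets too small to spare a validation row
train for the full budget. The output bias is initialized at the masked
label mean so the network starts at the mean-potency baseline. With fixed
seeds training is exactly reproducible (pure NumPy, no threading
nondeterminism).

Grid search is two-fold cross-validation minimizing validation MSE, ties
broken by grid enumeration order, deterministic per seed; a degenerate
all-identical-label training set returns the first grid point with a
warning. The full DNN grid (learning rate × dropout × batch size × depth ×
non-increasing width stacks from {100, 200, 1000, 2000} × batch norm) has
2340 points; `subsample_grid` provides the budget-limited random subset for
desk-scale runs. The width search is restricted to non-increasing stacks,
mirroring the pyramid shape of the reference architecture (2000 → 1000,
no batch norm, batch 128, dropout 0.1, learning rate 10⁻⁴), which is also
the `MT_DNN_REFERENCE` default. One reported convention note: grid
summaries elsewhere sometimes mention a selected leaf size of 3, which is
not in the candidate list; the printed list {1, 5, 10} is authoritative
here. Regression targets are raw pKi, never standardized, so all errors
are in pKi units.

## Evaluation

Per-class metrics: MAE, MedAE, MSE, Pearson r (r is flagged undefined — not
zero — when either side has zero variance or n < 2). Method comparison
counts a class for method A when its error is at least 0.1 pKi smaller
(inclusive, with a 1e-12 float tolerance at the boundary; strict mode
available) or its correlation at least 0.1 higher; "10% higher correlation"
is read as an absolute 0.1 difference, the same threshold applied to all
measures. Difficult classes satisfy e ≥ µ + 2σ over the class-error
distribution; σ defaults to the sample convention (ddof = 1, configurable),
and when σ = 0 every class sits exactly on the boundary and is flagged
suitable by default. The Wilcoxon test is the two-sample one-sided
rank-sum (Mann–Whitney) test — the two distributions compared being
error-difference sets of difficult vs suitable classes — exact for combined
n ≤ 25 without ties, normal approximation with tie correction otherwise.
Mean-potency baselines predict each test pair as the mean training pKi of
its task (`per_task`) or of all tasks pooled (`global`); a model whose test
error is not below its baseline error is flagged as having limited training
success. Global summaries are unweighted means ± sample standard deviation
across classes. No multiple-testing correction is applied.

## Synthetic fixtures

The generator emulates the *structure* of curated public potency data —
compounds organized into analog series (one scaffold template + varying
R-groups per series), sparse multi-target annotation, log-normal Ki — under
an additive potency model:

    true_pKi(c, t) = offset(t) + series_effect(series(c), t) + sub_effect(R(c))

Offsets are uniform on [6, 9] by default; series effects have sd 0.8 and
share a latent component across targets weighted by √ρ, giving exact
inter-target correlation ρ; substituent effects (sd 0.4) are keyed to the
R-group structure and shared across series and targets, so with zero noise
the labels are fully structure-determined and the best achievable error
equals the noise sd (0.3 by default). Observed labels are clipped to
[5.01, 11] — the lower edge just above the curation floor so round-trips
through curation are lossless. Cells are retained i.i.d. with probability
`density` (default 0.2; the sub-percent density of large public matrices is
reachable but leaves too few labels per target for desk-scale modeling).
The 16 built-in scaffold templates are pairwise non-matching under
single-cut fragmentation — validated at generation time — so ground-truth
series are exactly the MMP components.

What the fixtures do **not** emulate: activity cliffs, heteroscedastic
assay noise, correlated substituent × series interactions, realistic
scaffold-hopping similarity, or class-size imbalance. Passing tests
therefore establish the correctness of the pipeline's bookkeeping,
leakage guarantees and learning machinery — not predictive performance on
real assay data.

## Benchmark experiments and problem sizes

The packaged experiments (`potbench.benchmark`) run at deliberately small
sizes. Baseline dominance uses 16 series of 18–24 compounds (~330
compounds), one dense target, three trial splits at test fraction 0.25;
"strong signal" is noise-free with series sd 1.2 / substituent sd 0.3
(between-series differences dominate, as they do in practice), "zero
signal" is sd-0.5 noise around the task mean. RFR/SVR hyper-parameters are
grid-searched on the first trial and reused; the DNNs use a fixed
desk-scale configuration (512/256 hidden units, lr 10⁻³, dropout 0.1,
batch 64) — widths scaled down from the reference architecture, same shape
and protocol. Reported ratios are baseline-MSE / model-MSE averaged over
trials; the margin over the 5× bar is stochastic across generator seeds,
with tree ensembles typically the tightest family.

MT synergy uses 10 series of 10–16 compounds, 6 targets, one target
thinned to 30 labels, noise sd 0.2, series sd 1.0, test fraction 1/3.
Because the additive model shares substituent effects across targets, tasks
remain weakly related even at ρ = 0; "no systematic advantage" there means
a mean MAE gain below the 0.1 pKi relevance threshold, not exactly zero.

## Known limitations

- The NumPy network trains on a single CPU; the full 2340-point DNN grid is
  enumerable but impractical without subsampling.
- Cores are matched by exact canonical SMILES equality; tautomer- or
  stereo-aware matching is not attempted (and de-duplication is not
  stereochemistry-aware).
- AS splits meet the requested test fraction only up to whole-series
  granularity, and no balancing of per-target test sizes is done under
  global strategies.
- The fingerprint is one fixed representation; count fingerprints,
  pharmacophores and learned representations are out of scope.
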