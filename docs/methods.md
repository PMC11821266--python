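# Methods

## The problem

Scoring functions for protein–ligand binding affinity are trained on
databases of crystal complexes whose ligands and pockets recur heavily.
A model can therefore score well by memorizing *ligand identity* (the
same molecule tends to bind with similar affinity wherever it appears)
or *pocket identity* (similar pockets bind with similar affinity),
without modelling the interaction at all. sfprobe operationalizes this
concern: it provides predictors that can *only* exploit such bias,
benchmark constructions that selectively destroy it, and perturbation
generators that probe sensitivity to 3-D structure.

## Labels

Every complex carries one measured affinity (Ki, Kd or IC50 with a
unit). The regression target is pK = −log₁₀(value in molar). The three
measurement types are merged onto this single scale — a standard, if
lossy, convention; the type is retained on each record so users can
re-stratify. Qualifiers (`>`, `<`, `~`, `>=`, `<=`) are parsed and
stored but by default treated as exact values; `load_dataset(...,
exclude_qualified=True)` drops them instead. Complexes whose structure
or label cannot be parsed are excluded, never repaired, and every
exclusion is reported with a reason — the exclusion set necessarily
depends on the parsing toolkit version, so the report substitutes
transparency for bit-exact reproducibility of any particular corpus.

## Feature views

**Ligand view.** The full named RDKit 1D/2D descriptor battery is
computed on the training ligands; any descriptor that is non-finite or
exceeds an overflow threshold (default 1e8, configurable) on *any*
training ligand is excluded. The retained, alphabetically ordered list
is frozen into a serializable schema together with training medians,
which impute the rare predict-time descriptor failure. Descriptors are
functions of the molecular graph only, so every conformer and rigid
pose of a molecule maps to the same vector — this is what makes the
ligand view structurally blind. The retained count is a property of the
toolkit version, not a contract, which is why the schema records the
procedure rather than asserting a number.

**Pocket view.** A residue is in the pocket if any of its heavy atoms
lies within 15 Å (inclusive, Euclidean) of any ligand heavy atom; it
counts once regardless of how many atoms qualify. The feature vector is
the 21 counts (20 standard residues in fixed alphabetical 3-letter-code
order, plus UNK for non-standard residues, so pocket size is
conserved). Hydrogens are excluded from the distance test because their
placement is inconsistent across PDB files; both the threshold and the
heavy-atom rule are parameters. The 15 Å default is deliberately
generous — the point is to capture pocket *identity*, not geometry.

**Both view** concatenates the two blocks, ligand first. The ensemble
baseline instead averages the two single-view models' predictions
(unweighted by default; weights are exposed).

## Baseline training

Each baseline is a tree-ensemble regressor. Hyperparameters come from a
small fixed grid — two random-forest and two histogram-gradient-boosting
configurations — scored by K-fold (default 5) cross-validated RMSE,
with the winner refit on all non-excluded records. A fixed, documented
grid was chosen over an AutoML search deliberately: the selection
trajectory is then reproducible from the seed alone, and the grid's
members are the configurations practitioners actually reach for.
`search_budget` truncates the grid; at budget 1 the single default
configuration is fit directly without cross-validation, which is the
package's own default for simulation studies where the signal is strong
and the interest is in the *view*, not the tuning. Exclusion lists
(e.g. a benchmark's test complexes) are applied before fold assignment
and before the final refit. Everything is deterministic under a fixed
seed.

## Benchmark construction

*Zero-ligand-bias.* Records are clustered by full 27-character
InChI-Key (read strictly: "identical molecule" means identical
connectivity, stereochemistry and charge state); only keys occurring
twice or more form clusters. A cluster enters the test set when its
mean pK lies within [6, 7] (endpoints inclusive) and its sample
variance (n−1 denominator) strictly exceeds 1. The centering window
prevents the per-cluster-mean shortcut from inflating correlation; the
variance floor guarantees within-ligand spread that ligand identity
cannot explain. Any training record sharing an InChI-Key with a test
record is additionally excluded from the train side (toggleable):
leaving duplicates in training would reintroduce exactly the leakage
the benchmark exists to remove.

*Peptide holdout.* Test = ligand code contains "MER",
case-insensitively (component codes are conventionally upper case but
files vary). An optional maximum-length restriction is not defaulted.

*Time split.* Test = deposition year ≥ cutoff, inclusive; records with
no year join neither side and are reported.

Every split is checked by a generic validator: train/test/excluded are
disjoint, they account for the whole dataset, and the constructing
rule's predicate holds on every member.

## Perturbations

*Clashes.* The translation direction is the unit vector from the
globally closest ligand heavy atom to the globally closest protein
heavy atom — pointing into the protein — computed once from the
unperturbed complex and reused for all steps (ties broken by lowest
atom-index pair). Step k places the ligand at `x + k·1 Å·u`, so the
in-place RMSD to the crystal pose is exactly k Å and all interatomic
distances are preserved.

*Decoy binning.* RMSD is in-place (no superposition — pose accuracy is
positional) over order-matched heavy atoms. Bins are half-open
`[lo, hi)` with the final bin closed at 30 Å, a fixed convention that
prevents double-assignment at shared edges. Per bin, the pose
minimizing distance to the bin midpoint is selected; empty bins stay
empty; ties break on lowest pose id. Symmetry-corrected RMSD (for, e.g.,
flipped aromatic rings) is out of scope in this version.

## Metrics

Pearson R, R² and RMSE. R² is the coefficient of determination
1 − SS_res/SS_tot — not the square of Pearson R — and can be negative.
Zero-variance inputs raise an error and surface as undefined cells,
never as a silent 0. Confidence intervals are percentile bootstrap
(simple, cheap, deterministic): pairs resampled with replacement,
default 10 000 draws, CI at the 2.5/97.5 empirical percentiles. The
point estimate is always the full-sample metric. Degenerate resamples
(zero variance) are redrawn rather than dropped, keeping the effective
resample count, and the redraw count is recorded. Pairing is by complex
id join, never row order. In report tables the best cell per benchmark
is the highest point estimate; a cell is "tied" when its CI intersects
the best cell's CI (the alternative reading — best CI containing the
other's point — is a one-line switch in the overlap test). The "±"
rendering uses the larger half-width of the (possibly asymmetric) CI;
exact bounds are always emitted alongside. Correlations within a few
machine epsilons of ±1 are snapped onto the bound so a perfect
predictor reports exactly 1.00 with a zero-width interval.

## Synthetic data: what it emulates and what it does not

The generator reproduces only the statistical structure the baselines
exploit:

    pK = base + α·ligand_effect + β·pocket_effect + ε,  ε ~ N(0, σ²)

- *ligand_effect* is a fixed functional of ligand identity —
  standardized heavy-atom count, `(N_heavy − 12)/4` — over a built-in
  40-molecule drug-like library with seeded distance-geometry 3-D
  coordinates. Fixed (not resampled) so the signal is stable across any
  train/test split.
- *pocket_effect* is a fixed linear functional of the pocket
  composition: a standardized hydropathy weight vector dotted with the
  21-count vector, scaled by a frozen constant (23) so its spread is
  roughly unit across randomly sampled pockets. Compositions
  concentrate 25–45 residues on five residue types, giving strong
  between-pocket contrast.
- Defaults — 500 complexes, α = β = 1, σ = 0.3 pK, base 6.5, years
  uniform on 2010–2022 — are the package's standard simulation
  conditions: both bias channels comparably strong, label noise small
  relative to signal, ligands recurring across pockets as they do in
  real affinity databases.

Pockets are geometric scatters of rigid five-atom residue templates
placed 5–12 Å from the ligand centroid (verified ≤ 14 Å from the
nearest ligand atom, so composition recovery at the 15 Å cutoff is
exact by construction), with optional distractor residues verified
beyond 25 Å. They are not folded proteins, have no side-chain
chemistry, and template geometry is schematic; every in-scope
computation depends only on residue identity and atom distances, which
scatters control exactly. Consequently, passing tests demonstrate that
the pipeline's logic is correct and that the baselines recover planted
bias — they do not demonstrate accuracy on real structures, model real
binding physics, docking energetics, or descriptor distributions of
real chemistry.

The zero-bias testbed plants 12 duplicate-ligand clusters of 2–4
members whose pK values are constructed as `center + s·(e_i − ē)` with
center uniform in [6.2, 6.8] and `s` chosen so the sample variance hits
a target in [1.5, 3] — within-cluster spread carried entirely by the
pocket channel (the generator refuses α ≠ 0 here, since ligand identity
must not explain the spread). Decoy clusters with out-of-range means or
sub-threshold variance, plus singleton ligands, make filter precision a
meaningful quantity. Decoy poses at prescribed RMSDs combine a random
rotation about the centroid (capped to contribute at most half the
target) with a translation found by bisection on the realized RMSD,
accurate to 0.01 Å.

## Numerical and degenerate-input conventions

- Affinity units down to fM are accepted; pK of 10⁻ᵖ M is exactly p.
- An empty pocket is a legal all-zeros composition, not an error.
- Coincident closest atoms make the clash direction undefined and raise.
- `bootstrap_metric` requires ≥ 3 points; correlation on constant input
  raises rather than returning 0.
- All generator output, model predictions and metric results are
  reproducible from seeds, down to byte-identical fixture trees.

## Problem sizes in the verification scripts

The test suite and `scripts/acceptance.py` use 500-complex datasets
(5 seeds) for bias recovery, 10 random configurations for filter
precision/recall, 50 fixtures for the clash-direction oracle, 100
random multisets for the binning oracle, and 500 replicate datasets
(n = 200, 1 000 resamples each) for bootstrap CI coverage — sizes
chosen so each estimate is stable at the asserted margins while the
whole verification remains a desk-scale computation.

## Known limitations

- No protonation/tautomer assignment, structure repair, or mmCIF input.
- No symmetry-corrected RMSD.
- The descriptor battery, and hence the retained feature count, tracks
  the installed RDKit version.
- Qualified affinities are treated as exact unless excluded.
- The CLI covers the common paths; compositional workflows are expected
  to use the Python API.
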