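# Methods

This note records the model, the conventions, and the design choices
behind `torsionflux`, including the places where a convention had to be
fixed by us rather than by an external definition.

## Geometry

Dihedrals follow the IUPAC sign convention: 0° is cis, 180° is trans,
and the angle is positive for a clockwise rotation of the far bond
viewed from p2→p3.  Values live in the half-open interval (−180°, 180°].
φᵢ is measured over C(i−1)–N(i)–Cα(i)–C(i) and ψᵢ over
N(i)–Cα(i)–C(i)–N(i+1); the first φ and last ψ of a chain are
structurally undefined and carried as NaN with explicit masks — never
as silent zeros.  Degenerate geometry (coincident consecutive points,
collinear triples) flags the position rather than aborting the chain.

`build_backbone` places N/Cα/C atoms sequentially by natural-extension
(NeRF) internal-coordinate placement with ideal peptide geometry
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles N–Cα–C 111.2°,
Cα–C–N 116.2°, C–N–Cα 121.7°; ω = 180° unless given).  Measuring a
built backbone reproduces the input torsions to ~1e−13°, far inside
the 1e−6° round-trip tolerance the tests assert; this round trip is
what lets synthetic ensembles carry exactly known angular noise.

PDB reading uses Biopython.  Altlocs resolve to the highest-occupancy
conformer (first encountered on ties); residue order follows residue
sequence number plus insertion code as parsed; files without
MODEL/ENDMDL records count as one implicit model.  A residue missing a
backbone atom in any model is flagged and excluded from label
computation; the model is kept (this maximizes usable residues).  A
chain is rejected only when no residue has a complete backbone.

## Fluctuation labels

The per-residue, per-angle label is the wrapped standard deviation
about the circular mean, σ = sqrt((1/M) Σ wrap(θₘ − θ̄)²), normalized
by 180° so labels are dimensionless in [0, 1].  Choices worth stating:

* **Wrapped SD, not sqrt(−2 ln R).**  The wrapped deviation is bounded
  by 180°, so σ/180 is bounded by 1, matching the dimensionless label
  scale used throughout evaluation (the degree-scale errors 22.7°/24.3°
  of the reference predictor correspond to 0.126/0.135 on this scale,
  which is exactly /180).
* **Population (1/M) normalization** by default; `ddof=1` is available.
  With M ≥ 5 models the difference is small relative to sampling error.
* **Degenerate circular means** (resultant length ≈ 0, e.g. antipodal
  pairs) make the label undefined at that position rather than
  inventing a value.
* **Undefined positions** (termini, missing atoms, < 2 defined models)
  are excluded from training and evaluation, not imputed.

Dataset filters keep chains with ≥ 5 models, ≥ 25 residues, and only
standard amino acids — thresholds are strict "less than" rules, so
M = 5 and L = 25 survive.  Each removed chain is attributed to the
first failing rule, checked in that order.

## Features

The default per-residue layout is 77 columns in seven groups: one-hot
residue identity (20), the five-factor physicochemical solution of
Atchley et al. (5; shipped as package data), logistic-normalized PSSM
(20), PSSM monogram (1), PSSM bigram (20), structural (ASA + two H/C/E
secondary-structure probability sets, 7) and flexibility (disorder
probability, externally predicted Δφ/Δψ, PSEE, 4).  Conventions we
fixed:

* PSSM "normalization" is the logistic transform 1/(1+e^(−x)) of the
  integer log-odds scores; columns are reordered from PSI-BLAST layout
  to alphabetical amino-acid order.
* Monogram MG(i) is the mean of row i; bigram BG_k(i) =
  (1/20) Σⱼ P(i,j)·P(i+1,k), with a self-transition fallback
  P(i+1) = P(i) at the last residue.
* Probability-like inputs outside [0, 1] are clipped with a warning;
  a missing PSEE track is imputed with a per-chain constant so the
  column stays present and NaN-free.
* The window of odd width ws concatenates rows i−h…i+h
  (h = (ws−1)/2); out-of-range offsets are zero-filled by default
  (edge replication is available).  The layout is configurable; widths
  other than 77 arise by enabling/disabling groups.

## GA feature selection

Chromosomes are binary masks over feature columns.  Fitness is
objfit = 1 − MAE + PCC of pooled out-of-fold predictions of a fast
boosted-tree regressor (depth 6, learning rate 0.1, 100 trees,
min_child_weight 5, subsample 0.9, max_bin 500) under chain-level
3-fold CV; an empty mask carries a −∞ sentinel.  Evolution uses
elitism (default 2), fitness-proportional roulette selection on
min-shifted fitness, single-point crossover (rate 0.9) and per-gene
bit-flip mutation (rate 1/D).  Defaults are population 50 and 30
generations; the recovery experiments below use a smaller budget
(population 24, 12 generations), which suffices at their scale.
Repeated masks are served from a cache, and the whole search is
reproducible from one seed.

## Regression and evaluation

One LightGBM regressor per angle.  The shipped defaults (learning rate
0.014, 2561 trees, depth 19, 380 leaves, 138 bins, feature fraction
0.52) are the tuned full-scale operating point; simulations and tests
use compact configurations.  Cross-validation partitions whole chains
into k near-equal folds by seeded shuffle; metrics are computed on the
pooled predictions within each fold and then averaged across folds
(the aggregation level had to be fixed by us), and objfit is formed
from the aggregate MAE/PCC.  Improvement tables report
(base−new)/base·100 for MAE, (new−base)/base·100 for PCC, and their
mean.  Note that percent improvements recomputed from rounded
MAE/PCC values can differ from improvements computed on unrounded
internal values; `improvement_table` is defined on exactly the values
supplied.

## Synthetic data: what it emulates and what it does not

`synth_ensemble` draws each model's φᵢ/ψᵢ from a wrapped normal around
per-residue base angles (default helix-like −57°/−47°) with planted
per-residue SD, then realises coordinates through `build_backbone`.
This emulates the one property the label statistic measures — angular
dispersion across models — with an exactly known ground truth.  It does
not emulate correlated inter-residue dynamics, sequence-dependent
flexibility, experimental restraint artefacts, or side chains, so
passing recovery tests validates the measurement pipeline, not any
claim about real protein dynamics.

`synth_features` draws features i.i.d. U(0, 1) and builds labels as
0.5 + Σ coeff·(X[i+offset, col] − 0.5) + N(0, σ) clipped to [0, 1],
with the informative (offset, column) set recorded.  Real feature
tracks are correlated and non-uniform; planted-signal recovery shows
the selection and evaluation machinery works, not that real features
behave this way.

## Study conditions for the recovery experiments

Chosen once at design time; all sizes are desk-scale by construction.

* **Label recovery**: planted σ ∈ {0, 9, 18, 36}° at L = 40, M = 200;
  mean recovered label within 5% relative of σ/180 (exact at σ = 0).
  The per-residue estimator SE is σ/√(2M) ≈ 5% at M = 200; averaging
  over residues leaves ample margin.
* **GA recovery**: 5 informative of 50 columns, coefficients 0.35,
  noise SD 0.1, 20 chains × 25 residues (n = 500); at least 4 of the 5
  planted columns must appear in the best mask, and elitism must keep
  the best-ever fitness non-decreasing.
* **Window sweep**: labels built solely from offsets −1/+1 (coefficient
  0.4, noise SD 0.1), 200 base columns, 15 chains × 25 residues.  A
  width-3 window contains the entire signal, so wider windows can only
  add irrelevant context — but a boosted tree is robust to i.i.d. decoy
  columns, and the expected objfit penalty at ws = 5 is small relative
  to single-draw noise.  The experiment therefore uses a deliberately
  low-capacity regressor (20 trees, 7 leaves, learning rate 0.4,
  max_bin 63), in which every split spent on a decoy column costs
  accuracy, and replicates the sweep over independent datasets,
  averaging per-ws objfit before taking the argmax (48 replicates in
  the acceptance script, 12 in the seeded test).  The selected width is
  a property of the averaged curve, as a window-size choice should be.
* **CV learnability**: a noiseless 3-column linear signal must reach
  pooled CV PCC > 0.99 under 10-fold chain-level CV; feature-free
  labels must give |PCC| < 0.1.

## Numerical details and limitations

* Angles wrap into (−180°, 180°]; an exact −180 maps to +180.
* Circular-mean degeneracy threshold: resultant length ≤ 1e−12.
* Fold counts require at least k chains; folds are near-equal via
  round-robin over a seeded permutation.
* Roulette selection shifts fitness by its minimum plus 1e−12, so a
  population of equal fitness degenerates gracefully to uniform choice.
* The GA does not model feature interactions beyond what the fitness
  regressor sees, and with strongly correlated columns the selected
  mask is one of several equivalent optima — only planted-signal
  membership, not uniqueness, is asserted.
* Headline accuracies on curated NMR ensembles require external
  feature programs whose outputs are inputs here; nothing in this
  package claims to reproduce them.
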