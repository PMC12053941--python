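# Methods

## Problem and model

Transition-metal-catalyzed C–H borylation replaces one of a substrate's
C–H bonds with a Bpin group; which bond reacts is governed by a mix of
electronic and steric effects. `borylsite` treats selectivity prediction
as a per-site binary classification: every sp²/sp³ carbon bearing at least
one hydrogen is a candidate row, labeled 1 if that position undergoes a
site-selective (≥95%) borylation under the recorded conditions and 0
otherwise. Because a selective reaction has one productive site among
several candidates, the class balance is inherently skewed (roughly 1:4
at ~5.2 candidate sites per substrate).

The dominant features are computed atomic charges at the site: for each of
six charge schemes (Mulliken, NPA, MBS, Hirshfeld, CM5, ChelpG) the
hydrogen charge q_H, the carbon charge q_C, and the derived *heavy-atom
charge* q_heavy = q_C + Σ q_H over the hydrogens bonded to that carbon.
Charge computation itself is out of scope: charges arrive as a CSV from
the user's quantum-chemistry workflow, keyed by (substrate_id, atom_index)
in the canonical atom order the parser assigns. Canonical order is
obtained by rebuilding the molecule from its canonical SMILES, which makes
atom indices reproducible for any input writing of the same structure.

Symmetry-equivalent sites are collapsed topologically (canonical-rank
equivalence without tie-breaking), not geometrically: a curated database
counts unique positions, and graph automorphism is the convention that
reproduces those counts. Aldehydic C–H (carbon double-bonded to oxygen)
and sp carbons are excluded as outside the sp²/sp³ C–H scope. The
"exactly one selective site per substrate" integrity check is a toggle
(`curated=True`) because condition-resolved datasets legitimately contain
the same substrate under different catalyst–ligand pairs with different
selected sites.

## Descriptors

Molecule-level descriptors are computed on the explicit-hydrogen 2-D
graph:

* **Autocorrelations.** For an atomic property vector w and topological
  distance d(i,j): ATS_k = Σ_{d(i,j)=k} w_i w_j (ATS_0 = Σ w_i²); AATS_k
  divides by the pair count at lag k; ATSC/AATSC use centered weights;
  the Moran coefficient MATS_k = AATSC_k / AATSC_0; the Geary coefficient
  GATS_k = [Σ (w_i−w_j)²/(2 n_k)] / [Σ (w_i−w̄)²/(N−1)]. Ten weightings
  are provided (Gasteiger charge, valence and sigma electron counts,
  Kier–Hall intrinsic state, Z, mass, van der Waals volume, Pauling
  electronegativity, polarizability, ionization energy) at lags 0–5.
  Undefined combinations (no pairs at a lag, zero-variance weight) yield
  NaN — a flagged missing value, never a silent zero.
* **BCUTZ-1l** is the lowest eigenvalue of the Burden matrix
  (hydrogen-suppressed graph, atomic numbers on the diagonal, 0.1 × bond
  order off-diagonal, 0.001 for non-bonded pairs).
* **RPCG** is the largest positive Gasteiger charge divided by the sum of
  positive charges.
* **FilterItLogS** slot: filled by a Delaney-type linear aqueous
  solubility estimate (logS from clogP, molecular weight, rotatable
  bonds, aromatic proportion). This is the package's own estimate for
  that column; deposited datasets supplying their own values override it.

Four atom-level descriptors (steric effect index, atomic polarizability
of the bonding carbon, distance degree, Dreiding energy) are normally
supplied as input columns from external software. When absent, clearly
labeled topological **surrogates** fill them: a distance-weighted
covalent-volume sum (Σ r_cov³/d³) for steric effect, a distance-damped
polarizability sum for atomic polarizability, the graph distance-sum for
distance degree, and a heavy-atom/ring/rotor combination for the
force-field energy slot. They preserve the column contract, not the
original numerics.

The condition registry encodes 7 precatalysts and 8 ligands as integers.
Three assignments are fixed by the source data ([Cp*RuCl₂]₂ = 1 among
catalysts; no added ligand = 1 and dtbpy = 2 among ligands); the remainder
follow a shipped conventional order and are flagged non-authoritative.
Distinct catalyst–ligand pairs that converge on the same active tris-boryl
complex share one active-catalyst code and, by construction of the
parameter table, one steric parameter vector. The shipped parameter CSV
contains synthetic placeholder magnitudes (file name says so) because the
underlying computed values are not published as a table. Temperature is
carried in °C; solvent-free reactions use the reserved "neat" code.

## Feature-reduction cascade

1. **Zero variance**: a column is constant iff all values are equal
   (exact comparison, immune to floating-point mean error).
2. **Correlation filter**: greedy scan in column order; a column is kept
   only if its |Pearson r| with every already-kept column is ≤ 0.95.
   Absolute correlation is used because the retained feature set still
   shows rank correlations down to −0.77 — sign alone is not grounds for
   removal. Keeping the earlier-ordered member makes the filter
   deterministic.
3. **Importance selection**: a seeded 100-tree random forest; retain
   columns with impurity importance ≥ the mean (degenerate ties retain
   everything).
4. **Ward clustering**: distance 1 − |r| between columns, Ward linkage,
   flat clusters at a threshold (default 0.5; the benchmark grid
   {0.1, 0.3, 0.5, 0.7} is exposed as configuration — these values are
   package defaults, not reproduced settings). One representative per
   cluster: highest importance if available, else earliest column.

The cascade is fitted on training rows only and applied to test rows by
column selection — a leakage guard adopted deliberately where the
procedure's provenance is silent.

## Training protocol

Each run: substrate-grouped 80:20 split (|train| = round(0.8 × n);
seeded permutation of sorted substrate ids) → random oversampling of the
minority class to exact parity (with-replacement duplicates of minority
rows only; test rows never touched) → cascade fit → learner fit. The
oversample-before-cascade order was chosen so the importance stage sees
balanced classes. Ten runs with fresh splits give every metric as mean ±
SD; re-randomizing the split (not just the learner seed) is documented as
this package's convention. All per-run seeds derive from one master seed
through a CRC-based counter, so a single integer reproduces everything.

The bench covers decision tree, SVM, random forest (500 trees, unlimited
depth — pinned here for determinism since no canonical setting exists),
multilayer perceptron, Gaussian process, Gaussian naive Bayes and
logistic regression. SVM, MLP, Gaussian process and logistic regression
receive row-wise unit-norm scaling (sample vectors normalized, not
columns), applied identically at fit and predict time. Binary calls use
strict `probability > 0.5`: a decision value of exactly 0.5 is a negative
call, consistent with treating 0.5 as the base value a positive decision
must exceed.

Per-site predictions aggregate across runs as vote fractions (6 positive
votes in 10 runs → 0.6). The interpretation layer is a pure function of
a substrate's vote fractions: exactly one site above 0.5 → *selective*
(≥5:1 expected), exactly two → *moderately selective* (≤4:1, both sites
viable), zero or three-plus → *nonselective* (multi-site output is
treated as no selective prediction). The 0.5 vote-fraction cut and the
strict inequality are package conventions; the source narrative does not
fix whether 5/10 counts as predicted.

## Controls, ablations, attributions

Ablations retrain the full protocol on feature-group subsets (charges /
experimental / molecular descriptors / steric-topological). The
shuffled-target control permutes the label assignment only; the
feature-order control permutes the *selected* columns inside each run,
after feature selection — shuffling before selection would change the
correlation filter's order-dependent tie-breaks and measure the wrong
thing.

SHAP attributions implement path-dependent TreeSHAP for sklearn tree
ensembles (the only learners the attribution game is defined for here;
others raise an unsupported-model error). Per tree the algorithm is exact;
forest attributions and the base value are tree averages, so local
accuracy — base + Σ contributions = predicted probability — holds to
machine precision and is verified against a brute-force
subset-enumeration Shapley oracle in the tests. After oversampling, the
training classes are balanced and the base value sits at ≈0.5.

The Spearman matrix uses average ranks for ties; constant columns yield
NaN entries and are listed in the result's `attrs["constant"]`.

## Synthetic generator

The generator emulates the statistical structure the classifier exploits,
at the study scale: 189 substrates, sites per substrate = 1 + Poisson(4.22)
(mean ≈ 5.2, ≈987 sites, ≈189:798 class ratio), exactly one borylating
site per substrate before label noise. Borylating sites draw the three
key charges uniformly inside the empirical windows (Hirshfeld-H
[0.04, 0.06] e, ChelpG heavy [−0.2, 0.1] e, Mulliken-H [0.10, 0.14] e;
closed intervals); nonborylating sites draw from wider overlapping
spreads but are rejection-sampled to violate at least one window, so the
window rule is Bayes-optimal on clean labels. NPA-H and Hirshfeld-heavy
are linear in Hirshfeld-H with small Gaussian scatter (the observed
linear charge–charge trends); every scheme's q_heavy satisfies
q_c + h_count·q_h exactly. Default label noise is 5% (independent
symmetric flips). Conditions are sampled uniformly from the registry; an
optional ligand-switch mode re-emits a fraction of substrates under
different conditions with the selected site moved, emulating
condition-dependent regiochemistry. Nuisance molecule-level descriptors
(plus a few exact duplicates and one constant column to exercise the
cascade) carry no signal. The class-overlap margins of the spreads are a
free choice — no quantitative overlap is published — fixed once at values
that make the task hard but learnable.

What passing on this generator shows: the pipeline recovers a planted,
separable charge-window mechanism under realistic imbalance, grouping and
label noise, with the correct qualitative ordering of algorithms,
ablations and controls. What it does not show: performance on real
chemistry, where charges are correlated with sterics and conditions in
ways no window rule captures, descriptors are not pure noise, and the
Bayes error is unknown. Real-data accuracy claims require the curated
literature dataset with DFT charges.

## Problem sizes and numerics

Acceptance-level checks use the full study-scale conditions (189
substrates, 10-run protocols, 10 repetitions for ordering/ablation
claims); unit tests use 40–120 substrates and 1–4 runs. The
importance-selection forest is 100 trees (a fixed seeded size; the
production classifier keeps 500). TreeSHAP diagnostics use a 50-tree,
depth-6 forest — additivity is exact for any size, and depth-limited
trees keep the Python implementation quick. Tolerances: heavy-atom-charge
identity 1e-9; SHAP additivity 1e-6 (observed ~1e-15); oracle
equivalences exact to 1e-12.

## Known limitations

* The registry's unattested code assignments and the catalyst parameter
  CSV are conventions/placeholders; supply project-specific tables for
  real work.
* The four external atom-level descriptors are surrogates unless provided
  as inputs; their absolute values are not comparable to the originals.
* TreeSHAP covers random forests and single trees only.
* The generator plants no catalyst-dependent selectivity by default;
  condition features are uninformative there unless ligand-switch mode is
  enabled.
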