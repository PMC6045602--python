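# Methods

This note documents the models, numerical choices and synthetic-data
design behind resistograph, and what the test suite does and does not
establish about real data.

## Stability landscape

Inputs are per-mutation folding free-energy changes ΔΔG_fold (kcal/mol,
mutant minus wild type, positive = destabilizing), typically three
replicate runs per mutation from an empirical force field. Replicates are
averaged arithmetically; the spread is reported as the sample standard
deviation (n−1 denominator, configurable to population form), with a
single replicate defined to have zero spread.

Categories use symmetric bin edges at ±0.46, ±0.92 and ±1.84 kcal/mol —
multiples of the ~0.46 kcal/mol accuracy of the predictors that produce
such tables, so "neutral" means indistinguishable from zero at that
accuracy. Values exactly on an edge belong to the bin closer to zero:
(−∞,−1.84) / [−1.84,−0.92) / [−0.92,−0.46) / [−0.46,0.46] / (0.46,0.92] /
(0.92,1.84] / (1.84,∞). "Moderate" in summaries means not in either
extreme bin.

Density curves use a Gaussian kernel with Silverman's rule-of-thumb
bandwidth by default (overridable). The evaluation grid extends four
bandwidths beyond the data range: three leaves up to 0.27 % of kernel
mass outside the grid for boundary-dominated samples, four keeps the
trapezoidal integral within 10⁻³ of unity. Peak detection is a
first-difference sign change; a flat plateau flanked by an ascent and a
descent counts once, at its midpoint, and an optional relative-prominence
filter (scipy's implementation) suppresses sampling ripples when the
question is "how many modes", not "where is every local maximum".

The stability–exposure association uses Spearman's rank correlation
(mean ranks on ties, scipy backend). Multi-site mutations have no single
residue exposure and are excluded from the pairing; they remain in
landscape summaries. A mutation at a residue missing from the SASA table
is an error, never a silent drop.

## Solvent-accessible surface area

Shrake–Rupley with a 1.4 Å water probe: each atom's van der Waals sphere
is inflated by the probe radius and covered with n deterministic test
points (default 960) laid out on a golden-section spiral — reproducible
without a random seed, quasi-uniform, with discretization error that
shrinks roughly as 1/n. A test point is buried if it falls inside any
neighbour's inflated sphere; neighbours are found with a k-d tree and
pruned to the exact occlusion range r_i + r_j + 2·probe. Per-atom area is
the accessible fraction times 4π(r+probe)². Van der Waals radii ship as
an element-keyed table (Bondi-style values) and can be overridden.
Hydrogens neither accumulate area nor occlude by default. Residue SASA
sums all atoms (side-chain-only as an option); exposure classes default
to buried < 5 Å² and exposed > 70 Å². All areas are in Å² throughout.

Because the point sphere is fixed in the laboratory frame, SASA under a
rigid rotation of the structure is reproduced only to discretization
tolerance (≲ 1–2 % at 960 points), which the tests assert explicitly.
Accuracy is checked against an independent Monte-Carlo surface
integrator and the analytic two-sphere cap formula (≤ 1 % deviation).

## Epistatic (Potts) scoring

E(σ) = Σ_i h_i(σ_i) + Σ_{i<j} J_ij(σ_i, σ_j); couplings are stored for
i<j only. ΔE = E(mutant) − E(wild type) with all sites of a multi-site
mutation applied jointly, so ΔE(double) = ΔE(a) + ΔE(b) + coupling
correction, collapsing to additivity exactly when no coupling touches
the mutated pair. Fitting the model is out of scope; models arrive
through a plain-text parameter format (`ALPHABET`/`L`/`POS`/`H`/`J`
records, 1-based positions, full float precision) or the synthetic
generator. A mutation at a position outside the model raises an error —
silently scoring 0 would bias summaries. Wild-type letters are checked
at every site. Pathogenicity labels are ingested annotations, never
predicted.

## Binding energetics and resistance calls

G = E_vdw + E_ele + E_int + G_gb + G_surf (+ G_qm for mixed
quantum/classical schemes) + (−TΔS). The entropy column is consumed, not
computed; when absent it is treated as 0 with a warning (enthalpy-only
end-state practice). G_surf = γ·SASA + β with γ = 0.0072
kcal·mol⁻¹·Å⁻², β = 0. ΔG_bind = G_complex − (G_receptor + G_ligand);
ΔΔG_FR = ΔG_mt − ΔG_wt, positive meaning affinity lost on mutation.
Experimental mutation energies derive from inhibition constants as
RT·ln(Ki_mut/Ki_wt), R = 1.9872×10⁻³ kcal·K⁻¹·mol⁻¹, T = 300 K default.

Scheme validation reports the squared Pearson correlation between
predicted and experimental ΔΔG_FR ("coefficient of determination" is
ambiguous; for a simple least-squares fit with intercept the regression
form is identical, and it is available behind a flag).

The resistance classifier runs, in order: (1) ΔΔG_FR(inhibitor) ≥
threshold → resistant; (2) else if ΔΔG_FR(inhibitor) < ΔΔG_FR(ATP) →
likely_sensitive (the inhibitor still out-competes the kinase's natural
substrate); (3) else → resistant, ties included — the conservative
reading; (4) no ATP reference below threshold → indeterminate. The
threshold is configurable with a default of 8.0 kcal/mol, chosen so that
the well-characterized calls in the ALK literature (gatekeeper
L1196M/crizotinib at 8.59 resistant; ceritinib/F1174C at 10.65
resistant; ceritinib/I1171T at 5.07 deferred to the ATP comparison
against 7.31; lorlatinib against L1198F/C1156Y at 8.64 resistant) fall
on the expected side. Calls near the threshold deserve a sensitivity
check, which the configurable flag makes trivial.

## Trajectory analysis

Superposition is the Kabsch algorithm via SVD of the cross-covariance,
with the determinant-sign correction so the rotation is always proper
(det +1); degenerate (collinear, < 3 atoms) inputs are rejected. RMSD
series superpose each frame to the reference (frame 0 by default) before
measuring; the mean excludes an initial burn-in given in time units
(strict inequality time > burn-in). Average structures are per-atom
means of superposed frames in a time window. Segment RMSD aligns on the
full structure or on the segment itself and reports over the segment —
full-structure alignment measures displacement in context (e.g. an
activation-segment shift), segment alignment measures internal
deformation only.

PCA centers the frames-×-3N coordinate matrix and takes a thin SVD —
the same eigensystem as diagonalizing the 3N×3N covariance, with
eigenvalues s²/(n−1) in Å². Total variance equals the trace of the
covariance (asserted to 10⁻⁶ relative); projections are uncorrelated
across components by construction. Atom selections default to all atoms
of the (synthetic) trajectories here; for real kinase-domain work a Cα
selection is the conventional choice and is what the selection argument
is for. Optional per-atom weights implement mass weighting; the bundled
generators are mass-uniform so no mass table ships.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical *structure* the analyses
assume, with all randomness from one seeded stream per call:

- **Landscape**: 20 rows per position (the synonymous self-substitution
  carries ΔΔG exactly 0 as a control); non-synonymous background ΔΔG
  from a single near-zero normal (mean 0.2, sd 1.0 kcal/mol); an
  "observed" subset (default 145 mutations) from a two-component
  mixture — weights 0.45/0.55, means 0.3/3.12, sds 0.6/1.2 kcal/mol —
  echoing the clinically observed excess of destabilizing mutations
  peaking near 3.12 kcal/mol. Replicate columns are noise-balanced to
  average exactly to the planted value. Per-residue SASA has an
  exponential marginal (scale 40 Å²) and is tied to ΔΔG through a
  Gaussian copula whose latent correlation r = 2·sin(π·ρ_s/6) targets a
  chosen Spearman ρ_s (default −0.57, the reported ALK value), so the
  planted rank correlation is analytically known and survives any
  monotone marginal transform.
- **Energy tables**: resistant (ligand, variant) cells are planted at
  ΔG_wt + 10 kcal/mol, sensitive at +0.5, ATP rows at +3.5 for sensitive
  variants so the competition rule discriminates; Ki values invert the
  RT·ln formula (lognormal noise optional), making the noiseless R²
  exactly 1 and label recovery exactly 100 %.
- **Trajectories**: reference structure plus orthonormal sinusoidal
  modes (variance amplitude²/2 each; default amplitudes 3:1 give a 9:1
  eigenvalue ratio) plus isotropic thermal noise, default σ = 0.05 Å so
  the two planted modes hold > 85 % of the variance on the default
  20-residue reference; optional per-frame rigid roto-translations
  (frame 0 untouched) exercise superposition removal.

Two statistical caveats the tests respect: a 145-draw sample from the
observed mixture fails to show two *raw* KDE modes for roughly 1 seed in
15 (sampling noise fills the dip), so bimodality checks run at a fixed
seed; and the copula's Spearman target is recovered to ±0.1 at ~1000
pairs, not exactly.

Passing on synthetic data shows the statistics, estimators and decision
rules are implemented correctly — it does not validate force fields,
solvation models or sampling on real systems. The quantities that need
those upstream engines (per-mutation ΔΔG_fold values, per-cell ΔΔG_FR
from structures, 50-ns RMSD averages) are consumed as inputs, never
recomputed here.

## Problem sizes

Defaults were sized for interactive use: 4940-mutation landscapes,
53-position (~1000-pair) correlation checks, 40-cell energy profiles,
5000-frame × 100-atom PCA recoveries. The full test suite runs in a few
seconds on one CPU; `scripts/acceptance.py` in about two.

## Known limitations

- The PDB reader handles fixed-column ATOM/HETATM coordinate records
  only (no mmCIF, no hydrogen placement); alternate locations resolve to
  the highest-occupancy copy.
- SASA ignores hydrogens by default, matching heavy-atom radii tables;
  radii sets are swappable but only one ships.
- The Potts text format stores dense fields and explicit couplings; it
  is meant for models up to a few hundred positions, not full-alignment
  production models.
- The resistance rule is deliberately transparent (two inputs, one
  threshold); it does not model pharmacokinetics, ATP concentration or
  mutation co-occurrence.
- Trajectory I/O is a long-format TSV (plus in-memory arrays); binary MD
  formats are expected to be converted upstream.
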