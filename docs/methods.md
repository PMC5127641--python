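# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would want written down.

## Enrichment ratios

A variant's fitness under FACS selection is scored as the log2 change of
its frequency between the sorted and naive pools. No single canonical
formula exists for SSM screens; we use the symmetric, pseudocounted
frequency ratio

e(i,a) = log2[ ((c_sorted + p)/(N_sorted + pV)) / ((c_naive + p)/(N_naive + pV)) ],

with additive pseudocount p = 0.5 (finite for zero counts, antisymmetric
under pool swap, scale-invariant at p = 0), pool totals N counting
substitution plus wild-type reads, and V the number of matrix cells. The
pseudocount and pool totals are recorded in the table metadata. Wild-type
reads form one shared tally: a read identical to the reference carries no
information about which position it "belongs" to, so every wild-type cell
of the matrix reports the same tally. Reads with more than one amino-acid
substitution are counted but excluded from the matrix — the library is
single-mutant by construction, so multi-mutants are PCR/sequencing
artifacts. The stop codon is a 21st column: reported (premature stops are
diagnostic of selection for unfolding) but excluded from per-position
means and maxima, which are defined over the 20 amino acids.

Coverage masking blanks cells with naive count < 10 by default (the
threshold is a parameter; 10 reads puts the Poisson CV of the naive
frequency below ~32%) and flags positions with more than half their cells
missing as insufficient-data. Position-wise normalization subtracts each
position's mean over the 20 amino acids (the stop column is shifted by
the same constant); deviation-from-maximum is invariant under this
centering, which the tests assert.

Specificity-mutation selection treats a missing competitor cell as
failing by default: absence of evidence of depletion is not evidence of
depletion. The alternative (missing passes) is exposed as a flag.

## 1:1 binding kinetics

Titrations are fit globally — one (kon, koff, Rmax) shared by all
concentrations of a pair — rather than per-curve: per-curve fits of
exponentials with similar rates are ill-conditioned, and sharing
parameters across concentrations is what makes kobs = kon·C + koff
identifiable. Fitting works in log10 parameter space with bounds
kon ∈ [1e2, 1e8] M⁻¹s⁻¹ and koff ∈ [1e-7, 1] s⁻¹ (the range BLI can
resolve), multi-start from a 4×4 log-spaced (kon, koff) grid, Rmax
initialized at the largest observed signal; the best converged start
wins. Dissociation phases start from the response the paired association
phase reached at its final time point (computed from the model, so R0 is
not a free parameter); a dissociation trace without a paired association
assumes equilibrium was reached. Optional per-trace additive offsets are
available as nuisance parameters (bounded at ±20% of the signal range)
but default off.

Censoring: a pair is unmeasurable when no trace shows a sustained
response — the mean of the last tenth of each association phase (first
tenth for dissociation) must exceed 3× a robust noise estimate
(1.4826·MAD of first differences / √2, which cancels smooth trends). A
single extreme point therefore cannot rescue a flat titration. Censored
pairs report KD > top tested concentration. Fold-specificity is the
minimum off-target/on-target KD ratio; censored off-targets enter at
their bound and flag the result as a lower bound when they are limiting.

CD denaturation scans are normalized as f = (signal − unfolded)/(folded −
unfolded), clipped to [0,1]; baselines may be sloping arrays. Full
thermodynamic m-value fitting is out of scope.

## Structural comparisons

Superposition is closed-form Kabsch (SVD with determinant correction, so
reflections are never returned); collinear point sets raise rather than
return an arbitrary rotation. Partner RMSD aligns the shared target
chain's Cα set and then measures the inhibitor chain's Cα RMSD **without
refitting** — the quantity that asks "given the target, where does the
inhibitor sit?". Residue correspondence is by residue number plus
insertion code; unmatched residues simply drop out, with no outlier
trimming. Multi-copy asymmetric units report per-copy values and their
mean. All RMSDs are Cα-only.

SASA is Shrake–Rupley with probe 1.4 Å and 960 points per atom on a
deterministic golden-spiral grid (no RNG, so areas are reproducible
bit-for-bit); heavy atoms only, standard van der Waals radii (C 1.70,
N 1.55, O 1.52, S 1.80 Å, table in `structure.VDW_RADII`), waters and
heteroatoms stripped. The isolated-sphere closed form is recovered within
1% at 960 points and two-sphere overlap within 2% (tested). Buried
surface area is the two-sided convention SASA(A)+SASA(B)−SASA(AB) — both
partners' lost area, not halved — and interface expansion is the
difference of two such BSAs; if a halved convention is wanted, divide
by 2.

Cross-links are evaluated on Cα–Cα distance with limits applied exactly:
≤ 30.0 Å for DSS/BS3 (11.4 Å spacer) and ≤ 26.0 Å for DSG (7.7 Å
spacer); a link detected by several reagents uses the most permissive
limit. Non-lysine endpoints warn but map (termini also react); endpoints
missing from the model make the link unmappable and it is excluded from
the summary rather than counted as violated. The support summary groups
links by how many distinct reagents detected them (3/2/1).

Funnel statistics average the k = 100 lowest ddG values per run class
(all of them, with a warning, when fewer exist). Absolute binding energy
is the local minimum; relative binding energy is local − global, negative
when the near-native funnel outscores the global surface search.

## Synthetic generators

Each generator takes an explicit seed, builds one `numpy` Generator, and
returns a ledger of everything it planted, so downstream expectations are
computable without re-running it.

- **SSM experiment**: naive pool near-uniform over all single
  substitutions plus wild type (weighted like 20 variants, mimicking the
  wild-type excess of real libraries) with log-normal abundance noise
  (σ = 0.3); survival probability logistic(selection_strength · fitness)
  — the simplest monotone map from fitness to sort survival; counts are
  multinomial at fixed depth (matching fixed sequencing depth; default
  1e5 reads/pool, a typical deep-sequencing depth for a ~400-variant
  library). Default fitness: substitutions ~ N(0, 2), stops at −5, wild
  type 0. Not emulated: sequencing error, PCR jackpots, multi-round
  sorts, gate physics — so passing tests show estimator correctness
  under sampling noise, not robustness to library artifacts.
- **BLI panel**: six inhibitors with on-target KD 0.05–1.5 nM (high
  picomolar to low nanomolar), kon 1e6 M⁻¹s⁻¹, one measurable off-target
  350–2000-fold weaker, remaining homologs giving pure noise up to the
  1 µM censor bound; Gaussian noise σ = 1% of Rmax; phase lengths scale
  with 1/koff so slow binders approach equilibrium. Instrument drift and
  mass-transport limitation are not modeled.
- **Helix bundles**: ideal α-helices (1.5 Å rise, 100°/residue, Cα
  radius 2.3 Å) in an antiparallel ring, Cα plus a dummy Cβ heavy atom;
  perturbed copies apply an exact recorded rigid motion plus optional
  iid coordinate jitter (E[RMSD] ≈ σ√3, tested to 10%). Every fifth
  residue is lysine to anchor cross-links.
- **Cross-link sets** plant true links among pairs within the chosen
  reagents' limit and false links beyond it; reagent support cycles
  through all levels deterministically.
- **Funnel tables**: local records with folded-normal RMSD and ddG ~
  N(local_mean, 3) plus a 0.5·RMSD penalty; global records uniform in
  RMSD with ddG ~ N(global_mean, 3).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use a 20-residue mutagenized
window (420 variant cells) at depth 1e5, 3-concentration titrations with
60 points per phase and 20 noise replicates, bundles of ≤ 90 residues,
18–20 cross-links and 2000-record score tables — sizes at which every
statistic is stable across seeds while the whole pipeline runs in
seconds. All randomness flows from explicit seeds; SASA grids and fit
multi-starts are deterministic, so identical seeds give identical output
files.

## Known limitations

- The enrichment formula is one defensible convention; screens analyzed
  with a different pseudocount or per-round scheme will shift absolute
  e-ratios (rank structure is robust, which is what the recovery tests
  measure).
- The kinetic fit assumes a clean 1:1 interaction; avidity, rebinding or
  heterogeneous ligand produce biased (kon, koff) even when the curve
  fit looks good.
- BSA depends on the radii table and the two-sided convention; compare
  conventions before comparing numbers across programs.
- Category conservation depends on the chosen partition of the 20 amino
  acids; the default six-category scheme is configurable and recorded in
  outputs.
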