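# Methods

## Isotopomer spectral analysis

**Model.** The analyte is a polymer of `n_units` condensed precursor units
(default 8 acetyl units for palmitate). Each unit is independently
tracer-derived with probability `D`; a tracer unit carries `tracer_labels`
heavy atoms (1 for [1-¹³C] ethanol, whose labelled carbon survives
oxidation into acetate C1), each present with probability `tracer_purity`
(default 0.99); all other atoms sit at natural isotopic abundance. The
polymer distribution is the n-fold convolution of the unit mixture, and
atoms of the analyte formula outside the units are convolved in at natural
abundance. The measured MID is then the mixture
`g · synthesized + (1 − g) · natural`, with `g` the fraction of the analyte
pool newly made during labelling. Both populations share one truncation
`n_tracked = n_units · tracer_labels + 3`, which retains ≥ 99.99% of mass
at natural abundance; vectors are renormalised after truncation.

**Analyte convention.** The default analyte model is the C16 carbon
skeleton. Fatty acids are measured as methyl esters, so a full-formula mode
(e.g. `C17H34O2`, including the derivatisation methyl carbon) is supported
by passing that formula; which convention an upstream instrument pipeline
used is not always recorded, so both are first-class and the formula is
carried in the output.

**Constants.** Natural abundances live in one editable table
(`chem.NATURAL_ABUNDANCE`); ¹³C is 0.0107. Supported elements: C, H, N, O,
S, Si (the silylation reagents' elements); anything else raises by name.

**Fitting.** Bounded least squares on (D, g) ∈ [0,1]², restarted from a
fixed-seed Latin hypercube (default 10 starts) because the objective is
shallow in D when g is small; the best local optimum is kept and the summed
squared residual reported. A flat D-profile at the fitted g (range < 1e-12
absolute + 1e-6 relative) marks the fit `unidentifiable` — this is what a
natural-abundance input produces — instead of returning an arbitrary D.
Optional residual-resampling bootstrap gives percentile intervals.
Tracer-contribution percent defaults to the `pool` convention (100·D); a
`carbon` convention scaling by labelled atoms per unit carbon and purity is
available, and the convention is attached to the output.

**Known limitation.** No correction for tracer recycling through the TCA
cycle; TCA intermediates are only a few percent enriched in the emulated
setting, so recycling into the acetyl pool is second-order and ignored.

## Flux balance analysis and the screen

FBA maximises the single biomass objective subject to S·v = 0 and bounds,
via `scipy.optimize.linprog` (HiGHS). Only the optimal objective value is
used downstream: alternate optimal flux vectors are ubiquitous, so fluxes
are reported but never compared. Growth values are rounded to 1e-12 (and so
is the with/without difference) before threshold comparison to keep the
classification from flapping on solver noise; thresholds are growth ≥
0.001 hr⁻¹ for "grows" and Δ ≥ 0.0001 hr⁻¹ for an acetate effect, both
configurable.

The carbon cap "100 mmol C/gDW/hr" is interpreted per metabolite: a source
with c carbons gets a molar influx bound of 100/c, equalising carbon supply
across sources; basal metabolites get unrestricted influx (no basal caps
are specified for the emulated medium), all other carbon influxes are
closed, and secretion is never restricted. The same cap rule applies to the
acetate co-substrate when it is opened. Opening an exchange only relaxes
the LP, so growth-with ≥ growth-without is asserted on every screen row.

Model i/o is COBRA-style JSON (readable by cobrapy, which the test suite
uses as an independent oracle). The published organism-scale model the
screen was designed around is not bundled; desk-scale validation uses the
toy fixtures, and any external COBRA-JSON model can be screened as-is.

**Toy fixtures.** `linear_chain` (optimum = uptake × yield) and
`two_substrate` (optimum 22/5 at an interior vertex) pin the LP machinery
to closed forms. `cometabolism` encodes the biological signature: acetate
enters only via an ATP-consuming acetyl-CoA-synthetase reaction and biomass
also requires a glycolytic precursor (PEP) that acetate cannot supply, so
acetate alone gives exactly zero growth, while with glycerol present
acetate-derived acetyl-CoA spares PEP and raises the optimum
(closed forms at cap 100: glycerol alone 100/6, glycerol + acetate 25). An
explicit ATP-maintenance sink is part of the network — without it the ATP
balance over-constrains the steady state and glycerol growth is infeasible.

## Compositional statistics

All group inference is on log-ratios, which are invariant to per-sample
sequencing depth. Zero handling differs by tool, mirroring standard
practice: summed-set log-ratios and Aitchison distances default to
pseudocount 1 (exact depth invariance holds at pseudocount 0, which the
invariance tests use on positive tables); the ordination instead treats
zeros as missing (robust CLR) and completes them with an iterative
truncated-SVD low-rank fit. That ordination is a deliberate simplification
of matrix-completion RPCA: on zero-free tables it reduces exactly to
CLR-PCA, and its acceptance is structural (group separation, dense-limit
equivalence), not coordinate-level agreement with any specific external
implementation. Axis signs are fixed by making each axis's
largest-magnitude loading positive.

Wilcoxon rank-sum tests are exact for combined n ≤ 20 without ties and
normal-approximated with tie correction otherwise; two samples that are
entirely tied return p = 1 by convention. Pairwise multiplicity is adjusted
by Benjamini–Hochberg by default; a parametric Tukey-HSD alternative is
offered explicitly because "rank-sum with HSD post hoc" is an ambiguous
pairing, and the choice is a flag rather than a guess.

PERMANOVA uses the standard among/within decomposition of squared
distances, a vectorised permutation loop, and
p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1) with 999 permutations and a
fixed seed by default; an `exhaustive` flag enumerates all distinct
labelings for small n, making the p-value exact. Taxon sets for log-ratio
contrasts are selected by annotation match (phylum/family columns), not by
loading-based automatic selection, so contrasts are reproducible from
metadata alone.

Pathway aggregation: within a reaction, multi-copy genes are resolved by
the maximum (the most abundant/most highly expressed copy); a pathway's
value is the mean over its reactions. RPK divides counts by length/1000.

## Thermodynamics

ΔG°′ is a signed sum of standard transformed formation energies; the
shipped TSV carries approximate literature values at pH 7 with the proton
as a species entry at −39.87 kJ/mol (the RT ln 10⁻⁷ convention), water at
activity 1, gases as partial pressures over 1 bar. The table is data, not
contract: the module computes ΔG = ΔG°′ + RT ln Q (R = 8.314 J/mol/K) for
whatever constants are supplied. Classification is strict
(ΔG < threshold ⇒ favorable; equality is equilibrium, hence unfavorable).
Under the shipped constants the ethanol → acetate + 2 H₂ example is
+9.65 kJ/mol at unit activities and becomes favorable only when H₂ is held
below roughly 10⁻² bar — the quantitative form of the claim that anoxic
ethanol oxidation needs a hydrogen-scavenging partner.

## Synthetic data: what it emulates and what it does not

* **MIDs**: forward-model truth plus additive Gaussian channel noise
  (default sd 0.003), clipped at zero and renormalised. This is a generator
  convention matching per-channel measurement error magnitude, not an
  instrument model; correlated detector drift, baseline and deconvolution
  artefacts are not emulated. If noise would clip more than half the
  entries the generator refuses and advises a smaller sd.
* **Community tables**: log-normal latent abundances (per-taxon baseline +
  group effect + dispersion 0.5 on the natural-log scale) turned into
  counts by multinomial sampling at a uniform random depth (20k–60k),
  which reproduces depth confounding and the zero pattern of real bin
  tables. Defaults: 7 + 7 samples mirroring the emulated N = 14 cohort;
  Bacteroidetes taxa +1 log₂, Enterococcaceae −1 log₂; expression features
  are bin|gene pairs with lengths (rpoA fixed at 1 kb by convention) where
  only *acs* carries an effect (+1.5 log₂) and only in Bacteroidetes bins.
  Phylogenetic correlation, strain-level variation and library-prep biases
  are not emulated, so passing tests demonstrate correct statistical
  behaviour under the stated sampling model, not robustness to every
  real-data pathology.
* **SCFA tables**: log-normal concentrations (CV 0.2) around fixed
  baselines for the eight standard analytes, acetate's mean multiplied by
  the planted fold (default 4) in the treated group; means are
  bias-corrected so the planted fold is the expectation. n_per_group = 1
  emits the table with a warning that group tests are impossible.
* **Toy models**: see above; stored analytic values always describe the
  unperturbed fixture, while bound perturbations apply to the returned
  model.

All generators are pure functions of their spec including the seed
(bitwise reproducibility), generated MIDs sum to 1 within 1e-12, and
null-configured generators are verified by simulation to give nominal
type-I error downstream.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale as
the package's own validation design: exhaustive MID enumeration up to 8
units and C20 formulas, LP vertex enumeration up to 12 reactions, 10×10
(tests) / 5×5 (script) noise-free recovery grids, 100 noisy-fit
replicates, 200 null seeds and 100 power seeds for the compositional
calibration (199 permutations per PERMANOVA inside those loops, 999 for
single reported analyses). LP feasibility tolerance is 1e-9; MID sum
tolerances are 1e-12 (generators) and 1e-9 (inputs); optimiser tolerances
are 1e-12 (xtol/ftol/gtol).
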