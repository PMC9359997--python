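# acetotrace

Analysis toolkit for the question of whether gut microbiota metabolise
ethanol directly or merely respond to the acetate that the liver makes from
it. It bundles the four quantitative pieces of that argument, each usable on
its own, plus seeded generators that produce every input the pipeline
consumes:

1. **Isotopomer spectral analysis (`acetotrace.isa`).** Palmitate is built
   from 8 condensed acetyl-CoA units. With a [1-¹³C] ethanol tracer, the
   measured palmitate mass isotopomer distribution (MID) is modelled as

   *MID = g · Conv(n=8)[D · unit₁₃C + (1−D) · unit_nat] ⊛ natural + (1−g) · natural*

   where **D** is the fraction of the lipogenic acetyl-CoA pool carrying one
   tracer ¹³C and **g** the fraction of palmitate newly synthesised during
   labelling. Bounded multi-start least squares recovers (D, g) per sample;
   100·D is the percent tracer contribution.
2. **Flux balance analysis and the acetate co-metabolism screen
   (`acetotrace.gem`).** COBRA-style JSON models, LP-based FBA (HiGHS), and
   a one-at-a-time carbon-source screen: each source opened at a
   100 mmol C/gDW/hr carbon cap, growth recorded with and without an acetate
   exchange. Growth < 0.001 hr⁻¹ counts as no growth; acetate "has an
   effect" when it adds ≥ 0.0001 hr⁻¹.
3. **Compositional microbiome statistics (`acetotrace.compositional`).**
   RPK normalisation, reference-frame log-ratios (e.g. *acs* over the
   *rpoA* housekeeping gene), CLR/Aitchison distances, robust-CLR
   ordination with low-rank completion of zeros, permutation PERMANOVA,
   pairwise Wilcoxon group tests, and reaction/pathway aggregation
   (max over gene copies, mean over reactions).
4. **Anaerobic feasibility (`acetotrace.thermo`).** ΔG = ΔG°′ + RT ln Q
   from an editable formation-energy table; classification is *favorable*
   iff ΔG < 0 (strict). The shipped example shows ethanol + H₂O →
   acetate⁻ + H⁺ + 2 H₂ is endergonic (≈ +9.7 kJ/mol) unless H₂ is drawn
   down.

`acetotrace.simulate` generates MID tables with known (D, g), community
count tables with planted Bacteroidetes/Enterococcaceae and *acs* effects
(7 + 7 cohort), SCFA tables with a planted 4× acetate fold, and toy
metabolic models with closed-form optima — so every statistical claim in
the test suite is checked against a known truth.

## Worked example

```sh
python examples/isotope_tracing.py
```

prints, for synthetic cecum samples generated with a planted enrichment
D = 0.18 and g = 0.6 plus GC-MS-scale channel noise:

```
cecum: planted D = 0.18
sample        D        g  tracer_contribution_pct
   s01 0.178989 0.603643                17.898851
   s02 0.181598 0.600873                18.159764
   s03 0.184756 0.601313                18.475564
  mean tracer contribution 18.2% of lipogenic acetyl-CoA
```

i.e. the fitter recovers that ~18% of the lipogenic acetyl-CoA pool feeding
new palmitate derives from the tracer. The other examples
(`carbon_source_screen.py`, `community_statistics.py`,
`thermodynamic_feasibility.py`, `synthetic_inputs.py`) each exercise one
module the same way and explain the numbers they print.

A thin CLI mirrors the library:
`acetotrace simulate {mids|community|scfa|gem}`, `acetotrace isa fit`,
`acetotrace gem screen`, `acetotrace comp {rpk|logratio|permanova}`,
`acetotrace thermo dg`.

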