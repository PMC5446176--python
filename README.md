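# nexkin — nucleotide-exchange kinetics of EF-Tu, simulated and inferred

Elongation factor Tu (EF-Tu) delivers aminoacyl-tRNA to the ribosome in its
GTP-bound state and is recycled by its exchange factor EF-Ts, which
accelerates the otherwise slow release of bound GDP.  The kinetics of this
cycle are classically dissected by stopped-flow fluorescence with
mant-labeled nucleotides: pseudo-first-order association titrations give the
on-rates (k₁ for GDP, k₅ for GTP), chases with excess unlabeled nucleotide
give the off-rates (k₋₁, k₋₅), and titrating EF-Ts against a preformed
EF-Tu·mant-nucleotide complex gives the effective second-order constants for
stimulated release, k₃/(1 + k₋₃/k₋₄) and k₆/(1 + k₋₆/k₋₇) — the flux
partition of the transient EF-Tu·nucleotide·EF-Ts complex between EF-Ts
release and nucleotide release.  Multiple-turnover GTPase assays and
aminoacyl-ester protection decays complete the functional picture.  A
recurring complication in drug studies is that tetracycline autofluorescence
overlaps the mant emission; a narrow 430 ± 10 nm band-pass filter reduces it
to an additive background.

`nexkin` is a simulation + inference package for exactly this experimental
program.  It contains:

- a mass-action ODE model of the full exchange scheme (15 species: labeled
  and unlabeled nucleotide pools, all EF-Tu/EF-Ts complexes), with analytic
  limits (pseudo-first-order rate `k_on·[L] + k_off`, equilibrium states,
  the flux-partitioned stimulated constant `k_on,Ts/(1 + k_off,Ts/k_rel)`);
- an observation model mapping trajectories to stopped-flow traces
  (FRET amplitude, dead time, band-pass spectral weighting, additive
  tetracycline background, point noise plus replicate-level variability);
- seeded generators for five synthetic assay families (association, chase,
  EF-Ts titration, GTPase quench series, protection decay) driven by a
  declared ground-truth parameter set;
- the staged analysis a kineticist would run: one-exponential transient
  fits, weighted secondary plots, initial-rate estimation with background
  subtraction, half-life fits, z-test condition comparisons, and
  Monte-Carlo power analysis for "what effect size could this design
  detect?";
- a pipeline + CLI that turns a config into a full rate table with
  per-constant verdicts across tetracycline levels.

The default ground truth is the published kinetics of *E. coli* EF-Tu under
near-physiological buffer conditions, with tetracycline deliberately absent
from the kinetics — it enters only as a fluorescence background.  The
package's central reproducibility claim is that the full simulate → fit
pipeline recovers every generating constant within its reported error, and
reports "no detected difference" between 0 and 100 µM tetracycline — the
null result — at the nominal rate.

## Worked example

```python
from nexkin import (AssociationDesign, ChaseDesign, default_truth,
                    generate_association_set, group_fits,
                    association_analysis)

truth = default_truth(tet_level_uM=0.0)
design = AssociationDesign()          # 0.3 uM EF-Tu, mant-GDP 0.5-5 uM, n=11
records = generate_association_set(design, truth, seed=1)
slope, intercept = association_analysis(
    group_fits(records, "ligand_conc_uM"), "GDP",
    tu_conc_uM=design.tu_conc_uM,
)
print(f"k1 = {slope.value/1e6:.2f} +/- {slope.se/1e6:.2f} x10^6 M^-1 s^-1")
```

prints

```
k1 = 2.07 +/- 0.07 x10^6 M^-1 s^-1
```

i.e. the GDP association constant recovered from 66 noisy synthetic traces,
to be compared with the generating value 2.1 × 10⁶ M⁻¹s⁻¹ — the recovered
slope sits well within its quoted standard error band.

The full battery, from a shell:

```bash
nexkin pipeline config.yaml --out run1     # simulate -> fit -> rate table
nexkin simulate config.yaml --out run1     # materialize CSV traces only
nexkin fit run1/records --out est.json     # re-fit records from disk
nexkin power k1r --effect 5 --n-sim 200    # power to detect a 5x change
```

where `config.yaml` may be empty (all defaults) or set seeds, tetracycline
levels, replicate counts and an `effect_hook` (e.g. `{k1r: 5.0}`) that
injects a counterfactual drug effect for power studies.  The rate table
mirrors the conventional reporting units (×10⁶ M⁻¹s⁻¹, ×10⁻³ s⁻¹,
×10⁻⁴ µM/s, minutes).

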