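# phagemix

Analysis and design toolkit for bacteriophage cocktails, built around an
anti-mastitis use case: virulent phages against the *Escherichia coli* and
*Staphylococcus aureus* strains that dominate bovine intramammary
infections. The package covers the full in-vitro evaluation pipeline a
phage-development lab runs — plaque-assay titer enumeration, lytic-activity
classification from plate-reader kinetics, spot-test host-range calling,
resistant-variant cross-sensitivity analysis with receptor confirmation,
receptor-diverse cocktail selection and formulation, biofilm/milk efficacy
metrics, and storage-stability statistics — plus a seeded synthetic-data
generator that emulates every assay so the whole pipeline is testable
without wet-lab data.

## Core quantities

**Titer enumeration.** From plaque counts on a ten-fold dilution series
(double-agar overlay, V mL plated per plate):

    Mf = Σc / (V · d · (N₁ + 0.5·N₂ + 0.25·N₃ + …))   [PFU/mL]

where Σc sums plaques over all countable plates (default window 3–300),
N_k is the number of counted plates at the k-th counted dilution and d is
the dilution factor of the least-dilute counted level. With one dilution
this reduces to the classical c/(V·d·N).

**Lytic activity.** A phage/strain pair is classified by the endpoint OD₆₂₀
difference Δ = mean(control) − mean(treated) at the final shared timepoint
(280 min assay): Δ > 0.1 strong, 0.05 ≤ Δ ≤ 0.1 weak, Δ < 0.05 none.
Panel summaries report per-phage percentages and an overlap row taking each
strain's best call.

**Host range.** Per spot-test replicate, the lowest spotted titer showing
clearance/turbidity/plaques is banded by order of magnitude: 10³–10⁵ PFU/mL
sensitive, 10⁶–10⁸ intermediate, no positive spot insensitive; replicates
combine by majority with ties toward the less sensitive label.

**Resistance analysis.** A variant × phage grid of +/−/⊗ cells yields the
distribution of variants still sensitive to ≥2 / exactly 1 / 0 other
phages, per-phage rescue counts, and *core phages* (sensitive in every
tested variant row). Mutated genes map onto receptor classes
(ompC→OmpC, ompA→OmpA, wzzB/wbbD→LPS O-antigen, tarS→WTA β-GlcNAc) to
confirm genome-based receptor predictions.

**Cocktail design.** Greedy maximum-coverage selection with receptor-aware
tie-breaking (prefer phages sharing the fewest main-receptor classes with
the current selection), per-strain redundancy depth counted over distinct
main-receptor classes, resilience to single-phage loss, and equal-split
formulation rounded to one significant digit.

**Efficacy.** Biofilm control EBC = 100 − mean(A_TS)·100/mean(A_C100%)
(OD₅₇₀, MTT); milk-model reduction
= 100·(1 − mean(log₁₀ N_phage)/mean(log₁₀ N_control)) with a two-sided
Student t-test on log counts. Storage stability
= 100·log₁₀(titer_t)/log₁₀(titer₀), integer-rounded.

## Worked example

```python
import phagemix as pm

# titer of a production lysate: 200 and 180 plaques at 1e-5, 21 at 1e-6
series = pm.PlaqueCountSeries(records=((1e-5, (200, 180)), (1e-6, (21,))),
                              volume_ml=0.1)
est = pm.estimate_titer(series)
print(f"titer: {est.mf:.3e} PFU/mL")

matrix = pm.load_fixture("cross_matrix")          # packaged variant grid
print(pm.analyze_cross_sensitivity(matrix.by_species("E. coli")).distribution)
print(pm.analyze_cross_sensitivity(matrix.by_species("S. aureus")).core_phages)

table = pm.stability_percent(pm.load_fixture("stability"))
print(table[["month", "final_titer", "stability"]].head(3).to_string(index=False))
```

prints

```
titer: 1.604e+08 PFU/mL
{'>=2': 14, '==1': 5, '==0': 1}
('357Saur119PP',)
 month  final_titer  stability
   0.0  344000000.0        100
   3.0  190200000.0         97
   6.0  198100000.0         97
```

The titer combines both countable dilutions (Σc = 401, d = 10⁻⁵, weighted
plate count 2.5). Of the 20 resistant *E. coli* variants, 14 remain
sensitive to at least two other cocktail phages and 5 to exactly one — the
receptor-diversity rationale in numbers. 357Saur119PP is the core
anti-*S. aureus* phage: every variant resistant to the other two Gram-positive
phages is still lysed by it. The cocktail loses ≤ 6% of its log-scale titer
over 24 months at 2–10 °C.

## Command line

```sh
phagemix simulate --seed 1 --out-dir data/      # synthetic assay campaign
phagemix titer data/plaques.csv
phagemix lytic data/kinetics.csv
phagemix hostrange data/spots.csv
phagemix resistance --matrix data/cross_matrix.csv
phagemix design --lytic-calls calls.csv --phages data/phages.csv
phagemix biofilm data/biofilm.csv
phagemix milk data/milk.csv
phagemix stability data/stability.csv
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes the pipeline's headline numbers from scratch — storage-stability
percentages from the packaged component-titer series, resistant-variant
distribution and core-phage rescue counts from the packaged
cross-sensitivity matrix, per-phage formulation titers, and biofilm
threshold fractions — and writes them as JSON. It reads nothing outside the
repository.
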