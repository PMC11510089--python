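# Methods

This note documents the models, numerical conventions and design choices
behind phagemix, and what the synthetic-data generators do and do not
emulate.

## Titer enumeration

The weighted-dilution estimator
`Mf = Σc / (V · d · (N₁ + 0.5·N₂ + 0.25·N₃ + …))` is implemented verbatim
as used in the double-agar overlay protocol, with weights continuing to
halve beyond the third dilution. Two conventions are fixed here:

- *d* ("the lowest dilution used") is read as the dilution factor of the
  least-dilute **counted** level (the largest d among countable plates).
  This makes the single-dilution case collapse to the classical
  `c/(V·d·N)` plate-count estimator.
- Countability window: plates with 3–300 plaques enter the formula;
  others (confluent lysis, zero plaques) are excluded first. The window is
  a parameter of `estimate_titer`.

Caveat, documented rather than resolved: for a ten-fold series the halving
weights (0.5, 0.25, …) are not the classical combined-count weights (which
would follow the dilution step, 0.1, 0.01, …). The estimator is therefore
slightly biased whenever more than one dilution is countable; on
single-dilution series — the recommended reading, and what the Poisson
recovery tests use — it is unbiased. No maximum-likelihood alternative is
provided; the assay formula is authoritative here.

## Lytic-activity classification

Endpoint OD difference Δ = mean(control endpoints) − mean(treated
endpoints) on a shared time grid. Thresholds (0.05, 0.1) are fixed assay
constants. Boundary convention: "between 0.1 and 0.05" is the closed
interval, so weak = [0.05, 0.1] and strong requires Δ > 0.1 strictly;
every Δ maps to exactly one label. Replicate wells are averaged before
differencing; blanks are not subtracted (controls and tests are compared
directly). The endpoint is the final common timepoint (280 min in the
standard assay); no area-under-curve statistic in this version. A
negative-control endpoint above a configurable OD (default 0.2) raises a
contamination warning rather than an error.

Panel summaries round percentages to one decimal. The overlap row
classifies each strain by its best call (strong ≻ weak ≻ none), so its
strong fraction dominates every per-phage strong fraction.

## Host-range calling

Spotted titers are banded by order of magnitude (`floor(log10 t)`): bands
3–5 → sensitive, 6–8 → intermediate, no positive spot → insensitive. The
banding-by-magnitude choice makes a 2 × 10^k ladder land inside the stated
power-of-ten bands; a positive only at 2 × 10⁸ (band 8) is called
intermediate, and bands below 3 are called sensitive (a strain lysed at
lower titers is at least as susceptible). Triplicate consensus is by
majority with ties resolved toward the less sensitive label — the
conservative choice, since the assay protocol states triplicates but no
consensus rule. The reported lowest positive titer is the minimum across
replicates agreeing with the consensus.

## Resistance analysis and receptor confirmation

Not-tested cells (⊗) are excluded from every denominator, never imputed. A
core phage must have at least one tested cell and be sensitive in all of
them; its rescue count then equals its tested-row count by construction.
Intergenic mutation records (e.g. partial 5S rRNA calls) are filtered
before confirmation logic since they cannot alter a surface receptor.

Confirmation semantics per phage: among variants resistant to it that have
non-silent mutation records, a variant *fully supports* the prediction if
every mutated gene maps (via the gene → receptor-class table) into the
predicted receptor set, and *partially supports* it if only a subset maps.
Status is `confirmed` / `partially_confirmed` / `not_confirmed`
accordingly, and `no_data` when no resistant variant was sequenced. The
`not_confirmed` state is this package's addition: without it, "sequenced
but nothing maps" (e.g. an ompA/wbbD mutant against a phage predicted to
bind OmpC-family porins) would be indistinguishable from "no mutant
sequences". With the shipped curated map (wzzB/wbbD → LPS O-antigen, which
is deliberately distinct from the LPS *core* class), predictions resting on
a porin gene alone confirm fully, while porin + O-antigen double mutants
yield partial confirmation — the O-antigen acts in phage adsorption but is
not the predicted irreversible receptor, and the package keeps that
distinction visible. The gene map ships as an editable CSV, not a
hard-coded table.

## Cocktail design

The design principle — combine phages recognizing different conserved
surface structures, anchored by a core phage whose receptor survives the
resistance mechanisms raised against the others — is formalized here as
greedy maximum coverage with receptor-aware tie-breaking. The original
campaign composed its cocktail by expert reasoning; the algorithmic
objective and its tie-breaks are this package's formalization:

1. maximize newly covered strains (coverage = strong or weak call by
   default, restrictable to strong-only);
2. fewest main-receptor classes shared with already-selected phages;
3. most strains strongly inhibited;
4. fewest support-receptor classes shared (support receptors never enter
   the primary diversity criterion);
5. lexicographic phage id.

Selection stops when coverage stops improving or a size cap is hit. Greedy
maximum coverage is within (1 − 1/e) of the optimal coverage at any fixed
size; the test suite verifies this bound and exact agreement with
exhaustive subset search on small random instances.

Redundancy depth counts covering phages once per distinct main-receptor
class set (receptor-identical phages provide no extra depth; unannotated
phages count individually). Resilience of a covered strain means it stays
covered after loss of any single selected phage: with a cross-sensitivity
matrix, the backup phage must additionally remain sensitive across all
variants raised against the lost phage; without one, receptor-class
distinctness (depth ≥ 2) stands in. Designs are per host species.

Formulation splits a component titer equally; the reported value is
rounded to one significant digit (1 × 10⁸ over 3 phages → 3 × 10⁷ PFU/mL)
with the exact value retained for audit.

Storage stability is 100 · log₁₀(summed titer at t) / log₁₀(summed titer
at month 0), reported integer-rounded to match release-table conventions,
raw value retained. The statistic is a ratio of logs, so it is exactly 100
at the reference point but is not invariant to unit changes elsewhere —
series must be in consistent units (PFU/mL throughout).

## Efficacy statistics

EBC uses replicate means in numerator and denominator; per-replicate EBC
values are available for plotting but the headline statistic is the mean
ratio. EBC is not clamped: negative values flag biofilm enhancement.
Threshold summaries (`summarize_ebc`) use an inclusive ≥ and report integer
percentages.

Milk-model reduction is the ratio of mean log₁₀ counts (not the mean of
per-replicate ratios), matching the "% of log relative to control log
assumed as 100%" definition. "Student t-test" is implemented as the
pooled-variance two-sample test, two-sided, with a Welch option for
unequal variances; stars at p < 0.05/0.01/0.001. Degenerate zero-variance
arms return p = 1 (equal means) or p = 0; single-replicate arms return the
reduction with the p-value withheld and a flag.

## Synthetic data: what it emulates, what it does not

All generators draw from substreams of one global seed via
`SeedSequence(seed, spawn_key=(stream, index))` with fixed per-assay stream
indices, so each assay is independently bit-reproducible.

- **Growth curves**: 4-parameter logistic in OD units (baseline 0.05,
  plateau uniform in 0.9–1.3, rate 0.05/min, midpoint 110 min), chosen so
  control endpoints resemble typical 96-well plate-reader curves; the assay
  protocol specifies only the measurement grid (0–280 min every 20 min),
  not a curve model. Phenotypes: full inhibition pins the treated curve at
  baseline; partial grows to 45% of the control's span; transient shifts
  the midpoint by 80 min so the curve visibly lags mid-assay yet rejoins
  the control by the endpoint; no-effect duplicates the control. Gaussian
  OD noise (default sd 0.02, floored at 0) is a package default — the
  source assays publish no replicate variance.
- **Phenotype mix**: the 24 h kinetics screen classified 36 of 40 strains
  (22 full, 6 partial, 4 transient, 4 unaffected); the default mix
  renormalizes over the 36 classified strains.
- **Plaque counts**: Poisson with mean titer × volume × dilution — the
  standard error model for plating counts.
- **Cross matrices**: a receptor-genotype model; a variant arises from a
  (strain, phage) pair by knocking out the inducing phage's main
  receptor class(es) present in that genotype, and any phage retaining at
  least one intact main receptor stays lytic. When a phage lists several
  main receptor classes the whole set is removed so the defining matrix
  invariant (variant insensitive to its inducing phage) always holds; for
  the single-receptor phages of the shipped panels this is exactly
  "knock out one class".
- **Spot grids**: deterministic detection at titers at or above a
  strain-specific threshold (the lowest positive level reads as plaques,
  higher levels as clearance); no misreading noise.
- **Biofilm plates**: absorbance = baseline × strain capacity ×
  suppression (+ Gaussian noise), i.e. a pure multiplicative-suppression
  model with no growth dynamics.
- **Milk endpoints**: lognormal around the printed untreated ranges
  (4 × 10⁷–2 × 10⁸ CFU/mL for E. coli, 3 × 10⁸–3 × 10⁹ for S. aureus,
  log-midpoint means), phage arm scaled to a planted %log reduction;
  default replicate sd 0.15 log₁₀.
- **Stability series**: exponential decay with lognormal measurement
  noise; default rates (0.030/month E. coli component, 0.055/month
  S. aureus) back-calculated once from the 24-month storage endpoints.

Not emulated: sequence-level data (no genomes or reads), mechanistic
adsorption/infection dynamics, plate-position or batch effects, and
between-day drift. A green test on synthetic data therefore establishes
that the estimators recover the parameters of these stated generative
models — not that the models capture every feature of real assay noise.

## Numerical conventions

Percentages: panel and host-range summaries round to one decimal; biofilm
threshold fractions and stability to integers; formulation titers to one
significant digit — all with exact values retained in the returned
objects. Sensitivity-consensus ties break toward less sensitive; greedy
ties break as listed above; banding uses floor of log₁₀. Degenerate
inputs (empty panels, all-uncountable plates, zero control absorbance,
non-positive titers) raise explicit errors rather than returning
sentinels.

## Known limitations

- The weighted-dilution titer formula's multi-dilution bias (above).
- Receptor-confirmation logic treats the gene → receptor map as exact;
  genes outside it warn and count as non-matching rather than unknown.
- Cocktail resilience against a cross matrix only sees variants actually
  present in the matrix; unobserved resistance mechanisms are out of
  scope.
- The milk t-test assumes approximate log-normality of endpoint counts at
  n = 4 replicates; with heavy contamination of that assumption the
  Welch/pooled p-values are both only indicative.
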