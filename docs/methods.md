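# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of the `mitoscreen` package in one place. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Scope and design

The package implements the analysis side of a multiparametric
mitochondrial-toxicity workflow — normalization, mitostress decomposition,
ETC-complex assignment, censored dose–response potency, Dunnett LOECs and
cross-assay mechanism calls — together with a synthetic-data generator
that emulates the study design those analyses assume. The generator is a
peer of the analysis code, not a test fixture: it is the package's
substitute for unreleased raw plate data, and its defaults *are* the study
conditions. Simulator ground-truth fields (`sim_mechanism`,
`sim_potency_log10M`, `sim_hill_slope` on `CompoundRecord`) are never read
by any analysis stage.

## The compound panel

`data/compound_panel.csv` lists 21 ETC inhibitors (8 complex-I, 5
complex-II, 8 complex-III; a 14-compound starred subset) with CAS numbers,
molecular weights and cLogP. Simulator potencies are package choices on
the log10-molar scale in [−12, −2]: nanomolar for the potent CI/CIII
compounds, 20–200 µM for the CII class (whose activity only appears on
the extended permeabilized ladder), and one protonophore (cyazofamid-like)
among the CIII-annotated compounds. A uniform simulator Hill slope of 2.0
is used — typical of single-site ETC inhibitors and steep enough that the
potent compounds reach ≥ 90% occupancy within their ladder.

Two ladder presets cover the two assay formats:

* `intact_default` — 8 points, 1-in-5 from 10 µM (0.128 nM … 10 µM);
* `permeabilized_extended` — 8 points, 1-in-10 from 500 µM. The source
  protocol used an irregular concentration set up to 500 µM; the preset
  regularizes it to a constant-fold ladder with the same span.

Concentrations are stored in molar and displayed in log10[M] rounded to
two decimals.

## Intact-cell mitostress model

Injection schedule: 3 baseline cycles, 5 post-compound cycles, 3 cycles
after each of oligomycin, FCCP and rotenone/antimycin A; 6-minute cycles
(3 min mix + 3 min read), times at cycle midpoints. The baseline cycle
count is a package convention (three, matching the per-injection count);
the protocol literature does not fix it.

Cell-line profiles (percent of basal OCR):

| parameter | HepG2-like | RPTEC/TERT1-like | meaning |
|---|---|---|---|
| maximal_ocr_pct | 159.4 | 337.4 | FCCP-uncoupled capacity |
| nonmito_pct | 10 | 10 | rotenone/antimycin-resistant OCR |
| leak_pct | 15 | 15 | proton leak share |
| glycolytic_reserve | 2.0 | 1.0 | max fold-rise of ECAR over basal |
| fccp_ecar_boost | no | yes | further ECAR rise after FCCP |
| glucose_rescue | 1.0 | 0.2 | ATP demand glycolysis can cover in glucose |
| culture_modifier_3d | 0.3 | 1.0 | scaling of rescue in spheroids |

The two maximal-OCR values are the study's reported uncoupled-capacity
means for the two lines; the remaining values are package choices in the
physiological range (the source reports no quantitative ECAR ceiling or
rescue fractions). A glycolytic, Crabtree-positive hepatoma line gets full
glucose rescue and a large ECAR reserve; the oxidative renal line the
converse. The 3-D modifier encodes the observed shift of spheroids toward
oxidative metabolism, which re-exposes them to ETC toxicity in glucose.

Per-phase expected OCR follows the flux table in the README. Noise is
multiplicative lognormal per measurement (CV, default 0.03) plus a
lognormal per-well scale factor (SD 0.05), chosen to resemble the visual
spread of published replicate traces; both default values are package
choices, not measured ones. Baseline normalization cancels the well scale
factor exactly, which is why the analysis is insensitive to it.

CII masking: intact-cell capacity for CII inhibitors is fixed at 1 (total
masking). An optional `cii_masking` parameter (< 1) on
`mitostress_expected` allows partial-masking sensitivity analyses.

ECAR: the fraction of the glycolytic reserve recruited equals the ATP
demand displaced onto glycolysis (the occupancy for CI/CIII inhibitors and
protonophores, 0 for masked CII and inactive compounds), saturates at 1
after oligomycin, and gains a further 0.25 after FCCP only in profiles
with `fccp_ecar_boost`. The "% of glycolytic range" scale anchors a well's
own basal ECAR at 0% and the plate's vehicle oligomycin maximum at 100%;
because both are baseline-relative ratios the scale is invariant to
per-well scale factors. The basal-relative scale (100% = pre-injection)
remains available on the baseline-normalized trace; activation potencies
are fit on the range scale.

## Permeabilized complex assay

Schedule: 3 baseline cycles on CI substrates, then three 2-measurement
stages (compound; succinate + rotenone; ascorbate/TMPD + antimycin A) of
2.5-minute cycles. The *second* measurement of each stage, as percent of
the pre-compound baseline, summarizes the stage. Vehicle stage levels
default to 100% / 90% / 140% of baseline (succinate-path and TMPD-driven
CIV capacities; package choices exposed as `stage_capacities`).

Classification thresholds: a stage is *inhibited* below 0.7× its vehicle
level and *rescued* at ≥ 0.7×; a terminal-stage ratio in (0.4, 0.7) marks
partial CIII rescue. The underlying decision table is qualitative in the
assay literature; these fractions are explicit free parameters, set so
that "only partially rescued" compounds land in the partial band, and all
are config-exposed. Headline calls are made at the lowest concentration
showing any inhibition (most-specific-dose principle); the per-
concentration call table is also emitted, so calls occurring only at the
top extended-ladder dose remain visible rather than suppressed.

## Endpoint panel (24 h assays)

Effective energy deficit = (coupling loss) × (1 − effective glucose
rescue), where coupling loss is the occupancy for CI/CIII inhibitors,
downstream inhibitors and protonophores, and 0 for masked CII and inactive
compounds. Viability (resazurin) and PI positivity are Hill functions of
the deficit (half-effect at deficit 0.4, slope 3, PI ceiling 90%); lactate
mirrors the ECAR model (gain 1.5 → up to 250% of control); membrane
potential falls with occupancy for CI/CIII, downstream and protonophore
mechanisms and stays flat for CII. Repeated exposure multiplies potency
geometrically, reaching 2-fold over a full 5 × 24 h course. The PI
endpoint stands for a pre-quantified image-analysis readout (a nucleus is
PI-positive when the PI signal overlaps > 10% of the nuclear mask);
segmentation itself is out of scope and enters only as this provenance
note. All endpoint parameters are package choices tuned for qualitative
fidelity (flat glucose-2D viability for HepG2-like cells, strong
galactose sensitisation), not fitted to data.

## Normalization ledger

1. kinetic wells → percent of own pre-injection baseline (arithmetic mean
   of baseline cycles; the mean-vs-last-cycle choice is a documented
   convention);
2. endpoint responses → percent of vehicle mean;
3. re-anchoring to the mean of ≥ 2 *non-effective* low concentrations,
   operationalized as non-significant (Dunnett) **and** within ±10% of
   control — both the count and the tolerance are config-exposed because
   the benchmark-concentration literature states no numeric rule; when no
   such prefix exists the curve is returned unchanged with a
   `no_noneffective_prefix` flag;
4. maximal OCR → percent of the vehicle FCCP maximum (vehicle wells only,
   so treated-well scaling is independent of the compound's own
   oligomycin/FCCP response);
5. ECAR → percent of glycolytic range (above).

All transforms are affine and order-preserving; re-anchoring is
idempotent; every emitted curve records its anchor and provenance.

## Mitostress decomposition and uncoupling

Phase summaries: compound = mean of the **last two** of five cycles
(equilibrated inhibition; which cycles summarize the effect is not fixed
in the protocol literature, so this is a documented guess), oligomycin =
minimum, FCCP = maximum, rotenone/antimycin A = mean. Derived quantities:
ATP-linked = compound − oligomycin; proton leak = oligomycin − non-mito.
On vehicle wells basal = ATP-linked + leak + non-mito holds exactly at
zero noise.

A protonophore is flagged when compound-phase OCR ≥ 115% of baseline
**and** the oligomycin level stays ≥ 100% of baseline (oligomycin cannot
suppress uncoupled respiration). Both thresholds are config-exposed; the
defaults sit far below the > 150% signal a strong uncoupler shows at top
doses in a high-spare-capacity line, and far above vehicle noise. In a
low-spare-capacity (HepG2-like) profile the oligomycin-resistance
criterion may not be met even at full drive — with maximal OCR 159.4%,
the post-oligomycin level tops out at ~84% — so uncoupler detection is
most sensitive in the oxidative profile, and the pipeline ORs the flag
across cell lines.

## Dose–response and statistics

Fits run in log10-concentration space; vehicle (zero-concentration)
points anchor normalization but are excluded from the fit abscissa.
Initialization: top = mean of the two lowest-concentration responses,
bottom = minimum (reversed for increasing curves), logIC₅₀ = the
half-range crossing, slope = 1; bounds slope ∈ [0.1, 10], bottom ∈
[−10, 110]. The trust-region fit uses the analytic Jacobian; a constant
curve returns a degenerate converged fit that downstream censoring turns
into "> top". Fits are on per-concentration means of replicates; SDs are
carried for plotting only.

Censoring: inhibition endpoints report "> log10(top)" when the fitted
curve never crosses 50% within the ladder (the reporting convention of
intact-cell summary tables); the permeabilized stage potencies use an
additional NR rule (total fitted range < 20%) mirroring the mixed
"NR"/"> top" vocabulary of such tables. Activation endpoints use the
1000-point point-to-point curve with first-crossing-from-low as the
tie-break for non-monotone curves, and report NR when 50% is never
reached.

LOECs come from Dunnett's many-to-one test (scipy's multivariate-t
implementation, seeded). The one-way ANOVA omnibus p-value is computed
and reported, but the per-concentration flags are *not* gated on it:
Dunnett alone controls the familywise error at α exactly, whereas an
ANOVA pre-gate deflates it to ~0.025 at α = 0.05 — outside the
calibration band the package holds itself to. Pooled-variance contract:
unequal spread across groups is tolerated, not modelled.

## Mechanism-of-action rule

Precedence: uncoupler > complex-specific inhibitor > downstream >
inactive. The protonophore signature dominates (contradictory evidence —
uncoupling plus a full ETC block — is annotated in the evidence record).
Otherwise the permeabilized complex call names the mechanism; CII is
reported as *masked* CII inhibition, and CI/CIII calls stand even when
the intact-cell assay was silent — intact silence with a clean
permeabilized pattern means the potency lies beyond the intact ladder,
not that the compound is inactive (the capsaicin-like weak-CI case).
With no complex evidence and no intact activity the compound is inactive.

## What passing tests do and do not show

The generator reproduces the qualitative patterns the analyses target —
dose-graded OCR loss with reciprocal ECAR gain, intact-cell CII silence,
stage-wise rescue patterns, protonophore oligomycin resistance,
glucose/galactose and 2D/3D viability coupling — with lognormal noise.
It is *not* a mechanistic model: no proton-motive force, no Q-cycle
kinetics, no time dynamics within a phase, no pharmacokinetics, no
metabolism or transport differences between cell lines, and the
protonophore is modelled as a pure uncoupler without any partial CIII
action. Recovery of simulated ground truth therefore validates the
analysis chain under the stated statistical structure, not the biology of
any particular compound. The OCR-vs-ECAR correlation illustrates the
leverage problem real data would share: the uncoupler's elevated-OCR
branch lies off the inhibitor line and lowers pooled r², most strongly in
the high-spare-capacity profile.

## Problem sizes

Default analysis runs use one well per compound × concentration plus six
vehicle wells per plate, single plates per cell line, 200 replicate
plates for classifier-accuracy estimates and 1000 simulated panels for
the Dunnett null calibration — sizes chosen to give stable estimates at
interactive runtimes on a single CPU.
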