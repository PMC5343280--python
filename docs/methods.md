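# Methods

## The positional label model

The atom map covers glucose → G6P → F6P → F16BP → {DHAP, GA3P} → 2/3-PG →
PEP → pyruvate, pyruvate dehydrogenase, and one TCA turn (citrate synthase →
aconitase → IDH → OGDH → SDH → fumarase → MDH). A metabolite pool is a
weighted set of per-carbon label masks; a reaction moves each substrate
carbon to its mapped product position or releases it as CO₂ (the released
label weight is tracked). The loader validates full atom balance: every
substrate carbon appears exactly once in the map-or-lost set and every
product carbon is hit exactly once.

Assumptions, all standard biochemistry:

* **Stereospecific aconitase/IDH.** Citrate is prochiral; the CO₂ released
  at IDH comes from the central carboxyl (oxaloacetate C1) and at OGDH from
  the 2-oxoglutarate C1 (oxaloacetate C4). Acetyl-derived carbons therefore
  survive to 2-oxoglutarate and succinate in the first turn.
* **Symmetry scrambling.** Succinate and fumarate have 2-fold rotational
  symmetry; each mask is replaced by an equal mixture of itself and its
  reversal (idempotent). This is what makes first-turn oxaloacetate a 50/50
  mixture of [1,2-¹³C] and [3,4-¹³C], and hence second-turn 2-oxoglutarate
  half M+3 / half M+4.
* **Complete triose-phosphate equilibration.** DHAP and GA3P become the same
  50/50 mixture of the two hexose halves (only visible for non-uniform
  tracers). No partial-equilibration parameter is exposed.
* **Turn bookkeeping, not flux.** Turn 1 condenses tracer-derived acetyl-CoA
  with unlabeled oxaloacetate; turn 2 condenses the turn-1 oxaloacetate with
  an independent draw of tracer-derived acetyl-CoA. Dilution by unlabeled
  acetyl-CoA between turns is deliberately not modeled positionally — it is
  an enrichment-scale phenomenon and is absorbed by the enrichment
  fractions downstream. There is no ¹³C-MFA fitting and no kinetics.
* **Scope.** The pentose phosphate shunt, pyruvate carboxylase anaplerosis,
  lactate/alanine exchange, and amino-acid pools are outside the label
  model (pyruvate carboxylase appears only as an enzyme activity). 2- and
  3-phosphoglycerate are one node (they are measured combined), and
  glyceraldehyde 3-phosphate, acetyl-CoA and oxaloacetate are modeled but
  not measured.

The implementation is checked against an independent brute-force oracle
that enumerates every positional path (triose branch, equilibration choice,
both symmetric orientations, the independent second acetyl draw) for all 64
glucose label masks over two turns.

## Transition design

Labeled masses are additive on nominal integer bases (the instrument table
rounded): Q1 = base + n for M+n, Q3 = base + retained labels. Fragment
rules: phosphate-type product ions (G6P, F6P, F16BP, DHAP, 2+3-PG at 97 Da;
PEP at 79 Da) carry no analyte carbon; pyruvate loses its C1 carboxyl; the
TCA acids lose exactly one carboxyl, each allowed carboxyl equally. With the
citrate numbering used here (C1 acetyl carboxyl, C5/C6 the
oxaloacetate-derived carboxyls; 2-oxoglutarate C1/C5) this reproduces every
published labeled ion mass. Two deliberate deviations from the published
list are documented as such: the aconitate first-turn product pair is
emitted as 86/87 (the rule applied to base 85; the printed "85 and 86"
contradicts both the base mass and the one-carboxyl retention rule and is
treated as a likely typo), and first-turn succinate products, absent from
the printed list, are emitted as 74/75. Instrument parameters (RT, DP, CE,
CXP) are label-invariant; ionization is negative-mode [M−H]⁻ throughout.
No isotope fine structure or high-resolution m/z is computed.

## Quantification

Percent enrichment per turn is the turn's labeled area (summed over product
ions) over total monitored signal, so it is invariant to uniform scaling of
a sample × analyte block, bounded in [0, 100], and turn fractions sum below
1. Missing transitions are missing data: a sample lacking the unlabeled
channel is flagged and excluded for that metabolite, never imputed zero.
No natural-¹³C-abundance correction is applied (an explicit choice: the
labeled species monitored here are well separated from the unlabeled
envelope, and the study design compares the same uncorrected quantity
between groups). Concentration uses a 4 nmol azidothymidine spike (4 μL ×
1 mM) and per-analyte response factors (default 1.0 — arbitrary units on a
common scale; with calibrated factors the same arithmetic yields absolute
nmol/g).

## Statistics

Two-way ANOVA is a full-factorial fixed-effects model (group × metabolite)
with Type III sums of squares on sum-to-zero contrasts, computed by direct
least squares (full model vs one-effect-dropped models). Type III matches
the commercial software convention for unbalanced layouts; the test suite
cross-checks against statsmodels' `anova_lm(typ=3)` and a closed-form
balanced decomposition. Fisher's LSD posttests use the ANOVA residual mean
square and df: `t = Δmean / √(MS_resid (1/n₁ + 1/n₂))`, uncorrected
two-sided p — by construction equal to the pooled t-test when one
metabolite is analyzed. Mice are treated as independent replicates and
metabolite as a fixed factor. No multiplicity correction anywhere; α = 0.05.
Degenerate inputs (empty cells, constant vectors, zero pooled variance) are
rejected or flagged, never silently propagated. The LSD's type-I error is
verified at 0.05 ± 0.01 under 5000 null simulations.

## Assays

Specific activity = |slope| / (ε · path) · volume / protein, reported in
nmol·min⁻¹·mg⁻¹. The fit window is the package's convention (no published
standard exists): the longest initial segment of ≥ 5 points whose linear
fit keeps r² ≥ 0.98; traces with no such window are flagged rather than
extrapolated. Defaults: ε(NADH/NADPH) = 6.22 mM⁻¹cm⁻¹ at 340 nm, ε(TNB) =
13.6 at 412 nm, an MTT-formazan calibration coefficient of 17.0 (per-assay
config — the MTT method needs an empirical factor), path length 0.55 cm for
a 0.2 mL microplate well, 1 cm for cuvette-style examples. State 4o is the
post-oligomycin stage. Respirometry arithmetic is exactly the staged
subtractions listed in the README; every parameter is nonmito-subtracted
first and protein-normalized, which makes the parameters invariant to a
constant offset on all raw stages and inversely proportional to protein.
Negative derived respiration is reported with a warning flag (possible
uncoupled preparation), undefined RCR (state 4o ≤ 0 after subtraction) is
flagged.

## The synthetic cohort generator

What it emulates — and the defaults, chosen once:

* **Cohort**: 11 No SE / 10 SE for tracing; 8/8 for enzymes; 7/7 for
  respirometry (mid-range of the reported 6–9 per assay).
* **Uptake structure**: a per-animal factor u ~ N(1, 0.15) multiplies all
  glycolytic enrichments, inducing the strong G6P–downstream correlations;
  in SE animals 2+3-PG swaps to an independent factor (its correlation
  collapses, as reported).
* **TCA coupling**: No SE first-turn enrichments follow realized pyruvate
  enrichment (× metabolite noise, CV 0.05); SE animals replace that driver
  with an independent mitochondrial-capacity factor N(1, 0.15), destroying
  the pyruvate–TCA correlations. First-turn succinate follows realized
  2-oxoglutarate; the No SE transfer-noise CV is solved in closed form from
  the targeted coupling r = 0.95 given the other variance components, and
  SE transfer scatter (SD 0.30) was derived the same way from the reported
  SE coupling (r ≈ 0.42).
* **Effects**: the reported percent reductions (figure-legend values where
  the text disagrees): glycolysis G6P 22 / F6P 21 / DHAP 17 / PEP 20; TCA
  turn 1 CIT 17 / ACO 17 / SUC 35 / FUM 23; turn 2 2OG 47 / SUC 55 / FUM 25 /
  MAL 29; enzymes PDH 33 / OGDH 55; respirometry all zero.
* **Baselines**: absolute enrichments are not published, so defaults are
  realistic choices (glycolytic 15–28%, TCA turn 1 5–8%, turn 2 2–3%) and
  irrelevant to the relative-effect targets. Concentrations are drawn
  around the published group means with SDs from the published SEMs
  assuming n = 8 (the study reports n = 6–9).
* **Noise**: lognormal area noise CV 0.10 applied per sample × analyte
  block (ionization/matrix effects are shared across a block's
  isotopologues) plus independent per-transition noise CV 0.015. Block-level
  noise cancels in the enrichment ratio — with all noise off, recovered
  enrichment equals the latent value exactly. Labeled signal is split
  across product ions by the positional pools under equal-probability
  carboxyl loss.
* **Assay synthesis**: enzyme activities (CV 0.20 between animals) are
  realized as linear absorbance traces (41 points over 10 min, jitter
  3 × 10⁻⁴ AU) via the inverse of the activity formula; respirometry stages
  get a shared preparation factor (SD 0.12) and per-stage noise (CV 0.08).

What it does **not** emulate: retention-time drift, batch effects, natural
abundance, missing injections, detector saturation, or raw chromatograms.
Passing round-trip tests therefore show the pipeline's arithmetic and
statistics are correct and unbiased under the study's stated structure, not
that the instrument model is realistic.

## Numerical choices

Pool weights are validated to sum to 1 within 1e-9 after every operation.
ANOVA sums of squares below a scale-relative floor (1e-12 × total SS) are
reported as exact zeros so constant data yields F = 0, p = 1. Pearson r is
clipped to [−1, 1] before the t transform; |r| = 1 reports p = 0. The
linear-window search treats an exactly flat segment as a perfect fit
(slope 0), so flat traces give zero activity rather than a flag.

## Problem sizes

The replication studies run 200 seeded cohorts for parameter recovery and
5000 null replicates for LSD calibration; the analysis driver uses 50
cohorts for its quick summary. These sizes give Monte-Carlo standard errors
comfortably inside the tolerances they are checked against (e.g. ±0.5
percentage points on a recovered 33% reduction at 200 replicates).

## Known limitations

* The published animal-level enrichment values and p-values cannot be
  reproduced (no deposited raw data); all quantitative validation is
  generator round-trip recovery.
* The label model stops at two turns and excludes anaplerosis; studies with
  substantial pyruvate carboxylase flux would see M+3 citrate species this
  design does not monitor.
* Enrichment inference assumes the monitored transitions capture all
  labeled species of an analyte; a tracer producing shifts outside the
  design would bias the denominator.
* The MTT calibration coefficient and response factors are configuration
  values, not measured calibrations.
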