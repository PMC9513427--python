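# Methods

## Data model

All tables are long-format pandas DataFrames. The atomic Cq record is one
reaction: `gene, group, bio_rep, tech_rep, cq`. Wells flagged by the
machine as not amplifying ("Undetermined", "Undet.", "NA", empty — matched
case-insensitively) are ingested with `cq = NaN` rather than dropped, so
row counts are conserved and missing wells surface later as explicit
pairing errors instead of silently shrinking a group. Ingestion rejects
duplicate `(gene, group, bio_rep, tech_rep)` combinations, non-positive
Cq, and dilution designs with fewer than three distinct concentrations.

Technical replicates are always averaged **on the Cq scale** before any
exponentiation, in every quantification route. Cq is the measured
quantity; averaging after exponentiation would weight wells unequally.

## Reverse-transcription planning

For each sample with full-precision mean concentration `c` (ng/ul):

    rna_vol   = round(1000 * rna_mass_ug / c, 2)        # half-to-even
    comp_vol  = vol_per_ug * rna_mass_ug                # per component
    water_vol = total_volume_ul - rna_vol - sum(comp_vol)

Water is defined as the remainder, so each row sums to the total exactly;
negative water (sample too dilute for the requested mass) is an error
naming the sample. Two numerical conventions matter and are deliberate:

* The mean concentration is carried at full precision; only display is
  rounded to 2 dp. A 2-dp pre-rounded mean can flip the RNA volume's last
  digit (e.g. 2000/163.333… = 12.24 but 2000/163.33 = 12.25).
* RNA volume rounds half-to-even at 2 dp (Python/IEEE default). No tie
  case distinguishes half-up from half-to-even in the worked examples, so
  this is documented as a convention rather than a verified behavior.

RNA mass and total volume are explicit required parameters with no
defaults: typical values (2 ug into 40 ul) are experiment choices, not
package opinions.

## Standard curves and efficiency

`fit_curve` performs OLS of Cq on x = log10(relative concentration)
(`scipy.stats.linregress`). The x-axis is base-10 regardless of the
dilution factor; the factor only sets the spacing of the concentration
grid, so any dilution factor > 1 is supported without changing the
efficiency formula `E = (10^(-1/slope) - 1) * 100`.

By default all reaction-level points enter the regression
(`use="all_points"`); `per_dilution_mean` first averages technical
replicates per dilution level. In balanced designs both give the same
slope, but R² differs (within-level scatter is removed by averaging), so
the point-level default is the more honest quality readout.

A non-negative slope marks the fit invalid: efficiency is undefined, the
report row is retained with a flag, and inverse prediction refuses the
curve. Quality thresholds (R² >= 0.99, efficiency in 90–110 %) are
reported as advisory flags only — no cutoff in the literature is universal
enough to hard-fail on.

Inverse prediction outside the fitted Cq range warns by default
(`ExtrapolationWarning`) and can be made an error (`extrapolation="forbid"`).

## Quantification routes

**Standard curve** (`expr_by_curve`): per-sample quantity through each
gene's own curve; normalization by the reference gene's quantity in the
exactly matching `(group, bio_rep)` — there is no pooled fallback, so a
missing reference well is an error listing the orphaned records, never a
silent misalignment. One reference gene by design; multi-reference
normalization lives in the NRQ route.

**2^-ddCt** (`expr_ddct`): ddCt is centered on the control group's *mean*
dCt per gene (the standard replicated-calibrator practice), not on a
single designated replicate. The base is exactly 2; efficiency correction
is deliberately left to the NRQ route so the two methods stay distinct and
their disagreement under unequal efficiencies is interpretable.
`ddct_admissibility` reports per-target |E_target − E_reference| against a
tolerance (default 5 percentage points), advisory only.

**Efficiency-corrected NRQ** (`expr_rqpcr`): RQ uses each gene's fitted
amplification factor and is centered on the gene's all-sample mean Cq — a
presentation choice only, since any per-gene constant cancels after
normalization and control scaling. The normalization factor is the
geometric mean of the reference genes' RQs per sample (order-invariant by
construction). Efficiencies are supplied as amplification factors
(2.0 = 100 %); `amp_factor_from_efficiency_pct` converts percentages, which
keeps the chronic E vs. E+1 ambiguity explicit at the API boundary.

**Control scaling uses the geometric mean.** `nrq_scaled = NRQ / geometric
mean(control-group NRQ)`. On the Cq scale this is arithmetic-mean
centering, so (i) with one reference and all A = 2, `nrq_scaled` equals the
2^-ddCt fold change exactly, record for record, and (ii) the geometric mean
of the control group's scaled values is exactly 1. An arithmetic-mean
scaling would break identity (i) whenever control replicates vary
(arithmetic mean of a log-normal exceeds its geometric mean) and was
rejected for that reason.

Uncertainty of NRQ is summarized empirically across biological replicates
(SD/SE in `summarize`), not by analytic CV propagation: the empirical route
is assumption-light and treats all three methods uniformly. Exact numeric
parity with any particular web tool's variance formulas is not claimed.

`stability_rank` scores candidate references by the SD of log2(RQ) across
samples — a deliberately simple, transparent criterion for flagging an
unstable housekeeping gene; it is advisory and gates nothing.

## Group statistics

The two-group test is Welch's (unequal variance) t-test — the safer
default given that "t-test" alone does not pin the variance assumption.
Stars: * / ** / *** at p < 0.05 / 0.01 / 0.001. Degenerate convention:
two identical zero-variance groups give p = 1. At very small group sizes
(n ≈ 6) Welch's test is mildly conservative — its true null rejection rate
sits near 0.045 rather than 0.050 — which is the expected cost of not
assuming equal variances; the calibration study's tolerance band
accommodates it.

Multi-group designs use one-way fixed-effects ANOVA plus all-pairs Tukey
HSD (`scipy.stats.tukey_hsd`, studentized range). The compact letter
display uses the insert-and-absorb algorithm: start from one letter
covering all groups; for each significant pair, split every letter
containing both into two (each missing one member); absorb subset letters.
This guarantees shared-letter <=> adjusted p >= alpha in both directions.
Letters are assigned 'a', 'b', … in descending order of group mean, ties
broken lexicographically by group name, so output is deterministic.

Tests operate on per-replicate expression values (never on Cq); a `log2`
option transforms values before testing for heavily skewed fold changes
while leaving the reported means/SDs on the raw scale. Cross-gene
multiplicity is out of scope: each gene's family of comparisons is
corrected internally (Tukey), but no FDR is applied across genes.

## Synthetic data generator

The generator emulates the three input kinds under a first-order noise
model: independent additive Gaussian noise on the Cq scale, optionally at
two levels (a shared per-biological-replicate shift plus per-well
technical noise). Ground truth per gene is `(amp_factor, base_cq)`; a
group's fold change F shifts Cq by `-log_A(F)`, and dilution step k raises
Cq by `k * log_A(dilution_factor)`. Everything is deterministic under a
fixed seed (byte-identical tables).

What it does **not** emulate: plateau/saturation kinetics, inhibitor
dose-dependence (efficiency drifting along the dilution series),
heteroscedastic noise at high Cq, pipetting-correlated errors, or
between-run calibration shifts. Passing recovery tests therefore shows the
estimators are correct under their own assumptions, not that real plates
meet those assumptions.

Default study conditions used by the recovery and calibration studies:
true fold change 4 with A = 2, Cq noise SD 0.15 cycles, 6 biological x 2
technical replicates, 500 simulated experiments; null calibration uses
2000 simulations of n = 6 normal samples at alpha = 0.05. Problem sizes
were chosen as typical bench-scale designs whose Monte-Carlo error is
comfortably inside the stated recovery bands.

## Numerical and interface choices

* Result-table serialization: volumes at 2 dp, expression quantities at 4
  significant digits, p-values in scientific notation — a round-trip
  through `write_result_table` preserves values at those precisions.
* Column mapping is user-supplied (defaults `gene/group/biorep/techrep/cq`)
  rather than hard-coded to any machine's export.
* XLSX input reads the first sheet unless a sheet name is given.
* Plots are plain matplotlib Figures returned to the caller for further
  styling; annotations are string-formatted from the same table cells they
  summarize. Error bars default to SE (configurable to SD).

## Known limitations

* No parsing of proprietary machine exports (RDML, .eds).
* No MCMC/reference-free quantification, no absolute quantification.
* Single-factor designs only; no mixed models or nonparametric tests.
* The RT planner does not pool master mixes or add pipetting overage.
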