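# Methods

## Data model

The unit of observation is a community-pharmacy dispensation: anonymized
patient code, birth date, gender, dispensation date, ATC level-5 code, number
of packages and the total number of Defined Daily Doses (DDD) dispensed. One
DDD is treated as one day of supply, so a record's `ddd_total` is its
duration in days; when a source table lacks the DDD column, duration falls
back to (packages × units per package × DDD per unit). Dates are calendar
dates; all intervals are closed on the left and open on the right, measured
in whole days — dispensing data carries no finer resolution. A separate
death registry (patient code, death date) is joined on the patient code.

Input tables are delimited text with a configurable column map and date
format (`records.Dialect`), defaulting to CSV with ISO-8601 dates. Rows with
a malformed ATC code, an unparseable date or an unknown gender are rejected
and counted in a read report; a missing mandatory column is a hard error.
Gender is restricted to male/female, the two values administrative extracts
in scope carry.

## Cohort selection

The new-user design is parameterized by `cohort.StudyConfig`:

| parameter | default | meaning |
|---|---|---|
| `data_window` | 2018-01-01 .. 2021-12-31 | observation window |
| `washout_year` | 2018 | year that must be free of antidiabetic (A10) dispensations |
| `index_year` | 2019 | year of the qualifying first dispensation |
| `age_reference_date` | 2021-12-31 | age measured here, in completed years |
| `min_age_years` | 18 | adult cut-off |
| `min_index_year_dispensations` | 1 | dispensations required in the index year |
| `min_follow_up_dispensations_per_year` | 2 | per-calendar-year rule after the index year |
| `combination_window_days` | 9 | first-line combination window |

Exclusion reasons are assessed in the fixed order age → wash-out →
index-year → follow-up frequency → death, and the first failure is recorded,
so the exclusion ledger partitions the screened population exactly. The
follow-up frequency rule is applied to every calendar year after the index
year up to the study end: antidiabetics treat a chronic condition, and a
patient who stops refilling is not a continuing user. Follow-up ends at the
patient's last antidiabetic dispensation or the window end, whichever is
earlier; "last prescription" is read as last *antidiabetic* prescription
since the study concerns antidiabetic therapy.

The 9-day combination window is inclusive at both ends: a second distinct
antidiabetic dispensed on the index date itself (a multi-drug start) or up
to day 9 marks a first-line combination initiator, who is set aside before
trajectory and adherence analysis. Distinct-drug identity is the full ATC
level-5 code; a fixed-dose combination (A10BD) is one drug, and a built-in
component table marks which A10BD products contain metformin.

## Comorbidity index

The adapted Rx-Risk index maps ATC level-2 classes to 21 conditions (4
diabetes-concordant, 17 discordant, per Piette's concordance notion). A
condition is flagged when the patient has ≥1 non-antidiabetic dispensation
in a mapped class during the whole study window — presence-based, with no
dose or duration threshold, because a dispensation is the only evidence the
data carries. Code ranges ("J01–J07") expand numerically within one letter
prefix at map-construction time. Antithrombotics (B01) sit under the
cardiovascular condition and C02/C03/C09 under hypertension in this
adaptation. Reporting filters keep conditions (and ATC level-1 groups in the
usage table) reaching ≥10 % prevalence in at least one subgroup. No summed
risk score is computed; the analysis uses flags only.

## First-intensification classification

Only the first therapy change is classified. With t\* the date of the first
non-metformin antidiabetic dispensation after the combination window:
no t\* → monotherapy; a metformin-containing fixed-dose combination at t\*
→ add-on; any plain-metformin dispensation on/after t\* → add-on (the
second drug joined continuing metformin — presence-based, with no minimum
overlap duration, the simplest reading consistent with dispensing data);
otherwise switch. A switch is a switch-then-discontinue when the last
antidiabetic supply runs out at least `discontinuation_gap_days` (default
90, a conventional refill-gap grace period — the underlying study never
defines discontinuation) before the window closes. Reporting rolls the
change drug up to its ATC level-4 class; all insulins report as one
"insulins alone or in combination" class, and A10BD codes as "fixed-dose
combination (components)".

## Adherence

CMA (continuous multiple-interval measure of medication availability) over
[index date, follow-up end): dispensations are swept in date order; each
supply starts at max(dispense date, end of accumulated supply) and is
truncated at the window end, so oversupply carries forward and CMA ≤ 100 %.
A dispensation on the window's final day contributes nothing (its supply is
unobservable). All antidiabetic supply is pooled into one availability
stream, giving a single per-patient CMA; per-drug averaging is not the
default because the cohort's outcome of interest is availability of *any*
antidiabetic treatment. A simple supply/window ratio (optionally uncapped)
is available as a sensitivity variant; on schedules with no overlapping
intervals and nothing crossing the window end it equals the carry-over
value. Fractional DDD totals are kept fractional; only display rounds to one
decimal. Strata: adherent CMA ≥ 80 %, partially adherent 40–80 %,
non-adherent < 40 %, closed at the lower edge. Medians and quartiles use
linear interpolation between order statistics (numpy's default), fixed here
for reproducibility.

## Significance tests and rendering

Baseline tables use the Pearson chi-square test without continuity
correction (df = (r−1)(c−1); zero margins are an error) and one-way ANOVA
(all-identical values return F = 0 with a warning, rather than 0/0).
Percentages and CMA render to one decimal with half-up rounding; p-values
below 0.01 render as "<0.01" while raw values stay in machine output.

## Synthetic data

The generator emulates a four-year health-authority dispensing stream with
eight patient archetypes (mix configurable, defaults: prevalent user 0.45,
naïve monotherapy 0.25, combination 0.02, add-on 0.07, switch 0.04,
switch-then-discontinue 0.01, sporadic 0.12, decedent 0.04 — prevalent users
dominate real extracts). Adherence behaviour is modelled through refill
gaps, the observable in dispensing data: the gap between consecutive
dispensations is days-of-supply / target CMA (plus optional ±2-day jitter;
zero jitter makes the realized CMA equal the target exactly). Default supply
is 28 DDD per dispensation. After an add-on change the two products
alternate on one pooled schedule so availability stays at the archetype's
target. Per-archetype CMA targets default to 0.46 for monotherapy and ~0.62
for multi-drug patients. Comorbidity co-dispensations are Bernoulli per
Rx-Risk condition with configurable prevalences (defaults from the
metformin-monotherapy stratum of the emulated population). Index-drug
weights default to a metformin-dominant first-line distribution (83.2 %
metformin; sulfonylureas, insulins, repaglinide and the newer classes make
up the rest, with the two sub-percent classes set to 0.5 %/1.3 % to close
the distribution). Every patient carries a ground-truth archetype label, and
the pipeline recovers all planted labels exactly at zero jitter.

Deterministic fixtures (no sampling) replant published marginal counts — the
1927-patient enrolled population (1090 male, 1759 single index drug), the
1361-patient metformin cohort (subgroups 931/289/92/31/18, with per-subgroup
comorbidity prevalences planted by half-up-rounded counts), the 289-patient
two-AD subgroup (189 add-on / 92 switch / 8 switch-then-discontinue) and the
nine-day population (those 1361 plus 103 combination initiators) — so
end-to-end checks are exact. Fixture patients refill every 35 days (CMA
80 %); their adherence medians are *not* calibrated to published values, and
the fixtures reproduce marginal counts only, not joint age/sex/drug
distributions. Passing fixture tests therefore shows the selection,
classification and counting rules are correct, not that the generator
matches real prescribing behaviour.

## Problem sizes and limitations

The test suite runs the generator at up to 5000 patients and the fixtures at
their natural sizes (≤1927 patients, ≈60k records), comfortably small for a
single CPU. Known limitations: no persistence/time-to-gap analysis, no
dose-adjusted adherence (DDD-only data), no propensity matching, no linkage
to clinical outcomes; the per-row DDD total is assumed to describe the whole
row even when several packages differ in content, since the source schema
stores one total per row.
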