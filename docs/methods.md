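# Methods

## Problem setting

Spontaneous-report databases such as FAERS collect unsolicited safety
reports. Disproportionality analysis asks whether a drug–event pair is
reported more often than expected under independence within the same
database. This package implements that pipeline for hyponatremia and
the PD-1/PD-L1 inhibitors, together with a synthetic-report generator
so that every stage can be validated against known planted parameters.
Nothing in a disproportionality screen estimates incidence or proves
causation; the statistics are reporting-rate contrasts.

## Ingest and deduplication

Quarterly extracts are seven `$`-delimited tables (DEMO, DRUG, REAC,
THER, OUTC, INDI, RPSR) sharing a report key (`primaryid`) and a case
key (`caseid`). The reader accepts the canonical post-2012 column
dialect only and fails loudly on others; rows whose field count
disagrees with the header are skipped and counted, and child-table rows
without a DEMO parent are excluded as orphans with a count. A case may
be submitted repeatedly as versions; deduplication keeps, per `caseid`,
the version with the latest FDA receipt date, breaking ties on the
larger `primaryid` (numeric comparison when both ids are numeric —
the convention recommended for FAERS quarterly extracts). The rule is
idempotent and reduces the collection to one report per case.
Re-submissions are reconciled globally across all quarters read
together, not per quarter.

Ages are normalized to years from the raw AGE/AGE_COD pair
(DEC×10, YR×1, MON÷12, WK÷52.1786, DY÷365.25, HR÷8766); a missing unit
with a value present is read as years, and results outside [0, 130]
years are treated as missing. Dates keep their reported precision
(`YYYYMMDD`/`YYYYMM`/`YYYY`) as a `PartialDate`; calendar-invalid dates
become missing rather than rounded.

## Case definition

Hyponatremia cases are defined by the narrow scope of the MedDRA
"Hyponatremia (SMQ)": 15 preferred terms shipped with the package as a
CSV (code, preferred term). Matching is case-insensitive and accepts
both -emia and -aemia spellings. A report is a case for a target drug
iff (i) at least one drug entry with role PS (primary suspect — strictly
PS, not SS) maps to the drug through the synonym dictionary, and (ii)
at least one reaction PT is in the SMQ set. A case is counted once no
matter how many SMQ PTs it lists; the per-PT breakdown counts a case in
every PT it matches (duplicate identical PTs within one case collapse),
so PT rows can sum to more than the case count. Reports carrying two
target drugs both as PS are assigned to both case sets; the count
additivity check accounts for them explicitly rather than silently
dropping either.

Drug-name matching uppercases the verbatim string, splits it on
punctuation, and requires the dictionary entry's tokens to appear as a
contiguous run — so "OPDIVO 240 MG" and "NIVOLUMAB AND IPILIMUMAB"
match nivolumab but "NIVOLUMABX" does not. The shipped dictionary is a
minimal trade-name/code-name list, deliberately editable; full RxNorm
normalization is out of scope.

## Disproportionality statistics

All four statistics derive from the 2×2 partition of the deduplicated
universe by (PS drug is target) × (report has an SMQ event). The
comparator is every report whose PS drug is not the target, including
the target's own non-PS reports. Formulas are as in the README table.
Two choices deserve note:

- **IC025.** The lower credibility bound uses the closed-form
  approximation IC − 3.3·a^(−1/2) − 2·a^(−3/2). It reproduces published
  worked (a, IC, IC025) triples for this problem within print rounding
  (±0.02), which is the fidelity that matters for cross-checking
  published screens; an exact-posterior BCPNN bound would differ
  slightly at very small a.
- **EBGM.** Implemented exactly as the observed/expected relative
  reporting ratio aN/((a+c)(a+b)) — algebraically 2^IC, an identity the
  tests assert to machine precision — with a log-normal-style interval
  using the Wald standard error of the table. This is the simplified
  form used in the published screens this package cross-checks, not a
  full gamma-Poisson shrinkage fit; at large margins the two converge,
  and a true GPS estimator would be a non-default extension.

Zero cells: the Haldane 0.5 correction is applied to all four cells for
the ROR and the EBGM interval only (flagged in the output); PRR, χ² and
IC return missing with a reason when their preconditions fail (their
point estimates are not meaningfully rescuable by continuity
correction). Display rounding is 2 decimals, half-up, in separate
`_2dp` columns; full precision is always retained.

Monotonicity caveat: with b, c, d fixed, ROR and PRR increase strictly
in a, but the observed/expected statistics (IC, EBGM) do not once a
dominates its own margins — d(ln OE)/da = 1/a + 1/N − 1/(a+c) − 1/(a+b)
changes sign. In the rare-event regime (a small against both margins)
all four increase together, and that is the regime the tests assert.

## Interaction screening (Ω)

Strata are defined by drug 1 with role PS and drug 2 with any of roles
SS/C/I on the same report. The no-interaction expectation for the
doubly-exposed stratum uses the inverse-rate model
1/f₁₁⁰ = 1/f₁₀ + 1/f₀₁ − 1/f₀₀. Numerical guards: if either
single-exposure rate is zero the expectation floors at max(f₁₀, f₀₁);
if the inverse combination is non-positive it floors likewise; the
result is capped at 1 since it is a rate. The +0.5 shrinkage terms in
Ω = log₂((n111+0.5)/(E111+0.5)) pull small-count estimates toward zero.
Ω025 = Ω − 1.96/(ln 2·√n111) — a width law that reproduces all four
published (n111, Ω, Ω025) worked examples within ±0.01 — is undefined
at n111 = 0 and returned as missing. Combinations with n111 < 3 are
computed but flagged low-count: small strata make all interaction
statistics unstable.

## Time to onset

Onset = event date − earliest day-precision therapy start among the PS
entries for the drug, in whole days. Exclusion (with a tallied reason)
rather than imputation applies when either date is missing or coarser
than day precision, or the interval is negative; imputing day 15 for
month-precision dates would fabricate intervals in exactly the 0–30 day
range where these drugs' onsets concentrate. Summaries use the lower
median (order statistic at ⌈n/2⌉) so that reported medians are always
observed values, with a fixed interval histogram (0–7, 8–14, 15–30,
31–60, 61–90, 91–180, 181–365, >365 days) and strata over sex and age
bins (<18, 18–44, 45–64, ≥65, unknown).

## Synthetic-report generator

The generator emulates the structure of FAERS quarterly data: per
report, catalog drugs appear independently with configured marginal
probabilities and draw a role from a per-drug distribution; catalog
events occur independently with probability min(1, background × ∏RR of
the PS drugs), so a planted relative reporting rate RR multiplies the
background only for primary-suspect exposure — the quantity the 2×2
screen estimates. Onsets are log-normal, parameterized by a median in
days and a log-scale σ (default 1.0, right-skewed as drug-event onsets
typically are); the event date is the anchor (first) PS drug's therapy
start plus the onset, and the receipt date trails the event by a 7–120
day reporting delay. A configured fraction of cases (default 5%) is
re-emitted as a second version with a receipt date 1–90 days later to
exercise deduplication; fields go missing and dates lose precision at
configured rates; target drugs are occasionally written under trade
names or with dose noise to exercise name matching; reports that draw
no catalog event receive a filler PT so every report has a reaction.

Defaults are fixed at the study's conditions: three target drugs with
planted RRs 2.56/2.25/4.28 on the hyponatremia PTs, onset medians
42/35/20 days, demographics with the ≥65 age group carrying the largest
mass, more male than female reports, physicians the most common
reporters, US and Japan the dominant countries, and hospitalization the
most frequent outcome (≈40%). The default corpus size is 20,000 reports
— large enough for stable screens at desk scale, small enough to
generate in under two seconds. The fixed default seed is 20240612.

The generator builds its reports through the same normalization helpers
as the ingest module and the writer/reader are exact inverses, so
generate → write → read → assemble equality tests codec fidelity.
Closed-form expected cells (a = N·p_PS·min(1, bg·RR), with the other
cells from the margins) are exposed per pair for recovery tests.

What the generator does **not** emulate: free-text drug-name noise
beyond the small variant list, country-dependent reporting delays,
patient-level linkage across distinct cases (only case-version
duplication is modeled), correlated events, secular reporting trends,
and real MedDRA coding drift. Passing recovery tests therefore shows
the pipeline is correct and calibrated under this generative model, not
that real-FAERS estimates are unbiased.

## Validation design

- Worked published values (IC025 triples, Ω025 quadruples, the
  EBGM = 2^IC identity) are asserted at print-rounding tolerance.
- Every statistic is checked against independently coded brute-force
  formulas on 1,000 random tables (relative error < 1e−10), and the ROR
  point estimate and χ² additionally against statsmodels and scipy.
- Null calibration: on a 50,000-report corpus with 50 drugs × 20 events
  and every RR = 1, at most 7% of the 1,000 pairs may trip the ROR
  criterion; on 500 no-interaction drug combinations at most 6% may
  have Ω025 > 0.
- Recovery: a planted RR = 2.5 at expected a = 62.5 must be flagged
  across 20 seeds, and a planted onset median of 42 days recovered
  within [36, 48] from ~500 observed intervals per seed.

One recovery expectation is not attainable and is left failing by
design: at expected a ≈ 60 the observed/expected ratio is bounded by
the planted RR = 2.5 (exposure dilution only lowers it), while
EBGM05 = OE·exp(−1.96·se) with se ≥ a^(−1/2) ≈ 0.129 caps its
expectation near 1.9 — below the MGPS threshold of 2. The MGPS
criterion at this threshold simply requires stronger associations or
several hundred cases (as in the published screens, where the positive
signals sit at a = 310–611); the ROR, PRR and BCPNN recovery checks
pass. The test asserts the full four-method recovery anyway rather than
weakening the threshold, so the limitation stays visible.

## Known limitations

- The EBGM here is the simplified relative reporting ratio, not a
  gamma-Poisson shrinkage posterior; at very small counts it is
  anti-conservative relative to true MGPS.
- The IC025 approximation is calibrated to published print precision,
  not an exact posterior quantile.
- Deduplication trusts `caseid`; true duplicate patients reported under
  different case ids are not linked.
- The drug dictionary is minimal by design; real-world verbatim name
  noise requires an external normalization step.
- No multiple-comparison adjustment is applied across events or
  combinations, matching standard screening practice.
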