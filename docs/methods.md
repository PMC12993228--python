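# Methods

## Scope and data model

The unit of analysis is one product over one annual period: quantities
purchased and dispensed, purchase value excluding VAT, gross-profit
components (sales revenue, purchase cost, reimbursed dispensing-service
fees) or an already-netted gross profit, and optional opening/closing
inventory balances. The ledger is a plain UTF-8 CSV with a header row,
"." decimal separator and a configurable delimiter; currency is
unit-agnostic (no conversion is attempted). Gross-profit aggregates are
assumed to be *per annum*, matching the other ledger columns; a
precomputed `gross_profit`, when present, wins over the derived
`sales − cost + fees` figure because source systems typically store
margins already netted for discounts and promotions.

The medical / non-medical sector split follows regulator registration
and is therefore derivable from the assortment class (prescription
medicines, OTC medicines and medical devices are medical). An explicit
`sector` column overrides the derivation; a mismatch is a warning, not
an error, since registration status can genuinely change within a year.

## Cumulative-share (Pareto) classifier

ABC and HML-P are the same engine: sort by amount descending (ties by
ascending product id, for determinism), accumulate shares of the
positive total, and cut at cumulative 70% / 90% / 100%. Decisions the
procedure's usual statement leaves open:

* **Boundary rule.** The item whose inclusion crosses a cut-off joins
  the *higher* class (`crossing_item_up`), making the top class the
  minimal prefix reaching 70% — the natural reading of "the items that
  consume 70% of the budget". `crossing_item_down` is available for
  sensitivity analysis.
* **Non-positive amounts.** Gross profit can be negative
  (loss-leaders); cumulative shares are ill-defined with negative
  terms. By default such items are forced to the lowest class and
  excluded from the denominator (`force_lowest`);
  `include_in_ranking` keeps them in the signed walk.
* Cut-offs are configurable but default to (0.70, 0.20, 0.10); the
  implied per-class value boundaries (min/max amount per class) are
  reported as an output rather than treated as primary thresholds.
* Comparisons use an absolute guard of 1e−12 on cumulative shares so
  that inputs aligning exactly with a cut-off classify as intended
  despite binary floating point.

## FSN classification

"Dispensed *n* times per day" is operationalised as dispensed
*quantity* per calendar day (`qty_dispensed / period_days`), because
annual ledgers record quantities, not transaction events. The class
intervals follow the stated thresholds verbatim: F = (4, ∞), S = [1, 4]
closed at both ends, N = [0, 1). `period_days` defaults to 365 calendar
days (not working days), consistent with the 365 in the days-held
formula.

## Matrix consolidation

Cross-tabulation is exact bookkeeping; every sector product must carry
both axis labels (a missing label is an error naming the id and axis).
The cell-to-category mapping is data — a nine-entry table defaulting to
row A ∪ column F/H → I, the CN/CL corner → III, remainder → II — so a
pharmacy can adapt the control logic in configuration.

Axis-label scope is genuinely ambiguous for sector matrices: class
labels can be computed on the pooled inventory and then restricted to
each sector, or recomputed within each sector. Both modes are
implemented (`label_scope = "pooled" | "sector"`); pooled is the
default and neither is asserted as canonical. Published reference
matrices are shipped as aggregate cell counts with synthetic member ids
(the underlying data are proprietary); their nine non-medical cells sum
to 8,049 against a reported sector size of 8,051 — a discrepancy in the
source aggregates that is preserved, not repaired.

## Turnover metrics

`ratio = value / ((opening + closing)/2)`, `days = 365/ratio`, with the
year length fixed at 365 (no leap-year switch). Class-level aggregates
sum member purchased values and member average balances; summing
average balances equals averaging summed balances under this
definition, so there is no aggregation ambiguity. A zero or negative
average balance makes the ratio undefined (an error), never infinity.
Members are summed in product-id order so reports are invariant to
record order. Report tables round ratios and days half-up to one
decimal; internal values are unrounded, so printed (ratio, days) pairs
need not satisfy `days × ratio = 365` exactly after rounding.

## Synthetic ledger generator

The generator emulates the stylised facts of a mixed community-pharmacy
assortment, with one seeded `numpy` generator threaded through every
draw (fixed seed ⇒ byte-identical ledger):

* **Purchase values** are lognormal with log-sigma 1.8 (median scale
  55 currency units — only the shape matters; every classification is
  scale-invariant). At sigma 1.8 the top ~10% of items carry ~70% of
  total spend.
* **Dispensing** is a two-part mixture. A fixed-size active set —
  3.2% of items, sampled with √value weighting so that moving items
  also carry an outsized value share — gets rates ≥ 1/day (19% of them
  fast movers above 4/day); the rest get a cubed-uniform rate below
  1/day, piling mass near zero.
* **Sector mix and margins:** 23.6% of items are medical; margins are
  drawn per assortment class, with regulated medical ranges
  (8–25%) capped below non-medical ones (18–45%); prescription items
  earn a small reimbursed service fee per dispensed unit.
* **Balances** are noisy fractions of annual purchase value (base
  fraction 0.22, lognormal noise), shrinking mildly with item value so
  high-spend items turn faster — giving the A > B > C turnover
  gradient real assortments show and an overall ratio in the
  mid-single digits.

What the generator does **not** emulate: seasonality and within-year
trends, price changes, correlated demand across products, expiry and
write-offs, and multi-facility heterogeneity. Passing tests on
synthetic data therefore demonstrate correctness of the computations
and stability of the pipeline, not calibration to any real facility.

## Numerical and reporting choices

Percentages and displayed ratios round half-up (commercial rounding) to
one decimal by default; banker's rounding would bias boundary cases
like 0.25% downward relative to how such tables are conventionally
printed. Over a three-class partition the rounded percentage column can
drift from 100.0 by up to ±0.15 in principle; ±0.1 in practice. Report
data files contain no timestamps, so identical inputs and configuration
reproduce byte-identical bundles; only the run log records wall-clock
time. The CLI maps error families to exit codes (2 validation,
3 degenerate input, 4 I/O).

Test and demonstration problem sizes (hundreds to 10,000 products, five
seeds for distributional checks) were chosen as representative of a
real assortment's scale while keeping the default suite quick to run.

## Known limitations

* No VED/VEN (criticality) axis — category assignment is purely
  economic/movement-based and is decision support, not clinical triage.
* Single facility, single period; no before–after evaluation of
  implementing the control categories.
* FSN thresholds expressed in quantity-per-day inherit any pack-size
  heterogeneity present in the ledger's quantity units.
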