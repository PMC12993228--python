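# pharmstock

Selective inventory control analytics for community pharmacies.

Community pharmacies stock thousands of products — regulator-registered
*medical* items (prescription medicines, OTC medicines, medical devices)
and a larger *non-medical* assortment (supplements, cosmetics, teas, baby
products, ...). Spend and movement are extremely skewed: roughly a tenth
of the items consume most of the budget, and the vast majority are
dispensed less than once a day. `pharmstock` implements the dual-matrix
selective-control model that turns an annual per-product ledger into
actionable oversight tiers, for pharmacy managers and health-services
researchers.

## The model

Three single-dimension classifications feed two 3×3 matrices:

* **ABC** — rank all products by annual purchase value (excl. VAT),
  walk the cumulative share and cut at 70% / 20% / 10%: class A holds
  the minimal prefix reaching 70% of spend, B the next 20%, C the rest.
* **FSN** — dispensing frequency *r* = annual dispensed quantity / 365:
  Fast if *r* > 4 per day, Slow if 1 ≤ *r* ≤ 4, Non-moving (dead stock)
  if *r* < 1.
* **HML-P** — the same 70/20/10 cumulative split applied to annual gross
  profit, *GP* = sales revenue − purchase cost + reimbursed service
  fees: High / Medium / Low profitability.

Medical products are cross-tabulated ABC × FSN, non-medical products
ABC × HML-P. Each matrix folds into control categories:

| | F / H | S / M | N / L |
|---|---|---|---|
| **A** | I | I | I |
| **B** | I | II | II |
| **C** | I | II | III |

Category I = strict control, II = moderate, III = minimal (candidates
for reduction or de-listing). Turnover metrics complete the picture:

```
turnover ratio = annual purchased value / ((opening + closing balance) / 2)
days inventory held = 365 / turnover ratio
```

Because real facility ledgers are proprietary, the package ships a
seeded synthetic generator reproducing the field's stylised facts
(heavy-tailed spend, ~3% of items moving ≥ 1/day, regulated medical
margins) plus the reference matrices of a published 10,541-product
annual assortment.

## Worked example

```
python examples/consolidate_reference_matrices.py
```

prints, for the medical ABC × FSN matrix,

```
    F   S     N
A  22  74    39
B   3  46   126
C  11  35  2134

medical categories: {'I': 149, 'II': 207, 'III': 2134}
```

— of 2,490 medical products, 149 need strict control, 207 moderate, and
2,134 (the low-value non-moving corner cell CN) only minimal oversight.
The non-medical matrix consolidates to 580 / 1,251 / 6,218.

The full pipeline on synthetic data:

```
python examples/classify_synthetic_ledger.py
```

```
5000 products: 1180 medical (23.6%), 3820 non-medical (76.4%)
ABC class sizes (by purchase value): {'A': 474, 'B': 998, 'C': 3528}
FSN class sizes (by dispense rate): {'F': 24, 'S': 136, 'N': 4840}
HML-P class sizes (by gross profit): {'H': 507, 'M': 1029, 'L': 3464}
medical control categories (strict/moderate/minimal): {'I': 111, 'II': 252, 'III': 817}
non-medical control categories: {'I': 439, 'II': 773, 'III': 2608}
```

Class A holds ~9% of items (474/5000) yet 70% of spend — the Pareto
pattern the model exploits — and 97% of items move less than once a day.

The same pipeline runs from the shell:

```
pharmstock synth --n 10000 --seed 1 --out ledger.csv
pharmstock classify --input ledger.csv --out report/
```

writing one CSV per table (ABC/FSN/HML-P summaries, both matrices and
category counts, per-product labels, turnover) plus `summary.json`.

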