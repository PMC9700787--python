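# Methods

## The index and its assumptions

The EFSI of a food item is a weighted sum of normalized characterized
impacts: `sum_c e_c / NF_c * w_c / 100` over the 13 ILCD midpoint categories
retained after excluding the three toxicity-related ones (human toxicity
cancer and non-cancer, ecotoxicity), whose characterization models are
considered insufficiently robust for weighting.  The functional unit is fixed
at 1 kg of final product for every item — no per-portion variants — so items
are directly comparable and the index stays a per-kg intensity.

Normalization expresses each impact as a fraction of the *per-capita yearly
impact of a European reference food basket* (`NF_c = sum_i FC(i) e_c(i) /
population`).  This makes the index dimensionless and food-referenced:
an item whose impact profile equals the per-capita basket profile scores
exactly the weight total.  The bundled reference tables use the EU-28 basket
with population 509,718,000 (the 2013 figure attached to the published
table, used as printed) and the EC-recommended weighting factors, which sum
to 100.02 % and are deliberately **not** renormalized to 100 — they are
applied verbatim as `w/100`.  Consequently the exact self-consistency
constant of the package is 1.0002, not 1.

A computed `NormalizationTable` (provenance `"computed"`) and the bundled one
(`"EFSI-Table1"`) are distinct objects; the scorer uses whichever the caller
passes and never mixes them.  The EC Single Score shares the formula but
needs the Commission's economy-wide normalization references, which are not
published in a form this package may bundle; they are supplied via the
tables config (`{code, nf, unit, weight_percent}` records, units validated
against the registry).

## Grading

Raw-scale cutoffs 4e-4 / 1.45e-3 / 2e-3 / 1e-2 split the index into grades
A–E.  Lower bounds are inclusive: a value exactly at a cutoff takes the
higher grade (literal reading of the published "<" and "≥" signs).  The
choice is consequential only for values landing exactly on a cutoff, which
the test suite probes with `nextafter`.  Negative index values (net
end-of-life credits) grade A with a logged warning rather than erroring,
since LCA credits are legitimate; thresholds are config-overridable and every
grade records the thresholds it was computed with.  The index is stored raw;
the ×10³ "milli" rendering exists only for reporting (score medians are
conventionally printed on that scale) and never feeds the grader.

## Validation statistics

* **Distribution summaries** report per-group median and IQR under
  linear-interpolation quantiles (the default of mainstream statistical
  environments); the convention is recorded in the output because published
  IQRs rarely disambiguate it.
* **Weighted Cohen's kappa** uses disagreement weights `|i-j|/(K-1)`
  (linear, the default), `((i-j)/(K-1))^2` (quadratic) or 0/1 (unweighted):
  `kappa = 1 - sum(w O) / sum(w E)` with O observed and E chance-expected
  cell proportions.  Linear is the default because the grade scale is
  ordinal with plausibly equidistant steps; the scheme is configurable since
  agreement studies frequently fail to state theirs.  The p-value for
  H0: kappa = 0 uses the large-sample normal test on the null-hypothesis
  variance (Fleiss–Cohen–Everitt); an exact permutation p-value is available
  and preferable at the n ≈ 20 scale typical of expert panels.  A table with
  all mass in one category has undefined kappa; it is reported as 1 when
  observed agreement is also perfect.
* **Correlation matrices** default to Pearson (configurable to Spearman) via
  pandas; constant variables are rejected rather than yielding NaN cells.

## Synthetic data

The generator emulates *characterized* impact tables, not LCA inventories.
A basket item is built as `e_c = t * NF_c * L_c`, where `L_c` is log-normal
composition noise (sigma 0.4 on the log scale) around the bundled per-capita
reference profile and the vector is rescaled so the item's EFSI equals its
ladder value `t` exactly.  The 23 default ladder values are log-spaced over
4e-5 – 2e-2, which provably places at least one item in every grade; product
names follow a typical European basket ordered by per-kg impact (water and
sugar low, ruminant meat high).  Per-capita consumption is log-normal
(median 25 kg/yr, sigma 0.8), scaled by the population.

Hypothetical variants apply multiplicative scenario factors: air freight
strongly inflates the fossil-energy-driven categories (CC ×14, POF ×12,
RUe ×12, RI ×5, others ×1.5), long-distance lorry a milder version of the
same profile, a water-stressed origin inflates only WS (×6), heated
greenhouses CC/RUe (~×2.5), and production-method tweaks (organic,
intensive) stay near unity.  These constants are invented for ordinal
realism — air transport can move a product two or more grades, production
method at most one — and do not claim to reproduce any measured dataset;
tests assert grade shifts, not magnitudes.  Variants are deterministic
multiples of their base by default (`jitter_sigma = 0`), which is what makes
the monotonicity property (all multipliers ≥ 1 never lower the grade) exact;
the dataset generator adds mild jitter (sigma 0.15) for diversity.  The
default study-scale dataset is 21 products × 5–9 variants (~150 items, 149
in the reference study design).  `delphi_fixture` builds paired A–E labels
with a controlled exact-agreement rate and adjacent-grade disagreements, the
structure typical of expert-panel near-misses.

What passing tests on synthetic data do *not* show: real impact tables have
category correlations induced by shared supply-chain structure (the
generator's composition noise is independent across categories), discrete
origin/transport mixtures rather than smooth log-normals, and genuinely
negative entries from packaging credits.  Structural properties
(self-consistency, linearity, grade monotonicity, agreement arithmetic) are
data-independent; distributional realism is not claimed.

## Numerical choices

* The self-consistency identity (basket scored under its own NFs equals
  1.0002 per capita) holds to 1e-9 relative and is the primary correctness
  oracle tying normalization to aggregation.
* CSV floats are written with `%.17g` and parsed with Python's
  correctly-rounded `float()`, so write/read round-trips are bit-exact and
  identical runs produce byte-identical outputs (pandas' fast CSV parser is
  deliberately bypassed for numeric columns).
* Missing impact categories are an explicit state; scoring refuses
  incomplete vectors unless the caller opts into `ImpactVector.filled(0)`,
  which logs, because silent zeros bias scores low.

## Reproducing published reference statistics

The per-item basket tables behind the bundled NF column, the ~150-item
variant inventories and the expert categorizations live in the original
study's supplementary spreadsheets, which are not redistributable here.
`tests/test_acceptance.py::test_paper_supplementary_reproduction` implements
the full recomputation (NF column, milli-scale score medians, index/WS
correlations, within-product agreement kappas with and without air-freight
items) against CSV conversions placed under `data/supplementary/`
(`sp2_basket.csv` in the basket schema, `sp3_items.csv` in the impacts
schema, `sp1_ec_scores.csv`, `sp1_representative_grades.csv`); without those
files the test fails by design rather than silently passing.  The expert
panel's own kappa (0.642) is not recomputable even with the supplement: the
individual expert labels were never published and the printed contingency
percentages admit no consistent integer counts for n = 22.

## Known limitations

* The EC Single Score path depends entirely on user-supplied reference
  tables; no cross-index comparisons are possible out of the box.
* Scenario multipliers are package constants, not fitted to data.
* The asymptotic kappa p-value is anti-conservative below n ≈ 30; use the
  permutation option there.
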