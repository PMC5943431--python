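# Methods

## The model

`lifeyears` quantifies the human cost of slow oncology drug development
with a deterministic product model. For one drug–tumor example let

- Δs — the incremental gain in *median* overall survival demonstrated by
  the pivotal randomized trial, in years;
- E — the eligible population: annual deaths from the malignancy
  (North America or worldwide), optionally restricted to a biomarker- or
  histology-defined subgroup;
- T — the development interval: time from drug discovery (US patent
  application as surrogate) to FDA marketing approval, in years;
- T\* — a counterfactual development interval;
- p — the fraction of eligible patients actually treated.

Then, per example and region:

    L   = p · Δs · E              life-years gained per year of earlier availability
    LYL = L · T                   life-years forgone during development
    S   = L · max(0, T − T*)      life-years saved had development taken T* years

The portfolio result is the collection of row results plus summaries
(median under two conventions, min, max, cumulative sum) per metric and
region.

### Assumptions and what the numbers mean

The product model assumes (i) every eligible patient would have received
the drug the moment it was approved (relaxed linearly via p), (ii) the
trial's median-survival gain transfers unchanged to the whole eligible
population and to every year of the development interval, and (iii)
annual death counts are stationary over that interval. None of these
hold exactly in the real world; the outputs are therefore upper-bound
*illustrations* of scale, not forecasts. Because each output is a plain
product, every assumption violation scales the result multiplicatively —
which is why the treated-fraction knob is exposed as a first-class
parameter rather than folded into the inputs.

## Eligible populations and subgroup adjustment

Where a therapy benefits only a tumor subgroup, the eligible pool is the
site-level annual death count times a published subgroup prevalence
(`derive_eligible`, rounded half-away-from-zero to a whole person):
NSCLC = 85% of lung cancers (squamous 25%, nonsquamous 60%), HER2+
breast = 20% of breast cancers, EGFR+ colorectal = 97%, HER2+ gastric =
21%, BRAF-mutant melanoma = 50%, squamous head/neck = 90%.

The packaged registry (`"paper-2018"`, 27 examples of
survival-prolonging therapies approved 1998–2015) stores the *published*
eligible counts as authoritative and the site totals + fractions as
secondary derivation inputs, because a handful of published cells are
not exact products of other published cells (two colorectal totals
differ by ~0.9%; one lung-subset count by ~13%). Validation compares the
stored count against the derivation and warns above a 15% relative
mismatch; nothing in the packaged registry exceeds that.

## Date arithmetic

Discovery dates are approximate: `ApproximateDate` carries a year and an
optional month. The development interval is

- month resolution at both ends: months difference / 12, rounded
  half-up to one decimal (computed in exact integer arithmetic, so ties
  like 105/12 = 8.75 → 8.8 never depend on binary representation);
- year resolution at either end: whole-year difference.

Ordering respects resolution: a year-only date is never "provably
earlier" than a month date in the same year, so such pairs pass the
date-inversion check.

These rules reproduce 26 of the 27 published intervals exactly. The one
exception (vemurafenib: computed 6.7 vs published 6.8) is unreachable by
any uniform rounding rule, so the registry keeps the published value as
`duration_override_years`; overrides always take precedence over
computed durations. The packaged registry stores the published interval
as an override for every row, pinning the analysis to the published
acceptance surface while the date columns remain independently testable.

## Rounding policy

All model arithmetic runs in full double precision; integers appear only
at presentation boundaries (reports, summaries quoted as whole
life-years), rounded half-away-from-zero. Before rounding, values are
snapped to six decimals so representation dust (0.23 × 24050 =
5531.499999…) cannot flip a half tie. An alternative
`presentation-integer` mode rounds row results as they are computed, for
consumers that want table-ready integers. Full precision plus terminal
rounding reproduces more published cells than any scheme that rounds
intermediates.

## Two median conventions

Published portfolio tables of this kind do not always use the textbook
median. The package computes both and every report labels them:

- `median_standard` — middle element (odd n) or mean of the two middle
  elements (even n);
- `median_paper` — the ⌊n/2⌋-th smallest value (1-based), a lower-middle
  order statistic that matches the per-row "Median" lines of the
  registry's source tables (e.g. 79,920 worldwide life-years per year;
  1,020,900 worldwide life-years lost), while the standard convention
  matches the 5-year-counterfactual headline (43,981 for North America).

Neither convention alone reproduces every published headline, which is
precisely why both are first-class. `AnalysisConfig.median_convention`
only selects which one headline reports quote.

## The synthetic generator

`generate_registry` draws registries for pipeline testing: gains uniform
on [0.10, 1.40] years (2-decimal precision, matching registry storage),
North-American site deaths uniform on [10³, 2×10⁵] and worldwide on
[2×10⁴, 1.5×10⁶] per year, subgroup fractions from the prevalence set
{1.0, 0.85, 0.60, 0.50, 0.25, 0.21, 0.20}, and development intervals of
6–24 years built *backwards* from a uniform approval month by an integer
number of months — so the month-arithmetic duration provably lands in
range. Eligible counts are set to `derive_eligible(site_deaths,
fraction)`, making every generated registry validation-clean. Sampling
is uniform and fields are independent by design: the generator's job is
structural coverage of the pipeline (signs, ranges, resolutions, key
uniqueness), not epidemiological realism — it has no correlation between
gain and mortality, no survival curves, and no approval-era trends, so
green tests on synthetic data certify the arithmetic and plumbing, not
real-world calibration. Draws are made row by row in a fixed field
order from a single seeded generator, so the first k rows are identical
for any n ≥ k. `perturb_registry` multiplies each row's gain and
regional death counts by independent uniform factors from [1−ε, 1+ε]
(full float precision retained), so a per-year value moves by at most
(1+ε)² − 1.

## Numerical and design choices

- Registry order is preserved everywhere; no sorting on load; row
  identity is the (drug, site, subgroup) triple, which must be unique.
- Errors (negative quantities, provable date inversions, duplicate keys,
  empty table) block analysis; derivation mismatches only warn.
- `target_years` may exceed a row's interval; savings clamp at zero.
- Treated fraction applies at the per-year stage, so every downstream
  quantity scales linearly (tested as an invariant).
- Problem sizes in the test suite: property checks run on 1,000-row
  synthetic registries, distributional checks on 10,000 rows — large
  enough to exercise the ranges densely while keeping the default suite
  a few seconds.

## Known limitations

- No uncertainty propagation: survival gains and death counts are point
  estimates; the model is a product of them, so there are no intervals,
  tests, discounting, quality adjustment (QALY), or age-structured
  life-table corrections.
- US approval dates stand in for worldwide approval, which understates
  worldwide delay; the patent-application surrogate can overstate the
  plausibly compressible interval.
- The subgroup adjustment assumes subgroup mortality is proportional to
  prevalence.
- Two published summary numbers are internally inconsistent with their
  own published row cells (the worldwide 5-year-counterfactual median
  and the worldwide cumulative life-years lost); the package reproduces
  the self-consistent quantities and documents, rather than matches,
  those two.
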