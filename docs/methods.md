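# Methods

## Case/non-case model

The analysis treats a spontaneous-report database as a multinomial sample
of reports over the 2×2 partition defined by "mentions the target drug"
× "mentions an event in the category". Disproportionality is measured by
observed-to-expected statistics on that table:

* **Information component (IC).** With `E = n_Drug·n_Event/n_Total` the
  shrunk IC is `log2((a+0.5)/(E+0.5))` (bits). The +0.5 terms are the
  shrinkage transformation: they bound the statistic at small counts,
  define it at `a = 0`, and preserve the sign of the raw log-ratio
  (`IC > 0 ⇔ a > E`, asserted by a property test) while attenuating its
  magnitude.
* **Reporting odds ratio (ROR).** The Haldane–Anscombe-corrected odds
  ratio `((a+0.5)(d+0.5))/((b+0.5)(c+0.5))` with the Woolf (log-normal)
  95% interval computed on the corrected cells. An alternative
  "as-printed" variant — the shrunk observed/expected ratio itself,
  identical to `2^IC` — is selectable (`ror_variant="as-printed"`); it is
  not the default because the corrected odds ratio, not the O/E ratio, is
  what reproduces the published carfilzomib interval estimates (the total
  row's 2.02 with Woolf bounds 1.95–2.10 on the reconstructed table,
  whereas `2^0.90 ≈ 1.87`).
* **Signal rule.** `IC025 > 0` and `ROR025 > 1` and `a ≥ 3`, all strict:
  a bound exactly on its threshold is not a signal. Each criterion is a
  one-sided 2.5% test, so the joint rule is conservative; no further
  multiplicity correction is applied — shrinkage is the stated
  false-positive control of this family of methods.

### IC interval methods

Two interval methods are implemented and config-selectable:

* `approximation` (default): the standard shrinkage-IC asymptotic bounds
  `IC025 ≈ IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2` and
  `IC975 ≈ IC + 2.4(a+0.5)^−1/2 + 0.5(a+0.5)^−3/2`.
* `gamma`: quantiles of the gamma posterior of the Poisson rate with
  shape `a + 0.5` and the shrunk denominator, i.e.
  `log2(Q_γ(p; a+0.5)/(E+0.5))`.

On the reconstructed total carfilzomib row the two methods give IC025 of
0.8438 and 0.8515 respectively (published: 0.85), and neither reproduces
the published IC975 of 0.96 (both give ≈0.94); published interval bounds
of this kind are therefore not used as exact anchors anywhere — only the
point estimates and the Woolf ROR bound are. Signal decisions agree
between the two methods on every reconstructed row.

### Reconstruction from published marginals

`reconstruct_table(a, n_drug, n_total, ror)` recovers the comparator
event count `c` by a scalar root-solve of the corrected odds ratio and
rounds it to an integer (the rounding perturbs the recomputed statistics
by < 10⁻⁴). This makes published summary rows — which report only `N`,
IC, ROR and the drug/database totals — fully recomputable, and is what
`scripts/acceptance.py` uses.

## Record cleaning

* **Dedup key**: sex, age truncated to integer years (source databases
  mix age units; truncation stabilizes the key), country, event date,
  reporting year, the *set* of (normalized drug name, start date, end
  date) triples, the set of normalized reaction PTs, and the outcome-code
  set. Drug-name normalization case-folds, collapses whitespace and
  strips common salt suffixes. Records missing *any* key component are
  never merged (missing ≠ missing); among complete keys the first record
  in input order survives. The operation is idempotent, and permuting the
  input changes which representative survives but never the counts.
  Binding each start/end date to its drug (triples rather than parallel
  sets) is marginally stricter than comparing the field sets
  independently; it is deterministic and makes verbatim-copy duplicates
  exactly countable.
* **Aberrant dates**: a record is excluded iff the earliest target-drug
  start date and the event date are both present and start > event
  (strict; start = event is a valid time-to-onset of zero). The earliest
  start across multiple target-drug entries anchors both this rule and
  time-to-onset.
* **No imputation** anywhere; every percentage downstream is reported
  against its own "data available" denominator.

## Synthetic report generator

The generator emulates the structure the cleaning and disproportionality
stages assume: multi-drug multi-reaction reports with demographics,
dates, outcomes, exact-key duplicates, aberrant date orderings and
field-level missingness, plus configurable drug–event association
multipliers with a closed-form ground truth.

Per base report: reaction PTs are independent Bernoulli draws from their
marginal probabilities; each drug is then included independently with
probability `clip(p_drug · Π λ(drug, cat), 1)` over the event categories
present on the report, and if no drug is drawn one is drawn from the
tilted probabilities (polypharmacy with a minimum of one drug; the drug
count is Poisson-binomial rather than an explicit Poisson draw, which is
what makes the ground truth exactly computable). Because the multiplier
tilts *drug* inclusion given the events, λ is a reporting-rate ratio
whose implied observed/expected ratio tends to λ as the pair becomes
rare; the exact cell probabilities for any pair are obtained by
enumerating the presence pattern of the "active" categories (those named
in any multiplier), which must have disjoint PT sets for the pattern
probabilities to factorize — overlap among *active* categories raises a
configuration error (non-active categories may overlap freely).
`ground_truth_pair` returns these cell probabilities and the implied IC;
λ = 1 yields IC = 0 exactly, and a brute-force simulation oracle at n =
10⁶ confirms the closed form in the test suite.

Dates: event dates are uniform over the configured window
(2015-01-01 … 2019-12-31 by default, matching a five-year study window);
drug start dates precede the event by a log-normal lag (median 41 days,
σ = 1.5 — chosen to reproduce the right-skewed onset distribution with
its published median and roughly its quartile spread — truncated at
3650 days to keep dates in-range and spans physiologic); receipt dates
follow the event by 0–60 days so the reporting year is always present.
Default demographics approximate the published cohort (55% male, age
≈ N(67, 10) clipped to 1–95 and rounded, country mix led by the US) and
default missingness rates mirror the published "data available"
denominators (sex 14%, age 30%, dates 25–40%, outcome 10%).

Injected artifacts: `round(aberrant_fraction·n)` base reports get the
target drug forced present with start strictly after the (non-missing)
event date; `round(duplicate_fraction·n)` extra reports are verbatim
copies — every dedup-key field identical, fresh identifier — of base
reports whose key fields are all present (so each copy is removable by
the dedup rule by construction). Duplicate sources exclude aberrant
records, which keeps the two removal counts exactly separable regardless
of stage order. Ledger counts assume no accidental key collisions among
distinct base reports; with continuous date lags the collision
probability is negligible at the configuration sizes used.

The generator does **not** model reporter behavior (stimulated
reporting, notoriety effects), country-specific reporting cultures,
indication fields, or sex/age-dependent association strengths (tests
that need subgroup-specific effects compose several generated streams).
Passing tests therefore demonstrate statistical correctness of the
pipeline under a known sampling model, not robustness to the biases of
real spontaneous data.

## Simulation study conditions

Chosen from the closed-form ground truth when the condition itself fixes
only part of the design:

* **Null calibration**: λ = 1 everywhere, 500 replicates of 50,000
  reports, watched pair with drug marginal 5% and category marginal
  ≈ 2% (expected pair count ≈ 52 ≥ 20); the signal rule must fire in
  ≤ 5% of replicates.
* **Parameter recovery**: λ = 4 on a rare event (single PT, marginal
  0.5%), target-drug marginal 10% against a dense 12-drug background
  (fallback share < 3%), 200 replicates of 200,000 reports. The
  ground-truth IC for this configuration is 1.977 bits (the gap to
  log2 4 = 2 is the event-marginal correction λ/(1+q(λ−1)) and the small
  fallback dilution), and the mean shrunk IC must lie within ±0.05 bits
  of both log2 4 and the ground truth. The expected case count (≈ 400)
  keeps shrinkage bias near 0.005 bits.
* **Oracle equivalence**: on 100 generated 5,000-report sets, the
  vectorized 2×2 cells and estimates must equal a per-report brute-force
  recount.

These sizes keep the full suite at roughly six minutes on one core.

## Other numeric conventions

* Quantiles: linear interpolation between order statistics (the numpy
  default); pinned by a test, changing it is a breaking change.
* Early-onset windows: "first month/three months" = ≤ 30 / ≤ 90 days;
  calendar-month arithmetic on durations is ill-defined.
* Outcome severity precedence for multi-coded records: death >
  life-threatening > disability > hospitalization > congenital anomaly >
  required intervention > other serious; each record contributes to one
  level so outcome columns sum to the available denominator.
* Time-trend analyses use cumulative-through-year subsets, so interval
  widths are non-increasing over years.
* Stratification defaults to sex × (<65 / ≥65 years), the conventional
  geriatric cutoff; configurable. Per-category analyses keep reports of
  other categories in the background (the "non-case" set is the full
  complement), and the restricted-background sensitivity analysis reruns
  the identical computation on a predicate-selected subset.
* Per-category case counts may sum to more than the total-cardiovascular
  count: a report belongs to every category with a matching PT and once
  to the union.

## Known limitations

* PT matching is exact on normalized strings at PT level; no HLT/HLGT
  traversal and no broad-SMQ algorithmic terms.
* The dedup rule is the stated key rule, not probabilistic record
  linkage or case-version reconciliation.
* The published IC975 values cannot be reproduced exactly by either
  implemented interval method (see above); they are documented, not used.
* Figure-shaped outputs are emitted as delimited tables; no plot
  rendering is included.
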