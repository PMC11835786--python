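# Methods

## Scope and pipeline

`nutrirank` implements a deterministic recommendation pipeline for daily
catering menus: contextual prefilter → three component scorers → fixed-weight
hybrid combination → explanation payloads. Nothing is learned or fitted; all
parameters are configuration, which makes every ranking exactly reproducible
and every explanation exactly re-derivable.

## Nutrients and units

Twelve nutrients are scored, stored **per portion**: fiber (g), vitamin A
(µg RE), vitamin B12 (µg), vitamin C (mg), monounsaturated fat (g),
polyunsaturated fat (g), protein (g), total fat (g), calcium (mg), iron (mg),
saturated fat (g), carbohydrate (g); energy (kcal) is carried for display
only. Per-portion storage is deliberate: both the intake arithmetic and the
weighting operate on consumed portions. Menu CSVs may instead supply
per-100 g columns together with an explicit `portion_g` column; conversion
happens at load.

## FFQ intake estimation and status classification

Daily intake is standard food-frequency arithmetic: per answered item,
frequency/day × portion multiplier × standard portion (g) / 100 × nutrient
content per 100 g, summed over items. The estimate is linear in frequencies
and permutation-invariant over answers.

Each nutrient is classified against a daily reference range: intake strictly
below the lower bound → **Low**, strictly above the upper bound → **High**,
otherwise **Normal**. The bounds classify as Normal on purpose: a user at
exactly the recommended intake should not be flagged. The shipped ranges
(`nutrirank/data/reference_ranges.yaml`) are editable, population-agnostic
placeholders in dietary-reference-value style — e.g. fiber [25, 45] g/day,
calcium [800, 2500] mg/day — and are **not clinical guidance**; deployments
must substitute population-appropriate values.

Food-group contribution analysis attributes one macronutrient's total intake
(carbohydrate, protein or total fat) to ten food groups (vegetables, fruit,
potatoes/rice/pasta, bread/savory biscuits, dairy, meat/fish, fats/spreads,
sweets/snacks, drinks, other); the top group is the argmax with an
alphabetical tie-break, and zero total intake is an error rather than a
silent 0/0.

## Prefilter

Passes run in fixed order — location equality, allergen safety, lifestyle,
recency — and the first triggering reason is logged per excluded meal, so
candidates plus log always partition the menu.

* **Allergens**: a meal is unsafe if any meal- or ingredient-level allergen
  tag intersects the user's allergies. In strict composite mode (default) a
  meal containing an unresolved composite ingredient ("house sauce",
  constituents unknown) is unsafe for *any* allergic user: unknown equals
  unsafe. Lenient mode trusts the declared tags.
* **Lifestyle**: the preference vocabulary is split into required diet tags
  (vegan, vegetarian, halal, kosher — the meal must carry them) and avoidance
  tags (everything else — the meal must not carry the tag nor contain an
  ingredient of that name). The split reflects how caterers tag meals; an
  avoidance like "coriander" is an ingredient, not a meal label, so
  ingredient names are checked too.
* **Recency**: a meal is excluded if it appeared in the user's shown
  recommendation lists within the previous 3 calendar days (window
  `[today − 3, today − 1]`; same-day records don't count). The source is
  configurable (recommendations, orders, or both) because either reading is
  defensible; shown recommendations is the default.
* **Variety fallback**: if fewer than `min_candidates` (default 3) meals
  survive, recency exclusions are restored most-stale first. Safety and
  lifestyle exclusions are never restored — an empty screen is preferable to
  an unsafe suggestion.

Tags are lowercase with internal spaces preserved; matching is exact after
normalization. The two controlled vocabularies ship with the package (34
allergen tags, 31 preference tags) and unknown tags are rejected at load.

## Scoring

* **Normalization**: per nutrient, min–max over the post-filter candidate set
  (not a global archive) — today's options should be compared against each
  other. A constant column maps to 0.5: no information, neutral.
* **Knowledge**: raw score = Σ weight(nutrient, status) × normalized amount;
  the raw scores are then min–max rescaled to [0, 1] across the candidates
  (constant → 0.5). Rescaling across candidates rather than by a theoretical
  maximum preserves the ranking (which is what the 65% weight acts on) and
  avoids profile-dependent score compression. The default weight table gives
  deficient nutrients positive pull (fiber/vitamin C/calcium 5 when Low),
  over-consumed ones a discount (−0.5 to −1 when High), total fat a uniform
  −1, and Normal always 0.
* **Content**: taste vector from events (+1 per ingredient per order or
  thumbs-up, −2 per explicitly disliked ingredient on a thumbs-down; the −2
  makes one explicit dislike outweigh a single like, since negative feedback
  is rarer and stronger). Cosine with the meal's binary ingredient vector,
  affinely mapped from [−1, 1] to [0, 1]; a cold (zero) vector or
  ingredient-less meal is neutral 0.5.
* **Collaborative**: order-count vectors per user, cosine similarity, top
  k = 5 neighbours with alphabetical user-id tie-break; the score is the
  fraction of neighbours who ever ordered the meal. The component returns 0
  for every meal until 14 days of order history exist (counting the first
  order's day as day 1) or while the user has no orders: a constant shift is
  rank-neutral, and keeping the weights fixed preserves the 65/25/10
  semantics at all times rather than renormalizing during cold start.
* **Combination**: final = 0.65·knowledge + 0.25·content +
  0.10·collaborative (configurable; weights must be non-negative and sum to
  1 within 1e-12). Descending sort; ties broken by higher knowledge score,
  then lexicographic meal id. All tie-breaks are deterministic, so identical
  inputs give identical rankings across runs and platforms.

A fully neutral user (all-Normal profile, no history) therefore scores every
meal 0.65·0.5 + 0.25·0.5 + 0.10·0 = 0.45.

## Explanations

Three payloads per recommendation, fixed order: nutritional alignment, past
choices, popularity. Strings come from per-locale template files with the
configured percentages injected at render time, so reconfiguring the hybrid
weights changes the rendered "65%"/"10%" consistently. Every number in a
payload is recomputable from the scoring context (weight × normalized amount
rows summing to the raw knowledge score; pairwise ingredient cosines for the
top-3 similar past meals; neighbour count and ordered fraction), and the test
suite asserts this by re-parsing payloads. Percentages render as integers;
internal values stay exact. Before collaborative activation, the popularity
payload says so instead of showing a vacuous 0.

## Synthetic data

The generator emulates a workplace deployment: a pool of 40 distinct meals
drawn from a 37-ingredient catalogue (with realistic allergen tags), 10–20
meals offered per day over 35 days by default, ~15% vegan meals, an allergy
prevalence of 0.3, 7 weeks of order/feedback logs with ~0.75 orders per user
per day, and baseline + post FFQ responses over a ≥ 50-item bank spanning all
ten food groups with plausible food-composition-style per-100 g values
(hard-coded ranges; synthetic, not measured).

Profile planting is analytic, not statistical: the item bank includes one
pure single-nutrient "concentrated source" item per nutrient (ids prefixed
`conc_`); a random multi-item base response is scaled until every Low-target
nutrient sits below its bound, then each Normal/High nutrient is topped up
through its concentrated item to the range midpoint (Normal) or 1.25× the
upper bound (High). Because the concentrated items touch no other nutrient,
`classify_status(compute_intake(...))` recovers the planted profile exactly,
by construction — recovery failures indicate an implementation defect, not
noise. Taste planting biases daily meal choice 4:1 toward meals containing
the user's preferred ingredients.

Randomness comes from one seed split into four independent streams (menus,
users, FFQ, orders), so the same config is byte-identical on re-run and
adding users does not perturb menus.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: real food-composition correlations between nutrients,
FFQ measurement error and under-reporting, participant drop-out, menu
seasonality, and any correlation between a user's nutritional profile and
their taste. Results on synthetic worlds validate the mechanics of the
engine, not its behavioural impact.

## Numerical choices and degenerate inputs

Min–max with zero span → 0.5 everywhere; zero taste vector → content 0.5;
zero total macronutrient intake → explicit error; empty candidate set after
filtering → explicit error (the CLI exits 2); missing scored nutrient or
unknown vocabulary tag → validation error naming the offender; unknown meal
ids in event logs → warning and skip. Boundary intakes classify Normal.
Comparisons in tests use absolute tolerance 1e-12 where arithmetic is exact
up to floating point.

## Problem sizes

Default test and verification sizes: 12–100 synthetic users, 2–35 days,
menus of 10–20 meals, 200 random small menus (≤ 6 meals) for the brute-force
ranking-oracle comparison, 100 seeded users for profile recovery. These sizes
exercise every code path while keeping the full suite and the acceptance
script comfortably fast on one CPU.

## Limitations

* Reference ranges and the FFQ item bank are synthetic stand-ins; no claim
  of clinical validity.
* The content model is bag-of-ingredients; portion sizes and preparation are
  invisible to it, and composite ingredients without declared constituents
  reduce both matching quality and (in lenient mode) safety.
* No diversity re-ranking beyond the recency rule: a strongly deficient
  profile yields similar recommendations day after day by design.
* The collaborative component uses raw co-ordering; it does not model
  healthiness, which is precisely why its weight is capped at 10%.
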