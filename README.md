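# nutrirank

An explainable hybrid recommender for healthy meal choices in workplace
catering. Given a day's menu, a user's allergies and lifestyle preferences,
their food-frequency-questionnaire (FFQ)–derived nutrient-status profile, and
the site's order/feedback history, `nutrirank` ranks the menu and attaches
three recomputable explanations to every recommendation.

## Who this is for

Caterers and nutrition researchers who want to steer employees toward meals
that address *their* nutritional gaps — not just what is popular or what they
already like — while keeping every recommendation safe (allergen filtering),
varied (recency filtering) and transparent (explanations whose every number
can be re-derived from the scores).

## The model

A candidate meal's final score is a fixed convex combination of three
component scores, each in [0, 1]:

```
final = 0.65 · knowledge + 0.25 · content + 0.10 · collaborative
```

**Knowledge-based (65%).** An FFQ plus a food-composition table gives the
user's estimated daily intake per nutrient,

```
intake[n] = Σ_items  freq/day · portion multiplier · portion g / 100 · content per 100 g,
```

classified Low / Normal / High against per-nutrient reference ranges
(strictly below the lower bound → Low, strictly above the upper → High,
bounds inclusive → Normal). A weight table maps each (nutrient, status) to a
scoring weight — e.g. fiber when Low carries weight 5, polyunsaturated fat
when High carries −0.5, Normal is always 0 — and the meal's raw knowledge
score is the weighted sum of its min–max-normalized nutrient amounts across
the day's candidates, rescaled to [0, 1].

**Content-based (25%).** Orders and thumbs-up add +1 per meal ingredient to
the user's taste vector; a thumbs-down adds −2 to the explicitly disliked
ingredients. The component is the cosine similarity between the meal's binary
ingredient vector and the taste vector, mapped to [0, 1].

**Collaborative (10%).** Among the user's k = 5 nearest neighbours (cosine
over meal-order-count vectors), the fraction who ever ordered the meal.
Inactive — 0 for every meal, hence rank-neutral — until 14 days of order
history exist.

Before scoring, a contextual prefilter removes unsafe and irrelevant meals:
location mismatch, allergen matches (conservatively treating meals with
unresolved composite ingredients as unsafe for allergic users), lifestyle
violations (required diet tags such as `vegan` vs. avoidance tags such as
`coriander`), and meals recommended in the previous 3 calendar days.

## Worked example

Generate a synthetic 10-user, 4-week deployment and recommend:

```bash
$ nutrirank simulate demo --seed 7 --n-users 10 --n-days 28
wrote 28 menus, 10 users, 206 orders to demo

$ nutrirank recommend u003 2022-02-07 --data-dir demo
Top recommendations for u003 on 2022-02-07:
  1. dish 023 [meal023] nutriscore=D final=0.8769
  2. dish 038 [meal038] nutriscore=B final=0.5679
  3. dish 028 [meal028] nutriscore=B final=0.5569
  4. dish 007 [meal007] nutriscore=E final=0.5093
  5. dish 021 [meal021] nutriscore=D final=0.5093
```

The final scores are the 0.65/0.25/0.10 mixture; `--out-csv` writes the
component breakdown per meal. Asking *why* the top meal was recommended
prints the three explanation payloads:

```bash
$ nutrirank explain u003 2022-02-07 meal023 --data-dir demo
Your recommendations are 65% influenced by your nutritional profile.
  carbohydrate (Low): weight 3 x normalized amount 0.788 = +2.363
  iron (Low): weight 2 x normalized amount 1.000 = +2.000
  ...

Based on your previously chosen meals, we try to find similar recipes.
  meal019: similarity 0.316
  ...

The most popular meals are not always the healthiest meals. Therefore, the
popularity of a meal is only taken into account for 10%.
  4 of 5 similar users ordered this meal (80%).
```

Each nutritional row is the user's status, the table weight, the meal's
normalized amount and their product; the rows sum to the meal's raw knowledge
score. The percentages come from the configured hybrid weights, not from
hard-coded strings. `nutrirank profile u003 --data-dir demo` prints the
underlying intake estimates and Low/Normal/High statuses for all 12 scored
nutrients.

The same pipeline is available as a library (`nutrirank.apply_prefilter`,
`nutrirank.hybrid_rank`, `nutrirank.explain_all`, ...), and
`nutrirank.generate_toy_worked_example()` returns a 3-meal, 2-user bundle
whose every intermediate quantity is documented and hand-checkable.

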