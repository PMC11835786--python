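# English explanation templates. Percentages are injected from the configured
# hybrid weights at render time; no number is hard-coded in the engine.
nutritional_headline: "Your recommendations are {knowledge_pct}% influenced by your nutritional profile."
past_choices_headline: "Based on your previously chosen meals, we try to find similar recipes."
past_choices_cold: "You have no orders or liked meals yet, so this recommendation is based on your nutritional profile."
popularity_headline: "The most popular meals are not always the healthiest meals. Therefore, the popularity of a meal is only taken into account for {collaborative_pct}%."
popularity_inactive: "Meal popularity is not yet taken into account: the system needs {activation_days} days of order history first."
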