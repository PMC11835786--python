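# Nutrient scoring weights by intake status.
# "low" weights favour meals rich in nutrients the user lacks; negative "high"
# weights discount nutrients the user already over-consumes; "normal" is always 0
# (a nutrient at recommended intake neither promotes nor demotes a meal).
fiber:                {low: 5,  normal: 0, high: 0}
vitamin_a:            {low: 2,  normal: 0, high: 0}
vitamin_b12:          {low: 3,  normal: 0, high: 0}
vitamin_c:            {low: 5,  normal: 0, high: 0}
monounsaturated_fat:  {low: 1,  normal: 0, high: 0}
polyunsaturated_fat:  {low: 3,  normal: 0, high: -0.5}
protein:              {low: 3,  normal: 0, high: -0.3}
total_fat:            {low: -1, normal: 0, high: -1}
calcium:              {low: 5,  normal: 0, high: 0}
iron:                 {low: 2,  normal: 0, high: 0}
saturated_fat:        {low: 0,  normal: 0, high: -1}
carbohydrate:         {low: 3,  normal: 0, high: -0.5}
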