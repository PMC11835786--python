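# Daily intake reference ranges used to classify each nutrient Low/Normal/High.
# NON-CLINICAL PLACEHOLDERS in dietary-reference-value style for a generic adult;
# edit per population before any real use. Intake strictly below "lower" -> Low,
# strictly above "upper" -> High, otherwise (bounds inclusive) -> Normal.
# Units per day: fiber g, vitamin_a ug RE, vitamin_b12 ug, vitamin_c mg,
# fats/protein/carbohydrate g, calcium mg, iron mg.
fiber:                {lower: 25,   upper: 45}
vitamin_a:            {lower: 600,  upper: 3000}
vitamin_b12:          {lower: 2.4,  upper: 100}
vitamin_c:            {lower: 75,   upper: 1000}
monounsaturated_fat:  {lower: 15,   upper: 45}
polyunsaturated_fat:  {lower: 8,    upper: 25}
protein:              {lower: 50,   upper: 130}
total_fat:            {lower: 45,   upper: 95}
calcium:              {lower: 800,  upper: 2500}
iron:                 {lower: 8,    upper: 45}
saturated_fat:        {lower: 5,    upper: 22}
carbohydrate:         {lower: 130,  upper: 340}
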