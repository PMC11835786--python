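coriander
taurine
coloring
sulfur
phosphate
caffeine
nitrates
sorbates
alcohol
poultry meat
blackened
halal
beef
benzoates
kosher
acesulfame e962
vegan
aspartame e951
lamb
sweetener
preservative
pig meat
antioxidant
genetic modified
flavor enhancer
glutamate
quinine
vegetarian
carrot
cacao
propionates
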