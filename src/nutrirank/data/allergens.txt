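barley
fish
lupine
mollusk
corn
wheat
sulfides
gluten
brazil nuts
shellfish
mustard
sunflower seeds
egg
hazelnuts
celery
spelt
pistachio nuts
macadamia nuts
nut
lactose
poppy seeds
pecan nuts
rye
milk dairy
sesame
oats
walnuts
peanut
legume pulse
khorasan wheat
cashews
soy
almonds
seeds
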