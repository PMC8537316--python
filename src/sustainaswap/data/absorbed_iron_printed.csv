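# Published estimated-absorption cells for the beef-comparison serves,
# used only to audit the fixture against the absorption model.
name,printed_absorbed_fe_mg
Beef,0.33
Pork,0.16
Lamb,0.22
Chicken,0.07
Egg,0.26
Salmon,0.11
White fish,0.1
"Beans, mixed",0.38
Chickpeas,0.31
Lentils,0.45
Baked beans,0.23
"Tofu, firm",0.46
"Tofu, silken",0.64
Mixed nuts,0.09
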