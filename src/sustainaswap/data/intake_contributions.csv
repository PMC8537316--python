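# Daily energy and protein contributions of commonly consumed foods in the
# pregnancy cohort; blank cells were not reported and load as 0.
food,energy_kj_per_day,protein_g_per_day
Rice,539,2.3
Pasta,518,4.5
Full-cream milk,281,3.4
Chocolate,271,
Yogurt,236,3.9
Chicken,199,4.6
Cakes,148,
Beef,142,6.4
Mixed dishes,131,1.9
Tropical fruits,123,
Lamb,,1.9
Fish,,2.2
Eggs,,1.6
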