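# Beef-comparison food table: one serve of each food carries the energy of a
# standard cooked beef serve (471 kJ / 65 g). Nutrients are per that serve.
# Retail serve weights are not published; each is derived from the GHG identity
#   serve_weight_retail_kg = per_serve_ghg / ghg_intensity,
# with the unrounded per-serve footprint recovered from the published
# weekly-serve pregnancy total divided by 270/7 serves, and GHG intensity per kg
# retail weight taken from the published text (beef 99.5, chicken 9.9, white
# fish 13.6) or from global life-cycle-assessment means otherwise (beef retail
# weight is fixed at 0.100 kg, the figure the published totals imply).
# The remaining per-kg intensities follow as per_serve_metric / retail_weight,
# so serve- and pregnancy-scale footprints reproduce the published values.
name,origin,serve_weight_cooked_g,serve_weight_retail_kg,energy_kj,protein_g,sfa_g,fiber_g,iron_mg,zinc_mg,calcium_mg,iodine_ug,folate_dfe_ug,ghg_kgco2e_per_kg,land_m2_per_kg,acid_gso2e_per_kg,eutroph_gpo4e_per_kg,water_l_per_kg
Beef,animal,65,0.1,471,20.2,1.2,0.0,1.7,5.1,5.2,1.1,0.0,99.5037037,326.2,318.8111111,301.3888889,34732.4963
Pork,animal,83,0.1174165901,471,23.7,0.6,0.0,0.8,2.0,3.3,0.7,36.6,12.1,17.11222628,140.3423358,75.13923358,65764.53777
Lamb,animal,49,0.06870043847,471,14.2,2.5,0.0,1.1,2.1,4.5,0.2,7.9,39.7,369.9043726,139.0254753,97.13669202,141969.9926
Chicken,animal,74,0.092442948,471,21.4,0.9,0.0,0.4,0.6,6.7,0.4,2.2,9.9,12.19971671,102.3373938,48.65864023,14168.24618
Egg,animal,81,0.08105321596,471,10.0,2.1,0.0,1.3,1.0,31.5,38.2,67.0,4.67,6.269315068,53.48109589,21.71869863,17908.77829
Salmon,animal,39,0.04489008451,471,11.4,1.6,0.0,0.6,0.2,3.9,3.8,0.0,13.63,8.432118644,66.07084746,235.6950424,41674.01377
White fish,animal,89,0.102369281,471,23.4,0.5,0.0,0.5,0.6,38.3,39.6,1.8,13.6,8.408193669,65.94860335,235.2774674,41604.98324
"Beans, mixed",plant,110,0.1115249328,471,7.1,0.1,6.8,2.2,0.9,47.5,0.6,74.0,1.79,15.45909091,21.89844156,16.94688312,22264.78714
Chickpeas,plant,101,0.1013863025,471,6.4,0.2,4.7,1.8,1.0,45.4,0.5,63.6,1.79,15.54742857,22.017,17.03057143,22389.55014
Lentils,plant,133,0.133250569,471,9.0,0.1,4.9,2.7,1.2,22.6,0.7,26.6,1.79,15.56521739,22.04423913,17.06336957,22425.00326
Baked beans,plant,133,0.133250569,471,6.5,0.1,6.9,1.3,0.7,51.7,2.0,66.3,1.79,15.52630435,21.98586957,17.005,22360.91348
"Tofu, firm",plant,94,0.09517112049,471,11.3,0.9,3.3,2.7,1.6,300.0,2.7,28.1,3.16,3.459655172,6.592413793,6.102068966,5036.84931
"Tofu, silken",plant,210,0.2124941397,471,11.3,0.7,4.8,3.8,1.1,50.4,2.5,27.3,3.16,3.465019305,6.625019305,6.124787645,5055.328958
Mixed nuts,plant,18,0.01798330122,471,3.9,1.4,1.1,0.5,0.7,16.2,0.1,10.2,1.73,10.95666667,33.59083333,16.435,144438.565
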