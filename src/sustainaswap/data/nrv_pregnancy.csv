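# Pregnancy nutrient reference values (NHMRC): EAR = estimated average
# requirement, AI = adequate intake.
nutrient,kind,threshold
protein,EAR,49
dietary_fiber,AI,28
iron,EAR,22
zinc,EAR,9.0
calcium,EAR,840
folate_dfe,EAR,520
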