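# Nine Calpha-Calpha harmonic distance restraints bridging the PD and PDZ
# domains of the HtrA2 monomer, inferred from tryptophan-induced-quenching
# distance tendencies. k in kcal/(mol A^2).
res_a	res_b	target	k
I179	L398	26.00	1.0
A201	Y361	13.00	1.0
P225	Y361	13.00	1.0
P225	V364	13.00	1.0
M323	P384	25.00	1.0
M323	M365	9.00	1.0
F331	M365	12.00	1.0
V226	L367	8.00	1.0
F331	I373	10.00	1.0
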