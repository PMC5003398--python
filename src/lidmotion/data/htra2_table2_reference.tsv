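# Published reference distances (A) for the nine restrained pairs:
# the closed-state (inactive crystal, 1LCY) Calpha-Calpha distances, the
# restraint targets, and the distances reached by the authors' restrained
# optimization. Used as printed reference data for report layout and for
# the closed-state restraint-energy bookkeeping; not recomputed here.
res_a	res_b	d_closed	target	d_optimized
I179	L398	7.96	26.00	23.5
A201	Y361	8.44	13.00	14.6
P225	Y361	8.47	13.00	13.0
P225	V364	8.79	13.00	13.6
M323	P384	17.19	25.00	21.2
M323	M365	8.93	9.00	10.7
F331	M365	12.31	12.00	12.1
V226	L367	9.71	8.00	9.5
F331	I373	11.13	10.00	12.0
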