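# Domain topology of human HtrA2(Omi), author (deposition) numbering.
# Closed intervals "start-end". The mature construct spans residues 134-458;
# the protease domain (PD, chymotrypsin fold) and the PDZ lid are joined by
# a flexible linker that is unresolved in the inactive-state crystals.
pd_range: 150-343
linker_range: 344-358
pdz_range: 359-458

# Two perpendicular beta-barrel lobes of the PD (approximate boundaries).
n_barrel: 160-250
c_barrel: 251-332

# Catalytic triad His/Asp/Ser and the interface-opening reporter pair
# I179(beta2) - L398(beta15), whose Calpha-Calpha distance is the opening
# distance Delta.
triad: 198, 228, 306
opening_pair: 179, 398

# Sign-reference vector for the rotation axis: Calpha331 -> Calpha343,
# approximating the N->C direction of the C-terminal PD helix alpha4.
axis_reference: 331, 343

# Chymotrypsin-nomenclature loops. L3 (the regulatory sensor loop,
# beta8-beta9) and the linker are pinned by the deposition's unresolved
# spans; the remaining intervals are approximate defaults anchored on
# residues with known loop assignments (A197 in LB, P225/V226 in LC,
# V325/F331 in beta11-L2-beta12) and are user-overridable.
loop.LA: 168-177
loop.LB: 193-199
loop.LC: 219-227
loop.LD: 266-273
loop.LE: 203-208
loop.L1: 300-310
loop.L2: 321-332
loop.L3: 281-290

# Noncovalent hinges of the PDZ lid: clusters of interfacing residues.
# Hinge A: (beta11-L2-beta12)_PD with (beta14-alpha5)_PDZ (harbors V325).
# Hinge B: (beta5-LC-beta6)_PD with (beta13/alpha7)_PDZ (harbors V226).
hinge_a_pd: 320-332
hinge_a_pdz: 359-376
hinge_b_pd: 219-230
hinge_b_pdz: 418-430
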