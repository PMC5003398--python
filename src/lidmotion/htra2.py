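"""Reference facts about the human HtrA2(Omi) system.

Small, documented constants used by report layouts and bookkeeping checks;
everything coordinate-dependent lives in the packaged topology and
restraint files instead.
"""

#: residue span of the mature protease construct (after processing)
MATURE_CONSTRUCT: tuple[int, int] = (134, 458)

#: span kept in simulation models: the N-terminal IAP-binding motif
#: (134–138) is omitted as irrelevant to protease function
MODELED_SPAN: tuple[int, int] = (139, 458)

#: the PDZ-activating heptapeptide ligand
ACTIVATING_PEPTIDE: str = "GWTMFWV"

#: deposited crystal structures of the system: the inactive protease
#: (S306A), its hinge-B variant (V226K/S306A), and the lone PDZ domain
#: in complex with the activating peptide
DEPOSITIONS: dict[str, str] = {
    "inactive_protease": "1LCY",
    "hinge_b_variant": "5FHT",
    "pdz_peptide_complex": "2PZD",
}


def modeled_monomer_residue_count(with_ligand: bool = False) -> int:
    """Residues per modeled monomer: the modeled span, plus the activating
    heptapeptide when the ligand-bound complex is built."""
    lo, hi = MODELED_SPAN
    n = hi - lo + 1
    if with_ligand:
        n += len(ACTIVATING_PEPTIDE)
    return n
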