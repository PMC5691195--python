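"""Physical constants and unit conversions (single source of truth).

Internal mechanical units are pN, nm and K; free energies are reported in
kcal/mol.  1 pN nm = 1e-21 J, so 1 kcal/mol = 4184 J / N_A = 6.948 pN nm.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Boltzmann constant, pN nm K^-1.
KB_PN_NM = 1.380649e-2

#: Default absolute temperature (room temperature), K.
DEFAULT_TEMPERATURE = 298.15

#: pN nm per kcal/mol (4184 / 6.02214e23 * 1e21).
PN_NM_PER_KCAL_MOL = 6.9477

#: kcal/mol per pN nm.
KCAL_MOL_PER_PN_NM = 1.0 / PN_NM_PER_KCAL_MOL

#: Rosetta Energy Unit in kcal/mol (empirical calibration).
KCAL_PER_REU = 0.57

#: Contour length per amino-acid residue, nm.
NM_PER_RESIDUE = 0.35

#: Kuhn segments per residue mapping (~3.7 aa per 1.4 nm Kuhn segment).
RESIDUES_PER_KUHN = 3.7


def rt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kcal/mol at the given temperature."""
    return R_KCAL * temperature


def kt_pn_nm(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in pN nm at the given temperature."""
    return KB_PN_NM * temperature
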