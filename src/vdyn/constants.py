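"""Physical constants and package-wide defaults.

Units follow the conventions used throughout the package: coordinates in
Angstrom, energies in kcal/mol, temperatures in Kelvin, times in ns.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
BOLTZMANN_KCAL: float = 1.987204259e-3

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE: float = 300.0

#: Default snapshot interval between stored frames (ns); 10 ps.
DEFAULT_FRAME_INTERVAL_NS: float = 0.01

#: Flexible-loop residue ranges (sequence numbering, inclusive) that are
#: unresolved in the substrate-free CYP3A5 crystal structure and excluded by
#: default from deviation and essential-dynamics analyses.
CYP3A5_FLEXIBLE_LOOPS: tuple[tuple[int, int], ...] = ((260, 270), (280, 288))

#: Default offset between a 0-based array index and the CYP3A5 construct
#: sequence position (sequence position = array index + offset).
CYP3A5_NUMBERING_OFFSET: int = 25

#: Heavy-atom contact cutoff (Angstrom) for the fraction of native contacts.
NATIVE_CONTACT_CUTOFF: float = 4.5
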